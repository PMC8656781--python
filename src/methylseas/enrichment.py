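"""Hypergeometric over-representation analysis of miR target sets.

For a query target set of size n drawn from a universe of N genes, the
overlap k with a pathway of K members is tested against the hypergeometric
upper tail P[X >= k]; p-values are Benjamini-Hochberg adjusted across the
pathways tested for one miR.  The default universe is the union of all
pathway genes, overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["pathway", "k", "K", "n", "N", "p_value", "q_value"]


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}
        if not self.universe:
            u: set[str] = set()
            for members in self.sets.values():
                u |= members
            self.universe = frozenset(u)
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if not members <= self.universe:
                raise ValueError(f"gene set {name!r} not contained in the universe")


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *genes = fields
            sets[name] = frozenset(g for g in genes if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def hypergeom_ora(
    target_set, pathways: GeneSetCollection
) -> pd.DataFrame:
    """Exact hypergeometric upper-tail enrichment of ``target_set`` against
    every pathway, BH-adjusted within the collection, sorted by p."""
    if not pathways.universe:
        raise ValueError("gene-set universe is empty")
    targets = set(target_set)
    dropped = targets - pathways.universe
    if dropped:
        log.info("hypergeom_ora: dropped %d target genes outside the universe",
                 len(dropped))
    targets &= pathways.universe
    N = len(pathways.universe)
    n = len(targets)
    rows = []
    for name, members in pathways.sets.items():
        K = len(members)
        k = len(targets & members)
        p = float(hypergeom.sf(k - 1, N, K, n)) if n else 1.0
        rows.append({"pathway": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    res = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
    else:
        res["q_value"] = []
    return res.sort_values(["p_value", "pathway"], kind="stable").reset_index(drop=True)


def pathway_mir_counts(
    per_mir_results: dict[str, pd.DataFrame], alpha: float = 0.05
) -> tuple[pd.Series, pd.Series]:
    """Count significant pathways per miR and significant miRs per pathway.

    Significance is p < alpha on the raw hypergeometric p.  Both series are
    sorted by descending count, ties broken lexicographically.
    """
    per_mir = {}
    per_pathway: dict[str, int] = {}
    for mir, res in per_mir_results.items():
        sig = res[res["p_value"] < alpha]
        per_mir[mir] = len(sig)
        for pw in sig["pathway"]:
            per_pathway[pw] = per_pathway.get(pw, 0) + 1
    def _sorted(d: dict[str, int]) -> pd.Series:
        items = sorted(d.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.Series({k: v for k, v in items}, dtype=int)
    return _sorted(per_mir), _sorted(per_pathway)


def broad_mirs(per_mir_counts: pd.Series, min_pathways: int = 11) -> list[str]:
    """miRs significant for at least ``min_pathways`` pathways — the broad
    regulators that recur across most of a curated pathway panel."""
    return sorted(per_mir_counts[per_mir_counts >= min_pathways].index)
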