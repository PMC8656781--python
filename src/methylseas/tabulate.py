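"""Count tables over significant sites.

Reproduces the study-style summaries: chromosome x neighborhood-group x
direction cross-tabulations (for all sites and for the miR-gene subset),
functional-region x direction tables, percentage summaries, and the
site x fold-change matrix behind the candidate heat map.  North/south shores
and shelves collapse into Shore/Shelf groups for the cross-tabs; the full
six-class breakdown stays available from the annotation table itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .annotation import FunctionalClass

REGION_GROUPS = ("OpenSea", "Island", "Shelf", "Shore")
DIRECTIONS = ("hyper", "hypo")

_REGION_TO_GROUP = {
    "Island": "Island",
    "N_Shore": "Shore",
    "S_Shore": "Shore",
    "N_Shelf": "Shelf",
    "S_Shelf": "Shelf",
    "OpenSea": "OpenSea",
}


def round_half_up(x: float, ndigits: int = 1) -> float:
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


@dataclass
class CrossTab:
    """chromosome x (region group, direction) counts with margins."""

    table: pd.DataFrame  # index chrom, columns MultiIndex (group, direction)
    rejects: list[str] = field(default_factory=list)

    @property
    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    @property
    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    @property
    def grand_total(self) -> int:
        return int(self.table.to_numpy().sum())

    def region_totals(self) -> pd.Series:
        return self.table.T.groupby(level=0).sum().sum(axis=1)

    def direction_totals(self) -> pd.Series:
        return self.table.T.groupby(level=1).sum().sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Long layout mirroring the printed tables (chrom rows, Status column)."""
        records = []
        for chrom in self.table.index:
            for status, direction in (("Hypomethylated", "hypo"), ("Hypermethylated", "hyper")):
                rec = {"chrom": chrom, "status": status}
                for group in REGION_GROUPS:
                    rec[group] = int(self.table.loc[chrom, (group, direction)])
                records.append(rec)
        return pd.DataFrame(records)


def _significant(results: pd.DataFrame) -> pd.DataFrame:
    return results[results["direction"].isin(DIRECTIONS)]


def _chrom_sort_key(chroms) -> list:
    def key(c):
        s = str(c)
        for pre in ("chr", "Chr", "CHR"):
            if s.startswith(pre):
                s = s[len(pre):]
        return (0, int(s)) if s.isdigit() else (1, s)
    return sorted(chroms, key=key)


def crosstab_region(
    results: pd.DataFrame, annotations: pd.DataFrame, subset: str = "all"
) -> CrossTab:
    """Count significant sites per chromosome x region group x direction.

    ``subset='mir_only'`` restricts to sites annotated within miR genes.
    Sites lacking an annotation row are excluded and listed in ``rejects``.
    """
    if subset not in ("all", "mir_only"):
        raise ValueError("subset must be 'all' or 'mir_only'")
    sig = _significant(results)
    merged = sig.merge(annotations, on="probe_id", how="left", indicator=True)
    rejects = merged.loc[merged["_merge"] != "both", "probe_id"].tolist()
    merged = merged[merged["_merge"] == "both"]
    if subset == "mir_only":
        merged = merged[merged["is_mir"].astype(bool)]
    merged = merged.assign(group=merged["region"].map(_REGION_TO_GROUP))

    chroms = _chrom_sort_key(merged["chrom"].unique())
    cols = pd.MultiIndex.from_product([REGION_GROUPS, DIRECTIONS])
    table = pd.DataFrame(0, index=pd.Index(chroms, name="chrom"), columns=cols)
    counts = merged.groupby(["chrom", "group", "direction"], observed=True).size()
    for (chrom, group, direction), n in counts.items():
        table.loc[chrom, (group, direction)] = int(n)
    return CrossTab(table=table, rejects=rejects)


def crosstab_features(results: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Unique-site counts per functional class x direction.

    A site assigned to several genes increments each of its classes at most
    once; a site with no gene assignment counts as Intergenic.
    """
    sig = _significant(results)
    merged = sig.merge(annotations, on="probe_id", how="inner")
    classes = [c.value for c in FunctionalClass]
    out = pd.DataFrame(0, index=pd.Index(classes, name="functional_class"),
                       columns=list(DIRECTIONS))
    for row in merged.itertuples(index=False):
        spec = row.functional
        if spec:
            site_classes = {token.split(":", 1)[0] for token in spec.split(";")}
        else:
            site_classes = {FunctionalClass.INTERGENIC.value}
        for cls in site_classes:
            out.loc[cls, row.direction] += 1
    return out


def summarize_percentages(crosstab: CrossTab) -> dict[str, float]:
    """Region-group and direction percentages of the grand total, one decimal
    (half-up rounding)."""
    total = crosstab.grand_total
    if total == 0:
        raise ValueError("cannot summarize an empty cross-tabulation")
    out = {}
    for group, n in crosstab.region_totals().items():
        out[group] = round_half_up(100.0 * n / total)
    for direction, n in crosstab.direction_totals().items():
        out[direction] = round_half_up(100.0 * n / total)
    return out


def export_heatmap_matrix(
    selected: pd.DataFrame, annotations: pd.DataFrame, path=None
) -> pd.DataFrame:
    """Site x signed-fold-change matrix behind the candidate heat map.

    One row per selected CpG site with its assigned miR gene labels (genes
    with overlapping reading frames all listed), ordered by gene then
    position.  Written as TSV when ``path`` is given.
    """
    cols = ["probe_id", "mir_genes", "chrom", "pos", "fold_change"]
    if selected.empty:
        out = pd.DataFrame(columns=cols)
    else:
        merged = selected.merge(annotations, on="probe_id", how="inner")
        records = []
        for row in merged.itertuples(index=False):
            genes = sorted({tok.split(":", 1)[1] for tok in row.functional.split(";") if tok})
            records.append({
                "probe_id": row.probe_id,
                "mir_genes": ",".join(genes),
                "chrom": row.chrom,
                "pos": int(row.pos),
                "fold_change": row.fold_change,
                "_genekey": genes[0] if genes else "",
            })
        out = pd.DataFrame(records).sort_values(["_genekey", "pos"], kind="stable")
        out = out.drop(columns="_genekey").reset_index(drop=True)[cols]
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


# ---------------------------------------------------------------------------
# packaged fixture transcribing the published count tables
# ---------------------------------------------------------------------------

def load_table_fixture() -> pd.DataFrame:
    """Load the packaged transcription of the published genome-wide and
    miR-specific count tables (columns: table in {global, mir}, chrom,
    status, OpenSea, Island, Shelf, Shore)."""
    ref = resources.files("methylseas.data").joinpath("table1_table2_fixture.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def expand_fixture_sites(fixture: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand the count fixture into per-site results + annotations.

    Every counted site becomes one synthetic probe row so the cross-tab
    operations can be run on the published tables exactly as they run on a
    real analysis.  miR-table counts are carved out of the matching global
    cells (they are a subset); a miR cell exceeding its global cell raises.
    """
    group_to_region = {"OpenSea": "OpenSea", "Island": "Island",
                       "Shelf": "N_Shelf", "Shore": "N_Shore"}
    status_to_dir = {"Hypomethylated": "hypo", "Hypermethylated": "hyper"}

    glob = fixture[fixture["table"] == "global"].set_index(["chrom", "status"])
    mir = fixture[fixture["table"] == "mir"].set_index(["chrom", "status"])

    res_rows, ann_rows = [], []
    counter = 0

    def add_sites(n: int, chrom: str, direction: str, group: str, is_mir: bool):
        nonlocal counter
        for _ in range(n):
            pid = f"fx{counter:06d}"
            counter += 1
            res_rows.append({
                "probe_id": pid,
                "median_diff": 0.1 if direction == "hyper" else -0.1,
                "fold_change": 2.0 if direction == "hyper" else -2.0,
                "p_raw": 0.01, "p_maxt": 0.01,
                "direction": direction,
            })
            ann_rows.append({
                "probe_id": pid, "chrom": chrom, "pos": counter,
                "region": group_to_region[group],
                "functional": "Body:mirfix" if is_mir else "",
                "gene_context": "noncoding" if is_mir else "intergenic",
                "gene_ids": "mirfix" if is_mir else "",
                "is_mir": is_mir,
            })

    for (chrom, status), row in glob.iterrows():
        direction = status_to_dir[status]
        for group in REGION_GROUPS:
            total = int(row[group])
            n_mir = 0
            if (chrom, status) in mir.index:
                n_mir = int(mir.loc[(chrom, status), group])
            if n_mir > total:
                raise ValueError(
                    f"miR count exceeds global count at {chrom}/{status}/{group}")
            add_sites(n_mir, chrom, direction, group, True)
            add_sites(total - n_mir, chrom, direction, group, False)

    results = pd.DataFrame(res_rows)
    annotations = pd.DataFrame(ann_rows)
    return results, annotations
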