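"""Synthetic genomes, manifests, gene models, and paired methylation data.

The generator emulates the design of a paired tumor/normal methylation-array
study (24 matched pairs by default): a single synthetic chromosome carries
CpG islands planted so that every 200 bp window satisfies the island
criterion, separated by CpG-depleted background (no CG dinucleotides at all,
so no spurious windows qualify) with > 8 kb between islands so open-sea
positions exist.  Gene models (coding, non-coding, and miR genes, both
island-promoter and open-sea) and a probe manifest are laid out on top.

Beta values behave like methylation fractions: per probe a two-component
baseline (island/promoter probes hypomethylated near 0.15, open-sea probes
methylated near 0.75) with Beta-distributed noise at concentration
``noise_kappa``; planted tumor effects shift the tumor-sample mean by
``+effect_delta`` (hyper) or ``-effect_delta`` (hypo), clipped to (0.001,
0.999).  Every artifact draws from its own RNG stream derived from the single
config seed, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GENE_MODEL_COLUMNS, GenomicInterval, detect_cpg_islands

log = logging.getLogger(__name__)

ISLAND_SEPARATION_BP = 8000
#: baseline (normal-tissue) beta means by probe neighborhood
BASELINE_MEANS = {"island": 0.15, "shore": 0.35, "shelf": 0.55, "open_sea": 0.75}
CLIP_LO, CLIP_HI = 0.001, 0.999
CHROM = "chr1"

# fixed RNG stream tags, one per generated artifact
_STREAM_GENOME, _STREAM_MANIFEST, _STREAM_BETAS, _STREAM_TARGETS, _STREAM_PATHWAYS = range(5)

_ISLAND_TILE = "ACGCGG"  # GC 2/3, two CpG per 6 bp -> obs/exp ~ 2


@dataclass(frozen=True)
class SimConfig:
    genome_length: int = 300_000
    n_islands: int = 20
    island_length: int = 600
    n_probes: int = 1000
    n_pairs: int = 24
    n_true_hyper: int = 100
    n_true_hypo: int = 100
    effect_delta: float = 0.3
    noise_kappa: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_hyper + self.n_true_hypo > self.n_probes:
            raise ValueError("n_true_hyper + n_true_hypo must not exceed n_probes")
        if not (0 < self.effect_delta < 1) and (self.n_true_hyper or self.n_true_hypo):
            if self.effect_delta != 0:
                raise ValueError("effect_delta must lie in (0, 1)")
        if self.effect_delta < 0 or self.effect_delta >= 1:
            raise ValueError("effect_delta must lie in [0, 1)")
        if self.genome_length < self.n_islands * (self.island_length + ISLAND_SEPARATION_BP):
            raise ValueError(
                "genome_length must be >= n_islands * (island_length + 8000)")
        if self.n_pairs < 2:
            raise ValueError("need at least 2 sample pairs")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _island_sequence(length: int) -> str:
    reps = length // len(_ISLAND_TILE) + 1
    return (_ISLAND_TILE * reps)[:length]


def _background(rng: np.random.Generator, length: int) -> str:
    letters = rng.choice(np.array(list("ACGT")), size=length,
                         p=[0.3, 0.2, 0.2, 0.3])
    seq = "".join(letters)
    # remove every CpG dinucleotide so no background window can qualify
    return seq.replace("CG", "CA")


def island_layout(config: SimConfig) -> list[GenomicInterval]:
    """Deterministic, evenly spaced island placement."""
    if config.n_islands == 0:
        return []
    gap = (config.genome_length - config.n_islands * config.island_length) // (
        config.n_islands + 1)
    if gap <= ISLAND_SEPARATION_BP:
        raise ValueError(
            "islands cannot be placed with > 8 kb separation; "
            "increase genome_length or reduce n_islands/island_length")
    out = []
    pos = gap
    for _ in range(config.n_islands):
        out.append(GenomicInterval(CHROM, pos, pos + config.island_length))
        pos += config.island_length + gap
    return out


def generate_genome(
    config: SimConfig,
) -> tuple[str, list[GenomicInterval], pd.DataFrame]:
    """Emit (sequence, planted island intervals, gene models).

    Every planted island satisfies the CpG-island criterion in each of its
    200 bp windows (verified against the package's own detector before
    emission); the background contains no CpG dinucleotide, hence no
    qualifying windows outside the planted intervals.
    """
    rng = config.rng(_STREAM_GENOME)
    islands = island_layout(config)
    pieces = []
    cursor = 0
    for iv in islands:
        pieces.append(_background(rng, iv.start - cursor))
        pieces.append(_island_sequence(len(iv)))
        cursor = iv.end
    pieces.append(_background(rng, config.genome_length - cursor))
    sequence = "".join(pieces)

    # truth-by-construction check: detector must recover exactly the layout
    detected = detect_cpg_islands(sequence, CHROM)
    ok = len(detected) == len(islands) and all(
        d.interval.start < iv.end and iv.start < d.interval.end
        for d, iv in zip(detected, islands)
    )
    if not ok:
        raise RuntimeError("planted islands failed self-verification")

    gene_models = _gene_models(config, islands)
    return sequence, islands, gene_models


def _gene_models(config: SimConfig, islands: list[GenomicInterval]) -> pd.DataFrame:
    rows = []
    glen = 2400

    def biotype_for(i: int) -> str:
        return ("coding", "coding", "miR", "noncoding")[i % 4]

    for i, iv in enumerate(islands):
        center = (iv.start + iv.end) // 2
        strand = "+" if i % 2 == 0 else "-"
        bt = biotype_for(i)
        if strand == "+":
            start, end, tss = center, center + glen, center
            exons = [(tss, tss + 300), (tss + 1200, tss + 1500), (tss + 2100, tss + 2400)]
            utr5, utr3 = (tss, tss + 120), (tss + 2300, tss + 2400)
        else:
            start, end, tss = center - glen, center, center
            exons = [(tss - 2400, tss - 2100), (tss - 1500, tss - 1200), (tss - 300, tss)]
            utr5, utr3 = (tss - 120, tss), (tss - 2400, tss - 2300)
        rows.append(dict(
            gene_id=f"{'mir' if bt == 'miR' else bt}_isl_{i:03d}", chrom=CHROM,
            start=start, end=end, strand=strand, biotype=bt, tss=tss,
            exons=";".join(f"{s}-{e}" for s, e in exons),
            utr5=f"{utr5[0]}-{utr5[1]}", utr3=f"{utr3[0]}-{utr3[1]}",
        ))

    # open-sea genes in the wide inter-island gaps, > 4 kb from any island
    glen_os = 1200
    bounds = [0] + [iv.end for iv in islands]
    next_starts = [iv.start for iv in islands] + [config.genome_length]
    for j, (lo, hi) in enumerate(zip(bounds, next_starts)):
        center = (lo + hi) // 2
        start = center - glen_os // 2
        end = start + glen_os
        if start < lo + 4500 or end > hi - 4500:
            continue
        bt = "miR" if j % 2 == 0 else "coding"
        tss = start
        rows.append(dict(
            gene_id=f"{'mir' if bt == 'miR' else bt}_sea_{j:03d}", chrom=CHROM,
            start=start, end=end, strand="+", biotype=bt, tss=tss,
            exons=f"{start}-{start + 300};{start + 900}-{end}",
            utr5=f"{start}-{start + 60}", utr3=f"{end - 60}-{end}",
        ))
    return pd.DataFrame(rows, columns=GENE_MODEL_COLUMNS)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def generate_manifest(
    config: SimConfig,
    islands: list[GenomicInterval],
    gene_models: pd.DataFrame,
    snp_fraction: float = 0.02,
    nonunique_fraction: float = 0.01,
) -> pd.DataFrame:
    """Place probes across islands, shores, shelves, and open seas.

    The neighborhood mix (35/18/8/39 %) mirrors the genome-wide distribution
    of differentially methylated CpGs the pipeline is meant to exercise.
    Open-sea probes preferentially fall inside open-sea gene bodies (miR and
    coding) so the miR-subset tabulations are non-trivial.
    """
    rng = config.rng(_STREAM_MANIFEST)
    n = config.n_probes
    if not islands:
        raise ValueError("manifest generation requires at least one island")
    n_island = int(round(0.35 * n))
    n_shore = int(round(0.18 * n))
    n_shelf = int(round(0.08 * n))
    n_sea = n - n_island - n_shore - n_shelf

    positions: list[tuple[int, str]] = []
    for k in range(n_island):
        iv = islands[k % len(islands)]
        positions.append((int(rng.integers(iv.start, iv.end)), "island"))
    for k in range(n_shore):
        iv = islands[k % len(islands)]
        d = int(rng.integers(0, 2001))
        pos = iv.end + d if k % 2 == 0 else iv.start - 1 - d
        positions.append((pos, "shore"))
    for k in range(n_shelf):
        iv = islands[k % len(islands)]
        d = int(rng.integers(2001, 4001))
        pos = iv.end + d if k % 2 == 0 else iv.start - 1 - d
        positions.append((pos, "shelf"))

    sea_genes = gene_models[gene_models["gene_id"].str.contains("_sea_")]
    bounds = [0] + [iv.end for iv in islands]
    next_starts = [iv.start for iv in islands] + [config.genome_length]
    gaps = [(lo + 4501, hi - 4502) for lo, hi in zip(bounds, next_starts)
            if hi - 4502 > lo + 4501]
    for k in range(n_sea):
        if len(sea_genes) and k % 3 != 0:
            g = sea_genes.iloc[k % len(sea_genes)]
            pos = int(rng.integers(g.start, g.end))
        else:
            lo, hi = gaps[k % len(gaps)]
            pos = int(rng.integers(lo, hi + 1))
        positions.append((pos, "open_sea"))

    manifest = pd.DataFrame({
        "probe_id": [f"cg{idx:08d}" for idx in range(len(positions))],
        "chrom": CHROM,
        "pos": [p for p, _ in positions],
        "snp_within_5bp": rng.random(len(positions)) < snp_fraction,
        "unique_mapping": rng.random(len(positions)) >= nonunique_fraction,
        "region_hint": [h for _, h in positions],
    })
    manifest["baseline_mean"] = manifest["region_hint"].map(BASELINE_MEANS)
    return manifest


# ---------------------------------------------------------------------------
# paired betas
# ---------------------------------------------------------------------------

def generate_paired_betas(
    manifest: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw paired tumor/normal beta matrices with planted effects.

    Hypermethylation effects are planted on island probes (low baseline,
    headroom upward) and hypomethylation effects on open-sea probes,
    mirroring the island-hyper / open-sea-hypo asymmetry of tumor
    methylomes.  Returns ``(tumor, normal, truth)``; the truth table lists
    every manifest probe exactly once.
    """
    if manifest.empty:
        raise ValueError("manifest must be non-empty")
    rng = config.rng(_STREAM_BETAS)
    n_probes = len(manifest)
    mean0 = manifest.get("baseline_mean")
    if mean0 is None:
        mean0 = pd.Series(0.5, index=manifest.index)
    mean0 = mean0.to_numpy(dtype=float)

    hint = manifest.get("region_hint", pd.Series("open_sea", index=manifest.index))
    island_idx = np.flatnonzero((hint == "island").to_numpy())
    sea_idx = np.flatnonzero((hint == "open_sea").to_numpy())
    other_idx = np.setdiff1d(np.arange(n_probes), np.concatenate([island_idx, sea_idx]))

    def pick(primary: np.ndarray, n: int, taken: set[int]) -> np.ndarray:
        avail = np.array([i for i in primary if i not in taken], dtype=int)
        chosen = rng.choice(avail, size=min(n, avail.size), replace=False)
        if chosen.size < n:
            rest = np.array([i for i in np.concatenate([other_idx, sea_idx, island_idx])
                             if i not in taken and i not in set(chosen.tolist())], dtype=int)
            extra = rng.choice(rest, size=n - chosen.size, replace=False)
            chosen = np.concatenate([chosen, extra])
        return chosen

    taken: set[int] = set()
    hyper_idx = pick(island_idx, config.n_true_hyper, taken) if config.n_true_hyper else np.array([], int)
    taken |= set(hyper_idx.tolist())
    hypo_idx = pick(sea_idx, config.n_true_hypo, taken) if config.n_true_hypo else np.array([], int)

    effect = np.zeros(n_probes)
    effect[hyper_idx] = config.effect_delta
    effect[hypo_idx] = -config.effect_delta

    mean_tumor = np.clip(mean0 + effect, CLIP_LO, CLIP_HI)
    n_clipped = int(((mean0 + effect) != mean_tumor).sum())
    if n_clipped:
        log.warning("generate_paired_betas: %d tumor means clipped to (%.3f, %.3f)",
                    n_clipped, CLIP_LO, CLIP_HI)

    shape = (n_probes, config.n_pairs)
    if np.isinf(config.noise_kappa):
        normal = np.tile(mean0[:, None], (1, config.n_pairs))
        tumor = np.tile(mean_tumor[:, None], (1, config.n_pairs))
    else:
        kappa = float(config.noise_kappa)
        normal = rng.beta(mean0[:, None] * kappa, (1 - mean0[:, None]) * kappa, size=shape)
        tumor = rng.beta(mean_tumor[:, None] * kappa, (1 - mean_tumor[:, None]) * kappa,
                         size=shape)
        normal = np.clip(normal, CLIP_LO, CLIP_HI)
        tumor = np.clip(tumor, CLIP_LO, CLIP_HI)

    idx = pd.Index(manifest["probe_id"], name="probe_id")
    t_cols = [f"T{j + 1:02d}" for j in range(config.n_pairs)]
    n_cols = [f"N{j + 1:02d}" for j in range(config.n_pairs)]
    tumor_df = pd.DataFrame(tumor, index=idx, columns=t_cols)
    normal_df = pd.DataFrame(normal, index=idx, columns=n_cols)

    direction = np.array(["null"] * n_probes, dtype=object)
    direction[hyper_idx] = "hyper"
    direction[hypo_idx] = "hypo"
    truth = pd.DataFrame({
        "probe_id": manifest["probe_id"].to_numpy(),
        "true_direction": direction,
        "true_effect": effect,
    })
    return tumor_df, normal_df, truth


def pairing_map(tumor: pd.DataFrame, normal: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({"tumor_id": tumor.columns, "normal_id": normal.columns})


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def generate_intensities(
    betas: pd.DataFrame, total_intensity: float, offset: float = 0.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert the beta computation: meth + unmeth + offset = total_intensity.

    Requires every beta <= (total - offset) / total so that the unmethylated
    channel stays non-negative; ``compute_beta`` then recovers the input
    exactly (to floating point).
    """
    if total_intensity <= offset:
        raise ValueError("total_intensity must exceed offset")
    b = betas.to_numpy(dtype=float)
    if (b < 0).any() or (b > 1).any():
        raise ValueError("betas must lie in [0, 1]")
    if (b > (total_intensity - offset) / total_intensity).any():
        raise ValueError(
            "betas too large for the requested offset/total_intensity; "
            "increase total_intensity or lower offset")
    meth = betas * total_intensity
    unmeth = total_intensity - offset - meth
    return meth, unmeth


# ---------------------------------------------------------------------------
# enrichment inputs
# ---------------------------------------------------------------------------

def generate_target_map(
    gene_models: pd.DataFrame, config: SimConfig,
    targets_per_mir: int = 30, universe_size: int = 200,
) -> pd.DataFrame:
    """Two-column miR -> target-gene map over a synthetic gene universe."""
    rng = config.rng(_STREAM_TARGETS)
    mirs = gene_models.loc[gene_models["biotype"] == "miR", "gene_id"].tolist()
    coding = gene_models.loc[gene_models["biotype"] == "coding", "gene_id"].tolist()
    extra = [f"g{k:04d}" for k in range(max(0, universe_size - len(coding)))]
    universe = np.array(coding + extra)
    rows = []
    for mir in mirs:
        targets = rng.choice(universe, size=min(targets_per_mir, universe.size),
                             replace=False)
        rows.extend({"mir_id": mir, "target_gene": t} for t in sorted(targets))
    return pd.DataFrame(rows, columns=["mir_id", "target_gene"])


def generate_pathways(
    target_map: pd.DataFrame, config: SimConfig,
    n_pathways: int = 17, enriched_overlap: int = 15, background_genes: int = 10,
):
    """GMT-style pathway sets, each enriched for one miR's target set."""
    from .enrichment import GeneSetCollection

    rng = config.rng(_STREAM_PATHWAYS)
    universe = np.array(sorted(target_map["target_gene"].unique()))
    mirs = sorted(target_map["mir_id"].unique())
    sets = {}
    for p in range(n_pathways):
        mir = mirs[p % len(mirs)] if mirs else None
        members: set[str] = set()
        if mir is not None:
            targets = target_map.loc[target_map["mir_id"] == mir, "target_gene"].to_numpy()
            members |= set(rng.choice(targets, size=min(enriched_overlap, targets.size),
                                      replace=False).tolist())
        members |= set(rng.choice(universe, size=min(background_genes, universe.size),
                                  replace=False).tolist())
        sets[f"pathway_{p:02d}"] = frozenset(members)
    return GeneSetCollection(sets, universe=frozenset(universe.tolist()))


# ---------------------------------------------------------------------------
# file I/O (all round-trip tested against the package's readers)
# ---------------------------------------------------------------------------

def write_fasta(sequence: str, path, chrom: str = CHROM, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i:i + width] + "\n")


def write_gene_models(gene_models: pd.DataFrame, path) -> None:
    gene_models.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"manifest missing column {col!r}")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    # keep_default_na: the direction label "null" must stay a string
    return pd.read_csv(path, sep="\t", keep_default_na=False)
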