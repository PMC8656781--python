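"""CpG-island detection and genomic context classification.

A CpG island is detected directly from sequence using the classic
Gardiner-Garden & Frommer style criterion: a 200 bp window qualifies when its
GC fraction exceeds 0.5 (strict) and its observed/expected CpG ratio is at
least 0.6 (inclusive), with

    obs/exp = (N_CpG * L) / (N_C * N_G)

Qualifying windows slid at 1 bp steps are union-merged into maximal islands.
Positions are then classified relative to islands: shores within 2 kb of an
island edge, shelves within 2-4 kb, open sea beyond 4 kb.  North denotes the
lower-coordinate (5' genomic) side of an island, so a position whose nearest
island lies at a higher coordinate is in the island's north flank (``N_*``).

Functional gene classes follow the methylation-array convention: TSS200 and
TSS1500 are windows up to 200 bp and 200-1500 bp upstream of a transcription
start site; inside a gene a position is 5'UTR, first exon, 3'UTR, or body,
with one class per (position, gene) pair under the precedence
TSS200 > TSS1500 > UTR5 > FirstExon > UTR3 > Body.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import enum
from bisect import bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SHORE_BP = 2000
SHELF_BP = 4000

# float guard so an obs/exp ratio of exactly min_oe qualifies (inclusive bound)
_OE_TOL = 1e-12


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_ratio: float


class RegionClass(str, enum.Enum):
    ISLAND = "Island"
    N_SHORE = "N_Shore"
    S_SHORE = "S_Shore"
    N_SHELF = "N_Shelf"
    S_SHELF = "S_Shelf"
    OPEN_SEA = "OpenSea"


class FunctionalClass(str, enum.Enum):
    TSS200 = "TSS200"
    TSS1500 = "TSS1500"
    UTR5 = "UTR5"
    FIRST_EXON = "FirstExon"
    BODY = "Body"
    UTR3 = "UTR3"
    INTERGENIC = "Intergenic"


#: per-gene precedence when a position falls in several feature windows
FUNCTIONAL_PRECEDENCE = (
    FunctionalClass.TSS200,
    FunctionalClass.TSS1500,
    FunctionalClass.UTR5,
    FunctionalClass.FIRST_EXON,
    FunctionalClass.UTR3,
    FunctionalClass.BODY,
)

BIOTYPES = frozenset({"coding", "noncoding", "miR"})


@dataclass
class GeneContext:
    value: str  # coding | noncoding | intergenic
    gene_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# island detection
# ---------------------------------------------------------------------------

def _base_indicators(sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    is_c = arr == b"C"
    is_g = arr == b"G"
    is_n = ~np.isin(arr, (b"A", b"C", b"G", b"T"))
    cg = is_c[:-1] & is_g[1:] if len(arr) > 1 else np.zeros(0, bool)
    return is_c, is_g, is_n, cg


def _window_sums(ind: np.ndarray, window: int) -> np.ndarray:
    """Sliding-window sums of a 0/1 indicator at 1 bp steps."""
    c = np.concatenate(([0], np.cumsum(ind, dtype=np.int64)))
    return c[window:] - c[:-window]


def detect_cpg_islands(
    sequence: str,
    chrom: str = "chr1",
    min_gc: float = 0.5,
    min_oe: float = 0.6,
    window: int = 200,
) -> list[CpGIsland]:
    """Scan ``sequence`` for CpG islands.

    A window of ``window`` bp qualifies iff GC fraction > ``min_gc`` (strict),
    obs/exp CpG ratio >= ``min_oe`` (inclusive), and it contains no ambiguous
    base.  Overlapping or book-ended qualifying windows merge into maximal
    islands whose GC and obs/exp statistics are recomputed over the merged
    interval.  Returns islands sorted by start; a sequence shorter than the
    window yields an empty list.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(sequence)
    if n < window:
        return []
    is_c, is_g, is_n, cg = _base_indicators(sequence)
    n_c = _window_sums(is_c, window)
    n_g = _window_sums(is_g, window)
    n_n = _window_sums(is_n, window)
    # CG dinucleotides fully inside window starting at i: positions i..i+window-2
    n_cg = _window_sums(cg, window - 1)[: n - window + 1]

    gc_ok = (n_c + n_g) > min_gc * window
    denom = (n_c * n_g).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, n_cg * float(window) / denom, 0.0)
    qualify = gc_ok & (oe >= min_oe - _OE_TOL) & (n_n == 0)

    starts = np.flatnonzero(qualify)
    if starts.size == 0:
        return []

    islands: list[CpGIsland] = []
    run_start = int(starts[0])
    cur_end = run_start + window

    def _emit(s: int, e: int) -> None:
        seg_c = int(is_c[s:e].sum())
        seg_g = int(is_g[s:e].sum())
        seg_cg = int(cg[s : e - 1].sum()) if e - s > 1 else 0
        length = e - s
        gc = (seg_c + seg_g) / length
        ratio = seg_cg * length / (seg_c * seg_g) if seg_c and seg_g else 0.0
        islands.append(
            CpGIsland(GenomicInterval(chrom, s, e), gc_fraction=gc, obs_exp_ratio=ratio)
        )

    for s in starts[1:]:
        s = int(s)
        if s <= cur_end:  # overlap or book-ended
            cur_end = s + window
        else:
            _emit(run_start, cur_end)
            run_start = s
            cur_end = s + window
    _emit(run_start, cur_end)
    return islands


# ---------------------------------------------------------------------------
# neighborhood classification
# ---------------------------------------------------------------------------

def _validate_islands(intervals: list[GenomicInterval]) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.end:
            raise ValueError("island list must be sorted and non-overlapping")


def classify_neighborhood(
    islands: list[CpGIsland] | list[GenomicInterval],
    chrom: str,
    pos: int,
) -> RegionClass:
    """Classify ``pos`` relative to sorted non-overlapping islands.

    Distance to an island is the number of bases strictly between the
    position and the island; a base adjacent to an island edge has d = 0.
    d <= 2000 is shore, 2000 < d <= 4000 shelf, d > 4000 open sea.  ``N_``
    when the nearest island lies at a higher coordinate than the position.
    Equidistant islands tie-break toward the island with the lower start.
    """
    ivals = [i.interval if isinstance(i, CpGIsland) else i for i in islands]
    ivals = [i for i in ivals if i.chrom == chrom]
    _validate_islands(ivals)
    if not ivals:
        return RegionClass.OPEN_SEA

    starts = [i.start for i in ivals]
    idx = bisect_right(starts, pos)
    left = ivals[idx - 1] if idx > 0 else None
    right = ivals[idx] if idx < len(ivals) else None

    if left is not None and left.contains(pos):
        return RegionClass.ISLAND

    d_left = pos - left.end if left is not None else None  # island at lower coord
    d_right = right.start - pos - 1 if right is not None else None

    if d_right is None or (d_left is not None and d_left <= d_right):
        d, north = d_left, False  # nearest island lies south of... at lower coord
    else:
        d, north = d_right, True
    if d <= SHORE_BP:
        return RegionClass.N_SHORE if north else RegionClass.S_SHORE
    if d <= SHELF_BP:
        return RegionClass.N_SHELF if north else RegionClass.S_SHELF
    return RegionClass.OPEN_SEA


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

GENE_MODEL_COLUMNS = [
    "gene_id", "chrom", "start", "end", "strand", "biotype",
    "tss", "exons", "utr5", "utr3",
]


def _parse_intervals(spec: str) -> list[tuple[int, int]]:
    if not spec or (isinstance(spec, float) and np.isnan(spec)):
        return []
    out = []
    for token in str(spec).split(";"):
        token = token.strip()
        if not token:
            continue
        s, e = token.split("-")
        out.append((int(s), int(e)))
    return out


def assign_functional_regions(
    gene_models: pd.DataFrame, chrom: str, pos: int
) -> set[tuple[FunctionalClass, str]]:
    """Per-gene functional class of ``pos``; empty set = no gene covers it.

    The upstream distance u is strand-aware: for a + strand gene
    u = tss - pos; for a - strand gene (tss stored as the half-open end
    coordinate) u = pos - tss.  u in [1, 200] is TSS200, (200, 1500] TSS1500.
    Inside the gene the precedence is UTR5 > FirstExon > UTR3 > Body.
    """
    out: set[tuple[FunctionalClass, str]] = set()
    for row in gene_models.itertuples(index=False):
        if row.chrom != chrom:
            continue
        if row.end <= row.start:
            raise ValueError(f"gene {row.gene_id}: end <= start")
        cls = _classify_against_gene(row, pos)
        if cls is not None:
            out.add((cls, row.gene_id))
    return out


def _classify_against_gene(row, pos: int) -> FunctionalClass | None:
    tss = int(row.tss)
    u = (tss - pos) if row.strand == "+" else (pos - tss)
    if 1 <= u <= 200:
        return FunctionalClass.TSS200
    if 200 < u <= 1500:
        return FunctionalClass.TSS1500
    if not (row.start <= pos < row.end):
        return None
    for (cls, spec) in ((FunctionalClass.UTR5, row.utr5),):
        for s, e in _parse_intervals(spec):
            if s <= pos < e:
                return cls
    exons = _parse_intervals(row.exons)
    if exons:
        first = exons[0] if row.strand == "+" else exons[-1]
        if first[0] <= pos < first[1]:
            return FunctionalClass.FIRST_EXON
    for s, e in _parse_intervals(row.utr3):
        if s <= pos < e:
            return FunctionalClass.UTR3
    return FunctionalClass.BODY


def classify_gene_context(
    assignments: set[tuple[FunctionalClass, str]], gene_models: pd.DataFrame
) -> GeneContext:
    """coding > noncoding (incl. miR) > intergenic across all assigned genes."""
    gene_ids = sorted({g for _, g in assignments})
    if not gene_ids:
        return GeneContext("intergenic", [])
    biotype = gene_models.set_index("gene_id")["biotype"]
    kinds = set()
    for g in gene_ids:
        bt = biotype.get(g)
        if bt not in BIOTYPES:
            raise ValueError(f"unknown biotype {bt!r} for gene {g}")
        kinds.add(bt)
    if "coding" in kinds:
        return GeneContext("coding", gene_ids)
    return GeneContext("noncoding", gene_ids)


# ---------------------------------------------------------------------------
# probe annotation
# ---------------------------------------------------------------------------

def annotate_probes(
    manifest: pd.DataFrame,
    islands: dict[str, list[CpGIsland]] | list[CpGIsland],
    gene_models: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join region, functional, and gene-context classes onto every probe.

    ``islands`` may be a flat list or a dict keyed by chromosome.  Probes on
    chromosomes absent from ``islands`` are returned in a rejects table, not
    silently dropped.  Returns ``(annotations, rejects)``.
    """
    if isinstance(islands, dict):
        by_chrom = islands
    else:
        by_chrom = {}
        for isl in islands:
            by_chrom.setdefault(isl.interval.chrom, []).append(isl)
    biotype = gene_models.set_index("gene_id")["biotype"] if len(gene_models) else pd.Series(dtype=object)

    rows, rejects = [], []
    for probe in manifest.itertuples(index=False):
        chrom, pos = probe.chrom, int(probe.pos)
        if chrom not in by_chrom:
            rejects.append({"probe_id": probe.probe_id, "chrom": chrom,
                            "reason": "chromosome absent from genome"})
            continue
        region = classify_neighborhood(by_chrom[chrom], chrom, pos)
        assignments = assign_functional_regions(gene_models, chrom, pos)
        ctx = classify_gene_context(assignments, gene_models)
        is_mir = any(biotype.get(g) == "miR" for _, g in assignments)
        rows.append({
            "probe_id": probe.probe_id,
            "chrom": chrom,
            "pos": pos,
            "region": region.value,
            "functional": ";".join(sorted(f"{c.value}:{g}" for c, g in assignments)),
            "gene_context": ctx.value,
            "gene_ids": ",".join(ctx.gene_ids),
            "is_mir": is_mir,
        })
    cols = ["probe_id", "chrom", "pos", "region", "functional",
            "gene_context", "gene_ids", "is_mir"]
    ann = pd.DataFrame(rows, columns=cols)
    rej = pd.DataFrame(rejects, columns=["probe_id", "chrom", "reason"])
    return ann, rej


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exons": str, "utr5": str, "utr3": str},
                     keep_default_na=False)
    missing = [c for c in GENE_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gene model table missing columns: {missing}")
    return df


def write_islands_bed(islands: list[CpGIsland], path) -> None:
    """6-column BED: name = island index, score = round(1000 * obs/exp)."""
    with open(path, "w") as fh:
        for i, isl in enumerate(islands):
            iv = isl.interval
            score = min(1000, round(1000 * isl.obs_exp_ratio))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tisland_{i}\t{score}\t.\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
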