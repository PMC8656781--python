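"""Beta-value computation and probe-exclusion rules.

The beta value at a probe is the methylated signal as a fraction of total
locus intensity, beta = M / (M + U + offset).  The offset (default 100)
stabilizes the ratio at low-intensity loci; offset 0 gives the literal ratio.

Probe exclusions follow the standard methylation-array hygiene rules:
probes on the sex chromosomes, probes with a common SNP within 5 bp of the
targeted CpG, and probes that do not map uniquely to the reference.  SNP and
mapping evidence are consumed as manifest flags, not recomputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY", "ChrX", "ChrY"})


@dataclass
class FilterReport:
    sex_chromosome: int = 0
    snp_within_5bp: int = 0
    non_unique_mapping: int = 0
    kept: int = 0

    @property
    def excluded(self) -> int:
        return self.sex_chromosome + self.snp_within_5bp + self.non_unique_mapping

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": ["sex_chromosome", "snp_within_5bp", "non_unique_mapping", "kept"],
             "count": [self.sex_chromosome, self.snp_within_5bp,
                       self.non_unique_mapping, self.kept]}
        )


def compute_beta(
    meth: pd.DataFrame, unmeth: pd.DataFrame, offset: float = 100.0
) -> pd.DataFrame:
    """beta = meth / (meth + unmeth + offset), elementwise.

    Cells whose denominator is zero become missing (NaN) and are counted in
    the log.  Row and column labels must match between channels.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if not meth.index.equals(unmeth.index) or not meth.columns.equals(unmeth.columns):
        raise ValueError("meth and unmeth matrices must share identical labels")
    denom = meth + unmeth + offset
    zero = denom == 0
    n_zero = int(zero.to_numpy().sum())
    if n_zero:
        log.warning("compute_beta: %d cells with zero total intensity set to missing", n_zero)
    beta = meth / denom.where(~zero)
    return beta


def filter_probes(manifest: pd.DataFrame) -> tuple[pd.Index, FilterReport]:
    """Apply the exclusion rules; each probe is attributed to the first
    matching rule in the order sex chromosome, SNP proximity, non-unique
    mapping.  Returns the kept probe ids and a :class:`FilterReport`.
    """
    for col in ("chrom", "snp_within_5bp", "unique_mapping"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing required column {col!r}")
    chrom = manifest["chrom"].astype(str)
    sex = chrom.isin(SEX_CHROMOSOMES) | chrom.str.upper().isin({"X", "Y", "CHRX", "CHRY"})
    snp = manifest["snp_within_5bp"].astype(bool) & ~sex
    nonuniq = ~manifest["unique_mapping"].astype(bool) & ~sex & ~snp
    keep = ~(sex | snp | nonuniq)
    report = FilterReport(
        sex_chromosome=int(sex.sum()),
        snp_within_5bp=int(snp.sum()),
        non_unique_mapping=int(nonuniq.sum()),
        kept=int(keep.sum()),
    )
    kept_ids = pd.Index(manifest.loc[keep, "probe_id"])
    return kept_ids, report


def median_scale_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Optional per-sample median scaling (off by default in the pipeline).

    Rescales every column so its median equals the global median of column
    medians; a coarse stand-in for upstream control normalization.
    """
    med = matrix.median(axis=0)
    target = float(np.median(med))
    scale = target / med.replace(0, np.nan)
    return matrix * scale


# ---------------------------------------------------------------------------
# TSV I/O for matrices and pairing maps
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Probe x sample matrix: first column probe_id, header row of samples."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_pairing(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("tumor_id", "normal_id"):
        if col not in df.columns:
            raise ValueError(f"pairing map missing column {col!r}")
    return df


def write_pairing(pairing: pd.DataFrame, path) -> None:
    pairing.to_csv(path, sep="\t", index=False)
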