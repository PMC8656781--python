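"""Paired differential-methylation testing.

Per probe, tumor and normal beta values from matched sample pairs are
compared with the Wilcoxon signed-rank test (two-sided; zero differences
dropped, midranks for ties; exact null distribution when the reduced sample
size is <= 25 with no ties, otherwise a tie-corrected normal approximation
with continuity correction).

Family-wise error is controlled with the Westfall-Young step-down maxT
procedure under the paired sign-flip null: each permutation flips the sign of
every pair's difference vector (the same flip applied across all probes of
that pair, preserving inter-probe correlation).  The per-probe statistic is
the absolute standardized signed-rank statistic |sum_j s_j r_j| / sqrt(sum r_j^2),
whose permutation variance under random flips is exactly sum r_j^2, so
midrank ties are handled automatically.

Direction calls: a site significant at the chosen p column is hypermethylated
when the median tumor beta exceeds the median normal beta and hypomethylated
otherwise.  The fold-change methylation difference is a signed ratio of
pseudo-counted medians: r = (med_t + pseudo)/(med_n + pseudo), reported as r
when r >= 1 and -1/r otherwise, so magnitude is always >= 1 and a positive
sign means hypermethylation in tumor.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EXACT_MAX_N = 25


def wilcoxon_signed_rank(tumor, normal) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(W, p)`` where W is the sum of ranks of positive differences
    (tumor - normal) after dropping zero differences.  All differences zero
    is degenerate: returns ``(0.0, 1.0)``.
    """
    tumor = np.asarray(tumor, dtype=float)
    normal = np.asarray(normal, dtype=float)
    if tumor.shape != normal.shape:
        raise ValueError("paired vectors must have equal length")
    if tumor.size < 2:
        raise ValueError("need at least 2 pairs")
    d = tumor - normal
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    ties = np.unique(np.abs(d)).size < n
    if n <= EXACT_MAX_N and not ties:
        method = "exact"
    else:
        method = "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                             alternative="two-sided", method=method)
    return w_pos, float(min(res.pvalue, 1.0))


# ---------------------------------------------------------------------------
# maxT
# ---------------------------------------------------------------------------

def _signed_rank_matrix(diffs: np.ndarray) -> np.ndarray:
    """Per-row signed midranks of |d|; zero differences get rank 0 (dropped)."""
    m, n = diffs.shape
    out = np.zeros_like(diffs, dtype=float)
    absd = np.abs(diffs)
    for i in range(m):
        nz = diffs[i] != 0
        if nz.any():
            r = stats.rankdata(absd[i, nz])
            out[i, nz] = np.sign(diffs[i, nz]) * r
    return out


def _standardized_stats(signed_ranks: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """|sum_j f_j s_j r_j| / sqrt(sum r_j^2) for every probe x flip column."""
    denom = np.sqrt((signed_ranks ** 2).sum(axis=1))
    denom[denom == 0] = 1.0
    return np.abs(signed_ranks @ flips) / denom[:, None]


def _flip_matrix(n_pairs: int, n_perm: int, seed) -> np.ndarray:
    """Sign-flip columns; exhaustive 2^n enumeration when it fits in n_perm."""
    if 2 ** n_pairs <= n_perm:
        count = 2 ** n_pairs
        bits = (np.arange(count)[None, :] >> np.arange(n_pairs)[:, None]) & 1
        return bits * 2.0 - 1.0
    rng = np.random.default_rng(seed)
    return rng.choice(np.array([-1.0, 1.0]), size=(n_pairs, n_perm))


def maxt_adjust(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = None,
) -> pd.Series:
    """Westfall-Young step-down maxT adjusted p-values under sign-flipping.

    ``tumor`` and ``normal`` are probe x sample matrices with column j of one
    paired with column j of the other.  Returns adjusted p-values indexed like
    the input rows; p = (1 + #{perm: tail-max >= observed}) / (n_perm + 1),
    with monotonicity enforced along the ordering by decreasing observed
    statistic.  When 2^n_pairs <= n_perm the full flip set is enumerated and
    the result is seed-independent.
    """
    if seed is None:
        raise ValueError("seed is required for the permutation procedure")
    if n_perm < 100:
        log.warning("maxt_adjust: n_perm=%d is very small", n_perm)
    if not tumor.index.equals(normal.index):
        raise ValueError("tumor and normal matrices must share probe ids")
    n_pairs = tumor.shape[1]
    if tumor.shape[0] < 1 or n_pairs < 2:
        raise ValueError("need >= 1 probe and >= 2 pairs")

    diffs = tumor.to_numpy(dtype=float) - normal.to_numpy(dtype=float)
    sr = _signed_rank_matrix(diffs)
    obs = _standardized_stats(sr, np.ones((n_pairs, 1)))[:, 0]

    flips = _flip_matrix(n_pairs, n_perm, seed)
    n_used = flips.shape[1]
    perm = _standardized_stats(sr, flips)  # m x n_used

    order = np.argsort(-obs, kind="stable")
    # successive maxima over the ordered tail, least significant upward
    tail_max = np.maximum.accumulate(perm[order[::-1], :], axis=0)[::-1, :]
    counts = (tail_max >= obs[order][:, None] - 1e-12).sum(axis=1)
    p_ord = (counts + 1) / (n_used + 1)
    p_ord = np.maximum.accumulate(p_ord)  # enforce step-down monotonicity
    p = np.empty_like(p_ord)
    p[order] = p_ord
    return pd.Series(np.minimum(p, 1.0), index=tumor.index, name="p_maxt")


# ---------------------------------------------------------------------------
# fold change and site calls
# ---------------------------------------------------------------------------

def compute_fold_change(
    median_tumor: float, median_normal: float, pseudo: float = 0.01
) -> float:
    """Signed ratio of pseudo-counted medians; |fc| >= 1, + means hyper."""
    r = (median_tumor + pseudo) / (median_normal + pseudo)
    return float(r) if r >= 1 else float(-1.0 / r)


def call_sites(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    alpha: float = 0.05,
    use_maxt: bool = False,
    n_perm: int = 10000,
    seed: int | None = None,
    pseudo: float = 0.01,
) -> pd.DataFrame:
    """Per-probe medians, fold change, p-values and direction calls.

    Direction is ``hyper``/``hypo`` for sites with p <= alpha on the gating
    column (maxT-adjusted if ``use_maxt`` else raw) and a nonzero median
    difference, ``none`` otherwise.  Output is sorted by (gating p, probe_id).
    """
    if not tumor.index.equals(normal.index):
        raise ValueError("tumor and normal matrices must share probe ids")
    if tumor.shape[1] != normal.shape[1]:
        raise ValueError("tumor and normal must have the same number of samples")
    if tumor.empty:
        return pd.DataFrame(columns=[
            "probe_id", "median_tumor", "median_normal", "median_diff",
            "fold_change", "w_statistic", "p_raw", "p_maxt", "direction"])

    t = tumor.to_numpy(dtype=float)
    n = normal.to_numpy(dtype=float)
    med_t = np.median(t, axis=1)
    med_n = np.median(n, axis=1)
    rows = []
    for i, probe in enumerate(tumor.index):
        w, p = wilcoxon_signed_rank(t[i], n[i])
        rows.append((probe, w, p))
    res = pd.DataFrame(rows, columns=["probe_id", "w_statistic", "p_raw"])
    res["median_tumor"] = med_t
    res["median_normal"] = med_n
    res["median_diff"] = med_t - med_n
    res["fold_change"] = [
        compute_fold_change(a, b, pseudo) for a, b in zip(med_t, med_n)
    ]
    if use_maxt or seed is not None:
        if seed is None:
            raise ValueError("seed is required when use_maxt is enabled")
        res["p_maxt"] = maxt_adjust(tumor, normal, n_perm=n_perm, seed=seed).to_numpy()
    else:
        res["p_maxt"] = np.nan
    gate = res["p_maxt"] if use_maxt else res["p_raw"]
    selected = gate <= alpha
    res["direction"] = np.where(
        selected & (res["median_diff"] > 0), "hyper",
        np.where(selected & (res["median_diff"] < 0), "hypo", "none"),
    )
    res = res.sort_values([("p_maxt" if use_maxt else "p_raw"), "probe_id"],
                          kind="stable").reset_index(drop=True)
    return res[["probe_id", "median_tumor", "median_normal", "median_diff",
                "fold_change", "w_statistic", "p_raw", "p_maxt", "direction"]]


def select_fold_candidates(
    results: pd.DataFrame, min_abs_fc: float = 2.0
) -> pd.DataFrame:
    """Significant sites with |fold change| >= ``min_abs_fc``, both directions."""
    mask = (results["direction"] != "none") & (results["fold_change"].abs() >= min_abs_fc)
    return results.loc[mask].reset_index(drop=True)
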