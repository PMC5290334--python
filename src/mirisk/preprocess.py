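"""Normalization and QC for miRNA read-count matrices.

The pipeline is: keep robustly expressed miRNAs (row total over all
samples above a threshold), drop any superabundant miRNA dominating the
grand total, divide each sample's counts by the mean of that sample's
top-k counts (removing per-sample multiplicative library scale exactly),
then standardize each miRNA against the mean and s.d. computed over the
unaffected reference group only.  QC utilities cover technical-duplicate
concordance, the exact null tail of the Pearson correlation, and
concordance of sequencing counts with qPCR Cq values.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

VALID_GROUPS = ("unaffected", "nonprogressed", "progressed")


def filter_robust(counts: pd.DataFrame, min_total: int = 10000) -> list[str]:
    """miRNAs whose total reads over all samples meet the threshold.

    The comparison is inclusive (``>=``); input row order is preserved.
    """
    totals = counts.sum(axis=1)
    return [m for m in counts.index if totals[m] >= min_total]


def drop_superabundant(
    counts: pd.DataFrame, max_fraction: float = 0.5
) -> tuple[list[str], list[tuple[str, float]]]:
    """Drop miRNAs holding more than ``max_fraction`` of all reads.

    Returns (kept ids, [(dropped id, fraction of grand total)]).  The
    rule is per-miRNA: several rows each below the threshold all survive
    even if they jointly exceed it.
    """
    if not 0 < max_fraction < 1:
        raise ValueError(f"max_fraction must be in (0, 1), got {max_fraction}")
    grand = float(counts.to_numpy().sum())
    kept, dropped = [], []
    for m in counts.index:
        frac = float(counts.loc[m].sum()) / grand if grand > 0 else 0.0
        if frac > max_fraction:
            dropped.append((m, frac))
        else:
            kept.append(m)
    return kept, dropped


def _top_k_mean(col: pd.Series, top_k: int) -> float:
    # Deterministic top-k under ties: count descending, then id ascending.
    order = sorted(col.index, key=lambda m: (-col[m], m))
    top = [col[m] for m in order[:top_k]]
    return float(np.mean(top))


def quotient_normalize(counts: pd.DataFrame, top_k: int = 30) -> pd.DataFrame:
    """Divide each sample by the mean of its ``top_k`` largest counts.

    Per-sample multiplicative scale cancels exactly, so two samples that
    differ only by library size normalize to identical columns.  A
    sample with fewer than ``top_k`` positive counts cannot be
    normalized and raises.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(counts.index) < top_k:
        raise ValueError(f"matrix has fewer than top_k={top_k} miRNAs")
    out = {}
    for s in counts.columns:
        col = counts[s]
        if int((col > 0).sum()) < top_k:
            raise ValueError(
                f"sample {s!r} has fewer than {top_k} miRNAs with positive counts"
            )
        out[s] = col / _top_k_mean(col, top_k)
    q = pd.DataFrame(out)
    q.index = counts.index
    return q[counts.columns]


def zscore_reference(
    q: pd.DataFrame, metadata: pd.DataFrame, reference: str = "unaffected"
) -> pd.DataFrame:
    """Standardize each miRNA against the reference group's mean and s.d.

    The s.d. uses the n-1 denominator.  Over reference-group samples each
    row then has mean 0 and s.d. 1; all other samples are expressed on
    that scale.  miRNAs constant across the reference group are
    degenerate and rejected by name.
    """
    ref_samples = metadata.loc[metadata["group"] == reference, "sample_id"].tolist()
    ref_samples = [s for s in ref_samples if s in q.columns]
    if len(ref_samples) < 2:
        raise ValueError(f"need >= 2 reference samples in group {reference!r}")
    ref = q[ref_samples]
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    degenerate = [m for m in q.index if sd[m] == 0 or not math.isfinite(sd[m])]
    if degenerate:
        raise ValueError(f"zero reference-group s.d. for miRNAs: {degenerate}")
    z = q.sub(mu, axis=0).div(sd, axis=0)
    z.attrs["reference_group"] = reference
    return z


def duplicate_concordance(
    z: pd.DataFrame, s1: str, s2: str
) -> tuple[float, float, int]:
    """Pearson r of two sample columns and its rank among all pairs.

    Returns ``(r, percentile, n_pairs)`` where ``n_pairs = n(n-1)/2`` over
    the matrix's samples and ``percentile`` is the percentage of all
    sample-pair correlations that do not exceed the (s1, s2) pair's.
    """
    for s in (s1, s2):
        if s not in z.columns:
            raise KeyError(f"unknown sample id: {s!r}")
    if len(z.index) < 3:
        raise ValueError("need >= 3 miRNAs for a meaningful correlation")
    mat = z.to_numpy(dtype=float)
    if np.ptp(mat[:, z.columns.get_loc(s1)]) == 0 or np.ptp(mat[:, z.columns.get_loc(s2)]) == 0:
        raise ValueError("correlation undefined for a constant sample column")
    corr = np.corrcoef(mat.T)
    i, j = z.columns.get_loc(s1), z.columns.get_loc(s2)
    r = float(corr[i, j])
    n = len(z.columns)
    iu = np.triu_indices(n, k=1)
    all_r = corr[iu]
    all_r = all_r[np.isfinite(all_r)]
    percentile = 100.0 * float(np.mean(all_r <= r))
    return r, percentile, n * (n - 1) // 2


def drop_least_concordant(z: pd.DataFrame, s1: str, s2: str, k: int = 20) -> float:
    """Pearson r of two columns after dropping the k least-concordant miRNAs.

    "Least concordant" is operationalized as the smallest per-miRNA
    contribution ``(x_i - x̄)(y_i - ȳ)`` to the centered cross-product of
    the two columns.  Dropping rows that fight the correlation can only
    raise it on the kinds of discordance this QC step targets.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if k >= len(z.index) - 2:
        raise ValueError("k must leave at least 3 miRNAs")
    x = z[s1].to_numpy(dtype=float)
    y = z[s2].to_numpy(dtype=float)
    contrib = (x - x.mean()) * (y - y.mean())
    keep = np.argsort(contrib, kind="stable")[k:] if k else np.arange(x.size)
    xr, yr = x[keep], y[keep]
    if np.ptp(xr) == 0 or np.ptp(yr) == 0:
        raise ValueError("correlation undefined after dropping miRNAs")
    return float(np.corrcoef(xr, yr)[0, 1])


def null_correlation_tail(r: float, dim: int) -> float:
    """P(R > r) for the Pearson correlation of two independent normal vectors.

    Exact null tail via the t-transform ``t = r sqrt((n-2)/(1-r^2))`` with
    ``n-2`` degrees of freedom, where ``n = dim`` is the vector length.
    One-sided; ``r = 0`` gives 0.5 by symmetry.
    """
    if not -1 < r < 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    if dim < 3:
        raise ValueError(f"dim must be >= 3, got {dim}")
    df = dim - 2
    t = r * math.sqrt(df / (1.0 - r * r))
    return float(stats.t.sf(t, df))


def pcr_mean_center(cq: pd.DataFrame) -> pd.DataFrame:
    """Subtract each subject's mean Cq from that subject's raw Cq values.

    Subjects are columns.  Missing values are dropped from the subject's
    average (and stay missing in the output); an all-missing subject is
    rejected.  Column means of the result are 0, so gross per-sample
    biases (e.g. input amount) cancel.
    """
    for s in cq.columns:
        if cq[s].dropna().empty:
            raise ValueError(f"subject {s!r} has no Cq values")
    return cq - cq.mean(axis=0, skipna=True)


def cross_platform_concordance(
    cq: pd.DataFrame,
    counts: pd.DataFrame,
    *,
    negate_cq: bool = True,
) -> tuple[pd.Series, dict]:
    """Per-subject Spearman correlation of qPCR and sequencing values.

    Cq is inversely monotone in abundance, so by default ``-Cq`` is
    correlated against read counts and concordance comes out positive;
    ``negate_cq=False`` gives the raw orientation.  Returns the
    per-subject rho Series and a summary with mean, s.d. (n-1) and min.
    """
    subjects = [s for s in cq.columns if s in counts.columns]
    if not subjects:
        raise ValueError("no shared subjects between Cq and count matrices")
    rhos = {}
    for s in subjects:
        shared = cq.index.intersection(counts.index)
        pair = pd.DataFrame({"cq": cq.loc[shared, s], "ct": counts.loc[shared, s]}).dropna()
        if len(pair) < 3:
            raise ValueError(f"subject {s!r}: fewer than 3 shared miRNAs")
        x = -pair["cq"] if negate_cq else pair["cq"]
        rho = stats.spearmanr(x, pair["ct"]).statistic
        rhos[s] = float(rho)
    rho_s = pd.Series(rhos)
    summary = {
        "n_subjects": len(rho_s),
        "mean": float(rho_s.mean()),
        "sd": float(rho_s.std(ddof=1)) if len(rho_s) > 1 else float("nan"),
        "min": float(rho_s.min()),
    }
    return rho_s, summary
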