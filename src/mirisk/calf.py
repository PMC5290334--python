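"""CALF: Coarse Approximation Linear Function classifier.

A greedy forward-selection classifier whose markers carry only +1 or -1
weights.  Iteration 1 picks the single miRNA whose z-scores best separate
the two classes by two-sample t-test p-value, oriented so the classifier
increases with risk (positive class has the higher mean).  Each later
iteration tries every unused miRNA with both signs added to the running
weighted sum and accepts the best candidate only if it strictly lowers
the p-value; the search stops at the marker limit or when no candidate
improves the metric.  Coarse weights trade a little training fit for
stability: refitting on perturbed subsets tends to reproduce identical
weights, which real-valued regression coefficients rarely do.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ClassifierModel:
    """An ordered set of (miRNA id, +/-1 weight) terms with its fit trace."""

    terms: list[tuple[str, int]]
    metric_trace: list[float] = field(default_factory=list)
    final_auc: float | None = None

    def __post_init__(self) -> None:
        ids = [t[0] for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate miRNA ids in model terms")
        if any(w not in (+1, -1) for _, w in self.terms):
            raise ValueError("weights must be +1 or -1")

    def to_json(self, path=None) -> str:
        payload = {
            "terms": [{"mirna": m, "weight": w} for m, w in self.terms],
            "metric_trace": self.metric_trace,
            "final_auc": self.final_auc,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "ClassifierModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            terms=[(t["mirna"], int(t["weight"])) for t in payload["terms"]],
            metric_trace=list(payload.get("metric_trace", [])),
            final_auc=payload.get("final_auc"),
        )


@dataclass
class RocCurve:
    """Empirical ROC points with a pointwise bootstrap confidence band."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    band_fpr: np.ndarray | None = None
    band_lo: np.ndarray | None = None
    band_hi: np.ndarray | None = None


def two_sample_t_pvalue(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided pooled-variance Student t-test p-value.

    Degenerate inputs (zero pooled variance) return p = 1 with a warning,
    so a greedy search simply never prefers them.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    p = _pooled_t_pvalues(
        np.vstack([np.concatenate([x, y])]),
        np.arange(x.size + y.size) < x.size,
    )[0]
    if p == 1.0 and np.var(np.concatenate([x, y])) == 0:
        warnings.warn("degenerate (zero-variance) t-test input; p set to 1", stacklevel=2)
    return float(p)


def _pooled_t_pvalues(X: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Row-wise pooled t-test p-values for candidate score matrices.

    ``X`` is (n_candidates, n_samples); ``mask_a`` marks group A columns.
    Rows with zero pooled variance get p = 1.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = ~mask_a
    n1, n2 = int(mask_a.sum()), int(mask_b.sum())
    a, b = X[:, mask_a], X[:, mask_b]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    v1 = a.var(axis=1, ddof=1)
    v2 = b.var(axis=1, ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m2 - m1) / denom
    p = np.ones(X.shape[0])
    ok = np.isfinite(t) & (denom > 0)
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), n1 + n2 - 2)
    return p


def _as_matrix(z) -> tuple[np.ndarray, list[str]]:
    if isinstance(z, pd.DataFrame):
        return z.to_numpy(dtype=float), list(z.index)
    z = np.asarray(z, dtype=float)
    return z, [str(i) for i in range(z.shape[0])]


def greedy_calf(z, labels, max_markers: int = 6) -> ClassifierModel:
    """Greedy +/-1-weight marker selection minimizing the t-test p-value.

    Parameters
    ----------
    z : DataFrame (miRNA x sample) or 2-D array
        Normalized expression; rows are candidate markers.
    labels : boolean sequence per sample
        True marks the positive (risk) class.
    max_markers : int
        Upper bound on selected markers; selection also stops early when
        no candidate strictly improves the metric.

    Ties among equal p-values break deterministically: lowest miRNA id,
    and +1 before -1 within a marker.
    """
    Z, ids = _as_matrix(z)
    labels = np.asarray(labels, dtype=bool)
    if labels.size != Z.shape[1]:
        raise ValueError("labels length must match number of samples")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("both classes need at least 2 samples")
    if max_markers < 1:
        raise ValueError("max_markers must be >= 1")

    mask_neg = ~labels  # group A = negative class; t-test is symmetric in sign
    unused = np.ones(Z.shape[0], dtype=bool)
    terms: list[tuple[str, int]] = []
    trace: list[float] = []
    running = np.zeros(Z.shape[1])
    best_p = np.inf

    while len(terms) < max_markers:
        cand_idx = np.flatnonzero(unused)
        if cand_idx.size == 0:
            break
        plus = running + Z[cand_idx]
        minus = running - Z[cand_idx]
        p_plus = _pooled_t_pvalues(plus, mask_neg)
        p_minus = _pooled_t_pvalues(minus, mask_neg)

        best = None  # (p, id, sign, row)
        for j, row in enumerate(cand_idx):
            for sign, p in ((+1, p_plus[j]), (-1, p_minus[j])):
                key = (p, ids[row], -sign)
                if best is None or key < best[0]:
                    best = (key, row, sign)
        (p_best, _, _), row, sign = best
        if not p_best < best_p:
            break
        if not terms:
            # Orient the first marker so the positive class scores higher.
            zrow = Z[row]
            if zrow[labels].mean() < zrow[~labels].mean():
                sign = -1
            running = sign * zrow
        else:
            running = running + sign * Z[row]
        terms.append((ids[row], sign))
        trace.append(float(p_best))
        best_p = p_best
        unused[row] = False

    model = ClassifierModel(terms=terms, metric_trace=trace)
    model.final_auc = auc(score_samples(model, z), labels) if terms else 0.5
    return model


def score_samples(model: ClassifierModel, z) -> pd.Series:
    """Signed sum of z-scores per sample under the model's weights."""
    if isinstance(z, pd.DataFrame):
        missing = [m for m, _ in model.terms if m not in z.index]
        if missing:
            raise KeyError(f"model miRNAs missing from matrix: {missing}")
        scores = pd.Series(0.0, index=z.columns)
        for m, w in model.terms:
            scores = scores + w * z.loc[m]
        return scores
    Z = np.asarray(z, dtype=float)
    scores = np.zeros(Z.shape[1])
    for m, w in model.terms:
        scores += w * Z[int(m)]
    return pd.Series(scores)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney estimate, ties count 1/2).

    Equals the probability that a random positive-class sample scores
    above a random negative-class sample.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(
    scores,
    labels,
    bootstrap_n: int = 2000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> RocCurve:
    """Empirical ROC points plus a pointwise percentile bootstrap band.

    The band resamples each class with replacement and reports the
    alpha/2 and 1-alpha/2 percentiles of sensitivity on a fixed
    1-specificity grid.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    fpr, tpr, thr = _sk_roc(labels, scores, drop_intermediate=False)
    a = auc(scores, labels)

    grid = np.linspace(0.0, 1.0, 101)
    band_lo = band_hi = None
    if bootstrap_n > 0:
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        sens = np.empty((bootstrap_n, grid.size))
        for b in range(bootstrap_n):
            bp = rng.choice(pos, size=pos.size, replace=True)
            bn = rng.choice(neg, size=neg.size, replace=True)
            bl = np.concatenate([np.ones(bp.size, bool), np.zeros(bn.size, bool)])
            bf, bt, _ = _sk_roc(bl, np.concatenate([bp, bn]), drop_intermediate=False)
            sens[b] = np.interp(grid, bf, bt)
        band_lo = np.quantile(sens, alpha / 2.0, axis=0)
        band_hi = np.quantile(sens, 1.0 - alpha / 2.0, axis=0)
    return RocCurve(
        fpr=fpr, tpr=tpr, thresholds=thr, auc=a,
        band_fpr=grid, band_lo=band_lo, band_hi=band_hi,
    )


def apply_to_groups(
    model: ClassifierModel,
    z: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str,
) -> float:
    """AUC of a fixed model restricted to two metadata groups.

    ``group_b`` is treated as the positive class.
    """
    for g in (group_a, group_b):
        if g not in set(metadata["group"]):
            raise ValueError(f"unknown group: {g!r}")
    sel = metadata[metadata["group"].isin([group_a, group_b])]
    samples = [s for s in sel["sample_id"] if s in z.columns]
    lbl = sel.set_index("sample_id").loc[samples, "group"] == group_b
    if lbl.sum() < 2 or (~lbl).sum() < 2:
        raise ValueError("both groups need at least 2 samples with expression data")
    scores = score_samples(model, z[samples])
    return auc(scores.to_numpy(), lbl.to_numpy())
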