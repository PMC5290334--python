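"""Resampling validation of the whole classifier-building procedure.

The prudent-classifier framework validates not a fixed model but the
model-building algorithm itself:

1. train on true labels and record the performance number (training AUC);
2. randomly permute the case/control labels and re-run the *entire*
   greedy selection on the pseudo data, many times, recording each pseudo
   AUC — the true AUC's rank in that null yields an add-one Monte Carlo
   p-value, with a beta-distribution fit as a smooth alternative;
3. re-run the selection on many random 80% subsets of each class and
   tally how often each marker is chosen (stability selection);
4. integrate: keep the markers that are both stably selected and present
   in the full-data model, with the full-data weights;
5. probe robustness of the fixed integrated model on random fixed-size
   subsets, optionally stratified to maximize or minimize a binary
   confounder such as medication exposure.

Only the two compared classes are ever permuted or subsampled; the
unaffected reference group defines the z-score scale and stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mirisk.calf import ClassifierModel, auc, greedy_calf, score_samples


@dataclass
class PermutationSummary:
    """Null distribution of training AUCs under label permutation."""

    true_auc: float
    pseudo_aucs: np.ndarray
    p_montecarlo: float
    p_beta: float
    seed: int | None
    true_model: ClassifierModel | None = None


@dataclass
class StabilitySummary:
    """Per-marker selection counts over random class subsets."""

    n_trials: int
    counts: pd.Series  # index: miRNA id; values: times selected
    subset_fraction: float
    max_markers: int

    def stable_set(self, min_count: int) -> list[str]:
        return [m for m in self.counts.index if self.counts[m] >= min_count]


def monte_carlo_pvalue(k_exceed: int, n_trials: int) -> float:
    """Add-one Monte Carlo p-value (k+1)/(N+1).

    ``k_exceed`` null statistics met the exceedance rule among
    ``n_trials`` resamples; the add-one correction keeps the estimate
    strictly positive and unbiased-conservative.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 <= k_exceed <= n_trials:
        raise ValueError(f"k_exceed must be in [0, {n_trials}], got {k_exceed}")
    return (k_exceed + 1) / (n_trials + 1)


def beta_fit_pvalue(pseudo_aucs, true_auc: float) -> float:
    """Upper tail of a maximum-likelihood beta fit to the pseudo AUCs.

    Values at exactly 0 or 1 are nudged inward by machine epsilon before
    fitting.  Smooth alternative to the rank-based Monte Carlo p-value;
    can extrapolate beyond the observed null range.
    """
    x = np.asarray(pseudo_aucs, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 pseudo values for a beta fit")
    if ((x < 0) | (x > 1)).any():
        raise ValueError("pseudo AUCs must lie in [0, 1]")
    eps = np.finfo(float).eps
    x = np.clip(x, eps, 1.0 - eps)
    try:
        a, b, _, _ = stats.beta.fit(x, floc=0.0, fscale=1.0)
    except Exception as exc:  # scipy raises FitSolverError on stiff MLEs
        raise RuntimeError(f"beta fit did not converge: {exc}") from exc
    if not (np.isfinite(a) and np.isfinite(b)):
        raise RuntimeError("beta fit did not converge")
    return float(stats.beta.sf(true_auc, a, b))


def _two_class_arrays(z, labels):
    if isinstance(z, pd.DataFrame):
        Z = z.to_numpy(dtype=float)
        ids = list(z.index)
    else:
        Z = np.asarray(z, dtype=float)
        ids = [str(i) for i in range(Z.shape[0])]
    labels = np.asarray(labels, dtype=bool)
    if labels.size != Z.shape[1]:
        raise ValueError("labels length must match number of samples")
    return Z, ids, labels


def permutation_test(
    z,
    labels,
    n_perm: int = 1000,
    max_markers: int = 6,
    seed: int | None = None,
) -> PermutationSummary:
    """Permutation null for the greedy training procedure.

    Class labels of the compared samples are permuted (class sizes
    preserved exactly) and the entire greedy selection re-run per
    permutation; the training AUCs of these pseudo classifiers form the
    null.  "Exceeds" is strict (pseudo > true) in the Monte Carlo count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Z, ids, labels = _two_class_arrays(z, labels)
    rng = np.random.default_rng(seed)

    true_model = greedy_calf(z, labels, max_markers=max_markers)
    true_auc = true_model.final_auc

    pseudo = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(labels)
        pseudo[i] = greedy_calf(Z, perm, max_markers=max_markers).final_auc
    k = int((pseudo > true_auc).sum())
    if n_perm >= 10:
        try:
            p_beta = beta_fit_pvalue(pseudo, true_auc)
        except RuntimeError:
            p_beta = float("nan")  # rank-based p_montecarlo remains valid
    else:
        p_beta = float("nan")
    return PermutationSummary(
        true_auc=float(true_auc),
        pseudo_aucs=pseudo,
        p_montecarlo=monte_carlo_pvalue(k, n_perm),
        p_beta=p_beta,
        seed=seed,
        true_model=true_model,
    )


def stability_selection(
    z,
    labels,
    subset_fraction: float = 0.8,
    n_trials: int = 1000,
    max_markers: int = 6,
    seed: int | None = None,
) -> StabilitySummary:
    """How often each marker is selected over random class subsets.

    Per trial, an independent uniform without-replacement subset of each
    class (size ``floor(fraction * class size)``) is drawn and the greedy
    selection re-run; counts tally selections regardless of sign.
    """
    Z, ids, labels = _two_class_arrays(z, labels)
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    n_pos = int(np.floor(subset_fraction * pos.size))
    n_neg = int(np.floor(subset_fraction * neg.size))
    if n_pos < 2 or n_neg < 2:
        raise ValueError("subset_fraction leaves fewer than 2 samples in a class")
    rng = np.random.default_rng(seed)
    counts = pd.Series(0, index=ids, dtype=int)
    for _ in range(n_trials):
        sp = rng.choice(pos, size=n_pos, replace=False)
        sn = rng.choice(neg, size=n_neg, replace=False)
        cols = np.concatenate([sn, sp])
        sub_labels = np.concatenate([np.zeros(n_neg, bool), np.ones(n_pos, bool)])
        model = greedy_calf(Z[:, cols], sub_labels, max_markers=max_markers)
        for row_id, _ in model.terms:
            counts[ids[int(row_id)]] += 1
    return StabilitySummary(
        n_trials=n_trials,
        counts=counts,
        subset_fraction=subset_fraction,
        max_markers=max_markers,
    )


def integrate_classifier(
    stability: StabilitySummary,
    full_model: ClassifierModel,
    min_count: int = 225,
) -> ClassifierModel:
    """Intersect the stable marker set with the full-data model.

    Markers selected in at least ``min_count`` stability trials *and*
    present in the full-data model are retained, with the full-data
    weights and order.  An empty intersection is an error — the stability
    threshold should be reviewed rather than silently returning an empty
    classifier.
    """
    if not full_model.terms:
        raise ValueError("full_model has no terms")
    stable = set(stability.stable_set(min_count))
    terms = [(m, w) for m, w in full_model.terms if m in stable]
    if not terms:
        raise ValueError(
            f"no full-model marker reached {min_count} of {stability.n_trials} "
            "stability selections; review the threshold"
        )
    return ClassifierModel(terms=terms)


def subset_auc_distribution(
    model: ClassifierModel,
    z,
    labels,
    n_per_group: int = 25,
    n_trials: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """AUC distribution of a fixed model over random equal-size subsets.

    No retraining: the model is scored on ``n_per_group`` samples drawn
    without replacement from each class, ``n_trials`` times.  Returns
    (mean, s.d., all AUCs).
    """
    if not isinstance(z, pd.DataFrame):
        raise TypeError("z must be a DataFrame with miRNA ids as index")
    labels = np.asarray(labels, dtype=bool)
    scores = score_samples(model, z).to_numpy()
    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    if pos.size < n_per_group or neg.size < n_per_group:
        raise ValueError(f"each class needs >= {n_per_group} samples")
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_trials)
    for i in range(n_trials):
        sp = rng.choice(pos, size=n_per_group, replace=False)
        sn = rng.choice(neg, size=n_per_group, replace=False)
        s = np.concatenate([scores[sn], scores[sp]])
        l = np.concatenate([np.zeros(n_per_group, bool), np.ones(n_per_group, bool)])
        aucs[i] = auc(s, l)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs


def confound_extremal_subsets(
    model: ClassifierModel,
    z,
    labels,
    flag,
    n_per_group: int = 25,
    n_trials: int = 1000,
    mode: str = "maximize",
    seed: int | None = None,
) -> np.ndarray:
    """AUCs of a fixed model on subsets extremal in a binary confounder.

    Per class, all flagged samples (``mode='maximize'``) or all unflagged
    samples (``mode='minimize'``) enter first; the subset is filled to
    ``n_per_group`` with a uniform draw from the remainder.  If the AUC
    range is insensitive to the mode, the confounder has little influence
    on the classifier.
    """
    if mode not in ("maximize", "minimize"):
        raise ValueError("mode must be 'maximize' or 'minimize'")
    if not isinstance(z, pd.DataFrame):
        raise TypeError("z must be a DataFrame with miRNA ids as index")
    labels = np.asarray(labels, dtype=bool)
    flag = np.asarray(flag, dtype=bool)
    if flag.size != labels.size:
        raise ValueError("flag must be defined for every sample")
    scores = score_samples(model, z).to_numpy()
    rng = np.random.default_rng(seed)

    def draw(cls_idx: np.ndarray) -> np.ndarray:
        preferred = cls_idx[flag[cls_idx]] if mode == "maximize" else cls_idx[~flag[cls_idx]]
        rest = np.setdiff1d(cls_idx, preferred)
        if cls_idx.size < n_per_group:
            raise ValueError(f"class has only {cls_idx.size} samples; need {n_per_group}")
        if preferred.size >= n_per_group:
            return rng.choice(preferred, size=n_per_group, replace=False)
        fill = rng.choice(rest, size=n_per_group - preferred.size, replace=False)
        return np.concatenate([preferred, fill])

    pos = np.flatnonzero(labels)
    neg = np.flatnonzero(~labels)
    aucs = np.empty(n_trials)
    for i in range(n_trials):
        sp, sn = draw(pos), draw(neg)
        s = np.concatenate([scores[sn], scores[sp]])
        l = np.concatenate([np.zeros(n_per_group, bool), np.ones(n_per_group, bool)])
        aucs[i] = auc(s, l)
    return aucs
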