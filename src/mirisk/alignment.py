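"""Smith-Waterman similarity of miRNA sequences with a Monte Carlo null.

Local alignment with unit weights (match +1, mismatch -1, linear gap -1
per gap symbol, zero floor) measures mutual sequence similarity among a
selected marker panel; a Monte Carlo null draws same-size panels from a
background pool and asks how often random panels are at least as mutually
similar (inclusive exceedance), yielding an add-one p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from mirisk.quantify import MatureMirna, canonicalize_rna
from mirisk.validation import monte_carlo_pvalue

#: miRBase v21 mature sequences of the five-miRNA leukocyte
#: psychosis-risk panel (miR-941 up-weighted together with miR-103a-3p;
#: miR-92a-3p, miR-199a-3p and miR-31-5p carry weight -1 in the
#: risk-increasing classifier).
RISK_PANEL_V21: dict[str, str] = {
    "hsa-miR-941": "CACCCGGCUGUGUGCACAUGUGC",
    "hsa-miR-103a-3p": "AGCAGCAUUGUACAGGGCUAUGA",
    "hsa-miR-92a-3p": "UAUUGCACUUGUCCCGGCCUGU",
    "hsa-miR-199a-3p": "ACAGUAGUCUGCACAUUGGUUA",
    "hsa-miR-31-5p": "AGGCAAGAUGCUGGCAUAGCU",
}


@dataclass(frozen=True)
class AlignmentParams:
    """Unit alignment weights; gap is linear (per gap symbol)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0

    def __post_init__(self) -> None:
        if not self.match > 0:
            raise ValueError("match weight must be positive")
        if self.mismatch > 0:
            raise ValueError("mismatch weight must be <= 0")
        if self.gap > 0:
            raise ValueError("gap weight must be <= 0")


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local score with one optimal traceback's decomposition."""

    score: float
    n_match: int
    n_mismatch: int
    n_gap: int


def _as_seq(s) -> str:
    if isinstance(s, MatureMirna):
        s = s.sequence
    seq = canonicalize_rna(str(s))
    if not seq:
        raise ValueError("empty sequence")
    return seq


def smith_waterman(a, b, params: AlignmentParams | None = None) -> AlignmentResult:
    """Optimal local alignment score with linear gaps and zero floor.

    Returns the score and the match/mismatch/gap counts of one optimal
    traceback (ties resolved diagonal > up > left), satisfying
    ``score = match*n_match + mismatch*n_mismatch + gap*n_gap``.
    """
    params = params or AlignmentParams()
    sa, sb = _as_seq(a), _as_seq(b)
    la, lb = len(sa), len(sb)
    H = np.zeros((la + 1, lb + 1))
    for i in range(1, la + 1):
        ca = sa[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, lb + 1):
            d = prev[j - 1] + (params.match if ca == sb[j - 1] else params.mismatch)
            row[j] = max(0.0, d, prev[j] + params.gap, row[j - 1] + params.gap)
    score = float(H.max())
    if score == 0.0:
        return AlignmentResult(0.0, 0, 0, 0)
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    n_match = n_mismatch = n_gap = 0
    while H[i, j] > 0:
        diag = H[i - 1, j - 1] + (
            params.match if sa[i - 1] == sb[j - 1] else params.mismatch
        )
        if i > 0 and j > 0 and H[i, j] == diag:
            if sa[i - 1] == sb[j - 1]:
                n_match += 1
            else:
                n_mismatch += 1
            i, j = i - 1, j - 1
        elif i > 0 and H[i, j] == H[i - 1, j] + params.gap:
            n_gap += 1
            i -= 1
        else:
            n_gap += 1
            j -= 1
    return AlignmentResult(score, n_match, n_mismatch, n_gap)


def pairwise_average(
    seqs: Sequence, params: AlignmentParams | None = None
) -> tuple[float, pd.DataFrame]:
    """Mean Smith-Waterman score over all C(k, 2) sequence pairs.

    Returns (off-diagonal mean, symmetric score matrix with NaN
    diagonal).  Sequences may be strings or :class:`MatureMirna`.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or AlignmentParams()
    names = [s.id if isinstance(s, MatureMirna) else f"seq{i}" for i, s in enumerate(seqs)]
    k = len(seqs)
    mat = np.full((k, k), np.nan)
    scores = []
    for i in range(k):
        for j in range(i + 1, k):
            s = smith_waterman(seqs[i], seqs[j], params).score
            mat[i, j] = mat[j, i] = s
            scores.append(s)
    return float(np.mean(scores)), pd.DataFrame(mat, index=names, columns=names)


def similarity_null_test(
    selected: Sequence,
    pool: Sequence,
    n_trials: int = 1000,
    params: AlignmentParams | None = None,
    seed: int | None = None,
) -> tuple[float, np.ndarray, float]:
    """Monte Carlo test of whether selected markers are mutually similar.

    Draws ``n_trials`` same-size panels from ``pool`` (without
    replacement within a draw), computes each panel's pairwise-average
    score, counts draws whose mean is at least the observed mean
    (inclusive exceedance) and returns ``(observed mean, null means,
    add-one p-value)``.  The pool must not contain any selected sequence.
    """
    params = params or AlignmentParams()
    k = len(selected)
    if k < 2:
        raise ValueError("need at least 2 selected sequences")
    if len(pool) < k:
        raise ValueError(f"pool must contain at least k={k} sequences")
    sel_seqs = {_as_seq(s) for s in selected}
    pool_seqs = [_as_seq(s) for s in pool]
    if sel_seqs & set(pool_seqs):
        raise ValueError("pool must be disjoint from the selected set")
    observed, _ = pairwise_average(list(selected), params)
    # Pool pair scores are reused across draws; align each pair once.
    n = len(pool_seqs)
    pool_scores = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            s = smith_waterman(pool_seqs[i], pool_seqs[j], params).score
            pool_scores[i, j] = pool_scores[j, i] = s
    rng = np.random.default_rng(seed)
    null = np.empty(n_trials)
    iu = np.triu_indices(k, 1)
    for t in range(n_trials):
        draw = rng.choice(n, size=k, replace=False)
        null[t] = pool_scores[np.ix_(draw, draw)][iu].mean()
    k_exceed = int((null >= observed).sum())
    return observed, null, monte_carlo_pvalue(k_exceed, n_trials)
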