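"""Scoring model predictions against the ground-truth grouping.

AUC here is the Mann-Whitney probability that a randomly chosen positive
sample scores above a randomly chosen negative one, ties counted one half.
Two orientations are offered:

* ``direction="fixed"``: higher score means class 1, never flipped, so values
  below 0.5 are reported as such.
* ``direction="auto"``: the orientation is chosen by comparing the median
  score of the two classes (flip when the negative-class median is higher),
  the default convention of the standard ROC tooling.  This is a median heuristic, not a
  maximisation — AUCs at or below 0.5 still occur.

The multiclass AUC is the Hand-Till style unweighted average over all
unordered class pairs of the pairwise AUC of the single score vector, which
reduces exactly to the binary AUC for two classes.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

from .exceptions import InvalidInputError, UndefinedAUCError

__all__ = ["auc_binary", "auc_multiclass", "auc_ranks"]


def _mann_whitney_auc(scores: np.ndarray, positive: np.ndarray) -> float:
    n_pos = int(positive.sum())
    n_neg = positive.size - n_pos
    ranks = rankdata(scores)  # midranks handle ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_binary(scores, truth, direction: str = "fixed") -> float:
    """AUC of real-valued scores against 0/1 truth.

    With ``direction="fixed"`` a higher score is evidence for class 1; with
    ``direction="auto"`` the median rule described in the module docstring
    picks the orientation first.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if scores.shape != truth.shape:
        raise InvalidInputError("scores and truth must have equal length")
    positive = truth == 1
    if positive.all() or not positive.any():
        raise UndefinedAUCError("both classes must be present in truth")
    auc = _mann_whitney_auc(scores, positive)
    if direction == "auto":
        if np.median(scores[~positive]) > np.median(scores[positive]):
            auc = 1.0 - auc  # exact complement, ties contribute 1/2 both ways
    elif direction != "fixed":
        raise InvalidInputError(f"unknown direction: {direction!r}")
    return auc


def auc_multiclass(scores, truth, direction: str = "fixed") -> float:
    """Average pairwise AUC of one score vector over all class pairs.

    For each unordered pair of observed classes (i < j) the binary AUC is
    computed on the samples of those classes with j as the positive class;
    the multiclass AUC is the unweighted mean over pairs.  Exactly two
    classes reduce to :func:`auc_binary`.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    classes = np.unique(truth)
    if classes.size < 2:
        raise UndefinedAUCError("need at least two classes in truth")
    aucs = []
    for a_idx in range(classes.size):
        for b_idx in range(a_idx + 1, classes.size):
            mask = (truth == classes[a_idx]) | (truth == classes[b_idx])
            aucs.append(
                auc_binary(
                    scores[mask], (truth[mask] == classes[b_idx]).astype(int), direction
                )
            )
    return float(np.mean(aucs))


def auc_ranks(
    auc_table, tie_method: str = "average", seed: int | None = None
) -> np.ndarray:
    """Rank competing pipelines' AUCs within each matched condition.

    ``auc_table`` is an (n_conditions, n_variants) array of AUCs obtained on
    identical conditions; the result holds, per condition, the rank of each
    variant's AUC (1 = lowest).  Ties are resolved by the mean rank
    (``"average"``) or broken by a seeded random permutation (``"random"``),
    in which case every integer rank is used exactly once per condition.
    """
    table = np.atleast_2d(np.asarray(auc_table, dtype=float))
    if tie_method == "average":
        return np.vstack([rankdata(row, method="average") for row in table])
    if tie_method == "random":
        rng = np.random.default_rng(seed)
        out = np.empty_like(table)
        for i, row in enumerate(table):
            perm = rng.permutation(row.size)
            out[i, perm] = rankdata(row[perm], method="ordinal")
        return out
    raise InvalidInputError(f"unknown tie method: {tie_method!r}")
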