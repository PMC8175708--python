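"""Statistical machinery for blinded model comparison.

Four tools mirror a crowdsourced-challenge scoring pipeline:

* :func:`bootstrap_compare` — paired bootstrap (same resample applied to
  both prediction sets per iteration) with a Bayes factor
  ``K = wins_ref / wins_other`` summarizing how often the reference set
  scores better; ties are split evenly between the two sides.
* :func:`ladder_update` — anti-overfitting submission rule: a new
  submission's score is only accepted when it beats the previous one
  with K > 3 ("substantially better").
* :func:`permutation_null` — random-prediction baseline from shuffling
  the measured pKd values across pairs; a prediction counts as better
  than random when it beats all permuted scores (empirical P = 0.0).
* :func:`replicate_bound` — the practical upper bound on any model's
  accuracy, from bootstrapping replicate pKd measurements between two
  independent profiling studies after matching the inactive-pair
  (pKd = 5) fraction of the test set.

Metric direction is handled throughout: higher is better for
{spearman, pearson, ci, f1, avg_auc}, lower is better for {rmse}.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import f1_score, roc_auc_score

from .io import InteractionTable, PredictionSet
from .metrics import AVG_AUC_THRESHOLDS, F1_CUTOFF, _ci_from_arrays

__all__ = [
    "HIGHER_BETTER",
    "BootstrapComparison",
    "LadderDecision",
    "NullDistribution",
    "ReplicateBound",
    "bootstrap_compare",
    "ladder_update",
    "permutation_null",
    "replicate_bound",
]

HIGHER_BETTER = {
    "spearman": True,
    "pearson": True,
    "ci": True,
    "f1": True,
    "avg_auc": True,
    "rmse": False,
}


@dataclass
class BootstrapComparison:
    """Paired bootstrap score distributions and the resulting Bayes factor.

    ``bayes_factor`` is the win-count ratio in favor of set b (the
    reference): ``K = (wins_b + ties/2) / (wins_a + ties/2)``; a zero
    denominator yields ``inf``.  Reciprocal under swapping a and b.
    """

    metric: str
    model_a: str
    model_b: str
    n_boot: int
    seed: int
    scores_a: np.ndarray
    scores_b: np.ndarray
    wins_a: int
    wins_b: int
    ties: int
    bayes_factor: float

    def to_dict(self) -> dict:
        k = self.bayes_factor
        return {
            "metric": self.metric,
            "model_a": self.model_a,
            "model_b": self.model_b,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "wins_a": self.wins_a,
            "wins_b": self.wins_b,
            "ties": self.ties,
            "bayes_factor": "inf" if math.isinf(k) else k,
        }


@dataclass
class LadderDecision:
    """Outcome of one ladder-protocol submission."""

    accepted: bool
    candidate_score: float
    previous_score: float | None
    comparison: BootstrapComparison | None


@dataclass
class NullDistribution:
    """Permutation null of a metric plus an observed score's placement."""

    metric: str
    n_perm: int
    seed: int
    values: np.ndarray
    observed: float
    empirical_p: float

    @property
    def better_than_random(self) -> bool:
        """True when the observed score beats every permuted score."""
        if HIGHER_BETTER[self.metric]:
            return bool(self.observed > self.values.max())
        return bool(self.observed < self.values.min())


@dataclass
class ReplicateBound:
    """Bootstrap distributions of between-study replicate agreement."""

    spearman_values: np.ndarray
    rmse_values: np.ndarray
    n_sub: int
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------
# vectorized row-wise scoring
# ---------------------------------------------------------------------------

def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    num = np.sum(A * B, axis=1)
    den = np.sqrt(np.sum(A * A, axis=1) * np.sum(B * B, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)


def _rowwise_scores(metric: str, P: np.ndarray, T: np.ndarray) -> np.ndarray:
    """Score each row of predictions P against the matching row of truths T."""
    if metric == "rmse":
        return np.sqrt(np.mean((P - T) ** 2, axis=1))
    if metric == "pearson":
        return _rowwise_pearson(P, T)
    if metric == "spearman":
        return _rowwise_pearson(
            stats.rankdata(P, axis=1), stats.rankdata(T, axis=1)
        )
    if metric == "ci":
        return np.array([_ci_from_arrays(p, t) for p, t in zip(P, T)])
    if metric == "f1":
        return np.array(
            [
                f1_score(t > F1_CUTOFF, p > F1_CUTOFF, zero_division=0.0)
                for p, t in zip(P, T)
            ]
        )
    if metric == "avg_auc":
        out = np.empty(len(P))
        for i, (p, t) in enumerate(zip(P, T)):
            aucs = [
                roc_auc_score(t > thr, p)
                for thr in AVG_AUC_THRESHOLDS
                if 0 < np.sum(t > thr) < len(t)
            ]
            out[i] = np.mean(aucs) if aucs else np.nan
        return out
    raise ValueError(f"unknown metric {metric!r}")


def _aligned_values(
    preds: Sequence[PredictionSet], measured: InteractionTable
) -> tuple[list[np.ndarray], np.ndarray]:
    pairs = measured.pairs()
    vectors = []
    for ps in preds:
        missing = [p for p in pairs if p not in ps.entries]
        if missing:
            raise KeyError(
                f"prediction set {ps.model_id!r} missing measured pairs, "
                f"e.g. {missing[:3]}"
            )
        vectors.append(ps.values_for(pairs))
    return vectors, measured.frame["pkd"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# bootstrap Bayes factor & ladder
# ---------------------------------------------------------------------------

def bootstrap_compare(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    measured: InteractionTable,
    metric: str = "spearman",
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapComparison:
    """Paired bootstrap comparison of two prediction sets.

    Each iteration resamples the measured pairs with replacement (the
    identical resample indexing both sets — the paired design reduces
    variance) and scores both sets; a win is counted for whichever set
    is strictly better in the metric's favorable direction, and exact
    ties are split half-and-half.  ``pred_b`` plays the reference role:
    ``K > 1`` favors it.
    """
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    if metric not in HIGHER_BETTER:
        raise ValueError(f"unknown metric {metric!r}")
    (va, vb), truth = _aligned_values([pred_a, pred_b], measured)
    rng = np.random.default_rng(seed)
    n = len(truth)
    idx = rng.integers(0, n, size=(n_boot, n))
    T = truth[idx]
    scores_a = _rowwise_scores(metric, va[idx], T)
    scores_b = _rowwise_scores(metric, vb[idx], T)
    if HIGHER_BETTER[metric]:
        b_better = scores_b > scores_a
        a_better = scores_a > scores_b
    else:
        b_better = scores_b < scores_a
        a_better = scores_a < scores_b
    wins_b = int(np.sum(b_better))
    wins_a = int(np.sum(a_better))
    ties = n_boot - wins_a - wins_b
    num = wins_b + ties / 2.0
    den = wins_a + ties / 2.0
    k = math.inf if den == 0 else num / den
    return BootstrapComparison(
        metric=metric,
        model_a=pred_a.model_id,
        model_b=pred_b.model_id,
        n_boot=n_boot,
        seed=seed,
        scores_a=scores_a,
        scores_b=scores_b,
        wins_a=wins_a,
        wins_b=wins_b,
        ties=ties,
        bayes_factor=k,
    )


#: Bayes-factor threshold for "substantially better" in the ladder protocol
LADDER_THRESHOLD = 3.0


def ladder_update(
    previous: PredictionSet | None,
    candidate: PredictionSet,
    measured: InteractionTable,
    metric: str = "spearman",
    n_boot: int = 10_000,
    seed: int = 0,
) -> LadderDecision:
    """Decide whether a new submission's score replaces the previous one.

    The first submission is always accepted.  Afterwards the candidate
    is accepted only when the paired bootstrap yields K > 3 in its
    favor, which prevents leaderboard climbing by noise overfitting.
    """
    pairs = measured.pairs()
    truth = measured.frame["pkd"].to_numpy(dtype=float)
    cand_score = float(
        _rowwise_scores(metric, candidate.values_for(pairs)[None, :], truth[None, :])[0]
    )
    if previous is None:
        return LadderDecision(True, cand_score, None, None)
    prev_score = float(
        _rowwise_scores(metric, previous.values_for(pairs)[None, :], truth[None, :])[0]
    )
    comp = bootstrap_compare(previous, candidate, measured, metric, n_boot, seed)
    return LadderDecision(
        comp.bayes_factor > LADDER_THRESHOLD, cand_score, prev_score, comp
    )


# ---------------------------------------------------------------------------
# permutation null & replicate upper bound
# ---------------------------------------------------------------------------

def permutation_null(
    measured: InteractionTable,
    metric: str = "spearman",
    n_perm: int = 10_000,
    seed: int = 0,
    observed: "PredictionSet | float | None" = None,
) -> NullDistribution:
    """Random-prediction null from shuffling the measured pKd values.

    Each permutation shuffles the pKd vector across the pair set and
    scores the shuffled vector as if it were a prediction of the
    original.  ``observed`` may be a prediction set (scored here) or a
    pre-computed score; ``empirical_p`` is the fraction of null values
    at least as favorable as the observed score.
    """
    if len(measured) < 2:
        raise ValueError("permutation null needs >= 2 pairs")
    if metric not in HIGHER_BETTER:
        raise ValueError(f"unknown metric {metric!r}")
    truth = measured.frame["pkd"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(truth, (n_perm, 1)), axis=1)
    values = _rowwise_scores(metric, perms, np.tile(truth, (n_perm, 1)))
    if isinstance(observed, PredictionSet):
        obs = float(
            _rowwise_scores(
                metric,
                observed.values_for(measured.pairs())[None, :],
                truth[None, :],
            )[0]
        )
    elif observed is None:
        obs = math.nan
    else:
        obs = float(observed)
    if math.isnan(obs):
        p = math.nan
    elif HIGHER_BETTER[metric]:
        p = float(np.mean(values >= obs))
    else:
        p = float(np.mean(values <= obs))
    return NullDistribution(metric, n_perm, seed, values, obs, p)


def replicate_bound(
    replicates: pd.DataFrame,
    target_frac_pkd5: float,
    n_sub: int,
    n_boot: int = 10_000,
    seed: int = 0,
    inactive_pkd: float = 5.0,
) -> ReplicateBound:
    """Practical upper bound from between-study replicate measurements.

    ``replicates`` must have columns ``pkd_study1`` and ``pkd_study2``
    (one row per compound–kinase pair measured in both studies).  The
    pool is first composed to match the test set's inactive fraction:
    all active rows are kept and inactive rows (pKd = 5 in both studies)
    are randomly subsampled so they make up ``target_frac_pkd5`` of the
    pool.  Then ``n_boot`` resamples of size ``n_sub`` (with
    replacement) are drawn and Spearman/RMSE between the two studies'
    pKd values computed for each.
    """
    if not (0.0 <= target_frac_pkd5 < 1.0):
        raise ValueError("target_frac_pkd5 must be in [0, 1)")
    for col in ("pkd_study1", "pkd_study2"):
        if col not in replicates.columns:
            raise ValueError(f"replicate table missing column {col!r}")
    s1 = replicates["pkd_study1"].to_numpy(dtype=float)
    s2 = replicates["pkd_study2"].to_numpy(dtype=float)
    inactive = (s1 == inactive_pkd) & (s2 == inactive_pkd)
    n_active = int(np.sum(~inactive))
    rng = np.random.default_rng(seed)
    if target_frac_pkd5 == 0:
        n_inact = 0
    else:
        n_inact = round(target_frac_pkd5 * n_active / (1.0 - target_frac_pkd5))
    if n_inact > int(np.sum(inactive)):
        raise ValueError(
            f"need {n_inact} inactive replicate rows to reach fraction "
            f"{target_frac_pkd5}, only {int(np.sum(inactive))} available"
        )
    inact_idx = np.flatnonzero(inactive)
    chosen = rng.choice(inact_idx, size=n_inact, replace=False)
    pool = np.concatenate([np.flatnonzero(~inactive), chosen])
    p1, p2 = s1[pool], s2[pool]
    idx = rng.integers(0, len(pool), size=(n_boot, n_sub))
    A, B = p1[idx], p2[idx]
    spearman_vals = _rowwise_pearson(
        stats.rankdata(A, axis=1), stats.rankdata(B, axis=1)
    )
    rmse_vals = np.sqrt(np.mean((A - B) ** 2, axis=1))
    return ReplicateBound(spearman_vals, rmse_vals, n_sub, n_boot, seed)
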