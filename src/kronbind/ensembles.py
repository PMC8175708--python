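"""Ensemble construction over prediction sets.

Covers the 440-member CGKronRLS grid ensemble (5 regularization
strengths x 11 training-epoch settings x 8 compound kernels, uniformly
averaged), generic aggregation of arbitrary prediction files (mean,
median, rank-weighted), top-k ensemble curves, and a random-ensemble
control with an empirical P value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import InteractionTable, PredictionSet
from .kernels import KernelMatrix
from .kronrls import TrainSpec, fit_cg, predict

__all__ = [
    "QedGrid",
    "EnsembleCurve",
    "RandomEnsembleResult",
    "qed_ensemble",
    "aggregate",
    "topk_curve",
    "random_ensembles",
    "DEFAULT_LAMS",
    "DEFAULT_EPOCHS",
]

DEFAULT_LAMS = (0.1, 0.5, 1.0, 1.5, 2.0)
DEFAULT_EPOCHS = tuple(range(400, 501, 10))  # 400, 410, ..., 500


@dataclass
class QedGrid:
    """The regressor grid of the grid-ensemble model.

    Size = |lams| x |epoch_list| x |compound_kernels|; with the defaults
    and eight compound kernels that is 5 x 11 x 8 = 440 members.  Members
    enumerate in lexicographic (lam, epochs, kernel index) order so that
    any member is addressable by its grid coordinates.
    """

    compound_kernels: list[KernelMatrix]
    protein_kernel: KernelMatrix
    lams: Sequence[float] = DEFAULT_LAMS
    epoch_list: Sequence[int] = DEFAULT_EPOCHS
    tol: float = 1e-8

    @property
    def size(self) -> int:
        return len(self.lams) * len(self.epoch_list) * len(self.compound_kernels)

    def members(self):
        """Yield (lam, epochs, kernel_index) in lexicographic order."""
        for lam in self.lams:
            for epochs in self.epoch_list:
                for ki in range(len(self.compound_kernels)):
                    yield lam, epochs, ki


@dataclass
class EnsembleCurve:
    """Metric values of mean-aggregated top-k ensembles for k = 1..max_k."""

    ks: list[int]
    member_ids: list[list[str]]
    spearman: list[float]
    rmse: list[float]

    @property
    def best_k(self) -> int:
        """k with the highest ensemble Spearman correlation."""
        return self.ks[int(np.argmax(self.spearman))]


@dataclass
class RandomEnsembleResult:
    """Scores of random k-subsets plus the reference's empirical P."""

    scores: np.ndarray
    reference_score: float
    empirical_p: float
    metric: str


def qed_ensemble(
    grid: QedGrid,
    train: InteractionTable,
    test_pairs: Sequence[tuple[str, str]],
    model_id: str = "qed_ensemble",
) -> PredictionSet:
    """Fit every grid member with CGKronRLS and average their predictions.

    One sparse regressor is fitted per (lam, epochs, compound kernel)
    grid point, all sharing the single protein kernel; the ensemble is
    the uniform (unweighted) mean of the members' predicted pKd per
    test pair.
    """
    if grid.size == 0:
        raise ValueError("empty ensemble grid")
    test_pairs = [tuple(p) for p in test_pairs]
    total = np.zeros(len(test_pairs))
    for lam, epochs, ki in grid.members():
        spec = TrainSpec(lam=lam, epochs=epochs, tol=grid.tol)
        model = fit_cg(grid.compound_kernels[ki], grid.protein_kernel, train, spec)
        total += predict(model, test_pairs).values_for(test_pairs)
    mean = total / grid.size
    return PredictionSet(model_id, dict(zip(test_pairs, map(float, mean))))


def _common_pairs(sets: Sequence[PredictionSet]) -> list[tuple[str, str]]:
    if not sets:
        raise ValueError("need at least one prediction set")
    ref = sets[0].pairs()
    for ps in sets[1:]:
        if ps.pairs() != ref:
            diff = sorted(ps.pairs() ^ ref)
            raise KeyError(
                f"prediction sets disagree on pair keys; symmetric "
                f"difference e.g. {diff[:5]}"
            )
    return sorted(ref)


def aggregate(
    sets: Sequence[PredictionSet],
    method: str = "mean",
    model_id: str | None = None,
) -> PredictionSet:
    """Aggregate prediction sets pair-by-pair.

    ``mean`` and ``median`` are order-invariant.  ``rank_weighted``
    takes the input order as the ranking (first = rank 1 = best) and
    weights rank r of N sets by ``N + 1 - r``, i.e. the weighted sum of
    predictions divided by the sum of the weights N(N+1)/2.  All sets
    must share the identical pair key set.
    """
    if method not in ("mean", "median", "rank_weighted"):
        raise ValueError(f"unknown aggregation method {method!r}")
    pairs = _common_pairs(sets)
    M = np.vstack([ps.values_for(pairs) for ps in sets])
    if method == "mean":
        agg = M.mean(axis=0)
    elif method == "median":
        agg = np.median(M, axis=0)
    else:
        n = len(sets)
        weights = np.arange(n, 0, -1, dtype=float)  # N+1-r for r=1..N
        agg = weights @ M / weights.sum()
    return PredictionSet(
        model_id or f"{method}_ensemble_{len(sets)}",
        dict(zip(pairs, map(float, agg))),
    )


def _spearman_rmse(
    pred: PredictionSet, measured: InteractionTable
) -> tuple[float, float]:
    pairs = measured.pairs()
    p = pred.values_for(pairs)
    t = measured.frame["pkd"].to_numpy(dtype=float)
    rho = float(stats.spearmanr(p, t).statistic)
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    return rho, rmse


def topk_curve(
    sets: Sequence[PredictionSet],
    measured: InteractionTable,
    max_k: int | None = None,
) -> EnsembleCurve:
    """Mean-aggregation ensemble curve over the top-k ranked sets.

    ``sets`` must be pre-ranked (best first, e.g. by single-model
    Spearman).  For each k the first k sets are mean-aggregated and
    scored (Spearman and RMSE) against the measured table; ``best_k``
    reports the Spearman-optimal ensemble size.
    """
    if max_k is None:
        max_k = len(sets)
    if not (1 <= max_k <= len(sets)):
        raise ValueError(f"max_k must be in [1, {len(sets)}], got {max_k}")
    ks, ids, rhos, rmses = [], [], [], []
    for k in range(1, max_k + 1):
        ens = aggregate(sets[:k], "mean")
        rho, rmse = _spearman_rmse(ens, measured)
        ks.append(k)
        ids.append([s.model_id for s in sets[:k]])
        rhos.append(rho)
        rmses.append(rmse)
    return EnsembleCurve(ks, ids, rhos, rmses)


def random_ensembles(
    sets: Sequence[PredictionSet],
    measured: InteractionTable,
    k: int,
    n_draws: int = 1000,
    seed: int = 0,
    reference: PredictionSet | None = None,
    metric: str = "spearman",
) -> RandomEnsembleResult:
    """Score mean ensembles of random k-subsets of the prediction sets.

    Draws ``n_draws`` uniform k-subsets without replacement (within a
    draw), mean-aggregates and scores each.  When a reference ensemble
    is given, ``empirical_p`` is the fraction of draws scoring at least
    as favorably — a reference better than every draw gives an
    empirical P of exactly 0.0.
    """
    if not (1 <= k <= len(sets)):
        raise ValueError(f"k must be in [1, {len(sets)}], got {k}")
    if metric not in ("spearman", "rmse"):
        raise ValueError("random_ensembles supports metrics 'spearman' and 'rmse'")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_draws)
    for i in range(n_draws):
        members = rng.choice(len(sets), size=k, replace=False)
        ens = aggregate([sets[j] for j in members], "mean")
        rho, rmse = _spearman_rmse(ens, measured)
        scores[i] = rho if metric == "spearman" else rmse
    if reference is None:
        ref_score, p = float("nan"), float("nan")
    else:
        rho, rmse = _spearman_rmse(reference, measured)
        ref_score = rho if metric == "spearman" else rmse
        if metric == "spearman":
            p = float(np.mean(scores >= ref_score))
        else:
            p = float(np.mean(scores <= ref_score))
    return RandomEnsembleResult(scores, ref_score, p, metric)
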