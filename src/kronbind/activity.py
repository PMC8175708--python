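"""Occupancy-based activity conversion and class enrichment.

At equilibrium the fraction of protein bound by a ligand at
concentration L is the occupancy ``L / (L + Kd)``.  Expressed on the
pKd scale this converts a binding affinity into the %inhibition
expected from a single-dose assay at dose L:

    expected inhibition (%) = 100 * L / (L + 10^-pKd)

With the 1 µM single-dose convention this gives 0% at pKd 3, 1% at
pKd 4, 10% at pKd 5, 50% at pKd 6 and ~100% at pKd 9 (after rounding
to integer percent).  The combined predictor averages a measured
single-dose %inhibition with the expected inhibition implied by a
model-predicted pKd — a cheap way to fuse a noisy measurement with a
model opinion on the same % scale.

Class enrichment asks whether a kinase group or family concentrates at
the top (worst-predicted) or bottom of the absolute-error ranking of
compound–kinase pairs, via a weighted Kolmogorov–Smirnov running-sum
statistic of the GSEA family with a label-permutation null and
Benjamini–Hochberg adjustment across classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import InteractionTable, KinaseAnnotation, PredictionSet

__all__ = [
    "AssayContext",
    "EnrichmentResult",
    "expected_inhibition",
    "inverse_expected_inhibition",
    "combined_predictor",
    "absolute_errors",
    "ks_enrichment",
]


@dataclass(frozen=True)
class AssayContext:
    """Assay concentrations, in molar.

    ``ligand_concentration`` is the fixed dose of the single-dose assay
    (default 1 µM); ``kd_ceiling`` the top concentration of the
    dose-response assay (default 10 µM), above which pairs are reported
    as inactive (pKd = 5).
    """

    ligand_concentration: float = 1e-6
    kd_ceiling: float = 1e-5

    def __post_init__(self) -> None:
        if self.ligand_concentration <= 0 or self.kd_ceiling <= 0:
            raise ValueError("assay concentrations must be > 0")


def expected_inhibition(pkd, ctx: AssayContext = AssayContext()):
    """Expected single-dose %inhibition from a pKd via ligand occupancy.

    ``100 * L / (L + 10^-pKd)`` with L the assay ligand concentration.
    Strictly increasing in pKd, mapping the real line onto (0, 100);
    accepts scalars or arrays.
    """
    kd = np.power(10.0, -np.asarray(pkd, dtype=float))
    L = ctx.ligand_concentration
    out = 100.0 * L / (L + kd)
    return float(out) if out.ndim == 0 else out


def inverse_expected_inhibition(pct, ctx: AssayContext = AssayContext()):
    """Recover the pKd producing a given expected %inhibition in (0, 100)."""
    pct = np.asarray(pct, dtype=float)
    if np.any(pct <= 0) or np.any(pct >= 100):
        raise ValueError("%inhibition must lie strictly inside (0, 100)")
    kd = ctx.ligand_concentration * (100.0 - pct) / pct
    out = -np.log10(kd)
    return float(out) if out.ndim == 0 else out


def combined_predictor(
    measured_inhibition, predicted_pkd, ctx: AssayContext = AssayContext()
):
    """Average of measured and model-expected single-dose inhibition.

    ``measured_inhibition`` is clipped to [0, 100] before averaging with
    ``expected_inhibition(predicted_pkd)``.  Monotone in both arguments;
    accepts scalars or arrays.
    """
    meas = np.clip(np.asarray(measured_inhibition, dtype=float), 0.0, 100.0)
    out = (meas + expected_inhibition(predicted_pkd, ctx)) / 2.0
    return float(out) if np.ndim(out) == 0 else out


def absolute_errors(pred: PredictionSet, measured: InteractionTable) -> pd.DataFrame:
    """Per-pair absolute error |predicted - measured|, ranked descending.

    Ties in AE are broken by pair key (compound then protein id) so the
    ranking is stable and reproducible.  Returns a DataFrame with
    columns ``compound_id, protein_id, ae``.
    """
    pairs = measured.pairs()
    missing = [p for p in pairs if p not in pred.entries]
    if missing:
        raise KeyError(f"prediction set missing measured pairs, e.g. {missing[:3]}")
    ae = np.abs(
        pred.values_for(pairs) - measured.frame["pkd"].to_numpy(dtype=float)
    )
    df = pd.DataFrame(
        {
            "compound_id": [c for c, _ in pairs],
            "protein_id": [p for _, p in pairs],
            "ae": ae,
        }
    )
    return df.sort_values(
        ["ae", "compound_id", "protein_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class EnrichmentResult:
    """One class's enrichment along the absolute-error ranking.

    ``es > 0``: the class concentrates among the worst-predicted pairs
    (top of the descending-AE ranking); ``es < 0``: among the best.
    """

    class_name: str
    class_size: int
    es: float
    p_value: float
    adjusted_p: float


def _running_es(weights: np.ndarray, member: np.ndarray) -> float:
    """GSEA-style running-sum enrichment score.

    Member steps are proportional to their weight (here the pair's AE,
    exponent 1); non-member steps are uniform.  If all member weights
    are zero, member steps fall back to uniform.
    """
    total_w = weights[member].sum()
    n_miss = int((~member).sum())
    hit = np.where(member, weights, 0.0)
    hit = hit / total_w if total_w > 0 else member / max(int(member.sum()), 1)
    miss = np.where(member, 0.0, 1.0 / n_miss) if n_miss else np.zeros_like(weights)
    dev = np.cumsum(hit - miss)
    return float(dev[np.argmax(np.abs(dev))])


def ks_enrichment(
    ranking: pd.DataFrame,
    annotations: Mapping[str, KinaseAnnotation],
    level: str = "family",
    n_perm: int = 10_000,
    seed: int = 0,
    min_class_size: int = 2,
) -> list[EnrichmentResult]:
    """Weighted KS enrichment of kinase classes over an AE ranking.

    ``ranking`` is the output of :func:`absolute_errors` (descending
    AE).  Each compound–kinase pair is a ranked unit; its class is the
    kinase's ``group`` or ``family`` annotation.  For each class of
    size >= ``min_class_size`` not covering every pair, the enrichment
    score is the maximum deviation of the weighted running sum, and the
    P value the fraction of ``n_perm`` membership-label permutations
    with at least as extreme |ES| (add-one corrected so the minimum P
    is 1/(n_perm+1)).  P values are Benjamini–Hochberg adjusted across
    the tested classes.
    """
    if level not in ("group", "family"):
        raise ValueError(f"level must be 'group' or 'family', got {level!r}")
    unannotated = sorted(
        set(ranking["protein_id"]) - set(annotations)
    )
    if unannotated:
        raise ValueError(f"kinases without annotation: {unannotated[:5]}")
    classes = ranking["protein_id"].map(
        lambda pid: getattr(annotations[pid], level)
    ).to_numpy()
    weights = ranking["ae"].to_numpy(dtype=float)
    n = len(ranking)
    rng = np.random.default_rng(seed)
    tested: list[tuple[str, int, float, float]] = []
    for cls in sorted(set(classes)):
        member = classes == cls
        size = int(member.sum())
        if size < min_class_size or size == n:
            continue
        es = _running_es(weights, member)
        perm_hits = 0
        for _ in range(n_perm):
            perm_member = np.zeros(n, dtype=bool)
            perm_member[rng.choice(n, size=size, replace=False)] = True
            if abs(_running_es(weights, perm_member)) >= abs(es):
                perm_hits += 1
        p = (1 + perm_hits) / (n_perm + 1)
        tested.append((cls, size, es, p))
    if not tested:
        return []
    raw_p = [t[3] for t in tested]
    adjusted = multipletests(raw_p, method="fdr_bh")[1]
    return [
        EnrichmentResult(cls, size, es, p, float(adj))
        for (cls, size, es, p), adj in zip(tested, adjusted)
    ]
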