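"""ROC construction and early-enrichment metrics for virtual screening.

Screening benchmarks rank a mixture of known actives and property-matched
decoys by docking score (lower = better) and ask how early the actives are
recovered. Three metrics are computed from the ranked list:

* **AUC** — ordinary area under the ROC curve, equal to the probability
  that a randomly chosen active outscores a randomly chosen decoy.
* **LogAUC** — ROC area on a log10-scaled false-positive axis over
  [lambda, 1] (lambda = 0.001), normalized by the axis length (3 at the
  default) and, when adjusted, reduced by the chance baseline 0.145 so
  that a random ranking scores 0. This weights the very early part of
  the ranking, where a prospective screen actually operates.
* **EF(chi)** — enrichment factor: the fraction of actives found in the
  top chi of the database, divided by chi. EF1 (chi = 0.01) of 10 means
  10% of the actives were recovered after screening 1% of the database.

AUC and LogAUC are reported as percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Chance baseline subtracted by the adjusted LogAUC at the standard
#: lambda = 0.001 (the published constant; the exact integral of the
#: chance diagonal is (1 - lambda) / (3 ln 10) ~ 0.1446).
LOGAUC_CHANCE_CONSTANT = 0.145

#: Standard lower limit of the log-scaled false-positive axis.
DEFAULT_LAMBDA = 0.001


@dataclass(frozen=True)
class ScoredCompound:
    """One row of a docking hit list: compound id, score, active/decoy label."""

    ligand_id: str
    score: float
    label: int  # 1 = active, 0 = decoy

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"{self.ligand_id}: label must be 0 or 1")
        if not math.isfinite(self.score):
            raise ValueError(f"{self.ligand_id}: score must be finite")


@dataclass(frozen=True)
class RocCurve:
    """Stepwise ROC curve: cumulative decoy fraction (x) vs active fraction (y)."""

    fpr: np.ndarray
    tpr: np.ndarray
    n_actives: int
    n_decoys: int

    def __post_init__(self) -> None:
        fpr, tpr = np.asarray(self.fpr, float), np.asarray(self.tpr, float)
        if fpr.shape != tpr.shape:
            raise ValueError("fpr and tpr must have equal length")
        for arr, name in ((fpr, "fpr"), (tpr, "tpr")):
            if arr[0] != 0.0 or arr[-1] != 1.0:
                raise ValueError(f"{name} must start at 0 and end at 1")
            if np.any(np.diff(arr) < 0):
                raise ValueError(f"{name} must be nondecreasing")
        if self.n_actives < 1 or self.n_decoys < 1:
            raise ValueError("need at least one active and one decoy")


@dataclass(frozen=True)
class EnrichmentMetrics:
    """AUC and LogAUC (percent) plus enrichment factors keyed by fraction."""

    auc_pct: float
    logauc_pct: float
    ef: dict[float, float] = field(default_factory=dict)
    n_actives: int = 0
    n_decoys: int = 0


def rank_compounds(compounds: list[ScoredCompound]) -> list[ScoredCompound]:
    """Order a hit list best-first: ascending score (most negative first),
    score ties broken by ligand id so the ranking is deterministic."""
    n_act = sum(c.label for c in compounds)
    n_dec = len(compounds) - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError(
            f"ranking requires both classes: {n_act} actives, {n_dec} decoys"
        )
    return sorted(compounds, key=lambda c: (c.score, c.ligand_id))


def build_roc(ranked: list[ScoredCompound]) -> RocCurve:
    """ROC curve of a ranked hit list.

    Walks the list best-first; each active raises the true-positive
    fraction, each decoy the false-positive fraction, yielding one vertex
    per compound plus the (0, 0) origin.
    """
    labels = np.fromiter((c.label for c in ranked), dtype=int, count=len(ranked))
    n_act = int(labels.sum())
    n_dec = len(labels) - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError(
            f"ROC requires both classes: {n_act} actives, {n_dec} decoys"
        )
    tpr = np.concatenate([[0.0], np.cumsum(labels) / n_act])
    fpr = np.concatenate([[0.0], np.cumsum(1 - labels) / n_dec])
    return RocCurve(fpr=fpr, tpr=tpr, n_actives=n_act, n_decoys=n_dec)


def auc(roc: RocCurve) -> float:
    """ROC area (trapezoidal) in percent.

    On a tie-free stepwise curve this equals the Mann-Whitney probability
    that a random active ranks ahead of a random decoy, times 100.
    """
    return float(np.trapezoid(roc.tpr, roc.fpr)) * 100.0


def chance_logauc(lam: float = DEFAULT_LAMBDA) -> float:
    """Analytic unadjusted LogAUC of the chance diagonal y = x on a log10
    axis over [lam, 1]: (1 - lam) / (-log10(lam) * ln 10)."""
    if not 0.0 < lam < 1.0:
        raise ValueError("lam must lie in (0, 1)")
    return (1.0 - lam) / (-math.log10(lam) * math.log(10.0))


def log_auc(
    roc: RocCurve, lam: float = DEFAULT_LAMBDA, adjusted: bool = True
) -> float:
    """Log-scaled ROC area in percent.

    The true-positive fraction is integrated (trapezoid) over
    u = log10(fpr) on [log10(lam), 0], with false-positive fractions
    below ``lam`` clipped up to ``lam`` (the first vertices sit at
    fpr = 0, which has no log image). The area is divided by
    ``-log10(lam)`` (3 at the default) and, when ``adjusted``, reduced
    by the chance baseline — the published 0.145 at the standard
    lambda, the analytic chance value otherwise. Range at defaults:
    [-14.5, 85.5] percent.
    """
    if not 0.0 < lam < 1.0:
        raise ValueError("lam must lie in (0, 1)")
    u = np.log10(np.clip(roc.fpr, lam, None))
    area = float(np.trapezoid(roc.tpr, u))
    value = area / (-math.log10(lam))
    if adjusted:
        baseline = (
            LOGAUC_CHANCE_CONSTANT if lam == DEFAULT_LAMBDA else chance_logauc(lam)
        )
        value -= baseline
    return value * 100.0


def enrichment_factor(ranked: list[ScoredCompound], chi: float = 0.01) -> float:
    """Enrichment factor at fraction ``chi`` of the ranked database.

    EF = (actives among the top ceil(chi*N) / total actives) / chi, so
    0 <= EF <= 1/chi and EF(1) = 1 for any labeling.
    """
    if not 0.0 < chi <= 1.0:
        raise ValueError("chi must lie in (0, 1]")
    n = len(ranked)
    n_act = sum(c.label for c in ranked)
    if n_act == 0:
        raise ValueError("enrichment factor requires at least one active")
    k = math.ceil(chi * n)
    hits = sum(c.label for c in ranked[:k])
    return (hits / n_act) / chi


def metrics_from_arrays(
    ids: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    chis: tuple[float, ...] = (0.01,),
) -> EnrichmentMetrics:
    """Vectorized equivalent of :func:`compute_metrics` on parallel arrays.

    Same semantics as the object path (ascending score, id tie-break);
    used for large simulated benchmarks where building one record object
    per compound would dominate the runtime.
    """
    ids = np.asarray(ids)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    n_act = int(labels.sum())
    n_dec = labels.size - n_act
    if n_act == 0 or n_dec == 0:
        raise ValueError(
            f"ranking requires both classes: {n_act} actives, {n_dec} decoys"
        )
    order = np.lexsort((ids, scores))
    sorted_labels = labels[order]
    tpr = np.concatenate([[0.0], np.cumsum(sorted_labels) / n_act])
    fpr = np.concatenate([[0.0], np.cumsum(1 - sorted_labels) / n_dec])
    auc_frac = float(np.trapezoid(tpr, fpr))
    u = np.log10(np.clip(fpr, lam, None))
    logauc_frac = float(np.trapezoid(tpr, u)) / (-math.log10(lam))
    baseline = LOGAUC_CHANCE_CONSTANT if lam == DEFAULT_LAMBDA else chance_logauc(lam)
    ef = {}
    for chi in chis:
        if not 0.0 < chi <= 1.0:
            raise ValueError("chi must lie in (0, 1]")
        k = math.ceil(chi * labels.size)
        ef[chi] = (float(sorted_labels[:k].sum()) / n_act) / chi
    return EnrichmentMetrics(
        auc_pct=auc_frac * 100.0,
        logauc_pct=(logauc_frac - baseline) * 100.0,
        ef=ef,
        n_actives=n_act,
        n_decoys=n_dec,
    )


def compute_metrics(
    compounds: list[ScoredCompound],
    lam: float = DEFAULT_LAMBDA,
    chis: tuple[float, ...] = (0.01,),
) -> EnrichmentMetrics:
    """Rank a hit list and compute all three enrichment metrics."""
    ranked = rank_compounds(compounds)
    roc = build_roc(ranked)
    return EnrichmentMetrics(
        auc_pct=auc(roc),
        logauc_pct=log_auc(roc, lam=lam),
        ef={chi: enrichment_factor(ranked, chi) for chi in chis},
        n_actives=roc.n_actives,
        n_decoys=roc.n_decoys,
    )
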