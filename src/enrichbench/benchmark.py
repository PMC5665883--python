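"""Template-ensemble benchmarking and screening-hit triage.

Rigid docking is sensitive to the receptor conformation, so before a
prospective screen every available crystal structure ("template") is
benchmarked against a shared set of known actives and property-matched
decoys. Each template gets AUC / LogAUC / EF metrics; templates are
ranked by LogAUC because early enrichment is what matters when only the
top of a ranked multi-hundred-thousand-compound library will be
purchased. The module also triages a prospective hit list: rule-of-five
filter, rank by score, truncate, and carry free-text human-inspection
flags (which annotate but never remove a compound).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .chem import Ligand, compute_descriptors, lipinski_pass
from .enrichment import (
    DEFAULT_LAMBDA,
    EnrichmentMetrics,
    metrics_from_arrays,
)

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("worst", "drop")


@dataclass
class ScoreMatrix:
    """Templates x compounds docking-score table with active/decoy labels.

    ``scores`` is indexed by template id with one column per compound id;
    NaN marks a compound the docking engine failed to score for that
    template. ``labels`` maps compound id to 1 (active) or 0 (decoy).
    """

    scores: pd.DataFrame
    labels: dict[str, int]

    def __post_init__(self) -> None:
        unlabeled = [c for c in self.scores.columns if c not in self.labels]
        if unlabeled:
            raise ValueError(f"unlabeled compounds: {unlabeled[:5]}...")

    @property
    def templates(self) -> list[str]:
        return list(self.scores.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.scores.columns)

    @classmethod
    def from_long(
        cls, rows: pd.DataFrame, labels: dict[str, int]
    ) -> "ScoreMatrix":
        """Build from a long table with columns template_id, ligand_id, score."""
        wide = rows.pivot(index="template_id", columns="ligand_id", values="score")
        return cls(scores=wide, labels=labels)


@dataclass
class BenchmarkReport:
    """Per-template enrichment metrics plus ensemble summaries."""

    per_template: dict[str, EnrichmentMetrics]
    mean_sd: dict[str, tuple[float, float]]
    pearson_auc_logauc: float | None
    best_template: str
    selection_metric: str
    missing_counts: dict[str, int] = field(default_factory=dict)
    excluded_templates: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_template": {
                t: {
                    "auc_pct": m.auc_pct,
                    "logauc_pct": m.logauc_pct,
                    "ef": {str(k): v for k, v in m.ef.items()},
                    "n_actives": m.n_actives,
                    "n_decoys": m.n_decoys,
                }
                for t, m in self.per_template.items()
            },
            "mean_sd": {k: list(v) for k, v in self.mean_sd.items()},
            "pearson_auc_logauc": self.pearson_auc_logauc,
            "best_template": self.best_template,
            "selection_metric": self.selection_metric,
            "missing_counts": self.missing_counts,
            "excluded_templates": self.excluded_templates,
        }


@dataclass(frozen=True)
class TriageEntry:
    rank: int
    ligand_id: str
    score: float
    lipinski_pass: bool
    violations: tuple[str, ...]
    flags: str = ""


@dataclass
class TriageList:
    """Ranked, rule-of-five-filtered screening candidates for purchase."""

    entries: list[TriageEntry]
    n_top: int
    rejected: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["rank", "ligand_id", "score", "lipinski_pass", "violations", "flags"]
            )
            for e in self.entries:
                writer.writerow(
                    [
                        e.rank,
                        e.ligand_id,
                        e.score,
                        str(e.lipinski_pass).lower(),
                        ";".join(e.violations),
                        e.flags,
                    ]
                )


def _template_metrics(
    row: np.ndarray,
    ids: np.ndarray,
    labels: np.ndarray,
    lam: float,
    chis: tuple[float, ...],
    missing: str,
) -> tuple[EnrichmentMetrics | None, int]:
    """Metrics for one template row, applying the missing-score policy.

    Returns (metrics, n_missing); metrics is None when the template has
    no scored active or no scored decoy after the policy is applied.
    """
    nan_mask = np.isnan(row)
    n_missing = int(nan_mask.sum())
    if missing == "drop":
        row, ids, labels = row[~nan_mask], ids[~nan_mask], labels[~nan_mask]
    elif n_missing:
        # Unscored compounds rank behind every scored one (treated as
        # never recovered), ties among them broken by id via lexsort.
        worst = (np.nanmax(row) if n_missing < row.size else 0.0) + 1.0
        row = np.where(nan_mask, worst, row)
    if labels.size == 0 or labels.sum() in (0, labels.size):
        return None, n_missing
    return metrics_from_arrays(ids, row, labels, lam=lam, chis=chis), n_missing


def evaluate_templates(
    m: ScoreMatrix,
    lam: float = DEFAULT_LAMBDA,
    chis: tuple[float, ...] = (0.01,),
    missing: str = "worst",
    selection_metric: str = "logauc",
) -> BenchmarkReport:
    """Benchmark every template of a score matrix.

    Computes per-template enrichment metrics, their mean +/- SD across
    templates, and the Pearson correlation between the per-template AUC
    and LogAUC vectors. Templates left without a scored active or decoy
    by the missing-value policy are excluded with a warning.

    ``missing``: ``"worst"`` ranks unscored compounds behind every scored
    one (treated as never recovered); ``"drop"`` removes them from that
    template's evaluation.
    """
    if missing not in MISSING_POLICIES:
        raise ValueError(f"unknown missing policy {missing!r}")
    per_template: dict[str, EnrichmentMetrics] = {}
    missing_counts: dict[str, int] = {}
    excluded: list[str] = []
    ids = np.asarray(m.scores.columns, dtype=object)
    labels = np.array([m.labels[c] for c in m.scores.columns], dtype=int)
    values = m.scores.to_numpy(dtype=float)
    for i, template in enumerate(m.templates):
        metrics, n_missing = _template_metrics(
            values[i], ids, labels, lam, chis, missing
        )
        missing_counts[template] = n_missing
        if metrics is None:
            logger.warning(
                "template %s excluded: no scored active or decoy", template
            )
            excluded.append(template)
        else:
            per_template[template] = metrics
    if not per_template:
        raise ValueError("all templates excluded; nothing to benchmark")

    aucs = np.array([v.auc_pct for v in per_template.values()])
    logaucs = np.array([v.logauc_pct for v in per_template.values()])
    mean_sd = {
        "auc_pct": (float(aucs.mean()), float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0),
        "logauc_pct": (
            float(logaucs.mean()),
            float(logaucs.std(ddof=1)) if len(logaucs) > 1 else 0.0,
        ),
    }
    for chi in chis:
        efs = np.array([v.ef[chi] for v in per_template.values()])
        mean_sd[f"ef_{chi}"] = (
            float(efs.mean()),
            float(efs.std(ddof=1)) if len(efs) > 1 else 0.0,
        )

    if len(aucs) > 1 and aucs.std() > 0 and logaucs.std() > 0:
        pearson = float(stats.pearsonr(aucs, logaucs).statistic)
    else:
        pearson = None

    report = BenchmarkReport(
        per_template=per_template,
        mean_sd=mean_sd,
        pearson_auc_logauc=pearson,
        best_template="",
        selection_metric=selection_metric,
        missing_counts=missing_counts,
        excluded_templates=excluded,
    )
    report.best_template = select_best_template(report, metric=selection_metric)
    return report


def select_best_template(report: BenchmarkReport, metric: str = "logauc") -> str:
    """Pick the template that maximizes the selection metric.

    Default metric is LogAUC (early enrichment drives prospective screen
    yield, so a template with the best LogAUC is preferred even when
    another template has a higher plain AUC). Ties break by higher EF at
    the smallest evaluated fraction, then higher AUC, then template id.
    """
    if not report.per_template:
        raise ValueError("empty benchmark report")
    metric_attr = {"logauc": "logauc_pct", "auc": "auc_pct"}
    if metric not in metric_attr:
        raise ValueError(f"unknown selection metric {metric!r}")

    def sort_key(item: tuple[str, EnrichmentMetrics]):
        tid, met = item
        primary = getattr(met, metric_attr[metric])
        ef_small = met.ef[min(met.ef)] if met.ef else 0.0
        return (-primary, -ef_small, -met.auc_pct, tid)

    return min(report.per_template.items(), key=sort_key)[0]


def triage_hits(
    scored_candidates: list[tuple[Ligand, float]],
    n_top: int = 40,
    flags: dict[str, str] | None = None,
) -> TriageList:
    """Triage a prospective hit list for purchase.

    Applies the rule-of-five filter, ranks survivors by ascending score
    (docking convention: lower is better) and truncates to ``n_top``.
    Human-inspection notes in ``flags`` (ligand id -> text) are attached
    to the surviving entries; a flagged compound is annotated, never
    removed — discarding on geometric grounds is a recorded human
    decision, not an algorithm.
    """
    flags = flags or {}
    survivors: list[tuple[Ligand, float, tuple[str, ...]]] = []
    rejected: list[tuple[str, tuple[str, ...]]] = []
    for ligand, score in scored_candidates:
        passed, violations = lipinski_pass(compute_descriptors(ligand))
        if passed:
            survivors.append((ligand, score, tuple(violations)))
        else:
            rejected.append((ligand.id, tuple(violations)))
            logger.info(
                "triage: %s filtered out (%s)", ligand.id, ", ".join(violations)
            )
    if not survivors:
        logger.warning("triage: no candidates survive the rule-of-five filter")
    survivors.sort(key=lambda t: (t[1], t[0].id))
    entries = [
        TriageEntry(
            rank=i + 1,
            ligand_id=lig.id,
            score=score,
            lipinski_pass=True,
            violations=viol,
            flags=flags.get(lig.id, ""),
        )
        for i, (lig, score, viol) in enumerate(survivors[:n_top])
    ]
    return TriageList(entries=entries, n_top=n_top, rejected=rejected)


def read_score_matrix(
    matrix_path: str | Path, labels_path: str | Path
) -> ScoreMatrix:
    """Read a long-format score CSV (template_id,ligand_id,score) and a
    labels CSV (ligand_id,label)."""
    rows = pd.read_csv(matrix_path)
    labels_df = pd.read_csv(labels_path)
    labels = dict(zip(labels_df["ligand_id"], labels_df["label"].astype(int)))
    return ScoreMatrix.from_long(rows, labels)
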