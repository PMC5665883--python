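"""Synthetic benchmark generators with known ground truth.

Real template benchmarking needs hundreds of docking runs; development
and validation instead use two generators:

* :func:`gen_score_matrix` emulates the per-template docking-score table.
  Decoy scores are Gaussian around a baseline; active scores are shifted
  better (more negative) by a per-template effect size ``delta_t`` in SD
  units. The Gaussian model gives the closed-form link
  ``AUC = Phi(delta / (sigma * sqrt(2)))``, so simulated enrichment can
  be checked against normal theory; a Student-t option provides heavier
  tails for robustness testing. The planted template ordering is emitted
  as a sidecar object, never inside the matrix itself.
* :func:`gen_ligand_library` emulates activity-database records: unique,
  parseable structures drawn from a substituted-scaffold grammar
  (several ring families x enumerable substituents), log-uniform
  activities, and deterministic fractions of rule-of-five violators and
  peptide-flagged records to exercise the curation filters.

Both generators are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem

from .benchmark import ScoreMatrix
from .chem import Ligand, compute_descriptors, lipinski_pass, make_ligand

#: Ring cores with two substitution slots. Families: benzene, pyridine,
#: thiophene, cyclohexane, piperidine, naphthalene.
SCAFFOLD_CORES = (
    "c1cc({a})cc({b})c1",
    "c1nc({a})cc({b})c1",
    "c1sc({a})cc1{b}",
    "C1CC({a})CC({b})C1",
    "C1CC({a})CN({b})C1",
    "c1cc2cc({a})cc({b})c2cc1",
)

SUBSTITUENTS = (
    "C",
    "CC",
    "CCC",
    "C(C)C",
    "O",
    "OC",
    "N",
    "NC",
    "Cl",
    "F",
    "C#N",
    "C(=O)O",
    "C(=O)N",
    "CO",
    "CN",
    "S(=O)(=O)N",
    "C(F)(F)F",
    "OCC",
    "NCC",
)


@dataclass
class BenchmarkSpec:
    """Parameters of a synthetic template x compound score matrix.

    ``separations`` holds one effect size per template: active scores are
    drawn from Normal(mu_d - delta_t * sigma, sigma) against decoys from
    Normal(mu_d, sigma). Benchmark proportions default to 96 actives and
    5398 decoys per template.
    """

    n_templates: int
    n_actives: int = 96
    n_decoys: int = 5398
    separations: tuple[float, ...] | None = None
    mu_d: float = -20.0
    sigma: float = 5.0
    seed: int = 0
    score_dist: str = "normal"  # or "t"
    t_df: float = 3.0

    def __post_init__(self) -> None:
        if min(self.n_templates, self.n_actives, self.n_decoys) < 1:
            raise ValueError("counts must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.score_dist not in ("normal", "t"):
            raise ValueError(f"unknown score distribution {self.score_dist!r}")
        if self.separations is None:
            self.separations = (0.0,) * self.n_templates
        if len(self.separations) != self.n_templates:
            raise ValueError("need one separation per template")


@dataclass
class LibrarySpec:
    """Parameters of a synthetic ligand library.

    Activities are log-uniform Ki over ``ki_range`` (uM); a deterministic
    ``frac_ic50`` of annotated records carry the value as IC50 = 2 * Ki
    instead. ``frac_lipinski_violators`` records receive a long greasy
    chain guaranteeing rule-of-five failure; ``frac_peptide`` records are
    peptide-flagged. Fractions translate to exact counts (round(f * n)).
    """

    n: int
    seed: int = 0
    role: str = "active"
    ki_range: tuple[float, float] = (1e-3, 10.0)
    frac_ic50: float = 0.25
    frac_lipinski_violators: float = 0.0
    frac_peptide: float = 0.0
    annotate_activity: bool = True
    id_prefix: str = "SYN"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        lo, hi = self.ki_range
        if not 0 < lo < hi:
            raise ValueError("ki_range must be increasing and positive")
        for f in (self.frac_ic50, self.frac_lipinski_violators, self.frac_peptide):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


def gen_score_matrix(spec: BenchmarkSpec) -> tuple[ScoreMatrix, dict]:
    """Generate a score matrix with planted per-template enrichment.

    Returns the matrix plus a ground-truth sidecar: the seed, the planted
    separations and the template ordering by decreasing separation (ties
    by template id). The template with the largest separation is the
    stochastically best-enriching one.
    """
    rng = np.random.default_rng(spec.seed)
    templates = [f"T{i + 1:03d}" for i in range(spec.n_templates)]
    actives = [f"A{i + 1:05d}" for i in range(spec.n_actives)]
    decoys = [f"D{i + 1:05d}" for i in range(spec.n_decoys)]
    labels = {c: 1 for c in actives} | {c: 0 for c in decoys}

    def draw(n: int) -> np.ndarray:
        if spec.score_dist == "normal":
            return rng.standard_normal(n)
        return rng.standard_t(spec.t_df, size=n)

    rows = np.empty((spec.n_templates, spec.n_actives + spec.n_decoys))
    for t, delta in enumerate(spec.separations):
        rows[t, : spec.n_actives] = (
            spec.mu_d - delta * spec.sigma + spec.sigma * draw(spec.n_actives)
        )
        rows[t, spec.n_actives :] = spec.mu_d + spec.sigma * draw(spec.n_decoys)
    scores = pd.DataFrame(rows, index=templates, columns=actives + decoys)

    order = sorted(
        zip(templates, spec.separations), key=lambda td: (-td[1], td[0])
    )
    ground_truth = {
        "seed": spec.seed,
        "separations": dict(zip(templates, spec.separations)),
        "ordering": [t for t, _ in order],
        "best_template": order[0][0],
    }
    return ScoreMatrix(scores=scores, labels=labels), ground_truth


def theoretical_auc(delta: float) -> float:
    """Closed-form AUC (percent) of the Gaussian score model at effect
    size ``delta`` in SD units: Phi(delta / sqrt(2)) * 100."""
    from scipy.stats import norm

    return float(norm.cdf(delta / np.sqrt(2.0))) * 100.0


def _grammar_stream(rng: np.random.Generator):
    """Deterministically shuffled stream of (core, a, b) combinations."""
    combos = list(
        itertools.product(SCAFFOLD_CORES, SUBSTITUENTS, SUBSTITUENTS)
    )
    for idx in rng.permutation(len(combos)):
        core, a, b = combos[idx]
        yield core.format(a=a, b=b)


def gen_ligand_library(spec: LibrarySpec) -> list[Ligand]:
    """Generate a unique, parseable synthetic ligand library.

    Structures are drawn (seeded shuffle) from the scaffold grammar and
    deduplicated on canonical SMILES; the first ``round(frac * n)``
    records get their violator / IC50 / peptide decorations, so the
    realized counts are exact, not binomial.
    """
    rng = np.random.default_rng(spec.seed)
    n_violators = round(spec.frac_lipinski_violators * spec.n)
    n_peptide = round(spec.frac_peptide * spec.n)
    n_ic50 = round(spec.frac_ic50 * spec.n)

    smiles_list: list[str] = []
    seen: set[str] = set()
    stream = _grammar_stream(rng)
    # Violators: a long alkyl chain pushes clogP (and usually MW) far
    # past the rule-of-five bounds; growing length keeps them unique.
    for j in range(n_violators):
        smi = "c1cc(" + "C" * (40 + j) + ")ccc1C"
        smiles_list.append(smi)
        seen.add(smi)
    while len(smiles_list) < spec.n:
        try:
            smi = next(stream)
        except StopIteration:
            raise RuntimeError(
                "scaffold grammar exhausted before reaching n unique "
                "structures; extend SCAFFOLD_CORES/SUBSTITUENTS"
            ) from None
        canonical = Chem.CanonSmiles(smi)
        if canonical in seen:
            continue
        # regular records are rule-of-five compliant by construction, so
        # the violator count is exactly the requested one
        d = compute_descriptors(make_ligand("tmp", canonical))
        if not lipinski_pass(d)[0]:
            continue
        seen.add(canonical)
        smiles_list.append(canonical)

    lo, hi = spec.ki_range
    log_ki = rng.uniform(np.log10(lo), np.log10(hi), size=spec.n)
    ligands = []
    for i, smi in enumerate(smiles_list):
        ki = float(10.0 ** log_ki[i])
        if spec.annotate_activity:
            if i < n_ic50:
                atype, value = "IC50", 2.0 * ki
            else:
                atype, value = "Ki", ki
        else:
            atype, value = "none", None
        ligands.append(
            make_ligand(
                f"{spec.id_prefix}{i + 1:05d}",
                smi,
                role=spec.role,
                activity_value=value,
                activity_type=atype,
                # peptide flags take the tail indices so they do not
                # coincide with the violator block at the head
                is_peptide=i >= spec.n - n_peptide,
            )
        )
    return ligands
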