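"""Benchmark-set curation and scaffold-novelty analysis.

Three curation stages mirror how a docking benchmark is assembled from a
public activity database:

1. **Actives extraction** — keep small-molecule inhibitors (MW < 500 Da)
   with activity stronger than 10 uM (Ki, or IC50/2 when only an IC50 is
   deposited), dropping peptide-annotated records.
2. **Representative selection** — order actives by ligand efficiency
   (LE = -1.37 * log10(Ki[M]) / heavy atoms, the binding free energy per
   atom at 298 K) and greedily keep only compounds not sharing Tanimoto
   similarity above 0.6 with an already-kept compound, so the benchmark
   spans chemotypes instead of oversampling one congeneric series.
3. **Decoy matching** — for each active, pick pool compounds that match
   its physicochemical descriptors inside narrow windows but are
   topologically dissimilar (Tanimoto below a cap), the classic
   property-matched decoy construction.

Scaffold novelty of a hit is quantified as the distribution of pairwise
Tanimoto coefficients against a corpus of known inhibitors: a low mean
and low maximum mean the scaffold is new chemotype space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .chem import (
    Ligand,
    compute_descriptors,
    fingerprint,
    hetero_atom_count,
    tanimoto,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecoySpec:
    """Descriptor windows and similarity cap defining a matched decoy.

    A decoy must sit inside every +/- window around its paired active's
    descriptors, match its formal charge when ``charge_match``, and have
    Tanimoto similarity to the active of at most ``tc_cap``.
    """

    mw_window: float = 25.0
    clogp_window: float = 1.0
    hba_window: int = 1
    hbd_window: int = 1
    rotb_window: int = 2
    charge_match: bool = True
    tc_cap: float = 0.35
    n_per_active: int = 50

    def __post_init__(self) -> None:
        windows = (
            self.mw_window,
            self.clogp_window,
            self.hba_window,
            self.hbd_window,
            self.rotb_window,
        )
        if min(windows) < 0:
            raise ValueError("descriptor windows must be non-negative")
        if not 0.0 < self.tc_cap < 1.0:
            raise ValueError("tc_cap must lie in (0, 1)")
        if self.n_per_active < 1:
            raise ValueError("n_per_active must be >= 1")


@dataclass
class NoveltyReport:
    """Pairwise-Tanimoto summary of a query compound against a corpus."""

    query_id: str
    corpus_size: int
    tc_mean: float
    tc_sd: float
    tc_max: float
    nearest_id: str
    histogram: dict = field(default_factory=dict)
    fingerprint_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "query_id": self.query_id,
            "corpus_size": self.corpus_size,
            "tc_mean": self.tc_mean,
            "tc_sd": self.tc_sd,
            "tc_max": self.tc_max,
            "nearest_id": self.nearest_id,
            "histogram": self.histogram,
            "fingerprint_params": self.fingerprint_params,
        }


def ki_from_ic50(ic50: float) -> float:
    """Estimate Ki from an IC50 (both uM) as IC50 / 2.

    Applied only when no measured Ki exists for a record.
    """
    if not ic50 > 0:
        raise ValueError("IC50 must be positive")
    return ic50 / 2.0


def effective_ki(ligand: Ligand) -> float | None:
    """Ki in uM for filtering/LE: the measured Ki, or IC50/2, or None."""
    if ligand.activity_type == "Ki":
        return ligand.activity_value
    if ligand.activity_type == "IC50":
        return ki_from_ic50(ligand.activity_value)
    return None


def ligand_efficiency(ki: float, heavy_atoms: int) -> float:
    """Ligand efficiency: -1.37 * log10(Ki in molar) / heavy-atom count.

    ``ki`` is in uM (converted to molar internally); -1.37 kcal/mol is
    RT*ln(10) at 298 K, so LE is the per-atom binding free energy in
    kcal/mol. A 1 uM inhibitor with 20 heavy atoms scores 0.411.
    """
    if not ki > 0:
        raise ValueError("Ki must be positive")
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return -1.37 * math.log10(ki * 1e-6) / heavy_atoms


def ligand_le(ligand: Ligand, hetero_only: bool = False) -> float:
    """Ligand efficiency of a record with activity annotation.

    ``hetero_only`` divides by the heteroatom (non-C, non-H) count
    instead of the standard heavy-atom count.
    """
    ki = effective_ki(ligand)
    if ki is None:
        raise ValueError(f"{ligand.id}: no activity annotation")
    atoms = hetero_atom_count(ligand) if hetero_only else ligand.heavy_atom_count
    return ligand_efficiency(ki, atoms)


def filter_actives(
    ligands: list[Ligand], mw_max: float = 500.0, act_max: float = 10.0
) -> list[Ligand]:
    """Extract benchmark actives from an annotated ligand set.

    Keeps non-peptide records with molecular weight below ``mw_max`` Da
    and effective Ki (measured, or IC50/2) stronger than ``act_max`` uM.
    Both thresholds are strict.
    """
    survivors = []
    for lig in ligands:
        if lig.is_peptide:
            continue
        ki = effective_ki(lig)
        if ki is None or ki >= act_max:
            continue
        if compute_descriptors(lig).mw >= mw_max:
            continue
        survivors.append(lig)
    if not survivors:
        logger.warning("filter_actives: no ligands pass the activity/MW filters")
    return survivors


def select_representatives(
    actives: list[Ligand],
    tc_max: float = 0.6,
    radius: int = 2,
    nbits: int = 2048,
    hetero_only: bool = False,
) -> list[Ligand]:
    """Greedy diversity selection of benchmark representatives.

    Actives are visited in order of decreasing ligand efficiency (ties
    by id); a compound is kept iff its Tanimoto similarity to every
    already-kept compound is at most ``tc_max`` (strictly-above
    similarity excludes, exactly ``tc_max`` keeps). The kept set is
    therefore pairwise-diverse and biased toward the most efficient
    binder of each chemotype.
    """
    if not actives:
        return []
    ordered = sorted(actives, key=lambda l: (-ligand_le(l, hetero_only), l.id))
    fps = {l.id: fingerprint(l, radius=radius, nbits=nbits) for l in ordered}
    kept: list[Ligand] = []
    for lig in ordered:
        if all(tanimoto(fps[lig.id], fps[k.id]) <= tc_max for k in kept):
            kept.append(lig)
    # post-condition: the kept set is pairwise diverse
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            assert tanimoto(fps[a.id], fps[b.id]) <= tc_max
    return kept


def match_decoys(
    active: Ligand,
    pool: list[Ligand],
    spec: DecoySpec = DecoySpec(),
    radius: int = 2,
    nbits: int = 2048,
) -> list[Ligand]:
    """Select property-matched, topologically different decoys for an active.

    Pool compounds qualify when every descriptor falls inside the spec's
    windows around the active's descriptors, formal charge matches (if
    required), and Tanimoto similarity to the active is at most
    ``tc_cap``. When more compounds qualify than ``n_per_active``, the
    most dissimilar (lowest-Tc) ones are taken; fewer qualifiers than
    requested are returned in full with a warning.
    """
    ref = compute_descriptors(active)
    ref_fp = fingerprint(active, radius=radius, nbits=nbits)
    qualifiers: list[tuple[float, str, Ligand]] = []
    for cand in pool:
        if cand.smiles == active.smiles:
            continue
        d = compute_descriptors(cand)
        if abs(d.mw - ref.mw) > spec.mw_window:
            continue
        if abs(d.clogp - ref.clogp) > spec.clogp_window:
            continue
        if abs(d.hba - ref.hba) > spec.hba_window:
            continue
        if abs(d.hbd - ref.hbd) > spec.hbd_window:
            continue
        if abs(d.rotatable_bonds - ref.rotatable_bonds) > spec.rotb_window:
            continue
        if spec.charge_match and d.net_charge != ref.net_charge:
            continue
        tc = tanimoto(ref_fp, fingerprint(cand, radius=radius, nbits=nbits))
        if tc > spec.tc_cap:
            continue
        qualifiers.append((tc, cand.id, cand))
    qualifiers.sort(key=lambda t: (t[0], t[1]))
    if len(qualifiers) < spec.n_per_active:
        logger.warning(
            "%s: only %d of %d requested decoys qualify",
            active.id,
            len(qualifiers),
            spec.n_per_active,
        )
    return [lig for _, _, lig in qualifiers[: spec.n_per_active]]


def tc_histogram(values: np.ndarray, bin_width: float = 0.05) -> dict:
    """Histogram of Tanimoto values on [0, 1], right-open bins except the
    last; includes a log10(count + 1) column for log-scaled display."""
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(values, bins=edges)
    return {
        "bin_edges": edges.tolist(),
        "counts": counts.astype(int).tolist(),
        "log10_counts": np.log10(counts + 1.0).tolist(),
    }


def novelty_profile(
    query: Ligand,
    corpus: list[Ligand],
    radius: int = 2,
    nbits: int = 2048,
) -> NoveltyReport:
    """Pairwise-Tanimoto novelty profile of a query against a corpus.

    Reports mean, sample SD, maximum and the nearest corpus member, plus
    a 0.05-wide-bin histogram whose counts sum to the corpus size. Low
    mean/max indicate a scaffold unlike any known inhibitor.
    """
    if not corpus:
        raise ValueError("novelty_profile requires a non-empty corpus")
    qfp = fingerprint(query, radius=radius, nbits=nbits)
    tcs = np.array(
        [tanimoto(qfp, fingerprint(c, radius=radius, nbits=nbits)) for c in corpus]
    )
    imax = int(np.argmax(tcs))
    return NoveltyReport(
        query_id=query.id,
        corpus_size=len(corpus),
        tc_mean=float(tcs.mean()),
        tc_sd=float(tcs.std(ddof=1)) if len(tcs) > 1 else 0.0,
        tc_max=float(tcs[imax]),
        nearest_id=corpus[imax].id,
        histogram=tc_histogram(tcs),
        fingerprint_params={"radius": radius, "nbits": nbits},
    )


def corpus_self_similarity(
    corpus: list[Ligand], radius: int = 2, nbits: int = 2048
) -> np.ndarray:
    """All pairwise Tanimoto values within a corpus (upper triangle),
    for the comparison histogram alongside a query's profile."""
    fps = [fingerprint(c, radius=radius, nbits=nbits) for c in corpus]
    out = []
    for i in range(len(fps)):
        for j in range(i + 1, len(fps)):
            out.append(tanimoto(fps[i], fps[j]))
    return np.array(out)
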