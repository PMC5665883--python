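"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by a different route than the library
(pair counting, fine-grained numerical integration, exhaustive
re-simulation) so agreement is a genuine cross-check.
"""

import math

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors


def mann_whitney_auc(scores_active, scores_decoy):
    """AUC (fraction) by exhaustive active x decoy pair counting.

    Lower score = better, so a pair counts when the active outscores
    (is more negative than) the decoy; ties count half.
    """
    wins = 0.0
    for a in scores_active:
        for d in scores_decoy:
            if a < d:
                wins += 1.0
            elif a == d:
                wins += 0.5
    return wins / (len(scores_active) * len(scores_decoy))


def logauc_midpoint(ranked_labels, lam=1e-3, adjusted=True, n_grid=1_000_001,
                    chance=0.145):
    """Log-scaled ROC area by midpoint-rule numerical integration.

    Reconstructs the staircase tpr(fpr) from the ranked 0/1 labels,
    integrates tpr over u = log10(fpr) on [log10(lam), 0] using a
    >=1e6-point grid augmented with the staircase breakpoints (so every
    cell lies inside one constant piece and the midpoint rule is exact
    up to float rounding).
    """
    labels = np.asarray(ranked_labels, dtype=int)
    n_act, n_dec = labels.sum(), (1 - labels).sum()
    tpr = np.concatenate([[0.0], np.cumsum(labels) / n_act])
    fpr = np.concatenate([[0.0], np.cumsum(1 - labels) / n_dec])
    u_lo = math.log10(lam)
    breaks = np.log10(np.clip(fpr, lam, None))
    grid = np.union1d(np.linspace(u_lo, 0.0, n_grid), breaks)
    mids = (grid[:-1] + grid[1:]) / 2.0
    # right-continuous staircase value at given fpr
    idx = np.searchsorted(fpr, 10.0 ** mids, side="right") - 1
    heights = tpr[idx]
    area = float(np.sum(heights * np.diff(grid)))
    value = area / (-u_lo)
    if adjusted:
        value -= chance
    return value


def ef_recount(ranked_labels, chi):
    """Enrichment factor by direct recount over the top slice."""
    labels = list(ranked_labels)
    k = math.ceil(chi * len(labels))
    return (sum(labels[:k]) / sum(labels)) / chi


def _rdkit_fp(smiles, radius=2, nbits=2048):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=nbits)
    return gen.GetFingerprint(Chem.MolFromSmiles(smiles))


def greedy_representatives(ligands, le_values, tc_max=0.6):
    """Re-simulation of the diversity pick using RDKit bit vectors.

    ligands: list with .id/.smiles; le_values: dict id -> LE.
    """
    fps = {l.id: _rdkit_fp(l.smiles) for l in ligands}
    ordered = sorted(ligands, key=lambda l: (-le_values[l.id], l.id))
    kept = []
    for lig in ordered:
        if all(
            DataStructs.TanimotoSimilarity(fps[lig.id], fps[k.id]) <= tc_max
            for k in kept
        ):
            kept.append(lig)
    return [l.id for l in kept]


def brute_force_decoys(active, pool, spec):
    """Independent filter-and-sort re-computation of decoy matching."""
    def desc(smiles):
        mol = Chem.MolFromSmiles(smiles)
        return (
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcNumLipinskiHBA(mol),
            rdMolDescriptors.CalcNumLipinskiHBD(mol),
            rdMolDescriptors.CalcNumRotatableBonds(mol),
            Chem.GetFormalCharge(mol),
        )

    ref = desc(active.smiles)
    ref_fp = _rdkit_fp(active.smiles)
    windows = (
        spec.mw_window,
        spec.clogp_window,
        spec.hba_window,
        spec.hbd_window,
        spec.rotb_window,
    )
    qualifiers = []
    for cand in pool:
        if cand.smiles == active.smiles:
            continue
        d = desc(cand.smiles)
        if any(abs(d[i] - ref[i]) > windows[i] for i in range(5)):
            continue
        if spec.charge_match and d[5] != ref[5]:
            continue
        tc = DataStructs.TanimotoSimilarity(ref_fp, _rdkit_fp(cand.smiles))
        if tc > spec.tc_cap:
            continue
        qualifiers.append((tc, cand.id))
    qualifiers.sort()
    return [cid for _, cid in qualifiers[: spec.n_per_active]]
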