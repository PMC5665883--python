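"""Actives curation, ligand efficiency, decoy matching and novelty."""

import numpy as np
import pytest

from enrichbench import (
    DecoySpec,
    LibrarySpec,
    compute_descriptors,
    effective_ki,
    filter_actives,
    fingerprint,
    gen_ligand_library,
    ki_from_ic50,
    ligand_efficiency,
    ligand_le,
    make_ligand,
    match_decoys,
    novelty_profile,
    select_representatives,
    tanimoto,
)
from oracles import brute_force_decoys, greedy_representatives


class TestKiConversion:
    def test_ic50_halved(self):
        assert ki_from_ic50(4.6) == pytest.approx(2.3)
        assert ki_from_ic50(0.15) == pytest.approx(0.075)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ki_from_ic50(0.0)

    def test_measured_ki_takes_precedence(self):
        lig = make_ligand("x", "CCO", activity_value=1.0, activity_type="Ki")
        assert effective_ki(lig) == 1.0  # no halving applied
        lig2 = make_ligand("x", "CCO", activity_value=1.0, activity_type="IC50")
        assert effective_ki(lig2) == 0.5


class TestLigandEfficiency:
    def test_one_micromolar_twenty_atoms(self):
        assert ligand_efficiency(1.0, 20) == pytest.approx(0.411)

    def test_one_molar_is_zero(self):
        assert ligand_efficiency(1e6, 17) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ligand_efficiency(-1.0, 10)
        with pytest.raises(ValueError):
            ligand_efficiency(1.0, 0)

    def test_strictly_decreasing_in_ki_and_ha(self):
        kis = np.logspace(-3, 1, 10)
        les = [ligand_efficiency(k, 20) for k in kis]
        assert all(b < a for a, b in zip(les, les[1:]))
        les_ha = [ligand_efficiency(0.5, ha) for ha in range(10, 40)]
        assert all(b < a for a, b in zip(les_ha, les_ha[1:]))

    def test_ordering_matches_recomputation_oracle(self, library50):
        import math

        by_le = sorted(library50, key=lambda l: -ligand_le(l))
        oracle_le = {
            l.id: -1.37
            * math.log10(effective_ki(l) * 1e-6)
            / l.heavy_atom_count
            for l in library50
        }
        oracle = sorted(library50, key=lambda l: -oracle_le[l.id])
        assert [l.id for l in by_le] == [l.id for l in oracle]

    def test_hetero_only_variant_differs(self):
        lig = make_ligand("x", "CCOCC", activity_value=1.0, activity_type="Ki")
        assert ligand_le(lig, hetero_only=True) > ligand_le(lig)


class TestFilterActives:
    def test_small_potent_ligand_retained(self):
        # a ~306 Da inhibitor with Ki 0.019 uM sails through both filters
        lig = make_ligand(
            "hit",
            "O=C(Nc1ccncc1)c1ccc2ccccc2c1CC1CCCC1",
            activity_value=0.019,
            activity_type="Ki",
        )
        assert compute_descriptors(lig).mw < 500
        assert filter_actives([lig]) == [lig]

    def test_heavy_ligand_removed_despite_potency(self):
        lig = make_ligand(
            "big",
            "c1ccccc1" + "C" * 32,  # MW > 500
            activity_value=0.001,
            activity_type="Ki",
        )
        assert compute_descriptors(lig).mw > 500
        assert filter_actives([lig]) == []

    def test_weak_ligand_removed(self):
        lig = make_ligand("weak", "CCO", activity_value=50.0, activity_type="Ki")
        assert filter_actives([lig]) == []

    def test_peptide_flag_removes(self):
        lig = make_ligand(
            "pep", "CCO", activity_value=0.1, activity_type="Ki", is_peptide=True
        )
        assert filter_actives([lig]) == []

    def test_ic50_converted_before_threshold(self):
        # IC50 = 15 uM -> Ki 7.5 uM < 10: retained
        lig = make_ligand("i", "CCO", activity_value=15.0, activity_type="IC50")
        assert filter_actives([lig]) == [lig]

    def test_survivor_count_matches_recount(self):
        lib = gen_ligand_library(
            LibrarySpec(
                n=100,
                seed=13,
                frac_lipinski_violators=0.2,
                frac_peptide=0.1,
                ki_range=(1e-3, 100.0),
            )
        )
        survivors = filter_actives(lib)
        expected = [
            l
            for l in lib
            if not l.is_peptide
            and effective_ki(l) is not None
            and effective_ki(l) < 10.0
            and compute_descriptors(l).mw < 500.0
        ]
        assert survivors == expected
        assert 0 < len(survivors) < 100


class TestSelectRepresentatives:
    def annotated(self, smiles_le):
        out = []
        for i, (smi, ki) in enumerate(smiles_le):
            out.append(
                make_ligand(f"R{i}", smi, activity_value=ki, activity_type="Ki")
            )
        return out

    def test_similar_series_collapses_to_best_le(self):
        # three close homologues, pairwise Tc > 0.6: only the best LE kept
        ligands = self.annotated(
            [("CCCCCCCCCO", 0.01), ("CCCCCCCCCCO", 0.1), ("CCCCCCCCCCCO", 1.0)]
        )
        fps = [fingerprint(l) for l in ligands]
        assert all(
            tanimoto(a, b) > 0.6 for i, a in enumerate(fps) for b in fps[i + 1 :]
        )
        kept = select_representatives(ligands)
        assert [l.id for l in kept] == ["R0"]

    def test_dissimilar_set_fully_kept(self):
        ligands = self.annotated(
            [("CCO", 0.1), ("c1ccccc1C(=O)O", 0.2), ("C1CCNCC1", 0.3)]
        )
        kept = select_representatives(ligands)
        assert len(kept) == 3

    def test_boundary_tc_kept(self):
        """Similarity exactly at the threshold does not exclude."""
        ligands = self.annotated([("CCO", 0.1), ("CCN", 0.2)])
        fps = [fingerprint(l) for l in ligands]
        tc = tanimoto(fps[0], fps[1])
        kept = select_representatives(ligands, tc_max=tc)
        assert len(kept) == 2

    def test_empty_input(self):
        assert select_representatives([]) == []

    def test_matches_greedy_oracle(self, library50):
        kept = select_representatives(library50, tc_max=0.6)
        le = {l.id: ligand_le(l) for l in library50}
        assert [l.id for l in kept] == greedy_representatives(
            library50, le, tc_max=0.6
        )

    def test_pairwise_diversity_postcondition(self, library100):
        kept = select_representatives(library100, tc_max=0.4)
        fps = [fingerprint(l) for l in kept]
        for i in range(len(fps)):
            for j in range(i + 1, len(fps)):
                assert tanimoto(fps[i], fps[j]) <= 0.4


class TestMatchDecoys:
    def test_copies_of_active_excluded(self):
        active = make_ligand("act", "c1ccccc1CCO")
        pool = [make_ligand(f"p{i}", "c1ccccc1CCO") for i in range(5)]
        assert match_decoys(active, pool) == []

    def test_mw_window_semantics(self):
        active = make_ligand("act", "Cc1ccccc1")  # 92.1 Da
        inside = make_ligand("in", "CCc1ccncc1")  # +15 Da
        outside = make_ligand("out", "CCCCCc1ccncc1")  # +57 Da > 25
        spec = DecoySpec(mw_window=25.0, clogp_window=10.0, hba_window=1,
                         rotb_window=5, tc_cap=0.9, n_per_active=10)
        got = match_decoys(active, [inside, outside], spec)
        assert [l.id for l in got] == ["in"]

    def test_matches_brute_force_oracle(self, library100):
        active = make_ligand(
            "act", "c1cc(OC)cc(CC)c1", activity_value=1.0, activity_type="Ki"
        )
        spec = DecoySpec(mw_window=60.0, clogp_window=2.0, hba_window=2,
                         hbd_window=2, rotb_window=3, tc_cap=0.5, n_per_active=10)
        got = [l.id for l in match_decoys(active, library100, spec)]
        assert got == brute_force_decoys(active, library100, spec)

    def test_constraints_hold_on_output(self, library100):
        active = make_ligand("act", "c1cc(OC)cc(CC)c1")
        spec = DecoySpec(mw_window=60.0, clogp_window=2.0, hba_window=2,
                         hbd_window=2, rotb_window=3, tc_cap=0.5, n_per_active=50)
        ref = compute_descriptors(active)
        ref_fp = fingerprint(active)
        for decoy in match_decoys(active, library100, spec):
            d = compute_descriptors(decoy)
            assert abs(d.mw - ref.mw) <= spec.mw_window
            assert abs(d.clogp - ref.clogp) <= spec.clogp_window
            assert tanimoto(ref_fp, fingerprint(decoy)) <= spec.tc_cap
            assert decoy.smiles != active.smiles

    def test_underfull_pool_warns(self, caplog):
        active = make_ligand("act", "CCO")
        with caplog.at_level("WARNING"):
            match_decoys(active, [make_ligand("p", "CCN")],
                         DecoySpec(n_per_active=50, tc_cap=0.9))
        assert "qualify" in caplog.text


class TestNoveltyProfile:
    def test_self_corpus(self):
        q = make_ligand("q", "c1ccccc1CC(=O)O")
        rep = novelty_profile(q, [q])
        assert rep.tc_mean == rep.tc_max == 1.0
        assert rep.nearest_id == "q"
        assert rep.tc_sd == 0.0

    def test_disjoint_corpus(self):
        q = make_ligand("q", "c1ccccc1")
        rep = novelty_profile(q, [make_ligand("c", "NCCN")])
        assert rep.tc_mean == rep.tc_max == 0.0

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            novelty_profile(make_ligand("q", "CCO"), [])

    def test_matches_brute_force(self, library100):
        from rdkit import Chem, DataStructs
        from rdkit.Chem import rdFingerprintGenerator

        q = make_ligand("q", "c1cc(C(=O)N)cc(NCC)c1")
        rep = novelty_profile(q, library100)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        qfp = gen.GetFingerprint(Chem.MolFromSmiles(q.smiles))
        tcs = np.array(
            [
                DataStructs.TanimotoSimilarity(
                    qfp, gen.GetFingerprint(Chem.MolFromSmiles(l.smiles))
                )
                for l in library100
            ]
        )
        assert rep.tc_mean == pytest.approx(tcs.mean(), abs=1e-12)
        assert rep.tc_sd == pytest.approx(tcs.std(ddof=1), abs=1e-12)
        assert rep.tc_max == pytest.approx(tcs.max(), abs=1e-12)
        assert rep.nearest_id == library100[int(np.argmax(tcs))].id

    def test_histogram_conserves_counts(self, library100):
        q = make_ligand("q", "c1ccccc1CCN")
        rep = novelty_profile(q, library100)
        assert sum(rep.histogram["counts"]) == rep.corpus_size
        assert rep.tc_max >= rep.tc_mean
        assert len(rep.histogram["counts"]) == 20
        np.testing.assert_allclose(
            rep.histogram["log10_counts"],
            np.log10(np.array(rep.histogram["counts"]) + 1.0),
        )
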