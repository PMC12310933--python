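"""Closed forms and invariances of the evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimil.alleles import PositionTable
from epimil.metrics import (ContactMap, CoreAnnotation, attention_recovery,
                            classification_metrics, contact_map,
                            contacts_to_pseudo, core_accuracy, f1_score_at,
                            per_allele_report, position_entropy,
                            read_pdb_atoms)


class TestF1:
    def test_precision_recall_half_gives_half(self):
        # scores: 2 TP, 2 FP, 2 FN, 2 TN -> precision = recall = 0.5
        scores = [0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1]
        labels = [1, 1, 0, 0, 1, 1, 0, 0]
        assert f1_score_at(scores, labels) == pytest.approx(0.5)

    def test_printed_formula_example(self):
        # precision 1.0, recall 0.5 -> F1 = 2*0.5/1.5
        scores = [0.9, 0.1]
        labels = [1, 1]
        assert f1_score_at(scores, labels) == pytest.approx(2 / 3)

    def test_perfect_separation_unit_aucs(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        m = classification_metrics(scores, labels)
        assert m["roc_auc"] == 1.0
        assert m["pr_auc"] == pytest.approx(1.0)
        assert m["f1"] == 1.0
        assert m["tpr"] == 1.0

    def test_single_class_raises_for_aucs(self):
        with pytest.raises(ValueError):
            classification_metrics([0.5, 0.6], [1, 1])

    def test_formula_matches_confusion_matrix_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(4, 30))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            pred = scores >= 0.5
            tp = int((pred & (labels == 1)).sum())
            fp = int((pred & (labels == 0)).sum())
            fn = int((~pred & (labels == 1)).sum())
            if tp == 0:
                expected = 0.0
            else:
                p, r = tp / (tp + fp), tp / (tp + fn)
                expected = 2 * p * r / (p + r)
            assert f1_score_at(scores, labels) == pytest.approx(expected)


class TestPerAllele:
    def test_all_hits_give_unit_tpr(self):
        table, overall = per_allele_report(
            ["A", "A", "B"], [0.9, 0.8, 0.99], [1, 1, 1])
        assert table["A"] == (1.0, 2)
        assert table["B"] == (1.0, 1)
        assert overall == 1.0

    def test_pooled_tpr_is_hit_ratio(self):
        table, overall = per_allele_report(
            ["A", "A", "B", "B"], [0.9, 0.1, 0.9, 0.1], [1, 1, 1, 1])
        assert overall == pytest.approx(0.5)

    def test_allele_without_positives_warns(self):
        with pytest.warns(UserWarning, match="no positives"):
            table, _ = per_allele_report(["A", "B"], [0.9, 0.9], [1, 0])
        assert "B" not in table


class TestCoreAccuracy:
    def test_classification_of_predictions(self):
        anns = [CoreAnnotation("ACDEFGHIKLM", 1, "X"),
                CoreAnnotation("ACDEFGHIKLM", 0, "X"),
                CoreAnnotation("A" * 40, 3, "X")]
        correct, wrong, unsupported = core_accuracy([1, 2, None], anns)
        assert (correct, wrong, unsupported) == (1, 1, 1)

    def test_nine_mer_always_correct_when_supported(self):
        anns = [CoreAnnotation("ACDEFGHIK", 0, "X")]
        assert core_accuracy([0], anns) == (1, 0, 0)

    def test_annotation_beyond_peptide_rejected(self):
        with pytest.raises(ValueError):
            CoreAnnotation("ACDEFGHIK", 3, "X")


class TestEntropy:
    def test_identical_cores_zero_entropy(self):
        h = position_entropy(["ACDEFGHIK"] * 50)
        assert np.allclose(h, 0.0)

    def test_uniform_composition_approaches_log2_20(self):
        cores = ["".join("ACDEFGHIKLMNPQRSTVWY"[(i + p) % 20]
                         for p in range(9)) for i in range(20)]
        h = position_entropy(cores)
        assert np.allclose(h, np.log2(20), atol=1e-9)

    def test_anchor_positions_less_entropic_in_dr_like_world(self):
        from epimil.synthetic import generate_world
        world = generate_world(n_alleles=1, n_samples=1,
                               positives_per_sample=2000,
                               polyallelic_max=1, seed=8)
        cores = [p.peptide[p.core_offset:p.core_offset + 9]
                 for _, p in world.positives()]
        h = position_entropy(cores)
        anchors = np.array([0, 3, 5, 8])
        others = np.setdiff1d(np.arange(9), anchors)
        assert h[anchors].mean() < h[others].mean()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            position_entropy([])

    @given(st.lists(st.text(alphabet="ACDE", min_size=9, max_size=9),
                    min_size=2, max_size=30))
    @settings(max_examples=40, deadline=None)
    def test_order_invariance_and_uniform_bound(self, cores):
        h = position_entropy(cores)
        h_rev = position_entropy(cores[::-1])
        assert np.allclose(h, h_rev)
        assert (h <= np.log2(20) + 1e-9).all()


class TestContacts:
    def test_three_angstrom_contact_six_angstrom_none(self):
        pep = {1: np.array([[0.0, 0.0, 0.0]])}
        near = {1: np.array([[3.0, 0.0, 0.0]])}
        far = {1: np.array([[6.0, 0.0, 0.0]])}
        assert contact_map(pep, near).contacts[0, 0]
        assert not contact_map(pep, far).contacts[0, 0]

    def test_exact_cutoff_is_not_a_contact(self):
        pep = {1: np.array([[0.0, 0.0, 0.0]])}
        at5 = {1: np.array([[5.0, 0.0, 0.0]])}
        assert not contact_map(pep, at5).contacts[0, 0]

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pep = {i: rng.normal(size=(3, 3)) for i in range(4)}
        chain = {i: rng.normal(size=(2, 3)) + 2 for i in range(6)}
        base = contact_map(pep, chain).contacts
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        t = np.array([5.0, -3.0, 2.0])
        pep2 = {k: v @ R.T + t for k, v in pep.items()}
        chain2 = {k: v @ R.T + t for k, v in chain.items()}
        assert np.array_equal(base, contact_map(pep2, chain2).contacts)

    def test_minimal_pdb_reader_skips_hydrogens(self, tmp_path):
        pdb = tmp_path / "toy.pdb"
        pdb.write_text(
            "ATOM      1  N   ALA A   1       0.000   0.000   0.000"
            "  1.00  0.00           N\n"
            "ATOM      2  H   ALA A   1       1.000   0.000   0.000"
            "  1.00  0.00           H\n"
            "ATOM      3  CA  GLY B   2       2.000   1.000   0.000"
            "  1.00  0.00           C\n"
            "HETATM    4  O   HOH A   9       9.000   9.000   9.000"
            "  1.00  0.00           O\n")
        atoms = read_pdb_atoms(pdb)
        assert set(atoms) == {"A", "B"}
        assert len(atoms["A"][1]) == 1          # hydrogen skipped
        assert atoms["B"][2][0][0] == pytest.approx(2.0)


class TestAttentionRecovery:
    def _table(self):
        return PositionTable(tuple(range(15)), tuple(range(19)))

    def test_one_hot_attention_on_contacts_recovers_all(self):
        contacts = np.zeros((9, 34), dtype=bool)
        contacts[2, 5] = contacts[7, 20] = True
        attn = np.full((1, 1, 9, 34), 1e-6)
        attn[0, 0, 2, 5] = 1.0
        attn[0, 0, 7, 20] = 1.0
        rec, best = attention_recovery(attn, contacts, k=3)
        assert best == 1.0

    def test_uniform_attention_recovers_k_over_keys(self):
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(200):
            contacts = np.zeros((9, 34), dtype=bool)
            qs = rng.integers(0, 9, 6)
            ks = rng.integers(0, 34, 6)
            contacts[qs, ks] = True
            attn = rng.random((1, 1, 9, 34)) * 1e-9 + 1.0  # ~uniform, random ties
            rec, _ = attention_recovery(attn, contacts, k=3)
            fracs.append(rec[0, 0])
        assert np.mean(fracs) == pytest.approx(3 / 34, abs=0.02)

    def test_empty_restricted_contacts_is_nan(self):
        rec, best = attention_recovery(np.ones((2, 2, 9, 34)),
                                       np.zeros((9, 34), dtype=bool))
        assert np.isnan(rec).all() and np.isnan(best)

    def test_pseudo_restriction_maps_chain_columns(self):
        table = self._table()
        alpha = ContactMap(np.zeros((9, 40), dtype=bool), "alpha")
        beta = ContactMap(np.zeros((9, 40), dtype=bool), "beta")
        alpha.contacts[4, table.alpha_positions[3]] = True
        beta.contacts[1, table.beta_positions[10]] = True
        # a contact outside the groove table must vanish
        outside = next(i for i in range(40)
                       if i not in table.alpha_positions)
        alpha.contacts[0, outside] = True
        restricted = contacts_to_pseudo(alpha, beta, table)
        assert restricted[4, 3]
        assert restricted[1, 15 + 10]
        assert restricted.sum() == 2
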