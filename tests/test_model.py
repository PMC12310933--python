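"""Architecture contracts: shapes, the MIL max, invariances, checkpoints."""

import numpy as np
import pytest

from epimil.model import (AlleleCountError, ModelConfig, PresentationModel,
                          load_checkpoint, make_batch, predict,
                          save_checkpoint)

PEP = "ACDEFGHIKLMNPQR"   # 15 AAs -> 7 windows


def _batch(model, peptides, registry, names=None):
    names = names or sorted(registry)
    return make_batch(peptides, [names] * len(peptides), registry,
                      model.config.max_alleles)


class TestShapes:
    def test_default_head_width_is_1152(self):
        cfg = ModelConfig()
        assert cfg.head_hidden == 1152

    def test_flattened_interaction_features(self, tiny_model,
                                            synthetic_alleles):
        batch = _batch(tiny_model, [PEP], synthetic_alleles)
        pep = tiny_model.encode_peptide(batch.pep_tokens, batch.pep_mask)
        alle = tiny_model.encode_allele(batch.allele_tokens)
        feats, _ = tiny_model.interact(pep, batch, alle)
        assert feats.shape == (1, 5, 7, 9 * tiny_model.config.d_model)

    def test_peptide_encoding_dimensions(self, tiny_model, synthetic_alleles):
        batch = _batch(tiny_model, [PEP], synthetic_alleles)
        enc = tiny_model.encode_peptide(batch.pep_tokens, batch.pep_mask)
        assert enc.shape == (1, len(PEP), tiny_model.config.d_model)

    def test_allele_encoding_dimensions(self, tiny_model, synthetic_alleles):
        batch = _batch(tiny_model, [PEP], synthetic_alleles)
        enc = tiny_model.encode_allele(batch.allele_tokens)
        assert enc.shape == (5, 34, tiny_model.config.d_model)

    def test_wrong_pseudo_length_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.encode_allele(np.zeros((1, 20), dtype=np.int64))

    def test_heads_must_divide_d_model(self):
        with pytest.raises(ValueError):
            ModelConfig(n_heads=3, d_model=32)


class TestDeterminismAndSensitivity:
    def test_evaluation_mode_is_deterministic(self, tiny_model,
                                              synthetic_alleles):
        a, _ = tiny_model.pair_scores(PEP, list(synthetic_alleles.values()))
        b, _ = tiny_model.pair_scores(PEP, list(synthetic_alleles.values()))
        assert np.array_equal(a.scores, b.scores)

    def test_distant_mutation_changes_encoding(self, tiny_model,
                                               synthetic_alleles):
        """Self-attention propagates a far-away substitution to position 0."""
        mut = "W" + PEP[1:-1] + "W"
        assert len(mut) == len(PEP)
        b1 = _batch(tiny_model, [PEP], synthetic_alleles)
        b2 = _batch(tiny_model, [mut], synthetic_alleles)
        e1 = tiny_model.encode_peptide(b1.pep_tokens, b1.pep_mask).data
        e2 = tiny_model.encode_peptide(b2.pep_tokens, b2.pep_mask).data
        mid = len(PEP) // 2
        assert not np.allclose(e1[0, mid], e2[0, mid], atol=1e-6)

    def test_no_encoding_collisions_across_alleles(self, tiny_model):
        rng = np.random.default_rng(3)
        tokens = rng.integers(0, 20, size=(100, 34))
        enc = tiny_model.encode_allele(tokens).data.reshape(100, -1)
        d = np.linalg.norm(enc[:, None] - enc[None, :], axis=-1)
        assert (d[~np.eye(100, dtype=bool)] > 1e-4).all()

    def test_pair_features_independent_of_other_alleles(self, tiny_model,
                                                        synthetic_alleles):
        names = sorted(synthetic_alleles)
        full, _ = tiny_model.pair_scores(
            PEP, [synthetic_alleles[n] for n in names])
        solo, _ = tiny_model.pair_scores(PEP, [synthetic_alleles[names[2]]])
        assert np.allclose(full.scores[2], solo.scores[0], atol=1e-5)


class TestMilAggregation:
    def test_final_score_is_brute_force_max(self, tiny_model,
                                            synthetic_alleles):
        mat, _ = tiny_model.pair_scores(PEP, list(synthetic_alleles.values()))
        assert mat.final_score == pytest.approx(mat.scores.max())
        ai, off = mat.argmax
        assert mat.scores[ai, off] == mat.scores.max()

    def test_allele_permutation_invariance(self, tiny_model,
                                           synthetic_alleles):
        alleles = list(synthetic_alleles.values())
        p1 = predict(PEP, alleles, [tiny_model])
        p2 = predict(PEP, alleles[::-1], [tiny_model])
        assert p1.score == pytest.approx(p2.score, abs=1e-6)
        assert p1.allele == p2.allele
        assert p1.core_offset == p2.core_offset

    def test_adding_alleles_never_decreases_score(self, tiny_model,
                                                  synthetic_alleles):
        names = sorted(synthetic_alleles)
        prev = 0.0
        for k in range(1, len(names) + 1):
            s = predict(PEP, [synthetic_alleles[n] for n in names[:k]],
                        [tiny_model]).score
            assert s >= prev - 1e-7
            prev = s

    def test_scores_strictly_inside_unit_interval(self, tiny_model,
                                                  synthetic_alleles):
        mat, _ = tiny_model.pair_scores(PEP, list(synthetic_alleles.values()))
        assert (mat.scores > 0).all() and (mat.scores < 1).all()

    def test_ensemble_of_identical_states_equals_single(self, tiny_model,
                                                        synthetic_alleles):
        alleles = list(synthetic_alleles.values())
        single = predict(PEP, alleles, [tiny_model])
        double = predict(PEP, alleles, [tiny_model, tiny_model])
        assert single.score == pytest.approx(double.score, abs=1e-7)

    def test_mean_of_max_aggregation_flag(self, tiny_model,
                                          synthetic_alleles):
        """mean-of-max >= max-of-mean, with equality for identical states."""
        alleles = list(synthetic_alleles.values())
        other = PresentationModel(tiny_model.config, seed=23)
        mp = predict(PEP, alleles, [tiny_model, other], aggregate="mean_pair")
        mm = predict(PEP, alleles, [tiny_model, other], aggregate="mean_max")
        assert mm.score >= mp.score - 1e-7
        same = predict(PEP, alleles, [tiny_model, tiny_model],
                       aggregate="mean_max")
        assert same.score == pytest.approx(
            predict(PEP, alleles, [tiny_model]).score, abs=1e-7)

    def test_single_allele_single_window(self, tiny_model, synthetic_alleles):
        allele = next(iter(synthetic_alleles.values()))
        mat, _ = tiny_model.pair_scores("ACDEFGHIK", [allele])
        assert mat.scores.shape == (1, 1)
        assert predict("ACDEFGHIK", [allele],
                       [tiny_model]).score == pytest.approx(mat.scores[0, 0])


class TestPaddingInvariance:
    def test_scores_identical_across_pad_lengths(self, tiny_config,
                                                 synthetic_alleles):
        """Masked attention must make pads invisible to the scores."""
        model = PresentationModel(tiny_config, seed=1)
        names = sorted(synthetic_alleles)
        regs = {n: synthetic_alleles[n] for n in names}
        short = make_batch([PEP], [names], regs)           # padded to 15
        long = make_batch([PEP, "A" * 26], [names, names], regs)  # padded to 26
        l_short, m_short, _ = model.forward(short)
        l_long, m_long, _ = model.forward(long)
        M = short.window_count
        a = np.where(m_short[0], l_short.data[0], np.nan)
        b = np.where(m_long[0][:, :M], l_long.data[0][:, :M], np.nan)
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)], atol=1e-5)


class TestLimits:
    def test_too_many_alleles_rejected(self, tiny_model):
        rng = np.random.default_rng(0)
        from epimil.alleles import AlleleSpec
        from epimil.seqcore import AA_ALPHABET
        alleles = [AlleleSpec.from_pseudo(
            f"A{i:02d}", "".join(AA_ALPHABET[j]
                                 for j in rng.integers(0, 20, 34)))
            for i in range(15)]
        with pytest.raises(AlleleCountError):
            tiny_model.pair_scores(PEP, alleles)

    def test_out_of_range_peptide_rejected(self, tiny_model,
                                           synthetic_alleles):
        alleles = list(synthetic_alleles.values())[:1]
        with pytest.raises(ValueError):
            tiny_model.pair_scores("ACDEFGHI", alleles)       # 8 AAs
        with pytest.raises(ValueError):
            tiny_model.pair_scores("A" * 31, alleles)


class TestAttention:
    def test_attention_rows_sum_to_one(self, tiny_model, synthetic_alleles):
        _, record = tiny_model.pair_scores(
            PEP, list(synthetic_alleles.values()), record_attention=True)
        w = record.weights      # (blocks, B, N, M, heads, 9, 34)
        assert w.shape[0] == tiny_model.config.n_blocks
        assert w.shape[-2:] == (9, 34)
        assert np.allclose(w.sum(axis=-1), 1.0, atol=1e-5)


class TestCheckpoint:
    def test_round_trip_preserves_scores_and_scenario(self, tmp_path,
                                                      tiny_config,
                                                      synthetic_alleles):
        model = PresentationModel(tiny_config, seed=5,
                                  scenario="screened_9mer_disjoint")
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert loaded.scenario == "screened_9mer_disjoint"
        assert loaded.config == tiny_config
        a, _ = model.pair_scores(PEP, list(synthetic_alleles.values()))
        b, _ = loaded.pair_scores(PEP, list(synthetic_alleles.values()))
        assert np.array_equal(a.scores, b.scores)


def test_sigmoid_of_zero_logits_is_half(tiny_model, synthetic_alleles):
    """Zeroing the head weights makes every pair score exactly 0.5."""
    model = PresentationModel(tiny_model.config, seed=9)
    model.head.w.data[:] = 0.0
    model.head.b.data[:] = 0.0
    mat, _ = model.pair_scores(PEP, list(synthetic_alleles.values()))
    assert np.allclose(mat.scores, 0.5)
    assert mat.final_score == pytest.approx(0.5)
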