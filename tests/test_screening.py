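"""Window enumeration, germline filtering, epitope counting, LOO calibration."""

import numpy as np
import pandas as pd
import pytest

from epimil.screening import (ADALabel, GermlineDB, ScreenHit,
                              count_epitopes, enumerate_screen_windows,
                              filter_germline, hotspot_heatmap, loo_cutoff,
                              mapps_heatmap, resolve_duplicate_labels,
                              score_neoantigen, screen_chain)
from epimil.synthetic import make_toy_antibody

GERMLINE = {
    "V": "EVQLVESGGGLVQPGGSLRLSCAASGFTFS",
    "J": "WGQGTLVTVSS",
    "C": "ASTKGPSVFPLAPSSKSTSGGTAALGCLVK",
}
FOREIGN = ["WWHHWWHHW", "YYKKYYKKY"]


def oracle_scorer(foreign_cores):
    """Scores 1.0 for windows containing a planted core, else 0.01."""
    cores = set(foreign_cores)

    def score(peptide: str) -> ScreenHit:
        for off in range(len(peptide) - 8):
            w = peptide[off:off + 9]
            if w in cores:
                return ScreenHit(1.0, off, w, "SYN-000")
        return ScreenHit(0.01, 0, peptide[:9], "SYN-000")

    return score


@pytest.fixture(scope="module")
def db():
    return GermlineDB(GERMLINE)


class TestWindows:
    def test_length_20_chain_has_56_windows(self):
        wins = enumerate_screen_windows("A" * 9 + "CDEFGHIKLMN")  # 20 AAs
        # brute force: sum over sizes {9, 12..19} of (20 - w + 1)
        assert len(wins) == 12 + sum(20 - w + 1 for w in range(12, 20))
        assert len(wins) == 56

    def test_length_nine_chain_single_window(self):
        wins = enumerate_screen_windows("ACDEFGHIK")
        assert wins == [("ACDEFGHIK", 0, 9)]

    def test_external_model_sizes_have_no_ninemers(self):
        wins = enumerate_screen_windows("A" * 20, sizes=range(12, 20))
        assert all(size >= 12 for _, _, size in wins)

    def test_too_short_chain_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert enumerate_screen_windows("ACDEF") == []


class TestGermlineFilter:
    def test_germline_core_removed(self, db):
        core = GERMLINE["V"][3:12]
        assert filter_germline({core}, db) == set()

    def test_point_substitution_retained(self, db):
        core = list(GERMLINE["V"][3:12])
        core[4] = "W" if core[4] != "W" else "Y"
        assert filter_germline({"".join(core)}, db) == {"".join(core)}

    def test_idempotent(self, db):
        cores = {GERMLINE["V"][:9], "WWWWWWWWW"}
        once = filter_germline(cores, db)
        assert filter_germline(once, db) == once


class TestEpitopeCounting:
    def test_oracle_recovers_planted_core_count(self, db):
        chains, truth = make_toy_antibody(GERMLINE, FOREIGN, seed=0)
        reports, total = count_epitopes(chains, oracle_scorer(FOREIGN), db)
        assert total == len(FOREIGN)
        assert reports["H"].epitope_cores == set(FOREIGN)

    def test_pure_germline_chain_has_zero_epitopes(self, db):
        # a chain lying wholly inside one germline segment: every core is
        # germline, so the filter dominates any score
        chain = GERMLINE["V"]
        scorer = lambda pep: ScreenHit(0.99, 0, pep[:9], "SYN-000")
        _, total = count_epitopes({"H": chain}, scorer, db)
        assert total == 0

    def test_duplicate_core_counted_once(self, db):
        chain = FOREIGN[0] + GERMLINE["J"] + FOREIGN[0] + GERMLINE["J"]
        _, total = count_epitopes({"H": chain}, oracle_scorer(FOREIGN), db)
        assert total == 1

    def test_count_monotone_in_threshold(self, db):
        chains, _ = make_toy_antibody(GERMLINE, FOREIGN, seed=0)
        rng = np.random.default_rng(0)

        def noisy(pep):
            return ScreenHit(float(rng.random()), 0, pep[:9], "SYN-000")

        counts = []
        for thr in (0.1, 0.5, 0.9):
            rng = np.random.default_rng(0)
            _, total = count_epitopes(chains, noisy, db, threshold=thr)
            counts.append(total)
        assert counts[0] >= counts[1] >= counts[2]


class TestHeatmaps:
    def test_single_core_hotspot_footprint(self, db):
        chain = GERMLINE["V"][:5] + FOREIGN[0] + GERMLINE["J"]
        report = screen_chain("H", chain, oracle_scorer(FOREIGN), db,
                              sizes=(9,))
        hot = hotspot_heatmap(report)
        assert np.allclose(hot[5:14], 1.0)
        assert np.allclose(np.delete(hot, np.s_[5:14]), 0.0)

    def test_mapps_normalisation(self):
        chain = "ACDEFGHIKLMNPQRSTVWY"
        cov = mapps_heatmap([chain[0:12], chain[2:12], chain[2:14]], chain)
        assert cov.max() == 1.0
        assert cov[0] == pytest.approx(1 / 3)
        assert cov[3] == pytest.approx(1.0)
        assert cov[15:].sum() == 0

    def test_unalignable_peptide_raises(self):
        with pytest.raises(ValueError):
            mapps_heatmap(["WWWWWWWWWWWW"], "ACDEFGHIKLMNPQRSTVWY")

    def test_hotspot_covers_planted_positions(self, db):
        chains, truth = make_toy_antibody(GERMLINE, FOREIGN, seed=0)
        report = screen_chain("H", chains["H"], oracle_scorer(FOREIGN), db)
        hot = hotspot_heatmap(report)
        for off, _core in truth["H"]:
            assert (hot[off:off + 9] > 0).all()


class TestAdaCalibration:
    def test_separable_counts_give_unit_youden(self):
        counts = np.array([1, 2, 3, 4, 5, 20, 21, 22, 23, 24, 25])
        labels = [ADALabel(f"ab{i}", 2.0) for i in range(5)] + \
                 [ADALabel(f"ab{i}", 50.0) for i in range(5, 11)]
        mean_cutoff, folds, f1 = loo_cutoff(counts, labels)
        assert all(5 < c <= 20 for c in folds)
        assert f1 == pytest.approx(1.0)

    def test_fold_structure(self):
        counts = np.array([1, 2, 30, 40])
        labels = [ADALabel("a", 0.0), ADALabel("b", 5.0),
                  ADALabel("c", 20.0), ADALabel("d", 90.0)]
        _, folds, _ = loo_cutoff(counts, labels)
        assert len(folds) == len(counts)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            loo_cutoff(np.array([1, 2, 3]),
                       [ADALabel(str(i), 50.0) for i in range(3)])

    def test_shuffled_labels_give_baseline_f1(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 50, 40)
        f1s = []
        for _ in range(100):
            ada = rng.permutation([2.0] * 28 + [50.0] * 12)
            labels = [ADALabel(str(i), a) for i, a in enumerate(ada)]
            f1s.append(loo_cutoff(counts, labels)[2])
        prevalence = 12 / 40
        # mean LOO F1 under label permutation sits near the chance level
        assert abs(np.mean(f1s) - prevalence) < 0.15


class TestDuplicateResolution:
    def test_same_side_pair_keeps_one(self):
        df = pd.DataFrame({"antibody": ["a", "b"], "sequence": ["QQQ", "QQQ"],
                           "ada_fraction": [3.0, 7.0]})
        out = resolve_duplicate_labels(df)
        assert len(out) == 1
        assert out["ada_fraction"].iloc[0] <= 10

    def test_conflicting_pair_dropped(self):
        df = pd.DataFrame({"antibody": ["a", "b"], "sequence": ["QQQ", "QQQ"],
                           "ada_fraction": [5.0, 15.0]})
        assert len(resolve_duplicate_labels(df)) == 0

    def test_mixed_table_bookkeeping(self):
        rows = []
        for i in range(207):
            rows.append((f"u{i}", f"SEQ{i}", 5.0))
        # 3 same-side pairs (duplicate of u0..u2) and 2 conflicting pairs
        for i in range(3):
            rows.append((f"dup{i}", f"SEQ{i}", 7.0))
        rows.append(("x1", "CONF1", 5.0))
        rows.append(("x2", "CONF1", 15.0))
        rows.append(("y1", "CONF2", 3.0))
        rows.append(("y2", "CONF2", 30.0))
        df = pd.DataFrame(rows, columns=["antibody", "sequence",
                                         "ada_fraction"])
        out = resolve_duplicate_labels(df)
        assert len(df) == 214
        assert len(out) == 207  # 3 dup rows dropped, 4 conflicting dropped


class TestNeoantigen:
    def test_tier_boundaries(self):
        mk = lambda s: (lambda pep: ScreenHit(s, 0, pep[:9], "X"))
        pep = "ACDEFGHIKLMNPQRSTVWY"
        assert score_neoantigen(pep, mk(0.97))[1] == "high-likelihood"
        assert score_neoantigen(pep, mk(0.5))[1] == "low-likelihood"
        assert score_neoantigen(pep, mk(0.2))[1] == "not-presented"

    def test_long_peptide_score_is_brute_force_max(self):
        rng = np.random.default_rng(1)
        pep = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                      for i in rng.integers(0, 20, 40))
        values = {}

        def scorer(window):
            if window not in values:
                values[window] = float(rng.random())
            return ScreenHit(values[window], 0, window[:9], "X")

        score, tier, core, off = score_neoantigen(pep, scorer)
        brute = max(values[pep[s:s + w]]
                    for w in (9, *range(12, 20))
                    for s in range(len(pep) - w + 1))
        assert score == pytest.approx(brute)

    def test_short_peptide_rejected(self):
        with pytest.raises(ValueError):
            score_neoantigen("ACDEF", lambda p: ScreenHit(1, 0, p, "X"))
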