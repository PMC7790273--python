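"""t-tests, Spearman correlations, Bonferroni families, weight summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fnirsdecode as fd
from fnirsdecode.errors import ValidationError
from fnirsdecode.stats import BONFERRONI_M, accuracy_tests_by_fraction

from conftest import gaussian_feature_problem


class TestOneSampleT:
    def test_all_at_chance_gives_t_zero_p_one(self):
        r = fd.one_sample_t_vs_chance([50.0, 50.0, 50.0])
        assert r.statistic == 0.0 and r.p_raw == 1.0

    def test_frozen_hand_computed_t(self):
        # mean 70, sd 10, n 3: t = 20 / (10 / sqrt(3)) = 3.464
        r = fd.one_sample_t_vs_chance([60.0, 70.0, 80.0])
        assert r.statistic == pytest.approx(3.4641016, abs=0.01)
        assert r.df == 2

    def test_bonferroni_family_is_120(self):
        r = fd.one_sample_t_vs_chance([55.0, 65.0, 60.0])
        assert r.m_corrections == 120
        assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 120))

    def test_multiplication_example(self):
        # p_raw 0.0004 with m = 120 -> 0.048
        assert min(1.0, 0.0004 * BONFERRONI_M["accuracy"]) == pytest.approx(0.048)


class TestTwoSampleT:
    def test_identical_groups_null(self):
        r = fd.two_sample_t_ratings([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p_raw == pytest.approx(1.0)
        assert r.m_corrections == 12

    def test_table_parameter_power_positive_vs_negative_valence(self):
        # cohorts drawn from the pooled valence parameters separate reliably
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            pos = [fd.generate_ratings("reactive", "positive", rng)[0]
                   for _ in range(20)]
            neg = [fd.generate_ratings("reactive", "negative", rng)[0]
                   for _ in range(20)]
            r = fd.two_sample_t_ratings(pos, neg)
            hits += (r.p_bonferroni < 0.01)
        assert hits / n_seeds >= 0.95

    def test_direction_of_reactive_arousal_contrast(self):
        # positive (4.82) vs neutral (2.71) arousal: the simulated effect is
        # positive-direction; only the sign is asserted
        rng = np.random.default_rng(3)
        pos = [fd.generate_ratings("reactive", "positive", rng)[1]
               for _ in range(20)]
        neu = [fd.generate_ratings("reactive", "neutral", rng)[1]
               for _ in range(20)]
        assert fd.two_sample_t_ratings(pos, neu).statistic > 0

    def test_tiny_group_rejected(self):
        with pytest.raises(ValidationError):
            fd.two_sample_t_ratings([1.0], [2.0, 3.0])


class TestSpearman:
    def test_perfect_monotone_pair(self):
        acc = [51.0, 55.0, 60.0, 72.0]
        mood = np.repeat([[1.0], [3.0], [7.0], [10.0]], 16, axis=1)
        res = fd.spearman_mood(acc, mood, mood * 0.0)
        pre_first = res[0]
        assert pre_first.statistic == pytest.approx(1.0)
        assert pre_first.m_corrections == 64

    def test_tie_handling_matches_midrank_oracle(self):
        acc = np.array([50.0, 50.0, 60.0, 70.0, 70.0, 80.0])
        v = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0])

        def midrank(x):
            order = np.argsort(x, kind="mergesort")
            ranks = np.empty(len(x))
            i = 0
            xs = x[order]
            while i < len(x):
                j = i
                while j + 1 < len(x) and xs[j + 1] == xs[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
                i = j + 1
            return ranks
        ra, rv = midrank(acc), midrank(v)
        expected = np.corrcoef(ra, rv)[0, 1]
        res = fd.spearman_mood(acc, v[:, None], np.zeros((6, 1)))
        assert res[0].statistic == pytest.approx(expected, abs=1e-9)

    def test_independent_mood_shows_no_corrected_significance(self):
        rhos = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            acc = rng.uniform(40, 90, size=20)
            pre = rng.integers(0, 11, size=(20, 16)).astype(float)
            post = rng.integers(0, 11, size=(20, 16)).astype(float)
            res = fd.spearman_mood(acc, pre, post)
            assert not any(r.significant for r in res)
            rhos.append(abs(res[0].statistic))
        assert np.median(rhos) <= 0.3

    def test_constant_vector_flagged_with_p_one(self):
        res = fd.spearman_mood([50.0, 60.0, 70.0], np.ones((3, 2)),
                               np.ones((3, 2)))
        assert all(r.p_raw == 1.0 for r in res)
        assert all(r.extra == {"flagged": "constant input"} for r in res)


class TestBonferroniProperty:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(1e-12, 1.0), st.sampled_from(["accuracy", "mood", "ratings"]))
    def test_correction_never_lowers_p(self, p_raw, family):
        from fnirsdecode.stats import _bonferroni
        p_bonf, m = _bonferroni(p_raw, family)
        assert p_raw <= p_bonf <= 1.0
        assert m == BONFERRONI_M[family]


class TestWeightsAndReport:
    def _model(self, rng, names):
        X, y = gaussian_feature_problem(rng, n_per_class=20,
                                        n_features=len(names), sep=1.0)
        return fd.fit_lda(X, y, feature_names=names)

    def test_three_feature_hbr_model_summary(self, montage, rng):
        names = ["6-7_HbR", "5-4_HbR", "4-4_HbR"]
        table = fd.summarize_weights(self._model(rng, names), montage)
        assert len(table) == 3
        assert set(table["chromophore"]) == {"HbR"}
        tally = fd.region_tally(table)
        assert tally["n_features"].sum() == 3

    def test_opposed_planted_directions_yield_opposed_signs(self, montage, rng):
        X = rng.normal(size=(60, 2))
        y = np.array(["positive"] * 30 + ["neutral"] * 30)
        X[:30, 0] += 2.0   # positive > neutral on 6-7
        X[30:, 1] += 2.0   # neutral > positive on 5-4
        model = fd.fit_lda(X, y, classes=("positive", "neutral"),
                           feature_names=["6-7_HbR", "5-4_HbR"])
        table = fd.summarize_weights(model, montage)
        w67 = table.loc[table.channel == "6-7", "weight"].iloc[0]
        w54 = table.loc[table.channel == "5-4", "weight"].iloc[0]
        assert np.sign(w67) == -np.sign(w54)

    def test_unnamed_model_rejected(self, montage, rng):
        model = self._model(rng, ["a_HbO"])
        model.feature_names = None
        with pytest.raises(ValidationError):
            fd.summarize_weights(model, montage)

    def test_report_formatting_and_round_trip(self, tmp_path, rng):
        rows = []
        for frac in (0.05, 0.10):
            for s in range(4):
                rows.append({"comparison": "pos_vs_neu", "task": "active",
                             "subset_fraction": frac, "subject_id": f"s{s}",
                             "balanced_accuracy_pct": 50 + 5 * s + frac * 10,
                             "n_selected": 3})
        frame = pd.DataFrame(rows)
        text = fd.report(frame, out_dir=tmp_path)
        assert "best fraction" in text
        import re
        assert re.search(r"\d+\.\d{2} ± \d+\.\d{2}%", text)
        back = pd.read_csv(tmp_path / "results.tsv", sep="\t")
        pd.testing.assert_frame_equal(back, frame)

    def test_empty_report_is_valid(self):
        assert fd.report(pd.DataFrame()) == "No decoding results.\n"

    def test_null_accuracy_family_type_one_control(self):
        # 200 null accuracy tests: corrected significance should be rare
        sig = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            accs = rng.normal(50, 10, size=6)
            sig += fd.one_sample_t_vs_chance(accs).significant
        assert sig / 200 <= 0.05
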