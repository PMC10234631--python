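"""Event selection, control sampling, outlier trimming, and group comparisons."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from foxsplice import synthetic
from foxsplice.config import SimulationConfig
from foxsplice.retention import (compare_composition, compare_retained_vs_control,
                                 compare_scores, remove_score_outliers,
                                 sample_unaffected, select_events)


def events_frame(rows):
    return pd.DataFrame(rows, columns=["event_id", "dpsi", "mv_dpsi"])


class TestSelectEvents:
    @pytest.mark.parametrize("dpsi,mv,expected", [
        (5.0, 0.14, "unchanged"),      # below cutoff
        (5.0, 0.15, "more_retained"),  # inclusive cutoff
        (-5.0, 0.2, "less_retained"),
        (0.0, 0.5, "unchanged"),       # significant magnitude but no direction
    ])
    def test_classification_rule(self, dpsi, mv, expected):
        df = select_events(events_frame([("e1", dpsi, mv)]))
        assert df["class"].iloc[0] == expected

    def test_generator_roundtrip_matches_truth(self, config, intron_set):
        events, truth = synthetic.gen_retention_events(intron_set, config)
        classified = select_events(events)
        retained = set(classified.loc[classified["class"] == "more_retained", "event_id"])
        assert retained == set(truth.loc[truth["retained"], "event_id"])

    def test_row_permutation_stable(self, config, intron_set):
        events, _ = synthetic.gen_retention_events(intron_set, config)
        shuffled = events.sample(frac=1.0, random_state=1)
        a = select_events(events).set_index("event_id")["class"]
        b = select_events(shuffled).set_index("event_id")["class"]
        assert a.sort_index().equals(b.sort_index())


class TestSampleUnaffected:
    def test_identity_when_exact_size(self):
        ids = [f"e{i}" for i in range(500)]
        assert sample_unaffected(ids, n=500, seed=0) == sorted(ids)

    def test_takes_all_with_warning_when_short(self):
        with pytest.warns(UserWarning):
            out = sample_unaffected(["a", "b"], n=5, seed=0)
        assert out == ["a", "b"]

    def test_seeded_determinism(self):
        ids = [f"e{i}" for i in range(100)]
        assert sample_unaffected(ids, 20, seed=3) == sample_unaffected(ids, 20, seed=3)

    def test_inclusion_rate_uniform(self):
        ids = [f"e{i:02d}" for i in range(20)]
        n, n_seeds = 5, 400
        hits = {i: 0 for i in ids}
        for seed in range(n_seeds):
            for picked in sample_unaffected(ids, n, seed=seed):
                hits[picked] += 1
        rate = n / len(ids)
        sigma = np.sqrt(rate * (1 - rate) / n_seeds)
        rates = np.array([hits[i] / n_seeds for i in ids])
        assert (np.abs(rates - rate) <= 3 * sigma).all()


class TestOutlierRemoval:
    def test_all_equal_untouched(self):
        kept, removed = remove_score_outliers([2.0] * 10)
        assert removed == 0 and len(kept) == 10

    def test_single_extreme_removed(self):
        rng = np.random.default_rng(0)
        scores = np.append(rng.normal(0, 1, 99), 50.0)
        kept, removed = remove_score_outliers(scores)
        assert removed == 1 and 50.0 not in kept

    def test_gaussian_false_removal_rate_near_nominal(self):
        rng = np.random.default_rng(1)
        q = 0.005
        scores = rng.normal(0, 1, 20_000)
        _, removed = remove_score_outliers(scores, q=q)
        sigma = np.sqrt(q * (1 - q) / scores.size)
        assert abs(removed / scores.size - q) <= 3 * sigma + 1e-4

    def test_too_few_values_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = remove_score_outliers([1.0, 2.0, 3.0])
        assert removed == 0


class TestCompareScores:
    def test_identical_groups_p_one(self):
        _, _, p = compare_scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_small_sample_p(self):
        # all 3 low vs all 3 high ranks: 2 of C(6,3)=20 orderings as extreme
        _, _, p = compare_scores([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_large_shift_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 200)
        _, _, p = compare_scores(a, a + 10)
        assert p < 1e-6

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            compare_scores([1.0], [1.0, 2.0])


class TestCompareComposition:
    def test_crich_vs_urich_direction_and_significance(self):
        cfg = SimulationConfig(seed=21)
        crich = synthetic.gen_intron_set(cfg, "crich", n=400).records
        urich = synthetic.gen_intron_set(cfg, "urich", n=500).records
        report = compare_composition(crich, urich)
        c_a, c_b = report.composition_means["C"]
        u_a, u_b = report.composition_means["U"]
        assert c_a > c_b and u_a < u_b
        assert report.composition_pvalues["C"] < 0.01
        assert report.composition_pvalues["U"] < 0.01

    def test_single_sequence_groups_suppress_tests(self, intron_set):
        with pytest.warns(UserWarning):
            report = compare_composition(intron_set.records[:1], intron_set.records[1:2])
        assert report.tests_suppressed
        assert not report.composition_pvalues
        assert report.composition_means  # profile still reported

    def test_null_pvalues_roughly_uniform(self):
        """Groups drawn from one profile give dispersed, non-degenerate p."""
        ps = []
        for seed in range(60):
            cfg = SimulationConfig(seed=seed)
            recs = synthetic.gen_intron_set(cfg, "crich", n=120).records
            report = compare_composition(recs[:60], recs[60:])
            ps.append(report.composition_pvalues["C"])
        ps = np.array(ps)
        assert (ps < 0.05).mean() <= 0.15
        assert 0.3 <= ps.mean() <= 0.7


class TestEndToEnd:
    def test_planted_association_recovered(self, config, intron_set):
        events, _ = synthetic.gen_retention_events(intron_set, config)
        intron_map = dict(zip(events["event_id"], intron_set.records))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = compare_retained_vs_control(events, intron_map, seed=0)
        c_ret, c_ctl = report.composition_means["C"]
        assert c_ret > c_ctl
        assert report.composition_pvalues["C"] < 0.01

    def test_missing_sequences_counted(self, config, intron_set):
        events, _ = synthetic.gen_retention_events(intron_set, config)
        intron_map = dict(zip(events["event_id"], intron_set.records))
        dropped = events["event_id"].iloc[0]
        intron_map.pop(dropped)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = compare_retained_vs_control(events, intron_map, seed=0)
        assert report.n_missing_sequence == 1
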