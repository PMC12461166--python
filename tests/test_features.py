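"""Baseline z-scoring, change ratios, static masking, mask bookkeeping."""

import numpy as np
import pytest

from longicog.cohort import FeatureSpec, Visit
from longicog.features import (
    BaselineChangeFeaturizer,
    ControlStats,
    change_ratios,
    engineer_sample,
    fit_control_stats,
    mask_static_in_change,
    zscore_baseline,
)
from longicog.pipeline import TrainingPair, augment_prefixes
from ._util import date_at, make_patient, simple_specs

NAMES = ["memory", "attention", "bmi", "family_history"]


def _pair_from(patient):
    return augment_prefixes(patient)[-1]


def _control_pairs(values_by_visit):
    p = make_patient("c", list(range(len(values_by_visit))),
                     ["Control"] * len(values_by_visit), values_by_visit)
    return augment_prefixes(p)


class TestControlStats:
    def test_mean_and_sample_sd(self):
        pairs = _control_pairs([{"memory": 1.0}, {"memory": 2.0},
                                {"memory": 3.0}, {"memory": 9.9}])
        stats = fit_control_stats(pairs, NAMES)
        j = NAMES.index("memory")
        # the target visit (9.9) is never part of any prefix
        assert stats.mean[j] == pytest.approx(2.0)
        assert stats.sd[j] == pytest.approx(1.0)

    def test_underobserved_feature_flagged(self):
        pairs = _control_pairs([{"memory": 1.0}, {"memory": 2.0}, {}])
        stats = fit_control_stats(pairs, NAMES)
        assert stats.flagged[NAMES.index("attention")]
        assert not stats.flagged[NAMES.index("memory")]

    def test_json_roundtrip(self, tmp_path):
        pairs = _control_pairs([{"memory": 1.0}, {"memory": 4.0}, {}])
        stats = fit_control_stats(pairs, NAMES)
        stats.to_json(tmp_path / "stats.json")
        back = ControlStats.from_json(tmp_path / "stats.json")
        np.testing.assert_allclose(back.mean, stats.mean)
        assert list(back.flagged) == list(stats.flagged)


class TestZScore:
    def _stats(self, mean, sd):
        K = len(NAMES)
        return ControlStats(NAMES, np.full(K, mean), np.full(K, sd),
                            np.full(K, 10), np.zeros(K, dtype=bool), 10)

    def test_direct_value(self):
        visit = Visit(date_at(0), {"memory": 5.0}, "Control")
        z, mask = zscore_baseline(visit, self._stats(3.0, 2.0))
        j = NAMES.index("memory")
        assert z[j] == pytest.approx(1.0) and mask[j] == 1.0

    def test_missing_stays_missing(self):
        visit = Visit(date_at(0), {"memory": np.nan}, "Control")
        z, mask = zscore_baseline(visit, self._stats(0.0, 1.0))
        assert np.isnan(z).all() and mask.sum() == 0

    def test_identity_stats_idempotent(self):
        visit = Visit(date_at(0), {n: v for n, v in zip(NAMES, [1., 2., 3., 4.])},
                      "Control")
        ident = self._stats(0.0, 1.0)
        once, _ = zscore_baseline(visit, ident)
        twice, _ = zscore_baseline(once, ident)
        np.testing.assert_allclose(once, twice)

    def test_control_population_self_normalizes(self, prepared):
        """Re-scoring the training controls with their own statistics gives
        per-feature mean ~0 and sample sd ~1."""
        from longicog.features import control_visits_from_pairs
        train_pairs = prepared.train_pairs_for_fold(0)
        names = prepared.cohort.feature_names
        stats = fit_control_stats(train_pairs, names)
        zs = np.stack([zscore_baseline(v, stats)[0]
                       for v in control_visits_from_pairs(train_pairs)])
        for j, name in enumerate(names):
            if stats.flagged[j]:
                continue
            col = zs[:, j][np.isfinite(zs[:, j])]
            assert abs(col.mean()) < 1e-9
            assert abs(col.std(ddof=1) - 1.0) < 1e-9


class TestChangeRatios:
    def test_ratio_formula_and_first_column(self):
        prefix = [Visit(date_at(0), {"memory": 2.0, "attention": 4.0}, "Control"),
                  Visit(date_at(1), {"memory": 3.0, "attention": 2.0}, "Control")]
        change, mask = change_ratios(prefix, NAMES)
        jm, ja = NAMES.index("memory"), NAMES.index("attention")
        assert change[jm, 0] == pytest.approx(1.0)
        assert change[jm, 1] == pytest.approx(1.5)
        assert change[ja, 1] == pytest.approx(0.5)
        observed_first = mask[:, 0] > 0
        np.testing.assert_allclose(change[observed_first, 0], 1.0)

    def test_zero_denominator_masks_feature_row(self):
        prefix = [Visit(date_at(0), {"memory": 0.0}, "Control"),
                  Visit(date_at(1), {"memory": 5.0}, "Control")]
        change, mask = change_ratios(prefix, NAMES)
        j = NAMES.index("memory")
        assert mask[j].sum() == 0 and np.isnan(change[j]).all()

    def test_missing_denominator_masks_row(self):
        prefix = [Visit(date_at(0), {}, "Control"),
                  Visit(date_at(1), {"memory": 5.0}, "Control")]
        _, mask = change_ratios(prefix, NAMES)
        assert mask.sum() == 0


class TestStaticMasking:
    def test_static_rows_zeroed_dynamic_untouched(self):
        mask = np.ones((4, 3))
        out = mask_static_in_change(mask, simple_specs())
        j_static = NAMES.index("family_history")
        assert out[j_static].sum() == 0
        assert out.sum() == 9  # 3 dynamic features x 3 timesteps
        assert mask.sum() == 12  # input untouched


class TestEngineerSample:
    def test_single_visit_prefix_gives_empty_change(self):
        p = make_patient("a", [0, 4], ["Control", "aMCI"],
                         [{"memory": 2.0}, {"memory": 1.0}])
        pair = augment_prefixes(p)[0]
        stats = fit_control_stats(_control_pairs(
            [{"memory": 1.0}, {"memory": 3.0}, {}]), NAMES)
        sample = engineer_sample(pair, stats, simple_specs())
        assert sample.n_timesteps == 0
        assert sample.target_label == "aMCI"

    def test_mask_conservation(self, engineered):
        """Engineering never invents observations: every observed cell in
        the outputs corresponds to an observed raw cell."""
        train, evals, _ = engineered
        for s in train[:50] + evals[:20]:
            K = s.baseline.shape[0]
            assert np.isfinite(s.baseline[s.baseline_mask > 0]).all()
            if s.n_timesteps:
                assert np.isfinite(s.change[s.change_mask > 0]).all()
                assert s.change_mask.shape == s.change.shape

    def test_validation_scored_with_training_stats(self, prepared):
        fz = BaselineChangeFeaturizer(prepared.cohort.feature_specs)
        train_pairs = prepared.train_pairs_for_fold(0)
        fz.fit(train_pairs)
        mean_before = fz.stats_.mean.copy()
        fz.transform(prepared.eval_pairs_for_fold(0))
        np.testing.assert_array_equal(fz.stats_.mean, mean_before)


def test_featurizer_requires_fit_and_specs(prepared):
    fz = BaselineChangeFeaturizer(prepared.cohort.feature_specs)
    with pytest.raises(RuntimeError):
        fz.transform([])
    with pytest.raises(ValueError):
        BaselineChangeFeaturizer(None).fit([])
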