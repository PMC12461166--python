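"""Properties of the synthetic cohort generator."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from longicog.cohort import AD, AMCI, CONTROL
from longicog.simulate import (
    SimulationConfig,
    inject_missingness,
    null_cohort,
    simulate_cohort,
)


def _cognition_values(cohort, trajectory, visit="first"):
    names = [s.name for s in cohort.feature_specs if s.group == "cognition"]
    rows = []
    for p in cohort.patients:
        if p.final_label != trajectory:
            continue
        v = p.visits[0] if visit == "first" else p.visits[-1]
        rows.append([v.value(n) for n in names])
    return np.array(rows)


def test_same_seed_gives_byte_identical_cohorts():
    cfg = SimulationConfig(n_patients=40, seed=7)
    a, b = simulate_cohort(cfg), simulate_cohort(cfg)
    assert a.to_frame().equals(b.to_frame())


def test_class_proportions_near_mix():
    cfg = SimulationConfig(n_patients=300, class_mix=(1 / 3, 1 / 3, 1 / 3), seed=7,
                           missing_rate=0.0)
    cohort = simulate_cohort(cfg)
    counts = {c: sum(p.final_label == c for p in cohort.patients)
              for c in (CONTROL, AMCI, AD)}
    assert sum(counts.values()) == 300
    for c, n in counts.items():
        assert 60 <= n <= 140, f"{c}: {n} far from multinomial expectation"


def test_positive_coding_and_static_constancy():
    cohort = simulate_cohort(SimulationConfig(n_patients=50, missing_rate=0.2, seed=3))
    static_names = [s.name for s in cohort.feature_specs if s.static]
    for p in cohort.patients:
        for v in p.visits:
            for name, val in v.values.items():
                if np.isfinite(val):
                    assert val > 0
        for name in static_names:
            observed = {v.value(name) for v in p.visits
                        if np.isfinite(v.value(name))}
            assert len(observed) <= 1


def test_labels_never_revert_within_record():
    from longicog.cohort import SEVERITY
    cohort = simulate_cohort(SimulationConfig(n_patients=120, seed=9))
    for p in cohort.patients:
        sev = [SEVERITY[v.label] for v in p.visits]
        assert all(b >= a for a, b in zip(sev, sev[1:]))


def test_null_cohort_first_visit_means_show_no_signal():
    """With effect_size=0 and no missingness, first-visit means are
    indistinguishable between stable controls and AD converters for almost
    every feature (two-sample t-test at alpha=0.01)."""
    cfg = SimulationConfig(n_patients=600, effect_size=0.0, missing_rate=0.0, seed=21)
    cohort = simulate_cohort(cfg)
    ctrl = _cognition_values(cohort, CONTROL)
    ad = _cognition_values(cohort, AD)
    pvals = [sps.ttest_ind(ctrl[:, j], ad[:, j]).pvalue
             for j in range(ctrl.shape[1])]
    assert np.mean(np.array(pvals) > 0.01) >= 0.9


def test_null_cohort_only_differs_from_signal_cohort_in_drift():
    """The null cohort is the same draw with the decline switched off:
    patient ids, labels, dates and health features are identical."""
    cfg = SimulationConfig(n_patients=30, seed=13, missing_rate=0.0)
    sig, nul = simulate_cohort(cfg), null_cohort(cfg)
    for ps, pn in zip(sig.patients, nul.patients):
        assert ps.patient_id == pn.patient_id
        for vs, vn in zip(ps.visits, pn.visits):
            assert vs.date == vn.date and vs.label == vn.label
            assert vs.value("hlt_00") == vn.value("hlt_00")


def test_converter_drift_matches_effect_size_and_is_monotone():
    """AD converters' cognition features drop by about effect_size
    population SDs first-to-last visit, and the drop grows with effect."""
    drops = []
    for effect in (0.5, 1.0, 2.0):
        cfg = SimulationConfig(n_patients=500, effect_size=effect,
                               missing_rate=0.0, seed=37)
        cohort = simulate_cohort(cfg)
        first = _cognition_values(cohort, AD, "first").mean(axis=0)
        last = _cognition_values(cohort, AD, "last").mean(axis=0)
        # population SD of each feature, estimated from controls
        ctrl = _cognition_values(cohort, CONTROL, "first")
        drop_sd = (first - last) / ctrl.std(axis=0, ddof=1)
        drops.append(drop_sd.mean())
    assert drops[0] < drops[1] < drops[2]
    assert drops[2] == pytest.approx(2.0, abs=0.5)


def test_mcar_rate_and_identity_and_block_mechanism():
    cfg = SimulationConfig(n_patients=60, missing_rate=0.0, seed=2)
    cohort = simulate_cohort(cfg)
    same = inject_missingness(cohort, 0.0)
    assert same.to_frame().equals(cohort.to_frame())

    dropped = inject_missingness(cohort, 0.3, "MCAR", seed=5)
    frame = dropped.to_frame()[dropped.feature_names]
    frac = float(frame.isna().to_numpy().mean())
    assert abs(frac - 0.3) < 0.02

    blocked = inject_missingness(cohort, 0.4, "visit_block", seed=5)
    n_block = 0
    for p in blocked.patients:
        for name in blocked.feature_names:
            vals = [v.value(name) for v in p.visits]
            if all(not np.isfinite(x) for x in vals):
                n_block += 1
    # blocked features exist and labels/dates survive
    assert n_block > 0
    assert all(v.label for p in blocked.patients for v in p.visits)


@pytest.mark.parametrize("bad", [
    {"class_mix": (0.5, 0.5, 0.5)},
    {"missing_rate": 1.0},
    {"span_years": (0.0, 5.0)},
    {"n_cognition": 0},
    {"reliability": 1.5},
])
def test_invalid_configs_rejected(bad):
    with pytest.raises(ValueError):
        dataclasses.replace(SimulationConfig(), **bad).validate()


def test_missingness_rate_one_rejected():
    cohort = simulate_cohort(SimulationConfig(n_patients=5, seed=1))
    with pytest.raises(ValueError):
        inject_missingness(cohort, 1.0)


def test_csv_roundtrip(tmp_path):
    cohort = simulate_cohort(SimulationConfig(n_patients=12, seed=4))
    path = tmp_path / "cohort.csv"
    cohort.write_csv(path)
    back = type(cohort).read_csv(path)
    assert back.to_frame().equals(cohort.to_frame())
    assert [s.name for s in back.feature_specs] == cohort.feature_names
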