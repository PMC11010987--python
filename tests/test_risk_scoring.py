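"""Composite risk scores and cutoff calibration."""

import itertools

import numpy as np
import pytest

from conftest import make_record

from obbpa import synthetic_cohort as sc
from obbpa.risk_scoring import (
    BELOW_DIRECTION,
    CalibrationError,
    RiskModel,
    calibrate_cutoffs,
    component_flags,
    model_skeleton,
    qfpsa,
    records_to_frame,
    score,
)


def small_skeleton(components=("RASSF1A", "MIR129-2", "NRIP3"), tau=2,
                   targets=("cs_PCa",)):
    return RiskModel(
        variant="piRISK2",
        components=components,
        cutoffs={},
        tau=tau,
        sensitivity_targets=targets,
    )


def exhaustive_calibration(records, skeleton):
    """Independent oracle: full grid search over all candidate cutoffs.

    Enumerates every combination of midpoint/extreme cutoffs per
    component and returns the best specificity achievable under the
    100%-sensitivity constraint.
    """
    comps = skeleton.components
    x = np.array(
        [[_value(r, c) for c in comps] for r in records], dtype=float
    )
    target = np.array([r.group in skeleton.sensitivity_targets for r in records])
    bph = np.array([r.group == "BPH" for r in records])
    cand_per_comp = []
    for j in range(len(comps)):
        uniq = np.unique(x[:, j])
        cands = [uniq[0] - 1.0] + list(0.5 * (uniq[:-1] + uniq[1:])) + [uniq[-1] + 1.0]
        cand_per_comp.append(cands)
    best_spe = -1.0
    for thetas in itertools.product(*cand_per_comp):
        flags = np.zeros(len(records), dtype=int)
        for j, c in enumerate(comps):
            if c in BELOW_DIRECTION:
                flags += (x[:, j] < thetas[j]).astype(int)
            else:
                flags += (x[:, j] > thetas[j]).astype(int)
        if np.all(flags[target] >= skeleton.tau):
            best_spe = max(best_spe, float(np.mean(flags[bph] < skeleton.tau)))
    return 100.0 * best_spe


def _value(record, component):
    if component == "age":
        return record.age
    if component == "cfDNA_ng_ml":
        return record.cfdna_ng_ml
    if component == "QfPSA":
        return record.qfpsa_pct
    return record.marker_copies_per_ml[component]


class TestQfpsa:
    @pytest.mark.parametrize("fpsa,tpsa,expected", [(1.0, 4.0, 25.0),
                                                    (4.0, 4.0, 100.0),
                                                    (0.0, 4.0, 0.0)])
    def test_ratio(self, fpsa, tpsa, expected):
        assert qfpsa(fpsa, tpsa) == pytest.approx(expected)

    def test_nonpositive_tpsa_rejected(self):
        with pytest.raises(ValueError):
            qfpsa(1.0, 0.0)


class TestComponentFlags:
    def model(self):
        skel = model_skeleton("PRISK2")
        cutoffs = {"RASSF1A": 50.0, "MIR129-2": 50.0, "NRIP3": 50.0,
                   "SOX8": 50.0, "cfDNA_ng_ml": 40.0, "age": 65.0, "QfPSA": 20.0}
        return RiskModel(variant=skel.variant, components=skel.components,
                         cutoffs=cutoffs, tau=skel.tau,
                         sensitivity_targets=skel.sensitivity_targets)

    def test_risk_free_extremes_give_zero_vector(self):
        rec = make_record(age=45, qfpsa=50.0, cfdna=5.0)
        assert component_flags(rec, self.model()).sum() == 0

    def test_low_qfpsa_is_risky(self):
        rec = make_record(age=45, qfpsa=10.0, cfdna=5.0)
        flags = component_flags(rec, self.model())
        qf_idx = self.model().components.index("QfPSA")
        assert flags[qf_idx] == 1

    def test_value_exactly_at_cutoff_does_not_flag(self):
        rec = make_record(age=45, qfpsa=50.0, cfdna=5.0, RASSF1A=50.0)
        flags = component_flags(rec, self.model())
        assert flags[self.model().components.index("RASSF1A")] == 0

    def test_missing_component_is_named(self):
        rec = make_record()
        del rec.marker_copies_per_ml["SOX8"]
        with pytest.raises(ValueError, match="SOX8"):
            component_flags(rec, self.model())

    def test_score_monotone_in_risk_direction(self):
        model = self.model()
        rec = make_record(age=45, qfpsa=50.0, cfdna=5.0)
        s0, _ = score(rec, model)
        for marker, value in [("RASSF1A", 100.0), ("NRIP3", 500.0)]:
            rec.marker_copies_per_ml[marker] = value
            s1, _ = score(rec, model)
            assert s1 >= s0
            s0 = s1


class TestScore:
    def test_all_flags_zero_is_negative(self):
        model = TestComponentFlags().model()
        rec = make_record(age=45, qfpsa=50.0, cfdna=5.0)
        assert score(rec, model) == (0, False)

    def test_five_of_seven_flags_is_positive_for_prisk(self):
        model = TestComponentFlags().model()
        rec = make_record(age=70, qfpsa=10.0, cfdna=100.0,
                          RASSF1A=100.0, SOX8=100.0)
        s, call = score(rec, model)
        assert s == 5 and call

    def test_two_flags_below_pirisk_threshold_is_negative(self):
        skel = model_skeleton("piRISK2")
        model = RiskModel(
            variant="piRISK2", components=skel.components,
            cutoffs={c: 50.0 for c in skel.components}, tau=3,
            sensitivity_targets=skel.sensitivity_targets,
        )
        rec = make_record(age=70, qfpsa=50.0, cfdna=5.0, RASSF1A=100.0)
        s, call = score(rec, model)
        assert s == 2 and not call

    def test_prisk_requires_qfpsa_component(self):
        with pytest.raises(ValueError, match="QfPSA"):
            RiskModel(variant="PRISK1", components=("RASSF1A", "age"),
                      cutoffs={}, tau=1, sensitivity_targets=("cs_PCa",))


class TestCalibration:
    def test_decisive_marker_yields_perfect_separation(self):
        cohort = (
            [make_record(f"b{i}", "BPH", RASSF1A=0.0) for i in range(3)]
            + [make_record(f"c{i}", "cs_PCa", RASSF1A=150.0 + i) for i in range(3)]
        )
        skel = small_skeleton(tau=1)
        model = calibrate_cutoffs(cohort, skel)
        assert model.achieved_sen_pct == 100.0
        assert model.achieved_spe_pct == 100.0

    def test_identical_patient_in_both_classes_caps_specificity(self):
        twin_kwargs = dict(age=65, qfpsa=25.0, cfdna=40.0, RASSF1A=80.0,
                           **{"MIR129-2": 80.0}, NRIP3=80.0)
        cohort = (
            [make_record("bph_twin", "BPH", **twin_kwargs)]
            + [make_record(f"b{i}", "BPH") for i in range(3)]
            + [make_record("cs_twin", "cs_PCa", **twin_kwargs)]
        )
        model = calibrate_cutoffs(cohort, small_skeleton(tau=1))
        assert model.achieved_sen_pct == 100.0
        assert model.achieved_spe_pct < 100.0

    def test_constraint_holds_on_synthetic_cohort(self):
        cfg = sc.default_config(
            seed=13, group_sizes={"BPH": 40, "indolent_PCa": 7, "cs_PCa": 32}
        )
        cohort = sc.generate_cohort(cfg)
        for variant in ("piRISK1", "PRISK2"):
            model = calibrate_cutoffs(cohort, model_skeleton(variant))
            assert model.achieved_sen_pct == 100.0
            for rec in cohort:
                if rec.group in model.sensitivity_targets:
                    _, call = score(rec, model)
                    assert call

    def test_patient_order_does_not_change_model(self):
        cfg = sc.default_config(
            seed=17, group_sizes={"BPH": 20, "cs_PCa": 15}
        )
        cohort = sc.generate_cohort(cfg)
        m1 = calibrate_cutoffs(cohort, model_skeleton("PRISK2"))
        rng = np.random.default_rng(0)
        shuffled = list(cohort)
        rng.shuffle(shuffled)
        m2 = calibrate_cutoffs(shuffled, model_skeleton("PRISK2"))
        assert m1.cutoffs == m2.cutoffs
        assert m1.achieved_spe_pct == m2.achieved_spe_pct

    def test_agrees_with_exhaustive_search_on_tiny_cohorts(self):
        for seed in range(6):
            rng = np.random.default_rng(seed)
            cohort = []
            for i in range(4):
                cohort.append(make_record(
                    f"b{i}", "BPH",
                    RASSF1A=float(rng.integers(0, 5) * 20),
                    **{"MIR129-2": float(rng.integers(0, 5) * 20)},
                    NRIP3=float(rng.integers(0, 5) * 20),
                ))
            for i in range(3):
                cohort.append(make_record(
                    f"c{i}", "cs_PCa",
                    RASSF1A=float(rng.integers(1, 6) * 20),
                    **{"MIR129-2": float(rng.integers(1, 6) * 20)},
                    NRIP3=float(rng.integers(1, 6) * 20),
                ))
            skel = small_skeleton(tau=2)
            model = calibrate_cutoffs(cohort, skel)
            assert model.achieved_spe_pct == pytest.approx(
                exhaustive_calibration(cohort, skel)
            )

    def test_missing_group_raises(self):
        cohort = [make_record("b0", "BPH")]
        with pytest.raises(CalibrationError):
            calibrate_cutoffs(cohort, small_skeleton())

    def test_prisk2_not_less_specific_than_pirisk2_on_average(self):
        """The free-PSA ratio adds discriminative information."""
        diffs = []
        for seed in range(8):
            cfg = sc.default_config(
                seed=seed, group_sizes={"BPH": 40, "indolent_PCa": 7, "cs_PCa": 32}
            )
            cohort = sc.generate_cohort(cfg)
            spe_p = calibrate_cutoffs(cohort, model_skeleton("PRISK2")).achieved_spe_pct
            spe_pi = calibrate_cutoffs(cohort, model_skeleton("piRISK2")).achieved_spe_pct
            diffs.append(spe_p - spe_pi)
        assert np.mean(diffs) >= 0


def test_records_frame_roundtrip():
    cohort = sc.generate_cohort(sc.default_config(seed=2,
                                                  group_sizes={"BPH": 5}))
    frame = records_to_frame(cohort)
    assert list(frame["sample_id"]) == [r.sample_id for r in cohort]
    assert frame["QfPSA"].iloc[0] == pytest.approx(cohort[0].qfpsa_pct)
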