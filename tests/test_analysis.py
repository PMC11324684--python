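"""Fold changes, thresholds, statistics cascade and MoA calls."""

import math

import numpy as np
import pandas as pd
import pytest

from ismn.analysis import (
    ClassificationThresholds,
    EndpointCall,
    classify_endpoint,
    dose_response_stats,
    fold_change,
    moa_call,
    rcg,
    summarize_experiment,
)


class TestRcg:
    def test_examples(self):
        assert rcg(5e5, 1e6) == 50.0
        assert rcg(7.0e5, 7.0e5) == 100.0
        assert rcg(1.09e6, 2e6) == pytest.approx(54.5)

    def test_zero_vehicle_rejected(self):
        with pytest.raises(ValueError):
            rcg(1e5, 0.0)


class TestFoldChange:
    def test_examples(self):
        fc = fold_change(2.0, 1.0)
        assert fc.raw == 2.0 and fc.sqrt == pytest.approx(math.sqrt(2))
        assert fold_change(1.0, 1.0) == fold_change(3.0, 3.0)

    def test_zero_vehicle_flagged_nan(self):
        fc = fold_change(1.0, 0.0)
        assert math.isnan(fc.raw) and math.isnan(fc.sqrt)

    def test_scale_invariance(self):
        a = fold_change(0.12, 0.04)
        b = fold_change(0.12 * 7.3, 0.04 * 7.3)
        assert a.raw == pytest.approx(b.raw) and a.sqrt == pytest.approx(b.sqrt)


class TestThresholds:
    def test_sqrt_rounded_cutoffs(self):
        t = ClassificationThresholds()
        assert t.h2ax_up_sqrt == 1.2
        assert t.p53_up_sqrt == 1.2
        assert t.ph3_up_sqrt == 1.1
        assert t.ph3_down_sqrt == 0.8
        assert t.mn_up_sqrt == 1.4

    def test_exact_sqrt_option_agrees_pre_rounding(self):
        exact = ClassificationThresholds(rounded=False)
        assert exact.h2ax_up_sqrt == pytest.approx(math.sqrt(1.5))
        # raw-scale and sqrt-scale classification agree with exact roots
        raw_exceeds = 1.55 / 1.0 > 1.5
        sqrt_exceeds = math.sqrt(1.55) >= exact.h2ax_up_sqrt
        assert raw_exceeds == sqrt_exceeds


class TestClassifyEndpoint:
    def test_ph3_increase_by_cutoff(self):
        call = classify_endpoint("ph3", 1.15, 0.2)
        assert call.direction == "increase" and call.positive

    def test_significance_or_rule(self):
        call = classify_endpoint("h2ax", 1.0, 0.01)
        assert call.positive  # significant despite fc below cutoff

    def test_mn_needs_significance_or_twofold(self):
        call = classify_endpoint("mn", 1.3, 0.07)
        assert not call.positive and call.direction == "no_change"
        assert classify_endpoint("mn", 1.3, 0.04).positive
        assert classify_endpoint("mn", 1.45, 0.5).positive

    def test_ph3_decrease(self):
        call = classify_endpoint("ph3", 0.75, 0.5)
        assert call.direction == "decrease" and call.positive

    def test_unknown_endpoint(self):
        with pytest.raises(ValueError):
            classify_endpoint("comet", 1.0, 1.0)


def make_calls(**directions):
    calls = {}
    for ep in ("mn", "h2ax", "ph3", "p53"):
        d = directions.get(ep, "no_change")
        calls[ep] = EndpointCall(ep, d, d != "no_change", 1.0, 1.0)
    return calls


class TestMoaCall:
    def test_aneugenic_profile(self):
        calls = make_calls(mn="increase", p53="increase", ph3="increase", h2ax="decrease")
        assert moa_call(calls) == "aneugenic"

    def test_clastogenic_profile(self):
        calls = make_calls(p53="increase", h2ax="increase", ph3="decrease")
        assert moa_call(calls) == "clastogenic"

    def test_all_quiet_negative(self):
        assert moa_call(make_calls()) == "negative"

    def test_lone_biomarker_shift_without_damage_is_negative(self):
        assert moa_call(make_calls(ph3="increase")) == "negative"

    def test_damage_with_conflicting_signature_equivocal(self):
        calls = make_calls(mn="increase", h2ax="increase", ph3="increase")
        assert moa_call(calls) == "equivocal"

    def test_missing_endpoint(self):
        calls = make_calls()
        del calls["p53"]
        with pytest.raises(ValueError):
            moa_call(calls)


class TestStatsCascade:
    def test_normal_data_uses_dunnett(self):
        rng = np.random.default_rng(0)
        vals = {d: rng.normal(10, 1, 3) for d in [0.0, 1.0, 2.0]}
        st = dose_response_stats(vals)
        assert st.test_used == "dunnett"
        assert set(st.p_by_dose) == {1.0, 2.0}

    def test_extreme_heteroscedasticity_routes_to_dunn(self):
        vals = {
            0.0: np.array([10.0, 10.1, 9.9]),
            1.0: np.array([5.0, 40.0, 80.0]),
            2.0: np.array([1.0, 90.0, 200.0]),
        }
        st = dose_response_stats(vals)
        assert st.test_used == "dunn"

    def test_identical_values_give_no_positives(self):
        vals = {d: np.array([5.0, 5.0, 5.0]) for d in [0.0, 1.0, 2.0]}
        st = dose_response_stats(vals)
        assert all(p >= 0.99 for p in st.p_by_dose.values())

    def test_single_replicate_descriptive(self):
        vals = {0.0: [1.0], 1.0: [2.0]}
        st = dose_response_stats(vals)
        assert st.test_used == "descriptive"
        assert math.isnan(st.p_by_dose[1.0])

    def test_missing_vehicle(self):
        with pytest.raises(ValueError):
            dose_response_stats({1.0: [1, 2, 3], 2.0: [1, 2, 3]})

    def test_dunn_detects_large_shift(self):
        vals = {
            0.0: np.array([1.0, 1.2, 0.9, 1.1, 1.05, 0.95]),
            1.0: np.array([9.0, 9.5, 10.0, 8.5, 9.2, 9.9]),
        }
        from ismn.analysis import dunns_test

        p = dunns_test([vals[0.0], vals[1.0]])
        assert p[0] < 0.01


def synthetic_classified(rng, doses, reps, n, effects):
    """Programmatic per-cell flags table (no images)."""
    rows = []
    manifest = []
    for d in doses:
        shift = effects(d)
        for r in range(1, reps + 1):
            sid = f"s_d{d}_r{r}"
            manifest.append(
                dict(
                    sample_id=sid,
                    dose=d,
                    replicate=r,
                    is_vehicle=d == 0,
                    is_stained=True,
                    cells_per_ml=1e6 * (1 - 0.05 * d),
                )
            )
            for i in range(n):
                ph3 = rng.random() < 0.05 * shift["ph3"]
                rows.append(
                    dict(
                        sample_id=sid,
                        focused=True,
                        single=True,
                        healthy=True,
                        dna_positive=True,
                        ph3_pos=ph3,
                        ph3_neg=not ph3,
                        true_nuclear_ph3=ph3,
                        true_nuclear_h2ax=(not ph3)
                        and rng.random() < 0.08 * shift["h2ax"],
                        p53_overall=rng.random() < 0.15 * shift["p53"],
                        mononucleated=not ph3,
                        mn_count=int(rng.random() < 0.03 * shift["mn"]),
                        cycle_stage="G1",
                    )
                )
    return pd.DataFrame(rows), pd.DataFrame(manifest)


class TestSummarize:
    def test_vehicle_only_fold_changes_are_one(self):
        rng = np.random.default_rng(0)
        classified, manifest = synthetic_classified(
            rng, [0.0], 3, 200, lambda d: dict(ph3=1, h2ax=1, p53=1, mn=1)
        )
        results, profile = summarize_experiment(classified, manifest)
        assert len(results) == 1
        assert all(v == 1.0 for v in results[0].fold_changes_raw.values())
        assert profile.overall == "negative"

    def test_programmed_clastogen_profile(self):
        rng = np.random.default_rng(1)
        effects = lambda d: dict(
            ph3=1 - 0.1 * d, h2ax=1 + 0.3 * d, p53=1 + 0.2 * d, mn=1 + 0.3 * d
        )
        classified, manifest = synthetic_classified(rng, [0.0, 2.5, 5.0], 3, 600, effects)
        results, profile = summarize_experiment(classified, manifest)
        assert profile.overall == "clastogenic"

    def test_no_vehicle_aborts(self):
        rng = np.random.default_rng(2)
        classified, manifest = synthetic_classified(
            rng, [1.0], 3, 100, lambda d: dict(ph3=1, h2ax=1, p53=1, mn=1)
        )
        with pytest.raises(ValueError):
            summarize_experiment(classified, manifest)

    def test_min_cell_warnings_emitted(self):
        rng = np.random.default_rng(3)
        classified, manifest = synthetic_classified(
            rng, [0.0, 5.0], 3, 100, lambda d: dict(ph3=1, h2ax=1, p53=1, mn=1)
        )
        results, _ = summarize_experiment(
            classified, manifest, min_cells_biomarkers=13000, min_cells_mn=10000
        )
        assert all(r.warnings for r in results)
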