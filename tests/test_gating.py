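"""Gate fitting and per-cell classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ismn.features import CellFeatures
from ismn.gating import (
    BiomarkerGates,
    CycleGates,
    GateSet,
    HealthGates,
    assign_cycle_stage,
    classify_cell,
    combined_average_gate,
    fit_cycle_gates,
    fit_healthy_thresholds,
    fit_unstained_peak,
    healthy_gate,
    qc_gate,
    tenfold_gate,
)


def feat(**kwargs):
    defaults = dict(
        bf_aspect_ratio=0.9,
        bf_area_um2=200.0,
        gradient_rms=80.0,
        cytoplasm_contrast=0.05,
        nuclear_area_um2=30.0,
        dna_intensity=2.0e5,
        n_nuclei=1,
    )
    defaults.update(kwargs)
    return CellFeatures(**defaults)


class TestQcGate:
    def test_passing_cell(self):
        focused, single = qc_gate(feat(), GateSet())
        assert focused and single

    def test_low_aspect_ratio_fails_single(self):
        _, single = qc_gate(feat(bf_aspect_ratio=0.5), GateSet())
        assert not single

    def test_boundary_area_excluded_strictly(self):
        _, single = qc_gate(feat(bf_area_um2=70.0), GateSet())
        assert not single

    def test_unfocused(self):
        focused, _ = qc_gate(feat(gradient_rms=50.0), GateSet())
        assert not focused


class TestHealthyGate:
    def test_percentile_thresholds(self):
        rng = np.random.default_rng(0)
        areas = rng.normal(30, 5, 500)
        contrasts = rng.normal(0.05, 0.01, 500)
        h = fit_healthy_thresholds(areas, contrasts)
        gates = GateSet(health=h)
        assert healthy_gate(feat(nuclear_area_um2=35, cytoplasm_contrast=0.04), gates)
        # tiny-nucleus (apoptotic-like) cell fails
        assert not healthy_gate(feat(nuclear_area_um2=5.0), gates)

    def test_identical_population_all_healthy(self):
        h = fit_healthy_thresholds([30.0] * 100, [0.05] * 100)
        gates = GateSet(health=h)
        assert healthy_gate(feat(nuclear_area_um2=30.0, cytoplasm_contrast=0.05), gates)


class TestCycleGates:
    @staticmethod
    def simulate(n=2000, mu=2.0e5, shift=1.9, cv=0.05, fr=(0.55, 0.10, 0.35), seed=11):
        rng = np.random.default_rng(seed)
        stages = rng.choice(3, size=n, p=fr)
        x = np.empty(n)
        x[stages == 0] = mu * rng.lognormal(0, cv, (stages == 0).sum())
        x[stages == 1] = rng.uniform(mu, shift * mu, (stages == 1).sum())
        x[stages == 2] = shift * mu * rng.lognormal(0, cv, (stages == 2).sum())
        ph3 = np.zeros(n, bool)
        g2 = np.flatnonzero(stages == 2)
        ph3[rng.choice(g2, size=len(g2) // 6, replace=False)] = True
        return x, np.array(["G1", "S", "G2M"])[stages], ph3

    def test_mixture_recovery(self):
        x, truth, ph3 = self.simulate()
        gates = fit_cycle_gates(x, ph3, g2_shift=1.9)
        pred = np.array([assign_cycle_stage(v, gates) for v in x])
        assert (pred == truth).mean() >= 0.90

    def test_pure_g1_population_leaves_g2m_empty(self):
        rng = np.random.default_rng(1)
        x = 2e5 * rng.lognormal(0, 0.05, 1000)
        gates = fit_cycle_gates(x, None)
        assert ((x >= gates.g2m[0]) & (x <= gates.g2m[1])).sum() == 0

    def test_g2_gate_is_scaled_g1_without_ph3(self):
        x, _, _ = self.simulate(seed=2)
        gates = fit_cycle_gates(x, None, g2_shift=2.0)
        assert gates.g2m[0] == pytest.approx(2.0 * gates.g1[0])
        assert gates.g2m[1] == pytest.approx(2.0 * gates.g1[1])

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            fit_cycle_gates(np.ones(100) * 2e5, None)

    def test_order_invariance(self):
        x, _, ph3 = self.simulate(seed=3)
        g1 = fit_cycle_gates(x, ph3)
        perm = np.random.default_rng(0).permutation(len(x))
        g2 = fit_cycle_gates(x[perm], ph3[perm])
        assert g1.g1 == pytest.approx(g2.g1)
        assert g1.g2m == pytest.approx(g2.g2m)


class TestBiomarkerGateFits:
    def test_unstained_peak_contains_median(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(7, 0.3, 2000)
        lo, hi = fit_unstained_peak(x)
        assert lo < np.median(x) < hi

    def test_two_identical_samples_average_to_same(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(7, 0.3, 500)
        single = fit_unstained_peak(x)
        double = fit_unstained_peak([x, x.copy()])
        assert double == pytest.approx(single)

    def test_shifted_copies_average_to_midpoint(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(7, 0.3, 500)
        a = fit_unstained_peak(x)
        b = fit_unstained_peak(x + 100.0)
        avg = fit_unstained_peak([x, x + 100.0])
        assert avg[0] == pytest.approx((a[0] + b[0]) / 2)
        assert avg[1] == pytest.approx((a[1] + b[1]) / 2)

    def test_too_few_cells(self):
        with pytest.raises(ValueError):
            fit_unstained_peak(np.ones(50))

    def test_tenfold_examples(self):
        assert tenfold_gate((100.0, 1000.0)) == (1000.0, 10000.0)
        lo, hi = tenfold_gate((100.0, 1000.0), p53_variant=True)
        assert lo == pytest.approx(900.0) and hi == pytest.approx(10000.0)
        assert tenfold_gate((0.0, 0.0)) == (0.0, 0.0)

    def test_combined_average(self):
        assert combined_average_gate((1000, 10000), (2000, 12000)) == (1500, 11000)
        g = (500.0, 800.0)
        assert combined_average_gate(g, g) == g

    @settings(max_examples=30, derandomize=True)
    @given(c=st.floats(min_value=0.1, max_value=100.0))
    def test_tenfold_scale_equivariance(self, c):
        rng = np.random.default_rng(5)
        x = rng.lognormal(6, 0.4, 400)
        base = tenfold_gate(fit_unstained_peak(x))
        scaled = tenfold_gate(fit_unstained_peak(c * x))
        assert scaled[0] == pytest.approx(c * base[0], rel=1e-9)
        assert scaled[1] == pytest.approx(c * base[1], rel=1e-9)


class TestClassifyCell:
    @staticmethod
    def gates():
        gs = GateSet(
            health=HealthGates(nuclear_area_min_um2=10.0, cytoplasm_contrast_max=0.2),
            cycle=CycleGates(g1=(1.5e5, 2.5e5), s=(2.5e5, 3.0e5), g2m=(3.0e5, 5.0e5)),
        )
        for marker in ("h2ax", "ph3", "p53"):
            gs.biomarkers[marker] = BiomarkerGates(
                combined_average=(3.0e4, 3.0e5), plusplus_bound=1.0e5
            )
        return gs

    def test_induced_nuclear_h2ax(self):
        f = feat(h2ax_nuclear=2.0e5, similarity_h2ax=2.5)
        flags = classify_cell(f, self.gates())
        assert flags.h2ax_plusplus and flags.true_nuclear_h2ax
        assert not flags.h2ax_plus

    def test_background_h2ax_is_plus_only(self):
        f = feat(h2ax_nuclear=5.0e4, similarity_h2ax=2.0)
        flags = classify_cell(f, self.gates())
        assert flags.h2ax_plus and not flags.h2ax_plusplus

    def test_cytoplasmic_ph3_not_true_nuclear(self):
        f = feat(ph3_nuclear=1.0e5, similarity_ph3=-0.8)
        flags = classify_cell(f, self.gates())
        assert flags.ph3_pos and not flags.true_nuclear_ph3

    def test_ph3_positive_excluded_from_mn_population(self):
        f = feat(ph3_nuclear=1.0e5, similarity_ph3=2.0)
        flags = classify_cell(f, self.gates())
        assert flags.ph3_pos and not flags.mononucleated

    def test_ph3_flags_mutually_exclusive(self):
        for nuclear in (1.0e3, 1.0e5):
            flags = classify_cell(feat(ph3_nuclear=nuclear), self.gates())
            assert not (flags.ph3_pos and flags.ph3_neg)

    def test_dim_dna_cell_unassigned(self):
        f = feat(dna_intensity=5.0e4, p53_whole=1.0e5)
        flags = classify_cell(f, self.gates())
        assert not flags.dna_positive
        assert not flags.p53_overall  # positivity requires DNA staining
        assert flags.cycle_stage == "unassigned"

    def test_missing_features_default_false(self):
        flags = classify_cell(CellFeatures(), self.gates())
        assert not any(
            [flags.ph3_pos, flags.h2ax_plus, flags.p53_overall, flags.healthy]
        )
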