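"""Dose-response metrics, statistical calls and mode-of-action profiles.

Per-dose endpoint metrics (micronucleus frequency, true-nuclear pH3 and
ɣH2AX++ fractions, overall-p53 fraction, cell-cycle fractions, relative
cell growth) are turned into fold changes versus the vehicle control,
square-root transformed for display and thresholding, tested against a
Dunnett/Dunn cascade, and combined into a clastogenic / aneugenic /
negative / equivocal call from the biomarker signature (ɣH2AX up with
pH3 not up = clastogenic; pH3 up with ɣH2AX not up = aneugenic), backed
by micronucleus or p53 positivity as the genotoxic-damage evidence.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ENDPOINTS = ("mn", "h2ax", "ph3", "p53")


def rcg(treated_cells_per_ml: float, vehicle_cells_per_ml: float) -> float:
    """Relative cell growth, 100 x treated / vehicle cell concentration."""
    if vehicle_cells_per_ml <= 0:
        raise ValueError("vehicle cell concentration must be positive")
    return 100.0 * treated_cells_per_ml / vehicle_cells_per_ml


@dataclass(frozen=True)
class FoldChange:
    raw: float
    sqrt: float


def fold_change(metric_treated: float, metric_vehicle: float) -> FoldChange:
    """Raw and square-root-transformed fold change versus vehicle.

    The square root normalises the strongly right-skewed raw fold
    changes for display and thresholding.  A zero vehicle metric leaves
    the fold change undefined (NaN, flagged by the caller).
    """
    if metric_vehicle < 0:
        raise ValueError("vehicle metric must be >= 0")
    if metric_vehicle == 0:
        return FoldChange(float("nan"), float("nan"))
    raw = metric_treated / metric_vehicle
    return FoldChange(float(raw), float(math.sqrt(raw)))


@dataclass(frozen=True)
class ClassificationThresholds:
    """Fold-change cut-offs on the raw scale, with sqrt-scale values
    derived by square-rooting and rounding to one decimal (1.5 -> 1.2,
    1.3 -> 1.1, 0.7 -> 0.8, 2.0 -> 1.4)."""

    ph3_up: float = 1.3
    ph3_down: float = 0.7
    h2ax_up: float = 1.5
    p53_up: float = 1.5
    mn_up: float = 2.0
    alpha: float = 0.05
    #: compare on the rounded sqrt scale (the published convention) or
    #: against exact square roots
    rounded: bool = True

    def _sqrt(self, raw: float) -> float:
        value = math.sqrt(raw)
        return round(value, 1) if self.rounded else value

    @property
    def ph3_up_sqrt(self) -> float:
        return self._sqrt(self.ph3_up)

    @property
    def ph3_down_sqrt(self) -> float:
        return self._sqrt(self.ph3_down)

    @property
    def h2ax_up_sqrt(self) -> float:
        return self._sqrt(self.h2ax_up)

    @property
    def p53_up_sqrt(self) -> float:
        return self._sqrt(self.p53_up)

    @property
    def mn_up_sqrt(self) -> float:
        return self._sqrt(self.mn_up)

    def bounds_for(self, endpoint: str) -> tuple[float | None, float | None]:
        """(up, down) sqrt-scale cut-offs; None where no cut-off applies."""
        return {
            "ph3": (self.ph3_up_sqrt, self.ph3_down_sqrt),
            "h2ax": (self.h2ax_up_sqrt, None),
            "p53": (self.p53_up_sqrt, None),
            "mn": (self.mn_up_sqrt, None),
        }[endpoint]


@dataclass
class EndpointCall:
    endpoint: str
    direction: str  # increase / decrease / no_change
    positive: bool
    sqrt_fold_change: float
    p_value: float


def classify_endpoint(
    endpoint: str,
    sqrt_fc: float,
    p_value: float,
    thresholds: ClassificationThresholds | None = None,
) -> EndpointCall:
    """Call one endpoint at one dose.

    Biomarkers are positive when the mean response exceeds the
    fold-change cut-off OR is statistically significant.  The MN
    endpoint is significance-first: positive on p < alpha, otherwise on
    a greater-than-twofold increase (sqrt scale 1.4).
    """
    thresholds = thresholds or ClassificationThresholds()
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    up, down = thresholds.bounds_for(endpoint)
    significant = bool(np.isfinite(p_value) and p_value < thresholds.alpha)
    direction = "no_change"
    if np.isfinite(sqrt_fc):
        if up is not None and sqrt_fc >= up:
            direction = "increase"
        elif down is not None and sqrt_fc <= down:
            direction = "decrease"
        elif significant:
            direction = "increase" if sqrt_fc > 1.0 else "decrease"
    positive = direction != "no_change"
    return EndpointCall(endpoint, direction, positive, sqrt_fc, p_value)


# ---------------------------------------------------------------------------
# statistics cascade
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseStats:
    test_used: str  # "dunnett", "dunn" or "descriptive"
    anova_p: float
    p_by_dose: dict[float, float]
    bartlett_p: float = float("nan")
    shapiro_p: float = float("nan")


def dunns_test(groups: Sequence[np.ndarray]) -> list[float]:
    """Dunn's rank-based multiple-comparison z-test of each treated
    group against the first (control) group, with tie correction.
    Two-sided p-values, unadjusted."""
    all_vals = np.concatenate(groups)
    n = all_vals.size
    ranks = stats.rankdata(all_vals)
    _, counts = np.unique(all_vals, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n - 1))) if n > 1 else 0.0
    var_unit = n * (n + 1) / 12.0 - tie_term
    splits = np.cumsum([len(g) for g in groups])[:-1]
    rank_groups = np.split(ranks, splits)
    r0 = rank_groups[0].mean()
    n0 = len(groups[0])
    out = []
    for g in rank_groups[1:]:
        se = math.sqrt(var_unit * (1.0 / n0 + 1.0 / len(g)))
        if se == 0:
            out.append(1.0)
            continue
        z = (g.mean() - r0) / se
        out.append(float(2.0 * stats.norm.sf(abs(z))))
    return out


def dose_response_stats(
    values_by_dose: Mapping[float, Sequence[float]],
    alpha: float = 0.05,
) -> DoseResponseStats:
    """Run the distribution-checked testing cascade.

    Variance homogeneity (Bartlett) and normality (Shapiro-Wilk, on
    within-group residuals) are tested first; when both pass (p > 0.05)
    a one-way ANOVA is run and each dose is compared with the vehicle
    by Dunnett's test.  When either check fails, the non-parametric
    Dunn's test is used on the raw responses.  With fewer than two
    replicates per group only descriptive output is possible.
    """
    doses = sorted(values_by_dose)
    if 0.0 not in doses:
        raise ValueError("vehicle (dose 0) group required")
    groups = [np.asarray(values_by_dose[d], dtype=float) for d in doses]
    treated_doses = [d for d in doses if d != 0.0]
    if min(len(g) for g in groups) < 2:
        return DoseResponseStats(
            "descriptive", float("nan"), {d: float("nan") for d in treated_doses}
        )

    control = groups[doses.index(0.0)]
    treated = [np.asarray(values_by_dose[d], dtype=float) for d in treated_doses]

    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # identical values everywhere: nothing to test
        return DoseResponseStats("dunnett", 1.0, {d: 1.0 for d in treated_doses}, 1.0, 1.0)

    residuals = np.concatenate([g - g.mean() for g in groups])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            bart_p = float(stats.bartlett(*groups).pvalue)
        except Exception:
            bart_p = 0.0
        try:
            shap_p = float(stats.shapiro(residuals).pvalue)
        except Exception:
            shap_p = 0.0
    if not (np.isfinite(bart_p) and np.isfinite(shap_p)):
        bart_p = bart_p if np.isfinite(bart_p) else 0.0
        shap_p = shap_p if np.isfinite(shap_p) else 0.0

    if bart_p > alpha and shap_p > alpha:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova_p = float(stats.f_oneway(*groups).pvalue)
            # fixed rng: the multivariate-t quadrature behind Dunnett's
            # p-values is randomized and must not break run determinism
            res = stats.dunnett(*treated, control=control, rng=0)
        p_by_dose = {d: float(p) for d, p in zip(treated_doses, res.pvalue)}
        return DoseResponseStats("dunnett", anova_p, p_by_dose, bart_p, shap_p)

    pvals = dunns_test([control] + treated)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            anova_p = float(stats.kruskal(*groups).pvalue)
        except Exception:
            anova_p = float("nan")
    return DoseResponseStats(
        "dunn", anova_p, dict(zip(treated_doses, pvals)), bart_p, shap_p
    )


# ---------------------------------------------------------------------------
# experiment summary and MoA call
# ---------------------------------------------------------------------------


@dataclass
class DoseGroupResult:
    dose: float
    n_cells_scored: int
    n_mononucleated: int
    rcg_percent: float
    mn_frequency: float
    ph3_fraction: float
    h2ax_fraction: float
    p53_fraction: float
    cycle_fractions: dict[str, float]
    fold_changes_raw: dict[str, float] = field(default_factory=dict)
    fold_changes_sqrt: dict[str, float] = field(default_factory=dict)
    p_value_vs_vehicle: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MoAProfile:
    per_endpoint: dict[str, EndpointCall]
    overall: str  # clastogenic / aneugenic / negative / equivocal
    top_dose_called: float
    test_used: dict[str, str] = field(default_factory=dict)


def moa_call(calls: Mapping[str, EndpointCall]) -> str:
    """Overall mode-of-action from the endpoint calls at the top
    analysable dose.

    Genotoxic-damage evidence is a positive MN or p53 endpoint; the
    biomarker signature then sets the direction: ɣH2AX increase without
    a pH3 increase is clastogenic, a pH3 increase without a ɣH2AX
    increase is aneugenic.  Without damage evidence the profile is
    negative; with damage evidence but an uninformative signature it is
    equivocal.
    """
    missing = [e for e in ENDPOINTS if e not in calls]
    if missing:
        raise ValueError(f"missing endpoint calls: {missing}")
    damage = calls["mn"].positive or calls["p53"].positive
    h2ax_up = calls["h2ax"].direction == "increase"
    ph3_up = calls["ph3"].direction == "increase"
    if not damage:
        return "negative"
    if h2ax_up and not ph3_up:
        return "clastogenic"
    if ph3_up and not h2ax_up:
        return "aneugenic"
    return "equivocal"


_METRIC_COLUMNS = {
    "mn": "mn_frequency",
    "h2ax": "h2ax_fraction",
    "ph3": "ph3_fraction",
    "p53": "p53_fraction",
}


def summarize_experiment(
    classified: pd.DataFrame,
    manifest: pd.DataFrame,
    thresholds: ClassificationThresholds | None = None,
    min_cells_biomarkers: int = 13000,
    min_cells_mn: int = 10000,
    rcg_floor: float = 30.0,
) -> tuple[list[DoseGroupResult], MoAProfile]:
    """Reduce per-cell flags to per-dose metrics and the MoA profile.

    Metrics use the stated populations: pH3 and p53 fractions on
    healthy DNA-positive cells, ɣH2AX on the pH3-negative subset, MN
    frequency on healthy pH3-negative mononucleated cells.  Replicate
    fractions feed the statistics cascade; per-dose metrics are means
    of replicate fractions; fold changes compare each dose with the
    vehicle.  Endpoint calls for the MoA are made at the highest dose
    whose relative cell growth still reaches ``rcg_floor`` percent.
    Warnings are attached when the scored-cell minimums (13k healthy /
    10k mononucleated per dose at full scale; relaxable for desk-scale
    runs) are not met.
    """
    thresholds = thresholds or ClassificationThresholds()
    df = classified.merge(
        manifest[["sample_id", "dose", "replicate", "is_vehicle", "is_stained", "cells_per_ml"]],
        on="sample_id",
        how="left",
    )
    df = df[df.is_stained.astype(bool)]
    if not (df.dose == 0).any():
        raise ValueError("no vehicle sample present")

    qc = df.focused & df.single
    healthy_pop = qc & df.healthy & df.dna_positive
    ph3_neg_pop = healthy_pop & df.ph3_neg
    mono_pop = qc & df.mononucleated & df.dna_positive

    def frac(num_mask: pd.Series, den_mask: pd.Series) -> float:
        den = int(den_mask.sum())
        return float((num_mask & den_mask).sum() / den) if den else float("nan")

    # replicate-level metrics
    rep_rows = []
    for (dose, rep), g in df.groupby(["dose", "replicate"]):
        idx = g.index
        rep_rows.append(
            {
                "dose": dose,
                "replicate": rep,
                "mn_frequency": frac(g.mn_count >= 1, mono_pop.loc[idx]),
                "ph3_fraction": frac(g.true_nuclear_ph3, healthy_pop.loc[idx]),
                "h2ax_fraction": frac(g.true_nuclear_h2ax, ph3_neg_pop.loc[idx]),
                "p53_fraction": frac(g.p53_overall, healthy_pop.loc[idx]),
                "cells_per_ml": g.cells_per_ml.iloc[0],
            }
        )
    reps = pd.DataFrame(rep_rows)

    stats_by_endpoint: dict[str, DoseResponseStats] = {}
    for ep, col in _METRIC_COLUMNS.items():
        values = {
            float(d): g[col].dropna().to_numpy() for d, g in reps.groupby("dose")
        }
        stats_by_endpoint[ep] = dose_response_stats(values, alpha=thresholds.alpha)

    vehicle_ml = reps.loc[reps.dose == 0, "cells_per_ml"].mean()
    vehicle_metrics = {
        ep: float(reps.loc[reps.dose == 0, col].mean())
        for ep, col in _METRIC_COLUMNS.items()
    }

    results: list[DoseGroupResult] = []
    for dose, g in reps.groupby("dose"):
        dose = float(dose)
        sub = df[df.dose == dose]
        idx = sub.index
        n_scored = int(healthy_pop.loc[idx].sum())
        n_mono = int(mono_pop.loc[idx].sum())
        cyc = sub[healthy_pop.loc[idx]]
        cycle_fractions = {
            stage: float((cyc.cycle_stage == stage).mean()) if len(cyc) else float("nan")
            for stage in ("G1", "S", "G2M")
        }
        res = DoseGroupResult(
            dose=dose,
            n_cells_scored=n_scored,
            n_mononucleated=n_mono,
            rcg_percent=rcg(float(g.cells_per_ml.mean()), float(vehicle_ml)),
            mn_frequency=float(g.mn_frequency.mean()),
            ph3_fraction=float(g.ph3_fraction.mean()),
            h2ax_fraction=float(g.h2ax_fraction.mean()),
            p53_fraction=float(g.p53_fraction.mean()),
            cycle_fractions=cycle_fractions,
        )
        for ep, col in _METRIC_COLUMNS.items():
            fc = fold_change(getattr(res, col), vehicle_metrics[ep]) if dose else FoldChange(1.0, 1.0)
            res.fold_changes_raw[ep] = fc.raw
            res.fold_changes_sqrt[ep] = fc.sqrt
            res.p_value_vs_vehicle[ep] = (
                stats_by_endpoint[ep].p_by_dose.get(dose, float("nan"))
                if dose
                else float("nan")
            )
        if n_scored < min_cells_biomarkers:
            res.warnings.append(
                f"only {n_scored} healthy cells scored at dose {dose:g} "
                f"(minimum {min_cells_biomarkers})"
            )
        if n_mono < min_cells_mn:
            res.warnings.append(
                f"only {n_mono} mononucleated cells at dose {dose:g} "
                f"(minimum {min_cells_mn})"
            )
        results.append(res)
    results.sort(key=lambda r: r.dose)

    analysable = [r for r in results if r.dose > 0 and r.rcg_percent >= rcg_floor]
    top = analysable[-1] if analysable else results[-1]
    calls = {
        ep: classify_endpoint(
            ep, top.fold_changes_sqrt[ep], top.p_value_vs_vehicle[ep], thresholds
        )
        for ep in ENDPOINTS
    }
    profile = MoAProfile(
        per_endpoint=calls,
        overall=moa_call(calls),
        top_dose_called=top.dose,
        test_used={ep: s.test_used for ep, s in stats_by_endpoint.items()},
    )
    return results, profile


def results_frame(results: list[DoseGroupResult]) -> pd.DataFrame:
    """Flatten per-dose results into a tidy table (one row per dose)."""
    rows = []
    for r in results:
        row = {
            "dose": r.dose,
            "n_cells_scored": r.n_cells_scored,
            "n_mononucleated": r.n_mononucleated,
            "rcg_percent": r.rcg_percent,
            "mn_frequency": r.mn_frequency,
            "ph3_fraction": r.ph3_fraction,
            "h2ax_fraction": r.h2ax_fraction,
            "p53_fraction": r.p53_fraction,
        }
        for stage, v in r.cycle_fractions.items():
            row[f"frac_{stage}"] = v
        for ep in ENDPOINTS:
            row[f"fc_raw_{ep}"] = r.fold_changes_raw.get(ep, float("nan"))
            row[f"fc_sqrt_{ep}"] = r.fold_changes_sqrt.get(ep, float("nan"))
            row[f"p_{ep}"] = r.p_value_vs_vehicle.get(ep, float("nan"))
        row["warnings"] = "; ".join(r.warnings)
        rows.append(row)
    return pd.DataFrame(rows)
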