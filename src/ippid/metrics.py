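"""Glycemic outcome metrics and arm comparison.

Per patient and per window (whole day-and-night record, and the union of the
4-h post-prandial windows after main meals) the battery is: mean and standard
deviation of glucose, the time-in-range percentages TR [70-180], TTR
[70-140], TA180 (>180), TA250 (>250), TB70 (<70), and the low/high blood
glucose risk indices.  LBGI/HBGI use the standard symmetrizing risk
transform

    f(g) = 1.509 ((ln g)^1.084 - 5.381),   risk(g) = 10 f(g)^2,

with LBGI the mean risk over samples with f < 0 (hypoglycemic side, zero
contribution otherwise) and HBGI the analogue for f > 0.

Arms are compared with the two-sided Mann-Whitney U test for continuous
metrics and Fisher's exact test for the categorical hypo-treatment fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .protocol import Scenario

RISK_A = 1.509
RISK_B = 1.084
RISK_C = 5.381
RISK_DOMAIN = (20.0, 600.0)  # mg/dl; the risk scale's defined glucose range

CONTINUOUS_METRICS = ("gm", "gstd", "tr", "ttr", "ta180", "ta250", "tb70",
                      "lbgi", "hbgi")
SIGNIFICANCE_TIERS = (0.001, 0.01, 0.05)


def postprandial_mask(scenario: Scenario, t_abs: np.ndarray,
                      horizon: float = 240.0) -> np.ndarray:
    """Union of [meal, meal + horizon) windows over the main meals.

    ``t_abs`` is the absolute time grid in minutes from the scenario start.
    Snacks and rescues are excluded from the window definition.
    """
    t = np.asarray(t_abs, dtype=float)
    mask = np.zeros(t.size, dtype=bool)
    for e in scenario.main_meals():
        mask |= (t >= e.t_abs) & (t < e.t_abs + horizon)
    return mask


def risk_f(g: np.ndarray) -> np.ndarray:
    """Symmetrizing risk transform; glucose clamped to the scale's domain."""
    g = np.clip(np.asarray(g, dtype=float), *RISK_DOMAIN)
    return RISK_A * (np.log(g) ** RISK_B - RISK_C)


def lbgi_hbgi(g: np.ndarray):
    """Low/high blood-glucose indices of a trace; nonpositive samples are
    excluded from the transform with a warning."""
    g = np.asarray(g, dtype=float)
    bad = g <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} nonpositive glucose "
                      "samples from the risk transform")
        g = g[~bad]
    if g.size == 0:
        return 0.0, 0.0
    f = risk_f(g)
    risk = 10.0 * f * f
    lbgi = float(np.mean(np.where(f < 0, risk, 0.0)))
    hbgi = float(np.mean(np.where(f > 0, risk, 0.0)))
    return lbgi, hbgi


def glycemic_metrics(G: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Metric battery over the (optionally masked) glucose trace."""
    G = np.asarray(G, dtype=float)
    if mask is not None:
        G = G[np.asarray(mask, dtype=bool)]
    if G.size == 0:
        raise ValueError("empty masked trace")
    pct = 100.0 / G.size
    lbgi, hbgi = lbgi_hbgi(G)
    return dict(
        gm=float(np.mean(G)),
        gstd=float(np.std(G, ddof=1)) if G.size > 1 else 0.0,
        tr=float(np.count_nonzero((G >= 70) & (G <= 180)) * pct),
        ttr=float(np.count_nonzero((G >= 70) & (G <= 140)) * pct),
        ta180=float(np.count_nonzero(G > 180) * pct),
        ta250=float(np.count_nonzero(G > 250) * pct),
        tb70=float(np.count_nonzero(G < 70) * pct),
        lbgi=lbgi, hbgi=hbgi)


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    p_value: float
    test: str         # "mann-whitney" | "fisher"
    tier: str         # "<0.001" | "<0.01" | "<0.05" | "ns"


def _tier(p: float) -> str:
    for level in SIGNIFICANCE_TIERS:
        if p < level:
            return f"<{level:g}"
    return "ns"


def compare_arms(a, b, kind: str = "continuous",
                 metric: str = "") -> ComparisonResult:
    """Two-sided comparison of one metric between arms.

    ``kind='continuous'``: ``a`` and ``b`` are per-patient samples
    (Mann-Whitney U).  ``kind='categorical'``: ``a`` and ``b`` are
    (successes, total) count pairs (Fisher's exact test).
    """
    if kind == "continuous":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size == 0 or b.size == 0:
            raise ValueError("empty sample")
        if np.ptp(np.concatenate([a, b])) == 0:
            return ComparisonResult(metric, 1.0, "mann-whitney", "ns")
        method = "exact" if max(a.size, b.size) <= 8 else "auto"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        p = float(res.pvalue)
        return ComparisonResult(metric, p, "mann-whitney", _tier(p))
    if kind == "categorical":
        (ka, na), (kb, nb) = a, b
        table = [[ka, na - ka], [kb, nb - kb]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1])
        return ComparisonResult(metric, p, "fisher", _tier(p))
    raise ValueError("kind must be 'continuous' or 'categorical'")


@dataclass(frozen=True)
class MetricsReport:
    """Per-arm medians [25th, 75th] with comparison p-values."""

    table: pd.DataFrame        # rows: metric x window; columns per arm + p
    per_patient: pd.DataFrame  # long form: arm, patient, window, metric values

    def to_text(self) -> str:
        return self.table.to_string()


def _median_iqr(x) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.2f} [{q1:.2f}, {q3:.2f}]"


def build_report(arm_results: dict, ht_counts: dict | None = None) -> MetricsReport:
    """Tabulate per-patient metrics of two (or more) arms.

    ``arm_results`` maps arm name -> DataFrame with columns ``patient``,
    ``window`` and the metric columns; ``ht_counts`` maps arm name ->
    per-patient hypo-treatment counts (aligned with patients).
    """
    arms = list(arm_results)
    patient_sets = [tuple(sorted(df["patient"].unique()))
                    for df in arm_results.values()]
    if len(set(patient_sets)) != 1:
        raise ValueError("arms were run on different patient sets")
    windows = sorted(arm_results[arms[0]]["window"].unique())
    rows = []
    for metric in CONTINUOUS_METRICS:
        for window in windows:
            row = {"metric": metric.upper(), "window": window}
            samples = {}
            for arm in arms:
                df = arm_results[arm]
                vals = df.loc[df["window"] == window, metric].to_numpy()
                samples[arm] = vals
                row[arm] = _median_iqr(vals)
            if len(arms) == 2:
                cmp = compare_arms(samples[arms[0]], samples[arms[1]],
                                   "continuous", metric)
                row["p_value"] = cmp.p_value
                row["tier"] = cmp.tier
            rows.append(row)
    if ht_counts is not None:
        n = len(patient_sets[0])
        counts = {arm: int(sum(1 for c in ht_counts[arm] if c >= 1))
                  for arm in arms}
        row = {"metric": "HT%", "window": "D&N"}
        for arm in arms:
            row[arm] = f"{100.0 * counts[arm] / n:.0f}"
        if len(arms) == 2:
            cmp = compare_arms((counts[arms[0]], n), (counts[arms[1]], n),
                               "categorical", "ht_pct")
            row["p_value"] = cmp.p_value
            row["tier"] = cmp.tier
        rows.append(row)
        row = {"metric": "HT#", "window": "D&N"}
        for arm in arms:
            row[arm] = _median_iqr(np.asarray(list(ht_counts[arm])))
        rows.append(row)
    long = pd.concat([df.assign(arm=arm) for arm, df in arm_results.items()],
                     ignore_index=True)
    return MetricsReport(table=pd.DataFrame(rows), per_patient=long)
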