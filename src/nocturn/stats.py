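"""Sleep-deprivation rebound analysis and group statistics.

The rebound analysis pairs, per animal, a 24-h baseline day with the
recovery day (6 h enforced wakefulness from lights-on, then free sleep),
computes NREM%, REM% and normalized NREM delta power in matched ZT bins
(2-h or 6-h), and reports recovery-minus-baseline differences.  Bins
inside the deprivation window [ZT0, ZT6) are kept for
wake-enforcement QC but flagged so they can be excluded from
sleep-rebound statistics.  Delta power on both days is normalized by the
*baseline* day's NREM total-power scalar, so homeostatic changes on the
recovery day are visible rather than normalized away.

The group-statistics surface is the conventional one for such studies —
one-way and two-way fixed-effects ANOVA, Bonferroni-adjusted pairwise
comparisons, Tukey HSD for circadian-amplitude contrasts, paired
two-tailed t-tests within line — delegated to scipy/statsmodels.
Degenerate inputs (zero variance everywhere) are reported as
non-testable instead of propagating NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .architecture import sleep_latency, state_amounts
from .core import Hypnogram, State
from .errors import AlignmentError
from .spectral import (BandDefinition, BANDS, EpochSpectra,
                       nrem_delta_timecourse, nrem_total_power_normalizer)

__all__ = [
    "SD_END_ZT_S",
    "day_measures",
    "rebound_differences",
    "post_sd_latency",
    "one_way_anova",
    "two_way_anova",
    "pairwise_bonferroni",
    "tukey_hsd",
    "paired_ttest",
    "bonferroni_adjust",
    "group_compare",
    "StatsReport",
]

#: End of the 6-h deprivation window, seconds after lights-on.
SD_END_ZT_S = 6 * 3600.0


def day_measures(hypnogram: Hypnogram, spectra: EpochSpectra | None = None,
                 bin_h: float = 2.0,
                 delta_band: BandDefinition = BANDS["delta"],
                 delta_normalizer: float | None = None) -> pd.DataFrame:
    """Per-ZT-bin NREM%, REM% and (when spectra are given) normalized
    NREM delta power for one recorded day."""
    amounts = state_amounts(hypnogram, bin_h=bin_h)
    out = pd.DataFrame({
        "NREM_pct": amounts["NREM"],
        "REM_pct": amounts["REM"],
    })
    if spectra is not None:
        delta = nrem_delta_timecourse(hypnogram=hypnogram, spectra=spectra,
                                      bin_h=bin_h, band=delta_band,
                                      normalizer=delta_normalizer)
        out["delta_pct"] = delta.reindex(out.index).to_numpy()
    return out


def rebound_differences(baseline: pd.DataFrame, recovery: pd.DataFrame,
                        bin_h: float | None = None) -> pd.DataFrame:
    """Recovery − baseline per matched ZT bin, tidy long format.

    Inputs are :func:`day_measures` tables indexed by ZT bin start
    (hours); the indices must match exactly.  The output has columns
    ``(zt_h, measure, baseline, recovery, difference, in_sd_window)``;
    differences are NaN wherever either day is undefined.
    """
    if len(baseline.index) != len(recovery.index) or \
            not np.allclose(baseline.index, recovery.index):
        raise AlignmentError("baseline and recovery days are not ZT-aligned")
    if bin_h is not None:
        step = np.diff(baseline.index)
        if step.size and not np.allclose(step, bin_h):
            raise AlignmentError(
                f"tables are binned at {step[0]} h, expected {bin_h} h")
    rows = []
    sd_end_h = SD_END_ZT_S / 3600.0
    widths = np.diff(baseline.index)
    width = widths[0] if widths.size else 24.0
    for measure in baseline.columns:
        if measure not in recovery.columns:
            continue
        for zt in baseline.index:
            b = baseline.loc[zt, measure]
            r = recovery.loc[zt, measure]
            rows.append({
                "zt_h": float(zt),
                "measure": measure,
                "baseline": b,
                "recovery": r,
                "difference": r - b,
                "in_sd_window": bool(zt + width <= sd_end_h + 1e-9),
            })
    return pd.DataFrame(rows)


def post_sd_latency(hypnogram_recovery: Hypnogram,
                    sd_end_zt_s: float = SD_END_ZT_S,
                    target: State = State.NREM, **kwargs) -> float:
    """Latency (min) from the end of deprivation to consolidated sleep;
    delegates to :func:`nocturn.architecture.sleep_latency`."""
    return sleep_latency(hypnogram_recovery, reference_zt_s=sd_end_zt_s,
                         target=target, **kwargs)


# ---------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------

def _group_arrays(df: pd.DataFrame, dv: str, between: str
                  ) -> dict[str, np.ndarray]:
    return {str(g): sub[dv].dropna().to_numpy()
            for g, sub in df.groupby(between, observed=True)}


def one_way_anova(df: pd.DataFrame, dv: str, between: str) -> dict:
    """Fixed-effects one-way ANOVA.  Returns F, p, dfs, and
    ``testable=False`` when every value is identical."""
    groups = list(_group_arrays(df, dv, between).values())
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(groups)
    df_between = len(groups) - 1
    df_within = pooled.size - len(groups)
    if np.ptp(pooled) < 1e-300:
        return {"F": np.nan, "p": np.nan, "df_between": df_between,
                "df_within": df_within, "testable": False}
    F, p = sstats.f_oneway(*groups)
    return {"F": float(F), "p": float(p), "df_between": df_between,
            "df_within": df_within, "testable": True}


def two_way_anova(df: pd.DataFrame, dv: str, factor_a: str, factor_b: str
                  ) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction (type-II SS)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = df.rename(columns={dv: "_dv", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_dv ~ C(_fa) * C(_fb)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table.index = [str(i).replace("C(_fa)", factor_a)
                   .replace("C(_fb)", factor_b) for i in table.index]
    return table


def bonferroni_adjust(pvalues) -> np.ndarray:
    """p → min(1, m·p) for m comparisons."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * p.size)


def pairwise_bonferroni(df: pd.DataFrame, dv: str, between: str
                        ) -> pd.DataFrame:
    """All pairwise two-sample t-tests with Bonferroni-adjusted p."""
    groups = _group_arrays(df, dv, between)
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            t, p = sstats.ttest_ind(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b,
                         "mean_diff": float(groups[a].mean()
                                            - groups[b].mean()),
                         "t": float(t), "p_uncorrected": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bonferroni"] = bonferroni_adjust(out["p_uncorrected"])
    return out


def tukey_hsd(df: pd.DataFrame, dv: str, between: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (statsmodels)."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = df[[dv, between]].dropna()
    res = pairwise_tukeyhsd(sub[dv].to_numpy(),
                            sub[between].astype(str).to_numpy())
    return pd.DataFrame(res.summary().data[1:],
                        columns=res.summary().data[0])


def paired_ttest(x, y) -> dict:
    """Two-tailed paired t-test (baseline vs recovery within line)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 2 or np.ptp(x - y) < 1e-300:
        return {"t": np.nan, "p": np.nan, "n": int(x.size),
                "testable": False}
    t, p = sstats.ttest_rel(x, y)
    return {"t": float(t), "p": float(p), "n": int(x.size), "testable": True}


@dataclass
class StatsReport:
    """Bundle of the study's group statistics for one measure."""

    measure: str
    one_way: dict
    pairwise: pd.DataFrame
    two_way: pd.DataFrame | None = None
    tukey: pd.DataFrame | None = None
    alpha: float = 0.05

    def to_text(self) -> str:
        lines = [f"Measure: {self.measure}"]
        ow = self.one_way
        if ow.get("testable", True):
            lines.append(
                f"  one-way ANOVA: F({ow['df_between']},{ow['df_within']}) "
                f"= {ow['F']:.3f}, p = {ow['p']:.4g}")
        else:
            lines.append("  one-way ANOVA: not testable (no variance)")
        if len(self.pairwise):
            lines.append("  pairwise (Bonferroni):")
            for _, row in self.pairwise.iterrows():
                lines.append(
                    f"    {row.group_a} vs {row.group_b}: "
                    f"diff = {row.mean_diff:+.3f}, "
                    f"p_adj = {row.p_bonferroni:.4g}")
        return "\n".join(lines)


def group_compare(values: pd.DataFrame, dv: str, between: str = "line",
                  interval: str | None = None,
                  tukey: bool = False) -> StatsReport:
    """One-way line comparison of a per-animal measure, with Bonferroni
    post-hoc (and optionally Tukey HSD, used for LD-amplitude
    contrasts).  ``values`` is tidy: one row per animal, columns
    including ``dv`` and ``between`` (and optionally ``interval``)."""
    df = values
    if interval is not None:
        df = df[df["interval"] == interval]
    report = StatsReport(
        measure=dv if interval is None else f"{dv} ({interval})",
        one_way=one_way_anova(df, dv, between),
        pairwise=pairwise_bonferroni(df, dv, between),
        tukey=tukey_hsd(df, dv, between) if tukey else None,
    )
    if "interval" in values.columns and interval is None and \
            values["interval"].nunique() > 1:
        report.two_way = two_way_anova(values, dv, between, "interval")
    return report
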