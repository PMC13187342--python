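"""Group statistics of the cross-over study.

Small-sample machinery: Lilliefors normality (Monte Carlo p), two-sided
paired t tests with Student-t confidence intervals, Benjamini-Hochberg
step-up FDR adjustment across the declared comparison family, OLS
regression R^2, the min/max-normalised reaction-time contrast, and Monte
Carlo post-hoc power.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from ._rand import child_rng
from .errors import ValidationError
from .signals import DAYS


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05
    fdr_q: float = 0.05
    ci_level: float = 0.95
    mc_iterations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha", "fdr_q", "ci_level"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValidationError(f"{name} must be in (0, 1)")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p: float
    ci_low: float
    ci_high: float
    mean: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValidationError("CI must bracket the mean")
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError("p outside [0, 1]")


def _lilliefors_stat(sample: np.ndarray) -> float:
    x = np.sort(sample)
    n = x.size
    z = (x - x.mean()) / x.std(ddof=1)
    cdf = sstats.norm.cdf(z)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def lilliefors(sample: Sequence[float], config: StatsConfig = StatsConfig()) -> float:
    """Monte Carlo Lilliefors test of composite normality.

    The KS distance to the normal with estimated mean/sd is compared
    against its null distribution, resampled with the config seed.
    """
    x = np.asarray(sample, float)
    if x.size < 4:
        raise ValidationError("Lilliefors test requires n >= 4")
    if np.ptp(x) == 0:
        raise ValidationError("constant sample has no defined normality test")
    d_obs = _lilliefors_stat(x)
    rng = child_rng(config.seed, "lilliefors", x.size)
    n = x.size
    sims = rng.standard_normal((config.mc_iterations, n))
    sims.sort(axis=1)
    means = sims.mean(axis=1, keepdims=True)
    sds = sims.std(axis=1, ddof=1, keepdims=True)
    cdf = sstats.norm.cdf((sims - means) / sds)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    d_null = np.maximum((grid_hi - cdf).max(axis=1), (cdf - grid_lo).max(axis=1))
    return float((np.sum(d_null >= d_obs) + 1) / (config.mc_iterations + 1))


def paired_contrast_test(
    deltas: Sequence[float], ci_level: float = 0.95
) -> TestResult:
    """Two-sided one-sample t test on paired deltas with a Student-t CI."""
    x = np.asarray(deltas, float)
    if x.size < 2:
        raise ValidationError("paired test requires n >= 2")
    if not np.all(np.isfinite(x)):
        raise ValidationError("deltas must be finite")
    if np.allclose(x.std(ddof=1), 0.0):
        raise ValidationError("zero-variance deltas: t statistic undefined")
    n = x.size
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(n))
    t = mean / se
    df = n - 1
    p = float(2.0 * sstats.t.sf(abs(t), df))
    tcrit = float(sstats.t.ppf(0.5 * (1.0 + ci_level), df))
    return TestResult(
        statistic=float(t), df=df, p=p,
        ci_low=mean - tcrit * se, ci_high=mean + tcrit * se, mean=mean,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regress_r2(x: Sequence[float], y: Sequence[float]) -> Dict[str, float]:
    """Ordinary least squares of y on x: r^2, slope and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("regression requires n >= 3 paired points")
    if np.ptp(x) == 0:
        raise ValidationError("constant x: slope undefined")
    res = sstats.linregress(x, y)
    return {"r2": float(res.rvalue**2), "slope": float(res.slope),
            "p": float(res.pvalue), "intercept": float(res.intercept)}


def rt_contrast(behaviour: pd.DataFrame) -> Dict[str, float]:
    """Site-contrasted reaction-time reduction for one participant.

    RTs are min/max normalised within each participant-day (all 240
    trials), block medians taken, the active block normalised to the
    same-day sham as a percent reduction, and the Ventricle-day value
    subtracted from the GPi-day value.
    """
    required = {"day", "condition", "rt"}
    if not required <= set(behaviour.columns):
        raise ValidationError(f"behaviour table needs columns {sorted(required)}")
    reductions = {}
    for day in DAYS:
        day_df = behaviour[behaviour.day == day]
        if day_df.empty:
            raise ValidationError(f"no trials for {day}")
        rts = day_df.rt.to_numpy(float)
        lo, hi = rts.min(), rts.max()
        if hi == lo:
            raise ValidationError("degenerate reaction times (min == max)")
        norm = (rts - lo) / (hi - lo)
        day_df = day_df.assign(rt_norm=norm)
        medians = {
            cond: float(g.rt_norm.median())
            for cond, g in day_df.groupby("condition")
        }
        if "sham" not in medians or "active" not in medians:
            raise ValidationError(f"{day} lacks a sham or active block")
        if medians["sham"] == 0:
            raise ValidationError("zero sham median after normalisation")
        reductions[day] = 100.0 * (
            medians["sham"] - medians["active"]
        ) / medians["sham"]
    return {
        "gpi_reduction_pct": reductions["GPi_day"],
        "ventricle_reduction_pct": reductions["Ventricle_day"],
        "site_contrast_pct": reductions["GPi_day"] - reductions["Ventricle_day"],
    }


def posthoc_power(
    effect: float,
    sd: float,
    n: int,
    config: StatsConfig = StatsConfig(),
    iterations: int = 5000,
) -> float:
    """Monte Carlo power of the paired t test at the given effect and n."""
    if n < 2:
        raise ValidationError("power calculation requires n >= 2")
    if sd <= 0:
        raise ValidationError("sd must be > 0")
    rng = child_rng(config.seed, "power", n)
    samples = effect + sd * rng.standard_normal((iterations, n))
    means = samples.mean(axis=1)
    ses = samples.std(axis=1, ddof=1) / np.sqrt(n)
    t = np.abs(means / np.maximum(ses, 1e-300))
    tcrit = sstats.t.ppf(1.0 - config.alpha / 2.0, n - 1)
    return float(np.mean(t > tcrit))
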