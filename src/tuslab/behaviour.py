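"""Random-dot-motion reaction-time trials with a planted condition effect.

Each participant-day holds 240 trials: two ~5-minute runs per condition
(sham first, then active), 60 trials per run, inter-stimulus intervals
uniform in [1.25, 1.75] s, dot coherence 8% or 50%, and log-normal
reaction times truncated to the recorded [0.1, 2] s window.

The condition effect is planted on the estimator's own scale: the
analysis min/max-normalises RTs within a participant-day before taking
block medians, which distorts any raw multiplicative shift. The
generator therefore calibrates the raw active-condition scale factor (on
a large-sample quantile approximation, independent of the trial draws)
so that the planted effect equals the requested normalised-median
reduction — 17.70% on the targeted day by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._rand import child_rng
from .errors import ValidationError
from .signals import DAYS

RT_MIN, RT_MAX = 0.1, 2.0
TRIALS_PER_DAY = 240
RUNS_PER_CONDITION = 2
COHERENCE_LEVELS = (0.08, 0.50)


@dataclass(frozen=True)
class BehaviourSpec:
    """Log-normal RT model and the planted per-day condition effects.

    ``planted_reduction_pct`` maps day name to the target percent
    reduction of the min/max-normalised median RT in active vs sham
    blocks on that day.
    """

    log_median: float = np.log(0.55)  # log s
    log_sigma: float = 0.35
    planted_reduction_pct: Optional[Dict[str, float]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log_sigma <= 0:
            raise ValidationError("log_sigma must be > 0")
        if self.planted_reduction_pct is None:
            object.__setattr__(
                self,
                "planted_reduction_pct",
                {"GPi_day": 17.70, "Ventricle_day": 0.0},
            )


def _truncated_median(mu: float, sigma: float) -> float:
    """Median of the lognormal truncated to the recorded RT window."""
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    lo, hi = dist.cdf(RT_MIN), dist.cdf(RT_MAX)
    return float(dist.ppf(lo + 0.5 * (hi - lo)))


def _mixture_quantile(mu: float, sigma: float, scale: float, q: float) -> float:
    """Quantile of the equal-weight sham/active truncated-RT mixture."""
    d1 = stats.lognorm(s=sigma, scale=np.exp(mu))
    d2 = stats.lognorm(s=sigma, scale=scale * np.exp(mu))

    def cdf(x):
        def trunc(d):
            lo, hi = d.cdf(RT_MIN), d.cdf(RT_MAX)
            return np.clip((d.cdf(x) - lo) / (hi - lo), 0.0, 1.0)

        return 0.5 * trunc(d1) + 0.5 * trunc(d2)

    return float(
        optimize.brentq(lambda x: cdf(x) - q, RT_MIN, RT_MAX, xtol=1e-10)
    )


def _normalised_reduction(mu: float, sigma: float, scale: float) -> float:
    """Asymptotic normalised-median reduction for a raw scale factor.

    Normalisation bounds are approximated by the expected extreme
    quantiles of the day's 240-trial mixture.
    """
    m_sham = _truncated_median(mu, sigma)
    m_act = _truncated_median(mu + np.log(scale), sigma)
    q = 1.0 / (TRIALS_PER_DAY + 1)
    lo = _mixture_quantile(mu, sigma, scale, q)
    return 100.0 * (m_sham - m_act) / (m_sham - lo)


def calibrate_scale(
    spec: BehaviourSpec, target_reduction_pct: float
) -> float:
    """Raw active/sham RT scale factor realising the target normalised-
    median reduction (1.0 when the target is zero)."""
    if target_reduction_pct == 0.0:
        return 1.0

    def objective(s):
        return _normalised_reduction(spec.log_median, spec.log_sigma, s) - (
            target_reduction_pct
        )

    return float(optimize.brentq(objective, 0.3, 1.0, xtol=1e-8))


def generate_behaviour(
    spec: BehaviourSpec,
    seed: Optional[int] = None,
    ground_truth=None,
) -> pd.DataFrame:
    """Trial table for both days of one participant.

    Columns: day, condition, run, trial, onset (s within run), dot
    coherence, direction, response, correct, rt (s, truncated to the
    recorded window). When a session :class:`~tuslab.signals.GroundTruth`
    is passed, the planted per-day normalised-median RT reductions are
    recorded on it.
    """
    master = spec.seed if seed is None else seed
    if ground_truth is not None:
        ground_truth.rt_reduction_pct.update(spec.planted_reduction_pct)
    rows = []
    trials_per_run = TRIALS_PER_DAY // (2 * RUNS_PER_CONDITION)
    for day in DAYS:
        scale = calibrate_scale(spec, spec.planted_reduction_pct[day])
        for condition in ("sham", "active"):
            s = scale if condition == "active" else 1.0
            for run in range(RUNS_PER_CONDITION):
                rng = child_rng(master, "behaviour", day, condition, run)
                isi = rng.uniform(1.25, 1.75, size=trials_per_run)
                onsets = np.cumsum(isi)
                z = rng.standard_normal(trials_per_run)
                rt = np.exp(spec.log_median + np.log(s) + spec.log_sigma * z)
                rt = np.clip(rt, RT_MIN, RT_MAX)
                coher = rng.choice(COHERENCE_LEVELS, size=trials_per_run)
                direction = rng.choice(["left", "right"], size=trials_per_run)
                # responses mostly correct; low coherence slightly worse
                p_correct = np.where(coher > 0.1, 0.98, 0.85)
                correct = rng.uniform(size=trials_per_run) < p_correct
                response = np.where(
                    correct,
                    direction,
                    np.where(direction == "left", "right", "left"),
                )
                for i in range(trials_per_run):
                    rows.append(
                        {
                            "day": day,
                            "condition": condition,
                            "run": run,
                            "trial": i,
                            "onset": float(onsets[i]),
                            "dot_coherence": float(coher[i]),
                            "direction": direction[i],
                            "response": response[i],
                            "correct": bool(correct[i]),
                            "rt": float(rt[i]),
                        }
                    )
    df = pd.DataFrame(rows)
    counts = df.groupby("day").size()
    assert (counts == TRIALS_PER_DAY).all()
    return df
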