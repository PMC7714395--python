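"""Growth-curve summaries and resampling statistics.

Two small tools: a t-based confidence interval for endpoint culture density
across biological replicates, and a percentile bootstrap for the effect of a
genetic intervention on culture density at a chosen time.  The bootstrap
resamples whole replicate curves within each arm — the biological replicate
is the exchangeable unit, which sidesteps modeling the autocorrelation of
points along one curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GrowthCurve",
    "EndpointSummary",
    "BootstrapCI",
    "endpoint_summary",
    "effect_at_time",
    "bootstrap_effect_ci",
    "read_growth_csv",
    "growth_curves_to_frame",
]


@dataclass(frozen=True)
class GrowthCurve:
    """OD600 vs time (hours) for one replicate culture."""

    arm: str  # "experiment" | "control"
    replicate: str
    times: tuple[float, ...]
    od600: tuple[float, ...]

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        od = np.asarray(self.od600)
        if t.size < 2:
            raise ValueError("a growth curve needs at least two time points")
        if t.size != od.size:
            raise ValueError("times and od600 must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(od < 0):
            raise ValueError("od600 must be non-negative")

    def at(self, t_eval: float) -> float:
        """OD at ``t_eval`` by linear interpolation; errors outside the span."""
        if not self.times[0] <= t_eval <= self.times[-1]:
            raise ValueError(
                f"t_eval={t_eval} outside curve span "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return float(np.interp(t_eval, self.times, self.od600))


@dataclass(frozen=True)
class EndpointSummary:
    n: int
    mean: float
    ci95: tuple[float, float]


@dataclass(frozen=True)
class BootstrapCI:
    level: float
    effect: float  # observed effect at t_eval
    lo: float
    hi: float
    n_boot: int
    seed: int


def endpoint_summary(values, level: float = 0.95) -> EndpointSummary:
    """Mean endpoint OD with a t-distribution confidence interval."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("confidence interval undefined for fewer than 2 values")
    mean = float(v.mean())
    se = float(v.std(ddof=1) / np.sqrt(v.size))
    tcrit = float(stats.t.ppf(0.5 + level / 2, df=v.size - 1))
    half = tcrit * se
    return EndpointSummary(n=int(v.size), mean=mean, ci95=(mean - half, mean + half))


def _arm_mean_at(curves, t_eval: float) -> float:
    return float(np.mean([c.at(t_eval) for c in curves]))


def effect_at_time(experiment, control, t_eval: float) -> float:
    """Mean experiment OD minus mean control OD at ``t_eval`` (interpolated)."""
    experiment, control = list(experiment), list(control)
    if not experiment or not control:
        raise ValueError("both arms need at least one curve")
    return _arm_mean_at(experiment, t_eval) - _arm_mean_at(control, t_eval)


def bootstrap_effect_ci(
    experiment,
    control,
    t_eval: float,
    level: float = 0.999,
    n_boot: int = 10_000,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile bootstrap CI for the OD effect at ``t_eval``.

    Replicate curves are resampled with replacement within each arm and the
    effect recomputed per resample.  Output is reproducible given the seed.
    """
    experiment, control = list(experiment), list(control)
    if not experiment or not control:
        raise ValueError("both arms need at least one curve")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    exp_vals = np.array([c.at(t_eval) for c in experiment])
    ctrl_vals = np.array([c.at(t_eval) for c in control])
    observed = float(exp_vals.mean() - ctrl_vals.mean())
    rng = np.random.default_rng(seed)
    idx_e = rng.integers(0, exp_vals.size, size=(n_boot, exp_vals.size))
    idx_c = rng.integers(0, ctrl_vals.size, size=(n_boot, ctrl_vals.size))
    effects = exp_vals[idx_e].mean(axis=1) - ctrl_vals[idx_c].mean(axis=1)
    alpha = 1.0 - level
    lo, hi = np.quantile(effects, [alpha / 2, 1 - alpha / 2])
    return BootstrapCI(
        level=level,
        effect=observed,
        lo=float(lo),
        hi=float(hi),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_GROWTH_COLUMNS = ["arm", "replicate", "time_hr", "od600"]


def read_growth_csv(source) -> list[GrowthCurve]:
    """Read a long-form growth table: arm, replicate, time_hr, od600[, dilution].

    When a ``dilution`` column is present the OD values are multiplied by it
    (measurements of turbid cultures taken in five- or tenfold dilution).
    """
    df = pd.read_csv(source)
    missing = set(_GROWTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    od = df["od600"].to_numpy(dtype=float)
    if "dilution" in df.columns:
        od = od * df["dilution"].fillna(1.0).to_numpy(dtype=float)
    df = df.assign(od600_corrected=od)
    curves = []
    for (arm, replicate), group in sorted(df.groupby(["arm", "replicate"])):
        group = group.sort_values("time_hr")
        curves.append(
            GrowthCurve(
                arm=str(arm),
                replicate=str(replicate),
                times=tuple(group["time_hr"].astype(float)),
                od600=tuple(group["od600_corrected"].astype(float)),
            )
        )
    return curves


def growth_curves_to_frame(curves) -> pd.DataFrame:
    rows = [
        {"arm": c.arm, "replicate": c.replicate, "time_hr": t, "od600": od}
        for c in curves
        for t, od in zip(c.times, c.od600)
    ]
    return pd.DataFrame(rows, columns=_GROWTH_COLUMNS)
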