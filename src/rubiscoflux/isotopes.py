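"""Inference of rubisco's share of 3PG synthesis from 13C labeling data.

Cells grown on ~99% 13C substrate build nearly fully labeled biomass; any
excess 12C must have entered from ambient CO2 via rubisco carboxylation.
Serine is the sentinel amino acid: it is made from 3-phosphoglycerate (3PG),
and 3PG has two origins — lower glycolysis (all carbons substrate-derived)
and rubisco carboxylation, where one of the two product 3PG molecules
carries the CO2-derived carbon at its carboxyl position.

The mixture model: let ``b`` be the per-carbon 12C probability of purely
substrate-derived carbon (measured from a rubisco-independent control
strain, which captures substrate purity and every systematic effect), ``c``
the 12C fraction of intracellular CO2, ``d`` the fraction of rubisco-derived
3PG molecules that carry the CO2 carbon (1/2 for the canonical two-product
carboxylation), and ``x`` the fraction of 3PG production due to rubisco.
Then

    total-serine mode:  f12C_exp     = b + x d (c - b) / 3
    carboxyl mode:      f12C_carboxyl = b + x d (c - b)

The carboxyl-specific 12C fraction is measured by MRM on the serine M+2
isotopologue, whose fragmentation separates ions whose carboxyl carbon is
13C (61.1 m/z channel) from those where it is 12C (62.1 m/z).  Because the
measurement conditions on M+2 (exactly one 12C among three carbons), the
observed channel ratio is a conditional probability; the estimator inverts
that conditioning before applying the mixture formula, so that both modes
estimate the same unconditional quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "IsotopologueDistribution",
    "MrmPair",
    "LabelingExperiment",
    "MixtureParams",
    "FluxFractionEstimate",
    "total_13c_fraction",
    "total_12c_fraction",
    "mrm_carboxyl_13c",
    "carboxyl_12c_from_m2",
    "estimate_rubisco_fraction",
    "compare_to_fba",
    "read_isotopologue_csv",
    "read_mrm_csv",
    "experiments_to_frames",
]

_SUM_TOL = 1e-6


@dataclass(frozen=True)
class IsotopologueDistribution:
    """M+i fractions f_0..f_N of one compound with N carbons."""

    compound: str
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.size < 2:
            raise ValueError("need at least M+0 and M+1 fractions (N >= 1)")
        if np.any(f < -_SUM_TOL) or np.any(f > 1 + _SUM_TOL):
            raise ValueError(f"{self.compound}: fractions must lie in [0, 1]")
        if abs(f.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.compound}: isotopologue fractions sum to {f.sum():.8f}, "
                "expected 1"
            )

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1


@dataclass(frozen=True)
class MrmPair:
    """Peak integrals of the serine M+2 fragment channels.

    ``peak_61_1`` collects M+2 ions whose carboxyl carbon is 13C,
    ``peak_62_1`` those where it is 12C.
    """

    peak_61_1: float
    peak_62_1: float

    def __post_init__(self) -> None:
        if self.peak_61_1 < 0 or self.peak_62_1 < 0:
            raise ValueError("peak integrals must be non-negative")
        if self.peak_61_1 == 0 and self.peak_62_1 == 0:
            raise ValueError("at least one MRM channel must be nonzero")


@dataclass(frozen=True)
class LabelingExperiment:
    """One biological replicate's measured labeling state."""

    role: str  # "experiment" | "control"
    replicate: str
    distributions: tuple[IsotopologueDistribution, ...]
    mrm: MrmPair | None = None

    def __post_init__(self) -> None:
        if self.role not in ("experiment", "control"):
            raise ValueError(f"role must be experiment/control, got {self.role!r}")

    def distribution(self, compound: str) -> IsotopologueDistribution:
        for d in self.distributions:
            if d.compound == compound:
                return d
        raise KeyError(
            f"replicate {self.replicate!r} has no {compound!r} distribution"
        )


@dataclass(frozen=True)
class MixtureParams:
    """Parameters of the two-origin 3PG mixture model."""

    c: float = 0.989  # 12C fraction of intracellular CO2 (ambient air)
    d: float = 0.5  # rubisco-derived 3PG carrying the CO2 carbon / total
    mode: str = "carboxyl_mrm"  # or "total_serine"

    def __post_init__(self) -> None:
        if not 0.0 < self.c <= 1.0:
            raise ValueError("c must lie in (0, 1]")
        if not 0.0 < self.d <= 1.0:
            raise ValueError("d must lie in (0, 1]")
        if self.mode not in ("total_serine", "carboxyl_mrm"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class FluxFractionEstimate:
    """Inferred fraction of 3PG production due to rubisco."""

    x: float  # mean across replicates, clipped to [0, 1]
    per_replicate: tuple[float, ...]
    mean: float
    min: float
    clipped: tuple[bool, ...]
    background_b: float
    params: MixtureParams

    @property
    def any_clipped(self) -> bool:
        return any(self.clipped)


# ---------------------------------------------------------------------------
# Label-fraction arithmetic
# ---------------------------------------------------------------------------

def total_13c_fraction(d: IsotopologueDistribution) -> float:
    """Carbon-weighted average 13C fraction: sum_i f_i * i / N."""
    f = np.asarray(d.fractions)
    i = np.arange(f.size)
    return float((f * i).sum() / d.n_carbons)


def total_12c_fraction(d: IsotopologueDistribution) -> float:
    return 1.0 - total_13c_fraction(d)


def mrm_carboxyl_13c(m: MrmPair) -> float:
    """Carboxyl-carbon 13C fraction among serine M+2 ions: A / (A + B)."""
    return m.peak_61_1 / (m.peak_61_1 + m.peak_62_1)


def carboxyl_12c_from_m2(q12: float, b: float) -> float:
    """Undo the M+2 conditioning of the MRM channel ratio.

    For independent carbon positions with carboxyl 12C probability ``p`` and
    background 12C probability ``b`` at the other two positions, the chance
    that an M+2 serine ion (exactly one 12C) has its 12C at the carboxyl is

        q12 = p (1-b) / (p (1-b) + 2 b (1-p))

    Inverting for ``p`` recovers the unconditional carboxyl 12C fraction
    that the mixture model is written in.
    """
    if not 0.0 <= q12 <= 1.0:
        raise ValueError("q12 must lie in [0, 1]")
    if not 0.0 < b < 1.0:
        raise ValueError("background b must lie in (0, 1)")
    if q12 == 1.0:
        return 1.0
    odds = 2.0 * b * q12 / ((1.0 - b) * (1.0 - q12))
    return odds / (1.0 + odds)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

def _as_list(x) -> list[LabelingExperiment]:
    if isinstance(x, LabelingExperiment):
        return [x]
    return list(x)


def estimate_rubisco_fraction(
    experiment,
    control,
    params: MixtureParams = MixtureParams(),
    compound: str = "serine",
) -> FluxFractionEstimate:
    """Estimate the rubisco share x of 3PG production from labeling data.

    ``experiment`` and ``control`` are :class:`LabelingExperiment` replicates
    (single instances or iterables).  The background per-carbon 12C
    probability ``b`` is the mean total-serine 12C fraction of the control
    replicates; each experiment replicate then yields one estimate, clipped
    to [0, 1] with an explicit flag when clipping occurred.
    """
    exps = _as_list(experiment)
    ctrls = _as_list(control)
    if not exps or not ctrls:
        raise ValueError("need at least one experiment and one control replicate")
    b = float(
        np.mean([total_12c_fraction(r.distribution(compound)) for r in ctrls])
    )
    if params.c <= b:
        raise ValueError(
            f"no labeling contrast: CO2 12C fraction c={params.c} must exceed "
            f"the background b={b:.4f}"
        )
    denom = params.d * (params.c - b)
    raw: list[float] = []
    for rep in exps:
        if params.mode == "total_serine":
            f12 = total_12c_fraction(rep.distribution(compound))
            raw.append(3.0 * (f12 - b) / denom)
        else:  # carboxyl_mrm
            if rep.mrm is None:
                raise ValueError(
                    f"replicate {rep.replicate!r} has no MRM pair; "
                    "carboxyl_mrm mode needs one"
                )
            q12 = 1.0 - mrm_carboxyl_13c(rep.mrm)
            p = carboxyl_12c_from_m2(q12, b)
            raw.append((p - b) / denom)
    clipped = tuple(not 0.0 <= v <= 1.0 for v in raw)
    vals = tuple(float(np.clip(v, 0.0, 1.0)) for v in raw)
    mean = float(np.mean(vals))
    return FluxFractionEstimate(
        x=mean,
        per_replicate=vals,
        mean=mean,
        min=float(np.min(vals)),
        clipped=clipped,
        background_b=b,
        params=params,
    )


def compare_to_fba(est: FluxFractionEstimate, prediction) -> dict:
    """Set the labeling estimate against the FBA point and FVA range.

    ``prediction`` is ``(point, (low, high))`` on the same 0-1 fraction
    scale as the estimate.  Returns a plain record with an inside-range flag
    and the absolute gap to the nearest end of the range (0 when inside).
    """
    point, (lo, hi) = prediction
    mean = est.mean
    inside = lo <= mean <= hi
    gap = 0.0 if inside else min(abs(mean - lo), abs(mean - hi))
    return {
        "estimate_mean": mean,
        "estimate_min": est.min,
        "estimate_per_replicate": list(est.per_replicate),
        "prediction_point": point,
        "prediction_range": [lo, hi],
        "inside_range": inside,
        "absolute_gap": gap,
    }


# ---------------------------------------------------------------------------
# Tabular I/O (long-form CSV dialects)
# ---------------------------------------------------------------------------

_ISO_COLUMNS = ["compound", "n_carbons", "replicate", "role", "m_plus", "fraction"]
_MRM_COLUMNS = ["replicate", "role", "peak_61_1", "peak_62_1"]


def read_isotopologue_csv(source, mrm_source=None) -> list[LabelingExperiment]:
    """Read long-form isotopologue (and optionally MRM) tables.

    The isotopologue CSV has columns ``compound, n_carbons, replicate, role,
    m_plus, fraction``; the optional MRM CSV has ``replicate, role,
    peak_61_1, peak_62_1``.  Returns one :class:`LabelingExperiment` per
    (role, replicate), sorted.
    """
    iso = pd.read_csv(source)
    missing = set(_ISO_COLUMNS) - set(iso.columns)
    if missing:
        raise ValueError(f"isotopologue table missing columns: {sorted(missing)}")
    mrm_lookup: dict[tuple[str, str], MrmPair] = {}
    if mrm_source is not None:
        mrm_lookup = {
            (row.role, str(row.replicate)): MrmPair(row.peak_61_1, row.peak_62_1)
            for row in read_mrm_csv(mrm_source).itertuples()
        }
    out = []
    for (role, replicate), group in sorted(
        iso.groupby(["role", "replicate"], sort=True)
    ):
        dists = []
        for compound, cg in sorted(group.groupby("compound")):
            n = int(cg["n_carbons"].iloc[0])
            fractions = np.zeros(n + 1)
            for row in cg.itertuples():
                fractions[int(row.m_plus)] = row.fraction
            dists.append(IsotopologueDistribution(compound, tuple(fractions)))
        out.append(
            LabelingExperiment(
                role=role,
                replicate=str(replicate),
                distributions=tuple(dists),
                mrm=mrm_lookup.get((role, str(replicate))),
            )
        )
    return out


def read_mrm_csv(source) -> pd.DataFrame:
    mrm = pd.read_csv(source)
    missing = set(_MRM_COLUMNS) - set(mrm.columns)
    if missing:
        raise ValueError(f"MRM table missing columns: {sorted(missing)}")
    return mrm


def experiments_to_frames(
    experiments,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Serialize LabelingExperiments back to the two long-form tables."""
    iso_rows, mrm_rows = [], []
    for rep in experiments:
        for dist in rep.distributions:
            for i, frac in enumerate(dist.fractions):
                iso_rows.append(
                    {
                        "compound": dist.compound,
                        "n_carbons": dist.n_carbons,
                        "replicate": rep.replicate,
                        "role": rep.role,
                        "m_plus": i,
                        "fraction": frac,
                    }
                )
        if rep.mrm is not None:
            mrm_rows.append(
                {
                    "replicate": rep.replicate,
                    "role": rep.role,
                    "peak_61_1": rep.mrm.peak_61_1,
                    "peak_62_1": rep.mrm.peak_62_1,
                }
            )
    return (
        pd.DataFrame(iso_rows, columns=_ISO_COLUMNS),
        pd.DataFrame(mrm_rows, columns=_MRM_COLUMNS),
    )
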