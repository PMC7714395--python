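"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators, each a pure function of its spec (seeds included in the
spec), emulating the data the analysis stages consume:

* :func:`make_toy_model` — a nine-reaction, carbon-balanced caricature of
  glycerol metabolism in which deleting the ribose-phosphate isomerase
  (T5_rpi) turns Ru5P into a dead-end that only the Prk + rubisco detour can
  drain.  Its FBA behavior is simple enough to solve by hand, which makes it
  the oracle for the LP machinery.
* :func:`simulate_labeling` — serine (and glycine) isotopologue tables plus
  serine M+2 MRM fragment pairs under the two-origin 3PG mixture model at a
  chosen true rubisco fraction ``x_true``.
* :func:`simulate_growth_curves` — logistic replicate growth curves with a
  configured endpoint effect between experiment and control arms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import HeterologousSpec
from .growth import GrowthCurve
from .isotopes import IsotopologueDistribution, LabelingExperiment, MrmPair
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToyNetworkSpec",
    "LabelingSimSpec",
    "GrowthSimSpec",
    "make_toy_model",
    "toy_heterologous_spec",
    "simulate_labeling",
    "simulate_growth_curves",
]


# ---------------------------------------------------------------------------
# Toy rubisco-coupled network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyNetworkSpec:
    """Configuration of the toy glycerol network.

    Biomass consumes ``biomass_g3p`` units of G3P and ``biomass_ri5p`` of
    Ri5P per unit growth.  With the defaults the hand-solvable optima are
    3.75 (wild type, no detour), 0 (delta-rpi), and 5.0 (delta-rpi + detour,
    rubisco flux 10).
    """

    glycerol_uptake: float = 10.0
    biomass_g3p: float = 1.0
    biomass_ri5p: float = 1.0
    include_heterologous: bool = True

    def __post_init__(self) -> None:
        if self.glycerol_uptake <= 0:
            raise ValueError("glycerol_uptake must be positive")
        if self.biomass_g3p <= 0 or self.biomass_ri5p <= 0:
            raise ValueError("biomass coefficients must be positive")


def toy_heterologous_spec() -> HeterologousSpec:
    """The Prk/rubisco detour spec matching the toy network's metabolite ids."""
    return HeterologousSpec(
        prk_id="T6_prk",
        rubisco_id="T7_rubisco",
        ru5p_id="ru5p",
        rubp_id="rubp",
        co2_id="co2",
        target_metabolite_id="g3p",
    )


def make_toy_model(spec: ToyNetworkSpec = ToyNetworkSpec()) -> MetabolicModel:
    """Build the toy network (9 reactions with the detour, 7 without).

    Carbon is balanced by construction (e.g. the lumped non-oxidative PP
    reaction T4 moves 15 carbons on each side), so steady-state mass balance
    doubles as a carbon audit.  Energy cofactors are deliberately absent.
    """
    mets = [
        Metabolite("glyc", "glycerol", "e"),
        Metabolite("g3p", "glyceraldehyde/glycerate 3-phosphate pool"),
        Metabolite("f6p", "fructose 6-phosphate"),
        Metabolite("ru5p", "ribulose 5-phosphate"),
        Metabolite("ri5p", "ribose 5-phosphate"),
        Metabolite("co2", "carbon dioxide", "e"),
    ]
    rxns = [
        Reaction("EX_glyc", {"glyc": -1.0}, -spec.glycerol_uptake, math.inf,
                 is_exchange=True),
        Reaction("T2_glycolysis", {"glyc": -1.0, "g3p": 1.0}),
        Reaction("T3_f6p_synthesis", {"g3p": -2.0, "f6p": 1.0}),
        Reaction(
            "T4_nonox_ppp",
            {"f6p": -2.0, "g3p": -1.0, "ru5p": 2.0, "ri5p": 1.0},
        ),
        Reaction("T5_rpi", {"ru5p": -1.0, "ri5p": 1.0}),
        Reaction("EX_co2", {"co2": -1.0}, -1000.0, 1000.0, is_exchange=True),
        Reaction(
            "T9_biomass",
            {"g3p": -spec.biomass_g3p, "ri5p": -spec.biomass_ri5p},
        ),
    ]
    model = MetabolicModel(tuple(mets), tuple(rxns), "T9_biomass", name="toy")
    if spec.include_heterologous:
        from .design import add_heterologous

        model, _ = add_heterologous(model, toy_heterologous_spec())
    return model


# ---------------------------------------------------------------------------
# Labeling simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelingSimSpec:
    """Forward model of the 13C-glycerol labeling experiment.

    Cells grow on ``purity`` atom-fraction 13C substrate, so every purely
    substrate-derived carbon is 12C with probability ``b = 1 - purity``.
    In the experiment arm a fraction ``x_true`` of 3PG comes from rubisco,
    and a fraction ``d`` of those molecules carry a CO2-derived carboxyl
    carbon that is 12C with probability ``c`` (ambient CO2).  Serine
    inherits 3PG's carbons; its isotopologue counts are multinomial at depth
    ``counts_per_replicate`` and the M+2 subpopulation is split into MRM
    fragment channels by the 13C/12C state of the carboxyl carbon.
    """

    x_true: float = 0.14
    purity: float = 0.99
    c: float = 0.989
    d: float = 0.5
    n_replicates: int = 4
    counts_per_replicate: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("x_true", "purity", "c", "d"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_replicates < 1 or self.counts_per_replicate < 1:
            raise ValueError("n_replicates and counts_per_replicate must be >= 1")

    @property
    def background_b(self) -> float:
        return 1.0 - self.purity


def _isotopologue_probs(p12_per_position) -> np.ndarray:
    """P(M+0..M+N) for independent positions with given 12C probabilities."""
    probs = np.array([1.0])
    for p12 in p12_per_position:
        probs = np.convolve(probs, [p12, 1.0 - p12])  # [12C, 13C] per position
    return probs


def _simulate_arm(
    spec: LabelingSimSpec, role: str, x: float, rng: np.random.Generator
) -> list[LabelingExperiment]:
    b = spec.background_b
    p_cbx = b + x * spec.d * (spec.c - b)  # carboxyl 12C probability
    serine_p12 = [p_cbx, b, b]  # carboxyl first, then C2/C3
    serine_probs = _isotopologue_probs(serine_p12)
    glycine_probs = _isotopologue_probs([b, b])
    # MRM channels partition the serine M+2 population
    p_m2_cbx13 = (1.0 - p_cbx) * 2.0 * b * (1.0 - b)
    p_m2_cbx12 = p_cbx * (1.0 - b) ** 2
    p_m2 = serine_probs[2]
    out = []
    prefix = "exp" if role == "experiment" else "ctrl"
    for i in range(spec.n_replicates):
        counts = rng.multinomial(spec.counts_per_replicate, serine_probs)
        gly_counts = rng.multinomial(spec.counts_per_replicate, glycine_probs)
        n_m2 = int(counts[2])
        mrm = None
        if n_m2 > 0 and p_m2 > 0:
            a = int(rng.binomial(n_m2, p_m2_cbx13 / p_m2))
            mrm = MrmPair(peak_61_1=float(a), peak_62_1=float(n_m2 - a))
        out.append(
            LabelingExperiment(
                role=role,
                replicate=f"{prefix}_{i + 1}",
                distributions=(
                    IsotopologueDistribution(
                        "serine", tuple(counts / counts.sum())
                    ),
                    IsotopologueDistribution(
                        "glycine", tuple(gly_counts / gly_counts.sum())
                    ),
                ),
                mrm=mrm,
            )
        )
    return out


def simulate_labeling(
    spec: LabelingSimSpec = LabelingSimSpec(),
) -> tuple[list[LabelingExperiment], list[LabelingExperiment]]:
    """Generate (experiment, control) replicate tables; control has x = 0."""
    rng = np.random.default_rng(spec.seed)
    experiment = _simulate_arm(spec, "experiment", spec.x_true, rng)
    control = _simulate_arm(spec, "control", 0.0, rng)
    return experiment, control


# ---------------------------------------------------------------------------
# Growth-curve simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSimSpec:
    """Logistic replicate growth curves with a configured endpoint effect.

    Both arms share the logistic shape (rate ``growth_rate`` per hour,
    midpoint ``t_mid`` hours); the experiment arm's carrying capacity is
    raised so the arm difference at ``t_eval`` equals ``effect`` exactly in
    the noise-free limit.  Gaussian noise (sd ``noise_sd`` OD units) is
    added per sample and truncated at zero.
    """

    effect: float = 0.6
    noise_sd: float = 0.02
    n_replicates: int = 3
    t_eval: float = 80.0
    times: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(t) for t in range(0, 101, 2))
    )
    baseline_od: float = 0.005
    control_capacity: float = 0.10
    growth_rate: float = 0.15
    t_mid: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not self.times or any(
            t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])
        ):
            raise ValueError("times must be nonempty and strictly increasing")
        if not self.times[0] <= self.t_eval <= self.times[-1]:
            raise ValueError("t_eval must lie within the time grid")


def _logistic_saturation(spec: GrowthSimSpec, t: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-spec.growth_rate * (t - spec.t_mid)))


def simulate_growth_curves(
    spec: GrowthSimSpec = GrowthSimSpec(),
) -> tuple[list[GrowthCurve], list[GrowthCurve]]:
    """Generate (experiment, control) replicate curves."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.times)
    sat = _logistic_saturation(spec, t)
    sat_eval = float(_logistic_saturation(spec, np.asarray([spec.t_eval]))[0])
    ctrl_mean = spec.baseline_od + spec.control_capacity * sat
    # capacity gap chosen so the arm difference at t_eval is exactly `effect`
    exp_mean = ctrl_mean + (spec.effect / sat_eval) * sat
    out: dict[str, list[GrowthCurve]] = {"experiment": [], "control": []}
    for arm, mean in (("experiment", exp_mean), ("control", ctrl_mean)):
        prefix = "exp" if arm == "experiment" else "ctrl"
        for i in range(spec.n_replicates):
            noise = (
                rng.normal(0.0, spec.noise_sd, size=t.size)
                if spec.noise_sd > 0
                else np.zeros(t.size)
            )
            od = np.clip(mean + noise, 0.0, None)
            out[arm].append(
                GrowthCurve(
                    arm=arm,
                    replicate=f"{prefix}_{i + 1}",
                    times=tuple(t),
                    od600=tuple(od),
                )
            )
    return out["experiment"], out["control"]
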