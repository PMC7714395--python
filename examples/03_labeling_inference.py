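"""Infer rubisco's contribution to 3PG synthesis from 13C labeling.

Simulates a labeling experiment (99% 13C glycerol feed, ambient 12CO2, true
rubisco fraction 14%) for four biological replicates of an experiment strain
and a rubisco-independent control, then inverts the mixture model two ways:
from total serine 12C content and from the serine M+2 MRM fragment channels
that isolate the carboxyl carbon.
"""

from rubiscoflux import (
    LabelingSimSpec,
    MixtureParams,
    estimate_rubisco_fraction,
    simulate_labeling,
    total_12c_fraction,
)

spec = LabelingSimSpec(x_true=0.14, purity=0.99, n_replicates=4,
                       counts_per_replicate=100_000, seed=42)
experiment, control = simulate_labeling(spec)

f12_exp = sum(total_12c_fraction(r.distribution("serine"))
              for r in experiment) / len(experiment)
f12_ctrl = sum(total_12c_fraction(r.distribution("serine"))
               for r in control) / len(control)
print(f"serine 12C fraction: experiment {f12_exp:.4f}, control {f12_ctrl:.4f} "
      f"({f12_exp / f12_ctrl:.1f}-fold enrichment)")
print("excess 12C in the experiment arm can only have entered from ambient")
print("CO2 via rubisco, because the feedstock is 99% 13C.")

for mode in ("total_serine", "carboxyl_mrm"):
    est = estimate_rubisco_fraction(experiment, control,
                                    MixtureParams(mode=mode))
    reps = ", ".join(f"{x:.3f}" for x in est.per_replicate)
    print(f"\n{mode} mode: per-replicate x = [{reps}]")
    print(f"  mean {est.mean:.3f}, min {est.min:.3f} "
          f"(true value {spec.x_true}) — the fraction of 3PG production "
          "attributed to rubisco")
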