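"""Design a rubisco-dependent knockout strain on the toy glycerol network.

Builds the built-in toy model, screens all knockout sets of size <= 2 among
its internal sugar-phosphate reactions, and reports which deletions make
growth depend on the Prk + rubisco detour, how tightly rubisco flux is then
coupled to biomass, and rubisco's predicted share of 3PG production.
"""

from rubiscoflux import (
    ToyNetworkSpec,
    apply_knockouts,
    make_toy_model,
    predicted_rubisco_3pg_fraction,
    scan_knockouts,
    toy_heterologous_spec,
)
from rubiscoflux.model import set_carbon_source
from rubiscoflux.design import add_heterologous

het = toy_heterologous_spec()
host = make_toy_model(ToyNetworkSpec(include_heterologous=False))

candidates = ["T3_f6p_synthesis", "T4_nonox_ppp", "T5_rpi"]
hits = scan_knockouts(host, het, sources=["EX_glyc"],
                      candidate_rxns=candidates, max_size=2)

print(f"screened all size-1/2 subsets of {candidates} on glycerol")
print(f"rubisco-dependent designs found: {len(hits)}")
for cand in hits:
    slope = cand.slopes["EX_glyc"]
    print(f"  delete {cand.deleted}: growth without detour "
          f"{cand.growth_without_het:.2f}, with detour "
          f"{cand.growth_with_het:.2f} mmol/gDW/h")
    print(f"  coupling slope {slope.slope:.2f} (min rubisco flux per unit "
          f"biomass), intercept {slope.intercept:.2f}")

# rubisco's predicted share of 3PG production in the winning design
design, _ = add_heterologous(host, het)
design = apply_knockouts(set_carbon_source(design, "EX_glyc", 10.0),
                         hits[0].deleted)
point, (lo, hi) = predicted_rubisco_3pg_fraction(design, het)
print(f"FBA-predicted rubisco share of 3PG production: {point:.1f}% "
      f"(FVA range {lo:.1f}-{hi:.1f}%)")
print("a collapsed range means rubisco flux is fully pinned by growth —")
print("the knockout makes rubisco activity strictly required, which is the")
print("design goal for a selection strain.")
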