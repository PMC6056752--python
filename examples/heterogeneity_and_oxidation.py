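"""N-terminal heterogeneity content and cysteine-oxidation ratios.

Simulates the two ratio experiments and evaluates them:

* the three reported N-terminal start variants of an Abatacept-like
  product, quantified through their common y4 fragment and expressed as
  percent of the most abundant variant plus share of the variant total;
* the reduced-monomer / disulfide-dimer balance of the VFCTK signature
  peptide across buffer conditions, each species as percent of its
  reference condition (control monomer = 100; fully oxidized dimer =
  100).  "N.D." marks species below the detection threshold.
"""

from mrmquant import heterogeneity_content, oxidation_ratio
from mrmquant.simulate import SimulationConfig, simulate_heterogeneity, simulate_oxidation

config = SimulationConfig(seed=1)

print("N-terminal variant content (common y4 quantifier):")
for v in heterogeneity_content(simulate_heterogeneity(config)):
    pct = "N.D." if v.percent_of_max is None else f"{v.percent_of_max:g}"
    share = "N.D." if v.share_pct is None else f"{v.share_pct:g}%"
    print(f"  {v.label:<18} percent-of-max {pct:>6}   share {share:>7}")

print("\nVFCTK oxidation state (percent of reference condition):")
conditions = simulate_oxidation(config)
for r in oxidation_ratio(conditions, monomer_reference="control", dimer_reference="H2O2"):
    mono = "N.D." if r.monomer_pct is None else f"{r.monomer_pct:g}"
    dimer = "N.D." if r.dimer_pct is None else f"{r.dimer_pct:g}"
    print(f"  {r.condition:<16} monomer {mono:>7}   dimer {dimer:>7}")
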