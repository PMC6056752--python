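"""Compute MRM transitions for the two signature peptides.

Builds the y-series transition table for VFCTK (doubly charged
precursor) and MHVAQPAVVLASSR (triply charged), prints the quantifier
and qualifier m/z pairs, the disulfide-bridged VFCTK homodimer species
used to monitor cysteine oxidation, and shows how an instrument-nominal
Q1/Q3 pair maps back to a computed ion with its deviation.
"""

from mrmquant import build_transition_table, disulfide_dimer_species, match_transition
from mrmquant._rounding import round_half_away

for peptide, z in (("VFCTK", 2), ("MHVAQPAVVLASSR", 3)):
    table = build_transition_table(peptide, precursor_charges=(z,))
    print(f"\n{peptide} [M+{z}H]{z}+ = {round_half_away(table[0].precursor_mz, 1)}")
    for t in table[:3]:
        print(
            f"  {round_half_away(t.precursor_mz, 1):>6} -> "
            f"{round_half_away(t.fragment_mz, 1):>6} "
            f"(y{t.fragment_index}+)  {t.role}"
        )

dimer_mass, dimer_mz3, dehydro_y4 = disulfide_dimer_species("VFCTK")
print(
    f"\nVFCTK oxidized dimer: mass {dimer_mass:.3f} Da, "
    f"[M+3H]3+ {dimer_mz3:.2f}, dehydro-y4+ {dehydro_y4:.2f}"
)
# an instrument-tuned Q3 value (247.9) still maps onto the computed y2 ion
table = build_transition_table("VFCTK", precursor_charges=(2,))
match = match_transition(299.3, 247.9, table)
print(
    f"observed 299.3->247.9 matches y{match.transition.fragment_index}+ "
    f"(computed {match.transition.fragment_mz:.2f}, dQ3 {match.delta_q3:+.2f})"
)
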