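"""Screen tryptic peptides of two Fc-fusion constructs as signature candidates.

Digests the bundled synthetic Etanercept-like and Abatacept-like toy
sequences, screens every peptide against the selection rules (8-15
residues, no cysteine, no missed cleavage, away from disulfides, unique
vs the Fc/IgG background, not protein-terminal), and prints the ranked
candidate lists.  The violation column shows why each peptide is or is
not usable — for these constructs, as for real Fc-fusion drugs, no
peptide is violation-free, so the least-bad candidates top the list.
"""

from mrmquant import background_peptide_set, fc_background, select_candidates
from mrmquant.data import ABATACEPT_TOY, BACKGROUND_IGG_TOY, ETANERCEPT_TOY

background = background_peptide_set(
    fc_background([ETANERCEPT_TOY, ABATACEPT_TOY]) + [BACKGROUND_IGG_TOY]
)

for protein in (ETANERCEPT_TOY, ABATACEPT_TOY):
    print(f"\n{protein.id} ({protein.name}):")
    print(f"{'rank':>4}  {'peptide':<28} {'aa':>9}  violations")
    for report in select_candidates(protein, background=background)[:6]:
        p = report.peptide
        print(
            f"{report.rank:>4}  {p.sequence:<28} {p.start:>4}-{p.end:<4} "
            f"{'; '.join(report.violations) or '(none)'}"
        )
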