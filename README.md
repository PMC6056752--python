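# mrmquant

Tools for developing and validating LC-MS (MRM) bioanalytical assays of
therapeutic proteins — in particular Fc-fusion biopharmaceuticals such as
Etanercept (TNFR2–Fc) and Abatacept (CTLA-4–Fc) quantified in serum via a
tryptic *signature peptide*.

Quantifying an intact protein drug by LC-MS means choosing one tryptic
peptide to stand in for it, monitoring one precursor → fragment (Q1 → Q3)
transition of that peptide on a triple-quadrupole instrument, normalizing
each peak area to a co-injected internal-standard peptide (ISTD), and
demonstrating — against regulatory guideline criteria — that the resulting
calibration quantifies accurately and precisely. `mrmquant` covers each
computational step of that workflow:

- **`mrmquant.proteins`** — annotated therapeutic sequences and in-silico
  tryptic digestion (cleave after K/R except before P, configurable missed
  cleavages), including enumeration of reported N-terminal start variants.
- **`mrmquant.selection`** — signature-peptide screening: 8–15 residues, no
  cysteine, no missed cleavage, not near a disulfide bridge, unique versus a
  background peptide set (I/L collapsed, since MRM cannot distinguish them),
  not protein-terminal. Peptides are never dropped; each is reported with
  its explicit violation list and rank, because for Fc-fusion proteins the
  best available candidate often violates something.
- **`mrmquant.masses`** — exact monoisotopic arithmetic: peptide masses,
  `[M+zH]z+` precursors, b/y fragment series, disulfide-bridged homodimer
  species, transition-table construction and observed-pair matching.
- **`mrmquant.quant`** — ISTD normalization, weighted linear calibration
  (`1/x²` default) with per-level back-calculated accuracy, inverse
  prediction with range flags, N-terminal heterogeneity content and
  monomer/dimer oxidation ratios (not-detected ≠ zero).
- **`mrmquant.validation`** — run/pooled mean, SD (n−1), CV% = 100·SD/mean,
  accuracy% = 100·mean/nominal per QC level, with guideline acceptance:
  accuracy within ±15% and CV ≤ 15% (both 20% at the LLOQ), the
  75%-of-calibrators rule, and blank selectivity.
- **`mrmquant.simulate`** — a seeded synthetic peak-area generator
  (lognormal multiplicative noise at stated CVs) reproducing a full study
  design: 10-point 2-fold calibration from 100 μg/mL, QC levels at
  0.195/0.586/9.38/80.0 μg/mL × 3 runs × 5 replicates, variant mixtures,
  oxidation conditions.

A thin CLI (`mrmquant digest|select|transitions|simulate|quantify|validate`)
wraps the library for shell use; `examples/` holds one narrative script per
capability.

## Worked example

```bash
python examples/design_transitions.py
```

```
VFCTK [M+2H]2+ = 299.2
   299.2 ->  498.2 (y4+)  quantitation
   299.2 ->  351.2 (y3+)  structure
   299.2 ->  248.2 (y2+)  structure
...
VFCTK oxidized dimer: mass 1190.583 Da, [M+3H]3+ 397.87, dehydro-y4+ 497.23
observed 299.3->247.9 matches y2+ (computed 248.16, dQ3 -0.26)
```

The doubly protonated VFCTK precursor (m/z 299.2) fragments into the y4/y3
quantifier and qualifier ions used for Etanercept quantitation; the
disulfide-bridged VFCTK homodimer (two monomers minus two hydrogens) is the
species monitored to assess cysteine oxidation. All values are computed
monoisotopic m/z — when an instrument-tuned table value differs (247.9
versus computed 248.16), the matcher reports the deviation rather than
adopting the printed number.

```bash
python examples/run_validation_study.py
```

```
calibration: slope 0.01974, intercept 0.00022, range 0.195-100 ug/mL
...
pooled  LLOQ     0.195   0.189  0.0191   10.1   96.7  pass
pooled  LQC      0.586   0.571  0.0338   5.92   97.5  pass
pooled  MQC       9.38    9.31   0.441   4.74   99.2  pass
pooled  HQC       80.0    81.1    3.35   4.13  101.0  pass

calibration pass: True, selectivity pass: True, overall: True
```

Each pooled row is the mean/SD/CV%/accuracy% of 15 back-calculated QC
replicates at that level; every level meets the 15/20% guideline rule, the
calibration back-calculates within tolerance at ≥ 75% of its 10 levels, and
blank responses stay below the selectivity limits, so the simulated study
passes overall.

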