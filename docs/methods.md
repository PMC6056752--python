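# Methods

## Digestion model

Trypsin specificity is the standard rule: cleave C-terminal to K or R
unless the next residue is P. Peptides are enumerated for 0..`max_missed`
missed cleavages (`max_missed` defaults to 2 for digestion so that
missed-cleavage context around heterogeneous termini is visible; the
selection screen uses 0 unless the missed-cleavage criterion is disabled).
Coordinates are 1-based inclusive, the convention of assay documentation
("aa. 42-46"); a converter to 0-based half-open spans is provided at the
I/O boundary. At 0 missed cleavages the peptides partition the parent
exactly — this, superset monotonicity in `max_missed`, and equality with an
exhaustive substring-enumeration oracle are property-tested.

`min_cys_distance` is the primary-sequence residue distance from a peptide
to the nearest *annotated* disulfide cysteine (0 if the peptide spans one).
Structural (3-D) proximity is deliberately out of scope. A parent with no
annotated cysteines assigns every peptide a distance equal to the sequence
length, i.e. "far".

N-terminal start variants are declared as (label, prefix) pairs; the
variant sequence is the prefix prepended to the parent, and the variant's
first tryptic peptide is returned. A prefix that itself ends in a cleavage
site therefore shortens the first peptide, which is the correct chemistry.

## Selection rules

The screen encodes the community criteria for surrogate peptides: length
8–15, cysteine-free, no missed cleavage, not near a disulfide bridge, not
protein-terminal (terminal ragging creates quantitation bias), and unique
against a background peptide set. Design choices:

- **Uniqueness replaces CDR-specificity.** Fc-fusion proteins have no CDR;
  specificity is operationalized as absence from the exact tryptic peptide
  set of the background (by default the Fc/framework portions at/after each
  protein's fusion junction, plus any user-supplied endogenous IgG
  sequences). I and L are collapsed before comparison because their
  residues are isobaric and indistinguishable by MRM; without the collapse
  an I/L twin would count as falsely unique.
- **Disulfide vicinity window.** No community-standard numeric definition
  of "near a disulfide" exists; the default window is 3 residues
  (primary-sequence distance) and is exposed in configuration and CLI help.
- **Nothing is dropped.** Every peptide is reported with its violation
  list; an all-violating list is a meaningful result — it is precisely the
  situation Fc-fusion assays find themselves in, where the least-bad
  candidate (a cysteine-containing or N-terminal peptide) must be chosen
  deliberately. Ranking is fewest violations, then longer peptides, then
  N-to-C position; the tie-break order is a package convention.
- Relaxing any single criterion never shrinks the violation-free set
  (property-tested monotonicity).

## Mass arithmetic

Monoisotopic residue masses (standard 20-residue table), water 18.010565
Da, proton 1.007276 Da, neutral hydrogen 1.007825 Da. Peptide mass = sum of
residues + water; `[M+zH]z+` = (M + z·proton)/z; b_i = (first i residues +
z·proton)/z; y_i = (last i residues + water + z·proton)/z. The b/y
complementarity identity (b_i + y_{n−i} = M + 2·proton for singly charged
fragments) is property-tested, and all masses are cross-checked against
pyteomics as an independent oracle in the test suite only.

Disulfide-bridged homodimer of a single-cysteine peptide: 2·M − 2·H
(bridge formation loses two hydrogens); a fragment released by disulfide
cleavage keeps the dehydro form and is one hydrogen atom lighter than its
reduced counterpart. No other modifications are modeled — assays run under
TCEP without alkylation, so there is no carbamidomethyl-cysteine.

Reported precision follows assay-documentation practice: m/z rounded
half-away-from-zero to 1 decimal in transition tables and 2 decimals for
calibration standards. The package always reports *computed* monoisotopic
values; instrument method tables often carry machine-tuned nominal values
(e.g. a y2 stored as 247.9 where the monoisotopic value is 248.16), so
`match_transition` maps an observed Q1/Q3 pair to the nearest computed
transition (Chebyshev distance, 0.5 Th default tolerance, deterministic
tie-breaks) and reports the deviation instead of treating either number as
wrong.

## Quantitation

Normalized response = analyte area / ISTD area from the same injection; a
non-positive ISTD area means a failed injection and is an error, not a
zero. Calibration is weighted least squares of response on concentration.
The default weighting is 1/x², the standard choice for bioanalytical
calibrations spanning ~3 orders of magnitude where variance grows with
signal; `none` and `1/x` are available. At least 6 distinct levels are
required. Blanks and zeros never enter the fit. Back-calculated accuracy is
evaluated per level (replicates averaged); levels outside ±15% (±20% at
the lowest level) are flagged and excluded from the usable range.
Inverse-predicted concentrations below zero clamp to 0 with a flag so
validation tables can still aggregate; out-of-range values are flagged,
not rejected.

Heterogeneity content expresses each N-terminal variant (quantified
through the common y4 fragment, so one response factor is shared) on two
scales: percent of the most abundant variant (max = 100) and share of the
variant total (sums to 100). Oxidation ratios express monomer and dimer
responses as percent of their respective reference conditions. In both,
a species below the detection threshold is carried as `None`/"N.D.",
never as 0.0 — an undetected dimer is information, a zero is a claim.
Ratios are reported to 3 significant figures.

## Validation statistics

Per run and pooled, per QC level: arithmetic mean, SD with the n−1
denominator, CV% = 100·SD/mean (not computable at zero mean), accuracy% =
100·mean/nominal. Pooled cells are recomputed from all individual
replicate values rather than assembled from run summaries — pooling
printed run statistics cannot reproduce replicate-level pooled SD, so the
package never emulates that shortcut. Reported cells round
half-away-from-zero to 3 significant figures; verdicts are evaluated on
unrounded values.

Guideline acceptance uses the low-molecular-weight-drug criteria:
per-level accuracy within ±15% of nominal and CV ≤ 15%, both relaxed to
20% at the LLOQ; calibration passes when at least 6 levels and at least
75% of levels back-calculate within the same tolerances; selectivity
passes when mean blank analyte response ≤ 20% of the mean LLOQ response
and blank ISTD-channel response ≤ 5% of the ISTD reference. All thresholds
are inclusive at the boundary and configurable. The overall verdict is
evaluated on the pooled per-level statistics together with the calibration
rule; per-run cells carry informational verdicts only, a deliberate choice
documented here because guidelines are ambiguous about run-versus-pooled
evaluation.

## Synthetic data

The generator emulates instrument output at the peak-area level only —
integration, chromatography and ionization physics are out of scope. Model:
`analyte_area = istd_area × (slope·c + intercept) × ε` with ε lognormal,
unit mean, parameterized by CV (lognormal keeps areas positive and makes
CV the natural noise unit; Gaussian noise would allow negative areas at
the LLOQ). ISTD areas are themselves lognormal around 1×10⁵ (CV 5%).
Blanks draw both channels from a small uniform background; zeros carry
ISTD but background analyte.

Default study design: 10-point 2-fold calibration from 100 μg/mL (lowest
level 100/2⁹ = 0.195 μg/mL), QC levels 0.195/0.586/9.38/80.0 μg/mL, 3 runs
× 5 replicates. Default per-measurement CVs: calibrators 12% at the lowest
level, 8% at the second, 5% above (signal-proportional noise dominates
near the LLOQ); QC levels 10/8/6/5% from LLOQ to HQC — magnitudes matching
routinely observed serum-assay run CVs (roughly 3–11%). True curve slope
0.02 with zero intercept is arbitrary; only recovery is asserted, never
the absolute value. Heterogeneity true shares default to 0.705/0.261/0.034
and oxidation monomer fractions to 1.0/0.00255/0.956/0.816 across the four
conditions, the regimes the ratio analyses are designed to resolve.

Every generator is a pure function of its configuration; identical
configurations give byte-identical CSV output, tested as such.

What passing tests on this generator shows — and does not: the pipeline
arithmetic is correct, unbiased under the assumed noise model, and the
study design passes guideline criteria with ≥ 95% probability over a
pinned 200-seed battery. It does not show robustness to matrix effects,
carryover, drift, peak-integration error or interferences, none of which
the noise model contains; those remain instrument-side concerns.

## Problem sizes and numerics

Statistical tests use: 1000 random peptides for the b/y complementarity
battery, 1000 seeds for calibration slope recovery (zero-noise relative
bias < 1%, noisy mean within 3 Monte-Carlo standard errors), 300 seeds for
accuracy-centering, and a pinned 200-seed end-to-end battery — sizes at
which the Monte-Carlo standard errors are comfortably below the asserted
tolerances. WLS fitting is delegated to statsmodels; ties and boundaries
are resolved as documented above (inclusive thresholds, half-away-from-zero
rounding, Chebyshev-then-combined-deviation-then-index transition
tie-break).

## Known limitations

- Only b/y singly-to-multiply protonated fragments and the disulfide
  dimer/dehydro species are modeled; no neutral losses, internal fragments
  or isotope envelopes.
- Collision energies, voltages and retention times are opaque metadata.
- The bundled full-length sequences are synthetic demonstration
  constructs, not the licensed products' sequences; real assay development
  should load the authentic sequences via FASTA + annotation sidecar.
- Linear calibration only; 4PL/quadratic models are out of scope.
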