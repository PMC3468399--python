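# Methods

## Model and assumptions

`protpair` addresses two-class case/control discrimination from label-free
peptide peak areas. Its unit of analysis is the within-sample intensity
ratio of a peptide pair, R_ijk = I_ik / I_jk. Because both intensities come
from the same LC-MS run, any common per-run scale factor (injection amount,
ionisation efficiency drift, detector gain) cancels; this is why the
pipeline deliberately applies **no normalisation** to the raw peak areas.
The implicit assumptions are: (i) within one sample the two peptides share
the run-level scale factor; (ii) class information, if present, shifts the
location of the ratio distribution between classes; (iii) technical
replicates of a patient are exchangeable with each other but not across
patients.

The Discriminability Index (DI) of a pair is

    d_ij = (median(R^C) − median(R^P)) / (sd(R^C) · sd(R^P)),

a separation-over-spread score in the tradition of detection-theoretic
d′-type indices: the median gives an outlier-robust location, and the
*product* of the class standard deviations penalises spread in either
class. The median of an even-length vector is the mean of the two central
order statistics; the standard deviation uses divisor n−1 by default
(`sd_mode="sample"`, the conventional choice at the small per-class n this
method targets; `"population"` gives divisor n).

### Log-ratio evaluation (default) and the raw-ratio mode

Applied to raw ratios the DI is dimensionally inhomogeneous: it carries
units of 1/ratio. For a pair whose ratios sit around scale c, the numerator
grows like c but the denominator like c², so |d| ∝ 1/c. Across a table
whose peptides span several orders of magnitude of abundance — the normal
situation in plasma proteomics — the ranking would then be dominated by
arbitrary abundance offsets and by the arbitrary orientation chosen for
each pair, not by discrimination. We therefore evaluate the statistic on
the natural log of the ratios by default (`ratio_scale="log"`): the index
becomes scale-free, the two orientations of a pair are exact negatives, and
empirically the ranked scores decay gently over the list instead of
spanning orders of magnitude. The literal raw-ratio form is retained as
`ratio_scale="raw"` for completeness; all symmetry properties asserted by
the test suite hold in both modes.

### Missing and nonpositive values

Peak integration can yield zero or absent areas; ratios are undefined
there. A sample contributes a ratio only when both peptides are strictly
positive in it; a pair needs at least two usable samples in *each* class to
be scored, and pairs whose ratio vector is constant in either class (zero
SD) are excluded with reason "degenerate-spread" rather than being assigned
an infinite score — at per-class n of order 10, ties in peak areas do occur
and infinities would dominate the ranking meaninglessly. No imputation is
performed anywhere.

## Peptide-to-protein rollup

Proteins are admitted only with ≥ 2 mapped peptides present in the table
(`min_peptides`, the usual two-peptide identification-confidence rule).
For a protein pair, D is the **median of the signed d** over all
cross-protein peptide pairs, orientation-harmonised so that every
contribution is expressed as protein_1 relative to protein_2
(protein_1 = lexicographically smaller id; in log mode the orientation flip
is an exact sign flip). Using signed values means mixed directions cancel:
a high |D| operationalises "consistent direction of change across all
constituent peptide pairs". The reported `direction_consistency` (fraction
of contributing d sharing D's sign) is a diagnostic, not a filter.
Intra-protein peptide pairs never contribute. Ranking is by |D| with
deterministic tie-breaks (more supporting peptide pairs first, then
lexicographic ids); the `up_in_P` column names the member whose relative
abundance is higher in progressors, while the signed D and canonical
orientation are retained.

## Permutation significance

Class labels are permuted at the **patient** level (both technical
replicates move together, preserving the patient counts per class), because
replicates are not exchangeable across patients; a sample-level mode exists
behind `permute_unit="sample"`. Each permutation reruns the entire scan —
the usable-pair universe is re-derived, since exclusion rules can differ —
and, at protein level, the rollup. Pooled absolute null scores give the
empirical p-value of a score T as the plain exceedance fraction (no
pseudocount). The empirical FDR at T is S_null/S_true, where S_true counts
observed scores ≥ T and S_null counts null exceedances divided by the
number of permutations — the "equal totals" rescaling of the null to the
observed-set size. FDR is capped at 1 for reporting. Default n_perm = 100,
configurable.

For the *top* score specifically, the pooled-null p-value is biased small
by construction (a maximum compared against a null of all pairs).
`top_score_pvalue` therefore also compares the observed top |D| against the
per-permutation *maximum* null score; under exchangeability this
family-wise p is uniform on {0, 1/n_perm, …, 1}, and the test suite
verifies that calibration on no-signal cohorts.

## Classifier and cross-validation

The classifier has exactly one tunable parameter: a threshold t on the
abundance ratio of one representative peptide pair from the top-ranked
protein pair. The representative pair is the constituent pair with maximal
|d| (default `cv_rule="top-peptide"`); `cv_rule="vote"` instead fits one
threshold per constituent pair and takes a majority vote (ties predict C).
The side of t that predicts P is fixed by which side holds the P-class
median ratio; t itself maximises training accuracy over midpoints of
adjacent sorted training ratios, with accuracy ties broken toward the
maximal-margin midpoint. A test ratio exactly equal to t is assigned to C.

Generalisation is estimated by leave-one-**patient**-out cross-validation:
each fold removes all measurements of one patient, refits everything —
protein-pair ranking, representative-pair choice, threshold — on the
remaining patients only, and predicts each held-out replicate
independently. Missing intensities at prediction time yield an abstention,
counted as an error (conservative; keeps N fixed at the full sample
count). The reported rate is 1 − e/N. Folds whose training data would be
single-class are skipped with a warning and excluded from N.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, on the
natural-log scale: protein base abundances ~ N(13.8, 2.3) (≈ 10⁶ peak-area
units, ~4 orders of magnitude across proteins); fixed per-peptide response
factors ~ N(0, 1.0) (digestion/ionisation efficiency); patient-level
biological noise sd 0.4 (~40% between-patient CV); replicate-level
technical noise sd 0.15 (~15% CV); 5% of measurements missing completely
at random. The default design is 8 control and 13 progressor patients with
2 technical replicates (42 samples), 50 proteins with 2–4 peptides each,
and one planted pair perturbed anti-correlated (+1.0 / −1.0 log-units in
progressors), mimicking an acute-phase-response pattern where one protein
rises as its partner falls.

What it does *not* emulate: intensity-dependent (censoring-type)
missingness, correlated noise across proteins (shared pathways), peptide
misidentification, retention-time alignment artefacts, or heavier-than-
lognormal tails. Passing the synthetic recovery tests therefore shows the
pipeline finds consistently co-dysregulated pairs under clean multiplicative
noise, not that it is robust to those real-data complications.

A property worth knowing when interpreting recovery experiments: when a
planted pair has a strong effect, *both* its members individually
discriminate, so every pairing of a planted protein with a null protein
carries roughly half the planted numerator. At cohort sizes of 8/13
patients the product-of-SDs denominator is estimated with few effective
degrees of freedom (patient-level noise is shared by replicates), and the
ranking *among* these signal-bearing pairs fluctuates accordingly: the
top-ranked pair virtually always involves a planted protein, while the
exact planted pair is top-1 only in a minority of runs at ±1.0 log-effect
under the default noise. This is a small-sample property of the
product-denominator index itself, and it is measured (not hidden) by the
validation suite.

## Validation problem sizes

The exhaustive-scan implementation is verified pair-for-pair (exact
equality, both ratio scales) against a literal double-loop reference on
200 random tables of ≤ 20 peptides × ≤ 10 samples with missing and zero
entries. Symmetry tests assert per-sample rescale invariance and class-swap
antisymmetry numerically. Monte-Carlo experiments use 50 seeds of the
default cohort for recovery and top-p calibration (n_perm = 20 per seed)
and 12 no-signal cohorts for p < 0.05 calibration; cross-validation
monotonicity uses 5 seeds at 3 effect levels. These sizes keep each
experiment in the seconds-to-minutes range while leaving binomial error
well below the asserted margins.

## Known limitations

- The raw-ratio DI is not comparable across pairs of different abundance
  scale; the log default removes this, but published raw-mode scores can
  only be compared within a pair.
- The empirical p-value has resolution 1/(n_perm · n_pairs) and is 0 when
  the observed score exceeds every null score; no pseudocount is added.
- One peptide maps to one protein; shared-peptide ambiguity must be
  resolved upstream.
- The classifier uses a single pair and a single threshold by design;
  multi-pair decision rules are out of scope.
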