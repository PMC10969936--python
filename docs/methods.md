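# Methods

## Data model and the bundled tables

The analysis operates on compound × group quantification tables: each
compound carries, per sample group, a mean concentration, a standard
deviation, a replicate count (3 throughout the reference dataset) and a
detection flag. "n.d." (not detected) is encoded as `detected=False` with
no mean/sd. Two conventions follow from that encoding, chosen so that the
bundled tables reproduce both the published per-grade totals and the
published Venn counts: for sums, totals and simulated replicate matrices an
undetected cell contributes exactly 0; for detection-set (Venn) analysis it
is absence. Volatile concentrations are μg/kg; non-volatiles mg/g (bulk
assays such as water extract in %), with a unit field on every record.

The package ships transcriptions of the reference study's tables as CSV
fixtures: 112 volatiles (retention times, calculated/literature retention
indices, per-grade mean ± sd with Duncan letters, odor thresholds in water,
VIP scores, ANOVA p-values) and 49 non-volatile rows of which 5 are
aggregates (total catechins, ester catechins, non-galloylated catechins,
total free amino acids, total flavones and flavonol glycosides) flagged
`derived=true` and excluded from marker screening, leaving the 44
individual non-volatile compounds. Compound identity is the source table's
row number; CAS strings are carried through verbatim for joining external
tables.

Chemical categories (ketone, aldehyde, alcohol, hydrocarbon, ester,
phenolic, methoxy-phenolic, lactone) are a curated annotation file: the
source table prints only the per-category tallies (29/26/22/17/8/4/4/2),
so each compound was classified by its chemistry under two constraints from
the source text: 4-ethyl-2-methoxyphenol counts among the four phenolics
(the four methoxy-phenolics being 1,2-dimethoxybenzene,
3,4-dimethoxytoluene, 1,2,3-trimethoxybenzene and
4-ethyl-1,2-dimethoxybenzene), and the terpenoid ethers theaspirane and
caryophyllene oxide are tallied with the hydrocarbons — the only
assignment consistent with the printed totals.

## Retention indices and semi-quantification

Kovats RI interpolates linearly in retention time between consecutive
n-alkanes: RI = 100n + 100(RT_x − RT_n)/(RT_{n+1} − RT_n). The alkane with
k carbons maps to exactly 100k, the index is invariant under affine
re-timing of the chromatogram, and no extrapolation is performed by default
(the formula is only defined for bracketed analytes; linear extrapolation
is opt-in). Internal-standard quantification is deliberately
semi-quantitative: concentration = (area/IS area)·(IS μg)/(sample kg) with
a response factor fixed at 1.0 and configurable — the reference study
names neither the IS amount nor per-compound response factors, so these
live in configuration (`QuantSpec`), and the IS is treated as an opaque
reference peak.

## Odor activity values

OAV = per-group mean concentration / odor threshold in water (both μg/kg).
OAVs are computed from group means — replicate-level OAVs are not defined,
matching how such tables are published. An OAV is undefined (NaN) when the
compound is undetected or no threshold exists; undefined OAVs are excluded
from, not failed by, OAV > 1 filters, so compounds without thresholds
(notably three of the four methoxy-phenolics) pass through the statistical
screen but cannot be called odor-active. Displayed OAVs are rounded to 2
decimals; comparisons always use unrounded values. When validating against
the published OAV column, the tolerance propagates the ±0.005 rounding of
*both* printed inputs through the division, (0.005 + OAV·0.005)/threshold
+ 0.005: for sub-μg/kg thresholds the printed OAVs visibly reflect
unrounded source values (e.g. a printed 0.59 threshold that behaves as
0.587), so a flat absolute tolerance would be wrong in both directions.

## ANOVA and Duncan's multiple range test

The one-way decomposition depends on the data only through per-group
(mean, sd, n), so the summary route and the replicate route are
algebraically identical — tested as an exact identity. F = (SSB/(k−1)) /
MSE with MSE the pooled within-group variance; p from the upper tail of
the F distribution. Degenerate inputs are flagged rather than silently
propagated: MSE = 0 with unequal means gives p = 0, with equal means an
undefined p.

Duncan's test uses the classical "special protection level"
α_r = 1 − (1−α)^(r−1) for a stretch of r ranked means, with critical range
q(1−α_r, r, df)·√(MSE/n) from the studentized-range distribution (scipy),
quantiles cached because they dominate runtime. Stepwise testing proceeds
from the widest span inward; any stretch found homogeneous protects all
nested pairs. Unequal group sizes use the harmonic mean n (Kramer); the
reference design is balanced so this never triggers on the fixtures. For
k = 2 the procedure reduces to the pooled two-sample t-test, which is
asserted. Compact letters are assigned along the ranking, by default
descending (largest mean gets "a", the dominant convention in the source
tables; ascending is available as some rows use it). Variables undetected
in all but one group are untestable; undetected in exactly one group are
tested across the remaining groups and flagged `partial`. No
multiple-testing correction is applied across compounds by default,
matching the source analysis.

## PLS-DA

X is autoscaled (centered, unit variance — the common chemometrics
default; center-only and Pareto are options) and Y is the column-centered
one-hot class matrix. Components are extracted by NIPALS PLS2 (alternate
w ∝ X′u, t = Xw, q ∝ Y′t, u = Yq; deflate X by tp′ and Y by tq′), with
convergence judged on the weight vector (tolerance 1e-9, up to 5000
iterations — permuted-label refits can be nearly degenerate and converge
slowly). Each weight vector's largest-magnitude element is made positive
so scores are reproducible. Zero-variance variables are dropped before
scaling (kept but inert inside cross-validation so train/test column
spaces match). Two components are the default, matching 2-D score plots.

Q² = 1 − PRESS/SS of centered Y, with PRESS accumulated over held-out
folds; folds are venetian blinds stratified by class (deterministic), 7 by
default, degrading to leave-one-out when samples are fewer. The scaler and
class means are re-estimated inside every training fold. VIP_j =
√(p·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a); the mean of squared VIPs is 1 by
construction and asserted to 1e-9 on every fit. The permutation test
shuffles Y rows (re-drawing permutations identical to the original),
refits, and regresses R²Y and Q² on the mean absolute Pearson correlation
between permuted and original one-hot columns, the original model anchored
at correlation 1; the model is judged valid iff the Q² intercept at
correlation 0 is negative. scikit-learn's `PLSRegression` serves as an
independent oracle in the tests (scores up to column sign, R²Y to 1e-6);
it is never the implementation.

The published R²/Q² values (e.g. 0.999/0.996 for the volatile model)
depend on undeposited replicate data and a proprietary CV scheme; they are
treated as qualitative references of high separability. On seeded
synthetic triplicates drawn from the published means/SDs the package
obtains R²X 0.936, R²Y 0.999, Q² 0.996 and a negative permutation Q²
intercept — computed, not asserted as constants.

## Marker screening

Stage 1 keeps compounds with VIP > 1 and p < 0.05 (strict inequalities, as
printed). Stage 2 additionally requires OAV > 1 in at least one grade —
"at least one" rather than "all" because the published 43-compound set
includes grade-specific compounds; the stricter all-grades scope is
configurable. The two filters commute (asserted). Non-volatile markers are
the non-aggregate rows with VIP > 1. On the bundled tables these screens
yield 80, 43 and 22 compounds respectively.

## Synthetic replicates

`simulate_grade_dataset` draws n_reps (default 3, the reference design)
values per detected (compound, group) cell from a normal distribution
truncated at zero with the template's mean and sd; printed SDs are small
relative to means, so the truncation bias is far below the 5% moment-
recovery tolerance tested at n = 1000. A moment-matched lognormal is
available for stress tests. Undetected cells are exactly 0 in every
replicate. The global seed expands to per-compound substreams keyed by a
CRC of the compound id, so adding or removing a compound never perturbs
the other compounds' draws (asserted). Compounds are drawn independently:
the source provides no within-replicate correlation structure, so
between-compound correlations present in real extracts are not emulated —
synthetic-data results demonstrate the correctness of the statistics, not
biological covariation. The sensor-panel generator likewise emulates only
group-level mean separation plus iid within-group noise (no drift or
sensor cross-talk): enough to exercise discriminant models at controlled
effect sizes, including the null (effect size 0) case.

## Numerical and design choices

* Problem sizes: the pipeline's PLS-DA stage runs on 9 samples × 112
  variables (3 grades × 3 replicates), the permutation test at 200
  refits, null calibrations at 1000 variables per batch pooled over 5
  batches, and moment-recovery checks at 1000 replicates.
* Determinism: every stochastic step takes an explicit seed; fold
  assignment and HCA tie-breaks are deterministic; the pipeline's report
  is byte-identical under a fixed seed.
* HCA defaults: Euclidean distance, Ward linkage, autoscaled columns —
  a common chemometrics choice; the source names no method.
* The "Total free amino acids" aggregate is stored as printed, without
  recomputation from the 20 amino-acid rows.

## Known limitations

* Raw chromatogram/peak processing, spectral library matching and
  instrument control are out of scope; peak areas and quantified tables
  are inputs.
* Duncan's test follows the classical variant; statistical packages
  differ in detail and the source names no variant. Agreement is
  validated against the printed letter displays and p-values.
* Odor thresholds are matrix-dependent; the water thresholds used here
  are the source's choice and are user-replaceable.
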