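# Methods

## Scope and model

`crowdnn` treats duplex formation of self-complementary DNA oligomers
(2S ⇌ D) as a two-state equilibrium with temperature-independent ΔH° and
ΔS° (ΔCp = 0). This is a deliberate, fixed assumption, not a
configuration option: the entire analysis chain — the linearity of Tm⁻¹
in ln Ct, the baseline-median Tm, the ΔG°37 bookkeeping — relies on it,
and duplexes with measurable intermediate states are out of scope. The
non-self-complementary Ct/4 variant of the van't Hoff relation is
documented here but rejected at runtime: every entry point validates
that the input strand equals its own reverse complement.

Energies are kcal·mol⁻¹ throughout (R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹);
temperatures are kelvin internally and °C only at I/O boundaries.
ΔG°37 is evaluated at 310.15 K.

## Nearest-neighbor bookkeeping

The 16 dinucleotide steps collapse into 10 canonical NN sets (a step and
its reverse complement describe the same stacked pair); the canonical
label is the conventional table form (AA, AT, TA, CA, GT, CT, GA, CG,
GC, GG read as the 5'→3' top strand). The lookup covering all 16 steps
is built once and unit-tested exhaustively.

Initiation is classed by the **terminal base pair**: A·T or T·A termini
take the A·T initiation penalty, G·C or C·G termini the G·C one. Both
termini of a self-complementary duplex are the same type, so the first
base decides. This rule — rather than "any G·C present ⇒ G·C
initiation" — is the one that reproduces the published per-sequence
crowding calculations for A·T-terminated duplexes, and it is applied
identically in dilute and crowding predictions.

The dilute 1 M NaCl ΔG°37 increments (with init G·C = 1.82,
init A·T = 2.80, symmetry +0.43) are embedded as constants and verified
at test time by inverting the crowding scaling against the tabulated
crowding parameters ((C − 0.117)/0.666 agrees with every embedded value
within the crowding table's rounding half-width). The dilute ΔH°/ΔS° NN
tables are deliberately **not** embedded: the packaged study tables
provide the dilute predicted ΔG°37/Tm columns as inputs, because no
internal consistency check could validate independently transcribed
ΔH°/ΔS° constants, and the printed dilute predicted column is in any
case not bit-reproducible under a single initiation/symmetry convention
(the convention ambiguity is documented, not resolved).

The crowding prediction omits the symmetry term; the crowding parameter
set was defined from self-complementary sequences only and absorbs it.

## Synthetic melting curves

`meltsim` is the package's study-condition generator, not a test helper:
it emulates a 0–90 °C melt at 0.5 °C resolution with

* absorbance A(T) = α(T)·lower(T) + (1 − α(T))·upper(T) + ε,
  α from the exact mass-action quadratic;
* linear baselines, defaults lower = 2×10⁻⁴·T + 1.0 and
  upper = 5×10⁻⁴·T + 1.9865 — a unit-amplitude hyperchromic transition
  at mid-range with gently sloping ends, typical of oligomer melts;
* i.i.d. Gaussian noise ε per point (default sd 0 for deterministic
  work; 0.002 ≈ 0.2 % of amplitude is the noisy study condition used in
  the recovery tests), no smoothing;
* concentration series of 12 log-spaced Ct values over 2–200 µM (a
  100-fold range, matching the 10–12-point series the van't Hoff
  analysis expects), each curve seeded from the master seed plus a fixed
  per-curve stride, so a whole series is reproducible from one integer.

What the generator does **not** emulate: annealing hysteresis,
instrument drift, condensation artifacts, concentration error between
cuvettes, or wavelength-dependent baselines. Passing recovery tests
therefore demonstrate correctness of the analysis chain on ideal
two-state data, not robustness to every instrument pathology.

## Tm extraction and the baseline problem

Tm is defined as the crossing of the melting profile with the mid-line
between the two fitted baselines, located by linear interpolation
between adjacent grid points; with multiple crossings the one nearest
the steepest-slope temperature is chosen and flagged. Default windows
are the lowest and highest 15 % of the scanned range (user-overridable
per curve, mirroring the analyst's manual choice), with ≥ 8 points per
window. Curves whose transition amplitude is below 5× the
baseline-residual noise are refused. No per-curve Tm uncertainty is
produced; fit errors enter only through the van't Hoff regression.

A subtlety matters quantitatively: on a 0–90 °C scan the duplex baseline
is never fully reached for moderate |ΔH°| — at ΔH° = −70 kcal/mol and
Tm ≈ 30 °C the duplexed fraction at the default lower-window edge is
only ≈ 0.97. A single-pass OLS baseline fit is then biased by the
transition tail inside the window, shifting Tm by 0.1–2 °C and ΔH° by
1–10 %. Moving the windows closer to the transition makes this worse
(verified numerically). `tm_from_curve` therefore refines the baselines
iteratively by default: the apparent duplexed fraction implied by the
current baselines is fitted to the two-state form (ln K linear in 1/T
over the 0.2 ≤ α ≤ 0.8 band), the modeled tail contribution is
subtracted from the window points, the lines are refitted, and the loop
runs to self-consistency (tolerance 10⁻¹⁰ on the line coefficients,
≤ 40 iterations, with fallback to the single-pass fit and a
`refine_failed` flag on any numerical failure). The Tm definition itself
is unchanged. On ideal two-state curves the refinement converges to the
true baselines: noiseless ΔH° recovery through the full pipeline is
exact to < 0.01 % and extracted Tm agrees with the van't Hoff Tm to
< 0.002 °C. `refine=False` gives the literal single-pass spreadsheet
procedure.

The method needs both baselines to be observable: when a transition
extends past the scan limits (e.g. ΔH° = −40 kcal/mol with Tm = 70 °C,
where the strands are still ~30 % duplexed at the upper window) no
baseline-median variant is meaningful, and the extraction returns a
flagged result rather than failing silently. Derivative-maximum and
global-fit Tm definitions are intentionally not implemented.

## Van't Hoff fitting and errors

Unweighted OLS of Tm⁻¹ on ln Ct (the analysis gives no weighting
scheme); ΔH° = R/slope, ΔS° = R·intercept/slope, ΔG°37 from the identity
above. Standard errors are first-order (delta-method) propagations using
the full slope–intercept covariance matrix σ²(XᵀX)⁻¹ with
σ² = RSS/(n−2); the covariance term matters because ΔS° and ΔG°37 depend
on both coefficients. The propagated se(ΔG°37) is cross-checked against
a residual bootstrap in the tests. Two-point series return point
estimates with a warning and undefined errors; identical-Ct series are
rejected as degenerate.

Pair-difference summaries (for duplexes with identical NN composition)
report absolute |ΔTm| and percentage differences
|a − b| / max(|a|, |b|) × 100; the max-denominator convention is the one
that reproduces the published ΔG°37 pair average (4.3 %). The published
ΔH°/TΔS° pair percentages are not reproducible under any simple
denominator convention from the printed values and are not asserted.

## Regression layer

The condition-level relations are unweighted OLS fits of the 28
individual sequence points with explicit exclusion sets (default:
identical-NN pairs 1 and 8 for ΔG°37, additionally the 14-mer
d(CGATCGGCCGATCG) for Tm — the documented outliers attributed to G·C-rich
6-mers and 5'-T·A terminal fraying). r² is the squared Pearson
correlation. Leave-one-out refits the relation with each included
sequence held out and reports mean |relative ΔG°37 error| and mean
|ΔTm|. Prediction-accuracy summaries round predictions to 1 decimal
before differencing — the printed-table convention under which the
published 4.7 %/1.2 °C averages are recovered; pass
`round_decimals=None` for unrounded comparisons. The computed
leave-one-out averages (5.1 %, 1.3 °C) sit slightly above the
published 4.6 %/1.1 °C, which are not recoverable from the
rounded printed inputs under any averaging convention we tried; the
reproduction report lists them as documented exemptions.

The (a, b) search uses all 19 designs with pair-averaged measured ΔG°37
and **no** exclusions (the search, unlike the condition-level fits, was
defined over the full design set). Because the calculated value is the
affine image a·(Σ nᵢDᵢ + I_d) + b·(Σ nᵢ + 1) of fixed per-design sums,
the regression of measured on calculated reduces to closed-form moment
algebra in (a, b), and the full default grid (a ∈ [0.5, 0.8],
b ∈ [−0.3, 0.5], step 5×10⁻⁴, ≈ 10⁶ points) is evaluated vectorized in
well under a second. Objective: (slope − 1)² + intercept², ties broken
by higher r², then lexicographically smaller (a, b) — the published
"slope 1, intercept 0" criterion defines no metric, and this is the
simplest faithful scalarization. Errors on scaled parameters follow
σ → a·σ.

## Fixture integrity

The packaged tables are validated on load: row counts, required
columns, typographic-minus normalization, ΔG°37 = ΔH° − TΔS° closure to
the rounding half-width, and a full cross-check of every tabulated NN
frequency row against fresh counting of its sequence. Two print
discrepancies are carried as documented exemptions rather than
"corrected": row 8b's ΔH°/TΔS° are internally inconsistent with its
ΔG°37 (the ΔG°37/Tm values are the ones consistent with its
identical-NN partner and all downstream statistics), and the tabulated
crowding calculation for pair 7 (−4.7) disagrees with the parameter
arithmetic (−4.8). Neither is forced to agree.

## Problem sizes

The recovery test battery uses 12-curve series at 181 grid points per
curve, 50 seeded noisy replicates across ΔH° ∈ {−50, −80, −110}
kcal/mol, a 3×3×3 (ΔH°, Tm, Ct) extraction grid, 1000 bootstrap
resamples, and 20 planted-truth (a, b) searches on a 2×10⁻³ grid —
sizes chosen so the full suite runs in seconds while leaving the
statistical assertions well-powered.

## Known limitations

* Two-state, ΔCp = 0, self-complementary duplexes only; no mismatches,
  dangling ends, loops, RNA, or hybrid duplexes.
* The crowding parameter set is specific to 40 wt% PEG 200 in 0.1 M
  NaCl; the dextran 70 / Ficoll 70 table ships for pair-similarity
  checks only, and no parameters are derived for those cosolutes.
* The crowding NN set carries ΔG°37 only — no crowding ΔH°/ΔS°
  decomposition — so crowding Tm at arbitrary Ct cannot be computed
  from it; Tm predictions go through the condition-level linear
  relation at its reference concentration (100 µM).
* The linear crowding relations were established on 6–16-mers and do
  not model cosolute size or duplex length explicitly.
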