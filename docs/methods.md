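# Methods

This note records the modelling assumptions, numerical choices, and known
limitations behind `qsarx`.  It documents what the code computes and why;
every number quoted here is produced by the test suite or the acceptance
script, not asserted from memory.

## HSAB descriptors

Vertical ionization energy and electron affinity follow Koopmans' theorem
(I = −E_HOMO, A = −E_LUMO); electronegativity, hardness, chemical
potential, electrophilicity, and the fraction of electrons transferred
(ΔN) follow the standard conceptual-DFT definitions.  All energies are eV
throughout; no unit conversion is performed internally.

**Metal reference.**  ΔN requires the electronegativity and hardness of
the metal surface.  The default is the bulk-iron convention of the
corrosion-inhibition literature, χ_Fe = 7.0 eV and η_Fe = 0 eV (iron as a
perfect electron sink).  These values reproduce the bundled ten-drug
reference table's ΔN column: recomputed from the printed 2-d.p. orbital
energies, all ten values agree within ±0.01, and cephaloridine,
mercaptopurine, and acepromazine agree exactly at the printed precision
(1.40, 1.40, 1.37).  The residual ±0.01 discrepancies (e.g. dipyridamole
1.56 vs a printed 1.55) are consistent with the inputs themselves being
rounded to 2 d.p.  Both reference values are configurable.

**Electrophilicity modes.**  The tabulated ω values in this model family's
published descriptor tables do not satisfy the textbook ω = μ²/2η (for
dipyridamole the textbook value is 3.79 eV against a tabulated 0.77 eV);
they satisfy ω = χ/4 exactly, to within half a unit of the printed last
digit for all ten bundled drugs.  Why the tabulated convention is χ/4 is
not known (a nonstandard η or a unit slip are both plausible); rather than
guess, both behaviours are exposed as `standard` (default) and
`table_compatible`.  The frozen published regression model was fitted
against table-scale ω, so its predictions require `table_compatible`
values in the ω slot.

**Rounding.**  Computations carry full floating precision.  Comparisons
against printed tables round half-away-from-zero to the table's printed
precision (`qsarx.util.round_half_away`), matching typesetting convention
rather than banker's rounding.

## Design matrix and FROLS

The response is static and linear in parameters with no intercept: the
model family this package implements contains no constant term.  Columns
are used in their raw units — the published model's coefficients are in
IE% per raw descriptor unit, confirming no standardization was applied
upstream.  Both choices have opt-in escapes in `build_design_matrix`
(`add_intercept=True` prepends a unit column; `standardize=True` z-scores
the candidates), default off.

FROLS follows the classical NARMAX formulation: step 1 selects the raw
candidate with the highest ERR; from step 2 onward every remaining
candidate is orthogonalized against the selected basis by classical
Gram–Schmidt with one reorthogonalization pass (numerical stabilization)
before its ERR is evaluated.  Ties in ERR break to the lowest column
index, making selection deterministic.  A candidate whose orthogonalized
squared norm falls below 1e−12 of its original squared norm is skipped as
collinear, with a diagnostic.

**Stopping.**  Selection stops when ESR = 1 − ΣERR ≤ ρ (default ρ =
0.005), when no candidate would reduce ESR by more than a minimum gain
(default 1e−6 — a guard against an unreachable ρ on noisy data), when
`max_terms` is reached, or when all remaining candidates are collinear.
The model records which rule fired.  The dual rule exists because a fixed
ρ is not always attainable: reported SERR values in this model family's
literature (e.g. 99.4514%) correspond to ESR above the stated ρ, so a
pure-ρ stop would not terminate where the published selection did.

**Weights.**  The published "β = y Z⁻¹" formulation is dimensionally
impossible for non-square Z; weights are the least-squares solution
computed by QR factorization, which is what a linear-in-parameters model
implies.  Rank deficiency is detected by pivoted QR and reported with the
offending column indices.

FROLS is greedy: on orthogonal dictionaries it provably coincides with
exhaustive best-subset selection (asserted in tests); on correlated
dictionaries the selected k-subset may be suboptimal, which is inherent to
the method, not a defect.

## Cross-validation and metrics

Fivefold CV shuffles rows with a seeded `numpy` generator, splits into
five near-equal folds, fits FROLS on four and scores MSE on the held-out
fold; the lowest-MSE fold model is promoted.  All randomness flows from
explicit seeds; identical seeds give identical partitions and promotions.

MAPE, MSE, and RMSE follow their standard definitions.  The SD metric is
the n−1 sample standard deviation of the residuals about their mean: of
the readings admitted by the ambiguous mixed formula in this model
family's literature, it is the only one consistent with every reported
(SD, RMSE) pair satisfying SD ≤ √(n/(n−1))·RMSE.

**Screening bands.**  Predictions are never clipped.  Screening labels
follow the published handling: > 100% is physically unrealistic (excluded
from interpretation), ≥ 95% is the high-efficiency band used to shortlist
candidates (chosen upstream to keep shortlisted drugs above the 90%
industrial requirement after a ~5% MAPE), and the moderate band's lower
edge (84.92%) is the smallest efficiency in the published
intermediate-performance group.  All thresholds are configurable.

**Published-model caveat.**  Evaluating the frozen model on 2-d.p. rounded
descriptor tables deviates from the originally printed IE% by up to ~16
points (mercaptopurine: 82.34 from rounded descriptors vs 98.66 printed),
because the ω coefficient (6579) amplifies third-decimal descriptor error
by tens of IE%.  The original fit evidently used unrounded internal
descriptors, which are not published; the package documents this rather
than compensating for it.

## Electrochemistry

EIS and Tafel efficiencies, the CPE conversions, and coverage are direct
algebraic transcriptions (raw-spectrum equivalent-circuit fitting and
Tafel-slope extraction are out of scope; the package consumes fitted
circuit parameters).  The blank cell is a Randles circuit with no film
branch, so R_p,blank = R_ct,blank (127 Ω·cm² in the bundled lidocaine
table).  Recomputing the bundled table's IE% column from its printed
resistances agrees within 0.15 percentage points at 20/50/100 ppm; the
10 ppm row deviates by ~0.4 points (3.2 printed vs 2.83 recomputed),
consistent with the printed resistances being rounded after the original
efficiency was computed.

**Langmuir analysis.**  C/θ is regressed on C by ordinary least squares
(`scipy.stats.linregress`); R² is the squared Pearson correlation,
identical to the coefficient of determination for simple OLS with
intercept.  Slope and R² are invariant to the concentration unit; the
intercept, k_ads = 1/intercept, and ΔG°_ads assume mol/L.  The adsorption
free energy uses the standard form ΔG°_ads = −RT ln(55.5 k_ads) with
55.5 mol/L the molarity of water; the variant sometimes printed with 55.5
multiplying RT outside the logarithm is dimensionally inconsistent and
does not reproduce the reference value (−38.39 kJ/mol from the printed
intercept 8×10⁻⁶ mol/L), whereas the standard form does.  "Room
temperature" defaults to 293.15 K, which reproduces that reference value
within 0.05 kJ/mol (298.15 K would shift it by ~0.7 kJ/mol); the
temperature is a parameter everywhere it appears.  The bundled lidocaine
fit uses the three highest concentrations (20/50/100 ppm); the 10 ppm
point (θ ≈ 0.03) lies far off the isotherm and the published regression is
only reproducible without it — the `--min-coverage` option makes this
exclusion explicit.  Mechanism classification uses |ΔG| bands (<20
physisorption, 20–40 combined, >40 chemisorption), with boundary values
assigned to the combined class.

## Synthetic benchmark generator

The generator exists so every pipeline stage is testable without external
data.  It draws all ten descriptors independently and uniformly within
ranges anchored to the published high-efficiency cohort (pKa 1.70–9.46,
E_HOMO −5.87…−4.34 eV, E_LUMO −4.01…−1.83 eV, ω 0.77–1.23, ΔN 1.12–1.55),
with the remaining physicochemical descriptors spanning typical
small-molecule drug ranges (MW 150–850 Da, logP −2…5, logS −6…0, PSA
20–300 Å², α 15–80 Å³).  Responses are y = Σβx + Gaussian noise (default
SD 2 IE%), and coverage curves invert the Langmuir model.  All randomness
is seeded; no global state is touched.

**Why ω and ΔN are drawn, not derived.**  In real tables ω and ΔN are
functions of the orbital energies.  For the benchmark they are sampled
independently, because table-scale ω = χ/4 is an exact linear combination
of E_HOMO and E_LUMO: a generating support containing a derived ω would be
linearly unidentifiable and support recovery would be meaningless.  Tables
with missing ω/ΔN columns still get them derived through the HSAB
operations, as in the real pipeline.

**Default generating model.**  The default support is the published
model's five descriptors (pKa, E_HOMO, E_LUMO, ω, ΔN) with weights
(−7, −45, 28, 140, −150) IE% per unit.  The weights were designed for
identifiability of the benchmark, on two explicit principles.  First, each
term contributes a comparable 15–20 IE% to the response spread, well above
the 2 IE% noise floor and large enough that each term's energy share
clears the ρ = 0.005 stopping threshold.  Second, because the model has no
intercept and ERR is uncentred, the response mean must be carried by the
descriptor columns themselves; the signs are arranged so that the mean
(≈49 IE%) aligns constructively with the near-constant quantum-chemical
columns and destructively with the wide physicochemical ones.  This makes
the first FROLS pick a near-constant true column, after which
orthogonalization effectively centres the remaining candidates and the
later selection steps are well conditioned.  A mean-dominated response
with arbitrary signs instead entangles the constant direction with one
column's variation at step 1 and suppresses subsequent true-term ERR gains
to the level of chance correlations, degrading support recovery — a
property of uncentred forward selection, not of the data scale.  Under the
default conditions (50 compounds, fivefold CV, noise SD 2) the promoted
model recovers the exact generating support in ≳95 of 100 seeded
replicates with median maximum relative weight error ≈2%.

**What the generator does not emulate.**  Real descriptor tables are
strongly correlated (ω and ΔN are near-deterministic in the orbital
energies; MW, PSA, and polarizability co-vary), real IE% lies in [0, 100]
with measurement error that is neither Gaussian nor homoscedastic, and
real responses are not exactly linear.  Passing the recovery study
demonstrates that the identification machinery is correct on data obeying
its own assumptions; it does not certify performance on experimental
tables, where collinearity can make the selected support non-unique.  The
synthetic response is deliberately not clipped to [0, 100], so generated
tables exercise the same unclipped-prediction path as the screening step.

## Problem sizes

The test suite's statistical checks use 40-row dictionaries for FROLS
correctness, 100 replicates of 50 compounds for the recovery study, and
3–7-point isotherms — sizes at which the exhaustive-search oracles
(best-subset enumeration, full OLS) are exact and fast.  The whole suite
runs in a few seconds.

## Known limitations

- The original 42-compound training table is unpublished, so the published
  model's training metrics are not recomputable; the frozen coefficients
  are provided as a predictor, and the selection machinery is validated on
  synthetic data instead.
- ERR/FROLS is uncentred and intercept-free by design; on mean-dominated
  responses forward selection is poorly conditioned (see above).  Users
  fitting such data should consider the `add_intercept` or `standardize`
  opt-ins of `build_design_matrix`.
- ΔG°_ads classification bands treat the boundary values as "combined";
  literature conventions at exactly 20 or 40 kJ/mol differ.
- The CPE conversions assume the fitted circuit topology of the bundled
  tables (Randles blank; two-CPE inhibited cell).
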