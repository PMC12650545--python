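# Methods

`phenolmetry` implements a quantitative, ratiometric pH assay built on the
phenol red indicator present in most cell-culture media, together with the
surrounding machinery needed to exercise and validate it without instrument
data: a synthetic spectrum generator, a mechanistic acid–base titration
simulator, and a reporting-completeness auditor for tissue-dissociation
protocol surveys.

## 1. Ratiometric pH from phenol-red absorbance

Phenol red is a two-state chromophore: the protonated form absorbs near
430 nm (yellow), the deprotonated form near 560 nm (red/purple), with an
isosbestic point near 480 nm and a useful indication range of about pH
6.8–8.2. The assay reads a 300–800 nm absorbance spectrum per well of a
microplate and reduces it to the band ratio

    R = A(560 nm) / A(430 nm),

which cancels dye concentration and path length. Calibration uses three
reference samples: the stock medium at its manufacturer-stated pH, an acid
extreme titrated below 6.8 and a base extreme titrated above 8.2. The
extremes provide the ratio bounds R_min and R_max; the stock provides an
apparent pKa via the two-point difference form

    pKa_app = pH_stock − log10( |A430_stock − A_acid| / |A_base − A560_stock| ),

where A_acid is the acid extreme at 430 nm and A_base the base extreme at
560 nm. Sample pH then follows from the Henderson–Hasselbalch-type relation

    pH = pKa_app + log10( (R − R_min) / (R_max − R) ).

**Sign handling.** The literal difference quotient (without absolute
values) is negative for any stock lying between the extremes, because the
acid extreme *maximises* the 430-nm band; `sign_mode="as_printed"` keeps
the literal form and raises an explanatory error, `"magnitude"` (default)
takes absolute values. Both are exposed so the behaviour of the published
formula is documentable rather than silently papered over.

**Known bias of the chained formulas.** For an idealised two-state
spectrum, exact inversion of the ratio requires the effective constant
pKa_true + log10(ε_HA(430)/ε_A(430)) in the pH formula (ε are the
extinction coefficients of the protonated/deprotonated forms). The
two-point difference calibration instead yields
pKa_true − log10((ε_HA(430) − ε_A(430)) / (ε_A(560) − ε_HA(560))). The two
coincide only for particular extinction-coefficient combinations. Under
this package's default synthetic band model they differ by ≈ 1.0 pH, so
the default pipeline carries a nearly constant negative offset: linearity
and slope (≈ 1.03) against a reference instrument are excellent, absolute
accuracy is not. Whether the offset largely cancels for phenol red's real
extinction coefficients cannot be settled from synthetic spectra; the bias
curve is frozen as a regression test, and two remedies are built in:

- `calibrate(..., method="stock_ratio")` — a self-consistent one-point
  calibration, pKa_app = pH_stock − log10((R_stock − R_min)/(R_max −
  R_stock)), which recovers synthetic pH to ≈ 0.02 units; and
- `ph_from_ratio(..., mode="corrected")` — adds the extinction-ratio term
  log10(A430_acid/A430_base) for users wanting the exact ratiometric form.

Both are opt-in; the default remains the published two-point chain.

**Other numerical choices.** Band absorbances default to the fixed grid
points nearest 430/560 nm (ties resolve to the lower wavelength);
`window_max` over ±10 nm is available for coarse grids. Replicate wells
are averaged pointwise before any ratio is formed. pH values outside
6.8–8.2 are returned flagged (`in_range=False`) rather than clipped, so
titration anchors stay plottable; ratios at or beyond R_min/R_max raise a
saturation error, which the series assembler converts into a flagged step
with no calculated pH. An optional per-well baseline correction subtracts
the mean absorbance over 700–800 nm (off by default — both bands are far
from that window and the reference workflow does not blank).

## 2. Measured-vs-calculated validation

A titration series pairs the glass-probe reference pH of each replicate
group with the spectrophotometrically calculated pH, ordered by cumulative
titrant volume. Agreement is summarised by ordinary least squares of
calculated (y) on measured (x) — the reference on the x-axis, the standard
method-comparison convention — reporting slope, intercept, R² and n.
Saturated steps are excluded; by default so are steps whose calculated pH
leaves the indication window, with a flag to include everything. At the
canonical synthetic conditions (13 steps at pH 6.9–8.1, 3 replicates,
0.002 AU noise) the pipeline yields R² > 0.999.

## 3. Synthetic spectrum generator

Each protonation state contributes one unit-height Gaussian band:

    A(λ) = s·[(1−α)·a_a·g(λ; 430, 40) + α·a_b·g(λ; 560, 45)] + baseline + ε(λ)

with α = 1/(1 + 10^(pKa_true − pH)), pKa_true = 7.5 (the midpoint of the
indication range), dye-scale surrogate s, and i.i.d. additive Gaussian
noise ε of standard deviation 0.002 AU by default — a realistic
plate-reader noise floor. The base-band amplitude is pinned analytically
(a_b = a_a·g(480;430,40)/g(480;560,45) ≈ 2.2233) so the two bands cross at
exactly 480.0 nm, giving the model a true isosbestic point; the resulting
≈ 1:2.2 amplitude ratio is consistent with phenol red's stronger basic
band. The default grid is 300–800 nm at 1 nm. Whole plates are simulated
with auto-assigned roles (acid extreme below 6.8, base extreme above 8.2,
a designated stock step) and the generator's true pH recorded as the
reference reading; a fixed seed makes persisted plates byte-identical.

What the generator does *not* emulate: real phenol-red band shapes and
shoulders, turbidity/scattering, temperature dependence of the indicator
pKa, heteroscedastic or wavelength-correlated instrument noise, and
medium components that absorb in the visible range. Passing tests
therefore demonstrate the correctness and internal consistency of the
computation, not the absolute accuracy of the assay on any particular
real medium.

## 4. Charge-balance acid–base simulator

Solution pH is the unique root of the electroneutrality condition over all
protonation states of every dissolved polyprotic species, plus strong
(spectator) ions and the water terms [H⁺] − Kw/[H⁺] (Kw = 1e-14, 25 °C).
Speciation fractions come from cumulative log10 dissociation terms with
max-subtraction for numerical stability. The salt form of a species is
encoded as net strong-ion charge per formula unit (free acid 0,
hydrochloride −1, mono-sodium +1, ...). The balance is strictly decreasing
in pH, so plain bisection on [0, 14] is robust; it is iterated to an
interval of 1e-13 pH so the residual net charge is ≤ 1e-12 M. Titrant
dosing accounts for dilution by the added volume and brackets the target
by doubling before bisecting; the result is the smallest volume reaching
the target pH within 1e-3.

Shipped pKa ladders (editable YAML data, 25 °C literature values): HEPES
{7.5}; L-cysteine {1.71, 8.33, 10.78}; EDTA {2.0, 2.66, 6.16, 10.24, with
the two strongest acidities folded into the salt form}; carbonic acid
{6.35, 10.33}; phosphate {2.15, 7.20, 12.38}.

This is the computational twin of the papain-reconstitution workflow:
dissolving L-cysteine (as the hydrochloride) and free-acid EDTA into a
weakly buffered HEPES medium acidifies it, and a microliter-scale dose of
5 M NaOH restores the physiological target. The commercial media used in
the wet-lab workflow have proprietary buffer compositions and unstated
salt forms, so the simulator is validated against mechanistic properties
(monotone acidification, Henderson–Hasselbalch agreement within 0.02 pH
for single buffers ≥ 1 mM near their pKa, µL-scale restoration volumes,
charge residuals ≤ 1e-12 M) rather than against the published lab
readings. Ionic-strength/activity corrections, temperature-dependent
equilibria, CO₂ exchange and metal–EDTA chelation are documented
limitations.

## 5. Protocol-survey auditor

The auditor ingests a 15-column protocol-survey table (one row per
publication) coded tri-state: `x`/`X` = not reported, `N/A` = not
available, `Use` = reagent use recorded, `yes` (± a parenthesised value) =
explicitly reported, any other token = the reported value itself. Numeric
ranges (`15–20`, `E16–E17`, en dash or hyphen) parse to (low, high).
Completeness percentages use the record count as denominator; the
"not reported" percentage is the complement of "reported", with the
not-available count kept separately. The composite `concentration` field
counts a record as reported when either the mg/mL value or the activity
units are given. Digestion units are activity units × incubation minutes,
with the midpoint taken for ranges. A papain-source three-way
completeness split is deliberately not computed: the category boundaries
cannot be reconciled with the printed columns, so manufacturer and
catalog completeness are reported separately instead. One known
discrepancy is documented rather than resolved: the shipped survey's
maximum digestion-unit product is 3000 under the midpoint policy, while
the figure caption it mirrors speaks of "nearly 4000".

The shipped fixture (`data/table2_survey.csv`) is a verbatim transcription
of a 50-publication survey of papain-based primary-neuron dissociation
protocols (2009–2024); every percentage the survey's prose states is
reproduced exactly by the auditor and locked in the test suite.

## 6. Problem sizes and determinism

Default study conditions used throughout tests and the acceptance script:
titration steps pH 6.9–8.1 in 0.1 increments, three replicates per step,
extremes at pH 5.5/9.5, stock at 7.4, noise 0.002 AU, 501-point spectra
(1 nm grid; 0.5 nm for the isosbestic search), Monte-Carlo loops of 20–50
seeds. All randomness flows through explicitly seeded numpy generators;
noiseless paths are bit-deterministic.
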