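# Methods

## Mass arithmetic

The packaged element table uses CODATA/AME most-abundant-isotope masses
(C = 12 exactly, H 1.00782503, N 14.0030740, O 15.9949146, F 18.9984032,
S 31.9720710, Na 22.9897693 Da) and IUPAC standard atomic weights for
average masses. Singly charged ions add or subtract the proton mass
1.0072765 Da (electron mass included) or add the Na⁺ cation mass
22.9892222 Da; this is required to reproduce published 4-decimal HRMS
values, which the test suite checks to ±0.0005 Da. The packaged table is
additionally cross-checked against an independent implementation
(pyteomics) on every formula in that suite.

Covalent adduct shifts subtract the leaving group from the compound
formula. Leaving groups are data, not inference: the packaged compound
table stores them explicitly (acetate C2H4O2, propionate C3H6O2, pivalate
C5H10O2, phenylacetate C8H8O2, phenylcarbamate C7H7NO2,
4-methoxyphenylcarbamate C8H9NO3), reflecting the β-elimination chemistry
in which the carboxylic/carbamic acid departs. A vinylsulfone compound has
no leaving group and adds its entire mass. Deconvoluted intact-protein
spectra live on the average-mass scale, so peak matching uses average
shifts with a 1.0 Da default tolerance (observed isozyme-panel differences
scatter by up to ~0.6 Da around theory); candidate ties (e.g. an acetate
ester and the bare vinylsulfone produce the identical adduct) resolve to
the first candidate in input order.

## Melt curves

Two-state unfolding with ΔGu(T) = ΔHu(1 − T/Tm) + ΔCpu(T − Tm − T ln(T/Tm))
and linear native/unfolded baselines anchored at Tm. Tm is defined as the
folded-fraction-½ temperature, not the derivative maximum; the two differ
negligibly for the baseline slopes this model handles. ΔCpu is fixed during
per-curve fitting (default 17 kJ/(mol·K), order-of-magnitude typical for a
~30 kDa globular domain) because a single curve cannot identify it; it is a
keyword argument everywhere. Initial guesses: Tm from the
Savitzky–Golay-smoothed |dF/dT| maximum, baselines from the first/last 10%
of points. A fit whose amplitude is below 3× the residual RMS, or whose Tm
falls outside the scanned range, raises `NoTransitionError` rather than
returning a number. Temperatures are kelvin internally, Celsius at file
boundaries.

## FTSA dosing

The dosing relation (see README) treats the ligand as binding only the
native state, with the binding constant extrapolated to the melting region
by the integrated van't Hoff equation. Binding enthalpy defaults are
ΔHb = −42 kJ/mol and ΔCpb = −0.8 kJ/(mol·K) — typical sulfonamide–CA
values; both are explicit parameters echoed into every result because
reported Kd values at 37 °C depend on them when Tm sits 20–40 K above the
reference temperature. Protein concentration defaults to 5 µM in the final
mix (10 µM stock diluted 1:1; isozyme-specific overrides supported).

The fit has a single free parameter, log10 Kd, minimized by Nelder–Mead
from three starts spanning 10⁻¹³–10⁻⁴ M with residuals in Tm space. The
per-dose model Tm comes from a vectorized bisection of the dosing relation
on [Tm_ref, Tm_ref + 40 K] (tolerance 10⁻⁴ K), which keeps a full fit in
the tens of milliseconds. Confidence intervals come from the curvature of
the chi-square surface in log10 Kd. Replicates combine as geometric means.

Covalent compounds violate the reversible model: once the protein is
stoichiometrically modified the dosing curve flattens. We deliberately
report the reversible-model fit as an *apparent* Kd — exactly how such
assays are analyzed in practice — and attach a saturation flag (top ≥ 3
doses spread < 0.5 K while the model predicts > 1 K) instead of inventing
a kinetic correction. When the entire dosed range is flat the result is
marked upper-bound-only.

## Competition on cells

Free target P solves P(1 + At/(KdA+P) + Bt/(KdB+P)) = Pt by bisection to
10⁻¹⁴ relative; conservation closes to 10⁻¹² relative by construction.
Totals, not free concentrations, parameterize the model: with apparent Kd
values (0.3 nM) far below the 5 nM target concentration, depletion is
severe and the free≈total shortcut would bias fits badly. The signal model
is S = background + scale·PB/Bt with both nuisance parameters fitted.

The default generator dose grid is 12 fourfold dilutions from 100 µM plus
a no-competitor well. The narrow 80 nM serial-dilution layout used to
*prepare* plates cannot span the displacement transition of a 15–22 nM
competitor facing a probe with competition strength Bt/KdB ≈ 67 (transition
midpoint ≈ 1.5 µM); complete outcompetition at 100 µM fixes the regime the
fitted curves must cover, and the fitter's precondition (≥ 6 doses spanning
the transition) encodes the same requirement. `gen_dose_grid` still
produces the serial-dilution layouts when needed.

## Covalent kinetics

The scheme E+I ⇌ E·I → E·A → E−A is integrated with LSODA at rtol 10⁻⁸ /
atol 10⁻¹²·max(E0, I0); both conservation laws hold to 10⁻⁹ relative at
every output point, enforced in tests. Activity is free E only — bound,
activated, and covalent forms are all inactive, consistent with full
inhibition at 1:1 stoichiometry. The scheme grants E·A no dissociation
path, so ktrans is rate-limiting whenever kinact is fast.

No rate constants are fitted (they are not separately identifiable for
these compounds); instead two presets bracket the chemistry:
`ester-fast` (kon 10⁶ M⁻¹s⁻¹, koff 10⁻² s⁻¹, ktrans 4×10⁻³ s⁻¹,
kinact 1 s⁻¹ → covalent half-time ≈ 3 min at 1:1, 10 µM) and
`carbamate-slow` (ktrans 100× smaller, matching the two-orders-of-magnitude
reactivity gap between ester and carbamate leaving groups).

IC50(t) interpolates activity = 0.5 in log dose. Washout modes:
instantaneous-dilution clamps free inhibitor at zero (ideal dialysis);
first-order-removal decays it with a 2 h default half-time over a 32 h
default duration, mirroring a multi-exchange dialysis experiment.

## Synthetic data and what passing tests show

Generators emulate the assay layouts: FTSA dose grids are 8-point twofold
or 12-point 1.5-fold serial dilutions of a 10 mM stock, diluted 12.5× into
buffer and 1:1 with protein (top final dose 400 µM); melt ramps are
25–90 °C at 1 °C spacing. Noise defaults — fluorescence σ = 1% of
amplitude, Tm σ = 0.2 K, mass error 20 ppm, competition CV 5% — are
plausible instrument figures, configurable, and recorded in every truth
side-car. All randomness flows from one integer seed through
`numpy.random.default_rng`; identical configs give byte-identical CSVs.

Recovery tests therefore demonstrate *self-consistency*: the fitters
recover parameters from data generated by the same forward models under
realistic noise. They do not probe model misspecification in real data —
dye-binding artifacts, multi-transition unfolding, cell-to-cell target
heterogeneity (surface concentrations vary severalfold), washing-step
kinetics, or compound aggregation at high doses are all outside the
generators and the models alike. Acceptance-scale problem sizes (9–13-dose
series, 30 noisy replicates per affinity, 3 affinities per assay) keep the
full suite under half a minute.

## Known limitations

* The FTSA apparent Kd of a covalent compound is a snapshot quantity; the
  saturation flag marks, but does not correct, the irreversible
  contribution.
* Fitting ΔHb/ΔCpb from dosing data is unsupported by design; wrong fixed
  values shift the extrapolated Kd systematically.
* Two-transition melt curves (some isozymes show a second fluorescence
  shift) are out of scope; the per-curve fit will flag or mis-fit them.
* Peak matching assumes deconvoluted neutral masses; raw m/z charge
  deconvolution and isotope-pattern simulation are not implemented.
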