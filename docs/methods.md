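# Methods

`aurprof` implements three quantitative pipelines for profiling ATP-competitive
Aurora kinase inhibitors — biochemical Ki estimation under tight-binding
conditions, immunofluorescence-based cellular potency, and live-imaging
cell-cycle event statistics — together with synthetic-data generators that
stand in for raw plates, image fields and movies. This note records the
models, the parameter choices that matter, the numerical conventions, and
what the synthetic data do and do not establish.

## Biochemical model

**Michaelis–Menten.** `fit_michaelis_menten` estimates Km(ATP) and Vmax by
unweighted nonlinear least squares on v = Vmax·[S]/(Km+[S])
(`scipy.optimize.curve_fit`; Vmax initialized at max(v), Km at the
substrate concentration whose velocity is nearest half-maximal). A Km
estimate outside the sampled substrate range is flagged: it means the
titration did not bracket the constant and the estimate is extrapolated.

**Four-parameter logistic (4PL).** All dose–response curves — plates,
cellular marker intensities, live-event statistics — are fitted with the
variable-slope logistic

    response = bottom + (top − bottom) / (1 + ([I]/IC50)^h)

on linear response versus log10 concentration. Conventions:

- *Zero-dose anchoring.* Vehicle wells enter the fit at a
  pseudo-concentration three decades below the lowest tested dose (a log
  axis cannot host zero). This is standard plate-analysis practice and
  leaves the top plateau data-driven; it also bounds "exact" recovery of
  noiseless curves at ~1e-5 of the span, which the tests account for.
- *Initialization.* top = vehicle mean, bottom = top-dose mean, midpoint =
  dose with response nearest half-span, slope from the log-dose distance
  between the 25% and 75% span crossings (clipped to [0.3, 10]).
- *Orientation.* Rising curves (e.g. G2 duration versus dose) are fitted
  with a negative slope; reported parameters are normalized so top ≥
  bottom and the predicted response at IC50 is (top+bottom)/2 exactly.
- *No-effect rule.* If the span between the control level and the top-dose
  mean is strictly below 20% of control, the curve is flagged no-effect and
  no IC50 is reported.
- *Weighting.* Unweighted by default; optional 1/variance weights.
- *Normalization.* Plate fits divide by the vehicle-well mean by default;
  fitting raw signal is supported (`normalize=False`). Results differ only
  through the implicit weighting of residuals.
- *Determinism.* Wells are lexicographically sorted before fitting, so the
  fit is invariant to well order; optimizer tolerances are set to 1e-12.

**Tight-binding conversion.** When the total active enzyme concentration
[E]t is comparable to Ki, free inhibitor is depleted by binding and the
plain Cheng–Prusoff relation fails. The conversion used is

    Ki = (IC50 − [E]t/2) / (1 + [S]/Km)

which reduces to Cheng–Prusoff at [E]t = 0 and has denominator exactly 2
when the assay is run at [S] = Km — the reason the biochemical assays fix
[ATP] = Km(ATP). [E]t is estimated by `estimate_active_enzyme` from an
inhibitor titration in the stoichiometric regime ([E]t, [I] ≫ Ki), where
the half-activity point sits at [E]t/2; the result is flagged unless
IC50/Ki exceeds a configurable factor (default 100).

**Upper bounds.** The conversion subtracts two similar numbers when Ki is
far below [E]t, so a resolution floor is enforced: when
(IC50 − [E]t/2) < 0.1·[E]t, or the ~95% interval of the fitted IC50
includes [E]t/2, the result is reported as an upper bound,
max(floor, (IC50_upper95 − [E]t/2)/(1+[S]/Km)), with the floor at 0.01 nM
(10 pM). A true Ki of 0.05·[E]t sits exactly at this boundary, so in noisy
replicates such a compound reports a mixture of point estimates and bounds
whose values agree closely; an aggregate containing any bound is itself a
bound. Negative Ki is never reported.

**Morrison closed form.** The generator (and the oracle used in tests) is
the tight-binding fractional-activity quadratic

    v/v0 = 1 − [(Et+I+Ki') − sqrt((Et+I+Ki')² − 4·Et·I)] / (2·Et)

with Ki' = Ki·(1+[S]/Km). Its half-activity point is exactly Ki' + Et/2
for all regimes. A symmetric 4PL fitted to this asymmetric shape carries a
small midpoint bias that grows with the dose window; the default simulated
titration therefore spans ±1.25 decades around the expected IC50 (24
points, ~1.27-fold steps), a dense design appropriate for tight-binding
work, for which the residual bias is ≲0.5% of IC50.

**Aggregation and selectivity.** Replicate experiments aggregate as mean ±
sample SD (ddof = 1) with n recorded. Fold selectivity of a compound for
enzyme X over Y is Ki(Y)/Ki(X), computed on unrounded values; display
rounding (three significant figures for Ki; one decimal below 100, integer
above, for ratios) is applied only in table output, and upper-bound Ki
values in the denominator produce ">x" lower-bound ratios. Published
selectivity tables that were computed from unrounded internal values
cannot be reproduced from their printed means (e.g. a printed 1030-fold
entry versus 66.8/0.06 = 1113 from printed values); the package keeps raw
values in machine output precisely so such discrepancies stay auditable.
Compounds with slow binding kinetics violate the equilibrium assumption of
the whole workflow and should be flagged by the caller rather than fitted.

## Cellular pipeline

Mitotic cells are gated as connected components of the MPM2 channel above
a frozen threshold, size-filtered (default 50–5000 px²). Phospho-objects
(pLATS2 foci, pH3 chromatin) are extracted per marker by intensity
threshold → erosion → dilation (disk structuring element, default radius 1
px each; radius 0 reduces to pure threshold + area filter) → area filter
(defaults 4–400 px² for foci, 50–5000 px² for chromatin). Per cell, the
measurement is the mean marker intensity over (object mask ∩ cell
footprint); a gated cell with no surviving object pixels scores 0 — that
convention is what drives the curve to its bottom plateau at saturating
inhibition. Wells average cells with equal weight and are dropped below 20
mitotic cells. Curves normalize to the vehicle-well mean and are
classified as:

- **NE@top** — top-dose inhibition strictly below 20%,
- **partial (%Inh@top)** — responsive but fitted bottom plateau above 50%
  of control, or non-convergent fit,
- **IC50** — otherwise, from the 4PL fit.

*Threshold policy.* Thresholds are calibrated once on vehicle wells and
applied unchanged to all doses of a series. MPM2 gating uses Otsu's
threshold on the pooled vehicle MPM2 channel (bright mitotic labeling is
strongly bimodal). Marker thresholds use background + k·sigma with k = 5,
where background level and sigma are estimated robustly (median and
MAD-derived sigma) so that the bright objects present in vehicle wells do
not inflate the statistic. A non-robust mean+SD rule would raise the
marker threshold several-fold and truncate dim objects well before the
curve midpoint, biasing fitted IC50s low.

The RNAi-validation quantification variants are also provided:
`box_quantify_pole` (background-subtracted integrated signal in a 10×10 px
box at each spindle pole) and `mask_quantify_chromatin` (mean pH3 inside a
DNA mask minus the mean in the 20-px annulus around it), plus the
unpaired two-sided t-test used to compare conditions, viability
normalization for proliferation plates, and apoptotic-fraction scoring.

Coordinates are 0-based pixel-centered rows/columns; areas are px² with
the physical pixel size carried as metadata only.

## Live-imaging event calling

A G2 call takes a track's per-frame PCNA-foci visibility and NEBD frame:
G2 starts at the first frame after the last foci-visible frame and ends at
NEBD, so duration = (NEBD − start)·frame interval — by construction an
integer multiple of the frame interval (12 min for the G2 assay). A single
foci-absent frame flanked by visible frames is treated as annotation
flicker and ignored. Tracks whose window ends before NEBD are censored and
excluded from per-dose means (not imputed); tracks with no foci epoch are
invalid. Whether the G2 start frame is inclusive is a convention the
source assays leave open; the one above is declared and fixed.

Cytokinesis outcome: failure on any binucleated daughter, or a single
daughter with no midbody; success on midbody plus two mononucleated
daughters; anything else indeterminate. Per-dose statistics (mean G2
duration; % failure among determinate tracks) feed the same 4PL fitter,
with the rising orientation giving the assay midpoint.

## Synthetic-data generators

All generators take an explicit seed (`numpy.random.default_rng`) and are
byte-identical under a fixed seed; emitted objects satisfy the invariants
of the types they instantiate. Defaults encode the emulated study
conditions: [E]t = 0.4 nM active kinase, [ATP] = Km, triplicate 24-point
curves at 2% multiplicative CV (plate-reader noise is proportional to
signal); 16 cells per 256×256 field at 50% mitotic fraction, ≥ 20 mitotic
cells per 4-field dose point; 12-min/5-min frame intervals over a 24-h
window with 60 tracks per dose (within the 40–100-cell cohorts typical of
manual tracking); G2 baseline 240 min (sd 45), maximal lengthening
+360 min; cytokinesis failure 5% baseline rising to 90%.

Image fields place non-overlapping disk cells on a flat background
(level 10 counts, Gaussian camera noise sd 5). Mitotic cells receive a
bright MPM2 disk, two pole foci in the pLATS2 channel and a chromatin disk
in the pH3 channel, with amplitudes ~500 counts scaled by a per-marker 4PL
of dose and a per-cell lognormal factor (10% CV). Foci and chromatin are
uniform-intensity (top-hat) disks rather than Gaussian spots: with a
frozen intensity threshold, the mean over a thresholded Gaussian spot is a
logarithmic, not linear, function of the planted amplitude (the surviving
mask shrinks with dose), which would shift the measured curve's midpoint
off the planted IC50 by tens of percent and make the planted value an
invalid truth reference. Top-hat objects keep the object-mean readout
proportional to the planted activity fraction, so the planted midpoint is
the correct recovery target; with amplitude ≫ background the residual
midpoint bias from the un-subtracted background is < 2%. The renderer
consequently tests the pipeline's operators (gating, morphology,
measurement, normalization, fitting), not photorealism: real fields add
autofluorescence gradients, focus variation, touching cells and
non-mitotic marker signal that this generator deliberately omits, so
passing recovery tests demonstrates correctness of the analysis chain, not
robustness to those artifacts.

Live tracks draw G2 durations from Normal(baseline + shift·r(dose), sd)
truncated at one frame and rounded to the frame grid, and cytokinesis
failures from Bernoulli(baseline + span·r(dose)), with r a rising 4PL.
The two effects have independent midpoints, so an Aurora A-like compound
lengthens G2 without raising the failure rate and vice versa — the
specificity contract the tests exercise. At 60 cells per dose the failure
fraction has ~6-percentage-point binomial sd near the midpoint, so
single-cohort midpoint estimates scatter by tens of percent; summary
statistics therefore use medians over replicate seeded cohorts.

## Problem sizes used in checks

The reproduction checks run at desk scale: 20 simulated plates per Ki
across Ki ∈ {0.02, 0.2, 2, 20, 200} nM (pooled median error reported), 10
imaging series of 8 doses × 4 fields, and 9 (G2) / 21 (cytokinesis)
replicate track cohorts of 11 doses × 60 tracks. These sizes were chosen
so each summary statistic (median, rate) is stable across seeds while a
full run completes in well under a minute of compute per stage.

## Known limitations

- Equilibrium-only biochemistry: no time-dependent (slow-binding) model,
  no mechanism discrimination beyond assumed ATP-competition, no modeling
  of the coupled luminescence chemistry.
- Cellular: no instance segmentation beyond MPM2 connected components, no
  illumination correction, 2-D projections only.
- Live: annotations are the input; no pixel-based tracking or NEBD
  detection, no lineage reconstruction.
- The cellular and live generators are statistical stand-ins; quantitative
  claims about real microscopy data require the acquisition-matched
  thresholds and controls described above.
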