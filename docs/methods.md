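# Methods

`dsdpore` models a nanopore-array readout of DNA strand-displacement (DSD)
circuits end to end: circuit kinetics as mass-action ODEs, the flow cell as a
bank of independent pores with periodic voltage-flip ejection, and the
analysis chain (event detection → feature/length filtering → raw-signal
barcode classification → capture-statistics quantification) as it would run
on real bulk current data.  This note records the model assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Circuit kinetics

Circuits are deterministic mass-action networks in micromolar/second units.
The catalytic seesaw gate is two reversible bimolecular steps,

    input + gate         <->  intermediate + output      (k_d, k_d·ρ)
    fuel  + intermediate <->  waste + input               (k_f, k_f·ρ)

with defaults k_d = k_f = 0.1 µM⁻¹s⁻¹ (= 1×10⁵ M⁻¹s⁻¹, the typical
toehold-mediated displacement scale) and reversibility ratio ρ = 0.01.  The
forward bias is a design choice: toehold asymmetry makes displacement
strongly forward in engineered seesaw gates, and a symmetric choice (ρ = 1)
caps the catalytic displaced fraction at ~0.81 for the standard
0.5 µM gate / 2 µM fuel / 0.2 µM input operating point, whereas these
circuits are engineered for near-complete turnover.  Both rates and ρ are
per-reaction configurable; only relative kinetics are asserted anywhere.

An optional leak reaction `gate + reporter → gate:reporter + quencher`
models blunt-end stacking on a fluorophore/quencher reporter.  It produces a
spurious *fluorescent* signal but releases no barcoded output — a direct
readout of the free output strand is leak-free by construction, which is the
mechanistic point the leak term exists to demonstrate.  Streptavidin is
always in excess and is treated as instantaneous (not a kinetic species).

Competitive miRNA probes (the let-7 panel) are single-turnover:
one irreversible displacement per nonzero entry of an
(inputs × probes) rate matrix, with off-diagonal entries encoding
crosstalk (default panel: let-7e → let-7a probe at 0.1 × the on-target
rate).  No fuel reactions exist in probe systems.

Integration uses `scipy.integrate.solve_ivp` (LSODA) with rtol 1e-10 and
atol 1e-13 µM on a fixed output grid.  These are tighter than strictly
needed for the trajectories themselves; they keep every strand-conservation
linear combination constant to better than 1e-8 relative over multi-hour
horizons, which the test suite asserts.  Each species can declare its strand
composition, so conservation is checked mechanically, and every reaction is
validated for strand balance at construction.  Concentrations more negative
than −1e-9 µM abort the run (no silent clipping); smaller excursions within
integrator tolerance are zeroed.

## Synthetic nanopore signal

Each channel is an independent pore sampled at 10 kHz with Gaussian
open-pore current (default 220 ± 2 pA).  A voltage flip every
`flip_period` (default 15 s; 10 s also used in practice — configurable)
ejects any captured strand; the flip itself is rendered as a 0.1 s saturated
negative excursion, which is how the analysis stage finds segment
boundaries (negative current cannot occur in an intact pore at positive
bias).

Between flips, the waiting time to capture is exponential with rate
`capture_rate_per_uM × Σ concentrations` (competing barcodes chosen
proportional to concentration; concentrations held piecewise-constant per
15 s cycle, far shorter than any circuit timescale here).  The default
capture rate, 0.2 s⁻¹µM⁻¹, puts the mean time between captures at 10 s per
pore for a 0.5 µM strand.  A captured strand is stoppered by
biotin–streptavidin and blocks the pore until the next flip, so event
duration = capture time to next flip boundary — this is what makes a ≥ 2 s
length filter meaningful.

A blockade's fractional current is `mean_fractional_current` plus a
per-event level offset ~N(0, `level_sd`) (capture-to-capture and
pore-to-pore variability), plus i.i.d. per-sample noise
~N(0, `within_event_sd`), optionally plus two-state telegraph flicker
(`flicker_depth`, `flicker_rate`) emulating the multi-level noise structure
of real blockades.  Models with mean fractional current ≥ 0.7 are rejected
at construction: they would sit above the detection threshold by design.
Background noise blockades are short (default < 1.5 s), arbitrary-leveled,
high-variance events injected into open-pore stretches; by construction
they violate the length filter or the feature envelopes.

What the generator does **not** emulate: channel death and recovery, open-pore
drift over hours, ASIC digitization artifacts, autocorrelated (pink) noise,
and any within-event sequence structure beyond the telegraph term.  Passing
tests therefore demonstrate the correctness of the pipeline's logic and its
statistical calibration against a known ground truth — not robustness to
every failure mode of real flow cells.

## Event detection and filtering

Analysis segments are maximal non-negative stretches between flip artifacts.
The open-pore level I_o is estimated per segment as the median of samples
above 0.9 × the segment maximum — robust to blockades occupying most of the
segment; a segment whose estimate falls outside a plausible window
(default 150–400 pA) is skipped as having no open pore.  A capture event is
a maximal run of samples at or below 0.7 × I_o lasting strictly longer than
1 ms (10 samples at 10 kHz); events are truncated at flip boundaries and
never merged across them (physical ejection).  The span convention is
[first below-threshold sample, one past the last), times = index / rate.
The event detector is vectorized run-length coding, and its boundaries are
asserted identical to an independent per-sample reference scan in the tests.

Each event carries five features of its fractional-current trace — mean,
median, minimum, maximum, standard deviation (sample sd, ddof = 1).  The
noise filter keeps an event iff all five features fall inside per-feature
envelopes and its duration is ≥ 2 s.  Envelopes are calibrated empirically:
per feature, the union over barcodes of the central 99.5% quantile interval
of characterization events, padded by 5% of its width.  The filter spec
records its provenance (global default vs calibrated per experiment), since
either convention is defensible.

One wrinkle matters for quantification: in single-barcode experiments no
classifier is needed, and applying the 2 s length filter to *counting* (its
only purpose is to guarantee a full classification window) would drop
ejection-limited captures that start near a flip and bias waiting-time
statistics upward by 10–20%.  Labeling in single-barcode runs therefore
uses only the mean/median envelopes (the two features whose calibration
transfers to arbitrarily short events) with the 1 ms detection floor.
Multi-barcode runs keep the full filter; their frequency quantities are
ratios of identically-filtered runs, so the convention cancels.

## Classification

The window is the first 2 s of the event (20,000 fractional-current samples)
reshaped row-major to 100 × 200 (the reshape dimensions are a free choice;
they are configurable and recorded with every model).  Classifier families:

* `logreg_mean` — logistic regression on the event mean (internally
  standardized, weak regularization: multi-way interval boundaries on a
  single feature need sharp logits);
* `random_forest_5feat` — random forest (200 trees) on the five features;
* `cnn4` — four conv(3×3)+ReLU+maxpool(2×2) layers over channels
  (8, 16, 32, 32), a fully connected layer with log-sigmoid activation, and
  a per-class output layer;
* `resnet18_style` — a residual CNN (stem conv, stages of identity-skip
  blocks with channel-doubling downsampling transitions); depth is
  configurable and shallow by default, sized for CPU training.

The neural families run on a small numpy engine written for this package
(im2col convolutions, Adam, softmax cross-entropy, float32 throughout,
fully seeded).  Before the first convolution the 2D window is average-pooled
5× and affinely rescaled ((x − 0.4)/0.15): blockade structure lives far
below the 10 kHz bandwidth, and the pooling makes single-core training take
minutes rather than hours.  Confidence is the softmax-normalized score of
the argmax class; an optional preset threshold (e.g. 0.9) filters out
low-confidence predictions, which downstream stages then treat as
pore-occupying but unreadable.

Training contracts: the sample is capped at the smallest class, split
80/20 stratified by class, and fully determined by the spec seed.  The
default epoch budget is 250; the suite and the acceptance script train for
25 and 15 epochs respectively (seeds recorded in each spec) — on the preset
barcode sets the loss plateaus well before epoch 10, so the reduced budgets
change nothing but runtime.  Models serialize to disk (weights + spec +
training manifest) and reload bit-identically.

The preset barcode sets define two regimes.  The *separable* set has ten
levels spaced 0.05 apart with within-event sd 0.0125 (gap = 4× sd) — the
high-accuracy regime.  The *hard* set overlaps deliberately: two barcodes
share a crowded mean region and differ mainly in noise amplitude, and two
have identical levels and stationary moments but flicker at 2 vs 40 s⁻¹, so
only temporal structure separates them.  This is what produces the accuracy
ladder (mean-only < five-feature forest < CNN) asserted in the tests:
each model class sees strictly more of the signal's structure.

## Quantification

Time between captures (TBC) is the unoccupied waiting time between
consecutive same-barcode captures at a pore: `start₂ − end₁` minus the total
duration of any other-label blockades (noise, other barcodes, unclassified)
inside the gap; gaps pool across all functional pores.  Negative corrected
gaps are an integrity error and are surfaced, never clamped.  A "good
channel" is one with at least one valid open-pore segment.

The standard curve is `TBC = a/C + b` — the first-order capture law, with
`b` absorbing per-capture dead time — fitted by inverse-variance weighted
least squares on 1/C.  For the per-point "average TBC", the curve consumes
the exposure estimate (total unoccupied open-pore seconds / number of
captures) rather than the plain mean of completed gaps: when a run lasts
only a few mean waiting times (the low end of a titration), the final,
length-biased gap is censored by the run end and the naive mean is biased
low by 10–25%; the exposure form is the censoring-aware maximum-likelihood
mean for exponential waiting.  Both values are reported in titration tables.
Titration presets use the 0.02–1 µM grid with longer runs and more pooled
pores at low concentration (20 min / 64 pores at 0.02 µM down to
10 min / 10 pores at 1 µM), sized so the fitted `a` lands within a few
percent of truth.

Normalization is the exact affine map `(x − background)/(saturated −
background)`, applied to TBC, to capture frequency (reads per good channel
per minute), or to curve-converted concentration.  No clamping: values
slightly outside [0, 1] are meaningful.  Kinetics series bin the run into
5-minute intervals, assigning each gap to the bin of its gap midpoint (a
convention; events are assigned by event midpoint for frequency).  Bins
with no contributing gaps are emitted as missing, never zero-filled.  Note
that TBC is affine in 1/C, so Eq.-style normalization of raw TBC is *not*
linear in concentration; when a kinetics trace is to be compared against a
concentration trajectory, the `concentration` metric (TBC → C through the
standard curve, then the affine map) is the right choice and is what the
end-to-end tests use.  Background and saturated references are measured
through the identical pipeline: a no-input run and a separate
fully-displaced-output run.

## Problem sizes and numerical conventions

The test suite and `scripts/acceptance.py` run everything at desk scale,
chosen as the package's own demonstration sizes: detector/oracle
equivalence over 100 (tests) or 20 (script) seeded traces of 1–10 minutes;
the five-point titration as above; the separable-set CNN at 1000 (tests) or
300 (script) events per class; end-to-end kinetics on a 30-channel array over 50 minutes with the slow demonstration rate set
(4×10⁻³ µM⁻¹s⁻¹, so the rise spans ~8 bins); multiplex profiles at 12–24
channels and 10-minute samples with shared reference measurements.  Traces
are generated and analyzed one channel at a time, and stored event arrays
are truncated beyond 2.5 s (features are computed first), keeping peak
memory under ~2 GB.

Known limitations: pores are independent and immortal; capture physics is
first-order in concentration with no saturation of the capture cross
section; classification operates on fractional current (a flag exists to
switch to raw pA, at the cost of cross-channel comparability); the
confidence measure is post-softmax score, which is not a calibrated
probability; and the deterministic ODE layer ignores copy-number noise,
which is negligible at ≥ nM concentrations in µL volumes.
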