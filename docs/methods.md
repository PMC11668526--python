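# Methods

## Scope and model

The package analyzes population calcium imaging of the two zebrafish
gonadotroph types (LH-like and FSH-like cells) and ships a generative model
of such recordings.  The analysis chain is fixed: raw fluorescence →
block-minimum ΔF/F → conditional zero-phase low-pass → (a) transient
detection and kinetics, (b) lag-maximized pairwise cross-correlation, (c)
percentile-rule responsiveness classification across a basal/stimulation
session pair.

## ΔF/F

Per cell, frames are partitioned into consecutive non-overlapping blocks of
N = round(fs × block_seconds) frames (block_seconds default 5).  F₀ is the
minimum of the block means; ΔF/F = F/F₀ − 1.  A trailing partial block
participates iff it has ≥ N/2 frames — without this, a session that is not
an exact multiple of 5 s could lose its quietest stretch.  Whether blocks
should overlap is not constrained by the conventions this follows;
non-overlapping blocks were chosen and are flagged here.  By construction
the minimum block-mean of ΔF/F is exactly 0 per cell, and ΔF/F is invariant
to rescaling the raw trace (tested) but not to additive offsets
(counter-example test).

When fs exceeds 4 Hz (strictly — the 4 Hz boundary is not filtered), a
low-pass Butterworth of order 4 with Nyquist-normalized cutoff
2 Hz/(fs/2) is applied forward–backward (`filtfilt`).  The filter family
and order are a declared choice; zero-phase filtering was chosen so event
timing feeding the synchrony stage is unbiased (tested: a slow sinusoid
peaks at lag 0 against its filtered version; DC gain 1 within 1e−3).
Filtering operates on ΔF/F, after normalization.

## Transient detection

The reference detector per cell: baseline = median of the trace, noise =
1.4826 × MAD, threshold = baseline + k·noise (k default 3), event = maximal
run above threshold lasting ≥ 1 s; amplitude = run maximum − baseline;
half-width = full width at half maximum around the peak, crossings located
by linear interpolation while walking outward from the peak over the whole
trace.  Events whose half-level crossings leave the session are reported
with a missing half-width, not extrapolated.  Sub-peaks inside one run are
not split.

Two intrinsic biases are worth knowing:

* **Tail chatter.** The transient waveform decays exponentially, so near
  the threshold the trace lingers; noise dips split the tail into
  additional low-amplitude "events" (~0.2–0.3 ΔF/F at the shipped noise
  levels, roughly a fifth of detections on busy traces).  They lower pooled
  mean amplitudes slightly; the recovery tolerances absorb this.
* **Global-median baseline.** An event that occupies a large fraction of
  the session raises the median, which lowers the measured amplitude and
  (because the half level rides on the amplitude) shortens the measured
  half-width — about −3% at 75 s width in a 10-min session, −14% at 125 s.
  Kinetics unbiasedness is therefore asserted (to <2%) on *isolated*
  waveforms on long quiet traces; preset recovery targets carry ±15%.

## Synchrony

For each pair, mean-subtracted traces are cross-correlated over lags −L..L
(L = round(maxlag × fs), maxlag default 30 s — common toolkits default to
n−1 lags, which inflates the maximum under noise), normalized by the
geometric mean of zero-lag autocorrelations; the maximum over lags and its
lag are recorded (ties resolve to the smallest |lag|).  Mean subtraction is
deliberate: a shared baseline would otherwise push all coefficients toward
1.  Zero-variance traces get missing rows/columns and a warning.
Population synchrony averages unordered off-diagonal pairs; the
reference-ROI mode ("auto" = highest-variance cell of the population of
interest) scores each cell against one reference.  An O(n²·lags·frames)
direct-sum oracle pins the FFT implementation to 1e−8.

Which of the two modes the per-fish summaries of the original workflow
averaged is ambiguous; both are provided, all-pairs being the default for
population means and the reference vector the default for per-cell
responsiveness coefficients.

## Responsiveness

Threshold = linear-interpolation percentile (default 80th) of the basal
per-cell coefficients, per fish and per population (not pooled across
fish); responsive ⇔ stimulation coefficient strictly above it.  Cells with
a missing coefficient in either session leave both numerator and
denominator.  Note a structural property: if stimulation resembles basal,
~20% of cells exceed the 80th percentile by exchangeability, so recovered
responder percentages sit a few points above the generator's true responder
fraction when that fraction is below 1 — the binomial-interval tolerance on
those targets accounts for it.  Pre/post hormone comparisons use the exact
one-sided Wilcoxon signed-rank test (exact null for n ≤ 25, enumeration-
tested); population contrasts dispatch to the two-tailed unpaired t test or
one-way ANOVA with Tukey–Kramer (type-I error calibration tested at
0.035–0.065 for α = 0.05).

## Synthetic recordings

Raw fluorescence per cell:

    F(t) = B · (1 + Σ events w(t) + drift(t)) · e^(−βt) + B · ε(t),

with B log-normal across cells (cv 0.2), ε white Gaussian photon noise,
drift a Gaussian process (white noise smoothed with a 60 s kernel) and β a
mild bleach rate.  Traces are floored at 1% of B so raw fluorescence stays
strictly positive.  The transient waveform is a product of exponentials
w(t) = A·k·(1 − e^(−t/τr))·e^(−t/τd), τr = 0.1 × target half-width, τd
solved by bisection (10⁻⁴ s) so the realized FWHM equals the drawn
half-width (within 2% after 10 Hz sampling; tested), k normalizing the peak
to A.  Event placement: independent Poisson bursts with a refractory gap
(next onset ≥ previous onset + 2× half-width), shared population events
with per-cell participation, Gaussian onset jitter, and log-normal
amplitude/duration scatter, and stimulus-evoked events given to a
Bernoulli responder subset with half-normal latencies.  An evoked event
whose 99%-mass tail would pass the last frame is rejected at simulation
time.  All randomness flows from one seeded generator; identical spec +
seed reproduces bit-identical traces and ground truth.

### Preset calibration

Fields with published anchors (burst/event kinetics, responder fractions,
population coefficients, event rates) are hard-coded to those numbers in
`presets.yaml`.  Free fields were fixed once by the sweeps in
`analysis/00_calibrate_presets.py` and not revisited:

* **Noise levels.** Ex vivo: photon noise 3% of baseline, drift 1%,
  bleach 2×10⁻⁵ s⁻¹ (~1% per session; a stronger bleach would let the
  block-minimum F₀ come from the faded session end and inflate early-event
  ΔF/F).  In vivo basal recordings (water-flow chamber, galvo scanning) use
  5% noise and 3% drift, which also sets the detector threshold high enough
  that tail chatter stays small next to the 0.6 ΔF/F bursts.
* **LH synchronized event.** With a single shared event, the ±30 s lag
  search absorbs any onset jitter smaller than the window, so pairwise
  coefficients saturate near 1 regardless of jitter — the anchored 0.89
  is unreachable by noise alone at realistic levels.  Two mechanisms the
  lag search cannot undo were calibrated: onset dispersion *comparable to
  the lag cap* (jitter SD 24 s on a 75 s-wide event; pairs whose offset
  exceeds the window lose correlation while detected kinetics are
  untouched) and per-cell event-duration scatter (cv 0.2, shape mismatch).
  The published coefficient below 1 implies such independent structure in
  the real traces.
* **FSH follow-event.** Amplitude 0.95 / width 30 s (unpublished; free),
  jitter 8 s, duration scatter 0.3; the basal burst background (rate 4,
  published range 1–7) supplies the rest of the decorrelation to the 0.66
  anchor.
* **CCK response widths.** The published per-fish half-width range
  (40.3–172 s) fixes the mean to 60 s — inside the range and the largest
  value whose 99% tail fits a 10-min session with the 30 s stimulus onset —
  and motivates a wide per-cell duration cv (0.7), which lands the FSH
  coefficient on its 0.7 anchor.
* **Unpublished responder details.** GnRH-evoked FSH kinetics (1.2 ΔF/F,
  30 s) are free but must clear the percentile rule; CCK LH participation
  uses 0.6, the midpoint of the published 20–100% range.
* **Basal ex vivo LH.** Small transients (published ranges → means 0.445
  ΔF/F, 5.4 s) at rate 2, with five small-group shared events
  (participation 0.35, jitter 1.5 s) reproducing "synchronized between
  small groups of neighbouring cells".

### What a green test does and does not establish

The generator reproduces the *statistical* structure of the recordings:
two populations, their kinetics, synchrony levels, responder fractions,
photon noise, drift, bleach.  It does not model motion artifacts, ROI
segmentation errors, overlapping cells, spike-to-calcium nonlinearity, or
gap-junction biophysics; passing recovery tests therefore establishes that
the pipeline measures what the model emits at realistic noise, not that it
is robust to un-modelled artifacts (motion correction is assumed done
upstream).

## Numerical choices

* Percentile definition: numpy linear interpolation; strict inequality at
  the threshold (both documented so re-implementations match).
* Correlation tie-break: smallest |lag|.
* FWHM solver: brentq on τd, tolerance 10⁻⁴ s; cached per
  (half-width, rise fraction).
* ROI geometry: circular masks, pixel centre strictly within radius;
  freehand ROI shapes of real exports are not recoverable, circles are the
  declared stand-in.  Rendered cells are Gaussian-profile disks scaled so
  the mask mean equals the trace value (round-trip correlation > 0.99,
  tested).
* Trace CSVs carry 6 decimals; round trips are bit-exact at that
  precision.
* Wilcoxon: exact method for n ≤ 25 without ties, normal approximation
  otherwise.

## Known limitations

* The detector's global-median baseline biases very long events (above);
  use longer sessions or a local-baseline detector when events occupy
  >20% of a recording.
* Mean per-population coefficients on 20-cell sessions carry a seed-to-seed
  SD of ~0.04 (five-replicate means); tolerance bands on synchrony targets
  are read with that in mind.
* The percentile rule's ~20% exchangeability floor makes responder
  percentages conservative only above that floor.
* `maxlag` caps the detectable inter-cell delay; events offset by more
  than the window score as unsynchronized by construction.
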