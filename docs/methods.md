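# Methods note

This note records the mathematical definitions, the synthetic instrument
model and its calibration, the numerical choices, and the limitations of the
`mapsfc` pipeline. All data produced by this package are synthetic.

## 1. Acquisition model

Default digitizer geometry (`AcquisitionConfig`):

| parameter | default | unit |
| --- | --- | --- |
| sampling rate | 10 | MHz (0.1 µs/sample) |
| recorded window | 8 (max 16) | µs (80 samples) |
| trigger point | 2 | µs (sample index 20) |
| channels | 8 (SSC, FSCL, FSCM, FSCU, FL-PI, FL-FITC, AUX1, AUX2) | — |
| ADC | 16 | bit (0–65535 counts) |
| analog low-pass | 7 | MHz |

One event is an 8 × 80 uint16 matrix; 640 data points per event. Pulses are
stored raw in the fixed-stride, versioned `.psb` container; the conventional
height/area/width scalars (H = max above baseline, A = clipped integral in
counts·µs, W = time between linearly interpolated 50 %-of-height crossings)
plus the fluorescence scalars go to a linked FCS 3.0 list-mode file, joined on
`event_id`.

## 2. MODWT features and level selection

The maximum-overlap DWT uses the pyramid algorithm with filters rescaled by
1/√2 per level and circular boundary handling. It is shift-equivariant, keeps
one coefficient per sample at every level, and satisfies exactly

- energy: ‖x‖² = Σⱼ ‖Wⱼ‖² + ‖V_J‖², and
- additive MRA: x = Σⱼ Dⱼ + S_J.

Both identities are enforced in tests to 1e−8 relative, and the pyramid output
is checked to 1e−10 against an independent oracle that builds the equivalent
level-j filters by upsample-and-convolve cascades and applies them by direct
circular convolution. With 80-sample pulses, levels 1–6 are available
(2⁶ = 64 ≤ 80).

**Level selection.** For each level j, every pulse is reconstructed from that
level alone (MRA component Dⱼ); the standard deviation across events is taken
at each of the 80 timepoints and summed. The feature level maximizes this sum
(ties break toward the smaller level; a cohort with no variation raises a
degenerate-data error, using a threshold of ~16·eps per sample relative to the
data scale so that bitwise-identical pulses are detected despite matmul
rounding noise). On synthetic cohorts at realistic pulse scales the procedure
selects Haar level 4 — the band of ~0.8–1.6 µs structure at 10 MHz — on both
FSCL and FSCU, with a ≈14 % margin over level 5 across seeds. The selected
level's 80 detail coefficients per event (no normalization, so amplitude stays
informative) are the cluster features.

## 3. Clustering and phase mapping

Per channel, k-means (k = 8, k-means++, 10 restarts, Lloyd) quantizes the
feature vectors. Centroids are reordered by descending L2 norm (coordinates as
tiebreak) so cluster numbering is seed- and machine-stable; a SHA-256
fingerprint over the rounded centroids plus metadata identifies the model.
FSCL × FSCU labels combine into 64 clusters (id = a·8 + b).

Reference gates: the singlet gate fits a robust linear PI-W ~ PI-H trend (on
the core within 3 MAD of the median width) and keeps events within 2 robust SD
of it; the BrdU threshold is the valley between the two largest modes of the
log₁₀ FITC histogram; the PI 2N window is µ ± 2σ of the 2N mode among
BrdU-negative singlets and the 4N window is 2µ ± 2·(2σ) — the spread scales
with the mean. S takes precedence over the PI windows (BrdU is the more
specific S marker).

For cluster c and phase p the enrichment factor is e(c,p) = f_c(p)/f_all(p),
computed over labeled singlets; it satisfies Σₚ f_all(p)·e(c,p) = 1 (tested).
Clusters under 0.5 % of events are excluded (`below_cutoff`). A cluster is
pure G1 or G2/M when that enrichment ≥ 1.5 and the others stay < 1.1; it is a
mixed group (G1&S / S&G1 / S&G2M) when its two top phases are cell-cycle
adjacent and both reach 1.1; otherwise undefined. G1–G2/M is non-adjacent: no
mixed group exists for that pair. The thresholds (t_specific = 1.5,
t_mixed = 1.1) and the enrichment convention are documented free parameters of
this package.

Centroid transfer assigns new acquisitions to the frozen reference centroids
by nearest-centroid rule; fingerprints are compared before any cross-sample
report. The arrest rule labels clusters that grow ≥ 1.2-fold in a sample taken
right after release from a G2 arrest as G2/M and clusters that shrink by the
reciprocal factor as G1&S, with no fluorescence used.

## 4. Synthetic instrument model

Morphology is modeled phenomenologically from the observed pulse vocabulary,
not from electromagnetic scattering theory. Per event, a cell-cycle class is
drawn from the mixture (defaults 0.5/0.3/0.2 for G1/S/G2M), then diameter
(12/13/14.5 µm mean, CV 8 %), per-channel peak distance
(G1 2.5, S 2.75, G2M 3.0 µs on FSCL/FSCU, SD 0.1 µs), and amplitude ratio
(growing with phase, strongest on FSCU: 1.10 → 1.35 → 1.60).

The optical profile along the flow axis is, per two-lobe channel, two lobes
separated by the drawn peak distance (converted to µm via the 5 m/s flow
speed), with a bridge between them: a dip to 40 % of the smaller lobe by
default, or — for 30 % of S-phase cells — a plateau at 75 % with a sinusoidal
modulation. SSC is a single Gaussian with width 0.25·diameter. Amplitude
scales with diameter². The profile is convolved with the Gaussian beam
(5.75 µm FWHM / 5 m/s → 1.15 µs transit FWHM; unit-integral kernel), low-pass
filtered at 7 MHz on a 10× oversampled grid (the analog cutoff exceeds the
5 MHz digital Nyquist, so filtering must precede decimation), decimated to
10 MHz, offset by the baseline (12,000 counts) plus Gaussian noise (SD 15),
and quantized to uint16. Events are generated on the maximum 16 µs raw window
and aligned so the first upward SSC threshold crossing sits at sample 20;
events that never trigger are rejected and logged.

**Lobe sharpening (difference of Gaussians).** Recorded forward-scatter peaks
on real instruments are narrower (0.6–1.0 µs FWHM) than the 1.15 µs beam
transit — the angular scattering pattern has diffraction-like structure and is
not a plain intensity image of the cell, so a nonnegative profile convolved
with the beam cannot reproduce it. Each lobe is therefore a difference of
Gaussians: a sharp core (σ = 0.10·diameter) with weight (1+k) minus a wider
negative surround (scale α·σ) with weight k/α. The calibration was driven by
the measured cohort peak FWHM: a surround comparable to the beam width (α = 2)
barely narrows the recorded peak (~1.45 µs); α = 3, k = 3 brings the median
FWHM to ~1.05 µs, the closest the convolution model gets to the sub-beam band
without clipping the ADC floor. The undershoot (~25 % of peak) is why the
baseline default is 12,000 counts. A residual gap to the 0.6–1.0 µs band
remains; it is a structural limit of the convolution model, not a tuning
artifact.

**Peak-distance calibration.** The inter-peak bridge pulls the convolved
maxima inward, so the effective lobe separation is calibrated per event by a
3-iteration fixed point until the *measured* post-beam peak distance equals
the drawn ground truth (class parameters describe distances as measured on
recorded pulses). Residual per-event recovery error: mean −0.001 µs, 95th
percentile ≤ 0.1 µs (one sample), worst case ~0.11 µs.

Doublets (2 % by default) are sums of two time-offset singlets (offset
2.0 ± 0.4 µs); PI area and FITC add exactly, PI width is inflated by the
offset. FSCM is a noisy, gain-jittered copy of FSCU (the detectors are
redundant). Fluorescence scalars: PI-H at 2N (20,000) for G1, 4N (40,000) for
G2/M, uniform in between for S (CV 4 %); FITC lognormal, high only for S.

## 5. What passing on synthetic data shows — and what it does not

The suite demonstrates that the *analysis* is implemented correctly: the
MODWT satisfies its exact identities and matches an independent construction;
the level-selection procedure, enrichment arithmetic, group rules, centroid
transfer, and determinism behave as specified; and when the generator encodes
the documented class differences, the pipeline recovers them (level 4
features, 0.5 µs peak-distance offset, pure G1/G2M clusters, sorted-aliquot
enrichment). It does **not** validate the biology: the generator is
phenomenological, its class separations are put in by construction, and
passing here says nothing about classification performance on a real
instrument, real cell lines, or morphologies outside the modeled vocabulary.

## 6. Numerical choices and limitations

- MODWT uses circular boundaries (exact identities); reflection is available
  and the identities then hold on the analyzed extension.
- K-means uses unscaled coefficients deliberately; amplitude carries class
  information. Results are bit-reproducible given the seed.
- The PI 4N window scales its spread with the mean (2σ → 4σ); a constant-width
  window under-covers the 4N peak because PI CV is multiplicative.
- The trigger threshold defaults to baseline + max(12·SD, 100) counts.
- The enrichment definition, group thresholds, gate widths, and all generator
  parameters are package conventions, documented above, not measured values.
- The FCS writer emits a minimal single-dataset FCS 3.0 (float32, little
  endian) sufficient for round-tripping numeric parameters; it does not aim at
  full standard coverage (no analysis segment, no compensation keywords).
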