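"""Synthetic multi-angle pulse-shape cohorts with cell-cycle ground truth.

Emulates the instrument's signal chain so every downstream stage can be
exercised without measured data: an optical-response profile along the flow
axis per cell and scatter channel, convolution with the Gaussian laser-beam
profile (5.75 um FWHM short axis, ~5 m/s flow, hence a 1.15 us transit
FWHM), a 7 MHz analog low-pass, 10 MHz sampling, 16-bit quantization, and
SSC-triggered window alignment (trigger point at 2 us).

Cell-cycle morphology is modeled phenomenologically from the observed
pulse vocabulary rather than from scattering physics: forward-scatter
pulses are two Gaussian lobes whose separation (*peak distance*) grows by
0.5 us from G1 to G2/M, whose amplitude ratio grows with phase in FSCU,
and whose inter-peak dip is replaced in a fraction of S-phase cells by a
plateau with oscillatory modulation. Cell size grows G1 < S < G2/M and
scales pulse amplitude. SSC is single-lobed with width proportional to
diameter. FSCM is generated as a noisy copy of FSCU (the two detectors are
redundant). Matched fluorescence scalars provide the reference labels: PI
at 2N for G1, 4N for G2/M, uniform in between for S, and BrdU-FITC high
for S-phase cells only. Doublets are sums of two time-offset singlets with
summed PI area and inflated PI width.

The 7 MHz analog cutoff exceeds the 5 MHz digital Nyquist; the low-pass is
applied on a 10x-oversampled grid before decimation, which mirrors the
analog electronics and avoids aliasing artifacts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ContractError
from .io import AcquisitionConfig, PulseDataset, derive_haw_table

logger = logging.getLogger(__name__)

TWO_LOBE_CHANNELS = ("FSCL", "FSCM", "FSCU")
SCATTER_CHANNELS = ("SSC",) + TWO_LOBE_CHANNELS

# base pulse amplitude (ADC counts) per channel at the 13 um reference diameter
_AMP0 = {"SSC": 9000.0, "FSCL": 15000.0, "FSCM": 12000.0, "FSCU": 12000.0}
_REF_DIAMETER = 13.0
_LOBE_WIDTH_FRAC = 0.10   # lobe sigma as a fraction of cell diameter (um)
_SSC_WIDTH_FRAC = 0.25    # SSC sigma as a fraction of diameter (um)
_LOBE_SHARPEN = 3.0       # weight of the negative surround in each lobe
_LOBE_SURROUND_SCALE = 3.0  # surround sigma relative to the core sigma


@dataclass(frozen=True)
class BeamModel:
    """Gaussian laser-spot profile along the flow axis."""

    fwhm_um: float = 5.75
    flow_speed_m_s: float = 5.0

    def __post_init__(self):
        if self.fwhm_um <= 0 or self.flow_speed_m_s <= 0:
            raise ContractError("beam FWHM and flow speed must be positive")

    @property
    def transit_fwhm_us(self) -> float:
        # um / (m/s) = us
        return self.fwhm_um / self.flow_speed_m_s

    @property
    def sigma_um(self) -> float:
        return self.fwhm_um / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class CellClassSpec:
    """Morphology and fluorescence distribution of one cell-cycle class.

    Peak distances and amplitude ratios are per two-lobe scatter channel
    (FSCM inherits FSCU). PI is a normal around ``pi_mean`` unless
    ``pi_range`` is given (uniform between 2N and 4N for S-phase cells).
    """

    phase: str
    mixture_weight: float
    diameter_mean_um: float
    diameter_cv: float = 0.08
    peak_distance_us: dict = field(default_factory=dict)   # channel -> (mean, sd)
    amplitude_ratio: dict = field(default_factory=dict)    # channel -> (mean, sd)
    dip_depth: float = 0.6
    s_phase_plateau_prob: float = 0.0
    s_phase_oscillation_amp: float = 0.15
    pi_mean: float = 20000.0
    pi_cv: float = 0.04
    pi_range: tuple | None = None
    brdu_positive: bool = False


def default_classes() -> list[CellClassSpec]:
    """The three cell-cycle classes at the study's observed pulse scales.

    Peak distance grows by 0.5 us from G1 (2.5 us) to G2/M (3.0 us); the
    FSCU amplitude ratio grows with phase; 30 % of S-phase cells show the
    plateau/oscillation dip morphology; diameters grow G1 < S < G2/M; PI is
    2N for G1, 4N for G2/M and uniform in between for S; only S is BrdU+.
    Mixture weights 0.5/0.3/0.2 mimic an unsynchronized dividing culture.
    """
    pi_2n, pi_4n = 20000.0, 40000.0
    return [
        CellClassSpec(
            phase="G1", mixture_weight=0.5, diameter_mean_um=12.0,
            peak_distance_us={"FSCL": (2.5, 0.10), "FSCU": (2.5, 0.10)},
            amplitude_ratio={"FSCL": (1.05, 0.05), "FSCU": (1.10, 0.07)},
            pi_mean=pi_2n,
        ),
        CellClassSpec(
            phase="S", mixture_weight=0.3, diameter_mean_um=13.0,
            peak_distance_us={"FSCL": (2.75, 0.10), "FSCU": (2.75, 0.10)},
            amplitude_ratio={"FSCL": (1.10, 0.05), "FSCU": (1.35, 0.07)},
            s_phase_plateau_prob=0.3,
            pi_mean=0.5 * (pi_2n + pi_4n), pi_range=(pi_2n, pi_4n),
            brdu_positive=True,
        ),
        CellClassSpec(
            phase="G2M", mixture_weight=0.2, diameter_mean_um=14.5,
            peak_distance_us={"FSCL": (3.0, 0.10), "FSCU": (3.0, 0.10)},
            amplitude_ratio={"FSCL": (1.15, 0.05), "FSCU": (1.60, 0.07)},
            pi_mean=pi_4n,
        ),
    ]


def sorted_classes(classes: list[CellClassSpec], phase: str) -> list[CellClassSpec]:
    """A pure aliquot of one phase (weight 1), emulating FACS sorting."""
    for spec in classes:
        if spec.phase == phase:
            return [CellClassSpec(**{**spec.__dict__, "mixture_weight": 1.0})]
    raise ContractError(f"no class with phase {phase!r}")


@dataclass(frozen=True)
class NoiseModel:
    """Baseline, analog filtering and doublet contamination."""

    baseline_level: float = 12000.0  # offset leaves headroom for the negative
    baseline_sd: float = 15.0        # scatter-lobe surrounds (no ADC clipping)
    lowpass_cutoff: float = 7e6
    doublet_fraction: float = 0.0
    doublet_offset_mean_us: float = 2.0
    doublet_offset_sd_us: float = 0.4

    def __post_init__(self):
        if not 0 <= self.doublet_fraction <= 1:
            raise ContractError("doublet_fraction must be a probability")


def default_noise(doublet_fraction: float = 0.02) -> NoiseModel:
    return NoiseModel(doublet_fraction=doublet_fraction)


# ---------------------------------------------------------------------------
# Per-event draws


@dataclass
class CellDraw:
    """One event's realized morphology parameters (the ground truth)."""

    phase: str
    diameter_um: float
    peak_distance_us: dict      # channel -> us
    amplitude_ratio: dict       # channel -> ratio
    dip_depth: float
    plateau: bool
    oscillation_amp: float


def _profile_values(x_um: np.ndarray, draw: CellDraw, channel: str,
                    beam_speed_m_s: float, sep_um: float | None = None) -> np.ndarray:
    """Optical-response profile of one cell evaluated at axial positions (um)."""
    amp = _AMP0[channel] * (draw.diameter_um / _REF_DIAMETER) ** 2
    if channel == "SSC":
        sigma = _SSC_WIDTH_FRAC * draw.diameter_um
        return amp * np.exp(-0.5 * (x_um / sigma) ** 2)
    key = "FSCU" if channel == "FSCM" else channel
    sep = sep_um if sep_um is not None else draw.peak_distance_us[key] * beam_speed_m_s
    ratio = draw.amplitude_ratio[key]
    sigma = _LOBE_WIDTH_FRAC * draw.diameter_um
    a1, a2 = amp, amp / ratio

    def lobe(center, a):
        # Gaussian peak with a negative diffraction-like surround: forward
        # scatter edge features are sharper than the illumination transit,
        # so each lobe is a difference of Gaussians whose convolution with
        # the beam keeps the recorded peak FWHM in the observed sub-us range
        n1 = np.exp(-0.5 * ((x_um - center) / sigma) ** 2)
        n2 = np.exp(-0.5 * ((x_um - center) / (_LOBE_SURROUND_SCALE * sigma)) ** 2)
        return a * ((1 + _LOBE_SHARPEN) * n1
                    - (_LOBE_SHARPEN / _LOBE_SURROUND_SCALE) * n2)

    lobes = lobe(-sep / 2, a1) + lobe(sep / 2, a2)
    floor = min(a1, a2)
    if draw.plateau:
        bridge = (0.75 * floor * np.exp(-((x_um / (0.25 * sep)) ** 4))
                  * (1.0 + draw.oscillation_amp * np.sin(2 * np.pi * 3 * x_um / sep)))
    else:
        bridge = (1.0 - draw.dip_depth) * floor * np.exp(-((x_um / (0.25 * sep)) ** 4))
    return lobes + bridge


def make_profile(draw: CellDraw, channel: str, beam: BeamModel | None = None):
    """Continuous optical-response function of axial position for one event.

    Two-lobe channels get two Gaussian peaks separated by the drawn peak
    distance (converted to length via the flow speed), amplitudes set by the
    drawn ratio, and a central dip of the drawn depth — or, for plateau
    events, a flat bridge with sinusoidal modulation. SSC is single-lobed
    with width proportional to diameter. Non-scatter channels are refused.
    """
    if channel not in SCATTER_CHANNELS:
        raise ContractError(f"{channel!r} is not a scatter channel {SCATTER_CHANNELS}")
    beam = beam or BeamModel()

    def profile(x_um):
        return _profile_values(np.asarray(x_um, dtype=np.float64), draw, channel,
                               beam.flow_speed_m_s)

    return profile


# ---------------------------------------------------------------------------
# Signal chain


def _fine_grid(config: AcquisitionConfig, oversample: int,
               duration_us: float | None = None) -> np.ndarray:
    duration = duration_us if duration_us is not None else config.window_us
    dt = config.sample_period_us / oversample
    n = int(round(duration / dt))
    return np.arange(n) * dt


def _beam_kernel(beam: BeamModel, dx_um: float) -> np.ndarray:
    half = int(np.ceil(4 * beam.sigma_um / dx_um))
    x = np.arange(-half, half + 1) * dx_um
    k = np.exp(-0.5 * (x / beam.sigma_um) ** 2)
    return k / k.sum()  # unit integral: convolution preserves profile amplitude


def beam_convolve(profile, beam: BeamModel, config: AcquisitionConfig | None = None,
                  oversample: int = 10, duration_us: float | None = None,
                  center_us: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Convolve an optical profile with the beam; returns (t_us, pulse values).

    ``pulse(t) = integral profile(x) beam(x - v t) dx`` evaluated on a grid
    oversampled ``oversample``-fold relative to the digitizer rate, with the
    beam normalized to unit integral so a broad profile keeps its amplitude
    and a delta-like profile maps to the beam shape in time (transit FWHM
    1.15 us at defaults). Linear in the profile.
    """
    config = config or AcquisitionConfig()
    t = _fine_grid(config, oversample, duration_us)
    center = center_us if center_us is not None else t[-1] / 2
    x = (t - center) * beam.flow_speed_m_s   # um
    vals = np.asarray(profile(x), dtype=np.float64)
    kernel = _beam_kernel(beam, dx_um=(x[1] - x[0]))
    pulse = sps.fftconvolve(vals, kernel, mode="same", axes=-1)
    return t, pulse


def _lowpass_sos(noise: NoiseModel, fs_fine: float):
    return sps.butter(4, noise.lowpass_cutoff / (fs_fine / 2), output="sos")


def sample_and_digitize(pulse, noise: NoiseModel, config: AcquisitionConfig,
                        rng: np.random.Generator, oversample: int = 10,
                        duration_us: float | None = None) -> np.ndarray:
    """Low-pass filter, sample at the digitizer rate, add baseline, quantize.

    ``pulse`` is either a callable of time (us) or an array already on the
    oversampled grid. The low-pass runs on the oversampled grid (the analog
    cutoff of 7 MHz exceeds the digital Nyquist), then every
    ``oversample``-th point is kept, Gaussian baseline noise is added and
    the result is clipped to the ADC range and rounded to uint16.
    Deterministic given the generator state.
    """
    t = _fine_grid(config, oversample, duration_us)
    vals = np.asarray(pulse(t) if callable(pulse) else pulse, dtype=np.float64)
    squeeze = vals.ndim == 1
    vals = np.atleast_2d(vals)
    fs_fine = config.sampling_rate * oversample
    if noise.lowpass_cutoff < fs_fine / 2:
        vals = sps.sosfiltfilt(_lowpass_sos(noise, fs_fine), vals, axis=-1)
    samples = vals[..., ::oversample] + noise.baseline_level
    if noise.baseline_sd > 0:
        samples = samples + rng.normal(0.0, noise.baseline_sd, size=samples.shape)
    out = np.clip(np.rint(samples), 0, config.adc_max).astype(np.uint16)
    return out[0] if squeeze else out


def trigger_align(channels: np.ndarray, config: AcquisitionConfig, threshold: float,
                  rng: np.random.Generator | None = None,
                  baseline_level: float = 0.0, baseline_sd: float = 0.0,
                  trigger_channel: int = 0) -> np.ndarray | None:
    """Align a raw multi-channel recording on the SSC trigger crossing.

    All channels are shifted so the first upward threshold crossing of the
    trigger channel sits at the trigger index (sample 20 at defaults);
    content outside the window is discarded and vacated samples are filled
    with baseline draws. Returns None when the trigger never fires.
    """
    channels = np.atleast_2d(np.asarray(channels))
    trig = channels[trigger_channel].astype(np.float64)
    above = trig >= threshold
    upward = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    if upward.size == 0:
        return None
    shift = int(upward[0]) - config.trigger_index
    n_out = config.n_samples
    n_raw = channels.shape[1]
    src = np.arange(n_out) + shift
    valid = (src >= 0) & (src < n_raw)
    out = np.empty((channels.shape[0], n_out), dtype=np.float64)
    out[:, valid] = channels[:, src[valid]]
    n_fill = int((~valid).sum())
    if n_fill:
        if rng is not None and baseline_sd > 0:
            fill = rng.normal(baseline_level, baseline_sd, size=(channels.shape[0], n_fill))
        else:
            fill = np.full((channels.shape[0], n_fill), baseline_level)
        out[:, ~valid] = fill
    return np.clip(np.rint(out), 0, config.adc_max).astype(np.uint16)


# ---------------------------------------------------------------------------
# Cohort simulation


def _draw_events(classes: list[CellClassSpec], n: int,
                 rng: np.random.Generator) -> list[CellDraw]:
    weights = np.array([c.mixture_weight for c in classes], dtype=np.float64)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ContractError(f"class weights must sum to 1, got {weights.sum()}")
    which = rng.choice(len(classes), size=n, p=weights)
    draws = []
    for idx in which:
        spec = classes[idx]
        d = spec.diameter_mean_um * max(1.0 + spec.diameter_cv * rng.normal(), 0.3)
        pd_us, ratio = {}, {}
        for ch in ("FSCL", "FSCU"):
            m, s = spec.peak_distance_us.get(ch, (2.5, 0.1))
            pd_us[ch] = max(m + s * rng.normal(), 0.5)
            rm, rs = spec.amplitude_ratio.get(ch, (1.0, 0.0))
            ratio[ch] = max(rm + rs * rng.normal(), 0.5)
        plateau = (spec.phase == "S") and (rng.random() < spec.s_phase_plateau_prob)
        draws.append(CellDraw(
            phase=spec.phase, diameter_um=d, peak_distance_us=pd_us,
            amplitude_ratio=ratio, dip_depth=spec.dip_depth, plateau=plateau,
            oscillation_amp=spec.s_phase_oscillation_amp,
        ))
    return draws


def _fluorescence(spec_by_phase: dict, draws: list[CellDraw],
                  rng: np.random.Generator) -> pd.DataFrame:
    n = len(draws)
    pi_h = np.empty(n)
    fitc = np.empty(n)
    for i, d in enumerate(draws):
        spec = spec_by_phase[d.phase]
        if spec.pi_range is not None:
            base = rng.uniform(*spec.pi_range)
        else:
            base = spec.pi_mean
        pi_h[i] = max(base * (1.0 + spec.pi_cv * rng.normal()), 0.0)
        if spec.brdu_positive:
            fitc[i] = np.exp(rng.normal(np.log(25000.0), 0.25))
        else:
            fitc[i] = np.exp(rng.normal(np.log(1500.0), 0.35))
    pi_w = rng.normal(3.0, 0.15, size=n)
    pi_a = pi_h * pi_w * 0.5
    return pd.DataFrame({"PI-H": pi_h, "PI-A": pi_a, "PI-W": pi_w, "FITC-H": fitc})


def _peak_separation_um(pulses: np.ndarray, dx_um: float) -> np.ndarray:
    """Distance between the outermost local maxima above 30 % of each pulse's
    peak; NaN where fewer than two peaks are resolved."""
    left = pulses > np.roll(pulses, 1, axis=-1)
    right = pulses >= np.roll(pulses, -1, axis=-1)
    high = pulses > 0.3 * pulses.max(axis=-1, keepdims=True)
    is_peak = left & right & high
    is_peak[:, 0] = is_peak[:, -1] = False
    out = np.full(pulses.shape[0], np.nan)
    for i in np.flatnonzero(is_peak.sum(axis=-1) >= 2):
        idx = np.flatnonzero(is_peak[i])
        out[i] = (idx[-1] - idx[0]) * dx_um
    return out


def _batch_scatter_fine(draws: list[CellDraw], channel: str, beam: BeamModel,
                        t_fine: np.ndarray, center_us: float) -> np.ndarray:
    """Beam-convolved fine-grid pulses for all events of one channel.

    For two-lobe channels the effective lobe separation is calibrated per
    event (two fixed-point iterations) so that the *observed* post-beam peak
    distance equals the drawn ground-truth peak distance: the inter-peak
    bridge otherwise pulls the convolved maxima inward, and the class
    parameters describe distances as measured on recorded pulses.
    """
    x = (t_fine - center_us) * beam.flow_speed_m_s
    dx = x[1] - x[0]
    kernel = _beam_kernel(beam, dx_um=dx)
    out = np.empty((len(draws), len(t_fine)))
    key = "FSCU" if channel == "FSCM" else channel
    chunk = 1024
    for lo in range(0, len(draws), chunk):
        block_draws = draws[lo:lo + chunk]
        if channel == "SSC":
            block = np.stack([
                _profile_values(x, d, channel, beam.flow_speed_m_s)
                for d in block_draws
            ])
            out[lo:lo + chunk] = sps.fftconvolve(block, kernel[None, :],
                                                 mode="same", axes=-1)
            continue
        target = np.array([d.peak_distance_us[key] * beam.flow_speed_m_s
                           for d in block_draws])
        sep_eff = target.copy()
        conv = None
        for _ in range(3):
            block = np.stack([
                _profile_values(x, d, channel, beam.flow_speed_m_s, sep_um=s)
                for d, s in zip(block_draws, sep_eff)
            ])
            conv = sps.fftconvolve(block, kernel[None, :], mode="same", axes=-1)
            measured = _peak_separation_um(conv, dx)
            err = target - measured
            err[~np.isfinite(err)] = 0.0  # merged peaks: leave uncorrected
            if np.max(np.abs(err)) < 0.25 * dx:
                break
            sep_eff = np.maximum(sep_eff + err, 0.5)
        out[lo:lo + chunk] = conv
    return out


def simulate_cohort(
    classes: list[CellClassSpec] | None = None,
    n_events: int = 1000,
    noise: NoiseModel | None = None,
    beam: BeamModel | None = None,
    config: AcquisitionConfig | None = None,
    seed: int = 0,
    oversample: int = 10,
    raw_window_us: float = 16.0,
    trigger_threshold: float | None = None,
) -> tuple[PulseDataset, pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of events drawn i.i.d. from the class mixture.

    Generates raw recordings over the maximum 16 us trigger window on an
    oversampled grid, pushes them through the signal chain (beam
    convolution, 7 MHz low-pass, 10 MHz sampling, baseline noise, 16-bit
    quantization), aligns each event on its SSC trigger crossing, and
    derives the linked event table (per-channel H/A/W plus fluorescence
    scalars). Doublets are sums of two time-offset singlets with summed PI
    area and inflated PI width. Fully reproducible from ``seed``.

    Returns
    -------
    (PulseDataset, EventTable DataFrame, GroundTruth DataFrame)
    """
    if n_events <= 0:
        raise ContractError("n_events must be positive")
    classes = classes if classes is not None else default_classes()
    noise = noise or NoiseModel()
    beam = beam or BeamModel()
    config = config or AcquisitionConfig()
    rng = np.random.default_rng(seed)

    draws = _draw_events(classes, n_events, rng)
    pre_doublet = rng.random(n_events) < noise.doublet_fraction
    partners = _draw_events(classes, int(pre_doublet.sum()), rng) if pre_doublet.any() else []
    offsets_us = rng.normal(noise.doublet_offset_mean_us, noise.doublet_offset_sd_us,
                            size=len(partners))

    t_fine = _fine_grid(config, oversample, raw_window_us)
    dt_fine = t_fine[1] - t_fine[0]
    center = raw_window_us / 2.0

    fine = {ch: _batch_scatter_fine(draws, ch, beam, t_fine, center)
            for ch in SCATTER_CHANNELS}
    if partners:
        rows = np.flatnonzero(pre_doublet)
        for ch in SCATTER_CHANNELS:
            extra = _batch_scatter_fine(partners, ch, beam, t_fine, center)
            for k, row in enumerate(rows):
                shift = int(round(offsets_us[k] / dt_fine))
                shifted = np.zeros_like(extra[k])
                if shift >= 0:
                    shifted[shift:] = extra[k][:len(shifted) - shift]
                else:
                    shifted[:shift] = extra[k][-shift:]
                fine[ch][row] += shifted

    # digitize: low-pass on the oversampled grid, decimate, noise, quantize
    fs_fine = config.sampling_rate * oversample
    sos = _lowpass_sos(noise, fs_fine)
    raw = {}
    for ch in SCATTER_CHANNELS:
        v = sps.sosfiltfilt(sos, fine[ch], axis=-1)[:, ::oversample]
        v = v + noise.baseline_level + rng.normal(0, noise.baseline_sd, size=v.shape)
        raw[ch] = np.clip(np.rint(v), 0, config.adc_max)
    # FSCM: redundant to FSCU but with an independent noise/gain realization
    gain = rng.normal(1.0, 0.02, size=(n_events, 1))
    raw["FSCM"] = np.clip(np.rint(
        (raw["FSCM"] - noise.baseline_level) * gain + noise.baseline_level
        + rng.normal(0, noise.baseline_sd, size=raw["FSCM"].shape)
    ), 0, config.adc_max)

    threshold = (trigger_threshold if trigger_threshold is not None
                 else noise.baseline_level + max(12 * noise.baseline_sd, 100.0))

    n_samples = config.n_samples
    data = np.zeros((n_events, config.n_channels, n_samples), dtype=np.uint16)
    keep = np.ones(n_events, dtype=bool)
    scatter_idx = {ch: config.channel_index(ch) for ch in SCATTER_CHANNELS}
    for i in range(n_events):
        stack = np.stack([raw[ch][i] for ch in SCATTER_CHANNELS])
        aligned = trigger_align(stack, config, threshold, rng=rng,
                                baseline_level=noise.baseline_level,
                                baseline_sd=noise.baseline_sd, trigger_channel=0)
        if aligned is None:
            keep[i] = False
            continue
        for k, ch in enumerate(SCATTER_CHANNELS):
            data[i, scatter_idx[ch]] = aligned[k]
    # non-scatter channels: baseline only (fluorescence is stored as scalars)
    other = [j for j in range(config.n_channels) if j not in scatter_idx.values()]
    if other:
        base = rng.normal(noise.baseline_level, noise.baseline_sd,
                          size=(n_events, len(other), n_samples))
        data[:, other, :] = np.clip(np.rint(base), 0, config.adc_max).astype(np.uint16)

    n_rejected = int((~keep).sum())
    if n_rejected:
        warnings.warn(f"{n_rejected} events never crossed the SSC trigger and were rejected")
        logger.info("rejected %d sub-threshold events", n_rejected)
    data = data[keep]
    draws = [d for d, k in zip(draws, keep) if k]
    doublet = pre_doublet[keep]
    event_ids = np.arange(len(draws), dtype=np.uint32)

    dataset = PulseDataset(config=config, data=data, event_ids=event_ids)

    spec_by_phase = {c.phase: c for c in classes}
    fluor = _fluorescence(spec_by_phase, draws, rng)
    if partners:
        # partner k belongs to the k-th doublet in pre-filter event order;
        # restrict to partners whose host event survived triggering
        partner_keep = keep[np.flatnonzero(pre_doublet)]
        kept_partners = [p for p, k in zip(partners, partner_keep) if k]
        kept_offsets = offsets_us[partner_keep]
        partner_fluor = _fluorescence(spec_by_phase, kept_partners, rng)
        rows = np.flatnonzero(doublet)
        # PI area adds exactly; PI width is inflated by the transit offset
        fluor.loc[rows, "PI-A"] = (fluor.loc[rows, "PI-A"].to_numpy()
                                   + partner_fluor["PI-A"].to_numpy())
        fluor.loc[rows, "FITC-H"] = (fluor.loc[rows, "FITC-H"].to_numpy()
                                     + partner_fluor["FITC-H"].to_numpy())
        fluor.loc[rows, "PI-W"] = (
            np.maximum(fluor.loc[rows, "PI-W"].to_numpy(),
                       partner_fluor["PI-W"].to_numpy()) + np.abs(kept_offsets))
        fluor.loc[rows, "PI-H"] = np.maximum(
            fluor.loc[rows, "PI-H"].to_numpy(), partner_fluor["PI-H"].to_numpy())

    events = derive_haw_table(dataset, channels=list(SCATTER_CHANNELS))
    for col in fluor.columns:
        events[col] = fluor[col].to_numpy()
    events["singlet"] = False
    events["reference_phase"] = "unlabeled"

    truth = pd.DataFrame({
        "event_id": event_ids.astype(np.int64),
        "phase": [d.phase for d in draws],
        "doublet": doublet,
        "diameter_um": [d.diameter_um for d in draws],
        "peak_distance_FSCL_us": [d.peak_distance_us["FSCL"] for d in draws],
        "peak_distance_FSCU_us": [d.peak_distance_us["FSCU"] for d in draws],
        "amplitude_ratio_FSCL": [d.amplitude_ratio["FSCL"] for d in draws],
        "amplitude_ratio_FSCU": [d.amplitude_ratio["FSCU"] for d in draws],
        "plateau": [d.plateau for d in draws],
    })
    return dataset, events, truth


def arrest_timecourse_weights(t_hours: np.ndarray | list,
                              control=(0.5, 0.3, 0.2),
                              arrested=(0.05, 0.05, 0.90),
                              relax_hours: float = 2.0) -> list[tuple]:
    """(G1, S, G2M) mixture weights relaxing from G2-arrest back to control.

    Immediately after release (t=0) nearly all cells sit in G2/M; the
    composition relaxes exponentially toward the untreated control with the
    given time constant.
    """
    control = np.asarray(control, dtype=np.float64)
    arrested = np.asarray(arrested, dtype=np.float64)
    out = []
    for t in np.asarray(t_hours, dtype=np.float64):
        w = control + (arrested - control) * np.exp(-t / relax_hours)
        out.append(tuple(w / w.sum()))
    return out
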