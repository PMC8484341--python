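"""Synthetic signal chain: beam convolution, digitization, trigger, cohorts."""

import numpy as np
import pytest
from scipy.signal import find_peaks

import mapsfc as m
from mapsfc.errors import ContractError
from mapsfc.io import AcquisitionConfig
from mapsfc.simulate import (BeamModel, CellDraw, NoiseModel, arrest_timecourse_weights,
                             beam_convolve, default_classes, make_profile,
                             sample_and_digitize, simulate_cohort, sorted_classes,
                             trigger_align)


def _fwhm(t, y):
    half = y.max() / 2
    above = np.flatnonzero(y >= half)
    return t[above[-1]] - t[above[0]]


def test_delta_profile_maps_to_beam_transit():
    # a near-delta optical profile records the beam shape in time: 1.15 us FWHM
    beam = BeamModel()
    t, pulse = beam_convolve(lambda x: np.exp(-0.5 * (x / 0.01) ** 2), beam,
                             oversample=10)
    assert _fwhm(t, pulse) == pytest.approx(beam.transit_fwhm_us, rel=0.02)
    assert beam.transit_fwhm_us == pytest.approx(1.15)


def test_two_delta_lobes_keep_their_spacing():
    # two narrow lobes 15 um apart -> two resolved peaks 3 us apart at 5 m/s
    beam = BeamModel()
    t, pulse = beam_convolve(
        lambda x: np.exp(-0.5 * ((x - 7.5) / 0.01) ** 2)
        + np.exp(-0.5 * ((x + 7.5) / 0.01) ** 2), beam, oversample=10)
    peaks, _ = find_peaks(pulse, height=pulse.max() * 0.5)
    assert len(peaks) == 2
    assert t[peaks[1]] - t[peaks[0]] == pytest.approx(3.0, abs=0.02)


def test_beam_convolution_is_linear():
    beam = BeamModel()
    f = lambda x: np.exp(-0.5 * (x / 2.0) ** 2)
    g = lambda x: np.exp(-0.5 * ((x - 4) / 1.0) ** 2)
    _, pf = beam_convolve(f, beam)
    _, pg = beam_convolve(g, beam)
    _, pfg = beam_convolve(lambda x: 2 * f(x) + g(x), beam)
    np.testing.assert_allclose(pfg, 2 * pf + pg, atol=1e-9)


def test_make_profile_rejects_non_scatter_channels():
    draw = CellDraw(phase="G1", diameter_um=12.0,
                    peak_distance_us={"FSCL": 2.5, "FSCU": 2.5},
                    amplitude_ratio={"FSCL": 1.0, "FSCU": 1.0},
                    dip_depth=0.6, plateau=False, oscillation_amp=0.0)
    with pytest.raises(ContractError):
        make_profile(draw, "FL-PI")
    profile = make_profile(draw, "FSCL")
    vals = profile(np.linspace(-20, 20, 100))
    assert vals.shape == (100,) and np.isfinite(vals).all()


def test_sample_and_digitize_range_and_determinism():
    cfg = AcquisitionConfig()
    noise = NoiseModel(baseline_sd=10.0)
    pulse = lambda t: 5000.0 * np.exp(-0.5 * ((t - 4) / 0.5) ** 2)
    a = sample_and_digitize(pulse, noise, cfg, np.random.default_rng(0))
    b = sample_and_digitize(pulse, noise, cfg, np.random.default_rng(0))
    assert a.dtype == np.uint16 and a.shape == (cfg.n_samples,)
    np.testing.assert_array_equal(a, b)
    assert a.max() <= cfg.adc_max


def test_trigger_align_places_crossing_at_trigger_index():
    cfg = AcquisitionConfig()
    raw = np.zeros((2, 160))
    raw[0, 90:110] = 1000.0          # SSC crossing at raw sample 90
    raw[1, 95:105] = 500.0
    out = trigger_align(raw, cfg, threshold=500.0)
    assert out.shape == (2, cfg.n_samples)
    trig = out[0].astype(float)
    crossing = np.flatnonzero(trig >= 500.0)[0]
    assert crossing == cfg.trigger_index
    assert trigger_align(np.zeros((2, 160)), cfg, threshold=500.0) is None


def test_cohort_shapes_ids_and_trigger_location(small_cohort):
    ds, ev, gt = small_cohort
    assert ds.data.shape == (ds.n_events, 8, 80)
    assert len(ev) == len(gt) == ds.n_events
    assert np.all(np.diff(ds.event_ids.astype(np.int64)) > 0)
    # SSC first upward crossing sits at the trigger index for every event
    ssc = ds.channel("SSC")
    noise = m.default_noise()
    thr = noise.baseline_level + max(12 * noise.baseline_sd, 100.0)
    crossings = (ssc >= thr).argmax(axis=1)
    assert (crossings == ds.config.trigger_index).mean() > 0.99


def test_cohort_class_counts_follow_mixture_weights(small_cohort):
    _, _, gt = small_cohort
    n = len(gt)
    for phase, w in (("G1", 0.5), ("S", 0.3), ("G2M", 0.2)):
        k = (gt["phase"] == phase).sum()
        sd = np.sqrt(n * w * (1 - w))
        assert abs(k - n * w) < 5 * sd


def test_cohort_peak_distance_recovery():
    # the drawn peak distance is recovered from the recorded pulses
    ds, _, gt = m.simulate_cohort(
        n_events=150, noise=NoiseModel(doublet_fraction=0, baseline_sd=5.0), seed=21)
    pulses = ds.channel("FSCL") - NoiseModel().baseline_level
    dt = ds.config.sample_period_us
    err = []
    for p, truth in zip(pulses, gt["peak_distance_FSCL_us"]):
        peaks, _ = find_peaks(p, height=0.3 * p.max())
        if len(peaks) >= 2:
            err.append((peaks[-1] - peaks[0]) * dt - truth)
    err = np.abs(err)
    assert len(err) > 140
    assert np.mean(err) < 0.05
    assert np.quantile(err, 0.95) <= 0.1 + dt / 2


def test_doublets_inflate_pi_width_and_area():
    _, ev, gt = m.simulate_cohort(n_events=800, noise=m.default_noise(0.15), seed=9)
    dbl = gt["doublet"].to_numpy()
    assert 0.08 < dbl.mean() < 0.25
    assert ev.loc[dbl, "PI-W"].mean() > ev.loc[~dbl, "PI-W"].mean() + 1.0
    assert ev.loc[dbl, "PI-A"].mean() > 1.5 * ev.loc[~dbl, "PI-A"].mean()


def test_sorted_classes_yield_pure_aliquots():
    classes = default_classes()
    pure = sorted_classes(classes, "G2M")
    assert len(pure) == 1 and pure[0].mixture_weight == 1.0
    _, _, gt = m.simulate_cohort(classes=pure, n_events=50, seed=2)
    assert (gt["phase"] == "G2M").all()
    with pytest.raises(ContractError):
        sorted_classes(classes, "M")


def test_arrest_timecourse_weights_relax_to_control():
    control, arrested = (0.5, 0.3, 0.2), (0.05, 0.05, 0.9)
    w = arrest_timecourse_weights([0.0, 100.0], control, arrested)
    np.testing.assert_allclose(w[0], arrested, atol=1e-6)
    np.testing.assert_allclose(w[1], control, atol=1e-6)
    assert all(abs(sum(row) - 1.0) < 1e-9 for row in w)
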