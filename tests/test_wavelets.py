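"""MODWT invariants, the independent filter oracle, and level selection."""

import numpy as np
import pytest
import pywt
from sklearn.base import clone

from mapsfc.errors import ContractError, DegenerateDataError
from mapsfc.wavelets import ModwtFeaturizer, extract_features, modwt, modwt_mra, select_feature_level


# --- independent oracle: equivalent level-j filters by upsample-and-convolve


def _oracle_filters(wavelet: str, level: int):
    """Equivalent MODWT filters built by cascade, independent of the pyramid."""
    w = pywt.Wavelet(wavelet)
    g = np.asarray(w.dec_lo)[::-1] / np.sqrt(2.0)
    h = np.asarray(w.dec_hi)[::-1] / np.sqrt(2.0)

    def upsample(f, factor):
        out = np.zeros((len(f) - 1) * factor + 1)
        out[::factor] = f
        return out

    cascade = np.array([1.0])
    for j in range(level - 1):
        cascade = np.convolve(cascade, upsample(g, 2 ** j))
    h_j = np.convolve(cascade, upsample(h, 2 ** (level - 1)))
    g_j = np.convolve(cascade, upsample(g, 2 ** (level - 1)))
    return h_j, g_j


def _oracle_modwt(x, wavelet, level):
    n = len(x)
    details = []
    for j in range(1, level + 1):
        h_j, g_j = _oracle_filters(wavelet, j)
        idx = (np.arange(n)[:, None] - np.arange(len(h_j))[None, :]) % n
        details.append(x[idx] @ h_j)
    smooth = x[(np.arange(n)[:, None] - np.arange(len(g_j))[None, :]) % n] @ g_j
    return np.stack(details), smooth


@pytest.mark.parametrize("wavelet", ["haar", "db2", "db4"])
def test_modwt_matches_direct_convolution_oracle(wavelet):
    rng = np.random.default_rng(0)
    x = rng.normal(size=80)
    level = 4
    details, smooth = modwt(x, wavelet=wavelet, level=level)
    o_details, o_smooth = _oracle_modwt(x, wavelet, level)
    np.testing.assert_allclose(details, o_details, atol=1e-10)
    np.testing.assert_allclose(smooth, o_smooth, atol=1e-10)


@pytest.mark.parametrize("wavelet", ["haar", "db2"])
def test_modwt_energy_conservation(wavelet):
    rng = np.random.default_rng(1)
    x = rng.normal(size=(5, 80))
    details, smooth = modwt(x, wavelet=wavelet, level=6)
    energy = (details ** 2).sum(axis=(-2, -1)) + (smooth ** 2).sum(axis=-1)
    np.testing.assert_allclose(energy, (x ** 2).sum(axis=-1), rtol=1e-8)


@pytest.mark.parametrize("boundary", ["circular", "reflection"])
def test_mra_additive_reconstruction(boundary):
    rng = np.random.default_rng(2)
    x = rng.normal(size=(4, 80))
    comps = modwt_mra(x, "haar", level=6, boundary=boundary)
    np.testing.assert_allclose(comps.sum(axis=-2), x, atol=1e-8)


def test_modwt_shift_equivariance():
    rng = np.random.default_rng(3)
    x = rng.normal(size=80)
    shift = 13
    d0, s0 = modwt(x, "haar", level=5)
    d1, s1 = modwt(np.roll(x, shift), "haar", level=5)
    np.testing.assert_allclose(np.roll(d0, shift, axis=-1), d1, atol=1e-12)
    np.testing.assert_allclose(np.roll(s0, shift), s1, atol=1e-12)


def test_modwt_rejects_too_deep_level_and_nonfinite():
    with pytest.raises(ContractError):
        modwt(np.zeros(80), level=7)          # 2**7 > 80
    with pytest.raises(ContractError):
        modwt(np.array([1.0, np.nan] + [0.0] * 78), level=2)


def test_level_selection_is_order_and_duplication_invariant():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(60, 80)) * np.linspace(1, 3, 80)
    base = select_feature_level(X).selected_level
    shuffled = select_feature_level(X[rng.permutation(60)]).selected_level
    doubled = select_feature_level(np.vstack([X, X])).selected_level
    assert base == shuffled == doubled


def test_level_selection_tracks_dominant_scale():
    # cohorts varying only at one scale select the matching level band
    rng = np.random.default_rng(5)
    t = np.arange(80)
    slow = np.sin(2 * np.pi * t / 64)[None, :] * rng.normal(size=(100, 1))
    fast = np.sin(2 * np.pi * t / 4)[None, :] * rng.normal(size=(100, 1))
    assert select_feature_level(slow).selected_level > select_feature_level(fast).selected_level


def test_featurizer_degenerate_cohorts_raise():
    with pytest.raises(DegenerateDataError):
        ModwtFeaturizer().fit(np.zeros((1, 80)))          # too few events
    with pytest.raises(DegenerateDataError):
        ModwtFeaturizer().fit(np.tile(np.sin(np.arange(80.0)), (10, 1)))  # identical


def test_featurizer_fixed_level_and_transform_shape():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(12, 80))
    fz = ModwtFeaturizer(level=3).fit(X)
    F = fz.transform(X)
    assert F.shape == (12, 80)
    details, _ = modwt(X, "haar", level=3)
    np.testing.assert_allclose(F, details[:, 2, :])
    # module-function wrapper agrees with the estimator
    np.testing.assert_allclose(extract_features(X, level=3), F)


def test_featurizer_is_sklearn_compatible():
    fz = ModwtFeaturizer(level=2, wavelet="db2")
    cl = clone(fz)
    assert cl.get_params() == fz.get_params()
    with pytest.raises(ContractError):
        ModwtFeaturizer(level=2).transform(np.zeros((2, 80)))  # unfitted
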