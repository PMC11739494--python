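"""Cleaning chain: noise floor, S/N filter, recalibration, blank
subtraction, replicate intersection, TIC normalization."""
import numpy as np
import pytest

from domtrace.chem import KENDRICK_CH2, MolecularFormula
from domtrace.errors import (ContractViolationError, DegenerateInputError,
                             InsufficientDataError,
                             InsufficientRecalibrantsError)
from domtrace.io import Spectrum
from domtrace.preprocess import (blank_removal_set, estimate_noise,
                                 filter_snr, intersect_replicates,
                                 normalize_tic, pick_recalibrants,
                                 recalibrate, subtract_blank)


def _mz_with_kmd(target_kmd, n, lo=100.0, hi=900.0, rng=None):
    """m/z values whose CH2-Kendrick defect equals target_kmd.

    ``target_kmd`` may be a scalar or a (low, high) band to sample from.
    """
    rng = rng or np.random.default_rng(0)
    km_int = rng.integers(int(lo), int(hi), n)
    if isinstance(target_kmd, tuple):
        kmd = rng.uniform(*target_kmd, n)
    else:
        kmd = np.full(n, float(target_kmd))
    km = km_int - kmd + 1.0  # ceil(km) - km = kmd
    return np.sort(km / KENDRICK_CH2)


def test_noise_floor_recovered_from_void_window():
    rng = np.random.default_rng(4)
    noise_mz = _mz_with_kmd((0.905, 0.945), 1000, rng=rng)
    noise_int = rng.uniform(8, 12, 1000)              # planted floor ~10
    signal_mz = _mz_with_kmd((0.20, 0.40), 400, rng=rng)  # outside the window
    signal_int = rng.uniform(1000, 5000, 400)
    sp = Spectrum.from_arrays(np.concatenate([noise_mz, signal_mz]),
                              np.concatenate([noise_int, signal_int]))
    est = estimate_noise(sp)
    assert est.method == "kmd_void"
    assert est.level == pytest.approx(10.0, abs=2.0)


def test_noise_fallback_branch_on_uniform_intensities():
    mz = _mz_with_kmd(0.30, 200)  # nothing in the void window
    sp = Spectrum.from_arrays(mz, np.full(200, 7.5))
    est = estimate_noise(sp)
    assert est.method == "low_quartile"
    assert est.level == 7.5


def test_noise_estimate_deterministic_and_needs_100_peaks():
    mz = _mz_with_kmd(0.925, 150)
    sp = Spectrum.from_arrays(mz, np.full(150, 3.0))
    assert estimate_noise(sp) == estimate_noise(sp)
    small = Spectrum.from_arrays(mz[:50], np.full(50, 3.0))
    with pytest.raises(InsufficientDataError):
        estimate_noise(small)


def test_snr_filter_strict_inequality():
    from domtrace.preprocess import NoiseEstimate

    sp = Spectrum.from_arrays([100.0, 200.0, 300.0], [50.0, 150.0, 101.0])
    out = filter_snr(sp, NoiseEstimate(10.0, "fixed", 10), threshold=10)
    assert list(out.intensity) == [150.0, 101.0]
    ident = filter_snr(sp, NoiseEstimate(10.0, "fixed", 10), threshold=0)
    assert list(ident.intensity) == [50.0, 150.0, 101.0]


def test_snr_filter_matches_bruteforce_scan():
    from domtrace.preprocess import NoiseEstimate

    rng = np.random.default_rng(9)
    mz = np.sort(rng.uniform(100, 900, 500))
    inten = rng.lognormal(3, 2, 500)
    sp = Spectrum.from_arrays(mz, inten)
    noise = NoiseEstimate(20.0, "fixed", 10)
    out = filter_snr(sp, noise, threshold=10)
    expected = [i for i in sp.intensity if i > 10 * 20.0]
    assert list(out.intensity) == expected


def _series_spectrum(err_ppm_fn=None, n_extra=0):
    """Spectrum of one 12-member CH2 series of CHO formulas (O=4, DBE=4)."""
    formulas = [MolecularFormula(c=c, h=2 * (c - 3), o=4) for c in range(8, 20)]
    mz = np.array([f.mz_deprotonated() for f in formulas])
    true = mz.copy()
    if err_ppm_fn is not None:
        mz = mz * (1 + err_ppm_fn(mz) * 1e-6)
    inten = np.linspace(5000, 1000, mz.size)
    return Spectrum.from_arrays(mz, inten), list(zip(mz, true)), formulas


def test_pick_recalibrants_returns_whole_planted_series():
    sp, _, formulas = _series_spectrum()
    pairs = pick_recalibrants(sp, tol_ppm=3.0)
    assert len(pairs) == 12
    for (obs, true), f in zip(pairs, formulas):
        assert true == pytest.approx(f.mz_deprotonated(), abs=1e-9)


def test_pick_recalibrants_errors_without_series():
    sp = Spectrum.from_arrays([150.1111, 233.2222, 377.3333, 411.4444],
                              np.ones(4))
    with pytest.raises(InsufficientRecalibrantsError):
        pick_recalibrants(sp)


def test_pick_recalibrants_tiebreak_prefers_intense_series():
    # two 6-member series; the heavier-intensity one must win
    s1 = [MolecularFormula(c=c, h=2 * (c - 3), o=4) for c in range(8, 14)]
    s2 = [MolecularFormula(c=c, h=2 * (c - 1), o=2) for c in range(8, 14)]
    mz = [f.mz_deprotonated() for f in s1 + s2]
    inten = [1.0] * 6 + [100.0] * 6
    sp = Spectrum.from_arrays(mz, inten)
    pairs = pick_recalibrants(sp, tol_ppm=3.0, min_series=5)
    got = {round(t, 4) for _, t in pairs}
    assert got == {round(f.mz_deprotonated(), 4) for f in s2}


def test_recalibration_removes_injected_constant_error():
    sp, pairs, _ = _series_spectrum(err_ppm_fn=lambda mz: np.full(mz.size, 2.0))
    corrected, model = recalibrate(sp, pairs)
    assert model.intercept_ppm == pytest.approx(2.0, abs=0.05)
    assert abs(model.slope_ppm_per_mz) < 1e-4
    true_mz = np.array([t for _, t in pairs])
    resid = (np.sort(corrected.mz) - np.sort(true_mz)) / true_mz * 1e6
    assert np.all(np.abs(resid) < 0.05)


def test_recalibration_identity_on_zero_error():
    sp, pairs, _ = _series_spectrum()
    corrected, model = recalibrate(sp, pairs)
    assert model.intercept_ppm == pytest.approx(0.0, abs=1e-6)
    np.testing.assert_allclose(corrected.mz, sp.mz, rtol=1e-12)


def test_recalibration_coverage_flag():
    rng = np.random.default_rng(1)
    mz = np.sort(rng.uniform(105, 800, 300))
    inten = np.ones(300)
    sp = Spectrum.from_arrays(mz, inten)
    # mz80 for uniform intensities is ~80th percentile of the mass list
    pairs_short = [(m, m) for m in mz if m <= 400][:50]
    _, model = recalibrate(sp, pairs_short)
    assert model.coverage_warning
    pairs_full = [(m, m) for m in mz]
    _, model2 = recalibrate(sp, pairs_full)
    assert not model2.coverage_warning
    with pytest.raises(InsufficientRecalibrantsError):
        recalibrate(sp, pairs_full[:5])


def test_blank_removal_prefix_rule():
    blank = Spectrum.from_arrays([100.0, 200.0, 300.0, 400.0],
                                 [50.0, 30.0, 15.0, 5.0], role="blank")
    removal = blank_removal_set(blank, 0.95)
    assert sorted(removal) == [100.0, 200.0, 300.0]  # cumulative 95 of 100
    assert blank_removal_set(blank, 0.0).size == 0


def test_blank_subtraction_removes_matches_only():
    blank = Spectrum.from_arrays([100.0, 200.0, 300.0, 400.0],
                                 [50.0, 30.0, 15.0, 5.0], role="blank")
    sample = Spectrum.from_arrays([100.00001, 250.0, 300.00002, 550.0],
                                  [1.0, 2.0, 3.0, 4.0])
    out = subtract_blank(sample, blank, 0.95, tol_ppm=2.0)
    assert list(out.mz) == [250.0, 550.0]
    disjoint = Spectrum.from_arrays([150.0, 650.0], [1.0, 1.0])
    out2 = subtract_blank(disjoint, blank, 0.95, tol_ppm=2.0)
    assert len(out2) == 2
    # cum_fraction 0 -> identity
    assert len(subtract_blank(sample, blank, 0.0, 2.0)) == 4


def _gw(mz, inten, rep):
    return Spectrum.from_arrays(mz, inten, sample_id="s", role="groundwater",
                                replicate=rep)


def test_replicate_intersection_identity_and_disjoint():
    mz = [100.0, 200.0, 300.0]
    a, b = _gw(mz, [1.0, 2.0, 3.0], 1), _gw(mz, [1.0, 2.0, 3.0], 2)
    out = intersect_replicates(a, b)
    np.testing.assert_allclose(out.mz, mz)
    np.testing.assert_allclose(out.intensity, [1.0, 2.0, 3.0])
    c = _gw([150.0, 450.0], [1.0, 1.0], 2)
    assert len(intersect_replicates(a, c)) == 0


def test_replicate_consensus_arithmetic():
    a = _gw([250.00000], [4.0], 1)
    b = _gw([250.00040], [2.0], 2)  # 1.6 ppm apart
    out = intersect_replicates(a, b, tol_ppm=2.0)
    assert len(out) == 1
    assert out.intensity[0] == pytest.approx(3.0)
    assert out.mz[0] == pytest.approx((250.0 * 4 + 250.0004 * 2) / 6, abs=1e-9)


def test_replicate_intersection_contract_checks():
    a = _gw([100.0], [1.0], 1)
    seep = Spectrum.from_arrays([100.0], [1.0], sample_id="s", role="seepage",
                                replicate=2)
    with pytest.raises(ContractViolationError):
        intersect_replicates(a, seep)
    with pytest.raises(ContractViolationError):
        intersect_replicates(a, _gw([100.0], [1.0], 1))


def test_normalize_tic_sums_to_one_and_is_idempotent():
    sp = Spectrum.from_arrays([100.0, 200.0], [1.0, 3.0])
    out = normalize_tic(sp)
    np.testing.assert_allclose(out.intensity, [0.25, 0.75])
    again = normalize_tic(out)
    np.testing.assert_allclose(again.intensity, out.intensity)
    rng = np.random.default_rng(3)
    sp2 = Spectrum.from_arrays(np.sort(rng.uniform(100, 900, 200)),
                               rng.lognormal(5, 1, 200))
    assert normalize_tic(sp2).tic == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(DegenerateInputError):
        normalize_tic(Spectrum.from_arrays([100.0], [0.0]))
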