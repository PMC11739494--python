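"""Spectral cleaning chain for DI-HR-MS DOM peak lists.

Fixed stage order: noise estimation / S/N filtering -> recalibration ->
blank subtraction -> replicate intersection -> TIC normalization.  Every
stage is deterministic, takes and returns a valid :class:`Spectrum`, and is
idempotent where that is meaningful (normalization, blank subtraction with
the same blank).

Noise estimation uses a chemically void window of the CH2-based Kendrick
mass defect: real DOM formulas cluster in a narrow KMD band, so peaks whose
defect falls in the void window (default (0.90, 0.95)) are overwhelmingly
electronic noise, and their trimmed mean intensity estimates the noise
floor.  If the window is too sparsely populated, the estimator falls back to
the median of the lowest-intensity quartile.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .assign import ElementRanges, enumerate_candidates, neutral_mass_from_mz
from .chem import kendrick_mass_defect
from .errors import (ContractViolationError, DegenerateInputError,
                     InsufficientDataError, InsufficientRecalibrantsError)
from .io import Spectrum


@dataclasses.dataclass(frozen=True)
class NoiseEstimate:
    level: float
    method: str  # "kmd_void" or "low_quartile"
    n_support: int


def estimate_noise(
    spectrum: Spectrum,
    void_window: tuple[float, float] = (0.90, 0.95),
    trim: float = 0.1,
) -> NoiseEstimate:
    """Estimate the noise floor from the KMD void window (see module docs)."""
    if len(spectrum) < 100:
        raise InsufficientDataError(
            f"noise estimation needs >=100 peaks, got {len(spectrum)}")
    kmd = kendrick_mass_defect(spectrum.mz)
    in_void = (kmd > void_window[0]) & (kmd < void_window[1])
    if in_void.sum() >= 10:
        level = float(stats.trim_mean(spectrum.intensity[in_void], trim))
        return NoiseEstimate(level=level, method="kmd_void",
                             n_support=int(in_void.sum()))
    quartile = np.sort(spectrum.intensity)[: max(1, len(spectrum) // 4)]
    return NoiseEstimate(level=float(np.median(quartile)),
                         method="low_quartile", n_support=quartile.size)


def filter_snr(spectrum: Spectrum, noise: NoiseEstimate,
               threshold: float = 10.0) -> Spectrum:
    """Keep peaks with intensity strictly above threshold x noise level."""
    keep = spectrum.intensity > threshold * noise.level
    return spectrum.replace_peaks(spectrum.mz[keep], spectrum.intensity[keep])


@dataclasses.dataclass(frozen=True)
class CalibrationModel:
    """Linear ppm error model  error_ppm = intercept + slope * m/z."""

    intercept_ppm: float
    slope_ppm_per_mz: float
    residual_rms_ppm: float
    coverage: tuple[float, float]
    n_recalibrants: int
    coverage_warning: bool = False


def recalibrate(
    spectrum: Spectrum,
    recalibrants: Sequence[tuple[float, float]],
    coverage_low: float = 110.0,
) -> tuple[Spectrum, CalibrationModel]:
    """Least-squares linear recalibration from (observed, true) m/z pairs.

    The fitted ppm error is inverted on every peak.  A coverage warning is
    raised on the model when the recalibrants do not span from ~m/z 110 up
    to the m/z at which cumulative intensity reaches 80% of the total.
    """
    if len(recalibrants) < 10:
        raise InsufficientRecalibrantsError(
            f"need >=10 recalibrant pairs, got {len(recalibrants)}")
    obs = np.array([p[0] for p in recalibrants], dtype=float)
    true = np.array([p[1] for p in recalibrants], dtype=float)
    err_ppm = (obs - true) / true * 1e6
    slope, intercept = np.polyfit(obs, err_ppm, 1)
    corrected = spectrum.mz / (1.0 + (intercept + slope * spectrum.mz) * 1e-6)
    obs_corr = obs / (1.0 + (intercept + slope * obs) * 1e-6)
    resid = (obs_corr - true) / true * 1e6
    rms = float(np.sqrt(np.mean(resid ** 2)))

    cum = np.cumsum(spectrum.intensity)
    total = cum[-1] if cum.size else 0.0
    if total > 0:
        mz80 = float(spectrum.mz[np.searchsorted(cum, 0.8 * total)])
    else:
        mz80 = float(spectrum.mz[-1]) if len(spectrum) else 0.0
    warn = not (obs.min() <= coverage_low and obs.max() >= mz80)
    model = CalibrationModel(
        intercept_ppm=float(intercept), slope_ppm_per_mz=float(slope),
        residual_rms_ppm=rms, coverage=(float(obs.min()), float(obs.max())),
        n_recalibrants=obs.size, coverage_warning=warn)
    return spectrum.replace_peaks(corrected, spectrum.intensity), model


_CHO_RANGES = ElementRanges(n=(0, 0), s=(0, 0))


def pick_recalibrants(
    spectrum: Spectrum,
    tol_ppm: float = 3.0,
    min_series: int = 5,
    ranges: ElementRanges = _CHO_RANGES,
) -> list[tuple[float, float]]:
    """Select recalibrants as the longest CH2-homologous series of
    provisional CHO-only matches.

    Each peak receives a provisional CHO assignment at ``tol_ppm``; only
    unique-candidate matches are used (a mis-assigned recalibrant corrupts
    the error model).  Series share (O, DBE) and differ in C; the longest
    one wins, ties resolved by higher summed intensity.  Returns
    (observed m/z, theoretical [M-H]- m/z) pairs.
    """
    series: dict[tuple[int, float], list[tuple[int, float, float, float]]] = {}
    for m, inten in zip(spectrum.mz, spectrum.intensity):
        cands = enumerate_candidates(neutral_mass_from_mz(m), tol_ppm, ranges)
        if len(cands) != 1:
            continue
        f = cands[0]
        key = (f.o, f.dbe)
        series.setdefault(key, []).append((f.c, m, f.mz_deprotonated(), inten))
    best: Optional[list] = None
    best_rank = (0, 0.0)
    for members in series.values():
        distinct_c = {m[0] for m in members}
        rank = (len(distinct_c), sum(m[3] for m in members))
        if rank > best_rank:
            best_rank = rank
            best = members
    if best is None or best_rank[0] < min_series:
        raise InsufficientRecalibrantsError(
            f"no CH2-homologous series of length >= {min_series} found")
    return [(m[1], m[2]) for m in sorted(best)]


def blank_removal_set(blank: Spectrum, cum_fraction: float = 0.95) -> np.ndarray:
    """Smallest set of highest-intensity blank peaks whose summed intensity
    reaches ``cum_fraction`` of the blank total; returns their m/z values."""
    if len(blank) == 0:
        raise DegenerateInputError("blank spectrum is empty")
    order = np.argsort(blank.intensity)[::-1]
    cum = np.cumsum(blank.intensity[order])
    total = cum[-1]
    if cum_fraction <= 0:
        return np.array([], dtype=float)
    k = int(np.searchsorted(cum, cum_fraction * total)) + 1
    return np.sort(blank.mz[order[:k]])


def subtract_blank(spectrum: Spectrum, blank: Spectrum,
                   cum_fraction: float = 0.95, tol_ppm: float = 2.0) -> Spectrum:
    """Remove sample peaks matching the dominant blank peaks within tol_ppm."""
    removal = blank_removal_set(blank, cum_fraction)
    if removal.size == 0 or len(spectrum) == 0:
        return spectrum
    idx = np.searchsorted(removal, spectrum.mz)
    lo = np.clip(idx - 1, 0, removal.size - 1)
    hi = np.clip(idx, 0, removal.size - 1)
    d_lo = np.abs(spectrum.mz - removal[lo]) / spectrum.mz * 1e6
    d_hi = np.abs(spectrum.mz - removal[hi]) / spectrum.mz * 1e6
    keep = np.minimum(d_lo, d_hi) > tol_ppm
    return spectrum.replace_peaks(spectrum.mz[keep], spectrum.intensity[keep])


def intersect_replicates(rep_a: Spectrum, rep_b: Spectrum,
                         tol_ppm: float = 2.0) -> Spectrum:
    """Consensus spectrum of two duplicate measurements.

    Peaks are matched one-to-one across replicates, closest ppm distance
    first, each peak used at most once.  Consensus m/z is the
    intensity-weighted mean, consensus intensity the arithmetic mean.
    Applies to groundwater duplicates only.
    """
    for rep in (rep_a, rep_b):
        if rep.role != "groundwater":
            raise ContractViolationError(
                "replicate intersection applies to groundwater samples only, "
                f"got role {rep.role!r}")
    if rep_a.sample_id != rep_b.sample_id:
        raise ContractViolationError("replicates must share sample_id")
    if rep_a.replicate == rep_b.replicate:
        raise ContractViolationError("replicate labels must differ")
    pairs = []
    for i, m in enumerate(rep_a.mz):
        j0 = np.searchsorted(rep_b.mz, m)
        for j in (j0 - 1, j0):
            if 0 <= j < rep_b.mz.size:
                dppm = abs(rep_b.mz[j] - m) / m * 1e6
                if dppm <= tol_ppm:
                    pairs.append((dppm, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    mz_out, int_out = [], []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        ia, ib = rep_a.intensity[i], rep_b.intensity[j]
        w = ia + ib
        if w > 0:
            mz_out.append((rep_a.mz[i] * ia + rep_b.mz[j] * ib) / w)
        else:
            mz_out.append(0.5 * (rep_a.mz[i] + rep_b.mz[j]))
        int_out.append(0.5 * (ia + ib))
    return Spectrum.from_arrays(
        mz_out, int_out, sample_id=rep_a.sample_id, role=rep_a.role,
        site=rep_a.site, well_or_location=rep_a.well_or_location,
        date=rep_a.date, replicate=None)


def normalize_tic(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by their sum (relative abundances, sum to 1)."""
    total = spectrum.tic
    if len(spectrum) == 0 or total <= 0:
        raise DegenerateInputError("cannot TIC-normalize an all-zero spectrum")
    return spectrum.replace_peaks(spectrum.mz, spectrum.intensity / total)
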