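"""Feature alignment and the percentage-similarity (PS) indicator.

PS between two TIC-normalized spectra is (1 - Bray-Curtis dissimilarity)
x 100, computed over features aligned across samples.  Each groundwater
sample is referenced against the full set of soil-seepage spectra from its
assigned reference site and the per-reference values averaged, which buffers
the indicator against spatial heterogeneity of the soil surface.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError
from .io import Spectrum


@dataclasses.dataclass
class FeatureMatrix:
    """Aligned features x samples relative-abundance matrix.

    Columns are renormalized to sum to 1 after alignment; absent features
    are zero.
    """

    mz: np.ndarray            # consensus feature m/z, ascending
    sample_ids: list[str]
    abundance: np.ndarray     # shape (n_features, n_samples)

    def column(self, sample_id: str) -> np.ndarray:
        return self.abundance[:, self.sample_ids.index(sample_id)]


def align_features(spectra: Sequence[Spectrum], tol_ppm: float = 2.0) -> FeatureMatrix:
    """Single-linkage gap clustering of the pooled m/z list.

    A new cluster starts when the gap to the left neighbour exceeds
    ``tol_ppm`` or the running cluster would exceed a width of 2 x tol_ppm
    relative to its first member.  Each sample contributes at most one peak
    per feature (highest intensity wins); columns are renormalized.
    """
    if not spectra:
        raise InsufficientDataError("no spectra to align")
    mz_all, int_all, samp_all = [], [], []
    for k, sp in enumerate(spectra):
        mz_all.append(sp.mz)
        int_all.append(sp.intensity)
        samp_all.append(np.full(len(sp), k, dtype=int))
    mz = np.concatenate(mz_all)
    inten = np.concatenate(int_all)
    samp = np.concatenate(samp_all)
    order = np.argsort(mz, kind="stable")
    mz, inten, samp = mz[order], inten[order], samp[order]

    cluster = np.empty(mz.size, dtype=int)
    cid = 0
    start_mz = mz[0] if mz.size else 0.0
    for i in range(mz.size):
        if i == 0:
            cluster[i] = 0
            continue
        gap_ppm = (mz[i] - mz[i - 1]) / mz[i - 1] * 1e6
        width_ppm = (mz[i] - start_mz) / start_mz * 1e6
        if gap_ppm > tol_ppm or width_ppm > 2 * tol_ppm:
            cid += 1
            start_mz = mz[i]
        cluster[i] = cid
    n_feat = cid + 1
    n_samp = len(spectra)

    w = np.bincount(cluster, weights=inten, minlength=n_feat)
    wm = np.bincount(cluster, weights=inten * mz, minlength=n_feat)
    cnt = np.bincount(cluster, minlength=n_feat)
    plain = np.bincount(cluster, weights=mz, minlength=n_feat)
    consensus = np.where(w > 0, np.divide(wm, w, out=np.zeros_like(w), where=w > 0),
                         plain / cnt)

    abundance = np.zeros((n_feat, n_samp))
    # highest intensity wins when a sample has several peaks in one feature
    for f, s, val in zip(cluster, samp, inten):
        if val > abundance[f, s]:
            abundance[f, s] = val
    totals = abundance.sum(axis=0)
    nonzero = totals > 0
    abundance[:, nonzero] /= totals[nonzero]
    return FeatureMatrix(mz=consensus, sample_ids=[sp.sample_id for sp in spectra],
                         abundance=abundance)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity  sum|u-v| / sum(u+v)  in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    denom = float((u + v).sum())
    if denom == 0:
        raise DegenerateInputError("Bray-Curtis undefined for two zero vectors")
    return float(np.abs(u - v).sum() / denom)


def ps_min_form(u, v) -> float:
    """Closed-form PS for normalized columns: 100 * sum(min(u, v)).

    Used as an internal cross-check of the ratio definition; the two agree
    exactly when both columns sum to one.
    """
    return 100.0 * float(np.minimum(np.asarray(u, float), np.asarray(v, float)).sum())


@dataclasses.dataclass(frozen=True)
class PSRecord:
    sample_id: str
    date: Optional[_dt.date]
    mean_ps: float
    per_reference_ps: tuple[float, ...]
    n_reference: int


def percentage_similarity(
    gw: np.ndarray,
    references: Sequence[np.ndarray],
    sample_id: str = "",
    date: Optional[_dt.date] = None,
) -> PSRecord:
    """PS of one groundwater column against each reference column, averaged."""
    if len(references) == 0:
        raise InsufficientDataError("need at least one reference column")
    per_ref = tuple((1.0 - bray_curtis(gw, r)) * 100.0 for r in references)
    return PSRecord(sample_id=sample_id, date=date,
                    mean_ps=float(np.mean(per_ref)),
                    per_reference_ps=per_ref, n_reference=len(per_ref))


@dataclasses.dataclass(frozen=True)
class DriftReport:
    n_measurements: int
    sd_ps: float
    kendall_tau_vs_index: float
    p_value: float
    drift_detected: bool


def reference_drift(reference_ps: Sequence[float], alpha: float = 0.05) -> DriftReport:
    """Drift QC on repeated reference-standard PS values.

    Reports the sample standard deviation and a Kendall trend test of PS
    against measurement order; drift is declared when p <= alpha.  An
    all-tied (constant) series has tau 0 and no drift by convention.
    """
    vals = np.asarray(reference_ps, dtype=float)
    if vals.size < 3:
        raise InsufficientDataError("drift QC needs >=3 reference measurements")
    sd = float(np.std(vals, ddof=1))
    from .trend import kendall_tau_test

    try:
        tau, p = kendall_tau_test(np.arange(vals.size), vals)
    except DegenerateInputError:
        tau, p = 0.0, 1.0
    return DriftReport(n_measurements=int(vals.size), sd_ps=sd,
                       kendall_tau_vs_index=float(tau), p_value=float(p),
                       drift_detected=bool(p <= alpha))


def reference_set_spread(references: Sequence[np.ndarray]) -> float:
    """Standard deviation among pairwise PS values of the seepage references
    themselves — a QC for surface heterogeneity of the reference set."""
    refs = list(references)
    if len(refs) < 2:
        return 0.0
    ps = [(1.0 - bray_curtis(refs[i], refs[j])) * 100.0
          for i in range(len(refs)) for j in range(i + 1, len(refs))]
    return float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0
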