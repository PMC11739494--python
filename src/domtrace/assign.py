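"""Molecular formula assignment for [M-H]- DOM spectra.

Candidate CHON(0-4)S(0-1) compositions are enumerated within a ppm window
around the neutral mass and filtered by the community-standard DOM
plausibility rules (integer non-negative DBE, H/C in [0.3, 2.5], O/C <= 1.2,
DBE <= 25).  Ties are broken deterministically: smallest |ppm error|, then
fewest heteroatoms (N+S), then fewest O.

The enumeration solves for the hydrogen count: for each (C, N, O, S) within
bounds there is at most one integer H whose composition mass falls inside
a <=10 ppm window (the proton mass dwarfs the window), so the grid over the
heavy elements is exhaustive.
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .chem import (MASS_C, MASS_H, MASS_N, MASS_O, MASS_S, PROTON_MASS,
                   MolecularFormula, passes_dom_filters)
from .errors import UnsupportedIonModeError
from .io import Spectrum


@dataclasses.dataclass(frozen=True)
class ElementRanges:
    """Inclusive element-count bounds for candidate enumeration."""

    c: tuple[int, int] = (1, 60)
    n: tuple[int, int] = (0, 4)
    o: tuple[int, int] = (0, 40)
    s: tuple[int, int] = (0, 1)
    dbe_max: float = 25.0
    hc_range: tuple[float, float] = (0.3, 2.5)
    oc_max: float = 1.2


DEFAULT_RANGES = ElementRanges()


def neutral_mass_from_mz(mz: float, ion_mode: str = "[M-H]-") -> float:
    """Neutral monoisotopic mass of a singly deprotonated ion."""
    if ion_mode != "[M-H]-":
        raise UnsupportedIonModeError(f"ion mode {ion_mode!r} not supported")
    return mz + PROTON_MASS


def mz_from_neutral_mass(neutral_mass: float, ion_mode: str = "[M-H]-") -> float:
    if ion_mode != "[M-H]-":
        raise UnsupportedIonModeError(f"ion mode {ion_mode!r} not supported")
    return neutral_mass - PROTON_MASS


_TABLE_CACHE: dict = {}


def _formula_table(ranges: ElementRanges):
    """Precomputed mass-sorted table of every composition passing the
    plausibility filters within the element bounds.

    Built once per ranges object and cached; candidate enumeration then
    reduces to a binary-search window on the mass axis.
    """
    key = (ranges.c, ranges.n, ranges.o, ranges.s, ranges.dbe_max,
           ranges.hc_range, ranges.oc_max)
    cached = _TABLE_CACHE.get(key)
    if cached is not None:
        return cached
    c = np.arange(ranges.c[0], ranges.c[1] + 1)
    n = np.arange(ranges.n[0], ranges.n[1] + 1)
    o = np.arange(ranges.o[0], ranges.o[1] + 1)
    s = np.arange(ranges.s[0], ranges.s[1] + 1)
    h_max = min(int(2 * ranges.c[1] + ranges.n[1] + 2),
                int(ranges.hc_range[1] * ranges.c[1]) + 1)
    h = np.arange(1, h_max + 1)
    C, H, N, O, S = (a.ravel() for a in np.meshgrid(c, h, n, o, s, indexing="ij"))
    ok = (H + N) % 2 == 0  # nitrogen rule (integer DBE)
    dbe = C - H / 2.0 + N / 2.0 + 1.0
    ok &= (dbe >= 0) & (dbe <= ranges.dbe_max)
    hc = H / C
    ok &= (hc >= ranges.hc_range[0]) & (hc <= ranges.hc_range[1])
    ok &= O / C <= ranges.oc_max
    C, H, N, O, S = C[ok], H[ok], N[ok], O[ok], S[ok]
    mass = (C * MASS_C + H * MASS_H + N * MASS_N + O * MASS_O + S * MASS_S)
    order = np.argsort(mass, kind="stable")
    table = (mass[order], C[order], H[order], N[order], O[order], S[order])
    _TABLE_CACHE[key] = table
    return table


def enumerate_candidates(
    neutral_mass: float,
    tol_ppm: float = 1.0,
    ranges: ElementRanges = DEFAULT_RANGES,
) -> list[MolecularFormula]:
    """All plausible CHNOS compositions within ``tol_ppm`` of a neutral mass.

    Returns formulas sorted by |ppm error| ascending, ties broken by (N+S)
    then O ascending.  May be empty.
    """
    mass, C, H, N, O, S = _formula_table(ranges)
    window = tol_ppm * 1e-6 * neutral_mass
    lo = np.searchsorted(mass, neutral_mass - window, side="left")
    hi = np.searchsorted(mass, neutral_mass + window, side="right")
    if lo == hi:
        return []
    err_ppm = (mass[lo:hi] - neutral_mass) / neutral_mass * 1e6
    keep = np.abs(err_ppm) <= tol_ppm
    idx = np.flatnonzero(keep) + lo
    if idx.size == 0:
        return []
    err = np.abs(err_ppm[keep])
    order = np.lexsort((O[idx], N[idx] + S[idx], err))
    idx = idx[order]
    return [MolecularFormula(c=int(C[i]), h=int(H[i]), n=int(N[i]),
                             o=int(O[i]), s=int(S[i])) for i in idx]


@dataclasses.dataclass(frozen=True)
class Assignment:
    """Formula assignment for one peak; formula is None when unassigned."""

    mz: float
    intensity: float
    formula: Optional[MolecularFormula]
    error_ppm: Optional[float]
    n_candidates: int


@dataclasses.dataclass(frozen=True)
class AssignmentQC:
    """Fraction of total spectral intensity carried by assigned peaks."""

    assigned_intensity_fraction: Optional[float]
    n_assigned: int
    n_peaks: int
    undefined: bool = False


def assign_spectrum(
    spectrum: Spectrum,
    tol_ppm: float = 1.0,
    policy: str = "strict",
    ranges: ElementRanges = DEFAULT_RANGES,
) -> tuple[list[Assignment], AssignmentQC]:
    """Assign formulas to every peak of a (recalibrated) spectrum.

    policy "best": take the top candidate after the deterministic sort.
    policy "strict": assign only when exactly one candidate survives.
    """
    if policy not in ("best", "strict"):
        raise ValueError(f"unknown policy {policy!r}")
    out: list[Assignment] = []
    assigned_intensity = 0.0
    for m, inten in zip(spectrum.mz, spectrum.intensity):
        cands = enumerate_candidates(neutral_mass_from_mz(m), tol_ppm, ranges)
        formula = None
        err = None
        if cands and (policy == "best" or len(cands) == 1):
            formula = cands[0]
            err = (m - mz_from_neutral_mass(formula.neutral_mass)) / m * 1e6
            assigned_intensity += inten
        out.append(Assignment(mz=float(m), intensity=float(inten),
                              formula=formula, error_ppm=err,
                              n_candidates=len(cands)))
    total = spectrum.tic
    if total <= 0 or len(spectrum) == 0:
        qc = AssignmentQC(None, 0, len(spectrum), undefined=True)
    else:
        qc = AssignmentQC(assigned_intensity / total,
                          sum(1 for a in out if a.formula is not None),
                          len(spectrum))
    return out, qc


# re-export filter for callers validating externally supplied formulas
is_plausible_formula = passes_dom_filters
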