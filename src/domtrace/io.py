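"""Peak-list and manifest I/O plus the core :class:`Spectrum` container.

The pipeline's atom is a centroided peak list (m/z, intensity) with sample
metadata.  On-disk format is CSV with header ``mz,intensity``; mzML files
holding a single centroided spectrum are read through pyteomics.  Peaks
closer than 0.2 ppm — well below the resolving power of the instruments
these lists come from — are merged on load (intensity-weighted mean m/z,
summed intensity).
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractViolationError, ParseError

ROLES = frozenset({"groundwater", "seepage", "blank", "reference"})

#: peaks closer than this are treated as one physical peak
MERGE_TOL_PPM = 0.2


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclasses.dataclass(frozen=True)
class Spectrum:
    """A centroided spectrum with sample metadata.

    ``mz`` is strictly ascending with gaps above 0.2 ppm; build instances via
    :meth:`from_arrays` (which sorts, validates and merges) rather than the
    raw constructor.
    """

    sample_id: str
    role: str
    site: str
    well_or_location: str
    date: Optional[_dt.date]
    replicate: Optional[int]
    mz: np.ndarray
    intensity: np.ndarray

    @classmethod
    def from_arrays(
        cls,
        mz,
        intensity,
        *,
        sample_id: str = "",
        role: str = "groundwater",
        site: str = "",
        well_or_location: str = "",
        date: Optional[_dt.date] = None,
        replicate: Optional[int] = None,
    ) -> "Spectrum":
        mz = np.asarray(mz, dtype=float)
        intensity = np.asarray(intensity, dtype=float)
        if role not in ROLES:
            raise ContractViolationError(f"unknown role {role!r}; expected one of {sorted(ROLES)}")
        if mz.shape != intensity.shape or mz.ndim != 1:
            raise ParseError("mz and intensity must be 1-D arrays of equal length")
        if mz.size and (mz <= 0).any():
            raise ParseError("all m/z values must be positive")
        if intensity.size and (intensity < 0).any():
            raise ParseError("intensities must be non-negative")
        order = np.argsort(mz, kind="stable")
        mz, intensity = _merge_close_peaks(mz[order], intensity[order])
        return cls(sample_id=sample_id, role=role, site=site,
                   well_or_location=well_or_location, date=date,
                   replicate=replicate, mz=mz, intensity=intensity)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def __len__(self) -> int:
        return int(self.mz.size)

    def replace_peaks(self, mz, intensity) -> "Spectrum":
        """New Spectrum with the same metadata and the given peaks."""
        return Spectrum.from_arrays(
            mz, intensity, sample_id=self.sample_id, role=self.role,
            site=self.site, well_or_location=self.well_or_location,
            date=self.date, replicate=self.replicate)


def _merge_close_peaks(mz: np.ndarray, intensity: np.ndarray,
                       tol_ppm: float = MERGE_TOL_PPM):
    """Merge sorted peaks closer than tol_ppm to their left neighbour.

    Merged m/z is the intensity-weighted mean, intensity the sum.  Runs of
    near-coincident peaks collapse to one.
    """
    if mz.size < 2:
        return mz.copy(), intensity.copy()
    gap_ppm = np.diff(mz) / mz[:-1] * 1e6
    if (gap_ppm > tol_ppm).all():
        return mz.copy(), intensity.copy()
    # cluster index increments whenever the gap to the left exceeds tol
    cluster = np.concatenate([[0], np.cumsum(gap_ppm > tol_ppm)])
    n = cluster[-1] + 1
    w = np.bincount(cluster, weights=intensity, minlength=n)
    wm = np.bincount(cluster, weights=intensity * mz, minlength=n)
    cnt = np.bincount(cluster, minlength=n)
    plain = np.bincount(cluster, weights=mz, minlength=n)
    # zero-intensity clusters fall back to the plain mean m/z
    out_mz = np.where(w > 0, np.divide(wm, w, out=np.zeros_like(w), where=w > 0),
                      plain / cnt)
    return out_mz, w


def read_peaklist(path, metadata: Optional[dict] = None) -> Spectrum:
    """Read a peak list (CSV ``mz,intensity`` or single-spectrum mzML).

    ``metadata`` is a manifest-row-like mapping supplying sample_id, role,
    site, well/location, date and replicate.
    """
    path = Path(path)
    meta = dict(metadata or {})
    kwargs = dict(
        sample_id=str(meta.get("sample_id", path.stem)),
        role=str(meta.get("role", "groundwater")),
        site=str(meta.get("site", "")),
        well_or_location=str(meta.get("well", meta.get("location", meta.get("well_or_location", "")))),
        date=_coerce_date(meta.get("date")),
        replicate=_coerce_replicate(meta.get("replicate")),
    )
    if path.suffix.lower() == ".mzml":
        mz, intensity = _read_mzml(path)
        return Spectrum.from_arrays(mz, intensity, **kwargs)
    return Spectrum.from_arrays(*_read_csv_peaks(path), **kwargs)


def _read_csv_peaks(path: Path):
    try:
        text = path.read_text()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    lines = text.splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = [h.strip().lower() for h in lines[0].split(",")]
    if header[:2] != ["mz", "intensity"]:
        raise ParseError(f"{path}: line 1: expected header 'mz,intensity', got {lines[0]!r}")
    mzs, intens = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        try:
            m = float(parts[0])
            i = float(parts[1])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}: line {lineno}: malformed row {line!r}") from exc
        if m <= 0:
            raise ParseError(f"{path}: line {lineno}: non-positive m/z {m}")
        if i < 0:
            raise ParseError(f"{path}: line {lineno}: negative intensity {i}")
        mzs.append(m)
        intens.append(i)
    return np.array(mzs, dtype=float), np.array(intens, dtype=float)


def _read_mzml(path: Path):
    from pyteomics import mzml as _mzml

    with _mzml.read(str(path)) as reader:
        for entry in reader:
            return (np.asarray(entry["m/z array"], dtype=float),
                    np.asarray(entry["intensity array"], dtype=float))
    raise ParseError(f"{path}: mzML file contains no spectrum")


def write_peaklist(spectrum: Spectrum, path) -> None:
    """Write a spectrum as CSV; round-trips through :func:`read_peaklist`
    losslessly within IEEE double precision (repr round-trip)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r},{float(i)!r}\n")


MANIFEST_COLUMNS = ["sample_id", "role", "site", "well", "location",
                    "date", "replicate", "file"]


def read_manifest(path) -> pd.DataFrame:
    """Load a sample manifest CSV and validate its contract.

    sample_id must be unique per (sample_id, replicate); every referenced
    file must exist relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate": "Int64"})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: manifest missing columns {missing}")
    bad_roles = set(df["role"]) - ROLES
    if bad_roles:
        raise ParseError(f"{path}: unknown roles {sorted(bad_roles)}")
    keys = list(zip(df["sample_id"], df["replicate"].fillna(-1)))
    if len(keys) != len(set(keys)):
        raise ParseError(f"{path}: duplicate (sample_id, replicate) rows")
    root = path.parent
    for _, row in df.iterrows():
        f = root / row["file"]
        if not f.exists():
            raise ParseError(f"{path}: referenced file missing: {row['file']}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    df.attrs["root"] = str(root)
    return df


def load_spectra(manifest: pd.DataFrame) -> list[Spectrum]:
    """Read every spectrum referenced by a manifest."""
    root = Path(manifest.attrs.get("root", "."))
    out = []
    for _, row in manifest.iterrows():
        meta = row.to_dict()
        out.append(read_peaklist(root / row["file"], meta))
    return out


def _coerce_date(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, _dt.date) and not isinstance(value, _dt.datetime):
        return value
    return pd.Timestamp(value).date()


def _coerce_replicate(value):
    if value is None or value is pd.NA:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    return int(value)
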