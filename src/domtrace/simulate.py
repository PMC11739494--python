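"""Synthetic monitoring campaign with known ground truth.

The generator emulates the sampling design of a multi-year groundwater
monitoring effort: quarterly groundwater duplicates per well, recurring
soil-seepage samples from a few surface locations, procedural blanks, and a
repeatedly measured in-house reference standard.  Each groundwater spectrum
is a two-endmember mixture — alpha(t) x seepage + (1 - alpha(t)) x deep
groundwater — where the seepage mixing fraction alpha carries a linear
trend, a seasonal sinusoid and a step (optionally a slope change) at a
drought breakpoint.  Spectra are perturbed by multiplicative intensity
noise, per-peak detection dropout, planted electronic-noise peaks, blank
contaminants, and a linear ppm-scale mass-calibration error.

Design notes
------------
* Endmember intensities are log-normal (sigma = 1), the heavy-tailed
  abundance profile typical of DOM spectra.
* Formulas shared by both endmembers carry the same intensity in each, and
  the seepage-only block is rescaled to the groundwater-only block total, so
  mixing preserves the TIC.  This makes the mixing fraction identifiable
  from composition alone and gives background pathways an exactly null
  abundance trend (see docs/methods.md).
* Three CH2-homologous CHO series are planted in the shared background so
  every sample spectrum supports series-based recalibration.
* All randomness flows through numpy SeedSequences keyed on (seed, stream),
  so regeneration from the same (config, seed) is bit-identical.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import math
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chem import MolecularFormula, passes_dom_filters
from .errors import ValidationError
from .io import MANIFEST_COLUMNS, Spectrum, write_peaklist

SUBSETS = ("seepage_only", "groundwater_only", "shared", "contaminant")

_PATHWAY_GROUPS = (
    "Xenobiotics biodegradation and metabolism",
    "Biosynthesis of secondary metabolites",
    "Carbohydrate metabolism",
    "Amino acid metabolism",
    "Energy metabolism",
)

# (o, dbe, c range) of the planted CH2-homologous recalibrant series
_SEED_SERIES = ((4, 4, range(8, 25)), (7, 7, range(10, 27)), (2, 2, range(6, 21)))


#: Kendrick-defect band kept free of library formulas; covers the noise
#: estimator's default void window (0.90, 0.95) with margin.  Real DOM
#: spectra have such voids because plausible compositions cluster in defect
#: bands; the generator reproduces that structure.
VOID_BAND = (0.89, 0.96)


def _in_void_band(f: MolecularFormula) -> bool:
    from .chem import kendrick_mass_defect

    kmd = float(kendrick_mass_defect(f.mz_deprotonated()))
    return VOID_BAND[0] < kmd < VOID_BAND[1]


def make_formula_library(seed: int, n_formulas: int) -> list[MolecularFormula]:
    """Draw a deduplicated CHON(0-4)S(0-1) formula library.

    C in [4, 40], O in [0, 30], neutral mass in [100, 900] Da; every formula
    passes the standard DOM plausibility filters and avoids the Kendrick
    void band exploited by noise estimation.  Heteroatom counts are drawn
    with weights favouring CHO, matching the composition balance of natural
    DOM, and three CH2-homologous CHO series are planted first.
    Deterministic in (seed, n_formulas); output sorted by neutral mass.
    """
    if n_formulas < 10:
        raise ValidationError(f"n_formulas must be >= 10, got {n_formulas}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    out: set[MolecularFormula] = set()
    for o, dbe, c_range in _SEED_SERIES:
        for c in c_range:
            h = 2 * (c + 1 - dbe)
            f = MolecularFormula(c=c, h=h, o=o)
            if (passes_dom_filters(f) and 100.0 <= f.neutral_mass <= 900.0
                    and not _in_void_band(f)):
                out.add(f)
            if len(out) >= n_formulas:
                break
        if len(out) >= n_formulas:
            break
    n_weights = np.array([0.55, 0.20, 0.12, 0.08, 0.05])
    s_weights = np.array([0.88, 0.12])
    while len(out) < n_formulas:
        c = int(rng.integers(4, 41))
        n = int(rng.choice(5, p=n_weights))
        s = int(rng.choice(2, p=s_weights))
        o = int(rng.integers(0, min(30, int(1.2 * c)) + 1))
        h_lo = max(2, math.ceil(0.3 * c), 2 * c + n - 48)
        h_hi = min(math.floor(2.5 * c), 2 * c + n + 2)
        if h_lo > h_hi:
            continue
        h = int(rng.integers(h_lo, h_hi + 1))
        if (h + n) % 2:
            h += 1 if h < h_hi else -1
        f = MolecularFormula(c=c, h=h, n=n, o=o, s=s)
        if (passes_dom_filters(f) and 100.0 <= f.neutral_mass <= 900.0
                and not _in_void_band(f)):
            out.add(f)
    return sorted(out, key=lambda f: f.neutral_mass)


@dataclasses.dataclass
class TrajectoryComponents:
    """Parametric form of the seepage mixing fraction alpha(t)."""

    baseline: float = 0.2
    slope_per_year: float = 0.0375     # ~0.2 -> 0.5 over eight years
    step: float = 0.05                 # applied at/after break_date
    seasonal_amplitude: float = 0.03
    break_date: _dt.date = _dt.date(2018, 7, 1)
    slope_post: Optional[float] = None  # slope after break; None = unchanged


@dataclasses.dataclass
class MixingTrajectory:
    well_id: str
    times: list[_dt.date]
    alpha: np.ndarray
    components: TrajectoryComponents
    seasonal_phase: float

    @staticmethod
    def evaluate(components: TrajectoryComponents, times: Sequence[_dt.date],
                 phase: float) -> np.ndarray:
        t0 = times[0]
        t = np.array([(d - t0).days for d in times], float) / 365.25
        tb = (components.break_date - t0).days / 365.25
        alpha = components.baseline + components.slope_per_year * t
        post = t >= tb
        alpha[post] += components.step
        if components.slope_post is not None:
            alpha[post] += (components.slope_post - components.slope_per_year) * (t[post] - tb)
        alpha += components.seasonal_amplitude * np.sin(2 * np.pi * (t + phase))
        return np.clip(alpha, 0.0, 1.0)

    @classmethod
    def build(cls, well_id: str, times: Sequence[_dt.date],
              components: TrajectoryComponents, phase: float) -> "MixingTrajectory":
        return cls(well_id=well_id, times=list(times),
                   alpha=cls.evaluate(components, times, phase),
                   components=components, seasonal_phase=phase)


@dataclasses.dataclass
class SimulationConfig:
    """All generator knobs; defaults are the campaign's study conditions."""

    n_formulas: int = 500
    wells: tuple = ("well-1", "well-2", "well-3")
    site: str = "site-A"
    seepage_locations: tuple = ("loc-1", "loc-2")
    start_date: _dt.date = _dt.date(2014, 1, 15)
    n_quarters: int = 32
    trajectory: TrajectoryComponents = dataclasses.field(default_factory=TrajectoryComponents)
    n_seepage_per_location: int = 8
    n_blanks: int = 3
    n_reference: int = 12
    alpha_reference: float = 0.5
    # noise model
    intensity_cv: float = 0.2
    dropout: float = 0.05
    n_noise_peaks: int = 300
    noise_intensity_range: tuple = (5.0, 15.0)
    base_intensity_scale: float = 1e4
    lognormal_sigma: float = 1.0
    location_sigma: float = 0.3
    contaminant_scale: float = 5e4
    # calibration error model (ppm intercept + ppm-per-Th slope, per spectrum)
    cal_intercept_mean: float = 1.2
    cal_intercept_sd: float = 0.4
    cal_slope_sd: float = 3e-4
    mz_jitter_ppm: float = 0.03
    # library partition fractions (remainder is shared)
    frac_contaminant: float = 0.04
    frac_seepage_only: float = 0.26
    frac_groundwater_only: float = 0.26

    def validate(self) -> None:
        if not 0.0 <= self.dropout <= 1.0:
            raise ValidationError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.intensity_cv < 0:
            raise ValidationError("intensity_cv must be >= 0")
        if self.n_quarters < 1 or self.n_formulas < 10:
            raise ValidationError("campaign needs >=1 quarter and >=10 formulas")
        fr = self.frac_contaminant + self.frac_seepage_only + self.frac_groundwater_only
        if not 0.0 < fr < 1.0:
            raise ValidationError("subset fractions must leave a shared remainder")
        if not 0.0 <= self.alpha_reference <= 1.0:
            raise ValidationError("alpha_reference must be in [0, 1]")
        if self.n_noise_peaks < 0 or self.n_blanks < 0 or self.n_reference < 0:
            raise ValidationError("counts must be non-negative")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "trajectory" in data and isinstance(data["trajectory"], dict):
            tdata = dict(data["trajectory"])
            tknown = {f.name for f in dataclasses.fields(TrajectoryComponents)}
            tunknown = set(tdata) - tknown
            if tunknown:
                raise ValidationError(f"unknown trajectory keys: {sorted(tunknown)}")
            if "break_date" in tdata and isinstance(tdata["break_date"], str):
                tdata["break_date"] = _dt.date.fromisoformat(tdata["break_date"])
            data["trajectory"] = TrajectoryComponents(**tdata)
        for key in ("wells", "seepage_locations", "noise_intensity_range"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "start_date" in data and isinstance(data["start_date"], str):
            data["start_date"] = _dt.date.fromisoformat(data["start_date"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclasses.dataclass
class SyntheticTruth:
    """Ground truth of a generated campaign; JSON-serializable losslessly."""

    seed: int
    trajectories: dict            # well_id -> MixingTrajectory
    library: dict                 # subset name -> list of formula strings
    endmembers: dict              # subset name -> {formula string: intensity}
    calibration: dict             # sample file stem -> {"intercept_ppm", "slope_ppm_per_mz"}
    enriched_pathways: list = dataclasses.field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "trajectories": {
                w: {
                    "well_id": t.well_id,
                    "times": [d.isoformat() for d in t.times],
                    "alpha": list(map(float, t.alpha)),
                    "seasonal_phase": t.seasonal_phase,
                    "components": {
                        "baseline": t.components.baseline,
                        "slope_per_year": t.components.slope_per_year,
                        "step": t.components.step,
                        "seasonal_amplitude": t.components.seasonal_amplitude,
                        "break_date": t.components.break_date.isoformat(),
                        "slope_post": t.components.slope_post,
                    },
                } for w, t in self.trajectories.items()
            },
            "library": self.library,
            "endmembers": self.endmembers,
            "calibration": self.calibration,
            "enriched_pathways": list(self.enriched_pathways),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        trajectories = {}
        for w, t in payload["trajectories"].items():
            comp = dict(t["components"])
            comp["break_date"] = _dt.date.fromisoformat(comp["break_date"])
            components = TrajectoryComponents(**comp)
            trajectories[w] = MixingTrajectory(
                well_id=t["well_id"],
                times=[_dt.date.fromisoformat(d) for d in t["times"]],
                alpha=np.array(t["alpha"], float),
                components=components,
                seasonal_phase=t["seasonal_phase"])
        return cls(seed=payload["seed"], trajectories=trajectories,
                   library=payload["library"], endmembers=payload["endmembers"],
                   calibration=payload["calibration"],
                   enriched_pathways=payload["enriched_pathways"])


def partition_library(formulas: Sequence[MolecularFormula], seed: int,
                      config: SimulationConfig) -> dict[str, list[MolecularFormula]]:
    """Deterministically split the library into the four source subsets.

    The planted CH2 recalibrant series stay in the shared background so that
    every sample spectrum supports recalibration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    series_keys = set()
    for o, dbe, c_range in _SEED_SERIES:
        for c in c_range:
            series_keys.add((c, 2 * (c + 1 - dbe), 0, o, 0))
    is_series = np.array([(f.c, f.h, f.n, f.o, f.s) in series_keys for f in formulas])
    free_idx = np.flatnonzero(~is_series)
    perm = rng.permutation(free_idx)
    n = len(formulas)
    n_cont = int(round(config.frac_contaminant * n))
    n_seep = int(round(config.frac_seepage_only * n))
    n_gw = int(round(config.frac_groundwater_only * n))
    parts = {
        "contaminant": perm[:n_cont],
        "seepage_only": perm[n_cont:n_cont + n_seep],
        "groundwater_only": perm[n_cont + n_seep:n_cont + n_seep + n_gw],
    }
    shared = np.concatenate([perm[n_cont + n_seep + n_gw:], np.flatnonzero(is_series)])
    out = {k: sorted((formulas[i] for i in v), key=lambda f: f.neutral_mass)
           for k, v in parts.items()}
    out["shared"] = sorted((formulas[i] for i in shared), key=lambda f: f.neutral_mass)
    return out


def _endmember_intensities(partition, seed: int, config: SimulationConfig):
    """Log-normal endmember vectors; seepage-only block rescaled to the
    groundwater-only block total so mixing preserves the TIC."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    scale = config.base_intensity_scale
    sig = config.lognormal_sigma
    shared = {str(f): float(v) for f, v in zip(
        partition["shared"], scale * rng.lognormal(0.0, sig, len(partition["shared"])))}
    seep = {str(f): float(v) for f, v in zip(
        partition["seepage_only"], scale * rng.lognormal(0.0, sig, len(partition["seepage_only"])))}
    gw = {str(f): float(v) for f, v in zip(
        partition["groundwater_only"], scale * rng.lognormal(0.0, sig, len(partition["groundwater_only"])))}
    cont = {str(f): float(v) for f, v in zip(
        partition["contaminant"],
        config.contaminant_scale * rng.lognormal(0.0, 0.5, len(partition["contaminant"])))}
    total_gw = sum(gw.values())
    total_seep = sum(seep.values())
    if total_seep > 0:
        factor = total_gw / total_seep
        seep = {k: v * factor for k, v in seep.items()}
    return {"shared": shared, "seepage_only": seep, "groundwater_only": gw,
            "contaminant": cont}


def _quarter_dates(start: _dt.date, n_quarters: int) -> list[_dt.date]:
    dates = []
    y, m = start.year, start.month
    for _ in range(n_quarters):
        dates.append(_dt.date(y, m, min(start.day, 28)))
        m += 3
        if m > 12:
            m -= 12
            y += 1
    return dates


def _spread_dates(start: _dt.date, end: _dt.date, n: int) -> list[_dt.date]:
    if n == 1:
        return [start]
    span = (end - start).days
    return [start + _dt.timedelta(days=round(i * span / (n - 1))) for i in range(n)]


class _CampaignBuilder:
    def __init__(self, config: SimulationConfig, seed: int):
        config.validate()
        self.config = config
        self.seed = int(seed)
        self.library = make_formula_library(seed, config.n_formulas)
        self.partition = partition_library(self.library, seed, config)
        self.endmembers = _endmember_intensities(self.partition, seed, config)
        # full feature axis: every non-contaminant formula, ascending ion m/z
        feats = (self.partition["shared"] + self.partition["seepage_only"]
                 + self.partition["groundwater_only"])
        self.features = sorted(feats, key=lambda f: f.mz_deprotonated())
        self.feat_mz = np.array([f.mz_deprotonated() for f in self.features])
        em = self.endmembers
        self.vec_seep = np.array([em["shared"].get(str(f), 0.0)
                                  + em["seepage_only"].get(str(f), 0.0)
                                  for f in self.features])
        self.vec_deep = np.array([em["shared"].get(str(f), 0.0)
                                  + em["groundwater_only"].get(str(f), 0.0)
                                  for f in self.features])
        self.cont_mz = np.array([f.mz_deprotonated() for f in self.partition["contaminant"]])
        self.cont_int = np.array([em["contaminant"][str(f)]
                                  for f in self.partition["contaminant"]])
        self.all_lib_mz = np.sort(np.concatenate([self.feat_mz, self.cont_mz]))
        rng_phase = np.random.default_rng(np.random.SeedSequence([self.seed, 3]))
        self.phases = {w: float(rng_phase.uniform(0, 1)) for w in config.wells}
        rng_loc = np.random.default_rng(np.random.SeedSequence([self.seed, 4]))
        self.loc_factors = {
            loc: np.exp(rng_loc.normal(0.0, config.location_sigma, self.feat_mz.size))
            for loc in config.seepage_locations}
        self.calibration: dict[str, dict] = {}

    # --- per-sample machinery -------------------------------------------
    def _rng(self, idx: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, 100 + idx]))

    def _noise_peaks(self, rng):
        cfg = self.config
        n = cfg.n_noise_peaks
        if n == 0:
            return np.empty(0), np.empty(0)
        mzs: list[float] = []
        while len(mzs) < n:
            draw = rng.uniform(100.0, 900.0, 2 * (n - len(mzs)))
            idx = np.clip(np.searchsorted(self.all_lib_mz, draw), 1, self.all_lib_mz.size - 1)
            near = np.minimum(np.abs(draw - self.all_lib_mz[idx - 1]),
                              np.abs(draw - self.all_lib_mz[idx]))
            ok = near / draw * 1e6 > 5.0
            mzs.extend(draw[ok][: n - len(mzs)])
        inten = rng.uniform(*cfg.noise_intensity_range, n)
        return np.array(mzs), inten

    def _perturb(self, mz, inten, rng, dropout=True):
        cfg = self.config
        if cfg.intensity_cv > 0:
            sigma = math.sqrt(math.log(1.0 + cfg.intensity_cv ** 2))
            inten = inten * rng.lognormal(0.0, sigma, inten.size)
        else:
            inten = inten.copy()
        if dropout and cfg.dropout > 0:
            keep = rng.uniform(size=inten.size) >= cfg.dropout
            mz, inten = mz[keep], inten[keep]
        return mz, inten

    def _calibrate(self, mz, rng, stem: str):
        cfg = self.config
        a = float(rng.normal(cfg.cal_intercept_mean, cfg.cal_intercept_sd)) \
            if cfg.cal_intercept_sd > 0 or cfg.cal_intercept_mean != 0 else 0.0
        b = float(rng.normal(0.0, cfg.cal_slope_sd)) if cfg.cal_slope_sd > 0 else 0.0
        self.calibration[stem] = {"intercept_ppm": a, "slope_ppm_per_mz": b}
        out = mz * (1.0 + (a + b * mz) * 1e-6)
        if cfg.mz_jitter_ppm > 0:
            out = out * (1.0 + rng.normal(0.0, cfg.mz_jitter_ppm, mz.size) * 1e-6)
        return out

    def _compose(self, base_mz, base_int, rng, stem, *, contaminants=True,
                 dropout=True):
        mz, inten = base_mz, base_int
        nonzero = inten > 0
        mz, inten = mz[nonzero], inten[nonzero]
        mz, inten = self._perturb(mz, inten, rng, dropout=dropout)
        if contaminants and self.cont_mz.size:
            cmz, cint = self._perturb(self.cont_mz, self.cont_int, rng, dropout=False)
            mz = np.concatenate([mz, cmz])
            inten = np.concatenate([inten, cint])
        nmz, nint = self._noise_peaks(rng)
        mz = np.concatenate([mz, nmz])
        inten = np.concatenate([inten, nint])
        mz = self._calibrate(mz, rng, stem)
        return mz, inten

    def build(self):
        cfg = self.config
        quarters = _quarter_dates(cfg.start_date, cfg.n_quarters)
        end = quarters[-1]
        trajectories = {
            w: MixingTrajectory.build(w, quarters, cfg.trajectory, self.phases[w])
            for w in cfg.wells}
        samples = []   # (stem, spectrum, manifest row)
        idx = 0

        def manifest_row(stem, role, well, location, date, replicate):
            return {"sample_id": stem.rsplit("-r", 1)[0] if replicate else stem,
                    "role": role, "site": cfg.site, "well": well,
                    "location": location, "date": date.isoformat(),
                    "replicate": replicate, "file": f"{stem}.csv"}

        for w in cfg.wells:
            traj = trajectories[w]
            for q, (date, alpha) in enumerate(zip(traj.times, traj.alpha)):
                base = alpha * self.vec_seep + (1.0 - alpha) * self.vec_deep
                for rep in (1, 2):
                    stem = f"gw-{w}-q{q:02d}-r{rep}"
                    rng = self._rng(idx); idx += 1
                    mz, inten = self._compose(self.feat_mz, base, rng, stem)
                    sp = Spectrum.from_arrays(
                        mz, inten, sample_id=f"gw-{w}-q{q:02d}", role="groundwater",
                        site=cfg.site, well_or_location=w, date=date, replicate=rep)
                    samples.append((stem, sp, manifest_row(stem, "groundwater", w,
                                                           "", date, rep)))
        for loc in cfg.seepage_locations:
            dates = _spread_dates(cfg.start_date, end, cfg.n_seepage_per_location)
            base = self.vec_seep * self.loc_factors[loc]
            for k, date in enumerate(dates):
                stem = f"seep-{loc}-{k:02d}"
                rng = self._rng(idx); idx += 1
                mz, inten = self._compose(self.feat_mz, base, rng, stem)
                sp = Spectrum.from_arrays(
                    mz, inten, sample_id=stem, role="seepage", site=cfg.site,
                    well_or_location=loc, date=date, replicate=None)
                samples.append((stem, sp, manifest_row(stem, "seepage", "", loc,
                                                       date, None)))
        for k, date in enumerate(_spread_dates(cfg.start_date, end, max(cfg.n_blanks, 1))
                                 [: cfg.n_blanks]):
            stem = f"blank-{k:02d}"
            rng = self._rng(idx); idx += 1
            mz, inten = self._compose(np.empty(0), np.empty(0), rng, stem)
            sp = Spectrum.from_arrays(mz, inten, sample_id=stem, role="blank",
                                      site=cfg.site, well_or_location="",
                                      date=date, replicate=None)
            samples.append((stem, sp, manifest_row(stem, "blank", "", "", date, None)))
        ref_base = (cfg.alpha_reference * self.vec_seep
                    + (1.0 - cfg.alpha_reference) * self.vec_deep)
        for k, date in enumerate(_spread_dates(cfg.start_date, end, max(cfg.n_reference, 1))
                                 [: cfg.n_reference]):
            stem = f"ref-{k:02d}"
            rng = self._rng(idx); idx += 1
            mz, inten = self._compose(self.feat_mz, ref_base, rng, stem)
            sp = Spectrum.from_arrays(mz, inten, sample_id=stem, role="reference",
                                      site=cfg.site, well_or_location="",
                                      date=date, replicate=None)
            samples.append((stem, sp, manifest_row(stem, "reference", "", "", date, None)))

        truth = SyntheticTruth(
            seed=self.seed, trajectories=trajectories,
            library={k: [str(f) for f in v] for k, v in self.partition.items()},
            endmembers=self.endmembers, calibration=self.calibration)
        manifest = pd.DataFrame([row for _, _, row in samples],
                                columns=MANIFEST_COLUMNS)
        return samples, manifest, truth


def generate_campaign(config: SimulationConfig, seed: int):
    """In-memory campaign: (list of (stem, Spectrum), manifest df, truth)."""
    return _CampaignBuilder(config, seed).build()


def simulate_campaign(config: SimulationConfig, seed: int, outdir):
    """Write a full synthetic campaign to ``outdir``.

    Produces per-sample CSV peak lists, ``manifest.csv`` and ``truth.json``;
    returns (manifest DataFrame, SyntheticTruth).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples, manifest, truth = generate_campaign(config, seed)
    for stem, spectrum, _ in samples:
        write_peaklist(spectrum, outdir / f"{stem}.csv")
    manifest.to_csv(outdir / "manifest.csv", index=False)
    truth.to_json(outdir / "truth.json")
    return manifest, truth


def simulate_isotopes(
    wells: Sequence[str],
    years: Sequence[int],
    base_variance: float,
    variance_growth: float,
    seed: int,
    n_per_year: int = 12,
    seasonal_amplitude: float = 0.1,
    mean_delta18O: float = -9.0,
) -> tuple[pd.DataFrame, dict]:
    """Seasonal delta-18O series with linearly growing intra-annual variance.

    Per well-year, values follow a seasonal sinusoid plus Gaussian noise
    whose variance grows by ``variance_growth`` per year from
    ``base_variance``.  Returns (observations DataFrame with columns well,
    date, delta18O; truth dict well -> year -> total true variance, i.e.
    noise variance plus the sinusoid population variance amplitude^2/2).
    """
    if base_variance <= 0:
        raise ValidationError("base_variance must be > 0")
    if n_per_year < 3:
        raise ValidationError("need >= 3 observations per well-year")
    years = sorted(int(y) for y in years)
    rows = []
    truth: dict[str, dict[int, float]] = {}
    for wi, well in enumerate(wells):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5, wi]))
        truth[well] = {}
        for k, year in enumerate(years):
            var = base_variance + variance_growth * k
            truth[well][year] = var + seasonal_amplitude ** 2 / 2.0
            doy = np.linspace(15, 350, n_per_year)
            vals = (mean_delta18O
                    + seasonal_amplitude * np.sin(2 * np.pi * doy / 365.25)
                    + rng.normal(0.0, math.sqrt(var), n_per_year))
            for d, v in zip(doy, vals):
                rows.append({"well": well,
                             "date": _dt.date(year, 1, 1) + _dt.timedelta(days=int(d) - 1),
                             "delta18O": float(v)})
    return pd.DataFrame(rows), truth


def simulate_pathway_db(
    n_pathways: int,
    size_range: tuple[int, int],
    n_enriched: int,
    partition: dict[str, Sequence[MolecularFormula]],
    seed: int,
    wells: Sequence[str] = ("well-1", "well-2", "well-3"),
    presence_prob: float = 0.85,
    enriched_seepage_fraction: float = 0.8,
):
    """Toy pathway database with planted seepage-enriched pathways.

    Enriched pathways draw >= ``enriched_seepage_fraction`` of their members
    from the seepage-only library subset (the rest from the shared
    background); background pathways draw from shared (70%) and
    groundwater-only (30%) subsets, never seepage-only, so their summed
    abundance carries no mixing trend.  MAG profiles mark enriched pathways
    present in every well and others present with ``presence_prob``.

    Returns (compound table df, pathway metadata df, MAG profiles dict,
    set of enriched pathway ids).
    """
    if n_enriched > n_pathways:
        raise ValidationError("n_enriched must be <= n_pathways")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    seep = list(partition["seepage_only"])
    shared = list(partition["shared"])
    gw = list(partition["groundwater_only"])
    comp_rows, meta_rows = [], []
    profiles: dict[str, set] = {w: set() for w in wells}
    enriched_ids = []
    cpd = 0
    for i in range(n_pathways):
        pid = f"pw{i:03d}"
        enriched = i < n_enriched
        k = int(rng.integers(size_range[0], size_range[1] + 1))
        if enriched:
            k_seep = min(math.ceil(enriched_seepage_fraction * k), len(seep))
            members = list(rng.choice(len(seep), k_seep, replace=False))
            members = [seep[j] for j in members]
            rest = [shared[j] for j in rng.choice(len(shared), k - k_seep, replace=False)]
            members += rest
            enriched_ids.append(pid)
        else:
            k_shared = min(math.ceil(0.7 * k), len(shared))
            members = [shared[j] for j in rng.choice(len(shared), k_shared, replace=False)]
            members += [gw[j] for j in rng.choice(len(gw), k - k_shared, replace=False)]
        for f in members:
            comp_rows.append({"compound_id": f"cpd{cpd:05d}", "formula": str(f),
                              "pathway_ids": pid})
            cpd += 1
        meta_rows.append({"pathway_id": pid, "name": f"pathway {i}",
                          "group": _PATHWAY_GROUPS[int(rng.integers(len(_PATHWAY_GROUPS)))]})
        for w in wells:
            if enriched or rng.uniform() < presence_prob:
                profiles[w].add(pid)
    compounds = pd.DataFrame(comp_rows)
    meta = pd.DataFrame(meta_rows)
    return compounds, meta, profiles, set(enriched_ids)
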