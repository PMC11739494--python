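"""End-to-end orchestration: simulate/load -> preprocess -> assign ->
similarity -> trend -> pathway screen -> report.

One :class:`RunConfig` drives every stage; the resolved configuration is
written next to the outputs so a run is reproducible by construction.  All
randomness is confined to the generator seed; the processing stages are
deterministic, so rerunning the same (config, seed) yields an identical
report body.
"""
from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import preprocess as pp
from .assign import assign_spectrum
from .errors import (DomtraceError, InsufficientDataError,
                     InsufficientRecalibrantsError, ValidationError)
from .io import Spectrum, load_spectra, read_manifest
from .pathways import (ambiguity_metrics, build_formula_index,
                       detect_pathway_abundance, read_compound_table,
                       read_mag_profiles, screen_correlations)
from .similarity import (align_features, percentage_similarity,
                         reference_drift, reference_set_spread)
from .simulate import (SimulationConfig, generate_campaign, simulate_campaign,
                       simulate_pathway_db)
from .trend import STLParams, linear_trend, piecewise_slopes, quarterly_series, stl_decompose

log = logging.getLogger("domtrace")


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration for a full pipeline run."""

    outdir: str = "domtrace-run"
    seed: int = 0
    simulation: Optional[SimulationConfig] = dataclasses.field(
        default_factory=SimulationConfig)
    manifest: Optional[str] = None        # use existing data instead of simulating
    compound_table: Optional[str] = None
    mag_profiles: Optional[str] = None
    # preprocessing
    snr_threshold: float = 10.0
    tol_ppm: float = 2.0
    blank_cum_fraction: float = 0.95
    recalibrant_tol_ppm: float = 3.0
    # assignment
    assign_tol_ppm: float = 1.0
    assign_policy: str = "strict"
    # trend
    stl: STLParams = dataclasses.field(default_factory=STLParams)
    break_date: _dt.date = _dt.date(2018, 7, 1)
    # pathway screen (synthetic database when no compound table is given)
    run_pathways: bool = True
    n_pathways: int = 30
    pathway_size_range: tuple = (12, 30)
    n_enriched: int = 6
    screen_alpha: float = 0.01
    min_formulas: int = 10
    min_fraction: float = 0.25

    def validate(self) -> None:
        if self.simulation is not None:
            self.simulation.validate()
        if not 0.0 <= self.blank_cum_fraction <= 1.0:
            raise ValidationError("blank_cum_fraction must be in [0, 1]")
        if self.snr_threshold < 0 or self.tol_ppm <= 0:
            raise ValidationError("snr_threshold >= 0 and tol_ppm > 0 required")
        if self.assign_policy not in ("strict", "best"):
            raise ValidationError(f"unknown assignment policy {self.assign_policy!r}")
        if not 0 < self.screen_alpha < 1:
            raise ValidationError("screen_alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(data.get("simulation"), dict):
            data["simulation"] = SimulationConfig.from_dict(data["simulation"])
        if isinstance(data.get("stl"), dict):
            data["stl"] = STLParams(**data["stl"])
        if isinstance(data.get("break_date"), str):
            data["break_date"] = _dt.date.fromisoformat(data["break_date"])
        if isinstance(data.get("pathway_size_range"), list):
            data["pathway_size_range"] = tuple(data["pathway_size_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return enc(dataclasses.asdict(obj))
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, _dt.date):
                return obj.isoformat()
            return obj
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def preprocess_spectra(spectra: list[Spectrum], config: RunConfig):
    """Run the cleaning chain; returns (processed sample spectra, QC dict).

    Order: S/N filter -> recalibrate -> blank subtract -> replicate
    intersect (groundwater) -> TIC normalize.  Blanks receive the S/N filter
    only and are pooled into one composite blank.
    """
    qc: dict = {"n_input": len(spectra), "recalibration": {}}
    blanks = [s for s in spectra if s.role == "blank"]
    samples = [s for s in spectra if s.role != "blank"]

    def snr(s: Spectrum) -> Spectrum:
        if len(s) < 100:
            return s  # too small for noise estimation; keep as-is, logged
        noise = pp.estimate_noise(s)
        return pp.filter_snr(s, noise, config.snr_threshold)

    blanks = [snr(b) for b in blanks]
    composite_blank = None
    if blanks:
        mz = np.concatenate([b.mz for b in blanks])
        inten = np.concatenate([b.intensity for b in blanks])
        composite_blank = Spectrum.from_arrays(mz, inten, sample_id="blank-pool",
                                               role="blank")
    cleaned = []
    for s in samples:
        s2 = snr(s)
        try:
            recal = pp.pick_recalibrants(s2, tol_ppm=config.recalibrant_tol_ppm)
            s2, model = pp.recalibrate(s2, recal)
            qc["recalibration"][f"{s.sample_id}-r{s.replicate}" if s.replicate
                                else s.sample_id] = {
                "residual_rms_ppm": model.residual_rms_ppm,
                "n_recalibrants": model.n_recalibrants,
                "coverage_warning": model.coverage_warning}
        except InsufficientRecalibrantsError:
            log.warning("no recalibrant series for %s; spectrum left uncalibrated",
                        s.sample_id)
        if composite_blank is not None and len(composite_blank):
            s2 = pp.subtract_blank(s2, composite_blank,
                                   config.blank_cum_fraction, config.tol_ppm)
        cleaned.append(s2)

    # replicate intersection for groundwater duplicates
    by_key: dict = {}
    for s in cleaned:
        by_key.setdefault((s.sample_id, s.role), []).append(s)
    processed = []
    n_gw_pairs = 0
    for (sid, role), group in sorted(by_key.items()):
        if role == "groundwater" and len(group) >= 2:
            group = sorted(group, key=lambda s: s.replicate or 0)
            merged = pp.intersect_replicates(group[0], group[1], config.tol_ppm)
            n_gw_pairs += 1
        else:
            merged = group[0]
        if len(merged) and merged.tic > 0:
            processed.append(pp.normalize_tic(merged))
        else:
            log.warning("sample %s empty after cleaning; dropped", sid)
    qc["n_groundwater_pairs"] = n_gw_pairs
    qc["n_processed"] = len(processed)
    return processed, qc


def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute the full chain and return the machine-readable run report."""
    config.validate()
    outdir = Path(config.outdir)
    report: dict = {"config": config.to_dict(), "stages": {}}
    truth = None

    # --- stage: inputs ---------------------------------------------------
    if config.manifest:
        manifest = read_manifest(config.manifest)
        spectra = load_spectra(manifest)
    else:
        if write_outputs:
            outdir.mkdir(parents=True, exist_ok=True)
            simulate_campaign(config.simulation, config.seed, outdir / "data")
        samples, manifest, truth = generate_campaign(config.simulation, config.seed)
        spectra = [sp for _, sp, _ in samples]
    report["stages"]["input"] = {"n_spectra": len(spectra)}

    # --- stage: preprocess ----------------------------------------------
    processed, qc = preprocess_spectra(spectra, config)
    report["stages"]["preprocess"] = {
        "n_input": qc["n_input"], "n_processed": qc["n_processed"],
        "n_groundwater_pairs": qc["n_groundwater_pairs"],
        "mean_recal_residual_rms_ppm": (
            float(np.mean([v["residual_rms_ppm"] for v in qc["recalibration"].values()]))
            if qc["recalibration"] else None)}

    gw = [s for s in processed if s.role == "groundwater"]
    seep = [s for s in processed if s.role == "seepage"]
    refs = [s for s in processed if s.role == "reference"]
    if not gw or not seep:
        raise InsufficientDataError("pipeline needs groundwater and seepage spectra")

    # --- stage: assignment (QC + pathway inputs) -------------------------
    sample_assignments = {}
    qc_fracs = []
    for s in gw:
        assignments, aqc = assign_spectrum(s, config.assign_tol_ppm, config.assign_policy)
        sample_assignments[s.sample_id] = assignments
        if aqc.assigned_intensity_fraction is not None:
            qc_fracs.append(aqc.assigned_intensity_fraction)
    report["stages"]["assignment"] = {
        "n_spectra": len(gw),
        "assigned_intensity_fraction_mean": float(np.mean(qc_fracs)) if qc_fracs else None,
        "assigned_intensity_fraction_sd": float(np.std(qc_fracs, ddof=1))
        if len(qc_fracs) > 1 else None}

    # --- stage: similarity ----------------------------------------------
    fm = align_features(gw + seep + refs, config.tol_ppm)
    ref_cols = [fm.column(s.sample_id) for s in seep]
    ps_records = []
    for s in gw:
        ps_records.append(percentage_similarity(fm.column(s.sample_id), ref_cols,
                                                sample_id=s.sample_id, date=s.date))
    drift = None
    if len(refs) >= 3:
        ref_order = sorted(refs, key=lambda s: (s.date, s.sample_id))
        ref_ps = [percentage_similarity(fm.column(s.sample_id), ref_cols).mean_ps
                  for s in ref_order]
        drift = reference_drift(ref_ps)
    report["stages"]["similarity"] = {
        "n_features": int(fm.mz.size), "n_groundwater": len(gw),
        "n_reference_seepage": len(seep),
        "seepage_reference_ps_sd": reference_set_spread(ref_cols),
        "drift": dataclasses.asdict(drift) if drift else None}
    wells = {s.sample_id: s.well_or_location for s in gw}
    ps_table = pd.DataFrame([{
        "sample_id": r.sample_id, "well": wells.get(r.sample_id, ""),
        "date": r.date.isoformat() if r.date else None,
        "mean_ps": r.mean_ps, "n_reference": r.n_reference} for r in ps_records])
    report["ps_table"] = ps_table.to_dict(orient="records")

    # --- stage: trend ----------------------------------------------------
    trend_out: dict = {}
    for well, grp in ps_table.groupby("well"):
        dates = pd.to_datetime(grp["date"]).dt.date.tolist()
        vals = grp["mean_ps"].to_numpy(float)
        entry: dict = {}
        try:
            slope, intercept, p = linear_trend(dates, vals)
            entry["linear"] = {"slope_per_year": slope, "intercept": intercept, "p": p}
        except DomtraceError as exc:
            entry["linear"] = {"error": str(exc)}
        try:
            s_pre, s_post, ratio = piecewise_slopes(dates, vals, config.break_date)
            entry["piecewise"] = {"slope_pre": s_pre, "slope_post": s_post,
                                  "ratio": ratio}
        except DomtraceError as exc:
            entry["piecewise"] = {"error": str(exc)}
        try:
            series = quarterly_series(dates, vals)
            comp = stl_decompose(series, config.stl)
            entry["stl"] = {
                "quarters": [str(p_) for p_ in comp.index],
                "trend": [float(v) for v in comp.trend],
                "seasonal": [float(v) for v in comp.seasonal],
                "trend_change": float(comp.trend.iloc[-1] - comp.trend.iloc[0])}
        except DomtraceError as exc:
            entry["stl"] = {"error": str(exc)}
        trend_out[str(well)] = entry
    report["trend"] = trend_out

    # --- stage: pathway screen -------------------------------------------
    if config.run_pathways:
        if config.compound_table:
            compounds = read_compound_table(config.compound_table)
            meta = None
            profiles = read_mag_profiles(config.mag_profiles) if config.mag_profiles else None
            enriched_truth = None
        else:
            if truth is None:
                raise ValidationError(
                    "pathway screen without a compound table requires simulation")
            from .chem import MolecularFormula
            partition = {k: [MolecularFormula.from_string(s) for s in v]
                         for k, v in truth.library.items()}
            compounds, meta, profiles, enriched = simulate_pathway_db(
                config.n_pathways, config.pathway_size_range, config.n_enriched,
                partition, config.seed, wells=config.simulation.wells)
            enriched_truth = sorted(enriched)
            truth.enriched_pathways = enriched_truth
        index, records = build_formula_index(compounds, meta)
        abund, detected = detect_pathway_abundance(
            sample_assignments, index, sample_wells=wells, mag_profiles=profiles)
        ps_map = {r.sample_id: r.mean_ps for r in ps_records}
        try:
            screen = screen_correlations(
                abund, ps_map, records, detected, alpha=config.screen_alpha,
                min_formulas=config.min_formulas, min_fraction=config.min_fraction)
        except InsufficientDataError as exc:
            screen = []
            report["stages"]["pathways"] = {"error": str(exc)}
        all_assigned = [a.formula for asn in sample_assignments.values()
                        for a in asn if a.formula is not None]
        amb = ambiguity_metrics(all_assigned, index)
        report["screen"] = [dataclasses.asdict(r) for r in screen]
        report["stages"].setdefault("pathways", {}).update({
            "n_pathways_tested": len(screen),
            "n_significant": sum(r.significant for r in screen),
            "unambiguous_fraction": amb.unambiguous_fraction,
            "matched_fraction": amb.matched_fraction,
            "enriched_truth": enriched_truth})

    # --- outputs ---------------------------------------------------------
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
        (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        ps_table.to_csv(outdir / "ps_table.csv", index=False)
        if report.get("screen"):
            pd.DataFrame(report["screen"]).to_csv(outdir / "screen.csv", index=False)
    return report
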