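"""Metagenome-constrained pathway screen.

Assigned molecular formulas are mapped to metabolic pathways through a
compound table (compound -> formula -> pathway ids).  Detected pathways are
constrained per well to those present in that well's metagenome-assembled
genomes (MAG pathway-presence profiles), filtered by detection depth
(>=10 distinct formulas OR >=25% of the pathway's theoretical length), and
their per-sample summed relative abundances rank-correlated against the PS
indicator with Bonferroni control (significant: rho > 0 and corrected
p < 0.01).

A formula shared by several pathways contributes its full abundance to each
of them ("multi-counting"); a split-abundance alternative divides it evenly.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assign import Assignment
from .chem import MolecularFormula, passes_dom_filters
from .errors import InsufficientDataError, ParseError

XENOBIOTICS_GROUP = "Xenobiotics biodegradation and metabolism"


@dataclasses.dataclass
class PathwayRecord:
    pathway_id: str
    name: str
    group: str
    member_formulas: frozenset  # distinct MolecularFormula compositions

    @property
    def theoretical_length(self) -> int:
        return len(self.member_formulas)


def read_compound_table(path) -> pd.DataFrame:
    """Load a compound table CSV (compound_id, formula, pathway_ids)."""
    df = pd.read_csv(path, dtype=str)
    need = {"compound_id", "formula", "pathway_ids"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: compound table needs columns {sorted(need)}")
    return df


def read_mag_profiles(path) -> dict[str, set]:
    """Load MAG pathway-presence profiles CSV (well_id, pathway_id)."""
    df = pd.read_csv(path, dtype=str)
    need = {"well_id", "pathway_id"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: MAG profile needs columns {sorted(need)}")
    out: dict[str, set] = {}
    for _, row in df.iterrows():
        out.setdefault(row["well_id"], set()).add(row["pathway_id"])
    return out


def build_formula_index(
    compounds: pd.DataFrame,
    pathway_meta: Optional[pd.DataFrame] = None,
) -> tuple[dict[MolecularFormula, frozenset], list[PathwayRecord]]:
    """Index formulas to the union of their pathway memberships.

    A formula appearing in several compounds unions their pathway sets;
    pathway member formulas are deduplicated by composition.  Rows with an
    empty pathway set or an invalid formula are rejected with their row
    number.  ``pathway_meta`` optionally supplies (pathway_id, name, group).
    """
    fmap: dict[MolecularFormula, set] = {}
    members: dict[str, set] = {}
    for rownum, row in enumerate(compounds.itertuples(index=False), start=1):
        raw = getattr(row, "pathway_ids", "") or ""
        pids = {p.strip() for p in str(raw).split(";") if p.strip()}
        if not pids:
            raise ParseError(f"compound table row {rownum}: empty pathway set")
        try:
            f = MolecularFormula.from_string(str(row.formula))
        except ParseError as exc:
            raise ParseError(f"compound table row {rownum}: {exc}") from exc
        if not passes_dom_filters(f):
            raise ParseError(
                f"compound table row {rownum}: implausible formula {row.formula}")
        fmap.setdefault(f, set()).update(pids)
        for p in pids:
            members.setdefault(p, set()).add(f)
    meta = {}
    if pathway_meta is not None:
        for row in pathway_meta.itertuples(index=False):
            meta[str(row.pathway_id)] = (str(getattr(row, "name", row.pathway_id)),
                                         str(getattr(row, "group", "")))
    records = [PathwayRecord(pathway_id=p,
                             name=meta.get(p, (p, ""))[0],
                             group=meta.get(p, (p, ""))[1],
                             member_formulas=frozenset(f))
               for p, f in sorted(members.items())]
    index = {f: frozenset(p) for f, p in fmap.items()}
    return index, records


def constrain_by_mags(
    detected: dict[str, set],
    profiles: dict[str, set],
) -> dict[str, set]:
    """Per well, retain only the detected pathways present in that well's
    MAG profile.  Wells without a profile are dropped with a warning."""
    import warnings

    out: dict[str, set] = {}
    for well, pathways in detected.items():
        if well not in profiles:
            warnings.warn(f"no MAG profile for well {well!r}; dropping it")
            continue
        out[well] = set(pathways) & profiles[well]
    return out


def detect_pathway_abundance(
    sample_assignments: dict[str, Sequence[Assignment]],
    index: dict[MolecularFormula, frozenset],
    sample_wells: Optional[dict[str, str]] = None,
    mag_profiles: Optional[dict[str, set]] = None,
    split_abundance: bool = False,
) -> tuple[pd.DataFrame, dict[str, set]]:
    """Per-sample summed relative abundance and detected formulas per pathway.

    ``sample_assignments`` maps sample_id -> assignments from a normalized
    spectrum.  When ``mag_profiles`` (and ``sample_wells``) are given, a
    pathway is counted for a sample only if present in the sample well's
    profile.  Returns (samples x pathways abundance table, pathway ->
    detected distinct formulas).
    """
    rows = {}
    detected: dict[str, set] = {}
    for sid, assignments in sample_assignments.items():
        well = (sample_wells or {}).get(sid)
        allowed = None
        if mag_profiles is not None:
            allowed = mag_profiles.get(well, set()) if well is not None else set()
        sums: dict[str, float] = {}
        for a in assignments:
            if a.formula is None or a.formula not in index:
                continue
            pids = index[a.formula]
            if allowed is not None:
                pids = pids & allowed
            if not pids:
                continue
            share = a.intensity / len(pids) if split_abundance else a.intensity
            for p in pids:
                sums[p] = sums.get(p, 0.0) + share
                detected.setdefault(p, set()).add(a.formula)
        rows[sid] = sums
    table = (pd.DataFrame.from_dict(rows, orient="index")
             .reindex(list(rows.keys())).fillna(0.0).sort_index(axis=1))
    return table, detected


def filter_pathways(
    detected_counts: dict[str, int],
    theoretical_lengths: dict[str, int],
    min_formulas: int = 10,
    min_fraction: float = 0.25,
) -> set:
    """Detection-depth filter: keep a pathway iff >= min_formulas distinct
    formulas detected OR >= min_fraction of its theoretical length (both
    bounds inclusive)."""
    keep = set()
    for p, n_det in detected_counts.items():
        length = theoretical_lengths.get(p, 0)
        frac = n_det / length if length else 0.0
        if n_det >= min_formulas or frac >= min_fraction:
            keep.add(p)
    return keep


@dataclasses.dataclass(frozen=True)
class ScreenResult:
    pathway_id: str
    n_detected_formulas: int
    fraction_length: float
    rho: float
    p_raw: float
    p_bonferroni: float
    significant: bool


@dataclasses.dataclass(frozen=True)
class AmbiguityMetrics:
    """(i) fraction of detected formulas mapping to exactly one pathway;
    (ii) fraction of all assigned spectrum formulas matching any pathway."""

    unambiguous_fraction: float
    matched_fraction: float


def ambiguity_metrics(
    assigned_formulas: Sequence[MolecularFormula],
    index: dict[MolecularFormula, frozenset],
) -> AmbiguityMetrics:
    distinct = set(assigned_formulas)
    matched = [f for f in distinct if f in index]
    if not distinct:
        return AmbiguityMetrics(float("nan"), float("nan"))
    unamb = sum(1 for f in matched if len(index[f]) == 1)
    return AmbiguityMetrics(
        unambiguous_fraction=unamb / len(matched) if matched else float("nan"),
        matched_fraction=len(matched) / len(distinct))


def screen_correlations(
    abundances: pd.DataFrame,
    ps: dict[str, float],
    records: Sequence[PathwayRecord],
    detected: dict[str, set],
    alpha: float = 0.01,
    min_formulas: int = 10,
    min_fraction: float = 0.25,
    method: str = "spearman",
) -> list[ScreenResult]:
    """Bonferroni-corrected rank-correlation screen of pathway abundance
    against PS.

    Correlations run over samples present in both the abundance table and
    the PS mapping (>=8 required).  The Bonferroni factor m is the number
    of pathways surviving the detection filter.
    """
    samples = [s for s in abundances.index if s in ps]
    if len(samples) < 8:
        raise InsufficientDataError(
            f"screen needs >=8 samples with PS values, got {len(samples)}")
    lengths = {r.pathway_id: r.theoretical_length for r in records}
    counts = {p: len(fs) for p, fs in detected.items()}
    retained = sorted(filter_pathways(counts, lengths, min_formulas, min_fraction)
                      & set(abundances.columns))
    if not retained:
        raise InsufficientDataError("no pathway survives the detection filter")
    m = len(retained)
    ps_vec = np.array([ps[s] for s in samples], dtype=float)
    results = []
    for p in retained:
        ab = abundances.loc[samples, p].to_numpy(float)
        if np.ptp(ab) == 0 or np.ptp(ps_vec) == 0:
            rho, p_raw = 0.0, 1.0
        elif method == "spearman":
            rho, p_raw = stats.spearmanr(ab, ps_vec)
        elif method == "kendall":
            rho, p_raw = stats.kendalltau(ab, ps_vec)
        else:
            raise ValueError(f"unknown method {method!r}")
        p_bonf = min(1.0, float(p_raw) * m)
        results.append(ScreenResult(
            pathway_id=p, n_detected_formulas=counts.get(p, 0),
            fraction_length=counts.get(p, 0) / lengths[p] if lengths.get(p) else 0.0,
            rho=float(rho), p_raw=float(p_raw), p_bonferroni=p_bonf,
            significant=bool(rho > 0 and p_bonf < alpha)))
    return results
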