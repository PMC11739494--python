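"""Synthetic campaign generator: constraints, determinism, ground truth."""
import datetime as dt
import json

import numpy as np
import pandas as pd
import pytest

from domtrace.chem import MolecularFormula
from domtrace.errors import ValidationError
from domtrace.simulate import (MixingTrajectory, SimulationConfig,
                               SyntheticTruth, TrajectoryComponents,
                               generate_campaign, make_formula_library,
                               partition_library, simulate_campaign,
                               simulate_isotopes, simulate_pathway_db)
from conftest import noiseless_config


class TestLibrary:
    def test_constraints_hold_by_construction(self):
        lib = make_formula_library(1, 1000)
        assert len(lib) == 1000
        assert len(set(lib)) == 1000
        for f in lib:
            assert 4 <= f.c <= 40 and 0 <= f.n <= 4 and 0 <= f.s <= 1
            assert 0 <= f.o <= 30
            assert (f.h + f.n) % 2 == 0
            assert f.dbe >= 0 and f.dbe == int(f.dbe)
            assert 100.0 <= f.neutral_mass <= 900.0

    def test_same_seed_identical_library(self):
        assert make_formula_library(5, 300) == make_formula_library(5, 300)
        assert make_formula_library(5, 300) != make_formula_library(6, 300)

    def test_masses_recomputable_from_atomic_masses(self):
        from domtrace.chem import MASS_C, MASS_H, MASS_N, MASS_O, MASS_S

        for f in make_formula_library(2, 200):
            manual = (f.c * MASS_C + f.h * MASS_H + f.n * MASS_N
                      + f.o * MASS_O + f.s * MASS_S)
            assert abs(manual - f.neutral_mass) < 1e-9

    def test_minimum_size_enforced(self):
        with pytest.raises(ValidationError):
            make_formula_library(1, 5)


class TestTrajectory:
    def test_alpha_clipped_and_reconstructable(self):
        comp = TrajectoryComponents(baseline=0.9, slope_per_year=0.1,
                                    step=0.3, seasonal_amplitude=0.2)
        times = [dt.date(2014, 1, 1) + dt.timedelta(days=91 * k) for k in range(40)]
        traj = MixingTrajectory.build("w", times, comp, phase=0.25)
        assert np.all((traj.alpha >= 0) & (traj.alpha <= 1))
        rebuilt = MixingTrajectory.evaluate(comp, times, 0.25)
        np.testing.assert_array_equal(traj.alpha, rebuilt)

    def test_step_and_slope_change_applied_after_break(self):
        comp = TrajectoryComponents(baseline=0.2, slope_per_year=0.0, step=0.1,
                                    seasonal_amplitude=0.0,
                                    break_date=dt.date(2015, 1, 1),
                                    slope_post=0.05)
        times = [dt.date(2014, 1, 1) + dt.timedelta(days=182 * k) for k in range(8)]
        alpha = MixingTrajectory.evaluate(comp, times, 0.0)
        assert np.all(alpha[:2] == pytest.approx(0.2))
        assert alpha[3] > 0.3 - 1e-9   # step applied
        assert alpha[-1] > alpha[3]    # post-break slope


class TestCampaign:
    def test_bit_identical_regeneration(self, small_config):
        s1, m1, t1 = generate_campaign(small_config, 9)
        s2, m2, t2 = generate_campaign(small_config, 9)
        assert m1.equals(m2)
        for (n1, sp1, _), (n2, sp2, _) in zip(s1, s2):
            assert n1 == n2
            np.testing.assert_array_equal(sp1.mz, sp2.mz)
            np.testing.assert_array_equal(sp1.intensity, sp2.intensity)
        for w in t1.trajectories:
            np.testing.assert_array_equal(t1.trajectories[w].alpha,
                                          t2.trajectories[w].alpha)

    def test_noiseless_replicates_identical(self):
        cfg = noiseless_config()
        samples, _, _ = generate_campaign(cfg, 1)
        by_id = {}
        for stem, sp, _ in samples:
            if sp.role == "groundwater":
                by_id.setdefault(sp.sample_id, []).append(sp)
        assert by_id
        for reps in by_id.values():
            a, b = reps
            np.testing.assert_array_equal(a.mz, b.mz)
            np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_mixture_is_convex_combination_of_endmembers(self):
        cfg = noiseless_config(n_blanks=0)
        samples, _, truth = generate_campaign(cfg, 2)
        em = truth.endmembers
        alpha = truth.trajectories["well-1"].alpha
        stem, sp, _ = next(s for s in samples if s[1].role == "groundwater")
        a = alpha[0]
        by_formula = {}
        for subset in ("shared", "seepage_only", "groundwater_only"):
            for fstr, v in em[subset].items():
                f = MolecularFormula.from_string(fstr)
                seep_v = em["shared"].get(fstr, 0.0) + em["seepage_only"].get(fstr, 0.0)
                deep_v = em["shared"].get(fstr, 0.0) + em["groundwater_only"].get(fstr, 0.0)
                by_formula[round(f.mz_deprotonated(), 6)] = (
                    a * seep_v + (1 - a) * deep_v)
        cont_mz = {round(MolecularFormula.from_string(fs).mz_deprotonated(), 6)
                   for fs in em["contaminant"]}
        for mz, inten in zip(sp.mz, sp.intensity):
            key = round(mz, 6)
            if key in cont_mz:
                continue
            assert inten == pytest.approx(by_formula[key], rel=1e-12)

    def test_alpha_one_reproduces_seepage_endmember(self):
        cfg = noiseless_config(
            n_blanks=0,
            trajectory=TrajectoryComponents(baseline=1.0, slope_per_year=0.0,
                                            step=0.0, seasonal_amplitude=0.0))
        samples, _, truth = generate_campaign(cfg, 2)
        em = truth.endmembers
        seep_expected = {}
        for fstr in set(em["shared"]) | set(em["seepage_only"]):
            seep_expected[round(MolecularFormula.from_string(fstr).mz_deprotonated(), 6)] = (
                em["shared"].get(fstr, 0.0) + em["seepage_only"].get(fstr, 0.0))
        _, sp, _ = next(s for s in samples if s[1].role == "groundwater")
        cont_mz = {round(MolecularFormula.from_string(fs).mz_deprotonated(), 6)
                   for fs in em["contaminant"]}
        sample_signal = {round(m, 6): i for m, i in zip(sp.mz, sp.intensity)
                         if round(m, 6) not in cont_mz}
        assert sample_signal == pytest.approx(seep_expected, rel=1e-12)

    def test_campaign_files_roundtrip(self, tmp_path, small_config):
        manifest, truth = simulate_campaign(small_config, 4, tmp_path)
        from domtrace.io import load_spectra, read_manifest

        df = read_manifest(tmp_path / "manifest.csv")
        spectra = load_spectra(df.head(3))
        assert all(len(s) > 0 for s in spectra)
        back = SyntheticTruth.from_json(tmp_path / "truth.json")
        assert back.seed == truth.seed
        for w in truth.trajectories:
            np.testing.assert_array_equal(back.trajectories[w].alpha,
                                          truth.trajectories[w].alpha)
        assert back.endmembers == truth.endmembers

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(dropout=2.0).validate()
        with pytest.raises(ValidationError):
            SimulationConfig.from_dict({"no_such_knob": 1})


class TestIsotopes:
    def test_null_growth_tau_centred_near_zero(self):
        from domtrace.trend import intra_annual_variance

        taus = []
        for seed in range(30):
            obs, _ = simulate_isotopes(["w"], range(2014, 2022), 0.04, 0.0,
                                       seed, n_per_year=12)
            _, trends = intra_annual_variance(obs)
            taus.append(trends["w"][0])
        assert abs(np.mean(taus)) < 0.15

    def test_truth_records_growing_variance(self):
        _, truth = simulate_isotopes(["w"], range(2014, 2018), 0.04, 0.04, 1)
        v = [truth["w"][y] for y in range(2014, 2018)]
        assert v == sorted(v) and v[-1] > v[0]

    def test_validation(self):
        with pytest.raises(ValidationError):
            simulate_isotopes(["w"], range(2014, 2016), 0.0, 0.1, 1)
        with pytest.raises(ValidationError):
            simulate_isotopes(["w"], range(2014, 2016), 0.1, 0.1, 1, n_per_year=2)


@pytest.fixture(scope="module")
def db(small_campaign):
    _, _, truth = small_campaign
    partition = {k: [MolecularFormula.from_string(s) for s in v]
                 for k, v in truth.library.items()}
    return partition, simulate_pathway_db(
        30, (12, 30), 6, partition, 7, wells=("well-1",))


class TestPathwayDB:
    def test_sizes_within_range_and_truth_set(self, db):
        _, (compounds, meta, profiles, enriched) = db
        sizes = compounds.groupby("pathway_ids")["formula"].nunique()
        assert len(meta) == 30 and len(enriched) == 6
        assert ((sizes >= 12) & (sizes <= 30)).all()

    def test_enriched_pathways_seepage_dominated(self, db, small_campaign):
        partition, (compounds, _, _, enriched) = db
        _, _, truth = small_campaign
        em = truth.endmembers
        for pid in enriched:
            members = compounds[compounds.pathway_ids == pid]["formula"].unique()
            s_tot = sum(em["shared"].get(f, 0.0) + em["seepage_only"].get(f, 0.0)
                        for f in members)
            d_tot = sum(em["shared"].get(f, 0.0) + em["groundwater_only"].get(f, 0.0)
                        for f in members)
            assert s_tot > d_tot

    def test_enriched_present_in_all_wells(self, db):
        _, (_, _, profiles, enriched) = db
        for w, present in profiles.items():
            assert enriched <= present

    def test_zero_enriched_gives_empty_truth(self, db):
        partition, _ = db
        _, _, _, enriched = simulate_pathway_db(10, (12, 20), 0, partition, 1,
                                                wells=("well-1",))
        assert enriched == set()

    def test_xenobiotics_group_reserved(self, db):
        _, (_, meta, _, _) = db
        from domtrace.pathways import XENOBIOTICS_GROUP
        assert XENOBIOTICS_GROUP in set(meta["group"])
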