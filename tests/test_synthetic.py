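import numpy as np
import pandas as pd
import pytest

from mafld_traj import phenotyping, taxonomy
from mafld_traj.errors import ConfigError
from mafld_traj.synthetic import (
    SimulationConfig,
    config_from_yaml,
    config_to_yaml,
    piecewise_exponential_times,
    simulate_biomarkers,
    simulate_cohort,
)


def cfg(**overrides):
    base = dict(n_participants=500, seed=0,
                disease_catalog={"D10": 0.02, "D11": 0.02})
    base.update(overrides)
    return SimulationConfig(**base)


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError, match="hazard"):
            cfg(disease_catalog={"D10": -0.1}).validate()

    def test_psi_below_one_rejected(self):
        with pytest.raises(ConfigError, match="psi"):
            cfg(pair_amplification={("D10", "D11"): 0.5}).validate()

    def test_allele_freq_bounds(self):
        with pytest.raises(ConfigError, match="frequency"):
            cfg(allele_freqs={"snp_pnpla3": 1.5}).validate()

    def test_cyclic_amplification_rejected(self):
        with pytest.raises(ConfigError, match="cyclic"):
            cfg(pair_amplification={("D10", "D11"): 2.0,
                                    ("D11", "D10"): 2.0}).validate()

    def test_self_pair_rejected(self):
        with pytest.raises(ConfigError, match="self-pair"):
            cfg(pair_amplification={("D10", "D10"): 2.0}).validate()

    def test_yaml_round_trip(self, tmp_path):
        c = cfg(pair_amplification={("D10", "D11"): 3.0})
        path = tmp_path / "sim.yaml"
        config_to_yaml(c, path)
        back = config_from_yaml(path)
        assert back.pair_amplification == {("D10", "D11"): 3.0}
        assert back.disease_catalog == c.disease_catalog


class TestPiecewiseExponential:
    def test_plain_exponential_when_no_breakpoints(self):
        e = np.array([1.0, 2.0])
        t = piecewise_exponential_times(e, np.array([0.5, 0.5]), [])
        assert np.allclose(t, [2.0, 4.0])

    def test_zero_rate_never_fires(self):
        t = piecewise_exponential_times(np.array([1.0]), np.array([0.0]), [])
        assert np.isinf(t[0])

    def test_amplified_segment_hand_computed(self):
        # rate 0.1/day, breakpoint at t=10 with psi=5:
        # cumhaz(10)=1; draw E=2 -> t = 10 + (2-1)/0.5 = 12
        t = piecewise_exponential_times(
            np.array([2.0]), np.array([0.1]), [(np.array([10.0]), 5.0)]
        )
        assert t[0] == pytest.approx(12.0)

    def test_infinite_breakpoint_ignored(self):
        t = piecewise_exponential_times(
            np.array([2.0]), np.array([0.1]), [(np.array([np.inf]), 5.0)]
        )
        assert t[0] == pytest.approx(20.0)


class TestSimulateCohort:
    def test_zero_rates_empty_diagnoses(self):
        c = cfg(disease_catalog={"D10": 0.0, "D11": 0.0})
        _, diagnoses, _, _ = simulate_cohort(c)
        assert diagnoses.empty

    def test_zero_participants_empty_tables(self):
        p, d, de, truth = simulate_cohort(cfg(n_participants=0))
        assert p.empty and d.empty and de.empty
        assert truth.exposed_flags == {}

    def test_determinism_same_seed(self):
        a = simulate_cohort(cfg(seed=42, death_cause_hazards={
            "I64": {"rate": 0.005, "disease_multipliers": {}}}))
        b = simulate_cohort(cfg(seed=42, death_cause_hazards={
            "I64": {"rate": 0.005, "disease_multipliers": {}}}))
        for x, y in zip(a[:3], b[:3]):
            pd.testing.assert_frame_equal(x, y)

    def test_different_seed_differs(self):
        a = simulate_cohort(cfg(seed=1))[1]
        b = simulate_cohort(cfg(seed=2))[1]
        assert not a.equals(b)

    def test_exponential_cdf_oracle(self):
        # single category, rate lam, no exposure effect:
        # incidence ~= 1 - exp(-lam * T) within 3 Monte-Carlo SEs at n=10,000
        lam, T, n = 0.03, 13.0, 10_000
        c = cfg(n_participants=n, seed=7, disease_catalog={"D10": lam},
                follow_up_years=T)
        _, diagnoses, _, _ = simulate_cohort(c)
        p_hat = len(diagnoses) / n
        p_true = 1 - np.exp(-lam * T)
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(p_hat - p_true) < 3 * se

    def test_cumulative_hazard_recovery(self):
        lam, T, n = 0.05, 10.0, 20_000
        c = cfg(n_participants=n, seed=8, disease_catalog={"D10": lam},
                follow_up_years=T)
        _, diagnoses, _, _ = simulate_cohort(c)
        surv = 1 - len(diagnoses) / n
        assert -np.log(surv) == pytest.approx(lam * T, rel=0.05)

    def test_event_count_conservation(self):
        c = cfg(n_participants=2000, seed=3,
                disease_catalog={"D10": 0.1, "D11": 0.1})
        _, diagnoses, _, _ = simulate_cohort(c)
        assert not diagnoses.duplicated(["participant_id", "icd10_code"]).any()

    def test_no_diagnoses_after_death(self):
        c = cfg(n_participants=3000, seed=4,
                disease_catalog={"D10": 0.05, "D11": 0.05},
                death_cause_hazards={"I64": {"rate": 0.05,
                                             "disease_multipliers": {}}})
        _, diagnoses, deaths, _ = simulate_cohort(c)
        merged = diagnoses.merge(deaths, on="participant_id",
                                 suffixes=("_dx", "_death"))
        assert (pd.to_datetime(merged["date_dx"])
                <= pd.to_datetime(merged["date_death"])).all()

    def test_dates_within_window(self):
        c = cfg(n_participants=2000, seed=5, disease_catalog={"D10": 0.2})
        p, diagnoses, _, _ = simulate_cohort(c)
        dates = pd.to_datetime(diagnoses["date"])
        assert (dates >= pd.Timestamp(p["assessment_date"].iloc[0])).all()
        assert (dates <= pd.Timestamp(p["censor_date"].iloc[0])).all()

    def test_exposure_hr_shifts_incidence(self):
        c = cfg(n_participants=10_000, seed=6,
                disease_catalog={"D10": 0.01}, exposure_hr={"D10": 4.0})
        p, diagnoses, _, truth = simulate_cohort(c)
        exposed = p["participant_id"].map(truth.exposed_flags)
        has = p["participant_id"].isin(set(diagnoses["participant_id"]))
        rate_exp = has[exposed].mean()
        rate_unexp = has[~exposed].mean()
        assert rate_exp > 2.5 * rate_unexp


class TestBiomarkers:
    def test_knob_zero_no_steatosis(self):
        c = cfg(n_participants=3000,
                steatosis_model={**SimulationConfig(1).steatosis_model,
                                 "prevalence": 0.0})
        rng = np.random.default_rng(0)
        bio = simulate_biomarkers(c, rng)
        fli = phenotyping.compute_fli(bio["tg"], bio["bmi"], bio["ggt"],
                                      bio["waist"])
        assert (fli < 60).all()

    def test_degenerate_genotypes_max_prs(self):
        c = cfg(n_participants=200,
                allele_freqs={k: 1.0 for k in SimulationConfig(1).allele_freqs})
        bio = simulate_biomarkers(c, np.random.default_rng(0))
        prs = phenotyping.compute_prs(
            bio[list(phenotyping.SNP_COLUMNS)].to_numpy()
        )
        assert np.allclose(prs, 8.0)

    def test_knob_half_controls_fli_fraction(self):
        c = cfg(n_participants=20_000)
        bio = simulate_biomarkers(c, np.random.default_rng(1))
        fli = phenotyping.compute_fli(bio["tg"], bio["bmi"], bio["ggt"],
                                      bio["waist"])
        assert abs((fli >= 60).mean() - 0.5) < 0.03

    def test_negative_scale_rejected(self):
        params = dict(SimulationConfig(1).covariate_params)
        params["hdl"] = {"mean": 1.3, "sd": -1.0}
        with pytest.raises(ConfigError, match="scale"):
            simulate_biomarkers(cfg(covariate_params=params),
                                np.random.default_rng(0))

    def test_zero_variance_permitted(self):
        params = dict(SimulationConfig(1).covariate_params)
        params["hdl"] = {"mean": 1.3, "sd": 0.0}
        bio = simulate_biomarkers(cfg(covariate_params=params),
                                  np.random.default_rng(0))
        assert (bio["hdl"] == 1.3).all()

    def test_prs_effect_links_genotype_to_steatosis(self):
        sm = {**SimulationConfig(1).steatosis_model, "prs_effect": 0.6}
        c = cfg(n_participants=20_000, steatosis_model=sm)
        bio = simulate_biomarkers(c, np.random.default_rng(2))
        prs = phenotyping.compute_prs(bio[list(phenotyping.SNP_COLUMNS)].to_numpy())
        steat = bio["_steatosis_latent"].to_numpy()
        assert prs[steat].mean() > prs[~steat].mean() + 0.1


class TestEndToEndPairDetection:
    def test_planted_pair_detectable(self, small_cohort):
        from mafld_traj import pairs as pairs_mod

        truth = small_cohort["truth"]
        exposed = [pid for pid, flag in truth.exposed_flags.items() if flag]
        out = pairs_mod.run_pair_inference(
            small_cohort["events"], exposed,
            list(small_cohort["config"].disease_catalog),
            n_exposed=len(exposed),
        )
        row = out.set_index(["d1", "d2"]).loc[("D10", "D11")]
        assert bool(row["confirmed"])
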