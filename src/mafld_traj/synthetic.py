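"""Seeded synthetic cohort generator.

Emits the four tables the pipeline consumes — participants, diagnoses,
deaths, and a ground-truth record — with the statistical structure the
analysis assumes: a latent steatosis process driving the FLI inputs, planted
per-category exposure hazard ratios, directed D1->D2 hazard amplification,
and cause-specific death hazards with disease-conditional multipliers.

Time is continuous in days internally; dates are emitted as ISO-8601
calendar days relative to a fixed synthetic study start. One master seed
spawns deterministic per-stream child generators.
"""
from __future__ import annotations

import graphlib
import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .phenotyping import (
    FLI_COEF,
    TG_MGDL_PER_MMOL,
    fli_linear_predictor_inverse,
    phenotype_table,
)

DAYS_PER_YEAR = 365.25
STUDY_START = date(2010, 1, 1)

DEFAULT_COVARIATE_PARAMS: dict = {
    "male_fraction": 0.5,
    "age": {"mean": 57.0, "sd": 8.0, "min": 39.0, "max": 69.0},
    "townsend": {"mean": -1.5, "sd": 2.8},
    "alcohol": {"mean_log": 2.2, "sd_log": 0.9},
    "bmi_nonsteatotic": {"mean": 25.0, "sd": 3.0, "min": 18.0, "max": 45.0},
    "bmi_steatotic": {"mean": 31.0, "sd": 3.0, "min": 25.0, "max": 48.0},
    "hdl": {"mean": 1.35, "sd": 0.30, "min": 0.4},
    "ast": {"mean": 26.0, "sd": 8.0, "min": 8.0},
    "alt": {"mean": 28.0, "sd": 10.0, "min": 8.0},
    "platelets": {"mean": 250.0, "sd": 55.0, "min": 80.0},
    "albumin": {"mean": 4.4, "sd": 0.25, "min": 3.0},
    "glucose": {"mean": 93.0, "sd": 10.0, "min": 60.0},
    "hba1c": {"mean": 5.4, "sd": 0.4, "min": 4.0},
    "sbp": {"mean": 135.0, "sd": 17.0, "min": 80.0},
    "dbp": {"mean": 82.0, "sd": 10.0, "min": 40.0},
    "bp_med_fraction": 0.2,
    "t2d_base_fraction": 0.04,
    "t2d_steatotic_fraction": 0.15,
}

DEFAULT_STEATOSIS_MODEL: dict = {
    "prevalence": 0.5,          # single knob controlling the FLI >= 60 fraction
    "prs_effect": 0.0,          # logit shift per centred PRS unit
    "fli_nonsteatotic": (5.0, 55.0),
    "fli_steatotic": (65.0, 98.0),
    "tg_share": (0.35, 0.65),   # share of the FLI predictor carried by ln TG
    "waist_slope": 2.4,
    "waist_sex_shift": 10.0,
    "waist_sd": 4.0,
}

DEFAULT_ALLELE_FREQS = {
    "snp_mboat7": 0.43,
    "snp_gckr": 0.39,
    "snp_tm6sf2": 0.07,
    "snp_pnpla3": 0.22,
}
DEFAULT_SNP_BETAS = {k: 1.0 for k in DEFAULT_ALLELE_FREQS}


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    exposed_flags: dict
    planted_hr: dict
    planted_pairs: dict

    def to_json(self, path) -> None:
        payload = {
            "exposed_flags": {str(k): bool(v) for k, v in self.exposed_flags.items()},
            "planted_hr": {k: float(v) for k, v in self.planted_hr.items()},
            "planted_pairs": [
                [d1, d2, float(psi)] for (d1, d2), psi in sorted(self.planted_pairs.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulationConfig:
    n_participants: int
    seed: int = 0
    follow_up_years: float = 13.0
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    steatosis_model: dict = field(default_factory=lambda: dict(DEFAULT_STEATOSIS_MODEL))
    allele_freqs: dict = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    snp_betas: dict = field(default_factory=lambda: dict(DEFAULT_SNP_BETAS))
    #: category code -> baseline annual hazard
    disease_catalog: dict = field(default_factory=dict)
    #: category code -> multiplicative hazard for exposed participants
    exposure_hr: dict = field(default_factory=dict)
    #: (d1, d2) -> psi >= 1, applied to d2's hazard from the day after d1
    pair_amplification: dict = field(default_factory=dict)
    #: cause ICD-10 code -> {"rate": annual, "disease_multipliers": {category: m}}
    death_cause_hazards: dict = field(default_factory=dict)
    secondary_cause_window_days: float = 30.0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if self.follow_up_years <= 0:
            raise ConfigError("follow_up_years must be positive")
        for code, rate in self.disease_catalog.items():
            if rate < 0:
                raise ConfigError(f"negative baseline hazard for {code}")
        for code, hr in self.exposure_hr.items():
            if code not in self.disease_catalog:
                raise ConfigError(f"exposure_hr for unknown category {code}")
            if hr <= 0:
                raise ConfigError(f"non-positive exposure HR for {code}")
        for (d1, d2), psi in self.pair_amplification.items():
            if d1 == d2:
                raise ConfigError(f"self-pair amplification {d1}->{d2}")
            if d1 not in self.disease_catalog or d2 not in self.disease_catalog:
                raise ConfigError(f"amplified pair {d1}->{d2} outside the catalog")
            if psi < 1:
                raise ConfigError(f"pair amplification psi must be >= 1 ({d1}->{d2})")
        for snp, freq in self.allele_freqs.items():
            if not 0.0 <= freq <= 1.0:
                raise ConfigError(f"allele frequency for {snp} outside [0, 1]")
        for cause, spec in self.death_cause_hazards.items():
            if spec.get("rate", 0.0) < 0:
                raise ConfigError(f"negative death hazard for {cause}")
            for cat, m in spec.get("disease_multipliers", {}).items():
                if m <= 0:
                    raise ConfigError(
                        f"non-positive death multiplier for {cause} after {cat}"
                    )
        prev = self.steatosis_model["prevalence"]
        if not 0.0 <= prev <= 1.0:
            raise ConfigError("steatosis prevalence knob outside [0, 1]")
        for key, params in self.covariate_params.items():
            if isinstance(params, dict) and params.get("sd", 0.0) < 0:
                raise ConfigError(f"negative scale parameter for {key}")
        # amplification must be acyclic so categories can be simulated in order
        self._topological_categories()

    def _topological_categories(self) -> list[str]:
        sorter = graphlib.TopologicalSorter(
            {c: set() for c in self.disease_catalog}
        )
        for (d1, d2) in self.pair_amplification:
            sorter.add(d2, d1)
        try:
            return list(sorter.static_order())
        except graphlib.CycleError as exc:
            raise ConfigError(f"pair_amplification graph is cyclic: {exc}") from exc


def config_from_yaml(path) -> SimulationConfig:
    """Load a SimulationConfig; pair amplification given as [d1, d2, psi] rows."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    pairs = {
        (d1, d2): float(psi) for d1, d2, psi in raw.pop("pair_amplification", [])
    }
    cfg = SimulationConfig(**raw)
    cfg.pair_amplification = pairs
    cfg.validate()
    return cfg


def config_to_yaml(config: SimulationConfig, path) -> None:
    raw = asdict(config)
    raw["pair_amplification"] = [
        [d1, d2, psi] for (d1, d2), psi in sorted(config.pair_amplification.items())
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# biomarkers

def _truncnorm(rng, n, params) -> np.ndarray:
    x = rng.normal(params["mean"], params["sd"], size=n)
    return np.clip(x, params.get("min", -np.inf), params.get("max", np.inf))


def simulate_biomarkers(config: SimulationConfig, rng: np.random.Generator
                        ) -> pd.DataFrame:
    """Draw the participant baseline table.

    Biomarkers are tied together through a latent steatosis indicator: a
    target FLI is drawn on either side of the 60-point cutoff and the TG/GGT
    pair is solved to reproduce it exactly given BMI and waist, so the
    FLI >= 60 fraction equals the prevalence knob up to binomial noise (and
    is exactly zero when the knob is zero).
    """
    config.validate()
    n = config.n_participants
    cp = config.covariate_params
    sm = config.steatosis_model

    male = rng.random(n) < cp["male_fraction"]
    age = _truncnorm(rng, n, cp["age"])
    townsend = rng.normal(cp["townsend"]["mean"], cp["townsend"]["sd"], size=n)
    alcohol = rng.lognormal(cp["alcohol"]["mean_log"], cp["alcohol"]["sd_log"], size=n)

    snps = sorted(config.allele_freqs)
    dosages = {
        s: rng.binomial(2, config.allele_freqs[s], size=n).astype(float) for s in snps
    }
    betas = np.array([config.snp_betas.get(s, 1.0) for s in snps])
    dosage_mat = np.column_stack([dosages[s] for s in snps]) if snps else np.zeros((n, 0))
    if snps:
        prs = (dosage_mat @ betas) * (len(snps) / betas.sum())
        expected_prs = (
            np.array([2 * config.allele_freqs[s] for s in snps]) @ betas
        ) * (len(snps) / betas.sum())
    else:
        prs = np.zeros(n)
        expected_prs = 0.0

    knob = float(sm["prevalence"])
    if knob <= 0.0:
        p_steat = np.zeros(n)
    elif knob >= 1.0:
        p_steat = np.ones(n)
    else:
        logit_knob = np.log(knob / (1 - knob))
        shift = float(sm.get("prs_effect", 0.0)) * (prs - expected_prs)
        p_steat = 1.0 / (1.0 + np.exp(-(logit_knob + shift)))
    steatosis = rng.random(n) < p_steat

    bmi = np.where(
        steatosis,
        _truncnorm(rng, n, cp["bmi_steatotic"]),
        _truncnorm(rng, n, cp["bmi_nonsteatotic"]),
    )
    waist = np.clip(
        bmi * sm["waist_slope"] + male * sm["waist_sex_shift"]
        + rng.normal(0.0, sm["waist_sd"], size=n),
        50.0,
        None,
    )

    lo0, hi0 = sm["fli_nonsteatotic"]
    lo1, hi1 = sm["fli_steatotic"]
    target_fli = np.where(
        steatosis, rng.uniform(lo1, hi1, size=n), rng.uniform(lo0, hi0, size=n)
    )
    # split the required predictor mass between ln TG and ln GGT
    need = (
        fli_linear_predictor_inverse(target_fli)
        - FLI_COEF["intercept"]
        - FLI_COEF["bmi"] * bmi
        - FLI_COEF["waist"] * waist
    )
    share = rng.uniform(*sm["tg_share"], size=n)
    tg_mgdl = np.exp(share * need / FLI_COEF["ln_tg"])
    ggt = np.exp((1.0 - share) * need / FLI_COEF["ln_ggt"])
    tg = tg_mgdl / TG_MGDL_PER_MMOL

    t2d_frac = np.where(
        steatosis, cp["t2d_steatotic_fraction"], cp["t2d_base_fraction"]
    )
    participants = pd.DataFrame(
        {
            "participant_id": [f"P{i:07d}" for i in range(n)],
            "age": np.round(age, 1),
            "sex": np.where(male, "male", "female"),
            "townsend": np.round(townsend, 3),
            "bmi": np.round(bmi, 2),
            "waist": np.round(waist, 1),
            "tg": tg,
            "hdl": _truncnorm(rng, n, cp["hdl"]),
            "ggt": ggt,
            "ast": _truncnorm(rng, n, cp["ast"]),
            "alt": _truncnorm(rng, n, cp["alt"]),
            "platelets": _truncnorm(rng, n, cp["platelets"]),
            "albumin": _truncnorm(rng, n, cp["albumin"]),
            "glucose": _truncnorm(rng, n, cp["glucose"]) + 8.0 * steatosis,
            "hba1c": _truncnorm(rng, n, cp["hba1c"]) + 0.25 * steatosis,
            "sbp": _truncnorm(rng, n, cp["sbp"]),
            "dbp": _truncnorm(rng, n, cp["dbp"]),
            "bp_med": (rng.random(n) < cp["bp_med_fraction"]).astype(int),
            "t2d": (rng.random(n) < t2d_frac).astype(int),
            "alcohol": np.round(alcohol, 2),
        }
    )
    for s in snps:
        participants[s] = dosages[s].astype(int)
    participants["_steatosis_latent"] = steatosis
    return participants


# ---------------------------------------------------------------------------
# event-time machinery

def piecewise_exponential_times(
    rng_draws: np.ndarray,
    base_daily: np.ndarray,
    breakpoints: list[tuple[np.ndarray, float]],
) -> np.ndarray:
    """Invert unit-exponential draws through a piecewise-constant hazard.

    ``breakpoints`` is a list of ``(start_times, multiplier)``: from each
    participant's start time onward the hazard is multiplied by that factor
    (``inf`` start = never). Returns event times in days (``inf`` = never).
    """
    n = base_daily.shape[0]
    e = rng_draws
    if not breakpoints:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(base_daily > 0, e / np.where(base_daily > 0, base_daily, 1.0),
                         np.inf)
        return t
    starts = np.column_stack([s for s, _ in breakpoints])          # (n, p)
    mults = np.array([m for _, m in breakpoints], dtype=float)      # (p,)
    order = np.argsort(starts, axis=1)
    s_sorted = np.take_along_axis(starts, order, axis=1)
    m_sorted = np.take_along_axis(np.broadcast_to(mults, starts.shape), order, axis=1)
    cum_mult = np.cumprod(m_sorted, axis=1)                         # rate after k-th
    p = starts.shape[1]
    # segment rates: base before s_1, base*cum_mult_k after s_k
    rates = np.concatenate([base_daily[:, None], base_daily[:, None] * cum_mult],
                           axis=1)                                  # (n, p+1)
    bounds = np.concatenate([np.zeros((n, 1)), s_sorted], axis=1)   # (n, p+1)
    seg_len = np.diff(np.concatenate([bounds, np.full((n, 1), np.inf)], axis=1), axis=1)
    with np.errstate(invalid="ignore"):
        seg_haz = rates * seg_len
    seg_haz = np.nan_to_num(seg_haz, nan=0.0, posinf=np.inf)        # 0 * inf -> 0
    cum_haz = np.concatenate([np.zeros((n, 1)), np.cumsum(seg_haz, axis=1)], axis=1)
    # locate the segment holding each draw
    k = np.sum(cum_haz[:, 1:-1] <= e[:, None], axis=1)              # in [0, p]
    rows = np.arange(n)
    rate_k = rates[rows, k]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = bounds[rows, k] + (e - cum_haz[rows, k]) / rate_k
    t[rate_k <= 0] = np.inf
    return t


def _cause_specific_times(
    rng: np.random.Generator,
    n: int,
    annual_rate: float,
    multipliers: dict,
    diag_times: dict,
) -> np.ndarray:
    base = np.full(n, annual_rate / DAYS_PER_YEAR)
    breaks = [
        (diag_times[cat] + 1.0, float(m))
        for cat, m in sorted(multipliers.items())
        if cat in diag_times
    ]
    return piecewise_exponential_times(rng.exponential(size=n), base, breaks)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate participants, diagnoses, deaths and the planted ground truth.

    Diagnosis waiting times are piecewise exponential: the hazard for
    category D is ``baseline(D) * exposure_hr(D)^exposed * prod(psi(D1, D))``
    over already-diagnosed D1 (effective from the day after D1). Death
    competes with further diagnoses; no event is dated after death.
    """
    config.validate()
    n = config.n_participants
    ss = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("covariates", "diagnoses", "deaths"), ss.spawn(3)
        )
    }

    participants = simulate_biomarkers(config, streams["covariates"])
    follow_days = config.follow_up_years * DAYS_PER_YEAR
    assessment = pd.Timestamp(STUDY_START)
    censor = assessment + pd.Timedelta(days=int(np.floor(follow_days)))
    participants["assessment_date"] = assessment.date().isoformat()
    participants["censor_date"] = censor.date().isoformat()

    # exposure truth: MAFLD computed from the generated panel
    if n:
        pheno = phenotype_table(participants, snp_betas=None)
        exposed = pheno["mafld"].fillna(False).to_numpy(dtype=bool)
    else:
        exposed = np.zeros(0, dtype=bool)
    participants = participants.drop(columns=["_steatosis_latent"])

    rng_d = streams["diagnoses"]
    diag_times: dict[str, np.ndarray] = {}
    for cat in config._topological_categories():
        annual = config.disease_catalog[cat]
        hr = config.exposure_hr.get(cat, 1.0)
        base = np.where(exposed, annual * hr, annual) / DAYS_PER_YEAR
        breaks = [
            (diag_times[d1] + 1.0, float(psi))
            for (d1, d2), psi in sorted(config.pair_amplification.items())
            if d2 == cat
        ]
        diag_times[cat] = piecewise_exponential_times(
            rng_d.exponential(size=n), base, breaks
        )

    rng_death = streams["deaths"]
    causes = sorted(config.death_cause_hazards)
    if causes and n:
        cause_times = np.column_stack(
            [
                _cause_specific_times(
                    rng_death,
                    n,
                    config.death_cause_hazards[c].get("rate", 0.0),
                    config.death_cause_hazards[c].get("disease_multipliers", {}),
                    diag_times,
                )
                for c in causes
            ]
        )
        death_time = cause_times.min(axis=1)
        primary_idx = cause_times.argmin(axis=1)
    else:
        cause_times = np.full((n, max(len(causes), 1)), np.inf)
        death_time = np.full(n, np.inf)
        primary_idx = np.zeros(n, dtype=int)

    horizon = np.minimum(follow_days, death_time)
    max_day = int(np.floor(follow_days))

    diag_rows = []
    pids = participants["participant_id"].to_numpy() if n else np.array([])
    for cat in sorted(diag_times):
        t = diag_times[cat]
        hit = t <= horizon
        days = np.minimum(np.floor(t[hit]).astype(int) + 1, max_day)
        for pid, d in zip(pids[hit], days):
            diag_rows.append((pid, cat, (assessment + pd.Timedelta(days=int(d))).date().isoformat()))
    diagnoses = pd.DataFrame(diag_rows, columns=["participant_id", "icd10_code", "date"])
    diagnoses = diagnoses.sort_values(["participant_id", "icd10_code"]).reset_index(drop=True)

    death_rows = []
    died = death_time <= follow_days
    window = config.secondary_cause_window_days
    for i in np.flatnonzero(died):
        day = min(int(np.floor(death_time[i])) + 1, max_day)
        primary = causes[primary_idx[i]]
        secondary = sorted(
            causes[j]
            for j in range(len(causes))
            if j != primary_idx[i] and cause_times[i, j] <= death_time[i] + window
        )
        death_rows.append(
            (
                pids[i],
                (assessment + pd.Timedelta(days=day)).date().isoformat(),
                ";".join([primary, *secondary]),
            )
        )
    deaths = pd.DataFrame(death_rows, columns=["participant_id", "date", "cause_codes"])
    deaths = deaths.sort_values("participant_id").reset_index(drop=True)

    truth = GroundTruth(
        exposed_flags=dict(zip(pids, map(bool, exposed))),
        planted_hr={c: h for c, h in sorted(config.exposure_hr.items()) if h != 1.0},
        planted_pairs=dict(config.pair_amplification),
    )
    return participants, diagnoses, deaths, truth


def write_tables(outdir, participants, diagnoses, deaths, truth) -> None:
    """Write the four artifact files in their canonical dialects."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    participants.to_csv(outdir / "participants.csv", index=False)
    diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    deaths.to_csv(outdir / "deaths.csv", index=False)
    truth.to_json(outdir / "ground_truth.json")
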