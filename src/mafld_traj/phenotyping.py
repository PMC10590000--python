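"""Fatty-liver phenotyping: FLI, NAFLD fibrosis score, MAFLD, PRS, subgroups.

All scalar functions are vectorized over numpy arrays / pandas Series.
Canonical units: triglycerides and HDL in mmol/L, fasting glucose in mg/dL,
GGT/AST/ALT in U/L, platelets in 10^9/L, albumin in g/dL, waist in cm,
alcohol in g/day. Unit conversions are handled internally where a formula
requires a different unit.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .errors import PhenotypeError

# mg/dL per mmol/L for triglycerides
TG_MGDL_PER_MMOL = 88.57

#: FLI linear-predictor coefficients (TG in mg/dL, GGT in U/L, waist in cm).
FLI_COEF = {"ln_tg": 0.953, "bmi": 0.139, "ln_ggt": 0.718, "waist": 0.053,
            "intercept": -15.745}

FLI_STEATOSIS_CUTOFF = 60.0
NFS_FIBROSIS_CUTOFF = -1.455

#: Default fixed PRS tertile cutoffs (cohort-specific in the source study).
PRS_TERTILE_CUTOFFS = (0.76, 2.35)

SNP_COLUMNS = ("snp_mboat7", "snp_gckr", "snp_tm6sf2", "snp_pnpla3")


def _asarray(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def compute_fli(tg_mmol, bmi, ggt, waist) -> np.ndarray:
    """Fatty liver index in [0, 100].

    ``100 * expit(0.953 ln(TG mg/dL) + 0.139 BMI + 0.718 ln(GGT) +
    0.053 waist - 15.745)``. TG is taken in mmol/L and converted.
    """
    tg_mmol, bmi, ggt, waist = map(_asarray, (tg_mmol, bmi, ggt, waist))
    for name, arr in (("triglycerides", tg_mmol), ("ggt", ggt)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise PhenotypeError(f"{name} must be strictly positive for FLI")
    for name, arr in (("bmi", bmi), ("waist", waist)):
        if np.any(arr[~np.isnan(arr)] <= 0):
            raise PhenotypeError(f"{name} must be positive for FLI")
    lp = (
        FLI_COEF["ln_tg"] * np.log(tg_mmol * TG_MGDL_PER_MMOL)
        + FLI_COEF["bmi"] * bmi
        + FLI_COEF["ln_ggt"] * np.log(ggt)
        + FLI_COEF["waist"] * waist
        + FLI_COEF["intercept"]
    )
    return 100.0 * expit(lp)


def fli_linear_predictor_inverse(fli: np.ndarray) -> np.ndarray:
    """Linear predictor that yields a given FLI value (used by the simulator)."""
    return logit(_asarray(fli) / 100.0)


def compute_nfs(age, bmi, t2d, ast, alt, platelets, albumin) -> np.ndarray:
    """NAFLD fibrosis score.

    ``-1.675 + 0.037 age + 0.094 BMI + 1.13 [T2D] + 0.99 AST/ALT
    - 0.013 platelets - 0.66 albumin``.
    """
    age, bmi, t2d, ast, alt, platelets, albumin = map(
        _asarray, (age, bmi, t2d, ast, alt, platelets, albumin)
    )
    if np.any(alt[~np.isnan(alt)] <= 0):
        raise PhenotypeError("alt must be strictly positive for the AST/ALT ratio")
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * t2d
        + 0.99 * (ast / alt)
        - 0.013 * platelets
        - 0.66 * albumin
    )


def advanced_fibrosis(nfs, cutoff: float = NFS_FIBROSIS_CUTOFF,
                      inclusive: bool = False) -> np.ndarray:
    """Flag scores above the fibrosis cutoff (strict ``>`` by default)."""
    nfs = _asarray(nfs)
    return nfs >= cutoff if inclusive else nfs > cutoff


def _criterion(true_mask: np.ndarray, known_mask: np.ndarray):
    return true_mask & known_mask, known_mask


def classify_mafld(
    steatosis,
    *,
    t2d,
    bmi,
    glucose_mgdl,
    hba1c,
    hdl,
    tg_mmol,
    sbp,
    dbp,
    bp_med,
    waist,
    male,
) -> pd.arrays.BooleanArray:
    """Tri-state MAFLD classification.

    True iff steatosis AND (T2D, or BMI >= 25, or at least two of:
    prediabetes, low HDL, TG >= 1.7 mmol/L, blood pressure >= 130/85 or
    medication, elevated waist circumference). Missing inputs yield ``NA``
    when (and only when) the outcome cannot be decided either way.
    """
    steat = _asarray(steatosis)
    t2d, bmi, glucose, hba1c, hdl, tg, sbp, dbp, bp_med, waist = map(
        _asarray, (t2d, bmi, glucose_mgdl, hba1c, hdl, tg_mmol, sbp, dbp, bp_med, waist)
    )
    male = np.asarray(male, dtype=bool)

    def known(x):
        return ~np.isnan(x)

    # metabolic-abnormality menu (insulin resistance unavailable -> 5 items)
    crits = []
    pre_t = (np.nan_to_num(glucose, nan=-np.inf) >= 100.0) | (
        np.nan_to_num(hba1c, nan=-np.inf) >= 5.7
    )
    crits.append(_criterion(pre_t, pre_t | (known(glucose) & known(hba1c))))
    hdl_thr = np.where(male, 1.03, 1.29)
    crits.append(_criterion(hdl < hdl_thr, known(hdl)))
    crits.append(_criterion(tg >= 1.7, known(tg)))
    bp_t = (
        (np.nan_to_num(sbp, nan=-np.inf) >= 130.0)
        | (np.nan_to_num(dbp, nan=-np.inf) >= 85.0)
        | (np.nan_to_num(bp_med, nan=0.0) == 1)
    )
    crits.append(_criterion(bp_t, bp_t | (known(sbp) & known(dbp) & known(bp_med))))
    waist_thr = np.where(male, 102.0, 88.0)
    crits.append(_criterion(waist >= waist_thr, known(waist)))

    n_true = np.sum([t for t, _ in crits], axis=0)
    n_unknown = np.sum([~k for _, k in crits], axis=0)

    t2d_true, t2d_known = np.nan_to_num(t2d, nan=0.0) == 1, known(t2d)
    bmi_true, bmi_known = np.nan_to_num(bmi, nan=-np.inf) >= 25.0, known(bmi)
    steat_true, steat_known = np.nan_to_num(steat, nan=0.0) == 1, known(steat)

    is_true = steat_true & (
        (t2d_true & t2d_known) | (bmi_true & bmi_known) | (n_true >= 2)
    )
    is_false = (steat_known & ~steat_true) | (
        steat_known
        & t2d_known & ~t2d_true
        & bmi_known & ~bmi_true
        & ((n_true + n_unknown) < 2)
    )
    values = np.where(is_true, True, False)
    mask = ~(is_true | is_false)  # undetermined
    return pd.arrays.BooleanArray(values.astype(bool), mask)


def compute_prs(dosages, betas=None) -> np.ndarray:
    """Normalized polygenic risk score.

    ``(sum beta_i * dosage_i) * (n_snps / sum beta_i)`` with dosages in
    {0, 1, 2}; attainable range is [0, 2 * n_snps] for any positive weights.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.ndim == 1:
        dosages = dosages[None, :]
    n_snps = dosages.shape[1]
    if betas is None:
        betas = np.ones(n_snps)
    betas = np.asarray(betas, dtype=float)
    if betas.shape != (n_snps,) or np.any(betas <= 0):
        raise PhenotypeError("betas must be positive, one per SNP")
    valid = np.isin(dosages[~np.isnan(dosages)], (0.0, 1.0, 2.0))
    if not valid.all():
        raise PhenotypeError("dosages must lie in {0, 1, 2}")
    return (dosages @ betas) * (n_snps / betas.sum())


def prs_tertiles(prs, mode: str = "fixed",
                 cutoffs: tuple[float, float] = PRS_TERTILE_CUTOFFS) -> pd.Series:
    """Label scores low / intermediate / high.

    ``fixed`` uses the supplied cutoffs (low < c1 <= intermediate <= c2 < high);
    ``empirical`` computes cohort tertiles instead.
    """
    prs = pd.Series(_asarray(prs))
    if mode == "empirical":
        c1, c2 = prs.quantile([1 / 3, 2 / 3])
    elif mode == "fixed":
        c1, c2 = cutoffs
    else:
        raise ValueError(f"unknown tertile mode {mode!r}")
    labels = pd.Series("intermediate", index=prs.index, dtype=object)
    labels[prs < c1] = "low"
    labels[prs > c2] = "high"
    labels[prs.isna()] = pd.NA
    return labels


def subgroup_flags(bmi, alcohol_g_day, male) -> pd.DataFrame:
    """Overweight (BMI >= 25) and sex-specific heavy-drinker flags.

    Heavy drinking: >= 30 g/day for men, >= 20 g/day for women.
    """
    bmi = _asarray(bmi)
    alcohol = _asarray(alcohol_g_day)
    male = np.asarray(male, dtype=bool)
    thr = np.where(male, 30.0, 20.0)
    return pd.DataFrame(
        {
            "overweight": pd.arrays.BooleanArray(bmi >= 25.0, np.isnan(bmi)),
            "heavy_drinker": pd.arrays.BooleanArray(alcohol >= thr, np.isnan(alcohol)),
        }
    )


def phenotype_table(
    participants: pd.DataFrame,
    *,
    fli_cutoff: float = FLI_STEATOSIS_CUTOFF,
    nfs_cutoff: float = NFS_FIBROSIS_CUTOFF,
    snp_betas=None,
    tertile_mode: str = "fixed",
    tertile_cutoffs: tuple[float, float] = PRS_TERTILE_CUTOFFS,
) -> pd.DataFrame:
    """Compute every phenotype column for a participant table.

    Expects the canonical participant schema (see :mod:`mafld_traj.synthetic`).
    Returns one row per participant with fli, steatosis, nfs,
    advanced_fibrosis, mafld, prs, genetic_tertile, overweight, heavy_drinker.
    """
    p = participants
    male = p["sex"].astype(str).str.lower().eq("male").to_numpy()
    fli = compute_fli(p["tg"], p["bmi"], p["ggt"], p["waist"])
    steatosis = fli >= fli_cutoff
    nfs = compute_nfs(p["age"], p["bmi"], p["t2d"], p["ast"], p["alt"],
                      p["platelets"], p["albumin"])
    mafld = classify_mafld(
        steatosis,
        t2d=p["t2d"], bmi=p["bmi"], glucose_mgdl=p["glucose"], hba1c=p["hba1c"],
        hdl=p["hdl"], tg_mmol=p["tg"], sbp=p["sbp"], dbp=p["dbp"],
        bp_med=p["bp_med"], waist=p["waist"], male=male,
    )
    out = pd.DataFrame({"participant_id": p["participant_id"].to_numpy()})
    out["fli"] = fli
    out["steatosis"] = steatosis
    out["nfs"] = nfs
    out["advanced_fibrosis"] = advanced_fibrosis(nfs, cutoff=nfs_cutoff)
    out["mafld"] = mafld
    if all(c in p.columns for c in SNP_COLUMNS):
        prs = compute_prs(p[list(SNP_COLUMNS)].to_numpy(), snp_betas)
        out["prs"] = prs
        out["genetic_tertile"] = prs_tertiles(
            prs, mode=tertile_mode, cutoffs=tertile_cutoffs
        ).to_numpy()
    flags = subgroup_flags(p["bmi"], p["alcohol"], male)
    out["overweight"] = flags["overweight"].to_numpy()
    out["heavy_drinker"] = flags["heavy_drinker"].to_numpy()
    return out
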