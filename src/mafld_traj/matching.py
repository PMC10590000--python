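"""1:1 propensity-score matching with balance diagnostics.

Propensity is an additive logistic model of exposure on the matching
covariates; pairing is greedy nearest-neighbour without replacement on the
logit-propensity scale, in seed-randomized order, with exact matching on sex
and an optional caliper (default 0.2 SD of the logit propensity). Reused for
decedent-vs-survivor matching in the death workflow (ratio >= 1 supported).
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import MatchingError, SeparationError

DEFAULT_COVARIATES = ("age", "sex", "townsend")


@dataclass
class MatchSpec:
    exposure: str
    covariates: tuple = DEFAULT_COVARIATES
    ratio: int = 1
    #: "auto" = 0.2 SD of logit propensity, "none" disables, or a float
    caliper: object = "auto"
    seed: int = 0
    exact: tuple = ("sex",)


@dataclass
class MatchedCohort:
    pairs: pd.DataFrame          # columns: exposed_id, control_id
    balance: pd.DataFrame        # covariate, smd_before, smd_after
    n_unmatched_exposed: int = 0

    @property
    def matched_ids(self) -> pd.Index:
        return pd.Index(
            np.concatenate([self.pairs["exposed_id"], self.pairs["control_id"]])
        )


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            codes, _ = pd.factorize(col, sort=True)
            X[cov] = codes.astype(float)
        else:
            X[cov] = col.astype(float)
    return X


def estimate_propensity(df: pd.DataFrame, spec: MatchSpec) -> pd.Series:
    """Fitted exposure probability per participant (additive logistic model)."""
    missing = [c for c in (*spec.covariates, spec.exposure) if c not in df.columns]
    if missing:
        raise MatchingError(f"missing columns: {missing}")
    X = _design(df, spec.covariates)
    if X.isna().to_numpy().any():
        raise MatchingError("missing covariate values; exclude them before matching")
    y = df[spec.exposure].astype(float)
    if y.nunique() < 2:
        raise MatchingError("exposure column is constant")
    # constant covariates (e.g. sex inside a single-sex subgroup) carry no
    # information and make the design singular
    X = X.loc[:, X.nunique() > 1]
    if X.shape[1] == 0:
        prev = float(y.mean())
        return pd.Series(np.clip(prev, 1e-12, 1 - 1e-12), index=df.index,
                         name="propensity")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError and kin
        raise SeparationError(
            "propensity model failed (likely perfect separation); "
            "fall back to caliper-free exact matching"
        ) from exc
    if np.any(np.abs(fit.params.to_numpy()[1:]) > 30):
        raise SeparationError(
            "propensity model is (quasi-)separated; "
            "fall back to caliper-free exact matching"
        )
    p = fit.predict(Xc)
    return pd.Series(np.clip(p, 1e-12, 1 - 1e-12), index=df.index, name="propensity")


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p / (1.0 - p))


def standardized_mean_difference(a: np.ndarray, b: np.ndarray) -> float:
    """|mean difference| / pooled SD; 0 when both groups are degenerate-equal."""
    va, vb = np.var(a, ddof=1) if len(a) > 1 else 0.0, np.var(b, ddof=1) if len(b) > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2.0)
    diff = float(np.mean(a) - np.mean(b))
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else np.inf
    return abs(diff) / pooled


def balance_table(df: pd.DataFrame, spec: MatchSpec,
                  pairs: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-covariate SMD before and (if pairs given) after matching."""
    X = _design(df, spec.covariates)
    exp_mask = df[spec.exposure].astype(bool).to_numpy()
    rows = []
    idx = df.set_index("participant_id").index
    for cov in spec.covariates:
        x = X[cov].to_numpy()
        before = standardized_mean_difference(x[exp_mask], x[~exp_mask])
        after = np.nan
        if pairs is not None and len(pairs):
            pos = pd.Series(np.arange(len(df)), index=idx)
            xe = x[pos.loc[pairs["exposed_id"]].to_numpy()]
            xc = x[pos.loc[pairs["control_id"]].to_numpy()]
            after = standardized_mean_difference(xe, xc)
        rows.append({"covariate": cov, "smd_before": before, "smd_after": after})
    return pd.DataFrame(rows)


def match_pairs(df: pd.DataFrame, propensity: pd.Series, spec: MatchSpec
                ) -> MatchedCohort:
    """Greedy nearest-neighbour matching without replacement.

    Exposed participants are visited in seed-randomized order; each takes the
    nearest remaining control on the logit-propensity scale within its exact
    stratum and caliper. Unmatched exposed are dropped (count reported).
    """
    exp_mask = df[spec.exposure].astype(bool).to_numpy()
    if exp_mask.sum() == 0 or (~exp_mask).sum() == 0:
        raise MatchingError("need at least one exposed and one control participant")
    lp = _logit(propensity.to_numpy())
    if spec.caliper == "auto":
        caliper = 0.2 * float(np.std(lp, ddof=1)) if len(lp) > 1 else np.inf
    elif spec.caliper in (None, "none"):
        caliper = np.inf
    else:
        caliper = float(spec.caliper)
        if caliper < 0:
            raise MatchingError("caliper must be >= 0")

    ids = df["participant_id"].to_numpy()
    strata_cols = [c for c in spec.exact if c in df.columns]
    strata = (
        df[strata_cols].astype(str).agg("|".join, axis=1).to_numpy()
        if strata_cols
        else np.full(len(df), "")
    )

    rng = np.random.default_rng(spec.seed)
    pair_rows: list[tuple] = []
    n_unmatched = 0
    for stratum in sorted(set(strata)):
        in_s = strata == stratum
        e_idx = np.flatnonzero(in_s & exp_mask)
        c_idx = np.flatnonzero(in_s & ~exp_mask)
        if len(e_idx) == 0:
            continue
        e_idx = e_idx[rng.permutation(len(e_idx))]
        order = np.argsort(lp[c_idx], kind="stable")
        pool_lp = list(lp[c_idx][order])
        pool_id = list(ids[c_idx][order])
        for _round in range(spec.ratio):
            for i in e_idx:
                if not pool_lp:
                    n_unmatched += 1
                    continue
                x = lp[i]
                j = bisect.bisect_left(pool_lp, x)
                best, best_d = None, np.inf
                for cand in (j - 1, j):
                    if 0 <= cand < len(pool_lp):
                        d = abs(pool_lp[cand] - x)
                        if d < best_d:
                            best, best_d = cand, d
                if best is None or best_d > caliper:
                    n_unmatched += 1
                    continue
                pair_rows.append((ids[i], pool_id[best]))
                pool_lp.pop(best)
                pool_id.pop(best)
    pairs = pd.DataFrame(pair_rows, columns=["exposed_id", "control_id"])
    pairs = pairs.sort_values(["exposed_id", "control_id"]).reset_index(drop=True)
    balance = balance_table(df, spec, pairs)
    return MatchedCohort(pairs=pairs, balance=balance, n_unmatched_exposed=n_unmatched)


def match(df: pd.DataFrame, spec: MatchSpec) -> MatchedCohort:
    """Estimate propensities and match in one call."""
    ps = estimate_propensity(df, spec)
    return match_pairs(df, ps, spec)
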