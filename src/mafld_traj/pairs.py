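"""Temporal disease-pair inference.

From a set of PheWAS-significant categories: enumerate all n(n-1) ordered
pairs, keep pairs co-occurring in more than a fraction (default 0.5%) of
exposed participants, test temporal direction with an exact one-sided
binomial test (same-day ties removed from the trial count), and confirm the
association with a univariate logistic model of D2 on D1-before-D2.
Bonferroni denominators follow the sequential flow: the direction stage uses
the number of pairs passing the co-occurrence filter, the association stage
the number passing direction.
"""
from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_PAIR_FRACTION = 0.005


def enumerate_pairs(categories) -> list[tuple[str, str]]:
    """All ordered pairs of distinct categories; n(n-1) of them."""
    cats = sorted(set(categories))
    if len(cats) < 2:
        logger.info("fewer than two categories; no pairs to enumerate")
        return []
    return [p for p in itertools.permutations(cats, 2)]


def event_date_index(events: pd.DataFrame, participant_ids=None) -> dict:
    """category -> Series(participant_id -> first-diagnosis date)."""
    ev = events
    if participant_ids is not None:
        ev = ev[ev["participant_id"].isin(set(participant_ids))]
    out = {}
    for cat, sub in ev.groupby("category"):
        out[cat] = pd.Series(
            pd.to_datetime(sub["date"]).to_numpy(), index=sub["participant_id"]
        )
    return out


def count_pair(d1_dates: pd.Series, d2_dates: pd.Series) -> tuple[int, int, int]:
    """(n_both, n_d2_after, n_ties) over participants holding both diagnoses."""
    common = d1_dates.index.intersection(d2_dates.index)
    if len(common) == 0:
        return 0, 0, 0
    t1 = d1_dates.loc[common].to_numpy()
    t2 = d2_dates.loc[common].to_numpy()
    n_both = len(common)
    n_after = int((t2 > t1).sum())
    n_ties = int((t2 == t1).sum())
    return n_both, n_after, n_ties


def binomial_direction_test(
    n_d2_after: int, n_both: int, n_ties: int, method: str = "exact"
) -> tuple[float, float]:
    """Fraction of D2-later participants and one-sided binomial p.

    Ties are excluded from the trial count: p = P(X >= n_d2_after) with
    X ~ Binomial(n_both - n_ties, 1/2). ``method="normal"`` uses the normal
    approximation (available for large counts); default is exact.
    """
    trials = n_both - n_ties
    if trials <= 0:
        return np.nan, np.nan
    frac = n_d2_after / trials
    if method == "exact":
        p = stats.binomtest(n_d2_after, trials, 0.5, alternative="greater").pvalue
    elif method == "normal":
        z = (n_d2_after - trials / 2.0) / np.sqrt(trials / 4.0)
        p = stats.norm.sf(z)
    else:
        raise ValueError(f"unknown binomial method {method!r}")
    return frac, float(p)


def logistic_pair_test(
    d1_dates: pd.Series,
    d2_dates: pd.Series,
    population: pd.Index,
    baseline_dates: pd.Series | None = None,
) -> dict:
    """Univariate logistic model of D2 on D1-before-D2 among exposed.

    The risk set is the exposed population free of D2 at baseline; D1
    counts as exposure when diagnosed strictly before D2 (cases) or at any
    time during follow-up (non-cases). With no covariates the OR equals the
    2x2 cross-product ratio; zero cells are flagged non-estimable.
    """
    pop = pd.Index(population)
    if baseline_dates is not None:
        base = baseline_dates.reindex(pop)
        prevalent = d2_dates.reindex(pop)
        drop = prevalent.notna() & base.notna() & (prevalent <= base)
        pop = pop[~drop.to_numpy()]
    y = pop.isin(d2_dates.index).astype(int)
    t1 = d1_dates.reindex(pop)
    t2 = d2_dates.reindex(pop)
    x = np.where(
        y == 1,
        t1.notna().to_numpy() & (t1.to_numpy() < t2.to_numpy()),
        t1.notna().to_numpy(),
    ).astype(int)

    tab = pd.crosstab(pd.Series(x, name="d1"), pd.Series(y, name="d2"))
    tab = tab.reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    na = {"or": np.nan, "or_low": np.nan, "or_high": np.nan, "p": np.nan}
    if (tab.to_numpy() == 0).any():
        logger.info("zero cell in the D1/D2 2x2 table; pair non-estimable")
        return {**na, "status": "zero_cell"}
    X = sm.add_constant(pd.DataFrame({"d1": x}), has_constant="add")
    try:
        fit = sm.Logit(np.asarray(y), X).fit(disp=0, maxiter=200)
    except Exception as exc:
        logger.warning("logistic pair fit failed: %s", exc)
        return {**na, "status": "non_convergence"}
    coef = fit.params["d1"]
    lo, hi = fit.conf_int().loc["d1"]
    return {
        "or": float(np.exp(coef)),
        "or_low": float(np.exp(lo)),
        "or_high": float(np.exp(hi)),
        "p": float(fit.pvalues["d1"]),
        "status": "ok",
    }


def cooccurrence_threshold(n_exposed: int, fraction: float = DEFAULT_PAIR_FRACTION
                           ) -> int:
    """floor(fraction * n_exposed); pairs must strictly exceed it."""
    import math

    return math.floor(fraction * n_exposed)


def run_pair_inference(
    events: pd.DataFrame,
    exposed_ids,
    categories,
    n_exposed: int | None = None,
    alpha: float = 0.05,
    fraction: float = DEFAULT_PAIR_FRACTION,
    baseline_dates: pd.Series | None = None,
    binom_method: str = "exact",
    run_log=None,
) -> pd.DataFrame:
    """Full pair pipeline; one row per enumerated pair, stage exit recorded.

    ``stage`` holds the last stage a pair survived:
    ``cooccurrence`` (failed the co-occurrence filter), ``direction``
    (failed the binomial stage), ``association`` (failed the logistic
    stage), or ``confirmed``.
    """
    exposed_ids = pd.Index(pd.unique(pd.Series(list(exposed_ids))))
    n_exposed = n_exposed if n_exposed is not None else len(exposed_ids)
    dates = event_date_index(events, exposed_ids)
    pairs = enumerate_pairs(categories)
    threshold = cooccurrence_threshold(n_exposed, fraction)
    if run_log is not None:
        run_log.log("pairs", "cooccurrence_filter", n_exposed=n_exposed,
                    fraction=fraction, threshold=threshold, n_pairs=len(pairs))

    empty = pd.Series(pd.to_datetime([]), index=pd.Index([]))
    rows = []
    for d1, d2 in pairs:
        n_both, n_after, n_ties = count_pair(dates.get(d1, empty), dates.get(d2, empty))
        rows.append({
            "d1": d1, "d2": d2, "n_both": n_both, "n_d2_after": n_after,
            "n_ties": n_ties, "passes_cooccurrence": n_both > threshold,
        })
    df = pd.DataFrame(
        rows, columns=["d1", "d2", "n_both", "n_d2_after", "n_ties",
                       "passes_cooccurrence"],
    )
    for col in ("frac_d2_later", "binom_p", "or", "or_low", "or_high", "logit_p"):
        df[col] = np.nan
    df["direction_ok"] = False
    df["association_ok"] = False
    df["status"] = ""

    kept = df.index[df["passes_cooccurrence"]] if len(df) else []
    n_direction_tests = len(kept)
    dir_cut = alpha / n_direction_tests if n_direction_tests else np.nan
    for i in kept:
        frac, p = binomial_direction_test(
            int(df.at[i, "n_d2_after"]), int(df.at[i, "n_both"]),
            int(df.at[i, "n_ties"]), method=binom_method,
        )
        df.at[i, "frac_d2_later"] = frac
        df.at[i, "binom_p"] = p
        if np.isnan(frac):
            df.at[i, "status"] = "all_tied"
            continue
        df.at[i, "direction_ok"] = (frac > 0.5) and (p < dir_cut)

    assoc_idx = df.index[df["direction_ok"]] if len(df) else []
    n_assoc_tests = len(assoc_idx)
    assoc_cut = alpha / n_assoc_tests if n_assoc_tests else np.nan
    for i in assoc_idx:
        res = logistic_pair_test(
            dates.get(df.at[i, "d1"], empty), dates.get(df.at[i, "d2"], empty),
            exposed_ids, baseline_dates=baseline_dates,
        )
        df.at[i, "or"] = res["or"]
        df.at[i, "or_low"] = res["or_low"]
        df.at[i, "or_high"] = res["or_high"]
        df.at[i, "logit_p"] = res["p"]
        if res["status"] != "ok":
            df.at[i, "status"] = res["status"]
            continue
        df.at[i, "association_ok"] = (res["or"] > 1.0) and (res["p"] < assoc_cut)

    df["confirmed"] = df["direction_ok"] & df["association_ok"]
    if df.empty:
        df["stage"] = pd.Series(dtype=object)
        df.attrs["cooccurrence_threshold"] = threshold
        df.attrs["direction_bonferroni_n"] = 0
        df.attrs["association_bonferroni_n"] = 0
        return df
    df["stage"] = np.select(
        [df["confirmed"], df["direction_ok"], df["passes_cooccurrence"]],
        ["confirmed", "association", "direction"],
        default="cooccurrence",
    )
    df.attrs["cooccurrence_threshold"] = threshold
    df.attrs["direction_bonferroni_n"] = n_direction_tests
    df.attrs["association_bonferroni_n"] = n_assoc_tests
    if run_log is not None:
        run_log.log("pairs", "bonferroni", alpha=alpha,
                    direction_n=n_direction_tests, association_n=n_assoc_tests,
                    n_confirmed=int(df["confirmed"].sum()))
    return df


def select_pairs(tested: pd.DataFrame) -> pd.DataFrame:
    """Pairs that passed co-occurrence, direction and association stages."""
    return tested[tested["confirmed"]].reset_index(drop=True)
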