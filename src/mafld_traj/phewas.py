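"""Phenome-wide association sweep.

Per-outcome subcohort construction (prevalent-case exclusion), an incidence
filter on exposed case counts, Cox proportional-hazards regression of the
exposure flag (Efron tie handling), and Bonferroni selection. Outcomes may
be disease categories or cause-of-death categories; the exposure flag may be
MAFLD, a PRS tertile contrast, death status, or a prior disease.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from . import taxonomy

logger = logging.getLogger(__name__)

DEFAULT_MIN_CASE_FRACTION = 0.01


@dataclass(frozen=True)
class OutcomeSpec:
    code: str
    kind: str = "disease"                 # "disease" | "death_cause"
    min_case_fraction: float = DEFAULT_MIN_CASE_FRACTION

    def __post_init__(self):
        if not 0.0 < self.min_case_fraction < 1.0:
            raise ValueError("min_case_fraction must lie in (0, 1)")
        if self.kind not in {"disease", "death_cause"}:
            raise ValueError(f"unknown outcome kind {self.kind!r}")


def incidence_threshold(n_exposed: int, fraction: float) -> int:
    """Minimum exposed-case count: ``floor(fraction * n_exposed)``.

    Outcomes whose exposed case count does not *exceed* this value are
    skipped (strict ``>``).
    """
    if n_exposed <= 0:
        raise ValueError("n_exposed must be positive")
    return math.floor(fraction * n_exposed)


def _as_day_number(s: pd.Series) -> pd.Series:
    return pd.to_datetime(s, format="ISO8601")


def build_subcohort(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    exposure: str,
    outcome: OutcomeSpec,
) -> pd.DataFrame:
    """Per-outcome analysis table.

    ``cohort`` needs participant_id, the exposure flag, assessment_date and
    censor_date. Participants with the outcome on or before the assessment
    date are excluded (events dated exactly on the assessment date count as
    prevalent). Follow-up runs from assessment to first outcome, death, or
    censor date; death censors disease outcomes.
    """
    tab = cohort[["participant_id", exposure]].copy()
    tab["exposure"] = tab.pop(exposure).astype(int)
    assess = _as_day_number(cohort["assessment_date"]).to_numpy()
    censor = _as_day_number(cohort["censor_date"]).to_numpy()

    death_date = pd.Series(pd.NaT, index=tab.index)
    if len(deaths):
        dmap = deaths.set_index("participant_id")["date"]
        death_date = tab["participant_id"].map(dmap)
    death_np = pd.to_datetime(death_date).to_numpy()

    if outcome.kind == "disease":
        ev = events.loc[events["category"] == outcome.code]
        emap = ev.set_index("participant_id")["date"]
        event_date = pd.to_datetime(tab["participant_id"].map(emap)).to_numpy()
    else:
        if len(deaths):
            has_cause = deaths["causes"].map(lambda cs: outcome.code in cs)
            dmap = deaths.loc[has_cause].set_index("participant_id")["date"]
            event_date = pd.to_datetime(tab["participant_id"].map(dmap)).to_numpy()
        else:
            event_date = np.full(len(tab), np.datetime64("NaT"))

    prevalent = (~pd.isna(event_date)) & (event_date <= assess)
    end = censor.copy()
    has_death = ~pd.isna(death_np)
    end[has_death] = np.minimum(end[has_death], death_np[has_death])
    has_event = (~pd.isna(event_date)) & (event_date <= end)
    stop = end.copy()
    stop[has_event] = event_date[has_event]

    time_days = (stop - assess) / np.timedelta64(1, "D")
    out = pd.DataFrame(
        {
            "participant_id": tab["participant_id"],
            "exposure": tab["exposure"],
            "event": has_event.astype(int),
            "time": time_days.astype(float),
        }
    )
    out = out[~prevalent].reset_index(drop=True)
    return out[out["time"] > 0].reset_index(drop=True)


def sensitivity_exclusion(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    exposure: str,
    outcome: OutcomeSpec,
    scheme,
) -> pd.DataFrame:
    """Subcohort that also drops anyone with a baseline disease in the
    outcome's chapter-level system group (the 16 cause-of-death scheme)."""
    group = taxonomy.chapter_group(outcome.code, scheme)
    assess = (
        cohort.set_index("participant_id")["assessment_date"].pipe(_as_day_number)
    )
    if group is not None and len(events):
        ev = events.copy()
        ev["group"] = ev["category"].map(lambda c: taxonomy.chapter_group(c, scheme))
        ev = ev[ev["group"] == group]
        ev_assess = ev["participant_id"].map(assess)
        baseline_ids = set(
            ev.loc[pd.to_datetime(ev["date"]) <= pd.to_datetime(ev_assess),
                   "participant_id"]
        )
    else:
        baseline_ids = set()
    kept = cohort[~cohort["participant_id"].isin(baseline_ids)]
    return build_subcohort(kept, events, deaths, exposure, outcome)


def fit_time_to_event(table: pd.DataFrame) -> dict:
    """Cox PH fit of the exposure flag; Wald CI and p.

    Returns hr/ci_low/ci_high/p with status "ok", or a flagged status
    ("no_events_arm", "non_convergence", "no_events") with NaN estimates.
    """
    na = {"hr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
    events_by_arm = table.groupby("exposure")["event"].sum()
    if table["event"].sum() == 0:
        return {**na, "status": "no_events"}
    if len(events_by_arm) < 2 or (events_by_arm == 0).any():
        return {**na, "status": "no_events_arm"}
    cph = CoxPHFitter()
    try:
        cph.fit(
            table[["time", "event", "exposure"]],
            duration_col="time",
            event_col="event",
        )
    except (ConvergenceError, ValueError) as exc:
        logger.warning("Cox fit failed: %s", exc)
        return {**na, "status": "non_convergence"}
    row = cph.summary.loc["exposure"]
    return {
        "hr": float(row["exp(coef)"]),
        "ci_low": float(row["exp(coef) lower 95%"]),
        "ci_high": float(row["exp(coef) upper 95%"]),
        "p": float(row["p"]),
        "status": "ok",
    }


def run_phewas(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    exposure: str,
    outcomes: list[OutcomeSpec],
    alpha: float = 0.05,
    n_categories: int | None = None,
    sensitivity: bool = False,
    scheme=None,
    run_log=None,
) -> pd.DataFrame:
    """Sweep outcomes; never aborts on a per-outcome failure.

    Significance: HR > 1 and p below ``alpha / denominator`` where the
    denominator is ``n_categories`` when given (the full catalogue size),
    else the number of outcomes actually tested.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    n_exposed = int(cohort[exposure].astype(bool).sum())
    rows = []
    for spec in outcomes:
        try:
            if sensitivity:
                tab = sensitivity_exclusion(cohort, events, deaths, exposure, spec,
                                            scheme or taxonomy.load_death_scheme())
            else:
                tab = build_subcohort(cohort, events, deaths, exposure, spec)
        except Exception as exc:
            logger.warning("subcohort for %s failed: %s", spec.code, exc)
            rows.append({"outcome": spec.code, "kind": spec.kind, "n_cases": 0,
                         "n_exposed_cases": 0, "hr": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "status": "subcohort_error"})
            continue
        n_cases = int(tab["event"].sum())
        n_exposed_cases = int(tab.loc[tab["exposure"] == 1, "event"].sum())
        threshold = incidence_threshold(n_exposed, spec.min_case_fraction)
        if run_log is not None:
            run_log.log("phewas", "incidence_filter", outcome=spec.code,
                        n_exposed=n_exposed, fraction=spec.min_case_fraction,
                        threshold=threshold, n_exposed_cases=n_exposed_cases)
        if n_exposed_cases <= threshold:
            rows.append({"outcome": spec.code, "kind": spec.kind, "n_cases": n_cases,
                         "n_exposed_cases": n_exposed_cases, "hr": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "status": "skipped_incidence"})
            continue
        fit = fit_time_to_event(tab)
        rows.append({"outcome": spec.code, "kind": spec.kind, "n_cases": n_cases,
                     "n_exposed_cases": n_exposed_cases, **fit})
    results = pd.DataFrame(rows)
    denom = n_categories if n_categories is not None else int(
        (results["status"] == "ok").sum() or 1
    )
    cut = alpha / denom
    results["significant"] = (
        (results["status"] == "ok") & (results["hr"] > 1.0) & (results["p"] < cut)
    )
    results.attrs["alpha"] = alpha
    results.attrs["bonferroni_denominator"] = denom
    results.attrs["p_cutoff"] = cut
    if run_log is not None:
        run_log.log("phewas", "bonferroni", alpha=alpha, denominator=denom,
                    p_cutoff=cut, n_significant=int(results["significant"].sum()))
    return results
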