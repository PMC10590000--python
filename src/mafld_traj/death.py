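"""Death-trajectory and genetic-susceptibility workflows.

The death variant: (1) exposure -> cause-of-death PheWAS over the 16 cause
categories on the matched cohort; (2) decedents matched to survivors within
the exposed group; (3) disease-as-exposure -> death PheWAS per retained
cause; (4) pair inference restricted to decedents of each cause, with a
per-cause pruned trajectory graph terminating in the death node.

The genetic variant reruns the standard pipeline with exposure = highest vs
lowest PRS tertile (middle tertile dropped).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import graph as graph_mod
from . import matching, pairs, phewas, taxonomy
from .errors import MatchingError

logger = logging.getLogger(__name__)


@dataclass
class DeathWorkflowSpec:
    scheme: dict = field(default_factory=taxonomy.load_death_scheme)
    match_covariates: tuple = matching.DEFAULT_COVARIATES
    survivor_ratio: int = 1
    alpha: float = 0.05
    cause_fraction: float = 0.01
    disease_fraction: float = 0.01
    pair_fraction: float = pairs.DEFAULT_PAIR_FRACTION
    n_categories: int | None = None
    disease_death_model: str = "cox"      # or "logistic"
    seed: int = 0


@dataclass
class DeathWorkflowResult:
    cause_phewas: pd.DataFrame
    matched: "matching.MatchedCohort"
    per_cause: dict  # cause -> {"disease_phewas", "pairs", "graph"}


def _death_node(cause: str) -> str:
    return f"death:{cause}"


def _disease_death_association(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    disease: str,
    cause: str,
    model: str,
) -> dict:
    """Association between having a disease and dying of a given cause.

    Default is a Cox model of death-from-cause with a time-fixed flag for
    the disease being diagnosed before the event (a pragmatic anchor; a
    logistic mode is provided as a fallback).
    """
    cohort = cohort.reset_index(drop=True)
    tab = cohort[["participant_id"]].copy()
    ev = events[events["category"] == disease].set_index("participant_id")["date"]
    diag_date = pd.to_datetime(tab["participant_id"].map(ev))
    dmap = deaths.set_index("participant_id")
    death_date = pd.to_datetime(tab["participant_id"].map(dmap["date"]))
    died_cause = tab["participant_id"].map(
        dmap["causes"].map(lambda cs: cause in cs)
    ).eq(True)
    censor = pd.to_datetime(cohort["censor_date"])
    assess = pd.to_datetime(cohort["assessment_date"])
    end = death_date.fillna(censor)
    has_disease = (diag_date.notna() & (diag_date <= end.to_numpy())).astype(int)

    if model == "logistic":
        from . import pairs as pairs_mod

        d1 = pd.Series(diag_date.to_numpy(), index=tab["participant_id"])
        d1 = d1[d1.notna()]
        d2 = pd.Series(death_date.to_numpy(), index=tab["participant_id"])
        d2 = d2[died_cause.to_numpy() & d2.notna()]
        res = pairs_mod.logistic_pair_test(d1, d2, pd.Index(tab["participant_id"]))
        return {"hr": res["or"], "ci_low": res["or_low"], "ci_high": res["or_high"],
                "p": res["p"], "status": res["status"]}

    analysis = pd.DataFrame({
        "time": (end - assess).dt.days.astype(float),
        "event": died_cause.to_numpy().astype(int),
        "exposure": has_disease.to_numpy(),
    })
    analysis = analysis[analysis["time"] > 0]
    return phewas.fit_time_to_event(analysis)


def run_death_workflow(
    matched_cohort: pd.DataFrame,
    events: pd.DataFrame,
    deaths: pd.DataFrame,
    exposure: str,
    significant_diseases: list[str],
    spec: DeathWorkflowSpec,
    run_log=None,
) -> DeathWorkflowResult:
    """Run the full death-trajectory variant.

    ``matched_cohort``: participant table of the main matched cohort with
    the exposure flag. ``deaths`` must already carry grouped ``causes``
    (see :func:`mafld_traj.taxonomy.prepare_deaths`).
    """
    causes = sorted({c for cause, _ in spec.scheme.values() for c in [cause]})
    n_causes = len(causes)
    cause_outcomes = [
        phewas.OutcomeSpec(code=c, kind="death_cause",
                           min_case_fraction=spec.cause_fraction)
        for c in causes
    ]
    cause_phewas = phewas.run_phewas(
        matched_cohort, events, deaths, exposure, cause_outcomes,
        alpha=spec.alpha, n_categories=n_causes, run_log=run_log,
    )
    retained = sorted(cause_phewas.loc[cause_phewas["significant"], "outcome"])

    # decedent-vs-survivor matching within the exposed group
    exposed = matched_cohort[matched_cohort[exposure].astype(bool)].copy()
    exposed["died"] = exposed["participant_id"].isin(set(deaths["participant_id"])).astype(int)
    if exposed["died"].sum() == 0 or len(retained) == 0:
        logger.info("no decedents or no retained causes; death workflow is empty")
        empty = matching.MatchedCohort(
            pairs=pd.DataFrame(columns=["exposed_id", "control_id"]),
            balance=pd.DataFrame(columns=["covariate", "smd_before", "smd_after"]),
        )
        return DeathWorkflowResult(cause_phewas=cause_phewas, matched=empty,
                                   per_cause={})
    mspec = matching.MatchSpec(
        exposure="died", covariates=spec.match_covariates,
        ratio=spec.survivor_ratio, seed=spec.seed,
    )
    try:
        matched = matching.match(exposed, mspec)
    except MatchingError:
        raise
    study_ids = matched.matched_ids
    study = exposed[exposed["participant_id"].isin(set(study_ids))]

    per_cause = {}
    for cause in retained:
        decedents = study.loc[
            study["participant_id"].isin(set(deaths["participant_id"]))
            & study["participant_id"].map(
                deaths.set_index("participant_id")["causes"]
            ).map(lambda cs: isinstance(cs, frozenset) and cause in cs),
            "participant_id",
        ]
        if len(decedents) == 0:
            logger.info("cause %s has no decedents in the matched set; skipped", cause)
            continue
        assoc_rows = []
        for disease in sorted(significant_diseases):
            res = _disease_death_association(
                study, events, deaths, disease, cause, spec.disease_death_model
            )
            assoc_rows.append({"outcome": disease, "kind": "disease_to_death",
                               "cause": cause, **res})
        disease_phewas = pd.DataFrame(assoc_rows)
        if len(disease_phewas):
            denom = spec.n_categories or len(significant_diseases)
            disease_phewas["significant"] = (
                (disease_phewas["status"] == "ok")
                & (disease_phewas["hr"] > 1.0)
                & (disease_phewas["p"] < spec.alpha / denom)
            )
        retained_diseases = sorted(
            disease_phewas.loc[disease_phewas.get("significant", False), "outcome"]
        ) if len(disease_phewas) else []

        pair_df = pairs.run_pair_inference(
            events, decedents, retained_diseases,
            n_exposed=len(decedents), alpha=spec.alpha,
            fraction=spec.pair_fraction, run_log=run_log,
        )
        confirmed = pairs.select_pairs(pair_df)

        annot = disease_phewas.rename(columns={"cause": "_cause"})
        annot = annot[["outcome", "hr", "p"]].copy()
        annot["n_cases"] = 0
        g = graph_mod.assemble_graph(annot, confirmed)
        death_node = _death_node(cause)
        g.add_node(death_node, hr=float("nan"), n_cases=int(len(decedents)))
        for disease in retained_diseases:
            row = disease_phewas.set_index("outcome").loc[disease]
            if disease not in g:
                g.add_node(disease, hr=float(row["hr"]), n_cases=0)
            g.add_edge(disease, death_node, or_=float(row["hr"]),
                       n_both=0, binom_p=float("nan"), logit_p=float(row["p"]))
        pruned = graph_mod.transitive_prune(g)
        per_cause[cause] = {
            "disease_phewas": disease_phewas,
            "pairs": pair_df,
            "graph": pruned,
        }
        if run_log is not None:
            run_log.log("death", "cause_done", cause=cause,
                        n_decedents=int(len(decedents)),
                        n_retained_diseases=len(retained_diseases),
                        n_confirmed_pairs=int(len(confirmed)))
    return DeathWorkflowResult(cause_phewas=cause_phewas, matched=matched,
                               per_cause=per_cause)


def genetic_exposure_cohort(participants: pd.DataFrame, phenotypes: pd.DataFrame
                            ) -> pd.DataFrame:
    """Cohort with exposure = high vs low PRS tertile (middle dropped)."""
    merged = participants.merge(
        phenotypes[["participant_id", "genetic_tertile"]], on="participant_id"
    )
    sub = merged[merged["genetic_tertile"].isin(["low", "high"])].copy()
    n_low = int((sub["genetic_tertile"] == "low").sum())
    n_high = int((sub["genetic_tertile"] == "high").sum())
    if n_low == 0 or n_high == 0:
        raise MatchingError(
            f"degenerate PRS tertiles (low={n_low}, high={n_high}); "
            "cannot form the genetic exposure contrast"
        )
    sub["genetic_exposure"] = (sub["genetic_tertile"] == "high").astype(int)
    return sub.reset_index(drop=True)
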