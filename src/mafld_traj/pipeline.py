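"""End-to-end pipeline orchestration.

Stages: taxonomy -> phenotyping -> matching -> PheWAS -> pair inference ->
trajectory graph, with optional death and genetic-susceptibility workflows.
Every threshold and stage count is written to a JSON-lines run log; a fixed
config and seed reproduce byte-identical outputs.
"""
from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import death as death_mod
from . import graph as graph_mod
from . import matching, pairs, phenotyping, phewas, synthetic, taxonomy
from ._log import RunLog
from .errors import ConfigError


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the study's stated values."""

    outdir: str = "output"
    seed: int = 0
    # input paths (None -> simulate with `simulation`)
    participants: str | None = None
    diagnoses: str | None = None
    deaths: str | None = None
    mapping: str | None = None            # None -> built-in default mapping
    death_scheme: str | None = None
    simulation: dict | None = None        # SimulationConfig fields
    # phenotyping
    fli_cutoff: float = 60.0
    nfs_cutoff: float = -1.455
    tertile_mode: str = "fixed"
    tertile_cutoffs: tuple = (0.76, 2.35)
    # matching
    covariates: tuple = matching.DEFAULT_COVARIATES
    caliper: object = "auto"
    # phewas
    alpha: float = 0.05
    min_case_fraction: float = 0.01
    bonferroni_mode: str = "catalog"      # "catalog" | "tested"
    sensitivity: bool = False
    # pairs
    pair_fraction: float = 0.005
    # filters / variants
    subgroup: str | None = None           # pandas query on participant+phenotype table
    run_death: bool = False
    run_genetic: bool = False
    survivor_ratio: int = 1
    unmapped_policy: str = "drop"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _load_inputs(config: RunConfig, log: RunLog):
    if config.simulation is not None or config.participants is None:
        sim_raw = dict(config.simulation or {})
        pair_amp = {
            (d1, d2): float(psi)
            for d1, d2, psi in sim_raw.pop("pair_amplification", [])
        }
        sim_cfg = synthetic.SimulationConfig(
            seed=config.seed, **sim_raw
        )
        sim_cfg.pair_amplification = pair_amp
        sim_cfg.validate()
        participants, diagnoses, deaths_raw, truth = synthetic.simulate_cohort(sim_cfg)
        log.log("simulate", "done", n_participants=len(participants),
                n_diagnoses=len(diagnoses), n_deaths=len(deaths_raw),
                seed=config.seed)
    else:
        participants = pd.read_csv(config.participants)
        diagnoses = pd.read_csv(config.diagnoses) if config.diagnoses else pd.DataFrame(
            columns=["participant_id", "icd10_code", "date"])
        deaths_raw = pd.read_csv(config.deaths) if config.deaths else pd.DataFrame(
            columns=["participant_id", "date", "cause_codes"])
        truth = None
        log.log("load", "done", n_participants=len(participants),
                n_diagnoses=len(diagnoses), n_deaths=len(deaths_raw))
    return participants, diagnoses, deaths_raw, truth


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; returns a dict of stage artifacts."""
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = RunLog(outdir / "run_log.jsonl")
    log.log("pipeline", "start", seed=config.seed)

    participants, diagnoses, deaths_raw, truth = _load_inputs(config, log)
    participants.to_csv(outdir / "participants.csv", index=False)
    diagnoses.to_csv(outdir / "diagnoses.csv", index=False)
    deaths_raw.to_csv(outdir / "deaths.csv", index=False)
    if truth is not None:
        truth.to_json(outdir / "ground_truth.json")

    # taxonomy
    if config.mapping is not None:
        mapping = taxonomy.load_mapping(config.mapping)
    elif config.simulation is not None and config.simulation.get("disease_catalog"):
        mapping = taxonomy.identity_mapping(config.simulation["disease_catalog"])
    else:
        mapping = taxonomy.default_mapping()
    scheme = taxonomy.load_death_scheme(config.death_scheme)
    events = taxonomy.collapse_events(diagnoses, mapping,
                                      unmapped=config.unmapped_policy)
    deaths = taxonomy.prepare_deaths(deaths_raw, scheme)
    log.log("taxonomy", "collapsed", n_categories=mapping.n_categories,
            n_events=len(events))

    # phenotyping
    phenos = phenotyping.phenotype_table(
        participants,
        fli_cutoff=config.fli_cutoff,
        nfs_cutoff=config.nfs_cutoff,
        tertile_mode=config.tertile_mode,
        tertile_cutoffs=tuple(config.tertile_cutoffs),
    )
    phenos.to_csv(outdir / "phenotypes.csv", index=False)
    table = participants.merge(phenos, on="participant_id")
    n_undetermined = int(table["mafld"].isna().sum())
    table = table[table["mafld"].notna()].copy()
    table["mafld"] = table["mafld"].astype(bool).astype(int)
    log.log("phenotype", "done", n_mafld=int(table["mafld"].sum()),
            n_undetermined_excluded=n_undetermined)

    # subgroup filter (applied before matching: each subgroup is rematched)
    if config.subgroup:
        n_before = len(table)
        table = table.query(config.subgroup).copy()
        log.log("subgroup", "filtered", expression=config.subgroup,
                n_before=n_before, n_after=len(table))

    # matching
    mspec = matching.MatchSpec(
        exposure="mafld", covariates=tuple(config.covariates),
        caliper=config.caliper, seed=config.seed,
    )
    matched = matching.match(table, mspec)
    matched.pairs.to_csv(outdir / "matched_pairs.csv", index=False)
    matched.balance.to_csv(outdir / "balance_report.tsv", sep="\t", index=False)
    log.log("match", "done", n_pairs=len(matched.pairs),
            n_unmatched_exposed=matched.n_unmatched_exposed,
            caliper=str(config.caliper), covariates=list(config.covariates))
    cohort = table[table["participant_id"].isin(set(matched.matched_ids))].copy()

    # phewas over all mapped categories
    catalog = sorted(mapping.categories)
    outcomes = [
        phewas.OutcomeSpec(code=c, min_case_fraction=config.min_case_fraction)
        for c in catalog
    ]
    n_categories = len(catalog) if config.bonferroni_mode == "catalog" else None
    results = phewas.run_phewas(
        cohort, events, deaths, "mafld", outcomes,
        alpha=config.alpha, n_categories=n_categories,
        sensitivity=config.sensitivity, scheme=scheme, run_log=log,
    )
    results.to_csv(outdir / "phewas_results.tsv", sep="\t", index=False)
    significant = sorted(results.loc[results["significant"], "outcome"])

    # pairs among exposed members of the matched cohort
    exposed_ids = cohort.loc[cohort["mafld"] == 1, "participant_id"]
    pair_df = pairs.run_pair_inference(
        events, exposed_ids, significant,
        n_exposed=len(exposed_ids), alpha=config.alpha,
        fraction=config.pair_fraction, run_log=log,
    )
    pair_df.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
    confirmed = pairs.select_pairs(pair_df)

    # graph
    g = graph_mod.assemble_graph(results, confirmed)
    pruned = graph_mod.transitive_prune(g)
    graph_mod.export_graph(pruned, outdir, stem="graph")
    log.log("graph", "done", n_nodes=pruned.number_of_nodes(),
            n_edges=pruned.number_of_edges(),
            n_pruned=len(pruned.graph.get("pruned_edges", [])))

    artifacts = {
        "participants": participants, "events": events, "deaths": deaths,
        "phenotypes": phenos, "matched": matched, "cohort": cohort,
        "phewas": results, "pairs": pair_df, "graph": pruned, "truth": truth,
    }

    if config.run_death:
        dspec = death_mod.DeathWorkflowSpec(
            scheme=scheme, match_covariates=tuple(config.covariates),
            survivor_ratio=config.survivor_ratio, alpha=config.alpha,
            pair_fraction=config.pair_fraction, seed=config.seed,
        )
        dres = death_mod.run_death_workflow(
            cohort, events, deaths, "mafld", significant, dspec, run_log=log,
        )
        ddir = outdir / "death"
        ddir.mkdir(exist_ok=True)
        dres.cause_phewas.to_csv(ddir / "cause_phewas.tsv", sep="\t", index=False)
        for cause, parts in sorted(dres.per_cause.items()):
            cdir = ddir / cause
            cdir.mkdir(exist_ok=True)
            parts["disease_phewas"].to_csv(cdir / "phewas_results.tsv", sep="\t",
                                           index=False)
            parts["pairs"].to_csv(cdir / "pairs.tsv", sep="\t", index=False)
            graph_mod.export_graph(parts["graph"], cdir, stem="graph")
        artifacts["death"] = dres

    if config.run_genetic:
        gen = death_mod.genetic_exposure_cohort(participants, phenos)
        gen_matched = matching.match(
            gen,
            matching.MatchSpec(exposure="genetic_exposure",
                               covariates=tuple(config.covariates),
                               caliper=config.caliper, seed=config.seed),
        )
        gcohort = gen[gen["participant_id"].isin(set(gen_matched.matched_ids))]
        gres = phewas.run_phewas(
            gcohort, events, deaths, "genetic_exposure", outcomes,
            alpha=config.alpha, n_categories=n_categories, run_log=log,
        )
        gdir = outdir / "genetic"
        gdir.mkdir(exist_ok=True)
        gres.to_csv(gdir / "phewas_results.tsv", sep="\t", index=False)
        gsig = sorted(gres.loc[gres["significant"], "outcome"])
        g_exposed = gcohort.loc[gcohort["genetic_exposure"] == 1, "participant_id"]
        gpairs = pairs.run_pair_inference(
            events, g_exposed, gsig, n_exposed=len(g_exposed),
            alpha=config.alpha, fraction=config.pair_fraction, run_log=log,
        )
        gpairs.to_csv(gdir / "pairs.tsv", sep="\t", index=False)
        gg = graph_mod.transitive_prune(
            graph_mod.assemble_graph(gres, pairs.select_pairs(gpairs))
        )
        graph_mod.export_graph(gg, gdir, stem="graph")
        artifacts["genetic"] = {"phewas": gres, "pairs": gpairs, "graph": gg}

    log.log("pipeline", "end", n_significant=len(significant),
            n_confirmed_pairs=int(len(confirmed)))
    return artifacts
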