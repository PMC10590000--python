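# mafld-traj

Temporal disease- and death-trajectory analysis for MAFLD-style cohorts,
built as a reusable, tested pipeline:

1. **Taxonomy** (`mafld_traj.taxonomy`) — collapse 3-character ICD-10
   diagnosis codes into combined disease categories (first occurrence per
   participant kept, pregnancy/symptom chapters excluded), and group
   cause-of-death codes into a 16-category chapter scheme.
2. **Phenotyping** (`mafld_traj.phenotyping`) — fatty liver index (FLI,
   steatosis at ≥ 60), NAFLD fibrosis score (advanced fibrosis above
   −1.455), MAFLD classification (steatosis plus T2D / BMI ≥ 25 / ≥ 2
   metabolic abnormalities), normalized 4-SNP polygenic risk score with
   tertiles, and subgroup flags (overweight, sex-specific heavy drinking).
3. **Matching** (`mafld_traj.matching`) — 1:1 propensity-score matching on
   age, sex and deprivation index (logistic propensity, greedy nearest
   neighbour without replacement, exact on sex, optional caliper), with
   standardized-mean-difference balance reporting.
4. **PheWAS** (`mafld_traj.phewas`) — per-outcome subcohorts excluding
   prevalent cases, an incidence filter (> 1% of exposed by default), Cox
   proportional-hazards regression of the exposure flag, and Bonferroni
   selection (HR > 1 and p < α/n).
5. **Pair inference** (`mafld_traj.pairs`) — all n(n−1) ordered pairs of
   significant categories, a > 0.5% co-occurrence filter, an exact one-sided
   binomial test of temporal direction (ties excluded), and a univariate
   logistic confirmation (OR > 1).
6. **Trajectory graph** (`mafld_traj.graph`) — assembly of confirmed pairs
   into an annotated directed network, transitive-edge pruning that
   preserves reachability (cycle edges exempted and reported), node layering
   (original / intermediary / terminal), and GraphML/JSON/TSV export.
7. **Death & genetic workflows** (`mafld_traj.death`) — cause-of-death
   PheWAS, decedent-vs-survivor matching within the exposed group,
   disease→death association, per-cause pair inference and per-cause graphs;
   plus a variant using the highest-vs-lowest PRS tertile as the exposure.
8. **Synthetic cohorts** (`mafld_traj.synthetic`) — a seeded generator
   emitting participants/diagnoses/deaths tables with a latent steatosis
   process driving the FLI inputs, planted per-category exposure hazard
   ratios, directed D1→D2 hazard amplification, and cause-specific death
   hazards, together with the ground truth needed for recovery tests.

## CLI

```bash
# full run from a config file (see below)
mafld-traj run-all --config config.yaml --seed 1 --outdir output

# variants and filters
mafld-traj run-all --config config.yaml --death --genetic
mafld-traj run-all --config config.yaml --subgroup "sex == 'female'" --sensitivity

# individual stages
mafld-traj simulate --config config.yaml
mafld-traj phenotype --config config.yaml
mafld-traj match --config config.yaml
```

A minimal config for a synthetic run:

```yaml
outdir: output
seed: 1
simulation:
  n_participants: 2000
  disease_catalog: {D10: 0.02, D11: 0.03, D12: 0.02}
  exposure_hr: {D10: 3.0}
  pair_amplification: [[D10, D11, 4.0]]
  death_cause_hazards:
    I64: {rate: 0.004, disease_multipliers: {D10: 3.0}}
```

To analyse real tables instead, set `participants`, `diagnoses`, `deaths`
and `mapping` to CSV/TSV paths (`participants.csv` columns: id, age, sex,
townsend, anthropometrics, lipid/liver/glycaemic biomarkers, blood pressure
and medication/diabetes flags, alcohol, four SNP dosage columns, assessment
and censor dates; `diagnoses.csv`: participant_id, icd10_code, date;
`deaths.csv`: participant_id, date, semicolon-joined cause_codes). The
ICD-10 mapping file is tab-separated with columns
`icd10_code, combined_code, description`; small built-in defaults ship with
the package for testing.

Outputs per run: `phenotypes.csv`, `matched_pairs.csv`,
`balance_report.tsv`, `phewas_results.tsv`, `pairs.tsv`, `graph.graphml`,
`graph.json`, `graph_nodes.tsv`, `graph_edges.tsv` (pruned shortcut edges
are kept and flagged, not discarded), and a timestamp-free JSON-lines
`run_log.jsonl` recording every threshold applied. Identical config + seed
reproduce byte-identical outputs.

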