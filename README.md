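# fibronet

Network-pharmacology inference for multi-compound herbal extracts: from a
curated compound library to a single prioritized protein target, with every
filtering rule explicit, tested, and reproducible.

The motivating use case is the lipophilic fraction of *Salvia miltiorrhiza*
(Danshen), a traditional herb used clinically against liver fibrosis. Such
extracts act through many compounds hitting many targets, so the analysis
expands a handful of compounds with documented anti-fibrotic activity
("seeds") into a larger set of structurally similar candidate actives,
predicts and filters their protein targets, asks which pathways those
targets crowd into, and finally triages the targets of the best-supported
pathway against curated literature directions to nominate one protein for
experimental validation.

## Method

1. **Similarity expansion (guilt-by-association).** Every compound is
   fingerprinted with ECFP4 (Morgan radius 2, 2048 bits). For fingerprints
   A and B the Tanimoto coefficient is `T(A,B) = |A∩B| / |A∪B|`. A non-seed
   compound becomes a *candidate active* iff `T > τ` (default τ = 0.5,
   strict) to at least one seed; the resulting seed-anchored graph is the
   activity network.
2. **Target profiles.** Per-compound target-prediction scores (probability
   scale, SwissTargetPrediction-style tables) are aggregated per target over
   the network compounds; a target is kept iff its mean score exceeds 0.1
   and at least 3 compounds support it.
3. **Enrichment.** Potential targets are tested against pathway/disease
   collections with the one-sided hypergeometric test
   `P(X ≥ k)` for overlap k (set size K, query n, background N), with
   Benjamini–Hochberg FDR per category; significant sets need FDR < 0.05
   and overlap ≥ 3. A second, evidence-based filter keeps only sets with
   > 10 potential targets, > 1 affinity-verified known target (Kd/IC50
   < 10 µM), and > 10 % of the overlap re-found as differential genes.
4. **Differential genes.** Two-group expression contrasts are called with a
   Welch t-test on log2(intensity + 1); a gene is differential iff p < 0.05
   and the linear fold change is ≥ 2 or ≤ 0.5 (inclusive).
5. **Triage.** Within the surviving pathway, each target's compound action
   (inhibition, from affinity records), transcriptome direction, and curated
   disease-link direction are combined through four ordered contradiction
   rules; retained targets are ranked by (mean score, supporting compounds)
   and the top one is selected.

A synthetic-data module generates every input with planted ground truth
(scaffold-clustered compound families, score tables, expression, gene sets),
so the full chain is testable end to end without any download.

## Worked example

```bash
fibronet generate --outdir demo --seed 17     # synthetic study + truth manifest
fibronet run --config demo/config.yaml --outdir demo_run
fibronet report --rundir demo_run
```

prints `selected target: TRG01` and writes `demo_run/report.md`, which for
this seed reads (abridged):

```
## Library
- 138 compounds (8 seeds); class counts: {'diterpenoid': 90, 'other': 22, 'steroid': 12, 'triterpenoid': 14}

## Activity network
- 80 nodes, 72 edges, 72 candidate compounds

## Potential targets
- 40 targets profiled, 12 pass the score/support filters

## Enrichment
- 30 sets tested, 1 significant, 1 kept after the evidence filter: ['PW_PLANTED']

## Triage
- verdicts: {'excluded_contradiction': 2, 'excluded_no_disease_link': 1, 'retained': 3, 'unassessed': 6}
- ranking: ['TRG01', 'TRG05', 'TRG03']
- **selected target: TRG01**
```

Reading: the 8 seed compounds pull all 72 planted family members (and no
unrelated decoy) into the network; the 12 planted true targets pass the
score/support filters exactly; the planted pathway survives both enrichment
filters; and the triage rules exclude the planted contradictions, leaving
the intended target ranked first. `demo/manifest.json` holds the planted
truth for comparison.

The package also ships a small curated worked example — the JAK/STAT
pathway slice of the Danshen analysis (19 member proteins, published
affinity records and treatment fold changes, and the disease-link table) —
under `fibronet.datasets`; the triage on it retains STAT3 and AKT2 and
selects STAT3. Single stages are available as library calls
(`fibronet.network.build_activity_network`, `fibronet.enrichment.enrich_sets`,
...) and via `fibronet net build` for the network stage alone.

## Layout

- `src/fibronet/library.py` — compound library I/O, canonicalization, dedup
- `src/fibronet/network.py` — fingerprints, Tanimoto, activity network, export
- `src/fibronet/profiles.py` — target-score aggregation and filtering
- `src/fibronet/enrichment.py` — hypergeometric ORA, BH-FDR, evidence filter
- `src/fibronet/evidence.py` — affinity records, differential-expression calling
- `src/fibronet/triage.py` — contradiction rules and ranking
- `src/fibronet/synth.py` — ground-truth generators
- `src/fibronet/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, and design choices
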