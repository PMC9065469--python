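# Methods

## Scope and model

`fibronet` implements a ligand-based network-pharmacology chain for
multi-compound extracts: similarity expansion from known actives,
consensus target filtering, evidence-filtered over-representation analysis,
and contradiction-aware target triage. The chain is deliberately modular —
each stage consumes and produces plain TSV/GMT/GraphML files — because in
practice the upstream resources (target-prediction services, annotation
databases, expression repositories) are consumed through exported tables,
not APIs.

## Similarity expansion

Structures are handled by RDKit. Canonical identity is RDKit's canonical
isomeric SMILES: stereochemistry is preserved and salts are not stripped,
the least surprising default for curated natural-product tables. Duplicate
structures merge keeping the first-seen identifier and the union of seed
flags, so a documented active never loses its status to a duplicate row.

Fingerprints are Morgan radius-2 hashed to 2048 bits, the standard ECFP4
realization; bit length is a free parameter (`fingerprint_bits`). The
Tanimoto threshold τ = 0.5 is applied strictly (`> τ`), so a compound at
exactly 0.5 is excluded; this matters only for boundary cases but is applied
consistently everywhere.

The expansion is *seed-centric*: a non-seed enters the network only through
an edge to a seed, and candidate–candidate edges are not created by default.
This is the one genuinely open structural choice in this design — the
published network descriptions of this kind are usually seed-centric, but
nothing forbids linking candidates to each other. It is therefore exposed
as a config switch (`include_candidate_edges`, default off). The candidate
*set* is provably invariant under the switch; only the edge count changes.

Degenerate case: two empty fingerprints make the Tanimoto formula 0/0. The
convention here is 1.0 (two featureless molecules are identically
featureless), logged as a warning. RDKit returns 0.0 for this case, so the
branch is handled before delegating.

## Target profiles

Prediction scores are aggregated as the arithmetic mean over the predicting
compounds *within the activity network* (seeds + candidates), not the whole
library — compounds that failed the similarity screen should not vote.
Filters: mean score strictly > 0.1, and support from ≥ 3 compounds ("more
than two"). Duplicate (compound, target) rows keep the maximum score;
targets are keyed by upper-cased gene symbol with no ortholog mapping.

## Enrichment and the evidence filter

The test is the one-sided hypergeometric upper tail (Fisher exact
enrichment): for a background of N genes containing K set members and a
query of n targets, `p = P(X ≥ k)` via `scipy.stats.hypergeom.sf`. The
background defaults to the union of all collection members and is
configurable; query genes outside the background are dropped (they cannot
have been drawn from the urn). Benjamini–Hochberg runs separately within
each category (pathway vs disease), since the two collections answer
different questions. Significance: FDR < 0.05 and overlap ≥ 3.

The second-stage evidence filter keeps a set iff its overlap has
(i) more than 10 potential targets, (ii) more than one affinity-verified
known target, and (iii) strictly more than 10 % of the overlap re-found as
differential genes — the fraction's denominator is the overlap size, i.e.
it measures how much of the predicted overlap is independently confirmed.
All three bounds are strict; tightening any of them can only shrink the
kept set (tested property).

## Evidence streams

Affinity records count as verified only for Kd and IC50 strictly below
10 µM; Ki/EC50 rows are not credited, mirroring the credibility rule of the
motivating analysis. Records are treated as inhibition unless an explicit
action column says otherwise — every record in the bundled curated table is
an inhibitor, and affinity screens of natural products overwhelmingly
report inhibition.

Differential expression uses a Welch two-sample t-test on log2(x + 1),
unadjusted p < 0.05, plus an *inclusive* two-fold rule on the linear-scale
ratio of group means (≥ 2 or ≤ 0.5). Inclusivity at exactly 2.0 is forced
by the curated example, which counts a gene at fold change 2.0 as
differential. A moderated statistic (limma-style) would be more powerful at
n = 3, but the rule being reproduced is a plain per-gene p-value; the test
choice is isolated in one function and is straightforward to swap. Genes
with zero variance in both groups and equal means get p = 1 (no evidence of
change). At n = 3 per group the Welch correction is conservative: the
observed null p < 0.05 rate is ≈ 0.035–0.04 rather than 0.05, which the
acceptance band (0.05 ± 0.02) accommodates.

## Triage rules

The published exclusion narrative is formalized as four ordered rules over
(compound action, transcriptome direction, desired modulation):

1. evidence but no curated disease link → excluded (unassessable);
2. compounds inhibit a target whose activation is beneficial → contradiction;
3. inhibition beneficial + compounds inhibit + treatment up-regulates →
   contradiction between the two evidence streams;
4. inhibition beneficial + up-regulation with no binding evidence →
   contradiction (transcriptome moves opposite to the needed direction).

Rule 4 is the declared interpretation of the tersest published exclusion
("contradictory compound–target–disease interactions" for targets with only
up-regulation evidence); it is the only rule that rests on interpretation
rather than an explicit statement. Candidates with no evidence at all are
*not* pushed through the rules: with a known disease link they are retained
by default, otherwise they form a separate "unassessed" bucket and are
never ranked — matching how proteins without compound-level evidence are
reported rather than triaged.

Ranking of retained targets: mean prediction score descending, then
supporting-compound count, then symbol (deterministic tiebreak).

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the study inputs with known
truth:

- **Library** (default 138 compounds, 8 seeds): 8 scaffold families of 10
  plus 58 unrelated singletons. Scaffolds are branched C/N/O/S backbones
  (16–22 heavy atoms) with halogen/carbonyl decorations; family members
  differ by short terminal tails. The separation contract — within-family
  Tanimoto ≥ 0.6, cross-family ≤ 0.3 under the real fingerprints — is
  *verified*, and violating scaffolds are resampled (retry cap 80, fatal
  afterwards). Under that contract, recovery at τ = 0.5 is exact by
  construction of the thresholds, which is the point: the network stage is
  tested against a knowable answer.
- **Predictions** (default 40 targets, 12 true): true targets score
  U(0.12, 0.60) over ≥ 4 network compounds, decoys U(0, 0.09) over ≤ 2, so
  the score/support filters recover the true set exactly. One designated
  target gets the top score regime, giving the pipeline a unique intended
  answer.
- **Expression** (default 2000 genes, 3 vs 3): log-normal intensities
  (log2 means U(6, 10), noise sd 0.25), planted shifts of 4-fold (0.25 for
  down) for power at n = 3.
- **Annotation sets** (default 30): one planted pathway containing all true
  targets (hence > 10 overlap, ≥ 2 affinity-backed, > 10 % differential),
  the rest random draws from a non-target universe.

Not emulated: real natural-product chemistry (ring-system families,
stereocenters), realistic score correlations between similar compounds,
expression covariance and batch structure, and overlapping/nested pathway
collections. Passing tests therefore demonstrate that the *rules and
plumbing* are correct under conditions where the right answer is knowable —
not that the method's biological conclusions transfer to any particular
real dataset.

## Numerical and operational choices

- All randomness flows through one `numpy.random.default_rng` seed per
  generator; identical seeds give byte-identical files.
- Summary JSON floats are rounded to 6 decimal places before serialization
  for cross-platform stability; exported edge similarities print at 4 dp.
- Unknown config keys and out-of-range thresholds are fatal at load time,
  naming the key.
- Problem sizes in the test-suite and acceptance script (2000-gene
  expression replicates, 30 null replicates, 20 end-to-end seeds,
  brute-force urns to N ≤ 12) were chosen to estimate each checked quantity
  comfortably within its tolerance; the full suite runs in seconds.

## Known limitations

- The published compound structures behind the original 71-node network are
  not distributed with the package, so the network stage is validated on
  the synthetic emulation and structural invariants, not on the original
  node/edge counts.
- Symbol-keyed target identity ignores species and isoform subtleties.
- The hypergeometric background is only as good as the supplied collection;
  a biased GMT biases every p-value.
- The DE caller's unadjusted p-values are faithful to the reproduced
  rule but anticonservative across many contrasts; interpret the DE
  stream as corroborating evidence, not discovery.
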