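# gutcomm

Co-occurrence community analysis of infant gut microbiome count data, as a
tested, reusable pipeline:

1. **preprocess** — OTU filtering (≥50 reads in ≥10 samples), genus
   aggregation from Greengenes-style lineages, rare-genus exclusion
   (<0.01 % of total reads), and per-child selection of the stool sample
   closest to age 6 months within a 3–9 month window.
2. **network** — compositionality-corrected Spearman co-occurrence network
   (ReBoot scheme: permutation null with per-sample renormalization vs a
   sample bootstrap, two-sided z test); edges require p < 0.05 and
   ρ > 0.4; the largest connected component is retained.
3. **stability** — Markov-stability community detection (exact matrix
   exponential, generalized Louvain optimizer) with the community number
   chosen as the k > 2 holding the longest plateau over Markov time.
4. **stratify** — per-community subject stratification: UniFrac distances
   (weighted-normalized default, unweighted available), deterministic PAM
   (BUILD + SWAP with a double-swap escape), Calinski–Harabasz selection
   of the cluster number, classical-scaling (PCoA) coordinates.
5. **associations** — diet covariates (breast-feeding status,
   food-complexity score >3 vs ≤3), Fisher exact tests, per-community
   taxon enrichment, Kaplan–Meier curves, two-group proportional-hazards
   hazard ratios with log-rank tests, rank-sum abundance comparisons, and
   per-age-bin abundance trajectories.
6. **butyrate** — per-sample but/buk pathway ratio from a KO table
   (but = K01034 + K01035, buk = K00634 + K00929) and its group comparison.
7. **synthetic** — a generator for all pipeline inputs (counts with planted
   co-varying genus communities, subject metadata with a planted high-risk
   subgroup, genus tree, KO table) plus ground-truth labels for recovery
   testing.
8. **pipeline / cli** — end-to-end orchestration with a single seeded
   config and a JSON report.

Ages are stored in days throughout (6 months = 183 days, window
[91, 275] days inclusive).

## CLI

```sh
gutcomm simulate --out sim/ --seed 7            # write a synthetic bundle
gutcomm pipeline --counts sim/counts.tsv --metadata sim/metadata.csv \
    --tree sim/tree.nwk --ko sim/ko.tsv --out run/ --seed 7
```

`run/report.json` then contains the network summary, the community
assignment and stability curve, per-community clusterings with PCoA
coordinates, all association tests, a flagged risk subgroup, and the
but/buk comparison. `run/config.resolved.yaml` records every threshold and
seed; re-running with the same config reproduces the report byte for byte.
Individual stages are also exposed (`preprocess`, `network`, `communities`,
`stratify`, `butyrate`); see `gutcomm --help`.

All artifacts are plain text: count/KO tables are TSV, metadata is CSV,
trees are newick, reports are JSON.

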