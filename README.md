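# stressrec

Temporal multi-omics analysis of drug-induced stress buildup and recovery in
cancer cells, plus gene-expression signatures of CRISPR dependency.

## The problem

When tumor cells survive a pulse of a cytotoxic drug — the motivating case is
a proteasome-inhibitor pulse in multiple myeloma cells — they spend days
resolving the induced stress. Profiling the transcriptome, proteome and
metabolome at baseline and on days 1, 2, 4, 6, 8 and 10 after the pulse gives
feature-by-sample matrices whose temporal structure encodes the phases of
stress buildup and resolution. `stressrec` implements the computational side
of such a study as a tested, reusable pipeline:

1. **Deregulation calling.** Each omic layer is log-normalized (transcripts:
   `log2(CPM + 0.5)`; intensities: per-sample median-centered `log2`) and each
   post-baseline day is contrasted against day 0 with a moderated t statistic:
   the pooled per-feature variance s² (df *d*) is shrunk toward a prior
   (d₀, s₀²) fitted across features by matching the moments of log s² (a
   trigamma-inverse fit), giving s̃² = (d₀s₀² + d·s²)/(d₀ + d) and
   t = log2FC / (s̃·√(1/n₁+1/n₂)) on d₀ + d df. P values are
   Benjamini–Hochberg adjusted per omic per day; a feature is called
   deregulated at q ≤ 0.05, with the additional |log2FC| ≥ 1 cutoff for
   transcripts.
2. **Temporal similarity network.** The z-scored day-course of every
   deregulated transcript defines a correlation similarity
   s_ij; the graph is the union of the minimum spanning tree of the distance
   d_ij = √(2(1−s_ij)) with each node's k nearest neighbours (k = 5), so it
   is connected by construction.
3. **Multiscale Markov Stability clustering.** The partition quality at
   Markov time t is r(t,H) = trace[Hᵀ(Π e^{−tL} − ππᵀ)H] with
   L = I − D⁻¹A and π = d/2m; its linearization
   r_lin(t,H) = (1−t) + t·Σ_c W_c/2m − Σ_c π_c² equals Newman–Girvan
   modularity at t = 1 and is optimized with a Louvain-style greedy
   algorithm (restarts + node-level refinement) as a generalized modularity
   with resolution 1/t. Partitions are scanned over a log-spaced grid of
   Markov times and the partition at the centre of the longest plateau with
   constant cluster count and near-zero restart variation of information is
   selected.
4. **Single-sample enrichment.** A rank-based KS running-sum score per gene
   set per sample, scaled per set to [−1, 1] across samples.
5. **Exchange rates.** Metabolite consumption (negative) and release
   (positive) rates from supernatant concentrations and viable-cell
   densities: rate = ΔC·V / ∫N dt, in nmol per 10⁶ cells per hour.
6. **Dependency signatures.** From a CRISPR essentiality screen, the most
   dependent cell lines and a tissue-matched least-dependent group define a
   directional expression signature (moderated t + BH, top-|t| genes); the
   signature is projected onto tumor transcriptomes, and a tumor is
   classified dependent when more than 80% of signature genes agree in
   z-score sign with the signature direction.

A first-class synthetic-data generator (`stressrec.synthetic`) emulates the
study design with known ground truth — planted temporal archetypes,
negative-binomial counts, lagged/attenuated protein coupling, a ~50%
viable-cell dip at day 2, a lactate consumption-to-release flip peaking at
day 4, and dependency cohorts with planted signatures — so every stage is
testable without external downloads.

## Worked example

```python
from stressrec import differential, network, stability
from stressrec.synthetic import SyntheticStudyConfig, simulate_timecourse_study

cfg = SyntheticStudyConfig(n_transcripts=600, n_proteins=600, seed=0)
study = simulate_timecourse_study(cfg)

table = differential.differential_table(study.transcripts)
print(differential.deregulation_counts(table).to_string(index=False))

called = network.deregulated_features(table)
profiles = network.standardize_profiles(table, feature_subset=called)
graph = network.similarity_graph(profiles, k=5)
scan = stability.scan_markov_times(graph, n_restarts=20, seed=0)
partition, info = stability.select_robust_partition(scan)
print(f"selected {partition.n_clusters} clusters at Markov time t={info['t']:.2f}")
```

prints

```
 day  up  down  total
   1  27    19     46
   2  23    15     38
   4  25     0     25
   6  40    13     53
   8  23    15     38
  10  29     0     29
selected 6 clusters at Markov time t=3.39
```

The per-day table counts transcripts called deregulated vs day 0 (46 of 600
at day 1 under the default ~15%-responsive conditions); the scan recovers
the six planted temporal archetypes as six clusters on a wide robust plateau
of Markov times. On the same study,
`differential.crossomics_fc_correlation(tx_table, prot_table, day=2)`
returns r = 0.630 over the 39 features called in either layer at day 2 —
the moderate positive mRNA–protein coupling the generator plants.

A CLI wraps the two workflows:

```bash
stressrec simulate --seed 3 --out sim/
stressrec recovery --transcripts sim/transcript.tsv \
    --transcript-samples sim/transcript_samples.csv --out results/
stressrec dependency --simulate-cohort --seed 1 --out dep/
```

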