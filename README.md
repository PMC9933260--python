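# methentropy

Age-related DNA methylation drift is stochastic: individual CpG sites gain or
lose methylation as tissues age, most prominently at CpG islands, and the
*heterogeneity* of methylation patterns across alleles grows with every stem
cell division. `methentropy` quantifies that disorder from read-level
bisulfite data (RRBS-style epireads) and tests the hypothesis that it is
driven by stem-cell replication. It is aimed at epigenomics researchers who
have per-read CpG methylation calls and per-CpG count tables and want
entropy, drift and enrichment statistics without reinventing them.

## What it computes

**Epiallele entropy.** An epiallele locus is a group of 4 CpGs within 60 bp
covered by ≥ 40 reads that each call all four positions. Each read collapses
to its number of methylated CpGs, giving a 5-category frequency vector
P(ℓ), ℓ ∈ {0,…,4}. A locus's disorder in a sample is its Jensen-Shannon
distance from a reference distribution Q built from young samples:

    JSD(P, Q) = sqrt( (D(P, M) + D(Q, M)) / 2 ),   M = (P + Q)/2,
    D(P, M)   = Σ_ℓ P(ℓ) log2( P(ℓ) / M(ℓ) ).

JSD is a metric on [0, 1]: 0 iff the distributions coincide, 1 iff their
supports are disjoint. Unlike Shannon entropy — which scores fully
methylated and fully unmethylated loci identically at 0 bits — JSD is
sensitive to the direction of change. Group-level statistics include the
fold change of mean JSD with age, (mean_old − mean_young)/mean_young,
Brown–Forsythe variance-shift tests with Bonferroni correction, and the
Pearson correlation of fold change with 30-day tissue turnover rates
(30 × the per-day cell turnover fraction).

**Per-CpG drift.** Coverage filtering (≥ 20 reads in ≥ 75% of samples),
two-condition differential methylation (pooled-count chi-square with Yates
correction, Benjamini–Hochberg q-values, |Δ| > 5 percentage points and
q < 0.05 to call a site), a permutation test of the Spearman correlation of
percent methylation with age (1000 label shuffles, empirical p = r/n,
|ρ| ≥ 0.5 and p < 0.05 to call a site), Fisher's-exact odds ratios of
significant sites per genomic compartment (Promoter-CpGi, nonPromoter-CpGi,
Promoter-nonCpGi, nonPromoter-nonCpGi), and promoter-methylation /
expression linkage.

**Simulator.** A forward model of replication-coupled drift: every CpG on
every allele is a two-state Markov chain with per-division error rates
ε_gain and ε_loss, run for `divisions_per_month × age` divisions, with
differentiated cells receiving a few extra divisions. Mean methylation obeys
the closed form m_t = m_∞ + (m_0 − m_∞)(1 − ε_g − ε_l)^t with
m_∞ = ε_g/(ε_g + ε_l), which the tests verify. The simulator writes
epiread and Bismark-coverage files, so every analysis stage can be exercised
— and its parameter recovery checked — without sequencing data.

## Worked example

Simulate three tissues with very different stem-cell division rates (colon
10/month, lung 1/month, heart 0.1/month), four replicate mice per age at 4
and 24 months, then measure entropy change and its relation to turnover:

```python
import pandas as pd
import methentropy as me

cfg = me.SimulationConfig(
    n_loci=80, n_cells=300, coverage_mean=60, seed=7,
    divisions_per_month={"colon": 10.0, "lung": 1.0, "heart": 0.1},
)
rows = [
    (f"{t}_{int(a)}m_r{k}", t, a, "stem", 1)
    for t in ("colon", "lung", "heart") for a in (4.0, 24.0) for k in range(4)
]
design = me.SampleSheet(pd.DataFrame(
    rows, columns=["sample_id", "tissue", "age_months", "cell_type", "pool_size"]))
manifest = me.simulate_study(cfg, design, "example")

reads = {s: me.read_epireads(v["epireads"]) for s, v in manifest["samples"].items()}
dists = me.extract_distributions(reads, min_coverage=40, max_span_bp=60)
refs = me.build_reference(dists, design, reference_age=4.0)
records = me.jsd_records(dists, refs, design)
fcs = me.jsd_fold_change(records, design, old_age=24.0, young_age=4.0)
for fc in fcs:
    print(f"{fc.tissue:6s} mean JSD young={fc.mean_jsd_young:.3f} "
          f"old={fc.mean_jsd_old:.3f} fold change={fc.fold_change:.2f}")

turnover = me.TurnoverTable(pd.DataFrame(
    {"organ": ["colon", "lung", "heart"], "per_day_turnover": [0.050, 0.005, 0.0005]}))
r, p, _ = me.correlate_turnover(fcs, turnover)
print(f"fold change vs 30-day turnover: Pearson r={r:.2f} (p={p:.3f})")
```

Output:

```
colon  mean JSD young=0.084 old=0.235 fold change=1.81
heart  mean JSD young=0.083 old=0.119 fold change=0.44
lung   mean JSD young=0.078 old=0.119 fold change=0.53
fold change vs 30-day turnover: Pearson r=1.00 (p=0.013)
```

The highly proliferative colon nearly triples its mean epiallele JSD between
4 and 24 months while the nearly quiescent heart barely moves; across the
three tissues the fold change tracks the 30-day turnover rate. The young
means are nonzero because finite read sampling keeps every sample a small
distance from the averaged reference.

The same stages are available from the shell — `methentropy simulate`,
`extract-epialleles`, `jsd`, `fold-change`, `turnover-corr`, `dm`,
`permute`, `compartments`, `report`, and `run` for the whole pipeline from
one YAML config. See `methentropy --help`.

## Layout

- `src/methentropy/io.py` — formats: Bismark coverage, epiread TSV, BED,
  sample sheet, turnover and expression tables; validated containers.
- `src/methentropy/epialleles.py` — locus extraction and 5-category
  distributions.
- `src/methentropy/entropy.py` — JSD, Shannon entropy, references, fold
  change, variance and turnover statistics.
- `src/methentropy/drift.py` — per-CpG filtering, differential methylation,
  permutation testing, compartments, expression linkage.
- `src/methentropy/simulate.py` — the replication-drift simulator.
- `src/methentropy/pipeline.py`, `cli.py` — orchestration and the CLI.
- `docs/methods.md` — the model, its assumptions, parameter choices and
  limitations.
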