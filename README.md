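# amfgen

Tools for asking how exotic-plant dominance reshapes the arbuscular
mycorrhizal fungal (AMF) communities in plant roots: an amplicon
read-processing pipeline, iterated-rarefaction diversity, a partner
generalism statistic, AIC-based mixed-model selection, and a synthetic
mesocosm-experiment generator that ties them together.

## The scientific problem

AMF are obligate root symbionts that trade soil nutrients for plant
carbon. When exotic plants come to dominate a community, the fungal
partners available to all residents can change — the "degraded
mutualisms" hypothesis predicts fewer, and more generalist, fungal
partners. Testing this requires an experiment that *varies invasion
extent*: here, 20 eight-species plant communities spanning 0–100%
planted exotic proportion, replicated eight times (160 mesocosms) with
crossed soil-origin and herbivore treatments, with AMF communities read
out by amplicon sequencing of individual root samples.

`amfgen` implements that analysis end to end for anyone working with
plant–AMF amplicon data:

1. **Read pipeline** (`amfgen.filtering`, `amfgen.pipeline`) — reads
   shorter than 170 bp or with more than one expected error
   (EE = Σ 10^(−Q/10)) are removed; exact dereplication with per-sample
   provenance; unique sequences seen fewer than three times in the whole
   dataset are discarded; greedy abundance-sorted centroid clustering at
   97% global pairwise identity yields OTUs.
2. **Table construction** (`amfgen.otu_table`) — OTUs are kept only with
   a reference hit of ≥ 200 bp and ≥ 90% identity; negative-control
   counts are subtracted OTU-wise from every sample (floored at zero);
   samples under 1000 reads are dropped; analysis restricted to
   mycorrhizal host species.
3. **Diversity** (`amfgen.diversity`) — richness under random
   rarefaction without replacement, iterated (default 500×) at the
   minimum unit depth; per sample (alpha) and per mesocosm after count
   aggregation (gamma). The estimator is validated against the
   hypergeometric closed form E[S] = Σⱼ (1 − C(N−Nⱼ, n)/C(N, n)).
4. **Generalism** (`amfgen.generalism`) — for each OTU *k*, reads are
   pooled by plant species across the experiment; with species shares
   p_i, D_k = exp(−Σ p_i ln p_i) is the Hill q=1 "effective number of
   plant partners". Each mesocosm's weighted generalism score is
   (Σ_k a_k·D_k) / richness-at-harvest, with a_k the OTU's local read
   share.
5. **Models** (`amfgen.models`) — all-subsets enumeration of fixed
   effects under marginality, Gaussian LMMs fit by ML (statsmodels
   MixedLM; crossed random intercepts for plant species and mesocosm
   nested in community), zero-inflated beta regression for proportional
   responses, and the selection rule: most parsimonious model within
   delta-AIC < 2 of the best.
6. **Synthetic experiments** (`amfgen.simulate`) — Dirichlet-multinomial
   counts over a generalist/specialist OTU pool with right-skewed
   abundances, plant mortality, and tunable exotic-dominance effects on
   richness and generalism; plus a FASTQ renderer with known spiked
   artifacts and contamination for exact truth-recovery testing.

## Worked example

```python
import numpy as np
from amfgen import (SimConfig, simulate_experiment, partner_diversity,
                    weighted_generalism, mean_rarefied_richness)
from amfgen.workflows import prepare_analysis_table

meta, table, truth = simulate_experiment(SimConfig(), seed=42)
tab = prepare_analysis_table(table, meta)   # depth >= 1000, AMF hosts only
alpha = mean_rarefied_richness(tab, iterations=500, seed=42)
profiles = partner_diversity(tab, meta)
scores = weighted_generalism(tab, meta, profiles)
```

Running the numbered drivers reproduces the full analysis narrative
(`python analysis/01_simulate_experiment.py`, then 02–05). With the
seeds committed in the drivers this prints, among other things:

```
n_mesocosms: 160          n_plants_sampled: 953
top2_otu_read_share_pct: 48.4
alpha richness: 9.44 at 0% exotic  ->  7.23 at 100% exotic (depth 1125, 500 iterations)
gamma richness: 24.60 at 0%        -> 19.93 at 100%
truth_table_recovered_exactly: True
[richness]   selected richness ~ prop_exotic_planted + provenance + prop_exotic_planted:provenance
[generalism] selected generalism ~ prop_exotic_planted + root_diameter
```

i.e. per-plant and community-level fungal richness fall with exotic
dominance, the weighted generalism score rises, and the selection rule
retains the exotic-proportion term — the qualitative behaviour the
package's statistics are designed to detect. Tables land under
`results/`.

The command-line entry point mirrors the library
(`amfgen filter | cluster | table | diversity | generalism | fit | simulate`);
see `amfgen --help`.

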