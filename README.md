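# msatpop

Microsatellite population genetics and demographic inference in Python:
diversity and Weir–Cockerham F-statistics, Hardy–Weinberg and linkage
permutation tests, Brookfield null-allele estimation, Ohta's LD variance
decomposition, LD-based effective population size, distance/tree/AMOVA/IBD
structure analyses, maximum-likelihood mixture clustering with
KIC model selection and hybrid-class detection, a generalised-stepwise-
mutation (GSM) coalescent simulator, and Approximate Bayesian Computation
(ABC) model choice — plus synthetic-data generators with known truth so the
whole pipeline is testable end to end without external data.

## Layout

| module | contents |
|---|---|
| `msatpop.io` | genotype-table / GenePop reading and writing, dataset summaries |
| `msatpop.stats` | allele frequencies, diversity, rarefied richness, F-statistics, HWE Monte-Carlo tests, null alleles |
| `msatpop.linkage` | EM likelihood-ratio LD tests, Ohta D-statistics, LD-based Ne |
| `msatpop.structure` | pairwise FST, chord distances, neighbour joining, AMOVA, Mantel/IBD, EM clustering + KIC, hybrid classification, DAPC, FCA |
| `msatpop.coalescent` | multi-population coalescent with GSM + single-nucleotide-indel mutation, declarative demographic scenarios with priors |
| `msatpop.abc` | summary statistics, reference tables, rejection + LDA + weighted multinomial-logistic model choice, local-linear parameter posteriors |
| `msatpop.synth` | island worlds, hybrid panels, domesticated bottleneck strains, and a study-scale 150-population world with known truth |
| `msatpop.cli` | `msatpop` command-line pipeline with seeded, reproducible stages |

## Quick start

```python
from msatpop import synth, stats, structure

gm, truth = synth.make_global_fixture(seed=1)   # 150 pops, 2862 individuals
print(stats.wc_fstats(gm).fst)                  # overall theta ~ 0.24

best_k, table, models = structure.select_k(gm, range(1, 26), criterion="KIC",
                                           seed=1, n_restarts=3)
```

CLI:

```sh
msatpop simulate --kind island --demes 8 --n-per-deme 20 --seed 1 --out world.csv
msatpop stats world.csv --out stats_out
msatpop cluster world.csv --k-min 1 --k-max 10 --seed 1
msatpop amova world.csv --hierarchy population
msatpop ne world.csv
msatpop report --config config.json     # full seeded pipeline
```

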