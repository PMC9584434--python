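# oscnet

Inference of small **core oscillator** gene regulatory networks (GRNs)
from time-series expression data, for systems biologists studying
cell-cycle-, circadian- or other clock-like transcriptional programs.
Rather than claiming one "true" network, `oscnet` is a hypothesis-reduction
pipeline: it prunes the space of genes, then pairwise regulations, then
whole networks, and returns rankings that prioritize which genes to
perturb experimentally.

## The three stages

**Node finding.** Each gene g is scored by an amplitude p-value
p_reg(g) (fraction of resampled curves whose log-variability exceeds the
gene's) and a periodicity p-value p_per(g) (exact permutation tail of the
Kendall concordance between the trace and cosine templates, Bonferroni
corrected over the template grid).  The combined score

    score(g) = p_reg · p_per · [1 + (p_reg/0.001)²] · [1 + (p_per/0.001)²]

ranks genes ascending; the top of the list is enriched for core clock
components.

**Edge finding.** Every signed pair hypothesis "H regulates G" is a
five-parameter Hill model dG/dt = γ − βG + F(H) with
F = αHⁿ/(kⁿ+Hⁿ) (activation) or αkⁿ/(kⁿ+Hⁿ) (repression), fitted by
basin hopping and weighed by a Laplace-approximation evidence that
balances fit quality against robustness to parameter perturbation.
Per-target posteriors (*pld scores*) over all allowed single-edge models
produce the **local edge ranking**; replicates chain Bayes-style.

**Network finding.** Around the seed network (edges with pld above a
threshold) the sampler draws strongly connected candidate networks from
the top-ranked edges.  Each network's qualitative dynamics are enumerated
combinatorially: parameter space decomposes into finitely many regions,
each with a state transition graph whose stable strongly connected
components reveal oscillation.  The **oscillation score** is the fraction
of regions with a stable full cycle; the **pattern match score** is the
fraction of those whose cycle can reproduce the observed cyclic order of
expression maxima and minima (the data's extremum partial order at a
chosen noise level).  Top networks feed **edge prevalence**
P(i→j) = N(i→j)/T and the **global edge/node rankings**; comparing local
and global node participation flags which genes to pursue and which (for
example a spurious but rhythmic gene) to dismiss.

The package ships a fully self-contained benchmark: a six-gene Hill
oscillator (genes A–F, three stored parameterizations with disparate
dynamics, ≥4-fold amplitude for every gene) plus a sinusoidal decoy gene
G, used throughout the test-suite as ground truth.

## Worked example

```python
from oscnet import (parse_network, GROUND_TRUTH_NETWORK,
                    count_parameter_regions, oscillation_score,
                    simulate_ground_truth, periodic_data_graph,
                    score_network, fold_change_check)

net = parse_network(GROUND_TRUTH_NETWORK)
print("essential parameter regions:", count_parameter_regions(net, essential_only=True))

neg = parse_network("A : ~B\nB : A")
print("negative-loop oscillation score:", oscillation_score(neg))

ts = simulate_ground_truth(1)                      # benchmark dataset 1
print("min fold change, dataset 1:", round(fold_change_check(ts), 2))
dg = periodic_data_graph(ts, epsilon=0.0)          # one period of extrema
print("events in one period:", dg.n_events)
scores = score_network(net, {"column1": dg})
print("oscillation score:", scores.oscillation_score)
print("pattern match score:", round(scores.pattern_match_score, 3))
```

prints

```
essential parameter regions: 2016
negative-loop oscillation score: 1.0
min fold change, dataset 1: 7.3
events in one period: 12
oscillation score: 1.0
pattern match score: 0.199
```

The six-gene network admits 2016 essential qualitative parameterizations,
every one of which supports a stable oscillation (score 1.0); a two-gene
negative feedback loop is likewise a perfect combinatorial oscillator.
Dataset 1 swings at least 7.3-fold peak-to-trough for every gene and
contributes 12 extremum events per period; 19.9% of the network's
parameter regions reproduce that cyclic event order exactly under the
strict event-localization convention documented in `docs/methods.md`.

## Command line

```
oscnet simulate --out-dir data            # write the benchmark datasets
oscnet edges data/column1.tsv --seed 1 --out-dir out
oscnet networks data/column1.tsv --seed 1 --out-dir out
oscnet all data/column1.tsv --config cfg.json --seed 1 --out-dir out
```

Outputs are TSV ranking tables (`item, score, rank`), a per-network score
table and the local-versus-global node comparison used for experimental
prioritization.

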