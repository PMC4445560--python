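# dloopabc

Demographic inference for domesticated cattle (*Bos taurus*) mitochondrial
D-loop sequences: a serial-coalescent simulator for heterochronous (ancient +
modern) samples under a two-deme domestication/expansion model, rejection
approximate Bayesian computation (ABC) over a 32-element summary-statistic
vector, and the descriptive population-genetic and spatial analyses that
surround such a study — diversity indices, neutrality tests, pairwise F_ST
with permutation tests, Mantel tests of isolation by distance, and non-metric
MDS.

The package is aimed at population geneticists working with ancient mtDNA
who want a tested, reproducible re-implementation of this class of analysis,
plus a synthetic-data generator so every stage can be exercised without any
sequence downloads.

## The model

Backwards in time (t in generations BP, 6-year generations, present =
2000 CE):

* The Near Eastern/Anatolian deme has modern female effective size
  N_NE = 1,007,170 and shrinks exponentially back to the domestication
  bottleneck size **N_D** at T_dom = 1,750 generations BP (8,500 BCE);
  beyond that lies the ancestral wild aurochs pool, N_anc = 45,000.
* Europe is founded at T_split = 1,400 generations BP (6,400 BCE) by a
  proportion **P** of the Near Eastern deme and grows to a modern size
  N_E = 7,942,392.
* Migration between the demes is symmetric per lineage: rate **M_E**
  ("early") from the split until 5,000 BCE, and **M_L** ("late") from
  5,000 BCE to the present.
* mtDNA is haploid: a pair of lineages in a deme of size N coalesces at
  rate 1/N. Mutation is finite-sites at 45% per site per million years
  (2.7e-6 per site per generation) on 240 bp sequences.

The four free parameters carry uniform priors — N_D ~ U(1, 1000),
P ~ U(0, 1), M_E and M_L ~ U(0, 0.01) — and are estimated by plain
rejection ABC: simulate, compute the 32 summary statistics (K, Ĥ, π, S,
Tajima's D per sample group; Φ_ST and mean between-group differences per
group pair), standardize, retain the closest fraction, and summarize the
accepted sets with boundary-reflected KDEs (modes, HPD intervals).

## Worked example

Generate a pseudo-observed dataset at known parameters, then recover them:

```bash
dloopabc synth --params 100 0.7 0.002 0.0001 --scale 0.1 --seed 3 --outdir data
dloopabc simulate --metadata data/metadata.tsv --profile desk --seed 5 --outdir sims
dloopabc abc --table sims/simulations.tsv --fasta data/sequences.fasta \
             --metadata data/metadata.tsv --profile desk --outdir posterior
```

The `abc` step prints the marginal posterior summaries, e.g. (seed-dependent):

```
"N_D": { "mode": 63.6, "hpd_50": [21.4, 114.5], "hpd_95": [1.0, 315.8] }
"P":   { "mode": 1.0,  "hpd_95": [0.09, 1.0] }
```

meaning the bottleneck size N_D has its posterior mode near 64 females with
a wide 95% HPD interval containing the simulated truth (100), and the
founding proportion P is high but weakly identified at this reduced scale —
the expected behaviour for a 0.1x sample-size desk run. `dloopabc stats`
produces a per-group diversity table (n, haplotypes, Ĥ ± sd, π ± sd, S,
Tajima's D and Fu's Fs with simulation-based p-values), and
`dloopabc mantel` / `dloopabc mds` run the spatial analyses on a pairwise
F_ST matrix.

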