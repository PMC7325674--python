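# phylosample

Supermatrix phylogenomics at desk scale: how much genome-scale data does a
phylogeny need before its topology stops changing, and what does that
phylogeny say about the ancestral lifestyle of the group?

The package implements a complete, self-contained pipeline of the kind used
to analyze hundreds of single-copy ortholog alignments across tens to
hundreds of fungal genomes:

1. **Alignment filtering and supermatrix construction** — strict gap-free
   conserved-block trimming (Gblocks-style) or a per-column gap-fraction
   ceiling (GUIDANCE-style), gene selection by length (> 1 kb) and taxon
   coverage, a greedy zero-missing-data reduction, and concatenation into a
   partitioned supermatrix (FASTA + RAxML-style partition file).
2. **Column-resampling convergence experiment** — at each sampling effort
   *e* (a fraction of supermatrix columns), 30 replicate matrices are drawn
   without replacement, a tree is inferred from each, and its normalized
   Robinson–Foulds distance to the full-supermatrix reference,
   RF/2(n−3), is recorded.  Per-effort distributions are compared by
   one-way ANOVA with Tukey, Bonferroni and Scheffé post hoc tests; the
   convergence effort is the smallest effort whose comparison with the next
   one is non-significant (α = 0.01) under all three procedures.
3. **Self-contained tree inference** — Jukes–Cantor distances with
   neighbor joining (deterministic, tie-broken by taxon label), and an
   optional NNI hill-climb under the JC likelihood.  Externally inferred
   trees are accepted as newick wherever a tree is an input.
4. **Ancestral lifestyle-state reconstruction** — a 10-state lifestyle
   character (lichenized, rock-inhabiting, plant pathogen, saprotroph,
   epiphyte, animal pathogen, fungal pathogen, ectomycorrhizal, endophyte,
   extremophile) analyzed at the basal node under the one-parameter Markov
   k-state model (Mk1), P<sub>ii</sub>(t) = 1/k + (k−1)/k·e<sup>−kβt</sup>,
   with the rate β fitted by maximum likelihood, plus Fitch/Sankoff
   parsimony.  States within 2.0 log-likelihood units of the best state form
   the reported best-state set.
5. **Synthetic data generation** — birth–death species trees, unlinked gene
   alignments under JC/HKY with heterogeneous lengths and per-taxon
   missingness (up to 90%), and Mk1-evolved discrete traits, so that every
   stage is testable without downloads, with known ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
genome-scale dataset (48 taxa, 200 genes, ~340 kb; heavy gene missingness
for four "poorly assembled" taxa):

```sh
python analysis/01_simulate_dataset.py
python analysis/02_filter_and_concatenate.py
python analysis/03_resampling_convergence.py
python analysis/04_ancestral_states.py
```

which prints (seed 1):

```
155/200 genes > 1000 bp after block filtering
supermatrix: 48 taxa x 307,350 columns (155 partitions)
effort  0.001: median nRF 0.3333  sd 0.0737
effort   0.01: median nRF 0.1111  sd 0.0646
effort    0.1: median nRF 0.0444  sd 0.0275
effort    0.2: median nRF 0.0556  sd 0.0307
effort    0.3: median nRF 0.0444  sd 0.0261
ANOVA: F=187.4, p=3.16e-56
convergence effort (all three post hoc agree): 0.1
Mk1 rate estimate: beta = 0.6100 (simulated at 0.5)
```

Reading: trees inferred from 0.1% of the columns sit far from the reference
(median normalized RF 0.33) with a wide spread; by a 10% effort the
distributions flatten out and the three post hoc procedures agree that
adding more columns no longer shifts the RF distribution — about a tenth of
this supermatrix already fixes the topology.  The Mk1 rate fitted from the
simulated lifestyle trait recovers the generating value within ~20%.

Every stage is also scriptable directly (`phylosample simulate | filter |
concat | resample | infer | compare | converge | outliers | asr`), e.g.:

```sh
phylosample resample --efforts 0.001,0.01,0.1,0.2,0.3 --replicates 30 \
    --seed 42 --engine nj --out-records records.tsv supermatrix.fasta \
    supermatrix.partitions
phylosample asr --tree tree.nwk --traits traits.tsv --outgroup T1 --threshold 2.0
```

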