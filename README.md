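# gednn — graph-embedded deep neural networks for genotype–phenotype classification

`gednn` implements a graph-embedded deep neural network (G-EDNN) for
classifying a binary phenotype (case/control) from SNP genotypes when the
number of variants far exceeds the number of samples. Instead of a fully
connected first layer, the SNP→gene weight matrix is masked by an
eQTL-derived bipartite adjacency `A` (a SNP connects only to genes whose
expression it is associated with, optionally augmented by positional cis
links), and the following gene→gene layer is masked by a PPI-derived
symmetric adjacency `A′` with unit diagonal:

    X₁ = δ(X₀ (W₀ ⊙ A)  + b₀)
    X₂ = δ(X₁ (W₁ ⊙ A′) + b₁)
    X₃ = δ(X₂ W₂ + b₂), …,  P(y | X₀) = softmax(Xₙ Wₙ + bₙ)

with ReLU activations, dropout, Adam, and cross-entropy plus an α-weighted
weight penalty. The Hadamard masks (`⊙`) give sparse connectivity that
encodes prior biology, prevents overfitting in the n ≪ p regime, and makes
the network interpretable: for every wired SNP–gene pair a **pathway score**

    PS(s, g) = |W₀ ⊙ A|[s, g] × (gene g's downstream influence on the disease output)

ranks SNP→gene→phenotype paths by learned importance. Three ablations are
built in for comparison on identical splits: a plain dense `dnn`, an
`e_dnn` masking only the SNP→gene layer, and a `gedfn` masking only the
gene→gene layer.

The package is aimed at statistical-genetics and systems-biology users who
have a genotype matrix, case/control labels, an eQTL SNP–gene pair list and
a PPI edge list (all plain delimited text), plus a synthetic-data generator
that plants causal SNP→gene→phenotype paths through jointly generated
eQTL/PPI structure, so the whole pipeline is testable without any external
download.

## Worked example

Simulate a coupled dataset (500 samples, 1000 SNPs, 100 genes, 20 planted
causal paths), preprocess it, build the masks, train the doubly masked
model, and rank pathways:

```bash
gednn simulate --out demo/ --seed 2
gednn preprocess --genotypes demo/genotypes.tsv --labels demo/labels.tsv --out demo/clean.tsv
gednn build-masks --genotypes demo/clean.tsv --eqtl demo/eqtl_pairs.tsv \
      --ppi demo/ppi_edges.tsv --out demo/masks.npz
gednn train --genotypes demo/clean.tsv --labels demo/clean_labels.tsv \
      --masks demo/masks.npz --mode gednn --seed 2 --out demo/model.npz
gednn pathways --model demo/model.npz --top 5 --out demo/ps.tsv
```

which prints

```
wrote dataset to demo
kept 995 SNPs x 500 samples -> demo/clean.tsv
A: (995, 100), A': (100, 100) -> demo/masks.npz
mode=gednn test AUC=0.7312 -> demo/model.npz
wrote top 5 pathways -> demo/ps.tsv
```

Preprocessing kept 995 of 1000 SNPs (missingness ≤ 20%, MAF > 0.05). The
held-out test AUC of 0.73 is typical for the default conditions (median
≈ 0.69 over 10 seeds; with a 50-sample test set, single runs scatter by
about ±0.07). The ranked table `demo/ps.tsv`:

```
rank	SNP	Gene	PS
1	rs378	g058	53.62859107195856
2	rs829	g086	50.06176114449044
3	rs695	g086	49.268116938279384
4	rs353	g036	48.64634242407818
5	rs280	g086	46.61725773624745
```

Each row is one SNP→gene→disease path; PS is the unnormalized product of
the learned SNP→gene weight magnitude and the gene's downstream influence,
so scores are comparable within a run. In this simulation 5 of the top 20
ranked pairs are planted causal paths, against 0.29 expected from a random
ranking of the 1374 wired pairs — a ~17× enrichment. Python users can drive
the same pipeline
through `gednn.simulate`, `gednn.run_preprocess`, `gednn.build_masks`,
`gednn.run_comparison`, `gednn.pathway_scores`; see `docs/methods.md` for
the model, parameter and generator details.

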