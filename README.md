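# osn-identity

Analysis toolkit for the population transcriptomic identity of olfactory
sensory neurons (OSNs). Every mature OSN expresses a single odorant
receptor (OR) gene, so the olfactory epithelium is a natural collection of
hundreds of genetically indexed neuronal subpopulations. This package
implements the statistics needed to ask two questions about them:

1. **Do neurons expressing the same receptor share a transcriptomic
   identity, and what predicts it?** Pairwise Euclidean distances in PC
   space are split into *intra*- and *inter*-population sets and compared
   by Cohen's d, `d = (x̄_intra − x̄_inter)/s_pooled`, against a label-
   permutation null (1000 permutations) and a two-sample Kolmogorov–Smirnov
   test. Population centroid distances are then joined with two other
   distance worlds — genomic distance between OR gene start codons (with OR
   gene clusters detected by Jenks natural breaks, k = 3, threshold =
   intra-cluster mean + 3·SD) and the Miyata amino-acid replacement
   distance between receptor proteins — to test whether transcriptomic
   proximity follows shared genomic neighbourhood or receptor sequence
   similarity (binned Spearman correlations, four-way near/far ×
   similar/dissimilar Wilcoxon comparisons, enhancer-set contrasts).

2. **Is odorant-evoked modulation transcriptional?** Bulk counts of sorted
   populations are normalized by median-of-ratios size factors, tested by a
   simplified negative-binomial Wald test against the null |log₂FC| ≤ 0.5
   with Benjamini–Hochberg adjustment, and dissected by exon–intron split
   analysis (EISA): a gene whose exonic *and* intronic reads move together
   is transcriptionally modulated; exon-only changes point to mRNA
   stability.

A synthetic-data module generates OR families (duplication trees with
cis-duplication confounding sequence similarity and genomic proximity),
single-cell UMI matrices whose population expression programs can be
coupled to receptor sequence similarity with tunable strength, and bulk
exon/transcript count tables with known modulation classes — providing
ground truth for every stage. See `docs/methods.md` for models,
parameters, and limitations.

## Worked example

```python
from osn_identity import (
    ORFamilySpec, OSNSimSpec, simulate_or_family, simulate_osn_counts,
    PopulationDistance, log_normalize, pca_embed,
)

family = simulate_or_family(ORFamilySpec(n_receptors=60, alignment_length=150, seed=0))
cells = simulate_osn_counts(family, OSNSimSpec(n_genes=300, program_scale=0.5, seed=1))
normed = log_normalize(cells.to_count_matrix())
embedding = pca_embed(normed, n_components=30)   # kneedle picks the top PCs
result = PopulationDistance(
    embedding.coordinates, cells.true_population, n_pcs=embedding.n_selected
).fit(n_perm=200, seed=2)
print(result.summary().to_string(index=False))
```

```
                     statistic   value
                         cells     683
                   populations      53
                      PCs used       9
                   intra pairs    9031
                   inter pairs  223872
    Cohen's d (intra vs inter) -2.8409
 KS statistic (intra vs inter)  0.9527
                    KS p value     0.0
                  permutations     200
mean Cohen's d (intra vs perm) -3.3003
mean Cohen's d (inter vs perm)  0.1072
       pooled perm-intra pairs 1806200
```

Cohen's d of −2.84 means cells expressing the same receptor are far closer
to each other in PC space than cells of different populations; the
permutation null confirms the intra distribution sits ~3.3 pooled SDs below
randomly relabelled data, while the inter distribution is indistinguishable
from it (mean d ≈ 0.11).

The same objects feed the downstream stages: `fit_cluster_model` on the
family's GTF-style annotations detects OR gene clusters,
`pairwise_aa_matrix(trim_alignment(...))` scores receptor sequence
differences, `association.build_pair_table` joins the three distance
worlds, and `NBWaldDE` / `ExonIntronSplit` analyse bulk exposure tables.

## Command line

```bash
osn-identity simulate sc --out run/sim --seed 2
osn-identity preprocess --counts run/sim --out run/prep
osn-identity distances --embedding run/prep/embedding.tsv \
    --assignment run/prep/assignment.tsv --out run/dist.tsv --pcs 15 --n-perm 1000
osn-identity run-all --config config.yaml --out run/all
```

Single-cell data travel as 10x-style MTX triplets, OR families as gapped
FASTA + GTF + newick, bulk tables and results as TSV; a YAML config with
per-stage blocks drives `run-all`, which writes a manifest with per-output
checksums.

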