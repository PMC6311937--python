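# alnvalid

Clustering-free benchmarking of protein sequence-alignment methods by
cluster validity.

## The problem

Protein families give alignment benchmarking a biological ground truth:
every sequence carries a known class label. Instead of scoring alignments
against manual reference alignments (SP/CS-style scores) or running a
clustering algorithm and matching its output to the taxonomy — both of
which inject biases of their own — `alnvalid` evaluates an alignment
method by how well the **distances** it induces separate the known
families. It is aimed at anyone choosing between pairwise (PSA) and
multiple (MSA) alignment strategies for family-level analyses.

The pipeline: pool per-family FASTA files into a labeled dataset (dropping
sequences claimed by more than one family), draw 90% resamples ten times,
run each alignment method, convert alignments to percent-identity
distances, score the distance/label fit, and compare methods with a t-test
across the matched resamples.

## Scores

For an aligned pair, percent identity and distance are

    ID  = (matched residues) / (aligned length),        dis = 1 − ID.

Given the n×n matrix of `dis` values and family labels, two cluster
validity indices are computed directly — no clustering step:

* **Silhouette width** `SW = (1/n) Σᵢ S(i)` with
  `S(i) = (b(i) − a(i)) / max{a(i), b(i)}`, where `a(i)` is the mean
  distance from sequence i to the rest of its family and `b(i)` the
  smallest mean distance to another family. Range [−1, 1]; near 1 means
  tight, well-separated families.
* **RS index** `RS = (SS_t − SS_w)/SS_t` over the pairwise distances,
  where `SS_t` is the total sum of squares about the global mean distance
  and `SS_w` the within-family sum of squares. Range [0, 1].

Both are ratios of within/between contrasts, so uniformly shrinking all
distances (as a PSA does relative to an MSA) changes neither — the
comparison is fair by construction. See `docs/methods.md` for conventions
and edge cases.

The internal PSA route is global Needleman–Wunsch (Gotoh affine gaps,
BLOSUM62, open −10 / extend −1 by default, deterministic traceback).
MSA programs are driven as external executables through adapters and never
re-implemented.

## Worked example

Generate a 3-family synthetic dataset, compute the PSA distance matrix,
and score it against the true labels:

```
$ alnvalid simulate --families 3 --per-family 4 --length 120 \
      --between 0.6 --within 0.1 --indel 0.01 --seed 7 \
      --out synth.fasta --labels synth.tsv
wrote 12 sequences (3 families) to synth.fasta

$ alnvalid align-psa --in synth.fasta --out dist.tsv
wrote 12x12 distance matrix to dist.tsv

$ alnvalid validity --dist dist.tsv --labels synth.tsv --out validity.tsv
n=12  SW=0.714567  RS=0.996201
```

`SW = 0.714567` says family members sit much closer to each other than to
the nearest other family (1.0 would be perfect separation);
`RS = 0.996201` says almost all variance among pairwise distances is
between-family rather than within-family. `validity.tsv` lists the
per-sequence silhouettes (e.g. `fam1_s1  fam1  0.711099`) with the SW/RS
summary rows at the bottom.

Other entry points: `alnvalid dist-msa` projects pairwise distances from
an aligned FASTA; `alnvalid bench run --config bench.yaml --seed 42 --out
results/` runs the whole multi-group, multi-method benchmark from a YAML
config and writes score, comparison, and summary tables.

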