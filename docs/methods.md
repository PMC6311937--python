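# Methods

`alnvalid` benchmarks protein sequence-alignment programs by how well the
distances they induce separate known protein families, without ever running
a clustering algorithm. Families in a curated dataset play the role of
class labels; an alignment method is good to the extent that the pairwise
distances it produces are small within families and large between them.
This note records the model, the numerical conventions, and the design
choices that were genuinely open.

## Pipeline

1. **Dataset assembly.** Per-family FASTA files are pooled into one labeled
   dataset. A sequence id claimed by more than one family cannot carry a
   single class label and is excluded entirely (logged). Sequence order is
   stable and defines the row/column order of every downstream matrix; ids
   travel with every matrix to prevent silent label misalignment.
2. **Resampling.** Each benchmark group consists of the original dataset
   plus `reps` replicates (default 10), each drawing `floor(fraction * n)`
   sequences (default 90%) uniformly without replacement, unstratified by
   family. `floor` guarantees strict subsampling; stratification is not
   applied because the protocol being emulated samples sequences, not
   families. All randomness flows from one top-level seed through named
   `numpy.random.SeedSequence` sub-streams (group, replicate), so a fixed
   seed reproduces the draws exactly. The group sub-seed is derived with a
   process-independent string hash, not Python's salted `hash()`.
3. **Alignment.** The internal PSA route aligns every unordered pair once
   with global Needleman–Wunsch; external MSA programs are invoked through
   argument templates (`{input}`, optional `{output}`), never
   re-implemented. Adapter output is checked for integrity: the aligned
   FASTA must contain exactly the input ids and degap back to the input
   residues.
4. **Evaluation.** Distances feed two cluster-validity indices, SW and RS
   (below). Per-replicate scores of two methods are compared with a
   two-sided Welch t-test (a paired variant is available since replicates
   are matched across methods; Welch is the default because the protocol
   being emulated specifies only "t test"). Identical score vectors get
   p = 1 by convention; distinct constant vectors get p = 0.

## Distances

Percent identity of an aligned pair is

    ID = (number of matched residues) / (whole length of aligned sequences)

and the distance is `dis = 1 - ID`. A column pairing a residue with a gap
counts toward the length but never toward the matches; gap–gap columns
never match. Identical letters match regardless of case (input is
upper-cased); `X–X`, `B–B` etc. count as matches, since ID counts identical
letters, not substitution-matrix-positive pairs.

For pairwise projections out of an MSA the denominator is governed by a
gap-column policy. The default, `keep-all`, reads "whole length" literally:
dual-gap columns count. This is why an MSA can assign identity < 1 even to
identical sequences — the documented behavior of the score, not a bug.
`drop-dual-gap`, the common convention elsewhere, is available as a flag
for sensitivity analysis. Alignments produced by the pairwise DP contain no
dual-gap columns, so both policies agree on the PSA route.

## Needleman–Wunsch / Gotoh

Scores default to BLOSUM62 with affine gaps, open −10 / extend −1 (a gap
run of length k costs `open + (k-1)*extend`), end gaps penalized. These are
community-standard protein defaults; they are configurable because the
PSA tool being emulated does not publish its parameters, which also means
exact reproduction of that tool's published scores is not claimed. A linear
mode (every gap residue costs `gap_open`) exists mainly so the exhaustive
enumeration oracle in the tests stays simple and exact; internally it is
Gotoh with open = extend.

Numerical conventions:

* Traceback ties are broken diagonal > up (gap in the second sequence) >
  left, at every cell and at the final cell (M > X > Y states). ID depends
  on which optimal traceback is taken, so determinism here is part of the
  contract.
* Ambiguity codes B/Z/X are scored by the matrix's own rows; U (absent from
  BLOSUM62) scores 0 against everything. A residue with neither a matrix
  row nor a neutral fallback raises a scoring error naming the residue.
* The DP kernel is numba-compiled with a pure-Python fallback; both paths
  execute the same code.

## Cluster validity

**Silhouette width.** For sequence i, `a(i)` is the mean distance to the
other members of its family (self excluded), `b(i)` the smallest mean
distance to any other family, and

    S(i) = (b(i) - a(i)) / max{a(i), b(i)},    SW = mean_i S(i).

Conventions: a member of a singleton family gets S(i) = 0 (neutral; a 90%
resample can strand a family with one member), and a(i) = b(i) = 0 also
gives 0. SW lies in [−1, 1].

**RS index.** The "samples" are the n(n−1)/2 pairwise distances x_k:

    RS = (SS_t - SS_w) / SS_t

with SS_t the sum of squared deviations of all pairwise distances from
their global mean, and SS_w the sum, over families, of squared deviations
of within-family distances from that family's mean within-distance.
Squared deviations are used even though the underlying sum-of-squares
definition is sometimes printed without the square — unsquared deviations
about a mean sum identically to zero and would make the index vacuous.
Per-family centering of SS_w makes SS_w ≤ SS_t, so RS ∈ [0, 1]; the
alternative reading that centers SS_w on the global mean is implemented
behind `ss_w_center="global"` (it can only lower RS). SS_t = 0 (all
distances equal) means no separable structure exists and RS is defined
as 0. This within/total decomposition is one consistent reading of a
definition that is ambiguous in its source; the flag exists precisely
because the ambiguity is unresolvable from the text.

Both indices are ratios of distance contrasts, so multiplying every
distance by a common factor changes neither. This is the fairness property
that lets PSA distances (systematically smaller) and MSA distances share
one scale: a method gains nothing by uniformly shrinking distances, only by
improving the within/between contrast. Scores are reported to 6 decimal
places in output tables.

## Synthetic data

The generator emulates the statistical skeleton of a curated multi-family
benchmark: a root sequence drawn i.i.d. over the 20 standard residues;
family ancestors obtained by substituting each root site with probability
`between_divergence`; members by substituting ancestor sites at
`within_divergence` and applying single-residue indels
(insertion/deletion equiprobable) at `indel_prob` per site. Substituted
sites are replaced uniformly by one of the other 19 residues — the simplest
model with closed-form identities: a sequence and its mutated copy share
`1 - d` of sites in expectation (`expected_identity`), and two independent
descendants of one ancestor share `(1-d)^2 + d^2/19`
(`expected_pair_identity`). Both closed forms are exact only at
`indel_prob = 0`.

Defaults — 4 families × 10 members, length 200, between 0.5, within 0.05,
indel 0.01 — describe clearly separable but non-trivial families at
realistic protein lengths. Presets (`rv11_like`, `rv12_like`, `rv20_like`)
map the generator onto the identity bands of the standard curated reference
groups (< 20%, 20–40%, > 40% within-family identity) with no claim of
reproducing their content.

What the generator does *not* emulate: phylogenetic rate heterogeneity,
BLOSUM-biased substitution, long or nested indels, domain shuffling,
N/C-terminal extensions, or orphan sequences. Passing tests therefore show
that the pipeline recovers planted family structure under a star-phylogeny
substitution model — they do not certify performance on curated structural
benchmarks, whose difficulty comes exactly from the features listed above.

## Problem sizes

The test suite and the acceptance script run the full pipeline at
deliberately modest scale — one synthetic group of 40 sequences of length
~200 with ten 90% resamples, ~8,000 pairwise alignments end to end — which
is ample to exercise every code path and to reproduce the framework's
design counts (8 groups × 11 datasets × 7 methods = 616 scheduled runs)
and its qualitative PSA-vs-MSA contrast. The divergence-recovery check uses
a 5-level between-divergence grid at fixed within-divergence and 100 label
permutations of the strongest grid point.

## Known limitations

* The RS decomposition is one consistent reading of an ambiguous
  definition (see flag above).
* Identity-based distances ignore substitution similarity: a conservative
  substitution and a radical one are equally "different".
* The PSA route is O(n² · L²); no k-mer prefiltering or banding is
  provided, so very large datasets are out of scope.
* External MSA results depend on the binaries and versions installed;
  adapter integrity checks catch dropped or mutated sequences but cannot
  validate alignment quality itself.
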