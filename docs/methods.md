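# Methods

## Identity scoring

Pairwise similarity of sequences uses Smith–Waterman local alignment with
BLOSUM62 and affine gap penalties (gap open 10, gap extend 1; both
configurable and recorded in every pipeline log). The identity score is
the number of identical columns in the optimal local alignment divided by
the **length of the shorter sequence**, clipped to [0, 1]; a pair with no
positive-scoring local alignment scores 0. Two normalizations were
considered:

- *aligned columns* (identities / alignment length, gaps included): gives
  1.0 for exact substring hits but also scores unrelated peptides very
  high, because the optimal local alignment of two random peptides is
  typically a short (3–6 residue) near-exact match — a 3/3 match scores
  identity 1.0. Under this convention an identity threshold of 0.60
  cannot discriminate random sequences at all.
- *shorter sequence* (identities / min(len a, len b)): also gives 1.0 for
  exact substring hits, while a short chance match over longer sequences
  scores low. This is the only convention consistent with identity
  thresholds in the 0.3–0.9 range acting as meaningful classifiers
  against shuffled or random negatives, and is therefore the default.
  The aligned-columns mode remains available via
  `AlignmentParams(normalization="aligned_columns")`.

Alignment is delegated to Biopython's `PairwiseAligner`; when several
local alignments are co-optimal the aligner's first (deterministic)
traceback is used. The identity *value* is tie-break-insensitive in every
case exercised by the oracle tests, which compare against an independent
Gotoh dynamic program and accept any optimal-alignment identity.

Redundancy filtering sweeps records greedily (input order, or descending
priority score) and removes a record whose identity to an already-kept
record exceeds the cutoff; full-identity duplicates are always removed,
so a cutoff of 1.0 removes exactly the duplicates. Scaffold extraction is
the same sweep in descending-centrality order with a strict `<` keep
condition, which yields a checkable certificate: kept records are
pairwise below the cutoff, and every dropped record is blocked by a kept
record of higher rank.

## Descriptors

Ten descriptors, computed from published per-residue scales shipped in
`pepcsn.scales`:

| descriptor | definition | units |
|---|---|---|
| length | residue count | residues |
| net charge | Henderson–Hasselbalch sum at pH 7, Lehninger pKa set | e |
| isoelectric point | bisection of the charge function to \|z\| < 1e-4 | pH |
| molecular weight | average isotopic masses (Biopython ProtParam) | Da |
| Boman index | mean residue solubility value (Boman 2003) | kcal/mol |
| hydrophobic moment | Eisenberg moment at 100°/residue | — |
| avg hydrophilicity | Hopp–Woods mean | scale units |
| hydrophobic periodicity | normalized Fourier amplitude of the mean-centred Eisenberg profile at 100° | [0, 1] |
| aliphatic index | Ikai: 100·(x_A + 2.9·x_V + 3.9·(x_I + x_L)) | — |
| instability index | Guruprasad DIWV dipeptide sum (Biopython); 0 for single residues | — |

The proline Boman value, unmeasured in the underlying transfer-energy
series, is set to 0. The descriptor set is pluggable
(`descriptor_set=...`); aggregation-operator indices are not included
because no public definition exists for them. Exact numeric parity with
any other descriptor implementation is not claimed — descriptors only
need to induce a meaningful geometry for the CSN.

Min–max normalization maps every column by (x − min)/(max − min);
constant columns map to 0, since a constant carries no distance
information.

## Chemical space networks

Similarity between peptides is 1 − the min–max-scaled Euclidean distance
between their normalized descriptor rows, with the distance scaling taken
over **all unordered pairs of the current input set**. This makes
similarity dataset-relative: adding or removing peptides changes the
scaling. Edges join pairs with similarity ≥ t; all records remain as
nodes, so isolated nodes (outliers) are first-class. Metrics follow the
usual conventions: density 2E/(N(N−1)) and average degree 2E/N on the
graph as given; clustering coefficient as the mean local coefficient;
diameter and average path length on the largest connected component in
unweighted hops. Louvain community detection (networkx implementation)
uses edge weights and a fixed seed (default 42) for determinism; its
reported modularity is the weighted Newman modularity of the returned
partition.

## Centrality

Weighted degree sums incident edge similarities. Harmonic and betweenness
use unweighted hop distances — the conventional default, configurable in
principle but deliberately fixed here for comparability. Community
hub-bridge is

    CHB(u) = |C(u)| · k_intra(u) + NNC(u) · k_inter(u)

with C(u) the node's community, k_intra/k_inter its intra-/
inter-community degree and NNC(u) the number of distinct neighboring
communities; this follows the modular-centrality literature and collapses
to |V|·deg(u) on a single-community graph. Scores are min–max normalized
per measure; rank ties break lexicographically by id.

The "top 10%" pruning variant keeps records with normalized centrality
≥ (1 − f)·max over the considered set (f = 0.10 by default). It is a
secondary path: the default pipeline uses plain scaffold extraction.

## Model building and searching

The standard pipeline is: 98%-identity dedup → descriptor CSN at t = 0.60
→ outlier split → Louvain clustering → scaffold extraction at 0.60 for
harmonic and weighted-degree centrality → union with the outlier set.
Outliers enter the query model raw (not post-scaffold), so the union is a
complete representation of the positive chemical space. Classification is
inclusive: fused score ≥ θ is positive. The prospective screen chains the
3–25-residue length/annotation filter, the 95% redundancy filter, MAX-SIM
search at θ = 0.60, and removal of fused scores equal to 1 (rounded to 6
decimals) — an exact match to a query is already a known peptide, not a
discovery. Nearest-neighbor reports embed hits into the reference CSN
jointly (descriptor normalization and distance scaling over the union)
and list the k = 3 most similar directly-attached reference nodes; hits
sharing ≥ 2 neighbors are flagged as redundant candidates.

## Statistics

The eight confusion-matrix statistics use the standard formulas
(accuracy; Cohen's κ with Pc from the marginals; sensitivity;
specificity; positive/negative precision; MCC; FAR% = 100·FP/(FP+TN)).
Undefined ratios (zero denominator) are reported as missing ("NA"); an
MCC with a zero denominator is 0 by the usual convention. Display
rounding is 3 decimals for proportions and 2 for percentages; raw values
are kept at full precision. With balanced classes Pc = 1/2 exactly, so
κ = 2·Ac − 1 — a useful algebraic cross-check asserted in the tests. The
Friedman test ranks methods within blocks (average ranks on ties) and
compares χ² = 12/(n·k·(k+1))·ΣR_j² − 3·n·(k+1) to a chi-square with k − 1
degrees of freedom.

## Synthetic data

The generator emulates the family structure of curated bioactive-peptide
collections: each family is `family_size` mutants of a random seed
sequence that carries a conserved 5-residue motif, with an 8%
per-position substitution rate outside the motif, lengths 10–22 residues,
plus unrelated uniform-random peptides (defaults: 6 families × 12 + 28
unrelated = 100 peptides; all parameters and the RNG seed are in
`SyntheticSpec`). Benchmarks pair each positive with a
composition-preserving residue shuffle as its negative, which is a harder
negative model than uniform random draws: descriptor components that
depend only on composition are identical between a positive and its
negative, so CSN separation cannot come from composition alone. Scale
choices keep the default test-suite problem sizes at ~100 peptides and
~200 benchmark targets, which exercises every pipeline stage while
keeping alignment counts in the tens of thousands.

What passing tests show — and what they don't: the synthetic families
have much higher within- than between-family identity by construction, so
planted-family recovery (Sn, Sp ≥ 0.9 at θ = 0.6) validates the machinery
(fusion, thresholds, scaffold certificates), not real-world predictive
performance. Real THP collections have skewed length and composition
distributions, literature-driven redundancy patterns, and negatives that
are not composition-matched shuffles; numbers obtained on synthetic data
do not transfer.

## Numerical and degeneracy choices

- Identity is computed on a canonically ordered sequence pair, so it is
  exactly symmetric.
- Similarity/identity comparisons at thresholds are inclusive (≥), per
  the classification contract; the score-1 removal uses rounding to 6
  decimals to avoid float-equality traps.
- Degenerate inputs: empty sequences are rejected; single-residue
  peptides have instability index 0; an edgeless network yields one
  community per node with modularity 0; constant descriptor columns and
  constant centrality vectors normalize to 0.
- All randomness (synthetic data, Louvain) is seed-controlled;
  identical seeds give byte-identical FASTA output.

## Known limitations

- Descriptor parity with other toolboxes is not guaranteed, so node/edge
  counts of networks built from external datasets may differ slightly
  from published counts even when the pipeline is identical.
- The community hub-bridge formula is an interpretive choice from the
  modular-centrality literature; other weightings exist.
- Identity normalization by the shorter sequence makes containment
  symmetric with identity 1.0: a 5-mer fully contained in a 25-mer counts
  as redundant with it. This is intended for scaffold extraction but may
  over-collapse sets with heavy length variation.
- The Friedman test reports the classic chi-square approximation; for
  very small block counts an exact permutation test would be preferable.
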