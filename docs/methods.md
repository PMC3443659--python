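# Methods

## The DMk representation

A DNA sequence over Σ = {A, C, G, T} of length *s* contains s − k + 1
overlapping k-tuples. For each of the 4^k possible tuples *w* the
model summarizes *where* the tuple occurs, not just how often:

1. Occurrence positions p_1 < p_2 < … < p_m (1-based starts; p_0 = 0).
2. Reciprocal gaps α_r = 1/(p_r − p_{r−1}) ∈ (0, 1]. The first term
   1/p_1 anchors the series to the absolute position of the first
   occurrence — this is why positions must be 1-based: a 0-based
   convention would make α_1 infinite for a tuple starting the
   sequence.
3. Partial sums β_j = Σ_{r≤j} α_r, strictly increasing; {β_j} and
   {α_r} determine one another, so no information is lost.
4. Normalized weights q_j = β_j / Σβ and Shannon entropy
   H(w) = −Σ q_j log₂ q_j, in bits.

H is 0 for a tuple seen 0 or 1 times (we define the m = 0 coordinate
as 0 to keep a fixed-length vector; m = 1 gives the degenerate
distribution q = (1)). Because β is strictly increasing, q is never
uniform for m ≥ 2, so H < log₂ m strictly. The 4^k coordinates are
ordered lexicographically (A < C < G < T), frozen so serialized
vectors are comparable across runs.

**DMk distance** = Euclidean distance between entropy vectors.
**k-tuple distance** (baseline) = L1 distance between raw overlapping
count vectors. Both are norms of vector differences, hence true
metrics at the vector level. Sequences of very different lengths are
compared as-is — no length normalization — which mirrors how the
measure is used on real gene families; the caveat is that entropy
magnitudes grow with occurrence counts, so grossly different lengths
inflate distances.

**Choice of k.** Default k = 3 (suits protein-coding genes; larger k
rapidly produces mostly-zero vectors and weaker signal). Valid range
1–8; 4^8 = 65 536 coordinates is the memory guard. The baseline uses
raw counts rather than length-normalized frequencies.

**Complexity.** Featurization of one sequence is one vectorized k-mer
scan plus a stable argsort to group positions per tuple:
O(l log l + 4^k) with small constants, empirically indistinguishable
from linear in l over the 10–50 kb range (measured exponent ≈ 0.5–0.7
because fixed per-call overhead still matters at these sizes).

## mBKM

Bisecting K-means repeatedly 2-means-splits one cluster until K
clusters exist, producing a binary tree whose K-leaf frontier is the
flat partition. The two modifications:

* **Seeding.** The two initial centroids of every bisection are the
  pair of members at maximal distance (O(n²) per split). This avoids
  the classical failure of random seeding — two adjacent seeds → local
  optimum — and removes every source of randomness from the algorithm.
* **Split selection.** The cluster split next is the one with maximal
  variance σ_j = Σ_{i∈C_j} d²(s_i, μ_j)/n_j, i.e. the least compact,
  recomputed fresh from current members each round (cheap, and robust
  to centroid drift across rounds). Largest-size splitting — the usual
  BKM rule, kept in the BKM baseline — partitions big natural clusters
  first and degrades on datasets with unequal family sizes.

Assignment and centroid updates inside every 2-means use Euclidean
distance in feature space, consistent with DMk being Euclidean; with
the count representation the seeding pair may be chosen under L1
while assignment stays Euclidean. The inner loop stops when the
assignment is unchanged between iterations (exact, float-safe) with a
cap of 100 iterations against pathological oscillation. If an
iteration empties one side, the point farthest from the surviving
centroid is moved over, so no split returns an empty cluster. All
ties — equidistant assignment, equal maximal seeding distance, equal
variance, equal merge distance in the agglomerative methods — break
toward the lowest index, making every deterministic path bitwise
reproducible and testable.

**Baselines.** KM is Lloyd's algorithm seeded with uniform-random
distinct data points, best of n runs by inertia (per-run partitions
are kept for average-performance reporting). BKM seeds each bisection
with random member pairs, best of 5 restarts per split by
within-cluster sum of squares, and splits the largest cluster
("best of 5" is read as 5 seeded restarts; the alternative reading,
5 Lloyd iterations, would not define a selection criterion). SL/CL/AL
are agglomerative with min/max/size-weighted-mean cluster distances;
AL's merge rule is exactly the UPGMA criterion (the "unweighted" in
UPGMA's name refers to equal weighting of original observations,
which is the size-weighted Lance–Williams update), so one
agglomerative core serves both, with `upgma` additionally recording
node heights at half the merge distance — yielding an ultrametric
tree. Flat clusterings come from cutting the dendrogram: descend from
the root, splitting the highest node, until K subtrees remain.

**Newick export.** mBKM/BKM trees define no branch lengths and emit
bare topology; UPGMA/agglomerative trees emit lengths as
parent-height minus child-height. A frontier leaf holding several
sequences becomes an unresolved clade.

## F-measure

For class i and cluster j with overlap n_ij, precision = n_ij/n_j,
recall = n_ij/n_i, F(i,j) their harmonic mean (0 when n_ij = 0, which
also covers empty clusters in imported assignments), and the overall
score is F = Σ_i (n_i/N)·max_j F(i,j) ∈ [0, 1], reaching 1 exactly for
a relabelling of the classes. The score is asymmetric — over-splitting
is penalized through recall, under-splitting through precision — and
is reproduced as-is because it is the standard index in this
literature. Sequences without a label are excluded from the table with
a logged count.

## Synthetic families

The generator draws, per family, a uniform-random ACGT ancestor of the
requested length, then derives each member independently by per-site
substitution (uniform over the 3 alternative bases) and optional
per-site indels (geometric lengths, capped, off by default so the
default mode is a clean substitution-only recovery problem). Members
are emitted in a seeded shuffle so input order carries no signal.
Defaults used throughout the tests: 2% substitution, 1 kb ancestors,
either 4×20 balanced families or 50/5/5 unbalanced ones — sizes chosen
to be small enough for second-scale tests while exhibiting the
balanced-easy / unbalanced-hard contrast the split-selection rule
targets. Timing sweeps use 100 equal-length sequences in 4 families at
10–50 kb.

What this does *not* emulate: within-family phylogeny (members are
independent draws from the ancestor, so families are star-shaped),
realistic base composition, substitution-model structure (no
transition/transversion bias, no rate heterogeneity), codon structure,
or homology between families. Perfect recovery on these fixtures
therefore shows the pipeline separates families whose divergence is
moderate and noise i.i.d.; it does not guarantee performance on deeply
diverged or compositionally biased real families.

## Numerical and design notes

* Non-ACGT input characters are stripped by default (with a logged
  count) before featurization; a `reject` policy raises instead. How
  ambiguous bases are best handled is genuinely open — stripping
  preserves flanking positional structure better than splitting
  records, but shifts downstream positions.
* PHYLIP square matrices are written in the classic 10-character-name
  dialect by default (a `relaxed` option keeps full names); the reader
  accepts both. Distances are reported to 2 decimals in reports but
  held at full precision internally.
* Feature-vector TSVs round-trip through 12-significant-digit decimal
  text.
* The bundled β-globin matrix contains published k = 3 DMk distances
  among 10 vertebrate β-globin genes and serves as a fixed external
  benchmark for UPGMA topology checks (primate clade; gallus outside
  the placental core). The underlying GenBank sequences are not
  bundled, so the matrix is data, not a recomputation target.
* Reverse-complement canonicalization is deliberately absent: tuples
  are strand-specific. Protein alphabets and automatic selection of K
  are out of scope.
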