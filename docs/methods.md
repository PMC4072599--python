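# Methods

This note records the model, the numerical and design choices behind
`bayesasm`, what the synthetic data generator does and does not emulate,
and the known limitations. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Assembly graph

The hypothesis space is a reduced de Bruijn graph. Nodes are the distinct
k-mers of the oriented reads (forward mates plus reverse-complemented
reverse mates; no reverse-complement canonicalization — a library whose
fragments are reported on one reference strand yields a single-strand
graph), edges are observed (k+1)-mer adjacencies, and windows containing
non-ACGT characters are skipped. Reduction proceeds in three steps:

1. **Tip trimming.** For a circular target genome every node of in- or
   out-degree zero is spurious, so trimming iterates to a fixpoint. A
   `linear` mode removes only dangling chains whose spelled length is
   below 2k, for genomes with true sequence ends.
2. **Unambiguous-path merging.** Every edge (u, v) with out-degree(u) = 1
   and in-degree(v) = 1 is contracted; a merged node's annotation is the
   first node's annotation extended by each subsequent annotation minus
   the k−1 overlap. A fully unambiguous cycle collapses to one node with
   a self-edge, so a non-empty reduced graph always retains at least one
   edge for the state vector.
3. **Largest weakly connected component**, by total annotation length
   (ties: the component containing the lexicographically smallest
   annotation).

Edge indices are enumerated sorted by (source annotation, target
annotation), making boolean state vectors reproducible across runs.
Cycle contigs are spelled with the final k−1 characters trimmed and
canonicalized to the lexicographically minimal rotation (Booth's
algorithm), so the same circular sequence always produces the same
string regardless of traversal start.

### k-mer abundance threshold

`build_debruijn` accepts `min_count`, the minimum k-mer abundance kept at
construction (default 1). This matters because a substitution error in
the middle of a read creates k erroneous k-mers that branch off the
backbone and *rejoin* it k nodes later — a bubble, not a tip, so tip
trimming cannot remove it. At the default study scale (about 1 Mb of
read bases at error rate 0.002) roughly 1,500 such error bubbles would
survive trimming and swamp the sampler. The pipeline default
(`BayesianAssembly(min_count=5)`, about 3% of per-base coverage) drops
k-mers seen fewer than five times: error k-mers recur at a given
position only by coincidence (expected Poisson rate ≈ 0.12 per site at
these conditions, so five-fold recurrence is vanishingly rare), while
minor-haplotype k-mers at 10% of ~165× k-mer coverage are expected ~16
times and survive. This is standard abundance filtering at graph
construction, distinct from topology-based bubble-popping heuristics
(which are deliberately absent: real variant bubbles must be retained
for sampling).

## Probability model

**Likelihood.** Under an i.i.d. per-base substitution model (match
probability 1−ε, each specific mismatch ε/3; N counts as a mismatch),
the probability that the assembly generated read r is the sum of its
placement probabilities over every contig, strand and start position,
divided by the number of possible placements. The per-read mean of the
log of this quantity is the LAP score, reported by `lap_score`; the
posterior uses the **total** log likelihood (N times the mean), because
the probability of the read set is the product over reads. A per-read
average in the acceptance ratio would make the posterior asymptotically
flat in the data — with 4,000 reads the entire likelihood contrast
between a major and a minor bubble branch would be under one log unit —
and the data could never dominate the prior.

**Circular contigs.** Contigs arising from cycles are scored circularly:
placements may wrap the origin, and the number of start positions per
strand is L rather than L−ℓ+1. Scoring a cycle as a linear string would
floor the ~ℓ/L fraction of reads spanning the (arbitrary) rotation
origin, a penalty of roughly ℓ·log(ε/3) each; the maximum-posterior
state is then not the true cycle but an open path that wraps the genome
and dangles half a bubble branch at each end. Circular scoring removes
this artifact at the cost of treating the contig as exactly circular.

**Placement enumeration.** Exhaustive scanning (every window, vectorized)
is exact and is used for short reads and all oracle comparisons. For
reads of length ≥ 32 the default is exact seed-and-extend: 16-mer seeds
at offsets 0, 16, 32, … are looked up in a positional index of the
contig and each candidate window is scored fully. A placement is missed
only if every seed covering it contains an error (probability < 1e-3 per
read at ε = 0.002, and the missed placements are the negligible tail of
the placement sum). Unplaceable reads receive a floor equal to the worst
possible placement, ℓ·log(ε/3) − log(denominator), keeping the posterior
finite while penalizing unexplained reads.

**Priors.** Gamma densities parameterized by shape α > 1 and mode c,
with scale θ = c/(α−1) so that (α−1)θ = c exactly. "Centered at" is read
as the mode: the maximum a priori total length sits exactly at the known
genome length (5,386 bp default) and the contig-count prior peaks at 1,
for every shape. Defaults use α = 5 for both. `flat` mode zeroes the log
prior; `prior_only` zeroes the log likelihood (both used in prior
sensitivity checks). Degenerate states (zero length or zero contigs)
receive a large finite floor (−1e12) rather than −∞ so the sampler can
still compare them.

**Paired-end information** is not used by the likelihood: mates are
scored independently as single reads. An insert-size term would add
resolving power for repeats, which the boolean edge-vector state space
cannot represent anyway (an edge is visited at most once).

## Sampler

A proposal applies `n_perturbations` (default 3) single-edge
perturbations. Each perturbation draws one edge uniformly:

* **Active edge** — deactivated; the containing path splits (or a cycle
  opens). Nothing else changes.
* **Inactive edge** — activated, then extended from both endpoints by
  uniform random walks over inactive edges. A walk stops at the first
  node that already touches an active edge other than the one just
  traversed (so it also terminates cleanly if it loops back onto the
  chain being built) or at a node with no inactive continuation, with a
  2E-step safety cap. If the pre-existing assembly runs between the two
  attachment points, that displaced branch is deactivated (the
  one-move bubble flip); otherwise only the directly conflicting old
  edges at the attachment nodes are removed. A perturbation whose result
  is invalid is re-drawn; after E failed draws the state is returned
  unchanged.

Acceptance is plain Metropolis on the posterior odds ratio, computed in
log space; the ratio is exponentiated only when negative. The initial
state applies E perturbations to the all-inactive vector. Independent
chains are seeded from a spawned seed sequence and share one memoizing
posterior evaluator (per-contig read-placement vectors keyed by contig
string and circularity; per-state log posteriors keyed by the packed
edge vector — the proposal changes few contigs per move and chains
revisit states, so both caches hit constantly).

### No Hastings correction — measured consequences

The kernel is intrinsically asymmetric: activation adds a whole chain of
edges in one move, while deactivation removes exactly one, so many moves
have no single-move reverse. With no proposal-density correction the
chain's stationary distribution is therefore not exactly the target.
The package quantifies this directly (see the sampler enumeration checks
in the test suite and the `sampler_enum_max_freq_dev_*` entries of
`scripts/acceptance.py`): on an 8-edge two-bubble toy graph with a
constant posterior, per-state frequencies deviate from uniform by up to
~0.10 (full-cycle states are over-visited, and "detached partial branch"
states — e.g. two active fragments not touching any common path — are
unreachable, because activation always extends to contact). The
deviation is reported, not corrected, for two reasons: computing the
exact multi-perturbation proposal density is intractable, and the bias
concentrates mass on *maximal contiguous assemblies*, which is where the
posterior mass lies for any informative likelihood. In the end-to-end
setting the likelihood contrasts between states are hundreds of log
units, rejection dominates the walk asymmetry, and independent chains
agree to < 0.001 in edge frequency while recovering the true genome
exactly; for diffuse posteriors, absolute state frequencies should be
read as approximate.

## Consensus and annotation

Majority-rule consensus activates edges with sampling frequency ≥ the
threshold (default 0.5, ties kept), resolving validity conflicts
greedily by descending frequency (exact ties: lower edge index, with the
decision flagged in the output); the result always validates and spells.
Contig-level posterior is the minimum edge posterior along the path
(conservative). External assemblies are annotated by exact matching on
either strand: nodes by their annotation, edges by the junction
(k+1)-mer spanning the edge after overlap merge. Note that a feature
spanning a circular contig's rotation origin will not match the linear
FASTA of that contig; doubling the external sequence restores the match.

## Synthetic data

The generator emulates the summary statistics of the phiX174 MiSeq test
subset: a uniform-random 5,386 bp circular genome, 2,000 read pairs,
insert length normal with mean 357 and SD 40 (the real subset's insert
SD is not published; 40 is an arbitrary documented default), fragment
starts uniform on the circle, forward mate from the 5′ end and reverse
mate reverse-complemented from the 3′ end, i.i.d. substitution errors at
rate 0.002, and constant Q38 qualities (so simulated data passes the
mean-quality > 37 subset filter by construction). Variant haplotypes
inject biallelic sites (alt ≠ ref, positions ≥ 500 bp apart on the
circle) applied to each fragment independently with the minor fraction
(default 10%).

Two read-length conventions are provided. The default end-to-end
conditions use fixed 251 bp reads (nominal coverage 2·2000·251/5386 ≈
186×). The `simulate_phix_like` preset instead draws variable mate
lengths (99% uniform on 34–214 bp, 1% at the full 251 bp machine length,
mean ≈ 125 bp), reproducing simultaneously the real subset's pair count
(2,000), maximum read length (251 bp) and ≈ 93× fold coverage — three
statistics that are mutually inconsistent under fixed-length reads,
since 2,000 pairs of fixed 251 bp reads give 186×, not 93×.

What the generator does **not** emulate: indels, position- and
cycle-dependent quality profiles, adapter read-through, chimeric
fragments, strand-specific coverage biases, and genomic repeats (the
uniform-random genome is repeat-free at k = 31 with overwhelming
probability). Passing tests therefore demonstrate correct inference under
the stated generative model, not robustness to every artifact of real
libraries.

## Problem sizes and numerical choices

* End-to-end runs use 3 chains × 20,000 iterations with 3 perturbations
  per proposal; the enumeration checks use 3 × 50,000 iterations on an
  8-edge toy graph; oracle comparisons use 500 random instances with
  contigs ≤ 50 bp and reads ≤ 10 bp (agreement to 1e−9) and 100
  mutant-ranking trials on 120 bp circular genomes at 10× coverage.
* All randomness flows through `numpy.random.Generator`; chain seeds are
  spawned from a single seed sequence and every public entry point takes
  an explicit seed.
* Log-space throughout; short placement lists use a hand-rolled
  log-sum-exp, long ones `scipy.special.logsumexp`.
* The gamma log density is evaluated directly from `gammaln` (cheaper
  and no less accurate than a frozen scipy distribution in the hot
  path).

## Known limitations

* Repeats: edges are visited at most once, so genomes with k-mer repeats
  collapse or fragment; an integer-multiplicity state space would be
  required.
* The sampler targets the posterior only approximately (see above);
  edge/node posteriors are well calibrated when the posterior is sharp
  and approximate when it is diffuse.
* Exact-match annotation of external assemblies is conservative: a
  single mismatch or indel in an external contig hides an otherwise
  corresponding feature.
* The subset-selection filter reproduces the stated criteria (mean
  quality strictly > 37 per mate, optional exact-substring adapter
  screen, first-n pairs); the exact behavior of the original filtering
  tool is not otherwise specified, and its adapter catalog is not
  bundled — the default adapter list is empty.
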