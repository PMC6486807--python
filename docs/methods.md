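# Methods

This note documents the models, numerical choices and limitations of
`plastevo`, in the order of the pipeline.

## Genome model and conventions

Coordinates are 0-based half-open internally and 1-based inclusive in GFF3 on
disk. A feature spanning the origin of a circular record is stored once with
a wrap flag (`start > end`) and written to GFF3 as two lines sharing an ID;
the reader merges them back. Topology comes from an `Is_circular=true`
attribute on the GFF3 landmark `region` line. GC content excludes `N` from
the denominator. Gene names are normalized to lower case with trailing copy
suffixes (`_1`, `_2`) stripped, so presence/absence matrices and
distinct-gene counts have stable keys; genes named `trn*`/`rrn*` are classed
as tRNA/rRNA, everything else as protein coding. Distinct-gene counts
exclude `status=pseudo` annotations — a summary is a count of functional
gene species, with duplicates (e.g. genes inside both repeat copies)
reported separately.

## Rearrangement distances

Gene orders are encoded as signed permutations over maximal blocks of genes
that are contiguous and co-oriented in both genomes (genes absent from
either genome, or multi-copy in either, are ignored). This is a
gene-order-resolution stand-in for alignment-derived locally collinear
blocks; it is exact on genomes that differ only by inversions of whole-gene
segments.

Both distances use the linear capped convention (caps 0 and n+1) and are
computed on the composition q⁻¹∘p against the identity, giving one code path
for every pair:

* **Breakpoint distance**: the number of signed adjacencies (x, y) of one
  permutation such that neither (x, y) nor (−y, −x) is an adjacency of the
  other.
* **Inversion distance**: the Hannenhalli–Pevzner formula
  d = (n+1) − c + h + f on the breakpoint graph. Cycles are found on the
  unsigned 2n+2-point extension; a gray edge is oriented iff its position
  span has even length; components are connected sets of cycles under gray-
  edge interleaving; hurdles are minimal unoriented components plus the
  greatest unoriented component when it contains all others; the fortress
  term is 1 iff the hurdle count is odd and every hurdle protects a
  component that would become a hurdle on its removal. The implementation
  was validated by exhaustive breadth-first search over the entire signed
  permutation group for n ≤ 7 (645,120 states); the shipped tests keep
  exhaustive n ≤ 5 plus 500 random n = 7 instances to stay fast.

Sorting scenarios are produced greedily: at each step the lowest-index
reversal that reduces the distance by one is applied, which is always
possible and makes scenarios deterministic. The BFS oracle
(`inversion_distance_bfs`) is exact and intended for n ≤ 8.

A caveat recorded deliberately: published distance tables computed with
other tools depend on that tool's linear/circular convention and block
decomposition, so cell-by-cell agreement with such tables is not guaranteed
by these definitions.

## Repeat detection

Exact matches only (identity 1.0): maximality is then well defined and every
reported pair is non-extendable on either side. Detection is seed-and-extend
over (min_len+1)-mers (strict "> min_len" threshold; default 15 bp), on the
doubled sequence for circular records so wrap-spanning copies extend
correctly. Direct pairs whose copies overlap at a fixed period are collapsed
into a tandem-array entry with unit length and copy count, and internal
self-matches of the array are suppressed. Reverse-complement palindromes at
a single locus are excluded. Pairs at or above 1 kb — the DR/IR region pair
itself — are excluded from dispersed-repeat summaries, mirroring the removal
of one repeat-region copy before counting; the size bins default to
(15, 30], (30, 50], (50, ∞).

## Recombination model

The model operates at segment resolution: a molecule is a circular ordered
list of (segment, orientation) tokens delimited by repeat copies, with the
two copies of a pair sharing a token. This is the resolution at which
flip/split events act; nucleotide detail adds nothing. Canonical keys are
the lexicographic minimum over all rotations and the reflection (reversal
with orientations negated): the reverse complement of a circular DNA
molecule is the same physical molecule, so reflection-equivalent forms are
identified. A consequence worth stating: in the IR + small-inverted-pair
architecture, the two subgenomes excised from isomer I are canonically — and
physically — the same two molecules as those excised from isomer II, so the
reachable population holds 3 full-length isomers and 2 distinct subgenomic
circles, reached through 4 split child slots.

Events: a **flip** at an inverted pair reverses the arc strictly between the
copies (either arc gives the same canonical circle, a geometric fact the
tests check); a **split** at a direct pair yields two circles, each keeping
one repeat copy and one arc. Subgenomic molecules are terminal — they carry
single copies only, and inter-molecular recombination (merges, concatemers,
linear/branched intermediates) is out of scope. Enumeration is breadth-first
closure with canonical deduplication and a 10,000-form guard.
Classification: `DR`/`IR` for the master by co-orientation of the longest
pair (≥ 1 kb, else "no quadripartite structure"); `IRDR_coexisting` when the
reachable full-length forms include both orientations of the large pair.
Stoichiometry is uniform over full-length isomers — the equilibrium of
highly efficient reciprocal recombination; no kinetic rates are modelled.

## Codon model and rate contrasts

Pairwise estimation under a GY94-type reversible codon model: 61 sense
codons of genetic code 11 (the plastid standard), single-nucleotide
exchanges with transition/transversion ratio κ and nonsynonymous scaling ω,
stationary frequencies F3×4 computed from the union of the two sequences of
each pair, generator scaled to mean rate 1 so t is in expected substitutions
per codon. The likelihood uses unordered pattern compression (valid by
reversibility) and eigendecomposition of the symmetrized generator for
P(t). Optimization is bounded L-BFGS-B in log space (t ∈ [1e−6, 50],
κ ∈ [0.01, 100], ω ∈ [1e−4, 20]) with three restarts seeded from a stable
hash of the gene/pair, making estimates deterministic. dS and dN partition t
by the fitted model's synonymous/nonsynonymous flux against the mutational
(ω = 1) site proportions; dS > 5 is flagged saturated. Gapped or ambiguous
codons are deleted pairwise. Identical sequences short-circuit to t = 0.

The Nei–Gojobori (1986) counting estimator is the independent cross-check:
per-codon site counts exclude mutations to stop codons, multi-step codon
differences average syn/nonsyn counts over stop-free substitution paths with
equal weights, and proportions are Jukes–Cantor corrected (saturation
flagged when the log argument is nonpositive). ML and NG86 agree in the
weak-divergence limit; the tests require median agreement within 15% at
t = 0.05.

Group contrasts pool one estimate per (gene × labelled species pair);
cross-class pairs carry no label and are excluded — the conservative reading
when a published grouping is underspecified. Wilcoxon rank-sum tests are
exact (enumeration) for ≤ 20 tie-free observations and otherwise use the
normal approximation with tie and continuity corrections; a fully tied
pooled sample returns p = 1 by convention.

## Mk ancestral states and contrasts

The DR/IR character evolves under the 2-state symmetric Markov model
("unordered and equally weighted"): p(change | branch b) =
(1 − e^(−2rb))/2. One rate r is ML-fitted per tree (bounded scalar search on
log r); the root prior is flat (0.5, 0.5), forced by the symmetric model.
Marginal states at every node come from the standard inside/outside pass,
equivalent to re-rooting. A monomorphic tip set is a boundary case: rate 0,
logL = ln 0.5, degenerate marginals, noted on the fit. Across a tree sample,
clades are matched by tip bipartition; per clade the summary reports the
presence fraction, mean marginals, and the fraction of trees in which the
most-probable state differs across the subtending branch — the operational
definition of "a change on a branch", chosen because marginal
reconstructions do not define state changes directly.

PIC follows Felsenstein's algorithm exactly (standardized contrasts,
precision-weighted ancestral values, branch lengthening by v₁v₂/(v₁+v₂)).
Polytomies are rejected rather than zero-resolved, to avoid silently
inflating degrees of freedom; zero-variance cherries are errors. The PIC
correlation is through the origin with n_contrasts − 1 degrees of freedom.

## Synthetic data: what it emulates, and what it does not

Architectures emulate the studied plastomes: ~110–147 kb circles, a large
repeat pair (default layout LSC–[small copy]–bigA–SSC–[small copy]–bigB)
with 7–17 kb copies, an optional ~1.8–2.7 kb small pair with one copy per
single-copy region, GC targets around 0.51–0.56. Background sequence is
i.i.d. nucleotides at the GC target — sufficient for repeat detection, GC
and recombination tests; it has no codon structure, no real gene sequences,
no indels, and no repeat families beyond the planted pairs, so passing tests
demonstrate algorithmic correctness, not performance on real genomic
sequence complexity. Planted repeat copies are made exactly maximal by
nudging a flanking base when it would extend a copy by chance, so detection
recovers planted coordinates bit-exactly. Codon pairs are simulated from the
same GY94 generator used for estimation (parameter recovery, not an
independent emulator); trees are Yule (forward construction, run one extra
inter-birth wait so pendant edges are positive); characters and Brownian
values follow their model definitions. Every generator draws from a single
numpy Generator stream keyed by its seed and is bit-reproducible.

## Problem sizes

The test suite and acceptance script use reduced problem sizes chosen to
exercise every code path while keeping runs short: 1/10-scale architectures
(~12 kb genomes, 1.3 kb large pairs) for structural tests, full ~119 kb
genomes for GC and summary checks, 500-codon alignments with 20–50
replicates for estimator calibration, 14–20-tip trees with 200–500
replicates for Mk/PIC calibration, and exhaustive reversal-graph search up
to n = 5 (n = 7 spot-checked against a full BFS table). These sizes are the
package's own test design; all operations accept full-size inputs.

## Known limitations

* Breakpoint/inversion distances assume equal block content; no DCJ,
  translocation or unequal-content models.
* Repeat detection is exact-match only; degenerate repeat families are out
  of scope.
* The recombination model is combinatorial, not kinetic, and stops at
  subgenomic circles.
* The codon model is pairwise only (no branch/site models); F3×4 is the only
  frequency model.
* Mk is binary and symmetric; no asymmetric or multi-state extensions.
* The bundled lycophyte distance table is transcribed from a published
  printed table of 15 taxa; correlations computed from it reflect that
  table as printed.
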