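# plastevo

Structural evolution of plastid genomes (plastomes), built for lineages —
like the spikemoss family Selaginellaceae — whose plastomes carry a pair of
large **direct** repeats (DR) instead of the canonical **inverted** repeats
(IR), and where repeat-mediated homologous recombination turns a single
assembled genome into a dynamic population of isomers and subgenomic
molecules.

The package provides, as plain library functions plus a thin `plastevo` CLI:

* **Genome model & I/O** — circular/linear records with gene, repeat-copy and
  region features (FASTA + GFF3), Table-style summaries (size, distinct gene
  counts with duplicates, GC content), and gene presence/absence matrices.
* **Rearrangement distances** — gene orders encoded as signed permutations of
  locally collinear blocks; breakpoint distance BP and exact signed inversion
  distance IV via the Hannenhalli–Pevzner formula
  `d = (n+1) − c + h + f` (cycles, hurdles, fortress), with a BFS oracle,
  optimal sorting scenarios, and pairwise "BP/IV" distance tables.
* **Repeat detection** — all maximal exact repeat pairs > 15 bp, direct and
  inverted, circular wrap respected, tandem arrays collapsed to
  unit × copy-count.
* **Recombination model** — the core of the package: from a master
  chromosome, recombination between *inverted* repeat copies flips the arc
  between them (a full-length isomer), and between *direct* copies excises
  two subgenomic circles. Breadth-first closure of these events gives the
  reachable molecule population, classifying a plastome as `DR_only`,
  `IR_only`, or `IRDR_coexisting`, with uniform equilibrium stoichiometry
  over full-length isomers.
* **Substitution rates** — pairwise maximum-likelihood (t, κ, ω) under a
  GY94-type 61×61 codon model with F3×4 frequencies (genetic code 11), dN/dS
  by flux partitioning; a Nei–Gojobori (1986) counting estimator as a
  cross-check; Wilcoxon rank-sum contrasts between structural classes and
  between genes inside/outside a rearranged region.
* **Trait analysis** — 2-state symmetric Mk ancestral-state reconstruction
  (Felsenstein pruning, marginal states at every node, summaries over tree
  samples), Pearson correlation, and phylogenetically independent contrasts
  with through-origin correlation.
* **Synthetic data** — generators for every input: plastome architectures
  with planted repeat pairs, inversion histories, codon pairs with known
  (t, κ, ω), Yule trees, Mk characters, Brownian tip values. All generators
  are deterministic given a seed.

## Worked example

Simulate an IR-structured master chromosome with a second small inverted
repeat pair (one copy in each single-copy region) and enumerate its
recombination products:

```python
from plastevo.simulate import ArchitectureSpec, simulate_architecture
from plastevo.recombination import (
    classify_master_structure, enumerate_forms, classify_dynamic,
)

spec = ArchitectureSpec(
    big_repeat={"length": 12_800, "orientation": "inverted"},
    small_repeat={"length": 2_700, "orientation": "inverted"},
    lsc_bp=52_000, ssc_bp=41_000, gc_target=0.549, seed=42,
)
rec = simulate_architecture(spec)
print("genome:", len(rec.sequence), "bp")
print("master structure:", classify_master_structure(rec))
graph = enumerate_forms(rec)
print("full-length isomers:", len(graph.full_length_forms()))
print("subgenomic molecules:", len(graph.subgenomic_forms()))
print("dynamic class:", classify_dynamic(graph))
```

prints

```
genome: 118600 bp
master structure: IR
full-length isomers: 3
subgenomic molecules: 2
dynamic class: IRDR_coexisting
```

Reading the output: the master carries the large pair inverted (IR).
Recombination across the large IR flips one single-copy region, turning the
small pair direct (isomer I); recombination across the small IR instead turns
the large pair direct (isomer II) — three full-length isomers in all, at
equal expected stoichiometry. Each isomer with a direct pair then excises two
subgenomic circles; the two excision routes yield the same two physical
molecules (a circle and its reverse complement are one molecule), so two
distinct subgenomes coexist with the isomers. Because reachable forms include
both orientations of the large pair, the plastome is classified
IR/DR-coexisting.

The same stages are scriptable from the shell:

```
plastevo simulate --config arch.yaml --seed 42 --out run/
plastevo classify  --genome run/genome.fasta run/genome.gff3
plastevo enumerate --genome run/genome.fasta run/genome.gff3 --out run/
plastevo repeats   --genome run/genome.fasta run/genome.gff3
plastevo distances --perms perms.tsv
```

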