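"""Synthetic data generation for every pipeline stage.

Generates circular plastome architectures with planted repeat pairs (the
large DR/IR pair separating two single-copy regions, plus an optional small
psbK–trnQ-like pair with one copy per single-copy region), inversion
histories over signed block permutations, codon sequence pairs evolved under
the GY94 model with known (t, kappa, omega), Yule trees, binary characters
under the 2-state symmetric Markov (Mk) model, and Brownian tip values.

Every generator is deterministic given its seed. Defaults emulate
Selaginellaceae-like plastomes: ~110–147 kb circles, a 7–17 kb repeat pair,
GC around 0.51–0.56.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from . import codons
from .genome import Feature, GenomeRecord
from .rearrangement import SignedPermutation, _reversal

__all__ = [
    "ArchitectureSpec",
    "InversionHistory",
    "simulate_architecture",
    "simulate_inversion_history",
    "simulate_codon_pair",
    "simulate_yule_tree",
    "simulate_binary_character",
    "simulate_brownian",
    "fixture_figure5",
]


@dataclass
class RepeatSpec:
    length: int
    orientation: str  # direct | inverted

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("repeat length must be positive")
        if self.orientation not in ("direct", "inverted"):
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass
class ArchitectureSpec:
    big_repeat: RepeatSpec
    lsc_bp: int = 50_000
    ssc_bp: int = 52_000
    small_repeat: RepeatSpec | None = None
    gc_target: float = 0.529
    n_genes: int = 0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.big_repeat, dict):
            self.big_repeat = RepeatSpec(**self.big_repeat)
        if isinstance(self.small_repeat, dict):
            self.small_repeat = RepeatSpec(**self.small_repeat)
        if self.lsc_bp <= 0 or self.ssc_bp <= 0:
            raise ValueError("single-copy regions must be positive")
        if not 0 < self.gc_target < 1:
            raise ValueError("gc_target must be in (0, 1)")
        if self.small_repeat is not None:
            # one small copy sits inside each single-copy region
            if self.small_repeat.length * 2 >= min(self.lsc_bp, self.ssc_bp):
                raise ValueError("small repeat does not fit inside the SC regions")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, (1 - gc) / 2, gc / 2, gc / 2])
    return "".join(np.array(list("ATGC"))[rng.choice(4, size=n, p=p)])


_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_architecture(spec: ArchitectureSpec) -> GenomeRecord:
    """Build a circular master chromosome from an architecture spec.

    Layout (clockwise): LSC1, [small copy A], LSC2, big copy A, SSC1,
    [small copy B], SSC2, big copy B. The second copy of a pair is the
    reverse complement of the first iff the pair is inverted. Optionally
    plants ``n_genes`` uniformly through the single-copy regions for
    gene-order encoding.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_target
    big = _random_seq(rng, spec.big_repeat.length, gc)
    big_b = big if spec.big_repeat.orientation == "direct" else _rc(big)

    small = small_b = ""
    if spec.small_repeat is not None:
        small = _random_seq(rng, spec.small_repeat.length, gc)
        small_b = small if spec.small_repeat.orientation == "direct" else _rc(small)

    lsc_flank = spec.lsc_bp - len(small)
    ssc_flank = spec.ssc_bp - len(small_b)
    lsc1 = _random_seq(rng, lsc_flank // 2, gc)
    lsc2 = _random_seq(rng, lsc_flank - len(lsc1), gc)
    ssc1 = _random_seq(rng, ssc_flank // 2, gc)
    ssc2 = _random_seq(rng, ssc_flank - len(ssc1), gc)

    chunks, features = [], []
    cursor = 0

    def emit(seq, feat=None):
        nonlocal cursor
        chunks.append(seq)
        if feat is not None:
            fid, kind, strand, attrs = feat
            features.append(
                Feature(fid, kind, cursor, cursor + len(seq), strand, attrs)
            )
        cursor += len(seq)

    lsc_start = cursor
    emit(lsc1)
    if small:
        emit(small, ("small_A", "repeat_copy", "+", {"pair_id": "small"}))
    emit(lsc2)
    features.append(
        Feature("LSC", "region", lsc_start, cursor, "+", {"region_name": "LSC"})
    )
    big_kind = "DR" if spec.big_repeat.orientation == "direct" else "IR"
    emit(
        big,
        (
            f"{big_kind}_A",
            "repeat_copy",
            "+",
            {"pair_id": "big", "region_name": f"{big_kind}_A"},
        ),
    )
    ssc_start = cursor
    emit(ssc1)
    if small_b:
        strand = "+" if spec.small_repeat.orientation == "direct" else "-"
        emit(small_b, ("small_B", "repeat_copy", strand, {"pair_id": "small"}))
    emit(ssc2)
    features.append(
        Feature("SSC", "region", ssc_start, cursor, "+", {"region_name": "SSC"})
    )
    strand_b = "+" if spec.big_repeat.orientation == "direct" else "-"
    emit(
        big_b,
        (
            f"{big_kind}_B",
            "repeat_copy",
            strand_b,
            {"pair_id": "big", "region_name": f"{big_kind}_B"},
        ),
    )

    sequence = _break_flank_extensions("".join(chunks), features)
    record = GenomeRecord(
        id=f"synthetic_{big_kind.lower()}_{spec.seed}",
        sequence=sequence,
        topology="circular",
        features=features,
    )
    if spec.n_genes:
        _plant_genes(record, spec.n_genes)
    record.validate()
    return record


def _break_flank_extensions(sequence: str, features: list) -> str:
    """Make planted repeat copies exactly maximal.

    A chance match of the bases flanking two copies would let detection
    extend the pair beyond the planted interval; nudge one flank base so the
    planted coordinates are the maximal ones.
    """
    seq = list(sequence)
    L = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    nxt = {"A": "C", "C": "G", "G": "T", "T": "A"}
    by_pair: dict[str, list] = {}
    for f in features:
        pid = f.attributes.get("pair_id")
        if pid is not None:
            by_pair.setdefault(pid, []).append(f)
    for copies in by_pair.values():
        if len(copies) != 2:
            continue
        a, b = sorted(copies, key=lambda f: f.start)
        direct = a.strand == b.strand
        if direct:
            constraints = [
                ((a.start - 1) % L, (b.start - 1) % L, False),
                (a.end % L, b.end % L, False),
            ]
        else:
            constraints = [
                (a.end % L, (b.start - 1) % L, True),
                ((a.start - 1) % L, b.end % L, True),
            ]
        for p, q, complemented in constraints:
            other = comp[seq[p]] if complemented else seq[p]
            if seq[q] == other:
                seq[q] = nxt[seq[q]]
    return "".join(seq)


def _plant_genes(record: GenomeRecord, n_genes: int) -> None:
    """Place gene features evenly through the single-copy regions."""
    sc = [f for f in record.features if f.attributes.get("region_name") in ("LSC", "SSC")]
    repeat_spans = [
        (f.start, f.end) for f in record.features_of_kind("repeat_copy")
    ]
    slots = []
    for region in sc:
        length = region.end - region.start
        k = max(1, round(n_genes * length / sum(r.end - r.start for r in sc)))
        step = length // (k + 1)
        for i in range(1, k + 1):
            pos = region.start + i * step
            if any(s <= pos < e or s < pos + 60 <= e for s, e in repeat_spans):
                continue
            slots.append(pos)
    for idx, pos in enumerate(slots[:n_genes], start=1):
        record.features.append(
            Feature(
                f"g{idx:03d}",
                "gene",
                pos,
                pos + 60,
                "+",
                {"gene": f"g{idx:03d}"},
            )
        )


def genes_in_order(record: GenomeRecord) -> list:
    return sorted(
        record.features_of_kind("gene"), key=lambda f: (f.start, f.end)
    )


@dataclass
class InversionHistory:
    start_perm: SignedPermutation
    events: list
    end_perm: SignedPermutation
    seed: int


def simulate_inversion_history(
    start: SignedPermutation, k: int, seed: int = 0
) -> InversionHistory:
    """Apply k uniformly chosen index-range reversals to a signed permutation."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    rng = np.random.default_rng(seed)
    blocks = tuple(start.blocks)
    n = len(blocks)
    events = []
    for _ in range(k):
        i, j = sorted(rng.integers(0, n, size=2))
        events.append((int(i), int(j)))
        blocks = _reversal(blocks, int(i), int(j))
    end = SignedPermutation(f"{start.taxon}_derived", blocks, start.frame)
    return InversionHistory(start_perm=start, events=events, end_perm=end, seed=seed)


def simulate_codon_pair(
    t: float,
    kappa: float,
    omega: float,
    n_codons: int,
    freqs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[str, str]:
    """Ancestor/descendant codon sequences under the GY94 model.

    The ancestor is drawn from ``freqs`` (61 sense codons, default uniform);
    the descendant evolves for ``t`` expected substitutions per codon under
    the mean-rate-1 generator. No internal stops by construction.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    pi = codons.uniform_frequencies() if freqs is None else np.asarray(freqs, float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("codon frequencies must be nonnegative and sum to 1")
    rng = np.random.default_rng(seed)
    anc_idx = rng.choice(len(codons.SENSE_CODONS), size=n_codons, p=pi)
    if t == 0:
        anc = "".join(codons.SENSE_CODONS[i] for i in anc_idx)
        return anc, anc
    Q = codons.gy94_generator(kappa, omega, pi)
    P = codons.SpectralGenerator(Q, pi).transition_matrix(t)
    cum = np.cumsum(P, axis=1)
    u = rng.random(n_codons)
    des_idx = np.array(
        [np.searchsorted(cum[i], x) for i, x in zip(anc_idx, u)]
    )
    anc = "".join(codons.SENSE_CODONS[i] for i in anc_idx)
    des = "".join(codons.SENSE_CODONS[min(i, 60)] for i in des_idx)
    return anc, des


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Rooted binary pure-birth (Yule) tree, tips labelled t1..tn.

    Forward construction: k active lineages split after Exp(k*birth) waits;
    after the n-th lineage appears the process runs for one further
    Exp(n*birth) wait so every pendant edge has positive length.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    c1, c2 = dendropy.Node(), dendropy.Node()
    root.add_child(c1)
    root.add_child(c2)
    t = 0.0
    active = [c1, c2]
    for node in active:
        node.birth_time = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        parent = active.pop(rng.integers(k))
        parent.edge.length = t - parent.birth_time
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            parent.add_child(child)
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    order = rng.permutation(n_tips)
    for idx, node in zip(order, active):
        node.edge.length = t - node.birth_time
        node.taxon = taxa[int(idx)]
    tree.seed_node.edge.length = 0.0
    return tree


def simulate_binary_character(
    tree: dendropy.Tree,
    rate: float,
    root_state: str = "DR",
    seed: int = 0,
    states: tuple = ("IR", "DR"),
) -> dict:
    """Evolve a 2-state symmetric Markov character down the tree.

    P(change over branch b) = (1 - exp(-2*rate*b)) / 2. Returns
    {tip label: state}.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if root_state not in states:
        raise ValueError(f"root_state must be one of {states}")
    rng = np.random.default_rng(seed)
    other = {states[0]: states[1], states[1]: states[0]}
    node_state = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_state[node] = root_state
        else:
            b = node.edge.length or 0.0
            p_change = 0.5 * (1.0 - np.exp(-2.0 * rate * b))
            parent = node_state[node.parent_node]
            node_state[node] = other[parent] if rng.random() < p_change else parent
        if node.is_leaf():
            out[node.taxon.label] = node_state[node]
    return out


def simulate_brownian(tree: dendropy.Tree, seed: int = 0, rate: float = 1.0) -> dict:
    """Brownian-motion tip values (root value 0, variance = rate * path length)."""
    rng = np.random.default_rng(seed)
    value = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            value[node] = 0.0
        else:
            b = node.edge.length or 0.0
            value[node] = value[node.parent_node] + rng.normal(0.0, np.sqrt(rate * b))
        if node.is_leaf():
            out[node.taxon.label] = value[node]
    return out


def fixture_figure5(scale: float = 1.0, seed: int = 5) -> dict:
    """Three reference architectures for the recombination model.

    * ``DR_only`` — large direct pair, no small pair (S. vardei-like).
    * ``IRDR_uncinata`` — large inverted pair plus a ~2.7-kb inverted small
      pair with one copy per single-copy region (S. uncinata-like).
    * ``DRIR_bisulcata`` — large direct pair plus a ~1.8-kb inverted small
      pair (S. bisulcata-like).

    ``scale`` shrinks all region lengths for fast tests.
    """

    def sz(n):
        return max(64, int(n * scale))

    specs = {
        "DR_only": ArchitectureSpec(
            big_repeat=RepeatSpec(sz(13_000), "direct"),
            lsc_bp=sz(46_000),
            ssc_bp=sz(48_000),
            gc_target=0.532,
            seed=seed,
        ),
        "IRDR_uncinata": ArchitectureSpec(
            big_repeat=RepeatSpec(sz(12_800), "inverted"),
            small_repeat=RepeatSpec(sz(2_700), "inverted"),
            lsc_bp=sz(52_000),
            ssc_bp=sz(41_000),
            gc_target=0.549,
            seed=seed + 1,
        ),
        "DRIR_bisulcata": ArchitectureSpec(
            big_repeat=RepeatSpec(sz(12_600), "direct"),
            small_repeat=RepeatSpec(sz(1_800), "inverted"),
            lsc_bp=sz(55_600),
            ssc_bp=sz(59_700),
            gc_target=0.528,
            seed=seed + 2,
        ),
    }
    out = {}
    for name, spec in specs.items():
        rec = simulate_architecture(spec)
        rec.id = name
        out[name] = rec
    return out
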