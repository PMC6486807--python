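"""Repeat-mediated homologous recombination on circular plastomes.

A plastome with a pair of large repeats supports intramolecular recombination
between the copies. If the copies are inverted relative to each other the
event flips the arc between them (a full-length isomer); if they are direct
it excises the arc into two subgenomic circles, each retaining one repeat
copy. Enumerating the closure of these events from the assembled master
chromosome yields the reachable molecule population, and classifies the
plastome as DR, IR, or IR/DR-coexisting.

Molecules are modelled at segment resolution: a circular ordered list of
(segment_id, orientation) tokens delimited by repeat copies. Copies of a pair
share a token. Canonical keys are invariant under rotation and reflection
(reversal with all orientations flipped) — the reverse complement of a DNA
circle is the same physical molecule.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .genome import GenomeRecord
from .repeats import large_repeat_pair

__all__ = [
    "MoleculeForm",
    "RecombinationEvent",
    "StateGraph",
    "classify_master_structure",
    "flip",
    "split",
    "enumerate_forms",
    "classify_dynamic",
    "stoichiometry",
    "master_form_from_record",
]

MAX_FORMS = 10_000


@dataclass(frozen=True)
class MoleculeForm:
    segments: tuple  # ((segment_id, +1/-1), ...)
    kind: str = "full_length"  # full_length | subgenomic

    def __post_init__(self):
        if self.kind not in ("full_length", "subgenomic"):
            raise ValueError(f"unknown molecule kind {self.kind!r}")
        object.__setattr__(
            self, "segments", tuple((str(s), int(o)) for s, o in self.segments)
        )

    @property
    def canonical_key(self) -> str:
        return _canonical_key(self.segments)

    def pair_positions(self, pair_id: str) -> list:
        return [i for i, (s, _) in enumerate(self.segments) if s == pair_id]

    def pair_orientation(self, pair_id: str) -> str:
        pos = self.pair_positions(pair_id)
        if len(pos) != 2:
            raise ValueError(f"pair {pair_id!r} does not have two copies on this form")
        i, j = pos
        return "direct" if self.segments[i][1] == self.segments[j][1] else "inverted"

    def segment_multiset(self):
        from collections import Counter

        return Counter(s for s, _ in self.segments)


def _canonical_key(segments: tuple) -> str:
    def render(segs):
        return "|".join(f"{s}{'+' if o > 0 else '-'}" for s, o in segs)

    n = len(segments)
    reflected = tuple((s, -o) for s, o in reversed(segments))
    best = None
    for base in (segments, reflected):
        for r in range(n):
            cand = render(base[r:] + base[:r])
            if best is None or cand < best:
                best = cand
    return best


@dataclass(frozen=True)
class RecombinationEvent:
    type: str  # flip | split
    pair_id: str
    parent: str
    children: tuple

    def __post_init__(self):
        if self.type == "flip" and len(self.children) != 1:
            raise ValueError("flip yields exactly one child")
        if self.type == "split" and len(self.children) != 2:
            raise ValueError("split yields exactly two children")


@dataclass
class StateGraph:
    forms: dict  # canonical_key -> MoleculeForm
    events: set  # of RecombinationEvent
    master_key: str
    big_pair_id: str

    def full_length_forms(self) -> list:
        return [f for f in self.forms.values() if f.kind == "full_length"]

    def subgenomic_forms(self) -> list:
        return [f for f in self.forms.values() if f.kind == "subgenomic"]

    def to_json_dict(self) -> dict:
        return {
            "master": self.master_key,
            "big_pair": self.big_pair_id,
            "forms": [
                {
                    "key": k,
                    "kind": f.kind,
                    "segments": [[s, o] for s, o in f.segments],
                }
                for k, f in sorted(self.forms.items())
            ],
            "events": [
                {
                    "type": e.type,
                    "pair": e.pair_id,
                    "parent": e.parent,
                    "children": list(e.children),
                }
                for e in sorted(
                    self.events, key=lambda e: (e.type, e.pair_id, e.parent)
                )
            ],
        }

    def to_dot(self) -> str:
        lines = ["digraph stategraph {"]
        for k, f in sorted(self.forms.items()):
            shape = "ellipse" if f.kind == "full_length" else "box"
            label = k.replace("|", "\\n")
            lines.append(f'  "{k}" [shape={shape}, label="{label}"];')
        for e in sorted(self.events, key=lambda e: (e.type, e.pair_id, e.parent)):
            style = "dir=both" if e.type == "flip" else "style=dashed"
            for child in e.children:
                lines.append(f'  "{e.parent}" -> "{child}" [{style}, label="{e.pair_id}"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def classify_master_structure(record: GenomeRecord, min_len: int = 1000) -> str:
    """DR if the two copies of the largest repeat pair are co-oriented, else IR."""
    pair = large_repeat_pair(record, min_len=min_len)
    return "DR" if pair.strand_a == pair.strand_b else "IR"


def flip(form: MoleculeForm, pair_id: str) -> MoleculeForm:
    """Recombination between inverted copies: reverse the arc strictly between
    them, negating orientations. Either arc gives the same canonical circle."""
    if form.pair_orientation(pair_id) != "inverted":
        raise ValueError(f"pair {pair_id!r} is not inverted on this form")
    i, j = form.pair_positions(pair_id)
    segs = form.segments
    arc = tuple((s, -o) for s, o in reversed(segs[i + 1 : j]))
    new = segs[: i + 1] + arc + segs[j:]
    return MoleculeForm(new, kind=form.kind)


def split(form: MoleculeForm, pair_id: str) -> tuple[MoleculeForm, MoleculeForm]:
    """Recombination between direct copies: excise into two circles, each
    keeping one repeat copy and one of the two arcs."""
    if form.pair_orientation(pair_id) != "direct":
        raise ValueError(f"pair {pair_id!r} is not direct on this form")
    i, j = form.pair_positions(pair_id)
    segs = form.segments
    child_a = (segs[i],) + segs[i + 1 : j]
    child_b = (segs[j],) + segs[j + 1 :] + segs[:i]
    return (
        MoleculeForm(child_a, kind="subgenomic"),
        MoleculeForm(child_b, kind="subgenomic"),
    )


def _pairs_on(form: MoleculeForm) -> list:
    from collections import Counter

    counts = Counter(s for s, _ in form.segments)
    return sorted(s for s, c in counts.items() if c == 2 and s.startswith("R:"))


def master_form_from_record(record: GenomeRecord) -> MoleculeForm:
    """Segment the master circle at annotated repeat-copy boundaries.

    Repeat copies become pair tokens ``R:<pair_id>`` (orientation from
    strand); the arcs between them become unique ``A<n>`` tokens.
    """
    copies = [
        f
        for f in record.features_of_kind("repeat_copy")
        if f.attributes.get("pair_id")
    ]
    if not copies:
        raise ValueError("record has no annotated repeat copies")
    for f in copies:
        if f.wrap:
            raise ValueError("wrapped repeat copies are not supported here")
    copies.sort(key=lambda f: f.start)
    segments = []
    arc_n = 0
    L = len(record.sequence)
    for idx, f in enumerate(copies):
        segments.append((f"R:{f.attributes['pair_id']}", 1 if f.strand == "+" else -1))
        nxt = copies[(idx + 1) % len(copies)]
        gap_start, gap_end = f.end, nxt.start if idx + 1 < len(copies) else nxt.start + L
        if gap_end > gap_start:
            arc_n += 1
            segments.append((f"A{arc_n}", 1))
    return MoleculeForm(tuple(segments), kind="full_length")


def enumerate_forms(master, big_pair_id: str | None = None) -> StateGraph:
    """Breadth-first closure of flips and splits from the master chromosome.

    ``master`` may be a GenomeRecord with annotated repeat copies or a
    MoleculeForm. Forms are deduplicated by canonical key; subgenomic
    molecules are terminal.
    """
    if isinstance(master, GenomeRecord):
        if big_pair_id is None:
            big_pair_id = f"R:{large_repeat_pair(master, min_len=1).pair_id}"
        master = master_form_from_record(master)
    elif big_pair_id is None:
        pairs = _pairs_on(master)
        if not pairs:
            raise ValueError("form carries no repeat pairs")
        big_pair_id = pairs[0]

    master_key = master.canonical_key
    forms = {master_key: master}
    events = set()
    queue = deque([master])
    while queue:
        form = queue.popleft()
        if form.kind != "full_length":
            continue
        key = form.canonical_key
        for pid in _pairs_on(form):
            if form.pair_orientation(pid) == "inverted":
                child = flip(form, pid)
                ck = child.canonical_key
                events.add(RecombinationEvent("flip", pid, key, (ck,)))
                if ck not in forms:
                    forms[ck] = child
                    queue.append(child)
            else:
                c1, c2 = split(form, pid)
                k1, k2 = c1.canonical_key, c2.canonical_key
                events.add(RecombinationEvent("split", pid, key, tuple(sorted((k1, k2)))))
                for c, ck in ((c1, k1), (c2, k2)):
                    if ck not in forms:
                        forms[ck] = c
            if len(forms) > MAX_FORMS:
                raise RuntimeError("state space exceeds form limit; runaway input")
    return StateGraph(forms=forms, events=events, master_key=master_key, big_pair_id=big_pair_id)


def classify_dynamic(graph: StateGraph) -> str:
    """DR_only / IR_only / IRDR_coexisting from the reachable full-length forms."""
    orientations = set()
    for f in graph.full_length_forms():
        try:
            orientations.add(f.pair_orientation(graph.big_pair_id))
        except ValueError:  # big pair absent from a degenerate form
            continue
    if orientations == {"direct", "inverted"}:
        return "IRDR_coexisting"
    if orientations == {"direct"}:
        return "DR_only"
    if orientations == {"inverted"}:
        return "IR_only"
    raise ValueError("cannot classify: big pair not found on full-length forms")


def stoichiometry(graph: StateGraph) -> dict:
    """Uniform equilibrium over full-length isomers (highly efficient
    reciprocal recombination); fractions sum to 1."""
    full = graph.full_length_forms()
    if not full:
        raise ValueError("empty graph")
    share = 1.0 / len(full)
    return {f.canonical_key: share for f in full}
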