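"""Annotated genome data model and FASTA/GFF3 I/O.

The unit of structural analysis is a :class:`GenomeRecord`: a single circular
or linear DNA sequence carrying gene, repeat-copy, and region features.
Coordinates are 0-based half-open internally; GFF3 on disk is 1-based
inclusive. A feature spanning the origin of a circular record is stored with
``wrap=True`` and ``start > end`` (interval ``[start, L) + [0, end)``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Feature",
    "GenomeRecord",
    "GenomeSummary",
    "read_genome",
    "write_genome",
    "gc_content",
    "genome_summary",
    "gene_presence_matrix",
    "normalize_gene_name",
]

FEATURE_KINDS = ("gene", "repeat_copy", "region")
GENE_STATUSES = ("intact", "pseudo", "intron_lost", "absent")

# GFF3 column-3 type <-> internal feature kind
_KIND_TO_GFF = {"gene": "gene", "repeat_copy": "repeat_region", "region": "region"}
_GFF_TO_KIND = {v: k for k, v in _KIND_TO_GFF.items()}


@dataclass
class Feature:
    id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)
    wrap: bool = False

    def length(self, seq_len: int | None = None) -> int:
        if self.wrap:
            if seq_len is None:
                raise ValueError("wrapped feature length needs sequence length")
            return (seq_len - self.start) + self.end
        return self.end - self.start

    def validate(self, seq_len: int, topology: str) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} on feature {self.id}")
        if self.wrap:
            if topology != "circular":
                raise ValueError(f"wrapped feature {self.id} on a linear record")
            if not (0 <= self.end <= self.start <= seq_len):
                raise ValueError(f"bad wrapped interval on feature {self.id}")
        else:
            if not (0 <= self.start < self.end <= seq_len):
                raise ValueError(
                    f"feature {self.id} interval [{self.start}, {self.end}) outside "
                    f"[0, {seq_len})"
                )


@dataclass
class GenomeRecord:
    id: str
    sequence: str
    topology: str = "circular"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
        seen = set()
        for f in self.features:
            if f.id in seen:
                raise ValueError(f"duplicate feature id {f.id!r}")
            seen.add(f.id)
            f.validate(len(self.sequence), self.topology)

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def feature_sequence(self, feat: Feature) -> str:
        if feat.wrap:
            raw = self.sequence[feat.start :] + self.sequence[: feat.end]
        else:
            raw = self.sequence[feat.start : feat.end]
        if feat.strand == "-":
            raw = str(Seq(raw).reverse_complement())
        return raw

    def copy(self) -> "GenomeRecord":
        return GenomeRecord(
            id=self.id,
            sequence=self.sequence,
            topology=self.topology,
            features=[replace(f, attributes=dict(f.attributes)) for f in self.features],
        )


@dataclass
class GenomeSummary:
    id: str
    size_bp: int
    n_genes: int
    n_protein_coding: int
    n_trna: int
    n_rrna: int
    n_protein_duplicated: int
    n_trna_duplicated: int
    n_rrna_duplicated: int
    gc: float
    repeat_region_bp: int


def normalize_gene_name(name: str) -> str:
    """Lower-case and strip a trailing copy suffix like ``_1`` / ``_2``."""
    name = name.strip().lower()
    head, sep, tail = name.rpartition("_")
    if sep and tail.isdigit():
        return head
    return name


def gene_class(name: str) -> str:
    n = normalize_gene_name(name)
    if n.startswith("trn"):
        return "trna"
    if n.startswith("rrn"):
        return "rrna"
    return "protein_coding"


def gc_content(record: GenomeRecord) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    counts = Counter(record.sequence.upper())
    denom = sum(counts[b] for b in "ACGT")
    if denom == 0:
        raise ValueError("empty or all-N sequence")
    return (counts["G"] + counts["C"]) / denom


def genome_summary(record: GenomeRecord) -> GenomeSummary:
    """Per-genome summary: size, distinct gene counts, duplicates, GC, repeat span.

    A gene annotated in both repeat copies counts once among "different genes";
    the extra copies are reported in the duplicated columns. Pseudogenes
    (``status=pseudo``) are excluded from the distinct-gene counts.
    """
    by_class: dict[str, Counter] = {
        "protein_coding": Counter(),
        "trna": Counter(),
        "rrna": Counter(),
    }
    for f in record.features_of_kind("gene"):
        status = f.attributes.get("status", "intact")
        if status not in GENE_STATUSES:
            raise ValueError(f"unknown gene status {status!r} on {f.id}")
        if status in ("pseudo", "absent"):
            continue
        name = normalize_gene_name(f.attributes.get("gene", f.id))
        by_class[gene_class(name)][name] += 1

    def distinct(cls: str) -> int:
        return len(by_class[cls])

    def duplicated(cls: str) -> int:
        return sum(1 for n, c in by_class[cls].items() if c > 1)

    repeat_bp = sum(
        f.length(len(record.sequence)) for f in record.features_of_kind("repeat_copy")
    )
    n_p, n_t, n_r = distinct("protein_coding"), distinct("trna"), distinct("rrna")
    return GenomeSummary(
        id=record.id,
        size_bp=len(record.sequence),
        n_genes=n_p + n_t + n_r,
        n_protein_coding=n_p,
        n_trna=n_t,
        n_rrna=n_r,
        n_protein_duplicated=duplicated("protein_coding"),
        n_trna_duplicated=duplicated("trna"),
        n_rrna_duplicated=duplicated("rrna"),
        gc=gc_content(record),
        repeat_region_bp=repeat_bp,
    )


def summaries_to_tsv(summaries: list[GenomeSummary]) -> str:
    header = "id\tsize_bp\tn_genes\tn_protein\tn_trna\tn_rrna\tgc\trepeat_region_bp"
    lines = [header]
    for s in summaries:
        lines.append(
            f"{s.id}\t{s.size_bp}\t{s.n_genes}\t{s.n_protein_coding}\t{s.n_trna}"
            f"\t{s.n_rrna}\t{s.gc:.4f}\t{s.repeat_region_bp}"
        )
    return "\n".join(lines) + "\n"


def gene_presence_matrix(
    records: list[GenomeRecord], gene_universe: list[str]
) -> pd.DataFrame:
    """Species x gene matrix of {intact, pseudo, intron_lost, absent}.

    Gene ids are matched case-insensitively after copy-suffix stripping; the
    state is read from the feature attribute ``status`` (default ``intact``).
    """
    universe = [normalize_gene_name(g) for g in gene_universe]
    rows = {}
    for rec in records:
        state = dict.fromkeys(universe, "absent")
        for f in rec.features_of_kind("gene"):
            name = normalize_gene_name(f.attributes.get("gene", f.id))
            if name not in state:
                continue
            status = f.attributes.get("status", "intact")
            if status not in GENE_STATUSES:
                raise ValueError(f"unknown gene status {status!r} on {f.id}")
            # an intact copy anywhere outranks pseudo/absent annotations
            rank = {"absent": 0, "pseudo": 1, "intron_lost": 2, "intact": 3}
            if rank[status] > rank[state[name]]:
                state[name] = status
        rows[rec.id] = state
    return pd.DataFrame.from_dict(rows, orient="index", columns=universe)


# ---------------------------------------------------------------------------
# FASTA + GFF3 I/O
# ---------------------------------------------------------------------------


def read_genome(seq_path, ann_path) -> GenomeRecord:
    """Read one FASTA record plus its GFF3 annotation into a GenomeRecord.

    GFF3 1-based inclusive coordinates become 0-based half-open. Topology is
    circular iff the landmark ``region`` feature carries ``Is_circular=true``.
    Two GFF3 lines sharing an ID that abut the origin are merged into a single
    wrapped feature.
    """
    fasta = list(SeqIO.parse(str(seq_path), "fasta"))
    if len(fasta) != 1:
        raise ValueError(f"expected exactly one FASTA record, got {len(fasta)}")
    seq_id = fasta[0].id
    sequence = str(fasta[0].seq).upper()

    db = gffutils.create_db(
        str(ann_path),
        dbfn=":memory:",
        from_string=False,
        merge_strategy="create_unique",
        keep_order=True,
    )
    topology = "linear"
    parts: dict[str, list] = {}
    for gf in db.all_features(order_by=("seqid", "start")):
        if gf.seqid != seq_id:
            raise ValueError(f"GFF3 seqid {gf.seqid!r} does not match FASTA id {seq_id!r}")
        if gf.featuretype == "region" and "Is_circular" in gf.attributes:
            # landmark line: carries topology, is not a record feature
            circ = gf.attributes["Is_circular"][0].lower()
            if circ == "true":
                topology = "circular"
            continue
        kind = _GFF_TO_KIND.get(gf.featuretype)
        if kind is None:
            continue
        if gf.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {gf.strand!r} in GFF3 feature")
        raw_id = gf.attributes.get("ID", [gf.id])[0]
        attrs = {
            k: v[0]
            for k, v in gf.attributes.items()
            if k not in ("ID",) and v
        }
        parts.setdefault(raw_id, []).append(
            (gf.start - 1, gf.end, gf.strand, kind, attrs)
        )

    features = []
    L = len(sequence)
    for fid, pieces in parts.items():
        if len(pieces) == 1:
            s, e, strand, kind, attrs = pieces[0]
            features.append(Feature(fid, kind, s, e, strand, attrs))
        elif len(pieces) == 2:
            pieces.sort()
            (s1, e1, st1, k1, a1), (s2, e2, st2, k2, a2) = pieces
            if s1 == 0 and e2 == L and st1 == st2 and k1 == k2:
                features.append(
                    Feature(fid, k1, s2, e1, st1, {**a2, **a1}, wrap=True)
                )
            else:
                raise ValueError(f"feature {fid!r} split but does not wrap the origin")
        else:
            raise ValueError(f"feature {fid!r} has {len(pieces)} parts")
    features.sort(key=lambda f: (f.start, f.end))
    return GenomeRecord(id=seq_id, sequence=sequence, topology=topology, features=features)


def _gff3_attr_str(fid: str, attrs: dict) -> str:
    parts = [f"ID={fid}"]
    for k, v in sorted(attrs.items()):
        parts.append(f"{k}={v}")
    return ";".join(parts)


def write_genome(record: GenomeRecord, seq_path, ann_path) -> None:
    """Write FASTA + GFF3 (wrapped features emitted as two lines sharing an ID)."""
    with open(seq_path, "w") as fh:
        fh.write(f">{record.id}\n")
        seq = record.sequence
        for i in range(0, len(seq), 70):
            fh.write(seq[i : i + 70] + "\n")

    L = len(record.sequence)
    lines = ["##gff-version 3", f"##sequence-region {record.id} 1 {L}"]
    circ = "true" if record.topology == "circular" else "false"
    lines.append(
        f"{record.id}\tplastevo\tregion\t1\t{L}\t.\t+\t.\t"
        f"ID={record.id}:region;Is_circular={circ}"
    )
    for f in sorted(record.features, key=lambda f: (f.start, f.end)):
        gtype = _KIND_TO_GFF[f.kind]
        attr = _gff3_attr_str(f.id, f.attributes)
        if f.wrap:
            lines.append(
                f"{record.id}\tplastevo\t{gtype}\t{f.start + 1}\t{L}\t.\t{f.strand}\t.\t{attr}"
            )
            lines.append(
                f"{record.id}\tplastevo\t{gtype}\t1\t{f.end}\t.\t{f.strand}\t.\t{attr}"
            )
        else:
            lines.append(
                f"{record.id}\tplastevo\t{gtype}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attr}"
            )
    with open(ann_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
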