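"""Detection of exact dispersed repeat pairs in plastome sequences.

Finds all maximal exact repeated pairs longer than a threshold (default
>15 bp), in both orientations (direct = same strand, inverted = reverse
complement), with circular wrap respected. Tandem arrays (copies overlapping
at a fixed period) are collapsed to one entry carrying the unit length and
copy number. Matching is exact (identity 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import GenomeRecord

__all__ = ["RepeatPair", "find_repeats", "repeat_summary", "large_repeat_pair"]

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class RepeatPair:
    pair_id: str
    start_a: int
    end_a: int
    strand_a: str
    start_b: int
    end_b: int
    strand_b: str
    length: int
    orientation: str  # direct | inverted
    identity: float = 1.0
    copies: int = 2
    unit_length: int | None = None  # set for collapsed tandem arrays

    def intervals(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (self.start_a, self.end_a), (self.start_b, self.end_b)


def _doubled(record: GenomeRecord) -> tuple[str, int]:
    """Sequence doubled for circular records so wrap-spanning copies extend."""
    seq = record.sequence.upper()
    if record.topology == "circular":
        return seq + seq, len(seq)
    return seq, len(seq)


def find_repeats(
    record: GenomeRecord, min_len: int = 15
) -> list[RepeatPair]:
    """All maximal exact repeat pairs of length > ``min_len``.

    Seed-and-extend over (min_len + 1)-mers; a hit is kept only if it cannot
    be extended by one base on either side (maximality). Direct pairs whose
    copies overlap with a fixed period are reported once as a tandem array.
    Reverse-complement palindromes at a single locus are excluded.
    """
    if min_len < 4:
        raise ValueError("min_len below seed width")
    L = len(record.sequence)
    if L < 2 * min_len:
        raise ValueError("sequence shorter than twice min_len")
    seq, L = _doubled(record)
    k = min_len + 1

    seeds: dict[str, list[int]] = {}
    for i in range(L):  # seed starts restricted to one genome copy
        seeds.setdefault(seq[i : i + k], []).append(i)

    found: dict[tuple, RepeatPair] = {}

    def extend(i: int, j: int, inverted: bool) -> None:
        """Maximally extend an exact match seeded at (i, j)."""
        if not inverted:
            # skip non-left-maximal seed pairs
            if i > 0 and j > 0 and seq[i - 1] == seq[j - 1]:
                return
            a0, b0, n = i, j, k
            while (
                i + n < len(seq)
                and j + n < len(seq)
                and seq[i + n] == seq[j + n]
                and j + n < i + 2 * L  # stay within one wrap of the circle
            ):
                n += 1
            a, b = a0 % L, b0 % L
            if (a, b) > (b, a):
                a, b = b, a
            key = ("D", a, b, n)
            if key in found:
                return
            if a == b:
                return
            period = b - a
            if period < n:  # overlapping copies: tandem array
                span_end = b + n
                tkey = ("T", a, span_end)
                prev = found.get(tkey)
                if prev is not None and prev.unit_length <= period:
                    return
                total = span_end - a
                copies = total // period
                found[tkey] = RepeatPair(
                    pair_id=f"tandem_{a}",
                    start_a=a,
                    end_a=a + period,
                    strand_a="+",
                    start_b=a + period,
                    end_b=a + 2 * period,
                    strand_b="+",
                    length=n,
                    orientation="direct",
                    copies=copies,
                    unit_length=period,
                )
            else:
                found[key] = RepeatPair(
                    pair_id=f"direct_{a}_{b}",
                    start_a=a,
                    end_a=a + n,
                    strand_a="+",
                    start_b=b,
                    end_b=b + n,
                    strand_b="+",
                    length=n,
                    orientation="direct",
                )
        else:
            # match: seq[i:i+n] == rc(seq[j:j+n]); extension moves j left
            n = k
            while (
                i + n < len(seq)
                and j - 1 >= 0
                and seq[i + n] == seq[j - 1].translate(_COMP)
            ):
                n += 1
                j -= 1
            # left-maximality of i / right side of j
            if i > 0 and j + n < len(seq) and seq[i - 1] == seq[j + n].translate(_COMP):
                return
            a, b = i % L, j % L
            if (a, b) > (b, a):
                (a, b) = (b, a)
            if a == b:
                return
            # overlapping palindromic hit at one locus
            ia, ib = sorted(((i % L), (j % L)))
            if ib < ia + n:
                return
            key = ("I", a, b, n)
            if key not in found:
                found[key] = RepeatPair(
                    pair_id=f"inverted_{a}_{b}",
                    start_a=a,
                    end_a=a + n,
                    strand_a="+",
                    start_b=b,
                    end_b=b + n,
                    strand_b="-",
                    length=n,
                    orientation="inverted",
                )

    # direct pairs
    for positions in seeds.values():
        if len(positions) < 2:
            continue
        for ii in range(len(positions)):
            for jj in range(ii + 1, len(positions)):
                i, j = positions[ii], positions[jj]
                if (j - i) % L == 0:
                    continue  # same locus seen through the doubling
                extend(i, j, inverted=False)

    # inverted pairs: find k-mers whose reverse complement also occurs.
    # Both (i, j) role assignments are tried: only the left-maximal one
    # extends to the full match, and the duplicate dedupes on its key.
    for kmer, positions in seeds.items():
        rk = _rc(kmer)
        if rk not in seeds:
            continue
        for i in positions:
            for j in seeds[rk]:
                if i != j:
                    extend(i, j, inverted=True)

    pairs = list(found.values())
    # suppress pairs that are internal self-matches of a tandem array
    spans = [
        (p.start_a, p.start_a + p.unit_length + p.length)
        for p in pairs
        if p.unit_length is not None
    ]
    pairs = [
        p
        for p in pairs
        if p.unit_length is not None
        or not any(
            s <= p.start_a and p.end_a <= e and s <= p.start_b and p.end_b <= e
            for s, e in spans
        )
    ]
    # drop pairs fully contained in a longer pair with the same copies
    pairs.sort(key=lambda p: -p.length)
    kept: list[RepeatPair] = []
    for p in pairs:
        contained = False
        for q in kept:
            if (
                q.orientation == p.orientation
                and q.start_a <= p.start_a
                and p.end_a <= q.end_a
                and q.start_b <= p.start_b
                and p.end_b <= q.end_b
            ):
                contained = True
                break
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.start_a, p.start_b))
    return kept


DEFAULT_BINS = ((15, 30), (30, 50), (50, None))


def repeat_summary(
    pairs: list[RepeatPair],
    size_bins=DEFAULT_BINS,
    exclude_over: int | None = 1000,
) -> dict:
    """Counts of repeat pairs per (size bin, orientation).

    Bins are (lo, hi] with hi=None meaning unbounded. Pairs at least
    ``exclude_over`` bp long (the large DR/IR pair itself) are left out of
    the dispersed-repeat statistics, mirroring removal of one repeat-region
    copy before counting; pass ``exclude_over=None`` to keep everything.
    """
    bins = list(size_bins)
    for i, (lo, hi) in enumerate(bins):
        if hi is not None and hi <= lo:
            raise ValueError("empty bin")
        for lo2, hi2 in bins[i + 1 :]:
            hi_eff = float("inf") if hi is None else hi
            hi2_eff = float("inf") if hi2 is None else hi2
            if max(lo, lo2) < min(hi_eff, hi2_eff):
                raise ValueError("overlapping bins")
    counted = [
        p for p in pairs if exclude_over is None or p.length < exclude_over
    ]
    counts = {
        (b, orient): 0 for b in bins for orient in ("direct", "inverted")
    }
    total = 0
    for p in counted:
        for lo, hi in bins:
            if p.length > lo and (hi is None or p.length <= hi):
                counts[((lo, hi), p.orientation)] += 1
                total += 1
                break
    counts["total"] = total
    return counts


def large_repeat_pair(record: GenomeRecord, min_len: int = 1000) -> RepeatPair:
    """The longest repeat pair (the DR/IR region pair).

    Prefers annotated ``repeat_copy`` features (two copies sharing a
    ``pair_id``); otherwise falls back to sequence-level detection. Raises if
    no pair of at least ``min_len`` exists (no quadripartite structure).
    """
    by_pair: dict[str, list] = {}
    for f in record.features_of_kind("repeat_copy"):
        pid = f.attributes.get("pair_id")
        if pid is not None:
            by_pair.setdefault(pid, []).append(f)
    best = None
    for pid, copies in by_pair.items():
        if len(copies) != 2:
            continue
        a, b = sorted(copies, key=lambda f: f.start)
        length = a.length(len(record.sequence))
        if length >= min_len and (best is None or length > best.length):
            orientation = "direct" if a.strand == b.strand else "inverted"
            best = RepeatPair(
                pair_id=pid,
                start_a=a.start,
                end_a=a.end,
                strand_a=a.strand,
                start_b=b.start,
                end_b=b.end,
                strand_b=b.strand,
                length=length,
                orientation=orientation,
            )
    if best is not None:
        return best

    candidates = [p for p in find_repeats(record, min_len=15) if p.length >= min_len]
    if not candidates:
        raise ValueError("no repeat pair >= 1 kb: no quadripartite structure")
    return max(candidates, key=lambda p: p.length)
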