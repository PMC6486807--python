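"""Pairwise dN/dS estimation and group contrasts.

Per-gene pairwise estimates of (t, kappa, omega) under the GY94 codon model
with F3x4 frequencies computed from the two sequences of each pair; dS and dN
are derived by partitioning t over the synonymous/nonsynonymous flux of the
fitted model against the mutational (omega = 1) site proportions. A
Nei–Gojobori (1986) counting estimator with Jukes–Cantor correction serves as
an independent check, and Wilcoxon rank-sum tests compare distributions of
estimates between structural classes of plastomes or between gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
from scipy import optimize, stats

from . import codons

__all__ = [
    "CodonAlignment",
    "RateEstimate",
    "GroupComparison",
    "ml_pairwise_rates",
    "ng86_rates",
    "wilcoxon_rank_sum",
    "compare_rate_groups",
    "partition_by_region",
]


@dataclass
class CodonAlignment:
    gene: str
    seq_by_taxon: dict

    def __post_init__(self):
        lengths = {len(s) for s in self.seq_by_taxon.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must share length")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError("alignment length must be a codon multiple")
        for taxon, seq in self.seq_by_taxon.items():
            s = seq.upper().replace("U", "T")
            self.seq_by_taxon[taxon] = s
            for i in range(0, length, 3):
                codon = s[i : i + 3]
                if codon in ("TAA", "TAG", "TGA"):
                    raise ValueError(f"internal stop codon in {taxon} at codon {i//3}")

    @property
    def n_codons(self) -> int:
        return len(next(iter(self.seq_by_taxon.values()))) // 3


@dataclass
class RateEstimate:
    gene: str
    taxon_pair: tuple
    dN: float
    dS: float
    omega: float | None
    kappa: float
    t: float
    logL: float | None
    method: str
    n_codons: int
    flags: tuple = ()


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    statistic: float
    p_two_sided: float
    n_a: int
    n_b: int
    direction: str


def _shared_codons(aln: CodonAlignment, pair) -> list:
    a, b = pair
    if a not in aln.seq_by_taxon or b not in aln.seq_by_taxon:
        raise ValueError(f"pair {pair} not in alignment {aln.gene}")
    sa, sb = aln.seq_by_taxon[a], aln.seq_by_taxon[b]
    out = []
    for i in range(0, len(sa), 3):
        ca, cb = sa[i : i + 3], sb[i : i + 3]
        if ca in codons.CODON_INDEX and cb in codons.CODON_INDEX:
            out.append((ca, cb))
    return out


def ml_pairwise_rates(
    aln: CodonAlignment,
    pair: tuple,
    min_codons: int = 30,
    n_restarts: int = 3,
) -> RateEstimate:
    """Maximum-likelihood (t, kappa, omega) for one species pair and gene.

    F3x4 codon frequencies come from the union of the two sequences. The
    generator is scaled to mean rate 1, so t is in expected substitutions per
    codon; optimization is bounded (t in [1e-6, 50], kappa in [0.01, 100],
    omega in [1e-4, 20]) with random restarts in log space.
    """
    shared = _shared_codons(aln, pair)
    if len(shared) < min_codons:
        raise ValueError(f"fewer than {min_codons} ungapped shared codons")
    n = len(shared)
    if all(ca == cb for ca, cb in shared):
        return RateEstimate(
            gene=aln.gene,
            taxon_pair=tuple(pair),
            dN=0.0,
            dS=0.0,
            omega=None,
            kappa=1.0,
            t=0.0,
            logL=None,
            method="ML_F3x4",
            n_codons=n,
            flags=("identical",),
        )

    pi = codons.f3x4_from_sequences(["".join(c for c, _ in shared), "".join(c for _, c in shared)])
    # pair counts (unordered pattern compression: reversibility makes the
    # likelihood symmetric in the two sequences)
    from collections import Counter

    patterns = Counter()
    for ca, cb in shared:
        i, j = codons.CODON_INDEX[ca], codons.CODON_INDEX[cb]
        patterns[(min(i, j), max(i, j))] += 1
    idx_i = np.array([k[0] for k in patterns])
    idx_j = np.array([k[1] for k in patterns])
    weights = np.array(list(patterns.values()), dtype=float)
    log_pi = np.log(pi)

    bounds_log = [
        (np.log(1e-6), np.log(50.0)),
        (np.log(0.01), np.log(100.0)),
        (np.log(1e-4), np.log(20.0)),
    ]

    def neg_loglik(x):
        t, kappa, omega = np.exp(x)
        try:
            Q = codons.gy94_generator(kappa, omega, pi)
            P = codons.SpectralGenerator(Q, pi).transition_matrix(t)
        except (ValueError, np.linalg.LinAlgError):
            return 1e12
        pij = np.clip(P[idx_i, idx_j], 1e-300, None)
        return -float(np.sum(weights * (log_pi[idx_i] + np.log(pij))))

    import zlib

    rng = np.random.default_rng(
        zlib.crc32(f"{aln.gene}|{'|'.join(sorted(pair))}".encode()) % (2**31)
    )
    starts = [np.log([0.3, 2.0, 0.5])]
    for _ in range(n_restarts - 1):
        starts.append(
            np.array([rng.uniform(lo, hi) for lo, hi in bounds_log])
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            neg_loglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds_log,
            options={"ftol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("codon ML optimization failed to converge")

    t, kappa, omega = np.exp(best.x)
    rho_s, rho_n = codons.substitution_flux(kappa, omega, pi)
    p_s, p_n = codons.site_proportions(kappa, pi)
    dS = t * rho_s / (3.0 * p_s)
    dN = t * rho_n / (3.0 * p_n)
    flags = []
    if dS > 5.0:
        flags.append("dS_saturated")
    return RateEstimate(
        gene=aln.gene,
        taxon_pair=tuple(pair),
        dN=float(dN),
        dS=float(dS),
        omega=float(dN / dS) if dS > 0 else None,
        kappa=float(kappa),
        t=float(t),
        logL=-float(best.fun),
        method="ML_F3x4",
        n_codons=n,
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Nei-Gojobori 1986 counting estimator
# ---------------------------------------------------------------------------


def _ng_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; mutations to stops excluded."""
    syn = nonsyn = 0.0
    for p in range(3):
        for b in "TCAG":
            if b == codon[p]:
                continue
            mut = codon[:p] + b + codon[p + 1 :]
            if mut not in codons.CODON_INDEX:
                continue  # stop codon: not a countable site
            if codons.translate(mut) == codons.translate(codon):
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


def _ng_path_counts(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences, averaged over stop-free mutation paths."""
    diffs = [p for p in range(3) if ca[p] != cb[p]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in permutations(diffs):
        cur = ca
        s = n = 0.0
        ok = True
        for p in order:
            nxt = cur[:p] + cb[p] + cur[p + 1 :]
            if nxt not in codons.CODON_INDEX:
                ok = False
                break
            if codons.translate(nxt) == codons.translate(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            paths.append((s, n))
    if not paths:  # all paths pass through a stop; fall back to all orders
        for order in permutations(diffs):
            cur = ca
            s = n = 0.0
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1 :]
                aa_cur = codons.translate(cur) if cur in codons.CODON_INDEX else "*"
                aa_nxt = codons.translate(nxt) if nxt in codons.CODON_INDEX else "*"
                if aa_cur == aa_nxt:
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n))
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def _jc_correct(p: float) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        return float("nan")
    return -0.75 * np.log(arg)


def ng86_rates(aln: CodonAlignment, pair: tuple, min_codons: int = 30) -> RateEstimate:
    """Nei-Gojobori proportions with Jukes-Cantor correction (counting oracle)."""
    shared = _shared_codons(aln, pair)
    if len(shared) < min_codons:
        raise ValueError(f"fewer than {min_codons} ungapped shared codons")
    S = N = Sd = Nd = 0.0
    for ca, cb in shared:
        sa, na = _ng_site_counts(ca)
        sb, nb = _ng_site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        s, nn = _ng_path_counts(ca, cb)
        Sd += s
        Nd += nn
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS, dN = _jc_correct(pS), _jc_correct(pN)
    flags = []
    if np.isnan(dS) or np.isnan(dN):
        flags.append("saturated")
    omega = None
    if dS and dS > 0 and not np.isnan(dS) and not np.isnan(dN):
        omega = float(dN / dS)
    return RateEstimate(
        gene=aln.gene,
        taxon_pair=tuple(pair),
        dN=float(dN),
        dS=float(dS),
        omega=omega,
        kappa=float("nan"),
        t=float("nan"),
        logL=None,
        method="NG86",
        n_codons=len(shared),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum and group contrasts
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(a, b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration for n_a + n_b <= 20 with no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:  # a single tied value: no evidence either way
        w = a.size * (pooled.size + 1) / 2.0
        return GroupComparison("a", "b", "", w, 1.0, int(a.size), int(b.size), "a=b")
    no_ties = len(np.unique(pooled)) == a.size + b.size
    method = "exact" if (a.size + b.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    # rank-sum statistic W for group a from the Mann-Whitney U
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    direction = "a>b" if np.median(a) > np.median(b) else "a<b" if np.median(a) < np.median(b) else "a=b"
    return GroupComparison(
        group_a="a",
        group_b="b",
        metric="",
        statistic=w,
        p_two_sided=float(min(res.pvalue, 1.0)),
        n_a=int(a.size),
        n_b=int(b.size),
        direction=direction,
    )


def compare_rate_groups(estimates: list, grouping: dict) -> list:
    """All pairwise label contrasts of dS, dN, omega distributions.

    ``grouping`` maps a taxon pair (unordered) to a class label; estimates
    for pairs without a label (e.g. cross-class pairs) are ignored. Each
    (gene x labelled pair) estimate contributes one value per metric.
    """
    norm = {frozenset(k): v for k, v in grouping.items()}
    labels = sorted(set(norm.values()))
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    pooled = {lab: {"dS": [], "dN": [], "omega": []} for lab in labels}
    for est in estimates:
        lab = norm.get(frozenset(est.taxon_pair))
        if lab is None:
            continue
        if not np.isnan(est.dS):
            pooled[lab]["dS"].append(est.dS)
        if not np.isnan(est.dN):
            pooled[lab]["dN"].append(est.dN)
        if est.omega is not None:
            pooled[lab]["omega"].append(est.omega)
    for lab in labels:
        if not pooled[lab]["dS"]:
            raise ValueError(f"label {lab!r} has no estimates")
    out = []
    for la, lb in combinations(labels, 2):
        for metric in ("dS", "dN", "omega"):
            xa, xb = pooled[la][metric], pooled[lb][metric]
            if not xa or not xb:
                continue
            cmp = wilcoxon_rank_sum(xa, xb)
            ma, mb = float(np.median(xa)), float(np.median(xb))
            direction = f"{la}>{lb}" if ma > mb else f"{la}<{lb}" if ma < mb else f"{la}={lb}"
            out.append(
                GroupComparison(
                    group_a=la,
                    group_b=lb,
                    metric=metric,
                    statistic=cmp.statistic,
                    p_two_sided=cmp.p_two_sided,
                    n_a=cmp.n_a,
                    n_b=cmp.n_b,
                    direction=direction,
                )
            )
    return out


def partition_by_region(genes: list, inside_set: list) -> dict:
    """Label genes as inside/outside a rearranged region (e.g. the ~50-kb
    inversion that reoriented the large repeat)."""
    genes = list(genes)
    unknown = set(inside_set) - set(genes)
    if unknown:
        raise ValueError(f"genes not in universe: {sorted(unknown)}")
    inside = set(inside_set)
    return {g: ("inside" if g in inside else "outside") for g in genes}
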