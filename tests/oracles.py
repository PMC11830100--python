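"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — O(n^2) pairwise scans, direct
series summation — and shares no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def poisson_tail_sum(k: int, lam: float, extra_terms: int = 2000) -> float:
    """P[X >= k] by direct log-space term summation."""
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    # lower tail is summed when it is the smaller side, for accuracy
    if k <= lam:
        lower = math.fsum(
            math.exp(i * math.log(lam) - lam - math.lgamma(i + 1)) for i in range(k)
        )
        return 1.0 - lower
    terms = []
    for i in range(k, k + extra_terms):
        t = math.exp(i * math.log(lam) - lam - math.lgamma(i + 1))
        terms.append(t)
        if t < 1e-320:
            break
    return math.fsum(terms)


def overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    """>= 1 bp overlap of half-open intervals."""
    return a_start < b_end and b_start < a_end


def blacklist_survivors(peaks: list[tuple], blacklist: list[tuple]) -> list[tuple]:
    """O(n*m) scan; intervals are (contig, start, end)."""
    out = []
    for p in peaks:
        hit = any(p[0] == b[0] and overlaps(p[1], p[2], b[1], b[2]) for b in blacklist)
        if not hit:
            out.append(p)
    return out


def overlap_clusters_bruteforce(labelled: list[tuple]) -> set:
    """Transitive-closure clusters of (contig, start, end, set_name) records
    via all-pairs union-find.  Returns a set of
    (contig, start, end, frozenset(names)) merged clusters."""
    n = len(labelled)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = labelled[i], labelled[j]
            if a[0] == b[0] and overlaps(a[1], a[2], b[1], b[2]):
                parent[find(i)] = find(j)
    clusters: dict[int, list] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(labelled[i])
    out = set()
    for members in clusters.values():
        contig = members[0][0]
        start = min(m[1] for m in members)
        end = max(m[2] for m in members)
        names = frozenset(m[3] for m in members)
        out.add((contig, start, end, names))
    return out


def assign_peak_bruteforce(peak: tuple, catalog) -> tuple:
    """Exhaustive per-peak precedence classification.

    Returns (feature_class, sorted gene-id tuple)."""
    contig, start, end = peak
    for cls, table in (
        ("promoter", catalog.promoters),
        ("enhancer", catalog.enhancers),
        ("gene_body", catalog.genes),
    ):
        genes = sorted(
            {
                row.gene_id
                for row in table.itertuples(index=False)
                if row.contig == contig and overlaps(start, end, row.start, row.end)
            }
        )
        if genes:
            return cls, tuple(genes)
    return "intergenic", ()


def bh_adjust(pvals: list[float]) -> list[float]:
    """Hand Benjamini-Hochberg: p_(i) * n / i with a step-up running min."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj


def de_sets_rowwise(table, p_field: str, p_cut: float, lfc_cut: float):
    """Row-by-row re-evaluation of the DE rule (strict inequalities)."""
    up, down = set(), set()
    for row in table.itertuples(index=False):
        p = getattr(row, p_field)
        if p < p_cut and row.log2fc > lfc_cut:
            up.add(row.gene_id)
        elif p < p_cut and row.log2fc < -lfc_cut:
            down.add(row.gene_id)
    return up, down


def site_recall_precision(peaks_df, sites_df) -> tuple[float, float]:
    """Fraction of planted sites hit by >= 1 peak, and of peaks hitting a site."""
    sites = list(zip(sites_df["contig"], sites_df["start"], sites_df["end"]))
    peaks = list(zip(peaks_df["contig"], peaks_df["start"], peaks_df["end"]))
    hit_sites = sum(
        any(s[0] == p[0] and overlaps(s[1], s[2], p[1], p[2]) for p in peaks) for s in sites
    )
    hit_peaks = sum(
        any(s[0] == p[0] and overlaps(s[1], s[2], p[1], p[2]) for s in sites) for p in peaks
    )
    recall = hit_sites / len(sites) if sites else float("nan")
    precision = hit_peaks / len(peaks) if peaks else float("nan")
    return recall, precision


def random_intervals(rng: np.random.Generator, n: int, contigs: list, max_pos: int = 100_000):
    out = []
    for _ in range(n):
        contig = contigs[int(rng.integers(len(contigs)))]
        start = int(rng.integers(0, max_pos))
        end = start + int(rng.integers(1, 2000))
        out.append((contig, start, end))
    return out
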