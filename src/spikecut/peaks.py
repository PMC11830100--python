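"""IgG-referenced peak calling with fold and Poisson retention.

Candidate windows of width ``w`` slide at step ``w/2`` along each genome
contig.  A window with experimental tag count k and normalized control
expectation lam = max(lam_min, size_factor * control tags) is retained iff

    k / lam >= F   and   P[X >= k | X ~ Poisson(lam)] <= alpha.

The control tag count entering lam is itself floored at the genome-wide
average control density for the span, so that randomly undersampled
control windows cannot manufacture enrichment; this mirrors the
expected-background behaviour of histone-mode region calling.

Retained windows within a stitch gap are merged and the merged span is
re-tested as a whole; a stitched peak failing the joint test is dropped.
Duplicate fragments are kept (no clonal filtering) by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import PEAK_COLUMNS, PeakSet, TagTrack
from .normalization import SizeFactors

__all__ = [
    "PeakCallParams",
    "poisson_tail",
    "scan_windows",
    "call_peaks",
    "filter_blacklist",
    "overlap_peak_sets",
]


@dataclass(frozen=True)
class PeakCallParams:
    window: int = 500  # candidate window width, bp
    gap: int = 1000  # stitch gap between retained windows, bp
    fold: float = 4.0  # minimum expr/control tag ratio
    alpha: float = 1e-4  # Poisson upper-tail cutoff
    lam_min: float = 0.5  # floor on the control expectation per window
    clonal_filter: bool = False  # duplicate-fragment filtering (off)

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window width must be positive")
        if self.fold < 1:
            raise ValueError("fold threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.lam_min <= 0:
            raise ValueError("lam_min must be positive")
        if self.clonal_filter:
            raise NotImplementedError("clonal filtering is not implemented (kept off)")


def poisson_tail(k: int, lam: float) -> float:
    """Upper cumulative Poisson tail P[X >= k] for X ~ Poisson(lam).

    Evaluated through the regularized-gamma survival function, which is
    stable in log space for large k; no explicit series summation.
    """
    if k < 0 or lam < 0:
        raise ValueError("poisson_tail requires k >= 0 and lam >= 0")
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def _tail_vec(k: np.ndarray, lam: np.ndarray) -> np.ndarray:
    out = np.ones_like(lam, dtype=float)
    pos = k > 0
    out[pos] = stats.poisson.sf(k[pos] - 1, lam[pos])
    return out


def _size_factor(sf: "SizeFactors | float") -> float:
    return sf.size_factor if isinstance(sf, SizeFactors) else float(sf)


def scan_windows(
    expr: TagTrack, ctrl: TagTrack, sf: "SizeFactors | float", params: PeakCallParams | None = None
) -> pd.DataFrame:
    """Sliding-window retention scan: every candidate window passing the
    fold and Poisson criteria, before stitching.

    Window retention is monotone in the thresholds (raising F or lowering
    alpha can only drop windows); stitched peak counts need not be, since
    looser thresholds can merge neighbouring windows into one peak.
    """
    params = params or PeakCallParams()
    if not expr.same_grid(ctrl):
        raise ValueError("experimental and control tracks use different layouts/bins")
    if params.window % expr.binsize:
        raise ValueError("window must be a multiple of the track binsize")
    factor = _size_factor(sf)
    wbins = params.window // expr.binsize
    sbins = max(wbins // 2, 1)
    genome_bp = sum(expr.layout.lengths[c] for c in expr.layout.genome_contigs)
    ctrl_density = ctrl.total_tags() / genome_bp  # control tags per bp
    rows = []
    for contig in expr.layout.genome_contigs:
        ev, cv = expr.counts[contig], ctrl.counts[contig]
        if len(ev) < wbins:
            continue
        ecum = np.concatenate(([0.0], np.cumsum(ev)))
        ccum = np.concatenate(([0.0], np.cumsum(cv)))
        w0 = np.arange(0, len(ev) - wbins + 1, sbins)
        k = ecum[w0 + wbins] - ecum[w0]
        ctrl_tags = np.maximum(ccum[w0 + wbins] - ccum[w0], ctrl_density * params.window)
        lam = np.maximum(params.lam_min, factor * ctrl_tags)
        p = _tail_vec(k, lam)
        keep = (k / lam >= params.fold) & (p <= params.alpha)
        length = expr.layout.lengths[contig]
        for b, kk, ll, pp in zip(w0[keep], k[keep], lam[keep], p[keep]):
            s = int(b * expr.binsize)
            e = min(int((b + wbins) * expr.binsize), length)
            rows.append((contig, s, e, int(kk), float(ll), float(kk / ll), float(pp)))
    return pd.DataFrame(rows, columns=PEAK_COLUMNS)


def call_peaks(
    expr: TagTrack,
    ctrl: TagTrack,
    sf: "SizeFactors | float",
    params: PeakCallParams | None = None,
    sample_id: str = "peaks",
) -> PeakSet:
    """Call peaks on ``expr`` against the size-factor-scaled control:
    retained windows are stitched across gaps <= ``params.gap`` and each
    stitched span is re-tested as a whole (failures are dropped)."""
    params = params or PeakCallParams()
    windows = scan_windows(expr, ctrl, sf, params)
    factor = _size_factor(sf)
    genome_bp = sum(expr.layout.lengths[c] for c in expr.layout.genome_contigs)
    ctrl_density = ctrl.total_tags() / genome_bp
    rows = []
    for contig in expr.layout.genome_contigs:
        spans = [
            (int(r.start), int(r.end))
            for r in windows[windows["contig"] == contig].itertuples(index=False)
        ]
        if not spans:
            continue
        ecum = np.concatenate(([0.0], np.cumsum(expr.counts[contig])))
        ccum = np.concatenate(([0.0], np.cumsum(ctrl.counts[contig])))
        stitched = [list(spans[0])]
        for s, e in spans[1:]:
            if s - stitched[-1][1] <= params.gap:
                stitched[-1][1] = max(stitched[-1][1], e)
            else:
                stitched.append([s, e])
        for s, e in stitched:
            b0, b1 = s // expr.binsize, -(-e // expr.binsize)
            kk = float(ecum[b1] - ecum[b0])
            ctag = max(float(ccum[b1] - ccum[b0]), ctrl_density * (e - s))
            ll = max(params.lam_min, factor * ctag)
            pp = poisson_tail(int(kk), ll)
            if kk / ll >= params.fold and pp <= params.alpha:
                rows.append((contig, s, e, int(kk), ll, kk / ll, pp))
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(sample_id=sample_id, df=df)


def _interval_trees(df: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)
    return trees


def filter_blacklist(peaks: PeakSet, blacklist: pd.DataFrame) -> PeakSet:
    """Drop peaks overlapping any blacklist interval by >= 1 bp."""
    if len(blacklist) == 0 or len(peaks) == 0:
        return PeakSet(peaks.sample_id, peaks.df.copy())
    trees = _interval_trees(blacklist)
    keep = [
        not (row.contig in trees and trees[row.contig].overlaps(row.start, row.end))
        for row in peaks.df.itertuples(index=False)
    ]
    return PeakSet(peaks.sample_id, peaks.df[keep].reset_index(drop=True))


def overlap_peak_sets(sets: "list[PeakSet] | dict[str, PeakSet]"):
    """Merge peaks across sets by literal >= 1 bp coordinate overlap.

    Overlap is closed transitively (a chain of pairwise-overlapping peaks
    forms one cluster).  Returns ``(clusters, counts)``: a DataFrame with
    the merged span and the sorted, comma-joined label of contributing
    sets, and a per-label cluster count.
    """
    if not isinstance(sets, dict):
        sets = {ps.sample_id: ps for ps in sets}
    if len(sets) < 2:
        raise ValueError("overlap_peak_sets needs at least two peak sets")
    records = []
    for name, ps in sets.items():
        for row in ps.df.itertuples(index=False):
            records.append((row.contig, int(row.start), int(row.end), name))
    clusters = []
    by_contig: dict[str, list] = {}
    for rec in records:
        by_contig.setdefault(rec[0], []).append(rec)
    for contig in sorted(by_contig):
        recs = sorted(by_contig[contig], key=lambda r: (r[1], r[2], r[3]))
        cur_s, cur_e, members = recs[0][1], recs[0][2], {recs[0][3]}
        for _, s, e, name in recs[1:]:
            if s < cur_e:  # >=1 bp overlap; touching half-open ends do not merge
                cur_e = max(cur_e, e)
                members.add(name)
            else:
                clusters.append((contig, cur_s, cur_e, ",".join(sorted(members))))
                cur_s, cur_e, members = s, e, {name}
        clusters.append((contig, cur_s, cur_e, ",".join(sorted(members))))
    df = pd.DataFrame(clusters, columns=["contig", "start", "end", "members"])
    counts = df["members"].value_counts().to_dict()
    return df, counts
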