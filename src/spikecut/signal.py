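"""Log2-ratio coverage tracks and region-centered signal matrices.

The ratio track compares an experimental track to the control scaled
1:S (S = ratio_expr / ratio_ctrl):

    value_b = log2((expr_b + pc) / (S * ctrl_b + pc))

Matrices collect the track signal in fixed-width bins across +/- flank
around each region's midpoint; cells running off a contig are treated as
missing and excluded from column means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeLayout, TagTrack
from .normalization import CoverageScale

__all__ = ["SignalMatrix", "log2_ratio_track", "compute_matrix", "profile_and_order"]


@dataclass
class SignalMatrix:
    region_ids: list
    offsets: np.ndarray  # left edge of each column relative to region center
    values: np.ndarray  # regions x columns; NaN marks missing
    flank: int
    binsize: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[int(o) for o in self.offsets])
        df.insert(0, "region_id", self.region_ids)
        return df


def log2_ratio_track(
    expr: TagTrack, ctrl: TagTrack, S: "CoverageScale | float", pseudocount: float = 1.0
) -> TagTrack:
    """Per-bin log2((expr + pc) / (S * ctrl + pc)) as a float-valued track."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if not expr.same_grid(ctrl):
        raise ValueError("tracks use different layouts or bin widths")
    scale = S.S if isinstance(S, CoverageScale) else float(S)
    values = {
        contig: np.log2((expr.counts[contig] + pseudocount) / (scale * ctrl.counts[contig] + pseudocount))
        for contig in expr.counts
    }
    return TagTrack(
        binsize=expr.binsize, counts=values, layout=expr.layout, effective_total=float("nan")
    )


def _contig_integral(values: np.ndarray, binsize: int, length: int):
    """Piecewise-linear cumulative integral of the track, for exact
    length-weighted averages over arbitrary spans."""
    edges = np.arange(len(values) + 1, dtype=float) * binsize
    edges[-1] = min(edges[-1], length) if len(values) else 0.0
    widths = np.diff(edges)
    cum = np.concatenate(([0.0], np.cumsum(values * widths)))
    return edges, cum


def compute_matrix(
    track: TagTrack,
    centers: pd.DataFrame,
    flank: int = 4000,
    binsize: int | None = None,
) -> SignalMatrix:
    """Signal matrix around region midpoints.

    ``centers`` needs contig/start/end (and optionally region_id) columns;
    the row center is the interval midpoint.  Columns tile [-flank, +flank)
    in ``binsize`` steps (default: the track's bin width); flank must be a
    multiple of binsize.  Cell values are length-weighted averages of the
    track over the cell span, with off-contig portions excluded; fully
    off-contig cells are NaN.
    """
    if binsize is None:
        binsize = track.binsize
    if flank % binsize:
        raise ValueError("flank must be a multiple of binsize")
    ncol = 2 * flank // binsize
    offsets = -flank + binsize * np.arange(ncol)
    if "region_id" in centers.columns:
        region_ids = list(centers["region_id"])
    else:
        region_ids = [f"region_{i:06d}" for i in range(len(centers))]
    integrals = {
        c: _contig_integral(track.counts[c], track.binsize, track.layout.lengths[c])
        for c in track.counts
    }
    values = np.full((len(centers), ncol), np.nan)
    for i, row in enumerate(centers.itertuples(index=False)):
        if row.contig not in integrals:
            raise ValueError(f"region on unknown contig {row.contig!r}")
        edges, cum = integrals[row.contig]
        length = track.layout.lengths[row.contig]
        center = (int(row.start) + int(row.end)) // 2
        lo = np.clip(center + offsets.astype(float), 0, length)
        hi = np.clip(center + offsets.astype(float) + binsize, 0, length)
        span = hi - lo
        ok = span > 0
        integ = np.interp(hi[ok], edges, cum) - np.interp(lo[ok], edges, cum)
        values[i, ok] = integ / span[ok]
    return SignalMatrix(
        region_ids=region_ids, offsets=offsets, values=values, flank=flank, binsize=binsize
    )


def profile_and_order(matrix: SignalMatrix):
    """Column-mean profile and heatmap row order.

    The profile averages non-missing cells per column.  Rows are ordered by
    descending row mean; ties break by region id (so all-equal rows keep
    their id order).
    """
    if len(matrix.region_ids) == 0:
        raise ValueError("empty signal matrix")
    with np.errstate(invalid="ignore"):
        profile = np.nanmean(matrix.values, axis=0)
        row_means = np.nanmean(matrix.values, axis=1)
    order = sorted(
        range(len(matrix.region_ids)),
        key=lambda i: (-(row_means[i] if np.isfinite(row_means[i]) else -np.inf), str(matrix.region_ids[i])),
    )
    return profile, [matrix.region_ids[i] for i in order]
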