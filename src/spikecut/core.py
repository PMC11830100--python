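"""Shared domain containers.

All genomic intervals in this package are 0-based, half-open
``[start, end)`` — the BED convention.  Strand is ignored throughout:
fragment tag counting and peak calling are unstranded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "FragmentSet",
    "AlignmentCounts",
    "FeatureCatalog",
    "PeakSet",
    "TagTrack",
    "PEAK_COLUMNS",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Contig name -> length map with a spike-in partition.

    ``spike_contigs`` flags the exogenous calibration contigs (the E. coli
    or Drosophila spike-in genome); everything else is "genome".
    """

    lengths: dict[str, int]
    spike_contigs: frozenset = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_contigs", frozenset(self.spike_contigs))
        for name, length in self.lengths.items():
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise ValueError(f"contig {name!r} has non-positive length {length}")
        unknown = self.spike_contigs - set(self.lengths)
        if unknown:
            raise ValueError(f"spike contigs not in layout: {sorted(unknown)}")

    @property
    def contigs(self) -> tuple:
        return tuple(self.lengths)

    @property
    def genome_contigs(self) -> tuple:
        return tuple(c for c in self.lengths if c not in self.spike_contigs)

    def is_spike(self, contig: str) -> bool:
        return contig in self.spike_contigs

    def length(self, contig: str) -> int:
        return self.lengths[contig]


@dataclass
class FragmentSet:
    """Aligned fragments for one library, stored as parallel arrays."""

    sample_id: str
    contigs: np.ndarray  # unicode array
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    layout: GenomeLayout

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype="U64")
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.contigs) == len(self.starts) == len(self.ends)):
            raise ValueError("fragment arrays have unequal lengths")
        self.validate()

    def __len__(self) -> int:
        return len(self.starts)

    def validate(self) -> None:
        if len(self) == 0:
            return
        uniq, inverse = np.unique(self.contigs, return_inverse=True)
        for contig in uniq:
            if str(contig) not in self.layout.lengths:
                raise ValueError(f"fragment on unknown contig {contig!r}")
        if (self.starts < 0).any() or (self.ends <= self.starts).any():
            raise ValueError("fragments must satisfy 0 <= start < end")
        lens = np.array([self.layout.lengths[str(c)] for c in uniq])[inverse]
        if (self.ends > lens).any():
            bad = int(np.argmax(self.ends > lens))
            raise ValueError(
                f"fragment {self.contigs[bad]}:{self.starts[bad]}-{self.ends[bad]} "
                "extends past contig end"
            )


@dataclass(frozen=True)
class AlignmentCounts:
    """Per-sample totals of genome-aligned and spike-in-aligned fragments."""

    sample_id: str
    genome_reads: int
    spike_reads: int

    def __post_init__(self) -> None:
        if self.genome_reads < 0 or self.spike_reads < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def total(self) -> int:
        return self.genome_reads + self.spike_reads


def _check_intervals(df: pd.DataFrame, what: str) -> None:
    if len(df) and (df["end"] <= df["start"]).any():
        raise ValueError(f"{what}: intervals must satisfy start < end")


@dataclass
class FeatureCatalog:
    """The annotation universe: promoters, gene-linked enhancers, genes,
    and blacklist regions.

    Tables are DataFrames.  ``promoters``/``enhancers``/``genes`` carry
    ``feature_id, contig, start, end, gene_id`` (enhancers additionally a
    ``score``, the enhancer-gene association confidence); ``blacklist``
    carries ``contig, start, end``.
    """

    promoters: pd.DataFrame
    enhancers: pd.DataFrame
    genes: pd.DataFrame
    blacklist: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("promoters", "enhancers", "genes"):
            df = getattr(self, name)
            missing = {"feature_id", "contig", "start", "end", "gene_id"} - set(df.columns)
            if missing:
                raise ValueError(f"{name} table lacks columns {sorted(missing)}")
            _check_intervals(df, name)
        if not {"contig", "start", "end"} <= set(self.blacklist.columns):
            raise ValueError("blacklist table lacks contig/start/end")
        _check_intervals(self.blacklist, "blacklist")

    def unresolved_gene_ids(self) -> set:
        """Promoter/enhancer gene ids that do not resolve to the gene table."""
        known = set(self.genes["gene_id"])
        out = set(self.promoters["gene_id"]) | set(self.enhancers["gene_id"])
        return out - known


PEAK_COLUMNS = ["contig", "start", "end", "count", "lam", "fold", "p"]


@dataclass
class PeakSet:
    """Called (or imported) peaks with their enrichment statistics.

    ``df`` columns: contig, start, end, count (experimental tags k),
    lam (normalized control expectation), fold (k / lam) and p
    (upper Poisson tail P[X >= k | lam]).
    """

    sample_id: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(PEAK_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"peak table lacks columns {sorted(missing)}")
        _check_intervals(self.df, "peaks")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def intervals(self) -> pd.DataFrame:
        return self.df[["contig", "start", "end"]]


@dataclass
class TagTrack:
    """Binned fragment-tag counts per genome contig.

    One fragment contributes one tag, placed in the bin containing its
    midpoint, so window counts of disjoint windows are sums of independent
    fragment events.  ``effective_total`` is the (possibly normalized)
    library size associated with the track — the tag-directory total-read
    analogue.
    """

    binsize: int
    counts: dict[str, np.ndarray]
    layout: GenomeLayout
    effective_total: float

    @classmethod
    def from_fragments(
        cls, frags: FragmentSet, binsize: int = 50, effective_total: float | None = None
    ) -> "TagTrack":
        if binsize <= 0:
            raise ValueError("binsize must be positive")
        layout = frags.layout
        counts: dict[str, np.ndarray] = {}
        mids = (frags.starts + frags.ends) // 2
        for contig in layout.genome_contigs:
            nbins = -(-layout.lengths[contig] // binsize)
            mask = frags.contigs == contig
            idx = np.minimum(mids[mask] // binsize, nbins - 1)
            counts[contig] = np.bincount(idx, minlength=nbins).astype(np.float64)
        total = float(sum(v.sum() for v in counts.values()))
        if effective_total is None:
            effective_total = total
        return cls(binsize=binsize, counts=counts, layout=layout, effective_total=effective_total)

    def total_tags(self) -> float:
        return float(sum(v.sum() for v in self.counts.values()))

    def same_grid(self, other: "TagTrack") -> bool:
        return (
            self.binsize == other.binsize
            and set(self.counts) == set(other.counts)
            and all(len(self.counts[c]) == len(other.counts[c]) for c in self.counts)
        )
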