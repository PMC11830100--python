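"""Readers and writers for the external text formats the pipeline touches.

BED and bedGraph are native (0-based half-open).  Gene/promoter/enhancer
tables are header-carrying TSV.  GFF-like 1-based closed gene coordinates
are converted to half-open on read.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .core import (
    PEAK_COLUMNS,
    AlignmentCounts,
    FeatureCatalog,
    FragmentSet,
    GenomeLayout,
    PeakSet,
    TagTrack,
)

__all__ = [
    "read_fragments",
    "count_reads",
    "read_peaks",
    "write_peaks",
    "write_bedgraph",
    "read_bedgraph",
    "read_layout",
    "write_layout",
    "read_feature_table",
    "write_feature_table",
    "read_catalog",
    "write_catalog",
    "read_de_table",
    "write_de_table",
    "validate_de_table",
    "read_bed_intervals",
]


class ParseError(ValueError):
    """Malformed record in an external file; carries the line number."""


def _parse_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split("\t")


def read_fragments(path: str, layout: GenomeLayout, sample_id: str | None = None) -> FragmentSet:
    """Read aligned fragments from BED (3+ cols) or BEDPE (6+ cols).

    Files ending in ``.bedpe`` are parsed as BEDPE; the fragment is the
    outer span of the mate pair.  Record order is preserved.
    """
    is_bedpe = str(path).endswith(".bedpe")
    contigs, starts, ends = [], [], []
    for lineno, fields in _parse_lines(path):
        try:
            if is_bedpe:
                if len(fields) < 6:
                    raise ValueError("BEDPE needs >= 6 columns")
                c1, s1, e1, c2, s2, e2 = fields[:6]
                if c1 != c2:
                    raise ValueError(f"mate contigs differ: {c1} vs {c2}")
                start = min(int(s1), int(s2))
                end = max(int(e1), int(e2))
                contig = c1
            else:
                if len(fields) < 3:
                    raise ValueError("BED needs >= 3 columns")
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if contig not in layout.lengths:
            raise ParseError(f"{path}:{lineno}: unknown contig {contig!r}")
        contigs.append(contig)
        starts.append(start)
        ends.append(end)
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    return FragmentSet(
        sample_id=sample_id,
        contigs=np.array(contigs, dtype="U64"),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        layout=layout,
    )


def count_reads(frags: FragmentSet) -> AlignmentCounts:
    """Tally genome- vs spike-in-aligned fragments (the flagstat analogue)."""
    if len(frags) == 0:
        return AlignmentCounts(frags.sample_id, 0, 0)
    spike = np.isin(frags.contigs, list(frags.layout.spike_contigs))
    return AlignmentCounts(
        sample_id=frags.sample_id,
        genome_reads=int((~spike).sum()),
        spike_reads=int(spike.sum()),
    )


def write_peaks(peaks: PeakSet, path: str) -> None:
    """Write peaks as BED6+4: name/score/strand then count, lam, fold, p.

    p is written in scientific notation with full double precision so that
    tiny tail probabilities round-trip without textual underflow.
    """
    df = peaks.df
    with open(path, "w") as fh:
        for i, row in enumerate(df.itertuples(index=False)):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\tpeak_{i + 1}\t"
                f"{min(1000, int(round(row.fold)))}\t.\t"
                f"{int(row.count)}\t{float(row.lam)!r}\t{float(row.fold)!r}\t{row.p:.17e}\n"
            )


def read_peaks(path: str, sample_id: str | None = None) -> PeakSet:
    rows = []
    for lineno, fields in _parse_lines(path):
        try:
            if len(fields) < 10:
                raise ValueError("peak BED needs 10 columns")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"end {end} <= start {start}")
            rows.append(
                (fields[0], start, end, int(fields[6]), float(fields[7]),
                 float(fields[8]), float(fields[9]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    return PeakSet(sample_id=sample_id, df=df)


def write_bedgraph(track: TagTrack, path: str) -> None:
    """Write a binned track as bedGraph, merging adjacent equal-value bins."""
    with open(path, "w") as fh:
        for contig in track.layout.genome_contigs:
            values = track.counts[contig]
            if np.isnan(values).any():
                raise ValueError(f"NaN value in track on contig {contig}")
            length = track.layout.lengths[contig]
            run_start = 0
            for i in range(1, len(values) + 1):
                if i == len(values) or values[i] != values[run_start]:
                    lo = run_start * track.binsize
                    hi = min(i * track.binsize, length)
                    fh.write(f"{contig}\t{lo}\t{hi}\t{float(values[run_start])!r}\n")
                    run_start = i


def read_bedgraph(path: str, layout: GenomeLayout, binsize: int) -> TagTrack:
    """Re-bin a bedGraph file onto a fixed grid (records must align to it)."""
    counts = {
        c: np.zeros(-(-layout.lengths[c] // binsize)) for c in layout.genome_contigs
    }
    for lineno, fields in _parse_lines(path):
        try:
            contig, lo, hi, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if contig not in counts:
            raise ParseError(f"{path}:{lineno}: unknown contig {contig!r}")
        b0 = lo // binsize
        b1 = -(-hi // binsize)
        counts[contig][b0:b1] = val
    total = float(sum(v.sum() for v in counts.values()))
    return TagTrack(binsize=binsize, counts=counts, layout=layout, effective_total=total)


# ---------------------------------------------------------------------------
# layout / annotation / DE tables (header TSV)


def read_layout(path: str) -> GenomeLayout:
    df = pd.read_csv(path, sep="\t")
    spike = frozenset(df.loc[df["is_spike"].astype(bool), "contig"])
    return GenomeLayout(dict(zip(df["contig"], df["length"].astype(int))), spike)


def write_layout(layout: GenomeLayout, path: str) -> None:
    pd.DataFrame(
        {
            "contig": list(layout.lengths),
            "length": list(layout.lengths.values()),
            "is_spike": [c in layout.spike_contigs for c in layout.lengths],
        }
    ).to_csv(path, sep="\t", index=False)


_FEATURE_PREFIX = {"promoters": "P", "enhancers": "E", "genes": "G", "blacklist": "BL"}


def read_feature_table(path: str, kind: str) -> pd.DataFrame:
    """Read a promoter/enhancer/gene/blacklist TSV.

    Expected columns: contig, start, end[, gene_id][, score][, feature_id].
    A ``feature_id`` is synthesized from file order when absent.  If the
    table looks GFF-like (a ``one_based`` column set truthy), coordinates
    are converted from 1-based closed to 0-based half-open.
    """
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    if "one_based" in df.columns and df["one_based"].astype(bool).any():
        df["start"] = df["start"] - 1
        df = df.drop(columns=["one_based"])
    if "feature_id" not in df.columns and kind != "blacklist":
        prefix = _FEATURE_PREFIX.get(kind, "F")
        df.insert(0, "feature_id", [f"{prefix}{i:06d}" for i in range(len(df))])
    return df


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_catalog(promoters: str, enhancers: str, genes: str, blacklist: str) -> FeatureCatalog:
    return FeatureCatalog(
        promoters=read_feature_table(promoters, "promoters"),
        enhancers=read_feature_table(enhancers, "enhancers"),
        genes=read_feature_table(genes, "genes"),
        blacklist=read_feature_table(blacklist, "blacklist"),
    )


def write_catalog(catalog: FeatureCatalog, outdir: str) -> dict:
    paths = {}
    for kind in ("promoters", "enhancers", "genes", "blacklist"):
        path = os.path.join(outdir, f"{kind}.tsv")
        write_feature_table(getattr(catalog, kind), path)
        paths[kind] = path
    return paths


def read_bed_intervals(path: str) -> pd.DataFrame:
    """Plain BED3 -> DataFrame(contig, start, end)."""
    rows = []
    for lineno, fields in _parse_lines(path):
        try:
            rows.append((fields[0], int(fields[1]), int(fields[2])))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


DE_REQUIRED = ["gene_id", "log2fc", "pvalue", "padj"]


def validate_de_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(DE_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"DE table lacks columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError("DE table gene ids must be unique")
    for col in ("pvalue", "padj"):
        vals = df[col]
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"DE table {col} outside [0, 1]")
    count_cols = [c for c in df.columns if c.startswith("counts_")]
    if count_cols and (df[count_cols] < 0).to_numpy().any():
        raise ValueError("DE table raw counts must be >= 0")
    return df


def read_de_table(path: str) -> pd.DataFrame:
    return validate_de_table(pd.read_csv(path, sep="\t"))


def write_de_table(df: pd.DataFrame, path: str) -> None:
    validate_de_table(df).to_csv(path, sep="\t", index=False)
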