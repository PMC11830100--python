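"""Peak-to-feature assignment and histone-mark combination states.

Peaks are assigned to exactly one class by the precedence
promoter > enhancer > gene_body > intergenic, using >= 1 bp overlap.
Features are conditioned on binding by up to two target peak sets and
classified into one of the 16 subsets of
{H3K4me1, H3K4me3, H3K27ac, H3K27me3} whose peaks overlap them.
"""

from __future__ import annotations

import pandas as pd
from intervaltree import IntervalTree

from .core import FeatureCatalog, PeakSet

__all__ = [
    "MARKS",
    "drop_promoter_overlapping_enhancers",
    "assign_peaks",
    "class_percentages",
    "condition_features",
    "classify_states",
    "state_distribution",
    "gene_level_state",
    "gene_state_table",
    "feature_universe",
]

MARKS = ("H3K4me1", "H3K4me3", "H3K27ac", "H3K27me3")

CLASS_ORDER = ("promoter", "enhancer", "gene_body", "intergenic")


def _tree_with_payload(df: pd.DataFrame, payload_cols: list[str]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for row in df.itertuples(index=False):
        data = tuple(getattr(row, c) for c in payload_cols)
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end, data)
    return trees


def drop_promoter_overlapping_enhancers(catalog: FeatureCatalog) -> FeatureCatalog:
    """Remove enhancers overlapping any promoter by >= 1 bp."""
    trees = _tree_with_payload(catalog.promoters, [])
    enh = catalog.enhancers
    keep = [
        not (row.contig in trees and trees[row.contig].overlaps(row.start, row.end))
        for row in enh.itertuples(index=False)
    ]
    return FeatureCatalog(
        promoters=catalog.promoters.copy(),
        enhancers=enh[keep].reset_index(drop=True),
        genes=catalog.genes.copy(),
        blacklist=catalog.blacklist.copy(),
    )


def assign_peaks(peaks: PeakSet, catalog: FeatureCatalog) -> pd.DataFrame:
    """Classify each peak by feature-class precedence.

    Promoter-overlapping enhancers should already have been removed.
    Returns one row per peak: peak_index, contig, start, end, feature_class
    and the comma-joined sorted gene ids of every same-class feature the
    peak overlaps (empty for intergenic).
    """
    layers = [
        ("promoter", _tree_with_payload(catalog.promoters, ["gene_id"])),
        ("enhancer", _tree_with_payload(catalog.enhancers, ["gene_id"])),
        ("gene_body", _tree_with_payload(catalog.genes, ["gene_id"])),
    ]
    rows = []
    for idx, row in enumerate(peaks.df.itertuples(index=False)):
        cls, genes = "intergenic", []
        for name, trees in layers:
            if row.contig in trees:
                hits = trees[row.contig].overlap(row.start, row.end)
                if hits:
                    cls = name
                    genes = sorted({iv.data[0] for iv in hits})
                    break
        rows.append((idx, row.contig, row.start, row.end, cls, ",".join(genes)))
    return pd.DataFrame(
        rows, columns=["peak_index", "contig", "start", "end", "feature_class", "gene_ids"]
    )


def class_percentages(assignment: pd.DataFrame) -> dict[str, float]:
    """Percent of peaks in each class (100 * count / total)."""
    n = len(assignment)
    if n == 0:
        return {cls: 0.0 for cls in CLASS_ORDER}
    counts = assignment["feature_class"].value_counts()
    return {cls: 100.0 * int(counts.get(cls, 0)) / n for cls in CLASS_ORDER}


def feature_universe(catalog: FeatureCatalog) -> pd.DataFrame:
    """All annotated features with their class, one row per feature."""
    frames = []
    for kind, cls in (("promoters", "promoter"), ("enhancers", "enhancer"), ("genes", "gene_body")):
        df = getattr(catalog, kind)[["feature_id", "contig", "start", "end", "gene_id"]].copy()
        df["feature_class"] = cls
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _overlapping_feature_ids(features: pd.DataFrame, peaks: PeakSet) -> set:
    trees = _tree_with_payload(peaks.df, [])
    hit = set()
    for row in features.itertuples(index=False):
        if row.contig in trees and trees[row.contig].overlaps(row.start, row.end):
            hit.add(row.feature_id)
    return hit


def condition_features(features: pd.DataFrame, peak_sets: dict[str, PeakSet]) -> pd.Series:
    """Label each feature by which of (at most two) target sets bind it.

    Labels: ``bound_both``, ``bound_<name>`` or ``unbound``; indexed by
    feature_id.
    """
    if len(peak_sets) > 2:
        raise ValueError("condition_features accepts at most two target peak sets")
    bound = {name: _overlapping_feature_ids(features, ps) for name, ps in peak_sets.items()}
    names = sorted(bound)
    labels = {}
    for fid in features["feature_id"]:
        mine = [n for n in names if fid in bound[n]]
        if len(mine) == 2:
            labels[fid] = "bound_both"
        elif len(mine) == 1:
            labels[fid] = f"bound_{mine[0]}"
        else:
            labels[fid] = "unbound"
    return pd.Series(labels, name="condition").rename_axis("feature_id")


def state_label(marks: frozenset) -> str:
    return "+".join(m for m in MARKS if m in marks) or "none"


def classify_states(features: pd.DataFrame, mark_sets: dict[str, PeakSet]) -> pd.Series:
    """Each feature's chromatin state: the set of marks overlapping it.

    ``mark_sets`` must supply all four marks (possibly with empty peak
    sets).  Returns a Series of '+'-joined mark labels ('none' for the
    empty state), indexed by feature_id.
    """
    missing = set(MARKS) - set(mark_sets)
    if missing:
        raise ValueError(f"mark peak sets missing for {sorted(missing)}")
    hits = {mark: _overlapping_feature_ids(features, mark_sets[mark]) for mark in MARKS}
    states = {
        fid: state_label(frozenset(m for m in MARKS if fid in hits[m]))
        for fid in features["feature_id"]
    }
    return pd.Series(states, name="state").rename_axis("feature_id")


def state_distribution(
    features: pd.DataFrame, states: pd.Series, conditions: pd.Series
) -> pd.DataFrame:
    """Fraction of features in each state per (feature_class, condition).

    Long-format rows (feature_class, condition, state, fraction, n);
    fractions within each (feature_class, condition) sum to 1.
    """
    df = features[["feature_id", "feature_class"]].copy()
    df["state"] = df["feature_id"].map(states)
    df["condition"] = df["feature_id"].map(conditions)
    rows = []
    for (cls, cond), grp in df.groupby(["feature_class", "condition"], sort=True):
        total = len(grp)
        for state, n in grp["state"].value_counts().sort_index().items():
            rows.append((cls, cond, state, n / total, int(n)))
    return pd.DataFrame(rows, columns=["feature_class", "condition", "state", "fraction", "n"])


def gene_level_state(gene_id: str, catalog: FeatureCatalog, states: pd.Series) -> dict:
    """The gene's unique promoter (and, when linked, enhancer) state.

    Multi-promoter/multi-enhancer genes are resolved to the
    lexicographically smallest feature id and flagged.
    """
    if gene_id not in set(catalog.genes["gene_id"]):
        raise KeyError(f"unknown gene id {gene_id!r}")
    record: dict = {"gene_id": gene_id}
    for kind, tab in (("promoter", catalog.promoters), ("enhancer", catalog.enhancers)):
        ids = sorted(tab.loc[tab["gene_id"] == gene_id, "feature_id"])
        record[f"{kind}_id"] = ids[0] if ids else None
        record[f"{kind}_state"] = states.get(ids[0]) if ids else None
        record[f"{kind}_multi"] = len(ids) > 1
    return record


def gene_state_table(catalog: FeatureCatalog, states: pd.Series) -> pd.DataFrame:
    """One record per gene in the catalog (cardinality = number of genes)."""
    rows = [gene_level_state(g, catalog, states) for g in catalog.genes["gene_id"]]
    return pd.DataFrame(rows)
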