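"""Differential-expression set construction and binding integration.

Two named threshold presets are provided:

* ``volcano`` — p < 0.05 and |log2FC| > 1 (the p-value field, raw or
  adjusted, must be chosen explicitly).
* ``strict_fc`` — adjusted p < 0.001 and linear |FC| > 1.5
  (|log2FC| > log2 1.5).

All inequalities are strict.  Double-mutant-specific genes additionally
require |log2FC_double| > r * |log2FC_single| for both singles (default
r = 1.3), with sign agreement between double and singles required;
genes excluded solely by sign disagreement are reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import validate_de_table

__all__ = [
    "DEThresholds",
    "DESets",
    "VOLCANO",
    "STRICT_FC",
    "filter_low_counts",
    "classify_de",
    "double_specific_sets",
    "venn_counts",
    "link_de_to_binding",
]


@dataclass(frozen=True)
class DEThresholds:
    name: str
    p_field: str  # "pvalue" (raw) or "padj" (adjusted) — must be explicit
    p_cutoff: float
    log2fc_cutoff: float
    double_ratio: float = 1.3

    def __post_init__(self) -> None:
        if self.p_field not in ("pvalue", "padj"):
            raise ValueError("p_field must be 'pvalue' or 'padj'")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p cutoff must lie in (0, 1)")
        if self.log2fc_cutoff <= 0 or self.double_ratio <= 0:
            raise ValueError("cutoffs must be positive")


VOLCANO = DEThresholds("volcano", p_field="pvalue", p_cutoff=0.05, log2fc_cutoff=1.0)
STRICT_FC = DEThresholds(
    "strict_fc", p_field="padj", p_cutoff=0.001, log2fc_cutoff=math.log2(1.5)
)


@dataclass
class DESets:
    contrast: str
    up: set = field(default_factory=set)
    down: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up- and down-regulated")


def filter_low_counts(table: pd.DataFrame, min_sum: int) -> pd.DataFrame:
    """Drop genes whose raw counts sum over all samples is < min_sum."""
    if min_sum < 0:
        raise ValueError("min_sum must be >= 0")
    count_cols = [c for c in table.columns if c.startswith("counts_")]
    if not count_cols:
        raise ValueError("DE table has no counts_* columns")
    keep = table[count_cols].sum(axis=1) >= min_sum
    return table[keep].reset_index(drop=True)


def classify_de(table: pd.DataFrame, thr: DEThresholds) -> DESets:
    """Up/down gene sets under a threshold rule (strict inequalities)."""
    validate_de_table(table)
    sig = table[thr.p_field] < thr.p_cutoff
    up = set(table.loc[sig & (table["log2fc"] > thr.log2fc_cutoff), "gene_id"])
    down = set(table.loc[sig & (table["log2fc"] < -thr.log2fc_cutoff), "gene_id"])
    return DESets(contrast=thr.name, up=up, down=down)


def _universe(table: pd.DataFrame) -> set:
    return set(table["gene_id"])


def double_specific_sets(
    single_c: pd.DataFrame,
    single_d: pd.DataFrame,
    double: pd.DataFrame,
    thr: DEThresholds = STRICT_FC,
) -> dict:
    """Mutation-specific gene sets for two single mutants and their double.

    * ``C_specific`` / ``D_specific``: genes passing ``thr`` in one single
      mutant with any gene also passing in the other single removed.
    * ``double_specific``: genes passing ``thr`` in the double mutant whose
      |log2FC| exceeds ``thr.double_ratio`` times the |log2FC| of *both*
      singles, with matching sign; ``sign_flagged`` lists genes that met
      the magnitude rule but were excluded because a single-mutant log2FC
      has the opposite sign.
    """
    uni = _universe(double)
    for name, tab in (("single_C", single_c), ("single_D", single_d)):
        missing = uni ^ _universe(tab)
        if missing:
            raise ValueError(
                f"gene universe mismatch with {name}: {sorted(missing)[:10]}"
            )
    sets_c = classify_de(single_c, thr)
    sets_d = classify_de(single_d, thr)
    sets_dd = classify_de(double, thr)

    lfc_c = single_c.set_index("gene_id")["log2fc"]
    lfc_d = single_d.set_index("gene_id")["log2fc"]
    lfc_dd = double.set_index("gene_id")["log2fc"]

    out: dict = {
        "C_specific_up": sets_c.up - sets_d.up,
        "C_specific_down": sets_c.down - sets_d.down,
        "D_specific_up": sets_d.up - sets_c.up,
        "D_specific_down": sets_d.down - sets_c.down,
    }
    r = thr.double_ratio
    for direction, dd_set in (("up", sets_dd.up), ("down", sets_dd.down)):
        chosen, flagged = set(), set()
        for gene in dd_set:
            d_val = lfc_dd[gene]
            magnitude_ok = abs(d_val) > r * abs(lfc_c[gene]) and abs(d_val) > r * abs(
                lfc_d[gene]
            )
            if not magnitude_ok:
                continue
            signs_agree = (
                np.sign(lfc_c[gene]) in (0, np.sign(d_val))
                and np.sign(lfc_d[gene]) in (0, np.sign(d_val))
            )
            (chosen if signs_agree else flagged).add(gene)
        out[f"double_specific_{direction}"] = chosen
        out[f"double_sign_flagged_{direction}"] = flagged
    return out


def venn_counts(sets: dict[str, set]) -> dict[str, int]:
    """Exact-membership counts for every nonempty intersection region.

    For sets A, B, C the region 'A&B' counts elements in A and B but not C.
    Region counts sum to the size of the union.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 sets")
    names = sorted(sets)
    union = set().union(*sets.values())
    counts: dict[str, int] = {}
    for mask in range(1, 2 ** len(names)):
        inside = [names[i] for i in range(len(names)) if mask >> i & 1]
        outside = [n for n in names if n not in inside]
        region = set(union)
        for n in inside:
            region &= sets[n]
        for n in outside:
            region -= sets[n]
        counts["&".join(inside)] = len(region)
    return counts


def link_de_to_binding(de: DESets, groups: dict[str, set]) -> tuple[pd.DataFrame, set]:
    """Contingency of DE genes across binding-condition gene groups.

    ``groups`` must partition a gene universe.  Returns a long table
    (group, direction, count, fraction — fractions per direction sum to 1
    over the groups) and the set of DE genes outside the universe.
    """
    names = sorted(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if groups[a] & groups[b]:
                raise ValueError(f"groups {a!r} and {b!r} overlap; not a partition")
    universe = set().union(*groups.values()) if groups else set()
    outside = (de.up | de.down) - universe
    rows = []
    for direction, genes in (("up", de.up), ("down", de.down)):
        in_uni = genes & universe
        for name in names:
            n = len(genes & groups[name])
            frac = n / len(in_uni) if in_uni else 0.0
            rows.append((name, direction, n, frac))
    return pd.DataFrame(rows, columns=["group", "direction", "count", "fraction"]), outside
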