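"""Synthetic CUT&RUN / RNA-seq data with planted ground truth.

The generator emulates the statistical structure of spike-in calibrated
CUT&RUN libraries and bulk RNA-seq DE tables: a uniform Poisson fragment
background over the genome contigs, planted binding sites whose expected
in-site fragment density is ``enrichment`` times the background, a
spike-in contig receiving a planted fraction of the library, promoter /
enhancer / gene annotations with planted histone-mark combination states,
and negative-binomial DE tables with planted log2 fold changes.

Every quantity is drawn from a stream keyed by (seed, stream name), so
adding samples never perturbs existing ones and identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .core import FeatureCatalog, FragmentSet, GenomeLayout

__all__ = [
    "SimulationConfig",
    "TruthBundle",
    "generate_layout_and_catalog",
    "simulate_sample",
    "simulate_de_table",
    "write_truth",
    "read_truth",
]

PROMOTER_UP = 1000  # promoter window upstream of the TSS, bp
PROMOTER_DOWN = 100  # and downstream, bp

DEFAULT_PROMOTER_MARK_PROBS = {
    "H3K4me1": 0.15,
    "H3K4me3": 0.6,
    "H3K27ac": 0.4,
    "H3K27me3": 0.2,
}
DEFAULT_ENHANCER_MARK_PROBS = {
    "H3K4me1": 0.6,
    "H3K4me3": 0.05,
    "H3K27ac": 0.35,
    "H3K27me3": 0.15,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    contigs: dict = field(default_factory=lambda: {"chr1": 2_000_000})
    spike_contig: str = "spike"
    spike_length: int = 100_000
    # binding sites
    n_sites: int = 200
    site_width: int = 1_000
    enrichment: float = 8.0  # in-site fragment density / background density
    target_membership_probs: tuple = (0.35, 0.35, 0.3)  # C only, D only, both
    # fragment model
    background_rate: float = 0.02  # fragments per bp (lambda = 10 per 500 bp)
    spike_fraction: float = 0.01  # spike reads / total reads
    fragment_min: int = 80
    fragment_max: int = 300
    # annotation
    n_genes: int = 120
    gene_length: int = 4_000
    n_enhancers: int = 150
    enhancer_width: int = 600
    frac_overlapping_enhancers: float = 0.2
    n_blacklist: int = 10
    blacklist_width: int = 2_000
    # histone-mark plan
    mark_enrichment: float = 8.0
    promoter_mark_probs: dict = field(default_factory=lambda: dict(DEFAULT_PROMOTER_MARK_PROBS))
    enhancer_mark_probs: dict = field(default_factory=lambda: dict(DEFAULT_ENHANCER_MARK_PROBS))
    # DE plan
    de_frac_nonnull: float = 0.1
    de_effect_mean: float = 2.0
    de_effect_sd: float = 0.5
    de_sigma_null: float = 0.15
    de_noise_free: bool = True  # planted log2FC reported exactly
    de_nb_mean_log: float = 5.5  # lognormal mean of baseline counts
    de_nb_mean_sigma: float = 1.2
    de_dispersion: float = 0.1
    de_samples_per_group: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ValueError("spike_fraction must lie in (0, 1)")
        if self.background_rate <= 0:
            raise ValueError("background_rate must be positive")
        if self.enrichment < 1 or self.mark_enrichment < 1:
            raise ValueError("enrichment factors must be >= 1")
        for frac in (self.frac_overlapping_enhancers, self.de_frac_nonnull):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TruthBundle:
    """Planted ground truth written alongside every synthetic dataset."""

    sites: pd.DataFrame  # site_id, contig, start, end, enrichment, targets
    spike_fraction: float
    feature_states: pd.DataFrame  # feature_id, state
    de: pd.DataFrame  # gene_id, is_de, true_log2fc

    def sites_for_target(self, target: str) -> pd.DataFrame:
        mask = self.sites["targets"].str.split(",").apply(lambda t: target in t)
        return self.sites[mask].reset_index(drop=True)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(stream.encode())])


def _place_nonoverlapping(rng: np.random.Generator, length: int, widths: np.ndarray) -> np.ndarray:
    """Starts of non-overlapping intervals with the given widths, uniformly
    at random, in random order along the contig."""
    widths = np.asarray(widths, dtype=np.int64)
    free = length - int(widths.sum())
    if free < 0:
        raise ValueError(
            f"genome too small: need >= {int(widths.sum())} bp for features, have {length}"
        )
    perm = rng.permutation(len(widths))
    u = np.sort(rng.integers(0, free + 1, size=len(widths)))
    starts_perm = u + np.concatenate(([0], np.cumsum(widths[perm][:-1])))
    starts = np.empty(len(widths), dtype=np.int64)
    starts[perm] = starts_perm
    return starts


def generate_layout_and_catalog(config: SimulationConfig):
    """Build the genome layout, annotation catalog and planted truth."""
    rng = _rng(config.seed, "catalog")
    lengths = dict(config.contigs)
    lengths[config.spike_contig] = config.spike_length
    layout = GenomeLayout(lengths, frozenset({config.spike_contig}))

    contig_names = list(config.contigs)
    contig_lens = np.array([config.contigs[c] for c in contig_names], dtype=float)
    probs = contig_lens / contig_lens.sum()

    n_overlap = int(round(config.frac_overlapping_enhancers * config.n_enhancers))
    n_distal = config.n_enhancers - n_overlap
    if n_overlap > config.n_genes:
        raise ValueError("more overlapping enhancers requested than promoters available")

    # one exclusive block per gene (promoter margin + body), distal enhancer
    # and blacklist region; blocks are mutually non-overlapping per contig
    kinds = (
        ["gene"] * config.n_genes + ["enhancer"] * n_distal + ["blacklist"] * config.n_blacklist
    )
    widths = np.array(
        [PROMOTER_UP + config.gene_length] * config.n_genes
        + [config.enhancer_width] * n_distal
        + [config.blacklist_width] * config.n_blacklist,
        dtype=np.int64,
    )
    homes = rng.choice(len(contig_names), size=len(kinds), p=probs)
    placed = {"gene": [], "enhancer": [], "blacklist": []}
    for ci, cname in enumerate(contig_names):
        mask = homes == ci
        if not mask.any():
            continue
        starts = _place_nonoverlapping(rng, config.contigs[cname], widths[mask])
        for kind, width, start in zip(
            np.array(kinds)[mask], widths[mask], starts
        ):
            placed[kind].append((cname, int(start), int(start + width)))

    genes, promoters = [], []
    for i, (cname, block_s, block_e) in enumerate(sorted(placed["gene"])):
        gid = f"G{i:05d}"
        tss = block_s + PROMOTER_UP
        genes.append((gid, cname, tss, block_e, gid))
        promoters.append((f"P{i:05d}", cname, tss - PROMOTER_UP, tss + PROMOTER_DOWN, gid))
    genes_df = pd.DataFrame(genes, columns=["feature_id", "contig", "start", "end", "gene_id"])
    prom_df = pd.DataFrame(promoters, columns=["feature_id", "contig", "start", "end", "gene_id"])

    enhancers = []
    gene_ids = list(genes_df["gene_id"])
    for cname, s, e in sorted(placed["enhancer"]):
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        enhancers.append((cname, s, e, gid, round(float(rng.uniform(1, 30)), 2)))
    # planted promoter-overlapping enhancers (exercise their removal)
    overlap_prom_idx = rng.choice(len(prom_df), size=n_overlap, replace=False)
    for pi in sorted(overlap_prom_idx):
        prow = prom_df.iloc[int(pi)]
        length = config.contigs[prow["contig"]]
        start = int(min(max(prow["end"] - config.enhancer_width // 2, 0), length - config.enhancer_width))
        gid = gene_ids[int(rng.integers(0, len(gene_ids)))]
        enhancers.append((prow["contig"], start, start + config.enhancer_width, gid,
                          round(float(rng.uniform(1, 30)), 2)))
    enh_df = pd.DataFrame(enhancers, columns=["contig", "start", "end", "gene_id", "score"])
    enh_df = enh_df.sort_values(["contig", "start", "end"]).reset_index(drop=True)
    enh_df.insert(0, "feature_id", [f"E{i:05d}" for i in range(len(enh_df))])

    bl_df = pd.DataFrame(sorted(placed["blacklist"]), columns=["contig", "start", "end"])

    catalog = FeatureCatalog(
        promoters=prom_df, enhancers=enh_df, genes=genes_df, blacklist=bl_df
    )

    sites = _plant_sites(rng, config, contig_names, probs, bl_df)
    feature_states = _plant_states(rng, config, prom_df, enh_df)
    de_truth = _plant_de(rng, config, genes_df)

    truth = TruthBundle(
        sites=sites,
        spike_fraction=config.spike_fraction,
        feature_states=feature_states,
        de=de_truth,
    )
    return layout, catalog, truth


def _plant_sites(rng, config, contig_names, probs, blacklist: pd.DataFrame) -> pd.DataFrame:
    """Non-overlapping binding sites placed outside the blacklist, by
    rejection sampling (they may overlap genes and regulatory features)."""
    taken: dict[str, list] = {c: sorted(
        (int(r.start), int(r.end)) for r in blacklist.itertuples(index=False) if r.contig == c
    ) for c in contig_names}
    labels = ["C", "D", "C,D"]
    rows = []
    attempts = 0
    while len(rows) < config.n_sites:
        attempts += 1
        if attempts > 200 * config.n_sites:
            raise ValueError("genome too small to place the requested binding sites")
        ci = int(rng.choice(len(contig_names), p=probs))
        cname = contig_names[ci]
        length = config.contigs[cname]
        if length < config.site_width:
            continue
        start = int(rng.integers(0, length - config.site_width + 1))
        end = start + config.site_width
        if any(s < end and start < e for s, e in taken[cname]):
            continue
        taken[cname].append((start, end))
        membership = labels[int(rng.choice(3, p=list(config.target_membership_probs)))]
        rows.append((cname, start, end, float(config.enrichment), membership))
    rows.sort()
    return pd.DataFrame(
        [(f"S{i:05d}",) + r for i, r in enumerate(rows)],
        columns=["site_id", "contig", "start", "end", "enrichment", "targets"],
    )


def _plant_states(rng, config, prom_df, enh_df) -> pd.DataFrame:
    from .annotation import MARKS, state_label

    rows = []
    for df, prob_map in ((prom_df, config.promoter_mark_probs), (enh_df, config.enhancer_mark_probs)):
        for fid in df["feature_id"]:
            marks = frozenset(m for m in MARKS if rng.uniform() < prob_map.get(m, 0.0))
            rows.append((fid, state_label(marks)))
    return pd.DataFrame(rows, columns=["feature_id", "state"])


def _plant_de(rng, config, genes_df) -> pd.DataFrame:
    gene_ids = list(genes_df["gene_id"])
    n = len(gene_ids)
    n_de = int(round(config.de_frac_nonnull * n))
    de_idx = set(rng.choice(n, size=n_de, replace=False).tolist())
    rows = []
    for i, gid in enumerate(gene_ids):
        if i in de_idx:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            lfc = sign * abs(rng.normal(config.de_effect_mean, config.de_effect_sd))
            rows.append((gid, True, float(lfc)))
        else:
            rows.append((gid, False, 0.0))
    return pd.DataFrame(rows, columns=["gene_id", "is_de", "true_log2fc"])


def _planted_intervals(truth: TruthBundle, role: str, mark: str | None, target: str | None):
    """(contig, start, end, enrichment) rows the sample is enriched at."""
    if role == "IgG":
        return []
    if role == "target":
        if target is None:
            raise ValueError("role='target' requires target='C' or 'D'")
        df = truth.sites_for_target(target)
        return list(zip(df["contig"], df["start"], df["end"], df["enrichment"]))
    raise ValueError(f"unknown role {role!r}")


def simulate_sample(
    layout: GenomeLayout,
    truth: TruthBundle,
    config: SimulationConfig,
    role: str,
    sample_id: str | None = None,
    mark: str | None = None,
    target: str | None = None,
    catalog: FeatureCatalog | None = None,
) -> FragmentSet:
    """Simulate one library: uniform Poisson background over the genome
    contigs, planted enrichment at the role's sites, and a spike-in
    component sized so spike/genome read counts match the planted
    fraction.  ``role`` is 'IgG', 'target' (with target='C'|'D') or 'mark'
    (with a mark name and the catalog, whose planted-state features define
    the mark's sites)."""
    if role not in ("IgG", "target", "mark"):
        raise ValueError(f"unknown role {role!r}")
    if sample_id is None:
        sample_id = {"IgG": "IgG", "target": f"target_{target}", "mark": str(mark)}[role]
    rng = _rng(config.seed, f"sample:{sample_id}")

    if role == "mark":
        if mark is None or catalog is None:
            raise ValueError("role='mark' requires mark=<name> and the catalog")
        state_map = dict(zip(truth.feature_states["feature_id"], truth.feature_states["state"]))
        feats = pd.concat([catalog.promoters, catalog.enhancers], ignore_index=True)
        sel = feats["feature_id"].map(lambda f: mark in state_map.get(f, "").split("+"))
        planted = [
            (r.contig, int(r.start), int(r.end), config.mark_enrichment)
            for r in feats[sel].itertuples(index=False)
        ]
    else:
        planted = _planted_intervals(truth, role, mark, target)

    contigs_out, mids_out = [], []
    for cname in layout.genome_contigs:
        length = layout.lengths[cname]
        n_bg = int(rng.poisson(config.background_rate * length))
        mids = rng.integers(0, length, size=n_bg)
        contigs_out.append(np.full(n_bg, cname, dtype="U64"))
        mids_out.append(mids)
    for cname, s, e, enrich in planted:
        extra = int(rng.poisson((enrich - 1.0) * config.background_rate * (e - s)))
        if extra:
            contigs_out.append(np.full(extra, cname, dtype="U64"))
            mids_out.append(rng.integers(s, e, size=extra))
    contigs = np.concatenate(contigs_out) if contigs_out else np.array([], dtype="U64")
    mids = np.concatenate(mids_out).astype(np.int64) if mids_out else np.array([], dtype=np.int64)

    # spike-in: expected spike/genome ratio f/(1-f)
    n_genome = len(mids)
    f = config.spike_fraction
    n_spike = int(rng.poisson(n_genome * f / (1.0 - f)))
    spike_contig = sorted(layout.spike_contigs)[0]
    spike_len = layout.lengths[spike_contig]
    contigs = np.concatenate([contigs, np.full(n_spike, spike_contig, dtype="U64")])
    mids = np.concatenate([mids, rng.integers(0, spike_len, size=n_spike).astype(np.int64)])

    widths = rng.integers(config.fragment_min, config.fragment_max + 1, size=len(mids))
    uniq, inverse = np.unique(contigs, return_inverse=True)
    lens = np.array([layout.lengths[str(c)] for c in uniq], dtype=np.int64)[inverse]
    starts = np.maximum(mids - widths // 2, 0)
    ends = np.minimum(starts + widths, lens)
    starts = np.minimum(starts, ends - 1)  # guard degenerate clips at contig ends

    order_key = {c: i for i, c in enumerate(layout.contigs)}
    keys = np.array([order_key[str(c)] for c in uniq])[inverse]
    order = np.lexsort((ends, starts, keys))
    return FragmentSet(
        sample_id=sample_id,
        contigs=contigs[order],
        starts=starts[order],
        ends=ends[order],
        layout=layout,
    )


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH adjusted p-values (scipy's step-up FDR control)."""
    return stats.false_discovery_control(np.asarray(pvals, dtype=float), method="bh")


def simulate_de_table(config: SimulationConfig, truth: TruthBundle) -> pd.DataFrame:
    """DE table with planted effects: null genes get N(0, sigma_null)
    log2FC and uniform p; planted genes their true log2FC (exactly, unless
    de_noise_free is off) and a tiny p.  Counts are negative binomial with
    the group-2 mean shifted by 2**log2FC; adjusted p is Benjamini-
    Hochberg over the table."""
    rng = _rng(config.seed, "de")
    rows = []
    k = config.de_samples_per_group
    inv_disp = 1.0 / config.de_dispersion
    for r in truth.de.itertuples(index=False):
        if r.is_de:
            lfc = r.true_log2fc if config.de_noise_free else r.true_log2fc + rng.normal(0, 0.1)
            p = float(rng.uniform(0.0, 1e-8))
        else:
            lfc = float(rng.normal(0.0, config.de_sigma_null))
            p = float(rng.uniform())
        mu = float(rng.lognormal(config.de_nb_mean_log, config.de_nb_mean_sigma))
        mu2 = mu * 2.0 ** lfc
        c1 = rng.negative_binomial(inv_disp, inv_disp / (inv_disp + mu), size=k)
        c2 = rng.negative_binomial(inv_disp, inv_disp / (inv_disp + mu2), size=k)
        rows.append([r.gene_id, float(lfc), p] + c1.tolist() + c2.tolist())
    cols = (
        ["gene_id", "log2fc", "pvalue"]
        + [f"counts_ctrl_{i + 1}" for i in range(k)]
        + [f"counts_mut_{i + 1}" for i in range(k)]
    )
    df = pd.DataFrame(rows, columns=cols)
    df.insert(3, "padj", benjamini_hochberg(df["pvalue"].to_numpy()))
    return df


def write_truth(truth: TruthBundle, path: str) -> None:
    payload = {
        "sites": truth.sites.to_dict(orient="list"),
        "spike_fraction": truth.spike_fraction,
        "feature_states": truth.feature_states.to_dict(orient="list"),
        "de": truth.de.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path: str) -> TruthBundle:
    with open(path) as fh:
        payload = json.load(fh)
    return TruthBundle(
        sites=pd.DataFrame(payload["sites"])[
            ["site_id", "contig", "start", "end", "enrichment", "targets"]
        ],
        spike_fraction=payload["spike_fraction"],
        feature_states=pd.DataFrame(payload["feature_states"])[["feature_id", "state"]],
        de=pd.DataFrame(payload["de"])[["gene_id", "is_de", "true_log2fc"]],
    )
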