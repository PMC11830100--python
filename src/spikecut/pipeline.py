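"""End-to-end orchestration of the synthetic-data analysis.

``run_pipeline`` simulates a full spike-in calibrated CUT&RUN experiment
(IgG control, two targets, four histone marks), normalizes, calls and
filters peaks, overlaps the target peak sets, annotates and classifies
chromatin states, builds a signal matrix, constructs DE sets and joins
them to binding-conditioned gene groups.  Every stage writes stable
filenames and the manifest records the seed, all parameters, per-sample
normalization factors, per-stage record counts and output hashes, so an
identical config reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
import os

import pandas as pd

from . import annotation, de as de_mod, io, normalization, peaks as peaks_mod, signal as signal_mod
from .core import TagTrack
from .simulate import SimulationConfig, generate_layout_and_catalog, simulate_de_table, simulate_sample, write_truth

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulation": {},  # overrides for SimulationConfig fields
    "samples": [
        {"id": "IgG", "role": "IgG"},
        {"id": "target_C", "role": "target", "target": "C"},
        {"id": "target_D", "role": "target", "target": "D"},
        {"id": "H3K4me1", "role": "mark", "mark": "H3K4me1"},
        {"id": "H3K4me3", "role": "mark", "mark": "H3K4me3"},
        {"id": "H3K27ac", "role": "mark", "mark": "H3K27ac"},
        {"id": "H3K27me3", "role": "mark", "mark": "H3K27me3"},
    ],
    "normalization": {"scheme": "spike_ratio", "aimed_reads": {}, "processed_reads": {}},
    "tracks": {"binsize": 50},
    "peaks": {"window": 500, "gap": 1000, "fold": 4.0, "alpha": 1e-4, "lam_min": 0.5},
    "matrix": {"flank": 4000, "binsize": 50, "pseudocount": 1.0},
    "de": {"enabled": True, "rule": "volcano", "p_field": "pvalue", "min_count_sum": 60},
    "write_fragments": False,
}


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (extra or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    """Default config, optionally merged with a YAML file and overrides."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml

        with open(path) as fh:
            config = _deep_merge(config, yaml.safe_load(fh) or {})
    if overrides:
        config = _deep_merge(config, overrides)
    _validate_config(config)
    return config


def _validate_config(config: dict) -> None:
    roles = [s.get("role") for s in config.get("samples", [])]
    if "IgG" not in roles:
        raise PipelineError(
            "stage=validate: the sample plan must include an IgG control "
            "(peak calling is referenced to the IgG background)"
        )
    if config["normalization"]["scheme"] not in ("spike_ratio", "aimed_reads"):
        raise PipelineError("stage=validate: unknown normalization scheme")
    if config["de"]["enabled"] and config["de"]["rule"] not in ("volcano", "strict_fc"):
        raise PipelineError("stage=validate: unknown DE rule")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _de_thresholds(de_cfg: dict) -> de_mod.DEThresholds:
    if de_cfg["rule"] == "volcano":
        base = de_mod.VOLCANO
    else:
        base = de_mod.STRICT_FC
    return dataclasses.replace(base, p_field=de_cfg["p_field"])


def run_pipeline(config: dict, outdir: str) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest."""
    _validate_config(config)
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {"config": config, "seed": config["seed"], "stages": {}, "outputs": {}}

    def emit(name: str, path: str) -> None:
        manifest["outputs"][name] = {"path": os.path.basename(path), "sha256": _sha256(path)}

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimulationConfig(seed=config["seed"], **config["simulation"])
    try:
        layout, catalog, truth = generate_layout_and_catalog(sim_cfg)
    except ValueError as exc:
        raise PipelineError(f"stage=simulate: {exc}") from exc
    io.write_layout(layout, os.path.join(outdir, "layout.tsv"))
    emit("layout", os.path.join(outdir, "layout.tsv"))
    for kind, path in io.write_catalog(catalog, outdir).items():
        emit(kind, path)
    write_truth(truth, os.path.join(outdir, "truth.json"))
    emit("truth", os.path.join(outdir, "truth.json"))

    frags = {}
    for sample in config["samples"]:
        frags[sample["id"]] = simulate_sample(
            layout,
            truth,
            sim_cfg,
            role=sample["role"],
            sample_id=sample["id"],
            mark=sample.get("mark"),
            target=sample.get("target"),
            catalog=catalog,
        )
    manifest["stages"]["simulate"] = {s: len(f) for s, f in frags.items()}

    # --- normalize --------------------------------------------------------
    igg_id = next(s["id"] for s in config["samples"] if s["role"] == "IgG")
    counts = {sid: io.count_reads(f) for sid, f in frags.items()}
    factors, scales = {}, {}
    rows = []
    for sid, ac in counts.items():
        if sid == igg_id:
            continue
        try:
            sf = normalization.compute_size_factors(ac, counts[igg_id])
            sc = normalization.coverage_scale(ac, counts[igg_id])
        except ValueError as exc:
            raise PipelineError(f"stage=normalize sample={sid}: {exc}") from exc
        factors[sid], scales[sid] = sf, sc
        rows.append(
            {
                "sample_id": sid,
                "scheme": config["normalization"]["scheme"],
                "genome_reads": ac.genome_reads,
                "spike_reads": ac.spike_reads,
                "ratio_expr": sf.ratio_expr,
                "ratio_ctrl": sf.ratio_ctrl,
                "size_factor": sf.size_factor,
                "norm_ctrl_genome": sf.norm_ctrl_genome,
                "coverage_scale_S": sc.S,
            }
        )
    if config["normalization"]["scheme"] == "aimed_reads":
        aimed = config["normalization"]["aimed_reads"]
        processed = config["normalization"]["processed_reads"]
        alt_samples = [
            normalization.AltSample(
                counts=counts[sid],
                aimed_reads=float(aimed.get(sid, counts[sid].total)),
                processed_reads=float(processed.get(sid, counts[sid].total)),
            )
            for sid in counts
        ]
        alt = normalization.compute_alt_norm(alt_samples, counts[igg_id])
        alt_by_id = {a.sample_id: a for a in alt}
        for row in rows:
            row["norm_sample_genome"] = alt_by_id[row["sample_id"]].norm_sample_genome
    factors_path = os.path.join(outdir, "normalization_factors.tsv")
    pd.DataFrame(rows).to_csv(factors_path, sep="\t", index=False)
    emit("normalization_factors", factors_path)
    manifest["stages"]["normalize"] = {r["sample_id"]: r["size_factor"] for r in rows}

    # --- peak calling -----------------------------------------------------
    binsize = config["tracks"]["binsize"]
    tracks = {sid: TagTrack.from_fragments(f, binsize=binsize) for sid, f in frags.items()}
    params = peaks_mod.PeakCallParams(**config["peaks"])
    peak_sets = {}
    peak_counts = {}
    for sid in tracks:
        if sid == igg_id:
            continue
        called = peaks_mod.call_peaks(
            tracks[sid], tracks[igg_id], factors[sid], params, sample_id=sid
        )
        filtered = peaks_mod.filter_blacklist(called, catalog.blacklist)
        peak_sets[sid] = filtered
        peak_counts[sid] = {"called": len(called), "after_blacklist": len(filtered)}
        path = os.path.join(outdir, f"peaks_{sid}.bed")
        io.write_peaks(filtered, path)
        emit(f"peaks_{sid}", path)
    manifest["stages"]["peaks"] = peak_counts

    # --- cross-sample overlap (target C vs target D) ----------------------
    target_ids = [s["id"] for s in config["samples"] if s["role"] == "target"]
    if len(target_ids) >= 2:
        clusters, cluster_counts = peaks_mod.overlap_peak_sets(
            {tid: peak_sets[tid] for tid in target_ids[:2]}
        )
        path = os.path.join(outdir, "overlap_clusters.tsv")
        clusters.to_csv(path, sep="\t", index=False)
        emit("overlap_clusters", path)
        manifest["stages"]["overlap"] = cluster_counts

    # --- annotation and chromatin states ----------------------------------
    catalog2 = annotation.drop_promoter_overlapping_enhancers(catalog)
    primary_target = target_ids[0] if target_ids else next(iter(peak_sets))
    assignment = annotation.assign_peaks(peak_sets[primary_target], catalog2)
    path = os.path.join(outdir, "peak_assignment.tsv")
    assignment.to_csv(path, sep="\t", index=False)
    emit("peak_assignment", path)
    manifest["stages"]["annotation"] = {
        "enhancers_removed": len(catalog.enhancers) - len(catalog2.enhancers),
        "class_percentages": annotation.class_percentages(assignment),
    }

    features = annotation.feature_universe(catalog2)
    conditions = annotation.condition_features(
        features, {tid: peak_sets[tid] for tid in target_ids[:2]}
    )
    mark_ids = {s["mark"]: s["id"] for s in config["samples"] if s["role"] == "mark"}
    states = annotation.classify_states(
        features, {mark: peak_sets[sid] for mark, sid in mark_ids.items()}
    )
    dist = annotation.state_distribution(features, states, conditions)
    per_feature = features[["feature_id", "feature_class"]].copy()
    per_feature["condition"] = per_feature["feature_id"].map(conditions)
    per_feature["state"] = per_feature["feature_id"].map(states)
    for name, df in (("feature_states", per_feature), ("state_distribution", dist)):
        path = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(path, sep="\t", index=False)
        emit(name, path)
    gene_states = annotation.gene_state_table(catalog2, states)
    path = os.path.join(outdir, "gene_states.tsv")
    gene_states.to_csv(path, sep="\t", index=False)
    emit("gene_states", path)
    manifest["stages"]["states"] = {"features": len(per_feature), "genes": len(gene_states)}

    # --- signal matrix around primary-target peaks ------------------------
    mcfg = config["matrix"]
    scale = scales[primary_target]
    ratio = signal_mod.log2_ratio_track(
        tracks[primary_target], tracks[igg_id], scale, pseudocount=mcfg["pseudocount"]
    )
    if len(peak_sets[primary_target]):
        matrix = signal_mod.compute_matrix(
            ratio, peak_sets[primary_target].intervals(), flank=mcfg["flank"], binsize=mcfg["binsize"]
        )
        profile, order = signal_mod.profile_and_order(matrix)
        mat_path = os.path.join(outdir, "signal_matrix.tsv")
        matrix.to_frame().to_csv(mat_path, sep="\t", index=False)
        emit("signal_matrix", mat_path)
        prof_path = os.path.join(outdir, "signal_profile.tsv")
        pd.DataFrame({"offset": matrix.offsets, "mean_log2_ratio": profile}).to_csv(
            prof_path, sep="\t", index=False
        )
        emit("signal_profile", prof_path)
        manifest["stages"]["matrix"] = {"regions": len(matrix.region_ids), "columns": len(matrix.offsets)}
    else:
        manifest["stages"]["matrix"] = "skipped (no peaks)"

    # --- DE integration ----------------------------------------------------
    if config["de"]["enabled"]:
        thr = _de_thresholds(config["de"])
        table = simulate_de_table(sim_cfg, truth)
        table = de_mod.filter_low_counts(table, config["de"]["min_count_sum"])
        de_path = os.path.join(outdir, "de_table.tsv")
        io.write_de_table(table, de_path)
        emit("de_table", de_path)
        sets = de_mod.classify_de(table, thr)
        sets_df = pd.DataFrame(
            [("de", "up", g) for g in sorted(sets.up)] + [("de", "down", g) for g in sorted(sets.down)],
            columns=["contrast", "direction", "gene_id"],
        )
        path = os.path.join(outdir, "de_sets.tsv")
        sets_df.to_csv(path, sep="\t", index=False)
        emit("de_sets", path)

        # join DE genes to promoter binding conditions at gene level
        prom_cond = per_feature[per_feature["feature_class"] == "promoter"]
        gene_of = dict(zip(catalog2.promoters["feature_id"], catalog2.promoters["gene_id"]))
        groups: dict[str, set] = {}
        seen = set()
        for row in prom_cond.itertuples(index=False):
            gene = gene_of[row.feature_id]
            if gene in seen:  # multi-promoter genes: first (smallest) feature id wins
                continue
            seen.add(gene)
            groups.setdefault(row.condition, set()).add(gene)
        promoterless = set(catalog2.genes["gene_id"]) - seen
        if promoterless:
            groups.setdefault("no_promoter", set()).update(promoterless)
        contingency, outside = de_mod.link_de_to_binding(sets, groups)
        path = os.path.join(outdir, "de_binding_contingency.tsv")
        contingency.to_csv(path, sep="\t", index=False)
        emit("de_binding_contingency", path)
        manifest["stages"]["de"] = {
            "genes_after_count_filter": len(table),
            "up": len(sets.up),
            "down": len(sets.down),
            "de_genes_outside_universe": len(outside),
        }
    else:
        manifest["stages"]["de"] = "skipped"

    if config.get("write_fragments"):
        for sid, f in frags.items():
            path = os.path.join(outdir, f"fragments_{sid}.bed")
            with open(path, "w") as fh:
                for c, s, e in zip(f.contigs, f.starts, f.ends):
                    fh.write(f"{c}\t{s}\t{e}\n")
            emit(f"fragments_{sid}", path)

    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
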