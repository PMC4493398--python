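"""End-to-end orchestration: simulate -> call peaks -> annotate -> patterns
-> integrate -> enrich, driven by a single config with a reproducibility
manifest.

Every stage can be skipped by supplying its inputs externally (real-data
mode): external gene/probe/expression tables or per-array peak BEDs drop in
at the matching stage boundary.  All thresholds (FDR 0.05, 2-of-3 replicate
consensus, 500 bp window, >=4 probes, cutoff fractions 0.90-0.15, 20
permutations, 5000 bp TSS cutoff, gene region -5000/+1500, 2-fold expression
change) surface as named config keys with those defaults.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import annotate as _annotate
from . import enrich as _enrich
from . import expression as _expression
from . import io as _io
from . import patterns as _patterns
from . import peaks as _peaks
from . import synthetic as _synthetic

log = logging.getLogger("nfkb_switchscan")

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "results/run",
    "simulate": {},
    "peak_calling": {},
    "annotation": {"tss_cutoff_bp": 5000, "region_upstream_bp": 5000,
                   "region_downstream_bp": 1500},
    "patterns": {"fdr_threshold": 0.05, "consensus_min": 2},
    "expression": {"pseudocount": 0.1, "fc_threshold": 2.0,
                   "time_map": dict(_expression.DEFAULT_TIME_MAP)},
    "enrichment": {"gmt": None, "p_cutoff": 0.05},
    "inputs": {},
}


def load_pipeline_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in raw.items():
        if key not in cfg:
            raise ValueError(f"unknown config section {key!r}")
        if isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _array_seed(base: int, rep: int, time_idx: int) -> int:
    return (int(base) * 1000 + rep * 100 + time_idx) % (2 ** 31 - 1)


def run_pipeline(config, outdir=None) -> dict:
    """Execute all stages; returns the manifest (also written to
    manifest.json in the output directory)."""
    cfg = load_pipeline_config(config)
    outdir = Path(outdir if outdir is not None else cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = {"config": cfg, "seed": seed, "version": __version__,
                "stages": {}, "outputs": {}}
    outputs: dict[str, Path] = {}

    def stage(name):
        t0 = time.perf_counter()
        log.info("stage %s started", name)
        return t0

    def done(name, t0, **info):
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}
        log.info("stage %s finished (%.2fs) %s", name,
                 time.perf_counter() - t0, info or "")

    inputs = cfg["inputs"]

    # ---- stage: simulate (or load external inputs) ------------------------
    t0 = stage("simulate")
    sim_cfg = _synthetic.SimulationConfig(**{"seed": seed, **cfg["simulate"]})
    truth = None
    if inputs.get("genes"):
        genes = _io.read_gene_table(inputs["genes"])
        arrays = {}
        for key, path in (inputs.get("arrays") or {}).items():
            rep_s, tl = key.split(":", 1)
            rep = int(rep_s)
            arrays[(rep, tl)] = _io.read_probe_array(path, rep, tl)
        expression_raw = (_io.read_expression_table(inputs["expression"])
                          if inputs.get("expression") else None)
        done("simulate", t0, mode="external", n_genes=len(genes))
    else:
        ds = _synthetic.generate_dataset(sim_cfg)
        genes, arrays, truth = ds.genes, ds.arrays, ds.truth
        expression_raw = ds.expression
        paths = _synthetic.write_dataset(ds, outdir / "synthetic")
        outputs.update({f"synthetic/{k}": Path(v) for k, v in paths.items()})
        done("simulate", t0, mode="synthetic", n_genes=len(genes),
             n_arrays=len(arrays))

    time_labels = list(sim_cfg.time_labels)

    # ---- stage: peak calling ---------------------------------------------
    t0 = stage("peak_calling")
    params = _peaks.PeakCallerParams(**{
        k: (tuple(v) if k == "cutoff_fractions" else v)
        for k, v in cfg["peak_calling"].items()})
    if inputs.get("peaks"):
        frames = []
        for key, path in inputs["peaks"].items():
            rep_s, tl = key.split(":", 1)
            df = _io.read_peaks_bed(path)
            df["replicate"] = int(rep_s)
            df["time_label"] = tl
            df["n_probes"] = pd.NA
            df["mean_log2"] = pd.NA
            frames.append(df)
        all_peaks = pd.concat(frames, ignore_index=True)
        done("peak_calling", t0, mode="external", n_peaks=len(all_peaks))
    else:
        if not arrays:
            raise RuntimeError("stage peak_calling failed: no probe arrays available")
        frames = []
        for (rep, tl), probes in sorted(arrays.items()):
            stats = _peaks.compute_array_stats(probes, params)
            called = _peaks.call_peaks(probes, stats, params)
            called = _peaks.permutation_fdr(
                probes, stats, called, params,
                seed=_array_seed(seed, rep, time_labels.index(tl)))
            frames.append(called)
        all_peaks = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=_io.PEAK_COLUMNS)
        peaks_path = outdir / "peaks.tsv"
        all_peaks.to_csv(peaks_path, sep="\t", index=False)
        outputs["peaks"] = peaks_path
        for (rep, tl) in sorted(arrays):
            sub = all_peaks[(all_peaks["replicate"] == rep)
                            & (all_peaks["time_label"] == tl)]
            bed = outdir / f"peaks_rep{rep}_{tl}.bed"
            _io.write_peaks_bed(sub, bed)
            outputs[f"peaks_rep{rep}_{tl}_bed"] = bed
        done("peak_calling", t0, n_peaks=len(all_peaks),
             n_significant=int((all_peaks["fdr"] <= params.fdr_threshold).sum()))

    # ---- stage: annotation ------------------------------------------------
    t0 = stage("annotation")
    ann_cfg = cfg["annotation"]
    annotated, unannotated = _annotate.annotate_peaks(
        all_peaks, genes, tss_cutoff_bp=ann_cfg["tss_cutoff_bp"],
        region_upstream_bp=ann_cfg["region_upstream_bp"],
        region_downstream_bp=ann_cfg["region_downstream_bp"])
    ann_path = outdir / "annotated_peaks.tsv"
    annotated.to_csv(ann_path, sep="\t", index=False)
    outputs["annotated_peaks"] = ann_path
    hist, modes = _annotate.tss_distance_profile(annotated)
    hist_path = outdir / "tss_distance_profile.tsv"
    hist.to_csv(hist_path, sep="\t", index=False)
    outputs["tss_distance_profile"] = hist_path
    done("annotation", t0, n_annotated=len(annotated),
         n_unannotated=len(unannotated), modes=modes)

    # ---- stage: patterns --------------------------------------------------
    t0 = stage("patterns")
    pat_cfg = cfg["patterns"]
    matrix = _patterns.binarize(
        annotated, genes, times=time_labels,
        replicates=sorted({r for r, _ in arrays}) if arrays else None,
        fdr_threshold=pat_cfg["fdr_threshold"],
        consensus_min=pat_cfg["consensus_min"])
    assignments, counts = _patterns.assign_patterns(matrix)
    classified = _patterns.classify_switches(assignments, n_times=len(time_labels))
    merged = assignments.merge(
        classified[["gene_id", "switch_class", "arm"]], on="gene_id", how="left")
    merged[["switch_class", "arm"]] = merged[["switch_class", "arm"]].fillna("none")
    pat_path = outdir / "gene_patterns.tsv"
    merged.to_csv(pat_path, sep="\t", index=False)
    outputs["gene_patterns"] = pat_path
    counts_path = outdir / "pattern_counts.tsv"
    counts.to_csv(counts_path, sep="\t", index=False)
    outputs["pattern_counts"] = counts_path
    done("patterns", t0, n_bound=int((assignments["pattern_code"] != 0).sum()),
         fdr_threshold=pat_cfg["fdr_threshold"],
         consensus=f"{pat_cfg['consensus_min']} of {matrix.n_replicates}")

    # ---- stage: expression integration ------------------------------------
    t0 = stage("integration")
    expr_cfg = cfg["expression"]
    joined = summary = None
    if expression_raw is not None:
        time_map = dict(expr_cfg["time_map"])
        followups = list(time_map.values())
        baseline = list(sim_cfg.expression_time_labels)[0]
        expr = _expression.compute_fold_changes(
            expression_raw, baseline_label=baseline, followup_labels=followups,
            pseudocount=expr_cfg["pseudocount"], fc_threshold=expr_cfg["fc_threshold"])
        joined, summary, report = _expression.integrate(
            assignments, genes, expr, time_map=time_map, binding_times=time_labels)
        joined_path = outdir / "binding_expression.tsv"
        joined.to_csv(joined_path, sep="\t", index=False)
        outputs["binding_expression"] = joined_path
        summary_path = outdir / "pattern_summary.tsv"
        summary.to_csv(summary_path, sep="\t", index=False)
        outputs["pattern_summary"] = summary_path
        arm_summary, contrasts = _expression.switch_expression_summary(
            joined, time_map=time_map, n_times=len(time_labels))
        arm_path = outdir / "switch_expression.tsv"
        arm_summary.to_csv(arm_path, sep="\t", index=False)
        outputs["switch_expression"] = arm_path
        contrast_path = outdir / "switch_contrasts.tsv"
        contrasts.to_csv(contrast_path, sep="\t", index=False)
        outputs["switch_contrasts"] = contrast_path
        log.info("pattern summary:\n%s", summary.to_string(index=False))
        done("integration", t0, **{k: v for k, v in report.items()})
    else:
        done("integration", t0, mode="skipped")

    # ---- stage: enrichment -------------------------------------------------
    t0 = stage("enrichment")
    enr_cfg = cfg["enrichment"]
    if enr_cfg.get("gmt"):
        collection = _enrich.read_gmt(enr_cfg["gmt"])
        universe = set(genes["gene_id"])
        per_class = {}
        source = classified if joined is None else joined.merge(
            classified[["gene_id", "switch_class", "arm"]], on="gene_id")
        for cls, sub in source.groupby("switch_class"):
            gene_list = sub[sub["de_for_pattern"]]["gene_id"] \
                if "de_for_pattern" in sub.columns and cls != "constitutive" \
                else sub["gene_id"]
            res = _enrich.hypergeom_enrich(gene_list, collection, universe,
                                           p_cutoff=enr_cfg["p_cutoff"])
            res.insert(0, "switch_class", cls)
            per_class[cls] = res
        enr = pd.concat(per_class.values(), ignore_index=True) if per_class \
            else pd.DataFrame()
        enr_path = outdir / "enrichment.tsv"
        enr.to_csv(enr_path, sep="\t", index=False)
        outputs["enrichment"] = enr_path
        done("enrichment", t0, n_classes=len(per_class))
    else:
        done("enrichment", t0, mode="skipped")

    # ---- manifest -----------------------------------------------------------
    manifest["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                           for k, p in sorted(outputs.items())}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
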