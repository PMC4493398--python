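"""Binding-to-expression integration at offset time points.

Binding at 1h is paired with expression at 4h and binding at 6h with
expression at 12h, reflecting the lag between transcription-factor binding
and measurable transcript change.  Fold change over baseline is computed on
the log2 scale with a pseudocount; a gene is differentially expressed when
its fold change is at least ``fc_threshold`` (default 2) above or below
baseline.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import match_by_refseq
from .patterns import binary_string, classify_switches

DEFAULT_TIME_MAP = {"1h": "4h", "6h": "12h"}


def validate_time_map(time_map: dict, binding_times) -> None:
    non_baseline = list(binding_times)[1:]
    if len(set(time_map.values())) != len(time_map):
        raise ValueError("time map must be injective")
    missing = [t for t in non_baseline if t not in time_map]
    if missing:
        raise ValueError(f"binding times {missing} have no mapped expression time")


def compute_fold_changes(expr: pd.DataFrame, baseline_label: str = "0h",
                         followup_labels=("4h", "12h"), pseudocount: float = 0.1,
                         fc_threshold: float = 2.0) -> pd.DataFrame:
    """Add log2fc_<t> and de_<t> columns per follow-up time.

    log2fc = log2(rpkm_t + pseudocount) - log2(rpkm_0 + pseudocount);
    DE iff |log2fc| >= log2(fc_threshold) (boundary inclusive).
    """
    base_col = f"rpkm_{baseline_label}"
    if base_col not in expr.columns:
        raise ValueError(f"missing baseline column {base_col}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = expr.copy()
    log_thr = math.log2(fc_threshold)
    base = out[base_col].to_numpy(dtype=float)
    for t in followup_labels:
        col = f"rpkm_{t}"
        if col not in out.columns:
            raise ValueError(f"missing follow-up column {col}")
        lfc = np.log2(out[col].to_numpy(dtype=float) + pseudocount) \
            - np.log2(base + pseudocount)
        out[f"log2fc_{t}"] = lfc
        out[f"de_{t}"] = np.abs(lfc) >= log_thr
    return out


def integrate(assignments: pd.DataFrame, genes: pd.DataFrame,
              expr_records: pd.DataFrame, time_map: dict = None,
              binding_times=("0h", "1h", "6h")):
    """Join pattern assignments to DE flags at the mapped follow-up times.

    A gene counts as DE for its pattern if it is DE at the expression time
    mapped from any non-baseline time at which its pattern bit is 1.
    Patterns bound only at baseline have no mapped time; they are evaluated
    at every follow-up and flagged ``baseline_only_convention``.  Genes with
    no expression match are excluded from DE counts but reported.

    Returns (joined per-gene table, 7-row pattern summary, report dict).
    The summary reproduces the bound-vs-DE layout for patterns 1-7; for the
    constitutive pattern the DE column reports all bound-and-measured genes
    (footnoted), not differentially expressed ones.
    """
    if time_map is None:
        time_map = dict(DEFAULT_TIME_MAP)
    validate_time_map(time_map, binding_times)
    missing_de = [t for t in time_map.values() if f"de_{t}" not in expr_records.columns]
    if missing_de:
        raise ValueError(
            f"expression records lack de_ columns for {missing_de}; "
            "run compute_fold_changes first")
    n_times = len(binding_times)
    full_code = 2 ** n_times - 1

    withref = assignments.merge(genes[["gene_id", "refseq_id"]], on="gene_id", how="left")
    bound = withref[withref["pattern_code"] != 0].copy()
    joined, report = match_by_refseq(bound, expr_records.drop(columns=["gene_id"],
                                                              errors="ignore"))
    report["n_bound"] = len(bound)

    followups = list(time_map.values())
    de_rows, eval_times, baseline_only = [], [], []
    for _, row in joined.iterrows():
        bits = [int(b) for b in row["binary"]]
        bound_times = [t for t, b in zip(binding_times, bits) if b]
        mapped = [time_map[t] for t in bound_times if t in time_map]
        b_only = not mapped
        if b_only:
            mapped = followups          # baseline-only pattern: check both
        de_rows.append(bool(any(row.get(f"de_{t}", False) for t in mapped)))
        eval_times.append(",".join(mapped))
        baseline_only.append(b_only)
    joined["de_for_pattern"] = de_rows
    joined["de_times_evaluated"] = eval_times
    joined["baseline_only_convention"] = baseline_only

    rows = []
    for code in range(1, full_code + 1):
        in_pat = withref["pattern_code"] == code
        matched = joined[joined["pattern_code"] == code]
        if code == full_code:
            n_de = int(len(matched))    # bound & measured, per the footnote
            foot = True
        else:
            n_de = int(matched["de_for_pattern"].sum())
            foot = False
        rows.append({
            "pattern_code": code,
            "binary": binary_string(code, n_times),
            "n_bound_genes": int(in_pat.sum()),
            "n_de_genes": n_de,
            "bound_and_measured_footnote": foot,
        })
    summary = pd.DataFrame(rows)
    return joined, summary, report


def switch_expression_summary(joined: pd.DataFrame, time_map: dict = None,
                              n_times: int = 3):
    """Per switch class / arm / follow-up time: gene count and mean +/- SD of
    log2 fold change, plus a binding-minus-unbinding contrast per class.

    Empty arms are absent from the output rather than reported as zero.
    """
    if time_map is None:
        time_map = dict(DEFAULT_TIME_MAP)
    followups = list(time_map.values())
    classified = classify_switches(joined, n_times=n_times)

    rows = []
    for (cls, arm), sub in classified.groupby(["switch_class", "arm"], sort=True):
        for t in followups:
            col = f"log2fc_{t}"
            vals = sub[col].to_numpy(dtype=float)
            rows.append({
                "switch_class": cls, "arm": arm, "expr_time": t,
                "n_genes": len(vals),
                "mean_log2fc": float(vals.mean()) if len(vals) else np.nan,
                "sd_log2fc": float(vals.std(ddof=0)) if len(vals) else np.nan,
            })
    summary = pd.DataFrame(rows, columns=["switch_class", "arm", "expr_time",
                                          "n_genes", "mean_log2fc", "sd_log2fc"])

    contrasts = []
    for cls in ("immediate", "transient", "delayed"):
        for t in followups:
            sel = summary[(summary["switch_class"] == cls) & (summary["expr_time"] == t)]
            b = sel[sel["arm"] == "binding"]["mean_log2fc"]
            u = sel[sel["arm"] == "unbinding"]["mean_log2fc"]
            if len(b) and len(u):
                contrasts.append({"switch_class": cls, "expr_time": t,
                                  "contrast": float(b.iloc[0] - u.iloc[0])})
            else:
                warnings.warn(f"switch class {cls} at {t} lacks a complete arm pair")
    return summary, pd.DataFrame(contrasts, columns=["switch_class", "expr_time", "contrast"])
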