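"""Readers and writers for probe arrays, gene annotations, peaks and expression.

Conventions
-----------
All on-disk genomic coordinates follow the native convention of each format
(1-based inclusive for probe tables and GFF3, 0-based half-open for BED).
Internally, *interval* coordinates (peak start/end, gene regions) are 0-based
half-open; probe ``position`` is kept as the 1-based central coordinate of the
probe, since probes are treated as points.  Every conversion happens exactly
once, in this module.

Tables are plain tab-separated files with a header line; the probe-signal
dialect is ``probe_id  chrom  position  log2_ratio``.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "chrom", "position", "log2_ratio"]
GENE_COLUMNS = ["gene_id", "refseq_id", "chrom", "strand", "tss", "transcript_end"]
PEAK_COLUMNS = [
    "chrom", "start", "end", "score", "n_probes", "mean_log2",
    "fdr", "replicate", "time_label",
]


class FormatError(ValueError):
    """Raised when an on-disk table violates its dialect."""


# ---------------------------------------------------------------------------
# probe arrays
# ---------------------------------------------------------------------------

def read_probe_array(path, replicate: int, time_label: str) -> pd.DataFrame:
    """Read one array's probe signals, validate, and sort by (chrom, position).

    Returns a DataFrame with PROBE_COLUMNS plus ``replicate`` and
    ``time_label``.  Duplicate (chrom, position) pairs, non-finite ratios and
    malformed rows are rejected with the offending line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    # line numbers: header is line 1, first data row line 2
    pos_numeric = pd.to_numeric(df["position"], errors="coerce")
    bad = df.index[pos_numeric.isna() | (pos_numeric < 1) | (pos_numeric % 1 != 0)]
    if len(bad):
        raise FormatError(f"{path}: malformed position at line {bad[0] + 2}")
    ratio = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = df.index[~np.isfinite(ratio)]
    if len(bad):
        raise FormatError(f"{path}: non-finite log2_ratio at line {bad[0] + 2}")
    df["position"] = pos_numeric.astype(np.int64)
    df["log2_ratio"] = ratio.astype(float)
    dup = df.duplicated(subset=["chrom", "position"])
    if dup.any():
        raise FormatError(
            f"{path}: duplicate (chrom, position) at line {df.index[dup][0] + 2}"
        )
    df["replicate"] = int(replicate)
    df["time_label"] = str(time_label)
    return df.sort_values(["chrom", "position"], kind="mergesort").reset_index(drop=True)


def write_probe_array(probes: pd.DataFrame, path) -> None:
    probes.loc[:, PROBE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "refseq_id": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise FormatError(f"{path}: invalid strand at line {df.index[bad_strand][0] + 2}")
    plus = df["strand"] == "+"
    if ((plus & (df["tss"] > df["transcript_end"]))
            | (~plus & (df["tss"] < df["transcript_end"]))).any():
        raise FormatError(f"{path}: tss/transcript_end inconsistent with strand")
    return df.reset_index(drop=True)


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes.loc[:, GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_genes_bed(genes: pd.DataFrame, path) -> None:
    """Write gene spans (TSS to transcript end) as BED6, name = gene_id."""
    start1 = np.minimum(genes["tss"], genes["transcript_end"])
    end1 = np.maximum(genes["tss"], genes["transcript_end"])
    bed = pd.DataFrame({
        "chrom": genes["chrom"],
        "start": start1 - 1,          # 1-based inclusive -> 0-based half-open
        "end": end1,
        "name": genes["gene_id"],
        "score": 0,
        "strand": genes["strand"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def gene_region(genes: pd.DataFrame, upstream_bp: int = 5000,
                downstream_bp: int = 1500) -> pd.DataFrame:
    """Strand-aware gene region: upstream_bp before the TSS to downstream_bp
    past the transcript end, as internal 0-based half-open [start, end).
    """
    plus = (genes["strand"] == "+").to_numpy()
    tss0 = genes["tss"].to_numpy() - 1
    tend0 = genes["transcript_end"].to_numpy() - 1
    start = np.where(plus, tss0 - upstream_bp, tend0 - downstream_bp)
    end = np.where(plus, tend0 + downstream_bp + 1, tss0 + upstream_bp + 1)
    out = genes[["gene_id", "chrom"]].copy()
    out["region_start"] = np.maximum(start, 0)
    out["region_end"] = end
    return out


# ---------------------------------------------------------------------------
# peaks: BED6 / GFF3
# ---------------------------------------------------------------------------

def _peak_name(i: int, row) -> str:
    fdr = row["fdr"]
    tag = "na" if (fdr is None or (isinstance(fdr, float) and math.isnan(fdr))) \
        else format(float(fdr), ".6g")
    return f"peak{i};fdr={tag}"


def write_peaks_bed(peaks: pd.DataFrame, path) -> None:
    """BED6: 0-based half-open; score column = peak score scaled to 0-1000;
    empirical FDR carried in the name field."""
    with open(path, "w") as fh:
        fh.write('track name="peaks"\n')
        for i, (_, row) in enumerate(peaks.iterrows(), start=1):
            fh.write("\t".join([
                str(row["chrom"]),
                str(int(row["start"])),
                str(int(row["end"])),
                _peak_name(i, row),
                str(int(round(float(row["score"]) * 1000))),
                ".",
            ]) + "\n")


def read_peaks_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            fdr = np.nan
            if len(f) > 3 and "fdr=" in f[3]:
                tag = f[3].split("fdr=")[1]
                fdr = np.nan if tag == "na" else float(tag)
            rows.append({
                "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                "score": int(f[4]) / 1000.0 if len(f) > 4 else np.nan,
                "fdr": fdr,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "fdr"])


def write_peaks_gff(peaks: pd.DataFrame, path) -> None:
    """GFF3: 1-based inclusive; score = raw peak score; FDR as attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (_, row) in enumerate(peaks.iterrows(), start=1):
            fdr = row.get("fdr", np.nan)
            attrs = f"ID=peak{i}"
            if fdr is not None and not (isinstance(fdr, float) and math.isnan(fdr)):
                attrs += f";fdr={float(fdr):.6g}"
            if "n_probes" in row and not pd.isna(row["n_probes"]):
                attrs += f";n_probes={int(row['n_probes'])}"
            fh.write("\t".join([
                str(row["chrom"]), "nfkb-switchscan", "binding_site",
                str(int(row["start"]) + 1),     # half-open -> 1-based inclusive
                str(int(row["end"])),
                format(float(row["score"]), ".6g"), ".", ".", attrs,
            ]) + "\n")


def read_peaks_gff(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            rows.append({
                "chrom": f[0],
                "start": int(f[3]) - 1,         # 1-based inclusive -> half-open
                "end": int(f[4]),
                "score": float(f[5]),
                "fdr": float(attrs["fdr"]) if "fdr" in attrs else np.nan,
            })
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score", "fdr"])


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression_table(path, time_labels=None) -> pd.DataFrame:
    """Read a per-gene RPKM table: gene_id, refseq_id, rpkm_<time> columns.

    Negative RPKM is an error; the expected time columns may be passed
    explicitly, otherwise every ``rpkm_*`` column is taken.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "refseq_id": str})
    for col in ("gene_id", "refseq_id"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    if time_labels is None:
        rpkm_cols = [c for c in df.columns if c.startswith("rpkm_")]
    else:
        rpkm_cols = [f"rpkm_{t}" for t in time_labels]
        missing = [c for c in rpkm_cols if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing columns {missing}")
    if not rpkm_cols:
        raise FormatError(f"{path}: no rpkm_* columns")
    for c in rpkm_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"{path}: non-numeric {c}")
        if (vals < 0).any():
            line = df.index[vals < 0][0] + 2
            raise FormatError(f"{path}: negative RPKM in {c} at line {line}")
        df[c] = vals.astype(float)
    return df.reset_index(drop=True)


def write_expression_table(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index=False)


def match_by_refseq(left: pd.DataFrame, right: pd.DataFrame,
                    how: str = "inner") -> tuple[pd.DataFrame, dict]:
    """Join two tables on refseq_id, reporting how many rows failed to match.

    Duplicate RefSeq ids on either side collapse to the first occurrence with
    a warning (deterministic first-match).
    """
    report = {}
    l, r = left, right
    for name, df in (("left", l), ("right", r)):
        ndup = int(df["refseq_id"].duplicated().sum())
        if ndup:
            warnings.warn(f"{ndup} duplicate refseq_id on {name} side; keeping first")
        report[f"n_duplicate_{name}"] = ndup
    l = l.drop_duplicates(subset="refseq_id", keep="first")
    r = r.drop_duplicates(subset="refseq_id", keep="first")
    merged = l.merge(r, on="refseq_id", how=how, suffixes=("", "_expr"))
    report["n_left"] = len(l)
    report["n_right"] = len(r)
    report["n_matched"] = int(l["refseq_id"].isin(r["refseq_id"]).sum())
    report["n_unmatched_left"] = report["n_left"] - report["n_matched"]
    return merged, report


# ---------------------------------------------------------------------------
# generic BED intervals (accessibility tracks etc.)
# ---------------------------------------------------------------------------

def read_bed_intervals(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            rows.append({"chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                         "name": f[3] if len(f) > 3 else "."})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
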