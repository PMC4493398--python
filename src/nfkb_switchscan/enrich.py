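"""Gene-set over-representation analysis (hypergeometric tail + BH).

A plain exact hypergeometric upper tail with Benjamini-Hochberg correction
over the tested sets.  This deliberately differs from DAVID-style functional
annotation clustering (modified Fisher / EASE score, term clustering): it is
a transparent, reproducible stand-in that answers the same question — which
named gene sets are over-represented in a query list relative to a
background universe.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

RESULT_COLUMNS = ["set_name", "k", "K", "n", "N", "p_value", "q_value", "significant"]


def read_gmt(path) -> dict[str, set]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            if fields[0] in sets:
                raise ValueError(f"duplicate gene set name {fields[0]!r}")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(collection: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in collection.items():
            fh.write("\t".join([name, description] + sorted(members)) + "\n")


def hypergeom_enrich(query, collection: dict, universe, p_cutoff: float = 0.05) -> pd.DataFrame:
    """Exact upper-tail over-representation P(X >= k) per gene set.

    query genes outside the universe are dropped with a warning; gene-set
    members outside the universe are ignored.  Results are BH-corrected and
    sorted by p-value.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("background universe is empty")
    query = set(query)
    outside = query - universe
    if outside:
        warnings.warn(f"{len(outside)} query genes outside the universe dropped")
        query &= universe
    N, n = len(universe), len(query)

    rows = []
    for name, members in collection.items():
        members = set(members) & universe
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))   # P(X >= k)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    res = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-2])
    if len(res):
        res["q_value"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res["significant"] = res["p_value"] <= p_cutoff
        res = res.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        res["q_value"] = []
        res["significant"] = []
    return res
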