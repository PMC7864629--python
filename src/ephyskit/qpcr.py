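"""Relative gene expression from qPCR Ct tables.

Quantification follows the comparative-Ct scheme with two housekeeping
genes: technical replicates are averaged on the Ct scale, the mean of the
two housekeeping-gene Cts is subtracted from each target gene's Ct
(dCt), relative expression is 2**(-dCt), and values are optionally
rescaled to a designated reference sample so the reference reads 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["delta_ct", "normalize_to_reference"]

DEFAULT_HOUSEKEEPING = ("GPI", "GAPDH")


def _validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def delta_ct(table: pd.DataFrame,
             housekeeping=DEFAULT_HOUSEKEEPING) -> pd.DataFrame:
    """dCt and relative expression per (sample, gene).

    Technical replicates are averaged on the Ct scale first.  For each
    sample, dCt(gene) = mean Ct(gene) - mean over the housekeeping genes of
    their mean Cts, and rel_expr = 2**(-dCt).  Housekeeping genes missing
    for a sample raise, naming the sample.
    """
    table = _validate_ct_table(table)
    housekeeping = list(housekeeping)
    mean_ct = (table.groupby(["sample_id", "gene"], sort=False)["ct"]
               .mean().reset_index())
    rows = []
    for sample, sub in mean_ct.groupby("sample_id", sort=False):
        hk = sub[sub["gene"].isin(housekeeping)]
        if set(hk["gene"]) != set(housekeeping):
            absent = sorted(set(housekeeping) - set(hk["gene"]))
            raise ValueError(
                f"sample {sample!r} lacks housekeeping gene(s) {absent}")
        hk_ref = hk["ct"].mean()  # mean of the per-gene mean Cts
        targets = sub[~sub["gene"].isin(housekeeping)]
        for _, r in targets.iterrows():
            dct = r["ct"] - hk_ref
            rows.append([sample, r["gene"], dct, 2.0 ** (-dct)])
    return pd.DataFrame(rows,
                        columns=["sample_id", "gene", "delta_ct", "rel_expr"])


def normalize_to_reference(expr: pd.DataFrame,
                           reference_sample: str) -> pd.DataFrame:
    """Scale rel_expr gene-wise to a reference sample (reference reads 1.0).

    Adds a ``rel_to_reference`` column; genes for which the reference sample
    is absent or has zero expression raise.
    """
    out = expr.copy()
    ref = expr[expr["sample_id"] == reference_sample]
    if ref.empty:
        raise ValueError(f"reference sample {reference_sample!r} not found")
    ref_map = dict(zip(ref["gene"], ref["rel_expr"]))
    vals = []
    for _, r in out.iterrows():
        if r["gene"] not in ref_map:
            raise ValueError(
                f"gene {r['gene']!r} missing for reference sample")
        denom = ref_map[r["gene"]]
        if denom == 0 or not np.isfinite(denom):
            raise ValueError(
                f"reference expression for {r['gene']!r} is zero")
        vals.append(r["rel_expr"] / denom)
    out["rel_to_reference"] = vals
    return out
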