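"""Synthetic qPCR Ct tables with known fold changes."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["simulate_qpcr"]


def simulate_qpcr(n_samples: int,
                  genes,
                  true_log2_fold_changes,
                  housekeeping_genes=("GPI", "GAPDH"),
                  ct_noise_sd: float = 0.2,
                  baseline_target_ct: float = 25.0,
                  housekeeping_ct: float = 20.0,
                  n_replicates: int = 2,
                  condition_labels=("control", "treated"),
                  seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate a long-format Ct table for two conditions.

    Each condition has ``n_samples`` biological samples; every assay is run
    in ``n_replicates`` technical replicates (duplicates by default).
    Housekeeping Cts are drawn around ``housekeeping_ct``; target Cts are
    ``baseline_target_ct`` in the first condition and shifted by
    ``-log2_fold_change`` in the second (one extra cycle of threshold per
    halving of template).  Gaussian noise of ``ct_noise_sd`` cycles is added
    per replicate.

    Returns a DataFrame with columns sample_id, condition, gene, replicate,
    ct.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    genes = list(genes)
    fc = dict(zip(genes, np.asarray(true_log2_fold_changes, dtype=float)))
    if len(fc) != len(genes):
        raise ValueError("one log2 fold change per gene required")
    rows = []
    for ci, cond in enumerate(condition_labels):
        for s in range(n_samples):
            sid = f"{cond}_{s + 1}"
            # sample-level pipetting offset shifts all assays together
            sample_offset = rng.normal(0.0, ct_noise_sd / 2) \
                if ct_noise_sd > 0 else 0.0
            for gene in list(housekeeping_genes) + genes:
                if gene in fc:
                    base = baseline_target_ct
                    if ci == 1:
                        base = base - fc[gene]
                else:
                    base = housekeeping_ct
                for rep in range(1, n_replicates + 1):
                    noise = rng.normal(0.0, ct_noise_sd) \
                        if ct_noise_sd > 0 else 0.0
                    rows.append([sid, cond, gene, rep,
                                 base + sample_offset + noise])
    return pd.DataFrame(
        rows, columns=["sample_id", "condition", "gene", "replicate", "ct"])
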