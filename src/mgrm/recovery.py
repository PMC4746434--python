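"""Replication-level parameter-recovery indices.

For each replication the estimated item bank is compared with the
generating bank by parameter class: one class per discrimination dimension
(``a_1 .. a_H``, each over the L/H items loading that dimension) and one
per boundary position (``b_1 .. b_K``, each over all L items).  Per class
the indices are

    bias = mean(estimate - true)
    RMSE = sqrt(mean((estimate - true)^2))
    r    = Pearson correlation(true, estimate)

Discrimination classes deliberately exclude the structural zeros: those
are fixed, not estimated, and including them would mechanically shrink
bias/RMSE and inflate correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import CalibrationResult
from .model import ItemBank

__all__ = [
    "compute_bias",
    "compute_rmse",
    "compute_correlation",
    "indices_for_replication",
]


def _check_pair(true_values, estimates) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if t.size < 2:
        raise ValueError("need at least 2 values per class")
    return t, e


def compute_bias(true_values, estimates) -> float:
    """Mean signed deviation of estimates from truth."""
    t, e = _check_pair(true_values, estimates)
    return float(np.mean(e - t))


def compute_rmse(true_values, estimates) -> float:
    """Root mean squared deviation of estimates from truth."""
    t, e = _check_pair(true_values, estimates)
    return float(np.sqrt(np.mean((e - t) ** 2)))


def compute_correlation(true_values, estimates) -> float:
    """Pearson correlation between truth and estimates.

    Returns NaN (reported as missing) when either vector has zero
    variance, where the correlation is undefined.
    """
    t, e = _check_pair(true_values, estimates)
    if np.std(t) == 0 or np.std(e) == 0:
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])


def indices_for_replication(
    true_bank: ItemBank, result: CalibrationResult
) -> pd.DataFrame:
    """All three indices for every parameter class of one replication.

    Banks are aligned by item_id; the result's failed flag is copied onto
    every row.  Returns a long-format frame with columns
    ``class, bias, rmse, correlation, failed``.
    """
    est_bank = result.bank_hat
    true_by_id = {it.item_id: it for it in true_bank.items}
    est_by_id = {it.item_id: it for it in est_bank.items}
    if set(true_by_id) != set(est_by_id):
        raise ValueError("item_id sets of true and estimated banks differ")
    for iid, it in true_by_id.items():
        if est_by_id[iid].loading_dim != it.loading_dim:
            raise ValueError(f"item {iid}: loading dimension mismatch")
    H, K = true_bank.H, true_bank.K
    ids = sorted(true_by_id)
    rows = []
    for h in range(1, H + 1):
        sel = [iid for iid in ids if true_by_id[iid].loading_dim == h]
        t = [true_by_id[iid].a_loading for iid in sel]
        e = [est_by_id[iid].a_loading for iid in sel]
        rows.append(
            {
                "class": f"a_{h}",
                "bias": compute_bias(t, e),
                "rmse": compute_rmse(t, e),
                "correlation": compute_correlation(t, e),
            }
        )
    for k in range(1, K + 1):
        t = [true_by_id[iid].b[k - 1] for iid in ids]
        e = [est_by_id[iid].b[k - 1] for iid in ids]
        rows.append(
            {
                "class": f"b_{k}",
                "bias": compute_bias(t, e),
                "rmse": compute_rmse(t, e),
                "correlation": compute_correlation(t, e),
            }
        )
    df = pd.DataFrame(rows)
    df["failed"] = bool(result.failed)
    return df
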