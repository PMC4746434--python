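"""Readers and writers for the package's plain-text interchange formats.

* Item bank: CSV with columns ``item_id, loading_dim, a1..aH, b1..bK`` plus
  a JSON sidecar (same path with ``.json`` suffix) carrying H, K, D.  The
  pair round-trips bit-exactly (full float precision).
* Responses: CSV, one row per respondent, header ``item_1..item_L``,
  0-based integer categories.
* Structure: JSON ``{"H":, "K":, "D":, "items": [{"item_id":, "loading_dim":}]}``.
* Estimates: item bank schema plus ``se_a, se_b1..se_bK`` columns.
* Fit: JSON with the log-likelihood trace, cycles, convergence and the
  estimated latent correlations.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibrate import BankStructure, CalibrationConfig, CalibrationResult
from .model import ItemBank, ItemParameters

__all__ = [
    "write_item_bank",
    "read_item_bank",
    "write_responses",
    "read_responses",
    "write_thetas",
    "write_structure",
    "read_structure",
    "write_estimates",
    "write_fit",
    "load_calibration_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_item_bank(bank: ItemBank, path) -> None:
    path = Path(path)
    H, K = bank.H, bank.K
    cols = {"item_id": [it.item_id for it in bank.items],
            "loading_dim": [it.loading_dim for it in bank.items]}
    A, B = bank.a_matrix(), bank.b_matrix()
    for h in range(H):
        cols[f"a{h + 1}"] = A[:, h]
    for k in range(K):
        cols[f"b{k + 1}"] = B[:, k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    _sidecar(path).write_text(
        json.dumps({"H": H, "K": K, "D": bank.D}, indent=1) + "\n"
    )


def read_item_bank(path) -> ItemBank:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    H, K, D = int(meta["H"]), int(meta["K"]), float(meta["D"])
    df = pd.read_csv(path, float_precision="round_trip")
    items = []
    for _, row in df.iterrows():
        a = np.array([row[f"a{h + 1}"] for h in range(H)])
        b = np.array([row[f"b{k + 1}"] for k in range(K)])
        items.append(
            ItemParameters(
                item_id=int(row["item_id"]),
                loading_dim=int(row["loading_dim"]),
                a=a,
                b=b,
                D=D,
            )
        )
    return ItemBank(items=tuple(items))


def write_responses(X: np.ndarray, path) -> None:
    X = np.asarray(X)
    cols = [f"item_{j + 1}" for j in range(X.shape[1])]
    pd.DataFrame(X, columns=cols).to_csv(path, index=False)


def read_responses(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=np.int64)


def write_thetas(thetas: np.ndarray, path) -> None:
    thetas = np.asarray(thetas)
    cols = [f"theta_{h + 1}" for h in range(thetas.shape[1])]
    pd.DataFrame(thetas, columns=cols).to_csv(path, index=False, float_format="%.17g")


def write_structure(structure: BankStructure, path) -> None:
    payload = {
        "H": structure.H,
        "K": structure.K,
        "D": structure.D,
        "items": [
            {"item_id": int(i), "loading_dim": int(d)}
            for i, d in zip(structure.item_ids, structure.loading_dims)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_structure(path) -> BankStructure:
    meta = json.loads(Path(path).read_text())
    return BankStructure(
        H=int(meta["H"]),
        K=int(meta["K"]),
        D=float(meta.get("D", 1.0)),
        item_ids=tuple(int(it["item_id"]) for it in meta["items"]),
        loading_dims=tuple(int(it["loading_dim"]) for it in meta["items"]),
    )


def write_estimates(result: CalibrationResult, path) -> None:
    """Estimated bank in the item-bank schema plus standard-error columns."""
    path = Path(path)
    bank = result.bank_hat
    write_item_bank(bank, path)
    df = pd.read_csv(path)
    K = bank.K
    if result.se is not None:
        df["se_a"] = result.se[:, 0]
        for k in range(K):
            df[f"se_b{k + 1}"] = result.se[:, k + 1]
    df.to_csv(path, index=False, float_format="%.17g")


def write_fit(result: CalibrationResult, path) -> None:
    payload = {
        "loglik_trace": [float(v) for v in result.loglik_trace],
        "n_cycles": int(result.n_cycles),
        "converged": bool(result.converged),
        "failed": bool(result.failed),
        "failure_reason": result.failure_reason,
        "corr_hat": result.corr_hat.matrix.tolist(),
        "notes": list(result.notes),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_calibration_config(path) -> CalibrationConfig:
    """Calibration settings from a YAML/JSON mapping; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {
        "nodes_per_dim",
        "quad_range",
        "max_cycles",
        "param_tol",
        "se_threshold",
        "estimate_corr",
        "compute_se",
        "start_a",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown calibration config keys: {sorted(unknown)}")
    if "quad_range" in raw:
        raw["quad_range"] = tuple(float(v) for v in raw["quad_range"])
    return CalibrationConfig(**raw)
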