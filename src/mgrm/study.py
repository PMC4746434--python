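"""Factorial simulation study: orchestration, ANOVA effect sizes, summaries.

The full design crosses test length L in {30, 90, 240}, sample size N in
{500, 1000, 1500, 2000} and latent correlation r in {0.2, 0.5, 0.7}, each
cell replicated 30 times with a fresh item bank and fresh simulees per
replication.  Replication-level recovery indices are summarized by a
three-way fixed-effects ANOVA whose effect sizes are

    eta^2 = SS_effect / SS_total

with SS_total the sum of all model sums of squares including the
residual, so the eta^2 values (residual included) sum to one by
construction even on unbalanced designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .calibrate import CalibrationConfig, calibrate
from .recovery import indices_for_replication
from .synthetic import (
    ConfigError,
    GenerationConfig,
    generate_responses,
    replication_rng,
    sample_item_bank,
    sample_thetas,
)

__all__ = [
    "DesignGrid",
    "StudyConfig",
    "run_replication",
    "run_condition",
    "run_design",
    "anova_eta_squared",
    "running_means",
    "marginal_summary",
]

INDEX_COLUMNS = [
    "L",
    "N",
    "r",
    "rep",
    "class",
    "bias",
    "rmse",
    "correlation",
    "failed",
]


@dataclass(frozen=True)
class DesignGrid:
    """Factor levels and replication count of the crossed design."""

    levels_L: tuple[int, ...] = (30, 90, 240)
    levels_N: tuple[int, ...] = (500, 1000, 1500, 2000)
    levels_r: tuple[float, ...] = (0.2, 0.5, 0.7)
    reps: int = 30
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.levels_L and self.levels_N and self.levels_r):
            raise ConfigError("all factor level lists must be non-empty")
        if self.reps < 1:
            raise ConfigError("reps must be >= 1")

    def cells(self) -> list[tuple[int, int, float]]:
        return [
            (L, N, r)
            for L in self.levels_L
            for N in self.levels_N
            for r in self.levels_r
        ]


@dataclass(frozen=True)
class StudyConfig:
    """Generation and calibration settings shared by every cell.

    ``exclude_cells`` lists (L, N) pairs whose replications are marked as
    excluded from downstream aggregation, mirroring the removal of the
    240-item / 500-examinee cells; ``auto_exclude`` additionally excludes
    any cell whose calibration failure rate exceeds
    ``auto_exclude_threshold``.
    """

    H: int = 3
    K: int = 3
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    exclude_cells: tuple[tuple[int, int], ...] = ((240, 500),)
    auto_exclude: bool = False
    auto_exclude_threshold: float = 0.5
    n_jobs: int = 1


def _condition_key(L: int, N: int, r: float) -> tuple[int, int, int]:
    return (int(L), int(N), int(round(float(r) * 1000)))


def run_replication(
    L: int,
    N: int,
    r: float,
    rep: int,
    master_seed: int,
    config: StudyConfig,
) -> pd.DataFrame:
    """One replication: fresh bank, fresh simulees, calibration, indices."""
    gen = GenerationConfig(
        L=L, H=config.H, K=config.K, N=N, r=r,
        D=1.0, master_seed=master_seed,
    )
    rng = replication_rng(master_seed, _condition_key(L, N, r), rep)
    bank = sample_item_bank(gen, rng)
    thetas = sample_thetas(N, gen.corr, rng)
    X = generate_responses(thetas, bank, rng)
    try:
        result = calibrate(X, bank, config.calibration)
        df = indices_for_replication(bank, result)
    except Exception as exc:  # calibration failures never abort a condition
        classes = [f"a_{h}" for h in range(1, config.H + 1)] + [
            f"b_{k}" for k in range(1, config.K + 1)
        ]
        df = pd.DataFrame(
            {
                "class": classes,
                "bias": np.nan,
                "rmse": np.nan,
                "correlation": np.nan,
                "failed": True,
            }
        )
        warnings.warn(f"replication (L={L}, N={N}, r={r}, rep={rep}) failed: {exc}")
    df.insert(0, "L", L)
    df.insert(1, "N", N)
    df.insert(2, "r", r)
    df.insert(3, "rep", rep)
    return df[INDEX_COLUMNS]


def run_condition(
    L: int,
    N: int,
    r: float,
    reps: int,
    master_seed: int,
    config: StudyConfig = StudyConfig(),
) -> pd.DataFrame:
    """All replications of one design cell (reps x (H + K) index rows)."""
    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        frames = Parallel(n_jobs=config.n_jobs)(
            delayed(run_replication)(L, N, r, rep, master_seed, config)
            for rep in range(reps)
        )
    else:
        frames = [
            run_replication(L, N, r, rep, master_seed, config)
            for rep in range(reps)
        ]
    return pd.concat(frames, ignore_index=True)


def run_design(
    grid: DesignGrid, config: StudyConfig = StudyConfig()
) -> pd.DataFrame:
    """Iterate every cell of the design and mark excluded cells.

    Adds an ``excluded`` column: True for rows of cells named in
    ``config.exclude_cells`` (and, with ``auto_exclude``, cells whose
    failure rate exceeds the threshold).  Excluded and failed rows are
    retained in the table and skipped by the aggregation functions.
    """
    frames = []
    for L, N, r in grid.cells():
        cell = run_condition(L, N, r, grid.reps, grid.master_seed, config)
        excluded = (int(L), int(N)) in {
            (int(a), int(b)) for a, b in config.exclude_cells
        }
        if config.auto_exclude and not excluded:
            rate = cell.groupby("rep")["failed"].any().mean()
            excluded = rate > config.auto_exclude_threshold
        cell["excluded"] = excluded
        frames.append(cell)
    return pd.concat(frames, ignore_index=True)


def _analysis_rows(indices: pd.DataFrame) -> pd.DataFrame:
    """Rows entering aggregation: not failed, not excluded."""
    out = indices[~indices["failed"].astype(bool)]
    if "excluded" in out.columns:
        out = out[~out["excluded"].astype(bool)]
    return out


def anova_eta_squared(
    indices: pd.DataFrame, dv: str, klass: str
) -> pd.DataFrame:
    """Three-way fixed-effects ANOVA effect sizes for one dv and class.

    Fits an effects-coded (sum-to-zero) full factorial linear model on the
    replication-level values with Type-II sums of squares and returns a
    table with columns ``source, ss, df, eta_squared``; eta^2 of every
    effect plus the residual sums to one.  Factors left with a single
    level after exclusions are dropped with a warning.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if dv not in {"bias", "rmse", "correlation"}:
        raise ValueError(f"unknown dependent variable {dv!r}")
    data = _analysis_rows(indices)
    data = data[data["class"] == klass].dropna(subset=[dv]).copy()
    if data.empty:
        raise ValueError(f"no usable rows for class {klass!r}")
    factors = []
    for f in ["L", "N", "r"]:
        if data[f].nunique() >= 2:
            factors.append(f)
        else:
            warnings.warn(f"factor {f!r} has a single level and was dropped")
    if not factors:
        raise ValueError("no factor has two or more levels")
    terms = " * ".join(f"C({f}, Sum)" for f in factors)
    model = smf.ols(f"{dv} ~ {terms}", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels F-test NaN chatter
        table = sm.stats.anova_lm(model, typ=2)
    pretty = {f"C({f}, Sum)": f for f in factors}

    def _name(source: str) -> str:
        if source == "Residual":
            return "Residual"
        parts = [pretty.get(p, p) for p in source.split(":")]
        return " x ".join(parts)

    out = pd.DataFrame(
        {
            "source": [_name(s) for s in table.index],
            "ss": table["sum_sq"].to_numpy(),
            "df": table["df"].to_numpy(),
        }
    )
    out["eta_squared"] = out["ss"] / out["ss"].sum()
    return out.reset_index(drop=True)


def running_means(
    indices: pd.DataFrame,
    condition: tuple[int, int, float] | None = None,
) -> pd.DataFrame:
    """Cumulative means of each index versus replication count, per class.

    Used as the pilot diagnostic for choosing the number of replications:
    trajectories that flatten indicate enough replications.
    """
    df = indices
    if condition is not None:
        L, N, r = condition
        df = df[(df["L"] == L) & (df["N"] == N) & (np.isclose(df["r"], r))]
    df = _analysis_rows(df).sort_values("rep")
    empty = pd.DataFrame(
        columns=["class", "rep", "n_reps", "bias", "rmse", "correlation"]
    )
    if df.empty:
        return empty
    frames = []
    for klass, sub in df.groupby("class", sort=True):
        sub = sub.sort_values("rep")
        cum = sub[["bias", "rmse", "correlation"]].expanding().mean()
        cum.insert(0, "class", klass)
        cum.insert(1, "rep", sub["rep"].to_numpy())
        cum.insert(2, "n_reps", np.arange(1, len(sub) + 1))
        frames.append(cum)
    return pd.concat(frames, ignore_index=True)


def marginal_summary(indices: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Marginal means of each index by level of one factor.

    Replication values are first averaged within each design cell; the
    summary then reports, per factor level, class and index, the mean and
    the standard deviation of those cell means (SD is missing when a
    level spans a single cell).
    """
    if factor not in {"L", "N", "r"}:
        raise ValueError(f"unknown factor {factor!r}")
    df = _analysis_rows(indices)
    cell_means = (
        df.groupby(["L", "N", "r", "class"], as_index=False)[
            ["bias", "rmse", "correlation"]
        ].mean()
    )
    long = cell_means.melt(
        id_vars=["L", "N", "r", "class"],
        value_vars=["bias", "rmse", "correlation"],
        var_name="index",
        value_name="value",
    )
    out = (
        long.groupby([factor, "class", "index"], as_index=False)["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
             n_cells="count")
        .rename(columns={factor: "level"})
    )
    out.insert(0, "factor", factor)
    return out
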