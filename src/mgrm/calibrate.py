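"""Marginal maximum likelihood (MML-EM) calibration of the MGRM.

Latent traits are integrated out over a fixed rectangular tensor grid on a
bounded range (default 21 points per dimension on [-3.5, 3.5]) with prior
mass proportional to the multivariate normal density at each node.  The EM
cycle alternates

* an E-step computing each respondent's posterior distribution over grid
  nodes and accumulating expected respondent mass ``n_bar`` and expected
  category counts ``r_bar``,
* per-item M-steps maximizing the expected complete-data log likelihood by
  Newton iterations on a smooth reparameterization (first boundary free,
  positive gaps on the log scale), and
* an exact M-step for the latent correlation matrix on the discretized
  prior, warm-started at the rescaled posterior second moments.

Under simple structure the respondent likelihood factorizes across
dimensions, so per-respondent node posteriors are assembled from per-
dimension tables; the full tensor grid only enters through the prior
weights and the correlation update.  All heavy paths are vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import multivariate_normal

from .model import (
    PROB_FLOOR,
    ItemBank,
    ItemParameters,
    LatentCorrelation,
)

__all__ = [
    "QuadratureGrid",
    "build_quadrature",
    "CalibrationConfig",
    "BankStructure",
    "ExpectedCounts",
    "CalibrationResult",
    "e_step",
    "m_step_item",
    "update_latent_correlation",
    "calibrate",
    "compute_standard_errors",
    "flag_failed_calibration",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# quadrature


@dataclass(frozen=True)
class QuadratureGrid:
    """Tensor-product rectangular quadrature over a bounded latent range.

    ``nodes`` is the Q x H tensor grid (Q = nodes_per_dim**H) of equally
    spaced univariate nodes; ``weights`` carries the normalized prior mass
    at each node under the correlation the grid was built with.
    ``weights_for`` recomputes the mass for any other correlation on the
    same geometry.
    """

    nodes_per_dim: int
    range: tuple[float, float]
    H: int
    univariate: np.ndarray  # (m,)
    nodes: np.ndarray  # (Q, H)
    dim_idx: np.ndarray  # (Q, H) int index into `univariate` per dimension
    weights: np.ndarray  # (Q,) normalized prior mass

    @property
    def Q(self) -> int:
        return self.nodes.shape[0]

    def weights_for(self, corr: LatentCorrelation) -> np.ndarray:
        """Normalized MVN(0, corr) prior mass at the grid nodes."""
        dens = multivariate_normal(mean=np.zeros(self.H), cov=corr.matrix).pdf(
            self.nodes
        )
        dens = np.atleast_1d(dens)
        return dens / dens.sum()


def build_quadrature(
    nodes_per_dim: int, range_: tuple[float, float], corr: LatentCorrelation
) -> QuadratureGrid:
    """Equally spaced univariate nodes tensored over H dimensions."""
    if nodes_per_dim < 3:
        raise ConfigError("nodes_per_dim must be >= 3")
    lo, hi = range_
    if not lo < hi:
        raise ConfigError("quadrature range must satisfy lo < hi")
    H = corr.H
    if nodes_per_dim**H > 10_000_000:
        raise ConfigError(
            f"grid of {nodes_per_dim}^{H} nodes exceeds the 1e7 node guard"
        )
    t = np.linspace(lo, hi, nodes_per_dim)
    idx = np.indices((nodes_per_dim,) * H).reshape(H, -1).T  # (Q, H)
    nodes = t[idx]
    grid = QuadratureGrid(
        nodes_per_dim=nodes_per_dim,
        range=(lo, hi),
        H=H,
        univariate=t,
        nodes=nodes,
        dim_idx=idx,
        weights=np.empty(0),
    )
    object.__setattr__(grid, "weights", grid.weights_for(corr))
    return grid


# ---------------------------------------------------------------------------
# configuration and result containers


@dataclass(frozen=True)
class CalibrationConfig:
    """Estimation settings.

    nodes_per_dim / quad_range follow the study's quadrature (21 points on
    [-3.5, 3.5]); param_tol is the maximum absolute per-cycle parameter
    change at which EM stops; se_threshold operationalizes "unusually
    large" standard errors for the failure flag.
    """

    nodes_per_dim: int = 21
    quad_range: tuple[float, float] = (-3.5, 3.5)
    max_cycles: int = 500
    param_tol: float = 1e-4
    se_threshold: float = 1.0
    estimate_corr: bool = True
    fixed_corr: np.ndarray | None = None
    compute_se: bool = True
    prob_floor: float = PROB_FLOOR
    start_a: float = 1.5
    newton_max_iter: int = 20


@dataclass(frozen=True)
class BankStructure:
    """Confirmatory zero pattern: which dimension each item loads."""

    H: int
    K: int
    item_ids: tuple[int, ...]
    loading_dims: tuple[int, ...]
    D: float = 1.0

    def __post_init__(self) -> None:
        if len(self.item_ids) != len(self.loading_dims):
            raise ConfigError("item_ids and loading_dims must align")
        if not all(1 <= d <= self.H for d in self.loading_dims):
            raise ConfigError("loading_dims must lie in [1, H]")

    @property
    def L(self) -> int:
        return len(self.item_ids)

    @classmethod
    def from_bank(cls, bank: ItemBank) -> "BankStructure":
        return cls(
            H=bank.H,
            K=bank.K,
            item_ids=tuple(it.item_id for it in bank.items),
            loading_dims=tuple(it.loading_dim for it in bank.items),
            D=bank.D,
        )


@dataclass
class ExpectedCounts:
    """EM sufficient statistics over the full tensor grid.

    ``n_bar[q]`` is the expected respondent mass at node q (sums to N);
    ``r_bar[j, k, q]`` the expected count of category-k responses to item j
    at node q (sums over k to ``n_bar`` for every item).
    """

    n_bar: np.ndarray  # (Q,)
    r_bar: np.ndarray  # (L, K+1, Q)
    loglik: float


@dataclass
class CalibrationResult:
    bank_hat: ItemBank
    corr_hat: LatentCorrelation
    loglik_trace: np.ndarray
    n_cycles: int
    converged: bool
    se: np.ndarray | None = None  # (L, 1+K): columns a, b_1..b_K
    failed: bool = False
    failure_reason: str = ""
    notes: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# internal vectorized E-step machinery


def _dim_item_groups(
    loading_dims: np.ndarray, H: int, item_ids: np.ndarray | None = None
) -> list[np.ndarray]:
    """Item positions grouped by loading dimension.

    When ``item_ids`` is given, positions within a group are ordered by
    item id, which makes every accumulation order canonical: permuting the
    items of a bank then permutes all estimates bit-exactly.
    """
    groups = []
    for h in range(H):
        idx = np.flatnonzero(loading_dims == h + 1)
        if item_ids is not None:
            idx = idx[np.argsort(np.asarray(item_ids)[idx], kind="stable")]
        groups.append(idx)
    return groups


def _dim_log_prob_tables(
    a_load: np.ndarray,
    B: np.ndarray,
    D: float,
    t: np.ndarray,
    groups: list[np.ndarray],
    floor: float,
) -> list[np.ndarray]:
    """Per-dimension (L_h, K+1, m) log category probabilities at the
    univariate nodes.  Valid under simple structure only."""
    K = B.shape[1]
    tables = []
    for idx in groups:
        if idx.size == 0:
            tables.append(np.zeros((0, K + 1, t.size)))
            continue
        z = D * a_load[idx, None, None] * (t[None, None, :] - B[idx, :, None])
        star = np.empty((idx.size, K + 2, t.size))
        star[:, 0] = 1.0
        star[:, -1] = 0.0
        star[:, 1:-1] = expit(z)
        probs = star[:, :-1] - star[:, 1:]
        tables.append(np.log(np.maximum(probs, floor)))
    return tables


def _posterior_quantities(
    X: np.ndarray,
    a_load: np.ndarray,
    B: np.ndarray,
    D: float,
    groups: list[np.ndarray],
    grid: QuadratureGrid,
    weights: np.ndarray,
    floor: float,
    want_full_posterior: bool = False,
):
    """One E-pass: marginal posteriors per dimension, node masses, loglik.

    Returns a dict with keys ``loglik``, ``n_bar`` (Q,), ``post_dim``
    (list of N x m marginal posteriors per dimension), ``log_tables``
    (per-dimension log category probability tables) and optionally
    ``posterior`` (N x Q).
    """
    N = X.shape[0]
    H = grid.H
    m = grid.nodes_per_dim
    log_tables = _dim_log_prob_tables(a_load, B, D, grid.univariate, groups, floor)
    A = []
    shifts = np.zeros(N)
    for h in range(H):
        logA = np.zeros((N, m))
        tab = log_tables[h]
        for jj, j in enumerate(groups[h]):
            logA += tab[jj, X[:, j], :]
        s = logA.max(axis=1)
        shifts += s
        A.append(np.exp(logA - s[:, None]))
    G = A[0][:, grid.dim_idx[:, 0]]
    for h in range(1, H):
        G *= A[h][:, grid.dim_idx[:, h]]
    G *= weights[None, :]
    Z = G.sum(axis=1)
    loglik = float((np.log(Z) + shifts).sum())
    G /= Z[:, None]  # now the posterior
    n_bar = G.sum(axis=0)
    shape = (N,) + (m,) * H
    G_nd = G.reshape(shape)
    post_dim = []
    for h in range(H):
        axes = tuple(ax for ax in range(1, H + 1) if ax != h + 1)
        post_dim.append(G_nd.sum(axis=axes) if axes else G_nd.reshape(N, m))
    out = {
        "loglik": loglik,
        "n_bar": n_bar,
        "post_dim": post_dim,
        "log_tables": log_tables,
    }
    if want_full_posterior:
        out["posterior"] = G
    return out


def _collapsed_counts(
    X: np.ndarray, post_dim: list[np.ndarray], groups: list[np.ndarray], K: int
) -> list[np.ndarray]:
    """Expected category counts per item over that item's own dimension's
    univariate nodes: list (per dim) of (L_h, K+1, m) arrays."""
    out = []
    cats = np.arange(K + 1)
    for h, idx in enumerate(groups):
        ph = post_dim[h]
        r = np.empty((idx.size, K + 1, ph.shape[1]))
        for jj, j in enumerate(idx):
            onehot = (X[:, j][:, None] == cats).astype(float)  # (N, K+1)
            r[jj] = onehot.T @ ph
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# public E-step


def _validate_responses(X: np.ndarray, L: int, K: int) -> np.ndarray:
    X = np.asarray(X)
    if X.ndim != 2 or X.shape[1] != L:
        raise ValueError(f"response matrix must be N x {L}, got {X.shape}")
    if not np.issubdtype(X.dtype, np.integer):
        Xi = X.astype(np.int64)
        if not np.array_equal(Xi, X):
            raise ValueError("responses must be integer categories")
        X = Xi
    if X.min() < 0 or X.max() > K:
        raise ValueError(f"response categories must lie in [0, {K}]")
    return X


def e_step(
    responses: np.ndarray,
    bank: ItemBank,
    corr: LatentCorrelation,
    grid: QuadratureGrid,
    floor: float = PROB_FLOOR,
) -> ExpectedCounts:
    """Expected node masses and per-item category counts at the current
    parameters, over the full tensor grid."""
    X = _validate_responses(responses, bank.L, bank.K)
    a_load = np.array([it.a_loading for it in bank.items])
    B = bank.b_matrix()
    groups = _dim_item_groups(
        bank.loading_dims(), bank.H, np.array([it.item_id for it in bank.items])
    )
    weights = grid.weights_for(corr)
    q = _posterior_quantities(
        X, a_load, B, bank.D, groups, grid, weights, floor, want_full_posterior=True
    )
    P = q["posterior"]  # (N, Q)
    K = bank.K
    cats = np.arange(K + 1)
    r_bar = np.empty((bank.L, K + 1, grid.Q))
    for j in range(bank.L):
        onehot = (X[:, j][:, None] == cats).astype(float)
        r_bar[j] = onehot.T @ P
    return ExpectedCounts(n_bar=q["n_bar"], r_bar=r_bar, loglik=q["loglik"])


# ---------------------------------------------------------------------------
# M-step for one item


def _eta_to_ab(eta: np.ndarray) -> tuple[float, np.ndarray]:
    """(a, b1, log-gaps) -> (a, increasing b)."""
    a = eta[0]
    b = eta[1] + np.concatenate(([0.0], np.cumsum(np.exp(eta[2:]))))
    return a, b


def _ab_to_eta(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate(([a, b[0]], np.log(np.maximum(gaps, 1e-8))))


def _item_neg_ll_grad(
    eta: np.ndarray, r: np.ndarray, t: np.ndarray, D: float, floor: float
):
    """Negative expected complete-data log likelihood of one item and its
    analytic gradient in the (a, b1, log-gap) parameterization.

    ``r`` is the (K+1, m) expected count table over the item's loading
    dimension's univariate nodes ``t``.
    """
    K = r.shape[0] - 1
    a, b = _eta_to_ab(eta)
    z = D * a * (t[None, :] - b[:, None])  # (K, m)
    S = expit(z)
    star = np.vstack([np.ones_like(t), S, np.zeros_like(t)])  # (K+2, m)
    P = star[:-1] - star[1:]  # (K+1, m)
    Pf = np.maximum(P, floor)
    f = -(r * np.log(Pf)).sum()
    W = r / Pf  # (K+1, m)
    Sp = S * (1.0 - S)  # (K, m) logistic density factor
    dstar_da = D * (t[None, :] - b[:, None]) * Sp  # (K, m)
    dstar_db = -D * a * Sp  # (K, m)
    pad = np.zeros((1, t.size))
    dP_da = np.vstack([pad, dstar_da]) - np.vstack([dstar_da, pad])  # (K+1, m)
    g_a = -(W * dP_da).sum()
    # df/db_k = -sum_q (W[k] - W[k-1]) * dstar_db[k], categories 0-based
    g_b = -((W[1:] - W[:-1]) * dstar_db).sum(axis=1)  # (K,)
    grad = np.empty_like(eta)
    grad[0] = g_a
    grad[1] = g_b.sum()
    # d b_k / d g_l = exp(g_l) for k >= l (gaps enter all later boundaries)
    for l in range(2, K + 1):
        grad[l] = np.exp(eta[l]) * g_b[l - 1 :].sum()
    return f, grad


def _newton_maximize_item(
    eta0: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    D: float,
    floor: float,
    max_iter: int = 20,
) -> tuple[np.ndarray, bool]:
    """Newton with step halving on the smooth item objective.

    The Hessian is taken by central finite differences of the analytic
    gradient.  Falls back to a bounded derivative-free (Powell) search when
    steps go non-finite.  Returns (eta, ok).
    """
    eta = eta0.copy()
    f, g = _item_neg_ll_grad(eta, r, t, D, floor)
    n = eta.size
    for _ in range(max_iter):
        if np.max(np.abs(g)) < 1e-9:
            return eta, True
        Hss = np.empty((n, n))
        h = 1e-5 * np.maximum(1.0, np.abs(eta))
        finite = True
        for p in range(n):
            ep = np.zeros(n)
            ep[p] = h[p]
            _, gp = _item_neg_ll_grad(eta + ep, r, t, D, floor)
            _, gm = _item_neg_ll_grad(eta - ep, r, t, D, floor)
            Hss[:, p] = (gp - gm) / (2 * h[p])
            if not np.all(np.isfinite(Hss[:, p])):
                finite = False
                break
        if finite:
            Hss = 0.5 * (Hss + Hss.T)
            try:
                step = np.linalg.solve(Hss, -g)
            except np.linalg.LinAlgError:
                step = -g
            if not np.all(np.isfinite(step)) or g @ step > 0:
                step = -g
        else:
            step = -g
        if not np.all(np.isfinite(step)):
            break  # to fallback
        lam, accepted = 1.0, False
        for _ in range(30):
            eta_new = eta + lam * step
            if eta_new[0] > 1e-3:
                f_new, g_new = _item_neg_ll_grad(eta_new, r, t, D, floor)
                if np.isfinite(f_new) and f_new <= f + 1e-12:
                    accepted = True
                    break
            lam *= 0.5
        if not accepted:
            return eta, True  # at (numerical) optimum already
        moved = np.max(np.abs(eta_new - eta))
        eta, f, g = eta_new, f_new, g_new
        if moved < 1e-10:
            return eta, True
    if np.max(np.abs(g)) < 1e-6:
        return eta, True
    # bounded derivative-free fallback
    K = r.shape[0] - 1
    bounds = [(1e-3, 60.0), (-10.0, 10.0)] + [(-10.0, 4.0)] * (K - 1)
    eta = np.clip(eta, [b[0] for b in bounds], [b[1] for b in bounds])
    res = optimize.minimize(
        lambda e: _item_neg_ll_grad(e, r, t, D, floor)[0],
        eta,
        method="Powell",
        bounds=bounds,
        options={"xtol": 1e-8, "ftol": 1e-10, "maxiter": 2000},
    )
    if np.isfinite(res.fun) and res.fun <= f + 1e-9:
        return res.x, True
    return eta0, False


def _batched_neg_ll_grad(
    eta: np.ndarray, r: np.ndarray, t: np.ndarray, D: float, floor: float
):
    """Vectorized item objective/gradient over a batch of items sharing
    the same univariate nodes.  ``eta`` is (n, 1+K) in the (a, b1,
    log-gap) parameterization, ``r`` is (n, K+1, m).  Same mathematics as
    :func:`_item_neg_ll_grad`, evaluated for all items at once."""
    n, K1, m = r.shape
    K = K1 - 1
    a = eta[:, 0]
    b = eta[:, 1][:, None] + np.concatenate(
        [np.zeros((n, 1)), np.cumsum(np.exp(eta[:, 2:]), axis=1)], axis=1
    )  # (n, K)
    z = D * a[:, None, None] * (t[None, None, :] - b[:, :, None])  # (n, K, m)
    S = expit(z)
    star = np.empty((n, K + 2, m))
    star[:, 0] = 1.0
    star[:, -1] = 0.0
    star[:, 1:-1] = S
    P = star[:, :-1] - star[:, 1:]  # (n, K+1, m)
    Pf = np.maximum(P, floor)
    f = -(r * np.log(Pf)).sum(axis=(1, 2))
    W = r / Pf
    Sp = S * (1.0 - S)
    dstar_da = D * (t[None, None, :] - b[:, :, None]) * Sp
    dstar_db = -D * a[:, None, None] * Sp
    pad = np.zeros((n, 1, m))
    dP_da = np.concatenate([pad, dstar_da], axis=1) - np.concatenate(
        [dstar_da, pad], axis=1
    )
    g_a = -(W * dP_da).sum(axis=(1, 2))
    g_b = -((W[:, 1:] - W[:, :-1]) * dstar_db).sum(axis=2)  # (n, K)
    grad = np.empty_like(eta)
    grad[:, 0] = g_a
    grad[:, 1] = g_b.sum(axis=1)
    for l in range(2, K + 1):
        grad[:, l] = np.exp(eta[:, l]) * g_b[:, l - 1 :].sum(axis=1)
    return f, grad


def _newton_maximize_items_batched(
    eta0: np.ndarray,
    r: np.ndarray,
    t: np.ndarray,
    D: float,
    floor: float,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched Newton-with-step-halving across items of one dimension.

    Identical per-item mathematics to :func:`_newton_maximize_item`
    (finite-difference Hessian of the analytic gradient, gradient-descent
    fallback direction, positivity guard on the discrimination), with the
    loop carried jointly over items via an active mask.  Returns
    ``(eta, ok)`` where ``ok`` marks items that finished cleanly; the rest
    fall back to the scalar path.
    """
    eta = eta0.copy()
    n, P = eta.shape
    f, g = _batched_neg_ll_grad(eta, r, t, D, floor)
    ok = np.zeros(n, dtype=bool)
    active = np.ones(n, dtype=bool)
    for _ in range(max_iter):
        done = np.abs(g).max(axis=1) < 1e-9
        ok |= active & done
        active &= ~done
        if not active.any():
            break
        idx = np.flatnonzero(active)
        ea, ra = eta[idx], r[idx]
        fa, ga = f[idx], g[idx]
        # FD Hessian of the analytic gradient, batched over items
        h = 1e-5 * np.maximum(1.0, np.abs(ea))
        Hss = np.empty((idx.size, P, P))
        for p in range(P):
            ep = np.zeros_like(ea)
            ep[:, p] = h[:, p]
            _, gp = _batched_neg_ll_grad(ea + ep, ra, t, D, floor)
            _, gm = _batched_neg_ll_grad(ea - ep, ra, t, D, floor)
            Hss[:, :, p] = (gp - gm) / (2 * h[:, p][:, None])
        Hss = 0.5 * (Hss + np.swapaxes(Hss, 1, 2))
        bad = ~np.isfinite(Hss).all(axis=(1, 2))
        Hss[bad] = np.eye(P)
        try:
            step = np.linalg.solve(Hss, -ga[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = -ga.copy()
        else:
            fallback = (
                bad
                | ~np.isfinite(step).all(axis=1)
                | ((ga * step).sum(axis=1) > 0)
            )
            step[fallback] = -ga[fallback]
        lam = np.ones(idx.size)
        pending = np.ones(idx.size, dtype=bool)
        eta_new, f_new, g_new = ea.copy(), fa.copy(), ga.copy()
        for _ in range(30):
            trial = ea + lam[:, None] * step
            ft, gt = _batched_neg_ll_grad(trial, ra, t, D, floor)
            good = (
                pending
                & (trial[:, 0] > 1e-3)
                & np.isfinite(ft)
                & (ft <= fa + 1e-12)
            )
            eta_new[good] = trial[good]
            f_new[good] = ft[good]
            g_new[good] = gt[good]
            pending &= ~good
            if not pending.any():
                break
            lam[pending] *= 0.5
        # items with no acceptable step are at a numerical optimum
        stuck = pending
        moved = np.abs(eta_new - ea).max(axis=1)
        finished = stuck | (moved < 1e-10)
        eta[idx] = eta_new
        f[idx] = f_new
        g[idx] = g_new
        ok[idx[finished]] = True
        active[idx[finished]] = False
        if not active.any():
            break
    # anything still active converged loosely or needs the scalar fallback
    if active.any():
        ok |= active & (np.abs(g).max(axis=1) < 1e-6)
    return eta, ok


def _collapse_full_r(r_bar_j: np.ndarray, grid: QuadratureGrid, dim: int) -> np.ndarray:
    """Collapse a full-grid (K+1, Q) count table onto one dimension's
    univariate nodes."""
    K1 = r_bar_j.shape[0]
    m, H = grid.nodes_per_dim, grid.H
    shape = (K1,) + (m,) * H
    axes = tuple(ax for ax in range(1, H + 1) if ax != dim)
    return r_bar_j.reshape(shape).sum(axis=axes)


def m_step_item(
    counts: ExpectedCounts,
    item: ItemParameters,
    grid: QuadratureGrid,
    item_index: int | None = None,
    floor: float = PROB_FLOOR,
    max_iter: int = 20,
) -> ItemParameters:
    """Maximize the expected complete-data log likelihood for one item.

    ``item_index`` is the item's row in ``counts.r_bar``; defaults to
    ``item.item_id - 1``.
    """
    j = item.item_id - 1 if item_index is None else item_index
    r = _collapse_full_r(counts.r_bar[j], grid, item.loading_dim)
    eta0 = _ab_to_eta(item.a_loading, item.b)
    eta, ok = _newton_maximize_item(
        eta0, r, grid.univariate, item.D, floor, max_iter=max_iter
    )
    if not ok:
        return item
    a_new, b_new = _eta_to_ab(eta)
    a_vec = np.zeros(item.H)
    a_vec[item.loading_dim - 1] = a_new
    return ItemParameters(
        item_id=item.item_id, loading_dim=item.loading_dim, a=a_vec, b=b_new, D=item.D
    )


# ---------------------------------------------------------------------------
# latent correlation update


def _moment_corr(n_bar: np.ndarray, grid: QuadratureGrid, N: float) -> np.ndarray:
    """Posterior second-moment matrix rescaled to unit diagonal (used as
    the warm start of the exact correlation M-step)."""
    M = (n_bar @ (grid.nodes[:, :, None] * grid.nodes[:, None, :]).reshape(grid.Q, -1))
    M = M.reshape(grid.H, grid.H) / N
    d = np.sqrt(np.diag(M))
    C = M / np.outer(d, d)
    w, V = np.linalg.eigh(0.5 * (C + C.T))
    if w.min() < 1e-6:
        C = (V * np.maximum(w, 1e-6)) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def _corr_from_n_bar(
    n_bar: np.ndarray, grid: QuadratureGrid, N: float,
    corr_start: LatentCorrelation | None = None,
) -> LatentCorrelation:
    """Exact correlation M-step on the discretized prior.

    Maximizes ``sum_q n_bar_q log w_q(C)`` over unit-diagonal positive
    definite C, where ``w_q(C)`` are the normalized node masses of the
    MVN(0, C) density on the (bounded, discretized) grid.  The rescaled
    posterior second moment is only the maximizer of the untruncated
    continuous problem; on the bounded grid it is biased toward zero, so
    it serves as the warm start of a short quasi-Newton search instead.
    """
    H = grid.H
    if H == 1:
        return LatentCorrelation(matrix=np.eye(1))
    iu = np.triu_indices(H, 1)
    nodes = grid.nodes
    N_tot = float(n_bar.sum())

    def make_C(v: np.ndarray) -> np.ndarray:
        rho = np.tanh(v)
        C = np.eye(H)
        C[iu] = rho
        C[(iu[1], iu[0])] = rho
        return C

    def neg_and_grad(v: np.ndarray):
        C = make_C(v)
        try:
            chol = np.linalg.cholesky(C)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros_like(v)
        sol = np.linalg.solve(chol, nodes.T)
        logpdf = -0.5 * (sol**2).sum(axis=0) - np.log(np.diag(chol)).sum()
        shift = logpdf.max()
        ew = np.exp(logpdf - shift)
        Z = ew.sum()
        logZ = shift + np.log(Z)
        f = -float(n_bar @ (logpdf - logZ))
        # d logpdf_q / d rho_ij = (S x_q x_q^T S - S)_ij with S = C^{-1};
        # the -S terms cancel between the data and normalization parts.
        S = np.linalg.inv(C)
        Y = nodes @ S  # (Q, H)
        A_n = (Y * n_bar[:, None]).T @ Y
        A_w = (Y * (ew / Z)[:, None]).T @ Y
        dg_drho = -(A_n - N_tot * A_w)[iu]
        grad = dg_drho * (1.0 - np.tanh(v) ** 2)
        return f, grad

    warm = _moment_corr(n_bar, grid, N)
    starts = [np.arctanh(np.clip(warm[iu], -0.999, 0.999))]
    if corr_start is not None:
        starts.insert(
            0, np.arctanh(np.clip(corr_start.matrix[iu], -0.999, 0.999))
        )
    best = None
    for v0 in starts:
        res = optimize.minimize(
            neg_and_grad, v0, jac=True, method="L-BFGS-B",
            options={"maxiter": 60, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break
    C = make_C(best.x)
    np.fill_diagonal(C, 1.0)
    return LatentCorrelation(matrix=C)


def update_latent_correlation(
    responses: np.ndarray,
    bank: ItemBank,
    corr: LatentCorrelation,
    grid: QuadratureGrid,
    floor: float = PROB_FLOOR,
) -> LatentCorrelation:
    """One EM update of the latent correlation matrix.

    Runs an E-pass at the current parameters and maximizes the expected
    complete-data log prior over unit-diagonal correlation matrices (warm
    started at the rescaled posterior second moment).  Always returns a
    symmetric positive definite matrix with an exactly unit diagonal; the
    1x1 case returns the identity.
    """
    if bank.H == 1:
        return LatentCorrelation(matrix=np.eye(1))
    X = _validate_responses(responses, bank.L, bank.K)
    a_load = np.array([it.a_loading for it in bank.items])
    B = bank.b_matrix()
    groups = _dim_item_groups(
        bank.loading_dims(), bank.H, np.array([it.item_id for it in bank.items])
    )
    q = _posterior_quantities(
        X, a_load, B, bank.D, groups, grid, grid.weights_for(corr), floor
    )
    return _corr_from_n_bar(q["n_bar"], grid, X.shape[0], corr_start=corr)


# ---------------------------------------------------------------------------
# start values


def _start_bank(
    X: np.ndarray, structure: BankStructure, start_a: float
) -> ItemBank:
    """Deterministic start values: a = start_a on the loading dimension,
    b_k at the logit of the observed proportion below category k, clipped
    to [-3, 3] and nudged apart where ties occur."""
    items = []
    K = structure.K
    for j in range(structure.L):
        x = X[:, j]
        b = np.empty(K)
        for k in range(1, K + 1):
            p_ge = np.mean(x >= k)
            p_ge = min(max(p_ge, 1e-3), 1 - 1e-3)
            b[k - 1] = np.log((1 - p_ge) / p_ge)
        b = np.clip(b, -3.0, 3.0)
        for k in range(1, K):
            b[k] = max(b[k], b[k - 1] + 0.05)
        a_vec = np.zeros(structure.H)
        a_vec[structure.loading_dims[j] - 1] = start_a
        items.append(
            ItemParameters(
                item_id=structure.item_ids[j],
                loading_dim=structure.loading_dims[j],
                a=a_vec,
                b=b,
                D=structure.D,
            )
        )
    return ItemBank(items=tuple(items))


# ---------------------------------------------------------------------------
# full EM calibration


def calibrate(
    responses: np.ndarray,
    structure: BankStructure | ItemBank,
    config: CalibrationConfig = CalibrationConfig(),
) -> CalibrationResult:
    """Confirmatory MML-EM estimation of item parameters and latent
    correlations.

    ``structure`` supplies only the zero pattern (H, K, D and each item's
    loading dimension); when an :class:`ItemBank` is given its parameter
    values are ignored.  EM stops when the maximum absolute parameter
    change falls below ``config.param_tol`` or after ``config.max_cycles``
    cycles.
    """
    if isinstance(structure, ItemBank):
        structure = BankStructure.from_bank(structure)
    X = _validate_responses(responses, structure.L, structure.K)
    N = X.shape[0]
    notes: list[str] = []
    for j in range(structure.L):
        observed = np.unique(X[:, j])
        if observed.size < 2:
            notes.append(f"item {structure.item_ids[j]}: single observed category")
        elif observed.size < structure.K + 1:
            notes.append(f"item {structure.item_ids[j]}: empty observed category")

    bank = _start_bank(X, structure, config.start_a)
    if config.fixed_corr is not None:
        corr = LatentCorrelation(matrix=np.asarray(config.fixed_corr, dtype=float))
        estimate_corr = False
    else:
        corr = LatentCorrelation(matrix=np.eye(structure.H))
        estimate_corr = config.estimate_corr and structure.H > 1
    grid = build_quadrature(config.nodes_per_dim, config.quad_range, corr)

    loading_dims = np.array(structure.loading_dims)
    groups = _dim_item_groups(loading_dims, structure.H, np.array(structure.item_ids))
    floor = config.prob_floor

    trace: list[float] = []
    converged = False
    n_cycles = 0
    items = list(bank.items)
    for _ in range(config.max_cycles):
        n_cycles += 1
        a_load = np.array([it.a_loading for it in items])
        B = np.stack([it.b for it in items])
        q = _posterior_quantities(
            X, a_load, B, structure.D, groups, grid, grid.weights_for(corr), floor
        )
        trace.append(q["loglik"])
        r_by_dim = _collapsed_counts(X, q["post_dim"], groups, structure.K)
        max_change = 0.0
        new_items = list(items)
        for h, idx in enumerate(groups):
            if idx.size == 0:
                continue
            eta0 = np.stack(
                [_ab_to_eta(items[j].a_loading, items[j].b) for j in idx]
            )
            eta_batch, ok_batch = _newton_maximize_items_batched(
                eta0,
                r_by_dim[h],
                grid.univariate,
                structure.D,
                floor,
                max_iter=config.newton_max_iter,
            )
            for jj, j in enumerate(idx):
                it = items[j]
                if ok_batch[jj]:
                    eta = eta_batch[jj]
                else:
                    eta, ok = _newton_maximize_item(
                        eta0[jj],
                        r_by_dim[h][jj],
                        grid.univariate,
                        structure.D,
                        floor,
                        max_iter=config.newton_max_iter,
                    )
                    if not ok:
                        notes.append(
                            f"item {it.item_id}: M-step not converged in cycle "
                            f"{n_cycles}; previous values retained"
                        )
                        continue
                a_new, b_new = _eta_to_ab(eta)
                a_vec = np.zeros(structure.H)
                a_vec[it.loading_dim - 1] = a_new
                new_items[j] = ItemParameters(
                    item_id=it.item_id,
                    loading_dim=it.loading_dim,
                    a=a_vec,
                    b=b_new,
                    D=structure.D,
                )
                max_change = max(
                    max_change,
                    abs(a_new - it.a_loading),
                    float(np.max(np.abs(b_new - it.b))),
                )
        items = new_items
        if estimate_corr:
            corr_new = _corr_from_n_bar(q["n_bar"], grid, N, corr_start=corr)
            max_change = max(
                max_change, float(np.max(np.abs(corr_new.matrix - corr.matrix)))
            )
            corr = corr_new
        if max_change < config.param_tol:
            converged = True
            break

    bank_hat = ItemBank(items=tuple(items))
    # final log likelihood at the accepted parameters
    a_load = np.array([it.a_loading for it in items])
    B = np.stack([it.b for it in items])
    q_final = _posterior_quantities(
        X, a_load, B, structure.D, groups, grid, grid.weights_for(corr), floor
    )
    trace.append(q_final["loglik"])

    result = CalibrationResult(
        bank_hat=bank_hat,
        corr_hat=corr,
        loglik_trace=np.asarray(trace),
        n_cycles=n_cycles,
        converged=converged,
        notes=tuple(notes),
    )
    if config.compute_se and config.max_cycles > 0:
        result.se = compute_standard_errors(
            result, X, grid, floor=floor, _post_dim=q_final["post_dim"]
        )
    flag_failed_calibration(result, config.se_threshold)
    return result


# ---------------------------------------------------------------------------
# standard errors (outer product of gradients)


def compute_standard_errors(
    result: CalibrationResult,
    responses: np.ndarray,
    grid: QuadratureGrid,
    floor: float = PROB_FLOOR,
    _post_dim: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Per-parameter standard errors from the cross-product (outer product
    of gradients) approximation to the marginal-likelihood information.

    By Fisher's identity the score of respondent i with respect to item
    j's parameters is the posterior expectation of the complete-data
    score, which under simple structure involves only the posterior over
    the item's loading dimension.  Returns an (L, 1+K) array with columns
    (a, b_1..b_K); a singular information matrix yields +inf entries.
    """
    bank = result.bank_hat
    X = _validate_responses(responses, bank.L, bank.K)
    N = X.shape[0]
    K = bank.K
    groups = _dim_item_groups(
        bank.loading_dims(), bank.H, np.array([it.item_id for it in bank.items])
    )
    if _post_dim is None:
        a_load = np.array([it.a_loading for it in bank.items])
        B = bank.b_matrix()
        q = _posterior_quantities(
            X,
            a_load,
            B,
            bank.D,
            groups,
            grid,
            grid.weights_for(result.corr_hat),
            floor,
        )
        _post_dim = q["post_dim"]
    t = grid.univariate
    P_params = 1 + K
    S = np.empty((N, bank.L * P_params))
    for h, idx in enumerate(groups):
        ph = _post_dim[h]  # (N, m)
        for j in idx:
            it = bank.items[j]
            a, b, D = it.a_loading, it.b, it.D
            z = D * a * (t[None, :] - b[:, None])
            Sig = expit(z)
            star = np.vstack([np.ones_like(t), Sig, np.zeros_like(t)])
            P = star[:-1] - star[1:]
            Pf = np.maximum(P, floor)
            Sp = Sig * (1.0 - Sig)
            dstar_da = D * (t[None, :] - b[:, None]) * Sp
            dstar_db = -D * a * Sp
            pad = np.zeros((1, t.size))
            dP_da = np.vstack([pad, dstar_da]) - np.vstack([dstar_da, pad])
            # dlogP[k, q, p]: derivative of log P_k at node q wrt param p
            dlogP = np.zeros((K + 1, t.size, P_params))
            dlogP[:, :, 0] = dP_da / Pf
            for mth in range(1, K + 1):
                dlogP[mth, :, mth] += dstar_db[mth - 1] / Pf[mth]
                dlogP[mth - 1, :, mth] -= dstar_db[mth - 1] / Pf[mth - 1]
            picked = dlogP[X[:, j]]  # (N, m, P_params)
            S[:, j * P_params : (j + 1) * P_params] = np.einsum(
                "nmp,nm->np", picked, ph
            )
    info = S.T @ S
    se = np.full((bank.L, P_params), np.inf)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.all(np.isfinite(diag)) and np.all(diag > 0):
            se = np.sqrt(diag).reshape(bank.L, P_params)
    except np.linalg.LinAlgError:
        pass
    return se


def flag_failed_calibration(
    result: CalibrationResult, se_threshold: float = 1.0
) -> bool:
    """Mark a fit failed when it did not converge or any item-parameter
    standard error is unusually large (or the information was singular)."""
    reasons = []
    if not result.converged:
        reasons.append("EM did not converge")
    if result.se is not None:
        if not np.all(np.isfinite(result.se)):
            reasons.append("information matrix singular")
        elif float(np.max(result.se)) > se_threshold:
            reasons.append(
                f"max item-parameter SE {float(np.max(result.se)):.3f} "
                f"> {se_threshold}"
            )
    result.failed = bool(reasons)
    result.failure_reason = "; ".join(reasons)
    return result.failed
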