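"""Core probability mathematics of the multidimensional graded response model.

The multidimensional graded response model (MGRM) describes ordered
categorical item responses (e.g. Likert ratings) driven by a vector of
latent traits theta.  For item ``j`` with discriminations ``a_jh`` and
strictly increasing boundary parameters ``b_j1 < ... < b_jK``, the boundary
(cumulative) probability of responding in category ``k`` or above is the
multivariate two-parameter logistic

    P*_jk(theta) = 1 / (1 + exp(-D * sum_h a_jh * (theta_h - b_jk)))

with the conventions ``P*_j0 = 1`` and ``P*_j(K+1) = 0``.  Category
probabilities are differences of adjacent boundaries,
``P_jk = P*_jk - P*_j(k+1)``.  Under simple structure (each item loads a
single dimension) each item reduces to a unidimensional graded response
model in its loading trait.

This module is pure computation: no sampling, no estimation.  It is shared
by the synthetic generator and the MML-EM calibrator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ItemParameters",
    "ItemBank",
    "LatentCorrelation",
    "boundary_probability",
    "category_probabilities",
    "bank_log_category_probabilities",
    "marginal_log_likelihood",
    "PROB_FLOOR",
]

#: Floor applied to category probabilities before logs; prevents -inf under
#: extreme parameter values with negligible bias at realistic ranges.
PROB_FLOOR = 1e-10


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of a single simple-structure MGRM item.

    Parameters
    ----------
    item_id
        Integer identifier, unique within a bank.
    loading_dim
        1-based index of the single dimension the item loads.
    a
        Length-H discrimination vector; exactly one nonzero entry, at
        ``loading_dim - 1``, and all entries nonnegative.
    b
        Length-K strictly increasing boundary parameters, on the trait scale.
    D
        Logistic scaling constant; 1.0 gives the logistic metric, 1.7
        approximates the normal ogive.
    """

    item_id: int
    loading_dim: int
    a: np.ndarray
    b: np.ndarray
    D: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        object.__setattr__(self, "b", np.asarray(self.b, dtype=float))
        H = self.a.shape[0]
        if not 1 <= self.loading_dim <= H:
            raise ValueError(f"loading_dim {self.loading_dim} outside [1, {H}]")
        if np.any(self.a < 0):
            raise ValueError("discriminations must be nonnegative")
        nonzero = np.flatnonzero(self.a)
        if nonzero.size != 1 or nonzero[0] != self.loading_dim - 1:
            raise ValueError(
                "simple structure requires exactly one nonzero discrimination, "
                "on the loading dimension"
            )
        if self.b.ndim != 1 or self.b.size < 1:
            raise ValueError("b must be a vector with K >= 1 boundaries")
        if np.any(np.diff(self.b) <= 0):
            raise ValueError("boundary parameters must be strictly increasing")

    @property
    def H(self) -> int:
        return self.a.shape[0]

    @property
    def K(self) -> int:
        return self.b.shape[0]

    @property
    def a_loading(self) -> float:
        """The single nonzero discrimination."""
        return float(self.a[self.loading_dim - 1])


@dataclass(frozen=True)
class ItemBank:
    """An ordered collection of items sharing H dimensions and K boundaries."""

    items: tuple[ItemParameters, ...]

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise ValueError("item bank must contain at least one item")
        H, K = items[0].H, items[0].K
        for it in items:
            if it.H != H or it.K != K:
                raise ValueError("all items must share the same H and K")
        if len({it.item_id for it in items}) != len(items):
            raise ValueError("item_id values must be unique")

    @property
    def L(self) -> int:
        return len(self.items)

    @property
    def H(self) -> int:
        return self.items[0].H

    @property
    def K(self) -> int:
        return self.items[0].K

    @property
    def D(self) -> float:
        return self.items[0].D

    def a_matrix(self) -> np.ndarray:
        """L x H matrix of discriminations (structural zeros included)."""
        return np.stack([it.a for it in self.items])

    def b_matrix(self) -> np.ndarray:
        """L x K matrix of boundary parameters."""
        return np.stack([it.b for it in self.items])

    def loading_dims(self) -> np.ndarray:
        """Length-L vector of 1-based loading dimensions."""
        return np.array([it.loading_dim for it in self.items], dtype=int)

    def with_items(self, items) -> "ItemBank":
        return ItemBank(items=tuple(items))


@dataclass(frozen=True)
class LatentCorrelation:
    """H x H latent-trait correlation matrix: unit diagonal, symmetric, PD."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(np.diag(m), 1.0, atol=1e-12):
            raise ValueError("correlation matrix must have unit diagonal")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        # Cholesky doubles as the positive-definiteness check.
        try:
            np.linalg.cholesky(m)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix must be positive definite") from exc

    @property
    def H(self) -> int:
        return self.matrix.shape[0]

    @classmethod
    def exchangeable(cls, H: int, r: float) -> "LatentCorrelation":
        """Common off-diagonal correlation r, unit diagonal."""
        m = np.full((H, H), float(r))
        np.fill_diagonal(m, 1.0)
        return cls(matrix=m)


def boundary_probability(theta: np.ndarray, item: ItemParameters, k: int) -> float:
    """Boundary (cumulative) probability P*_jk(theta) of category >= k.

    ``k = 0`` returns exactly 1 and ``k = K + 1`` exactly 0, matching the
    model's boundary conventions.
    """
    if not 0 <= k <= item.K + 1:
        raise IndexError(f"boundary index {k} outside [0, {item.K + 1}]")
    if k == 0:
        return 1.0
    if k == item.K + 1:
        return 0.0
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (item.H,):
        raise ValueError(f"theta must have shape ({item.H},)")
    if not np.all(np.isfinite(theta)):
        raise ValueError("theta must be finite")
    z = item.D * float(item.a @ (theta - item.b[k - 1]))
    # expit via exp of the negated argument; stable for both signs
    if z >= 0:
        return 1.0 / (1.0 + np.exp(-z))
    ez = np.exp(z)
    return float(ez / (1.0 + ez))


def category_probabilities(theta: np.ndarray, item: ItemParameters) -> np.ndarray:
    """Vector of the K+1 category probabilities at theta (sums to 1)."""
    star = np.array(
        [boundary_probability(theta, item, k) for k in range(item.K + 2)]
    )
    return star[:-1] - star[1:]


def bank_log_category_probabilities(
    bank: ItemBank, points: np.ndarray, floor: float = PROB_FLOOR
) -> np.ndarray:
    """Log category probabilities for every item at a set of latent points.

    Parameters
    ----------
    bank
        Item bank (L items, K+1 categories each).
    points
        Q x H array of latent-trait points.
    floor
        Probability floor applied before taking logs.

    Returns
    -------
    ndarray of shape (L, K+1, Q).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[1] != bank.H:
        raise ValueError(
            f"points have {points.shape[1]} columns, bank has H={bank.H}"
        )
    A = bank.a_matrix()  # (L, H)
    B = bank.b_matrix()  # (L, K)
    D = bank.D
    # z[j, k, q] = D * sum_h a[j,h] * (theta[q,h] - b[j,k])
    proj = points @ A.T  # (Q, L): sum_h a_jh theta_qh
    asum = A.sum(axis=1)  # (L,): sum_h a_jh (single nonzero under simple structure)
    z = D * (proj.T[:, None, :] - (B * asum[:, None])[:, :, None])  # (L, K, Q)
    star = np.empty((bank.L, bank.K + 2, points.shape[0]))
    star[:, 0, :] = 1.0
    star[:, -1, :] = 0.0
    with np.errstate(over="ignore"):
        star[:, 1:-1, :] = 1.0 / (1.0 + np.exp(-z))
    probs = star[:, :-1, :] - star[:, 1:, :]
    return np.log(np.maximum(probs, floor))


def marginal_log_likelihood(
    responses: np.ndarray,
    bank: ItemBank,
    corr: LatentCorrelation,
    grid,
) -> float:
    """Quadrature-approximated marginal log likelihood of a response matrix.

    Latent traits are integrated out over the grid's nodes using its
    normalized prior weights:

        sum_i log sum_q w_q prod_j P_{j, x_ij}(theta_q)

    The grid's weights are recomputed for ``corr`` so the prior always
    matches the supplied latent correlation.
    """
    X = np.asarray(responses)
    if X.ndim != 2 or X.shape[1] != bank.L:
        raise ValueError(
            f"response matrix must be N x {bank.L}, got {X.shape}"
        )
    if X.min() < 0 or X.max() > bank.K:
        raise ValueError(f"response categories must lie in [0, {bank.K}]")
    if corr.H != bank.H:
        raise ValueError("correlation dimension does not match bank")
    logw = np.log(grid.weights_for(corr))  # (Q,)
    logp = bank_log_category_probabilities(bank, grid.nodes)  # (L, K+1, Q)
    N = X.shape[0]
    ll_iq = np.zeros((N, logw.shape[0]))
    for j in range(bank.L):
        ll_iq += logp[j, X[:, j], :]
    ll_iq += logw[None, :]
    shift = ll_iq.max(axis=1)
    total = shift + np.log(np.exp(ll_iq - shift[:, None]).sum(axis=1))
    return float(total.sum())
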