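"""Synthetic item banks, latent traits, and graded responses.

Generation follows the study conditions throughout: a three-dimensional
simple-structure graded response model with four response categories,
discriminations drawn from U[1.1, 2.8], and the three boundary parameters
drawn from the contiguous intervals U[-2, -0.67], U[-0.67, 0.67] and
U[0.67, 2] with adjacent boundaries kept at least 0.5 apart by rejection
sampling.  Latent traits are multivariate normal with zero means, unit
variances and a common off-diagonal correlation; responses are single
categorical draws from the model's category probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ItemBank, ItemParameters, LatentCorrelation, category_probabilities

__all__ = [
    "GenerationConfig",
    "sample_boundaries",
    "sample_item_bank",
    "sample_thetas",
    "generate_responses",
    "replication_rng",
]

#: Cap on full-triple redraws in the boundary rejection sampler.
MAX_REJECTION_DRAWS = 100_000


class ConfigError(ValueError):
    """Invalid generation or design configuration."""


@dataclass(frozen=True)
class GenerationConfig:
    """Sampling rules for one simulation condition.

    Defaults are the study conditions: H=3 dimensions, K=3 boundaries
    (four categories), discriminations U[1.1, 2.8], boundaries uniform on
    three contiguous thirds of [-2, 2] with a minimum adjacent gap of 0.5.
    """

    L: int = 30
    H: int = 3
    K: int = 3
    N: int = 500
    r: float = 0.5
    a_range: tuple[float, float] = (1.1, 2.8)
    b_intervals: tuple[tuple[float, float], ...] = (
        (-2.0, -0.67),
        (-0.67, 0.67),
        (0.67, 2.0),
    )
    min_gap: float = 0.5
    D: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.N <= 0:
            raise ConfigError("L and N must be positive")
        if self.H < 1 or self.K < 1:
            raise ConfigError("H and K must be >= 1")
        if self.L % self.H != 0:
            raise ConfigError(f"L={self.L} must be divisible by H={self.H}")
        if len(self.b_intervals) != self.K:
            raise ConfigError("need one boundary interval per boundary")
        if self.min_gap < 0:
            raise ConfigError("min_gap must be nonnegative")
        lo, hi = self.a_range
        if not lo < hi:
            raise ConfigError("a_range must satisfy low < high")
        for (lo1, hi1) in self.b_intervals:
            if not lo1 < hi1:
                raise ConfigError("each boundary interval must satisfy low < high")
        for (_, hi1), (lo2, _) in zip(self.b_intervals[:-1], self.b_intervals[1:]):
            if lo2 < hi1 - 1e-12:
                raise ConfigError("boundary intervals must be ordered and non-overlapping")

    @property
    def corr(self) -> LatentCorrelation:
        return LatentCorrelation.exchangeable(self.H, self.r)


def _propose_boundaries(rng: np.random.Generator, config: GenerationConfig, size: int = 1) -> np.ndarray:
    """Draw `size` independent boundary tuples, one uniform per interval."""
    lows = np.array([lo for lo, _ in config.b_intervals])
    highs = np.array([hi for _, hi in config.b_intervals])
    return rng.uniform(lows, highs, size=(size, config.K))


def _gap_ok(b: np.ndarray, min_gap: float) -> np.ndarray:
    """Acceptance predicate of the rejection step (vectorized over rows)."""
    b = np.atleast_2d(b)
    if b.shape[1] == 1:
        return np.ones(b.shape[0], dtype=bool)
    return np.all(np.diff(b, axis=1) >= min_gap, axis=1)


def sample_boundaries(rng: np.random.Generator, config: GenerationConfig) -> np.ndarray:
    """Sample one increasing boundary vector by full-triple rejection.

    The whole tuple is redrawn until every adjacent gap is at least
    ``config.min_gap``, which preserves the uniform-within-interval
    marginals conditioned on acceptance.
    """
    for _ in range(MAX_REJECTION_DRAWS):
        b = _propose_boundaries(rng, config, size=1)[0]
        if _gap_ok(b, config.min_gap)[0]:
            return b
    raise RuntimeError(
        f"boundary rejection sampler exceeded {MAX_REJECTION_DRAWS} draws; "
        "check that the gap constraint is satisfiable"
    )


def sample_item_bank(config: GenerationConfig, rng: np.random.Generator) -> ItemBank:
    """Draw a fresh simple-structure item bank.

    Items are allocated to dimensions in contiguous blocks: the first L/H
    items load dimension 1, the next L/H dimension 2, and so on, so every
    dimension carries an equal number of items.
    """
    per_dim = config.L // config.H
    items = []
    for j in range(config.L):
        dim = j // per_dim + 1
        a = np.zeros(config.H)
        a[dim - 1] = rng.uniform(*config.a_range)
        b = sample_boundaries(rng, config)
        items.append(
            ItemParameters(item_id=j + 1, loading_dim=dim, a=a, b=b, D=config.D)
        )
    return ItemBank(items=tuple(items))


def sample_thetas(N: int, corr: LatentCorrelation, rng: np.random.Generator) -> np.ndarray:
    """N independent MVN(0, corr) latent-trait vectors (N x H)."""
    if N <= 0:
        raise ConfigError("N must be positive")
    chol = np.linalg.cholesky(corr.matrix)
    z = rng.standard_normal((N, corr.H))
    return z @ chol.T


def generate_responses(
    thetas: np.ndarray, bank: ItemBank, rng: np.random.Generator
) -> np.ndarray:
    """Draw one categorical response per person-item pair (N x L, in 0..K).

    Each entry is a single draw from the item's category probabilities at
    the person's latent-trait vector (the first draw of a multinomial with
    one trial).
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.ndim != 2 or thetas.shape[1] != bank.H:
        raise ValueError("thetas must be N x H with H matching the bank")
    N = thetas.shape[0]
    X = np.empty((N, bank.L), dtype=np.int64)
    A = bank.a_matrix()
    B = bank.b_matrix()
    asum = A.sum(axis=1)
    proj = thetas @ A.T  # (N, L)
    with np.errstate(over="ignore"):
        star = 1.0 / (
            1.0 + np.exp(-bank.D * (proj.T[:, None, :] - (B * asum[:, None])[:, :, None]))
        )  # (L, K, N)
    # cumulative category probabilities: P(X <= k) = 1 - P*_{k+1}
    cum = 1.0 - star  # (L, K, N); last slice is P(X <= K-1); P(X <= K) = 1
    u = rng.uniform(size=(N, bank.L))
    for j in range(bank.L):
        # sampled category = number of cumulative thresholds P(X<=k) below u
        X[:, j] = (u[:, j][None, :] >= cum[j]).sum(axis=0)
    return X


def replication_rng(master_seed: int, condition_key: tuple[int, ...], rep: int) -> np.random.Generator:
    """Counter-based per-replication stream.

    The stream is derived from (master seed, condition key, replication
    index) through ``SeedSequence`` spawn keys, so replications are
    reproducible and independent regardless of execution order or
    parallelism.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(*condition_key, int(rep)))
    return np.random.Generator(np.random.PCG64(ss))
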