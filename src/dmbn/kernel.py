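"""The deletion-mutant (DM) kernel and the kernel generalized variance (KGV).

Deletion-mutant profiles are dominated by zeros (no significant change), so
the trivial discrete kernel ``k(x, y) = 1{x == y}`` would report almost every
pair of mutants as highly similar.  The DM kernel discards co-absence: two
calls are similar (kernel value 1) only when both are +1 or both are -1.

The DM kernel factorizes exactly through a two-dimensional indicator feature
map per variable: ``phi(x) = (1{x == +1}, 1{x == -1})``.  All production KGV
computations therefore run in feature space — covariances are 2x2 blocks and
no N x N Gram matrix is ever formed — which turns the O(N^3) kernel
computation into O(N m^2 + m^3) for m variables over N genes.  The full
Gram-matrix formulation is retained (``kgv_multiinfo_gram``) purely as a
brute-force cross-check.

The KGV multi-information of variables X_1..X_m is

    J = -1/2 * log( det(R_kappa) / det(D_kappa) )

where R_kappa is the 2m x 2m block *correlation* matrix of the centered
indicator features (covariances C_ij = Phi_i' Phi_j / N rescaled so every
non-degenerate feature has unit variance) with ridge kappa*I added, and
D_kappa is its block diagonal.  Applying the ridge on the correlation scale
makes kappa dimensionless relative to feature variance — essential here
because sparse profiles give the indicators tiny raw variances (p(1-p) for
DEG density p), and a ridge on the covariance scale would swamp them and
destroy the explaining-away that conditioning is supposed to provide.
Zero-variance features (a call never observed in a column) simply carry the
ridge alone.  J >= 0, J = 0 for a single variable, and J grows with
statistical dependence among the variables; it plays the role of a
mutual-information surrogate inside the network score.  Natural logarithms
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError
from .io import PerturbationMatrix

__all__ = [
    "KernelFeatureBlock",
    "KgvConfig",
    "dm_kernel_value",
    "indicator_features",
    "feature_block",
    "centered_gram",
    "kgv_multiinfo",
    "kgv_multiinfo_gram",
    "KgvEngine",
]

_ALPHABET = (-1, 0, 1)


def dm_kernel_value(x: int, y: int) -> int:
    """DM kernel on a pair of calls: 1 iff both +1 or both -1, else 0."""
    if x not in _ALPHABET or y not in _ALPHABET:
        raise ValueError(f"calls must be in {{-1, 0, 1}}, got ({x!r}, {y!r})")
    return 1 if (x == y and x != 0) else 0


@dataclass(frozen=True)
class KgvConfig:
    """KGV estimator settings.

    kappa is the ridge added to each variable's 2x2 feature covariance
    (dimensionless, > 0).  Feature centering is always on — the KGV is
    defined on centered features.
    """

    kappa: float = 0.01

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")


@dataclass(frozen=True)
class KernelFeatureBlock:
    """Centered N x 2 indicator features of one mutant's call column."""

    variable_id: str
    features: np.ndarray  # (N, 2), centered
    n_samples: int


def _validate_calls(column: np.ndarray) -> np.ndarray:
    col = np.asarray(column)
    if not np.isin(col, _ALPHABET).all():
        bad = col[~np.isin(col, _ALPHABET)][0]
        raise ValueError(f"calls must be in {{-1, 0, 1}}, got {bad!r}")
    return col.astype(np.int8)


def indicator_features(column: np.ndarray) -> np.ndarray:
    """Uncentered N x 2 map phi(x) = (1{x == +1}, 1{x == -1}).

    Satisfies phi(x) . phi(y) == dm_kernel_value(x, y) exactly.
    """
    col = _validate_calls(column)
    feats = np.empty((col.size, 2))
    feats[:, 0] = col == 1
    feats[:, 1] = col == -1
    return feats


def feature_block(column: np.ndarray, variable_id: str = "") -> KernelFeatureBlock:
    """Centered feature block for one call column."""
    feats = indicator_features(column)
    feats -= feats.mean(axis=0, keepdims=True)
    return KernelFeatureBlock(variable_id, feats, feats.shape[0])


def centered_gram(column: np.ndarray) -> np.ndarray:
    """Doubly centered N x N DM-kernel Gram matrix H K H.

    Symmetric, positive semi-definite, rank <= 2.  This materializes an
    N x N matrix and exists for diagnostics and cross-checks; the production
    KGV path works in the 2-dimensional feature space instead.
    """
    col = _validate_calls(column)
    k = (col[:, None] == col[None, :]) & (col[:, None] != 0)
    k = k.astype(float)
    # sequential row/column mean removal equals H K H exactly
    k -= k.mean(axis=0, keepdims=True)
    k -= k.mean(axis=1, keepdims=True)
    return k


def _blocks_covariance(blocks: list[KernelFeatureBlock]) -> np.ndarray:
    """Stacked 2m x 2m covariance Phi' Phi / N of centered features."""
    n = blocks[0].n_samples
    for b in blocks:
        if b.n_samples != n:
            raise DimensionError(
                f"feature blocks disagree on N: {b.n_samples} != {n}"
            )
    phi = np.hstack([b.features for b in blocks])
    return phi.T @ phi / n


def _to_correlation(cov: np.ndarray) -> np.ndarray:
    """Rescale a covariance matrix to unit diagonal; zero-variance
    coordinates are left at 0 (they only ever carry the ridge)."""
    d = np.sqrt(np.diag(cov))
    scale = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return cov * scale[:, None] * scale[None, :]


def _kgv_from_cov(cov: np.ndarray, m: int, kappa: float) -> float:
    """KGV from a 2m x 2m block covariance matrix (2x2 blocks)."""
    reg = _to_correlation(cov) + kappa * np.eye(2 * m)
    sign, logdet_full = np.linalg.slogdet(reg)
    if sign <= 0:  # pragma: no cover - reg is PD by construction
        raise FloatingPointError("regularized covariance not positive definite")
    logdet_diag = 0.0
    for i in range(m):
        blk = reg[2 * i : 2 * i + 2, 2 * i : 2 * i + 2]
        s, ld = np.linalg.slogdet(blk)
        if s <= 0:  # pragma: no cover
            raise FloatingPointError("diagonal block not positive definite")
        logdet_diag += ld
    j = -0.5 * (logdet_full - logdet_diag)
    if j < -1e-9:  # pragma: no cover - indicates a numerical defect
        raise FloatingPointError(f"KGV estimate {j} below tolerance")
    return max(j, 0.0)


def kgv_multiinfo(blocks: list[KernelFeatureBlock], cfg: KgvConfig) -> float:
    """KGV multi-information estimate (nats) for m >= 1 variables.

    Returns 0 exactly for a single variable; always >= 0.
    """
    if not blocks:
        raise ValueError("need at least one feature block")
    m = len(blocks)
    if m == 1:
        if blocks[0].features.shape[0] < 1:
            raise DimensionError("empty feature block")
        return 0.0
    cov = _blocks_covariance(blocks)
    return _kgv_from_cov(cov, m, cfg.kappa)


def _weighted_centered_gram(column: np.ndarray) -> np.ndarray:
    """Centered Gram of the variance-standardized DM-kernel feature map.

    Built element-wise from calls, never from feature matrices: the kernel
    k_w(x, y) = 1{x == y == +1} / var_+  +  1{x == y == -1} / var_-
    with var_s = p_s (1 - p_s) the variance of the indicator of call s
    (zero-variance indicators dropped), then doubly centered.
    """
    col = _validate_calls(column)
    n = col.size
    k = np.zeros((n, n))
    for s in (1, -1):
        p = float(np.mean(col == s))
        var = p * (1 - p)
        if var > 0:
            ind = (col == s).astype(float)
            k += np.outer(ind, ind) / var
    k -= k.mean(axis=0, keepdims=True)
    k -= k.mean(axis=1, keepdims=True)
    return k


def kgv_multiinfo_gram(columns: list[np.ndarray], cfg: KgvConfig) -> float:
    """N-dimensional Gram-matrix formulation of the same quantity.

    Uses the regularized centered Gram K_i/N + kappa*I of each variable
    (K_i the standardized-feature kernel of :func:`_weighted_centered_gram`):

        J = -1/2 [ (m-1) N log kappa
                   + logdet( sum_i K_i/N + kappa*I )
                   - sum_i logdet( K_i/N + kappa*I ) ]

    which is algebraically identical to the feature-space value (Sylvester's
    determinant identity applied block-wise).  O(N^3); cross-check only.
    """
    if not columns:
        raise ValueError("need at least one column")
    m = len(columns)
    n = np.asarray(columns[0]).size
    for c in columns:
        if np.asarray(c).size != n:
            raise DimensionError("columns disagree on N")
    if m == 1:
        return 0.0
    kappa = cfg.kappa
    grams = [_weighted_centered_gram(c) / n for c in columns]
    eye = np.eye(n)
    _, logdet_sum = np.linalg.slogdet(sum(grams) + kappa * eye)
    logdet_each = sum(np.linalg.slogdet(g + kappa * eye)[1] for g in grams)
    j = -0.5 * ((m - 1) * n * np.log(kappa) + logdet_sum - logdet_each)
    return max(j, 0.0)


class KgvEngine:
    """Precomputed KGV evaluator over the columns of a perturbation matrix.

    The full 2R x 2R feature covariance is computed once; the KGV of any
    subset of variables is then a pair of small log-determinants on the
    corresponding sub-blocks.
    """

    def __init__(self, matrix: PerturbationMatrix, cfg: KgvConfig) -> None:
        self.cfg = cfg
        self.node_ids = list(matrix.mutant_ids)
        self._index = {m: i for i, m in enumerate(self.node_ids)}
        self.n_samples = matrix.n_genes
        blocks = [
            feature_block(matrix.column(mid), mid) for mid in self.node_ids
        ]
        self._cov = _blocks_covariance(blocks)
        # column variance: a mutant with no DEGs contributes nothing
        var = np.array(
            [np.trace(self._cov[2 * i : 2 * i + 2, 2 * i : 2 * i + 2]) for i in range(len(blocks))]
        )
        self.zero_variance = {m for m, v in zip(self.node_ids, var) if v <= 0.0}

    def multiinfo(self, node_ids: list[str]) -> float:
        """KGV multi-information (nats) of a set of mutant columns."""
        m = len(node_ids)
        if m <= 1:
            return 0.0
        idx = np.concatenate(
            [[2 * self._index[n], 2 * self._index[n] + 1] for n in node_ids]
        )
        cov = self._cov[np.ix_(idx, idx)]
        return _kgv_from_cov(cov, m, self.cfg.kappa)
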