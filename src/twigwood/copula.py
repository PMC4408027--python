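"""Gaussian-copula sampling of trait vectors with range-bounded marginals.

A Gaussian copula draws correlated latent standard normals, pushes them
through the normal CDF to correlated uniforms, and maps each uniform
through the inverse CDF of the trait's marginal.  Marginals here are
scaled Beta distributions on a (low, high) support, optionally with a
prescribed mean, which keeps every generated value inside its stated
range by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class NotPositiveSemidefiniteError(ValueError):
    """Latent correlation matrix has negative eigenvalues.

    Carries a ``suggestion`` attribute with the nearest valid correlation
    matrix (eigenvalue clipping followed by re-scaling to unit diagonal).
    """

    def __init__(self, message: str, suggestion: np.ndarray):
        super().__init__(message)
        self.suggestion = suggestion


def nearest_correlation(matrix: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the closest valid correlation matrix.

    Eigenvalue clipping at ``eps`` followed by renormalisation to a unit
    diagonal — one pass of Higham's alternating projections, which is
    accurate enough for mildly indefinite empirical matrices.
    """
    sym = (matrix + matrix.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.clip(vals, eps, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def validate_correlation(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check symmetry, unit diagonal and positive semidefiniteness."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("latent correlation must be a square matrix")
    if not np.allclose(matrix, matrix.T, atol=tol):
        raise ValueError("latent correlation must be symmetric")
    if not np.allclose(np.diag(matrix), 1.0, atol=tol):
        raise ValueError("latent correlation must have a unit diagonal")
    min_eig = float(np.linalg.eigvalsh(matrix).min())
    if min_eig < -tol:
        raise NotPositiveSemidefiniteError(
            f"latent correlation is not positive semidefinite "
            f"(smallest eigenvalue {min_eig:.3e}); the nearest valid "
            f"correlation matrix is available as the error's .suggestion",
            suggestion=nearest_correlation(matrix),
        )
    return matrix


@dataclass(frozen=True)
class RangeMarginal:
    """Scaled Beta marginal on ``(low, high)`` with an optional target mean.

    ``concentration`` is the Beta pseudo-sample-size ``alpha + beta``;
    larger values concentrate mass around the mean.  The default of 8
    gives unimodal, moderately spread trait distributions.
    """

    low: float
    high: float
    mean: float | None = None
    concentration: float = 8.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(
                f"marginal low must be below high (got low={self.low}, high={self.high})"
            )
        if self.mean is not None and not (self.low < self.mean < self.high):
            raise ValueError("marginal mean must lie strictly inside (low, high)")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def _beta_params(self) -> tuple[float, float]:
        m = 0.5 if self.mean is None else (self.mean - self.low) / (self.high - self.low)
        a = m * self.concentration
        b = (1.0 - m) * self.concentration
        return a, b

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a, b = self._beta_params
        return self.low + (self.high - self.low) * stats.beta.ppf(u, a, b)


class GaussianCopula:
    """Sampler of correlated trait vectors with given marginals.

    Parameters
    ----------
    names : sequence of str
        Trait (or latent driver) names, one per matrix row.
    latent_correlation : array, optional
        Correlation of the latent normals; identity when omitted.
    marginals : mapping name -> RangeMarginal (or any object with ``ppf``)
        Missing names are returned on the latent-normal scale.
    """

    def __init__(self, names, latent_correlation=None, marginals=None):
        self.names = list(names)
        d = len(self.names)
        if latent_correlation is None:
            latent_correlation = np.eye(d)
        matrix = validate_correlation(np.asarray(latent_correlation, dtype=float))
        if matrix.shape[0] != d:
            raise ValueError("latent correlation size does not match number of names")
        self.latent_correlation = matrix
        self.marginals = dict(marginals or {})
        # eigenvalue factor instead of Cholesky: tolerates semidefinite matrices
        vals, vecs = np.linalg.eigh(matrix)
        vals = np.clip(vals, 0.0, None)
        self._factor = vecs * np.sqrt(vals)

    def sample_latent(self, n: int, rng: np.random.Generator) -> np.ndarray:
        white = rng.standard_normal((n, len(self.names)))
        return white @ self._factor.T

    def transform(self, latent: np.ndarray) -> dict[str, np.ndarray]:
        """Map latent normals to trait values through the marginals."""
        u = stats.norm.cdf(latent)
        # avoid infinities from ppf at exactly 0/1
        u = np.clip(u, 1e-12, 1.0 - 1e-12)
        out: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.names):
            marg = self.marginals.get(name)
            out[name] = marg.ppf(u[:, j]) if marg is not None else latent[:, j]
        return out

    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        return self.transform(self.sample_latent(n, rng))
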