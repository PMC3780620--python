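"""Conjugate probability kernel for a CRP mixture over (count, color) observations.

The observer's generative model assumes each trial belongs to a latent perceptual
category ``k``.  Categories are assigned by a Chinese restaurant process with
concentration ``alpha``; each category emits the (true) circle count from a
Gaussian with category-specific mean and variance under a normal-inverse-gamma
prior, and the circle color from a category-specific multinomial under a
symmetric Dirichlet prior.  All category parameters are integrated out
analytically, so a category is fully summarized by its sufficient statistics
(:class:`CategoryStats`) and the observer only ever evaluates posterior
*predictive* densities:

* colors: Dirichlet-multinomial, ``(lam + N_ck) / (C*lam + M_k)``
* counts: Student-t with ``2*a_k`` degrees of freedom, location ``mu_hat_k``
  and squared scale ``beta_k = b_k (1 + eta_k) / (a_k eta_k)``

where the posterior parameters are the standard conjugate updates

.. math::

    \\hat\\mu_k = \\frac{\\eta_0\\mu_0 + M_k \\bar x_k}{\\eta_k},\\qquad
    \\eta_k = M_k + \\eta_0,\\qquad
    a_k = \\frac{M_k + a_0}{2},

.. math::

    b_k = b_0 + \\tfrac12\\sum_i \\delta[z_i,k](x_i-\\bar x_k)^2
          + \\frac{M_k\\eta_0(\\mu_0-\\bar x_k)^2}{2\\eta_k}.

Note the shape parameterization: the prior on the category variance is
``IG(a0/2, b0)`` so that the *prior* predictive is a t with ``a0`` degrees of
freedom.  ``beta_k`` is the squared scale of the predictive t (taking it as the
scale itself fails a direct numerical marginalization check; see the test
suite's quadrature oracle).

Everything here is vectorized: the statistics arguments of the array-level
functions may be scalars or numpy arrays of any broadcastable shape, which is
what the particle filter relies on.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.special import gammaln

__all__ = [
    "Hyperparameters",
    "CategoryStats",
    "PosteriorParams",
    "crp_prior",
    "color_predictive",
    "posterior_params",
    "count_predictive_logpdf",
    "update_stats",
    "downdate_stats",
    "student_t_logpdf",
]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior and noise parameters of the ideal observer.

    Parameters
    ----------
    alpha : float
        CRP concentration.  ``alpha -> 0`` merges all trials into one
        category; ``alpha -> inf`` gives one category per trial (the
        exemplar limit).
    a0, b0 : float
        Inverse-gamma shape/scale hyperparameters of the prior on the
        category variance, parameterized so the variance prior is
        ``IG(a0/2, b0)`` (prior predictive t has ``a0`` dof, ``b0`` sets
        the scale of sigma_k^2).
    eta0 : float
        Prior pseudo-count on the category mean.
    mu0 : float
        Prior category mean (0 for recentered data).
    lam : float
        Symmetric Dirichlet parameter of the color prior.
    sigma_y : float
        Sensory noise standard deviation (y ~ N(x, sigma_y^2)).
    n_colors : int
        Number of available circle colors C.
    """

    alpha: float = 0.5
    a0: float = 1.0
    b0: float = 10.0
    eta0: float = 0.05
    mu0: float = 55.0
    lam: float = 1.0
    sigma_y: float = 8.0
    n_colors: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        for name in ("a0", "b0", "eta0", "lam", "sigma_y"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.n_colors < 2:
            raise ValueError(f"n_colors must be >= 2, got {self.n_colors}")

    def replace(self, **changes) -> "Hyperparameters":
        return replace(self, **changes)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "Hyperparameters":
        return cls(**json.loads(s))


class PosteriorParams(NamedTuple):
    """Posterior NIG parameters of one category (possibly array-valued)."""

    mu_hat: np.ndarray
    eta: np.ndarray
    a: np.ndarray
    b: np.ndarray
    beta: np.ndarray  # squared scale of the predictive t


@dataclass
class CategoryStats:
    """Sufficient statistics of one perceptual category.

    ``M`` trials, per-color counts ``N_c`` (length C), running mean and
    sum of squared deviations of the observed counts.
    """

    n_colors: int
    M: int = 0
    N_c: np.ndarray = None  # type: ignore[assignment]
    mean_x: float = 0.0
    sse_x: float = 0.0

    def __post_init__(self) -> None:
        if self.N_c is None:
            self.N_c = np.zeros(self.n_colors, dtype=int)

    def copy(self) -> "CategoryStats":
        return CategoryStats(self.n_colors, self.M, self.N_c.copy(),
                             self.mean_x, self.sse_x)


def update_stats(stats: CategoryStats, x: float, color: int) -> CategoryStats:
    """Add observation ``(x, color)``; Welford one-pass update; returns a new object."""
    if not 1 <= color <= stats.n_colors:
        raise ValueError(f"color {color} out of range 1..{stats.n_colors}")
    out = stats.copy()
    out.M += 1
    out.N_c[color - 1] += 1
    delta = x - out.mean_x
    out.mean_x += delta / out.M
    out.sse_x += delta * (x - out.mean_x)
    return out


def downdate_stats(stats: CategoryStats, x: float, color: int) -> CategoryStats:
    """Remove a previously added observation (exact inverse of :func:`update_stats`)."""
    if stats.M <= 0:
        raise RuntimeError("cannot downdate an empty category")
    if stats.N_c[color - 1] <= 0:
        raise RuntimeError(f"no observation with color {color} to remove")
    out = stats.copy()
    out.N_c[color - 1] -= 1
    out.M -= 1
    if out.M == 0:
        out.mean_x = 0.0
        out.sse_x = 0.0
        return out
    mean_prev = (stats.mean_x * stats.M - x) / out.M
    out.sse_x = stats.sse_x - (x - mean_prev) * (x - stats.mean_x)
    out.sse_x = max(out.sse_x, 0.0)  # guard tiny negative round-off
    out.mean_x = mean_prev
    return out


def crp_prior(category_sizes, alpha: float) -> np.ndarray:
    """CRP assignment probabilities for the next trial.

    Returns a vector of length ``K + 1``: entry ``k`` is ``M_k / (t-1+alpha)``
    for each occupied category, the last entry ``alpha / (t-1+alpha)`` is the
    probability of opening a new category.  With no previous trials the new
    category has probability 1 regardless of ``alpha``.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    sizes = np.asarray(category_sizes, dtype=float)
    if sizes.size == 0:
        return np.array([1.0])
    if np.any(sizes < 1):
        raise ValueError("category sizes must all be >= 1")
    t1 = sizes.sum()
    denom = t1 + alpha
    if denom == 0:  # alpha == 0 and no customers: handled above
        raise ValueError("degenerate CRP: no customers and alpha == 0")
    return np.append(sizes, alpha) / denom


def color_predictive(stats: CategoryStats, color: int, hp: Hyperparameters) -> float:
    """Dirichlet-multinomial posterior predictive P(color | category)."""
    if not 1 <= color <= hp.n_colors:
        raise ValueError(f"color {color} out of range 1..{hp.n_colors}")
    return (hp.lam + stats.N_c[color - 1]) / (hp.n_colors * hp.lam + stats.M)


def posterior_params(M, mean_x, sse_x, hp: Hyperparameters) -> PosteriorParams:
    """Posterior NIG parameters from sufficient statistics (broadcastable)."""
    M = np.asarray(M, dtype=float)
    mean_x = np.asarray(mean_x, dtype=float)
    sse_x = np.asarray(sse_x, dtype=float)
    eta = M + hp.eta0
    a = (M + hp.a0) / 2.0
    mu_hat = (hp.eta0 * hp.mu0 + M * mean_x) / eta
    b = hp.b0 + sse_x / 2.0 + M * hp.eta0 * (hp.mu0 - mean_x) ** 2 / (2.0 * eta)
    beta = b * (1.0 + eta) / (a * eta)
    return PosteriorParams(mu_hat, eta, a, b, beta)


def posterior_params_stats(stats: CategoryStats, hp: Hyperparameters) -> PosteriorParams:
    """Object-level convenience wrapper of :func:`posterior_params`."""
    return posterior_params(stats.M, stats.mean_x, stats.sse_x, hp)


def student_t_logpdf(x, df, loc, scale_sq) -> np.ndarray:
    """Log density of a Student-t with ``df`` dof, location ``loc`` and
    SQUARED scale ``scale_sq`` (broadcastable)."""
    x = np.asarray(x, dtype=float)
    df = np.asarray(df, dtype=float)
    loc = np.asarray(loc, dtype=float)
    scale_sq = np.asarray(scale_sq, dtype=float)
    z2 = (x - loc) ** 2 / scale_sq
    return (gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0)
            - 0.5 * np.log(df * math.pi * scale_sq)
            - (df + 1.0) / 2.0 * np.log1p(z2 / df))


def count_predictive_logpdf(x, stats: CategoryStats, hp: Hyperparameters):
    """Log posterior-predictive density of a count under one category."""
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    pp = posterior_params_stats(stats, hp)
    return student_t_logpdf(x, 2.0 * pp.a, pp.mu_hat, pp.beta)
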