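"""Linear-Gaussian surrogate model for verifying the bound pipeline.

With the forward map replaced by a fixed matrix ``G`` and a Gaussian prior
``N(0, C)``, every quantity the package estimates has a closed form:

* data information: ``J_D = G^T Sigma_z^{-1} G``;
* Bayesian CRB:     ``V_m = (C^{-1} + J_D)^{-1}`` (the posterior covariance);
* MAP estimate:     ``(C^{-1} + J_D)^{-1} G^T Sigma_z^{-1} y``
  (the posterior mean).

The surrogate implements the same duck-typed interface as
:class:`pactoed.likelihood.PactModel` (``split``, ``simulate_data``,
``score``, ``forward``, ``gauss_newton_misfit_action``) so the Monte-Carlo
information estimator and the Newton-CG reconstructor run on it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import Measurement, ScoreResult

__all__ = ["LinearGaussianModel", "DenseGaussianPrior"]


@dataclass
class _LinearState:
    m: np.ndarray
    predicted: list


class LinearGaussianModel:
    """Observation model ``d = G m + z`` with ``z ~ N(0, sigma2 I)``."""

    def __init__(self, G: np.ndarray, sigma2: float):
        self.G = np.asarray(G, dtype=float)
        self.sigma2 = float(sigma2)

    @property
    def n_latent(self) -> int:
        return self.G.shape[1]

    def split(self, m):
        return m, None

    def forward(self, m1, m2=None) -> _LinearState:
        return _LinearState(m=m1, predicted=[self.G @ m1])

    def simulate_data(self, m1, m2=None, seed=None, rng=None,
                      sigma2=None, state=None) -> Measurement:
        if rng is None:
            rng = np.random.default_rng(seed)
        s2 = self.sigma2 if sigma2 is None else float(sigma2)
        d = self.G @ m1
        if s2 > 0:
            d = d + np.sqrt(s2) * rng.standard_normal(d.shape)
        return Measurement(data=[d], sigma2=max(s2, np.finfo(float).tiny),
                           seed=seed)

    def log_likelihood(self, m1, m2, y: Measurement, state=None) -> float:
        r = self.G @ m1 - y.data[0]
        return -0.5 * float(r @ r) / y.sigma2

    def score(self, m1, m2, y: Measurement, state=None) -> ScoreResult:
        g = self.G.T @ (y.data[0] - self.G @ m1) / y.sigma2
        return ScoreResult(g1=g, g2=None, fluences=[], adjoints=[])

    def gauss_newton_misfit_action(self, state, v1, v2):
        return self.G.T @ (self.G @ v1) / self.sigma2, None

    # -- closed forms used as test oracles -----------------------------
    def information(self) -> np.ndarray:
        return self.G.T @ self.G / self.sigma2

    def posterior_covariance(self, prior_precision: np.ndarray) -> np.ndarray:
        return np.linalg.inv(prior_precision + self.information())

    def posterior_mean(self, prior_precision: np.ndarray,
                       y: Measurement) -> np.ndarray:
        rhs = self.G.T @ y.data[0] / y.sigma2
        return self.posterior_covariance(prior_precision) @ rhs


class DenseGaussianPrior:
    """Dense-covariance Gaussian prior with the :class:`JointPrior` API."""

    def __init__(self, cov: np.ndarray):
        self.cov = np.asarray(cov, dtype=float)
        self.precision = np.linalg.inv(self.cov)
        self._chol = np.linalg.cholesky(self.cov)

    @property
    def n_total(self) -> int:
        return self.cov.shape[0]

    def sample(self, rng: np.random.Generator):
        return self._chol @ rng.standard_normal(self.n_total), None

    def apply_precision(self, m1, m2=None):
        return self.precision @ m1, None

    def dense_precision_total(self) -> np.ndarray:
        return self.precision
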