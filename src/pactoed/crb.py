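"""Bayesian Cramér–Rao bound estimation and A-optimal design metrics.

The Bayesian information for the latent parameter ``m`` decomposes as
``J_m = J_P + J_D`` with prior term ``J_P = C^{-1}`` (Gaussian prior) and
data term

    J_D = E[ grad_m log p(y|m) grad_m log p(y|m)^T ] ,

estimated by Monte-Carlo over i.i.d. draws from the joint density: sample
``m`` from the prior, simulate ``y`` given ``m``, and accumulate the outer
products of the likelihood score.  The bound is ``V_m = J_m^{-1}``; the
block of ``V_m`` belonging to ``m1`` carries the nuisance-marginalised bound
(post-marginalisation), and a diagonal change-of-variable congruence maps it
to a bound on the absorption coefficient ``mu_a = mu_a_bar exp(m1)``.

Design schemes are ranked by the mass-weighted trace ``tr_M(V_mua)`` --
the discrete counterpart of the integrated pointwise error bound, i.e. a
Bayesian A-optimality criterion consistent with the function-space limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .geometry import FemOperators
from .optical import MU_A_BAR

__all__ = [
    "BoundResult",
    "estimate_scores",
    "estimate_JD",
    "jd_from_scores",
    "assemble_bound",
    "change_of_variable",
    "design_metric",
    "trace_metric",
]


def estimate_scores(model, prior, n_samples: int, seed: int,
                    sigma2: float | None = None) -> np.ndarray:
    """Likelihood scores at ``n_samples`` joint draws, one column each.

    Sample ``i`` uses its own counter-based seed stream (reproducible
    independently of ``n_samples``, embarrassingly parallel).  Forward or
    adjoint failures are re-raised with the failing sample index attached.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    cols = np.empty((prior.n_total, n_samples))
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n_samples)):
        rng = np.random.default_rng(ss)
        m1, m2 = prior.sample(rng)
        try:
            y = model.simulate_data(m1, m2, rng=rng, sigma2=sigma2)
            cols[:, i] = model.score(m1, m2, y).stacked()
        except Exception as exc:
            raise RuntimeError(f"score evaluation failed at sample {i}") from exc
    return cols


def jd_from_scores(scores: np.ndarray) -> np.ndarray:
    """Symmetrised outer-product average ``(1/Ns) sum g g^T``."""
    J = scores @ scores.T / scores.shape[1]
    return 0.5 * (J + J.T)


def estimate_JD(model, prior, n_samples: int, seed: int,
                sigma2: float | None = None) -> np.ndarray:
    """Monte-Carlo estimate of the data term of the Bayesian information."""
    return jd_from_scores(estimate_scores(model, prior, n_samples, seed,
                                          sigma2=sigma2))


def _prior_precision_dense(prior) -> np.ndarray:
    if hasattr(prior, "dense_precision_total"):
        return prior.dense_precision_total()
    return scipy.linalg.block_diag(*[p.dense_precision()
                                     for p in prior.blocks])


@dataclass
class BoundResult:
    """Bayesian information / CRB matrices and derived design metrics."""

    J_D: np.ndarray
    J_m: np.ndarray
    V_m: np.ndarray
    V_m1: np.ndarray
    n1: int
    n_samples: int | None = None
    seed: int | None = None
    c_hat: np.ndarray | None = None
    V_mua: np.ndarray | None = None
    tr_M_m1: float | None = None
    tr_M_mua: float | None = None

    @property
    def pointwise_m1(self) -> np.ndarray:
        """Nodal map of the marginal bound on ``m1``."""
        return np.diag(self.V_m1).copy()

    @property
    def pointwise_mua(self) -> np.ndarray:
        if self.V_mua is None:
            raise ValueError("change_of_variable has not been applied")
        return np.diag(self.V_mua).copy()


def assemble_bound(J_D: np.ndarray, prior, fem: FemOperators | None = None,
                   n_samples: int | None = None,
                   seed: int | None = None) -> BoundResult:
    """Form ``J_m = C^{-1} + J_D`` and invert it by Cholesky.

    ``J_m`` is the sum of an SPD prior precision and a PSD Monte-Carlo
    average, hence SPD; a Cholesky failure indicates an upstream bug and is
    deliberately not regularised away.
    """
    J_D = np.asarray(J_D)
    if not np.allclose(J_D, J_D.T, atol=1e-10 * max(1.0, np.abs(J_D).max())):
        raise ValueError("J_D must be symmetric")
    J_m = _prior_precision_dense(prior) + J_D
    J_m = 0.5 * (J_m + J_m.T)
    c, low = scipy.linalg.cho_factor(J_m, lower=True)
    V_m = scipy.linalg.cho_solve((c, low), np.eye(J_m.shape[0]))
    V_m = 0.5 * (V_m + V_m.T)
    n1 = getattr(prior, "prior_m1", None)
    n1 = n1.n_nodes if n1 is not None else J_m.shape[0]
    bound = BoundResult(J_D=J_D, J_m=J_m, V_m=V_m, V_m1=V_m[:n1, :n1],
                        n1=n1, n_samples=n_samples, seed=seed)
    if fem is not None:
        bound.tr_M_m1 = trace_metric(bound.V_m1, fem)
    return bound


def change_of_variable(bound: BoundResult, prior_m1,
                       mode: str = "monte_carlo", n_samples: int = 5000,
                       seed: int = 0, mu_a_bar: float = MU_A_BAR,
                       fem: FemOperators | None = None):
    """Transform the ``m1`` bound into a bound on ``mu_a``.

    The congruence matrix is diagonal with entries
    ``E[d mu_a / d m1] = E[mu_a_bar exp(m1)]`` per node: the lognormal mean
    ``mu_a_bar exp(var/2)`` in ``closed_form`` mode, or a Monte-Carlo
    average of ``mu_a_bar exp(m1)`` over prior samples otherwise.  Updates
    and returns the :class:`BoundResult`.
    """
    if mode == "closed_form":
        var = prior_m1.pointwise_variance()
        c_hat = mu_a_bar * np.exp(0.5 * var)
    elif mode == "monte_carlo":
        acc = np.zeros(bound.n1)
        for ss in np.random.SeedSequence(seed).spawn(n_samples):
            rng = np.random.default_rng(ss)
            acc += np.exp(prior_m1.sample(rng))
        c_hat = mu_a_bar * acc / n_samples
    else:
        raise ValueError(f"unknown change-of-variable mode {mode!r}")
    bound.c_hat = c_hat
    bound.V_mua = c_hat[:, None] * bound.V_m1 * c_hat[None, :]
    if fem is not None:
        bound.tr_M_mua = trace_metric(bound.V_mua, fem)
    return bound


def trace_metric(X: np.ndarray, fem: FemOperators) -> float:
    """Mass-weighted trace ``tr(M X)`` over a single-field block."""
    if X.shape[0] != fem.n_nodes:
        raise ValueError("block size does not match the mesh")
    return float(fem.mass.dot(X).diagonal().sum())


def design_metric(bound: BoundResult, fem: FemOperators) -> float:
    """A-optimality metric ``tr_M(V_mua)`` (computing it if needed)."""
    if bound.V_mua is None:
        raise ValueError("apply change_of_variable before the design metric")
    if bound.tr_M_mua is None:
        bound.tr_M_mua = trace_metric(bound.V_mua, fem)
    if bound.tr_M_m1 is None:
        bound.tr_M_m1 = trace_metric(bound.V_m1, fem)
    return bound.tr_M_mua


def save_bound(bound: BoundResult, path) -> None:
    """Persist a :class:`BoundResult` (matrices, metrics, provenance) to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        for name in ("J_D", "J_m", "V_m", "V_m1", "c_hat", "V_mua"):
            arr = getattr(bound, name)
            if arr is not None:
                f.create_dataset(name, data=arr, compression="gzip")
        f.attrs["n1"] = bound.n1
        for name in ("n_samples", "seed", "tr_M_m1", "tr_M_mua"):
            val = getattr(bound, name)
            if val is not None:
                f.attrs[name] = val


def load_bound(path) -> BoundResult:
    """Load a :class:`BoundResult` written by :func:`save_bound`."""
    import h5py

    with h5py.File(path, "r") as f:
        kw = {name: f[name][:] for name in
              ("J_D", "J_m", "V_m", "V_m1", "c_hat", "V_mua") if name in f}
        a = f.attrs
        return BoundResult(
            n1=int(a["n1"]),
            n_samples=int(a["n_samples"]) if "n_samples" in a else None,
            seed=int(a["seed"]) if "seed" in a else None,
            tr_M_m1=float(a["tr_M_m1"]) if "tr_M_m1" in a else None,
            tr_M_mua=float(a["tr_M_mua"]) if "tr_M_mua" in a else None,
            **kw)
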