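"""End-to-end study orchestration: configurations, runs, and design ranking.

Three canonical studies mirror the virtual-imaging-trial layout:

* study 1 -- single uniform illumination (``q = 1`` AU on the boundary),
  known scattering; used to validate the bound against the MAP error.
* study 2 -- contiguous vs interlaced multi-illumination schemes, known
  scattering; the bound ranks the two designs.
* study 3 -- the same two schemes with the reduced scattering coefficient
  as an unknown nuisance field (prior variance 0.05).

Each study exists at ``full`` scale (the published configuration: study
mesh, 360 transducers, 184 times, 5000 bound samples, 10000 MAP solves --
workstation/cluster budgets) and at ``desk`` scale (coarse mesh, 60
transducers, 64 times, 200 bound samples, 100 MAP solves) so that the whole
pipeline runs on one CPU in minutes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import crb
from .acoustic import AcousticGeometry, build_crt
from .geometry import assemble_fem, build_disk_mesh, write_vtk
from .illumination import make_design, normalize_power
from .likelihood import PactModel
from .map_recon import MapSolverConfig, expected_mse
from .optical import MU_A_BAR, MU_S_BAR, DiffusionSolver, OpticalParameters
from .prior import JointPrior, calibrate_prior

__all__ = ["StudyConfig", "StudyResult", "study_config", "run_study",
           "compare_designs", "snr_db"]

_FULL = dict(h_boundary=0.08, h_center=0.15, n_transducers=360, n_times=184,
             dt=2e-7, n_samples_bound=5000, n_samples_cov=5000,
             n_trials_mse=10000)
_DESK = dict(h_boundary=0.4, h_center=0.4, n_transducers=60, n_times=64,
             dt=2e-7 * 184 / 64, n_samples_bound=200, n_samples_cov=2000,
             n_trials_mse=100)


@dataclass
class StudyConfig:
    """Declarative description of one study run."""

    name: str
    schemes: tuple
    unknown_scattering: bool = False
    radius: float = 5.0
    h_boundary: float = 0.4
    h_center: float = 0.4
    mesh_seed: int = 1
    prior_variance_m1: float = 0.2
    prior_variance_m2: float = 0.05
    prior_corr_length: float = 5.0
    n_sources: int = 10
    n_illuminations: int = 4
    ring_radius: float = 10.0
    n_transducers: int = 60
    n_times: int = 64
    dt: float = 2e-7 * 184 / 64
    sigma2: float = 1e-3
    n_samples_bound: int = 200
    n_samples_cov: int = 2000
    n_trials_mse: int = 100
    cov_mode: str = "monte_carlo"
    seed: int = 0


def study_config(study: int, scale: str = "desk", **overrides) -> StudyConfig:
    """Preset configuration for studies 1-3 at ``full`` or ``desk`` scale."""
    if scale == "full":
        base = dict(_FULL)
    elif scale == "desk":
        base = dict(_DESK)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if study == 1:
        kw = dict(name=f"study1-{scale}", schemes=("single_uniform",),
                  n_illuminations=1, unknown_scattering=False)
    elif study == 2:
        kw = dict(name=f"study2-{scale}", schemes=("contiguous", "interlaced"),
                  unknown_scattering=False)
    elif study == 3:
        kw = dict(name=f"study3-{scale}", schemes=("contiguous", "interlaced"),
                  unknown_scattering=True)
    else:
        raise ValueError("study must be 1, 2 or 3")
    base.update(kw)
    base.update(overrides)
    return StudyConfig(**base)


@dataclass
class StudyResult:
    """Everything one run produced, ready for reporting or persistence."""

    config: StudyConfig
    table: pd.DataFrame
    bounds: dict
    mses: dict
    scores: dict
    timings: dict
    mesh: object = None
    fem: object = None


def _build_problem(config: StudyConfig):
    mesh = build_disk_mesh(config.radius, config.h_boundary, config.h_center,
                           seed=config.mesh_seed)
    fem = assemble_fem(mesh)
    prior_m1 = calibrate_prior(fem, config.prior_variance_m1,
                               config.prior_corr_length)
    prior_m2 = None
    if config.unknown_scattering:
        prior_m2 = calibrate_prior(fem, config.prior_variance_m2,
                                   config.prior_corr_length)
    prior = JointPrior(prior_m1, prior_m2)
    geom = AcousticGeometry(n_transducers=config.n_transducers,
                            n_times=config.n_times, dt=config.dt)
    crt = build_crt(mesh, geom)
    return mesh, fem, prior, geom, crt


def _make_model(config: StudyConfig, scheme: str, mesh, fem, crt) -> PactModel:
    design = make_design(scheme, ring_radius=config.ring_radius,
                         S=config.n_sources, I=config.n_illuminations)
    if not design.uniform_flux:
        ref = DiffusionSolver(OpticalParameters.reference(fem.n_nodes), fem)
        design = normalize_power(design, lambda q: ref.solve(q).phi, mesh)
    return PactModel(fem, design, crt, sigma2=config.sigma2,
                     infer_scattering=config.unknown_scattering)


def run_study(config: StudyConfig, outdir: str | Path | None = None,
              compute_mse: bool | None = None,
              map_config: MapSolverConfig | None = None) -> StudyResult:
    """Run the bound pipeline (and optionally the MAP validation) per scheme.

    Writes, when ``outdir`` is given: the resolved configuration, a summary
    table mirroring the study report (rows = schemes, columns = MSE and
    bound for ``m1`` and ``mu_a``), and pointwise maps as VTK point data.
    """
    if compute_mse is None:
        compute_mse = config.n_trials_mse > 0
    t0 = time.time()
    try:
        mesh, fem, prior, geom, crt = _build_problem(config)
    except Exception as exc:
        raise RuntimeError(f"study stage 'setup' failed: {exc}") from exc
    timings = {"setup": time.time() - t0}

    bounds, mses, scores = {}, {}, {}
    rows = []
    for scheme in config.schemes:
        t0 = time.time()
        try:
            model = _make_model(config, scheme, mesh, fem, crt)
            S = crb.estimate_scores(model, prior, config.n_samples_bound,
                                    seed=config.seed)
            bound = crb.assemble_bound(crb.jd_from_scores(S), prior, fem,
                                       n_samples=config.n_samples_bound,
                                       seed=config.seed)
            crb.change_of_variable(bound, prior.prior_m1,
                                   mode=config.cov_mode,
                                   n_samples=config.n_samples_cov,
                                   seed=config.seed + 1, fem=fem)
            crb.design_metric(bound, fem)
        except Exception as exc:
            raise RuntimeError(
                f"study stage 'bound[{scheme}]' failed: {exc}") from exc
        timings[f"bound[{scheme}]"] = time.time() - t0
        bounds[scheme], scores[scheme] = bound, S

        row = {"scheme": scheme, "bound_m1": bound.tr_M_m1,
               "bound_mua": bound.tr_M_mua,
               "mse_m1": np.nan, "mse_mua": np.nan}
        if compute_mse:
            t0 = time.time()
            try:
                mse = expected_mse(model, prior, fem, config.n_trials_mse,
                                   seed=config.seed + 2, config=map_config)
            except Exception as exc:
                raise RuntimeError(
                    f"study stage 'mse[{scheme}]' failed: {exc}") from exc
            timings[f"mse[{scheme}]"] = time.time() - t0
            mses[scheme] = mse
            row["mse_m1"], row["mse_mua"] = mse.tr_M_m1, mse.tr_M_mua
        rows.append(row)

    table = pd.DataFrame(rows).set_index("scheme")[
        ["mse_m1", "bound_m1", "mse_mua", "bound_mua"]]
    result = StudyResult(config=config, table=table, bounds=bounds,
                         mses=mses, scores=scores, timings=timings,
                         mesh=mesh, fem=fem)
    if outdir is not None:
        _persist(result, Path(outdir))
    return result


def _persist(result: StudyResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = asdict(result.config)
    cfg["schemes"] = list(cfg["schemes"])
    (outdir / "config.json").write_text(json.dumps(cfg, indent=2))
    result.table.to_csv(outdir / "summary.csv")
    (outdir / "timings.json").write_text(json.dumps(result.timings, indent=2))
    for scheme, bound in result.bounds.items():
        data = {"bound_m1": bound.pointwise_m1,
                "bound_mua": bound.pointwise_mua}
        if scheme in result.mses:
            data["mse_m1"] = result.mses[scheme].pointwise_m1
            data["mse_mua"] = result.mses[scheme].pointwise_mua
        write_vtk(result.mesh, outdir / f"maps_{scheme}.vtk", data)


def compare_designs(result: StudyResult) -> pd.DataFrame:
    """Rank schemes by ``tr_M(V_mua)`` with half-sample error intervals.

    The Monte-Carlo scores of each scheme are split into disjoint halves and
    the design metric recomputed on each half; the interval is the span of
    the two half estimates around the full estimate.  The ``ranked`` flag is
    set only when the intervals of successive schemes do not overlap.
    """
    fem = result.fem
    prior_cfg = result.config
    rows = []
    for scheme, S in result.scores.items():
        ns = S.shape[1]
        if ns < 2:
            lo = hi = result.bounds[scheme].tr_M_mua
        else:
            halves = []
            prior = _rebuild_prior(result)
            for part in (S[:, :ns // 2], S[:, ns // 2:]):
                b = crb.assemble_bound(crb.jd_from_scores(part), prior, fem)
                crb.change_of_variable(b, prior.prior_m1,
                                       mode=prior_cfg.cov_mode,
                                       n_samples=prior_cfg.n_samples_cov,
                                       seed=prior_cfg.seed + 1, fem=fem)
                halves.append(crb.design_metric(b, fem))
            lo, hi = min(halves), max(halves)
        rows.append({"scheme": scheme,
                     "metric": result.bounds[scheme].tr_M_mua,
                     "half_low": lo, "half_high": hi})
    df = pd.DataFrame(rows).sort_values("metric").reset_index(drop=True)
    ranked = all(df.loc[i, "half_high"] < df.loc[i + 1, "half_low"]
                 for i in range(len(df) - 1))
    df.attrs["ranked"] = bool(ranked)
    df["rank"] = np.arange(1, len(df) + 1) if ranked else pd.NA
    return df


def _rebuild_prior(result: StudyResult) -> JointPrior:
    cfg = result.config
    p1 = calibrate_prior(result.fem, cfg.prior_variance_m1,
                         cfg.prior_corr_length)
    p2 = (calibrate_prior(result.fem, cfg.prior_variance_m2,
                          cfg.prior_corr_length)
          if cfg.unknown_scattering else None)
    return JointPrior(p1, p2)


def snr_db(model: PactModel, prior: JointPrior, n_samples: int = 20,
           seed: int = 0) -> float:
    """Signal-to-noise ratio ``10 log10(E||signal||^2 / (K sigma^2))``.

    The expectation of the mean squared noise-free data value is taken over
    prior draws; this is one reasonable convention among several and is
    reported, not asserted against external figures.
    """
    acc = cnt = 0.0
    for ss in np.random.SeedSequence(seed).spawn(n_samples):
        rng = np.random.default_rng(ss)
        m1, m2 = prior.sample(rng)
        state = model.forward(m1, m2)
        for d in state.predicted:
            acc += float(d @ d)
            cnt += d.size
    return 10.0 * np.log10(acc / cnt / model.sigma2)
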