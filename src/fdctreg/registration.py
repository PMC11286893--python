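"""The semi-automated registration workflow.

Stages, mirroring the clinical procedure: a user (or the phantom generator)
supplies three corresponding anatomical landmarks in the fixed and moving
images; a closed-form rigid fit to those pairs initializes the transform;
a coarse-to-fine Gaussian pyramid then refines the six rigid parameters by
gradient ascent on sampled mutual information.  Either modality may play
the fixed role — the workflow is direction-agnostic.

The estimator follows scikit-learn conventions: hyperparameters in
``__init__``, data in ``fit``, fitted state in trailing-underscore
attributes, and ``predict`` mapping fixed-space points into moving space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .errors import NoOverlapError, RegistrationError
from .metric import MetricConfig, MIObjective
from .optimize import OptimizationTrace, OptimizerConfig, ascend
from .transforms import (LandmarkPairSet, RigidTransform3D, fit_landmarks,
                         params_to_transform, transform_to_params)
from .volume import Volume3D

__all__ = [
    "RegistrationConfig",
    "RegistrationResult",
    "RigidRegistration",
    "initialize",
    "register",
    "pyramid_level",
]


@dataclass
class RegistrationConfig:
    """All tunables of the workflow; defaults are the clinical settings
    (50 bins, 1% sampling, learning rate 1.0, 100 iterations, convergence
    1e-6 over a 10-value window) plus a conventional 3-level pyramid."""

    metric: MetricConfig = field(default_factory=MetricConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    levels: int = 3
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas_mm: tuple = (2.0, 1.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.levels == len(self.shrink_factors) == len(self.smoothing_sigmas_mm)):
            raise ValueError("levels, shrink_factors and smoothing_sigmas_mm lengths must agree")
        f = list(self.shrink_factors)
        if any(v < 1 for v in f) or any(a < b for a, b in zip(f, f[1:])):
            raise ValueError("shrink factors must be positive and non-increasing")


@dataclass
class RegistrationResult:
    """Estimated fixed->moving rigid map plus provenance of the run."""

    transform: RigidTransform3D
    initial_transform: RigidTransform3D
    traces: list[OptimizationTrace]
    converged: bool
    metric_initial: float = float("nan")
    metric_final: float = float("nan")


def initialize(pairs: LandmarkPairSet) -> RigidTransform3D:
    """Landmark initialization: closed-form rigid fit to the 3+ user pairs."""
    return fit_landmarks(pairs)


def pyramid_level(vol: Volume3D, shrink: int, sigma_mm: float) -> Volume3D:
    """Gaussian-smooth (physical-unit sigma) then decimate by ``shrink``.

    Smoothing in mm blurs CT and FDCT comparably despite their different
    voxel sizes.  Decimation keeps voxel (0,0,0), so the origin is unchanged
    and spacing scales by the shrink factor.
    """
    data = vol.data.astype(float)
    if sigma_mm > 0:
        data = ndimage.gaussian_filter(data, sigma=sigma_mm / vol.spacing, mode="nearest")
    if shrink > 1:
        data = data[::shrink, ::shrink, ::shrink]
    return Volume3D(data, vol.spacing * shrink, vol.origin, vol.direction)


class RigidRegistration(BaseEstimator):
    """Landmark-initialized, MI-refined rigid registration estimator.

    Parameters mirror :class:`RegistrationConfig` flattened to scalars so
    the estimator plays well with ``get_params``/``set_params`` and sklearn
    model selection.

    Attributes (after ``fit``)
    --------------------------
    transform_ : RigidTransform3D
        Estimated fixed->moving physical map.
    initial_transform_ : RigidTransform3D
        The landmark-fit starting transform.
    traces_ : list of OptimizationTrace
        One ascent trace per pyramid level (coarse to fine).
    converged_ : bool
        Whether the finest level stopped on the convergence window.
    """

    def __init__(self, bins: int = 50, sampling_fraction: float = 0.01,
                 min_samples: int = 5000, learning_rate: float = 1.0,
                 max_iterations: int = 100, convergence_min: float = 1e-6,
                 convergence_window: int = 10, fd_step_rotation: float = 1e-3,
                 fd_step_translation: float = 0.1, levels: int = 3,
                 shrink_factors: tuple = (4, 2, 1),
                 smoothing_sigmas_mm: tuple = (2.0, 1.0, 0.0), seed: int = 0):
        self.bins = bins
        self.sampling_fraction = sampling_fraction
        self.min_samples = min_samples
        self.learning_rate = learning_rate
        self.max_iterations = max_iterations
        self.convergence_min = convergence_min
        self.convergence_window = convergence_window
        self.fd_step_rotation = fd_step_rotation
        self.fd_step_translation = fd_step_translation
        self.levels = levels
        self.shrink_factors = shrink_factors
        self.smoothing_sigmas_mm = smoothing_sigmas_mm
        self.seed = seed

    # -- config plumbing ----------------------------------------------------

    def _config(self) -> RegistrationConfig:
        return RegistrationConfig(
            metric=MetricConfig(bins=self.bins, sampling_fraction=self.sampling_fraction,
                                seed=self.seed, min_samples=self.min_samples),
            optimizer=OptimizerConfig(
                learning_rate=self.learning_rate, max_iterations=self.max_iterations,
                convergence_min=self.convergence_min,
                convergence_window=self.convergence_window,
                fd_step_rotation=self.fd_step_rotation,
                fd_step_translation=self.fd_step_translation),
            levels=self.levels, shrink_factors=tuple(self.shrink_factors),
            smoothing_sigmas_mm=tuple(self.smoothing_sigmas_mm), seed=self.seed)

    @classmethod
    def from_config(cls, cfg: RegistrationConfig) -> "RigidRegistration":
        return cls(bins=cfg.metric.bins, sampling_fraction=cfg.metric.sampling_fraction,
                   min_samples=cfg.metric.min_samples,
                   learning_rate=cfg.optimizer.learning_rate,
                   max_iterations=cfg.optimizer.max_iterations,
                   convergence_min=cfg.optimizer.convergence_min,
                   convergence_window=cfg.optimizer.convergence_window,
                   fd_step_rotation=cfg.optimizer.fd_step_rotation,
                   fd_step_translation=cfg.optimizer.fd_step_translation,
                   levels=cfg.levels, shrink_factors=cfg.shrink_factors,
                   smoothing_sigmas_mm=cfg.smoothing_sigmas_mm, seed=cfg.seed)

    # -- estimator API ------------------------------------------------------

    def fit(self, X, y: LandmarkPairSet):
        """Estimate the fixed->moving rigid transform.

        Parameters
        ----------
        X : tuple (fixed, moving) of Volume3D
            The image pair; the transform maps fixed physical points into
            the moving volume's physical space.
        y : LandmarkPairSet
            The >= 3 manually identified corresponding points driving the
            initialization (the "supervision" of the semi-automated loop).
        """
        try:
            fixed, moving = X
        except (TypeError, ValueError) as exc:
            raise TypeError("X must be a (fixed, moving) pair of Volume3D") from exc
        if not isinstance(fixed, Volume3D) or not isinstance(moving, Volume3D):
            raise TypeError("X must be a (fixed, moving) pair of Volume3D")
        if not isinstance(y, LandmarkPairSet):
            raise TypeError("y must be a LandmarkPairSet")
        cfg = self._config()

        t_init = initialize(y)
        center = y.fixed_points.mean(axis=0)
        p = transform_to_params(t_init, center)

        # unit rotation step ~ unit translation step in physical distance
        half_diag = 0.5 * float(np.linalg.norm(np.array(fixed.size) * fixed.spacing))
        scales = np.array([1.0 / half_diag] * 3 + [1.0] * 3)

        traces: list[OptimizationTrace] = []
        objective_fine = None
        for lvl in range(cfg.levels):
            shrink = cfg.shrink_factors[lvl]
            sigma = cfg.smoothing_sigmas_mm[lvl]
            f_l = pyramid_level(fixed, shrink, sigma)
            m_l = pyramid_level(moving, shrink, sigma)
            mcfg = MetricConfig(bins=cfg.metric.bins,
                                sampling_fraction=cfg.metric.sampling_fraction,
                                seed=cfg.seed + lvl, min_samples=cfg.metric.min_samples)
            try:
                mi = MIObjective(f_l, m_l, mcfg,
                                 overlap_transform=params_to_transform(p, center))
            except NoOverlapError as exc:
                raise RegistrationError(
                    "no fixed/moving overlap at the initialized transform; "
                    "check the initialization landmarks") from exc

            def obj(params, _mi=mi):
                try:
                    return _mi(params_to_transform(params, center))
                except NoOverlapError:
                    return float("nan")

            if lvl == 0 and not np.isfinite(obj(p)):
                raise RegistrationError(
                    "no fixed/moving overlap at the initialized transform; "
                    "check the initialization landmarks")
            ocfg = OptimizerConfig(
                learning_rate=cfg.optimizer.learning_rate,
                max_iterations=cfg.optimizer.max_iterations,
                convergence_min=cfg.optimizer.convergence_min,
                convergence_window=cfg.optimizer.convergence_window,
                fd_step_rotation=cfg.optimizer.fd_step_rotation,
                fd_step_translation=cfg.optimizer.fd_step_translation,
                parameter_scales=scales)
            p, trace = ascend(obj, p, ocfg)
            traces.append(trace)
            objective_fine = obj

        # refinement must never certify a worse solution than the
        # landmark start: compare on the finest-level objective
        p_init = transform_to_params(t_init, center)
        f_init = objective_fine(p_init)
        f_final = objective_fine(p)
        if not np.isfinite(f_final) or (np.isfinite(f_init) and f_init > f_final):
            p, f_final = p_init, f_init

        self.transform_ = params_to_transform(p, center)
        self.initial_transform_ = t_init
        self.traces_ = traces
        self.converged_ = traces[-1].stop_reason == "converged"
        self.metric_initial_ = float(f_init)
        self.metric_final_ = float(f_final)
        self.result_ = RegistrationResult(
            transform=self.transform_, initial_transform=t_init, traces=traces,
            converged=self.converged_, metric_initial=self.metric_initial_,
            metric_final=self.metric_final_)
        return self

    def predict(self, P) -> np.ndarray:
        """Map fixed-space physical points (N, 3) into moving space."""
        if not hasattr(self, "transform_"):
            raise RuntimeError("RigidRegistration is not fitted")
        return self.transform_(np.asarray(P, dtype=float))


def register(fixed: Volume3D, moving: Volume3D, pairs: LandmarkPairSet,
             cfg: RegistrationConfig | None = None) -> RegistrationResult:
    """Functional wrapper over :class:`RigidRegistration`."""
    est = RigidRegistration() if cfg is None else RigidRegistration.from_config(cfg)
    est.fit((fixed, moving), pairs)
    return est.result_
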