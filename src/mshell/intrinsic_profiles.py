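"""Intrinsic configurations: the cell-shape-change programs driving
invagination, and analytic test configurations.

An intrinsic configuration prescribes, along undeformed arclength, the
locally stress-free stretches (f_s0, f_phi0) and curvatures
(kappa_s0, kappa_phi0) encoding cell shape changes, plus the thickness
parameter t = eps*h.  It is generally incompatible (not embeddable), so
the equilibrium shape carries residual stress.

The invagination scenario mimics the observed cell-shape program of a
spherical Volvox embryo: a bend region [s0 - w, s0] of wedge-shaped cells
with large negative intrinsic meridional curvature kappa_b, a posterior
region (s < s0) of meridionally contracted cells with intrinsic stretch
f_p < 1, and an unchanged anterior (kappa_a, f_a).  Step discontinuities
are regularized by logistic transitions of width delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ScenarioParams",
    "IntrinsicConfig",
    "volvox_intrinsic",
    "compatible_sphere_intrinsic",
    "eta_field",
    "read_profile_csv",
]

MODELS = ("large_bending", "classical")


@dataclass(frozen=True)
class ScenarioParams:
    """Parameters of the piecewise intrinsic profiles (units of R and 1/R).

    kappa_p/kappa_b/kappa_a: intrinsic meridional curvature in the
    posterior, bend and anterior regions; f_p/f_a: intrinsic meridional
    stretch in posterior/anterior; s0 and w: position and width of the
    bend region [s0 - w, s0]; eps_h: thickness parameter t; delta:
    step-smoothing width.
    """

    kappa_p: float = 1.0
    kappa_b: float = -2.0
    kappa_a: float = 1.0
    f_p: float = 0.8
    f_a: float = 1.0
    s0: float = 1.5
    w: float = 0.2
    eps_h: float = 0.15
    delta: float = 0.05
    model: str = "large_bending"
    n_grid: int = 401

    def __post_init__(self):
        if self.w <= 0:
            raise ValueError("bend-region width w must be positive")
        if not 0.0 < self.s0 <= np.pi:
            raise ValueError("bend-region position s0 must lie in (0, pi]")
        if self.s0 - self.w <= 0.0:
            raise ValueError("bend region [s0 - w, s0] must lie inside (0, pi)")
        if self.eps_h <= 0 or self.delta <= 0:
            raise ValueError("eps_h and delta must be positive")
        if self.f_p <= 0 or self.f_a <= 0:
            raise ValueError("intrinsic stretches must be positive")
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}")

    def with_k(self, k: float) -> "ScenarioParams":
        """Copy with the continuation parameter k = -kappa_b applied."""
        return replace(self, kappa_b=-k)


@dataclass
class IntrinsicConfig:
    """Intrinsic stretches/curvatures sampled on an arclength grid."""

    s: np.ndarray
    fs0: np.ndarray
    fphi0: np.ndarray
    kappa_s0: np.ndarray
    kappa_phi0: np.ndarray
    t: float

    def __post_init__(self):
        if np.any(self.fs0 <= 0) or np.any(self.fphi0 <= 0):
            raise ValueError("intrinsic stretches must be positive everywhere")

    @property
    def g0(self) -> np.ndarray:
        """Intrinsic areal stretch of the midsurface."""
        return self.fs0 * self.fphi0

    @property
    def eta(self) -> np.ndarray:
        """Pointwise large-bending parameter kappa_s0 * t / (2 g0)."""
        return self.kappa_s0 * self.t / (2.0 * self.g0)

    @property
    def max_abs_eta(self) -> float:
        return float(np.max(np.abs(self.eta)))


def _steps(s, values, positions, delta):
    """Piecewise-constant profile with logistic transitions.

    values = [v0, v1, ..., vk] on regions separated by `positions`
    (ascending).  Each step is smoothed over a transition of width
    ~delta (logistic scale delta/4, so the maximal slope is
    amplitude/delta and the 10-90% rise occupies ~0.55 delta).
    """
    out = np.full_like(s, float(values[0]))
    for v_lo, v_hi, pos in zip(values[:-1], values[1:], positions):
        out = out + (v_hi - v_lo) * expit(4.0 * (s - pos) / delta)
    return out


def volvox_intrinsic(params: ScenarioParams, s: np.ndarray | None = None) -> IntrinsicConfig:
    """Invagination scenario: piecewise intrinsic profiles, regularized.

    kappa_s0 steps kappa_p -> kappa_b -> kappa_a at s0 - w and s0;
    f_s0 steps f_p -> f_a at s0; f_phi0 = 1; kappa_phi0 steps
    kappa_p -> kappa_a at s0 (the bend amplification applies to the
    meridional curvature only).
    """
    if s is None:
        s = np.linspace(0.0, np.pi, params.n_grid)
    d = params.delta
    kappa_s0 = _steps(
        s, [params.kappa_p, params.kappa_b, params.kappa_a], [params.s0 - params.w, params.s0], d
    )
    kappa_phi0 = _steps(s, [params.kappa_p, params.kappa_a], [params.s0], d)
    fs0 = _steps(s, [params.f_p, params.f_a], [params.s0], d)
    fphi0 = np.ones_like(s)
    return IntrinsicConfig(
        s=s, fs0=fs0, fphi0=fphi0, kappa_s0=kappa_s0, kappa_phi0=kappa_phi0, t=params.eps_h
    )


def compatible_sphere_intrinsic(
    f: float, s: np.ndarray | None = None, t: float = 0.15, n_grid: int = 401
) -> IntrinsicConfig:
    """Intrinsically compatible sphere of radius f*R.

    Uniform stretches f and curvatures 1/(f R): this configuration is
    embeddable, so the equilibrium is the stress-free sphere of radius
    f*R with (near-)zero energy.
    """
    if f <= 0:
        raise ValueError("stretch f must be positive")
    if s is None:
        s = np.linspace(0.0, np.pi, n_grid)
    one = np.ones_like(s)
    return IntrinsicConfig(
        s=s, fs0=f * one, fphi0=f * one, kappa_s0=one / f, kappa_phi0=one / f, t=t
    )


def eta_field(config: IntrinsicConfig) -> np.ndarray:
    """Pointwise large-bending parameter; depends on intrinsic data only."""
    return config.eta


def read_profile_csv(path, t: float) -> IntrinsicConfig:
    """User-supplied intrinsic profiles: CSV columns s,fs0,fphi0,kappa_s0,kappa_phi0."""
    df = pd.read_csv(path, float_precision="round_trip")
    cols = ["s", "fs0", "fphi0", "kappa_s0", "kappa_phi0"]
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV missing columns: {sorted(missing)}")
    return IntrinsicConfig(*(df[c].to_numpy() for c in cols), t=t)
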