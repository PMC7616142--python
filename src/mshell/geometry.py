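"""Axisymmetric midsurface geometry and through-thickness closed forms.

Shapes live on a uniform grid of *undeformed* arclength s in [0, pi*R]
(lengths in units of the reference radius R).  A closed axisymmetric
surface is described by the tangent angle psi(s) and the meridional
stretch f_s(s) = d s_tilde / d s; cylindrical coordinates follow by
quadrature, and the meridional and azimuthal curvatures by

    kappa_s = psi' / f_s,       kappa_phi = sin(psi) / r,

with the removable pole singularity kappa_phi -> kappa_s at r = 0.

The through-thickness functions encode the leading-order incompressible
response across the shell: the intrinsic transverse profile Z0(zeta), the
surface offsets h+/h-, and the first-order correction Z1 to the transverse
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import ConstrictionLimitError

__all__ = [
    "MidsurfaceShape",
    "ThroughThickness",
    "undeformed_sphere",
    "shape_from_tangent_fields",
    "z0_profile",
    "surface_offsets",
    "z1_correction",
    "diff_matrix",
    "simpson_weights",
]

SHAPE_COLUMNS = ["s", "r", "z", "psi", "stretch_s", "kappa_s", "kappa_phi"]


@dataclass
class MidsurfaceShape:
    """Axisymmetric midsurface fields on an undeformed-arclength grid.

    All lengths in units of R; curvatures in 1/R; psi in radians.
    ``stretch_s`` is the meridional stretch (identically 1 for an
    undeformed shape).
    """

    s: np.ndarray
    r: np.ndarray
    z: np.ndarray
    psi: np.ndarray
    stretch_s: np.ndarray
    kappa_s: np.ndarray
    kappa_phi: np.ndarray
    closure_residual: float = 0.0

    @property
    def n(self) -> int:
        return self.s.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s": self.s,
                "r": self.r,
                "z": self.z,
                "psi": self.psi,
                "stretch_s": self.stretch_s,
                "kappa_s": self.kappa_s,
                "kappa_phi": self.kappa_phi,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MidsurfaceShape":
        # round_trip parser: the fast default can be off by one ulp
        df = pd.read_csv(path, float_precision="round_trip")
        missing = set(SHAPE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"shape CSV missing columns: {sorted(missing)}")
        return cls(*(df[c].to_numpy() for c in SHAPE_COLUMNS))


@dataclass
class ThroughThickness:
    """Leading-order transverse solution across the shell thickness.

    ``Z0`` is the intrinsic transverse profile, ``Z_of_0``/``S_of_0`` the
    leading-order normal/parallel displacements (Kirchhoff result:
    Z_(0) = Z0 and S_(0) = 0), ``p0`` the leading-order Lagrange
    multiplier (identically 1), ``h_plus``/``h_minus`` the surface
    offsets with h_plus + h_minus = H0.
    """

    lambda_s0: float
    zeta_grid: np.ndarray
    Z0: np.ndarray
    Z1: np.ndarray | None = None
    h_plus: float | None = None
    h_minus: float | None = None
    H0: float | None = None
    p0: np.ndarray | None = None
    Z_of_0: np.ndarray | None = None
    S_of_0: np.ndarray | None = None
    conservation_residual: float | None = None


@lru_cache(maxsize=32)
def _diff_matrix_cached(n: int, ds: float) -> np.ndarray:
    """Dense second-order finite-difference matrix on a uniform grid."""
    D = np.zeros((n, n))
    for i in range(1, n - 1):
        D[i, i - 1] = -0.5 / ds
        D[i, i + 1] = 0.5 / ds
    D[0, 0], D[0, 1], D[0, 2] = -1.5 / ds, 2.0 / ds, -0.5 / ds
    D[-1, -1], D[-1, -2], D[-1, -3] = 1.5 / ds, -2.0 / ds, 0.5 / ds
    return D


def diff_matrix(s: np.ndarray) -> np.ndarray:
    ds = s[1] - s[0]
    if not np.allclose(np.diff(s), ds):
        raise ValueError("grid must be uniform")
    return _diff_matrix_cached(s.size, float(ds))


@lru_cache(maxsize=32)
def _simpson_weights_cached(n: int, ds: float) -> np.ndarray:
    w = np.ones(n)
    if n >= 3 and n % 2 == 1:
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        w *= ds / 3.0
    else:  # even number of nodes: trapezoid (solver enforces odd n)
        w *= ds
        w[0] = w[-1] = 0.5 * ds
    return w


def simpson_weights(s: np.ndarray) -> np.ndarray:
    """Composite-Simpson quadrature weights (odd node count required for
    the Simpson rule proper; falls back to trapezoid otherwise)."""
    ds = s[1] - s[0]
    return _simpson_weights_cached(s.size, float(ds))


def undeformed_sphere(radius: float = 1.0, n_grid: int = 401) -> MidsurfaceShape:
    """Unit-stretch sphere of given radius: the pre-invagination embryo.

    s in [0, pi*R]; the posterior pole sits at s = 0 (z = -R), the
    anterior pole at s = pi*R (z = +R); both curvatures equal 1/R
    (outward normal, sphere curvatures positive).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_grid < 50:
        raise ValueError("n_grid must be at least 50")
    s = np.linspace(0.0, np.pi * radius, n_grid)
    one = np.ones(n_grid)
    return MidsurfaceShape(
        s=s,
        r=radius * np.sin(s / radius),
        z=-radius * np.cos(s / radius),
        psi=s / radius,
        stretch_s=one,
        kappa_s=one / radius,
        kappa_phi=one / radius,
    )


def shape_from_tangent_fields(
    psi: np.ndarray, stretch_s: np.ndarray, reference: MidsurfaceShape
) -> MidsurfaceShape:
    """Reconstruct a deformed midsurface from (psi, f_s) on the reference grid.

    Cylindrical coordinates by trapezoid quadrature of r' = f_s cos(psi),
    z' = f_s sin(psi); the axial gauge pins z at the anterior pole
    (s = pi*R) to its reference value, so the posterior-pole displacement
    is read directly at s = 0.  Closure (r returning to 0 at the anterior
    pole) is the solver's constraint; here the residual is only reported
    on the returned shape.
    """
    s = reference.s
    if psi.shape != s.shape or stretch_s.shape != s.shape:
        raise ValueError("psi and stretch_s must be sampled on the reference grid")
    if np.any(stretch_s <= 0):
        raise ValueError("stretch_s must be positive")
    u = stretch_s * np.cos(psi)
    v = stretch_s * np.sin(psi)
    r = cumulative_trapezoid(u, s, initial=0.0)
    z_raw = cumulative_trapezoid(v, s, initial=0.0)
    z = z_raw + (reference.z[-1] - z_raw[-1])  # anterior-pole gauge
    closure = float(r[-1])

    D = diff_matrix(s)
    kappa_s = (D @ psi) / stretch_s
    kappa_phi = np.empty_like(kappa_s)
    kappa_phi[1:-1] = np.sin(psi[1:-1]) / r[1:-1]
    kappa_phi[0] = kappa_s[0]
    kappa_phi[-1] = kappa_s[-1]
    return MidsurfaceShape(
        s=s,
        r=r,
        z=z,
        psi=psi.copy(),
        stretch_s=stretch_s.copy(),
        kappa_s=kappa_s,
        kappa_phi=kappa_phi,
        closure_residual=closure,
    )


def z0_profile(zeta, lambda_s0: float):
    """Intrinsic transverse profile Z0(zeta) from leading-order intrinsic
    volume conservation: (1 - lambda_s0 Z0) dZ0/dzeta = 1, Z0(0) = 0.

    Closed form Z0 = (1 - sqrt(1 - 2 lambda_s0 zeta)) / lambda_s0; the
    analytic small-lambda limit zeta (1 + lambda_s0 zeta / 2) is used for
    |lambda_s0| < 1e-8.
    """
    zeta = np.asarray(zeta, dtype=float)
    if abs(lambda_s0) < 1e-8:
        return zeta * (1.0 + 0.5 * lambda_s0 * zeta)
    arg = 1.0 - 2.0 * lambda_s0 * zeta
    if np.any(arg <= 0.0):
        raise ConstrictionLimitError(
            "transverse coordinate beyond the geometric singularity "
            "(1 - 2 lambda_s0 zeta <= 0)"
        )
    return (1.0 - np.sqrt(arg)) / lambda_s0


def surface_offsets(H0: float, lambda_s0: float) -> tuple[float, float]:
    """Shell-surface offsets h+ and h- with h+ + h- = H0 exactly.

    h_pm = (H0/2)(1 -/+ lambda_s0 H0 / 4): the surface on the side of the
    intrinsic curvature sits closer to the midsurface.
    """
    if abs(lambda_s0) * H0 / 4.0 >= 1.0:
        raise ConstrictionLimitError("|lambda_s0| * H0 / 4 must be < 1")
    h_plus = 0.5 * H0 * (1.0 - lambda_s0 * H0 / 4.0)
    h_minus = 0.5 * H0 * (1.0 + lambda_s0 * H0 / 4.0)
    return h_plus, h_minus


def z1_correction(Z0, strains, lambda_s0: float):
    """First-order transverse correction Z1 from O(eps) incompressibility.

    ``strains`` is a tuple (E_s, E_phi, L_s, L_phi) of scalars or arrays
    broadcastable against Z0.  The closed form is verified against the
    reconstructed O(eps) incompressibility relation by the symbolic
    oracle (:func:`mshell.asymptotics.z1_residual_check`).
    """
    Z0 = np.asarray(Z0, dtype=float)
    Es, Ephi, Ls, Lphi = strains
    denom = 1.0 - lambda_s0 * Z0
    if np.any(denom <= 0.0):
        raise ConstrictionLimitError("1 - lambda_s0 Z0 must stay positive")
    num = (
        6.0 * (Es + Ephi)
        - 3.0 * Z0 * (Ls + Lphi + lambda_s0 * (Es + Ephi))
        + 2.0 * lambda_s0 * Lphi * Z0**2
    )
    return -Z0 * num / (6.0 * denom)
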