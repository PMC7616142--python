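"""Shell strain measures and the two energy densities.

Strains are relative deviations of the deformed from the intrinsic
geometry.  The implementation works throughout in *physical* strains with
the asymptotic bookkeeping parameter absorbed: writing t = eps*h for the
thickness and e = eps*E for the shell strains, the large-bending energy
density per unit undeformed midsurface area is (material constant C = 1)

  e_hat = (1/2) { t [ab_ss e_s^2 + 2 ab_sp e_s e_p + a_pp e_p^2]
                + 2 t^2 [bb_ss e_s K_s + bb_sp e_s K_p
                         + b_ps e_p K_s + b_pp e_p K_p]
                + t^3 [g_ss K_s^2 + 2 g_sp K_s K_p + g_pp K_p^2] },

with the moduli of :mod:`mshell.coefficients` evaluated at the pointwise
eta, and the alternative curvature strains

  K_s = (f~_s k~_s - f_s0 k_s0) / (f_s0^2 f_phi0),
  K_p = (f~_p k~_p - f_phi0 k_p0) / (f_s0 f_phi0^2),

which vanish for pure stretching.  The classical (eta -> 0) density is
  e0_hat = 2 [ t (e_s^2 + e_s e_p + e_p^2) + (t^3/12)(K_s^2 + K_s K_p + K_p^2) ].
Since eps^3 h E^2 = (eps h)(eps E)^2, eps^3 h^2 E L = (eps h)^2 (eps E) L
and eps^3 h^3 L^2 = (eps h)^3 L^2, this physical form is identical,
symbol by symbol, to the density written in the bookkeeping variables
(h, E, L; a unit test verifies the mapping).

Energies are reported in units of C R^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coefficients import CoefficientSet, coefficient_set, k_of_eta
from .geometry import MidsurfaceShape, simpson_weights
from .intrinsic_profiles import IntrinsicConfig

__all__ = [
    "StrainField",
    "EnergyBreakdown",
    "shell_strains",
    "energy_density",
    "total_energy",
    "energy_excess",
]


@dataclass
class StrainField:
    """Per-point shell strains and both curvature-strain families.

    es/ephi are the physical shell strains (eps absorbed); Ks/Kphi the
    alternative curvature strains (preferred: they vanish for pure
    stretching); Ls/Lphi the raw curvature differences, retained for
    diagnostics only (the energy uses K).  eta is the pointwise
    large-bending parameter of the intrinsic data.
    """

    s: np.ndarray
    es: np.ndarray
    ephi: np.ndarray
    Ks: np.ndarray
    Kphi: np.ndarray
    Ls: np.ndarray
    Lphi: np.ndarray
    eta: np.ndarray


@dataclass
class EnergyBreakdown:
    """Stretch/couple/bend split of the energy density (units C*R), with
    integrated totals (units C*R^3) when a measure is attached."""

    s: np.ndarray
    stretch: np.ndarray
    couple: np.ndarray
    bend: np.ndarray
    total_stretch: float | None = None
    total_couple: float | None = None
    total_bend: float | None = None
    total: float | None = None

    @property
    def density_total(self) -> np.ndarray:
        return self.stretch + self.couple + self.bend

    def to_frame(self, strains: StrainField | None = None) -> pd.DataFrame:
        data = {}
        if strains is not None:
            data.update(
                s=strains.s, es=strains.es, ephi=strains.ephi,
                Ks=strains.Ks, Kphi=strains.Kphi, eta=strains.eta,
            )
        else:
            data["s"] = self.s
        data.update(
            e_stretch=self.stretch, e_couple=self.couple,
            e_bend=self.bend, e_total=self.density_total,
        )
        return pd.DataFrame(data)


def shell_strains(deformed: MidsurfaceShape, intrinsic: IntrinsicConfig) -> StrainField:
    """Strain measures of a deformed shape relative to intrinsic data.

    The azimuthal stretch f~_phi = r~/r is evaluated at the poles by its
    regular limit stretch_s * cos(psi~)/cos(psi_ref) (L'Hopital along the
    generator); the azimuthal curvature carried by ``deformed`` already
    contains the pole limit kappa_phi -> kappa_s.
    """
    s = intrinsic.s
    if deformed.s.shape != s.shape or not np.allclose(deformed.s, s):
        raise ValueError("deformed shape and intrinsic config use different grids")
    fs0, fphi0 = intrinsic.fs0, intrinsic.fphi0
    ks0, kp0 = intrinsic.kappa_s0, intrinsic.kappa_phi0

    f_s = deformed.stretch_s
    # reference radius is sin(s) for the unit sphere generator; recover it
    # from the grid rather than assuming: r_ref = sin(s) in units of R.
    r_ref = np.sin(s)
    fphi = np.empty_like(f_s)
    fphi[1:-1] = deformed.r[1:-1] / r_ref[1:-1]
    fphi[0] = f_s[0] * np.cos(deformed.psi[0]) / 1.0
    fphi[-1] = f_s[-1] * np.cos(deformed.psi[-1]) / -1.0

    es = f_s / fs0 - 1.0
    ephi = fphi / fphi0 - 1.0
    Ks = (f_s * deformed.kappa_s - fs0 * ks0) / (fs0**2 * fphi0)
    Kphi = (fphi * deformed.kappa_phi - fphi0 * kp0) / (fs0 * fphi0**2)
    g0 = intrinsic.g0
    Ls = (deformed.kappa_s - ks0) / g0
    Lphi = (deformed.kappa_phi - kp0) / g0
    return StrainField(s=s, es=es, ephi=ephi, Ks=Ks, Kphi=Kphi, Ls=Ls, Lphi=Lphi,
                       eta=intrinsic.eta)


def _coeffs_for(strains: StrainField, model: str) -> CoefficientSet:
    if model == "classical":
        return coefficient_set(np.zeros_like(strains.eta))
    if model != "large_bending":
        raise ValueError("model must be 'large_bending' or 'classical'")
    return coefficient_set(strains.eta)


def energy_density(strains: StrainField, t: float, model: str = "large_bending") -> EnergyBreakdown:
    """Pointwise stretch/couple/bend densities (energy per undeformed area).

    model='large_bending' uses the eta-dependent moduli; model='classical'
    the eta -> 0 limit (no stretch-curvature coupling).
    """
    c = _coeffs_for(strains, model)
    es, ep, Ks, Kp = strains.es, strains.ephi, strains.Ks, strains.Kphi
    stretch = 0.5 * t * (
        c.alpha_bar_ss * es**2 + (c.alpha_bar_sphi + c.alpha_bar_phis) * es * ep
        + c.alpha_phiphi * ep**2
    )
    couple = t**2 * (
        c.beta_bar_ss * es * Ks + c.beta_bar_sphi * es * Kp
        + c.beta_phis * ep * Ks + c.beta_phiphi * ep * Kp
    )
    bend = 0.5 * t**3 * (
        c.gamma_ss * Ks**2 + (c.gamma_sphi + c.gamma_phis) * Ks * Kp
        + c.gamma_phiphi * Kp**2
    )
    return EnergyBreakdown(s=strains.s, stretch=stretch, couple=couple, bend=bend)


def integrate_density(density: np.ndarray, s: np.ndarray, r_ref: np.ndarray) -> float:
    """2 pi * integral of density * r over the undeformed generator."""
    return float(2.0 * np.pi * np.sum(simpson_weights(s) * r_ref * density))


def total_energy(
    deformed: MidsurfaceShape,
    intrinsic: IntrinsicConfig,
    model: str = "large_bending",
    return_breakdown: bool = False,
):
    """Total elastic energy 2 pi * int e_hat(s) r(s) ds (undeformed measure)."""
    strains = shell_strains(deformed, intrinsic)
    bd = energy_density(strains, intrinsic.t, model)
    s = intrinsic.s
    r_ref = np.sin(s)
    bd.total_stretch = integrate_density(bd.stretch, s, r_ref)
    bd.total_couple = integrate_density(bd.couple, s, r_ref)
    bd.total_bend = integrate_density(bd.bend, s, r_ref)
    bd.total = bd.total_stretch + bd.total_couple + bd.total_bend
    if return_breakdown:
        return bd.total, bd, strains
    return bd.total


def energy_excess(strains: StrainField, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form excess of the large-bending over the classical split.

    stretch_excess = (t/2) eta^2 (2 - eta^2)/(1 - eta^2)^2 (2 e_s + e_phi)^2
    (nonnegative, zero iff e_phi = -2 e_s);
    bend_excess = (t^3/2) eta^2 (3 - 2 eta^2)/(36 (1 - eta^2)^2)
                  * (3 K_s + K_phi)(k(eta) K_s + K_phi),
    negative exactly when K_s K_phi < 0 and k(eta)|K_s| < |K_phi| < 3|K_s|.
    Each equals the direct difference of the corresponding breakdown terms.
    """
    eta = strains.eta
    q = (1.0 - eta**2) ** 2
    stretch_excess = (
        0.5 * t * eta**2 * (2.0 - eta**2) / q * (2.0 * strains.es + strains.ephi) ** 2
    )
    k = k_of_eta(eta)
    bend_excess = (
        0.5 * t**3 * eta**2 * (3.0 - 2.0 * eta**2) / (36.0 * q)
        * (3.0 * strains.Ks + strains.Kphi) * (k * strains.Ks + strains.Kphi)
    )
    return stretch_excess, bend_excess
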