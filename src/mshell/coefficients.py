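"""Moduli of the quadratic shell-energy form as functions of the
large-bending parameter eta.

The effective two-dimensional energy density of an incompressible
neo-Hookean shell with a large intrinsic meridional curvature is a
quadratic form in the shell strains (e_s, e_phi) and curvature strains
(K_s, K_phi).  Its eleven raw moduli (alpha_*, beta_*, gamma_*), the four
combined moduli (alpha_bar_*, beta_bar_*) that appear when the energy is
written in the alternative curvature strains, and the bending-excess
multiplier k(eta) are all functions of

    eta = kappa_s0 * t / (2 * g0),        g0 = f_s0 * f_phi0,

with t the shell thickness (in units of the reference radius R).  All
moduli are finite on |eta| < 1 and diverge like (1 - |eta|)^-2 in the
constriction limit |eta| -> 1 (fully wedge-shaped cells).

Closed forms involve atanh(eta)/eta^n and suffer catastrophic cancellation
as eta -> 0; evaluation switches to frozen Taylor series (validated at
runtime against the symbolic oracle in :mod:`mshell.asymptotics`) below a
small threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import ConstrictionLimitError

__all__ = [
    "CoefficientSet",
    "coefficient_set",
    "divergence_scaled_set",
    "k_of_eta",
    "classical_moduli",
    "SERIES_SWITCH",
    "TAYLOR_TABLES",
]

#: |eta| below which the Taylor branch is used for atanh-bearing moduli.
SERIES_SWITCH = 0.05

#: |eta| below which the Taylor branch is used for k(eta), whose closed
#: form cancels through O(eta^5).
K_SERIES_SWITCH = 0.15

#: Guard band: |eta| beyond 1 - ETA_GUARD raises ConstrictionLimitError.
ETA_GUARD = 1e-6

# Taylor coefficients about eta = 0 (powers 0, 1, 2, ...), generated by the
# symbolic oracle (mshell.asymptotics.series_oracle) and frozen here.  Only
# the moduli whose closed forms contain atanh(eta) cancellations need a
# series branch; the remainder are plain rational functions.
TAYLOR_TABLES = {
    "alpha_ss": [4, 0, 8 / 3, 0, 17 / 5, 0, 30 / 7, 0, 47 / 9, 0, 68 / 11, 0, 93 / 13],
    "alpha_sphi": [2, 0, 7 / 3, 0, 16 / 5, 0, 29 / 7, 0, 46 / 9, 0, 67 / 11, 0, 92 / 13],
    "beta_sphi": [0, -1 / 3, 0, -8 / 15, 0, -29 / 42, 0, -23 / 27, 0, -67 / 66, 0, -46 / 39],
    "beta_phis": [0, -5 / 6, 0, -7 / 5, 0, -27 / 14, 0, -22 / 9, 0, -65 / 22, 0, -45 / 13],
    "gamma_ss": [1 / 3, 0, 13 / 20, 0, 13 / 14, 0, 43 / 36, 0, 16 / 11, 0, 89 / 52, 0, 59 / 30],
    "gamma_sphi": [1 / 6, 0, 7 / 30, 0, 9 / 28, 0, 11 / 27, 0, 65 / 132, 0, 15 / 26, 0, 119 / 180],
    "beta_bar_ss": [0, -5 / 3, 0, -14 / 5, 0, -27 / 7, 0, -44 / 9, 0, -65 / 11, 0, -90 / 13],
    "k": [13 / 5, 0, 26 / 105, 0, 4 / 35, 0, 184 / 3465, 0, 3104 / 135135, 0, 3184 / 405405, 0, 8464 / 20675655],
}


@dataclass(frozen=True)
class CoefficientSet:
    """All eta-dependent moduli of the quadratic energy form.

    Fields may be scalars or numpy arrays (vectorized over eta).  The
    symmetric pairs satisfy ``alpha_sphi == alpha_phis``,
    ``gamma_sphi == gamma_phis`` and ``alpha_bar_sphi == alpha_bar_phis``
    exactly.
    """

    eta: np.ndarray
    alpha_ss: np.ndarray
    alpha_sphi: np.ndarray
    alpha_phis: np.ndarray
    alpha_phiphi: np.ndarray
    beta_ss: np.ndarray
    beta_sphi: np.ndarray
    beta_phis: np.ndarray
    beta_phiphi: np.ndarray
    gamma_ss: np.ndarray
    gamma_sphi: np.ndarray
    gamma_phis: np.ndarray
    gamma_phiphi: np.ndarray
    alpha_bar_ss: np.ndarray
    alpha_bar_sphi: np.ndarray
    alpha_bar_phis: np.ndarray
    beta_bar_ss: np.ndarray
    beta_bar_sphi: np.ndarray

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def scaled_by(self, factor) -> "CoefficientSet":
        """Return a copy with every modulus (not eta) multiplied by factor."""
        d = self.as_dict()
        eta = d.pop("eta")
        return CoefficientSet(eta=eta, **{k: v * factor for k, v in d.items()})


def _check_eta(eta, bound=1.0 - ETA_GUARD):
    eta = np.asarray(eta, dtype=float)
    if np.any(np.abs(eta) > bound):
        raise ConstrictionLimitError(
            f"|eta| exceeds {bound}: the intrinsic state is at the constriction "
            "limit (wedge-shaped cells), where the shell-energy moduli diverge."
        )
    return eta


def _atanh(eta):
    # controlled evaluation approaching the logarithmic singularity
    return 0.5 * np.log((1.0 + eta) / (1.0 - eta))


def _two_branch(eta, closed, name):
    """Evaluate `closed` away from 0 and the frozen Taylor series near 0."""
    eta = np.asarray(eta, dtype=float)
    small = np.abs(eta) < (K_SERIES_SWITCH if name == "k" else SERIES_SWITCH)
    out = np.empty_like(eta)
    if np.any(~small):
        out[~small] = closed(eta[~small])
    if np.any(small):
        out[small] = np.polynomial.polynomial.polyval(
            eta[small], np.asarray(TAYLOR_TABLES[name])
        )
    return out


def coefficient_set(eta) -> CoefficientSet:
    """Evaluate all raw and combined moduli at eta (scalar or array).

    Raises :class:`ConstrictionLimitError` for |eta| > 1 - 1e-6.  Relative
    accuracy is ~1e-13 on both evaluation branches.
    """
    eta = _check_eta(eta)
    e2 = eta * eta
    q = (1.0 - e2) ** 2  # (1 - eta^2)^2

    alpha_ss = _two_branch(
        eta, lambda n: (n**4 - 2 * n**2 + 2) / (1 - n**2) ** 2 + 2 * _atanh(n) / n, "alpha_ss"
    )
    alpha_sphi = _two_branch(
        eta, lambda n: 1 / (1 - n**2) ** 2 + _atanh(n) / n, "alpha_sphi"
    )
    alpha_phiphi = (3 * e2 * e2 - 6 * e2 + 4) / q
    beta_ss = -eta * (2 - e2) / (2 * q)
    beta_sphi = _two_branch(
        eta,
        lambda n: (n**6 + 4 * n**4 - 11 * n**2 + 3) / (18 * n * (1 - n**2) ** 2)
        - _atanh(n) / (6 * n**2),
        "beta_sphi",
    )
    beta_phis = _two_branch(
        eta,
        lambda n: -1 / (2 * n * (1 - n**2) ** 2) + _atanh(n) / (2 * n**2),
        "beta_phis",
    )
    beta_phiphi = eta * (3 * e2 * e2 - 5 * e2 + 1) / (6 * q)
    gamma_ss = _two_branch(
        eta,
        lambda n: (n**4 - 2 * n**2 + 2) / (4 * n**2 * (1 - n**2) ** 2)
        - _atanh(n) / (2 * n**3),
        "gamma_ss",
    )
    gamma_sphi = _two_branch(
        eta,
        lambda n: (n**6 - 2 * n**4 + n**2 + 3) / (36 * n**2 * (1 - n**2) ** 2)
        - _atanh(n) / (12 * n**3),
        "gamma_sphi",
    )
    gamma_phiphi = (10 * e2 * e2 - 21 * e2 + 12) / (36 * q)

    alpha_bar_ss = 4.0 / q
    alpha_bar_sphi = 2.0 / q
    beta_bar_ss = _two_branch(
        eta,
        lambda n: -1 / (n * (1 - n**2) ** 2) + _atanh(n) / n**2,
        "beta_bar_ss",
    )
    beta_bar_sphi = -eta * (2 - e2) / (3 * q)

    return CoefficientSet(
        eta=eta,
        alpha_ss=alpha_ss,
        alpha_sphi=alpha_sphi,
        alpha_phis=alpha_sphi,
        alpha_phiphi=alpha_phiphi,
        beta_ss=beta_ss,
        beta_sphi=beta_sphi,
        beta_phis=beta_phis,
        beta_phiphi=beta_phiphi,
        gamma_ss=gamma_ss,
        gamma_sphi=gamma_sphi,
        gamma_phis=gamma_sphi,
        gamma_phiphi=gamma_phiphi,
        alpha_bar_ss=alpha_bar_ss,
        alpha_bar_sphi=alpha_bar_sphi,
        alpha_bar_phis=alpha_bar_sphi,
        beta_bar_ss=beta_bar_ss,
        beta_bar_sphi=beta_bar_sphi,
    )


def divergence_scaled_set(eta) -> CoefficientSet:
    """Moduli multiplied by (1 - |eta|)^2, their divergence rate.

    Each scaled modulus remains bounded as |eta| -> 1; e.g. the scaled
    alpha_bar_ss equals 4/(1 + |eta|)^2 -> 1.
    """
    eta = np.asarray(eta, dtype=float)
    if np.any(eta == 0.0) or np.any(np.abs(eta) >= 1.0):
        raise ConstrictionLimitError("divergence_scaled_set requires 0 < |eta| < 1")
    return coefficient_set(eta).scaled_by((1.0 - np.abs(eta)) ** 2)


def k_of_eta(eta):
    """The K_s multiplier in the factorized excess bending energy.

    The excess of the large-bending over the classical bending energy
    factorizes as proportional to (3 K_s + K_phi)(k(eta) K_s + K_phi);
    k increases from k(0) = 13/5 to k(+-1) = 3.  Defined on |eta| <= 1,
    endpoints by limit.
    """
    eta = np.asarray(eta, dtype=float)
    scalar = eta.ndim == 0
    eta = np.atleast_1d(eta)
    if np.any(np.abs(eta) > 1.0):
        raise ConstrictionLimitError("k(eta) is defined for |eta| <= 1 only")
    out = np.empty_like(eta)
    end = np.abs(eta) == 1.0
    out[end] = 3.0  # limit value: the atanh term is suppressed by (1-eta^2)^2

    def closed(n):
        return (
            -n * (4 * n**6 - 11 * n**4 + 10 * n**2 - 6)
            - 6 * (1 - n**2) ** 2 * _atanh(n)
        ) / (n**5 * (3 - 2 * n**2))

    inner = ~end
    if np.any(inner):
        out[inner] = _two_branch(eta[inner], closed, "k")
    return out[0] if scalar else out


def classical_moduli(t=None):
    """Elastic constants of the classical (eta -> 0) limit, computed from
    the moduli themselves.

    The classical stretching form t*(alpha_bar_ss e_s^2 + 2 alpha_bar_sphi
    e_s e_phi + alpha_phiphi e_phi^2)/2 is that of a Hookean shell with
    Poisson ratio nu = alpha_bar_sphi/alpha_bar_ss and Young's modulus
    E = alpha_bar_ss (1 - nu^2) (in units of the material constant C).

    Returns a dict with nu, youngs_modulus (units C), the stretching-
    modulus prefactor (units C*t) and bending-modulus prefactor (units
    C*t^3); if t is given the dimensional moduli are included too.
    """
    c0 = coefficient_set(0.0)
    nu = float(c0.alpha_bar_sphi / c0.alpha_bar_ss)
    youngs = float(c0.alpha_bar_ss) * (1.0 - nu**2)
    out = {
        "nu": nu,
        "youngs_modulus": youngs,
        "stretching_prefactor": float(c0.alpha_bar_ss),  # = E/(1-nu^2)
        "bending_prefactor": float(c0.gamma_ss),  # = E/(12(1-nu^2)) * 4
    }
    if t is not None:
        out["stretching_modulus"] = out["stretching_prefactor"] * t
        out["bending_modulus"] = out["bending_prefactor"] * t**3
    return out
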