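"""Equilibrium shapes by direct minimization of the discretized energy,
with pseudo-arclength continuation and fold detection.

The unknowns are the tangent angle psi(s) at interior nodes (endpoint
values pinned to 0 and pi) and the meridional stretch f_s(s) at all
nodes.  The shell must close: the radius reconstructed by quadrature of
r' = f_s cos(psi) has to return to zero at the anterior pole,

    g(psi, f_s) = int_0^pi f_s cos(psi) ds = 0,

which is enforced exactly by a Lagrange multiplier (augmented-Lagrangian
outer loop for globalization, Newton on the stationarity system for
machine-precision finish).  The energy and its analytic gradient are
assembled from the quadratic strain form of :mod:`mshell.strains_energy`
on a composite-Simpson quadrature weighted by the undeformed radius, so
the pole singularities are naturally suppressed.

Branches in the (k, d) plane -- k = -kappa_b the intrinsic bend-region
curvature, d the posterior-pole displacement -- are traced by
pseudo-arclength continuation of the stationarity system, which follows
the branch around saddle-node folds; folds are detected as sign changes
of dk along the branch and refined by a local quadratic fit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import minimize

from .coefficients import coefficient_set
from .errors import ConstrictionLimitError, ConvergenceError
from .geometry import (MidsurfaceShape, diff_matrix, shape_from_tangent_fields,
                       simpson_weights, undeformed_sphere)
from .intrinsic_profiles import IntrinsicConfig, ScenarioParams, volvox_intrinsic
from .strains_energy import EnergyBreakdown, StrainField, energy_density, \
    integrate_density, shell_strains

__all__ = [
    "EquilibriumSolution",
    "ContinuationBranch",
    "solve_equilibrium",
    "pole_displacement",
    "continue_branch",
    "critical_width",
    "DEFAULT_MARGIN",
]

logger = logging.getLogger("mshell")

#: Default constriction margin: large-bending solves are refused when
#: max|eta| > 1 - DEFAULT_MARGIN (asymptoticity is lost when 1 - |eta|
#: becomes comparable to the thinness parameter).
DEFAULT_MARGIN = 0.02


@dataclass
class EquilibriumSolution:
    shape: MidsurfaceShape
    strains: StrainField
    energy: EnergyBreakdown
    d: float
    model: str
    diagnostics: dict = field(default_factory=dict)
    _x: np.ndarray | None = None
    _lam: float = 0.0


@dataclass
class ContinuationBranch:
    """A traced (k, d) branch with fold and jump annotations."""

    k: np.ndarray
    d: np.ndarray
    energy_total: np.ndarray
    max_eta: np.ndarray
    fold_flag: np.ndarray
    folds: list
    jumps: list
    model: str
    params: ScenarioParams
    terminated_reason: str = "completed"

    @property
    def n_folds(self) -> int:
        return len(self.folds)


class Discretization:
    """Energy, closure and their analytic gradients on a fixed grid."""

    def __init__(self, intrinsic: IntrinsicConfig, model: str = "large_bending"):
        self.intrinsic = intrinsic
        self.model = model
        s = intrinsic.s
        self.s = s
        self.n = s.size
        self.ds = float(s[1] - s[0])
        self.t = intrinsic.t
        self.r_ref = np.sin(s)
        self.W = 2.0 * np.pi * simpson_weights(s) * self.r_ref
        self.wt = np.full(self.n, self.ds)  # trapezoid weights for closure
        self.wt[0] = self.wt[-1] = 0.5 * self.ds
        self.D = diff_matrix(s)
        self.fs0 = intrinsic.fs0
        self.fphi0 = intrinsic.fphi0
        self.ks0 = intrinsic.kappa_s0
        self.kp0 = intrinsic.kappa_phi0
        eta = intrinsic.eta if model == "large_bending" else np.zeros(self.n)
        self.c = coefficient_set(eta)
        # strain normalizers
        self._Ks_den = self.fs0**2 * self.fphi0
        self._Kp_den = self.fs0 * self.fphi0**2

    # -- packing ---------------------------------------------------------
    def pack(self, psi: np.ndarray, f: np.ndarray) -> np.ndarray:
        return np.concatenate([psi[1:-1], f])

    def unpack(self, x: np.ndarray):
        psi = np.empty(self.n)
        psi[0] = 0.0
        psi[-1] = np.pi
        psi[1:-1] = x[: self.n - 2]
        f = x[self.n - 2 :]
        return psi, f

    def identity_x(self) -> np.ndarray:
        return self.pack(self.s.copy(), np.ones(self.n))

    # -- strain evaluation ----------------------------------------------
    def _strain_arrays(self, psi, f):
        cos, sin = np.cos(psi), np.sin(psi)
        u = f * cos
        r = cumulative_trapezoid(u, self.s, initial=0.0)
        psip = self.D @ psi
        es = f / self.fs0 - 1.0
        ephi = np.empty(self.n)
        ephi[1:-1] = (r[1:-1] / self.r_ref[1:-1]) / self.fphi0[1:-1] - 1.0
        ephi[0] = f[0] * cos[0] / self.fphi0[0] - 1.0
        ephi[-1] = -f[-1] * cos[-1] / self.fphi0[-1] - 1.0
        Ks = (psip - self.fs0 * self.ks0) / self._Ks_den
        Kp = np.empty(self.n)
        Kp[1:-1] = (sin[1:-1] / self.r_ref[1:-1] - self.fphi0[1:-1] * self.kp0[1:-1]) \
            / self._Kp_den[1:-1]
        Kp[[0, -1]] = (psip[[0, -1]] - self.fphi0[[0, -1]] * self.kp0[[0, -1]]) \
            / self._Kp_den[[0, -1]]
        return cos, sin, u, r, psip, es, ephi, Ks, Kp

    def energy_grad(self, x: np.ndarray):
        """Total energy and its gradient with respect to x."""
        psi, f = self.unpack(x)
        cos, sin, u, r, psip, es, ep, Ks, Kp = self._strain_arrays(psi, f)
        c, t, W = self.c, self.t, self.W
        t2, t3 = t * t, t**3

        e_hat = 0.5 * (
            t * (c.alpha_bar_ss * es**2 + 2.0 * c.alpha_bar_sphi * es * ep
                 + c.alpha_phiphi * ep**2)
            + 2.0 * t2 * (c.beta_bar_ss * es * Ks + c.beta_bar_sphi * es * Kp
                          + c.beta_phis * ep * Ks + c.beta_phiphi * ep * Kp)
            + t3 * (c.gamma_ss * Ks**2 + 2.0 * c.gamma_sphi * Ks * Kp
                    + c.gamma_phiphi * Kp**2)
        )
        E = float(np.sum(W * e_hat))

        G_es = W * (t * (c.alpha_bar_ss * es + c.alpha_bar_sphi * ep)
                    + t2 * (c.beta_bar_ss * Ks + c.beta_bar_sphi * Kp))
        G_ep = W * (t * (c.alpha_bar_sphi * es + c.alpha_phiphi * ep)
                    + t2 * (c.beta_phis * Ks + c.beta_phiphi * Kp))
        G_Ks = W * (t2 * (c.beta_bar_ss * es + c.beta_phis * ep)
                    + t3 * (c.gamma_ss * Ks + c.gamma_sphi * Kp))
        G_Kp = W * (t2 * (c.beta_bar_sphi * es + c.beta_phiphi * ep)
                    + t3 * (c.gamma_sphi * Ks + c.gamma_phiphi * Kp))

        gf = G_es / self.fs0
        gpsi = self.D.T @ (G_Ks / self._Ks_den)
        gpsi[1:-1] += G_Kp[1:-1] * cos[1:-1] / (self.r_ref[1:-1] * self._Kp_den[1:-1])

        # adjoint of the cumulative trapezoid for the e_phi(r) dependence
        a = np.zeros(self.n)
        a[1:-1] = G_ep[1:-1] / (self.r_ref[1:-1] * self.fphi0[1:-1])
        csum = np.cumsum(a[::-1])[::-1]  # csum[j] = sum_{i >= j} a_i
        T = np.empty(self.n)
        T[:-1] = csum[1:]
        T[-1] = 0.0
        grad_u = self.ds * T + 0.5 * self.ds * a
        grad_u[0] = 0.5 * self.ds * T[0]
        gf += grad_u * cos
        gpsi += -grad_u * f * sin

        return E, np.concatenate([gpsi[1:-1], gf])

    def closure_grad(self, x: np.ndarray):
        psi, f = self.unpack(x)
        cos, sin = np.cos(psi), np.sin(psi)
        g = float(np.sum(self.wt * f * cos))
        gpsi = -self.wt * f * sin
        gf = self.wt * cos
        return g, np.concatenate([gpsi[1:-1], gf])

    # -- stationarity system --------------------------------------------
    def kkt_residual(self, y: np.ndarray) -> np.ndarray:
        """F(x, lam) = [grad E + lam grad g; g]."""
        x, lam = y[:-1], y[-1]
        _, gE = self.energy_grad(x)
        g, gg = self.closure_grad(x)
        return np.concatenate([gE + lam * gg, [g]])


def _newton_kkt(disc: Discretization, x, lam, tol=1e-11, maxiter=25, fd_step=1e-7):
    """Newton iteration on the stationarity system, dense FD Jacobian."""
    y = np.concatenate([x, [lam]])
    m = y.size
    F = disc.kkt_residual(y)
    best = np.max(np.abs(F))
    it = 0
    for it in range(maxiter):
        if best < tol:
            break
        J = np.empty((m, m))
        for j in range(m):
            h = fd_step * max(1.0, abs(y[j]))
            yp = y.copy()
            yp[j] += h
            J[:, j] = (disc.kkt_residual(yp) - F) / h
        try:
            lu = lu_factor(J)
            step = lu_solve(lu, -F)
        except Exception:
            break
        # damped update
        alpha = 1.0
        for _ in range(10):
            y_new = y + alpha * step
            F_new = disc.kkt_residual(y_new)
            if np.max(np.abs(F_new)) < best:
                y, F = y_new, F_new
                best = np.max(np.abs(F))
                break
            alpha *= 0.5
        else:
            break
    return y[:-1], float(y[-1]), best, it + 1


def _check_margin(intrinsic: IntrinsicConfig, model: str, margin: float):
    if model != "large_bending":
        return
    m = intrinsic.max_abs_eta
    if m > 1.0 - DEFAULT_MARGIN:
        if m > 1.0 - margin:
            raise ConstrictionLimitError(
                f"max|eta| = {m:.4f} exceeds 1 - margin ({1 - margin:.4f}): "
                "intrinsic data at the constriction limit"
            )
        warnings.warn(
            f"max|eta| = {m:.4f} is within {DEFAULT_MARGIN} of the constriction "
            "limit; the large-bending asymptotics are marginal there",
            stacklevel=3,
        )
    elif m > 1.0 - margin:
        raise ConstrictionLimitError(
            f"max|eta| = {m:.4f} exceeds 1 - margin ({1 - margin:.4f})"
        )


def _build_solution(disc: Discretization, x, lam, iters) -> EquilibriumSolution:
    psi, f = disc.unpack(x)
    reference = undeformed_sphere(n_grid=disc.n)
    shape = shape_from_tangent_fields(psi, f, reference)
    strains = shell_strains(shape, disc.intrinsic)
    bd = energy_density(strains, disc.t, disc.model)
    bd.total_stretch = integrate_density(bd.stretch, disc.s, disc.r_ref)
    bd.total_couple = integrate_density(bd.couple, disc.s, disc.r_ref)
    bd.total_bend = integrate_density(bd.bend, disc.s, disc.r_ref)
    bd.total = bd.total_stretch + bd.total_couple + bd.total_bend
    g, gg = disc.closure_grad(x)
    _, gE = disc.energy_grad(x)
    grad_norm = float(np.max(np.abs(gE + lam * gg)))
    sol = EquilibriumSolution(
        shape=shape,
        strains=strains,
        energy=bd,
        d=pole_displacement_shape(shape, reference),
        model=disc.model,
        diagnostics={
            "gradient_norm": grad_norm,
            "closure_residual": abs(g),
            "iterations": iters,
            "max_abs_eta": disc.intrinsic.max_abs_eta,
            "energy_total": bd.total,
            "lagrange_multiplier": lam,
        },
        _x=x,
        _lam=lam,
    )
    return sol


def solve_equilibrium(
    intrinsic: IntrinsicConfig,
    model: str = "large_bending",
    init=None,
    options: dict | None = None,
) -> EquilibriumSolution:
    """Minimize the discretized energy subject to the closure constraint.

    ``init`` may be a MidsurfaceShape, a previous EquilibriumSolution, or
    None (identity embedding).  Deterministic given the initial iterate.
    Options: margin (constriction refusal, default 0.02), gtol
    (stationarity tolerance, default 1e-9), maxiter (inner L-BFGS cap).
    """
    opt = {"margin": DEFAULT_MARGIN, "gtol": 1e-9, "maxiter": 4000,
           "newton_polish": True}
    opt.update(options or {})
    _check_margin(intrinsic, model, opt["margin"])
    disc = Discretization(intrinsic, model)

    if init is None:
        x = disc.identity_x()
        lam = 0.0
    elif isinstance(init, EquilibriumSolution):
        if init._x is not None and init._x.size == 2 * disc.n - 2:
            x, lam = init._x.copy(), init._lam
        else:
            x = disc.pack(init.shape.psi, init.shape.stretch_s)
            lam = init._lam
    elif isinstance(init, MidsurfaceShape):
        x = disc.pack(init.psi, init.stretch_s)
        lam = 0.0
    else:
        raise TypeError("init must be None, MidsurfaceShape or EquilibriumSolution")

    # augmented-Lagrangian globalization
    mu = 1.0
    total_iters = 0
    g_prev = np.inf
    for outer in range(25):
        def objective(z, lam=lam, mu=mu):
            E, gE = disc.energy_grad(z)
            g, gg = disc.closure_grad(z)
            return E + lam * g + mu * g * g, gE + (lam + 2.0 * mu * g) * gg

        res = minimize(objective, x, jac=True, method="L-BFGS-B",
                       options={"maxiter": opt["maxiter"], "ftol": 1e-16,
                                "gtol": 1e-9, "maxcor": 30})
        x = res.x
        total_iters += res.nit
        g, _ = disc.closure_grad(x)
        if abs(g) < 1e-10 and res.nit < opt["maxiter"]:
            break
        lam += 2.0 * mu * g
        if abs(g) > 0.25 * g_prev:
            mu = min(mu * 10.0, 1e8)
        g_prev = abs(g)

    if opt["newton_polish"]:
        x, lam, resid, nit = _newton_kkt(disc, x, lam)
        total_iters += nit

    sol = _build_solution(disc, x, lam, total_iters)
    if sol.diagnostics["gradient_norm"] > 100 * opt["gtol"] or \
            sol.diagnostics["closure_residual"] > 1e-8:
        raise ConvergenceError(
            f"equilibrium solve did not converge: gradient norm "
            f"{sol.diagnostics['gradient_norm']:.2e}, closure "
            f"{sol.diagnostics['closure_residual']:.2e}",
            last_iterate=sol,
            diagnostics=sol.diagnostics,
        )
    return sol


def pole_displacement_shape(shape: MidsurfaceShape, reference: MidsurfaceShape) -> float:
    """Posterior-pole displacement d = z~(0) - z(0) in the anterior-pole
    gauge; positive when the posterior pole moves toward the anterior
    (invagination)."""
    return float(shape.z[0] - reference.z[0])


def pole_displacement(solution: EquilibriumSolution, reference: MidsurfaceShape | None = None) -> float:
    if reference is None:
        reference = undeformed_sphere(n_grid=solution.shape.n)
    return pole_displacement_shape(solution.shape, reference)


def _branch_point(disc, x, lam, reference):
    psi, f = disc.unpack(x)
    shape = shape_from_tangent_fields(psi, f, reference)
    d = pole_displacement_shape(shape, reference)
    E, _ = disc.energy_grad(x)
    return d, E


def constriction_line(params: ScenarioParams) -> float:
    """The k = -kappa_b value at which the bend region reaches |eta| = 1,
    k = 2 g0 / t with g0 = f_p (azimuthal intrinsic stretch 1)."""
    return 2.0 * params.f_p / params.eps_h


def continue_branch(
    params: ScenarioParams,
    k_range: tuple[float, float] | None = None,
    model: str = "large_bending",
    n_grid: int = 201,
    ds0: float = 0.1,
    ds_max: float = 0.25,
    ds_min: float = 1e-4,
    max_steps: int = 600,
    d_max: float = 2.5,
    margin: float = DEFAULT_MARGIN,
    stop_at_fold: bool = False,
) -> ContinuationBranch:
    """Trace the equilibrium branch in k = -kappa_b by pseudo-arclength
    continuation.

    Each accepted point is a converged stationary point of the
    constrained energy.  Folds (saddle-node points) are detected as sign
    changes of dk along the branch and refined by a quadratic fit of
    k(arclength); for S-shaped branches the discontinuous jump in d under
    a natural upward sweep of k is annotated from the branch geometry.

    By default the sweep covers each model's admissible range up to the
    constriction line k = 2 g0/t of the bend region: the classical model
    (no constriction singularity) is swept to the line itself, while a
    large-bending branch terminates at the guard max|eta| > 1 - margin.
    """
    if k_range is None:
        k_range = (0.5, constriction_line(params))
    s = np.linspace(0.0, np.pi, n_grid)
    reference = undeformed_sphere(n_grid=n_grid)
    disc_cache: dict[float, Discretization] = {}

    def disc_at(k: float) -> Discretization:
        key = round(float(k), 12)
        if key not in disc_cache:
            if len(disc_cache) > 64:
                disc_cache.clear()
            disc_cache[key] = Discretization(
                volvox_intrinsic(params.with_k(k), s), model
            )
        return disc_cache[key]

    k0, k1 = k_range

    def max_eta_at(k):
        return volvox_intrinsic(params.with_k(k), s).max_abs_eta

    # first two points by natural continuation
    sol = solve_equilibrium(volvox_intrinsic(params.with_k(k0), s), model,
                            options={"margin": margin})
    m = sol._x.size
    wx = 1.0 / np.sqrt(m)  # grid-independent weighting of the state part

    ks, ds_, Es, etas, xs, lams = [k0], [sol.d], [sol.energy.total], \
        [max_eta_at(k0)], [sol._x], [sol._lam]

    dk_nat = min(0.1, 0.1 * (k1 - k0))
    sol2 = solve_equilibrium(volvox_intrinsic(params.with_k(k0 + dk_nat), s), model,
                             init=sol, options={"margin": margin})
    ks.append(k0 + dk_nat)
    ds_.append(sol2.d)
    Es.append(sol2.energy.total)
    etas.append(max_eta_at(k0 + dk_nat))
    xs.append(sol2._x)
    lams.append(sol2._lam)

    def Y_of(i):
        return np.concatenate([xs[i], [lams[i]], [ks[i]]])

    def weighted(v):
        w = np.concatenate([np.full(m, wx), [1.0], [1.0]])
        return v * w

    h = ds0
    reason = "completed"
    fd_step = 1e-7
    for step in range(max_steps):
        Y_prev, Y_cur = Y_of(len(ks) - 2), Y_of(len(ks) - 1)
        T = Y_cur - Y_prev
        nrm = np.linalg.norm(weighted(T))
        if nrm == 0:
            reason = "stalled"
            break
        T = T / nrm

        accepted = False
        while h >= ds_min:
            Y_pred = Y_cur + h * T
            Y = Y_pred.copy()
            ok = False
            for newton_it in range(8):
                x_, lam_, k_ = Y[:-2], Y[-2], Y[-1]
                if abs(k_) > 1e3:
                    break
                try:
                    dsc = disc_at(k_)
                except ConstrictionLimitError:
                    break  # corrector wandered past |eta| = 1; shrink step
                F_top = dsc.kkt_residual(np.concatenate([x_, [lam_]]))
                F_arc = float(np.dot(weighted(T), weighted(Y - Y_pred)))
                F = np.concatenate([F_top, [F_arc]])
                if np.max(np.abs(F)) < 1e-10:
                    ok = True
                    break
                # bordered Jacobian by finite differences
                mm = Y.size
                J = np.empty((mm, mm))
                for j in range(mm - 1):
                    hj = fd_step * max(1.0, abs(Y[j]))
                    Yp = Y.copy()
                    Yp[j] += hj
                    F_top_p = dsc.kkt_residual(np.concatenate([Yp[:-2], [Yp[-2]]]))
                    J[:-1, j] = (F_top_p - F_top) / hj
                # k column: rebuild discretization
                hk = 1e-6 * max(1.0, abs(k_))
                try:
                    dsc_p = disc_at(k_ + hk)
                except ConstrictionLimitError:
                    dsc_p = disc_at(k_ - hk)
                    hk = -hk
                F_top_k = dsc_p.kkt_residual(np.concatenate([x_, [lam_]]))
                J[:-1, -1] = (F_top_k - F_top) / hk
                J[-1, :] = weighted(weighted(T))  # d F_arc / dY = T * w^2
                try:
                    Y = Y + lu_solve(lu_factor(J), -F)
                except Exception:
                    break
            if ok:
                accepted = True
                break
            h *= 0.5
        if not accepted:
            reason = "step_failure"
            break

        x_, lam_, k_ = Y[:-2], float(Y[-2]), float(Y[-1])
        dsc = disc_at(k_)
        d_, E_ = _branch_point(dsc, x_, lam_, reference)
        eta_ = max_eta_at(k_)
        ks.append(k_)
        ds_.append(d_)
        Es.append(E_)
        etas.append(eta_)
        xs.append(x_)
        lams.append(lam_)
        logger.info("continuation step %d: k=%.4f d=%.4f |eta|=%.3f h=%.3g",
                    step, k_, d_, eta_, h)

        if newton_it <= 3:
            h = min(h * 1.3, ds_max)
        elif newton_it >= 6:
            h = max(h * 0.5, ds_min)

        if stop_at_fold and len(ks) >= 3 and \
                (ks[-1] - ks[-2]) * (ks[-2] - ks[-3]) < 0:
            reason = "fold_detected"
            break
        if model == "large_bending" and eta_ > 1.0 - margin:
            reason = "constriction_limit"
            break
        if d_ > d_max:
            reason = "d_max_reached"
            break
        if k_ > k1 and ks[-1] > ks[-2]:
            reason = "completed"
            break
        if k_ < k0 - 1e-9:
            reason = "exited_backwards"
            break

    ks = np.asarray(ks)
    ds_arr = np.asarray(ds_)
    Es = np.asarray(Es)
    etas = np.asarray(etas)

    # fold detection: sign changes of dk along the branch
    fold_flag = np.zeros(ks.size, dtype=bool)
    folds = []
    dk = np.diff(ks)
    sign = np.sign(dk)
    for i in range(1, sign.size):
        if sign[i] != 0 and sign[i - 1] != 0 and sign[i] != sign[i - 1]:
            # quadratic fit of k vs arclength through points i-1, i, i+1
            idx = [i - 1, i, i + 1]
            arc = np.concatenate([[0.0], np.cumsum(
                [abs(ds_arr[j + 1] - ds_arr[j]) + abs(ks[j + 1] - ks[j])
                 for j in idx[:-1]])])
            coeff = np.polyfit(arc, ks[idx], 2)
            if abs(coeff[0]) > 1e-14:
                arc_star = -coeff[1] / (2 * coeff[0])
                k_star = float(np.polyval(coeff, arc_star))
                d_star = float(np.interp(arc_star, arc, ds_arr[idx]))
            else:
                k_star, d_star = float(ks[i]), float(ds_arr[i])
            fold_flag[i] = True
            folds.append({"index": i, "k": k_star, "d": d_star,
                          "direction": int(sign[i])})

    # jump annotation for S-shaped branches: natural upward sweep of k
    jumps = []
    if len(folds) >= 2:
        up_fold = folds[0]  # first turning point: k stops increasing
        k_jump = up_fold["k"]
        after = folds[1]["index"]
        seg_k = ks[after:]
        seg_d = ds_arr[after:]
        landed = np.where(seg_k >= k_jump)[0]
        if landed.size:
            j = landed[0]
            if j > 0:
                frac = (k_jump - seg_k[j - 1]) / (seg_k[j] - seg_k[j - 1])
                d_after = float(seg_d[j - 1] + frac * (seg_d[j] - seg_d[j - 1]))
            else:
                d_after = float(seg_d[0])
            jumps.append({"k": k_jump, "d_before": up_fold["d"], "d_after": d_after})

    return ContinuationBranch(
        k=ks, d=ds_arr, energy_total=Es, max_eta=etas, fold_flag=fold_flag,
        folds=folds, jumps=jumps, model=model, params=params,
        terminated_reason=reason,
    )


def critical_width(
    params: ScenarioParams,
    w_interval: tuple[float, float],
    model: str = "large_bending",
    tol: float = 0.025,
    k_range: tuple[float, float] | None = None,
    n_grid: int = 151,
    **branch_kwargs,
) -> float:
    """Bisection on the bend-region width w for the onset of a fold in the
    (k, d) branch.  ``w_interval`` must bracket the onset: no fold at the
    lower endpoint, a fold at the upper one.

    The sweep window is part of the definition of the onset: the fold
    retreats toward the constriction line |eta| = 1 as w decreases, so
    only folds within each model's admissible range count (by default,
    the classical branch is swept to the constriction line itself while
    the large-bending branch stops at its validity guard; a fold that the
    large-bending theory pushes beyond the guard does not count)."""
    w_lo, w_hi = w_interval

    def has_fold(w: float) -> bool:
        branch = continue_branch(replace(params, w=w), k_range=k_range,
                                 model=model, n_grid=n_grid, stop_at_fold=True,
                                 **branch_kwargs)
        return branch.n_folds > 0

    if has_fold(w_lo):
        raise ValueError(f"w = {w_lo} already folds; interval does not bracket onset")
    if not has_fold(w_hi):
        raise ValueError(f"w = {w_hi} does not fold; interval does not bracket onset")
    while w_hi - w_lo > tol:
        w_mid = 0.5 * (w_lo + w_hi)
        if has_fold(w_mid):
            w_hi = w_mid
        else:
            w_lo = w_mid
    return 0.5 * (w_lo + w_hi)
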