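"""Joint maximum-likelihood fitting of selection models.

The combined log likelihood couples a small vector of shared log-weights
with per-marker nuisance parameters (Delta_m, tau2_m).  Conditionally on
the log-weights the markers are independent, so the joint optimum is found
by profiling: an outer BFGS over the log-weights drives a batched inner
Newton solver that maximizes every marker's 2-parameter likelihood
simultaneously.  This is numerically identical to one joint BFGS over the
full parameter vector; the joint finite-difference gradient is verified at
the solution and the joint information matrix is assembled blockwise
(weights block, per-marker blocks, cross blocks) and inverted via the Schur
complement, giving the same covariance the full dense information matrix
would.

Between-study variances are unrestricted by default; markers whose
likelihood diverges at the feasibility boundary (sigma_i^2 + tau2 -> 0+,
the classic degenerate random-effects case) or whose information block is
not positive definite are flagged as non-converged and reported, never
silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .likelihood import (
    CompiledCorpus,
    StudyResult,
    compile_corpus,
    per_marker_loglik,
)
from .models import ModelSpec

__all__ = [
    "FitOptions",
    "FitResult",
    "DerivedEffect",
    "fit",
    "exclusion_protocol",
    "derive_reporting_probability",
    "reporting_probability",
    "contrast_probability",
    "model_table",
    "corrected_estimates",
]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975); CI = estimate +/- 1.96 SE uses 1.96
_CI_MULT = 1.96


@dataclass
class FitOptions:
    """Optimizer and convergence settings.

    gtol
        Max-norm threshold on the joint finite-difference gradient for the
        fit to count as converged.
    variance_floor
        If True, constrain tau2 >= 0 instead of the default unrestricted
        between-study variance.
    fd_step
        Relative step of the central differences used for the information
        matrix: h = fd_step * max(1, |theta|).
    """

    gtol: float = 1e-5
    inner_gtol: float = 1e-7
    outer_gtol: float = 1e-6
    fd_step: float = 1e-4
    variance_floor: bool = False
    max_inner_iter: int = 100
    n_restarts: int = 3
    seed: int = 0


@dataclass
class DerivedEffect:
    """A relative reporting probability with its 95% confidence interval."""

    name: str
    estimate: float       # on the log scale
    se: float
    point: float          # exp(estimate)
    ci_low: float
    ci_high: float


@dataclass
class FitResult:
    model_name: str
    effects_mode: str
    spec: ModelSpec
    param_names: tuple
    theta_w: np.ndarray           # shared log-weight estimates
    se_w: np.ndarray
    cov_w: np.ndarray             # (p, p) covariance of the log-weights
    marker_ids: tuple             # converged markers, in fit order
    delta: np.ndarray             # per converged marker
    tau2: np.ndarray
    se_delta: np.ndarray
    se_tau2: np.ndarray
    loglik: float
    aic: float
    n_parameters: int
    converged: bool
    excluded_markers: tuple       # markers flagged non-converged by this fit
    optimizer_diag: dict
    n_studies: int
    marker_cov: np.ndarray = None  # (m, q, q) per-marker covariance blocks
    cross_cov: np.ndarray = None   # (m, p, q) weight-by-marker covariance

    @property
    def converged_markers(self) -> tuple:
        return self.marker_ids

    def full_covariance(self) -> np.ndarray:
        """Dense covariance over all free parameters, ordered as the shared
        log-weights followed by each converged marker's (delta[, tau2])."""
        p = len(self.param_names)
        m = len(self.marker_ids)
        q = self.marker_cov.shape[1] if m else (2 if self.effects_mode == "random" else 1)
        n = p + q * m
        cov = np.zeros((n, n))
        cov[:p, :p] = self.cov_w
        for i in range(m):
            s = p + q * i
            cov[s:s + q, s:s + q] = self.marker_cov[i]
            if p:
                cov[:p, s:s + q] = self.cross_cov[i]
                cov[s:s + q, :p] = self.cross_cov[i].T
        return cov

    def weight_estimates(self) -> dict:
        return dict(zip(self.param_names, self.theta_w.tolist()))

    def param_index(self, name: str) -> int:
        try:
            return self.param_names.index(name)
        except ValueError:
            raise KeyError(
                f"model {self.model_name!r} has no parameter {name!r}; "
                f"available: {self.param_names}"
            ) from None

    def to_dict(self) -> dict:
        return {
            "model_name": self.model_name,
            "effects_mode": self.effects_mode,
            "param_names": list(self.param_names),
            "theta_w": self.theta_w.tolist(),
            "se_w": self.se_w.tolist(),
            "cov_w": self.cov_w.tolist(),
            "marker_ids": list(self.marker_ids),
            "delta": self.delta.tolist(),
            "tau2": self.tau2.tolist(),
            "se_delta": self.se_delta.tolist(),
            "se_tau2": self.se_tau2.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_parameters": self.n_parameters,
            "converged": self.converged,
            "excluded_markers": list(self.excluded_markers),
            "optimizer_diag": self.optimizer_diag,
            "n_studies": self.n_studies,
            "marker_cov": self.marker_cov.tolist(),
            "cross_cov": self.cross_cov.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


# ---------------------------------------------------------------------------
# Inner solver: batched per-marker Newton on (delta, tau2)
# ---------------------------------------------------------------------------

class _InnerState:
    """Mutable per-marker state shared across profile evaluations."""

    def __init__(self, c: CompiledCorpus, random_effects: bool, floor: bool):
        self.c = c
        self.random = random_effects
        self.floor = floor
        m = c.n_markers
        # likelihood domain: tau2 > -min_i sigma_i^2 per marker (the floor,
        # when active, is a projection constraint on top of this)
        min_s2 = np.full(m, np.inf)
        np.minimum.at(min_s2, c.marker_idx, c.sigma**2)
        self.tau2_min = -min_s2
        self.delta = np.zeros(m)
        self.tau2 = np.zeros(m)
        self.failed = np.zeros(m, bool)
        self.banned = np.zeros(m, bool)  # permanent, e.g. non-PD Hessian
        self.stall = np.zeros(m, int)
        self.freesteps = np.zeros(m, int)
        self.ll = np.full(m, np.nan)
        self.at_floor = np.zeros(m, bool)  # active tau2 >= 0 constraint

    def start_values(self, mask: Optional[np.ndarray] = None) -> None:
        """Inverse-variance means and DerSimonian-Laird moments.

        With ``mask`` given, only those markers are (re)initialized and
        their failure flags cleared.
        """
        c = self.c
        w = 1.0 / c.sigma**2
        sw = np.bincount(c.marker_idx, w, c.n_markers)
        swx = np.bincount(c.marker_idx, w * c.x, c.n_markers)
        delta = swx / sw
        if self.random:
            resid2 = (c.x - delta[c.marker_idx]) ** 2
            q = np.bincount(c.marker_idx, w * resid2, c.n_markers)
            sw2 = np.bincount(c.marker_idx, w**2, c.n_markers)
            denom = np.maximum(sw - sw2 / sw, 1e-12)
            dof = np.maximum(c.n_per_marker - 1, 1)
            tau2 = np.clip((q - dof) / denom, 0.0, None) + 1e-6
        else:
            tau2 = np.zeros(c.n_markers)
        if mask is None:
            mask = np.ones(c.n_markers, bool)
        mask = mask & ~self.banned
        self.delta = np.where(mask, delta, self.delta)
        self.tau2 = np.where(mask, tau2, self.tau2)
        self.failed &= ~mask
        self.stall[mask] = 0


def _inner_solve(state: _InnerState, theta_w: np.ndarray, opts: FitOptions,
                 gtol: Optional[float] = None) -> None:
    """Maximize every marker's likelihood in (delta[, tau2]) at fixed weights.

    All markers are stepped simultaneously (damped Newton on central
    differences); as markers converge their studies drop out of the
    evaluation subset, so late iterations only touch the stragglers.
    """
    c = state.c
    gtol = opts.inner_gtol if gtol is None else gtol
    state.stall[:] = 0  # stalls and trust-steps are judged within one solve
    state.freesteps[:] = 0

    def pm(d, t, idx=None):
        return per_marker_loglik(c, theta_w, d, t, idx)

    f_cur = pm(state.delta, state.tau2)
    bad_now = ~np.isfinite(f_cur) & ~state.failed
    if np.any(bad_now):
        # infeasible warm start (can follow a big outer step): reset
        state.tau2[bad_now] = np.maximum(state.tau2[bad_now], 0.0) + 1e-6
        f_cur = pm(state.delta, state.tau2)
        state.failed |= ~np.isfinite(f_cur)
    moving = ~state.failed  # markers still being optimized in this solve

    for _ in range(opts.max_inner_iter):
        if not np.any(moving):
            break
        idx = np.nonzero(moving[c.marker_idx])[0]
        d, t = state.delta, state.tau2
        h_d = 1e-5 * np.maximum(1.0, np.abs(d))
        margin = t - state.tau2_min
        h_t = np.minimum(1e-5 * np.maximum(1.0, np.abs(t)),
                         np.maximum(0.25 * margin, 1e-12))
        f0 = pm(d, t, idx)
        f_pd, f_md = pm(d + h_d, t, idx), pm(d - h_d, t, idx)
        g_d = (f_pd - f_md) / (2 * h_d)
        H_dd = (f_pd - 2 * f0 + f_md) / h_d**2
        if state.random:
            f_pt, f_mt = pm(d, t + h_t, idx), pm(d, t - h_t, idx)
            g_t = (f_pt - f_mt) / (2 * h_t)
            H_tt = (f_pt - 2 * f0 + f_mt) / h_t**2
        else:
            g_t = np.zeros(c.n_markers)
            H_tt = np.full(c.n_markers, -1.0)

        # divergence toward the tau2 feasibility boundary
        if state.random and not state.floor:
            at_barrier = moving & (margin < 1e-7) & (g_t < 0)
            state.failed |= at_barrier
            moving &= ~at_barrier
        # floor mode: ignore downhill tau2 gradient at the floor
        g_t_eff = g_t.copy()
        if state.floor:
            g_t_eff[(t <= 0) & (g_t < 0)] = 0.0

        gnorm = np.maximum(np.abs(g_d), np.abs(g_t_eff))
        runaway = moving & (~np.isfinite(gnorm) | (np.abs(d) > 50) | (t > 1e4))
        state.failed |= runaway
        moving &= ~runaway
        moving &= gnorm > gtol  # converged markers leave the subset
        if not np.any(moving):
            break

        # cross-derivative only for the markers still moving
        idx2 = np.nonzero(moving[c.marker_idx])[0]
        if state.random:
            f_pp = pm(d + h_d, t + h_t, idx2)
            f_pm = pm(d + h_d, t - h_t, idx2)
            f_mp = pm(d - h_d, t + h_t, idx2)
            f_mm = pm(d - h_d, t - h_t, idx2)
            H_dt = (f_pp - f_pm - f_mp + f_mm) / (4 * h_d * h_t)
        else:
            H_dt = np.zeros(c.n_markers)

        # Newton direction where the Hessian is negative definite
        det = H_dd * H_tt - H_dt**2
        nd = (H_dd < 0) & (det > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            step_d = np.where(nd, -(H_tt * g_d - H_dt * g_t_eff) / det, 0.0)
            step_t = np.where(nd, -(H_dd * g_t_eff - H_dt * g_d) / det, 0.0)
        # fallback: scaled gradient ascent
        scale = 1.0 / (np.maximum(np.abs(H_dd), np.abs(H_tt)) + 1.0)
        step_d = np.where(nd, step_d, g_d * scale)
        step_t = np.where(nd, step_t, g_t_eff * scale)
        if state.floor:
            # active floor: step along the constraint (1-d Newton in delta),
            # not the full 2-d step, which would re-enter tau2 > 0 through
            # the cross-curvature
            on_floor = (t <= 0) & (g_t < 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                newton_d = np.where(H_dd < 0, -g_d / H_dd, g_d * scale)
            step_d = np.where(on_floor, newton_d, step_d)
            step_t = np.where(on_floor, 0.0, step_t)
        if not state.random:
            step_t = np.zeros(c.n_markers)
        # cap absurd steps
        cap = 10.0
        norm = np.maximum(np.abs(step_d), np.abs(step_t))
        shrink = np.where(norm > cap, cap / np.maximum(norm, 1e-300), 1.0)
        step_d = step_d * shrink
        step_t = step_t * shrink

        # when the expected improvement drops under the rounding noise of
        # the likelihood values, a value-based line search cannot make
        # progress: take the (tiny) Newton step on trust, a few times at
        # most, so the gradient still contracts quadratically
        exp_impr = np.abs(g_d * step_d) + np.abs(g_t_eff * step_t)
        deadend = moving & ~nd & (exp_impr < 1e-13)
        moving &= ~deadend
        if not np.any(moving):
            break
        free = moving & nd & (exp_impr < 1e-11)
        state.freesteps[free] += 1
        settled = free & (state.freesteps >= 3)
        moving &= ~settled
        free &= ~settled
        if not np.any(moving):
            break

        f0 = np.where(moving, f0, 0.0)
        tstep = np.where(moving, 1.0, 0.0)
        accepted = ~moving
        best_d, best_t, best_f = d.copy(), t.copy(), f0.copy()
        for _ in range(12):
            cd = d + tstep * step_d
            ct = t + tstep * step_t
            if state.floor:
                ct = np.maximum(ct, 0.0)
            fc = pm(cd, ct, idx2)
            improve = (moving & ~accepted & np.isfinite(fc)
                       & ((fc >= f0 - 1e-13) | free))
            best_d[improve] = cd[improve]
            best_t[improve] = ct[improve]
            best_f[improve] = fc[improve]
            accepted |= improve
            if np.all(accepted):
                break
            tstep[~accepted] *= 0.5
        stalled = moving & ~accepted
        state.stall[stalled] += 1
        state.stall[moving & accepted] = 0
        give_up = moving & (state.stall >= 3)
        state.failed |= give_up
        moving &= ~give_up
        state.delta, state.tau2 = best_d, best_t
    else:
        # markers still moving after max_inner_iter are non-converged
        state.failed |= moving

    ll = pm(state.delta, state.tau2)
    state.ll = np.where(~state.failed, ll, np.nan)
    if state.floor and state.random:
        h = 1e-6
        g_t_fin = (pm(state.delta, state.tau2 + h)
                   - pm(state.delta, state.tau2 - h)) / (2 * h)
        state.at_floor = (~state.failed) & (state.tau2 <= 0) & (g_t_fin < 0)
    else:
        state.at_floor[:] = False


# ---------------------------------------------------------------------------
# Information matrix (blockwise central differences + Schur complement)
# ---------------------------------------------------------------------------

def _information_blocks(c, theta_w, delta, tau2, active, random_effects, h_rel,
                        at_floor=None):
    """Negative-Hessian blocks of the joint log likelihood at the optimum.

    For markers whose tau2 >= 0 constraint is active (``at_floor``) the tau2
    coordinate is not an interior estimate: its row and column are dropped
    from the information (identity-padded), so its SE is undefined rather
    than misleading.
    """
    p = theta_w.size
    q = 2 if random_effects else 1

    def total(th, d, t):
        v = per_marker_loglik(c, th, d, t)
        return np.nansum(np.where(active, v, 0.0))

    def permarker(th, d, t):
        return per_marker_loglik(c, th, d, t)

    h_w = h_rel * np.maximum(1.0, np.abs(theta_w))
    h_d = h_rel * np.maximum(1.0, np.abs(delta))
    h_t = h_rel * np.maximum(1.0, np.abs(tau2))
    # keep tau2 perturbations feasible
    if random_effects:
        min_s2 = np.full(c.n_markers, np.inf)
        np.minimum.at(min_s2, c.marker_idx, c.sigma**2)
        h_t = np.minimum(h_t, np.maximum(0.25 * (tau2 + min_s2), 1e-12))

    # weights block
    A = np.zeros((p, p))
    f0 = total(theta_w, delta, tau2)
    for a in range(p):
        ea = np.zeros(p); ea[a] = h_w[a]
        A[a, a] = -(total(theta_w + ea, delta, tau2) - 2 * f0
                    + total(theta_w - ea, delta, tau2)) / h_w[a] ** 2
        for b in range(a + 1, p):
            eb = np.zeros(p); eb[b] = h_w[b]
            v = (total(theta_w + ea + eb, delta, tau2)
                 - total(theta_w + ea - eb, delta, tau2)
                 - total(theta_w - ea + eb, delta, tau2)
                 + total(theta_w - ea - eb, delta, tau2)) / (4 * h_w[a] * h_w[b])
            A[a, b] = A[b, a] = -v

    # per-marker blocks (all markers perturbed simultaneously)
    g0 = permarker(theta_w, delta, tau2)
    f_pd, f_md = permarker(theta_w, delta + h_d, tau2), permarker(theta_w, delta - h_d, tau2)
    D = np.zeros((c.n_markers, q, q))
    D[:, 0, 0] = -(f_pd - 2 * g0 + f_md) / h_d**2
    if random_effects:
        f_pt = permarker(theta_w, delta, tau2 + h_t)
        f_mt = permarker(theta_w, delta, tau2 - h_t)
        D[:, 1, 1] = -(f_pt - 2 * g0 + f_mt) / h_t**2
        f_pp = permarker(theta_w, delta + h_d, tau2 + h_t)
        f_pm = permarker(theta_w, delta + h_d, tau2 - h_t)
        f_mp = permarker(theta_w, delta - h_d, tau2 + h_t)
        f_mm = permarker(theta_w, delta - h_d, tau2 - h_t)
        cross = -(f_pp - f_pm - f_mp + f_mm) / (4 * h_d * h_t)
        D[:, 0, 1] = D[:, 1, 0] = cross

    # cross blocks weights x marker coordinates
    B = np.zeros((c.n_markers, p, q))
    for a in range(p):
        ea = np.zeros(p); ea[a] = h_w[a]
        for bcoord in range(q):
            if bcoord == 0:
                dp, dm, tp, tm = delta + h_d, delta - h_d, tau2, tau2
                hb = h_d
            else:
                dp, dm, tp, tm = delta, delta, tau2 + h_t, tau2 - h_t
                hb = h_t
            v = (permarker(theta_w + ea, dp, tp)
                 - permarker(theta_w + ea, dm, tm)
                 - permarker(theta_w - ea, dp, tp)
                 + permarker(theta_w - ea, dm, tm)) / (4 * h_w[a] * hb)
            B[:, a, bcoord] = -v
    if at_floor is not None and q == 2 and np.any(at_floor):
        D[at_floor, 0, 1] = 0.0
        D[at_floor, 1, 0] = 0.0
        D[at_floor, 1, 1] = 1.0
        B[at_floor, :, 1] = 0.0
    return A, B, D


def _is_pd(mat: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(mat)
        return True
    except np.linalg.LinAlgError:
        return False


def _joint_gradient_norm(c, theta_w, delta, tau2, active, random_effects,
                         floor, tau2_min) -> float:
    """Max-norm of the joint central-difference gradient at the optimum."""
    def total(th, d, t):
        v = per_marker_loglik(c, th, d, t)
        return np.nansum(np.where(active, v, 0.0))

    h = 1e-5
    comps = []
    for a in range(theta_w.size):
        ea = np.zeros(theta_w.size); ea[a] = h
        comps.append((total(theta_w + ea, delta, tau2)
                      - total(theta_w - ea, delta, tau2)) / (2 * h))
    h_d = np.full(delta.size, h)
    g_d = (per_marker_loglik(c, theta_w, delta + h_d, tau2)
           - per_marker_loglik(c, theta_w, delta - h_d, tau2)) / (2 * h_d)
    comps.extend(np.abs(g_d[active]).tolist())
    if random_effects:
        h_t = np.minimum(h, np.maximum(0.25 * (tau2 - tau2_min), 1e-12))
        g_t = (per_marker_loglik(c, theta_w, delta, tau2 + h_t)
               - per_marker_loglik(c, theta_w, delta, tau2 - h_t)) / (2 * h_t)
        if floor:
            g_t = np.where((tau2 <= 0) & (g_t < 0), 0.0, g_t)
        comps.extend(np.abs(g_t[active]).tolist())
    return float(np.max(np.abs(np.asarray(comps)))) if comps else 0.0


def _profile_gradient(c, theta_w, state, active) -> np.ndarray:
    """Central-difference gradient of the log likelihood w.r.t. the weights
    at the inner optimum (equals the profile gradient there)."""
    p = theta_w.size
    g = np.zeros(p)
    h = 1e-6 * np.maximum(1.0, np.abs(theta_w))
    for a in range(p):
        ea = np.zeros(p); ea[a] = h[a]
        fp = per_marker_loglik(c, theta_w + ea, state.delta, state.tau2)
        fm = per_marker_loglik(c, theta_w - ea, state.delta, state.tau2)
        g[a] = (np.nansum(np.where(active, fp, 0.0))
                - np.nansum(np.where(active, fm, 0.0))) / (2 * h[a])
    return g


def _schur(A, B, D, active):
    """Schur complement of the weights block; skips non-PD marker blocks."""
    S = A.copy()
    for i in np.where(active)[0]:
        if not _is_pd(D[i]):
            continue
        S -= B[i] @ np.linalg.inv(D[i]) @ B[i].T
    return 0.5 * (S + S.T)


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------

def fit(corpus: Sequence[StudyResult], spec: ModelSpec,
        options: Optional[FitOptions] = None) -> FitResult:
    """Joint ML fit of one selection model to a categorized corpus."""
    opts = options or FitOptions()
    corpus = list(corpus)
    c = compile_corpus(corpus, spec)
    random_effects = spec.effects_mode == "random"
    p = spec.n_free_weight_params
    rng = np.random.default_rng(opts.seed)

    best = None
    for attempt in range(opts.n_restarts + 1):
        state = _InnerState(c, random_effects, opts.variance_floor)
        state.start_values()
        theta0 = np.zeros(p)
        if attempt > 0:
            theta0 = theta0 + rng.normal(0.0, 0.1, size=p)

        diag = {"restarts_used": attempt}
        theta_w = theta0.copy()
        tight = min(opts.inner_gtol, 1e-9)
        for excl_round in range(3):
            for round_ in range(3):
                if p:
                    def neg_profile(th):
                        _inner_solve(state, th, opts)
                        return -float(np.nansum(state.ll[~state.failed]))

                    res = minimize(neg_profile, theta_w, method="BFGS",
                                   options={"gtol": opts.outer_gtol,
                                            "maxiter": 200})
                    theta_w = np.asarray(res.x, float)
                    diag.update(outer_iterations=int(res.nit),
                                outer_status=res.message,
                                outer_success=bool(res.success))
                else:
                    diag.update(outer_iterations=0,
                                outer_status="no weight parameters",
                                outer_success=True)
                _inner_solve(state, theta_w, opts, gtol=tight)
                if not np.any(state.failed):
                    break
                # markers can fail transiently while the outer search passes
                # through extreme weights: retry them from fresh start values
                prev_failed = state.failed.copy()
                state.start_values(mask=prev_failed)
                _inner_solve(state, theta_w, opts, gtol=tight)
                if np.array_equal(state.failed, prev_failed):
                    break  # failures are stable

            active = ~state.failed
            if not np.any(active):
                raise RuntimeError("no marker converged; corpus is degenerate")

            # Newton polish of the weights on the profile surface: the Schur
            # complement of the information matrix is exactly the profile
            # Hessian, so a few steps drive the joint gradient to the noise
            # floor of the finite differences.
            for _ in range(5):
                if not p:
                    break
                g_w = _profile_gradient(c, theta_w, state, active)
                if np.max(np.abs(g_w)) < 0.3 * opts.gtol:
                    break
                A, B, D = _information_blocks(
                    c, theta_w, state.delta, state.tau2, active,
                    random_effects, opts.fd_step, at_floor=state.at_floor,
                )
                S = _schur(A, B, D, active)
                if S is None or not _is_pd(S):
                    break
                theta_w = theta_w + np.linalg.solve(S, g_w)
                _inner_solve(state, theta_w, opts, gtol=tight)
                active = ~state.failed

            A, B, D = _information_blocks(
                c, theta_w, state.delta, state.tau2, active, random_effects,
                opts.fd_step, at_floor=state.at_floor,
            )
            marker_pd = np.array([_is_pd(D[i]) if active[i] else False
                                  for i in range(c.n_markers)])
            hess_failed = active & ~marker_pd
            if not np.any(hess_failed) or excl_round == 2:
                break
            # a non-positive-definite per-marker information block is a
            # convergence failure: exclude those markers and re-optimize
            state.banned |= hess_failed
            state.failed |= hess_failed

        q = 2 if random_effects else 1
        active2 = active & marker_pd

        Dinv = np.zeros_like(D)
        for i in np.where(active2)[0]:
            Dinv[i] = np.linalg.inv(D[i])
        if p:
            S = A.copy()
            for i in np.where(active2)[0]:
                S -= B[i] @ Dinv[i] @ B[i].T
            S = 0.5 * (S + S.T)
            s_pd = _is_pd(S)
            cov_w = np.linalg.inv(S) if s_pd else np.full((p, p), np.nan)
        else:
            s_pd = True
            cov_w = np.zeros((0, 0))

        gnorm = _joint_gradient_norm(c, theta_w, state.delta, state.tau2,
                                     active2, random_effects,
                                     opts.variance_floor, state.tau2_min)
        # scipy's line-search status is diagnostic only: the Newton polish
        # runs afterwards, so the joint gradient norm is the real criterion
        converged = bool(s_pd and not np.any(hess_failed) and gnorm < opts.gtol)
        diag.update(joint_gradient_max_norm=gnorm, weights_info_pd=s_pd,
                    n_marker_hessian_failures=int(hess_failed.sum()))

        ll_active = float(np.nansum(state.ll[active2]))
        cand = (converged, ll_active, state, theta_w, cov_w, Dinv, B, active2,
                hess_failed, diag, s_pd)
        if best is None or (cand[0] and not best[0]) or (cand[0] == best[0] and
                                                         cand[1] > best[1]):
            best = cand
        if converged:
            break

    (converged, ll_active, state, theta_w, cov_w, Dinv, B, active2,
     hess_failed, diag, s_pd) = best
    q = 2 if random_effects else 1

    # per-marker covariance via the Schur identity
    m_all = c.n_markers
    q_dim = 2 if random_effects else 1
    se_delta = np.full(m_all, np.nan)
    se_tau2 = np.full(m_all, np.nan)
    cov_mm = np.full((m_all, q_dim, q_dim), np.nan)
    cov_wm = np.full((m_all, p, q_dim), np.nan)
    for i in np.where(active2)[0]:
        cov_m = Dinv[i].copy()
        if p and s_pd:
            correction = Dinv[i] @ B[i].T @ cov_w @ B[i] @ Dinv[i]
            cov_m = cov_m + correction
            cov_wm[i] = -cov_w @ B[i] @ Dinv[i]
        cov_mm[i] = cov_m
        se_delta[i] = np.sqrt(max(cov_m[0, 0], 0.0))
        if random_effects:
            se_tau2[i] = (np.nan if state.at_floor[i]
                          else np.sqrt(max(cov_m[1, 1], 0.0)))

    keep = np.where(active2)[0]
    excluded = tuple(c.marker_ids[i] for i in range(m_all) if not active2[i])
    se_w = (np.sqrt(np.clip(np.diag(cov_w), 0.0, None))
            if (p and s_pd) else np.full(p, np.nan))
    k_total = p + q * keep.size
    loglik = ll_active
    n_kept_studies = int(c.n_per_marker[keep].sum())

    return FitResult(
        model_name=spec.name,
        effects_mode=spec.effects_mode,
        spec=spec,
        param_names=spec.param_names,
        theta_w=theta_w,
        se_w=se_w,
        cov_w=cov_w,
        marker_ids=tuple(c.marker_ids[i] for i in keep),
        delta=state.delta[keep].copy(),
        tau2=state.tau2[keep].copy(),
        se_delta=se_delta[keep],
        se_tau2=se_tau2[keep],
        loglik=loglik,
        aic=2.0 * k_total - 2.0 * loglik,
        n_parameters=k_total,
        converged=converged,
        excluded_markers=excluded,
        optimizer_diag=diag,
        n_studies=n_kept_studies,
        marker_cov=cov_mm[keep],
        cross_cov=cov_wm[keep],
    )


def exclusion_protocol(corpus: Sequence[StudyResult], all_specs: Sequence[ModelSpec],
                       options: Optional[FitOptions] = None, max_rounds: int = 5,
                       on_error: str = "raise"):
    """Markers that fail convergence under *any* model, excluded from
    *every* model so that fits stay comparable.

    Exclusion is iterated to a fixed point: removing markers can itself
    change which markers converge, so each round refits all models on the
    surviving corpus until no model flags anything new.  Returns
    ``(excluded_ids, per_model, fits)`` where ``per_model`` maps model name
    to all markers that ever failed under it and ``fits`` holds the final
    round's FitResults — every one computed on the identical corpus with no
    further exclusions, ready for model comparison.
    """
    corpus = list(corpus)
    specs = list(all_specs)
    per_model: dict = {spec.name: set() for spec in specs}
    excluded: set = set()
    fits: dict = {}
    for _ in range(max_rounds):
        kept = [s for s in corpus if s.marker_id not in excluded]
        fits = {}
        for spec in list(specs):
            if on_error == "raise":
                fits[spec.name] = fit(kept, spec, options)
            else:
                try:
                    fits[spec.name] = fit(kept, spec, options)
                except Exception:  # drop the model, keep the protocol going
                    specs.remove(spec)
        new: set = set()
        for name, res in fits.items():
            per_model[name].update(res.excluded_markers)
            new.update(res.excluded_markers)
        if not new:
            break
        excluded |= new
    per_model = {name: tuple(sorted(ids)) for name, ids in per_model.items()}
    return excluded, per_model, fits


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def reporting_probability(estimate: float, se: float, name: str = "") -> DerivedEffect:
    """exp(log-weight estimate) with exp(estimate +/- 1.96 SE) interval."""
    if se < 0 or not np.isfinite(se):
        raise ValueError("standard error must be finite and nonnegative")
    return DerivedEffect(
        name=name,
        estimate=float(estimate),
        se=float(se),
        point=float(np.exp(estimate)),
        ci_low=float(np.exp(estimate - _CI_MULT * se)),
        ci_high=float(np.exp(estimate + _CI_MULT * se)),
    )


def contrast_probability(est1: float, est2: float, var1: float, var2: float,
                         cov: float, name: str = "") -> DerivedEffect:
    """Relative reporting probability exp(-(est1 - est2)) for a difference of
    two log-weights, with SE sqrt(var1 + var2 - 2 cov)."""
    se = float(np.sqrt(var1 + var2 - 2.0 * cov))
    return reporting_probability(-(est1 - est2), se, name=name)


def derive_reporting_probability(fit_result: FitResult, parameter) -> DerivedEffect:
    """Relative reporting probability for one log-weight, or for the
    contrast ``(name1, name2)`` meaning exp(-(log w1 - log w2))."""
    if isinstance(parameter, str):
        i = fit_result.param_index(parameter)
        if not np.all(np.isfinite(fit_result.cov_w)):
            raise ValueError("fit has no valid covariance; cannot derive CI")
        return reporting_probability(
            fit_result.theta_w[i], fit_result.se_w[i], name=parameter
        )
    name1, name2 = parameter
    i, j = fit_result.param_index(name1), fit_result.param_index(name2)
    cov = fit_result.cov_w
    if not np.all(np.isfinite(cov)):
        raise ValueError("fit has no valid covariance; cannot derive contrast")
    return contrast_probability(
        fit_result.theta_w[i], fit_result.theta_w[j],
        cov[i, i], cov[j, j], cov[i, j],
        name=f"{name1}-{name2}",
    )


# ---------------------------------------------------------------------------
# Comparison tables
# ---------------------------------------------------------------------------

def model_table(fits: Sequence[FitResult], baseline: FitResult):
    """Model-comparison table of weight estimates, Delta L and Delta AIC
    against the unbiased baseline; the lowest-AIC model is flagged.

    All fits must cover the identical post-exclusion marker set and share
    the effects mode, so per-marker parameters cancel in the differences and
    Delta AIC = 2 Delta k_w - 2 Delta L.
    """
    import pandas as pd

    ref = set(baseline.marker_ids)
    for f in fits:
        if set(f.marker_ids) != ref:
            raise ValueError(
                f"fit {f.model_name!r} covers a different marker set than the "
                "baseline; run the exclusion protocol first"
            )
        if f.effects_mode != baseline.effects_mode:
            raise ValueError("all fits must share the effects mode")
    rows = []
    for f in fits:
        est = {
            name: f"{f.theta_w[i]:.2f} ({f.se_w[i]:.2f})"
            for i, name in enumerate(f.param_names)
        }
        d_l = f.loglik - baseline.loglik
        d_k = f.spec.n_free_weight_params - baseline.spec.n_free_weight_params
        rows.append({
            "model": f.model_name,
            **est,
            "delta_loglik": d_l,
            "n_weight_params": f.spec.n_free_weight_params,
            "delta_aic": 2.0 * d_k - 2.0 * d_l,
            "converged": f.converged,
        })
    table = pd.DataFrame(rows).set_index("model")
    table["best"] = table["delta_aic"] == table["delta_aic"].min()
    return table


def corrected_estimates(fit_selection: FitResult, fit_unbiased: FitResult):
    """Per-marker effects and between-study variances, uncorrected
    (unbiased model) vs. corrected (selection model), with a shrinkage
    summary."""
    import pandas as pd

    if set(fit_selection.marker_ids) != set(fit_unbiased.marker_ids):
        raise ValueError("fits cover different marker sets")
    unb = {mid: i for i, mid in enumerate(fit_unbiased.marker_ids)}
    rows = []
    for i, mid in enumerate(fit_selection.marker_ids):
        j = unb[mid]
        rows.append({
            "marker_id": mid,
            "delta_uncorrected": fit_unbiased.delta[j],
            "se_delta_uncorrected": fit_unbiased.se_delta[j],
            "tau2_uncorrected": fit_unbiased.tau2[j],
            "delta_corrected": fit_selection.delta[i],
            "se_delta_corrected": fit_selection.se_delta[i],
            "tau2_corrected": fit_selection.tau2[i],
        })
    table = pd.DataFrame(rows).set_index("marker_id")
    summary = {
        "mean_abs_delta_uncorrected": float(np.mean(np.abs(table["delta_uncorrected"]))),
        "mean_abs_delta_corrected": float(np.mean(np.abs(table["delta_corrected"]))),
        "mean_tau2_uncorrected": float(np.mean(table["tau2_uncorrected"])),
        "mean_tau2_corrected": float(np.mean(table["tau2_corrected"])),
    }
    summary["abs_effect_shrunk"] = (
        summary["mean_abs_delta_corrected"] <= summary["mean_abs_delta_uncorrected"]
    )
    summary["tau2_shrunk"] = (
        summary["mean_tau2_corrected"] <= summary["mean_tau2_uncorrected"]
    )
    return table, summary
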