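"""Ecological equilibria of the coarse-grained relative-abundance dynamics.

The community obeys the replicator-like system

    df_mu/dt = f_mu [ sum_i r_{mu,i} h_i(f) - 1 ],
    h_i(f)   = kappa_i / (sum_mu r_{mu,i} f_mu),

where ``h_i`` is the local availability of resource i and ``kappa_i`` its
supply share.  These dynamics admit the strictly concave potential

    Phi(f) = sum_i kappa_i log(sum_mu r_{mu,i} f_mu) - sum_mu f_mu,

whose gradient equals the per-capita growth rates.  The unique maximizer of
Phi over f >= 0 is therefore the uninvadable equilibrium: survivors have
zero growth, excluded strains non-positive growth, and the abundances
self-normalize to sum_mu f_mu = 1.  We locate it with a multiplicative
warm phase (each update increases Phi) followed by an active-set Newton
polish with LP pivoting for degenerate saturated supports, producing exact
zeros for excluded strains and machine-precision KKT residuals.

An independent ODE integrator of the same dynamics is provided as a
cross-validation oracle.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import linprog

from .sampling import Environment, SpeciesPool, Strain

__all__ = [
    "CommunityState",
    "EquilibriumError",
    "growth_rates",
    "compute_equilibrium",
    "integrate_dynamics",
    "potential",
]

#: relative abundance below which a strain is declared extinct
EXTINCTION_THRESHOLD = 1e-10
#: growth-rate margin within which an excluded strain is flagged marginal
DEGENERACY_TOL = 1e-9


class EquilibriumError(RuntimeError):
    pass


def _as_strains(pool) -> list[Strain]:
    if isinstance(pool, SpeciesPool):
        return pool.strains
    return list(pool)


def _uptake_matrix(strains: Sequence[Strain], R: int) -> np.ndarray:
    A = np.empty((len(strains), R))
    for k, st in enumerate(strains):
        A[k] = st.uptake
    return A


@dataclasses.dataclass
class CommunityState:
    """An equilibrium (or candidate) state of a strain collection.

    ``f`` is indexed like ``strains`` and contains exact zeros for excluded
    strains.  ``h`` and ``g`` are full length-R vectors with NaN entries for
    resources no candidate strain consumes (their availability is undefined
    in the coarse-grained model); ``active_resources`` marks the rest.
    ``g_i = h_i / h_bar - 1`` is the excess availability relative to the
    mean over active resources.
    """

    strains: list[Strain]
    env: Environment
    f: np.ndarray
    h: np.ndarray
    g: np.ndarray
    h_bar: float
    active_resources: np.ndarray
    survivor_mask: np.ndarray
    kkt_survivor_residual: float
    kkt_excluded_residual: float
    degenerate: bool
    tol: float

    @property
    def survivors(self) -> np.ndarray:
        """Indices into ``strains`` of the surviving members."""
        return np.flatnonzero(self.survivor_mask)

    @property
    def survivor_ids(self) -> list[str]:
        return [self.strains[i].id for i in self.survivors]

    @property
    def n_survivors(self) -> int:
        return int(self.survivor_mask.sum())

    @property
    def niche_saturation(self) -> float:
        return self.n_survivors / int(self.active_resources.sum())

    def survivor_strains(self) -> list[Strain]:
        return [self.strains[i] for i in self.survivors]

    def index_of(self, strain_id: str) -> int:
        for k, st in enumerate(self.strains):
            if st.id == strain_id:
                return k
        raise KeyError(strain_id)


def _active_kappa(A: np.ndarray, env: Environment):
    """Resources with at least one consumer, and supply shares renormalized
    over them (unconsumed resources drop out of the dynamics entirely)."""
    active = A.sum(axis=0) > 0
    if not active.any():
        raise EquilibriumError("no resource is consumed by any strain")
    kappa = env.kappa[active]
    ksum = kappa.sum()
    if ksum < 1.0 - 1e-12:
        warnings.warn(
            f"{int((~active).sum())} resources have no consumer; "
            "dropping them and renormalizing supply shares"
        )
    return active, kappa / ksum


def growth_rates(f: np.ndarray, pool, env: Environment) -> np.ndarray:
    """Per-capita growth rates  sum_i r_{mu,i} h_i(f) - 1  for all strains.

    Zero-abundance strains get their invasion growth rate, which is what
    non-invasibility checks need.
    """
    strains = _as_strains(pool)
    A = _uptake_matrix(strains, env.R)
    active, kappa = _active_kappa(A, env)
    f = np.asarray(f, dtype=float)
    q = A[:, active].T @ f
    if np.any(q <= 0):
        raise EquilibriumError(
            "a consumed resource has zero total consumption at this f; "
            "its availability diverges"
        )
    return A[:, active] @ (kappa / q) - 1.0


def potential(f: np.ndarray, pool, env: Environment) -> float:
    """Lyapunov potential Phi(f); non-decreasing along trajectories."""
    strains = _as_strains(pool)
    A = _uptake_matrix(strains, env.R)
    active, kappa = _active_kappa(A, env)
    q = A[:, active].T @ np.asarray(f, dtype=float)
    return float(kappa @ np.log(q) - np.sum(f))


def _multiplicative_phase(A_act, kappa, f, n_iter, gtol=1e-11):
    """Multiplicative (EM-like) updates f <- f * [sum_i r_i h_i(f)].

    Each update increases Phi; excluded strains decay geometrically, which
    quickly sorts candidates into (approximate) survivors and losers.
    """
    for _ in range(n_iter):
        q = np.maximum(A_act.T @ f, 1e-300)
        ratio = A_act @ (kappa / q)
        f = f * ratio
        if np.max(np.abs(ratio - 1.0)) < gtol:
            break
    return f


def _newton_on_support(A_act, kappa, f_s, max_iter=60, gtol=1e-13):
    """Damped Newton solving growth(f_s) = 0 on a fixed support.

    Returns (f_s, converged).  Steps are damped to keep f_s positive; the
    caller drops members that collapse toward the boundary.
    """
    n = len(f_s)
    eye = np.eye(n)
    for _ in range(max_iter):
        q = A_act.T @ f_s
        if np.any(q <= 0):
            return f_s, False
        w = kappa / q
        grad = A_act @ w - 1.0
        if np.max(np.abs(grad)) < gtol:
            return f_s, True
        B = A_act * (w / q)          # (n, R_act)
        H = B @ A_act.T              # positive semidefinite
        if n > A_act.shape[1]:
            # support exceeds the active resource count: H is singular, use
            # the minimum-norm step (caller sparsifies afterwards)
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        else:
            try:
                step = np.linalg.solve(H + 1e-14 * eye, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # Newton direction for maximizing Phi, damped to keep f_s positive
        t = 1.0
        shrinking = step < 0
        if shrinking.any():
            t = min(1.0, 0.9 * np.min(f_s[shrinking] / -step[shrinking]))
        f_s = f_s + t * step
    q = np.maximum(A_act.T @ f_s, 1e-300)
    return f_s, np.max(np.abs(A_act @ (kappa / q) - 1.0)) < 1e-10


def compute_equilibrium(
    pool,
    env: Environment,
    tol: float = 1e-10,
    f0: np.ndarray | None = None,
    extinction_threshold: float = EXTINCTION_THRESHOLD,
    max_active_set_iter: int = 200,
) -> CommunityState:
    """Find the uninvadable equilibrium of a candidate strain collection.

    Parameters
    ----------
    pool : SpeciesPool or sequence of Strain
    f0 : optional warm-start abundances (same order as the pool).

    The returned state satisfies the KKT conditions of the concave program:
    survivor growth rates vanish and excluded strains have non-positive
    invasion growth, both to ~1e-9 or better.
    """
    strains = _as_strains(pool)
    S = len(strains)
    if S == 0:
        raise EquilibriumError("empty pool")
    A = _uptake_matrix(strains, env.R)
    active, kappa = _active_kappa(A, env)
    A_act = A[:, active]

    R_act_n = kappa.size
    if f0 is None:
        f = np.full(S, 1.0 / S)
        max_warm, chunk = 10000, 500
    else:
        f = np.maximum(np.asarray(f0, dtype=float), 1e-12)
        max_warm, chunk = 200, 50
    # run the multiplicative phase in chunks until the candidate survivor
    # set is comfortably below the competitive-exclusion bound (or we hit
    # the iteration budget; stragglers are handled by the active set)
    done = 0
    while done < max_warm:
        f = _multiplicative_phase(A_act, kappa, f, chunk)
        done += chunk
        if (f > 1e-8 * f.max()).sum() <= R_act_n + 20:
            break

    # --- active-set Newton with column generation ---------------------------
    # Competitive exclusion bounds the support by the number of consumed
    # resources, so the restricted Newton solves stay small even when the
    # candidate pool is large.  Strains the warm phase has not yet separated
    # are re-admitted later if they can invade the restricted optimum.
    R_act = kappa.size
    cap = R_act
    q = np.maximum(A_act.T @ f, 1e-300)
    grads = A_act @ (kappa / q) - 1.0
    support = np.zeros(S, dtype=bool)
    cand = np.flatnonzero((f > 1e-8 * f.max()) | (grads > 0))
    if len(cand) > cap:
        cand = cand[np.argsort(f[cand])[-cap:]]
    if len(cand) == 0:
        cand = [int(np.argmax(f))]
    support[cand] = True

    for _ in range(max_active_set_iter):
        idx = np.flatnonzero(support)
        f_s = np.maximum(f[idx], extinction_threshold)
        f_s, ok = _newton_on_support(A_act[idx], kappa, f_s)
        small = f_s <= 10 * extinction_threshold
        if small.any():
            if small.all():
                raise EquilibriumError("active-set collapse: no feasible support")
            support[idx[small]] = False
            f[idx] = np.maximum(f_s, 0.0)
            continue
        if (not ok or len(idx) > R_act) and len(idx) > R_act:
            # More members than active resources: the restricted optimum is
            # not interior.  Pivot: re-express the current consumption
            # vector with the minimum-total-abundance nonnegative
            # combination.  The basic LP solution has <= R_act positive
            # members and can only increase Phi (same q, smaller sum f),
            # which rules out cycling.
            q_cur = A_act[idx].T @ f_s
            lp = linprog(
                c=np.ones(len(idx)), A_eq=A_act[idx].T, b_eq=q_cur,
                bounds=(0, None), method="highs",
            )
            if not lp.success:
                raise EquilibriumError(f"pivot LP failed: {lp.message}")
            fb = lp.x
            pos = fb > extinction_threshold
            if 0 < pos.sum() < len(idx):
                support[:] = False
                support[idx[pos]] = True
                f = np.zeros(S)
                f[idx[pos]] = fb[pos]
                continue
            # LP kept everyone: fall through with the LP representation
            f_s = np.maximum(fb, extinction_threshold)
        if not ok and len(idx) <= R_act:
            # stagnation without boundary collapse: drop the smallest member
            support[idx[np.argmin(f_s)]] = False
            continue
        f = np.zeros(S)
        f[idx] = f_s
        # re-admit excluded strains that can invade the restricted optimum
        q = A_act.T @ f
        grads = A_act @ (kappa / q) - 1.0
        viol = np.flatnonzero(~support & (grads > 1e-10))
        if len(viol):
            if len(viol) > 10:
                viol = viol[np.argsort(grads[viol])[-10:]]
            support[viol] = True
            f[viol] = max(1e-6, extinction_threshold * 100)
            continue
        break
    else:
        raise EquilibriumError(
            f"active-set loop did not converge in {max_active_set_iter} iterations"
        )

    q = A_act.T @ f
    grads = A_act @ (kappa / q) - 1.0
    surv_res = float(np.max(np.abs(grads[support]))) if support.any() else 0.0
    excl = ~support
    excl_res = float(np.max(grads[excl])) if excl.any() else -np.inf
    if surv_res > 1e-8 or excl_res > 1e-8:
        raise EquilibriumError(
            f"KKT residuals too large: survivors {surv_res:.2e}, "
            f"excluded {excl_res:.2e}"
        )
    degenerate = bool(excl.any() and np.max(grads[excl]) > -DEGENERACY_TOL)

    h = np.full(env.R, np.nan)
    h[active] = kappa / q
    h_bar = float(np.nanmean(h[active]))
    g = np.full(env.R, np.nan)
    g[active] = h[active] / h_bar - 1.0

    return CommunityState(
        strains=strains, env=env, f=f, h=h, g=g, h_bar=h_bar,
        active_resources=active, survivor_mask=support,
        kkt_survivor_residual=surv_res,
        kkt_excluded_residual=max(excl_res, 0.0) if np.isfinite(excl_res) else 0.0,
        degenerate=degenerate, tol=tol,
    )


def integrate_dynamics(
    pool,
    env: Environment,
    f0: np.ndarray,
    t_max: float = 1e4,
    tol: float = 1e-10,
    n_out: int = 50,
    settle: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the relative-abundance ODE from a strictly positive start.

    Returns ``(t, F)`` with ``F[k]`` the abundance vector at ``t[k]``.  With
    ``settle=True`` integration continues in chunks of ``t_max`` (up to 20)
    until the dynamics are quiescent, which is what the oracle comparison
    against :func:`compute_equilibrium` uses.
    """
    strains = _as_strains(pool)
    f0 = np.asarray(f0, dtype=float)
    if np.any(f0 <= 0):
        raise ValueError("f0 must be strictly positive on all pool members")
    A = _uptake_matrix(strains, env.R)
    active, kappa = _active_kappa(A, env)
    A_act = A[:, active]

    def rhs(t, f):
        fp = np.maximum(f, 0.0)
        q = np.maximum(A_act.T @ fp, 1e-300)
        return fp * (A_act @ (kappa / q) - 1.0)

    ts, fs = [], []
    f_start, t0 = f0, 0.0
    n_chunks = 20 if settle else 1
    for _ in range(n_chunks):
        t_eval = np.linspace(t0, t0 + t_max, n_out)
        sol = solve_ivp(
            rhs, (t0, t0 + t_max), f_start, method="LSODA",
            t_eval=t_eval, rtol=1e-10, atol=1e-14,
        )
        if not sol.success:
            raise EquilibriumError(f"ODE integration failed: {sol.message}")
        ts.append(sol.t)
        fs.append(sol.y.T)
        f_start, t0 = sol.y[:, -1], sol.t[-1]
        if np.max(np.abs(rhs(t0, f_start))) < 0.01 * tol:
            break
    F = np.vstack(fs)
    if np.any(F[-1] < -tol):
        raise EquilibriumError("negative abundances beyond tolerance")
    return np.concatenate(ts), F
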