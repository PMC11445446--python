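"""Random species pools and resource environments.

Communities are assembled from a pool of strains whose resource-uptake
phenotypes are drawn from a common statistical ensemble.  Each strain is
summarized by an overall (log) uptake budget ``X = log(sum_i r_i)`` and a
normalized consumption strategy ``alpha = r / sum_i r_i`` on the resource
simplex.  The default "binary" scheme gives each strain an independent
probability ``R0/R`` of using each resource, uniform effort over the used
set, and a Gaussian budget ``X ~ N(0, std_X^2)``.  Only the spread of X
matters: the relative-abundance dynamics are invariant under a common shift
of all budgets.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Environment",
    "Strain",
    "SpeciesPool",
    "sample_pool",
    "make_environment",
    "register_scheme",
]


@dataclasses.dataclass(frozen=True)
class Environment:
    """A fixed set of externally supplied resources.

    Attributes
    ----------
    R : int
        Number of resources (>= 2).
    K : ndarray, shape (R,)
        Positive supply rates, arbitrary units.
    """

    R: int
    K: np.ndarray

    def __post_init__(self):
        K = np.asarray(self.K, dtype=float)
        if self.R < 2:
            raise ValueError(f"need at least 2 resources, got R={self.R}")
        if K.shape != (self.R,):
            raise ValueError(f"K must have shape ({self.R},), got {K.shape}")
        if not np.all(K > 0):
            raise ValueError("all supply rates K_i must be positive")
        object.__setattr__(self, "K", K)

    @property
    def kappa(self) -> np.ndarray:
        """Supply shares kappa_i = K_i / sum_j K_j."""
        return self.K / self.K.sum()

    @property
    def K_bar(self) -> float:
        """Average supply rate."""
        return float(self.K.mean())

    @property
    def var_K_rel(self) -> float:
        """Scaled supply variance Var(K) / K_bar^2 (population variance)."""
        return float(self.K.var() / self.K.mean() ** 2)


@dataclasses.dataclass
class Strain:
    """One consumer phenotype.

    ``alpha`` lives on the resource simplex; uptake rates are recovered as
    ``r_i = exp(X) * alpha_i``.
    """

    id: str
    X: float
    alpha: np.ndarray
    lineage_id: str | None = None
    parent_id: str | None = None
    n_mutations: int = 0

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.lineage_id is None:
            self.lineage_id = self.id
        if np.any(self.alpha < 0):
            raise ValueError(f"strain {self.id}: alpha must be non-negative")
        tot = self.alpha.sum()
        if not np.isclose(tot, 1.0, atol=1e-8):
            raise ValueError(f"strain {self.id}: alpha sums to {tot}, not 1")
        if not np.any(self.alpha > 0):
            raise ValueError(f"strain {self.id}: empty support")

    @property
    def support(self) -> np.ndarray:
        """Indices of resources this strain consumes."""
        return np.flatnonzero(self.alpha > 0)

    @property
    def uptake(self) -> np.ndarray:
        """Absolute uptake rates r_i = e^X alpha_i."""
        return np.exp(self.X) * self.alpha


@dataclasses.dataclass
class SpeciesPool:
    """An ordered collection of strains drawn from one sampling scheme."""

    strains: list[Strain]
    R: int
    R0: float
    std_X: float
    scheme: str
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.strains)

    @property
    def S(self) -> int:
        return len(self.strains)

    def uptake_matrix(self) -> np.ndarray:
        """(S, R) matrix of uptake rates r_{mu,i}."""
        A = np.empty((len(self.strains), self.R))
        for k, st in enumerate(self.strains):
            A[k] = st.uptake
        return A


# ---------------------------------------------------------------------------
# sampling schemes

def _binary_alpha(rng: np.random.Generator, R: int, R0: float) -> np.ndarray:
    # each resource used independently w.p. R0/R; empty supports resampled
    while True:
        used = rng.random(R) < R0 / R
        if used.any():
            break
    return used / used.sum()


def _dirichlet_alpha(rng: np.random.Generator, R: int, R0: float) -> np.ndarray:
    # symmetric Dirichlet over all R resources, concentration chosen so the
    # strategy spread E[sum alpha^2] = 1/R0 matches the binary scheme
    if R0 >= R:
        c = 1e6
    else:
        c = max((R0 - 1.0) / (R - R0), 1e-3)
    return rng.dirichlet(np.full(R, c))


_SCHEMES: dict[str, Callable[[np.random.Generator, int, float], np.ndarray]] = {
    "binary": _binary_alpha,
    "dirichlet": _dirichlet_alpha,
}


def register_scheme(
    name: str, fn: Callable[[np.random.Generator, int, float], np.ndarray]
) -> None:
    """Register a custom strategy sampler ``fn(rng, R, R0) -> alpha``."""
    _SCHEMES[name] = fn


def sample_pool(
    R: int,
    R0: float,
    S: int,
    std_X: float = 0.0,
    scheme: str = "binary",
    seed: int | np.random.Generator | None = None,
    id_prefix: str = "s",
) -> SpeciesPool:
    """Draw a random species pool.

    Parameters
    ----------
    R, R0 : number of resources; expected resources used per strain.
    S : pool size (number of strains sampled).
    std_X : standard deviation of the Gaussian log uptake budget.
    scheme : name of a registered strategy sampler.
    seed : int seed or a Generator (consumed in place).
    """
    if not (1 <= R0 <= R):
        raise ValueError(f"require 1 <= R0 <= R, got R0={R0}, R={R}")
    if S < 1:
        raise ValueError(f"pool size must be >= 1, got S={S}")
    if std_X < 0:
        raise ValueError("std_X must be non-negative")
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; known: {sorted(_SCHEMES)}")
    rng = np.random.default_rng(seed)
    draw = _SCHEMES[scheme]
    strains = []
    for k in range(S):
        alpha = draw(rng, R, R0)
        X = float(rng.normal(0.0, std_X)) if std_X > 0 else 0.0
        strains.append(Strain(id=f"{id_prefix}{k:05d}", X=X, alpha=alpha))
    return SpeciesPool(
        strains=strains, R=R, R0=R0, std_X=std_X, scheme=scheme,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def make_environment(
    R: int,
    mode: str = "uniform",
    cv: float = 0.0,
    seed: int | np.random.Generator | None = None,
    K_bar: float = 1.0,
) -> Environment:
    """Construct a supply environment.

    Modes
    -----
    ``uniform``
        All supply rates equal to ``K_bar``.
    ``cv``
        Deterministic two-level vector with Var(K)/K_bar^2 = cv^2 exactly.
    ``cv_gaussian``
        i.i.d. Gaussian K ~ N(K_bar, (cv*K_bar)^2), clipped at 0.1*K_bar.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    if mode == "uniform" or cv == 0:
        K = np.full(R, K_bar)
    elif mode == "cv":
        # +/- pattern, centered and scaled to unit rms, hits cv^2 exactly
        v = np.where(np.arange(R) < R // 2, 1.0, -1.0)
        v = v - v.mean()
        v = v / np.sqrt(np.mean(v**2))
        K = K_bar * (1.0 + cv * v)
        if np.any(K <= 0):
            raise ValueError(f"cv={cv} produces non-positive supply rates")
    elif mode == "cv_gaussian":
        rng = np.random.default_rng(seed)
        K = np.maximum(rng.normal(K_bar, cv * K_bar, size=R), 0.1 * K_bar)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return Environment(R=R, K=K)


# ---------------------------------------------------------------------------
# calibration


@dataclasses.dataclass
class CalibrationResult:
    S: int
    std_X: float
    method: str                  # "table" | "pilot"
    predicted_S_star: float
    target_S_star: float
    flag: str | None = None      # e.g. "closest_achievable"


def calibrate_pool(
    target_niche_saturation: float,
    target_permissivity: float,
    R: int,
    R0: float,
    env: Environment | None = None,
    scheme: str = "binary",
    seed: int | None = None,
    n_pilot: int = 20,
    rel_tol: float = 0.05,
) -> CalibrationResult:
    """Choose (S, std_X) so assembly hits a target niche saturation S*/R at
    a given sampling permissivity S*/S.

    The pool size follows from the definitions, S = S*_target / permissivity.
    The budget spread is found by inverting the survivor-count surrogate
    (monotone decreasing in std_X); off-table ensembles fall back to
    bisection on pilot assemblies.  Saturation targets unreachable even at
    vanishing budget spread return the closest achievable point, flagged.
    """
    from . import theory as _theory

    if not (0 < target_niche_saturation <= 1):
        raise ValueError("target niche saturation must be in (0, 1]")
    if not (0 < target_permissivity <= 1):
        raise ValueError("target permissivity must be in (0, 1]")
    if env is None:
        env = make_environment(R)
    target = target_niche_saturation * R
    S = int(round(target / target_permissivity))
    if S < target:
        raise ValueError("permissivity > 1 implied: S < S* target")

    entries = _theory._table_entries(R, R0, scheme) if env.var_K_rel < 1e-12 else []
    if entries:
        xs = sorted({e["std_X"] for e in entries})
        lo, hi = min(xs), max(xs)

        def pred(sx: float) -> float:
            return _theory.predict_survivors(S, sx, R, R0, env, scheme).S_star

        p_lo, p_hi = pred(lo), pred(hi)
        if target > p_lo:
            flag = None if target <= p_lo * (1 + rel_tol) else "closest_achievable"
            return CalibrationResult(S, lo, "table", p_lo, target, flag)
        if target < p_hi:
            # need more spread than tabulated; fall through to pilots
            pass
        else:
            from scipy.optimize import brentq

            sx = float(brentq(lambda x: pred(x) - target, lo, hi, xtol=1e-5))
            return CalibrationResult(S, sx, "table", pred(sx), target)

    # pilot bisection (monotone decreasing mean S* in std_X)
    from .equilibrium import compute_equilibrium

    def pilot_mean(sx: float) -> float:
        ss = np.random.SeedSequence([seed if seed is not None else 0, hash(round(sx, 8)) & 0x7FFFFFFF])
        vals = []
        for child in ss.spawn(n_pilot):
            pool = sample_pool(R, R0, S, sx, scheme=scheme,
                               seed=np.random.default_rng(child))
            vals.append(compute_equilibrium(pool, env).n_survivors)
        return float(np.mean(vals))

    lo, hi = 1e-3, 0.5
    m_lo = pilot_mean(lo)
    if target > m_lo:
        flag = None if target <= m_lo * (1 + rel_tol) else "closest_achievable"
        return CalibrationResult(S, lo, "pilot", m_lo, target, flag)
    while pilot_mean(hi) > target and hi < 8:
        hi *= 2
    for _ in range(12):
        mid = np.sqrt(lo * hi)
        if pilot_mean(mid) > target:
            lo = mid
        else:
            hi = mid
    sx = float(np.sqrt(lo * hi))
    return CalibrationResult(S, sx, "pilot", pilot_mean(sx), target)
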