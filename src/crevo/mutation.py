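"""Mutant phenotypes, invasion fitness, and distributions of fitness effects.

A mutation shifts a strain's uptake budget (X -> X + dX) and/or its
consumption strategy (alpha -> alpha + d_alpha, staying on the simplex).
The canonical single-resource moves are the knock-out (lose a used
resource, remaining effort renormalized) and the knock-in (gain an unused
resource at the mean share of the current repertoire).

The invasion fitness of a rare mutant is its per-capita growth rate at the
unperturbed resident equilibrium,

    s_exact  = e^(X+dX) * sum_i (alpha + d_alpha)_i h_i - 1,

and the community-ecology approximation used by the analytic theory is

    s_approx = dX + sum_i d_alpha_i g_i,

with g_i the excess resource availability.  The exact value drives all
simulated fates; the approximation is carried alongside for validation.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .equilibrium import CommunityState, compute_equilibrium
from .sampling import Environment, Strain

__all__ = [
    "Mutation",
    "MutationError",
    "DFESummary",
    "knockout",
    "knockin",
    "multi_mutation",
    "apply_mutation",
    "invasion_fitness",
    "enumerate_dfe",
    "monoculture_fitness",
    "dfe_correlation",
]


class MutationError(ValueError):
    pass


@dataclasses.dataclass
class Mutation:
    """A phenotype change relative to a parent strain.

    ``d_alpha`` sums to zero so the mutant strategy stays on the simplex;
    ``norm_d_alpha`` is its Euclidean magnitude, the phenotypic effect size.
    """

    parent_id: str
    kind: str  # knockout | knockin | multi | budget_only
    target: int | None
    dX: float
    d_alpha: np.ndarray

    def __post_init__(self):
        self.d_alpha = np.asarray(self.d_alpha, dtype=float)
        if abs(self.d_alpha.sum()) > 1e-10:
            raise MutationError(
                f"d_alpha must sum to 0, got {self.d_alpha.sum():.3e}"
            )

    @property
    def norm_d_alpha(self) -> float:
        return float(np.linalg.norm(self.d_alpha))


def knockout(parent: Strain, i: int, dX: float = 0.0) -> Mutation:
    """Lose the ability to consume resource ``i``; effort renormalizes.

    For a uniform-strategy parent using k resources the effect size is
    ||d_alpha|| = 1/sqrt(k(k-1)) ~ 1/k.
    """
    if parent.alpha[i] <= 0:
        raise MutationError(f"resource {i} is not used by strain {parent.id}")
    if len(parent.support) < 2:
        raise MutationError("cannot knock out the last used resource")
    new_alpha = parent.alpha.copy()
    new_alpha[i] = 0.0
    new_alpha /= new_alpha.sum()
    return Mutation(parent.id, "knockout", i, dX, new_alpha - parent.alpha)


def knockin(parent: Strain, i: int, dX: float = 0.0) -> Mutation:
    """Gain the ability to consume resource ``i``.

    The new resource receives the mean strategy share of the currently used
    resources before renormalization, so a uniform parent stays uniform
    over the enlarged repertoire and ||d_alpha|| ~ 1/k.
    """
    if parent.alpha[i] > 0:
        raise MutationError(f"resource {i} is already used by strain {parent.id}")
    k = len(parent.support)
    share = 1.0 / k  # mean share of used resources (alpha sums to 1)
    new_alpha = parent.alpha.copy()
    new_alpha[i] = share
    new_alpha /= new_alpha.sum()
    return Mutation(parent.id, "knockin", i, dX, new_alpha - parent.alpha)


def multi_mutation(parent: Strain, d_alpha: np.ndarray, dX: float = 0.0) -> Mutation:
    """A general strategy shift affecting any number of resources."""
    d_alpha = np.asarray(d_alpha, dtype=float)
    if abs(d_alpha.sum()) > 1e-8:
        raise MutationError("d_alpha must sum to zero")
    d_alpha = d_alpha - d_alpha.mean()  # exact zero-sum
    if np.any(parent.alpha + d_alpha < -1e-12):
        raise MutationError("d_alpha drives some strategy entries negative")
    kind = "budget_only" if np.allclose(d_alpha, 0.0) else "multi"
    return Mutation(parent.id, kind, None, dX, d_alpha)


def apply_mutation(parent: Strain, mut: Mutation, new_id: str) -> Strain:
    """Construct the mutant strain (lineage metadata inherited)."""
    alpha = np.maximum(parent.alpha + mut.d_alpha, 0.0)
    alpha /= alpha.sum()
    return Strain(
        id=new_id,
        X=parent.X + mut.dX,
        alpha=alpha,
        lineage_id=parent.lineage_id,
        parent_id=parent.id,
        n_mutations=parent.n_mutations + 1,
    )


# ---------------------------------------------------------------------------
# invasion fitness


def _parent_index(state: CommunityState, parent_id: str) -> int:
    k = state.index_of(parent_id)
    if not state.survivor_mask[k]:
        raise MutationError(f"parent {parent_id} is not a survivor")
    return k


def invasion_fitness(state: CommunityState, mut: Mutation) -> tuple[float, float]:
    """Exact and approximate invasion fitness of a rare mutant.

    The exact value is the mutant's per-capita growth rate at the resident
    equilibrium; the approximate value is the linearized community form
    ``dX + sum_i d_alpha_i g_i``.  Mutations reaching into resources with
    no current consumer have undefined availability and are rejected.
    """
    k = _parent_index(state, mut.parent_id)
    parent = state.strains[k]
    alpha_new = np.maximum(parent.alpha + mut.d_alpha, 0.0)
    used = alpha_new > 0
    if np.any(used & ~state.active_resources):
        raise MutationError(
            "mutation targets a resource with no current consumer; "
            "its availability is undefined in the coarse-grained model"
        )
    h = state.h
    s_exact = float(
        np.exp(parent.X + mut.dX) * np.sum(alpha_new[used] * h[used]) - 1.0
    )
    g = state.g
    nz = mut.d_alpha != 0
    s_approx = float(mut.dX + np.sum(mut.d_alpha[nz] * g[nz]))
    return s_exact, s_approx


def monoculture_fitness(parent: Strain, env: Environment, mut: Mutation) -> float:
    """Fitness effect of the mutation if the parent lived alone.

    The parent is equilibrated in monoculture (trivially f = 1) and the
    linearized fitness is evaluated with the monoculture excess
    availabilities.  Only mutations supported within the parent's
    repertoire are defined (knock-ins reach resources with no monoculture
    consumer).
    """
    nz = np.flatnonzero(mut.d_alpha != 0)
    if np.any(parent.alpha[nz] <= 0):
        raise MutationError(
            "monoculture fitness undefined: mutation uses resources outside "
            "the parent repertoire"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lone strain leaves resources unconsumed
        mono = compute_equilibrium([parent], env)
    g = mono.g
    return float(mut.dX + np.sum(mut.d_alpha[nz] * g[nz]))


# ---------------------------------------------------------------------------
# DFE enumeration

_DFE_COLUMNS = [
    "parent_id", "kind", "target", "dX", "norm_d_alpha",
    "s_inv", "s_inv_approx", "s_mono",
]


@dataclasses.dataclass
class DFESummary:
    """All enumerated single-resource mutations of one community state."""

    samples: pd.DataFrame

    @property
    def sigma_hat(self) -> float:
        return float(self.samples["s_inv"].std(ddof=1))

    @property
    def mean_hat(self) -> float:
        return float(self.samples["s_inv"].mean())

    @property
    def beneficial_fraction(self) -> float:
        return float((self.samples["s_inv"] > 0).mean())

    def __len__(self) -> int:
        return len(self.samples)


def _survivor_arrays(state: CommunityState):
    surv = state.survivors
    strains = [state.strains[i] for i in surv]
    X = np.array([st.X for st in strains])
    Al = np.array([st.alpha for st in strains])  # (n, R)
    return strains, X, Al


def enumerate_dfe(
    state: CommunityState,
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
    include_monoculture: bool = False,
) -> DFESummary:
    """Enumerate every single-resource mutation of every survivor.

    Knock-outs cover each survivor's used resources (skipping
    single-resource specialists); knock-ins cover unused resources that
    have at least one consumer in the community.  All mutations are
    unweighted, mirroring an unbiased mutational scan.
    """
    kinds = set(kinds)
    strains, X, Al = _survivor_arrays(state)
    h, g = state.h, state.g
    rows: list[tuple] = []
    for st, x, alpha in zip(strains, X, Al):
        supp = np.flatnonzero(alpha > 0)
        T = np.exp(x + dX)  # e^{X+dX}; sum_i e^X alpha_i h_i = 1 at equilibrium
        if "knockout" in kinds and len(supp) >= 2:
            b = np.exp(x) * alpha[supp] * h[supp]  # per-resource growth share
            s_ex = T / np.exp(x) * (1.0 - b) / (1.0 - alpha[supp]) - 1.0
            # d_alpha for knockout of i: alpha*a_i/(1-a_i) off-target, -a_i on target
            a_i = alpha[supp]
            scale = a_i / (1.0 - a_i)
            sq = (alpha**2).sum()
            norm2 = scale**2 * (sq - a_i**2) + a_i**2
            s_ap = dX - a_i * g[supp] + scale * (
                (alpha * np.where(np.isnan(g), 0.0, g)).sum() - a_i * g[supp]
            )
            for j, i in enumerate(supp):
                rows.append((st.id, "knockout", int(i), dX,
                             float(np.sqrt(norm2[j])),
                             float(s_ex[j]), float(s_ap[j]), np.nan))
        if "knockin" in kinds:
            eligible = np.flatnonzero(
                (alpha == 0) & state.active_resources
            )
            if len(eligible):
                k = len(supp)
                m = 1.0 / k
                s_ex_in = T / np.exp(x) * (1.0 + m * np.exp(x) * h[eligible]) / (1.0 + m) - 1.0
                # d_alpha: target gains m/(1+m); others scaled by 1/(1+m)
                shrink = 1.0 / (1.0 + m)
                sq = (alpha**2).sum()
                norm2_in = (shrink - 1.0) ** 2 * sq + (m * shrink) ** 2
                g_dot = (alpha * np.where(np.isnan(g), 0.0, g)).sum()
                s_ap_in = dX + (shrink - 1.0) * g_dot + m * shrink * g[eligible]
                for j, i in enumerate(eligible):
                    rows.append((st.id, "knockin", int(i), dX,
                                 float(np.sqrt(norm2_in)),
                                 float(s_ex_in[j]), float(s_ap_in[j]), np.nan))
    df = pd.DataFrame(rows, columns=_DFE_COLUMNS)
    if include_monoculture:
        mono_cache: dict[str, np.ndarray] = {}
        s_mono = np.full(len(df), np.nan)
        for r, row in enumerate(df.itertuples(index=False)):
            if row.kind != "knockout":
                continue  # knock-ins have undefined monoculture availability
            pid = row.parent_id
            if pid not in mono_cache:
                parent = state.strains[state.index_of(pid)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mono_cache[pid] = compute_equilibrium([parent], state.env).g
            parent = state.strains[state.index_of(pid)]
            gm = mono_cache[pid]
            a = parent.alpha
            i = int(row.target)
            supp = np.flatnonzero(a > 0)
            scale = a[i] / (1.0 - a[i])
            gm_dot = np.sum(a[supp] * gm[supp])
            s_mono[r] = row.dX - a[i] * gm[i] + scale * (gm_dot - a[i] * gm[i])
        df["s_mono"] = s_mono
    return DFESummary(samples=df)


def dfe_correlation(
    states: Sequence[CommunityState],
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
) -> tuple[float, bool]:
    """Pearson correlation between community and monoculture fitness effects.

    Pooled over all enumerated mutations of all states.  Under uniform
    resource supply every monoculture knockout has the same fitness effect
    (the monoculture availabilities are equal across the repertoire), so
    the correlation is undefined; that case returns (0.0, True) where the
    flag marks degeneracy.
    """
    frames = [
        enumerate_dfe(st, kinds=kinds, dX=dX, include_monoculture=True).samples
        for st in states
    ]
    df = pd.concat(frames, ignore_index=True).dropna(subset=["s_mono"])
    if len(df) < 2:
        raise MutationError("need at least two mutations with monoculture fitness")
    s_inv = df["s_inv"].to_numpy()
    s_mono = df["s_mono"].to_numpy()
    if np.std(s_mono) < 1e-12 * max(1.0, np.std(s_inv)) or np.std(s_inv) < 1e-15:
        return 0.0, True
    r, _ = stats.pearsonr(s_inv, s_mono)
    return float(r), False
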