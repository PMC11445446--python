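"""Fate of a successful mutant: coexistence, replacement, and extinctions.

A beneficial mutant is introduced into an equilibrated community and the
system is re-equilibrated.  Under the default *sequential* policy only the
current survivors plus the mutant compete; the *reinvasion* and
*simultaneous* policies let the full original species pool re-enter, so
previously excluded species can be "rescued" by the perturbation.  Because
the uninvadable equilibrium of a candidate set is unique, reinvasion and
simultaneous assembly coincide at the level of final states; both are kept
as explicit policies for protocol clarity.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .equilibrium import CommunityState, compute_equilibrium
from .mutation import (
    Mutation,
    MutationError,
    apply_mutation,
    enumerate_dfe,
    invasion_fitness,
)

__all__ = [
    "InvasionResult",
    "ExhaustionError",
    "resolve_invasion",
    "sample_successful_mutation",
    "first_step_ensemble",
    "coexistence_probability",
    "extinction_statistics",
]

FATE_NOT_BENEFICIAL = "NOT_BENEFICIAL"
FATE_COEXISTS = "COEXISTS"
FATE_REPLACES_PARENT = "REPLACES_PARENT"
FATE_MUTANT_DIES = "MUTANT_DIES"


class ExhaustionError(RuntimeError):
    """No beneficial mutation exists in the current state."""


@dataclasses.dataclass
class InvasionResult:
    mutation: Mutation
    mutant_id: str
    s_inv: float
    fate: str
    extinct_ids: list[str]          # non-parent extinctions
    parent_extinct: bool
    rescued_ids: list[str]
    pre_state: CommunityState
    post_state: CommunityState | None
    policy: str
    f_parent_pre: float
    degenerate: bool = False


def resolve_invasion(
    pre_state: CommunityState,
    mut: Mutation,
    policy: str = "sequential",
    mutant_id: str | None = None,
) -> InvasionResult:
    """Introduce a mutant and re-equilibrate.

    ``sequential`` competes the mutant against the pre-invasion survivors;
    ``reinvasion``/``simultaneous`` compete it against the full original
    candidate pool (rescues possible).  A non-beneficial mutant leaves the
    state untouched.
    """
    if policy not in ("sequential", "reinvasion", "simultaneous"):
        raise ValueError(f"unknown policy {policy!r}")
    s_inv, _ = invasion_fitness(pre_state, mut)
    parent_idx = pre_state.index_of(mut.parent_id)
    parent = pre_state.strains[parent_idx]
    f_parent_pre = float(pre_state.f[parent_idx])
    if mutant_id is None:
        mutant_id = f"{mut.parent_id}.m"
    mutant = apply_mutation(parent, mut, mutant_id)

    if s_inv <= 0:
        return InvasionResult(
            mutation=mut, mutant_id=mutant_id, s_inv=s_inv,
            fate=FATE_NOT_BENEFICIAL, extinct_ids=[], parent_extinct=False,
            rescued_ids=[], pre_state=pre_state, post_state=None,
            policy=policy, f_parent_pre=f_parent_pre,
        )

    pre_surv_ids = set(pre_state.survivor_ids)
    if policy == "sequential":
        base = pre_state.survivor_strains()
        f0 = np.append(pre_state.f[pre_state.survivors], 1e-6)
        candidates = base + [mutant]
    else:
        base = list(pre_state.strains)
        f0 = np.append(np.maximum(pre_state.f, 1e-8), 1e-6)
        candidates = base + [mutant]
        if policy == "simultaneous":
            f0 = None  # fresh assembly from scratch
    post = compute_equilibrium(candidates, pre_state.env, f0=f0)

    post_surv_ids = set(post.survivor_ids)
    mutant_alive = mutant_id in post_surv_ids
    parent_alive = mut.parent_id in post_surv_ids
    extinct = sorted(pre_surv_ids - post_surv_ids - {mut.parent_id})
    rescued = sorted(post_surv_ids - pre_surv_ids - {mutant_id})
    if mutant_alive and parent_alive:
        fate = FATE_COEXISTS
    elif mutant_alive:
        fate = FATE_REPLACES_PARENT
    else:
        fate = FATE_MUTANT_DIES
    return InvasionResult(
        mutation=mut, mutant_id=mutant_id, s_inv=s_inv, fate=fate,
        extinct_ids=extinct, parent_extinct=not parent_alive,
        rescued_ids=rescued, pre_state=pre_state, post_state=post,
        policy=policy, f_parent_pre=f_parent_pre,
        degenerate=post.degenerate,
    )


def sample_successful_mutation(
    pre_state: CommunityState,
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
    rng: np.random.Generator | None = None,
    parent_weighting: str = "abundance",
) -> Mutation:
    """Draw one establishing mutation.

    The sampling law factorizes as (mutational supply) x (establishment):
    parents are chosen proportionally to their abundance f_P (or uniformly
    with ``parent_weighting='uniform'``), the target resource uniformly
    among eligible moves, and the candidate establishes with probability
    proportional to max(s_inv, 0).  Raises :class:`ExhaustionError` when no
    beneficial mutation exists.
    """
    rng = np.random.default_rng(rng)
    dfe = enumerate_dfe(pre_state, kinds=kinds, dX=dX)
    df = dfe.samples
    if not len(df):
        raise ExhaustionError("no eligible mutations in this state")
    f_by_id = {
        pre_state.strains[i].id: pre_state.f[i] for i in pre_state.survivors
    }
    fP = df["parent_id"].map(f_by_id).to_numpy()
    if parent_weighting == "uniform":
        fP = np.ones_like(fP)
    n_moves = df.groupby("parent_id")["s_inv"].transform("size").to_numpy()
    w = (fP / n_moves) * np.maximum(df["s_inv"].to_numpy(), 0.0)
    total = w.sum()
    if total <= 0:
        raise ExhaustionError("no beneficial mutation in this state")
    row = df.iloc[int(rng.choice(len(df), p=w / total))]
    from .mutation import knockin, knockout  # local to avoid cycle at import

    parent = pre_state.strains[pre_state.index_of(row["parent_id"])]
    maker = knockout if row["kind"] == "knockout" else knockin
    return maker(parent, int(row["target"]), float(row["dX"]))


def first_step_ensemble(
    pre_states: Sequence[CommunityState],
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
    policy: str = "sequential",
    parent_weighting: str = "abundance",
) -> list[InvasionResult]:
    """Monte-Carlo first-step experiments over a set of communities.

    Each draw picks a community (round-robin), samples one establishing
    mutation, and resolves its invasion.  Communities whose beneficial
    mutations are exhausted are skipped.
    """
    rng = np.random.default_rng(rng)
    results: list[InvasionResult] = []
    n_states = len(pre_states)
    k = 0
    attempts = 0
    while len(results) < n_samples and attempts < 10 * n_samples:
        attempts += 1
        state = pre_states[k % n_states]
        k += 1
        try:
            mut = sample_successful_mutation(
                state, kinds=kinds, dX=dX, rng=rng,
                parent_weighting=parent_weighting,
            )
        except ExhaustionError:
            continue
        results.append(
            resolve_invasion(state, mut, policy=policy,
                             mutant_id=f"{mut.parent_id}.m{len(results)}")
        )
    return results


def coexistence_probability(
    pre_states: Sequence[CommunityState],
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
    n_samples: int = 100,
    rng: np.random.Generator | None = None,
    policy: str = "sequential",
    results: Sequence[InvasionResult] | None = None,
) -> tuple[float, float]:
    """P(mutant coexists with parent | successful invasion), with SE.

    Rare MUTANT_DIES outcomes (possible only when rescued species compete)
    are excluded from numerator and denominator.  Pass precomputed
    ``results`` to reuse an ensemble.
    """
    if results is None:
        results = first_step_ensemble(
            pre_states, kinds=kinds, dX=dX, n_samples=n_samples,
            rng=rng, policy=policy,
        )
    fates = [r.fate for r in results if r.fate in (FATE_COEXISTS,
                                                   FATE_REPLACES_PARENT)]
    n = len(fates)
    if n == 0:
        raise RuntimeError("no successful invasions to estimate P_coex from")
    p = sum(f == FATE_COEXISTS for f in fates) / n
    se = np.sqrt(p * (1 - p) / n)
    return float(p), float(se)


# ---------------------------------------------------------------------------
# extinction statistics (saturated-community invasion aftermath)


def _shared_resources(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum((a > 0) & (b > 0)))


def extinction_statistics(
    results: Sequence[InvasionResult],
    n_abundance_bins: int = 10,
    bin_mode: str = "log",
) -> dict:
    """Aggregate the aftermath of successful invasions.

    Returns a dict with:

    - ``mean_extinctions``: mean non-parent extinctions per successful
      invasion;
    - ``extinction_counts`` / ``poisson_reference``: the count histogram
      and a Poisson pmf matched on the empirical zero fraction,
      lambda = -log P(0);
    - ``shared_displaced`` / ``shared_background``: resources jointly used
      with the mutant, for displaced vs. all resident species;
    - ``abundance_bin_edges`` / ``extinction_prob_by_abundance``:
      extinction probability within pre-invasion abundance quantile bins;
    - ``fold_change_target_use``: per mutation kind, P(displaced uses the
      target resource) / P(resident uses it).
    """
    results = [r for r in results if r.fate in (FATE_COEXISTS,
                                                FATE_REPLACES_PARENT)]
    if not results:
        raise ValueError("no successful invasions supplied")

    counts = []
    shared_disp, shared_bg = [], []
    f_all, died_all = [], []
    target_rows = []  # (kind, displaced?, uses_target)
    for r in results:
        pre = r.pre_state
        mutant_alpha = np.maximum(
            pre.strains[pre.index_of(r.mutation.parent_id)].alpha
            + r.mutation.d_alpha, 0.0,
        )
        extinct = set(r.extinct_ids)
        counts.append(len(extinct))
        target = r.mutation.target
        for i in pre.survivors:
            st = pre.strains[i]
            if st.id == r.mutation.parent_id:
                continue
            died = st.id in extinct
            sh = _shared_resources(st.alpha, mutant_alpha)
            shared_bg.append(sh)
            if died:
                shared_disp.append(sh)
            f_all.append(pre.f[i])
            died_all.append(died)
            if target is not None:
                target_rows.append(
                    (r.mutation.kind, died, bool(st.alpha[target] > 0))
                )

    counts = np.asarray(counts)
    p0 = float(np.mean(counts == 0))
    if p0 > 0:
        lam = -np.log(p0)
        kmax = int(counts.max()) + 1
        from scipy.stats import poisson
        poisson_ref = {"lambda": float(lam),
                       "pmf": poisson.pmf(np.arange(kmax + 1), lam).tolist()}
    else:
        poisson_ref = {"lambda": None, "pmf": None, "flag": "P(0)=0"}

    f_all = np.asarray(f_all)
    died_all = np.asarray(died_all)
    if bin_mode == "log":
        # equal bins in log relative abundance (matching how abundance
        # distributions are usually displayed)
        edges = np.geomspace(f_all.min(), f_all.max(), n_abundance_bins + 1)
    elif bin_mode == "quantile":
        edges = np.quantile(f_all, np.linspace(0, 1, n_abundance_bins + 1))
    else:
        raise ValueError(f"unknown bin_mode {bin_mode!r}")
    edges[0], edges[-1] = 0.0, f_all.max() * (1 + 1e-12)
    which = np.clip(np.searchsorted(edges, f_all, side="right") - 1,
                    0, n_abundance_bins - 1)
    prob_by_bin = np.array([
        died_all[which == b].mean() if np.any(which == b) else np.nan
        for b in range(n_abundance_bins)
    ])

    folds = {}
    tdf = pd.DataFrame(target_rows, columns=["kind", "died", "uses_target"])
    for kind, sub in tdf.groupby("kind"):
        p_bg = sub["uses_target"].mean()
        disp = sub[sub["died"]]
        if len(disp) == 0 or p_bg == 0:
            folds[kind] = np.nan
        else:
            folds[kind] = float(disp["uses_target"].mean() / p_bg)

    return {
        "n_invasions": len(results),
        "mean_extinctions": float(counts.mean()),
        "extinction_counts": np.bincount(counts).tolist(),
        "poisson_reference": poisson_ref,
        "shared_displaced": np.asarray(shared_disp),
        "shared_background": np.asarray(shared_bg),
        "abundance_bin_edges": edges,
        "extinction_prob_by_abundance": prob_by_bin,
        "fold_change_target_use": folds,
    }
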