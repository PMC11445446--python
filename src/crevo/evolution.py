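"""Multi-step mutation-limited (SSWM) evolution with lineage tracking.

One mutation segregates at a time: an establishing mutation is drawn
(parents weighted by abundance, establishment weight proportional to
invasion fitness), its invasion is resolved sequentially, and the
community relaxes to the new uninvadable equilibrium before the next
mutation arises.  "Time" is the count of successful mutations.  The run
stops when any surviving strain has accumulated ``stop_mutations``
mutations (default 10) or when beneficial mutations are exhausted.

Mutant-parent coexistence events ("diversifications") found a pair of
branches; each strain carries the branch tags of all the divergences in
its ancestry, so the time until one branch of a pair loses its last
living member is well-defined even as further mutations accumulate.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np

from .equilibrium import CommunityState, compute_equilibrium
from .invasion import (
    FATE_COEXISTS,
    FATE_REPLACES_PARENT,
    ExhaustionError,
    resolve_invasion,
    sample_successful_mutation,
)
from .mutation import Mutation, enumerate_dfe
from .sampling import Environment, SpeciesPool

__all__ = [
    "EvolutionEvent",
    "PairRecord",
    "EvolutionLog",
    "run_evolution",
    "lineage_statistics",
    "dfe_snapshot_compare",
]


@dataclasses.dataclass
class EvolutionEvent:
    step: int
    parent_id: str
    mutant_id: str
    mutation: Mutation
    s_inv: float
    fate: str
    extinct_ids: list[str]
    parent_extinct: bool
    f_parent_pre: float
    f_extinct_pre: dict[str, float]
    n_survivors_post: int
    max_n_mutations: int


@dataclasses.dataclass
class PairRecord:
    """One mutant-parent divergence and the lifetime of its two branches."""

    pair_id: int
    birth_step: int
    parent_id: str
    mutant_id: str
    end_step: int | None = None      # None while both branches alive

    def duration(self, final_step: int) -> int:
        return (self.end_step if self.end_step is not None else final_step) \
            - self.birth_step

    def censored(self) -> bool:
        return self.end_step is None


@dataclasses.dataclass
class EvolutionLog:
    events: list[EvolutionEvent]
    pairs: list[PairRecord]
    strain_counts: list[int]          # survivors after each event (index 0 = initial)
    related_counts: list[int]         # survivors sharing a founder with another
    dfe_snapshots: dict[int, np.ndarray]
    initial_state: CommunityState
    final_state: CommunityState
    termination: str                  # "stop_rule" | "exhausted" | "max_steps"
    parent_tree: dict[str, str | None]

    @property
    def n_steps(self) -> int:
        return len(self.events)


def _related_count(state: CommunityState) -> int:
    from collections import Counter

    founders = Counter(st.lineage_id for st in state.survivor_strains())
    return sum(
        1 for st in state.survivor_strains() if founders[st.lineage_id] > 1
    )


def run_evolution(
    pool: SpeciesPool,
    env: Environment,
    kinds: Iterable[str] = ("knockout",),
    dX: float = 0.0,
    stop_mutations: int = 10,
    max_steps: int = 2000,
    seed=None,
    snapshot_every: int = 25,
    parent_weighting: str = "abundance",
) -> EvolutionLog:
    """Run one SSWM trajectory from a freshly assembled community."""
    rng = np.random.default_rng(seed)
    state = compute_equilibrium(pool, env)
    initial_state = state
    snapshots = {0: enumerate_dfe(state, kinds=kinds, dX=dX)
                 .samples["s_inv"].to_numpy()}
    events: list[EvolutionEvent] = []
    pairs: list[PairRecord] = []
    strain_counts = [state.n_survivors]
    related_counts = [_related_count(state)]
    parent_tree: dict[str, str | None] = {
        st.id: None for st in state.survivor_strains()
    }

    # branch tags: strain id -> list of (pair index, side); children inherit
    tags: dict[str, list[tuple[int, str]]] = {
        st.id: [] for st in state.survivor_strains()
    }
    pair_alive: list[dict[str, int]] = []   # per pair: live member count per side

    termination = "max_steps"
    for step in range(1, max_steps + 1):
        try:
            mut = sample_successful_mutation(
                state, kinds=kinds, dX=dX, rng=rng,
                parent_weighting=parent_weighting,
            )
        except ExhaustionError:
            termination = "exhausted"
            break
        mutant_id = f"m{step:05d}"
        res = resolve_invasion(state, mut, policy="sequential",
                               mutant_id=mutant_id)
        post = res.post_state
        parent_tree[mutant_id] = mut.parent_id

        # branch bookkeeping ------------------------------------------------
        mut_tags = list(tags.get(mut.parent_id, []))
        if res.fate == FATE_COEXISTS:
            pid = len(pairs)
            pairs.append(PairRecord(pid, step, mut.parent_id, mutant_id))
            pair_alive.append({"P": 1, "M": 1})
            for (q, side) in tags.get(mut.parent_id, []):
                pair_alive[q][side] += 1  # mutant joins all ancestral branches
            mut_tags = mut_tags + [(pid, "M")]
            tags[mut.parent_id] = tags.get(mut.parent_id, []) + [(pid, "P")]
        else:
            for (q, side) in mut_tags:
                pair_alive[q][side] += 1
        tags[mutant_id] = mut_tags

        dead = list(res.extinct_ids)
        if res.parent_extinct:
            dead.append(mut.parent_id)
        f_extinct = {
            d: float(state.f[state.index_of(d)]) for d in dead
        }
        for d in dead:
            for (q, side) in tags.pop(d, []):
                pair_alive[q][side] -= 1
                if pair_alive[q][side] == 0 and pairs[q].end_step is None:
                    pairs[q].end_step = step

        state = post
        max_mut = max(st.n_mutations for st in state.survivor_strains())
        events.append(EvolutionEvent(
            step=step, parent_id=mut.parent_id, mutant_id=mutant_id,
            mutation=mut, s_inv=res.s_inv, fate=res.fate,
            extinct_ids=res.extinct_ids, parent_extinct=res.parent_extinct,
            f_parent_pre=res.f_parent_pre, f_extinct_pre=f_extinct,
            n_survivors_post=state.n_survivors, max_n_mutations=max_mut,
        ))
        strain_counts.append(state.n_survivors)
        related_counts.append(_related_count(state))
        if step % snapshot_every == 0:
            snapshots[step] = enumerate_dfe(state, kinds=kinds, dX=dX) \
                .samples["s_inv"].to_numpy()
        if max_mut >= stop_mutations:
            termination = "stop_rule"
            break

    final_step = len(events)
    if final_step not in snapshots and final_step > 0:
        snapshots[final_step] = enumerate_dfe(state, kinds=kinds, dX=dX) \
            .samples["s_inv"].to_numpy()
    return EvolutionLog(
        events=events, pairs=pairs, strain_counts=strain_counts,
        related_counts=related_counts, dfe_snapshots=snapshots,
        initial_state=initial_state, final_state=state,
        termination=termination, parent_tree=parent_tree,
    )


def lineage_statistics(log: EvolutionLog) -> dict:
    """Summaries of one (or the tail of one) evolutionary trajectory.

    Includes the strain-count and related-strain trajectories, coexistence
    durations (community-wide mutational steps until one branch of a
    diverged pair dies; censored pairs enter the survival curve but not
    the mean), a Kaplan-Meier maintenance curve, the rolling fraction of
    coexistence outcomes, and abundance collections at mutation,
    diversification, and extinction events.
    """
    if not log.events:
        raise ValueError("empty evolution log")
    final_step = log.events[-1].step
    durations = np.array([p.duration(final_step) for p in log.pairs])
    observed = np.array([not p.censored() for p in log.pairs])

    if len(durations):
        from lifelines import KaplanMeierFitter

        kmf = KaplanMeierFitter()
        kmf.fit(durations, event_observed=observed)
        km_t = kmf.survival_function_.index.to_numpy(dtype=float)
        km_s = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    else:
        km_t, km_s = np.array([0.0]), np.array([1.0])

    n = len(log.events)
    decile = max(1, n // 10)
    fates = np.array([e.fate == FATE_COEXISTS for e in log.events])
    rolling = [
        float(fates[i:i + decile].mean()) for i in range(0, n, decile)
    ]

    return {
        "strain_counts": np.asarray(log.strain_counts),
        "related_counts": np.asarray(log.related_counts),
        "coexistence_durations": durations,
        "duration_observed": observed,
        "mean_coexistence_duration": (
            float(durations[observed].mean()) if observed.any() else np.nan
        ),
        "km_times": km_t,
        "km_survival": km_s,
        "coexistence_fraction": float(fates.mean()),
        "coexistence_fraction_rolling": rolling,
        "f_at_mutation": np.array([e.f_parent_pre for e in log.events]),
        "f_at_diversification": np.array(
            [e.f_parent_pre for e in log.events if e.fate == FATE_COEXISTS]
        ),
        "f_at_extinction": np.concatenate(
            [list(e.f_extinct_pre.values()) for e in log.events]
            or [np.empty(0)]
        ),
        "termination": log.termination,
        "n_events": n,
    }


def dfe_snapshot_compare(log: EvolutionLog, at_steps: Iterable[int]) -> dict:
    """Moment and tail-shape summaries of stored DFE snapshots.

    Excess kurtosis discriminates the initial Gaussian shape (~0) from the
    two-tailed exponential (Laplace) limit (~3).
    """
    from scipy.stats import kurtosis

    out = {}
    for step in at_steps:
        if step not in log.dfe_snapshots:
            raise KeyError(
                f"no DFE snapshot at step {step}; available: "
                f"{sorted(log.dfe_snapshots)}"
            )
        s = log.dfe_snapshots[step]
        out[step] = {
            "n": len(s),
            "mean": float(np.mean(s)),
            "sd": float(np.std(s, ddof=1)),
            "excess_kurtosis": float(kurtosis(s, fisher=True)),
        }
    return out
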