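"""Flat-file serialization: pools, states, event logs, lineage trees.

Everything is diffable text: TSV for tables (floats printed with 12
significant digits), JSON for metadata and state exports, Newick for
lineage trees with branch lengths in mutational steps.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Sequence

import numpy as np
import pandas as pd

from .equilibrium import CommunityState
from .evolution import EvolutionLog
from .invasion import InvasionResult
from .sampling import Environment, SpeciesPool, Strain

__all__ = [
    "ExperimentConfig",
    "save_pool",
    "load_pool",
    "state_to_json",
    "trajectory_to_tsv",
    "invasions_to_frame",
    "events_to_frame",
    "snapshots_to_tsv",
    "lineage_tree_to_newick",
]

_FLOAT_FMT = "%.12g"


@dataclasses.dataclass
class ExperimentConfig:
    """Declarative description of one experiment run.

    ``kind`` selects the recipe: assemble | dfe | firststep | evolve |
    theory-overlay.  Unused fields are ignored by a recipe.  The config
    round-trips losslessly through JSON.
    """

    kind: str
    R: int = 200
    R0: float = 40.0
    target_niche_saturation: float | None = None
    target_permissivity: float | None = None
    S: int | None = None
    std_X: float | None = None
    cv: float = 0.0
    scheme: str = "binary"
    mutation_kinds: tuple[str, ...] = ("knockout",)
    dX: float = 0.0
    replicates: int = 10
    n_samples: int = 100
    policy: str = "sequential"
    stop_mutations: int = 10
    max_steps: int = 2000
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["mutation_kinds"] = list(self.mutation_kinds)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        d = json.loads(text)
        d["mutation_kinds"] = tuple(d.get("mutation_kinds", ("knockout",)))
        return cls(**d)


# ---------------------------------------------------------------------------
# pools


def save_pool(pool: SpeciesPool, prefix: str | pathlib.Path) -> None:
    """Write ``<prefix>.tsv`` (id, X, strategy entries) and
    ``<prefix>.json`` (ensemble metadata)."""
    prefix = pathlib.Path(prefix)
    cols = {"id": [st.id for st in pool.strains],
            "X": [st.X for st in pool.strains]}
    A = np.array([st.alpha for st in pool.strains])
    df = pd.DataFrame(cols)
    for i in range(pool.R):
        df[f"alpha_{i}"] = A[:, i]
    df.to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False,
              float_format=_FLOAT_FMT)
    prefix.with_suffix(".json").write_text(json.dumps({
        "R": pool.R, "R0": pool.R0, "S": pool.S, "std_X": pool.std_X,
        "scheme": pool.scheme, "seed": pool.seed,
    }, indent=1))


def load_pool(prefix: str | pathlib.Path) -> SpeciesPool:
    prefix = pathlib.Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    df = pd.read_csv(prefix.with_suffix(".tsv"), sep="\t")
    acols = [c for c in df.columns if c.startswith("alpha_")]
    strains = [
        Strain(id=str(row["id"]), X=float(row["X"]),
               alpha=row[acols].to_numpy(dtype=float))
        for _, row in df.iterrows()
    ]
    return SpeciesPool(strains=strains, R=meta["R"], R0=meta["R0"],
                       std_X=meta["std_X"], scheme=meta["scheme"],
                       seed=meta["seed"])


# ---------------------------------------------------------------------------
# states & trajectories


def state_to_json(state: CommunityState, path: str | pathlib.Path) -> None:
    payload = {
        "survivor_ids": state.survivor_ids,
        "f": {st.id: float(f) for st, f in zip(state.strains, state.f)
              if f > 0},
        "h": [None if np.isnan(v) else float(v) for v in state.h],
        "g": [None if np.isnan(v) else float(v) for v in state.g],
        "h_bar": state.h_bar,
        "kkt_survivor_residual": state.kkt_survivor_residual,
        "kkt_excluded_residual": state.kkt_excluded_residual,
        "degenerate": state.degenerate,
    }
    pathlib.Path(path).write_text(json.dumps(payload, indent=1))


def trajectory_to_tsv(t: np.ndarray, F: np.ndarray,
                      path: str | pathlib.Path,
                      ids: Sequence[str] | None = None) -> None:
    df = pd.DataFrame(F, columns=ids if ids is not None
                      else [f"f{i}" for i in range(F.shape[1])])
    df.insert(0, "t", t)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# event tables


def invasions_to_frame(results: Sequence[InvasionResult]) -> pd.DataFrame:
    rows = []
    for k, r in enumerate(results):
        pre = r.pre_state
        parent = pre.strains[pre.index_of(r.mutation.parent_id)]
        mut_alpha = np.maximum(parent.alpha + r.mutation.d_alpha, 0.0)
        shared = [
            int(np.sum((pre.strains[pre.index_of(e)].alpha > 0)
                       & (mut_alpha > 0)))
            for e in r.extinct_ids
        ]
        rows.append({
            "replicate": k,
            "parent_id": r.mutation.parent_id,
            "f_parent": r.f_parent_pre,
            "kind": r.mutation.kind,
            "target": r.mutation.target,
            "dX": r.mutation.dX,
            "norm_d_alpha": r.mutation.norm_d_alpha,
            "s_inv": r.s_inv,
            "fate": r.fate,
            "n_extinct": len(r.extinct_ids),
            "parent_extinct": r.parent_extinct,
            "extinct_ids": ";".join(r.extinct_ids),
            "shared_resource_counts": ";".join(map(str, shared)),
            "n_rescued": len(r.rescued_ids),
            "policy": r.policy,
        })
    return pd.DataFrame(rows)


def snapshots_to_tsv(log: EvolutionLog, path: str | pathlib.Path) -> None:
    """All stored DFE snapshots in one long-format table (step, s_inv)."""
    frames = [
        pd.DataFrame({"step": step, "s_inv": vals})
        for step, vals in sorted(log.dfe_snapshots.items())
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT)


def events_to_frame(log: EvolutionLog) -> pd.DataFrame:
    rows = []
    for e in log.events:
        rows.append({
            "step": e.step,
            "parent_id": e.parent_id,
            "mutant_id": e.mutant_id,
            "kind": e.mutation.kind,
            "target": e.mutation.target,
            "s_inv": e.s_inv,
            "fate": e.fate,
            "f_parent_pre": e.f_parent_pre,
            "n_extinct": len(e.extinct_ids),
            "parent_extinct": e.parent_extinct,
            "extinct_ids": ";".join(e.extinct_ids),
            "n_survivors": e.n_survivors_post,
            "max_n_mutations": e.max_n_mutations,
        })
    return pd.DataFrame(rows)


def lineage_tree_to_newick(log: EvolutionLog) -> str:
    """Export the mutational genealogy as a Newick forest.

    Each founding survivor of the initial community roots one tree; branch
    lengths count community-wide successful-mutation steps between a
    strain's birth and its child's birth (or the end of the run).
    """
    birth = {sid: 0 for sid, p in log.parent_tree.items() if p is None}
    children: dict[str, list[str]] = {sid: [] for sid in log.parent_tree}
    for e in log.events:
        birth[e.mutant_id] = e.step
        children.setdefault(e.parent_id, []).append(e.mutant_id)
        children.setdefault(e.mutant_id, [])
    final_step = log.events[-1].step if log.events else 0

    def render(sid: str) -> str:
        kids = children.get(sid, [])
        if not kids:
            return sid
        parts = [
            f"{render(k)}:{birth[k] - birth[sid]}" for k in kids
        ]
        # the continuing parent branch is kept as an explicit leaf
        parts.append(f"{sid}:{final_step - birth[sid]}")
        return "(" + ",".join(parts) + ")" + sid + "_node"

    roots = [sid for sid, p in log.parent_tree.items() if p is None]
    return "\n".join(f"{render(r)};" for r in roots)
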