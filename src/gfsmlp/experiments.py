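"""The three GFSMLP selection experiments.

All three protocols repeat seeded training runs on one dataset and
aggregate what the gates did:

* **Propensity ranking** — start every run with all gates nearly closed,
  train gates and weights jointly, and count over many runs how often each
  group's gate ends open.  Frequently selected groups are the stronger
  determinants of the class.
* **Single-propensity evaluation** — clamp one gate fully open and all
  others fully closed, freeze the gates (mu = 0) and train the weights
  only; the training misclassification over repeated runs measures that
  group's discriminating power in isolation.
* **Pair cooperation** — open one gate at initialisation (still
  trainable), leave the rest nearly closed, train everything, and count
  which other gates the training opens.  This measures how groups
  collaborate rather than discriminate alone.

Every run ``r`` of an experiment uses the ``r``-th word of the seed stream
derived from the master seed, so an experiment of ``R`` runs is exactly
the union of two sub-experiments of ``R/2`` runs at offsets 0 and ``R/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model import GFSMLP, GFSMLPResults, TrainingConfig, gate_plan


def derive_run_seeds(master_seed: int, runs: int, run_offset: int = 0) -> np.ndarray:
    """Per-run 31-bit seeds: a deterministic counter-based stream from the master.

    The stream is a prefix property: runs ``[a, b)`` of a longer experiment
    receive the same seeds regardless of the total run count, which is what
    makes split experiments merge exactly.
    """
    ss = np.random.SeedSequence(master_seed)
    words = ss.generate_state(run_offset + runs, dtype=np.uint32)
    return (words[run_offset:] & np.uint32(0x7FFFFFFF)).astype(np.int64)


@dataclass
class SelectionFrequencyTable:
    """Per-group selection counts over repeated ranking runs."""

    counts: np.ndarray
    runs: int
    group_names: list[str]
    threshold: float
    master_seed: int
    run_offset: int = 0
    run_seeds: np.ndarray = field(default=None, repr=False)
    gates_per_run: np.ndarray = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.arange(1, len(self.counts) + 1),
                "name": self.group_names,
                "count": self.counts,
                "runs": self.runs,
            }
        )

    def ranking(self) -> list[int]:
        """1-based group indices, most frequently selected first (ties: lower index)."""
        order = np.lexsort((np.arange(len(self.counts)), -self.counts))
        return [int(i) + 1 for i in order]

    @classmethod
    def merge(cls, parts: Sequence["SelectionFrequencyTable"]) -> "SelectionFrequencyTable":
        """Combine sub-experiments run at complementary offsets."""
        first = parts[0]
        if any(p.group_names != first.group_names or p.threshold != first.threshold
               for p in parts):
            raise ValueError("cannot merge tables from different experiments")
        return cls(
            counts=np.sum([p.counts for p in parts], axis=0),
            runs=sum(p.runs for p in parts),
            group_names=first.group_names,
            threshold=first.threshold,
            master_seed=first.master_seed,
            run_offset=min(p.run_offset for p in parts),
            run_seeds=np.concatenate([p.run_seeds for p in parts]),
            gates_per_run=np.vstack([p.gates_per_run for p in parts]),
        )

    def summary(self) -> str:
        lines = [
            f"Selection frequency over {self.runs} runs "
            f"(gate threshold {self.threshold}, master seed {self.master_seed})",
            f"{'group':<30}{'count':>8}",
            "-" * 38,
        ]
        for i, (name, c) in enumerate(zip(self.group_names, self.counts), start=1):
            lines.append(f"{i}. {name:<27}{c:>8d}")
        return "\n".join(lines)


def rank_propensities(
    model: GFSMLP,
    config: TrainingConfig | None = None,
    runs: int = 1000,
    seed: int = 0,
    run_offset: int = 0,
    threshold: float = 0.5,
) -> SelectionFrequencyTable:
    """Rank groups by how often joint training selects them.

    Each run initialises all gates nearly closed, trains gates and weights
    jointly, and records the groups whose terminal gate exceeds
    ``threshold``.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = config or TrainingConfig()
    seeds = derive_run_seeds(seed, runs, run_offset)
    counts = np.zeros(model.n_groups, dtype=np.int64)
    gates = np.empty((runs, model.n_groups))
    for r in range(runs):
        res = model.fit(config, seed=int(seeds[r]))
        gates[r] = res.gates
        for g in res.selected_groups(threshold):
            counts[g - 1] += 1
    return SelectionFrequencyTable(
        counts=counts, runs=runs, group_names=model.group_names,
        threshold=threshold, master_seed=seed, run_offset=run_offset,
        run_seeds=seeds, gates_per_run=gates,
    )


@dataclass
class SinglePropensityResult:
    """Training-error distribution when only one group's gate is open."""

    group: int
    errors: np.ndarray
    group_names: list[str]
    master_seed: int

    @property
    def runs(self) -> int:
        return self.errors.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.errors))

    @property
    def sd(self) -> float:
        """Sample (n-1) standard deviation; 0 for a single run."""
        return float(np.std(self.errors, ddof=1)) if self.runs > 1 else 0.0

    def summary(self) -> str:
        name = self.group_names[self.group - 1]
        return (
            f"Training misclassification using only group {self.group} ({name}), "
            f"{self.runs} runs: {self.mean:.2f} +/- {self.sd:.2f} % "
            f"(sample sd, master seed {self.master_seed})"
        )


def evaluate_single_propensity(
    model: GFSMLP,
    group: int,
    config: TrainingConfig | None = None,
    runs: int = 100,
    seed: int = 0,
) -> SinglePropensityResult:
    """Train with one gate clamped open, all others closed, gates frozen.

    ``mu`` is forced to 0; the reported errors are training errors (the
    whole dataset is used both to fit and to score), measuring how well
    the single group can separate the classes, not generalisation.
    """
    if not 1 <= group <= model.n_groups:
        raise ValueError(f"group must be in 1..{model.n_groups}")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    config = replace(config or TrainingConfig(), mu=0.0)
    plan = gate_plan(
        model.n_groups,
        open_clamped=[group],
        closed=[g for g in range(1, model.n_groups + 1) if g != group],
    )
    seeds = derive_run_seeds(seed, runs)
    errors = np.empty(runs)
    for r in range(runs):
        res = model.fit(config, gate_init=plan, seed=int(seeds[r]))
        errors[r] = res.misclassification_rate()
    return SinglePropensityResult(
        group=group, errors=errors, group_names=model.group_names, master_seed=seed
    )


@dataclass
class PairCooperationTable:
    """Co-selection counts when one gate starts open and the rest nearly closed."""

    seed_group: int
    counts: np.ndarray
    runs: int
    group_names: list[str]
    threshold: float
    master_seed: int
    run_seeds: np.ndarray = field(default=None, repr=False)
    gates_per_run: np.ndarray = field(default=None, repr=False)

    @property
    def total_with_seed(self) -> int:
        """Row sum including the seeded group's own count."""
        return int(self.counts.sum())

    @property
    def total_without_seed(self) -> int:
        return int(self.counts.sum() - self.counts[self.seed_group - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": np.arange(1, len(self.counts) + 1),
                "name": self.group_names,
                "count": self.counts,
                "seeded": [g == self.seed_group for g in range(1, len(self.counts) + 1)],
            }
        )

    def summary(self) -> str:
        name = self.group_names[self.seed_group - 1]
        lines = [
            f"Co-selection over {self.runs} runs with group {self.seed_group} "
            f"({name}) opened at initialisation (master seed {self.master_seed})",
            f"{'group':<30}{'count':>8}",
            "-" * 38,
        ]
        for i, (gname, c) in enumerate(zip(self.group_names, self.counts), start=1):
            mark = "  <- seeded" if i == self.seed_group else ""
            lines.append(f"{i}. {gname:<27}{c:>8d}{mark}")
        lines.append(f"sum incl. seeded group: {self.total_with_seed}; "
                     f"excl.: {self.total_without_seed}")
        return "\n".join(lines)


def pair_cooperation(
    model: GFSMLP,
    seed_group: int,
    config: TrainingConfig | None = None,
    runs: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> PairCooperationTable:
    """Count which groups open when one gate starts open and training proceeds.

    The seeded gate starts open but stays trainable (``mu`` must be > 0),
    so a genuinely useless seeded group could be closed by training; the
    other gates start nearly closed as in the ranking protocol.
    """
    if not 1 <= seed_group <= model.n_groups:
        raise ValueError(f"seed_group must be in 1..{model.n_groups}")
    config = config or TrainingConfig()
    if config.mu <= 0:
        raise ValueError("pair cooperation requires mu > 0 (trainable gates)")
    plan = gate_plan(model.n_groups, open_trainable=[seed_group])
    seeds = derive_run_seeds(seed, runs)
    counts = np.zeros(model.n_groups, dtype=np.int64)
    gates = np.empty((runs, model.n_groups))
    for r in range(runs):
        res = model.fit(config, gate_init=plan, seed=int(seeds[r]))
        gates[r] = res.gates
        for g in res.selected_groups(threshold):
            counts[g - 1] += 1
    return PairCooperationTable(
        seed_group=seed_group, counts=counts, runs=runs,
        group_names=model.group_names, threshold=threshold,
        master_seed=seed, run_seeds=seeds, gates_per_run=gates,
    )
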