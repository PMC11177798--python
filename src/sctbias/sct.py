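"""Simulated comparator trials (SCTs): ideal randomization in silico.

An SCT is a synthetic two-arm trial of the same size as the candidate trial,
built from three parallel columns:

1. patient IDs 1..N,
2. a block-randomized allocation sequence over groups A and B (block size 4
   by default), and
3. N baseline values drawn uniformly (integers, with replacement) from the
   candidate trial's reported range, sorted ascending.

Because allocation is genuinely random and independent of the value column,
the two arms of an SCT differ only by sampling noise — the SCT embodies the
null hypothesis of ideal randomization against which a real trial's baseline
balance is judged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial_data import ArmSummary, ValueRange

__all__ = [
    "AllocationSequence",
    "SimulatedComparatorTrial",
    "block_randomize",
    "sample_baseline_values",
    "build_sct",
    "summarize_groups",
]

GROUP_A = "A"
GROUP_B = "B"


@dataclass(frozen=True)
class AllocationSequence:
    """Block-randomized assignments over {A, B}, one per patient position."""

    assignments: tuple[str, ...]
    block_size: int
    seed: int

    def __len__(self) -> int:
        return len(self.assignments)

    def count(self, group: str) -> int:
        return sum(1 for a in self.assignments if a == group)


@dataclass(frozen=True)
class SimulatedComparatorTrial:
    """The three-column SCT plus its derived per-arm summaries."""

    patient_ids: tuple[int, ...]
    allocation: AllocationSequence
    values: tuple[int, ...]
    arm_a: ArmSummary
    arm_b: ArmSummary

    @property
    def n_total(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        """The SCT as its canonical three-column table (id, allocation, value)."""
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "allocation": self.allocation.assignments,
                "value": self.values,
            }
        )

    def group_values(self, group: str) -> np.ndarray:
        mask = np.array([a == group for a in self.allocation.assignments])
        return np.asarray(self.values)[mask]


def _permuted_block(rng: np.random.Generator, block_size: int) -> list[str]:
    block = [GROUP_A] * (block_size // 2) + [GROUP_B] * (block_size // 2)
    return [block[i] for i in rng.permutation(block_size)]


def _block_assignments(rng: np.random.Generator, n_total: int, block_size: int) -> list[str]:
    assignments: list[str] = []
    while len(assignments) < n_total:
        assignments.extend(_permuted_block(rng, block_size))
    # a truncated final block keeps the first r assignments of one more
    # permuted block, bounding |n_A - n_B| by block_size/2
    return assignments[:n_total]


def block_randomize(n_total: int, block_size: int = 4, seed: int = 0) -> AllocationSequence:
    """Generate a block-randomized allocation sequence of length ``n_total``.

    Each complete block of ``block_size`` consecutive positions contains
    exactly ``block_size/2`` A's in uniformly random order; when ``n_total``
    is not a multiple of the block size, the trailing positions are the first
    elements of one further permuted block.  Deterministic for a fixed seed.
    """
    if n_total < 2:
        raise ValueError(f"n_total must be >= 2, got {n_total}")
    if block_size < 2 or block_size % 2:
        raise ValueError(f"block_size must be a positive even integer, got {block_size}")
    rng = np.random.default_rng(seed)
    return AllocationSequence(
        assignments=tuple(_block_assignments(rng, n_total, block_size)),
        block_size=block_size,
        seed=seed,
    )


def _sample_values(rng: np.random.Generator, value_range: ValueRange, n_total: int) -> np.ndarray:
    draws = rng.integers(value_range.low, value_range.high + 1, size=n_total)
    draws.sort()
    return draws


def sample_baseline_values(value_range: ValueRange, n_total: int, seed: int = 0) -> np.ndarray:
    """Draw ``n_total`` uniform integers on the inclusive range, sorted ascending.

    Duplicates are allowed (sampling is with replacement), mirroring how a
    plain uniform random-number generator would fill the SCT value column.
    """
    if n_total < 1:
        raise ValueError(f"n_total must be >= 1, got {n_total}")
    return _sample_values(np.random.default_rng(seed), value_range, n_total)


def _summarize(assignments: list[str] | tuple[str, ...], values: np.ndarray) -> tuple[ArmSummary, ArmSummary]:
    values = np.asarray(values, dtype=float)
    mask_a = np.array([a == GROUP_A for a in assignments])
    out = []
    for label, group in ((GROUP_A, values[mask_a]), (GROUP_B, values[~mask_a])):
        if group.size < 2:
            raise ValueError(f"group {label} has {group.size} member(s); sample SD needs at least 2")
        out.append(ArmSummary(label=label, mean=float(group.mean()), sd=float(group.std(ddof=1)), n=int(group.size)))
    return out[0], out[1]


def summarize_groups(sct: SimulatedComparatorTrial) -> tuple[ArmSummary, ArmSummary]:
    """Per-group mean, sample SD (n-1 denominator) and size for groups A and B."""
    return _summarize(sct.allocation.assignments, np.asarray(sct.values))


def build_sct(
    n_total: int,
    value_range: ValueRange,
    block_size: int = 4,
    seed: int = 0,
) -> SimulatedComparatorTrial:
    """Build one simulated comparator trial.

    A single seeded generator drives both random columns, allocation first,
    then values; the ascending value column is paired with the allocation
    column by row position.  Deterministic for a fixed seed.
    """
    if n_total < 4:
        raise ValueError(f"n_total must be >= 4 to populate both arms, got {n_total}")
    if block_size < 2 or block_size % 2:
        raise ValueError(f"block_size must be a positive even integer, got {block_size}")
    rng = np.random.default_rng(seed)
    assignments = _block_assignments(rng, n_total, block_size)
    values = _sample_values(rng, value_range, n_total)
    arm_a, arm_b = _summarize(assignments, values)
    return SimulatedComparatorTrial(
        patient_ids=tuple(range(1, n_total + 1)),
        allocation=AllocationSequence(assignments=tuple(assignments), block_size=block_size, seed=seed),
        values=tuple(int(v) for v in values),
        arm_a=arm_a,
        arm_b=arm_b,
    )
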