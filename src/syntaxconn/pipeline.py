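"""End-to-end drivers: simulated cohort -> group partial-correlation matrices.

The canonical processing order per participant is: simulate (or load)
the per-run region series, z-score each region within each run,
concatenate the runs (6 x 128 = 768 timepoints by default), estimate
the regress-out partial-correlation matrix, then average participants
entrywise into the group matrix.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .connectivity import (
    PartialCorrMatrix,
    group_average,
    partial_corr_matrix,
    randomize_series,
)
from .roi import RoiTimeSeriesSet, concatenate_runs, normalize_run
from .simulate import GenerativeSpec, simulate_participant

__all__ = [
    "participant_matrix",
    "matrix_from_runs",
    "simulate_group_matrix",
]


def matrix_from_runs(
    runs: Sequence[RoiTimeSeriesSet],
    condition_set: str = "combined",
    randomize_seed: int | None = None,
) -> PartialCorrMatrix:
    """Normalize per run, concatenate, and estimate partial correlations.

    With ``randomize_seed`` set, each region's normalized series is
    permuted within run boundaries first (the randomized-null control).
    """
    pooled = concatenate_runs([normalize_run(r) for r in runs])
    if randomize_seed is not None:
        pooled = randomize_series(pooled, randomize_seed)
    return partial_corr_matrix(pooled, condition_set=condition_set)


def participant_matrix(
    spec: GenerativeSpec,
    participant_seed: int,
    state: str = "combined",
    randomize_seed: int | None = None,
) -> PartialCorrMatrix:
    """Simulate one participant and estimate their connectivity matrix."""
    runs, _ = simulate_participant(spec, participant_seed, state=state)
    return matrix_from_runs(runs, condition_set=state, randomize_seed=randomize_seed)


def simulate_group_matrix(
    spec: GenerativeSpec,
    group: str,
    state: str = "combined",
    randomize: bool = False,
) -> PartialCorrMatrix:
    """Simulate a whole group and average into its group matrix.

    Participant seeds are derived from the spec's master seed, the
    group label and the participant index, so groups and states are
    reproducible independently of each other.
    """
    try:
        size = spec.group_sizes[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}") from None
    # deterministic group substream tag derived from the label bytes
    group_tag = int.from_bytes(group.encode()[:4].ljust(4, b"\0"), "little") % (2**16)
    members = []
    for s in range(size):
        participant_seed = int(
            np.random.default_rng([spec.seed, group_tag, s]).integers(2**31)
        )
        members.append(
            participant_matrix(
                spec,
                participant_seed,
                state=state,
                randomize_seed=(participant_seed + 1) if randomize else None,
            )
        )
    return group_average(members, group_label=group)
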