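"""Majority voting over multiple prediction runs.

Voting operates per relation key — (PMID, type, chemical term, gene term) —
so multi-type pairs are voted independently, consistent with the evaluation
treating each type as its own instance.  The default is strict majority: a
key survives only if it appears in more than half of the runs, which drops
ties under even run counts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .evaluation import RelationKey


@dataclass(frozen=True)
class VoteConfig:
    """Voting threshold as a fraction of the number of runs, in (0, 1]."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")


def majority_vote(
    runs: Sequence[set[RelationKey]], cfg: VoteConfig = VoteConfig()
) -> set[RelationKey]:
    """Keep keys supported by strictly more than ``threshold * n`` runs.

    With ``threshold=1.0`` the cutoff is unanimity (the intersection); as
    the threshold approaches 0 the output approaches the union.  The result
    is invariant under run order.
    """
    if not runs:
        raise ValueError("majority_vote requires at least one run")
    n = len(runs)
    votes: Counter = Counter()
    for run in runs:
        votes.update(run)
    if cfg.threshold >= 1.0:
        return {key for key, c in votes.items() if c == n}
    cutoff = cfg.threshold * n
    return {key for key, c in votes.items() if c > cutoff}
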