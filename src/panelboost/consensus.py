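"""2-of-3 consensus voting over per-learner ranked gene subsets.

A gene enters the candidate pool when it appears in at least ``vote_min`` of
the ranked subsets; candidates are ordered by vote count, then by mean
normalized rank across the subsets containing them (importance scales of
different learners are incommensurable, ranks are not), then by gene id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .ranking import RankedFeatureSet

__all__ = ["ConsensusSelection", "ShortSelectionWarning", "consensus_select"]


class ShortSelectionWarning(UserWarning):
    """Fewer genes reached the vote threshold than the requested panel size."""


@dataclass
class ConsensusSelection:
    gene_ids: list[str]
    votes: dict[str, int]
    aggregate_rank: dict[str, float]
    source_ranks: dict[str, dict[str, int]] = field(default_factory=dict)
    short: bool = False


def _normalized_rank(position: int, size: int) -> float:
    """(r-1)/(m-1) for 1-based position r in a subset of size m; 0 if m=1."""
    if size <= 1:
        return 0.0
    return (position - 1) / (size - 1)


def consensus_select(
    subsets: list[RankedFeatureSet],
    vote_min: int = 2,
    final_size: int = 10,
) -> ConsensusSelection:
    """Combine ranked subsets into the final panel by voting + rank aggregation.

    Returns the first ``final_size`` candidates ordered by (votes desc,
    mean normalized rank asc, gene id).  When fewer candidates reach
    vote_min, the short panel is returned with a warning — the vote
    threshold is never silently relaxed.
    """
    if not subsets:
        raise ValueError("at least one ranked subset required")
    if not (1 <= vote_min <= len(subsets)):
        raise ValueError(f"vote_min must be in [1, {len(subsets)}]")
    if final_size < 1:
        raise ValueError("final_size must be >= 1")

    votes: dict[str, int] = {}
    norm_ranks: dict[str, list[float]] = {}
    source_ranks: dict[str, dict[str, int]] = {}
    for idx, sub in enumerate(subsets):
        name = f"{sub.learner.kind}#{idx}"
        m = len(sub.gene_ids)
        for pos, g in enumerate(sub.gene_ids, start=1):
            votes[g] = votes.get(g, 0) + 1
            norm_ranks.setdefault(g, []).append(_normalized_rank(pos, m))
            source_ranks.setdefault(g, {})[name] = pos

    pool = [g for g, v in votes.items() if v >= vote_min]
    agg = {g: sum(norm_ranks[g]) / len(norm_ranks[g]) for g in pool}
    ordered = sorted(pool, key=lambda g: (-votes[g], agg[g], g))
    panel = ordered[:final_size]

    short = len(panel) < final_size
    if short:
        warnings.warn(
            f"only {len(panel)} genes reached {vote_min} votes "
            f"(requested panel of {final_size})",
            ShortSelectionWarning,
            stacklevel=2,
        )
    return ConsensusSelection(
        gene_ids=panel,
        votes={g: votes[g] for g in panel},
        aggregate_rank={g: agg[g] for g in panel},
        source_ranks={g: source_ranks[g] for g in panel},
        short=short,
    )
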