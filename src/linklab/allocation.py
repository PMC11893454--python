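"""Overlap-above-chance metrics for neurons and dendritic branches.

For two memory ensembles A and B drawn from a population of ``n_total``
units, chance overlap is the product of the ensemble percentages
(``pct_A * pct_B / 100``) and the reported quantity is
``(observed - chance) / chance``.  The same percentage algebra is
applied by analogy at the branch level, where a branch "holds" a memory
if it carries at least ``branch_cluster_k`` potentiated synapses from
that memory (a synapse cluster).

Note the normalization convention: these model metrics normalize by the
population size, matching the chance formula; the imaging-session
overlap in :mod:`linklab.ensemble` divides by the *average ensemble
size* instead, as done for recorded ROIs.  The two conventions are
deliberately kept distinct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Collection

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .protocol import TrialResult

__all__ = [
    "OverlapSummary",
    "ensemble_overlap_above_chance",
    "branch_cluster_overlap",
    "new_clustered_synapse_overlap",
]


@dataclass
class OverlapSummary:
    observed_pct: float
    chance_pct: float
    above_chance: float      # (observed - chance) / chance; nan if undefined
    n_A: int
    n_B: int
    n_total: int

    @property
    def defined(self) -> bool:
        return np.isfinite(self.above_chance)


def ensemble_overlap_above_chance(
    set_A: Collection, set_B: Collection, n_total: int
) -> OverlapSummary:
    """Overlap of two member sets relative to product-of-percentages chance."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    A, B = set(set_A), set(set_B)
    observed = 100.0 * len(A & B) / n_total
    pct_A = 100.0 * len(A) / n_total
    pct_B = 100.0 * len(B) / n_total
    chance = pct_A * pct_B / 100.0
    above = (observed - chance) / chance if chance > 0 else float("nan")
    return OverlapSummary(observed, chance, above, len(A), len(B), n_total)


def _branch_overlap(counts_A: np.ndarray, counts_B: np.ndarray, k: int) -> OverlapSummary:
    counts_A = np.asarray(counts_A)
    counts_B = np.asarray(counts_B)
    if counts_A.shape != counts_B.shape or counts_A.size == 0:
        raise ValueError("per-branch counts must be same-length and non-empty")
    has_A = counts_A >= k
    has_B = counts_B >= k
    n = counts_A.size
    return ensemble_overlap_above_chance(
        set(np.flatnonzero(has_A)), set(np.flatnonzero(has_B)), n
    )


def branch_cluster_overlap(trial: "TrialResult", k: int | None = None) -> OverlapSummary:
    """Overlap between branches carrying potentiated-synapse clusters of
    each memory (>= k potentiated synapses per memory on the branch)."""
    k = trial.params.branch_cluster_k if k is None else k
    return _branch_overlap(
        trial.branch_pot_counts["A"], trial.branch_pot_counts["B"], k
    )


def new_clustered_synapse_overlap(
    trial: "TrialResult", cluster_k: int | None = None
) -> OverlapSummary:
    """Overlap between branches gaining clusters of *newly* potentiated
    synapses during each memory's consolidation."""
    k = trial.params.branch_cluster_k if cluster_k is None else cluster_k
    return _branch_overlap(
        trial.branch_newpot_counts["A"], trial.branch_newpot_counts["B"], k
    )
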