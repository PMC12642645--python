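"""Consensus clustering across seeded solutions at a fixed K.

Independent runs of any of the clusterers return partitions whose labels
are only defined up to permutation. The consensus procedure (i) picks a
reference solution, (ii) relabels every other solution by the
Hamming-minimizing permutation found with the Hungarian algorithm, and
(iii) assigns each ROI the label it receives most frequently across the
aligned solutions. The result is stable across label switching and, for
pure relabelings of a single partition, reproduces it exactly (up to the
reference's labeling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import FCCommError
from .metrics import hamming_distance
from .types import Partition

__all__ = ["ConsensusResult", "align_to_reference", "consensus_partition"]


@dataclass(frozen=True)
class ConsensusResult:
    """Majority-vote consensus over aligned solutions."""

    reference: Partition
    aligned: tuple  # relabeled input partitions
    consensus: Partition
    agreement: np.ndarray  # per-ROI fraction voting for the consensus label
    uses_all_labels: bool  # False when the consensus lost some label


def align_to_reference(reference: Partition, other: Partition) -> Partition:
    """Relabel ``other`` with the Hamming-minimizing permutation against
    ``reference``. The aligned mismatch proportion never exceeds the raw
    one."""
    if reference.n != other.n:
        raise FCCommError("partitions must have the same length")
    if reference.K != other.K:
        raise FCCommError(
            f"K mismatch: reference has {reference.K}, other has {other.K}"
        )
    _, perm = hamming_distance(reference, other)
    return other.relabeled(perm)


def consensus_partition(
    solutions,
    reference_rule: str = "first",
    scores=None,
    reference_index: int | None = None,
) -> ConsensusResult:
    """Align solutions to a reference and take the per-ROI majority label.

    The reference is selected by ``reference_rule``:

    * ``"first"`` — the first solution in the list;
    * ``"max_score"`` — the solution with the largest entry in ``scores``
      (log-likelihoods for WSBM pools, silhouettes for the baselines);
    * ``"index"`` — the solution at ``reference_index``.

    Majority-vote ties go to the smaller label. If the consensus uses
    fewer than K distinct labels it is still returned, flagged via
    ``uses_all_labels=False``.
    """
    solutions = list(solutions)
    if not solutions:
        raise FCCommError("consensus needs at least one solution")
    n, K = solutions[0].n, solutions[0].K
    for s in solutions[1:]:
        if s.n != n or s.K != K:
            raise FCCommError("all solutions must share the same n and K")

    if reference_rule == "first":
        ref_idx = 0
    elif reference_rule == "max_score":
        if scores is None or len(scores) != len(solutions):
            raise FCCommError("max_score rule needs one score per solution")
        ref_idx = int(np.argmax(scores))
    elif reference_rule == "index":
        if reference_index is None or not 0 <= reference_index < len(solutions):
            raise FCCommError("index rule needs a valid reference_index")
        ref_idx = int(reference_index)
    else:
        raise FCCommError(f"unknown reference rule {reference_rule!r}")

    reference = solutions[ref_idx]
    aligned = tuple(align_to_reference(reference, s) for s in solutions)
    votes = np.stack([a.labels for a in aligned], axis=0)  # m x n

    cons = np.empty(n, dtype=np.int64)
    agree = np.empty(n)
    m = votes.shape[0]
    for i in range(n):
        counts = np.bincount(votes[:, i], minlength=K + 1)[1:]
        cons[i] = int(np.argmax(counts)) + 1  # argmax takes smallest on ties
        agree[i] = counts[cons[i] - 1] / m
    consensus = Partition(cons, K)
    return ConsensusResult(
        reference=reference,
        aligned=aligned,
        consensus=consensus,
        agreement=agree,
        uses_all_labels=consensus.n_used == K,
    )
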