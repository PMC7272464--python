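"""Assign Read-2 fragments to genes against the two-species transcript reference.

A seed-and-verify matcher: transcripts are indexed by k-mers (default k=21),
candidate (gene, offset) pairs are gathered from seeds sampled along the
read in both orientations, and a candidate is confirmed when the full read
aligns to the transcript at the seeded offset with at most ``max_mismatches``
substitutions. Reads confirming more than one gene are ambiguous and are
discarded from counting; reads confirming none are unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from ._utils import reverse_complement
from .simulate import ReferenceSet

ASSIGNED = "assigned"
AMBIGUOUS = "ambiguous"
UNASSIGNED = "unassigned"

DEFAULT_K = 21
DEFAULT_MAX_MISMATCHES = 2


@dataclass(frozen=True)
class Assignment:
    outcome: str  # ASSIGNED | AMBIGUOUS | UNASSIGNED
    gene_id: str | None = None


@dataclass
class AssignStats:
    reads: int = 0
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "reads": self.reads,
            "assigned": self.assigned,
            "ambiguous": self.ambiguous,
            "unassigned": self.unassigned,
        }


class GeneIndex:
    """k-mer seed table over a ReferenceSet plus per-gene annotation."""

    def __init__(self, ref: ReferenceSet, k: int = DEFAULT_K):
        if not ref.transcripts:
            raise ValueError("cannot index an empty reference")
        if k < 11:
            raise ValueError("k must be >= 11 (shorter seeds hit by chance)")
        self.k = k
        self.sequences: dict[str, str] = ref.sequences()
        table = ref.gene_table()
        self.species: dict[str, str] = dict(zip(table.gene_id, table.species))
        self.is_mito: dict[str, bool] = dict(zip(table.gene_id, table.is_mito.astype(bool)))
        self.seeds: dict[str, list[tuple[str, int]]] = {}
        for gene_id, seq in self.sequences.items():
            if len(seq) < k:
                raise ValueError(f"transcript {gene_id} shorter than k={k}")
            for pos in range(len(seq) - k + 1):
                self.seeds.setdefault(seq[pos : pos + k], []).append((gene_id, pos))

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.sequences)


def build_index(ref: ReferenceSet, k: int = DEFAULT_K) -> GeneIndex:
    return GeneIndex(ref, k)


def _mismatches(read: str, transcript: str, offset: int, budget: int) -> int | None:
    """Substitution count of the read aligned at `offset`, or None if it
    overruns the transcript or exceeds `budget`."""
    if offset < 0 or offset + len(read) > len(transcript):
        return None
    mm = 0
    window = transcript[offset : offset + len(read)]
    if read == window:
        return 0
    for a, b in zip(read, window):
        if a != b:
            mm += 1
            if mm > budget:
                return None
    return mm


def _confirm(read: str, index: GeneIndex, max_mismatches: int) -> set[str]:
    k = index.k
    length = len(read)
    seed_positions = sorted({0, (length - k) // 2, length - k})
    candidates: set[tuple[str, int]] = set()
    for sp in seed_positions:
        for gene_id, pos in index.seeds.get(read[sp : sp + k], ()):
            candidates.add((gene_id, pos - sp))
    confirmed: set[str] = set()
    for gene_id, offset in candidates:
        if gene_id in confirmed:
            continue
        if _mismatches(read, index.sequences[gene_id], offset, max_mismatches) is not None:
            confirmed.add(gene_id)
    return confirmed


def assign_read(
    read2: str,
    index: GeneIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
) -> Assignment:
    """Assign one Read 2 to a gene, checking both orientations.

    The forward orientation is tried first (the capture protocol produces
    forward reads); the reverse complement is consulted only when no forward
    candidate confirms, so orientation never creates ambiguity on its own.
    """
    if len(read2) < index.k:
        return Assignment(UNASSIGNED)
    confirmed = _confirm(read2, index, max_mismatches)
    if not confirmed:
        confirmed = _confirm(reverse_complement(read2), index, max_mismatches)
    if len(confirmed) == 1:
        return Assignment(ASSIGNED, next(iter(confirmed)))
    if len(confirmed) >= 2:
        return Assignment(AMBIGUOUS)
    return Assignment(UNASSIGNED)


def assign_stream(
    reads: Iterable[str],
    index: GeneIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    stats: AssignStats | None = None,
):
    """Yield an Assignment per read, tallying outcomes into `stats`."""
    if stats is None:
        stats = AssignStats()
    for read in reads:
        a = assign_read(read, index, max_mismatches)
        stats.reads += 1
        if a.outcome == ASSIGNED:
            stats.assigned += 1
        elif a.outcome == AMBIGUOUS:
            stats.ambiguous += 1
        else:
            stats.unassigned += 1
        yield a
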