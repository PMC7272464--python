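"""Read-1 parsing and cell-barcode correction.

Read 1 carries the capture oligo's information content: bases 1-6 are the
cell barcode, bases 7-13 the UMI, and everything beyond base 13 is poly-T
pad that is ignored. Observed barcodes are matched to the well whitelist
exactly or rescued at Hamming distance 1 when the rescue is unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import pysam

from ._utils import ALPHABET
from .simulate import BARCODE_LEN, UMI_LEN

_MIN_READ1_LEN = BARCODE_LEN + UMI_LEN  # 13

# correction outcome states
EXACT = "exact"
CORRECTED = "corrected"
AMBIGUOUS = "ambiguous"
NO_MATCH = "no_match"

_AMBIG_SENTINEL = object()


@dataclass(frozen=True)
class TaggedRead:
    barcode: str  # whitelist member (after correction)
    umi: str  # 7-mer over {A,C,G,T,N}
    read2: str


@dataclass
class TagStats:
    """Disjoint per-read-pair outcome tallies; categories sum to reads_seen."""

    reads_seen: int = 0
    exact: int = 0
    corrected: int = 0
    rejected_ambiguous: int = 0
    rejected_no_match: int = 0
    rejected_malformed: int = 0

    @property
    def accepted(self) -> int:
        return self.exact + self.corrected

    def as_dict(self) -> dict[str, int]:
        return {
            "reads_seen": self.reads_seen,
            "exact": self.exact,
            "corrected": self.corrected,
            "rejected_ambiguous": self.rejected_ambiguous,
            "rejected_no_match": self.rejected_no_match,
            "rejected_malformed": self.rejected_malformed,
        }


def parse_read1(seq: str) -> tuple[str, str] | None:
    """Split Read 1 into (barcode, umi); None if the read is too short.

    Parsing is purely positional: bases 1-6 and 7-13 (1-based, inclusive).
    """
    if len(seq) < _MIN_READ1_LEN:
        return None
    return seq[:BARCODE_LEN], seq[BARCODE_LEN:_MIN_READ1_LEN]


class BarcodeCorrector:
    """Whitelist lookup with unambiguous single-substitution rescue.

    Precomputes every Hamming-1 neighbor of every whitelist barcode. A
    neighbor generated by two different whitelist entries is marked ambiguous
    and will be rejected rather than guessed. 'N' bases never match, so a
    barcode containing 'N' can still be rescued if exactly one whitelist
    entry is one substitution away.
    """

    def __init__(self, whitelist: Iterable[str]):
        self.whitelist = list(dict.fromkeys(whitelist))
        for bc in self.whitelist:
            if len(bc) != BARCODE_LEN:
                raise ValueError(f"whitelist barcode {bc!r} is not {BARCODE_LEN} bases")
        self._members = set(self.whitelist)
        self._neighbors: dict[str, object] = {}
        for bc in self.whitelist:
            for variant in _hamming1_variants(bc):
                if variant in self._members:
                    continue  # exact membership takes precedence
                existing = self._neighbors.get(variant)
                if existing is None:
                    self._neighbors[variant] = bc
                elif existing != bc:
                    self._neighbors[variant] = _AMBIG_SENTINEL

    def correct(self, observed: str) -> tuple[str | None, str]:
        """Return (whitelist barcode or None, outcome state)."""
        if observed in self._members:
            return observed, EXACT
        hit = self._neighbors.get(observed)
        if hit is None:
            # observed may contain 'N' or other symbols: fall back to a scan
            # counting N as a mismatch against every whitelist entry
            if "N" in observed:
                return self._correct_with_n(observed)
            return None, NO_MATCH
        if hit is _AMBIG_SENTINEL:
            return None, AMBIGUOUS
        return hit, CORRECTED

    def _correct_with_n(self, observed: str) -> tuple[str | None, str]:
        candidates = [
            bc
            for bc in self.whitelist
            if sum(o != b or o == "N" for o, b in zip(observed, bc)) <= 1
        ]
        if len(candidates) == 1:
            return candidates[0], CORRECTED
        if len(candidates) > 1:
            return None, AMBIGUOUS
        return None, NO_MATCH


def _hamming1_variants(barcode: str) -> Iterator[str]:
    for i, original in enumerate(barcode):
        for b in ALPHABET:
            if b != original:
                yield barcode[:i] + b + barcode[i + 1 :]


def correct_barcode(observed: str, whitelist: Iterable[str]) -> tuple[str | None, str]:
    """One-shot barcode correction (builds a throwaway index; see BarcodeCorrector)."""
    return BarcodeCorrector(whitelist).correct(observed)


def tag_stream(
    r1_path,
    r2_path,
    whitelist: Iterable[str],
    stats: TagStats | None = None,
) -> Iterator[TaggedRead]:
    """Stream (Read 1, Read 2) pairs into TaggedReads, correcting barcodes.

    The two FASTQ files must be record-paired in order; a length mismatch is
    a fatal I/O error. Pass a TagStats instance to receive the outcome
    tallies (it is filled in as the stream is consumed).
    """
    if stats is None:
        stats = TagStats()
    corrector = whitelist if isinstance(whitelist, BarcodeCorrector) else BarcodeCorrector(whitelist)
    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        sentinel = object()
        it1, it2 = iter(f1), iter(f2)
        while True:
            rec1 = next(it1, sentinel)
            rec2 = next(it2, sentinel)
            if rec1 is sentinel and rec2 is sentinel:
                break
            if rec1 is sentinel or rec2 is sentinel:
                raise IOError(
                    f"FASTQ files {r1_path} and {r2_path} have different record counts"
                )
            stats.reads_seen += 1
            parsed = parse_read1(rec1.sequence)
            if parsed is None:
                stats.rejected_malformed += 1
                continue
            observed_bc, umi = parsed
            barcode, state = corrector.correct(observed_bc)
            if state == EXACT:
                stats.exact += 1
            elif state == CORRECTED:
                stats.corrected += 1
            elif state == AMBIGUOUS:
                stats.rejected_ambiguous += 1
                continue
            else:
                stats.rejected_no_match += 1
                continue
            yield TaggedRead(barcode, umi, rec2.sequence)
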