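"""Shared low-level helpers: RNG derivation, Hamming distances, FASTQ output."""

from __future__ import annotations

import gzip
import zlib
from typing import IO, Iterable

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a generator for one pipeline stage, salted by the stage name.

    A single run-level seed deterministically spawns independent substreams,
    so a stage can be rerun in isolation and still see the same randomness.
    """
    salt = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings; 'N' mismatches everything."""
    if len(a) != len(b):
        raise ValueError(f"hamming() requires equal lengths, got {len(a)} and {len(b)}")
    return sum(x != y or x == "N" for x, y in zip(a, b))


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into a base-4 integer (A=0, C=1, G=2, T=3)."""
    code = 0
    for base in kmer:
        code = (code << 2) | _BASE_INDEX[base]
    return code


def decode_kmer(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append(ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(out))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


_RC_TABLE = str.maketrans("ACGTN", "TGCAN")


def open_maybe_gzip(path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        if "w" in mode:
            # mtime=0 keeps rewrites of identical content byte-identical
            import io

            raw = gzip.GzipFile(path, "wb", mtime=0)
            return io.TextIOWrapper(raw) if "t" in mode else raw
        return gzip.open(path, mode)
    return open(path, mode)


class FastqWriter:
    """Minimal buffered FASTQ writer (gzip if the path ends in .gz).

    Qualities are constant: the simulator does not model quality scores and
    downstream stages do not read them.
    """

    def __init__(self, path, quality_char: str = "I"):
        self._handle = open_maybe_gzip(path, "wt")
        self._qual = quality_char
        self._buf: list[str] = []

    def write(self, name: str, seq: str) -> None:
        self._buf.append(f"@{name}\n{seq}\n+\n{self._qual * len(seq)}\n")
        if len(self._buf) >= 100_000:
            self.flush()

    def flush(self) -> None:
        if self._buf:
            self._handle.write("".join(self._buf))
            self._buf.clear()

    def close(self) -> None:
        self.flush()
        self._handle.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def apply_substitutions(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    """Apply independent per-base substitution errors at the given rate."""
    if error_rate <= 0:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < error_rate)
    if hits.size == 0:
        return seq
    chars = list(seq)
    for i in hits:
        original = chars[i]
        # substitute with one of the three other bases, uniformly
        choices = [b for b in ALPHABET if b != original]
        chars[i] = choices[rng.integers(0, len(choices))]
    return "".join(chars)


def chunked(iterable: Iterable, size: int):
    """Yield lists of up to `size` items."""
    chunk = []
    for item in iterable:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk
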