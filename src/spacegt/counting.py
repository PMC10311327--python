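"""Canonical spaced k-mer extraction and counting.

Applying a seed to every length-``l`` window of a sequence yields one
spaced ``w``-mer per window: the characters at the seed's care positions.
Counting pools canonical k-mers (the lexicographically smaller of a k-mer
and its reverse complement) across all reads of a sample; for palindromic
seeds the forward and reverse strand of a window produce reverse-complement
spaced k-mers, so counting is strand symmetric.

The heavy path packs k-mers into 2-bit-per-base 64-bit integers and runs on
numpy; :func:`extract_spaced_kmers` is the simple string-level reference
used for small inputs and in tests.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .seeds import Seed

__all__ = [
    "KmerCountTable",
    "extract_spaced_kmers",
    "canonicalize",
    "reverse_complement",
    "count_reads",
    "count_sequences",
    "kmers_covering_position",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code; anything that is not an upper/lower-case ACGT maps to 255
_CODES = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODES[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODES[_b] = _i

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(kmer: str) -> str:
    """Return ``min(kmer, reverse_complement(kmer))`` under A<C<G<T."""
    if set(kmer) - set("ACGT"):
        raise ValueError(f"k-mer contains non-ACGT symbols: {kmer!r}")
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def extract_spaced_kmers(sequence: str, seed: Seed) -> list[str]:
    """Spaced k-mers of every window, left to right, not canonicalized.

    Windows with a non-ACGT symbol at any care position are omitted;
    don't-care positions may hold any symbol.  Input case is ignored.
    """
    seq = sequence.upper()
    out = []
    offs = seed.care_offsets
    for start in range(len(seq) - seed.l + 1):
        kmer = "".join(seq[start + o] for o in offs)
        if set(kmer) - set("ACGT"):
            continue
        out.append(kmer)
    return out


def kmers_covering_position(seed: Seed) -> int:
    """Number of window placements in which a fixed position is sampled.

    A position is covered by a placement when it falls on a care position,
    which happens for exactly ``w`` of the ``l`` placements overlapping it.
    """
    return seed.w


def encode_sequence(seq: str) -> np.ndarray:
    """2-bit codes of a sequence (255 for non-ACGT), as uint8."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODES[raw]


def spaced_kmer_codes(codes: np.ndarray, seed: Seed) -> tuple[np.ndarray, int, int]:
    """Canonical spaced k-mers of all valid windows as packed uint64.

    Returns ``(kmers, windows_total, windows_skipped)``.  Requires
    ``seed.w <= 31`` so a k-mer fits 2 bits/base in a uint64 with headroom.
    """
    l, w = seed.l, seed.w
    if w > 31:
        raise ValueError("packed counting supports seed weights up to 31")
    n = codes.shape[0]
    if n < l:
        return np.empty(0, dtype=np.uint64), 0, 0
    starts = np.arange(n - l + 1)
    offs = np.asarray(seed.care_offsets)
    sub = codes[starts[:, None] + offs[None, :]]
    valid = (sub < 4).all(axis=1)
    windows_total = starts.shape[0]
    windows_skipped = int(windows_total - valid.sum())
    sub = sub[valid].astype(np.uint64)
    fwd = np.zeros(sub.shape[0], dtype=np.uint64)
    rev = np.zeros(sub.shape[0], dtype=np.uint64)
    for j in range(w):
        fwd = (fwd << np.uint64(2)) | sub[:, j]
        rev = (rev << np.uint64(2)) | (np.uint64(3) - sub[:, w - 1 - j])
    return np.minimum(fwd, rev), windows_total, windows_skipped


def decode_kmers(packed: np.ndarray, w: int) -> list[str]:
    """Unpack uint64 k-mers back to ACGT strings."""
    n = packed.shape[0]
    cols = np.empty((n, w), dtype=np.uint8)
    vals = packed.copy()
    for j in range(w - 1, -1, -1):
        cols[:, j] = (vals & np.uint64(3)).astype(np.uint8)
        vals >>= np.uint64(2)
    ascii_cols = _BASE_LUT[cols]
    return [row.tobytes().decode("ascii") for row in ascii_cols]


@dataclass
class KmerCountTable:
    """Counts of canonical spaced k-mers across a read set.

    Invariants: every key has length ``seed.w`` over ACGT, is canonical, and
    the counts sum to ``windows_total - windows_skipped``.
    """

    seed: Seed
    counts: dict[str, int] = field(default_factory=dict)
    windows_total: int = 0
    windows_skipped: int = 0

    def get(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        """Dump as ``kmer<TAB>count``, lexicographically sorted, with a
        ``#seed=`` header — bit-exact across runs."""
        with open(path, "w") as fh:
            fh.write(f"#seed={self.seed.pattern}\n")
            fh.write(f"#windows_total={self.windows_total}\n")
            fh.write(f"#windows_skipped={self.windows_skipped}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerCountTable":
        seed = None
        counts: dict[str, int] = {}
        windows_total = windows_skipped = 0
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if line.startswith("#seed="):
                    seed = Seed(line[len("#seed="):])
                elif line.startswith("#windows_total="):
                    windows_total = int(line.split("=", 1)[1])
                elif line.startswith("#windows_skipped="):
                    windows_skipped = int(line.split("=", 1)[1])
                elif line.startswith("#") or not line:
                    continue
                else:
                    try:
                        kmer, count = line.split("\t")
                        counts[kmer] = int(count)
                    except ValueError as exc:
                        raise ValueError(
                            f"malformed count record at line {i + 1} of {path}"
                        ) from exc
        if seed is None:
            raise ValueError(f"missing #seed= header in {path}")
        return cls(seed, counts, windows_total, windows_skipped)


def _iter_sequences(reads: str | Path | Iterable[str]) -> Iterator[str]:
    if isinstance(reads, (str, Path)):
        path = str(reads)
        # pysam.FastxFile handles FASTA/FASTQ, plain or gzipped
        with pysam.FastxFile(path) as fh:
            for i, rec in enumerate(fh):
                if rec.sequence is None:
                    raise ValueError(f"empty or truncated record #{i} in {path}")
                yield rec.sequence
    else:
        yield from reads


def count_sequences(sequences: Iterable[str], seed: Seed) -> KmerCountTable:
    """Count canonical spaced k-mers over in-memory sequences."""
    chunks = []
    windows_total = windows_skipped = 0
    for seq in sequences:
        packed, wt, ws = spaced_kmer_codes(encode_sequence(seq), seed)
        windows_total += wt
        windows_skipped += ws
        if packed.size:
            chunks.append(packed)
    counts: dict[str, int] = {}
    if chunks:
        allk = np.concatenate(chunks)
        uniq, cnt = np.unique(allk, return_counts=True)
        counts = dict(zip(decode_kmers(uniq, seed.w), cnt.tolist()))
    return KmerCountTable(seed, counts, windows_total, windows_skipped)


def count_reads(reads: str | Path | Iterable[str], seed: Seed,
                *more_files: str | Path) -> KmerCountTable:
    """Count canonical spaced k-mers across one or more read files.

    ``reads`` may be a FASTA/FASTQ path (plain or gzipped) or an iterable of
    sequence strings; additional paths are pooled into the same table (both
    mates of paired data are treated as independent reads).  Quality strings
    are ignored.  Deterministic for a fixed input.
    """
    def gen() -> Iterator[str]:
        yield from _iter_sequences(reads)
        for path in more_files:
            yield from _iter_sequences(path)

    return count_sequences(gen(), seed)
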