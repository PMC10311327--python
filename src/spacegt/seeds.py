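"""Spaced seeds: patterns of care ('1') and don't-care ('0') positions.

A seed samples ``w`` (its *weight*) out of ``l`` (its *length*) consecutive
sequence positions.  Contiguous k-mers are the special case ``w == l``.
Palindromic seeds — patterns equal to their own reversal — guarantee that
the spaced k-mers read from the forward and reverse strand of a window are
reverse complements of each other, which makes canonical representation
well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path

__all__ = [
    "Seed",
    "parse_seed",
    "is_palindromic",
    "mirror_extend",
    "count_palindromic_seeds",
    "contiguous_seed",
    "read_seed_file",
    "resolve_seed",
]


class SeedError(ValueError):
    """Raised for structurally invalid seed patterns."""


@dataclass(frozen=True)
class Seed:
    """A binary care/don't-care pattern.

    Attributes
    ----------
    pattern:
        The seed serialized as a string over ``{'0', '1'}``.  The first and
        last characters are always ``'1'``: leading or trailing don't-care
        positions would only shift windows without changing the sampled
        k-mers.
    """

    pattern: str
    care_offsets: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        p = self.pattern
        if not p:
            raise SeedError("empty seed pattern")
        if set(p) - {"0", "1"}:
            raise SeedError(f"seed pattern may only contain '0'/'1': {p!r}")
        if p[0] != "1" or p[-1] != "1":
            raise SeedError(
                f"seed pattern must start and end with a care position: {p!r}"
            )
        object.__setattr__(
            self, "care_offsets", tuple(i for i, c in enumerate(p) if c == "1")
        )

    @property
    def l(self) -> int:  # noqa: E743 - established seed notation
        """Total length of the pattern."""
        return len(self.pattern)

    @property
    def w(self) -> int:
        """Weight: number of care positions."""
        return len(self.care_offsets)

    @property
    def is_contiguous(self) -> bool:
        return self.w == self.l

    def __str__(self) -> str:
        return self.pattern


def parse_seed(text: str) -> Seed:
    """Parse a '1'/'0' pattern string into a :class:`Seed`.

    Round-trips: ``str(parse_seed(p)) == p`` for every valid pattern.
    """
    return Seed(text)


def is_palindromic(seed: Seed) -> bool:
    """True iff the pattern equals its reversal."""
    return seed.pattern == seed.pattern[::-1]


def mirror_extend(base: Seed) -> Seed:
    """Extend ``base`` with its mirrored copy on the right.

    The final care position of the base serves as the centre of the result,
    so the result has length ``2*l - 1``, weight ``2*w - 1`` and is
    palindromic by construction.
    """
    p = base.pattern
    return Seed(p + p[-2::-1])


def count_palindromic_seeds(l: int, w: int) -> int:
    """Number of palindromic seeds of length ``l`` and weight ``w``.

    Seeds must start and end with '1'.  Choosing the free care positions in
    the left half gives ``binom(floor(l/2)-1, floor(w/2)-1)`` patterns.  An
    even-length palindrome necessarily has even weight, so the count is 0
    when ``l`` is even and ``w`` odd.  Exact integer arithmetic throughout.
    """
    if l < 1 or w < 1 or w > l:
        return 0
    if l == 1:
        return 1 if w == 1 else 0
    if w == 1:
        return 0  # endpoints alone already contribute weight 2
    if l % 2 == 0 and w % 2 == 1:
        return 0
    return comb(l // 2 - 1, w // 2 - 1)


def contiguous_seed(k: int) -> Seed:
    """The all-care seed of weight and length ``k``."""
    if k < 1:
        raise SeedError("contiguous seed weight must be >= 1")
    return Seed("1" * k)


def read_seed_file(path: str | Path) -> list[Seed]:
    """Read seeds from a plain-text file, one pattern per line.

    Blank lines and lines starting with '#' are ignored.
    """
    seeds = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        seeds.append(parse_seed(line))
    if not seeds:
        raise SeedError(f"no seed patterns found in {path}")
    return seeds


def resolve_seed(spec: str) -> Seed:
    """Interpret ``spec`` as an inline pattern or a path to a seed file.

    If the string consists solely of '0'/'1' it is parsed directly;
    otherwise it is treated as a file path and the first seed is returned.
    """
    if spec and not (set(spec) - {"0", "1"}):
        return parse_seed(spec)
    return read_seed_file(spec)[0]
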