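"""Internal pairwise-alignment helpers shared by clustering and MSA.

Global alignment with free end gaps, match=1 / mismatch=-1 / gap=-2,
backed by scikit-bio's vectorized aligner.
"""

from __future__ import annotations

from functools import lru_cache

from skbio.alignment import pair_align
from skbio.sequence import GrammaredSequence
from skbio.util import classproperty


class _GappyDNA(GrammaredSequence):
    """DNA alphabet restricted to {A,C,G,T,N}; tolerant of none else."""

    @classproperty
    def degenerate_map(cls):
        return {"N": set("ACGT")}

    @classproperty
    def definite_chars(cls):
        return set("ACGT")

    @classproperty
    def default_gap_char(cls):
        return "-"

    @classproperty
    def gap_chars(cls):
        return set("-.")


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences with free end gaps.

    Returns the two gapped rows. Scores: match 1, mismatch -1, affine
    gaps (open 4, extend 2). Affine costs keep long indels contiguous; a
    linear gap cost of 2 admits co-optimal paths that scatter a long gap
    through surrounding matches, which breaks downstream gap-compatible
    merging.
    """
    res = pair_align(
        _GappyDNA(a),
        _GappyDNA(b),
        mode="global",
        sub_score=(1.0, -1.0),
        gap_cost=(4.0, 2.0),
        free_ends=True,
        max_paths=1,
    )
    row_a, row_b = res.paths[0].to_aligned((_GappyDNA(a), _GappyDNA(b)))
    return str(row_a), str(row_b)


def _trim_span(row_a: str, row_b: str) -> tuple[int, int]:
    """Column span excluding terminal-gap columns of either row."""
    n = len(row_a)
    a_start = next(i for i, c in enumerate(row_a) if c != "-")
    b_start = next(i for i, c in enumerate(row_b) if c != "-")
    a_end = n - next(i for i, c in enumerate(reversed(row_a)) if c != "-")
    b_end = n - next(i for i, c in enumerate(reversed(row_b)) if c != "-")
    return max(a_start, b_start), min(a_end, b_end)


def identity_from_rows(row_a: str, row_b: str) -> float:
    """Alignment identity: matches / columns, terminal gap columns
    excluded, N matching any base."""
    lo, hi = _trim_span(row_a, row_b)
    if hi <= lo:
        return 0.0
    matches = 0
    for x, y in zip(row_a[lo:hi], row_b[lo:hi]):
        if x == "-" or y == "-":
            continue
        if x == y or x == "N" or y == "N":
            matches += 1
    return matches / (hi - lo)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two DNA strings (see identity_from_rows)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    return _cached_identity(a, b) if a < b else _cached_identity(b, a)


@lru_cache(maxsize=65536)
def _cached_identity(a: str, b: str) -> float:
    return identity_from_rows(*align_pair(a, b))
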