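"""Quality trimming, paired-read merging, and per-locus error estimation.

The first pipeline stage: trims each mate with a two-ended block-window
quality scan, merges mates on their best overlap (falling back to an
artificial N-join so the pair still travels together), estimates a
per-locus sequencing error rate from the retained PHRED scores, and emits
per-locus FASTA plus the taxon and locus-error tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .io_formats import (
    AnnotatedReadPair,
    HeaderConfig,
    RejectLog,
    SequenceRecord,
    parse_annotated_fastq,
    write_purc_fasta,
    write_tables,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrimResult",
    "MergeResult",
    "PreprocessConfig",
    "PreprocessResult",
    "trim_read",
    "merge_pair",
    "estimate_locus_error",
    "run_preprocess",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

EPS_MIN = 1e-6
EPS_MAX = 0.5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TrimResult:
    """Outcome of quality trimming: keep flag plus a half-open slice."""

    kept: bool
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class MergeResult:
    mode: str  # overlap_merged | artificially_joined | single_survivor
    sequence: str
    qual: tuple[int, ...]


def trim_read(
    seq: str,
    qual: Sequence[int],
    q_threshold: int = 20,
    min_length: int = 100,
) -> TrimResult:
    """Two-ended block-window quality trim.

    The read is scanned in non-overlapping windows of width
    ``max(1, len // 10)``.  The leading cut is the start of the first
    window (5'->3') whose mean PHRED reaches ``q_threshold``; the trailing
    cut is found symmetrically from the 3' end.  Reads where no window
    passes, or where the trimmed slice is shorter than ``min_length``,
    are dropped.
    """
    n = len(seq)
    if n == 0 or n != len(qual):
        raise ValueError("seq and qual must be equal-length and non-empty")
    w = max(1, n // 10)

    start: Optional[int] = None
    for i in range(0, n, w):
        window = qual[i : i + w]
        if sum(window) / len(window) >= q_threshold:
            start = i
            break
    if start is None:
        return TrimResult(kept=False)

    end: Optional[int] = None
    j = n
    while j > 0:
        window = qual[max(0, j - w) : j]
        if sum(window) / len(window) >= q_threshold:
            end = j
            break
        j -= w
    assert end is not None  # some window passed the leading scan

    if end - start < min_length:
        return TrimResult(kept=False)
    return TrimResult(kept=True, start=start, end=end)


def merge_pair(
    seq1: str,
    qual1: Sequence[int],
    seq2: str,
    qual2: Sequence[int],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
    n_pad: int = 10,
) -> MergeResult:
    """Merge a trimmed pair on its best suffix/prefix overlap.

    ``seq2`` is reverse-complemented internally. Candidate overlaps of
    length >= ``min_overlap`` are scored by mismatch fraction (N matches
    anything); the lowest fraction wins, ties going to the longest
    overlap. At each conflicting position the base with the higher PHRED
    score is emitted (tie -> read 1). If no candidate is acceptable the
    mates are joined with a run of ``n_pad`` N's (quality 0).
    """
    rc2 = revcomp(seq2)
    rq2 = list(qual2)[::-1]
    len1, len2 = len(seq1), len(seq2)

    best: Optional[tuple[float, int]] = None  # (mismatch_frac, overlap_len)
    for length in range(min_overlap, min(len1, len2) + 1):
        a = seq1[len1 - length :]
        b = rc2[:length]
        mismatches = sum(
            1 for x, y in zip(a, b) if x != y and x != "N" and y != "N"
        )
        frac = mismatches / length
        if best is None or frac < best[0] or (frac == best[0] and length > best[1]):
            best = (frac, length)

    if best is not None and best[0] <= max_mismatch_frac:
        length = best[1]
        out_seq = list(seq1[: len1 - length])
        out_qual = list(qual1[: len1 - length])
        for k in range(length):
            b1, q1 = seq1[len1 - length + k], qual1[len1 - length + k]
            b2, q2 = rc2[k], rq2[k]
            if b1 == b2:
                out_seq.append(b1)
                out_qual.append(max(q1, q2))
            elif b1 == "N":
                out_seq.append(b2)
                out_qual.append(q2)
            elif b2 == "N" or q1 >= q2:
                out_seq.append(b1)
                out_qual.append(q1)
            else:
                out_seq.append(b2)
                out_qual.append(q2)
        out_seq.extend(rc2[length:])
        out_qual.extend(rq2[length:])
        return MergeResult("overlap_merged", "".join(out_seq), tuple(out_qual))

    joined = seq1 + "N" * n_pad + rc2
    qual = tuple(qual1) + (0,) * n_pad + tuple(rq2)
    return MergeResult("artificially_joined", joined, qual)


def estimate_locus_error(
    reads_by_locus: Mapping[str, Iterable[Sequence[int]]]
) -> dict[str, float]:
    """Per-locus error rate from PHRED scores.

    Q-bar for a locus is the mean over reads of each read's mean PHRED;
    the error rate is ``10**(-Qbar/10)``, clamped to [1e-6, 0.5]. Loci
    with no retained reads are omitted with a warning.
    """
    table: dict[str, float] = {}
    for locus, reads in reads_by_locus.items():
        means = [sum(q) / len(q) for q in reads if len(q) > 0]
        if not means:
            logger.warning("locus %s has no retained reads; omitted", locus)
            continue
        q_bar = sum(means) / len(means)
        eps = 10.0 ** (-q_bar / 10.0)
        table[locus] = min(max(eps, EPS_MIN), EPS_MAX)
    return table


@dataclass(frozen=True)
class PreprocessConfig:
    q_threshold: int = 20
    min_length: int = 100
    min_overlap: int = 10
    max_mismatch_frac: float = 0.25
    n_pad: int = 10
    phred_offset: int = 33
    header: HeaderConfig = HeaderConfig()


@dataclass
class PreprocessResult:
    """Counts and output paths; input pairs reconcile exactly:
    n_input == n_rejected + n_discarded + n_merged + n_njoined + n_single.
    """

    n_input: int = 0
    n_rejected: int = 0
    n_discarded: int = 0
    n_merged: int = 0
    n_njoined: int = 0
    n_single: int = 0
    fasta_paths: dict[str, Path] = field(default_factory=dict)
    taxon_table: dict[str, Optional[int]] = field(default_factory=dict)
    locus_error_table: dict[str, float] = field(default_factory=dict)

    @property
    def n_emitted(self) -> int:
        return self.n_merged + self.n_njoined + self.n_single

    def reconciles(self) -> bool:
        return self.n_input == (
            self.n_rejected + self.n_discarded + self.n_emitted
        )


def run_preprocess(
    path_r1: Union[str, Path],
    path_r2: Union[str, Path],
    out_dir: Union[str, Path],
    config: PreprocessConfig = PreprocessConfig(),
) -> PreprocessResult:
    """Full first stage: trim, merge, estimate errors, write outputs.

    Writes ``<locus>.fasta`` per locus, ``taxon_table.txt``,
    ``locus_err.txt``, ``preprocess.log`` and ``rejects.txt`` under
    ``out_dir``. Deterministic for fixed input and config.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = PreprocessResult()
    rejects = RejectLog()

    records: list[SequenceRecord] = []
    quals_by_locus: dict[str, list[Sequence[int]]] = {}
    uid_counter: dict[tuple[str, str], int] = {}

    for pair in parse_annotated_fastq(
        path_r1,
        path_r2,
        header=config.header,
        phred_offset=config.phred_offset,
        reject_log=rejects,
    ):
        result.taxon_table.setdefault(pair.taxon, None)
        t1 = trim_read(pair.seq1, pair.qual1, config.q_threshold, config.min_length)
        t2 = trim_read(pair.seq2, pair.qual2, config.q_threshold, config.min_length)
        if not t1.kept and not t2.kept:
            result.n_discarded += 1
            continue

        s1 = pair.seq1[t1.start : t1.end] if t1.kept else ""
        q1 = list(pair.qual1[t1.start : t1.end]) if t1.kept else []
        s2 = pair.seq2[t2.start : t2.end] if t2.kept else ""
        q2 = list(pair.qual2[t2.start : t2.end]) if t2.kept else []

        if t1.kept and t2.kept:
            merged = merge_pair(
                s1, q1, s2, q2,
                min_overlap=config.min_overlap,
                max_mismatch_frac=config.max_mismatch_frac,
                n_pad=config.n_pad,
            )
            if merged.mode == "overlap_merged":
                result.n_merged += 1
            else:
                result.n_njoined += 1
            sequence = merged.sequence
            retained_quals = [q1, q2]
        else:
            # exactly one mate survived: emit it alone
            result.n_single += 1
            sequence = s1 if t1.kept else revcomp(s2)
            retained_quals = [q1 if t1.kept else q2]

        key = (pair.taxon, pair.locus)
        uid_counter[key] = uid_counter.get(key, 0) + 1
        records.append(
            SequenceRecord(pair.taxon, pair.locus, uid_counter[key], sequence)
        )
        quals_by_locus.setdefault(pair.locus, []).extend(retained_quals)

    result.n_input = rejects.n_input
    result.n_rejected = rejects.n_rejected
    result.fasta_paths = write_purc_fasta(records, out_dir)
    result.locus_error_table = estimate_locus_error(quals_by_locus)
    write_tables(
        result.taxon_table,
        result.locus_error_table,
        out_dir / "taxon_table.txt",
        out_dir / "locus_err.txt",
    )
    rejects.write(out_dir / "rejects.txt")

    log_lines = [
        f"input_pairs\t{result.n_input}",
        f"rejected\t{result.n_rejected}",
        f"discarded\t{result.n_discarded}",
        f"merged\t{result.n_merged}",
        f"n_joined\t{result.n_njoined}",
        f"single_survivor\t{result.n_single}",
        f"emitted\t{result.n_emitted}",
    ]
    (out_dir / "preprocess.log").write_text("\n".join(log_lines) + "\n")
    logger.info("preprocess: %s", "; ".join(log_lines).replace("\t", "="))
    if not result.reconciles():
        raise AssertionError("read accounting failed to reconcile")
    return result


def phred_from_error(eps: float) -> float:
    """Inverse of the error model: PHRED score for an error probability."""
    return -10.0 * math.log10(eps)
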