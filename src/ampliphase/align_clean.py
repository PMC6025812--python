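"""Internal realignment and alignment cleaning.

A center-star multiple aligner (match=1, mismatch=-1, gap=-2, merged by
gap propagation) plus a column-occupancy cleaner. These replace the
external aligner / alignment trimmer pair used by the original workflow,
so the tested default has no binary dependencies. A hook for shelling out
to an external aligner is provided but not exercised in CI.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from ._align import align_pair, pairwise_identity

__all__ = ["Alignment", "center_star_align", "clean_columns", "external_align"]

_ALPHABET = frozenset("ACGTN-")


@dataclass
class Alignment:
    """Rows of equal-length gapped sequences."""

    rows: list[tuple[str, str]]  # (label, gapped sequence)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment needs >= 1 row")
        width = len(self.rows[0][1])
        for label, seq in self.rows:
            if len(seq) != width:
                raise ValueError(f"row {label!r} has unequal length")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValueError(f"row {label!r} has invalid characters {bad}")

    @property
    def width(self) -> int:
        return len(self.rows[0][1])

    def ungapped(self, i: int) -> str:
        return self.rows[i][1].replace("-", "")


def _pick_center(seqs: Sequence[str]) -> int:
    """Index of the sequence with maximal summed pairwise identity
    (ties -> longest, then lexicographically smallest)."""
    n = len(seqs)
    sums = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[i], seqs[j])
            sums[i] += ident
            sums[j] += ident
    return max(range(n), key=lambda i: (sums[i], len(seqs[i]), _neg_lex(seqs[i])))


class _neg_lex(str):
    """Inverts lexicographic order so max() prefers the smaller string."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)


def center_star_align(
    seqs: Sequence[str], labels: Optional[Sequence[str]] = None
) -> Alignment:
    """Center-star multiple alignment.

    Each non-center sequence is pairwise-aligned to the center and the
    pairwise alignments are merged by propagating center gaps. Ungapping
    any row recovers its input sequence exactly.
    """
    if not seqs or any(not s for s in seqs):
        raise ValueError("need >= 1 non-empty sequence")
    if labels is None:
        labels = [str(i) for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError("labels/seqs length mismatch")
    if len(seqs) == 1:
        return Alignment([(labels[0], seqs[0])])

    c = _pick_center(seqs)
    master = seqs[c]  # center row, accumulating gaps
    rows: list[Optional[str]] = [None] * len(seqs)

    for i, seq in enumerate(seqs):
        if i == c:
            continue
        row_c, row_s = align_pair(seqs[c], seq)
        master, row_s, rows = _merge_into_master(master, row_c, row_s, rows)
        rows[i] = row_s
    rows[c] = master
    return Alignment(
        [(labels[i], rows[i]) for i in range(len(seqs))]  # type: ignore[misc]
    )


def _merge_into_master(
    master: str, row_c: str, row_s: str, rows: list[Optional[str]]
) -> tuple[str, str, list[Optional[str]]]:
    """Reconcile one pairwise alignment with the gapped master center row.

    Walks master and row_c (both spell the center sequence when
    ungapped); wherever one has a gap the other lacks, a gap column is
    inserted into the other side (and into all previously merged rows for
    master-side insertions).
    """
    out_master: list[str] = []
    out_s: list[str] = []
    insert_cols: list[int] = []  # master-frame positions needing a new gap col
    i = j = 0
    while i < len(master) or j < len(row_c):
        mc = master[i] if i < len(master) else None
        cc = row_c[j] if j < len(row_c) else None
        if mc is not None and cc is not None and (mc == cc or (mc != "-" and cc != "-")):
            out_master.append(mc)
            out_s.append(row_s[j])
            i += 1
            j += 1
        elif mc == "-" and (cc is None or cc != "-"):
            # master already has a gap here; pad the new row
            out_master.append("-")
            out_s.append("-")
            i += 1
        else:
            # new row introduces a gap column into the master frame
            insert_cols.append(len(out_master))
            out_master.append("-")
            out_s.append(row_s[j])
            j += 1
    if insert_cols:
        new_rows: list[Optional[str]] = []
        for row in rows:
            if row is None:
                new_rows.append(None)
                continue
            chars = list(row)
            for pos in insert_cols:
                chars.insert(pos, "-")
            new_rows.append("".join(chars))
        rows = new_rows
    return "".join(out_master), "".join(out_s), rows


def clean_columns(aln: Alignment, min_occupancy: float = 0.33) -> Alignment:
    """Drop columns whose fraction of non-gap, non-N characters is below
    ``min_occupancy`` (strictly-less-than; N counts as missing)."""
    if not 0.0 <= min_occupancy <= 1.0:
        raise ValueError("min_occupancy must be in [0, 1]")
    n_rows = len(aln.rows)
    keep = []
    for col in range(aln.width):
        occupied = sum(
            1 for _, seq in aln.rows if seq[col] not in ("-", "N")
        )
        if occupied / n_rows >= min_occupancy:
            keep.append(col)
    if not keep:
        raise ValueError(
            "cleaning removed every column; reduce the occupancy threshold"
        )
    rows = [
        (label, "".join(seq[c] for c in keep)) for label, seq in aln.rows
    ]
    return Alignment(rows)


def external_align(
    seqs: Sequence[str],
    labels: Optional[Sequence[str]] = None,
    command: str = "mafft",
) -> Alignment:
    """Optional hook: align via a user-installed external aligner.

    Not used by default; the internal center-star aligner is the tested
    path.
    """
    if shutil.which(command) is None:
        raise RuntimeError(f"external aligner {command!r} not found on PATH")
    if labels is None:
        labels = [str(i) for i in range(len(seqs))]
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fasta"
        fasta.write_text(
            "".join(f">{lab}\n{seq}\n" for lab, seq in zip(labels, seqs))
        )
        proc = subprocess.run(
            [command, "--auto", "--quiet", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows: list[tuple[str, str]] = []
    label, chunks = None, []
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            if label is not None:
                rows.append((label, "".join(chunks).upper()))
            label, chunks = line[1:].strip(), []
        else:
            chunks.append(line.strip())
    if label is not None:
        rows.append((label, "".join(chunks).upper()))
    return Alignment(rows)
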