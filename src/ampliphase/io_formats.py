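"""Readers and writers for every file the pipeline touches.

Formats handled:

* annotated paired-end FASTQ (taxon/locus labels carried in the header),
* per-locus FASTA with the ``>taxon|locus|uid`` header grammar,
* clustered FASTA with ``;size=S`` abundance annotations,
* the two-column taxon-ploidy and locus-error TSV tables.

All writers are atomic (temp file + rename) so a crashed run never leaves
a half-written output behind.
"""

from __future__ import annotations

import os
import re
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "AnnotatedReadPair",
    "SequenceRecord",
    "ClusterRecord",
    "HeaderConfig",
    "RejectLog",
    "parse_annotated_fastq",
    "write_purc_fasta",
    "parse_purc_fasta",
    "write_clusters_fasta",
    "parse_clusters_fasta",
    "read_taxon_table",
    "write_taxon_table",
    "read_locus_error_table",
    "write_locus_error_table",
    "read_tables",
    "write_tables",
]

_LABEL_BAD = re.compile(r"[|\s]")
_DNA_OK = frozenset("ACGTN")


def _check_label(value: str, what: str) -> str:
    if not value or _LABEL_BAD.search(value):
        raise ValueError(
            f"{what} label {value!r} is empty or contains '|' or whitespace"
        )
    return value


@dataclass
class AnnotatedReadPair:
    """One demultiplexed read pair with its taxon and locus annotation."""

    read_id: str
    taxon: str
    locus: str
    seq1: str
    seq2: str
    qual1: Sequence[int]
    qual2: Sequence[int]

    def __post_init__(self) -> None:
        _check_label(self.taxon, "taxon")
        _check_label(self.locus, "locus")
        if len(self.seq1) != len(self.qual1):
            raise ValueError(f"read {self.read_id}: seq1/qual1 length mismatch")
        if len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.read_id}: seq2/qual2 length mismatch")


@dataclass(frozen=True)
class SequenceRecord:
    """One processed sequence, serialized as ``>taxon|locus|uid``."""

    taxon: str
    locus: str
    uid: int
    sequence: str

    def __post_init__(self) -> None:
        _check_label(self.taxon, "taxon")
        _check_label(self.locus, "locus")
        if self.uid < 1:
            raise ValueError(f"uid must be a positive integer, got {self.uid}")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")

    @property
    def header(self) -> str:
        return f"{self.taxon}|{self.locus}|{self.uid}"


@dataclass(frozen=True)
class ClusterRecord:
    """One abundance-annotated cluster: ``>taxon|locus|clusterN;size=S``."""

    taxon: str
    locus: str
    cluster_index: int
    size: int
    sequence: str

    def __post_init__(self) -> None:
        _check_label(self.taxon, "taxon")
        _check_label(self.locus, "locus")
        if self.cluster_index < 0:
            raise ValueError("cluster_index must be non-negative")
        if self.size < 1:
            raise ValueError(f"cluster size must be >= 1, got {self.size}")

    @property
    def header(self) -> str:
        return f"{self.taxon}|{self.locus}|cluster{self.cluster_index};size={self.size}"


@dataclass(frozen=True)
class HeaderConfig:
    """Where taxon and locus live inside an annotated FASTQ header.

    The header is split on whitespace; token ``token_index`` is then split
    on ``delimiter`` and the ``taxon_field``/``locus_field`` entries are
    taken. The default reads the last whitespace token as ``taxon:locus``,
    the dialect the bundled simulator writes.
    """

    token_index: int = -1
    delimiter: str = ":"
    taxon_field: int = 0
    locus_field: int = 1

    def extract(self, title: str) -> tuple[str, str]:
        tokens = title.split()
        try:
            fields = tokens[self.token_index].split(self.delimiter)
            taxon = fields[self.taxon_field]
            locus = fields[self.locus_field]
        except IndexError:
            raise ValueError(f"header {title!r} lacks taxon/locus annotation")
        if not taxon or not locus:
            raise ValueError(f"header {title!r} lacks taxon/locus annotation")
        return taxon, locus


@dataclass
class RejectLog:
    """Accounting for reads that could not be annotated.

    Every input pair is either emitted or recorded here; totals reconcile
    exactly.
    """

    entries: list[tuple[str, str]] = field(default_factory=list)
    n_emitted: int = 0

    def add(self, read_id: str, reason: str) -> None:
        self.entries.append((read_id, reason))

    @property
    def n_rejected(self) -> int:
        return len(self.entries)

    @property
    def n_input(self) -> int:
        return self.n_emitted + self.n_rejected

    def write(self, path: Union[str, Path]) -> None:
        _atomic_write(path, "".join(f"{rid}\t{why}\n" for rid, why in self.entries))


def _decode_phred(qual: str, offset: int, where: str) -> list[int]:
    scores = [ord(c) - offset for c in qual]
    for s in scores:
        if not 0 <= s <= 93:
            raise ValueError(f"{where}: PHRED score {s} outside [0, 93]")
    return scores


def parse_annotated_fastq(
    path_r1: Union[str, Path],
    path_r2: Union[str, Path],
    header: HeaderConfig = HeaderConfig(),
    phred_offset: int = 33,
    reject_log: Optional[RejectLog] = None,
) -> Iterator[AnnotatedReadPair]:
    """Stream paired, annotated reads from two FASTQ files.

    Pairing is by position. Unequal record counts raise a hard error
    naming both files; records missing the taxon/locus annotation are
    routed to ``reject_log`` (never silently dropped).
    """
    path_r1, path_r2 = Path(path_r1), Path(path_r2)
    with open(path_r1) as h1, open(path_r2) as h2:
        it1 = _counting_fastq(h1, path_r1)
        it2 = _counting_fastq(h2, path_r2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                raise ValueError(
                    f"FASTQ pair count mismatch between {path_r1} and {path_r2}"
                )
            title1, seq1, q1 = rec1
            title2, seq2, q2 = rec2
            read_id = title1.split()[0] if title1.split() else title1
            try:
                taxon, locus = header.extract(title1)
            except ValueError as exc:
                if reject_log is not None:
                    reject_log.add(read_id, str(exc))
                    continue
                raise
            pair = AnnotatedReadPair(
                read_id=read_id,
                taxon=taxon,
                locus=locus,
                seq1=seq1.upper(),
                seq2=seq2.upper(),
                qual1=_decode_phred(q1, phred_offset, f"{path_r1}:{read_id}"),
                qual2=_decode_phred(q2, phred_offset, f"{path_r2}:{read_id}"),
            )
            if reject_log is not None:
                reject_log.n_emitted += 1
            yield pair


def _counting_fastq(handle, path: Path):
    """FASTQ iterator that reports the record number on parse failure."""
    n = 0
    try:
        for rec in FastqGeneralIterator(handle):
            n += 1
            yield rec
    except ValueError as exc:
        raise ValueError(
            f"malformed FASTQ record near record {n + 1} "
            f"(~line {4 * n + 1}) in {path}: {exc}"
        ) from exc


# ---------------------------------------------------------------------------
# FASTA with the '>taxon|locus|uid' grammar, one file per locus
# ---------------------------------------------------------------------------

def write_purc_fasta(
    records: Iterable[SequenceRecord], out_dir: Union[str, Path]
) -> dict[str, Path]:
    """Write one FASTA per locus; returns ``{locus: path}``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_locus: dict[str, list[SequenceRecord]] = {}
    seen: set[tuple[str, str, int]] = set()
    for rec in records:
        key = (rec.taxon, rec.locus, rec.uid)
        if key in seen:
            raise ValueError(
                f"duplicate uid {rec.uid} for taxon {rec.taxon}, locus {rec.locus}"
            )
        seen.add(key)
        by_locus.setdefault(rec.locus, []).append(rec)
    paths: dict[str, Path] = {}
    for locus, recs in by_locus.items():
        path = out_dir / f"{locus}.fasta"
        _atomic_write(
            path, "".join(f">{r.header}\n{r.sequence}\n" for r in recs)
        )
        paths[locus] = path
    return paths


def parse_purc_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    records = []
    for header, seq in _iter_fasta(path):
        parts = header.split("|")
        if len(parts) != 3:
            raise ValueError(f"{path}: bad header '>{header}' (want taxon|locus|uid)")
        taxon, locus, uid = parts
        records.append(SequenceRecord(taxon, locus, int(uid), seq))
    return records


_CLUSTER_HEADER = re.compile(
    r"^(?P<taxon>[^|]+)\|(?P<locus>[^|]+)\|cluster(?P<idx>\d+);size=(?P<size>\d+)$"
)


def write_clusters_fasta(
    clusters: Iterable[ClusterRecord], path: Union[str, Path]
) -> None:
    _atomic_write(
        path, "".join(f">{c.header}\n{c.sequence}\n" for c in clusters)
    )


def parse_clusters_fasta(path: Union[str, Path]) -> list[ClusterRecord]:
    out = []
    for header, seq in _iter_fasta(path):
        m = _CLUSTER_HEADER.match(header)
        if m is None:
            raise ValueError(
                f"{path}: bad cluster header '>{header}' "
                "(want taxon|locus|clusterN;size=S)"
            )
        out.append(
            ClusterRecord(
                m["taxon"], m["locus"], int(m["idx"]), int(m["size"]), seq
            )
        )
    return out


def _iter_fasta(path: Union[str, Path]) -> Iterator[tuple[str, str]]:
    header: Optional[str] = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    yield header, "".join(chunks)
                header = line[1:].strip()
                chunks = []
            elif line:
                chunks.append(line.strip())
        if header is not None:
            yield header, "".join(chunks)


# ---------------------------------------------------------------------------
# Taxon-ploidy and locus-error TSV tables
# ---------------------------------------------------------------------------

def write_taxon_table(
    table: dict[str, Optional[int]], path: Union[str, Path]
) -> None:
    lines = []
    for taxon in table:
        ploidy = table[taxon]
        if ploidy is not None and (not isinstance(ploidy, int) or ploidy < 1):
            raise ValueError(f"taxon {taxon}: ploidy must be a positive int or None")
        lines.append(f"{taxon}\t{'None' if ploidy is None else ploidy}\n")
    _atomic_write(path, "".join(lines))


def read_taxon_table(path: Union[str, Path]) -> dict[str, Optional[int]]:
    table: dict[str, Optional[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                taxon, value = line.split("\t")
            except ValueError:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            if taxon in table:
                raise ValueError(f"{path}:{lineno}: duplicate taxon {taxon!r}")
            if value == "None":
                table[taxon] = None
            else:
                try:
                    ploidy = int(value)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: unparseable ploidy {value!r} "
                        f"for taxon {taxon!r}"
                    ) from None
                if ploidy < 1:
                    raise ValueError(
                        f"{path}:{lineno}: ploidy must be >= 1 for taxon {taxon!r}"
                    )
                table[taxon] = ploidy
    return table


def write_locus_error_table(
    table: dict[str, float], path: Union[str, Path]
) -> None:
    lines = []
    for locus, eps in table.items():
        if not 0.0 < eps < 1.0:
            raise ValueError(f"locus {locus}: error rate {eps} outside (0, 1)")
        lines.append(f"{locus}\t{eps:.7g}\n")
    _atomic_write(path, "".join(lines))


def read_locus_error_table(path: Union[str, Path]) -> dict[str, float]:
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                locus, value = line.split("\t")
                eps = float(value)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: expected 'locus<TAB>error_rate'"
                ) from None
            if not 0.0 < eps < 1.0:
                raise ValueError(f"{path}:{lineno}: error rate {eps} outside (0, 1)")
            table[locus] = eps
    return table


def write_tables(
    taxon_table: dict[str, Optional[int]],
    locus_error_table: dict[str, float],
    taxon_path: Union[str, Path],
    locus_err_path: Union[str, Path],
) -> None:
    write_taxon_table(taxon_table, taxon_path)
    write_locus_error_table(locus_error_table, locus_err_path)


def read_tables(
    taxon_path: Union[str, Path], locus_err_path: Union[str, Path]
) -> tuple[dict[str, Optional[int]], dict[str, float]]:
    return read_taxon_table(taxon_path), read_locus_error_table(locus_err_path)


def _atomic_write(path: Union[str, Path], text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
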