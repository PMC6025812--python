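"""Haplotype inference from abundance-sorted clusters.

Implements the final pipeline stage: merging of gap-identical clusters,
integer-partition enumeration, a multinomial likelihood over haplotype
dosage configurations for known ploidy, a real-vs-error likelihood scan
for unknown ploidy, and a haploid/consensus mode.

Model sketch: an individual of ploidy K carrying haplotype copy numbers
(k_1 >= ... >= k_j) generates reads multinomially. Cluster i <= j draws
probability (1 - eps) * k_i / K; the remaining clusters split the error
mass eps uniformly. Only the multinomial kernel sum(n_i * ln p_i) is
evaluated — the combinatorial constant is shared by every configuration
and cannot change the ranking.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .align_clean import Alignment, center_star_align, clean_columns
from .io_formats import (
    ClusterRecord,
    parse_clusters_fasta,
    read_locus_error_table,
    read_taxon_table,
    _atomic_write,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterSet",
    "HaplotypeConfiguration",
    "UnknownPloidyScan",
    "HaplotypeCall",
    "merge_gap_identical",
    "integer_partitions",
    "config_loglik",
    "infer_known_ploidy",
    "scan_unknown_ploidy",
    "call_haploid",
    "crunch",
    "CrunchOptions",
]

EPS_MIN = 1e-6
EPS_MAX = 0.5


def _clamp_eps(eps: float) -> float:
    if not EPS_MIN < eps < EPS_MAX:
        clamped = min(max(eps, EPS_MIN), EPS_MAX)
        logger.warning("error rate %g clamped to %g", eps, clamped)
        return clamped
    return eps


def _cluster_sort_key(cluster: tuple[str, int]) -> tuple[int, str]:
    seq, size = cluster
    return (-size, seq)


@dataclass
class ClusterSet:
    """Abundance-sorted clusters for one taxon x locus."""

    taxon: str
    locus: str
    clusters: list[tuple[str, int]]  # (sequence, size), size descending

    def __post_init__(self) -> None:
        if not self.clusters:
            raise ValueError(f"{self.taxon}|{self.locus}: empty cluster set")
        for seq, size in self.clusters:
            if size < 1:
                raise ValueError(f"{self.taxon}|{self.locus}: size {size} < 1")
        self.clusters = sorted(self.clusters, key=_cluster_sort_key)

    @property
    def m(self) -> int:
        return len(self.clusters)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(size for _, size in self.clusters)

    @property
    def total_reads(self) -> int:
        return sum(self.sizes)


@dataclass(frozen=True)
class HaplotypeConfiguration:
    """An integer partition of K with its log-likelihood."""

    partition: tuple[int, ...]
    loglik: float


@dataclass(frozen=True)
class UnknownPloidyScan:
    """Log-likelihoods for h = 0..m real haplotypes and the accepted h*."""

    logliks: tuple[float, ...]
    h_star: int
    cutoff: float


@dataclass(frozen=True)
class HaplotypeCall:
    taxon: str
    locus: str
    mode: str  # known_ploidy | unknown_ploidy | haploid
    haplotypes: tuple[tuple[str, int], ...]  # (sequence, copies)
    configuration: Optional[HaplotypeConfiguration] = None
    scan: Optional[UnknownPloidyScan] = None


# ---------------------------------------------------------------------------
# Gap-identical cluster merging
# ---------------------------------------------------------------------------

def _gap_compatible(a: str, b: str) -> bool:
    """True if the two aligned rows agree at every column where both carry
    a non-gap, non-N character."""
    for x, y in zip(a, b):
        if x in "-N" or y in "-N":
            continue
        if x != y:
            return False
    return True


def _merge_survivor(
    a: tuple[str, int], b: tuple[str, int]
) -> tuple[str, int]:
    """Keep the sequence with fewer gap+N characters (tie -> larger size,
    then lexicographic); sum the sizes."""
    def missing(seq: str) -> int:
        return seq.count("-") + seq.count("N")

    total = a[1] + b[1]
    ka = (missing(a[0]), -a[1], a[0])
    kb = (missing(b[0]), -b[1], b[0])
    winner = a[0] if ka <= kb else b[0]
    return winner, total


def merge_gap_identical(clusters: ClusterSet) -> ClusterSet:
    """Merge clusters identical up to gaps/Ns, iterating in size order.

    Requires mutually aligned (equal-length) sequences; realign first
    otherwise. Repeatedly merges the first compatible pair in size-sorted
    order until no pair merges.
    """
    lengths = {len(seq) for seq, _ in clusters.clusters}
    if len(lengths) > 1:
        raise ValueError(
            f"{clusters.taxon}|{clusters.locus}: clusters are not aligned "
            "(unequal lengths); run with --realign"
        )
    current = list(clusters.clusters)
    merged = True
    while merged:
        merged = False
        current.sort(key=_cluster_sort_key)
        for i in range(len(current)):
            for j in range(i + 1, len(current)):
                if _gap_compatible(current[i][0], current[j][0]):
                    survivor = _merge_survivor(current[i], current[j])
                    current = (
                        current[:i]
                        + current[i + 1 : j]
                        + current[j + 1 :]
                        + [survivor]
                    )
                    merged = True
                    break
            if merged:
                break
    return ClusterSet(clusters.taxon, clusters.locus, current)


# ---------------------------------------------------------------------------
# Integer partitions and the multinomial kernel
# ---------------------------------------------------------------------------

def integer_partitions(k: int) -> list[tuple[int, ...]]:
    """All partitions of ``k`` as non-increasing tuples, in decreasing
    lexicographic order: 4 -> (4), (3,1), (2,2), (2,1,1), (1,1,1,1)."""
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    out: list[tuple[int, ...]] = []

    def rec(remaining: int, cap: int, prefix: tuple[int, ...]) -> None:
        if remaining == 0:
            out.append(prefix)
            return
        for part in range(min(cap, remaining), 0, -1):
            rec(remaining - part, part, prefix + (part,))

    rec(k, k, ())
    return out


def config_loglik(
    clusters: Union[ClusterSet, Sequence[int]],
    partition: Sequence[int],
    eps: float,
) -> float:
    """Multinomial kernel log-likelihood of a dosage configuration.

    Cluster i <= j gets p_i = (1 - eps) * k_i / K; the remaining m - j
    clusters share p = eps / (m - j). When the partition covers every
    cluster (j == m) the error mass is renormalized away: p_i = k_i / K.
    """
    sizes = clusters.sizes if isinstance(clusters, ClusterSet) else tuple(clusters)
    m = len(sizes)
    j = len(partition)
    big_k = sum(partition)
    if j > m:
        raise ValueError(f"partition has {j} parts but only {m} clusters")
    if any(k < 1 for k in partition):
        raise ValueError("partition parts must be positive")

    loglik = 0.0
    for i, n_i in enumerate(sizes):
        if i < j:
            p = (partition[i] / big_k) if j == m else (1.0 - eps) * partition[i] / big_k
        else:
            p = eps / (m - j)
        if p <= 0.0:
            if n_i > 0:
                return -math.inf
            continue
        loglik += n_i * math.log(p)
    return loglik


def infer_known_ploidy(
    clusters: ClusterSet,
    ploidy: int,
    eps: float,
    unique: bool = False,
) -> HaplotypeCall:
    """Maximum-likelihood dosage configuration for a known ploidy K.

    Evaluates every integer partition of K with at most min(K, m) parts;
    ties prefer fewer distinct haplotypes, then a larger leading dosage.
    Haplotype i is reported with ``copies = k_i`` (or 1 with ``unique``).
    """
    if ploidy < 1:
        raise ValueError(f"ploidy must be >= 1, got {ploidy}")
    eps = _clamp_eps(eps)
    m = clusters.m
    best: Optional[HaplotypeConfiguration] = None
    for partition in integer_partitions(ploidy):
        if len(partition) > min(ploidy, m):
            continue
        ll = config_loglik(clusters, partition, eps)
        if best is None or _config_key(ll, partition) > _config_key(
            best.loglik, best.partition
        ):
            best = HaplotypeConfiguration(partition, ll)
    assert best is not None
    haps = tuple(
        (clusters.clusters[i][0], 1 if unique else k)
        for i, k in enumerate(best.partition)
    )
    return HaplotypeCall(
        clusters.taxon, clusters.locus, "known_ploidy", haps, configuration=best
    )


def _config_key(ll: float, partition: Sequence[int]) -> tuple:
    # maximize loglik; tie -> fewer parts; tie -> larger k_1 (lex larger)
    return (ll, -len(partition), tuple(partition))


def scan_unknown_ploidy(
    clusters: ClusterSet,
    eps: float,
    cutoff: float = 0.10,
) -> tuple[UnknownPloidyScan, HaplotypeCall]:
    """Real-vs-error likelihood scan for unknown ploidy.

    Hypothesis h treats the h largest clusters as real — p_i = (1-eps)/h
    — and the rest as errors sharing p = eps/(m-h); h = 0 puts uniform
    mass 1/m everywhere (all clusters errors), and h = m renormalizes to
    1/m. Starting from h = 1, h+1 is accepted while the relative
    log-likelihood increase (LL(h+1) - LL(h)) / |LL(h)| reaches
    ``cutoff``; at least one haplotype is always returned.
    """
    eps = _clamp_eps(eps)
    m = clusters.m
    sizes = clusters.sizes
    logliks: list[float] = []
    for h in range(m + 1):
        ll = 0.0
        for i, n_i in enumerate(sizes):
            if h == 0:
                p = 1.0 / m
            elif h == m:
                p = 1.0 / h
            elif i < h:
                p = (1.0 - eps) / h
            else:
                p = eps / (m - h)
            ll += n_i * math.log(p)
        logliks.append(ll)

    h_star = 1
    while h_star < m:
        prev, nxt = logliks[h_star], logliks[h_star + 1]
        denom = abs(prev)
        gain = (nxt - prev) / denom if denom > 0 else math.inf
        if gain >= cutoff:
            h_star += 1
        else:
            break

    scan = UnknownPloidyScan(tuple(logliks), h_star, cutoff)
    haps = tuple((clusters.clusters[i][0], 1) for i in range(h_star))
    call = HaplotypeCall(
        clusters.taxon, clusters.locus, "unknown_ploidy", haps, scan=scan
    )
    return scan, call


def call_haploid(clusters: ClusterSet) -> HaplotypeCall:
    """Return only the cluster with the most reads (tie -> lexicographically
    smallest sequence)."""
    seq, _ = min(clusters.clusters, key=_cluster_sort_key)
    return HaplotypeCall(
        clusters.taxon, clusters.locus, "haploid", ((seq, 1),)
    )


# ---------------------------------------------------------------------------
# Driver: crunch a directory of cluster files
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrunchOptions:
    haploid: bool = False
    unique: bool = False
    cutoff: float = 0.10
    realign: bool = False
    clean: Optional[float] = None  # column occupancy threshold, e.g. 0.33
    merge_gaps: bool = True


def crunch(
    cluster_files: Iterable[Union[str, Path]],
    taxon_table_path: Union[str, Path],
    locus_err_path: Union[str, Path],
    out_dir: Union[str, Path],
    options: CrunchOptions = CrunchOptions(),
) -> dict[str, list[HaplotypeCall]]:
    """Infer haplotypes for every taxon x locus in the cluster files.

    Dispatch: integer ploidy -> known-ploidy ML; "None" -> unknown-ploidy
    scan; ``options.haploid`` overrides both. Writes one haplotype FASTA
    per locus (headers ``>taxon|locus|hapN_copyM``) plus ``crunch_report.tsv``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    taxon_table = read_taxon_table(taxon_table_path)
    locus_err = read_locus_error_table(locus_err_path)

    by_locus: dict[str, dict[str, list[ClusterRecord]]] = {}
    for path in cluster_files:
        for rec in parse_clusters_fasta(path):
            by_locus.setdefault(rec.locus, {}).setdefault(rec.taxon, []).append(rec)

    missing_taxa = sorted(
        {t for groups in by_locus.values() for t in groups} - set(taxon_table)
    )
    if missing_taxa:
        raise ValueError(
            "taxa missing from the taxon table: " + ", ".join(missing_taxa)
        )
    missing_loci = sorted(set(by_locus) - set(locus_err))
    if missing_loci:
        raise ValueError(
            "loci missing from the locus-error table: " + ", ".join(missing_loci)
        )

    calls_by_locus: dict[str, list[HaplotypeCall]] = {}
    report = [
        "taxon\tlocus\tmode\tm\tN\tepsilon\tresult\tlogliks\n"
    ]
    for locus in sorted(by_locus):
        eps = locus_err[locus]
        calls: list[HaplotypeCall] = []
        for taxon in sorted(by_locus[locus]):
            recs = by_locus[locus][taxon]
            cs = ClusterSet(
                taxon, locus, [(r.sequence, r.size) for r in recs]
            )
            cs = _prepare_clusters(cs, options)
            ploidy = taxon_table[taxon]
            if options.haploid:
                call = call_haploid(cs)
                detail, lls = "largest_cluster", ""
            elif ploidy is None:
                scan, call = scan_unknown_ploidy(cs, eps, options.cutoff)
                detail = f"h_star={scan.h_star}"
                lls = ";".join(f"{ll:.4f}" for ll in scan.logliks)
            else:
                call = infer_known_ploidy(cs, ploidy, eps, unique=options.unique)
                assert call.configuration is not None
                detail = "partition=" + ",".join(map(str, call.configuration.partition))
                lls = f"{call.configuration.loglik:.4f}"
            calls.append(call)
            report.append(
                f"{taxon}\t{locus}\t{call.mode}\t{cs.m}\t{cs.total_reads}"
                f"\t{eps:.7g}\t{detail}\t{lls}\n"
            )
        calls_by_locus[locus] = calls
        _write_haplotype_fasta(calls, out_dir / f"{locus}_haplotypes.fasta")
    _atomic_write(out_dir / "crunch_report.tsv", "".join(report))
    return calls_by_locus


def _prepare_clusters(cs: ClusterSet, options: CrunchOptions) -> ClusterSet:
    if options.realign and cs.m > 1:
        aln = center_star_align([seq for seq, _ in cs.clusters])
        if options.clean is not None:
            aln = clean_columns(aln, options.clean)
        cs = ClusterSet(
            cs.taxon,
            cs.locus,
            [
                (row, size)
                for (_, row), (_, size) in zip(aln.rows, cs.clusters)
            ],
        )
    elif options.clean is not None and cs.m > 1:
        lengths = {len(seq) for seq, _ in cs.clusters}
        if len(lengths) == 1:
            aln = clean_columns(
                Alignment(
                    [(str(i), seq) for i, (seq, _) in enumerate(cs.clusters)]
                ),
                options.clean,
            )
            cs = ClusterSet(
                cs.taxon,
                cs.locus,
                [
                    (row, size)
                    for (_, row), (_, size) in zip(aln.rows, cs.clusters)
                ],
            )
    if options.merge_gaps and cs.m > 1:
        lengths = {len(seq) for seq, _ in cs.clusters}
        if len(lengths) == 1:
            cs = merge_gap_identical(cs)
        elif options.realign:
            raise AssertionError("realigned clusters should share a length")
        else:
            raise ValueError(
                f"{cs.taxon}|{cs.locus}: clusters are unaligned "
                "(unequal lengths); use --realign to merge gap-identical clusters"
            )
    return cs


def _write_haplotype_fasta(calls: list[HaplotypeCall], path: Path) -> None:
    chunks = []
    for call in calls:
        for i, (seq, copies) in enumerate(call.haplotypes, start=1):
            chunks.append(
                f">{call.taxon}|{call.locus}|hap{i}_copy{copies}\n{seq}\n"
            )
    _atomic_write(path, "".join(chunks))
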