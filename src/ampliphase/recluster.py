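"""Iterative chimera filtering plus identity-based centroid clustering.

Stand-in for the clustering stage of the pipeline: abundance-sorted greedy
centroid clustering at a schedule of identity thresholds, interleaved with
a two-parent chimera filter. Simplified, documented equivalents of the
USEARCH/UCHIME operations — deliberately not byte-compatible with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from ._align import align_pair, identity_from_rows, pairwise_identity
from .io_formats import ClusterRecord, SequenceRecord, parse_purc_fasta, write_clusters_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "RoundConfig",
    "Centroid",
    "pairwise_identity",
    "greedy_cluster",
    "chimera_filter",
    "recluster_iterative",
    "recluster_locus_file",
]


@dataclass(frozen=True)
class RoundConfig:
    """Schedule and thresholds for the iterative clustering rounds."""

    identity_thresholds: tuple[float, ...] = (0.997, 0.995, 0.990, 0.997)
    abundance_skew: float = 2.0
    chimera_identity: float = 0.99

    def __post_init__(self) -> None:
        if not self.identity_thresholds:
            raise ValueError("identity_thresholds must be non-empty")
        for t in self.identity_thresholds:
            if not 0.5 < t <= 1.0:
                raise ValueError(f"identity threshold {t} outside (0.5, 1]")
        if self.abundance_skew <= 0:
            raise ValueError("abundance_skew must be positive")


@dataclass
class Centroid:
    sequence: str
    size: int
    members: list[int] = field(default_factory=list)


def _sort_key(c: Centroid) -> tuple[int, str]:
    return (-c.size, c.sequence)


def greedy_cluster(
    records: Sequence[Centroid], threshold: float
) -> list[Centroid]:
    """Abundance-sorted greedy clustering.

    Records are scanned largest first (ties broken lexicographically by
    sequence); each joins the best-identity existing centroid at or above
    ``threshold``, else founds a new one. Centroid sequences are their
    founders'; sizes are the sum of absorbed member sizes.
    """
    ordered = sorted(records, key=_sort_key)
    centroids: list[Centroid] = []
    for rec in ordered:
        best_i: Optional[int] = None
        best_id = -1.0
        for i, cen in enumerate(centroids):
            ident = pairwise_identity(rec.sequence, cen.sequence)
            if ident > best_id:
                best_id, best_i = ident, i
        if best_i is not None and best_id >= threshold:
            cen = centroids[best_i]
            cen.size += rec.size
            cen.members.extend(rec.members)
        else:
            centroids.append(
                Centroid(rec.sequence, rec.size, list(rec.members))
            )
    return sorted(centroids, key=_sort_key)


def _segment_match_profile(seq: str, parent: str) -> tuple[list[int], int]:
    """Cumulative match counts along ``seq`` against ``parent``.

    Aligns once; returns (prefix_matches, total) where prefix_matches[s]
    is the number of matched positions among seq[:s]. A position matches
    when its alignment column pairs it with an equal base (N wildcard).
    """
    row_s, row_p = align_pair(seq, parent)
    prefix = [0]
    total = 0
    for x, y in zip(row_s, row_p):
        if x == "-":
            continue  # insertion in parent; consumes no seq position
        matched = y != "-" and (x == y or x == "N" or y == "N")
        total += 1 if matched else 0
        prefix.append(total)
    return prefix, total


def chimera_filter(
    centroids: Sequence[Centroid], config: RoundConfig
) -> tuple[list[Centroid], list[Centroid]]:
    """Flag two-parent chimeras among abundance-sorted centroids.

    A candidate is flagged iff two parents exist, each at least
    ``abundance_skew`` times its size, such that some split point gives
    prefix identity >= ``chimera_identity`` to one parent and suffix
    identity >= ``chimera_identity`` to the other, while the candidate's
    full-length identity to each of those parents stays below
    ``chimera_identity``. Flagged sizes are NOT redistributed.
    """
    kept: list[Centroid] = []
    flagged: list[Centroid] = []
    ordered = sorted(centroids, key=_sort_key)
    for cand in ordered:
        parents = [
            p
            for p in ordered
            if p is not cand and p.size >= config.abundance_skew * cand.size
        ]
        if len(parents) < 2 or _is_chimera(cand, parents, config) is False:
            kept.append(cand)
        else:
            flagged.append(cand)
    return kept, flagged


def _is_chimera(
    cand: Centroid, parents: list[Centroid], config: RoundConfig
) -> bool:
    n = len(cand.sequence)
    if n < 2:
        return False
    profiles = []
    for p in parents:
        full_id = pairwise_identity(cand.sequence, p.sequence)
        if full_id >= config.chimera_identity:
            # candidate is simply a variant of this parent
            continue
        prefix, total = _segment_match_profile(cand.sequence, p.sequence)
        profiles.append((prefix, total))
    for i, (pre1, _) in enumerate(profiles):
        for j, (pre2, tot2) in enumerate(profiles):
            if i == j:
                continue
            for s in range(1, n):
                prefix_id = pre1[s] / s
                suffix_id = (tot2 - pre2[s]) / (n - s)
                if (
                    prefix_id >= config.chimera_identity
                    and suffix_id >= config.chimera_identity
                ):
                    return True
    return False


def recluster_iterative(
    records: Sequence[Centroid], config: RoundConfig = RoundConfig()
) -> tuple[list[Centroid], list[Centroid]]:
    """Run the full round schedule: filter chimeras, then cluster, feeding
    centroids forward. Returns (centroids, all_flagged_chimeras)."""
    current = list(records)
    all_flagged: list[Centroid] = []
    for round_no, threshold in enumerate(config.identity_thresholds):
        current, flagged = chimera_filter(current, config)
        all_flagged.extend(flagged)
        current = greedy_cluster(current, threshold)
        logger.debug(
            "round %d: threshold=%.4f -> %d centroids, %d chimeras flagged",
            round_no,
            threshold,
            len(current),
            len(flagged),
        )
    return current, all_flagged


def recluster_locus_file(
    locus_fasta: Union[str, Path],
    out_dir: Union[str, Path],
    config: RoundConfig = RoundConfig(),
) -> tuple[Path, Path]:
    """Cluster one per-locus FASTA, per taxon, and write the results.

    Sequences from different taxa never merge: haplotypes are called per
    individual downstream, and cross-taxon clustering would destroy the
    per-taxon sizes. Writes ``<locus>_clusters.fasta`` plus a chimera
    report TSV; returns both paths.
    """
    locus_fasta = Path(locus_fasta)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = parse_purc_fasta(locus_fasta)
    if not records:
        raise ValueError(f"{locus_fasta}: no records")
    locus = records[0].locus

    by_taxon: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        by_taxon.setdefault(rec.taxon, []).append(rec)

    clusters_out: list[ClusterRecord] = []
    chimera_lines = ["taxon\tlocus\tsize\tsequence\n"]
    for taxon in sorted(by_taxon):
        seeds = [
            Centroid(r.sequence, 1, [r.uid]) for r in by_taxon[taxon]
        ]
        centroids, flagged = recluster_iterative(seeds, config)
        for i, cen in enumerate(centroids):
            clusters_out.append(
                ClusterRecord(taxon, locus, i, cen.size, cen.sequence)
            )
        for chi in flagged:
            chimera_lines.append(f"{taxon}\t{locus}\t{chi.size}\t{chi.sequence}\n")

    clusters_path = out_dir / f"{locus}_clusters.fasta"
    report_path = out_dir / f"{locus}_chimeras.tsv"
    write_clusters_fasta(clusters_out, clusters_path)
    report_path.write_text("".join(chimera_lines))
    return clusters_path, report_path
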