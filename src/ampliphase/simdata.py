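"""Synthetic annotated paired-end amplicon reads with known ground truth.

Generates haplotypes with integer dosages per taxon x locus, paired-end
reads with PHRED-consistent substitution errors, a controllable fraction
of non-overlapping pairs (realized by fragment sizing), and two-parent
PCR chimeras at a stated rate. Fixed seed -> byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .io_formats import _atomic_write
from .preprocess import revcomp

__all__ = ["SimConfig", "SimTruth", "simulate_haplotypes", "simulate_reads", "simulate"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    taxa: dict[str, Optional[int]]  # taxon -> ploidy (None = unknown)
    loci: dict[str, int]  # locus -> amplicon length (bp)
    dosages: dict[tuple[str, str], tuple[int, ...]]  # (taxon, locus) -> dosage
    divergence: float = 0.02  # substitutions/site between haplotypes
    depth: int = 100  # read pairs per taxon x locus
    read_length: int = 150
    epsilon: float = 0.005  # per-base error probability
    chimera_rate: float = 0.0
    non_overlap_fraction: float = 0.0
    min_overlap: int = 10
    seed: int = 1

    def __post_init__(self) -> None:
        for frac in (self.divergence, self.chimera_rate, self.non_overlap_fraction):
            if not 0.0 <= frac < 1.0:
                raise ValueError(f"fraction {frac} outside [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        for (taxon, locus), dosage in self.dosages.items():
            if taxon not in self.taxa or locus not in self.loci:
                raise ValueError(f"dosage references unknown {taxon}/{locus}")
            if any(d < 1 for d in dosage):
                raise ValueError("dosages must be positive")
            ploidy = self.taxa[taxon]
            if ploidy is not None and sum(dosage) != ploidy:
                raise ValueError(
                    f"{taxon}/{locus}: dosage {dosage} does not sum to ploidy {ploidy}"
                )
        if self.non_overlap_fraction > 0:
            for locus, length in self.loci.items():
                if length <= 2 * self.read_length - self.min_overlap:
                    raise ValueError(
                        f"locus {locus} (length {length}) is too short to "
                        "generate non-overlapping pairs"
                    )


@dataclass
class SimTruth:
    """Ground truth: haplotypes and per-read provenance."""

    haplotypes: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    dosages: dict[tuple[str, str], tuple[int, ...]] = field(default_factory=dict)
    # per read: (read_id, taxon, locus, origin, overlapping)
    reads: list[tuple[str, str, str, str, bool]] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(
    rng: np.random.Generator, seq: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each site with probability ``rate`` (never to itself)."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_haplotypes(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> SimTruth:
    """Draw an ancestral sequence per locus and mutate one haplotype per
    dosage entry at the divergence rate. Colliding haplotypes trigger a
    bounded regeneration."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = SimTruth()
    ancestral = {
        locus: _random_seq(rng, length)
        for locus, length in sorted(config.loci.items())
    }
    for (taxon, locus) in sorted(config.dosages):
        dosage = config.dosages[(taxon, locus)]
        n_hap = len(dosage)
        for attempt in range(20):
            haps = [
                _to_str(_mutate(rng, ancestral[locus], config.divergence))
                for _ in range(n_hap)
            ]
            if len(set(haps)) == n_hap or n_hap == 1:
                break
        else:
            raise RuntimeError(
                f"{taxon}/{locus}: could not generate {n_hap} distinct "
                f"haplotypes at divergence {config.divergence}"
            )
        if n_hap == 1:
            haps = [_to_str(ancestral[locus])]
        truth.haplotypes[(taxon, locus)] = haps
        truth.dosages[(taxon, locus)] = tuple(dosage)
    return truth


def _quality_string(
    rng: np.random.Generator, length: int, epsilon: float
) -> tuple[str, np.ndarray]:
    """PHRED string whose per-read mean equals -10*log10(epsilon) in
    expectation (symmetric integer jitter of +-3 around the rounded Q)."""
    q0 = int(round(-10.0 * math.log10(epsilon)))
    quals = q0 + rng.integers(-3, 4, size=length)
    quals = np.clip(quals, 2, 41)
    return "".join(chr(33 + q) for q in quals), quals


def _apply_errors(
    rng: np.random.Generator, seq: str, epsilon: float
) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    return _to_str(_mutate(rng, arr, epsilon))


def simulate_reads(
    truth: SimTruth,
    config: SimConfig,
    out_dir: Union[str, Path],
    rng: Optional[np.random.Generator] = None,
) -> tuple[Path, Path]:
    """Write R1/R2 FASTQ plus truth tables; returns the FASTQ paths.

    Reads are drawn from haplotypes proportional to dosage;
    ``chimera_rate`` of fragments are single-breakpoint two-parent
    recombinants; ``non_overlap_fraction`` of pairs come from full-length
    fragments that cannot overlap, the rest from fragments short enough
    to guarantee an overlap.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    r = config.read_length
    overlap_frag = 2 * r - max(config.min_overlap, 50)

    r1_chunks: list[str] = []
    r2_chunks: list[str] = []
    serial = 0
    for (taxon, locus) in sorted(truth.haplotypes):
        haps = truth.haplotypes[(taxon, locus)]
        dosage = np.asarray(truth.dosages[(taxon, locus)], dtype=float)
        probs = dosage / dosage.sum()
        for _ in range(config.depth):
            serial += 1
            read_id = f"sim{serial:07d}"
            if len(haps) > 1 and rng.random() < config.chimera_rate:
                i, j = rng.choice(len(haps), size=2, replace=False, p=probs)
                bp = int(rng.integers(1, len(haps[i])))
                template = haps[i][:bp] + haps[j][bp:]
                origin = f"chimera:{i}+{j}@{bp}"
            else:
                i = int(rng.choice(len(haps), p=probs))
                template = haps[i]
                origin = f"hap{i}"

            non_overlap = (
                config.non_overlap_fraction > 0
                and rng.random() < config.non_overlap_fraction
            )
            frag = template if non_overlap else template[: min(len(template), overlap_frag)]
            fwd = frag[:r]
            rev = revcomp(frag[-r:] if len(frag) >= r else frag)
            fwd = _apply_errors(rng, fwd, config.epsilon)
            rev = _apply_errors(rng, rev, config.epsilon)
            q1, _ = _quality_string(rng, len(fwd), config.epsilon)
            q2, _ = _quality_string(rng, len(rev), config.epsilon)
            header = f"{read_id} {taxon}:{locus}"
            r1_chunks.append(f"@{header}\n{fwd}\n+\n{q1}\n")
            r2_chunks.append(f"@{header}\n{rev}\n+\n{q2}\n")
            overlapping = len(frag) <= 2 * r - config.min_overlap
            truth.reads.append((read_id, taxon, locus, origin, overlapping))

    r1_path = out_dir / "R1.fastq"
    r2_path = out_dir / "R2.fastq"
    _atomic_write(r1_path, "".join(r1_chunks))
    _atomic_write(r2_path, "".join(r2_chunks))
    _write_truth(truth, config, out_dir)
    return r1_path, r2_path


def _write_truth(truth: SimTruth, config: SimConfig, out_dir: Path) -> None:
    hap_lines = ["taxon\tlocus\thap\tdosage\tsequence\n"]
    for (taxon, locus) in sorted(truth.haplotypes):
        for i, hap in enumerate(truth.haplotypes[(taxon, locus)]):
            hap_lines.append(
                f"{taxon}\t{locus}\t{i}\t{truth.dosages[(taxon, locus)][i]}\t{hap}\n"
            )
    _atomic_write(out_dir / "truth_haplotypes.tsv", "".join(hap_lines))
    read_lines = ["read_id\ttaxon\tlocus\torigin\toverlapping\n"]
    for rid, taxon, locus, origin, overlapping in truth.reads:
        read_lines.append(f"{rid}\t{taxon}\t{locus}\t{origin}\t{overlapping}\n")
    _atomic_write(out_dir / "truth_reads.tsv", "".join(read_lines))
    echo = asdict(config)
    echo["dosages"] = {f"{t}|{l}": list(d) for (t, l), d in config.dosages.items()}
    _atomic_write(out_dir / "sim_config.json", json.dumps(echo, indent=2) + "\n")


def simulate(config: SimConfig, out_dir: Union[str, Path]) -> SimTruth:
    """Convenience wrapper: haplotypes + reads + truth tables in one call."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_haplotypes(config, rng)
    simulate_reads(truth, config, out_dir, rng)
    return truth
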