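import itertools
import math
import random

import pytest

from ampliphase.haplotypes import (
    ClusterSet,
    CrunchOptions,
    call_haploid,
    config_loglik,
    crunch,
    infer_known_ploidy,
    integer_partitions,
    merge_gap_identical,
    scan_unknown_ploidy,
)
from ampliphase.io_formats import (
    ClusterRecord,
    write_clusters_fasta,
    write_locus_error_table,
    write_taxon_table,
)
from conftest import mutate, random_dna


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_partitions(k: int) -> set[tuple[int, ...]]:
    """Brute force: enumerate all compositions of k, deduplicate by
    sorting each one descending."""
    out = set()

    def compositions(remaining, prefix):
        if remaining == 0:
            out.add(tuple(sorted(prefix, reverse=True)))
            return
        for first in range(1, remaining + 1):
            compositions(remaining - first, prefix + [first])

    compositions(k, [])
    return out


def oracle_loglik(sizes, partition, eps):
    """Direct kernel evaluation, written independently of the package."""
    m, j, K = len(sizes), len(partition), sum(partition)
    ll = 0.0
    for i, n in enumerate(sizes):
        if i < j:
            p = partition[i] / K if j == m else (1 - eps) * partition[i] / K
        else:
            p = eps / (m - j)
        if p == 0:
            return -math.inf
        ll += n * math.log(p)
    return ll


def oracle_best_partition(sizes, K, eps):
    """Exhaustive maximization over ALL configurations with the documented
    tie rules (more likely; then fewer parts; then larger leading dosage)."""
    best = None
    for part in sorted(oracle_partitions(K)):
        if len(part) > min(K, len(sizes)):
            continue
        key = (oracle_loglik(sizes, part, eps), -len(part), part)
        if best is None or key > best:
            best = key
    return best[2]


# ---------------------------------------------------------------------------
# ClusterSet
# ---------------------------------------------------------------------------

class TestClusterSet:
    def test_sorted_and_totals(self):
        cs = ClusterSet("T", "L", [("AA", 3), ("CC", 10), ("GG", 5)])
        assert cs.sizes == (10, 5, 3)
        assert cs.m == 3 and cs.total_reads == 18

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ClusterSet("T", "L", [])

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            ClusterSet("T", "L", [("AA", 0)])


# ---------------------------------------------------------------------------
# merge_gap_identical
# ---------------------------------------------------------------------------

class TestMergeGapIdentical:
    def test_gapped_variant_absorbed(self):
        cs = ClusterSet("T", "L", [("ACGTAATTGA", 7), ("ACGT----GA", 5)])
        merged = merge_gap_identical(cs)
        assert merged.clusters == [("ACGTAATTGA", 12)]

    def test_conflicting_column_blocks_merge(self):
        cs = ClusterSet("T", "L", [("ACGTAATTGA", 7), ("ACGTCC--GA", 5)])
        merged = merge_gap_identical(cs)
        assert merged.m == 2

    def test_n_counts_as_missing(self):
        cs = ClusterSet("T", "L", [("ACGTAATTGA", 7), ("ACGTNN--GA", 5)])
        merged = merge_gap_identical(cs)
        assert merged.clusters == [("ACGTAATTGA", 12)]

    def test_three_way_chain_follows_size_order(self):
        # A~B, B~C compatible, but A conflicts with C: size order decides.
        a = ("ACGTAATTGA", 10)  # full
        b = ("ACGT----GA", 6)  # compatible with both
        c = ("ACGTCC--GA", 5)  # conflicts with A at columns 4-5
        merged = merge_gap_identical(ClusterSet("T", "L", [a, b, c]))
        # first compatible pair in size order is (A, B) -> A absorbs B;
        # C conflicts with the survivor, so two clusters remain
        assert merged.clusters == [("ACGTAATTGA", 16), ("ACGTCC--GA", 5)]

    def test_survivor_has_fewer_gaps_regardless_of_size(self):
        cs = ClusterSet("T", "L", [("ACGT----GA", 50), ("ACGTAATTGA", 2)])
        merged = merge_gap_identical(cs)
        assert merged.clusters == [("ACGTAATTGA", 52)]

    def test_exhaustive_small_instances(self):
        # every <=4-cluster instance over a tiny motif family: merging
        # always conserves total size and never merges conflicting pairs
        motifs = ["AATT", "AA--", "--TT", "CCTT", "NNTT"]
        for seqs in itertools.combinations(motifs, 3):
            clusters = [(s, 4 - i) for i, s in enumerate(seqs)]
            merged = merge_gap_identical(ClusterSet("T", "L", list(clusters)))
            assert merged.total_reads == sum(n for _, n in clusters)
            for (s1, _), (s2, _) in itertools.combinations(merged.clusters, 2):
                conflict = any(
                    x != y
                    for x, y in zip(s1, s2)
                    if x not in "-N" and y not in "-N"
                )
                assert conflict, f"{s1} and {s2} should have merged"

    def test_unaligned_input_is_hard_error(self):
        cs = ClusterSet("T", "L", [("ACGTAATTGA", 7), ("ACGTGA", 5)])
        with pytest.raises(ValueError, match="realign"):
            merge_gap_identical(cs)


# ---------------------------------------------------------------------------
# integer partitions
# ---------------------------------------------------------------------------

class TestIntegerPartitions:
    def test_tetraploid_matches_published_configurations(self):
        assert integer_partitions(4) == [
            (4,),
            (3, 1),
            (2, 2),
            (2, 1, 1),
            (1, 1, 1, 1),
        ]

    def test_k1(self):
        assert integer_partitions(1) == [(1,)]

    def test_counts_against_composition_oracle(self):
        expected = [1, 2, 3, 5, 7, 11, 15, 22, 30, 42]
        for k, count in zip(range(1, 11), expected):
            parts = integer_partitions(k)
            assert len(parts) == count
            assert set(parts) == oracle_partitions(k)
            # non-increasing parts, decreasing lexicographic order
            assert all(tuple(sorted(p, reverse=True)) == p for p in parts)
            assert parts == sorted(parts, reverse=True)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            integer_partitions(0)


# ---------------------------------------------------------------------------
# config_loglik
# ---------------------------------------------------------------------------

class TestConfigLoglik:
    def test_single_cluster_full_partition_is_zero(self):
        cs = ClusterSet("T", "L", [("AAAA", 37)])
        assert config_loglik(cs, (2,), 0.01) == 0.0

    def test_even_split_diploid(self):
        cs = ClusterSet("T", "L", [("AAAA", 50), ("CCCC", 50)])
        assert config_loglik(cs, (1, 1), 0.01) == pytest.approx(
            100 * math.log(0.5)
        )

    def test_homozygote_with_error_cluster(self):
        cs = ClusterSet("T", "L", [("AAAA", 50), ("CCCC", 50)])
        expected = 50 * math.log(0.99) + 50 * math.log(0.01)
        assert config_loglik(cs, (2,), 0.01) == pytest.approx(expected)
        assert config_loglik(cs, (2,), 0.01) == pytest.approx(-230.76, abs=0.01)

    def test_matches_oracle_on_random_instances(self, rng):
        for _ in range(200):
            m = rng.randrange(1, 7)
            sizes = sorted(rng.choices(range(1, 200), k=m), reverse=True)
            K = rng.randrange(1, 9)
            parts = [p for p in integer_partitions(K) if len(p) <= m]
            part = rng.choice(parts)
            eps = rng.choice([0.001, 0.01, 0.1])
            cs = ClusterSet(
                "T", "L", [(f"{'ACGT'[i % 4]* 4}{i}", n) for i, n in enumerate(sizes)]
            )
            assert config_loglik(cs, part, eps) == pytest.approx(
                oracle_loglik(sizes, part, eps)
            )

    def test_oversized_partition_rejected(self):
        cs = ClusterSet("T", "L", [("AAAA", 10)])
        with pytest.raises(ValueError):
            config_loglik(cs, (1, 1), 0.01)


# ---------------------------------------------------------------------------
# infer_known_ploidy
# ---------------------------------------------------------------------------

def _cs(sizes):
    return ClusterSet(
        "T", "L", [(mutable_seq(i), n) for i, n in enumerate(sizes)]
    )


def mutable_seq(i):
    # distinct deterministic sequence per index (base-4 encoding in ACGT)
    digits = []
    n = i
    for _ in range(4):
        digits.append("ACGT"[n % 4])
        n //= 4
    return "".join(digits) * 3


class TestInferKnownPloidy:
    def test_balanced_heterozygote(self):
        call = infer_known_ploidy(_cs([50, 50]), 2, 0.01)
        assert call.configuration.partition == (1, 1)
        assert [c for _, c in call.haplotypes] == [1, 1]

    def test_skewed_homozygote(self):
        call = infer_known_ploidy(_cs([97, 3]), 2, 0.01)
        assert call.configuration.partition == (2,)
        assert call.haplotypes[0][1] == 2

    def test_copies_sum_to_ploidy(self, rng):
        for _ in range(30):
            m = rng.randrange(1, 8)
            K = rng.randrange(1, 8)
            sizes = rng.choices(range(1, 100), k=m)
            call = infer_known_ploidy(_cs(sizes), K, 0.01)
            assert sum(c for _, c in call.haplotypes) == K
            assert len(call.haplotypes) <= min(K, m)

    def test_tetraploid_never_more_than_four(self, rng):
        sizes = [40, 30, 20, 10, 5, 4, 3]
        call = infer_known_ploidy(_cs(sizes), 4, 0.01)
        assert len(call.haplotypes) <= 4

    def test_unique_collapses_copies(self):
        call = infer_known_ploidy(_cs([97, 3]), 2, 0.01, unique=True)
        assert [c for _, c in call.haplotypes] == [1]

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(300):
            m = rng.randrange(1, 9)
            K = rng.randrange(1, 9)
            sizes = sorted(rng.choices(range(1, 500), k=m), reverse=True)
            eps = rng.choice([1e-4, 1e-3, 1e-2, 0.1])
            call = infer_known_ploidy(_cs(sizes), K, eps)
            assert call.configuration.partition == oracle_best_partition(
                sizes, K, eps
            ), (sizes, K, eps)

    def test_eps_clamped(self):
        call = infer_known_ploidy(_cs([50, 50]), 2, 0.0)
        assert call.configuration.partition == (1, 1)


# ---------------------------------------------------------------------------
# scan_unknown_ploidy
# ---------------------------------------------------------------------------

class TestScanUnknownPloidy:
    def test_single_cluster_floor(self):
        scan, call = scan_unknown_ploidy(_cs([42]), 0.01)
        assert scan.h_star == 1
        assert len(scan.logliks) == 2
        assert len(call.haplotypes) == 1

    def test_two_real_one_error(self):
        scan, call = scan_unknown_ploidy(_cs([100, 100, 1]), 0.01, 0.10)
        assert scan.h_star == 2
        assert scan.logliks[1] == pytest.approx(-536.14, abs=0.01)
        assert scan.logliks[2] == pytest.approx(-145.24, abs=0.01)
        assert scan.logliks[3] == pytest.approx(-220.82, abs=0.01)
        assert [c for _, c in call.haplotypes] == [1, 1]

    def test_three_real_one_error(self):
        scan, _ = scan_unknown_ploidy(_cs([10, 9, 8, 1]), 0.01, 0.10)
        assert scan.h_star == 3

    def test_h_star_bounded_by_m(self, rng):
        for _ in range(40):
            m = rng.randrange(1, 9)
            sizes = rng.choices(range(1, 300), k=m)
            scan, _ = scan_unknown_ploidy(_cs(sizes), 0.01)
            assert 1 <= scan.h_star <= m
            assert len(scan.logliks) == m + 1

    def test_monotone_in_cutoff(self, rng):
        for _ in range(20):
            m = rng.randrange(2, 8)
            sizes = rng.choices(range(1, 300), k=m)
            cs = _cs(sizes)
            h_stars = [
                scan_unknown_ploidy(cs, 0.01, cutoff)[0].h_star
                for cutoff in (0.001, 0.01, 0.1, 0.5, 2.0)
            ]
            assert h_stars == sorted(h_stars, reverse=True)

    def test_degenerate_single_cluster_low_eps(self):
        scan, call = scan_unknown_ploidy(_cs([100]), 1e-9)
        assert scan.h_star == 1 and len(call.haplotypes) == 1


class TestCallHaploid:
    def test_largest_cluster_wins(self):
        cs = ClusterSet("T", "L", [("AAAA", 30), ("CCCC", 2), ("GGGG", 1)])
        call = call_haploid(cs)
        assert call.haplotypes == (("AAAA", 1),)

    def test_single_cluster(self):
        cs = ClusterSet("T", "L", [("TTTT", 5)])
        assert call_haploid(cs).haplotypes == (("TTTT", 1),)

    def test_tie_breaks_lexicographically(self):
        cs = ClusterSet("T", "L", [("GGGG", 10), ("CCCC", 10)])
        assert call_haploid(cs).haplotypes == (("CCCC", 1),)


# ---------------------------------------------------------------------------
# crunch driver
# ---------------------------------------------------------------------------

def _write_inputs(tmp_path, rng, taxa):
    base = random_dna(rng, 120)
    alt = mutate(rng, base, 10)
    clusters = []
    for taxon in taxa:
        clusters.extend(
            [
                ClusterRecord(taxon, "LocX", 0, 60, base),
                ClusterRecord(taxon, "LocX", 1, 40, alt),
                ClusterRecord(taxon, "LocX", 2, 1, mutate(rng, base, 1)),
            ]
        )
    path = tmp_path / "LocX_clusters.fasta"
    write_clusters_fasta(clusters, path)
    write_taxon_table(taxa, tmp_path / "taxon_table.txt")
    write_locus_error_table({"LocX": 0.005}, tmp_path / "locus_err.txt")
    return path


class TestCrunch:
    def test_mixed_modes_in_one_run(self, tmp_path, rng):
        path = _write_inputs(tmp_path, rng, {"Dip": 2, "Unk": None})
        calls = crunch(
            [path],
            tmp_path / "taxon_table.txt",
            tmp_path / "locus_err.txt",
            tmp_path / "out",
        )
        by_taxon = {c.taxon: c for c in calls["LocX"]}
        assert by_taxon["Dip"].mode == "known_ploidy"
        assert by_taxon["Unk"].mode == "unknown_ploidy"
        assert sum(c for _, c in by_taxon["Dip"].haplotypes) == 2
        report = (tmp_path / "out/crunch_report.tsv").read_text()
        assert "Dip\tLocX\tknown_ploidy" in report

    def test_diploid_single_dominant_cluster(self, tmp_path, rng):
        base = random_dna(rng, 120)
        clusters = [
            ClusterRecord("Dip", "LocX", 0, 99, base),
            ClusterRecord("Dip", "LocX", 1, 1, mutate(rng, base, 2)),
        ]
        path = tmp_path / "LocX_clusters.fasta"
        write_clusters_fasta(clusters, path)
        write_taxon_table({"Dip": 2}, tmp_path / "tt.txt")
        write_locus_error_table({"LocX": 0.005}, tmp_path / "le.txt")
        calls = crunch(
            [path], tmp_path / "tt.txt", tmp_path / "le.txt", tmp_path / "out"
        )
        (call,) = calls["LocX"]
        assert len(call.haplotypes) == 1
        assert call.haplotypes[0][1] == 2

    def test_haploid_overrides_everything(self, tmp_path, rng):
        path = _write_inputs(tmp_path, rng, {"Dip": 2, "Unk": None})
        calls = crunch(
            [path],
            tmp_path / "taxon_table.txt",
            tmp_path / "locus_err.txt",
            tmp_path / "out",
            CrunchOptions(haploid=True),
        )
        assert all(
            c.mode == "haploid" and len(c.haplotypes) == 1 for c in calls["LocX"]
        )

    def test_missing_taxon_is_hard_error(self, tmp_path, rng):
        path = _write_inputs(tmp_path, rng, {"Dip": 2})
        write_taxon_table({"Other": 2}, tmp_path / "tt2.txt")
        with pytest.raises(ValueError, match="Dip"):
            crunch(
                [path], tmp_path / "tt2.txt", tmp_path / "locus_err.txt",
                tmp_path / "out",
            )

    def test_missing_locus_is_hard_error(self, tmp_path, rng):
        path = _write_inputs(tmp_path, rng, {"Dip": 2})
        write_locus_error_table({"OtherLocus": 0.01}, tmp_path / "le2.txt")
        with pytest.raises(ValueError, match="LocX"):
            crunch(
                [path], tmp_path / "taxon_table.txt", tmp_path / "le2.txt",
                tmp_path / "out",
            )

    def test_output_header_grammar(self, tmp_path, rng):
        path = _write_inputs(tmp_path, rng, {"Dip": 2})
        crunch(
            [path], tmp_path / "taxon_table.txt", tmp_path / "locus_err.txt",
            tmp_path / "out",
        )
        text = (tmp_path / "out/LocX_haplotypes.fasta").read_text()
        assert ">Dip|LocX|hap1_copy1" in text

    def test_realign_merges_njoined_variant(self, tmp_path, rng):
        # a full-length cluster and its N-joined twin (middle replaced by
        # N's) merge after realignment, keeping the fuller sequence
        full = random_dna(rng, 200)
        joined = full[:80] + "N" * 10 + full[130:]
        clusters = [
            ClusterRecord("Dip", "LocX", 0, 60, full),
            ClusterRecord("Dip", "LocX", 1, 40, joined),
        ]
        path = tmp_path / "LocX_clusters.fasta"
        write_clusters_fasta(clusters, path)
        write_taxon_table({"Dip": 2}, tmp_path / "tt.txt")
        write_locus_error_table({"LocX": 0.005}, tmp_path / "le.txt")
        calls = crunch(
            [path], tmp_path / "tt.txt", tmp_path / "le.txt", tmp_path / "out",
            CrunchOptions(realign=True),
        )
        (call,) = calls["LocX"]
        assert len(call.haplotypes) == 1
        assert call.haplotypes[0][0].replace("-", "") == full
        assert call.haplotypes[0][1] == 2

    def test_unaligned_without_realign_is_hard_error(self, tmp_path, rng):
        clusters = [
            ClusterRecord("Dip", "LocX", 0, 60, random_dna(rng, 100)),
            ClusterRecord("Dip", "LocX", 1, 40, random_dna(rng, 90)),
        ]
        path = tmp_path / "LocX_clusters.fasta"
        write_clusters_fasta(clusters, path)
        write_taxon_table({"Dip": 2}, tmp_path / "tt.txt")
        write_locus_error_table({"LocX": 0.005}, tmp_path / "le.txt")
        with pytest.raises(ValueError, match="realign"):
            crunch(
                [path], tmp_path / "tt.txt", tmp_path / "le.txt",
                tmp_path / "out",
            )


# ---------------------------------------------------------------------------
# stochastic parameter recovery
# ---------------------------------------------------------------------------

class TestParameterRecovery:
    def test_tetraploid_2_2_recovered(self):
        # 200 reads from a (2,2) tetraploid at eps=0.005: error reads form
        # singleton clusters, real reads split evenly
        recovered = 0
        n_rep = 200
        for seed in range(n_rep):
            local = random.Random(seed)
            h1 = random_dna(local, 300)
            h2 = mutate(local, h1, 6)  # 2% divergence
            counts = {h1: 0, h2: 0}
            errors = []
            for _ in range(200):
                if local.random() < 0.005:
                    errors.append(mutate(local, local.choice([h1, h2]), 3))
                else:
                    hap = h1 if local.random() < 0.5 else h2
                    counts[hap] += 1
            clusters = [(h, n) for h, n in counts.items() if n > 0]
            clusters += [(e, 1) for e in errors]
            call = infer_known_ploidy(
                ClusterSet("T", "L", clusters), 4, 0.005
            )
            if call.configuration.partition == (2, 2):
                recovered += 1
        assert recovered >= 0.95 * n_rep

    def test_diploid_single_haplotype_recovered(self):
        recovered = 0
        n_rep = 200
        for seed in range(n_rep):
            local = random.Random(10_000 + seed)
            h1 = random_dna(local, 300)
            n_err = sum(1 for _ in range(200) if local.random() < 0.005)
            clusters = [(h1, 200 - n_err)]
            clusters += [(mutate(local, h1, 2), 1) for _ in range(n_err)]
            call = infer_known_ploidy(ClusterSet("T", "L", clusters), 2, 0.005)
            if len(call.haplotypes) == 1:
                recovered += 1
        assert recovered >= 0.95 * n_rep
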