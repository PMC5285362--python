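"""Mismatch-bounded host matching against a brute-force Hamming oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from exomir.errors import ConfigurationError, ValidationError
from exomir.host_filter import (
    build_index,
    filter_host,
    host_layer_attribution,
    matches_host,
    scan_occurrences,
)
from exomir.read_prep import ReadSet
from exomir.reference_io import SequenceRecord, revcomp


def brute_force_matches(read: str, refs, mm: int) -> bool:
    """Independent oracle: per-window Hamming with N-never-matches, both strands."""
    for q in (read, revcomp(read)):
        for ref in refs:
            s = ref.sequence
            for i in range(len(s) - len(q) + 1):
                d = 0
                for a, b in zip(q, s[i : i + len(q)]):
                    if a != b or a == "N":
                        d += 1
                        if d > mm:
                            break
                else:
                    return True
    return False


def _random_ref(rng, n, ref_id="ref"):
    return SequenceRecord(ref_id, "".join(rng.choice(list("ACGT"), size=n)))


class TestBuildIndex:
    def test_posting_count_single_reference(self):
        idx = build_index([SequenceRecord("r", "ACGTACGTACGTACGT")], k=8)
        assert sum(len(v) for v in idx.seed_table.values()) == 16 - 8 + 1

    def test_empty_reference_list(self):
        with pytest.raises(ValidationError):
            build_index([])

    def test_k_too_large_for_read_length(self):
        with pytest.raises(ConfigurationError):
            build_index([SequenceRecord("r", "A" * 100)], k=10, max_mismatch=1, min_read_len=18)

    def test_seed_lookup_equals_naive_scan(self):
        rng = np.random.default_rng(0)
        ref = _random_ref(rng, 10_000)
        idx = build_index([ref], k=9)
        for _ in range(50):
            start = int(rng.integers(0, 10_000 - 9))
            kmer = ref.sequence[start : start + 9]
            naive = [
                i
                for i in range(len(ref.sequence) - 8)
                if ref.sequence[i : i + 9] == kmer
            ]
            assert sorted(off for _, off in idx.seed_table[kmer]) == naive


@pytest.fixture(scope="module")
def ref_and_index():
    rng = np.random.default_rng(7)
    ref = _random_ref(rng, 2000)
    return ref, build_index([ref], k=9, max_mismatch=1)


class TestMatchesHost:

    def test_exact_substring_matches(self, ref_and_index):
        ref, idx = ref_and_index
        assert matches_host(ref.sequence[100:121], idx)

    def test_reverse_complement_matches(self, ref_and_index):
        ref, idx = ref_and_index
        assert matches_host(revcomp(ref.sequence[500:521]), idx)

    def test_read_shorter_than_seed_rejected(self, ref_and_index):
        _, idx = ref_and_index
        with pytest.raises(ValueError):
            matches_host("ACGT", idx)

    def test_n_never_matches(self):
        ref = SequenceRecord("r", "ACGTACGTACGTACGTACGTACGT")
        idx = build_index([ref], k=8, max_mismatch=0, min_read_len=8)
        read = ref.sequence[:20]
        assert matches_host(read, idx, max_mismatch=0)
        assert not matches_host(read[:-1] + "N", idx, max_mismatch=0)
        # N in the read counts as the single allowed mismatch at bound 1
        assert matches_host(read[:-1] + "N", idx, max_mismatch=1)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), mm=st.integers(0, 2))
    def test_oracle_equivalence_random_reads(self, seed, mm):
        rng = np.random.default_rng(seed)
        ref = _random_ref(rng, 1500)
        idx = build_index([ref], k=9, max_mismatch=1, min_read_len=18)
        # half planted-with-mutations, half random
        L = int(rng.integers(18, 25))
        if rng.integers(2):
            start = int(rng.integers(0, 1500 - L))
            read = list(ref.sequence[start : start + L])
            for pos in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                read[pos] = "ACGT"[int(rng.integers(4))]
            read = "".join(read)
            if rng.integers(2):
                read = revcomp(read)
        else:
            read = "".join(rng.choice(list("ACGT"), size=L))
        assert matches_host(read, idx, max_mismatch=mm) == brute_force_matches(
            read, [ref], mm
        )

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(3)
        ref = _random_ref(rng, 1200)
        idx = build_index([ref], k=9, max_mismatch=1, min_read_len=18)
        reads = []
        for _ in range(80):
            L = int(rng.integers(18, 25))
            start = int(rng.integers(0, 1200 - L))
            read = list(ref.sequence[start : start + L])
            for pos in rng.choice(L, size=int(rng.integers(0, 4)), replace=False):
                read[pos] = "ACGT"[int(rng.integers(4))]
            reads.append("".join(read))
        sets = {
            mm: {r for r in reads if matches_host(r, idx, max_mismatch=mm)}
            for mm in (0, 1, 2)
        }
        assert sets[0] <= sets[1] <= sets[2]


class TestScanOccurrences:
    def test_planted_with_two_substitutions(self):
        rng = np.random.default_rng(11)
        ref_seq = "".join(rng.choice(list("ACGT"), size=3000))
        mature = "".join(rng.choice(list("ACGT"), size=21))
        variant = list(mature)
        variant[3] = {"A": "C", "C": "A", "G": "T", "T": "G"}[variant[3]]
        variant[15] = {"A": "G", "C": "T", "G": "A", "T": "C"}[variant[15]]
        planted = ref_seq[:400] + "".join(variant) + ref_seq[400:]
        ref = SequenceRecord("g", planted)
        hits2 = [h for h in scan_occurrences(mature, [ref], 2) if h.mismatches == 2]
        assert any(h.offset == 400 for h in hits2)
        assert all(
            h.offset != 400 or h.mismatches == 2 for h in scan_occurrences(mature, [ref], 2)
        )
        assert not [h for h in scan_occurrences(mature, [ref], 1) if h.offset == 400]

    def test_superset_as_bound_relaxes(self):
        rng = np.random.default_rng(13)
        ref = _random_ref(rng, 5000)
        mature = ref.sequence[1000:1021]
        prev: set = set()
        for mm in (0, 1, 2, 3):
            hits = {(h.ref_id, h.offset, h.strand) for h in scan_occurrences(mature, [ref], mm)}
            assert prev <= hits
            prev = hits

    def test_reverse_strand_reported(self):
        planted = "TGACAGAAGAGAGTGAGCAC"
        ref = SequenceRecord("g", "TTTTTTTTTT" + planted + "AAAAAAAAAA")
        hits = scan_occurrences(revcomp(planted), [ref], 0)
        assert [(h.offset, h.strand, h.mismatches) for h in hits] == [(10, "-", 0)]


class TestFilterHost:
    def test_all_host_reads_removed(self, study):
        world, _, _ = study
        idx = build_index(world.references, layers=world.layers)
        genome = world.references[0].sequence
        rng = np.random.default_rng(2)
        entries = {}
        for _ in range(60):
            L = int(rng.integers(18, 25))
            start = int(rng.integers(0, len(genome) - L))
            entries[genome[start : start + L]] = 1
        host, residual = filter_host(ReadSet("d", 60, entries), idx)
        assert residual.entries == {}
        assert host.n_unique == len(entries)

    def test_exogenous_matures_survive(self, study):
        world, _, _ = study
        idx = build_index(world.references, layers=world.layers)
        host_code = world.config.host_species_code
        planted = {p.mirna_id for p in world.config.planted_similar}
        exo = {
            r.sequence: 2
            for r in world.mature_records
            if not r.id.startswith(host_code) and r.id not in planted
        }
        host, residual = filter_host(ReadSet("d", 2 * len(exo), exo), idx)
        assert host.entries == {}
        assert residual.entries == exo

    def test_partition_conserves_counts(self, study):
        world, reads_by, _ = study
        idx = build_index(world.references, layers=world.layers)
        for meta in world.metadata[:2]:
            entries = {}
            for r in reads_by[meta.dataset_id]:
                entries[r] = entries.get(r, 0) + 1
            rs = ReadSet(meta.dataset_id, len(reads_by[meta.dataset_id]), entries)
            host, residual = filter_host(rs, idx)
            assert host.total_reads == residual.total_reads == rs.total_reads
            assert set(host.entries) | set(residual.entries) == set(rs.entries)
            assert not set(host.entries) & set(residual.entries)
            merged = {**host.entries, **residual.entries}
            assert merged == rs.entries


def test_layer_attribution_reports_each_layer(study):
    world, _, _ = study
    idx = build_index(world.references, layers=world.layers)
    genome = world.references[0].sequence
    transcript = world.references[1]
    entries = {genome[50:71]: 3, transcript.sequence[10:31]: 2}
    host, _ = filter_host(ReadSet("d", 5, entries), idx)
    attribution = host_layer_attribution(host, idx)
    assert attribution["genome"] == 5  # transcripts are genome windows
    assert attribution["transcript"] >= 2
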