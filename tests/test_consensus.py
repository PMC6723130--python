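"""Consensus stage: merging, barcoding, clustering, collapsing."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracle_consensus as oracle
from umivar import _seq
from umivar.consensus import (
    cluster_barcodes,
    collapse_bin,
    extract_barcode,
    merge_pair,
    merge_pairs,
    run_consensus,
)
from umivar.errors import DataError
from umivar.simulate import SimConfig, make_damage_profile, simulate_library

SEQ = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestMergePair:
    def test_identity(self):
        assert merge_pair("ACGT", "ACGT") == "ACGT"

    def test_single_mismatch_masked(self):
        assert merge_pair("ACGT", "ACGA") == "ACGN"

    def test_n_in_either_mate_masks(self):
        assert merge_pair("ANGT", "ACGT") == "ACGT".replace("C", "N", 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(DataError):
            merge_pair("ACGT", "ACG")

    @given(read=SEQ)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_agreeing_mates_pass_through(self, read):
        assert merge_pair(read, read) == read

    @given(read=SEQ, position=st.integers(0, 59))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_every_disagreement_becomes_n(self, read, position):
        position %= len(read)
        other = "ACGT"[("ACGT".index(read[position]) + 1) % 4]
        mutated = read[:position] + other + read[position + 1 :]
        merged = merge_pair(read, mutated)
        assert merged[position] == "N"
        assert merged.count("N") == 1

    def test_matrix_path_orients_mate_two(self):
        r1 = _seq.encode("AACCGGTT")[None, :]
        r2 = _seq.encode("AACCGGTT")[None, :]  # revcomp == itself here
        merged = merge_pairs(r1, r2)
        assert _seq.decode(merged[0]) == "AACCGGTT"

    def test_error_must_hit_same_base_both_mates_to_survive(self, rng):
        # at e=0.01 the survival rate of sequencing errors through merging
        # is ~e/3 of the per-mate rate: check by direct simulation
        e = 0.01
        n, width = 3000, 50
        template = rng.integers(0, 4, (n, width)).astype(np.uint8)
        r1, r2 = template.copy(), template.copy()
        for mate in (r1, r2):
            hits = rng.random((n, width)) < e
            shift = rng.integers(1, 4, (n, width)).astype(np.uint8)
            mate[hits] = (mate[hits] + shift[hits]) % 4
        merged = np.where((r1 == r2) & (r1 < 4), r1, 4)
        surviving = int(((merged != template) & (merged < 4)).sum())
        per_site = surviving / (n * width)
        assert per_site < e / 10  # well below the raw error rate
        assert per_site == pytest.approx(e * e / 3, rel=1.0)


class TestExtractBarcode:
    def test_150_base_read_gives_126_base_insert(self):
        merged = "A" * 12 + "CGTCA" + "G" * 121 + "T" * 12
        barcode, insert = extract_barcode(merged, umi_len=12)
        assert len(insert) == 126
        assert barcode.umi5 == "A" * 12
        assert barcode.umi3 == "T" * 12
        assert barcode.anchor == "CGTCA"
        assert len(barcode.joint) == 29

    def test_too_short_read_rejected(self):
        with pytest.raises(DataError):
            extract_barcode("A" * 29, umi_len=12)

    def test_n_in_umi_is_retained(self):
        merged = "N" * 12 + "CGTCA" + "G" * 30 + "T" * 12
        barcode, _ = extract_barcode(merged, umi_len=12)
        assert barcode.umi5 == "N" * 12


def _encode_barcodes(barcodes: list[str]) -> np.ndarray:
    return np.stack([_seq.encode(b) for b in barcodes])


class TestClusterBarcodes:
    def test_one_mismatch_joins(self):
        barcodes = ["AAAA"] * 3 + ["AAAT"]
        bins, founders = cluster_barcodes(_encode_barcodes(barcodes), 1)
        assert founders.size == 1
        assert len(set(bins.tolist())) == 1

    def test_two_mismatches_separate(self):
        barcodes = ["AAAA"] * 3 + ["AATT"] * 2
        bins, founders = cluster_barcodes(_encode_barcodes(barcodes), 1)
        assert founders.size == 2

    def test_n_counts_as_mismatch_against_base(self):
        barcodes = ["AAAA"] * 3 + ["AANN"]
        bins, founders = cluster_barcodes(_encode_barcodes(barcodes), 1)
        assert founders.size == 2

    @pytest.mark.parametrize("max_mismatch", [1, 2])
    def test_matches_greedy_oracle_on_random_fixture(self, rng, max_mismatch):
        pool = [_seq.decode(rng.integers(0, 4, 8).astype(np.uint8))
                for _ in range(12)]
        barcodes = []
        for _ in range(50):
            barcode = pool[rng.integers(len(pool))]
            if rng.random() < 0.4:  # sprinkle near-miss copies
                pos = int(rng.integers(8))
                barcode = (
                    barcode[:pos]
                    + "ACGTN"[rng.integers(5)]
                    + barcode[pos + 1 :]
                )
            barcodes.append(barcode)
        bins, founders = cluster_barcodes(
            _encode_barcodes(barcodes), max_mismatch
        )
        expected = oracle.greedy_cluster(barcodes, max_mismatch)
        # same partition of reads, up to bin relabelling
        ours = {}
        for barcode, bin_id in zip(barcodes, bins):
            ours.setdefault(bin_id, set()).add(barcode)
        theirs = {}
        for barcode in barcodes:
            theirs.setdefault(expected[barcode], set()).add(barcode)
        assert sorted(map(sorted, ours.values())) == sorted(
            map(sorted, theirs.values())
        )


class TestCollapseBin:
    def test_four_identical_members_rejected(self):
        assert collapse_bin(["ACGT"] * 4) is None

    def test_eighty_percent_majority_called(self):
        members = ["AAAA"] * 8 + ["GAAA"] * 2
        assert collapse_bin(members) == "AAAA"

    def test_seventy_percent_majority_masked(self):
        members = ["AAAA"] * 7 + ["GAAA"] * 3
        assert collapse_bin(members) == "NAAA"

    def test_even_split_masked_regardless_of_agreement(self):
        members = ["AAAA"] * 5 + ["GAAA"] * 5
        assert collapse_bin(members, agreement=0.5) == "NAAA"

    def test_n_members_stay_in_denominator(self):
        # 6 of 8 call A (75% of all members including the N-bearing ones)
        members = ["AAAA"] * 6 + ["NAAA"] * 2
        assert collapse_bin(members) == "AAAA"
        # 5 of 8 (62.5%) does not reach 75%
        members = ["AAAA"] * 5 + ["NAAA"] * 3
        assert collapse_bin(members) == "NAAA"

    def test_idempotent_on_singletons(self):
        for seq in ("ACGTN", "NNNNN", "AAAAA"):
            assert collapse_bin([seq], min_reads=1) == seq


def _library_pairs(result) -> list[tuple[str, str]]:
    pairs = []
    for pr in result.reads:
        for i in range(pr.r1.shape[0]):
            pairs.append((_seq.decode(pr.r1[i]), _seq.decode(pr.r2[i])))
    return pairs


class TestRunConsensus:
    def test_matches_brute_force_oracle(self, sim_panel):
        config = SimConfig(
            seed=21, captures_per_probe=18, reads_per_capture_mean=8,
            pcr_cycles=6, pcr_error_rate=1e-4, seq_error_rate=2e-3,
            damage_profile=make_damage_profile(sim_panel, seed=3),
        )
        result = simulate_library(sim_panel, config)
        pairs = _library_pairs(result)
        assert len(pairs) <= 200
        expected = oracle.run(pairs)
        ours = run_consensus(result.read_batches())
        observed = Counter(
            (read.seq, read.supporting_reads) for read in ours.iter_reads()
        )
        assert observed == expected

    def test_no_error_round_trip_recovers_templates(self, sim_panel):
        config = SimConfig(
            seed=22, captures_per_probe=40, reads_per_capture_mean=12,
            pcr_cycles=6, pcr_error_rate=0.0, seq_error_rate=0.0,
        )
        result = simulate_library(sim_panel, config)
        consensus = run_consensus(result.read_batches())
        template = sim_panel.probes[0].region_seq
        for read in consensus.iter_reads():
            assert read.seq == template
        kept = (result.truth.captures["n_reads"] >= 5).sum()
        assert len(consensus) == kept

    def test_consensus_count_tracks_poisson_tail(self, sim_panel):
        # number of consensus reads ~ captures x P(Poisson(mean) >= 5)
        from scipy import stats

        mean = 8.0
        n = 3_000
        config = SimConfig(
            seed=23, captures_per_probe=n, reads_per_capture_mean=mean,
            pcr_cycles=4, pcr_error_rate=0.0, seq_error_rate=0.0,
        )
        result = simulate_library(sim_panel, config)
        consensus = run_consensus(result.read_batches())
        p = 1 - stats.poisson.cdf(4, mean)
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(len(consensus) - n * p) < 4 * sigma

    def test_error_suppression_hundredfold(self, sim_panel):
        # raw per-base error ~1e-3; consensus bases wrong vs their own
        # capture template (which includes founding errors) must be <1e-5
        config = SimConfig(
            seed=24, captures_per_probe=800, reads_per_capture_mean=12,
            pcr_cycles=12, pcr_error_rate=1e-5, seq_error_rate=1e-3,
        )
        result = simulate_library(sim_panel, config)
        consensus = run_consensus(result.read_batches())
        mol = result.reads[0]
        truth = result.truth.captures
        by_umi = {
            (row.umi5, row.umi3): row.capture
            for row in truth.itertuples(index=False)
        }
        templates = {}
        pool_templates = None
        # recover templates from the simulation state
        import umivar.simulate as sim_mod

        # re-simulate molecules deterministically to fetch template matrix
        rng = np.random.default_rng(config.seed)
        molecules, _ = sim_mod.simulate_molecules(sim_panel, config, rng)
        sim_mod.simulate_pcr(molecules, config, rng)
        template_mat = molecules[0].templates
        wrong = total = 0
        for read in consensus.iter_reads():
            capture = by_umi.get((read.barcode.umi5, read.barcode.umi3))
            if capture is None:
                continue
            template = template_mat[capture]
            called = _seq.encode(read.seq)
            mask = called < 4
            total += int(mask.sum())
            wrong += int((called[mask] != template[mask]).sum())
        assert total > 0
        assert wrong / total < 1e-5

    def test_first_round_errors_survive_collapse(self, sim_panel):
        probe = sim_panel.probes[0]
        alt_code = (int(probe.codes[30]) + 1) % 4
        config = SimConfig(
            seed=25, captures_per_probe=3, reads_per_capture_mean=20,
            pcr_cycles=8, pcr_error_rate=0.0, seq_error_rate=0.0,
        )
        from umivar.simulate import simulate_library as run_sim

        result = run_sim(
            sim_panel, config,
            forced_errors=[(probe.probe_id, 0, 1, 30, alt_code)],
        )
        consensus = run_consensus(result.read_batches())
        alts = [
            read.seq[30] for read in consensus.iter_reads()
        ]
        assert alts.count(_seq.BASES[alt_code]) == 1  # the converted capture
        assert alts.count("N") == 0  # present at ~100%, never masked

    def test_late_pcr_errors_never_reach_consensus(self, sim_panel):
        probe = sim_panel.probes[0]
        alt_code = (int(probe.codes[40]) + 1) % 4
        config = SimConfig(
            seed=26, captures_per_probe=5, reads_per_capture_mean=30,
            pcr_cycles=8, pcr_error_rate=0.0, seq_error_rate=0.0,
        )
        from umivar.simulate import simulate_library as run_sim

        result = run_sim(
            sim_panel, config,
            forced_errors=[(probe.probe_id, c, 2, 40, alt_code)
                           for c in range(5)],
        )
        consensus = run_consensus(result.read_batches())
        template_base = probe.region_seq[40]
        for read in consensus.iter_reads():
            # a 25%-of-reads lineage never wins the 75% rule
            assert read.seq[40] in (template_base, "N")
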