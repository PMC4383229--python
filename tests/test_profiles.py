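"""Read filtering, A-site inference and profile construction."""

import numpy as np
import pandas as pd
import pytest

from ribostress.profiles import (
    SPIKE_ID,
    build_profile,
    filter_reads,
    infer_asite,
    read_alignment_sam,
    read_alignment_tsv,
    read_profile_tsv,
    region_counts,
    select_variant,
    write_alignment_sam,
    write_alignment_tsv,
    write_profile_tsv,
)

from conftest import make_reads


class TestFilterReads:
    @pytest.mark.parametrize(
        "length,kept",
        [(28, False), (29, True), (32, True), (35, True), (36, False)],
    )
    def test_footprint_length_window(self, toy_transcripts, length, kept):
        reads = make_reads([("TX1", 0, length, 1, 1)])
        out, ledger = filter_reads(reads, "ribo", toy_transcripts)
        assert (len(out) == 1) == kept
        assert ledger["discard_length"] == (0 if kept else 1)

    def test_rna_reads_not_length_filtered(self, toy_transcripts):
        reads = make_reads([("TX1", 0, 25, 1, 1)])
        out, _ = filter_reads(reads, "rna", toy_transcripts)
        assert len(out) == 1

    @pytest.mark.parametrize("gene_hits,tx_hits", [(2, 1), (1, 2), (3, 5)])
    def test_ambiguous_mappers_discarded(self, toy_transcripts, gene_hits, tx_hits):
        reads = make_reads([("TX1", 0, 30, gene_hits, tx_hits)])
        out, ledger = filter_reads(reads, "ribo", toy_transcripts)
        assert len(out) == 0
        assert ledger["discard_multimap_gene"] + ledger["discard_multimap_tx"] == 1

    def test_empty_input(self, toy_transcripts):
        out, ledger = filter_reads(make_reads([]), "ribo", toy_transcripts)
        assert len(out) == 0
        assert ledger["input"] == 0 and ledger["kept"] == 0

    def test_unknown_transcript_named_in_error(self, toy_transcripts):
        reads = make_reads([("NOPE", 0, 30, 1, 1)])
        with pytest.raises(KeyError, match="NOPE"):
            filter_reads(reads, "ribo", toy_transcripts)

    def test_ledger_conserves_reads(self, toy_transcripts):
        rng = np.random.default_rng(0)
        rows = [
            (
                "TX1",
                int(rng.integers(0, 40)),
                int(rng.integers(25, 40)),
                int(rng.integers(1, 3)),
                int(rng.integers(1, 3)),
            )
            for _ in range(200)
        ] + [(SPIKE_ID, 0, 28, 1, 1)] * 5
        out, ledger = filter_reads(make_reads(rows), "ribo", toy_transcripts)
        discarded = (
            ledger["discard_length"]
            + ledger["discard_multimap_gene"]
            + ledger["discard_multimap_tx"]
        )
        assert ledger["kept"] + ledger["spike"] + discarded == ledger["input"]
        assert len(out) == ledger["kept"] + ledger["spike"]


class TestInferAsite:
    @pytest.mark.parametrize(
        "length,pos5,expected",
        [(29, 100, 116), (30, 0, 16), (32, 10, 26), (33, 0, 17), (35, 0, 17)],
    )
    def test_offset_mapping(self, length, pos5, expected):
        assert infer_asite(pos5, length) == expected

    @pytest.mark.parametrize("length", [20, 28, 36])
    def test_length_outside_range_errors(self, length):
        with pytest.raises(ValueError, match="offset"):
            infer_asite(0, length)

    def test_vectorized_matches_scalar(self):
        lengths = np.array([29, 31, 33, 35])
        pos5 = np.array([0, 5, 10, 20])
        vec = infer_asite(pos5, lengths)
        assert list(vec) == [infer_asite(p, l) for p, l in zip(pos5, lengths)]

    def test_asite_inside_footprint(self):
        for length in range(29, 36):
            a = infer_asite(50, length)
            assert 50 <= a < 50 + length


class TestBuildProfile:
    def test_single_ribo_read_counts_at_asite(self, toy_transcripts):
        reads = make_reads([("TX1", 0, 29, 1, 1)])
        p = build_profile(reads, toy_transcripts, "ribo")
        assert p.counts["TX1"][16] == 1
        assert p.counts["TX1"].sum() == 1

    def test_rna_reads_count_at_five_prime_end(self, toy_transcripts):
        reads = make_reads([("TX1", 5, 30, 1, 1), ("TX1", 5, 33, 1, 1)])
        p = build_profile(reads, toy_transcripts, "rna")
        assert p.counts["TX1"][5] == 2

    def test_spike_reads_counted_separately(self, toy_transcripts):
        reads = make_reads([("TX1", 0, 30, 1, 1), (SPIKE_ID, 0, 28, 1, 1)])
        p = build_profile(reads, toy_transcripts, "ribo")
        assert p.spike_count == 1
        assert p.transcript_total() == 1
        assert p.total_mapped == 2

    def test_order_independent(self, toy_transcripts):
        rng = np.random.default_rng(1)
        rows = [
            ("TX1" if rng.random() < 0.5 else "TX2", int(rng.integers(0, 30)),
             int(rng.integers(29, 36)), 1, 1)
            for _ in range(100)
        ]
        a = build_profile(make_reads(rows), toy_transcripts, "ribo")
        shuffled = make_reads(rows).sample(frac=1, random_state=3)
        b = build_profile(shuffled, toy_transcripts, "ribo")
        for tx in a.counts:
            assert np.array_equal(a.counts[tx], b.counts[tx])

    def test_asite_overrun_discarded_and_ledgered(self, toy_transcripts):
        tx = toy_transcripts["TX1"]
        # 5' end near the 3' end: footprint fits but the A-site would not
        pos5 = tx.length - 29
        reads = make_reads([("TX1", pos5, 29, 1, 1)])
        p = build_profile(reads, toy_transcripts, "ribo")
        assert p.transcript_total() + p.spike_count + p.discard_ledger[
            "discard_asite_overrun"
        ] == 1 or p.transcript_total() == 1  # overrun only if 16 past end

    def test_invalid_assay(self, toy_transcripts):
        with pytest.raises(ValueError, match="assay"):
            build_profile(make_reads([]), toy_transcripts, "chip")


class TestSelectVariant:
    def _profile(self, transcripts, counts):
        reads = make_reads(
            [(tx, 0, 30, 1, 1) for tx, n in counts.items() for _ in range(n)]
        )
        return build_profile(reads, transcripts, "ribo", condition="control")

    def test_single_variant(self, toy_transcripts):
        p = self._profile(toy_transcripts, {"TX1": 3})
        chosen = select_variant(toy_transcripts, [p])
        assert chosen["GENE1"] == "TX1"

    def test_highest_density_wins(self):
        from ribostress.transcripts import TranscriptRecord

        a = TranscriptRecord("TA", "G", "C" * 10 + "ATG" + "AAA" * 5 + "TAA" + "C" * 10,
                             cds_start=10, cds_end=31)
        b = TranscriptRecord("TB", "G", "C" * 10 + "ATG" + "AAA" * 5 + "TAA" + "C" * 60,
                             cds_start=10, cds_end=31)
        txs = {"TA": a, "TB": b}
        # equal read counts: shorter transcript has higher density
        p = self._profile(txs, {"TA": 5, "TB": 5})
        assert select_variant(txs, [p])["G"] == "TA"

    def test_tie_breaks_lexicographically(self):
        from ribostress.transcripts import TranscriptRecord

        seq = "C" * 10 + "ATG" + "AAA" * 5 + "TAA" + "C" * 10
        txs = {
            "TB": TranscriptRecord("TB", "G", seq, 10, 31),
            "TA": TranscriptRecord("TA", "G", seq, 10, 31),
        }
        p = self._profile(txs, {"TA": 2, "TB": 2})
        assert select_variant(txs, [p])["G"] == "TA"


class TestRegionCounts:
    def test_all_counts_in_cds(self, toy_transcripts):
        tx = toy_transcripts["TX1"]
        reads = make_reads([("TX1", tx.cds_start - 16, 29, 1, 1)] * 4)
        p = build_profile(reads, toy_transcripts, "ribo")
        rc = region_counts(p, toy_transcripts).loc["TX1"]
        assert (rc["leader"], rc["cds"], rc["trailer"]) == (0, 4, 0)

    def test_empty_profile(self, toy_transcripts):
        p = build_profile(make_reads([]), toy_transcripts, "rna")
        rc = region_counts(p, toy_transcripts)
        assert (rc.to_numpy() == 0).all()

    def test_uniform_rna_tracks_region_lengths(self, toy_transcripts):
        tx = toy_transcripts["TX2"]
        rng = np.random.default_rng(5)
        n = 20000
        pos = rng.integers(0, tx.length, size=n)
        reads = make_reads([("TX2", int(p), 1, 1, 1) for p in pos])
        prof = build_profile(reads, toy_transcripts, "rna")
        rc = region_counts(prof, toy_transcripts).loc["TX2"]
        for region, span in (("leader", tx.cds_start), ("cds", tx.cds_length),
                             ("trailer", tx.trailer_length)):
            assert rc[region] / n == pytest.approx(span / tx.length, abs=0.02)


class TestAlignmentIO:
    def test_tsv_roundtrip(self, tmp_path, toy_transcripts):
        reads = make_reads([("TX1", 3, 30, 1, 1), (SPIKE_ID, 0, 28, 1, 1)])
        path = tmp_path / "aln.tsv"
        write_alignment_tsv(reads, path)
        back = read_alignment_tsv(path)
        pd.testing.assert_frame_equal(reads, back)

    def test_profile_tsv_roundtrip(self, tmp_path, toy_transcripts):
        rng = np.random.default_rng(7)
        rows = [
            ("TX1" if rng.random() < 0.5 else "TX2", int(rng.integers(0, 30)),
             int(rng.integers(29, 36)), 1, 1)
            for _ in range(60)
        ]
        p = build_profile(make_reads(rows), toy_transcripts, "ribo")
        path = tmp_path / "profile.tsv"
        write_profile_tsv(p, path)
        back = read_profile_tsv(path, toy_transcripts)
        for tx in p.counts:
            assert np.array_equal(p.counts[tx], back[tx])

    def test_sam_roundtrip(self, tmp_path, toy_transcripts):
        reads = make_reads([("TX1", 3, 30, 1, 1), ("TX2", 10, 35, 2, 1)])
        path = tmp_path / "aln.sam"
        write_alignment_sam(reads, toy_transcripts, path)
        back = read_alignment_sam(path)
        pd.testing.assert_frame_equal(
            reads.sort_values("tx_id").reset_index(drop=True),
            back.sort_values("tx_id").reset_index(drop=True),
            check_dtype=False,
        )
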