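"""uORF detection, translation calls, density centres and context tables."""

import shutil

import numpy as np
import pandas as pd
import pytest

from ribostress.transcripts import STOP_CODONS, TranscriptRecord
from ribostress.uorf import (
    ContextTable,
    best_uorf,
    call_translated,
    context_frequencies,
    density_center,
    density_shift,
    find_uorfs,
    leader_stats,
    position_frequency_matrix,
    relative_frequency,
    structure_energy_hook,
    uorf_te,
)

from conftest import random_leader_transcript


# --- independent brute-force oracles -------------------------------------


def oracle_find_uorfs(tx, start_codons=("ATG",)):
    """Enumerate every start-codon position, extend to stop or CDS, then
    drop candidates contained in an accepted same-frame uORF."""
    seq, cs = tx.sequence, tx.cds_start
    candidates = []
    for i in range(cs):
        if seq[i : i + 3] not in start_codons or i + 3 > cs:
            continue
        codons = [seq[j : j + 3] for j in range(i, cs - 2, 3) if j + 3 <= cs]
        end, truncated = cs, True
        for k, codon in enumerate(codons[1:], start=1):
            if codon in STOP_CODONS:
                end, truncated = i + 3 * k, False
                break
        n_codons = (end - i) // 3 if not truncated else (cs - i) // 3
        candidates.append((i, end, truncated, n_codons))
    accepted = []
    for cand in candidates:  # ascending start order
        i, end = cand[0], cand[1]
        contained = any(
            a[0] <= i and end <= a[1] and (i - a[0]) % 3 == 0 and i > a[0]
            for a in accepted
        )
        if not contained:
            accepted.append(cand)
    return accepted


def oracle_density_center(vec):
    """O(L^2) scan over every candidate coordinate."""
    v = np.asarray(vec)
    if v.sum() == 0:
        return None
    for c in range(len(v)):
        if v[: c + 1].sum() >= v[c + 1 :].sum():
            return c
    return len(v) - 1


def _tx_with_leader(leader, cds_codons=4):
    cds = "ATG" + "GCT" * (cds_codons - 1) + "TAA"
    return TranscriptRecord(
        "T", "G", leader + cds + "CCCCC", len(leader), len(leader) + len(cds)
    )


class TestFindUorfs:
    def test_simple_uorf(self):
        # leader AAA ATG AAA TAG CC: one uORF of 2 sense codons
        tx = _tx_with_leader("AAAATGAAATAGCC")
        (u,) = find_uorfs(tx)
        assert u.start == 3
        assert u.length_codons == 2
        assert not u.truncated_flag
        assert u.end == 9  # stop codon excluded

    def test_nested_same_frame_excluded(self):
        # second ATG in frame with and inside the first uORF
        leader = "ATG" + "AAA" + "ATG" + "CCC" + "TAA" + "GG"
        tx = _tx_with_leader(leader)
        uorfs = find_uorfs(tx)
        assert len(uorfs) == 1 and uorfs[0].start == 0

    def test_out_of_frame_overlap_kept(self):
        # ATG at 0 (frame 0) and at 4 (frame 1), overlapping: both kept
        leader = "ATGAATGCCCTAACCTAAGC"
        tx = _tx_with_leader(leader)
        starts = {u.start for u in find_uorfs(tx)}
        assert starts == {0, 4}

    def test_no_stop_truncates_at_cds(self):
        leader = "AA" + "ATG" + "AAA" * 4  # no stop before the CDS
        tx = _tx_with_leader(leader)
        (u,) = find_uorfs(tx)
        assert u.truncated_flag
        assert u.end == tx.cds_start
        assert u.length_codons == (tx.cds_start - 2) // 3

    def test_no_leader_no_uorfs(self):
        tx = TranscriptRecord("T", "G", "ATG" + "AAA" + "TAA", 0, 9)
        assert find_uorfs(tx) == []

    def test_near_cognate_starts_optional(self):
        leader = "CC" + "CTG" + "AAA" + "TAG" + "CC"
        tx = _tx_with_leader(leader)
        assert find_uorfs(tx) == []
        cug = find_uorfs(tx, start_codons=("ATG", "CTG"))
        assert len(cug) == 1 and cug[0].start_codon == "CTG"

    def test_matches_brute_force_oracle_on_random_leaders(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            tx = random_leader_transcript(rng)
            got = [
                (u.start, u.end, u.truncated_flag, u.length_codons)
                for u in find_uorfs(tx)
            ]
            assert got == oracle_find_uorfs(tx), tx.sequence


class TestTranslationCall:
    def _vec(self, tx, n):
        v = np.zeros(tx.length, dtype=int)
        v[3 : 3 + n] = 1  # n reads inside the uORF at start 3
        return v

    @pytest.mark.parametrize("reads,flag", [(6, True), (5, False), (0, False)])
    def test_more_than_five_reads_required(self, reads, flag):
        tx = _tx_with_leader("AAAATGAAATAGCC")
        (u,) = find_uorfs(tx)
        u = call_translated(u, self._vec(tx, reads))
        assert u.ribo_reads == reads
        assert u.translated_flag is flag

    def test_uorf_te_arithmetic(self):
        # 60 ribo reads on a 30-nt uORF vs 500 rna reads on a 1000-nt
        # transcript: (60/30)/(500/1000) = 4
        leader = "A" * 5 + "ATG" + "GGA" * 9 + "TAA" + "C" * 58
        cds = "ATG" + "GCT" * 299 + "TAA"
        seq = leader + cds + "T" * (1000 - len(leader) - len(cds))
        tx = TranscriptRecord("T", "G", seq, len(leader), len(leader) + len(cds))
        (u,) = find_uorfs(tx)
        assert u.length_nt == 30
        ribo = np.zeros(1000, dtype=int)
        ribo[u.start : u.end] = 2
        rna = np.zeros(1000, dtype=int)
        rna[::2] = 1
        assert uorf_te(u, ribo, rna) == pytest.approx(4.0)

    def test_zero_rna_flagged_nan(self):
        tx = _tx_with_leader("AAAATGAAATAGCC")
        (u,) = find_uorfs(tx)
        assert np.isnan(uorf_te(u, np.ones(tx.length), np.zeros(tx.length)))

    def test_best_uorf_by_read_count_then_position(self):
        tx = _tx_with_leader("ATGTAACCATGTAACC")
        uorfs = find_uorfs(tx)
        assert len(uorfs) == 2
        vec = np.zeros(tx.length, dtype=int)
        vec[0:3] = 4  # 12 reads on first
        vec[8:11] = 14  # 42 reads on second
        uorfs = [call_translated(u, vec) for u in uorfs]
        assert best_uorf(uorfs).start == 8
        # tie goes to the 5'-most
        vec[0:3] = 14
        uorfs = [call_translated(u, vec) for u in find_uorfs(tx)]
        assert best_uorf(uorfs).start == 0

    def test_best_uorf_requires_translated(self):
        tx = _tx_with_leader("AAAATGAAATAGCC")
        (u,) = find_uorfs(tx)
        with pytest.raises(ValueError):
            best_uorf([u])


class TestDensityCenter:
    def test_single_read(self):
        v = np.zeros(50, dtype=int)
        v[10] = 1
        assert density_center(v) == 10

    def test_two_distant_reads(self):
        v = np.zeros(200, dtype=int)
        v[0] = 1
        v[100] = 1
        assert density_center(v) == 0

    def test_empty_vector_is_none(self):
        assert density_center(np.zeros(10, dtype=int)) is None

    def test_matches_brute_force_on_random_sparse_vectors(self):
        rng = np.random.default_rng(99)
        for _ in range(300):
            L = int(rng.integers(1, 120))
            v = np.zeros(L, dtype=int)
            k = int(rng.integers(0, 6))
            if k:
                v[rng.integers(0, L, size=k)] += rng.integers(1, 5, size=k)
            assert density_center(v) == oracle_density_center(v)

    def test_shift_arithmetic_and_sign(self):
        r = density_shift("g", 50, 150, 100)
        assert r.shift == 1.0
        assert density_shift("g", 80, 80, 50).shift == 0.0
        assert density_shift("g", 100, 40, 120).shift < 0

    def test_zero_cds_length_rejected(self):
        with pytest.raises(ValueError):
            density_shift("g", 1, 2, 0)


class TestContextFrequencies:
    def test_worked_relative_frequency(self):
        # 640 occurrences among 35,841 sites -> 1.7857...%
        assert relative_frequency(640, 35841) == pytest.approx(1.7857, abs=1e-3)

    def test_single_site_is_hundred_percent(self):
        tx = _tx_with_leader("AAAATGAAATAGCC")
        ctx = context_frequencies({"T": tx}, [("T", 3)], window=(-3, 3))
        assert len(ctx.table) == 1
        assert ctx.table["percent"].iloc[0] == 100.0

    def test_out_of_bounds_site_skipped(self):
        tx = _tx_with_leader("AAAATGAAATAGCC")
        ctx = context_frequencies({"T": tx}, [("T", 2)], window=(-4, 4))
        assert ctx.n_skipped == 1 and ctx.n_sites_used == 0

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(11)
        txs, sites = {}, []
        for i in range(30):
            tx = random_leader_transcript(rng, leader_len=60)
            tx = TranscriptRecord(f"T{i}", f"G{i}", tx.sequence, tx.cds_start, tx.cds_end)
            txs[tx.tx_id] = tx
            sites.append((tx.tx_id, tx.cds_start))
        ctx = context_frequencies(txs, sites, window=(-4, 4))
        assert ctx.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)
        pfm = position_frequency_matrix(ctx)
        assert np.allclose(pfm.sum(axis=1), 1.0)
        # the window spans the start codon itself
        assert pfm.loc[0, "A"] == 1.0 and pfm.loc[2, "G"] == 1.0


class TestLeaderStats:
    def test_mean_leader_length_per_class(self):
        txs = {
            "T1": _tx_with_leader("A" * 100),
            "T2": _tx_with_leader("C" * 300),
        }
        txs = {
            k: TranscriptRecord(k, f"G{k}", v.sequence, v.cds_start, v.cds_end)
            for k, v in txs.items()
        }
        chosen = {"GT1": "T1", "GT2": "T2"}
        labels = pd.Series({"GT1": "resistant", "GT2": "resistant"})
        out = leader_stats(txs, chosen, labels, {})
        assert out.loc["resistant", "leader_mean"] == 200.0
        assert out.loc["resistant", "uorf_prevalence"] == 0.0


class TestStructureEnergyHook:
    def test_short_leader_excluded(self):
        r = structure_energy_hook("A" * 239)
        assert r.energy is None and r.status == "leader_too_short"

    def test_no_folder_records_not_computed(self):
        r = structure_energy_hook("A" * 240)
        assert r.energy is None and r.status == "not_computed"

    def test_callable_folder_passthrough(self):
        r = structure_energy_hook("G" * 240, folder=lambda s: -12.5)
        assert r.energy == -12.5 and r.status == "computed"

    def test_external_rnafold_executable(self):
        if shutil.which("RNAfold") is None:
            pytest.skip("RNAfold executable not on PATH")
        hairpin = ("GGGGCCCC" * 30)[:240]
        r = structure_energy_hook(hairpin, folder="RNAfold")
        assert r.status == "computed"
        assert r.energy is not None and r.energy < 0
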