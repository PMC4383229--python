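import numpy as np
import pandas as pd
import pytest

from ribostress.transcripts import TranscriptRecord


def make_reads(rows):
    """rows: list of (tx_id, pos5, length, n_gene_hits, n_tx_hits)."""
    return pd.DataFrame(
        rows, columns=["tx_id", "pos5", "length", "n_gene_hits", "n_tx_hits"]
    )


@pytest.fixture
def toy_transcript():
    # 30 nt leader with one 2-codon uORF (ATG AAA TAG at 3), 30 nt CDS (incl
    # stop), 20 nt trailer
    leader = "AAA" + "ATGAAATAG" + "C" * 18
    cds = "ATG" + "GAA" * 8 + "TAA"
    trailer = "G" * 20
    return TranscriptRecord(
        tx_id="TX1",
        gene_id="GENE1",
        sequence=leader + cds + trailer,
        cds_start=len(leader),
        cds_end=len(leader) + len(cds),
    )


@pytest.fixture
def toy_transcripts(toy_transcript):
    other = TranscriptRecord(
        tx_id="TX2",
        gene_id="GENE2",
        sequence="C" * 40 + "ATG" + "GGA" * 20 + "TGA" + "T" * 25,
        cds_start=40,
        cds_end=40 + 66,
    )
    return {t.tx_id: t for t in (toy_transcript, other)}


def random_leader_transcript(rng, leader_len=None, cds_codons=8):
    """A transcript with a fully random leader (uORFs arise by chance)."""
    if leader_len is None:
        leader_len = int(rng.integers(0, 120))
    leader = "".join(rng.choice(list("ACGT"), size=leader_len))
    cds = "ATG" + "GCT" * (cds_codons - 1) + "TAA"
    trailer = "".join(rng.choice(list("ACGT"), size=20))
    return TranscriptRecord(
        tx_id="RND",
        gene_id="RND",
        sequence=leader + cds + trailer,
        cds_start=leader_len,
        cds_end=leader_len + len(cds),
    )
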