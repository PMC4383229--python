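#!/usr/bin/env python
"""Library QC on the simulated study: read-region distribution, metagene
profiles around CDS boundaries, and per-length triplet periodicity."""

import argparse
from pathlib import Path

import pandas as pd

from ribostress.profiles import build_profile, filter_reads, region_counts
from ribostress.qc import metagene, periodicity
from ribostress.simulate import read_fixture

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "results" / "simulated")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "qc")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    transcripts, truth, design, reads = read_fixture(args.data)

    region_rows, period_tabs = [], {}
    for sample_id, row in design.iterrows():
        profile = build_profile(
            reads[sample_id], transcripts, row["assay"], sample_id=sample_id,
            condition=row["condition"], replicate=int(row["replicate"]),
        )
        rc = region_counts(profile, transcripts).sum()
        total = rc.sum()
        region_rows.append(
            {"sample_id": sample_id, **rc.to_dict(),
             "leader_pct": 100 * rc["leader"] / total,
             "cds_pct": 100 * rc["cds"] / total,
             "trailer_pct": 100 * rc["trailer"] / total}
        )
        if row["assay"] == "ribo" and row["condition"] == "control":
            mm = metagene(profile, transcripts)
            mm.start.to_csv(args.out / f"metagene_start_{sample_id}.tsv", sep="\t")
            mm.stop.to_csv(args.out / f"metagene_stop_{sample_id}.tsv", sep="\t")
            kept, _ = filter_reads(reads[sample_id], "ribo", transcripts)
            period_tabs[sample_id] = periodicity(kept, transcripts)

    regions = pd.DataFrame(region_rows).set_index("sample_id")
    regions.to_csv(args.out / "region_counts.tsv", sep="\t")
    print("read distribution over mRNA regions (% of in-transcript reads):")
    print(regions[["leader_pct", "cds_pct", "trailer_pct"]].round(1))

    for sample_id, tab in period_tabs.items():
        tab.to_csv(args.out / f"periodicity_{sample_id}.tsv", sep="\t")
        print(f"\ntriplet periodicity, {sample_id} (modal-frame fraction per length):")
        print(tab["modal_fraction"].round(3))


if __name__ == "__main__":
    main()
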