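#!/usr/bin/env python
"""Download the study's deposited sequences and prepare a replication run.

Fetches the per-locus GenBank accessions listed in the shipped specimen
table (requires network access; not used by the test suite), writes one
FASTA per locus with records renamed to specimen ids, exports the sample
table, and emits a ready-to-run pipeline config:

    python scripts/fetch_genbank.py --out replication/
    phylopart report --config replication/config.yaml --out replication/out

Sequences are fetched unaligned; align each locus (e.g. with mafft) before
running the pipeline if the downloads are not already length-consistent.
"""

from __future__ import annotations

import argparse
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import importlib.resources

import pandas as pd
import yaml
from Bio import Entrez, SeqIO

LOCI = ["cytb", "nd4", "mc1r", "acm4", "pdc"]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, required=True)
    parser.add_argument("--email", default="anonymous@example.org")
    parser.add_argument("--delay", type=float, default=0.4,
                        help="seconds between NCBI requests")
    args = parser.parse_args()
    Entrez.email = args.email
    args.out.mkdir(parents=True, exist_ok=True)

    with importlib.resources.files("phylopart.data").joinpath(
        "specimens.tsv"
    ).open() as fh:
        tab = pd.read_csv(fh, sep="\t", dtype={"specimen_id": str})
    tab = tab[tab["outgroup"] == 0]

    for locus in LOCI:
        col = f"acc_{locus}"
        wanted = tab.dropna(subset=[col])[["specimen_id", col]]
        records = []
        for sid, acc in wanted.itertuples(index=False):
            handle = Entrez.efetch(db="nucleotide", id=acc,
                                   rettype="fasta", retmode="text")
            rec = SeqIO.read(handle, "fasta")
            rec.id, rec.description = sid, acc
            records.append(rec)
            time.sleep(args.delay)
        SeqIO.write(records, args.out / f"{locus}.fasta", "fasta")
        print(f"{locus}: {len(records)} sequences")

    tab.drop(columns="outgroup").to_csv(
        args.out / "samples.tsv", sep="\t", index=False
    )
    config = {
        "inputs": {
            "sample_table": str(args.out / "samples.tsv"),
            "loci": {l: str(args.out / f"{l}.fasta") for l in ["cytb", "nd4"]},
            "combine": ["cytb", "nd4"],
        },
        "analysis": {"seed": 0, "n_perm": 1000, "n_resamples": 100},
    }
    (args.out / "config.yaml").write_text(yaml.safe_dump(config))
    print(f"config written to {args.out / 'config.yaml'}")


if __name__ == "__main__":
    main()
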