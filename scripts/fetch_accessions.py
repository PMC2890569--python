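#!/usr/bin/env python
"""One-time download of the nine study accessions from NCBI Entrez.

Saves GenBank flat files under data/accessions/ so that the
accession-dependent analyses and tests can run offline afterwards.

Usage:
    python scripts/fetch_accessions.py [--dest data/accessions]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from mitocomp.accessions import STUDY_ACCESSIONS, fetch_genbank


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--dest", type=Path,
                        default=Path("data") / "accessions")
    args = parser.parse_args()
    for accession, meta in STUDY_ACCESSIONS.items():
        dest = args.dest / f"{accession}.gb"
        if dest.exists():
            print(f"{accession} ({meta.species}): already present")
            continue
        fetch_genbank(accession, dest, timeout=60.0)
        print(f"{accession} ({meta.species}): saved to {dest}")


if __name__ == "__main__":
    main()
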