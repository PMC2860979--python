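"""Download the deposited study sequences (AB526881-AB527004) from GenBank.

Network-dependent helper; nothing in the package or tests requires it.
Sequences are fetched via NCBI Entrez, bucketed by marker keyword from
their definition lines, and written as one unaligned FASTA per marker.
Align each file (e.g. ``mafft --auto``) and pair it with a metadata TSV
before feeding it to ``neodiag all``.

Usage:
    python scripts/fetch_accessions.py --email you@example.org --outdir data/accessions
"""

from __future__ import annotations

import argparse
import time
from pathlib import Path

from Bio import Entrez, SeqIO

FIRST, LAST = 526881, 527004  # AB526881 .. AB527004
MARKER_KEYWORDS = {
    "COI": ("cytochrome c oxidase", "COI", "COX1"),
    "12S": ("12S",),
    "ITS": ("internal transcribed spacer", "ITS"),
    "28S": ("28S",),
}


def classify(description: str) -> str | None:
    for marker, keys in MARKER_KEYWORDS.items():
        if any(k.lower() in description.lower() for k in keys):
            return marker
    return None


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", required=True, help="identifies you to NCBI")
    ap.add_argument("--outdir", type=Path, default=Path("data/accessions"))
    ap.add_argument("--batch", type=int, default=50)
    args = ap.parse_args()

    Entrez.email = args.email
    accessions = [f"AB{i}" for i in range(FIRST, LAST + 1)]
    by_marker: dict[str, list] = {m: [] for m in MARKER_KEYWORDS}
    unclassified = []
    for start in range(0, len(accessions), args.batch):
        chunk = accessions[start : start + args.batch]
        with Entrez.efetch(
            db="nucleotide", id=",".join(chunk), rettype="fasta", retmode="text"
        ) as handle:
            for rec in SeqIO.parse(handle, "fasta"):
                marker = classify(rec.description)
                (by_marker[marker] if marker else unclassified).append(rec)
        time.sleep(0.4)  # stay under NCBI rate limits

    args.outdir.mkdir(parents=True, exist_ok=True)
    for marker, records in by_marker.items():
        path = args.outdir / f"{marker}.unaligned.fasta"
        SeqIO.write(records, path, "fasta")
        print(f"{marker}: {len(records)} records -> {path}")
    if unclassified:
        path = args.outdir / "unclassified.fasta"
        SeqIO.write(unclassified, path, "fasta")
        print(f"WARNING: {len(unclassified)} records not matched to a marker -> {path}")
    print("align each marker (e.g. `mafft --auto`) before running the pipeline")


if __name__ == "__main__":
    main()
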