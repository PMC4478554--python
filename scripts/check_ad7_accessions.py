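#!/usr/bin/env python
"""Opt-in real-data check against the published ad-7 allele sequences.

Downloads GenBank accessions (network required; NOT part of the default
test suite) and verifies that the RIP detector reproduces the published
comparison of the ancestral ad-7 allele with its RIP-induced mutants:

* 85 A (KP006652) vs RIP1 (KP006653): 45 differences, 6 intronic,
  39 affected exonic codons, including the nonsense change Q122*;
* RIP3T (KR349721) shows pure G>A polarity and RIP3C (KR349720) pure C>T
  on the sequenced strand.

Exon intervals are not annotated in these records, so the check focuses on
total difference counts, polarity, and the presence of hallmark effect
strings where a CDS annotation is available in the GenBank feature table.

Usage:
    python scripts/check_ad7_accessions.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import sys

from Bio import Entrez, SeqIO

from octadkit import SequencePair, align_pair, classify_substitutions

ACCESSIONS = {
    "85A": "KP006652",
    "RIP1": "KP006653",
    "RIP2": "KP006654",
    "RIP3C": "KR349720",
    "RIP3T": "KR349721",
}

EXPECTED = {
    # (ancestor, derived): (total differences, intronic differences)
    ("85A", "RIP1"): (45, 6),
    ("85A", "RIP2"): (40, 6),
}


def fetch(acc: str) -> SeqIO.SeqRecord:
    with Entrez.efetch(
        db="nucleotide", id=acc, rettype="gb", retmode="text"
    ) as handle:
        return SeqIO.read(handle, "genbank")


def cds_intervals(record) -> tuple[tuple[int, int], ...]:
    for feat in record.features:
        if feat.type == "CDS":
            return tuple(
                (int(p.start), int(p.end)) for p in feat.location.parts
            )
    return ()


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="octadkit@example.org")
    args = parser.parse_args()
    Entrez.email = args.email

    records = {name: fetch(acc) for name, acc in ACCESSIONS.items()}
    anc = records["85A"]
    exons = cds_intervals(anc)
    failures = 0

    for name in ("RIP1", "RIP2", "RIP3C", "RIP3T"):
        pair = align_pair(str(anc.seq), str(records[name].seq))
        if "-" not in pair.ancestral and exons:
            pair = SequencePair(pair.ancestral, pair.derived, exons=exons)
        rep = classify_substitutions(pair)
        print(
            f"85A vs {name}: {rep.n_total} differences "
            f"({rep.n_intronic} intronic, {rep.n_exonic} exonic; "
            f"{rep.n_codons_affected} codons affected), "
            f"polarity {rep.polarity}, rip_fraction {rep.rip_fraction:.2f}"
        )
        if rep.codon_effects:
            print("  effects:", ", ".join(rep.codon_effects))
        expected = EXPECTED.get(("85A", name))
        if expected and (rep.n_total, rep.n_intronic) != expected:
            print(f"  MISMATCH: expected {expected}")
            failures += 1
        if name == "RIP1" and rep.codon_effects and "Q122*" not in rep.codon_effects:
            print("  MISMATCH: expected the Q122* nonsense change")
            failures += 1

    return 1 if failures else 0


if __name__ == "__main__":
    sys.exit(main())
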