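"""In-silico breakpoint-junction PCR and toy junction-bearing genomes.

The presence/absence logic of junction-specific PCR is modeled as
substring detection: a junction is "amplified" iff its unique junction
motif occurs in any of the supplied sequences.  This is deliberately not a
thermodynamic primer model — presence/absence of the breakpoint junction
is all the genotyping procedure uses.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np

from .rearrangements import (
    NucleusState,
    RearrangementError,
    RearrangementSpec,
    junctions_present,
)

_ALPHABET = np.array(list("ACGT"))


class PCRConfigError(ValueError):
    pass


def simulate_junction_pcr(
    sequences: Iterable[str] | None = None,
    junction_motifs: Mapping[str, str] | None = None,
    nuclei: Sequence[NucleusState] | None = None,
    rearrangement: RearrangementSpec | None = None,
) -> frozenset[str]:
    """Junction classes detected in a DNA sample.

    Sequence mode: a junction is detected iff its motif occurs as a
    substring of any sequence; motifs must be unique and non-overlapping
    (no motif contained in another).  Model mode (``nuclei`` given, no
    sequences): falls back to the junction classes carried by the nuclei.
    """
    if sequences is None:
        if nuclei is None:
            raise PCRConfigError("provide sequences or nuclei")
        return junctions_present(nuclei, rearrangement)
    if not junction_motifs:
        raise PCRConfigError("sequence mode requires junction motifs")
    motifs = {k: v.upper() for k, v in junction_motifs.items()}
    vals = list(motifs.values())
    if len(set(vals)) != len(vals):
        raise PCRConfigError("duplicate junction motifs")
    for i, a in enumerate(vals):
        for b in vals[i + 1 :]:
            if a in b or b in a:
                raise PCRConfigError("overlapping junction motifs")
    pool = [s.upper() for s in sequences]
    return frozenset(
        j for j, m in motifs.items() if any(m in s for s in pool)
    )


def random_motifs(
    junctions: Iterable[str], rng: np.random.Generator, length: int = 24
) -> dict[str, str]:
    """Distinct random junction motifs of the given length."""
    out: dict[str, str] = {}
    seen: set[str] = set()
    for j in junctions:
        while True:
            m = "".join(rng.choice(_ALPHABET, size=length))
            if m not in seen and not any(m in s or s in m for s in seen):
                seen.add(m)
                out[j] = m
                break
    return out


def make_toy_genomes(
    spec: RearrangementSpec,
    rng: np.random.Generator,
    segment_length: int = 120,
    flank_length: int = 60,
    motif_length: int = 24,
) -> tuple[dict[str, dict[str, str]], dict[str, str]]:
    """Toy two-chromosome genomes for each segmental genotype.

    Builds a random translocated segment and chromosome flanks, embeds the
    junction motifs at the rearranged breakpoints, and assembles the donor
    and recipient chromosome of every genotype (T, N, Dp, Df for IT/QT).
    Returns ``(genomes, motifs)`` where ``genomes[genotype]`` maps
    ``"donor"``/``"recipient"`` to a sequence.  Junction PCR on a genotype's
    sequences reproduces the model-level junction logic, e.g. the pooled
    Dp + Df sequences light up the same junction set as T + N.
    """
    def rand(n: int) -> str:
        return "".join(rng.choice(_ALPHABET, size=n))

    motifs = random_motifs(sorted(spec.junction_classes), rng, motif_length)
    segment = rand(segment_length)
    d5, d3 = rand(flank_length), rand(flank_length)  # donor flanks
    r5, r3 = rand(flank_length), rand(flank_length)  # recipient flanks

    mA = motifs["A"]
    mB = motifs.get("B", "")
    mC = motifs.get("C", "")
    # donor: N-form keeps the segment in place; T-form deleted it, creating
    # junction A.  recipient: T-form carries the inserted segment flanked by
    # junctions B (and C for an IT); N-form is plain.
    genomes = {
        "T": {"donor": d5 + mA + d3, "recipient": r5 + mB + segment + mC + r3},
        "N": {"donor": d5 + segment + d3, "recipient": r5 + r3},
        "Dp": {"donor": d5 + segment + d3, "recipient": r5 + mB + segment + mC + r3},
        "Df": {"donor": d5 + mA + d3, "recipient": r5 + r3},
    }
    return genomes, motifs
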