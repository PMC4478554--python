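"""Repeat-induced point mutation (RIP): simulation and detection.

RIP is a premeiotic, sexual-stage process of Neurospora that riddles
duplicated DNA with G:C -> A:T transition mutations.  Mechanistically every
RIP mutation is a C -> T deamination on one strand; read on a fixed (top)
strand, a copy mutated on the top strand shows C>T changes and a copy
mutated on the bottom strand shows G>A changes.  In a single round of RIP
on a two-copy duplication the copies typically adopt opposite polarity —
one all G>A, the other all C>T on the sequenced strand.

The detector compares an ancestral allele with a derived (possibly RIP'd)
allele, classifies every substitution, splits events into exon and intron,
reports the strand polarity and annotates the codon-level consequences of
exonic changes in the conventional ``H22Y`` / ``Q122*`` / ``N97N`` style.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

TRANSITIONS = {("G", "A"), ("C", "T"), ("A", "G"), ("T", "C")}
RIP_CLASSES = ("G>A", "C>T")
BASES = set("ACGT")


class RipError(ValueError):
    pass


@dataclass
class SequencePair:
    """An aligned ancestral/derived allele pair.

    Sequences must have equal length (pre-aligned, upper/lower case
    insensitive).  ``exons`` are 0-based half-open intervals on the
    ancestral coordinate system (BED convention); the CDS is their
    concatenation in order, read on ``strand``.  Residue numbers in codon
    effect strings are 1-based on the translated CDS.
    """

    ancestral: str
    derived: str
    exons: tuple[tuple[int, int], ...] = ()
    strand: str = "+"

    def __post_init__(self) -> None:
        self.ancestral = self.ancestral.upper()
        self.derived = self.derived.upper()
        if len(self.ancestral) != len(self.derived):
            raise RipError(
                "sequences differ in length: alignment required "
                f"({len(self.ancestral)} vs {len(self.derived)})"
            )
        if self.strand not in ("+", "-"):
            raise RipError("strand must be '+' or '-'")
        exons = tuple(tuple(iv) for iv in self.exons)
        last = 0
        for s, e in exons:
            if not 0 <= s < e <= len(self.ancestral):
                raise RipError(f"exon ({s}, {e}) out of bounds")
            if s < last:
                raise RipError("exons must be sorted and non-overlapping")
            last = e
        self.exons = exons

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def cds(self, which: str = "ancestral") -> str:
        seq = self.ancestral if which == "ancestral" else self.derived
        cds = "".join(seq[s:e] for s, e in self.exons)
        if self.strand == "-":
            cds = str(Seq(cds).reverse_complement())
        return cds


@dataclass(frozen=True)
class SubstitutionEvent:
    position: int  # 1-based on the aligned pair
    ancestral: str
    derived: str
    klass: str  # "G>A" | "C>T" | "other-transition" | "transversion"
    region: str  # "exon" | "intron"


@dataclass
class SubstitutionReport:
    """Classified differences between an ancestral and a derived allele."""

    events: list[SubstitutionEvent]
    polarity: str  # "G>A" | "C>T" | "mixed" | "none"
    codon_effects: list[str] = field(default_factory=list)
    n_codons_affected: int = 0

    @property
    def n_total(self) -> int:
        return len(self.events)

    @property
    def n_exonic(self) -> int:
        return sum(e.region == "exon" for e in self.events)

    @property
    def n_intronic(self) -> int:
        return sum(e.region == "intron" for e in self.events)

    @property
    def n_rip(self) -> int:
        return sum(e.klass in RIP_CLASSES for e in self.events)

    @property
    def rip_fraction(self) -> float:
        """Share of events in the RIP classes (G>A, C>T on the top strand).

        Transitions at G:C pairs in the non-RIP direction (A>G, T>C) are
        excluded.  0.0 when there are no events.
        """
        if not self.events:
            return 0.0
        return self.n_rip / self.n_total


def _classify(anc: str, der: str) -> str:
    if (anc, der) == ("G", "A"):
        return "G>A"
    if (anc, der) == ("C", "T"):
        return "C>T"
    if (anc, der) in TRANSITIONS:
        return "other-transition"
    return "transversion"


def classify_substitutions(
    pair: SequencePair, annotate_codons: bool = True
) -> SubstitutionReport:
    """Classify every substitution between the aligned alleles.

    Aligned columns where either sequence has a non-ACGT character
    (gaps, ambiguity codes) are skipped.  Codon effects are filled in when
    exon annotation is present and the CDS is translatable; pass
    ``annotate_codons=False`` to suppress.
    """
    events: list[SubstitutionEvent] = []
    for i, (a, d) in enumerate(zip(pair.ancestral, pair.derived)):
        if a == d or a not in BASES or d not in BASES:
            continue
        events.append(
            SubstitutionEvent(
                position=i + 1,
                ancestral=a,
                derived=d,
                klass=_classify(a, d),
                region="exon" if pair.in_exon(i) else "intron",
            )
        )
    rip_classes = {e.klass for e in events if e.klass in RIP_CLASSES}
    if not rip_classes:
        polarity = "none"
    elif rip_classes == {"G>A"}:
        polarity = "G>A"
    elif rip_classes == {"C>T"}:
        polarity = "C>T"
    else:
        polarity = "mixed"
    report = SubstitutionReport(events=events, polarity=polarity)
    if annotate_codons and pair.exons and len(pair.cds()) % 3 == 0:
        report.codon_effects = annotate_codon_effects(pair)
        report.n_codons_affected = len(report.codon_effects)
    return report


def annotate_codon_effects(pair: SequencePair) -> list[str]:
    """Codon-level consequences of the exonic differences.

    One effect string per affected codon, in the conventional style:
    ``H22Y`` (missense), ``Q122*`` (nonsense), ``N97N`` (synonymous);
    residues are numbered 1-based on the translated CDS and the derived
    codon is translated with *all* of its changes applied.
    """
    if not pair.exons:
        raise RipError("codon annotation requires exon intervals")
    cds_anc = pair.cds("ancestral")
    cds_der = pair.cds("derived")
    if len(cds_anc) % 3 != 0:
        raise RipError(f"CDS length {len(cds_anc)} is not divisible by 3")
    effects = []
    for k in range(0, len(cds_anc), 3):
        ca, cd = cds_anc[k : k + 3], cds_der[k : k + 3]
        if ca == cd:
            continue
        if not (set(ca) <= BASES and set(cd) <= BASES):
            continue
        aa_a = str(Seq(ca).translate())
        aa_d = str(Seq(cd).translate())
        effects.append(f"{aa_a}{k // 3 + 1}{aa_d}")
    return effects


@dataclass
class RipParams:
    """Parameters of one simulated round of RIP on a duplication.

    rate : per-eligible-site mutation probability in [0, 1].
    polarity_per_copy : map copy index (0, 1) -> "C>T" or "G>A" (the
        mutation class seen on the top strand); by default the two copies
        receive opposite polarity.
    duplicated_region : 0-based half-open interval actually duplicated;
        sites outside it are never touched (default: whole sequence).
    context_weights : optional map dinucleotide (mutable base + next base,
        on the strand being mutated) -> relative weight multiplying
        ``rate``; RIP's CpA preference can be expressed here, off by
        default.
    """

    rate: float
    polarity_per_copy: dict[int, str] | None = None
    duplicated_region: tuple[int, int] | None = None
    context_weights: dict[str, float] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise RipError(f"rate must be in [0, 1], got {self.rate}")
        if self.polarity_per_copy is not None:
            for v in self.polarity_per_copy.values():
                if v not in RIP_CLASSES:
                    raise RipError(f"polarity must be 'G>A' or 'C>T', got {v!r}")


def _site_rate(
    seq: str, i: int, base: str, rate: float, weights: dict[str, float] | None,
    polarity: str,
) -> float:
    if weights is None:
        return rate
    # context is read on the strand being deaminated: for top-strand C>T the
    # top-strand dinucleotide starting at i; for G>A the bottom strand
    if polarity == "C>T":
        dinuc = seq[i : i + 2]
    else:
        upstream = seq[max(i - 1, 0) : i + 1]
        dinuc = str(Seq(upstream).reverse_complement())
    return rate * weights.get(dinuc, 1.0)


def rip_mutate(
    sequence: str,
    params: RipParams,
    rng: np.random.Generator | None = None,
    copy_count: int = 2,
) -> list[str]:
    """Apply one round of RIP to the two copies of a duplication.

    Returns ``copy_count`` mutated copies of ``sequence``.  For a copy with
    top-strand C>T polarity every C in the duplicated region mutates to T
    with probability ``rate``; for G>A polarity every G does (equivalent to
    C>T on the bottom strand).  By default copy 0 takes C>T and copy 1 takes
    G>A, modeling the observed opposite polarity of the two duplicate
    copies after a single round.
    """
    if copy_count != 2:
        raise RipError("a single RIP round acts on a two-copy duplication")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    sequence = sequence.upper()
    polarity = params.polarity_per_copy or {0: "C>T", 1: "G>A"}
    lo, hi = params.duplicated_region or (0, len(sequence))
    copies = []
    for c in range(copy_count):
        pol = polarity.get(c, "C>T" if c == 0 else "G>A")
        target = "C" if pol == "C>T" else "G"
        mutant = "T" if pol == "C>T" else "A"
        chars = list(sequence)
        for i in range(lo, hi):
            if chars[i] == target:
                p = _site_rate(sequence, i, target, params.rate,
                               params.context_weights, pol)
                if rng.random() < p:
                    chars[i] = mutant
        copies.append("".join(chars))
    return copies


def align_pair(ancestral: str, derived: str) -> SequencePair:
    """Convenience global alignment of two co-linear alleles.

    Uses a simple global aligner (match 2, mismatch -1, gap open -5,
    extend -1) and returns the gapped pair.  Bit-exact substitution counts
    are only guaranteed on pre-aligned input; this helper is for nearly
    identical alleles such as RIP'd copies of one gene.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    aln = aligner.align(ancestral.upper(), derived.upper())[0]
    return SequencePair(ancestral=str(aln[0]), derived=str(aln[1]))
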