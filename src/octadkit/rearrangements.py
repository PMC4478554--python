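"""Core data model for chromosome translocations and nuclear genotypes.

A translocation rearranges material between a *donor* and a *recipient*
chromosome.  Three elementary kinds are modeled:

``IT``
    insertional translocation — a segment of the donor chromosome is
    inserted into the recipient without reciprocal exchange.  Three
    breakpoint junctions define an IT: junction A at the deletion site on
    the donor, junctions B and C flanking the insertion on the recipient.
``QT``
    quasiterminal translocation — a distal donor segment is grafted onto
    the recipient tip; two junctions (A on the donor, B on the recipient).
``RT``
    reciprocal translocation — two chromosomes exchange terminal segments;
    two junctions (A, B), and two translocated segments.

Meiotic products of a translocation-heterozygous cross carry one donor-type
and one recipient-type chromosome each; the combination determines the
*segmental genotype*: ``T`` (translocation), ``N`` (normal sequence), ``Dp``
(segment duplicated, copy number 2) or ``Df`` (segment deficient, copy
number 0).  For an RT the genotype is a per-segment composite such as
``Dp1/Df2``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence


class Kind(str, Enum):
    """Elementary translocation kinds."""

    IT = "IT"
    QT = "QT"
    RT = "RT"


#: Junction classes defined by each kind.
KIND_JUNCTIONS: dict[Kind, frozenset[str]] = {
    Kind.IT: frozenset({"A", "B", "C"}),
    Kind.QT: frozenset({"A", "B"}),
    Kind.RT: frozenset({"A", "B"}),
}


class RearrangementError(ValueError):
    """Raised for inconsistent rearrangement specifications or variants."""


@dataclass(frozen=True)
class ChromosomeVariant:
    """One homolog of a chromosome involved in a rearrangement.

    ``translocated`` distinguishes the rearranged form (T-form) from the
    normal-sequence homolog (N-form).  ``carried_segments`` lists the
    translocated-segment ids physically present on this variant and
    ``junctions`` the breakpoint junction classes it carries.
    """

    rearrangement_id: str
    chrom: str
    role: str  # "donor" | "recipient"
    translocated: bool
    carried_segments: tuple[str, ...]
    junctions: frozenset[str]

    def __post_init__(self) -> None:
        if self.role not in ("donor", "recipient"):
            raise RearrangementError(f"invalid role {self.role!r}")


@dataclass(frozen=True)
class RearrangementSpec:
    """Definition of a translocation.

    ``c_donor`` / ``c_recipient`` are the default probabilities of an
    interstitial crossover (between centromere and breakpoint) on the donor
    and recipient chromosome in a heterozygous meiosis.

    ``assayable_junctions`` records which junction classes have working
    junction-specific PCR primers; it defaults to the full class set of the
    kind and only affects genotype *inference* from PCR patterns, never the
    segregation model itself.
    """

    id: str
    kind: Kind
    donor_chrom: str
    recipient_chrom: str
    segment_ids: tuple[str, ...]
    c_donor: float = 0.0
    c_recipient: float = 0.0
    assayable_junctions: frozenset[str] | None = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        kind = Kind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "segment_ids", tuple(self.segment_ids))
        n_expected = 2 if kind is Kind.RT else 1
        if len(self.segment_ids) != n_expected:
            raise RearrangementError(
                f"{kind.value} requires {n_expected} segment id(s), "
                f"got {self.segment_ids!r}"
            )
        for c, name in ((self.c_donor, "c_donor"), (self.c_recipient, "c_recipient")):
            if not 0.0 <= c <= 1.0:
                raise RearrangementError(f"{name} must be in [0, 1], got {c}")
        if self.assayable_junctions is None:
            object.__setattr__(self, "assayable_junctions", self.junction_classes)
        else:
            aj = frozenset(self.assayable_junctions)
            if not aj <= self.junction_classes:
                raise RearrangementError(
                    f"assayable junctions {sorted(aj)} not a subset of "
                    f"{sorted(self.junction_classes)}"
                )
            object.__setattr__(self, "assayable_junctions", aj)

    @property
    def junction_classes(self) -> frozenset[str]:
        return KIND_JUNCTIONS[Kind(self.kind)]

    # -- variant construction -------------------------------------------------

    def donor_variant(self, translocated: bool) -> ChromosomeVariant:
        """The donor-chromosome homolog (T-form or N-form)."""
        if self.kind is Kind.RT:
            s1, s2 = self.segment_ids
            segs = (s2,) if translocated else (s1,)
            junc = frozenset({"A"}) if translocated else frozenset()
        else:
            # IT/QT donor T-form lost its segment and carries junction A;
            # the N-form carries the segment in its native position.
            (s,) = self.segment_ids
            segs = () if translocated else (s,)
            junc = frozenset({"A"}) if translocated else frozenset()
        return ChromosomeVariant(
            self.id, self.donor_chrom, "donor", translocated, segs, junc
        )

    def recipient_variant(self, translocated: bool) -> ChromosomeVariant:
        """The recipient-chromosome homolog (T-form or N-form)."""
        if self.kind is Kind.RT:
            s1, s2 = self.segment_ids
            segs = (s1,) if translocated else (s2,)
            junc = frozenset({"B"}) if translocated else frozenset()
        else:
            (s,) = self.segment_ids
            segs = (s,) if translocated else ()
            if translocated:
                junc = frozenset({"B", "C"}) if self.kind is Kind.IT else frozenset({"B"})
            else:
                junc = frozenset()
        return ChromosomeVariant(
            self.id, self.recipient_chrom, "recipient", translocated, segs, junc
        )

    # -- (de)serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "kind": Kind(self.kind).value,
            "donor_chrom": self.donor_chrom,
            "recipient_chrom": self.recipient_chrom,
            "segment_ids": list(self.segment_ids),
            "c_donor": self.c_donor,
            "c_recipient": self.c_recipient,
            "assayable_junctions": sorted(self.assayable_junctions or ()),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RearrangementSpec":
        return cls(
            id=d["id"],
            kind=Kind(d["kind"]),
            donor_chrom=d["donor_chrom"],
            recipient_chrom=d["recipient_chrom"],
            segment_ids=tuple(d["segment_ids"]),
            c_donor=d.get("c_donor", 0.0),
            c_recipient=d.get("c_recipient", 0.0),
            assayable_junctions=(
                frozenset(d["assayable_junctions"])
                if d.get("assayable_junctions")
                else None
            ),
            metadata=d.get("metadata", {}),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RearrangementSpec":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class SegmentalGenotype:
    """Per-segment T/N/Dp/Df labels of one nucleus for one rearrangement."""

    per_segment: tuple[tuple[str, str], ...]  # (segment id, label)

    @property
    def label(self) -> str:
        labels = [lab for _, lab in self.per_segment]
        if len(set(labels)) == 1:
            return labels[0]
        # RT composite such as Dp1/Df2 (Dp listed first, as conventional)
        parts = [
            f"{lab}{i + 1}" for i, (_, lab) in enumerate(self.per_segment)
        ]
        parts.sort(key=lambda p: (not p.startswith("Dp"), p))
        return "/".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def segmental_genotype(
    donor: ChromosomeVariant,
    recipient: ChromosomeVariant,
    spec: RearrangementSpec,
) -> SegmentalGenotype:
    """Classify a (donor, recipient) variant pair as T, N, Dp or Df.

    The label follows from segment copy number over the two variants:
    2 copies → Dp, 0 → Df; a single copy is T when both variants are the
    translocated forms, N when both are normal-sequence.
    """
    for v in (donor, recipient):
        if v.rearrangement_id != spec.id:
            raise RearrangementError(
                f"variant belongs to {v.rearrangement_id!r}, not {spec.id!r}"
            )
    if donor.role != "donor" or recipient.role != "recipient":
        raise RearrangementError("expected a (donor, recipient) variant pair")
    carried = list(donor.carried_segments) + list(recipient.carried_segments)
    out = []
    for seg in spec.segment_ids:
        copies = carried.count(seg)
        if copies == 2:
            lab = "Dp"
        elif copies == 0:
            lab = "Df"
        elif donor.translocated and recipient.translocated:
            lab = "T"
        elif not donor.translocated and not recipient.translocated:
            lab = "N"
        else:  # pragma: no cover - unreachable for well-formed variants
            raise RearrangementError("inconsistent variant pair")
        out.append((seg, lab))
    return SegmentalGenotype(tuple(out))


@dataclass
class NucleusState:
    """One haploid nucleus: mating type, chromosome variants and markers.

    ``division_fitness`` is the relative nuclear division rate of this
    nucleus in a heterokaryon (1.0 = wild type, 0 = unable to divide).
    """

    mat: str  # "A" | "a"
    variants: dict[str, tuple[ChromosomeVariant, ChromosomeVariant]] = field(
        default_factory=dict
    )
    markers: dict[str, str] = field(default_factory=dict)
    division_fitness: float = 1.0

    def __post_init__(self) -> None:
        if self.mat not in ("A", "a"):
            raise RearrangementError(f"mating type must be 'A' or 'a', got {self.mat!r}")
        if self.division_fitness < 0:
            raise RearrangementError("division_fitness must be non-negative")

    def genotype(self, spec: RearrangementSpec) -> SegmentalGenotype:
        donor, recipient = self.variants[spec.id]
        return segmental_genotype(donor, recipient, spec)

    def genotype_label(self, spec: RearrangementSpec) -> str:
        return self.genotype(spec).label

    def junctions(self, rearrangement_id: str | None = None) -> frozenset[str]:
        """Junction classes physically present in this nucleus."""
        out: set[str] = set()
        for rid, (dv, rv) in self.variants.items():
            if rearrangement_id is not None and rid != rearrangement_id:
                continue
            out |= dv.junctions | rv.junctions
        return frozenset(out)

    def segment_copies(self, spec: RearrangementSpec) -> dict[str, int]:
        """Copy number of each translocated segment in this nucleus."""
        dv, rv = self.variants[spec.id]
        carried = list(dv.carried_segments) + list(rv.carried_segments)
        return {seg: carried.count(seg) for seg in spec.segment_ids}


# genotype label -> (donor translocated?, recipient translocated?)
_LABEL_TO_FORMS = {
    "T": (True, True),
    "N": (False, False),
    "Dp": (False, True),
    "Df": (True, False),
    # RT composites: Dp1/Df2 pairs the normal donor with the translocated
    # recipient (segment 1 duplicated), and vice versa.
    "Dp1/Df2": (False, True),
    "Dp2/Df1": (True, False),
}


def nucleus(
    spec: RearrangementSpec,
    genotype: str,
    mat: str,
    markers: dict[str, str] | None = None,
    division_fitness: float = 1.0,
) -> NucleusState:
    """Construct a nucleus of the named segmental genotype.

    ``genotype`` is one of T, N, Dp, Df (IT/QT) or T, N, Dp1/Df2, Dp2/Df1
    (RT).
    """
    try:
        donor_t, recip_t = _LABEL_TO_FORMS[genotype]
    except KeyError:
        raise RearrangementError(f"unknown genotype label {genotype!r}") from None
    if spec.kind is Kind.RT and genotype in ("Dp", "Df"):
        raise RearrangementError(
            "RT genotypes are per-segment composites (Dp1/Df2, Dp2/Df1)"
        )
    ns = NucleusState(
        mat=mat,
        variants={
            spec.id: (spec.donor_variant(donor_t), spec.recipient_variant(recip_t))
        },
        markers=dict(markers or {}),
        division_fitness=division_fitness,
    )
    return ns


def junctions_present(
    nuclei: Sequence[NucleusState], rearrangement: RearrangementSpec | None = None
) -> frozenset[str]:
    """Union of junction classes over a set of nuclei.

    This is what junction PCR on pooled DNA of the nuclei would report; a
    [T + N] pair and a [Dp + Df] pair give the identical set, which is the
    central ambiguity the genotype classifier has to resolve.
    """
    if not nuclei:
        raise RearrangementError("empty nucleus list")
    rid = rearrangement.id if rearrangement is not None else None
    out: set[str] = set()
    for n in nuclei:
        out |= n.junctions(rid)
    return frozenset(out)


def spore_viability(
    nuclei: Sequence[NucleusState],
    rearrangements: Iterable[RearrangementSpec],
    rule: str = "union",
) -> bool:
    """Is an ascospore containing these nuclei viable (black)?

    ``union`` (default): viable iff, for every rearrangement, the union of
    carried segments over all nuclei in the spore covers every translocated
    segment — complementation between nuclei of one spore is allowed, so a
    binucleate [Dp + Df] spore is viable.

    ``autonomous``: every nucleus must individually carry a full segment
    complement; [Dp1/Df2 + Dp2/Df1] spores are then inviable.
    """
    if not nuclei:
        raise RearrangementError("empty spore")
    if rule not in ("union", "autonomous"):
        raise RearrangementError(f"unknown viability rule {rule!r}")
    groups: list[Sequence[NucleusState]]
    if rule == "union":
        groups = [nuclei]
    else:
        groups = [[n] for n in nuclei]
    for spec in rearrangements:
        for grp in groups:
            covered: set[str] = set()
            for n in grp:
                if spec.id in n.variants:
                    dv, rv = n.variants[spec.id]
                    covered.update(dv.carried_segments)
                    covered.update(rv.carried_segments)
                else:
                    # nucleus not modeled for this rearrangement: assume a
                    # normal-sequence full complement
                    covered.update(spec.segment_ids)
            if not set(spec.segment_ids) <= covered:
                return False
    return True


# ---------------------------------------------------------------------------
# Built-in presets: the four translocations introgressed in the study this
# package models.  Sizes and gene counts are metadata only.
# ---------------------------------------------------------------------------

def _presets() -> dict[str, RearrangementSpec]:
    return {
        "EB4": RearrangementSpec(
            id="EB4",
            kind=Kind.IT,
            donor_chrom="VR",
            recipient_chrom="VII",
            segment_ids=("EB4-seg",),
            metadata={"size_bp": 145282, "n_genes": 39, "duplicated_loci": ["ad-7"]},
        ),
        "IBj5": RearrangementSpec(
            id="IBj5",
            kind=Kind.IT,
            donor_chrom="VIL",
            recipient_chrom="IR",
            segment_ids=("IBj5-seg",),
            assayable_junctions=frozenset({"A", "B"}),
            metadata={
                "size_bp": 405319,
                "n_genes": 120,
                "note": "possibly a complex rearrangement with a linked RT; "
                "modeled as a plain IT by default",
            },
        ),
        "UK14-1": RearrangementSpec(
            id="UK14-1",
            kind=Kind.QT,
            donor_chrom="VIR",
            recipient_chrom="VL",
            segment_ids=("UK14-1-seg",),
            assayable_junctions=frozenset({"A"}),
            metadata={"size_bp": 490958, "n_genes": 126},
        ),
        "B362i": RearrangementSpec(
            id="B362i",
            kind=Kind.IT,
            donor_chrom="IVR",
            recipient_chrom="IL",
            segment_ids=("B362i-seg",),
            metadata={"size_bp": 118782, "n_genes": 36},
        ),
    }


PRESETS: dict[str, RearrangementSpec] = _presets()


def get_preset(name: str) -> RearrangementSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise RearrangementError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def example_rt(rid: str = "RTx") -> RearrangementSpec:
    """A generic reciprocal translocation for simulations.

    None of the four built-in presets is an RT, but RT x N crosses (0B:8W
    under adjacent-1 segregation) are part of the model.
    """
    return RearrangementSpec(
        id=rid,
        kind=Kind.RT,
        donor_chrom="I",
        recipient_chrom="II",
        segment_ids=(f"{rid}-seg1", f"{rid}-seg2"),
    )
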