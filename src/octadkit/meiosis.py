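"""Forward simulation of a single Neurospora cross.

The model is chromatid-level.  Karyogamy brings together, for each
rearrangement, a donor homolog pair and a recipient homolog pair.  Each
homolog replicates into two sister chromatids; with probability ``c_donor``
(resp. ``c_recipient``) one interstitial crossover exchanges the
breakpoint-distal portion between one chromatid of each homolog, which at
this level of abstraction swaps the chromatids' full variant content while
leaving their centromere identity in place.  Meiosis I then assigns
centromeres to the two spindle poles — in a translocation heterozygote the
quadrivalent disjoins by the *alternate* pattern (both translocated
centromeres to one pole) with probability ``p_alt``, else *adjacent-1*
(donor-T with recipient-N) — meiosis II separates sisters, and the
postmeiotic mitosis duplicates each product into two adjacent octet
positions.

The mating-type locus always shows first-division segregation (the
mating-type chromosome of N. tetrasperma carries a recombination block, and
mat is tightly centromere-linked in N. crassa), so every octet has four
mat A and four mat a nuclei, and positions 1-4 descend from pole 1.

Ascospore packaging is species-specific: N. crassa partitions the eight
nuclei into eight uninucleate spores; N. tetrasperma packages four
binucleate spores, each receiving a pair of nonsister nuclei (one mat A +
one mat a), optionally with spore replacement (a dikaryotic spore replaced
by two smaller homokaryotic ones, giving 5-8-spored asci) and rare
three-nucleus packaging anomalies.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .rearrangements import (
    ChromosomeVariant,
    NucleusState,
    RearrangementError,
    RearrangementSpec,
    spore_viability,
)


class CrossError(ValueError):
    """Raised when a cross is not possible (e.g. same mating type)."""


@dataclass
class CrossParams:
    """Parameters of one simulated cross.

    p_alt : probability of alternate segregation in a translocation
        heterozygote (both segregation patterns are equally likely in a
        normal meiosis, hence the 0.5 default; set to 1.0 or 0.0 to force a
        pattern).
    c_donor, c_recipient : interstitial crossover probabilities; ``None``
        means "use the rearrangement's own defaults".
    species : "crassa" (8 uninucleate spores) or "tetrasperma"
        (4 binucleate spores).
    replacement_prob : per-spore probability that a dikaryotic
        N. tetrasperma spore is replaced by two homokaryotic ones.  The
        dominant Eight-spore (E) mutant is modeled purely as an elevated
        replacement probability with incomplete penetrance.
    anomaly_prob : per-ascus probability that one spore receives a third
        nucleus donated by an adjacent spore.
    msud_strength : scalar in [0, 1]; strength of meiotic silencing by
        unpaired DNA in this cross background (1.0 = OR-type, lower for
        Esm/Sad suppressor backgrounds).  Consumed by the fertility rule in
        :mod:`octadkit.heterokaryon`, not by the octet simulation itself.
    viability_rule : "union" (complementation within a spore allowed) or
        "autonomous".
    random_pairing : if True, the nonsister pairing of pole-1 with pole-2
        nuclei into binucleate spores is randomized instead of j-th with
        j-th; either way each spore gets one mat A + one mat a nucleus.
    fitness_fn : optional callable assigning division_fitness to each
        product nucleus (default: 1.0 everywhere).
    """

    p_alt: float = 0.5
    c_donor: float | None = None
    c_recipient: float | None = None
    species: str = "crassa"
    replacement_prob: float = 0.0
    anomaly_prob: float = 0.0
    msud_strength: float = 1.0
    viability_rule: str = "union"
    random_pairing: bool = False
    fitness_fn: Callable[[NucleusState], float] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("p_alt", "replacement_prob", "anomaly_prob", "msud_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("c_donor", "c_recipient"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.species not in ("crassa", "tetrasperma"):
            raise ValueError(f"species must be 'crassa' or 'tetrasperma'")


#: replacement probability used for the Eight-spore (E) mutant preset; the
#: study gives no measured rate, so this is an arbitrary documented default.
E_MUTANT_REPLACEMENT_PROB = 0.15


@dataclass
class Octet:
    """Ordered 8-nucleus product of one meiosis + postmeiotic mitosis."""

    nuclei: list[NucleusState]
    rearrangements: tuple[RearrangementSpec, ...]
    pole_of: tuple[int, ...] = (1, 1, 1, 1, 2, 2, 2, 2)
    sister_pairs: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7))

    def genotype_counts(self, spec: RearrangementSpec | None = None) -> Counter:
        spec = spec or self.rearrangements[0]
        return Counter(n.genotype_label(spec) for n in self.nuclei)

    def mat_counts(self) -> Counter:
        return Counter(n.mat for n in self.nuclei)


@dataclass
class Spore:
    """An ascospore with 1-3 nuclei and a viability (black/white) call."""

    nuclei: list[NucleusState]
    viable: bool

    def __post_init__(self) -> None:
        if not 1 <= len(self.nuclei) <= 3:
            raise RearrangementError(
                f"a spore holds 1-3 nuclei, got {len(self.nuclei)}"
            )


@dataclass
class Ascus:
    """A packaged ascus; total nuclei over spores is always 8."""

    spores: list[Spore]
    rearrangements: tuple[RearrangementSpec, ...]

    @property
    def n_nuclei(self) -> int:
        return sum(len(s.nuclei) for s in self.spores)

    @property
    def n_black(self) -> int:
        return sum(s.viable for s in self.spores)

    @property
    def n_white(self) -> int:
        return len(self.spores) - self.n_black

    @property
    def tally_class(self) -> str:
        """Row label in the style of the ascus-type tables.

        Eight-spored asci are classified by their black:white ratio
        ("8:0" ... "0:8"); asci with fewer spores (binucleate packaging)
        are classified by spore count ("4" ... "7").
        """
        if len(self.spores) == 8:
            return f"{self.n_black}:{self.n_white}"
        return str(len(self.spores))


@dataclass
class _Chromatid:
    centromere_translocated: bool
    content: ChromosomeVariant


def _resolve(params: CrossParams, spec: RearrangementSpec) -> tuple[float, float]:
    cd = params.c_donor if params.c_donor is not None else spec.c_donor
    cr = params.c_recipient if params.c_recipient is not None else spec.c_recipient
    return cd, cr


def simulate_meiosis_octet(
    parent1: NucleusState,
    parent2: NucleusState,
    rearrangements: Sequence[RearrangementSpec],
    params: CrossParams,
    rng: np.random.Generator,
) -> Octet:
    """Simulate karyogamy + meiosis of ``parent1 x parent2`` into an octet.

    Parents must be of opposite mating type and carry variants for every
    rearrangement in ``rearrangements``.
    """
    if parent1.mat == parent2.mat:
        raise CrossError(
            f"cross refused: both parents are mat {parent1.mat}"
        )
    rearrangements = tuple(rearrangements)

    # per pole, per rearrangement: (two donor chromatids, two recipient
    # chromatids)
    pole_chromatids: dict[int, dict[str, tuple[list, list]]] = {1: {}, 2: {}}

    for spec in rearrangements:
        try:
            d1, r1 = parent1.variants[spec.id]
            d2, r2 = parent2.variants[spec.id]
        except KeyError:
            raise CrossError(
                f"parent lacks variants for rearrangement {spec.id!r}"
            ) from None
        donor_h1 = [_Chromatid(d1.translocated, d1), _Chromatid(d1.translocated, d1)]
        donor_h2 = [_Chromatid(d2.translocated, d2), _Chromatid(d2.translocated, d2)]
        recip_h1 = [_Chromatid(r1.translocated, r1), _Chromatid(r1.translocated, r1)]
        recip_h2 = [_Chromatid(r2.translocated, r2), _Chromatid(r2.translocated, r2)]

        c_donor, c_recipient = _resolve(params, spec)
        # at most one interstitial crossover per region per meiosis, between
        # one randomly chosen chromatid of each homolog
        if rng.random() < c_donor:
            i, j = rng.integers(2), rng.integers(2)
            donor_h1[i].content, donor_h2[j].content = (
                donor_h2[j].content,
                donor_h1[i].content,
            )
        if rng.random() < c_recipient:
            i, j = rng.integers(2), rng.integers(2)
            recip_h1[i].content, recip_h2[j].content = (
                recip_h2[j].content,
                recip_h1[i].content,
            )

        donor_het = d1.translocated != d2.translocated
        recip_het = r1.translocated != r2.translocated
        if donor_het and recip_het:
            # quadrivalent: alternate sends both translocated centromeres to
            # the same pole, adjacent-1 sends donor-T with recipient-N
            alternate = rng.random() < params.p_alt
            t_pole = int(rng.integers(1, 3))
            o_pole = 3 - t_pole
            donor_t_h = donor_h1 if d1.translocated else donor_h2
            donor_n_h = donor_h2 if d1.translocated else donor_h1
            recip_t_h = recip_h1 if r1.translocated else recip_h2
            recip_n_h = recip_h2 if r1.translocated else recip_h1
            if alternate:
                assign = {
                    t_pole: (donor_t_h, recip_t_h),
                    o_pole: (donor_n_h, recip_n_h),
                }
            else:
                assign = {
                    t_pole: (donor_t_h, recip_n_h),
                    o_pole: (donor_n_h, recip_t_h),
                }
        else:
            # no quadrivalent; each homolog pair disjoins independently
            dp = int(rng.integers(1, 3))
            rp = int(rng.integers(1, 3))
            assign = {}
            assign[dp] = [donor_h1, None]
            assign[3 - dp] = [donor_h2, None]
            assign[rp][1] = recip_h1
            assign[3 - rp][1] = recip_h2
            assign = {p: tuple(v) for p, v in assign.items()}
        for pole in (1, 2):
            dh, rh = assign[pole]
            pole_chromatids[pole][spec.id] = (list(dh), list(rh))

    # first-division segregation of mat: one pole inherits parent1's allele
    p1_pole = int(rng.integers(1, 3))
    mat_of_pole = {p1_pole: parent1.mat, 3 - p1_pole: parent2.mat}

    # markers segregate at MI, one locus at a time (unlinked loci)
    loci = set(parent1.markers) | set(parent2.markers)
    marker_pole: dict[str, dict[int, str | None]] = {}
    for locus in loci:
        lp = int(rng.integers(1, 3))
        marker_pole[locus] = {
            lp: parent1.markers.get(locus),
            3 - lp: parent2.markers.get(locus),
        }

    nuclei: list[NucleusState] = []
    fitness_fn = params.fitness_fn or (lambda n: 1.0)
    for pole in (1, 2):
        # meiosis II: two nuclei per pole; for each chromosome pair the two
        # sister (or recombinant) chromatids are dealt one to each nucleus,
        # with random donor/recipient assortment
        products: list[dict[str, tuple[ChromosomeVariant, ChromosomeVariant]]] = [
            {},
            {},
        ]
        for spec in rearrangements:
            dh, rh = pole_chromatids[pole][spec.id]
            order_d = rng.permutation(2)
            order_r = rng.permutation(2)
            for k in range(2):
                products[k][spec.id] = (
                    dh[order_d[k]].content,
                    rh[order_r[k]].content,
                )
        markers = {
            locus: alleles[pole]
            for locus, alleles in marker_pole.items()
            if alleles[pole] is not None
        }
        for prod in products:
            # postmeiotic mitosis: duplicate into adjacent sister positions
            for _ in range(2):
                n = NucleusState(
                    mat=mat_of_pole[pole],
                    variants=dict(prod),
                    markers=dict(markers),
                )
                n.division_fitness = fitness_fn(n)
                nuclei.append(n)

    return Octet(nuclei=nuclei, rearrangements=rearrangements)


def package_ascospores(
    octet: Octet, params: CrossParams, rng: np.random.Generator
) -> Ascus:
    """Partition an octet into ascospores, species-specifically."""
    specs = octet.rearrangements
    rule = params.viability_rule

    def make_spore(nuc: list[NucleusState]) -> Spore:
        return Spore(nuc, viable=spore_viability(nuc, specs, rule=rule))

    if params.species == "crassa":
        spores = [make_spore([n]) for n in octet.nuclei]
        return Ascus(spores=spores, rearrangements=specs)

    # N. tetrasperma: pair the j-th nucleus of the pole-1 lineage with the
    # j-th (or a random) nucleus of the pole-2 lineage -> nonsister pairs,
    # one mat A + one mat a each
    pole1 = [i for i, p in enumerate(octet.pole_of) if p == 1]
    pole2 = [i for i, p in enumerate(octet.pole_of) if p == 2]
    if params.random_pairing:
        pole2 = [pole2[k] for k in rng.permutation(4)]
    spore_nuclei: list[list[NucleusState]] = [
        [octet.nuclei[i], octet.nuclei[j]] for i, j in zip(pole1, pole2)
    ]

    # spore replacement: a dikaryotic spore replaced by two homokaryotic ones
    replaced: list[list[NucleusState]] = []
    for nuc in spore_nuclei:
        if len(nuc) == 2 and rng.random() < params.replacement_prob:
            replaced.append([nuc[0]])
            replaced.append([nuc[1]])
        else:
            replaced.append(nuc)
    spore_nuclei = replaced

    # rare packaging anomaly: one spore receives a third nucleus donated by
    # an adjacent (dikaryotic) spore
    if rng.random() < params.anomaly_prob:
        candidates = [
            k
            for k in range(len(spore_nuclei) - 1)
            if len(spore_nuclei[k]) == 2 and len(spore_nuclei[k + 1]) == 2
        ]
        if candidates:
            k = int(rng.choice(candidates))
            donor_idx = int(rng.integers(2))
            spore_nuclei[k].append(spore_nuclei[k + 1].pop(donor_idx))

    return Ascus(
        spores=[make_spore(nuc) for nuc in spore_nuclei], rearrangements=specs
    )


def score_ascus(ascus: Ascus) -> tuple[int, int, str]:
    """Return (black spores, white spores, tally class label)."""
    return ascus.n_black, ascus.n_white, ascus.tally_class


#: canonical row order for tally tables
EIGHT_SPORE_CLASSES = ("8:0", "6:2", "4:4", "2:6", "0:8")
SPORE_COUNT_CLASSES = ("4", "5", "6", "7")


def simulate_cross_tally(
    parent1: NucleusState,
    parent2: NucleusState,
    rearrangements: Sequence[RearrangementSpec],
    n_asci: int,
    params: CrossParams,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate ``n_asci`` asci and tabulate ascus-type frequencies.

    Returns a DataFrame with columns ``class``, ``count`` and ``percent``
    (rows in canonical table order, zero-count canonical classes included).
    """
    if n_asci < 1:
        raise ValueError("n_asci must be >= 1")
    if rng is None or isinstance(rng, int):
        seed = params.rng_seed if rng is None else rng
        rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    for _ in range(n_asci):
        octet = simulate_meiosis_octet(parent1, parent2, rearrangements, params, rng)
        ascus = package_ascospores(octet, params, rng)
        counts[ascus.tally_class] += 1
    order = list(EIGHT_SPORE_CLASSES)
    if params.species == "tetrasperma":
        order = list(SPORE_COUNT_CLASSES) + order
    extra = sorted(set(counts) - set(order))
    classes = [c for c in order if c in counts or c in EIGHT_SPORE_CLASSES] + extra
    df = pd.DataFrame(
        {
            "class": classes,
            "count": [counts.get(c, 0) for c in classes],
        }
    )
    df["percent"] = 100.0 * df["count"] / n_asci
    df.attrs["n_asci"] = n_asci
    df.attrs["seed"] = params.rng_seed
    return df
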