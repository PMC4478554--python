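"""Vegetative phase of a pseudohomothallic heterokaryon.

Covers nuclear-ratio dynamics under unequal per-nucleus division fitness,
multinomial sampling of nuclei into conidia (vegetative spores),
phenotyping of conidial derivatives (self-fertile vs self-sterile, mating
type, junction-PCR pattern), the wiring of a self-cross (karyogamy partner
choice, which components are exposed to RIP) and the MSUD fertility rule.

The key biology: a [T + N] heterokaryon yields viable homokaryotic conidia
of both mating types, whereas a [Dp + Df] heterokaryon yields viable
homokaryons only of the Dp nucleus' mating type (a Df homokaryon lacks the
translocated segment and is inviable).  If the Df nucleus additionally has
division fitness 0 — the nucleus-limited-gene scenario — no self-fertile
conidial derivative can form at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .rearrangements import (
    NucleusState,
    RearrangementError,
    RearrangementSpec,
    junctions_present,
    spore_viability,
)


class HeterokaryonError(ValueError):
    pass


@dataclass
class Heterokaryon:
    """A mycelium with 1-3 genetically distinct nucleus types."""

    components: list[tuple[NucleusState, float]]

    def __post_init__(self) -> None:
        if not 1 <= len(self.components) <= 3:
            raise HeterokaryonError("a heterokaryon has 1-3 components")
        props = np.array([p for _, p in self.components], dtype=float)
        if (props < 0).any():
            raise HeterokaryonError("proportions must be non-negative")
        if not np.isclose(props.sum(), 1.0):
            raise HeterokaryonError(f"proportions must sum to 1, got {props.sum()}")

    @property
    def nuclei(self) -> list[NucleusState]:
        return [n for n, _ in self.components]

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for _, p in self.components], dtype=float)

    @property
    def fitness(self) -> np.ndarray:
        return np.array([n.division_fitness for n, _ in self.components], dtype=float)

    @property
    def is_self_fertile(self) -> bool:
        """Self-fertile iff both mating types occur among division-competent
        components."""
        mats = {n.mat for n, _ in self.components if n.division_fitness > 0}
        return mats == {"A", "a"}


def evolve_nuclear_ratio(
    initial: Sequence[float],
    fitness: Sequence[float],
    generations: int,
) -> np.ndarray:
    """Deterministic nuclear-ratio trajectory over mitotic generations.

    Each generation every component multiplies by its division fitness and
    the proportions are renormalised:
    ``rho_i' = rho_i * f_i / sum_j rho_j * f_j``.
    Returns an array of shape ``(generations + 1, k)`` whose rows sum to 1.
    """
    rho = np.asarray(initial, dtype=float)
    f = np.asarray(fitness, dtype=float)
    if rho.shape != f.shape:
        raise HeterokaryonError("initial and fitness must have the same length")
    if (rho < 0).any() or not np.isclose(rho.sum(), 1.0):
        raise HeterokaryonError("initial proportions must be non-negative, sum 1")
    if (f < 0).any():
        raise HeterokaryonError("fitness must be non-negative")
    traj = [rho.copy()]
    for _ in range(generations):
        w = rho * f
        tot = w.sum()
        if tot == 0:
            raise HeterokaryonError(
                "all present components have zero fitness; ratio undefined"
            )
        rho = w / tot
        traj.append(rho.copy())
    return np.array(traj)


@dataclass
class ConidialDerivative:
    """One germinated conidium from a heterokaryotic mycelium."""

    nuclei: tuple[int, ...]  # component indices, with multiplicity
    self_fertile: bool
    mat_phenotype: str  # "A" | "a" | "het"
    junction_pattern: frozenset[str]
    viable: bool = True


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    """Zero-truncated Poisson draw (rate ``mean``, k >= 1) by rejection."""
    while True:
        k = int(rng.poisson(mean))
        if k >= 1:
            return k


def sample_conidial_derivatives(
    het: Heterokaryon,
    n: int,
    rng: np.random.Generator,
    rearrangements: Iterable[RearrangementSpec] = (),
    mean_nuclei: float = 2.5,
    fixed_k: int | None = None,
    generations: int = 0,
) -> list[ConidialDerivative]:
    """Sample ``n`` conidia and phenotype the resulting derivatives.

    Each conidium draws ``k`` nuclei (``k`` from a zero-truncated Poisson
    with rate ``mean_nuclei`` unless ``fixed_k`` is given) multinomially
    from the current component proportions weighted by division fitness —
    a fitness-0 nucleus is neither packaged nor able to divide.  Proportions
    are first evolved for ``generations`` mitotic generations.

    A derivative is self-fertile iff both mating types occur among its
    division-competent nuclei; its mating-type phenotype and junction-PCR
    pattern are likewise read from the division-competent nuclei.  The
    ``viable`` flag marks conidia whose nuclei jointly cover all
    translocated segments (an uncomplemented Df conidium cannot grow).
    """
    if n < 1:
        raise HeterokaryonError("n must be >= 1")
    rho = het.proportions
    f = het.fitness
    if generations:
        rho = evolve_nuclear_ratio(rho, f, generations)[-1]
    w = rho * f
    if w.sum() == 0:
        raise HeterokaryonError("no division-competent nuclei to package")
    w = w / w.sum()
    specs = tuple(rearrangements)
    out = []
    k_indices = np.arange(len(het.components))
    for _ in range(n):
        k = fixed_k if fixed_k is not None else _truncated_poisson(rng, mean_nuclei)
        drawn = tuple(sorted(rng.choice(k_indices, size=k, p=w)))
        competent = [
            het.components[i][0]
            for i in set(drawn)
            if het.components[i][0].division_fitness > 0
        ]
        mats = {nuc.mat for nuc in competent}
        self_fertile = len(mats) == 2
        mat_phenotype = "het" if self_fertile else next(iter(mats))
        pattern = (
            junctions_present(competent) if competent else frozenset()
        )
        distinct = [het.components[i][0] for i in set(drawn)]
        viable = spore_viability(distinct, specs) if specs else True
        out.append(
            ConidialDerivative(
                nuclei=drawn,
                self_fertile=self_fertile,
                mat_phenotype=mat_phenotype,
                junction_pattern=frozenset(pattern),
                viable=viable,
            )
        )
    return out


@dataclass
class Zygote:
    """The karyogamy pair of a self-cross, with RIP exposure flags.

    ``rip_exposed`` marks, for each of the two zygote nuclei, whether any
    rearrangement segment is present in two copies in that nucleus: RIP
    acts premeiotically on duplicated DNA, so only Dp nuclei are exposed.
    A [T + N] self-cross therefore never exposes the translocated segment
    to RIP, while a [Dp + Df] self-cross exposes the Dp component.
    """

    nucleus_A: NucleusState
    nucleus_a: NucleusState
    rip_exposed: tuple[bool, bool]  # aligned with (nucleus_A, nucleus_a)

    @property
    def pair(self) -> tuple[NucleusState, NucleusState]:
        return (self.nucleus_A, self.nucleus_a)


def _has_duplicated_segment(
    nuc: NucleusState, specs: Iterable[RearrangementSpec]
) -> bool:
    return any(
        c == 2
        for spec in specs
        if spec.id in nuc.variants
        for c in nuc.segment_copies(spec).values()
    )


def self_cross_zygote(
    het: Heterokaryon,
    rearrangements: Iterable[RearrangementSpec],
    rng: np.random.Generator | None = None,
) -> Zygote:
    """Pick the mat A + mat a karyogamy pair for a self-cross.

    Raises if the heterokaryon is self-sterile (homokaryotic, or its only
    opposite-mating-type component cannot divide).
    """
    if not het.is_self_fertile:
        raise HeterokaryonError("self-sterile: cannot self-cross")
    specs = tuple(rearrangements)
    by_mat: dict[str, list[NucleusState]] = {"A": [], "a": []}
    for nuc, _ in het.components:
        if nuc.division_fitness > 0:
            by_mat[nuc.mat].append(nuc)
    pick = (
        (lambda lst: lst[int(rng.integers(len(lst)))])
        if rng is not None
        else (lambda lst: lst[0])
    )
    nuc_A = pick(by_mat["A"])
    nuc_a = pick(by_mat["a"])
    return Zygote(
        nucleus_A=nuc_A,
        nucleus_a=nuc_a,
        rip_exposed=(
            _has_duplicated_segment(nuc_A, specs),
            _has_duplicated_segment(nuc_a, specs),
        ),
    )


def msud_fertility(
    zygote: Zygote | tuple[NucleusState, NucleusState],
    rearrangements: Iterable[RearrangementSpec],
    msud_strength: float = 1.0,
    threshold: float = 0.5,
) -> str:
    """Rule-based fertility of a cross: "fertile" or "barren".

    Meiotic silencing by unpaired DNA (MSUD) renders a cross barren when a
    chromosome segment cannot be fully paired in the zygote.  At this
    abstraction every copy of a translocated segment needs a pairing
    partner, which is possible iff the segment's total copy number over the
    two zygote haplotypes is even (quadrivalent pairing covers a T x N
    zygote, whose complement a [Dp + Df] self-cross zygote reproduces
    exactly).  A Dp x N zygote carries three copies — one must stay
    unpaired — and is barren when ``msud_strength`` reaches ``threshold``;
    suppressor backgrounds (Sad, Esm) are modeled as lowered strength.
    """
    pair = zygote.pair if isinstance(zygote, Zygote) else tuple(zygote)
    n1, n2 = pair
    for spec in rearrangements:
        copies1 = n1.segment_copies(spec) if spec.id in n1.variants else {
            s: 1 for s in spec.segment_ids
        }
        copies2 = n2.segment_copies(spec) if spec.id in n2.variants else {
            s: 1 for s in spec.segment_ids
        }
        for seg in spec.segment_ids:
            if (copies1[seg] + copies2[seg]) % 2 == 1 and msud_strength >= threshold:
                return "barren"
    return "fertile"
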