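"""Heterokaryon genotype inference from conidial-derivative observations.

A self-fertile N. tetrasperma strain whose DNA amplifies breakpoint
junctions is either [T + N] or [Dp + Df]: junction PCR on heterokaryon DNA
cannot tell them apart because the union of junctions is identical.  The
discrimination procedure works from the strain's homokaryotic (self-sterile)
conidial derivatives:

* [T + N] strains yield viable homokaryons of *both* mating types (T-type
  with the full junction set, N-type with none);
* [Dp + Df] strains yield viable homokaryons of *only* the Dp nucleus'
  mating type (Df homokaryons are inviable), with the Dp pattern (the full
  set minus junction A).

A derivative whose DNA amplifies *only* junction A cannot be a viable
homokaryon (an uncomplemented Df) and is read as a heterokaryotic [N + Df]
derivative, revealing a third (Df) nucleus.

With few derivatives, an all-one-class result may just reflect skewed
sampling of a [T + N] strain; the classifier quantifies this with an exact
binomial tail probability and attaches an explicit "not excluded" caveat
below the configured evidence thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import pandas as pd
from scipy.stats import binomtest

from .rearrangements import RearrangementSpec

_MAT_ORDER = {"a": 0, "A": 1, "het": 2}
_TYPE_ORDER = {"T": 0, "N": 1, "Dp": 2, "Df": 3, "?": 4}


class ObservationError(ValueError):
    pass


@dataclass(frozen=True)
class DerivativeObs:
    """One conidial derivative: fertility, mating type, optional PCR set."""

    self_fertile: bool
    mat: str  # "A" | "a" | "het"
    junctions: frozenset[str] | None = None  # None = PCR not done


@dataclass
class ObservationRecord:
    """Observations on one self-fertile strain."""

    strain_id: str
    het_junctions: frozenset[str]
    derivatives: list[DerivativeObs] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.het_junctions = frozenset(self.het_junctions)
        for d in self.derivatives:
            if d.junctions is not None and not d.junctions <= self.het_junctions:
                raise ObservationError(
                    f"{self.strain_id}: derivative junction set "
                    f"{sorted(d.junctions)} not contained in heterokaryon set "
                    f"{sorted(self.het_junctions)}"
                )


@dataclass(frozen=True)
class NucleusCall:
    genotype: str  # "T" | "N" | "Dp" | "Df" | "?"
    mat: str

    def __str__(self) -> str:
        return f"{self.genotype} {self.mat}"


@dataclass
class GenotypeCall:
    """Inferred heterokaryon genotype with explicit caveats."""

    nuclei: list[NucleusCall]
    flags: list[str] = field(default_factory=list)
    skew_p: float | None = None
    evidence: str = "junction-pcr"  # "junction-pcr" | "mat-only" | "none"
    n_min: int = 10
    alpha: float = 0.05

    @property
    def label(self) -> str:
        if not self.nuclei:
            return "ND"
        ordered = sorted(
            self.nuclei,
            key=lambda c: (_MAT_ORDER.get(c.mat, 9), _TYPE_ORDER.get(c.genotype, 9)),
        )
        return "[" + " + ".join(str(c) for c in ordered) + "]"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def balanced_split_probability(n_type1: int, n_type2: int) -> float:
    """Two-sided exact binomial probability of a split at least this skewed.

    Under equal sampling of two nucleus types (p = 0.5), the probability of
    observing a mating-type split at least as extreme as
    ``n_type1 : n_type2``.  Symmetric in its arguments; 1.0 with no data.
    """
    if n_type1 < 0 or n_type2 < 0:
        raise ValueError("counts must be non-negative")
    n = n_type1 + n_type2
    if n == 0:
        return 1.0
    return min(1.0, binomtest(n_type1, n, 0.5).pvalue)


def _pattern_type(pattern: frozenset[str], observable: frozenset[str]) -> str:
    """Map a derivative's junction pattern to a nucleus type.

    Relative to the *observable* junction set of the rearrangement:
    the full set -> T; full minus A -> Dp; empty -> N; {A} alone (when A is
    a proper subset of the observable set) -> "NDf", a heterokaryotic
    [N + Df] derivative evidencing a Df nucleus.
    """
    if pattern == observable:
        return "T"
    if pattern == observable - {"A"}:
        return "Dp"
    if not pattern:
        return "N"
    if pattern == frozenset({"A"}):
        return "NDf"
    return "?"


def infer_heterokaryon_genotype(
    obs: ObservationRecord,
    rearrangement: RearrangementSpec,
    n_min: int = 10,
    alpha: float = 0.05,
) -> GenotypeCall:
    """Classify a strain's heterokaryon genotype from its derivatives.

    Rule cascade:

    1. type each self-sterile derivative from its junction pattern
       (T / Dp / N / [N + Df]);
    2. assemble the nucleus set whose junction union equals the
       heterokaryon's PCR set, adding a Df nucleus when junction A is in
       the heterokaryon set but appears in no T-pattern derivative;
    3. give the Df nucleus the mating type evidenced by [N + Df]
       derivatives, or failing that the mating type absent among the
       self-sterile derivatives;
    4. when only one homokaryon class was seen and the derivative count is
       below ``n_min`` or the skew probability at least ``alpha``, attach a
       "not excluded" caveat for the alternative genotype; a single
       derivative supports no partner call at all ("?");
    5. three evident nucleus types yield a triple-heterokaryon call.

    Without any derivative junction data the classifier falls back to the
    mating-type split + self-fertility logic ("mat-only evidence").
    """
    observable = frozenset(rearrangement.assayable_junctions or ())
    if not obs.het_junctions <= rearrangement.junction_classes:
        raise ObservationError(
            f"{obs.strain_id}: heterokaryon junctions {sorted(obs.het_junctions)} "
            f"not defined for a {rearrangement.kind.value}"
        )

    self_steriles = [d for d in obs.derivatives if not d.self_fertile]
    if not self_steriles:
        return GenotypeCall(
            nuclei=[],
            flags=["no self-sterile derivatives"],
            skew_p=None,
            evidence="none",
            n_min=n_min,
            alpha=alpha,
        )

    n_a = sum(1 for d in self_steriles if d.mat == "a")
    n_A = sum(1 for d in self_steriles if d.mat == "A")
    skew_p = balanced_split_probability(n_a, n_A)

    with_pcr = [d for d in self_steriles if d.junctions is not None]
    if not with_pcr:
        return _mat_only_call(self_steriles, n_a, n_A, skew_p, n_min, alpha)

    # rule 1: type each PCR'd self-sterile derivative
    typed: dict[tuple[str, str], int] = {}
    for d in with_pcr:
        t = _pattern_type(d.junctions, observable)
        if t == "?":
            raise ObservationError(
                f"{obs.strain_id}: uninterpretable junction pattern "
                f"{sorted(d.junctions)}"
            )
        typed[(t, d.mat)] = typed.get((t, d.mat), 0) + 1

    calls: set[NucleusCall] = set()
    df_mats: set[str] = set()
    for (t, mat), _count in typed.items():
        if t == "NDf":
            df_mats.add(mat)  # heterokaryotic [N + Df] derivative
        else:
            calls.add(NucleusCall(t, mat))

    flags: list[str] = []

    # rule 2: the called nuclei must jointly account for the heterokaryon's
    # junction set; junction A seen in the heterokaryon but in no T-pattern
    # derivative implies a Df nucleus
    def junction_union(cs: set[NucleusCall], with_df: bool) -> frozenset[str]:
        u: set[str] = set()
        for c in cs:
            if c.genotype == "T":
                u |= observable
            elif c.genotype == "Dp":
                u |= observable - {"A"}
        if with_df:
            u |= {"A"} & observable
        return frozenset(u)

    df_needed = bool(df_mats)
    if (
        "A" in obs.het_junctions
        and "A" in observable
        and not any(c.genotype == "T" for c in calls)
    ):
        df_needed = True
    if junction_union(calls, df_needed) != obs.het_junctions & observable:
        flags.append(
            "junction pattern unresolved: derivative types do not account "
            "for the heterokaryon PCR set"
        )

    # rule 3: mating type of the Df nucleus
    if df_needed:
        if df_mats:
            for m in sorted(df_mats):
                calls.add(NucleusCall("Df", m))
        else:
            seen_mats = {d.mat for d in self_steriles}
            missing = {"A", "a"} - seen_mats
            calls.add(NucleusCall("Df", missing.pop() if missing else "?"))

    # rule 4: single-class results and small numbers
    single_class = len({(d.mat, t) for d in with_pcr
                        for t in [_pattern_type(d.junctions, observable)]}) == 1
    if single_class and len({d.mat for d in self_steriles}) == 1:
        (t, mat) = next(iter(typed))
        count = len(self_steriles)
        other = "A" if mat == "a" else "a"
        if count == 1 and t == "T":
            # a single T derivative: the partner nucleus could be N, T, Dp
            # or Df — no basis for a call
            calls = {NucleusCall("T", mat), NucleusCall("?", other)}
            flags.append("single derivative: partner nucleus undetermined")
        else:
            inconclusive = count < n_min or skew_p >= alpha
            if t == "T":
                calls.add(NucleusCall("Df", other))
                alt = GenotypeCall([NucleusCall("T", mat), NucleusCall("N", other)])
            elif t == "N":
                if not any(c.genotype == "Df" for c in calls):
                    calls.add(NucleusCall("Df", other))
                alt = GenotypeCall([NucleusCall("N", mat), NucleusCall("T", other)])
            else:  # Dp
                if not any(c.genotype == "Df" for c in calls):
                    calls.add(NucleusCall("Df", other))
                alt = GenotypeCall([NucleusCall("Dp", mat), NucleusCall("N", other)])
            if inconclusive:
                flags.append(
                    f"{alt.label} not excluded (n={count}, skew_p={skew_p:.3g})"
                )

    # a self-fertile strain needs both mating types among its components
    mats_called = {c.mat for c in calls}
    for missing in {"A", "a"} - mats_called:
        if not any(c.mat == "?" for c in calls):
            calls.add(NucleusCall("?", missing))
            flags.append(f"no mat {missing} derivative observed: nucleus undetermined")

    nuclei = sorted(
        calls, key=lambda c: (_MAT_ORDER.get(c.mat, 9), _TYPE_ORDER.get(c.genotype, 9))
    )
    return GenotypeCall(
        nuclei=nuclei,
        flags=flags,
        skew_p=skew_p,
        evidence="junction-pcr",
        n_min=n_min,
        alpha=alpha,
    )


def _mat_only_call(
    self_steriles: Sequence[DerivativeObs],
    n_a: int,
    n_A: int,
    skew_p: float,
    n_min: int,
    alpha: float,
) -> GenotypeCall:
    """Fallback when no derivative junction PCR is available."""
    flags = ["mat-only evidence"]
    n = len(self_steriles)
    if n_a > 0 and n_A > 0:
        # both mating types give viable homokaryons: a [T + N]-type strain,
        # but which nucleus is T cannot be known without PCR
        nuclei = [NucleusCall("?", "a"), NucleusCall("?", "A")]
        flags.append("consistent with [T + N]; T/N assignment requires PCR")
    else:
        mat = "a" if n_a > 0 else "A"
        other = "A" if mat == "a" else "a"
        nuclei = [NucleusCall("Dp", mat), NucleusCall("Df", other)]
        if n < n_min or skew_p >= alpha:
            alt = GenotypeCall([NucleusCall("T", mat), NucleusCall("N", other)])
            flags.append(f"{alt.label} not excluded (n={n}, skew_p={skew_p:.3g})")
    return GenotypeCall(
        nuclei=nuclei,
        flags=flags,
        skew_p=skew_p,
        evidence="mat-only",
        n_min=n_min,
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Observation-table aggregation
# ---------------------------------------------------------------------------

#: column names of a strain-level observation summary table
SUMMARY_COLUMNS = (
    "serial",
    "strain",
    "n_conidial_derivatives",
    "n_self_sterile",
    "n_mat_a",
    "n_mat_A",
    "genotype",
    "footnote",
)


@dataclass
class TableSummary:
    n_strains: int
    total_derivatives: int
    total_self_sterile: int
    total_mat_a: int
    total_mat_A: int
    strains_all_self_sterile: list[str]

    @property
    def all_self_sterile(self) -> bool:
        return self.total_derivatives == self.total_self_sterile

    @property
    def fraction_self_fertile(self) -> float:
        if self.total_derivatives == 0:
            return float("nan")
        return 1.0 - self.total_self_sterile / self.total_derivatives


def summarize_observation_table(
    rows: pd.DataFrame,
    filter: Callable[[pd.Series], bool] | pd.Series | None = None,
) -> TableSummary:
    """Aggregate a strain-level observation summary table.

    ``rows`` must carry the numeric columns ``n_conidial_derivatives``,
    ``n_self_sterile``, ``n_mat_a`` and ``n_mat_A``; ``filter`` may be a
    per-row predicate or a boolean mask.  Totals are exact integers.
    """
    df = rows
    if filter is not None:
        mask = filter if isinstance(filter, pd.Series) else df.apply(filter, axis=1)
        df = df[mask]
    for _, row in df.iterrows():
        ident = row.get("strain", row.name)
        vals = [
            row["n_conidial_derivatives"],
            row["n_self_sterile"],
            row["n_mat_a"],
            row["n_mat_A"],
        ]
        if any(pd.isna(v) or int(v) != v or v < 0 for v in vals):
            raise ObservationError(f"malformed row for strain {ident!r}: {vals}")
        total, ss, na, nA = map(int, vals)
        if ss > total or na + nA > ss:
            raise ObservationError(
                f"inconsistent counts for strain {ident!r}: "
                f"derivatives={total}, self-sterile={ss}, mat a={na}, mat A={nA}"
            )
    all_ss = df[
        (df["n_self_sterile"] == df["n_conidial_derivatives"])
        & (df["n_conidial_derivatives"] > 0)
    ]
    return TableSummary(
        n_strains=len(df),
        total_derivatives=int(df["n_conidial_derivatives"].sum()),
        total_self_sterile=int(df["n_self_sterile"].sum()),
        total_mat_a=int(df["n_mat_a"].sum()),
        total_mat_A=int(df["n_mat_A"].sum()),
        strains_all_self_sterile=list(all_ss["strain"]) if "strain" in df else [],
    )
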