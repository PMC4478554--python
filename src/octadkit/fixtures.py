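"""Synthetic-fixture generation: every pipeline stage testable offline.

``generate_fixtures`` writes, under one output directory:

* toy FASTA genomes for T/N/Dp/Df nuclei with embedded junction motifs,
* observation TSVs sampled from heterokaryons of known genotype (ground
  truth in ``manifest.json``),
* ascus tally TSVs for a cross of each species,
* RIP'd allele FASTA pairs with known per-copy polarity,
* a copy of the packaged strain-table transcription.

Regeneration is byte-identical for a fixed configuration (all randomness
flows from the configured seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as okio
from .heterokaryon import Heterokaryon, sample_conidial_derivatives
from .inference import DerivativeObs, ObservationRecord
from .meiosis import CrossParams, simulate_cross_tally
from .pcr import make_toy_genomes
from .rearrangements import (
    RearrangementSpec,
    get_preset,
    junctions_present,
    nucleus,
)
from .rip import RipParams, rip_mutate


#: heterokaryon genotypes written as observation fixtures, as
#: (component genotype, mating type, division fitness) tuples
DEFAULT_GENOTYPES: dict[str, tuple[tuple[str, str, float], ...]] = {
    "T+N": (("T", "a", 1.0), ("N", "A", 1.0)),
    "Dp+Df": (("Dp", "a", 1.0), ("Df", "A", 1.0)),
    "Dp+Df_nucleus_limited": (("Dp", "a", 1.0), ("Df", "A", 0.0)),
    "Dp+N": (("Dp", "a", 1.0), ("N", "A", 1.0)),
    "T+Df": (("T", "a", 1.0), ("Df", "A", 1.0)),
    "N+Df": (("N", "a", 1.0), ("Df", "A", 1.0)),
    "T+N+Df": (("T", "a", 1.0), ("N", "A", 1.0), ("Df", "A", 1.0)),
}


@dataclass
class FixtureConfig:
    preset: str = "EB4"
    segment_length: int = 120
    flank_length: int = 60
    motif_length: int = 24
    derivatives_per_strain: int = 25
    n_asci: int = 200
    rip_rate: float = 0.05
    rip_sequence_length: int = 600
    seed: int = 2015

    def to_dict(self) -> dict:
        return asdict(self)


def make_heterokaryon(
    spec: RearrangementSpec,
    components: tuple[tuple[str, str, float], ...],
    proportions: tuple[float, ...] | None = None,
) -> Heterokaryon:
    """Build a heterokaryon from (genotype, mat, fitness) component specs."""
    if proportions is None:
        proportions = tuple(1.0 / len(components) for _ in components)
    return Heterokaryon(
        components=[
            (nucleus(spec, g, m, division_fitness=f), p)
            for (g, m, f), p in zip(components, proportions)
        ]
    )


def observe_heterokaryon(
    het: Heterokaryon,
    spec: RearrangementSpec,
    strain_id: str,
    n: int,
    rng: np.random.Generator,
    with_pcr: bool = True,
    **sample_kwargs,
) -> ObservationRecord:
    """Sample conidial derivatives into a strain observation record.

    Inviable conidia (uncomplemented Df) never germinate and are excluded;
    junction patterns are restricted to the rearrangement's assayable set
    when PCR is simulated, or dropped entirely with ``with_pcr=False``.
    """
    derivs = sample_conidial_derivatives(
        het, n, rng, rearrangements=[spec], **sample_kwargs
    )
    assayable = frozenset(spec.assayable_junctions or ())
    obs = []
    for d in derivs:
        if not d.viable:
            continue
        obs.append(
            DerivativeObs(
                self_fertile=d.self_fertile,
                mat=d.mat_phenotype,
                junctions=(d.junction_pattern & assayable) if with_pcr else None,
            )
        )
    het_junctions = junctions_present(het.nuclei, spec) & assayable
    return ObservationRecord(
        strain_id=strain_id, het_junctions=het_junctions, derivatives=obs
    )


def generate_fixtures(config: FixtureConfig, outdir: str | Path) -> dict:
    """Write the full fixture set; returns the manifest (also saved)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = get_preset(config.preset)
    manifest: dict = {"config": config.to_dict(), "preset": config.preset,
                      "files": {}, "ground_truth": {}}

    # (i) toy genomes with junction motifs
    rng = np.random.default_rng(config.seed)
    genomes, motifs = make_toy_genomes(
        spec, rng, config.segment_length, config.flank_length, config.motif_length
    )
    for gt, chroms in genomes.items():
        path = outdir / f"genome_{gt}.fasta"
        okio.write_fasta(
            {f"{config.preset}_{gt}_{role}": seq for role, seq in chroms.items()},
            path,
        )
        manifest["files"][f"genome_{gt}"] = path.name
    okio.write_json(motifs, outdir / "junction_motifs.json")
    manifest["files"]["junction_motifs"] = "junction_motifs.json"

    # (ii) observation tables for known heterokaryon genotypes
    for name, comps in DEFAULT_GENOTYPES.items():
        het = make_heterokaryon(spec, comps)
        rec = observe_heterokaryon(
            het, spec, strain_id=name, n=config.derivatives_per_strain, rng=rng
        )
        path = outdir / f"observations_{name.replace('+', '_')}.tsv"
        okio.write_observations([rec], path)
        manifest["files"][f"observations_{name}"] = path.name
        manifest["ground_truth"][name] = {
            "components": [list(c) for c in comps],
            "n_derivatives_observed": len(rec.derivatives),
        }

    # (iii) ascus tallies for a T x N cross in both species
    for species in ("crassa", "tetrasperma"):
        params = CrossParams(species=species, rng_seed=config.seed)
        tally = simulate_cross_tally(
            nucleus(spec, "T", "A"),
            nucleus(spec, "N", "a"),
            [spec],
            config.n_asci,
            params,
        )
        path = outdir / f"tally_TxN_{species}.tsv"
        okio.write_tally(tally, path)
        manifest["files"][f"tally_{species}"] = path.name

    # (iv) RIP'd allele pair with known polarity
    base = "".join(rng.choice(list("ACGT"), size=config.rip_sequence_length))
    copies = rip_mutate(base, RipParams(rate=config.rip_rate), rng)
    okio.write_fasta({"ancestral": base}, outdir / "rip_ancestral.fasta")
    okio.write_fasta(
        {"copy1_CtoT": copies[0], "copy2_GtoA": copies[1]},
        outdir / "rip_copies.fasta",
    )
    manifest["files"]["rip_ancestral"] = "rip_ancestral.fasta"
    manifest["files"]["rip_copies"] = "rip_copies.fasta"
    manifest["ground_truth"]["rip_polarity"] = {"copy1": "C>T", "copy2": "G>A"}

    # (v) the packaged strain-table transcription
    table2 = okio.load_table2()
    table2.to_csv(outdir / "table2.tsv", sep="\t", index=False)
    manifest["files"]["table2"] = "table2.tsv"

    okio.write_json(manifest, outdir / "manifest.json")
    return manifest
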