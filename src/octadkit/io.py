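"""Readers and writers for the package's tabular and sequence formats.

Observation TSV (one row per conidial derivative)::

    strain  derivative_id  self_fertile  mat  junctions
    1E1     1E1-d01        0             A    B,C

``junctions`` is a comma-separated list of junction classes, ``.`` for an
empty set and ``NA`` when PCR was not done.  A per-strain header row of
heterokaryon junctions is carried in a sidecar column ``het_junctions``
(identical within a strain).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .inference import DerivativeObs, ObservationRecord

OBS_COLUMNS = ("strain", "derivative_id", "self_fertile", "mat", "junctions",
               "het_junctions")


def _fmt_junctions(j: frozenset[str] | None) -> str:
    if j is None:
        return "NA"
    return ",".join(sorted(j)) if j else "."


def _parse_junctions(s: str) -> frozenset[str] | None:
    s = str(s).strip()
    if s == "NA":
        return None
    if s in (".", ""):
        return frozenset()
    return frozenset(p.strip() for p in s.split(","))


def write_observations(records: Iterable[ObservationRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for k, d in enumerate(rec.derivatives, 1):
            rows.append(
                {
                    "strain": rec.strain_id,
                    "derivative_id": f"{rec.strain_id}-d{k:02d}",
                    "self_fertile": int(d.self_fertile),
                    "mat": d.mat,
                    "junctions": _fmt_junctions(d.junctions),
                    "het_junctions": _fmt_junctions(rec.het_junctions),
                }
            )
    pd.DataFrame(rows, columns=list(OBS_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_observations(path: str | Path) -> list[ObservationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for strain, grp in df.groupby("strain", sort=False):
        het = _parse_junctions(grp["het_junctions"].iloc[0])
        derivatives = [
            DerivativeObs(
                self_fertile=bool(int(row["self_fertile"])),
                mat=row["mat"],
                junctions=_parse_junctions(row["junctions"]),
            )
            for _, row in grp.iterrows()
        ]
        records.append(
            ObservationRecord(
                strain_id=str(strain),
                het_junctions=het if het is not None else frozenset(),
                derivatives=derivatives,
            )
        )
    return records


def load_table2() -> pd.DataFrame:
    """The packaged transcription of the published self-fertile strain
    table (47 strains; per-strain derivative counts and genotype calls)."""
    ref = resources.files("octadkit.data").joinpath("table2.tsv")
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def write_tally(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_bed_intervals(path: str | Path) -> tuple[tuple[int, int], ...]:
    """0-based half-open intervals from the first three BED columns."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]), int(parts[2])))
    return tuple(sorted(out))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
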