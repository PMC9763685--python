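"""Shared readers/writers and run configuration.

All tabular interchange is TSV (UTF-8, '.' decimal); genomic coordinates in
files are 1-based inclusive. FASTA handling goes through Biopython.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("sulfassim")

COLONY_COLUMNS = ["plate", "row", "col", "strain", "replicate", "time_h", "size_px"]


@dataclasses.dataclass
class RunConfig:
    """Fully resolved run configuration; unknown keys are rejected."""

    seed: int = 0
    fitness: dict = dataclasses.field(default_factory=dict)
    kinetics: dict = dataclasses.field(default_factory=dict)
    ecfba: dict = dataclasses.field(default_factory=dict)
    homology: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    outputs: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


def read_colony_table(path: str | Path) -> pd.DataFrame:
    """Read a colony-size TSV with the documented header into a typed frame.

    Raises on missing columns, malformed numerics (with line numbers) and
    duplicate (plate, row, col, time_h) keys.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLONY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in {path}")
    for col, typ in [("row", int), ("col", int), ("replicate", int),
                     ("time_h", float), ("size_px", float)]:
        try:
            df[col] = df[col].astype(typ)
        except ValueError:
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
            raise ValueError(f"malformed numeric field '{col}' at line(s) {lines[:5]}")
    dup = df.duplicated(subset=["plate", "row", "col", "time_h"])
    if dup.any():
        lines = (df.index[dup] + 2).tolist()
        raise ValueError(f"duplicate (plate, position, time) at line(s) {lines[:5]}")
    return df[COLONY_COLUMNS]


def write_colony_table(df: pd.DataFrame, path: str | Path) -> None:
    df[COLONY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Parse FASTA into (id, sequence) pairs.

    Ids are the first whitespace token of the header; sequences are
    uppercased with gap characters preserved. An empty file yields an empty
    list; duplicate ids only warn.
    """
    records = []
    seen = set()
    path = Path(path)
    if path.stat().st_size == 0:
        return []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            logger.warning("duplicate FASTA id %s in %s", rec.id, path)
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def log_jsonl(path: str | Path, record: dict) -> None:
    with open(path, "a") as fh:
        fh.write(json.dumps(record) + "\n")
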