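"""File formats: library FASTA, assay and intensity CSV, run configuration.

Libraries are stored as FASTA with a pipe-delimited key=value header
dialect, ``>{id}|row={R}|col={C}``, one record per grid cell in row-major
order; write∘read is the identity (byte-for-byte, two-line records).
Assay and intensity tables are comma-separated UTF-8 with a required
header row; units with explicit suffixes in the column names (µM, µm, µL)
are converted to SI on read.
"""

from __future__ import annotations

import dataclasses
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binding import PulldownSample
from .design import MatrixLibrary, PILOT_TEMPLATE
from .errors import FormatError
from .properties import PeptideSequence, _AA_SET

logger = logging.getLogger(__name__)

ASSAY_COLUMNS = ["peptide_id", "C0_uM", "A_i", "A_f", "cells_cfu", "diameter_um", "volume_uL"]
INTENSITY_COLUMNS = ["position", "cell_mean", "background_mean"]


def write_library(library: MatrixLibrary, path) -> None:
    """Write a matrix library as two-line FASTA records in row-major order."""
    records = [
        SeqRecord(Seq(p.sequence), id=f"{p.id}|row={p.row}|col={p.col}", description="")
        for p in library.peptides()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def _parse_header(header: str, record_no: int) -> tuple[str, str, int]:
    parts = header.split("|")
    if len(parts) < 3:
        raise FormatError(f"record {record_no}: header {header!r} lacks row/col tags")
    pep_id, kv = parts[0], {}
    for part in parts[1:]:
        if "=" not in part:
            raise FormatError(f"record {record_no}: malformed header field {part!r}")
        k, v = part.split("=", 1)
        kv[k] = v
    for key in ("row", "col"):
        if key not in kv:
            raise FormatError(f"record {record_no} ({pep_id!r}): missing {key}= tag")
    unknown = set(kv) - {"row", "col"}
    if unknown:
        raise FormatError(f"record {record_no} ({pep_id!r}): unknown keys {sorted(unknown)}")
    try:
        col = int(kv["col"])
    except ValueError as exc:
        raise FormatError(f"record {record_no}: col must be an integer, got {kv['col']!r}") from exc
    return pep_id, kv["row"], col


def read_library(path) -> MatrixLibrary:
    """Read a matrix-library FASTA written by :func:`write_library`.

    Lowercase sequences are accepted and uppercased (logged); duplicate
    coordinates, malformed headers, and non-9-mers are format errors.
    """
    grid: dict[tuple[str, int], PeptideSequence] = {}
    with open(path) as fh:
        for record_no, rec in enumerate(SeqIO.parse(fh, "fasta"), start=1):
            pep_id, row, col = _parse_header(rec.id, record_no)
            seq = str(rec.seq)
            if seq != seq.upper():
                logger.info("record %d (%s): lowercase sequence uppercased", record_no, pep_id)
                seq = seq.upper()
            if len(seq) != 9:
                raise FormatError(
                    f"record {record_no} ({pep_id!r}): matrix members must be "
                    f"9-mers, got length {len(seq)}"
                )
            bad = set(seq) - _AA_SET
            if bad:
                raise FormatError(
                    f"record {record_no} ({pep_id!r}): invalid residues {sorted(bad)}"
                )
            if (row, col) in grid:
                raise FormatError(f"record {record_no}: duplicate coordinates ({row}, {col})")
            grid[(row, col)] = PeptideSequence(id=pep_id, sequence=seq, row=row, col=col)
    if not grid:
        raise FormatError(f"{path}: no records found")
    rows = tuple(sorted({r for r, _ in grid}))
    cols = tuple(sorted({c for _, c in grid}))
    try:
        return MatrixLibrary(row_labels=rows, column_indices=cols, grid=grid,
                             template=PILOT_TEMPLATE)
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty input file") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def read_assay_csv(path) -> list[PulldownSample]:
    """Read a pulldown assay table; µM/µm/µL columns are converted to SI."""
    df = _read_csv(path, ASSAY_COLUMNS)
    samples = []
    for idx, row in df.iterrows():
        try:
            vals = {c: float(row[c]) for c in ASSAY_COLUMNS[1:]}
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {idx + 2}: non-numeric cell") from exc
        try:
            samples.append(
                PulldownSample(
                    C0=vals["C0_uM"] * 1e-6,
                    A_i=vals["A_i"],
                    A_f=vals["A_f"],
                    cell_count=vals["cells_cfu"],
                    cell_diameter=vals["diameter_um"] * 1e-6,
                    volume=vals["volume_uL"] * 1e-6,
                    peptide_id=str(row["peptide_id"]),
                )
            )
        except Exception as exc:
            raise FormatError(f"{path} row {idx + 2}: {exc}") from exc
    return samples


def read_intensity_csv(path) -> list[tuple[tuple[str, int], float, float]]:
    """Read (position, cell_mean, background_mean) rows; position like "A1"."""
    df = _read_csv(path, INTENSITY_COLUMNS)
    out = []
    for idx, row in df.iterrows():
        pos = str(row["position"]).strip()
        if len(pos) < 2 or not pos[0].isalpha() or not pos[1:].isdigit():
            raise FormatError(
                f"{path} row {idx + 2}: position must look like 'A1', got {pos!r}"
            )
        try:
            cell = float(row["cell_mean"])
            bg = float(row["background_mean"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path} row {idx + 2}: non-numeric intensity") from exc
        if bg <= 0:
            raise FormatError(f"{path} row {idx + 2}: background mean must be > 0")
        out.append(((pos[0], int(pos[1:])), cell, bg))
    return out


@dataclass
class RunConfig:
    """Serializable run settings; round-trips losslessly through YAML."""

    scale: str = "kyte-doolittle"
    charge_mode: str = "formal"
    pka_set: str = "emboss"
    pH: float = 7.0
    seed: int | None = None
    out_dir: str = "."

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)
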