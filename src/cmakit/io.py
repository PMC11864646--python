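"""Readers and writers for the formats the pipeline touches.

All tabular formats are tab-separated UTF-8 with a required header row
and "." as the decimal separator; this round-trips gene identifiers
containing commas unambiguously.  Missing cells are empty fields and
are preserved as missing, never silently zeroed, because downstream
stages distinguish "not measured" from "measured zero".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger("cmakit")

PathLike = Union[str, Path]

#: The 20 proteinogenic amino acids (one-letter codes).
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Ambiguity code accepted only with ``allow_ambiguous=True``.
AMBIGUOUS = frozenset("X")

FASTA_WRAP = 60  # fixed line-wrapping width for FASTA output


class FormatError(ValueError):
    """A malformed input file; the message names the offending location."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence to be scanned for motifs.

    ``sequence`` is an uppercase amino-acid string over the 20-letter
    alphabet, optionally containing X when ambiguity codes were allowed
    at read time.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def _validate_sequence(seq: str, ident: str, line_no: int, allow_ambiguous: bool) -> None:
    allowed = AMINO_ACIDS | (AMBIGUOUS if allow_ambiguous else frozenset())
    bad = set(seq) - allowed
    if bad:
        raise FormatError(
            f"line {line_no}: sequence of {ident!r} contains invalid characters "
            f"{sorted(bad)} (pass allow_ambiguous=True to accept X)"
        )


def read_fasta(path: PathLike, *, allow_ambiguous: bool = False) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased and record order is preserved.  Characters
    outside the 20-letter alphabet are rejected unless
    ``allow_ambiguous`` permits X; motif rules are undefined for
    ambiguity codes, so the strict default protects downstream scans.

    Raises
    ------
    FormatError
        On text before the first header, an empty sequence, a
        duplicated id, or an invalid character — naming the line.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        ident, _, desc = header.partition(" ")
        seq = "".join(chunks).upper()
        if not ident:
            raise FormatError(f"line {header_line}: empty FASTA header")
        if not seq:
            raise FormatError(f"line {header_line}: record {ident!r} has no sequence")
        if ident in seen:
            raise FormatError(f"line {header_line}: duplicate protein id {ident!r}")
        _validate_sequence(seq, ident, header_line, allow_ambiguous)
        seen.add(ident)
        records.append(ProteinRecord(id=ident, sequence=seq, description=desc.strip()))

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                header_line = line_no
                chunks = []
            else:
                if header is None:
                    raise FormatError(f"line {line_no}: sequence data before first header")
                chunks.append(line)
        _flush()

    logger.info("read_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path_or_handle: PathLike | IO[str]) -> None:
    """Write records as FASTA, wrapping sequences at 60 columns."""

    def _write(fh: IO[str]) -> None:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), FASTA_WRAP):
                fh.write(rec.sequence[i : i + FASTA_WRAP] + "\n")

    if hasattr(path_or_handle, "write"):
        _write(path_or_handle)  # type: ignore[arg-type]
    else:
        with open(path_or_handle, "w", encoding="utf-8") as fh:  # type: ignore[arg-type]
            _write(fh)


@dataclass
class ExpressionTable:
    """Samples × genes relative-expression values.

    ``values`` holds floats with NaN where the input cell was empty;
    ``mask`` is True where a measurement is present.  Missing cells are
    carried through, never imputed — the score stage decides policy.
    """

    values: pd.DataFrame
    mask: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.mask = self.values.notna()

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)


def read_expression_table(path: PathLike) -> ExpressionTable:
    """Read a tab-separated samples × genes table.

    First column holds sample ids, the header row holds gene ids; an
    empty cell is missing.  Ragged rows and non-numeric cells raise
    :class:`FormatError` naming the row/column.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty expression table")
    header = lines[0].split("\t")
    genes = header[1:]
    n_cols = len(header)
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for line_no, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != n_cols:
            raise FormatError(
                f"line {line_no}: expected {n_cols} fields, found {len(fields)} (ragged row)"
            )
        sample_ids.append(fields[0])
        row: list[float] = []
        for gene, cell in zip(genes, fields[1:]):
            cell = cell.strip()
            if cell == "":
                row.append(math.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"line {line_no}, column {gene!r}: non-numeric cell {cell!r}"
                ) from None
        rows.append(row)
    values = pd.DataFrame(rows, index=sample_ids, columns=genes, dtype=float)
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate sample ids: {dupes}")
    table = ExpressionTable(values)
    logger.info(
        "read_expression_table: %d samples x %d genes from %s (%d missing cells)",
        len(table.samples), len(table.genes), path, int((~table.mask).values.sum()),
    )
    return table


def write_expression_table(table: ExpressionTable, path: PathLike) -> None:
    """Write an expression table; missing cells become empty fields."""
    table.values.to_csv(path, sep="\t", index_label="sample", na_rep="")


def read_network_config(path: PathLike):
    """Read a CMA-network definition file into an unweighted network.

    The format is tab-separated with a header and columns
    ``gene_id  group  direction  paralog_family  [weight]``; direction
    must be ``+1`` or ``-1`` (a bare ``1`` is accepted as ``+1``), and
    the optional weight column overrides the derived 1/n weight.

    Returns a :class:`cmakit.score.CmaNetwork`.
    """
    from .score import CmaNetwork, CmaNetworkElement  # deferred: avoid import cycle

    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty network")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = ["gene_id", "group", "direction", "paralog_family"]
    if header[: len(required)] != required:
        raise FormatError(
            f"{path}: network header must start with {required}, got {header}"
        )
    has_weight = len(header) > 4 and header[4] == "weight"

    elements: list[CmaNetworkElement] = []
    seen: set[str] = set()
    for line_no, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 4:
            raise FormatError(f"line {line_no}: expected at least 4 fields")
        gene_id, group, direction_tok, family = fields[:4]
        if gene_id in seen:
            raise FormatError(f"line {line_no}: duplicate gene id {gene_id!r}")
        seen.add(gene_id)
        if direction_tok in {"+1", "1"}:
            direction = 1
        elif direction_tok == "-1":
            direction = -1
        else:
            raise FormatError(
                f"line {line_no}: unknown direction token {direction_tok!r} "
                "(expected +1 or -1)"
            )
        if not family:
            raise FormatError(f"line {line_no}: empty paralog_family for {gene_id!r}")
        weight = None
        if has_weight and len(fields) > 4 and fields[4] != "":
            weight = float(fields[4])
            if weight <= 0:
                raise FormatError(f"line {line_no}: weight must be positive")
        elements.append(
            CmaNetworkElement(
                gene_id=gene_id,
                functional_group=group,
                direction=direction,
                paralog_family=family,
                explicit_weight=weight,
            )
        )
    if not elements:
        raise FormatError(f"{path}: empty network")
    network = CmaNetwork(elements)
    logger.info(
        "read_network_config: %d genes, %d families from %s",
        len(network.elements), len(network.families), path,
    )
    return network


def write_network_config(network, path: PathLike) -> None:
    """Write a network definition (including any assigned weights)."""
    rows = []
    for el in network.elements:
        rows.append(
            {
                "gene_id": el.gene_id,
                "group": el.functional_group,
                "direction": f"{el.direction:+d}",
                "paralog_family": el.paralog_family,
                "weight": "" if el.weight is None else repr(el.weight),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ion_table(path: PathLike) -> pd.DataFrame:
    """Read a long-format ion-abundance table.

    Columns: ``protein_id  ion_id  run_id  abundance``; an empty
    abundance field is a missing observation.  Each ion must belong to
    exactly one protein.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ion_id": str, "run_id": str})
    required = {"protein_id", "ion_id", "run_id", "abundance"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: ion table lacks columns {sorted(missing)}")
    df["abundance"] = pd.to_numeric(df["abundance"], errors="raise")
    if (df["abundance"].dropna() < 0).any():
        raise FormatError(f"{path}: negative ion abundances are not allowed")
    owners = df.dropna(subset=["abundance"]).groupby("ion_id")["protein_id"].nunique()
    shared = owners[owners > 1]
    if not shared.empty:
        raise FormatError(
            f"{path}: ions assigned to multiple proteins: {list(shared.index[:5])}"
        )
    logger.info(
        "read_ion_table: %d rows, %d proteins, %d runs from %s",
        len(df), df["protein_id"].nunique(), df["run_id"].nunique(), path,
    )
    return df


def configure_logging(level: int = logging.INFO, logfile: PathLike | None = None) -> None:
    """Attach a simple handler to the package logger (idempotent)."""
    logger.setLevel(level)
    if logfile is not None:
        handler: logging.Handler = logging.FileHandler(logfile)
    else:
        handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    if not any(type(h) is type(handler) for h in logger.handlers):
        logger.addHandler(handler)
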