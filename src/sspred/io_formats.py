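"""File formats: FASTA, query-anchored MSAs (aligned-FASTA and A3M), flat
secondary-structure datasets, and model checkpoints.

MSAs are always query-anchored: the first record is the query, every stored
row has exactly the query length, and the query itself is kept (ungapped) as
the first row for profile computation.  The A3M dialect marks insertions
relative to the query with lowercase letters; those columns are removed on
read so coordinates stay query-anchored, and '.' is treated as '-'.

The flat dataset format is three lines per protein::

    >identifier
    SEQUENCE
    SS8LABELS

Records containing ten or more consecutive undetermined residues (X) are
skipped with a warning, mirroring the filter applied when curating
structure-derived training sets.
"""

from __future__ import annotations

import io
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .alphabet import AA_ALPHABET, ValidationError, normalize_ss8

CHECKPOINT_FORMAT_VERSION = "1"


class FormatError(ValueError):
    """An input file violates its format contract."""


class CheckpointError(ValueError):
    """A checkpoint file is unreadable, truncated or of an unsupported version."""


@dataclass
class ProteinRecord:
    """A protein sequence with an optional per-residue 8-state label string."""

    id: str
    sequence: str
    ss8: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if len(self.sequence) < 1:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.sequence):
            if ch not in AA_ALPHABET:
                raise ValidationError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {i + 1}"
                )
        if self.ss8 is not None:
            self.ss8 = normalize_ss8(self.ss8)
            if len(self.ss8) != len(self.sequence):
                raise ValidationError(
                    f"record {self.id!r}: sequence length {len(self.sequence)} != "
                    f"ss8 length {len(self.ss8)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Alignment:
    """Query-anchored MSA: a query record plus homolog rows of query length.

    ``rows`` holds the homolog rows only; ``all_rows()`` prepends the query
    row when ``include_query_row`` is set (the default), which guarantees
    that every column has at least one non-gap character.
    """

    query: ProteinRecord
    rows: list[str] = field(default_factory=list)
    include_query_row: bool = True

    def __post_init__(self) -> None:
        L = len(self.query)
        norm = []
        for r, row in enumerate(self.rows):
            row = row.upper()
            if len(row) != L:
                raise FormatError(
                    f"alignment row {r + 1} has length {len(row)}, "
                    f"query length is {L}"
                )
            for ch in row:
                if ch != "-" and ch not in AA_ALPHABET:
                    raise FormatError(
                        f"alignment row {r + 1}: illegal character {ch!r}"
                    )
            norm.append(row)
        self.rows = norm
        if not self.include_query_row and not self.rows:
            raise FormatError("alignment with no rows at all")

    def all_rows(self) -> list[str]:
        if self.include_query_row:
            return [self.query.sequence] + self.rows
        return list(self.rows)

    @property
    def n_rows(self) -> int:
        return len(self.rows) + (1 if self.include_query_row else 0)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into validated :class:`ProteinRecord` objects.

    Multi-line sequences are concatenated and uppercased; records are
    returned in file order.  An empty file or an illegal residue character
    raises :class:`FormatError`.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            records.append(ProteinRecord(id=rec.id, sequence=seq))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# MSAs
# ---------------------------------------------------------------------------

def read_msa(path: str | Path, dialect: str = "aligned_fasta") -> Alignment:
    """Read a query-anchored MSA in ``aligned_fasta`` or ``a3m`` dialect.

    The first record is the query and must be ungapped after dialect
    normalization.  In A3M, lowercase letters are insertion states relative
    to the query and are deleted; '.' is read as '-'.  All resulting rows
    must have exactly the query length.
    """
    if dialect not in ("aligned_fasta", "a3m"):
        raise ValueError(f"unknown MSA dialect {dialect!r}")
    raw = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not raw:
        raise FormatError(f"{path}: empty MSA")

    def normalize(row: str) -> str:
        if dialect == "a3m":
            row = row.replace(".", "-")
            row = "".join(ch for ch in row if not ch.islower())
        return row.upper()

    qid, qrow = raw[0]
    qrow = normalize(qrow)
    if "-" in qrow:
        raise FormatError(
            f"{path}: query row {qid!r} contains gaps; MSAs must be query-anchored"
        )
    query = ProteinRecord(id=qid, sequence=qrow)
    rows = []
    for rid, row in raw[1:]:
        row = normalize(row)
        if len(row) != len(qrow):
            raise FormatError(
                f"{path}: row {rid!r} has length {len(row)} after normalization, "
                f"query length is {len(qrow)}"
            )
        rows.append(row)
    try:
        return Alignment(query=query, rows=rows)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_msa(aln: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA (query first, ungapped)."""
    with open(path, "w") as fh:
        fh.write(f">{aln.query.id}\n{aln.query.sequence}\n")
        for i, row in enumerate(aln.rows):
            fh.write(f">{aln.query.id}|hom{i + 1}\n{row}\n")


# ---------------------------------------------------------------------------
# Flat datasets
# ---------------------------------------------------------------------------

_CONSECUTIVE_X = re.compile("X{10,}")


def read_dataset(path: str | Path) -> list[ProteinRecord]:
    """Read a flat dataset of (sequence, ss8) blocks.

    Records with >=10 consecutive undetermined residues are skipped with a
    warning.  Length mismatches between sequence and label lines raise
    :class:`FormatError` naming the record.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty dataset file")
    if len(lines) % 3 != 0 or not lines[0].startswith(">"):
        raise FormatError(f"{path}: expected repeated '>id / sequence / ss8' blocks")
    records = []
    for i in range(0, len(lines), 3):
        header, seq, ss8 = lines[i], lines[i + 1], lines[i + 2]
        if not header.startswith(">"):
            raise FormatError(f"{path}: block {i // 3 + 1}: missing '>' header")
        rid = header[1:].split()[0]
        try:
            rec = ProteinRecord(id=rid, sequence=seq, ss8=ss8)
        except ValidationError as exc:
            raise FormatError(f"{path}: record {rid!r}: {exc}") from exc
        if _CONSECUTIVE_X.search(rec.sequence):
            warnings.warn(
                f"{path}: record {rid!r} has >=10 consecutive undetermined "
                "residues and was skipped",
                stacklevel=2,
            )
            continue
        records.append(rec)
    return records


def write_dataset(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.ss8 is None:
                raise ValidationError(f"record {rec.id!r} carries no ss8 labels")
            fh.write(f">{rec.id}\n{rec.sequence}\n{rec.ss8}\n")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def write_checkpoint(params, config, path, training_meta: dict | None = None) -> None:
    """Serialize model parameters + configuration to an npz container.

    The write->read round trip is bit-exact.  A manifest records the format
    version, the configuration, the frozen-block set and the block order, so
    truncated or mismatched files are rejected on read.
    """
    from .model import ModelConfig, ModelParams  # local import: no cycle at load

    assert isinstance(config, ModelConfig) and isinstance(params, ModelParams)
    manifest = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "config": config.to_dict(),
        "frozen": sorted(params.frozen),
        "blocks": [
            {"name": k, "shape": list(v.shape), "dtype": str(v.dtype)}
            for k, v in params.blocks.items()
        ],
        "training_meta": training_meta or {},
    }
    arrays = {f"block:{k}": v for k, v in params.blocks.items()}
    buf = io.BytesIO()
    np.savez(buf, manifest=np.array(json.dumps(manifest)), **arrays)
    Path(path).write_bytes(buf.getvalue())


def read_checkpoint(path):
    """Read a checkpoint back into ``(ModelParams, ModelConfig, training_meta)``."""
    from .model import ModelConfig, ModelParams

    try:
        with np.load(str(path), allow_pickle=False) as data:
            if "manifest" not in data:
                raise CheckpointError(f"{path}: not a model checkpoint (no manifest)")
            manifest = json.loads(str(data["manifest"]))
            version = manifest.get("format_version")
            if version != CHECKPOINT_FORMAT_VERSION:
                raise CheckpointError(
                    f"{path}: unsupported checkpoint version {version!r} "
                    f"(supported: {CHECKPOINT_FORMAT_VERSION!r})"
                )
            blocks = {}
            for spec in manifest["blocks"]:
                key = f"block:{spec['name']}"
                if key not in data:
                    raise CheckpointError(f"{path}: missing parameter block {spec['name']!r}")
                arr = data[key]
                if list(arr.shape) != spec["shape"]:
                    raise CheckpointError(
                        f"{path}: block {spec['name']!r} has shape {arr.shape}, "
                        f"manifest says {spec['shape']}"
                    )
                blocks[spec["name"]] = arr
    except CheckpointError:
        raise
    except Exception as exc:  # zipfile/IO errors on truncated or corrupt files
        raise CheckpointError(f"{path}: unreadable checkpoint ({exc})") from exc
    config = ModelConfig.from_dict(manifest["config"])
    params = ModelParams(blocks=blocks, frozen=frozenset(manifest["frozen"]))
    params.validate_against(config)
    return params, config, manifest.get("training_meta", {})
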