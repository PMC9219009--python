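"""Readers and writers for the external formats the pipeline touches.

Covers FASTA sequence sets (via Biopython), motif position-weight matrices
in the plain ``>id`` + one-row-per-position text layout, tab-delimited
GO annotation flat files (GAF-like, as distributed by TAIR), network export
to SIF and GraphML, and the YAML run configuration.

All genomic coordinates in outputs are 0-based, half-open.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SequenceRecord",
    "PWMDefinition",
    "RunConfig",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_pwm",
    "write_pwm",
    "read_annotation_table",
    "write_network",
    "read_network",
    "load_config",
    "log",
]

ALPHABET = ("A", "C", "G", "T")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def log(level: str, message: str) -> None:
    """Write a level-prefixed log line to stderr."""
    print(f"[{level.upper()}] {message}", file=sys.stderr)


@dataclass
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    description: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PWMDefinition:
    """A position-weight matrix: one probability row per motif position.

    ``matrix`` has shape (width, 4) with columns ordered A, C, G, T; each
    row is a probability vector (rows given as counts are normalized on
    construction).
    """

    motif_id: str
    matrix: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise FormatError(f"PWM {self.motif_id!r}: matrix must be width x 4")
        if m.shape[0] < 4:
            raise FormatError(f"PWM {self.motif_id!r}: width must be >= 4")
        if (m < 0).any():
            raise FormatError(f"PWM {self.motif_id!r}: negative entries")
        sums = m.sum(axis=1)
        if (sums <= 0).any():
            raise FormatError(f"PWM {self.motif_id!r}: all-zero position row")
        self.matrix = m / sums[:, None]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def consensus(self) -> str:
        """Most probable base at each position."""
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class RunConfig:
    """Thresholds and knobs shared across pipeline stages."""

    r_min: float = 0.7
    p_max: float = 0.05
    motif_p_max: float = 1e-4
    enrichment_q_max: float = 0.05
    upstream_length: int = 3000
    keywords_tf: tuple[str, ...] = ("transcription factor",)
    keywords_context: tuple[str, ...] = ("root",)
    random_seed: int = 0
    strand_policy: str = "both"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("p_max", "motif_p_max", "enrichment_q_max"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.upstream_length <= 0:
            raise ValueError("upstream_length must be positive")
        if self.strand_policy not in ("both", "forward"):
            raise ValueError("strand_policy must be 'both' or 'forward'")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in data.items() if k in known}
    for key in ("keywords_tf", "keywords_context"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into records, preserving file order.

    Raises :class:`FormatError` naming the offending record for empty
    sequences or duplicated ids.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        records.append(SequenceRecord(rec.id, desc, str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records in FASTA, wrapping sequence lines at ``wrap`` characters."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), wrap):
                fh.write(rec.residues[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# PWM text format: '>motif_id' header, then one whitespace-separated row of
# four numbers (A C G T; counts or frequencies) per motif position.


def read_pwm(path: str | Path) -> list[PWMDefinition]:
    pwms: list[PWMDefinition] = []
    motif_id: str | None = None
    rows: list[list[float]] = []

    def _flush() -> None:
        nonlocal rows, motif_id
        if motif_id is not None:
            if not rows:
                raise FormatError(f"{path}: motif {motif_id!r} has no matrix rows")
            pwms.append(PWMDefinition(motif_id, np.array(rows)))
        rows = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                motif_id = line[1:].split()[0] if line[1:].split() else ""
                if not motif_id:
                    raise FormatError(f"{path}:{lineno}: empty motif id")
                continue
            if motif_id is None:
                raise FormatError(f"{path}:{lineno}: matrix row before any '>' header")
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 numbers (A C G T), got {len(parts)}"
                )
            try:
                row = [float(x) for x in parts]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric entry") from exc
            if any(x < 0 for x in row):
                raise FormatError(f"{path}:{lineno}: negative matrix entry")
            rows.append(row)
    _flush()
    return pwms


def write_pwm(pwms: Iterable[PWMDefinition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\n")
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Annotation flat file


#: default positional layout of the tab-delimited annotation file
DEFAULT_ANNOTATION_COLUMNS: Mapping[str, int] = {
    "gene_id": 0,
    "term_id": 1,
    "term_name": 2,
    "aspect": 3,
    "evidence": 4,
    "slim_name": 5,
}


def read_annotation_table(path: str | Path, columns: Mapping[str, int] | None = None):
    """Parse a tab-delimited gene/GO-term annotation file.

    ``columns`` maps field names to 0-based column indices; the default
    expects gene_id, term_id, term_name, aspect, evidence[, slim_name].
    Extra columns are ignored (the TAIR slim file carries many); comment
    lines starting with ``!`` are skipped. Duplicate (gene, term) lines are
    retained — deduplication is the consumer's concern.
    """
    from .go_mining import AnnotationRecord, AnnotationTable

    cols = dict(columns or DEFAULT_ANNOTATION_COLUMNS)
    mandatory = ("gene_id", "term_id", "term_name", "aspect", "evidence")
    missing = [f for f in mandatory if f not in cols]
    if missing:
        raise FormatError(
            f"annotation schema missing columns {missing}; expected {list(mandatory)}"
        )

    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("!"):
                continue
            parts = raw.rstrip("\n").split("\t")
            needed = max(cols[f] for f in mandatory)
            if len(parts) <= needed:
                raise FormatError(
                    f"{path}:{lineno}: expected at least {needed + 1} tab-separated "
                    f"columns for fields {list(mandatory)}"
                )
            slim_idx = cols.get("slim_name")
            slim = parts[slim_idx] if slim_idx is not None and slim_idx < len(parts) else ""
            records.append(
                AnnotationRecord(
                    gene_id=parts[cols["gene_id"]],
                    term_id=parts[cols["term_id"]],
                    term_name=parts[cols["term_name"]],
                    aspect=parts[cols["aspect"]],
                    evidence=parts[cols["evidence"]],
                    slim_name=slim,
                )
            )
    return AnnotationTable(records)


# ---------------------------------------------------------------------------
# Network export


def write_network(network: nx.DiGraph, path: str | Path, dialect: str = "GraphML") -> None:
    """Export a term network as SIF (``parent<TAB>isa<TAB>child``) or GraphML.

    GraphML embeds all node and graph attributes and round-trips through
    :func:`read_network`.
    """
    dialect = dialect.lower()
    if dialect == "sif":
        with open(path, "w") as fh:
            for child, parent in network.edges():
                fh.write(f"{parent}\tisa\t{child}\n")
    elif dialect == "graphml":
        nx.write_graphml(network, str(path))
    else:
        raise ValueError(f"unknown network dialect {dialect!r}; use 'SIF' or 'GraphML'")


def read_network(path: str | Path) -> nx.DiGraph:
    return nx.read_graphml(str(path))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
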