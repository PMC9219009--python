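"""Keyword-based mining of GO annotation tables.

Identifies genes annotated with transcription-factor activity, genes
annotated to root-related processes, and their intersection — the
candidate set of context-relevant transcription factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "AnnotationRecord",
    "AnnotationTable",
    "GeneSet",
    "keyword_filter",
    "intersect_gene_sets",
    "export_gene_report",
]

_ASPECTS = {"P", "F", "C"}


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term annotation line."""

    gene_id: str
    term_id: str
    term_name: str
    aspect: str
    evidence: str
    slim_name: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id or not self.term_id:
            raise ValueError("annotation record needs non-empty gene_id and term_id")
        if self.aspect not in _ASPECTS:
            raise ValueError(f"aspect must be one of {sorted(_ASPECTS)}, got {self.aspect!r}")


@dataclass
class AnnotationTable:
    """Ordered list of annotation records; iteration order equals file order."""

    records: list[AnnotationRecord]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def genes(self) -> set[str]:
        return {r.gene_id for r in self.records}


@dataclass
class GeneSet:
    label: str
    genes: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


def keyword_filter(
    table: AnnotationTable,
    keywords: Sequence[str],
    fields: Sequence[str] = ("term_name", "slim_name"),
    word_boundary: bool = False,
) -> GeneSet:
    """Genes with at least one record matching any keyword.

    Matching is case-insensitive substring over the selected fields
    (``term_name`` and/or ``slim_name``); ``word_boundary=True`` restricts
    matches to whole words instead.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    fields = tuple(fields)
    allowed = {"term_name", "slim_name"}
    if not fields or not set(fields) <= allowed:
        raise ValueError(f"fields must be a non-empty subset of {sorted(allowed)}")

    import re

    lowered = [k.lower() for k in keywords]
    patterns = None
    if word_boundary:
        patterns = [re.compile(r"\b" + re.escape(k) + r"\b") for k in lowered]

    genes: set[str] = set()
    for rec in table:
        haystacks = [getattr(rec, f).lower() for f in fields]
        if word_boundary:
            hit = any(p.search(h) for p in patterns for h in haystacks)
        else:
            hit = any(k in h for k in lowered for h in haystacks)
        if hit:
            genes.add(rec.gene_id)
    return GeneSet(label="|".join(keywords), genes=genes)


def intersect_gene_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Set intersection; the label concatenates the inputs'."""
    return GeneSet(label=f"({a.label}) & ({b.label})", genes=a.genes & b.genes)


def matching_records(table: AnnotationTable, gene_id: str, keywords: Sequence[str]) -> list[AnnotationRecord]:
    lowered = [k.lower() for k in keywords]
    return [
        r
        for r in table
        if r.gene_id == gene_id
        and any(k in r.term_name.lower() or k in r.slim_name.lower() for k in lowered)
    ]


def export_gene_report(
    sets: Iterable[GeneSet],
    path: str | Path,
    table: AnnotationTable | None = None,
) -> None:
    """Write a TSV report: one block per gene set.

    Columns: set_label, gene_id, supporting_term_ids, matched_keyword.
    Supporting terms are looked up in ``table`` when provided.
    """
    with open(path, "w") as fh:
        fh.write("set_label\tgene_id\tsupporting_term_ids\tmatched_keyword\n")
        for gs in sets:
            keywords = [k for part in gs.label.replace("(", "").replace(")", "").split("&") for k in part.strip().split("|")]
            for gene in sorted(gs.genes):
                term_ids = ""
                matched = ""
                if table is not None:
                    recs = matching_records(table, gene, keywords) if keywords else []
                    term_ids = ",".join(sorted({r.term_id for r in recs}))
                    lowers = [k.lower() for k in keywords]
                    for r in recs:
                        for k in lowers:
                            if k in r.term_name.lower() or k in r.slim_name.lower():
                                matched = k
                                break
                        if matched:
                            break
                fh.write(f"{gs.label}\t{gene}\t{term_ids}\t{matched}\n")


def read_gene_report(path: str | Path) -> dict[str, set[str]]:
    """Inverse of :func:`export_gene_report`: label -> gene set."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            label, gene = line.rstrip("\n").split("\t")[:2]
            out.setdefault(label, set()).add(gene)
    return out
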