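"""Synthetic inputs with the statistical structure the pipeline assumes.

Every external file the analysis consumes — ontology, annotation table,
promoter FASTA, expression matrix, qPCR Ct table, segregation counts — can
be generated here with planted signal whose parameters serve as the ground
truth for recovery tests: a co-expressed gene block, AuxRE consensus
insertions in that block's promoters, an over-annotated "root"-named
ontology term, known log2 fold changes in Ct space, and binomially
segregating seed counts.

All generators are pure functions of (spec, seed): the master seed is split
into independent per-generator streams by stable labels, and promoters
additionally by gene index, so generating a subset of genes yields the same
sequences as generating all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .go_mining import AnnotationRecord, AnnotationTable
from .io_formats import PWMDefinition, SequenceRecord, write_fasta, write_pwm

__all__ = [
    "SimulationSpec",
    "CoexprBlockSpec",
    "CtSpec",
    "SegregationSpec",
    "default_auxre_pwm",
    "generate_ontology",
    "generate_annotations",
    "generate_promoters",
    "generate_expression",
    "generate_ct_table",
    "generate_segregation",
    "simulate",
]

_STREAMS = {
    "ontology": 11,
    "annotations": 23,
    "promoters": 37,
    "expression": 41,
    "ct": 53,
    "segregation": 67,
}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream], int(extra)]))


@dataclass(frozen=True)
class CoexprBlockSpec:
    """A block of genes sharing pairwise correlation ``r`` with the query."""

    n_genes: int = 20
    r: float = 0.9


@dataclass(frozen=True)
class CtSpec:
    """qPCR design: five biological x two technical replicates per line."""

    log2_fold_changes: tuple[tuple[str, float], ...] = (
        ("cRolB1", 2.0),
        ("cRolB2", 1.0),
    )
    sd: float = 0.1
    n_bio: int = 5
    n_tech: int = 2
    calibrator: str = "EV2"
    reference_gene: str = "L25"
    target_gene: str = "NtARF7"
    tissues: tuple[str, ...] = ("leaf", "stem", "root")


@dataclass(frozen=True)
class SegregationSpec:
    n_seeds: int = 150
    true_ratio: tuple[int, int] = (3, 1)
    n_lines: int = 1


@dataclass(frozen=True)
class SimulationSpec:
    seed: int = 0
    n_genes: int = 200
    n_terms: int = 60
    dag_branching: float = 2.0
    n_samples: int = 50
    coexpr_block: CoexprBlockSpec = CoexprBlockSpec()
    motif_plant_rate: float = 1.0
    promoter_length: int = 3000
    gc_content: float = 0.38
    planted_term_odds: float = 20.0
    root_name_fraction: float = 0.1
    annotation_rate: float = 2.0
    base_annotation_prob: float = 0.08
    ct_spec: CtSpec = CtSpec()
    segregation_spec: SegregationSpec = SegregationSpec()

    def __post_init__(self) -> None:
        for name in ("motif_plant_rate", "gc_content", "root_name_fraction",
                     "base_annotation_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_genes < 1 or self.n_terms < 2 or self.n_samples < 4:
            raise ValueError("counts out of range: need n_genes>=1, n_terms>=2, n_samples>=4")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")

    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]

    def block_gene_ids(self) -> list[str]:
        """The planted co-expression block; its first member is the query TF."""
        return self.gene_ids()[: self.coexpr_block.n_genes]

    def query_gene(self) -> str:
        return self.gene_ids()[0]

    def null_counterpart(self) -> "SimulationSpec":
        """Same dimensions with every planted signal removed."""
        return replace(
            self,
            coexpr_block=replace(self.coexpr_block, r=0.0),
            motif_plant_rate=0.0,
            planted_term_odds=1.0,
        )


def default_auxre_pwm(dominant: float = 0.91) -> PWMDefinition:
    """A tandem-repeat auxin-response-element matrix (TGTCTC dimer site).

    ARF dimers bind composite sites built from two TGTCTC boxes; the direct
    repeat keeps the motif informative enough for sub-1e-4 score p-values
    and is not palindromic, so strand assignments stay testable. Each
    position puts ``dominant`` probability mass on the consensus base and
    spreads the rest uniformly.
    """
    consensus = "TGTCTCTGTCTC"
    rest = (1.0 - dominant) / 3.0
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    m = np.full((len(consensus), 4), rest)
    for i, b in enumerate(consensus):
        m[i, base_index[b]] = dominant
    return PWMDefinition("AuxRE_synthetic", m)


# ---------------------------------------------------------------------------
# Ontology and annotations


def _term_ids(spec: SimulationSpec) -> list[str]:
    return [f"GO:9{i:06d}" for i in range(spec.n_terms)]


def _term_names(spec: SimulationSpec) -> list[str]:
    """Root term plus a deterministic mix of 'root'-named and generic terms."""
    rng = _rng(spec.seed, "ontology", 1)
    names = ["biological_process"]
    n_root = int(round(spec.root_name_fraction * (spec.n_terms - 1)))
    flags = np.zeros(spec.n_terms - 1, dtype=bool)
    if n_root:
        flags[rng.choice(spec.n_terms - 1, size=n_root, replace=False)] = True
    root_styles = ("root development process", "root morphogenesis process",
                   "root hair process", "lateral root process")
    for i, is_root in enumerate(flags, start=1):
        if is_root:
            names.append(f"{root_styles[i % len(root_styles)]} {i}")
        else:
            names.append(f"generic metabolic process {i}")
    return names


def planted_term(spec: SimulationSpec) -> str | None:
    """The enrichment-planting target: the last 'root'-named term, if any.

    Late terms have few or no descendants in the generated DAG, so the
    planted term keeps a small annotation count after true-path propagation
    and stays detectable.
    """
    found = None
    for tid, name in zip(_term_ids(spec), _term_names(spec)):
        if "root" in name:
            found = tid
    return found


def generate_ontology(spec: SimulationSpec, path: str | Path | None = None):
    """A single-namespace rooted DAG, acyclic by construction.

    Term i > 0 draws parents only among earlier terms, with mean out-degree
    ``dag_branching``. Returns an :class:`OntologyGraph`; also writes OBO
    when ``path`` is given.
    """
    from .enrichment_network import OntologyGraph
    import networkx as nx

    rng = _rng(spec.seed, "ontology")
    ids = _term_ids(spec)
    names = _term_names(spec)
    parents: dict[str, list[str]] = {ids[0]: []}
    for i in range(1, spec.n_terms):
        k = min(i, max(1, int(rng.poisson(max(spec.dag_branching - 1, 0)) + 1)))
        chosen = sorted(rng.choice(i, size=k, replace=False).tolist())
        parents[ids[i]] = [ids[j] for j in chosen]

    g = nx.DiGraph()
    for tid, name in zip(ids, names):
        g.add_node(tid, name=name, namespace="biological_process")
    for child, ps in parents.items():
        for p in ps:
            g.add_edge(child, p, relation="is_a")

    if path is not None:
        with open(path, "w") as fh:
            fh.write("format-version: 1.2\nontology: synthetic\n\n")
            for tid, name in zip(ids, names):
                fh.write("[Term]\n")
                fh.write(f"id: {tid}\n")
                fh.write(f"name: {name}\n")
                fh.write("namespace: biological_process\n")
                for p in parents[tid]:
                    fh.write(f"is_a: {p} ! {names[ids.index(p)]}\n")
                fh.write("\n")
    return OntologyGraph(g)


def generate_annotations(
    spec: SimulationSpec, dag=None, path: str | Path | None = None
) -> AnnotationTable:
    """Gene-to-term annotations with an optional planted enriched term.

    Each gene draws ``1 + Poisson(annotation_rate)`` terms uniformly from
    the non-root terms. The planted term is additionally annotated to
    study-pool genes (the co-expression block) with probability
    ``min(1, base_annotation_prob * planted_term_odds)`` versus
    ``base_annotation_prob`` for background genes; odds 1 is the null.
    """
    rng = _rng(spec.seed, "annotations")
    ids = _term_ids(spec)
    names = dict(zip(ids, _term_names(spec)))
    non_root = ids[1:]
    planted = planted_term(spec)
    pool = set(spec.block_gene_ids())
    p_pool = min(1.0, spec.base_annotation_prob * spec.planted_term_odds)

    records: list[AnnotationRecord] = []
    for gene in spec.gene_ids():
        k = 1 + int(rng.poisson(spec.annotation_rate))
        k = min(k, len(non_root))
        terms = set(rng.choice(len(non_root), size=k, replace=False).tolist())
        term_ids = {non_root[t] for t in terms}
        if planted is not None:
            p = p_pool if gene in pool else spec.base_annotation_prob
            if rng.random() < p:
                term_ids.add(planted)
            else:
                term_ids.discard(planted)
        for tid in sorted(term_ids):
            records.append(
                AnnotationRecord(
                    gene_id=gene,
                    term_id=tid,
                    term_name=names[tid],
                    aspect="P",
                    evidence="IEA",
                )
            )
    table = AnnotationTable(records)
    if path is not None:
        with open(path, "w") as fh:
            fh.write("! synthetic annotation table: gene_id, term_id, term_name, aspect, evidence\n")
            for r in records:
                fh.write(f"{r.gene_id}\t{r.term_id}\t{r.term_name}\t{r.aspect}\t{r.evidence}\n")
    return table


# ---------------------------------------------------------------------------
# Promoters


def motif_plant_list(spec: SimulationSpec) -> list[str]:
    """Block genes selected (deterministically) to receive a motif insert."""
    block = spec.block_gene_ids()
    if spec.motif_plant_rate <= 0:
        return []
    rng = _rng(spec.seed, "promoters", 0)
    n = int(round(spec.motif_plant_rate * len(block)))
    chosen = sorted(rng.choice(len(block), size=n, replace=False).tolist())
    return [block[i] for i in chosen]


def generate_promoters(
    spec: SimulationSpec,
    pwm: PWMDefinition,
    plant_list: Sequence[str],
    gene_ids: Sequence[str] | None = None,
    fasta_path: str | Path | None = None,
    truth_path: str | Path | None = None,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """i.i.d. promoter sequences with consensus insertions for planted genes.

    Each gene's sequence comes from its own seed stream, so generating any
    subset reproduces the same sequences. Planted genes receive one PWM
    consensus at a uniform offset on a uniformly chosen strand; the truth
    table records (gene, offset, strand).
    """
    if spec.promoter_length < pwm.width:
        raise ValueError("promoter_length shorter than motif width")
    all_genes = spec.gene_ids()
    index = {g: i for i, g in enumerate(all_genes)}
    genes = list(gene_ids) if gene_ids is not None else all_genes
    plant = set(plant_list)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    consensus = pwm.consensus()
    from .io_formats import reverse_complement

    records: list[SequenceRecord] = []
    truth_rows = []
    for g in genes:
        rng = _rng(spec.seed, "promoters", index[g] + 1)
        seq = "".join(bases[rng.choice(4, size=spec.promoter_length, p=probs)])
        if g in plant:
            offset = int(rng.integers(0, spec.promoter_length - pwm.width + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            insert = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:offset] + insert + seq[offset + pwm.width:]
            truth_rows.append({"gene": g, "offset": offset, "strand": strand})
        records.append(SequenceRecord(g, "synthetic promoter", seq))

    truth = pd.DataFrame(truth_rows, columns=["gene", "offset", "strand"])
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    if truth_path is not None:
        truth.to_csv(truth_path, sep="\t", index=False)
    return records, truth


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    spec: SimulationSpec, path: str | Path | None = None
) -> pd.DataFrame:
    """Block-correlated expression matrix (genes x samples).

    Block genes share pairwise correlation ``coexpr_block.r`` through a
    common factor; all other pairs are uncorrelated in expectation.
    """
    r = spec.coexpr_block.r
    nb = spec.coexpr_block.n_genes
    if r > 1.0 or r < -1.0 / max(nb - 1, 1):
        raise ValueError(f"block correlation {r} does not give a positive semidefinite model")
    rng = _rng(spec.seed, "expression")
    common = rng.standard_normal(spec.n_samples)
    X = rng.standard_normal((spec.n_genes, spec.n_samples))
    if r > 0:
        X[:nb] = np.sqrt(r) * common[None, :] + np.sqrt(1 - r) * X[:nb]
    df = pd.DataFrame(
        X,
        index=spec.gene_ids(),
        columns=[f"sample{j + 1:02d}" for j in range(spec.n_samples)],
    )
    if path is not None:
        df.to_csv(path, sep="\t")
    return df


# ---------------------------------------------------------------------------
# qPCR Ct table and segregation counts


def generate_ct_table(
    spec: SimulationSpec, path: str | Path | None = None
) -> pd.DataFrame:
    """Ct records implementing the comparative-Ct generative model.

    Reference Ct ~ Normal(15, sd); target Ct = reference + baseline -
    log2 fold change + noise; the calibrator line has fold change 0 in log2
    space. Technical replicates add small pipetting noise.
    """
    cs = spec.ct_spec
    rng = _rng(spec.seed, "ct")
    lines = [(cs.calibrator, 0.0)] + [(l, np.log2(f)) for l, f in cs.log2_fold_changes]
    baseline = 6.0
    sd_tech = min(cs.sd / 2, 0.05)
    rows = []
    for line, log2fc in lines:
        for tissue in cs.tissues:
            for b in range(1, cs.n_bio + 1):
                ref_ct = 15.0 + rng.normal(0.0, cs.sd)
                tgt_ct = ref_ct + baseline - log2fc + rng.normal(0.0, cs.sd)
                for t in range(1, cs.n_tech + 1):
                    for gene, ct in ((cs.reference_gene, ref_ct), (cs.target_gene, tgt_ct)):
                        rows.append(
                            {
                                "line": line,
                                "tissue": tissue,
                                "gene": gene,
                                "bio_rep": f"b{b}",
                                "tech_rep": f"t{t}",
                                "ct": ct + rng.normal(0.0, sd_tech),
                            }
                        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def generate_segregation(
    spec: SimulationSpec, path: str | Path | None = None
) -> pd.DataFrame:
    """Binomial resistant/sensitive counts under the true segregation ratio."""
    ss = spec.segregation_spec
    rng = _rng(spec.seed, "segregation")
    a, b = ss.true_ratio
    p = a / (a + b)
    rows = []
    for i in range(1, ss.n_lines + 1):
        resistant = int(rng.binomial(ss.n_seeds, p))
        rows.append(
            {
                "line": f"line{i}",
                "resistant": resistant,
                "sensitive": ss.n_seeds - resistant,
                "ratio": f"{a}:{b}",
            }
        )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def simulate(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write every synthetic input file into ``out_dir``; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pwm = default_auxre_pwm()
    paths = {
        "ontology": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "promoters": out / "promoters.fasta",
        "promoters_truth": out / "promoters.truth.tsv",
        "expression": out / "expr.tsv",
        "pwm": out / "pwm.txt",
        "ct": out / "ct.tsv",
        "segregation": out / "segregation.tsv",
    }
    generate_ontology(spec, paths["ontology"])
    generate_annotations(spec, path=paths["annotations"])
    generate_promoters(
        spec, pwm, motif_plant_list(spec),
        fasta_path=paths["promoters"], truth_path=paths["promoters_truth"],
    )
    generate_expression(spec, paths["expression"])
    write_pwm([pwm], paths["pwm"])
    generate_ct_table(spec, paths["ct"])
    generate_segregation(spec, paths["segregation"])
    return paths
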