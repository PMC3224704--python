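"""Per-pair features for same-strand adjacent genes.

Six features feed the operon classifier: a +/-1 protein-class agreement
score, the Czekanowski-Dice overlap of GO annotations, an information-
content (Lin) GO similarity, gene-order conservation counts across genomes,
intergenic distance in bp, and Pearson correlation of expression profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

FEATURE_NAMES = (
    "class_score",
    "cd_score",
    "ic_similarity",
    "conservation",
    "distance_bp",
    "r",
)


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene. Coordinates are 1-based inclusive; strand '+'/'-'."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_class: str | None = None
    go_terms: frozenset[str] = frozenset()
    regulator: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        object.__setattr__(self, "go_terms", frozenset(self.go_terms))


@dataclass
class GenePair:
    """An adjacent same-strand pair, oriented in transcription direction."""

    upstream: GeneRecord
    downstream: GeneRecord

    @property
    def key(self) -> frozenset:
        return frozenset((self.upstream.gene_id, self.downstream.gene_id))


def same_strand_adjacent_pairs(genes: Sequence[GeneRecord]) -> list[GenePair]:
    """Pairs of consecutive same-contig, same-strand genes.

    Input must be sorted by (contig, start). On the minus strand the
    upstream gene in transcription direction is the one with larger
    coordinates.
    """
    for i in range(1, len(genes)):
        a, b = genes[i - 1], genes[i]
        if a.contig_id == b.contig_id and a.start > b.start:
            raise ValueError("genes must be sorted by contig then start")
    pairs = []
    for a, b in zip(genes, genes[1:]):
        if a.contig_id != b.contig_id or a.strand != b.strand:
            continue
        if a.strand == "+":
            pairs.append(GenePair(a, b))
        else:
            pairs.append(GenePair(b, a))
    return pairs


def protein_class_score(class_a: str | None, class_b: str | None) -> float:
    """+1 same class, -1 different, NaN when either gene is unclassified."""
    if class_a is None or class_b is None:
        return math.nan
    return 1.0 if class_a == class_b else -1.0


def czekanowski_dice(terms_a: Iterable[str], terms_b: Iterable[str]) -> float:
    """2c/(a+b) term-set overlap; NaN when either set is empty."""
    sa, sb = set(terms_a), set(terms_b)
    if not sa or not sb:
        return math.nan
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


class TermDAG:
    """A rooted is-a DAG over ontology terms with corpus annotation counts.

    ``term_freq`` maps term -> number of direct corpus annotations; the
    frequency used for information content includes all descendants.
    IC(t) = -ln(cumfreq(t) / cumfreq(root)), so IC(root) = 0.
    """

    def __init__(self, parents: Mapping[str, Iterable[str]], term_freq: Mapping[str, float]):
        g = nx.DiGraph()
        for child, ps in parents.items():
            g.add_node(child)
            for p in ps:
                g.add_edge(child, p)  # edge child -> parent
        for t in term_freq:
            g.add_node(t)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(f"expected one root, found {roots}")
        self.root = roots[0]
        self.graph = g
        self._ancestors = {t: frozenset(nx.descendants(g, t)) | {t} for t in g.nodes}
        cum: dict[str, float] = {}
        for t in g.nodes:
            below = nx.ancestors(g, t) | {t}  # children side (edges point rootward)
            cum[t] = float(sum(term_freq.get(x, 0.0) for x in below))
        total = cum[self.root]
        if total <= 0:
            raise ValueError("corpus counts are empty")
        self._ic = {t: (-math.log(cum[t] / total) if cum[t] > 0 else math.inf) for t in g.nodes}

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def ic(self, term: str) -> float:
        if term not in self.graph:
            raise KeyError(f"term {term!r} not in ontology")
        return self._ic[term]

    def lin(self, t1: str, t2: str) -> float:
        """Lin similarity 2*IC(MICA)/(IC(t1)+IC(t2)), in [0,1]."""
        for t in (t1, t2):
            if t not in self.graph:
                raise KeyError(f"term {t!r} not in ontology")
        common = self._ancestors[t1] & self._ancestors[t2]
        mica_ic = max(self._ic[a] for a in common)
        denom = self._ic[t1] + self._ic[t2]
        if denom == 0 or not math.isfinite(denom):
            return 1.0 if (t1 == t2 and math.isfinite(self._ic[t1])) else 0.0
        return max(0.0, min(1.0, 2.0 * mica_ic / denom))


def ic_similarity(terms_a: Iterable[str], terms_b: Iterable[str], dag: TermDAG) -> float:
    """Best-match-average Lin similarity between two term sets; NaN if either empty."""
    sa, sb = sorted(set(terms_a)), sorted(set(terms_b))
    if not sa or not sb:
        return math.nan
    sim = np.array([[dag.lin(x, y) for y in sb] for x in sa])
    return float((sim.max(axis=1).mean() + sim.max(axis=0).mean()) / 2.0)


def intergenic_distance(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """Gap length in bp between the pair in transcription order.

    0 for abutting genes, negative when coding regions overlap.
    """
    if upstream.contig_id != downstream.contig_id:
        raise ValueError("pair spans contigs")
    if upstream.strand != downstream.strand:
        raise ValueError("pair spans strands")
    if upstream.strand == "+":
        return downstream.start - upstream.end - 1
    return upstream.start - downstream.end - 1


def expression_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; NaN on zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("profiles must be equal-length 1-D with >= 3 samples")
    if x.std() == 0 or y.std() == 0:
        return math.nan
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))


@dataclass
class ConservationTable:
    """Unordered adjacent-pair -> count of genomes conserving the gene order."""

    counts: dict[frozenset, int] = field(default_factory=dict)

    def get(self, gene_a: str, gene_b: str) -> int:
        return int(self.counts.get(frozenset((gene_a, gene_b)), 0))

    @classmethod
    def from_tsv(cls, path) -> "ConservationTable":
        """Columns: gene_a, gene_b, probability (ignored), genome_count."""
        df = pd.read_csv(path, sep="\t")
        counts = {}
        for row in df.itertuples(index=False):
            counts[frozenset((str(row[0]), str(row[1])))] = int(row[3])
        return cls(counts)


def read_annotation_table(path) -> list[GeneRecord]:
    """Annotation TSV: gene_id, contig, start, end, strand, protein_class, go_terms, regulator.

    go_terms are semicolon-separated; empty protein_class/go fields mean
    unannotated. Rows are returned sorted by (contig, start).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    genes = []
    for row in df.itertuples(index=False):
        cls_ = row.protein_class or None
        gos = frozenset(t for t in str(row.go_terms).split(";") if t)
        genes.append(
            GeneRecord(
                gene_id=row.gene_id, contig_id=row.contig, start=int(row.start),
                end=int(row.end), strand=row.strand, protein_class=cls_,
                go_terms=gos, regulator=str(row.regulator).lower() in ("1", "true", "yes"),
            )
        )
    genes.sort(key=lambda g: (g.contig_id, g.start))
    return genes


def write_annotation_table(genes: Sequence[GeneRecord], path) -> None:
    rows = [
        {
            "gene_id": g.gene_id, "contig": g.contig_id, "start": g.start, "end": g.end,
            "strand": g.strand, "protein_class": g.protein_class or "",
            "go_terms": ";".join(sorted(g.go_terms)), "regulator": int(g.regulator),
        }
        for g in genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_training_table(path) -> dict[frozenset, str]:
    """Training TSV: gene_a, gene_b, label in {KOP, NOP}."""
    df = pd.read_csv(path, sep="\t")
    labels = {}
    for row in df.itertuples(index=False):
        label = str(row[2]).upper()
        if label not in ("KOP", "NOP"):
            raise ValueError(f"bad label {label!r}")
        labels[frozenset((str(row[0]), str(row[1])))] = label
    return labels


def assemble_features(
    pairs: Sequence[GenePair],
    conservation: ConservationTable,
    expr: pd.DataFrame | None,
    selected_genes: set[str] | None = None,
    training_labels: Mapping[frozenset, str] | None = None,
    go_dag: TermDAG | None = None,
    namespaces: Mapping[str, set[str]] | None = None,
) -> pd.DataFrame:
    """One feature row per pair; index 'up~down'; NaN marks missing features.

    ``namespaces`` optionally maps namespace label -> term set; CD and IC
    similarities are then averaged over namespaces in which both genes are
    annotated. ``expr`` is the standardized concatenated matrix (genes x
    samples); correlation is missing for genes that failed selection.
    """
    training_labels = dict(training_labels or {})
    pair_keys = {p.key for p in pairs}
    for key in training_labels:
        if key not in pair_keys:
            raise ValueError(f"training label on non-adjacent/different-strand pair {sorted(key)}")
    rows = []
    index = []
    for p in pairs:
        u, d = p.upstream, p.downstream
        if namespaces:
            cds, ics = [], []
            for ns_terms in namespaces.values():
                ta, tb = u.go_terms & ns_terms, d.go_terms & ns_terms
                if ta and tb:
                    cds.append(czekanowski_dice(ta, tb))
                    if go_dag is not None:
                        ics.append(ic_similarity(ta, tb, go_dag))
            cd = float(np.mean(cds)) if cds else math.nan
            ic = float(np.mean(ics)) if ics else math.nan
        else:
            cd = czekanowski_dice(u.go_terms, d.go_terms)
            ic = ic_similarity(u.go_terms, d.go_terms, go_dag) if go_dag is not None else math.nan
        if expr is not None and u.gene_id in expr.index and d.gene_id in expr.index and (
            selected_genes is None or (u.gene_id in selected_genes and d.gene_id in selected_genes)
        ):
            r = expression_correlation(expr.loc[u.gene_id].to_numpy(), expr.loc[d.gene_id].to_numpy())
        else:
            r = math.nan
        rows.append(
            {
                "class_score": protein_class_score(u.protein_class, d.protein_class),
                "cd_score": cd,
                "ic_similarity": ic,
                "conservation": conservation.get(u.gene_id, d.gene_id),
                "distance_bp": intergenic_distance(u, d),
                "r": r,
                "label": training_labels.get(p.key, ""),
                "upstream": u.gene_id,
                "downstream": d.gene_id,
            }
        )
        index.append(f"{u.gene_id}~{d.gene_id}")
    df = pd.DataFrame(rows, index=index)
    return df
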