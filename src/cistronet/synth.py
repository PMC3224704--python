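"""Seeded synthetic data with known ground truth.

Emulates the statistical structure the pipeline assumes: operons of
geometric length with short internal and long boundary gaps, annotation
sharing and elevated gene-order conservation inside true operons, a
three-platform expression compendium in which member genes echo their
cistron's latent profile and target cistrons depend (linearly or
nonlinearly) on their hub regulator, and promoter regions carrying a
planted consensus motif in every member of each true module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import rng_for
from .compendium import PLATFORMS, ExpressionDataset
from .features import GeneRecord, TermDAG
from .operons import OperonMap

BACKGROUND_ACGT = (0.153, 0.351, 0.347, 0.149)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic compendium (defaults = test scale)."""

    n_genes: int = 1000
    operon_len_mean: float = 2.0          # geometric mean operon size
    gap_within_mean: float = 20.0         # bp, within-operon intergenic gap
    gap_between_mean: float = 150.0       # bp, operon-boundary gap
    gene_len_range: tuple[int, int] = (600, 1200)
    n_regulators: int = 60
    targets_per_regulator_mean: float = 8.0
    n_samples: tuple[int, int, int] = (70, 70, 60)
    noise_sd: float = 0.3                 # per-gene noise around the cistron latent
    link_noise_sd: float = 0.25           # dependency noise hub -> target
    nonlinear_fraction: float = 0.25      # fraction of quadratic/sigmoidal links
    absent_rate: float = 0.05
    oligo_coverage: float = 0.9           # fraction of genes with a probeset
    p_share: float = 0.72                 # annotation sharing within operons
    unclassified_rate: float = 0.15
    n_protein_classes: int = 25
    conservation_mean_operon: float = 12.0
    conservation_mean_boundary: float = 1.0
    motif_width: int = 8
    motif_identity: float = 0.9           # per-column consensus identity probability
    upstream_length: int = 300
    background: tuple[float, float, float, float] = BACKGROUND_ACGT
    n_kop_train: int = 425
    n_nop_train: int = 131


@dataclass
class TruthRegistry:
    """Ground truth recorded alongside the generated data."""

    operon_map: OperonMap = None
    cistron_of_gene: dict[str, str] = field(default_factory=dict)
    cistron_members: dict[str, list[str]] = field(default_factory=dict)
    regulator_cistrons: list[str] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)        # (hub, target)
    link_types: dict[tuple[str, str], str] = field(default_factory=dict)
    latent: pd.DataFrame | None = None                              # cistron x sample
    clean_genes: pd.DataFrame | None = None                         # gene x sample
    motif_consensus: dict[str, str] = field(default_factory=dict)   # hub -> consensus
    motif_placements: dict[str, dict[str, int]] = field(default_factory=dict)
    contig_length: int = 0


def generate_genome(cfg: SyntheticConfig, seed: int) -> tuple[list[GeneRecord], TruthRegistry]:
    """Lay operons of geometric length along one contig; record the truth map."""
    if cfg.n_genes < 10:
        raise ValueError("need >= 10 genes")
    rng = rng_for(seed, "genome")
    truth = TruthRegistry()
    genes: list[GeneRecord] = []
    units: list[list[str]] = []
    cursor = cfg.upstream_length + 200  # leave room for the first upstream window
    gid = 0
    p_geom = min(1.0, 1.0 / cfg.operon_len_mean)
    while gid < cfg.n_genes:
        size = min(int(rng.geometric(p_geom)), cfg.n_genes - gid)
        strand = "+" if rng.random() < 0.5 else "-"
        ids = []
        for j in range(size):
            length = int(rng.integers(cfg.gene_len_range[0], cfg.gene_len_range[1] + 1))
            start = cursor
            end = cursor + length - 1
            gene_id = f"g{gid + 1:05d}"
            genes.append(GeneRecord(gene_id, "chr", start, end, strand))
            ids.append(gene_id)
            gid += 1
            gap = int(rng.geometric(1.0 / (cfg.gap_within_mean + 1.0))) - 1
            cursor = end + 1 + gap
        # boundary gap replaces the trailing within-gap
        cursor = genes[-1].end + 1 + int(rng.geometric(1.0 / (cfg.gap_between_mean + 1.0))) - 1
        units.append(ids if strand == "+" else list(reversed(ids)))
    truth.operon_map = OperonMap(units)
    for i, unit in enumerate(units):
        cid = f"TU{i + 1:05d}"
        truth.cistron_members[cid] = list(unit)
        for g in unit:
            truth.cistron_of_gene[g] = cid
    n_reg = min(cfg.n_regulators, len(units))
    chosen = rng.choice(len(units), size=n_reg, replace=False)
    truth.regulator_cistrons = sorted(f"TU{i + 1:05d}" for i in chosen)
    truth.contig_length = genes[-1].end + cfg.upstream_length + 200
    return genes, truth


def build_toy_go_dag(cfg: SyntheticConfig) -> tuple[TermDAG, dict[str, set[str]], dict[str, list[str]]]:
    """Three-level toy ontology: root -> 2 namespaces -> mid terms -> leaves."""
    parents: dict[str, list[str]] = {"GO:BP": ["GO:ROOT"], "GO:MF": ["GO:ROOT"]}
    namespaces: dict[str, set[str]] = {"BP": set(), "MF": set()}
    leaves: dict[str, list[str]] = {"BP": [], "MF": []}
    freq: dict[str, float] = {}
    for ns in ("BP", "MF"):
        for i in range(8):
            mid = f"GO:{ns}:{i:02d}"
            parents[mid] = [f"GO:{ns}"]
            namespaces[ns].add(mid)
            for j in range(5):
                leaf = f"GO:{ns}:{i:02d}:{j}"
                parents[leaf] = [mid]
                namespaces[ns].add(leaf)
                leaves[ns].append(leaf)
                freq[leaf] = 1.0 + (i + j) % 3  # uneven corpus counts
    dag = TermDAG(parents, freq)
    return dag, namespaces, leaves


def generate_annotations(
    genes: Sequence[GeneRecord], truth: TruthRegistry, cfg: SyntheticConfig, seed: int
) -> tuple[list[GeneRecord], pd.DataFrame, TermDAG, dict[str, set[str]]]:
    """Attach protein classes, GO terms, regulator flags; emit a conservation table.

    Within-operon neighbors share class and GO terms with probability
    ``p_share``; conservation counts are Poisson with a higher mean for
    true-operon pairs than for operon-boundary pairs.
    """
    rng = rng_for(seed, "annotations")
    dag, namespaces, leaves = build_toy_go_dag(cfg)
    classes = [f"class_{i:03d}" for i in range(cfg.n_protein_classes)]
    regulator_genes = {truth.cistron_members[c][0] for c in truth.regulator_cistrons}
    annotated: list[GeneRecord] = []
    by_unit = {}
    for i, unit in enumerate(truth.operon_map.transcription_units):
        cid = f"TU{i + 1:05d}"
        unit_class = classes[int(rng.integers(len(classes)))]
        unit_terms = {
            ns: frozenset(rng.choice(leaves[ns], size=2, replace=False)) for ns in ("BP", "MF")
        }
        by_unit[cid] = (unit_class, unit_terms)
    for g in genes:
        cid = truth.cistron_of_gene[g.gene_id]
        unit_class, unit_terms = by_unit[cid]
        if rng.random() < cfg.unclassified_rate:
            cls = None
        elif rng.random() < cfg.p_share:
            cls = unit_class
        else:
            cls = classes[int(rng.integers(len(classes)))]
        terms: set[str] = set()
        for ns in ("BP", "MF"):
            if rng.random() < cfg.p_share:
                terms |= unit_terms[ns]
            else:
                terms |= set(rng.choice(leaves[ns], size=2, replace=False))
        annotated.append(
            GeneRecord(g.gene_id, g.contig_id, g.start, g.end, g.strand,
                       protein_class=cls, go_terms=frozenset(terms),
                       regulator=g.gene_id in regulator_genes)
        )
    # conservation for every same-strand adjacent pair
    from .features import same_strand_adjacent_pairs

    rows = []
    for p in same_strand_adjacent_pairs(annotated):
        same_unit = truth.cistron_of_gene[p.upstream.gene_id] == truth.cistron_of_gene[p.downstream.gene_id]
        mean = cfg.conservation_mean_operon if same_unit else cfg.conservation_mean_boundary
        count = int(rng.poisson(mean))
        rows.append({"gene_a": p.upstream.gene_id, "gene_b": p.downstream.gene_id,
                     "probability": round(float(rng.random()), 3), "genome_count": count})
    conservation = pd.DataFrame(rows)
    go_universe = {ns: {t for t in namespaces[ns]} for ns in namespaces}
    return annotated, conservation, dag, go_universe


def generate_expression(
    truth: TruthRegistry, cfg: SyntheticConfig, seed: int
) -> dict[str, ExpressionDataset]:
    """Three platform datasets with planted hub->target dependencies.

    Regulator cistron latents are i.i.d. standard normal across samples;
    each target's latent is a (possibly nonlinear) function of its hub plus
    dependency noise; member genes add i.i.d. measurement noise. Absent
    calls are sprinkled at ``absent_rate``; the oligo platform covers a
    random ``oligo_coverage`` subset of genes.
    """
    rng = rng_for(seed, "expression")
    n_total = int(sum(cfg.n_samples))
    cistrons = sorted(truth.cistron_members)
    regs = list(truth.regulator_cistrons)
    non_regs = [c for c in cistrons if c not in set(regs)]
    # assign disjoint target sets per regulator
    pool = list(non_regs)
    rng.shuffle(pool)
    truth.edges = set()
    truth.link_types = {}
    pos = 0
    for hub in regs:
        k = max(1, int(rng.poisson(cfg.targets_per_regulator_mean)))
        targets = pool[pos:pos + k]
        pos += len(targets)
        for t in targets:
            truth.edges.add((hub, t))
            if rng.random() < cfg.nonlinear_fraction:
                truth.link_types[(hub, t)] = "quadratic" if rng.random() < 0.5 else "sigmoid"
            else:
                truth.link_types[(hub, t)] = "linear"
    latent = pd.DataFrame(
        rng.standard_normal((len(cistrons), n_total)), index=cistrons,
        columns=[f"s{j + 1:03d}" for j in range(n_total)],
    )
    for (hub, t), kind in truth.link_types.items():
        x = latent.loc[hub].to_numpy()
        if kind == "linear":
            y = x.copy()
        elif kind == "quadratic":
            y = (x * x - 1.0) / np.sqrt(2.0)
        else:
            y = np.tanh(2.0 * x)
            y = (y - y.mean()) / y.std()
        y = y + cfg.link_noise_sd * rng.standard_normal(n_total)
        latent.loc[t] = (y - y.mean()) / y.std()
    truth.latent = latent
    gene_ids = sorted(truth.cistron_of_gene)
    clean = np.empty((len(gene_ids), n_total))
    for i, g in enumerate(gene_ids):
        base = latent.loc[truth.cistron_of_gene[g]].to_numpy()
        clean[i] = base + cfg.noise_sd * rng.standard_normal(n_total)
    truth.clean_genes = pd.DataFrame(clean, index=gene_ids, columns=latent.columns)

    datasets: dict[str, ExpressionDataset] = {}
    col0 = 0
    n_oligo = int(round(cfg.oligo_coverage * len(gene_ids)))
    oligo_genes = sorted(rng.choice(gene_ids, size=n_oligo, replace=False))
    for platform, n_s in zip(PLATFORMS, cfg.n_samples):
        cols = latent.columns[col0:col0 + n_s]
        col0 += n_s
        rows = oligo_genes if platform == "oligo_chip" else gene_ids
        vals = truth.clean_genes.loc[rows, cols].copy()
        mask = pd.DataFrame(
            rng.random((len(rows), n_s)) < cfg.absent_rate, index=rows, columns=cols
        )
        # never mask out an entire gene
        all_absent = mask.all(axis=1)
        for g in mask.index[all_absent]:
            mask.loc[g, cols[int(rng.integers(n_s))]] = False
        vals = vals.mask(mask)
        datasets[platform] = ExpressionDataset(platform, vals, mask)
    return datasets


def generate_promoters(
    genes: Sequence[GeneRecord], truth: TruthRegistry, cfg: SyntheticConfig, seed: int
) -> dict[str, str]:
    """Background-sampled genome with one motif instance per module member.

    For each regulator module (hub + its targets), a consensus of width
    ``motif_width`` is drawn and an instance (each column matching the
    consensus with probability ``motif_identity``, otherwise background) is
    written at a uniform offset inside each member's upstream window.
    """
    if cfg.upstream_length < cfg.motif_width:
        raise ValueError("motif wider than the upstream window")
    rng = rng_for(seed, "promoters")
    bases = np.array(list("ACGT"))
    bg = np.asarray(cfg.background, dtype=float)
    genome = rng.choice(bases, size=truth.contig_length, p=bg / bg.sum())
    by_id = {g.gene_id: g for g in genes}
    truth.motif_consensus = {}
    truth.motif_placements = {}
    W = cfg.motif_width
    for hub in truth.regulator_cistrons:
        members = [hub] + sorted(t for h, t in truth.edges if h == hub)
        consensus = "".join(rng.choice(bases, size=W))
        truth.motif_consensus[hub] = consensus
        placements = {}
        for cid in members:
            leader = by_id[truth.cistron_members[cid][0]]
            offset = int(rng.integers(0, cfg.upstream_length - W + 1))
            instance = [
                c if rng.random() < cfg.motif_identity else str(rng.choice(bases))
                for c in consensus
            ]
            if leader.strand == "+":
                # upstream window is [start-1-L, start-1) 0-based; offset from its 5' end
                w0 = (leader.start - 1) - cfg.upstream_length
                gpos = w0 + offset
                genome[gpos:gpos + W] = list(instance)
            else:
                # window is [end, end+L) 0-based, read reverse-complemented
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                rc = [comp[c] for c in reversed(instance)]
                gpos = leader.end + cfg.upstream_length - offset - W
                genome[gpos:gpos + W] = rc
            placements[cid] = offset
        truth.motif_placements[hub] = placements
    return {"chr": "".join(genome)}


def generate_training_set(
    genes: Sequence[GeneRecord], truth: TruthRegistry, cfg: SyntheticConfig, seed: int
) -> dict[frozenset, str]:
    """Sample KOP/NOP labels from the truth map's within/boundary pairs."""
    from .features import same_strand_adjacent_pairs

    rng = rng_for(seed, "training")
    within, boundary = [], []
    for p in same_strand_adjacent_pairs(list(genes)):
        key = p.key
        same = truth.cistron_of_gene[p.upstream.gene_id] == truth.cistron_of_gene[p.downstream.gene_id]
        (within if same else boundary).append(key)
    n_kop = min(cfg.n_kop_train, len(within))
    n_nop = min(cfg.n_nop_train, len(boundary))
    labels: dict[frozenset, str] = {}
    for idx in rng.choice(len(within), size=n_kop, replace=False):
        labels[within[idx]] = "KOP"
    for idx in rng.choice(len(boundary), size=n_nop, replace=False):
        labels[boundary[idx]] = "NOP"
    return labels


def write_genome_fasta(genome: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for contig, seq in genome.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_training_table(labels: dict[frozenset, str], path) -> None:
    rows = []
    for key, label in sorted(labels.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        rows.append({"gene_a": a, "gene_b": b, "label": label})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
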