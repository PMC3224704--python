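"""End-to-end orchestration: simulate -> compendium -> operons -> network -> modules.

Every stage persists plain-text artifacts (TSV/FASTA/SIF/JSON) under the
output directory, so any stage can be rerun in isolation from the previous
stage's files. A single master seed drives all randomness; per-stage seeds
are derived deterministically.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import compendium as comp
from . import features as feat
from . import modules as mod
from . import motifs as mot
from . import network as net
from . import operons as ops
from . import synth
from ._util import stage_seed

log = logging.getLogger("cistronet")

STAGES = ("simulate", "compendium", "operons", "network", "modules")


class PipelineConfig(BaseModel):
    """Validated pipeline settings; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    outdir: str = "cistronet_out"
    seed: int = 0
    # compendium
    absent_sentinel: str = "NA"
    absent_strict: float = 0.20
    absent_loose: float = 0.50
    sd_percentile: float = 25.0
    knn_k: int = 15
    # operon model
    kernel: str = "radial"
    svm_c: float = 1.0
    class_weight: str | None = None
    feature_subset: list[str] = Field(default_factory=lambda: list(feat.FEATURE_NAMES))
    # network
    p_threshold: float = 1.0e-9
    dpi_tolerance: float = 0.05
    n_null_permutations: int = 100_000
    bw_factor: float = 0.5
    # module analysis
    upstream_length: int = 300
    n_shuffles: int = 5
    p_enrich: float = 1.0e-4
    fdr: float = 0.01
    motif_width_min: int = 6
    motif_width_max: int = 24
    motif_restarts: int = 20
    n_motif_modules: int | None = None   # screen only the N highest-degree modules
    # synthetic data
    synthetic: dict = Field(default_factory=dict)

    @field_validator("dpi_tolerance")
    @classmethod
    def _dpi_range(cls, v):
        if not 0.0 <= v < 1.0:
            raise ValueError("dpi_tolerance must be in [0,1)")
        return v

    @field_validator("p_threshold", "p_enrich", "fdr")
    @classmethod
    def _prob_range(cls, v):
        if not 0.0 < v <= 1.0:
            raise ValueError("probability settings must be in (0,1]")
        return v

    @field_validator("kernel")
    @classmethod
    def _kernel(cls, v):
        if v not in ("linear", "radial"):
            raise ValueError("kernel must be 'linear' or 'radial'")
        return v


def validate_config(path) -> PipelineConfig:
    """Load and validate a YAML config; defaults injected for absent keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    sdir = out / "sim"
    sdir.mkdir(parents=True, exist_ok=True)
    scfg = synth.SyntheticConfig(**cfg.synthetic)
    genes, truth = synth.generate_genome(scfg, cfg.seed)
    genes, conservation, dag, namespaces = synth.generate_annotations(genes, truth, scfg, cfg.seed)
    datasets = synth.generate_expression(truth, scfg, cfg.seed)
    genome = synth.generate_promoters(genes, truth, scfg, cfg.seed)
    labels = synth.generate_training_set(genes, truth, scfg, cfg.seed)

    feat.write_annotation_table(genes, sdir / "annotation.tsv")
    conservation.to_csv(sdir / "conservation.tsv", sep="\t", index=False)
    for platform, ds in datasets.items():
        comp.write_expression_table(ds, sdir / f"expr_{platform}.tsv", cfg.absent_sentinel)
    (sdir / "probeset.txt").write_text(
        "\n".join(datasets["oligo_chip"].gene_ids) + "\n")
    synth.write_genome_fasta(genome, sdir / "genome.fasta")
    synth.write_training_table(labels, sdir / "training.tsv")
    dag_doc = {
        "parents": {t: sorted(dag.graph.successors(t)) for t in dag.graph.nodes},
        "freq": {},
        "namespaces": {k: sorted(v) for k, v in namespaces.items()},
    }
    _, _, leaves = synth.build_toy_go_dag(scfg)
    dag_doc["freq"] = {t: 1.0 + (int(t.split(":")[2]) + int(t.split(":")[3])) % 3
                       for ns in leaves for t in leaves[ns]}
    _write_json(dag_doc, sdir / "go_dag.json")
    truth_doc = {
        "transcription_units": truth.operon_map.transcription_units,
        "regulator_cistrons": truth.regulator_cistrons,
        "edges": sorted(map(list, truth.edges)),
        "link_types": {f"{h}->{t}": k for (h, t), k in truth.link_types.items()},
        "motif_consensus": truth.motif_consensus,
        "motif_placements": truth.motif_placements,
    }
    _write_json(truth_doc, sdir / "truth.json")


def _load_dag(path) -> tuple[feat.TermDAG, dict[str, set[str]]]:
    doc = json.loads(Path(path).read_text())
    dag = feat.TermDAG(doc["parents"], doc["freq"])
    namespaces = {k: set(v) for k, v in doc["namespaces"].items()}
    return dag, namespaces


def _stage_compendium(cfg: PipelineConfig, out: Path) -> None:
    sdir = out / "sim"
    cdir = out / "compendium"
    cdir.mkdir(parents=True, exist_ok=True)
    datasets = {}
    for platform in comp.PLATFORMS:
        path = sdir / f"expr_{platform}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing {path}; rerun the simulate stage")
        datasets[platform] = comp.read_expression_table(path, platform, cfg.absent_sentinel)
    probeset = (sdir / "probeset.txt").read_text().split()
    thresholds = comp.FilterThresholds(cfg.absent_strict, cfg.absent_loose, cfg.sd_percentile)
    matrix, selected = comp.prepare_compendium(datasets, probeset, thresholds, k=cfg.knn_k)
    comp.write_expression_table(matrix, cdir / "matrix.tsv", cfg.absent_sentinel)
    (cdir / "selected_genes.txt").write_text("\n".join(sorted(selected)) + "\n")


def _assemble_all_features(cfg: PipelineConfig, out: Path):
    sdir = out / "sim"
    genes = feat.read_annotation_table(sdir / "annotation.tsv")
    conservation = feat.ConservationTable.from_tsv(sdir / "conservation.tsv")
    labels = feat.read_training_table(sdir / "training.tsv")
    dag, namespaces = _load_dag(sdir / "go_dag.json")
    matrix = comp.read_expression_table(out / "compendium" / "matrix.tsv",
                                        "concat", cfg.absent_sentinel)
    selected = set((out / "compendium" / "selected_genes.txt").read_text().split())
    pairs = feat.same_strand_adjacent_pairs(genes)
    ns_terms = {ns: {t for t in terms} for ns, terms in namespaces.items()}
    table = feat.assemble_features(pairs, conservation, matrix.values, selected,
                                   labels, go_dag=dag, namespaces=ns_terms)
    return genes, pairs, table, matrix, selected


def _stage_operons(cfg: PipelineConfig, out: Path) -> None:
    odir = out / "operons"
    odir.mkdir(parents=True, exist_ok=True)
    if not (out / "compendium" / "matrix.tsv").exists():
        raise FileNotFoundError("missing compendium matrix; rerun the compendium stage")
    genes, pairs, table, _, _ = _assemble_all_features(cfg, out)
    model = ops.train_classifier(table, feature_subset=tuple(cfg.feature_subset),
                                 kernel=cfg.kernel, C=cfg.svm_c,
                                 class_weight=cfg.class_weight)
    scores = ops.predict_genome(model, table)
    calls = {p.key: bool(scores.loc[f"{p.upstream.gene_id}~{p.downstream.gene_id}"] > 0)
             for p in pairs}
    operon_map = ops.chain_operons(genes, calls)
    scores.rename("score").to_csv(odir / "pair_scores.tsv", sep="\t", index_label="pair")
    operon_map.to_tsv(odir / "operon_map.tsv")
    operon_map.to_gff3(odir / "operon_map.gff3", genes)


def _read_operon_map(path) -> ops.OperonMap:
    df = pd.read_csv(path, sep="\t")
    units: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        units.setdefault(row.operon_id, []).append(row.gene_id)
    return ops.OperonMap([units[k] for k in sorted(units)])


def _stage_network(cfg: PipelineConfig, out: Path) -> None:
    ndir = out / "network"
    ndir.mkdir(parents=True, exist_ok=True)
    if not (out / "operons" / "operon_map.tsv").exists():
        raise FileNotFoundError("missing operon map; rerun the operons stage")
    genes = feat.read_annotation_table(out / "sim" / "annotation.tsv")
    operon_map = _read_operon_map(out / "operons" / "operon_map.tsv")
    matrix = comp.read_expression_table(out / "compendium" / "matrix.tsv",
                                        "concat", cfg.absent_sentinel)
    selected = set((out / "compendium" / "selected_genes.txt").read_text().split())
    cistrons = net.aggregate_cistron_expression(operon_map, matrix, selected)
    regulators = net.select_regulator_cistrons(cistrons, genes)
    network = net.build_network(
        cistrons, regulators,
        net.NetworkConfig(cfg.p_threshold, cfg.dpi_tolerance,
                          cfg.n_null_permutations, bw_factor=cfg.bw_factor),
        seed=stage_seed(cfg.seed, "mi_null"),
    )
    network.to_sif(ndir / "edges.sif")
    network.module_mi_table().to_csv(ndir / "module_mi.tsv", sep="\t", index=False)
    modules = net.extract_modules(network)
    _write_json({m.module_id: {"hub": m.hub, "members": m.members} for m in modules},
                ndir / "modules.json")
    _write_json({"members": cistrons.members}, ndir / "cistron_members.json")
    try:
        fit = net.fit_degree_powerlaw(network)
        _write_json({"coefficient": fit.coefficient, "exponent": fit.exponent},
                    ndir / "degree_fit.json")
    except ValueError as e:
        _write_json({"error": str(e)}, ndir / "degree_fit.json")


def _stage_modules(cfg: PipelineConfig, out: Path) -> None:
    mdir = out / "modules"
    mdir.mkdir(parents=True, exist_ok=True)
    ndir = out / "network"
    if not (ndir / "modules.json").exists():
        raise FileNotFoundError("missing network modules; rerun the network stage")
    genes = feat.read_annotation_table(out / "sim" / "annotation.tsv")
    operon_map = _read_operon_map(out / "operons" / "operon_map.tsv")
    modules_doc = json.loads((ndir / "modules.json").read_text())
    members_doc = json.loads((ndir / "cistron_members.json").read_text())["members"]
    modules = [net.NetworkModule(mid, d["hub"], d["members"])
               for mid, d in sorted(modules_doc.items())]
    by_gene = {g.gene_id: g for g in genes}
    universe = sorted(members_doc)
    class_map = {c: {by_gene[g].protein_class for g in mem if by_gene[g].protein_class}
                 for c, mem in members_doc.items()}
    go_map = {c: set().union(*(by_gene[g].go_terms for g in mem)) if mem else set()
              for c, mem in members_doc.items()}
    results: list[mod.EnrichmentResult] = []
    for scheme_map in (class_map, go_map):
        scheme_results = []
        for m in modules:
            in_matrix = [c for c in m.members if c in members_doc]
            scheme_results.extend(
                mod.fisher_enrichment(in_matrix, scheme_map, universe, module_id=m.module_id))
        mod.attach_qvalues(scheme_results, seed=stage_seed(cfg.seed, "qvalue"))
        results.extend(scheme_results)
    mod.enrichment_table(results).to_csv(mdir / "enrichment.tsv", sep="\t", index=False)

    genome = mod.load_genome(out / "sim" / "genome.fasta")
    # background from the upstream regions of ALL predicted cistrons
    all_upstreams = []
    for i, unit in enumerate(operon_map.transcription_units):
        all_upstreams.append(mod.extract_upstream(unit, operon_map, genes, genome,
                                                  cfg.upstream_length))
    background = mot.background_from_upstreams(all_upstreams)
    screen = modules
    if cfg.n_motif_modules is not None:
        screen = sorted(modules, key=lambda m: -m.size)[: cfg.n_motif_modules]
    outcomes = []
    for m in screen:
        seqs = mod.module_upstreams(m, members_doc, operon_map, genes, genome,
                                    cfg.upstream_length)
        outcomes.append(mod.screen_module_motif(
            m, seqs, background,
            width_range=(cfg.motif_width_min, cfg.motif_width_max),
            n_shuffles=cfg.n_shuffles, n_restarts=cfg.motif_restarts,
            seed=stage_seed(cfg.seed, "motif"),
        ))
    mod.motif_summary_table(outcomes).to_csv(mdir / "motifs.tsv", sep="\t", index=False)
    mot.write_meme_minimal(outcomes, background, mdir / "motifs.meme")
    schemes = {
        "protein_class": set().union(*class_map.values()) if class_map else set(),
        "go": set().union(*go_map.values()) if go_map else set(),
    }
    shortlist, dual = mod.shortlist_modules(results, outcomes, cfg.p_enrich, cfg.fdr, schemes)
    _write_json({"shortlist": sorted(shortlist), "dual": sorted(dual)},
                mdir / "shortlist.json")


def run_pipeline(cfg: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Execute the requested stages in fixed order and write a run report."""
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    runners = {
        "simulate": _stage_simulate,
        "compendium": _stage_compendium,
        "operons": _stage_operons,
        "network": _stage_network,
        "modules": _stage_modules,
    }
    for stage in STAGES:
        if stage not in stages:
            continue
        t0 = time.time()
        log.info("stage %s: starting (seed=%d)", stage, cfg.seed)
        runners[stage](cfg, out)
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    report = build_report(cfg, out)
    _write_json(report, out / "report.json")
    return report


def build_report(cfg: PipelineConfig, out: Path) -> dict:
    """Collect headline counts from whatever stage outputs are present."""
    report: dict = {"seed": cfg.seed}
    cpath = out / "compendium" / "selected_genes.txt"
    if cpath.exists():
        report["genes_selected"] = len(cpath.read_text().split())
    opath = out / "operons" / "operon_map.tsv"
    if opath.exists():
        omap = _read_operon_map(opath)
        report["transcription_units"] = omap.n_units
        report["polycistronic_units"] = omap.n_polycistronic
    npath = out / "network" / "edges.sif"
    if npath.exists():
        edges = [ln for ln in npath.read_text().splitlines() if ln.strip()]
        report["network_edges"] = len(edges)
        nodes = set()
        for ln in edges:
            a, _, b = ln.split("\t")
            nodes.update((a, b))
        report["network_nodes"] = len(nodes)
        fit = json.loads((out / "network" / "degree_fit.json").read_text())
        report["degree_fit"] = fit
        mods = json.loads((out / "network" / "modules.json").read_text())
        report["network_modules"] = len(mods)
    mpath = out / "modules" / "enrichment.tsv"
    if mpath.exists():
        df = pd.read_csv(mpath, sep="\t")
        sig = df[(df["p_value"] < cfg.p_enrich) & (df["q_value"] <= cfg.fdr)]
        report["enriched_modules"] = int(sig["module"].nunique())
        short = json.loads((out / "modules" / "shortlist.json").read_text())
        report["shortlisted_modules"] = len(short["shortlist"])
        report["dual_enriched_shortlist"] = len(short["dual"])
    return report
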