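"""Functional characterization of network modules.

Each hub-centered module is scored for enrichment of protein classes and
GO terms (one-sided Fisher's exact test with Storey q-values, bootstrap
pi0), and its members' 300-bp upstream regions are mined for a shared
promoter motif whose significance is calibrated against five letter-shuffled
replicate runs. Modules passing both screens are shortlisted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from scipy.stats import fisher_exact

from .features import GeneRecord
from .motifs import (BackgroundModel, MotifOutcome, call_module_motif,
                     discover_motif, shuffle_evalue_threshold)
from .network import NetworkModule
from .operons import OperonMap


@dataclass
class EnrichmentResult:
    module_id: str
    term_id: str
    p_value: float
    member_hits: int
    universe_hits: int
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0,1]")
        if self.member_hits > self.universe_hits:
            raise ValueError("module hits exceed universe hits")


def fisher_enrichment(
    module_members: Iterable[str],
    term_map: Mapping[str, set[str]],
    universe: Iterable[str],
    module_id: str = "",
) -> list[EnrichmentResult]:
    """One-sided (enrichment) Fisher's exact p per term present in the module.

    ``term_map`` maps cistron -> term set (cistron annotation is the union
    over member genes, built by the caller).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    members = set(module_members)
    if not members <= universe:
        raise ValueError("module is not a subset of the universe")
    terms_in_module = set()
    for c in members:
        terms_in_module |= set(term_map.get(c, set()))
    results = []
    n_mod = len(members)
    n_uni = len(universe)
    for term in sorted(terms_in_module):
        with_term = {c for c in universe if term in term_map.get(c, set())}
        k = len(members & with_term)
        K = len(with_term)
        table = [[k, n_mod - k], [K - k, (n_uni - n_mod) - (K - k)]]
        _, p = fisher_exact(table, alternative="greater")
        results.append(EnrichmentResult(module_id=module_id, term_id=term,
                                        p_value=float(p), member_hits=k, universe_hits=K))
    return results


def estimate_qvalues(
    p_values: Sequence[float],
    n_bootstrap: int = 100,
    lambda_grid: Sequence[float] | None = None,
    seed: int = 0,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with pi0 chosen by the bootstrap method.

    For each lambda in the grid, pi0(lambda) = #{p > lambda} / (m (1-lambda));
    the bootstrap picks the lambda minimizing the estimated MSE of pi0
    relative to the minimum over the grid. Pass ``pi0`` to skip estimation
    (pi0=1 reproduces Benjamini-Hochberg). Output is monotone-adjusted.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size < 10 and pi0 is None:
        if p.ndim != 1:
            raise ValueError("p_values must be 1-D")
        if p.size < 10:
            raise ValueError("need >= 10 p-values to estimate pi0")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values outside [0,1]")
    m = p.size
    if pi0 is None:
        grid = np.asarray(lambda_grid if lambda_grid is not None
                          else np.arange(0.0, 0.95, 0.05), dtype=float)
        pi0_lam = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
        pi0_min = pi0_lam.min()
        rng = np.random.default_rng(seed)
        mse = np.zeros(grid.size)
        for _ in range(n_bootstrap):
            pb = p[rng.integers(0, m, size=m)]
            pi0_b = np.array([(pb > lam).sum() / (m * (1.0 - lam)) for lam in grid])
            mse += (pi0_b - pi0_min) ** 2
        pi0 = float(min(1.0, max(pi0_lam[int(np.argmin(mse))], 1.0 / m)))
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pi0 * m * p[i] / rank_from_top)
        q[i] = val
        prev = val
    return q


def attach_qvalues(results: Sequence[EnrichmentResult], seed: int = 0,
                   **kwargs) -> list[EnrichmentResult]:
    """q-values computed across all module x term tests pooled."""
    if not results:
        return []
    q = estimate_qvalues([r.p_value for r in results], seed=seed, **kwargs)
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return list(results)


# ---------------------------------------------------------------------------
# Upstream sequence extraction

def load_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def extract_upstream(
    cistron_members: Sequence[str],
    operons: OperonMap,
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    length: int = 300,
) -> str:
    """``length`` bp immediately 5' of the cistron's first gene, strand-aware.

    The first gene is the transcription-order leader (first member of the
    unit). Clipped at contig ends; reverse-complemented on the minus
    strand; uppercase.
    """
    by_id = {g.gene_id: g for g in genes}
    leader = by_id.get(cistron_members[0])
    if leader is None:
        raise ValueError(f"gene {cistron_members[0]!r} not annotated")
    contig = genome.get(leader.contig_id)
    if contig is None:
        raise ValueError(f"gene {leader.gene_id!r} not on a loaded contig")
    L = len(contig)
    if leader.strand == "+":
        hi = leader.start - 1            # 0-based exclusive end
        lo = max(0, hi - length)
        return contig[lo:hi].upper()
    lo = leader.end                      # 0-based inclusive start
    hi = min(L, lo + length)
    return str(Seq(contig[lo:hi]).reverse_complement()).upper()


def module_upstreams(
    module: NetworkModule,
    cistron_members: Mapping[str, Sequence[str]],
    operons: OperonMap,
    genes: Sequence[GeneRecord],
    genome: Mapping[str, str],
    length: int = 300,
) -> list[str]:
    return [
        extract_upstream(cistron_members[c], operons, genes, genome, length)
        for c in module.members
    ]


# ---------------------------------------------------------------------------
# Motif screening and shortlisting

def screen_module_motif(
    module: NetworkModule,
    sequences: Sequence[str],
    background: BackgroundModel,
    width_range: tuple[int, int] = (6, 24),
    n_shuffles: int = 5,
    n_restarts: int = 20,
    seed: int = 0,
) -> MotifOutcome:
    """Discover the module motif and attach its five-shuffle threshold."""
    finder = discover_motif(sequences, background, width_range, seed=seed,
                            n_restarts=n_restarts)
    threshold = shuffle_evalue_threshold(sequences, background, n_shuffles=n_shuffles,
                                         seed=seed, width_range=width_range,
                                         n_restarts=n_restarts)
    return MotifOutcome(
        module_id=module.module_id,
        pwm=finder.pwm_,
        log10_evalue=finder.log10_evalue_,
        log10_evalue_threshold=threshold,
        n_members_with_site=int(sum(finder.site_calls_)),
        n_members=len(sequences),
        site_calls=list(finder.site_calls_),
    )


def shortlist_modules(
    enrichment: Sequence[EnrichmentResult],
    motifs: Sequence[MotifOutcome],
    p_enrich: float = 1.0e-4,
    fdr: float = 0.01,
    schemes: Mapping[str, set[str]] | None = None,
) -> tuple[set[str], set[str]]:
    """Modules that are enriched AND carry a significant all-member motif.

    Returns (shortlist, dual_shortlist); the dual shortlist additionally
    requires enrichment in two annotation schemes (``schemes`` maps scheme
    label -> term ids; e.g. protein classes vs GO terms).
    """
    enriched_by_module: dict[str, set[str]] = {}
    for r in enrichment:
        if r.p_value < p_enrich and (np.isnan(r.q_value) or r.q_value <= fdr):
            enriched_by_module.setdefault(r.module_id, set()).add(r.term_id)
    motif_ok = {
        m.module_id
        for m in motifs
        if m.log10_evalue_threshold is not None
        and call_module_motif(m.log10_evalue, m.log10_evalue_threshold)
        and m.n_members_with_site == m.n_members
    }
    shortlist = set(enriched_by_module) & motif_ok
    dual = set()
    if schemes:
        for mod in shortlist:
            terms = enriched_by_module[mod]
            covered = [lbl for lbl, ts in schemes.items() if terms & ts]
            if len(covered) >= 2:
                dual.add(mod)
    return shortlist, dual


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"module": r.module_id, "term": r.term_id, "p_value": r.p_value,
             "q_value": r.q_value, "member_hits": r.member_hits,
             "universe_hits": r.universe_hits}
            for r in results
        ],
        columns=["module", "term", "p_value", "q_value", "member_hits", "universe_hits"],
    )


def motif_summary_table(outcomes: Sequence[MotifOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"module": o.module_id, "log10_evalue_threshold": o.log10_evalue_threshold,
             "log10_evalue": o.log10_evalue, "consensus": o.consensus,
             "members_total": o.n_members, "members_with_site": o.n_members_with_site,
             "significant": o.significant}
            for o in outcomes
        ],
        columns=["module", "log10_evalue_threshold", "log10_evalue", "consensus",
                 "members_total", "members_with_site", "significant"],
    )
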