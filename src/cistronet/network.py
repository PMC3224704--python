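"""Cistron-level mutual-information network inference with DPI pruning.

Expression is aggregated from genes to predicted transcription units
(cistrons). Mutual information between each regulator cistron and every
other cistron is estimated by Gaussian kernel density on copula-transformed
profiles; edges above a permutation-calibrated MI threshold survive, and
likely-indirect edges are removed by the data-processing inequality (DPI):
in every triangle, an edge weaker than (1 - tolerance) times the smaller of
the other two is pruned. Modules are the hub regulator plus its direct
neighbors; global connectivity is summarized by a log-log power-law fit of
the regulator degree distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator

from .compendium import ExpressionDataset
from .features import GeneRecord
from .operons import OperonMap


@dataclass
class CistronExpression:
    """Cistron x sample matrix; each row is the mean of its member-gene rows."""

    values: pd.DataFrame            # index: cistron ids
    members: dict[str, list[str]]   # cistron id -> member gene ids

    def __post_init__(self) -> None:
        if set(self.values.index) != set(self.members):
            raise ValueError("cistron ids differ between values and membership")

    @property
    def cistron_ids(self) -> list[str]:
        return list(self.values.index)


@dataclass
class NetworkConfig:
    p_threshold: float = 1.0e-9
    dpi_tolerance: float = 0.05
    n_null_permutations: int = 100_000
    mi_units: str = "nats"
    bw_factor: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        if not 0.0 <= self.dpi_tolerance < 1.0:
            raise ValueError("dpi_tolerance must be in [0,1)")
        if self.mi_units != "nats":
            raise ValueError("only nats are supported")


def aggregate_cistron_expression(
    operons: OperonMap, expr: ExpressionDataset, selected_genes: Iterable[str]
) -> CistronExpression:
    """Average selected member-gene rows per transcription unit.

    Units with no selected member are dropped; members missing from the
    expression matrix do not contribute.
    """
    selected = set(selected_genes)
    rows, members = [], {}
    for i, unit in enumerate(operons.transcription_units):
        keep = [g for g in unit if g in selected and g in expr.values.index]
        if not keep:
            continue
        cid = f"TU{i + 1:05d}"
        rows.append(pd.Series(expr.values.loc[keep].mean(axis=0), name=cid))
        members[cid] = keep
    values = pd.DataFrame(rows)
    return CistronExpression(values=values, members=members)


def select_regulator_cistrons(cistrons: CistronExpression, genes: Sequence[GeneRecord]) -> set[str]:
    """Cistrons containing at least one regulator-flagged gene."""
    regulator_genes = {g.gene_id for g in genes if g.regulator}
    return {cid for cid, mem in cistrons.members.items() if regulator_genes.intersection(mem)}


# ---------------------------------------------------------------------------
# Copula-KDE mutual information

def _copula(x: np.ndarray) -> np.ndarray:
    return rankdata(x) / (x.size + 1.0)


def _bandwidth(n: int, bw_factor: float) -> float:
    # Silverman's d=2 rule on the copula scale, shrunk by bw_factor and with
    # boundary reflection in the density; the uniform marginal sd is fixed.
    sigma = math.sqrt(1.0 / 12.0) * math.sqrt(n / (n + 1.0))  # sd of ranks/(n+1)
    return bw_factor * sigma * n ** (-1.0 / 6.0)


def _reflected_kernel_matrix(u: np.ndarray, h: float) -> np.ndarray:
    d = u[:, None] - u[None, :]
    s = u[:, None] + u[None, :]
    K = np.exp(-0.5 * (d / h) ** 2)
    K += np.exp(-0.5 * (s / h) ** 2)            # reflection at 0
    K += np.exp(-0.5 * ((s - 2.0) / h) ** 2)    # reflection at 1
    return K

def estimate_mi(x, y, bw_factor: float = 0.5) -> float:
    """Mutual information in nats between two profiles.

    Both profiles are copula-transformed (ranks scaled into (0,1)); the
    joint and marginal densities are Gaussian-kernel estimates with a
    shrunk Silverman bandwidth and boundary reflection; MI is the sample
    mean of log(f_xy/(f_x f_y)), clamped at 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 30:
        raise ValueError("profiles must be equal-length 1-D with >= 30 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant profile has undefined mutual information")
    n = x.size
    h = _bandwidth(n, bw_factor)
    Ku = _reflected_kernel_matrix(_copula(x), h)
    Kv = _reflected_kernel_matrix(_copula(y), h)
    fu = Ku.mean(axis=1)
    fv = Kv.mean(axis=1)
    fuv = (Ku * Kv).mean(axis=1)
    return max(float(np.mean(np.log(fuv / (fu * fv)))), 0.0)


class _MiEngine:
    """Vectorized MI over many profile pairs sharing one sample count.

    When profiles have no ties, every copula vector is a permutation of
    (1..n)/(n+1), so each profile's kernel matrix is a row/column gather of
    one base matrix; nothing is re-exponentiated per pair.
    """

    def __init__(self, n: int, bw_factor: float = 0.5):
        self.n = n
        self.h = _bandwidth(n, bw_factor)
        base = (np.arange(1, n + 1) / (n + 1.0)).astype(float)
        self.K0 = _reflected_kernel_matrix(base, self.h)
        self.bw_factor = bw_factor

    def ranks(self, x: np.ndarray) -> np.ndarray | None:
        r = rankdata(x)
        ri = r.astype(np.intp)
        return ri - 1 if np.all(r == ri) else None  # None on ties

    def mi_from_ranks(self, rx: np.ndarray, ry: np.ndarray) -> float:
        Ku = self.K0[np.ix_(rx, rx)]
        Kv = self.K0[np.ix_(ry, ry)]
        fu = Ku.mean(axis=1)
        fv = Kv.mean(axis=1)
        fuv = (Ku * Kv).mean(axis=1)
        return max(float(np.mean(np.log(fuv / (fu * fv)))), 0.0)

    def mi(self, x: np.ndarray, y: np.ndarray) -> float:
        rx, ry = self.ranks(x), self.ranks(y)
        if rx is None or ry is None:
            return estimate_mi(x, y, self.bw_factor)
        return self.mi_from_ranks(rx, ry)


def mi_threshold_from_pvalue(
    matrix: CistronExpression,
    p: float,
    n_perm: int = 100_000,
    seed: int = 0,
    bw_factor: float = 0.5,
) -> float:
    """MI threshold for significance level ``p`` from a permutation null.

    Null MI values come from randomly permuted profile pairs of the matrix;
    the upper decile of the null is fitted with an exponential tail
    log P(MI > m) = alpha - m/lam, and the threshold extrapolates to the
    requested ``p`` (which may be far below 1/n_perm).
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 cistrons for a permutation null")
    if np.any(np.ptp(X, axis=1) == 0):
        raise ValueError("degenerate null: zero-variance cistron profile")
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    engine = _MiEngine(n, bw_factor)
    null = np.empty(n_perm)
    n_rows = X.shape[0]
    for b in range(n_perm):
        i, j = rng.integers(0, n_rows, size=2)
        rx = engine.ranks(X[i])
        ry = engine.ranks(X[j][rng.permutation(n)])
        if rx is None or ry is None:
            null[b] = estimate_mi(X[i], rng.permutation(X[j]), bw_factor)
        else:
            null[b] = engine.mi_from_ranks(rx, ry)
    return fit_exponential_tail(null, p)


def fit_exponential_tail(null_values: np.ndarray, p: float) -> float:
    """Threshold for tail probability ``p`` by exponential extrapolation.

    Fits log P(X > m) = alpha - m/lam by OLS over the upper decile of the
    null sample and solves for the requested ``p``, which may lie far below
    the 1/n permutation resolution. ``p >= 1`` returns the sample minimum.
    """
    null = np.sort(np.asarray(null_values, dtype=float))
    n = null.size
    if p >= 1.0:
        return float(null[0])
    tail = null[int(math.floor(0.9 * n)):]
    m = tail.size
    surv = np.arange(m, 0, -1) / n  # empirical P(X > tail[k])
    A = np.column_stack([np.ones(m), tail])
    coef, *_ = np.linalg.lstsq(A, np.log(surv), rcond=None)
    alpha, slope = coef
    if slope >= 0:
        raise ValueError("null tail is not decaying; cannot extrapolate")
    return float((math.log(p) - alpha) / slope)


# ---------------------------------------------------------------------------
# Network construction

@dataclass
class RegulatoryNetwork:
    """MI-scored undirected edges, each touching at least one regulator."""

    nodes: list[str]
    regulators: set[str]
    edges: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in self.edges:
            if len(key) != 2:
                raise ValueError("self-edge in network")
            if not key & self.regulators:
                raise ValueError(f"edge {sorted(key)} touches no regulator")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for key in self.edges if node in key)

    def neighbors(self, node: str) -> set[str]:
        out = set()
        for key in self.edges:
            if node in key:
                out.update(key - {node})
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for key, mi in self.edges.items():
            a, b = sorted(key)
            g.add_edge(a, b, mi=mi)
        return g

    def to_sif(self, path) -> None:
        with open(path, "w") as fh:
            for key in sorted(self.edges, key=lambda k: sorted(k)):
                a, b = sorted(key)
                fh.write(f"{a}\tmi\t{b}\n")

    def module_mi_table(self) -> pd.DataFrame:
        """Long-form table: hub, target, MI — one row per edge per hub."""
        rows = []
        for key, mi in self.edges.items():
            for hub in sorted(key & self.regulators):
                target = next(iter(key - {hub}), hub)
                rows.append({"hub": hub, "target": target, "mi": mi})
        return pd.DataFrame(rows, columns=["hub", "target", "mi"])


def apply_dpi(edges: Mapping[frozenset, float], tolerance: float) -> dict[frozenset, float]:
    """Data-processing-inequality pruning.

    Every triangle of the input graph is evaluated against the ORIGINAL
    edge set: edge (i,j) is marked for removal iff
    MI_ij < (1 - tolerance) * min(MI_ik, MI_jk) for some common neighbor k.
    Marked edges are deleted afterwards, so the result is order-independent.
    """
    adj: dict[str, set[str]] = {}
    for key in edges:
        a, b = tuple(key)
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    doomed = set()
    factor = 1.0 - tolerance
    for key, mi_ij in edges.items():
        i, j = tuple(key)
        for k in adj[i] & adj[j]:
            mi_ik = edges[frozenset((i, k))]
            mi_jk = edges[frozenset((j, k))]
            if mi_ij < factor * min(mi_ik, mi_jk):
                doomed.add(key)
                break
    return {k: v for k, v in edges.items() if k not in doomed}


class MutualInfoNetwork(BaseEstimator):
    """ARACNE-style network estimator over a cistron expression matrix.

    ``fit`` scores MI for every regulator x cistron pair, thresholds at the
    permutation-calibrated MI for ``p_threshold``, applies DPI pruning, and
    exposes the result as ``network_`` / ``edges_`` / ``mi_threshold_``.
    """

    def __init__(self, p_threshold=1.0e-9, dpi_tolerance=0.05,
                 n_null_permutations=100_000, bw_factor=0.5, seed=0):
        self.p_threshold = p_threshold
        self.dpi_tolerance = dpi_tolerance
        self.n_null_permutations = n_null_permutations
        self.bw_factor = bw_factor
        self.seed = seed

    def fit(self, matrix: CistronExpression, regulators: Iterable[str]) -> "MutualInfoNetwork":
        regulators = set(regulators) & set(matrix.cistron_ids)
        if not regulators:
            raise ValueError("no regulator cistron present in the matrix")
        self.mi_threshold_ = mi_threshold_from_pvalue(
            matrix, self.p_threshold, n_perm=self.n_null_permutations,
            seed=self.seed, bw_factor=self.bw_factor,
        )
        X = matrix.values.to_numpy(dtype=float)
        ids = matrix.cistron_ids
        idx = {c: i for i, c in enumerate(ids)}
        engine = _MiEngine(X.shape[1], self.bw_factor)
        ranks = {}
        for c in ids:
            ranks[c] = engine.ranks(X[idx[c]])
        raw: dict[frozenset, float] = {}
        for reg in sorted(regulators):
            rr = ranks[reg]
            for c in ids:
                if c == reg:
                    continue
                key = frozenset((reg, c))
                if key in raw:
                    continue
                rc = ranks[c]
                if rr is None or rc is None:
                    mi = estimate_mi(X[idx[reg]], X[idx[c]], self.bw_factor)
                else:
                    mi = engine.mi_from_ranks(rr, rc)
                if mi >= self.mi_threshold_:
                    raw[key] = mi
        self.edges_ = apply_dpi(raw, self.dpi_tolerance)
        self.network_ = RegulatoryNetwork(nodes=ids, regulators=set(regulators), edges=self.edges_)
        return self


def build_network(
    matrix: CistronExpression,
    regulators: Iterable[str],
    config: NetworkConfig | None = None,
    seed: int = 0,
) -> RegulatoryNetwork:
    cfg = config or NetworkConfig()
    est = MutualInfoNetwork(
        p_threshold=cfg.p_threshold, dpi_tolerance=cfg.dpi_tolerance,
        n_null_permutations=cfg.n_null_permutations, bw_factor=cfg.bw_factor, seed=seed,
    )
    return est.fit(matrix, regulators).network_


# ---------------------------------------------------------------------------
# Modules and degree distribution

@dataclass
class NetworkModule:
    """A hub regulator cistron plus its predicted direct targets."""

    module_id: str
    hub: str
    members: list[str]  # hub first, then neighbors

    @property
    def size(self) -> int:
        return len(self.members)


def extract_modules(net: RegulatoryNetwork) -> list[NetworkModule]:
    """One module per regulator with >= 1 surviving edge."""
    modules = []
    ordered = sorted(net.regulators)
    for i, hub in enumerate(ordered, start=1):
        nbrs = sorted(net.neighbors(hub))
        if not nbrs:
            continue
        modules.append(NetworkModule(module_id=f"M{i:04d}", hub=hub, members=[hub] + nbrs))
    return modules


@dataclass
class DegreeFit:
    coefficient: float
    exponent: float


def powerlaw_fit_from_degrees(degrees: Sequence[int]) -> DegreeFit:
    """Log-log OLS fit p(k) = coefficient * k^exponent of the degree pmf.

    ``degrees`` are the (nonzero) degrees of the regulator nodes; degrees
    with zero empirical probability contribute no support point.
    """
    degrees = [d for d in degrees if d >= 1]
    if not degrees:
        raise ValueError("no nonzero-degree regulator nodes")
    ks, counts = np.unique(degrees, return_counts=True)
    if ks.size < 3:
        raise ValueError(f"need >= 3 distinct degree values, found {ks.size}")
    p = counts / counts.sum()
    A = np.column_stack([np.ones(ks.size), np.log(ks.astype(float))])
    coef, *_ = np.linalg.lstsq(A, np.log(p), rcond=None)
    return DegreeFit(coefficient=float(np.exp(coef[0])), exponent=float(coef[1]))


def fit_degree_powerlaw(net: RegulatoryNetwork) -> DegreeFit:
    degrees = [net.degree(r) for r in net.regulators]
    return powerlaw_fit_from_degrees([d for d in degrees if d >= 1])
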