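"""Multi-platform expression compendium: I/O, gene filtering, imputation, standardization.

A compendium is a set of per-platform expression matrices (genes x samples)
carrying absent-call masks. Genes are filtered by a Boolean rule requiring
good expression dynamics (few absent calls, standard deviation above the
25th-percentile of its platform) in at least one of the two two-channel
platforms, a minimum presence level in the other, and a probeset on the
oligonucleotide chip. Surviving genes are k-NN imputed and z-standardized
per platform, then concatenated column-wise into one analysis matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLATFORMS = ("cDNA_gDNA", "cDNA_cDNA", "oligo_chip")


@dataclass
class ExpressionDataset:
    """One platform's genes x samples matrix with an absent-call mask.

    ``values`` holds log-ratios/log-intensities; entries where
    ``absent_mask`` is True are undefined (stored as NaN) until imputed.
    """

    platform_id: str
    values: pd.DataFrame
    absent_mask: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.shape != self.absent_mask.shape:
            raise ValueError("values and absent_mask shapes differ")
        if not self.values.index.equals(self.absent_mask.index):
            raise ValueError("gene ids differ between values and mask")
        if not self.values.columns.equals(self.absent_mask.columns):
            raise ValueError("sample ids differ between values and mask")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.platform_id, self.values.copy(), self.absent_mask.copy())


@dataclass
class GeneFilterStats:
    """Per-gene inputs to the selection rule.

    a/c: fraction of absent flags on platforms 1/2 (1.0 when the gene is
    missing from the platform altogether); b/d: the corresponding standard
    deviations over present values; e: probeset present on the oligo chip.
    """

    gene_id: str
    a: float
    b: float
    c: float
    d: float
    e: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.c <= 1.0):
            raise ValueError(f"absent fractions outside [0,1] for {self.gene_id}")
        if self.b < 0 or self.d < 0:
            raise ValueError(f"negative sd for {self.gene_id}")


@dataclass
class FilterThresholds:
    absent_strict: float = 0.20
    absent_loose: float = 0.50
    sd_percentile: float = 25.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.absent_strict <= self.absent_loose <= 1.0:
            raise ValueError("require 0 <= absent_strict <= absent_loose <= 1")
        if not 0.0 <= self.sd_percentile <= 100.0:
            raise ValueError("sd_percentile must be in [0,100]")


def read_expression_table(path, platform_id: str, absent_sentinel: str = "NA") -> ExpressionDataset:
    """Read a TSV (header = sample ids, first column = gene ids).

    Cells equal to ``absent_sentinel`` become masked; their stored value is
    NaN and must be imputed before analysis.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str,
        keep_default_na=False, na_values=[],
    )
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty data section")
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    if df.isin([""]).any().any():
        raise ValueError(f"{path}: ragged rows (empty cells)")
    mask = df == absent_sentinel
    values = df.mask(mask).astype(float)
    return ExpressionDataset(platform_id, values, mask)


def write_expression_table(ds: ExpressionDataset, path, absent_sentinel: str = "NA") -> None:
    """Write the dialect `read_expression_table` consumes (masked cells -> sentinel)."""
    out = ds.values.astype(object).copy()
    out[ds.absent_mask] = absent_sentinel
    out.to_csv(path, sep="\t", index_label="gene_id")


def _absent_fraction_and_sd(ds: ExpressionDataset, gene: str) -> tuple[float, float]:
    if gene not in ds.values.index:
        return 1.0, 0.0
    row = ds.values.loc[gene]
    mask = ds.absent_mask.loc[gene]
    frac = float(mask.mean())
    present = row[~mask].to_numpy(dtype=float)
    sd = float(np.std(present, ddof=1)) if present.size >= 2 else 0.0
    return frac, sd


def compute_filter_stats(
    ds1: ExpressionDataset,
    ds2: ExpressionDataset,
    probeset_genes: Iterable[str],
) -> list[GeneFilterStats]:
    """One `GeneFilterStats` per gene in the union of ds1 and ds2 gene sets."""
    probeset = set(probeset_genes)
    genes = list(dict.fromkeys(list(ds1.values.index) + list(ds2.values.index)))
    if not genes:
        raise ValueError("no genes in either dataset")
    stats = []
    for g in genes:
        a, b = _absent_fraction_and_sd(ds1, g)
        c, d = _absent_fraction_and_sd(ds2, g)
        stats.append(GeneFilterStats(g, a=a, b=b, c=c, d=d, e=g in probeset))
    return stats


def sd_cutoffs(stats: Sequence[GeneFilterStats], sd_percentile: float = 25.0) -> tuple[float, float]:
    """Percentile cutoffs for b and d, over genes with a defined sd (>0 present pairs).

    Genes entirely absent from a platform (sd reported as 0 by convention)
    are excluded from that platform's percentile population.
    """
    b_pop = [s.b for s in stats if s.a < 1.0]
    d_pop = [s.d for s in stats if s.c < 1.0]
    b_cut = float(np.percentile(b_pop, sd_percentile)) if b_pop else 0.0
    d_cut = float(np.percentile(d_pop, sd_percentile)) if d_pop else 0.0
    return b_cut, d_cut


def select_genes(
    stats: Sequence[GeneFilterStats],
    thresholds: FilterThresholds | None = None,
) -> set[str]:
    """Evaluate the selection rule

        {(a<=s) AND (b>=B) AND (c<=l) AND e} OR {(c<=s) AND (d>=D) AND (a<=l) AND e}

    with s=absent_strict, l=absent_loose and B, D the sd_percentile-th
    percentiles of the b and d populations (recomputed from ``stats``).
    """
    if not stats:
        raise ValueError("empty stats collection")
    t = thresholds or FilterThresholds()
    b_cut, d_cut = sd_cutoffs(stats, t.sd_percentile)
    selected = set()
    for s in stats:
        first = s.a <= t.absent_strict and s.b >= b_cut and s.c <= t.absent_loose and s.e
        second = s.c <= t.absent_strict and s.d >= d_cut and s.a <= t.absent_loose and s.e
        if first or second:
            selected.add(s.gene_id)
    return selected


def impute_missing_knn(ds: ExpressionDataset, k: int = 15) -> ExpressionDataset:
    """Replace each masked cell by the mean of the k nearest genes at that sample.

    Distance is Euclidean over samples where both genes are present; a
    neighbor must itself be present at the target sample. Present cells are
    untouched.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = ds.values.to_numpy(dtype=float).copy()
    M = ds.absent_mask.to_numpy(dtype=bool)
    present = ~M
    n_present = present.sum(axis=1)
    if (n_present == 0).any():
        bad = ds.values.index[n_present == 0][0]
        raise ValueError(f"gene {bad!r} has zero present values; cannot impute")
    if not M.any():
        out = ds.copy()
        out.absent_mask[:] = False
        return out

    Xz = np.where(present, X, 0.0)
    out = X.copy()
    for i in np.flatnonzero(M.any(axis=1)):
        # squared Euclidean over mutually present samples, vs every other gene
        both = present & present[i]          # (n_genes, n_samples)
        diff = (Xz - Xz[i]) * both
        d2 = (diff * diff).sum(axis=1)
        n_both = both.sum(axis=1)
        d2 = np.where(n_both > 0, d2, np.inf)
        d2[i] = np.inf
        for j in np.flatnonzero(M[i]):
            cand = np.flatnonzero(present[:, j] & np.isfinite(d2))
            if cand.size == 0:
                gene = ds.values.index[i]
                raise ValueError(f"no present neighbors for gene {gene!r} at sample index {j}")
            order = cand[np.argsort(d2[cand], kind="stable")]
            nn = order[: min(k, order.size)]
            out[i, j] = X[nn, j].mean()
    values = pd.DataFrame(out, index=ds.values.index, columns=ds.values.columns)
    mask = pd.DataFrame(False, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(ds.platform_id, values, mask)


def z_standardize(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each gene row to mean 0, sample (n-1) standard deviation 1."""
    if ds.absent_mask.to_numpy().any():
        raise ValueError("matrix must be complete (impute first)")
    X = ds.values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples to standardize")
    sd = X.std(axis=1, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        gene = ds.values.index[zero[0]]
        raise ValueError(f"zero-variance gene {gene!r}; remove before standardizing")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    values = pd.DataFrame(Z, index=ds.values.index, columns=ds.values.columns)
    return ExpressionDataset(ds.platform_id, values, ds.absent_mask.copy())


def concat_datasets(parts: Sequence[ExpressionDataset], gene_ids: Iterable[str]) -> ExpressionDataset:
    """Column-wise concatenation of per-platform matrices over a common gene set."""
    gene_ids = list(gene_ids)
    if not parts:
        raise ValueError("no datasets to concatenate")
    seen: set[str] = set()
    blocks = []
    for ds in parts:
        missing = [g for g in gene_ids if g not in ds.values.index]
        if missing:
            raise ValueError(
                f"genes absent from platform {ds.platform_id}: {missing[:5]}"
                " (impute or drop before concatenation)"
            )
        overlap = seen.intersection(ds.sample_ids)
        if overlap:
            raise ValueError(f"overlapping sample ids: {sorted(overlap)[:5]}")
        seen.update(ds.sample_ids)
        blocks.append(ds.values.loc[gene_ids])
    values = pd.concat(blocks, axis=1)
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    return ExpressionDataset("+".join(p.platform_id for p in parts), values, mask)


def prepare_compendium(
    datasets: dict[str, ExpressionDataset],
    probeset_genes: Iterable[str],
    thresholds: FilterThresholds | None = None,
    k: int = 15,
) -> tuple[ExpressionDataset, set[str]]:
    """Filter -> impute -> standardize -> concatenate, per platform.

    ``datasets`` keys are the three platform labels. Genes selected by the
    rule but missing from the oligo platform's probeset rows are dropped
    from it only if truly unmeasured there; selection already requires a
    probeset, so selected genes are expected on all three platforms.
    Returns the concatenated standardized matrix and the selected gene set.
    """
    ds1 = datasets[PLATFORMS[0]]
    ds2 = datasets[PLATFORMS[1]]
    ds3 = datasets[PLATFORMS[2]]
    # a probeset only counts if the oligo matrix actually carries the gene
    stats = compute_filter_stats(ds1, ds2, set(ds3.values.index).intersection(probeset_genes))
    selected = select_genes(stats, thresholds)
    order = [g for g in ds1.gene_ids if g in selected]
    order += [g for g in ds2.gene_ids if g in selected and g not in set(order)]
    parts = []
    for ds in (ds1, ds2, ds3):
        keep = [g for g in order if g in ds.values.index]
        sub = ExpressionDataset(ds.platform_id, ds.values.loc[keep], ds.absent_mask.loc[keep])
        sub = impute_missing_knn(sub, k=k)
        sub = z_standardize(sub)
        parts.append(sub)
    common = [g for g in order if all(g in p.values.index for p in parts)]
    return concat_datasets(parts, common), set(common)
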