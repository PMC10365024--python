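"""Pathway scan: permutation-PCA test for coordinated regulatory variability.

For each pathway the scan extracts every network edge pointing at a pathway
gene, z-scales each edge across samples, and measures the fraction of
cross-sample variance captured by PC1. The same statistic is computed for
``n_perm`` random gene sets of equal size drawn from the pathway-collection
universe, giving a size-matched permutation null. A one-tailed t-test and a
signed Cohen's d compare the observed fraction to that null; p-values are
BH-adjusted across all tested pathways, and pathways pass when
``p_adjusted < alpha_fdr``, ``pc1_var_observed >= min_var_explained`` and
``effect_size >= min_effect_size`` (defaults 0.01 / 0.10 / 2.0).

:class:`PorcupineScan` is the scikit-learn-style front end; the module-level
functions are the individual steps.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import EdgeMatrix, PathwayCollection
from .io import RESULT_COLUMNS
from .stats import (
    bh_adjust,
    cohens_d,
    empirical_pvalue,
    pc1_variance_fraction,
    porcupine_pvalue,
    zscale_edges,
)

__all__ = [
    "PathwayTestResult",
    "TestConfig",
    "PathwayEdges",
    "extract_pathway_edges",
    "null_pc1_distribution",
    "run_porcupine",
    "filter_significant",
    "size_bias_report",
    "pathway_seed",
    "PorcupineScan",
]


@dataclass
class PathwayEdges:
    """Edges connected to a pathway's genes: the E_p x N weight block."""

    edge_ids: list[tuple[str, str]]
    weights: np.ndarray
    matched_genes: list[str]

    @property
    def n_edges(self) -> int:
        return len(self.edge_ids)


@dataclass
class PathwayTestResult:
    """Per-pathway outcome of the permutation-PCA test."""

    pathway: str
    n_genes_in_pathway: int
    n_genes_in_network: int
    n_edges: int
    pc1_var_observed: float
    null_var_fractions: np.ndarray
    p_value: float
    effect_size: float
    p_adjusted: float = float("nan")

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_var_fractions))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_var_fractions, ddof=1))

    def to_row(self) -> dict:
        return {
            "pathway": self.pathway,
            "n_genes_in_pathway": self.n_genes_in_pathway,
            "n_genes_in_network": self.n_genes_in_network,
            "n_edges": self.n_edges,
            "pc1_var_observed": self.pc1_var_observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "p_value": self.p_value,
            "p_adjusted": self.p_adjusted,
            "effect_size": self.effect_size,
        }


@dataclass
class TestConfig:
    """Scan thresholds and sizes.

    ``n_perm`` random gene sets per pathway (default 1000); pathways with
    more than ``max_pathway_genes`` listed genes (default 200) or fewer than
    ``min_pathway_genes_in_network`` genes present in the network (default 3)
    are skipped. ``pvalue_method`` selects the one-tailed t-test ("ttest")
    or the empirical permutation p-value ("empirical").
    """

    n_perm: int = 1000
    max_pathway_genes: int = 200
    min_pathway_genes_in_network: int = 3
    alpha_fdr: float = 0.01
    min_var_explained: float = 0.10
    min_effect_size: float = 2.0
    seed: int = 0
    pvalue_method: str = "ttest"

    def __post_init__(self) -> None:
        if self.n_perm < 2:
            raise ValueError("n_perm must be >= 2")
        for name in ("max_pathway_genes", "min_pathway_genes_in_network",
                     "alpha_fdr", "min_var_explained", "min_effect_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pvalue_method not in ("ttest", "empirical"):
            raise ValueError(f"unknown pvalue_method {self.pvalue_method!r}")


def extract_pathway_edges(matrix: EdgeMatrix, genes) -> PathwayEdges:
    """All edges whose target gene belongs to `genes`.

    Rows come out gene-major (genes in matrix order, TFs in matrix edge
    order within each gene), so every TF edge of a matched gene is included.
    """
    rows = matrix.rows_for_genes(genes)
    if rows.size == 0:
        raise ValueError("no pathway gene occurs among the network's target genes")
    matched = list(dict.fromkeys(matrix.genes[i] for i in rows))
    edge_ids = [(matrix.tfs[i], matrix.genes[i]) for i in rows]
    return PathwayEdges(
        edge_ids=edge_ids, weights=matrix.weights[rows], matched_genes=matched
    )


def _null_universe(matrix: EdgeMatrix, collection: PathwayCollection) -> list[str]:
    """Genes eligible for permutation sampling: GMT universe ∩ network genes.

    Sampling genes absent from the network would silently shrink the random
    sets, so the universe is intersected up front. Sorted for determinism.
    """
    return sorted(collection.universe & set(matrix.gene_names))


def null_pc1_distribution(
    matrix: EdgeMatrix,
    collection: PathwayCollection,
    set_size: int,
    n_perm: int,
    seed: int,
) -> np.ndarray:
    """PC1 variance fractions for ``n_perm`` random gene sets of ``set_size``.

    Each replicate samples ``set_size`` genes without replacement from the
    universe (GMT genes present in the network), extracts their edges,
    z-scales and takes the PC1 fraction. The full vector is returned.
    """
    universe = _null_universe(matrix, collection)
    return _null_pc1_from_universe(matrix, universe, set_size, n_perm, seed)


def _null_pc1_from_universe(
    matrix: EdgeMatrix, universe: list[str], set_size: int, n_perm: int, seed: int
) -> np.ndarray:
    if len(universe) < set_size:
        raise ValueError(
            f"sampling universe ({len(universe)} genes) smaller than set size {set_size}"
        )
    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe, dtype=object)
    out = np.empty(n_perm)
    for i in range(n_perm):
        picked = rng.choice(universe_arr, size=set_size, replace=False)
        rows = matrix.rows_for_genes(picked)
        scaled, _ = zscale_edges(matrix.weights[rows])
        out[i], _, _ = pc1_variance_fraction(scaled)
    return out


def pathway_seed(global_seed: int, pathway: str) -> int:
    """Deterministic per-pathway seed from (global seed, pathway name).

    Independent of pathway iteration order, so results do not change if the
    collection is reordered or pathways are processed in parallel.
    """
    digest = hashlib.blake2b(
        f"{global_seed}\x00{pathway}".encode(), digest_size=4
    ).digest()
    return int.from_bytes(digest, "big") % (2**31)


def run_porcupine(
    matrix: EdgeMatrix,
    collection: PathwayCollection,
    config: TestConfig | None = None,
    skip_log: list | None = None,
) -> list[PathwayTestResult]:
    """Run the permutation-PCA test over every eligible pathway.

    Pathways with more than ``config.max_pathway_genes`` listed genes or
    fewer than ``config.min_pathway_genes_in_network`` genes in the network
    are skipped (reasons appended to ``skip_log`` as (pathway, reason)).
    BH adjustment spans exactly the tested pathways. Results are sorted by
    ascending adjusted p-value, then descending effect size, then name.
    """
    config = config or TestConfig()
    universe = _null_universe(matrix, collection)
    network_genes = set(matrix.gene_names)
    if not (collection.universe & network_genes):
        raise ValueError("pathway collection and network share no genes")
    log = skip_log if skip_log is not None else []

    results: list[PathwayTestResult] = []
    for name in sorted(collection.pathways):
        genes = collection[name]
        if len(genes) > config.max_pathway_genes:
            log.append((name, f"size>{config.max_pathway_genes}"))
            continue
        matched = genes & network_genes
        if len(matched) < config.min_pathway_genes_in_network:
            log.append(
                (name, f"genes_in_network<{config.min_pathway_genes_in_network}")
            )
            continue
        try:
            sub = extract_pathway_edges(matrix, genes)
            scaled, _ = zscale_edges(sub.weights)
            observed, _, _ = pc1_variance_fraction(scaled)
            size = len(matched)
            null = _null_pc1_from_universe(
                matrix, universe, size, config.n_perm,
                pathway_seed(config.seed, name),
            )
            if config.pvalue_method == "empirical":
                p = empirical_pvalue(observed, null)
            else:
                p = porcupine_pvalue(observed, null)
            d = cohens_d(observed, null)
        except ValueError as exc:
            log.append((name, f"degenerate: {exc}"))
            continue
        results.append(
            PathwayTestResult(
                pathway=name,
                n_genes_in_pathway=len(genes),
                n_genes_in_network=size,
                n_edges=sub.n_edges,
                pc1_var_observed=observed,
                null_var_fractions=null,
                p_value=p,
                effect_size=d,
            )
        )

    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
    results.sort(key=lambda r: (r.p_adjusted, -r.effect_size, r.pathway))
    return results


def filter_significant(
    results: list[PathwayTestResult], config: TestConfig | None = None
) -> list[PathwayTestResult]:
    """Apply the significance gates; input order is preserved."""
    config = config or TestConfig()
    return [
        r
        for r in results
        if r.p_adjusted < config.alpha_fdr
        and r.pc1_var_observed >= config.min_var_explained
        and r.effect_size >= config.min_effect_size
    ]


SIZE_BINS = [(1, 50), (50, 100), (100, 150), (150, 201)]


def size_bias_report(
    results: list[PathwayTestResult],
    significant: list[PathwayTestResult],
) -> pd.DataFrame:
    """Pathway-size composition of tested vs significant pathways.

    Bins pathway sizes (genes listed in the collection) into <50, 50-100,
    100-150 and 150-200 and reports each bin's share of all tested pathways
    and of the significant subset. If the shares are similar the scan is not
    preferentially picking small (or large) pathways.
    """
    if not results:
        raise ValueError("no results to bin")

    def proportions(rows: list[PathwayTestResult]) -> list[float]:
        counts = []
        for lo, hi in SIZE_BINS:
            counts.append(
                sum(1 for r in rows if lo <= r.n_genes_in_pathway < hi)
            )
        total = sum(counts)
        return [c / total if total else float("nan") for c in counts]

    labels = ["<50", "50-100", "100-150", "150-200"]
    table = pd.DataFrame(
        {
            "size_bin": labels,
            "prop_tested": proportions(results),
            "prop_significant": proportions(significant) if significant else [float("nan")] * 4,
        }
    )
    return table


class PorcupineScan(BaseEstimator):
    """Scikit-learn-style estimator wrapping the pathway scan.

    Parameters mirror :class:`TestConfig`. After :meth:`fit`, the per-pathway
    table is in ``results_`` (a DataFrame in significance order), the raw
    result objects in ``raw_results_``, the significant subset in
    ``significant_`` and the skip log in ``skipped_``.

    Examples
    --------
    >>> scan = PorcupineScan(n_perm=100, random_state=7)
    >>> scan.fit(matrix, pathways)            # doctest: +SKIP
    >>> scan.results_.head()                  # doctest: +SKIP
    """

    def __init__(
        self,
        n_perm: int = 1000,
        max_pathway_genes: int = 200,
        min_pathway_genes_in_network: int = 3,
        alpha_fdr: float = 0.01,
        min_var_explained: float = 0.10,
        min_effect_size: float = 2.0,
        pvalue_method: str = "ttest",
        random_state: int = 0,
    ):
        self.n_perm = n_perm
        self.max_pathway_genes = max_pathway_genes
        self.min_pathway_genes_in_network = min_pathway_genes_in_network
        self.alpha_fdr = alpha_fdr
        self.min_var_explained = min_var_explained
        self.min_effect_size = min_effect_size
        self.pvalue_method = pvalue_method
        self.random_state = random_state

    def _config(self) -> TestConfig:
        return TestConfig(
            n_perm=self.n_perm,
            max_pathway_genes=self.max_pathway_genes,
            min_pathway_genes_in_network=self.min_pathway_genes_in_network,
            alpha_fdr=self.alpha_fdr,
            min_var_explained=self.min_var_explained,
            min_effect_size=self.min_effect_size,
            seed=self.random_state,
            pvalue_method=self.pvalue_method,
        )

    def fit(self, X: EdgeMatrix, y: PathwayCollection = None):
        """Run the scan on an :class:`EdgeMatrix` against a pathway collection."""
        if y is None:
            raise ValueError("a PathwayCollection must be passed as the second argument")
        config = self._config()
        skip_log: list = []
        raw = run_porcupine(X, y, config, skip_log=skip_log)
        self.raw_results_ = raw
        self.results_ = pd.DataFrame(
            [r.to_row() for r in raw], columns=RESULT_COLUMNS
        )
        self.significant_ = pd.DataFrame(
            [r.to_row() for r in filter_significant(raw, config)],
            columns=RESULT_COLUMNS,
        )
        self.skipped_ = skip_log
        self.n_tested_ = len(raw)
        return self

    def size_bias_report_(self) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "raw_results_")
        sig = filter_significant(self.raw_results_, self._config())
        return size_bias_report(self.raw_results_, sig)
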