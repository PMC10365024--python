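"""Synthetic cohorts of sample-specific bipartite networks.

The generator emulates the statistical structure the pathway scan consumes:
an edges x samples weight matrix with per-edge baselines, i.i.d. Gaussian
noise, and (optionally) a planted one-dimensional latent factor loading onto
all TF edges of a chosen pathway's genes:

    w[(tf, g), s] = mu[(tf, g)] + beta * l[(tf, g)] * u[s] * 1[g planted] + eps

with mu ~ N(0, baseline_sd^2), latent factor u_s ~ N(0, 1), edge loadings
l ~ N(0, 1) rescaled to root-mean-square 1 over the planted edges, and
eps ~ N(0, noise_sd^2). With that normalization the planted block's expected
PC1 variance share at large N is beta^2 * sum(l^2) / (beta^2 * sum(l^2)
+ E_p * noise_sd^2) = beta^2 / (beta^2 + noise_sd^2), so ``beta`` is the
factor's strength in noise-sd units. ``beta = 0`` gives a fully exchangeable
null cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CovariateTable, EdgeMatrix, PathwayCollection

__all__ = [
    "PlantedSpec",
    "CovariateSpec",
    "SimulationSpec",
    "simulate_cohort",
    "simulate_null_pathway_collection",
]


@dataclass
class PlantedSpec:
    """One planted latent factor: which pathway, how strong, how broad."""

    pathway_index: int = 0
    factor_strength: float = 1.0  # beta, in noise-sd units
    fraction_of_genes_affected: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.fraction_of_genes_affected <= 1):
            raise ValueError("fraction_of_genes_affected must be in (0, 1]")


@dataclass
class CovariateSpec:
    """Optional covariates: a categorical grouping and a numerical readout.

    ``numerical_link`` is the correlation between the numerical covariate and
    the latent factor u (0 = independent). The categorical covariate has
    ``n_levels`` levels; if ``categorical_linked`` it bins u by quantile,
    otherwise levels are assigned uniformly at random.
    """

    n_levels: int = 3
    categorical_linked: bool = False
    numerical_link: float = 0.0

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("categorical covariate needs >= 2 levels")
        if not (-1 <= self.numerical_link <= 1):
            raise ValueError("numerical_link must be a correlation in [-1, 1]")


@dataclass
class SimulationSpec:
    """Cohort dimensions and generative parameters.

    Defaults give a small but realistic scan problem: 20 TFs x 500 genes
    (10,000 edges), 40 samples, 20 pathways of 10-50 genes, unit noise.
    """

    n_tfs: int = 20
    n_genes: int = 500
    n_samples: int = 40
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 50)
    baseline_sd: float = 1.0
    noise_sd: float = 1.0
    planted: PlantedSpec | None = None
    covariates: CovariateSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tfs", "n_genes", "n_samples", "n_pathways"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("pathway_size_range must satisfy 0 < min <= max <= n_genes")
        if self.planted is not None and not (
            0 <= self.planted.pathway_index < self.n_pathways
        ):
            raise ValueError(
                f"planted pathway index {self.planted.pathway_index} out of range"
            )


def simulate_null_pathway_collection(
    n_pathways: int,
    size_range: tuple[int, int],
    gene_universe,
    seed: int,
) -> PathwayCollection:
    """Random gene sets: per pathway, a uniform size in ``size_range`` and a
    without-replacement draw from ``gene_universe``. Reproducible from seed."""
    universe = list(gene_universe)
    lo, hi = size_range
    if hi > len(universe):
        raise ValueError(f"pathway size {hi} exceeds universe size {len(universe)}")
    rng = np.random.default_rng(seed)
    pathways: dict[str, set[str]] = {}
    width = len(str(n_pathways))
    for i in range(n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(np.asarray(universe, dtype=object), size=size, replace=False)
        pathways[f"PW{i:0{width}d}"] = set(members)
    return PathwayCollection(pathways, source_description="synthetic")


def simulate_cohort(spec: SimulationSpec):
    """Generate ``(EdgeMatrix, PathwayCollection, CovariateTable, truth)``.

    ``truth`` is a dict recording the latent factor ``u`` per sample, the
    planted pathway name and genes, and the edge loadings, so recovery can
    be scored against ground truth. Bit-identical for equal seeds.
    """
    rng = np.random.default_rng(spec.seed)
    tf_names = [f"TF{i:03d}" for i in range(spec.n_tfs)]
    gene_names = [f"G{i:05d}" for i in range(spec.n_genes)]

    collection = simulate_null_pathway_collection(
        spec.n_pathways,
        spec.pathway_size_range,
        gene_names,
        seed=int(rng.integers(2**31)),
    )

    # full bipartite edge list, gene-major so extraction order is natural
    tfs = [tf for _ in gene_names for tf in tf_names]
    genes = [g for g in gene_names for _ in tf_names]
    n_edges = len(tfs)
    samples = [f"S{i:03d}" for i in range(spec.n_samples)]

    baseline = rng.normal(0.0, spec.baseline_sd, size=n_edges)
    weights = baseline[:, None] + rng.normal(
        0.0, spec.noise_sd, size=(n_edges, spec.n_samples)
    )

    u = rng.normal(0.0, 1.0, size=spec.n_samples)
    truth: dict = {
        "latent_factor": dict(zip(samples, u.tolist())),
        "planted_pathway": None,
        "planted_genes": [],
        "edge_loadings": {},
    }
    if spec.planted is not None and spec.planted.factor_strength != 0:
        name = sorted(collection.pathways)[spec.planted.pathway_index]
        members = sorted(collection[name])
        n_affected = max(1, round(spec.planted.fraction_of_genes_affected * len(members)))
        affected = list(
            rng.choice(np.asarray(members, dtype=object), size=n_affected, replace=False)
        )
        gene_pos = {g: i for i, g in enumerate(gene_names)}
        rows = np.concatenate(
            [np.arange(spec.n_tfs) + gene_pos[g] * spec.n_tfs for g in affected]
        )
        loadings = rng.normal(0.0, 1.0, size=rows.size)
        # root-mean-square 1: sum(l^2) = E_p, so beta is in noise-sd units
        loadings *= np.sqrt(rows.size) / np.linalg.norm(loadings)
        weights[rows] += spec.planted.factor_strength * np.outer(loadings, u)
        truth["planted_pathway"] = name
        truth["planted_genes"] = sorted(affected)
        truth["edge_loadings"] = {
            f"{tfs[r]}\t{genes[r]}": float(l) for r, l in zip(rows, loadings)
        }

    matrix = EdgeMatrix(tfs=tfs, genes=genes, samples=samples, weights=weights)

    covars = None
    if spec.covariates is not None:
        cs = spec.covariates
        if cs.categorical_linked:
            qs = np.quantile(u, np.linspace(0, 1, cs.n_levels + 1)[1:-1])
            group = np.searchsorted(qs, u)
        else:
            group = rng.integers(0, cs.n_levels, size=spec.n_samples)
        r = cs.numerical_link
        numeric = r * u + np.sqrt(max(0.0, 1 - r**2)) * rng.normal(
            0.0, 1.0, size=spec.n_samples
        )
        covars = CovariateTable(
            data=pd.DataFrame(
                {
                    "group": [f"L{int(g)}" for g in group],
                    "readout": numeric,
                },
                index=pd.Index(samples, name="sample"),
            ),
            kinds={"group": "categorical", "readout": "numerical"},
        )

    return matrix, collection, covars, truth


def write_truth(truth: dict, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
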