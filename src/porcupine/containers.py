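"""In-memory containers for cohorts of sample-specific regulatory networks.

The central object is :class:`EdgeMatrix`: a bipartite TF -> target-gene
network whose edge weights have been estimated once per sample (e.g. with
PANDA + LIONESS), stored as an edges x samples matrix. Pathway gene sets are
held in :class:`PathwayCollection`, and per-sample clinical/phenotype
annotations in :class:`CovariateTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["EdgeMatrix", "PathwayCollection", "CovariateTable"]


@dataclass
class EdgeMatrix:
    """Cohort of sample-specific networks as an edges x samples weight matrix.

    Parameters
    ----------
    tfs, genes : list of str
        Regulator (TF) and target-gene identifiers per edge; together they
        define ``edge_index`` as the ordered list of (tf, gene) pairs.
        Identifiers are opaque, case-sensitive strings.
    samples : list of str
        Unique sample identifiers (columns).
    weights : ndarray of shape (n_edges, n_samples)
        Continuous edge weights; network-inference scores, may be negative.
    """

    tfs: list[str]
    genes: list[str]
    samples: list[str]
    weights: np.ndarray
    _gene_rows: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.tfs = list(self.tfs)
        self.genes = list(self.genes)
        self.samples = list(self.samples)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.tfs) != len(self.genes):
            raise ValueError("tfs and genes must have equal length (one entry per edge)")
        n_edges = len(self.tfs)
        if self.weights.shape != (n_edges, len(self.samples)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n_edges} edges x {len(self.samples)} samples"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        if len(self.samples) < 3:
            raise ValueError("need at least 3 samples for cross-sample PCA")
        if np.isnan(self.weights).any():
            raise ValueError("weights contain missing values")
        pairs = list(zip(self.tfs, self.genes))
        if len(set(pairs)) != n_edges:
            raise ValueError("duplicate (tf, gene) edges")
        # target gene -> row indices, in edge order; drives pathway extraction
        gene_rows: dict[str, list[int]] = {}
        for i, g in enumerate(self.genes):
            gene_rows.setdefault(g, []).append(i)
        self._gene_rows = {g: np.asarray(idx, dtype=np.intp) for g, idx in gene_rows.items()}

    @property
    def edge_index(self) -> list[tuple[str, str]]:
        return list(zip(self.tfs, self.genes))

    @property
    def n_edges(self) -> int:
        return len(self.tfs)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def tf_names(self) -> list[str]:
        """Distinct TFs in first-appearance order."""
        return list(dict.fromkeys(self.tfs))

    @property
    def gene_names(self) -> list[str]:
        """Distinct target genes in first-appearance order."""
        return list(self._gene_rows)

    def rows_for_genes(self, genes) -> np.ndarray:
        """Row indices of all edges pointing to any of `genes`.

        Gene-major order: genes in matrix order, edges within a gene in
        matrix edge order.
        """
        wanted = set(genes)
        blocks = [idx for g, idx in self._gene_rows.items() if g in wanted]
        if not blocks:
            return np.empty(0, dtype=np.intp)
        return np.concatenate(blocks)

    def to_frame(self) -> pd.DataFrame:
        """Wide DataFrame: columns tf, gene, then one column per sample."""
        df = pd.DataFrame(self.weights, columns=self.samples)
        df.insert(0, "gene", self.genes)
        df.insert(0, "tf", self.tfs)
        return df


@dataclass
class PathwayCollection:
    """Named gene sets plus the gene universe used for permutation sampling."""

    pathways: dict[str, set[str]]
    source_description: str = ""

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            self.pathways[name] = set(members)

    @property
    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.pathways.values():
            out |= members
        return out

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self):
        return iter(self.pathways.items())

    def __getitem__(self, name: str) -> set[str]:
        return self.pathways[name]


@dataclass
class CovariateTable:
    """Per-sample covariates, each tagged categorical or numerical.

    ``data`` is indexed by sample identifier; ``kinds`` maps each column to
    "categorical" or "numerical".
    """

    data: pd.DataFrame
    kinds: dict[str, str]

    def __post_init__(self) -> None:
        unknown = set(self.kinds) - set(self.data.columns)
        if unknown:
            raise ValueError(f"kinds refer to unknown columns: {sorted(unknown)}")
        missing = set(self.data.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"columns without a declared kind: {sorted(missing)}")
        bad = {k: v for k, v in self.kinds.items() if v not in ("categorical", "numerical")}
        if bad:
            raise ValueError(f"invalid covariate kinds: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)
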