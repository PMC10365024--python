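"""Downstream interpretation of a significant pathway.

Once a pathway shows coordinated regulatory variability, three questions
follow: which edges/genes/TFs drive it (PC1 loadings, the "edge contribution
scores"), where each patient sits along it (per-sample PC1/PC2 projections,
the "pathway-based patient heterogeneity scores"), and whether that axis
relates to clinical covariates or splits the cohort into subtypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClusterMixin, TransformerMixin
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.utils.validation import check_is_fitted

from .containers import CovariateTable, EdgeMatrix
from .scan import extract_pathway_edges
from .stats import bh_adjust, principal_components, zscale_edges

__all__ = [
    "ContributionProfile",
    "HeterogeneityScores",
    "AssociationResult",
    "edge_contributions",
    "gene_contribution_summary",
    "patient_scores",
    "cluster_subtypes",
    "associate_covariates",
    "gene_targeting_scores",
    "PathwayPCA",
    "SubtypeKMeans",
]

TOP_EDGE_FACTOR = 1.5
TF_LABEL_PERCENTILE = 95.0


@dataclass
class ContributionProfile:
    """PC1 edge loadings of one pathway, with the top-contributor calls.

    ``expected_score`` is 1/sqrt(E_p): since the squared loadings sum to one,
    an edge contributing its equal share would load at exactly that value.
    Edges with |loading| > 1.5 x expected are flagged as top contributors.
    """

    pathway: str
    edge_ids: list[tuple[str, str]]
    contribution_scores: np.ndarray
    expected_score: float
    top_edges: np.ndarray
    tf_target_counts: dict[str, int]
    tf_labels: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tf": [t for t, _ in self.edge_ids],
                "gene": [g for _, g in self.edge_ids],
                "contribution_score": self.contribution_scores,
                "expected_score": self.expected_score,
                "top_edge": self.top_edges,
            }
        )


@dataclass
class HeterogeneityScores:
    """Per-sample coordinates on a pathway's leading principal components."""

    pathway: str
    samples: list[str]
    pc1_scores: np.ndarray
    pc2_scores: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"sample": self.samples, "pc1": self.pc1_scores}
        if self.pc2_scores is not None:
            data["pc2"] = self.pc2_scores
        return pd.DataFrame(data)


@dataclass
class AssociationResult:
    pathway: str
    covariate: str
    test: str  # "kruskal_wallis" | "pearson"
    statistic: float
    p_value: float
    p_adjusted: float = float("nan")
    significant: bool = False


def edge_contributions(
    loadings: np.ndarray,
    edge_ids: list[tuple[str, str]],
    pathway: str = "",
) -> ContributionProfile:
    """Build a :class:`ContributionProfile` from unit-norm PC1 loadings.

    Top edges are those with |loading| > 1.5 x the expected equal-contribution
    score 1/sqrt(E_p). TFs are then ranked by how many top edges they own;
    TFs whose count exceeds the 95th percentile (over TFs owning at least one
    top edge, linear interpolation) are labelled as hubs of co-regulation.
    """
    loadings = np.asarray(loadings, dtype=float)
    if loadings.ndim != 1 or len(loadings) != len(edge_ids):
        raise ValueError("loadings and edge_ids must align one-to-one")
    norm = float(np.sqrt(np.sum(loadings**2)))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"loadings are not unit-norm (|norm - 1| = {abs(norm - 1):.2e})")
    n_edges = len(loadings)
    expected = 1.0 / np.sqrt(n_edges)
    top = np.abs(loadings) > TOP_EDGE_FACTOR * expected
    counts: dict[str, int] = {}
    for (tf, _), is_top in zip(edge_ids, top):
        if is_top:
            counts[tf] = counts.get(tf, 0) + 1
    labels: list[str] = []
    if counts:
        cutoff = float(np.percentile(list(counts.values()), TF_LABEL_PERCENTILE))
        labels = sorted(tf for tf, c in counts.items() if c > cutoff)
    return ContributionProfile(
        pathway=pathway,
        edge_ids=list(edge_ids),
        contribution_scores=loadings,
        expected_score=float(expected),
        top_edges=top,
        tf_target_counts=counts,
        tf_labels=labels,
    )


def gene_contribution_summary(profile: ContributionProfile) -> pd.DataFrame:
    """Aggregate top edges by target gene.

    Returns a table (gene, n_top_edges, max_abs_loading), sorted by count
    descending, ties broken by max |loading| then gene name.
    """
    rows: dict[str, list[float]] = {}
    for (_, gene), loading, is_top in zip(
        profile.edge_ids, profile.contribution_scores, profile.top_edges
    ):
        if is_top:
            rows.setdefault(gene, []).append(abs(float(loading)))
    records = [
        {"gene": g, "n_top_edges": len(v), "max_abs_loading": max(v)}
        for g, v in rows.items()
    ]
    df = pd.DataFrame(records, columns=["gene", "n_top_edges", "max_abs_loading"])
    if df.empty:
        return df
    return df.sort_values(
        ["n_top_edges", "max_abs_loading", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)


def patient_scores(
    scaled: np.ndarray,
    samples: list[str],
    n_components: int = 1,
    pathway: str = "",
) -> HeterogeneityScores:
    """Project samples onto the leading principal components.

    ``scaled`` is the z-scaled E_p x N pathway block. Scores are the
    projections of the (centered) samples onto the unit-norm eigenvectors,
    sign-fixed so each component's largest-magnitude loading is positive.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    _, _, scores = principal_components(scaled, n_components=n_components)
    return HeterogeneityScores(
        pathway=pathway,
        samples=list(samples),
        pc1_scores=scores[:, 0],
        pc2_scores=scores[:, 1] if n_components == 2 else None,
    )


def cluster_subtypes(
    scores: HeterogeneityScores,
    k_range=range(2, 7),
    random_state: int = 0,
    n_init: int = 10,
):
    """K-means subtyping of patients from their PC1 (and PC2) scores.

    Fits K-means for each k in ``k_range`` and keeps the k maximizing the
    mean silhouette width (Euclidean) — the Average Silhouette Method.
    Returns ``(labels, chosen_k, silhouettes)`` with ``silhouettes`` a dict
    k -> mean silhouette.
    """
    model = SubtypeKMeans(
        k_range=list(k_range), random_state=random_state, n_init=n_init
    ).fit(_scores_array(scores))
    return model.labels_, model.k_, model.silhouettes_


def _scores_array(scores: HeterogeneityScores) -> np.ndarray:
    cols = [scores.pc1_scores]
    if scores.pc2_scores is not None:
        cols.append(scores.pc2_scores)
    return np.column_stack(cols)


class SubtypeKMeans(BaseEstimator, ClusterMixin):
    """K-means with silhouette-based selection of the cluster number.

    After ``fit``: ``k_`` (chosen number of clusters), ``labels_``,
    ``silhouettes_`` (k -> mean silhouette width), ``cluster_centers_``.
    """

    def __init__(self, k_range=(2, 3, 4, 5, 6), random_state: int = 0, n_init: int = 10):
        self.k_range = k_range
        self.random_state = random_state
        self.n_init = n_init

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n = X.shape[0]
        ks = sorted(set(int(k) for k in self.k_range))
        if not ks or ks[0] < 2 or ks[-1] > n - 1:
            raise ValueError(f"k_range must lie within [2, {n - 1}]")
        if np.allclose(X, X[0]):
            raise ValueError("degenerate input: all samples have identical scores")
        sil: dict[int, float] = {}
        fits: dict[int, KMeans] = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=self.n_init, random_state=self.random_state)
            labels = km.fit_predict(X)
            if len(np.unique(labels)) < 2:
                continue
            sil[k] = float(silhouette_score(X, labels, metric="euclidean"))
            fits[k] = km
        if not sil:
            raise ValueError("no k in range produced >= 2 clusters")
        # ties broken toward fewer clusters
        best = max(sil, key=lambda k: (sil[k], -k))
        self.k_ = best
        self.silhouettes_ = sil
        self.labels_ = fits[best].labels_
        self.cluster_centers_ = fits[best].cluster_centers_
        self._kmeans = fits[best]
        return self

    def predict(self, X):
        check_is_fitted(self, "k_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self._kmeans.predict(X)


def associate_covariates(
    scores: HeterogeneityScores,
    covars: CovariateTable,
    alpha: float = 0.05,
    skip_log: list | None = None,
) -> list[AssociationResult]:
    """Test the pathway's patient scores against each covariate.

    Kruskal-Wallis across levels for categorical covariates, Pearson
    correlation test for numerical ones, on the samples shared between the
    score vector and the covariate table. BH adjustment spans exactly the
    tests performed in this call; ``significant`` flags p_adjusted < alpha.
    Constant covariates are skipped with a reason.
    """
    log = skip_log if skip_log is not None else []
    score_by_sample = dict(zip(scores.samples, scores.pc1_scores))
    shared = [s for s in covars.samples if s in score_by_sample]
    if len(shared) < 3:
        raise ValueError("fewer than 3 samples shared between scores and covariates")
    y = np.array([score_by_sample[s] for s in shared])
    sub = covars.data.loc[shared]

    results: list[AssociationResult] = []
    for col in covars.columns:
        values = sub[col]
        mask = values.notna().to_numpy()
        if mask.sum() < 3:
            log.append((col, "fewer than 3 non-missing samples"))
            continue
        v, yy = values[mask], y[mask]
        if covars.kinds[col] == "categorical":
            groups = [yy[(v == lvl).to_numpy()] for lvl in pd.unique(v)]
            if len(groups) < 2:
                log.append((col, "constant after intersection"))
                continue
            stat, p = sps.kruskal(*groups)
            test = "kruskal_wallis"
        else:
            vv = v.to_numpy(dtype=float)
            if np.allclose(vv, vv[0]) or np.allclose(yy, yy[0]):
                log.append((col, "constant after intersection"))
                continue
            stat, p = sps.pearsonr(vv, yy)
            test = "pearson"
        results.append(
            AssociationResult(
                pathway=scores.pathway,
                covariate=col,
                test=test,
                statistic=float(stat),
                p_value=float(p),
            )
        )
    if results:
        adjusted = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, adjusted):
            r.p_adjusted = float(q)
            r.significant = bool(q < alpha)
    return results


def gene_targeting_scores(matrix: EdgeMatrix) -> pd.DataFrame:
    """Per-sample gene targeting scores: the sum of all edge weights
    pointing to each gene (weighted in-degree).

    Returns a genes x samples DataFrame; genes with no edges do not appear.
    """
    df = pd.DataFrame(matrix.weights, columns=matrix.samples)
    df["gene"] = matrix.genes
    out = df.groupby("gene", sort=False).sum()
    out.index.name = "gene"
    return out


class PathwayPCA(BaseEstimator, TransformerMixin):
    """Principal-component view of one pathway's regulatory edges.

    Extracts all edges targeting the pathway's genes from an
    :class:`EdgeMatrix`, z-scales each edge across samples and fits a PCA
    with samples as observations. Fitted attributes: ``var_fractions_``
    (variance explained per component), ``loadings_`` (edges x k, unit
    columns), ``scores_`` (samples x k heterogeneity scores), ``edge_ids_``,
    ``matched_genes_``, ``n_dropped_edges_``. ``transform`` returns the
    sample scores; ``contribution_profile()`` ranks edges and TFs.
    """

    def __init__(self, genes=(), n_components: int = 2, pathway: str = ""):
        self.genes = genes
        self.n_components = n_components
        self.pathway = pathway

    def fit(self, X: EdgeMatrix, y=None):
        sub = extract_pathway_edges(X, set(self.genes))
        scaled, n_dropped = zscale_edges(sub.weights)
        # same zero-variance mask zscale_edges applied, to align edge_ids
        kept = sub.weights.std(axis=1, ddof=1) > 0
        var_fr, loadings, scores = principal_components(
            scaled, n_components=self.n_components
        )
        self.edge_ids_ = [e for e, k in zip(sub.edge_ids, kept) if k]
        self.matched_genes_ = sub.matched_genes
        self.n_dropped_edges_ = n_dropped
        self.var_fractions_ = var_fr
        self.loadings_ = loadings
        self.scores_ = scores
        self.samples_ = list(X.samples)
        return self

    def transform(self, X=None):
        """Sample scores from the fit (projection of the fitted cohort)."""
        check_is_fitted(self, "scores_")
        return self.scores_

    def fit_transform(self, X: EdgeMatrix, y=None):
        return self.fit(X).transform()

    def heterogeneity_scores(self) -> HeterogeneityScores:
        check_is_fitted(self, "scores_")
        return HeterogeneityScores(
            pathway=self.pathway,
            samples=self.samples_,
            pc1_scores=self.scores_[:, 0],
            pc2_scores=self.scores_[:, 1] if self.scores_.shape[1] > 1 else None,
        )

    def contribution_profile(self) -> ContributionProfile:
        check_is_fitted(self, "loadings_")
        return edge_contributions(
            self.loadings_[:, 0], self.edge_ids_, pathway=self.pathway
        )
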