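"""Statistical primitives for the pathway-heterogeneity test.

The test statistic is the fraction of cross-sample variance explained by the
first principal component (PC1) of a pathway's z-scaled edge weights. Samples
are the observations and edges the variables, so PC1 is the single direction
in edge-space along which the cohort spreads most; a high PC1 fraction means
the pathway's regulation varies in a coordinated, one-dimensional way across
patients. Significance is judged against a permutation null of random gene
sets of equal size (see :mod:`porcupine.scan`).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.special import logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "zscale_edges",
    "pc1_variance_fraction",
    "principal_components",
    "porcupine_pvalue",
    "empirical_pvalue",
    "cohens_d",
    "bh_adjust",
    "overlap_significance",
]


def zscale_edges(submatrix: np.ndarray) -> tuple[np.ndarray, int]:
    """Standardize each edge (row) across samples to mean 0, sd 1 (ddof=1).

    Rows with zero variance carry no cross-sample information and cannot be
    scaled; they are dropped. Returns ``(scaled, n_dropped)``.

    Raises
    ------
    ValueError
        If fewer than 3 samples, or every row has zero variance.
    """
    X = np.asarray(submatrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D edges x samples matrix")
    if X.shape[1] < 3:
        raise ValueError("z-scaling requires at least 3 samples")
    sd = X.std(axis=1, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("degenerate input: all edges have zero variance across samples")
    X = X[keep]
    mean = X.mean(axis=1, keepdims=True)
    return (X - mean) / sd[keep, None], n_dropped


def principal_components(scaled: np.ndarray, n_components: int = 1):
    """Leading principal components of an edges x samples matrix.

    Samples are treated as observations in edge-space. Returns
    ``(var_fractions, loadings, scores)`` where ``var_fractions[i]`` is
    eigenvalue i over the total covariance spectrum, ``loadings`` has one
    unit-norm eigenvector over edges per column, and ``scores`` are the
    sample projections. Each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    X = np.asarray(scaled, dtype=float)
    n_edges, n_samples = X.shape
    if n_edges < 2:
        raise ValueError("need at least 2 edges")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    # observations = samples: center each edge (already ~0 after z-scaling)
    Xc = (X - X.mean(axis=1, keepdims=True)).T  # samples x edges
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("degenerate input: matrix has rank 0 after centering")
    rank = int(np.sum(s > s[0] * 1e-12))
    if rank < n_components:
        raise ValueError(f"matrix rank {rank} < requested components {n_components}")
    var_fractions = s[:n_components] ** 2 / total
    loadings = Vt[:n_components].T.copy()  # edges x k
    scores = (U[:, :n_components] * s[:n_components]).copy()  # samples x k
    for j in range(n_components):
        if loadings[np.argmax(np.abs(loadings[:, j])), j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return var_fractions, loadings, scores


def pc1_variance_fraction(scaled: np.ndarray):
    """PC1 variance fraction, loadings and sample scores of a scaled matrix.

    Returns ``(fraction, loadings, scores)`` with ``fraction`` = lambda_1 over
    the summed covariance spectrum, ``loadings`` the unit-norm first
    eigenvector over edges, and ``scores`` the per-sample projections.
    """
    fr, load, sc = principal_components(scaled, n_components=1)
    return float(fr[0]), load[:, 0], sc[:, 0]


def porcupine_pvalue(observed: float, null: np.ndarray) -> float:
    """One-tailed t-test of the permutation null against the observed value.

    One-sample t-test of the null PC1 fractions against mu = observed, with
    alternative "null mean < observed":
    t = (observed - null_mean) / (null_sd / sqrt(n)), p = upper Student-t
    tail with n - 1 degrees of freedom. Equals 0.5 when observed sits at the
    null mean and exceeds 0.5 when it falls below it.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 2:
        raise ValueError("null vector needs at least 2 replicates")
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null: zero standard deviation")
    t = (observed - null.mean()) / (sd / np.sqrt(null.size))
    return float(sps.t.sf(t, df=null.size - 1))


def empirical_pvalue(observed: float, null: np.ndarray) -> float:
    """Permutation p-value: (#{null >= observed} + 1) / (n + 1)."""
    null = np.asarray(null, dtype=float)
    if null.size < 1:
        raise ValueError("empty null vector")
    return float((np.sum(null >= observed) + 1) / (null.size + 1))


def cohens_d(observed: float, null: np.ndarray) -> float:
    """Signed Cohen's d of the observed value against the permutation null.

    d = (observed - null_mean) / null_sd with ddof=1; positive when the
    observed PC1 fraction exceeds the null mean.
    """
    null = np.asarray(null, dtype=float)
    if null.size < 2:
        raise ValueError("null vector needs at least 2 replicates")
    sd = null.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate null: zero standard deviation")
    return float((observed - null.mean()) / sd)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def overlap_significance(
    n_universe: int, n_set_a: int, n_set_b: int, n_overlap: int
) -> float:
    """Upper-tail hypergeometric probability of an overlap at least this large.

    P(X >= n_overlap) for X ~ Hypergeometric(population ``n_universe``,
    successes ``n_set_a``, draws ``n_set_b``). Summed in log-space so that
    extreme tails (e.g. ~1e-29 overlaps between two pathway hit lists) do
    not underflow.
    """
    M, a, b, k = int(n_universe), int(n_set_a), int(n_set_b), int(n_overlap)
    if not (0 <= k <= min(a, b) <= M and a <= M and b <= M):
        raise ValueError(
            f"inconsistent counts: universe={M}, set_a={a}, set_b={b}, overlap={k}"
        )
    if k == 0:
        return 1.0
    support = np.arange(k, min(a, b) + 1)
    logp = sps.hypergeom.logpmf(support, M, a, b)
    return float(np.exp(logsumexp(logp)))
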