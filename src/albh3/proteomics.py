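"""Proteomics time-course statistics.

Implements the protein-level analysis of a 2 cell line x 5 timepoint TMT
design: row/column bi-standardization, per-protein ordinary least squares
over [1, cellline, time, cellline*time], multiple-testing adjustment and
ranking, PCA, complete-linkage/k-means two-stage clustering, and gene-set
enrichment (hypergeometric over-representation and permutation GSEA with a
weighted Kolmogorov-Smirnov running sum).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ProteomicsMatrix",
    "ProteomicsError",
    "read_proteomics_tsv",
    "bistandardize",
    "fit_protein_regressions",
    "adjust_pvalues",
    "pca",
    "cluster_two_stage",
    "GeneSetCollection",
    "read_gmt",
    "ora_enrichment",
    "gsea_permutation",
]


class ProteomicsError(ValueError):
    """Invalid proteomics inputs (constant rows, rank deficiency, ...)."""


@dataclass(frozen=True)
class ProteomicsMatrix:
    """Protein x sample log2 intensities with sample metadata.

    ``values``: DataFrame indexed by protein_id with one column per sample.
    ``samples``: DataFrame indexed identically to the columns of ``values``
    with columns ``cell_line`` (ALMC1/ALMC2) and ``time_h``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ProteomicsError("values columns and sample metadata index must match")
        for col in ("cell_line", "time_h"):
            if col not in self.samples.columns:
                raise ProteomicsError(f"sample metadata missing column {col!r}")
        if self.samples[["cell_line", "time_h"]].isna().any().any():
            raise ProteomicsError("sample metadata must be complete")
        if not np.all(np.isfinite(self.values.to_numpy(float))):
            raise ProteomicsError("intensities must be finite")
        bad = set(self.samples["cell_line"]) - {"ALMC1", "ALMC2"}
        if bad:
            raise ProteomicsError(f"unknown cell_line value(s): {sorted(bad)}")

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, values_path: str, samples_path: str) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")


def read_proteomics_tsv(values_path: str, samples_path: str) -> ProteomicsMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    return ProteomicsMatrix(values=values, samples=samples)


# ---------------------------------------------------------------------------
# Bi-standardization
# ---------------------------------------------------------------------------

def bistandardize(
    matrix: ProteomicsMatrix, tol: float = 1e-6, max_iter: int = 100
) -> tuple[ProteomicsMatrix, dict]:
    """Iteratively standardize rows then columns to mean 0, variance 1.

    Sweeps alternate row and column centering/scaling (population variance)
    until every row and column mean is below ``tol`` in absolute value and
    every variance is within ``tol`` of 1, or ``max_iter`` sweeps elapse.
    Deterministic; returns the standardized matrix and an info dict with
    ``n_iter`` and ``converged``.
    """
    if tol <= 0:
        raise ProteomicsError("tol must be positive")
    x = matrix.values.to_numpy(float).copy()
    _check_nonconstant(x, matrix)

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=0, keepdims=True)) / x.std(axis=0, keepdims=True)
        row_ok = (np.abs(x.mean(axis=1)) < tol).all() and (
            np.abs(x.var(axis=1) - 1) < tol
        ).all()
        col_ok = (np.abs(x.mean(axis=0)) < tol).all() and (
            np.abs(x.var(axis=0) - 1) < tol
        ).all()
        if row_ok and col_ok:
            converged = True
            break
    out = ProteomicsMatrix(
        values=pd.DataFrame(x, index=matrix.values.index, columns=matrix.values.columns),
        samples=matrix.samples,
    )
    return out, {"n_iter": n_iter, "converged": converged}


def _check_nonconstant(x: np.ndarray, matrix: ProteomicsMatrix) -> None:
    row_sd = x.std(axis=1)
    if (row_sd == 0).any():
        which = matrix.values.index[int(np.flatnonzero(row_sd == 0)[0])]
        raise ProteomicsError(f"zero variance in row (protein) {which!r}")
    col_sd = x.std(axis=0)
    if (col_sd == 0).any():
        which = matrix.values.columns[int(np.flatnonzero(col_sd == 0)[0])]
        raise ProteomicsError(f"zero variance in column (sample) {which!r}")


# ---------------------------------------------------------------------------
# Per-protein regression
# ---------------------------------------------------------------------------

COEF_NAMES = ("b0", "b1", "b2", "b3")  # intercept, cell line, time, interaction


def design_matrix(samples: pd.DataFrame) -> np.ndarray:
    """[1, cellline, time, cellline*time]; cellline = 1 for ALMC1.

    A positive cell-line coefficient therefore means higher abundance in the
    AL line than in the myeloma line.
    """
    cl = (samples["cell_line"] == "ALMC1").to_numpy(float)
    t = samples["time_h"].to_numpy(float)
    return np.column_stack([np.ones(len(samples)), cl, t, cl * t])


def fit_protein_regressions(
    matrix: ProteomicsMatrix,
    rank_by: str = "b1",
    bonferroni_scope: str = "per_coefficient",
) -> pd.DataFrame:
    """Ordinary least squares per protein over cell line, hours, interaction.

    Returns one row per protein with coefficients, standard errors,
    t-statistics (n - 4 df), two-sided raw p-values, Bonferroni-adjusted
    p-values and Benjamini-Hochberg q-values per coefficient family, and a
    1..n rank by ascending BH q (ties broken by raw p then matrix order) of
    the ``rank_by`` coefficient.
    """
    X = design_matrix(matrix.samples)
    n, k = X.shape
    if n <= k:
        raise ProteomicsError(f"need more than {k} samples, got {n}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise ProteomicsError(
            "rank-deficient design: need both cell lines and at least two "
            f"timepoints per cell line (rank {rank} < {k})"
        )
    if rank_by not in COEF_NAMES:
        raise ProteomicsError(f"rank_by must be one of {COEF_NAMES}")

    Y = matrix.values.to_numpy(float)            # proteins x samples
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = Y @ X @ xtx_inv                       # proteins x 4
    resid = Y - beta @ X.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.outer(sigma2, np.diag(xtx_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    out = pd.DataFrame(index=matrix.values.index)
    m = matrix.n_proteins
    for j, name in enumerate(COEF_NAMES):
        out[name] = beta[:, j]
        out[f"se_{name}"] = se[:, j]
        out[f"t_{name}"] = tstat[:, j]
        out[f"p_{name}"] = pvals[:, j]
        # adjustment scope: the family is the set of proteins, separately per
        # coefficient
        out[f"bonferroni_{name}"] = adjust_pvalues(pvals[:, j], "bonferroni")
        out[f"q_{name}"] = adjust_pvalues(pvals[:, j], "bh")

    order = np.lexsort((np.arange(m), out[f"p_{rank_by}"].to_numpy(),
                        out[f"q_{rank_by}"].to_numpy()))
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    out["rank"] = ranks
    out["df_resid"] = dof
    return out


# ---------------------------------------------------------------------------
# Multiple-testing adjustment
# ---------------------------------------------------------------------------

_METHOD_MAP = {"bonferroni": "bonferroni", "bh": "fdr_bh", "holm_sidak": "holm-sidak"}


def adjust_pvalues(p: Sequence[float], method: str) -> np.ndarray:
    """Adjust a p-value vector by Bonferroni, Benjamini-Hochberg or Holm-Sidak.

    Bonferroni: min(1, m*p).  BH: step-up with enforced monotonicity.
    Holm-Sidak: step-down, adj_(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j+1),
    capped at 1.  The original input order is preserved in the output.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ProteomicsError("p must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ProteomicsError("p-values must lie in [0, 1]")
    if method not in _METHOD_MAP:
        raise ProteomicsError(f"unknown method {method!r}; use {sorted(_METHOD_MAP)}")
    return multipletests(p, alpha=0.05, method=_METHOD_MAP[method])[1]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(matrix: ProteomicsMatrix, n_components: int) -> dict:
    """Principal components of the samples over protein features.

    Samples (perturbation conditions) are the observations; protein
    intensities the features, column-centered internally.  Returns scores
    (samples x components), orthonormal loadings (components x proteins) and
    the variance_explained fractions.  Sign convention: the
    largest-magnitude loading of each component is positive.
    """
    n_samples, n_features = matrix.n_samples, matrix.n_proteins
    max_comp = min(n_samples, n_features)
    if not 1 <= n_components <= max_comp:
        raise ProteomicsError(f"n_components must lie in [1, {max_comp}]")
    x = matrix.values.to_numpy(float).T           # samples x proteins
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix signs so each component's largest-|loading| entry is positive
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    var = s**2
    total = var.sum()
    explained = var / total if total > 0 else np.zeros_like(var)
    scores = u[:, :n_components] * s[:n_components]
    return {
        "scores": pd.DataFrame(
            scores,
            index=matrix.values.columns,
            columns=[f"PC{i + 1}" for i in range(n_components)],
        ),
        "loadings": pd.DataFrame(
            vt[:n_components],
            index=[f"PC{i + 1}" for i in range(n_components)],
            columns=matrix.values.index,
        ),
        "variance_explained": explained[:n_components],
    }


# ---------------------------------------------------------------------------
# Two-stage clustering
# ---------------------------------------------------------------------------

def cluster_two_stage(
    matrix: ProteomicsMatrix,
    n_clusters: int = 9,
    k: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Complete-linkage tree cut followed by per-cluster k-means.

    An agglomerative complete-linkage dendrogram on Euclidean distances
    between protein profiles is cut into ``n_clusters``; within each cut
    cluster, k-means (k-means++ init, fixed seed) assigns up to ``k``
    sub-clusters.  Returns a frame indexed by protein with columns
    ``cluster`` and ``subcluster``; fully deterministic under a fixed seed.
    """
    n = matrix.n_proteins
    if n_clusters > n or k > n:
        raise ProteomicsError("cluster counts cannot exceed the number of proteins")
    if n_clusters < 1 or k < 1:
        raise ProteomicsError("cluster counts must be positive")
    x = matrix.values.to_numpy(float)
    z = linkage(x, method="complete", metric="euclidean")
    clusters = fcluster(z, t=n_clusters, criterion="maxclust")

    sub = np.zeros(n, dtype=int)
    for cid in np.unique(clusters):
        idx = np.flatnonzero(clusters == cid)
        kk = min(k, idx.size)
        if kk == 1:
            sub[idx] = 1
            continue
        km = KMeans(n_clusters=kk, init="k-means++", n_init=10, random_state=seed)
        sub[idx] = km.fit_predict(x[idx]) + 1
    return pd.DataFrame(
        {"cluster": clusters, "subcluster": sub}, index=matrix.values.index
    )


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSetCollection:
    """Named identifier sets filtered against a universe and size window."""

    sets: Mapping[str, frozenset[str]]
    universe: frozenset[str]
    min_size: int = 3
    max_size: int = 5000

    def filtered(self) -> dict[str, frozenset[str]]:
        """Sets intersected with the universe and size-filtered."""
        out = {}
        for name, members in self.sets.items():
            inter = frozenset(members) & self.universe
            if self.min_size <= len(inter) <= self.max_size:
                out[name] = inter
        return out


def read_gmt(path: str, universe: Sequence[str],
             min_size: int = 3, max_size: int = 5000) -> GeneSetCollection:
    """Parse a GMT file (set name, description, members per tab-separated line)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return GeneSetCollection(
        sets=sets, universe=frozenset(universe), min_size=min_size, max_size=max_size
    )


def ora_enrichment(query: Sequence[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in each gene set.

    For each retained set, the upper-tail probability of observing at least
    the seen overlap between the query and the set within the universe;
    BH-adjusted across sets.
    """
    universe = collection.universe
    if not universe:
        raise ProteomicsError("empty universe")
    query_set = frozenset(query) & universe
    if frozenset(query) - universe:
        raise ProteomicsError("query contains identifiers outside the universe")
    m_univ = len(universe)
    n_query = len(query_set)
    rows = []
    for name, members in collection.filtered().items():
        k = len(query_set & members)
        # P(X >= k) for X ~ Hypergeom(M=universe, K=set size, N=query size)
        p = float(stats.hypergeom.sf(k - 1, m_univ, len(members), n_query))
        expected = n_query * len(members) / m_univ
        odds = (k / expected) if expected > 0 else np.nan
        rows.append(
            {
                "set": name,
                "method": "ora",
                "set_size": len(members),
                "overlap": k,
                "statistic": odds,  # fold enrichment over expectation
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = adjust_pvalues(out["p"].to_numpy(), "bh")
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Permutation GSEA
# ---------------------------------------------------------------------------

def _enrichment_score(
    in_set: np.ndarray, abs_scores: np.ndarray
) -> tuple[float, int]:
    """Weighted (exponent 1) KS running-sum ES and the index of its peak.

    ``in_set`` is a boolean mask over the ranking (descending scores);
    ``abs_scores`` the matching |score| weights.
    """
    n = in_set.size
    nh = int(in_set.sum())
    hit_weights = np.where(in_set, abs_scores, 0.0)
    total_hit = hit_weights.sum()
    if total_hit == 0:  # all member scores zero: fall back to unweighted hits
        hit_weights = in_set.astype(float)
        total_hit = hit_weights.sum()
    p_hit = np.cumsum(hit_weights) / total_hit
    p_miss = np.cumsum(~in_set) / max(n - nh, 1)
    running = p_hit - p_miss
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def gsea_permutation(
    ranking: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation gene-set enrichment over a scored protein ranking.

    ``ranking`` maps protein identifiers to finite scores; proteins are
    ranked by descending score and each set's enrichment score (ES) is the
    maximum deviation of the weighted (exponent 1) Kolmogorov-Smirnov
    running sum.  Null ES values come from ``n_perm`` gene-label
    permutations (random member sets of the same size); the p-value is
    sign-aware and NES = ES / mean(|ES_perm|) among same-sign permutations.
    Sets without members in the ranking are skipped.  BH across sets.
    """
    scores = ranking.astype(float)
    if not np.all(np.isfinite(scores.to_numpy())):
        raise ProteomicsError("ranking scores must be finite")
    if n_perm < 100:
        raise ProteomicsError("n_perm must be at least 100")
    order = np.argsort(-scores.to_numpy(), kind="stable")
    ranked_ids = scores.index.to_numpy()[order]
    abs_scores = np.abs(scores.to_numpy()[order])
    pos = {pid: i for i, pid in enumerate(ranked_ids)}
    n = len(ranked_ids)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in collection.filtered().items():
        idx = [pos[m] for m in members if m in pos]
        if not idx:
            continue  # set does not intersect the ranking
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es, peak = _enrichment_score(mask, abs_scores)

        size = len(idx)
        es_perm = np.empty(n_perm)
        for b in range(n_perm):
            pmask = np.zeros(n, dtype=bool)
            pmask[rng.choice(n, size=size, replace=False)] = True
            es_perm[b], _ = _enrichment_score(pmask, abs_scores)

        same_sign = es_perm >= 0 if es >= 0 else es_perm <= 0
        n_same = int(same_sign.sum())
        if es >= 0:
            extreme = int((es_perm >= es).sum())
        else:
            extreme = int((es_perm <= es).sum())
        p = (extreme + 1) / (n_perm + 1)
        denom = np.abs(es_perm[same_sign]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan

        if es >= 0:
            leading = [str(ranked_ids[i]) for i in sorted(idx) if i <= peak]
        else:
            leading = [str(ranked_ids[i]) for i in sorted(idx) if i >= peak]
        rows.append(
            {
                "set": name,
                "method": "gsea",
                "set_size": size,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = adjust_pvalues(out["p"].to_numpy(), "bh")
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    return out
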