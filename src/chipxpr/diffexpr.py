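"""Self-contained two-group differential expression and expression clustering.

The DE stage is a deliberately minimal negative-binomial pipeline:
median-of-ratios size factors, method-of-moments dispersion, a Wald test
on the log2 fold change with a delta-method standard error, and
Benjamini–Hochberg adjustment. With the small replicate numbers typical
of these designs (n = 2–3 per condition) the Wald statistic is referred
to a t distribution with n1 + n2 − 2 degrees of freedom rather than a
normal: the moment-based variance estimate is itself noisy, and the
normal reference is visibly anti-conservative at n = 3.

Clustering of condition-mean profiles uses PAM (partitioning around
medoids, BUILD + SWAP) on gene-wise z-scored rows with Euclidean
distance, with an optional second-level k = 2 split inside one cluster —
the construction behind the common "major clusters + subclusters"
presentation of DE heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .formats import CountMatrix


def size_factors(counts: pd.DataFrame | CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq normalisation).

    factor_j = median over genes g (with all counts > 0) of
    count_gj / geometric-mean_g. Identical columns give factors of 1.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with positive counts in every sample")
    sub = mat[allpos]
    log_geomean = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class DEResult:
    """Per-gene two-group test results."""

    table: pd.DataFrame  # base_mean, log2fc, se, stat, pvalue, padj, flagged

    def __len__(self):
        return len(self.table)


def nb_wald_test(cm: CountMatrix, condition_pair: tuple[str, str],
                 dispersion_floor: float = 1e-8) -> DEResult:
    """Two-group NB Wald test of ``condition_pair[1]`` vs ``[0]`` (reference).

    Counts are scaled by median-of-ratios factors; per-condition
    dispersion is estimated by method of moments,
    alpha = max(0, (s² − m)/m²), then averaged across the two conditions
    and floored. log2FC uses shrunken means (pseudo-mean +0.5); the Wald
    statistic log2FC/SE is referred to t(n1+n2−2). Genes with all-zero
    counts in both groups get p = 1, log2FC = 0 and a flag.
    """
    ref, alt = condition_pair
    s_ref = cm.samples_of(ref)
    s_alt = cm.samples_of(alt)
    if len(s_ref) < 2 or len(s_alt) < 2:
        raise ValueError("need ≥2 replicates per condition")
    sf = size_factors(cm.counts[s_ref + s_alt])
    norm = cm.counts[s_ref + s_alt] / sf
    x_ref = norm[s_ref].to_numpy()
    x_alt = norm[s_alt].to_numpy()
    n1, n2 = x_ref.shape[1], x_alt.shape[1]

    m1 = x_ref.mean(axis=1)
    m2 = x_alt.mean(axis=1)
    v1 = x_ref.var(axis=1, ddof=1)
    v2 = x_alt.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a1 = np.where(m1 > 0, (v1 - m1) / m1 ** 2, 0.0)
        a2 = np.where(m2 > 0, (v2 - m2) / m2 ** 2, 0.0)
    alpha = np.maximum((np.maximum(a1, 0) + np.maximum(a2, 0)) / 2,
                       dispersion_floor)

    sm1 = m1 + 0.5
    sm2 = m2 + 0.5
    log2fc = np.log2(sm2 / sm1)
    # delta method on log2 of a mean of NB draws: Var(log2 x̄) ≈
    # (μ + αμ²) / (n μ² ln²2) = (1/μ + α) / (n ln²2)
    var_log2 = ((1.0 / sm1 + alpha) / n1 + (1.0 / sm2 + alpha) / n2) / np.log(2) ** 2
    se = np.sqrt(var_log2)
    stat = log2fc / se
    df = n1 + n2 - 2
    pvalue = 2 * stats.t.sf(np.abs(stat), df)

    allzero = (cm.counts[s_ref + s_alt].to_numpy() == 0).all(axis=1)
    log2fc[allzero] = 0.0
    stat[allzero] = 0.0
    pvalue[allzero] = 1.0

    padj = multipletests(pvalue, method="fdr_bh")[1]
    table = pd.DataFrame({
        "base_mean": np.concatenate([x_ref, x_alt], axis=1).mean(axis=1),
        "log2fc": log2fc, "se": se, "stat": stat,
        "pvalue": pvalue, "padj": padj, "flagged": allzero,
    }, index=cm.counts.index)
    return DEResult(table=table)


def select_de(de: DEResult, lfc_min: float = 1.5, fdr: float = 0.05,
              strict: bool = False) -> pd.DataFrame:
    """Select DE genes: padj ≤ fdr and |log2FC| ≥ lfc_min (inclusive).

    Returns a frame with log2fc, padj and a ``direction`` column
    (up/down). ``strict`` switches the fold-change comparison to >.
    """
    t = de.table
    if strict:
        passing = (t["padj"] <= fdr) & (t["log2fc"].abs() > lfc_min)
    else:
        passing = (t["padj"] <= fdr) & (t["log2fc"].abs() >= lfc_min)
    sel = t.loc[passing, ["log2fc", "padj"]].copy()
    sel["direction"] = np.where(sel["log2fc"] > 0, "up", "down")
    return sel


# ---------------------------------------------------------------------------
# PAM clustering of condition-mean profiles


def _pam_build(dist: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase; ties broken by lowest index."""
    n = dist.shape[0]
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        current = dist[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions in nearest distance
        gains = np.maximum(current[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return medoids


def _pam_swap(dist: np.ndarray, medoids: list[int],
              max_iter: int = 200) -> tuple[list[int], list[float]]:
    """SWAP until no single medoid↔non-medoid exchange improves the cost."""
    n = dist.shape[0]
    medoids = list(medoids)
    costs = [float(dist[:, medoids].min(axis=1).sum())]
    for _ in range(max_iter):
        best = (0.0, None, None)
        cost0 = costs[-1]
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for j, x in enumerate(medoids) if j != mi]
            for h in range(n):
                if h in med_set:
                    continue
                new_cost = float(
                    np.minimum(dist[:, others].min(axis=1) if others else np.inf,
                               dist[:, h]).sum())
                delta = new_cost - cost0
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        costs.append(cost0 + best[0])
    return medoids, costs


@dataclass
class ExpressionClusters:
    """Cluster labels over a condition-mean matrix with PAM medoids."""

    labels: pd.Series            # gene → cluster label (strings "1", "2", ...)
    medoids: dict[str, str]      # cluster label → medoid gene id
    costs: list[float]           # PAM objective across SWAP iterations
    sublabels: pd.Series | None = None  # e.g. "1A"/"1B" inside one cluster

    @property
    def final_labels(self) -> pd.Series:
        """Labels with the optional subcluster split applied."""
        if self.sublabels is None:
            return self.labels
        out = self.labels.copy().astype(object)
        out.loc[self.sublabels.index] = self.sublabels
        return out


def pam(matrix: np.ndarray, k: int) -> tuple[np.ndarray, list[int], list[float]]:
    """PAM k-medoids with Euclidean distance; deterministic.

    Returns (labels as medoid indices 0..k-1, medoid row indices,
    objective trace). Assignment ties go to the earlier medoid.
    """
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    dist = cdist(matrix, matrix)
    medoids = _pam_build(dist, k)
    medoids, costs = _pam_swap(dist, medoids)
    labels = np.argmin(dist[:, medoids], axis=1)
    return labels, medoids, costs


def cluster_de(mean_matrix: pd.DataFrame, k: int,
               subcluster: str | None = None, sub_k: int = 2
               ) -> ExpressionClusters:
    """Cluster gene condition-mean profiles into k groups with PAM.

    Rows are z-scored per gene across conditions before clustering so
    groups reflect expression *pattern*, not level; constant rows z-score
    to zero. Clusters are labelled "1".."k" by size (largest first).
    ``subcluster`` names one cluster to split again with PAM k=``sub_k``
    (labels "1A", "1B", ...), the usual major-cluster/subcluster
    presentation.
    """
    mat = mean_matrix.to_numpy(dtype=float)
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (mat - mu) / np.where(sd == 0, 1, sd), 0.0)
    raw_labels, medoid_idx, costs = pam(z, k)

    order = np.argsort([-(raw_labels == c).sum() for c in range(k)], kind="stable")
    rename = {int(c): str(i + 1) for i, c in enumerate(order)}
    labels = pd.Series([rename[int(c)] for c in raw_labels],
                       index=mean_matrix.index, name="cluster")
    medoids = {rename[i]: mean_matrix.index[m]
               for i, m in enumerate(medoid_idx)}

    sublabels = None
    if subcluster is not None:
        members = labels.index[labels == subcluster]
        if len(members) < sub_k:
            raise ValueError(f"cluster {subcluster!r} too small to split")
        sub_z = z[labels.to_numpy() == subcluster]
        sub_raw, sub_medoids, _ = pam(sub_z, sub_k)
        sub_order = np.argsort([-(sub_raw == c).sum() for c in range(sub_k)],
                               kind="stable")
        sub_rename = {int(c): subcluster + chr(ord("A") + i)
                      for i, c in enumerate(sub_order)}
        sublabels = pd.Series([sub_rename[int(c)] for c in sub_raw],
                              index=members, name="subcluster")
    return ExpressionClusters(labels=labels, medoids=medoids, costs=costs,
                              sublabels=sublabels)


def condition_means(cm: CountMatrix, genes=None) -> pd.DataFrame:
    """Size-factor-normalised per-condition mean counts (genes × conditions)."""
    sf = size_factors(cm.counts)
    norm = cm.counts / sf
    if genes is not None:
        norm = norm.loc[genes]
    cols = {}
    for cond in cm.condition_names:
        cols[cond] = norm[cm.samples_of(cond)].mean(axis=1)
    return pd.DataFrame(cols)
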