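"""Gene-set enrichment analysis: weighted KS enrichment score, NES, FDR q.

The enrichment score walks down a ranked gene list, incrementing by the
weighted metric for gene-set hits and decrementing uniformly for misses;
ES is the maximum signed deviation of the running sum. With weight
exponent p = 0 this is the classic Kolmogorov–Smirnov statistic. The
null is built by gene-set permutation (random sets of matching size) —
the appropriate choice when replicate numbers are too small for
phenotype permutation — and ES values are normalised by the mean
magnitude of sign-matched null scores to give the NES, with FDR q from
the standard sign-stratified pooling of observed and null NES.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RankedList:
    """Genes ordered by a ranking metric (descending; metric retained)."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate genes in ranked list")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self):
        return len(self.genes)


def rank_genes(matrix: pd.DataFrame, phenotypes: dict[str, str],
               pair: tuple[str, str], metric: str = "s2n",
               sd_floor_factor: float = 0.2) -> RankedList:
    """Rank genes by signal-to-noise or log2 fold change between phenotypes.

    s2n = (mean_a − mean_b) / (sd_a + sd_b); a zero sd is replaced by
    ``sd_floor_factor × |mean|`` (the conventional fix for degenerate
    variance). Ties are broken by gene id; order is descending in the
    metric. ``pair[0]`` is the phenotype whose high expressors rank first.
    """
    a_cols = [s for s in matrix.columns if phenotypes[s] == pair[0]]
    b_cols = [s for s in matrix.columns if phenotypes[s] == pair[1]]
    if not a_cols or not b_cols:
        raise ValueError("both phenotypes need ≥1 sample")
    ma = matrix[a_cols].mean(axis=1).to_numpy()
    mb = matrix[b_cols].mean(axis=1).to_numpy()
    if metric == "s2n":
        if len(a_cols) < 2 or len(b_cols) < 2:
            raise ValueError("signal-to-noise needs ≥2 samples per phenotype")
        sa = matrix[a_cols].std(axis=1, ddof=1).to_numpy()
        sb = matrix[b_cols].std(axis=1, ddof=1).to_numpy()
        # zero SDs only are replaced by the conventional 0.2·|mean| floor
        sa = np.where(sa < 1e-12,
                      np.maximum(sd_floor_factor * np.abs(ma), 1e-8), sa)
        sb = np.where(sb < 1e-12,
                      np.maximum(sd_floor_factor * np.abs(mb), 1e-8), sb)
        vals = (ma - mb) / (sa + sb)
    elif metric == "log2fc":
        # plain ratio of means; floor guards zero means
        vals = np.log2(np.maximum(ma, 1e-3) / np.maximum(mb, 1e-3))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.lexsort((matrix.index.to_numpy(), -vals))
    return RankedList(genes=matrix.index.to_numpy()[order], metric=vals[order])


def enrichment_score(ranked: RankedList, geneset,
                     p: float = 1.0) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score and the full running sum.

    Hits increment by |metric|^p / Σ_set |metric|^p, misses decrement by
    1/(N − N_set); ES is the running-sum value of maximal magnitude.
    Degenerate cases: a set covering every gene scores 1; all-zero hit
    weights fall back to equal weights.
    """
    members = np.isin(ranked.genes, list(geneset))
    n_set = int(members.sum())
    if n_set == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    n = len(ranked)
    if n_set == n:
        return 1.0, np.ones(n)
    weights = np.abs(ranked.metric) ** p
    total = weights[members].sum()
    steps = np.where(members,
                     weights / total if total > 0 else 1.0 / n_set,
                     -1.0 / (n - n_set))
    running = np.cumsum(steps)
    i = int(np.argmax(np.abs(running)))
    return float(running[i]), running


@dataclass
class EnrichmentResult:
    name: str
    es: float
    nes: float
    pvalue: float
    fdr_q: float
    n_perm: int
    size: int


def nes_fdr(ranked: RankedList, genesets: dict[str, set],
            n_perm: int = 1000, p: float = 1.0,
            seed: int | np.random.Generator = 0) -> list[EnrichmentResult]:
    """NES and FDR q for each gene set via gene-set permutation.

    Null ES come from ``n_perm`` random gene sets of matching size drawn
    from the ranked universe. NES = ES / mean(|null ES| of the same
    sign); nominal p is the same-sign null exceedance fraction; q follows
    the standard positive/negative pooling of observed vs null NES.
    Deterministic for a fixed seed.
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; q-value resolution is coarse")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(ranked)

    observed = {name: enrichment_score(ranked, gs, p=p)[0]
                for name, gs in genesets.items()}
    sizes = {name: int(np.isin(ranked.genes, list(gs)).sum())
             for name, gs in genesets.items()}

    # one null per distinct set size, reused across sets of that size
    null_by_size: dict[int, np.ndarray] = {}
    for size in sorted(set(sizes.values())):
        null = np.empty(n_perm)
        for i in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            null[i] = _es_from_indices(ranked, idx, p)
        null_by_size[size] = null

    def _nes(es, null):
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if len(same) else np.abs(null).mean()
        return es / denom if denom > 0 else 0.0

    nes_obs = {name: _nes(es, null_by_size[sizes[name]])
               for name, es in observed.items()}
    nes_null_all = np.concatenate([
        np.array([_nes(e, null_by_size[size]) for e in null_by_size[size]])
        for size in null_by_size
    ])
    nes_obs_all = np.array(list(nes_obs.values()))

    results = []
    for name, es in observed.items():
        null = null_by_size[sizes[name]]
        if es >= 0:
            same = null[null >= 0]
            pval = float((same >= es).mean()) if len(same) else 1.0
        else:
            same = null[null < 0]
            pval = float((same <= es).mean()) if len(same) else 1.0
        nes = nes_obs[name]
        if nes >= 0:
            num = (nes_null_all >= nes).mean() / max((nes_null_all >= 0).mean(), 1e-12)
            den = (nes_obs_all >= nes).mean() / max((nes_obs_all >= 0).mean(), 1e-12)
        else:
            num = (nes_null_all <= nes).mean() / max((nes_null_all < 0).mean(), 1e-12)
            den = (nes_obs_all <= nes).mean() / max((nes_obs_all < 0).mean(), 1e-12)
        q = float(np.clip(num / max(den, 1e-12), 0.0, 1.0))
        results.append(EnrichmentResult(
            name=name, es=float(es), nes=float(nes), pvalue=pval,
            fdr_q=q, n_perm=n_perm, size=sizes[name]))
    return results


def _es_from_indices(ranked: RankedList, member_idx: np.ndarray, p: float) -> float:
    """ES for a membership given directly as rank indices (permutation path)."""
    n = len(ranked)
    members = np.zeros(n, dtype=bool)
    members[member_idx] = True
    weights = np.abs(ranked.metric) ** p
    total = weights[members].sum()
    steps = np.where(members,
                     weights / total if total > 0 else 1.0 / members.sum(),
                     -1.0 / (n - members.sum()))
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_set": r.name, "size": r.size, "es": r.es, "nes": r.nes,
        "pvalue": r.pvalue, "fdr_q": r.fdr_q, "n_perm": r.n_perm,
    } for r in results])
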