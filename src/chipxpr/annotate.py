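"""Peak-to-gene assignment and cross-tabulation against expression clusters.

Every peak gets exactly one nearest-TSS assignment (ties broken by the
lexicographically smaller gene id) with a signed distance measured in the
gene's orientation: negative = upstream of the TSS. Cluster association
follows the convention of counting a peak for a cluster when its summit
lies within ±5 kb (inclusive) of any member gene's TSS; a peak near genes
of two clusters is counted once per cluster and flagged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .formats import GenomeAnnotation

FEATURE_PRIORITY = ["promoter", "exon", "intron", "downstream", "intergenic"]


def nearest_tss(peaks: pd.DataFrame, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Assign each peak to the gene with the closest TSS on its chromosome.

    Returns columns: peak, gene_id, distance (signed, gene orientation),
    abs_distance. Peaks on chromosomes without genes get gene_id NA and
    are flagged ``orphan``.
    """
    records = []
    for chrom, sub in peaks.groupby("chrom", sort=False):
        genes = annotation.genes_on(chrom)
        if genes.empty:
            for row in sub.itertuples():
                records.append((row.name, None, np.nan, np.nan, True))
            continue
        tss = genes["tss"].to_numpy()
        gids = genes["gene_id"].to_numpy()
        strands = genes["strand"].to_numpy()
        summits = sub["summit"].to_numpy()
        right = np.searchsorted(tss, summits, side="left")
        for row, r in zip(sub.itertuples(), right):
            # candidates: nearest TSS at/after the summit and the one before,
            # widened to all genes tied at the winning |distance|
            cand = []
            if r < len(tss):
                cand.append(r)
            if r > 0:
                cand.append(r - 1)
            best_abs = min(abs(int(row.summit) - int(tss[i])) for i in cand)
            # widen to ties: TSS array is sorted, equal-distance genes adjoin
            lo = r - 1
            while lo >= 0 and abs(int(row.summit) - int(tss[lo])) == best_abs:
                cand.append(lo)
                lo -= 1
            hi = r
            while hi < len(tss) and abs(int(row.summit) - int(tss[hi])) == best_abs:
                cand.append(hi)
                hi += 1
            tied = sorted({i for i in cand
                           if abs(int(row.summit) - int(tss[i])) == best_abs},
                          key=lambda i: gids[i])
            i = tied[0]
            sign = 1 if strands[i] == "+" else -1
            records.append((row.name, gids[i],
                            sign * (int(row.summit) - int(tss[i])), best_abs, False))
    return pd.DataFrame(
        records, columns=["peak", "gene_id", "distance", "abs_distance", "orphan"],
    )


def cluster_association(groups: dict[str, pd.DataFrame],
                        clusters: pd.Series,
                        annotation: GenomeAnnotation,
                        window: int = 5000) -> pd.DataFrame:
    """Count peaks within ±``window`` bp of clustered genes' TSS, per group.

    ``clusters`` maps gene_id → cluster label. A peak counts for cluster c
    iff |summit − TSS| ≤ window for ≥1 gene of c (inclusive boundary). A
    peak close to genes of several clusters counts once per cluster;
    ``n_multi`` flags how many such peaks each group contains. Fractions
    are counts over the group's total peak number, so they sum to ≤ 1 per
    group (the remainder sits near non-clustered genes or nothing at all).
    """
    cluster_labels = sorted(clusters.unique())
    gene_cluster = clusters.to_dict()
    rows = []
    for gname, peaks in groups.items():
        total = len(peaks)
        counts = {c: 0 for c in cluster_labels}
        multi = 0
        for chrom, sub in peaks.groupby("chrom", sort=False):
            genes = annotation.genes_on(chrom)
            if genes.empty:
                continue
            tss = genes["tss"].to_numpy()
            gids = genes["gene_id"].to_numpy()
            for row in sub.itertuples():
                lo = np.searchsorted(tss, row.summit - window, side="left")
                hi = np.searchsorted(tss, row.summit + window, side="right")
                near = {gene_cluster[g] for g in gids[lo:hi] if g in gene_cluster}
                for c in near:
                    counts[c] += 1
                if len(near) > 1:
                    multi += 1
        row_out = {"group": gname, "n_peaks": total, "n_multi": multi}
        for c in cluster_labels:
            row_out[f"count_{c}"] = counts[c]
            row_out[f"frac_{c}"] = counts[c] / total if total else 0.0
        rows.append(row_out)
    return pd.DataFrame(rows)


def genomic_features(peaks: pd.DataFrame, annotation: GenomeAnnotation,
                     promoter_window: tuple[int, int] = (-3000, 3000),
                     downstream_span: int = 3000) -> pd.Series:
    """Classify each peak summit into a genomic feature class.

    Priority promoter > exon > intron > downstream > intergenic, evaluated
    at the summit. The promoter window is relative to the TSS in gene
    orientation (default TSS ± 3 kb); downstream = within
    ``downstream_span`` bp past the gene end, again in orientation. The
    classes partition the peaks.
    """
    up, down = promoter_window
    exons_by_gene = {g: sub for g, sub in annotation.exons.groupby("gene_id")}
    labels = []
    for row in peaks.itertuples():
        genes = annotation.genes_on(row.chrom)
        label = "intergenic"
        if not genes.empty:
            s = int(row.summit)
            is_promoter = is_exon = is_intron = is_down = False
            for g in genes.itertuples():
                rel = (s - g.tss) if g.strand == "+" else (g.tss - s)
                if up <= rel <= down:
                    is_promoter = True
                    break
                if g.start <= s < g.end:
                    ex = exons_by_gene.get(g.gene_id)
                    in_exon = ex is not None and bool(
                        ((ex["start"] <= s) & (s < ex["end"])).any())
                    if in_exon:
                        is_exon = True
                    else:
                        is_intron = True
                    continue
                past = (s - g.end) if g.strand == "+" else (g.start - 1 - s)
                if 0 <= past < downstream_span:
                    is_down = True
            if is_promoter:
                label = "promoter"
            elif is_exon:
                label = "exon"
            elif is_intron:
                label = "intron"
            elif is_down:
                label = "downstream"
        labels.append(label)
    return pd.Series(labels, index=pd.Index(peaks["name"], name="peak"),
                     name="feature")


def feature_fractions(features: pd.Series) -> pd.DataFrame:
    """Tabulate feature-class counts and fractions (pie-chart source)."""
    counts = features.value_counts()
    rows = []
    for cls in FEATURE_PRIORITY:
        n = int(counts.get(cls, 0))
        rows.append({"feature": cls, "count": n,
                     "fraction": n / len(features) if len(features) else 0.0})
    return pd.DataFrame(rows)
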