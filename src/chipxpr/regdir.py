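"""Direction-of-regulation analysis for motif-stratified peak classes.

Given peaks assigned to genes (nearest TSS) and a DE call per gene, each
peak class is summarised by the fractions of its peaks whose assigned
genes are up-, down- or not regulated, and by smoothed curves of peak
density versus signed distance to the TSS — the view that separates
promoter-proximal repression from distal activation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def direction_fractions(assignments: pd.DataFrame, de_selection: pd.DataFrame,
                        classes: pd.Series) -> dict[str, pd.DataFrame]:
    """Tabulate up/down/non-DE fractions per peak class.

    ``assignments``: nearest-TSS table (peak, gene_id, ...);
    ``de_selection``: output of :func:`chipxpr.diffexpr.select_de`
    (indexed by gene, ``direction`` column); ``classes``: peak → class.

    Returns two tables: ``peak_level`` (each peak votes once via its
    assigned gene, so a gene with several peaks is counted once per
    peak) and ``gene_level`` (each distinct assigned gene counted once
    per class). Fractions over {up, down, non_de} sum to 1 per class.
    """
    gene_dir = de_selection["direction"].to_dict()
    merged = assignments[["peak", "gene_id"]].copy()
    merged["class"] = classes.reindex(merged["peak"]).to_numpy()
    merged = merged.dropna(subset=["class", "gene_id"])
    merged["direction"] = merged["gene_id"].map(lambda g: gene_dir.get(g, "non_de"))

    def _table(df: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for cls, sub in df.groupby("class"):
            n = len(sub)
            if n == 0:
                continue
            counts = sub["direction"].value_counts()
            row = {"class": cls, "n": n}
            for d in ("up", "down", "non_de"):
                row[f"n_{d}"] = int(counts.get(d, 0))
                row[f"frac_{d}"] = counts.get(d, 0) / n
            rows.append(row)
        return pd.DataFrame(rows)

    empty = set(classes.dropna().unique()) - set(merged["class"].unique())
    if empty:
        warnings.warn(f"peak classes with no assigned genes omitted: {sorted(empty)}")

    peak_level = _table(merged)
    gene_level = _table(merged.drop_duplicates(subset=["class", "gene_id"]))
    return {"peak_level": peak_level, "gene_level": gene_level}


def distance_direction_curve(assignments: pd.DataFrame,
                             de_selection: pd.DataFrame,
                             classes: pd.Series,
                             halfspan: int = 30000,
                             bandwidth: float = 2000,
                             n_grid: int = 200) -> pd.DataFrame:
    """Smoothed peak density vs signed TSS distance per (class, direction).

    A Gaussian kernel of the given bandwidth (bp) is summed over the
    signed distances of each (peak class × gene direction) stratum and
    evaluated on an ``n_grid``-point grid over [−halfspan, +halfspan].
    Curves are scaled to counts: each integrates (over the real line) to
    the stratum's peak count, so heights are comparable across strata.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    gene_dir = de_selection["direction"].to_dict()
    merged = assignments[["peak", "gene_id", "distance"]].copy()
    merged["class"] = classes.reindex(merged["peak"]).to_numpy()
    merged = merged.dropna(subset=["class", "gene_id", "distance"])
    merged["direction"] = merged["gene_id"].map(lambda g: gene_dir.get(g, "non_de"))

    grid = np.linspace(-halfspan, halfspan, n_grid)
    norm = 1.0 / (bandwidth * np.sqrt(2 * np.pi))
    frames = []
    for (cls, direction), sub in merged.groupby(["class", "direction"]):
        d = sub["distance"].to_numpy(dtype=float)
        dens = norm * np.exp(-0.5 * ((grid[:, None] - d[None, :]) / bandwidth) ** 2
                             ).sum(axis=1)
        frames.append(pd.DataFrame({
            "class": cls, "direction": direction, "n": len(d),
            "distance": grid, "density": dens,
        }))
    if not frames:
        return pd.DataFrame(columns=["class", "direction", "n",
                                     "distance", "density"])
    return pd.concat(frames, ignore_index=True)
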