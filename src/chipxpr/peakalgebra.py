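"""Summit-window construction and unique/common/k-way peak-set partitions.

The overlap rule throughout: two peaks overlap iff the ``w`` bp windows
centred on their summits share at least 1 bp, with all intervals 0-based
half-open. For the default ``w=300`` a summit pair 299 bp apart is
therefore "common" and a pair 300 bp apart is not.

The k-way partition merges pooled windows transitively (single linkage on
≥1 bp overlap), so a chain of pairwise-adjacent windows collapses into one
merged region labelled with every contributing set — the behaviour of
merge-based peak tooling. Because merging is many-to-one, class sizes are
reported both as merged regions and as contributing source peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def summit_windows(peaks: pd.DataFrame, w: int = 300,
                   chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Build ``w`` bp windows centred on peak summits.

    Window = [summit − w//2, summit + (w − w//2)), clipped to
    [0, chrom length) when sizes are known; clipping at 0 is always
    applied. Returns columns chrom, start, end, peak (source peak name).
    """
    if w < 1:
        raise ValueError("window width must be ≥ 1")
    half = w // 2
    start = peaks["summit"].to_numpy() - half
    end = peaks["summit"].to_numpy() + (w - half)
    start = np.maximum(start, 0)
    if chrom_sizes is not None:
        limits = np.array([chrom_sizes[c] for c in peaks["chrom"]])
        end = np.minimum(end, limits)
    out = pd.DataFrame({
        "chrom": peaks["chrom"].to_numpy(),
        "start": start, "end": end,
        "peak": peaks["name"].to_numpy(),
    })
    return out


def _overlaps_any(query: pd.DataFrame, target: pd.DataFrame) -> np.ndarray:
    """For each query window, does it overlap ≥1 bp with any target window?

    Sorted-sweep: per chromosome, targets sorted by start with a running
    prefix-max of ends; query [s, e) overlaps some target iff among
    targets with start < e the maximum end exceeds s.
    """
    result = np.zeros(len(query), dtype=bool)
    targets_by_chrom = {c: sub for c, sub in target.groupby("chrom", sort=False)}
    for chrom, qsub in query.groupby("chrom", sort=False):
        tsub = targets_by_chrom.get(chrom)
        if tsub is None:
            continue
        order = np.argsort(tsub["start"].to_numpy(), kind="stable")
        t_start = tsub["start"].to_numpy()[order]
        t_end_max = np.maximum.accumulate(tsub["end"].to_numpy()[order])
        idx = np.searchsorted(t_start, qsub["end"].to_numpy(), side="left")
        has = (idx > 0) & (t_end_max[np.maximum(idx - 1, 0)] > qsub["start"].to_numpy())
        result[qsub.index.to_numpy()] = has
    return result


@dataclass
class PairClasses:
    """classify_pair output: per-peak labels plus class summaries."""

    a_labels: pd.Series  # "unique" | "common", indexed by peak name
    b_labels: pd.Series
    a_name: str
    b_name: str

    def counts(self) -> dict[str, int]:
        return {
            f"{self.a_name}_unique": int((self.a_labels == "unique").sum()),
            "common": int((self.a_labels == "common").sum()
                          + (self.b_labels == "common").sum()),
            f"{self.b_name}_unique": int((self.b_labels == "unique").sum()),
        }


def classify_pair(set_a: pd.DataFrame, set_b: pd.DataFrame, w: int = 300,
                  names: tuple[str, str] = ("A", "B"),
                  chrom_sizes: dict[str, int] | None = None) -> PairClasses:
    """Classify peaks of two sets as set-unique or common.

    A peak is "common" iff its summit window overlaps ≥1 bp with at least
    one summit window of the other set; otherwise unique to its set. The
    operation is symmetric: swapping A and B exchanges the labels.
    """
    wa = summit_windows(set_a, w, chrom_sizes)
    wb = summit_windows(set_b, w, chrom_sizes)
    a_common = _overlaps_any(wa.reset_index(drop=True), wb)
    b_common = _overlaps_any(wb.reset_index(drop=True), wa)
    return PairClasses(
        a_labels=pd.Series(np.where(a_common, "common", "unique"),
                           index=pd.Index(set_a["name"], name="peak")),
        b_labels=pd.Series(np.where(b_common, "common", "unique"),
                           index=pd.Index(set_b["name"], name="peak")),
        a_name=names[0], b_name=names[1],
    )


@dataclass
class MembershipPartition:
    """Generalised Venn classes of merged summit windows.

    ``regions``: one row per merged region (chrom, start, end, members —
    a frozenset of set names — and the contributing peak names per set).
    ``set_names``: the input collection's names in input order.
    """

    regions: pd.DataFrame
    set_names: list[str]

    def class_counts(self) -> pd.DataFrame:
        """Region and source-peak counts per membership class.

        Covers every non-empty subset of the input sets, including classes
        with zero regions, so the 2^k − 1 Venn cells are all reported.
        """
        from itertools import combinations

        rows = []
        for r in range(1, len(self.set_names) + 1):
            for combo in combinations(self.set_names, r):
                key = frozenset(combo)
                sub = self.regions[self.regions["members"] == key]
                n_peaks = int(sum(
                    len(p) for peaks in sub["peaks"] for p in peaks.values()
                ))
                rows.append({
                    "members": "&".join(combo),
                    "n_regions": len(sub),
                    "n_source_peaks": n_peaks,
                })
        return pd.DataFrame(rows)

    def peaks_in_class(self, members: frozenset[str]) -> dict[str, list[str]]:
        """Contributing peak names per set for one membership class."""
        out: dict[str, list[str]] = {s: [] for s in members}
        for _, row in self.regions[self.regions["members"] == members].iterrows():
            for s, names in row["peaks"].items():
                out[s].extend(names)
        return out


def membership_partition(sets: dict[str, pd.DataFrame], w: int = 300,
                         chrom_sizes: dict[str, int] | None = None
                         ) -> MembershipPartition:
    """Pool summit windows from ≥2 named sets and merge transitively.

    Each merged region carries the set of contributing set names; class
    counts are the generalised Venn counts. Every input peak contributes
    to exactly one merged region.
    """
    if len(sets) < 2:
        raise ValueError("membership_partition needs ≥2 peak sets")
    frames = []
    for name, peaks in sets.items():
        win = summit_windows(peaks, w, chrom_sizes)
        win["set"] = name
        frames.append(win)
    pooled = pd.concat(frames, ignore_index=True)
    pooled = pooled.sort_values(["chrom", "start", "end"], kind="stable")

    regions = []
    for chrom, sub in pooled.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        run_max = np.maximum.accumulate(ends)
        # a new merged region begins where a window clears everything before it
        breaks = np.flatnonzero(starts[1:] >= run_max[:-1]) + 1
        bounds = np.concatenate([[0], breaks, [len(sub)]])
        for i0, i1 in zip(bounds[:-1], bounds[1:]):
            block = sub.iloc[i0:i1]
            peaks_by_set: dict[str, list[str]] = {}
            for s, names in block.groupby("set")["peak"]:
                peaks_by_set[s] = list(names)
            regions.append({
                "chrom": chrom,
                "start": int(block["start"].min()),
                "end": int(block["end"].max()),
                "members": frozenset(peaks_by_set),
                "peaks": peaks_by_set,
            })
    return MembershipPartition(
        regions=pd.DataFrame(regions,
                             columns=["chrom", "start", "end", "members", "peaks"]),
        set_names=list(sets),
    )


def partition_to_table(part: MembershipPartition) -> pd.DataFrame:
    """Flatten a partition to a writable table (one row per region)."""
    rows = []
    for i, r in part.regions.iterrows():
        rows.append({
            "region_id": f"region_{i}",
            "chrom": r["chrom"], "start": r["start"], "end": r["end"],
            "members": "&".join(sorted(r["members"])),
            "peak_ids": ";".join(
                f"{s}:{p}" for s in sorted(r["peaks"]) for p in r["peaks"][s]),
        })
    return pd.DataFrame(rows)
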