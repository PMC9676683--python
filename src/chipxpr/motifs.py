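"""Known-motif scanning in summit-centred windows.

Motifs are either IUPAC consensus strings (matched exactly up to a
mismatch budget) or position probability matrices scored as log-odds
against a uniform background. Scans cover both strands of a window of
±`halfwidth` bp around each peak summit (250 bp total at the default,
the span conventionally used for motif analysis around ChIP summits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    """Reverse-complement a (possibly degenerate) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 indices; non-ACGT bases become 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class MotifModel:
    """A named sequence motif: IUPAC consensus or PWM with threshold."""

    name: str
    kind: str  # "consensus" | "pwm"
    consensus: str | None = None
    max_mismatches: int = 0
    pwm: np.ndarray | None = field(default=None, repr=False)
    threshold: float | None = None

    @classmethod
    def from_consensus(cls, name: str, consensus: str,
                       max_mismatches: int = 0) -> "MotifModel":
        consensus = consensus.upper()
        if len(consensus) < 4:
            raise ValueError(f"motif {name!r}: length {len(consensus)} < 4")
        bad = set(consensus) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {name!r}: invalid IUPAC letter(s) {sorted(bad)}")
        if max_mismatches < 0:
            raise ValueError("max_mismatches must be ≥ 0")
        return cls(name=name, kind="consensus", consensus=consensus,
                   max_mismatches=max_mismatches)

    @classmethod
    def from_pwm(cls, name: str, pwm: np.ndarray, threshold: float) -> "MotifModel":
        pwm = np.asarray(pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValueError(f"motif {name!r}: PWM must be length × 4")
        if pwm.shape[0] < 4:
            raise ValueError(f"motif {name!r}: length {pwm.shape[0]} < 4")
        sums = pwm.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"motif {name!r}: PWM rows must sum to 1 ± 1e-6")
        return cls(name=name, kind="pwm", pwm=pwm, threshold=float(threshold))

    def __len__(self) -> int:
        return len(self.consensus) if self.kind == "consensus" else self.pwm.shape[0]

    # -- internal scan machinery -------------------------------------------

    def _allowed_table(self, consensus: str) -> np.ndarray:
        """Boolean (L × 5) table: allowed[i, b] for base index b (4 = other)."""
        table = np.zeros((len(consensus), 5), dtype=bool)
        for i, code in enumerate(consensus):
            for base in IUPAC[code]:
                table[i, _BASE_INDEX[base]] = True
        return table

    def _logodds(self) -> np.ndarray:
        """Log2-odds matrix against uniform background, padded for non-ACGT."""
        lo = np.log2(np.maximum(self.pwm, 1e-9) / 0.25)
        return np.hstack([lo, np.full((lo.shape[0], 1), -30.0)])

    def _scan_strand(self, enc: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (start positions, scores) of hits on an encoded sequence."""
        L = len(self)
        if enc.size < L:
            return np.empty(0, dtype=int), np.empty(0)
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        if self.kind == "consensus":
            allowed = self._allowed_table(self.consensus)
            ok = allowed[np.arange(L)[None, :], windows]
            mism = L - ok.sum(axis=1)
            pos = np.flatnonzero(mism <= self.max_mismatches)
            return pos, -mism[pos].astype(float)
        lo = self._logodds()
        scores = lo[np.arange(L)[None, :], windows].sum(axis=1)
        pos = np.flatnonzero(scores >= self.threshold)
        return pos, scores[pos]

    def scan(self, seq: str, dedup: bool = True) -> pd.DataFrame:
        """Scan both strands of ``seq``; return hits as a DataFrame.

        Columns: ``pos`` (0-based start of the hit on the forward strand),
        ``strand``, ``score`` (log-odds for PWMs, −mismatches for
        consensus). With ``dedup`` (default), a palindromic motif hitting
        both strands at the same position is reported once ('+' kept).
        """
        enc = _encode(seq)
        L = len(self)
        fwd_pos, fwd_score = self._scan_strand(enc)
        rc_enc = _encode(reverse_complement(seq))
        rev_raw, rev_score = self._scan_strand(rc_enc)
        # position p on the reverse strand maps to forward start n - p - L
        rev_pos = len(seq) - rev_raw - L
        hits = pd.DataFrame({
            "pos": np.concatenate([fwd_pos, rev_pos]),
            "strand": ["+"] * len(fwd_pos) + ["-"] * len(rev_pos),
            "score": np.concatenate([fwd_score, rev_score]),
        })
        hits = hits.sort_values(["pos", "strand"], kind="stable").reset_index(drop=True)
        if dedup:
            hits = hits.drop_duplicates(subset="pos", keep="first").reset_index(drop=True)
        return hits


# ---------------------------------------------------------------------------
# peak-window scanning


def scan_window(peaks: pd.DataFrame, genome: dict[str, str], motif: MotifModel,
                halfwidth: int = 125, dedup: bool = True) -> pd.DataFrame:
    """Scan ±``halfwidth`` bp around every peak summit for ``motif``.

    Returns one row per hit: peak name, motif name, strand, ``offset`` of
    the hit start relative to the summit, score, and a ``clipped`` flag set
    when the window ran off a sequence end and was truncated.
    """
    records = []
    for row in peaks.itertuples():
        seq = genome[row.chrom]
        w0 = row.summit - halfwidth
        w1 = row.summit + halfwidth
        clipped = w0 < 0 or w1 > len(seq)
        a, b = max(w0, 0), min(w1, len(seq))
        hits = motif.scan(seq[a:b], dedup=dedup)
        for h in hits.itertuples():
            records.append((row.name, motif.name, h.strand,
                            a + h.pos - row.summit, h.score, clipped))
    return pd.DataFrame(
        records, columns=["peak", "motif", "strand", "offset", "score", "clipped"],
    )


def counts_per_peak(hits: pd.DataFrame, peaks: pd.DataFrame,
                    groups: pd.Series | None = None):
    """Per-peak motif-instance counts and the {0,1,2,3+} histogram.

    Returns ``(counts, summary)``: ``counts`` is an integer Series indexed
    by peak name; ``summary`` a DataFrame with one row per group (a single
    ``all`` group when ``groups`` is None) giving the count distribution
    and the fraction of peaks with ≥1 instance.
    """
    counts = pd.Series(0, index=pd.Index(peaks["name"], name="peak"), dtype=int)
    if len(hits):
        observed = hits.groupby("peak").size()
        counts.loc[observed.index] = observed
    if groups is None:
        groups = pd.Series("all", index=counts.index)
    else:
        groups = groups.reindex(counts.index)
    rows = []
    for gname, sub in counts.groupby(groups):
        binned = np.clip(sub.to_numpy(), 0, 3)
        dist = np.bincount(binned, minlength=4)
        rows.append({
            "group": gname, "n_peaks": len(sub),
            "n0": dist[0], "n1": dist[1], "n2": dist[2], "n3plus": dist[3],
            "frac_with_motif": float((sub >= 1).mean()) if len(sub) else 0.0,
        })
    return counts, pd.DataFrame(rows)


def positional_distribution(hits: pd.DataFrame, n_peaks: int,
                            binsize: int = 10, halfwidth: int = 125) -> pd.DataFrame:
    """Fraction of peaks with ≥1 hit starting in each offset bin.

    Bins tile [−halfwidth, +halfwidth); ``binsize`` must divide the span.
    """
    span = 2 * halfwidth
    if span % binsize != 0:
        raise ValueError(f"binsize {binsize} does not divide window span {span}")
    edges = np.arange(-halfwidth, halfwidth + 1, binsize)
    centers = (edges[:-1] + edges[1:]) / 2
    freq = np.zeros(len(centers))
    if len(hits) and n_peaks > 0:
        bin_idx = (hits["offset"].to_numpy() + halfwidth) // binsize
        ok = (bin_idx >= 0) & (bin_idx < len(centers))
        per_bin = (
            pd.DataFrame({"bin": bin_idx[ok], "peak": hits["peak"].to_numpy()[ok]})
            .drop_duplicates().groupby("bin").size()
        )
        freq[per_bin.index.astype(int)] = per_bin.to_numpy() / n_peaks
    return pd.DataFrame({"bin_start": edges[:-1], "bin_center": centers,
                         "frequency": freq})


def partition_by_motif(peaks: pd.DataFrame, own_hits: pd.DataFrame,
                       ebox_hits: pd.DataFrame) -> pd.Series:
    """Partition peaks by motif content: own_only / ebox_containing / neither.

    A peak with ≥1 E-box hit is ``ebox_containing`` regardless of its own
    motif (the E-box marks bHLH co-binding); ``own_only`` requires ≥1 own
    hit and no E-box; the rest are ``neither``. Classes are disjoint and
    exhaustive over the input peaks.
    """
    names = pd.Index(peaks["name"], name="peak")
    has_own = names.isin(own_hits["peak"]) if len(own_hits) else np.zeros(len(names), bool)
    has_ebox = names.isin(ebox_hits["peak"]) if len(ebox_hits) else np.zeros(len(names), bool)
    labels = np.where(has_ebox, "ebox_containing",
                      np.where(has_own, "own_only", "neither"))
    return pd.Series(labels, index=names, name="motif_class")
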