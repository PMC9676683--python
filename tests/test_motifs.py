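"""Motif scanning: hand-derived hits, strand symmetry, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from chipxpr import motifs as M
from chipxpr.motifs import MotifModel, reverse_complement

from conftest import random_peaks


def _peak(chrom, summit, name="p0"):
    return pd.DataFrame([{
        "chrom": chrom, "start": max(summit - 200, 0), "end": summit + 200,
        "name": name, "score": 0, "strand": ".", "signal": 0.0,
        "p": 0.0, "q": 0.0, "summit_offset": 0, "summit": summit,
    }])


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestConsensusScan:
    def test_hand_positioned_hit(self):
        # CAGCTG sits 3 bp left of the 10-mer's centre
        seq = "TTCAGCTGAA"
        motif = MotifModel.from_consensus("EBOX", "CAGCTG")
        genome = {"c": seq}
        peaks = _peak("c", 5)
        hits = M.scan_window(peaks, genome, motif, halfwidth=5)
        assert len(hits) == 1
        assert hits["offset"].iloc[0] == -3

    def test_absent_motif_gives_empty_list(self):
        motif = MotifModel.from_consensus("GFI1", "AAATCACTGC")
        hits = M.scan_window(_peak("c", 100), {"c": "ACGT" * 100}, motif)
        assert len(hits) == 0

    def test_palindrome_dedup_and_per_strand(self):
        motif = MotifModel.from_consensus("EBOX", "CAGCTG")
        seq = "AAAACAGCTGAAAA"
        both = motif.scan(seq, dedup=False)
        one = motif.scan(seq, dedup=True)
        assert len(both) == 2 and set(both["strand"]) == {"+", "-"}
        assert len(one) == 1 and one["strand"].iloc[0] == "+"

    def test_mismatch_budget(self):
        motif = MotifModel.from_consensus("X", "AAAAAA", max_mismatches=1)
        assert len(motif.scan("CCAAAATACC")) == 1  # one mismatch inside
        strict = MotifModel.from_consensus("X", "AAAAAA")
        assert len(strict.scan("CCAAAATACC")) == 0

    def test_strand_consistency(self):
        """Scanning the reverse-complemented window equals scanning with the
        reverse-complement motif, offsets mirrored."""
        rng = np.random.default_rng(11)
        seq = _random_seq(rng, 400)
        motif = MotifModel.from_consensus("POU4F", "ATGCATAWT")
        rc_motif = MotifModel.from_consensus("POU4F_RC",
                                             reverse_complement("ATGCATAWT"))
        a = motif.scan(reverse_complement(seq), dedup=False)
        b = rc_motif.scan(seq, dedup=False)
        mirrored = sorted(len(seq) - p - len(motif) for p in a["pos"])
        assert mirrored == sorted(b["pos"].tolist())


class TestPwmScan:
    def test_agrees_with_naive_scoring(self):
        """Vectorised PWM scan equals per-position loop on 1 kb sequence."""
        rng = np.random.default_rng(23)
        seq = _random_seq(rng, 1000)
        pwm = rng.dirichlet(np.full(4, 0.4), size=8)
        motif = MotifModel.from_pwm("P", pwm, threshold=6.0)
        got = motif.scan(seq, dedup=False)

        idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        lo = np.log2(np.maximum(pwm, 1e-9) / 0.25)
        expected = []
        for strand, s in (("+", seq), ("-", reverse_complement(seq))):
            for i in range(len(s) - 8 + 1):
                score = sum(lo[j, idx[s[i + j]]] for j in range(8))
                if score >= 6.0:
                    pos = i if strand == "+" else len(seq) - i - 8
                    expected.append((pos, strand, round(score, 6)))
        observed = [(int(r.pos), r.strand, round(r.score, 6))
                    for r in got.itertuples()]
        assert sorted(observed) == sorted(expected)
        assert len(expected) > 0  # the oracle actually exercised hits


class TestCountsPerPeak:
    def test_two_planted_instances_counted(self):
        seq = "A" * 300
        seq = seq[:100] + "CAGCTG" + seq[106:180] + "CAGCTG" + seq[186:]
        motif = MotifModel.from_consensus("EBOX", "CAGCTG")
        peaks = _peak("c", 150)
        hits = M.scan_window(peaks, {"c": seq}, motif, halfwidth=125)
        counts, summary = M.counts_per_peak(hits, peaks)
        assert counts.iloc[0] == 2
        assert summary["n2"].iloc[0] == 1

    def test_instance_beyond_halfwidth_excluded(self):
        seq = "A" * 400
        seq = seq[:330] + "CAGGTG" + seq[336:]  # starts 130 bp past summit
        motif = MotifModel.from_consensus("EBOX", "CAGSTG")
        hits = M.scan_window(_peak("c", 200), {"c": seq}, motif, halfwidth=125)
        assert len(hits) == 0

    def test_group_without_hits_has_zero_fraction(self):
        peaks = _peak("c", 100)
        empty = pd.DataFrame(columns=["peak", "motif", "strand", "offset",
                                      "score", "clipped"])
        _, summary = M.counts_per_peak(empty, peaks)
        assert summary["frac_with_motif"].iloc[0] == 0.0


class TestPositionalDistribution:
    def test_single_center_bin(self):
        hits = pd.DataFrame({"peak": ["p0", "p1"], "offset": [0, 0]})
        curve = M.positional_distribution(hits, n_peaks=2)
        nonzero = curve[curve["frequency"] > 0]
        assert len(nonzero) == 1
        start = nonzero["bin_start"].iloc[0]
        assert start <= 0 < start + 10  # the bin containing the summit
        assert nonzero["frequency"].iloc[0] == 1.0

    def test_uniform_hits_give_flat_curve(self):
        rng = np.random.default_rng(4)
        n = 10_000
        hits = pd.DataFrame({"peak": [f"p{i}" for i in range(n)],
                             "offset": rng.integers(-125, 125, size=n)})
        curve = M.positional_distribution(hits, n_peaks=n)
        p = 10 / 250
        sd = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(curve["frequency"] - p) < 3.5 * sd)

    def test_indivisible_binsize_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            M.positional_distribution(pd.DataFrame({"peak": [], "offset": []}),
                                      n_peaks=1, binsize=7)

    def test_no_hits_all_zero(self):
        empty = pd.DataFrame({"peak": [], "offset": []})
        curve = M.positional_distribution(empty, n_peaks=5)
        assert (curve["frequency"] == 0).all()
        assert len(curve) == 25


class TestPartitionByMotif:
    def _hits(self, peaks):
        return pd.DataFrame({"peak": peaks})

    def test_classes_partition_peaks(self):
        rng = np.random.default_rng(8)
        peaks = random_peaks(rng, 30)
        own = self._hits(peaks["name"].iloc[:10])
        ebox = self._hits(peaks["name"].iloc[5:20])
        classes = M.partition_by_motif(peaks, own, ebox)
        assert classes.value_counts().sum() == 30
        # both-motif peaks (5..9) go to the E-box class
        assert (classes.iloc[5:20] == "ebox_containing").all()
        assert (classes.iloc[:5] == "own_only").all()
        assert (classes.iloc[20:] == "neither").all()
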