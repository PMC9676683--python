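"""Format readers/writers: conventions, validation, round trips."""

import numpy as np
import pandas as pd
import pytest

from chipxpr import formats
from chipxpr.formats import FormatError
from chipxpr.motifs import MotifModel

from conftest import random_peaks


def _write(tmp_path, text, name="f.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestNarrowPeak:
    def test_summit_from_offset(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t500\tp1\t0\t.\t5\t3\t2\t50\n")
        df = formats.read_narrowpeak(p)
        assert df["summit"].iloc[0] == 150

    def test_offset_minus_one_uses_floor_midpoint(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t500\tp1\t0\t.\t5\t3\t2\t-1\n"
                             "chr1\t100\t501\tp2\t0\t.\t5\t3\t2\t-1\n")
        df = formats.read_narrowpeak(p)
        assert df["summit"].tolist() == [300, 300]

    def test_too_few_columns_rejected(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t500\tp1\t0\t.\t5\t3\t2\n")
        with pytest.raises(FormatError, match="10 columns"):
            formats.read_narrowpeak(p)

    def test_summit_outside_interval_rejected(self, tmp_path):
        p = _write(tmp_path, "chr1\t100\t500\tp1\t0\t.\t5\t3\t2\t400\n")
        with pytest.raises(FormatError, match="outside interval"):
            formats.read_narrowpeak(p)

    def test_round_trip_preserves_fields(self, tmp_path):
        rng = np.random.default_rng(0)
        df = random_peaks(rng, 80)
        out = tmp_path / "x.narrowPeak"
        formats.write_narrowpeak(df, out)
        back = formats.read_narrowpeak(out)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), df.reset_index(drop=True),
            check_dtype=False)


class TestGeneModels:
    GTF = ('chr1\tsrc\tgene\t1001\t2000\t.\t{strand}\t.\tgene_id "gA";\n'
           'chr1\tsrc\texon\t1001\t1200\t.\t{strand}\t.\tgene_id "gA";\n')

    def test_gtf_plus_strand_conversion(self, tmp_path):
        ann = formats.read_gene_models(
            _write(tmp_path, self.GTF.format(strand="+")))
        g = ann.genes.iloc[0]
        assert (g.start, g.end, g.tss) == (1000, 2000, 1000)

    def test_gtf_minus_strand_tss(self, tmp_path):
        ann = formats.read_gene_models(
            _write(tmp_path, self.GTF.format(strand="-")))
        assert ann.genes.iloc[0].tss == 1999

    def test_duplicate_gene_id_rejected(self, tmp_path):
        text = self.GTF.format(strand="+") + self.GTF.format(strand="+")
        with pytest.raises(FormatError, match="duplicate gene id"):
            formats.read_gene_models(_write(tmp_path, text))

    def test_unknown_strand_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="strand"):
            formats.read_gene_models(
                _write(tmp_path, self.GTF.format(strand="?")))

    def test_bed6_reader(self, tmp_path):
        ann = formats.read_gene_models(
            _write(tmp_path, "chr1\t5000\t7000\tgB\t0\t-\n"))
        assert ann.genes.iloc[0].tss == 6999

    def test_gtf_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = []
        pos = 1000
        for i in range(30):
            length = int(rng.integers(500, 3000))
            rows.append({"gene_id": f"g{i:03d}", "chrom": "chr1",
                         "start": pos, "end": pos + length,
                         "strand": "+" if rng.integers(2) else "-"})
            pos += length + int(rng.integers(500, 2000))
        ann = formats.GenomeAnnotation(genes=pd.DataFrame(rows))
        out = tmp_path / "g.gtf"
        formats.write_gtf(ann, out)
        back = formats.read_gene_models(out)
        pd.testing.assert_frame_equal(
            back.genes[["gene_id", "chrom", "start", "end", "strand", "tss"]],
            ann.genes[["gene_id", "chrom", "start", "end", "strand", "tss"]])


class TestCounts:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.integers(0, 500, size=(40, 4)),
                          index=pd.Index([f"g{i}" for i in range(40)],
                                         name="gene_id"),
                          columns=["a1", "a2", "b1", "b2"])
        cond = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        cm = formats.CountMatrix(df, cond)
        out = tmp_path / "c.tsv"
        formats.write_counts(cm, out)
        back = formats.read_counts(out, cond)
        pd.testing.assert_frame_equal(back.counts, cm.counts)

    def test_fractional_count_rejected(self, tmp_path):
        p = _write(tmp_path, "gene\ts1\ts2\ng1\t3.5\t2\n", "c.tsv")
        with pytest.raises(FormatError, match="non-integer"):
            formats.read_counts(p, {"s1": "A", "s2": "B"})

    def test_negative_count_rejected(self):
        df = pd.DataFrame({"s1": [1, -2]}, index=["g1", "g2"])
        with pytest.raises(FormatError, match="negative"):
            formats.CountMatrix(df, {"s1": "A"})


class TestMotifFile:
    def test_consensus_record(self, tmp_path):
        models = formats.read_motifs(_write(tmp_path, "EBOX\tCAGCTG\n"))
        assert models[0].name == "EBOX" and len(models[0]) == 6

    def test_degenerate_codes_allowed(self, tmp_path):
        models = formats.read_motifs(_write(tmp_path, "M1\tCANNTG\t1\n"))
        assert models[0].max_mismatches == 1

    def test_invalid_iupac_rejected(self, tmp_path):
        with pytest.raises(FormatError, match="IUPAC"):
            formats.read_motifs(_write(tmp_path, "M1\tCAXGTG\n"))

    def test_pwm_rows_must_sum_to_one(self, tmp_path):
        text = ">M2\t2.0\n" + "0.5 0.5 0.1 0.0\n" * 4
        with pytest.raises(FormatError, match="sum to 1"):
            formats.read_motifs(_write(tmp_path, text))

    def test_round_trip_mixed(self, tmp_path):
        rng = np.random.default_rng(5)
        pwm = rng.dirichlet(np.ones(4), size=6)
        models = [
            MotifModel.from_consensus("CONS", "AWCAGSTGKT", max_mismatches=1),
            MotifModel.from_pwm("PWM1", pwm, 3.25),
        ]
        out = tmp_path / "m.txt"
        formats.write_motifs(models, out)
        back = formats.read_motifs(out)
        assert back[0].consensus == "AWCAGSTGKT"
        assert back[0].max_mismatches == 1
        assert back[1].threshold == pytest.approx(3.25)
        np.testing.assert_allclose(back[1].pwm, pwm, atol=1e-6)


class TestFasta:
    def test_round_trip_and_wrap(self, tmp_path):
        rng = np.random.default_rng(9)
        seqs = {"chr1": "".join(rng.choice(list("ACGT"), 301)),
                "chr2": "".join(rng.choice(list("ACGT"), 150))}
        out = tmp_path / "g.fa"
        formats.write_fasta(seqs, out)
        lines = out.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60
        assert formats.read_fasta(out) == seqs
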