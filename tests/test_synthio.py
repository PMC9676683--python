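"""Scenario generator: determinism, conventions, planted-structure fidelity."""

import numpy as np
import pandas as pd
import pytest

from chipxpr import motifs as M, synthio
from chipxpr.synthio import ScenarioSpec, gpa_preset


def _small_spec(seed=0, **over):
    defaults = dict(
        n_chroms=1, chrom_length=400_000,
        gene_classes={"neuronal_common": 8, "neuronal_only": 4, "hc_only": 8,
                      "downregulated": 4, "background": 16},
        seed=seed)
    defaults.update(over)
    return ScenarioSpec(**defaults)


class TestSpecValidation:
    def test_genes_must_fit(self):
        with pytest.raises(ValueError, match="too small"):
            _small_spec(chrom_length=100_000)

    def test_dispersion_positive(self):
        with pytest.raises(ValueError, match="dispersion"):
            _small_spec(dispersion=-0.1)

    def test_cobind_fraction_bounds(self):
        with pytest.raises(ValueError, match="cobind_fraction"):
            _small_spec(cobind_fraction=1.5)


class TestGenGenome:
    def test_deterministic_and_disjoint(self):
        spec = _small_spec(seed=3)
        g1, a1, t1 = synthio.gen_genome(spec)
        g2, a2, t2 = synthio.gen_genome(spec)
        assert g1 == g2
        pd.testing.assert_frame_equal(t1, t2)
        genes = a1.genes.sort_values(["chrom", "start"])
        for c, sub in genes.groupby("chrom"):
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()

    def test_strand_tss_convention(self):
        _, ann, _ = synthio.gen_genome(_small_spec(seed=1))
        g = ann.genes
        plus = g[g["strand"] == "+"]
        minus = g[g["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"] - 1).all()
        assert len(plus) > 0 and len(minus) > 0

    def test_background_composition_uniform(self):
        genome, _, _ = synthio.gen_genome(_small_spec(seed=2,
                                                      chrom_length=1_000_000))
        seq = genome["chr1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.02


class TestGenPeaks:
    def test_summit_jitter_tail(self):
        spec = _small_spec(seed=5, peak_jitter_sd=10.0)
        genome, ann, table = synthio.gen_genome(spec)
        peaksets, _, truth = synthio.gen_peaks(spec, ann, genome, table)
        tss = ann.genes.set_index("gene_id")["tss"]
        strand = ann.genes.set_index("gene_id")["strand"]
        frac_close = []
        for key, df in peaksets.items():
            t = truth[truth["name"].isin(df["name"]) & ~truth["cobound"]]
            merged = df.merge(t, on="name")
            intended = np.where(
                strand.loc[merged["gene_id"]].to_numpy() == "+",
                tss.loc[merged["gene_id"]].to_numpy() + spec.summit_offset,
                tss.loc[merged["gene_id"]].to_numpy() - spec.summit_offset)
            frac_close.append(
                (np.abs(merged["summit"] - intended) <= 40).mean())
        assert np.mean(frac_close) >= 0.99

    def test_zero_cobind_fraction_shares_no_summits(self):
        spec = _small_spec(seed=6, cobind_fraction=0.0)
        genome, ann, table = synthio.gen_genome(spec)
        peaksets, _, _ = synthio.gen_peaks(spec, ann, genome, table)
        partner = set(peaksets["A_GPA"]["summit"])
        g_summits = set(peaksets.get("G_GPA", pd.DataFrame(
            columns=["summit"]))["summit"])
        assert not partner & g_summits

    def test_cobound_peaks_copy_partner_summits_exactly(self):
        spec = _small_spec(seed=7, cobind_fraction=0.5)
        genome, ann, table = synthio.gen_genome(spec)
        peaksets, _, truth = synthio.gen_peaks(spec, ann, genome, table)
        cobound = truth.loc[truth["cobound"], "name"]
        g = peaksets["G_GPA"].set_index("name")
        partner_summits = set(peaksets["A_GPA"]["summit"])
        assert len(cobound) == round(0.5 * len(peaksets["A_GPA"]))
        assert set(g.loc[cobound, "summit"]) <= partner_summits

    def test_planted_motifs_fully_recoverable(self):
        """Every planted instance is found by the scan at the planting
        threshold (100% sensitivity)."""
        spec = _small_spec(seed=8)
        genome, ann, table = synthio.gen_genome(spec)
        peaksets, genome, truth = synthio.gen_peaks(spec, ann, genome, table)
        motifs = synthio.default_motifs()
        for key, df in peaksets.items():
            tf = key.split("_")[0]
            motif = motifs[spec.motif_names[tf]]
            hits = M.scan_window(df, genome, motif,
                                 halfwidth=spec.scan_halfwidth)
            planted = set(truth.loc[truth["name"].isin(df["name"])
                                    & truth["motif"].notna(), "name"])
            assert planted <= set(hits["peak"])

    def test_motif_longer_than_window_rejected(self):
        spec = _small_spec(seed=9, scan_halfwidth=4)
        genome, ann, table = synthio.gen_genome(spec)
        with pytest.raises(ValueError, match="longer than"):
            synthio.gen_peaks(spec, ann, genome, table)


class TestGenCounts:
    def test_null_fold_changes_centered_at_zero(self):
        spec = _small_spec(
            seed=10,
            fold_changes={c: {"Aonly": 0.0, "GPA": 0.0}
                          for c in _small_spec().gene_classes})
        _, _, table = synthio.gen_genome(spec)
        cm, truth = synthio.gen_counts(spec, table)
        ref = cm.counts[cm.samples_of("noDox")].mean(axis=1)
        alt = cm.counts[cm.samples_of("GPA")].mean(axis=1)
        lfc = np.log2((alt + 1) / (ref + 1))
        assert abs(lfc.mean()) < 0.2

    def test_planted_fold_change_ratio(self):
        spec = _small_spec(seed=11, baseline_log_sd=0.0)
        _, _, table = synthio.gen_genome(spec)
        cm, _ = synthio.gen_counts(spec, table)
        hc = table.loc[table["class"] == "hc_only", "gene_id"]
        ratio = (cm.counts.loc[hc, cm.samples_of("GPA")].mean(axis=1).mean()
                 / cm.counts.loc[hc, cm.samples_of("noDox")].mean(axis=1).mean())
        assert ratio == pytest.approx(8.0, rel=0.25)

    def test_nb_moments(self):
        """Across 5,000 constant-mean genes the empirical variance matches
        μ + αμ² within 10%."""
        spec = ScenarioSpec(
            n_chroms=2, chrom_length=25_000_000,
            gene_classes={"background": 5000},
            baseline_log_sd=0.0, dispersion=0.1, seed=12)
        table = pd.DataFrame({"gene_id": [f"g{i}" for i in range(5000)],
                              "class": "background"})
        cm, _ = synthio.gen_counts(spec, table)
        draws = cm.counts.to_numpy().ravel()
        mu = np.exp(spec.baseline_log_mean)
        expected = mu + spec.dispersion * mu ** 2
        assert abs(draws.var() / expected - 1) < 0.10
        assert abs(draws.mean() / mu - 1) < 0.05

    def test_deterministic(self):
        spec = _small_spec(seed=13)
        _, _, table = synthio.gen_genome(spec)
        a, _ = synthio.gen_counts(spec, table)
        b, _ = synthio.gen_counts(spec, table)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestWriteScenario:
    def test_rerun_is_byte_identical(self, tmp_path):
        for d in ("one", "two"):
            sc = synthio.build_scenario(spec=_small_spec(seed=14))
            synthio.write_scenario(sc, tmp_path / d)
        for f in sorted((tmp_path / "one").iterdir()):
            other = tmp_path / "two" / f.name
            if f.name == "config.yaml":
                continue  # embeds absolute paths
            assert f.read_bytes() == other.read_bytes(), f.name

    def test_truth_covers_everything_once(self, scenario):
        truth = scenario.truth
        truth.validate()
        all_peaks = pd.concat(scenario.peaksets.values())["name"]
        assert sorted(all_peaks) == sorted(truth.peaks["name"])
        assert sorted(scenario.counts.counts.index) == sorted(
            truth.genes["gene_id"])

    def test_gpa_preset_recruitment(self):
        spec = gpa_preset()
        assert spec.recruitment[("A", "Aonly")] == ["neuronal_common",
                                                    "neuronal_only"]
        assert spec.recruitment[("A", "GPA")] == ["neuronal_common",
                                                  "hc_only"]
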