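"""End-to-end orchestration: run every analysis stage on one config.

Stages execute in dependency order (diffexpr → peakalgebra → annotate →
motifs → regdir → gsea); a failure stops the run with an error naming
the stage. The report is a bag of tables plus a provenance block
(config hash, seed, package version) and is byte-identical across reruns
of the same config.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from . import annotate as ann_mod
from . import diffexpr, gsea, motifs as motifs_mod, peakalgebra, regdir
from .formats import (read_counts, read_fasta, read_gene_models, read_motifs,
                      read_narrowpeak)

log = logging.getLogger("chipxpr")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All inputs and tunables of one pipeline run."""

    genome: str
    genes: str
    counts: str
    motifs: str
    peaks: dict[str, str]
    samples: dict[str, str]
    reference: str
    contrasts: list[str]
    pair: list[str]
    trio: list[str]
    direction: dict[str, str]
    params: dict = field(default_factory=dict)

    DEFAULT_PARAMS = {
        "window": 300, "tss_window": 5000, "halfwidth": 125,
        "promoter_window": (-3000, 3000), "lfc_min": 1.5, "fdr": 0.05,
        "k": 4, "subcluster": None, "bandwidth": 2000, "halfspan": 30000,
        "n_perm": 1000, "seed": 0,
    }

    def __post_init__(self):
        merged = dict(self.DEFAULT_PARAMS)
        merged.update(self.params or {})
        self.params = merged
        for key in ("window", "tss_window", "halfwidth", "bandwidth",
                    "halfspan", "n_perm", "k", "lfc_min", "fdr"):
            if not self.params[key] or self.params[key] <= 0:
                raise ValueError(f"tunable {key!r} must be positive, "
                                 f"got {self.params[key]!r}")
        for name in ("genome", "genes", "counts", "motifs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for key, p in self.peaks.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"peak set {key!r} file not found: {p}")
        if len(self.pair) != 2:
            raise ValueError("pair must name exactly two peak sets")
        for key in self.pair + list(self.trio):
            if key not in self.peaks:
                raise ValueError(f"peak set {key!r} not among inputs")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps({
            "genome": self.genome, "genes": self.genes, "counts": self.counts,
            "motifs": self.motifs, "peaks": self.peaks, "samples": self.samples,
            "reference": self.reference, "contrasts": self.contrasts,
            "pair": self.pair, "trio": list(self.trio),
            "direction": self.direction,
            "params": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in self.params.items()},
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Report:
    """Structured pipeline output: named tables + richer stage objects."""

    tables: dict[str, pd.DataFrame]
    objects: dict
    provenance: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.tsv", sep="\t",
                      index=not isinstance(df.index, pd.RangeIndex))
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)


def run(config: PipelineConfig) -> Report:
    """Execute the full analysis described by ``config``."""
    P = config.params
    tables: dict[str, pd.DataFrame] = {}
    objects: dict = {}

    # -- load & validate inputs -------------------------------------------
    stage = "load"
    try:
        genome = read_fasta(config.genome)
        annotation = read_gene_models(config.genes)
        cm = read_counts(config.counts, config.samples)
        motif_list = read_motifs(config.motifs)
        motif_by_name = {m.name: m for m in motif_list}
        peaksets = {key: read_narrowpeak(p) for key, p in config.peaks.items()}
        genome_chroms = set(genome)
        for key, df in peaksets.items():
            extra = set(df["chrom"]) - genome_chroms
            if extra:
                raise ValueError(
                    f"chromosomes {sorted(extra)} in {config.peaks[key]} "
                    f"absent from genome {config.genome}")
        extra = set(annotation.genes["chrom"]) - genome_chroms
        if extra:
            raise ValueError(f"chromosomes {sorted(extra)} in {config.genes} "
                             f"absent from genome {config.genome}")
        chrom_sizes = {c: len(s) for c, s in genome.items()}
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("loaded %d peak sets, %d genes, %d×%d counts",
             len(peaksets), len(annotation.genes), *cm.counts.shape)

    # -- diffexpr ----------------------------------------------------------
    stage = "diffexpr"
    try:
        de_by_contrast = {}
        selection_by_contrast = {}
        for cond in config.contrasts:
            de = diffexpr.nb_wald_test(cm, (config.reference, cond))
            de_by_contrast[cond] = de
            selection_by_contrast[cond] = diffexpr.select_de(
                de, lfc_min=P["lfc_min"], fdr=P["fdr"])
            tables[f"de_{cond}"] = de.table
        de_union = sorted(set().union(
            *[set(s.index) for s in selection_by_contrast.values()]))
        if len(de_union) < P["k"]:
            raise ValueError(f"only {len(de_union)} DE genes; cannot cluster "
                             f"into k={P['k']}")
        means = diffexpr.condition_means(cm, genes=de_union)
        clusters = diffexpr.cluster_de(means, k=P["k"],
                                       subcluster=P.get("subcluster"))
        tables["clusters"] = clusters.final_labels.to_frame()
        objects["clusters"] = clusters
        objects["de"] = de_by_contrast
        objects["de_selection"] = selection_by_contrast
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("diffexpr: %d DE genes across %d contrasts",
             len(de_union), len(config.contrasts))

    # -- peakalgebra -------------------------------------------------------
    stage = "peakalgebra"
    try:
        a_key, b_key = config.pair
        pair = peakalgebra.classify_pair(
            peaksets[a_key], peaksets[b_key], w=P["window"],
            names=(a_key, b_key), chrom_sizes=chrom_sizes)
        objects["pair"] = pair
        tables["pair_counts"] = pd.DataFrame([pair.counts()])
        part = peakalgebra.membership_partition(
            {k: peaksets[k] for k in config.trio}, w=P["window"],
            chrom_sizes=chrom_sizes)
        objects["partition"] = part
        tables["partition_classes"] = part.class_counts()
        tables["partition_regions"] = peakalgebra.partition_to_table(part)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("peakalgebra: pair counts %s", tables["pair_counts"].iloc[0].to_dict())

    # -- annotate ----------------------------------------------------------
    stage = "annotate"
    try:
        assignments = {key: ann_mod.nearest_tss(df, annotation)
                       for key, df in peaksets.items()}
        objects["assignments"] = assignments
        tables["assignments"] = pd.concat(
            [df.assign(set=key) for key, df in assignments.items()],
            ignore_index=True)
        groups = {
            f"{a_key}_unique": peaksets[a_key][
                (pair.a_labels == "unique").to_numpy()],
            "common": pd.concat([
                peaksets[a_key][(pair.a_labels == "common").to_numpy()],
                peaksets[b_key][(pair.b_labels == "common").to_numpy()],
            ], ignore_index=True),
            f"{b_key}_unique": peaksets[b_key][
                (pair.b_labels == "unique").to_numpy()],
        }
        objects["pair_groups"] = groups
        tables["cluster_association"] = ann_mod.cluster_association(
            groups, clusters.final_labels, annotation, window=P["tss_window"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- motifs ------------------------------------------------------------
    stage = "motifs"
    try:
        dir_key = config.direction["peakset"]
        own_motif = motif_by_name[config.direction["own_motif"]]
        ebox_motif = motif_by_name[config.direction["ebox_motif"]]
        dir_peaks = peaksets[dir_key]
        own_hits = motifs_mod.scan_window(dir_peaks, genome, own_motif,
                                          halfwidth=P["halfwidth"])
        ebox_hits = motifs_mod.scan_window(dir_peaks, genome, ebox_motif,
                                           halfwidth=P["halfwidth"])
        motif_classes = motifs_mod.partition_by_motif(dir_peaks, own_hits,
                                                      ebox_hits)
        objects["motif_classes"] = motif_classes
        tables["motif_classes"] = motif_classes.to_frame()

        # per pair-group E-box content (occurrence histograms)
        hist_rows = []
        for gname, gpeaks in groups.items():
            hits = motifs_mod.scan_window(gpeaks, genome, ebox_motif,
                                          halfwidth=P["halfwidth"])
            _, summary = motifs_mod.counts_per_peak(hits, gpeaks)
            summary.insert(0, "peak_group", gname)
            hist_rows.append(summary)
        tables["motif_histograms"] = pd.concat(hist_rows, ignore_index=True)

        curves = []
        for mname, hits in [(own_motif.name, own_hits),
                            (ebox_motif.name, ebox_hits)]:
            curve = motifs_mod.positional_distribution(
                hits, n_peaks=len(dir_peaks), halfwidth=P["halfwidth"])
            curve.insert(0, "motif", mname)
            curves.append(curve)
        tables["positional_curves"] = pd.concat(curves, ignore_index=True)

        features = ann_mod.genomic_features(
            dir_peaks, annotation, promoter_window=tuple(P["promoter_window"]))
        objects["features"] = features
        frac_rows = []
        for cls, sub in features.groupby(motif_classes):
            f = ann_mod.feature_fractions(sub)
            f.insert(0, "motif_class", cls)
            frac_rows.append(f)
        tables["feature_fractions"] = pd.concat(frac_rows, ignore_index=True)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("motifs: class sizes %s", motif_classes.value_counts().to_dict())

    # -- regdir ------------------------------------------------------------
    stage = "regdir"
    try:
        contrast = config.direction.get("contrast", config.contrasts[-1])
        selection = selection_by_contrast[contrast]
        dir_tables = regdir.direction_fractions(
            assignments[dir_key], selection, motif_classes)
        tables["direction_peak_level"] = dir_tables["peak_level"]
        tables["direction_gene_level"] = dir_tables["gene_level"]
        tables["direction_curves"] = regdir.distance_direction_curve(
            assignments[dir_key], selection, motif_classes,
            halfspan=P["halfspan"], bandwidth=P["bandwidth"])
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- gsea --------------------------------------------------------------
    stage = "gsea"
    try:
        contrast = config.direction.get("contrast", config.contrasts[-1])
        sf = diffexpr.size_factors(cm)
        norm = cm.counts / sf
        ranked = gsea.rank_genes(norm, cm.conditions,
                                 (contrast, config.reference), metric="s2n")
        genesets = {f"cluster_{label}": set(idx)
                    for label, idx in
                    clusters.final_labels.groupby(clusters.final_labels).groups.items()}
        results = gsea.nes_fdr(ranked, genesets, n_perm=P["n_perm"],
                               seed=np.random.default_rng([P["seed"], 7]))
        tables["gsea"] = gsea.results_table(results)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    log.info("gsea: %d gene sets tested", len(tables["gsea"]))

    provenance = {
        "config_digest": config.digest(),
        "seed": P["seed"],
        "chipxpr_version": __version__,
        "n_peak_sets": len(peaksets),
        "n_genes": int(len(annotation.genes)),
        "n_de_genes": int(len(de_union)),
        "params": {k: list(v) if isinstance(v, tuple) else v
                   for k, v in P.items()},
    }
    return Report(tables=tables, objects=objects, provenance=provenance)


# ---------------------------------------------------------------------------
# scenario recovery


def scenario_recovery(scenario, report: Report) -> dict[str, float]:
    """Measure how well the pipeline recovered a scenario's planted truth.

    Returns a dict of recovery metrics: the fraction of planted
    recruited peaks landing in the recruited condition's unique class,
    the fraction of co-binder peaks classed common with the partner set,
    direction fractions for the motif-content classes, and the adjusted
    Rand index of recovered expression clusters against planted classes.
    """
    from . import peakalgebra as pa

    truth = scenario.truth
    spec = scenario.spec
    metrics: dict[str, float] = {}

    pair = report.objects["pair"]
    recruited = truth.peaks.loc[
        truth.peaks["intended_class"] == "recruited", "name"]
    labels = pair.b_labels.reindex(recruited)
    if labels.isna().any():
        raise ValueError("truth/report peak id mismatch in pair classification")
    metrics["recruited_unique_fraction"] = float((labels == "unique").mean())

    partner_key = f"{spec.cobind_partner[0]}_{spec.cobind_partner[1]}"
    cobind_key = f"{spec.cobind_tf}_{spec.cobind_partner[1]}"
    cls = pa.classify_pair(
        scenario.peaksets[cobind_key], scenario.peaksets[partner_key],
        names=(cobind_key, partner_key))
    cobound = truth.peaks.loc[truth.peaks["cobound"], "name"]
    metrics["cobound_common_fraction"] = float(
        (cls.a_labels.reindex(cobound) == "common").mean())

    dir_table = report.tables["direction_peak_level"].set_index("class")
    if "own_only" in dir_table.index:
        metrics["own_motif_down_fraction"] = float(
            dir_table.loc["own_only", "frac_down"])
    if "ebox_containing" in dir_table.index:
        metrics["ebox_up_fraction"] = float(
            dir_table.loc["ebox_containing", "frac_up"])

    clusters = report.objects["clusters"].final_labels
    gene_truth = truth.genes.set_index("gene_id")
    de_classes = [c for c in spec.gene_classes if c != "background"]
    common = [g for g in clusters.index
              if gene_truth.loc[g, "class"] in de_classes]
    metrics["cluster_ari"] = float(adjusted_rand_score(
        gene_truth.loc[common, "class"], clusters.loc[common]))
    metrics["n_de_recovered"] = float(len(clusters))
    return metrics
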