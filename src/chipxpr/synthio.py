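"""Self-contained synthetic scenario generator with ground-truth labels.

The generator emulates the statistical structure of a three-TF
reprogramming experiment — a "default" factor (A) bound at neuronal
genes in every condition, a "recruiter" factor (P) whose presence adds
binding of A at a second, sensory gene class via P's own motif, and a
"co-binder" factor (G) that sits on a subset of A's summits without its
own motif there while also binding its own motif at the promoters of a
set of repressed genes. Expression follows: recruited/maintained target
classes are planted up, the co-binder's own-motif targets down, against
a background class with no effect.

Everything is derived from a single integer seed and regenerating with
the same spec reproduces byte-identical files. Planted motif instances
are written into the background sequence in place (no insertions), so
all coordinates stay stable, and always land fully inside the ±125 bp
scan window around the planting peak's summit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .formats import (CountMatrix, GenomeAnnotation, write_counts, write_fasta,
                      write_gtf, write_motifs, write_narrowpeak)
from .motifs import IUPAC, MotifModel

DEFAULT_GENE_CLASSES = {
    "neuronal_common": 40,   # up in both induced conditions (C-1A analogue)
    "neuronal_only": 20,     # up only without the recruiter (C-1B analogue)
    "hc_only": 40,           # up only with the full combination (C-2 analogue)
    "downregulated": 20,     # repressed targets of the co-binder (C-3/4 analogue)
    "background": 280,       # no planted effect; must dominate so that
    #                          median-of-ratios normalisation is anchored on
    #                          unchanged genes, as in real transcriptomes
}

DEFAULT_RECRUITMENT = {
    ("A", "Aonly"): ["neuronal_common", "neuronal_only"],
    ("A", "GPA"): ["neuronal_common", "hc_only"],
    ("P", "GPA"): ["hc_only"],
    ("G", "GPA"): ["downregulated"],
}

DEFAULT_FOLD_CHANGES = {
    "neuronal_common": {"Aonly": 3.0, "GPA": 3.0},
    "neuronal_only": {"Aonly": 3.0, "GPA": 0.0},
    "hc_only": {"Aonly": 0.0, "GPA": 3.0},
    "downregulated": {"Aonly": -3.0, "GPA": -3.0},
    "background": {"Aonly": 0.0, "GPA": 0.0},
}


def default_motifs() -> dict[str, MotifModel]:
    """Synthetic stand-in motif models for the three factors.

    These are editable stand-ins, not measured matrices: an extended
    E-box consensus with the CAGSTG core and specific flanks (the kind of
    ~10 bp variant de novo discovery recovers for bHLH factors, rare
    enough on random background to be informative), an AT-rich
    POU-homeodomain consensus, and a zinc-finger consensus with the
    AATC core.
    """
    return {
        "EBOX": MotifModel.from_consensus("EBOX", "AWCAGSTGKT"),
        "POU4F": MotifModel.from_consensus("POU4F", "ATGCATAWT"),
        "GFI1": MotifModel.from_consensus("GFI1", "AAATCACTGC"),
    }


@dataclass
class ScenarioSpec:
    """Parameters of a synthetic scenario; defaults are the gpa preset."""

    n_chroms: int = 2
    chrom_length: int = 2_000_000
    gene_classes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GENE_CLASSES))
    motif_names: dict[str, str] = field(
        default_factory=lambda: {"A": "EBOX", "P": "POU4F", "G": "GFI1"})
    recruitment: dict[tuple[str, str], list[str]] = field(
        default_factory=lambda: dict(DEFAULT_RECRUITMENT))
    cobind_tf: str = "G"
    cobind_partner: tuple[str, str] = ("A", "GPA")
    cobind_fraction: float = 0.25
    summit_offset: int = -50        # intended summit relative to TSS (bp)
    peak_jitter_sd: float = 20.0
    peak_halfwidth: int = 200       # narrowPeak interval = summit ± this
    scan_halfwidth: int = 125       # planted motifs stay inside this window
    conditions: tuple[str, ...] = ("noDox", "Aonly", "GPA")
    reference: str = "noDox"
    n_replicates: int = 3
    fold_changes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FOLD_CHANGES.items()})
    baseline_log_mean: float = np.log(200.0)
    baseline_log_sd: float = 0.7
    dispersion: float = 0.1
    gene_length: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.n_chroms < 1 or self.chrom_length < 1:
            raise ValueError("counts must be positive")
        if any(v <= 0 for v in self.gene_classes.values()):
            raise ValueError("gene class counts must be positive")
        if not (0.0 <= self.cobind_fraction <= 1.0):
            raise ValueError("cobind_fraction must lie in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_replicates < 2:
            raise ValueError("need ≥2 replicates per condition")
        per_chrom = -(-self.n_genes // self.n_chroms)  # ceil division
        if self.chrom_length < 10 * per_chrom * 1000:
            raise ValueError(
                f"chromosome length {self.chrom_length} too small for "
                f"{per_chrom} genes per chromosome (needs ≥ {10 * per_chrom * 1000})")

    @property
    def n_genes(self) -> int:
        return sum(self.gene_classes.values())


def gpa_preset(seed: int = 0, **overrides) -> ScenarioSpec:
    """The default three-TF scenario (all defaults, just pick a seed)."""
    return ScenarioSpec(seed=seed, **overrides)


@dataclass
class TruthTable:
    """Ground truth for every emitted peak and gene (each appears once)."""

    peaks: pd.DataFrame   # name, tf, condition, gene_id, gene_class,
    #                       intended_class, motif, cobound
    genes: pd.DataFrame   # gene_id, class + direction_<cond> columns

    def validate(self):
        if self.peaks["name"].duplicated().any():
            raise ValueError("duplicate peak in truth table")
        if self.genes["gene_id"].duplicated().any():
            raise ValueError("duplicate gene in truth table")


# ---------------------------------------------------------------------------
# generators


def gen_genome(spec: ScenarioSpec):
    """Generate background sequence and non-overlapping gene models.

    Background is i.i.d. uniform over ACGT. Genes are laid out on an even
    grid per chromosome (so windows around different genes can never
    collide), strands drawn 50/50, each with a first and last exon of
    ~25% gene length. Gene classes are assigned by random shuffle.

    Returns (genome dict, GenomeAnnotation, gene table with class labels).
    """
    rng = np.random.default_rng([spec.seed, 1])
    genome = {}
    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chroms)]
    for c in chrom_names:
        genome[c] = "".join(
            np.array(list("ACGT"))[rng.integers(0, 4, spec.chrom_length)])

    n = spec.n_genes
    per_chrom = -(-n // spec.n_chroms)
    rows = []
    gi = 0
    for c in chrom_names:
        k = min(per_chrom, n - gi)
        spacing = spec.chrom_length // (k + 1)
        for j in range(k):
            start = (j + 1) * spacing
            end = start + spec.gene_length
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            rows.append({"gene_id": f"g{gi:04d}", "chrom": c,
                         "start": start, "end": end, "strand": strand})
            gi += 1
    genes = pd.DataFrame(rows)
    exon_len = max(spec.gene_length // 4, 1)
    exons = pd.concat([
        genes.assign(start=genes["start"], end=genes["start"] + exon_len),
        genes.assign(start=genes["end"] - exon_len, end=genes["end"]),
    ])[["gene_id", "chrom", "start", "end"]].reset_index(drop=True)
    annotation = GenomeAnnotation(genes=genes, exons=exons,
                                  chrom_sizes={c: spec.chrom_length
                                               for c in chrom_names})

    class_labels = np.concatenate([
        np.repeat(name, count) for name, count in spec.gene_classes.items()])
    perm = rng.permutation(n)
    gene_table = annotation.genes.copy()
    gene_table["class"] = class_labels[np.argsort(perm)]  # shuffled assignment
    return genome, annotation, gene_table


def _concrete_instance(consensus: str, rng) -> str:
    """Draw one concrete sequence matching a degenerate consensus."""
    return "".join(rng.choice(list(IUPAC[c])) for c in consensus)


def gen_peaks(spec: ScenarioSpec, annotation: GenomeAnnotation,
              genome: dict[str, str],
              gene_table: pd.DataFrame,
              motifs: dict[str, MotifModel] | None = None):
    """Place per-TF/condition peaks and plant motif instances in the genome.

    For each (TF, condition, target class): one peak per target gene with
    the summit drawn N(TSS + offset-in-orientation, jitter) and one
    concrete instance of the TF's motif written into the sequence inside
    the ±scan_halfwidth window of the summit. The co-binder additionally
    copies a ``cobind_fraction`` of its partner's summits exactly, with
    no own motif planted there. narrowPeak score/signal/p/q fields are
    populated with plausible values.

    Returns (peaksets dict keyed "TF_condition", mutated genome,
    peak-truth DataFrame).
    """
    motifs = motifs or default_motifs()
    rng = np.random.default_rng([spec.seed, 2])
    seq = {c: bytearray(s, "ascii") for c, s in genome.items()}
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    by_class = {cls: sub for cls, sub in gene_table.groupby("class")}
    truth_rows = []
    peaksets: dict[str, list[dict]] = {}

    def _plant(chrom: str, summit: int, motif: MotifModel) -> int:
        L = len(motif)
        if L > 2 * spec.scan_halfwidth:
            raise ValueError(f"motif {motif.name} longer than scan window")
        lo = summit - spec.scan_halfwidth
        hi = summit + spec.scan_halfwidth - L
        for _ in range(50):
            pos = int(rng.integers(lo, hi + 1))
            if pos < 0 or pos + L > len(seq[chrom]):
                continue
            if all(pos + L <= a or pos >= b for a, b in reserved[chrom]):
                inst = _concrete_instance(motif.consensus, rng)
                seq[chrom][pos:pos + L] = inst.encode("ascii")
                reserved[chrom].append((pos, pos + L))
                return pos
        raise RuntimeError("could not place motif instance without collision")

    def _peak_record(name, chrom, summit):
        start = max(summit - spec.peak_halfwidth, 0)
        end = min(summit + spec.peak_halfwidth, spec.chrom_length)
        signal = float(rng.uniform(5, 50))
        return {
            "chrom": chrom, "start": start, "end": end, "name": name,
            "score": int(min(1000, signal * 20)), "strand": ".",
            "signal": round(signal, 4),
            "p": round(float(rng.uniform(10, 100)), 4),
            "q": round(float(rng.uniform(5, 80)), 4),
            "summit_offset": summit - start, "summit": summit,
        }

    for (tf, cond), classes in spec.recruitment.items():
        key = f"{tf}_{cond}"
        peaksets.setdefault(key, [])
        motif = motifs[spec.motif_names[tf]]
        for cls in classes:
            for g in by_class[cls].itertuples():
                intended = int(g.tss + (spec.summit_offset if g.strand == "+"
                                        else -spec.summit_offset))
                summit = int(round(rng.normal(intended, spec.peak_jitter_sd)))
                summit = int(np.clip(summit, 0, spec.chrom_length - 1))
                name = f"{tf}_{cond}_{g.gene_id}"
                _plant(g.chrom, summit, motif)
                peaksets[key].append(_peak_record(name, g.chrom, summit))
                truth_rows.append({
                    "name": name, "tf": tf, "condition": cond,
                    "gene_id": g.gene_id, "gene_class": cls,
                    "intended_class": _intended_class(spec, tf, cond, cls),
                    "motif": motif.name, "cobound": False,
                })

    # co-binder peaks copied onto partner summits (no own motif planted)
    if spec.cobind_fraction > 0:
        partner_key = f"{spec.cobind_partner[0]}_{spec.cobind_partner[1]}"
        partner = peaksets.get(partner_key, [])
        n_cobind = int(round(spec.cobind_fraction * len(partner)))
        chosen = rng.choice(len(partner), size=n_cobind, replace=False)
        cond = spec.cobind_partner[1]
        key = f"{spec.cobind_tf}_{cond}"
        peaksets.setdefault(key, [])
        partner_truth = {r["name"]: r for r in truth_rows}
        for i in sorted(chosen):
            src = partner[i]
            name = f"{spec.cobind_tf}_{cond}_cb_{src['name']}"
            peaksets[key].append(_peak_record(name, src["chrom"], src["summit"]))
            src_truth = partner_truth[src["name"]]
            truth_rows.append({
                "name": name, "tf": spec.cobind_tf, "condition": cond,
                "gene_id": src_truth["gene_id"],
                "gene_class": src_truth["gene_class"],
                "intended_class": "cobound", "motif": None, "cobound": True,
            })

    genome_out = {c: bytes(b).decode("ascii") for c, b in seq.items()}
    frames = {}
    for key, records in peaksets.items():
        df = pd.DataFrame(records).sort_values(
            ["chrom", "start"], kind="stable").reset_index(drop=True)
        frames[key] = df
    return frames, genome_out, pd.DataFrame(truth_rows)


def _intended_class(spec: ScenarioSpec, tf: str, cond: str, cls: str) -> str:
    """Label a planted peak by the role it plays in the scenario."""
    if tf == spec.cobind_tf:
        return "own_promoter"
    bound_elsewhere = any(
        cls in classes for (t, c), classes in spec.recruitment.items()
        if t == tf and c != cond)
    if bound_elsewhere:
        return "maintained"
    if (tf, cond) == spec.cobind_partner:
        return "recruited"
    return "condition_unique"


def gen_counts(spec: ScenarioSpec, gene_table: pd.DataFrame):
    """Negative-binomial count matrix with planted class-wise fold changes.

    Per gene: baseline mean drawn log-normal; condition mean =
    baseline × 2^(planted log2FC for its class); counts NB with the
    spec's dispersion, replicates exchangeable.

    Returns (CountMatrix, gene truth with per-condition directions).
    """
    rng = np.random.default_rng([spec.seed, 3])
    genes = gene_table["gene_id"].to_numpy()
    classes = gene_table["class"].to_numpy()
    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd,
                             size=len(genes))
    r = 1.0 / spec.dispersion
    data = {}
    conditions = {}
    for cond in spec.conditions:
        lfc = np.array([spec.fold_changes.get(c, {}).get(cond, 0.0)
                        for c in classes])
        mu = baseline * np.power(2.0, lfc)
        for rep in range(spec.n_replicates):
            sample = f"{cond}_{rep + 1}"
            data[sample] = rng.negative_binomial(r, r / (r + mu))
            conditions[sample] = cond
    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    cm = CountMatrix(counts=counts, conditions=conditions)

    truth = gene_table[["gene_id", "class"]].copy()
    for cond in spec.conditions:
        if cond == spec.reference:
            continue
        lfc = np.array([spec.fold_changes.get(c, {}).get(cond, 0.0)
                        for c in classes])
        truth[f"direction_{cond}"] = np.where(
            lfc > 0, "up", np.where(lfc < 0, "down", "none"))
    return cm, truth


@dataclass
class Scenario:
    """A fully generated scenario: inputs plus ground truth."""

    spec: ScenarioSpec
    genome: dict[str, str]
    annotation: GenomeAnnotation
    peaksets: dict[str, pd.DataFrame]
    counts: CountMatrix
    motifs: dict[str, MotifModel]
    truth: TruthTable


def build_scenario(spec: ScenarioSpec | None = None,
                   seed: int | None = None) -> Scenario:
    """Generate a complete scenario in memory (deterministic under seed)."""
    if spec is None:
        spec = gpa_preset(seed=seed if seed is not None else 0)
    motifs = default_motifs()
    genome, annotation, gene_table = gen_genome(spec)
    peaksets, genome, peak_truth = gen_peaks(spec, annotation, genome,
                                             gene_table, motifs)
    counts, gene_truth = gen_counts(spec, gene_table)
    truth = TruthTable(peaks=peak_truth, genes=gene_truth)
    truth.validate()
    return Scenario(spec=spec, genome=genome, annotation=annotation,
                    peaksets=peaksets, counts=counts, motifs=motifs,
                    truth=truth)


def write_scenario(scenario: Scenario, outdir) -> dict[str, Path]:
    """Write a scenario to disk in standard formats plus a pipeline config.

    Emits genome.fa (60-column FASTA), genes.gtf, one narrowPeak per
    TF × condition, counts.tsv, motifs.txt, truth tables, and a
    config.yaml that chipxpr.pipeline.run can consume directly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["genome"] = outdir / "genome.fa"
    write_fasta(scenario.genome, paths["genome"])
    paths["genes"] = outdir / "genes.gtf"
    write_gtf(scenario.annotation, paths["genes"])
    for key, df in scenario.peaksets.items():
        p = outdir / f"{key}.narrowPeak"
        write_narrowpeak(df, p)
        paths[f"peaks_{key}"] = p
    paths["counts"] = outdir / "counts.tsv"
    write_counts(scenario.counts, paths["counts"])
    paths["motifs"] = outdir / "motifs.txt"
    write_motifs(list(scenario.motifs.values()), paths["motifs"])
    paths["truth_peaks"] = outdir / "truth_peaks.tsv"
    scenario.truth.peaks.to_csv(paths["truth_peaks"], sep="\t", index=False)
    paths["truth_genes"] = outdir / "truth_genes.tsv"
    scenario.truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)

    spec = scenario.spec
    config = {
        "genome": str(paths["genome"]),
        "genes": str(paths["genes"]),
        "counts": str(paths["counts"]),
        "motifs": str(paths["motifs"]),
        "peaks": {key: str(outdir / f"{key}.narrowPeak")
                  for key in scenario.peaksets},
        "samples": dict(scenario.counts.conditions),
        "reference": spec.reference,
        "contrasts": [c for c in spec.conditions if c != spec.reference],
        "pair": [f"{spec.cobind_partner[0]}_{c}"
                 for c in spec.conditions if c != spec.reference],
        "trio": sorted(scenario.peaksets),
        "direction": {
            "peakset": f"{spec.cobind_tf}_{spec.cobind_partner[1]}",
            "own_motif": spec.motif_names[spec.cobind_tf],
            "ebox_motif": spec.motif_names[spec.cobind_partner[0]],
            "contrast": spec.cobind_partner[1],
        },
        "params": {
            "window": 300, "tss_window": 5000, "halfwidth": spec.scan_halfwidth,
            "promoter_window": [-3000, 3000], "lfc_min": 1.5, "fdr": 0.05,
            "k": 4, "subcluster": None, "bandwidth": 2000, "halfspan": 30000,
            "n_perm": 1000, "seed": spec.seed,
        },
    }
    paths["config"] = outdir / "config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return paths
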