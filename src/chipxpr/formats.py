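"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GTF's
1-based closed coordinates are converted at this boundary and nowhere else.
Chromosome names are taken verbatim; no "chr" normalisation is attempted,
and mismatches between input files surface as hard errors downstream.

Peak sets are plain :class:`pandas.DataFrame` objects with the ten ENCODE
narrowPeak columns plus a derived absolute ``summit`` column; gene models
live in :class:`GenomeAnnotation`; counts in :class:`CountMatrix`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violated its format contract; carries path and line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc += ": "
        super().__init__(loc + message)
        self.path = path
        self.line = line


NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal", "p", "q", "summit_offset",
]

#: columns every in-memory peak table carries (narrowPeak + absolute summit)
PEAK_COLUMNS = NARROWPEAK_COLUMNS + ["summit"]


def read_narrowpeak(path) -> pd.DataFrame:
    """Read a 10-column ENCODE narrowPeak file into a peak table.

    The summit is resolved to an absolute coordinate: ``start + offset``,
    or the floor midpoint of the interval when the offset is -1 (the
    format's "no summit" sentinel). Row order is preserved.
    """
    path = str(path)
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        raise FormatError("empty narrowPeak file", path)
    if df.shape[1] != 10:
        raise FormatError(
            f"expected 10 columns, found {df.shape[1]}", path, line=1
        )
    df.columns = NARROWPEAK_COLUMNS
    for col, kind in [("start", int), ("end", int), ("score", float),
                      ("signal", float), ("p", float), ("q", float),
                      ("summit_offset", int)]:
        try:
            df[col] = df[col].astype(kind)
        except ValueError as exc:
            raise FormatError(f"non-numeric value in column {col!r}: {exc}", path)
    _validate_peaks(df, path)
    return resolve_summits(df)


def resolve_summits(df: pd.DataFrame) -> pd.DataFrame:
    """Attach an absolute ``summit`` column from the narrowPeak offset."""
    df = df.copy()
    offset = df["summit_offset"].to_numpy()
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) // 2
    summit = np.where(offset == -1, mid, df["start"].to_numpy() + offset)
    df["summit"] = summit
    bad = (summit < df["start"].to_numpy()) | (summit >= df["end"].to_numpy())
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise FormatError(
            f"summit {summit[i]} outside interval "
            f"[{df['start'].iat[i]}, {df['end'].iat[i]}) for peak "
            f"{df['name'].iat[i]!r}", line=i + 1,
        )
    return df


def _validate_peaks(df: pd.DataFrame, path: str | None) -> None:
    bad = ~(df["start"] < df["end"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"start >= end ({df['start'].iat[i]} >= {df['end'].iat[i]})",
            path, line=i + 1,
        )
    if (df["start"] < 0).any():
        i = int(np.flatnonzero((df["start"] < 0).to_numpy())[0])
        raise FormatError("negative start coordinate", path, line=i + 1)
    ok_strand = df["strand"].isin(["+", "-", "."])
    if not ok_strand.all():
        i = int(np.flatnonzero((~ok_strand).to_numpy())[0])
        raise FormatError(f"invalid strand {df['strand'].iat[i]!r}", path, line=i + 1)


def write_narrowpeak(df: pd.DataFrame, path) -> None:
    """Write a peak table as 10-column narrowPeak (summit as offset)."""
    out = df.copy()
    if "summit" in out.columns and "summit_offset" not in out.columns:
        out["summit_offset"] = out["summit"] - out["start"]
    out = out[NARROWPEAK_COLUMNS]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene models


@dataclass
class GenomeAnnotation:
    """Gene models with strand-aware TSS, indexed by chromosome.

    ``genes`` columns: gene_id, chrom, start, end, strand, tss (all
    0-based half-open; tss = start for '+' genes, end-1 for '-' genes).
    ``exons`` columns: gene_id, chrom, start, end (may be empty).
    """

    genes: pd.DataFrame
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "chrom", "start", "end"]))
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        g = self.genes
        if g["gene_id"].duplicated().any():
            dup = g.loc[g["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise FormatError(f"duplicate gene id {dup!r}")
        if not g["strand"].isin(["+", "-"]).all():
            bad = g.loc[~g["strand"].isin(["+", "-"]), "strand"].iloc[0]
            raise FormatError(f"unknown strand {bad!r}")
        expected = np.where(g["strand"] == "+", g["start"], g["end"] - 1)
        if "tss" not in g.columns:
            self.genes = g = g.assign(tss=expected)
        elif not (g["tss"].to_numpy() == expected).all():
            raise FormatError("tss column inconsistent with strand convention")
        # per-chromosome index sorted by TSS for nearest-TSS queries
        self._by_chrom: dict[str, pd.DataFrame] = {
            c: sub.sort_values(["tss", "gene_id"], kind="stable").reset_index(drop=True)
            for c, sub in self.genes.groupby("chrom", sort=False)
        }

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def genes_on(self, chrom: str) -> pd.DataFrame:
        """Genes on ``chrom`` sorted by TSS (empty frame if none)."""
        if chrom not in self._by_chrom:
            return self.genes.iloc[0:0]
        return self._by_chrom[chrom]

    def exons_of(self, gene_id: str) -> pd.DataFrame:
        return self.exons[self.exons["gene_id"] == gene_id]


_GTF_ATTR_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path) -> GenomeAnnotation:
    """Read gene models from a GTF (gene + exon features) or BED6 file.

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    """
    path = str(path)
    first = None
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                first = line
                break
    if first is None:
        raise FormatError("no records", path)
    if len(first.rstrip("\n").split("\t")) == 9:
        return _read_gtf(path)
    return _read_bed6(path)


def _read_gtf(path: str) -> GenomeAnnotation:
    genes, exons = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise FormatError(f"expected 9 GTF columns, found {len(parts)}",
                                  path, lineno)
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = parts
            if feature not in ("gene", "exon"):
                continue
            m = _GTF_ATTR_RE.search(attrs)
            if m is None:
                raise FormatError("missing gene_id attribute", path, lineno)
            if strand not in ("+", "-"):
                raise FormatError(f"unknown strand {strand!r}", path, lineno)
            rec = {
                "gene_id": m.group(1), "chrom": chrom,
                "start": int(start) - 1, "end": int(end), "strand": strand,
            }
            (genes if feature == "gene" else exons).append(rec)
    if not genes:
        raise FormatError("no gene features", path)
    gdf = pd.DataFrame(genes)
    if gdf["gene_id"].duplicated().any():
        dup = gdf.loc[gdf["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise FormatError(f"duplicate gene id {dup!r}", path)
    edf = (pd.DataFrame(exons)[["gene_id", "chrom", "start", "end"]]
           if exons else pd.DataFrame(columns=["gene_id", "chrom", "start", "end"]))
    return GenomeAnnotation(genes=gdf, exons=edf)


def _read_bed6(path: str) -> GenomeAnnotation:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 6:
        raise FormatError(f"expected ≥6 BED columns, found {df.shape[1]}", path, 1)
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"unknown strand {df['strand'].iat[i]!r}", path, i + 1)
    return GenomeAnnotation(
        genes=df[["gene_id", "chrom", "start", "end", "strand"]].copy())


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write gene + exon features (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        for _, g in annotation.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(f"{g.chrom}\tchipxpr\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            exons = annotation.exons_of(g.gene_id)
            for _, e in exons.iterrows():
                fh.write(f"{e.chrom}\tchipxpr\texon\t{e.start + 1}\t{e.end}\t.\t"
                         f"{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# counts


@dataclass
class CountMatrix:
    """Gene-level counts (genes × samples) with a sample→condition map."""

    counts: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self):
        if self.counts.isna().any().any():
            raise FormatError("missing cells in count matrix")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise FormatError("non-integer count")
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative count")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise FormatError(f"samples without condition label: {sorted(missing)}")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    @property
    def condition_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return seen


def read_counts(path, conditions: Mapping[str, str]) -> CountMatrix:
    """Read a TSV count matrix (gene rows, sample columns, header row)."""
    path = str(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}", path)
    for col in df.columns:
        bad = df[col] != np.floor(df[col])
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header line
            raise FormatError(f"non-integer count in sample {col!r}", path, lineno)
    return CountMatrix(counts=df.astype(np.int64), conditions=dict(conditions))


def write_counts(cm: CountMatrix, path) -> None:
    cm.counts.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# genome sequence


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an (ordered) name → uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    """Write sequences with 60-column wrapping."""
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# motifs (file format; the models themselves live in chipxpr.motifs)


def read_motifs(path) -> list:
    """Read motif models from the package's plain-text motif format.

    Two record kinds::

        NAME<TAB>IUPAC_CONSENSUS[<TAB>max_mismatches]
        >NAME<TAB>threshold
        pA pC pG pT        (one row per motif position; rows sum to 1)

    Returns a list of :class:`chipxpr.motifs.MotifModel`.
    """
    from .motifs import MotifModel  # local import to avoid a cycle

    path = str(path)
    models: list[MotifModel] = []
    pwm_name = None
    pwm_thresh = None
    pwm_rows: list[list[float]] = []
    start_line = 0

    def _flush(lineno):
        nonlocal pwm_name, pwm_thresh, pwm_rows
        if pwm_name is None:
            return
        if not pwm_rows:
            raise FormatError(f"PWM {pwm_name!r} has no rows", path, lineno)
        try:
            models.append(MotifModel.from_pwm(
                pwm_name, np.asarray(pwm_rows, dtype=float), pwm_thresh))
        except ValueError as exc:
            raise FormatError(str(exc), path, start_line)
        pwm_name, pwm_thresh, pwm_rows = None, None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush(lineno)
                parts = line[1:].split()
                if len(parts) != 2:
                    raise FormatError("PWM header needs '>NAME threshold'",
                                      path, lineno)
                pwm_name, pwm_thresh = parts[0], float(parts[1])
                start_line = lineno
            elif pwm_name is not None and line[0] in "0123456789.-":
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise FormatError("PWM row needs 4 probabilities", path, lineno)
                pwm_rows.append(vals)
            else:
                _flush(lineno)
                parts = line.split()
                if len(parts) not in (2, 3):
                    raise FormatError("consensus record needs 'NAME CONSENSUS "
                                      "[max_mismatches]'", path, lineno)
                mism = int(parts[2]) if len(parts) == 3 else 0
                try:
                    models.append(MotifModel.from_consensus(
                        parts[0], parts[1], max_mismatches=mism))
                except ValueError as exc:
                    raise FormatError(str(exc), path, lineno)
    _flush(-1)
    if not models:
        raise FormatError("no motif records", path)
    return models


def write_motifs(models, path) -> None:
    with open(path, "w") as fh:
        for m in models:
            if m.kind == "consensus":
                fh.write(f"{m.name}\t{m.consensus}\t{m.max_mismatches}\n")
            else:
                fh.write(f">{m.name}\t{m.threshold}\n")
                for row in m.pwm:
                    # enough digits that re-read rows still sum to 1 ± 1e-6
                    fh.write(" ".join(f"{x:.10f}" for x in row) + "\n")
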