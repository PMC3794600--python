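"""Readers and writers for every external format the pipeline touches.

Formats
-------
* subtype table: 2-column TSV, header ``cell_line<TAB>subtype``
* gene models: BED12 (preferred) or a minimal GTF subset (features
  ``gene``/``exon``, mandatory strand, ``gene_id "..."`` attribute)
* mapped reads: BED3, one file per cell line
* bin counts: TSV, rows ``gene:bin`` (or ``gene:region``), columns cell lines
* expression: TSV, rows genes, columns cell lines
* PWMs: TRANSFAC flat matrix format

BED intervals are read as-is (already 0-based half-open); GTF coordinates
are converted from 1-based closed.
"""

from __future__ import annotations

import importlib.resources
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    SUBTYPES,
    ExpressionMatrix,
    FormatError,
    GeneModel,
    PWM,
    PWMSet,
    ReadSet,
    SubtypeTable,
    ValidationError,
    normalize_name,
)

_PSEUDOCOUNT = 0.01  # per-base pseudo-count applied when normalizing PWM counts


# ---------------------------------------------------------------------------
# subtype table

def read_subtype_table(path: str | Path) -> SubtypeTable:
    """Read the cell-line -> subtype table, preserving file order."""
    path = Path(path)
    entries: list[tuple[str, str]] = []
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty subtype table")
    start = 1 if lines[0].lower().startswith("cell_line") else 0
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = line.split("\t")
        if len(fields) != 2:
            raise FormatError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        cell_line, subtype = normalize_name(fields[0]), fields[1].strip()
        if subtype not in SUBTYPES:
            raise FormatError(
                f"{path}:{lineno}: unknown subtype {subtype!r} for {cell_line!r}"
            )
        entries.append((cell_line, subtype))
    return SubtypeTable(tuple(entries))


def write_subtype_table(table: SubtypeTable, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("cell_line\tsubtype\n")
        for cell_line, subtype in table.entries:
            fh.write(f"{cell_line}\t{subtype}\n")


# ---------------------------------------------------------------------------
# gene models

def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 or a minimal GTF dialect.

    The dialect is chosen by extension (``.bed`` vs ``.gtf``/``.gff``);
    anything else is tried as BED12 first.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        return _read_gtf(path)
    return _read_bed12(path)


def _read_bed12(path: Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise FormatError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}"
                )
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: missing or bad strand {strand!r}")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != int(f[9]) or len(offsets) != int(f[9]):
                raise FormatError(f"{path}:{lineno}: blockCount mismatch")
            exons_genomic = [(start + off, start + off + sz) for off, sz in zip(offsets, sizes)]
            for s, e in exons_genomic:
                if s < start or e > end:
                    raise ValidationError(
                        f"{path}:{lineno}: exon [{s},{e}) outside gene span [{start},{end})"
                    )
            exons = exons_genomic if strand == "+" else exons_genomic[::-1]
            genes.append(GeneModel(name, chrom, strand, tuple(exons)))
    return genes


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def _read_gtf(path: Path) -> list[GeneModel]:
    spans: dict[str, tuple[str, str, int, int]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
            chrom, _src, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
            if feature not in ("gene", "exon"):
                continue
            if strand not in ("+", "-"):
                raise ValidationError(f"{path}:{lineno}: missing strand")
            m = _GTF_GENE_ID.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            gid = m.group(1)
            start, end = int(start1) - 1, int(end1)  # 1-based closed -> 0-based half-open
            if feature == "gene":
                spans[gid] = (chrom, strand, start, end)
                if gid not in order:
                    order.append(gid)
            else:
                exons.setdefault(gid, []).append((start, end))
                if gid not in order:
                    order.append(gid)
    genes = []
    for gid in order:
        ex = sorted(exons.get(gid, []))
        if gid in spans:
            chrom, strand, gstart, gend = spans[gid]
            for s, e in ex:
                if s < gstart or e > gend:
                    raise ValidationError(
                        f"{path}: gene {gid}: exon [{s},{e}) outside span [{gstart},{gend})"
                    )
        else:
            raise FormatError(f"{path}: exon features without a gene record for {gid}")
        if not ex:
            ex = [(gstart, gend)]
        if strand == "-":
            ex = ex[::-1]
        genes.append(GeneModel(gid, chrom, strand, tuple(ex)))
    return genes


def write_gene_models_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            genomic = sorted(g.exons)
            start = genomic[0][0]
            end = genomic[-1][1]
            sizes = ",".join(str(e - s) for s, e in genomic)
            offsets = ",".join(str(s - start) for s, _ in genomic)
            fh.write(
                f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{start}\t{end}\t0\t{len(genomic)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# reads and intervals

def read_reads_bed(path: str | Path, cell_line_id: str | None = None) -> ReadSet:
    """Read mapped-read intervals from BED3; cell line defaults to the stem."""
    path = Path(path)
    reads: list[tuple[str, int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED3 requires 3 columns")
            reads.append((f[0], int(f[1]), int(f[2])))
    name = cell_line_id if cell_line_id is not None else normalize_name(path.stem)
    return ReadSet(name, tuple(reads))


def read_intervals_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read plain BED3 intervals (e.g. CpG islands)."""
    return list(read_reads_bed(path, cell_line_id="_intervals").reads)


def write_intervals_bed(
    intervals: Iterable[tuple[str, int, int]], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# numeric matrices (expression, bin counts)

def _read_numeric_tsv(path: Path, what: str) -> pd.DataFrame:
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty {what} file")
        columns = header.split("\t")[1:]
        if not columns:
            raise FormatError(f"{path}: {what} header has no cell-line columns")
        index: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != len(columns) + 1:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(f)} fields, "
                    f"expected {len(columns) + 1})"
                )
            vals = []
            for col, cell in zip(columns, f[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column {col!r}"
                    ) from None
                if np.isnan(v):
                    raise FormatError(
                        f"{path}:{lineno}: missing value in column {col!r}"
                    )
                vals.append(v)
            index.append(f[0])
            rows.append(vals)
    if not rows:
        raise FormatError(f"{path}: {what} has no data rows")
    df = pd.DataFrame(rows, index=index, columns=[normalize_name(c) for c in columns])
    return df


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a gene x cell-line log-abundance TSV (rejects missing values)."""
    df = _read_numeric_tsv(Path(path), "expression matrix")
    return ExpressionMatrix(df, centered=False)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    _write_numeric_tsv(matrix.data, Path(path), index_name="gene")


def read_bin_counts(path: str | Path) -> pd.DataFrame:
    """Read a bin-count TSV; row ids ``gene:bin`` become a (gene, bin) index."""
    df = _read_numeric_tsv(Path(path), "bin counts")
    genes, bins = [], []
    for rid in df.index:
        gene, _, binpart = rid.rpartition(":")
        if not gene:
            raise FormatError(f"{path}: row id {rid!r} is not gene:bin")
        genes.append(gene)
        try:
            bins.append(int(binpart))
        except ValueError:
            bins.append(binpart)  # region-named rows
    df.index = pd.MultiIndex.from_arrays([genes, bins], names=["gene", "bin"])
    return df


def write_bin_counts(df: pd.DataFrame, path: str | Path) -> None:
    flat = df.copy()
    flat.index = [f"{g}:{b}" for g, b in df.index]
    _write_numeric_tsv(flat, Path(path), index_name="unit")


def _write_numeric_tsv(df: pd.DataFrame, path: Path, index_name: str) -> None:
    with path.open("w") as fh:
        fh.write(index_name + "\t" + "\t".join(map(str, df.columns)) + "\n")
        values = df.to_numpy()
        for rid, row in zip(df.index, values):
            fh.write(str(rid) + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# PWMs (TRANSFAC flat format)

def read_pwms(path: str | Path, pseudocount: float = _PSEUDOCOUNT) -> PWMSet:
    """Parse TRANSFAC-style matrix blocks into probability PWMs.

    Counts in each position row are normalized to probabilities after adding
    ``pseudocount`` to every base, so no base ever has probability zero.
    """
    path = Path(path)
    pwms: list[PWM] = []
    current_id: str | None = None
    rows: list[tuple[float, float, float, float]] = []

    def flush(lineno: int) -> None:
        nonlocal current_id, rows
        if current_id is None:
            return
        if not rows:
            raise FormatError(f"{path}:{lineno}: matrix {current_id} has no positions")
        probs = []
        for counts in rows:
            total = sum(counts)
            if total <= 0:
                raise FormatError(
                    f"{path}: matrix {current_id}: position row sums to {total}"
                )
            adj = [c + pseudocount for c in counts]
            s = sum(adj)
            probs.append(tuple(c / s for c in adj))
        pwms.append(PWM(current_id, tuple(probs)))
        current_id, rows = None, []

    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").strip()
            if not line:
                continue
            if line.startswith("//"):
                flush(lineno)
                continue
            tag = line.split()[0]
            if tag == "ID":
                flush(lineno)
                parts = line.split()
                if len(parts) < 2:
                    raise FormatError(f"{path}:{lineno}: ID line without identifier")
                current_id = parts[1]
            elif tag in ("P0", "PO"):
                continue  # column header A C G T
            elif re.fullmatch(r"\d+", tag):
                if current_id is None:
                    raise FormatError(f"{path}:{lineno}: position row outside a matrix")
                fields = line.split()
                if len(fields) < 5:
                    raise FormatError(
                        f"{path}:{lineno}: position row needs A C G T counts"
                    )
                try:
                    counts = tuple(float(x) for x in fields[1:5])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric count") from None
                rows.append(counts)  # type: ignore[arg-type]
            # other TRANSFAC tags (BF, NA, XX, ...) are ignored
    flush(-1)
    if not pwms:
        raise FormatError(f"{path}: no matrices found")
    return PWMSet(tuple(pwms))


def write_pwms(pwms: PWMSet, path: str | Path, scale: float = 100.0) -> None:
    """Write PWMs as TRANSFAC count blocks (probabilities x ``scale``)."""
    with Path(path).open("w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.matrix_id}\nP0\tA\tC\tG\tT\n")
            for i, row in enumerate(pwm.probs, start=1):
                counts = "\t".join(f"{v * scale:.4f}" for v in row)
                fh.write(f"{i:02d}\t{counts}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# FASTA (promoter sequences)

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an id -> uppercase-sequence mapping."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# bundled reference tables

def load_cell_line_panel() -> SubtypeTable:
    """The bundled 30-cell-line breast-cancer panel with subtype labels."""
    ref = importlib.resources.files("methexpr.data") / "cell_line_subtypes.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_subtype_table(p)


def load_tfbs_reference() -> pd.DataFrame:
    """Bundled reference list of downregulated targets with TFBS hits on
    hypermethylated promoter regions (target gene, binding TF, support rate)."""
    ref = importlib.resources.files("methexpr.data") / "tfbs_candidates.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    expected = ["target_gene", "binding_tf", "support_rate"]
    if list(df.columns) != expected:
        raise FormatError(f"bundled TFBS table has columns {list(df.columns)}")
    return df
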