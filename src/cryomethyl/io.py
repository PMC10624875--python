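"""Readers and writers for the on-disk formats the pipeline touches.

Dialects:

* Bismark *coverage* (6-column TSV): chrom, start, end, methylation %,
  count methylated, count unmethylated, with start == end == the 1-based
  cytosine position. No strand information.
* Bismark *cytosine/CX report* (7-column TSV): chrom, pos, strand,
  count methylated, count unmethylated, context, trinucleotide. Only
  ``CG``-context rows are retained.
* GFF3 gene models (via gffutils), reduced to one longest transcript per gene.
* BED (0-based half-open) and bedGraph for export; the methylation percent
  column of input files is always recomputed from the counts.
* Sperm-quality table: CSV with header male_id, condition, membrane, mito,
  motility, fert_norm.
"""

from __future__ import annotations

import csv
import logging
import os
import tempfile
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd
from pyfaidx import Fasta

from .types import CytosineRecord, GeneModel, SampleMethylome, SiteKey

log = logging.getLogger(__name__)


class FormatError(ValueError):
    """A malformed line in an input file; message names the line number."""


# ---------------------------------------------------------------------------
# cytosine count dialects
# ---------------------------------------------------------------------------

def read_bismark_coverage(path, fasta: Optional[str] = None) -> List[CytosineRecord]:
    """Read a 6-column Bismark coverage file.

    The coverage dialect carries no strand; if ``fasta`` is given the strand is
    resolved from the reference base at each position (C -> "+", G -> "-"),
    otherwise it is stored as ".". Zero-depth rows are skipped with a warning.
    The methylation-percent column is ignored: counts are the primitive data.
    """
    ref = Fasta(str(fasta)) if fasta is not None else None
    out: List[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise FormatError(f"{path}: line {lineno}: expected 6 columns, got {len(parts)}")
            try:
                chrom = parts[0]
                start = int(parts[1])
                n_meth = int(parts[4])
                n_unmeth = int(parts[5])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if n_meth + n_unmeth == 0:
                log.warning("%s: line %d: zero depth, record skipped", path, lineno)
                continue
            strand = "."
            if ref is not None:
                base = str(ref[chrom][start - 1 : start]).upper()
                if base == "C":
                    strand = "+"
                elif base == "G":
                    strand = "-"
            out.append(CytosineRecord(chrom, start, strand, n_meth, n_unmeth))
    return out


def read_cx_report(path) -> List[CytosineRecord]:
    """Read a Bismark cytosine (CX) report, keeping only CpG-context rows."""
    out: List[CytosineRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno}: expected >=6 columns")
            chrom, pos_s, strand, nm_s, nu_s, context = parts[:6]
            if context != "CG":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: unknown strand {strand!r}")
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(nm_s), int(nu_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if n_meth + n_unmeth == 0:
                continue
            out.append(CytosineRecord(chrom, pos, strand, n_meth, n_unmeth))
    return out


def write_bismark_coverage(records: Iterable[CytosineRecord], path) -> None:
    """Write records in the 6-column coverage dialect (percent recomputed)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.strand))
    with open(path, "w") as fh:
        for r in recs:
            pct = 100.0 * r.n_meth / r.depth
            fh.write(f"{r.chrom}\t{r.pos}\t{r.pos}\t{pct:.6g}\t{r.n_meth}\t{r.n_unmeth}\n")


def write_cx_report(records: Iterable[CytosineRecord], path) -> None:
    """Write records in the 7-column CX-report dialect (context always CG)."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.strand))
    with open(path, "w") as fh:
        for r in recs:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.strand}\t{r.n_meth}\t{r.n_unmeth}\tCG\tCGN\n")


def load_sample(path, male_id: int, condition: str, dialect: str = "cx",
                fasta: Optional[str] = None) -> SampleMethylome:
    """Load one sample file into a :class:`SampleMethylome`."""
    if dialect == "cx":
        records = read_cx_report(path)
    elif dialect == "coverage":
        records = read_bismark_coverage(path, fasta=fasta)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    sample = SampleMethylome(male_id=male_id, condition=condition)
    for rec in records:
        sample.add(rec)
    return sample


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gff3_genes(path) -> List[GeneModel]:
    """Parse gene models from GFF3, one :class:`GeneModel` per gene.

    For multi-transcript genes the transcript with the longest genomic span is
    used (tie: most exons, then lexicographic id). A gene without exon
    features falls back to its own span as a single exon, with a warning.
    """
    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(str(path), dbpath, force=True, keep_order=True,
                                merge_strategy="create_unique")
        genes: List[GeneModel] = []
        for gene in db.features_of_type("gene"):
            best: Optional[Tuple[int, int, str, List[Tuple[int, int]]]] = None
            for tr in db.children(gene, featuretype=("mRNA", "transcript"), level=1):
                exons = [(e.start, e.end) for e in db.children(tr, featuretype="exon")]
                if not exons:
                    continue
                span = tr.end - tr.start + 1
                cand = (span, len(exons), tr.id, sorted(exons))
                if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                    best = cand
            if best is None:
                # exons directly under the gene, or none at all
                exons = sorted((e.start, e.end) for e in db.children(gene, featuretype="exon"))
                if not exons:
                    log.warning("gene %s has no exons; using gene body", gene.id)
                    exons = [(gene.start, gene.end)]
                best = (gene.end - gene.start + 1, len(exons), gene.id, exons)
            exons = best[3]
            if gene.strand == "-":
                exons = exons[::-1]
                tss, tes = gene.end, gene.start
            else:
                tss, tes = gene.start, gene.end
            genes.append(GeneModel(gene_id=gene.id, chrom=gene.seqid,
                                   strand=gene.strand, tss=tss, tes=tes, exons=exons))
        return genes
    finally:
        os.unlink(dbpath)


# ---------------------------------------------------------------------------
# BED / bedGraph export (0-based half-open at the boundary)
# ---------------------------------------------------------------------------

def to_bed_interval(start_1based: int, end_1based: int) -> Tuple[int, int]:
    """1-based closed interval -> 0-based half-open (BED) interval."""
    return start_1based - 1, end_1based


def from_bed_interval(start0: int, end0: int) -> Tuple[int, int]:
    """0-based half-open (BED) interval -> 1-based closed interval."""
    return start0 + 1, end0


def write_bed(intervals: Sequence[Tuple[str, int, int]], path, header: str = "regions") -> None:
    """Write 1-based closed (chrom, start, end) intervals as sorted BED."""
    rows = sorted(intervals)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for chrom, s, e in rows:
            b0, b1 = to_bed_interval(s, e)
            fh.write(f"{chrom}\t{b0}\t{b1}\n")


def write_bedgraph(records: Iterable[CytosineRecord], path) -> None:
    """Write per-cytosine methylation ratios as sorted bedGraph."""
    recs = sorted(records, key=lambda r: (r.chrom, r.pos))
    with open(path, "w") as fh:
        fh.write("# methylation ratio per cytosine\n")
        for r in recs:
            b0, b1 = to_bed_interval(r.pos, r.pos)
            fh.write(f"{r.chrom}\t{b0}\t{b1}\t{r.ratio:.6g}\n")


# ---------------------------------------------------------------------------
# quality table and FASTA
# ---------------------------------------------------------------------------

QUALITY_COLUMNS = ["male_id", "condition", "membrane", "mito", "motility", "fert_norm"]


def read_quality_table(path) -> pd.DataFrame:
    """Read the per-male sperm-quality CSV (one row per male x condition)."""
    df = pd.read_csv(path)
    missing = set(QUALITY_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing quality columns {sorted(missing)}")
    if df.duplicated(subset=["male_id", "condition"]).any():
        raise FormatError(f"{path}: duplicate male_id x condition rows")
    return df


def write_quality_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=QUALITY_COLUMNS,
              quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def write_fasta(sequences: Dict[str, str], path, width: int = 80) -> None:
    """Write a reference genome FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA into a plain {name: sequence} dict (uppercased)."""
    ref = Fasta(str(path))
    return {name: str(ref[name][:]).upper() for name in ref.keys()}
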