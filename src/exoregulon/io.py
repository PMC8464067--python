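"""Readers and writers for the flat genomic formats the pipeline exchanges.

All in-memory coordinates are 0-based, half-open.  On disk each format
follows its own standard: BED and bedGraph are 0-based half-open, GFF3 is
1-based inclusive.  The converters here are the only place that mapping
happens.
"""

from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_COLUMNS = ["gene_id", "name", "strand", "start", "end", "operon_id", "cog"]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(path: str | Path, sequence: str, name: str = "chr") -> None:
    record = SeqRecord(Seq(sequence), id=name, description="")
    SeqIO.write([record], str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Return {contig name: uppercase sequence}."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

def write_gff3(path: str | Path, genes: pd.DataFrame, contig: str = "chr") -> None:
    """Write gene features; operon_id and cog become attributes when present."""
    lines = ["##gff-version 3"]
    for _, g in genes.iterrows():
        attrs = [f"ID={g.gene_id}", f"locus_tag={g.gene_id}", f"Name={g['name']}"]
        if pd.notna(g.get("operon_id")) and g.get("operon_id"):
            attrs.append(f"operon_id={g.operon_id}")
        if pd.notna(g.get("cog")) and g.get("cog"):
            attrs.append(f"cog={g.cog}")
        lines.append(
            "\t".join(
                [
                    contig,
                    "exoregulon",
                    "gene",
                    str(int(g.start) + 1),  # GFF3 is 1-based inclusive
                    str(int(g.end)),
                    ".",
                    g.strand,
                    ".",
                    ";".join(attrs),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_gff_attrs(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read gene features into the canonical gene table (0-based half-open)."""
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
        if fields[2] != "gene":
            continue
        start1, end1 = int(fields[3]), int(fields[4])
        if end1 < start1:
            raise ValueError(f"{path}:{lineno}: gene end < start")
        if fields[6] not in "+-":
            raise ValueError(f"{path}:{lineno}: bad strand {fields[6]!r}")
        attrs = _parse_gff_attrs(fields[8])
        gid = attrs.get("ID") or attrs.get("locus_tag")
        if gid is None:
            raise ValueError(f"{path}:{lineno}: gene without ID/locus_tag")
        rows.append(
            {
                "gene_id": gid,
                "name": attrs.get("Name", gid),
                "strand": fields[6],
                "start": start1 - 1,
                "end": end1,
                "operon_id": attrs.get("operon_id", ""),
                "cog": attrs.get("cog", ""),
            }
        )
    df = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return df.sort_values("start", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(path: str | Path, intervals: Iterable[tuple[int, int]] | pd.DataFrame,
              contig: str = "chr", names: Iterable[str] | None = None,
              scores: Iterable[float] | None = None) -> None:
    if isinstance(intervals, pd.DataFrame):
        ivs = list(zip(intervals["start"], intervals["end"]))
    else:
        ivs = list(intervals)
    names = list(names) if names is not None else [f"iv{i}" for i in range(len(ivs))]
    scores = list(scores) if scores is not None else [0] * len(ivs)
    with open(path, "w") as fh:
        for (s, e), nm, sc in zip(ivs, names, scores):
            fh.write(f"{contig}\t{int(s)}\t{int(e)}\t{nm}\t{sc}\t.\n")


def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    ivs = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
        s, e = int(fields[1]), int(fields[2])
        if e < s or s < 0:
            raise ValueError(f"{path}:{lineno}: bad interval [{s},{e})")
        ivs.append((s, e))
    return sorted(ivs)


# ---------------------------------------------------------------------------
# bedGraph coverage tracks
# ---------------------------------------------------------------------------

def write_bedgraph(path: str | Path, values: np.ndarray, contig: str = "chr") -> None:
    """Run-length encode a per-position vector; zero runs are omitted."""
    values = np.asarray(values)
    if values.size == 0:
        Path(path).write_text("")
        return
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [values.size]])
    with open(path, "w") as fh:
        for s, e in zip(starts, ends):
            v = values[s]
            if v != 0:
                v_out = int(v) if float(v).is_integer() else float(v)
                fh.write(f"{contig}\t{s}\t{e}\t{v_out}\n")


def scan_bedgraph(path: str | Path, genome_length: int | None = None) -> int:
    """Validate a bedGraph without densifying it; returns the record count."""
    n = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
        s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
        if s < 0 or e < s or (genome_length is not None and e > genome_length):
            raise ValueError(f"{path}:{lineno}: interval [{s},{e}) outside genome")
        if v < 0:
            raise ValueError(f"{path}:{lineno}: negative coverage value {v}")
        n += 1
    return n


def read_bedgraph(path: str | Path, genome_length: int) -> np.ndarray:
    """Expand a bedGraph to a dense per-position float vector."""
    values = np.zeros(genome_length, dtype=float)
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith(("#", "track")):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
        s, e, v = int(fields[1]), int(fields[2]), float(fields[3])
        if s < 0 or e > genome_length or e < s:
            raise ValueError(f"{path}:{lineno}: interval [{s},{e}) outside genome")
        if v < 0:
            raise ValueError(f"{path}:{lineno}: negative coverage value {v}")
        values[s:e] = v
    return values


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read an external differential-expression table.

    Expects columns gene_id, log2FoldChange, pvalue and optionally padj
    (computed by BH when absent).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2FoldChange", "pvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DE table missing columns {sorted(missing)}")
    df = df.rename(columns={"log2FoldChange": "log2fc"})
    if "padj" not in df.columns:
        from .regulon import bh_adjust

        df["padj"] = bh_adjust(df["pvalue"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_formats(paths: dict[str, str | Path], genome_length: int | None = None) -> dict:
    """Check input files for coordinate sanity and column contracts.

    `paths` maps a kind in {fasta, gff3, bed, bedgraph, tsv} (optionally
    suffixed, e.g. "bedgraph:ip1.fwd") to a file path.  Returns
    {"errors": [...], "warnings": [...]}; each entry names file and line.
    """
    errors: list[str] = []
    warnings: list[str] = []
    for kind, path in paths.items():
        base = kind.split(":")[0]
        path = Path(path)
        if not path.exists():
            errors.append(f"{path}: file not found")
            continue
        try:
            if base == "fasta":
                seqs = read_fasta(path)
                if not seqs:
                    errors.append(f"{path}: no FASTA records")
                for name, seq in seqs.items():
                    bad = set(seq) - set("ACGTNRYSWKMBDHV")
                    if bad:
                        errors.append(f"{path}: contig {name} has non-IUPAC letters {sorted(bad)}")
            elif base == "gff3":
                genes = read_gff3(path)
                if genes.empty:
                    warnings.append(f"{path}: no gene features")
                if genome_length is not None and not genes.empty:
                    if int(genes["end"].max()) > genome_length:
                        errors.append(f"{path}: gene beyond genome end")
            elif base == "bed":
                read_bed_intervals(path)
            elif base == "bedgraph":
                scan_bedgraph(path, genome_length)
            elif base == "tsv":
                pd.read_csv(path, sep="\t")
            else:
                warnings.append(f"{path}: unknown kind {kind!r}, skipped")
        except (ValueError, OSError) as exc:
            errors.append(str(exc))
    return {"errors": errors, "warnings": warnings}


def config_hash(obj) -> str:
    """Stable short hash of a config mapping (sorted-key repr)."""
    buf = _io.StringIO()
    _canonical_dump(obj, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()[:12]


def _canonical_dump(obj, buf) -> None:
    if isinstance(obj, dict):
        buf.write("{")
        for k in sorted(obj):
            buf.write(repr(k) + ":")
            _canonical_dump(obj[k], buf)
            buf.write(",")
        buf.write("}")
    elif isinstance(obj, (list, tuple)):
        buf.write("[")
        for v in obj:
            _canonical_dump(v, buf)
            buf.write(",")
        buf.write("]")
    else:
        buf.write(repr(obj))
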