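"""Readers and writers for the external formats the pipeline touches.

Formats: BED3/BED6/narrowPeak, bedGraph, a tabular gene table, MEME minimal
motif files, FASTA (via pyfaidx) and a TSV expression matrix with a one-line
group header.  Every reader validates records against the domain-type
invariants and reports the offending line number; nothing is silently dropped
or coerced.  Each writer emits files its paired reader parses back to an
equal value.
"""

from __future__ import annotations

import math
import os
from typing import Optional

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .motifs import PWMRecord
from .regions import GeneModel, GenomicInterval, RegionSet
from .stats import ExpressionMatrix
from .tracks import CoverageTrack

__all__ = [
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_gene_table",
    "write_gene_table",
    "read_meme_motifs",
    "write_meme_motifs",
    "read_expression",
    "write_expression",
    "open_fasta",
    "fetch_sequence",
]


class FormatError(ValueError):
    """A malformed record, reported with file and line number."""


def _err(path, lineno: int, msg: str) -> FormatError:
    return FormatError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------------------
# BED / narrowPeak

def read_bed(path, stage: Optional[str] = None) -> RegionSet:
    """Read BED3/BED6/narrowPeak into a RegionSet (input order preserved).

    Columns beyond the sixth (e.g. narrowPeak signalValue/pValue/qValue/peak)
    are retained verbatim in ``GenomicInterval.extra``.
    """
    label = stage if stage is not None else os.path.splitext(os.path.basename(path))[0]
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise _err(path, lineno, f"expected >=3 tab-separated columns, got {len(fields)}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise _err(path, lineno, f"non-integer coordinate: {exc}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise _err(path, lineno, f"non-numeric score {fields[4]!r}")
            strand = fields[5] if len(fields) > 5 else None
            try:
                iv = GenomicInterval(
                    fields[0], start, end, name=name, score=score, strand=strand,
                    extra=tuple(fields[6:]),
                )
            except ValueError as exc:
                raise _err(path, lineno, str(exc))
            intervals.append(iv)
    return RegionSet(stage=label, intervals=intervals, normalized=False)


def write_bed(regions: RegionSet | list[GenomicInterval], path) -> None:
    ivs = regions.intervals if isinstance(regions, RegionSet) else regions
    with open(path, "w") as fh:
        for iv in ivs:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            has_later = iv.score is not None or iv.strand is not None or iv.extra
            if iv.name is not None or has_later:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None or iv.strand is not None or iv.extra:
                fields.append(_fmt_score(iv.score) if iv.score is not None else ".")
            if iv.strand is not None or iv.extra:
                fields.append(iv.strand if iv.strand is not None else ".")
            fields.extend(str(x) for x in iv.extra)
            fh.write("\t".join(fields) + "\n")


def _fmt_score(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# bedGraph

def read_bedgraph(path) -> CoverageTrack:
    """Read a 4-column bedGraph.  Overlapping steps are an error, never merged."""
    steps: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise _err(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise _err(path, lineno, f"bad bedGraph record: {exc}")
            if not math.isfinite(value):
                raise _err(path, lineno, f"non-finite value {fields[3]!r}")
            if start >= end:
                raise _err(path, lineno, f"empty step ({start}, {end})")
            steps.setdefault(fields[0], []).append((start, end, value))
    try:
        return CoverageTrack(steps)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}")


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# Gene table
#
# Tab-separated, '#'-prefixed header, columns:
#   gene_id  chrom  strand  start  end  exon_starts  exon_ends
# Coordinates are 0-based half-open; exon_starts/exon_ends are comma-separated
# parallel lists (empty string = no exon annotation).

GENE_TABLE_HEADER = "#gene_id\tchrom\tstrand\tstart\tend\texon_starts\texon_ends"


def read_gene_table(path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise _err(path, lineno, f"expected >=5 columns, got {len(fields)}")
            gene_id, chrom, strand = fields[0], fields[1], fields[2]
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise _err(path, lineno, f"non-integer gene span: {exc}")
            exons: list[tuple[int, int]] = []
            if len(fields) >= 7 and fields[5]:
                try:
                    estarts = [int(x) for x in fields[5].split(",") if x]
                    eends = [int(x) for x in fields[6].split(",") if x]
                except ValueError as exc:
                    raise _err(path, lineno, f"bad exon list: {exc}")
                if len(estarts) != len(eends):
                    raise _err(path, lineno, "exon_starts and exon_ends differ in length")
                exons = list(zip(estarts, eends))
            try:
                genes.append(GeneModel(gene_id, chrom, strand, start, end, exons))
            except ValueError as exc:
                raise _err(path, lineno, str(exc))
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_TABLE_HEADER + "\n")
        for g in genes:
            estarts = ",".join(str(s) for s, _ in g.exons)
            eends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.gene_start}\t{g.gene_end}"
                f"\t{estarts}\t{eends}\n"
            )


# ---------------------------------------------------------------------------
# MEME minimal motif format

_ALPHABET = "ACGT"


def read_meme_motifs(path) -> list[PWMRecord]:
    """Parse a MEME minimal-format motif file into PWMRecords (file order).

    Rows whose probabilities deviate from summing to 1 by less than 1e-3 are
    renormalized; larger deviations are an error.  A missing ALPHABET line is
    an error.
    """
    with open(path) as fh:
        lines = fh.readlines()

    alphabet = None
    background = np.full(4, 0.25)
    motifs: list[PWMRecord] = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("ALPHABET"):
            alphabet = line.split("=", 1)[1].strip() if "=" in line else line.split()[-1]
        elif line.startswith("Background letter frequencies"):
            i += 1
            parts = lines[i].split()
            freq = {parts[j]: float(parts[j + 1]) for j in range(0, len(parts), 2)}
            background = np.array([freq.get(b, 0.25) for b in _ALPHABET])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            if alphabet is None:
                raise FormatError(f"{path}: MOTIF before ALPHABET line")
            if alphabet.upper() != _ALPHABET:
                raise FormatError(f"{path}: unsupported alphabet {alphabet!r}")
            # seek letter-probability header
            while i < len(lines) and not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            if i == len(lines):
                raise FormatError(f"{path}: motif {motif_id}: missing letter-probability matrix")
            header = lines[i].strip()
            width = None
            toks = header.replace("=", " = ").split()
            for j, tok in enumerate(toks):
                if tok == "w" and j + 2 < len(toks) + 1:
                    width = int(toks[j + 2])
            if width is None:
                raise FormatError(f"{path}: motif {motif_id}: no w= in matrix header")
            rows = []
            for k in range(width):
                i += 1
                vals = [float(x) for x in lines[i].split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}:{i + 1}: expected 4 probabilities")
                s = sum(vals)
                if abs(s - 1.0) >= 1e-3:
                    raise FormatError(
                        f"{path}:{i + 1}: motif {motif_id} row {k} sums to {s:.6f}, not 1"
                    )
                rows.append([v / s for v in vals])
            motifs.append(PWMRecord(motif_id, np.array(rows), background=background.copy()))
        i += 1
    return motifs


def write_meme_motifs(motifs: list[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if motifs:
            bg = motifs[0].background
            fh.write("Background letter frequencies\n")
            fh.write(" ".join(f"{b} {bg[j]:.6f}" for j, b in enumerate(_ALPHABET)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} nsites= 20 E= 0\n")
            for row in m.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Expression matrix TSV
#
# Line 1: "#groups" TAB one label per sample.
# Line 2: "gene_id" TAB sample ids.
# Body:   gene_id TAB values (non-negative, linear scale unless stated).


def read_expression(path) -> ExpressionMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
        if not first or first[0] != "#groups":
            raise FormatError(f"{path}:1: expected '#groups' header line")
        groups = first[1:]
        df = pd.read_csv(fh, sep="\t", index_col=0, float_precision="round_trip")
    if len(groups) != df.shape[1]:
        raise FormatError(
            f"{path}: {len(groups)} group labels for {df.shape[1]} sample columns"
        )
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in expression matrix")
    return ExpressionMatrix(
        genes=list(df.index.astype(str)),
        samples=list(zip(df.columns.astype(str), groups)),
        values=df.to_numpy(dtype=float),
    )


def write_expression(mat: ExpressionMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#groups\t" + "\t".join(g for _, g in mat.samples) + "\n")
        fh.write("gene_id\t" + "\t".join(s for s, _ in mat.samples) + "\n")
        for gid, row in zip(mat.genes, mat.values):
            fh.write(gid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def open_fasta(path) -> Fasta:
    return Fasta(str(path), sequence_always_upper=True)


def fetch_sequence(fasta: Fasta, interval: GenomicInterval) -> str:
    """Sequence of a 0-based half-open interval, uppercase."""
    return str(fasta[interval.chrom][interval.start : interval.end])
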