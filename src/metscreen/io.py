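"""Readers and writers for the plain-text formats the pipeline touches.

All tables are tab-separated UTF-8 with a header row; lines starting with
``#`` are comments.  BED peak files are the single place where the on-disk
0-based half-open convention meets the in-memory 1-based inclusive one.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    BedParseError,
    CountMatrix,
    DuplicateIdError,
    GeneAnnotation,
    GenomicInterval,
    NegativeCountError,
    NonIntegerCountError,
    PeakSet,
    PermissiveSampleRecord,
    SampleRecord,
    SurvivalRecord,
    ValidationError,
    validate_annotation,
)

log = logging.getLogger("metscreen")

_TSV = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such file: {p}")
    return p


# ---------------------------------------------------------------- counts

def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples integer count TSV (first column = gene ids)."""
    p = _require(path)
    df = pd.read_csv(p, index_col=0, **_TSV)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for j, s in enumerate(sample_ids):
        col = raw[:, j]
        try:
            values[:, j] = np.asarray(col, dtype=np.int64)
        except (ValueError, OverflowError):
            for i, cell in enumerate(col):
                try:
                    values[i, j] = int(cell)
                except ValueError:
                    raise NonIntegerCountError(
                        f"non-integer count {cell!r} for gene {gene_ids[i]!r}, "
                        f"sample {s!r} in {p}"
                    ) from None
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise NegativeCountError(
            f"negative count {values[i, j]} for gene {gene_ids[i]!r}, "
            f"sample {sample_ids[j]!r} in {p}"
        )
    return CountMatrix(gene_ids, sample_ids, values)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------- BED peaks

def read_bed_peaks(path: str | Path, tf_name: str, condition: str) -> PeakSet:
    """Read a >=3-column BED file into a :class:`PeakSet`.

    On disk BED is 0-based half-open; intervals come back 1-based
    inclusive, so line ``chr1 999 2000`` becomes ``chr1:1000-2000``.
    Duplicate identical intervals are dropped with a logged count.
    """
    p = _require(path)
    intervals: list[GenomicInterval] = []
    seen: set[tuple[str, int, int]] = set()
    n_dup = 0
    with open(p, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{p}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{p}:{lineno}: non-integer coordinates {fields[1]!r}, {fields[2]!r}"
                ) from None
            if start0 < 0 or start0 >= end0:
                raise BedParseError(
                    f"{p}:{lineno}: empty or inverted interval [{start0}, {end0})"
                )
            key = (chrom, start0 + 1, end0)
            if key in seen:
                n_dup += 1
                continue
            seen.add(key)
            intervals.append(GenomicInterval(chrom, start0 + 1, end0))
    if n_dup:
        log.info("%s: dropped %d duplicate peaks", p.name, n_dup)
    return PeakSet(tf_name=tf_name, condition=condition, intervals=intervals)


def write_bed_peaks(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for iv in peaks.intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


# ---------------------------------------------------------------- annotation

_ANNOT_COLS = ["gene_id", "chrom", "strand", "tss"]


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene table: gene_id, chrom, strand, tss[, gene_name]."""
    p = _require(path)
    df = pd.read_csv(p, **_TSV)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{p}: missing annotation columns {missing}")
    has_name = "gene_name" in df.columns
    annotations = []
    for row in df.itertuples(index=False):
        try:
            tss = int(getattr(row, "tss"))
        except ValueError:
            raise ValidationError(f"{p}: non-integer tss {row.tss!r} for {row.gene_id!r}") from None
        annotations.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                tss=tss,
                gene_name=str(row.gene_name) if has_name and row.gene_name else None,
            )
        )
    validate_annotation(annotations)
    return annotations


def write_annotation(annotations: list[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\tgene_name\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.chrom}\t{a.strand}\t{a.tss}\t{a.gene_name or ''}\n")


# ---------------------------------------------------------------- samples

def read_samples(path: str | Path, permissive: bool = False) -> list[SampleRecord]:
    """Read the sample design table: sample_id, patient_id, category, tissue."""
    p = _require(path)
    df = pd.read_csv(p, **_TSV)
    needed = ["sample_id", "patient_id", "category", "tissue"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{p}: missing sample columns {missing}")
    cls = PermissiveSampleRecord if permissive else SampleRecord
    records = [
        cls(str(r.sample_id), str(r.patient_id), str(r.category), str(r.tissue))
        for r in df.itertuples(index=False)
    ]
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            raise DuplicateIdError(f"duplicate sample id {r.sample_id!r} in {p}")
        seen.add(r.sample_id)
    return records


def write_samples(records: list[SampleRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tpatient_id\tcategory\ttissue\n")
        for r in records:
            fh.write(f"{r.sample_id}\t{r.patient_id}\t{r.category}\t{r.tissue}\n")


# ---------------------------------------------------------------- survival

def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read the clinical table: sample_id, time, event, age, psa, gleason, pt_stage."""
    p = _require(path)
    df = pd.read_csv(p, **_TSV)
    needed = ["sample_id", "time", "event", "age", "psa", "gleason", "pt_stage"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValidationError(f"{p}: missing survival columns {missing}")
    records = []
    for r in df.itertuples(index=False):
        gleason = None if r.gleason in ("", "NA", "nan") else int(float(r.gleason))
        records.append(
            SurvivalRecord(
                sample_id=str(r.sample_id),
                time=float(r.time),
                event=int(r.event),
                age=float(r.age),
                psa=float(r.psa),
                gleason=gleason,
                pt_stage=str(r.pt_stage),
            )
        )
    return records


def write_survival(records: list[SurvivalRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttime\tevent\tage\tpsa\tgleason\tpt_stage\n")
        for r in records:
            gs = "" if r.gleason is None else str(r.gleason)
            fh.write(
                f"{r.sample_id}\t{r.time:.6g}\t{r.event}\t{r.age:.6g}\t"
                f"{r.psa:.6g}\t{gs}\t{r.pt_stage}\n"
            )
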