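"""Core typed containers shared by every pipeline stage.

Coordinate convention: every genomic position in memory is 1-based and
inclusive at both ends.  BED files are converted at the I/O boundary
(:mod:`metscreen.io`) and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CATEGORIES = ("primary", "metastasis", "normal", "bph")
TISSUES = ("prostate", "liver", "adrenal", "bone", "subdural", "lymph_node")
PT_STAGES = ("pT2a", "pT2b", "pT3a", "pT3b")


class MetscreenError(Exception):
    """Base class for all package errors."""


class ValidationError(MetscreenError):
    """An input violated a documented invariant."""


class DuplicateIdError(ValidationError):
    """A gene or sample identifier occurred more than once."""


class NegativeCountError(ValidationError):
    """A count cell was negative."""


class NonIntegerCountError(ValidationError):
    """A count cell was not an integer."""


class BedParseError(ValidationError):
    """A BED line could not be parsed or described an empty interval."""


class ConfigurationError(MetscreenError):
    """The sample design cannot support the requested analysis."""


class NormalizationError(MetscreenError):
    """Median-of-ratios normalization is undefined for this matrix."""


class DegenerateStratificationError(MetscreenError):
    """Expression values cannot be split into non-empty high/low groups."""


class UndefinedTestError(MetscreenError):
    """A survival test is undefined (e.g. zero events)."""


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene reduced to the fields the pipeline needs: id, TSS, strand."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.tss < 1:
            raise ValidationError(f"gene {self.gene_id!r}: tss must be >= 1, got {self.tss}")


@dataclass(frozen=True)
class GenomicInterval:
    """1-based, both-ends-inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} violates 1 <= start <= end"
            )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) <= min(self.end, other.end)
        )


@dataclass
class PeakSet:
    """A named collection of ChIP-seq peaks for one TF under one condition."""

    tf_name: str
    condition: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class SampleRecord:
    """Design metadata for one RNA-seq library.

    Category/tissue consistency is enforced: prostate-derived categories
    (primary, bph) must sit in prostate tissue, while normals and
    metastases are by definition non-prostate in this design.
    """

    sample_id: str
    patient_id: str
    category: str
    tissue: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown category {self.category!r}"
            )
        if self.tissue not in TISSUES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown tissue {self.tissue!r} "
                "(pass permissive=True to accept)"
            )
        self._check_consistency()

    def _check_consistency(self) -> None:
        if self.category in ("primary", "bph") and self.tissue != "prostate":
            raise ValidationError(
                f"sample {self.sample_id!r}: category {self.category!r} requires prostate tissue"
            )
        if self.category in ("normal", "metastasis") and self.tissue == "prostate":
            raise ValidationError(
                f"sample {self.sample_id!r}: category {self.category!r} must be non-prostate"
            )


@dataclass(frozen=True)
class PermissiveSampleRecord(SampleRecord):
    """Sample record accepting tissue labels outside the closed vocabulary."""

    def __post_init__(self) -> None:  # noqa: D105
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown category {self.category!r}"
            )
        if self.tissue in TISSUES:
            self._check_consistency()


@dataclass(frozen=True)
class SurvivalRecord:
    """One patient's follow-up plus the clinical covariates of the Cox model."""

    sample_id: str
    time: float  # months of follow-up
    event: int  # 1 = biochemical recurrence, 0 = censored
    age: float  # years at diagnosis
    psa: float  # ng/mL at diagnosis
    gleason: int | None  # None = missing, record excluded from Cox
    pt_stage: str

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(f"sample {self.sample_id!r}: time must be > 0")
        if self.event not in (0, 1):
            raise ValidationError(f"sample {self.sample_id!r}: event must be 0 or 1")
        if self.psa < 0:
            raise ValidationError(f"sample {self.sample_id!r}: psa must be >= 0")
        if self.pt_stage not in PT_STAGES:
            raise ValidationError(
                f"sample {self.sample_id!r}: unmappable pT label {self.pt_stage!r}"
            )


class CountMatrix:
    """Genes x samples matrix of non-negative integer RNA-seq counts.

    Thin wrapper over a numpy integer array with ordered, unique gene and
    sample identifiers; the substrate of every downstream contrast.
    """

    def __init__(self, gene_ids, sample_ids, counts) -> None:
        gene_ids = list(gene_ids)
        sample_ids = list(sample_ids)
        counts = np.asarray(counts)
        if counts.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                bad = np.argwhere(counts != np.floor(counts))
                g, s = bad[0]
                raise NonIntegerCountError(
                    f"non-integer count {counts[g, s]!r} for gene "
                    f"{gene_ids[g]!r}, sample {sample_ids[s]!r}"
                )
        if (counts < 0).any():
            g, s = np.argwhere(counts < 0)[0]
            raise NegativeCountError(
                f"negative count {counts[g, s]} for gene {gene_ids[g]!r}, "
                f"sample {sample_ids[s]!r}"
            )
        for label, ids in (("gene", gene_ids), ("sample", sample_ids)):
            seen: set[str] = set()
            for x in ids:
                if x in seen:
                    raise DuplicateIdError(f"duplicate {label} id {x!r}")
                seen.add(x)
        self.gene_ids = gene_ids
        self.sample_ids = sample_ids
        self.counts = counts.astype(np.int64)
        self._gene_index = {g: i for i, g in enumerate(gene_ids)}
        self._sample_index = {s: j for j, s in enumerate(sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_columns(self, sample_ids) -> np.ndarray:
        """Column indices for the given sample ids, in the given order."""
        try:
            return np.array([self._sample_index[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown sample id {exc.args[0]!r}") from None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"CountMatrix({self.shape[0]} genes x {self.shape[1]} samples)"


def validate_annotation(annotations: list[GeneAnnotation]) -> None:
    """Raise if gene ids repeat within an annotation set."""
    seen: set[str] = set()
    for a in annotations:
        if a.gene_id in seen:
            raise DuplicateIdError(f"duplicate gene_id {a.gene_id!r} in annotation")
        seen.add(a.gene_id)
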