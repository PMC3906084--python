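"""Core domain objects: a called SNV and its strand-resolved read evidence.

A :class:`VariantRecord` is one biallelic single-nucleotide variant call
together with the quality metrics the two supported callers emit:

* total read depth (``td``, VCF INFO ``DP``),
* Phred-scaled variant quality (``snpq``, the VCF ``QUAL`` column),
* RMS mapping quality (``mq``, INFO ``MQ``),
* genotype quality of the called sample (``gq``, FORMAT ``GQ``),
* strand evidence — either the four ``DP4``-style counts (mpileup dialect)
  or a caller-emitted strand-bias score (UnifiedGenotyper dialect ``SB``),
* an optional Sanger-validation outcome.

Records are keyed by ``(chrom, pos, ref, alt)`` for all joins between call
sets; coordinates are 1-based as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace  # noqa: F401  (replace re-exported)
from enum import Enum
from typing import Optional, Tuple

__all__ = [
    "Caller",
    "Pipeline",
    "Validation",
    "StrandCounts",
    "VariantRecord",
    "VALID_BASES",
]

VALID_BASES = frozenset("ACGT")


class Caller(str, Enum):
    """Which variant caller produced the record."""

    SAMTOOLS = "samtools"
    GATK = "gatk"


class Pipeline(str, Enum):
    """Upstream alignment post-processing: plain BWA mapping vs. indel
    realignment + base-quality recalibration. Consumed as provenance only."""

    BASIC = "basic"
    RECALIBRATED = "recalibrated"


class Validation(str, Enum):
    """Sanger-sequencing outcome for the call (gold standard)."""

    VALIDATED = "validated"
    FAILED = "failed"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class StrandCounts:
    """The four strand-resolved read counts behind a call (DP4 order:
    reference-forward, reference-reverse, alternate-forward,
    alternate-reverse)."""

    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int

    def __post_init__(self) -> None:
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"StrandCounts.{name} must be a non-negative int, got {v!r}")

    @property
    def alt_total(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def total(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev


@dataclass
class VariantRecord:
    """One biallelic SNV call with caller provenance and quality metrics."""

    chrom: str
    pos: int
    ref: str
    alt: str
    caller: Caller
    pipeline: Pipeline = Pipeline.BASIC
    td: int = 0
    snpq: float = 0.0
    mq: Optional[float] = None
    gq: Optional[float] = None
    strand: Optional[StrandCounts] = None
    sb_score: Optional[float] = None
    validation: Validation = Validation.UNKNOWN

    def __post_init__(self) -> None:
        self.caller = Caller(self.caller)
        self.pipeline = Pipeline(self.pipeline)
        self.validation = Validation(self.validation)
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref not in VALID_BASES or self.alt not in VALID_BASES:
            raise ValueError(f"ref/alt must be single bases in ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.td < 0:
            raise ValueError(f"td must be >= 0, got {self.td}")
        if self.snpq < 0:
            raise ValueError(f"snpq must be >= 0, got {self.snpq}")
        if self.gq is not None and self.gq < 0:
            raise ValueError(f"gq must be >= 0 when present, got {self.gq}")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Join key: (chrom, pos, ref, alt)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_labeled(self) -> bool:
        return self.validation is not Validation.UNKNOWN
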