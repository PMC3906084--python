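"""Depth/quality category grids and derived per-variant metrics.

The calibration analysis stratifies SNV calls on a 5 x 9 grid: five total-
read-depth (TD) bins shared by both callers and nine caller-specific
variant-quality (SNPQ) bins. All bins are half-open, lower edge inclusive
(``a <= x < b``); the first bin is ``x < e0`` and the last is unbounded
above. The default edges are frozen to the values used in the original
calibration study and are regression-tested; custom edges may be supplied
for other data.

The strand-bias metric differs by caller: for mpileup-dialect calls it is
the alternate-allele-forward percentage AF% = 100 * alt_fwd / (alt_fwd +
alt_rev) computed from DP4 counts, and for UnifiedGenotyper-dialect calls
it is the caller-emitted SB score (more negative = less biased).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import yaml

from .errors import UndefinedMetricError, UsageError
from .records import Caller, StrandCounts, VariantRecord

__all__ = [
    "CategoryScheme",
    "CellIndex",
    "TD_EDGES",
    "SAMTOOLS_SNPQ_EDGES",
    "GATK_SNPQ_EDGES",
    "default_scheme",
    "assign_category",
    "compute_af_percent",
    "strand_bias_value",
    "metric_value",
    "METRIC_NAMES",
]

#: Depth breakpoints shared by both callers: TD<5, 5-10, 10-20, 20-40, 40+.
TD_EDGES: Tuple[float, ...] = (5.0, 10.0, 20.0, 40.0)

#: mpileup-dialect quality breakpoints (QUAL scale tops out near a few hundred).
SAMTOOLS_SNPQ_EDGES: Tuple[float, ...] = (10.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0, 200.0)

#: UnifiedGenotyper-dialect quality breakpoints (QUAL scale roughly 3x higher).
GATK_SNPQ_EDGES: Tuple[float, ...] = (20.0, 50.0, 100.0, 150.0, 200.0, 300.0, 500.0, 1000.0)


def _format_labels(edges: Sequence[float], symbol: str) -> Tuple[str, ...]:
    def fmt(e: float) -> str:
        return f"{int(e)}" if float(e).is_integer() else f"{e:g}"

    labels = [f"{symbol}<{fmt(edges[0])}"]
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{fmt(lo)}<={symbol}<{fmt(hi)}")
    labels.append(f"{fmt(edges[-1])}<={symbol}")
    return tuple(labels)


@dataclass(frozen=True)
class CellIndex:
    """0-based position of a variant in the SNPQ x TD grid."""

    snpq_bin: int
    td_bin: int


@dataclass(frozen=True)
class CategoryScheme:
    """Bin edges defining the TD x SNPQ grid for one caller.

    ``td_edges`` and ``snpq_edges`` are strictly increasing breakpoints;
    ``k`` edges define ``k + 1`` half-open bins partitioning ``[0, inf)``.
    """

    td_edges: Tuple[float, ...] = TD_EDGES
    snpq_edges: Tuple[float, ...] = SAMTOOLS_SNPQ_EDGES

    def __post_init__(self) -> None:
        for name in ("td_edges", "snpq_edges"):
            edges = tuple(float(e) for e in getattr(self, name))
            object.__setattr__(self, name, edges)
            if len(edges) == 0:
                raise ValueError(f"{name} must not be empty")
            if any(b <= a for a, b in zip(edges[:-1], edges[1:])):
                raise ValueError(f"{name} must be strictly increasing, got {edges}")
            if edges[0] <= 0:
                raise ValueError(f"{name} must start above 0, got {edges}")

    @property
    def n_td_bins(self) -> int:
        return len(self.td_edges) + 1

    @property
    def n_snpq_bins(self) -> int:
        return len(self.snpq_edges) + 1

    @property
    def td_labels(self) -> Tuple[str, ...]:
        return _format_labels(self.td_edges, "TD")

    @property
    def snpq_labels(self) -> Tuple[str, ...]:
        return _format_labels(self.snpq_edges, "SNPQ")

    def td_bin(self, td: float) -> int:
        if td < 0:
            raise ValueError(f"td must be >= 0, got {td}")
        return int(np.searchsorted(self.td_edges, td, side="right"))

    def snpq_bin(self, snpq: float) -> int:
        if snpq < 0:
            raise ValueError(f"snpq must be >= 0, got {snpq}")
        return int(np.searchsorted(self.snpq_edges, snpq, side="right"))

    # -- serialization ----------------------------------------------------

    def to_dict(self, caller: Optional[str] = None) -> Dict:
        d: Dict = {"td_edges": list(self.td_edges), "snpq_edges": list(self.snpq_edges)}
        if caller is not None:
            d["caller"] = str(Caller(caller).value)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "CategoryScheme":
        if "td_edges" in d or "snpq_edges" in d:
            kwargs = {}
            if "td_edges" in d:
                kwargs["td_edges"] = tuple(d["td_edges"])
            if "snpq_edges" in d:
                kwargs["snpq_edges"] = tuple(d["snpq_edges"])
            base = default_scheme(d["caller"]) if "caller" in d else cls()
            return cls(
                td_edges=kwargs.get("td_edges", base.td_edges),
                snpq_edges=kwargs.get("snpq_edges", base.snpq_edges),
            )
        if "caller" in d:
            return default_scheme(d["caller"])
        raise UsageError("scheme config must give 'caller' and/or explicit edges")

    def save(self, path, caller: Optional[str] = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(caller=caller), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CategoryScheme":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_scheme(caller: Union[Caller, str]) -> CategoryScheme:
    """The frozen default TD x SNPQ grid for one caller dialect."""
    caller = Caller(caller)
    snpq = SAMTOOLS_SNPQ_EDGES if caller is Caller.SAMTOOLS else GATK_SNPQ_EDGES
    return CategoryScheme(td_edges=TD_EDGES, snpq_edges=snpq)


def assign_category(td: float, snpq: float, scheme: CategoryScheme) -> CellIndex:
    """Place a (depth, quality) pair on the grid.

    Binning is half-open with the lower edge inclusive: ``v`` falls in bin
    ``i`` iff ``edge[i-1] <= v < edge[i]`` (``edge[-1] = 0``,
    ``edge[last] = inf``). Raises ``ValueError`` on negative inputs.
    """
    return CellIndex(snpq_bin=scheme.snpq_bin(snpq), td_bin=scheme.td_bin(td))


def compute_af_percent(strand: StrandCounts) -> float:
    """Alternate-allele-forward percentage: 100 * alt_fwd / (alt_fwd + alt_rev).

    The denominator counts alternate-supporting reads only. Undefined (and
    raised as :class:`UndefinedMetricError`) when no read supports the
    alternate allele — such a record cannot be strand-bias-filtered.
    """
    n = strand.alt_total
    if n < 1:
        raise UndefinedMetricError("AF% undefined: zero alternate-supporting reads")
    return 100.0 * strand.alt_fwd / n


def strand_bias_value(record: VariantRecord) -> Tuple[str, float]:
    """The caller-appropriate strand-bias metric for one record.

    mpileup-dialect records yield ``("AF_percent", AF%)`` from their DP4
    counts; UnifiedGenotyper-dialect records yield ``("SB", sb_score)``
    pass-through. The returned name disambiguates filter semantics (AF% is
    windowed, SB is thresholded below).
    """
    if record.caller is Caller.SAMTOOLS:
        if record.strand is None:
            raise UndefinedMetricError(
                f"strand bias undefined for {record.chrom}:{record.pos}: "
                "mpileup-dialect record lacks DP4 strand counts"
            )
        return ("AF_percent", compute_af_percent(record.strand))
    if record.sb_score is None:
        raise UndefinedMetricError(
            f"strand bias undefined for {record.chrom}:{record.pos}: "
            "UnifiedGenotyper-dialect record lacks SB score"
        )
    return ("SB", float(record.sb_score))


#: Metric identifiers accepted by :func:`metric_value`, profile and filter code.
METRIC_NAMES = ("snpq", "td", "mq", "gq", "af_percent", "sb")


def metric_value(record: VariantRecord, metric: str) -> Optional[float]:
    """Value of a named metric for one record, or None where undefined.

    Accepted names (case-insensitive): snpq, td, mq, gq, af_percent, sb.
    ``af_percent`` is defined only for mpileup-dialect records with at least
    one alternate-supporting read; ``sb`` only for UnifiedGenotyper-dialect
    records carrying an SB score.
    """
    m = metric.lower()
    if m == "snpq":
        return float(record.snpq)
    if m == "td":
        return float(record.td)
    if m == "mq":
        return None if record.mq is None else float(record.mq)
    if m == "gq":
        return None if record.gq is None else float(record.gq)
    if m == "af_percent":
        if record.caller is not Caller.SAMTOOLS or record.strand is None:
            return None
        if record.strand.alt_total < 1:
            return None
        return compute_af_percent(record.strand)
    if m == "sb":
        if record.caller is not Caller.GATK or record.sb_score is None:
            return None
        return float(record.sb_score)
    raise UsageError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
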