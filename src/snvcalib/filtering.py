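"""Caller-concordance partitioning, hard filters, and cutoff derivation.

Three related capabilities live here:

* :func:`partition_by_caller` splits two call sets into common vs
  caller-specific variants on the allele-aware key (chrom, pos, ref, alt),
  and :func:`partition_rates` compares their validation rates (common
  variants validate far better than caller-specific ones).
* :class:`FilterSpec` expresses a hard filter as a conjunction of
  threshold predicates over per-variant metrics; :func:`recommended_filter`
  returns the calibrated per-caller presets (SNPQ >= 40 / >= 300,
  MQ > 58, and strand bias 20 <= AF% < 80 / SB < -10), and
  :func:`apply_filter` evaluates a spec against a cohort, reporting the
  validation rate before and after.
* :func:`scan_cutoff` derives a quality cutoff from a cross-tab or metric
  profile: the smallest bin edge above which every bin (binwise mode) or
  the pooled aggregate (cumulative mode) meets a target validation rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import yaml

from .errors import DuplicateSiteError, UsageError
from .records import Caller, Validation, VariantRecord
from .rates import CrossTab, MetricProfile, RateEstimate, marginal_rates
from .strata import METRIC_NAMES, metric_value

__all__ = [
    "Conjunct",
    "FilterSpec",
    "FilterResult",
    "CommonVariant",
    "CallerPartition",
    "CutoffReport",
    "recommended_filter",
    "get_preset",
    "PRESET_NAMES",
    "apply_filter",
    "partition_by_caller",
    "partition_rates",
    "scan_cutoff",
]

_OPS = ("lt", "le", "gt", "ge", "window")


@dataclass(frozen=True)
class Conjunct:
    """One threshold predicate: metric OP threshold.

    ``op`` is one of lt/le/gt/ge, or ``window`` with a (low, high) pair
    meaning the half-open interval ``low <= value < high``.
    """

    metric: str
    op: str
    threshold: Union[float, Tuple[float, float]]

    def __post_init__(self) -> None:
        if self.metric.lower() not in METRIC_NAMES:
            raise UsageError(f"unknown metric {self.metric!r}; expected one of {METRIC_NAMES}")
        object.__setattr__(self, "metric", self.metric.lower())
        if self.op not in _OPS:
            raise UsageError(f"unknown comparator {self.op!r}; expected one of {_OPS}")
        if self.op == "window":
            lo, hi = self.threshold  # type: ignore[misc]
            if not lo < hi:
                raise UsageError(f"window threshold must satisfy low < high, got {self.threshold}")
            object.__setattr__(self, "threshold", (float(lo), float(hi)))
        else:
            object.__setattr__(self, "threshold", float(self.threshold))  # type: ignore[arg-type]

    def test(self, value: float) -> bool:
        if self.op == "lt":
            return value < self.threshold
        if self.op == "le":
            return value <= self.threshold
        if self.op == "gt":
            return value > self.threshold
        if self.op == "ge":
            return value >= self.threshold
        lo, hi = self.threshold  # window
        return lo <= value < hi

    def describe(self) -> str:
        if self.op == "window":
            lo, hi = self.threshold
            return f"{lo:g}<={self.metric}<{hi:g}"
        sym = {"lt": "<", "le": "<=", "gt": ">", "ge": ">="}[self.op]
        return f"{self.metric}{sym}{self.threshold:g}"


@dataclass(frozen=True)
class FilterSpec:
    """A conjunction of threshold predicates (a hard filter).

    A record is retained iff every conjunct holds. ``on_undefined``
    controls records for which a needed metric is undefined: ``fail``
    (default — conservative, the calibrated presets demand strand evidence
    for every retained call), ``pass``, or ``error``. ``caller``, when
    set, names which caller's metrics to use on merged common variants.
    """

    conjuncts: Tuple[Conjunct, ...] = ()
    on_undefined: str = "fail"
    caller: Optional[Caller] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "conjuncts", tuple(self.conjuncts))
        if self.on_undefined not in ("fail", "pass", "error"):
            raise UsageError(f"on_undefined must be fail/pass/error, got {self.on_undefined!r}")
        if self.caller is not None:
            object.__setattr__(self, "caller", Caller(self.caller))

    def evaluate(self, record: "VariantRecord | CommonVariant") -> Tuple[bool, bool]:
        """(retained, any_metric_undefined) for one record."""
        rec = record.for_caller(self.caller) if isinstance(record, CommonVariant) else record
        undefined = False
        retained = True
        for c in self.conjuncts:
            v = metric_value(rec, c.metric)
            if v is None:
                undefined = True
                if self.on_undefined == "error":
                    raise UsageError(
                        f"metric {c.metric!r} undefined for record {rec.chrom}:{rec.pos} "
                        "and on_undefined='error'"
                    )
                if self.on_undefined == "fail":
                    retained = False
                continue
            if not c.test(v):
                retained = False
        return retained, undefined

    def with_conjunct(self, conjunct: Conjunct) -> "FilterSpec":
        return FilterSpec(self.conjuncts + (conjunct,), self.on_undefined, self.caller)

    def describe(self) -> str:
        return " AND ".join(c.describe() for c in self.conjuncts) or "<no filter>"

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> Dict:
        return {
            "conjuncts": [
                {"metric": c.metric, "op": c.op, "threshold": list(c.threshold) if c.op == "window" else c.threshold}
                for c in self.conjuncts
            ],
            "on_undefined": self.on_undefined,
            "caller": None if self.caller is None else self.caller.value,
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "FilterSpec":
        conjuncts = tuple(
            Conjunct(c["metric"], c["op"], tuple(c["threshold"]) if c["op"] == "window" else c["threshold"])
            for c in d.get("conjuncts", [])
        )
        return cls(conjuncts, d.get("on_undefined", "fail"), d.get("caller"))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "FilterSpec":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def recommended_filter(caller: Union[Caller, str], *, strict_snpq: bool = False,
                       strict_mq: bool = True) -> FilterSpec:
    """The calibrated per-caller hard filter.

    mpileup dialect: SNPQ >= 40, MQ > 58, 20 <= AF% < 80.
    UnifiedGenotyper dialect: SNPQ >= 300, MQ > 58, SB < -10.

    The quality conjunct uses >= so that it coincides with the grid edges
    used when pooling cells above a cutoff; ``strict_snpq=True`` switches
    it to a strict >. ``strict_mq=False`` relaxes MQ > 58 to >=. Undefined
    metrics fail the filter.
    """
    caller = Caller(caller)
    q_op = "gt" if strict_snpq else "ge"
    mq_op = "gt" if strict_mq else "ge"
    if caller is Caller.SAMTOOLS:
        conjuncts = (
            Conjunct("snpq", q_op, 40),
            Conjunct("mq", mq_op, 58),
            Conjunct("af_percent", "window", (20, 80)),
        )
    else:
        conjuncts = (
            Conjunct("snpq", q_op, 300),
            Conjunct("mq", mq_op, 58),
            Conjunct("sb", "lt", -10),
        )
    return FilterSpec(conjuncts, on_undefined="fail", caller=caller)


PRESET_NAMES = ("recommended-samtools", "recommended-gatk")


def get_preset(name: str) -> FilterSpec:
    """Look up a named filter preset (see :data:`PRESET_NAMES`)."""
    if name == "recommended-samtools":
        return recommended_filter(Caller.SAMTOOLS)
    if name == "recommended-gatk":
        return recommended_filter(Caller.GATK)
    raise UsageError(f"unknown preset {name!r}; available: {PRESET_NAMES}")


@dataclass
class FilterResult:
    """Outcome of applying one hard filter to a cohort."""

    spec: FilterSpec
    retained: List[VariantRecord]
    n_before: int
    n_after: int
    rate_before: RateEstimate
    rate_after: RateEstimate
    undefined_metric_count: int

    @property
    def retained_fraction(self) -> Optional[float]:
        return None if self.n_before == 0 else self.n_after / self.n_before


def _labeled_counts(records: Iterable[VariantRecord], confidence: float) -> RateEstimate:
    k = n = 0
    for r in records:
        if r.validation is Validation.UNKNOWN:
            continue
        n += 1
        if r.validation is Validation.VALIDATED:
            k += 1
    return RateEstimate(k, n, confidence)


def apply_filter(
    records: Sequence["VariantRecord | CommonVariant"],
    spec: FilterSpec,
    confidence: float = 0.95,
) -> FilterResult:
    """Evaluate a hard filter over a cohort.

    Returns the retained records plus before/after validation rates over
    the labeled subset (records with an unknown outcome never enter the
    rates). An empty spec is the identity filter.
    """
    retained: List[VariantRecord] = []
    undefined = 0
    flat_before: List[VariantRecord] = []
    for rec in records:
        keep, undef = spec.evaluate(rec)
        base = rec.for_caller(spec.caller) if isinstance(rec, CommonVariant) else rec
        flat_before.append(base)
        undefined += int(undef)
        if keep:
            retained.append(base)
    return FilterResult(
        spec=spec,
        retained=retained,
        n_before=len(flat_before),
        n_after=len(retained),
        rate_before=_labeled_counts(flat_before, confidence),
        rate_after=_labeled_counts(retained, confidence),
        undefined_metric_count=undefined,
    )


# -- caller concordance --------------------------------------------------


@dataclass(frozen=True)
class CommonVariant:
    """A variant called by both callers: one record per caller, same key."""

    samtools: VariantRecord
    gatk: VariantRecord

    def __post_init__(self) -> None:
        if self.samtools.key != self.gatk.key:
            raise ValueError("merged records must share (chrom, pos, ref, alt)")

    @property
    def key(self):
        return self.samtools.key

    @property
    def validation(self) -> Validation:
        """Sanger outcome; per-caller labels agree for a real dataset, and
        a known label wins over unknown."""
        if self.samtools.validation is not Validation.UNKNOWN:
            return self.samtools.validation
        return self.gatk.validation

    def for_caller(self, caller: Optional[Caller]) -> VariantRecord:
        """The member record whose metrics a caller-specific filter uses."""
        if caller is None or Caller(caller) is Caller.SAMTOOLS:
            return self.samtools
        return self.gatk


@dataclass
class CallerPartition:
    """Common vs caller-specific split of two call sets (allele-aware)."""

    common: List[CommonVariant]
    only_a: List[VariantRecord]
    only_b: List[VariantRecord]

    @property
    def n_keys(self) -> int:
        return len(self.common) + len(self.only_a) + len(self.only_b)


def _index_by_key(records: Sequence[VariantRecord]) -> Dict[tuple, VariantRecord]:
    index: Dict[tuple, VariantRecord] = {}
    dups = []
    for rec in records:
        if rec.key in index:
            dups.append(rec.key)
        index[rec.key] = rec
    if dups:
        raise DuplicateSiteError(dups)
    return index


def partition_by_caller(
    records_a: Sequence[VariantRecord], records_b: Sequence[VariantRecord]
) -> CallerPartition:
    """Split two call sets into common and caller-specific variants.

    Keys are allele-aware: chr1:100 A>G and chr1:100 A>T are different
    variants. Common pairs are merged keeping both callers' metrics.
    Duplicate keys within one input raise :class:`DuplicateSiteError`.
    """
    ia, ib = _index_by_key(records_a), _index_by_key(records_b)
    common: List[CommonVariant] = []
    only_a = [ia[k] for k in ia if k not in ib]
    only_b = [ib[k] for k in ib if k not in ia]
    for k in ia:
        if k in ib:
            a, b = ia[k], ib[k]
            if a.caller is Caller.SAMTOOLS:
                common.append(CommonVariant(samtools=a, gatk=b))
            else:
                common.append(CommonVariant(samtools=b, gatk=a))
    return CallerPartition(common=common, only_a=only_a, only_b=only_b)


def partition_rates(
    partition: CallerPartition, confidence: float = 0.95
) -> Tuple[RateEstimate, RateEstimate]:
    """(common, caller-specific) validation rates; the specific estimate
    pools both callers' unique variants."""
    ck = cn = 0
    for cv in partition.common:
        if cv.validation is Validation.UNKNOWN:
            continue
        cn += 1
        ck += int(cv.validation is Validation.VALIDATED)
    specific = _labeled_counts(list(partition.only_a) + list(partition.only_b), confidence)
    return RateEstimate(ck, cn, confidence), specific


# -- cutoff derivation ---------------------------------------------------


@dataclass
class CutoffReport:
    """Result of a threshold scan along a binned metric.

    ``chosen_threshold`` is the minimal candidate bin edge meeting the
    mode's criterion, or None if no edge qualifies. ``table`` pairs each
    candidate with the rate estimate the mode evaluated there (binwise:
    the worst bin at/above the edge is what decided; the tabulated
    estimate is the pooled rate at/above for context in both modes).
    """

    metric_name: str
    mode: str
    target_rate: float
    chosen_threshold: Optional[float]
    table: List[Tuple[float, RateEstimate]]


def _bins_from_input(tab_or_profile: Union[CrossTab, MetricProfile]):
    """Normalize to (metric_name, lower_edges, estimates)."""
    if isinstance(tab_or_profile, CrossTab):
        lower = (0.0,) + tab_or_profile.scheme.snpq_edges
        return "snpq", lower, marginal_rates(tab_or_profile, "snpq")
    if isinstance(tab_or_profile, MetricProfile):
        return tab_or_profile.metric_name, tab_or_profile.lower_edges, tab_or_profile.estimates
    raise UsageError("scan_cutoff expects a CrossTab or MetricProfile")


def scan_cutoff(
    tab_or_profile: Union[CrossTab, MetricProfile],
    target_rate: float,
    mode: str = "binwise",
    confidence: float = 0.95,
) -> CutoffReport:
    """Find the smallest bin-edge cutoff achieving a target validation rate.

    Candidates are the bin lower edges. In ``binwise`` mode the chosen
    threshold is the minimal edge t such that every non-empty bin whose
    lower edge is >= t has rate >= target (empty bins are skipped). In
    ``cumulative`` mode it is the minimal edge t such that the pooled rate
    over all bins at/above t is >= target. A CrossTab input scans its SNPQ
    marginals.
    """
    if not (0 < target_rate < 1):
        raise UsageError(f"target_rate must be in (0, 1), got {target_rate}")
    if mode not in ("binwise", "cumulative"):
        raise UsageError(f"mode must be 'binwise' or 'cumulative', got {mode!r}")
    metric, lower, ests = _bins_from_input(tab_or_profile)
    chosen: Optional[float] = None
    table: List[Tuple[float, RateEstimate]] = []
    for i, t in enumerate(lower):
        pooled = RateEstimate(
            sum(e.validated for e in ests[i:]), sum(e.total for e in ests[i:]), confidence
        )
        table.append((t, pooled))
        if chosen is not None:
            continue
        if mode == "binwise":
            ok = all(e.total == 0 or e.rate >= target_rate for e in ests[i:])
            ok = ok and any(e.total > 0 for e in ests[i:])
        else:
            ok = pooled.total > 0 and pooled.rate >= target_rate
        if ok:
            chosen = t
    return CutoffReport(
        metric_name=metric, mode=mode, target_rate=target_rate,
        chosen_threshold=chosen, table=table,
    )
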