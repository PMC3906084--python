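"""Validation-rate cross-tabulation and uncertainty.

Builds the TD x SNPQ cross-tab of Sanger outcomes (the in-memory form of
the study's per-pipeline validation table), computes marginal and pooled
rates with Clopper-Pearson exact binomial confidence intervals, and
profiles the validation rate against any per-variant metric.

Rates are stored as proportions; percentage formatting with one decimal
("63.5%") happens only at the reporting layer. Empty cells render as
"0/0 (-)". Clopper-Pearson is used throughout because many grid cells hold
fewer than ten variants, where Wald/Wilson intervals misbehave.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyProfileError, UndefinedMetricError, UsageError
from .records import Validation, VariantRecord
from .strata import CategoryScheme, CellIndex, assign_category, metric_value

__all__ = [
    "RateEstimate",
    "CrossTab",
    "MetricProfile",
    "binomial_ci",
    "crosstab",
    "overall_rate",
    "marginal_rates",
    "aggregate_above",
    "profile_rate_by_metric",
    "render_crosstab",
    "crosstab_to_tidy",
]


def binomial_ci(validated: int, total: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval for k/n.

    Boundary conventions: k=0 forces the lower bound to 0; k=n forces the
    upper bound to 1. ``total == 0`` raises :class:`UndefinedMetricError`.
    """
    if not (0 < confidence < 1):
        raise UsageError(f"confidence must be in (0, 1), got {confidence}")
    if total == 0:
        raise UndefinedMetricError("confidence interval undefined for total=0")
    if not (0 <= validated <= total):
        raise UsageError(f"need 0 <= validated <= total, got {validated}/{total}")
    alpha = 1.0 - confidence
    low = 0.0 if validated == 0 else float(stats.beta.ppf(alpha / 2, validated, total - validated + 1))
    high = 1.0 if validated == total else float(stats.beta.ppf(1 - alpha / 2, validated + 1, total - validated))
    return (low, high)


@dataclass(frozen=True)
class RateEstimate:
    """A validated/total count pair with its exact binomial interval."""

    validated: int
    total: int
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.total < 0 or not (0 <= self.validated <= max(self.total, 0)):
            raise ValueError(f"need 0 <= validated <= total, got {self.validated}/{self.total}")

    @property
    def rate(self) -> Optional[float]:
        """Proportion validated, or None for an empty denominator."""
        return None if self.total == 0 else self.validated / self.total

    @property
    def ci(self) -> Optional[Tuple[float, float]]:
        if self.total == 0:
            return None
        return binomial_ci(self.validated, self.total, self.confidence)

    @property
    def percent(self) -> Optional[float]:
        r = self.rate
        return None if r is None else 100.0 * r

    def __str__(self) -> str:
        if self.total == 0:
            return "0/0 (-)"
        return f"{self.validated}/{self.total} ({self.percent:.1f}%)"

    def __add__(self, other: "RateEstimate") -> "RateEstimate":
        return RateEstimate(self.validated + other.validated, self.total + other.total, self.confidence)


@dataclass
class CrossTab:
    """Per-cell (validated, total) counts on a TD x SNPQ grid.

    ``validated`` and ``total`` are integer arrays of shape
    (n_snpq_bins, n_td_bins); marginals are always recomputed, never
    stored. ``n_unknown`` counts labeled-input records excluded for
    carrying an unknown validation outcome.
    """

    scheme: CategoryScheme
    validated: np.ndarray
    total: np.ndarray
    n_unknown: int = 0

    def __post_init__(self) -> None:
        shape = (self.scheme.n_snpq_bins, self.scheme.n_td_bins)
        self.validated = np.asarray(self.validated, dtype=int)
        self.total = np.asarray(self.total, dtype=int)
        if self.validated.shape != shape or self.total.shape != shape:
            raise ValueError(f"cell arrays must have shape {shape}")
        if (self.validated < 0).any() or (self.total < 0).any():
            raise ValueError("cell counts must be non-negative")
        if (self.validated > self.total).any():
            raise ValueError("validated must not exceed total in any cell")

    @classmethod
    def empty(cls, scheme: CategoryScheme) -> "CrossTab":
        shape = (scheme.n_snpq_bins, scheme.n_td_bins)
        return cls(scheme, np.zeros(shape, dtype=int), np.zeros(shape, dtype=int))

    def cell(self, index: CellIndex, confidence: float = 0.95) -> RateEstimate:
        return RateEstimate(
            int(self.validated[index.snpq_bin, index.td_bin]),
            int(self.total[index.snpq_bin, index.td_bin]),
            confidence,
        )

    @property
    def n_total(self) -> int:
        return int(self.total.sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CrossTab):
            return NotImplemented
        return (
            self.scheme == other.scheme
            and np.array_equal(self.validated, other.validated)
            and np.array_equal(self.total, other.total)
        )


def crosstab(records: Iterable[VariantRecord], scheme: CategoryScheme) -> CrossTab:
    """Cross-tabulate Sanger outcomes over the TD x SNPQ grid.

    Records with ``validation == unknown`` are excluded from the counts and
    tallied in ``n_unknown`` — never silently dropped. An empty input gives
    an all-zero cross-tab, not an error.
    """
    tab = CrossTab.empty(scheme)
    for rec in records:
        if rec.validation is Validation.UNKNOWN:
            tab.n_unknown += 1
            continue
        cell = assign_category(rec.td, rec.snpq, scheme)
        tab.total[cell.snpq_bin, cell.td_bin] += 1
        if rec.validation is Validation.VALIDATED:
            tab.validated[cell.snpq_bin, cell.td_bin] += 1
    return tab


def overall_rate(tab: CrossTab, confidence: float = 0.95) -> RateEstimate:
    """Pooled validated/total over every cell (the grand-total rate)."""
    return RateEstimate(int(tab.validated.sum()), int(tab.total.sum()), confidence)


def marginal_rates(tab: CrossTab, axis: str, confidence: float = 0.95) -> List[RateEstimate]:
    """Per-bin rates along one axis, summed across the other.

    ``axis="snpq"`` gives one estimate per SNPQ bin (rows), ``axis="td"``
    one per depth bin (columns).
    """
    if axis == "snpq":
        v, t = tab.validated.sum(axis=1), tab.total.sum(axis=1)
    elif axis == "td":
        v, t = tab.validated.sum(axis=0), tab.total.sum(axis=0)
    else:
        raise UsageError(f"axis must be 'snpq' or 'td', got {axis!r}")
    return [RateEstimate(int(k), int(n), confidence) for k, n in zip(v, t)]


def aggregate_above(tab: CrossTab, snpq_min: float, confidence: float = 0.95) -> RateEstimate:
    """Pooled rate over all cells whose SNPQ bin starts at or above a cutoff.

    ``snpq_min`` must coincide with a scheme edge (0 selects everything);
    anything else would split printed cells and raises :class:`UsageError`.
    """
    edges = (0.0,) + tab.scheme.snpq_edges
    if float(snpq_min) not in edges:
        raise UsageError(f"snpq_min must be one of the scheme edges {edges}, got {snpq_min}")
    first = edges.index(float(snpq_min))
    return RateEstimate(
        int(tab.validated[first:, :].sum()), int(tab.total[first:, :].sum()), confidence
    )


@dataclass
class MetricProfile:
    """Validation rate binned along one metric (quality, depth, MQ, GQ,
    AF% or SB). ``bin_edges`` are interior breakpoints; the first bin is
    open below and the last open above, so the bins partition the metric's
    whole range. ``n_undefined`` counts labeled records lacking the metric."""

    metric_name: str
    bin_edges: Tuple[float, ...]
    estimates: List[RateEstimate]
    n_undefined: int = 0

    @property
    def lower_edges(self) -> Tuple[float, ...]:
        return (float("-inf"),) + tuple(self.bin_edges)

    @property
    def labels(self) -> Tuple[str, ...]:
        name = self.metric_name
        out = [f"{name}<{self.bin_edges[0]:g}"]
        for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:]):
            out.append(f"{lo:g}<={name}<{hi:g}")
        out.append(f"{self.bin_edges[-1]:g}<={name}")
        return tuple(out)


def profile_rate_by_metric(
    records: Sequence[VariantRecord],
    metric: str,
    edges: Sequence[float],
    confidence: float = 0.95,
) -> MetricProfile:
    """Validation rate as a function of one per-variant metric.

    Bins are half-open, lower edge inclusive, with open ends below the
    first and above the last breakpoint. Labeled records for which the
    metric is undefined are counted in ``n_undefined``; if no record
    defines the metric at all, :class:`EmptyProfileError` is raised.
    """
    edges = tuple(float(e) for e in edges)
    if len(edges) == 0 or any(b <= a for a, b in zip(edges[:-1], edges[1:])):
        raise UsageError(f"edges must be non-empty and strictly increasing, got {edges}")
    n_bins = len(edges) + 1
    validated = np.zeros(n_bins, dtype=int)
    total = np.zeros(n_bins, dtype=int)
    n_undefined = 0
    any_defined = False
    for rec in records:
        if rec.validation is Validation.UNKNOWN:
            continue
        v = metric_value(rec, metric)
        if v is None:
            n_undefined += 1
            continue
        any_defined = True
        b = int(np.searchsorted(edges, v, side="right"))
        total[b] += 1
        if rec.validation is Validation.VALIDATED:
            validated[b] += 1
    if not any_defined:
        raise EmptyProfileError(f"no labeled record defines metric {metric!r}")
    return MetricProfile(
        metric_name=metric,
        bin_edges=edges,
        estimates=[RateEstimate(int(k), int(n), confidence) for k, n in zip(validated, total)],
        n_undefined=n_undefined,
    )


# -- reporting -----------------------------------------------------------


def render_crosstab(tab: CrossTab, confidence: float = 0.95) -> str:
    """Human-readable grid: rows = SNPQ bins, columns = TD bins, cells
    "k/n (p%)", plus recomputed Total row/column."""
    scheme = tab.scheme
    header = ["Category"] + list(scheme.td_labels) + ["Total"]
    rows = [header]
    snpq_marg = marginal_rates(tab, "snpq", confidence)
    for i, label in enumerate(scheme.snpq_labels):
        cells = [str(tab.cell(CellIndex(i, j), confidence)) for j in range(scheme.n_td_bins)]
        rows.append([label] + cells + [str(snpq_marg[i])])
    td_marg = marginal_rates(tab, "td", confidence)
    rows.append(["Total"] + [str(e) for e in td_marg] + [str(overall_rate(tab, confidence))])
    widths = [max(len(r[c]) for r in rows) for c in range(len(header))]
    return "\n".join("  ".join(c.ljust(w) for c, w in zip(r, widths)) for r in rows)


def crosstab_to_tidy(tab: CrossTab, set_id: str = "", confidence: float = 0.95) -> pd.DataFrame:
    """Long-format export: one row per cell with rate and CI columns."""
    scheme = tab.scheme
    rows = []
    for i, slab in enumerate(scheme.snpq_labels):
        for j, tlab in enumerate(scheme.td_labels):
            est = tab.cell(CellIndex(i, j), confidence)
            ci = est.ci
            rows.append(
                {
                    "set": set_id,
                    "snpq_bin": slab,
                    "td_bin": tlab,
                    "validated": est.validated,
                    "total": est.total,
                    "rate": est.rate,
                    "ci_low": None if ci is None else ci[0],
                    "ci_high": None if ci is None else ci[1],
                }
            )
    return pd.DataFrame(rows)
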