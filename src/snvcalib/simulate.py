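"""Synthetic labeled SNV cohorts with the structure the calibration assumes.

The generator draws, per variant, a latent true/false-positive flag and
then class-conditional quality metrics:

* depth TD ~ 1 + NegBin(mean ``td_mean``, dispersion ``td_dispersion``);
* variant quality SNPQ: for true variants, lognormal around a location
  that scales with log-depth (accumulating read evidence); for false
  positives, exponential with a low scale, independent of depth. The
  monotone-decreasing false-positive density makes the validation rate
  rise monotonically across quality bins, while the depth-independent
  false-positive quality induces the decoupling in which high-depth calls
  validate no better than low-depth ones;
* RMS mapping quality on [0, 60] and genotype quality on [0, 99], each a
  clipped normal per class;
* strand evidence: the alternate-forward probability is tight around 0.5
  for true variants and a mixture pushed toward 0 or 1 for false
  positives (artifactual calls cluster on one strand), realized as
  binomial DP4-style counts; a UnifiedGenotyper-style SB score is drawn
  well below -10 for true variants and near 0 for false positives;
* caller membership: a variant is called by both callers with a
  class-specific probability (true variants concordant far more often),
  otherwise by one caller at random. Both-caller variants contribute one
  record per caller sharing the same key; the UnifiedGenotyper-dialect
  record reports its quality on that caller's roughly 3x larger QUAL
  scale.

The Sanger label equals the latent truth unless ``sanger_error`` flips it
(default 0: Sanger is treated as gold standard). Everything is
reproducible from (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple, Union

import numpy as np

from .errors import InsufficientDataError, UsageError
from .records import Caller, Pipeline, StrandCounts, Validation, VariantRecord
from .strata import CategoryScheme, assign_category

__all__ = ["SimParams", "LabeledCohort", "simulate_cohort", "stratified_sample", "recover_rates"]


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for a synthetic cohort.

    ``(loc, sd)`` pairs parameterize clipped normals; ``(a, b)`` pairs
    parameterize betas. ``snpq_true`` is (intercept, log-depth
    coefficient, log-sd): a true variant's quality is
    ``(intercept + coef * ln TD) * exp(N(0, log_sd))`` on the mpileup QUAL
    scale; ``snpq_false_scale`` is the exponential scale of false-positive
    quality; ``gatk_snpq_scale`` maps the mpileup scale to the
    UnifiedGenotyper one. Defaults emulate the reference study's
    conditions: ~65% of candidate calls true, exome-like depth around 20,
    and strand bias concentrated in false positives.
    """

    n_variants: int = 20_000
    tp_fraction: float = 0.65
    td_mean: float = 20.0
    td_dispersion: float = 1.6
    snpq_true: Tuple[float, float, float] = (10.0, 30.0, 0.5)
    snpq_false_scale: float = 18.0
    gatk_snpq_scale: float = 3.0
    mq_true: Tuple[float, float] = (59.3, 0.6)
    mq_false: Tuple[float, float] = (54.0, 4.0)
    gq_true: Tuple[float, float] = (80.0, 18.0)
    gq_false: Tuple[float, float] = (65.0, 22.0)
    vaf_true: Tuple[float, float] = (14.0, 14.0)
    vaf_false: Tuple[float, float] = (4.0, 8.0)
    fwd_true: Tuple[float, float] = (30.0, 30.0)
    fwd_false: Tuple[float, float] = (0.5, 12.0)
    sb_true: Tuple[float, float] = (-30.0, 8.0)
    sb_false: Tuple[float, float] = (-2.0, 5.0)
    caller_overlap_true: float = 0.9
    caller_overlap_false: float = 0.35
    sanger_error: float = 0.0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise UsageError("SimParams.n_variants must be >= 1")
        for name in ("tp_fraction", "caller_overlap_true", "caller_overlap_false", "sanger_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise UsageError(f"SimParams.{name} must be in [0, 1], got {v}")
        if self.td_mean <= 0 or self.td_dispersion <= 0:
            raise UsageError("SimParams.td_mean and td_dispersion must be positive")
        if self.gatk_snpq_scale <= 0:
            raise UsageError("SimParams.gatk_snpq_scale must be positive")
        if self.snpq_true[0] <= 0 or self.snpq_true[2] <= 0:
            raise UsageError("SimParams.snpq_true intercept and log-sd must be positive")
        if self.snpq_false_scale <= 0:
            raise UsageError("SimParams.snpq_false_scale must be positive")
        for name in ("mq_true", "mq_false", "gq_true", "gq_false", "sb_true", "sb_false"):
            if getattr(self, name)[1] <= 0:
                raise UsageError(f"SimParams.{name} sd must be positive")
        for name in ("vaf_true", "vaf_false", "fwd_true", "fwd_false"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                raise UsageError(f"SimParams.{name} beta parameters must be positive")

    def to_dict(self) -> Dict:
        from dataclasses import asdict

        return {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: Dict) -> "SimParams":
        kwargs = {k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()}
        return cls(**kwargs)


def _pick(truth: np.ndarray, t, f) -> np.ndarray:
    return np.where(truth, t, f)


def _draw_metrics(params: SimParams, rng: np.random.Generator, n: int) -> Dict[str, np.ndarray]:
    """Vectorized per-variant draws (shared by the generator and the
    Monte-Carlo recovery oracle)."""
    truth = rng.random(n) < params.tp_fraction

    k, m = params.td_dispersion, params.td_mean
    td = rng.negative_binomial(k, k / (k + m), n) + 1

    it, bt, slog = params.snpq_true
    snpq_t = (it + bt * np.log(td)) * np.exp(rng.normal(0.0, slog, n))
    snpq_f = rng.exponential(params.snpq_false_scale, n)
    snpq = np.where(truth, snpq_t, snpq_f)

    mq = np.clip(
        rng.normal(_pick(truth, params.mq_true[0], params.mq_false[0]),
                   _pick(truth, params.mq_true[1], params.mq_false[1])),
        0.0, 60.0,
    )
    gq = np.clip(
        rng.normal(_pick(truth, params.gq_true[0], params.gq_false[0]),
                   _pick(truth, params.gq_true[1], params.gq_false[1])),
        0.0, 99.0,
    )

    vaf = rng.beta(_pick(truth, params.vaf_true[0], params.vaf_false[0]),
                   _pick(truth, params.vaf_true[1], params.vaf_false[1]))
    n_alt = np.clip(rng.binomial(td, vaf), 1, td)
    # forward-strand probability of alternate reads: symmetric mixture for FPs
    flip = rng.random(n) < 0.5
    a = np.where(truth, params.fwd_true[0], np.where(flip, params.fwd_false[0], params.fwd_false[1]))
    b = np.where(truth, params.fwd_true[1], np.where(flip, params.fwd_false[1], params.fwd_false[0]))
    p_fwd = rng.beta(a, b)
    alt_fwd = rng.binomial(n_alt, p_fwd)
    n_ref = td - n_alt
    ref_fwd = rng.binomial(n_ref, 0.5)

    sb = rng.normal(_pick(truth, params.sb_true[0], params.sb_false[0]),
                    _pick(truth, params.sb_true[1], params.sb_false[1]))

    both = rng.random(n) < _pick(truth, params.caller_overlap_true, params.caller_overlap_false)
    solo_samtools = rng.random(n) < 0.5

    flip_label = rng.random(n) < params.sanger_error
    validated = truth ^ flip_label

    ref_idx = rng.integers(0, 4, n)
    alt_shift = rng.integers(1, 4, n)

    return {
        "truth": truth, "td": td, "snpq": snpq, "mq": mq, "gq": gq,
        "n_alt": n_alt, "alt_fwd": alt_fwd, "n_ref": n_ref, "ref_fwd": ref_fwd,
        "sb": sb, "both": both, "solo_samtools": solo_samtools,
        "validated": validated, "ref_idx": ref_idx, "alt_shift": alt_shift,
    }


@dataclass
class LabeledCohort:
    """A simulated cohort: records (one per caller membership), the latent
    truth flag aligned to each record, and full provenance."""

    records: List[VariantRecord]
    truth: np.ndarray
    params: SimParams
    seed: int

    def __post_init__(self) -> None:
        self.truth = np.asarray(self.truth, dtype=bool)
        if len(self.truth) != len(self.records):
            raise ValueError("truth must align with records")

    def by_caller(self, caller: Union[Caller, str]) -> "LabeledCohort":
        caller = Caller(caller)
        idx = [i for i, r in enumerate(self.records) if r.caller is caller]
        return LabeledCohort(
            [self.records[i] for i in idx], self.truth[idx], self.params, self.seed
        )

    def __len__(self) -> int:
        return len(self.records)


_BASES = "ACGT"


def simulate_cohort(params: SimParams, seed: int) -> LabeledCohort:
    """Draw a fully labeled cohort; byte-identical given (params, seed).

    Positions are unique per caller (every variant gets its own site).
    A both-caller variant yields two records sharing a key, with the
    quality rescaled to the second caller's QUAL scale.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    n = params.n_variants
    d = _draw_metrics(params, rng, n)

    records: List[VariantRecord] = []
    truth_per_record: List[bool] = []
    for i in range(n):
        chrom = "chr1"
        pos = 1 + 100 * i
        ref = _BASES[d["ref_idx"][i]]
        alt = _BASES[(d["ref_idx"][i] + d["alt_shift"][i]) % 4]
        label = Validation.VALIDATED if d["validated"][i] else Validation.FAILED
        common = dict(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            td=int(d["td"][i]), mq=float(d["mq"][i]), gq=float(d["gq"][i]),
            validation=label,
        )
        want_samtools = d["both"][i] or d["solo_samtools"][i]
        want_gatk = d["both"][i] or not d["solo_samtools"][i]
        if want_samtools:
            strand = StrandCounts(
                ref_fwd=int(d["ref_fwd"][i]),
                ref_rev=int(d["n_ref"][i] - d["ref_fwd"][i]),
                alt_fwd=int(d["alt_fwd"][i]),
                alt_rev=int(d["n_alt"][i] - d["alt_fwd"][i]),
            )
            records.append(
                VariantRecord(caller=Caller.SAMTOOLS, pipeline=Pipeline.RECALIBRATED,
                              snpq=float(d["snpq"][i]), strand=strand, **common)
            )
            truth_per_record.append(bool(d["truth"][i]))
        if want_gatk:
            records.append(
                VariantRecord(caller=Caller.GATK, pipeline=Pipeline.RECALIBRATED,
                              snpq=float(d["snpq"][i] * params.gatk_snpq_scale),
                              sb_score=float(d["sb"][i]), **common)
            )
            truth_per_record.append(bool(d["truth"][i]))
    return LabeledCohort(records, np.array(truth_per_record, dtype=bool), params, seed)


def stratified_sample(
    cohort: LabeledCohort,
    scheme: CategoryScheme,
    per_cell: int,
    seed: int,
    caller: Optional[Union[Caller, str]] = None,
) -> LabeledCohort:
    """Draw up to ``per_cell`` records uniformly without replacement from
    every non-empty TD x SNPQ cell (mimicking a validation panel spread
    evenly over the grid). Deterministic given ``seed``; cells holding
    fewer than ``per_cell`` records contribute all of them. ``caller``
    restricts sampling to one caller's records.
    """
    if per_cell < 1:
        raise UsageError(f"per_cell must be >= 1, got {per_cell}")
    pool = cohort if caller is None else cohort.by_caller(caller)
    cells: Dict[Tuple[int, int], List[int]] = {}
    for i, rec in enumerate(pool.records):
        c = assign_category(rec.td, rec.snpq, scheme)
        cells.setdefault((c.snpq_bin, c.td_bin), []).append(i)
    rng = np.random.default_rng(seed)
    chosen: List[int] = []
    for key in sorted(cells):
        idx = cells[key]
        if len(idx) <= per_cell:
            chosen.extend(idx)
        else:
            chosen.extend(rng.choice(idx, size=per_cell, replace=False))
    chosen.sort()
    return LabeledCohort(
        [pool.records[i] for i in chosen], pool.truth[chosen], cohort.params, seed
    )


def recover_rates(
    cohort: LabeledCohort,
    scheme: CategoryScheme,
    caller: Union[Caller, str] = Caller.SAMTOOLS,
    min_cell_total: int = 30,
    min_cells: int = 10,
    mc_size: int = 200_000,
    mc_seed: Optional[int] = None,
):
    """Parameter-recovery check: per-cell empirical validation rate vs the
    model-implied probability, estimated by Monte Carlo from the same
    parameters with an INDEPENDENT random stream (so agreement is not
    trivially guaranteed by shared draws).

    Only cells with at least ``min_cell_total`` cohort records are
    eligible; fewer than ``min_cells`` eligible cells raises
    :class:`InsufficientDataError`. Returns a DataFrame with one row per
    eligible cell: counts, empirical and Monte-Carlo rates, the pooled
    standard error, the z-score and a ``within_3se`` flag.
    """
    import pandas as pd

    caller = Caller(caller)
    pool = cohort.by_caller(caller)
    scale = cohort.params.gatk_snpq_scale if caller is Caller.GATK else 1.0

    emp_v: Dict[Tuple[int, int], int] = {}
    emp_n: Dict[Tuple[int, int], int] = {}
    for rec in pool.records:
        c = assign_category(rec.td, rec.snpq, scheme)
        key = (c.snpq_bin, c.td_bin)
        emp_n[key] = emp_n.get(key, 0) + 1
        emp_v[key] = emp_v.get(key, 0) + int(rec.validation is Validation.VALIDATED)
    eligible = sorted(k for k, n in emp_n.items() if n >= min_cell_total)
    if len(eligible) < min_cells:
        raise InsufficientDataError(
            f"only {len(eligible)} cell(s) hold >= {min_cell_total} records; "
            f"need >= {min_cells} — simulate a larger cohort"
        )

    # independent oracle stream, decorrelated from the generation seed
    if mc_seed is None:
        mc_seed = int(np.random.SeedSequence([cohort.seed, 0x0C0FFEE]).generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(mc_seed)
    d = _draw_metrics(cohort.params, rng, mc_size)
    # restrict the oracle sample to the same caller membership
    in_caller = d["both"] | (d["solo_samtools"] if caller is Caller.SAMTOOLS else ~d["solo_samtools"])
    td, snpq, val = d["td"][in_caller], d["snpq"][in_caller] * scale, d["validated"][in_caller]
    sq_bins = np.searchsorted(scheme.snpq_edges, snpq, side="right")
    td_bins = np.searchsorted(scheme.td_edges, td, side="right")

    rows = []
    for (i, j) in eligible:
        mask = (sq_bins == i) & (td_bins == j)
        n_mc = int(mask.sum())
        if n_mc == 0:
            continue
        p_mc = float(val[mask].mean())
        n_emp = emp_n[(i, j)]
        p_emp = emp_v[(i, j)] / n_emp
        p_pool = (emp_v[(i, j)] + val[mask].sum()) / (n_emp + n_mc)
        se = float(np.sqrt(max(p_pool * (1 - p_pool), 1e-12) * (1 / n_emp + 1 / n_mc)))
        z = (p_emp - p_mc) / se
        rows.append(
            {
                "snpq_bin": i, "td_bin": j, "n": n_emp,
                "empirical_rate": p_emp, "model_rate": p_mc, "n_mc": n_mc,
                "se": se, "z": z, "within_3se": abs(z) <= 3.0,
            }
        )
    return pd.DataFrame(rows)
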