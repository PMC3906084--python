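"""Variant ingest: two VCF dialects, tabular variant files, and the
bundled reference cross-tabulation.

Two VCF dialects are understood, named after the caller that emits them:

* ``samtools`` (mpileup-style): INFO ``DP``, ``DP4`` (four strand counts),
  ``MQ``; FORMAT ``GQ``; the ``QUAL`` column is taken as the variant
  quality (SNPQ).
* ``gatk`` (UnifiedGenotyper-style): INFO ``DP``, ``MQ``, ``SB`` (strand
  bias score); FORMAT ``GQ``; ``QUAL`` as SNPQ.

Only biallelic SNV lines are converted; multi-allelic sites and indels
are skipped with a logged count, so parsing is total: every line is
converted, skipped-with-count, or raises a located error. Missing
optional keys yield absent fields, never fabricated zeros.

Tabular I/O round-trips :class:`~snvcalib.records.VariantRecord` through
tab- or comma-delimited files with a header row; output is always
tab-delimited, UTF-8, Unix newlines.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, TableValidationError, UsageError
from .records import Caller, Pipeline, StrandCounts, Validation, VariantRecord
from .rates import CrossTab
from .strata import default_scheme

__all__ = [
    "RecordList",
    "read_vcf",
    "read_variant_table",
    "write_variant_table",
    "records_to_frame",
    "frame_to_records",
    "load_reference_crosstab",
    "REFERENCE_SET_IDS",
    "SET_CALLER",
    "SET_PIPELINE",
    "DEFAULT_VALIDATION_ALIASES",
]

logger = logging.getLogger(__name__)


class RecordList(List[VariantRecord]):
    """A list of records that also carries ingest bookkeeping."""

    n_skipped: int = 0


# -- VCF -----------------------------------------------------------------


def _info_get(variant, key):
    try:
        return variant.INFO.get(key)
    except Exception:
        return None


def read_vcf(
    path,
    dialect: Union[Caller, str],
    pipeline: Union[Pipeline, str] = Pipeline.BASIC,
    sample_index: int = 0,
) -> RecordList:
    """Read one VCF into normalized records.

    ``dialect`` declares which INFO/FORMAT keys to expect (see module
    docstring). Multi-allelic and indel lines are skipped and counted in
    the returned list's ``n_skipped``; the count is also logged. Genotype
    quality is taken from the FORMAT GQ of ``sample_index``.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - present in supported envs
        raise ParseError(f"cyvcf2 is required for VCF ingest: {exc}") from exc

    dialect = Caller(dialect)
    pipeline = Pipeline(pipeline)
    out = RecordList()
    out.n_skipped = 0
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc

    record_no = 0
    try:
        for v in vcf:
            record_no += 1
            if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
                out.n_skipped += 1
                continue
            ref, alt = v.REF.upper(), v.ALT[0].upper()
            if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
                out.n_skipped += 1
                continue
            td = _info_get(v, "DP")
            mq = _info_get(v, "MQ")
            gq: Optional[float] = None
            try:
                quals = v.gt_quals
                if quals is not None and len(quals) > sample_index and quals[sample_index] >= 0:
                    gq = float(quals[sample_index])
            except Exception:
                gq = None
            strand = None
            sb = None
            if dialect is Caller.SAMTOOLS:
                dp4 = _info_get(v, "DP4")
                if dp4 is not None:
                    counts = [int(x) for x in np.atleast_1d(np.asarray(dp4)).ravel()]
                    if len(counts) != 4:
                        raise ParseError(
                            f"{path}: malformed DP4 at variant #{record_no} "
                            f"({v.CHROM}:{v.POS}): {counts}"
                        )
                    strand = StrandCounts(*counts)
            else:
                raw_sb = _info_get(v, "SB")
                if raw_sb is not None:
                    sb = float(np.atleast_1d(np.asarray(raw_sb)).ravel()[0])
            out.append(
                VariantRecord(
                    chrom=v.CHROM,
                    pos=int(v.POS),
                    ref=ref,
                    alt=alt,
                    caller=dialect,
                    pipeline=pipeline,
                    td=int(td) if td is not None else 0,
                    snpq=float(v.QUAL) if v.QUAL is not None else 0.0,
                    mq=float(mq) if mq is not None else None,
                    gq=gq,
                    strand=strand,
                    sb_score=sb,
                )
            )
    except ParseError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF near record #{record_no + 1}: {exc}") from exc
    if out.n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic-SNV line(s)", path, out.n_skipped)
    return out


# -- tabular -------------------------------------------------------------

#: Default normalization of validation-outcome tokens (case-insensitive).
DEFAULT_VALIDATION_ALIASES: Dict[str, Validation] = {
    "validated": Validation.VALIDATED,
    "true": Validation.VALIDATED,
    "pass": Validation.VALIDATED,
    "yes": Validation.VALIDATED,
    "1": Validation.VALIDATED,
    "failed": Validation.FAILED,
    "false": Validation.FAILED,
    "fail": Validation.FAILED,
    "no": Validation.FAILED,
    "0": Validation.FAILED,
    "unknown": Validation.UNKNOWN,
    "na": Validation.UNKNOWN,
    "nan": Validation.UNKNOWN,
    "none": Validation.UNKNOWN,
    "": Validation.UNKNOWN,
}

_REQUIRED_ROLES = ("chrom", "pos", "ref", "alt", "td", "snpq")
_OPTIONAL_ROLES = (
    "mq", "gq", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "sb",
    "validation", "caller", "pipeline",
)


def _normalize_validation(token, aliases: Mapping[str, Validation]) -> Validation:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return Validation.UNKNOWN
    key = str(token).strip().lower()
    if key in aliases:
        return aliases[key]
    raise ValueError(f"unrecognized validation token {token!r}")


def _opt_float(row, col) -> Optional[float]:
    if col is None or col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def read_variant_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    caller: Optional[Union[Caller, str]] = None,
    pipeline: Optional[Union[Pipeline, str]] = None,
    validation_aliases: Optional[Mapping[str, str]] = None,
    sep: Optional[str] = None,
) -> RecordList:
    """Read a per-variant table (one row per SNV, named columns).

    ``schema`` maps record roles to column names; unmapped roles default
    to the role name itself. Required roles: chrom, pos, ref, alt, td,
    snpq. ``caller``/``pipeline`` may come from columns or be supplied as
    constants here (a column wins). Validation tokens are normalized
    case-insensitively through ``validation_aliases`` merged over the
    defaults. Rows violating record invariants are rejected together, with
    their 1-based row numbers, via :class:`TableValidationError`.
    """
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if header.count("\t") >= header.count(",") else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return frame_to_records(
        frame, schema=schema, caller=caller, pipeline=pipeline,
        validation_aliases=validation_aliases,
    )


def frame_to_records(
    frame: pd.DataFrame,
    schema: Optional[Mapping[str, str]] = None,
    caller: Optional[Union[Caller, str]] = None,
    pipeline: Optional[Union[Pipeline, str]] = None,
    validation_aliases: Optional[Mapping[str, str]] = None,
) -> RecordList:
    """Convert a DataFrame of per-variant rows into records (see
    :func:`read_variant_table` for the contract)."""
    schema = dict(schema or {})
    colmap = {role: schema.get(role, role) for role in _REQUIRED_ROLES + _OPTIONAL_ROLES}
    missing = [role for role in _REQUIRED_ROLES if colmap[role] not in frame.columns]
    if missing:
        raise SchemaError(f"variant table is missing required role(s): {missing}")
    aliases = dict(DEFAULT_VALIDATION_ALIASES)
    for k, v in (validation_aliases or {}).items():
        aliases[str(k).strip().lower()] = Validation(v)

    def col(role):
        c = colmap[role]
        return c if c in frame.columns else None

    out = RecordList()
    bad_rows, bad_msgs = [], []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            strand = None
            if all(col(r) is not None and not pd.isna(row[col(r)])
                   for r in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev")):
                strand = StrandCounts(
                    int(row[col("ref_fwd")]), int(row[col("ref_rev")]),
                    int(row[col("alt_fwd")]), int(row[col("alt_rev")]),
                )
            row_caller = row[col("caller")] if col("caller") else caller
            row_pipeline = row[col("pipeline")] if col("pipeline") else pipeline
            if row_caller is None:
                raise ValueError("caller not given by column or argument")
            validation = Validation.UNKNOWN
            if col("validation") is not None:
                validation = _normalize_validation(row[col("validation")], aliases)
            out.append(
                VariantRecord(
                    chrom=str(row[col("chrom")]),
                    pos=int(row[col("pos")]),
                    ref=str(row[col("ref")]).upper(),
                    alt=str(row[col("alt")]).upper(),
                    caller=Caller(row_caller),
                    pipeline=Pipeline(row_pipeline) if row_pipeline is not None else Pipeline.BASIC,
                    td=int(row[col("td")]),
                    snpq=float(row[col("snpq")]),
                    mq=_opt_float(row, col("mq")),
                    gq=_opt_float(row, col("gq")),
                    strand=strand,
                    sb_score=_opt_float(row, col("sb")),
                    validation=validation,
                )
            )
        except (ValueError, TypeError) as exc:
            bad_rows.append(i)
            bad_msgs.append(f"row {i}: {exc}")
    if bad_rows:
        raise TableValidationError(bad_rows, bad_msgs)
    return out


_TABLE_COLUMNS = (
    "chrom", "pos", "ref", "alt", "caller", "pipeline", "td", "snpq",
    "mq", "gq", "ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "sb", "validation",
)


def records_to_frame(records: Sequence[VariantRecord]) -> pd.DataFrame:
    """Normalized tabular form of a record sequence (round-trippable)."""
    rows = []
    for r in records:
        rows.append(
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "ref": r.ref,
                "alt": r.alt,
                "caller": r.caller.value,
                "pipeline": r.pipeline.value,
                "td": r.td,
                "snpq": r.snpq,
                "mq": r.mq,
                "gq": r.gq,
                "ref_fwd": None if r.strand is None else r.strand.ref_fwd,
                "ref_rev": None if r.strand is None else r.strand.ref_rev,
                "alt_fwd": None if r.strand is None else r.strand.alt_fwd,
                "alt_rev": None if r.strand is None else r.strand.alt_rev,
                "sb": r.sb_score,
                "validation": r.validation.value,
            }
        )
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)


def write_variant_table(records: Sequence[VariantRecord], path) -> None:
    """Write records as a tab-delimited UTF-8 table with Unix newlines."""
    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


# -- bundled reference counts -------------------------------------------

REFERENCE_SET_IDS = ("set1", "set2", "set3", "set4")

#: Which caller produced each reference call set.
SET_CALLER: Dict[str, Caller] = {
    "set1": Caller.SAMTOOLS,
    "set2": Caller.GATK,
    "set3": Caller.SAMTOOLS,
    "set4": Caller.GATK,
}

#: Upstream alignment post-processing of each reference call set.
SET_PIPELINE: Dict[str, Pipeline] = {
    "set1": Pipeline.BASIC,
    "set2": Pipeline.BASIC,
    "set3": Pipeline.RECALIBRATED,
    "set4": Pipeline.RECALIBRATED,
}


def load_reference_crosstab(set_id: str) -> CrossTab:
    """Load the bundled per-cell Sanger-validation counts for one of the
    four reference call sets (set1/set3: mpileup, basic/recalibrated;
    set2/set4: UnifiedGenotyper, basic/recalibrated).

    Returns the 9 x 5 grid of (validated, total) pairs; marginals are
    recomputed downstream, never stored.
    """
    if set_id not in REFERENCE_SET_IDS:
        raise UsageError(f"unknown set_id {set_id!r}; expected one of {REFERENCE_SET_IDS}")
    with resources.files("snvcalib.data").joinpath("reference_counts.tsv").open("r") as fh:
        frame = pd.read_csv(fh, sep="\t")
    sub = frame[frame["set_id"] == set_id]
    scheme = default_scheme(SET_CALLER[set_id])
    tab = CrossTab.empty(scheme)
    if len(sub) != scheme.n_snpq_bins * scheme.n_td_bins:
        raise ParseError(f"reference counts for {set_id} have {len(sub)} rows, expected 45")
    for _, row in sub.iterrows():
        tab.validated[int(row["snpq_bin"]), int(row["td_bin"])] = int(row["validated"])
        tab.total[int(row["snpq_bin"]), int(row["td_bin"])] = int(row["total"])
    return tab
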