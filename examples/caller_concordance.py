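"""Common vs caller-specific variants: concordance as a quality signal.

Variants called by both mpileup and UnifiedGenotyper validate far better
than variants unique to either caller. The per-variant tables here are
the package's deterministic synthetic reconstruction of the reference
call sets (consistent with every published aggregate).
"""

from snvcalib import (
    partition_by_caller,
    partition_rates,
    synthetic_counterpart_records,
    synthetic_study_records,
)

# The basic mpileup selection (348 variants) against the other caller's
# membership list: 294 shared keys, 54 caller-specific.
part = partition_by_caller(synthetic_study_records("set1"), synthetic_counterpart_records("set1"))
common, specific = partition_rates(part)
print(f"basic mpileup set: {len(part.common)} common, {len(part.only_a)} caller-specific")
print(f"  common rate:   {common}")
print(f"  specific rate: {specific}")

# The recalibrated pair, joined allele-aware on (chrom, pos, ref, alt):
part34 = partition_by_caller(synthetic_study_records("set3"), synthetic_study_records("set4"))
common34, specific34 = partition_rates(part34)
print(f"recalibrated pair: {len(part34.common)} common, "
      f"{len(part34.only_a)} + {len(part34.only_b)} caller-specific")
print(f"  common rate:   {common34}")
print(f"  specific rate: {specific34}")
# Caller-specific calls validate at ~24-30% vs ~71% for concordant calls —
# requiring concordance is itself a strong (if lossy) filter.
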