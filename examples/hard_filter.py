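"""Apply the calibrated combined hard filters and report rate improvement.

The calibrated presets combine a variant-quality cutoff, a mapping-
quality cutoff, and a strand-bias criterion:

  mpileup:          SNPQ >= 40,  MQ > 58,  20 <= AF% < 80
  UnifiedGenotyper: SNPQ >= 300, MQ > 58,  SB < -10

where AF% is the percentage of alternate-supporting reads on the forward
strand (from DP4) and SB is the caller's strand-bias score.
"""

from snvcalib import FilterSpec, apply_filter, recommended_filter, synthetic_study_records

for set_id, preset in [("set3", "samtools"), ("set4", "gatk")]:
    records = synthetic_study_records(set_id)
    spec = recommended_filter(preset)
    print(f"{set_id}: {spec.describe()}")
    # build up the conjunction one predicate at a time
    partial = FilterSpec((), caller=spec.caller)
    for conjunct in spec.conjuncts:
        partial = partial.with_conjunct(conjunct)
        res = apply_filter(records, partial)
        print(f"  + {conjunct.describe():24s} retained {res.n_after:3d}/{res.n_before}  "
              f"rate {res.rate_after}")
# The combined filter lifts the validation rate from ~66-70% unfiltered
# to ~97-99% among retained calls.
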