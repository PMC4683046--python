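"""Narrow called DETs through a condition-annotation intersection chain.

Starting from the significant transcripts, keep those linked to at least one
condition of interest, then those common to all conditions, then those whose
observed direction agrees with every condition's expected direction.
"""

from adiposeq import (
    ConditionAnnotation,
    ExpressionSimSpec,
    call_differential,
    generate_expression,
    intersection_chain,
)
from adiposeq.simulate import generate_condition_annotation

matrix, _ = generate_expression(
    ExpressionSimSpec(n_transcripts=2000, frac_up=0.05, frac_down=0.02,
                      effect_fold=4.0, seed=1)
)
det = call_differential(matrix)
conditions = ["inflammatory response", "vascular disease", "cancer"]

# a synthetic annotation planting 40 linked DETs, 6 common to all three
# conditions, 2 of them fully direction-concordant
table = generate_condition_annotation(det, conditions, n_any=40, n_all=6,
                                      n_concordant=2, seed=9)
chain = intersection_chain(det, ConditionAnnotation(records=table), conditions)

n_det = sum(r.significant for r in det)
print(f"significant transcripts:            {n_det}")
print(f"linked to >=1 condition:            {len(chain['any'])}")
print(f"common to all {len(conditions)} conditions:        {len(chain['all'])}")
print(f"direction-concordant throughout:    {len(chain['concordant'])}")
# Each stage is a subset of the previous one; the final set is the shortlist
# of transcripts consistently implicated across all conditions.
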