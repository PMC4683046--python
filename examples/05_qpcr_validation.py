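"""Relative expression by the 2^ddCt method with an 18S reference gene.

Simulates a Ct table with two target genes (one induced ~1.8-fold, one
repressed ~2.4-fold in LOCK), then recovers group fold changes and p-values
the way a qPCR validation table reports them.
"""

from adiposeq import generate_ct_table, validation_table

ct = generate_ct_table(
    genes=["Col1a1", "Cish"],
    group_effects_log2={"Col1a1": 0.87, "Cish": -1.28},
    noise_sd=0.05,
    n_per_group=6,
    seed=4,
)
table = validation_table(ct)
for row in table.itertuples():
    print(f"{row.gene}: fold {row.fold_change:+.2f}, p = {row.p_value:.2g}")
# Positive folds mean higher expression in LOCK; negative folds use the
# reciprocal convention (-2.4 means RUN expression is 2.4x LOCK).
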