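"""Signed fold changes from group-mean RPKM values.

The signed convention reports down-regulation as the negative reciprocal
(-RUN/LOCK), so every fold change has magnitude >= 1 and the sign gives the
direction in LOCK relative to RUN.
"""

from adiposeq import round_half_up, signed_fold_change

examples = [
    ("fibronectin-like up-regulated transcript", 59.75, 202.91),
    ("strongly induced matrix enzyme", 8.567, 38.97),
    ("down-regulated calmodulin-like transcript", 17.35, 7.30),
]

for label, mean_run, mean_lock in examples:
    fc = signed_fold_change(mean_run, mean_lock)
    print(f"{label}: RUN {mean_run} -> LOCK {mean_lock}  "
          f"fold = {round_half_up(fc, 3):+.3f}")
# A fold of +3.396 means LOCK expression is 3.396x RUN;
# -2.377 means RUN is 2.377x LOCK.
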