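"""Two-group RPKM differential-expression cascade.

The filtering pipeline mirrors a common RNA-seq workflow on RPKM values:

1. keep known (annotated) transcripts expressed in each group;
2. intersect the two groups' expressed sets ("common transcripts");
3. per common transcript, a two-sided equal-variance Student t-test on the
   per-sample RPKM values, with Benjamini–Hochberg adjustment over the set;
4. call a transcript differentially expressed when all four criteria hold:
   q < fdr_max, p < p_max, |signed fold change| >= fc_min, and
   average RPKM >= rpkm_min.

Transcripts expressed in exactly one group (all-zero in the other) have an
undefined fold change and are reported separately as group-exclusive sets.

The signed fold-change convention reports down-regulation as the negative
reciprocal, so |fc| >= 1 always: LOCK/RUN when LOCK >= RUN, else -RUN/LOCK.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import DifferentialRecord, ExpressionMatrix, FilterCriteria


def rpkm_from_counts(reads: int, total_mapped: int, length_bp: int) -> float:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM = reads * 1e9 / (total_mapped * length_bp); invariant under scaling
    reads and total_mapped together.
    """
    if reads < 0:
        raise ValueError("read count must be non-negative")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    return reads * 1e9 / (total_mapped * length_bp)


def detect_expressed(matrix: ExpressionMatrix, group: str) -> set[str]:
    """Known transcripts expressed in a group (group-mean RPKM > 0)."""
    if not matrix.samples_in(group):
        raise ValueError(f"group {group} has no samples")
    means = matrix.group_means(group)
    mask = matrix.known & (means > 0)
    return {t for t, m in zip(matrix.transcript_ids, mask) if m}


def common_transcripts(matrix: ExpressionMatrix) -> set[str]:
    """Known transcripts expressed in both groups."""
    return detect_expressed(matrix, "RUN") & detect_expressed(matrix, "LOCK")


def signed_fold_change(mean_run: float, mean_lock: float) -> float:
    """Signed LOCK-over-RUN fold change; negative reciprocal when LOCK < RUN.

    Equal means give +1.0.  Undefined when either mean is zero — such
    transcripts belong in the group-exclusive sets, not here.
    """
    if mean_run <= 0 or mean_lock <= 0:
        raise ValueError(
            "fold change undefined for zero group mean; transcript is group-exclusive"
        )
    if mean_lock >= mean_run:
        return mean_lock / mean_run
    return -(mean_run / mean_lock)


def transcript_test(matrix: ExpressionMatrix, transcript_id: str) -> float:
    """Two-sided equal-variance Student t-test p-value for one transcript."""
    i = matrix.row(transcript_id)
    run = matrix.rpkm[i, matrix.columns_in("RUN")]
    lock = matrix.rpkm[i, matrix.columns_in("LOCK")]
    return _ttest_p(run, lock)


def _ttest_p(a: np.ndarray, b: np.ndarray) -> float:
    """Equal-variance t-test p with the degenerate zero-variance convention."""
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    matrix: ExpressionMatrix, criteria: FilterCriteria = FilterCriteria()
) -> list[DifferentialRecord]:
    """Run the full cascade and return one record per common transcript.

    Records are returned in matrix row order.  The BH adjustment spans the
    common set only; ``significant`` is the conjunction of all four criteria.
    """
    common = common_transcripts(matrix)
    ids = [t for t in matrix.transcript_ids if t in common]
    if not ids:
        return []
    mean_run = dict(zip(matrix.transcript_ids, matrix.group_means("RUN")))
    mean_lock = dict(zip(matrix.transcript_ids, matrix.group_means("LOCK")))
    run_cols = matrix.columns_in("RUN")
    lock_cols = matrix.columns_in("LOCK")
    rows = {t: i for i, t in enumerate(matrix.transcript_ids)}

    idx = np.array([rows[t] for t in ids])
    run_mat = matrix.rpkm[np.ix_(idx, run_cols)]
    lock_mat = matrix.rpkm[np.ix_(idx, lock_cols)]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = stats.ttest_ind(run_mat, lock_mat, axis=1, equal_var=True).pvalue
    degenerate = ~np.isfinite(p)  # zero variance in both groups
    if degenerate.any():
        equal = run_mat.mean(axis=1) == lock_mat.mean(axis=1)
        p[degenerate] = np.where(equal[degenerate], 1.0, 0.0)
    q = bh_fdr(p)

    records = []
    for k, t in enumerate(ids):
        mr, ml = float(mean_run[t]), float(mean_lock[t])
        fc = signed_fold_change(mr, ml)
        avg = (mr + ml) / 2.0
        sig = (
            q[k] < criteria.fdr_max
            and p[k] < criteria.p_max
            and abs(fc) >= criteria.fc_min
            and avg >= criteria.rpkm_min
        )
        records.append(
            DifferentialRecord(
                transcript_id=t,
                mean_run=mr,
                mean_lock=ml,
                fold_change=fc,
                p_value=float(p[k]),
                q_value=float(q[k]),
                average_rpkm=avg,
                significant=bool(sig),
                direction=("up" if fc > 0 else "down") if sig else None,
            )
        )
    return records


def summarize(records: list[DifferentialRecord], matrix: ExpressionMatrix) -> dict[str, int]:
    """Headline counts for the run: expressed per group, common, DET, up, down."""
    up = sum(1 for r in records if r.significant and r.direction == "up")
    down = sum(1 for r in records if r.significant and r.direction == "down")
    return {
        "n_known_run": len(detect_expressed(matrix, "RUN")),
        "n_known_lock": len(detect_expressed(matrix, "LOCK")),
        "n_common": len(records),
        "n_det": up + down,
        "n_up": up,
        "n_down": down,
    }


def exclusive_sets(matrix: ExpressionMatrix) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Known transcripts expressed in exactly one group.

    A transcript is RUN-only when every LOCK sample is exactly zero and its
    RUN group mean is positive (and vice versa).  No RPKM floor is applied.
    Each list holds (transcript_id, group_mean_rpkm) sorted by RPKM
    descending, ties broken lexicographically by id.
    """
    run_cols = matrix.columns_in("RUN")
    lock_cols = matrix.columns_in("LOCK")
    run_mean = matrix.group_means("RUN")
    lock_mean = matrix.group_means("LOCK")
    run_only, lock_only = [], []
    for i, t in enumerate(matrix.transcript_ids):
        if not matrix.known[i]:
            continue
        lock_zero = not matrix.rpkm[i, lock_cols].any()
        run_zero = not matrix.rpkm[i, run_cols].any()
        if run_mean[i] > 0 and lock_zero:
            run_only.append((t, float(run_mean[i])))
        elif lock_mean[i] > 0 and run_zero:
            lock_only.append((t, float(lock_mean[i])))
    key = lambda pair: (-pair[1], pair[0])
    return sorted(run_only, key=key), sorted(lock_only, key=key)
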