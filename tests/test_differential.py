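"""The filtering cascade: fold changes, t-tests, BH-FDR, calling, exclusives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adiposeq import (
    ExpressionSimSpec,
    FilterCriteria,
    bh_fdr,
    call_differential,
    common_transcripts,
    detect_expressed,
    exclusive_sets,
    generate_expression,
    rpkm_from_counts,
    signed_fold_change,
    summarize,
    transcript_test,
)

from conftest import make_matrix


# --- RPKM formula -----------------------------------------------------------


def test_rpkm_formula():
    assert rpkm_from_counts(10, 10**6, 1000) == 10.0
    assert rpkm_from_counts(0, 10**6, 500) == 0.0
    # scale invariance: doubling reads and library size changes nothing
    assert rpkm_from_counts(20, 2 * 10**6, 1000) == rpkm_from_counts(10, 10**6, 1000)
    with pytest.raises(ValueError):
        rpkm_from_counts(10, 0, 1000)
    with pytest.raises(ValueError):
        rpkm_from_counts(10, 10**6, 0)


# --- presence filters -------------------------------------------------------


def test_detect_expressed_policies():
    m = make_matrix(
        [
            [0, 0, 0, 1, 1, 1],  # absent in RUN
            [0, 2, 0, 1, 1, 1],  # one nonzero RUN sample -> expressed (mean > 0)
            [1, 1, 1, 1, 1, 1],
        ],
        known=np.array([True, True, False]),
    )
    run = detect_expressed(m, "RUN")
    assert "t0" not in run
    assert "t1" in run
    assert "t2" not in run  # unknown transcripts never count


def test_common_set_algebra(planted_bundle):
    matrix, _ = planted_bundle
    run = detect_expressed(matrix, "RUN")
    lock = detect_expressed(matrix, "LOCK")
    common = common_transcripts(matrix)
    assert len(common) == len(run) + len(lock) - len(run | lock)
    assert common <= run and common <= lock


def test_common_set_matches_truth_table(planted_bundle):
    """Common set = known transcripts minus exclusives minus full dropouts."""
    matrix, truth = planted_bundle
    expected = set()
    run_means = dict(zip(matrix.transcript_ids, matrix.group_means("RUN")))
    lock_means = dict(zip(matrix.transcript_ids, matrix.group_means("LOCK")))
    for t, label in zip(truth["transcript_id"], truth["label"]):
        if label in ("unknown", "run_only", "lock_only"):
            continue
        if run_means[t] > 0 and lock_means[t] > 0:
            expected.add(t)
    assert common_transcripts(matrix) == expected


# --- signed fold change -----------------------------------------------------


@pytest.mark.parametrize(
    "mean_run,mean_lock,expected",
    [
        (59.75, 202.91, 3.396),
        (8.567, 38.97, 4.549),
        (9.931, 36.05, 3.630),
        (2.80, 9.47, 3.382),
        (17.35, 7.30, -2.377),
        (106.20, 53.64, -1.980),
    ],
)
def test_signed_fold_change_reproduces_printed_rows(mean_run, mean_lock, expected):
    from adiposeq import round_half_up

    assert round_half_up(signed_fold_change(mean_run, mean_lock), 3) == expected


def test_signed_fold_change_equal_means_is_one():
    assert signed_fold_change(5.0, 5.0) == 1.0


def test_signed_fold_change_zero_mean_rejected():
    with pytest.raises(ValueError, match="exclusive"):
        signed_fold_change(0.0, 5.0)


@given(
    a=st.floats(min_value=1e-3, max_value=1e6),
    b=st.floats(min_value=1e-3, max_value=1e6),
)
@settings(max_examples=100, derandomize=True)
def test_signed_fold_change_antisymmetric_and_at_least_one(a, b):
    fc = signed_fold_change(a, b)
    assert abs(fc) >= 1.0
    if a != b:
        assert signed_fold_change(b, a) == pytest.approx(-fc, rel=1e-12)


# --- t-test -----------------------------------------------------------------


def test_identical_groups_give_p_one():
    m = make_matrix([[2.0] * 12])
    assert transcript_test(m, "t0") == 1.0


def test_huge_separation_gives_tiny_p():
    rng = np.random.default_rng(0)
    row = np.concatenate([1 + 1e-3 * rng.normal(size=6), 9 + 1e-3 * rng.normal(size=6)])
    m = make_matrix(row[None, :])
    assert transcript_test(m, "t0") < 1e-6


def test_t_test_matches_definitional_formula():
    """Equal-variance two-sample t, checked against the textbook formula."""
    from scipy import stats

    rng = np.random.default_rng(42)
    for _ in range(20):
        a = rng.lognormal(1, 0.5, size=6)
        b = rng.lognormal(1.2, 0.5, size=6)
        m = make_matrix(np.concatenate([a, b])[None, :])
        p = transcript_test(m, "t0")
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
        p_oracle = 2 * stats.t.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_oracle, rel=1e-10)


# --- BH-FDR -----------------------------------------------------------------


def brute_force_bh(p):
    """Step-up oracle: q_i = min over j with p_j >= p_i of p_(j) * m / rank_j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    return q


def test_bh_single_p_unchanged():
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)


def test_bh_worked_example():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_matches_brute_force_on_random_vectors():
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = rng.uniform(size=rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), rtol=1e-12)


def test_bh_monotone_on_sorted_input():
    rng = np.random.default_rng(9)
    p = np.sort(rng.uniform(size=50))
    q = bh_fdr(p)
    assert (np.diff(q) >= -1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# --- DET calling ------------------------------------------------------------


def _toy_matrix():
    """Three common transcripts: one passes all criteria, one fails |fc|,
    one fails the average-RPKM floor."""
    rng = np.random.default_rng(5)
    jitter = lambda mu, n=6: mu * (1 + 0.01 * rng.normal(size=n))
    rows = [
        np.concatenate([jitter(2.0), jitter(8.0)]),   # fc 4, avg 5: passes
        np.concatenate([jitter(5.0), jitter(6.0)]),   # fc 1.2: fails criterion 3
        np.concatenate([jitter(0.4), jitter(1.2)]),   # avg 0.8: fails criterion 4
    ]
    return make_matrix(np.vstack(rows))


def test_call_differential_toy_conjunction():
    records = call_differential(_toy_matrix())
    sig = [r for r in records if r.significant]
    assert len(sig) == 1
    assert sig[0].transcript_id == "t0"
    assert sig[0].direction == "up"


def test_infinite_fc_threshold_yields_nothing():
    records = call_differential(_toy_matrix(), FilterCriteria(fc_min=math.inf))
    assert not any(r.significant for r in records)


def test_record_invariants(planted_bundle):
    matrix, _ = planted_bundle
    criteria = FilterCriteria()
    records = call_differential(matrix, criteria)
    common = common_transcripts(matrix)
    for r in records:
        assert r.transcript_id in common
        assert abs(r.fold_change) >= 1.0
        assert r.average_rpkm == pytest.approx((r.mean_run + r.mean_lock) / 2)
        if r.significant:
            assert r.q_value < criteria.fdr_max
            assert r.p_value < criteria.p_max
            assert abs(r.fold_change) >= criteria.fc_min
            assert r.average_rpkm >= criteria.rpkm_min
            assert (r.direction == "up") == (r.fold_change > 0)


def test_up_plus_down_equals_total(planted_bundle):
    matrix, _ = planted_bundle
    records = call_differential(matrix)
    s = summarize(records, matrix)
    assert s["n_up"] + s["n_down"] == s["n_det"]
    assert s["n_det"] == sum(1 for r in records if r.significant)


def test_tightening_any_criterion_never_enlarges(planted_bundle):
    matrix, _ = planted_bundle
    base = {r.transcript_id for r in call_differential(matrix) if r.significant}
    tighter = [
        FilterCriteria(fdr_max=0.05),
        FilterCriteria(p_max=0.01),
        FilterCriteria(fc_min=3.0),
        FilterCriteria(rpkm_min=5.0),
    ]
    for c in tighter:
        sig = {r.transcript_id for r in call_differential(matrix, c) if r.significant}
        assert sig <= base


def test_fold_change_and_p_scale_invariant(planted_bundle):
    """Multiplying all RPKM by c > 0 changes no fold change or p-value."""
    matrix, _ = planted_bundle
    orig = make_matrix(matrix.rpkm[:100], known=matrix.known[:100])
    scaled = make_matrix(matrix.rpkm[:100] * 37.0, known=matrix.known[:100])
    rec_o = {r.transcript_id: r for r in call_differential(orig)}
    rec_s = {r.transcript_id: r for r in call_differential(scaled)}
    assert set(rec_o) == set(rec_s)
    for t in rec_o:
        assert rec_s[t].fold_change == pytest.approx(rec_o[t].fold_change, rel=1e-9)
        assert rec_s[t].p_value == pytest.approx(rec_o[t].p_value, rel=1e-9, abs=1e-12)


# --- exclusive sets ---------------------------------------------------------


def test_exclusive_sets_strict_zero_policy():
    m = make_matrix(
        [
            [2, 2, 2, 0, 0, 0],      # run-only
            [2, 2, 2, 0, 0.01, 0],   # one nonzero LOCK sample -> not exclusive
            [0, 0, 0, 5, 5, 5],      # lock-only
        ]
    )
    run_only, lock_only = exclusive_sets(m)
    assert [t for t, _ in run_only] == ["t0"]
    assert [t for t, _ in lock_only] == ["t2"]


def test_exclusive_sets_sorted_descending_with_lexicographic_ties():
    m = make_matrix(
        [
            [1, 1, 1, 0, 0, 0],
            [3, 3, 3, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
        ]
    )
    run_only, _ = exclusive_sets(m)
    assert [t for t, _ in run_only] == ["t1", "t0", "t2"]


def test_exclusive_sets_match_truth_minus_dropout(planted_bundle):
    matrix, truth = planted_bundle
    run_only, lock_only = exclusive_sets(matrix)
    run_means = dict(zip(matrix.transcript_ids, matrix.group_means("RUN")))
    lock_means = dict(zip(matrix.transcript_ids, matrix.group_means("LOCK")))
    expected_run = {
        t
        for t, lab in zip(truth["transcript_id"], truth["label"])
        if lab == "run_only" and run_means[t] > 0
    }
    expected_lock = {
        t
        for t, lab in zip(truth["transcript_id"], truth["label"])
        if lab == "lock_only" and lock_means[t] > 0
    }
    assert {t for t, _ in run_only} == expected_run
    assert {t for t, _ in lock_only} == expected_lock


def test_exclusive_and_significant_sets_disjoint(planted_bundle):
    matrix, _ = planted_bundle
    sig = {r.transcript_id for r in call_differential(matrix) if r.significant}
    run_only, lock_only = exclusive_sets(matrix)
    exclusive = {t for t, _ in run_only} | {t for t, _ in lock_only}
    assert not (sig & exclusive)


# --- planted-effect recovery ------------------------------------------------


def test_sensitivity_and_fdp_on_planted_effects():
    spec = ExpressionSimSpec(
        n_transcripts=2000,
        frac_up=0.05,
        frac_down=0.02,
        effect_fold=4.0,
        noise_cv=0.2,
        seed=11,
    )
    matrix, truth = generate_expression(spec)
    sig = {r.transcript_id for r in call_differential(matrix) if r.significant}
    planted = set(truth.loc[truth["label"].isin(["up", "down"]), "transcript_id"])
    tp = len(sig & planted)
    assert tp / len(planted) >= 0.9
    assert (len(sig) - tp) / max(len(sig), 1) <= 0.15


def test_null_data_significant_fraction_below_fdr():
    fracs = []
    for seed in range(20):
        spec = ExpressionSimSpec(
            n_transcripts=2000,
            frac_up=0.0,
            frac_down=0.0,
            frac_run_only=0.0,
            frac_lock_only=0.0,
            seed=seed,
        )
        matrix, _ = generate_expression(spec)
        records = call_differential(matrix)
        fracs.append(sum(r.significant for r in records) / len(records))
    assert np.mean(fracs) <= 0.1
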