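"""Annotation-intersection chain over differentially expressed transcripts.

Given a set of called DETs and a transcript-to-condition annotation table,
the chain narrows candidates in three monotone steps: transcripts associated
with at least one condition of interest, transcripts common to all of them,
and finally transcripts whose observed regulation direction agrees with the
direction each condition's pathway expects.  Each step's output is a subset
of the previous one, whatever the annotation.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .io_model import ConditionAnnotation, DifferentialRecord

log = logging.getLogger(__name__)


def _significant(det: Sequence[DifferentialRecord]) -> dict[str, str]:
    """Map transcript -> observed direction for significant records."""
    return {r.transcript_id: r.direction for r in det if r.significant}


def _check_conditions(ann: ConditionAnnotation, conditions: Iterable[str]) -> set[str]:
    conditions = set(conditions)
    if not conditions:
        raise ValueError("need at least one condition")
    missing = conditions - ann.conditions()
    for c in sorted(missing):
        log.warning("condition %r absent from annotation; treated as empty", c)
    return conditions


def associated_with_any(
    det: Sequence[DifferentialRecord],
    ann: ConditionAnnotation,
    conditions: Iterable[str],
) -> set[str]:
    """Significant transcripts linked to at least one listed condition."""
    conditions = _check_conditions(ann, conditions)
    sig = _significant(det)
    linked = set(
        ann.records.loc[ann.records["condition"].isin(conditions), "transcript_id"]
    )
    return set(sig) & linked


def common_to_all(
    det: Sequence[DifferentialRecord],
    ann: ConditionAnnotation,
    conditions: Iterable[str],
) -> set[str]:
    """Significant transcripts linked to every listed condition."""
    conditions = _check_conditions(ann, conditions)
    sig = set(_significant(det))
    for c in conditions:
        sig &= set(ann.links_for(c)["transcript_id"])
    return sig


def direction_concordant(
    candidates: set[str],
    det: Sequence[DifferentialRecord],
    ann: ConditionAnnotation,
    conditions: Iterable[str],
) -> set[str]:
    """Candidates whose observed direction matches every condition's expectation.

    An expected direction of 'any' (or a missing link, logged) always matches.
    """
    conditions = _check_conditions(ann, conditions)
    observed = _significant(det)
    expected: dict[tuple[str, str], str] = {
        (r.transcript_id, r.condition): r.expected_direction
        for r in ann.records.itertuples()
    }
    keep = set()
    for t in candidates:
        obs = observed.get(t)
        if obs is None:
            continue
        ok = True
        for c in conditions:
            exp = expected.get((t, c))
            if exp is None:
                log.info("no expected direction for (%s, %s); treated as 'any'", t, c)
                continue
            if exp != "any" and exp != obs:
                ok = False
                break
        if ok:
            keep.add(t)
    return keep


def intersection_chain(
    det: Sequence[DifferentialRecord],
    ann: ConditionAnnotation,
    conditions: Iterable[str],
) -> dict[str, set[str]]:
    """Run all three stages; keys 'any', 'all', 'concordant'."""
    conditions = set(conditions)
    any_set = associated_with_any(det, ann, conditions)
    all_set = common_to_all(det, ann, conditions)
    conc = direction_concordant(all_set, det, ann, conditions)
    return {"any": any_set, "all": all_set, "concordant": conc}
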