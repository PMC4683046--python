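"""Synthetic inputs with the statistical structure the analysis assumes.

Three generators emulate the two-group (RUN vs LOCK, n = 6 per group) study
design end to end with no external data:

* ``generate_expression`` — a transcripts-by-samples RPKM matrix with planted
  up/down-regulated, group-exclusive, and unannotated transcripts, log-normal
  baseline abundance, multiplicative log-normal noise, and a dropout floor;
* ``generate_adipocytes`` — adipocyte diameters from a truncated-at-zero
  normal for one depot of one animal;
* ``generate_ct_table`` — qPCR Ct values with a stable reference gene and
  per-gene group effects in log2 units.

Every generator is a pure function of its spec (including the seed): the same
spec always yields the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import AdipocytePopulation, CtTable, ExpressionMatrix

TRUTH_LABELS = ("null", "up", "down", "run_only", "lock_only", "unknown")


@dataclass(frozen=True)
class ExpressionSimSpec:
    """Parameters of the expression-matrix generator.

    Defaults emulate the study's scale and composition: ~17k known expressed
    transcripts per group, ~3.1% planted up and ~0.74% down among known
    transcripts, a handful exclusive to each group, six samples per group.
    Baseline abundance is log-normal (natural-log mean 1.5, sd 1.2, median
    ~4.5 RPKM); measurement noise is multiplicative log-normal with a 20%
    coefficient of variation; values below ``dropout_floor`` RPKM are zeroed.
    """

    n_transcripts: int = 18_000
    frac_unknown: float = 0.06
    n_per_group: int = 6
    frac_up: float = 0.031
    frac_down: float = 0.0074
    effect_fold: float = 2.0
    frac_run_only: float = 0.002
    frac_lock_only: float = 0.014
    baseline_log_mean: float = 1.5
    baseline_log_sd: float = 1.2
    noise_cv: float = 0.2
    dropout_floor: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_unknown,
            self.frac_up,
            self.frac_down,
            self.frac_run_only,
            self.frac_lock_only,
        )
        if any(f < 0 for f in fracs) or sum(fracs) > 1:
            raise ValueError("fractions must be non-negative and sum to at most 1")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 samples per group")
        if not self.effect_fold > 1:
            raise ValueError("effect_fold must exceed 1")
        if not self.noise_cv > 0:
            raise ValueError("noise_cv must be positive")
        if self.dropout_floor < 0:
            raise ValueError("dropout_floor must be non-negative")


@dataclass(frozen=True)
class MorphometrySimSpec:
    """Parameters of the adipocyte-diameter generator (one animal, one depot)."""

    n_cells: int = 300
    mean_diameter_um: float = 65.0
    sd_diameter_um: float = 10.0
    depot_mass_g: float = 2.5
    depot: str = "PRAT"
    animal_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        if self.mean_diameter_um <= 0 or self.sd_diameter_um < 0:
            raise ValueError("diameter parameters must be positive")
        if self.depot_mass_g <= 0:
            raise ValueError("depot mass must be positive")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative noise factors with mean 1 and coefficient of variation cv."""
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=shape)


def generate_expression(spec: ExpressionSimSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate an RPKM matrix plus a per-transcript truth table.

    Planted up-regulated transcripts have LOCK mean = effect_fold x RUN mean
    before noise; down-regulated transcripts are the mirror image (RUN mean =
    effect_fold x LOCK mean, with the baseline on the high side in both
    directions, so planted transcripts of either direction share the same
    average-abundance distribution).  Exclusive transcripts are exactly zero
    in the other group.  The truth table has columns ``transcript_id`` and
    ``label`` in {null, up, down, run_only, lock_only, unknown}.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    counts = {
        "unknown": int(round(spec.frac_unknown * n)),
        "up": int(round(spec.frac_up * n)),
        "down": int(round(spec.frac_down * n)),
        "run_only": int(round(spec.frac_run_only * n)),
        "lock_only": int(round(spec.frac_lock_only * n)),
    }
    if sum(counts.values()) > n:
        raise ValueError("fractions infeasible for n_transcripts")
    labels = np.array(["null"] * n, dtype=object)
    start = 0
    for name, c in counts.items():
        labels[start : start + c] = name
        start += c
    rng.shuffle(labels)

    baseline = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, size=n)
    mean_run = baseline.copy()
    mean_lock = baseline.copy()
    up = labels == "up"
    down = labels == "down"
    mean_lock[up] = baseline[up] * spec.effect_fold
    mean_run[down] = baseline[down] * spec.effect_fold
    mean_lock[labels == "run_only"] = 0.0
    mean_run[labels == "lock_only"] = 0.0

    m = spec.n_per_group
    run = mean_run[:, None] * _lognormal_noise(rng, spec.noise_cv, (n, m))
    lock = mean_lock[:, None] * _lognormal_noise(rng, spec.noise_cv, (n, m))
    rpkm = np.hstack([run, lock])
    rpkm[rpkm < spec.dropout_floor] = 0.0
    # exclusive transcripts must be exactly zero in the silent group
    rpkm[labels == "run_only", m:] = 0.0
    rpkm[labels == "lock_only", :m] = 0.0

    ids = [f"T{i:05d}" for i in range(n)]
    sample_ids = [f"RUN_{j+1}" for j in range(m)] + [f"LOCK_{j+1}" for j in range(m)]
    group_of = {s: ("RUN" if s.startswith("RUN") else "LOCK") for s in sample_ids}
    matrix = ExpressionMatrix(
        transcript_ids=ids,
        known=labels != "unknown",
        rpkm=rpkm,
        sample_ids=sample_ids,
        group_of=group_of,
    )
    truth = pd.DataFrame({"transcript_id": ids, "label": labels.astype(str)})
    return matrix, truth


def generate_adipocytes(spec: MorphometrySimSpec) -> AdipocytePopulation:
    """Draw diameters from a normal truncated at zero (resampling negatives)."""
    rng = np.random.default_rng(spec.seed)
    d = rng.normal(spec.mean_diameter_um, spec.sd_diameter_um, size=spec.n_cells)
    while (d <= 0).any():  # truncate at zero; negligible at realistic CVs
        bad = d <= 0
        d[bad] = rng.normal(spec.mean_diameter_um, spec.sd_diameter_um, size=bad.sum())
    return AdipocytePopulation(
        animal_id=spec.animal_id,
        depot=spec.depot,
        diameters_um=d,
        depot_mass_g=spec.depot_mass_g,
    )


def generate_ct_table(
    genes: list[str],
    group_effects_log2: dict[str, float],
    ref_ct: float = 15.0,
    noise_sd: float = 0.05,
    n_per_group: int = 6,
    seed: int = 0,
    base_delta: float = -8.0,
) -> CtTable:
    """Simulate a qPCR Ct table with a stable reference gene.

    For gene g and sample s:  Ct = ref_ct - base_delta - effect - noise, with
    the log2 ``effect`` applied only to LOCK samples, so LOCK expression is
    2**effect times RUN under the 2^ddCt readout.  ``base_delta`` is the
    gene's reference-relative offset (dCT = ref - gene) common to both groups.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if "18S" in genes:
        raise ValueError("reference gene must not appear among target genes")
    rng = np.random.default_rng(seed)
    rows = []
    samples = [("RUN", f"RUN_{j+1}") for j in range(n_per_group)] + [
        ("LOCK", f"LOCK_{j+1}") for j in range(n_per_group)
    ]
    for group, sample in samples:
        rows.append({"sample_id": sample, "group": group, "gene": "18S", "ct": ref_ct})
        for gene in genes:
            effect = group_effects_log2.get(gene, 0.0) if group == "LOCK" else 0.0
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            ct = ref_ct - base_delta - effect - noise
            rows.append({"sample_id": sample, "group": group, "gene": gene, "ct": ct})
    return CtTable(records=pd.DataFrame(rows), reference_gene="18S")


def generate_condition_annotation(
    det,
    conditions: list[str],
    n_any: int = 167,
    n_all: int = 12,
    n_concordant: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Build an annotation table planting a chosen intersection-chain pattern.

    From the significant records of ``det``, ``n_any`` transcripts are linked
    to at least one of ``conditions``; of these, ``n_all`` are linked to every
    condition; and of those, ``n_concordant`` have expected directions that
    match the observed direction for every condition (the rest get one
    deliberately discordant expectation).  Returns a frame with columns
    transcript_id, condition, expected_direction, suitable for
    ``ConditionAnnotation``.
    """
    if not (n_concordant <= n_all <= n_any):
        raise ValueError("need n_concordant <= n_all <= n_any")
    if len(conditions) < 2 and n_any > n_all:
        raise ValueError("partial linkage needs at least two conditions")
    sig = [(r.transcript_id, r.direction) for r in det if r.significant]
    if len(sig) < n_any:
        raise ValueError(f"only {len(sig)} significant transcripts; need {n_any}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sig))
    chosen = [sig[i] for i in order[:n_any]]
    flip = {"up": "down", "down": "up"}
    rows = []
    for k, (t, direction) in enumerate(chosen):
        if k < n_all:
            concordant = k < n_concordant
            for j, c in enumerate(conditions):
                expected = direction if concordant or j > 0 else flip[direction]
                rows.append(
                    {"transcript_id": t, "condition": c, "expected_direction": expected}
                )
        else:
            # link to a strict, non-empty subset of the conditions
            n_link = int(rng.integers(1, len(conditions)))
            for c in rng.choice(conditions, size=n_link, replace=False):
                rows.append(
                    {"transcript_id": t, "condition": str(c), "expected_direction": "any"}
                )
    return pd.DataFrame(rows, columns=["transcript_id", "condition", "expected_direction"])
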