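"""Group-characteristics reporting and pipeline orchestration.

``characteristics_table`` reproduces the classic animal-characteristics
layout: per measure and group, means ± SE at two timepoints, the per-animal
week-over-week delta, and an equal-variance Student t-test between groups.
``run_pipeline`` wires every stage together on a configuration dict and a
synthetic (or user-supplied) input bundle, writing TSV outputs and a JSON
summary; identical config and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import intersect, morphometry, qpcr
from .differential import call_differential, exclusive_sets, summarize
from .io_model import (
    ConditionAnnotation,
    ExpressionMatrix,
    FilterCriteria,
    read_annotation_table,
    read_expression_table,
    write_annotation_table,
    write_expression_table,
    write_results_table,
)
from .simulate import (
    ExpressionSimSpec,
    MorphometrySimSpec,
    generate_adipocytes,
    generate_condition_annotation,
    generate_ct_table,
    generate_expression,
)

log = logging.getLogger(__name__)


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``: 100·(after − before)/before."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return 100.0 * (after - before) / before


def standard_error(values) -> float:
    """SE of the mean: sample sd (ddof=1) over sqrt(n)."""
    v = np.asarray(values, dtype=float)
    return float(np.std(v, ddof=1) / np.sqrt(v.size))


def characteristics_table(measurements: pd.DataFrame, welch: bool = False) -> pd.DataFrame:
    """Group summary of two-timepoint per-animal measurements.

    Input columns: animal_id, group, measure, week10, week11.  Animals with a
    missing timepoint are excluded (logged).  Output: one row per measure
    with group means ± SE at each timepoint, the delta (week11 − week10,
    averaged over animals — equal to the difference of group means in a
    balanced design), and Student t-test p-values per row.  ``welch=True``
    switches to the unequal-variance test.
    """
    required = {"animal_id", "group", "measure", "week10", "week11"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    df = measurements.copy()
    incomplete = df["week10"].isna() | df["week11"].isna()
    for r in df[incomplete].itertuples():
        log.warning(
            "animal %s excluded from measure %r: missing timepoint", r.animal_id, r.measure
        )
    df = df[~incomplete]
    df["delta"] = df["week11"] - df["week10"]

    rows = []
    for measure, sub in df.groupby("measure", sort=False):
        row: dict[str, Any] = {"measure": measure}
        for g in ("RUN", "LOCK"):
            vals = sub[sub["group"] == g]
            if vals.empty:
                raise ValueError(f"measure {measure!r} has no {g} animals")
            for col in ("week10", "week11", "delta"):
                row[f"{g.lower()}_{col}_mean"] = float(vals[col].mean())
                row[f"{g.lower()}_{col}_se"] = standard_error(vals[col])
        for col in ("week10", "week11", "delta"):
            a = sub.loc[sub["group"] == "RUN", col].to_numpy()
            b = sub.loc[sub["group"] == "LOCK", col].to_numpy()
            row[f"p_{col}"] = _group_p(a, b, welch)
        rows.append(row)
    return pd.DataFrame(rows)


def _group_p(a: np.ndarray, b: np.ndarray, welch: bool) -> float:
    from scipy import stats

    if np.var(a) == 0 and np.var(b) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG: dict[str, Any] = {
    "criteria": {"fdr_max": 0.1, "p_max": 0.05, "fc_min": 1.5, "rpkm_min": 1.5},
    "conditions": ["inflammatory response", "vascular disease", "cancer"],
    "expression_sim": {},          # overrides for ExpressionSimSpec
    "morphometry_sim": {
        "RUN": {"mean_diameter_um": 62.2, "sd_diameter_um": 3.9, "depot_mass_g": 1.93},
        "LOCK": {"mean_diameter_um": 67.1, "sd_diameter_um": 1.4, "depot_mass_g": 3.43},
    },
    "qpcr_sim": {
        "genes": ["Col1a1", "Cish"],
        "group_effects_log2": {"Col1a1": 0.87, "Cish": -1.28},
        "noise_sd": 0.05,
    },
    "n_animals_per_group": 6,
    "seed": 0,
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute filter → intersect → morphometry → qpcr → report on the bundle
    described by ``config`` and write all stage outputs under ``out_dir``.

    Inputs come either from TSV paths in the config (``expression_path`` +
    ``group_map``, ``annotation_path``, ``ct_path`` + ``reference_gene``) or,
    when absent, from the synthetic generators seeded by ``config['seed']``.
    Returns the machine-readable summary that is also written as
    ``summary.json``.  Any stage failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    seed = int(cfg.get("seed", 0))
    summary: dict[str, Any] = {"seed": seed}

    stage = "inputs"
    try:
        matrix, annotation, ct, truth = _load_inputs(cfg, seed, out)

        stage = "filter"
        t0 = time.perf_counter()
        criteria = FilterCriteria(**cfg["criteria"])
        records = call_differential(matrix, criteria)
        run_only, lock_only = exclusive_sets(matrix)
        write_results_table(records, out / "det_table.tsv")
        pd.DataFrame(run_only, columns=["transcript_id", "mean_rpkm"]).to_csv(
            out / "run_only.tsv", sep="\t", index=False
        )
        pd.DataFrame(lock_only, columns=["transcript_id", "mean_rpkm"]).to_csv(
            out / "lock_only.tsv", sep="\t", index=False
        )
        summary["filter"] = summarize(records, matrix)
        summary["filter"]["n_run_only"] = len(run_only)
        summary["filter"]["n_lock_only"] = len(lock_only)
        log.info("stage filter done in %.2fs", time.perf_counter() - t0)

        stage = "intersect"
        t0 = time.perf_counter()
        if annotation is None:
            annotation = _planted_annotation(records, cfg, seed)
            write_annotation_table(annotation, out / "annotation.tsv")
        chain = intersect.intersection_chain(records, annotation, cfg["conditions"])
        chain_rows = [
            {"transcript_id": t, "stage": name}
            for name in ("any", "all", "concordant")
            for t in sorted(chain[name])
        ]
        pd.DataFrame(chain_rows, columns=["transcript_id", "stage"]).to_csv(
            out / "intersection.tsv", sep="\t", index=False
        )
        summary["intersect"] = {k: len(v) for k, v in chain.items()}
        log.info("stage intersect done in %.2fs", time.perf_counter() - t0)

        stage = "morphometry"
        t0 = time.perf_counter()
        morpho_rows = []
        for group, pops in _morphometry_inputs(cfg, seed):
            for pop in pops:
                s = morphometry.summarize_population(pop)
                morpho_rows.append({"animal_id": pop.animal_id, "group": group, **s})
        morpho_df = pd.DataFrame(morpho_rows)
        morpho_df.to_csv(out / "morphometry.tsv", sep="\t", index=False)
        summary["morphometry"] = {
            g: {
                "mean_diameter_um": float(
                    morpho_df.loc[morpho_df["group"] == g, "mean_diameter_um"].mean()
                ),
                "mean_cellularity": float(
                    morpho_df.loc[morpho_df["group"] == g, "cellularity"].mean()
                ),
            }
            for g in ("RUN", "LOCK")
        }
        log.info("stage morphometry done in %.2fs", time.perf_counter() - t0)

        stage = "qpcr"
        t0 = time.perf_counter()
        validation = qpcr.validation_table(ct)
        validation.to_csv(out / "qpcr_validation.tsv", sep="\t", index=False)
        summary["qpcr"] = {
            r.gene: {"fold_change": float(r.fold_change), "p_value": float(r.p_value)}
            for r in validation.itertuples()
        }
        log.info("stage qpcr done in %.2fs", time.perf_counter() - t0)

        stage = "report"
        if truth is not None:
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return summary


def _load_inputs(cfg, seed, out):
    truth = None
    if "expression_path" in cfg:
        matrix = read_expression_table(cfg["expression_path"], cfg["group_map"])
    else:
        spec = ExpressionSimSpec(**{"seed": seed, **cfg.get("expression_sim", {})})
        matrix, truth = generate_expression(spec)
        write_expression_table(matrix, out / "expression.tsv")
    if "annotation_path" in cfg:
        annotation = read_annotation_table(cfg["annotation_path"])
    else:
        annotation = None  # planted over the called DETs after the filter stage
    if "ct_path" in cfg:
        from .io_model import read_ct_table

        ct = read_ct_table(cfg["ct_path"], cfg.get("reference_gene", "18S"))
    else:
        q = cfg["qpcr_sim"]
        ct = generate_ct_table(
            genes=q["genes"],
            group_effects_log2=q["group_effects_log2"],
            noise_sd=q.get("noise_sd", 0.05),
            n_per_group=cfg.get("n_animals_per_group", 6),
            seed=seed + 1,
        )
    return matrix, annotation, ct, truth


def _planted_annotation(records, cfg, seed) -> ConditionAnnotation:
    """Synthetic annotation planted over the called DETs.

    Scales the study-like proportions (about 26% of DETs linked to at least
    one condition, 1.9% to all, 0.8% fully concordant) to the realized DET
    count; with no DETs the annotation is empty.
    """
    conditions = list(cfg["conditions"])
    n_det = sum(1 for r in records if r.significant)
    empty = pd.DataFrame(columns=["transcript_id", "condition", "expected_direction"])
    if n_det == 0:
        return ConditionAnnotation(records=empty)
    n_any = max(1, round(0.26 * n_det))
    n_all = min(n_any, max(1, round(0.019 * n_det)))
    n_conc = min(n_all, max(0, round(0.008 * n_det)))
    table = generate_condition_annotation(
        records, conditions, n_any=n_any, n_all=n_all, n_concordant=n_conc, seed=seed + 2
    )
    return ConditionAnnotation(records=table)


def _morphometry_inputs(cfg, seed):
    n = int(cfg.get("n_animals_per_group", 6))
    for gi, (group, params) in enumerate(cfg["morphometry_sim"].items()):
        pops = [
            generate_adipocytes(
                MorphometrySimSpec(
                    n_cells=int(params.get("n_cells", 300)),
                    mean_diameter_um=params["mean_diameter_um"],
                    sd_diameter_um=params["sd_diameter_um"],
                    depot_mass_g=params["depot_mass_g"],
                    animal_id=f"{group}_{j+1}",
                    seed=seed + 100 * (gi + 1) + j,
                )
            )
            for j in range(n)
        ]
        yield group, pops
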