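"""Relative quantification of qPCR data by the 2^ddCt method.

This implementation follows the inverted delta-Ct convention
dCT = reference Ct − gene Ct, under which a *larger* dCT means *higher*
expression (fewer cycles to threshold).  Per-sample relative expression is
2^(dCT − mean dCT of the RUN group), so RUN folds average 1 in log2 space;
group fold changes use the signed convention (negative reciprocal for
down-regulation) on group-mean relative expression, and p-values come from
an equal-variance t-test on the per-sample dCT values (log-scale, roughly
normal), not on the exponentiated folds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import _ttest_p, signed_fold_change
from .io_model import CtTable


def delta_ct(ref_ct: float, gene_ct: float) -> float:
    """Reference-minus-gene threshold cycle difference."""
    return ref_ct - gene_ct


def _delta_ct_frame(ct: CtTable) -> pd.DataFrame:
    """Long frame (sample_id, group, gene, dct) for all non-reference genes."""
    rec = ct.records
    ref = rec[rec["gene"] == ct.reference_gene].set_index("sample_id")["ct"]
    genes = rec[rec["gene"] != ct.reference_gene].copy()
    missing = set(genes["sample_id"]) - set(ref.index)
    if missing:
        raise ValueError(f"missing reference Ct for samples: {sorted(missing)}")
    genes["dct"] = genes["sample_id"].map(ref).to_numpy() - genes["ct"].to_numpy()
    return genes[["sample_id", "group", "gene", "dct"]]


def relative_expression(ct: CtTable) -> pd.DataFrame:
    """Per-sample, per-gene fold values normalized to the RUN group mean.

    Returns a frame (sample_id, group, gene, fold) with
    fold = 2^(dCT − mean over RUN samples of dCT for that gene); the
    geometric mean of RUN folds is 1 for every gene by construction.
    """
    dct = _delta_ct_frame(ct)
    run_mean = (
        dct[dct["group"] == "RUN"].groupby("gene")["dct"].mean().rename("run_mean_dct")
    )
    if run_mean.empty:
        raise ValueError("no RUN samples to normalize against")
    out = dct.merge(run_mean, on="gene")
    out["fold"] = 2.0 ** (out["dct"] - out["run_mean_dct"])
    return out[["sample_id", "group", "gene", "fold"]]


def group_fold(ct: CtTable, gene: str) -> tuple[float, float]:
    """Signed LOCK-vs-RUN fold change and t-test p-value for one gene.

    The fold is the signed ratio of group-mean relative expression; the
    p-value is from an equal-variance two-sided t-test on per-sample dCT.
    """
    rel = relative_expression(ct)
    rel = rel[rel["gene"] == gene]
    if rel.empty:
        raise KeyError(gene)
    mean_run = rel.loc[rel["group"] == "RUN", "fold"].mean()
    mean_lock = rel.loc[rel["group"] == "LOCK", "fold"].mean()
    fold = signed_fold_change(float(mean_run), float(mean_lock))

    dct = _delta_ct_frame(ct)
    dct = dct[dct["gene"] == gene]
    run = dct.loc[dct["group"] == "RUN", "dct"].to_numpy()
    lock = dct.loc[dct["group"] == "LOCK", "dct"].to_numpy()
    return fold, _ttest_p(run, lock)


def validation_table(ct: CtTable) -> pd.DataFrame:
    """Fold change and p-value for every target gene in the table."""
    rows = []
    for gene in ct.genes():
        fold, p = group_fold(ct, gene)
        rows.append({"gene": gene, "fold_change": fold, "p_value": p})
    return pd.DataFrame(rows, columns=["gene", "fold_change", "p_value"])
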