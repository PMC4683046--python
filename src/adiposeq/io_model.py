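"""Domain containers and tab-separated readers/writers shared by every stage.

The pipeline revolves around a transcripts-by-samples RPKM matrix for a
two-group design (RUN vs LOCK), a transcript-to-condition annotation table,
adipocyte diameter populations, and a qPCR Ct table.  All on-disk tables are
tab-delimited UTF-8 with '.' as the decimal separator; reading a table a
writer produced returns identical values field for field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("RUN", "LOCK")

DEPOTS = ("PRAT", "EAT", "OMAT")

#: Lipid density used to convert adipocyte volume (pl) to lipid mass (ng).
DEFAULT_LIPID_DENSITY_NG_PER_PL = 0.915


class TableFormatError(ValueError):
    """An input table violates the documented contract."""


@dataclass(frozen=True)
class FilterCriteria:
    """The four conjunctive significance criteria for calling a DET.

    A transcript is differentially expressed only if its BH-adjusted q-value
    is below ``fdr_max``, its raw p-value below ``p_max``, the magnitude of
    its signed fold change at least ``fc_min``, and its average RPKM (mean of
    the two group means) at least ``rpkm_min``.
    """

    fdr_max: float = 0.1
    p_max: float = 0.05
    fc_min: float = 1.5
    rpkm_min: float = 1.5

    def __post_init__(self) -> None:
        for name in ("fdr_max", "p_max", "fc_min", "rpkm_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.fc_min < 1:
            raise ValueError("fc_min must be >= 1 (signed fold changes have |fc| >= 1)")


@dataclass
class ExpressionMatrix:
    """RPKM expression matrix for a two-group design.

    Parameters
    ----------
    transcript_ids
        Unique transcript identifiers (row labels), case-sensitive.
    known
        Per-transcript flag: True for annotated ("known") transcripts.
    rpkm
        Non-negative array of shape (n_transcripts, n_samples).
    sample_ids
        Unique sample identifiers (column labels).
    group_of
        Mapping from each sample id to its group, ``"RUN"`` or ``"LOCK"``.
    """

    transcript_ids: list[str]
    known: np.ndarray
    rpkm: np.ndarray
    sample_ids: list[str]
    group_of: dict[str, str]

    def __post_init__(self) -> None:
        self.known = np.asarray(self.known, dtype=bool)
        self.rpkm = np.asarray(self.rpkm, dtype=float)
        n_t, n_s = len(self.transcript_ids), len(self.sample_ids)
        if self.rpkm.shape != (n_t, n_s):
            raise TableFormatError(
                f"rpkm shape {self.rpkm.shape} != ({n_t} transcripts, {n_s} samples)"
            )
        if self.known.shape != (n_t,):
            raise TableFormatError("known flag must have one entry per transcript")
        if len(set(self.transcript_ids)) != n_t:
            dupes = sorted({t for t in self.transcript_ids if self.transcript_ids.count(t) > 1})
            raise TableFormatError(f"duplicate transcript ids: {dupes[:5]}")
        if len(set(self.sample_ids)) != n_s:
            raise TableFormatError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.group_of]
        if missing:
            raise TableFormatError(f"samples without a group assignment: {missing}")
        bad_groups = {g for g in self.group_of.values() if g not in GROUPS}
        if bad_groups:
            raise TableFormatError(f"unknown group labels: {sorted(bad_groups)}")
        for g in GROUPS:
            if not self.samples_in(g):
                raise TableFormatError(f"group {g} has no samples")
        if np.isnan(self.rpkm).any() or (self.rpkm < 0).any():
            r, c = np.argwhere(np.isnan(self.rpkm) | (self.rpkm < 0))[0]
            raise TableFormatError(
                f"negative or missing RPKM at transcript {self.transcript_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group_of[s] == group]

    def columns_in(self, group: str) -> np.ndarray:
        members = set(self.samples_in(group))
        return np.array([i for i, s in enumerate(self.sample_ids) if s in members])

    def group_means(self, group: str) -> np.ndarray:
        """Per-transcript mean RPKM over the samples of one group."""
        cols = self.columns_in(group)
        if cols.size == 0:
            raise ValueError(f"group {group} has no samples")
        return self.rpkm[:, cols].mean(axis=1)

    def row(self, transcript_id: str) -> int:
        try:
            return self.transcript_ids.index(transcript_id)
        except ValueError:
            raise KeyError(transcript_id) from None

    def summary(self) -> dict[str, int]:
        """Counts used for the validate/summary report."""
        out = {
            "n_transcripts": len(self.transcript_ids),
            "n_known": int(self.known.sum()),
            "n_samples": len(self.sample_ids),
        }
        for g in GROUPS:
            expressed = self.known & (self.group_means(g) > 0)
            out[f"n_known_expressed_{g.lower()}"] = int(expressed.sum())
        return out


@dataclass(frozen=True)
class DifferentialRecord:
    """Per-transcript result of the differential-expression cascade."""

    transcript_id: str
    mean_run: float
    mean_lock: float
    fold_change: float
    p_value: float
    q_value: float
    average_rpkm: float
    significant: bool
    direction: str | None = None  # "up"/"down" when significant

    def __post_init__(self) -> None:
        if self.significant and self.direction not in ("up", "down"):
            raise ValueError("significant records need a direction")


@dataclass
class ConditionAnnotation:
    """Transcript-to-condition links with an expected regulation direction.

    Stands in for a pathway knowledge base: each record says a transcript is
    associated with a disease/condition and whether the condition's pathway
    expects the transcript up, down, or either ('any').
    """

    records: pd.DataFrame  # columns: transcript_id, condition, expected_direction

    _DIRECTIONS = ("up", "down", "any")

    def __post_init__(self) -> None:
        required = ["transcript_id", "condition", "expected_direction"]
        if list(self.records.columns) != required:
            self.records = self.records.loc[:, required]
        bad = set(self.records["expected_direction"]) - set(self._DIRECTIONS)
        if bad:
            raise TableFormatError(f"unknown expected_direction tokens: {sorted(bad)}")
        dup = self.records.duplicated(subset=["transcript_id", "condition"])
        if dup.any():
            pair = self.records.loc[dup.idxmax(), ["transcript_id", "condition"]]
            raise TableFormatError(
                f"duplicate (transcript, condition) pair: ({pair.iloc[0]}, {pair.iloc[1]})"
            )

    def conditions(self) -> set[str]:
        return set(self.records["condition"])

    def links_for(self, condition: str) -> pd.DataFrame:
        return self.records[self.records["condition"] == condition]


@dataclass
class AdipocytePopulation:
    """Measured adipocyte diameters for one depot of one animal."""

    animal_id: str
    depot: str
    diameters_um: np.ndarray
    depot_mass_g: float
    lipid_density_ng_per_pl: float = DEFAULT_LIPID_DENSITY_NG_PER_PL

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.depot not in DEPOTS:
            raise ValueError(f"depot must be one of {DEPOTS}, got {self.depot!r}")
        if self.diameters_um.size and (self.diameters_um <= 0).any():
            raise ValueError("diameters must be strictly positive")
        if not self.depot_mass_g > 0:
            raise ValueError("depot mass must be positive")
        if not self.lipid_density_ng_per_pl > 0:
            raise ValueError("lipid density must be positive")


@dataclass
class CtTable:
    """qPCR threshold-cycle values, one row per (sample, gene) after collapsing
    duplicate wells by mean Ct."""

    records: pd.DataFrame  # columns: sample_id, group, gene, ct
    reference_gene: str

    def __post_init__(self) -> None:
        required = ["sample_id", "group", "gene", "ct"]
        if list(self.records.columns) != required:
            self.records = self.records.loc[:, required]
        if not np.isfinite(self.records["ct"]).all():
            raise TableFormatError("non-finite Ct value")
        bad_groups = set(self.records["group"]) - set(GROUPS)
        if bad_groups:
            raise TableFormatError(f"unknown group labels: {sorted(bad_groups)}")
        # collapse duplicate wells
        self.records = (
            self.records.groupby(["sample_id", "group", "gene"], as_index=False, sort=False)
            .agg(ct=("ct", "mean"))
        )
        samples = set(self.records["sample_id"])
        with_ref = set(
            self.records.loc[self.records["gene"] == self.reference_gene, "sample_id"]
        )
        missing = samples - with_ref
        if missing:
            raise TableFormatError(
                f"reference gene {self.reference_gene!r} missing for samples: "
                f"{sorted(missing)}"
            )

    def genes(self) -> list[str]:
        return [g for g in self.records["gene"].unique() if g != self.reference_gene]


# ---------------------------------------------------------------------------
# readers / writers


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero at the given decimal place.

    Used for printed fold changes; stored values stay unrounded.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def read_expression_table(path: str | Path, group_map: Mapping[str, str]) -> ExpressionMatrix:
    """Read a ``transcript_id  known  <sample...>`` TSV into an ExpressionMatrix.

    ``group_map`` must assign every sample column to RUN or LOCK.  Row order
    is preserved.  Violations are rejected with row/column coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str}, float_precision="round_trip")
    if df.columns[0] != "transcript_id" or df.columns[1] != "known":
        raise TableFormatError(
            f"expected header starting 'transcript_id\\tknown', got {list(df.columns[:2])}"
        )
    sample_ids = list(df.columns[2:])
    unassigned = [s for s in sample_ids if s not in group_map]
    if unassigned:
        raise TableFormatError(f"sample columns without a group: {unassigned}")
    known = df["known"].astype(str).str.lower().isin(["true", "1", "yes"]).to_numpy()
    rpkm = df[sample_ids].to_numpy(dtype=float)
    return ExpressionMatrix(
        transcript_ids=list(df["transcript_id"]),
        known=known,
        rpkm=rpkm,
        sample_ids=sample_ids,
        group_of={s: group_map[s] for s in sample_ids},
    )


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.rpkm, columns=matrix.sample_ids)
    df.insert(0, "known", matrix.known)
    df.insert(0, "transcript_id", matrix.transcript_ids)
    df.to_csv(path, sep="\t", index=False)


def read_annotation_table(path: str | Path) -> ConditionAnnotation:
    """Read a ``transcript_id  condition  expected_direction`` TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["transcript_id", "condition", "expected_direction"]
    if list(df.columns) != required:
        raise TableFormatError(f"expected columns {required}, got {list(df.columns)}")
    return ConditionAnnotation(records=df)


def write_annotation_table(ann: ConditionAnnotation, path: str | Path) -> None:
    ann.records.to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = [
    "transcript_id",
    "fold_change",
    "mean_run",
    "mean_lock",
    "p_value",
    "q_value",
    "average_rpkm",
    "significant",
    "direction",
]


def write_results_table(records: Sequence[DifferentialRecord], path: str | Path) -> None:
    """Write differential records as TSV, fold change printed to 3 decimals
    (half-up), sorted by |fold change| descending within direction (up first).
    """
    ordered = sorted(
        records, key=lambda r: (0 if r.fold_change > 0 else 1, -abs(r.fold_change))
    )
    rows = []
    for r in ordered:
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "fold_change": f"{round_half_up(r.fold_change, 3):.3f}",
                "mean_run": repr(r.mean_run),
                "mean_lock": repr(r.mean_lock),
                "p_value": repr(r.p_value),
                "q_value": repr(r.q_value),
                "average_rpkm": repr(r.average_rpkm),
                "significant": r.significant,
                "direction": r.direction or "",
            }
        )
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> list[DifferentialRecord]:
    """Read a results TSV back into records.

    The file prints fold change rounded to 3 decimals; the unrounded value is
    recovered from the full-precision group means so write→read is the
    identity on stored values.
    """
    from .differential import signed_fold_change  # local import: avoids a cycle

    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "direction": str},
        float_precision="round_trip",
    )
    out = []
    for _, row in df.iterrows():
        direction = row.get("direction")
        if direction is None or (isinstance(direction, float) and math.isnan(direction)):
            direction = None
        mean_run, mean_lock = float(row["mean_run"]), float(row["mean_lock"])
        out.append(
            DifferentialRecord(
                transcript_id=row["transcript_id"],
                mean_run=mean_run,
                mean_lock=mean_lock,
                fold_change=signed_fold_change(mean_run, mean_lock),
                p_value=float(row["p_value"]),
                q_value=float(row["q_value"]),
                average_rpkm=float(row["average_rpkm"]),
                significant=bool(row["significant"]),
                direction=direction,
            )
        )
    return out


def read_diameter_tables(
    diameters_path: str | Path,
    masses_path: str | Path,
    lipid_density_ng_per_pl: float = DEFAULT_LIPID_DENSITY_NG_PER_PL,
) -> list[AdipocytePopulation]:
    """Read per-cell diameters (animal_id, depot, diameter_um) plus per-depot
    masses (animal_id, depot, mass_g) into AdipocytePopulation objects."""
    diam = pd.read_csv(diameters_path, sep="\t", dtype={"animal_id": str, "depot": str})
    mass = pd.read_csv(masses_path, sep="\t", dtype={"animal_id": str, "depot": str})
    mass_of = {(r.animal_id, r.depot): r.mass_g for r in mass.itertuples()}
    pops = []
    for (animal, depot), grp in diam.groupby(["animal_id", "depot"], sort=False):
        key = (animal, depot)
        if key not in mass_of:
            raise TableFormatError(f"no depot mass for animal {animal!r}, depot {depot!r}")
        pops.append(
            AdipocytePopulation(
                animal_id=animal,
                depot=depot,
                diameters_um=grp["diameter_um"].to_numpy(dtype=float),
                depot_mass_g=float(mass_of[key]),
                lipid_density_ng_per_pl=lipid_density_ng_per_pl,
            )
        )
    return pops


def read_ct_table(path: str | Path, reference_gene: str) -> CtTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str, "gene": str})
    return CtTable(records=df, reference_gene=reference_gene)


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.records.to_csv(path, sep="\t", index=False)
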