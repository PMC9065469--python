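"""Experimental evidence streams: binding affinities and differential genes.

Two independent streams back up the predicted compound–target interactions:

* **Direct**: curated binding-affinity records (ChEMBL-style rows of
  compound, target, measure type, value in nM). Only Kd and IC50 records
  below 10 µM (strictly) count as verified interactions.
* **Indirect**: two-group expression data (control vs compound-treated). A
  gene is called differential for a compound when a Welch two-sample t-test
  on log2(intensity + 1) gives p < 0.05 and the linear-scale fold change
  (treated mean / control mean) is at least two-fold in either direction —
  the two-fold bound is inclusive (≥ 2 or ≤ 0.5). p-values are unadjusted.

Both streams are finally mapped onto the potential-target set, flagging each
target for affinity and/or transcriptome support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

MEASURES = ("IC50", "Kd", "Ki", "EC50", "other")
AFFINITY_MEASURES = frozenset({"IC50", "Kd"})


@dataclass(frozen=True)
class InteractionRecord:
    compound_id: str
    target_id: str
    measure: str
    value_nm: float
    source: str = ""

    def __post_init__(self):
        if self.value_nm <= 0:
            raise InputError(f"non-positive affinity for {self.target_id}: {self.value_nm}")
        if self.measure not in MEASURES:
            raise InputError(f"unknown measure {self.measure!r}")


@dataclass(frozen=True)
class DifferentialGene:
    gene: str
    compound_id: str
    fold_change: float
    p_value: float
    direction: str  # up | down


@dataclass
class ExpressionMatrix:
    """Linear-scale intensities (genes × samples) with group labels."""

    values: pd.DataFrame  # index: gene symbols, columns: sample ids
    sample_groups: pd.DataFrame  # index: sample ids; columns: group, compound_id

    def samples_for(self, group: str, compound_id: str | None = None) -> list[str]:
        sel = self.sample_groups["group"] == group
        if compound_id is not None:
            sel &= self.sample_groups["compound_id"] == compound_id
        return list(self.sample_groups.index[sel])

    @property
    def treated_compounds(self) -> list[str]:
        treated = self.sample_groups[self.sample_groups["group"] == "treated"]
        return sorted(set(treated["compound_id"]))


@dataclass
class TargetEvidence:
    """Per-target collection of affinity and differential-expression records."""

    target_id: str
    affinity_records: list[InteractionRecord] = field(default_factory=list)
    de_records: list[DifferentialGene] = field(default_factory=list)

    @property
    def has_affinity_evidence(self) -> bool:
        return bool(self.affinity_records)

    @property
    def has_de_evidence(self) -> bool:
        return bool(self.de_records)


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Read a compound–target affinity TSV (values declared in nM).

    Columns: compound_id, target_id, measure, value_nm, source (optional).
    Rows with a non-numeric or non-positive value, or an unknown measure
    type, are rejected and logged.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["compound_id", "target_id", "measure", "value_nm"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path.name}: missing interaction column(s) {missing}")
    records: list[InteractionRecord] = []
    for i, row in frame.iterrows():
        try:
            value = float(row["value_nm"])
            rec = InteractionRecord(
                compound_id=row["compound_id"],
                target_id=row["target_id"].upper(),
                measure=row["measure"],
                value_nm=value,
                source=row.get("source", ""),
            )
        except (ValueError, InputError) as exc:
            logger.warning("%s row %d rejected: %s", path.name, int(i) + 2, exc)
            continue
        records.append(rec)
    return records


def filter_known_interactions(
    records: Iterable[InteractionRecord], max_nm: float = 10000.0
) -> list[InteractionRecord]:
    """Keep credible interactions: Kd or IC50 strictly below ``max_nm``."""
    return [
        r for r in records if r.measure in AFFINITY_MEASURES and r.value_nm < max_nm
    ]


def read_expression_matrix(
    expression_path: str | Path, sample_map_path: str | Path
) -> ExpressionMatrix:
    """Read an expression TSV (gene × samples) plus its sample-map TSV.

    Sample map columns: sample_id, group (control|treated), compound_id
    (empty for controls). A sample without a mapping is fatal. Duplicate
    gene rows are collapsed by mean with a warning.
    """
    expression_path = Path(expression_path)
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.upper()
    if values.index.has_duplicates:
        n_dup = int(values.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows collapsed by mean", expression_path.name, n_dup)
        values = values.groupby(level=0).mean()

    sample_map = pd.read_csv(sample_map_path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "group"]
    missing = [c for c in required if c not in sample_map.columns]
    if missing:
        raise InputError(f"sample map: missing column(s) {missing}")
    if "compound_id" not in sample_map.columns:
        sample_map["compound_id"] = ""
    sample_map = sample_map.set_index("sample_id")
    unmapped = [s for s in values.columns if s not in sample_map.index]
    if unmapped:
        raise InputError(f"samples without group mapping: {unmapped}")
    bad_groups = set(sample_map["group"]) - {"control", "treated"}
    if bad_groups:
        raise InputError(f"unknown sample groups: {sorted(bad_groups)}")
    return ExpressionMatrix(values=values, sample_groups=sample_map.loc[list(values.columns)])


def differential_expression_table(
    mat: ExpressionMatrix, compound_id: str
) -> pd.DataFrame:
    """Per-gene Welch t-test (log2 scale) and linear fold change for one contrast.

    Genes with a missing value in any sample of the contrast are dropped and
    logged. Zero variance in both groups gives p = 1 when the means agree
    (no evidence of change) and p = 0 when they differ exactly.
    """
    control = mat.samples_for("control")
    treated = mat.samples_for("treated", compound_id)
    if len(control) < 2 or len(treated) < 2:
        raise InputError(
            f"contrast {compound_id}: need ≥2 samples per group "
            f"(control={len(control)}, treated={len(treated)})"
        )
    sub = mat.values[control + treated]
    complete = sub.notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("contrast %s: %d genes with missing values dropped", compound_id, n_dropped)
    sub = sub[complete]

    ctrl = sub[control].to_numpy(dtype=float)
    trt = sub[treated].to_numpy(dtype=float)
    log_ctrl = np.log2(ctrl + 1.0)
    log_trt = np.log2(trt + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(log_trt, log_ctrl, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    mean_ctrl = ctrl.mean(axis=1)
    mean_trt = trt.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_ctrl > 0, mean_trt / mean_ctrl, np.inf)

    # degenerate: zero variance in both groups -> nan from Welch
    degenerate = np.isnan(p)
    if degenerate.any():
        equal = np.isclose(log_trt.mean(axis=1), log_ctrl.mean(axis=1))
        p[degenerate & equal] = 1.0
        p[degenerate & ~equal] = 0.0

    return pd.DataFrame(
        {
            "gene": sub.index,
            "compound_id": compound_id,
            "mean_control": mean_ctrl,
            "mean_treated": mean_trt,
            "fold_change": fc,
            "p_value": p,
        }
    ).reset_index(drop=True)


def call_differential_genes(
    mat: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
) -> list[DifferentialGene]:
    """Call differential genes for every treated compound in the matrix.

    A gene is differential iff p < ``alpha`` and the fold change is
    ≥ ``fc_threshold`` (up) or ≤ 1/``fc_threshold`` (down), bounds inclusive.
    """
    calls: list[DifferentialGene] = []
    for compound_id in mat.treated_compounds:
        table = differential_expression_table(mat, compound_id)
        sig = table[table["p_value"] < alpha]
        for _, row in sig.iterrows():
            fc = float(row["fold_change"])
            if fc >= fc_threshold:
                direction = "up"
            elif fc <= 1.0 / fc_threshold:
                direction = "down"
            else:
                continue
            calls.append(
                DifferentialGene(
                    gene=str(row["gene"]),
                    compound_id=compound_id,
                    fold_change=fc,
                    p_value=float(row["p_value"]),
                    direction=direction,
                )
            )
    return calls


def read_de_table(path: str | Path) -> list[DifferentialGene]:
    """Read a differential-gene TSV (gene, compound_id, fold_change, p_value).

    The direction column, if absent, is derived from the fold change with
    the inclusive two-fold convention.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"gene": str, "compound_id": str})
    records = []
    for _, row in frame.iterrows():
        fc = float(row["fold_change"])
        direction = row.get("direction")
        if not isinstance(direction, str):
            direction = "up" if fc >= 2.0 else "down"
        records.append(
            DifferentialGene(
                gene=str(row["gene"]).upper(),
                compound_id=str(row["compound_id"]),
                fold_change=fc,
                p_value=float(row["p_value"]),
                direction=direction,
            )
        )
    return records


def de_to_frame(calls: Sequence[DifferentialGene]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [c.gene for c in calls],
            "compound_id": [c.compound_id for c in calls],
            "fold_change": [round(c.fold_change, 4) for c in calls],
            "p_value": [c.p_value for c in calls],
            "direction": [c.direction for c in calls],
        }
    )


def map_evidence_to_targets(
    interactions: Iterable[InteractionRecord],
    de_genes: Iterable[DifferentialGene],
    target_ids: Iterable[str],
) -> dict[str, TargetEvidence]:
    """Attach both evidence streams to each target of interest."""
    evidence = {str(t).upper(): TargetEvidence(target_id=str(t).upper()) for t in target_ids}
    for rec in interactions:
        if rec.target_id in evidence:
            evidence[rec.target_id].affinity_records.append(rec)
    for de in de_genes:
        if de.gene in evidence:
            evidence[de.gene].de_records.append(de)
    return evidence
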