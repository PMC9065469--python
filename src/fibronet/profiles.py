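"""Per-target aggregation and filtering of compound→target prediction scores.

Ligand-based target prediction services (SwissTargetPrediction-style) emit,
per query compound, a ranked table of candidate protein targets with a
probability-like score in [0, 1]. This module merges such tables, restricts
them to the compounds retained in the activity network, aggregates them into
one profile per target (arithmetic mean score over the predicting compounds,
plus the supporting-compound set), and applies the two consensus filters
that define the potential-target set: mean score strictly above ``min_mean``
(default 0.1) and support from at least ``min_support`` compounds (default
3, i.e. "more than two").

Targets are keyed by upper-cased gene symbol; no ortholog mapping is done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError

logger = logging.getLogger(__name__)

TARGET_CLASSES = ("enzyme", "gpcr", "nuclear_receptor", "ion_channel", "other")

PREDICTION_COLUMNS = ("compound_id", "target_id", "score")


@dataclass(frozen=True)
class TargetProfile:
    """Aggregate of prediction scores for one target."""

    target_id: str
    mean_score: float
    supporting_compounds: frozenset[str]
    target_class: str = "other"

    @property
    def n_support(self) -> int:
        return len(self.supporting_compounds)

    @property
    def rank_key(self) -> tuple[float, int]:
        return (self.mean_score, self.n_support)


def read_prediction_tables(paths: Iterable[str | Path]) -> pd.DataFrame:
    """Read and merge per-compound target prediction TSVs.

    Expected columns: ``compound_id``, ``target_id``, ``score`` and an
    optional ``target_class``. Rows with a score outside [0, 1] are rejected
    (logged); duplicate (compound, target) pairs keep the maximum score with
    a warning.
    """
    frames = []
    for path in paths:
        path = Path(path)
        frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str, "target_id": str})
        missing = [c for c in PREDICTION_COLUMNS if c not in frame.columns]
        if missing:
            raise InputError(f"{path.name}: missing prediction column(s) {missing}")
        if "target_class" not in frame.columns:
            frame["target_class"] = "other"
        frames.append(frame[["compound_id", "target_id", "score", "target_class"]])
    if not frames:
        raise InputError("no prediction tables supplied")
    merged = pd.concat(frames, ignore_index=True)
    merged["target_id"] = merged["target_id"].str.upper()
    merged["score"] = pd.to_numeric(merged["score"], errors="coerce")

    bad = merged["score"].isna() | (merged["score"] < 0) | (merged["score"] > 1)
    if bad.any():
        logger.warning("rejected %d prediction rows with score outside [0, 1]", int(bad.sum()))
        merged = merged[~bad]

    merged["target_class"] = merged["target_class"].where(
        merged["target_class"].isin(TARGET_CLASSES), "other"
    )

    n_before = len(merged)
    merged = (
        merged.sort_values("score", ascending=False)
        .drop_duplicates(subset=["compound_id", "target_id"], keep="first")
        .sort_index()
        .reset_index(drop=True)
    )
    if len(merged) < n_before:
        logger.warning(
            "%d duplicate (compound, target) rows collapsed keeping max score",
            n_before - len(merged),
        )
    return merged


def aggregate_target_profiles(
    predictions: pd.DataFrame, restrict_to: Iterable[str]
) -> list[TargetProfile]:
    """One profile per target over the compounds in ``restrict_to`` only.

    ``restrict_to`` is normally the activity-network compound set (seeds +
    candidates); predictions from compounds outside it are ignored.
    """
    keep = set(restrict_to)
    if not keep:
        logger.warning("empty compound restriction: no target profiles produced")
        return []
    sub = predictions[predictions["compound_id"].isin(keep)]
    profiles = []
    for target_id, grp in sub.groupby("target_id", sort=True):
        classes = grp["target_class"].mode()
        profiles.append(
            TargetProfile(
                target_id=str(target_id),
                mean_score=float(grp["score"].mean()),
                supporting_compounds=frozenset(grp["compound_id"]),
                target_class=str(classes.iloc[0]) if len(classes) else "other",
            )
        )
    return profiles


def filter_target_profiles(
    profiles: Sequence[TargetProfile],
    min_mean: float = 0.1,
    min_support: int = 3,
) -> list[TargetProfile]:
    """Keep targets with mean score > ``min_mean`` and support ≥ ``min_support``.

    Both rules mirror the consensus cutoffs: the score bound is strict, and
    "more than two supporting compounds" means at least three.
    """
    return [
        p for p in profiles if p.mean_score > min_mean and p.n_support >= min_support
    ]


def classify_target_types(profiles: Sequence[TargetProfile]) -> dict[str, int]:
    """Histogram of target classes; unannotated targets count as 'other'."""
    hist = {k: 0 for k in TARGET_CLASSES}
    for p in profiles:
        cls = p.target_class if p.target_class in TARGET_CLASSES else "other"
        if cls != p.target_class:
            logger.warning("target %s: unknown class %r counted as 'other'", p.target_id, p.target_class)
        hist[cls] += 1
    return hist


def profiles_to_frame(profiles: Sequence[TargetProfile]) -> pd.DataFrame:
    """Tabular form: mean_score to 6 dp, supports semicolon-joined."""
    return pd.DataFrame(
        {
            "target_id": [p.target_id for p in profiles],
            "mean_score": [round(p.mean_score, 6) for p in profiles],
            "n_support": [p.n_support for p in profiles],
            "supporting_compounds": [";".join(sorted(p.supporting_compounds)) for p in profiles],
            "target_class": [p.target_class for p in profiles],
        }
    )
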