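"""Contradiction-aware triage and ranking of candidate targets.

Within a chosen pathway, each candidate target is annotated with three
directions of information:

* ``compound_action`` — what the compounds do to the target. Affinity
  records are inhibition assays unless stated otherwise, so any retained
  affinity record means "inhibits".
* ``transcriptome_direction`` — how treatment moved the target's transcript
  (up/down; conflicting contrasts flag both).
* ``desired_modulation`` — the curated literature direction in which
  perturbing the target should benefit the disease (inhibit_beneficial,
  activate_beneficial, or unknown).

Four ordered exclusion rules formalize the triage:

1. no curated disease link → ``excluded_no_disease_link``;
2. the compounds inhibit a target whose *activation* is beneficial →
   ``excluded_contradiction``;
3. inhibition is beneficial, the compounds inhibit the target, yet treatment
   *up*-regulates it → ``excluded_contradiction`` (the evidence streams
   disagree with each other);
4. inhibition is beneficial and treatment up-regulates the target with no
   direct binding evidence → ``excluded_contradiction`` (the transcriptome
   moves opposite to the needed direction).

Anything else is retained. Candidates with no evidence at all are not run
through the rules: with a known disease link they are retained by default,
otherwise they land in a separate ``unassessed`` bucket and are never
ranked. Retained candidates are ordered by (mean prediction score desc,
supporting-compound count desc, symbol asc).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InputError
from .evidence import TargetEvidence
from .profiles import TargetProfile

logger = logging.getLogger(__name__)

MODULATIONS = ("inhibit_beneficial", "activate_beneficial", "unknown")
VERDICTS = ("retained", "excluded_no_disease_link", "excluded_contradiction", "unassessed")


@dataclass(frozen=True)
class DiseaseLink:
    """Curated direction in which modulating a target benefits the disease."""

    target_id: str
    desired_modulation: str
    citation: str = ""

    def __post_init__(self):
        if self.desired_modulation not in MODULATIONS:
            raise InputError(
                f"{self.target_id}: unknown modulation {self.desired_modulation!r}"
            )


@dataclass(frozen=True)
class TargetCandidate:
    """One target's direction-annotated evidence and triage verdict."""

    target_id: str
    compound_action: str  # inhibits | activates | none
    transcriptome_directions: frozenset[str]  # subset of {up, down}
    desired_modulation: str
    verdict: str | None = None
    mean_score: float = 0.0
    n_support: int = 0

    @property
    def transcriptome_direction(self) -> str:
        if self.transcriptome_directions == {"up", "down"}:
            return "conflict"
        if self.transcriptome_directions:
            return next(iter(self.transcriptome_directions))
        return "none"

    @property
    def has_evidence(self) -> bool:
        return self.compound_action != "none" or bool(self.transcriptome_directions)

    @property
    def rank_key(self) -> tuple[float, int]:
        return (self.mean_score, self.n_support)


def read_disease_links(path: str | Path) -> dict[str, DiseaseLink]:
    """Read the curated disease-link TSV (target_id, desired_modulation, citation)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("target_id", "desired_modulation") if c not in frame.columns]
    if missing:
        raise InputError(f"disease links: missing column(s) {missing}")
    links: dict[str, DiseaseLink] = {}
    for _, row in frame.iterrows():
        link = DiseaseLink(
            target_id=row["target_id"].upper(),
            desired_modulation=row["desired_modulation"],
            citation=row.get("citation", ""),
        )
        if link.target_id in links:
            raise InputError(f"duplicate disease link for {link.target_id}")
        links[link.target_id] = link
    return links


def assign_direction(
    evidence: Mapping[str, TargetEvidence],
    links: Mapping[str, DiseaseLink],
    profiles: Mapping[str, TargetProfile] | None = None,
) -> list[TargetCandidate]:
    """Build direction-annotated candidates from the evidence summaries."""
    profiles = profiles or {}
    candidates = []
    for target_id in sorted(evidence):
        ev = evidence[target_id]
        action = "inhibits" if ev.has_affinity_evidence else "none"
        directions = frozenset(d.direction for d in ev.de_records)
        if directions == frozenset({"up", "down"}):
            logger.warning("target %s: conflicting transcriptome directions", target_id)
        link = links.get(target_id)
        profile = profiles.get(target_id)
        candidates.append(
            TargetCandidate(
                target_id=target_id,
                compound_action=action,
                transcriptome_directions=directions,
                desired_modulation=link.desired_modulation if link else "unknown",
                mean_score=profile.mean_score if profile else 0.0,
                n_support=profile.n_support if profile else 0,
            )
        )
    return candidates


def detect_contradictions(candidate: TargetCandidate) -> str:
    """Apply the ordered exclusion rules; returns the verdict string."""
    if not candidate.has_evidence:
        return "retained" if candidate.desired_modulation != "unknown" else "unassessed"
    up = "up" in candidate.transcriptome_directions
    if candidate.desired_modulation == "unknown":
        return "excluded_no_disease_link"
    if (
        candidate.compound_action == "inhibits"
        and candidate.desired_modulation == "activate_beneficial"
    ):
        return "excluded_contradiction"
    if (
        candidate.desired_modulation == "inhibit_beneficial"
        and up
        and candidate.compound_action == "inhibits"
    ):
        return "excluded_contradiction"
    if (
        candidate.desired_modulation == "inhibit_beneficial"
        and up
        and candidate.compound_action == "none"
    ):
        return "excluded_contradiction"
    return "retained"


def triage_targets(candidates: Sequence[TargetCandidate]) -> list[TargetCandidate]:
    """Assign a verdict to every candidate (a total partition)."""
    return [replace(c, verdict=detect_contradictions(c)) for c in candidates]


def prioritize_targets(
    candidates: Sequence[TargetCandidate],
    profiles: Mapping[str, TargetProfile] | None = None,
) -> list[TargetCandidate]:
    """Rank the retained candidates.

    Order: mean prediction score descending, supporting-compound count
    descending, then target symbol ascending as the final tiebreak. An empty
    retained set returns an empty list (logged).
    """
    ranked = []
    for cand in candidates:
        if cand.verdict != "retained":
            continue
        if profiles and cand.target_id in profiles:
            prof = profiles[cand.target_id]
            cand = replace(cand, mean_score=prof.mean_score, n_support=prof.n_support)
        ranked.append(cand)
    if not ranked:
        logger.warning("no retained candidates to rank")
        return []
    ranked.sort(key=lambda c: (-c.mean_score, -c.n_support, c.target_id))
    return ranked


def candidates_to_frame(candidates: Sequence[TargetCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target_id": [c.target_id for c in candidates],
            "compound_action": [c.compound_action for c in candidates],
            "transcriptome_direction": [c.transcriptome_direction for c in candidates],
            "desired_modulation": [c.desired_modulation for c in candidates],
            "verdict": [c.verdict for c in candidates],
            "mean_score": [round(c.mean_score, 6) for c in candidates],
            "n_support": [c.n_support for c in candidates],
        }
    )
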