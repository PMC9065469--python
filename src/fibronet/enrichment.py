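"""Over-representation analysis with BH-FDR and two-stage evidence filtering.

Stage one is the standard hypergeometric (one-sided Fisher) enrichment of the
potential-target set against pathway/disease gene-set collections: for a set
with K members in a background of N genes and a query of n targets, the
p-value is P(X ≥ k) for the observed overlap k. Benjamini–Hochberg step-up
correction is applied separately within each set category (pathway vs
disease), and a set is significant when FDR < alpha and the overlap holds at
least ``min_overlap`` targets ("more than two" → ≥ 3).

Stage two keeps only sets whose overlap is independently supported by
experimental evidence: more than 10 potential targets, more than one
affinity-verified known target, and more than 10% of the overlap re-found as
differential genes. All three bounds are strict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ContractError, InputError

logger = logging.getLogger(__name__)

SET_CATEGORIES = ("pathway", "disease")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    set_name: str
    category: str  # pathway | disease
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise InputError(f"gene set {self.set_id!r} is empty")


@dataclass
class EnrichmentResult:
    """One gene set's overlap, significance, and evidence counts."""

    set_id: str
    set_name: str
    category: str
    n_overlap: int
    overlap_ids: frozenset[str]
    p_value: float
    fdr: float = float("nan")
    significant: bool = False
    n_known_targets: int = 0
    n_known_de_genes: int = 0
    kept: bool = False

    @property
    def de_fraction(self) -> float:
        return self.n_known_de_genes / self.n_overlap if self.n_overlap else 0.0


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT collection (set_id TAB description TAB member...).

    The description field may carry ``category=pathway|disease``; otherwise
    the category defaults to pathway. Malformed lines and empty sets are
    dropped with a log entry; members are upper-cased and deduplicated.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as handle:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning("%s line %d: malformed GMT line dropped", path.name, line_no)
                continue
            set_id, desc = parts[0], parts[1]
            members = frozenset(m.strip().upper() for m in parts[2:] if m.strip())
            if not members:
                logger.warning("%s line %d: empty set %r dropped", path.name, line_no, set_id)
                continue
            category = "pathway"
            for token in desc.split(";"):
                token = token.strip()
                if token.startswith("category="):
                    value = token.split("=", 1)[1]
                    if value in SET_CATEGORIES:
                        category = value
            sets.append(GeneSet(set_id=set_id, set_name=desc, category=category, members=members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for gs in sets:
            handle.write(
                "\t".join([gs.set_id, gs.set_name, *sorted(gs.members)]) + "\n"
            )
    return path


def hypergeometric_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X ≥ k).

    Null model: draw ``n`` genes from a background of ``N`` containing ``K``
    set members; ``k`` is the observed overlap.
    """
    if not (0 <= k <= min(n, K) and K <= N and n <= N):
        raise ContractError(
            f"invalid hypergeometric urn: k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ContractError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def enrich_sets(
    target_ids: Iterable[str],
    sets: Sequence[GeneSet],
    background: Iterable[str] | None = None,
    fdr_alpha: float = 0.05,
    min_overlap: int = 3,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of the target set against each gene set.

    The background defaults to the union of all set members. Query targets
    outside the background are dropped with a warning (they cannot have been
    drawn from the urn). BH correction runs separately per category.
    """
    targets = {str(t).upper() for t in target_ids}
    if background is None:
        bg: set[str] = set().union(*(gs.members for gs in sets)) if sets else set()
    else:
        bg = {str(g).upper() for g in background}
        for gs in sets:
            outside = gs.members - bg
            if outside:
                logger.warning(
                    "set %s: %d members outside background dropped", gs.set_id, len(outside)
                )
    if not bg:
        raise InputError("empty background gene universe")

    query = targets & bg
    dropped = len(targets) - len(query)
    if dropped:
        logger.warning("%d query targets outside background dropped", dropped)

    N, n = len(bg), len(query)
    results: list[EnrichmentResult] = []
    for gs in sets:
        members = gs.members & bg
        if not members:
            continue
        overlap = members & query
        p = hypergeometric_test(len(overlap), n, len(members), N)
        results.append(
            EnrichmentResult(
                set_id=gs.set_id,
                set_name=gs.set_name,
                category=gs.category,
                n_overlap=len(overlap),
                overlap_ids=frozenset(overlap),
                p_value=p,
            )
        )
    for category in SET_CATEGORIES:
        idx = [i for i, r in enumerate(results) if r.category == category]
        if not idx:
            continue
        q = bh_fdr([results[i].p_value for i in idx])
        for i, qi in zip(idx, q):
            results[i].fdr = float(qi)
            results[i].significant = bool(
                qi < fdr_alpha and results[i].n_overlap >= min_overlap
            )
    return results


def apply_evidence_filter(
    results: Sequence[EnrichmentResult],
    known_targets: Iterable[str],
    known_de: Iterable[str],
    min_overlap: int = 11,
    min_known: int = 2,
    min_de_frac: float = 0.10,
) -> list[EnrichmentResult]:
    """Annotate evidence counts on every result and return the kept subset.

    Keep iff n_overlap ≥ ``min_overlap`` (i.e. more than 10 at the default),
    known-target count ≥ ``min_known`` (more than one), and DE fraction
    strictly above ``min_de_frac`` — the fraction's denominator is the
    overlap size, so it asks how much of the predicted overlap is re-found
    differentially expressed.
    """
    known = {str(t).upper() for t in known_targets}
    de = {str(g).upper() for g in known_de}
    kept: list[EnrichmentResult] = []
    for res in results:
        res.n_known_targets = len(res.overlap_ids & known)
        res.n_known_de_genes = len(res.overlap_ids & de)
        res.kept = (
            res.n_overlap >= min_overlap
            and res.n_known_targets >= min_known
            and res.de_fraction > min_de_frac
        )
        if res.kept:
            kept.append(res)
    return kept


def results_to_frame(results: Sequence[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.set_name for r in results],
            "category": [r.category for r in results],
            "n_overlap": [r.n_overlap for r in results],
            "overlap_ids": [";".join(sorted(r.overlap_ids)) for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "significant": [r.significant for r in results],
            "n_known_targets": [r.n_known_targets for r in results],
            "n_known_de_genes": [r.n_known_de_genes for r in results],
            "de_fraction": [round(r.de_fraction, 6) for r in results],
            "kept": [r.kept for r in results],
        }
    )
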