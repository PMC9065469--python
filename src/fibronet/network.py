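"""Seed-anchored compound similarity network (ECFP4 / Tanimoto).

Compounds are fingerprinted with extended-connectivity circular fingerprints
of diameter 4 (Morgan radius 2) hashed to 2048 bits, the standard ECFP4
realization. Pairwise structural similarity is the Tanimoto coefficient
|A∩B| / |A∪B| over the on-bits. The activity network links every pair of
compounds whose similarity strictly exceeds the threshold tau (default 0.5),
but only pairs involving at least one seed: the expansion is seed-centric,
so a non-seed enters the network only if it resembles a known active
(guilt-by-association), and candidate–candidate edges are off by default
(``include_candidate_edges`` flips that policy).

Degenerate case: two empty fingerprints give 0/0 in the Tanimoto formula;
the convention here is similarity 1.0 (identically featureless), logged as a
warning when it occurs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from rdkit.DataStructs.cDataStructs import ExplicitBitVect

from .errors import ConfigError, ContractError, InputError
from .library import Compound, CompoundLibrary, mol_from_smiles

logger = logging.getLogger(__name__)

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 2048


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary substructure fingerprint."""

    bits: ExplicitBitVect

    @property
    def n_bits(self) -> int:
        return self.bits.GetNumBits()

    @property
    def n_on(self) -> int:
        return self.bits.GetNumOnBits()

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(self.bits.GetOnBits())


@dataclass(frozen=True, order=True)
class SimilarityEdge:
    """Undirected similarity edge, ids stored in lexicographic order."""

    source_id: str
    target_id: str
    similarity: float

    @staticmethod
    def make(a: str, b: str, similarity: float) -> "SimilarityEdge":
        lo, hi = sorted((a, b))
        return SimilarityEdge(lo, hi, float(similarity))


@dataclass
class ActivityNetwork:
    """Seed + candidate nodes with similarity edges above tau."""

    seed_ids: list[str]
    candidate_ids: list[str]
    edges: list[SimilarityEdge]
    tau: float
    include_candidate_edges: bool = False

    @property
    def node_ids(self) -> list[str]:
        return list(self.seed_ids) + list(self.candidate_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.seed_ids) + len(self.candidate_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self, lib: CompoundLibrary | None = None) -> nx.Graph:
        graph = nx.Graph(tau=self.tau)
        for nid in self.seed_ids:
            graph.add_node(nid, is_seed=True)
        for nid in self.candidate_ids:
            graph.add_node(nid, is_seed=False)
        if lib is not None:
            for nid in self.node_ids:
                graph.nodes[nid]["compound_class"] = lib.get(nid).compound_class
        for edge in self.edges:
            graph.add_edge(edge.source_id, edge.target_id, similarity=edge.similarity)
        return graph


def compute_fingerprint(
    compound: Compound | str,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> Fingerprint:
    """ECFP-style circular fingerprint for one compound (or raw SMILES).

    Deterministic on structure: any SMILES notation of the same molecule
    yields identical bits.
    """
    if isinstance(compound, Compound):
        smiles, label = compound.smiles, compound.compound_id
    else:
        smiles, label = compound, compound
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise InputError(f"fingerprint failed: unparsable SMILES for {label!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return Fingerprint(bits=gen.GetFingerprint(mol))


def tanimoto_similarity(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient of two equal-length fingerprints."""
    if a.n_bits != b.n_bits:
        raise ContractError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    if a.n_on == 0 and b.n_on == 0:
        logger.warning("two empty fingerprints compared; similarity defined as 1.0")
        return 1.0
    return float(DataStructs.TanimotoSimilarity(a.bits, b.bits))


def fingerprint_library(
    lib: CompoundLibrary, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> dict[str, Fingerprint]:
    return {c.compound_id: compute_fingerprint(c, radius, n_bits) for c in lib}


def pairwise_similarity_matrix(
    lib: CompoundLibrary, radius: int = DEFAULT_RADIUS, n_bits: int = DEFAULT_N_BITS
) -> pd.DataFrame:
    """Symmetric all-against-all Tanimoto matrix keyed by compound id."""
    fps = fingerprint_library(lib, radius, n_bits)
    ids = lib.ids
    vecs = [fps[i].bits for i in ids]
    rows = []
    for i, fp in enumerate(vecs):
        sims = DataStructs.BulkTanimotoSimilarity(fp, vecs)
        rows.append(sims)
    mat = pd.DataFrame(rows, index=ids, columns=ids, dtype=float)
    for i, cid in enumerate(ids):
        if fps[cid].n_on == 0:
            # RDKit reports 0 for empty-vs-empty; apply the 1.0 convention
            for j, other in enumerate(ids):
                if fps[other].n_on == 0:
                    mat.iloc[i, j] = 1.0
        mat.loc[cid, cid] = 1.0
    return mat


def build_activity_network(
    lib: CompoundLibrary,
    tau: float = 0.5,
    include_candidate_edges: bool = False,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> ActivityNetwork:
    """Build the seed-anchored potential-active network at threshold tau.

    A non-seed becomes a candidate node iff its similarity to at least one
    seed strictly exceeds tau. Stored edges are seed–seed and seed–candidate
    pairs above tau; candidate–candidate pairs are added only when
    ``include_candidate_edges`` is set.
    """
    if not 0.0 <= tau <= 1.0:
        raise ConfigError(f"tau must be in [0, 1], got {tau}")
    seed_ids = [c.compound_id for c in lib if c.is_seed]
    if not seed_ids:
        raise InputError("cannot build activity network: library has no seeds")
    nonseed_ids = [c.compound_id for c in lib if not c.is_seed]
    sims = pairwise_similarity_matrix(lib, radius, n_bits)

    candidate_ids = [
        nid
        for nid in nonseed_ids
        if any(sims.loc[nid, s] > tau for s in seed_ids)
    ]
    edges: list[SimilarityEdge] = []
    for i, a in enumerate(seed_ids):
        for b in seed_ids[i + 1 :]:
            if sims.loc[a, b] > tau:
                edges.append(SimilarityEdge.make(a, b, sims.loc[a, b]))
    for a in seed_ids:
        for b in candidate_ids:
            if sims.loc[a, b] > tau:
                edges.append(SimilarityEdge.make(a, b, sims.loc[a, b]))
    if include_candidate_edges:
        for i, a in enumerate(candidate_ids):
            for b in candidate_ids[i + 1 :]:
                if sims.loc[a, b] > tau:
                    edges.append(SimilarityEdge.make(a, b, sims.loc[a, b]))
    edges.sort()
    logger.info(
        "activity network: %d seeds, %d candidates, %d edges (tau=%.2f)",
        len(seed_ids),
        len(candidate_ids),
        len(edges),
        tau,
    )
    return ActivityNetwork(
        seed_ids=seed_ids,
        candidate_ids=candidate_ids,
        edges=edges,
        tau=tau,
        include_candidate_edges=include_candidate_edges,
    )


def network_summary(net: ActivityNetwork, lib: CompoundLibrary) -> dict:
    """Node/edge/candidate counts, candidate class histogram, and degrees."""
    from .library import COMPOUND_CLASSES

    hist = {k: 0 for k in COMPOUND_CLASSES}
    for cid in net.candidate_ids:
        hist[lib.get(cid).compound_class] += 1
    degree: dict[str, int] = {nid: 0 for nid in net.node_ids}
    for edge in net.edges:
        degree[edge.source_id] += 1
        degree[edge.target_id] += 1
    return {
        "n_nodes": net.n_nodes,
        "n_edges": net.n_edges,
        "n_seeds": len(net.seed_ids),
        "n_candidates": len(net.candidate_ids),
        "candidate_class_counts": hist,
        "degree": degree,
        "tau": net.tau,
        "include_candidate_edges": net.include_candidate_edges,
    }


def export_network(
    net: ActivityNetwork,
    path: str | Path,
    format: str = "graphml",
    lib: CompoundLibrary | None = None,
) -> Path:
    """Write the network as GraphML, SIF, or a plain edge TSV.

    GraphML carries node attributes (is_seed, compound_class when a library
    is supplied) and the edge similarity; SIF uses interaction label ``sim``
    with one extra line per isolated node; the edge TSV prints similarity to
    4 decimal places.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net.to_networkx(lib), path)
    elif format == "sif":
        linked: set[str] = set()
        with open(path, "w") as handle:
            for edge in net.edges:
                handle.write(f"{edge.source_id}\tsim\t{edge.target_id}\n")
                linked.update((edge.source_id, edge.target_id))
            for nid in net.node_ids:
                if nid not in linked:
                    handle.write(f"{nid}\n")
    elif format == "edge_tsv":
        with open(path, "w") as handle:
            handle.write("source\ttarget\tsimilarity\n")
            for edge in net.edges:
                handle.write(f"{edge.source_id}\t{edge.target_id}\t{edge.similarity:.4f}\n")
    else:
        raise ConfigError(f"unknown network export format {format!r}")
    return path
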