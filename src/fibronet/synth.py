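"""Synthetic ground-truth data for every pipeline input.

The generators emulate the study conditions end to end so the whole chain is
testable without any external download: a compound library of
scaffold-clustered families containing planted known actives, per-compound
target-prediction score tables with planted true targets, two-group
expression data with planted fold changes, annotation collections with one
planted enriched set, a binding-affinity table, and a curated disease-link
table. A :class:`TruthManifest` records every planted fact, so the expected
output of every stage at default thresholds is known exactly.

Chemistry: each family is built from a shared heteroatom-patterned linear
scaffold (C/N/O/S chain, 18–24 heavy atoms, no adjacent heteroatoms)
decorated with short distinct tails. Real circular fingerprints are used
throughout, and the generator *verifies* the separation contract — minimum
within-family Tanimoto ≥ 0.6, maximum cross-family ≤ 0.3 at Morgan
radius 2 / 2048 bits — resampling violating scaffolds up to a retry cap.
Default dimensions mirror the study: 8 families of 10 plus 58 unrelated
singletons = 138 compounds with 8 seeds, and 40 candidate targets of which
12 are planted true targets (true-target scores ~ U(0.12, 0.60) over ≥ 4
supporting network compounds; decoys ~ U(0, 0.09) over ≤ 2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from rdkit import DataStructs

from .errors import FibronetError
from .library import COMPOUND_CLASSES, CompoundLibrary, canonical_smiles, library_from_records, write_library
from .network import DEFAULT_N_BITS, DEFAULT_RADIUS, compute_fingerprint

logger = logging.getLogger(__name__)

#: distinct decoration tails appended to a family scaffold (one per member)
TAILS = ("", "C", "O", "N", "CC", "CO", "CN", "OC", "NC", "CCC", "CCO", "CCN", "COC")

_BACKBONE_ATOMS = ["C", "C", "N", "O", "S"]
_BACKBONE_P = [0.3, 0.2, 0.2, 0.15, 0.15]
_DECORATIONS = ["C", "F", "Cl", "Br", "O", "N"]
_FREE_VALENCE = {"C": 2, "N": 1, "O": 0, "S": 0}

TARGET_CLASS_P = {
    "enzyme": 0.5,
    "gpcr": 0.2,
    "nuclear_receptor": 0.1,
    "ion_channel": 0.1,
    "other": 0.1,
}


@dataclass
class TruthManifest:
    """Everything planted by the generators, enough to predict every stage."""

    rng_seed: int
    planted_families: dict[str, list[str]] = field(default_factory=dict)
    planted_seed_ids: list[str] = field(default_factory=list)
    decoy_compound_ids: list[str] = field(default_factory=list)
    network_compound_ids: list[str] = field(default_factory=list)
    planted_true_targets: dict[str, dict] = field(default_factory=dict)
    decoy_targets: list[str] = field(default_factory=list)
    intended_top_target: str | None = None
    affinity_backed_targets: list[str] = field(default_factory=list)
    planted_de_genes: list[list] = field(default_factory=list)  # [gene, compound, fold, direction]
    planted_enriched_sets: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


def _make_scaffold(rng: np.random.Generator) -> str:
    """A branched heteroatom scaffold with halogen/carbonyl decorations.

    Valence is tracked explicitly so the SMILES is always parseable; the last
    backbone atom stays a plain carbon with a free valence, the attachment
    point for family decoration tails. The high per-atom entropy (C/N/O/S
    backbone plus C/F/Cl/Br/O/N substituents and carbonyls) is what keeps
    unrelated scaffolds dissimilar under circular fingerprints.
    """
    length = int(rng.integers(16, 23))
    backbone = (
        ["C"]
        + [str(rng.choice(_BACKBONE_ATOMS, p=_BACKBONE_P)) for _ in range(length - 2)]
        + ["C"]
    )
    parts: list[str] = []
    last = len(backbone) - 1
    for i, atom in enumerate(backbone):
        parts.append(atom)
        if i == last:
            break
        free = _FREE_VALENCE[atom] + (1 if i == 0 else 0)
        if atom == "C" and free >= 2 and rng.random() < 0.25:
            parts.append("(=O)")
            free -= 2
        while free > 0 and rng.random() < 0.3:
            parts.append(f"({rng.choice(_DECORATIONS)})")
            free -= 1
    return "".join(parts)


def _family_smiles(scaffold: str, size: int) -> list[str]:
    if size > len(TAILS):
        raise FibronetError(f"family_size {size} exceeds available decorations ({len(TAILS)})")
    return [scaffold + tail for tail in TAILS[:size]]


def generate_compound_library(
    n_families: int = 8,
    family_size: int = 10,
    n_seeds: int = 8,
    n_decoys: int = 58,
    rng_seed: int = 17,
    within_min: float = 0.6,
    between_max: float = 0.3,
    max_retries: int = 80,
    radius: int = DEFAULT_RADIUS,
    n_bits: int = DEFAULT_N_BITS,
) -> tuple[CompoundLibrary, TruthManifest]:
    """Scaffold-family library with planted seeds and verified separation.

    Seeds are placed one per family (the undecorated scaffold) for the first
    ``n_seeds`` families; decoys are unrelated singleton scaffolds. The
    similarity-separation contract is checked with real fingerprints and
    violating scaffolds are resampled, so at tau = 0.5 every non-seed member
    of a seeded family is recoverable as a candidate and no decoy is.
    """
    if n_seeds > n_families:
        raise FibronetError("n_seeds cannot exceed n_families (one seed per family)")
    rng = np.random.default_rng(rng_seed)
    family_scaffolds = [_make_scaffold(rng) for _ in range(n_families)]
    decoy_scaffolds = [_make_scaffold(rng) for _ in range(n_decoys)]

    def groups(fams, decs):
        # each decoy is its own group for the cross-group separation check
        return [_family_smiles(s, family_size) for s in fams] + [[s] for s in decs]

    for attempt in range(max_retries):
        smiles_groups = groups(family_scaffolds, decoy_scaffolds)
        fps = [[compute_fingerprint(s, radius, n_bits).bits for s in grp] for grp in smiles_groups]
        flat = [fp for grp in fps for fp in grp]
        group_of = [gi for gi, grp in enumerate(fps) for _ in grp]

        bad_groups: set[int] = set()
        # within-family minimum
        for gi in range(n_families):
            grp = fps[gi]
            for i in range(len(grp)):
                sims = DataStructs.BulkTanimotoSimilarity(grp[i], grp[i + 1 :])
                if sims and min(sims) < within_min:
                    bad_groups.add(gi)
                    break
        # cross-group maximum
        for i in range(len(flat)):
            sims = DataStructs.BulkTanimotoSimilarity(flat[i], flat[i + 1 :])
            for j_off, sim in enumerate(sims):
                j = i + 1 + j_off
                if group_of[i] != group_of[j] and sim > between_max:
                    bad_groups.add(group_of[i])
                    bad_groups.add(group_of[j])
        # canonical-structure collisions across the whole library
        canon = {}
        for gi, grp in enumerate(smiles_groups):
            for smi in grp:
                c = canonical_smiles(smi)
                if c in canon and canon[c] != gi:
                    bad_groups.update((gi, canon[c]))
                canon[c] = gi

        if not bad_groups:
            break
        for gi in sorted(bad_groups):
            if gi < n_families:
                family_scaffolds[gi] = _make_scaffold(rng)
            else:
                decoy_scaffolds[gi - n_families] = _make_scaffold(rng)
    else:
        raise FibronetError(
            f"similarity separation unattainable after {max_retries} retries "
            f"(within_min={within_min}, between_max={between_max})"
        )

    family_classes = [
        COMPOUND_CLASSES[0] if i < n_families - 3 else COMPOUND_CLASSES[(i - (n_families - 3)) % 3 + 1]
        for i in range(n_families)
    ]
    records = []
    manifest = TruthManifest(rng_seed=int(rng_seed))
    idx = 0
    for fi, scaffold in enumerate(family_scaffolds):
        fam_id = f"F{fi + 1:02d}"
        members = []
        for mi, smi in enumerate(_family_smiles(scaffold, family_size)):
            idx += 1
            cid = f"CPD{idx:03d}"
            is_seed = fi < n_seeds and mi == 0
            records.append((cid, f"synthetic compound {idx}", smi, family_classes[fi], is_seed))
            members.append(cid)
            if is_seed:
                manifest.planted_seed_ids.append(cid)
        manifest.planted_families[fam_id] = members
        if fi < n_seeds:
            manifest.network_compound_ids.extend(members)
    decoy_classes = rng.choice(
        np.array(COMPOUND_CLASSES), size=n_decoys, p=[0.65, 0.12, 0.05, 0.18]
    )
    for di, scaffold in enumerate(decoy_scaffolds):
        idx += 1
        cid = f"CPD{idx:03d}"
        records.append((cid, f"synthetic compound {idx}", scaffold, str(decoy_classes[di]), False))
        manifest.decoy_compound_ids.append(cid)

    lib = library_from_records(records)
    logger.info(
        "synthetic library: %d compounds in %d families + %d decoys (%d seeds)",
        len(lib), n_families, n_decoys, len(manifest.planted_seed_ids),
    )
    return lib, manifest


def generate_prediction_tables(
    manifest: TruthManifest,
    n_targets: int = 40,
    n_true: int = 12,
    rng_seed: int = 17,
    true_score_range: tuple[float, float] = (0.12, 0.40),
    top_score_range: tuple[float, float] = (0.45, 0.60),
    decoy_score_range: tuple[float, float] = (0.0, 0.09),
) -> list[tuple[str, str, float, str]]:
    """Prediction rows (compound, target, score, class) with planted truth.

    One designated true target (the manifest's intended top) receives the
    highest score regime and the widest compound support, so the final
    prioritization has a unique intended answer. Updates ``manifest`` in
    place and returns the rows.
    """
    if n_true > n_targets:
        raise FibronetError("n_true cannot exceed n_targets")
    rng = np.random.default_rng(rng_seed + 1)
    network = list(manifest.network_compound_ids)
    if n_true > 0 and len(network) < 4:
        raise FibronetError("need ≥4 network compounds to plant true targets")
    classes = np.array(list(TARGET_CLASS_P))
    class_p = np.array(list(TARGET_CLASS_P.values()))

    rows: list[tuple[str, str, float, str]] = []
    for ti in range(n_true):
        target = f"TRG{ti + 1:02d}"
        cls = str(rng.choice(classes, p=class_p))
        if ti == 0:
            lo, hi = top_score_range
            n_sup = min(10, len(network))
        else:
            lo, hi = true_score_range
            n_sup = int(rng.integers(4, min(9, len(network) + 1)))
        support = sorted(rng.choice(network, size=n_sup, replace=False))
        for cid in support:
            rows.append((str(cid), target, float(rng.uniform(lo, hi)), cls))
        manifest.planted_true_targets[target] = {
            "support": [str(c) for c in support],
            "target_class": cls,
            "score_range": [lo, hi],
        }
        if ti == 0:
            manifest.intended_top_target = target
    for di in range(n_targets - n_true):
        target = f"DCY{di + 1:02d}"
        cls = str(rng.choice(classes, p=class_p))
        n_sup = int(rng.integers(1, 3))
        support = sorted(rng.choice(network, size=min(n_sup, len(network)), replace=False))
        lo, hi = decoy_score_range
        for cid in support:
            rows.append((str(cid), target, float(rng.uniform(lo, hi)), cls))
        manifest.decoy_targets.append(target)
    return rows


def write_prediction_table(rows, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("compound_id\ttarget_id\tscore\ttarget_class\n")
        for cid, target, score, cls in rows:
            handle.write(f"{cid}\t{target}\t{score:.4f}\t{cls}\n")
    return path


def generate_interactions(
    manifest: TruthManifest, rng_seed: int = 17
) -> list[tuple[str, str, str, float, str]]:
    """Affinity rows: three true targets verified below 10 µM, plus rows the
    credibility filter must drop (a Ki record and a >10 µM record)."""
    rng = np.random.default_rng(rng_seed + 2)
    true_targets = list(manifest.planted_true_targets)
    backed = true_targets[: min(3, len(true_targets))]
    rows: list[tuple[str, str, str, float, str]] = []
    for target in backed:
        support = manifest.planted_true_targets[target]["support"]
        n_rec = min(int(rng.integers(2, 4)), len(support))
        for cid in sorted(rng.choice(support, size=n_rec, replace=False)):
            rows.append((str(cid), target, "IC50", float(rng.integers(500, 8000)), "synthetic"))
    manifest.affinity_backed_targets = backed
    if len(true_targets) > 4:
        support = manifest.planted_true_targets[true_targets[3]]["support"]
        rows.append((support[0], true_targets[3], "Ki", 500.0, "synthetic"))
        support = manifest.planted_true_targets[true_targets[4]]["support"]
        rows.append((support[0], true_targets[4], "IC50", 20000.0, "synthetic"))
    return rows


def write_interaction_table(rows, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("compound_id\ttarget_id\tmeasure\tvalue_nm\tsource\n")
        for cid, target, measure, value, source in rows:
            handle.write(f"{cid}\t{target}\t{measure}\t{value:.1f}\t{source}\n")
    return path


def default_planted_de(manifest: TruthManifest) -> list[tuple[str, str, float]]:
    """Default planted fold changes: two up-shifts and one down-shift on true
    targets 4–6, attributed to the first two seed compounds."""
    true_targets = list(manifest.planted_true_targets)
    if len(true_targets) < 6 or len(manifest.planted_seed_ids) < 2:
        return []
    c1, c2 = manifest.planted_seed_ids[:2]
    return [
        (true_targets[3], c1, 4.0),
        (true_targets[4], c1, 0.25),
        (true_targets[5], c2, 4.0),
    ]


def generate_expression_data(
    manifest: TruthManifest | None = None,
    genes: int = 2000,
    n_per_group: int = 3,
    planted: list[tuple[str, str, float]] | None = None,
    rng_seed: int = 17,
    noise_sd: float = 0.25,
    treated_compounds: list[str] | None = None,
):
    """Log-normal two-group intensities with planted fold changes.

    Returns ``(values_frame, sample_map_frame)``. Baseline log2 means are
    uniform on [6, 10] with Gaussian noise (sd ``noise_sd``); a planted gene's
    treated samples for the named compound are shifted by log2(fold). The
    default planted list (when a manifest is given) uses ≥4-fold shifts for
    power at n = 3 per group.
    """
    import pandas as pd

    rng = np.random.default_rng(rng_seed + 3)
    if planted is None:
        planted = default_planted_de(manifest) if manifest is not None else []
    if treated_compounds is None:
        if manifest is not None and len(manifest.planted_seed_ids) >= 2:
            treated_compounds = list(manifest.planted_seed_ids[:2])
        else:
            treated_compounds = sorted({c for _, c, _ in planted}) or ["CPD001"]

    symbols: list[str] = []
    if manifest is not None:
        symbols.extend(manifest.planted_true_targets)
        symbols.extend(manifest.decoy_targets)
    for g, _, _ in planted:
        if g not in symbols:
            symbols.append(g)
    filler = [f"G{i + 1:04d}" for i in range(max(0, genes - len(symbols)))]
    gene_ids = (symbols + filler)[:genes]

    samples = [f"CTRL_{i + 1}" for i in range(n_per_group)]
    groups = [("control", "")] * n_per_group
    for cid in treated_compounds:
        for i in range(n_per_group):
            samples.append(f"TRT_{cid}_{i + 1}")
            groups.append(("treated", cid))

    base = rng.uniform(6.0, 10.0, size=len(gene_ids))
    log2 = np.tile(base[:, None], (1, len(samples))) + rng.normal(
        0.0, noise_sd, size=(len(gene_ids), len(samples))
    )
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    planted_records = []
    for gene, cid, fold in planted:
        if gene not in gene_index or cid not in treated_compounds:
            continue
        cols = [j for j, (grp, c) in enumerate(groups) if grp == "treated" and c == cid]
        log2[gene_index[gene], cols] += np.log2(fold)
        direction = "up" if fold >= 1.0 else "down"
        if fold == 1.0:
            continue  # a planted unit fold is a null gene
        planted_records.append([gene, cid, float(fold), direction])
    if manifest is not None:
        manifest.planted_de_genes = planted_records

    values = pd.DataFrame(np.power(2.0, log2), index=gene_ids, columns=samples)
    values.index.name = "gene"
    sample_map = pd.DataFrame(
        {"sample_id": samples, "group": [g for g, _ in groups], "compound_id": [c for _, c in groups]}
    )
    return values, sample_map


def write_expression_data(values, sample_map, expr_path, map_path) -> tuple[Path, Path]:
    expr_path, map_path = Path(expr_path), Path(map_path)
    values.to_csv(expr_path, sep="\t", float_format="%.4f")
    sample_map.to_csv(map_path, sep="\t", index=False)
    return expr_path, map_path


def generate_annotation_sets(
    manifest: TruthManifest,
    n_sets: int = 30,
    n_filler_genes: int = 600,
    rng_seed: int = 17,
) -> list[tuple[str, str, list[str]]]:
    """GMT-ready sets with one planted enriched pathway.

    The planted set contains every planted true target (> 10 potential
    targets at the defaults, including the affinity-backed ones and the
    planted differential genes) plus a few bystander genes; background sets
    are random draws from a non-target gene universe.
    """
    rng = np.random.default_rng(rng_seed + 4)
    universe = list(manifest.decoy_targets) + [f"G{i + 1:04d}" for i in range(n_filler_genes)]
    sets: list[tuple[str, str, list[str]]] = []

    planted_members = list(manifest.planted_true_targets) + sorted(
        rng.choice(universe, size=5, replace=False).tolist()
    )
    sets.append(("PW_PLANTED", "planted signaling pathway;category=pathway", planted_members))
    manifest.planted_enriched_sets = ["PW_PLANTED"]

    for si in range(n_sets - 1):
        category = "disease" if si % 6 == 5 else "pathway"
        size = int(rng.integers(8, 41))
        members = sorted(rng.choice(universe, size=size, replace=False).tolist())
        sets.append((f"RS{si + 1:03d}", f"random set {si + 1};category={category}", members))
    return sets


def write_annotation_sets(sets, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as handle:
        for set_id, desc, members in sets:
            handle.write("\t".join([set_id, desc, *members]) + "\n")
    return path


def write_disease_links(manifest: TruthManifest, path: str | Path) -> Path:
    """Curated-direction table consistent with the planted truth.

    The intended top target and the down-regulated planted gene get an
    inhibition-beneficial link (retained); one affinity-backed target gets an
    activation-beneficial link (contradiction); one up-regulated planted gene
    gets an inhibition-beneficial link (contradiction); the remaining true
    targets carry no link.
    """
    true_targets = list(manifest.planted_true_targets)
    rows: list[tuple[str, str, str]] = []
    if manifest.intended_top_target:
        rows.append((manifest.intended_top_target, "inhibit_beneficial", "planted: inhibition beneficial"))
    if len(true_targets) >= 3:
        rows.append((true_targets[1], "activate_beneficial", "planted: activation beneficial"))
        rows.append((true_targets[2], "inhibit_beneficial", "planted: inhibition beneficial"))
    for gene, _cid, fold, direction in manifest.planted_de_genes:
        if gene == manifest.intended_top_target:
            continue
        if direction == "up" and gene == true_targets[3]:
            rows.append((gene, "inhibit_beneficial", "planted: transcriptome contradiction"))
        elif direction == "down":
            rows.append((gene, "inhibit_beneficial", "planted: inhibition beneficial"))
    path = Path(path)
    with open(path, "w") as handle:
        handle.write("target_id\tdesired_modulation\tcitation\n")
        for target, modulation, citation in rows:
            handle.write(f"{target}\t{modulation}\t{citation}\n")
    return path


def generate_all(
    outdir: str | Path,
    rng_seed: int = 17,
    n_families: int = 8,
    family_size: int = 10,
    n_seeds: int = 8,
    n_decoys: int = 58,
    n_targets: int = 40,
    n_true: int = 12,
    genes: int = 2000,
    n_per_group: int = 3,
    n_sets: int = 30,
) -> tuple[dict[str, Path], TruthManifest]:
    """Generate every pipeline input under ``outdir``; returns paths + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lib, manifest = generate_compound_library(
        n_families=n_families, family_size=family_size, n_seeds=n_seeds,
        n_decoys=n_decoys, rng_seed=rng_seed,
    )
    pred_rows = generate_prediction_tables(manifest, n_targets=n_targets, n_true=n_true, rng_seed=rng_seed)
    inter_rows = generate_interactions(manifest, rng_seed=rng_seed)
    values, sample_map = generate_expression_data(
        manifest, genes=genes, n_per_group=n_per_group, rng_seed=rng_seed
    )
    sets = generate_annotation_sets(manifest, n_sets=n_sets, rng_seed=rng_seed)

    paths = {
        "library": write_library(lib, outdir / "library.tsv"),
        "predictions": write_prediction_table(pred_rows, outdir / "predictions.tsv"),
        "interactions": write_interaction_table(inter_rows, outdir / "interactions.tsv"),
        "gene_sets": write_annotation_sets(sets, outdir / "gene_sets.gmt"),
        "disease_links": write_disease_links(manifest, outdir / "disease_links.tsv"),
    }
    expr, smap = write_expression_data(
        values, sample_map, outdir / "expression.tsv", outdir / "sample_map.tsv"
    )
    paths["expression"] = expr
    paths["sample_map"] = smap
    paths["manifest"] = manifest.save(outdir / "manifest.json")
    return paths, manifest
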