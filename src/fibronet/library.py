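"""Compound library I/O, canonicalization, deduplication, and validation.

A library is an ordered collection of small molecules, each carrying a
structure (SMILES), a chemotype class label (diterpenoid, triterpenoid,
steroid, or other — the four classes used for lipophilic *Salvia
miltiorrhiza* constituents), and a boolean flag marking compounds with
literature-documented anti-fibrotic activity ("seeds"). Seeds anchor the
guilt-by-association expansion performed by :mod:`fibronet.network`.

Structure handling is delegated to RDKit: a record whose SMILES RDKit cannot
parse is rejected (and logged), never silently kept. Canonical identity is
RDKit's canonical isomeric SMILES; stereochemistry is preserved and salts are
not stripped. Merging of duplicates keeps the first-seen identifier and takes
the union of seed flags, so a known active never loses its seed status to a
duplicate row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem, RDLogger

from .errors import ConfigError, InputError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

COMPOUND_CLASSES = ("diterpenoid", "triterpenoid", "steroid", "other")

#: default column names for CSV/TSV libraries (configurable per call)
DEFAULT_COLUMNS = {
    "id": "id",
    "name": "name",
    "smiles": "smiles",
    "class": "class",
    "seed": "is_seed",
}

_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", "", "nan", "none"}


@dataclass
class Compound:
    """A single library member."""

    compound_id: str
    name: str
    smiles: str
    compound_class: str
    is_seed: bool
    canonical_smiles: str | None = None

    def __post_init__(self) -> None:
        if self.compound_class not in COMPOUND_CLASSES:
            raise InputError(
                f"compound {self.compound_id!r}: class {self.compound_class!r} "
                f"not in {COMPOUND_CLASSES}"
            )


@dataclass
class Provenance:
    """Where a library came from and what was dropped on the way in."""

    sources: list[str] = field(default_factory=list)
    n_accepted: int = 0
    n_rejected: int = 0
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row, reason)
    n_duplicates_merged: int = 0


@dataclass
class CompoundLibrary:
    """Ordered, identifier-unique collection of compounds."""

    compounds: list[Compound]
    provenance: Provenance = field(default_factory=Provenance)

    def __post_init__(self) -> None:
        ids = [c.compound_id for c in self.compounds]
        if len(ids) != len(set(ids)):
            raise InputError("duplicate compound_id within library")

    def __len__(self) -> int:
        return len(self.compounds)

    def __iter__(self):
        return iter(self.compounds)

    def get(self, compound_id: str) -> Compound:
        for c in self.compounds:
            if c.compound_id == compound_id:
                return c
        raise KeyError(compound_id)

    @property
    def ids(self) -> list[str]:
        return [c.compound_id for c in self.compounds]

    @property
    def seeds(self) -> list[Compound]:
        return [c for c in self.compounds if c.is_seed]

    @property
    def seed_ids(self) -> set[str]:
        return {c.compound_id for c in self.compounds if c.is_seed}

    def class_counts(self) -> dict[str, int]:
        counts = {k: 0 for k in COMPOUND_CLASSES}
        for c in self.compounds:
            counts[c.compound_class] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.compound_id for c in self.compounds],
                "name": [c.name for c in self.compounds],
                "smiles": [c.smiles for c in self.compounds],
                "canonical_smiles": [c.canonical_smiles for c in self.compounds],
                "class": [c.compound_class for c in self.compounds],
                "is_seed": [c.is_seed for c in self.compounds],
            }
        )


def _parse_bool(value, row: int) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValueError(f"row {row}: unparsable boolean {value!r}")


def _coerce_class(value, compound_id: str) -> str:
    text = str(value).strip().lower()
    aliases = {"others": "other", "": "other", "nan": "other"}
    text = aliases.get(text, text)
    if text not in COMPOUND_CLASSES:
        logger.warning(
            "compound %s: unrecognized class %r coerced to 'other'", compound_id, value
        )
        return "other"
    return text


def mol_from_smiles(smiles: str) -> Chem.Mol | None:
    """Parse a SMILES string, returning None on failure."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles.strip())


def canonical_smiles(smiles: str) -> str:
    """Canonical isomeric SMILES for a parseable structure."""
    mol = mol_from_smiles(smiles)
    if mol is None:
        raise InputError(f"unparsable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


def read_compounds(
    path: str | Path,
    format: str | None = None,
    columns: dict[str, str] | None = None,
) -> CompoundLibrary:
    """Read a compound library from CSV/TSV, .smi, or SDF.

    Rows with unparsable SMILES are rejected and logged in the returned
    library's provenance; they never abort the read. Row order is preserved.

    Parameters
    ----------
    path
        Input file. Format inferred from the suffix unless ``format`` given.
    format
        One of ``csv``, ``tsv``, ``smi``, ``sdf``.
    columns
        Mapping with keys ``id, name, smiles, class, seed`` overriding the
        default CSV/TSV column names (SDF: data-tag names).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if format is None:
        format = {".csv": "csv", ".tsv": "tsv", ".smi": "smi", ".sdf": "sdf"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ConfigError(f"cannot infer format from suffix of {path.name!r}")
    if format not in ("csv", "tsv", "smi", "sdf"):
        raise ConfigError(f"unknown library format {format!r}")

    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)

    prov = Provenance(sources=[str(path)])
    compounds: list[Compound] = []
    seen_ids: set[str] = set()

    def accept(row_no, cid, name, smi, cls, seed) -> None:
        cid = str(cid).strip()
        if not cid:
            prov.rejected.append((row_no, "empty compound id"))
            return
        if cid in seen_ids:
            prov.rejected.append((row_no, f"duplicate compound id {cid!r}"))
            return
        mol = mol_from_smiles(smi)
        if mol is None:
            prov.rejected.append((row_no, f"unparsable SMILES {smi!r}"))
            return
        compounds.append(
            Compound(
                compound_id=cid,
                name=str(name) if name is not None else cid,
                smiles=str(smi).strip(),
                compound_class=_coerce_class(cls, cid),
                is_seed=seed,
            )
        )
        seen_ids.add(cid)

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        mandatory = [cols["id"], cols["smiles"]]
        missing = [c for c in mandatory if c not in frame.columns]
        if missing:
            raise ConfigError(f"{path.name}: missing mandatory column(s) {missing}")
        for i, row in frame.iterrows():
            row_no = int(i) + 2  # 1-based + header
            try:
                seed = _parse_bool(row.get(cols["seed"], "false"), row_no)
            except ValueError as exc:
                prov.rejected.append((row_no, str(exc)))
                continue
            accept(
                row_no,
                row[cols["id"]],
                row.get(cols["name"], row[cols["id"]]),
                row[cols["smiles"]],
                row.get(cols["class"], "other"),
                seed,
            )
    elif format == "smi":
        with open(path) as handle:
            for row_no, line in enumerate(handle, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                smi = parts[0]
                cid = parts[1] if len(parts) > 1 else f"SMI{row_no:04d}"
                accept(row_no, cid, cid, smi, "other", False)
    else:  # sdf
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for row_no, mol in enumerate(supplier, start=1):
            if mol is None:
                prov.rejected.append((row_no, "unparsable SDF record"))
                continue
            props = mol.GetPropsAsDict()
            cid = str(props.get(cols["id"], mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF{row_no:04d}"))
            try:
                seed = _parse_bool(props.get(cols["seed"], "false"), row_no)
            except ValueError as exc:
                prov.rejected.append((row_no, str(exc)))
                continue
            accept(
                row_no,
                cid,
                props.get(cols["name"], cid),
                Chem.MolToSmiles(mol),
                props.get(cols["class"], "other"),
                seed,
            )

    prov.n_accepted = len(compounds)
    prov.n_rejected = len(prov.rejected)
    for row_no, reason in prov.rejected:
        logger.warning("%s row %d rejected: %s", path.name, row_no, reason)
    if not compounds:
        raise InputError(f"{path.name}: no valid compound rows")
    return CompoundLibrary(compounds=compounds, provenance=prov)


def canonicalize_and_deduplicate(lib: CompoundLibrary) -> CompoundLibrary:
    """Compute canonical SMILES once per compound and merge duplicates.

    Duplicates (identical canonical structure) are merged keeping the
    first-seen identifier; the merged record is a seed if any copy was.
    """
    by_canonical: dict[str, Compound] = {}
    order: list[str] = []
    n_merged = 0
    for comp in lib.compounds:
        canon = comp.canonical_smiles or canonical_smiles(comp.smiles)
        if canon in by_canonical:
            kept = by_canonical[canon]
            if comp.is_seed and not kept.is_seed:
                by_canonical[canon] = replace(kept, is_seed=True)
            n_merged += 1
            logger.info(
                "duplicate structure: %s merged into %s", comp.compound_id, kept.compound_id
            )
        else:
            by_canonical[canon] = replace(comp, canonical_smiles=canon)
            order.append(canon)
    prov = replace(lib.provenance, n_duplicates_merged=lib.provenance.n_duplicates_merged + n_merged)
    return CompoundLibrary(compounds=[by_canonical[c] for c in order], provenance=prov)


def validate_library(lib: CompoundLibrary, require_seeds: bool = False) -> dict:
    """Summarize a library and optionally enforce the network-stage contract.

    Returns a report with class counts, seed count and merge/reject counts.
    With ``require_seeds=True`` a seedless library is a fatal error, because
    the similarity expansion has nothing to anchor on.
    """
    n_seeds = len(lib.seeds)
    report = {
        "n_compounds": len(lib),
        "n_seeds": n_seeds,
        "n_unknown_activity": len(lib) - n_seeds,
        "class_counts": lib.class_counts(),
        "n_rejected_rows": lib.provenance.n_rejected,
        "n_duplicates_merged": lib.provenance.n_duplicates_merged,
    }
    if n_seeds == 0 and require_seeds:
        raise InputError("library has no seed compounds; similarity expansion impossible")
    if n_seeds == len(lib):
        logger.warning("all compounds are seeds; downstream candidate set will be empty")
    return report


def write_library(lib: CompoundLibrary, path: str | Path) -> Path:
    """Write the normalized library TSV (includes canonical SMILES column)."""
    path = Path(path)
    frame = lib.to_frame()
    frame["is_seed"] = frame["is_seed"].map(lambda b: "true" if b else "false")
    frame.to_csv(path, sep="\t", index=False)
    return path


def library_from_records(records: Iterable[Sequence]) -> CompoundLibrary:
    """Build a library from (id, name, smiles, class, is_seed) tuples.

    Convenience constructor used by the synthetic generator and tests.
    """
    compounds = [
        Compound(
            compound_id=str(cid),
            name=str(name),
            smiles=smi,
            compound_class=cls,
            is_seed=bool(seed),
        )
        for cid, name, smi, cls, seed in records
    ]
    prov = Provenance(sources=["<records>"], n_accepted=len(compounds))
    return CompoundLibrary(compounds=compounds, provenance=prov)
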