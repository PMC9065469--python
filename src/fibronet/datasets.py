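"""Bundled curated datasets.

The package ships a small worked example: the JAK/STAT signaling pathway
slice of the *Salvia miltiorrhiza* lipophilic-constituent analysis. It
comprises the 19 pathway member proteins predicted as potential targets, the
published ChEMBL binding-affinity rows for four of them, the published
treatment fold changes (MCF7, tanshinone IIA / oleanolic acid) for six, and
the curated disease-link table used by the triage rules.

The differential-gene fixture's ``p_value`` column holds a nominal 0.01
placeholder: the source reports only that significance (p < 0.05) held for
these genes, not exact p-values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .evidence import DifferentialGene, InteractionRecord, read_de_table, read_interaction_table
from .triage import DiseaseLink, read_disease_links

_DATA = resources.files("fibronet") / "data"


def data_path(name: str) -> Path:
    """Filesystem path of a bundled data file."""
    return Path(str(_DATA / name))


def load_jak_stat_members() -> list[str]:
    """The 19 JAK/STAT pathway proteins in the potential-target set."""
    lines = data_path("jak_stat_members.txt").read_text().splitlines()
    return [ln.strip().upper() for ln in lines if ln.strip() and not ln.startswith("#")]


def load_jak_stat_interactions() -> list[InteractionRecord]:
    """Published sub-10-µM affinity records for the pathway targets."""
    return read_interaction_table(data_path("jak_stat_interactions.tsv"))


def load_jak_stat_differential_genes() -> list[DifferentialGene]:
    """Published treatment fold changes for the pathway genes."""
    return read_de_table(data_path("jak_stat_differential_genes.tsv"))


def load_disease_links() -> dict[str, DiseaseLink]:
    """Curated desired-modulation directions for liver fibrosis."""
    return read_disease_links(data_path("disease_links.tsv"))
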