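"""Bundled example tables: a small HMDB-like metabolite database and a
reference table of putative brain-metabolite assignments (name, neutral
formula, adduct, experimental m/z) used by the examples and tests."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import MetaboliteRecord, read_metabolite_db

__all__ = ["bundled_path", "load_brain_db", "load_brain_assignments"]


def bundled_path(name: str):
    """Filesystem path of a bundled data table."""
    return resources.files("aurimsi") / "data" / name


def load_brain_db() -> list[MetaboliteRecord]:
    """The bundled ~30-row metabolite database (HMDB-style records)."""
    records, rejects = read_metabolite_db(bundled_path("brain_metabolites.tsv"))
    assert not rejects, f"bundled database has malformed rows: {rejects}"
    return records


def load_brain_assignments() -> pd.DataFrame:
    """Bundled table of putative brain assignments with experimental m/z."""
    return pd.read_csv(bundled_path("brain_assignments.tsv"), sep="\t")
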