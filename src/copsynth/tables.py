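"""Loaders for the packaged reference tables.

Three small CSVs ship with the package:

* ``copepod_orders.csv`` — published order-level sampling counts for the
  Copepoda (described species and families per order, and how many of
  each carry molecular phylogenetic data);
* ``copepod_studies.csv`` — the manifest of the 31 published molecular
  phylogenies grafted into the copepod synthesis tree, with their ranks
  and comparator metadata;
* ``parasitic_clades.csv`` — the 14 independent parasitic clades with
  their evidence tier (direct / indirect / taxonomic) and the taxonomy
  names that anchor each clade.
"""

from __future__ import annotations

import io
from importlib.resources import files

import pandas as pd

__all__ = ["load_order_table", "load_study_manifest", "load_clade_table"]


def _read(name: str, **kwargs) -> pd.DataFrame:
    text = files("copsynth.data").joinpath(name).read_text()
    return pd.read_csv(io.StringIO(text), comment="#", **kwargs)


def load_order_table() -> pd.DataFrame:
    """Order-level species/family totals and sampled counts."""
    return _read("copepod_orders.csv")


def load_study_manifest() -> pd.DataFrame:
    """The ranked manifest of source phylogenies."""
    return _read("copepod_studies.csv")


def load_clade_table() -> pd.DataFrame:
    """The parasitic clade definitions with expected support tiers."""
    return _read("parasitic_clades.csv")
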