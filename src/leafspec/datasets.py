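"""Packaged reference tables: dataset composition and reference model skill.

Two small fixtures ship with the package:

- ``species_composition.csv``: leaves measured per species in each of three
  tropical campaigns (a Brazil campaign and two Panama campaigns).  Used to
  exercise the dataset bookkeeping and the species/site split designs at a
  realistic multi-campaign composition.
- ``plsr_performance_reference.csv``: reference validation skill
  (RMSE, trait range, %RMSE, R^2) of ensemble PLSR models per trait and
  split design, used as a worked example for the metric machinery.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

from .validation import Dataset

__all__ = [
    "load_species_composition",
    "load_performance_reference",
    "composition_to_dataset",
]

_CAMPAIGN_COLS = {
    "brazil_2012_13": ("Brazil_Tapajos", "2012-13"),
    "panama_2016_17": ("Panama_SanLorenzo", "2016-17"),
    "panama_2020": ("Panama_SanLorenzo", "2020"),
}


def _data_path(name: str):
    return importlib.resources.files("leafspec").joinpath(f"data/{name}")


def load_species_composition() -> pd.DataFrame:
    """Species x campaign leaf counts (wide, one row per species)."""
    with _data_path("species_composition.csv").open("rb") as fh:
        return pd.read_csv(fh)


def load_performance_reference() -> pd.DataFrame:
    """Reference validation-performance table (trait x split rows)."""
    with _data_path("plsr_performance_reference.csv").open("rb") as fh:
        return pd.read_csv(fh)


def composition_to_dataset(composition: pd.DataFrame | None = None) -> Dataset:
    """Expand the species x campaign counts into a per-leaf metadata table.

    One row per leaf with ``leaf_id``, ``species``, ``site`` and ``campaign``
    (no traits or spectra) -- enough to drive the split designs and the
    bookkeeping checks on the real study's composition.
    """
    if composition is None:
        composition = load_species_composition()
    rows = []
    counter = 0
    for _, sp in composition.iterrows():
        for col, (site, campaign) in _CAMPAIGN_COLS.items():
            for _ in range(int(sp[col])):
                counter += 1
                rows.append(
                    {
                        "leaf_id": f"leaf_{counter:04d}",
                        "species": sp["species"],
                        "site": site,
                        "campaign": campaign,
                    }
                )
    table = pd.DataFrame(rows)
    # placeholder trait column so trait-eligibility machinery has something
    # to chew on when only bookkeeping is exercised
    table["Vcmax25"] = np.nan
    return Dataset(table=table)
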