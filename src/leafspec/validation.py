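"""Train/validation split designs and performance metrics for spectra-trait models.

Three split designs probe increasingly hard generalisation questions:

- ``random``: a leaf-level simple random sample (80/20 by default); training
  and validation may share species and even plants.
- ``species``: a fraction of the species newly measured in the most recent
  campaign is held out entirely, so validation species never occur in
  training.
- ``site``: all Panama observations train, all Brazil observations validate
  -- different site, species and instrument.  Traits with no Brazil data are
  refused; sparse ones trigger a warning.

Model skill is summarised by R^2 (1 - SSres/SStot on the validation set,
which penalises bias and can be negative), RMSE, and %RMSE -- the RMSE
standardised by the trait's range over the whole dataset, making errors
comparable across traits with different units of magnitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraMatrix

__all__ = [
    "Dataset",
    "SplitSpec",
    "MetricsReport",
    "make_random_split",
    "make_species_split",
    "make_site_split",
    "compute_metrics",
    "percent_rmse",
    "trait_range",
    "reports_to_dataframe",
]

TRAITS = ("Vcmax25", "Jmax25", "Tp25", "Rdark25")


@dataclass
class Dataset:
    """Joined leaf table: traits + metadata, optionally with a spectra matrix.

    ``table`` must have columns ``leaf_id``, ``species``, ``site``,
    ``campaign`` plus any of the trait columns (NaN where a trait was not
    measured for a leaf).  When ``spectra`` is given, every leaf in the table
    must have a spectrum row.
    """

    table: pd.DataFrame
    spectra: SpectraMatrix | None = None

    def __post_init__(self) -> None:
        required = {"leaf_id", "species", "site", "campaign"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"dataset table missing columns: {sorted(missing)}")
        if self.table["leaf_id"].duplicated().any():
            raise ValueError("duplicate leaf_id in dataset table")
        if self.spectra is not None:
            have = set(map(str, self.spectra.leaf_ids))
            need = set(map(str, self.table["leaf_id"]))
            if not need <= have:
                raise ValueError("some leaves have no spectrum")

    def eligible(self, trait: str) -> pd.DataFrame:
        """Rows with a finite value for ``trait``."""
        if trait not in self.table.columns:
            raise KeyError(f"trait {trait!r} not in dataset")
        return self.table[np.isfinite(self.table[trait].to_numpy(dtype=float))]

    def design(self, trait: str, leaf_ids):
        """(X, y) for the given leaves: spectra rows and trait values."""
        if self.spectra is None:
            raise ValueError("dataset has no spectra")
        sub = self.table.set_index("leaf_id").loc[list(leaf_ids)]
        X = self.spectra.subset(np.asarray(leaf_ids)).values
        return X, sub[trait].to_numpy(dtype=float)


@dataclass
class SplitSpec:
    """A realised train/validation partition of leaf ids."""

    kind: str
    fraction: float | None
    seed: int | None
    train_ids: list
    val_ids: list

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.val_ids)
        if overlap:
            raise ValueError(f"train/validation overlap: {sorted(overlap)[:5]} ...")


@dataclass
class MetricsReport:
    """R^2 / RMSE / %RMSE of one trait on one validation set."""

    trait: str
    split: str
    n_obs: int
    n_val: int
    n_comp: int | None
    rmse: float
    range: float
    pct_rmse: float
    r2: float
    r2_definition: str = "1 - SSres/SStot"


def make_random_split(dataset: Dataset, trait: str, frac: float = 0.8, seed: int = 0) -> SplitSpec:
    """Leaf-level simple random sample of the trait-eligible leaves.

    ``floor(frac * n)`` leaves train; the remainder validate.
    """
    ids = dataset.eligible(trait)["leaf_id"].to_numpy()
    n = ids.size
    n_train = int(math.floor(frac * n))
    if n_train < 2 or n - n_train < 1:
        raise ValueError(f"too few eligible leaves (n={n}) for a {frac:.0%} split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return SplitSpec(
        kind="random",
        fraction=frac,
        seed=seed,
        train_ids=list(ids[perm[:n_train]]),
        val_ids=list(ids[perm[n_train:]]),
    )


def _new_species(table: pd.DataFrame, campaign: str) -> list:
    """Species present in ``campaign`` and absent from all earlier campaigns."""
    in_new = set(table.loc[table["campaign"] == campaign, "species"])
    in_old = set(table.loc[table["campaign"] != campaign, "species"])
    return sorted(in_new - in_old)


def make_species_split(
    dataset: Dataset,
    new_species_frac: float = 0.3,
    seed: int = 0,
    campaign: str = "2020",
) -> SplitSpec:
    """Hold out whole species that first appear in the given campaign.

    ``round(new_species_frac * n_new)`` of the new species (round half away
    from zero) are sampled; *all* their leaves form the validation set and
    every other leaf trains, so validation species never occur in training.
    """
    new = _new_species(dataset.table, campaign)
    if not new:
        raise ValueError(f"no species are new to campaign {campaign!r}")
    n_sample = int(math.floor(new_species_frac * len(new) + 0.5))
    n_sample = max(1, min(n_sample, len(new)))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(np.asarray(new, dtype=object), size=n_sample, replace=False))
    is_val = dataset.table["species"].isin(chosen)
    return SplitSpec(
        kind="species",
        fraction=new_species_frac,
        seed=seed,
        train_ids=list(dataset.table.loc[~is_val, "leaf_id"]),
        val_ids=list(dataset.table.loc[is_val, "leaf_id"]),
    )


def make_site_split(dataset: Dataset, trait: str, sparse_threshold: int = 15) -> SplitSpec:
    """Deterministic partition: Panama sites train, the Brazil site validates.

    Raises for traits with no Brazil observations; warns when the Brazil
    sample is thin enough that the validation metrics are fragile.
    """
    elig = dataset.eligible(trait)
    is_brazil = elig["site"].str.startswith("Brazil")
    n_val = int(is_brazil.sum())
    if n_val == 0:
        raise ValueError(
            f"site split unavailable for {trait!r}: no Brazil observations"
        )
    if n_val < sparse_threshold:
        warnings.warn(
            f"site split for {trait!r} has only {n_val} Brazil observations",
            RuntimeWarning,
        )
    return SplitSpec(
        kind="site",
        fraction=None,
        seed=None,
        train_ids=list(elig.loc[~is_brazil, "leaf_id"]),
        val_ids=list(elig.loc[is_brazil, "leaf_id"]),
    )


def percent_rmse(rmse: float, whole_dataset_range: float) -> float:
    """RMSE as a percentage of the trait's range over the whole dataset."""
    if whole_dataset_range <= 0:
        raise ValueError("trait range must be positive")
    return 100.0 * rmse / whole_dataset_range


def trait_range(dataset: Dataset, trait: str) -> float:
    """max - min of the trait over every leaf with a value, before any split."""
    vals = dataset.eligible(trait)[trait].to_numpy(dtype=float)
    return float(np.max(vals) - np.min(vals))


def compute_metrics(
    observed,
    predicted,
    whole_dataset_range: float,
    trait: str = "",
    split: str = "",
    n_obs: int | None = None,
    n_comp: int | None = None,
) -> MetricsReport:
    """RMSE, %RMSE and R^2 of predictions on a validation set.

    ``whole_dataset_range`` is the trait's max - min across the *entire*
    dataset (all campaigns), not just the validation part.  R^2 is
    ``1 - SSres/SStot`` on the validation observations; it is not clipped
    and can be negative for predictions worse than the validation mean.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.ndim != 1:
        raise ValueError("observed and predicted must be matching 1-d vectors")
    if observed.size < 2:
        raise ValueError("need at least 2 validation observations")
    if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(predicted))):
        raise ValueError("non-finite values in observed/predicted")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    sstot = float(np.sum((observed - observed.mean()) ** 2))
    if sstot == 0:
        warnings.warn("zero-variance observed vector: R^2 undefined", RuntimeWarning)
        r2 = float("nan")
    else:
        r2 = 1.0 - float(np.sum((observed - predicted) ** 2)) / sstot
    return MetricsReport(
        trait=trait,
        split=split,
        n_obs=int(n_obs) if n_obs is not None else observed.size,
        n_val=observed.size,
        n_comp=n_comp,
        rmse=rmse,
        range=float(whole_dataset_range),
        pct_rmse=percent_rmse(rmse, whole_dataset_range),
        r2=r2,
    )


def reports_to_dataframe(reports) -> pd.DataFrame:
    """Stack metric reports into a table (one row per trait x split)."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "split": r.split,
                "n_obs": r.n_obs,
                "n_val": r.n_val,
                "n_comp": r.n_comp,
                "rmse": r.rmse,
                "range": r.range,
                "pct_rmse": r.pct_rmse,
                "r2": r.r2,
            }
            for r in reports
        ]
    )
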