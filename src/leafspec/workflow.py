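"""End-to-end orchestration: curves -> traits -> spectra-trait models -> metrics.

Thin glue over the fitting, spectra and validation modules so the whole
pipeline (as run on a field campaign or on synthetic data) is a few calls:

>>> curves = read_gas_exchange("gas_exchange.csv")          # doctest: +SKIP
>>> fits_df, fits = fit_curves(curves, seed=1)              # doctest: +SKIP
>>> ds = assemble_dataset(fits_df, spectra_matrix, meta_df) # doctest: +SKIP
>>> report, ens, preds = evaluate_split(ds, "Vcmax25", split, seed=1)  # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aci import ACiModel, ACiResults, GasExchangeCurve
from .pls import SpectraTraitModel
from .spectra import SpectraMatrix
from .validation import Dataset, MetricsReport, SplitSpec, compute_metrics, trait_range

__all__ = ["fit_curves", "assemble_dataset", "evaluate_split"]


def fit_curves(
    curves: list[GasExchangeCurve],
    seed: int = 0,
    select_tp: bool = True,
    n_starts: int = 3,
) -> tuple[pd.DataFrame, list[ACiResults]]:
    """Fit every curve, AIC-selecting the Ap limb per leaf when ``select_tp``.

    Returns a trait table (leaf_id, Vcmax25, Jmax25, Tp25 -- NaN where the
    Ap-free model won -- and the fitting respiration Rd25) plus the full
    results objects.  Note the co-fitted Rd25 is not a dark-respiration
    measurement; Rdark25 comes from dark-adapted time series.
    """
    fits = []
    for i, curve in enumerate(curves):
        model = ACiModel(curve)
        if select_tp:
            fit = model.fit_select(seed=seed + i, n_starts=n_starts)
        else:
            fit = model.fit(include_tp=False, seed=seed + i, n_starts=n_starts)
        fits.append(fit)
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "leaf_id": f.leaf_id,
                "Vcmax25": p.Vcmax25,
                "Jmax25": p.Jmax25,
                "Tp25": p.Tp25 if p.Tp25 is not None else np.nan,
                "Rd25": p.Rd25,
                "sigma": f.sigma,
                "AIC": f.aic,
                "tp_included": f.tp_included,
                "reliable": f.reliable,
            }
        )
    return pd.DataFrame(rows), fits


def assemble_dataset(
    traits: pd.DataFrame,
    spectra: SpectraMatrix,
    metadata: pd.DataFrame | None = None,
) -> Dataset:
    """Join a trait table with per-leaf metadata and a spectra matrix."""
    table = traits.copy()
    if metadata is not None:
        table = table.merge(metadata, on="leaf_id", how="left", suffixes=("", "_meta"))
    for col in ("species", "site", "campaign"):
        if col not in table.columns:
            table[col] = "unknown"
    keep = [c for c in table.columns if not c.endswith("_meta")]
    return Dataset(table=table[keep], spectra=spectra.subset(table["leaf_id"].to_numpy()))


def evaluate_split(
    dataset: Dataset,
    trait: str,
    split: SplitSpec,
    ncomp: int | None = None,
    n_iter: int = 1000,
    train_frac: float = 0.7,
    seed: int = 0,
    max_ncomp: int = 25,
):
    """Train an ensemble on the split's training leaves, score its validation leaves.

    Leaves without a finite trait value are dropped from both sides.  The
    component count is PRESS/one-SE selected on the training part unless
    ``ncomp`` is fixed (as when replaying species/site splits with the count
    chosen on the random split).  Returns ``(MetricsReport, ensemble,
    predictions)``; %RMSE uses the trait's range over the whole dataset.
    """
    elig = set(dataset.eligible(trait)["leaf_id"])
    train_ids = [i for i in split.train_ids if i in elig]
    val_ids = [i for i in split.val_ids if i in elig]
    if len(val_ids) < 2:
        raise ValueError(f"split leaves {len(val_ids)} validation observations for {trait!r}")
    X_tr, y_tr = dataset.design(trait, train_ids)
    X_va, y_va = dataset.design(trait, val_ids)
    model = SpectraTraitModel(
        X_tr, y_tr, trait=trait, wavelengths=dataset.spectra.wavelengths
    )
    ens = model.fit(
        ncomp=ncomp, n_iter=n_iter, train_frac=train_frac, seed=seed, max_ncomp=max_ncomp
    )
    preds = ens.predict(X_va, leaf_ids=val_ids, seed=seed)
    report = compute_metrics(
        y_va,
        preds["mean"].to_numpy(),
        trait_range(dataset, trait),
        trait=trait,
        split=split.kind,
        n_obs=len(train_ids) + len(val_ids),
        n_comp=ens.ncomp,
    )
    return report, ens, preds
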