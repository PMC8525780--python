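"""Synthetic multi-species leaf datasets with the structure the pipeline assumes.

The generator emulates the statistical features of a multi-campaign tropical
gas-exchange + spectroscopy survey, so that every pipeline stage (curve
fitting, respiration averaging, spectra processing, PLSR training and the
three validation splits) can be exercised without field data:

- traits are drawn hierarchically from a multivariate log-normal: species
  means first, then leaves around their species mean, with strong positive
  correlation among Vcmax25, Jmax25, Tp25 and Rdark25;
- a Brazil-like site has lower photosynthetic capacity, no dark-respiration
  measurements and (almost) no Ap-limited curves, so the site-split code path
  -- including its refusals -- is exercised;
- A-Ci curves follow the standard 15-setpoint chamber CO2 sequence at
  30-32 degC leaf temperature, with Ci a fixed drawdown fraction of the
  setpoint and additive Gaussian measurement noise;
- reflectance spectra are a smooth vegetation-like baseline minus Gaussian
  absorption features whose depths are linear in the (standardised) traits,
  plus spatially correlated and white noise, so a linear method can recover
  the traits but not perfectly.

Defaults aim for the realistic regime of a tropical canopy survey (about 50
species, a few leaves per species, noise of the order of the instrument
noise); they are configuration, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aci import GasExchangeCurve
from .fvcb import FvCBParams, fvcb_forward, temp_scaler
from .spectra import SpectraMatrix, Spectrum, grid_wavelengths

__all__ = [
    "CO2_SETPOINTS",
    "TraitGeneratorConfig",
    "SpectraGeneratorConfig",
    "DatasetConfig",
    "gen_traits",
    "gen_aci_curve",
    "gen_dark_respiration",
    "gen_spectra",
    "gen_replicate_spectra",
    "gen_dataset",
]

#: chamber CO2 setpoint sequence of a standard A-Ci protocol (umol mol-1)
CO2_SETPOINTS = np.array(
    [400, 300, 225, 150, 100, 75, 50, 400, 475, 575, 675, 800, 1000, 1400, 1800],
    dtype=float,
)

_TRAITS = ("Vcmax25", "Jmax25", "Tp25", "Rdark25")


@dataclass
class TraitGeneratorConfig:
    """Hierarchical multivariate log-normal trait generator settings.

    ``log_means``/``log_sds`` are natural-log scale moments of the leaf-level
    marginals; ``correlations`` the 4x4 inter-trait correlation matrix in the
    order (Vcmax25, Jmax25, Tp25, Rdark25); ``species_var_frac`` the share of
    total log-variance placed at the species level.  ``site_fractions``
    allocates species to sites; the Brazil-like site gets ``brazil_log_shift``
    added to its species log-means, carries no Rdark25, and has Ap limitation
    in only ``1 - tp_present_frac_brazil`` of curves.  ``tp_present_frac``
    (default 0.32) is the fraction of non-Brazil leaves whose curves show an
    Ap limitation and hence a Tp25 value.
    """

    n_species: int = 50
    leaves_per_species: tuple[int, int] = (2, 8)
    log_means: dict = field(
        default_factory=lambda: {
            "Vcmax25": np.log(55.0),
            "Jmax25": np.log(95.0),
            "Tp25": np.log(6.5),
            "Rdark25": np.log(0.7),
        }
    )
    log_sds: dict = field(
        default_factory=lambda: {
            "Vcmax25": 0.45,
            "Jmax25": 0.45,
            "Tp25": 0.40,
            "Rdark25": 0.50,
        }
    )
    correlations: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [1.00, 0.90, 0.80, 0.60],
                [0.90, 1.00, 0.75, 0.55],
                [0.80, 0.75, 1.00, 0.50],
                [0.60, 0.55, 0.50, 1.00],
            ]
        )
    )
    species_var_frac: float = 0.6
    site_fractions: dict = field(
        default_factory=lambda: {
            "Panama_SanLorenzo": 0.65,
            "Panama_PNM": 0.20,
            "Brazil_Tapajos": 0.15,
        }
    )
    brazil_log_shift: dict = field(
        default_factory=lambda: {
            "Vcmax25": -0.55,
            "Jmax25": -0.55,
            "Tp25": -0.30,
            "Rdark25": 0.0,
        }
    )
    tp_present_frac: float = 0.32
    tp_present_frac_brazil: float = 0.02

    def __post_init__(self) -> None:
        C = np.asarray(self.correlations, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T):
            raise ValueError("correlations must be a symmetric 4x4 matrix")
        if np.min(np.linalg.eigvalsh(C)) <= 0:
            raise ValueError("correlation matrix is not positive definite")
        if not 0 <= self.species_var_frac <= 1:
            raise ValueError("species_var_frac must lie in [0, 1]")


def gen_traits(config: TraitGeneratorConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw a multi-species trait table with metadata.

    Returns one row per leaf with columns ``leaf_id``, ``species``, ``site``,
    ``campaign``, ``canopy_height_class``, ``leaf_age_class`` and the four
    traits.  Tp25 is NaN where the generated curve would show no Ap
    limitation; Rdark25 is NaN for the Brazil-like site.
    """
    cfg = config or TraitGeneratorConfig()
    rng = np.random.default_rng(seed)
    sds = np.array([cfg.log_sds[t] for t in _TRAITS])
    cov = np.outer(sds, sds) * np.asarray(cfg.correlations, dtype=float)
    cov_sp = cfg.species_var_frac * cov
    cov_leaf = (1.0 - cfg.species_var_frac) * cov
    mu = np.array([cfg.log_means[t] for t in _TRAITS])

    sites = list(cfg.site_fractions)
    probs = np.array([cfg.site_fractions[s] for s in sites], dtype=float)
    probs = probs / probs.sum()
    species_sites = rng.choice(sites, size=cfg.n_species, p=probs)

    rows = []
    counter = 0
    lo, hi = cfg.leaves_per_species
    for s in range(cfg.n_species):
        site = str(species_sites[s])
        mu_s = mu.copy()
        if site.startswith("Brazil"):
            mu_s = mu_s + np.array([cfg.brazil_log_shift[t] for t in _TRAITS])
            campaigns = ["2012-13"]
        else:
            # Panama species: new in 2020, older campaign only, or both
            u = rng.random()
            campaigns = ["2020"] if u < 0.45 else (["2016-17"] if u < 0.80 else ["2016-17", "2020"])
        sp_mean = rng.multivariate_normal(mu_s, cov_sp) if cfg.species_var_frac > 0 else mu_s
        n_leaves = int(rng.integers(lo, hi + 1))
        for _ in range(n_leaves):
            leaf_log = (
                rng.multivariate_normal(sp_mean, cov_leaf)
                if cfg.species_var_frac < 1
                else sp_mean
            )
            counter += 1
            vals = dict(zip(_TRAITS, np.exp(leaf_log)))
            tp_frac = (
                cfg.tp_present_frac_brazil if site.startswith("Brazil") else cfg.tp_present_frac
            )
            if rng.random() > tp_frac:
                vals["Tp25"] = np.nan
            if site.startswith("Brazil"):
                vals["Rdark25"] = np.nan
            rows.append(
                {
                    "leaf_id": f"syn_{counter:04d}",
                    "species": f"species_{s + 1:02d}",
                    "site": site,
                    "campaign": str(rng.choice(campaigns)),
                    "canopy_height_class": int(rng.integers(1, 6)),
                    "leaf_age_class": str(rng.choice(["young", "mature", "old"])),
                    **vals,
                }
            )
    return pd.DataFrame(rows)


def gen_aci_curve(
    traits: dict | pd.Series,
    co2_sequence=None,
    Tleaf: float | None = None,
    Q: float = 1800.0,
    noise_sd: float = 0.5,
    ci_drawdown: float = 0.8,
    seed: int = 0,
    leaf_id: str | None = None,
) -> GasExchangeCurve:
    """Simulate one leaf's A-Ci curve from its traits.

    Ci is a fixed stomatal drawdown fraction of the chamber setpoint; leaf
    temperature defaults to a draw from {30, 31, 32} degC; net assimilation
    is the FvCB forward prediction plus iid Gaussian noise (``noise_sd`` in
    umol m-2 s-1).  A NaN/absent Tp25 disables the Ap limb.
    """
    rng = np.random.default_rng(seed)
    for key in ("Vcmax25", "Jmax25"):
        if key not in traits or not np.isfinite(traits[key]):
            raise ValueError(f"missing trait {key!r} for curve simulation")
    tp = traits.get("Tp25", np.nan)
    tp = None if tp is None or not np.isfinite(tp) else float(tp)
    rd = traits.get("Rd25", traits.get("Rdark25", np.nan))
    rd = 1.0 if rd is None or not np.isfinite(rd) else float(rd)
    params = FvCBParams(
        Vcmax25=float(traits["Vcmax25"]),
        Jmax25=float(traits["Jmax25"]),
        Tp25=tp,
        Rd25=rd,
    )
    setpoints = CO2_SETPOINTS if co2_sequence is None else np.asarray(co2_sequence, dtype=float)
    if Tleaf is None:
        Tleaf = float(rng.choice([30.0, 31.0, 32.0]))
    Ci = ci_drawdown * setpoints
    A, _ = fvcb_forward(params, Ci, Tleaf, Q)
    A = A + rng.normal(0.0, noise_sd, size=A.shape) if noise_sd > 0 else A
    return GasExchangeCurve(
        leaf_id=str(leaf_id if leaf_id is not None else traits.get("leaf_id", "synthetic")),
        A=A,
        Ci=Ci,
        Tleaf=np.full_like(Ci, Tleaf),
        Q=np.full_like(Ci, Q),
    )


def gen_dark_respiration(
    rdark25: float,
    Tleaf: float = 30.0,
    n_samples: int = 60,
    sample_sd: float = 0.45,
    seed: int = 0,
):
    """1 Hz CO2-efflux samples around the temperature-scaled true respiration."""
    rng = np.random.default_rng(seed)
    true = rdark25 * float(temp_scaler("Rdark", Tleaf))
    return true + rng.normal(0.0, sample_sd, size=n_samples)


@dataclass
class SpectraGeneratorConfig:
    """Settings for the trait-linked reflectance generator.

    ``features`` is a list of ``(center_nm, width_nm, base_depth, loadings)``
    absorption features; each feature's depth is ``base_depth + loadings . z``
    with ``z`` the four standardised traits (Vcmax25, Jmax25, Tp25, Rdark25
    order).  Default centers echo chlorophyll (680 nm), the two water bands
    (1450/1940 nm) and a dry-matter SWIR feature (2100 nm).  ``white_noise_sd``
    is per-wavelength iid noise; ``smooth_noise_sd``/``smooth_scale_nm``
    control spatially correlated baseline noise.
    """

    grid_start: float = 500.0
    grid_end: float = 2400.0
    step: float = 1.0
    features: list = field(
        default_factory=lambda: [
            (680.0, 45.0, 0.22, (0.030, 0.012, 0.004, 0.010)),
            (1450.0, 60.0, 0.15, (0.010, 0.028, 0.008, 0.004)),
            (1940.0, 75.0, 0.20, (0.012, 0.010, 0.025, 0.008)),
            (2100.0, 80.0, 0.06, (0.008, 0.006, 0.006, 0.022)),
        ]
    )
    white_noise_sd: float = 0.002
    smooth_noise_sd: float = 0.004
    smooth_scale_nm: float = 50.0

    def wavelengths(self) -> np.ndarray:
        return grid_wavelengths(self.grid_start, self.grid_end, self.step)

    def __post_init__(self) -> None:
        wl = self.wavelengths()
        for c, w, d, load in self.features:
            if not wl[0] <= c <= wl[-1]:
                raise ValueError(f"feature center {c} nm outside the grid")


def _baseline(wl: np.ndarray) -> np.ndarray:
    """Smooth green-vegetation reflectance shape over 500-2400 nm."""
    red_edge = 0.38 / (1.0 + np.exp(-(wl - 715.0) / 18.0))
    green_bump = 0.06 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)
    swir_decline = 9e-5 * np.clip(wl - 1300.0, 0.0, None)
    return 0.06 + red_edge + green_bump - swir_decline


def _standardize_traits(traits: pd.DataFrame) -> np.ndarray:
    """Column-standardised trait matrix; missing values imputed at the mean (z=0)."""
    Z = np.empty((len(traits), len(_TRAITS)))
    for j, t in enumerate(_TRAITS):
        col = traits[t].to_numpy(dtype=float) if t in traits.columns else np.full(len(traits), np.nan)
        m = np.nanmean(col) if np.any(np.isfinite(col)) else 0.0
        s = np.nanstd(col) if np.any(np.isfinite(col)) else 1.0
        z = (col - m) / (s if s > 0 else 1.0)
        Z[:, j] = np.where(np.isfinite(z), z, 0.0)
    return Z


def _leaf_reflectance(z, cfg: SpectraGeneratorConfig, rng) -> np.ndarray:
    wl = cfg.wavelengths()
    refl = _baseline(wl).copy()
    for c, w, d0, load in cfg.features:
        depth = max(d0 + float(np.dot(load, z)), 0.0)
        refl -= depth * np.exp(-0.5 * ((wl - c) / w) ** 2)
    if cfg.smooth_noise_sd > 0:
        raw = rng.normal(0.0, 1.0, size=wl.size)
        kernel_half = int(3 * cfg.smooth_scale_nm / cfg.step)
        x = np.arange(-kernel_half, kernel_half + 1) * cfg.step
        kern = np.exp(-0.5 * (x / cfg.smooth_scale_nm) ** 2)
        kern /= np.sqrt(np.sum(kern**2))
        smooth = np.convolve(raw, kern, mode="same")
        refl += cfg.smooth_noise_sd * smooth
    if cfg.white_noise_sd > 0:
        refl += rng.normal(0.0, cfg.white_noise_sd, size=wl.size)
    return np.clip(refl, 0.0, 1.0)


def gen_spectra(
    traits: pd.DataFrame,
    config: SpectraGeneratorConfig | None = None,
    seed: int = 0,
) -> SpectraMatrix:
    """One reflectance spectrum per leaf, with absorption depths linear in traits."""
    cfg = config or SpectraGeneratorConfig()
    rng = np.random.default_rng(seed)
    Z = _standardize_traits(traits)
    values = np.array([_leaf_reflectance(Z[i], cfg, rng) for i in range(len(traits))])
    return SpectraMatrix(
        leaf_ids=traits["leaf_id"].to_numpy(),
        wavelengths=cfg.wavelengths(),
        values=values,
    )


def gen_replicate_spectra(
    traits: pd.DataFrame,
    config: SpectraGeneratorConfig | None = None,
    seed: int = 0,
    n_replicates: int = 3,
    replicate_sd: float = 0.004,
) -> list[Spectrum]:
    """Replicate scans per leaf: the leaf's spectrum plus white replicate jitter."""
    cfg = config or SpectraGeneratorConfig()
    rng = np.random.default_rng(seed)
    base = gen_spectra(traits, cfg, seed=seed)
    out = []
    for i, leaf_id in enumerate(base.leaf_ids):
        for r in range(n_replicates):
            noisy = base.values[i] + rng.normal(0.0, replicate_sd, size=base.wavelengths.size)
            out.append(
                Spectrum(
                    leaf_id=str(leaf_id),
                    wavelengths=base.wavelengths,
                    reflectance=np.clip(noisy, 0.0, 1.0),
                    replicate_index=r,
                )
            )
    return out


@dataclass
class DatasetConfig:
    """End-to-end dataset generation settings."""

    traits: TraitGeneratorConfig = field(default_factory=TraitGeneratorConfig)
    spectra: SpectraGeneratorConfig = field(default_factory=SpectraGeneratorConfig)
    aci_noise_sd: float = 0.5
    ci_drawdown: float = 0.8
    n_spectra_replicates: int = 3
    replicate_sd: float = 0.004
    rdark_sample_sd: float = 0.45


def gen_dataset(outdir, config: DatasetConfig | None = None, seed: int = 0) -> dict:
    """Write a complete synthetic study to ``outdir`` in the pipeline's CSV dialects.

    Files: ``gas_exchange.csv`` (leaf_id, A, Ci, Tleaf, Qin),
    ``dark_respiration.csv`` (leaf_id, time_s, efflux, Tleaf),
    ``spectra.csv`` (wide, with replicates), ``metadata.csv``,
    ``traits_true.csv`` (the generating values) and ``composition.csv``
    (species x campaign leaf counts).  Deterministic given ``seed``.
    """
    cfg = config or DatasetConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    s_traits, s_curves, s_rdark, s_spectra = [int(c.generate_state(1)[0] % (2**31)) for c in root.spawn(4)]

    traits = gen_traits(cfg.traits, seed=s_traits)

    gx_rows = []
    rd_rows = []
    for i, row in traits.iterrows():
        curve = gen_aci_curve(
            row,
            noise_sd=cfg.aci_noise_sd,
            ci_drawdown=cfg.ci_drawdown,
            seed=s_curves + i,
        )
        gx_rows.append(
            pd.DataFrame(
                {
                    "leaf_id": curve.leaf_id,
                    "A": curve.A,
                    "Ci": curve.Ci,
                    "Tleaf": curve.Tleaf,
                    "Qin": curve.Q,
                }
            )
        )
        if np.isfinite(row.get("Rdark25", np.nan)):
            samples = gen_dark_respiration(
                row["Rdark25"],
                Tleaf=float(curve.Tleaf[0]),
                sample_sd=cfg.rdark_sample_sd,
                seed=s_rdark + i,
            )
            rd_rows.append(
                pd.DataFrame(
                    {
                        "leaf_id": curve.leaf_id,
                        "time_s": np.arange(samples.size),
                        "efflux": samples,
                        "Tleaf": curve.Tleaf[0],
                    }
                )
            )

    spectra = gen_replicate_spectra(
        traits,
        cfg.spectra,
        seed=s_spectra,
        n_replicates=cfg.n_spectra_replicates,
        replicate_sd=cfg.replicate_sd,
    )

    from .spectra import write_spectra

    paths = {
        "gas_exchange": outdir / "gas_exchange.csv",
        "dark_respiration": outdir / "dark_respiration.csv",
        "spectra": outdir / "spectra.csv",
        "metadata": outdir / "metadata.csv",
        "traits_true": outdir / "traits_true.csv",
        "composition": outdir / "composition.csv",
    }
    pd.concat(gx_rows, ignore_index=True).to_csv(paths["gas_exchange"], index=False, float_format="%.6f")
    if rd_rows:
        pd.concat(rd_rows, ignore_index=True).to_csv(paths["dark_respiration"], index=False, float_format="%.6f")
    else:
        pd.DataFrame(columns=["leaf_id", "time_s", "efflux", "Tleaf"]).to_csv(paths["dark_respiration"], index=False)
    write_spectra(spectra, paths["spectra"])
    meta_cols = ["leaf_id", "species", "site", "campaign", "canopy_height_class", "leaf_age_class"]
    traits[meta_cols].to_csv(paths["metadata"], index=False)
    traits.to_csv(paths["traits_true"], index=False, float_format="%.6f")
    comp = (
        traits.groupby(["species", "campaign"]).size().unstack(fill_value=0).reset_index()
    )
    comp.to_csv(paths["composition"], index=False)
    return {k: str(v) for k, v in paths.items()}
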