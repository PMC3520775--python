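"""Published population estimates from the original (R)-[11C]verapamil studies.

The rat study (paired 140 + 60 min scans, tariquidar 3 or 15 mg/kg at 60 min
into the baseline scan) and the human study (120 + 40 min scans, tariquidar
2 mg/kg infused over 30 min) were analyzed with the same population model
this package implements.  The reported population estimates are shipped as
plain CSV resources: they seed the synthetic-study generator, serve as
realistic defaults, and are the inputs to the derived-quantity reports
(distribution volumes, fold changes, efflux-decrease summaries).

Two model variants exist per region: ``all_data`` (the full scans, with a
separate scan effect for the post-inhibition scan) and
``tq_window_excluded`` (the segment during and immediately after tariquidar
administration removed, in which case no scan effect is identifiable).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .model_core import BrainParams, CovariateEffects, Placement, PlasmaParams

RAT_REGIONS = ("WB", "CS", "EC", "SHipp", "THipp", "Th", "Cer", "FMC")

#: dose groups (mg/kg) appearing in each study
RAT_DOSE_GROUPS = (3.0, 15.0)
HUMAN_DOSE_GROUP = 2.0


def _read(name: str) -> pd.DataFrame:
    with resources.files("petpop.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_brain_estimates(species: str = "rat", variant: str = "all_data") -> pd.DataFrame:
    """Per-region brain-model estimates, indexed by region."""
    df = _read("reference_brain_estimates.csv")
    df = df[(df["species"] == species) & (df["variant"] == variant)]
    if df.empty:
        raise ValueError(f"no reference estimates for {species!r}/{variant!r}")
    return df.set_index("region")


def load_plasma_estimates(species: str = "rat") -> pd.DataFrame:
    """Plasma-model estimates (long format: param, estimate, iiv_sd)."""
    df = _read("reference_plasma_estimates.csv")
    df = df[df["species"] == species]
    if df.empty:
        raise ValueError(f"no reference plasma estimates for {species!r}")
    return df.set_index("param")


def reference_plasma_params(species: str = "rat") -> PlasmaParams:
    est = load_plasma_estimates(species)["estimate"]
    return PlasmaParams(
        vc=est["vc"], vp1=est["vp1"], vp2=est["vp2"],
        cl=est["cl"], q1=est["q1"], q2=est["q2"],
    )


def reference_brain_params(
    species: str = "rat", region: str = "WB", variant: str = "all_data"
) -> BrainParams:
    row = load_brain_estimates(species, variant).loc[region]
    return BrainParams(
        vbr1=row["vbr1"], vbr2=row["vbr2"], qin=row["qin"],
        qout=row["qout"], qbr=row["qbr"], vbr2_fixed=species == "rat",
    )


def reference_covariate_effects(
    species: str = "rat", region: str = "WB", variant: str = "all_data"
) -> CovariateEffects:
    """Covariate effects for one region; absent effects default to 1."""
    row = load_brain_estimates(species, variant).loc[region]
    if species == "rat":
        eff_tq = {3.0: float(row["eff_tq_3"]), 15.0: float(row["eff_tq_15"])}
    else:
        eff_tq = {2.0: float(row["eff_tq_2"])}
    eff_scan = float(row["eff_scan"]) if np.isfinite(row.get("eff_scan", np.nan)) else 1.0
    eff_se = float(row["eff_se"]) if np.isfinite(row.get("eff_se", np.nan)) else 1.0
    return CovariateEffects(
        eff_tariquidar=eff_tq, eff_scan=eff_scan, eff_se=eff_se,
        placement=Placement.ON_QOUT,
    )
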