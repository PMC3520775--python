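"""Dataset and curve I/O, configuration, and derived-quantity reports.

The headline quantities of the analysis are derived from the brain-model
estimates:

* the brain-to-plasma partition coefficient ``VT = Qin / (D * Qout)``,
  where ``D`` is the inhibition factor of the reported condition
  (baseline: D = 1; during/immediately after tariquidar: D = the dose-group
  effect; post-inhibition scan: dose-group effect x scan effect);
* fold change of VT versus baseline (equal to 1/D before rounding);
* the percent decrease in efflux clearance, ``100 * (1 - D)``, summarized
  as mean +/- SD across the analysis regions.

Reported values follow the conventions of the original tables: VT to two
significant figures, fold changes to one decimal, percent changes to whole
percent, all rounded half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import reference
from .model_core import (
    BrainParams,
    CovariateEffects,
    ModelError,
    TimeActivityCurve,
    Unit,
)
from .synthetic_data import Dataset, OBS_COLUMNS, SUBJECT_COLUMNS

#: the eight rat analysis regions summarized in the efflux-decrease report
ANALYSIS_REGIONS = reference.RAT_REGIONS

CONDITIONS = ("baseline", "during_tariquidar", "post_inhibition")


# ---------------------------------------------------------------------------
# Rounding conventions
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, half away from zero."""
    if x == 0 or not np.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x)))
    return round_half_away(x, sig - 1 - exponent)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def condition_d(effs: CovariateEffects, dose_group: float, condition: str) -> float:
    """Inhibition factor D for a reporting condition."""
    if condition == "baseline":
        return 1.0
    if dose_group not in effs.eff_tariquidar:
        raise ModelError(f"no tariquidar effect for dose group {dose_group}")
    eff = effs.eff_tariquidar[dose_group]
    if condition == "during_tariquidar":
        return eff
    if condition == "post_inhibition":
        return eff * effs.eff_scan
    raise ModelError(f"unknown condition {condition!r}")


def vt_nlme(brain: BrainParams, d: float = 1.0) -> float:
    """Equilibrium brain-to-plasma partition coefficient Qin / (D * Qout)."""
    return brain.qin / (brain.qout * d)


def vt_nlme_table(
    params: Mapping[str, tuple[BrainParams, CovariateEffects]],
    dose_group: float,
    conditions: Sequence[str] = CONDITIONS,
) -> pd.DataFrame:
    """Per-region VT and fold change versus baseline, with reported roundings.

    ``params`` maps region labels to (brain parameters, covariate effects).
    """
    if not params:
        raise ModelError("no regions given")
    rows = []
    for region, (brain, effs) in params.items():
        vt_base = vt_nlme(brain, 1.0)
        for condition in conditions:
            d = condition_d(effs, dose_group, condition)
            vt = vt_nlme(brain, d)
            fold = vt / vt_base
            rows.append(
                {
                    "region": region,
                    "condition": condition,
                    "dose_group": dose_group,
                    "d": d,
                    "vt": vt,
                    "vt_reported": round_sig(vt, 2),
                    "fold_change": fold,
                    "fold_reported": round_half_away(fold, 1),
                }
            )
    return pd.DataFrame(rows)


def qout_change_summary(
    effects: Mapping[str, CovariateEffects],
    dose_group: float,
    condition: str = "during_tariquidar",
) -> pd.DataFrame:
    """Percent decrease in efflux clearance per region, plus mean +/- SD.

    The decrease is ``100 * (1 - D)``; the summary row reports the mean and
    the sample (n-1) standard deviation across regions, rounded to whole
    percent.
    """
    if not effects:
        raise ModelError("no regions given")
    rows = []
    decreases = []
    for region, effs in effects.items():
        d = condition_d(effs, dose_group, condition)
        dec = 100.0 * (1.0 - d)
        decreases.append(dec)
        rows.append(
            {
                "region": region, "dose_group": dose_group, "condition": condition,
                "decrease_percent": dec,
                "decrease_reported": round_half_away(dec, 0),
            }
        )
    arr = np.asarray(decreases)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    rows.append(
        {
            "region": "mean", "dose_group": dose_group, "condition": condition,
            "decrease_percent": mean, "decrease_reported": round_half_away(mean, 0),
            "sd_percent": sd, "sd_reported": round_half_away(sd, 0),
        }
    )
    return pd.DataFrame(rows)


def reference_region_params(
    species: str = "rat", variant: str = "all_data",
    regions: Sequence[str] | None = None,
) -> dict[str, tuple[BrainParams, CovariateEffects]]:
    """(BrainParams, CovariateEffects) per region from the published estimates."""
    table = reference.load_brain_estimates(species, variant)
    regions = list(regions) if regions is not None else list(table.index)
    return {
        r: (
            reference.reference_brain_params(species, r, variant),
            reference.reference_covariate_effects(species, r, variant),
        )
        for r in regions
    }


# ---------------------------------------------------------------------------
# Dataset CSV I/O
# ---------------------------------------------------------------------------

_NUMERIC_OBS = ("scan", "time_min", "value")


def write_dataset(dataset: Dataset, path) -> None:
    """Write the denormalized long-format dataset CSV (lossless precision)."""
    dataset.to_long().to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> Dataset:
    """Read and validate a long-format dataset CSV.

    Schema violations raise ``ModelError`` naming the offending column or
    the 1-based data row numbers involved.
    """
    df = pd.read_csv(path)
    for col in OBS_COLUMNS + SUBJECT_COLUMNS:
        if col not in df.columns:
            raise ModelError(f"dataset file is missing mandatory column {col!r}")
    for col in _NUMERIC_OBS:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            rows = [int(i) + 1 for i in df.index[bad][:5]]
            raise ModelError(f"non-numeric {col!r} values at rows {rows}")
        df[col] = vals
    dup = df.duplicated(subset=["subject_id", "scan", "time_min", "obs_type"])
    if dup.any():
        rows = [int(i) + 1 for i in df.index[dup][:5]]
        raise ModelError(f"duplicate (subject, scan, time, obs_type) at rows {rows}")
    return Dataset.from_long(df)


def write_tac(tac: TimeActivityCurve, path) -> None:
    pd.DataFrame(
        {
            "label": tac.label, "time_min": tac.times,
            "value": tac.values, "unit": tac.unit.value,
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_tac(path) -> TimeActivityCurve:
    df = pd.read_csv(path)
    for col in ("label", "time_min", "value", "unit"):
        if col not in df.columns:
            raise ModelError(f"TAC file is missing mandatory column {col!r}")
    units = df["unit"].unique()
    if len(units) != 1:
        raise ModelError("TAC file mixes units")
    return TimeActivityCurve(
        str(df["label"].iloc[0]),
        df["time_min"].to_numpy(float),
        df["value"].to_numpy(float),
        Unit(units[0]),
    )


# ---------------------------------------------------------------------------
# Fit reports and config
# ---------------------------------------------------------------------------


def fit_report_frame(fit) -> pd.DataFrame:
    """Parameter table of a fit: estimate, RSE %, and IIV, like the
    published estimate tables (missing uncertainties reported as NaN)."""
    iiv_by_param: dict[str, float] = {}
    for b in fit.iiv:
        for nm in b.names:
            iiv_by_param[nm] = b.omega
    rows = []
    rse = fit.rse or {}
    for name, value in fit.theta.items():
        rows.append(
            {
                "parameter": name, "estimate": value,
                "rse_percent": rse.get(name, np.nan),
                "iiv_sd": iiv_by_param.get(name, np.nan),
                "fixed": name in fit.model.fixed,
            }
        )
    for key, value in fit.sigma.items():
        rows.append(
            {
                "parameter": f"sigma[{key}]", "estimate": value,
                "rse_percent": rse.get(f"sigma[{key}]", np.nan),
                "iiv_sd": np.nan, "fixed": key in fit.model.sigma_fixed,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["ofv"] = fit.ofv
    return df


def write_fit_report(fit, path_prefix) -> None:
    """Write a fit as a parameter CSV and a small YAML summary."""
    frame = fit_report_frame(fit)
    frame.to_csv(f"{path_prefix}_params.csv", index=False)
    summary = {
        "name": fit.model.name,
        "ofv": float(fit.ofv),
        "success": bool(fit.success),
        "nfev": int(fit.convergence.get("nfev", 0)),
        "sigma": {k: float(v) for k, v in fit.sigma.items()},
        "iiv": [
            {"names": list(b.names), "omega": float(b.omega)} for b in fit.iiv
        ],
    }
    with open(f"{path_prefix}_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ModelError("config file must contain a mapping")
    return cfg


def save_config(cfg: Mapping, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)
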