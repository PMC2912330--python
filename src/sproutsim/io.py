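"""Result containers on disk: self-describing arrays plus flat CSV summaries.

Converged fields are exported as an :class:`xarray.Dataset` with dimensions
``z``/``r`` for the volumetric species (both concentration frames) and
``z_bm`` for the basement-membrane layer, carrying the fully resolved
parameter set in the global attributes.  Written as classic NetCDF through
xarray's scipy backend.
"""

from __future__ import annotations

from dataclasses import fields

import numpy as np
import pandas as pd
import xarray as xr

from .analysis import MetricsRow, parameter_hash
from .scenarios import ScenarioResult

__all__ = ["result_to_dataset", "save_result", "save_metrics_csv", "load_dataset"]


def _flatten_params(params) -> dict:
    out = {}
    for sec in ("kinetics", "geometry", "matrix", "boundary"):
        rec = getattr(params, sec)
        for f in fields(rec):
            v = getattr(rec, f.name)
            if v is None:
                v = "none"
            out[f"{sec}.{f.name}"] = v
    return out


def result_to_dataset(result: ScenarioResult) -> xr.Dataset:
    model, st = result.model, result.state
    g = model.grid
    K = model.params.matrix.K_ECM

    data = {}
    for name in ("V165", "V114", "P", "V165H"):
        bulk = getattr(st.field, name)
        data[f"{name}_bulk"] = (("z", "r"), bulk)
        data[f"{name}_fluid"] = (("z", "r"), np.where(model.act, bulk / K, np.nan))

    z_bm = np.concatenate([g.z_centers[model.wall_iz], [0.0]])
    for name in ("V165", "V114", "P", "V165H", "R2", "V165R2", "V114R2", "P_teth"):
        data[f"bm_{name}"] = (("z_bm",), getattr(st.surface, name))
    data["bm_area"] = (("z_bm",), model.bm_area)

    attrs = _flatten_params(model.params)
    attrs["scenario"] = result.name
    attrs["parameter_hash"] = parameter_hash(model.params)
    for k, v in result.calibration.items():
        attrs[f"calibration.{k}"] = v
    for stage, diag in result.diagnostics.items():
        if isinstance(diag, dict):
            for k, v in diag.items():
                attrs[f"{stage}.{k}"] = v

    return xr.Dataset(
        data,
        coords={"z": g.z_centers, "r": g.r_centers, "z_bm": z_bm},
        attrs=attrs,
    )


def save_result(result: ScenarioResult, path) -> None:
    result_to_dataset(result).to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    return xr.open_dataset(path, engine="scipy")


def save_metrics_csv(rows, path) -> None:
    """Write metric rows (MetricsRow or mappings) as a flat CSV with floats
    at 6 significant digits for byte-stable output."""
    recs = [r.as_dict() if isinstance(r, MetricsRow) else dict(r) for r in rows]
    df = pd.DataFrame.from_records(recs)
    df.to_csv(path, index=False, float_format="%.6g")
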