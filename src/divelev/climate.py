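"""Per-gradient elevation → Bioclim calibration models.

Each mountain gradient gets one polynomial model per Bioclim variable,
fitted to calibration points (elevation, value).  Temperature variables
(Bio1, Bio5, Bio6) use a straight lapse line and are always accepted;
precipitation variables (Bio12–Bio19) pick the best of degrees 1–3 and are
accepted only when the adjusted R² clears a threshold (default 0.5), which
enforces the exclusion rule for poorly predicted precipitation surfaces.
Direct station/raster values, where available, take precedence over model
predictions when climate is attached to band statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TEMPERATURE_VARIABLES",
    "PRECIPITATION_VARIABLES",
    "ClimateModel",
    "ClimateModelRejected",
    "fit_lapse_model",
    "predict_climate",
    "attach_climate",
    "fit_all_models",
    "read_calibration",
]

TEMPERATURE_VARIABLES = ("bio1", "bio5", "bio6")
PRECIPITATION_VARIABLES = ("bio12", "bio13", "bio14", "bio18", "bio19")
CLIMATE_VARIABLES = TEMPERATURE_VARIABLES + PRECIPITATION_VARIABLES


class ClimateModelRejected(RuntimeError):
    """Prediction was requested from a model that failed the acceptance rule."""


@dataclass
class ClimateModel:
    gradient_id: str
    variable: str
    degree: int
    coef: np.ndarray          # ascending powers of elevation (m)
    r2: float
    adj_r2: float
    accepted: bool
    n_points: int


def _polyfit(elev: np.ndarray, value: np.ndarray, degree: int):
    # fit on rescaled elevation (cubes of metre values are badly conditioned)
    # and back-transform the coefficients exactly
    scale = max(float(np.max(np.abs(elev))), 1.0)
    Xs = np.vander(elev / scale, degree + 1, increasing=True)
    coef_s, *_ = np.linalg.lstsq(Xs, value, rcond=None)
    coef = coef_s / scale ** np.arange(degree + 1)
    fitted = Xs @ coef_s
    ss_res = float(((value - fitted) ** 2).sum())
    ss_tot = float(((value - value.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    n = len(value)
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - degree - 1)
    return coef, r2, adj


def fit_lapse_model(
    points,
    variable: str,
    threshold: float = 0.5,
    gradient_id: str = "",
    selection: str = "adj_r2",
) -> ClimateModel:
    """Fit the elevation → climate model for one gradient and variable.

    ``points`` is a sequence of (elevation_m, value) pairs or a 2-column
    array.  Temperature variables are restricted to degree 1 and always
    accepted; precipitation variables try degrees 1–3 (where the points
    allow) and keep the degree with the highest adjusted R² (or lowest AICc
    with ``selection="aicc"``), accepted only if adjusted R² > ``threshold``.
    """
    variable = variable.lower()
    if variable not in CLIMATE_VARIABLES:
        raise ValueError(f"unknown Bioclim variable {variable!r}")
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (elevation, value) pairs")
    elev, value = arr[:, 0], arr[:, 1]
    if np.ptp(elev) == 0:
        raise ValueError("all calibration elevations identical: singular design")
    is_temp = variable in TEMPERATURE_VARIABLES
    degrees = [1] if is_temp else [d for d in (1, 2, 3) if len(elev) >= d + 2]
    if not degrees or len(elev) < 3:
        raise ValueError(f"need at least 3 calibration points, got {len(elev)}")

    best = None
    for d in degrees:
        coef, r2, adj = _polyfit(elev, value, d)
        if selection == "aicc":
            n, k = len(value), d + 2  # coefficients + residual variance
            rss = max(float(((np.vander(elev, d + 1, increasing=True) @ coef - value) ** 2).sum()), 1e-300)
            score = n * np.log(rss / n) + 2 * k + (2 * k * (k + 1)) / max(n - k - 1, 1e-12)
            key = -score
        else:
            key = adj
        if best is None or key > best[0]:
            best = (key, d, coef, r2, adj)
    _, d, coef, r2, adj = best
    accepted = True if is_temp else bool(adj > threshold)
    return ClimateModel(
        gradient_id=str(gradient_id), variable=variable, degree=d,
        coef=coef, r2=r2, adj_r2=adj, accepted=accepted, n_points=len(value),
    )


def predict_climate(model: ClimateModel, elevation_m) -> float | np.ndarray:
    """Evaluate an accepted model at an elevation (°C or mm)."""
    if not model.accepted:
        raise ClimateModelRejected(
            f"{model.variable} model for gradient {model.gradient_id!r} was "
            f"rejected (adj R² = {model.adj_r2:.3f}); predictions refused"
        )
    elev = np.asarray(elevation_m, dtype=float)
    powers = np.vander(np.atleast_1d(elev), model.degree + 1, increasing=True)
    out = powers @ model.coef
    return float(out[0]) if np.isscalar(elevation_m) else out


def read_calibration(path) -> pd.DataFrame:
    """Calibration CSV: gradient_id,variable,elevation_m,value."""
    df = pd.read_csv(path)
    need = {"gradient_id", "variable", "elevation_m", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"calibration CSV needs columns {sorted(need)}")
    df["variable"] = df["variable"].str.lower()
    return df


def fit_all_models(calibration: pd.DataFrame, threshold: float = 0.5,
                   selection: str = "adj_r2") -> list[ClimateModel]:
    models = []
    for (gid, var), grp in calibration.groupby(["gradient_id", "variable"], sort=True):
        pts = grp[["elevation_m", "value"]].to_numpy()
        models.append(fit_lapse_model(pts, var, threshold=threshold,
                                      gradient_id=gid, selection=selection))
    return models


def attach_climate(
    stats: pd.DataFrame,
    models: list[ClimateModel],
    direct: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Add one column per Bioclim variable to a band-statistics frame.

    Direct values (same schema as calibration points) take precedence over
    model predictions; bands covered by neither stay NaN for that variable.
    Rejected models are never consulted.
    """
    out = stats.copy()
    by_key = {(m.gradient_id, m.variable): m for m in models}
    variables = sorted({m.variable for m in models})
    if direct is not None:
        variables = sorted(set(variables) | set(direct["variable"].unique()))
    for var in variables:
        col = np.full(len(out), np.nan)
        for i, row in enumerate(out.itertuples(index=False)):
            m = by_key.get((str(row.gradient_id), var))
            if m is not None and m.accepted:
                col[i] = predict_climate(m, float(row.elevation_m))
        if direct is not None:
            dd = direct[direct["variable"] == var]
            lookup = {
                (str(r.gradient_id), float(r.elevation_m)): float(r.value)
                for r in dd.itertuples(index=False)
            }
            for i, row in enumerate(out.itertuples(index=False)):
                key = (str(row.gradient_id), float(row.elevation_m))
                if key in lookup:
                    col[i] = lookup[key]
        out[var] = col
    return out
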