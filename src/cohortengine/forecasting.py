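"""ARIMA(0,1,1) forecasting of cohort-change series.

Each series is modelled independently as a driftless ARIMA(0,1,1),

    Y_t = Y_{t-1} + e_t - theta * e_{t-1},

whose one-step forecast is an exponentially weighted moving average of the
observed values with weights theta^k (1 - theta) — i.e. simple exponential
smoothing with weight alpha = 1 - theta — and whose forecasts at horizons
j > 1 stay constant at the one-step value.  The default estimator minimises
the conditional sum of squares (conditional ML with e_0 = 0), which makes
the smoothing equivalence exact in finite samples; an exact-likelihood
estimator is available as ``estimator="mle"``.

theta is constrained to [0, 0.999): values outside this range have no valid
exponential-smoothing weighting, and invertibility requires |theta| < 1.

Series with fewer than ``min_len`` non-missing points fall back to carrying
the last observation forward ("naive-last"); fully missing series are
flagged ``fallback-missing`` and left to the projection engine's blend
fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _dense
from .cohort_change import CohortChangeCollection

__all__ = ["ForecastEntry", "ForecastTable", "fit_arima011", "forecast_all"]

_METHOD_NAMES = {0: "arima011", 1: "naive-last", 2: "fallback-missing"}
MIN_LEN_DEFAULT = 4
THETA_BOUNDS = (0.0, 0.999)


@dataclass
class ForecastEntry:
    """Fit result for one series: MA parameter, flat-horizon forecast, method."""

    theta: float
    forecast: float
    method: str

    def __call__(self, horizon: int = 1) -> float:
        """Forecast at horizon ``j >= 1`` — constant in ``j`` for this model."""
        if horizon < 1:
            raise ValueError("horizon must be >= 1")
        return self.forecast


def fit_arima011(
    series: Sequence[float],
    min_len: int = MIN_LEN_DEFAULT,
    estimator: str = "css",
) -> ForecastEntry:
    """Fit one driftless ARIMA(0,1,1) and return its constant-horizon forecast.

    NaNs are dropped (the series is compacted).  A constant series forecasts
    its constant exactly with theta = 0.
    """
    x = np.asarray(list(series), dtype=float)
    if estimator == "mle":
        x = x[np.isfinite(x)]
        if len(x) == 0:
            return ForecastEntry(np.nan, np.nan, "fallback-missing")
        if len(x) < min_len:
            return ForecastEntry(np.nan, float(x[-1]), "naive-last")
        theta, fc = _dense.ma1_exact_mle(x, THETA_BOUNDS)
        return ForecastEntry(theta, fc, "arima011")
    if estimator != "css":
        raise ValueError("estimator must be 'css' or 'mle'")
    theta, fc, method = _dense.fit_ma1_many(x[None, :], min_len, THETA_BOUNDS)
    return ForecastEntry(float(theta[0]), float(fc[0]), _METHOD_NAMES[int(method[0])])


class ForecastTable:
    """Forecasts for every series of a :class:`CohortChangeCollection`.

    Carries both a tidy frame (one row per series) and the dense arrays the
    projection engine consumes: ``ccr_f``/``ccd_f`` of shape
    ``(A, R, S, 17)`` (NaN = fallback-missing) and ``cwr_f`` of shape
    ``(n_states, R)``.
    """

    def __init__(self, collection: CohortChangeCollection, min_len: int,
                 estimator: str = "css"):
        if estimator != "css":
            raise ValueError("forecast_all uses the vectorised css estimator")
        self.areas = collection.areas
        self.races = collection.races
        self.states = collection.states
        self.state_idx = collection.state_idx
        self.min_len = min_len
        self.kinds = collection.kinds

        self.ccr_f = self.ccd_f = None
        self._theta = {}
        self._method = {}
        for kind in ("CCR", "CCD"):
            arr = collection.ccr if kind == "CCR" else collection.ccd
            if arr is None:
                continue
            flat = arr.reshape(-1, arr.shape[-1])
            theta, fc, method = _dense.fit_ma1_many(flat, min_len, THETA_BOUNDS)
            shape = arr.shape[:-1]
            setattr(self, "ccr_f" if kind == "CCR" else "ccd_f", fc.reshape(shape))
            self._theta[kind] = theta.reshape(shape)
            self._method[kind] = method.reshape(shape)

        flat = collection.cwr.reshape(-1, collection.cwr.shape[-1])
        theta, fc, method = _dense.fit_ma1_many(flat, min_len, THETA_BOUNDS)
        shape = collection.cwr.shape[:-1]
        self.cwr_f = fc.reshape(shape)
        self._theta["CWR"] = theta.reshape(shape)
        self._method["CWR"] = method.reshape(shape)

    # ------------------------------------------------------------------
    @property
    def n_series(self) -> int:
        return sum(m.size for m in self._method.values())

    def fallback_counts(self) -> dict[str, int]:
        counts = {"arima011": 0, "naive-last": 0, "fallback-missing": 0}
        for m in self._method.values():
            for code, name in _METHOD_NAMES.items():
                counts[name] += int((m == code).sum())
        return counts

    def cwr_by_area(self) -> np.ndarray:
        return _dense.cwr_by_area(self.cwr_f, self.state_idx)

    def frame(self) -> pd.DataFrame:
        """Tidy export: kind, key columns, theta, forecast, method."""
        frames = []
        for kind in ("CCR", "CCD"):
            if kind not in self._theta:
                continue
            fc = self.ccr_f if kind == "CCR" else self.ccd_f
            idx = pd.MultiIndex.from_product(
                [self.areas, self.races, [1, 2], list(range(2, 19))],
                names=["area", "race", "sex", "age"],
            )
            df = pd.DataFrame(
                {
                    "theta": self._theta[kind].ravel(),
                    "forecast": fc.ravel(),
                    "method": [
                        _METHOD_NAMES[c] for c in self._method[kind].ravel()
                    ],
                },
                index=idx,
            ).reset_index()
            df.insert(0, "kind", kind)
            frames.append(df)
        idx = pd.MultiIndex.from_product(
            [self.states, self.races], names=["area", "race"]
        )
        df = pd.DataFrame(
            {
                "theta": self._theta["CWR"].ravel(),
                "forecast": self.cwr_f.ravel(),
                "method": [_METHOD_NAMES[c] for c in self._method["CWR"].ravel()],
            },
            index=idx,
        ).reset_index()
        df.insert(0, "kind", "CWR")
        df["sex"] = pd.NA
        df["age"] = pd.NA
        frames.append(df)
        out = pd.concat(frames, ignore_index=True)
        return out[["kind", "area", "race", "sex", "age", "theta", "forecast", "method"]]

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)


def forecast_all(
    collection: CohortChangeCollection, min_len: int = MIN_LEN_DEFAULT
) -> ForecastTable:
    """Fit every series in the collection independently (no pooling).

    Deterministic given the same inputs; series order does not matter because
    each fit sees only its own history.
    """
    return ForecastTable(collection, min_len)
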