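"""Model/Results front-end tying the pipeline together.

``HamiltonPerryModel`` is built from a historical population panel; ``fit``
computes every cohort-change series (CCR, CCD and pooled CWR) and fits an
independent driftless ARIMA(0,1,1) to each, returning a
``HamiltonPerryResults`` that carries the forecast table and exposes
projection, raking and summary methods::

    model = HamiltonPerryModel(panel, interval=5)
    res = model.fit()
    proj = res.project(horizon=15)        # blended CCD/CCR projection
    print(res.summary())
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohort_change import CohortChangeCollection, build_series
from .controls import rake_to_control
from .forecasting import ForecastTable, forecast_all
from .panel import ControlTable, GroupQuartersTable, PopulationPanel
from .projection import BlendDecision, ProjectionConfig, classify_growth, project

__all__ = ["HamiltonPerryModel", "HamiltonPerryResults"]


class HamiltonPerryModel:
    """Blended cohort-change-ratio / cohort-change-difference projection model.

    Parameters
    ----------
    panel : historical population counts at equally spaced census years.
    interval : census spacing in years (the ``y`` of every ratio).
    times : subset of census years to use (default: all panel years).
    gq : optional group-quarters table aligned to the launch year.
    srb : sex ratio at birth used for the 0-4 age group.
    """

    def __init__(
        self,
        panel: PopulationPanel,
        interval: int = 5,
        times: Sequence[int] | None = None,
        gq: GroupQuartersTable | None = None,
        srb: float = 1.05,
    ):
        self.panel = panel
        self.interval = interval
        self.times = list(times) if times is not None else panel.years
        self.gq = gq
        self.srb = srb

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HamiltonPerryModel":
        """Build from a raw long-format DataFrame (area, race, sex, age, year, value)."""
        return cls(PopulationPanel(df), **kwargs)

    def fit(self, min_len: int = 4) -> "HamiltonPerryResults":
        """Compute all cohort-change series and fit one ARIMA(0,1,1) per series."""
        series = build_series(self.panel, times=self.times, y=self.interval, kind="both")
        forecasts = forecast_all(series, min_len=min_len)
        return HamiltonPerryResults(self, series, forecasts)


class HamiltonPerryResults:
    """Fitted cohort-change forecasts plus projection/raking methods."""

    def __init__(
        self,
        model: HamiltonPerryModel,
        series: CohortChangeCollection,
        forecasts: ForecastTable,
    ):
        self.model = model
        self.series = series
        self.forecasts = forecasts
        self.decisions_: list[BlendDecision] | None = None

    # ------------------------------------------------------------------
    def _config(self, horizon: int, launch_year: int | None, mode: str,
                floor_at_zero: bool) -> ProjectionConfig:
        launch = launch_year if launch_year is not None else self.model.times[-1]
        return ProjectionConfig(
            launch_year=launch,
            horizon=horizon,
            interval=self.model.interval,
            srb=self.model.srb,
            blend_mode=mode,
            floor_at_zero=floor_at_zero,
        )

    def blend_decisions(
        self, horizon: int, launch_year: int | None = None
    ) -> list[BlendDecision]:
        """Grow/decline classification per (area, race) for a given horizon."""
        config = self._config(horizon, launch_year, "blended", True)
        return classify_growth(self.model.panel, self.forecasts, config)

    def project(
        self,
        horizon: int,
        launch_year: int | None = None,
        mode: str = "blended",
        floor_at_zero: bool = True,
        controls: ControlTable | None = None,
    ) -> PopulationPanel:
        """Project the panel ``horizon`` years past the launch year.

        ``mode`` selects "blended" (default), "ccr-only" or "ccd-only".
        With ``controls`` the projected years are raked to the given
        age-sex totals; the rake report is stored as ``rake_report_``.
        """
        config = self._config(horizon, launch_year, mode, floor_at_zero)
        out = project(self.model.panel, self.forecasts, self.model.gq, config)
        if mode == "blended":
            self.decisions_ = classify_growth(self.model.panel, self.forecasts, config)
        if controls is not None:
            out, report = rake_to_control(out, controls)
            self.rake_report_ = report
        return out

    # ------------------------------------------------------------------
    def summary(self) -> str:
        """Plain-text overview of the fitted series and forecast methods."""
        fb = self.forecasts.fallback_counts()
        f = self.forecasts
        lines = [
            "Hamilton-Perry blended CCR/CCD model",
            "=" * 44,
            f"areas: {len(f.areas)}   races: {len(f.races)}   "
            f"states: {len(f.states)}",
            f"census years: {self.series.years}",
            f"interval: {self.model.interval} y   srb: {self.model.srb}",
            f"series fitted: {self.forecasts.n_series} "
            f"(CCR {self.series.n_ccr}, CCD {self.series.n_ccd}, "
            f"CWR {self.series.n_cwr})",
            f"methods: arima011 {fb['arima011']}, naive-last {fb['naive-last']}, "
            f"fallback-missing {fb['fallback-missing']}",
        ]
        frame = self.forecasts.frame()
        fitted = frame[frame["method"] == "arima011"]
        if len(fitted):
            q = fitted["theta"].quantile([0.25, 0.5, 0.75])
            lines.append(
                "theta quartiles: "
                f"{q.iloc[0]:.3f} / {q.iloc[1]:.3f} / {q.iloc[2]:.3f}"
            )
        for kind in ("CCR", "CCD", "CWR"):
            sub = fitted[fitted["kind"] == kind]
            if len(sub):
                lines.append(
                    f"median forecast {kind}: {sub['forecast'].median():.4f}"
                )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<HamiltonPerryResults: {self.forecasts.n_series} series, "
            f"launch candidates {self.series.years}>"
        )
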