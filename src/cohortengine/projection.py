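"""Leslie-style population projection with blended CCR/CCD operators.

Populations advance in fixed intervals (default 5 years).  Ages 2-17 are the
shifted cohort scaled by a forecast cohort-change ratio or shifted by a
forecast difference; the open interval 85+ is fed by the pooled 80-and-over
population; ages 0-4 come from the forecast child-woman ratio applied to the
projected women aged 15-49 within the same step, split by the sex ratio at
birth (male share srb / (1 + srb)).

The blended model decides once per (area, race) — from a provisional
full-horizon additive projection — whether that combination is growing
(keep the additive CCD operator, which cannot compound explosively) or
declining (switch to the multiplicative CCR operator, which cannot go
negative).  The decision is held fixed across the whole horizon.

Group-quarters (institutional) populations do not respond to ordinary
demographic change; they are removed from the launch population, the
household remainder is projected, and the group-quarters counts are added
back unchanged at every projected year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _dense
from .forecasting import ForecastTable
from .panel import DensePanel, GroupQuartersTable, PopulationPanel

__all__ = ["ProjectionConfig", "BlendDecision", "project_step", "classify_growth", "project"]

logger = logging.getLogger(__name__)


@dataclass
class ProjectionConfig:
    """Settings for a projection run.

    launch_year : last observed year the projection starts from.
    horizon : total years to project; must be divisible by ``interval``.
    interval : step length in years (the ``y`` of the cohort-change ratios).
    srb : sex ratio at birth, male births per female birth.
    blend_mode : "blended" (per area x race choice), "ccr-only", "ccd-only".
    floor_at_zero : clip negative projected cells to zero after each step.
    """

    launch_year: int
    horizon: int
    interval: int = 5
    srb: float = 1.05
    blend_mode: str = "blended"
    floor_at_zero: bool = True

    def __post_init__(self):
        if self.horizon % self.interval != 0:
            raise ValueError(
                f"horizon {self.horizon} not divisible by interval {self.interval}"
            )
        if self.srb <= 0:
            raise ValueError("srb must be positive")
        if self.blend_mode not in {"blended", "ccr-only", "ccd-only"}:
            raise ValueError(f"unknown blend_mode {self.blend_mode!r}")

    @property
    def n_steps(self) -> int:
        return self.horizon // self.interval

    @property
    def projection_years(self) -> list[int]:
        return [
            self.launch_year + self.interval * (k + 1) for k in range(self.n_steps)
        ]


@dataclass
class BlendDecision:
    """Operator choice for one (area, race) combination."""

    area: str
    race: int
    choice: str                 # "CCD" (growing or tied) or "CCR" (declining)
    launch_total: float
    final_ccd_total: float


def _forecast_arrays(forecasts: ForecastTable, need_ccr: bool, need_ccd: bool):
    if need_ccr and forecasts.ccr_f is None:
        raise ValueError("forecast table has no CCR forecasts but the mode needs them")
    if need_ccd and forecasts.ccd_f is None:
        raise ValueError("forecast table has no CCD forecasts but the mode needs them")
    ccr_f = forecasts.ccr_f
    ccd_f = forecasts.ccd_f
    shape = (len(forecasts.areas), len(forecasts.races), 2, _dense.N_DEST)
    if ccr_f is None:
        ccr_f = np.full(shape, np.nan)
    if ccd_f is None:
        ccd_f = np.zeros(shape)
    return ccr_f, ccd_f, forecasts.cwr_by_area()


def _align_dense(panel: PopulationPanel, year: int, areas, races) -> np.ndarray:
    dense = panel.to_dense(years=[year])
    if dense.areas != areas or dense.races != races:
        sub = DensePanel(
            np.zeros((len(areas), len(races), 2, 18, 1)), list(areas), list(races), [year]
        )
        for ai, a in enumerate(areas):
            for ri, r in enumerate(races):
                if a in dense.areas and r in dense.races:
                    sub.values[ai, ri] = dense.values[
                        dense.areas.index(a), dense.races.index(r)
                    ]
        return sub.values[..., 0]
    return dense.values[..., 0]


def project_step(
    pop_t: PopulationPanel,
    forecasts: ForecastTable,
    kind: str,
    config: ProjectionConfig,
    year: int | None = None,
) -> PopulationPanel:
    """Advance a single-year panel slice one interval with one operator kind.

    ``kind`` is "CCR" or "CCD".  A CCR request for a cell whose ratio
    forecast is fallback-missing substitutes the additive difference for
    that cell (logged).
    """
    if kind not in {"CCR", "CCD"}:
        raise ValueError("kind must be 'CCR' or 'CCD'")
    year = year if year is not None else config.launch_year
    pop = _align_dense(pop_t, year, forecasts.areas, forecasts.races)
    ccr_f, ccd_f, cwr_area = _forecast_arrays(
        forecasts, need_ccr=kind == "CCR", need_ccd=kind == "CCD"
    )
    if kind == "CCR" and np.isnan(ccr_f).any():
        logger.info(
            "substituting CCD for %d cells with missing CCR forecasts",
            int(np.isnan(ccr_f).sum()),
        )
    nxt = _dense.step(
        pop, ccr_f, ccd_f, cwr_area, kind == "CCR", config.srb, config.floor_at_zero
    )
    return DensePanel(
        nxt[..., None], list(forecasts.areas), list(forecasts.races),
        [year + config.interval],
    ).to_panel()


def classify_growth(
    pop_launch: PopulationPanel,
    forecasts: ForecastTable,
    config: ProjectionConfig,
) -> list[BlendDecision]:
    """Grow-or-decline classification per (area, race).

    A provisional pure-CCD projection is run over the full horizon; the
    combination keeps the additive operator iff its final total meets or
    exceeds its launch total (ties count as growth).  All-zero areas are
    degenerate growth and default to CCD.
    """
    pop = _align_dense(pop_launch, config.launch_year, forecasts.areas, forecasts.races)
    ccr_f, ccd_f, cwr_area = _forecast_arrays(forecasts, False, True)
    use_ccr, launch, final = _dense.classify_dense(
        pop, ccr_f, ccd_f, cwr_area, config.n_steps, config.srb, config.floor_at_zero
    )
    return [
        BlendDecision(
            forecasts.areas[ai], forecasts.races[ri],
            "CCR" if use_ccr[ai, ri] else "CCD",
            float(launch[ai, ri]), float(final[ai, ri]),
        )
        for ai in range(len(forecasts.areas))
        for ri in range(len(forecasts.races))
    ]


def _use_ccr_mask(forecasts: ForecastTable, config: ProjectionConfig, pop0) -> np.ndarray | bool:
    if config.blend_mode == "ccr-only":
        return True
    if config.blend_mode == "ccd-only":
        return False
    ccr_f, ccd_f, cwr_area = _forecast_arrays(forecasts, True, True)
    use_ccr, _, _ = _dense.classify_dense(
        pop0, ccr_f, ccd_f, cwr_area, config.n_steps, config.srb, config.floor_at_zero
    )
    return use_ccr


def project(
    pop_history: PopulationPanel,
    forecasts: ForecastTable,
    gq: GroupQuartersTable | None,
    config: ProjectionConfig,
) -> PopulationPanel:
    """Project a panel over the configured horizon.

    The launch-year slice is split into household (total minus group
    quarters, clipped at zero) and group quarters; the household part is
    projected stepwise with the per-(area, race) blend decision fixed over
    the horizon, and group quarters are added back unchanged at every
    output year.  Output covers launch + y ... launch + horizon.
    """
    if config.launch_year not in pop_history.years:
        raise KeyError(f"launch year {config.launch_year} absent from panel")
    areas, races = forecasts.areas, forecasts.races
    pop0 = _align_dense(pop_history, config.launch_year, areas, races)

    if gq is not None:
        gq_arr = _align_dense(gq, config.launch_year, areas, races)
        over = gq_arr > pop0
        if over.any():
            logger.warning(
                "clipping %d group-quarters cells exceeding the total population",
                int(over.sum()),
            )
            gq_arr = np.minimum(gq_arr, pop0)
    else:
        gq_arr = np.zeros_like(pop0)
    household0 = pop0 - gq_arr

    use_ccr = _use_ccr_mask(forecasts, config, household0)
    need_ccr = config.blend_mode != "ccd-only"
    ccr_f, ccd_f, cwr_area = _forecast_arrays(
        forecasts, need_ccr, True if config.blend_mode != "ccr-only" else False
    )
    hh = _dense.project_dense(
        household0, ccr_f, ccd_f, cwr_area, use_ccr,
        config.n_steps, config.srb, config.floor_at_zero,
    )
    out = hh + gq_arr[..., None]
    return DensePanel(
        out, list(areas), list(races), config.projection_years
    ).to_panel()
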