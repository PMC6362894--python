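"""Scenario control preparation and proportional raking.

Scenario control tables give age-sex population totals per projection year
(five-year age codes to an open interval, two sexes).  Controls distributed
with a 100+ open interval are first truncated to the 85+ ladder used by the
panels.  Raking rescales every projected cell by control / raw within its
(age, sex, year) margin, which matches the margins to the controls while
preserving the area, race and within-margin age-sex structure.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import _dense
from .panel import (
    AGE_CODES,
    ControlTable,
    DensePanel,
    OPEN_AGE_CODE,
    PanelValidationError,
    PopulationPanel,
    SEX_CODES,
)

__all__ = ["RakeReport", "truncate_open_interval", "rake_to_control"]

logger = logging.getLogger(__name__)


class RakeReport:
    """Per-(year, sex, age) margin diagnostics of one raking pass."""

    COLUMNS = [
        "year", "sex", "age", "raw_total", "control_total",
        "scale_factor", "cells_affected", "unallocated",
    ]

    def __init__(self, df: pd.DataFrame):
        self.df = df[self.COLUMNS].reset_index(drop=True)

    @property
    def total_unallocated(self) -> float:
        return float(self.df["unallocated"].sum())


def truncate_open_interval(
    control: ControlTable, cutoff_age_code: int = OPEN_AGE_CODE
) -> ControlTable:
    """Collapse all age codes at or above the cutoff into one open interval.

    Controls shipped with ages to 100+ (codes beyond 18) are summed into
    code 18 (85+); younger codes and the grand totals are unchanged.  Age
    codes must be contiguous per (sex, year).
    """
    df = control.df
    for (sex, year), grp in df.groupby(["sex", "year"]):
        ages = sorted(grp["age"])
        if ages != list(range(ages[0], ages[-1] + 1)):
            raise PanelValidationError(
                f"age codes for sex {sex}, year {year} have gaps: {ages}"
            )
    keep = df[df["age"] < cutoff_age_code]
    tail = (
        df[df["age"] >= cutoff_age_code]
        .groupby(["sex", "year"], as_index=False)["value"]
        .sum()
        .assign(age=cutoff_age_code)
    )
    out = pd.concat([keep, tail[["sex", "age", "year", "value"]]], ignore_index=True)
    return ControlTable(out)


def rake_to_control(
    panel: PopulationPanel, control: ControlTable
) -> tuple[PopulationPanel, RakeReport]:
    """Rake a projected panel to age-sex control totals, year by year.

    Every cell is multiplied by control / raw within its (age, sex, year)
    margin.  Margins whose raw total is zero but whose control is positive
    are left at zero and the unallocated control mass is reported rather
    than invented.  Raking each year independently makes the operation
    idempotent and share-preserving.
    """
    extra_ages = set(control.ages) - set(AGE_CODES)
    if extra_ages:
        raise PanelValidationError(
            f"control has age codes {sorted(extra_ages)} beyond the panel ladder; "
            "apply truncate_open_interval first"
        )
    years = [y for y in panel.years if y in set(control.years)]
    missing = set(panel.years) - set(control.years)
    if missing:
        raise PanelValidationError(
            f"control table lacks panel years {sorted(missing)}"
        )
    dense = panel.to_dense()
    ctrl = np.zeros((len(SEX_CODES), len(AGE_CODES), len(years)))
    cdf = control.df[control.df["year"].isin(years)]
    si = cdf["sex"].to_numpy() - 1
    gi = cdf["age"].to_numpy() - 1
    ti = pd.Categorical(cdf["year"], categories=years).codes
    ctrl[si, gi, ti] = cdf["value"].to_numpy()
    has_row = np.zeros(ctrl.shape, dtype=bool)
    has_row[si, gi, ti] = True
    # every margin the panel populates must have a control row
    raw_margins = dense.values.sum(axis=(0, 1)) > 0
    bad = raw_margins & ~has_row
    if bad.any():
        s, g, t = np.nonzero(bad)
        missing_margins = [
            (years[tt], ss + 1, gg + 1) for ss, gg, tt in zip(s[:5], g[:5], t[:5])
        ]
        raise PanelValidationError(
            f"control lacks (year, sex, age) margins such as {missing_margins}"
        )
    rows = []
    out = np.empty_like(dense.values)
    n_cells = len(dense.areas) * len(dense.races)
    for k, year in enumerate(years):
        raked, scale, unalloc = _dense.rake_slice(dense.values[..., k], ctrl[..., k])
        out[..., k] = raked
        raw = dense.values[..., k].sum(axis=(0, 1))
        for s in range(2):
            for g in range(18):
                rows.append(
                    (year, s + 1, g + 1, raw[s, g], ctrl[s, g, k],
                     scale[s, g], n_cells, unalloc[s, g])
                )
    report = RakeReport(pd.DataFrame(rows, columns=RakeReport.COLUMNS))
    if report.total_unallocated > 0:
        logger.warning(
            "raking left %.3f persons unallocated in margins with zero raw totals",
            report.total_unallocated,
        )
    raked_panel = DensePanel(
        out, dense.areas, dense.races, years
    ).to_panel()
    return raked_panel, report
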