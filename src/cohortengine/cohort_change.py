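"""Cohort-change ratios, differences, and child-woman ratios.

A cohort-change ratio (CCR) for destination age group ``a`` at census time
``t`` is the population in age ``a`` at ``t`` divided by the same birth
cohort one age step younger at ``t - y``; the cohort-change difference (CCD)
is the corresponding numeric change.  Destination codes run 2..18: the open
interval (85+, code 18) is fed by the pooled 80-and-over population, and the
youngest group (0-4, code 1) is produced separately through the child-woman
ratio (CWR) — population 0-4 of both sexes over women aged 15-49 — pooled at
state x race level.

CCR cells with a zero denominator are masked missing (NaN) rather than set
to zero or infinity: tiny cohorts produce arbitrarily explosive ratios, and
downstream forecasting/projection handles the mask explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from . import _dense
from .panel import PopulationPanel, PanelValidationError

__all__ = [
    "CohortChangeSeries",
    "CohortChangeCollection",
    "compute_ccr",
    "compute_ccd",
    "compute_open_interval",
    "compute_cwr",
    "build_series",
]

DEST_AGE_CODES = tuple(range(2, 19))


@dataclass
class CohortChangeSeries:
    """One per-key history of CCR, CCD or CWR values.

    ``key`` is (area, race, sex, destination age) for CCR/CCD and
    (state, race) for CWR.  ``values`` uses NaN for masked-missing entries.
    """

    kind: str
    key: tuple
    times: np.ndarray
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


class CohortChangeCollection:
    """All cohort-change series built from one panel.

    Internally dense: ``ccr``/``ccd`` are ``(A, R, S, 17, T-1)`` arrays over
    destination ages 2..18 and transitions, ``cwr`` is ``(n_states, R, T)``.
    ``frame()`` exports the tidy long form.
    """

    def __init__(self, dense, kinds: tuple[str, ...], y: int):
        self.areas = dense.areas
        self.races = dense.races
        self.years = list(dense.years)
        self.y = y
        self.kinds = kinds
        state_idx, states = dense.state_of_area()
        self.states = states
        self.state_idx = state_idx
        self.ccr = _dense.series_ccr(dense.values) if "CCR" in kinds else None
        self.ccd = _dense.series_ccd(dense.values) if "CCD" in kinds else None
        self.cwr = _dense.series_cwr(dense.values, state_idx, len(states))

    # counts ----------------------------------------------------------------
    @property
    def n_ccr(self) -> int:
        return 0 if self.ccr is None else int(np.prod(self.ccr.shape[:-1]))

    @property
    def n_ccd(self) -> int:
        return 0 if self.ccd is None else int(np.prod(self.ccd.shape[:-1]))

    @property
    def n_cwr(self) -> int:
        return int(np.prod(self.cwr.shape[:-1]))

    @property
    def n_series(self) -> int:
        return self.n_ccr + self.n_ccd + self.n_cwr

    # access ----------------------------------------------------------------
    def iter_series(self) -> Iterator[CohortChangeSeries]:
        trans_times = np.asarray(self.years[1:])
        for kind, arr in (("CCR", self.ccr), ("CCD", self.ccd)):
            if arr is None:
                continue
            for ai, area in enumerate(self.areas):
                for ri, race in enumerate(self.races):
                    for si, sex in enumerate((1, 2)):
                        for di, dest in enumerate(DEST_AGE_CODES):
                            yield CohortChangeSeries(
                                kind, (area, race, sex, dest),
                                trans_times, arr[ai, ri, si, di],
                            )
        all_times = np.asarray(self.years)
        for sti, state in enumerate(self.states):
            for ri, race in enumerate(self.races):
                yield CohortChangeSeries(
                    "CWR", (state, race), all_times, self.cwr[sti, ri]
                )

    def get(self, kind: str, key: tuple) -> CohortChangeSeries:
        if kind == "CWR":
            sti = self.states.index(key[0])
            ri = self.races.index(key[1])
            return CohortChangeSeries(
                "CWR", key, np.asarray(self.years), self.cwr[sti, ri]
            )
        arr = self.ccr if kind == "CCR" else self.ccd
        area, race, sex, dest = key
        ai = self.areas.index(area)
        ri = self.races.index(race)
        return CohortChangeSeries(
            kind, key, np.asarray(self.years[1:]),
            arr[ai, ri, sex - 1, dest - 2],
        )

    def frame(self) -> pd.DataFrame:
        """Tidy long form: kind, area/state, race, sex, age, year, value."""
        rows = []
        for s in self.iter_series():
            if s.kind == "CWR":
                state, race = s.key
                rows.append(pd.DataFrame({
                    "kind": s.kind, "area": state, "race": race,
                    "sex": pd.NA, "age": pd.NA, "year": s.times,
                    "value": s.values,
                }))
            else:
                area, race, sex, dest = s.key
                rows.append(pd.DataFrame({
                    "kind": s.kind, "area": area, "race": race,
                    "sex": sex, "age": dest, "year": s.times,
                    "value": s.values,
                }))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# single-time-point operations
# ---------------------------------------------------------------------------

def _pair_dense(panel: PopulationPanel, t: int, y: int):
    years = panel.years
    if t not in years:
        raise KeyError(f"panel has no year {t}")
    if t - y not in years:
        raise KeyError(f"panel has no year {t - y} (needed as the earlier census)")
    return panel.to_dense(years=[t - y, t])


def _entries_frame(panel_dense, arr2d_last, kind: str, t: int) -> pd.DataFrame:
    A, R, S, D = arr2d_last.shape
    idx = pd.MultiIndex.from_product(
        [panel_dense.areas, panel_dense.races, [1, 2], list(range(2, 2 + D))],
        names=["area", "race", "sex", "age"],
    )
    df = pd.DataFrame({"value": arr2d_last.ravel()}, index=idx).reset_index()
    df.insert(4, "year", t)
    df.insert(0, "kind", kind)
    return df


def compute_ccr(panel: PopulationPanel, t: int, y: int = 5) -> pd.DataFrame:
    """CCR entries at census time ``t`` for destination ages 2-17.

    ``CCR_a = P[a, t] / P[a-1, t-y]``; zero denominators are NaN.
    """
    dense = _pair_dense(panel, t, y)
    arr = _dense.series_ccr(dense.values)[..., 0]
    return _entries_frame(dense, arr[..., :16], "CCR", t)


def compute_ccd(panel: PopulationPanel, t: int, y: int = 5) -> pd.DataFrame:
    """CCD entries at census time ``t``: ``P[a, t] - P[a-1, t-y]`` for ages 2-17."""
    dense = _pair_dense(panel, t, y)
    arr = _dense.series_ccd(dense.values)[..., 0]
    return _entries_frame(dense, arr[..., :16], "CCD", t)


def compute_open_interval(
    panel: PopulationPanel, t: int, y: int = 5, kind: str = "CCR"
) -> pd.DataFrame:
    """Open-interval (85+) entry at ``t``: numerator is the 85+ population,
    the denominator/subtrahend the pooled 80-and-over population at ``t-y``."""
    if kind not in {"CCR", "CCD"}:
        raise ValueError("kind must be 'CCR' or 'CCD'")
    dense = _pair_dense(panel, t, y)
    fn = _dense.series_ccr if kind == "CCR" else _dense.series_ccd
    arr = fn(dense.values)[..., 16:17, 0]
    df = _entries_frame(dense, arr, kind, t)
    df["age"] = 18
    return df


def compute_cwr(
    panel: PopulationPanel, t: int, pooling: str = "state_race"
) -> pd.DataFrame:
    """State x race pooled child-woman ratio at census time ``t``.

    The pool sums the 0-4 population (both sexes) and women aged 15-49 over
    every area sharing a two-character state prefix before taking the ratio,
    so large counties weigh more than small ones.
    """
    if pooling != "state_race":
        raise ValueError("only state_race pooling is supported")
    dense = panel.to_dense(years=[t])
    state_idx, states = dense.state_of_area()
    cwr = _dense.series_cwr(dense.values, state_idx, len(states))[..., 0]
    idx = pd.MultiIndex.from_product([states, dense.races], names=["state", "race"])
    df = pd.DataFrame({"value": cwr.ravel()}, index=idx).reset_index()
    df.insert(2, "year", t)
    df.insert(0, "kind", "CWR")
    return df


def build_series(
    panel: PopulationPanel,
    times: Sequence[int] | None = None,
    y: int = 5,
    kind: str = "both",
) -> CohortChangeCollection:
    """Build every cohort-change series a panel supports.

    One CCR and/or CCD series per (area, race, sex, destination age 2-18) of
    length ``len(times) - 1``, plus one CWR series per (state, race) over all
    time points.  ``times`` must be equally spaced by ``y``; fewer than two
    points is an error.
    """
    kinds = {"CCR": ("CCR",), "CCD": ("CCD",), "both": ("CCR", "CCD")}.get(kind)
    if kinds is None:
        raise ValueError("kind must be 'CCR', 'CCD' or 'both'")
    times = list(times) if times is not None else panel.years
    if len(times) < 2:
        raise PanelValidationError(
            f"need at least two equally spaced census times, got {times}"
        )
    gaps = np.diff(times)
    if not np.all(gaps == y):
        raise PanelValidationError(
            f"census times {times} are not equally spaced at interval {y}"
        )
    missing = sorted(set(times) - set(panel.years))
    if missing:
        raise KeyError(f"panel lacks census years {missing}")
    dense = panel.to_dense(years=times)
    return CohortChangeCollection(dense, kinds, y)
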