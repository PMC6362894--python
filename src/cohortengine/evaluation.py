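"""Projection error metrics and the ex-post-facto validation harness.

Three percent-error metrics are used, with ``A`` the observed and ``P`` the
projected count:

* APE  = |A - P| / A            — accuracy; undefined (NaN) when A = 0.
* ALPE = (P - A) / A            — bias; positive means over-projection.
  (A ``strict_sign=True`` flag returns (A - P) / A instead.)
* SAPE = |P - A| / (P + A)      — zero-safe accuracy in [0, 1]; defined as 0
  when A = P = 0, and 1 when exactly one of the pair is zero.

The harness fits the cohort-change pipeline on a base period, projects the
holdout years with the pure additive (CCD), pure multiplicative (CCR) and
blended variants — optionally also a raked variant controlled to the
observed age-sex totals — and summarises errors at several levels: joint
age/sex/race/area cells (median SAPE), the whole-population total, per-area
totals, per-age-group and per-race-group county totals (median and mean APE
and ALPE).  Cells with undefined APE/ALPE are excluded from the summaries
and counted.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import _dense
from .panel import PopulationPanel

__all__ = ["ape", "alpe", "sape", "ErrorReport", "holdout_validate", "run_holdout_dense"]


def ape(actual, predicted):
    """Absolute percent error |A - P| / A; NaN where A = 0 (excluded cells)."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(a - p) / a
    out = np.where(a == 0, np.nan, out)
    return out if out.ndim else float(out)


def alpe(actual, predicted, strict_sign: bool = False):
    """Algebraic (signed) percent error.

    Default sign convention is (P - A) / A, so over-projection is positive.
    ``strict_sign=True`` returns (A - P) / A instead.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (a - p) / a if strict_sign else (p - a) / a
    out = np.where(a == 0, np.nan, out)
    return out if out.ndim else float(out)


def sape(actual, predicted):
    """Symmetric absolute percent error |P - A| / (P + A) in [0, 1].

    Defined as 0 when both are zero (the zero-cell case the metric exists
    for); undefined only if an input is negative, which is rejected.
    """
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if (a < 0).any() or (p < 0).any():
        raise ValueError("sape requires non-negative inputs")
    denom = a + p
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(p - a) / denom
    out = np.where(denom == 0, 0.0, out)
    return out if out.ndim else float(out)


class ErrorReport:
    """Tidy error summaries: model, level, metric, summary, year, group, value."""

    COLUMNS = ["model", "level", "metric", "summary", "year", "group", "value", "n", "n_undefined"]

    def __init__(self, df: pd.DataFrame):
        self.df = df[self.COLUMNS].reset_index(drop=True)

    def value(self, model: str, level: str, metric: str, summary: str,
              year: int, group=None) -> float:
        df = self.df
        sel = (
            (df["model"] == model) & (df["level"] == level)
            & (df["metric"] == metric) & (df["summary"] == summary)
            & (df["year"] == year)
        )
        sel &= df["group"].isna() if group is None else (df["group"] == group)
        out = df.loc[sel, "value"]
        if len(out) != 1:
            raise KeyError(
                f"expected one row for {(model, level, metric, summary, year, group)}, "
                f"found {len(out)}"
            )
        return float(out.iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def _summaries(values: np.ndarray) -> tuple[float, float, int, int]:
    finite = values[np.isfinite(values)]
    n_und = int(values.size - finite.size)
    if finite.size == 0:
        return np.nan, np.nan, 0, n_und
    return float(np.median(finite)), float(np.mean(finite)), finite.size, n_und


def run_holdout_dense(
    values: np.ndarray,
    state_idx: np.ndarray,
    n_states: int,
    n_base: int,
    srb: float = 1.05,
    min_len: int = 4,
    models: Sequence[str] = ("CCD", "CCR", "blended"),
    rake: bool = False,
) -> dict[str, np.ndarray]:
    """Dense-core holdout run used by the harness and the Monte-Carlo suite.

    ``values`` is the full observed dense panel ``(A, R, S, 18, T)``; the
    first ``n_base`` time points form the base period, the rest the holdout.
    Returns projected arrays ``(A, R, S, 18, T - n_base)`` per model name.
    """
    base = values[..., :n_base]
    n_hold = values.shape[-1] - n_base
    ccr_s = _dense.series_ccr(base)
    ccd_s = _dense.series_ccd(base)
    cwr_s = _dense.series_cwr(base, state_idx, n_states)

    def fit(arr):
        flat = arr.reshape(-1, arr.shape[-1])
        _, fc, _ = _dense.fit_ma1_many(flat, min_len)
        return fc.reshape(arr.shape[:-1])

    ccr_f, ccd_f = fit(ccr_s), fit(ccd_s)
    cwr_f = _dense.cwr_by_area(fit(cwr_s), state_idx)
    pop0 = base[..., -1]

    out: dict[str, np.ndarray] = {}
    for model in models:
        if model == "CCD":
            use_ccr = False
        elif model == "CCR":
            use_ccr = True
        elif model == "blended":
            use_ccr, _, _ = _dense.classify_dense(
                pop0, ccr_f, ccd_f, cwr_f, n_hold, srb
            )
        else:
            raise ValueError(f"unknown model {model!r}")
        out[model] = _dense.project_dense(
            pop0, ccr_f, ccd_f, cwr_f, use_ccr, n_hold, srb
        )
    if rake and "blended" in out:
        raked = out["blended"].copy()
        for k in range(n_hold):
            ctrl = values[..., n_base + k].sum(axis=(0, 1))
            raked[..., k], _, _ = _dense.rake_slice(raked[..., k], ctrl)
        out["RAKE blended"] = raked
    return out


def _report_rows(model, year, actual, projected, state_idx_unused=None):
    """Error summaries for one (model, year) pair of dense slices (A,R,S,18)."""
    rows = []

    def add(level, metric, vals, group=None):
        med, mean, n, n_und = _summaries(np.asarray(vals, dtype=float).ravel())
        rows.append((model, level, metric, "median", year, group, med, n, n_und))
        rows.append((model, level, metric, "mean", year, group, mean, n, n_und))

    add("joint-asrc", "SAPE", sape(actual, projected))
    tot_a, tot_p = actual.sum(), projected.sum()
    add("total-us", "APE", ape(tot_a, tot_p))
    add("total-us", "ALPE", alpe(tot_a, tot_p))
    area_a = actual.sum(axis=(1, 2, 3))
    area_p = projected.sum(axis=(1, 2, 3))
    add("total-area", "APE", ape(area_a, area_p))
    add("total-area", "ALPE", alpe(area_a, area_p))
    age_a = actual.sum(axis=(1, 2))          # (A, 18) county x age totals
    age_p = projected.sum(axis=(1, 2))
    add("age-group", "APE", ape(age_a, age_p))
    add("age-group", "ALPE", alpe(age_a, age_p))
    for g in range(actual.shape[3]):
        add("age-group", "APE", ape(age_a[:, g], age_p[:, g]), group=g + 1)
        add("age-group", "ALPE", alpe(age_a[:, g], age_p[:, g]), group=g + 1)
    race_a = actual.sum(axis=(2, 3))         # (A, R) county x race totals
    race_p = projected.sum(axis=(2, 3))
    add("race-group", "APE", ape(race_a, race_p))
    add("race-group", "ALPE", alpe(race_a, race_p))
    for r in range(actual.shape[1]):
        add("race-group", "APE", ape(race_a[:, r], race_p[:, r]), group=r + 1)
        add("race-group", "ALPE", alpe(race_a[:, r], race_p[:, r]), group=r + 1)
    return rows


def holdout_validate(
    panel: PopulationPanel,
    base_times: Sequence[int],
    holdout_times: Sequence[int],
    y: int = 5,
    srb: float = 1.05,
    min_len: int = 4,
    models: Sequence[str] = ("CCD", "CCR", "blended"),
    rake: bool = False,
) -> ErrorReport:
    """Ex-post-facto evaluation: fit on ``base_times``, score ``holdout_times``.

    All requested model variants are launched from the last base year and
    projected across the holdout; errors are summarised per holdout year at
    the joint-cell, total, per-area, per-age and per-race levels.  With
    ``rake=True`` a "RAKE blended" variant controlled to the *observed*
    age-sex totals of each holdout year is added.
    """
    base_times = sorted(base_times)
    holdout_times = sorted(holdout_times)
    all_times = base_times + holdout_times
    if np.any(np.diff(all_times) != y):
        raise ValueError(
            f"base {base_times} + holdout {holdout_times} are not spaced by {y}"
        )
    missing = sorted(set(all_times) - set(panel.years))
    if missing:
        raise KeyError(f"panel lacks years {missing}")
    dense = panel.to_dense(years=all_times)
    state_idx, states = dense.state_of_area()
    projected = run_holdout_dense(
        dense.values, state_idx, len(states), len(base_times),
        srb=srb, min_len=min_len, models=models, rake=rake,
    )
    rows = []
    for model, arr in projected.items():
        for k, year in enumerate(holdout_times):
            actual = dense.values[..., len(base_times) + k]
            rows.extend(_report_rows(model, year, actual, arr[..., k]))
    return ErrorReport(pd.DataFrame(rows, columns=ErrorReport.COLUMNS))
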