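"""Synthetic population panels with known cohort-change dynamics.

The generator emulates the structure of US bridged-race population panels —
county-like areas nested in states, race and sex codes, eighteen 5-year age
groups, censuses at 5-year intervals — while evolving every cohort by known
constant (optionally trending) cohort-change ratios or differences and a
known state x race child-woman ratio.  Because the true dynamics are known,
parameter recovery and end-to-end projection recovery can be tested exactly,
and multiplicative lognormal observation noise with mean one can be layered
on top for Monte-Carlo studies without breaking non-negativity.

What the generator does **not** emulate: demographically calibrated US age
schedules, spatial correlation between counties, or boundary changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import ControlTable, DensePanel, GroupQuartersTable, PopulationPanel

__all__ = ["ScenarioSpec", "GroundTruth", "generate_panel", "generate_gq", "generate_controls"]


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth dynamics for one synthetic panel.

    dynamics : "CCR" (multiplicative, drawn in ``ccr_range``; defaults give a
        gently declining system) or "CCD" (additive, drawn in ``ccd_range``;
        defaults give steady growth).
    trend : additive drift applied to each true parameter per transition
        (0 = constant dynamics, the default).
    noise_sigma : sigma of mean-one multiplicative lognormal observation
        noise applied per cell and census; 0 = noise-free.
    """

    n_areas: int = 6
    n_states: int = 2
    n_races: int = 2
    times: tuple[int, ...] = (1970, 1975, 1980, 1985, 1990, 1995, 2000)
    interval: int = 5
    dynamics: str = "CCR"
    ccr_range: tuple[float, float] = (0.85, 0.98)
    ccd_range: tuple[float, float] = (2.0, 40.0)
    cwr_range: tuple[float, float] = (0.18, 0.28)
    trend: float = 0.0
    base_cell_range: tuple[float, float] = (200.0, 2000.0)
    srb: float = 1.05
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.dynamics not in {"CCR", "CCD"}:
            raise ValueError("dynamics must be 'CCR' or 'CCD'")
        if self.n_states > self.n_areas:
            raise ValueError("need at least one area per state")
        if np.any(np.diff(self.times) != self.interval):
            raise ValueError("times must be equally spaced by the interval")

    @property
    def area_codes(self) -> list[str]:
        """FIPS-like codes, sorted; the first two characters are the state.

        Areas are dealt round-robin to states, so states differ in size by at
        most one area.
        """
        return sorted(
            f"{(i % self.n_states) + 1:02d}{i + 1:03d}" for i in range(self.n_areas)
        )


@dataclass
class GroundTruth:
    """True dynamics behind a generated panel.

    ``ccr``/``ccd`` are ``(A, R, S, 17)`` per destination ages 2..18 at the
    first transition (add ``trend`` per later transition); ``cwr`` is
    ``(n_states, R)``.  ``clean`` is the noise-free dense evolution.
    """

    spec: ScenarioSpec
    ccr: np.ndarray | None
    ccd: np.ndarray | None
    cwr: np.ndarray
    clean: DensePanel
    n_floored: int = 0

    def param_at(self, transition: int) -> np.ndarray:
        base = self.ccr if self.ccr is not None else self.ccd
        return base + self.spec.trend * transition


def _evolve(spec: ScenarioSpec, param, cwr_state, init, state_idx):
    """Plain-loop evolution of the stated dynamics (kept independent of the
    projection engine's stepper so the two can check each other)."""
    A, R = init.shape[:2]
    T = len(spec.times)
    vals = np.zeros((A, R, 2, 18, T))
    vals[..., 0] = init
    n_floored = 0
    male = spec.srb / (1.0 + spec.srb)
    for k in range(1, T):
        prev = vals[..., k - 1]
        cur = vals[..., k]
        p = param + spec.trend * (k - 1)
        for d in range(17):                      # dest ages 2..18
            src = prev[:, :, :, d] if d < 16 else prev[:, :, :, 16] + prev[:, :, :, 17]
            if spec.dynamics == "CCR":
                cur[:, :, :, d + 1] = p[:, :, :, d] * src
            else:
                cur[:, :, :, d + 1] = p[:, :, :, d] + src
        neg = cur < 0
        n_floored += int(neg.sum())
        cur[neg] = 0.0
        women = cur[:, :, 1, 3:10].sum(axis=-1)
        births = cwr_state[state_idx] * women
        cur[:, :, 0, 0] = births * male
        cur[:, :, 1, 0] = births * (1.0 - male)
    return vals, n_floored


def _generate_dense(spec: ScenarioSpec) -> tuple[np.ndarray, GroundTruth, np.ndarray, int]:
    rng = np.random.default_rng(spec.seed)
    A, R = spec.n_areas, spec.n_races
    areas = spec.area_codes
    state_idx = np.array([int(a[:2]) - 1 for a in areas])

    shape = (A, R, 2, 17)
    if spec.dynamics == "CCR":
        param = rng.uniform(*spec.ccr_range, size=shape)
        ccr, ccd = param, None
    else:
        param = rng.uniform(*spec.ccd_range, size=shape)
        ccr, ccd = None, param
    cwr_state = rng.uniform(*spec.cwr_range, size=(spec.n_states, R))

    # initial census: declining age profile, age 0-4 made consistent with the
    # true CWR so the measured CWR series is constant from the first census
    base = rng.uniform(*spec.base_cell_range, size=(A, R, 2, 18))
    decay = np.exp(-0.04 * np.arange(18))
    init = base * decay
    women0 = init[:, :, 1, 3:10].sum(axis=-1)
    births0 = cwr_state[state_idx] * women0
    init[:, :, 0, 0] = births0 * spec.srb / (1 + spec.srb)
    init[:, :, 1, 0] = births0 / (1 + spec.srb)

    clean, n_floored = _evolve(spec, param, cwr_state, init, state_idx)

    observed = clean
    if spec.noise_sigma > 0:
        s = spec.noise_sigma
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=clean.shape)
        observed = clean * noise

    truth = GroundTruth(
        spec, ccr, ccd, cwr_state,
        DensePanel(clean, areas, list(range(1, R + 1)), list(spec.times)),
        n_floored,
    )
    return observed, truth, state_idx, n_floored


def generate_panel(spec: ScenarioSpec) -> tuple[PopulationPanel, GroundTruth]:
    """Generate an observed panel plus its ground truth.

    Deterministic: the same spec (including seed) yields a bit-identical
    panel.  With ``noise_sigma = 0`` the observed panel equals the clean
    evolution exactly.
    """
    observed, truth, _, _ = _generate_dense(spec)
    panel = DensePanel(
        observed, spec.area_codes, list(range(1, spec.n_races + 1)), list(spec.times)
    ).to_panel()
    return panel, truth


def generate_gq(
    spec: ScenarioSpec, fraction: float = 0.026, seed_offset: int = 101
) -> GroupQuartersTable:
    """Group-quarters table: a small fixed fraction of each launch cell.

    The default fraction mirrors the share of the US population living in
    group quarters (about 2.6%).
    """
    observed, truth, _, _ = _generate_dense(spec)
    rng = np.random.default_rng(spec.seed + seed_offset)
    frac = rng.uniform(0, 2 * fraction, size=observed.shape)
    gq = observed * frac
    dense = DensePanel(
        gq, spec.area_codes, list(range(1, spec.n_races + 1)), list(spec.times)
    )
    return GroupQuartersTable(dense.to_panel().df)


def generate_controls(
    panel: PopulationPanel,
    years: Sequence[int] | None = None,
    inflation: float | Sequence[float] = 1.0,
    open_interval_code: int = 18,
    seed: int = 0,
) -> ControlTable:
    """Control table from a panel's true age-sex totals times an inflation path.

    With ``inflation = 1`` raking the panel to these controls is the
    identity.  ``open_interval_code > 18`` emits controls in the style of
    scenario files with a later open interval (e.g. 21 for 100+): the 85+
    total is split randomly across codes 18..N, preserving the total, so the
    truncation step has a known correct answer.
    """
    years = list(years) if years is not None else panel.years
    infl = np.broadcast_to(np.asarray(inflation, dtype=float), (len(years),))
    df = panel.df[panel.df["year"].isin(years)]
    tot = df.groupby(["sex", "age", "year"], as_index=False)["value"].sum()
    tot["value"] = tot["value"] * tot["year"].map(dict(zip(years, infl)))
    if open_interval_code > 18:
        rng = np.random.default_rng(seed)
        keep = tot[tot["age"] < 18]
        tail_rows = []
        codes = list(range(18, open_interval_code + 1))
        for _, row in tot[tot["age"] == 18].iterrows():
            w = rng.dirichlet(np.ones(len(codes)))
            for code, share in zip(codes, w):
                tail_rows.append(
                    {"sex": row["sex"], "age": code, "year": row["year"],
                     "value": row["value"] * share}
                )
        tot = pd.concat([keep, pd.DataFrame(tail_rows)], ignore_index=True)
    return ControlTable(tot[["sex", "age", "year", "value"]])
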