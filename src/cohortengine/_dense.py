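"""Dense-array numerical core.

Everything here operates on the array layout produced by
``PopulationPanel.to_dense()``: ``values[area, race, sex, age, time]`` with 18
five-year age groups (index 17 = open interval 85+) and sexes (Male, Female).
The public modules wrap these functions with the tidy-table containers; the
Monte-Carlo validation harness calls them directly so that hundreds of
replicate pipelines stay cheap.

Conventions
-----------
* Cohort-change arrays are indexed ``[area, race, sex, dest, transition]``
  where ``dest`` 0..16 maps to destination age codes 2..18.  The last dest
  slot is the open interval, whose source is the pooled 80+ population.
* Child-woman ratios are per (state, race); ``cwr_by_area`` broadcasts them
  to member areas.
* The MA(1) model uses the sign convention ``w_t = e_t - theta * e_{t-1}``
  (random-walk plus negatively-lagged shock), under which the one-step
  forecast is exponential smoothing with weight ``alpha = 1 - theta``.
"""

from __future__ import annotations

import numpy as np

MALE_IDX, FEMALE_IDX = 0, 1
N_AGES = 18
N_DEST = 17  # destination age codes 2..18
CHILDBEARING_SLICE = slice(3, 10)  # age codes 4..10 == ages 15-49

# forecast method codes
METHOD_ARIMA, METHOD_NAIVE, METHOD_MISSING = 0, 1, 2


# ---------------------------------------------------------------------------
# cohort-change series
# ---------------------------------------------------------------------------

def series_ccr(values: np.ndarray) -> np.ndarray:
    """Cohort-change ratios for every transition in a dense panel.

    Returns ``(A, R, S, 17, T-1)``; entry ``[..., d, k]`` is the ratio for
    destination age code ``d+2`` over the transition ``times[k] ->
    times[k+1]``.  Zero denominators give NaN (masked-missing).
    """
    num = values[..., 1:, 1:]                      # ages 2..18 at t
    den = values[..., :-1, :-1].copy()             # ages 1..17 at t-y
    # open interval: denominator is the 80-and-over pool (codes 17 + 18)
    den[..., -1, :] = values[..., 16, :-1] + values[..., 17, :-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def series_ccd(values: np.ndarray) -> np.ndarray:
    """Cohort-change differences, same layout as :func:`series_ccr`."""
    sub = values[..., :-1, :-1].copy()
    sub[..., -1, :] = values[..., 16, :-1] + values[..., 17, :-1]
    return values[..., 1:, 1:] - sub


def series_cwr(
    values: np.ndarray, state_idx: np.ndarray, n_states: int
) -> np.ndarray:
    """Child-woman ratios pooled at state x race level, ``(n_states, R, T)``.

    CWR = population aged 0-4 (both sexes) / women aged 15-49, with sums
    taken over all member areas of the state.  Empty state x race pools fall
    back to the national pool for that race; NaN only if that is empty too.
    """
    children = values[:, :, :, 0, :].sum(axis=2)          # (A, R, T)
    women = values[:, :, FEMALE_IDX, CHILDBEARING_SLICE, :].sum(axis=2)
    A, R, T = children.shape
    ch_pool = np.zeros((n_states, R, T))
    wo_pool = np.zeros((n_states, R, T))
    np.add.at(ch_pool, state_idx, children)
    np.add.at(wo_pool, state_idx, women)
    with np.errstate(divide="ignore", invalid="ignore"):
        cwr = ch_pool / wo_pool
    # national x race fallback for empty pools
    nat_w = women.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nat = children.sum(axis=0) / nat_w
    nat = np.where(nat_w > 0, nat, np.nan)
    empty = wo_pool == 0
    cwr[empty] = np.broadcast_to(nat, cwr.shape)[empty]
    return cwr


def cwr_by_area(cwr_state: np.ndarray, state_idx: np.ndarray) -> np.ndarray:
    """Broadcast state x race CWRs to ``(A, R, ...)`` for member areas."""
    return cwr_state[state_idx]


# ---------------------------------------------------------------------------
# MA(1) fitting on first differences (ARIMA(0,1,1) without drift)
# ---------------------------------------------------------------------------

def _css_objective(W: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Conditional sum of squares of ``w_t = e_t - theta e_{t-1}`` with e_0=0.

    ``W`` is ``(k, m)`` (series x differences), ``theta`` is ``(g, k)`` or
    ``(g, 1)``; returns SSE of shape ``(g, k)``.
    """
    m = W.shape[1]
    e = W[None, :, 0] * np.ones_like(theta)
    sse = e**2
    for t in range(1, m):
        e = W[None, :, t] + theta * e
        sse = sse + e**2
    return sse


def _css_minimize(W: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Grid + two local refinements of theta on [lo, hi] per series."""
    k = W.shape[0]
    grid = np.linspace(lo, hi, 199)[:, None]          # (g, 1)
    sse = _css_objective(W, grid)
    best = grid[np.argmin(sse, axis=0), 0]            # (k,)
    span = grid[1, 0] - grid[0, 0]
    for _ in range(2):
        offs = np.linspace(-span, span, 41)[:, None]  # (g, 1)
        local = np.clip(best[None, :] + offs, lo, hi)  # (g, k)
        sse = _css_objective(W, local)
        best = local[np.argmin(sse, axis=0), np.arange(k)]
        span = 2 * span / 40
    return best


def _ses_forecast(x: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """One-step forecast of level series ``x`` (k, n) at fitted theta (k,).

    Equal by algebra to exponential smoothing with alpha = 1 - theta started
    at the first observation; constant for all horizons j >= 1.
    """
    e = np.zeros(theta.shape)
    for t in range(1, x.shape[1]):
        e = (x[:, t] - x[:, t - 1]) + theta * e
    return x[:, -1] - theta * e


def fit_ma1_many(
    X: np.ndarray,
    min_len: int = 4,
    theta_bounds: tuple[float, float] = (0.0, 0.999),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit ARIMA(0,1,1) independently to each row of ``X`` (NaN = missing).

    Missing interior values are dropped (series compacted).  Returns
    ``(theta, forecast, method)`` arrays of length ``X.shape[0]``; method is
    0 = arima011, 1 = naive-last (series shorter than ``min_len``),
    2 = fallback-missing (no observations).  The forecast is identical for
    every horizon j >= 1 (flat-horizon property of the model).
    """
    X = np.asarray(X, dtype=float)
    n_series = X.shape[0]
    theta = np.full(n_series, np.nan)
    forecast = np.full(n_series, np.nan)
    method = np.full(n_series, METHOD_MISSING, dtype=int)
    if X.size == 0:
        return theta, forecast, method

    finite = np.isfinite(X)
    counts = finite.sum(axis=1)

    short = (counts > 0) & (counts < min_len)
    if short.any():
        last_idx = X.shape[1] - 1 - np.argmax(finite[short][:, ::-1], axis=1)
        forecast[short] = X[np.flatnonzero(short), last_idx]
        method[short] = METHOD_NAIVE

    lo, hi = theta_bounds
    for n in np.unique(counts[counts >= min_len]):
        rows = np.flatnonzero(counts == n)
        # compact each row to its finite entries (same length within group)
        x = X[rows][finite[rows]].reshape(len(rows), n)
        W = np.diff(x, axis=1)
        scale = np.maximum(np.abs(x).max(axis=1), 1.0)
        const = np.abs(W).max(axis=1) <= 1e-12 * scale
        th = np.zeros(len(rows))
        if (~const).any():
            th[~const] = _css_minimize(W[~const], lo, hi)
        theta[rows] = th
        forecast[rows] = np.where(const, x[:, -1], _ses_forecast(x, th))
        method[rows] = METHOD_ARIMA
    return theta, forecast, method


def ma1_exact_mle(x: np.ndarray, theta_bounds=(0.0, 0.999)) -> tuple[float, float]:
    """Exact Gaussian ML fit of ARIMA(0,1,1) to a single series.

    Uses the innovations-algorithm likelihood of the differenced series with
    the error variance profiled out.  Returns (theta, one-step forecast).
    Provided as a slower, exact alternative to the conditional-SS default.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    w = np.diff(x)
    m = len(w)
    if m == 0 or np.abs(w).max() <= 1e-12 * max(1.0, np.abs(x).max()):
        return 0.0, float(x[-1])

    def neg_profile_loglik(theta: float) -> float:
        v = 1.0 + theta**2
        what = 0.0
        q = 0.0
        logdet = 0.0
        for t in range(m):
            u = w[t] - what
            q += u**2 / v
            logdet += np.log(v)
            coef = -theta / v
            what = coef * u
            v = 1.0 + theta**2 - theta**2 / v
        return m * np.log(q / m) + logdet

    from scipy.optimize import minimize_scalar

    res = minimize_scalar(neg_profile_loglik, bounds=theta_bounds, method="bounded")
    theta = float(res.x)
    # innovations one-step forecast of the next difference
    v = 1.0 + theta**2
    what = 0.0
    for t in range(m):
        u = w[t] - what
        what = (-theta / v) * u
        v = 1.0 + theta**2 - theta**2 / v
    return theta, float(x[-1] + what)


# ---------------------------------------------------------------------------
# projection stepping
# ---------------------------------------------------------------------------

def step(
    pop: np.ndarray,
    ccr_f: np.ndarray,
    ccd_f: np.ndarray,
    cwr_area_f: np.ndarray,
    use_ccr: np.ndarray | bool,
    srb: float = 1.05,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Advance a population slice one interval with Leslie-style operators.

    ``pop`` is ``(A, R, S, 18)``; ``ccr_f``/``ccd_f`` are forecast arrays
    ``(A, R, S, 17)`` for destination ages 2..18 (NaN in ``ccr_f`` means no
    usable ratio forecast: the additive difference is substituted cell-wise);
    ``cwr_area_f`` is ``(A, R)``; ``use_ccr`` is a per-(area, race) boolean
    (or scalar) choosing the multiplicative operator.

    Ages 2-17 are the shifted cohort, age 18 is fed by the 80-and-over pool,
    and age 1 is the child-woman ratio applied to the projected women aged
    15-49 within the same step, split by a sex ratio at birth ``srb``.
    """
    A, R, S, G = pop.shape
    src = np.empty((A, R, S, N_DEST))
    src[..., :16] = pop[..., :16]
    src[..., 16] = pop[..., 16] + pop[..., 17]      # 80+ pool feeds 85+

    mult = ccr_f * src
    addv = np.where(np.isnan(ccd_f), 0.0, ccd_f) + src
    use_ccr_cells = np.broadcast_to(
        np.asarray(use_ccr)[..., None, None] if np.ndim(use_ccr) else use_ccr,
        mult.shape,
    )
    chosen = np.where(use_ccr_cells, mult, addv)
    # ratio requested but forecast missing -> additive fallback for the cell
    chosen = np.where(np.isnan(chosen), addv, chosen)

    new = np.empty_like(pop)
    new[..., 1:] = chosen
    if floor_at_zero:
        np.clip(new[..., 1:], 0.0, None, out=new[..., 1:])

    women = new[:, :, FEMALE_IDX, CHILDBEARING_SLICE].sum(axis=-1)   # (A, R)
    births = np.where(np.isnan(cwr_area_f), 0.0, cwr_area_f) * women
    if floor_at_zero:
        births = np.clip(births, 0.0, None)
    new[:, :, MALE_IDX, 0] = births * (srb / (1.0 + srb))
    new[:, :, FEMALE_IDX, 0] = births * (1.0 / (1.0 + srb))
    return new


def project_dense(
    pop0: np.ndarray,
    ccr_f: np.ndarray,
    ccd_f: np.ndarray,
    cwr_area_f: np.ndarray,
    use_ccr: np.ndarray | bool,
    n_steps: int,
    srb: float = 1.05,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Iterate :func:`step`; returns ``(A, R, S, 18, n_steps)``."""
    out = np.empty(pop0.shape + (n_steps,))
    cur = pop0
    for k in range(n_steps):
        cur = step(cur, ccr_f, ccd_f, cwr_area_f, use_ccr, srb, floor_at_zero)
        out[..., k] = cur
    return out


def classify_dense(
    pop0: np.ndarray,
    ccr_f: np.ndarray,
    ccd_f: np.ndarray,
    cwr_area_f: np.ndarray,
    n_steps: int,
    srb: float = 1.05,
    floor_at_zero: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Grow-or-decline classification per (area, race).

    Runs a provisional full-horizon additive (CCD) projection; a combination
    is "growing" when its final-horizon total meets or exceeds its launch
    total, in which case the additive operator is retained; declining
    combinations switch to ratios.  Returns ``(use_ccr, launch_totals,
    final_ccd_totals)`` with shapes ``(A, R)``.
    """
    prov = project_dense(
        pop0, ccr_f, ccd_f, cwr_area_f, False, n_steps, srb, floor_at_zero
    )
    launch = pop0.sum(axis=(2, 3))
    final = prov[..., -1].sum(axis=(2, 3))
    use_ccr = final < launch          # tie -> additive (CCD)
    return use_ccr, launch, final


# ---------------------------------------------------------------------------
# raking to age-sex controls
# ---------------------------------------------------------------------------

def rake_slice(
    pop: np.ndarray, control_sa: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Proportionally scale one time slice to (sex, age) control totals.

    ``pop`` is ``(A, R, S, 18)``, ``control_sa`` is ``(S, 18)``.  Margins
    with zero raw total keep their zeros; the unallocated control mass is
    returned so callers can report it.  Returns ``(raked, scale, unallocated)``
    where ``scale``/``unallocated`` have shape ``(S, 18)``.
    """
    raw = pop.sum(axis=(0, 1))                      # (S, 18)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(raw > 0, control_sa / raw, 1.0)
    unallocated = np.where((raw == 0) & (control_sa > 0), control_sa, 0.0)
    return pop * scale[None, None], scale, unallocated
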