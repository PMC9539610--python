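"""Window-wise mixed-model testing of pupil time series.

The dependent variable is baseline-corrected pupil size binned into
uniform windows over the retention interval.  For each window a linear
mixed-effects model is fit with memory load (centered numeric, 1-4 minus
2.5) and color type (sum-coded, ambiguous = +0.5, prototypical = -0.5)
plus their interaction as fixed effects and, by default, by-participant
random intercepts and slopes for all fixed effects.  A fixed-effect term
is called significant when its p-value stays below alpha for a minimum
contiguous duration (default 200 ms, i.e. 20 consecutive 10-ms windows).

Because picking the "strongest" window and testing it on the same data is
circular, the localization test uses interleaved cross-validation: trials
are partitioned into folds by within-participant trial index modulo the
fold count; each fold's winning window (maximum |z| of the effect of
interest) is determined on the remaining folds, the held-out trials
contribute their pupil size at that window, and a single mixed model on
the pooled held-out values yields the reported z and p.  Follow-up models
test the color-type effect per memory load on the trial-mean pupil size
inside the localized window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "TERMS",
    "TimeSeriesTestConfig",
    "TimeSeriesTestResult",
    "windowed_lmm",
    "contiguous_significance",
    "crossval_localize_test",
    "followup_by_load",
    "run_time_series_analysis",
]

TERMS = ["intercept", "load", "color_type", "load:color_type"]


@dataclass
class TimeSeriesTestConfig:
    """Settings of the window-wise testing procedure."""

    alpha: float = 0.05
    min_duration_ms: float = 200.0
    n_folds: int = 4
    window_ms: float = 10.0
    effect_of_interest: str = "load:color_type"
    random_structure: str = "slopes"          # "slopes" or "intercept"
    fallback_random_structure: str = "intercept"
    load_center: float = 2.5

    def validate(self):
        ratio = self.min_duration_ms / self.window_ms
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("min_duration_ms must be a multiple of window_ms")
        if self.effect_of_interest not in TERMS:
            raise ValueError(f"unknown effect term {self.effect_of_interest!r}")
        for rs in (self.random_structure, self.fallback_random_structure):
            if rs not in ("slopes", "intercept"):
                raise ValueError(f"unknown random structure {rs!r}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        return self

    @property
    def min_windows(self) -> int:
        return int(round(self.min_duration_ms / self.window_ms))


@dataclass
class TimeSeriesTestResult:
    """Everything the time-series analysis reports."""

    per_window: pd.DataFrame                 # window_start_ms x term rows
    clusters: dict                           # term -> list of [start, end) ms
    cv_winning_samples: list                 # per-fold winning window starts
    cv_statistic: float
    cv_p: float
    followups: dict                          # load -> dict(coef, z, p)
    followup_window: tuple | None = None


def design_matrix(meta: pd.DataFrame, load_center: float = 2.5) -> np.ndarray:
    """Fixed-effects design: intercept, centered load, sum-coded color type,
    and their product, one row per trial."""
    load_c = meta["memory_load"].to_numpy(dtype=float) - load_center
    ctype = np.where(meta["color_type"].to_numpy() == "ambiguous", 0.5, -0.5)
    return np.column_stack([np.ones(len(meta)), load_c, ctype, load_c * ctype])


def _fit_one(endog, exog, groups, structure: str):
    exog_re = exog if structure == "slopes" else exog[:, :1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re)
        res = model.fit(reml=True, method="lbfgs", maxiter=200)
        se = np.asarray(res.bse_fe, dtype=float)
        cov_re = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise np.linalg.LinAlgError("degenerate standard errors")
    # a singular random-effects covariance (variance on the zero boundary)
    # leaves cov_params unusable even when the point estimates are fine
    if np.linalg.eigvalsh(cov_re).min() < 1e-8 * max(res.scale, 1e-12):
        raise np.linalg.LinAlgError("singular random-effects covariance")
    coefs = np.asarray(res.fe_params, dtype=float)
    z = coefs / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return coefs, z, p, bool(getattr(res, "converged", True))


def fit_window_model(endog, exog, groups, config: TimeSeriesTestConfig):
    """One mixed-model fit with convergence fallback.

    Returns (coefs, z, p, fallback_used) or None when even the fallback
    random structure is unfittable.
    """
    primary = None
    try:
        coefs, z, p, converged = _fit_one(endog, exog, groups,
                                          config.random_structure)
        if converged:
            return coefs, z, p, False
        primary = (coefs, z, p, True)
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        pass
    if config.fallback_random_structure != config.random_structure:
        try:
            coefs, z, p, _ = _fit_one(endog, exog, groups,
                                      config.fallback_random_structure)
            return coefs, z, p, True
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
            pass
    if primary is not None:
        return primary
    # zero between-participant variance reduces the mixed model to OLS
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.OLS(endog, exog).fit()
        se = np.asarray(res.bse, dtype=float)
        if np.all(np.isfinite(se)) and np.all(se > 0):
            coefs = np.asarray(res.params, dtype=float)
            z = coefs / se
            return coefs, z, 2.0 * stats.norm.sf(np.abs(z)), True
    except (np.linalg.LinAlgError, ValueError):
        pass
    return None


def _wide(data: pd.DataFrame):
    """Pivot the long windowed table to one row per trial.

    Returns (meta, Y, window_starts): trial metadata, a trials x windows
    pupil matrix, and the sorted window start times.
    """
    needed = {"participant", "trial", "window_start_ms", "pupil",
              "memory_load", "color_type"}
    missing = needed - set(data.columns)
    if missing:
        raise ValueError(f"windowed data lacks columns: {sorted(missing)}")
    wide = data.pivot_table(index=["participant", "trial", "memory_load",
                                   "color_type"],
                            columns="window_start_ms", values="pupil",
                            sort=True, dropna=False)
    meta = wide.index.to_frame(index=False)
    return meta, wide.to_numpy(), np.asarray(wide.columns, dtype=float)


def windowed_lmm(data: pd.DataFrame,
                 config: TimeSeriesTestConfig | None = None) -> pd.DataFrame:
    """Fit the mixed model separately for every time window.

    Returns a long table with one row per window x fixed-effect term
    (coef, z, p, fallback flag).  Windows where even the fallback
    structure fails are kept with NaN statistics and ``failed`` = True —
    never silently dropped.
    """
    config = (config or TimeSeriesTestConfig()).validate()
    meta, Y, starts = _wide(data)
    if meta["participant"].nunique() < 2:
        raise ValueError("windowed_lmm needs at least 2 participants")
    exog_all = design_matrix(meta, config.load_center)
    groups_all = meta["participant"].to_numpy()
    rows = []
    for j, start in enumerate(starts):
        endog = Y[:, j]
        ok = np.isfinite(endog)
        fit = None
        if ok.sum() >= exog_all.shape[1] + 2:
            fit = fit_window_model(endog[ok], exog_all[ok], groups_all[ok],
                                   config)
        if fit is None:
            for term in TERMS:
                rows.append({"window_start_ms": start, "term": term,
                             "coef": np.nan, "z": np.nan, "p": np.nan,
                             "fallback": False, "failed": True})
            continue
        coefs, z, p, fallback = fit
        for t, term in enumerate(TERMS):
            rows.append({"window_start_ms": start, "term": term,
                         "coef": coefs[t], "z": z[t], "p": p[t],
                         "fallback": fallback, "failed": False})
    return pd.DataFrame(rows)


def contiguous_significance(window_starts, pvalues,
                            config: TimeSeriesTestConfig | None = None) -> list:
    """Maximal runs of consecutive sub-alpha windows lasting long enough.

    Windows must be in time order with uniform spacing ``window_ms``.
    Returns ``[start_ms, end_ms)`` pairs; a run shorter than
    ``min_duration_ms`` (20 windows at the defaults) is not a cluster.
    NaN p-values break runs.
    """
    config = (config or TimeSeriesTestConfig()).validate()
    starts = np.asarray(window_starts, dtype=float)
    p = np.asarray(pvalues, dtype=float)
    if starts.size != p.size:
        raise ValueError("window_starts and pvalues must align")
    sig = np.nan_to_num(p, nan=1.0) < config.alpha
    clusters = []
    i = 0
    while i < sig.size:
        if sig[i]:
            j = i
            while j < sig.size and sig[j]:
                j += 1
            if j - i >= config.min_windows:
                clusters.append((float(starts[i]),
                                 float(starts[j - 1] + config.window_ms)))
            i = j
        else:
            i += 1
    return clusters


def _fold_assignment(meta: pd.DataFrame, n_folds: int) -> np.ndarray:
    """Interleaved folds: within-participant trial rank modulo n_folds."""
    rank = meta.groupby("participant")["trial"].rank(method="first").astype(int)
    return ((rank - 1) % n_folds).to_numpy()


def crossval_localize_test(data: pd.DataFrame,
                           config: TimeSeriesTestConfig | None = None):
    """Cross-validated localization and test of the effect of interest.

    For each interleaved fold, the remaining folds select the window with
    the largest |z| of ``effect_of_interest``; the held-out trials then
    contribute their pupil value at that window.  A single mixed model on
    the pooled held-out values (every trial exactly once) gives the
    reported statistic — the data that select the window never enter the
    final test.

    Returns ``(winning_starts, z, p)`` with one winning window per fold.
    """
    config = (config or TimeSeriesTestConfig()).validate()
    meta, Y, starts = _wide(data)
    exog_all = design_matrix(meta, config.load_center)
    groups_all = meta["participant"].to_numpy()
    folds = _fold_assignment(meta, config.n_folds)
    if np.bincount(folds, minlength=config.n_folds).min() == 0:
        raise ValueError("too few trials to populate every fold")
    term_idx = TERMS.index(config.effect_of_interest)

    winning, held_dv = [], np.full(len(meta), np.nan)
    for k in range(config.n_folds):
        train = folds != k
        best_z, best_j = -np.inf, None
        for j in range(starts.size):
            endog = Y[train, j]
            ok = np.isfinite(endog)
            if ok.sum() < exog_all.shape[1] + 2:
                continue
            fit = fit_window_model(endog[ok], exog_all[train][ok],
                                   groups_all[train][ok], config)
            if fit is None:
                continue
            _, z, _, _ = fit
            if np.isfinite(z[term_idx]) and abs(z[term_idx]) > best_z:
                best_z, best_j = abs(z[term_idx]), j
        if best_j is None:
            raise RuntimeError(f"training fit failed at every window (fold {k})")
        winning.append(float(starts[best_j]))
        held = folds == k
        held_dv[held] = Y[held, best_j]

    ok = np.isfinite(held_dv)
    fit = fit_window_model(held_dv[ok], exog_all[ok], groups_all[ok], config)
    if fit is None:
        raise RuntimeError("pooled cross-validation fit failed")
    _, z, p, _ = fit
    return winning, float(z[term_idx]), float(p[term_idx])


def followup_by_load(data: pd.DataFrame, window: tuple,
                     config: TimeSeriesTestConfig | None = None) -> dict:
    """Color-type effect per memory load on window-mean pupil size.

    Each trial's pupil values with window start in ``[t0, t1)`` are
    averaged; per load a mixed model with color type as the only fixed
    effect (by-participant random intercept + slope, with the usual
    fallback) yields the coefficient, z and p.  Loads absent from the
    data are skipped with a warning.
    """
    config = (config or TimeSeriesTestConfig()).validate()
    t0, t1 = window
    meta, Y, starts = _wide(data)
    inside = (starts >= t0) & (starts < t1)
    if not inside.any():
        raise ValueError(f"window [{t0}, {t1}) covers no analyzed windows")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        dv = np.nanmean(Y[:, inside], axis=1)
    ctype = np.where(meta["color_type"].to_numpy() == "ambiguous", 0.5, -0.5)
    out = {}
    for load in (1, 2, 3, 4):
        sel = (meta["memory_load"].to_numpy() == load) & np.isfinite(dv)
        if not sel.any():
            warnings.warn(f"memory load {load} absent from data; skipped")
            continue
        exog = np.column_stack([np.ones(sel.sum()), ctype[sel]])
        fit = fit_window_model(dv[sel], exog,
                               meta["participant"].to_numpy()[sel], config)
        if fit is None:
            out[load] = {"coef": np.nan, "z": np.nan, "p": np.nan,
                         "fallback": True}
            continue
        coefs, z, p, fallback = fit
        out[load] = {"coef": float(coefs[1]), "z": float(z[1]),
                     "p": float(p[1]), "fallback": fallback}
    return out


def run_time_series_analysis(data: pd.DataFrame,
                             config: TimeSeriesTestConfig | None = None
                             ) -> TimeSeriesTestResult:
    """Full procedure: per-window models, clusters, CV localization,
    follow-ups in the cross-validated window span."""
    config = (config or TimeSeriesTestConfig()).validate()
    per_window = windowed_lmm(data, config)
    clusters = {}
    for term in TERMS[1:]:
        sub = per_window[per_window["term"] == term]
        clusters[term] = contiguous_significance(
            sub["window_start_ms"].to_numpy(), sub["p"].to_numpy(), config)
    winning, cv_z, cv_p = crossval_localize_test(data, config)
    span = (min(winning), max(winning) + config.window_ms)
    followups = followup_by_load(data, span, config)
    return TimeSeriesTestResult(per_window=per_window, clusters=clusters,
                                cv_winning_samples=winning, cv_statistic=cv_z,
                                cv_p=cv_p, followups=followups,
                                followup_window=span)
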