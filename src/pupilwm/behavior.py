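"""Behavioral statistics: above-chance permutation check, repeated-measures
ANOVA on mixture parameters, paired follow-up tests and descriptive
circular response densities.

The permutation check asks, per participant, whether real absolute recall
errors are smaller than the errors obtained after shuffling that
participant's response hues across trials (one-sided two-sample t-test).
The mixture parameters (precision, guess rate) fitted per participant x
load x color-type cell feed a classical two-way within-subject ANOVA
(memory load x color type, both within factors); the interaction is
qualified by paired t-tests of ambiguous vs prototypical per load.
Greenhouse-Geisser sphericity corrections are computed and reported
alongside, but the primary F/df/p columns are uncorrected.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .mixture import circular_distance, vm_density_deg

__all__ = [
    "permutation_above_chance",
    "rm_anova",
    "paired_followups",
    "circular_response_density",
]

LOADS = (1, 2, 3, 4)
COLOR_TYPES = ("prototypical", "ambiguous")


def permutation_above_chance(trials: pd.DataFrame, n_shuffles: int = 1,
                             alpha: float = 0.05,
                             seed: int | None = None) -> pd.DataFrame:
    """Per-participant test that recall is better than a response shuffle.

    For each participant the response hues are permuted across that
    participant's trials ``n_shuffles`` times (default 1); the shuffled
    absolute errors (pooled over shuffles) are compared with the real
    absolute errors by a one-sided independent-samples t-test (real <
    shuffled).  ``above_chance`` is True when p < alpha.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for pp, sub in trials.groupby("participant", sort=True):
        targets = sub["target_hue"].to_numpy()
        responses = sub["response_hue"].to_numpy()
        if targets.size < 10:
            raise ValueError(f"participant {pp} has fewer than 10 trials")
        real = np.abs(circular_distance(responses, targets))
        shuffled = np.concatenate([
            np.abs(circular_distance(rng.permutation(responses), targets))
            for _ in range(n_shuffles)])
        t, p = stats.ttest_ind(real, shuffled, alternative="less")
        rows.append({"participant": pp, "t": float(t), "p": float(p),
                     "above_chance": bool(p < alpha)})
    return pd.DataFrame(rows)


def _cell_array(cells: pd.DataFrame, value: str) -> tuple:
    """Reshape a long cell table into (n, 4 loads, 2 color types)."""
    required = {"participant", "memory_load", "color_type", value}
    if missing := required - set(cells.columns):
        raise ValueError(f"cell table lacks columns: {sorted(missing)}")
    pivot = cells.pivot_table(index="participant",
                              columns=["memory_load", "color_type"],
                              values=value, sort=True)
    expected = [(ld, ct) for ld in LOADS for ct in COLOR_TYPES]
    missing_cells = [c for c in expected if c not in pivot.columns]
    if missing_cells or pivot.isna().any().any():
        nan_cells = [str(c) for c in pivot.columns[pivot.isna().any()]]
        raise ValueError(
            "unbalanced design; missing cells: "
            f"{missing_cells + nan_cells}")
    pivot = pivot[expected]
    n = len(pivot)
    return pivot.to_numpy().reshape(n, len(LOADS), len(COLOR_TYPES)), pivot


def _gg_epsilon(cell_matrix: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the effect spanned by ``contrast``.

    ``cell_matrix`` is participants x cells; ``contrast`` is an
    orthonormal contrast basis (df x cells).
    """
    S = np.cov(cell_matrix, rowvar=False)
    M = contrast @ S @ contrast.T
    eig = np.linalg.eigvalsh(M)
    df = contrast.shape[0]
    denom = df * np.sum(eig ** 2)
    if denom <= 0:                      # zero variance: sphericity moot
        return 1.0
    return float(np.sum(eig) ** 2 / denom)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert, normalized)."""
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0
        h[i - 1, i] = -i
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def rm_anova(cells: pd.DataFrame, value: str = "precision") -> pd.DataFrame:
    """Two-way within-subject ANOVA (memory load x color type).

    ``cells`` holds one value per participant x load x color-type cell and
    must be complete and balanced.  Returns one row per term (load,
    color_type, load:color_type) with the classical uncorrected F, dfs and
    p, plus Greenhouse-Geisser epsilon and corrected p.  At n = 30 the
    dfs are (3, 87), (1, 29) and (3, 87).
    """
    Y, pivot = _cell_array(cells, value)
    n, a, b = Y.shape
    if n < 2:
        raise ValueError("ANOVA needs at least 2 participants")
    grand = Y.mean()
    m_a = Y.mean(axis=(0, 2))            # load means
    m_b = Y.mean(axis=(0, 1))            # color-type means
    m_ab = Y.mean(axis=0)                # cell means
    m_s = Y.mean(axis=(1, 2))            # participant means
    m_sa = Y.mean(axis=2)                # participant x load
    m_sb = Y.mean(axis=1)                # participant x color type

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (Y - m_ab[None] - m_sa[:, :, None] - m_sb[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = np.sum(resid ** 2)

    cell_mat = pivot.to_numpy()          # n x 8, load-major ordering
    c_a = np.kron(_orthonormal_contrasts(a), np.ones((1, b)) / np.sqrt(b))
    c_b = np.kron(np.ones((1, a)) / np.sqrt(a), _orthonormal_contrasts(b))
    c_ab = np.kron(_orthonormal_contrasts(a), _orthonormal_contrasts(b))

    rows = []
    for term, ss_eff, ss_err, df1, contrast in [
            ("load", ss_a, ss_as, a - 1, c_a),
            ("color_type", ss_b, ss_bs, b - 1, c_b),
            ("load:color_type", ss_ab, ss_abs, (a - 1) * (b - 1), c_ab)]:
        df2 = df1 * (n - 1)
        ms_eff, ms_err = ss_eff / df1, ss_err / df2
        F = ms_eff / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
        eps = _gg_epsilon(cell_mat, contrast)
        p_gg = float(stats.f.sf(F, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
        rows.append({"term": term, "F": float(F), "df1": df1, "df2": df2,
                     "p": p, "eps_gg": eps, "p_gg": p_gg})
    return pd.DataFrame(rows)


def paired_followups(cells: pd.DataFrame,
                     value: str = "precision") -> pd.DataFrame:
    """Paired t-test of ambiguous vs prototypical per memory load.

    Positive t means larger values for ambiguous.  With identical
    condition vectors t = 0 and p = 1; a constant nonzero shift with zero
    within-pair variance is reported as |t| = inf, p = 0.
    """
    Y, _ = _cell_array(cells, value)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("paired follow-ups need at least 3 participants")
    rows = []
    for li, load in enumerate(LOADS):
        proto = Y[:, li, 0]
        ambig = Y[:, li, 1]
        diff = ambig - proto
        if np.allclose(diff.std(ddof=1), 0.0):
            if np.allclose(diff.mean(), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = np.sign(diff.mean()) * np.inf, 0.0
        else:
            t, p = stats.ttest_rel(ambig, proto)
        rows.append({"memory_load": load, "t": float(t), "df": n - 1,
                     "p": float(p)})
    return pd.DataFrame(rows)


def circular_response_density(trials: pd.DataFrame,
                              bandwidth_kappa: float = 50.0,
                              group_cols=("target_hue", "memory_load")
                              ) -> pd.DataFrame:
    """Von Mises kernel density of response hues per (memory hue, load).

    Evaluated on the 1-degree grid 0..359; each group's density integrates
    to 1 over the circle.  The default kernel concentration of 50
    corresponds to roughly an 8-degree SD.  Empty groups are omitted with
    a warning.
    """
    if bandwidth_kappa <= 0:
        raise ValueError("bandwidth_kappa must be > 0")
    grid = np.arange(360.0)
    frames = []
    for key, sub in trials.groupby(list(group_cols), sort=True):
        responses = sub["response_hue"].to_numpy(dtype=float)
        if responses.size == 0:  # pragma: no cover - groupby skips empties
            warnings.warn(f"group {key} empty; omitted")
            continue
        diff = circular_distance(grid[:, None], responses[None, :])
        dens = vm_density_deg(diff, bandwidth_kappa).mean(axis=1)
        frame = pd.DataFrame({"hue": grid, "density": dens})
        for col, val in zip(group_cols, np.atleast_1d(key)):
            frame[col] = val
        frames.append(frame)
    if not frames:
        raise ValueError("no non-empty groups")
    return pd.concat(frames, ignore_index=True)
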