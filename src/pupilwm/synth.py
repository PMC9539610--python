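"""Synthetic data generators for the full analysis pipeline.

Three generators emulate the inputs of a delayed-estimation pupillometry
study of continuous vs categorical color working memory:

* hue-categorization records (every participant labels all 360 integer
  hues with one of seven color names, with optional adjacent-label noise);
* delayed-estimation trials (memory loads 1-4 crossed with prototypical
  vs ambiguous target colors, responses drawn from a von Mises + uniform
  encoding mixture whose categorical weight may depend on load);
* per-trial pupil traces at a configurable sample rate with a load effect
  from a configurable onset, a color-type (interaction) effect inside a
  retention-interval window, AR(1) noise, between-trial baseline
  variability and zero-run blink artifacts.

Default design sizes follow the study being emulated: 30 participants,
32 trials per load x color-type cell (256 trials each), 7 color
categories, 2500-ms retention, 1000-Hz sampling, a load effect from
500 ms and a color-type-by-load effect over 1290-2140 ms.  All generators
are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter, lfilter_zi

from .categories import COLOR_LABELS_7, CategorySolution, find_prototypes
from .mixture import circular_distance
from .pupil import TrialPupil

__all__ = [
    "SimConfig",
    "PupilEffectSpec",
    "generate_category_structure",
    "simulate_categorization",
    "simulate_delayed_estimation",
    "simulate_pupil",
    "simulate_study",
]

LOADS = (1, 2, 3, 4)
COLOR_TYPES = ("prototypical", "ambiguous")


def _default_p_categorical() -> dict:
    # categorical encoding becomes dominant as load grows, for both color
    # types; for prototypical targets it is behaviorally near-invisible
    # because the category prototype coincides with the target
    p_by_load = {1: 0.1, 2: 0.4, 3: 0.7, 4: 0.9}
    return {(load, ctype): p for load, p in p_by_load.items()
            for ctype in COLOR_TYPES}


def _default_guess_rate() -> dict:
    return {1: 0.02, 2: 0.08, 3: 0.15, 4: 0.25}


def _default_interaction() -> dict:
    # positive = pupil larger for ambiguous; the emulated pattern flips
    # from ambiguous-larger at load 1 to ambiguous-smaller at load 4
    return {1: 20.0, 2: 7.0, 3: -7.0, 4: -20.0}


@dataclass
class PupilEffectSpec:
    """Ground-truth structure of simulated pupil traces.

    ``load_slope`` (a.u. per memorized item) applies from ``onset_ms``
    onward; ``interaction_amplitude_by_load`` is added to ambiguous trials
    inside ``interaction_window`` (positive = ambiguous larger).  Noise is
    AR(1) Gaussian per sample with stationary SD ``noise_sd``; blinks are
    zero-valued runs of ``blink_duration_ms`` occurring ``blink_rate``
    times per trial on average.
    """

    baseline_mean: float = 1000.0
    baseline_sd_between_trial: float = 50.0
    load_slope: float = 20.0
    onset_ms: float = 500.0
    interaction_window: tuple = (1290.0, 2140.0)
    interaction_amplitude_by_load: dict = field(default_factory=_default_interaction)
    noise_sd: float = 50.0
    noise_ar1: float = 0.9
    blink_rate: float = 1.0
    blink_duration_ms: float = 150.0
    sample_rate_hz: float = 1000.0
    trace_span_ms: tuple = (-1500.0, 2800.0)

    def validate(self):
        if not (0.0 <= self.noise_ar1 < 1.0):
            raise ValueError("noise_ar1 must be in [0, 1)")
        t0, t1 = self.interaction_window
        if not (0.0 <= t0 < t1 <= 2500.0):
            raise ValueError(
                "interaction_window must lie within the retention interval [0, 2500]")
        if self.sample_rate_hz <= 0 or self.blink_rate < 0:
            raise ValueError("sample_rate_hz must be > 0 and blink_rate >= 0")
        return self


@dataclass
class SimConfig:
    """Design and encoding-model parameters of a simulated study."""

    n_participants: int = 30
    trials_per_cell: int = 32       # per load x color-type cell; 256 per participant
    n_categories: int = 7
    kappa_continuous: float = 50.0
    kappa_categorical: float = 8.0
    p_categorical: dict = field(default_factory=_default_p_categorical)
    guess_rate_by_load: dict = field(default_factory=_default_guess_rate)
    ambiguous_bias: float = 0.5     # P(categorical encoder picks the upper flank)
    pupil_params: PupilEffectSpec = field(default_factory=PupilEffectSpec)
    seed: int = 0

    def validate(self):
        if self.n_participants < 1 or self.trials_per_cell < 1:
            raise ValueError("n_participants and trials_per_cell must be >= 1")
        if self.n_categories < 2:
            raise ValueError("n_categories must be >= 2")
        if min(self.kappa_continuous, self.kappa_categorical) < 0:
            raise ValueError("concentrations must be >= 0")
        for load in LOADS:
            for ctype in COLOR_TYPES:
                if (load, ctype) not in self.p_categorical:
                    raise ValueError(
                        f"p_categorical missing entry for ({load}, {ctype!r})")
            if load not in self.guess_rate_by_load:
                raise ValueError(f"guess_rate_by_load missing load {load}")
        probs = list(self.p_categorical.values()) + \
            list(self.guess_rate_by_load.values()) + [self.ambiguous_bias]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must be in [0, 1]")
        self.pupil_params.validate()
        return self

    @property
    def trials_per_participant(self) -> int:
        return self.trials_per_cell * len(LOADS) * len(COLOR_TYPES)


def generate_category_structure(n_categories: int, jitter: float = 0.0,
                                seed: int | None = None) -> CategorySolution:
    """Ground-truth category boundaries/prototypes, equally spaced + jitter.

    ``jitter`` is the SD (degrees) of Gaussian perturbation applied to the
    equally spaced boundaries.  With ``jitter`` = 0 boundaries sit exactly
    at multiples of 360/n.
    """
    if n_categories < 2:
        raise ValueError("n_categories must be >= 2")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    base = 360.0 / n_categories * np.arange(n_categories)
    boundaries = np.sort((base + rng.normal(0.0, jitter, n_categories)) % 360.0)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("jitter collapsed adjacent boundaries; reduce jitter")
    labels = COLOR_LABELS_7 if n_categories == 7 else None
    return CategorySolution(boundaries=boundaries,
                            prototypes=find_prototypes(boundaries),
                            labels=labels or [])


def simulate_categorization(structure: CategorySolution, n_participants: int,
                            label_noise: float = 0.0,
                            seed: int | None = None) -> pd.DataFrame:
    """Hue-categorization records: every participant labels all 360 hues once.

    With probability ``label_noise`` a response is a uniformly chosen
    *adjacent* category instead of the true one (labeling errors happen at
    category edges, not across the wheel).
    """
    if not 0.0 <= label_noise < 0.5:
        raise ValueError("label_noise must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    hues = np.arange(360)
    true_idx = structure.category_of(hues)
    n_cat = structure.n_categories
    frames = []
    for pp in range(n_participants):
        idx = true_idx.copy()
        noisy = rng.random(360) < label_noise
        shift = np.where(rng.random(360) < 0.5, -1, 1)
        idx = np.where(noisy, (idx + shift) % n_cat, idx)
        frames.append(pd.DataFrame({
            "participant": pp, "hue": hues,
            "label": np.asarray(structure.labels, dtype=object)[idx]}))
    return pd.concat(frames, ignore_index=True)


def _sample_von_mises_deg(rng, center_deg, kappa, size=None):
    if kappa == 0:
        return rng.uniform(0.0, 360.0, size)
    return (np.rad2deg(rng.vonmises(0.0, kappa, size)) + center_deg) % 360.0


def simulate_delayed_estimation(structure: CategorySolution,
                                config: SimConfig,
                                seed: int | None = None) -> pd.DataFrame:
    """Delayed-estimation trials under the mixed continuous/categorical model.

    Each response is, with probability ``guess_rate_by_load[load]``, uniform
    on the circle; otherwise with probability ``p_categorical[load, type]``
    a von Mises draw centered on the prototype of the target's category
    (``kappa_categorical``); otherwise a von Mises draw centered on the
    target itself (``kappa_continuous``).  Ambiguous targets sit exactly on
    a boundary; a categorical encoder picks the upper (counterclockwise)
    flanking category with probability ``ambiguous_bias`` (fair coin by
    default).  Trial order is randomized within participant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_cat = structure.n_categories
    rows = []
    for pp in range(config.n_participants):
        cells = [(load, ctype) for load in LOADS for ctype in COLOR_TYPES
                 for _ in range(config.trials_per_cell)]
        order = rng.permutation(len(cells))
        for trial, ci in enumerate(order):
            load, ctype = cells[ci]
            if ctype == "prototypical":
                cat = int(rng.integers(n_cat))
                target = float(structure.prototypes[cat])
                proto = target
            else:
                bi = int(rng.integers(n_cat))
                target = float(structure.boundaries[bi])
                lower, upper = structure.flanking_categories(bi)
                chosen = upper if rng.random() < config.ambiguous_bias else lower
                proto = float(structure.prototypes[chosen])
            if rng.random() < config.guess_rate_by_load[load]:
                response = float(rng.uniform(0.0, 360.0))
            elif rng.random() < config.p_categorical[(load, ctype)]:
                response = float(_sample_von_mises_deg(
                    rng, proto, config.kappa_categorical))
            else:
                response = float(_sample_von_mises_deg(
                    rng, target, config.kappa_continuous))
            rows.append((pp, trial, load, ctype, target, response))
    df = pd.DataFrame(rows, columns=["participant", "trial", "memory_load",
                                     "color_type", "target_hue", "response_hue"])
    df["response_error"] = circular_distance(
        df["response_hue"].to_numpy(), df["target_hue"].to_numpy())
    return df


def simulate_pupil(trials: pd.DataFrame, spec: PupilEffectSpec,
                   seed: int | None = None) -> list:
    """Pupil traces for every trial in the table.

    trace(t) = baseline (mean + per-trial jitter)
             + load_slope * load            for t >= onset_ms
             + interaction_amplitude[load]  for ambiguous trials,
                                            t inside interaction_window
             + AR(1) noise (stationary SD noise_sd),
    with blinks inserted as contiguous zero runs.
    """
    if len(trials) == 0:
        raise ValueError("trials table is empty")
    spec.validate()
    rng = np.random.default_rng(seed)
    step = 1000.0 / spec.sample_rate_hz
    t0, t1 = spec.trace_span_ms
    times = np.arange(t0, t1, step)
    n_t = times.size
    n_trials = len(trials)

    loads = trials["memory_load"].to_numpy()
    ambiguous = (trials["color_type"].to_numpy() == "ambiguous")
    w0, w1 = spec.interaction_window
    amps = np.array([spec.interaction_amplitude_by_load[ld] for ld in loads])

    signal = np.broadcast_to(
        spec.baseline_mean + np.zeros(n_t), (n_trials, n_t)).copy()
    signal += rng.normal(0.0, spec.baseline_sd_between_trial,
                         n_trials)[:, None]
    signal += (spec.load_slope * loads)[:, None] * (times >= spec.onset_ms)
    signal += (amps * ambiguous)[:, None] * ((times >= w0) & (times < w1))

    if spec.noise_sd > 0:
        innov_sd = spec.noise_sd * np.sqrt(1.0 - spec.noise_ar1 ** 2)
        w = rng.normal(0.0, innov_sd, (n_trials, n_t))
        x0 = rng.normal(0.0, spec.noise_sd, n_trials)
        zi = lfilter_zi([1.0], [1.0, -spec.noise_ar1])
        noise, _ = lfilter([1.0], [1.0, -spec.noise_ar1], w, axis=1,
                           zi=zi[None, :] * x0[:, None])
        signal += noise

    dur_n = max(1, int(round(spec.blink_duration_ms / step)))
    traces = []
    for i, (pp, trial) in enumerate(zip(trials["participant"], trials["trial"])):
        samples = signal[i]
        if spec.blink_rate > 0:
            for _ in range(rng.poisson(spec.blink_rate)):
                s = int(rng.integers(0, n_t))
                samples[s:s + dur_n] = 0.0
        traces.append(TrialPupil(participant=pp, trial=int(trial),
                                 times=times, samples=samples))
    return traces


def simulate_study(config: SimConfig, jitter: float = 0.0):
    """Convenience wrapper: structure + categorization + trials + pupil.

    The single configured seed is expanded into independent per-stage
    streams via ``numpy.random.SeedSequence.spawn``, so each stage is
    reproducible on its own.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed).spawn(4)
    structure = generate_category_structure(config.n_categories, jitter,
                                            seed=ss[0])
    categorization = simulate_categorization(structure, config.n_participants,
                                             seed=ss[1])
    trials = simulate_delayed_estimation(structure, config, seed=ss[2])
    traces = simulate_pupil(trials, config.pupil_params, seed=ss[3])
    return structure, categorization, trials, traces
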