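"""Synthetic trot data with known ground truth.

Two layers of simulation:

* :func:`generate_displacement_trace` builds vertical displacement traces
  for head and pelvis (two oscillations per trot stride, one per diagonal
  step) plus a pastern reference signal (one cycle per stride), with
  configurable per-side extremum offsets that inject exact, known
  per-stride asymmetry differences.
* :func:`generate_population` draws a cohort of horses with trial-level
  parameter summaries for four measurement conditions (straight line on
  hard and soft surface, lunge left/right) together with rider-linked
  sidedness questionnaire answers, under a null or alternative
  rider-perception association.

The waveform is piecewise-cosine between extremum knots that are snapped to
the sample grid, so in the noiseless case the sampled signal attains each
configured extremum value exactly and downstream extraction recovers the
injected asymmetries to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strides import DisplacementTrace

PARAMS = ("hd_min", "hd_max", "pd_min", "pd_max")

#: Default per-parameter probability that a given asymmetric horse's dominant
#: parameter is this one (head min / head max / pelvis min / pelvis max);
#: minimum-difference parameters are the more common triggers.
DEFAULT_PARAM_WEIGHTS = (0.265, 0.190, 0.293, 0.252)

#: Default graded-sidedness answer probabilities (no / mild / moderate /
#: severe) for question 1 of the rider questionnaire.
DEFAULT_Q1_PROBS = (0.085, 0.662, 0.225, 0.028)


class ConfigError(ValueError):
    """Invalid simulator configuration."""


@dataclass
class GaitConfig:
    """Free parameters of the single-trial trace simulator.

    Asymmetry parameters ``asym_*`` are signed trial-level injected
    differences in mm (positive = right-associated, see
    :mod:`equiasym.strides` for the sign convention).
    """

    n_strides: int = 30
    stride_duration_mean: float = 0.7  # s, typical trot
    stride_duration_cv: float = 0.03
    sample_rate: float = 200.0  # Hz
    head_amplitude: float = 25.0  # mm, half peak-to-peak
    pelvis_amplitude: float = 15.0
    asym_hd_min: float = 0.0
    asym_hd_max: float = 0.0
    asym_pd_min: float = 0.0
    asym_pd_max: float = 0.0
    #: stride-to-stride SD (mm) of each injected difference around its
    #: trial-level asym_* value (biological stride variability); scalar or
    #: one value per parameter (hd_min, hd_max, pd_min, pd_max)
    stride_asym_sd: float | tuple = 0.0
    noise_sd: float = 0.0  # mm, Gaussian sensor noise per sample
    outlier_stride_prob: float = 0.0
    outlier_magnitude: float = 20.0  # mm added to one head extremum
    seed: int = 0

    def validate(self) -> None:
        if self.n_strides < 1:
            raise ConfigError("n_strides must be >= 1")
        if self.sample_rate * self.stride_duration_mean < 20:
            raise ConfigError(
                "sample_rate too low: need >= 20 samples per stride"
            )
        if self.head_amplitude <= 0 or self.pelvis_amplitude <= 0:
            raise ConfigError("amplitudes must be positive")
        if not 0.0 <= self.outlier_stride_prob <= 1.0:
            raise ConfigError("outlier_stride_prob must be in [0, 1]")
        if self.noise_sd < 0 or self.stride_duration_cv < 0:
            raise ConfigError("noise_sd and stride_duration_cv must be >= 0")


@dataclass
class SimulatedTrial:
    """Traces plus the ground-truth stride table of one simulated trial."""

    head: DisplacementTrace
    pelvis: DisplacementTrace
    pastern: DisplacementTrace
    pastern_phase: np.ndarray
    truth: pd.DataFrame  # stride_index, start_s, duration_s, four params, is_outlier


def _cosine_segments(n_samples: int, knots: list[tuple[int, float]]) -> np.ndarray:
    """Piecewise-cosine interpolation through (sample_index, value) knots.

    Each segment has zero slope at both ends, so interior knots are the only
    local extrema of the resulting signal.
    """
    z = np.zeros(n_samples)
    for (i1, v1), (i2, v2) in zip(knots[:-1], knots[1:]):
        n = i2 - i1
        ramp = (1.0 - np.cos(np.pi * np.arange(n + 1) / n)) / 2.0
        z[i1 : i2 + 1] = v1 + (v2 - v1) * ramp
    return z


def generate_displacement_trace(config: GaitConfig) -> SimulatedTrial:
    """Simulate one trot trial: head, pelvis and pastern reference traces.

    Each stride contains exactly two head and two pelvic minima and maxima
    (while injected offsets keep the extrema ordered).  In the noiseless
    case the per-stride differences equal the configured ``asym_*`` values
    exactly; a ground-truth stride table is returned for oracle tests.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fs = config.sample_rate

    # per-stride lengths in samples, snapped to the grid
    n_mean = fs * config.stride_duration_mean
    lengths = np.maximum(
        20,
        np.rint(
            n_mean * (1.0 + config.stride_duration_cv
                      * rng.standard_normal(config.n_strides))
        ).astype(int),
    )
    lead = int(np.floor(lengths[0] / 4 + 0.5))
    tail = max(2, int(np.floor(lengths[-1] / 4 + 0.5)))
    starts = lead + np.concatenate(([0], np.cumsum(lengths[:-1])))
    total = lead + int(np.sum(lengths)) + tail
    t = np.arange(total + 1) / fs
    n_samples = total + 1

    def knot_offsets(n: int) -> list[int]:
        return [int(np.floor(n * f / 8 + 0.5)) for f in (1, 3, 5, 7)]

    # base extremum values: order within a stride is
    # max(right), min(right), max(left), min(left)
    def stride_values(amp, a_min, a_max):
        return (
            amp - a_max / 2.0,   # right max
            -amp - a_min / 2.0,  # right min
            amp + a_max / 2.0,   # left max
            -amp + a_min / 2.0,  # left min
        )

    is_outlier = rng.random(config.n_strides) < config.outlier_stride_prob
    outlier_knot = rng.integers(0, 4, config.n_strides)
    outlier_sign = rng.choice([-1.0, 1.0], config.n_strides)
    jitter_sd = np.broadcast_to(
        np.asarray(config.stride_asym_sd, dtype=float), (4,)
    )
    asym_jitter = (
        rng.normal(0.0, jitter_sd, (config.n_strides, 4))
        if np.any(jitter_sd > 0)
        else np.zeros((config.n_strides, 4))
    )

    head_knots: list[tuple[int, float]] = [(0, 0.0)]
    pelvis_knots: list[tuple[int, float]] = [(0, 0.0)]
    truth_rows = []
    for k in range(config.n_strides):
        offs = knot_offsets(lengths[k])
        j_hmin, j_hmax, j_pmin, j_pmax = asym_jitter[k]
        hvals = list(stride_values(config.head_amplitude,
                                   config.asym_hd_min + j_hmin,
                                   config.asym_hd_max + j_hmax))
        pvals = stride_values(config.pelvis_amplitude,
                              config.asym_pd_min + j_pmin,
                              config.asym_pd_max + j_pmax)
        if is_outlier[k]:
            hvals[outlier_knot[k]] += outlier_sign[k] * config.outlier_magnitude
        for o, hv, pv in zip(offs, hvals, pvals):
            head_knots.append((int(starts[k] + o), float(hv)))
            pelvis_knots.append((int(starts[k] + o), float(pv)))
        truth_rows.append(
            {
                "stride_index": k,
                "start_s": starts[k] / fs,
                "duration_s": lengths[k] / fs,
                # left-step minus right-step extremum values
                "hd_min_mm": hvals[3] - hvals[1],
                "hd_max_mm": hvals[2] - hvals[0],
                "pd_min_mm": pvals[3] - pvals[1],
                "pd_max_mm": pvals[2] - pvals[0],
                "is_outlier": bool(is_outlier[k]),
            }
        )
    head_knots.append((n_samples - 1, 0.0))
    pelvis_knots.append((n_samples - 1, 0.0))

    head_z = _cosine_segments(n_samples, head_knots)
    pelvis_z = _cosine_segments(n_samples, pelvis_knots)

    # pastern reference: one sinusoidal cycle per stride, phase 0 at stride
    # start; extended a quarter cycle before the first and after the last
    # stride so every boundary shows an upward zero crossing
    phase = np.empty(n_samples)
    phase[: starts[0]] = (np.arange(starts[0]) - starts[0]) / lengths[0]
    for k in range(config.n_strides):
        sl = slice(int(starts[k]), int(starts[k] + lengths[k]))
        phase[sl] = (np.arange(lengths[k])) / lengths[k] + k
    end = int(starts[-1] + lengths[-1])
    phase[end:] = (np.arange(n_samples - end)) / lengths[-1] + config.n_strides
    pastern_z = 15.0 * np.sin(2.0 * np.pi * phase)

    if config.noise_sd > 0:
        head_z = head_z + rng.normal(0.0, config.noise_sd, n_samples)
        pelvis_z = pelvis_z + rng.normal(0.0, config.noise_sd, n_samples)
        pastern_z = pastern_z + rng.normal(0.0, config.noise_sd, n_samples)

    return SimulatedTrial(
        head=DisplacementTrace("head", t, head_z),
        pelvis=DisplacementTrace("pelvis", t, pelvis_z),
        pastern=DisplacementTrace("pastern", t, pastern_z),
        pastern_phase=phase,
        truth=pd.DataFrame(truth_rows),
    )


@dataclass
class PopulationConfig:
    """Cohort-level simulation parameters.

    Defaults emulate the study conditions of a high-performing sport-horse
    cohort: ~70% prevalence of above-threshold movement asymmetry, a
    discipline mix of roughly half show jumpers with dressage horses and a
    small eventing contingent, more riders than one per horse but fewer
    riders than horses (riders may ride several horses), graded-sidedness
    answer frequencies heavily tilted towards "mild", and sporadic missing
    trials per condition.
    """

    n_horses: int = 71
    n_riders: int = 51
    discipline_mix: dict = field(
        default_factory=lambda: {
            "show_jumping": 0.50, "dressage": 0.38, "eventing": 0.12,
        }
    )
    asymmetry_prevalence: float = 0.70
    #: probability that the dominant above-threshold parameter is each of
    #: (hd_min, hd_max, pd_min, pd_max)
    param_weights: tuple = DEFAULT_PARAM_WEIGHTS
    #: exponential scale (mm) of each exceeding parameter's excess over
    #: its threshold + margin, per parameter (hd_min, hd_max, pd_min,
    #: pd_max); defaults give above-threshold |mean| averages near
    #: 12.4 / 10.1 / 5.4 / 5.5 mm
    excess_scales: tuple = (5.9, 3.6, 1.9, 2.0)
    #: probability that each non-dominant parameter of an asymmetric horse
    #: also exceeds its own threshold (real asymmetric horses typically
    #: trigger more than one parameter)
    secondary_exceed_prob: float = 0.29
    #: baseline SD (mm) of sub-threshold parameter means across horses
    baseline_sd: float = 0.7
    #: stride-level SD of the dominant parameter, as a fraction of its mean
    sd_frac_range: tuple = (0.3, 0.8)
    #: probability that an asymmetric horse shows high inter-stride
    #: variability (SD >= mean), which classifies it symmetric
    high_variability_prob: float = 0.09
    #: additive shift (mm) of pelvic-minimum asymmetry magnitude per
    #: sidedness grade (0 = null: questionnaire independent of asymmetry)
    sidedness_association_effect: float = 0.0
    #: per-rider random shift (mm) of asymmetry magnitude
    rider_effect_sd: float = 1.0
    #: hard/soft surface perturbation SD (mm) of the per-surface true means
    surface_effect_sd: float = 1.2
    #: systematic lunge-direction offset (mm) added to pelvic minimum
    #: difference: negative on the left circle, positive on the right
    lunge_systematic_mm: float = 4.0
    missing_prob_hard: float = 9.0 / 123.0
    missing_prob_soft: float = 12.0 / 123.0
    missing_prob_lunge: float = 2.0 / 123.0
    q1_probs: tuple = DEFAULT_Q1_PROBS
    seed: int = 0

    def validate(self) -> None:
        if self.n_horses < 1 or self.n_riders < 1:
            raise ConfigError("n_horses and n_riders must be >= 1")
        mix = np.array(list(self.discipline_mix.values()), dtype=float)
        if mix.size == 0 or np.any(mix < 0) or abs(mix.sum() - 1.0) > 1e-6:
            raise ConfigError("discipline_mix must be non-negative and sum to 1")
        if not 0.0 <= self.asymmetry_prevalence <= 1.0:
            raise ConfigError("asymmetry_prevalence must be in [0, 1]")
        w = np.asarray(self.param_weights, dtype=float)
        if w.size != 4 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
            raise ConfigError("param_weights must be 4 non-negative fractions summing to 1")


def study_profile(n_horses: int = 123, seed: int = 0, **overrides) -> PopulationConfig:
    """Cohort configuration emulating the high-performing sport-horse study.

    The prevalence parameter here is the probability that a horse truly has
    at least one above-threshold parameter (89/114 on the hard surface:
    79 classified asymmetric plus 10 with high inter-stride variability);
    10/89 of those fail the dispersion condition, so the *classified*
    prevalence lands near the reported 69%.  The secondary-exceedance
    probability reproduces the observed ~1.86 threshold-exceeding
    parameters per asymmetric horse (147 exceedances / 79 horses).
    """
    defaults = dict(
        n_horses=n_horses,
        n_riders=max(1, round(n_horses * 51 / 71)),
        asymmetry_prevalence=89.0 / 114.0,
        high_variability_prob=10.0 / 89.0,
        secondary_exceed_prob=(147.0 / 79.0 - 1.0) / 3.0,
        seed=seed,
    )
    defaults.update(overrides)
    return PopulationConfig(**defaults)


@dataclass
class PopulationTables:
    """Cohort ground truth, trial summaries and questionnaire answers."""

    horses: pd.DataFrame
    trials: pd.DataFrame
    questionnaire: pd.DataFrame


_THRESHOLD = {"hd_min": 6.0, "hd_max": 6.0, "pd_min": 3.0, "pd_max": 3.0}

_STRIDE_COUNTS = {
    "straight_hard": (33.0, 9.7, 16),
    "straight_soft": (31.0, 9.8, 16),
    "lunge_left": (56.0, 20.0, 25),
    "lunge_right": (56.0, 20.0, 25),
}


def _draw_q(rng, options, probs):
    return options[int(rng.choice(len(options), p=probs))]


def generate_population(config: PopulationConfig) -> PopulationTables:
    """Draw a horse cohort with per-condition trial summaries.

    Each horse gets trial summaries (parameter means/SDs, stride counts,
    mean stride duration) for straight-line hard/soft and both lunge
    directions, minus trials dropped by the per-condition missing-data
    probabilities, plus rider-linked questionnaire answers.  Reproducible
    given the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    disciplines = list(config.discipline_mix.keys())
    disc_p = np.array(list(config.discipline_mix.values()), dtype=float)
    disc_p = disc_p / disc_p.sum()

    # rider assignment: every rider gets at least one horse when possible
    rider_of = np.empty(config.n_horses, dtype=int)
    perm = rng.permutation(config.n_horses)
    for i, h in enumerate(perm):
        rider_of[h] = i if i < config.n_riders else rng.integers(0, config.n_riders)
    rider_shift = rng.normal(0.0, config.rider_effect_sd, config.n_riders)

    horse_rows, trial_rows, q_rows = [], [], []
    for h in range(config.n_horses):
        horse_id = f"H{h:04d}"
        discipline = disciplines[int(rng.choice(len(disciplines), p=disc_p))]
        rider = int(rider_of[h])
        is_asym = rng.random() < config.asymmetry_prevalence

        true_mean = {p: rng.normal(0.0, config.baseline_sd) for p in PARAMS}
        primary = ""
        exceeding: list = []
        high_var = False
        if is_asym:
            primary = PARAMS[int(rng.choice(4, p=np.asarray(config.param_weights)))]
            exceeding = [primary] + [
                p for p in PARAMS
                if p != primary and rng.random() < config.secondary_exceed_prob
            ]
            for p in exceeding:
                scale = config.excess_scales[PARAMS.index(p)]
                mag = _THRESHOLD[p] + 0.5 + rng.exponential(scale)
                true_mean[p] = float(rng.choice([-1.0, 1.0])) * mag
            high_var = rng.random() < config.high_variability_prob

        # graded sidedness, then alternative-hypothesis shift of |PDmin|
        grade = _draw_q(rng, ["no", "mild", "moderate", "severe"],
                        list(config.q1_probs))
        g_index = ["no", "mild", "moderate", "severe"].index(grade)
        shift = config.sidedness_association_effect * g_index
        shift += rider_shift[rider]
        sign_pd = np.sign(true_mean["pd_min"]) or 1.0
        new_mag = max(0.1, abs(true_mean["pd_min"]) + shift)
        true_mean["pd_min"] = sign_pd * new_mag

        true_sd = {}
        for p in PARAMS:
            if p in exceeding:
                lo, hi = config.sd_frac_range
                frac = rng.uniform(1.1, 2.0) if high_var else rng.uniform(lo, hi)
                true_sd[p] = frac * abs(true_mean[p])
            else:
                true_sd[p] = rng.uniform(0.8, 2.0)

        missing = {
            "straight_hard": rng.random() < config.missing_prob_hard,
            "straight_soft": rng.random() < config.missing_prob_soft,
        }
        missing_lunge = rng.random() < config.missing_prob_lunge
        missing["lunge_left"] = missing_lunge
        missing["lunge_right"] = missing_lunge

        surface_shift = {
            cond: {p: rng.normal(0.0, config.surface_effect_sd) for p in PARAMS}
            for cond in ("straight_hard", "straight_soft")
        }

        for cond, (n_mu, n_sd, n_min) in _STRIDE_COUNTS.items():
            n = max(n_min, int(np.rint(rng.normal(n_mu, n_sd))))
            dur = rng.normal(0.70, 0.04) + (0.03 if cond.startswith("lunge") else 0.0)
            means, sds = {}, {}
            for p in PARAMS:
                mu = true_mean[p]
                if cond in surface_shift:
                    mu = mu + surface_shift[cond][p]
                if cond == "lunge_left" and p == "pd_min":
                    mu = mu - config.lunge_systematic_mm
                if cond == "lunge_right" and p == "pd_min":
                    mu = mu + config.lunge_systematic_mm
                sd = max(0.2, true_sd[p])
                means[p] = mu + rng.normal(0.0, sd / np.sqrt(n))
                sds[p] = sd * np.sqrt(rng.chisquare(n - 1) / (n - 1))
            if missing[cond]:
                continue
            trial_rows.append(
                {
                    "horse_id": horse_id,
                    "condition": cond,
                    "n_strides": n,
                    **{f"mean_{p}": means[p] for p in PARAMS},
                    **{f"sd_{p}": sds[p] for p in PARAMS},
                    "mean_stride_duration": dur,
                }
            )

        horse_rows.append(
            {
                "horse_id": horse_id,
                "discipline": discipline,
                "rider_id": f"R{rider:03d}",
                "is_asymmetric": is_asym,
                "primary_param": primary,
                "high_variability": high_var,
                **{f"true_{p}": true_mean[p] for p in PARAMS},
            }
        )
        q_rows.append(
            {
                "horse_id": horse_id,
                "rider_id": f"R{rider:03d}",
                "q1_sidedness": grade,
                "q2_weak_hind": _draw_q(
                    rng, ["no", "left", "right", "na"], [0.38, 0.296, 0.296, 0.028]
                ),
                "q3_rein": _draw_q(
                    rng, ["no", "left", "right", "na"], [0.31, 0.352, 0.338, 0.0]
                ),
                "q4_drift": _draw_q(
                    rng, ["no", "left", "right", "na"], [0.451, 0.254, 0.281, 0.014]
                ),
                "q5_rider_side": _draw_q(
                    rng, ["no", "left", "right", "na"], [0.451, 0.24, 0.309, 0.0]
                ),
            }
        )

    return PopulationTables(
        horses=pd.DataFrame(horse_rows),
        trials=pd.DataFrame(trial_rows),
        questionnaire=pd.DataFrame(q_rows),
    )
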