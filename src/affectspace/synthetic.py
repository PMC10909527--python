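"""Synthetic trial tables with a planted autonomic-subjective factor structure.

The generator emulates a picture-viewing psychophysiology study: each of
``n_participants`` views ``n_stimuli`` normed emotional images once, yielding
per-trial subjective valence/arousal ratings (-10..+10 sliders), a
baseline-corrected pupil diameter (mm), a phasic skin-conductance amplitude
(uS) and a heart-rate change score (bpm, post minus pre, so deceleration is
negative).

Observed variables follow a linear two-factor latent model:

* ``f1`` — a shared affect factor loading on every variable.  Its sign
  convention is "negative-arousing": valence loads negatively, arousal
  positively.  A configurable share of ``f1`` variance is carried by the
  stimulus (its normative affect), the rest is trial-specific.
* ``f2`` — an orienting factor loading on the autonomic variables only,
  capturing nonspecific covariance between pupil, SCR and HR that subjective
  experience does not track.

On top of the factors each variable receives crossed participant and stimulus
random intercepts and a residual; pupil additionally receives a brightness
confound and a valence-by-arousal interaction, and SCR is kept nonnegative by
exponentiating its Gaussian latent (log-normal amplitudes, preserving the
monotone link to the factors).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    ACTIVE_VARS,
    AROUSAL_CATEGORY,
    AROUSAL_LEVELS,
    BRIGHTNESS,
    PARTICIPANT,
    STIMULUS,
    VALENCE_CATEGORY,
    VALENCE_LEVELS,
)

__all__ = [
    "GeneratorParams",
    "RawSignalParams",
    "ParameterizationError",
    "generate_stimuli",
    "generate_trial_table",
    "generate_raw_signals",
    "simulate",
]


class ParameterizationError(ValueError):
    """Raised when generator parameters imply an invalid covariance model."""


def _var_dict(valence=0.0, arousal=0.0, pupil=0.0, scr=0.0, hr=0.0) -> dict[str, float]:
    return {"valence": valence, "arousal": arousal, "pupil": pupil, "scr": scr, "hr": hr}


@dataclass
class RawSignalParams:
    """Shape and noise parameters for the optional raw-signal mode.

    Pupil series are emitted at 150 Hz, SCR at 10 Hz and HR as a slow pre/post
    step series; every event-related waveform is scaled on the actual sample
    grid so that, at zero noise, feature extraction recovers the trial-table
    feature exactly.
    """

    pupil_rate_hz: float = 150.0
    scr_rate_hz: float = 10.0
    hr_rate_hz: float = 1.0
    pupil_span_s: tuple[float, float] = (-1.5, 6.0)
    scr_span_s: tuple[float, float] = (-1.0, 8.0)
    hr_span_s: tuple[float, float] = (-4.0, 6.0)
    pupil_baseline_mm: float = 5.0
    pupil_noise_sd: float = 0.02
    #: expected blink count per trial (Poisson); gaps of 100-400 ms straddle
    #: the 150 ms interpolation limit on both sides.
    blink_rate: float = 1.0
    blink_duration_s: tuple[float, float] = (0.1, 0.4)
    scr_tonic_us: float = 2.0
    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.0
    scr_latency_s: tuple[float, float] = (1.0, 2.5)
    scr_noise_sd: float = 0.002
    hr_baseline_bpm: float = 70.0
    hr_pre_sd: float = 3.0
    hr_noise_sd: float = 0.0


@dataclass
class GeneratorParams:
    """Parameters of the planted latent model, on the standardized scale.

    Factor loadings, random-intercept SDs and residual SDs are expressed for
    unit-variance latents; ``rating_scale``/``pupil_scale``/``hr_scale`` and
    the SCR log-normal parameters map the standardized latents onto slider
    points, millimetres, microsiemens and beats per minute.
    """

    n_participants: int = 51
    n_stimuli: int = 56

    # -- latent structure ---------------------------------------------------
    f1_loadings: dict[str, float] = field(
        default_factory=lambda: _var_dict(valence=-0.85, arousal=0.85, pupil=0.57, scr=0.25, hr=-0.49)
    )
    f2_loadings: dict[str, float] = field(
        default_factory=lambda: _var_dict(pupil=0.38, scr=0.6, hr=0.61)
    )
    #: coefficients of the (z-valence x z-arousal) product on pupil / SCR
    interaction: dict[str, float] = field(
        default_factory=lambda: {"pupil": 0.16, "scr": -0.02}
    )
    brightness_beta: float = -0.96
    participant_sd: dict[str, float] = field(
        default_factory=lambda: _var_dict(0.35, 0.35, 0.3, 0.3, 0.3)
    )
    stimulus_sd: dict[str, float] = field(
        default_factory=lambda: _var_dict(0.25, 0.25, 0.25, 0.25, 0.25)
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: _var_dict(0.45, 0.45, 0.44, 0.57, 0.42)
    )
    #: residual correlation between the two subjective ratings, beyond f1
    valence_arousal_cor: float = -0.15
    #: share of f1 variance carried by the stimulus's normative affect
    stimulus_affect_share: float = 0.4
    #: weight of normative arousal (vs negated valence) in the stimulus affect
    affect_arousal_weight: float = 0.5

    # -- stimulus norms (nine-point scales) ---------------------------------
    norm_valence_mean: float = 5.07
    norm_valence_sd: float = 1.92
    norm_arousal_mean: float = 4.66
    norm_arousal_sd: float = 1.19
    norm_cor: float = -0.3
    valence_cuts: tuple[float, float] = (4.0, 6.0)
    arousal_cuts: tuple[float, float] = (4.0, 5.3)

    # -- output scales ------------------------------------------------------
    rating_scale: float = 3.0
    pupil_scale: float = 0.3
    pupil_offset: float = 0.05
    scr_log_mean: float = -2.0
    scr_log_scale: float = 0.5
    hr_scale: float = 2.5
    hr_offset: float = -0.3

    missing_rate: float = 0.0
    keep_latent: bool = False
    seed: int | None = None
    signal: RawSignalParams = field(default_factory=RawSignalParams)

    def validate(self) -> None:
        if self.n_participants < 1 or self.n_stimuli < 3:
            raise ParameterizationError("need n_participants >= 1 and n_stimuli >= 3")
        for name in ("participant_sd", "stimulus_sd", "residual_sd"):
            vals = getattr(self, name)
            if any(v < 0 for v in vals.values()):
                raise ParameterizationError(f"{name} must be nonnegative")
        if any(v <= 0 for v in self.residual_sd.values()):
            raise ParameterizationError("residual_sd must be positive")
        for name in ("valence_arousal_cor", "norm_cor"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ParameterizationError(f"{name} must lie strictly inside (-1, 1)")
        if not 0.0 <= self.stimulus_affect_share <= 1.0:
            raise ParameterizationError("stimulus_affect_share must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ParameterizationError("missing_rate must lie in [0, 1)")
        # the exp-quadratic SCR moments exist only for a sufficiently small
        # interaction coefficient; delegate the PD check to the moment code
        from . import implied

        implied.implied_covariance(self)

    @classmethod
    def null(cls, **overrides) -> "GeneratorParams":
        """Parameters with every cross-variable coupling removed.

        All factor loadings, interactions, the brightness effect and the
        residual valence-arousal correlation are zero, so the five observed
        columns are mutually independent (the calibration null).  Variance
        components keep their default magnitudes.
        """
        p = cls(
            f1_loadings=_var_dict(),
            f2_loadings=_var_dict(),
            interaction={"pupil": 0.0, "scr": 0.0},
            brightness_beta=0.0,
            valence_arousal_cor=0.0,
            **overrides,
        )
        return p

    # latent standard deviations of the subjective variables, needed to form
    # the standardized interaction regressor consistently everywhere
    def subjective_latent_sd(self, var: str) -> float:
        return float(
            np.sqrt(
                self.f1_loadings[var] ** 2
                + self.participant_sd[var] ** 2
                + self.stimulus_sd[var] ** 2
                + self.residual_sd[var] ** 2
            )
        )


def _categorize(values: np.ndarray, cuts: tuple[float, float], labels: tuple[str, ...]) -> np.ndarray:
    lo, hi = cuts
    if not lo < hi:
        raise ParameterizationError("category cut points must be increasing")
    out = np.where(values < lo, labels[0], np.where(values < hi, labels[1], labels[2]))
    return out


def generate_stimuli(
    n_stimuli: int = 56,
    seed: int | None = None,
    cut_points: tuple[float, float] | None = None,
    params: GeneratorParams | None = None,
) -> pd.DataFrame:
    """Draw a normed stimulus set.

    Normative valence and arousal live on bounded nine-point scales, so they
    are drawn from moment-matched Beta distributions on [1, 9] (exact target
    mean and SD, no boundary censoring) coupled through a Gaussian copula
    with the configured norm correlation.  Category labels are a
    deterministic function of the cut points, and brightness is an
    independent standardized luminance covariate.

    Returns a DataFrame with columns ``stimulus``, ``norm_valence``,
    ``norm_arousal``, ``valence_category``, ``arousal_category``,
    ``brightness``.
    """
    from scipy import stats

    if n_stimuli < 3:
        raise ParameterizationError("need at least 3 stimuli (one per category achievable)")
    p = params or GeneratorParams()
    vcuts = cut_points if cut_points is not None else p.valence_cuts
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_stimuli, 2))
    zv = z[:, 0]
    za = p.norm_cor * z[:, 0] + np.sqrt(1.0 - p.norm_cor**2) * z[:, 1]

    def beta_from_moments(mean, sd):
        m = (mean - 1.0) / 8.0
        v = (sd / 8.0) ** 2
        if not 0 < v < m * (1 - m):
            raise ParameterizationError("norm mean/sd not achievable on the [1, 9] scale")
        s = m * (1 - m) / v - 1.0
        return m * s, (1 - m) * s

    av, bv = beta_from_moments(p.norm_valence_mean, p.norm_valence_sd)
    aa, ba = beta_from_moments(p.norm_arousal_mean, p.norm_arousal_sd)
    norm_v = 1.0 + 8.0 * stats.beta.ppf(stats.norm.cdf(zv), av, bv)
    norm_a = 1.0 + 8.0 * stats.beta.ppf(stats.norm.cdf(za), aa, ba)
    brightness = rng.standard_normal(n_stimuli)  # independent of norms by construction
    return pd.DataFrame(
        {
            STIMULUS: [f"S{i + 1:03d}" for i in range(n_stimuli)],
            "norm_valence": norm_v,
            "norm_arousal": norm_a,
            VALENCE_CATEGORY: _categorize(norm_v, vcuts, VALENCE_LEVELS),
            AROUSAL_CATEGORY: _categorize(norm_a, p.arousal_cuts, AROUSAL_LEVELS),
            BRIGHTNESS: brightness,
        }
    )


def _stimulus_affect(stimuli: pd.DataFrame, params: GeneratorParams) -> np.ndarray:
    """Standardized per-stimulus affect score driving the shared factor.

    Built from the population-standardized norms as ``-z(valence)`` blended
    with ``+z(arousal)`` (negative-arousing convention), then rescaled to unit
    population variance using the configured norm moments.
    """
    zv = (stimuli["norm_valence"].to_numpy() - params.norm_valence_mean) / params.norm_valence_sd
    za = (stimuli["norm_arousal"].to_numpy() - params.norm_arousal_mean) / params.norm_arousal_sd
    w = params.affect_arousal_weight
    raw = -zv + w * za
    var = 1.0 + w**2 - 2.0 * w * params.norm_cor
    return raw / np.sqrt(var)


def generate_trial_table(
    stimuli: pd.DataFrame,
    params: GeneratorParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one long-format trial table from the planted latent model.

    One row per participant-stimulus pair (minus optional MCAR missing
    trials).  When ``params.keep_latent`` is set the factor scores ``f1`` and
    ``f2`` are retained as extra columns for recovery tests.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    P, S = params.n_participants, len(stimuli)
    n = P * S
    varnames = list(ACTIVE_VARS)

    part_idx = np.repeat(np.arange(P), S)
    stim_idx = np.tile(np.arange(S), P)

    u = {v: rng.normal(0.0, params.participant_sd[v], P)[part_idx] for v in varnames}
    s = {v: rng.normal(0.0, params.stimulus_sd[v], S)[stim_idx] for v in varnames}

    affect = _stimulus_affect(stimuli, params)[stim_idx]
    w_stim = params.stimulus_affect_share
    f1 = np.sqrt(w_stim) * affect + np.sqrt(1.0 - w_stim) * rng.standard_normal(n)
    f2 = rng.standard_normal(n)

    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    rho = params.valence_arousal_cor
    e = {
        "valence": params.residual_sd["valence"] * z1,
        "arousal": params.residual_sd["arousal"] * (rho * z1 + np.sqrt(1.0 - rho**2) * z2),
        "pupil": rng.normal(0.0, params.residual_sd["pupil"], n),
        "scr": rng.normal(0.0, params.residual_sd["scr"], n),
        "hr": rng.normal(0.0, params.residual_sd["hr"], n),
    }

    a1, a2 = params.f1_loadings, params.f2_loadings
    val_lat = a1["valence"] * f1 + u["valence"] + s["valence"] + e["valence"]
    aro_lat = a1["arousal"] * f1 + u["arousal"] + s["arousal"] + e["arousal"]
    prod = (val_lat / params.subjective_latent_sd("valence")) * (
        aro_lat / params.subjective_latent_sd("arousal")
    )

    bright = stimuli[BRIGHTNESS].to_numpy()[stim_idx]
    pup_lat = (
        a1["pupil"] * f1
        + a2["pupil"] * f2
        + params.interaction["pupil"] * prod
        + params.brightness_beta * bright
        + u["pupil"]
        + s["pupil"]
        + e["pupil"]
    )
    scr_lat = (
        a1["scr"] * f1
        + a2["scr"] * f2
        + params.interaction["scr"] * prod
        + u["scr"]
        + s["scr"]
        + e["scr"]
    )
    hr_lat = a1["hr"] * f1 + a2["hr"] * f2 + u["hr"] + s["hr"] + e["hr"]

    table = pd.DataFrame(
        {
            PARTICIPANT: [f"P{i + 1:02d}" for i in part_idx],
            STIMULUS: stimuli[STIMULUS].to_numpy()[stim_idx],
            VALENCE_CATEGORY: stimuli[VALENCE_CATEGORY].to_numpy()[stim_idx],
            AROUSAL_CATEGORY: stimuli[AROUSAL_CATEGORY].to_numpy()[stim_idx],
            "valence": np.clip(params.rating_scale * val_lat, -10.0, 10.0),
            "arousal": np.clip(params.rating_scale * aro_lat, -10.0, 10.0),
            "pupil": params.pupil_offset + params.pupil_scale * pup_lat,
            "scr": np.exp(params.scr_log_mean + params.scr_log_scale * scr_lat),
            "hr": params.hr_offset + params.hr_scale * hr_lat,
            BRIGHTNESS: bright,
            "norm_valence": stimuli["norm_valence"].to_numpy()[stim_idx],
            "norm_arousal": stimuli["norm_arousal"].to_numpy()[stim_idx],
        }
    )
    if params.keep_latent:
        table["f1"] = f1
        table["f2"] = f2
    if params.missing_rate > 0.0:
        keep = rng.random(n) >= params.missing_rate
        table = table.loc[keep].reset_index(drop=True)
    return table


def simulate(params: GeneratorParams, seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (stimuli, trial_table) from a single seed."""
    root = np.random.default_rng(params.seed if seed is None else seed)
    s_stim, s_table = root.integers(0, 2**31 - 1, size=2)
    stimuli = generate_stimuli(params.n_stimuli, seed=int(s_stim), params=params)
    table = generate_trial_table(stimuli, params, seed=int(s_table))
    return stimuli, table


# ---------------------------------------------------------------------------
# raw-signal mode
# ---------------------------------------------------------------------------


def _pupil_shapes(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Event-related dilation and brightness-step shapes on a sample grid."""
    dil = np.where(t > 0.2, 1.0 - np.exp(-np.maximum(t - 0.2, 0.0) / 0.5), 0.0)
    step = np.where(t > 0.1, 1.0 - np.exp(-np.maximum(t - 0.1, 0.0) / 0.3), 0.0)
    return dil, step


def generate_raw_signals(
    trial_table: pd.DataFrame,
    params: GeneratorParams,
    seed: int | None = None,
):
    """Back-generate per-trial raw signals from trial-table features.

    For every trial three recordings are produced (pupil at 150 Hz, SCR at
    10 Hz, HR as a pre/post step series), each carrying a single stimulus
    onset event at t = 0.  Waveform amplitudes are solved on the discrete
    sample grid so that the feature-extraction pipeline recovers the table's
    pupil/SCR/HR values exactly in the zero-noise, zero-blink limit.

    Returns a list of :class:`~affectspace.signals.SignalRecording`.
    """
    from .signals import SignalRecording  # local import to avoid a cycle

    sp = params.signal
    for name in ("pupil_rate_hz", "scr_rate_hz", "hr_rate_hz"):
        if getattr(sp, name) <= 0:
            raise ParameterizationError(f"{name} must be positive")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    recordings: list[SignalRecording] = []

    t_pup = np.arange(sp.pupil_span_s[0], sp.pupil_span_s[1], 1.0 / sp.pupil_rate_hz)
    t_scr = np.arange(sp.scr_span_s[0], sp.scr_span_s[1], 1.0 / sp.scr_rate_hz)
    t_hr = np.arange(sp.hr_span_s[0], sp.hr_span_s[1], 1.0 / sp.hr_rate_hz)

    dil_shape, step_shape = _pupil_shapes(t_pup)
    from .signals import window_mask

    base_mask = window_mask(t_pup, -1.0, 1.0)
    stim_mask = window_mask(t_pup, 0.0, 6.0)
    d_dil = dil_shape[stim_mask].mean() - dil_shape[base_mask].mean()
    d_step = step_shape[stim_mask].mean() - step_shape[base_mask].mean()

    for row in trial_table.itertuples(index=False):
        trial_id = f"{getattr(row, PARTICIPANT)}_{getattr(row, STIMULUS)}"
        meta = {
            "participant": getattr(row, PARTICIPANT),
            "stimulus": getattr(row, STIMULUS),
        }

        # pupil: baseline + brightness-driven step + dilation solving the
        # baseline-corrected window mean to equal the table feature
        b_amp = params.pupil_scale * params.brightness_beta * getattr(row, BRIGHTNESS)
        a_dil = (row.pupil - b_amp * d_step) / d_dil
        v = (
            sp.pupil_baseline_mm
            + a_dil * dil_shape
            + b_amp * step_shape
            + (rng.normal(0.0, sp.pupil_noise_sd, t_pup.size) if sp.pupil_noise_sd > 0 else 0.0)
        )
        valid = np.ones(t_pup.size, dtype=bool)
        if sp.blink_rate > 0:
            for _ in range(rng.poisson(sp.blink_rate)):
                onset = rng.uniform(t_pup[0], t_pup[-1])
                dur = rng.uniform(*sp.blink_duration_s)
                gap = (t_pup >= onset) & (t_pup < onset + dur)
                v = np.where(gap, 0.0, v)  # blink: pupil reads as invalid (0 mm)
        recordings.append(
            SignalRecording(
                modality="pupil",
                sampling_rate=sp.pupil_rate_hz,
                times=t_pup.copy(),
                values=np.asarray(v, dtype=float),
                valid=valid,
                events=[(trial_id, 0.0)],
                meta=dict(meta),
            )
        )

        # SCR: tonic + one bi-exponential phasic wave, peak scaled on-grid
        v = np.full(t_scr.size, sp.scr_tonic_us)
        if row.scr > 0:
            t0 = rng.uniform(*sp.scr_latency_s)
            rel = t_scr - t0
            wave = np.where(
                rel > 0,
                np.exp(-np.maximum(rel, 0.0) / sp.scr_decay_s)
                - np.exp(-np.maximum(rel, 0.0) / sp.scr_rise_s),
                0.0,
            )
            peak = wave.max()
            if peak > 0:
                v = v + (row.scr / peak) * wave
        if sp.scr_noise_sd > 0:
            v = v + rng.normal(0.0, sp.scr_noise_sd, t_scr.size)
        recordings.append(
            SignalRecording(
                modality="scr",
                sampling_rate=sp.scr_rate_hz,
                times=t_scr.copy(),
                values=np.asarray(v, dtype=float),
                valid=np.ones(t_scr.size, dtype=bool),
                events=[(trial_id, 0.0)],
                meta=dict(meta),
            )
        )

        # HR: constant pre level, post level shifted by the change score
        pre = sp.hr_baseline_bpm + rng.normal(0.0, sp.hr_pre_sd)
        post = pre + row.hr
        v = np.where(t_hr < 0.0, pre, post)
        if sp.hr_noise_sd > 0:
            v = v + rng.normal(0.0, sp.hr_noise_sd, t_hr.size)
        recordings.append(
            SignalRecording(
                modality="hr",
                sampling_rate=sp.hr_rate_hz,
                times=t_hr.copy(),
                values=np.asarray(v, dtype=float),
                valid=np.ones(t_hr.size, dtype=bool),
                events=[(trial_id, 0.0)],
                meta=dict(meta),
            )
        )
    return recordings


def params_to_dict(params: GeneratorParams) -> dict:
    """Serialize parameters to a plain JSON/YAML-ready dict."""
    return dataclasses.asdict(params)


def params_from_dict(d: dict) -> GeneratorParams:
    d = dict(d)
    if "signal" in d and isinstance(d["signal"], dict):
        sig = dict(d["signal"])
        for k, v in list(sig.items()):
            if isinstance(v, list):
                sig[k] = tuple(v)
        d["signal"] = RawSignalParams(**sig)
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return GeneratorParams(**d)
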