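"""Synthetic trial-level data for the visuo-tactile peripersonal-space task.

The generator emulates a multisensory interaction experiment: participants
respond vocally to a 100 ms vibrotactile target while a task-irrelevant
visual stimulus looms toward them along a LED strip.  Each of the 9
Light-Location x Tactile-Location conditions contains visuo-tactile (VT)
trials at five distances, tactile-only (TO) trials delivered at the delays
matching those distances, and visual-only catch trials.

Reaction times are generated from a Gaussian hierarchical linear model: a
grand mean, fixed condition offsets (a distance profile for VT trials, a
delay profile for TO trials), per-subject random effects (intercept plus
Light/Tactile offsets), and residual trial noise, optionally contaminated
with additive outliers and missing responses.

Three generative regimes mirror the hypotheses the analysis pipeline
discriminates: H0 (TO trials share the VT linear predictor), H1 (TO trials
have a single constant mean) and H2 (TO trials follow their own
delay-dependent profile, bell-shaped by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DesignConfig",
    "EffectConfig",
    "DELAY_LOOKUP_S",
    "DISTANCE_CM",
    "TRIAL_COLUMNS",
    "distance_to_delay",
    "bell_profile",
    "step_profile",
    "draw_subject_effects",
    "generate_dataset",
    "generate_under_hypothesis",
    "write_trials_csv",
    "read_trials_csv",
]

#: Distance level -> centimetres along the strip (D1 nearest the body).
DISTANCE_CM: dict[str, float] = {"D1": 1.0, "D2": 49.0, "D3": 98.0, "D4": 147.0, "D5": 196.0}

#: Distance level -> tactile-delivery delay in seconds.  These are the
#: apparatus' printed values; D1 and D2 deviate slightly from the nominal
#: (strip_length - d)/speed kinematics (see :func:`distance_to_delay`), and
#: the lookup is kept verbatim rather than recomputed.
DELAY_LOOKUP_S: dict[str, float] = {
    "D1": 6.125,
    "D2": 4.564,
    "D3": 3.063,
    "D4": 1.531,
    "D5": 0.0,
}

#: Canonical column order of the long-format trial table.
TRIAL_COLUMNS = [
    "participant",
    "light_location",
    "tactile_location",
    "trial_type",
    "distance",
    "rt_ms",
    "responded",
]

HYPOTHESES = ("H0", "H1", "H2")


class ConfigurationError(ValueError):
    """Raised when a design or effect configuration is internally inconsistent."""


def distance_to_delay(distance_cm: float, speed: float = 32.0, strip_length: float = 196.0) -> float:
    """Delay (s) until a stimulus looming at ``speed`` covers the strip.

    The looming stimulus starts at the far end of the strip and travels at a
    constant velocity, so the tactile stimulus paired with position
    ``distance_cm`` (measured from the body) is delivered after
    ``(strip_length - distance_cm) / speed`` seconds.

    Parameters
    ----------
    distance_cm
        Position on the strip, 0 (at the body) to ``strip_length``.
    speed
        Looming velocity in cm/s; must be positive.
    strip_length
        Strip length in cm.
    """
    if speed <= 0:
        raise ValueError(f"looming speed must be positive, got {speed}")
    if not 0 <= distance_cm <= strip_length:
        raise ValueError(f"distance {distance_cm} outside [0, {strip_length}] cm")
    return (strip_length - distance_cm) / speed


def bell_profile(
    distances: Sequence[str] = ("D1", "D2", "D3", "D4", "D5"),
    amplitude: float = 25.0,
    peak: str = "D3",
    width: float = 1.0,
) -> dict[str, float]:
    """Gaussian-bump delay profile peaking at ``peak`` (ms offsets).

    Models the non-monotonic tactile-only slowing: short delays benefit from
    the alerting sound, long delays from accumulated stimulus expectancy, so
    responses are slowest at intermediate delays.
    """
    idx = {d: i for i, d in enumerate(distances)}
    p = idx[peak]
    return {d: amplitude * float(np.exp(-((i - p) ** 2) / (2 * width**2))) for d, i in idx.items()}


def step_profile(
    lights: Sequence[str],
    distances: Sequence[str] = ("D1", "D2", "D3", "D4", "D5"),
    boundary_after: str | Mapping[str, str] = "D3",
    step: float = 25.0,
) -> dict[tuple[str, str], float]:
    """VT distance profile with a single step at the PPS boundary.

    Distances up to and including ``boundary_after`` (the near side, inside
    peripersonal space) get a ``-step`` ms facilitation; farther distances
    get 0.  ``boundary_after`` may be a single level or a per-light mapping,
    so different body parts can carry different boundaries.
    """
    order = list(distances)
    out: dict[tuple[str, str], float] = {}
    for light in lights:
        b = boundary_after[light] if isinstance(boundary_after, Mapping) else boundary_after
        cut = order.index(b)
        for i, d in enumerate(order):
            out[(light, d)] = -step if i <= cut else 0.0
    return out


@dataclass(frozen=True)
class DesignConfig:
    """Experimental design: factor levels, trial counts and geometry."""

    n_participants: int = 40
    light_levels: tuple[str, ...] = ("face", "hand", "foot")
    tactile_levels: tuple[str, ...] = ("face", "hand", "foot")
    distances: tuple[str, ...] = ("D1", "D2", "D3", "D4", "D5")
    distance_cm: Mapping[str, float] = field(default_factory=lambda: dict(DISTANCE_CM))
    delays_s: Mapping[str, float] = field(default_factory=lambda: dict(DELAY_LOOKUP_S))
    reps_vt_per_distance: int = 6
    reps_to_per_distance: int = 3
    n_catch: int = 3
    looming_speed: float = 32.0
    strip_length: float = 196.0

    def __post_init__(self) -> None:
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        if min(self.reps_vt_per_distance, self.reps_to_per_distance, self.n_catch) < 0:
            raise ConfigurationError("trial counts must be >= 0")
        missing = [d for d in self.distances if d not in self.distance_cm or d not in self.delays_s]
        if missing:
            raise ConfigurationError(f"distance labels without cm/delay values: {missing}")
        cm = [self.distance_cm[d] for d in self.distances]
        if any(b <= a for a, b in zip(cm, cm[1:])):
            raise ConfigurationError("distances must be strictly increasing in cm")
        delays = [self.delays_s[d] for d in self.distances]
        if any(b > a for a, b in zip(delays, delays[1:])):
            raise ConfigurationError("delays must be non-increasing with distance")

    @property
    def n_conditions(self) -> int:
        return len(self.light_levels) * len(self.tactile_levels)

    @property
    def trials_per_condition(self) -> int:
        n_d = len(self.distances)
        return n_d * self.reps_vt_per_distance + n_d * self.reps_to_per_distance + self.n_catch

    @classmethod
    def from_dict(cls, d: Mapping) -> "DesignConfig":
        d = dict(d)
        for key in ("light_levels", "tactile_levels", "distances"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class EffectConfig:
    """Generative effect sizes (ms scale) and contamination rates.

    ``delay_profile`` is the tactile-only offset per delay (bell-shaped by
    default, ~25 ms peak — the magnitude of the slowing observed mid-trial
    in this paradigm); ``distance_profile`` maps (light, distance) to the VT
    offset (a 25 ms facilitation step inside the boundary by default).
    ``to_offset`` is the constant TO-vs-VT level difference used when
    tactile-only times are generated as a single constant (regime H1).
    """

    grand_mean: float = 355.0
    delay_profile: Mapping[str, float] = field(default_factory=bell_profile)
    distance_profile: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: step_profile(("face", "hand", "foot"))
    )
    tactile_location_offsets: Mapping[str, float] = field(default_factory=dict)
    to_offset: float = 20.0
    subject_sd: float = 60.0
    random_effect_sd: float = 8.0
    random_effect_cov: np.ndarray | None = None
    residual_sd: float = 40.0
    outlier_rate: float = 0.02
    outlier_shift: float = 600.0
    miss_rate: float = 0.01
    catch_fa_rate: float = 0.01
    noise: str = "normal"

    def __post_init__(self) -> None:
        if min(self.subject_sd, self.random_effect_sd, self.residual_sd) < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        for r in (self.outlier_rate, self.miss_rate, self.catch_fa_rate):
            if not 0 <= r <= 1:
                raise ConfigurationError(f"rate {r} outside [0, 1]")
        if self.random_effect_cov is not None:
            cov = np.asarray(self.random_effect_cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ConfigurationError("random_effect_cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() < -1e-9:
                raise ConfigurationError("random_effect_cov must be positive semi-definite")
        if self.noise not in ("normal", "lognormal"):
            raise ConfigurationError("noise must be 'normal' or 'lognormal'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "EffectConfig":
        d = dict(d)
        if "distance_profile" in d and d["distance_profile"] is not None:
            prof = d["distance_profile"]
            if prof and not isinstance(next(iter(prof)), tuple):
                # YAML cannot key on tuples; accept {"light:distance": value}.
                prof = {tuple(k.split(":")): v for k, v in prof.items()}
            d["distance_profile"] = prof
        if "random_effect_cov" in d and d["random_effect_cov"] is not None:
            d["random_effect_cov"] = np.asarray(d["random_effect_cov"], dtype=float)
        return cls(**d)


def _subject_effect_cov(design: DesignConfig, effects: EffectConfig) -> np.ndarray:
    """Covariance of the per-subject effect vector (intercept, light, tactile).

    The vector is (1 + L + T)-dimensional with the light and tactile blocks
    constrained to sum to zero across levels; the returned covariance is for
    the unconstrained representation actually drawn (intercept plus the
    free level offsets of each factor).
    """
    q = 1 + (len(design.light_levels) - 1) + (len(design.tactile_levels) - 1)
    if effects.random_effect_cov is not None:
        cov = np.asarray(effects.random_effect_cov, dtype=float)
        if cov.shape != (q, q):
            raise ConfigurationError(f"random_effect_cov must be {q}x{q}, got {cov.shape}")
        return cov
    cov = np.eye(q) * effects.random_effect_sd**2
    cov[0, 0] = effects.subject_sd**2
    return cov


def draw_subject_effects(
    n_subjects: int, design: DesignConfig, effects: EffectConfig, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, dict[str, np.ndarray]]]:
    """Draw per-subject random effects.

    Returns the raw (n_subjects, q) effect matrix (intercept + free light
    levels + free tactile levels) and per-factor level lookups with the
    sum-to-zero last level reconstructed.
    """
    cov = _subject_effect_cov(design, effects)
    z = rng.standard_normal((n_subjects, cov.shape[0]))
    if np.any(cov):
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
        raw = z @ L.T
    else:  # exact noiseless limit
        raw = np.zeros_like(z)
    nl = len(design.light_levels) - 1
    light = raw[:, 1 : 1 + nl]
    tact = raw[:, 1 + nl :]
    lookup = {
        "intercept": {"": raw[:, 0]},
        "light": _levels_lookup(design.light_levels, light),
        "tactile": _levels_lookup(design.tactile_levels, tact),
    }
    return raw, lookup


def _levels_lookup(levels: Sequence[str], free: np.ndarray) -> dict[str, np.ndarray]:
    out = {lev: free[:, i] for i, lev in enumerate(levels[:-1])}
    out[levels[-1]] = -free.sum(axis=1)
    return out


def _resid(rng: np.random.Generator, n: int, effects: EffectConfig) -> np.ndarray:
    if effects.noise == "lognormal" and effects.residual_sd > 0:
        # multiplicative noise with approximately matched sd around 0
        s = effects.residual_sd / max(effects.grand_mean, 1.0)
        return effects.grand_mean * (np.exp(rng.normal(0.0, s, n) - s**2 / 2) - 1.0)
    return rng.normal(0.0, effects.residual_sd, n) if effects.residual_sd > 0 else np.zeros(n)


def generate_dataset(
    design: DesignConfig,
    effects: EffectConfig,
    seed: int,
    _to_mode: str = "H2",
) -> pd.DataFrame:
    """Simulate the full experiment; one row per trial.

    Trial order is randomized within each participant x condition block.
    Identical (configs, seed) yield identical tables.  ``_to_mode`` selects
    the tactile-only generative regime and is set by
    :func:`generate_under_hypothesis`; the default ("H2") gives tactile-only
    trials their own delay profile, the study's default generative truth.
    """
    if design.n_participants <= 0:
        raise ConfigurationError("n_participants must be positive to generate data")
    for light, d in effects.distance_profile:
        if d not in design.distances or light not in design.light_levels:
            raise ConfigurationError(f"distance_profile key ({light}, {d}) not in design")
    for d in effects.delay_profile:
        if d not in design.distances:
            raise ConfigurationError(f"delay_profile key {d} not in design")

    rng = np.random.default_rng(seed)
    _, subj_fx = draw_subject_effects(design.n_participants, design, effects, rng)
    tact_fixed = {t: effects.tactile_location_offsets.get(t, 0.0) for t in design.tactile_levels}

    blocks: list[pd.DataFrame] = []
    for s in range(design.n_participants):
        for light in design.light_levels:
            for tact in design.tactile_levels:
                rows = _condition_block(design, effects, s, light, tact, subj_fx, tact_fixed, rng, _to_mode)
                if len(rows):
                    rows = rows.iloc[rng.permutation(len(rows))]
                blocks.append(rows)
    if not blocks or sum(len(b) for b in blocks) == 0:
        return pd.DataFrame(columns=TRIAL_COLUMNS).astype({"responded": bool})
    out = pd.concat(blocks, ignore_index=True)
    return out[TRIAL_COLUMNS]


def _condition_block(
    design: DesignConfig,
    effects: EffectConfig,
    s: int,
    light: str,
    tact: str,
    subj_fx: dict,
    tact_fixed: dict,
    rng: np.random.Generator,
    to_mode: str,
) -> pd.DataFrame:
    base_subject = (
        subj_fx["intercept"][""][s] + subj_fx["light"][light][s] + subj_fx["tactile"][tact][s]
    )
    recs: list[tuple] = []

    def emit(trial_type: str, d: str | None, mu: float, n: int) -> None:
        if n <= 0:
            return
        rt = mu + _resid(rng, n, effects)
        miss = rng.random(n) < effects.miss_rate
        outl = rng.random(n) < effects.outlier_rate
        rt = np.where(outl, rt + effects.outlier_shift, rt)
        rt = np.maximum(rt, 1.0)  # physical RTs are positive
        for i in range(n):
            recs.append((s, light, tact, trial_type, d, np.nan if miss[i] else rt[i], not miss[i]))

    for d in design.distances:
        mu_vt = (
            effects.grand_mean
            + effects.distance_profile.get((light, d), 0.0)
            + tact_fixed[tact]
            + base_subject
        )
        emit("VT", d, mu_vt, design.reps_vt_per_distance)

        if to_mode == "H0":
            mu_to = mu_vt
            emit("TO", d, mu_to, design.reps_to_per_distance)
        elif to_mode == "H1":
            # single constant mean, no delay structure, no subject effects
            n = design.reps_to_per_distance
            if n > 0:
                rt = effects.grand_mean + effects.to_offset + _resid(rng, n, effects)
                miss = rng.random(n) < effects.miss_rate
                outl = rng.random(n) < effects.outlier_rate
                rt = np.maximum(np.where(outl, rt + effects.outlier_shift, rt), 1.0)
                for i in range(n):
                    recs.append((s, light, tact, "TO", d, np.nan if miss[i] else rt[i], not miss[i]))
        else:  # H2: delay-dependent tactile-only structure
            mu_to = (
                effects.grand_mean
                + effects.delay_profile.get(d, 0.0)
                + tact_fixed[tact]
                + base_subject
            )
            emit("TO", d, mu_to, design.reps_to_per_distance)

    fa = rng.random(design.n_catch) < effects.catch_fa_rate
    fa_rt = rng.uniform(200.0, 800.0, design.n_catch)
    for i in range(design.n_catch):
        recs.append((s, light, tact, "catch", None, fa_rt[i] if fa[i] else np.nan, bool(fa[i])))

    return pd.DataFrame(recs, columns=TRIAL_COLUMNS)


def generate_under_hypothesis(
    which: str, design: DesignConfig, effects: EffectConfig, seed: int
) -> pd.DataFrame:
    """Simulate under one of the three tactile-only hypotheses.

    H0: tactile-only trials share the visuo-tactile linear predictor.
    H1: tactile-only trials have a single constant mean (grand mean +
    ``to_offset``) plus residual noise; delay profile and subject effects
    are ignored for TO trials.
    H2: tactile-only trials follow their own delay profile (the default
    bell).  Visuo-tactile generation is identical across the three.
    """
    if which not in HYPOTHESES:
        raise ValueError(f"unknown hypothesis {which!r}; expected one of {HYPOTHESES}")
    return generate_dataset(design, effects, seed, _to_mode=which)


def write_trials_csv(trials: pd.DataFrame, path: str | Path, seed: int | None = None, config: Mapping | None = None) -> None:
    """Write the long-format trial CSV plus a JSON metadata sidecar."""
    path = Path(path)
    out = trials.copy()
    out["responded"] = out["responded"].astype(bool)
    out.to_csv(path, index=False, na_rep="")
    meta = {"n_trials": int(len(trials)), "seed": seed, "config": _jsonable(config)}
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return str(obj)


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read a long-format trial CSV (empty rt field = no response)."""
    df = pd.read_csv(path, dtype={"distance": "string"})
    df["distance"] = df["distance"].where(df["distance"].notna(), None)
    df["responded"] = df["responded"].astype(bool)
    return df[TRIAL_COLUMNS]
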