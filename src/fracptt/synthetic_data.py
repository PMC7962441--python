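"""Synthetic fixtures with the statistical structure the analysis assumes.

Three generators, all bit-reproducible under a fixed seed:

* :func:`synth_frames` — IR-camera-like surface temperature frame stacks: a
  saturating exponential time course times a Gaussian or flat-top
  (super-Gaussian) spatial profile, plus i.i.d. Gaussian sensor noise.
  Emulates what a thermal camera records over a heated solution surface.
* :func:`synth_caliper` — tumor caliper tables for three treatment arms:
  untreated exponential growth, treated-then-regrowing (regression until
  day 7, regrowth after), and monotone regression.  Volumes are converted
  to (length, width) pairs via a per-animal aspect ratio and multiplicative
  lognormal measurement noise.
* :func:`synth_solution_curve` — a single saturating heating curve
  ``T(t) = T_inf - (T_inf - T0) exp(-t/tau)`` with optional noise.

These are test/fixture generators: parametric idealisations of the
qualitative behaviour of the real measurements, not data claims.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dosimetry_stats import CaliperTable, DAYS
from .thermal_metrics import FrameStack

__all__ = [
    "FrameSynthSpec",
    "TumorSynthSpec",
    "synth_frames",
    "synth_caliper",
    "synth_solution_curve",
]

GENERATOR_VERSION = "1"


@dataclass(frozen=True)
class FrameSynthSpec:
    """Parameters of the synthetic IR frame generator.

    The spatial shape has unit peak: ``exp(-rho^2/scale^2)`` (gaussian) or
    ``exp(-(rho^2/scale^2)^4)`` (flat-top super-Gaussian).  Defaults echo
    the saturating solution-surface heating seen under fractional
    irradiation: ~25 degC baseline rising by ~37 degC with a ~40 s time
    constant (flat-top peaks near 62 degC, Gaussian runs cooler, ~55 degC).
    """

    profile: str = "gaussian"  # "gaussian" | "flattop"
    T_base_C: float = 25.0
    dT_max_C: float = 30.0
    scale_mm: float = 3.0
    tau_s: float = 40.0
    noise_sd_C: float = 0.3
    pixel_pitch_mm: float = 0.25
    frame_interval_s: float = 5.0
    extent_mm: float = 12.0  # half-width of the square field of view
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile not in ("gaussian", "flattop"):
            raise ValueError("profile must be 'gaussian' or 'flattop'")
        if self.tau_s <= 0 or self.noise_sd_C < 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("require tau > 0, noise sd >= 0, pixel pitch > 0")


def _spatial_shape(spec: FrameSynthSpec, rho2: np.ndarray) -> np.ndarray:
    u = rho2 / spec.scale_mm**2
    if spec.profile == "gaussian":
        return np.exp(-u)
    return np.exp(-(u**4))


def synth_frames(spec: FrameSynthSpec, duration_s: float = 180.0) -> FrameStack:
    """Generate a FrameStack of noisy saturating-heating surface maps.

    ``T(x, y, t) = T_base + dT_max (1 - e^{-t/tau}) S(rho) + eps`` with
    ``eps ~ N(0, noise_sd^2)`` i.i.d. per pixel and frame.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(2 * spec.extent_mm / spec.pixel_pitch_mm)) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_pitch_mm
    rho2 = ax[None, :] ** 2 + ax[:, None] ** 2
    S = _spatial_shape(spec, rho2)
    times = np.arange(0.0, duration_s + 1e-9, spec.frame_interval_s)
    sat = 1.0 - np.exp(-times / spec.tau_s)
    frames = spec.T_base_C + spec.dT_max_C * sat[:, None, None] * S[None, :, :]
    if spec.noise_sd_C > 0:
        frames = frames + rng.normal(0.0, spec.noise_sd_C, size=frames.shape)
    return FrameStack(
        times_s=times,
        frames=frames,
        pixel_pitch_mm=spec.pixel_pitch_mm,
        meta={
            "generator": "synth_frames",
            "version": GENERATOR_VERSION,
            "profile": spec.profile,
            "seed": spec.seed,
        },
    )


@dataclass(frozen=True)
class TumorSynthSpec:
    """Group kinetics for the synthetic caliper generator (rates per day).

    Control tumors grow exponentially; the flat arm regresses slowly until
    day 7 and then regrows; the mla arm decays monotonically.  Day-0
    volumes are lognormal around ``V0_mm3``; measured axes carry
    multiplicative lognormal noise of coefficient of variation
    ``noise_cv``.
    """

    g_control: float = 0.25  # control exponential growth rate, /day
    d_flat: float = 0.05  # flat-arm regression rate to day 7, /day
    g_flat_regrow: float = 0.35  # flat-arm regrowth rate after day 7, /day
    d_mla: float = 0.30  # mla-arm monotone decay rate, /day
    V0_mm3: float = 60.0  # median day-0 volume
    V0_sigma: float = 0.25  # lognormal sd of day-0 volume (log scale)
    noise_cv: float = 0.10
    n_per_group: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("need at least one animal per group")
        for r in (self.g_control, self.d_flat, self.g_flat_regrow, self.d_mla):
            if not math.isfinite(r):
                raise ValueError("rates must be finite")


def _model_volume(group: str, V0: float, day: float, spec: TumorSynthSpec) -> float:
    if group == "control":
        return V0 * math.exp(spec.g_control * day)
    if group == "flat":
        if day <= 7:
            return V0 * math.exp(-spec.d_flat * day)
        return V0 * math.exp(-spec.d_flat * 7) * math.exp(spec.g_flat_regrow * (day - 7))
    if group == "mla":
        return V0 * math.exp(-spec.d_mla * day)
    raise ValueError(f"unknown group {group!r}")


def synth_caliper(spec: TumorSynthSpec, days=DAYS) -> CaliperTable:
    """Generate a three-arm caliper table following the group kinetics.

    Each animal draws a day-0 volume and an aspect ratio l/w in [1.0, 1.6]
    once; the model volume V(day) is converted back to axes via
    ``V = l w^2 / 2`` with ``l = a w``, then both axes receive independent
    multiplicative lognormal noise of cv ``noise_cv``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0
    for group in ("control", "flat", "mla"):
        for i in range(spec.n_per_group):
            animal = f"{group}-{i+1:02d}"
            V0 = spec.V0_mm3 * math.exp(rng.normal(0.0, spec.V0_sigma))
            aspect = rng.uniform(1.0, 1.6)
            for day in days:
                V = _model_volume(group, V0, day, spec)
                w = (2.0 * V / aspect) ** (1.0 / 3.0)
                l = aspect * w
                if sigma > 0:
                    l *= math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                    w *= math.exp(rng.normal(0.0, sigma) - sigma**2 / 2.0)
                if w > l:  # noise can flip the axes; record as measured
                    l, w = w, l
                rows.append(
                    dict(animal_id=animal, group=group, day=day, length_mm=l, width_mm=w)
                )
    return CaliperTable(pd.DataFrame(rows))


def synth_solution_curve(
    T0_C: float,
    T_inf_C: float,
    tau_s: float,
    duration_s: float,
    noise_sd_C: float = 0.0,
    dt_s: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Saturating surface-heating time course, ``T = T_inf - (T_inf-T0) e^{-t/tau}``."""
    if tau_s <= 0:
        raise ValueError("tau must be positive")
    t = np.arange(0.0, duration_s + 1e-9, dt_s)
    T = T_inf_C - (T_inf_C - T0_C) * np.exp(-t / tau_s)
    if noise_sd_C > 0:
        T = T + np.random.default_rng(seed).normal(0.0, noise_sd_C, size=t.shape)
    return pd.DataFrame({"time_s": t, "T_C": T})
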