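"""Synthetic biosensor sensorgrams and 2D Brownian particle tracks.

Sensorgrams follow the 1:1 Langmuir binding model

    association:  R(t) = R_eq (1 - exp(-k_obs t)),  k_obs = k_on C + k_off,
                  R_eq = R_max C / (C + K_D),       K_D  = k_off / k_on
    dissociation: R(t) = R(t_assoc) exp(-k_off t)

with optional additive Gaussian noise. Tracks are 2D Brownian walks with
per-axis step variance 2 D dt plus optional Gaussian localization noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import SensorgramSet, TrackSet
from .synthetic_sequences import derive_rng


def langmuir_signal(t: np.ndarray, phase: str, concentration: float,
                    k_on: float, k_off: float, r_max: float,
                    t_assoc: float) -> np.ndarray:
    """Noiseless 1:1 Langmuir signal for one phase at one concentration."""
    k_obs = k_on * concentration + k_off
    kd = k_off / k_on
    r_eq = r_max * concentration / (concentration + kd)
    r_end = r_eq * (1.0 - np.exp(-k_obs * t_assoc))
    if phase == "assoc":
        return r_eq * (1.0 - np.exp(-k_obs * t))
    if phase == "dissoc":
        return r_end * np.exp(-k_off * t)
    raise ValueError(f"unknown phase {phase!r}")


def generate_sensorgrams(k_on: float, k_off: float, r_max: float,
                         concentrations: list[float], t_assoc: float,
                         t_dissoc: float, noise_sd: float = 0.0,
                         dt: float = 0.5, seed: int = 0) -> SensorgramSet:
    """Generate association + dissociation curves at each concentration.

    ``time_s`` is phase-relative (restarts at 0 for the dissociation).
    """
    if k_on <= 0 or k_off <= 0 or r_max <= 0:
        raise ValueError("rates and R_max must be positive")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    rng = derive_rng(seed, "sensorgrams")
    frames = []
    for conc in concentrations:
        for phase, t_end in (("assoc", t_assoc), ("dissoc", t_dissoc)):
            t = np.arange(0.0, t_end + dt / 2, dt)
            sig = langmuir_signal(t, phase, conc, k_on, k_off, r_max, t_assoc)
            if noise_sd > 0:
                sig = sig + rng.normal(0.0, noise_sd, size=t.shape)
            frames.append(pd.DataFrame({
                "time_s": t, "signal": sig,
                "concentration_M": conc, "phase": phase}))
    return SensorgramSet(pd.concat(frames, ignore_index=True),
                         t_assoc=t_assoc)


def generate_tracks(d_coeff: float, dt: float, n_tracks: int, n_steps: int,
                    loc_noise_sd: float = 0.0, seed: int = 0) -> TrackSet:
    """2D Brownian tracks: per-axis displacement variance 2 D dt; optional
    localization noise of sd ``loc_noise_sd`` added to every position."""
    if d_coeff < 0 or dt <= 0:
        raise ValueError("D must be >= 0 and dt > 0")
    rng = derive_rng(seed, "tracks")
    rows = []
    step_sd = np.sqrt(2.0 * d_coeff * dt)
    for tr in range(n_tracks):
        steps = rng.normal(0.0, step_sd, size=(n_steps, 2)) \
            if step_sd > 0 else np.zeros((n_steps, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        if loc_noise_sd > 0:
            pos = pos + rng.normal(0.0, loc_noise_sd, size=pos.shape)
        frames = np.arange(n_steps + 1)
        rows.append(pd.DataFrame({
            "track_id": tr, "frame": frames, "t_s": frames * dt,
            "x_um": pos[:, 0], "y_um": pos[:, 1]}))
    return TrackSet(pd.concat(rows, ignore_index=True), dt=dt)
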