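"""Seeded synthetic-data generators for every pipeline stage.

The generators emit data with the statistical structure the analysis
stages assume, so the whole pipeline is testable without imaging data:

* ``sample_stable`` — i.i.d. α-stable variates by the
  Chambers–Mallows–Stuck construction;
* ``simulate_levy_walk_cohort`` — per-cell Lévy walks whose step
  lengths follow condition-specific stable laws (treated conditions
  switch parameters at a configurable frame), with isotropic headings;
* ``simulate_fccs_experiment`` — per-cell FCCS measurements: totals
  drawn from expression ranges, complex from the binding isotherm,
  amplitudes inverted to correlation curves with multiplicative noise,
  plus positive (tandem fusion) and negative (independent species)
  control modes and injected QC failures;
* ``simulate_growth_speeds`` — log-normal microtubule growth-speed
  events with a configurable fast-tail shift between conditions.

Reproducibility: one global seed per run; per-cell substreams are
derived as ``default_rng([seed, cell_index])`` so cohorts are
bit-reproducible regardless of iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fccs
from .errors import ConfigError, ParameterError
from .stable import AlphaStableParams, stable_cdf
from .trajectories import Trajectory

__all__ = [
    "WalkSimConfig", "FccsSimConfig",
    "sample_stable", "simulate_levy_walk_cohort",
    "simulate_fccs_experiment", "simulate_growth_speeds",
    "DEFAULT_VEHICLE_PARAMS", "DEFAULT_TREATED_PARAMS",
]

# Walk defaults emulate brightfield tracking at 10-min frames: median step
# ~2.6 µm/frame in controls, with treatment suppressing the long-step tail
# (higher alpha) and shifting the distribution left (smaller gamma/delta).
DEFAULT_VEHICLE_PARAMS = AlphaStableParams(1.5, 0.5, 0.8, 2.6)
DEFAULT_TREATED_PARAMS = AlphaStableParams(1.6, 0.5, 0.6, 2.4)


def _rng(seed, *stream) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng([int(seed), *map(int, stream)])


def sample_stable(params: AlphaStableParams, n: int, seed=None) -> np.ndarray:
    """n i.i.d. stable variates via the Chambers–Mallows–Stuck construction."""
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    rng = _rng(seed)
    a, b = params.alpha, params.beta
    V = rng.uniform(-np.pi / 2, np.pi / 2, size=n)
    W = rng.standard_exponential(size=n)
    if abs(a - 1.0) > 1e-12:
        theta0 = math.atan(b * math.tan(math.pi * a / 2.0)) / a
        z = (
            np.sin(a * (V + theta0))
            / np.cos(V) ** (1.0 / a)
            * (np.cos(V - a * (V + theta0)) / W) ** ((1.0 - a) / a)
        )
        z *= (1.0 + (b * math.tan(math.pi * a / 2.0)) ** 2) ** (1.0 / (2.0 * a))
        p1 = params.as_s1()
        return params.gamma * z + p1.delta  # S1 scale/shift; matches S0 target
    # alpha == 1
    z = (2.0 / np.pi) * (
        (np.pi / 2.0 + b * V) * np.tan(V)
        - b * np.log((np.pi / 2.0 * W * np.cos(V)) / (np.pi / 2.0 + b * V))
    )
    p1 = params.as_s1()
    return params.gamma * z + (2.0 / np.pi) * b * params.gamma * np.log(params.gamma) + p1.delta


@dataclass(frozen=True)
class WalkSimConfig:
    """Lévy-walk cohort configuration.

    ``params`` maps condition label to its stable step-length law (S0).
    Conditions other than ``baseline`` use the baseline law before
    ``shift_time`` (frame index) and their own law afterwards, emulating
    a treatment added mid-experiment; ``shift_time=0`` means treated
    throughout.
    """

    params: dict[str, AlphaStableParams] = field(
        default_factory=lambda: {
            "vehicle": DEFAULT_VEHICLE_PARAMS,
            "dex": DEFAULT_TREATED_PARAMS,
        }
    )
    baseline: str = "vehicle"
    n_cells: int = 100
    n_frames: int = 25  # positions per track (steps = n_frames - 1)
    frame_interval: float = 10.0  # minutes
    shift_time: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_frames < 2:
            raise ConfigError("need n_cells >= 1 and n_frames >= 2")
        if not (0 <= self.shift_time <= self.n_frames):
            raise ConfigError("shift_time must lie within the frame range")
        if self.baseline not in self.params:
            raise ConfigError(f"baseline condition {self.baseline!r} not in params")


def _positive_stable_steps(params: AlphaStableParams, n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Rejection-resample a stable law to non-negative step lengths."""
    neg_mass = float(stable_cdf(0.0, params))
    if neg_mass > 0.5:
        raise ConfigError(
            f"step law has {neg_mass:.0%} mass below zero; rejection sampling refused"
        )
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = sample_stable(params, max(n - filled, 16), rng)
        draw = draw[draw >= 0]
        take = min(draw.size, n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def simulate_levy_walk_cohort(cfg: WalkSimConfig) -> dict[str, list[Trajectory]]:
    """Simulate per-condition cohorts of 2-D Lévy walks."""
    cohorts: dict[str, list[Trajectory]] = {}
    for ci, (condition, treated_params) in enumerate(sorted(cfg.params.items())):
        tracks = []
        for cell in range(cfg.n_cells):
            rng = _rng(cfg.seed, ci, cell)
            n_steps = cfg.n_frames - 1
            if condition == cfg.baseline or cfg.shift_time == 0:
                phases = [(treated_params, n_steps)]
            else:
                pre = min(cfg.shift_time, n_steps)
                phases = [(cfg.params[cfg.baseline], pre), (treated_params, n_steps - pre)]
            steps = np.concatenate(
                [_positive_stable_steps(p, k, rng) for p, k in phases if k > 0]
            )
            headings = rng.uniform(0.0, 2.0 * np.pi, size=n_steps)
            x = np.concatenate([[0.0], np.cumsum(steps * np.cos(headings))])
            y = np.concatenate([[0.0], np.cumsum(steps * np.sin(headings))])
            t = np.arange(cfg.n_frames) * cfg.frame_interval
            tracks.append(
                Trajectory(
                    track_id=f"{condition}_{cell:04d}", t=t, x=x, y=y,
                    frame_interval=cfg.frame_interval,
                )
            )
        cohorts[condition] = tracks
    return cohorts


# ---------------------------------------------------------------------------
# FCCS experiment simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FccsSimConfig:
    """FCCS experiment simulator configuration (concentrations in nM).

    ``control_mode``: "interacting" draws the complex from the binding
    isotherm at ``kd``; "tandem_fusion" forces complex = totals (one
    dual-labelled species, the positive control); "independent" forces
    complex = 0 (separate free fluorophores, the negative control).
    """

    kd: float = 100.0  # nM
    n_cells: int = 30
    green_range: tuple[float, float] = (20.0, 80.0)
    red_range: tuple[float, float] = (10.0, 400.0)
    curve_noise_sd: float = 0.02  # multiplicative, on G(tau)
    concentration_noise_sd: float = 0.0  # multiplicative, on the complex
    qc_fail_rate: float = 0.0
    control_mode: str = "interacting"
    effective_volume: float = 0.57e-15  # litres
    tau_d_free: float = 5e-4  # s, free species
    tau_d_complex: float = 1.5e-3  # s, bound complex
    triplet_fraction: float = 0.15
    triplet_time: float = 5e-6  # s
    compartment: str = "cytoplasm"
    seed: int = 0

    def __post_init__(self):
        if self.kd < 0:
            raise ConfigError("kd must be >= 0")
        if not (0.0 <= self.qc_fail_rate <= 1.0):
            raise ConfigError("qc_fail_rate must be in [0, 1]")
        if self.control_mode not in ("interacting", "tandem_fusion", "independent"):
            raise ConfigError(f"unknown control mode {self.control_mode!r}")


def equilibrium_complex(green_total: float, red_total: float, kd: float) -> float:
    """Exact complex concentration from the single-site binding isotherm.

    Solves c/(g) = (r − c)/(Kd + r − c), the quadratic whose physical
    root is c = [(g + r + Kd) − sqrt((g + r + Kd)² − 4 g r)] / 2.
    """
    g, r = green_total, red_total
    s = g + r + kd
    return 0.5 * (s - math.sqrt(s * s - 4.0 * g * r))


# 6 decades at ~8 points per octave, the multi-tau correlator standard
DEFAULT_LAGS = np.logspace(-6, 0, 160)  # seconds


def simulate_fccs_experiment(
    cfg: FccsSimConfig, lags: np.ndarray | None = None
) -> tuple[list[fccs.CorrelationCurve], pd.DataFrame]:
    """Simulate per-cell correlation curves and an amplitude/QC table."""
    lags = DEFAULT_LAGS if lags is None else np.asarray(lags, float)
    to_nM = 1e9 / (fccs.AVOGADRO * cfg.effective_volume)
    curves: list[fccs.CorrelationCurve] = []
    rows = []
    for cell in range(cfg.n_cells):
        rng = _rng(cfg.seed, 7, cell)
        g = rng.uniform(*cfg.green_range)
        if cfg.control_mode == "tandem_fusion":
            r, c = g, g
        elif cfg.control_mode == "independent":
            r = rng.uniform(*cfg.red_range)
            c = 0.0
        else:
            r = rng.uniform(*cfg.red_range)
            c = equilibrium_complex(g, r, cfg.kd)
            if cfg.concentration_noise_sd > 0:
                c *= 1.0 + cfg.concentration_noise_sd * rng.standard_normal()
                c = float(np.clip(c, 0.0, min(g, r)))
        # invert the amplitude->concentration relations
        Gg0 = to_nM / g
        Gr0 = to_nM / r
        Gx0 = c / (g * r) * to_nM

        free_g_frac = (g - c) / g
        free_r_frac = (r - c) / r
        for channel, N, fractions, tds, triplet in (
            ("green_auto", g / to_nM, (free_g_frac, 1 - free_g_frac),
             (cfg.tau_d_free, cfg.tau_d_complex), True),
            ("red_auto", r / to_nM, (free_r_frac, 1 - free_r_frac),
             (cfg.tau_d_free, cfg.tau_d_complex), True),
        ):
            result = fccs.AcfFitResult(
                N=N, fractions=fractions, tau_d=tds,
                triplet_fraction=cfg.triplet_fraction if triplet else 0.0,
                triplet_time=cfg.triplet_time,
            )
            model_cfg = fccs.AcfFitConfig(triplet=triplet)
            G = fccs.correlation_model(lags, result, model_cfg)
            G = G * (1.0 + cfg.curve_noise_sd * rng.standard_normal(lags.size))
            curves.append(fccs.CorrelationCurve(
                channel=channel, lags=lags, G=G, compartment=cfg.compartment,
                meta={"cell_id": cell},
            ))
        # cross curve: single component (the complex), no triplet
        if Gx0 > 0:
            cross_res = fccs.AcfFitResult(
                N=1.0 / Gx0, fractions=(1.0,), tau_d=(cfg.tau_d_complex,),
            )
            Gx = fccs.correlation_model(lags, cross_res, fccs.AcfFitConfig.for_cross())
            Gx = Gx * (1.0 + cfg.curve_noise_sd * rng.standard_normal(lags.size))
        else:
            # no co-diffusion: residual baseline fluctuations only
            Gx = 0.05 * cfg.curve_noise_sd * Gg0 * rng.standard_normal(lags.size)
        curves.append(fccs.CorrelationCurve(
            channel="cross", lags=lags, G=Gx, compartment=cfg.compartment,
            meta={"cell_id": cell},
        ))

        qc_fail = rng.uniform() < cfg.qc_fail_rate
        if qc_fail:
            # inject one of the two documented failure modes
            if rng.uniform() < 0.5:
                cpm_g, cpm_r, bl_g, bl_r = 0.5, 2.0, 0.02, 0.02
            else:
                cpm_g, cpm_r, bl_g, bl_r = 2.0, 2.0, 0.25, 0.02
        else:
            cpm_g, cpm_r, bl_g, bl_r = 2.5, 2.5, 0.02, 0.02
        rows.append({
            "cell_id": cell, "compartment": cfg.compartment,
            "treatment": cfg.control_mode,
            "Gg0": Gg0, "Gr0": Gr0, "Gx0": Gx0,
            "cpm_green_khz": cpm_g, "cpm_red_khz": cpm_r,
            "bleach_green": bl_g, "bleach_red": bl_r,
            "true_green_total": g, "true_red_total": r, "true_complex": c,
        })
    return curves, pd.DataFrame(rows)


def measurements_from_table(df: pd.DataFrame,
                            effective_volume: float = 0.57e-15
                            ) -> list[fccs.FccsPointMeasurement]:
    """Amplitude/QC table rows -> :class:`FccsPointMeasurement` objects."""
    processed = fccs.process_measurement_table(df, effective_volume)
    out = []
    for _, row in processed.iterrows():
        out.append(fccs.FccsPointMeasurement(
            green_total=row["green_total"], red_total=row["red_total"],
            complex_nM=min(row["complex_nM"],
                           min(row["green_total"], row["red_total"])),
            compartment=row["compartment"],
            cpm_green=row["cpm_green_khz"], cpm_red=row["cpm_red_khz"],
            photobleach_green=row["bleach_green"],
            photobleach_red=row["bleach_red"],
            qc_pass=bool(row["qc_pass"]),
        ))
    return out


# ---------------------------------------------------------------------------
# Microtubule growth speeds
# ---------------------------------------------------------------------------

def simulate_growth_speeds(
    n_ref: int = 9149,
    n_treated: int = 9669,
    median_speed: float = 17.2,  # µm/min, matches control comet tracking
    sigma_log: float = 0.45,
    fast_tail_shift: float = 1.05,
    seed: int = 0,
    ref_label: str = "vehicle",
    treated_label: str = "dex",
) -> pd.DataFrame:
    """Log-normal growth-speed events with a scaled fast tail in the treated arm.

    Treated events above the reference's upper-tertile edge are
    multiplied by ``fast_tail_shift``, emulating a treatment that speeds
    up the fastest-growing microtubule plus-ends while leaving the bulk
    unchanged.  Returns a ``condition,growth_speed_um_min`` table.
    """
    if n_ref < 3 or n_treated < 3:
        raise ConfigError("need at least 3 events per condition")
    if median_speed <= 0 or sigma_log <= 0:
        raise ConfigError("distribution parameters must be positive")
    rng = _rng(seed, 11)
    mu = math.log(median_speed)
    ref = rng.lognormal(mu, sigma_log, size=n_ref)
    treated = rng.lognormal(mu, sigma_log, size=n_treated)
    edge_fast = np.quantile(ref, 2.0 / 3.0)
    treated = np.where(treated > edge_fast, treated * fast_tail_shift, treated)
    return pd.DataFrame({
        "condition": [ref_label] * n_ref + [treated_label] * n_treated,
        "growth_speed_um_min": np.concatenate([ref, treated]),
    })
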