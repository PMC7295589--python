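"""Fluorescence cross-correlation spectroscopy (FCCS) binding analysis.

FCCS watches two spectrally distinct labels (a "green" prey and a "red"
bait) fluctuate through a confocal volume.  Each channel's
autocorrelation curve G(τ) decays on the timescale of the label's
diffusion; its zero-lag amplitude is the inverse of the mean number of
labelled molecules in the volume, which converts to a molar
concentration through the effective volume V_eff.  The cross-correlation
amplitude reports molecules carrying both labels, i.e. the complex.

The fitted model is the standard 3-D diffusion correlation function
with a fixed structural parameter S (axial/lateral ratio of the
detection volume) and up to two diffusing components, optionally
multiplied by a triplet-state relaxation term::

    G(τ) = [1 + T/(1−T)·exp(−τ/τ_T)] · (1/N) ·
           Σ_i f_i (1 + τ/τ_Di)^(−1) (1 + τ/(S² τ_Di))^(−1/2)

Autocorrelation curves are fitted with two components and a triplet;
cross-correlation curves with a single component (the complex is one
species) and no triplet.

Downstream quantities:

* concentrations  —  [total] = 1/(G0 · N_A · V_eff),
  [complex] = Gx0/(Gg0 · Gr0 · N_A · V_eff);
* relative cross-correlation  —  RCC = 100·Gx0/Gg0 (%), the fraction of
  the red-labelled species bound to the green-labelled one;
* the in vivo dissociation constant, from the single-site binding
  isotherm  [complex]/[green]_tot = ([red]_tot − [complex]) /
  (K_d + [red]_tot − [complex]).

Quality control rejects measurements with counts-per-molecule below
1 kHz or more than 10 % photobleaching in either channel, and the Kd
fit excludes points whose total concentrations sit more than three
standard deviations from the sample mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, FitError, InsufficientDataError, ParameterError

logger = logging.getLogger(__name__)

AVOGADRO = 6.02214076e23  # 1/mol

CHANNELS = ("green_auto", "red_auto", "cross")
COMPARTMENTS = ("cytoplasm", "nucleus")


@dataclass(frozen=True)
class CorrelationCurve:
    """One correlation curve: strictly increasing positive lags (s) and G values."""

    channel: str
    lags: np.ndarray
    G: np.ndarray
    compartment: str = "cytoplasm"
    weights: np.ndarray | None = None  # per-lag fit weights (e.g. 1/var over runs)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.channel not in CHANNELS:
            raise ParameterError(f"channel must be one of {CHANNELS}")
        lags = np.asarray(self.lags, dtype=float)
        G = np.asarray(self.G, dtype=float)
        if lags.size != G.size:
            raise DataError("lags and G must have equal length")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise DataError("lags must be strictly increasing and > 0")
        if not np.all(np.isfinite(G)):
            raise DataError("non-finite correlation values")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "G", G)


@dataclass(frozen=True)
class AcfFitConfig:
    """Correlation-model configuration.

    The structural parameter is fixed at 4 and the effective confocal
    volume at 0.57 fL (calibration constants measured upstream).
    """

    structural_parameter: float = 4.0
    n_components: int = 2
    triplet: bool = True
    effective_volume: float = 0.57e-15  # litres

    def __post_init__(self):
        if self.structural_parameter <= 0:
            raise ParameterError("structural parameter must be > 0")
        if self.effective_volume <= 0:
            raise ParameterError("effective volume must be > 0")
        if self.n_components not in (1, 2):
            raise ParameterError("n_components must be 1 or 2")

    @classmethod
    def for_cross(cls, **kw) -> "AcfFitConfig":
        """Cross-correlation default: one component (the complex), no triplet."""
        kw.setdefault("n_components", 1)
        kw.setdefault("triplet", False)
        return cls(**kw)


@dataclass(frozen=True)
class AcfFitResult:
    """Fitted correlation-curve parameters."""

    N: float  # mean occupancy of the confocal volume
    fractions: tuple[float, ...]  # component fractions, sum to 1
    tau_d: tuple[float, ...]  # diffusion times (s), ascending
    triplet_fraction: float = 0.0  # T in [0, 1)
    triplet_time: float = 0.0  # tau_T (s)
    residual_norm: float = float("nan")

    def __post_init__(self):
        if self.N <= 0:
            raise ParameterError("N must be > 0")
        if not (0.0 <= self.triplet_fraction < 1.0):
            raise ParameterError("triplet fraction must be in [0, 1)")
        if abs(sum(self.fractions) - 1.0) > 1e-6 or any(f < -1e-12 for f in self.fractions):
            raise ParameterError("fractions must be >= 0 and sum to 1")
        if list(self.tau_d) != sorted(self.tau_d):
            raise ParameterError("diffusion times must be ascending")

    @property
    def G0(self) -> float:
        """Triplet-corrected zero-lag amplitude 1/N used for concentrations."""
        return 1.0 / self.N


def correlation_model(lag, result: AcfFitResult, cfg: AcfFitConfig) -> np.ndarray:
    """Evaluate the diffusion (± triplet) correlation model at ``lag`` seconds."""
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ParameterError("lag must be >= 0")
    S2 = cfg.structural_parameter**2
    diff = np.zeros_like(lag, dtype=float)
    for f, td in zip(result.fractions, result.tau_d):
        diff += f / ((1.0 + lag / td) * np.sqrt(1.0 + lag / (S2 * td)))
    G = diff / result.N
    if cfg.triplet and result.triplet_fraction > 0:
        T, tauT = result.triplet_fraction, result.triplet_time
        G = G * (1.0 + (T / (1.0 - T)) * np.exp(-lag / tauT))
    return G


# ---------------------------------------------------------------------------
# Curve fitting
# ---------------------------------------------------------------------------

_TAU_GRID = np.logspace(-5, 0, 5)  # multi-start grid for diffusion times (s)


class CorrelationCurveModel:
    """Weighted least-squares fit of a correlation curve.

    Requires at least 20 lag points spanning three decades.  The fit is
    restarted from a fixed logarithmic grid of diffusion-time initial
    values (5×5 for two components) and the best solution kept, making
    the result reproducible.
    """

    def __init__(self, curve: CorrelationCurve, config: AcfFitConfig | None = None):
        if config is None:
            config = AcfFitConfig() if curve.channel != "cross" else AcfFitConfig.for_cross()
        self.curve = curve
        self.config = config
        lags = curve.lags
        if lags.size < 20:
            raise InsufficientDataError(f"need >= 20 lag points, got {lags.size}")
        if lags[-1] / lags[0] < 1e3:
            raise InsufficientDataError("lag range must span >= 3 decades")
        self.weights = curve.weights if curve.weights is not None else np.ones_like(lags)

    # Parameter vector layout: [N, f1, log10 tau_d..., T, log10 tauT]
    def _unpack(self, theta: np.ndarray) -> AcfFitResult:
        cfg = self.config
        i = 0
        N = theta[i]; i += 1
        if cfg.n_components == 2:
            f1 = theta[i]; i += 1
            td = sorted((10.0 ** theta[i], 10.0 ** theta[i + 1]))
            # keep fraction attached to its (sorted) component
            if 10.0 ** theta[i] <= 10.0 ** theta[i + 1]:
                fractions = (f1, 1.0 - f1)
            else:
                fractions = (1.0 - f1, f1)
            i += 2
        else:
            fractions = (1.0,)
            td = [10.0 ** theta[i]]; i += 1
        if cfg.triplet:
            T = theta[i]; tauT = 10.0 ** theta[i + 1]
        else:
            T, tauT = 0.0, 0.0
        return AcfFitResult(
            N=float(N), fractions=tuple(float(f) for f in fractions),
            tau_d=tuple(float(t) for t in td),
            triplet_fraction=float(T), triplet_time=float(tauT),
        )

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        try:
            res = self._unpack(theta)
        except ParameterError:
            return np.full(self.curve.G.size, 1e6)
        model = correlation_model(self.curve.lags, res, self.config)
        return np.sqrt(self.weights) * (model - self.curve.G)

    def _starts(self) -> list[np.ndarray]:
        cfg = self.config
        G0 = float(np.max(self.curve.G[: max(3, self.curve.G.size // 10)]))
        N0 = 1.0 / max(G0, 1e-6)
        starts = []
        if cfg.n_components == 2:
            for t1 in _TAU_GRID:
                for t2 in _TAU_GRID:
                    if t2 < t1:
                        continue
                    base = [N0, 0.5, np.log10(t1), np.log10(t2)]
                    if cfg.triplet:
                        base += [0.1, np.log10(5e-6)]
                    starts.append(np.array(base))
        else:
            for t1 in _TAU_GRID:
                base = [N0, np.log10(t1)]
                if cfg.triplet:
                    base += [0.1, np.log10(5e-6)]
                starts.append(np.array(base))
        return starts

    def _bounds(self) -> tuple[np.ndarray, np.ndarray]:
        cfg = self.config
        lo, hi = [1e-4], [1e7]  # N
        if cfg.n_components == 2:
            lo += [0.0, -6.0, -6.0]
            hi += [1.0, 1.0, 1.0]
        else:
            lo += [-6.0]
            hi += [1.0]
        if cfg.triplet:
            lo += [0.0, -7.0]
            hi += [0.8, -3.0]
        return np.array(lo), np.array(hi)

    def fit(self) -> AcfFitResult:
        if np.max(np.abs(self.curve.G)) < 1e-6:
            raise FitError("flat curve: no correlation amplitude to fit")
        bounds = self._bounds()
        best = None
        best_cost = np.inf
        for start in self._starts():
            start = np.clip(start, bounds[0], bounds[1])
            try:
                sol = optimize.least_squares(
                    self._residuals, start, bounds=bounds,
                    xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=2000,
                )
            except Exception:  # singular Jacobian on a bad start
                continue
            if sol.cost < best_cost:
                best_cost, best = sol.cost, sol
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("correlation-curve fit failed from every start",
                           best_residual=best_cost)
        res = self._unpack(best.x)
        return AcfFitResult(
            N=res.N, fractions=res.fractions, tau_d=res.tau_d,
            triplet_fraction=res.triplet_fraction, triplet_time=res.triplet_time,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
        )


def fit_correlation_curve(curve: CorrelationCurve,
                          config: AcfFitConfig | None = None) -> AcfFitResult:
    """Convenience wrapper around :class:`CorrelationCurveModel`."""
    return CorrelationCurveModel(curve, config).fit()


# ---------------------------------------------------------------------------
# QC, concentrations, RCC
# ---------------------------------------------------------------------------

def qc_filter(cpm_green: float, cpm_red: float,
              photobleach_green: float, photobleach_red: float,
              min_cpm: float = 1.0, max_bleach: float = 0.10) -> tuple[bool, list[str]]:
    """Measurement quality control.

    Fails iff CPM < 1 kHz in either channel or photobleaching > 10 % in
    either channel (strict inequalities: boundary values pass).
    """
    for name, v in (("cpm_green", cpm_green), ("cpm_red", cpm_red)):
        if v < 0:
            raise DataError(f"{name} must be >= 0, got {v}")
    for name, v in (("photobleach_green", photobleach_green),
                    ("photobleach_red", photobleach_red)):
        if not (0.0 <= v <= 1.0):
            raise DataError(f"{name} must be in [0, 1], got {v}")
    reasons = []
    if cpm_green < min_cpm:
        reasons.append("low-CPM-green")
    if cpm_red < min_cpm:
        reasons.append("low-CPM-red")
    if photobleach_green > max_bleach:
        reasons.append("bleach-green")
    if photobleach_red > max_bleach:
        reasons.append("bleach-red")
    return (len(reasons) == 0, reasons)


def concentrations_from_amplitudes(
    Gg0: float, Gr0: float, Gx0: float,
    effective_volume: float = 0.57e-15,
) -> tuple[float, float, float]:
    """Convert correlation amplitudes to (green_total, red_total, complex) in nM."""
    if Gg0 <= 0 or Gr0 <= 0:
        raise ParameterError("autocorrelation amplitudes must be > 0")
    if Gx0 < 0:
        raise ParameterError("cross amplitude must be >= 0")
    if Gx0 > min(Gg0, Gr0) * 1.05:
        raise DataError(
            f"unphysical cross amplitude Gx0={Gx0:.3g} exceeds "
            f"min(Gg0, Gr0)={min(Gg0, Gr0):.3g} by more than 5%"
        )
    to_nM = 1e9 / (AVOGADRO * effective_volume)
    green_total = to_nM / Gg0
    red_total = to_nM / Gr0
    complex_nM = Gx0 / (Gg0 * Gr0) * to_nM
    cap = min(green_total, red_total)
    if complex_nM > cap:
        warnings.warn("complex concentration capped at min(totals)", stacklevel=2)
        logger.warning("complex %.3g nM capped at %.3g nM", complex_nM, cap)
        complex_nM = cap
    return green_total, red_total, complex_nM


def relative_cross_correlation(Gg0: float, Gr0: float, Gx0: float,
                               reference: str = "green") -> float:
    """Relative cross-correlation (%): the bound fraction of the red species.

    RCC = 100·Gx0/Gg0 equals 100·[complex]/[red]_total (the green
    amplitude cancels the green concentration).  ``reference="red"``
    switches to Gx0/Gr0 (= bound fraction of the green species).
    Clipped to [0, 100] with a warning outside.
    """
    denom = Gg0 if reference == "green" else Gr0
    if denom <= 0:
        raise ParameterError("reference amplitude must be > 0")
    rcc = 100.0 * Gx0 / denom
    if rcc < -1e-9 or rcc > 100.0 + 1e-9:
        warnings.warn(f"RCC {rcc:.1f}% outside [0, 100]; clipped", stacklevel=2)
    return float(np.clip(rcc, 0.0, 100.0))


@dataclass(frozen=True)
class FccsPointMeasurement:
    """Per-confocal-spot concentrations plus QC fields (concentrations in nM)."""

    green_total: float
    red_total: float
    complex_nM: float
    compartment: str = "cytoplasm"
    cpm_green: float = 2.0  # kHz
    cpm_red: float = 2.0  # kHz
    photobleach_green: float = 0.0
    photobleach_red: float = 0.0
    qc_pass: bool = True

    def __post_init__(self):
        if self.green_total < 0 or self.red_total < 0 or self.complex_nM < 0:
            raise DataError("concentrations must be >= 0")
        if self.complex_nM > min(self.green_total, self.red_total) * (1 + 1e-9):
            raise DataError("complex cannot exceed either total concentration")


# ---------------------------------------------------------------------------
# Kd fitting
# ---------------------------------------------------------------------------

def _binding_fraction(x: np.ndarray, kd: float) -> np.ndarray:
    """Bound fraction y = x/(Kd + x) of the green species vs free red x."""
    return x / (kd + x)


@dataclass
class BindingResults:
    """In vivo Kd estimate with its uncertainty and exclusion audit trail."""

    kd: float  # nM
    se: float  # nM, from the least-squares covariance
    dof: int
    ci_level: float
    excluded: list[tuple[int, str]]
    residuals: np.ndarray
    x: np.ndarray  # free red (nM), included points
    y: np.ndarray  # bound fraction, included points
    model: "BindingModel"
    boundary_warning: bool = False

    def conf_int(self, level: float | None = None) -> tuple[float, float]:
        """t-based confidence interval for Kd, truncated at zero."""
        level = self.ci_level if level is None else level
        tcrit = stats.t.ppf(0.5 + level / 2.0, self.dof)
        lo = max(0.0, self.kd - tcrit * self.se)
        hi = self.kd + tcrit * self.se
        return (lo, hi)

    def conf_int_profile(self, level: float | None = None,
                         factor: float = 100.0) -> tuple[float, float]:
        """Profile-likelihood (F-test) interval, for asymmetric fits."""
        level = self.ci_level if level is None else level
        ssr0 = float(np.sum(self.residuals**2))
        thresh = ssr0 * (1.0 + stats.f.ppf(level, 1, self.dof) / self.dof)

        def excess(kd):
            return float(np.sum((self.y - _binding_fraction(self.x, kd)) ** 2)) - thresh

        if excess(1e-12) <= 0:
            lo = 0.0
        else:
            probe = self.kd / 2.0
            while probe > 1e-12 and excess(probe) <= 0:
                probe /= 10.0
            probe = max(probe, 1e-12)
            lo = optimize.brentq(excess, probe, self.kd) if excess(probe) > 0 else 0.0
        hi_bracket = self.kd * factor
        if excess(hi_bracket) <= 0:
            return (lo, float("inf"))
        hi = optimize.brentq(excess, self.kd, hi_bracket)
        return (float(lo), float(hi))

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "In vivo Kd fit (single-site isotherm)",
            "=" * 44,
            f"Kd                 {self.kd:.3f} nM",
            f"s.e.               {self.se:.3f} nM",
            f"{int(self.ci_level*100)}% CI             [{lo:.3f}, {hi:.3f}] nM",
            f"n points (fit)     {self.x.size}",
            f"n excluded         {len(self.excluded)}",
        ]
        for idx, reason in self.excluded:
            lines.append(f"  excluded #{idx}: {reason}")
        if self.boundary_warning:
            lines.append("warning: Kd pinned at the zero boundary")
        return "\n".join(lines)


class BindingModel:
    """Single-site binding model fitted to FCCS point measurements.

    Measurements are screened by the QC flag, then points whose total
    green or total red concentration lies more than ``exclude_sd``
    standard deviations from the sample mean are excluded (one pass).
    The bound fraction y = [complex]/[green]_total is regressed on the
    unbound bait x = [red]_total − [complex] through y = x/(Kd + x).
    """

    MIN_POINTS = 5

    def __init__(self, measurements: list[FccsPointMeasurement],
                 exclude_sd: float = 3.0):
        self.measurements = list(measurements)
        self.exclude_sd = exclude_sd

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "BindingModel":
        meas = [
            FccsPointMeasurement(
                green_total=row["green_total"], red_total=row["red_total"],
                complex_nM=row["complex_nM"],
                compartment=row.get("compartment", "cytoplasm"),
                qc_pass=bool(row.get("qc_pass", True)),
            )
            for _, row in df.iterrows()
        ]
        return cls(meas, **kw)

    def _select(self) -> tuple[list[int], list[tuple[int, str]]]:
        passing = [i for i, m in enumerate(self.measurements) if m.qc_pass]
        excluded: list[tuple[int, str]] = [
            (i, "qc-fail") for i, m in enumerate(self.measurements) if not m.qc_pass
        ]
        if len(passing) < self.MIN_POINTS:
            raise InsufficientDataError(
                f"need >= {self.MIN_POINTS} QC-passing measurements, got {len(passing)}"
            )
        greens = np.array([self.measurements[i].green_total for i in passing])
        reds = np.array([self.measurements[i].red_total for i in passing])
        kept: list[int] = []
        for i, g, r in zip(passing, greens, reds):
            reasons = []
            for name, v, arr in (("green_total", g, greens), ("red_total", r, reds)):
                sd = arr.std(ddof=1)
                if sd > 0 and abs(v - arr.mean()) > self.exclude_sd * sd:
                    reasons.append(f"{name} outlier (> {self.exclude_sd:g} SD)")
            if reasons:
                excluded.append((i, "; ".join(reasons)))
            else:
                kept.append(i)
        if not kept:
            raise DataError("all points excluded by QC/outlier rules")
        return kept, excluded

    def fit(self, ci_level: float = 0.95) -> BindingResults:
        kept, excluded = self._select()
        ms = [self.measurements[i] for i in kept]
        x = np.array([m.red_total - m.complex_nM for m in ms])
        y = np.array([m.complex_nM / m.green_total for m in ms])

        with np.errstate(divide="ignore", invalid="ignore"):
            inv = x * (1.0 - y) / np.where(y > 0, y, np.nan)
        kd0 = float(np.nanmedian(inv))
        if not np.isfinite(kd0) or kd0 <= 0:
            kd0 = max(float(np.median(x)), 1e-6)

        sol = optimize.least_squares(
            lambda th: _binding_fraction(x, th[0]) - y,
            x0=[kd0], bounds=([0.0], [np.inf]),
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        kd = float(sol.x[0])
        resid = _binding_fraction(x, kd) - y
        dof = max(x.size - 1, 1)
        s2 = float(np.sum(resid**2)) / dof
        J = sol.jac
        JtJ = float(np.asarray(J.T @ J).squeeze())
        se = float(np.sqrt(s2 / JtJ)) if JtJ > 0 else float("inf")
        boundary = kd < 1e-12
        if boundary:
            warnings.warn("Kd estimate pinned at the zero boundary", stacklevel=2)
        return BindingResults(
            kd=kd, se=se, dof=dof, ci_level=ci_level,
            excluded=excluded, residuals=resid, x=x, y=y,
            model=self, boundary_warning=boundary,
        )


def fit_kd(measurements: list[FccsPointMeasurement],
           ci_level: float = 0.95, exclude_sd: float = 3.0) -> BindingResults:
    """Convenience wrapper around :class:`BindingModel`."""
    return BindingModel(measurements, exclude_sd=exclude_sd).fit(ci_level=ci_level)


CI_LADDER = (0.95, 0.99, 0.999, 0.9999)


def compare_kd(result_a: BindingResults, result_b: BindingResults,
               ladder: tuple[float, ...] = CI_LADDER) -> str:
    """Highest confidence level at which the two Kd intervals are disjoint.

    Returns e.g. ``"0.999"`` or ``"n.s."`` when the 95 % intervals
    already overlap.
    """
    grade = "n.s."
    for level in sorted(ladder):
        lo_a, hi_a = result_a.conf_int(level)
        lo_b, hi_b = result_b.conf_int(level)
        if hi_a < lo_b or hi_b < lo_a:
            grade = f"{level:g}"
        else:
            break
    return grade


# ---------------------------------------------------------------------------
# Measurement-table processing
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = (
    "cell_id", "compartment", "treatment", "Gg0", "Gr0", "Gx0",
    "cpm_green_khz", "cpm_red_khz", "bleach_green", "bleach_red",
)


def process_measurement_table(df: pd.DataFrame,
                              effective_volume: float = 0.57e-15) -> pd.DataFrame:
    """Amplitude table -> concentrations, RCC and QC columns.

    Expects the columns in :data:`MEASUREMENT_COLUMNS`; returns a copy
    with ``green_total``, ``red_total``, ``complex_nM``, ``rcc_percent``,
    ``qc_pass`` and ``qc_reasons`` appended.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"measurement table missing column(s) {missing}")
    out = df.copy()
    rows = []
    for _, row in df.iterrows():
        ok, reasons = qc_filter(row["cpm_green_khz"], row["cpm_red_khz"],
                                row["bleach_green"], row["bleach_red"])
        g, r, c = concentrations_from_amplitudes(
            row["Gg0"], row["Gr0"], row["Gx0"], effective_volume
        )
        rcc = relative_cross_correlation(row["Gg0"], row["Gr0"], row["Gx0"])
        rows.append((g, r, c, rcc, ok, ";".join(reasons)))
    out[["green_total", "red_total", "complex_nM", "rcc_percent",
         "qc_pass", "qc_reasons"]] = pd.DataFrame(rows, index=df.index)
    return out
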