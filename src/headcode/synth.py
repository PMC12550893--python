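"""Synthetic head trajectories and parametric SP/MP populations.

Every downstream stage (tuning statistics, classification, decoding,
geometry) is testable against known ground truth using this module alone —
no RNN training and no data download required.

The head trajectory follows the same stochastic process used to drive the
ring-integrator RNN: angular head velocity is an AR(1) process,
``v_t = sigma * X_t + momentum * v_{t-1}`` with standard-normal ``X_t``.
With the study defaults (``sigma = 0.03`` rad per 25 ms step,
``momentum = 0.8``) the stationary AHV standard deviation is
``sigma / sqrt(1 - momentum^2) = 0.05`` rad/step, i.e. 2 rad/s — a
turning-speed distribution comparable to a freely moving rodent.

Units are von Mises-shaped: single-peaked (SP) units have one preferred
direction with concentration ``kappa``; multipeaked (MP) units are sums of
several narrow, well-separated bumps.  Units may carry a linear AHV gain
(symmetric or sign-specific), and rates can be corrupted with Poisson spike
counts per bin or additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .session import Session

__all__ = [
    "AHVSeries",
    "HDSeries",
    "SyntheticPopSpec",
    "simulate_ahv",
    "integrate_heading",
    "generate_population",
    "make_session",
    "vonmises_fwhm_to_kappa",
    "DEFAULT_STEP_SIGMA",
    "DEFAULT_MOMENTUM",
    "DEFAULT_DT",
]

# AR(1) parameters of the driving angular-velocity process, per 25 ms step.
DEFAULT_STEP_SIGMA = 0.03
DEFAULT_MOMENTUM = 0.8
DEFAULT_DT = 0.025

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class AHVSeries:
    """Angular head velocity series on a regular time grid.

    ``values`` carry the units of the ``sigma`` that generated them
    (rad/s for analysis-facing series; rad/step inside the RNN, where the
    Euler step absorbs dt).
    """

    values: np.ndarray
    dt: float
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 1:
            raise ValueError("AHV series must be a nonempty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("AHV series must be finite")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HDSeries:
    """Head direction series: wrapped angle plus its accumulated integral."""

    theta: np.ndarray        # wrapped to [0, 2pi)
    theta_accum: np.ndarray  # unwrapped
    dt: float

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(
            self, "theta_accum", np.asarray(self.theta_accum, dtype=float)
        )
        if self.theta.shape != self.theta_accum.shape:
            raise ValueError("theta and theta_accum must be aligned")

    def __len__(self) -> int:
        return len(self.theta)


def simulate_ahv(
    n_steps: int,
    sigma: float = DEFAULT_STEP_SIGMA / DEFAULT_DT,
    momentum: float = DEFAULT_MOMENTUM,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
) -> AHVSeries:
    """Simulate an AR(1) angular-head-velocity series.

    ``v_t = sigma * X_t + momentum * v_{t-1}`` with ``X_t ~ N(0, 1)`` drawn
    fresh each step and ``v_0 = sigma * X_0``.  The stationary SD is
    ``sigma / sqrt(1 - momentum**2)``.

    Parameters
    ----------
    sigma:
        Innovation SD; defaults to 1.2 rad/s, which reproduces the 0.03
        rad-per-25 ms-step process driving the RNN.
    momentum:
        AR(1) coefficient in ``[0, 1)``; values >= 1 are rejected as
        nonstationary.
    """
    if not (0 <= momentum < 1):
        raise ValueError(f"momentum must be in [0, 1), got {momentum}")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n_steps)
    if momentum == 0.0:
        values = sigma * x
    else:
        values = np.empty(n_steps)
        v = 0.0
        for t in range(n_steps):
            v = sigma * x[t] + momentum * v
            values[t] = v
    return AHVSeries(values=values, dt=dt, seed=seed)


def integrate_heading(ahv: AHVSeries, theta0: float = 0.0) -> HDSeries:
    """Integrate AHV into a head-direction trajectory.

    ``theta_accum[t] = theta0 + sum_{k<=t} ahv[k] * dt``; the wrapped angle
    is ``theta_accum mod 2pi``.  This is the exact (noise-free) integral the
    RNN is trained to track.
    """
    accum = theta0 + np.cumsum(ahv.values) * ahv.dt
    return HDSeries(theta=np.mod(accum, TWO_PI), theta_accum=accum, dt=ahv.dt)


def vonmises_fwhm_to_kappa(fwhm: float) -> float:
    """Concentration of a von Mises bump with the given full width at half max.

    Solves ``exp(kappa * (cos(fwhm/2) - 1)) = 1/2``.
    """
    if not (0 < fwhm < TWO_PI):
        raise ValueError("fwhm must be in (0, 2pi)")
    return float(np.log(2.0) / (1.0 - np.cos(fwhm / 2.0)))


def vonmises_kappa_to_fwhm(kappa: float) -> float:
    """Inverse of :func:`vonmises_fwhm_to_kappa`."""
    c = 1.0 - np.log(2.0) / kappa
    if c <= -1.0:
        return TWO_PI  # bump so broad the half-max level is never crossed
    return float(2.0 * np.arccos(c))


def vonmises_fwhm_minsub(kappa: float) -> float:
    """FWHM of a von Mises rate curve after min subtraction.

    Tuning-width measurement subtracts the curve's minimum first, so for a
    broad bump (whose trough exp(-2 kappa) is well above zero) the measured
    width is narrower than the raw bump's: the crossing level solves
    ``exp(kappa (cos d - 1)) = (1 + exp(-2 kappa)) / 2``.
    """
    c = 1.0 + np.log((1.0 + np.exp(-2.0 * kappa)) / 2.0) / kappa
    if c <= -1.0:
        return TWO_PI
    return float(2.0 * np.arccos(c))


@dataclass
class SyntheticPopSpec:
    """Recipe for a synthetic SP/MP population.

    Attributes
    ----------
    n_sp, n_mp:
        Unit counts per class.
    sp_concentration_range:
        von Mises ``kappa`` range for SP units (log-uniform draw).
    mp_peak_count_range:
        Inclusive range of peaks per MP unit.
    mp_peak_width:
        FWHM of each MP bump, radians.
    ahv_gain_range:
        Per-unit linear AHV gain magnitude range, (rad/s)^-1; the rate is
        modulated by ``max(0, 1 + g * ahv)``.  Set to (0, 0) for no AHV
        modulation.
    ahv_gain_class:
        Which class carries AHV gain: "mp", "sp", "both" or "none".
    ahv_sign_mode:
        "symmetric" applies the gain at all velocities; "signed" gives each
        unit a preferred rotation sign and applies the gain only there.
    base_rate:
        Peak firing rate, Hz.
    noise_model:
        "none", "poisson" (spike counts per bin, the biological data path)
        or "gaussian" (additive rate noise, the RNN-like path).
    """

    n_sp: int = 40
    n_mp: int = 10
    sp_concentration_range: tuple[float, float] = (1.0, 8.0)
    mp_peak_count_range: tuple[int, int] = (2, 4)
    mp_peak_width: float = 0.5
    ahv_gain_range: tuple[float, float] = (0.15, 0.35)
    ahv_gain_class: str = "mp"
    ahv_sign_mode: str = "signed"
    base_rate: float = 10.0
    noise_model: str = "poisson"
    gaussian_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sp < 0 or self.n_mp < 0:
            raise ValueError("unit counts must be nonnegative")
        if self.sp_concentration_range[0] <= 0:
            raise ValueError("kappa must be positive")
        if not (0 < self.mp_peak_width < np.pi):
            raise ValueError("mp_peak_width must be in (0, pi)")
        if self.noise_model not in {"none", "poisson", "gaussian"}:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.ahv_gain_class not in {"mp", "sp", "both", "none"}:
            raise ValueError(f"unknown ahv_gain_class {self.ahv_gain_class!r}")
        if self.ahv_sign_mode not in {"symmetric", "signed"}:
            raise ValueError(f"unknown ahv_sign_mode {self.ahv_sign_mode!r}")


def _mp_centers(rng, n_peaks: int, peak_width: float) -> np.ndarray:
    # evenly spaced slots guarantee >= 2x-width separation (including the
    # wrap-around gap); jitter is bounded by the spacing slack
    min_sep = 2.0 * peak_width
    n_slots = int(TWO_PI // min_sep)
    if n_slots < n_peaks:
        raise ValueError(
            f"cannot place {n_peaks} peaks of width {peak_width} with "
            "2x-width separation on the circle"
        )
    spacing = TWO_PI / n_slots
    max_jitter = 0.5 * (spacing - min_sep)
    slots = rng.choice(n_slots, size=n_peaks, replace=False)
    jitter = rng.uniform(-max_jitter, max_jitter, size=n_peaks)
    return np.mod(slots * spacing + jitter + rng.uniform(0, TWO_PI), TWO_PI)


def _unit_profiles(spec: SyntheticPopSpec, rng) -> list[dict]:
    """Draw per-unit ground-truth tuning parameters."""
    units: list[dict] = []
    lo, hi = spec.sp_concentration_range
    for i in range(spec.n_sp):
        kappa = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        units.append(
            {
                "kind": "SP",
                "mu": float(rng.uniform(0, TWO_PI)),
                "kappa": kappa,
                # ground truth follows the measurement convention
                # (min-subtracted half-max width)
                "fwhm": vonmises_fwhm_minsub(kappa),
            }
        )
    kmin, kmax = spec.mp_peak_count_range
    for i in range(spec.n_mp):
        n_peaks = int(rng.integers(kmin, kmax + 1))
        centers = _mp_centers(rng, n_peaks, spec.mp_peak_width)
        units.append(
            {
                "kind": "MP",
                "centers": [float(c) for c in centers],
                "kappa": vonmises_fwhm_to_kappa(spec.mp_peak_width),
                "fwhm": spec.mp_peak_width,
            }
        )
    glo, ghi = spec.ahv_gain_range
    for u in units:
        gained = spec.ahv_gain_class == "both" or (
            spec.ahv_gain_class != "none"
            and u["kind"] == spec.ahv_gain_class.upper()
        )
        u["ahv_gain"] = float(rng.uniform(glo, ghi)) if gained else 0.0
        u["ahv_sign"] = (
            int(rng.choice([-1, 1]))
            if (gained and spec.ahv_sign_mode == "signed")
            else 0
        )
    return units


def _noise_free_rates(units: list[dict], theta: np.ndarray, base_rate: float):
    rates = np.empty((len(units), len(theta)))
    for i, u in enumerate(units):
        if u["kind"] == "SP":
            prof = np.exp(u["kappa"] * (np.cos(theta - u["mu"]) - 1.0))
        else:
            prof = np.zeros_like(theta)
            for c in u["centers"]:
                prof += np.exp(u["kappa"] * (np.cos(theta - c) - 1.0))
            prof /= prof.max()
        rates[i] = base_rate * prof
    return rates


def generate_population(
    spec: SyntheticPopSpec, hd: HDSeries, ahv: AHVSeries
) -> Session:
    """Render a synthetic population onto a head trajectory.

    Ground-truth unit parameters (class, preferred directions, widths, AHV
    gains) are stored in ``session.meta["ground_truth"]`` so that recovery
    tests can compare estimated statistics against them.
    """
    if len(hd) != len(ahv):
        raise ValueError("hd and ahv must be aligned")
    if len(hd) == 0:
        raise ValueError("empty trajectory")
    rng = np.random.default_rng(spec.seed)
    units = _unit_profiles(spec, rng)
    rates = _noise_free_rates(units, hd.theta, spec.base_rate)

    for i, u in enumerate(units):
        if u["ahv_gain"] == 0.0:
            continue
        if u["ahv_sign"] == 0:
            # symmetric: faster turning in either direction raises the rate
            drive = np.abs(ahv.values)
        else:
            # sign-specific: only turns in the preferred direction modulate
            drive = np.where(
                np.sign(ahv.values) == u["ahv_sign"], np.abs(ahv.values), 0.0
            )
        rates[i] *= np.clip(1.0 + u["ahv_gain"] * drive, 0.0, None)

    if spec.noise_model == "poisson":
        rates = rng.poisson(np.clip(rates, 0, None) * ahv.dt) / ahv.dt
    elif spec.noise_model == "gaussian":
        rates = np.clip(
            rates + rng.normal(0.0, spec.gaussian_noise_sd, rates.shape), 0.0, None
        )

    labels = [u["kind"] for u in units]
    return Session(
        hd=hd.theta,
        ahv=ahv.values,
        rates=rates,
        dt=ahv.dt,
        unit_ids=[f"{u['kind'].lower()}{i:03d}" for i, u in enumerate(units)],
        meta={
            "source": "synthetic",
            "seed": spec.seed,
            "ground_truth": units,
            "labels": labels,
            "base_rate": spec.base_rate,
            "noise_model": spec.noise_model,
        },
    )


def make_session(
    spec: SyntheticPopSpec,
    n_steps: int = 80_000,
    dt: float = DEFAULT_DT,
    seed: int | None = None,
) -> Session:
    """Convenience: trajectory + population in one call.

    The trajectory uses the study's AR(1) velocity process converted to
    rad/s at the given bin width.
    """
    seed = spec.seed if seed is None else seed
    ahv = simulate_ahv(
        n_steps, sigma=DEFAULT_STEP_SIGMA / dt, momentum=DEFAULT_MOMENTUM,
        dt=dt, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    hd = integrate_heading(ahv, theta0=float(rng.uniform(0, TWO_PI)))
    return generate_population(spec, hd, ahv)
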