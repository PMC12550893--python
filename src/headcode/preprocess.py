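"""Behavioral and spike preprocessing for extracellular recordings.

Tracked head angles and per-unit spike timestamps are converted to aligned
HD, AHV and firing-rate series on a common 25 ms grid:

* the wrapped angle is circularly unwrapped to an accumulated angle and
  smoothed with a Gaussian kernel (sigma = 200 ms, truncated at 3 sigma per
  side and renormalized to unit sum);
* AHV is the accumulated angle convolved with a derivative-of-Gaussian
  kernel, normalized so that a unit ramp yields exactly its slope
  (counterclockwise positive);
* spike trains are binned and convolved with the same Gaussian kernel, so
  each spike contributes unit mass before conversion to Hz.

Samples closer than 3 sigma to a segment edge keep a validity mask bit so
tuning statistics can exclude kernel-truncation artifacts; the choice of
edge policy is a package decision, recorded here because upstream
conventions vary.
"""

from __future__ import annotations

import numpy as np

from .session import Session
from .synth import AHVSeries, HDSeries

__all__ = [
    "gaussian_kernel",
    "gaussian_derivative_kernel",
    "unwrap_and_smooth_angle",
    "angular_velocity",
    "spikes_to_rates",
    "build_session",
    "edge_mask",
]

DEFAULT_SIGMA_S = 0.200
DEFAULT_STEP_S = 0.025


def _half_width(sigma: float, step: float) -> int:
    """Kernel half-width in samples: 3 sigma per side (6 sigma total span)."""
    return max(1, int(round(3.0 * sigma / step)))


def gaussian_kernel(sigma: float = DEFAULT_SIGMA_S, step: float = DEFAULT_STEP_S):
    """Discrete Gaussian window, truncated at 3 sigma, unit sum."""
    k = _half_width(sigma, step)
    x = np.arange(-k, k + 1) * step
    g = np.exp(-0.5 * (x / sigma) ** 2)
    return g / g.sum()


def gaussian_derivative_kernel(
    sigma: float = DEFAULT_SIGMA_S, step: float = DEFAULT_STEP_S
):
    """Derivative-of-Gaussian window normalized to unit ramp response.

    ``G'(x) = G(x) * (x - mu) / sigma^2`` sampled on the grid, then scaled so
    convolving a ramp of slope ``w`` returns exactly ``w`` at interior
    samples.
    """
    k = _half_width(sigma, step)
    x = np.arange(-k, k + 1) * step
    g = np.exp(-0.5 * (x / sigma) ** 2)
    d = g * x / sigma**2
    # convolution flips the kernel: response to ramp slope 1 is
    # -step * sum(i * d[i]); normalize that response to 1
    idx = np.arange(-k, k + 1)
    ramp_response = -step * np.sum(idx * d)
    return d / ramp_response


def edge_mask(n: int, sigma: float = DEFAULT_SIGMA_S, step: float = DEFAULT_STEP_S):
    """Validity mask: False within 3 sigma of either series edge."""
    k = _half_width(sigma, step)
    mask = np.ones(n, dtype=bool)
    mask[:k] = False
    if k > 0:
        mask[-k:] = False
    return mask


def unwrap_and_smooth_angle(
    times: np.ndarray,
    raw_theta: np.ndarray,
    sigma: float = DEFAULT_SIGMA_S,
    step: float = DEFAULT_STEP_S,
    max_gap: float = 1.0,
) -> HDSeries:
    """Unwrap tracked head angles and smooth on a regular grid.

    Parameters
    ----------
    times, raw_theta:
        Tracking samples: seconds and wrapped angles (either ``[0, 2pi)`` or
        ``(-pi, pi]``).  Need not be regularly sampled; NaN angles mark
        tracking dropouts.
    max_gap:
        Longest dropout (seconds) bridged by linear interpolation of the
        accumulated angle; longer gaps raise, since splicing across them
        would fabricate velocities.
    """
    times = np.asarray(times, dtype=float)
    raw_theta = np.asarray(raw_theta, dtype=float)
    ok = np.isfinite(raw_theta) & np.isfinite(times)
    if ok.sum() < 2:
        raise ValueError("need at least two tracked samples")
    gaps = np.diff(times[ok])
    if np.any(gaps > max_gap):
        raise ValueError(
            f"tracking gap of {gaps.max():.3f}s exceeds max_gap={max_gap}s; "
            "split the session into segments"
        )
    accum = np.unwrap(raw_theta[ok])
    grid = np.arange(times[ok][0], times[ok][-1] + step / 2, step)
    accum_grid = np.interp(grid, times[ok], accum)
    kernel = gaussian_kernel(sigma, step)
    k = _half_width(sigma, step)
    # edge padding only stabilizes the (masked) boundary samples
    padded = np.pad(accum_grid, k, mode="edge")
    smoothed = np.convolve(padded, kernel, mode="valid")
    return HDSeries(
        theta=np.mod(smoothed, 2 * np.pi), theta_accum=smoothed, dt=step
    )


def angular_velocity(
    hd: HDSeries, sigma: float = DEFAULT_SIGMA_S
) -> AHVSeries:
    """AHV from the accumulated angle via a smoothed-derivative kernel."""
    step = hd.dt
    kernel = gaussian_derivative_kernel(sigma, step)
    k = _half_width(sigma, step)
    if len(hd) < len(kernel):
        raise ValueError(
            f"series of {len(hd)} samples is shorter than the {len(kernel)}-"
            "sample derivative window"
        )
    padded = np.pad(hd.theta_accum, k, mode="edge")
    vel = np.convolve(padded, kernel, mode="valid")
    return AHVSeries(values=vel, dt=step)


def spikes_to_rates(
    timestamps: np.ndarray,
    grid_start: float,
    n_bins: int,
    sigma: float = DEFAULT_SIGMA_S,
    step: float = DEFAULT_STEP_S,
    output: str = "hz",
) -> np.ndarray:
    """Smoothed firing rate of one spike train on the analysis grid.

    Spikes are counted per bin and convolved with the unit-sum Gaussian
    window, so total mass equals the spike count; ``output="hz"`` divides by
    the bin width.  An empty train yields a zero series.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.size and np.any(np.diff(timestamps) < 0):
        raise ValueError("spike timestamps must be sorted ascending")
    edges = grid_start + np.arange(n_bins + 1) * step
    counts, _ = np.histogram(timestamps, bins=edges)
    kernel = gaussian_kernel(sigma, step)
    k = _half_width(sigma, step)
    padded = np.pad(counts.astype(float), k, mode="constant")
    smoothed = np.convolve(padded, kernel, mode="valid")
    if output == "hz":
        return smoothed / step
    if output == "per_bin":
        return smoothed
    raise ValueError(f"unknown output {output!r}")


def build_session(
    track_times: np.ndarray,
    track_theta: np.ndarray,
    spike_trains: dict[str, np.ndarray],
    sigma: float = DEFAULT_SIGMA_S,
    step: float = DEFAULT_STEP_S,
    max_gap: float = 1.0,
) -> Session:
    """Full biological-path pipeline: tracking + spikes -> aligned Session."""
    hd = unwrap_and_smooth_angle(
        track_times, track_theta, sigma=sigma, step=step, max_gap=max_gap
    )
    ahv = angular_velocity(hd, sigma=sigma)
    t0 = float(np.asarray(track_times, dtype=float)[0])
    rates = np.vstack(
        [
            spikes_to_rates(ts, t0, len(hd), sigma=sigma, step=step)
            for ts in spike_trains.values()
        ]
    ) if spike_trains else np.zeros((0, len(hd)))
    return Session(
        hd=hd.theta,
        ahv=ahv.values,
        rates=rates,
        dt=step,
        unit_ids=list(spike_trains.keys()),
        valid=edge_mask(len(hd), sigma, step),
        meta={"source": "recording", "sigma_s": sigma, "grid_start": t0},
    )
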