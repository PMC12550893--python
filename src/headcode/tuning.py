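"""Single-unit tuning statistics for head direction and angular velocity.

For each unit this module computes:

* HD and AHV tuning curves (50 equal HD bins over ``[0, 2pi)``; 0.2 rad/s
  AHV bins), with per-bin SDs from 50 half-sample permutations;
* ``MI_HD`` — Skaggs-style mutual information between HD and firing rate,
  ``MI = sum_i p(i) fr(i) log2(fr(i)/fr)`` in bits/s (or bits/spike after
  dividing by the mean rate);
* ``Pr_AHV`` — the maximum over rotation signs of the absolute partial
  Pearson correlation between rate and AHV controlling for HD;
* shuffle significance of either statistic against a circular-shift null
  (random shift of at least 30 s, 99th percentile criterion);
* mean vector length (MVL, Rayleigh r) of the HD tuning curve;
* the two-rule single-peaked / multipeaked (SP/MP) classifier with
  strictness parameter alpha;
* FWHM of tuning peaks (mean over qualified peaks for MP units);
* the piecewise-linear fit of Pr_AHV against MI_HD with model comparison
  against single-line, quadratic and exponential alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .session import Session

__all__ = [
    "TuningCurve",
    "ShuffleResult",
    "tuning_curve",
    "mutual_information_hd",
    "mean_vector_length",
    "pr_ahv",
    "partial_corr",
    "shuffle_significance",
    "classify_sp_mp",
    "fwhm",
    "compute_unit_metrics",
    "piecewise_mi_pr_fit",
]

N_HD_BINS = 50
AHV_BIN_WIDTH = 0.2  # rad/s
TWO_PI = 2.0 * np.pi


# ----------------------------------------------------------------------
# tuning curves
@dataclass
class TuningCurve:
    """Binned mean firing rate against HD or AHV."""

    kind: str                 # "hd" or "ahv"
    bin_edges: np.ndarray
    mean_rate: np.ndarray     # NaN where unoccupied
    occupancy_p: np.ndarray   # sums to 1 over occupied bins
    sd: np.ndarray | None = None
    unit_id: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy_p > 0

    @property
    def n_bins(self) -> int:
        return len(self.mean_rate)


def _bin_means(values: np.ndarray, bin_idx: np.ndarray, n_bins: int):
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    sums = np.bincount(bin_idx, weights=values, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def tuning_curve(
    session: Session,
    unit: str | int,
    kind: str = "hd",
    n_permutations: int = 50,
    seed: int | None = None,
) -> TuningCurve:
    """Mean firing rate per HD (or AHV) bin over valid samples.

    Per-bin SDs come from ``n_permutations`` tuning curves, each built from
    a randomly selected half of the samples.
    """
    i = session.unit_index(unit)
    rates = session.rates[i, session.valid]
    if kind == "hd":
        var = session.hd[session.valid]
        edges = np.linspace(0.0, TWO_PI, N_HD_BINS + 1)
        bin_idx = np.minimum((var / TWO_PI * N_HD_BINS).astype(int), N_HD_BINS - 1)
    elif kind == "ahv":
        var = session.ahv[session.valid]
        lo = np.floor(var.min() / AHV_BIN_WIDTH) * AHV_BIN_WIDTH
        hi = np.ceil(var.max() / AHV_BIN_WIDTH) * AHV_BIN_WIDTH
        n_bins = max(1, int(round((hi - lo) / AHV_BIN_WIDTH)))
        edges = lo + np.arange(n_bins + 1) * AHV_BIN_WIDTH
        bin_idx = np.clip(((var - lo) / AHV_BIN_WIDTH).astype(int), 0, n_bins - 1)
    else:
        raise ValueError(f"unknown tuning-curve kind {kind!r}")

    n_bins = len(edges) - 1
    means, counts = _bin_means(rates, bin_idx, n_bins)
    occupancy = counts / counts.sum()

    sd = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        half = len(rates) // 2
        perm_curves = np.empty((n_permutations, n_bins))
        for p in range(n_permutations):
            pick = rng.choice(len(rates), size=half, replace=False)
            perm_curves[p], _ = _bin_means(rates[pick], bin_idx[pick], n_bins)
        sd = np.nanstd(perm_curves, axis=0)

    return TuningCurve(
        kind=kind,
        bin_edges=edges,
        mean_rate=means,
        occupancy_p=occupancy,
        sd=sd,
        unit_id=session.unit_ids[i],
    )


# ----------------------------------------------------------------------
# information and vector-length statistics
def mutual_information_hd(tc: TuningCurve) -> tuple[float, float]:
    """Skaggs mutual information of an HD tuning curve.

    Returns ``(bits_per_second, bits_per_spike)``.  Unoccupied bins are
    excluded (occupancy renormalized); zero-rate bins contribute nothing;
    a silent unit has MI 0 by definition.
    """
    occ = tc.occupied
    p = tc.occupancy_p[occ]
    p = p / p.sum()
    fr_i = tc.mean_rate[occ]
    fr = float(np.sum(p * fr_i))
    if fr <= 0:
        return 0.0, 0.0
    pos = fr_i > 0
    bits_per_s = float(np.sum(p[pos] * fr_i[pos] * np.log2(fr_i[pos] / fr)))
    return bits_per_s, bits_per_s / fr


def mean_vector_length(tc: TuningCurve) -> float:
    """Rayleigh r of the rate-weighted circular mean over bin centers.

    1 for a single concentrated peak, ~0 for uniform or symmetric
    multi-peak curves; undefined (NaN) for an all-zero curve.
    """
    if tc.kind != "hd":
        raise ValueError("MVL is defined for HD tuning curves")
    occ = tc.occupied
    lam = tc.mean_rate[occ]
    theta = tc.bin_centers[occ]
    total = lam.sum()
    if total <= 0:
        return float("nan")
    return float(np.abs(np.sum(lam * np.exp(1j * theta))) / total)


# ----------------------------------------------------------------------
# AHV partial correlation
def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """Partial Pearson correlation of x and y controlling for z:
    ``(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))``.
    """
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0 or not np.isfinite(denom):
        return float("nan")
    return float((r_xy - r_xz * r_yz) / denom)


def _pr_from_series(
    rates: np.ndarray,
    ahv: np.ndarray,
    hd: np.ndarray,
    min_samples: int = 100,
) -> float:
    vals = []
    for sign in (1.0, -1.0):
        sel = ahv * sign > 0
        if sel.sum() < min_samples:
            continue
        r, a, h = rates[sel], ahv[sel], hd[sel]
        if r.std() == 0 or a.std() == 0 or h.std() == 0:
            continue
        pr = partial_corr(r, a, h)
        if np.isfinite(pr):
            vals.append(abs(pr))
    return max(vals) if vals else float("nan")


def pr_ahv(
    session: Session,
    unit: str | int,
    min_samples: int = 100,
    conditioning: str = "wrapped",
) -> float:
    """AHV tuning strength of one unit.

    Within each rotation-sign subset (counterclockwise AHV > 0, clockwise
    AHV < 0) the absolute partial Pearson correlation between firing rate
    and AHV is computed controlling for HD; the larger of the two is
    returned.  ``conditioning="wrapped"`` controls for the raw wrapped
    angle; ``"cos_sin"`` partials out both circular components by linear
    regression before correlating, for sensitivity analyses.
    """
    i = session.unit_index(unit)
    v = session.valid
    rates, ahv, hd = session.rates[i, v], session.ahv[v], session.hd[v]
    if conditioning == "wrapped":
        return _pr_from_series(rates, ahv, hd, min_samples)
    if conditioning != "cos_sin":
        raise ValueError(f"unknown conditioning {conditioning!r}")
    vals = []
    for sign in (1.0, -1.0):
        sel = ahv * sign > 0
        if sel.sum() < min_samples:
            continue
        z = np.column_stack(
            [np.ones(sel.sum()), np.cos(hd[sel]), np.sin(hd[sel])]
        )
        res_r = rates[sel] - z @ np.linalg.lstsq(z, rates[sel], rcond=None)[0]
        res_a = ahv[sel] - z @ np.linalg.lstsq(z, ahv[sel], rcond=None)[0]
        if res_r.std() == 0 or res_a.std() == 0:
            continue
        vals.append(abs(np.corrcoef(res_r, res_a)[0, 1]))
    return max(vals) if vals else float("nan")


# ----------------------------------------------------------------------
# shuffle significance
@dataclass
class ShuffleResult:
    significant: bool
    observed: float
    threshold: float
    null: np.ndarray = field(repr=False, default=None)


def shuffle_significance(
    session: Session,
    unit: str | int,
    metric: str = "mi",
    n_shuffles: int = 1000,
    min_shift: float = 30.0,
    level: float = 0.99,
    seed: int | None = None,
    keep_null: bool = False,
) -> ShuffleResult:
    """Circular-shift significance test for MI_HD or Pr_AHV.

    The rate series is circularly shifted by a random interval of at least
    ``min_shift`` seconds (wrapping the end to the beginning), ``n_shuffles``
    times; the unit is significant if the observed statistic exceeds the
    ``level`` quantile of the shuffled distribution.
    """
    if session.duration <= 2 * min_shift:
        raise ValueError(
            f"session of {session.duration:.0f}s is too short for "
            f"{min_shift:.0f}s circular shifts"
        )
    i = session.unit_index(unit)
    rng = np.random.default_rng(seed)
    n = session.n_samples
    min_bins = int(np.ceil(min_shift / session.dt))
    shifts = rng.integers(min_bins, n - min_bins, size=n_shuffles)

    v = session.valid
    hd = session.hd[v]
    ahv = session.ahv[v]
    rates_full = session.rates[i]
    hd_idx = np.minimum((hd / TWO_PI * N_HD_BINS).astype(int), N_HD_BINS - 1)
    counts = np.bincount(hd_idx, minlength=N_HD_BINS).astype(float)
    p = counts / counts.sum()

    def mi_of(rates):
        sums = np.bincount(hd_idx, weights=rates, minlength=N_HD_BINS)
        fr_i = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
        fr = float(np.sum(p * fr_i))
        if fr <= 0:
            return 0.0
        pos = fr_i > 0
        return float(np.sum(p[pos] * fr_i[pos] * np.log2(fr_i[pos] / fr)))

    if metric == "mi":
        stat = lambda r: mi_of(r)  # noqa: E731
    elif metric == "pr":
        stat = lambda r: _pr_from_series(r, ahv, hd)  # noqa: E731
    else:
        raise ValueError(f"unknown metric {metric!r}")

    observed = stat(rates_full[v])
    null = np.empty(n_shuffles)
    for s, shift in enumerate(shifts):
        null[s] = stat(np.roll(rates_full, shift)[v])
    null = null[np.isfinite(null)]
    threshold = float(np.quantile(null, level)) if len(null) else float("inf")
    return ShuffleResult(
        significant=bool(np.isfinite(observed) and observed > threshold),
        observed=float(observed),
        threshold=threshold,
        null=null if keep_null else None,
    )


# ----------------------------------------------------------------------
# SP/MP classification
def _peak_range(curve: np.ndarray, peak: int, level: float) -> np.ndarray:
    """Contiguous circular run of bins around ``peak`` with rate >= level."""
    n = len(curve)
    in_range = np.zeros(n, dtype=bool)
    in_range[peak] = True
    j = peak
    for _ in range(n - 1):
        j = (j + 1) % n
        if curve[j] >= level and not in_range[j]:
            in_range[j] = True
        else:
            break
    j = peak
    for _ in range(n - 1):
        j = (j - 1) % n
        if curve[j] >= level and not in_range[j]:
            in_range[j] = True
        else:
            break
    return in_range


def classify_sp_mp(tc: TuningCurve, alpha: float = 0.10) -> str:
    """Two-rule SP/MP classifier with strictness parameter ``alpha``.

    A unit is single-peaked iff (i) no bin outside the contiguous half-peak
    range around the global maximum exceeds half of the maximum response,
    and (ii) fewer than ``alpha`` of bins outside the 20%-peak range exceed
    20% of the maximum.  Lower alpha makes SP stricter.  Flat curves are
    "untuned".  Classification is monotone in alpha by construction.
    """
    occ = tc.occupied
    curve = np.where(occ, tc.mean_rate, 0.0)
    peak_rate = np.nanmax(curve)
    if not np.isfinite(peak_rate) or peak_rate <= 0 or occ.sum() < 2:
        return "untuned"
    if np.allclose(curve[occ], curve[occ][0]):
        return "untuned"
    peak = int(np.nanargmax(curve))

    half = 0.5 * peak_rate
    half_range = _peak_range(curve, peak, half)
    if np.any(curve[~half_range] > half):
        return "MP"

    low = 0.2 * peak_rate
    low_range = _peak_range(curve, peak, low)
    n_outside_hot = int(np.sum(curve[~low_range] > low))
    if n_outside_hot >= alpha * tc.n_bins:
        return "MP"
    return "SP"


# ----------------------------------------------------------------------
# FWHM
def _half_crossings(curve: np.ndarray, peak: int, level: float, bin_width: float):
    """Angular half-span from ``peak`` to the ``level`` crossing, each side.

    Works on a circular curve; crossings are linearly interpolated between
    bins.  Returns (left_span, right_span), NaN where the curve never drops
    below ``level`` on that side before wrapping back to the peak.
    """
    n = len(curve)

    def span(direction: int) -> float:
        prev = curve[peak]
        for step in range(1, n):
            j = (peak + direction * step) % n
            cur = curve[j]
            if cur < level:
                frac = (prev - level) / (prev - cur) if prev != cur else 1.0
                return (step - 1 + frac) * bin_width
            prev = cur
        return float("nan")

    return span(-1), span(+1)


def fwhm(
    tc: TuningCurve,
    mode: str = "sp",
    min_separation_bins: int = 10,
) -> tuple[float, int]:
    """Full width at half maximum of tuning peaks, in radians.

    The curve is first normalized by subtracting its minimum.  In SP mode
    the width is the angular span between the half-maximum crossings around
    the global peak.  In MP mode local maxima are detected circularly with
    the given minimum separation (in bins); a peak qualifies if at least one
    flank drops below half of its height — its width is the full span when
    both flanks cross, else twice the detectable half-span — and the mean
    width over qualified peaks is returned.

    Returns ``(width_rad, n_qualified_peaks)``; ``(nan, 0)`` when no peak
    qualifies.
    """
    occ = tc.occupied
    if occ.sum() < 3:
        return float("nan"), 0
    curve = np.where(occ, tc.mean_rate, np.nanmin(tc.mean_rate))
    curve = curve - np.nanmin(curve)
    bin_width = float(tc.bin_edges[1] - tc.bin_edges[0])
    n = len(curve)
    if np.nanmax(curve) <= 0:
        return float("nan"), 0

    if mode.lower() == "sp":
        peak = int(np.nanargmax(curve))
        level = 0.5 * curve[peak]
        left, right = _half_crossings(curve, peak, level, bin_width)
        if np.isnan(left) and np.isnan(right):
            return float("nan"), 0
        if np.isnan(left):
            return 2.0 * right, 1
        if np.isnan(right):
            return 2.0 * left, 1
        return left + right, 1

    if mode.lower() != "mp":
        raise ValueError(f"unknown FWHM mode {mode!r}")

    # circular peak detection: tile the curve, keep maxima in the middle copy
    tiled = np.concatenate([curve, curve, curve])
    peaks, _ = find_peaks(tiled, distance=min_separation_bins)
    peaks = sorted({int(p - n) for p in peaks if n <= p < 2 * n})
    widths = []
    for peak in peaks:
        level = 0.5 * curve[peak]
        if level <= 0:
            continue
        left, right = _half_crossings(curve, peak, level, bin_width)
        if np.isnan(left) and np.isnan(right):
            continue  # not a qualified peak: no flank drops below half-max
        if np.isnan(left):
            widths.append(2.0 * right)
        elif np.isnan(right):
            widths.append(2.0 * left)
        else:
            widths.append(left + right)
    if not widths:
        return float("nan"), 0
    return float(np.mean(widths)), len(widths)


# ----------------------------------------------------------------------
# per-session metrics table
def compute_unit_metrics(
    session: Session,
    alpha: float = 0.10,
    n_shuffles: int = 1000,
    seed: int | None = None,
    min_separation_bins: int = 10,
    classifier: str = "rules",
    mvl_threshold: float = 0.5,
    min_mean_rate: float = 1e-4,
    shuffle: bool = True,
) -> pd.DataFrame:
    """All single-unit statistics for one session, one row per unit.

    ``classifier="rules"`` applies the two-rule SP/MP test (biological
    path); ``"mvl"`` splits at ``mvl_threshold`` (the automated version of
    the visual-inspection split used for RNN units, justified by the bimodal
    MVL distribution).  Units below ``min_mean_rate`` are labeled
    "excluded"; HD-nonsignificant units are "untuned".
    """
    rows = []
    rng = np.random.default_rng(seed)
    for uid in session.unit_ids:
        i = session.unit_index(uid)
        mean_rate = float(session.rates[i, session.valid].mean())
        row = {"unit_id": uid, "mean_rate": mean_rate}
        if mean_rate < min_mean_rate:
            row.update(
                mi_hd=np.nan, mi_per_spike=np.nan, pr_ahv=np.nan, mvl=np.nan,
                fwhm=np.nan, n_peaks=0, hd_sig=False, ahv_sig=False,
                label="excluded",
            )
            rows.append(row)
            continue
        tc = tuning_curve(session, uid, "hd", seed=int(rng.integers(2**31)))
        mi_s, mi_spk = mutual_information_hd(tc)
        mvl = mean_vector_length(tc)
        pr = pr_ahv(session, uid)
        row.update(mi_hd=mi_s, mi_per_spike=mi_spk, pr_ahv=pr, mvl=mvl)

        if shuffle:
            hd_sig = shuffle_significance(
                session, uid, "mi", n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)),
            ).significant
            ahv_sig = shuffle_significance(
                session, uid, "pr", n_shuffles=n_shuffles,
                seed=int(rng.integers(2**31)),
            ).significant
        else:
            hd_sig, ahv_sig = True, True
        row.update(hd_sig=hd_sig, ahv_sig=ahv_sig)

        if not hd_sig:
            label = "untuned"
        elif classifier == "mvl":
            label = "MP" if mvl < mvl_threshold else "SP"
        elif classifier == "rules":
            label = classify_sp_mp(tc, alpha=alpha)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        width, n_peaks = fwhm(
            tc,
            mode="mp" if label == "MP" else "sp",
            min_separation_bins=min_separation_bins,
        )
        row.update(fwhm=width, n_peaks=n_peaks, label=label)
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


# ----------------------------------------------------------------------
# MI–Pr relationship models
def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def piecewise_mi_pr_fit(
    mi: np.ndarray, pr: np.ndarray, n_breaks: int = 200
) -> dict:
    """Continuous two-segment linear fit of Pr_AHV on MI_HD.

    The breakpoint is chosen by grid search over interior MI values; the fit
    is least squares on the basis ``[1, min(x-c, 0), max(x-c, 0)]`` so the
    two lines join at the break.  R-squared is also reported for single-line,
    quadratic and exponential (``a*exp(b*x)+c``) alternatives.
    """
    x = np.asarray(mi, dtype=float)
    y = np.asarray(pr, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 10:
        raise ValueError(f"need at least 10 units, got {len(x)}")

    candidates = np.quantile(x, np.linspace(0.05, 0.95, n_breaks))
    best = None
    for c in np.unique(candidates):
        design = np.column_stack(
            [np.ones_like(x), np.minimum(x - c, 0.0), np.maximum(x - c, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        ss = float(np.sum((y - design @ coef) ** 2))
        if best is None or ss < best[0]:
            best = (ss, c, coef)
    _, c, coef = best
    yhat = (
        coef[0]
        + coef[1] * np.minimum(x - c, 0.0)
        + coef[2] * np.maximum(x - c, 0.0)
    )
    result = {
        "break": float(c),
        "slope_lo": float(coef[1]),
        "slope_hi": float(coef[2]),
        "r2": _r2(y, yhat),
    }

    lin = np.polyfit(x, y, 1)
    result["r2_linear"] = _r2(y, np.polyval(lin, x))
    result["slope_linear"] = float(lin[0])
    quad = np.polyfit(x, y, 2)
    result["r2_quadratic"] = _r2(y, np.polyval(quad, x))
    try:
        scale = max(x.std(), 1e-12)
        popt, _ = curve_fit(
            lambda t, a, b, c0: a * np.exp(b * t) + c0,
            x, y, p0=(y.max() - y.min(), -1.0 / scale, y.min()),
            maxfev=20000,
        )
        result["r2_exponential"] = _r2(
            y, popt[0] * np.exp(popt[1] * x) + popt[2]
        )
    except RuntimeError:
        result["r2_exponential"] = float("nan")
    return result
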