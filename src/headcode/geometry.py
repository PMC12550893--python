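"""Representational geometry of the head-direction manifold.

Population states are z-scored per unit and averaged within 360 HD bins,
tracing a closed ring in N-dimensional activity space.  Two summaries
quantify its richness:

* effective dimensionality ``ED = (sum lambda)^2 / sum lambda^2`` over the
  covariance eigenvalues — a participation ratio between 1 and the
  embedding dimension, computed on the full z-scored time series;
* trajectory length — the cumulative Euclidean distance between adjacent
  bin states, a proxy for local representational resolution (adjacent
  headings far apart in state space are easy to tell apart, which is what
  resolving angular velocity requires).

The module also builds FWHM-ordered SP subpopulations and runs the
replacement experiment in which a growing fraction of a single-peaked
subpopulation is swapped for multipeaked units while tracking changes in
trajectory length and decoding skill.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .decoding import DecoderSpec, decode
from .session import Session

__all__ = [
    "Manifold",
    "effective_dimension",
    "trajectory_length",
    "build_manifold",
    "split_by_fwhm",
    "replacement_experiment",
]

TWO_PI = 2.0 * np.pi
N_MANIFOLD_BINS = 360


def effective_dimension(points: np.ndarray) -> float:
    """Participation-ratio dimensionality of a point cloud.

    ``(sum_k lambda_k)^2 / sum_k lambda_k^2`` over the eigenvalues of the
    covariance of ``points`` (samples x dims): 1 for a rank-1 cloud, d for
    an isotropic one.  Invariant to rotation and overall scaling.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise ValueError("need a (samples, dims) array with >= 2 samples")
    c = np.cov(points, rowvar=False)
    c = np.atleast_2d(c)
    lam = np.linalg.eigvalsh(c)
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0:
        return float("nan")
    return float(total**2 / np.sum(lam**2))


def trajectory_length(states: np.ndarray, close_ring: bool = False) -> float:
    """Cumulative Euclidean distance between adjacent bin states.

    ``close_ring`` adds the segment from the last bin back to the first;
    the open path is the default.
    """
    states = np.asarray(states, dtype=float)
    if states.ndim != 2 or states.shape[0] < 2:
        raise ValueError("need at least 2 bin states")
    diffs = np.diff(states, axis=0)
    length = float(np.sum(np.linalg.norm(diffs, axis=1)))
    if close_ring:
        length += float(np.linalg.norm(states[0] - states[-1]))
    return length


@dataclass
class Manifold:
    """Binned, z-scored population representation of the HD circle."""

    states: np.ndarray       # (360, n_units)
    bin_centers: np.ndarray
    unit_ids: list[str]
    ed: float                # on the full z-scored time series
    ed_binned: float         # on the 360 bin states
    l_trajectory: float
    interpolated_bins: list[int]


def build_manifold(
    session: Session,
    units,
    n_bins: int = N_MANIFOLD_BINS,
    close_ring: bool = False,
) -> Manifold:
    """HD manifold of a unit subpopulation.

    Each unit's rate series is z-scored across the whole session, then
    averaged within ``n_bins`` equal HD bins.  Zero-variance units are
    dropped with a warning; unoccupied bins are filled by circular linear
    interpolation and recorded.  ED is computed on the full z-scored time
    series (the binned-state variant is also reported).
    """
    sub = session.select_units(units)
    v = sub.valid
    rates = sub.rates[:, v]
    sd = rates.std(axis=1)
    keep = sd > 0
    if not np.all(keep):
        import warnings

        dropped = [u for u, k in zip(sub.unit_ids, keep) if not k]
        warnings.warn(f"dropping zero-variance units: {dropped}")
    if keep.sum() == 0:
        raise ValueError("no unit with nonzero rate variance")
    uids = [u for u, k in zip(sub.unit_ids, keep) if k]
    z = (rates[keep] - rates[keep].mean(axis=1, keepdims=True)) / sd[
        keep, None
    ]

    hd = sub.hd[v]
    bin_idx = np.minimum((hd / TWO_PI * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    states = np.full((n_bins, keep.sum()), np.nan)
    for i in range(keep.sum()):
        sums = np.bincount(bin_idx, weights=z[i], minlength=n_bins)
        states[:, i] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    empty = np.flatnonzero(counts == 0)
    if len(empty):
        occ = np.flatnonzero(counts > 0)
        centers = (np.arange(n_bins) + 0.5) * TWO_PI / n_bins
        for i in range(states.shape[1]):
            # periodic interpolation across unoccupied headings
            states[empty, i] = np.interp(
                centers[empty], centers[occ], states[occ, i], period=TWO_PI
            )

    return Manifold(
        states=states,
        bin_centers=(np.arange(n_bins) + 0.5) * TWO_PI / n_bins,
        unit_ids=uids,
        ed=effective_dimension(z.T),
        ed_binned=effective_dimension(states),
        l_trajectory=trajectory_length(states, close_ring=close_ring),
        interpolated_bins=[int(b) for b in empty],
    )


def split_by_fwhm(
    metrics: pd.DataFrame,
    n_groups: int = 7,
    group_size: int = 11,
) -> list[list[str]]:
    """FWHM-ordered SP subpopulations.

    SP units are sorted by FWHM (ties broken by unit id) and cut into
    ``n_groups`` contiguous groups of ``group_size``.  When the SP count
    does not divide evenly, units are split into near-equal contiguous
    groups instead and the deviation is recorded on the result.
    """
    sp = metrics[metrics["label"] == "SP"].copy()
    sp = sp[np.isfinite(sp["fwhm"])]
    if len(sp) < n_groups:
        raise ValueError(
            f"need at least {n_groups} SP units with FWHM, got {len(sp)}"
        )
    sp = sp.sort_values(["fwhm", "unit_id"], kind="mergesort")
    order = list(sp.index)
    capacity = n_groups * group_size
    if len(order) >= capacity:
        # drop the broadest leftovers
        order = order[:capacity]
        groups = [
            order[g * group_size : (g + 1) * group_size]
            for g in range(n_groups)
        ]
    else:
        groups = [list(chunk) for chunk in np.array_split(order, n_groups)]
    return groups


def replacement_experiment(
    session: Session,
    sp_groups: list[list[str]],
    mp_pool: list[str],
    fractions=(0.2, 0.4, 0.6, 0.8),
    replicates: int = 20,
    seed: int = 0,
    decoder_spec: DecoderSpec | None = None,
    decode_targets=("hd", "ahv"),
) -> pd.DataFrame:
    """Swap SP units for MP units and track manifold and decoding changes.

    For each SP subpopulation and replacement fraction, ``replicates``
    random substitutions (without replacement within the MP pool) are drawn;
    each replicate reports the change in trajectory length and, when
    ``decode_targets`` is non-empty, in decoding r for each target, all
    relative to the pure-SP baseline of that group.  Fractions that round to
    zero replaced units are skipped.
    """
    rng = np.random.default_rng(seed)
    base = decoder_spec or DecoderSpec()
    rows = []
    for g, group in enumerate(sp_groups):
        baseline = build_manifold(session, group)
        base_r = {}
        for target in decode_targets:
            res = decode(
                session, group, dc_replace(base, target=target),
                seed=int(rng.integers(2**31)), population_label=f"SP{g+1}",
            )
            base_r[target] = res.r
        for frac in fractions:
            n_replace = int(round(frac * len(group)))
            if n_replace == 0:
                continue
            if n_replace > len(mp_pool):
                raise ValueError(
                    f"MP pool of {len(mp_pool)} cannot supply "
                    f"{n_replace} replacements"
                )
            for rep in range(replicates):
                out = list(rng.choice(len(group), n_replace, replace=False))
                mp_in = list(rng.choice(len(mp_pool), n_replace, replace=False))
                hybrid = [
                    u for i, u in enumerate(group) if i not in out
                ] + [mp_pool[i] for i in mp_in]
                man = build_manifold(session, hybrid)
                row = dict(
                    group=g + 1,
                    fraction=frac,
                    replicate=rep,
                    n_replaced=n_replace,
                    delta_l=man.l_trajectory - baseline.l_trajectory,
                )
                for target in decode_targets:
                    res = decode(
                        session, hybrid, dc_replace(base, target=target),
                        seed=int(rng.integers(2**31)),
                        population_label=f"SP{g+1}+MP",
                    )
                    row[f"delta_r_{target}"] = res.r - base_r[target]
                rows.append(row)
    return pd.DataFrame(rows)
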