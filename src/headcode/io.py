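"""Readers for recording-style data layouts and session-inclusion filters.

The supported on-disk layout mirrors how multisite silicon-probe recordings
are commonly distributed: one plain-text timestamp file per sorted unit
(one spike time, in seconds, per line) plus a whitespace-delimited tracking
table of time / head-angle columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import build_session
from .session import Session

__all__ = [
    "read_spike_file",
    "read_angle_table",
    "load_recording_dir",
    "filter_sessions",
]


def read_spike_file(path: str | Path) -> np.ndarray:
    """One spike timestamp (seconds) per line; blank lines ignored."""
    text = Path(path).read_text().split()
    ts = np.asarray([float(x) for x in text], dtype=float)
    if ts.size and (np.any(ts < 0) or np.any(np.diff(ts) < 0)):
        raise ValueError(f"{path}: timestamps must be nonnegative ascending")
    return ts


def read_angle_table(path: str | Path):
    """Two whitespace-delimited columns: time (s), head angle (rad).

    Angle values of -1 (a common missing-sample sentinel in tracking files)
    and NaN are treated as dropouts.
    """
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected columns time, angle")
    t, theta = data[:, 0], data[:, 1].copy()
    theta[theta == -1] = np.nan
    return t, theta


def load_recording_dir(
    directory: str | Path,
    angle_file: str = "angles.txt",
    spike_glob: str = "*.spk.txt",
    **preprocess_kwargs,
) -> Session:
    """Assemble a Session from a directory of text files.

    ``angle_file`` is the tracking table; every file matching
    ``spike_glob`` contributes one unit named after its stem.
    """
    directory = Path(directory)
    t, theta = read_angle_table(directory / angle_file)
    trains = {
        p.name.split(".")[0]: read_spike_file(p)
        for p in sorted(directory.glob(spike_glob))
    }
    if not trains:
        raise ValueError(f"no spike files matching {spike_glob!r} in {directory}")
    return build_session(t, theta, trains, **preprocess_kwargs)


def filter_sessions(
    sessions: list[dict],
    min_samples: int = 30_000,
    min_per_class: int = 4,
):
    """Session-inclusion rule for population decoding.

    Each entry needs ``n_samples``, ``n_sp`` and ``n_mp``.  A session is
    included iff it has strictly more than ``min_samples`` samples (small
    cross-validation variance) and at least ``min_per_class`` units in both
    the SP and MP groups.  Returns ``(included, exclusion_log)``.
    """
    included, log = [], []
    for s in sessions:
        sid = s.get("id", "?")
        if s["n_samples"] <= min_samples:
            log.append(f"{sid}: only {s['n_samples']} samples (need > {min_samples})")
        elif s["n_sp"] < min_per_class or s["n_mp"] < min_per_class:
            log.append(
                f"{sid}: {s['n_sp']} SP / {s['n_mp']} MP units "
                f"(need >= {min_per_class} each)"
            )
        else:
            included.append(s)
    return included, log
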