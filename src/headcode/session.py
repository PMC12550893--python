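"""Time-aligned session container shared by every analysis stage.

A :class:`Session` holds a head-direction trajectory (HD, wrapped angle),
its angular head velocity (AHV), and a unit-by-time firing-rate matrix on a
common time grid.  Sessions come from three places: the synthetic population
generator, rollouts of a trained ring-integrator RNN, or preprocessed
extracellular recordings.  The on-disk form is a ``.npz`` array container
with a JSON sidecar describing units, bin width, seeds and any ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Session"]


def _strip_ext(path: str | Path) -> Path:
    """Drop a trailing .npz/.json (only), keeping dots in the stem intact."""
    path = Path(path)
    name = path.name
    for ext in (".npz", ".json"):
        if name.endswith(ext):
            return path.parent / name[: -len(ext)]
    return path


@dataclass
class Session:
    """Aligned HD / AHV / firing-rate data for one recording or simulation.

    Parameters
    ----------
    hd:
        Head direction per time bin, radians wrapped to ``[0, 2pi)``.
    ahv:
        Angular head velocity per time bin, rad/s; counterclockwise positive.
    rates:
        ``(n_units, n_samples)`` instantaneous firing rates.
    dt:
        Bin width in seconds.
    unit_ids:
        One identifier per row of ``rates``.
    valid:
        Boolean mask of samples usable for tuning statistics (edge bins of
        the smoothing kernel are flagged invalid by the preprocessing stage).
    meta:
        Free-form JSON-serializable metadata: seeds, generator ground truth,
        trial seams, provenance.
    """

    hd: np.ndarray
    ahv: np.ndarray
    rates: np.ndarray
    dt: float
    unit_ids: list[str] = field(default_factory=list)
    valid: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hd = np.asarray(self.hd, dtype=float)
        self.ahv = np.asarray(self.ahv, dtype=float)
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        if self.hd.ndim != 1 or self.ahv.ndim != 1:
            raise ValueError("hd and ahv must be 1-D series")
        if len(self.hd) != len(self.ahv):
            raise ValueError("hd and ahv must be aligned (equal length)")
        if self.rates.shape[1] != len(self.hd):
            raise ValueError(
                f"rates has {self.rates.shape[1]} samples but hd has {len(self.hd)}"
            )
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.unit_ids:
            self.unit_ids = [f"u{i:03d}" for i in range(self.rates.shape[0])]
        if len(self.unit_ids) != self.rates.shape[0]:
            raise ValueError("unit_ids length must match number of rate rows")
        if self.valid is None:
            self.valid = np.ones(len(self.hd), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)

    # ------------------------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.rates.shape[1]

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.n_samples * self.dt

    @property
    def t(self) -> np.ndarray:
        """Time of each bin center, seconds from session start."""
        return (np.arange(self.n_samples) + 0.5) * self.dt

    def unit_index(self, unit: str | int) -> int:
        if isinstance(unit, (int, np.integer)):
            return int(unit)
        return self.unit_ids.index(unit)

    def mean_rates(self) -> np.ndarray:
        """Per-unit mean firing rate over valid samples."""
        return self.rates[:, self.valid].mean(axis=1)

    def select_units(self, units) -> "Session":
        """Return a view-like Session restricted to the given units."""
        idx = np.asarray([self.unit_index(u) for u in units], dtype=int)
        return Session(
            hd=self.hd,
            ahv=self.ahv,
            rates=self.rates[idx],
            dt=self.dt,
            unit_ids=[self.unit_ids[i] for i in idx],
            valid=self.valid,
            meta=dict(self.meta),
        )

    def exclude_silent(self, min_mean_rate: float = 1e-4) -> "Session":
        """Drop near-silent units before analysis.

        Units with mean rate below ``min_mean_rate`` carry no stable tuning
        and are removed from single-unit statistics.
        """
        keep = [
            uid
            for uid, m in zip(self.unit_ids, self.mean_rates())
            if m >= min_mean_rate
        ]
        out = self.select_units(keep)
        out.meta["excluded_low_rate"] = [
            uid for uid in self.unit_ids if uid not in keep
        ]
        return out

    # ------------------------------------------------------------------
    # serialization
    def save(self, path: str | Path) -> None:
        """Write ``<path>.npz`` arrays plus ``<path>.json`` metadata sidecar."""
        base = _strip_ext(path)
        np.savez(
            Path(str(base) + ".npz"),
            hd=self.hd,
            ahv=self.ahv,
            rates=self.rates,
            valid=self.valid,
        )
        sidecar = {
            "dt": self.dt,
            "unit_ids": list(self.unit_ids),
            "meta": self.meta,
        }
        Path(str(base) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Session":
        base = _strip_ext(path)
        with np.load(Path(str(base) + ".npz")) as arrays:
            hd = arrays["hd"]
            ahv = arrays["ahv"]
            rates = arrays["rates"]
            valid = arrays["valid"]
        sidecar = json.loads(Path(str(base) + ".json").read_text())
        return cls(
            hd=hd,
            ahv=ahv,
            rates=rates,
            dt=float(sidecar["dt"]),
            unit_ids=list(sidecar["unit_ids"]),
            valid=valid,
            meta=sidecar.get("meta", {}),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular export: time, hd, ahv, then one column per unit."""
        data = {"time": self.t, "hd": self.hd, "ahv": self.ahv}
        for uid, row in zip(self.unit_ids, self.rates):
            data[uid] = row
        return pd.DataFrame(data)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")
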