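"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` chains the stages — obtain a session (synthetic
population or trained-RNN rollout), compute single-unit metrics, classify
SP/MP, decode HD and AHV from each class, and characterize manifold
geometry — writing per-stage artifacts and a machine-readable summary.
Stage failures preserve partial results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import geometry, rnn, synth, tuning
from .decoding import DecoderSpec, decode

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full synthetic or RNN analysis run."""

    source: str = "synthetic"            # "synthetic" or "rnn"
    seed: int = 0
    out_dir: str = "headcode_out"
    n_steps: int = 60_000
    # synthetic-population stage
    pop: synth.SyntheticPopSpec = field(default_factory=synth.SyntheticPopSpec)
    # rnn stage
    rnn: rnn.RNNConfig = field(default_factory=rnn.RNNConfig)
    # analysis stage
    alpha: float = 0.10
    n_shuffles: int = 200
    classifier: str = "rules"
    run_decoding: bool = True
    run_geometry: bool = True
    decoder: DecoderSpec = field(default_factory=DecoderSpec)
    n_groups: int = 7
    group_size: int = 11
    min_samples: int = 30_000
    min_per_class: int = 4

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "pop" in kwargs:
            kwargs["pop"] = synth.SyntheticPopSpec(**kwargs["pop"])
        if "rnn" in kwargs:
            kwargs["rnn"] = rnn.RNNConfig(**kwargs["rnn"])
        if "decoder" in kwargs:
            kwargs["decoder"] = DecoderSpec(**kwargs["decoder"])
        return cls(**kwargs)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage; returns (and writes) the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": _jsonable(asdict(config)), "stages": []}
    rng = np.random.default_rng(config.seed)

    try:
        if config.source == "synthetic":
            pop = replace(config.pop, seed=config.seed)
            session = synth.make_session(pop, n_steps=config.n_steps)
        elif config.source == "rnn":
            cfg = replace(config.rnn, seed=config.seed)
            net = rnn.train(cfg)
            net.save(out / "rnn_checkpoint")
            session = rnn.generate_session(
                net, n_steps=config.n_steps, seed=int(rng.integers(2**31))
            )
        else:
            raise ValueError(f"unknown source {config.source!r}")
        session = session.exclude_silent()
        session.save(out / "session")
        summary["stages"].append("session")
        summary["session"] = {
            "n_units": session.n_units,
            "n_samples": session.n_samples,
            "duration_s": session.duration,
        }

        metrics = tuning.compute_unit_metrics(
            session,
            alpha=config.alpha,
            n_shuffles=config.n_shuffles,
            seed=int(rng.integers(2**31)),
            classifier=config.classifier,
        )
        metrics.to_csv(out / "unit_metrics.tsv", sep="\t")
        summary["stages"].append("metrics")
        counts = metrics["label"].value_counts().to_dict()
        summary["metrics"] = {
            "labels": counts,
            "frac_hd_sig": float(metrics["hd_sig"].mean()),
            "frac_conjunctive": float(
                (metrics["hd_sig"] & metrics["ahv_sig"]).mean()
            ),
        }

        sp = list(metrics.index[metrics["label"] == "SP"])
        mp = list(metrics.index[metrics["label"] == "MP"])
        if config.run_decoding and sp and mp:
            dec = {}
            for label, units in (("SP", sp), ("MP", mp)):
                for target in ("hd", "ahv"):
                    res = decode(
                        session, units, replace(config.decoder, target=target),
                        seed=int(rng.integers(2**31)), population_label=label,
                    )
                    dec[f"r_{target}_{label.lower()}"] = res.r
            summary["decoding"] = dec
            summary["stages"].append("decoding")

        if config.run_geometry and len(sp) >= config.n_groups:
            groups = geometry.split_by_fwhm(
                metrics, n_groups=config.n_groups, group_size=config.group_size
            )
            geo = []
            for g, group in enumerate(groups):
                man = geometry.build_manifold(session, group)
                geo.append(
                    dict(group=g + 1, n_units=len(group), ed=man.ed,
                         l_trajectory=man.l_trajectory,
                         mean_fwhm=float(metrics.loc[group, "fwhm"].mean()))
                )
            if mp:
                man = geometry.build_manifold(session, mp)
                geo.append(
                    dict(group="MP", n_units=len(mp), ed=man.ed,
                         l_trajectory=man.l_trajectory,
                         mean_fwhm=float(metrics.loc[mp, "fwhm"].mean()))
                )
            summary["geometry"] = geo
            summary["stages"].append("geometry")
    finally:
        (out / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=1)
        )
    return summary
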