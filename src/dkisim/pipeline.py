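"""End-to-end study pipeline: simulate -> fit -> roi -> stats.

One master seed drives the whole run; it is split with ``SeedSequence``
into independent per-stage (and, inside the simulator, per-tumor) streams
so that a fixed seed reproduces every artifact byte-for-byte and changing
one stage's workload never reshuffles another's draws.  Every run writes a
manifest (config hash, seed, package versions, per-stage wall time) next
to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .fitting import FitOptions, fit_maps
from .io import affine_for, save_cohort, save_maps
from .phantom import GroupSpec, control_spec, emt_spec, make_cohort
from .protocol import AcquisitionProtocol, NoiseModel
from .roi import (
    JitterSpec,
    consensus_means,
    measurements_to_frame,
    simulate_observers,
)
from .stats import stats_report

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    control: GroupSpec = field(default_factory=control_spec)
    emt: GroupSpec = field(default_factory=emt_spec)
    noise: NoiseModel = field(default_factory=NoiseModel)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    fit_options: FitOptions = field(default_factory=FitOptions)
    save_volumes: bool = True

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        if "save_volumes" in raw:
            kwargs["save_volumes"] = bool(raw["save_volumes"])
        if "protocol" in raw:
            p = dict(raw["protocol"])
            if "b_values" in p:
                p["b_values"] = tuple(p["b_values"])
            if "voxel_size" in p:
                p["voxel_size"] = tuple(p["voxel_size"])
            kwargs["protocol"] = AcquisitionProtocol(**p)
        if "control" in raw:
            kwargs["control"] = control_spec(**raw["control"])
        if "emt" in raw:
            kwargs["emt"] = emt_spec(**raw["emt"])
        if "noise" in raw:
            kwargs["noise"] = NoiseModel(**raw["noise"])
        if "jitter" in raw:
            kwargs["jitter"] = JitterSpec(**raw["jitter"])
        if "fit" in raw:
            f = dict(raw["fit"])
            if "adc_b_subset" in f and f["adc_b_subset"] is not None:
                f["adc_b_subset"] = tuple(f["adc_b_subset"])
            kwargs["fit_options"] = FitOptions(**f)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_all(config: RunConfig, out_dir: Path) -> dict:
    """Execute the full pipeline and write all artifacts under out_dir.

    Returns the statistics report (also written as report.json).  Any
    stage failure raises with a stage-tagged message.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.hash()
    root = np.random.SeedSequence(config.seed)
    sim_ss, roi_ss = root.spawn(2)
    timings: dict[str, float] = {}

    def stage(name):
        log.info("[%s] starting", name)
        return time.perf_counter()

    try:
        t0 = stage("simulate")
        samples = make_cohort(
            config.control, config.emt, config.protocol, config.noise,
            seed=sim_ss,
        )
        if config.save_volumes:
            save_cohort(samples, out_dir / "cohort", config.protocol)
        timings["simulate"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"[simulate] {e}") from e

    try:
        t0 = stage("fit")
        b = np.asarray(config.protocol.b_values)
        maps = {}
        for s in samples:
            maps[s.tumor_id] = fit_maps(s.signal, s.mask, b, config.fit_options)
            if config.save_volumes:
                save_maps(maps[s.tumor_id], out_dir / "maps", s.tumor_id,
                          affine_for(config.protocol))
        timings["fit"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"[fit] {e}") from e

    try:
        t0 = stage("roi")
        jitter_seeds = roi_ss.spawn(len(samples))
        rows = []
        for s, ss in zip(samples, jitter_seeds):
            rows.extend(
                simulate_observers(
                    maps[s.tumor_id], s.mask, config.jitter, seed=ss,
                    tumor_id=s.tumor_id, group=s.group,
                )
            )
        measurements = measurements_to_frame(rows)
        consensus = consensus_means(measurements)
        measurements.insert(0, "config_hash", cfg_hash)
        measurements.to_csv(out_dir / "measurements.csv", index=False)
        measurements = measurements.drop(columns="config_hash")
        timings["roi"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"[roi] {e}") from e

    try:
        t0 = stage("stats")
        from .io import truth_table

        histology = truth_table(samples)[
            ["tumor_id", "cellularity", "ki67", "ecadherin"]
        ]
        report = stats_report(consensus, measurements, histology)
        report["config_hash"] = cfg_hash
        report["seed"] = config.seed
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=_json_default)
        )
        timings["stats"] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"[stats] {e}") from e

    manifest = {
        "config": config.to_dict(),
        "config_hash": cfg_hash,
        "seed": config.seed,
        "dkisim_version": __version__,
        "numpy_version": np.__version__,
        "stage_seconds": timings,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=_json_default)
    )
    return report
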