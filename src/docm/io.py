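"""HDF5/JSON containers and run configuration.

Cohorts are stored as ``/subjects/<id>/session<k>/data`` datasets with the
sampling rate as a root attribute; generator ground truth lives under a
separate ``/ground_truth`` group so the pipeline-visible data can be
handed over without it.  Integrated graphs store paired ``/strengths`` and
``/labels`` arrays plus the full statistical-filtering configuration as
attributes, so every artifact is self-describing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .coupling import WindowSpec
from .docm_select import IDFCG, SurrogateConfig
from .synth import CouplingPlan, SubjectRecord, SyntheticCohort

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_idfcg",
    "load_idfcg",
    "PipelineConfig",
    "config_hash",
]


def save_cohort(cohort: SyntheticCohort, path, with_truth: bool = True) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["rate"] = cohort.rate
        f.attrs["n_rois"] = cohort.n_rois
        subs = f.create_group("subjects")
        for s in cohort.subjects:
            g = subs.create_group(s.subject_id)
            for k, data in enumerate(s.sessions):
                g.create_dataset(f"session{k}/data", data=data,
                                 compression="gzip", compression_opts=1)
        if with_truth:
            gt = f.create_group("ground_truth")
            for s in cohort.subjects:
                g = gt.create_group(s.subject_id)
                for k, t in enumerate(s.truth):
                    g.create_dataset(f"session{k}", data=t)


def load_cohort(path) -> SyntheticCohort:
    """Load a cohort container; rejects NaN/Inf data and mixed geometries."""
    with h5py.File(path, "r") as f:
        if "rate" not in f.attrs:
            raise ValueError("schema error: missing root attribute 'rate'")
        rate = float(f.attrs["rate"])
        if "subjects" not in f:
            raise ValueError("schema error: missing /subjects group")
        subjects = []
        roi_counts = set()
        for sid in sorted(f["subjects"]):
            g = f["subjects"][sid]
            sessions, truths = [], []
            for sk in sorted(g):
                data = np.asarray(g[sk]["data"])
                if not np.all(np.isfinite(data)):
                    raise ValueError(f"schema error: non-finite data in {sid}/{sk}")
                sessions.append(data)
                roi_counts.add(data.shape[0])
            if "ground_truth" in f and sid in f["ground_truth"]:
                tg = f["ground_truth"][sid]
                truths = [np.asarray(tg[k]) for k in sorted(tg)]
            n_rois = sessions[0].shape[0]
            subjects.append(SubjectRecord(sid, sessions, rate,
                                          CouplingPlan(n_rois, []), truths))
        if len(roi_counts) > 1:
            raise ValueError(f"schema error: mixed ROI counts {sorted(roi_counts)}")
    return SyntheticCohort(subjects, rate, roi_counts.pop())


def save_idfcg(idfcg: IDFCG, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("strengths", data=idfcg.strengths,
                         compression="gzip", compression_opts=1)
        f.create_dataset("labels", data=idfcg.labels,
                         compression="gzip", compression_opts=1)
        f.create_dataset("windows", data=idfcg.windows)
        f.attrs["rate"] = idfcg.rate
        for k, v in dataclasses.asdict(idfcg.cfg).items():
            f.attrs[f"cfg_{k}"] = v


def load_idfcg(path) -> IDFCG:
    with h5py.File(path, "r") as f:
        cfg = SurrogateConfig(**{k[4:]: f.attrs[k].item() if hasattr(f.attrs[k], "item")
                                 else f.attrs[k]
                                 for k in f.attrs if k.startswith("cfg_")})
        return IDFCG(np.asarray(f["strengths"]), np.asarray(f["labels"]),
                     np.asarray(f["windows"]), float(f.attrs["rate"]), cfg)


@dataclasses.dataclass
class PipelineConfig:
    """End-to-end run configuration; YAML-serialisable, hash-stamped."""

    n_subjects: int = 10
    n_rois: int = 20
    duration: float = 60.0
    rate: float = 600.0
    noise_level: float = 1.0
    seed: int = 0
    window: WindowSpec = dataclasses.field(default_factory=WindowSpec)
    surrogate: SurrogateConfig = dataclasses.field(default_factory=SurrogateConfig)
    state_grid: tuple = (2, 3)
    plateau_patience: int = 5
    out_dir: str = "docm_out"

    def validate(self) -> list[str]:
        notes = []
        if self.window.step > self.window.width:
            notes.append("window step exceeds width: gaps between windows")
        if self.duration < self.window.width:
            raise ValueError("recording shorter than the analysis window")
        if self.rate < 180:
            raise ValueError("rate below 180 Hz cannot cover the gamma2 band")
        return notes

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in raw:
            raw["window"] = WindowSpec(**raw["window"])
        if "surrogate" in raw:
            raw["surrogate"] = SurrogateConfig(**raw["surrogate"])
        if "state_grid" in raw:
            raw["state_grid"] = tuple(raw["state_grid"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["state_grid"] = list(d["state_grid"])
        Path(path).write_text(yaml.safe_dump(d))


def config_hash(config: PipelineConfig) -> str:
    """Stable provenance hash of a configuration."""
    d = dataclasses.asdict(config)
    return hashlib.sha256(json.dumps(d, sort_keys=True, default=str)
                          .encode()).hexdigest()[:16]
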