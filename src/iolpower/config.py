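"""Serializable pipeline configuration.

A :class:`PipelineConfig` bundles every tunable of the pipeline — optics
constants, filter criteria, split fraction, model hyperparameters,
evaluation thresholds and the synthetic-generator settings — under a single
master seed.  A saved config plus that seed reproduces a run bit-for-bit.

Named substreams derived from the master seed keep the stages' randomness
independent: reordering or skipping one stage does not perturb another.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Dict, Mapping

import numpy as np
import yaml

from .cohort import FilterCriteria
from .models import MlnnConfig, SvmConfig
from .optics import OpticsConstants
from .synthetic import MarginalSpec, SyntheticConfig

__all__ = ["PipelineConfig", "substream", "substream_seed", "load_config", "save_config"]


def substream_seed(master_seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    return (int(master_seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31)


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Seeded generator for a named stage of the pipeline."""
    return np.random.default_rng(substream_seed(master_seed, name))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full pipeline run."""

    master_seed: int = 0
    selection_fraction: float = 0.7
    optics: OpticsConstants = OpticsConstants()
    filters: FilterCriteria = FilterCriteria()
    svm: SvmConfig = SvmConfig()
    mlnn: MlnnConfig = MlnnConfig()
    synthetic: SyntheticConfig = SyntheticConfig()

    def with_seeds(self) -> "PipelineConfig":
        """Propagate the master seed into the per-stage seed slots."""
        return dataclasses.replace(
            self,
            svm=dataclasses.replace(self.svm, seed=substream_seed(self.master_seed, "svm")),
            mlnn=dataclasses.replace(self.mlnn, seed=substream_seed(self.master_seed, "mlnn")),
            synthetic=dataclasses.replace(
                self.synthetic, seed=substream_seed(self.master_seed, "synthetic")
            ),
        )


def _to_plain(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _tupled(d: Mapping[str, Any], keys: tuple[str, ...]) -> Dict[str, Any]:
    out = dict(d)
    for k in keys:
        if k in out and isinstance(out[k], list):
            out[k] = tuple(out[k])
    return out


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: Dict[str, Any] = {}
    for key in ("master_seed", "selection_fraction"):
        if key in raw:
            kwargs[key] = raw[key]
    if "optics" in raw:
        kwargs["optics"] = OpticsConstants(**raw["optics"])
    if "filters" in raw:
        f = _tupled(raw["filters"], ("acd_mm", "al_mm", "k_d", "age_years", "iol_implanted_d"))
        if "keyword_lists" in f:
            f["keyword_lists"] = {k: tuple(v) for k, v in f["keyword_lists"].items()}
        kwargs["filters"] = FilterCriteria(**f)
    if "svm" in raw:
        kwargs["svm"] = SvmConfig(**raw["svm"])
    if "mlnn" in raw:
        kwargs["mlnn"] = MlnnConfig(**raw["mlnn"])
    if "synthetic" in raw:
        s = dict(raw["synthetic"])
        for m in ("age", "k", "acd", "al", "rx_pre"):
            if m in s:
                s[m] = MarginalSpec(**s[m])
        if "optics" in s:
            s["optics"] = OpticsConstants(**s["optics"])
        kwargs["synthetic"] = SyntheticConfig(**s)
    return PipelineConfig(**kwargs)
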