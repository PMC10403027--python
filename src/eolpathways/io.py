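"""Flat-file interfaces: tables, configs, manifests.

All tables are delimited text (CSV) by default; paths ending in
``.parquet`` use the columnar binary format instead.  Sequences serialize
one row per patient, either as 365 single-character state codes or
run-length encoded (``A:12;H:353``).  Configs are hierarchical YAML with a
mandatory global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .distance import CostScheme, DissimilarityMatrix, constant_substitution
from .simulate import ArchetypeConfig, CohortConfig, CostConfig
from .states import SequenceSet


def write_table(frame: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        frame.to_parquet(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_cohort(cohort: pd.DataFrame, path) -> Path:
    return write_table(cohort, path)


def read_cohort(path) -> pd.DataFrame:
    cohort = read_table(path)
    if "deprivation_quintile" in cohort.columns:
        cohort["deprivation_quintile"] = cohort["deprivation_quintile"].astype("Int64")
    return cohort


def write_sequences(sequences: SequenceSet, path, rle: bool = False) -> Path:
    return write_table(sequences.to_frame(rle=rle), path)


def read_sequences(path) -> SequenceSet:
    return SequenceSet.from_frame(read_table(path))


def write_dissimilarity(D: DissimilarityMatrix, path) -> Path:
    frame = pd.DataFrame(D.values, columns=list(D.ids))
    frame.insert(0, "patient_id", list(D.ids))
    return write_table(frame, path)


def read_dissimilarity(path) -> DissimilarityMatrix:
    frame = read_table(path)
    ids = list(frame["patient_id"])
    return DissimilarityMatrix(ids, frame.drop(columns="patient_id").to_numpy(float))


@dataclass
class PipelineConfig:
    """Single configuration for the end-to-end pipeline.

    One global ``seed`` governs every stochastic stage; stage seeds are
    derived from it deterministically.
    """

    cohort: CohortConfig = field(default_factory=CohortConfig)
    archetypes: ArchetypeConfig = field(default_factory=ArchetypeConfig)
    costs: CostConfig = field(default_factory=CostConfig)
    indel_cost: float = 1.0
    substitution_cost: float = 2.0
    k: int | None = None          # fixed cluster count; None = elbow selection
    k_min: int = 2
    k_max: int = 8
    k_default: int = 3
    ward_variant: str = "squared"
    sample_size: int | None = None  # patients entering sequence analysis
    short_window: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        # the global seed overrides the per-stage seeds
        self.cohort.seed = _derive_seed(self.seed, 0)
        self.archetypes.seed = _derive_seed(self.seed, 1)
        self.costs.seed = _derive_seed(self.seed, 2)

    def cost_scheme(self) -> CostScheme:
        return CostScheme(self.indel_cost,
                          constant_substitution(self.substitution_cost))


def _derive_seed(seed: int, stream: int) -> int:
    return int(np.random.SeedSequence([seed, stream]).generate_state(1)[0] % (2**31))


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def save_config(config: PipelineConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
    return path


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    if "seed" not in raw:
        raise ValueError("config must declare a seed")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        kwargs["cohort"] = CohortConfig(**kwargs["cohort"])
    if "archetypes" in kwargs:
        arch = dict(kwargs["archetypes"])
        arch.pop("expanded", None)
        if "templates" in arch:
            arch["templates"] = [
                [(s, int(d)) for s, d in t] for t in arch["templates"]
            ]
        kwargs["archetypes"] = ArchetypeConfig(**arch)
    if "costs" in kwargs:
        costs = dict(kwargs["costs"])
        if "ambulatory" in costs:
            costs["ambulatory"] = {k: tuple(v) for k, v in costs["ambulatory"].items()}
        kwargs["costs"] = CostConfig(**costs)
    return PipelineConfig(**kwargs)


def config_digest(config: PipelineConfig) -> str:
    plain = _to_plain(config)
    if isinstance(plain.get("archetypes"), dict):
        plain["archetypes"].pop("expanded", None)
    blob = json.dumps(plain, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(out_dir, stage: str, config: PipelineConfig, files) -> Path:
    """Record stage provenance: seed, config digest, output file digests."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest = {
        "stage": stage,
        "seed": config.seed,
        "config_digest": config_digest(config),
        "package_version": __version__,
        "files": {Path(f).name: file_digest(f) for f in files},
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
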