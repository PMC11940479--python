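"""Run configuration: one YAML/JSON schema for the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Any

import yaml

from .dose_field import IntegrationDomain, MicrobeamGeometry
from .lqm import LQParams
from .synthetic_data import CellLineSpec, ModalitySpec, StudyDesign

__all__ = ["RunConfig", "load_config", "default_config_dict", "config_hash"]

SCHEMA_VERSION = 1


def default_config_dict() -> dict[str, Any]:
    """The reference study's configuration as a plain dict."""
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": 0,
        "geometry": {
            "slit_width_um": 30.0,
            "pitch_um": 300.0,
            "pvdr": 45.77,
            "field_size_mm": 20.0,
            "penumbra_um": 0.0,
        },
        "domain": {
            "shape": "square",
            "extent_mm": 3.0,
            "resolution_um": 5.0,
            "center_mm": [0.0, 0.0],
        },
        "interval_hours": 24.0,
        "modalities": [
            {"label": "BB_fx4", "kind": "broad_beam", "angles_deg": [0, 0, 0, 0]},
            {"label": "MRT_fx4", "kind": "microbeam", "angles_deg": [0, 0, 0, 0]},
            {"label": "MRT_fx4+R", "kind": "microbeam", "angles_deg": [0, 45, 90, 135]},
        ],
        "cell_lines": [
            {"label": "A549", "alpha": 0.29075, "beta": 0.01928, "pe": 0.70},
            {"label": "MRC-5", "alpha": 0.56606, "beta": 0.00004, "pe": 0.35},
        ],
        "study": {
            "dose_levels_gy": [1, 2, 4, 6, 8],
            "n_bio": 3,
            "n_tech": 6,
            "seeded_min": 100,
            "seeded_max": 2000,
            "control_seeded": 250,
            "dose_mode": "matched_eud",
            "bio_sd": 0.0,
            "noise": "poisson",
            "modality_effects": [],
        },
        "analysis": {
            "response_scale": "log",
            "dose_range_gy": None,
            "alpha_level": 0.05,
            "holm": False,
        },
    }


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration; pure function of the raw config dict."""

    raw: dict

    def __post_init__(self) -> None:
        r = self.raw
        if r.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version: {r.get('schema_version')}")
        if "seed" not in r:
            raise ValueError("config must set a master 'seed'")
        # constructing the parts validates them
        self.geometry
        self.domain
        self.design()

    @property
    def seed(self) -> int:
        return int(self.raw["seed"])

    @property
    def geometry(self) -> MicrobeamGeometry:
        return MicrobeamGeometry(**self.raw["geometry"])

    @property
    def domain(self) -> IntegrationDomain:
        d = dict(self.raw["domain"])
        if "center_mm" in d:
            d["center_mm"] = tuple(d["center_mm"])
        return IntegrationDomain(**d)

    @property
    def cell_lines(self) -> tuple[CellLineSpec, ...]:
        return tuple(
            CellLineSpec(c["label"], LQParams(c["alpha"], c["beta"]), c["pe"])
            for c in self.raw["cell_lines"]
        )

    @property
    def modalities(self) -> tuple[ModalitySpec, ...]:
        return tuple(
            ModalitySpec(m["label"], m["kind"], tuple(float(a) for a in m["angles_deg"]))
            for m in self.raw["modalities"]
        )

    @property
    def analysis(self) -> dict:
        return dict(self.raw.get("analysis", {}))

    def design(self, seed: int | None = None) -> StudyDesign:
        s = self.raw["study"]
        effects = tuple(
            ((e["cell_line"], e["modality"]), float(e["factor"]))
            for e in s.get("modality_effects", [])
        )
        return StudyDesign(
            geometry=self.geometry,
            domain=self.domain,
            cell_lines=self.cell_lines,
            modalities=self.modalities,
            dose_levels_gy=tuple(float(d) for d in s["dose_levels_gy"]),
            n_bio=int(s.get("n_bio", 3)),
            n_tech=int(s.get("n_tech", 6)),
            seeded_min=int(s.get("seeded_min", 100)),
            seeded_max=int(s.get("seeded_max", 2000)),
            control_seeded=int(s.get("control_seeded", 250)),
            dose_mode=s.get("dose_mode", "matched_eud"),
            bio_sd=float(s.get("bio_sd", 0.0)),
            noise=s.get("noise", "poisson"),
            interval_hours=float(self.raw.get("interval_hours", 24.0)),
            modality_effects=effects,
            seed=self.seed if seed is None else seed,
        )

    def with_seed(self, seed: int) -> "RunConfig":
        raw = json.loads(json.dumps(self.raw))
        raw["seed"] = int(seed)
        return RunConfig(raw)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON config file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig(raw)


def config_hash(cfg: RunConfig) -> str:
    """Stable hash of the canonicalized config dict."""
    canon = json.dumps(cfg.raw, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
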