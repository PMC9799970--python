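"""Pipeline configuration: one YAML block describing constants, conditions and options.

Angles are accepted in degrees in the file and converted to radians at the
type boundary; all other units follow the package convention (nm, pN,
pN·nm).  A written configuration reads back identical (round-trip safe).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

from . import constants
from .bead_lever import LeverGeometry
from .synthetic_data import Condition, SyntheticConfig
from .tip_assembly import CurlParams, TipConfig

__all__ = ["PipelineConfig", "ConditionSpec"]


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental condition and its ground-truth/initial tip model."""

    species: str = "bovine"
    mg_mM: float = 1.0
    treatment: str = "none"
    kappa_pn_nm_per_rad: float = 176.0
    mean_length_dimers: float = 2.3


@dataclass(frozen=True)
class PipelineConfig:
    segment_length_nm: float = constants.DEFAULT_SEGMENT_LENGTH_NM
    relaxed_angle_deg: float = 23.0
    n_protofilaments: int = constants.DEFAULT_N_PROTOFILAMENTS
    mt_radius_nm: float = constants.DEFAULT_MT_RADIUS_NM
    bead_radius_nm: float = constants.DEFAULT_BEAD_RADIUS_NM
    tether_length_nm: float = constants.DEFAULT_TETHER_LENGTH_NM
    leverage: float = constants.DEFAULT_LEVERAGE
    kbt_pn_nm: float = constants.KBT_PN_NM
    conditions: tuple = (ConditionSpec(),)
    trap_force_levels_pn: tuple = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    events_per_level: int = 30
    event_sd_nm: float = 8.0
    baseline_sd_nm: float = 2.5
    fit_init_kappa: float = 150.0
    fit_init_mean_length: float = 3.0
    output_dir: str = "pfwave_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "segment_length_nm",
            "n_protofilaments",
            "mt_radius_nm",
            "bead_radius_nm",
            "tether_length_nm",
            "leverage",
            "kbt_pn_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if isinstance(self.conditions, list):
            object.__setattr__(
                self,
                "conditions",
                tuple(
                    c if isinstance(c, ConditionSpec) else ConditionSpec(**c)
                    for c in self.conditions
                ),
            )

    # -- derived model objects -------------------------------------------

    @property
    def relaxed_angle_rad(self) -> float:
        return math.radians(self.relaxed_angle_deg)

    def lever(self) -> LeverGeometry:
        return LeverGeometry(
            bead_radius_nm=self.bead_radius_nm,
            tether_length_nm=self.tether_length_nm,
            leverage=self.leverage,
        )

    def tip_config(self, cond: ConditionSpec) -> TipConfig:
        return TipConfig(
            mean_length_dimers=cond.mean_length_dimers,
            elastica=CurlParams(
                segment_length_nm=self.segment_length_nm,
                relaxed_angle_rad=self.relaxed_angle_rad,
                kappa_pn_nm_per_rad=cond.kappa_pn_nm_per_rad,
            ),
            n_protofilaments=self.n_protofilaments,
            mt_radius_nm=self.mt_radius_nm,
        )

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            conditions=tuple(
                Condition(
                    tip=self.tip_config(c),
                    species=c.species,
                    mg_mM=c.mg_mM,
                    treatment=c.treatment,
                )
                for c in self.conditions
            ),
            lever=self.lever(),
            trap_force_levels_pn=tuple(self.trap_force_levels_pn),
            events_per_level=self.events_per_level,
            event_sd_nm=self.event_sd_nm,
            baseline_sd_nm=self.baseline_sd_nm,
            seed=self.seed,
        )

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = [dataclasses.asdict(c) for c in self.conditions]
        d["trap_force_levels_pn"] = list(self.trap_force_levels_pn)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["conditions"] = tuple(
            ConditionSpec(**c) for c in d.get("conditions", [{}])
        )
        d["trap_force_levels_pn"] = tuple(d.get("trap_force_levels_pn", (2.0,)))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Short stable hash of the configuration, for logging."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
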