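"""Run configuration: YAML loading, validation, defaults, provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .interventions import COVERAGE_LEVELS
from .synthetic import RegionProfile, make_two_region_demo


class ConfigError(ValueError):
    """Schema violation, reported with the offending field path."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; defaults mirror the study design:
    100-year programme horizon, 3% per-annum discounting, coverage grid
    50/80/95%."""

    regions: list[RegionProfile] = field(default_factory=list)
    horizon: int = 100
    burn_in: int = 100
    discount_rate: float = 0.03
    coverages: tuple[float, ...] = COVERAGE_LEVELS
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon: must be >= 1")
        if self.burn_in < 1:
            raise ConfigError("burn_in: must be >= 1")
        if self.discount_rate < 0:
            raise ConfigError("discount_rate: must be >= 0")
        for i, c in enumerate(self.coverages):
            if not (0.0 < c <= 1.0):
                raise ConfigError(f"coverages[{i}]: must be in (0, 1]")
        if not self.regions:
            self.regions = list(make_two_region_demo())

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coverages"] = list(self.coverages)
        for r in d["regions"]:
            r["cervical_incidence"] = _bands_to_keys(r["cervical_incidence"])
            r["breast_incidence"] = _bands_to_keys(r["breast_incidence"])
            r["colorectal_incidence"] = _bands_to_keys(r["colorectal_incidence"])
            r["hpv_attribution"] = list(r["hpv_attribution"])
            r["route_split"] = list(r["route_split"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _bands_to_keys(bands: dict) -> dict:
    return {f"{lo}-{hi}": v for (lo, hi), v in bands.items()}


def _keys_to_bands(d: dict, path: str) -> dict:
    out = {}
    for k, v in d.items():
        try:
            lo, hi = (int(x) for x in str(k).split("-"))
        except Exception:
            raise ConfigError(f"{path}.{k}: age band must look like '30-49'")
        out[(lo, hi)] = float(v)
    return out


def _profile_from_dict(d: dict, path: str) -> RegionProfile:
    kwargs = dict(d)
    for fld in ("cervical_incidence", "breast_incidence", "colorectal_incidence"):
        if fld not in kwargs:
            raise ConfigError(f"{path}.{fld}: required")
        kwargs[fld] = _keys_to_bands(kwargs[fld], f"{path}.{fld}")
    for fld in ("hpv_attribution", "route_split"):
        if fld in kwargs:
            kwargs[fld] = tuple(kwargs[fld])
    if "stage_distribution" in kwargs:
        kwargs["stage_distribution"] = dict(kwargs["stage_distribution"])
    try:
        return RegionProfile(**kwargs)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{path}: {e}") from e


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration; defaults filled in."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    regions = [
        _profile_from_dict(r, f"regions[{i}]")
        for i, r in enumerate(raw.pop("regions", []))
    ]
    if "coverages" in raw:
        raw["coverages"] = tuple(raw["coverages"])
    known = {
        "horizon",
        "burn_in",
        "discount_rate",
        "coverages",
        "output_dir",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    return RunConfig(regions=regions, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
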