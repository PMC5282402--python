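"""Geometry configuration and element radii tables.

Every distance/angle threshold used by the detectors lives in a
:class:`GeometryConfig`, loaded from the shipped ``data/geometry.yaml`` by
default and overridable from a user YAML file (CLI ``-c/--config``). Radii
tables (covalent: Pyykko single-bond scale; van der Waals: Bondi scale) ship
as ``data/radii.yaml``.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


class UnknownElementError(KeyError):
    """Raised when an element has no entry in a radii table."""

    def __init__(self, element: str, table: str) -> None:
        super().__init__(element)
        self.element = element
        self.table = table

    def __str__(self) -> str:  # pragma: no cover - trivial formatting
        return f"element {self.element!r} has no {self.table} radius entry"


def _data_text(name: str) -> str:
    return (resources.files("contactsift") / "data" / name).read_text()


# Distance fields that must not exceed the radial cutoff (atom-atom feature
# maxima). Ring/group centroid maxima are not atom-pair distances and are
# exempt (a 6 A centroid separation is compatible with a 5 A atom cutoff).
_ATOM_FEATURE_MAXIMA = (
    "hbond_dist_max",
    "weak_hbond_dist_max",
    "polar_dist_max",
    "weak_polar_dist_max",
    "ionic_dist_max",
    "metal_dist_max",
    "carbonyl_dist_max",
    "hydrophobic_dist_max",
    "aromatic_dist_max",
)

_ANGLE_FIELDS = (
    "hbond_angle_min",
    "weak_hbond_angle_min",
    "xbond_angle_min",
    "stacked_angle_max",
    "t_shaped_angle_min",
    "atom_ring_angle_max",
)


@dataclasses.dataclass
class GeometryConfig:
    """All geometric thresholds, in Angstrom and degrees."""

    cutoff: float = 5.0
    cov_tol: float = 0.1
    vdw_comp: float = 0.1

    hbond_dist_max: float = 3.9
    hbond_h_dist_max: float = 2.7
    hbond_angle_min: float = 90.0
    weak_hbond_dist_max: float = 3.6
    weak_hbond_h_dist_max: float = 3.0
    weak_hbond_angle_min: float = 130.0
    polar_dist_max: float = 3.5
    weak_polar_dist_max: float = 4.0
    xbond_angle_min: float = 120.0
    ionic_dist_max: float = 4.0
    metal_dist_max: float = 2.8
    carbonyl_dist_max: float = 3.6
    hydrophobic_dist_max: float = 4.5
    aromatic_dist_max: float = 4.0

    ring_ring_dist_max: float = 6.0
    stacked_angle_max: float = 30.0
    t_shaped_angle_min: float = 60.0
    atom_ring_dist_max: float = 4.5
    atom_ring_angle_max: float = 30.0
    amide_amide_dist_max: float = 5.0
    amide_ring_dist_max: float = 4.5
    met_arom_dist_max: float = 6.0
    include_all_thioethers: bool = False
    halogen_weak_acceptor: bool = True

    bond_tol: float = 0.45
    planarity_tol: float = 0.1

    cov_radii: dict = dataclasses.field(default_factory=dict, repr=False)
    vdw_radii: dict = dataclasses.field(default_factory=dict, repr=False)
    metals: frozenset = dataclasses.field(default_factory=frozenset, repr=False)

    def __post_init__(self) -> None:
        if not self.cov_radii or not self.vdw_radii:
            radii = yaml.safe_load(_data_text("radii.yaml"))
            self.cov_radii = self.cov_radii or {
                k.upper(): float(v) for k, v in radii["covalent"].items()
            }
            self.vdw_radii = self.vdw_radii or {
                k.upper(): float(v) for k, v in radii["vdw"].items()
            }
            if not self.metals:
                self.metals = frozenset(e.upper() for e in radii["metals"])
        self.validate()

    # -- loading ---------------------------------------------------------

    @classmethod
    def default(cls) -> "GeometryConfig":
        """Configuration from the shipped ``data/geometry.yaml``."""
        return cls.from_mapping(yaml.safe_load(_data_text("geometry.yaml")))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeometryConfig":
        with open(path) as fh:
            values = yaml.safe_load(fh) or {}
        base = yaml.safe_load(_data_text("geometry.yaml"))
        base.update(values)
        return cls.from_mapping(base)

    @classmethod
    def from_mapping(cls, values: Mapping) -> "GeometryConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(values))

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith(("_max", "_tol", "_comp")) or f.name == "cutoff":
                if isinstance(v, float) and not f.name.endswith("angle_max") and v <= 0:
                    raise ConfigError(f"{f.name} must be positive, got {v}")
        for name in _ANGLE_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 180.0:
                raise ConfigError(f"{name} must lie in [0, 180] degrees, got {v}")
        for name in _ATOM_FEATURE_MAXIMA:
            v = getattr(self, name)
            if v > self.cutoff:
                raise ConfigError(
                    f"{name}={v} exceeds the radial cutoff {self.cutoff}"
                )

    # -- radii lookups ---------------------------------------------------

    def rcov(self, element: str) -> float:
        try:
            return self.cov_radii[element.upper()]
        except KeyError:
            raise UnknownElementError(element, "covalent") from None

    def rvdw(self, element: str) -> float:
        try:
            return self.vdw_radii[element.upper()]
        except KeyError:
            raise UnknownElementError(element, "van der Waals") from None

    def has_radii(self, element: str) -> bool:
        e = element.upper()
        return e in self.cov_radii and e in self.vdw_radii

    def is_metal(self, element: str) -> bool:
        return element.upper() in self.metals

    def describe(self) -> str:
        """One-line-per-threshold summary for startup logging."""
        skip = {"cov_radii", "vdw_radii", "metals"}
        parts = [
            f"{f.name}={getattr(self, f.name)}"
            for f in dataclasses.fields(self)
            if f.name not in skip
        ]
        return ", ".join(parts)
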