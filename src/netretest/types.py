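"""Domain types shared across the pipeline.

The study design these types encode: each subject is scanned twice (baseline
``BL`` and follow-up ``FU``), belongs to one of two groups (healthy controls
``HC`` or patients with stable multiple sclerosis ``MS``), and every volume
lives on a common voxel grid alongside a stack of template network maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

SESSIONS: Tuple[str, str] = ("BL", "FU")
GROUPS: Tuple[str, str] = ("HC", "MS")

#: Finite stand-in for an infinite Z statistic (zero residual variance at a
#: voxel whose coefficient is nonzero, e.g. noiseless simulated data).
Z_CAP = 1.0e6


class ConfigurationError(ValueError):
    """A simulation or analysis configuration violates its constraints."""


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


class DegenerateInputError(ValueError):
    """An input is too degenerate for the statistic to be defined."""


def _as_triple(dims) -> Tuple[int, int, int]:
    t = tuple(int(d) for d in dims)
    if len(t) != 3 or any(d < 1 for d in t):
        raise ConfigurationError(f"grid_dims must be 3 positive integers, got {dims!r}")
    return t  # type: ignore[return-value]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic two-session, two-group resting-state study.

    Defaults mirror the emulated acquisition and design: 150 volumes at
    TR = 3 s, two sessions per subject, 14 HC and 20 MS subjects, nine
    networks.  The variance components control reliability: ``sigma_between``
    is the SD of the per-subject amplitude perturbation (stable across
    sessions), ``sigma_within`` the SD of the per-session perturbation, and
    ``sigma_noise`` the SD of the additive temporal Gaussian noise.
    """

    grid_dims: Tuple[int, int, int] = (24, 24, 24)
    n_networks: int = 9
    n_subjects_per_group: Union[int, Tuple[int, int]] = (14, 20)
    n_timepoints: int = 150
    tr_seconds: float = 3.0
    sigma_between: float = 0.5
    sigma_within: float = 0.1
    sigma_noise: float = 1.0
    session_shift: float = 0.0
    seed: int = 0
    #: Optional per-group override of sigma_within (e.g. larger for MS).
    sigma_within_by_group: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_dims", _as_triple(self.grid_dims))
        if self.n_networks < 1:
            raise ConfigurationError("n_networks must be >= 1")
        if self.n_timepoints < 1:
            raise ConfigurationError("n_timepoints must be >= 1")
        if self.tr_seconds <= 0:
            raise ConfigurationError("tr_seconds must be positive")
        for name in ("sigma_between", "sigma_within", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        n = self.n_subjects_per_group
        pair = (int(n), int(n)) if np.isscalar(n) else (int(n[0]), int(n[1]))
        if min(pair) < 1:
            raise ConfigurationError("n_subjects_per_group must be >= 1")
        object.__setattr__(self, "n_subjects_per_group", pair)

    @property
    def group_sizes(self) -> Mapping[str, int]:
        return dict(zip(GROUPS, self.n_subjects_per_group))

    @property
    def n_subjects(self) -> int:
        return sum(self.n_subjects_per_group)

    def sigma_within_for(self, group: str) -> float:
        if self.sigma_within_by_group and group in self.sigma_within_by_group:
            return float(self.sigma_within_by_group[group])
        return self.sigma_within

    def to_dict(self) -> dict:
        d = {
            "grid_dims": list(self.grid_dims),
            "n_networks": self.n_networks,
            "n_subjects_per_group": list(self.n_subjects_per_group),
            "n_timepoints": self.n_timepoints,
            "tr_seconds": self.tr_seconds,
            "sigma_between": self.sigma_between,
            "sigma_within": self.sigma_within,
            "sigma_noise": self.sigma_noise,
            "session_shift": self.session_shift,
            "seed": self.seed,
        }
        if self.sigma_within_by_group:
            d["sigma_within_by_group"] = dict(self.sigma_within_by_group)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "grid_dims" in d:
            d["grid_dims"] = tuple(d["grid_dims"])
        if "n_subjects_per_group" in d and not np.isscalar(d["n_subjects_per_group"]):
            d["n_subjects_per_group"] = tuple(d["n_subjects_per_group"])
        return cls(**d)


@dataclass
class TemplateSet:
    """Stack of network spatial maps (Z-like units) on a common 3D grid."""

    maps: np.ndarray  # (network, x, y, z)
    names: Sequence[str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=np.float64)
        if self.maps.ndim != 4:
            raise ValueError("template maps must be a (network, x, y, z) array")
        if len(self.names) != self.maps.shape[0]:
            raise ValueError("one name per network map required")

    @property
    def n_networks(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_dims(self) -> Tuple[int, int, int]:
        return self.maps.shape[1:]  # type: ignore[return-value]


@dataclass
class Bold4D:
    """One subject-session 4D BOLD series with design labels."""

    data: np.ndarray  # (x, y, z, t)
    tr_seconds: float
    subject_id: str
    session: str
    group: str
    mask: Optional[np.ndarray] = None  # binary 3D in-brain mask

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be a (x, y, z, t) array")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.data.shape[:3]:
                raise GridMismatchError(
                    f"mask grid {self.mask.shape} != data grid {self.data.shape[:3]}"
                )
            if np.isnan(self.data[self.mask]).any():
                raise ValueError("NaN values inside the in-brain mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    def get_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.data.shape[:3], dtype=bool)
        return self.mask


@dataclass
class GroundTruth:
    """Known subject-session spatial maps the generator mixed into the BOLD."""

    subject_maps: np.ndarray  # (subject, session, network, x, y, z)
    subject_amplitudes: np.ndarray  # (subject, session, network)
    group_labels: Sequence[str]
    subject_ids: Sequence[str]

    def __post_init__(self) -> None:
        if self.subject_maps.shape[1] != len(SESSIONS):
            raise ValueError("sessions dimension must have exactly 2 entries (BL, FU)")

    @property
    def n_subjects(self) -> int:
        return self.subject_maps.shape[0]

    @property
    def n_networks(self) -> int:
        return self.subject_maps.shape[2]


@dataclass
class TimeCourses:
    """Stage-1 output: one temporal regressor per network."""

    values: np.ndarray  # (t, network)
    names: Sequence[str]
    variance_normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("time courses must be a (t, network) array")


@dataclass
class SubjectNetworkMaps:
    """Stage-2 output: per-network beta and Z maps for one subject-session."""

    beta: np.ndarray  # (network, x, y, z)
    zmap: np.ndarray  # (network, x, y, z)
    subject_id: str
    session: str
    group: str = ""
    names: Sequence[str] = ()


@dataclass
class NetworkMask:
    """Binary 3D ROI with provenance.

    ``entire_network`` masks are thresholded group template support (no
    subject); ``subject_overlap`` masks are one subject's BL∩FU suprathreshold
    voxels.
    """

    voxels: np.ndarray
    network: str
    provenance: str  # entire_network | subject_overlap
    threshold: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.provenance not in ("entire_network", "subject_overlap"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "entire_network" and self.subject_id:
            raise ValueError("entire_network masks carry no subject_id")
        if self.provenance == "subject_overlap" and not self.subject_id:
            raise ValueError("subject_overlap masks require a subject_id")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0
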