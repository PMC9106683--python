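"""Domain types for horizon-resolved soil profiles along a degradation gradient.

A pasture degradation sequence is described by six ordered stages: S0 is the
intact reference (closed root mat), S1--S4 show widening polygonal surface
cracks, and S5 is bare soil without a root mat.  Each stage is sampled as a
set of replicate pedons (:class:`SoilProfile`), each an ordered stack of
horizons carrying organic-carbon and nitrogen contents, bulk density and
optional isotope / lignin / texture measurements.

Depth convention: centimetres, positive downward, 0 at the *current* surface
of the profile (which for a degraded plot sits ``crack_depth`` cm below the
original reference surface).  Horizon intervals are half-open
``[top, bottom)`` so every depth inside the profile belongs to exactly one
horizon.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import DataError

__all__ = [
    "DegradationStage",
    "Horizon",
    "SoilProfile",
    "StageEnsemble",
    "validate_profile",
    "horizon_at",
]

#: tolerance (cm) for horizon contiguity checks
_DEPTH_TOL = 1e-9


class DegradationStage(enum.IntEnum):
    """Ordered degradation stages, S0 (intact reference) to S5 (bare soil)."""

    S0 = 0
    S1 = 1
    S2 = 2
    S3 = 3
    S4 = 4
    S5 = 5

    @classmethod
    def from_label(cls, label: str) -> "DegradationStage":
        """Parse a stage code such as ``"S3"`` (case-insensitive)."""
        key = str(label).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise DataError(f"unknown degradation stage label: {label!r}") from None

    @property
    def is_reference(self) -> bool:
        return self is DegradationStage.S0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class Horizon:
    """One soil horizon with its measured properties.

    Parameters
    ----------
    label:
        Horizon designation (e.g. ``"Ah1"``); used only for matching and
        reporting, never interpreted pedologically.
    top_depth, bottom_depth:
        Depth interval in cm below the current surface, half-open
        ``[top, bottom)``.
    soc_content:
        Organic carbon content, g C per kg dry soil.
    bulk_density:
        Oven-dry bulk density, g cm^-3.
    n_content:
        Total nitrogen, g N per kg soil (optional).
    delta13c:
        Bulk delta-13C of the organic carbon, permil vs PDB (optional).
    vsc_content:
        Sum of vanillyl+syringyl+cinnamyl lignin phenols expressed as a
        fraction of SOC, dimensionless in [0, 1] (optional).
    clay:
        Clay content, % mass (optional).
    root_density:
        Root dry mass per soil volume, mg cm^-3 (optional).

    Missing optional measurements are ``None`` (never 0 -- zero is a valid
    measurement).
    """

    label: str
    top_depth: float
    bottom_depth: float
    soc_content: float
    bulk_density: float
    n_content: float | None = None
    delta13c: float | None = None
    vsc_content: float | None = None
    clay: float | None = None
    root_density: float | None = None

    @property
    def thickness(self) -> float:
        return self.bottom_depth - self.top_depth

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.top_depth + self.bottom_depth)


@dataclass
class SoilProfile:
    """One stage x replicate pedon: contiguous horizons from the surface down.

    ``crack_depth`` is the vertical extent (cm) of topsoil already removed at
    this plot, i.e. the local surface (depth 0) corresponds to depth
    ``crack_depth`` in the reference frame of the intact stage.  It is 0 for
    the reference stage S0.
    """

    stage: DegradationStage
    replicate: str
    crack_depth: float
    horizons: list[Horizon] = field(default_factory=list)

    @property
    def depth(self) -> float:
        """Total described depth (cm) of the profile."""
        return self.horizons[-1].bottom_depth if self.horizons else 0.0

    def to_reference_depth(self, local_depth: float) -> float:
        """Map a local depth to the reference (pre-erosion) depth frame."""
        return local_depth + self.crack_depth


@dataclass
class StageEnsemble:
    """All replicate profiles of one degradation stage."""

    stage: DegradationStage
    profiles: list[SoilProfile]

    def __post_init__(self) -> None:
        if not self.profiles:
            raise DataError(f"stage {self.stage}: empty ensemble")
        for p in self.profiles:
            if p.stage != self.stage:
                raise DataError(
                    f"stage {self.stage}: profile {p.replicate} has stage {p.stage}"
                )
        reps = [p.replicate for p in self.profiles]
        if len(set(reps)) != len(reps):
            raise DataError(f"stage {self.stage}: duplicate replicate ids {reps}")

    @property
    def n_replicates(self) -> int:
        return len(self.profiles)

    def mean_crack_depth(self) -> float:
        return sum(p.crack_depth for p in self.profiles) / len(self.profiles)


def validate_profile(profile: SoilProfile) -> list[str]:
    """Check all structural invariants of a profile.

    Returns a list of human-readable violations (empty iff the profile is
    well formed).  Violations are returned rather than raised so that file
    readers can report every problem in one pass.
    """
    violations: list[str] = []

    if profile.crack_depth < 0:
        violations.append(f"crack_depth: negative ({profile.crack_depth})")
    if profile.stage.is_reference and profile.crack_depth > 0:
        violations.append(
            f"crack_depth: reference crack (S0 requires 0, got {profile.crack_depth})"
        )

    if not profile.horizons:
        violations.append("horizons: empty profile")
        return violations

    for h in profile.horizons:
        if h.top_depth < 0:
            violations.append(f"horizon {h.label}: top_depth negative ({h.top_depth})")
        if not h.top_depth < h.bottom_depth:
            violations.append(
                f"horizon {h.label}: depth order "
                f"(top {h.top_depth} >= bottom {h.bottom_depth})"
            )
        if h.soc_content < 0:
            violations.append(f"horizon {h.label}: soc_content negative ({h.soc_content})")
        if not h.bulk_density > 0:
            violations.append(
                f"horizon {h.label}: bulk_density not positive ({h.bulk_density})"
            )
        if h.n_content is not None and h.n_content < 0:
            violations.append(f"horizon {h.label}: n_content negative ({h.n_content})")
        if h.vsc_content is not None and not (0.0 <= h.vsc_content <= 1.0):
            violations.append(
                f"horizon {h.label}: vsc_content outside [0,1] ({h.vsc_content})"
            )

    if abs(profile.horizons[0].top_depth) > _DEPTH_TOL:
        violations.append(
            f"horizons: first horizon starts at {profile.horizons[0].top_depth}, not 0"
        )
    for above, below in zip(profile.horizons, profile.horizons[1:]):
        if not math.isclose(
            above.bottom_depth, below.top_depth, abs_tol=_DEPTH_TOL, rel_tol=0.0
        ):
            violations.append(
                f"horizons: not contiguous between {above.label} "
                f"(bottom {above.bottom_depth}) and {below.label} (top {below.top_depth})"
            )

    return violations


def horizon_at(profile: SoilProfile, depth: float) -> Horizon:
    """Return the horizon whose half-open interval [top, bottom) contains *depth*.

    Raises :class:`DataError` when *depth* lies outside ``[0, profile.depth)``.
    """
    for h in profile.horizons:
        if h.top_depth <= depth < h.bottom_depth:
            return h
    raise DataError(
        f"depth out of range: {depth} cm not in [0, {profile.depth}) "
        f"of profile {profile.stage}/{profile.replicate}"
    )
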