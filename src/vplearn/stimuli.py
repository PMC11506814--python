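"""Dynamic Glass patterns, modified random-dot kinematograms and their
equivalent-noise variants, generated as geometric data.

A dynamic Glass pattern (GP) is a field of dot pairs ("dipoles") whose shared
orientation induces a global form; positions are resampled every frame while
orientations stay constant, which yields illusory non-directional motion. A
modified random-dot kinematogram (mRDK) is a field of single dots in which
signal dots step along a fixed axis with the up/down sign redrawn each frame,
so motion is seen along the axis but has no net direction.

Geometry is expressed in degrees of visual angle. Orientations are measured
from the vertical axis on the axial domain (-pi/2, pi/2]; per-frame motion
directions are full-circle. An orientation ``theta`` maps to the unit vector
``(sin theta, cos theta)``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from ._angles import wrap_axial, wrap_direction

__all__ = [
    "AnnulusGeometry",
    "GPSpec",
    "MRDKSpec",
    "ENStimulusSpec",
    "StimulusFrame",
    "FrameSequence",
    "generate_gp_frame",
    "generate_gp_sequence",
    "generate_mrdk_sequence",
    "generate_en_field",
    "render_frame",
    "sequence_to_dataframe",
]


class StimulusSpecError(ValueError):
    """A stimulus specification violates one of its invariants."""


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class AnnulusGeometry:
    """Annular aperture the elements live in.

    Defaults follow the standard display: inner radius 0.2 deg, outer radius
    5 deg, square dots 0.083 deg wide, white on gray.
    """

    inner_radius: float = 0.2
    outer_radius: float = 5.0
    element_size: float = 0.083
    background_level: float = 0.5
    dot_level: float = 1.0

    def __post_init__(self):
        if not 0 <= self.inner_radius < self.outer_radius:
            raise StimulusSpecError(
                "annulus requires 0 <= inner_radius < outer_radius, got "
                f"inner_radius={self.inner_radius}, outer_radius={self.outer_radius}"
            )
        if self.element_size <= 0:
            raise StimulusSpecError(f"element_size must be > 0, got {self.element_size}")


@dataclass(frozen=True)
class GPSpec:
    """Dynamic Glass pattern: 250 dipoles, 0.18 deg dot separation, 10 Hz."""

    n_dipoles: int = 250
    dipole_separation: float = 0.18
    coherence: float = 1.0
    signal_orientation: float = 0.0
    geometry: AnnulusGeometry = field(default_factory=AnnulusGeometry)
    frame_rate: float = 10.0
    frame_duration: float = 0.1

    def __post_init__(self):
        if self.n_dipoles <= 0:
            raise StimulusSpecError(f"n_dipoles must be > 0, got {self.n_dipoles}")
        if not 0.0 <= self.coherence <= 1.0:
            raise StimulusSpecError(f"coherence must lie in [0, 1], got {self.coherence}")
        if self.dipole_separation <= 0:
            raise StimulusSpecError(
                f"dipole_separation must be > 0, got {self.dipole_separation}"
            )
        if abs(self.frame_rate * self.frame_duration - 1.0) > 1e-6:
            raise StimulusSpecError(
                "frame_rate * frame_duration must equal 1, got "
                f"{self.frame_rate} * {self.frame_duration}"
            )


@dataclass(frozen=True)
class MRDKSpec:
    """Modified RDK: 500 dots, 0.18 deg step per frame, vertical signal axis."""

    n_dots: int = 500
    step_size: float = 0.18
    coherence: float = 1.0
    signal_axis: float = 0.0
    dot_lifetime: int = 2
    geometry: AnnulusGeometry = field(default_factory=AnnulusGeometry)
    frame_rate: float = 10.0
    frame_duration: float = 0.1

    def __post_init__(self):
        if self.n_dots <= 0:
            raise StimulusSpecError(f"n_dots must be > 0, got {self.n_dots}")
        if not 0.0 <= self.coherence <= 1.0:
            raise StimulusSpecError(f"coherence must lie in [0, 1], got {self.coherence}")
        if self.step_size <= 0:
            raise StimulusSpecError(f"step_size must be > 0, got {self.step_size}")
        if self.dot_lifetime < 1:
            raise StimulusSpecError(f"dot_lifetime must be >= 1, got {self.dot_lifetime}")


@dataclass(frozen=True)
class ENStimulusSpec:
    """Equivalent-noise variant: every element is signal; orientations or
    directions are drawn from a Gaussian around (vertical + mean_offset) with
    SD sigma_ext, wrapped onto the domain."""

    base: Union[GPSpec, MRDKSpec]
    mean_offset: float = 0.0
    sigma_ext: float = 0.0

    def __post_init__(self):
        if self.sigma_ext < 0:
            raise StimulusSpecError(f"sigma_ext must be >= 0, got {self.sigma_ext}")
        coherence = self.base.coherence
        if coherence != 1.0:
            raise StimulusSpecError(
                "equivalent-noise stimuli treat every element as signal; "
                f"base coherence must be 1, got {coherence}"
            )


@dataclass
class StimulusFrame:
    """One stimulus frame: element centers (deg), orientations/directions
    (rad) and signal flags. GP frames additionally carry the two dot centers
    per dipole; mRDK frames carry per-dot age and a repositioned mask (dots
    relocated on the step into this frame)."""

    element_centers: np.ndarray
    element_orientations_or_directions: np.ndarray
    is_signal: np.ndarray
    kind: str  # "gp" or "mrdk"
    dot_centers: np.ndarray | None = None  # GP: (n_dipoles, 2, 2)
    age: np.ndarray | None = None  # mRDK: frames since (re)placement
    repositioned: np.ndarray | None = None

    @property
    def n_elements(self) -> int:
        return len(self.element_centers)


@dataclass
class FrameSequence:
    """Ordered frames of one stimulus interval."""

    frames: list[StimulusFrame]
    frame_rate: float

    @property
    def duration(self) -> float:
        return len(self.frames) / self.frame_rate

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> StimulusFrame:
        return self.frames[i]

    def __iter__(self) -> Iterator[StimulusFrame]:
        return iter(self.frames)


def _sample_annulus(geometry: AnnulusGeometry, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-by-area positions in the annulus."""
    r = np.sqrt(
        rng.uniform(geometry.inner_radius**2, geometry.outer_radius**2, size=n)
    )
    phi = rng.uniform(0.0, 2 * np.pi, size=n)
    return np.column_stack([r * np.sin(phi), r * np.cos(phi)])


def _orientation_unit(theta: np.ndarray) -> np.ndarray:
    return np.column_stack([np.sin(theta), np.cos(theta)])


def _inside_annulus(points: np.ndarray, geometry: AnnulusGeometry) -> np.ndarray:
    r = np.hypot(points[..., 0], points[..., 1])
    return (r >= geometry.inner_radius) & (r <= geometry.outer_radius)


def n_signal_elements(coherence: float, n_elements: int) -> int:
    """Signal-element count: round-half-up of coherence * n_elements."""
    return _round_half_up(coherence * n_elements)


def _place_dipoles(
    orientations: np.ndarray, spec: GPSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dipole centers uniform in the annulus; configurations whose dots would
    protrude beyond the annulus are resampled so density stays uniform."""
    n = len(orientations)
    half = 0.5 * spec.dipole_separation * _orientation_unit(orientations)
    centers = np.empty((n, 2))
    pending = np.arange(n)
    for _ in range(10_000):
        candidate = _sample_annulus(spec.geometry, len(pending), rng)
        ok = _inside_annulus(candidate + half[pending], spec.geometry) & _inside_annulus(
            candidate - half[pending], spec.geometry
        )
        centers[pending[ok]] = candidate[ok]
        pending = pending[~ok]
        if len(pending) == 0:
            break
    else:  # pragma: no cover - would need a pathological geometry
        raise StimulusSpecError("could not place dipoles inside the annulus")
    dots = np.stack([centers + half, centers - half], axis=1)
    return centers, dots


def generate_gp_frame(spec: GPSpec, rng) -> StimulusFrame:
    """One Glass-pattern frame: round(coherence * n_dipoles) dipoles at the
    signal orientation, the rest uniformly oriented, centers uniform over the
    annulus, each dipole realised as two dots dipole_separation apart."""
    rng = _as_rng(rng)
    n = spec.n_dipoles
    n_sig = n_signal_elements(spec.coherence, n)
    orientations = np.empty(n)
    orientations[:n_sig] = wrap_axial(spec.signal_orientation)
    orientations[n_sig:] = wrap_axial(rng.uniform(-np.pi / 2, np.pi / 2, size=n - n_sig))
    is_signal = np.zeros(n, dtype=bool)
    is_signal[:n_sig] = True
    centers, dots = _place_dipoles(orientations, spec, rng)
    return StimulusFrame(
        element_centers=centers,
        element_orientations_or_directions=orientations,
        is_signal=is_signal,
        kind="gp",
        dot_centers=dots,
    )


def generate_gp_sequence(spec: GPSpec, n_frames: int, rng) -> FrameSequence:
    """Independent frames (fresh positions, no dipole correspondence); the
    signal orientation is constant across frames."""
    if n_frames < 1:
        raise StimulusSpecError(f"n_frames must be >= 1, got {n_frames}")
    rng = _as_rng(rng)
    return FrameSequence(
        frames=[generate_gp_frame(spec, rng) for _ in range(n_frames)],
        frame_rate=spec.frame_rate,
    )


def generate_mrdk_sequence(spec: MRDKSpec, n_frames: int, rng) -> FrameSequence:
    """mRDK frames: signal dots step by step_size along the signal axis with
    the up/down sign redrawn per dot per frame; noise dots step in uniformly
    random directions; dots reaching dot_lifetime (or leaving the annulus)
    are relocated uniformly with their lifetime reset."""
    if n_frames < 1:
        raise StimulusSpecError(f"n_frames must be >= 1, got {n_frames}")
    rng = _as_rng(rng)
    n = spec.n_dots
    n_sig = n_signal_elements(spec.coherence, n)
    is_signal = np.zeros(n, dtype=bool)
    is_signal[:n_sig] = True

    positions = _sample_annulus(spec.geometry, n, rng)
    # staggered ages so a constant fraction of dots relocates per frame
    age = rng.integers(0, spec.dot_lifetime, size=n)
    repositioned = np.zeros(n, dtype=bool)

    frames: list[StimulusFrame] = []
    for _ in range(n_frames):
        # direction of the step taken out of this frame
        directions = np.empty(n)
        sign = rng.integers(0, 2, size=n_sig)  # up or down along the axis
        directions[:n_sig] = wrap_direction(spec.signal_axis + np.pi * sign)
        directions[n_sig:] = wrap_direction(rng.uniform(-np.pi, np.pi, size=n - n_sig))

        frames.append(
            StimulusFrame(
                element_centers=positions.copy(),
                element_orientations_or_directions=directions,
                is_signal=is_signal.copy(),
                kind="mrdk",
                age=age.copy(),
                repositioned=repositioned.copy(),
            )
        )

        step = spec.step_size * _orientation_unit(directions)
        stepped = positions + step
        expired = age + 1 >= spec.dot_lifetime
        escaped = ~_inside_annulus(stepped, spec.geometry)
        relocate = expired | escaped
        stepped[relocate] = _sample_annulus(spec.geometry, int(relocate.sum()), rng)
        age = np.where(relocate, 0, age + 1)
        positions = stepped
        repositioned = relocate
    return FrameSequence(frames=frames, frame_rate=spec.frame_rate)


def generate_en_field(spec: ENStimulusSpec, n_frames: int, rng) -> FrameSequence:
    """Equivalent-noise stimulus: every element is signal and its orientation
    (GP) or per-frame direction axis (mRDK) is drawn from a Gaussian with
    mean vertical + mean_offset and SD sigma_ext, wrapped onto the axial
    domain (wrapping rather than truncation avoids distorting the tails)."""
    if n_frames < 1:
        raise StimulusSpecError(f"n_frames must be >= 1, got {n_frames}")
    rng = _as_rng(rng)
    base = spec.base
    frames: list[StimulusFrame] = []
    if isinstance(base, GPSpec):
        for _ in range(n_frames):
            theta = wrap_axial(
                rng.normal(spec.mean_offset, spec.sigma_ext, size=base.n_dipoles)
            )
            centers, dots = _place_dipoles(theta, base, rng)
            frames.append(
                StimulusFrame(
                    element_centers=centers,
                    element_orientations_or_directions=theta,
                    is_signal=np.ones(base.n_dipoles, dtype=bool),
                    kind="gp",
                    dot_centers=dots,
                )
            )
        return FrameSequence(frames=frames, frame_rate=base.frame_rate)
    if isinstance(base, MRDKSpec):
        n = base.n_dots
        positions = _sample_annulus(base.geometry, n, rng)
        age = rng.integers(0, base.dot_lifetime, size=n)
        repositioned = np.zeros(n, dtype=bool)
        for _ in range(n_frames):
            axis = rng.normal(spec.mean_offset, spec.sigma_ext, size=n)
            sign = rng.integers(0, 2, size=n)
            directions = wrap_direction(axis + np.pi * sign)
            frames.append(
                StimulusFrame(
                    element_centers=positions.copy(),
                    element_orientations_or_directions=wrap_axial(axis),
                    is_signal=np.ones(n, dtype=bool),
                    kind="mrdk",
                    age=age.copy(),
                    repositioned=repositioned.copy(),
                )
            )
            step = base.step_size * _orientation_unit(directions)
            stepped = positions + step
            relocate = (age + 1 >= base.dot_lifetime) | ~_inside_annulus(
                stepped, base.geometry
            )
            stepped[relocate] = _sample_annulus(base.geometry, int(relocate.sum()), rng)
            age = np.where(relocate, 0, age + 1)
            positions = stepped
            repositioned = relocate
        return FrameSequence(frames=frames, frame_rate=base.frame_rate)
    raise StimulusSpecError(f"unsupported base spec {type(base).__name__}")


def render_frame(
    frame: StimulusFrame,
    pixels_per_degree: float,
    image_size: int = 512,
    geometry: AnnulusGeometry | None = None,
) -> np.ndarray:
    """Rasterise a frame: white square dots on a gray background, origin at
    the image center, y up. Returns a uint8 array (deterministic given the
    frame). Raises if the frame does not fit the image."""
    if pixels_per_degree <= 0:
        raise StimulusSpecError(f"pixels_per_degree must be > 0, got {pixels_per_degree}")
    geometry = geometry or AnnulusGeometry()
    if frame.kind == "gp" and frame.dot_centers is not None:
        points = frame.dot_centers.reshape(-1, 2)
    else:
        points = np.asarray(frame.element_centers, dtype=float).reshape(-1, 2)

    bg = int(round(255 * geometry.background_level))
    fg = int(round(255 * geometry.dot_level))
    image = np.full((image_size, image_size), bg, dtype=np.uint8)
    if len(points) == 0:
        return image

    half_px = max(1, int(round(geometry.element_size * pixels_per_degree))) / 2.0
    cx = (image_size - 1) / 2.0
    col = cx + points[:, 0] * pixels_per_degree
    row = cx - points[:, 1] * pixels_per_degree
    lo_c, hi_c = np.floor(col - half_px).astype(int), np.ceil(col + half_px).astype(int)
    lo_r, hi_r = np.floor(row - half_px).astype(int), np.ceil(row + half_px).astype(int)
    if lo_c.min() < 0 or lo_r.min() < 0 or hi_c.max() > image_size or hi_r.max() > image_size:
        raise ValueError(
            "frame extent exceeds the image; increase image_size or reduce "
            "pixels_per_degree"
        )
    for r0, r1, c0, c1 in zip(lo_r, hi_r, lo_c, hi_c):
        image[r0:r1, c0:c1] = fg
    return image


def save_frame_png(frame: StimulusFrame, path, pixels_per_degree: float,
                   image_size: int = 512, geometry: AnnulusGeometry | None = None) -> None:
    from PIL import Image

    Image.fromarray(render_frame(frame, pixels_per_degree, image_size, geometry)).save(path)


def sequence_to_dataframe(seq: FrameSequence) -> pd.DataFrame:
    """Long-format geometry table: frame, element_id, x_deg, y_deg, theta_rad,
    is_signal. GP frames emit one row per dot (two per dipole, sharing the
    dipole's element_id and orientation)."""
    rows = []
    for t, frame in enumerate(seq):
        if frame.kind == "gp" and frame.dot_centers is not None:
            for i in range(frame.n_elements):
                for dot in frame.dot_centers[i]:
                    rows.append(
                        (t, i, dot[0], dot[1],
                         frame.element_orientations_or_directions[i],
                         bool(frame.is_signal[i]))
                    )
        else:
            for i in range(frame.n_elements):
                rows.append(
                    (t, i, frame.element_centers[i, 0], frame.element_centers[i, 1],
                     frame.element_orientations_or_directions[i],
                     bool(frame.is_signal[i]))
                )
    return pd.DataFrame(
        rows, columns=["frame", "element_id", "x_deg", "y_deg", "theta_rad", "is_signal"]
    )


# --- spec (de)serialisation -------------------------------------------------

_SPEC_CLASSES = {"GPSpec": GPSpec, "MRDKSpec": MRDKSpec, "ENStimulusSpec": ENStimulusSpec}


def spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    d["_type"] = type(spec).__name__
    if isinstance(spec, ENStimulusSpec):
        d["base"]["_type"] = type(spec.base).__name__
    return d


def spec_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("_type")
    if kind == "ENStimulusSpec":
        base = spec_from_dict(d.pop("base"))
        return ENStimulusSpec(base=base, **d)
    cls = _SPEC_CLASSES[kind]
    if "geometry" in d and isinstance(d["geometry"], dict):
        d["geometry"] = AnnulusGeometry(**d["geometry"])
    return cls(**d)


def spec_to_yaml(spec) -> str:
    return yaml.safe_dump(spec_to_dict(spec), sort_keys=True)


def spec_from_yaml(text: str):
    return spec_from_dict(yaml.safe_load(text))
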