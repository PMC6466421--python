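"""Helical-minichannel geometry and rotation-synchronized acquisition.

The sample cartridge is a threaded cylinder: a rectangular minichannel
(600 µm wide, 100 µm deep by default) winds around it like the thread of
a bolt.  Rotating the cartridge in a matching nut advances the imaged
region along the channel, so a camera triggered every ``angular_step``
degrees tiles the channel with fields of view of known volume.  The
functions here convert frame counts into interrogated sample volume and
sanity-check that a scan plan is physically consistent with the channel.

All user-facing lengths carry a unit suffix (``_um`` or ``_mm``); volumes
are reported in µL.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "ChannelSpec",
    "AcquisitionPlan",
    "ArcStep",
    "frame_volume",
    "total_sampled_volume",
    "frames_per_revolution",
    "helix_channel_length",
    "channel_capacity",
    "arc_per_step",
]

#: cubic micrometres per microlitre
UM3_PER_UL = 1.0e9


@dataclass(frozen=True)
class ChannelSpec:
    """Physical geometry of the helical minichannel and its cartridge.

    Parameters
    ----------
    channel_width_um, channel_depth_um:
        Cross-section of the rectangular channel, µm.
    pitch_um:
        Axial centre-to-centre spacing of adjacent helix turns, µm.  Must
        be at least ``channel_width_um`` or adjacent turns would overlap.
        The default of 700 µm (600 µm channel plus a 100 µm wall) is an
        assumption; the cartridge drawing does not fix it.
    cartridge_diameter_mm, cartridge_length_mm:
        Outer dimensions of the cylindrical cartridge, mm.
    threaded_length_mm:
        Portion of the cartridge length actually carrying the channel,
        mm.  Defaults to 56 mm (66 mm cartridge minus an assumed 10 mm
        head/coupling).
    """

    channel_width_um: float = 600.0
    channel_depth_um: float = 100.0
    pitch_um: float = 700.0
    cartridge_diameter_mm: float = 6.0
    cartridge_length_mm: float = 66.0
    threaded_length_mm: float = 56.0

    def __post_init__(self) -> None:
        for name in (
            "channel_width_um",
            "channel_depth_um",
            "pitch_um",
            "cartridge_diameter_mm",
            "cartridge_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.threaded_length_mm < 0:
            raise ValueError("threaded_length_mm must be >= 0")
        if self.pitch_um < self.channel_width_um:
            raise ValueError(
                "pitch_um must be >= channel_width_um (helix turns must not overlap): "
                f"{self.pitch_um} < {self.channel_width_um}"
            )
        if self.threaded_length_mm > self.cartridge_length_mm:
            raise ValueError("threaded_length_mm cannot exceed cartridge_length_mm")


@dataclass(frozen=True)
class AcquisitionPlan:
    """One rotation-synchronized scan: frame geometry, pixel grid, stepping.

    ``frame_width_um`` runs across the channel, ``frame_height_um`` along
    it.  Each trigger yields one frame *pair* (one frame per fluorescence
    channel), so ``n_frame_pairs`` counts interrogated fields of view, not
    raw images.  Defaults follow the prototype: a 0.6 × 0.49 mm field on a
    1280 × 960 sensor, stepped 20° per frame.
    """

    frame_width_um: float = 600.0
    frame_height_um: float = 490.0
    angular_step_deg: float = 20.0
    n_frame_pairs: int = 100
    pixels_x: int = 1280
    pixels_y: int = 960

    def __post_init__(self) -> None:
        if self.frame_width_um <= 0 or self.frame_height_um <= 0:
            raise ValueError("frame dimensions must be > 0")
        if not (0 < self.angular_step_deg <= 360):
            raise ValueError("angular_step_deg must be in (0, 360]")
        if self.n_frame_pairs < 1:
            raise ValueError("n_frame_pairs must be >= 1")
        if self.pixels_x < 1 or self.pixels_y < 1:
            raise ValueError("pixel counts must be >= 1")

    @property
    def pixel_scale_x_um(self) -> float:
        """µm spanned by one pixel across the channel."""
        return self.frame_width_um / self.pixels_x

    @property
    def pixel_scale_y_um(self) -> float:
        """µm spanned by one pixel along the channel."""
        return self.frame_height_um / self.pixels_y

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_scale_x_um * self.pixel_scale_y_um

    def downscaled(self, factor: int) -> "AcquisitionPlan":
        """Same physical field of view on a coarser pixel grid."""
        if factor < 1 or self.pixels_x % factor or self.pixels_y % factor:
            raise ValueError(f"factor {factor} must divide both pixel counts")
        return AcquisitionPlan(
            frame_width_um=self.frame_width_um,
            frame_height_um=self.frame_height_um,
            angular_step_deg=self.angular_step_deg,
            n_frame_pairs=self.n_frame_pairs,
            pixels_x=self.pixels_x // factor,
            pixels_y=self.pixels_y // factor,
        )


class ArcStep(NamedTuple):
    """Cartridge surface arc travelled per trigger, and whether consecutive
    frames overlap along the channel (arc shorter than the frame height)."""

    arc_mm: float
    overlaps: bool


def frame_volume(plan: AcquisitionPlan, channel: ChannelSpec) -> float:
    """Sample volume interrogated by a single field of view, in µL.

    The camera images the full channel depth, so one frame covers
    ``frame_width × frame_height × channel_depth``.  With the default
    geometry (0.6 mm × 0.49 mm field, 0.1 mm deep channel) this is the
    0.0294 µL per image that absolute counting divides by.
    """
    return (
        plan.frame_width_um * plan.frame_height_um * channel.channel_depth_um
    ) / UM3_PER_UL


def total_sampled_volume(plan: AcquisitionPlan, channel: ChannelSpec) -> float:
    """Total probe volume of a scan: ``n_frame_pairs`` × :func:`frame_volume`, µL.

    Linear in the number of frame pairs.  Warns if the plan claims more
    volume than the channel can physically hold (see
    :func:`channel_capacity`).
    """
    vol = plan.n_frame_pairs * frame_volume(plan, channel)
    cap = channel_capacity(channel)
    if vol > cap:
        warnings.warn(
            f"total sampled volume {vol:.4g} µL exceeds channel capacity "
            f"{cap:.4g} µL; the plan re-images sample or is inconsistent",
            stacklevel=2,
        )
    return vol


def frames_per_revolution(plan: AcquisitionPlan) -> float:
    """Number of frames per full cartridge revolution, 360 / angular_step.

    A non-integer quotient (the motor step does not tile the revolution
    exactly) is legal hardware behaviour and raises a warning only.
    """
    q = 360.0 / plan.angular_step_deg
    if abs(q - round(q)) > 1e-9:
        warnings.warn(
            f"angular step {plan.angular_step_deg}° does not divide 360°: "
            f"{q:.4g} frames per revolution",
            stacklevel=2,
        )
    return q


def helix_channel_length(channel: ChannelSpec) -> float:
    """Unrolled arc length of the helical channel, mm.

    Each turn of a helix of diameter *d* and pitch *p* has length
    ``sqrt((π d)² + p²)`` (unroll the cylinder into a plane); the number
    of turns is ``threaded_length / pitch``.  Always at least the axial
    travel ``threaded_length``.
    """
    pitch_mm = channel.pitch_um / 1000.0
    n_turns = channel.threaded_length_mm / pitch_mm
    per_turn = math.hypot(math.pi * channel.cartridge_diameter_mm, pitch_mm)
    return n_turns * per_turn


def channel_capacity(channel: ChannelSpec) -> float:
    """Total volume the helical channel holds, µL.

    Arc length × cross-section.  This bounds :func:`total_sampled_volume`
    for any plan that does not image the same fluid twice.
    """
    width_mm = channel.channel_width_um / 1000.0
    depth_mm = channel.channel_depth_um / 1000.0
    return helix_channel_length(channel) * width_mm * depth_mm  # mm³ == µL


def arc_per_step(channel: ChannelSpec, plan: AcquisitionPlan) -> ArcStep:
    """Surface arc the channel advances per angular step, with overlap flag.

    ``arc = π · diameter · step/360``.  If the arc is shorter than the
    frame height, consecutive frames overlap along the channel and cells
    could be counted twice.
    """
    arc = math.pi * channel.cartridge_diameter_mm * plan.angular_step_deg / 360.0
    return ArcStep(arc_mm=arc, overlaps=arc < plan.frame_height_um / 1000.0)
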