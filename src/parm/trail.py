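"""Trail-spread-function (TSF) velocimetry.

A microbubble moving through the imaging plane traces a continuous bright
tube through the 3D spatio-temporal stack (t, z, x): the trail spread
function.  The orientation of that tube encodes the instantaneous velocity —
a tube parallel to the time axis is a stationary bubble, while the in-plane
components of the tube axis give displacement per frame.  This module
estimates per-voxel tube orientation with a 3D structure tensor built from
Gaussian-derivative gradients, and converts it to per-voxel speed and flow
direction.  No localization or tracking of individual bubbles is involved:
every sufficiently bright, sufficiently tube-like voxel yields one feature
point.

For a voxel with structure tensor eigenvalues l1 >= l2 >= l3, the tube axis
is the eigenvector of l3 (the direction of least intensity variation) and
the coherence (l2 - l3) / (l2 + l3) in [0, 1] measures how tube-like the
neighborhood is — 1 for an ideal line, 0 for isotropic texture.  Distorted
signal from overlapping bubbles is rejected by a coherence floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .synthetic import CeusSequence

__all__ = [
    "SpatioTemporalStack",
    "OrientationField",
    "FeaturePointSet",
    "build_stack",
    "tensor_orientation",
    "extract_feature_points",
    "default_v_max",
]


@dataclass
class SpatioTemporalStack:
    """A (t, z, x) intensity block plus the mask of accepted MB voxels."""

    voxels: np.ndarray                 # (t, z, x) intensities
    pixel_size: float                  # mm
    frame_interval: float              # s
    mb_mask: np.ndarray                # (t, z, x) bool
    segment: tuple = (0, 0)            # (start, end) frames in the source sequence

    def __post_init__(self):
        if self.mb_mask.shape != self.voxels.shape:
            raise ValueError("mb_mask shape must equal voxels shape")

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]


@dataclass
class OrientationField:
    """Principal tube axis and coherence at the masked voxels of a stack.

    ``indices`` holds the (t, z, x) coordinates of the voxels (in the order
    of ``np.nonzero`` on the mask); ``axes`` the unit eigenvectors
    (u_t, u_z, u_x) with u_t >= 0; ``coherence`` the tube-ness in [0, 1].
    """

    indices: tuple                     # 3-tuple of (n,) int arrays (t, z, x)
    axes: np.ndarray                   # (n, 3) unit vectors (u_t, u_z, u_x)
    coherence: np.ndarray              # (n,)


@dataclass
class FeaturePointSet:
    """Per-voxel instantaneous flow samples — the clustering input.

    Column-array container; one row per accepted voxel.  ``direction`` is
    radians in (-pi, pi] measured from +x toward +z; ``speed`` mm/s clipped
    at the configured maximum (``clipped`` marks affected rows).
    """

    t_index: np.ndarray                # frame index in the source sequence
    x: np.ndarray                      # mm
    z: np.ndarray                      # mm
    speed: np.ndarray                  # mm/s
    direction: np.ndarray              # radians, (-pi, pi]
    coherence: np.ndarray
    intensity: np.ndarray
    clipped: np.ndarray                # bool, speed hit v_max
    voxel_indices: tuple = ()          # (t, z, x) stack-local indices
    source_segment: tuple = (0, 0)
    pixel_size: float = 0.0
    frame_interval: float = 0.0

    def __len__(self) -> int:
        return len(self.speed)

    def select(self, sel: np.ndarray) -> "FeaturePointSet":
        """Row subset by boolean mask."""
        vox = tuple(a[sel] for a in self.voxel_indices) \
            if self.voxel_indices else ()
        return FeaturePointSet(
            t_index=self.t_index[sel], x=self.x[sel], z=self.z[sel],
            speed=self.speed[sel], direction=self.direction[sel],
            coherence=self.coherence[sel], intensity=self.intensity[sel],
            clipped=self.clipped[sel], voxel_indices=vox,
            source_segment=self.source_segment, pixel_size=self.pixel_size,
            frame_interval=self.frame_interval)

    def without_clipped(self) -> "FeaturePointSet":
        """Drop speed-saturated samples (distorted velocity estimates).

        Clipped samples come from near-horizontal tubes — usually bubble
        overlap or boundary artifacts — whose implied speed exceeds the
        measurable maximum; keeping them would also stretch the min-max
        speed normalization and squash the genuine speed range.
        """
        if not self.clipped.any():
            return self
        return self.select(~self.clipped)

    @classmethod
    def concat(cls, sets: list) -> "FeaturePointSet":
        """Merge point sets from separately processed frame segments."""
        if not sets:
            raise ValueError("nothing to concatenate")
        first = sets[0]
        cat = {name: np.concatenate([getattr(s, name) for s in sets])
               for name in ("t_index", "x", "z", "speed", "direction",
                            "coherence", "intensity", "clipped")}
        vox = tuple(np.concatenate([s.voxel_indices[i] for s in sets])
                    for i in range(3)) if all(s.voxel_indices for s in sets) \
            else ()
        seg = (min(s.source_segment[0] for s in sets),
               max(s.source_segment[1] for s in sets))
        return cls(voxel_indices=vox, source_segment=seg,
                   pixel_size=first.pixel_size,
                   frame_interval=first.frame_interval, **cat)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": self.t_index, "z": self.z, "x": self.x,
            "speed": self.speed, "direction": self.direction,
            "coherence": self.coherence, "intensity": self.intensity,
        })

    def to_csv(self, path: str):
        self.to_dataframe().to_csv(path, index=False)

    def to_h5(self, path: str):
        with h5py.File(path, "w") as fh:
            g = fh.create_group("points")
            for name in ("t_index", "x", "z", "speed", "direction",
                         "coherence", "intensity"):
                g.create_dataset(name, data=getattr(self, name))
            fh.attrs["segment_start"], fh.attrs["segment_end"] = self.source_segment
            fh.attrs["pixel_size_mm"] = self.pixel_size
            fh.attrs["frame_interval_s"] = self.frame_interval

    @classmethod
    def from_h5(cls, path: str) -> "FeaturePointSet":
        with h5py.File(path, "r") as fh:
            g = fh["points"]
            kw = {name: g[name][...] for name in
                  ("t_index", "x", "z", "speed", "direction",
                   "coherence", "intensity")}
            n = len(kw["speed"])
            return cls(clipped=np.zeros(n, dtype=bool),
                       source_segment=(int(fh.attrs["segment_start"]),
                                       int(fh.attrs["segment_end"])),
                       pixel_size=float(fh.attrs["pixel_size_mm"]),
                       frame_interval=float(fh.attrs["frame_interval_s"]),
                       **kw)


class EmptyFeatureSetError(RuntimeError):
    """Raised when no voxel survives masking and coherence gating."""


def build_stack(seq: CeusSequence, segment: tuple | None = None,
                detect_threshold: float = 0.99) -> SpatioTemporalStack:
    """Cut a frame segment into a spatio-temporal block and mask MB voxels.

    The mask keeps voxels at or above the ``detect_threshold`` quantile of
    the positive intensities (quantile 1.0 gives an empty mask; an all-zero
    segment gives an empty mask).
    """
    start, end = (0, seq.n_frames) if segment is None else segment
    if not (0 <= start < end <= seq.n_frames):
        raise ValueError(f"segment {segment} outside sequence")
    voxels = seq.frames[start:end]
    positives = voxels[voxels > 0]
    if positives.size == 0:
        mask = np.zeros(voxels.shape, dtype=bool)
    else:
        thr = float(np.quantile(positives, detect_threshold))
        mask = voxels > thr if detect_threshold >= 1.0 else voxels >= thr
    return SpatioTemporalStack(voxels=voxels, pixel_size=seq.pixel_size,
                               frame_interval=seq.frame_interval,
                               mb_mask=mask, segment=(start, end))


def tensor_orientation(stack: SpatioTemporalStack,
                       gradient_sigma: float = 1.0,
                       window_sigma: float = 2.0,
                       time_scale: float = 1.0) -> OrientationField:
    """Per-voxel tube axis and coherence from the 3D structure tensor.

    Gradients are Gaussian derivatives (sigma ``gradient_sigma`` voxels);
    their outer products are averaged in a Gaussian window (sigma
    ``window_sigma`` voxels).  ``time_scale`` is the voxel anisotropy factor
    a (expected pixels of travel per frame): the time derivative is divided
    by it, which is equivalent to stretching the time axis so that the
    tube metric is isotropic.  The axis sign is fixed so u_t >= 0, making
    the in-plane components point along the physical flow direction.
    Zero-gradient voxels get coherence 0.
    """
    if stack.n_frames < 2 * window_sigma:
        raise ValueError("stack too short for the tensor window")
    vol = stack.voxels.astype(np.float32)

    g = [ndi.gaussian_filter(vol, gradient_sigma, order=tuple(int(ax == i)
                                                              for ax in range(3)))
         for i in range(3)]
    g[0] /= float(time_scale)

    # six unique tensor components, window-averaged
    j = {}
    for a in range(3):
        for b in range(a, 3):
            j[(a, b)] = ndi.gaussian_filter(g[a] * g[b], window_sigma)
    del g

    idx = np.nonzero(stack.mb_mask)
    n = idx[0].size
    tensors = np.empty((n, 3, 3), dtype=np.float64)
    for a in range(3):
        for b in range(a, 3):
            comp = j[(a, b)][idx]
            tensors[:, a, b] = comp
            tensors[:, b, a] = comp

    if n == 0:
        return OrientationField(indices=idx, axes=np.empty((0, 3)),
                                coherence=np.empty(0))

    eigvals, eigvecs = np.linalg.eigh(tensors)   # ascending eigenvalues
    # tube axis: least-variation direction = first eigenvector
    axes = eigvecs[:, :, 0]
    l3, l2 = eigvals[:, 0], eigvals[:, 1]
    denom = l2 + l3
    coherence = np.where(denom > 0, (l2 - l3) / np.where(denom > 0, denom, 1.0),
                         0.0)
    trace = eigvals.sum(axis=1)
    coherence = np.where(trace > 1e-12 * max(trace.max(), 1.0), coherence, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)

    # resolve the eigenvector sign ambiguity: forward in time
    flip = axes[:, 0] < 0
    axes[flip] *= -1.0
    return OrientationField(indices=idx, axes=axes, coherence=coherence)


def default_v_max(pixel_size: float, frame_interval: float,
                  window_sigma: float = 2.0) -> float:
    """Largest credibly measurable speed: half the tensor-window extent
    (~4 sigma in voxels) traversed per frame, in mm/s."""
    return 0.5 * (pixel_size / frame_interval) * (4.0 * window_sigma)


def extract_feature_points(stack: SpatioTemporalStack,
                           orientations: OrientationField,
                           v_max: float | None = None,
                           min_coherence: float = 0.5,
                           time_scale: float = 1.0) -> FeaturePointSet:
    """Convert tube orientations at masked voxels into flow samples.

    For axis (u_t, u_z, u_x): vx = (u_x / u_t) * pixel_size / frame_interval
    and likewise vz, so speed = hypot(vx, vz) and direction = atan2(vz, vx).
    Near-horizontal tubes (u_t below the floor implied by ``v_max``) would
    imply unmeasurably high speed; they are clipped to ``v_max`` and
    flagged.  Voxels with coherence below ``min_coherence`` are dropped —
    this is the rejection of distorted signal from overlapping bubbles.
    """
    if v_max is None:
        v_max = default_v_max(stack.pixel_size, stack.frame_interval)
    keep = orientations.coherence >= min_coherence
    if not np.any(keep):
        raise EmptyFeatureSetError(
            "no MB signal: no voxel passes the coherence gate")
    axes = orientations.axes[keep]
    coh = orientations.coherence[keep]
    it, iz, ix = (a[keep] for a in orientations.indices)

    scale = stack.pixel_size / stack.frame_interval    # mm/s per (px/frame)
    u_t, u_z, u_x = axes[:, 0], axes[:, 1] * time_scale, axes[:, 2] * time_scale
    u_xy = np.hypot(u_x, u_z)
    # u_t floor: slope implying speed > v_max
    floor = u_xy * scale / v_max if v_max > 0 else np.zeros_like(u_t)
    clipped = u_t < floor
    safe_t = np.maximum(u_t, 1e-12)
    vx = (u_x / safe_t) * scale
    vz = (u_z / safe_t) * scale
    speed = np.hypot(vx, vz)
    over = speed > v_max
    clipped = clipped | over
    speed = np.minimum(speed, v_max)
    direction = np.arctan2(vz, vx)
    # wrap -pi to +pi so the range is (-pi, pi]
    direction = np.where(direction == -np.pi, np.pi, direction)

    start, _ = stack.segment
    return FeaturePointSet(
        t_index=it + start,
        x=(ix + 0.5) * stack.pixel_size,
        z=(iz + 0.5) * stack.pixel_size,
        speed=speed, direction=direction, coherence=coh,
        intensity=stack.voxels[it, iz, ix].astype(float),
        clipped=clipped,
        voxel_indices=(it, iz, ix),
        source_segment=stack.segment,
        pixel_size=stack.pixel_size,
        frame_interval=stack.frame_interval,
    )
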