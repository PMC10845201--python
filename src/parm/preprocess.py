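"""Clutter rejection and motion screening for CEUS sequences.

Tissue signal in ultrafast contrast-enhanced ultrasound is spatially
coherent and slowly varying, so it concentrates in the leading singular
components of the Casorati matrix (pixels x frames).  Removing those
components leaves the flowing-microbubble signal.  Frames corrupted by
bulk motion are detected by the Pearson correlation of adjacent B-mode
frames and excised before filtering; the survivors are split into
contiguous segments that are processed independently downstream so that
velocity estimation never spans a temporal gap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .synthetic import CeusSequence

__all__ = [
    "CasoratiDecomposition",
    "MotionReport",
    "casorati_svd",
    "svd_filter",
    "screen_motion",
]


@dataclass
class CasoratiDecomposition:
    """Economy SVD of the (pixels x frames) Casorati matrix of a sequence."""

    singular_values: np.ndarray        # (r,), non-increasing, >= 0
    spatial_components: np.ndarray     # (r, nz, nx) left singular vectors
    temporal_components: np.ndarray    # (r, nt) right singular vectors
    cutoff_low: int = 0
    cutoff_high: int | None = None
    frame_shape: tuple = ()

    @property
    def n_components(self) -> int:
        return len(self.singular_values)

    def reconstruct(self, low: int = 0, high: int | None = None) -> np.ndarray:
        """Frames rebuilt from components ``low .. high`` (inclusive)."""
        high = self.n_components - 1 if high is None else high
        sl = slice(low, high + 1)
        nz, nx = self.frame_shape
        u = self.spatial_components[sl].reshape(-1, nz * nx).T    # (px, k)
        sv = self.singular_values[sl]
        vt = self.temporal_components[sl]                          # (k, nt)
        rec = (u * sv) @ vt                                        # (px, nt)
        return rec.T.reshape(-1, nz, nx)


def casorati_svd(seq: CeusSequence) -> CasoratiDecomposition:
    """Decompose a sequence into spatiotemporal singular components.

    Exact in the sense that rebuilding from all components reproduces the
    input to floating-point accuracy.
    """
    nt, nz, nx = seq.frames.shape
    if nt < 2:
        raise ValueError("need at least 2 frames")
    casorati = seq.frames.reshape(nt, nz * nx).T.astype(np.float64)  # (px, t)
    u, s, vt = np.linalg.svd(casorati, full_matrices=False)
    return CasoratiDecomposition(
        singular_values=s,
        spatial_components=u.T.reshape(-1, nz, nx),
        temporal_components=vt,
        frame_shape=(nz, nx),
    )


def adaptive_cutoff(singular_values: np.ndarray) -> int:
    """Tissue/blood cutoff as the largest-curvature turning point of the
    log singular-value curve, searched over the first half of the spectrum.

    Returns the index of the first component to *retain*.
    """
    s = np.asarray(singular_values, dtype=float)
    s = np.maximum(s, np.finfo(float).tiny)
    logs = np.log10(s)
    half = max(len(logs) // 2, 3)
    d2 = np.diff(logs[:half], n=2)                # curvature at indices 1..half-2
    if d2.size == 0:
        return 1
    return int(np.argmax(d2) + 1)


def svd_filter(seq: CeusSequence, cutoff: int | str = "adaptive",
               cutoff_high: int | None = None,
               decomposition: CasoratiDecomposition | None = None
               ) -> tuple[CeusSequence, CasoratiDecomposition]:
    """Remove low-order (tissue) components and rebuild the MB signal.

    Parameters
    ----------
    cutoff
        Index of the first retained component ("fixed" policy), or
        ``"adaptive"`` to place it at the largest-curvature turning point of
        the log singular-value curve.
    cutoff_high
        Last retained component (None keeps all high-order components).

    Returns the filtered sequence (negative ripple clipped at zero) and the
    decomposition with the chosen cutoffs recorded.
    """
    dec = decomposition if decomposition is not None else casorati_svd(seq)
    if cutoff == "adaptive":
        low = adaptive_cutoff(dec.singular_values)
    else:
        low = int(cutoff)
    if low >= dec.n_components:
        raise ValueError(f"cutoff_low {low} >= number of components "
                         f"{dec.n_components}")
    high = dec.n_components - 1 if cutoff_high is None else int(cutoff_high)
    dec.cutoff_low, dec.cutoff_high = low, high
    frames = dec.reconstruct(low, high)
    np.clip(frames, 0.0, None, out=frames)
    return seq.copy_with(frames.astype(np.float32)), dec


# --------------------------------------------------------------------------
# motion screening
# --------------------------------------------------------------------------

@dataclass
class MotionReport:
    """Adjacent-frame correlations, excluded frames and retained segments."""

    frame_correlations: np.ndarray     # (nt - 1,)
    excluded_frames: list = field(default_factory=list)
    segments: list = field(default_factory=list)   # (start, end) half-open

    def to_json(self) -> str:
        return json.dumps({
            "frame_correlations": np.asarray(self.frame_correlations).tolist(),
            "excluded_frames": [int(i) for i in self.excluded_frames],
            "segments": [[int(a), int(b)] for a, b in self.segments],
        })

    @classmethod
    def from_json(cls, text: str) -> "MotionReport":
        d = json.loads(text)
        return cls(np.asarray(d["frame_correlations"]),
                   list(d["excluded_frames"]),
                   [tuple(s) for s in d["segments"]])


def screen_motion(bmode: CeusSequence, threshold: float = 0.8,
                  min_segment_len: int = 50) -> MotionReport:
    """Flag motion-corrupted frames by adjacent-frame Pearson correlation.

    Both frames of any pair whose correlation falls below ``threshold`` are
    excluded.  Retained frames are partitioned into contiguous segments;
    runs shorter than ``min_segment_len`` are excluded as well (too short
    for stable velocimetry).  Zero-variance (constant) frames correlate
    perfectly by convention.
    """
    frames = bmode.frames.reshape(bmode.n_frames, -1).astype(np.float64)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    centered = frames - frames.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    corr = np.empty(frames.shape[0] - 1)
    for i in range(len(corr)):
        if norms[i] == 0 or norms[i + 1] == 0:
            corr[i] = 1.0
        else:
            corr[i] = float(centered[i] @ centered[i + 1]
                            / (norms[i] * norms[i + 1]))

    excluded = np.zeros(frames.shape[0], dtype=bool)
    bad = np.nonzero(corr < threshold)[0]
    excluded[bad] = True
    excluded[bad + 1] = True

    segments = []
    start = None
    for i in range(frames.shape[0] + 1):
        inside = i < frames.shape[0] and not excluded[i]
        if inside and start is None:
            start = i
        elif not inside and start is not None:
            if i - start >= min_segment_len:
                segments.append((start, i))
            else:
                excluded[start:i] = True
            start = None

    return MotionReport(frame_correlations=corr,
                        excluded_frames=np.nonzero(excluded)[0].tolist(),
                        segments=segments)
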