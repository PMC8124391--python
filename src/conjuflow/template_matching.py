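"""Step-2 fine motion correction by vessel template matching.

Residual drift after coarse registration (respiration, fixational tremor) is
removed by tracking one conspicuous vessel across frames.  The template
vessel is chosen by a weighted score of min-max normalized segment length
and diameter,

    N(L, D) = w1 * L_hat + w2 * D_hat,        w1 + w2 = 1,

its minimum bounding box (plus a small margin) is cropped from the template
frame, and each frame is searched with the normalized correlation
coefficient

    R(x, y) = sum(T * I_win) / sqrt(sum(T^2) * sum(I_win^2))

at every placement.  The offset of the best match from the template's
reference position is the frame's residual displacement, which is then
subtracted.  Frames whose peak correlation falls below ``min_corr`` are
flagged and excluded from downstream velocimetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import locate_template
from .io import FrameSequence
from .morphology import VesselGraph
from .registration import shift_frame

__all__ = [
    "select_template_vessel",
    "match_template",
    "correct_sequence",
    "TemplateSelection",
    "FineCorrection",
]


@dataclass
class TemplateSelection:
    """The chosen template vessel and its cropped image."""

    scores: dict[int, float]
    chosen_segment_id: int
    template_image: np.ndarray
    box: tuple[int, int, int, int]  # (row, col, h, w) in the template frame


@dataclass
class FineCorrection:
    """Per-frame fine displacements and the corrected sequence."""

    displacements: np.ndarray       # (T, 2) integer (dx, dy)
    corrected: FrameSequence
    peak_correlation: np.ndarray    # (T,)
    flagged: list[int] = field(default_factory=list)  # positions with low peak R

    def usable(self) -> FrameSequence:
        """Corrected sequence with low-correlation frames dropped."""
        keep = [i for i in range(len(self.corrected)) if i not in set(self.flagged)]
        return self.corrected.subset(keep)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def select_template_vessel(
    graph: VesselGraph,
    template_frame: np.ndarray,
    w1: float = 0.5,
    w2: float = 0.5,
    margin: int = 5,
) -> TemplateSelection:
    """Pick the vessel segment maximizing ``w1*L_hat + w2*D_hat`` and crop it.

    Length and diameter are min-max normalized across segments so the two
    scales are comparable.  Ties resolve to the lower segment id.  The crop
    covers the segment's bounding box widened by half its diameter plus
    ``margin`` pixels, clipped to the frame.
    """
    if len(graph.segments) == 0:
        raise ValueError("empty vessel graph")
    if any(s.diameter_px is None for s in graph.segments):
        raise ValueError("segment diameters not set; run segment_diameter first")
    L = np.array([s.length_px for s in graph.segments], dtype=float)
    D = np.array([s.diameter_px for s in graph.segments], dtype=float)
    score = w1 * _minmax(L) + w2 * _minmax(D)
    ids = [s.id for s in graph.segments]
    best = int(np.argmax(score))  # first maximum -> lowest id on ties
    seg = graph.segments[best]
    pad = int(np.ceil(seg.diameter_px / 2)) + margin
    h, w = template_frame.shape
    r0 = max(0, seg.pixels[:, 0].min() - pad)
    r1 = min(h, seg.pixels[:, 0].max() + pad + 1)
    c0 = max(0, seg.pixels[:, 1].min() - pad)
    c1 = min(w, seg.pixels[:, 1].max() + pad + 1)
    return TemplateSelection(
        scores=dict(zip(ids, map(float, score))),
        chosen_segment_id=ids[best],
        template_image=template_frame[r0:r1, c0:c1].copy(),
        box=(int(r0), int(c0), int(r1 - r0), int(c1 - c0)),
    )


def match_template(
    frame: np.ndarray,
    template: np.ndarray,
    ref_pos: tuple[int, int] = (0, 0),
    zero_mean: bool = False,
    subpixel: bool = False,
) -> tuple[int, int, float]:
    """Locate ``template`` in ``frame``; return ``(dx, dy, peak_R)``.

    The displacement is measured from the template's reference top-left
    position ``ref_pos`` (row, col).  ``zero_mean=True`` switches to the
    illumination-robust zero-normalized variant; ``subpixel=True`` refines
    the peak by parabolic interpolation and returns float displacements.
    """
    if template.shape[0] >= frame.shape[0] or template.shape[1] >= frame.shape[1]:
        raise ValueError("template must be strictly smaller than the frame")
    return locate_template(frame, template, ref_pos, zero_mean=zero_mean,
                           subpixel=subpixel)


def correct_sequence(
    seq: FrameSequence,
    selection: TemplateSelection,
    min_corr: float = 0.5,
    zero_mean: bool = False,
) -> FineCorrection:
    """Remove per-frame residual displacement by template matching.

    Each frame is shifted by minus its matched displacement.  Frames whose
    peak correlation is below ``min_corr`` keep their (unreliable) shift but
    are flagged for exclusion from spatial-temporal analysis.
    """
    ref = (selection.box[0], selection.box[1])
    n = len(seq)
    displacements = np.zeros((n, 2), dtype=int)
    peaks = np.zeros(n)
    out = np.empty_like(seq.frames)
    flagged = []
    for i in range(n):
        dx, dy, r = match_template(
            seq.frames[i], selection.template_image, ref, zero_mean=zero_mean
        )
        displacements[i] = (dx, dy)
        peaks[i] = r
        if r < min_corr:
            flagged.append(i)
        out[i] = shift_frame(seq.frames[i], -dx, -dy) if (dx or dy) else seq.frames[i]
    corrected = FrameSequence(
        out,
        fps=seq.fps,
        microns_per_pixel=seq.microns_per_pixel,
        frame_indices=seq.frame_indices.copy(),
    )
    return FineCorrection(
        displacements=displacements,
        corrected=corrected,
        peak_correlation=peaks,
        flagged=flagged,
    )
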