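"""Pixel-vote consensus maps across annotators and overlay rendering.

A vote map counts, for every pixel of a scan, how many annotators'
region annotations cover it — the panel's pixel-level consensus on where
a structure lies.  Overlays render the counts with a perceptually
uniform sequential colour ramp (zero votes transparent over a dark
background) and can superimpose the AI annotator's mask as a
semi-transparent white fill, for visual comparison of the AI prediction
against the spread of expert opinion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image

from . import metrics
from .model import Annotation, GeometryKind, Status, StudyManifest


class UnsupportedGeometryError(ValueError):
    """Vote maps are area-based; line-kind groups are not supported."""


@dataclass
class VoteMap:
    counts: np.ndarray  # int, shape (height, width)
    n_annotators: int
    scan_id: str
    group_id: str

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_annotators:
            raise ValueError("vote counts must lie in [0, n_annotators]")


def vote_map(annotations: list[Annotation], manifest: StudyManifest,
             scan_id: str, group_id: str) -> VoteMap:
    """Count per-pixel annotator votes for one scan and region-kind group.

    Only human annotations with status present/absent participate; an
    absent annotation votes for no pixel.
    """
    if manifest.group_kind(group_id) is not GeometryKind.REGION:
        raise UnsupportedGeometryError(
            f"group {group_id!r} is line-kind; vote maps are area-based"
        )
    scan = manifest.scan(scan_id)
    humans = set(manifest.humans)
    counts = np.zeros((scan.image_height, scan.image_width), dtype=int)
    n = 0
    for ann in annotations:
        if ann.scan_id != scan_id or ann.structure_id != group_id:
            continue
        if ann.annotator_id not in humans:
            continue
        if ann.status is Status.PRESENT:
            counts += metrics.rasterize(
                ann.components, scan.image_width, scan.image_height
            ).grid.astype(int)
            n += 1
        elif ann.status is Status.ABSENT:
            n += 1  # votes nowhere but is part of the panel
    return VoteMap(counts, n_annotators=max(n, int(counts.max(initial=0))), scan_id=scan_id, group_id=group_id)


def render_overlay(vote: VoteMap, ai_mask: metrics.RasterMask | None = None,
                   path: str | Path | None = None, *, cmap: str = "viridis") -> np.ndarray:
    """Render a vote map (optionally with the AI mask) to an RGBA image.

    Zero-vote pixels show the dark background; the AI mask, when given,
    is blended on top as semi-transparent white.  Output is deterministic
    for identical inputs.  Returns the RGBA array and, when ``path`` is
    given, also writes it as PNG.
    """
    counts = vote.counts
    if ai_mask is not None and ai_mask.grid.shape != counts.shape:
        raise ValueError("AI mask dimensions differ from the vote map")
    ramp = colormaps[cmap]
    denom = max(vote.n_annotators, 1)
    rgba = ramp(counts.astype(float) / denom)  # (h, w, 4) floats
    rgba[counts == 0] = (0.08, 0.08, 0.08, 1.0)  # uniform dark background
    if ai_mask is not None:
        alpha = 0.5
        sel = ai_mask.grid
        rgba[sel, :3] = (1 - alpha) * rgba[sel, :3] + alpha * 1.0
    out = (np.clip(rgba, 0, 1) * 255).round().astype(np.uint8)
    if path is not None:
        try:
            Image.fromarray(out, mode="RGBA").save(Path(path), format="PNG")
        except OSError as exc:
            raise OSError(f"could not write overlay to {path}: {exc}") from exc
    return out
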