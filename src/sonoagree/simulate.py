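"""Synthetic multi-annotator studies with controllable error processes.

Because no raw expert annotation data are distributed, the whole
pipeline is exercised on simulated studies that reproduce the study
design: 19 human experts plus one AI annotator outline 20 structures
(18 grouped analysis units) over 6 block regions x 5 scans.

Each scan gets a *ground-truth scene*: one parametric shape per
structure — an ellipse with low-order harmonic boundary perturbation for
arteries, muscles and nerves, a smooth open curve for fascial/serosal
planes.  Each annotator then re-draws every ground-truth shape through a
noise model:

* translation jitter of the whole outline (Gaussian, per axis);
* log-normal area-scale jitter about the centroid;
* smooth correlated boundary noise (a low-order Fourier series along
  the outline parameter, so the perturbation has a period of at least
  four vertices and does not self-intersect at default amplitudes);
* with some probability, the structure is omitted ("not visible"),
  drawn with the wrong geometry kind (flagged invalid), or the whole
  scan is skipped.

Per-class difficulty multipliers scale every annotator's noise and
omission rate, so the familiar agreement ordering — arteries easiest,
then muscles, nerves hardest — emerges from the noise model rather than
being hard-coded.  All randomness derives from a single master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import integrate

from .model import (
    Annotation,
    GeometryKind,
    Region,
    Status,
    StructureClass,
    StudyManifest,
    ValidationError,
    default_manifest,
)

__all__ = [
    "AnnotatorProfile",
    "StudyConfig",
    "generate_scene",
    "simulate_annotator",
    "simulate_study",
    "replica_study_annotations",
    "analytic_dice_disks",
    "expected_dice_under_jitter",
    "disk_polygon",
]


class GenerationError(RuntimeError):
    """A structure cannot be placed inside the image bounds."""


@dataclass(frozen=True)
class AnnotatorProfile:
    """Noise and error parameters of one synthetic annotator.

    Sigmas are in pixels except ``scale_sigma`` (dimensionless sd of the
    log area-scale factor).  Probabilities apply per structure, except
    ``p_skip_image`` which applies once per scan.
    """

    annotator_id: str
    role: str = "human"
    translation_sigma: float = 2.0
    boundary_noise_sigma: float = 1.5
    scale_sigma: float = 0.05
    p_omit: float = 0.03
    p_wrong_kind: float = 26 / 1900
    p_skip_image: float = 2 / 570

    def __post_init__(self):
        for name in ("translation_sigma", "boundary_noise_sigma", "scale_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("p_omit", "p_wrong_kind", "p_skip_image"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


#: per-class difficulty multipliers on annotator noise and omission;
#: the ordering artery < muscle < nerve mirrors how hard the classes are
#: to delineate on B-mode ultrasound
DEFAULT_CLASS_DIFFICULTY = {
    StructureClass.ARTERY: 0.7,
    StructureClass.MUSCLE: 1.0,
    StructureClass.FASCIA_SEROSA: 1.2,
    StructureClass.NERVE: 2.5,
}

#: anchor positions (fractions of width/height) used to lay structures
#: out within a scene without systematic overlap
_ANCHORS = [(0.30, 0.35), (0.62, 0.38), (0.45, 0.68), (0.72, 0.65),
            (0.25, 0.70), (0.75, 0.30), (0.50, 0.20)]

#: per-class half-axis ranges as fractions of image height
_CLASS_SIZE = {
    StructureClass.ARTERY: ((0.040, 0.060), (0.036, 0.055)),
    StructureClass.MUSCLE: ((0.150, 0.220), (0.065, 0.100)),
    StructureClass.NERVE: ((0.022, 0.042), (0.018, 0.034)),
}

_N_OUTLINE_VERTICES = 64
_N_LINE_VERTICES = 48
_NOISE_ORDERS = 6  # Fourier orders of boundary noise; 64/6 > 4 vertices per period

#: structure radius (px) at which profile sigmas apply verbatim; noise on
#: region outlines scales linearly with the structure's rms radius, so a
#: profile describes *relative* sloppiness and the Dice score of a class
#: depends on its difficulty multiplier rather than its size
REFERENCE_RADIUS = 20.0


def _ellipse_blob(rng: np.random.Generator, cx: float, cy: float,
                  a: float, b: float, phi: float, rel_amp: float = 0.05) -> np.ndarray:
    """Closed blob outline: rotated ellipse with harmonic boundary
    perturbation of relative amplitude ``rel_amp``."""
    theta = np.linspace(0.0, 2 * math.pi, _N_OUTLINE_VERTICES, endpoint=False)
    pert = np.zeros_like(theta)
    for k in range(2, 6):
        pert += rng.normal(0, rel_amp / 2) * np.cos(k * theta) + \
                rng.normal(0, rel_amp / 2) * np.sin(k * theta)
    ra = a * (1 + pert)
    rb = b * (1 + pert)
    x = ra * np.cos(theta)
    y = rb * np.sin(theta)
    c, s = math.cos(phi), math.sin(phi)
    return np.column_stack([cx + c * x - s * y, cy + s * x + c * y])


def _smooth_line(rng: np.random.Generator, width: int, y0: float,
                 amplitude: float) -> np.ndarray:
    """Open curve spanning most of the image width at baseline ``y0``."""
    x = np.linspace(0.12 * width, 0.88 * width, _N_LINE_VERTICES)
    t = (x - x[0]) / (x[-1] - x[0])
    y = np.full_like(x, float(y0))
    for k in range(1, 4):
        y += rng.normal(0, amplitude / k) * np.sin(2 * math.pi * k * t + rng.uniform(0, 2 * math.pi))
    return np.column_stack([x, y])


def generate_scene(region: Region, manifest: StudyManifest, width: int, height: int,
                   rng_seed) -> dict[str, tuple[np.ndarray, ...]]:
    """Ground-truth geometry for every structure of a region's protocol.

    Returns a mapping structure_id -> geometry components.  Deterministic
    for a given seed.  Raises :class:`GenerationError` when a structure
    cannot fit inside the image.
    """
    rng = np.random.default_rng(rng_seed)
    structures = manifest.structures_in_region(region, quantitative_only=False)
    margin = 4.0
    out: dict[str, tuple[np.ndarray, ...]] = {}
    n_lines = 0
    for idx, spec in enumerate(structures):
        fx, fy = _ANCHORS[idx % len(_ANCHORS)]
        if spec.geometry_kind is GeometryKind.LINE:
            y0 = (0.30 + 0.18 * n_lines) * height
            n_lines += 1
            if not margin < y0 < height - margin:
                raise GenerationError(f"{spec.structure_id}: line baseline outside image")
            pts = _smooth_line(rng, width, y0, amplitude=0.02 * height)
            if pts[:, 1].min() < margin or pts[:, 1].max() > height - margin:
                pts[:, 1] = np.clip(pts[:, 1], margin, height - margin)
        else:
            (a_lo, a_hi), (b_lo, b_hi) = _CLASS_SIZE[spec.structure_class]
            a = rng.uniform(a_lo, a_hi) * height
            b = rng.uniform(b_lo, b_hi) * height
            if 2 * a >= min(width, height) - 2 * margin:
                raise GenerationError(
                    f"{spec.structure_id}: size {a:.0f} px cannot fit in {width}x{height}"
                )
            cx = fx * width + rng.uniform(-0.03, 0.03) * width
            cy = fy * height + rng.uniform(-0.03, 0.03) * height
            phi = rng.uniform(0, math.pi)
            pts = _ellipse_blob(rng, cx, cy, a, b, phi)
            # keep fully inside the frame: shift, then clip defensively
            pts[:, 0] += np.clip(margin - pts[:, 0].min(), 0, None)
            pts[:, 0] -= np.clip(pts[:, 0].max() - (width - margin), 0, None)
            pts[:, 1] += np.clip(margin - pts[:, 1].min(), 0, None)
            pts[:, 1] -= np.clip(pts[:, 1].max() - (height - margin), 0, None)
            if (pts[:, 0].min() < 0 or pts[:, 1].min() < 0
                    or pts[:, 0].max() > width or pts[:, 1].max() > height):
                raise GenerationError(f"{spec.structure_id}: cannot fit in {width}x{height}")
        out[spec.structure_id] = (pts,)
    return out


def _fourier_noise(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Smooth zero-mean noise of sd ~ sigma along a closed/open parameter
    of length n, built from Fourier orders 1.._NOISE_ORDERS."""
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    coeff_sd = sigma / math.sqrt(_NOISE_ORDERS)
    out = np.zeros(n)
    for k in range(1, _NOISE_ORDERS + 1):
        out += rng.normal(0, coeff_sd) * np.cos(k * t) + rng.normal(0, coeff_sd) * np.sin(k * t)
    return out


def _perturb_region(rng: np.random.Generator, pts: np.ndarray,
                    profile: AnnotatorProfile, mult: float,
                    width: int, height: int) -> np.ndarray:
    centroid = pts.mean(axis=0)
    rel = pts - centroid
    # log-normal area-scale jitter
    scale = math.exp(rng.normal(0, profile.scale_sigma))
    rel = rel * scale
    radii = np.hypot(rel[:, 0], rel[:, 1])
    size_scale = math.sqrt(float(np.mean(radii**2))) / REFERENCE_RADIUS
    # smooth radial boundary noise; clip so the outline cannot fold
    # through its own centroid (self-intersection guard)
    noise = _fourier_noise(rng, len(pts), profile.boundary_noise_sigma * mult * size_scale)
    noise = np.maximum(noise, -0.8 * radii)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(radii[:, None] > 0, rel / radii[:, None], 0.0)
    rel = rel + unit * noise[:, None]
    shift = rng.normal(0, profile.translation_sigma * mult * size_scale, size=2)
    out = centroid + rel + shift
    out[:, 0] = np.clip(out[:, 0], 0, width)
    out[:, 1] = np.clip(out[:, 1], 0, height)
    return out


def _perturb_line(rng: np.random.Generator, pts: np.ndarray,
                  profile: AnnotatorProfile, mult: float,
                  width: int, height: int) -> np.ndarray:
    # local unit normals of the polyline
    d = np.gradient(pts, axis=0)
    norm = np.hypot(d[:, 0], d[:, 1])
    normal = np.column_stack([-d[:, 1], d[:, 0]]) / norm[:, None]
    noise = _fourier_noise(rng, len(pts), profile.boundary_noise_sigma * mult)
    shift = rng.normal(0, profile.translation_sigma * mult, size=2)
    out = pts + normal * noise[:, None] + shift
    out[:, 0] = np.clip(out[:, 0], 0, width)
    out[:, 1] = np.clip(out[:, 1], 0, height)
    return out


def simulate_annotator(scene: dict[str, tuple[np.ndarray, ...]],
                       profile: AnnotatorProfile, manifest: StudyManifest,
                       scan_id: str, rng_seed,
                       class_difficulty: dict[StructureClass, float] | None = None,
                       ) -> list[Annotation]:
    """One annotator's (noisy) annotation set for one scan.

    Error processes are drawn in a fixed order so the output is
    deterministic for a given seed: first the whole-scan skip, then per
    structure omission, wrong-geometry-kind, and geometric perturbation.
    """
    rng = np.random.default_rng(rng_seed)
    difficulty = class_difficulty or DEFAULT_CLASS_DIFFICULTY
    scan = manifest.scan(scan_id)
    out: list[Annotation] = []
    skip_scan = rng.random() < profile.p_skip_image
    for structure_id, components in scene.items():
        spec = manifest.structure(structure_id)
        mult = difficulty[spec.structure_class]
        if skip_scan:
            out.append(Annotation(profile.annotator_id, scan_id, structure_id, (), Status.IMAGE_SKIPPED))
            continue
        if rng.random() < min(profile.p_omit * mult, 1.0):
            out.append(Annotation(profile.annotator_id, scan_id, structure_id, (), Status.ABSENT))
            continue
        if rng.random() < profile.p_wrong_kind:
            out.append(Annotation(profile.annotator_id, scan_id, structure_id, (), Status.INVALID_GEOMETRY))
            continue
        perturbed = []
        for comp in components:
            if spec.geometry_kind is GeometryKind.REGION:
                perturbed.append(_perturb_region(rng, comp, profile, mult,
                                                 scan.image_width, scan.image_height))
            else:
                perturbed.append(_perturb_line(rng, comp, profile, mult,
                                               scan.image_width, scan.image_height))
        out.append(Annotation(profile.annotator_id, scan_id, structure_id,
                              tuple(perturbed), Status.PRESENT))
    return out


@dataclass(frozen=True)
class StudyConfig:
    """Study-level simulation settings.

    The defaults reproduce the study design: a 19-expert human panel
    plus one AI annotator, 6 regions x 5 scans of 512x384 px, and error
    rates matching the observed frequencies of whole-image skips and
    wrong-geometry-kind annotations.
    """

    n_humans: int = 19
    scans_per_region: int = 5
    regions: tuple[Region, ...] = tuple(Region)
    width: int = 512
    height: int = 384
    human_profile: AnnotatorProfile = AnnotatorProfile("template")
    ai_profile: AnnotatorProfile = AnnotatorProfile(
        "AI", role="ai", translation_sigma=3.0, boundary_noise_sigma=0.8,
        scale_sigma=0.04, p_omit=0.0, p_wrong_kind=0.0, p_skip_image=0.0,
    )
    class_difficulty: dict[StructureClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_DIFFICULTY)
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_humans < 2:
            raise ValidationError("need at least 2 human annotators")
        if self.scans_per_region < 1 or self.width <= 0 or self.height <= 0:
            raise ValidationError("scans_per_region and image dimensions must be positive")
        missing = set(StructureClass) - set(self.class_difficulty)
        if missing:
            raise ValidationError(f"class_difficulty missing {sorted(c.value for c in missing)}")


def _build_manifest(config: StudyConfig) -> StudyManifest:
    base = default_manifest()
    from .model import AnnotatorRecord, Role, ScanRecord  # local to avoid clutter

    annotators = [AnnotatorRecord(f"E{i:02d}", Role.HUMAN) for i in range(1, config.n_humans + 1)]
    annotators.append(AnnotatorRecord(config.ai_profile.annotator_id, Role.AI))
    scans = [
        ScanRecord(f"{region.value.lower()}_{i:02d}", region, config.width, config.height)
        for region in config.regions
        for i in range(1, config.scans_per_region + 1)
    ]
    structures = [s for s in base.structures if s.region in config.regions]
    return StudyManifest(annotators=annotators, scans=scans, structures=structures)


def simulate_study(config: StudyConfig = StudyConfig()) -> tuple[StudyManifest, list[Annotation]]:
    """Generate a complete loadable study: manifest plus every
    annotator's annotations for every scan.

    Reproducible from the master seed: scene seeds and per-annotator
    per-scan seeds are spawned deterministically from it.
    """
    manifest = _build_manifest(config)
    master = np.random.SeedSequence(config.seed)
    scan_seeds = master.spawn(len(manifest.scans))
    annotations: list[Annotation] = []
    profiles = [
        replace(config.human_profile, annotator_id=f"E{i:02d}")
        for i in range(1, config.n_humans + 1)
    ] + [config.ai_profile]
    for scan, scan_seed in zip(manifest.scans, scan_seeds):
        children = scan_seed.spawn(1 + len(profiles))
        scene = generate_scene(scan.region, manifest, scan.image_width,
                               scan.image_height, children[0])
        for profile, child in zip(profiles, children[1:]):
            annotations.extend(
                simulate_annotator(scene, profile, manifest, scan.scan_id,
                                   child, config.class_difficulty)
            )
    return manifest, annotations


def replica_study_annotations(seed: int = 0) -> tuple[StudyManifest, list[Annotation]]:
    """A deterministic status-level replica of the study's annotation
    accounting: every entry present except one annotator's skips of one
    ISB and one ESPB scan, and 26 wrong-geometry-kind annotations spread
    over distinct (annotator, scan, group) triples.

    Geometry is a placeholder triangle/segment per structure (the audit
    counts depend only on statuses).  The seed moves the placement of the
    wrong-kind events, which the audit totals are invariant to.
    """
    manifest = default_manifest()
    rng = np.random.default_rng(seed)
    tri = ((10.0, 10.0), (40.0, 10.0), (25.0, 35.0))
    seg = ((10.0, 50.0), (100.0, 55.0))

    skipper = "E07"
    skipped_scans = {"isb_01", "espb_01"}

    # choose 26 grouped targets away from the skipped annotator-scans
    candidates = [
        (a, s.scan_id, g)
        for a in manifest.humans
        for s in manifest.scans
        for g in manifest.groups_in_region(s.region)
        if not (a == skipper and s.scan_id in skipped_scans)
    ]
    idx = rng.choice(len(candidates), size=26, replace=False)
    wrong_kind = {candidates[i] for i in idx}

    annotations: list[Annotation] = []
    for rec in manifest.annotators:
        for scan in manifest.scans:
            for spec in manifest.structures_in_region(scan.region):
                key = (rec.annotator_id, scan.scan_id, spec.group_id)
                if rec.annotator_id == skipper and scan.scan_id in skipped_scans:
                    status, comps = Status.IMAGE_SKIPPED, ()
                elif key in wrong_kind:
                    status, comps = Status.INVALID_GEOMETRY, ()
                else:
                    status = Status.PRESENT
                    comps = (tri,) if spec.geometry_kind is GeometryKind.REGION else (seg,)
                annotations.append(
                    Annotation(rec.annotator_id, scan.scan_id, spec.structure_id, comps, status)
                )
    return manifest, annotations


# ---------------------------------------------------------------------------
# Analytic oracles
# ---------------------------------------------------------------------------


def analytic_dice_disks(r_a: float, r_b: float, d: float) -> float:
    """Closed-form Dice of two disks with radii ``r_a``, ``r_b`` at
    centre distance ``d``, via the circular-lens intersection area."""
    if r_a <= 0 or r_b <= 0 or d < 0:
        raise ValueError("radii must be positive and distance non-negative")
    if d >= r_a + r_b:
        return 0.0
    if d <= abs(r_a - r_b):
        lens = math.pi * min(r_a, r_b) ** 2
    else:
        alpha = math.acos((d * d + r_a * r_a - r_b * r_b) / (2 * d * r_a))
        beta = math.acos((d * d + r_b * r_b - r_a * r_a) / (2 * d * r_b))
        lens = (r_a * r_a * (alpha - math.sin(2 * alpha) / 2)
                + r_b * r_b * (beta - math.sin(2 * beta) / 2))
    return 2.0 * lens / (math.pi * (r_a * r_a + r_b * r_b))


def expected_dice_under_jitter(radius: float, sigma: float) -> float:
    """Semi-analytic expectation of the Dice score between a disk and a
    translated copy whose offset is isotropic Gaussian with per-axis sd
    ``sigma``: the centre distance is then Rayleigh(sigma), and the
    expectation is the closed-form lens Dice integrated over it."""
    if sigma == 0:
        return 1.0

    def integrand(d: float) -> float:
        pdf = (d / (sigma * sigma)) * math.exp(-d * d / (2 * sigma * sigma))
        return analytic_dice_disks(radius, radius, d) * pdf

    value, _ = integrate.quad(integrand, 0.0, 2 * radius, limit=200)
    return value


def disk_polygon(cx: float, cy: float, radius: float, n_vertices: int = 256) -> np.ndarray:
    """Regular polygon approximation of a disk (for oracle experiments)."""
    theta = np.linspace(0.0, 2 * math.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(theta), cy + radius * np.sin(theta)])
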