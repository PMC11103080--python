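"""Study data model: manifest, structures, scans, annotations, and their
on-disk exchange formats.

A *study* is a panel of annotators (human experts plus one AI system) who
each outline a fixed list of anatomical structures on a fixed set of
ultrasound scans.  Arteries, muscles and nerves are drawn as closed
polygons ("region" geometry); fascial/serosal planes are drawn as open
polylines ("line" geometry).  Some structures are analysed jointly
(e.g. the C5 and C6 nerve roots; the anterior and posterior layers of the
rectus sheath) and share a ``group_id``.

Coordinates are continuous pixel coordinates with the origin at the
top-left corner of the image, x rightward and y downward.  Polygons are
implicitly closed (last vertex connects back to the first).  Coordinates
are stored to a precision of 0.01 px, which keeps serialisation
round-trips exact without float-noise churn.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

COORD_DECIMALS = 2  # coordinates stored to 0.01 px


class FormatError(ValueError):
    """A file does not follow the expected exchange schema."""


class ValidationError(ValueError):
    """Data violates a model invariant; ``violations`` lists every one."""

    def __init__(self, violations: Sequence[str] | str):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class Region(str, Enum):
    ISB = "ISB"    # interscalene brachial plexus
    AxB = "AxB"    # axillary brachial plexus
    ESPB = "ESPB"  # erector spinae plane
    RSB = "RSB"    # rectus sheath
    ACB = "ACB"    # adductor canal
    SNB = "SNB"    # popliteal sciatic nerve


class StructureClass(str, Enum):
    ARTERY = "artery"
    MUSCLE = "muscle"
    NERVE = "nerve"
    FASCIA_SEROSA = "fascia_serosa"


class GeometryKind(str, Enum):
    REGION = "region"  # closed outline, compared by Dice overlap
    LINE = "line"      # open polyline, compared by Hausdorff distance


class Status(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"                    # deliberately not annotated ("not visible")
    INVALID_GEOMETRY = "invalid_geometry"  # wrong geometry kind / degenerate outline
    IMAGE_SKIPPED = "image_skipped"      # whole scan left unannotated in error


class Role(str, Enum):
    HUMAN = "human"
    AI = "ai"


#: geometry kind implied by each structure class
CLASS_KIND = {
    StructureClass.ARTERY: GeometryKind.REGION,
    StructureClass.MUSCLE: GeometryKind.REGION,
    StructureClass.NERVE: GeometryKind.REGION,
    StructureClass.FASCIA_SEROSA: GeometryKind.LINE,
}


@dataclass(frozen=True)
class StructureSpec:
    """One named anatomical structure of the study protocol.

    ``group_id`` equals ``structure_id`` for structures analysed on their
    own.  ``quantitative`` is False for structures that appear only in the
    qualitative assessment (the pleura) and are excluded from the
    pairwise-agreement analysis.
    """

    structure_id: str
    display_name: str
    region: Region
    structure_class: StructureClass
    geometry_kind: GeometryKind
    group_id: str
    quantitative: bool = True


@dataclass(frozen=True)
class ScanRecord:
    scan_id: str
    region: Region
    image_width: int
    image_height: int


@dataclass(frozen=True)
class AnnotatorRecord:
    annotator_id: str
    role: Role


def _round_components(components: Iterable) -> tuple[np.ndarray, ...]:
    out = []
    for comp in components:
        arr = np.asarray(comp, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValidationError(f"component must be an (n, 2) vertex list, got shape {arr.shape}")
        arr = np.round(arr, COORD_DECIMALS)
        arr.setflags(write=False)
        out.append(arr)
    return tuple(out)


@dataclass
class Annotation:
    """One annotator's geometry for one structure (or structure group) on
    one scan.

    ``structure_id`` names the structure as drawn; after grouping it holds
    the ``group_id`` of the merged unit.  ``components`` is a tuple of
    (n, 2) float arrays — closed polygons for region-kind structures, open
    polylines for line-kind ones.  A non-present status always carries an
    empty geometry: invalid drawings are recorded as a flag only.
    """

    annotator_id: str
    scan_id: str
    structure_id: str
    components: tuple[np.ndarray, ...] = ()
    status: Status = Status.PRESENT

    def __post_init__(self):
        self.status = Status(self.status)
        self.components = _round_components(self.components)
        if self.status is not Status.PRESENT and len(self.components) > 0:
            raise ValidationError(
                f"{self.annotator_id}/{self.scan_id}/{self.structure_id}: "
                f"status {self.status.value} must carry no geometry"
            )

    def __eq__(self, other):
        if not isinstance(other, Annotation):
            return NotImplemented
        return (
            self.annotator_id == other.annotator_id
            and self.scan_id == other.scan_id
            and self.structure_id == other.structure_id
            and self.status == other.status
            and len(self.components) == len(other.components)
            and all(np.array_equal(a, b) for a, b in zip(self.components, other.components))
        )

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.annotator_id, self.scan_id, self.structure_id)

    def validate(self, scan: ScanRecord, kind: GeometryKind) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        errs: list[str] = []
        ident = f"{self.annotator_id}/{self.scan_id}/{self.structure_id}"
        min_vertices = 3 if kind is GeometryKind.REGION else 2
        if self.status is Status.PRESENT:
            if not self.components:
                errs.append(f"{ident}: present annotation has no geometry")
            for comp in self.components:
                if len(comp) < min_vertices:
                    errs.append(
                        f"{ident}: component with {len(comp)} vertices "
                        f"(minimum {min_vertices} for {kind.value} kind)"
                    )
                if comp.size and (
                    comp[:, 0].min() < 0
                    or comp[:, 1].min() < 0
                    or comp[:, 0].max() > scan.image_width
                    or comp[:, 1].max() > scan.image_height
                ):
                    errs.append(
                        f"{ident}: coordinates outside image bounds "
                        f"[0, {scan.image_width}] x [0, {scan.image_height}]"
                    )
        return errs


@dataclass
class StudyManifest:
    """The complete study protocol: who annotated what, where."""

    annotators: list[AnnotatorRecord]
    scans: list[ScanRecord]
    structures: list[StructureSpec]

    def __post_init__(self):
        self.validate()

    # -- lookups -----------------------------------------------------------

    @property
    def humans(self) -> list[str]:
        return [a.annotator_id for a in self.annotators if a.role is Role.HUMAN]

    @property
    def ai_annotator(self) -> str | None:
        ais = [a.annotator_id for a in self.annotators if a.role is Role.AI]
        return ais[0] if ais else None

    @property
    def quantitative_structures(self) -> list[StructureSpec]:
        return [s for s in self.structures if s.quantitative]

    @property
    def group_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.quantitative_structures:
            seen.setdefault(s.group_id, None)
        return list(seen)

    def scan(self, scan_id: str) -> ScanRecord:
        for s in self.scans:
            if s.scan_id == scan_id:
                return s
        raise KeyError(f"unknown scan_id {scan_id!r}")

    def structure(self, structure_id: str) -> StructureSpec:
        for s in self.structures:
            if s.structure_id == structure_id:
                return s
        raise KeyError(f"unknown structure_id {structure_id!r}")

    def group_members(self, group_id: str) -> list[StructureSpec]:
        return [s for s in self.structures if s.group_id == group_id]

    def group_kind(self, key: str) -> GeometryKind:
        """Geometry kind for a structure_id or group_id."""
        members = [s for s in self.structures if key in (s.structure_id, s.group_id)]
        if not members:
            raise KeyError(f"unknown structure or group {key!r}")
        kinds = {s.geometry_kind for s in members}
        if len(kinds) != 1:
            raise ValidationError(f"group {key!r} mixes geometry kinds")
        return kinds.pop()

    def group_class(self, group_id: str) -> StructureClass:
        classes = {s.structure_class for s in self.group_members(group_id)}
        if len(classes) != 1:
            raise ValidationError(f"group {group_id!r} mixes structure classes")
        return classes.pop()

    def structures_in_region(self, region: Region, *, quantitative_only: bool = True) -> list[StructureSpec]:
        pool = self.quantitative_structures if quantitative_only else self.structures
        return [s for s in pool if s.region == region]

    def groups_in_region(self, region: Region) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.structures_in_region(region):
            seen.setdefault(s.group_id, None)
        return list(seen)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        errs: list[str] = []
        ids = [a.annotator_id for a in self.annotators]
        if len(set(ids)) != len(ids):
            errs.append("duplicate annotator_id")
        n_ai = sum(1 for a in self.annotators if a.role is Role.AI)
        if n_ai > 1:
            errs.append(f"{n_ai} AI annotators declared; at most one allowed")
        if len(self.humans) < 2:
            errs.append("fewer than 2 human annotators; human-human comparison impossible")
        sids = [s.structure_id for s in self.structures]
        if len(set(sids)) != len(sids):
            errs.append("duplicate structure_id")
        scids = [s.scan_id for s in self.scans]
        if len(set(scids)) != len(scids):
            errs.append("duplicate scan_id")
        for s in self.structures:
            if CLASS_KIND[s.structure_class] is not s.geometry_kind:
                errs.append(
                    f"structure {s.structure_id}: class {s.structure_class.value} "
                    f"requires geometry_kind {CLASS_KIND[s.structure_class].value}, "
                    f"got {s.geometry_kind.value}"
                )
        for sc in self.scans:
            if sc.image_width <= 0 or sc.image_height <= 0:
                errs.append(f"scan {sc.scan_id}: non-positive image dimensions")
        regions_with_scans = {sc.region for sc in self.scans}
        for s in self.structures:
            if s.region not in regions_with_scans:
                errs.append(f"structure {s.structure_id}: region {s.region.value} has no scans")
        # grouped structures must share region, class and kind
        by_group: dict[str, list[StructureSpec]] = {}
        for s in self.structures:
            by_group.setdefault(s.group_id, []).append(s)
        for gid, members in by_group.items():
            if len({m.geometry_kind for m in members}) > 1:
                errs.append(f"group {gid}: members mix geometry kinds")
            if len({m.region for m in members}) > 1:
                errs.append(f"group {gid}: members span regions")
        if errs:
            raise ValidationError(errs)


# ---------------------------------------------------------------------------
# Manifest I/O (strict YAML/JSON schema)
# ---------------------------------------------------------------------------

_MANIFEST_KEYS = {"annotators", "scans", "structures", "grouping"}
_ANNOTATOR_KEYS = {"id", "role"}
_SCAN_KEYS = {"id", "region", "width", "height"}
_STRUCTURE_KEYS = {"id", "name", "region", "class", "kind", "quantitative"}


def _require_keys(item: dict, allowed: set, required: set, what: str) -> None:
    unknown = set(item) - allowed
    if unknown:
        raise FormatError(f"{what}: unknown key(s) {sorted(unknown)}")
    missing = required - set(item)
    if missing:
        raise FormatError(f"{what}: missing key(s) {sorted(missing)}")


def manifest_from_dict(doc: dict) -> StudyManifest:
    if not isinstance(doc, dict):
        raise FormatError("manifest document must be a mapping")
    _require_keys(doc, _MANIFEST_KEYS, {"annotators", "scans", "structures"}, "manifest")
    grouping: dict[str, str] = doc.get("grouping") or {}
    annotators, scans, structures = [], [], []
    for item in doc["annotators"]:
        _require_keys(item, _ANNOTATOR_KEYS, _ANNOTATOR_KEYS, "annotator entry")
        try:
            role = Role(item["role"])
        except ValueError:
            raise FormatError(f"annotator {item['id']}: unknown role {item['role']!r}") from None
        annotators.append(AnnotatorRecord(str(item["id"]), role))
    for item in doc["scans"]:
        _require_keys(item, _SCAN_KEYS, _SCAN_KEYS, "scan entry")
        try:
            region = Region(item["region"])
        except ValueError:
            raise FormatError(f"scan {item['id']}: unknown region {item['region']!r}") from None
        scans.append(ScanRecord(str(item["id"]), region, int(item["width"]), int(item["height"])))
    for item in doc["structures"]:
        _require_keys(item, _STRUCTURE_KEYS, {"id", "name", "region", "class", "kind"}, "structure entry")
        sid = str(item["id"])
        try:
            region = Region(item["region"])
            cls = StructureClass(item["class"])
            kind = GeometryKind(item["kind"])
        except ValueError as exc:
            raise FormatError(f"structure {sid}: {exc}") from None
        structures.append(
            StructureSpec(
                structure_id=sid,
                display_name=str(item["name"]),
                region=region,
                structure_class=cls,
                geometry_kind=kind,
                group_id=grouping.get(sid, sid),
                quantitative=bool(item.get("quantitative", True)),
            )
        )
    known_sids = {s.structure_id for s in structures}
    for sid in grouping:
        if sid not in known_sids:
            raise FormatError(f"grouping: unknown structure_id {sid!r}")
    return StudyManifest(annotators=annotators, scans=scans, structures=structures)


def manifest_to_dict(manifest: StudyManifest) -> dict:
    grouping = {
        s.structure_id: s.group_id for s in manifest.structures if s.group_id != s.structure_id
    }
    doc = {
        "annotators": [
            {"id": a.annotator_id, "role": a.role.value} for a in manifest.annotators
        ],
        "scans": [
            {"id": s.scan_id, "region": s.region.value, "width": s.image_width, "height": s.image_height}
            for s in manifest.scans
        ],
        "structures": [
            {
                "id": s.structure_id,
                "name": s.display_name,
                "region": s.region.value,
                "class": s.structure_class.value,
                "kind": s.geometry_kind.value,
                **({} if s.quantitative else {"quantitative": False}),
            }
            for s in manifest.structures
        ],
    }
    if grouping:
        doc["grouping"] = grouping
    return doc


def load_manifest(path: str | Path) -> StudyManifest:
    """Load and validate a study manifest from a YAML (or JSON) file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: not valid YAML/JSON: {exc}") from exc
    return manifest_from_dict(doc)


def write_manifest(manifest: StudyManifest, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(manifest_to_dict(manifest), sort_keys=False))


def default_manifest() -> StudyManifest:
    """The bundled default study manifest: 19 human experts + 1 AI,
    6 block regions x 5 scans, 20 quantitative structures in 18 groups
    (plus the pleura, carried for the qualitative assessment only)."""
    with resources.files("sonoagree.data").joinpath("default_manifest.yaml").open() as fh:
        return manifest_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Annotation I/O (GeoJSON FeatureCollection per annotator x scan)
# ---------------------------------------------------------------------------


def _coords_to_geometry(annotation: Annotation, kind: GeometryKind) -> dict | None:
    if annotation.status is not Status.PRESENT:
        return None
    comps = [c.tolist() for c in annotation.components]
    if kind is GeometryKind.REGION:
        if len(comps) == 1:
            return {"type": "Polygon", "coordinates": [comps[0]]}
        return {"type": "MultiPolygon", "coordinates": [[c] for c in comps]}
    if len(comps) == 1:
        return {"type": "LineString", "coordinates": comps[0]}
    return {"type": "MultiLineString", "coordinates": comps}


def _geometry_to_components(geom: dict | None) -> tuple[list, GeometryKind | None]:
    """Return (component vertex lists, geometry kind implied by the feature)."""
    if geom is None:
        return [], None
    gtype = geom.get("type")
    coords = geom.get("coordinates", [])
    if gtype == "Polygon":
        return [list(ring) for ring in coords[:1]], GeometryKind.REGION
    if gtype == "MultiPolygon":
        return [list(poly[0]) for poly in coords if poly], GeometryKind.REGION
    if gtype == "LineString":
        return [list(coords)], GeometryKind.LINE
    if gtype == "MultiLineString":
        return [list(part) for part in coords], GeometryKind.LINE
    raise FormatError(f"unsupported GeoJSON geometry type {gtype!r}")


def annotation_filename(annotator_id: str, scan_id: str) -> str:
    return f"{annotator_id}__{scan_id}.geojson"


def write_annotations(annotations: Iterable[Annotation], directory: str | Path,
                      manifest: StudyManifest) -> None:
    """Write one GeoJSON FeatureCollection per (annotator, scan).

    Coordinates are pixel coordinates (no CRS); each feature carries
    ``annotator_id``, ``scan_id``, ``structure_id`` and ``status``
    properties.  Non-present annotations are written with a null geometry
    so that explicit "not visible" and skip records survive round-trips.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_file: dict[tuple[str, str], list[Annotation]] = {}
    for ann in annotations:
        by_file.setdefault((ann.annotator_id, ann.scan_id), []).append(ann)
    for (annotator_id, scan_id), group in sorted(by_file.items()):
        features = []
        for ann in sorted(group, key=lambda a: a.structure_id):
            kind = manifest.group_kind(ann.structure_id)
            features.append(
                {
                    "type": "Feature",
                    "geometry": _coords_to_geometry(ann, kind),
                    "properties": {
                        "annotator_id": ann.annotator_id,
                        "scan_id": ann.scan_id,
                        "structure_id": ann.structure_id,
                        "status": ann.status.value,
                    },
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        (directory / annotation_filename(annotator_id, scan_id)).write_text(
            json.dumps(doc, separators=(",", ":"))
        )


def load_annotations(path: str | Path, manifest: StudyManifest) -> list[Annotation]:
    """Load annotations from a GeoJSON file or a directory of them.

    A feature whose geometry kind contradicts the manifest (a closed
    enclosure drawn for a line structure or vice versa), or a degenerate
    outline with too few vertices, is loaded with status
    ``invalid_geometry`` and its geometry discarded, with a warning.
    Coordinates outside the scan bounds raise a :class:`ValidationError`
    naming the offending annotation.
    """
    path = Path(path)
    files = sorted(path.glob("*.geojson")) if path.is_dir() else [path]
    out: list[Annotation] = []
    errs: list[str] = []
    for fp in files:
        try:
            doc = json.loads(fp.read_text())
        except json.JSONDecodeError as exc:
            raise FormatError(f"{fp}: not valid GeoJSON: {exc}") from exc
        if doc.get("type") != "FeatureCollection":
            raise FormatError(f"{fp}: expected a FeatureCollection")
        for feat in doc.get("features", []):
            props = feat.get("properties", {})
            try:
                annotator_id = props["annotator_id"]
                scan_id = props["scan_id"]
                structure_id = props["structure_id"]
                status = Status(props.get("status", "present"))
            except (KeyError, ValueError) as exc:
                raise FormatError(f"{fp}: bad feature properties: {exc}") from exc
            ident = f"{annotator_id}/{scan_id}/{structure_id}"
            try:
                scan = manifest.scan(scan_id)
                declared_kind = manifest.group_kind(structure_id)
            except KeyError as exc:
                raise ValidationError(str(exc)) from exc
            components, file_kind = _geometry_to_components(feat.get("geometry"))
            if status is Status.PRESENT:
                if file_kind is not None and file_kind is not declared_kind:
                    logger.warning(
                        "%s: %s geometry for a %s-kind structure; flagged invalid",
                        ident, file_kind.value, declared_kind.value,
                    )
                    out.append(Annotation(annotator_id, scan_id, structure_id, (), Status.INVALID_GEOMETRY))
                    continue
                min_vertices = 3 if declared_kind is GeometryKind.REGION else 2
                if not components or any(len(c) < min_vertices for c in components):
                    logger.warning("%s: degenerate geometry; flagged invalid", ident)
                    out.append(Annotation(annotator_id, scan_id, structure_id, (), Status.INVALID_GEOMETRY))
                    continue
            ann = Annotation(annotator_id, scan_id, structure_id, tuple(components), status)
            errs.extend(ann.validate(scan, declared_kind))
            out.append(ann)
    if errs:
        raise ValidationError(errs)
    return out
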