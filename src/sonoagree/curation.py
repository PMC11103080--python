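"""Inclusion/exclusion rules, structure grouping, and the annotation audit.

The study's curation rules, applied per human annotator and per scan:

* If **no** structure on a scan was annotated by an annotator, the whole
  image is assumed to have been skipped in error and all of that
  annotator's entries for the scan are excluded.
* If a structure was not annotated while at least one other structure on
  the same image was, the structure is assumed to have been judged "not
  visible" and is retained as an explicit empty annotation.
* Annotations drawn with the wrong geometry kind (an enclosure for a
  line structure or vice versa) are excluded individually.
* The AI annotator is exempt: an empty AI output is a genuine
  "not highlighted" prediction and is retained as absent.

Excluded entries are not deleted; their status is rewritten to
``image_skipped`` / left as ``invalid_geometry`` and downstream analysis
ignores every status other than present/absent.  This keeps curation
idempotent and preserves provenance of what was excluded and why.

Grouped structures (C5+C6 nerve roots; anterior+posterior rectus sheath
layers) are merged into single analysis units before the rules apply,
because the exclusion counts of the study are counted on grouped units.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .model import (
    Annotation,
    Status,
    StudyManifest,
    ValidationError,
)

#: statuses that enter the pairwise analysis
ANALYSED_STATUSES = (Status.PRESENT, Status.ABSENT)


@dataclass(frozen=True)
class AuditReport:
    """Accounting of annotations from the raw files to the analysed set.

    ``potential_annotations`` counts human annotators x ungrouped
    structure instances; ``grouped_potential`` the same after grouping;
    ``analysed`` = grouped_potential - total_removed.
    """

    potential_annotations: int
    grouped_potential: int
    discarded_image_skips: int
    discarded_invalid_geometry: int
    total_removed: int
    analysed: int

    def __post_init__(self):
        if self.total_removed != self.discarded_image_skips + self.discarded_invalid_geometry:
            raise ValidationError("audit: total_removed does not equal the sum of its parts")
        if self.analysed != self.grouped_potential - self.total_removed:
            raise ValidationError("audit: analysed does not equal grouped_potential - total_removed")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        return (
            f"Potential annotations (annotators x structures): {self.potential_annotations}\n"
            f"After grouping:                                  {self.grouped_potential}\n"
            f"Removed - whole-image skips:                     {self.discarded_image_skips}\n"
            f"Removed - wrong geometry kind:                   {self.discarded_invalid_geometry}\n"
            f"Total removed:                                   {self.total_removed}\n"
            f"Collected and analysed:                          {self.analysed}\n"
        )


def merge_statuses(statuses: list[Status]) -> Status:
    """Status of a grouped annotation from its members' statuses.

    Present if any member is present; invalid if any member is invalid
    and none present; image_skipped if all members were skipped; absent
    otherwise.
    """
    if not statuses:
        raise ValueError("cannot merge an empty status list")
    if Status.PRESENT in statuses:
        return Status.PRESENT
    if Status.INVALID_GEOMETRY in statuses:
        return Status.INVALID_GEOMETRY
    if all(s is Status.IMAGE_SKIPPED for s in statuses):
        return Status.IMAGE_SKIPPED
    return Status.ABSENT


def apply_grouping(annotations: list[Annotation], manifest: StudyManifest) -> list[Annotation]:
    """Merge member-structure annotations into grouped analysis units.

    For each (annotator, scan, group), components are concatenated and
    the statuses merged by :func:`merge_statuses`.  Annotations of
    ungrouped structures pass through with ``structure_id`` rewritten to
    their (identical) group key.  Group members with mixed geometry kinds
    are rejected at manifest level already.
    """
    merged: dict[tuple[str, str, str], list[Annotation]] = {}
    order: list[tuple[str, str, str]] = []
    for ann in annotations:
        try:
            spec = manifest.structure(ann.structure_id)
            gid = spec.group_id
        except KeyError:
            # already a group key (re-grouping is a no-op merge)
            manifest.group_kind(ann.structure_id)
            gid = ann.structure_id
        key = (ann.annotator_id, ann.scan_id, gid)
        if key not in merged:
            merged[key] = []
            order.append(key)
        merged[key].append(ann)
    out = []
    for key in order:
        annotator_id, scan_id, gid = key
        members = merged[key]
        status = merge_statuses([m.status for m in members])
        components: tuple = ()
        if status is Status.PRESENT:
            components = tuple(c for m in members for c in m.components)
        out.append(Annotation(annotator_id, scan_id, gid, components, status))
    return out


def _materialize(grouped: list[Annotation], manifest: StudyManifest) -> list[Annotation]:
    """Add explicit absent entries for every (annotator, scan, group)
    combination of the manifest that the input does not mention."""
    have = {ann.key for ann in grouped}
    out = list(grouped)
    for rec in manifest.annotators:
        for scan in manifest.scans:
            for gid in manifest.groups_in_region(scan.region):
                key = (rec.annotator_id, scan.scan_id, gid)
                if key not in have:
                    out.append(Annotation(rec.annotator_id, scan.scan_id, gid, (), Status.ABSENT))
    return out


def curate(annotations: list[Annotation], manifest: StudyManifest,
           *, group: bool = True) -> tuple[list[Annotation], AuditReport]:
    """Apply the exclusion rules and produce the audit accounting.

    Returns the complete curated collection (one entry per annotator,
    scan and quantitative group, with final statuses) and the
    :class:`AuditReport`.  Entries with status ``present``/``absent``
    constitute the analysed set; ``image_skipped``/``invalid_geometry``
    entries are the excluded ones the audit counts (humans only — the AI
    is never curated away).
    """
    known = {a.annotator_id for a in manifest.annotators}
    for ann in annotations:
        if ann.annotator_id not in known:
            raise ValidationError(f"annotator {ann.annotator_id!r} not declared in manifest")
    grouped = apply_grouping(annotations, manifest) if group else list(annotations)
    # qualitative-only structures (no quantitative member) never enter the
    # agreement analysis or its accounting
    quant_groups = set(manifest.group_ids)
    grouped = [a for a in grouped if a.structure_id in quant_groups]
    complete = _materialize(grouped, manifest)

    humans = set(manifest.humans)
    by_annotator_scan: dict[tuple[str, str], list[Annotation]] = {}
    for ann in complete:
        by_annotator_scan.setdefault((ann.annotator_id, ann.scan_id), []).append(ann)

    n_skips = 0
    n_invalid = 0
    curated: list[Annotation] = []
    for (annotator_id, scan_id), entries in sorted(by_annotator_scan.items()):
        if annotator_id in humans:
            annotated = any(
                e.status in (Status.PRESENT, Status.INVALID_GEOMETRY) for e in entries
            )
            if not annotated:
                # whole image unannotated -> assumed skipped in error
                n_skips += len(entries)
                curated.extend(
                    Annotation(e.annotator_id, e.scan_id, e.structure_id, (), Status.IMAGE_SKIPPED)
                    for e in entries
                )
                continue
            for e in entries:
                if e.status is Status.INVALID_GEOMETRY:
                    n_invalid += 1
                curated.append(e)
        else:
            # AI entries are retained as-is; a wrong-kind AI output carries
            # no usable geometry and scores as absent
            for e in entries:
                if e.status in ANALYSED_STATUSES:
                    curated.append(e)
                else:
                    curated.append(Annotation(e.annotator_id, e.scan_id, e.structure_id, (), Status.ABSENT))

    n_humans = len(humans)
    per_scan_structures = sum(
        len(manifest.structures_in_region(s.region)) for s in manifest.scans
    )
    per_scan_groups = sum(len(manifest.groups_in_region(s.region)) for s in manifest.scans)
    report = AuditReport(
        potential_annotations=n_humans * per_scan_structures,
        grouped_potential=n_humans * per_scan_groups,
        discarded_image_skips=n_skips,
        discarded_invalid_geometry=n_invalid,
        total_removed=n_skips + n_invalid,
        analysed=n_humans * per_scan_groups - n_skips - n_invalid,
    )
    return curated, report


def analysed_annotations(curated: list[Annotation]) -> list[Annotation]:
    """Entries that enter the pairwise analysis (present or absent)."""
    return [a for a in curated if a.status in ANALYSED_STATUSES]
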