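"""Per-read genomic feature assignment.

Each read receives exactly one label: the feature class it overlaps (ER,
iR, PR, 5UR, 3UR, known_sncRNA, repeat), IR when it overlaps nothing, or MF
("multiple feature") when its blocks touch two or more distinct classes.
Reads touching an already-annotated sncRNA or a repeat are labelled as such
regardless of other overlaps — they are excluded from novelty calling.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io import AlignedRead, FeatureRecord, GenomicInterval, strands_compatible

log = logging.getLogger(__name__)

ASSIGNMENT_LABELS = ("ER", "iR", "PR", "5UR", "3UR", "IR", "known_sncRNA", "repeat", "MF")
EXCLUSION_CLASSES = ("known_sncRNA", "repeat")


@dataclass(frozen=True)
class FeatureAssignment:
    read_id: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in ASSIGNMENT_LABELS:
            raise ValueError(f"unknown label {self.label!r}")


class FeatureIndex:
    """Per-contig interval tree over feature records; strand filtering is
    applied at query time so one index serves both library modes."""

    def __init__(self, features: Sequence[FeatureRecord]):
        self._trees: dict[str, IntervalTree] = {}
        self.features = list(features)
        for feat in self.features:
            iv = feat.interval
            self._trees.setdefault(iv.contig, IntervalTree()).addi(iv.start, iv.end, feat)

    def query(self, interval: GenomicInterval, stranded: bool = False) -> list[FeatureRecord]:
        tree = self._trees.get(interval.contig)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(interval.start, interval.end)]
        if stranded:
            hits = [f for f in hits if strands_compatible(f.interval.strand, interval.strand)]
        return hits

    def has_contig(self, contig: str) -> bool:
        return contig in self._trees


def build_index(features: Sequence[FeatureRecord]) -> FeatureIndex:
    return FeatureIndex(features)


def assign_read(read: AlignedRead, index: FeatureIndex, stranded: bool = False,
                same_class_is_unique: bool = True) -> FeatureAssignment:
    """Label one read from the feature classes overlapped by any of its blocks.

    With ``same_class_is_unique`` (default), two overlapping records of the
    same class (e.g. introns of two genes) still count as one class; MF is
    reserved for reads spanning *different* feature types.
    """
    if not index.has_contig(read.contig):
        log.warning("contig %s absent from the feature index; read %s -> IR",
                    read.contig, read.read_id)
        return FeatureAssignment(read.read_id, "IR")
    classes: set[str] = set()
    n_records = 0
    for block in read.blocks:
        for feat in index.query(block, stranded=stranded):
            classes.add(feat.feature_class)
            n_records += 1
    for excl in EXCLUSION_CLASSES:
        if excl in classes:
            return FeatureAssignment(read.read_id, excl)
    if not classes:
        return FeatureAssignment(read.read_id, "IR")
    if len(classes) == 1 and (same_class_is_unique or n_records == 1):
        return FeatureAssignment(read.read_id, next(iter(classes)))
    if len(classes) == 1:
        return FeatureAssignment(read.read_id, "MF")
    return FeatureAssignment(read.read_id, "MF")


def assign_reads(reads: Iterable[AlignedRead], index: FeatureIndex,
                 stranded: bool = False, same_class_is_unique: bool = True) -> list[FeatureAssignment]:
    return [assign_read(r, index, stranded, same_class_is_unique) for r in reads]


def composition_summary(assignments: Sequence[FeatureAssignment]) -> pd.DataFrame:
    """Read counts and fractions per label; fractions sum to 1, counts to the
    input size."""
    counts = Counter(a.label for a in assignments)
    total = len(assignments)
    rows = [
        {"label": label, "count": counts.get(label, 0),
         "fraction": counts.get(label, 0) / total if total else 0.0}
        for label in ASSIGNMENT_LABELS
    ]
    return pd.DataFrame(rows)
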