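"""Hierarchical class annotation of mapped small-RNA sequences.

Every mapped unique sequence receives exactly one class label by an ordered
cascade with remove-on-first-assignment semantics: classes are tried in a
fixed priority order and a sequence leaves the pool as soon as it matches.
A sequence matches a class when it is an exact sense-strand substring of any
reference sequence of that class (tRNA also matches through its CCA-tailed
form).  After the sequence classes and the tRNA 3' trailer stage, sequences
whose genomic hits overlap a repeat locus become 'genomic repeat'; the rest
are 'unknown'.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import pandas as pd

from .classes import (
    CASCADE_ORDER,
    DISPLAY_NAMES,
    MISC_RNA_CLASSES,
    SEQUENCE_CLASSES,
    ClassLabel,
)
from .mapper import GenomeHit
from .preprocess import UniqueSeqRecord
from .reference import ReferenceBundle, TrailerRegion, build_cca_trnas
from .trailers import match_offset


class _ClassMatcher:
    """Substring search over one class's reference corpus.

    References are concatenated with a separator so the common case (no
    match) is a single C-speed scan; individual references are only walked
    to recover the matched id.
    """

    SEP = "#"

    def __init__(self, refs: Sequence[tuple[str, str]]):
        self.refs = list(refs)
        self._blob = self.SEP + self.SEP.join(seq for _, seq in self.refs) + self.SEP

    def match(self, seq: str) -> str | None:
        if not self.refs or seq not in self._blob:
            return None
        for ref_id, ref_seq in self.refs:
            if seq in ref_seq:
                return ref_id
        return None


@dataclasses.dataclass
class AnnotationResult:
    records: list[UniqueSeqRecord]
    class_counts: dict[str, dict[ClassLabel, int]]  # lib -> label -> raw count
    mapped_totals: dict[str, int]


def _hit_overlaps(hit: GenomeHit, seq_len: int, locus) -> bool:
    hit_end = hit.start + seq_len - 1
    return hit.chrom == locus.chrom and hit.start <= locus.end and hit_end >= locus.start


def annotate_cascade(
    records: Iterable[UniqueSeqRecord],
    bundle: ReferenceBundle,
    trailer_regions: Sequence[TrailerRegion],
    hits: dict[str, list[GenomeHit]] | None = None,
    order: Sequence[ClassLabel] = CASCADE_ORDER,
) -> AnnotationResult:
    """Run the priority cascade over all mapped records.

    ``hits`` (sequence -> genomic hits) is needed for the repeat fallback;
    records rescued off-genome have no hits and can never be repeats.
    Records pre-labelled tRNA by the one-mismatch rescue keep that label.
    Output is independent of input record order.
    """
    records = sorted(
        (r for r in records if r.status == "mapped"), key=lambda r: r.sequence
    )
    hits = hits or {}
    matchers: dict[ClassLabel, _ClassMatcher] = {}
    for label in SEQUENCE_CLASSES:
        refs = [(r.ref_id, r.sequence) for r in bundle.refs_of(label)]
        if label is ClassLabel.TRNA:
            refs = refs + build_cca_trnas(bundle)
        matchers[label] = _ClassMatcher(refs)

    pool = [r for r in records if r.label is None]
    skipped: list[str] = []
    for label in order:
        if label in SEQUENCE_CLASSES:
            matcher = matchers[label]
            if not matcher.refs:
                skipped.append(label.value)
                continue
            remaining = []
            for rec in pool:
                ref_id = matcher.match(rec.effective_seq)
                if ref_id is not None:
                    rec.label, rec.matched_ref = label, ref_id
                else:
                    remaining.append(rec)
            pool = remaining
        elif label is ClassLabel.TRNA_TRAILER:
            remaining = []
            for rec in pool:
                matched = None
                for region in trailer_regions:
                    if region.region_seq and match_offset(rec.effective_seq, region.region_seq) is not None:
                        matched = region.trna_name
                        break
                if matched is not None:
                    rec.label, rec.matched_ref = label, matched
                else:
                    remaining.append(rec)
            pool = remaining
        elif label is ClassLabel.GENOMIC_REPEAT:
            remaining = []
            for rec in pool:
                seq_hits = hits.get(rec.sequence, [])
                seq_len = len(rec.effective_seq)
                if any(
                    _hit_overlaps(h, seq_len, locus)
                    for h in seq_hits
                    for locus in bundle.repeat_loci
                ):
                    rec.label = label
                else:
                    remaining.append(rec)
            pool = remaining
        elif label is ClassLabel.UNKNOWN:
            for rec in pool:
                rec.label = label
            pool = []
    if skipped:
        warnings.warn(
            "no reference sequences for classes: "
            + ", ".join(skipped)
            + "; those stages were skipped",
            stacklevel=2,
        )

    class_counts: dict[str, dict[ClassLabel, int]] = {}
    mapped_totals: dict[str, int] = {}
    for rec in records:
        for lib, count in rec.counts.items():
            class_counts.setdefault(lib, {}).setdefault(rec.label, 0)
            class_counts[lib][rec.label] += count
            mapped_totals[lib] = mapped_totals.get(lib, 0) + count
    return AnnotationResult(records, class_counts, mapped_totals)


def format_percent(value: float) -> str:
    """One decimal place, two below 1 (report-table convention: 79.1 but
    0.63 and 0.08)."""
    return f"{value:.2f}" if value < 1.0 else f"{value:.1f}"


def composition_table(
    class_counts: dict[str, dict[ClassLabel, int]],
    totals: dict[str, int] | None = None,
    collapse_misc: bool = True,
) -> pd.DataFrame:
    """Per-class raw counts and percentage of library total, per library.

    ``totals`` defaults to the per-library sums of ``class_counts``; passing
    explicit totals allows recomputation from published count tables.  The
    low-abundance housekeeping classes are rolled up into a 'miscRNA' row
    for presentation (the cascade itself never uses the roll-up).
    """
    libs = sorted(class_counts)
    if totals is None:
        totals = {lib: sum(class_counts[lib].values()) for lib in libs}
    for lib in libs:
        if totals[lib] == 0:
            raise ValueError(f"library {lib!r} has zero total count")
    rows = []
    misc = {lib: 0 for lib in libs}
    for label in CASCADE_ORDER:
        counts = {lib: class_counts[lib].get(label, 0) for lib in libs}
        if collapse_misc and label in MISC_RNA_CLASSES:
            for lib in libs:
                misc[lib] += counts[lib]
            continue
        row: dict[str, object] = {"class": DISPLAY_NAMES[label]}
        for lib in libs:
            row[f"{lib}_count"] = counts[lib]
            row[f"{lib}_percent"] = counts[lib] / totals[lib] * 100.0
        rows.append(row)
    if collapse_misc:
        row = {"class": "miscRNA"}
        for lib in libs:
            row[f"{lib}_count"] = misc[lib]
            row[f"{lib}_percent"] = misc[lib] / totals[lib] * 100.0
        rows.append(row)
    return pd.DataFrame(rows)
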