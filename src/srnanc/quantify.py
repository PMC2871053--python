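"""Normalization, N/C enrichment statistics and miRNA-level analyses.

Abundances are normalized to reads per million (RPM) against the mapped
total of each library.  A sequence's subcellular distribution is summarized
by N/C, the ratio of nuclear to cytoplasmic RPM; sequences observed in only
one compartment carry an exclusivity flag instead of a number.  Only
sequences with raw count greater than 10 in at least one library are
eligible for N/C analyses — eligibility always uses raw counts, never RPM,
because the threshold models sampling noise.

miRNA analyses group sequences into isomiR families per mature miRNA, take
the most abundant isomiR as each library's representative, drop miRNAs whose
representatives disagree between libraries, and correlate representative
abundances across compartments.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .preprocess import UniqueSeqRecord

#: raw-count eligibility threshold ("greater than 10", strict)
ELIGIBILITY_MIN_COUNT = 10
NUCLEAR_ONLY = "nuclear-only"
CYTOPLASMIC_ONLY = "cytoplasmic-only"


def rpm_normalize(raw: int | float, library_mapped_total: int) -> float:
    """Reads-per-million: raw / mapped-total x 10^6."""
    if library_mapped_total <= 0:
        raise ValueError("library mapped total must be positive")
    return raw / library_mapped_total * 1e6


def assign_rpm(
    records: Iterable[UniqueSeqRecord], mapped_totals: dict[str, int]
) -> None:
    """Fill each mapped record's ``rpm`` map from its raw counts."""
    for rec in records:
        if rec.status != "mapped":
            continue
        rec.rpm = {
            lib: rpm_normalize(count, mapped_totals[lib])
            for lib, count in rec.counts.items()
        }


@dataclasses.dataclass
class NCRecord:
    sequence: str
    nuclear_rpm: float
    cytoplasmic_rpm: float
    nc: float | None
    flag: str | None  # NUCLEAR_ONLY | CYTOPLASMIC_ONLY | None
    eligible: bool
    label: object = None


def nc_ratio(nuclear_rpm: float, cytoplasmic_rpm: float) -> tuple[float | None, str | None]:
    """N/C ratio, or an exclusivity flag when one compartment is empty.

    Exclusive sequences are reported as categories, never as 0 or infinity.
    """
    if nuclear_rpm < 0 or cytoplasmic_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    if nuclear_rpm == 0 and cytoplasmic_rpm == 0:
        raise ValueError("N/C undefined when both compartments are zero")
    if cytoplasmic_rpm == 0:
        return None, NUCLEAR_ONLY
    if nuclear_rpm == 0:
        return None, CYTOPLASMIC_ONLY
    return nuclear_rpm / cytoplasmic_rpm, None


def nc_records(
    records: Iterable[UniqueSeqRecord],
    nuclear_lib: str = "nuclear",
    cytoplasmic_lib: str = "cytoplasmic",
    min_count: int = ELIGIBILITY_MIN_COUNT,
) -> list[NCRecord]:
    """Build N/C records for all mapped sequences with any signal."""
    out = []
    for rec in records:
        if rec.status != "mapped":
            continue
        n_raw = rec.counts.get(nuclear_lib, 0)
        c_raw = rec.counts.get(cytoplasmic_lib, 0)
        if n_raw == 0 and c_raw == 0:
            continue
        nuc = rec.rpm.get(nuclear_lib, 0.0)
        cyt = rec.rpm.get(cytoplasmic_lib, 0.0)
        nc, flag = nc_ratio(nuc, cyt)
        out.append(
            NCRecord(
                rec.sequence,
                nuc,
                cyt,
                nc,
                flag,
                eligible=max(n_raw, c_raw) > min_count,
                label=rec.label,
            )
        )
    return out


@dataclasses.dataclass
class NCSummary:
    n_eligible: int
    fraction_in_range: float
    fraction_nuclear_only: float
    fraction_cytoplasmic_only: float
    histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges) over log10(nc)


def nc_summary(
    records: Sequence[NCRecord],
    nc_range: tuple[float, float] = (0.02, 5.0),
    n_bins: int = 40,
    log_limits: tuple[float, float] = (-4.0, 4.0),
) -> NCSummary:
    """Distribution summary of N/C over eligible records.

    Reports the fraction with N/C inside ``nc_range`` (inclusive), the
    fractions exclusive to either compartment, and a histogram of log10(N/C)
    on logarithmic bins.
    """
    eligible = [r for r in records if r.eligible]
    if not eligible:
        raise ValueError("no eligible records")
    n = len(eligible)
    lo, hi = nc_range
    in_range = sum(1 for r in eligible if r.nc is not None and lo <= r.nc <= hi)
    n_only = sum(1 for r in eligible if r.flag == NUCLEAR_ONLY)
    c_only = sum(1 for r in eligible if r.flag == CYTOPLASMIC_ONLY)
    values = [math.log10(r.nc) for r in eligible if r.nc is not None]
    edges = np.linspace(log_limits[0], log_limits[1], n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return NCSummary(n, in_range / n, n_only / n, c_only / n, (counts, edges))


# ---------------------------------------------------------------------------
# isomiR grouping
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class IsomiRGroup:
    mirna_id: str
    members: list[UniqueSeqRecord]
    representatives: dict[str, UniqueSeqRecord]
    discordant: bool

    def representative_rpm(self, lib: str) -> float:
        return self.representatives[lib].rpm.get(lib, 0.0)

    def representative_raw(self, lib: str) -> int:
        return self.representatives[lib].counts.get(lib, 0)


def _argmax_member(members: Sequence[UniqueSeqRecord], lib: str) -> UniqueSeqRecord:
    # highest count wins; ties fall to the lexicographically smallest sequence
    return min(members, key=lambda r: (-r.counts.get(lib, 0), r.sequence))


def group_isomirs(
    records: Iterable[UniqueSeqRecord],
    mirna_catalog: Sequence[tuple[str, str]] | None = None,
    hairpin_arms: dict[str, list[tuple[str, int, int]]] | None = None,
    libraries: tuple[str, str] = ("nuclear", "cytoplasmic"),
) -> list[IsomiRGroup]:
    """Group miRNA-labelled sequences into per-mature-miRNA isomiR families.

    Assignment uses the mature catalog when given: a record joins the mature
    miRNA whose sequence it overlaps the most within the matched hairpin
    (``hairpin_arms`` maps hairpin ref id to (mature_id, start, end) arms,
    1-based on the hairpin).  Without a catalog, records are grouped by their
    matched reference id.
    """
    groups: dict[str, list[UniqueSeqRecord]] = {}
    for rec in records:
        if rec.status != "mapped":
            continue
        mirna_id = rec.matched_ref or "unassigned"
        if hairpin_arms and rec.matched_ref in hairpin_arms:
            arms = hairpin_arms[rec.matched_ref]
            hairpin_seq = None
            if mirna_catalog:
                hairpin_seq = dict(mirna_catalog).get(rec.matched_ref)
            best_overlap, best_id = 0, None
            for mature_id, start, end in arms:
                pos = None
                if hairpin_seq is not None:
                    found = hairpin_seq.find(rec.effective_seq)
                    pos = found + 1 if found != -1 else None
                if pos is None:
                    continue
                rec_end = pos + len(rec.effective_seq) - 1
                overlap = min(rec_end, end) - max(pos, start) + 1
                if overlap > best_overlap:
                    best_overlap, best_id = overlap, mature_id
            if best_id is not None:
                mirna_id = best_id
        groups.setdefault(mirna_id, []).append(rec)
    out = []
    for mirna_id in sorted(groups):
        members = sorted(groups[mirna_id], key=lambda r: r.sequence)
        reps = {lib: _argmax_member(members, lib) for lib in libraries}
        discordant = len({id(r) for r in reps.values()}) > 1
        out.append(IsomiRGroup(mirna_id, members, reps, discordant))
    return out


def concordant_groups(groups: Iterable[IsomiRGroup]) -> list[IsomiRGroup]:
    """Groups whose most-abundant isomiR agrees between libraries; only these
    enter representative-level analyses."""
    return [g for g in groups if not g.discordant]


def mirna_correlation(
    groups: Sequence[IsomiRGroup],
    libraries: tuple[str, str] = ("nuclear", "cytoplasmic"),
    log_transform: bool = False,
) -> float:
    """Squared Pearson correlation of representative abundances between
    the two libraries."""
    if len(groups) < 2:
        raise ValueError("need at least two miRNA groups for a correlation")
    x = np.array([g.representative_rpm(libraries[0]) for g in groups])
    y = np.array([g.representative_rpm(libraries[1]) for g in groups])
    if log_transform:
        x, y = np.log10(x + 1.0), np.log10(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in representative abundances")
    if len(groups) == 2:
        warnings.warn("correlation on two points is degenerate (R^2 = 1)", stacklevel=2)
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


# ---------------------------------------------------------------------------
# 3' end motifs
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MotifRecord:
    sequence: str
    hexamer: str
    nc: float | None


def hexamer_extract(sequence: str) -> str:
    """Last six nucleotides of a sequence (the 3'-end hexanucleotide)."""
    if len(sequence) < 6:
        raise ValueError(f"sequence shorter than 6 nt: {sequence!r}")
    return sequence[-6:]


def motif_records(nc_recs: Iterable[NCRecord]) -> list[MotifRecord]:
    return [
        MotifRecord(r.sequence, hexamer_extract(r.sequence), r.nc)
        for r in nc_recs
        if r.eligible and r.nc is not None and len(r.sequence) >= 6
    ]


@dataclasses.dataclass
class MotifAssociation:
    motif: str
    n_with: int
    n_without: int
    median_nc_with: float | None
    median_nc_without: float | None
    mannwhitney_u: float | None
    p_value: float | None


def motif_nc_association(records: Sequence[MotifRecord], motif: str) -> MotifAssociation:
    """Compare N/C between carriers and non-carriers of a terminal motif.

    The motif (3–7 nt) is matched as a sequence suffix.  The comparison is
    descriptive (medians) plus a rank-based Mann-Whitney test; an empty
    carrier group is reported, not an error.
    """
    motif = motif.upper().replace("U", "T")
    if not 3 <= len(motif) <= 7:
        raise ValueError("motif length must be 3-7 nt")
    carriers = [r.nc for r in records if r.sequence.upper().replace("U", "T").endswith(motif)]
    others = [r.nc for r in records if not r.sequence.upper().replace("U", "T").endswith(motif)]
    u = p = None
    if carriers and others and len(carriers) > 1 and len(others) > 1:
        u, p = stats.mannwhitneyu(carriers, others, alternative="two-sided")
        u, p = float(u), float(p)
    return MotifAssociation(
        motif,
        len(carriers),
        len(others),
        float(np.median(carriers)) if carriers else None,
        float(np.median(others)) if others else None,
        u,
        p,
    )


# ---------------------------------------------------------------------------
# length distributions
# ---------------------------------------------------------------------------

def length_distribution(
    records: Iterable[UniqueSeqRecord],
    library: str,
    class_label: object = None,
    min_len: int = 16,
    max_len: int = 30,
) -> dict[int, int]:
    """Count-weighted read-length histogram for one library (optionally one
    class).  Lengths use the full sequence, untemplated tail included."""
    hist = {length: 0 for length in range(min_len, max_len + 1)}
    any_hit = False
    for rec in records:
        if rec.status != "mapped":
            continue
        if class_label is not None and rec.label is not class_label:
            continue
        length = len(rec.sequence)
        if min_len <= length <= max_len:
            hist[length] += rec.counts.get(library, 0)
            any_hit = True
    if not any_hit:
        warnings.warn(f"no records for library {library!r}", stacklevel=2)
    return hist


def histogram_mode(hist: dict[int, int]) -> int | None:
    if not any(hist.values()):
        return None
    return max(sorted(hist), key=lambda k: hist[k])
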