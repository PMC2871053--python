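"""tRNA 3' trailer calling, isotrailer aggregation and end statistics.

In pre-tRNA processing, RNase Z cleaves immediately 3' of the tRNA body and
releases the trailer, a Pol III product whose templated oligo-U terminator
usually leaves a terminal U-stretch.  A small RNA is called a trailer of a
tRNA gene when it perfectly matches the 40-nt genomic region downstream of
that gene starting at the region's first or second nucleotide.  All sequence
variants matching the same gene's region ("isotrailers") are aggregated; a
trailer's abundance is the sum over its isotrailers.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

from .preprocess import UniqueSeqRecord
from .reference import TrailerRegion

#: trailer eligibility: summed isotrailer raw count must exceed this in
#: at least one library ("more than 10", read strictly)
MIN_TRAILER_TOTAL = 10
#: a U-tail is a terminal run of at least this many uridines
MIN_U_TAIL = 2
ALLOWED_START_OFFSETS = (1, 2)


def match_offset(seq: str, region_seq: str) -> int | None:
    """Offset (1 or 2) at which ``seq`` perfectly matches the region, else None.

    Offset 1 is preferred when both would match (only possible for degenerate
    repetitive regions).
    """
    for offset in ALLOWED_START_OFFSETS:
        start = offset - 1
        if region_seq[start : start + len(seq)] == seq and start + len(seq) <= len(region_seq):
            return offset
    return None


@dataclasses.dataclass
class Isotrailer:
    sequence: str
    start_offset: int
    counts: dict[str, int]

    @property
    def end_offset(self) -> int:
        """1-based region position of the isotrailer's last nucleotide."""
        return self.start_offset + len(self.sequence) - 1


@dataclasses.dataclass
class TrailerCall:
    trna_name: str
    region_seq: str
    isotrailers: list[Isotrailer]
    representative_lib: str = "cytoplasmic"

    def aggregate_counts(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for iso in self.isotrailers:
            for lib, count in iso.counts.items():
                totals[lib] = totals.get(lib, 0) + count
        return totals

    def representative_seq(self) -> str:
        """Most abundant isotrailer in the designated (cytoplasmic) library;
        ties broken lexicographically."""
        lib = self.representative_lib
        return min(
            self.isotrailers,
            key=lambda iso: (-iso.counts.get(lib, 0), iso.sequence),
        ).sequence

    def u_tail(self) -> bool:
        return classify_u_tail(self.representative_seq())


def classify_u_tail(seq: str, min_run: int = MIN_U_TAIL) -> bool:
    """True iff the sequence ends with a run of >= ``min_run`` uridines
    (T in DNA space)."""
    seq = seq.upper().replace("U", "T")
    run = 0
    for base in reversed(seq):
        if base != "T":
            break
        run += 1
    return run >= min_run


def call_trailers(
    records: Iterable[UniqueSeqRecord],
    regions: Sequence[TrailerRegion],
    representative_lib: str = "cytoplasmic",
) -> list[TrailerCall]:
    """Match sequences against trailer regions at start offsets 1 and 2.

    A sequence matching several genes' regions joins every matching gene's
    isotrailer set (gene-level view); class-composition accounting counts it
    once, which the annotator handles.
    """
    records = list(records)
    calls: dict[str, TrailerCall] = {}
    for region in regions:
        if not region.region_seq:
            continue
        for rec in records:
            offset = match_offset(rec.effective_seq, region.region_seq)
            if offset is None:
                continue
            call = calls.setdefault(
                region.trna_name,
                TrailerCall(region.trna_name, region.region_seq, [], representative_lib),
            )
            call.isotrailers.append(
                Isotrailer(rec.effective_seq, offset, dict(rec.counts))
            )
    out = list(calls.values())
    out.sort(key=lambda c: c.trna_name)
    return out


def naive_call_trailers(
    records: Iterable[UniqueSeqRecord], regions: Sequence[TrailerRegion]
) -> dict[str, set[str]]:
    """Brute-force oracle: every (gene, sequence) pair where the sequence
    equals region[s .. s+len-1] for s in {1, 2}."""
    out: dict[str, set[str]] = {}
    for region in regions:
        for rec in records:
            seq = rec.effective_seq
            for s in ALLOWED_START_OFFSETS:
                if region.region_seq[s - 1 : s - 1 + len(seq)] == seq and len(seq) <= len(region.region_seq) - (s - 1):
                    out.setdefault(region.trna_name, set()).add(seq)
    return out


def aggregate_isotrailers(
    calls: Iterable[TrailerCall], min_total: int = MIN_TRAILER_TOTAL
) -> list[TrailerCall]:
    """Keep trailers whose summed raw isotrailer count exceeds ``min_total``
    in at least one library (strict inequality)."""
    kept = []
    for call in calls:
        totals = call.aggregate_counts()
        if any(total > min_total for total in totals.values()):
            kept.append(call)
    return kept


@dataclasses.dataclass
class EndHeterogeneity:
    trna_name: str
    start_distribution: dict[int, int]  # offset -> summed raw count
    end_distribution: dict[int, int]
    start_entropy: float
    end_entropy: float

    @property
    def n_distinct_starts(self) -> int:
        return len(self.start_distribution)

    @property
    def n_distinct_ends(self) -> int:
        return len(self.end_distribution)


def _shannon_entropy(weights: Iterable[int]) -> float:
    total = sum(weights)
    if total == 0:
        return 0.0
    entropy = 0.0
    for w in weights:
        if w > 0:
            p = w / total
            entropy -= p * math.log2(p)
    return entropy


def end_heterogeneity(calls: Iterable[TrailerCall]) -> list[EndHeterogeneity]:
    """Count-weighted 5' and 3' end-position distributions per gene.

    Trailers typically show consistent 5' ends (precise RNase Z cleavage at
    offset 1 or 2) and heterogeneous 3' ends (Pol III terminator slippage);
    the Shannon entropies quantify both.
    """
    out = []
    for call in calls:
        starts: dict[int, int] = {}
        ends: dict[int, int] = {}
        for iso in call.isotrailers:
            weight = sum(iso.counts.values())
            starts[iso.start_offset] = starts.get(iso.start_offset, 0) + weight
            ends[iso.end_offset] = ends.get(iso.end_offset, 0) + weight
        out.append(
            EndHeterogeneity(
                call.trna_name,
                starts,
                ends,
                _shannon_entropy(starts.values()),
                _shannon_entropy(ends.values()),
            )
        )
    return out
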