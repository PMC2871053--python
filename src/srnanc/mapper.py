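"""Exact all-hits genome mapping with rescue stages and 3' tail trimming.

Mapping is exact-match, all occurrences, both strands — the contract of an
``-n 0 -a`` short-read alignment.  It is implemented as a k-mer hash seed
(k = 16, the minimum read length) with full verification, so every hit set
can be checked against a naive sliding-window oracle.

Sequences that fail genome mapping are offered four rescue stages, in order:

1. exact substring of the rRNA repeat unit (rDNA is typically absent from
   genome assemblies);
2. exact substring of an exon–exon junction sequence;
3. exact substring of a CCA-tailed tRNA (the CCA is untemplated);
4. substring of a tRNA reference with exactly one mismatch (heavily modified
   tRNA positions misread as substitutions); a stage-4 success pre-labels
   the sequence as tRNA-derived.

Sequences still unplaced may carry 3' untemplated additions: if the longest
genomic exact-match prefix is at least ``min_prefix`` (17) nt, the tail is
trimmed and the prefix re-enters the mapped set; otherwise the sequence is
discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

from .preprocess import UniqueSeqRecord
from .reference import ReferenceBundle, revcomp
from .classes import ClassLabel

SEED_K = 16
MIN_TRIM_PREFIX = 17


@dataclasses.dataclass(frozen=True)
class GenomeHit:
    """One exact occurrence of a query on the genome.

    ``start`` is the 1-based leftmost genome coordinate of the matched
    interval regardless of strand; ``via`` records which stage placed the
    sequence.
    """

    chrom: str
    start: int
    strand: str
    via: str = "genome"


class GenomeIndex:
    """k-mer hash index over the forward genome with verification extension.

    Queries shorter than k are rejected (the pipeline's 16-nt minimum read
    length equals k, so this never triggers for retained records).
    """

    def __init__(self, genome: dict[str, str], k: int = SEED_K):
        self.genome = genome
        self.k = k
        index: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((chrom, i))
        self._index = index

    def _forward_hits(self, query: str) -> list[tuple[str, int]]:
        hits = []
        seed = query[: self.k]
        for chrom, i in self._index.get(seed, ()):
            if self.genome[chrom][i : i + len(query)] == query:
                hits.append((chrom, i + 1))
        return hits

    def map_exact_all(self, query: str) -> list[GenomeHit]:
        """Every exact occurrence of ``query`` on either strand, ordered by
        (chrom, start, strand)."""
        if len(query) < self.k:
            raise ValueError(
                f"query shorter than seed length k={self.k}: {query!r}"
            )
        hits = [GenomeHit(c, p, "+") for c, p in self._forward_hits(query)]
        rc = revcomp(query)
        # a minus-strand hit is a forward occurrence of the reverse complement
        for chrom, pos in self._forward_hits(rc):
            hits.append(GenomeHit(chrom, pos, "-"))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def naive_map_exact_all(query: str, genome: dict[str, str]) -> list[GenomeHit]:
    """Brute-force both-strand sliding-window scan; the mapper's oracle."""
    hits = []
    rc = revcomp(query)
    for chrom in sorted(genome):
        seq = genome[chrom]
        for target, strand in ((query, "+"), (rc, "-")):
            start = seq.find(target)
            while start != -1:
                hits.append(GenomeHit(chrom, start + 1, strand))
                start = seq.find(target, start + 1)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# Rescue stages
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AuxReferences:
    """Derived references consumed by the rescue stages."""

    rrna_units: list[tuple[str, str]]
    junctions: list[tuple[str, str]]
    cca_trnas: list[tuple[str, str]]
    trna_refs: list[tuple[str, str]]


@dataclasses.dataclass(frozen=True)
class RescueHit:
    ref_id: str
    via: str  # 'rRNA' | 'junction' | 'tRNA-CCA' | 'tRNA-1mm'


def _substring_of(query: str, refs: Sequence[tuple[str, str]]) -> str | None:
    for ref_id, seq in refs:
        if query in seq:
            return ref_id
    return None


def _one_mismatch_in(query: str, ref_seq: str) -> bool:
    """True iff query aligns inside ref_seq with exactly one substitution."""
    qlen = len(query)
    for offset in range(len(ref_seq) - qlen + 1):
        mismatches = 0
        for a, b in zip(query, ref_seq[offset : offset + qlen]):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        if mismatches == 1:
            return True
    return False


def rescue(query: str, aux: AuxReferences) -> RescueHit | None:
    """Try the four rescue stages in order; return the first success."""
    ref = _substring_of(query, aux.rrna_units)
    if ref is not None:
        return RescueHit(ref, "rRNA")
    ref = _substring_of(query, aux.junctions)
    if ref is not None:
        return RescueHit(ref, "junction")
    ref = _substring_of(query, aux.cca_trnas)
    if ref is not None:
        return RescueHit(ref, "tRNA-CCA")
    for ref_id, seq in aux.trna_refs:  # file order; first wins
        if _one_mismatch_in(query, seq):
            return RescueHit(ref_id, "tRNA-1mm")
    return None


def trim_untemplated_3prime(
    seq: str, index: GenomeIndex, min_prefix: int = MIN_TRIM_PREFIX
) -> tuple[str, str] | None:
    """Split off a 3' untemplated tail.

    Finds the longest L such that ``seq[:L]`` occurs exactly in the genome
    (either strand); returns ``(seq[:L], seq[L:])`` if ``min_prefix <= L <
    len(seq)``, else None.  The longest prefix is used so the recorded
    untemplated tail is minimal.
    """
    for length in range(len(seq) - 1, min_prefix - 1, -1):
        if index.map_exact_all(seq[:length]):
            return seq[:length], seq[length:]
    return None


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MappingResult:
    records: list[UniqueSeqRecord]
    hits: dict[str, list[GenomeHit]]  # per mapped sequence (genome-placed only)

    def mapped(self) -> list[UniqueSeqRecord]:
        return [r for r in self.records if r.status == "mapped"]

    def mapped_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for rec in self.mapped():
            for lib, count in rec.counts.items():
                totals[lib] = totals.get(lib, 0) + count
        return totals


def map_records(
    records: Iterable[UniqueSeqRecord],
    bundle: ReferenceBundle,
    aux: AuxReferences,
    index: GenomeIndex | None = None,
    min_prefix: int = MIN_TRIM_PREFIX,
    enabled_rescues: tuple[str, ...] = ("rRNA", "junction", "tRNA-CCA", "tRNA-1mm"),
) -> MappingResult:
    """Assign mapped/discarded status to every unique sequence.

    Order of attempts per sequence: exact all-hits genome mapping, the rescue
    cascade, 3' untemplated-tail trimming.  Each sequence ends in exactly one
    of {mapped, discarded}.  ``enabled_rescues`` exists for ablation tests.
    """
    if index is None:
        index = GenomeIndex(bundle.genome)
    if enabled_rescues != ("rRNA", "junction", "tRNA-CCA", "tRNA-1mm"):
        stage_refs = {
            "rRNA": aux.rrna_units,
            "junction": aux.junctions,
            "tRNA-CCA": aux.cca_trnas,
            "tRNA-1mm": aux.trna_refs,
        }
        aux = AuxReferences(
            rrna_units=stage_refs["rRNA"] if "rRNA" in enabled_rescues else [],
            junctions=stage_refs["junction"] if "junction" in enabled_rescues else [],
            cca_trnas=stage_refs["tRNA-CCA"] if "tRNA-CCA" in enabled_rescues else [],
            trna_refs=stage_refs["tRNA-1mm"] if "tRNA-1mm" in enabled_rescues else [],
        )
    out_records = []
    hit_map: dict[str, list[GenomeHit]] = {}
    for rec in records:
        hits = index.map_exact_all(rec.sequence)
        if hits:
            rec.status, rec.via = "mapped", "genome"
            hit_map[rec.sequence] = hits
            out_records.append(rec)
            continue
        rhit = rescue(rec.sequence, aux)
        if rhit is not None:
            rec.status, rec.via = "mapped", rhit.via
            rec.matched_ref = rhit.ref_id
            if rhit.via == "tRNA-1mm":
                rec.label = ClassLabel.TRNA
            out_records.append(rec)
            continue
        trimmed = trim_untemplated_3prime(rec.sequence, index, min_prefix)
        if trimmed is not None:
            prefix, tail = trimmed
            rec.status, rec.via = "mapped", "trimmed"
            rec.trimmed_tail = tail
            hit_map[rec.sequence] = index.map_exact_all(prefix)
            out_records.append(rec)
            continue
        rec.status, rec.via = "discarded", None
        out_records.append(rec)
    return MappingResult(out_records, hit_map)
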