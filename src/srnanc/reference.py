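"""Reference bundle: genome, class-labelled reference RNAs and gene loci.

The pipeline needs four kinds of reference information: a genome, a corpus of
known RNA sequences whose FASTA headers carry a ``class=<label>`` key, the
genomic loci of tRNA genes and repeats, and exon-chain models of mRNAs (and
any intron-containing tRNAs).  From these it derives three auxiliary
references used by the mapping rescue stages and the trailer caller:

* exon–exon junction sequences, so junction-spanning reads can be rescued;
* CCA-tailed tRNA sequences, because the 3' CCA of mature tRNA is added
  post-transcriptionally and is absent from the genome;
* the 40-nt genomic region immediately downstream of each tRNA gene, where
  pre-tRNA 3' trailers live.

Coordinates are 1-based closed internally; BED input is converted from its
native 0-based half-open convention at the parsing boundary, GFF3 is already
1-based closed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .classes import ClassLabel, parse_class_label

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: default trailer-region length (nt downstream of the tRNA gene 3' end)
TRAILER_REGION_LENGTH = 40
#: default junction flank: max read length (30) minus one, so every
#: junction-spanning read of <=30 nt is a substring of the junction sequence
JUNCTION_FLANK = 29


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (N-safe)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class Locus:
    """A genomic interval, 1-based closed, stranded."""

    chrom: str
    start: int
    end: int
    strand: str
    name: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval {self.start}..{self.end} for {self.name}")


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """An exon-chain gene model; exons are 1-based closed, ordered 5'->3'
    in genomic coordinates (i.e. ascending start)."""

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValueError(f"exons of {self.name} overlap or are unordered")
            if end < start:
                raise ValueError(f"exon {start}..{end} of {self.name} inverted")
            prev_end = end


@dataclasses.dataclass(frozen=True)
class RefRNA:
    """One class-labelled reference RNA sequence."""

    class_label: ClassLabel
    ref_id: str
    sequence: str


@dataclasses.dataclass(frozen=True)
class TrailerRegion:
    """The genomic region immediately 3' of a tRNA gene, read on the gene
    strand (minus-strand regions are reverse-complemented)."""

    trna_name: str
    chrom: str
    strand: str
    region_seq: str
    truncated: bool = False


@dataclasses.dataclass
class ReferenceBundle:
    genome: dict[str, str]
    ref_rnas: list[RefRNA]
    trna_loci: list[Locus]
    mrna_models: list[GeneModel]
    repeat_loci: list[Locus]

    def validate(self) -> None:
        """Check every locus against chromosome bounds and exon ordering."""
        for locus in list(self.trna_loci) + list(self.repeat_loci):
            self._check_bounds(locus.chrom, locus.start, locus.end, locus.name)
        for model in self.mrna_models:
            for start, end in model.exons:
                self._check_bounds(model.chrom, start, end, model.name)

    def _check_bounds(self, chrom: str, start: int, end: int, name: str) -> None:
        if chrom not in self.genome:
            raise ValueError(f"locus {name}: unknown chromosome {chrom!r}")
        if end > len(self.genome[chrom]):
            raise ValueError(
                f"locus {name}: end {end} exceeds length of {chrom} "
                f"({len(self.genome[chrom])})"
            )

    def refs_of(self, label: ClassLabel) -> list[RefRNA]:
        return [r for r in self.ref_rnas if r.class_label is label]

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Extract genome[start..end] (1-based closed), strand-corrected."""
        seq = self.genome[chrom][start - 1 : end]
        return revcomp(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _normalize_seq(seq: str) -> str:
    """Uppercase and map U->T so RNA-space references compare in DNA space."""
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (full header, normalized sequence) pairs."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.description, _normalize_seq(str(rec.seq))))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _parse_ref_rnas(path: str | Path) -> list[RefRNA]:
    refs = []
    for header, seq in read_fasta(path):
        fields = header.split()
        ref_id = fields[0]
        tokens = dict(
            field.split("=", 1) for field in fields[1:] if "=" in field
        )
        if "class" not in tokens:
            raise ValueError(
                f"reference record {ref_id!r} lacks a class=<label> header key"
            )
        label = parse_class_label(tokens["class"])
        refs.append(RefRNA(label, ref_id, seq))
    return refs


def _parse_bed(path: str | Path) -> tuple[list[Locus], list[GeneModel], list[Locus]]:
    """Parse a BED file of tRNA/repeat/mRNA loci.

    The name column is ``<kind>:<name>`` with kind one of ``tRNA``,
    ``repeat`` or ``mRNA``; mRNA rows must be BED12 (blocks become exons).
    BED is 0-based half-open; output is 1-based closed.
    """
    trnas: list[Locus] = []
    models: list[GeneModel] = []
    repeats: list[Locus] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise ValueError(f"{path}:{lineno}: expected >=6 BED columns")
            chrom, start0, end0, name, _score, strand = cols[:6]
            start, end = int(start0) + 1, int(end0)
            if ":" not in name:
                raise ValueError(
                    f"{path}:{lineno}: BED name must be '<kind>:<name>', got {name!r}"
                )
            kind, short = name.split(":", 1)
            if kind == "tRNA":
                trnas.append(Locus(chrom, start, end, strand, short))
            elif kind == "repeat":
                repeats.append(Locus(chrom, start, end, strand, short))
            elif kind == "mRNA":
                if len(cols) < 12:
                    raise ValueError(
                        f"{path}:{lineno}: mRNA rows need BED12 blocks"
                    )
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
                exons = tuple(
                    (start + off, start + off + size - 1)
                    for off, size in zip(offsets, sizes)
                )
                models.append(GeneModel(short, chrom, strand, exons))
            else:
                raise ValueError(f"{path}:{lineno}: unknown locus kind {kind!r}")
    return trnas, models, repeats


def _parse_gff3_attrs(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            key, value = item.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def _parse_gff3(path: str | Path) -> tuple[list[Locus], list[GeneModel], list[Locus]]:
    """Parse tRNA / repeat_region / exon features from GFF3 (1-based closed).

    Exons are grouped into gene models by their ``Parent`` attribute.
    """
    trnas: list[Locus] = []
    repeats: list[Locus] = []
    exons_by_parent: dict[str, list[tuple[str, str, int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols[:9]
            info = _parse_gff3_attrs(attrs)
            if ftype == "tRNA":
                trnas.append(Locus(chrom, int(start), int(end), strand, info.get("ID", f"tRNA{lineno}")))
            elif ftype == "repeat_region":
                repeats.append(Locus(chrom, int(start), int(end), strand, info.get("ID", f"rep{lineno}")))
            elif ftype == "exon":
                parent = info.get("Parent", info.get("ID", f"gene{lineno}"))
                exons_by_parent.setdefault(parent, []).append(
                    (chrom, strand, int(start), int(end))
                )
    models = []
    for parent, exons in exons_by_parent.items():
        exons.sort(key=lambda x: x[2])
        chrom, strand = exons[0][0], exons[0][1]
        models.append(
            GeneModel(parent, chrom, strand, tuple((s, e) for _, _, s, e in exons))
        )
    return trnas, models, repeats


def load_bundle(
    genome_path: str | Path,
    rnas_path: str | Path,
    loci_path: str | Path | None = None,
) -> ReferenceBundle:
    """Load and validate a reference bundle.

    Parameters
    ----------
    genome_path:
        Genome FASTA.
    rnas_path:
        Reference RNA corpus FASTA; each header must carry ``class=<label>``.
    loci_path:
        Optional BED (``.bed``) or GFF3 file of tRNA/mRNA/repeat loci.
    """
    genome = {header.split()[0]: seq for header, seq in read_fasta(genome_path)}
    ref_rnas = _parse_ref_rnas(rnas_path)
    trnas: list[Locus] = []
    models: list[GeneModel] = []
    repeats: list[Locus] = []
    if loci_path is not None:
        if str(loci_path).endswith((".gff", ".gff3")):
            trnas, models, repeats = _parse_gff3(loci_path)
        else:
            trnas, models, repeats = _parse_bed(loci_path)
    bundle = ReferenceBundle(genome, ref_rnas, trnas, models, repeats)
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# Derived auxiliary references
# ---------------------------------------------------------------------------

def build_trailer_regions(
    bundle: ReferenceBundle, length: int = TRAILER_REGION_LENGTH
) -> list[TrailerRegion]:
    """Extract the genomic region immediately 3' of each tRNA gene.

    For a plus-strand gene ending at position ``p`` the region is
    ``genome[p+1 .. p+length]``; for a minus-strand gene starting at ``s`` it
    is the reverse complement of ``genome[s-length .. s-1]``.  Regions running
    off a chromosome end are truncated and flagged, never fatal.
    """
    regions = []
    for locus in bundle.trna_loci:
        chrom_len = len(bundle.genome[locus.chrom])
        if locus.strand == "+":
            start = locus.end + 1
            end = min(locus.end + length, chrom_len)
            if start > chrom_len:
                seq, truncated = "", True
            else:
                seq = bundle.fetch(locus.chrom, start, end)
                truncated = end - start + 1 < length
        else:
            end = locus.start - 1
            start = max(locus.start - length, 1)
            if end < 1:
                seq, truncated = "", True
            else:
                seq = bundle.fetch(locus.chrom, start, end, strand="-")
                truncated = end - start + 1 < length
        regions.append(
            TrailerRegion(locus.name, locus.chrom, locus.strand, seq, truncated)
        )
    return regions


def build_cca_trnas(bundle: ReferenceBundle) -> list[tuple[str, str]]:
    """Append the post-transcriptional CCA to every tRNA reference sequence."""
    return [
        (ref.ref_id, ref.sequence + "CCA")
        for ref in bundle.refs_of(ClassLabel.TRNA)
    ]


def spliced_transcript(bundle: ReferenceBundle, model: GeneModel) -> str:
    """Concatenate a model's exons in transcription order on the gene strand."""
    parts = [bundle.fetch(model.chrom, s, e) for s, e in model.exons]
    seq = "".join(parts)
    return revcomp(seq) if model.strand == "-" else seq


def build_junction_library(
    bundle: ReferenceBundle, flank: int = JUNCTION_FLANK
) -> list[tuple[str, str]]:
    """Build exon–exon junction sequences for every adjacent exon pair.

    Each junction is the last ``flank`` nt of the upstream exon followed by
    the first ``flank`` nt of the downstream exon, in transcription order on
    the gene strand.  With the default flank of 29 nt any junction-spanning
    read of <=30 nt is an exact substring.
    """
    junctions = []
    for model in bundle.mrna_models:
        exon_seqs = [bundle.fetch(model.chrom, s, e) for s, e in model.exons]
        if model.strand == "-":
            exon_seqs = [revcomp(s) for s in reversed(exon_seqs)]
        for i in range(len(exon_seqs) - 1):
            seq = exon_seqs[i][-flank:] + exon_seqs[i + 1][:flank]
            junctions.append((f"{model.name}|junction{i + 1}", seq))
    return junctions


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]], note: str = "") -> None:
    """Write (id, sequence) pairs as FASTA, with an optional provenance note
    appended to each header."""
    with open(path, "w") as handle:
        for ref_id, seq in records:
            header = f">{ref_id}" + (f" {note}" if note else "")
            handle.write(header + "\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def trailer_regions_to_fasta(path: str | Path, regions: Iterable[TrailerRegion]) -> None:
    with open(path, "w") as handle:
        for region in regions:
            handle.write(
                f">{region.trna_name} chrom={region.chrom} strand={region.strand}"
                f" truncated={'yes' if region.truncated else 'no'}\n{region.region_seq}\n"
            )
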