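"""Synthetic nuclear/cytoplasmic small-RNA data with known ground truth.

The generator builds a toy genome with planted, non-overlapping features —
miRNA hairpins with designated mature arms, tRNA genes each followed by an
engineered 40-nt trailer region, box C/D and H/ACA snoRNAs, scaRNAs
(including one ACA45-like miRNA-mimic), a mitochondrial contig, an off-genome
rRNA repeat unit with transcribed spacers, multi-exon mRNAs, repeat families
placed at several loci, and intergenic space — and then draws paired
nuclear/cytoplasmic read libraries from those features.

Each source fragment carries a planted compartment mixing ratio: the source
gets expected library shares (w_N/Sigma w_N, w_C/Sigma w_C) and read counts
are Poisson at the configured depths, so the N/C estimator's sampling error
is analytically checkable.  Reads optionally receive isomiR 3'-end jitter,
untemplated 3' additions, CCA-tailed tRNA 3' fragments, single-mismatch tRNA
reads, a ligated 3' adapter, and poly-A / 5'-adapter / adapter-less
contaminants.  Every emitted read is traceable to its source and true class.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path

import numpy as np
import yaml

from .classes import ClassLabel
from .preprocess import MAX_LEN
from .reference import (
    GeneModel,
    Locus,
    RefRNA,
    ReferenceBundle,
    TrailerRegion,
    build_trailer_regions,
)

BASES = "ACGT"

# canonical small-RNA-seq adapters (Illumina small RNA kit style)
DEFAULT_ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


@dataclasses.dataclass
class SimConfig:
    """Study conditions for the simulator.

    Depths and read length mirror a deeply sequenced pair of compartment
    libraries scaled to desk size; per-class N:C ratios follow the
    directions observed in fractionation experiments (snoRNAs nuclear,
    mitochondrial RNAs and tRNA trailers cytoplasmic, miRNAs near parity).
    """

    seed: int = 0
    chrom_length: int = 120_000
    mito_length: int = 12_000
    read_length: int = 35

    n_mirna: int = 25
    n_trna: int = 15
    n_cd_snorna: int = 8
    n_haca_snorna: int = 5
    n_scarna: int = 3  # one of these is ACA45-like (miRNA-like N/C)
    n_mrna: int = 5
    n_repeat_families: int = 3
    repeat_copies: int = 3
    n_mito_sources: int = 12
    n_intergenic_sources: int = 15

    # expected N:C mixing ratio per class; per-source log-normal jitter on top
    class_nc: dict[str, float] = dataclasses.field(
        default_factory=lambda: {
            "miRNA": 1.2,
            "mitochondrial_RNA": 0.1,
            "rRNA": 0.6,
            "ITS": 2.0,
            "ETS": 10.0,
            "HACA_snoRNA": 8.0,
            "CD_snoRNA": 40.0,
            "scaRNA": 2.0,
            "tRNA": 0.25,
            "tRNA_trailer": 0.06,
            "mRNA": 1.5,
            "genomic_repeat": 0.6,
            "unknown": 0.8,
        }
    )
    nc_jitter_sd: float = 0.5  # sd of log2 per-source ratio jitter
    abundance_range: tuple[float, float] = (20.0, 2000.0)  # log-uniform weights

    # 3'-end heterogeneity of miRNA reads: offset -> probability
    isomir_end_probs: dict[int, float] = dataclasses.field(
        default_factory=lambda: {-2: 0.05, -1: 0.15, 0: 0.6, 1: 0.15, 2: 0.05}
    )
    # trailer 3'-end jitter within the templated U-run, and 5' offset-2 rate
    trailer_end_probs: dict[int, float] = dataclasses.field(
        default_factory=lambda: {-1: 0.2, 0: 0.6, 1: 0.2}
    )
    trailer_offset2_rate: float = 0.25
    # trailer U-tail (templated oligo-U terminator) length distribution
    u_tail_lengths: dict[int, float] = dataclasses.field(
        default_factory=lambda: {3: 0.3, 4: 0.4, 5: 0.3}
    )
    u_tail_fraction: float = 0.8  # fraction of trailers ending in a U-run

    untemplated_rate: float = 0.05
    untemplated_alphabet: str = "TA"
    cca_fragment_rate: float = 0.2
    one_mismatch_rate: float = 0.1

    depth: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"nuclear": 100_000, "cytoplasmic": 100_000}
    )
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    polya_rate: float = 0.01
    adapter5_rate: float = 0.01
    no_adapter_rate: float = 0.02

    def validate(self) -> None:
        for name in ("isomir_end_probs", "trailer_end_probs", "u_tail_lengths"):
            probs = getattr(self, name)
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        if any(d <= 0 for d in self.depth.values()):
            raise ValueError("library depths must be positive")
        for rate in (
            self.untemplated_rate,
            self.cca_fragment_rate,
            self.one_mismatch_rate,
            self.polya_rate,
            self.adapter5_rate,
            self.no_adapter_rate,
        ):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["abundance_range"] = list(self.abundance_range)
        return out


@dataclasses.dataclass
class Source:
    """One planted fragment family: a sequence with a compartment mixing
    ratio and the feature it derives from."""

    source_id: str
    true_class: ClassLabel
    feature_id: str
    sequence: str
    weight: dict[str, float]
    planted_nc: float = 0.0  # ratio of library shares, filled after weighting
    expected: dict[str, float] = dataclasses.field(default_factory=dict)
    kind: str = "plain"  # 'plain'|'mirna'|'trna'|'trailer'
    extra: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class GroundTruth:
    sources: list[Source]
    # (library, insert sequence, source_id, class value) -> read count
    read_truth: Counter
    trailer_truth: dict[str, dict]  # trna_name -> {sequence, u_tail}
    isomir_families: dict[str, str]  # mature id -> hairpin id


@dataclasses.dataclass
class SimulatedDataset:
    config: SimConfig
    bundle: ReferenceBundle
    trailer_regions: list[TrailerRegion]
    libraries: dict[str, list[tuple[str, int]]]  # lib -> [(read, count)]
    truth: GroundTruth
    mirna_catalog: list[tuple[str, str]]
    hairpin_arms: dict[str, list[tuple[str, int, int]]]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def _choice(rng: np.random.Generator, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    return int(rng.choice(keys, p=[probs[k] for k in keys]))


# ---------------------------------------------------------------------------
# Reference simulation
# ---------------------------------------------------------------------------

def simulate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceBundle, dict]:
    """Build the toy genome, reference corpus and loci, plus a scaffold of
    planted-feature metadata consumed by :func:`simulate_libraries`."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    chrom = "chr1"
    plan: list[tuple[str, int]] = []  # (feature tag, length on genome)
    plan += [("mirna", 70)] * config.n_mirna
    plan += [("trna", 72 + 40)] * config.n_trna  # gene + engineered trailer
    plan += [("cd", 80)] * config.n_cd_snorna
    plan += [("haca", 130)] * config.n_haca_snorna
    plan += [("scarna", 130)] * config.n_scarna
    plan += [("mrna", 0)] * config.n_mrna  # sized at placement
    plan += [("repeat", 0)] * (config.n_repeat_families * config.repeat_copies)

    order = rng.permutation(len(plan))
    scaffold: dict = {
        "mirna": [],
        "trna": [],
        "cd": [],
        "haca": [],
        "scarna": [],
        "mrna": [],
        "repeat": [],
        "gaps": [],
    }

    genome_parts: list[str] = []
    cursor = 0  # 0-based length so far
    refs: list[RefRNA] = []
    trna_loci: list[Locus] = []
    repeat_loci: list[Locus] = []
    mrna_models: list[GeneModel] = []
    mirna_catalog: list[tuple[str, str]] = []
    hairpin_arms: dict[str, list[tuple[str, int, int]]] = {}
    trailer_truth: dict[str, dict] = {}

    repeat_consensus = {
        f"repFam{i + 1}": _random_seq(rng, 200)
        for i in range(config.n_repeat_families)
    }
    repeat_copy_counter: Counter = Counter()
    counters: Counter = Counter()

    def add_gap() -> None:
        nonlocal cursor
        gap_len = int(rng.integers(80, 300))
        gap = _random_seq(rng, gap_len)
        scaffold["gaps"].append((cursor + 1, cursor + gap_len))
        genome_parts.append(gap)
        cursor += gap_len

    add_gap()
    for idx in order:
        tag, _ = plan[idx]
        counters[tag] += 1
        n = counters[tag]
        if tag == "mirna":
            hairpin = _random_seq(rng, 70)
            arm_start, arm_end = 16, 37  # 22-nt mature arm, 1-based on hairpin
            hp_id = f"hsa-mir-sim{n}"
            mat_id = f"hsa-miR-sim{n}"
            refs.append(RefRNA(ClassLabel.MIRNA, hp_id, hairpin))
            mirna_catalog.append((hp_id, hairpin))
            hairpin_arms[hp_id] = [(mat_id, arm_start, arm_end)]
            scaffold["mirna"].append(
                {"id": hp_id, "mature_id": mat_id, "hairpin": hairpin,
                 "arm": (arm_start, arm_end)}
            )
            genome_parts.append(hairpin)
            cursor += len(hairpin)
        elif tag == "trna":
            gene = _random_seq(rng, 72)
            name = f"tRNA-sim{n}"
            refs.append(RefRNA(ClassLabel.TRNA, name, gene))
            # engineered trailer region: core + templated U-run + filler
            core_len = int(rng.integers(15, 19))
            core = _random_seq(rng, core_len - 1) + rng.choice(list("ACG"))
            if rng.random() < config.u_tail_fraction:
                run = _choice(rng, config.u_tail_lengths)
                tail = "T" * run
            else:
                tail = "".join(rng.choice(list("ACG")) for _ in range(3))
            filler_len = 40 - core_len - len(tail)
            filler = rng.choice(list("ACG")) + _random_seq(rng, filler_len - 1)
            region = core + tail + filler
            assert len(region) == 40
            trailer_seq = core + tail
            trailer_truth[name] = {
                "sequence": trailer_seq,
                "u_tail": tail.endswith("TT"),
            }
            gene_start = cursor + 1
            genome_parts.append(gene + region)
            trna_loci.append(Locus(chrom, gene_start, gene_start + 71, "+", name))
            cursor += len(gene) + 40
            scaffold["trna"].append({"id": name, "gene": gene, "trailer": trailer_seq})
        elif tag in ("cd", "haca", "scarna"):
            length = 80 if tag == "cd" else 130
            seq = _random_seq(rng, length)
            label = {
                "cd": ClassLabel.CD_SNORNA,
                "haca": ClassLabel.HACA_SNORNA,
                "scarna": ClassLabel.SCARNA,
            }[tag]
            name = {"cd": "SNORD-sim", "haca": "SNORA-sim", "scarna": "SCARNA-sim"}[tag] + str(n)
            if tag == "scarna" and n == 1:
                name = "ACA45-sim"  # miRNA-like processing mimic
            refs.append(RefRNA(label, name, seq))
            scaffold[tag].append({"id": name, "seq": seq})
            genome_parts.append(seq)
            cursor += length
        elif tag == "mrna":
            n_exons = int(rng.integers(2, 4))
            name = f"mRNA-sim{n}"
            exons = []
            pieces = []
            local = cursor
            for e in range(n_exons):
                exon_len = int(rng.integers(150, 300))
                exons.append((local + 1, local + exon_len))
                pieces.append(_random_seq(rng, exon_len))
                local += exon_len
                if e < n_exons - 1:
                    intron_len = int(rng.integers(80, 150))
                    pieces.append(_random_seq(rng, intron_len))
                    local += intron_len
            genome_parts.append("".join(pieces))
            cursor = local
            model = GeneModel(name, chrom, "+", tuple(exons))
            mrna_models.append(model)
            transcript = "".join(
                p for i, p in enumerate(pieces) if i % 2 == 0
            )
            refs.append(RefRNA(ClassLabel.MRNA, name, transcript))
            scaffold["mrna"].append(
                {"id": name, "transcript": transcript,
                 "exon_lens": [e - s + 1 for s, e in exons]}
            )
        elif tag == "repeat":
            fam = f"repFam{(n - 1) % config.n_repeat_families + 1}"
            repeat_copy_counter[fam] += 1
            seq = repeat_consensus[fam]
            start = cursor + 1
            genome_parts.append(seq)
            cursor += len(seq)
            repeat_loci.append(Locus(chrom, start, cursor, "+", fam))
        add_gap()

    if cursor > config.chrom_length:
        raise ValueError(
            f"genome too small for requested features: need >{cursor} nt, "
            f"have {config.chrom_length}"
        )
    pad = config.chrom_length - cursor
    if pad:
        scaffold["gaps"].append((cursor + 1, cursor + pad))
        genome_parts.append(_random_seq(rng, pad))
    chr1 = "".join(genome_parts)
    assert len(chr1) == config.chrom_length

    chrm = _random_seq(rng, config.mito_length)
    refs.append(RefRNA(ClassLabel.MITO, "MT-transcript", chrm))

    # off-genome rRNA repeat unit: 5'ETS | 18S | ITS1 | 28S | 3'ETS
    segments = {
        "ETS5": _random_seq(rng, 400),
        "18S": _random_seq(rng, 1000),
        "ITS1": _random_seq(rng, 300),
        "28S": _random_seq(rng, 1100),
        "ETS3": _random_seq(rng, 200),
    }
    refs.append(RefRNA(ClassLabel.RRNA, "18S-sim", segments["18S"]))
    refs.append(RefRNA(ClassLabel.RRNA, "28S-sim", segments["28S"]))
    refs.append(RefRNA(ClassLabel.ITS, "ITS1-sim", segments["ITS1"]))
    refs.append(RefRNA(ClassLabel.ETS, "ETS5-sim", segments["ETS5"]))
    refs.append(RefRNA(ClassLabel.ETS, "ETS3-sim", segments["ETS3"]))
    scaffold["rrna_segments"] = segments
    scaffold["repeat_consensus"] = repeat_consensus
    scaffold["mirna_catalog"] = mirna_catalog
    scaffold["hairpin_arms"] = hairpin_arms
    scaffold["trailer_truth"] = trailer_truth

    bundle = ReferenceBundle(
        genome={"chr1": chr1, "chrM": chrm},
        ref_rnas=refs,
        trna_loci=trna_loci,
        mrna_models=mrna_models,
        repeat_loci=repeat_loci,
    )
    bundle.validate()
    return bundle, scaffold


# ---------------------------------------------------------------------------
# Source construction
# ---------------------------------------------------------------------------

def _fragment(rng: np.random.Generator, seq: str, lo: int = 18, hi: int = 24) -> str:
    length = int(rng.integers(lo, min(hi, len(seq)) + 1))
    start = int(rng.integers(0, len(seq) - length + 1))
    return seq[start : start + length]


def _build_sources(
    config: SimConfig, bundle: ReferenceBundle, scaffold: dict, rng: np.random.Generator
) -> list[Source]:
    sources: list[Source] = []

    def ratio_for(class_key: str) -> float:
        base = config.class_nc.get(class_key, 1.0)
        return base * float(2.0 ** rng.normal(0.0, config.nc_jitter_sd))

    def add(source_id, true_class, feature_id, seq, class_key, kind="plain", extra=None):
        lo, hi = config.abundance_range
        abundance = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        r = ratio_for(class_key)
        weight = {"cytoplasmic": abundance, "nuclear": abundance * r}
        sources.append(
            Source(source_id, true_class, feature_id, seq, weight,
                   kind=kind, extra=extra or {})
        )

    for mir in scaffold["mirna"]:
        start, end = mir["arm"]
        mature = mir["hairpin"][start - 1 : end]
        add(f"src:{mir['mature_id']}", ClassLabel.MIRNA, mir["id"], mature,
            "miRNA", kind="mirna",
            extra={"hairpin": mir["hairpin"], "arm": mir["arm"]})
    for i, trna in enumerate(scaffold["trna"]):
        gene = trna["gene"]
        frag = _fragment(rng, gene[:40], 18, 22)
        add(f"src:{trna['id']}:frag", ClassLabel.TRNA, trna["id"], frag,
            "tRNA", kind="trna", extra={"gene": gene})
        add(f"src:{trna['id']}:trailer", ClassLabel.TRNA_TRAILER, trna["id"],
            trna["trailer"], "tRNA_trailer", kind="trailer",
            extra={"trailer": trna["trailer"]})
    for sno in scaffold["cd"]:
        add(f"src:{sno['id']}", ClassLabel.CD_SNORNA, sno["id"],
            _fragment(rng, sno["seq"]), "CD_snoRNA")
    for sno in scaffold["haca"]:
        add(f"src:{sno['id']}", ClassLabel.HACA_SNORNA, sno["id"],
            _fragment(rng, sno["seq"]), "HACA_snoRNA")
    for sca in scaffold["scarna"]:
        # the ACA45-like scaRNA is processed into miRNA-like sRNAs with a
        # miRNA-like compartment ratio; other scaRNAs stay nuclear-leaning
        key = "miRNA" if sca["id"].startswith("ACA45") else "scaRNA"
        add(f"src:{sca['id']}", ClassLabel.SCARNA, sca["id"],
            _fragment(rng, sca["seq"]), key)
    for i in range(config.n_mito_sources):
        frag = _fragment(rng, bundle.genome["chrM"])
        add(f"src:mito{i + 1}", ClassLabel.MITO, "MT-transcript", frag,
            "mitochondrial_RNA")
    seg = scaffold["rrna_segments"]
    rrna_plan = [("18S", ClassLabel.RRNA, "rRNA", 4), ("28S", ClassLabel.RRNA, "rRNA", 4),
                 ("ITS1", ClassLabel.ITS, "ITS", 2), ("ETS5", ClassLabel.ETS, "ETS", 2),
                 ("ETS3", ClassLabel.ETS, "ETS", 1)]
    for seg_name, label, key, count in rrna_plan:
        for i in range(count):
            add(f"src:{seg_name}:{i + 1}", label, f"{seg_name}-sim",
                _fragment(rng, seg[seg_name]), key)
    for gene in scaffold["mrna"]:
        transcript = gene["transcript"]
        exon_lens = gene["exon_lens"]
        # interior fragments stay within one exon
        bounds = np.cumsum([0] + exon_lens)
        for i in range(2):
            e = int(rng.integers(0, len(exon_lens)))
            exon_seq = transcript[bounds[e] : bounds[e + 1]]
            add(f"src:{gene['id']}:ex{i + 1}", ClassLabel.MRNA, gene["id"],
                _fragment(rng, exon_seq), "mRNA")
        # one junction-spanning fragment per gene
        boundary = int(bounds[1])
        over = int(rng.integers(6, 11))
        length = int(rng.integers(18, 25))
        start = boundary - over
        add(f"src:{gene['id']}:jx", ClassLabel.MRNA, gene["id"],
            transcript[start : start + length], "mRNA")
    for fam, consensus in scaffold["repeat_consensus"].items():
        for i in range(2):
            add(f"src:{fam}:{i + 1}", ClassLabel.GENOMIC_REPEAT, fam,
                _fragment(rng, consensus, 18, 22), "genomic_repeat")
    gaps = [g for g in scaffold["gaps"] if g[1] - g[0] + 1 >= 40]
    for i in range(config.n_intergenic_sources):
        start, end = gaps[int(rng.integers(0, len(gaps)))]
        gap_seq = bundle.genome["chr1"][start - 1 : end]
        add(f"src:intergenic{i + 1}", ClassLabel.UNKNOWN, "intergenic",
            _fragment(rng, gap_seq), "unknown")

    # convert weights to expected counts and planted N/C (ratio of shares)
    totals = {
        lib: sum(s.weight[lib] for s in sources) for lib in ("nuclear", "cytoplasmic")
    }
    for s in sources:
        share = {lib: s.weight[lib] / totals[lib] for lib in totals}
        s.planted_nc = share["nuclear"] / share["cytoplasmic"]
        s.expected = {
            lib: share[lib] * config.depth[lib] for lib in config.depth
        }
    return sources


# ---------------------------------------------------------------------------
# Read emission
# ---------------------------------------------------------------------------

def _untemplated_tail(
    rng: np.random.Generator, config: SimConfig, next_genomic: str
) -> str:
    """A 1-3 nt tail whose first base differs from the templated
    continuation, so the genomic prefix of the read is exactly the source."""
    length = int(rng.integers(1, 4))
    choices = [b for b in config.untemplated_alphabet if b != next_genomic]
    if not choices:
        choices = [b for b in BASES if b != next_genomic]
    tail = rng.choice(choices)
    for _ in range(length - 1):
        tail += rng.choice(list(config.untemplated_alphabet))
    return str(tail)


def _emit_insert(
    source: Source, config: SimConfig, rng: np.random.Generator,
    genome: dict[str, str],
) -> str:
    """One insert drawn from a source, applying class-specific end
    heterogeneity and error channels."""
    seq = source.sequence
    if source.kind == "mirna":
        hairpin = source.extra["hairpin"]
        start, end = source.extra["arm"]
        delta = _choice(rng, config.isomir_end_probs)
        end = min(max(end + delta, start + 15), len(hairpin))
        seq = hairpin[start - 1 : end]
    elif source.kind == "trailer":
        trailer = source.extra["trailer"]
        delta = _choice(rng, config.trailer_end_probs)
        end = min(max(len(trailer) + delta, 16), len(trailer) + 0)
        seq = trailer[:end]
        if rng.random() < config.trailer_offset2_rate and len(seq) > 16:
            seq = seq[1:]
    elif source.kind == "trna":
        gene = source.extra["gene"]
        roll = rng.random()
        if roll < config.cca_fragment_rate:
            k = int(rng.integers(14, 21))
            seq = gene[-k:] + "CCA"
        elif roll < config.cca_fragment_rate + config.one_mismatch_rate:
            pos = int(rng.integers(0, len(seq)))
            alt = rng.choice([b for b in BASES if b != seq[pos]])
            seq = seq[:pos] + alt + seq[pos + 1 :]
            return seq  # mismatch read: no further modification
    if source.kind in ("mirna", "plain") and rng.random() < config.untemplated_rate:
        # untemplated additions violate the genome beyond the source 3' end
        nxt = ""
        if source.kind == "mirna":
            hairpin = source.extra["hairpin"]
            idx = hairpin.find(seq) + len(seq)
            nxt = hairpin[idx : idx + 1]
        else:
            pos = genome.get("chr1", "").find(seq)
            if pos != -1:
                nxt = genome["chr1"][pos + len(seq) : pos + len(seq) + 1]
        tail = _untemplated_tail(rng, config, nxt)
        seq = (seq + tail)[: MAX_LEN]
    return seq


def simulate_libraries(
    bundle: ReferenceBundle,
    scaffold: dict,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sources: list[Source] | None = None,
) -> tuple[dict[str, list[tuple[str, int]]], GroundTruth]:
    """Draw the paired read libraries and the per-read ground truth."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if sources is None:
        sources = _build_sources(config, bundle, scaffold, rng)

    libraries: dict[str, Counter] = {lib: Counter() for lib in config.depth}
    read_truth: Counter = Counter()
    for source in sources:
        for lib in config.depth:
            k = int(rng.poisson(source.expected[lib]))
            for _ in range(k):
                insert = _emit_insert(source, config, rng, bundle.genome)
                read = (insert + config.adapter3)[: config.read_length]
                libraries[lib][read] += 1
                read_truth[(lib, insert, source.source_id, source.true_class.value)] += 1

    # contaminants (not part of the planted truth; all should be discarded)
    for lib, depth in config.depth.items():
        for _ in range(int(rng.poisson(config.polya_rate * depth))):
            insert = "A" * int(rng.integers(20, 29))
            read = (insert + config.adapter3)[: config.read_length]
            libraries[lib][read] += 1
        for _ in range(int(rng.poisson(config.adapter5_rate * depth))):
            k5 = int(rng.integers(10, 15))
            insert = config.adapter5[-k5:] + _random_seq(rng, int(rng.integers(8, 13)))
            read = (insert + config.adapter3)[: config.read_length]
            libraries[lib][read] += 1
        for _ in range(int(rng.poisson(config.no_adapter_rate * depth))):
            libraries[lib][_random_seq(rng, config.read_length)] += 1

    out = {
        lib: sorted(counter.items()) for lib, counter in libraries.items()
    }
    truth = GroundTruth(
        sources=sources,
        read_truth=read_truth,
        trailer_truth=scaffold["trailer_truth"],
        isomir_families={
            mat_id: hp_id
            for hp_id, arms in scaffold["hairpin_arms"].items()
            for mat_id, _, _ in arms
        },
    )
    return out, truth


def simulate(config: SimConfig | None = None) -> SimulatedDataset:
    """End-to-end simulation: reference bundle plus paired libraries."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    bundle, scaffold = simulate_reference(config, rng)
    libraries, truth = simulate_libraries(bundle, scaffold, config, rng)
    return SimulatedDataset(
        config=config,
        bundle=bundle,
        trailer_regions=build_trailer_regions(bundle),
        libraries=libraries,
        truth=truth,
        mirna_catalog=scaffold["mirna_catalog"],
        hairpin_arms=scaffold["hairpin_arms"],
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the simulated dataset as plain-text files and return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genome_path = outdir / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom, seq in dataset.bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    paths["genome"] = genome_path

    refs_path = outdir / "refs.fa"
    with open(refs_path, "w") as fh:
        for ref in dataset.bundle.ref_rnas:
            fh.write(f">{ref.ref_id} class={ref.class_label.value}\n")
            for i in range(0, len(ref.sequence), 70):
                fh.write(ref.sequence[i : i + 70] + "\n")
    paths["refs"] = refs_path

    loci_path = outdir / "loci.bed"
    with open(loci_path, "w") as fh:
        for locus in dataset.bundle.trna_loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\ttRNA:{locus.name}\t0\t{locus.strand}\n"
            )
        for locus in dataset.bundle.repeat_loci:
            fh.write(
                f"{locus.chrom}\t{locus.start - 1}\t{locus.end}\trepeat:{locus.name}\t0\t{locus.strand}\n"
            )
        for model in dataset.bundle.mrna_models:
            start0 = model.exons[0][0] - 1
            end = model.exons[-1][1]
            sizes = ",".join(str(e - s + 1) for s, e in model.exons)
            offsets = ",".join(str(s - 1 - start0) for s, _ in model.exons)
            fh.write(
                f"{model.chrom}\t{start0}\t{end}\tmRNA:{model.name}\t0\t{model.strand}"
                f"\t{start0}\t{end}\t0\t{len(model.exons)}\t{sizes}\t{offsets}\n"
            )
    paths["loci"] = loci_path

    for lib, reads in dataset.libraries.items():
        read_path = outdir / f"reads_{lib}.fa"
        with open(read_path, "w") as fh:
            for i, (read, count) in enumerate(reads, 1):
                fh.write(f">{lib}{i}_x{count}\n{read}\n")
        paths[f"reads_{lib}"] = read_path

    truth_path = outdir / "truth_sources.tsv"
    with open(truth_path, "w") as fh:
        fh.write(
            "source_id\tclass\tfeature_id\tsequence\tplanted_nc\t"
            + "\t".join(f"expected_{lib}" for lib in dataset.config.depth)
            + "\n"
        )
        for s in dataset.truth.sources:
            expected = "\t".join(
                f"{s.expected[lib]:.3f}" for lib in dataset.config.depth
            )
            fh.write(
                f"{s.source_id}\t{s.true_class.value}\t{s.feature_id}\t"
                f"{s.sequence}\t{s.planted_nc:.6f}\t{expected}\n"
            )
    paths["truth_sources"] = truth_path

    reads_truth_path = outdir / "truth_reads.tsv"
    with open(reads_truth_path, "w") as fh:
        fh.write("library\tinsert\tsource_id\tclass\tcount\n")
        for (lib, insert, src, cls), count in sorted(dataset.truth.read_truth.items()):
            fh.write(f"{lib}\t{insert}\t{src}\t{cls}\t{count}\n")
    paths["truth_reads"] = reads_truth_path

    config_path = outdir / "sim_config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(dataset.config.to_dict(), fh, sort_keys=True)
    paths["config"] = config_path
    return paths
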