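"""Read cleanup and collapsing.

Raw small-RNA reads carry a ligated 3' adapter; the insert is recovered by
locating the leftmost terminal occurrence of an adapter prefix of at least
``min_overlap`` nt.  Inserts are then filtered (no adapter, poly-A artifact,
5'-adapter ligation chimera, outside the 16–30-nt window) and collapsed into
unique sequences with per-library raw counts.  All filters are sequence-only,
so FASTA input is sufficient; quality scores are ignored.
"""

from __future__ import annotations

import dataclasses
import gzip
from collections import Counter
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

MIN_LEN = 16
MAX_LEN = 30
MIN_ADAPTER_OVERLAP = 5
POLYA_FRACTION = 0.9
FIVE_PRIME_CONTAMINANT_MIN = 10

NO_ADAPTER = "no-adapter"

#: discard reason codes, in reporting order
DISCARD_REASONS = (
    "contains-N",
    "no-adapter",
    "poly-A",
    "5p-adapter",
    "too-short",
    "too-long",
)


@dataclasses.dataclass
class UniqueSeqRecord:
    """One distinct insert sequence with per-library raw counts.

    Mapping status, class label and normalized abundance are filled in by the
    downstream stages; a freshly collapsed record is unmapped and unlabelled.
    """

    sequence: str
    counts: dict[str, int]
    rpm: dict[str, float] = dataclasses.field(default_factory=dict)
    status: str = "unmapped"
    via: str | None = None
    label: object = None  # ClassLabel, assigned by the annotator
    matched_ref: str | None = None
    trimmed_tail: str = ""

    @property
    def effective_seq(self) -> str:
        """The genome-anchored part of the sequence: the whole sequence,
        or the retained prefix when a 3' untemplated tail was trimmed."""
        if self.trimmed_tail:
            return self.sequence[: len(self.sequence) - len(self.trimmed_tail)]
        return self.sequence

    def total_count(self) -> int:
        return sum(self.counts.values())


def trim_3prime_adapter(
    read: str, adapter: str, min_overlap: int = MIN_ADAPTER_OVERLAP
) -> str | None:
    """Return the insert preceding the 3' adapter, or None if no adapter.

    A match qualifies when a prefix of the adapter of length >= ``min_overlap``
    occurs in the read and either extends to the read's 3' end or is the full
    adapter.  The leftmost qualifying match wins, yielding the shortest
    credible insert.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = read.upper().replace("U", "T")
    adapter = adapter.upper().replace("U", "T")
    n, m = len(read), len(adapter)
    best: int | None = None
    # full-adapter occurrence anywhere
    pos = read.find(adapter)
    if pos != -1:
        best = pos
    # terminal occurrence of an adapter prefix
    for start in range(0, n - min_overlap + 1):
        if best is not None and start >= best:
            break
        plen = n - start
        if plen > m:
            continue  # cannot reach the read end with a prefix this long
        if read[start:] == adapter[:plen]:
            best = start
            break
    if best is None:
        return None
    return read[:best]


def filter_insert(
    insert: str,
    five_prime_adapter: str = "",
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    polya_fraction: float = POLYA_FRACTION,
) -> str:
    """Classify a trimmed insert: returns 'keep' or a discard reason code.

    Discards poly-A artifacts (>= ``polya_fraction`` adenine), 5'-adapter
    ligation chimeras (insert starting with >=10 nt of the 5' adapter's 3'
    end) and inserts outside the [min_len, max_len] window.
    """
    if not insert:
        return "too-short"
    if "N" in insert:
        return "contains-N"
    if insert.count("A") / len(insert) >= polya_fraction:
        return "poly-A"
    if five_prime_adapter:
        a5 = five_prime_adapter.upper().replace("U", "T")
        limit = min(len(a5), len(insert))
        for k in range(limit, FIVE_PRIME_CONTAMINANT_MIN - 1, -1):
            if insert[:k] == a5[-k:]:
                return "5p-adapter"
    if len(insert) < min_len:
        return "too-short"
    if len(insert) > max_len:
        return "too-long"
    return "keep"


@dataclasses.dataclass
class PreprocessResult:
    records: list[UniqueSeqRecord]
    n_input: dict[str, int]
    n_kept: dict[str, int]
    discard_log: dict[str, Counter]

    def conservation_ok(self) -> bool:
        for lib, total in self.n_input.items():
            discarded = sum(self.discard_log.get(lib, Counter()).values())
            if self.n_kept.get(lib, 0) + discarded != total:
                return False
        return True


def _open_maybe_gz(path: str | Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def iter_reads(path: str | Path) -> Iterator[tuple[str, int]]:
    """Yield (sequence, count) from FASTA/FASTQ/TSV read files.

    FASTA headers of the form ``name_x<count>`` (collapsed-read convention)
    contribute <count> reads; otherwise each record counts once.  A ``.tsv``
    file is two columns: sequence, count.
    """
    spath = str(path)
    base = spath[:-3] if spath.endswith(".gz") else spath
    if base.endswith((".tsv", ".txt")):
        with _open_maybe_gz(path) as handle:
            for line in handle:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                seq, count = line.split("\t")[:2]
                yield seq.upper().replace("U", "T"), int(count)
        return
    fmt = "fastq" if base.endswith((".fastq", ".fq")) else "fasta"
    with _open_maybe_gz(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            count = 1
            name = rec.id
            if "_x" in name:
                tail = name.rsplit("_x", 1)[1]
                if tail.isdigit():
                    count = int(tail)
            yield str(rec.seq).upper().replace("U", "T"), count


def preprocess_libraries(
    libraries: dict[str, Iterable[tuple[str, int]]],
    adapter3: str,
    adapter5: str = "",
    min_overlap: int = MIN_ADAPTER_OVERLAP,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    skip_trim: bool = False,
) -> PreprocessResult:
    """Trim, filter and collapse reads from one or more libraries.

    ``libraries`` maps a library id (e.g. ``nuclear``/``cytoplasmic``) to an
    iterable of (read sequence, multiplicity).  With ``skip_trim`` the input
    is taken as already adapter-trimmed inserts.
    """
    kept: dict[str, Counter] = {lib: Counter() for lib in libraries}
    n_input = {lib: 0 for lib in libraries}
    n_kept = {lib: 0 for lib in libraries}
    discard_log: dict[str, Counter] = {lib: Counter() for lib in libraries}
    for lib, reads in libraries.items():
        for seq, count in reads:
            n_input[lib] += count
            if "N" in seq:
                discard_log[lib]["contains-N"] += count
                continue
            if skip_trim:
                insert = seq
            else:
                insert = trim_3prime_adapter(seq, adapter3, min_overlap)
                if insert is None:
                    discard_log[lib]["no-adapter"] += count
                    continue
            verdict = filter_insert(insert, adapter5, min_len, max_len)
            if verdict != "keep":
                discard_log[lib][verdict] += count
                continue
            kept[lib][insert] += count
            n_kept[lib] += count
    sequences = sorted(set().union(*(c.keys() for c in kept.values())) if kept else [])
    records = [
        UniqueSeqRecord(seq, {lib: kept[lib].get(seq, 0) for lib in libraries})
        for seq in sequences
    ]
    return PreprocessResult(records, n_input, n_kept, discard_log)


def write_collapsed_tsv(path: str | Path, result: PreprocessResult) -> None:
    libs = sorted(result.n_input)
    with open(path, "w") as handle:
        handle.write("sequence\t" + "\t".join(libs) + "\n")
        for rec in result.records:
            counts = "\t".join(str(rec.counts.get(lib, 0)) for lib in libs)
            handle.write(f"{rec.sequence}\t{counts}\n")
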