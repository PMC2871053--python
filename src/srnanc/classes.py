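"""RNA class vocabulary for the annotation cascade.

Small RNAs are assigned to exactly one class by an ordered,
remove-on-first-match cascade: a sequence matching an earlier class never
reaches a later one.  The order below IS the cascade order; ``GENOMIC_REPEAT``
and ``UNKNOWN`` are terminal fallbacks assigned from genomic context, never
from reference-sequence matches.
"""

from __future__ import annotations

import enum


class ClassLabel(str, enum.Enum):
    """Ordered small-RNA class vocabulary.

    Iteration order equals annotation priority (highest first).
    """

    MIRNA = "miRNA"
    MITO = "mitochondrial_RNA"
    RRNA = "rRNA"
    ITS = "ITS"
    ETS = "ETS"
    HACA_SNORNA = "HACA_snoRNA"
    CD_SNORNA = "CD_snoRNA"
    SCARNA = "scaRNA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    RNASEP = "RNaseP"
    SRP_RNA = "SRP_RNA"
    XIST = "Xist"
    RN7SK = "7SK"
    H19 = "H19"
    VRNA = "vRNA"
    HY_RNA = "hY_RNA"
    RNASEMRP = "RNaseMRP"
    MRNA = "mRNA"
    TRNA_TRAILER = "tRNA_trailer"
    GENOMIC_REPEAT = "genomic_repeat"
    UNKNOWN = "unknown"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Cascade order: sequence-reference classes tried first, in this order.
CASCADE_ORDER: tuple[ClassLabel, ...] = tuple(ClassLabel)

#: Classes matched against reference sequences (everything before the trailer
#: stage); the trailer stage uses genomic trailer regions and the last two
#: labels use genomic context.
SEQUENCE_CLASSES: tuple[ClassLabel, ...] = CASCADE_ORDER[: CASCADE_ORDER.index(ClassLabel.MRNA) + 1]

#: Terminal labels never carried by reference sequences.
FALLBACK_CLASSES: frozenset[ClassLabel] = frozenset(
    {ClassLabel.GENOMIC_REPEAT, ClassLabel.UNKNOWN}
)

#: Reporting roll-up of low-abundance housekeeping RNAs (a presentation
#: grouping only; the cascade always uses the individual classes).
MISC_RNA_CLASSES: frozenset[ClassLabel] = frozenset(
    {
        ClassLabel.RN7SK,
        ClassLabel.VRNA,
        ClassLabel.RNASEMRP,
        ClassLabel.RNASEP,
        ClassLabel.XIST,
        ClassLabel.H19,
    }
)

#: Human-readable names used in report tables.
DISPLAY_NAMES: dict[ClassLabel, str] = {
    ClassLabel.MIRNA: "miRNA",
    ClassLabel.MITO: "mitochondrial RNA",
    ClassLabel.RRNA: "rRNA",
    ClassLabel.ITS: "internal transcribed spacer of rRNA",
    ClassLabel.ETS: "external transcribed spacer of rRNA",
    ClassLabel.HACA_SNORNA: "box H/ACA snoRNA",
    ClassLabel.CD_SNORNA: "box C/D snoRNA",
    ClassLabel.SCARNA: "scaRNA",
    ClassLabel.TRNA: "tRNA",
    ClassLabel.SNRNA: "snRNA",
    ClassLabel.RNASEP: "RNaseP RNA",
    ClassLabel.SRP_RNA: "SRP RNA",
    ClassLabel.XIST: "Xist",
    ClassLabel.RN7SK: "7SK RNA",
    ClassLabel.H19: "H19",
    ClassLabel.VRNA: "vRNA",
    ClassLabel.HY_RNA: "Y RNA",
    ClassLabel.RNASEMRP: "RNaseMRP RNA",
    ClassLabel.MRNA: "mRNA",
    ClassLabel.TRNA_TRAILER: "tRNA 3' trailer",
    ClassLabel.GENOMIC_REPEAT: "genomic repeat",
    ClassLabel.UNKNOWN: "unknown",
}


def parse_class_label(token: str) -> ClassLabel:
    """Parse a ``class=`` token from a FASTA header into a :class:`ClassLabel`.

    Raises
    ------
    ValueError
        If the token is not in the vocabulary or names a fallback label,
        which reference sequences may never carry.
    """
    try:
        label = ClassLabel(token)
    except ValueError:
        valid = ", ".join(c.value for c in SEQUENCE_CLASSES)
        raise ValueError(
            f"unknown RNA class label {token!r}; expected one of: {valid}"
        ) from None
    if label in FALLBACK_CLASSES or label is ClassLabel.TRNA_TRAILER:
        raise ValueError(
            f"class {token!r} is assigned from genomic context and cannot "
            "label a reference sequence"
        )
    return label
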