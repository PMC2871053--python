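"""Published worked-example inputs from a nuclear/cytoplasmic sRNA study.

These values come from a deep-sequencing study of nuclear and cytoplasmic
small-RNA fractions of the human 5-8F nasopharyngeal carcinoma cell line:
per-class raw read counts with the stated library totals, the top
nuclear-enriched miRNAs with their representative-isomiR sequences and
per-library RPM, and the five most abundant human tRNA 3' trailers with
their per-library RPM.  Only the *inputs* are stored here — raw counts,
RPM values and sequences; derived quantities (N/C ratios, composition
percentages, hexanucleotides, U-tail calls) are always recomputed by the
package at run time.
"""

from __future__ import annotations

#: stated per-library totals of the mapped data sets (raw reads)
LIBRARY_TOTALS = {"nuclear": 5_321_867, "cytoplasmic": 4_079_549}

#: per-class raw read counts (non-normalized), per library
CLASS_COUNTS: dict[str, dict[str, int]] = {
    "box C/D snoRNA": {"nuclear": 174_833, "cytoplasmic": 3_132},
    "external transcribed spacer of rRNA": {"nuclear": 40_913, "cytoplasmic": 3_266},
    "box H/ACA snoRNA": {"nuclear": 2_780, "cytoplasmic": 353},
    "scaRNA": {"nuclear": 14_027, "cytoplasmic": 5_175},
    "miRNA": {"nuclear": 4_208_498, "cytoplasmic": 2_156_495},
    "internal transcribed spacer of rRNA": {"nuclear": 3_225, "cytoplasmic": 1_879},
    "mRNA": {"nuclear": 117_038, "cytoplasmic": 74_840},
    "snRNA": {"nuclear": 13_881, "cytoplasmic": 11_140},
    "SRP RNA": {"nuclear": 2_919, "cytoplasmic": 3_256},
    "rRNA": {"nuclear": 237_973, "cytoplasmic": 367_524},
    "Y RNA": {"nuclear": 8_033, "cytoplasmic": 22_629},
    "tRNA": {"nuclear": 111_904, "cytoplasmic": 476_974},
    "mitochondrial RNA": {"nuclear": 33_690, "cytoplasmic": 311_742},
    "tRNA 3' trailer": {"nuclear": 6_295, "cytoplasmic": 180_657},
    "genomic repeat": {"nuclear": 64_527, "cytoplasmic": 117_314},
    "miscRNA": {"nuclear": 1_119, "cytoplasmic": 1_281},
    "unknown": {"nuclear": 280_215, "cytoplasmic": 341_913},
}

#: top nuclear-enriched miRNAs: (miRNA, representative isomiR sequence,
#: nuclear RPM, cytoplasmic RPM), ordered by published rank
MIRNA_EXAMPLES: list[tuple[str, str, float, float]] = [
    ("hsa-miR-32", "UAUUGCACAUUACUAAGUUGCAU", 15.6, 2.5),
    ("hsa-miR-148a", "UCAGUGCACUACAGAACUUUGU", 41.9, 8.6),
    ("hsa-miR-29b", "UAGCACCAUUUGAAAUCAGUGUU", 355.3, 78.2),
    ("hsa-miR-148b", "UCAGUGCAUCACAGAACUUUGU", 145.1, 39.0),
    ("hsa-miR-1", "UGGAAUGUAAAGAAGUAUGUAU", 43.4, 12.5),
    ("hsa-miR-1285", "UCUGGGCAACAAAGUGAGACCU", 19.0, 5.9),
    ("hsa-miR-652", "AAUGGCGCCACUAGGGUUGUG", 10.7, 3.7),
    ("hsa-miR-29c", "UAGCACCAUUUGAAAUCGGUUA", 222.7, 78.4),
    ("hsa-miR-15b", "UAGCAGCACAUCAUGGUUUACA", 52.6, 19.1),
    ("hsa-miR-135b", "UAUGGCUUUUCAUUCCUAUGUGA", 13.5, 5.1),
]

#: five most abundant human tRNA 3' trailers: (tRNA, representative
#: cytoplasmic isotrailer sequence, cytoplasmic RPM, nuclear RPM)
TRAILER_EXAMPLES: list[tuple[str, str, float, float]] = [
    ("tRNA-Ser (TGA)", "GAAGCGGGUGCUCUUAUUU", 39_889.0, 264.2),
    ("tRNA-Arg (ACG)", "GUGUAAGCAGGGUCGUUUU", 1_176.6, 196.0),
    ("tRNA-Ala (CGC)", "AGGCGAUCACGUAGAUUUUGUUUA", 853.0, 203.3),
    ("tRNA-Thr (CGT)", "AGGGUGUGCGUGUUUUUUU", 349.3, 144.7),
    ("tRNA-Phe (GAA)", "GAGAGCGCUCGGUUUUU", 316.9, 23.7),
]
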