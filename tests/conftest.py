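import warnings

import pytest

import srnanc
from srnanc.classes import ClassLabel
from srnanc.reference import GeneModel, Locus, RefRNA, ReferenceBundle
from srnanc.simulate import SimConfig


@pytest.fixture
def tiny_bundle():
    """Hand-built two-contig bundle with one feature of each locus kind.

    chr1 layout (1-based): tRNA gene at 11..40, its trailer region at 41..80,
    a minus-strand tRNA at 101..130, a repeat at 151..170, and a two-exon
    gene with exons 201..230 and 261..290.
    """
    import numpy as np

    rng = np.random.default_rng(42)
    chr1 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=400))
    chr2 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=120))
    genome = {"chr1": chr1, "chr2": chr2}
    trna_plus = Locus("chr1", 11, 40, "+", "tRNA-A")
    trna_minus = Locus("chr1", 101, 130, "-", "tRNA-B")
    model = GeneModel("geneX", "chr1", "+", ((201, 230), (261, 290)))
    refs = [
        RefRNA(ClassLabel.TRNA, "tRNA-A", chr1[10:40]),
        RefRNA(ClassLabel.TRNA, "tRNA-B", srnanc.reference.revcomp(chr1[100:130])),
        RefRNA(ClassLabel.MIRNA, "mir-1", chr1[300:360]),
        RefRNA(ClassLabel.RRNA, "rrna-unit", chr2),
        RefRNA(ClassLabel.MRNA, "geneX", chr1[200:230] + chr1[260:290]),
    ]
    bundle = ReferenceBundle(
        genome=genome,
        ref_rnas=refs,
        trna_loci=[trna_plus, trna_minus],
        mrna_models=[model],
        repeat_loci=[Locus("chr1", 151, 170, "+", "repFam1")],
    )
    bundle.validate()
    return bundle


@pytest.fixture(scope="session")
def sim_dataset():
    """Default-condition simulation at reduced depth for unit tests."""
    cfg = SimConfig(seed=3, depth={"nuclear": 20_000, "cytoplasmic": 20_000})
    return srnanc.simulate(cfg)


@pytest.fixture(scope="session")
def sim_result(sim_dataset):
    ds = sim_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return srnanc.run_on_libraries(
            ds.libraries,
            ds.bundle,
            ds.config.adapter3,
            ds.config.adapter5,
            trailer_regions=ds.trailer_regions,
            mirna_catalog=ds.mirna_catalog,
            hairpin_arms=ds.hairpin_arms,
        )


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-heterogeneity study conditions: no end jitter, no untemplated
    additions, no CCA fragments, no mismatch reads; full depth."""
    cfg = SimConfig(
        seed=11,
        isomir_end_probs={0: 1.0},
        trailer_end_probs={0: 1.0},
        trailer_offset2_rate=0.0,
        untemplated_rate=0.0,
        cca_fragment_rate=0.0,
        one_mismatch_rate=0.0,
        depth={"nuclear": 100_000, "cytoplasmic": 100_000},
    )
    return srnanc.simulate(cfg)


@pytest.fixture(scope="session")
def clean_result(clean_dataset):
    ds = clean_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return srnanc.run_on_libraries(
            ds.libraries,
            ds.bundle,
            ds.config.adapter3,
            ds.config.adapter5,
            trailer_regions=ds.trailer_regions,
            mirna_catalog=ds.mirna_catalog,
            hairpin_arms=ds.hairpin_arms,
        )
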