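"""Exact all-hits mapping, rescue stages and untemplated-tail trimming."""

import numpy as np
import pytest

from srnanc.mapper import (
    AuxReferences,
    GenomeIndex,
    map_records,
    naive_map_exact_all,
    rescue,
    trim_untemplated_3prime,
)
from srnanc.pipeline import build_aux
from srnanc.preprocess import UniqueSeqRecord
from srnanc.reference import revcomp


def _random_genome(rng, sizes):
    return {
        f"chr{i + 1}": "".join("ACGT"[b] for b in rng.integers(0, 4, size=size))
        for i, size in enumerate(sizes)
    }


class TestExactAllHits:
    def test_planted_single_hit(self):
        rng = np.random.default_rng(0)
        genome = _random_genome(rng, [500])
        query = genome["chr1"][100:120]  # 1-based 101..120
        index = GenomeIndex(genome)
        hits = index.map_exact_all(query)
        forward = [h for h in hits if h.strand == "+"]
        assert [(h.chrom, h.start) for h in forward] == [("chr1", 101)]

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        genome = _random_genome(rng, [500])
        query = genome["chr1"][200:222]
        index = GenomeIndex(genome)
        plus = index.map_exact_all(query)
        minus = index.map_exact_all(revcomp(query))
        assert {(h.chrom, h.start) for h in plus} == {(h.chrom, h.start) for h in minus}
        assert {h.strand for h in minus if h.start == 201} == {"-"}

    def test_multi_locus_count_matches_oracle(self):
        rng = np.random.default_rng(2)
        genome = _random_genome(rng, [2000])
        insert = genome["chr1"][50:70]
        # plant the same 20-mer at two more loci
        chr1 = genome["chr1"]
        chr1 = chr1[:500] + insert + chr1[520:]
        chr1 = chr1[:1000] + insert + chr1[1020:]
        genome = {"chr1": chr1}
        index = GenomeIndex(genome)
        hits = index.map_exact_all(insert)
        oracle = naive_map_exact_all(insert, genome)
        assert hits == oracle
        assert sum(1 for h in hits if h.strand == "+") == 3

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_genomes(self, seed):
        """Hit sets identical to the naive both-strand scan."""
        rng = np.random.default_rng(seed)
        genome = _random_genome(rng, [int(rng.integers(1000, 5000)), 400])
        index = GenomeIndex(genome)
        for _ in range(25):
            if rng.random() < 0.7:  # planted query
                chrom = rng.choice(sorted(genome))
                length = int(rng.integers(16, 31))
                start = int(rng.integers(0, len(genome[chrom]) - length))
                query = genome[chrom][start : start + length]
                if rng.random() < 0.5:
                    query = revcomp(query)
            else:  # random query, usually absent
                query = "".join("ACGT"[b] for b in rng.integers(0, 4, size=20))
            assert index.map_exact_all(query) == naive_map_exact_all(query, genome)


class TestRescue:
    @pytest.fixture
    def aux(self):
        rng = np.random.default_rng(3)
        trna = "".join("ACGT"[b] for b in rng.integers(0, 4, size=72))
        rrna = "".join("ACGT"[b] for b in rng.integers(0, 4, size=300))
        junction = "".join("ACGT"[b] for b in rng.integers(0, 4, size=58))
        return AuxReferences(
            rrna_units=[("rrna-unit", rrna)],
            junctions=[("geneX|junction1", junction)],
            cca_trnas=[("tRNA-A", trna + "CCA")],
            trna_refs=[("tRNA-A", trna)],
        ), trna, rrna, junction

    def test_cca_tail_fragment(self, aux):
        refs, trna, _, _ = aux
        read = trna[-17:] + "CCA"  # 20 nt ending in untemplated CCA
        hit = rescue(read, refs)
        assert hit is not None and hit.via == "tRNA-CCA"

    def test_junction_spanning_read(self, aux):
        refs, _, _, junction = aux
        read = junction[21:37]  # spans the exon boundary by 8 nt each side
        hit = rescue(read, refs)
        assert hit is not None and hit.via == "junction"

    def test_rrna_takes_priority(self, aux):
        refs, _, rrna, _ = aux
        hit = rescue(rrna[100:120], refs)
        assert hit is not None and hit.via == "rRNA"

    def test_one_mismatch_rescued_two_rejected(self, aux):
        refs, trna, _, _ = aux
        frag = trna[10:30]

        def mutate(seq, pos):
            alt = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]]
            return seq[:pos] + alt + seq[pos + 1 :]

        one_mm = mutate(frag, 9)
        hit = rescue(one_mm, refs)
        assert hit is not None and hit.via == "tRNA-1mm"
        two_mm = mutate(one_mm, 14)
        assert rescue(two_mm, refs) is None

    def test_one_mismatch_agrees_with_alignment_enumeration(self, aux):
        """Oracle: enumerate every offset and count substitutions."""
        refs, trna, _, _ = aux
        rng = np.random.default_rng(4)
        for _ in range(50):
            length = int(rng.integers(16, 25))
            start = int(rng.integers(0, len(trna) - length))
            frag = list(trna[start : start + length])
            n_mut = int(rng.integers(0, 3))
            for pos in rng.choice(length, size=n_mut, replace=False):
                frag[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[frag[pos]]
            query = "".join(frag)
            oracle = any(
                sum(a != b for a, b in zip(query, trna[off : off + length])) == 1
                for off in range(len(trna) - length + 1)
            )
            hit = rescue(query, refs)
            got_1mm = hit is not None and hit.via == "tRNA-1mm"
            if hit is None or hit.via == "tRNA-1mm":
                assert got_1mm == oracle

    def test_rescue_stage_order_ablation(self, sim_dataset):
        """Disabling a later stage never changes earlier-stage outcomes."""
        ds = sim_dataset
        aux = build_aux(ds.bundle)
        stages = ("rRNA", "junction", "tRNA-CCA", "tRNA-1mm")
        # collect sequences rescued at each stage under the full cascade
        records = [
            UniqueSeqRecord(seq, {"nuclear": 1})
            for seq in {
                insert
                for (_, insert, _, _) in ds.truth.read_truth
                if 16 <= len(insert) <= 30
            }
        ]
        index = GenomeIndex(ds.bundle.genome)
        full = map_records(
            [UniqueSeqRecord(r.sequence, dict(r.counts)) for r in records],
            ds.bundle, aux, index=index,
        )
        full_via = {r.sequence: r.via for r in full.records}
        for k, removed in enumerate(stages):
            ablated = map_records(
                [UniqueSeqRecord(r.sequence, dict(r.counts)) for r in records],
                ds.bundle, aux, index=index,
                enabled_rescues=tuple(s for s in stages if s != removed),
            )
            for rec in ablated.records:
                if full_via[rec.sequence] in stages[:k]:
                    assert rec.via == full_via[rec.sequence]


class TestUntemplatedTrimming:
    @pytest.fixture
    def indexed_genome(self):
        rng = np.random.default_rng(5)
        genome = _random_genome(rng, [3000])
        return genome, GenomeIndex(genome), rng

    def test_planted_tail_recovered(self, indexed_genome):
        genome, index, _ = indexed_genome
        prefix = genome["chr1"][100:120]  # 20 genomic nt
        nxt = genome["chr1"][120]
        tail = "TT" if nxt != "T" else "AA"
        result = trim_untemplated_3prime(prefix + tail, index)
        assert result == (prefix, tail)

    def test_sixteen_nt_prefix_rejected(self, indexed_genome):
        """A longest genomic prefix of 16 nt is below the 17-nt floor."""
        genome, index, _ = indexed_genome
        prefix = genome["chr1"][200:216]  # 16 nt
        nxt = genome["chr1"][216]
        tail = ("GG" if nxt != "G" else "CC")
        assert trim_untemplated_3prime(prefix + tail, index) is None

    def test_fully_genomic_not_applicable(self, indexed_genome):
        genome, index, _ = indexed_genome
        seq = genome["chr1"][300:322]
        assert index.map_exact_all(seq)  # precondition: already mapped

    def test_agrees_with_all_prefix_brute_force(self, indexed_genome):
        """Oracle: test every prefix length by brute-force genome scan."""
        genome, index, rng = indexed_genome

        def oracle(seq):
            best = None
            for length in range(16, len(seq) + 1):
                if naive_map_exact_all(seq[:length], genome):
                    best = length
            if best is None or best < 17 or best == len(seq):
                return None
            return seq[:best], seq[best:]

        for _ in range(100):
            length = int(rng.integers(17, 28))
            start = int(rng.integers(0, 2900))
            prefix = genome["chr1"][start : start + length]
            tail_len = int(rng.integers(0, 4))
            tail = "".join(str(rng.choice(list("TA"))) for _ in range(tail_len))
            seq = prefix + tail
            if index.map_exact_all(seq):
                continue  # fully genomic by chance: trimming not applicable
            assert trim_untemplated_3prime(seq, index) == oracle(seq)

    def test_trimmed_prefix_maps_original_does_not(self, sim_dataset, sim_result):
        index = GenomeIndex(sim_dataset.bundle.genome)
        trimmed = [r for r in sim_result.mapping.records if r.via == "trimmed"]
        assert trimmed, "simulation should produce untemplated-tail reads"
        for rec in trimmed:
            assert index.map_exact_all(rec.effective_seq)
            assert not index.map_exact_all(rec.sequence)
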