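import math

import numpy as np
import pytest

from vectortrace.dna import gc_fraction, revcomp
from vectortrace.synthetic_data import (
    CellPopulationSpec,
    ErrorModel,
    Fragment,
    apply_errors,
    cas9_enrich,
    fragment_genome,
    fragment_intervals,
    make_toy_genome,
    simulate_amplicon_reads,
    simulate_long_reads,
)


class TestToyGenome:
    def test_deterministic_for_fixed_seed(self):
        g1, l1 = make_toy_genome(2, [20_000, 12_000], 0, seed=1)
        g2, l2 = make_toy_genome(2, [20_000, 12_000], 0, seed=1)
        assert g1 == g2 and l1 == l2
        g3, _ = make_toy_genome(2, [20_000, 12_000], 0, seed=2)
        assert g3 != g1

    def test_planted_protospacer_retrievable(self):
        genome, locus = make_toy_genome(1, [30_000], 0, seed=3)
        start = locus.cut_site - 17
        seq = genome[locus.chrom]
        assert seq[start:start + 20] == locus.protospacer
        assert seq[start + 20:start + 23] == locus.pam
        assert locus.pam[1:] == "GG"

    def test_gc_fraction_near_half(self):
        genome, _ = make_toy_genome(1, [100_000], 0, seed=4)
        assert 0.47 <= gc_fraction(genome["chr1"]) <= 0.53

    def test_locus_must_fit(self):
        with pytest.raises(ValueError):
            make_toy_genome(1, [5_000], 0, seed=1)


class TestFragmentation:
    def test_fragments_tile_molecule(self, rng):
        from vectortrace.dna import random_dna

        mol = random_dna(50_000, rng)
        frags = fragment_genome(mol, 2_000, seed=5)
        assert "".join(frags) == mol

    def test_mean_fragment_length(self, rng):
        lengths = []
        for seed in range(8):
            ivs = fragment_intervals(1_000_000, 10_000, np.random.default_rng(seed))
            lengths += [e - s for s, e in ivs]
        assert len(lengths) >= 50
        assert abs(np.mean(lengths) - 10_000) / 10_000 < 0.2

    def test_single_fragment_probability(self):
        # P(no breakpoint) = exp(-L/mean) for a Poisson process
        L, mean = 1_000, 5_000
        singles = sum(
            len(fragment_intervals(L, mean, np.random.default_rng(seed))) == 1
            for seed in range(400)
        )
        p = math.exp(-L / mean)
        sigma = math.sqrt(p * (1 - p) / 400)
        assert abs(singles / 400 - p) < 4 * sigma


class TestCas9Enrichment:
    def _fragments(self, n=2000, flen=100):
        return [Fragment(0, i * flen, (i + 1) * flen) for i in range(n)]

    def test_no_enrichment_limit_is_independent(self, rng):
        # at capture_bias=1 every candidate piece (a cut half or an uncut
        # fragment) is retained with the same probability p_cut
        from scipy.stats import chi2_contingency

        frags = self._fragments()
        # every 10th fragment is cut at its centre, yielding two pieces
        sites = [i * 1000 + 50 for i in range(0, 200)]
        retained = cas9_enrich(frags, {0: sites}, capture_bias=1.0, rng=rng, p_cut=0.5)
        n_overlap_src = sum(1 for f in frags if any(f.start < s < f.end for s in sites))
        trials = {True: 2 * n_overlap_src, False: len(frags) - n_overlap_src}
        kept = {True: 0, False: 0}
        for f in retained:
            kept[f.cut_left or f.cut_right] += 1
        table = [
            [kept[True], trials[True] - kept[True]],
            [kept[False], trials[False] - kept[False]],
        ]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_enriched_fraction_dominates_at_default_bias(self, rng):
        frags = self._fragments()
        sites = [i * 1000 + 50 for i in range(0, 200)]  # 10% of fragments overlap
        retained = cas9_enrich(frags, {0: sites}, capture_bias=20.0, rng=rng, p_cut=0.9)
        cut = sum(1 for f in retained if f.cut_left or f.cut_right)
        assert cut / len(retained) > 0.5

    def test_split_at_exact_cut_coordinate(self, rng):
        frag = Fragment(0, 1000, 2000)
        retained = cas9_enrich([frag], {0: [1500]}, capture_bias=1.0, rng=rng, p_cut=1.0)
        assert sorted((f.start, f.end) for f in retained) == [(1000, 1500), (1500, 2000)]
        assert all(f.cut_right or f.cut_left for f in retained)


class TestErrorEngine:
    """apply_errors output must be a consistent alignment of read to source."""

    def _check_alignment(self, source, read, ops, sub_rate_zero):
        si = ri = 0
        for op, n in ops:
            if op == "M":
                if sub_rate_zero:
                    assert read[ri:ri + n] == source[si:si + n]
                si += n
                ri += n
            elif op == "I":
                ri += n
            elif op == "D":
                si += n
        assert si == len(source)
        assert ri == len(read)

    @pytest.mark.parametrize("err", [
        ErrorModel.perfect(),
        ErrorModel(0.05, 0.0, 0.0),
        ErrorModel(0.0, 0.05, 0.05),
        ErrorModel.nanopore(),
    ])
    def test_ops_reconstruct_read(self, err, rng):
        from vectortrace.dna import random_dna

        for _ in range(20):
            source = random_dna(int(rng.integers(1, 500)), rng)
            read, ops = apply_errors(source, err, rng)
            self._check_alignment(source, read, ops, err.sub_rate == 0)

    def test_substitution_rate_statistics(self, rng):
        from vectortrace.dna import random_dna

        source = random_dna(200_000, rng)
        read, ops = apply_errors(source, ErrorModel(0.02, 0.0, 0.0), rng)
        assert len(read) == len(source)
        mism = sum(1 for a, b in zip(read, source) if a != b)
        p = 0.02
        sigma = math.sqrt(p * (1 - p) * len(source))
        assert abs(mism - p * len(source)) < 3 * sigma


class TestLongReadSimulation:
    def test_noise_free_reads_match_reference_exactly(self, scenario):
        sim = simulate_long_reads(
            scenario.population, scenario.genome, scenario.vector, scenario.locus,
            ErrorModel.perfect(), 120, seed=7,
        )
        refs = dict(sim.combined.contigs)
        for read in sim.reads:
            for seg in read.truth.segments:
                expected = refs[seg.reference][seg.ref_start:seg.ref_end]
                observed = read.sequence[seg.read_start:seg.read_end]
                if seg.strand == "-":
                    observed = revcomp(observed)
                # segments may carry true indels (NHEJ molecules) but here
                # alignment ops must still be pure matches for most reads
                if all(op == "M" for op, _ in seg.ops):
                    assert observed == expected

    def test_hdr_junction_truth_coordinates(self, scenario):
        sim = simulate_long_reads(
            scenario.population, scenario.genome, scenario.vector, scenario.locus,
            ErrorModel.perfect(), 300, seed=7,
        )
        cut = scenario.locus.cut_site
        hdr_junctions = {
            (j.host_chrom, j.host_coord)
            for r in sim.reads
            for j in r.truth.junctions
            if r.truth.source_label.startswith("HDR")
        }
        assert (scenario.locus.chrom, cut) in hdr_junctions
        cdna = scenario.vector.segment("CDNA")
        polya = scenario.vector.segment("POLYA")
        vec_coords = {
            j.vector_coord
            for r in sim.reads
            for j in r.truth.junctions
            if j.host_chrom == scenario.locus.chrom
        }
        assert vec_coords <= {cdna.start, polya.end}

    def test_episome_reads_have_vector_only_truth(self, scenario):
        spec = CellPopulationSpec(
            fractions={"WT": 1.0},
            episome_copies_per_genome=5.0,
        )
        sim = simulate_long_reads(
            spec, scenario.genome, scenario.vector, scenario.locus,
            ErrorModel.perfect(), 150, seed=11,
        )
        episome_reads = [r for r in sim.reads if r.truth.source_label == "episome"]
        assert episome_reads, "expected some episomal reads at 5 copies/genome"
        for r in episome_reads:
            assert {s.reference for s in r.truth.segments} == {scenario.vector.name}
            assert not r.truth.junctions

    def test_truth_segments_partition_each_read(self, scenario):
        sim = simulate_long_reads(
            scenario.population, scenario.genome, scenario.vector, scenario.locus,
            ErrorModel.nanopore(), 150, seed=13,
        )
        for read in sim.reads:
            segs = sorted(read.truth.segments, key=lambda s: s.read_start)
            pos = 0
            for seg in segs:
                assert seg.read_start >= pos
                pos = seg.read_end
            assert pos <= len(read.sequence)

    def test_byte_identical_outputs_for_same_seed(self, scenario, tmp_path):
        def run(tag):
            sim = simulate_long_reads(
                scenario.population, scenario.genome, scenario.vector, scenario.locus,
                ErrorModel.nanopore(), 60, seed=3,
            )
            fq = tmp_path / f"{tag}.fastq"
            sam = tmp_path / f"{tag}.sam"
            sim.write_fastq(fq)
            sim.write_truth_sam(sam)
            return fq.read_bytes(), sam.read_bytes()

        assert run("a") == run("b")

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            CellPopulationSpec(fractions={"WT": 0.5, "HDR": 0.6})


class TestAmpliconSimulation:
    def test_pure_population_zero_error_reads_identical(self, scenario):
        alleles = [(a, 1.0 if a.label == "WT" else 0.0) for a in scenario.amplicon_alleles()]
        sim = simulate_amplicon_reads(alleles, None, ErrorModel.perfect(), 50, seed=2)
        wt = scenario.amplicon("WT")
        assert all(seq == wt for _, seq in sim.reads)

    def test_label_fraction_binomial(self, scenario):
        amp = scenario.amplicon_alleles()
        weights = {"WT": 0.6, "NHEJ": 0.4, "HDR": 0.0}
        sim = simulate_amplicon_reads(
            [(a, weights[a.label]) for a in amp], None, ErrorModel.perfect(), 10_000, seed=8,
        )
        frac = sim.labels.count("NHEJ") / len(sim.labels)
        sigma = math.sqrt(0.4 * 0.6 / 10_000)
        assert abs(frac - 0.4) <= 3 * sigma

    def test_zero_reads_is_not_an_error(self, scenario, tmp_path):
        amp = scenario.amplicon_alleles()
        sim = simulate_amplicon_reads([(amp[0], 1.0)], None, ErrorModel.perfect(), 0, seed=1)
        out = tmp_path / "empty.fastq"
        sim.write_fastq(out)
        assert out.read_text() == ""

    def test_bad_weights_rejected(self, scenario):
        amp = scenario.amplicon_alleles()
        with pytest.raises(ValueError, match="sum"):
            simulate_amplicon_reads([(amp[0], 0.7)], None, ErrorModel.perfect(), 10, seed=1)
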