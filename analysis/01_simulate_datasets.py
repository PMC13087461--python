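#!/usr/bin/env python
"""Generate the truth-annotated datasets for the two downstream analyses.

Builds the default scenario (toy genome with a Fancc-like locus on chr13,
AAV donor vector, ~20% HDR / ~32% NHEJ population, one clonal random
integration on chr3) and writes:

* a Cas9-enriched long-read library (FASTQ + truth SAM + truth junctions),
* an amplicon pool from the three-primer PCR products,
* the vector map, locus and combined reference used throughout.
"""

from pathlib import Path

from vectortrace.scenario import build_scenario
from vectortrace.synthetic_data import ErrorModel, simulate_amplicon_reads, simulate_long_reads

SEED = 1
N_LONG_READS = 800
N_AMPLICON_READS = 5000

# bulky read-level data goes to scratch/ (regenerated on demand);
# summary tables go to results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scen = build_scenario(SEED)
    print(f"scenario: locus {scen.locus.chrom}:{scen.locus.cut_site}, "
          f"vector {len(scen.vector.sequence)} bp, fractions {scen.population.fractions}")
    print(f"random integrations: {[(r.chrom, r.position) for r in scen.population.random_integrations]}")

    sim = simulate_long_reads(
        scen.population, scen.genome, scen.vector, scen.locus,
        ErrorModel.nanopore(), N_LONG_READS, SEED,
    )
    sim.write_fastq(OUT / "longreads.fastq")
    sim.write_truth_sam(OUT / "longreads.truth.sam")
    sim.write_truth_tsv(OUT / "longreads.truth_junctions.tsv")
    n_chimeric = sum(1 for r in sim.reads if r.truth.junctions)
    print(f"long reads: {len(sim.reads)} total, {n_chimeric} spanning a vector-host junction")

    amp = scen.amplicon_alleles()
    weights = {a.label: scen.population.fractions[a.label] for a in amp}
    pool = simulate_amplicon_reads(
        [(a, weights[a.label]) for a in amp], None, ErrorModel.amplicon(),
        N_AMPLICON_READS, SEED + 1,
    )
    pool.write_fastq(OUT / "amplicons.fastq")
    print(f"amplicon reads: {len(pool.reads)} "
          f"(labels: { {l: pool.labels.count(l) for l in sorted(set(pool.labels))} })")

    scen.vector.to_json(OUT / "vector_map.json")
    scen.vector.to_bed(OUT / "vector_map.bed")
    scen.locus.to_json(OUT / "locus.json")
    sim.combined.to_fasta(OUT / "combined_reference.fa")
    print(f"wrote datasets under {OUT}")


if __name__ == "__main__":
    main()
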