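"""Desk-scale study scenario: toy genome, donor vector, alleles, primers.

Bundles the default conditions every analysis runs under: a two/three
chromosome toy genome standing in for the mouse genome with a Fancc-like
locus on "chr13", an AAV donor carrying 1-kb homology arms, a 1.7-kb cDNA
and a 0.2-kb polyA between 145-bp ITRs, silent protospacer/PAM mutations on
the knock-in allele, a cell population with ~20% HDR and ~40% NHEJ, and a
clonal random integration on "chr3" — the qualitative outcome structure the
assays are designed to resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dna import random_dna, revcomp
from .editing_quant import PrimerSet
from .synthetic_data import CellPopulationSpec, RandomIntegration, make_toy_genome
from .vector_model import (
    AlleleModel,
    TargetLocus,
    VectorMap,
    build_hdr_allele,
    build_nhej_allele,
    build_vector_map,
    build_wt_allele,
)

#: outer primers sit 250 bp outside each homology arm; with 1-kb arms the
#: unedited outer-primer product is 2.5 kb
OUTER_OFFSET = 1250
#: donor-internal reverse primer 5' end at cassette offset 349, so the
#: HDR-specific product is 1.6 kb
CDNA_PRIMER_END = 350
PRIMER_LEN = 20

DEFAULT_SILENT_MUTATIONS = 2  # PAM-proximal protospacer mutations on the HDR allele
DEFAULT_NHEJ_DELETION = 3  # bp deleted at the cut in the NHEJ allele

#: ~20% HDR overall; NHEJ set so indels are ~40% of the non-HDR (upper-band)
#: alleles, the compartment the indel assay actually sequences
DEFAULT_FRACTIONS = {"WT": 0.48, "NHEJ": 0.32, "HDR": 0.2}


def offtarget_background_experiment(
    seed: int,
    n_sites: int = 14,
    reads_per_site: int = 2000,
    sub_rate: float = 0.002,
    window_bp: int = 5,
    genome_length: int = 100_000,
    edited_fraction: float = 0.0,
    nhej_deletion: int = 3,
):
    """Amplicon-sequence *n_sites* predicted off-target sites with
    substitution-only noise and (optionally) planted editing.

    A toy genome is seeded with mutated copies of the guide (0–4 mismatches,
    cycling) at spaced positions; candidates are then re-discovered by the
    mismatch scan, each site's amplicon is sequenced at *reads_per_site*
    with substitution-only errors, and the cut-window indel caller is run
    per site.  Returns (screen table, sites, locus).
    """
    from .offtarget_screen import (
        SiteAmplicon,
        enumerate_offtargets,
        screen_offtarget_indels,
        site_amplicon_context,
        site_key,
    )
    from .synthetic_data import ErrorModel, apply_errors, make_toy_genome

    genome, locus = make_toy_genome(1, [genome_length], 0, seed)
    rng = np.random.default_rng(seed + 7)
    flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
    seq = genome[locus.chrom]
    for i in range(n_sites):
        mm = i % 5
        offsets = sorted(rng.choice(20, size=mm, replace=False)) if mm else []
        copy = list(locus.protospacer)
        for o in offsets:
            copy[int(o)] = flip[copy[int(o)]]
        pos = 2000 + 3000 * i
        seq = seq[:pos] + "".join(copy) + "AGG" + seq[pos + 23:]
    genome[locus.chrom] = seq
    sites = enumerate_offtargets(
        genome, locus.protospacer, 4, on_target=(locus.chrom, locus.cut_site - 17, "+")
    )[:n_sites]
    err = ErrorModel(sub_rate, 0.0, 0.0)
    amplicons = {}
    for i, site in enumerate(sites):
        ref, cut = site_amplicon_context(genome, site)
        n_edit = int(round(edited_fraction * reads_per_site))
        reads = []
        for k in range(reads_per_site):
            if k < n_edit:
                template = ref[:cut - nhej_deletion] + ref[cut:]
            else:
                template = ref
            read, _ = apply_errors(template, err, rng)
            reads.append((f"s{i}r{k}", read))
        amplicons[site_key(site)] = SiteAmplicon(ref, cut, reads)
    table = screen_offtarget_indels(sites, amplicons, window_bp=window_bp)
    return table, sites, locus


def design_primer_set(locus: TargetLocus, genome: dict[str, str], cassette: str) -> PrimerSet:
    """Three-primer set with the study's product geometry (2.5 kb / 1.6 kb)."""
    c = locus.cut_site
    host = genome[locus.chrom]
    p_out5 = host[c - OUTER_OFFSET:c - OUTER_OFFSET + PRIMER_LEN]
    p_out3 = revcomp(host[c + OUTER_OFFSET - PRIMER_LEN:c + OUTER_OFFSET])
    p_cdna = revcomp(cassette[CDNA_PRIMER_END - PRIMER_LEN:CDNA_PRIMER_END])
    return PrimerSet(p_out5=p_out5, p_out3=p_out3, p_cdna=p_cdna)


def default_silent_mutations(locus: TargetLocus, n: int = DEFAULT_SILENT_MUTATIONS) -> list[tuple[int, str]]:
    """PAM-proximal protospacer substitutions (offsets 18, 19, ...)."""
    muts = []
    for offset in range(19, 19 - n, -1):
        orig = locus.protospacer[offset]
        muts.append((offset, {"A": "G", "G": "A", "C": "T", "T": "C"}[orig]))
    return muts


@dataclass
class Scenario:
    """Everything the two emulated experiments need, generated from one seed."""

    genome: dict[str, str]
    locus: TargetLocus
    vector: VectorMap
    alleles: dict[str, AlleleModel]
    primers: PrimerSet
    population: CellPopulationSpec
    seed: int
    amplicon_regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def cassette(self) -> str:
        return self.vector.segment_sequence("CDNA") + self.vector.segment_sequence("POLYA")

    def amplicon(self, label: str) -> str:
        lo, hi = self.amplicon_regions[label]
        return self.alleles[label].sequence[lo:hi]

    def amplicon_alleles(self) -> list[AlleleModel]:
        """Allele models restricted to their PCR products (the sequenced bands)."""
        return [AlleleModel(label=l, sequence=self.amplicon(l)) for l in ("WT", "NHEJ", "HDR")]

    @property
    def wt_amplicon_cut(self) -> int:
        return OUTER_OFFSET  # cut site sits OUTER_OFFSET into the outer-primer product


def build_scenario(
    seed: int,
    chrom_lengths: list[int] | None = None,
    chrom_names: list[str] | None = None,
    locus_chrom_index: int = 0,
    fractions: dict[str, float] | None = None,
    episome_copies_per_genome: float = 0.0,
    n_random_integrations: int = 1,
    cdna_len: int = 1700,
    polya_len: int = 200,
    itr_len: int = 145,
) -> Scenario:
    """Assemble the default study scenario deterministically from *seed*.

    Random integrations are placed uniformly on the non-locus chromosomes
    (the first mirrors the observed extra event on "chr3") and insert the
    vector's ITR-containing 3' end, the common ITR-mediated mode.
    """
    if chrom_lengths is None:
        chrom_lengths = [100_000, 60_000] if n_random_integrations <= 1 else [100_000, 60_000, 60_000]
    if chrom_names is None:
        chrom_names = (["chr13", "chr3"] + [f"chr{i}" for i in range(4, 4 + len(chrom_lengths))])[
            : len(chrom_lengths)
        ]
    genome, locus = make_toy_genome(
        len(chrom_lengths), chrom_lengths, locus_chrom_index, seed, names=chrom_names
    )
    rng = np.random.default_rng(seed + 1_000_003)
    cdna = random_dna(cdna_len, rng)
    polya = random_dna(polya_len, rng)
    itr = random_dna(itr_len, rng)
    ha5 = genome[locus.chrom][locus.ha5_interval[0]:locus.ha5_interval[1]]
    ha3 = genome[locus.chrom][locus.ha3_interval[0]:locus.ha3_interval[1]]
    vector = build_vector_map(ha5=ha5, cdna=cdna, polya=polya, ha3=ha3, itr=itr)

    wt = build_wt_allele(locus, genome)
    c = locus.cut_site
    nhej = build_nhej_allele(
        locus, genome, (c - DEFAULT_NHEJ_DELETION, genome[locus.chrom][c - DEFAULT_NHEJ_DELETION:c], "")
    )
    hdr = build_hdr_allele(locus, genome, vector, default_silent_mutations(locus))
    primers = design_primer_set(locus, genome, hdr.sequence[c:c + cdna_len + polya_len])

    others = [n for n in chrom_names if n != locus.chrom]
    integrations = []
    vec_len = len(vector.sequence)
    for i in range(n_random_integrations):
        chrom = others[i % len(others)]
        pos = int(rng.integers(5_000, len(genome[chrom]) - 5_000))
        integrations.append(
            RandomIntegration(
                chrom=chrom,
                position=pos,
                vector_interval=(vec_len - 600, vec_len),
                orientation="+",
            )
        )
    population = CellPopulationSpec(
        fractions=dict(fractions or DEFAULT_FRACTIONS),
        episome_copies_per_genome=episome_copies_per_genome,
        random_integrations=integrations,
    )
    cassette_len = cdna_len + polya_len
    regions = {
        "WT": (c - OUTER_OFFSET, c + OUTER_OFFSET),
        "NHEJ": (c - OUTER_OFFSET, c + OUTER_OFFSET - DEFAULT_NHEJ_DELETION),
        "HDR": (c - OUTER_OFFSET, c + CDNA_PRIMER_END),
    }
    return Scenario(
        genome=genome,
        locus=locus,
        vector=vector,
        alleles={"WT": wt, "NHEJ": nhej, "HDR": hdr},
        primers=primers,
        population=population,
        seed=seed,
        amplicon_regions=regions,
    )
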