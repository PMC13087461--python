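"""Truth-annotated synthetic data emulating the study's two experiments.

Two sequencing experiments are emulated, both at desk scale:

* a Cas9-enriched long-read library for AAV integration-site detection —
  genomic DNA fragmented to ~10 kb, cleaved in vitro by Cas9 at an array of
  guides tiling the vector (ITR, homology arms, cDNA), the cut fragments
  preferentially retained, and sequenced with nanopore-like errors;
* amplicon pools for editing-outcome quantification — reads drawn from
  explicit WT / NHEJ / HDR allele sequences at stated mixture fractions.

Every simulated read carries a :class:`TruthRecord`; chimeric reads are also
emitted as a truth SAM (primary + supplementary records with soft-clipped
CIGARs and ``SA:Z`` tags per the SAM spec), so the junction caller is
testable without an external aligner.  All randomness flows through a single
``numpy`` generator per operation, seeded explicitly: identical seeds give
byte-identical FASTQ/SAM output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .dna import random_dna, revcomp, seq_to_codes, _BASE_ARR
from .vector_model import CombinedReference, TargetLocus, VectorMap

MAX_REF_GAP = 100  # same-contig pieces closer than this merge into one alignment (D ops)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Independent per-base substitution / insertion / deletion rates."""

    sub_rate: float = 0.02
    ins_rate: float = 0.005
    del_rate: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate"):
            r = getattr(self, name)
            if not 0.0 <= r <= 0.2:
                raise ValueError(f"{name}={r} outside [0, 0.2]")

    @classmethod
    def nanopore(cls) -> "ErrorModel":
        """Long-read default: ~3% total error, substitution-dominated."""
        return cls(0.02, 0.005, 0.005)

    @classmethod
    def amplicon(cls) -> "ErrorModel":
        """Short-read amplicon default: substitutions dominate, indels rare."""
        return cls(0.002, 1e-4, 1e-4)

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class RandomIntegration:
    """A non-targeted vector insertion: a vector subinterval dropped into a
    host position in the given orientation."""

    chrom: str
    position: int
    vector_interval: tuple[int, int]
    orientation: str = "+"


@dataclass
class CellPopulationSpec:
    """Mixture of editing outcomes in the simulated cell population."""

    fractions: dict[str, float]
    episome_copies_per_genome: float = 0.0
    random_integrations: list[RandomIntegration] = field(default_factory=list)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError("population fractions must be nonnegative")
        if self.episome_copies_per_genome < 0:
            raise ValueError("episome_copies_per_genome must be nonnegative")


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------

def make_toy_genome(
    n_chrom: int,
    lengths: list[int],
    locus_chrom_index: int,
    seed: int,
    names: list[str] | None = None,
    ha_length: int = 1000,
) -> tuple[dict[str, str], TargetLocus]:
    """Uniform-random toy genome with a planted Cas9 target locus.

    A 20-nt protospacer followed by an AGG PAM is planted at the centre of
    the locus chromosome; homology-arm intervals of *ha_length* flank the
    blunt cut between protospacer bases 17 and 18.
    """
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if names is None:
        names = [f"chr{i + 1}" for i in range(n_chrom)]
    locus_len = lengths[locus_chrom_index]
    if locus_len < 10_000:
        raise ValueError("locus chromosome must be at least 10 kb")
    rng = np.random.default_rng(seed)
    genome = {name: random_dna(length, rng) for name, length in zip(names, lengths)}

    chrom = names[locus_chrom_index]
    ps_start = locus_len // 2
    protospacer = random_dna(20, rng)
    pam = random_dna(1, rng) + "GG"
    seq = genome[chrom]
    genome[chrom] = seq[:ps_start] + protospacer + pam + seq[ps_start + 23:]
    cut_site = ps_start + 17  # 3 bp 5' of the PAM
    if cut_site - ha_length < 0 or cut_site + ha_length > locus_len:
        raise ValueError("locus does not fit: homology arms fall off the chromosome")
    locus = TargetLocus(
        chrom=chrom,
        strand="+",
        cut_site=cut_site,
        protospacer=protospacer,
        pam=pam,
        ha5_interval=(cut_site - ha_length, cut_site),
        ha3_interval=(cut_site, cut_site + ha_length),
    )
    return genome, locus


# ---------------------------------------------------------------------------
# Fragmentation and Cas9 enrichment
# ---------------------------------------------------------------------------

def fragment_intervals(length: int, mean_len: float, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Poisson-process breakpoints at rate 1/mean_len; intervals tile [0, length)."""
    if mean_len < 1000:
        raise ValueError("mean_len must be >= 1000")
    points = []
    x = 0.0
    while True:
        x += rng.exponential(mean_len)
        if x >= length:
            break
        p = int(round(x))
        if 0 < p < length and (not points or p > points[-1]):
            points.append(p)
    bounds = [0] + points + [length]
    return list(zip(bounds[:-1], bounds[1:]))


def fragment_genome(molecule: str, mean_len: float, seed: int) -> list[str]:
    """Shear one DNA molecule into fragments that exactly tile it."""
    rng = np.random.default_rng(seed)
    return [molecule[s:e] for s, e in fragment_intervals(len(molecule), mean_len, rng)]


@dataclass(frozen=True)
class Fragment:
    """A sheared piece of a source molecule, in molecule coordinates."""

    molecule_id: int
    start: int
    end: int
    cut_left: bool = False  # boundary created by Cas9 cleavage
    cut_right: bool = False

    def __len__(self) -> int:
        return self.end - self.start


def cas9_enrich(
    fragments: list[Fragment],
    guide_sites: dict[int, list[int]],
    capture_bias: float,
    rng: np.random.Generator,
    p_cut: float = 0.9,
) -> list[Fragment]:
    """In-vitro Cas9 cleavage and capture.

    Fragments overlapping a guide site are cut at every overlapped site; the
    resulting pieces (which now expose Cas9-cut ends for adapter ligation)
    are each retained with probability *p_cut*.  Fragments with no guide site
    are retained at the background rate ``p_cut / capture_bias``.
    """
    if capture_bias < 1:
        raise ValueError("capture_bias must be >= 1")
    retained: list[Fragment] = []
    for frag in fragments:
        sites = sorted(
            s for s in guide_sites.get(frag.molecule_id, []) if frag.start < s < frag.end
        )
        if sites:
            bounds = [frag.start] + sites + [frag.end]
            for i, (s, e) in enumerate(zip(bounds[:-1], bounds[1:])):
                piece = Fragment(
                    frag.molecule_id,
                    s,
                    e,
                    cut_left=(i > 0) or frag.cut_left,
                    cut_right=(i < len(bounds) - 2) or frag.cut_right,
                )
                if rng.random() < p_cut:
                    retained.append(piece)
        else:
            if rng.random() < p_cut / capture_bias:
                retained.append(frag)
    return retained


# ---------------------------------------------------------------------------
# Sequencing-error engine
# ---------------------------------------------------------------------------

def apply_errors(
    seq: str, err: ErrorModel, rng: np.random.Generator
) -> tuple[str, list[tuple[str, int]]]:
    """Apply per-base errors to *seq*; return (read, CIGAR-style ops).

    Per source base, in order: an insertion of one random base may precede it
    (never before the first base, so segment alignments cannot begin with an
    insertion), then the base is either deleted or emitted, substituted to a
    different random base with probability ``sub_rate``.  Ops use M/I/D and
    are run-length encoded; M covers both matches and substitutions.
    """
    L = len(seq)
    if L == 0:
        return "", []
    ins = rng.random(L) < err.ins_rate
    ins[0] = False
    dele = rng.random(L) < err.del_rate
    sub = rng.random(L) < err.sub_rate
    shift = rng.integers(1, 4, size=L)
    ins_base = rng.integers(0, 4, size=L)

    codes = seq_to_codes(seq).astype(np.int64)
    out_codes = np.where(sub, (codes + shift) % 4, codes)
    main = _BASE_ARR[out_codes]
    ins_chars = _BASE_ARR[ins_base]

    keep = ~dele
    counts = ins.astype(np.int64) + keep
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    out[starts[ins]] = ins_chars[ins]
    out[starts[keep] + ins[keep]] = main[keep]

    slot_starts = np.concatenate(([0], np.cumsum(ins.astype(np.int64) + 1)[:-1]))
    opcodes = np.empty(int(L + ins.sum()), dtype=np.uint8)
    opcodes[slot_starts[ins]] = 1
    opcodes[slot_starts + ins] = np.where(dele, 2, 0)
    change = np.flatnonzero(np.diff(opcodes))
    bounds = np.concatenate(([0], change + 1, [len(opcodes)]))
    ops = [("MID"[opcodes[b]], int(e - b)) for b, e in zip(bounds[:-1], bounds[1:])]
    return out.tobytes().decode(), ops


# ---------------------------------------------------------------------------
# Molecules and truth-annotated reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruthPiece:
    """One building block of a simulated molecule.

    ``ref is None`` marks a literal (non-reference) insertion carrying its
    own sequence; otherwise the piece is ``ref[start:end)`` on *strand*.
    """

    ref: str | None
    start: int = 0
    end: int = 0
    strand: str = "+"
    seq: str | None = None

    def length(self) -> int:
        return len(self.seq) if self.ref is None else self.end - self.start


@dataclass
class Molecule:
    id: int
    pieces: list[TruthPiece]
    sequence: str
    label: str = ""

    @classmethod
    def build(cls, mol_id: int, pieces: list[TruthPiece], refs: dict[str, str], label: str = "") -> "Molecule":
        parts = []
        for p in pieces:
            if p.ref is None:
                parts.append(p.seq)
            else:
                s = refs[p.ref][p.start:p.end]
                parts.append(revcomp(s) if p.strand == "-" else s)
        return cls(mol_id, pieces, "".join(parts), label)


@dataclass
class TruthSegment:
    """One aligned block of a read: reference interval, read interval (in the
    emitted read's orientation), strand, and M/I/D ops along the read."""

    reference: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    ops: list[tuple[str, int]]


@dataclass
class TruthJunction:
    host_chrom: str
    host_coord: int
    vector_coord: int
    host_flank: int  # read bp aligned on the host side
    vector_flank: int


@dataclass
class TruthRecord:
    read_id: str
    segments: list[TruthSegment]
    junctions: list[TruthJunction]
    source_label: str


@dataclass
class SimulatedRead:
    read_id: str
    sequence: str
    truth: TruthRecord
    flipped: bool


def _clip_pieces(pieces: list[TruthPiece], a: int, b: int) -> list[TruthPiece]:
    """Sub-pieces of a molecule interval [a, b) in molecule coordinates."""
    out = []
    offset = 0
    for p in pieces:
        plen = p.length()
        lo, hi = max(a, offset), min(b, offset + plen)
        if lo < hi:
            i, j = lo - offset, hi - offset
            if p.ref is None:
                out.append(TruthPiece(None, seq=p.seq[i:j]))
            elif p.strand == "+":
                out.append(TruthPiece(p.ref, p.start + i, p.start + j, "+"))
            else:
                out.append(TruthPiece(p.ref, p.end - j, p.end - i, "-"))
        offset += plen
    return out


def _group_alignments(pieces: list[TruthPiece]) -> list[list[TruthPiece]]:
    """Group clipped pieces into alignment units.

    Adjacent same-reference forward pieces separated by a small reference
    gap (a true deletion) merge into one alignment; literal pieces attach to
    the surrounding same-reference alignment as true insertions.
    """
    groups: list[list[TruthPiece]] = []
    for p in pieces:
        if groups:
            cur = groups[-1]
            last_ref = next((q for q in reversed(cur) if q.ref is not None), None)
            if p.ref is None and last_ref is not None:
                cur.append(p)
                continue
            if (
                p.ref is not None
                and last_ref is not None
                and p.ref == last_ref.ref
                and p.strand == "+"
                and last_ref.strand == "+"
                and 0 <= p.start - last_ref.end <= MAX_REF_GAP
            ):
                cur.append(p)
                continue
        groups.append([p])
    # a group that is only literals cannot be aligned anywhere; keep separate
    return groups


def _segment_from_group(
    group: list[TruthPiece],
    refs: dict[str, str],
    err: ErrorModel,
    rng: np.random.Generator,
    read_cursor: int,
) -> tuple[str, TruthSegment | None]:
    """Sequence + truth segment for one alignment group, with errors applied."""
    if all(p.ref is None for p in group):
        raw = "".join(p.seq for p in group)
        read, _ = apply_errors(raw, err, rng)
        return read, None
    strand = next(p.strand for p in group if p.ref is not None)
    ops: list[tuple[str, int]] = []
    read_parts: list[str] = []
    ref_lo, ref_hi = None, None
    prev: TruthPiece | None = None
    for p in group:
        if p.ref is None:
            sub_read, _ = apply_errors(p.seq, ErrorModel(err.sub_rate, 0.0, 0.0), rng)
            if sub_read:
                read_parts.append(sub_read)
                ops.append(("I", len(sub_read)))
            continue
        if prev is not None and prev.ref == p.ref:
            gap = p.start - prev.end if strand == "+" else prev.start - p.end
            if gap > 0:
                ops.append(("D", gap))
        raw = refs[p.ref][p.start:p.end]
        if strand == "-":
            raw = revcomp(raw)
        sub_read, sub_ops = apply_errors(raw, err, rng)
        read_parts.append(sub_read)
        ops.extend(sub_ops)
        ref_lo = p.start if ref_lo is None else min(ref_lo, p.start)
        ref_hi = p.end if ref_hi is None else max(ref_hi, p.end)
        prev = p
    # merge adjacent identical ops
    merged: list[tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    # trim edge deletions into the reference interval
    while merged and merged[0][0] == "D":
        n = merged.pop(0)[1]
        if strand == "+":
            ref_lo += n
        else:
            ref_hi -= n
    while merged and merged[-1][0] == "D":
        n = merged.pop()[1]
        if strand == "+":
            ref_hi -= n
        else:
            ref_lo += n
    read = "".join(read_parts)
    if not merged or ref_lo is None or ref_lo >= ref_hi:
        return read, None
    if strand == "-":
        # store ops reference-forward so SAM emission never re-orders them
        merged = merged[::-1]
    seg = TruthSegment(
        reference=next(p.ref for p in group if p.ref is not None),
        ref_start=ref_lo,
        ref_end=ref_hi,
        read_start=read_cursor,
        read_end=read_cursor + len(read),
        strand=strand,
        ops=merged,
    )
    return read, seg


def build_read(
    molecule: Molecule,
    interval: tuple[int, int],
    refs: dict[str, str],
    err: ErrorModel,
    rng: np.random.Generator,
    read_id: str,
    vector_contig: str,
    flip: bool | None = None,
) -> SimulatedRead:
    """Sequence one molecule fragment into a truth-annotated read."""
    pieces = _clip_pieces(molecule.pieces, *interval)
    groups = _group_alignments(pieces)
    cursor = 0
    parts: list[str] = []
    segments: list[TruthSegment] = []
    for group in groups:
        read_part, seg = _segment_from_group(group, refs, err, rng, cursor)
        parts.append(read_part)
        cursor += len(read_part)
        if seg is not None:
            segments.append(seg)
    built = "".join(parts)
    flipped = bool(rng.random() < 0.5) if flip is None else flip

    junctions: list[TruthJunction] = []
    for a, b in zip(segments[:-1], segments[1:]):
        refs_pair = {a.reference, b.reference}
        if vector_contig in refs_pair and len(refs_pair) == 2:
            host, vec = (a, b) if b.reference == vector_contig else (b, a)
            host_coord = _facing_coord(host, left=(host is a))
            vec_coord = _facing_coord(vec, left=(vec is a))
            junctions.append(
                TruthJunction(
                    host_chrom=host.reference,
                    host_coord=host_coord,
                    vector_coord=vec_coord,
                    host_flank=host.read_end - host.read_start,
                    vector_flank=vec.read_end - vec.read_start,
                )
            )

    L = len(built)
    if flipped:
        emitted = revcomp(built)
        out_segments = []
        for s in segments:
            out_segments.append(
                TruthSegment(
                    reference=s.reference,
                    ref_start=s.ref_start,
                    ref_end=s.ref_end,
                    read_start=L - s.read_end,
                    read_end=L - s.read_start,
                    strand="-" if s.strand == "+" else "+",
                    ops=s.ops,
                )
            )
        out_segments.reverse()
    else:
        emitted = built
        out_segments = segments
    truth = TruthRecord(read_id, out_segments, junctions, molecule.label)
    return SimulatedRead(read_id, emitted, truth, flipped)


def _facing_coord(seg: TruthSegment, left: bool) -> int:
    """Reference coordinate facing the junction (built-read orientation).

    *left* means the segment sits left of the junction on the read; a
    forward segment then faces the junction with its reference end, a
    reverse segment with its reference start (mirrored on the right side).
    """
    if left:
        return seg.ref_end if seg.strand == "+" else seg.ref_start
    return seg.ref_start if seg.strand == "+" else seg.ref_end


# ---------------------------------------------------------------------------
# Long-read experiment
# ---------------------------------------------------------------------------

def default_guide_positions(vector: VectorMap) -> list[int]:
    """Midpoints of the guide-array targets tiling the vector (ITRs, homology
    arms, cDNA)."""
    return [
        (seg.start + seg.end) // 2
        for seg in vector.segments
        if seg.label in ("ITR5", "HA5", "CDNA", "HA3", "ITR3")
    ]


@dataclass
class LongReadSimulation:
    reads: list[SimulatedRead]
    combined: CombinedReference
    vector_contig: str
    seed: int

    def write_fastq(self, path: str | Path) -> None:
        write_fastq([(r.read_id, r.sequence) for r in self.reads], path, comment=f"seed={self.seed}")

    def write_truth_sam(self, path: str | Path) -> None:
        write_truth_sam(self.reads, self.combined, path)

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsource\thost_chrom\thost_coord\tvector_coord\thost_flank\tvector_flank\n")
            for r in self.reads:
                for j in r.truth.junctions:
                    fh.write(
                        f"{r.read_id}\t{r.truth.source_label}\t{j.host_chrom}\t"
                        f"{j.host_coord}\t{j.vector_coord}\t{j.host_flank}\t{j.vector_flank}\n"
                    )

    def true_junctions(self, min_flank: int = 0) -> set[tuple[str, int, int]]:
        out = set()
        for r in self.reads:
            for j in r.truth.junctions:
                if j.host_flank >= min_flank and j.vector_flank >= min_flank:
                    out.add((j.host_chrom, j.host_coord, j.vector_coord))
        return out

    def true_sites(self) -> set[tuple[str, int]]:
        return {(j[0], j[1]) for j in self.true_junctions()}


def _class_molecules(
    label: str,
    genome: dict[str, str],
    vector: VectorMap,
    locus: TargetLocus,
    population: CellPopulationSpec,
    refs: dict[str, str],
    nhej_indel: tuple[int, str, str],
) -> list[Molecule]:
    """One genome copy's molecules for an editing-outcome class."""
    per_chrom: dict[str, list[TruthPiece]] = {
        name: [TruthPiece(name, 0, len(seq))] for name, seq in genome.items()
    }
    if label == "HDR":
        cdna = vector.segment("CDNA")
        polya = vector.segment("POLYA")
        c = locus.cut_site
        per_chrom[locus.chrom] = [
            TruthPiece(locus.chrom, 0, c),
            TruthPiece(vector.name, cdna.start, polya.end),
            TruthPiece(locus.chrom, c, len(genome[locus.chrom])),
        ]
    elif label == "NHEJ":
        pos, ref_span, alt_span = nhej_indel
        pieces = [TruthPiece(locus.chrom, 0, pos)]
        if alt_span:
            pieces.append(TruthPiece(None, seq=alt_span))
        pieces.append(TruthPiece(locus.chrom, pos + len(ref_span), len(genome[locus.chrom])))
        per_chrom[locus.chrom] = pieces
    # random integrations are clonal: present in every class
    for ri in population.random_integrations:
        pieces = per_chrom[ri.chrom]
        new: list[TruthPiece] = []
        offset = 0
        inserted = False
        for p in pieces:
            plen = p.length()
            if not inserted and p.ref == ri.chrom and p.start <= ri.position <= p.end:
                i = ri.position - p.start
                if i > 0:
                    new.append(TruthPiece(p.ref, p.start, p.start + i))
                new.append(
                    TruthPiece(vector.name, ri.vector_interval[0], ri.vector_interval[1], ri.orientation)
                )
                if i < plen:
                    new.append(TruthPiece(p.ref, p.start + i, p.end))
                inserted = True
            else:
                new.append(p)
            offset += plen
        per_chrom[ri.chrom] = new
    mols = []
    for i, (name, pieces) in enumerate(per_chrom.items()):
        mols.append(Molecule.build(i, pieces, refs, label=f"{label}:{name}"))
    return mols


def simulate_long_reads(
    population: CellPopulationSpec,
    genome: dict[str, str],
    vector: VectorMap,
    locus: TargetLocus,
    err: ErrorModel,
    n_reads: int,
    seed: int,
    mean_fragment_len: float = 10_000.0,
    capture_bias: float = 20.0,
    p_cut: float = 0.9,
    guide_positions: list[int] | None = None,
    nhej_indel: tuple[int, str, str] | None = None,
    flip: bool | None = None,
) -> LongReadSimulation:
    """Emulate the Cas9-enriched nanopore integration assay.

    Genome copies are drawn from the population's outcome classes; each copy
    is sheared to ~*mean_fragment_len* fragments, cleaved in vitro at the
    guide array tiling any vector sequence present, enriched, and the
    retained fragments are sequenced with *err* until *n_reads* reads exist.
    Episomal vector molecules are added per copy at the population's rate.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    from .vector_model import build_combined_reference

    combined = build_combined_reference(genome, vector)
    refs = dict(combined.contigs)
    rng = np.random.default_rng(seed)
    if guide_positions is None:
        guide_positions = default_guide_positions(vector)
    if nhej_indel is None:
        c = locus.cut_site
        nhej_indel = (c - 3, genome[locus.chrom][c - 3:c], "")

    labels = sorted(population.fractions)
    probs = np.array([population.fractions[l] for l in labels])
    class_cache = {
        l: _class_molecules(l, genome, vector, locus, population, refs, nhej_indel)
        for l in labels
        if population.fractions[l] > 0
    }
    episome = Molecule.build(-1, [TruthPiece(vector.name, 0, len(vector.sequence))], refs, label="episome")

    def molecule_guide_sites(mol: Molecule) -> list[int]:
        sites = []
        offset = 0
        for p in mol.pieces:
            if p.ref == vector.name:
                for g in guide_positions:
                    if p.start < g < p.end:
                        if p.strand == "+":
                            sites.append(offset + (g - p.start))
                        else:
                            sites.append(offset + (p.end - g))
            offset += p.length()
        return sites

    reads: list[SimulatedRead] = []
    while len(reads) < n_reads:
        label = labels[rng.choice(len(labels), p=probs)]
        molecules = list(class_cache[label])
        n_epi = int(rng.poisson(population.episome_copies_per_genome))
        molecules += [episome] * n_epi
        for mol in molecules:
            frags = [
                Fragment(mol.id, s, e)
                for s, e in fragment_intervals(len(mol.sequence), mean_fragment_len, rng)
            ]
            sites = molecule_guide_sites(mol)
            retained = cas9_enrich(frags, {mol.id: sites}, capture_bias, rng, p_cut=p_cut)
            for frag in retained:
                rid = f"read{len(reads):06d}"
                reads.append(
                    build_read(mol, (frag.start, frag.end), refs, err, rng, rid, vector.name, flip=flip)
                )
    return LongReadSimulation(reads[:n_reads], combined, vector.name, seed)


# ---------------------------------------------------------------------------
# Amplicon experiment
# ---------------------------------------------------------------------------

@dataclass
class AmpliconSimulation:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    labels: list[str]
    seed: int

    def write_fastq(self, path: str | Path) -> None:
        write_fastq(self.reads, path, comment=f"seed={self.seed}")


def simulate_amplicon_reads(
    alleles,
    region: tuple[int, int] | None,
    err: ErrorModel,
    n_reads: int,
    seed: int,
) -> AmpliconSimulation:
    """Sample amplicon reads from weighted allele sequences.

    *alleles* is a list of ``(AlleleModel, weight)``; weights must sum to 1.
    *region* restricts every allele to an interval of its own coordinates
    (``None`` keeps the full sequence).
    """
    weights = np.array([w for _, w in alleles], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("allele weights must sum to 1")
    templates = []
    for allele, _ in alleles:
        seq = allele.sequence if region is None else allele.sequence[region[0]:region[1]]
        if not seq:
            raise ValueError("empty amplicon region")
        templates.append(seq)
    rng = np.random.default_rng(seed)
    reads: list[tuple[str, str]] = []
    labels: list[str] = []
    for i in range(n_reads):
        k = int(rng.choice(len(alleles), p=weights))
        read, _ = apply_errors(templates[k], err, rng)
        reads.append((f"amp{i:06d}", read))
        labels.append(alleles[k][0].label)
    return AmpliconSimulation(reads, labels, seed)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fastq(reads: list[tuple[str, str]], path: str | Path, comment: str = "") -> None:
    """Phred+33 FASTQ with constant Q20 placeholder qualities."""
    q = chr(20 + 33)
    with open(path, "w") as fh:
        for rid, seq in reads:
            head = f"@{rid} {comment}".rstrip()
            fh.write(f"{head}\n{seq}\n+\n{q * len(seq)}\n")


def write_truth_sam(reads: list[SimulatedRead], combined: CombinedReference, path: str | Path) -> None:
    """Emit each read's truth alignment as SAM records with SA tags.

    The longest aligned block becomes the primary record; the others are
    supplementary (flag 0x800).  Soft clips cover the rest of the read and
    ``SA:Z`` entries use 1-based positions per the SAM spec.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in combined.contigs],
        }
    )
    tid = {name: i for i, (name, _) in enumerate(combined.contigs)}

    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            segs = read.truth.segments
            if not segs:
                continue
            L = len(read.sequence)
            rendered = []
            for seg in segs:
                # stored SEQ follows the reference-forward strand; ops are
                # already reference-forward (see _segment_from_group)
                if seg.strand == "+":
                    stored = read.sequence
                    p, q = seg.read_start, seg.read_end
                else:
                    stored = revcomp(read.sequence)
                    p, q = L - seg.read_end, L - seg.read_start
                parts = []
                if p > 0:
                    parts.append(f"{p}S")
                parts += [f"{n}{op}" for op, n in seg.ops]
                if L - q > 0:
                    parts.append(f"{L - q}S")
                cigar = "".join(parts)
                rendered.append((seg, stored, cigar))
            lengths = [s.read_end - s.read_start for s in segs]
            primary_idx = int(np.argmax(lengths))
            for i, (seg, stored, cigar) in enumerate(rendered):
                a = pysam.AlignedSegment(header)
                a.query_name = read.read_id
                a.reference_id = tid[seg.reference]
                a.reference_start = seg.ref_start
                a.mapping_quality = 60
                a.cigarstring = cigar
                a.flag = (16 if seg.strand == "-" else 0) | (0 if i == primary_idx else 2048)
                a.query_sequence = stored
                a.query_qualities = pysam.qualitystring_to_array(chr(20 + 33) * L)
                others = [
                    f"{s.reference},{s.ref_start + 1},{s.strand},{c},60,0;"
                    for j, (s, _, c) in enumerate(rendered)
                    if j != i
                ]
                if others:
                    a.set_tag("SA", "".join(others))
                out.write(a)
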