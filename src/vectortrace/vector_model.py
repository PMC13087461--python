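"""AAV donor-vector map, combined host+vector reference, and allele models.

The donor vector is an AAV cassette ``ITR + 5'HA + cDNA + polyA + 3'HA + ITR``
used to knock a promoterless cDNA into a genomic locus by homology-directed
repair (HDR).  Integration-site detection aligns long reads against a
*combined* reference in which the vector sequence is appended to the host
genome as one extra contig, so vector-host chimeric reads produce
supplementary alignments across the two.

This module builds the vector map, the combined reference, and explicit
allele sequences (WT, NHEJ-indel, HDR knock-in) for the target locus; the
allele models drive both the amplicon simulator and the in-silico PCR assay.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dna import check_dna

SEGMENT_LABELS = ("ITR5", "HA5", "CDNA", "POLYA", "HA3", "ITR3")

#: Conventional AAV2 ITR length used by fixtures; the real vector's ITR
#: structure is configurable wherever a map is built.
DEFAULT_ITR_LENGTH = 145


class DuplicateContigError(ValueError):
    """Vector contig name collides with a host contig name."""


class LocusMismatchError(ValueError):
    """Homology-arm intervals do not match the host sequence."""


@dataclass(frozen=True)
class Segment:
    label: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class VectorMap:
    """Annotated AAV vector: full sequence plus ordered, labelled segments."""

    name: str
    sequence: str
    segments: list[Segment]

    def __post_init__(self) -> None:
        prev_end = 0
        labels = [s.label for s in self.segments]
        for seg in self.segments:
            if not (0 <= seg.start <= seg.end <= len(self.sequence)):
                raise ValueError(f"segment {seg} outside vector [0, {len(self.sequence)})")
            if seg.start < prev_end:
                raise ValueError(f"segments overlap or are unsorted at {seg}")
            prev_end = seg.end
        for required in ("HA5", "HA3"):
            if labels.count(required) != 1:
                raise ValueError(f"label {required} must appear exactly once, got {labels}")

    def segment_sequence(self, label: str) -> str:
        seg = self.segment(label)
        return self.sequence[seg.start:seg.end]

    def segment(self, label: str) -> Segment:
        for seg in self.segments:
            if seg.label == label:
                return seg
        raise KeyError(label)

    def segment_at(self, pos: int) -> str | None:
        """Label of the segment containing *pos*.

        A coordinate equal to a segment's exclusive end (a junction
        coordinate facing right) is attributed to that segment when it is
        not the start of the next one.
        """
        for seg in self.segments:
            if seg.start <= pos < seg.end:
                return seg.label
        for seg in self.segments:
            if pos == seg.end:
                return seg.label
        return None

    # -- serialisation ---------------------------------------------------
    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for seg in self.segments:
                fh.write(f"{self.name}\t{seg.start}\t{seg.end}\t{seg.label}\n")

    def to_json(self, path: str | Path) -> None:
        obj = {
            "name": self.name,
            "length": len(self.sequence),
            "sequence": self.sequence,
            "segments": [[s.label, s.start, s.end] for s in self.segments],
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "VectorMap":
        obj = json.loads(Path(path).read_text())
        return cls(
            name=obj["name"],
            sequence=obj["sequence"],
            segments=[Segment(l, s, e) for l, s, e in obj["segments"]],
        )


@dataclass
class TargetLocus:
    """The genomic site targeted by the guide RNA.

    ``cut_site`` is the 0-based position *between* two bases — the blunt
    SpCas9 cut between protospacer bases 17 and 18 (3 bp 5' of the PAM).
    """

    chrom: str
    strand: str
    cut_site: int
    protospacer: str
    pam: str
    ha5_interval: tuple[int, int]
    ha3_interval: tuple[int, int]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if self.ha5_interval[1] > self.cut_site:
            raise ValueError("ha5_interval must end at or before cut_site")
        if self.ha3_interval[0] < self.cut_site:
            raise ValueError("ha3_interval must start at or after cut_site")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TargetLocus":
        obj = json.loads(Path(path).read_text())
        obj["ha5_interval"] = tuple(obj["ha5_interval"])
        obj["ha3_interval"] = tuple(obj["ha3_interval"])
        return cls(**obj)


@dataclass
class AlleleModel:
    """Explicit sequence of one allele class at the target locus.

    ``edits`` lists (position-in-WT, ref_span, alt_span) applied to the WT
    chromosome sequence; the WT allele has no edits.  For the HDR allele,
    ``insert_interval`` gives the cassette's coordinates in allele space
    (used for junction-fidelity checks).
    """

    label: str
    sequence: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)
    insert_interval: tuple[int, int] | None = None
    protospacer_pam: str | None = None


@dataclass
class CombinedReference:
    """Host contigs followed by the vector contig, in deterministic order."""

    contigs: list[tuple[str, str]]
    vector_contig_name: str

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def __getitem__(self, name: str) -> str:
        for n, s in self.contigs:
            if n == name:
                return s
        raise KeyError(name)

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        write_fasta(dict(self.contigs), path, width=width)

    @classmethod
    def from_fasta(cls, path: str | Path, vector_contig_name: str) -> "CombinedReference":
        contigs = list(read_fasta(path).items())
        return cls(contigs=contigs, vector_contig_name=vector_contig_name)


# ---------------------------------------------------------------------------
# FASTA I/O (thin Biopython wrappers; 60-column wrapping)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 60) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_vector_map(
    ha5: str,
    cdna: str,
    polya: str,
    ha3: str,
    itr: str,
    name: str = "pAAV",
) -> VectorMap:
    """Assemble the donor vector ``ITR+HA5+CDNA+POLYA+HA3+ITR``.

    Segment coordinates follow directly from the concatenation order; both
    ITR copies come from the same *itr* sequence.
    """
    parts = {"itr": itr, "ha5": ha5, "cdna": cdna, "polya": polya, "ha3": ha3}
    for pname, seq in parts.items():
        check_dna(seq, pname)
    order = [("ITR5", itr), ("HA5", ha5), ("CDNA", cdna), ("POLYA", polya), ("HA3", ha3), ("ITR3", itr)]
    segments = []
    pos = 0
    for label, seq in order:
        segments.append(Segment(label, pos, pos + len(seq)))
        pos += len(seq)
    return VectorMap(name=name, sequence="".join(seq for _, seq in order), segments=segments)


def build_combined_reference(host: dict[str, str], vector: VectorMap) -> CombinedReference:
    """Append the vector as the final contig of the host genome."""
    if vector.name in host:
        raise DuplicateContigError(f"host genome already has a contig named {vector.name!r}")
    contigs = list(host.items()) + [(vector.name, vector.sequence)]
    return CombinedReference(contigs=contigs, vector_contig_name=vector.name)


def _apply_point_edits(seq: str, edits: Iterable[tuple[int, str]]) -> str:
    arr = list(seq)
    for pos, base in edits:
        arr[pos] = base
    return "".join(arr)


def protospacer_interval(locus: TargetLocus) -> tuple[int, int]:
    """Host interval [start, end) covered by protospacer+PAM on the + strand.

    For a + strand guide the cut falls between protospacer offsets 17 and 18,
    so the protospacer starts ``cut_site - 17``; the PAM follows the
    protospacer.  For a - strand guide the layout mirrors.
    """
    n = len(locus.protospacer)
    if locus.strand == "+":
        start = locus.cut_site - (n - 3)
        return start, start + n + len(locus.pam)
    start = locus.cut_site - 3 - len(locus.pam)
    return start, start + n + len(locus.pam)


def build_hdr_allele(
    locus: TargetLocus,
    host: dict[str, str],
    vector: VectorMap,
    silent_mutations: list[tuple[int, str]],
) -> AlleleModel:
    """Model the precise HDR knock-in allele.

    The allele is ``host[..ha5_end) + CDNA + POLYA + host[ha3_start..)``: the
    homology arms are genomic, so no ITR sequence enters the allele.  Silent
    mutations (offset within protospacer+PAM, replacement base) are applied
    to the genomic copy of the protospacer region so the knock-in allele can
    no longer be re-cut by Cas9.
    """
    chrom_seq = host[locus.chrom]
    ha5_start, ha5_end = locus.ha5_interval
    ha3_start, ha3_end = locus.ha3_interval
    if chrom_seq[ha5_start:ha5_end] != vector.segment_sequence("HA5"):
        raise LocusMismatchError("vector HA5 does not match host ha5_interval")
    if chrom_seq[ha3_start:ha3_end] != vector.segment_sequence("HA3"):
        raise LocusMismatchError("vector HA3 does not match host ha3_interval")
    if not silent_mutations:
        warnings.warn(
            "HDR allele built without silent protospacer mutations: the "
            "knock-in allele remains cleavable by Cas9",
            UserWarning,
            stacklevel=2,
        )
    ps_start, ps_end = protospacer_interval(locus)
    span = ps_end - ps_start
    genomic_edits = []
    for offset, base in silent_mutations:
        if not 0 <= offset < span:
            raise ValueError(f"silent-mutation offset {offset} outside protospacer+PAM [0,{span})")
        if locus.strand == "+":
            genomic_edits.append((ps_start + offset, base))
        else:
            from .dna import revcomp

            genomic_edits.append((ps_end - 1 - offset, revcomp(base)))
    mutated = _apply_point_edits(chrom_seq, genomic_edits)

    cassette = vector.segment_sequence("CDNA") + vector.segment_sequence("POLYA")
    replaced = mutated[ha5_end:ha3_start]
    sequence = mutated[:ha5_end] + cassette + mutated[ha3_start:]

    # protospacer+PAM as it reads in the HDR allele (mapped through the
    # cassette insertion), for cleavability checks
    def allele_pos(g: int) -> int:
        return g if g < ha5_end else g - ha3_start + ha5_end + len(cassette)

    ps_bases = "".join(sequence[allele_pos(g)] for g in range(ps_start, ps_end))
    if locus.strand == "-":
        from .dna import revcomp

        ps_bases = revcomp(ps_bases)

    edits: list[tuple[int, str, str]] = [(ha5_end, replaced, cassette)]
    edits += [(g, chrom_seq[g], b) for g, b in sorted(genomic_edits)]
    return AlleleModel(
        label="HDR",
        sequence=sequence,
        edits=edits,
        insert_interval=(ha5_end, ha5_end + len(cassette)),
        protospacer_pam=ps_bases,
    )


def build_wt_allele(locus: TargetLocus, host: dict[str, str]) -> AlleleModel:
    return AlleleModel(label="WT", sequence=host[locus.chrom], edits=[])


def build_nhej_allele(
    locus: TargetLocus,
    host: dict[str, str],
    indel: tuple[int, str, str],
    window: int = 20,
) -> AlleleModel:
    """Model an NHEJ allele carrying one small indel near the cut site."""
    pos, ref_span, alt_span = indel
    if not (locus.cut_site - window <= pos <= locus.cut_site + window):
        raise ValueError(f"indel position {pos} outside ±{window} bp of cut site {locus.cut_site}")
    chrom_seq = host[locus.chrom]
    if chrom_seq[pos:pos + len(ref_span)] != ref_span:
        raise LocusMismatchError(
            f"ref_span {ref_span!r} does not match host at {locus.chrom}:{pos}"
        )
    sequence = chrom_seq[:pos] + alt_span + chrom_seq[pos + len(ref_span):]
    return AlleleModel(label="NHEJ", sequence=sequence, edits=[(pos, ref_span, alt_span)])
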