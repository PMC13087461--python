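"""AAV–host junction calling from chimeric alignments on a combined reference.

A read spanning an integration breakpoint aligns in pieces: one piece to the
vector contig and one to a host chromosome.  Aligners report the extra
pieces as supplementary alignments listed in the primary record's ``SA:Z``
tag.  This module parses those tags and each piece's CIGAR to place every
aligned block on both the read and the reference, emits a
:class:`JunctionEvent` for each adjacent vector↔host pair on the read,
single-linkage-clusters events into :class:`IntegrationSite`\\ s, and
classifies sites as targeted (at the edited locus) or other.

Coordinates are 0-based half-open internally; SA-tag positions are 1-based
as in the SAM spec and converted on parse.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import pysam

from .vector_model import TargetLocus, VectorMap

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 20
DEFAULT_MIN_SEGMENT_LEN = 200
DEFAULT_MAX_JUNCTION_GAP = 100
DEFAULT_MERGE_DISTANCE = 50
#: chimeric pieces may share up to this much read sequence (microhomology)
DEFAULT_MAX_OVERLAP = 50
DEFAULT_TARGETED_WINDOW = 100

_READ_CONSUMING = set("MIS=X")
_REF_CONSUMING = set("MDN=X")
_CIGAR_OPS = set("MIDNSH=X")


class SATagError(ValueError):
    """SA:Z tag entry does not conform to the SAM grammar."""


@dataclass(frozen=True)
class ChimericSegment:
    """One aligned piece of a read."""

    reference: str
    ref_interval: tuple[int, int]
    read_interval: tuple[int, int]  # in original read orientation
    strand: str
    cigar: str
    mapq: int
    is_supplementary: bool = False

    @property
    def read_length_aligned(self) -> int:
        return self.read_interval[1] - self.read_interval[0]


@dataclass(frozen=True)
class JunctionEvent:
    """An inferred vector–host breakpoint seen on one read."""

    read_id: str
    vector_coord: int
    host_chrom: str
    host_coord: int
    orientation: str  # "vector->host" or "host->vector" along the read
    vector_segment_label: str | None
    read_gap: int


@dataclass
class IntegrationSite:
    host_chrom: str
    representative_coord: int
    support: int
    members: list[JunctionEvent]
    classification: str = "unclassified"


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = []
    n = ""
    for ch in cigar:
        if ch.isdigit():
            n += ch
        elif ch in _CIGAR_OPS:
            if not n:
                raise ValueError(f"malformed CIGAR {cigar!r}")
            ops.append((ch, int(n)))
            n = ""
        else:
            raise ValueError(f"unsupported CIGAR operator {ch!r} in {cigar!r}")
    if n:
        raise ValueError(f"malformed CIGAR {cigar!r}: trailing digits")
    return ops


def cigar_query_length(cigar: str) -> int:
    """Full query length implied by a CIGAR (clips included)."""
    return sum(n for op, n in _parse_cigar(cigar) if op in _READ_CONSUMING or op == "H")


def parse_sa_tag(tag_value: str) -> list[tuple[str, int, str, str, int]]:
    """Parse an ``SA:Z`` value into (rname, 0-based pos, strand, cigar, mapq)
    stubs, one per semicolon-terminated entry."""
    stubs = []
    for entry in tag_value.split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        if len(fields) != 6:
            raise SATagError(f"SA entry {entry!r}: expected 6 comma-separated fields")
        rname, pos_s, strand, cigar, mapq_s, _nm = fields
        try:
            pos = int(pos_s)
            mapq = int(mapq_s)
        except ValueError as exc:
            raise SATagError(f"SA entry {entry!r}: non-integer pos/mapq") from exc
        if pos < 1:
            raise SATagError(f"SA entry {entry!r}: pos must be >= 1 (1-based)")
        if strand not in "+-":
            raise SATagError(f"SA entry {entry!r}: bad strand {strand!r}")
        _parse_cigar(cigar)
        stubs.append((rname, pos - 1, strand, cigar, mapq))
    return stubs


def cigar_intervals(
    cigar: str, ref_start: int, strand: str, read_length: int
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Read and reference intervals covered by an alignment.

    The read interval is reported in the *original read orientation*: for a
    reverse-strand alignment the leading clip (in SEQ-as-stored order) sits
    at the read's 3' end, so the interval flips.
    """
    ops = _parse_cigar(cigar)
    qlen = sum(n for op, n in ops if op in _READ_CONSUMING or op == "H")
    if qlen != read_length:
        raise ValueError(
            f"CIGAR {cigar!r} implies query length {qlen}, expected {read_length}"
        )
    lead = 0
    for op, n in ops:
        if op in "SH":
            lead += n
        else:
            break
    trail = 0
    for op, n in reversed(ops):
        if op in "SH":
            trail += n
        else:
            break
    aligned = sum(n for op, n in ops if op in "MI=X")
    ref_span = sum(n for op, n in ops if op in _REF_CONSUMING)
    if strand == "+":
        read_iv = (lead, lead + aligned)
    else:
        read_iv = (trail, trail + aligned)
    return read_iv, (ref_start, ref_start + ref_span)


def extract_chimeric_segments(
    record: pysam.AlignedSegment,
    read_length: int | None = None,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[ChimericSegment]:
    """All aligned pieces of a read: the primary record plus its SA entries,
    sorted by read-interval start.

    Reads whose pieces overlap on the read by more than *max_overlap* bp are
    ambiguous chimeras and yield an empty list (with a warning).
    """
    if read_length is None:
        read_length = record.infer_read_length()
    own_strand = "-" if record.is_reverse else "+"
    read_iv, ref_iv = cigar_intervals(
        record.cigarstring, record.reference_start, own_strand, read_length
    )
    segments = [
        ChimericSegment(
            reference=record.reference_name,
            ref_interval=ref_iv,
            read_interval=read_iv,
            strand=own_strand,
            cigar=record.cigarstring,
            mapq=record.mapping_quality,
            is_supplementary=record.is_supplementary,
        )
    ]
    if record.has_tag("SA"):
        for rname, pos, strand, cigar, mapq in parse_sa_tag(record.get_tag("SA")):
            read_iv, ref_iv = cigar_intervals(cigar, pos, strand, read_length)
            segments.append(
                ChimericSegment(rname, ref_iv, read_iv, strand, cigar, mapq, True)
            )
    segments.sort(key=lambda s: s.read_interval)
    for a, b in zip(segments[:-1], segments[1:]):
        if a.read_interval[1] - b.read_interval[0] > max_overlap:
            warnings.warn(
                f"read {record.query_name}: chimeric segments overlap by "
                f"{a.read_interval[1] - b.read_interval[0]} bp > {max_overlap}; skipped",
                UserWarning,
                stacklevel=2,
            )
            return []
    return segments


def _facing_coord(seg: ChimericSegment, left_of_junction: bool) -> int:
    if left_of_junction:
        return seg.ref_interval[1] if seg.strand == "+" else seg.ref_interval[0]
    return seg.ref_interval[0] if seg.strand == "+" else seg.ref_interval[1]


def call_junctions(
    read_id: str,
    segments: list[ChimericSegment],
    vector_contig: str,
    vector_map: VectorMap | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN,
    max_junction_gap: int = DEFAULT_MAX_JUNCTION_GAP,
) -> list[JunctionEvent]:
    """Junction events from one read's segments (sorted by read interval).

    Each adjacent vector↔host pair passing the mapq/length/gap filters emits
    one event; the event coordinates are the reference bases facing the
    junction on each side.
    """
    events = []
    for a, b in zip(segments[:-1], segments[1:]):
        on_vector = (a.reference == vector_contig, b.reference == vector_contig)
        if on_vector[0] == on_vector[1]:
            continue
        if min(a.mapq, b.mapq) < min_mapq:
            continue
        if min(a.read_length_aligned, b.read_length_aligned) < min_segment_len:
            continue
        gap = b.read_interval[0] - a.read_interval[1]
        if abs(gap) > max_junction_gap:
            continue
        vec, host = (a, b) if on_vector[0] else (b, a)
        vector_coord = _facing_coord(vec, left_of_junction=(vec is a))
        host_coord = _facing_coord(host, left_of_junction=(host is a))
        events.append(
            JunctionEvent(
                read_id=read_id,
                vector_coord=vector_coord,
                host_chrom=host.reference,
                host_coord=host_coord,
                orientation="vector->host" if on_vector[0] else "host->vector",
                vector_segment_label=(
                    vector_map.segment_at(vector_coord) if vector_map else None
                ),
                read_gap=gap,
            )
        )
    return events


def call_junctions_from_alignments(
    path: str | Path,
    vector_contig: str,
    vector_map: VectorMap | None = None,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    min_segment_len: int = DEFAULT_MIN_SEGMENT_LEN,
    max_junction_gap: int = DEFAULT_MAX_JUNCTION_GAP,
    max_overlap: int = DEFAULT_MAX_OVERLAP,
) -> list[JunctionEvent]:
    """Run junction calling over every primary alignment in a SAM/BAM file."""
    events: list[JunctionEvent] = []
    n_primary = n_vector = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for record in bam:
            if record.is_unmapped or record.is_secondary or record.is_supplementary:
                continue
            n_primary += 1
            refs = {record.reference_name}
            if record.has_tag("SA"):
                refs |= {e.split(",")[0] for e in record.get_tag("SA").split(";") if e}
            if vector_contig not in refs:
                continue
            n_vector += 1
            segments = extract_chimeric_segments(record, max_overlap=max_overlap)
            events.extend(
                call_junctions(
                    record.query_name,
                    segments,
                    vector_contig,
                    vector_map,
                    min_mapq=min_mapq,
                    min_segment_len=min_segment_len,
                    max_junction_gap=max_junction_gap,
                )
            )
    if n_vector == 0:
        warnings.warn(
            "no vector-aligned reads found; integration output will be empty",
            UserWarning,
            stacklevel=2,
        )
    logger.info(
        "scanned %d primary alignments, %d touching the vector, %d junction events",
        n_primary,
        n_vector,
        len(events),
    )
    return events


def cluster_sites(
    events: list[JunctionEvent],
    merge_distance: int = DEFAULT_MERGE_DISTANCE,
    min_support: int = 1,
) -> list[IntegrationSite]:
    """Single-linkage clustering of junction events per chromosome.

    Events on the same chromosome chain into one site while consecutive
    sorted coordinates are within *merge_distance*.  The representative is
    the lower median of member coordinates; support counts distinct reads.
    """
    if merge_distance < 0:
        raise ValueError("merge_distance must be >= 0")
    by_chrom: dict[str, list[JunctionEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.host_chrom, []).append(ev)
    sites = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: e.host_coord)
        cluster: list[JunctionEvent] = []
        for ev in evs:
            if cluster and ev.host_coord - cluster[-1].host_coord > merge_distance:
                sites.append(_make_site(chrom, cluster))
                cluster = []
            cluster.append(ev)
        if cluster:
            sites.append(_make_site(chrom, cluster))
    sites = [s for s in sites if s.support >= min_support]
    sites.sort(key=lambda s: (s.host_chrom, s.representative_coord))
    return sites


def _make_site(chrom: str, members: list[JunctionEvent]) -> IntegrationSite:
    coords = sorted(e.host_coord for e in members)
    rep = coords[(len(coords) - 1) // 2]  # lower median
    return IntegrationSite(
        host_chrom=chrom,
        representative_coord=rep,
        support=len({e.read_id for e in members}),
        members=list(members),
    )


def classify_sites(
    sites: list[IntegrationSite],
    locus: TargetLocus,
    targeted_window: int = DEFAULT_TARGETED_WINDOW,
    predicted_offtargets: list[tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Label each site targeted/other and report distance to the nearest
    predicted off-target site.

    A site is *targeted* when it lies on the locus chromosome within
    *targeted_window* of the homology-arm span.  The returned frame has one
    row per site; ``nearest_offtarget_distance`` is NA when no predicted
    site shares the chromosome (or none were supplied).
    """
    if targeted_window < 0:
        raise ValueError("targeted_window must be >= 0")
    span = (locus.ha5_interval[0] - targeted_window, locus.ha3_interval[1] + targeted_window)
    rows = []
    for site in sites:
        targeted = site.host_chrom == locus.chrom and span[0] <= site.representative_coord <= span[1]
        site.classification = "targeted" if targeted else "other"
        dist = None
        if predicted_offtargets:
            same = [
                abs(site.representative_coord - pos)
                for chrom, pos in predicted_offtargets
                if chrom == site.host_chrom
            ]
            dist = min(same) if same else None
        rows.append(
            {
                "host_chrom": site.host_chrom,
                "coord": site.representative_coord,
                "support": site.support,
                "classification": site.classification,
                "nearest_offtarget_distance": dist,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["host_chrom", "coord", "support", "classification", "nearest_offtarget_distance"],
    )


# ---------------------------------------------------------------------------
# Output writers
# ---------------------------------------------------------------------------

def write_sites_bed(sites: list[IntegrationSite], path: str | Path) -> None:
    """BED6: width-1 interval at the representative coordinate, name =
    classification, score = read support."""
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.host_chrom}\t{s.representative_coord}\t{s.representative_coord + 1}\t"
                f"{s.classification}\t{s.support}\t.\n"
            )


def write_junctions_tsv(events: list[JunctionEvent], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "read_id": e.read_id,
                "vector_coord": e.vector_coord,
                "vector_segment": e.vector_segment_label,
                "host_chrom": e.host_chrom,
                "host_coord": e.host_coord,
                "orientation": e.orientation,
                "gap": e.read_gap,
            }
            for e in events
        ],
        columns=["read_id", "vector_coord", "vector_segment", "host_chrom", "host_coord", "orientation", "gap"],
    )
    df.to_csv(path, sep="\t", index=False)


def summarize_sites(sites: list[IntegrationSite]) -> dict:
    per_chrom: dict[str, int] = {}
    for s in sites:
        per_chrom[s.host_chrom] = per_chrom.get(s.host_chrom, 0) + 1
    return {
        "n_sites": len(sites),
        "per_chromosome": dict(sorted(per_chrom.items())),
        "targeted": sum(1 for s in sites if s.classification == "targeted"),
        "other": sum(1 for s in sites if s.classification == "other"),
    }


def write_summary_json(summary: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=1, sort_keys=True) + "\n")
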