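"""Guide off-target enumeration and per-site indel background screening.

Candidate off-target sites are found by a plain Hamming scan: every
NGG-adjacent 20-mer on either genomic strand within a mismatch budget of
the protospacer.  Each candidate is then screened exactly like the
on-target site — amplicon reads are aligned and indels called in a window
around the predicted cut position — and sites whose indel fraction exceeds
the background threshold are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .dna import InvalidSequenceError, revcomp, seq_to_codes
from .editing_quant import NoDataError, call_indels_window
from .junction_caller import IntegrationSite

#: the assay's reported background indel level (<0.1%)
DEFAULT_BACKGROUND_THRESHOLD = 0.001
CUT_OFFSET = 17  # blunt cut between protospacer bases 17 and 18


@dataclass(frozen=True)
class OffTargetSite:
    chrom: str
    start: int  # 0-based start of the 20-mer on the + strand of the genome
    strand: str
    site_sequence: str  # 20 nt + PAM, guide orientation
    n_mismatches: int
    annotation: str = "unannotated"

    @property
    def cut_position(self) -> int:
        """Genomic (+ strand) coordinate of the blunt cut."""
        if self.strand == "+":
            return self.start + CUT_OFFSET
        return self.start + 20 - CUT_OFFSET


def _scan_strand(codes: np.ndarray, guide: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(start positions, mismatch counts) of NGG-adjacent guide matches on
    one strand (codes already oriented 5'→3' for that strand)."""
    L = len(codes)
    if L < 23:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    windows = sliding_window_view(codes, 23)
    mm = (windows[:, :20] != guide).sum(axis=1)
    g = 2  # code for G
    pam_ok = (windows[:, 21] == g) & (windows[:, 22] == g)
    return np.flatnonzero(pam_ok), mm[pam_ok]


def enumerate_offtargets(
    genome: dict[str, str],
    protospacer: str,
    max_mismatches: int,
    on_target: tuple[str, int, str] | None = None,
) -> list[OffTargetSite]:
    """Hamming scan of both strands for NGG-adjacent near-matches.

    Mismatches are counted in the 20-nt protospacer only; the PAM must be
    NGG exactly.  *on_target* (chrom, 20-mer start, strand) is excluded from
    the results when given.  Sites are sorted by (mismatches, chrom, start).
    """
    if len(protospacer) != 20:
        raise InvalidSequenceError("protospacer must be 20 nt")
    if set(protospacer) - set("ACGT"):
        raise InvalidSequenceError("protospacer contains non-ACGT characters")
    if max_mismatches > 6:
        raise ValueError("max_mismatches must be <= 6")
    guide = seq_to_codes(protospacer)
    sites = []
    for chrom in genome:
        seq = genome[chrom]
        L = len(seq)
        fwd_codes = seq_to_codes(seq)
        starts, mms = _scan_strand(fwd_codes, guide)
        for pos, mm in zip(starts, mms):
            if mm <= max_mismatches:
                sites.append(
                    OffTargetSite(chrom, int(pos), "+", seq[pos:pos + 23], int(mm))
                )
        rev_codes = seq_to_codes(revcomp(seq))
        starts, mms = _scan_strand(rev_codes, guide)
        for pos, mm in zip(starts, mms):
            if mm <= max_mismatches:
                start = L - int(pos) - 23 + 3  # + strand start of the 20-mer
                sites.append(
                    OffTargetSite(chrom, start, "-", revcomp(seq[start - 3:start + 20]), int(mm))
                )
    if on_target is not None:
        sites = [
            s
            for s in sites
            if (s.chrom, s.start, s.strand) != (on_target[0], on_target[1], on_target[2])
        ]
    sites.sort(key=lambda s: (s.n_mismatches, s.chrom, s.start, s.strand))
    return sites


def annotate_sites(sites: list[OffTargetSite], features: pd.DataFrame | None) -> list[OffTargetSite]:
    """Attach a feature annotation from a BED-like frame (chrom, start, end,
    name); sites outside every feature stay 'unannotated'."""
    if features is None:
        return sites
    out = []
    for s in sites:
        hit = features[
            (features["chrom"] == s.chrom)
            & (features["start"] <= s.start)
            & (features["end"] > s.start)
        ]
        out.append(
            OffTargetSite(
                s.chrom, s.start, s.strand, s.site_sequence, s.n_mismatches,
                annotation=str(hit.iloc[0]["name"]) if len(hit) else "unannotated",
            )
        )
    return out


@dataclass
class SiteAmplicon:
    """Amplicon context for one screened site: the reference amplicon, the
    cut position inside it, and the reads to call."""

    reference_amplicon: str
    cut_site_in_amplicon: int
    reads: list[tuple[str, str]]


def screen_offtarget_indels(
    sites: list[OffTargetSite],
    amplicons: dict[str, SiteAmplicon],
    window_bp: int = 5,
    min_indel_len: int = 1,
    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD,
    on_target: SiteAmplicon | None = None,
) -> pd.DataFrame:
    """Per-site indel fractions, one row per screened site plus an on-target
    row when provided.

    *amplicons* maps ``"chrom:start:strand"`` keys (see :func:`site_key`) to
    that site's amplicon and reads.  Sites without reads get a ``no-data``
    row rather than an exception; fractions above *background_threshold*
    are flagged.
    """
    rows = []
    entries = [("OT", None, on_target)] if on_target is not None else []
    entries += [(f"OFT{i + 1}", s, amplicons.get(site_key(s))) for i, s in enumerate(sites)]
    for label, site, amp in entries:
        row = {
            "site": label,
            "chrom": site.chrom if site else None,
            "start": site.start if site else None,
            "strand": site.strand if site else None,
            "n_mismatches": site.n_mismatches if site else 0,
            "annotation": site.annotation if site else "on-target",
        }
        if amp is None or not amp.reads:
            row.update({"n_reads": 0, "indel_fraction": np.nan, "status": "no-data", "flagged": False})
        else:
            try:
                res = call_indels_window(
                    amp.reads,
                    amp.reference_amplicon,
                    amp.cut_site_in_amplicon,
                    window_bp=window_bp,
                    min_indel_len=min_indel_len,
                )
            except NoDataError:
                row.update({"n_reads": 0, "indel_fraction": np.nan, "status": "no-data", "flagged": False})
                rows.append(row)
                continue
            row.update(
                {
                    "n_reads": res.n_reads_analyzed,
                    "indel_fraction": res.indel_fraction,
                    "status": "ok",
                    "flagged": bool(res.indel_fraction > background_threshold),
                }
            )
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["site", "chrom", "start", "strand", "n_mismatches", "annotation",
                 "n_reads", "indel_fraction", "status", "flagged"],
    )


def site_key(site: OffTargetSite) -> str:
    return f"{site.chrom}:{site.start}:{site.strand}"


def site_amplicon_context(
    genome: dict[str, str],
    site: OffTargetSite,
    upstream: int = 110,
    downstream: int = 110,
) -> tuple[str, int]:
    """(reference amplicon, cut position inside it) for a screened site."""
    cut = site.cut_position
    seq = genome[site.chrom]
    lo = max(0, cut - upstream)
    hi = min(len(seq), cut + downstream)
    return seq[lo:hi], cut - lo


def compare_sites_to_integrations(
    offtargets: list[OffTargetSite],
    sites: list[IntegrationSite],
    distance_bp: int = 1000,
) -> pd.DataFrame:
    """Does any detected integration site fall near a predicted off-target?

    One row per integration site with the nearest predicted off-target cut
    position and a correspond/no-correspond verdict at *distance_bp*.
    """
    rows = []
    for site in sites:
        same = [
            abs(site.representative_coord - ot.cut_position)
            for ot in offtargets
            if ot.chrom == site.host_chrom
        ]
        dist = min(same) if same else None
        rows.append(
            {
                "host_chrom": site.host_chrom,
                "coord": site.representative_coord,
                "classification": site.classification,
                "nearest_offtarget_distance": dist,
                "verdict": "correspond" if dist is not None and dist <= distance_bp else "no-correspond",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["host_chrom", "coord", "classification", "nearest_offtarget_distance", "verdict"],
    )


def write_offtargets_bed(sites: list[OffTargetSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(f"{s.chrom}\t{s.start}\t{s.start + 20}\tmm{s.n_mismatches}\t{s.n_mismatches}\t{s.strand}\n")
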