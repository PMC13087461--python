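"""In-silico three-primer PCR and amplicon-based editing quantification.

The three-primer assay distinguishes editing outcomes by product size: two
outer primers anneal to genomic sequence outside the homology arms and one
primer anneals inside the donor cDNA.  Unedited and NHEJ alleles yield the
long outer-primer product (~2.5 kb in the bundled fixtures); precise HDR
knock-in alleles yield a shorter outer×cDNA product (~1.6 kb); episomal
vector, which lacks the outer-primer sites, yields nothing.  HDR efficiency
is the HDR band's share of total band intensity, and indel frequency is
called per read from a banded global alignment around the cut site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit
from numpy.lib.stride_tricks import sliding_window_view

from .dna import InvalidSequenceError, revcomp, seq_to_codes
from .vector_model import AlleleModel

DEFAULT_MAX_MISMATCHES = 1
DEFAULT_MIN_PRODUCT = 50
#: long products amplify poorly; this suppresses the outer-primer product on
#: the HDR allele and reproduces the two-band gel pattern
DEFAULT_MAX_PRODUCT = 3500
ANCHOR_3PRIME = 3  # 3'-terminal bases that must match exactly

DEFAULT_WINDOW_BP = 5
DEFAULT_MIN_INDEL_LEN = 1


class BandWidthError(ValueError):
    """Alignment band narrower than the read/reference length difference."""


class NoDataError(ValueError):
    """No analyzable reads (or no nonzero band) to quantify."""


@dataclass(frozen=True)
class PrimerSet:
    """Three-primer assay: outer-host forward, outer-host reverse, and a
    donor-internal primer opposing the forward outer primer."""

    p_out5: str
    p_out3: str
    p_cdna: str

    def __post_init__(self) -> None:
        for name in ("p_out5", "p_out3", "p_cdna"):
            seq = getattr(self, name)
            if set(seq) - set("ACGT"):
                raise InvalidSequenceError(f"primer {name} contains degenerate/non-ACGT bases")
            if len(seq) < 15:
                raise ValueError(f"primer {name} shorter than 15 nt")

    def items(self):
        return [("p_out5", self.p_out5), ("p_out3", self.p_out3), ("p_cdna", self.p_cdna)]


@dataclass(frozen=True)
class PcrProduct:
    interval: tuple[int, int]  # template coordinates, 0-based half-open
    length: int
    primer_pair: tuple[str, str]  # (forward primer name, reverse primer name)


def _binding_sites(template_codes: np.ndarray, primer: str, max_mismatches: int) -> np.ndarray:
    """Start positions where *primer* (given 5'→3' along the template strand
    searched) binds with ≤ max_mismatches, 3'-terminal bases exact."""
    k = len(primer)
    if len(template_codes) < k:
        return np.empty(0, dtype=np.int64)
    p = seq_to_codes(primer)
    windows = sliding_window_view(template_codes, k)
    mm = (windows != p).sum(axis=1)
    exact3 = (windows[:, -ANCHOR_3PRIME:] == p[-ANCHOR_3PRIME:]).all(axis=1)
    return np.flatnonzero((mm <= max_mismatches) & exact3)


def insilico_pcr(
    template: str,
    primers: PrimerSet,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    min_len: int = DEFAULT_MIN_PRODUCT,
    max_len: int = DEFAULT_MAX_PRODUCT,
) -> list[PcrProduct]:
    """Enumerate convergent primer-pair products on *template*.

    Product length runs from the 5' end of the forward primer site to the
    5' end of the reverse primer site, inclusive.
    """
    if not max_len > min_len >= 50:
        raise ValueError("require max_len > min_len >= 50")
    codes = seq_to_codes(template)
    fwd: dict[str, np.ndarray] = {}
    rev: dict[str, np.ndarray] = {}
    for name, seq in primers.items():
        fwd[name] = _binding_sites(codes, seq, max_mismatches)
        rev[name] = _binding_sites(codes, revcomp(seq), max_mismatches)
    products = []
    for fname, fsites in fwd.items():
        for rname, rsites in rev.items():
            k_rev = len(dict(primers.items())[rname])
            for i in fsites:
                for j in rsites:
                    length = int(j) + k_rev - int(i)
                    if min_len <= length <= max_len:
                        products.append(
                            PcrProduct((int(i), int(j) + k_rev), length, (fname, rname))
                        )
    products.sort(key=lambda p: (p.interval, p.primer_pair))
    return products


def product_class(primer_pair: tuple[str, str]) -> str:
    """Gel-band class of a product: donor-internal primer ⇒ HDR band."""
    return "HDR" if "p_cdna" in primer_pair else "WT/NHEJ"


def predict_bands(
    alleles: list[AlleleModel],
    primers: PrimerSet,
    **pcr_kwargs,
) -> pd.DataFrame:
    """Expected PCR products per allele, one row per (allele, product)."""
    rows = []
    for allele in alleles:
        for prod in insilico_pcr(allele.sequence, primers, **pcr_kwargs):
            rows.append(
                {
                    "allele": allele.label,
                    "allele_class": product_class(prod.primer_pair),
                    "predicted_length": prod.length,
                    "start": prod.interval[0],
                    "end": prod.interval[1],
                    "primer_pair": "x".join(prod.primer_pair),
                }
            )
    return pd.DataFrame(
        rows, columns=["allele", "allele_class", "predicted_length", "start", "end", "primer_pair"]
    )


def band_table_from_read_lengths(
    read_lengths: list[int],
    predicted: pd.DataFrame,
    rel_tolerance: float = 0.15,
) -> pd.DataFrame:
    """Band intensities as read counts per product class.

    Each read is assigned to the predicted product class whose length is
    nearest its own (within *rel_tolerance*); unassignable reads are
    dropped.  Mirrors quantifying a gel by sequencing the excised bands.
    """
    classes = (
        predicted.groupby("allele_class")["predicted_length"].min().to_dict()
    )
    counts = {cls: 0 for cls in classes}
    for L in read_lengths:
        best, best_d = None, None
        for cls, plen in classes.items():
            d = abs(L - plen)
            if best_d is None or d < best_d:
                best, best_d = cls, d
        if best is not None and best_d <= rel_tolerance * classes[best]:
            counts[best] += 1
    rows = [
        {"allele_class": cls, "predicted_length": classes[cls], "intensity": float(counts[cls])}
        for cls in sorted(classes)
    ]
    return pd.DataFrame(rows, columns=["allele_class", "predicted_length", "intensity"])


def quantify_hdr_from_bands(bands: pd.DataFrame, molar_correction: bool = False) -> float:
    """HDR fraction = HDR band intensity over total band intensity.

    With *molar_correction* each intensity is divided by its product length
    first (mass → molarity), mirroring an optional gel normalisation.
    """
    if (bands["intensity"] < 0).any():
        raise ValueError("band intensities must be nonnegative")
    weights = bands["intensity"].astype(float)
    if molar_correction:
        weights = weights / bands["predicted_length"].astype(float)
    total = weights.sum()
    if total <= 0:
        raise NoDataError("all band intensities are zero; HDR fraction undefined")
    hdr = weights[bands["allele_class"] == "HDR"].sum()
    return float(hdr / total)


# ---------------------------------------------------------------------------
# Banded global alignment with affine gaps
# ---------------------------------------------------------------------------

_NEG = -(1 << 40)


@njit(cache=True)
def _banded_affine(q, r, dlo, W, match, mismatch, gap_open, gap_extend):
    n = q.shape[0]
    m = r.shape[0]
    M = np.full((n + 1, W), _NEG, np.int64)
    X = np.full((n + 1, W), _NEG, np.int64)  # gap in read (consumes reference, D)
    Y = np.full((n + 1, W), _NEG, np.int64)  # gap in reference (consumes read, I)
    Mp = np.full((n + 1, W), np.int8(-1), np.int8)
    Xp = np.full((n + 1, W), np.int8(-1), np.int8)
    Yp = np.full((n + 1, W), np.int8(-1), np.int8)
    c00 = -dlo
    M[0, c00] = 0
    Mp[0, c00] = 3  # start marker
    for j in range(1, m + 1):
        c = j - dlo
        if c >= W:
            break
        fm = M[0, c - 1] + gap_open + gap_extend
        fx = X[0, c - 1] + gap_extend
        if fm >= fx:
            X[0, c] = fm
            Xp[0, c] = 0
        else:
            X[0, c] = fx
            Xp[0, c] = 1
    for i in range(1, n + 1):
        c0 = -i - dlo
        if 0 <= c0 < W - 1:
            fm = M[i - 1, c0 + 1] + gap_open + gap_extend
            fx = X[i - 1, c0 + 1] + gap_open + gap_extend
            fy = Y[i - 1, c0 + 1] + gap_extend
            best, p = fm, 0
            if fx > best:
                best, p = fx, 1
            if fy > best:
                best, p = fy, 2
            Y[i, c0] = best
            Yp[i, c0] = p
        jlo = i + dlo
        if jlo < 1:
            jlo = 1
        jhi = i + dlo + W - 1
        if jhi > m:
            jhi = m
        for j in range(jlo, jhi + 1):
            c = j - i - dlo
            s = match if q[i - 1] == r[j - 1] else mismatch
            bm, bx, by = M[i - 1, c], X[i - 1, c], Y[i - 1, c]
            best, p = bm, 0
            if bx > best:
                best, p = bx, 1
            if by > best:
                best, p = by, 2
            M[i, c] = best + s
            Mp[i, c] = p
            if c - 1 >= 0:
                fm = M[i, c - 1] + gap_open + gap_extend
                fx = X[i, c - 1] + gap_extend
                fy = Y[i, c - 1] + gap_open + gap_extend
                best, p = fm, 0
                if fx > best:
                    best, p = fx, 1
                if fy > best:
                    best, p = fy, 2
                X[i, c] = best
                Xp[i, c] = p
            if c + 1 < W:
                fm = M[i - 1, c + 1] + gap_open + gap_extend
                fx = X[i - 1, c + 1] + gap_open + gap_extend
                fy = Y[i - 1, c + 1] + gap_extend
                best, p = fm, 0
                if fx > best:
                    best, p = fx, 1
                if fy > best:
                    best, p = fy, 2
                Y[i, c] = best
                Yp[i, c] = p
    return M, X, Y, Mp, Xp, Yp


@dataclass
class AmpliconAlignment:
    """Global alignment of a read to a reference amplicon.

    ``ops`` is a run-length edit script over {=, X, I, D}; I consumes read
    only, D consumes reference only.
    """

    score: int
    ops: list[tuple[str, int]]

    @property
    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)

    def indels(self) -> list[tuple[str, int, int]]:
        """(op, reference_position, length) for every I/D run; an insertion's
        position is the reference boundary it sits on."""
        out = []
        ref_pos = 0
        for op, n in self.ops:
            if op == "I":
                out.append(("I", ref_pos, n))
            elif op == "D":
                out.append(("D", ref_pos, n))
                ref_pos += n
            else:
                ref_pos += n
        return out


def align_amplicon(
    read: str,
    reference: str,
    band_width: int | None = None,
    match: int = 2,
    mismatch: int = -4,
    gap_open: int = -6,
    gap_extend: int = -1,
) -> AmpliconAlignment:
    """Banded global alignment with affine gaps (length-k gap costs
    ``gap_open + k*gap_extend``).

    Tie-breaking is deterministic: diagonal (match/mismatch) beats a gap,
    and a gap in the read (D) beats a gap in the reference (I).  The band
    must be at least as wide as the read/reference length difference.
    """
    n, m = len(read), len(reference)
    if band_width is None:
        band_width = abs(n - m) + 16
    if abs(n - m) > band_width:
        raise BandWidthError(
            f"band_width {band_width} < length difference {abs(n - m)}"
        )
    if n == 0:
        return AmpliconAlignment(gap_open + m * gap_extend if m else 0, [("D", m)] if m else [])
    if m == 0:
        return AmpliconAlignment(gap_open + n * gap_extend, [("I", n)])
    dlo = min(0, m - n) - band_width
    dhi = max(0, m - n) + band_width
    W = dhi - dlo + 1
    q = seq_to_codes(read)
    r = seq_to_codes(reference)
    M, X, Y, Mp, Xp, Yp = _banded_affine(q, r, dlo, W, match, mismatch, gap_open, gap_extend)

    cend = m - n - dlo
    finals = (M[n, cend], X[n, cend], Y[n, cend])
    state = 0
    if finals[1] > finals[state]:
        state = 1
    if finals[2] > finals[state]:
        state = 2
    score = int(finals[state])
    ops_rev: list[str] = []
    i, j = n, m
    while not (i == 0 and j == 0):
        c = j - i - dlo
        if state == 0:
            prev = Mp[i, c]
            ops_rev.append("=" if q[i - 1] == r[j - 1] else "X")
            i, j = i - 1, j - 1
        elif state == 1:
            prev = Xp[i, c]
            ops_rev.append("D")
            j -= 1
        else:
            prev = Yp[i, c]
            ops_rev.append("I")
            i -= 1
        state = int(prev)
    ops: list[tuple[str, int]] = []
    for op in reversed(ops_rev):
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + 1)
        else:
            ops.append((op, 1))
    return AmpliconAlignment(score, ops)


# ---------------------------------------------------------------------------
# Indel calling in a cut-site window
# ---------------------------------------------------------------------------

def _load_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(reads), "fastq")]
    return list(reads)


@dataclass
class IndelCallResult:
    indel_fraction: float
    n_reads_analyzed: int
    n_reads_failed: int
    per_read: pd.DataFrame


def call_indels_window(
    reads,
    reference_amplicon: str,
    cut_site_in_amplicon: int,
    window_bp: int = DEFAULT_WINDOW_BP,
    min_indel_len: int = DEFAULT_MIN_INDEL_LEN,
    band_width: int | None = None,
    max_len_diff: int = 200,
) -> IndelCallResult:
    """Per-read indel calls around the cut site.

    A read is indel-positive when its alignment to the reference amplicon
    contains an insertion or deletion of ≥ *min_indel_len* bp overlapping
    ``[cut − window, cut + window)``.  Reads whose length differs from the
    reference by more than *max_len_diff* cannot be aligned globally and are
    excluded (counted in ``n_reads_failed``).
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    read_list = _load_reads(reads)
    lo, hi = cut_site_in_amplicon - window_bp, cut_site_in_amplicon + window_bp
    rows = []
    n_failed = 0
    for rid, seq in read_list:
        if abs(len(seq) - len(reference_amplicon)) > max_len_diff:
            n_failed += 1
            continue
        aln = align_amplicon(seq, reference_amplicon, band_width=band_width)
        positive = False
        largest = 0
        for op, pos, length in aln.indels():
            if length < min_indel_len:
                continue
            if op == "I":
                hit = lo <= pos <= hi
            else:
                hit = pos < hi and pos + length > lo
            if hit:
                positive = True
                largest = max(largest, length)
        rows.append({"read_id": rid, "indel": positive, "largest_indel": largest})
    per_read = pd.DataFrame(rows, columns=["read_id", "indel", "largest_indel"])
    if per_read.empty:
        raise NoDataError("zero analyzable reads for indel calling")
    fraction = float(per_read["indel"].mean())
    return IndelCallResult(fraction, len(per_read), n_failed, per_read)


# ---------------------------------------------------------------------------
# Homology-arm junction fidelity
# ---------------------------------------------------------------------------

@dataclass
class FidelityResult:
    verdict: str  # "precise" or "imprecise"
    n_reads_analyzed: int
    n_reads_excluded: int
    consensus_mismatches: int
    consensus_indels: int
    per_read: pd.DataFrame


def verify_junction_fidelity(
    reads,
    hdr_allele: AlleleModel,
    junction: str = "5prime",
    flank_bp: int = 200,
    max_allowed_mismatches: int = 0,
    min_identity: float = 0.7,
) -> FidelityResult:
    """Check that reads across a homology-arm junction match the expected
    knock-in sequence.

    Each read is aligned to the HDR allele's junction region (± *flank_bp*
    around the cassette boundary); a majority-vote consensus over reference
    columns is compared against the model.  The verdict is "precise" when
    the consensus has no indels and at most *max_allowed_mismatches*
    mismatches.  Reads below *min_identity* to the region (e.g. episomal
    vector reads lacking the genomic flank) are excluded.
    """
    if flank_bp < 20:
        raise ValueError("flank_bp must be >= 20")
    if hdr_allele.insert_interval is None:
        raise ValueError("HDR allele lacks an insert_interval; cannot locate junction")
    if junction not in ("5prime", "3prime"):
        raise ValueError("junction must be '5prime' or '3prime'")
    j = hdr_allele.insert_interval[0] if junction == "5prime" else hdr_allele.insert_interval[1]
    lo = max(0, j - flank_bp)
    hi = min(len(hdr_allele.sequence), j + flank_bp)
    region = hdr_allele.sequence[lo:hi]
    if not region:
        raise ValueError("junction region absent from allele")
    read_list = _load_reads(reads)
    m = len(region)
    col_votes = [dict() for _ in range(m)]  # base or '-' per reference column
    ins_votes = np.zeros(m + 1, dtype=int)
    rows = []
    n_excluded = 0
    for rid, seq in read_list:
        if abs(len(seq) - m) > max(100, m // 2):
            n_excluded += 1
            continue
        aln = align_amplicon(seq, region)
        matches = sum(n for op, n in aln.ops if op == "=")
        if matches / m < min_identity:
            n_excluded += 1
            continue
        mismatches = sum(n for op, n in aln.ops if op == "X")
        indels = sum(n for op, n in aln.ops if op in "ID")
        rows.append({"read_id": rid, "mismatches": mismatches, "indel_bases": indels})
        ref_pos = 0
        read_pos = 0
        for op, n in aln.ops:
            if op in "=X":
                for k in range(n):
                    b = seq[read_pos + k]
                    votes = col_votes[ref_pos + k]
                    votes[b] = votes.get(b, 0) + 1
                ref_pos += n
                read_pos += n
            elif op == "D":
                for k in range(n):
                    votes = col_votes[ref_pos + k]
                    votes["-"] = votes.get("-", 0) + 1
                ref_pos += n
            else:
                ins_votes[ref_pos] += 1
                read_pos += n
    per_read = pd.DataFrame(rows, columns=["read_id", "mismatches", "indel_bases"])
    if per_read.empty:
        return FidelityResult("no-data", 0, n_excluded, 0, 0, per_read)
    n_used = len(per_read)
    cons_mm = 0
    cons_indel = int((ins_votes > n_used / 2).sum())
    for pos, votes in enumerate(col_votes):
        if not votes:
            continue
        top = max(sorted(votes), key=lambda b: votes[b])
        if top == "-":
            cons_indel += 1
        elif top != region[pos]:
            cons_mm += 1
    verdict = "precise" if cons_indel == 0 and cons_mm <= max_allowed_mismatches else "imprecise"
    return FidelityResult(verdict, n_used, n_excluded, cons_mm, cons_indel, per_read)
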