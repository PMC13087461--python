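"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package implementations they
check: plain unbanded dynamic programming, base-by-base CIGAR walking,
all-pairs clustering, and sliding-window mismatch scans.
"""

from __future__ import annotations

NEG = float("-inf")


def nw_affine_score(a: str, b: str, match=2, mismatch=-4, gap_open=-6, gap_extend=-1) -> int:
    """Unbanded global affine-gap alignment score; a length-k gap costs
    gap_open + k*gap_extend."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    M[0][0] = 0
    for j in range(1, m + 1):
        X[0][j] = max(M[0][j - 1] + gap_open, X[0][j - 1]) + gap_extend
    for i in range(1, n + 1):
        Y[i][0] = max(M[i - 1][0] + gap_open, Y[i - 1][0]) + gap_extend
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i][j - 1] + gap_open, X[i][j - 1], Y[i][j - 1] + gap_open) + gap_extend
            Y[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_open, Y[i - 1][j]) + gap_extend
    return int(max(M[n][m], X[n][m], Y[n][m]))


def walk_cigar(cigar: str, ref_start: int, strand: str, read_length: int):
    """Base-by-base CIGAR walk returning (read_interval in original read
    orientation, ref_interval)."""
    import re

    ops = [(m.group(2), int(m.group(1))) for m in re.finditer(r"(\d+)([MIDNSH=X])", cigar)]
    q = 0  # position in stored SEQ orientation
    ref = ref_start
    q_positions = []
    for op, n in ops:
        for _ in range(n):
            if op in "M=X":
                q_positions.append(q)
                q += 1
                ref += 1
            elif op == "I":
                q_positions.append(q)
                q += 1
            elif op in "DN":
                ref += 1
            elif op in "SH":
                q += 1
    q_lo, q_hi = min(q_positions), max(q_positions) + 1
    if strand == "-":
        q_lo, q_hi = read_length - q_hi, read_length - q_lo
    return (q_lo, q_hi), (ref_start, ref)


def single_linkage_clusters(coords: list[int], merge_distance: int) -> list[list[int]]:
    """All-pairs single-linkage clustering of 1-D coordinates."""
    items = list(enumerate(coords))
    parent = list(range(len(coords)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, ci in items:
        for j, cj in items:
            if i < j and abs(ci - cj) <= merge_distance:
                parent[find(i)] = find(j)
    groups = {}
    for i, c in items:
        groups.setdefault(find(i), []).append(c)
    return sorted(sorted(g) for g in groups.values())


def scan_offtargets_bruteforce(genome: dict[str, str], protospacer: str, max_mm: int):
    """Sliding-window mismatch scan of both strands for NGG-adjacent sites;
    returns {(chrom, plus_strand_start_of_20mer, strand, n_mismatches)}."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def rc(s):
        return "".join(comp[c] for c in reversed(s))

    found = set()
    for chrom, seq in genome.items():
        L = len(seq)
        for i in range(L - 22):
            window = seq[i:i + 23]
            if window[21:23] == "GG":
                mm = sum(1 for x, y in zip(window[:20], protospacer) if x != y)
                if mm <= max_mm:
                    found.add((chrom, i, "+", mm))
            w_rc = rc(window)
            if w_rc[21:23] == "GG":
                mm = sum(1 for x, y in zip(w_rc[:20], protospacer) if x != y)
                if mm <= max_mm:
                    found.add((chrom, i + 3, "-", mm))
    return found
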