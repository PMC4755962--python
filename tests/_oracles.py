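"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the slowest, most literal method
available (quadratic DP, exhaustive scans) and share no code with the
package implementation.
"""

from __future__ import annotations

NEG_INF = float("-inf")

# BLOSUM62 in the standard 20-letter ordering, transcribed column table
_B62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_B62_ROWS = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""

BLOSUM62: dict[tuple[str, str], int] = {}
for _i, _row in enumerate(_B62_ROWS.strip().splitlines()):
    for _j, _v in enumerate(_row.split()):
        BLOSUM62[(_B62_ORDER[_i], _B62_ORDER[_j])] = int(_v)
for _c in _B62_ORDER + "X":
    BLOSUM62[("X", _c)] = 0
    BLOSUM62[(_c, "X")] = 0


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> float:
    """Smith-Waterman local alignment score, affine gaps, Gotoh recursion.

    Opening a gap of length L costs gap_open + L * gap_extend.  The empty
    alignment is allowed, so the minimum score is 0.
    """
    n, m = len(a), len(b)
    best = 0.0
    H_prev = [0.0] * (m + 1)
    E_prev = [NEG_INF] * (m + 1)  # gap in a (vertical) carried per column
    for i in range(1, n + 1):
        H_cur = [0.0] * (m + 1)
        E_cur = [NEG_INF] * (m + 1)
        F = NEG_INF  # gap in b (horizontal) within this row
        for j in range(1, m + 1):
            E_cur[j] = max(
                H_prev[j] - gap_open - gap_extend, E_prev[j] - gap_extend
            )
            F = max(H_cur[j - 1] - gap_open - gap_extend, F - gap_extend)
            diag = H_prev[j - 1] + BLOSUM62[(a[i - 1], b[j - 1])]
            H_cur[j] = max(0.0, diag, E_cur[j], F)
            if H_cur[j] > best:
                best = H_cur[j]
        H_prev, E_prev = H_cur, E_cur
    return best


def brute_force_top_hits(hits) -> dict[str, str]:
    """Argmax per query under the tie chain bit desc, evalue asc, subject
    lexicographic — computed by exhaustive comparison, no sorting."""
    best = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        if (h.bit_score, -h.evalue) > (cur.bit_score, -cur.evalue) or (
            (h.bit_score, h.evalue) == (cur.bit_score, cur.evalue)
            and h.subject_id < cur.subject_id
        ):
            best[h.query_id] = h
    return {q: h.subject_id for q, h in best.items()}


def brute_force_reciprocal(forward_hits, reverse_hits) -> set[tuple[str, str]]:
    """Reciprocity over all candidate pairs, from first principles."""
    fwd = brute_force_top_hits(forward_hits)
    rev = brute_force_top_hits(reverse_hits)
    out = set()
    for t in fwd:
        for r in rev:
            if fwd[t] == r and rev[r] == t:
                out.add((t, r))
    return out


def brute_force_upstream_gap(gene, all_genes, genome_length: int) -> int:
    """Literal scan over every other gene for the upstream intergenic room."""
    if gene.strand == "+":
        prev_ends = [g.end for g in all_genes if g is not gene and g.end < gene.start]
        prev = max(prev_ends) if prev_ends else 0
        return max(0, gene.start - 1 - prev)
    next_starts = [
        g.start for g in all_genes if g is not gene and g.start > gene.end
    ]
    nxt = min(next_starts) if next_starts else genome_length + 1
    return max(0, nxt - gene.end - 1)


def brute_force_upstream_slice(gene, residues: str, take: int) -> tuple[str, tuple[int, int]]:
    """Independent slicer: the `take` bases 5' of the start codon in
    transcription direction, truncated at contig ends."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    if gene.strand == "+":
        lo = max(1, gene.start - take)
        hi = gene.start - 1
        return residues[lo - 1 : hi], (lo, hi)
    lo = gene.end + 1
    hi = min(len(residues), gene.end + take)
    forward = residues[lo - 1 : hi]
    return "".join(comp[c] for c in reversed(forward)), (lo, hi)
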