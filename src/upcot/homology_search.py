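"""All-vs-all protein similarity search between two proteomes.

The ortholog step needs, for every protein of one genome, its best-scoring
match in another genome above an E-value cutoff.  Two routes produce the
required hit tables:

* a built-in exact Smith-Waterman local aligner (Biopython's C kernel,
  BLOSUM62, affine gaps 11/1) with Karlin-Altschul E-value statistics —
  exhaustive and exact, intended for desk-scale proteomes; or
* ingestion of a standard 12-column tabular hit file ("outfmt 6") produced
  by an external search tool, for real genome scale.

Both routes yield a :class:`HitTable` with an identical sort contract, so
everything downstream is agnostic to the route.

E-values follow the Karlin-Altschul statistic for gapped BLOSUM62 (lambda
0.267, K 0.041): bit = (lambda*S - ln K)/ln 2 and E = m*n*2**(-bit) with m,
n the two sequence lengths.  No effective-length correction is applied;
only the ranking and a coarse cutoff matter to reciprocal-best-hit calling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Mapping

from Bio import Align
from Bio.Align import substitution_matrices

PROTEIN_ALPHABET = frozenset("ARNDCQEGHILKMFPSTWYVX")

TABULAR_COLUMNS = 12


class HitTableParseError(ValueError):
    """A tabular hit file line could not be parsed."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    Defaults are the standard gapped-BLOSUM62 parameters (gap open 11,
    gap extend 1, lambda 0.267, K 0.041).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("Karlin-Altschul constants must be positive")

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        return m * n * 2.0 ** (-self.bit_score(raw_score))


@dataclass(frozen=True)
class Hit:
    """One directed similarity hit. ``raw_score`` is None for hits loaded
    from an external tabular file (only bits and E-value are carried)."""

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    raw_score: float | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("E-value must be non-negative")


def _hit_sort_key(hit: Hit) -> tuple:
    return (-hit.bit_score, hit.evalue, hit.subject_id)


@dataclass
class HitTable:
    """Directed hits from one genome's proteome against another's.

    Hits are sorted, within each query, by descending bit score, then
    ascending E-value, then lexicographic subject id — the tie chain that
    makes best-hit extraction deterministic.
    """

    query_genome_id: str
    subject_genome_id: str
    hits: list[Hit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.query_genome_id == self.subject_genome_id:
            raise ValueError(
                f"self-comparison of genome {self.query_genome_id!r} refused"
            )

    def sort(self) -> None:
        self.hits.sort(key=lambda h: (h.query_id,) + _hit_sort_key(h))


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(matrix_name).copy()
    # X is treated as fully ambiguous: zero against everything.
    if "X" in matrix.alphabet:
        for c in matrix.alphabet:
            matrix["X", c] = 0.0
            matrix[c, "X"] = 0.0
    aligner = Align.PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    return aligner


def _check_alphabet(sequence: str, label: str) -> None:
    bad = set(sequence) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(
            f"{label}: characters outside the amino-acid alphabet+X: "
            f"{sorted(bad)}"
        )


def score_pair(
    a: str,
    b: str,
    scheme: ScoringScheme = ScoringScheme(),
    query_id: str = "query",
    subject_id: str = "subject",
) -> Hit:
    """Smith-Waterman local alignment of two protein sequences.

    Returns the raw local-alignment score (0 when no positive-scoring
    local alignment exists), the bit score and the E-value for the pair.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    _check_alphabet(a, query_id)
    _check_alphabet(b, subject_id)
    raw = float(_aligner(scheme.matrix_name, scheme.gap_open, scheme.gap_extend).score(a, b))
    raw = max(0.0, raw)
    return Hit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=scheme.bit_score(raw),
        evalue=scheme.evalue(raw, len(a), len(b)),
    )


def search(
    query: Mapping[str, str],
    subject: Mapping[str, str],
    query_genome_id: str,
    subject_genome_id: str,
    scheme: ScoringScheme = ScoringScheme(),
    evalue_cutoff: float = 1e-3,
) -> HitTable:
    """Score every query x subject pair; keep hits with E <= cutoff.

    ``query`` and ``subject`` map locus_tag -> amino-acid sequence
    (see :meth:`AnnotatedGenome.proteome`).
    """
    if not query or not subject:
        raise ValueError("both proteomes must be non-empty")
    table = HitTable(query_genome_id, subject_genome_id)
    for q_tag in sorted(query):
        for s_tag in sorted(subject):
            hit = score_pair(
                query[q_tag], subject[s_tag], scheme,
                query_id=q_tag, subject_id=s_tag,
            )
            if hit.evalue <= evalue_cutoff:
                table.hits.append(hit)
    table.sort()
    return table


def load_hit_table(
    path: str | Path, query_genome_id: str, subject_genome_id: str
) -> HitTable:
    """Load a 12-column tabular hit file (query, subject, %id, length,
    mismatches, gapopens, qstart, qend, sstart, send, evalue, bitscore).

    Only columns 1, 2, 11 and 12 are consumed; raw scores are unset.
    """
    table = HitTable(query_genome_id, subject_genome_id)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != TABULAR_COLUMNS:
                raise HitTableParseError(
                    f"{path} line {line_no}: expected {TABULAR_COLUMNS} "
                    f"columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bit = float(fields[11])
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path} line {line_no}: {exc}"
                ) from exc
            table.hits.append(
                Hit(query_id=fields[0], subject_id=fields[1],
                    bit_score=bit, evalue=evalue)
            )
    table.sort()
    return table


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Export a HitTable in the 12-column tabular layout.

    Alignment-detail columns the built-in aligner does not track (%id,
    length, mismatches, gap opens, coordinates) are written as zeros; a
    reload preserves exactly what best-hit extraction consumes.
    """
    with open(path, "w") as fh:
        for h in table.hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t0.0\t0\t0\t0\t0\t0\t0\t0\t"
                f"{h.evalue:.6g}\t{h.bit_score:.3f}\n"
            )


def top_hit_per_query(table: HitTable) -> dict[str, str]:
    """Best subject per query under the documented tie chain.

    Queries with no retained hit are absent from the map.
    """
    best: dict[str, Hit] = {}
    for hit in table.hits:
        cur = best.get(hit.query_id)
        if cur is None or _hit_sort_key(hit) < _hit_sort_key(cur):
            best[hit.query_id] = hit
    return {q: h.subject_id for q, h in best.items()}
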