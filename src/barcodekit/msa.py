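"""Global pairwise and progressive multiple sequence alignment.

Alignment here serves one purpose: put a set of closely related ~200-bp
marker sequences into a common coordinate system so distances can be
computed column-wise. The aligner is a classic three-state affine-gap
global dynamic program (Gotoh), used both for sequence pairs and — via
frequency-profile scoring — for the progressive merge along a UPGMA guide
tree ("once a gap, always a gap"). It is a documented stand-in for
Clustal-style alignment, not an emulation of any particular program; a
precomputed alignment can always be supplied instead.

Scoring conventions
-------------------
* a gap run of length L costs ``gap_open + (L - 1) * gap_extend``;
* unambiguous bases score ``match`` / ``mismatch``;
* a pair involving an ambiguity code scores 0 when the IUPAC sets are
  compatible (e.g. R vs A) and ``mismatch`` otherwise;
* ties in the traceback prefer diagonal, then up, then left.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage

from .core import Dataset, IUPAC_SETS, SequenceRecord

__all__ = [
    "ScoringParams",
    "PairwiseAlignment",
    "AlignmentMatrix",
    "pairwise_align",
    "progressive_align",
    "read_alignment",
    "write_alignment",
]

_ALPHABET = "ACGTRYSWKMBDHVN-"
_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_GAP = _CODE["-"]
_NEG = -np.inf


@dataclass(frozen=True)
class ScoringParams:
    """Affine-gap scoring parameters (Clustal-like magnitudes by default)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -10.0
    gap_extend: float = -0.5

    def matrix(self) -> np.ndarray:
        """16x16 substitution matrix over the IUPAC+gap alphabet.

        Gap rows/columns are zero; they only matter for profile scoring,
        where a gap contributes nothing to the column score.
        """
        n = len(_ALPHABET)
        S = np.zeros((n, n))
        for a in _ALPHABET[:-1]:
            for b in _ALPHABET[:-1]:
                if a in "ACGT" and b in "ACGT":
                    S[_CODE[a], _CODE[b]] = self.match if a == b else self.mismatch
                elif IUPAC_SETS[a] & IUPAC_SETS[b]:
                    S[_CODE[a], _CODE[b]] = 0.0
                else:
                    S[_CODE[a], _CODE[b]] = self.mismatch
        return S


@dataclass(frozen=True)
class PairwiseAlignment:
    """Optimal global alignment of two records."""

    id_a: str
    id_b: str
    gapped_a: str
    gapped_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped rows differ in length")
        if any(x == "-" and y == "-"
               for x, y in zip(self.gapped_a, self.gapped_b)):
            raise ValueError("gap-gap column in pairwise alignment")

    def p_distance(self) -> float:
        """Proportion of mismatching residue-residue columns."""
        pairs = [(x, y) for x, y in zip(self.gapped_a, self.gapped_b)
                 if x != "-" and y != "-"]
        if not pairs:
            return 1.0
        return sum(x != y for x, y in pairs) / len(pairs)


@dataclass
class AlignmentMatrix:
    """Equal-length gapped rows over an ordered set of record IDs."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]

    def degapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace("-", "")

    def to_codes(self) -> np.ndarray:
        """(n_rows, n_columns) uint8 code matrix over the IUPAC+gap alphabet."""
        out = np.empty((len(self.rows), self.n_columns), dtype=np.uint8)
        for i, row in enumerate(self.rows):
            out[i] = np.frombuffer(row.encode(), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for c, i in _CODE.items():
            lut[ord(c)] = i
        return lut[out]


# ---------------------------------------------------------------------------
# Gotoh core on a precomputed column-score grid
# ---------------------------------------------------------------------------

def _gotoh(grid: np.ndarray, go: float, ge: float) -> tuple[float, list[str]]:
    """Affine-gap global DP over an (n, m) pairwise column-score grid.

    Returns the optimal score and the move list from the start: 'D'
    consumes a column of both inputs, 'U' consumes only the first input
    (gap in the second), 'L' only the second. Tie-breaking prefers
    D, then U, then L, applied to both the final state and every
    traceback step. All scores are sums of the exact float parameters, so
    equality tests in the traceback are exact.
    """
    n, m = grid.shape
    M = np.full((n + 1, m + 1), _NEG)
    U = np.full((n + 1, m + 1), _NEG)
    L = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if m:
        L[0, 1:] = go + ge * np.arange(m)
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        mp, up, lp = M[i - 1], U[i - 1], L[i - 1]
        M[i, 1:] = grid[i - 1] + np.maximum(np.maximum(mp[:-1], up[:-1]), lp[:-1])
        U[i] = np.maximum(np.maximum(mp + go, up + ge), lp + go)
        # L[i, j] = go + (j-1-k)*ge + best over k<j of max(M,U)[i, k]
        best = np.maximum(M[i, :-1], U[i, :-1])
        L[i, 1:] = go + ge * (js - 1) + np.maximum.accumulate(best - ge * np.arange(m))

    i, j = n, m
    finals = (M[i, j], U[i, j], L[i, j])
    state = "DUL"[int(np.argmax(finals))]  # argmax keeps first (preferred) max
    moves: list[str] = []
    while i > 0 or j > 0:
        moves.append(state)
        if state == "D":
            i, j = i - 1, j - 1
            cands = (M[i, j], U[i, j], L[i, j])
        elif state == "U":
            i -= 1
            cands = (M[i, j] + go, U[i, j] + ge, L[i, j] + go)
        else:
            j -= 1
            cands = (M[i, j] + go, U[i, j] + go, L[i, j] + ge)
        if i == 0 and j == 0:
            break
        # the predecessor attaining the cell value; first max = D > U > L
        state = "DUL"[int(np.argmax(cands))]
    moves.reverse()
    return float(max(finals)), moves


def _encode(residues: str) -> np.ndarray:
    return np.array([_CODE[c] for c in residues], dtype=np.intp)


def pairwise_align(a: SequenceRecord, b: SequenceRecord,
                   params: ScoringParams | None = None) -> PairwiseAlignment:
    """Optimal global affine-gap alignment of two records."""
    params = params or ScoringParams()
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    S = params.matrix()
    ca, cb = _encode(a.residues), _encode(b.residues)
    grid = S[np.ix_(ca, cb)]
    score, moves = _gotoh(grid, params.gap_open, params.gap_extend)
    ga, gb, i, j = [], [], 0, 0
    for mv in moves:
        if mv == "D":
            ga.append(a.residues[i]); gb.append(b.residues[j]); i += 1; j += 1
        elif mv == "U":
            ga.append(a.residues[i]); gb.append("-"); i += 1
        else:
            ga.append("-"); gb.append(b.residues[j]); j += 1
    return PairwiseAlignment(a.id, b.id, "".join(ga), "".join(gb), score)


# ---------------------------------------------------------------------------
# Progressive alignment along a UPGMA guide tree
# ---------------------------------------------------------------------------

class _Profile:
    """A block of already-aligned rows, stored as a code matrix."""

    def __init__(self, indices: list[int], codes: np.ndarray) -> None:
        self.indices = indices          # positions in the input order
        self.codes = codes              # (n_rows, n_cols) uint8

    def freqs(self) -> np.ndarray:
        """(n_cols, 16) per-column code frequencies."""
        n_rows, n_cols = self.codes.shape
        out = np.zeros((n_cols, len(_ALPHABET)))
        for i in range(n_rows):
            out[np.arange(n_cols), self.codes[i]] += 1.0
        return out / n_rows


def _merge(pa: _Profile, pb: _Profile, S: np.ndarray,
           params: ScoringParams) -> _Profile:
    grid = pa.freqs() @ S @ pb.freqs().T
    _, moves = _gotoh(grid, params.gap_open, params.gap_extend)
    cols_a, cols_b = [], []
    ia = ib = 0
    for mv in moves:
        if mv == "D":
            cols_a.append(ia); cols_b.append(ib); ia += 1; ib += 1
        elif mv == "U":
            cols_a.append(ia); cols_b.append(-1); ia += 1
        else:
            cols_a.append(-1); cols_b.append(ib); ib += 1

    def expand(codes: np.ndarray, cols: list[int]) -> np.ndarray:
        out = np.full((codes.shape[0], len(cols)), _GAP, dtype=np.uint8)
        for k, c in enumerate(cols):
            if c >= 0:
                out[:, k] = codes[:, c]
        return out

    merged = np.vstack([expand(pa.codes, cols_a), expand(pb.codes, cols_b)])
    return _Profile(pa.indices + pb.indices, merged)


def progressive_align(dataset: Dataset,
                      params: ScoringParams | None = None) -> AlignmentMatrix:
    """Progressive multiple alignment of all records in a dataset.

    Pairwise p-distances from optimal global alignments feed a UPGMA
    guide tree; profiles are merged in guide-tree order with the same
    affine DP, scoring profile columns by frequency-weighted expected
    substitution score (gaps contribute zero). Gaps, once introduced, are
    never removed. Output rows follow the input record order, so the
    result is deterministic for a given input.
    """
    params = params or ScoringParams()
    records = dataset.records
    n = len(records)
    if n < 2:
        raise ValueError("progressive alignment needs >=2 records")
    if n == 2:
        pw = pairwise_align(records[0], records[1], params)
        return AlignmentMatrix([records[0].id, records[1].id],
                               [pw.gapped_a, pw.gapped_b])

    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(
                pairwise_align(records[i], records[j], params).p_distance())
    Z = linkage(np.asarray(condensed), method="average")

    S = params.matrix()
    profiles: dict[int, _Profile] = {
        i: _Profile([i], _encode(r.residues).astype(np.uint8)[None, :])
        for i, r in enumerate(records)
    }
    for step, (left, right, _, _) in enumerate(Z):
        pa, pb = profiles.pop(int(left)), profiles.pop(int(right))
        profiles[n + step] = _merge(pa, pb, S, params)
    final = profiles[n + len(Z) - 1]

    rows = [""] * n
    for pos, idx in enumerate(final.indices):
        rows[idx] = "".join(_ALPHABET[c] for c in final.codes[pos])
    return AlignmentMatrix([r.id for r in records], rows)


# ---------------------------------------------------------------------------
# Aligned-FASTA I/O
# ---------------------------------------------------------------------------

def write_alignment(aln: AlignmentMatrix, path: str | Path,
                    width: int = 60) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i:i + width] + "\n")


def read_alignment(path: str | Path) -> AlignmentMatrix:
    """Read a precomputed aligned FASTA (rows must be equal length)."""
    from Bio import SeqIO

    ids, rows = [], []
    for entry in SeqIO.parse(str(path), "fasta"):
        ids.append(entry.id)
        rows.append(str(entry.seq).upper().replace("U", "T"))
    if not ids:
        raise ValueError(f"{path}: no FASTA entries")
    return AlignmentMatrix(ids, rows)
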