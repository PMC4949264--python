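"""Kimura two-parameter (K2P) distances from a multiple alignment.

The K2P model corrects observed divergence for multiple hits while
distinguishing transitions (purine<->purine, pyrimidine<->pyrimidine)
from transversions. With P and Q the observed proportions of sites
showing a transition and a transversion difference,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)   [substitutions/site]

Sites where either sequence carries a gap or an ambiguity code are
excluded pair by pair (pairwise deletion), the common default of distance
software, so each pair uses the maximum number of cleanly comparable
sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .msa import AlignmentMatrix

__all__ = [
    "K2PError",
    "K2PResult",
    "DistanceMatrix",
    "k2p_pair",
    "distance_matrix",
    "k2p_from_codes",
    "write_phylip",
    "write_long_tsv",
]

_PURINE = frozenset("AG")
_VALID = frozenset("ACGT")


class K2PError(ValueError):
    """No comparable sites, or observed divergence beyond the K2P domain."""


@dataclass(frozen=True)
class K2PResult:
    """Transition/transversion proportions and corrected distance for a pair."""

    P: float
    Q: float
    n_sites: int
    d: float


def k2p_pair(row_a: str, row_b: str) -> K2PResult:
    """K2P distance between two equal-length gapped alignment rows.

    Raises :class:`K2PError` when no site is comparable or when
    ``1 - 2P - Q <= 0`` or ``1 - 2Q <= 0`` (saturation: the correction
    diverges).
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows differ in length; both must come from one alignment")
    n = ts = tv = 0
    for x, y in zip(row_a, row_b):
        if x not in _VALID or y not in _VALID:
            continue
        n += 1
        if x != y:
            if (x in _PURINE) == (y in _PURINE):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise K2PError("no comparable sites")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise K2PError(f"K2P saturation (P={P:.4g}, Q={Q:.4g})")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P=P, Q=Q, n_sites=n, d=abs(d))


@dataclass
class DistanceMatrix:
    """Symmetric K2P distance matrix keyed by record ID.

    ``P``, ``Q`` and ``n_sites`` matrices are carried along for long-form
    reporting; they are not required by downstream consumers.
    """

    ids: list[str]
    values: np.ndarray
    species_of: dict[str, str]
    P: np.ndarray | None = None
    Q: np.ndarray | None = None
    n_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("distances must be finite and >= 0")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])

    @property
    def species_list(self) -> list[str]:
        """Distinct species in first-appearance order over ids."""
        out: list[str] = []
        for rid in self.ids:
            sp = self.species_of[rid]
            if sp not in out:
                out.append(sp)
        return out

    def species_indices(self) -> dict[str, np.ndarray]:
        groups: dict[str, list[int]] = {}
        for i, rid in enumerate(self.ids):
            groups.setdefault(self.species_of[rid], []).append(i)
        return {sp: np.asarray(ix) for sp, ix in groups.items()}

    def _pair_mask(self) -> tuple[np.ndarray, np.ndarray]:
        """(upper-triangle mask, conspecific-pair mask)."""
        n = len(self.ids)
        upper = np.triu(np.ones((n, n), dtype=bool), k=1)
        sp = np.array([self.species_of[r] for r in self.ids])
        same = sp[:, None] == sp[None, :]
        return upper, same

    def intra_distances(self) -> np.ndarray:
        """All conspecific pairwise distances, pooled."""
        upper, same = self._pair_mask()
        return self.values[upper & same]

    def inter_distances(self) -> np.ndarray:
        """All heterospecific pairwise distances, pooled."""
        upper, same = self._pair_mask()
        return self.values[upper & ~same]

    def subset(self, keep_ids: list[str]) -> "DistanceMatrix":
        ix = np.array([self.ids.index(r) for r in keep_ids])
        return DistanceMatrix(
            ids=list(keep_ids),
            values=self.values[np.ix_(ix, ix)],
            species_of={r: self.species_of[r] for r in keep_ids},
            P=None if self.P is None else self.P[np.ix_(ix, ix)],
            Q=None if self.Q is None else self.Q[np.ix_(ix, ix)],
            n_sites=None if self.n_sites is None else self.n_sites[np.ix_(ix, ix)],
        )


def k2p_from_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray, np.ndarray]:
    """Vectorized all-pairs K2P over a uint8 code matrix.

    Codes 0..3 are A,C,G,T; anything else (ambiguity or gap) is excluded
    pairwise. Returns (d, P, Q, n_sites) as (n, n) arrays; entries outside
    the K2P domain or with no comparable sites are NaN in ``d`` (callers
    decide whether that is an error or a replicate to redraw).
    """
    X = codes.astype(np.int16)
    valid = X < 4
    pv = valid[:, None, :] & valid[None, :, :]
    eq = X[:, None, :] == X[None, :, :]
    purine = (X == 0) | (X == 2)  # A or G
    sameclass = purine[:, None, :] == purine[None, :, :]
    ts = (pv & ~eq & sameclass).sum(axis=-1)
    tv = (pv & ~eq & ~sameclass).sum(axis=-1)
    n = pv.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(n > 0, ts / n, np.nan)
        Q = np.where(n > 0, tv / n, np.nan)
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        d = np.where((w1 > 0) & (w2 > 0),
                     -0.5 * np.log(np.abs(w1)) - 0.25 * np.log(np.abs(w2)),
                     np.nan)
    np.fill_diagonal(d, 0.0)
    return d, P, Q, n


def distance_matrix(aln: AlignmentMatrix,
                    species_of: dict[str, str]) -> DistanceMatrix:
    """All-pairs K2P distances for an alignment.

    Any pair with no comparable sites or with saturated divergence aborts
    with a :class:`K2PError` listing the offending pairs.
    """
    if len(aln.ids) < 2:
        raise ValueError("need >=2 rows for a distance matrix")
    missing = [r for r in aln.ids if r not in species_of]
    if missing:
        raise ValueError(f"ids lacking species labels: {missing}")
    d, P, Q, n = k2p_from_codes(aln.to_codes())
    bad = np.argwhere(~np.isfinite(d))
    if len(bad):
        pairs = sorted({tuple(sorted((aln.ids[i], aln.ids[j])))
                        for i, j in bad if i != j})
        raise K2PError(f"K2P undefined for pairs: {pairs}")
    return DistanceMatrix(
        ids=list(aln.ids), values=d,
        species_of={r: species_of[r] for r in aln.ids},
        P=P, Q=Q, n_sites=n)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Square PHYLIP distance matrix with relaxed (untruncated) names."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for rid, row in zip(dm.ids, dm.values):
            # 17 significant digits: reloading reproduces the floats exactly
            fh.write(rid + "  " + "  ".join(f"{v:.17g}" for v in row) + "\n")


def write_long_tsv(dm: DistanceMatrix, path: str | Path) -> None:
    """Long-form per-pair table: id_a, id_b, P, Q, n_sites, d."""
    rows = []
    for i in range(len(dm.ids)):
        for j in range(i + 1, len(dm.ids)):
            rows.append({
                "id_a": dm.ids[i], "id_b": dm.ids[j],
                "P": None if dm.P is None else dm.P[i, j],
                "Q": None if dm.Q is None else dm.Q[i, j],
                "n_sites": None if dm.n_sites is None else int(dm.n_sites[i, j]),
                "d": dm.values[i, j],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
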