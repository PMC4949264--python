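"""Species identification against a labeled reference set.

Two classic barcode evaluation procedures, each applied leave-one-out
(every record queried once against all the others — by default the query
itself is excluded from the reference set, since matching a sequence to
itself says nothing about identification power):

* **nearest distance** — the reference(s) at the smallest K2P distance;
* **best hit ("BLAST1"-style)** — the reference(s) with the highest
  global alignment score. BLAST itself is not run: with a reference set
  of this size an exhaustive optimal-alignment ranking is exact and free
  of heuristic seeding effects.

The outcome of a query is *correct* when all tied best hits are from the
query's own species, *ambiguous* when the best hits span several species
including the query's, and *incorrect* otherwise. Ties use exact score/
distance equality — distances and scores derive deterministically from
discrete site counts, so no epsilon is warranted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import Dataset
from .k2p import DistanceMatrix
from .msa import ScoringParams, pairwise_align

__all__ = [
    "QueryOutcome",
    "IdentificationReport",
    "identify_nearest",
    "identify_blast1",
    "evaluate_all",
]


@dataclass(frozen=True)
class QueryOutcome:
    """Per-query identification result."""

    query_id: str
    method: str                  # "nearest_distance" | "blast1"
    best_hits: tuple[str, ...]   # reference ids attaining the optimum
    hit_species: frozenset
    outcome: str                 # "correct" | "ambiguous" | "incorrect"


def _classify(query_species: str, hit_species: frozenset) -> str:
    if hit_species == {query_species}:
        return "correct"
    if len(hit_species) > 1 and query_species in hit_species:
        return "ambiguous"
    return "incorrect"


def identify_nearest(dm: DistanceMatrix, query_id: str,
                     include_self: bool = False) -> QueryOutcome:
    """Assign the query to the species of its minimum-distance reference(s)."""
    if len(dm.ids) < 2:
        raise ValueError("need >=2 records")
    qi = dm.ids.index(query_id)
    row = dm.values[qi]
    refs = [i for i in range(len(dm.ids)) if include_self or i != qi]
    dmin = row[refs].min()
    hits = tuple(dm.ids[i] for i in refs if row[i] == dmin)
    species = frozenset(dm.species_of[h] for h in hits)
    return QueryOutcome(
        query_id=query_id, method="nearest_distance", best_hits=hits,
        hit_species=species,
        outcome=_classify(dm.species_of[query_id], species))


def _score_matrix(dataset: Dataset, params: ScoringParams) -> np.ndarray:
    """All-pairs global alignment scores (symmetric)."""
    n = len(dataset)
    S = np.zeros((n, n))
    recs = dataset.records
    for i in range(n):
        S[i, i] = pairwise_align(recs[i], recs[i], params).score
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = pairwise_align(recs[i], recs[j], params).score
    return S


def identify_blast1(dataset: Dataset, query_id: str,
                    params: ScoringParams | None = None,
                    include_self: bool = False,
                    scores: np.ndarray | None = None) -> QueryOutcome:
    """Assign the query to the species of its best-scoring reference(s).

    ``scores`` may carry a precomputed all-pairs score matrix (in dataset
    record order) to avoid realigning for every query.
    """
    params = params or ScoringParams()
    dataset.require_labels()
    if len(dataset) < 2:
        raise ValueError("need >=2 records")
    if scores is None:
        scores = _score_matrix(dataset, params)
    ids = dataset.ids
    qi = ids.index(query_id)
    refs = [i for i in range(len(ids)) if include_self or i != qi]
    smax = scores[qi, refs].max()
    hits = tuple(ids[i] for i in refs if scores[qi, i] == smax)
    species_of = dataset.species_of
    species = frozenset(species_of[h] for h in hits)
    return QueryOutcome(
        query_id=query_id, method="blast1", best_hits=hits,
        hit_species=species,
        outcome=_classify(species_of[query_id], species))


@dataclass(frozen=True)
class IdentificationReport:
    """Per-method success-rate triple over all queries."""

    method: str
    n_samples: int
    n_species: int
    pct_correct: float
    pct_ambiguous: float
    pct_incorrect: float
    outcomes: tuple[QueryOutcome, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "n_samples": self.n_samples,
            "n_species": self.n_species,
            "pct_correct": self.pct_correct,
            "pct_ambiguous": self.pct_ambiguous,
            "pct_incorrect": self.pct_incorrect,
        }

    def summary_tsv(self, decimals: int = 1) -> str:
        head = ("Method\tNo. of samples\tNo. of species\tCorrect (%)\t"
                "Incorrect (%)\tAmbiguous (%)")
        row = (f"{self.method}\t{self.n_samples}\t{self.n_species}\t"
               f"{self.pct_correct:.{decimals}f}\t"
               f"{self.pct_incorrect:.{decimals}f}\t"
               f"{self.pct_ambiguous:.{decimals}f}")
        return head + "\n" + row + "\n"

    def per_query_tsv(self) -> str:
        lines = ["query_id\tmethod\toutcome\tbest_hit_ids\thit_species"]
        for o in self.outcomes:
            lines.append(f"{o.query_id}\t{o.method}\t{o.outcome}\t"
                         f"{','.join(o.best_hits)}\t"
                         f"{','.join(sorted(o.hit_species))}")
        return "\n".join(lines) + "\n"

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.with_suffix(".summary.tsv").write_text(self.summary_tsv())
        prefix.with_suffix(".queries.tsv").write_text(self.per_query_tsv())
        prefix.with_suffix(".json").write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_all(dataset: Dataset, dm: DistanceMatrix | None, method: str,
                 params: ScoringParams | None = None,
                 include_self: bool = False) -> IdentificationReport:
    """Query every record once and report the correct/ambiguous/incorrect rates.

    ``method`` is "nearest_distance" (requires ``dm``) or "blast1"
    (aligns all pairs once, then ranks scores).
    """
    dataset.require_labels()
    outcomes: list[QueryOutcome] = []
    if method == "nearest_distance":
        if dm is None:
            raise ValueError("nearest_distance needs a distance matrix")
        for rid in dataset.ids:
            outcomes.append(identify_nearest(dm, rid, include_self))
    elif method == "blast1":
        scores = _score_matrix(dataset, params or ScoringParams())
        for rid in dataset.ids:
            outcomes.append(identify_blast1(dataset, rid, params,
                                            include_self, scores=scores))
    else:
        raise ValueError(f"unknown method {method!r}")
    n = len(outcomes)
    counts = {"correct": 0, "ambiguous": 0, "incorrect": 0}
    for o in outcomes:
        counts[o.outcome] += 1
    return IdentificationReport(
        method=method,
        n_samples=n,
        n_species=len(dataset.species()),
        pct_correct=100.0 * counts["correct"] / n,
        pct_ambiguous=100.0 * counts["ambiguous"] / n,
        pct_incorrect=100.0 * counts["incorrect"] / n,
        outcomes=tuple(outcomes),
    )
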