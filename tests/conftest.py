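"""Shared fixtures and small builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barcodekit import (AlignmentMatrix, Dataset, DistanceMatrix,
                        SequenceRecord, simulate)


def make_dm(entries: dict[tuple[str, str], float],
            species_of: dict[str, str]) -> DistanceMatrix:
    """Build a DistanceMatrix from a sparse {(id_a, id_b): d} mapping."""
    ids = list(species_of)
    n = len(ids)
    values = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = ids.index(a), ids.index(b)
        values[i, j] = values[j, i] = d
    return DistanceMatrix(ids=ids, values=values, species_of=dict(species_of))


def aligned_from_dataset(dataset: Dataset) -> AlignmentMatrix:
    """Treat equal-length ungapped records as an alignment."""
    return AlignmentMatrix(dataset.ids, [r.residues for r in dataset])


@pytest.fixture(scope="session")
def small_sim():
    """10 species x 2 samples + 2 outgroup, no indels (pre-aligned)."""
    return simulate(n_species=10, samples_per_species=2, indel_rate=0.0,
                    n_outgroup=2, seed=11)


@pytest.fixture(scope="session")
def small_sim_aln(small_sim):
    return aligned_from_dataset(small_sim.dataset)


@pytest.fixture()
def records():
    def build(*seqs: str, species: list[str] | None = None) -> Dataset:
        recs = []
        for i, s in enumerate(seqs):
            sp = species[i] if species else f"sp{i}"
            recs.append(SequenceRecord(id=f"r{i}", residues=s, species=sp))
        return Dataset(recs)
    return build
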