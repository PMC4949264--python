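"""Nearest-distance and best-hit identification with the three-way rules."""

import numpy as np
import pytest
from Bio import Align

from barcodekit import (Dataset, ScoringParams, SequenceRecord, evaluate_all,
                        identify_blast1, identify_nearest)

from conftest import aligned_from_dataset, make_dm


def _ds(seqs: dict[str, tuple[str, str]]) -> Dataset:
    return Dataset([SequenceRecord(id=k, residues=seq, species=sp)
                    for k, (seq, sp) in seqs.items()])


class TestNearest:
    def test_unique_conspecific_nearest_is_correct(self):
        dm = make_dm({("q", "a"): 0.01, ("q", "b"): 0.10, ("a", "b"): 0.10},
                     {"q": "X", "a": "X", "b": "Y"})
        out = identify_nearest(dm, "q")
        assert out.outcome == "correct"
        assert out.best_hits == ("a",)

    def test_cross_species_zero_tie_is_ambiguous(self):
        dm = make_dm({("q", "a"): 0.0, ("q", "b"): 0.0, ("a", "b"): 0.0},
                     {"q": "X", "a": "X", "b": "Y"})
        out = identify_nearest(dm, "q")
        assert out.outcome == "ambiguous"
        assert set(out.best_hits) == {"a", "b"}

    def test_singleton_species_is_incorrect(self):
        dm = make_dm({("q", "a"): 0.02, ("q", "b"): 0.05, ("a", "b"): 0.01,
                      ("q", "c"): 0.06, ("a", "c"): 0.04, ("b", "c"): 0.03},
                     {"q": "Solo", "a": "X", "b": "X", "c": "Y"})
        out = identify_nearest(dm, "q")
        assert out.outcome == "incorrect"

    def test_include_self_degenerates_to_self_hit(self):
        dm = make_dm({("q", "a"): 0.01, ("q", "b"): 0.1, ("a", "b"): 0.1},
                     {"q": "X", "a": "Y", "b": "Z"})
        out = identify_nearest(dm, "q", include_self=True)
        assert out.best_hits == ("q",)
        assert out.outcome == "correct"  # trivially; the reason self is excluded


class TestBlast1:
    def test_identical_conspecific_reference_wins(self):
        ds = _ds({
            "q": ("ACGTACGTAA", "X"),
            "a": ("ACGTACGTAA", "X"),
            "b": ("TTTTTTTTTT", "Y"),
        })
        out = identify_blast1(ds, "q")
        assert out.outcome == "correct"
        assert out.best_hits == ("a",)

    def test_identical_across_two_species_is_ambiguous(self):
        ds = _ds({
            "q": ("ACGTACGTAA", "X"),
            "a": ("ACGTACGTAA", "X"),
            "b": ("ACGTACGTAA", "Y"),
            "c": ("TTTTTTTTTT", "Z"),
        })
        out = identify_blast1(ds, "q")
        assert out.outcome == "ambiguous"
        assert set(out.hit_species) == {"X", "Y"}

    def test_five_record_toy_matches_independent_scorer(self):
        """Outcomes agree with a ranking computed by an independent
        aligner (biopython) under identical scoring."""
        ds = _ds({
            "q1": ("ACGTACGTACGTACGT", "X"),
            "r1": ("ACGTACGTACGAACGT", "X"),
            "r2": ("ACGTACTTACGAACGA", "Y"),
            "r3": ("ACCTACTTACGAACGA", "Y"),
            "r4": ("TTGTACGTACGTACCT", "Z"),
        })
        p = ScoringParams()
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = p.match
        aligner.mismatch_score = p.mismatch
        aligner.open_gap_score = p.gap_open
        aligner.extend_gap_score = p.gap_extend
        for query in ds.ids:
            got = identify_blast1(ds, query, p)
            scores = {r.id: aligner.score(ds[query].residues, r.residues)
                      for r in ds if r.id != query}
            smax = max(scores.values())
            hits = {rid for rid, s in scores.items() if s == smax}
            assert set(got.best_hits) == hits


class TestEvaluateAll:
    def test_fully_separable_dataset_is_all_correct(self):
        ds = _ds({
            "x1": ("ACGTACGTAC", "X"), "x2": ("ACGTACGTAC", "X"),
            "y1": ("TGCATGCATG", "Y"), "y2": ("TGCATGCATG", "Y"),
        })
        dm = make_dm({("x1", "y1"): 0.3, ("x1", "y2"): 0.3,
                      ("x2", "y1"): 0.3, ("x2", "y2"): 0.3},
                     {r.id: r.species for r in ds})
        for method in ("nearest_distance", "blast1"):
            rep = evaluate_all(ds, dm, method)
            assert rep.pct_correct == 100.0

    def test_two_of_ten_cross_ties_gives_80_0_20(self):
        species = {f"s{i}": f"sp{i // 2}" for i in range(10)}
        entries = {}
        ids = list(species)
        for i in range(10):
            for j in range(i + 1, 10):
                a, b = ids[i], ids[j]
                if species[a] == species[b]:
                    entries[(a, b)] = 0.01
                else:
                    entries[(a, b)] = 0.10
        # s8 and s9 (conspecifics) each tie at 0.01 with s0 (species sp0):
        # hit set spans two species including their own -> ambiguous. s0
        # itself stays correct because its own conspecific s1 is closer.
        entries[("s0", "s8")] = 0.01
        entries[("s0", "s9")] = 0.01
        entries[("s0", "s1")] = 0.005
        dm = make_dm(entries, species)
        rep = evaluate_all(
            Dataset([SequenceRecord(id=k, residues="ACGT", species=v)
                     for k, v in species.items()]),
            dm, "nearest_distance")
        assert rep.pct_correct == pytest.approx(80.0)
        assert rep.pct_incorrect == pytest.approx(0.0)
        assert rep.pct_ambiguous == pytest.approx(20.0)

    def test_percentages_always_sum_to_100(self, small_sim):
        from barcodekit import distance_matrix

        ds = small_sim.dataset.ingroup()
        dm = distance_matrix(aligned_from_dataset(small_sim.dataset),
                             small_sim.dataset.species_of).subset(ds.ids)
        for method in ("nearest_distance", "blast1"):
            rep = evaluate_all(ds, dm, method)
            total = rep.pct_correct + rep.pct_ambiguous + rep.pct_incorrect
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_barcoding_gap_sufficiency(self):
        """If every inter-specific distance exceeds every intra-specific one
        and all species have >=2 samples, nearest-distance is 100% correct."""
        rng = np.random.default_rng(9)
        species = {f"r{i}": f"sp{i // 2}" for i in range(12)}
        ids = list(species)
        entries = {}
        for i in range(12):
            for j in range(i + 1, 12):
                a, b = ids[i], ids[j]
                same = species[a] == species[b]
                entries[(a, b)] = (rng.uniform(0.0, 0.01) if same
                                   else rng.uniform(0.05, 0.2))
        dm = make_dm(entries, species)
        ds = Dataset([SequenceRecord(id=k, residues="ACGT", species=v)
                      for k, v in species.items()])
        rep = evaluate_all(ds, dm, "nearest_distance")
        assert rep.pct_correct == 100.0

    def test_methods_agree_on_consistent_rankings(self, small_sim):
        from barcodekit import distance_matrix

        ds = small_sim.dataset.ingroup()
        dm = distance_matrix(aligned_from_dataset(small_sim.dataset),
                             small_sim.dataset.species_of).subset(ds.ids)
        rep_n = evaluate_all(ds, dm, "nearest_distance")
        rep_b = evaluate_all(ds, dm, "blast1")
        for on, ob in zip(rep_n.outcomes, rep_b.outcomes):
            assert on.outcome == ob.outcome, on.query_id
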