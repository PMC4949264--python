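"""End-to-end orchestration: filters -> alignment -> K2P -> reports.

Each stage writes its artifact(s) into the output directory and logs a
one-line summary. A stage whose artifacts already exist is loaded rather
than recomputed (delete an artifact to regenerate it and everything
downstream of it; pass ``force=True`` to regenerate everything). The
top-level ``report.json`` aggregates every stage's headline numbers and
is byte-identical across reruns with the same inputs, parameters and
seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import divergence as _divergence
from . import gap as _gap
from .core import Dataset, read_fasta, read_metadata, summarize, write_fasta
from .filters import apply_filters
from .identify import evaluate_all
from .k2p import DistanceMatrix, distance_matrix, write_long_tsv, write_phylip
from .msa import AlignmentMatrix, ScoringParams, progressive_align, \
    read_alignment, write_alignment
from .phylogeny import bootstrap_supports, read_newick, root_at_outgroup, \
    write_newick
from .separability import separability_table, write_separability_tsv, \
    zero_separability_fraction

logger = logging.getLogger("barcodekit")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Inputs, stage parameters and output location for one run."""

    fasta: Path
    metadata: Path
    outdir: Path
    alignment: Path | None = None     # precomputed aligned FASTA, used verbatim
    tree: Path | None = None          # externally built Newick, used verbatim
    min_len: int = 100
    scoring: ScoringParams = field(default_factory=ScoringParams)
    bin_width: float = 0.005
    threshold: float = 0.035
    n_reps: int = 1000
    seed: int = 0
    include_self: bool = False
    dispersion: str = "sd"
    force: bool = False

    def __post_init__(self) -> None:
        self.fasta = Path(self.fasta)
        self.metadata = Path(self.metadata)
        self.outdir = Path(self.outdir)
        for p, what in ((self.fasta, "FASTA"), (self.metadata, "metadata")):
            if not p.exists():
                raise FileNotFoundError(f"{what} input not found: {p}")


def _read_phylip(path: Path, species_of: dict[str, str]) -> DistanceMatrix:
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    ids, rows = [], []
    for line in lines[1:n + 1]:
        parts = line.split()
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return DistanceMatrix(ids=ids, values=np.array(rows),
                          species_of={r: species_of[r] for r in ids})


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and return the aggregated report dict."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    fresh = lambda *paths: config.force or not all(p.exists() for p in paths)

    # -- input + filters ---------------------------------------------------
    @_stage("filters")
    def stage_filter() -> tuple[Dataset, dict]:
        filtered_fa = out / "filtered.fasta"
        report_tsv = out / "filter_report.tsv"
        raw = read_fasta(config.fasta)
        raw, unmatched = read_metadata(config.metadata, raw)
        if fresh(filtered_fa, report_tsv):
            dataset, rep = apply_filters(raw, min_len=config.min_len)
            write_fasta(dataset, filtered_fa)
            rep.write(report_tsv)
            dropped = len(rep.dropped)
        else:
            keep = set(read_fasta(filtered_fa).ids)
            dataset = Dataset([r for r in raw if r.id in keep], name=raw.name)
            dropped = len(raw) - len(dataset)
        logger.info("filters: kept %d, dropped %d (min_len=%d)",
                    len(dataset), dropped, config.min_len)
        info = {"n_input": len(raw), "n_kept": len(dataset),
                "n_dropped": dropped, "unmatched_metadata_ids": unmatched}
        return dataset, info

    dataset, filter_info = stage_filter()

    @_stage("summary")
    def stage_summary() -> dict:
        path = out / "summary.json"
        if fresh(path):
            summ = summarize(dataset)
            path.write_text(summ.to_json())
            (out / "summary.tsv").write_text(summ.to_tsv())
        data = json.loads(path.read_text())
        logger.info("summary: %d records, %d species, mean length %.1f bp, "
                    "mean GC %.1f%%", data["n_records"], data["n_species"],
                    data["length_mean"], data["gc_mean"])
        return data

    summary = stage_summary()

    # -- alignment ---------------------------------------------------------
    @_stage("msa")
    def stage_align() -> AlignmentMatrix:
        path = out / "alignment.fasta"
        if config.alignment is not None:
            aln = read_alignment(config.alignment)
            missing = set(dataset.ids) - set(aln.ids)
            if missing:
                raise ValueError(f"precomputed alignment lacks: {sorted(missing)}")
            keep = [i for i, rid in enumerate(aln.ids) if rid in set(dataset.ids)]
            aln = AlignmentMatrix([aln.ids[i] for i in keep],
                                  [aln.rows[i] for i in keep])
            write_alignment(aln, path)
        elif fresh(path):
            aln = progressive_align(dataset, config.scoring)
            write_alignment(aln, path)
        else:
            aln = read_alignment(path)
        logger.info("msa: %d rows x %d columns", len(aln.ids), aln.n_columns)
        return aln

    aln = stage_align()

    # -- distances ---------------------------------------------------------
    @_stage("k2p")
    def stage_distances() -> DistanceMatrix:
        phylip = out / "distances.phylip"
        if fresh(phylip):
            dm = distance_matrix(aln, dataset.species_of)
            write_phylip(dm, phylip)
            write_long_tsv(dm, out / "distances.tsv")
        else:
            dm = _read_phylip(phylip, dataset.species_of)
        logger.info("k2p: %d x %d matrix, pairwise deletion", len(dm), len(dm))
        return dm

    dm = stage_distances()
    ingroup_ids = [r.id for r in dataset if r.role == "ingroup"]
    dm_in = dm.subset(ingroup_ids) if len(ingroup_ids) < len(dm) else dm
    ds_in = dataset.ingroup()

    # -- divergence metrics ------------------------------------------------
    @_stage("divergence")
    def stage_divergence() -> dict:
        path = out / "divergence.json"
        if fresh(path):
            summ = _divergence.divergence_summary(dm_in, config.dispersion)
            path.write_text(summ.to_json())
            (out / "divergence.tsv").write_text(summ.to_tsv())
        data = json.loads(path.read_text())
        logger.info("divergence: all_intra %.4f, all_inter %.4f",
                    data["all_intra"]["mean"], data["all_inter"]["mean"])
        return data

    div = stage_divergence()

    # -- barcoding gap -----------------------------------------------------
    @_stage("gap")
    def stage_gap() -> dict:
        path = out / "gap.json"
        if fresh(path):
            ga = _gap.gap_analysis(dm_in, config.bin_width, config.threshold)
            ga.write_json(path)
            ga.write_histogram(out / "gap_histogram.tsv")
        data = json.loads(path.read_text())
        logger.info("gap: %.2f%% inter pairs at zero, %.1f%% above %.3f, "
                    "wilcoxon p=%.3g", data["pct_inter_zero"],
                    data["pct_inter_gt_threshold"], data["threshold"],
                    data["wilcoxon_p"])
        return data

    gap_data = stage_gap()

    # -- identification ----------------------------------------------------
    @_stage("identification")
    def stage_identify() -> dict:
        results = {}
        for method in ("nearest_distance", "blast1"):
            prefix = out / f"identification_{method}"
            jpath = prefix.with_suffix(".json")
            if fresh(jpath):
                rep = evaluate_all(ds_in, dm_in, method,
                                   params=config.scoring,
                                   include_self=config.include_self)
                rep.write(prefix)
            results[method] = json.loads(jpath.read_text())
            logger.info("identification %s: %.1f%% correct, %.1f%% ambiguous, "
                        "%.1f%% incorrect", method,
                        results[method]["pct_correct"],
                        results[method]["pct_ambiguous"],
                        results[method]["pct_incorrect"])
        return results

    ident = stage_identify()

    # -- separability ------------------------------------------------------
    @_stage("separability")
    def stage_separability() -> dict:
        path = out / "separability.tsv"
        if fresh(path):
            table = separability_table(dm_in)
            write_separability_tsv(table, path)
            zero = zero_separability_fraction(table)
            n_disc = sum(r.discriminable for r in table)
            n_sp = len(table)
        else:
            lines = path.read_text().splitlines()[1:]
            seps = [float(l.split("\t")[3]) for l in lines]
            disc = [l.split("\t")[6] == "true" for l in lines]
            zero = 100.0 * sum(s == 0.0 for s in seps) / len(seps)
            n_disc, n_sp = sum(disc), len(seps)
        logger.info("separability: %.1f%% of species at zero separability, "
                    "%d/%d discriminable", zero, n_disc, n_sp)
        return {"table": str(path), "pct_zero_separability": zero,
                "n_discriminable": n_disc, "n_species": n_sp}

    sep = stage_separability()

    # -- phylogeny ---------------------------------------------------------
    @_stage("phylogeny")
    def stage_tree() -> dict:
        path = out / "tree.nwk"
        outgroup = [r.id for r in dataset if r.role == "outgroup"]
        if config.tree is not None:
            tree = read_newick(config.tree)
            write_newick(tree, path)
            source = "imported"
        elif fresh(path):
            tree = bootstrap_supports(
                aln, dataset.species_of, n_reps=config.n_reps,
                seed=np.random.default_rng([config.seed, 8]))
            if outgroup:
                tree = root_at_outgroup(tree, outgroup)
            write_newick(tree, path)
            source = "nj+bootstrap"
        else:
            source = "cached"
        logger.info("phylogeny: %s tree at %s (n_reps=%d)", source, path,
                    config.n_reps)
        return {"newick": str(path), "n_bootstrap": config.n_reps,
                "outgroup": outgroup}

    tree_info = stage_tree()

    report = {
        "config": {
            "fasta": str(config.fasta),
            "metadata": str(config.metadata),
            "min_len": config.min_len,
            "scoring": config.scoring.__dict__,
            "bin_width": config.bin_width,
            "threshold": config.threshold,
            "n_reps": config.n_reps,
            "seed": config.seed,
            "include_self": config.include_self,
            "dispersion": config.dispersion,
        },
        "filters": filter_info,
        "summary": summary,
        "divergence": div,
        "gap": gap_data,
        "identification": ident,
        "separability": sep,
        "phylogeny": tree_info,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    logger.info("report written to %s", out / "report.json")
    return report
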