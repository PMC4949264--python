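"""Per-taxon separability versus within-taxon heterogeneity.

For each species, compare the worst case within (heterogeneity = the
maximum conspecific distance; 0 for singletons) with the best case
without (separability = the minimum distance to any heterospecific
individual), and report the taxon attaining that minimum as the closest
relative. A species is discriminable by the marker when its separability
strictly exceeds its heterogeneity and is non-zero — the "clear species
boundary" criterion of taxon-gap displays. Species whose separability is
exactly zero share an identical (at compared sites) sequence with another
taxon and cannot be told apart by this marker at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .k2p import DistanceMatrix

__all__ = [
    "SeparabilityRecord",
    "separability_table",
    "zero_separability_fraction",
    "write_separability_tsv",
    "plot_separability",
]


@dataclass(frozen=True)
class SeparabilityRecord:
    """One species' heterogeneity/separability summary."""

    species: str
    heterogeneity: float           # max conspecific distance; 0 if singleton
    mean_heterogeneity: float      # mean conspecific distance (secondary)
    separability: float            # min distance to any other species
    closest_relative: str          # alphabetically first on ties
    closest_relatives: tuple[str, ...]  # all tied labels
    discriminable: bool            # separability > heterogeneity and > 0


def separability_table(dm: DistanceMatrix) -> list[SeparabilityRecord]:
    """One record per species, ordered by species label.

    Ties for the closest relative are broken alphabetically; all tied
    labels are retained in ``closest_relatives``.
    """
    groups = dm.species_indices()
    if len(groups) < 2:
        raise ValueError("need >=2 species")
    species_arr = np.array([dm.species_of[r] for r in dm.ids])
    out: list[SeparabilityRecord] = []
    for sp in sorted(groups):
        own = groups[sp]
        others = np.setdiff1d(np.arange(len(dm.ids)), own)
        cross = dm.values[np.ix_(own, others)]
        sep = float(cross.min())
        # other-species columns attaining the minimum
        col_hit = others[np.any(cross == sep, axis=0)]
        tied = tuple(sorted(set(species_arr[col_hit])))
        if len(own) >= 2:
            sub = dm.values[np.ix_(own, own)]
            vals = sub[np.triu_indices(len(own), k=1)]
            het, het_mean = float(vals.max()), float(vals.mean())
        else:
            het = het_mean = 0.0
        out.append(SeparabilityRecord(
            species=sp,
            heterogeneity=het,
            mean_heterogeneity=het_mean,
            separability=sep,
            closest_relative=tied[0],
            closest_relatives=tied,
            discriminable=(sep > het and sep > 0.0),
        ))
    return out


def zero_separability_fraction(table: list[SeparabilityRecord]) -> float:
    """Percent of species whose separability is exactly zero."""
    if not table:
        raise ValueError("empty separability table")
    return 100.0 * sum(r.separability == 0.0 for r in table) / len(table)


def write_separability_tsv(table: list[SeparabilityRecord],
                           path: str | Path) -> None:
    lines = ["species\theterogeneity\tmean_heterogeneity\tseparability"
             "\tclosest_relative\tclosest_relatives\tdiscriminable"]
    for r in table:
        lines.append(
            f"{r.species}\t{r.heterogeneity:.6f}\t{r.mean_heterogeneity:.6f}\t"
            f"{r.separability:.6f}\t{r.closest_relative}\t"
            f"{','.join(r.closest_relatives)}\t{str(r.discriminable).lower()}")
    Path(path).write_text("\n".join(lines) + "\n")


def plot_separability(table: list[SeparabilityRecord],
                      path: str | Path) -> None:
    """Horizontal-bar display: heterogeneity (light) vs separability (dark)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [r.species for r in table]
    y = np.arange(len(table))
    fig, ax = plt.subplots(figsize=(7, max(3, 0.25 * len(table))))
    ax.barh(y + 0.2, [r.heterogeneity for r in table], height=0.4,
            color="lightgray", label="heterogeneity (max intra)")
    ax.barh(y - 0.2, [r.separability for r in table], height=0.4,
            color="dimgray", label="separability (min inter)")
    for yi, r in zip(y, table):
        ax.text(r.separability, yi - 0.2, f" {r.closest_relative}",
                va="center", fontsize=6)
    ax.set_yticks(y, names, fontsize=6)
    ax.invert_yaxis()
    ax.set_xlabel("K2P distance (substitutions/site)")
    ax.legend(loc="lower right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
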