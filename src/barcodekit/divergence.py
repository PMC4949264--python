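"""Intra- and inter-specific divergence summaries of a distance matrix.

Six standard barcode-evaluation metrics, three per side of the species
boundary:

* **all_intra** — mean over every conspecific pair, pooled;
* **theta** — per-species mean conspecific distance, averaged over
  species with >=2 samples (debiases unequal sampling within species);
* **coalescent_depth** — per-species *maximum* conspecific distance,
  averaged over species with >=2 samples (how deep within-species
  variation reaches);
* **all_inter** — mean over every heterospecific pair, pooled;
* **theta_prime** — per-species-pair mean distance, averaged over pairs
  (debiases unequal sampling between species);
* **min_inter** — each species' minimum distance to any heterospecific
  individual, averaged over species.

Dispersions are reported as the standard deviation (ddof=0) to match the
"mean ± spread" convention of barcode-evaluation tables; standard error
is available via ``dispersion="se"``.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .k2p import DistanceMatrix

__all__ = [
    "Dispersed",
    "DivergenceSummary",
    "intra_metrics",
    "inter_metrics",
    "divergence_summary",
]


class Dispersed(NamedTuple):
    """A metric with its dispersion (both in substitutions/site)."""

    mean: float
    spread: float

    def __str__(self) -> str:
        return f"{self.mean:.3f} +/- {self.spread:.3f}"


def _dispersed(values: np.ndarray, dispersion: str) -> Dispersed:
    values = np.asarray(values, dtype=float)
    spread = float(np.std(values))
    if dispersion == "se":
        spread /= np.sqrt(len(values))
    elif dispersion != "sd":
        raise ValueError("dispersion must be 'sd' or 'se'")
    return Dispersed(float(np.mean(values)), spread)


def intra_metrics(dm: DistanceMatrix, dispersion: str = "sd",
                  ) -> tuple[Dispersed, Dispersed, Dispersed]:
    """(all_intra, theta, coalescent_depth); needs >=1 multi-sample species."""
    groups = dm.species_indices()
    multi = {sp: ix for sp, ix in groups.items() if len(ix) >= 2}
    if not multi:
        raise ValueError("no species with >=2 samples; intra metrics undefined")
    pooled = dm.intra_distances()
    per_mean, per_max = [], []
    for sp in sorted(multi):
        ix = multi[sp]
        sub = dm.values[np.ix_(ix, ix)]
        vals = sub[np.triu_indices(len(ix), k=1)]
        per_mean.append(vals.mean())
        per_max.append(vals.max())
    return (_dispersed(pooled, dispersion),
            _dispersed(np.array(per_mean), dispersion),
            _dispersed(np.array(per_max), dispersion))


def inter_metrics(dm: DistanceMatrix, dispersion: str = "sd",
                  global_min: bool = False,
                  ) -> tuple[Dispersed, Dispersed, Dispersed]:
    """(all_inter, theta_prime, min_inter); needs >=2 species.

    With ``global_min=True`` the third element is the single smallest
    heterospecific distance in the whole matrix (spread 0) instead of the
    per-species average of minima.
    """
    groups = dm.species_indices()
    if len(groups) < 2:
        raise ValueError("need >=2 species for inter metrics")
    pooled = dm.inter_distances()
    pair_means = []
    for sp_a, sp_b in itertools.combinations(sorted(groups), 2):
        cross = dm.values[np.ix_(groups[sp_a], groups[sp_b])]
        pair_means.append(cross.mean())
    per_min = []
    for sp in sorted(groups):
        own = groups[sp]
        others = np.setdiff1d(np.arange(len(dm.ids)), own)
        per_min.append(dm.values[np.ix_(own, others)].min())
    if global_min:
        min_part = Dispersed(float(pooled.min()), 0.0)
    else:
        min_part = _dispersed(np.array(per_min), dispersion)
    return (_dispersed(pooled, dispersion),
            _dispersed(np.array(pair_means), dispersion),
            min_part)


#: Report row labels, in conventional table order.
_LABELS = {
    "all_inter": "All interspecific distance",
    "theta_prime": "Theta prime",
    "min_inter": "The minimum interspecific distance",
    "all_intra": "All intraspecific distance",
    "theta": "Theta",
    "coalescent_depth": "Coalescent depth",
}


@dataclass(frozen=True)
class DivergenceSummary:
    """The six divergence metrics with dispersions, plus species counts."""

    all_inter: Dispersed
    theta_prime: Dispersed
    min_inter: Dispersed
    all_intra: Dispersed
    theta: Dispersed
    coalescent_depth: Dispersed
    n_species: int
    n_species_multi: int

    def to_dict(self) -> dict:
        out: dict = {}
        for key in _LABELS:
            val: Dispersed = getattr(self, key)
            out[key] = {"mean": val.mean, "spread": val.spread}
        out["n_species"] = self.n_species
        out["n_species_multi"] = self.n_species_multi
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self, decimals: int = 3) -> str:
        lines = ["Measurement\tK2P value"]
        for key, label in _LABELS.items():
            val: Dispersed = getattr(self, key)
            lines.append(
                f"{label}\t{val.mean:.{decimals}f} ± {val.spread:.{decimals}f}")
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def divergence_summary(dm: DistanceMatrix, dispersion: str = "sd",
                       global_min: bool = False) -> DivergenceSummary:
    """Compute all six metrics from one distance matrix."""
    all_inter, theta_prime, min_inter = inter_metrics(
        dm, dispersion, global_min=global_min)
    all_intra, theta, coal = intra_metrics(dm, dispersion)
    groups = dm.species_indices()
    return DivergenceSummary(
        all_inter=all_inter, theta_prime=theta_prime, min_inter=min_inter,
        all_intra=all_intra, theta=theta, coalescent_depth=coal,
        n_species=len(groups),
        n_species_multi=sum(len(ix) >= 2 for ix in groups.values()),
    )
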