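"""Pre-analysis sequence exclusion rules.

Two rules, applied before any distance work: drop sequences shorter than a
minimum length (default 100 bp — too short to be a credibly complete
marker region), and drop records whose species label uses open
nomenclature ("aff.", species affinis), which flags uncertain or possibly
contaminated identifications.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .core import Dataset

__all__ = ["FilterReport", "apply_filters"]

# "aff." as its own token, case-insensitive; "affinis" must not match.
_AFF_TOKEN = re.compile(r"(?:^|[\s.])aff\.(?:\s|$)", re.IGNORECASE)


@dataclass(frozen=True)
class FilterReport:
    """IDs kept and dropped, with a reason per dropped record."""

    kept: list[str]
    dropped: list[tuple[str, str]]  # (id, reason in {too_short, suspect_name})

    def to_tsv(self) -> str:
        lines = ["id\tstatus\treason"]
        lines += [f"{rid}\tkept\t" for rid in self.kept]
        lines += [f"{rid}\tdropped\t{reason}" for rid, reason in self.dropped]
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())


def _suspect_name(species: str | None) -> bool:
    return species is not None and _AFF_TOKEN.search(species) is not None


def apply_filters(dataset: Dataset, min_len: int = 100,
                  ) -> tuple[Dataset, FilterReport]:
    """Drop too-short and suspect-name records, preserving survivor order.

    A record shorter than ``min_len`` bp is dropped with reason
    ``too_short`` (a record of exactly ``min_len`` is kept). A record
    whose species label contains the token "aff." is dropped with reason
    ``suspect_name``; the match is word-bounded so names like
    "P. affinis" survive. Raises if nothing survives. Idempotent.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    kept: list = []
    dropped: list[tuple[str, str]] = []
    for rec in dataset:
        if len(rec) < min_len:
            dropped.append((rec.id, "too_short"))
        elif _suspect_name(rec.species):
            dropped.append((rec.id, "suspect_name"))
        else:
            kept.append(rec)
    if not kept:
        raise ValueError("empty dataset after filtering")
    report = FilterReport(kept=[r.id for r in kept], dropped=dropped)
    return Dataset(kept, name=dataset.name), report
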