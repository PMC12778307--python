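"""Local vulnerability scoring and Red List tabulation.

Each cited species receives three parameters on a 1-3 scale:

* **P1** — citation-frequency level: CF < 5% → 1, 5% ≤ CF < 15% → 2,
  CF ≥ 15% → 3 (more users, more pressure).
* **P2** — use-category breadth: fewer than 2 categories → 1, 2-3 → 2,
  4 or more → 3 (more kinds of use, more pressure).
* **P3** — perceived scarcity, from the modal pebble-technique
  availability judgement: very abundant/abundant → 1, not abundant
  ("scarce") → 2, rare/very rare → 3.

The vulnerability index is their mean, ``VI = (P1+P2+P3)/3``, classified
as less vulnerable (VI < 2), moderately vulnerable (2 ≤ VI < 2.5) or
vulnerable (VI ≥ 2.5). VI is carried as an exact rational so the
boundary cases (VI = 2, VI = 2.5) classify exactly as printed.

The modal availability judgement is summarized with its *consensus
value* — the share of judgements agreeing with the mode. Ties between
equally frequent categories break toward the scarcer category by
default (precautionary), configurable to the more abundant one.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal, Sequence

from .data_model import (
    Availability,
    IUCNCategory,
    SurveyDataset,
    TaxonRecord,
)
from .use_indices import citation_frequency

__all__ = [
    "VulnerabilityClass",
    "VulnerabilityScore",
    "AvailabilityConsensus",
    "scale_citation_frequency",
    "scale_use_categories",
    "scale_presence",
    "consensus_availability",
    "vulnerability_index",
    "compute_vulnerability_table",
    "iucn_summary",
    "THREATENED_OR_NEAR",
]


class VulnerabilityClass(str, enum.Enum):
    LESS_VULNERABLE = "less_vulnerable"
    MODERATELY_VULNERABLE = "moderately_vulnerable"
    VULNERABLE = "vulnerable"


@dataclass(frozen=True)
class AvailabilityConsensus:
    """Modal availability judgement and the share of agreement with it."""

    species_id: str
    modal_category: Availability
    consensus_value: float  # in (0, 1]; ≥ 1/5 with ≥1 judgement


@dataclass(frozen=True)
class VulnerabilityScore:
    """Per-species vulnerability parameters, index and class.

    ``p3``, ``vi`` and ``vclass`` are None for species lacking any
    availability judgement; such species are flagged, not classified.
    """

    species_id: str
    p1: int
    p2: int
    p3: int | None
    vi: Fraction | None
    vclass: VulnerabilityClass | None
    consensus: AvailabilityConsensus | None = None

    @property
    def vi_float(self) -> float | None:
        return None if self.vi is None else float(self.vi)


def scale_citation_frequency(cf: float) -> int:
    """P1 level from the citation frequency (percent)."""
    if not 0 <= cf <= 100:
        raise ValueError(f"cf must be a percentage in [0, 100], got {cf}")
    if cf < 5:
        return 1
    if cf < 15:
        return 2
    return 3


def scale_use_categories(k: int) -> int:
    """P2 level from the number of distinct use categories."""
    if k < 0:
        raise ValueError(f"use-category count must be non-negative, got {k}")
    if k < 2:
        return 1
    if k <= 3:
        return 2
    return 3


_PRESENCE_LEVEL = {
    Availability.VERY_ABUNDANT: 1,
    Availability.ABUNDANT: 1,
    Availability.NOT_ABUNDANT: 2,
    Availability.RARE: 3,
    Availability.VERY_RARE: 3,
}


def scale_presence(modal_category: Availability) -> int:
    """P3 level from the modal availability category."""
    return _PRESENCE_LEVEL[Availability(modal_category)]


def consensus_availability(
    judgements: Sequence[Availability],
    species_id: str = "",
    tie_break: Literal["scarcer", "more_abundant"] = "scarcer",
) -> AvailabilityConsensus:
    """Modal availability category with its consensus value.

    ``tie_break`` picks among equally frequent categories: "scarcer"
    (default, precautionary) or "more_abundant".
    """
    if not judgements:
        raise ValueError("consensus undefined: no availability judgements")
    counts = Counter(Availability(j) for j in judgements)
    top = max(counts.values())
    tied = [cat for cat, c in counts.items() if c == top]
    reverse = tie_break == "scarcer"
    modal = sorted(tied, key=lambda c: c.scarcity_rank, reverse=reverse)[0]
    return AvailabilityConsensus(
        species_id=species_id,
        modal_category=modal,
        consensus_value=top / len(judgements),
    )


def vulnerability_index(
    p1: int, p2: int, p3: int
) -> tuple[Fraction, VulnerabilityClass]:
    """VI = (P1+P2+P3)/3 and its class, with exact threshold arithmetic."""
    for name, p in (("p1", p1), ("p2", p2), ("p3", p3)):
        if p not in (1, 2, 3):
            raise ValueError(f"{name} must be 1, 2 or 3, got {p}")
    vi = Fraction(p1 + p2 + p3, 3)
    if vi < 2:
        vclass = VulnerabilityClass.LESS_VULNERABLE
    elif vi < Fraction(5, 2):
        vclass = VulnerabilityClass.MODERATELY_VULNERABLE
    else:
        vclass = VulnerabilityClass.VULNERABLE
    return vi, vclass


def compute_vulnerability_table(
    dataset: SurveyDataset,
    tie_break: Literal["scarcer", "more_abundant"] = "scarcer",
) -> list[VulnerabilityScore]:
    """Score every cited species; order by species_id.

    Species without availability judgements get P1/P2 but no P3, VI or
    class — they are flagged for the caller rather than guessed at.
    """
    species = dataset.species()
    if not species:
        raise ValueError("cannot score vulnerability on an empty dataset")
    n = dataset.n_respondents
    scores = []
    for s in species:
        p1 = scale_citation_frequency(citation_frequency(dataset.n_citers(s), n))
        p2 = scale_use_categories(len(dataset.use_categories(s)))
        judgements = dataset.availability_judgements(s)
        if judgements:
            consensus = consensus_availability(judgements, s, tie_break)
            p3 = scale_presence(consensus.modal_category)
            vi, vclass = vulnerability_index(p1, p2, p3)
        else:
            consensus, p3, vi, vclass = None, None, None, None
        scores.append(
            VulnerabilityScore(
                species_id=s, p1=p1, p2=p2, p3=p3,
                vi=vi, vclass=vclass, consensus=consensus,
            )
        )
    return scores


#: Red List categories counted as globally threatened or near-threatened.
THREATENED_OR_NEAR = frozenset(
    {IUCNCategory.NT, IUCNCategory.VU, IUCNCategory.EN, IUCNCategory.CR}
)


def iucn_summary(taxa: Iterable[TaxonRecord]) -> dict[str, int]:
    """Species counts per Red List category plus the threatened-or-near total.

    Returns a mapping with one key per category code (always all seven,
    zero-filled) and ``"threatened_or_near"`` for |{NT, VU, EN, CR}|.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("cannot summarize an empty taxon list")
    counts = Counter(t.iucn_category for t in taxa)
    summary = {c.value: counts.get(c, 0) for c in IUCNCategory}
    summary["threatened_or_near"] = sum(
        counts.get(c, 0) for c in THREATENED_OR_NEAR
    )
    return summary
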