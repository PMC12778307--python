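"""Use-importance indices for ethnozoological survey data.

For each cited species the battery comprises:

* **CFsp** — citation frequency, ``100·ni/N``: the percentage of
  respondents citing the species.
* **RUsp** — reported use, ``ΣNCp``: the number of distinct
  (part, specific use) combinations reported for the species.
* **UVsp** — use value, ``100·RUsp/ΣRU``: the species' share of all
  reported uses. ΣRU defaults to the sum over species in the dataset,
  so UV values sum to 100; an explicit total may be supplied when
  reproducing a published table normalized against a different base.
* **NSUi / UDIsp** — use-diversity: the number of distinct specific-use
  labels, scaled so the species with the most specific uses scores 100
  (``100·NSUi/NSUmax``).
* **IVIUsp = CFsp + UVsp + UDIsp** — the Importance Value-in-use Index,
  in [0, 300], used to rank species by local importance.

All arithmetic is full precision; rounding to 2 decimals is applied
only when serializing reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_model import SurveyDataset, UseCategory

__all__ = [
    "UseIndices",
    "citation_frequency",
    "use_value",
    "use_diversity_index",
    "importance_value_in_use",
    "compute_use_table",
    "use_typology_summary",
    "use_table_to_frame",
]


@dataclass(frozen=True)
class UseIndices:
    """Per-species use-importance indices (full precision)."""

    species_id: str
    cf: float    # citation frequency, % of respondents
    ru: int      # reported use, distinct part-uses
    uv: float    # use value, % of all reported uses
    nsu: int     # number of distinct specific uses
    udi: float   # use diversity index, % of the dataset maximum
    iviu: float  # CF + UV + UDI


def citation_frequency(n_citers: int, n_respondents: int) -> float:
    """CFsp = 100·ni/N."""
    if n_respondents < 1:
        raise ZeroDivisionError(
            "citation frequency undefined: dataset has no respondents"
        )
    if not 0 <= n_citers <= n_respondents:
        raise ValueError(
            f"n_citers must be in [0, N={n_respondents}], got {n_citers}"
        )
    return 100.0 * n_citers / n_respondents


def use_value(ru_sp: int, ru_total: int) -> float:
    """UVsp = 100·RUsp/ΣRU; 0 for an empty dataset (ΣRU = 0)."""
    if ru_sp < 0:
        raise ValueError(f"ru_sp must be non-negative, got {ru_sp}")
    if ru_sp > ru_total:
        raise ValueError(
            f"ru_sp ({ru_sp}) exceeds the total reported use ({ru_total})"
        )
    if ru_total == 0:
        return 0.0
    return 100.0 * ru_sp / ru_total


def use_diversity_index(nsu_i: int, nsu_max: int) -> float:
    """UDIsp = 100·NSUi/NSUmax; the most-used species scores 100."""
    if nsu_max < 1:
        raise ZeroDivisionError(
            "use diversity undefined: no specific uses recorded"
        )
    if not 0 <= nsu_i <= nsu_max:
        raise ValueError(f"nsu_i must be in [0, {nsu_max}], got {nsu_i}")
    return 100.0 * nsu_i / nsu_max


def importance_value_in_use(cf: float, uv: float, udi: float) -> float:
    """IVIUsp = CFsp + UVsp + UDIsp."""
    for name, value in (("cf", cf), ("uv", uv), ("udi", udi)):
        if not 0 <= value <= 100:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {value}")
    return cf + uv + udi


def compute_use_table(
    dataset: SurveyDataset, ru_total: int | None = None
) -> list[UseIndices]:
    """Compute the full index battery, ranked by IVIU descending.

    Ties are broken by species_id (lexicographic) so output order is
    deterministic. ``ru_total`` overrides the use-value denominator
    (default: ΣRU over the dataset's species, which makes Σ UV = 100).
    """
    species = dataset.species()
    if not species:
        raise ValueError("cannot compute use indices on an empty dataset")
    n = dataset.n_respondents
    ru = {s: dataset.reported_use(s) for s in species}
    nsu = {s: dataset.n_specific_uses(s) for s in species}
    denominator = sum(ru.values()) if ru_total is None else ru_total
    nsu_max = max(nsu.values())
    rows = []
    for s in species:
        cf = citation_frequency(dataset.n_citers(s), n)
        uv = use_value(ru[s], denominator)
        udi = use_diversity_index(nsu[s], nsu_max)
        rows.append(
            UseIndices(
                species_id=s,
                cf=cf,
                ru=ru[s],
                uv=uv,
                nsu=nsu[s],
                udi=udi,
                iviu=importance_value_in_use(cf, uv, udi),
            )
        )
    rows.sort(key=lambda r: (-r.iviu, r.species_id))
    return rows


def use_typology_summary(dataset: SurveyDataset) -> dict[UseCategory, float]:
    """Percentage of all use citations falling in each use category.

    Counts raw records (citation volume, not the deduplicated use
    repertoire): this mirrors how field studies report "x% of all uses".
    Always returns all six categories; the values sum to 100.
    """
    counts = dataset.category_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("cannot summarize use typology of an empty dataset")
    return {
        category: 100.0 * counts.get(category, 0) / total
        for category in UseCategory
    }


def use_table_to_frame(rows: list[UseIndices], digits: int | None = 2) -> pd.DataFrame:
    """Render the ranked table as a DataFrame (2-dp display by default)."""
    df = pd.DataFrame(
        [
            {
                "species": r.species_id,
                "CF": r.cf,
                "RU": r.ru,
                "UV": r.uv,
                "NSU": r.nsu,
                "UDI": r.udi,
                "IVIU": r.iviu,
            }
            for r in rows
        ]
    )
    if digits is not None:
        for col in ("CF", "UV", "UDI", "IVIU"):
            df[col] = df[col].round(digits)
    return df
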