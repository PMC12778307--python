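"""Core data structures for ethnozoological interview surveys.

A survey is a flat table of *citations*: one row records that one
respondent reported one use of one animal species — the part used, the
use category (one of six standard classes of wildlife use), a free-text
label for the specific use, and optionally the respondent's judgement of
the species' local availability (five-level "pebble technique" scale,
from very abundant to very rare).

All use indices downstream consume three counting primitives exposed
here:

* ``N`` — the number of distinct respondents in the dataset,
* ``ni`` — the number of distinct respondents citing a species,
* ``NCp`` — per (species, part), the number of distinct specific uses
  reported for that part; their sum over parts is the species' reported
  use RUsp.

``NCp`` deliberately deduplicates across respondents: two respondents
naming the same (part, use) contribute one reported use, so RUsp counts
the breadth of the species' use repertoire rather than interview volume
and may be smaller than ``ni``.
"""

from __future__ import annotations

import enum
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "UseCategory",
    "Availability",
    "IUCNCategory",
    "SurveyRecord",
    "SurveyDataset",
    "TaxonRecord",
    "SchemaError",
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "read_taxonomy",
    "count_citers",
    "SURVEY_COLUMNS",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


class SurveyValidationError(ValueError):
    """A row of an input table carries an invalid value."""


class UseCategory(str, enum.Enum):
    """The six standard categories of wildlife use."""

    FOOD = "food"
    MEDICINAL = "medicinal"
    COSMETIC = "cosmetic"
    TRADITIONAL_CULTURAL = "traditional_cultural"
    ARTISANAL = "artisanal"
    COMMERCIAL = "commercial"


class Availability(str, enum.Enum):
    """Pebble-technique availability judgement, most to least abundant."""

    VERY_ABUNDANT = "very_abundant"   # > 75% available
    ABUNDANT = "abundant"             # 50%-75%
    NOT_ABUNDANT = "not_abundant"     # 25%-50% ("scarce")
    RARE = "rare"                     # < 25%
    VERY_RARE = "very_rare"           # barely existing

    @property
    def scarcity_rank(self) -> int:
        """0 (very abundant) .. 4 (very rare); higher = scarcer."""
        return _SCARCITY_ORDER[self]


_SCARCITY_ORDER = {
    Availability.VERY_ABUNDANT: 0,
    Availability.ABUNDANT: 1,
    Availability.NOT_ABUNDANT: 2,
    Availability.RARE: 3,
    Availability.VERY_RARE: 4,
}


class IUCNCategory(str, enum.Enum):
    """IUCN Red List category codes."""

    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    DD = "DD"
    NE = "NE"


#: Canonical survey CSV column names. A column mapping passed to
#: :func:`read_survey` maps these canonical names to the file's headers.
SURVEY_COLUMNS = (
    "respondent_id",
    "species_id",
    "part_used",
    "use_category",
    "specific_use",
    "availability",
)

_WS = re.compile(r"\s+")


def canonical_use_label(label: str) -> str:
    """Case-fold and collapse whitespace, so 'Grilled  Meat' == 'grilled meat'."""
    return _WS.sub(" ", str(label).strip()).casefold()


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent's citation of one (species, part, specific use)."""

    respondent_id: str
    species_id: str
    part_used: str
    use_category: UseCategory
    specific_use: str
    availability: Availability | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.use_category, UseCategory):
            object.__setattr__(
                self, "use_category", UseCategory(self.use_category)
            )
        if self.availability is not None and not isinstance(
            self.availability, Availability
        ):
            object.__setattr__(
                self, "availability", Availability(self.availability)
            )


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic placement and global conservation status of one species."""

    species_id: str
    common_name: str
    genus: str
    family: str
    order: str
    class_: str
    iucn_category: IUCNCategory

    def __post_init__(self) -> None:
        if not isinstance(self.iucn_category, IUCNCategory):
            object.__setattr__(
                self, "iucn_category", IUCNCategory(self.iucn_category)
            )


@dataclass
class SurveyDataset:
    """A validated collection of survey citations.

    Exposes the counting primitives every index consumes; the heavier
    aggregations (index tables) live in :mod:`ethnozoo.use_indices` and
    :mod:`ethnozoo.vulnerability`.
    """

    records: list[SurveyRecord]
    metadata: dict = field(default_factory=dict)
    #: Respondent registry: interviewees enrolled in the survey whether or
    #: not they cited anything. N is the union of the registry and the
    #: respondents appearing in records, so N is always derived from the
    #: dataset at hand (subsetting records shrinks N only when the registry
    #: is empty, e.g. for data read from a bare citation CSV).
    registered_respondents: set[str] = field(default_factory=set)

    # -- counting primitives -------------------------------------------------

    @property
    def respondents(self) -> set[str]:
        return self.registered_respondents | {
            r.respondent_id for r in self.records
        }

    @property
    def n_respondents(self) -> int:
        """N — the total number of respondents."""
        return len(self.respondents)

    def species(self) -> list[str]:
        """Cited species, sorted for deterministic iteration."""
        return sorted({r.species_id for r in self.records})

    def records_for(self, species_id: str) -> list[SurveyRecord]:
        return [r for r in self.records if r.species_id == species_id]

    def citers(self, species_id: str) -> set[str]:
        return {
            r.respondent_id for r in self.records if r.species_id == species_id
        }

    def n_citers(self, species_id: str) -> int:
        """ni — distinct respondents citing the species (0 if absent)."""
        return len(self.citers(species_id))

    def part_use_pairs(self, species_id: str) -> set[tuple[str, str]]:
        """Distinct (part, canonical specific use) combinations for a species."""
        return {
            (r.part_used, canonical_use_label(r.specific_use))
            for r in self.records
            if r.species_id == species_id
        }

    def part_citations(self, species_id: str) -> dict[str, int]:
        """NCp per part: distinct specific uses reported for each part."""
        uses_per_part: dict[str, set[str]] = {}
        for part, use in self.part_use_pairs(species_id):
            uses_per_part.setdefault(part, set()).add(use)
        return {part: len(uses) for part, uses in uses_per_part.items()}

    def reported_use(self, species_id: str) -> int:
        """RUsp = ΣNCp — total distinct part-uses of the species."""
        return len(self.part_use_pairs(species_id))

    def total_reported_use(self) -> int:
        """ΣRU over all cited species."""
        return sum(self.reported_use(s) for s in self.species())

    def specific_uses(self, species_id: str) -> set[str]:
        """Distinct canonical specific-use labels (NSU numerator)."""
        return {
            canonical_use_label(r.specific_use)
            for r in self.records
            if r.species_id == species_id
        }

    def n_specific_uses(self, species_id: str) -> int:
        return len(self.specific_uses(species_id))

    def use_categories(self, species_id: str) -> set[UseCategory]:
        """Distinct use categories of the species (vulnerability P2 input)."""
        return {
            r.use_category for r in self.records if r.species_id == species_id
        }

    def availability_judgements(self, species_id: str) -> list[Availability]:
        return [
            r.availability
            for r in self.records
            if r.species_id == species_id and r.availability is not None
        ]

    def category_counts(self) -> Counter:
        """Raw citation counts per use category over all records."""
        return Counter(r.use_category for r in self.records)

    # -- IO ------------------------------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "respondent_id": r.respondent_id,
                "species_id": r.species_id,
                "part_used": r.part_used,
                "use_category": r.use_category.value,
                "specific_use": r.specific_use,
                "availability": "" if r.availability is None else r.availability.value,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))


def _records_from_frame(df: pd.DataFrame, source: str) -> list[SurveyRecord]:
    records: list[SurveyRecord] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        cat_label = str(row.use_category).strip()
        try:
            category = UseCategory(cat_label)
        except ValueError:
            raise SurveyValidationError(
                f"{source}, row {idx}: unknown use_category {cat_label!r}; "
                f"expected one of {[c.value for c in UseCategory]}"
            ) from None
        avail_label = "" if pd.isna(row.availability) else str(row.availability).strip()
        availability: Availability | None
        if avail_label == "":
            availability = None
        else:
            try:
                availability = Availability(avail_label)
            except ValueError:
                raise SurveyValidationError(
                    f"{source}, row {idx}: unknown availability {avail_label!r}; "
                    f"expected one of {[a.value for a in Availability]}"
                ) from None
        records.append(
            SurveyRecord(
                respondent_id=str(row.respondent_id),
                species_id=str(row.species_id),
                part_used=str(row.part_used).strip(),
                use_category=category,
                specific_use=str(row.specific_use),
                availability=availability,
            )
        )
    return records


def read_survey(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> SurveyDataset:
    """Read and validate a survey CSV into a :class:`SurveyDataset`.

    Parameters
    ----------
    path
        UTF-8, comma-separated file with a header row.
    column_map
        Optional mapping from canonical column names
        (:data:`SURVEY_COLUMNS`) to the file's actual headers, to
        tolerate field-export naming variants. ``availability`` may be
        absent from the file, in which case every record has no
        judgement.

    Unknown use-category or availability labels are rejected with the
    offending row number, never silently coerced.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mapping = dict(column_map or {})
    rename = {}
    for canonical in SURVEY_COLUMNS:
        actual = mapping.get(canonical, canonical)
        if actual in df.columns:
            rename[actual] = canonical
        elif canonical != "availability":
            raise SchemaError(
                f"{path}: missing required column {actual!r} "
                f"(canonical name {canonical!r})"
            )
    df = df.rename(columns=rename)
    if "availability" not in df.columns:
        df["availability"] = ""
    df = df[list(SURVEY_COLUMNS)]
    return SurveyDataset(records=_records_from_frame(df, str(path)))


def write_survey(dataset: SurveyDataset, path: str | Path) -> None:
    """Write the dataset back to canonical survey CSV (UTF-8)."""
    dataset.to_dataframe().to_csv(path, index=False)


def read_taxonomy(path: str | Path) -> list[TaxonRecord]:
    """Read a species taxonomy/Red-List table.

    Expects columns ``species_id, common_name, genus, family, order,
    class, iucn_category``; duplicate species and unknown Red List codes
    are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        "species_id", "common_name", "genus", "family", "order",
        "class", "iucn_category",
    ]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    taxa: list[TaxonRecord] = []
    seen: set[str] = set()
    for idx, row in enumerate(df.to_dict("records"), start=2):
        sp = str(row["species_id"]).strip()
        if sp in seen:
            raise SurveyValidationError(
                f"{path}, row {idx}: duplicate species_id {sp!r}"
            )
        seen.add(sp)
        code = str(row["iucn_category"]).strip()
        try:
            iucn = IUCNCategory(code)
        except ValueError:
            raise SurveyValidationError(
                f"{path}, row {idx}: unknown IUCN category {code!r}; "
                f"expected one of {[c.value for c in IUCNCategory]}"
            ) from None
        taxa.append(
            TaxonRecord(
                species_id=sp,
                common_name=str(row["common_name"]),
                genus=str(row["genus"]),
                family=str(row["family"]),
                order=str(row["order"]),
                class_=str(row["class"]),
                iucn_category=iucn,
            )
        )
    return taxa


def count_citers(dataset: SurveyDataset, species_id: str) -> int:
    """ni — distinct respondents with at least one record for the species."""
    return dataset.n_citers(species_id)
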