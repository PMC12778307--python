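"""Synthetic survey generation and packaged study fixtures.

Two kinds of data live here:

1. :func:`generate_survey` — a seeded stochastic generator emulating the
   structure of a village-interview bushmeat survey: each respondent
   cites each species independently with a per-species probability, each
   citation reports 1-3 parts with specific uses drawn from a
   six-category multinomial, and carries one pebble-technique
   availability judgement. Sociodemographic attributes (gender,
   ethnicity, religion, age) are generated as inert respondent metadata;
   no index reads them.

2. :func:`table3_fixture` — a deterministic dataset over the 48 species
   of the Alédjo Wildlife Reserve use-importance table, reverse-
   engineered from the published index values: with 17 effective
   respondents, per-species citer counts ni = round(CF·17/100), distinct
   part-use counts RU = round(UV·185/100) and specific-use counts
   NSU = round(UDI·3/100) reproduce every published CF, UV and UDI at
   2 decimals. Note the published UV column is normalized against a
   base of 185 reported uses although the reconstructed per-species RU
   sum to 193 (the published UV column itself sums to 104.28%, not
   100%); the fixture therefore records ``reference_use_total = 185`` in
   its metadata so the published values can be reproduced, while the
   default (self-normalizing) analysis yields UV summing to 100.

:func:`aledjo_taxonomy` loads the packaged 49-species taxonomy and Red
List table for the same study area.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

from .data_model import (
    Availability,
    SurveyDataset,
    SurveyRecord,
    TaxonRecord,
    UseCategory,
    read_taxonomy,
)

__all__ = [
    "GeneratorConfig",
    "generate_survey",
    "table3_fixture",
    "aledjo_taxonomy",
    "TABLE3_PUBLISHED",
    "RESPONDENT_ATTRIBUTE_PRESET",
]

_CATEGORIES = list(UseCategory)
_AVAILABILITIES = list(Availability)

#: Sociodemographic proportions of the study's respondent pool, offered
#: as a generator preset; attributes are inert metadata.
RESPONDENT_ATTRIBUTE_PRESET = {
    "gender": {"male": 0.8255, "female": 0.1745},
    "ethnicity": {"Tem": 0.7987, "Kabye": 0.1007, "Fulani": 0.0705, "Moba": 0.0302},
    "religion": {"Islam": 0.6309, "Christianity": 0.2686, "Animism": 0.1007},
    "mean_age": 31,
}


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic survey generator.

    Defaults emulate the study conditions: a respondent pool of the
    field campaign's size, six use categories dominated by food
    (~0.68 of citations, with medicinal and traditional/cultural the
    main secondary uses), mostly single-part citations, and availability
    judgements centred on the middle of the abundance scale.
    """

    n_respondents: int = Field(298, ge=1)
    species_pool: list[str] = Field(min_length=1)
    citation_prob: dict[str, float] | float = 0.3
    parts_per_citation_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    use_category_probs: tuple[float, ...] = (
        0.68, 0.14, 0.02, 0.09, 0.03, 0.04
    )  # food, medicinal, cosmetic, traditional_cultural, artisanal, commercial
    nsu_range: tuple[int, int] = (1, 3)
    availability_probs: tuple[float, ...] = (0.10, 0.25, 0.35, 0.20, 0.10)
    seed: int = 0

    @field_validator("use_category_probs", "availability_probs",
                     "parts_per_citation_probs")
    @classmethod
    def _sums_to_one(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"probability vector must sum to 1, got {sum(v)}")
        if any(p < 0 for p in v):
            raise ValueError("probabilities must be non-negative")
        return v

    @model_validator(mode="after")
    def _check_lengths(self) -> "GeneratorConfig":
        if len(self.use_category_probs) != len(_CATEGORIES):
            raise ValueError("use_category_probs must have six entries")
        if len(self.availability_probs) != len(_AVAILABILITIES):
            raise ValueError("availability_probs must have five entries")
        lo, hi = self.nsu_range
        if not 1 <= lo <= hi:
            raise ValueError("nsu_range must satisfy 1 <= lo <= hi")
        if isinstance(self.citation_prob, dict):
            missing = set(self.species_pool) - set(self.citation_prob)
            if missing:
                raise ValueError(f"citation_prob missing species: {sorted(missing)}")
            probs = self.citation_prob.values()
        else:
            probs = [self.citation_prob]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("citation probabilities must lie in [0, 1]")
        return self

    def prob_for(self, species: str) -> float:
        if isinstance(self.citation_prob, dict):
            return self.citation_prob[species]
        return self.citation_prob


_PARTS = (
    "meat", "skin", "bone", "head", "fat", "tail", "whole animal",
    "organs", "blood", "teeth", "claws", "eggs", "liver", "heart",
    "bile", "scales", "feet", "brain",
)

# Specific-use vocabulary per category; the generator assembles a
# species' use repertoire by drawing categories then a label.
_SPECIFIC_USES = {
    UseCategory.FOOD: ("bushmeat consumption", "smoked meat", "soup preparation"),
    UseCategory.MEDICINAL: ("remedy preparation", "wound treatment", "fever remedy"),
    UseCategory.COSMETIC: ("skin ointment", "hair treatment"),
    UseCategory.TRADITIONAL_CULTURAL: ("ritual ceremony", "totem", "amulet"),
    UseCategory.ARTISANAL: ("leather craft", "ornament making"),
    UseCategory.COMMERCIAL: ("sale at market", "live animal trade"),
}


def _preset_choice(
    rng: np.random.Generator, preset: dict[str, float], n: int
) -> np.ndarray:
    # published percentages carry rounding error; renormalize
    p = np.asarray(list(preset.values()), dtype=float)
    return rng.choice(list(preset), size=n, p=p / p.sum())


def _draw_attributes(rng: np.random.Generator, n: int) -> dict[str, dict]:
    """Inert sociodemographic metadata per respondent, from the preset."""
    genders = _preset_choice(rng, RESPONDENT_ATTRIBUTE_PRESET["gender"], n)
    ethnicities = _preset_choice(rng, RESPONDENT_ATTRIBUTE_PRESET["ethnicity"], n)
    religions = _preset_choice(rng, RESPONDENT_ATTRIBUTE_PRESET["religion"], n)
    ages = rng.poisson(RESPONDENT_ATTRIBUTE_PRESET["mean_age"], size=n)
    return {
        f"R{i + 1:04d}": {
            "gender": str(genders[i]),
            "ethnicity": str(ethnicities[i]),
            "religion": str(religions[i]),
            "age": int(ages[i]),
        }
        for i in range(n)
    }


def generate_survey(config: GeneratorConfig) -> SurveyDataset:
    """Generate a seeded synthetic survey dataset.

    Each respondent cites species *s* with probability
    ``citation_prob[s]``; a citation emits one record per reported part
    (1-3 parts), each with a specific use drawn from the category
    multinomial, plus one availability judgement attached to the first
    record of the citation. The same seed always yields the same
    dataset.
    """
    rng = np.random.default_rng(config.seed)
    records: list[SurveyRecord] = []
    respondent_ids = [f"R{i + 1:04d}" for i in range(config.n_respondents)]
    attributes = _draw_attributes(rng, config.n_respondents)
    lo, hi = config.nsu_range
    for respondent in respondent_ids:
        for species in config.species_pool:
            if rng.random() >= config.prob_for(species):
                continue
            n_parts = 1 + rng.choice(3, p=config.parts_per_citation_probs)
            parts = rng.choice(len(_PARTS), size=int(n_parts), replace=False)
            availability = _AVAILABILITIES[
                rng.choice(len(_AVAILABILITIES), p=config.availability_probs)
            ]
            for j, part_idx in enumerate(parts):
                category = _CATEGORIES[
                    rng.choice(len(_CATEGORIES), p=config.use_category_probs)
                ]
                labels = _SPECIFIC_USES[category]
                label = labels[rng.integers(0, min(len(labels), hi))]
                records.append(
                    SurveyRecord(
                        respondent_id=respondent,
                        species_id=species,
                        part_used=_PARTS[part_idx],
                        use_category=category,
                        specific_use=label,
                        availability=availability if j == 0 else None,
                    )
                )
    if not records:
        # keep the respondent registry meaningful even if nobody cited
        raise ValueError(
            "generated survey is empty; raise citation_prob or n_respondents"
        )
    return SurveyDataset(
        records=records,
        registered_respondents=set(respondent_ids),
        metadata={
            "generator": "ethnozoo.synthetic_data.generate_survey",
            "seed": config.seed,
            "n_respondents": config.n_respondents,
            "respondent_attributes": attributes,
        },
    )


#: Published use-importance table: (species, CF%, UV%, UDI%, IVIU).
TABLE3_PUBLISHED: tuple[tuple[str, float, float, float, float], ...] = (
    ("Erythrocebus patas", 47.06, 1.62, 66.67, 115.35),
    ("Naja melanoleuca", 5.88, 4.32, 100.00, 110.21),
    ("Dendroaspis viridis", 35.29, 3.24, 66.67, 105.20),
    ("Python regius", 23.53, 9.19, 66.67, 99.39),
    ("Bitis arietans", 23.53, 5.41, 66.67, 95.60),
    ("Lycaon pictus", 47.06, 2.70, 33.33, 83.09),
    ("Tragelaphus scriptus", 47.06, 2.70, 33.33, 83.09),
    ("Xerus erythropus", 35.29, 3.24, 33.33, 71.87),
    ("Sylvicapra grimmia", 29.41, 6.49, 33.33, 69.23),
    ("Cephalophus rufilatus", 29.41, 6.49, 33.33, 69.23),
    ("Cercopithecus petaurista petaurista", 29.41, 3.78, 33.33, 66.53),
    ("Python sebae", 29.41, 4.32, 33.33, 67.07),
    ("Hystrix cristata", 29.41, 1.08, 33.33, 63.83),
    ("Marmota mumbled", 29.41, 0.54, 33.33, 63.29),
    ("Numida meleagris", 29.41, 0.54, 33.33, 63.29),
    ("Clarias spp.", 23.53, 1.08, 33.33, 57.94),
    ("Rattus rattus", 17.65, 6.49, 33.33, 57.47),
    ("Lemniscomys zebra", 23.53, 0.54, 33.33, 57.40),
    ("Mus mattheyi", 23.53, 0.54, 33.33, 57.40),
    ("Treron calvus", 17.65, 1.62, 33.33, 52.60),
    ("Ptilopachus petrosus", 17.65, 1.08, 33.33, 52.06),
    ("Eumenes pedunculatus", 17.65, 0.54, 33.33, 51.52),
    ("Pycnonotus barbatus", 17.65, 0.54, 33.33, 51.52),
    ("Atelerix albiventrix", 11.76, 2.70, 33.33, 47.80),
    ("Philantomba walteri", 11.76, 2.70, 33.33, 47.80),
    ("Phacochoerus africanus", 11.76, 0.54, 33.33, 45.64),
    ("Lepus microtis", 5.88, 5.95, 33.33, 45.16),
    ("Naja nigricollis", 5.88, 4.32, 33.33, 43.54),
    ("Thryonomys swinderianus", 5.88, 3.78, 33.33, 43.00),
    ("Francolinus bicalcaratus", 5.88, 2.70, 33.33, 41.92),
    ("Kobus kob ssp. kob", 5.88, 2.70, 33.33, 41.92),
    ("Kinixys homeana", 5.88, 1.08, 33.33, 40.30),
    ("Papio anubus", 5.88, 1.08, 33.33, 40.30),
    ("Varanus exanthematicus", 5.88, 1.08, 33.33, 40.30),
    ("Varanus niloticus", 5.88, 0.54, 33.33, 39.76),
    ("Accipiter melanoleucus", 5.88, 0.54, 33.33, 39.76),
    ("Apis mellifra", 5.88, 0.54, 33.33, 39.76),
    ("Atractaspis aterrima", 5.88, 0.54, 33.33, 39.76),
    ("Atractaspis dahomeyensis", 5.88, 0.54, 33.33, 39.76),
    ("Canis aureus", 5.88, 0.54, 33.33, 39.76),
    ("Chlorocebus tantalus", 5.88, 0.54, 33.33, 39.76),
    ("Eidolon helvum", 5.88, 0.54, 33.33, 39.76),
    ("Felis silvestris", 5.88, 0.54, 33.33, 39.76),
    ("Mus minutoides", 5.88, 0.54, 33.33, 39.76),
    ("Pandinus imperator", 5.88, 0.54, 33.33, 39.76),
    ("Phataginus tricuspis", 5.88, 0.54, 33.33, 39.76),
    ("Streptopelia semitorquata", 5.88, 0.54, 33.33, 39.76),
    ("Streptopelia vinacea", 5.88, 0.54, 33.33, 39.76),
)

#: Effective respondent count and use-value base behind the published table.
TABLE3_N_RESPONDENTS = 17
TABLE3_USE_TOTAL = 185
TABLE3_NSU_MAX = 3

# One specific use per diversity slot, each in a distinct category so a
# species with NSU uses also spans NSU use categories.
_FIXTURE_USES = (
    (UseCategory.FOOD, "bushmeat consumption"),
    (UseCategory.MEDICINAL, "remedy preparation"),
    (UseCategory.TRADITIONAL_CULTURAL, "ritual ceremony"),
)

# Deterministic availability per species: cycle the five categories in
# table order (the study does not publish per-species judgements).
_FIXTURE_AVAILABILITY = _AVAILABILITIES


def table3_fixture() -> SurveyDataset:
    """Deterministic survey dataset reproducing the published use table.

    For each species the dataset contains ``RU`` distinct (part,
    specific use) pairs — all reported by the species' first citing
    respondent — and one repeat citation of the first pair by each of
    the remaining ``ni - 1`` citers, so distinct-citer and distinct-use
    counts are exactly the reconstructed ni and RU. Every citer also
    carries the species' (cycled) availability judgement.
    """
    records: list[SurveyRecord] = []
    respondents = [f"F{i + 1:02d}" for i in range(TABLE3_N_RESPONDENTS)]
    cursor = 0  # rotate citers so all 17 respondents appear in the data
    for sp_idx, (species, cf, uv, udi, _) in enumerate(TABLE3_PUBLISHED):
        ni = round(cf * TABLE3_N_RESPONDENTS / 100)
        ru = round(uv * TABLE3_USE_TOTAL / 100)
        nsu = round(udi * TABLE3_NSU_MAX / 100)
        availability = _FIXTURE_AVAILABILITY[sp_idx % len(_FIXTURE_AVAILABILITY)]
        pairs = []
        for j in range(ru):
            category, label = _FIXTURE_USES[j % nsu]
            part = _PARTS[j % len(_PARTS)]
            if j >= len(_PARTS):  # > 18 distinct parts needed: suffix keeps pairs distinct
                part = f"{part} ({j // len(_PARTS) + 1})"
            pairs.append((part, category, label))
        citers = [
            respondents[(cursor + k) % TABLE3_N_RESPONDENTS] for k in range(ni)
        ]
        cursor += ni
        for part, category, label in pairs:
            records.append(
                SurveyRecord(
                    respondent_id=citers[0],
                    species_id=species,
                    part_used=part,
                    use_category=category,
                    specific_use=label,
                    availability=availability,
                )
            )
        for citer in citers[1:]:
            part, category, label = pairs[0]
            records.append(
                SurveyRecord(
                    respondent_id=citer,
                    species_id=species,
                    part_used=part,
                    use_category=category,
                    specific_use=label,
                    availability=availability,
                )
            )
    return SurveyDataset(
        records=records,
        metadata={
            "generator": "ethnozoo.synthetic_data.table3_fixture",
            "reference_use_total": TABLE3_USE_TOTAL,
            "n_respondents": TABLE3_N_RESPONDENTS,
        },
    )


def aledjo_taxonomy() -> list[TaxonRecord]:
    """The packaged 49-species taxonomy and Red List table."""
    source = resources.files("ethnozoo.data").joinpath("aledjo_taxonomy.csv")
    with resources.as_file(source) as path:
        return read_taxonomy(path)
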