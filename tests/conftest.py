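"""Shared fixtures and the independent brute-force oracle.

The oracle recomputes every counting primitive and index directly from
raw record tuples with plain loops and sets — no shared code with the
package's aggregation path — so tests can compare the two routes.
"""

from __future__ import annotations

import re

import pytest

from ethnozoo import SurveyDataset, SurveyRecord, table3_fixture
from ethnozoo.synthetic_data import (
    TABLE3_N_RESPONDENTS,
    TABLE3_PUBLISHED,
    TABLE3_USE_TOTAL,
    TABLE3_NSU_MAX,
)


def brute_force_indices(records):
    """Recount ni, RU, NSU, use-category breadth per species from raw tuples.

    ``records`` is an iterable of (respondent, species, part, category,
    specific_use) tuples. Returns {species: dict} with keys ni, ru, nsu,
    n_categories, plus "_n_respondents" / "_ru_total" entries.
    """

    def canon(label):
        return re.sub(r"\s+", " ", str(label).strip()).casefold()

    respondents = set()
    per_species = {}
    for resp, sp, part, cat, use in records:
        respondents.add(resp)
        d = per_species.setdefault(
            sp, {"citers": set(), "pairs": set(), "uses": set(), "cats": set()}
        )
        d["citers"].add(resp)
        d["pairs"].add((part, canon(use)))
        d["uses"].add(canon(use))
        d["cats"].add(cat)
    out = {
        sp: {
            "ni": len(d["citers"]),
            "ru": len(d["pairs"]),
            "nsu": len(d["uses"]),
            "n_categories": len(d["cats"]),
        }
        for sp, d in per_species.items()
    }
    out["_n_respondents"] = len(respondents)
    out["_ru_total"] = sum(v["ru"] for sp, v in out.items() if not sp.startswith("_"))
    return out


def as_tuples(dataset: SurveyDataset):
    return [
        (r.respondent_id, r.species_id, r.part_used, r.use_category, r.specific_use)
        for r in dataset.records
    ]


@pytest.fixture(scope="session")
def fixture_dataset() -> SurveyDataset:
    return table3_fixture()


@pytest.fixture(scope="session")
def published_table() -> dict[str, tuple[float, float, float, float]]:
    """Published per-species (CF, UV, UDI, IVIU) reference values."""
    return {sp: (cf, uv, udi, iviu) for sp, cf, uv, udi, iviu in TABLE3_PUBLISHED}


@pytest.fixture(scope="session")
def fixture_constants() -> dict[str, int]:
    return {
        "n_respondents": TABLE3_N_RESPONDENTS,
        "use_total": TABLE3_USE_TOTAL,
        "nsu_max": TABLE3_NSU_MAX,
    }


def make_dataset(rows) -> SurveyDataset:
    """Build a dataset from (respondent, species, part, category, use[, avail])."""
    records = []
    for row in rows:
        avail = row[5] if len(row) > 5 else None
        records.append(
            SurveyRecord(
                respondent_id=row[0],
                species_id=row[1],
                part_used=row[2],
                use_category=row[3],
                specific_use=row[4],
                availability=avail,
            )
        )
    return SurveyDataset(records=records)
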