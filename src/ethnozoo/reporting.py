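"""Pipeline orchestration: read → indices → vulnerability → summaries.

`run_pipeline` drives the full analysis from a :class:`RunConfig` and
writes a report bundle (CSV tables plus full-precision JSON and a run
manifest) to an output directory. Stage-level logging records the
record counts flowing through each stage so validation losses are
auditable.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import pandas as pd
from pydantic import BaseModel, model_validator

from . import __version__
from .data_model import SurveyDataset, TaxonRecord, read_survey, read_taxonomy
from .synthetic_data import GeneratorConfig, generate_survey, table3_fixture
from .use_indices import (
    UseIndices,
    compute_use_table,
    use_table_to_frame,
    use_typology_summary,
)
from .vulnerability import (
    VulnerabilityScore,
    compute_vulnerability_table,
    iucn_summary,
)

logger = logging.getLogger("ethnozoo")

__all__ = [
    "RunConfig",
    "ReportBundle",
    "run_pipeline",
    "diversity_tabulation",
]


class RunConfig(BaseModel):
    """Configuration of one pipeline run.

    Exactly one survey source must be supplied: a CSV path
    (``survey_path``), a generator configuration (``generator``), or the
    packaged deterministic fixture (``use_fixture=True``).
    """

    survey_path: Path | None = None
    taxonomy_path: Path | None = None
    generator: GeneratorConfig | None = None
    use_fixture: bool = False
    output_dir: Path = Path("ethnozoo_report")
    display_digits: int = 2
    tie_break: Literal["scarcer", "more_abundant"] = "scarcer"
    use_reference_total: bool = True  # honour fixture metadata's UV base
    column_map: dict[str, str] | None = None

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        sources = sum(
            [self.survey_path is not None, self.generator is not None,
             self.use_fixture]
        )
        if sources != 1:
            raise ValueError(
                "exactly one of survey_path, generator or use_fixture "
                "must be supplied"
            )
        return self


@dataclass
class ReportBundle:
    """In-memory results of a pipeline run."""

    dataset: SurveyDataset
    use_table: list[UseIndices]
    typology: dict
    vulnerability: list[VulnerabilityScore]
    taxa: list[TaxonRecord] | None
    iucn: dict[str, int] | None
    diversity: dict[str, dict[str, int]] | None
    manifest: dict


def diversity_tabulation(taxa: Iterable[TaxonRecord]) -> dict[str, dict[str, int]]:
    """Species counts by family, order and class.

    Each table is ordered by descending count, ties alphabetical, so
    output is deterministic.
    """
    taxa = list(taxa)
    if not taxa:
        raise ValueError("cannot tabulate an empty taxon list")
    out: dict[str, dict[str, int]] = {}
    for level, key in (
        ("family", lambda t: t.family),
        ("order", lambda t: t.order),
        ("class", lambda t: t.class_),
    ):
        counts = Counter(key(t) for t in taxa)
        out[level] = dict(
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
    return out


def _load_dataset(config: RunConfig) -> SurveyDataset:
    if config.use_fixture:
        logger.info("stage=load source=packaged-fixture")
        return table3_fixture()
    if config.generator is not None:
        logger.info("stage=load source=generator seed=%s", config.generator.seed)
        return generate_survey(config.generator)
    logger.info("stage=load source=%s", config.survey_path)
    return read_survey(config.survey_path, config.column_map)


def _vulnerability_frame(
    scores: list[VulnerabilityScore], digits: int
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": s.species_id,
                "P1": s.p1,
                "P2": s.p2,
                "P3": "" if s.p3 is None else s.p3,
                "VI": "" if s.vi is None else round(float(s.vi), digits),
                "class": "unscored" if s.vclass is None else s.vclass.value,
                "consensus": ""
                if s.consensus is None
                else round(s.consensus.consensus_value, digits),
            }
            for s in scores
        ]
    )


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Run the full analysis and write the report bundle.

    Writes ``use_table.csv``, ``use_typology.csv``,
    ``vulnerability.csv`` (plus ``iucn_summary.csv``,
    ``diversity_*.csv`` when a taxonomy is given), a full-precision
    ``results.json`` and a ``manifest.json`` into ``output_dir``.
    """
    dataset = _load_dataset(config)
    logger.info(
        "stage=validate records=%d respondents=%d species=%d",
        len(dataset.records), dataset.n_respondents, len(dataset.species()),
    )

    ru_total = None
    if config.use_reference_total:
        ru_total = dataset.metadata.get("reference_use_total")
    use_table = compute_use_table(dataset, ru_total=ru_total)
    logger.info("stage=use_indices species=%d ru_total=%s",
                len(use_table), ru_total or "data-derived")

    typology = use_typology_summary(dataset)
    vulnerability = compute_vulnerability_table(dataset, config.tie_break)
    unscored = sum(1 for s in vulnerability if s.vclass is None)
    logger.info("stage=vulnerability scored=%d unscored=%d",
                len(vulnerability) - unscored, unscored)

    taxa = iucn = diversity = None
    if config.taxonomy_path is not None:
        taxa = read_taxonomy(config.taxonomy_path)
        iucn = iucn_summary(taxa)
        diversity = diversity_tabulation(taxa)
        logger.info("stage=taxonomy species=%d", len(taxa))

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    digits = config.display_digits

    use_table_to_frame(use_table, digits).to_csv(out / "use_table.csv", index=False)
    pd.DataFrame(
        [(c.value, round(p, digits)) for c, p in typology.items()],
        columns=["use_category", "percent"],
    ).to_csv(out / "use_typology.csv", index=False)
    _vulnerability_frame(vulnerability, digits).to_csv(
        out / "vulnerability.csv", index=False
    )
    if taxa is not None:
        pd.DataFrame(
            sorted(iucn.items()), columns=["category", "count"]
        ).to_csv(out / "iucn_summary.csv", index=False)
        for level, table in diversity.items():
            pd.DataFrame(
                table.items(), columns=[level, "species_count"]
            ).to_csv(out / f"diversity_{level}.csv", index=False)

    results = {
        "use_table": [vars(r) for r in use_table],
        "use_typology": {c.value: p for c, p in typology.items()},
        "vulnerability": [
            {
                "species_id": s.species_id,
                "p1": s.p1,
                "p2": s.p2,
                "p3": s.p3,
                "vi": None if s.vi is None else float(s.vi),
                "class": None if s.vclass is None else s.vclass.value,
            }
            for s in vulnerability
        ],
        "iucn_summary": iucn,
        "diversity": diversity,
    }
    (out / "results.json").write_text(json.dumps(results, indent=2))

    manifest = {
        "version": __version__,
        "survey_source": (
            "fixture" if config.use_fixture
            else "generator" if config.generator is not None
            else str(config.survey_path)
        ),
        "seed": None if config.generator is None else config.generator.seed,
        "taxonomy": None if config.taxonomy_path is None else str(config.taxonomy_path),
        "n_records": len(dataset.records),
        "n_respondents": dataset.n_respondents,
        "n_species": len(dataset.species()),
        "uv_denominator": ru_total if ru_total is not None
        else dataset.total_reported_use(),
        "display_digits": digits,
        "tie_break": config.tie_break,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("stage=report output=%s", out)

    return ReportBundle(
        dataset=dataset,
        use_table=use_table,
        typology=typology,
        vulnerability=vulnerability,
        taxa=taxa,
        iucn=iucn,
        diversity=diversity,
        manifest=manifest,
    )
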