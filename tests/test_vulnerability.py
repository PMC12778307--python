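"""Vulnerability scaling, consensus availability, VI classification, IUCN."""

import itertools
from fractions import Fraction

import pytest

from conftest import make_dataset

from ethnozoo import (
    Availability,
    IUCNCategory,
    TaxonRecord,
    UseCategory,
    VulnerabilityClass,
    aledjo_taxonomy,
    compute_vulnerability_table,
    consensus_availability,
    iucn_summary,
    scale_citation_frequency,
    scale_presence,
    scale_use_categories,
    vulnerability_index,
)


@pytest.mark.parametrize(
    "cf,level",
    [(0, 1), (4.9, 1), (5.0, 2), (5.88, 2), (14.99, 2), (15.0, 3), (47.06, 3), (100, 3)],
)
def test_scale_citation_frequency(cf, level):
    assert scale_citation_frequency(cf) == level


@pytest.mark.parametrize("k,level", [(0, 1), (1, 1), (2, 2), (3, 2), (4, 3), (6, 3)])
def test_scale_use_categories(k, level):
    assert scale_use_categories(k) == level


@pytest.mark.parametrize(
    "category,level",
    [
        (Availability.VERY_ABUNDANT, 1),
        (Availability.ABUNDANT, 1),
        (Availability.NOT_ABUNDANT, 2),
        (Availability.RARE, 3),
        (Availability.VERY_RARE, 3),
    ],
)
def test_scale_presence(category, level):
    assert scale_presence(category) == level


def test_scale_domain_errors():
    with pytest.raises(ValueError):
        scale_citation_frequency(101)
    with pytest.raises(ValueError):
        scale_use_categories(-1)
    with pytest.raises(ValueError):
        vulnerability_index(0, 1, 1)


def test_consensus_mode_and_value():
    judgements = [Availability.RARE, Availability.RARE, Availability.ABUNDANT]
    c = consensus_availability(judgements, "X")
    assert c.modal_category is Availability.RARE
    assert c.consensus_value == pytest.approx(2 / 3)
    single = consensus_availability([Availability.ABUNDANT])
    assert single.modal_category is Availability.ABUNDANT
    assert single.consensus_value == 1.0
    with pytest.raises(ValueError):
        consensus_availability([])


def test_consensus_tie_breaks_exhaustive_two_judgements():
    """Over every pair of categories, a tie resolves to the scarcer one
    (precautionary default) or the more abundant one when configured."""
    for a, b in itertools.product(Availability, repeat=2):
        scarcer = max(a, b, key=lambda c: c.scarcity_rank)
        abundant = min(a, b, key=lambda c: c.scarcity_rank)
        assert consensus_availability([a, b]).modal_category is scarcer
        assert (
            consensus_availability([a, b], tie_break="more_abundant").modal_category
            is abundant
        )
        assert consensus_availability([a, b]).consensus_value == (
            1.0 if a is b else 0.5
        )


def _hand_rule(total):
    """Independent statement of the three-class rule on P1+P2+P3."""
    if total < 6:  # VI < 2
        return VulnerabilityClass.LESS_VULNERABLE
    if total < 7.5:  # 2 <= VI < 2.5
        return VulnerabilityClass.MODERATELY_VULNERABLE
    return VulnerabilityClass.VULNERABLE


def test_vulnerability_index_matches_enumeration_of_all_27_triples():
    """vi = (p1+p2+p3)/3 exactly, and the class matches an independent
    hand rule, over every (P1, P2, P3) triple."""
    for p1, p2, p3 in itertools.product((1, 2, 3), repeat=3):
        vi, vclass = vulnerability_index(p1, p2, p3)
        assert vi == Fraction(p1 + p2 + p3, 3)
        assert vclass is _hand_rule(p1 + p2 + p3)


def test_boundary_classification_is_inclusive():
    """VI = 2 is moderately vulnerable; VI = 2.5 does not occur on thirds,
    but the nearest sums straddle the vulnerable bound as printed."""
    assert vulnerability_index(2, 2, 2) == (
        Fraction(2),
        VulnerabilityClass.MODERATELY_VULNERABLE,
    )
    vi, vclass = vulnerability_index(3, 3, 1)  # 7/3 < 2.5
    assert vclass is VulnerabilityClass.MODERATELY_VULNERABLE
    vi, vclass = vulnerability_index(3, 3, 2)  # 8/3 >= 2.5
    assert vclass is VulnerabilityClass.VULNERABLE


def test_vi_monotone_in_each_parameter():
    """Raising any parameter never lowers VI or softens the class."""
    order = list(VulnerabilityClass)
    for p1, p2, p3 in itertools.product((1, 2, 3), repeat=3):
        vi, vclass = vulnerability_index(p1, p2, p3)
        for bumped in ((p1 + 1, p2, p3), (p1, p2 + 1, p3), (p1, p2, p3 + 1)):
            if max(bumped) > 3:
                continue
            vi2, vclass2 = vulnerability_index(*bumped)
            assert vi2 >= vi
            assert order.index(vclass2) >= order.index(vclass)


def test_heavily_used_scarce_species_are_moderately_vulnerable():
    """cf >= 15, 2-3 use categories, judged scarce → VI = 7/3 for every
    species (forced by the scaling rules)."""
    rows = []
    for sp in ("A sp", "B sp"):
        for resp in ("R1", "R2"):
            rows += [
                (resp, sp, "meat", UseCategory.FOOD, "grilled",
                 Availability.NOT_ABUNDANT),
                (resp, sp, "bone", UseCategory.MEDICINAL, "powder remedy",
                 Availability.NOT_ABUNDANT),
            ]
    scores = compute_vulnerability_table(make_dataset(rows))
    assert all(s.vi == Fraction(7, 3) for s in scores)
    assert all(s.vclass is VulnerabilityClass.MODERATELY_VULNERABLE for s in scores)


def test_sole_respondent_abundant_species_is_less_vulnerable():
    """A single-respondent dataset has cf = 100 (P1 = 3), one category and
    abundance give P2 = P3 = 1 → VI = 5/3, less vulnerable."""
    scores = compute_vulnerability_table(
        make_dataset(
            [("R1", "X", "meat", UseCategory.FOOD, "grilled", Availability.ABUNDANT)]
        )
    )
    (s,) = scores
    assert (s.p1, s.p2, s.p3) == (3, 1, 1)
    assert s.vi == Fraction(5, 3)
    assert s.vclass is VulnerabilityClass.LESS_VULNERABLE


def test_species_without_judgements_is_flagged_not_classified():
    scores = compute_vulnerability_table(
        make_dataset(
            [
                ("R1", "X", "meat", UseCategory.FOOD, "grilled", Availability.RARE),
                ("R1", "Y", "meat", UseCategory.FOOD, "grilled"),
            ]
        )
    )
    by_id = {s.species_id: s for s in scores}
    assert by_id["Y"].p3 is None and by_id["Y"].vclass is None
    assert by_id["X"].vclass is not None
    # partition: every species is scored exactly once
    assert sorted(by_id) == ["X", "Y"]


def test_iucn_summary_on_packaged_taxonomy():
    """The study area's Red List table: 5 NT + 2 CR + 1 EN + 1 VU = 9
    globally threatened or near-threatened species."""
    summary = iucn_summary(aledjo_taxonomy())
    assert summary["NT"] == 5
    assert summary["CR"] == 2
    assert summary["EN"] == 1
    assert summary["VU"] == 1
    assert summary["DD"] == 2
    assert summary["NE"] == 2
    assert summary["threatened_or_near"] == 9


def test_iucn_summary_all_least_concern():
    taxa = [
        TaxonRecord(f"Sp {i}", "x", "G", "F", "O", "C", IUCNCategory.LC)
        for i in range(3)
    ]
    summary = iucn_summary(taxa)
    assert summary["threatened_or_near"] == 0
    assert summary["LC"] == 3
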