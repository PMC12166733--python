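"""Fisher enrichment, the Bayesian PoP combiner and PM1 reclassification."""

import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from scipy.stats import hypergeom

from featshift import (ContingencyTable, Evidence, EvidenceSet,
                       FrameworkParams, VariantRecord, build_contingency,
                       classify_pop, compute_pop, enrich_features,
                       fisher_enrichment, reclassify_vus)


def fisher_two_sided_oracle(a, b, c, d):
    """Hypergeometric enumeration: sum P(tables with the same margins) over
    tables whose probability does not exceed the observed one."""
    N = a + b + c + d
    r = a + b        # first-row total
    k = a + c        # first-column total
    lo, hi = max(0, r + k - N), min(r, k)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, N, k, r)
    p_obs = hypergeom.pmf(a, N, k, r)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def pop_oracle(points, prior="0.1", odds_vs="350"):
    """Closed-form PoP at 50-digit precision, independent of the package."""
    getcontext().prec = 50
    prior = Decimal(prior)
    odds = Decimal(odds_vs) ** (Decimal(points) / Decimal(8))
    return float((odds * prior) / ((odds - 1) * prior + 1))


def _variants(labels):
    out = []
    for i, label in enumerate(labels):
        out.append(VariantRecord(f"P{i}", 1, "M", "K", label))
    return out


class TestBuildContingency:
    def test_counts_partition_variant_set(self):
        labels = (["pathogenic"] * 2 + ["benign"] * 1 + ["pathogenic"] * 3
                  + ["benign"] * 4)
        inside = [True] * 3 + [False] * 7
        table, excluded = build_contingency(_variants(labels), inside)
        assert (table.a, table.b, table.c, table.d) == (2, 1, 3, 4)
        assert excluded == 0

    def test_vus_excluded_and_counted(self):
        labels = ["pathogenic", "VUS", "benign", "VUS"]
        table, excluded = build_contingency(_variants(labels),
                                            [True, True, False, False])
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 1)
        assert excluded == 2

    def test_empty_variant_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_contingency([], [])

    def test_fixture_cohort_shows_designed_excess(self, fixture_set):
        """With pathogenic variants planted inside features at 0.8 vs benign
        at 0.2, the pathogenic in-feature rate must exceed the benign one."""
        truth = {t.protein_id: t for t in fixture_set.true_tracks}
        variants = [v for v in fixture_set.variants if v.label != "VUS"]
        membership = [bool(truth[v.protein_id].labels[v.position - 1])
                      for v in variants]
        table, _ = build_contingency(variants, membership)
        assert table.a / (table.a + table.c) > table.b / (table.b + table.d)


class TestFisherEnrichment:
    def test_balanced_table(self):
        res = fisher_enrichment(ContingencyTable(10, 10, 10, 10))
        assert res.odds_ratio == 1.0
        assert res.p_value == 1.0
        assert res.direction == "neither"

    def test_enriched_table_or_and_oracle_p(self):
        res = fisher_enrichment(ContingencyTable(20, 5, 10, 50))
        assert res.odds_ratio == pytest.approx(20.0)
        assert res.p_value == pytest.approx(
            fisher_two_sided_oracle(20, 5, 10, 50), rel=1e-9)
        assert res.direction == "pathogenic-enriched"

    def test_simultaneous_row_column_swap_invariant(self):
        r1 = fisher_enrichment(ContingencyTable(20, 5, 10, 50))
        r2 = fisher_enrichment(ContingencyTable(50, 10, 5, 20))  # d,c,b,a
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_zero_cell_reports_infinite_or(self):
        res = fisher_enrichment(ContingencyTable(5, 0, 3, 7))
        assert math.isinf(res.odds_ratio) and res.or_infinite
        assert 0 <= res.p_value <= 1

    def test_haldane_correction_finite(self):
        res = fisher_enrichment(ContingencyTable(5, 0, 3, 7),
                                haldane_correction=True)
        assert res.odds_ratio == pytest.approx((5.5 * 7.5) / (0.5 * 3.5))

    def test_oracle_equivalence_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            res = fisher_enrichment(ContingencyTable(a, b, c, d))
            assert res.p_value == pytest.approx(
                fisher_two_sided_oracle(a, b, c, d), rel=1e-7, abs=1e-12)

    def test_or_directionally_consistent(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            res = fisher_enrichment(ContingencyTable(a, b, c, d))
            if a / (a + c) > b / (b + d):
                assert res.odds_ratio > 1

    def test_bh_adjustment_across_features(self):
        tables = {
            "motif": ContingencyTable(40, 5, 10, 45),
            "domain": ContingencyTable(10, 10, 10, 10),
            "turn": ContingencyTable(5, 40, 45, 10),
        }
        report = enrich_features(tables, multiple_testing="bh")
        directions = dict(zip(report["feature"], report["direction"]))
        assert directions["motif"] == "pathogenic-enriched"
        assert directions["domain"] == "neither"
        assert directions["turn"] == "benign-enriched"
        assert (report["p_adjusted"] >= report["p_value"] - 1e-15).all()


class TestComputePop:
    def test_no_evidence_returns_prior_exactly(self):
        for prior in (0.1, 0.25, 0.5):
            assert compute_pop(EvidenceSet(),
                               FrameworkParams(prior=prior)) == prior

    def test_single_moderate_criterion_closed_form(self):
        """One moderate criterion (2 points): O = 350^(1/4), PoP ≈ 0.302."""
        pop = compute_pop(EvidenceSet((Evidence("PM1", "moderate"),)))
        assert pop == pytest.approx(pop_oracle(2), rel=1e-12)
        assert pop == pytest.approx(0.3246, abs=5e-4)

    @pytest.mark.parametrize("tiers,points", [
        (("supporting",), 1), (("moderate",), 2), (("strong",), 4),
        (("very strong",), 8), (("moderate", "strong"), 6),
        (("supporting", "supporting", "moderate"), 4),
    ])
    def test_matches_decimal_oracle(self, tiers, points):
        ev = EvidenceSet(tuple(Evidence(f"E{i}", t)
                               for i, t in enumerate(tiers)))
        assert ev.points == points
        assert compute_pop(ev) == pytest.approx(pop_oracle(points), rel=1e-12)

    def test_benign_evidence_counts_negative(self):
        ev = EvidenceSet((Evidence("BS1", "strong", "benign"),))
        assert ev.points == -4
        assert compute_pop(ev) == pytest.approx(pop_oracle(-4), rel=1e-12)

    def test_monotone_in_pathogenic_evidence(self):
        """Adding any pathogenic criterion strictly increases PoP; adding any
        benign criterion strictly decreases it."""
        rng = np.random.default_rng(0)
        tiers = list(("supporting", "moderate", "strong", "very strong"))
        for _ in range(30):
            base = EvidenceSet(tuple(
                Evidence(f"E{i}", tiers[int(rng.integers(4))],
                         ["pathogenic", "benign"][int(rng.integers(2))])
                for i in range(int(rng.integers(0, 4)))))
            p0 = compute_pop(base)
            for tier in tiers:
                up = EvidenceSet(base.items + (Evidence("X", tier),))
                down = EvidenceSet(base.items
                                   + (Evidence("X", tier, "benign"),))
                assert compute_pop(up) > p0
                assert compute_pop(down) < p0

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError, match="prior"):
            FrameworkParams(prior=0.0)


class TestReclassifyVus:
    def test_outside_enriched_features_unchanged(self):
        variants = _variants(["VUS"])
        pairs = [(variants[0], EvidenceSet((Evidence("PP3", "supporting"),)))]
        report = reclassify_vus(pairs, [False])
        row = report.iloc[0]
        assert row["pop_before"] == row["pop_after"]
        assert not row["reclassified"]

    def test_boundary_vus_flips_to_pathogenic_with_pm1(self):
        """One strong plus one moderate criterion (6 points) give
        PoP ≈ 0.8999, just below the 0.9 boundary (a VUS); adding moderate
        PM1 pushes the variant over into the pathogenic class."""
        ev = EvidenceSet((Evidence("PS1", "strong"),
                          Evidence("PM2", "moderate")))
        pop0 = compute_pop(ev)
        assert 0.85 < pop0 < 0.9 and classify_pop(pop0) == "VUS"
        pairs = [(VariantRecord("P0", 1, "M", "K", "VUS"), ev)]
        report = reclassify_vus(pairs, [True])
        row = report.iloc[0]
        assert row["class_before"] == "VUS"
        assert row["class_after"] == "pathogenic"
        assert row["reclassified"]
        assert row["pop_after"] == pytest.approx(pop_oracle(8), rel=1e-12)

    def test_reclassified_fraction_definition(self):
        ev_flip = EvidenceSet((Evidence("PS1", "strong"),
                               Evidence("PM2", "moderate")))
        ev_stay = EvidenceSet((Evidence("PP3", "supporting"),))
        pairs = [
            (VariantRecord("P0", 1, "M", "K"), ev_flip),
            (VariantRecord("P1", 1, "M", "K"), ev_stay),
            (VariantRecord("P2", 1, "M", "K"), EvidenceSet()),
        ]
        report = reclassify_vus(pairs, [True, True, False])
        n_changed = int(report["reclassified"].sum())
        # the empty evidence set sits exactly at the prior (0.1), which is
        # the benign boundary, so only the first two are baseline VUS
        assert report.attrs["n_vus"] == 2
        assert report.attrs["reclassified_fraction"] == n_changed / 2
        assert 0 <= report.attrs["reclassified_fraction"] <= 1

    def test_reclassification_never_moves_toward_benign(self):
        """PM1 is pathogenic evidence: pop_after >= pop_before always."""
        rng = np.random.default_rng(7)
        tiers = ("supporting", "moderate", "strong")
        pairs, membership = [], []
        for i in range(40):
            items = tuple(
                Evidence(f"E{j}", tiers[int(rng.integers(3))],
                         ["pathogenic", "benign"][int(rng.integers(2))])
                for j in range(int(rng.integers(0, 4))))
            pairs.append((VariantRecord(f"P{i}", 1, "M", "K"),
                          EvidenceSet(items)))
            membership.append(bool(rng.integers(2)))
        report = reclassify_vus(pairs, membership)
        assert (report["pop_after"] >= report["pop_before"] - 1e-15).all()
        assert not ((report["class_before"] != "benign")
                    & (report["class_after"] == "benign")).any()
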