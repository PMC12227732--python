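import itertools
import logging

import numpy as np
import pytest

from viroclean.decontam import (
    build_negativeome,
    decontaminate,
    decontamination_summary,
    species_decontaminate,
    strain_decontaminate,
    strain_sharing,
    votu_sharing,
)
from viroclean.strains import StrainComparison
from viroclean.synthetic import evaluate_against_truth

from conftest import toy_matrix


@pytest.fixture
def two_study_matrix():
    """2 studies, 2 samples + 1 NC each, 4 vOTUs with known NC content."""
    meta = [
        ("A_s1", "A", "sample"), ("A_s2", "A", "sample"), ("A_nc", "A", "nc"),
        ("B_s1", "B", "sample"), ("B_s2", "B", "sample"), ("B_nc", "B", "nc"),
    ]
    rpkm = {
        # v1: in NCs of both studies
        "v1": {"A_s1": 6.0, "A_nc": 1.0, "B_s1": 2.0, "B_nc": 4.0},
        # v2: only study A's NC
        "v2": {"A_s1": 3.0, "A_s2": 5.0, "A_nc": 2.0},
        # v3: only study B's NC
        "v3": {"B_s2": 1.0, "B_nc": 9.0, "A_s1": 1.0},
        # v4: never in NCs
        "v4": {"A_s2": 2.0, "B_s1": 8.0, "B_s2": 3.0},
    }
    return toy_matrix(rpkm, meta)


class TestBuildNegativeome:
    def test_entries_and_overlap_histogram(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        assert catalog.votus_for_study("A") == {"v1", "v2"}
        assert catalog.votus_for_study("B") == {"v1", "v3"}
        assert catalog.ncs_for("v2", "A") == ("A_nc",)
        assert catalog.overlap_histogram() == {1: 2, 2: 1}

    def test_histogram_matches_set_algebra_oracle(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        per_study = {
            st: catalog.votus_for_study(st) for st in ("A", "B")
        }
        oracle = {}
        for v in set(itertools.chain(*per_study.values())):
            k = sum(v in votus for votus in per_study.values())
            oracle[k] = oracle.get(k, 0) + 1
        assert catalog.overlap_histogram() == oracle

    def test_no_ncs_rejected(self):
        m = toy_matrix({"v1": {"s1": 1.0}}, [("s1", "A", "sample")])
        with pytest.raises(ValueError, match="negative controls"):
            build_negativeome(m)


class TestVotuSharing:
    def test_own_study_metrics(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        records, metrics = votu_sharing(two_study_matrix, catalog, "own_study")
        # A_s1 detects v1, v2, v3 (richness 3); own negativeome = {v1, v2}
        assert metrics.at["A_s1", "n_shared"] == 2
        assert metrics.at["A_s1", "pct_richness_shared"] == pytest.approx(100 * 2 / 3)
        # abundance share: (6 + 3) / (6 + 3 + 1)
        assert metrics.at["A_s1", "pct_abundance_shared"] == pytest.approx(90.0)
        shared = {(r.sample_id, r.votu_id) for r in records}
        assert ("A_s1", "v3") not in shared and ("A_s1", "v1") in shared

    def test_no_overlap_gives_zero(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        _, metrics = votu_sharing(two_study_matrix, catalog, "own_study")
        # A_s2 detects v2, v4; only v2 is in own negativeome
        assert metrics.at["A_s2", "n_shared"] == 1
        # B_s1 detects v1, v4; own (B) negativeome has v1, v3
        assert metrics.at["B_s1", "n_shared"] == 1

    def test_external_scope_uses_other_studies(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        _, metrics = votu_sharing(two_study_matrix, catalog, "external")
        # A_s1 detects v1,v2,v3; other-study (B) negativeome = {v1, v3}
        assert metrics.at["A_s1", "n_shared"] == 2


def comp(votu, a, b, popani_diff, compared=10_000, L=10_000):
    return StrainComparison(votu, a, b, L, compared, popani_diff, popani_diff)


class TestStrainSharing:
    def test_identical_strain_promoted(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        comps = [comp("v1", "A_s1", "A_nc", 0)]
        promoted = strain_sharing(records, comps)
        assert {(r.sample_id, r.votu_id) for r in promoted} == {("A_s1", "v1")}
        assert promoted[0].level == "strain"

    def test_divergent_strain_not_promoted(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        comps = [comp("v1", "A_s1", "A_nc", 50)]  # popANI 99.5
        assert strain_sharing(records, comps) == []

    def test_low_fraction_promoted_only_in_decontamination_mode(
        self, two_study_matrix
    ):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        comps = [comp("v1", "A_s1", "A_nc", 0, compared=4000)]  # fraction 0.4
        assert strain_sharing(records, comps, mode="analysis") == []
        promoted = strain_sharing(records, comps, mode="decontamination")
        assert {(r.sample_id, r.votu_id) for r in promoted} == {("A_s1", "v1")}

    def test_missing_comparison_warns_and_skips(self, two_study_matrix, caplog):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        with caplog.at_level(logging.WARNING, logger="viroclean.decontam"):
            promoted = strain_sharing(records, [])
        assert promoted == []
        assert "no strain comparison" in caplog.text


class TestDecontaminate:
    def test_planted_contaminant_cell_zeroed(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        comps = [comp("v1", "A_s1", "A_nc", 0)]
        strain_records = strain_sharing(records, comps)
        clean, report = strain_decontaminate(two_study_matrix, strain_records)
        assert clean.rpkm.at["v1", "A_s1"] == 0.0
        assert (
            report.per_sample.at["A_s1", "richness_before"]
            - report.per_sample.at["A_s1", "richness_after_strain"]
        ) == 1
        # every other cell untouched
        diff = two_study_matrix.rpkm - clean.rpkm
        assert diff.drop(index="v1").to_numpy().sum() == 0
        assert diff.at["v1", "A_s1"] == 6.0

    def test_different_strain_cell_untouched(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        records, _ = votu_sharing(two_study_matrix, catalog, "own_study")
        comps = [comp("v1", "A_s1", "A_nc", 50)]
        clean, _ = strain_decontaminate(
            two_study_matrix, strain_sharing(records, comps)
        )
        assert clean.rpkm.equals(two_study_matrix.rpkm)

    def test_species_level_zeroes_all_own_study_cells(self, two_study_matrix):
        catalog = build_negativeome(two_study_matrix)
        clean, report = species_decontaminate(two_study_matrix, catalog)
        assert clean.rpkm.at["v2", "A_s1"] == 0.0
        assert clean.rpkm.at["v2", "A_s2"] == 0.0
        # v3 is only in study B's NC: untouched in study A samples
        assert clean.rpkm.at["v3", "A_s1"] == 1.0
        assert clean.rpkm.at["v3", "B_s2"] == 0.0
        assert report.removed_species["A_s1"] == ["v1", "v2"]

    def test_full_run_invariants_on_simulation(
        self, default_dataset, default_comparisons
    ):
        matrix = default_dataset.matrix
        outcome = decontaminate(matrix, default_comparisons)
        before = matrix.rpkm.to_numpy()
        for clean in (outcome.strain_matrix, outcome.species_matrix):
            after = clean.rpkm.to_numpy()
            assert (after <= before).all()  # zeros only
            changed = after != before
            assert (after[changed] == 0).all()
        for s, votus in outcome.report.removed_strain.items():
            assert set(votus) <= set(outcome.report.removed_species[s])
        per = outcome.report.per_sample
        assert (per["richness_after_strain"] >= per["richness_after_species"]).all()

    def test_idempotent(self, default_dataset, default_comparisons):
        outcome = decontaminate(default_dataset.matrix, default_comparisons)
        again = decontaminate(outcome.strain_matrix, default_comparisons)
        assert again.strain_matrix.rpkm.equals(outcome.strain_matrix.rpkm)

    def test_recovers_planted_truth(self, default_dataset, default_comparisons):
        outcome = decontaminate(default_dataset.matrix, default_comparisons)
        metrics = evaluate_against_truth(
            outcome.report.removed_strain, default_dataset.truth,
            default_dataset.matrix,
        )
        assert metrics.sensitivity == 1.0
        assert metrics.false_removal_rate == 0.0


class TestSummary:
    def test_all_clean_study_zero_drops(self):
        m = toy_matrix(
            {"v1": {"s1": 1.0, "nc1": 0.0}, "v2": {"s1": 2.0, "nc1": 3.0}},
            [("s1", "A", "sample"), ("nc1", "A", "nc")],
        )
        outcome = decontaminate(m, [comp("v2", "s1", "nc1", 100)])
        summary = decontamination_summary(
            outcome.report, m.sample_meta, contaminated_only=False
        )
        assert summary.at["A", "pct_richness_drop_strain_median"] == 0.0

    def test_medians_match_quantile_oracle(
        self, default_dataset, default_comparisons
    ):
        outcome = decontaminate(default_dataset.matrix, default_comparisons)
        summary = decontamination_summary(
            outcome.report, default_dataset.matrix.sample_meta
        )
        per = outcome.report.per_sample.copy()
        per["study"] = default_dataset.matrix.sample_meta.loc[per.index, "study"]
        per = per[per["pct_richness_shared_votu"] > 0]
        drops = 100 * (
            per["richness_before"] - per["richness_after_species"]
        ) / per["richness_before"]
        for study, grp in drops.groupby(per["study"]):
            assert summary.at[study, "pct_richness_drop_species_median"] == (
                pytest.approx(np.median(grp))
            )
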