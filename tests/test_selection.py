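import numpy as np
import pytest

from conftest import make_annotation
from seropanel.errors import SelectionError, SeropanelError
from seropanel.io import AnalyteMatrix
from seropanel.ks import ks_two_sample
from seropanel.search import BeamSearchConfig
from seropanel.selection import (
    SelectionConfig,
    candidate_set,
    define_populations,
    select_biomarkers,
)
from seropanel.synthetic import SiteSpec, SyntheticConfig, default_study_mimic, generate


class TestDefinePopulations:
    def test_tiny_cohort(self):
        annotations = [
            make_annotation("S1", "case"),
            make_annotation("S2", "case"),
            make_annotation("S3", "control", control_subtype="benign_nodule"),
            make_annotation("S4", "control", control_subtype="smoker_no_nodule"),
        ]
        pop1, pop2 = define_populations(annotations)
        assert pop1.tolist() == [True, True, True, False]
        assert pop2.tolist() == [True, True, False, True]

    def test_study_mimic_population_sizes(self):
        _, annotations = generate(
            default_study_mimic(
                seed=0, n_analytes=5, n_disease_markers=2, n_site_artifacts=1
            )
        )
        pop1, pop2 = define_populations(annotations)
        cases = np.array([a.is_case for a in annotations])
        assert int((pop1 & ~cases).sum()) == 565  # benign-nodule controls
        assert int((pop2 & ~cases).sum()) == 470  # all other smoker controls

    def test_all_nodule_controls_rejected(self):
        annotations = [
            make_annotation("S1", "case"),
            make_annotation("S2", "control", control_subtype="benign_nodule"),
        ]
        with pytest.raises(SelectionError, match="non-nodule"):
            define_populations(annotations)

    def test_no_nodule_controls_rejected(self):
        annotations = [
            make_annotation("S1", "case"),
            make_annotation("S2", "control", control_subtype="smoker_no_nodule"),
        ]
        with pytest.raises(SelectionError, match="benign-nodule"):
            define_populations(annotations)


def _shifted_cohort():
    """Constructed instance: analyte 0 separates classes pooled but not at
    site BB (effect present only at site AA); analyte 1 is null."""
    rng = np.random.default_rng(77)
    n_per = 120
    annotations, rows = [], []
    for site, effect in (("AA", 2.0), ("BB", 0.0)):
        for i in range(n_per):
            is_case = i < n_per // 2
            sid = f"{site}{i}"
            annotations.append(
                make_annotation(sid, "case" if is_case else "control", site=site)
            )
            x0 = rng.normal(effect if is_case else 0.0, 1.0)
            x1 = rng.normal(0.0, 1.0)
            rows.append([np.exp(x0), np.exp(x1)])
    matrix = AnalyteMatrix([a.sample_id for a in annotations], ["A0", "A1"], rows)
    return matrix, annotations


class TestCandidateSet:
    def test_combined_but_not_per_site(self):
        matrix, annotations = _shifted_cohort()
        mask = np.ones(len(annotations), dtype=bool)
        combined = candidate_set(matrix, annotations, mask, "combined")
        per_site = candidate_set(matrix, annotations, mask, "per_site")
        both = candidate_set(matrix, annotations, mask, "both")
        assert "A0" in combined
        assert "A0" not in per_site
        assert "A0" not in both
        assert "A1" not in combined

    def test_both_is_intersection(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        mask = np.ones(len(annotations), dtype=bool)
        combined = set(candidate_set(matrix, annotations, mask, "combined"))
        per_site = set(candidate_set(matrix, annotations, mask, "per_site"))
        both = set(candidate_set(matrix, annotations, mask, "both"))
        assert both == combined & per_site

    def test_ks_threshold_monotonicity(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        mask = np.ones(len(annotations), dtype=bool)
        loose = candidate_set(
            matrix, annotations, mask, "combined", SelectionConfig(ks_threshold=0.1)
        )
        tight = candidate_set(
            matrix, annotations, mask, "combined", SelectionConfig(ks_threshold=0.4)
        )
        assert set(tight) <= set(loose)

    def test_exclusion_list_applied(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        mask = np.ones(len(annotations), dtype=bool)
        config = SelectionConfig(ks_threshold=0.1, exclusion_list=("A0000",))
        assert "A0000" not in candidate_set(matrix, annotations, mask, "combined", config)

    def test_empty_population_rejected(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        with pytest.raises(SeropanelError, match="empty"):
            candidate_set(
                matrix, annotations, np.zeros(len(annotations), dtype=bool), "combined"
            )

    def test_null_analyte_rarely_selected(self):
        config = SyntheticConfig(
            sites=(SiteSpec("AA", 200, 350, 350),), n_analytes=20, seed=3
        )
        matrix, annotations = generate(config)
        mask = np.ones(len(annotations), dtype=bool)
        assert candidate_set(matrix, annotations, mask, "combined") == []


@pytest.fixture(scope="module")
def small_selection_run():
    config = SyntheticConfig(
        sites=(
            SiteSpec("AA", 50, 45, 45),
            SiteSpec("BB", 50, 45, 45, "smoker_unknown_nodule"),
        ),
        n_analytes=24,
        disease_markers={j: 1.3 for j in range(4)},
        site_artifact_markers={10: (1.2, -1.2)},
        seed=21,
    )
    matrix, annotations = generate(config)
    report = select_biomarkers(
        matrix,
        annotations,
        SelectionConfig(frequency_threshold=2),
        BeamSearchConfig(beam_width=50, max_panel_size=5),
        seed=0,
    )
    return config, matrix, report


class TestSelectBiomarkers:
    def test_six_analyses(self, small_selection_run):
        _, _, report = small_selection_run
        assert len(report.analyses) == 6
        assert {a.name for a in report.analyses} == {
            f"pop{i}_{c}" for i in (1, 2) for c in ("per_site", "combined", "both")
        }

    def test_union_is_union_of_qualified(self, small_selection_run):
        _, _, report = small_selection_run
        expected = set()
        for a in report.analyses:
            expected |= set(a.qualified)
        assert set(report.union) == expected

    def test_provenance_bookkeeping(self, small_selection_run):
        _, _, report = small_selection_run
        for analyte in report.union:
            assert len(report.provenance[analyte]) >= 1

    def test_recovers_planted_markers(self, small_selection_run):
        config, matrix, report = small_selection_run
        planted = {matrix.analyte_ids[j] for j in config.disease_markers}
        assert planted <= set(report.union)

    def test_site_artifact_not_selected(self, small_selection_run):
        config, matrix, report = small_selection_run
        artifacts = {matrix.analyte_ids[j] for j in config.site_artifact_markers}
        assert not (artifacts & set(report.union))

    def test_infinite_frequency_threshold_empties_union(self, small_selection_run):
        config, matrix, _ = small_selection_run
        _, annotations = generate(config)
        report = select_biomarkers(
            matrix,
            annotations,
            SelectionConfig(frequency_threshold=float("inf")),
            BeamSearchConfig(beam_width=20, max_panel_size=3),
        )
        assert report.union == ()

    def test_frequency_threshold_monotonicity(self, small_selection_run):
        config, matrix, report = small_selection_run
        _, annotations = generate(config)
        stricter = select_biomarkers(
            matrix,
            annotations,
            SelectionConfig(frequency_threshold=5),
            BeamSearchConfig(beam_width=50, max_panel_size=5),
        )
        assert set(stricter.union) <= set(report.union)
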