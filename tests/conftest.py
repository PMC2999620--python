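import numpy as np
import pytest

from seropanel.io import SampleAnnotation
from seropanel.synthetic import SiteSpec, SyntheticConfig, generate


def make_annotation(sample_id, class_label="control", site="AA", **kwargs):
    defaults = dict(
        control_subtype="smoker_no_nodule" if class_label == "control" else "not_applicable",
        stage="not_applicable" if class_label == "control" else "I",
        histology="unknown" if class_label == "control" else "adenocarcinoma",
        age=60.0,
        sex="male",
        smoking_status="ex",
        pack_years=30.0,
        gold_grade="II",
        barcode=f"B{sample_id}",
    )
    defaults.update(kwargs)
    return SampleAnnotation(sample_id=sample_id, class_label=class_label, site=site, **defaults)


@pytest.fixture(scope="session")
def two_site_cohort():
    """Modest two-site cohort: markers 0 (up) and 1 (down) planted, analyte 5
    is a pure site artifact."""
    config = SyntheticConfig(
        sites=(
            SiteSpec("AA", 60, 40, 40),
            SiteSpec("BB", 60, 40, 40, "smoker_unknown_nodule"),
        ),
        n_analytes=10,
        disease_markers={0: 1.2, 1: -1.0},
        site_artifact_markers={5: (1.0, -1.0)},
        seed=42,
    )
    matrix, annotations = generate(config)
    return config, matrix, annotations


@pytest.fixture(scope="session")
def planted_training_cohort():
    """Training-scale cohort (213/772, 4 sites) with a 12-marker delta=1 panel."""
    from seropanel.synthetic import training_scale_sites

    config = SyntheticConfig(
        sites=training_scale_sites(),
        n_analytes=30,
        disease_markers={j: 1.0 for j in range(12)},
        seed=7,
    )
    matrix, annotations = generate(config)
    return config, matrix, annotations


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
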