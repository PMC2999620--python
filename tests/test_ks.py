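import numpy as np
import pytest
import scipy.special
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from _oracles import bh_brute, ks_brute
from seropanel.errors import SeropanelError
from seropanel.io import case_mask, control_mask
from seropanel.ks import bh_qvalues, ks_p_value, ks_two_sample, screen_markers
from seropanel.synthetic import SiteSpec, SyntheticConfig, generate

samples = st.lists(
    st.floats(-50, 50, allow_nan=False).map(lambda v: round(v, 2)),
    min_size=1,
    max_size=25,
)


class TestKSTwoSample:
    def test_identical_multisets(self):
        assert ks_two_sample([1, 2, 2, 3], [2, 3, 1, 2]) == 0.0

    def test_disjoint_supports(self):
        assert ks_two_sample([1, 2, 3, 4], [5, 6, 7, 8]) == 1.0

    def test_interleaved(self):
        assert ks_two_sample([1, 3], [2, 4]) == 0.5

    def test_empty_sample_rejected(self):
        with pytest.raises(SeropanelError):
            ks_two_sample([], [1.0])

    @given(x=samples, y=samples)
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, x, y):
        assert ks_two_sample(x, y) == pytest.approx(ks_brute(x, y), abs=1e-12)

    @given(x=samples, y=samples, scale=st.floats(0.1, 5), shift=st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_monotone_transform_invariance(self, x, y, scale, shift):
        d0 = ks_two_sample(x, y)
        fx = [np.exp(scale * v / 50) + shift for v in x]
        fy = [np.exp(scale * v / 50) + shift for v in y]
        assert ks_two_sample(fx, fy) == pytest.approx(d0, abs=1e-12)

    def test_matches_scipy(self, rng):
        from scipy.stats import ks_2samp

        x = rng.normal(size=40)
        y = rng.normal(0.5, size=60)
        assert ks_two_sample(x, y) == pytest.approx(
            ks_2samp(x, y).statistic, abs=1e-12
        )


class TestKSPValue:
    def test_d_zero_clips_to_one(self):
        assert ks_p_value(0.0, 10, 10) == 1.0

    def test_series_value(self):
        # frozen from the stated series with ne = 10; independent oracle:
        # scipy.special.kolmogorov(sqrt(10)*0.5) = 0.013475889875863678
        p = ks_p_value(0.5, 20, 20)
        assert p == pytest.approx(0.013475889875863688, rel=1e-12)
        assert p == pytest.approx(
            scipy.special.kolmogorov(np.sqrt(10.0) * 0.5), rel=1e-10
        )

    def test_monotone_in_d(self):
        ps = [ks_p_value(d, 30, 40) for d in np.linspace(0.05, 0.9, 20)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_range(self):
        for d in (0.01, 0.3, 0.99, 1.0):
            assert 0.0 < ks_p_value(d, 15, 25) <= 1.0


class TestBHQValues:
    def test_single(self):
        assert bh_qvalues([0.05]).tolist() == [0.05]

    def test_tied_step_up(self):
        assert bh_qvalues([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_two_values(self):
        assert bh_qvalues([0.001, 0.5]).tolist() == pytest.approx([0.002, 0.5])

    def test_bad_p_rejected(self):
        with pytest.raises(SeropanelError):
            bh_qvalues([0.0, 0.5])

    @given(p=st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_and_statsmodels(self, p):
        q = bh_qvalues(p)
        assert q.tolist() == pytest.approx(bh_brute(p), abs=1e-12)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert q.tolist() == pytest.approx(q_sm.tolist(), abs=1e-12)

    @given(p=st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=15), seed=st.integers(0, 99))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, p, seed):
        perm = np.random.default_rng(seed).permutation(len(p))
        q = bh_qvalues(p)
        q_perm = bh_qvalues([p[i] for i in perm])
        assert [q[i] for i in perm] == pytest.approx(q_perm.tolist(), abs=1e-15)


@pytest.fixture(scope="module")
def screened(two_site_cohort):
    _, matrix, annotations = two_site_cohort
    return screen_markers(
        matrix, annotations, case_mask(annotations), control_mask(annotations)
    )


class TestScreenMarkers:
    def test_one_record_per_analyte(self, screened, two_site_cohort):
        _, matrix, _ = two_site_cohort
        assert [r.analyte_id for r in screened] == matrix.analyte_ids

    def test_planted_directions(self, screened):
        assert screened[0].direction == "up"
        assert screened[1].direction == "down"

    def test_identical_groups_give_zero(self):
        from seropanel.io import AnalyteMatrix

        values = np.array([[1.0], [2.0], [3.0], [1.0], [2.0], [3.0]])
        matrix = AnalyteMatrix([f"S{i}" for i in range(6)], ["A1"], values)
        mask = np.array([True] * 3 + [False] * 3)
        (rec,) = screen_markers(matrix, None, mask, ~mask)
        assert rec.ks == 0.0 and rec.q_value == 1.0

    def test_overlapping_masks_rejected(self, two_site_cohort):
        _, matrix, annotations = two_site_cohort
        mask = case_mask(annotations)
        with pytest.raises(SeropanelError, match="disjoint"):
            screen_markers(matrix, annotations, mask, mask)

    def test_planted_marker_clears_threshold(self):
        # delta = 1.2 at 200/700: population KS ~ 0.451, so D > 0.3 w.h.p.
        config = SyntheticConfig(
            sites=(SiteSpec("AA", 200, 350, 350),),
            n_analytes=5,
            disease_markers={0: 1.2},
            seed=31,
        )
        matrix, annotations = generate(config)
        records = screen_markers(
            matrix, annotations, case_mask(annotations), control_mask(annotations)
        )
        assert records[0].ks > 0.3
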