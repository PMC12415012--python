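import numpy as np
import pytest
from scipy import stats as ss

from efconn.atlas import excluded_rois
from efconn.classify import classify_hubs
from efconn.communities import louvain
from efconn.graphs import build_from_cohort
from efconn.metrics import compute_node_metrics
from efconn.synthetic import (generate_cohort, make_synthetic_atlas,
                              recovery_report, SyntheticSpec)

SMALL = dict(n_subjects=24, n_roi=68, n_modules=3, module_size=6, n_hubs=3)


def test_synthetic_atlas_covers_17_networks():
    atlas = make_synthetic_atlas(200)
    assert atlas.n_roi == 200
    assert len(atlas.networks()) == 17
    assert atlas.table.iloc[0]["hemisphere"] == "LH"
    assert atlas.table.iloc[150]["hemisphere"] == "RH"


class TestSpecValidation:
    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SyntheticSpec(p_within=1.5)

    def test_r_ranges_respect_threshold(self):
        with pytest.raises(ValueError):
            SyntheticSpec(r_high=(0.70, 0.9))
        with pytest.raises(ValueError):
            SyntheticSpec(r_low=(0.0, 0.8))


class TestGenerateCohort:
    def test_matrices_are_valid_connectomes(self):
        cohort, _ = generate_cohort(SyntheticSpec(seed=0, **SMALL))
        assert len(cohort) == 24
        m = cohort[0].matrix
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 1.0)
        assert np.abs(m).max() <= 1.0

    def test_deterministic_given_seed(self):
        a, _ = generate_cohort(SyntheticSpec(seed=3, **SMALL))
        b, _ = generate_cohort(SyntheticSpec(seed=3, **SMALL))
        np.testing.assert_array_equal(a[5].matrix, b[5].matrix)

    def test_degenerate_certain_edges(self):
        spec = SyntheticSpec(seed=1, p_within=1.0, p_hub=1.0,
                             p_background=0.0, **SMALL)
        cohort, truth = generate_cohort(spec)
        excl = excluded_rois(truth.atlas, spec.excluded_networks)
        g = build_from_cohort(cohort, excl, min_subjects=10)
        for i, j, _ in truth.planted_edges:
            assert g[i][j]["weight"] == spec.n_subjects

    def test_degenerate_empty(self):
        spec = SyntheticSpec(seed=1, p_within=0.0, p_hub=0.0,
                             p_background=0.0, **SMALL)
        cohort, truth = generate_cohort(spec)
        excl = excluded_rois(truth.atlas, spec.excluded_networks)
        g = build_from_cohort(cohort, excl, min_subjects=10)
        assert g.number_of_edges() == 0

    def test_planted_weights_within_binomial_bounds(self):
        spec = SyntheticSpec(seed=2, p_within=0.5, p_hub=0.5,
                             p_background=0.0, n_subjects=144,
                             n_roi=68, n_modules=3, module_size=6, n_hubs=3)
        cohort, truth = generate_cohort(spec)
        excl = excluded_rois(truth.atlas, spec.excluded_networks)
        g = build_from_cohort(cohort, excl, min_subjects=1)
        lo, hi = ss.binom.ppf([0.0005, 0.9995], 144, 0.5)
        for i, j, _ in truth.planted_edges:
            w = g[i][j]["weight"] if g.has_edge(i, j) else 0
            assert lo <= w <= hi, (i, j, w)

    def test_excluded_rois_never_in_graph(self):
        spec = SyntheticSpec(seed=4, p_background=0.2, **SMALL)
        cohort, truth = generate_cohort(spec)
        excl = excluded_rois(truth.atlas, spec.excluded_networks)
        g = build_from_cohort(cohort, excl, min_subjects=2)
        assert not (set(g.nodes) & excl)


class TestRecoveryReport:
    def _run(self, seed):
        spec = SyntheticSpec(seed=seed)
        cohort, truth = generate_cohort(spec)
        excl = excluded_rois(truth.atlas, spec.excluded_networks)
        g = build_from_cohort(cohort, excl)
        hubs = classify_hubs(compute_node_metrics(g))
        return g, hubs, louvain(g, seed=seed), truth

    def test_perfect_detection_scores_one(self):
        g, hubs, part, truth = self._run(0)
        rep = recovery_report(g, set(truth.hubs), part, truth)
        assert rep.hub_precision == 1.0 and rep.hub_recall == 1.0

    def test_no_hubs_detected_recall_zero(self):
        g, hubs, part, truth = self._run(0)
        rep = recovery_report(g, set(), part, truth)
        assert rep.hub_recall == 0.0 and rep.hub_precision == 0.0

    def test_default_spec_recovery(self):
        g, hubs, part, truth = self._run(1)
        rep = recovery_report(g, hubs.members, part, truth)
        assert rep.hub_recall >= 0.9
        assert rep.partition_ari >= 0.8
        assert 0.02 <= rep.edge_density <= 0.08
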