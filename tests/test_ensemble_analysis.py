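import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_ensemble, straight_chain
from ighloci.ensemble_analysis import (
    BeadAnnotation,
    center_of_mass,
    cluster_conformations,
    cm_distance_profiles,
    conditional_cmv_distance,
    partners_per_bead,
    read_annotation_tsv,
    spearman,
    vd_stats,
    vh_contact_fraction,
)
from ighloci.synthetic import igh_bead_annotation


class TestAnnotation:
    def test_igh_fixture_layout(self):
        ann = BeadAnnotation(igh_bead_annotation())
        assert ann.vh_beads[0] == 24 and ann.vh_beads[-1] == 146
        assert ann.vh_beads.size == 123
        assert 6 in ann.beads_of_class("CBE3prime")
        assert 19 in ann.beads_of_class("IGCR1")

    def test_round_trip_tsv(self, tmp_path):
        df = igh_bead_annotation()
        p = tmp_path / "beads.tsv"
        df.to_csv(p, sep="\t", index=False)
        ann = read_annotation_tsv(p)
        assert np.array_equal(ann.vh_beads, BeadAnnotation(df).vh_beads)

    def test_duplicate_or_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            BeadAnnotation(pd.DataFrame({
                "bead_index": [1, 1], "element_class": ["VH", "VH"]}))
        with pytest.raises(ValueError):
            BeadAnnotation(pd.DataFrame({
                "bead_index": [1], "element_class": ["mystery"]}))


class TestPartnersPerBead:
    def test_frozen_straight_chain(self):
        ens = make_ensemble([straight_chain(5)])
        partners = partners_per_bead(ens)
        assert list(partners) == [1, 2, 2, 2, 1]

    def test_two_conformation_hand_average(self):
        near = straight_chain(4)
        near[3] = [1.0, 1.0, 0.0]  # bead 4 moves next to bead 1 (and stays by 3)
        ens = make_ensemble([straight_chain(4), near])
        partners = partners_per_bead(ens)
        # bead 1: 1 partner in the straight frame, 2 in the bent one
        assert partners[0] == 1.5

    def test_upper_bound(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(scale=0.9, size=(6, 7, 3)).cumsum(axis=1)
        ens = make_ensemble(frames)
        assert (partners_per_bead(ens) <= 6).all()


class TestVdStats:
    def test_toy_fraction(self, toy_annotation):
        # DH bead 1 at origin; only VH bead 3 within 1.5a
        conf = np.array([
            [0, 0, 0], [1, 0, 0], [1.2, 0.5, 0],
            [3, 0, 0], [4, 0, 0], [5, 0, 0],
        ], dtype=float)
        ens = make_ensemble([conf])
        frac, per_d, per_v = vd_stats(ens, toy_annotation)
        assert frac[0] == pytest.approx(1 / 3)
        assert per_d.loc[1] == 1
        assert per_v.loc[3] == 1 and per_v.loc[4] == 0

    def test_no_contacts(self, toy_annotation):
        ens = make_ensemble([straight_chain(6, spacing=2.0)])
        frac, per_d, per_v = vd_stats(ens, toy_annotation)
        assert frac[0] == 0
        assert per_d.sum() == 0 and per_v.sum() == 0

    def test_event_conservation_on_random_ensembles(self, toy_annotation):
        rng = np.random.default_rng(11)
        frames = rng.normal(scale=0.8, size=(20, 6, 3)).cumsum(axis=1)
        ens = make_ensemble(frames)
        _, per_d, per_v = vd_stats(ens, toy_annotation)
        assert per_d.sum() == per_v.sum()

    def test_explicit_bead_set_override(self, toy_annotation):
        ens = make_ensemble([straight_chain(6)])
        _, per_d, _ = vd_stats(ens, toy_annotation, dh_beads=np.array([1, 2]))
        assert set(per_d.index) == {1, 2}

    def test_missing_class_is_an_error(self):
        ann = BeadAnnotation(pd.DataFrame({
            "bead_index": [1, 2], "element_class": ["VH", "none"]}))
        ens = make_ensemble([straight_chain(2)])
        with pytest.raises(ValueError):
            vd_stats(ens, ann)


class TestCenterOfMass:
    def test_two_bead_midpoint(self):
        conf = np.array([[0, 0, 0], [2, 0, 0]], dtype=float)
        assert np.allclose(center_of_mass(conf), [1, 0, 0])

    def test_singleton_subset(self):
        conf = np.array([[0, 0, 0], [2, 5, 1]], dtype=float)
        assert np.allclose(center_of_mass(conf, [2]), [2, 5, 1])

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        conf = rng.normal(size=(9, 3))
        t = np.array([1.0, -2.0, 0.5])
        assert np.allclose(center_of_mass(conf + t), center_of_mass(conf) + t)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass(np.zeros((3, 3)), [])


class TestCmProfiles:
    def test_symmetric_pair(self):
        ann = BeadAnnotation(pd.DataFrame({
            "bead_index": [1, 2], "element_class": ["VH", "VH"]}))
        conf = np.array([[-1, 0, 0], [1, 0, 0]], dtype=float)
        prof = cm_distance_profiles(make_ensemble([conf]), ann)
        assert np.allclose(prof["mean_dist_cm"], 1.0)
        # all beads are VH, so CMv == CM
        assert np.allclose(prof["mean_dist_cm"], prof["mean_dist_cmv"])

    def test_two_conformation_hand_average(self, toy_annotation):
        c1 = straight_chain(6)
        c2 = straight_chain(6, spacing=2.0)
        prof = cm_distance_profiles(make_ensemble([c1, c2]), toy_annotation)
        vh = [2, 3, 4]  # 0-based indices of VH beads 3,4,5
        expected_bead1 = np.mean([
            np.linalg.norm(c1[0] - c1.mean(axis=0)),
            np.linalg.norm(c2[0] - c2.mean(axis=0)),
        ])
        assert prof.loc[prof.bead_index == 1, "mean_dist_cm"].iloc[0] == pytest.approx(
            expected_bead1)
        expected_cmv_bead1 = np.mean([
            np.linalg.norm(c1[0] - c1[vh].mean(axis=0)),
            np.linalg.norm(c2[0] - c2[vh].mean(axis=0)),
        ])
        assert prof.loc[prof.bead_index == 1, "mean_dist_cmv"].iloc[0] == pytest.approx(
            expected_cmv_bead1)


class TestConditionalCmvDistance:
    def test_partner_always_in_contact_equals_unconditional(self, toy_annotation):
        frames = [straight_chain(6), straight_chain(6)]
        ens = make_ensemble(frames)
        mean, n = conditional_cmv_distance(ens, toy_annotation, bead=2, partner=3)
        prof = cm_distance_profiles(ens, toy_annotation)
        assert n == 2
        assert mean == pytest.approx(
            prof.loc[prof.bead_index == 2, "mean_dist_cmv"].iloc[0])

    def test_partner_never_in_contact_flagged_undefined(self, toy_annotation):
        ens = make_ensemble([straight_chain(6)])
        mean, n = conditional_cmv_distance(ens, toy_annotation, bead=1, partner=6)
        assert n == 0 and np.isnan(mean)

    def test_subset_mean_hand_checked(self, toy_annotation):
        c1 = straight_chain(6)
        c2 = straight_chain(6) + np.array([0.2, 0, 0])
        c3 = straight_chain(6, spacing=2.0)  # bead1-bead2 at 2a: no contact
        ens = make_ensemble([c1, c2, c3])
        mean, n = conditional_cmv_distance(ens, toy_annotation, bead=1, partner=2)
        assert n == 2
        vh = [2, 3, 4]
        expected = np.mean([
            np.linalg.norm(c[0] - c[vh].mean(axis=0)) for c in (c1, c2)
        ])
        assert mean == pytest.approx(expected)
        # conditional mean lies within [min, max] of conditioned values
        vals = [np.linalg.norm(c[0] - c[vh].mean(axis=0)) for c in (c1, c2)]
        assert min(vals) <= mean <= max(vals)


class TestVhContactFraction:
    def test_all_vh_straight_chain_interior(self):
        n = 6
        ann = BeadAnnotation(pd.DataFrame({
            "bead_index": np.arange(1, n + 1), "element_class": ["VH"] * n}))
        frac = vh_contact_fraction(make_ensemble([straight_chain(n)]), ann)
        assert frac[2] == pytest.approx(2 / (n - 1))
        assert frac[0] == pytest.approx(1 / (n - 1))

    def test_bounded_in_unit_interval(self, toy_annotation):
        rng = np.random.default_rng(4)
        frames = rng.normal(scale=0.8, size=(10, 6, 3)).cumsum(axis=1)
        frac = vh_contact_fraction(make_ensemble(frames), toy_annotation)
        assert ((frac >= 0) & (frac <= 1)).all()

    def test_two_conformation_hand_case(self, toy_annotation):
        c1 = straight_chain(6)          # bead 2 (idx 1) touches VH bead 3 (idx 2)
        c2 = straight_chain(6, 2.0)     # no contacts at all
        frac = vh_contact_fraction(make_ensemble([c1, c2]), toy_annotation)
        # bead 2: 1 of 3 VH beads in c1, 0 in c2 -> mean 1/6
        assert frac[1] == pytest.approx(np.mean([1 / 3, 0]))


class TestClustering:
    def test_duplicates_form_the_largest_cluster(self):
        rng = np.random.default_rng(3)
        base = rng.normal(scale=0.8, size=(8, 3)).cumsum(axis=0)
        other = base + 0  # start from same then perturb strongly
        other = base[::-1] * 1.7
        frames = [base] * 5 + [other]
        labels, maps = cluster_conformations(make_ensemble(frames), k=2)
        sizes = np.bincount(labels)[1:]
        assert sorted(sizes) == [1, 5]
        assert set(maps) == set(np.unique(labels))

    def test_rigid_motion_gives_zero_dissimilarity(self):
        rng = np.random.default_rng(6)
        base = rng.normal(scale=0.8, size=(8, 3)).cumsum(axis=0)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = base @ q + np.array([5.0, 1.0, -2.0])
        labels, _ = cluster_conformations(make_ensemble([base, moved, base * 2]), k=2)
        assert labels[0] == labels[1] != labels[2]

    def test_rmsd_matrix_matches_direct_formula(self):
        rng = np.random.default_rng(7)
        frames = rng.normal(scale=0.9, size=(3, 5, 3)).cumsum(axis=1)
        from scipy.spatial.distance import pdist, squareform

        # direct evaluation of sqrt(mean over i<j (d_ij(c1) - d_ij(c2))^2)
        def dvec(conf):
            return pdist(conf)

        expected01 = np.sqrt(np.mean((dvec(frames[0]) - dvec(frames[1])) ** 2))
        # reproduce through the module by clustering with cut 0 (labels unused)
        from ighloci.ensemble_analysis import pairwise_distances

        iu, ju = np.triu_indices(5, k=1)
        vecs = np.array([pairwise_distances(c)[iu, ju] for c in frames])
        got = squareform(pdist(vecs) / np.sqrt(iu.size))
        assert got[0, 1] == pytest.approx(expected01)

    def test_contact_overlap_metric_runs(self):
        rng = np.random.default_rng(9)
        frames = rng.normal(scale=0.8, size=(6, 8, 3)).cumsum(axis=1)
        labels, maps = cluster_conformations(
            make_ensemble(frames), method="contact_overlap", k=2)
        assert len(labels) == 6

    def test_k_larger_than_ensemble_is_an_error(self):
        frames = np.zeros((2, 4, 3))
        frames[:, :, 0] = np.arange(4)
        with pytest.raises(ValueError):
            cluster_conformations(make_ensemble(frames), k=5)

    def test_mixture_of_two_regimes_recovered(self, compiled_kernel):
        """50/50 mixture of homopolymer and strongly collapsed chains."""
        from ighloci.polymer import ModelParams, SamplingSchedule, mc_sample

        n = 16
        params = ModelParams(n_beads=n)
        open_eps = np.zeros((n, n))
        collapsed = np.full((n, n), -2.5)
        np.fill_diagonal(collapsed, 0.0)
        sch = SamplingSchedule(100, 10)
        e1 = mc_sample(open_eps, params, 25, seed=41, schedule=sch)
        e2 = mc_sample(collapsed, params, 25, seed=43, schedule=sch)
        mixed = make_ensemble(np.concatenate([e1.coords, e2.coords]))
        labels, _ = cluster_conformations(mixed, k=2)
        truth = np.array([0] * 25 + [1] * 25)
        purity = max(
            np.mean((labels - 1) == truth), np.mean((labels - 1) == 1 - truth)
        )
        assert purity >= 0.9


class TestSpearman:
    def test_monotone_sequences(self):
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman([1, 2, 3, 4], [4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_ties_match_exhaustive_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 4.0, 4.0, 6.0, 5.0, 9.0, 9.0])
        rho, _ = spearman(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)  # average ranks
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_missing_values_dropped_pairwise(self):
        rho, _ = spearman([1, 2, np.nan, 4, 5], [2, 4, 100, 8, 10])
        assert rho == pytest.approx(1.0)

    def test_constant_input_flagged(self):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(rho) and np.isnan(p)

    def test_too_short_is_an_error(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [3, 4])
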