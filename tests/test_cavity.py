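"""Cavity vectors, Tanimoto similarity, clustering, PCA and dispersion."""

from __future__ import annotations

import numpy as np
import pytest

from hemepocket.cavity import (
    CORE_ATOMS,
    cavity_vector,
    cluster_cavities,
    correlate_pc_with_distortion,
    dispersion,
    heme_coverage,
    lattice_points,
    pca_within_cluster,
    reference_core,
    superpose_on_core,
    tanimoto,
)
from hemepocket.curation import Atom, StructureModel, extract_hemes
from hemepocket.nsd import decompose
from hemepocket.synthetic import (
    GeneratorConfig,
    _random_rotation,
    build_pocket,
    distort_porphyrin,
    reference_porphyrin,
)
from hemepocket.voxel import VDW_RADIUS


def _model(coords, elements, res="ALA"):
    atoms = [Atom(e, f"{e}{i}", res, i + 1, "A", np.asarray(p, float), False)
             for i, (p, e) in enumerate(zip(coords, elements))]
    return StructureModel("m", 1.5, atoms, [], {"A": [res] * len(atoms)})


def _pocket(seed=0, amps=None, sigma=0.1):
    cfg = GeneratorConfig(n=1, seed=seed, sigma=sigma)
    rng = np.random.default_rng(seed)
    amps = amps or {"saddling": 0.3}
    heme = distort_porphyrin(reference_porphyrin(), amps)
    model, _ = build_pocket(heme, amps, cfg, rng)
    return model


class TestSuperposeOnCore:
    def test_identity_for_reference(self):
        model = _pocket(seed=1)
        (heme,) = extract_hemes(model)
        out = superpose_on_core(model, heme)
        # the five core atoms land on the reference core
        core = np.array([out_atom.pos for out_atom in out.het_groups[0][1]
                         if out_atom.name in CORE_ATOMS])
        ref = reference_core()
        assert np.abs(np.sort(core, axis=0) - np.sort(ref, axis=0)).max() < 0.1

    def test_rotated_sample_fe_lands_on_reference(self):
        model = _pocket(seed=2)
        rot = _random_rotation(np.random.default_rng(3))
        moved = model.transformed(rot, np.array([5.0, 6.0, -7.0]))
        (heme,) = extract_hemes(moved)
        out = superpose_on_core(moved, heme)
        fe = [a.pos for a in out.het_groups[0][1] if a.name == "FE"][0]
        # reference core has Fe at the origin; the distorted Fe may sit
        # slightly off it, identically for any rigid motion of the input
        (heme0,) = extract_hemes(model)
        fe0 = [a.pos for a in superpose_on_core(model, heme0).het_groups[0][1] if a.name == "FE"][0]
        assert np.abs(fe - fe0).max() < 1e-6

    def test_missing_core_atom_errors(self):
        model = _pocket(seed=4)
        (heme,) = extract_hemes(model)
        del heme.skeleton["NB"]
        with pytest.raises(ValueError, match="NB"):
            superpose_on_core(model, heme)


class TestCavityVector:
    def test_no_protein_all_bits_set(self):
        v = cavity_vector(_model([], []))
        assert v.bits.all()
        assert len(v) == len(lattice_points())

    def test_single_carbon_excludes_19_points(self):
        v = cavity_vector(_model([[0.0, 0.0, 0.0]], ["C"]))
        assert int((1 - v.bits).sum()) == 19

    def test_length_is_fixed_constant(self):
        n = int(np.sum(np.linalg.norm(lattice_points(), axis=1) <= 8.5))
        assert len(cavity_vector(_model([], []))) == n
        assert len(cavity_vector(_pocket(seed=5))) == n

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-9, 9, size=(30, 3))
        elements = rng.choice(["C", "N", "O", "S"], size=30)
        v = cavity_vector(_model(coords, elements))
        pts = lattice_points()
        for idx in rng.choice(len(pts), 200, replace=False):
            p = pts[idx]
            free = all(np.linalg.norm(p - c) > VDW_RADIUS[e] for c, e in zip(coords, elements))
            assert bool(v.bits[idx]) == free


class TestTanimoto:
    def test_worked_example(self):
        assert tanimoto(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0])) == pytest.approx(1 / 3)

    def test_identity_and_disjoint(self):
        v = np.array([1, 0, 1, 0])
        assert tanimoto(v, v) == 1.0
        assert tanimoto(v, np.array([0, 1, 0, 1])) == 0.0

    def test_both_empty_is_one(self):
        z = np.zeros(6, np.uint8)
        assert tanimoto(z, z) == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a, b = (rng.random(50) < 0.4), (rng.random(50) < 0.4)
        assert tanimoto(a, b) == tanimoto(b, a)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(4), np.ones(5))


def _bit_family(rng, template, n, flip=3):
    out = []
    for _ in range(n):
        v = template.copy()
        idx = rng.choice(len(v), flip, replace=False)
        v[idx] ^= 1
        out.append(v)
    return out


class TestClustering:
    def test_two_families_separate_cleanly(self):
        rng = np.random.default_rng(0)
        a = np.zeros(120, np.uint8); a[:40] = 1
        b = np.zeros(120, np.uint8); b[80:] = 1
        vecs = _bit_family(rng, a, 6) + _bit_family(rng, b, 6)
        labels = cluster_cavities(vecs, n_clusters=2)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]

    def test_singletons_when_k_equals_n(self):
        rng = np.random.default_rng(1)
        vecs = [(rng.random(40) < 0.5).astype(np.uint8) for _ in range(5)]
        labels = cluster_cavities(vecs, n_clusters=5)
        assert len(set(labels)) == 5

    def test_order_invariant_partition(self):
        rng = np.random.default_rng(2)
        a = np.zeros(100, np.uint8); a[:30] = 1
        b = np.zeros(100, np.uint8); b[60:] = 1
        vecs = _bit_family(rng, a, 5) + _bit_family(rng, b, 5)
        labels = np.asarray(cluster_cavities(vecs, n_clusters=2))
        perm = np.random.default_rng(3).permutation(len(vecs))
        labels_p = np.asarray(cluster_cavities([vecs[i] for i in perm], n_clusters=2))
        # same partition up to label renaming
        for i in range(len(vecs)):
            for j in range(len(vecs)):
                same0 = labels[perm[i]] == labels[perm[j]]
                same1 = labels_p[i] == labels_p[j]
                assert same0 == same1

    def test_too_few_vectors_errors(self):
        with pytest.raises(ValueError):
            cluster_cavities([np.ones(5, np.uint8)], n_clusters=2)


class TestPCA:
    def test_loadings_supported_on_varying_region(self):
        rng = np.random.default_rng(0)
        vecs = []
        for i in range(10):
            v = np.zeros(60, np.uint8)
            v[:10 + 2 * i] = 1  # variation confined to the first 30 positions
            vecs.append(v)
        res = pca_within_cluster(vecs)
        loadings = np.abs(res.components[0])
        assert loadings[:30].sum() > 0.99 * loadings.sum()

    def test_scores_zero_mean_and_evr_bounded(self):
        rng = np.random.default_rng(1)
        vecs = [(rng.random(40) < 0.4).astype(np.uint8) for _ in range(8)]
        res = pca_within_cluster(vecs)
        assert np.abs(res.scores.mean(axis=0)).max() < 1e-8
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pca_within_cluster([np.ones(10, np.uint8)] * 4)

    def test_loadings_table_shape(self):
        rng = np.random.default_rng(2)
        n = len(lattice_points())
        vecs = [(rng.random(n) < 0.5).astype(np.uint8) for _ in range(5)]
        table = pca_within_cluster(vecs).loadings_table()
        assert list(table.columns) == ["x", "y", "z", "loading"]
        assert len(table) == n


class TestCorrelation:
    def test_exact_linear_relation(self):
        scores = np.linspace(-2, 2, 20)
        table = correlate_pc_with_distortion(scores, {"saddling": 3 * scores + 1})
        assert table.loc["saddling", "r"] == pytest.approx(1.0)
        assert table.loc["saddling", "slope"] == pytest.approx(3.0)

    def test_independent_pairing_uncorrelated(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        table = correlate_pc_with_distortion(scores, {"m": rng.normal(size=50)})
        assert abs(table.loc["m", "r"]) < 0.5

    def test_zero_variance_flagged(self):
        table = correlate_pc_with_distortion(np.arange(5.0), {"m": np.ones(5)})
        assert not table.loc["m", "defined"]
        assert np.isnan(table.loc["m", "r"])


class TestDispersion:
    def test_identical_members_zero(self):
        v = np.array([1, 0, 1], np.uint8)
        assert dispersion([v, v, v]).mean_distance == 0.0

    def test_hand_worked_pair(self):
        rep = dispersion([np.array([1, 0]), np.array([0, 1])])
        assert np.allclose(rep.barycenter, [0.5, 0.5])
        assert rep.mean_distance == pytest.approx(np.sqrt(0.5))
        assert rep.n == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        vecs = [(rng.random(20) < 0.5).astype(np.uint8) for _ in range(6)]
        d0 = dispersion(vecs).mean_distance
        d1 = dispersion(vecs[::-1]).mean_distance
        assert d0 == pytest.approx(d1)

    def test_duplicating_nearest_member_bounded(self):
        rng = np.random.default_rng(1)
        vecs = [(rng.random(30) < 0.5).astype(float) for _ in range(8)]
        rep = dispersion(vecs)
        dists = [np.linalg.norm(v - rep.barycenter) for v in vecs]
        nearest = vecs[int(np.argmin(dists))]
        grown = dispersion(vecs + [nearest])
        assert grown.mean_distance <= max(dists) + 1e-12

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError):
            dispersion([])


class TestHemeCoverage:
    def test_enclosed_pocket_full_coverage(self):
        model = _pocket(seed=6)
        (heme,) = extract_hemes(model)
        assert heme_coverage(model, heme) == pytest.approx(1.0)

    def test_isolated_heme_zero(self):
        model = _pocket(seed=7)
        (heme,) = extract_hemes(model)
        bare = StructureModel("b", 1.5, [a for a in model.atoms if a.is_het],
                              model.het_groups, {})
        assert heme_coverage(bare, heme) == 0.0

    def test_half_enclosed_pocket_about_half(self):
        """Burial of exactly 12 of 25 skeleton atoms gives coverage 12/25."""
        model = _pocket(seed=8, sigma=0.0)
        (heme,) = extract_hemes(model)
        skel = heme.skeleton_array()
        chosen = np.argsort(skel[:, 0])[-12:]  # the 12 atoms at largest x
        protectors = [Atom("C", "CP", "ALA", 500 + i, "A", skel[i] + [0, 0, 0.5], False)
                      for i in chosen]
        half = StructureModel("h", 1.5, protectors + [a for a in model.atoms if a.is_het],
                              model.het_groups, {})
        cov = heme_coverage(half, heme, cutoff=1.0)
        assert cov == pytest.approx(12 / 25)


class TestSimilarityVsSkeletonRmsd:
    def test_similar_cavities_have_similar_hemes(self):
        """Replicate pairs (same amplitudes, noise only) show high cavity
        similarity and low skeleton RMSD; dissimilar pairs the opposite."""
        rng = np.random.default_rng(0)
        vecs, skels = [], []
        for b in range(6):
            amps = {"saddling": rng.uniform(-1, 1), "ruffling": rng.uniform(-1, 1)}
            for rep in range(2):
                model = _pocket(seed=100 + 10 * b + rep, amps=amps, sigma=0.05)
                (heme,) = extract_hemes(model)
                sup = superpose_on_core(model, heme)
                vecs.append(cavity_vector(sup))
                (sup_heme,) = extract_hemes(sup)
                skels.append(sup_heme.skeleton_array())
        sims, rmsds = [], []
        for i in range(len(vecs)):
            for j in range(i + 1, len(vecs)):
                sims.append(tanimoto(vecs[i], vecs[j]))
                rmsds.append(float(np.sqrt(np.mean(np.sum((skels[i] - skels[j]) ** 2, axis=1)))))
        sims, rmsds = np.array(sims), np.array(rmsds)
        hi, lo = sims >= np.quantile(sims, 0.8), sims <= np.quantile(sims, 0.2)
        assert rmsds[hi].mean() < rmsds[lo].mean()
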