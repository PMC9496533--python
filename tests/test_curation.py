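"""Structure reading, heme extraction, filters and sequence redundancy."""

from __future__ import annotations

import numpy as np
import pytest

from hemepocket.curation import (
    Atom,
    StructureModel,
    apply_filters,
    assign_heme_type,
    cluster_sequences,
    deduplicate_sequences,
    detect_axial_ligands,
    extract_hemes,
    pairwise_identity,
    read_structure,
)
from hemepocket.nsd import SKELETON_ATOMS
from hemepocket.synthetic import GeneratorConfig, build_pocket, distort_porphyrin

MINIMAL_PDB = """\
HEADER    TEST                                    01-JAN-20   XXXX
REMARK   2 RESOLUTION.    1.50 ANGSTROMS.
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00 20.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.500  1.00 20.00           C
ATOM      3  C   ALA A   1       3.000   3.000   4.000  1.00 20.00           C
END
"""


def _synthetic_model(seed=0, **kwargs) -> tuple[StructureModel, dict]:
    from hemepocket.synthetic import reference_porphyrin

    cfg = GeneratorConfig(n=1, seed=seed, sigma=0.0)
    rng = np.random.default_rng(seed)
    amps = {"saddling": 0.4}
    heme = distort_porphyrin(reference_porphyrin(), amps)
    model, _seq = build_pocket(heme, amps, cfg, rng, **kwargs)
    return model, amps


class TestReadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "mini.pdb"
        p.write_text(MINIMAL_PDB)
        model = read_structure(p)
        assert len(model.atoms) == 3
        assert model.resolution == pytest.approx(1.5)
        assert model.atoms[0].element == "N"
        assert np.allclose(model.atoms[0].pos, [1.0, 2.0, 3.0])

    def test_cross_format_round_trip(self, tmp_path, corpus_dir):
        """The same structure read as PDB and as mmCIF must agree to 1e-3 A."""
        import gemmi

        pdb_path = sorted(corpus_dir.glob("*.pdb"))[0]
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "copy.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = read_structure(pdb_path, fmt="pdb")
        b = read_structure(cif_path, fmt="mmcif")
        assert len(a.atoms) == len(b.atoms)
        pa = np.array([at.pos for at in a.atoms])
        pb = np.array([at.pos for at in b.atoms])
        assert np.abs(pa - pb).max() < 1e-3

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "broken.cif"
        bad.write_text("data_x\n_atom_site.id\nloop_ garbage { unterminated\n")
        with pytest.raises((ValueError, FileNotFoundError)):
            read_structure(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")


class TestExtractHemes:
    def test_one_complete_heme(self, clean_corpus):
        samples, _ = clean_corpus
        hemes = extract_hemes(samples[0].model)
        assert len(hemes) == 1
        assert hemes[0].complete

    def test_count_matches_het_groups(self, clean_corpus):
        samples, _ = clean_corpus
        for s in samples[:5]:
            assert len(extract_hemes(s.model)) == len(s.model.het_groups)

    def test_missing_fe_flagged_incomplete(self):
        model, _ = _synthetic_model(seed=3, omit_fe=True)
        (heme,) = extract_hemes(model)
        assert not heme.complete
        with pytest.raises(ValueError):
            heme.skeleton_array()

    def test_two_heme_groups(self):
        m1, _ = _synthetic_model(seed=1, het_id="HEM")
        m2, _ = _synthetic_model(seed=2, het_id="HEC")
        # merge the second heme group into the first model under a new residue id
        moved = [Atom(a.element, a.name, a.res_name, 910, a.chain_id, a.pos + 30.0, a.is_het)
                 for a in m2.het_groups[0][1]]
        merged = StructureModel(
            entry_id="two", resolution=1.5,
            atoms=m1.atoms + moved,
            het_groups=m1.het_groups + [("HEC", moved)],
            chains=m1.chains,
        )
        hemes = extract_hemes(merged)
        assert [h.het_id for h in hemes] == ["HEM", "HEC"]


def _model_with_contact(dist: float, res_name: str, atom_name: str, element: str):
    model, _ = _synthetic_model(seed=5)
    (heme,) = extract_hemes(model)
    fe = heme.skeleton["FE"]
    # place the probe along +x to stay clear of walls and the proximal His
    probe = Atom(element, atom_name, res_name, 700, "A", fe + np.array([dist, 0, 0]), res_name == "HOH")
    model.atoms.append(probe)
    return model, heme


class TestAxialLigands:
    def test_histidine_contact_detected(self):
        model, _ = _synthetic_model(seed=5)
        (heme,) = extract_hemes(model)
        detect_axial_ligands(model, heme)
        his = [lig for lig in heme.axial_ligands if lig.res_name == "HIS"]
        assert his and his[0].is_amino_acid
        assert his[0].distance == pytest.approx(2.05, abs=0.05)

    @pytest.mark.parametrize(
        "dist,expected", [(2.1, True), (3.1, True), (3.2, False)],
        ids=["well-inside", "boundary-closed", "outside"],
    )
    def test_cutoff_is_closed_interval(self, dist, expected):
        model, heme = _model_with_contact(dist, "GLY", "CA", "C")
        detect_axial_ligands(model, heme)
        found = any(lig.atom_name == "CA" for lig in heme.axial_ligands)
        assert found is expected

    def test_water_contact_not_amino(self):
        model, heme = _model_with_contact(2.5, "HOH", "O", "O")
        detect_axial_ligands(model, heme)
        water = [lig for lig in heme.axial_ligands if lig.res_name == "HOH"]
        assert water and not water[0].is_amino_acid

    def test_incomplete_skeleton_rejected(self):
        model, _ = _synthetic_model(seed=6, omit_fe=True)
        (heme,) = extract_hemes(model)
        with pytest.raises(ValueError):
            detect_axial_ligands(model, heme)


class TestFilters:
    def _sample(self, seed=8, **kwargs):
        model, _ = _synthetic_model(seed=seed, **kwargs)
        (heme,) = extract_hemes(model)
        if heme.complete:
            detect_axial_ligands(model, heme)
        return heme

    def test_resolution_rejection(self):
        s = self._sample()
        s.resolution = 2.5
        kept, rejected = apply_filters([s])
        assert not kept and rejected[0].reason == "resolution"

    def test_boundary_resolution_kept(self):
        s = self._sample()
        s.resolution = 2.0
        kept, _ = apply_filters([s])
        assert kept

    def test_missing_resolution_rejected(self):
        s = self._sample()
        s.resolution = None
        _, rejected = apply_filters([s])
        assert rejected[0].reason == "no_resolution"

    def test_water_ligand_rejection(self):
        s = self._sample(seed=9, water_ligand=True)
        kept, rejected = apply_filters([s])
        assert not kept and rejected[0].reason == "axial_ligand"

    def test_compliant_set_is_identity(self):
        samples = [self._sample(seed=s) for s in (10, 11, 12)]
        kept, rejected = apply_filters(samples)
        assert kept == samples and not rejected

    def test_every_rejection_has_one_reason(self):
        samples = [self._sample(seed=13), self._sample(seed=14, water_ligand=True),
                   self._sample(seed=15, omit_fe=True)]
        samples[0].resolution = 3.0
        kept, rejected = apply_filters(samples)
        assert set(r.reason for r in rejected) == {"resolution", "axial_ligand", "incomplete_skeleton"}
        assert len(kept) + len(rejected) == len(samples)


class TestHemeType:
    @pytest.mark.parametrize("het,expected", [("HEM", "b"), ("HEC", "c"), ("HEA", "a"), ("HEO", "o")])
    def test_compound_id_mapping(self, het, expected):
        model, _ = _synthetic_model(seed=20, het_id=het)
        (heme,) = extract_hemes(model)
        assert assign_heme_type(heme) == expected

    def test_missing_peripherals_unknown(self):
        model, _ = _synthetic_model(seed=21)
        (heme,) = extract_hemes(model)
        stripped = type(heme)(
            entry_id=heme.entry_id, het_id=heme.het_id, skeleton=heme.skeleton,
            extra_atom_names=frozenset(), resolution=heme.resolution,
        )
        assert assign_heme_type(stripped) == "unknown"

    def test_unrecognized_id_errors(self):
        model, _ = _synthetic_model(seed=22)
        (heme,) = extract_hemes(model)
        bad = type(heme)(entry_id="x", het_id="ZZZ", skeleton=heme.skeleton,
                         extra_atom_names=frozenset(), resolution=1.5)
        with pytest.raises(ValueError):
            assign_heme_type(bad)


class TestSequenceRedundancy:
    def test_identical_chains_collapse(self):
        chains = [("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR")]
        assert len(deduplicate_sequences(chains)) == 1

    def test_one_mismatch_in_100_kept(self):
        seq = "ACDEFGHIKL" * 10
        mutated = "P" + seq[1:]
        assert pairwise_identity(seq, mutated) == pytest.approx(99.0)
        kept = deduplicate_sequences([("a", seq), ("b", mutated)])
        assert len(kept) == 2

    def test_single_chain_kept(self):
        assert deduplicate_sequences([("a", "MKT")]) == [("a", "MKT")]

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            deduplicate_sequences([("a", "")])

    def test_idempotent_and_no_close_pairs(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aas, 40)) for _ in range(8)]
        chains = [(f"c{i}", s) for i, s in enumerate(seqs + seqs[:4])]
        kept = deduplicate_sequences(chains)
        assert deduplicate_sequences(kept) == kept
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert pairwise_identity(kept[i][1], kept[j][1]) < 99.99

    def test_identical_chains_one_cluster(self):
        clusters = cluster_sequences([("a", "MKTAYIAKQR"), ("b", "MKTAYIAKQR")])
        assert len(clusters) == 1 and sorted(clusters[0].members) == ["a", "b"]

    def test_divergent_chains_two_clusters(self):
        rng = np.random.default_rng(1)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        s1 = "".join(rng.choice(aas, 60))
        s2 = "".join(rng.choice(aas, 60))
        assert pairwise_identity(s1, s2) < 60
        clusters = cluster_sequences([("a", s1), ("b", s2)], identity_threshold=90.0)
        assert len(clusters) == 2

    def test_empty_input(self):
        assert cluster_sequences([]) == []

    def test_clusters_partition_input(self):
        rng = np.random.default_rng(2)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(aas, 50))
        chains = [(f"c{i}", base) for i in range(3)]
        chains += [(f"d{i}", "".join(rng.choice(aas, 50))) for i in range(4)]
        clusters = cluster_sequences(chains)
        members = [m for cl in clusters for m in cl.members]
        assert sorted(members) == sorted(c for c, _ in chains)
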