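"""Feature perception, conformer generation, pharmacophore fitting."""

import numpy as np
import pytest
from rdkit.Chem import rdMolAlign

from covgen.chem import Fragment, Molecule, Role
from covgen.errors import CovgenError
from covgen.pharmacophore import (
    ExclusionVolume,
    Feature,
    FeatureType,
    PharmacophoreModel,
    cap_attachment_points,
    fit,
    generate_conformers,
    model_from_conformer,
    perceive_features,
)


def random_rigid_motion(seed=0):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q, rng.normal(scale=5.0, size=3)


class TestPerceiveFeatures:
    def test_benzene_single_aromatic_centroid(self):
        cs = generate_conformers(Molecule.from_smiles("c1ccccc1"), 1, seed=3)
        feats = perceive_features(cs.molecule, cs.conformers[0])
        assert [t for t, _ in feats] == [FeatureType.AROMATIC]
        ring = cs.conformers[0][:6]
        np.testing.assert_allclose(feats[0][1], ring.mean(axis=0), atol=1e-6)

    def test_methanol_donor_and_acceptor(self):
        cs = generate_conformers(Molecule.from_smiles("CO"), 1, seed=3)
        types = sorted(t.value for t, _ in perceive_features(cs.molecule, cs.conformers[0]))
        assert types == ["HBA", "HBD"]

    def test_warhead_beta_carbon_is_residue_bonding_point(self, warhead):
        frag = Fragment.from_smiles("*C1CCCN(C(=O)C=C)C1", Role.VALUE2)
        capped = cap_attachment_points(frag)
        cs = generate_conformers(capped, 1, seed=3)
        feats = perceive_features(cs.molecule, cs.conformers[0], warhead)
        rbp = [p for t, p in feats if t is FeatureType.RESIDUE_BONDING_POINT]
        assert len(rbp) == 1
        # beta carbon: terminal CH2 of the acrylamide
        match = cs.molecule.GetSubstructMatch(warhead.query())
        np.testing.assert_allclose(rbp[0], cs.conformers[0][match[0]])


class TestGenerateConformers:
    def test_rigid_benzene(self):
        cs = generate_conformers(Molecule.from_smiles("c1ccccc1"), 5, seed=1)
        assert len(cs.conformers) >= 1
        for i in range(1, len(cs.conformers)):
            rms = rdMolAlign.GetBestRMS(cs.molecule, cs.molecule, prbId=i, refId=0)
            assert rms < 0.5

    def test_flexible_octane_varies(self):
        cs = generate_conformers(Molecule.from_smiles("CCCCCCCC"), 25, seed=1)
        assert len(cs.conformers) > 1
        rms = [rdMolAlign.GetBestRMS(cs.molecule, cs.molecule, prbId=i, refId=0)
               for i in range(1, len(cs.conformers))]
        assert max(rms) > 0.5

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            generate_conformers(Molecule.from_smiles("CC"), 0, seed=1)

    def test_determinism(self):
        a = generate_conformers(Molecule.from_smiles("CCOCC"), 5, seed=9)
        b = generate_conformers(Molecule.from_smiles("CCOCC"), 5, seed=9)
        assert len(a.conformers) == len(b.conformers)
        for ca, cb in zip(a.conformers, b.conformers):
            np.testing.assert_allclose(ca, cb)


@pytest.fixture(scope="module")
def aminopyrimidine_fit(warhead):
    """Conformers and a self-derived model for a warhead-bearing compound."""
    mol = Molecule.from_smiles("Nc1ncnc2c1cnn2C1CCCN(C(=O)C=C)C1")
    confs = generate_conformers(mol, 8, seed=5)
    model = model_from_conformer(confs.molecule, confs.conformers[0],
                                 radius=1.5, warhead=warhead)
    return confs, model


class TestFit:
    def test_self_fit_is_near_perfect(self, aminopyrimidine_fit, warhead):
        confs, model = aminopyrimidine_fit
        res = fit(confs, model, warhead=warhead)
        assert res.best_score >= 0.99
        assert res.fit and res.matched_features == len(model.features)
        assert res.rmsd < 0.1

    def test_rigid_motion_invariance(self, aminopyrimidine_fit, warhead):
        confs, model = aminopyrimidine_fit
        base = fit(confs, model, warhead=warhead)
        for seed in (1, 2):
            R, t = random_rigid_motion(seed)
            moved = fit(confs, model.transformed(R, t), warhead=warhead)
            assert abs(moved.best_score - base.best_score) < 1e-6
            assert moved.conformer_index == base.conformer_index

    def test_no_compatible_assignment_scores_zero(self):
        cs = generate_conformers(Molecule.from_smiles("CCCCC"), 2, seed=1)
        model = PharmacophoreModel(features=(
            Feature(FeatureType.AROMATIC, (0.0, 0.0, 0.0), 1.5),
        ))
        res = fit(cs, model)
        assert res.best_score == 0.0 and not res.fit

    def test_exclusion_on_fitted_atom_forces_clash(self):
        """A rigid single-feature fit has no escape assignment: putting an
        exclusion sphere on the fitted position zeroes the score."""
        cs = generate_conformers(Molecule.from_smiles("c1ccccc1"), 1, seed=2)
        centroid = cs.conformers[0][:6].mean(axis=0)
        model = PharmacophoreModel(
            features=(Feature(FeatureType.AROMATIC, tuple(centroid), 1.5),),
            exclusion_volumes=(ExclusionVolume(tuple(centroid), 2.0),),
        )
        res = fit(cs, model)
        assert res.best_score == 0.0 and res.clash

    def test_radius_monotonicity(self, aminopyrimidine_fit, warhead):
        confs, model = aminopyrimidine_fit
        tight = PharmacophoreModel(
            features=tuple(Feature(f.type, f.position, 0.4, f.optional)
                           for f in model.features))
        wide = PharmacophoreModel(
            features=tuple(Feature(f.type, f.position, 2.5, f.optional)
                           for f in model.features))
        s_tight = fit(confs, tight, warhead=warhead).best_score
        s_mid = fit(confs, model, warhead=warhead).best_score
        s_wide = fit(confs, wide, warhead=warhead).best_score
        assert s_tight <= s_mid <= s_wide

    def test_exclusion_monotonicity(self, aminopyrimidine_fit, warhead):
        confs, model = aminopyrimidine_fit
        base = fit(confs, model, warhead=warhead).best_score
        ex = ExclusionVolume(tuple(model.features[0].position), 1.2)
        withex = fit(confs, PharmacophoreModel(model.features, (ex,)),
                     warhead=warhead).best_score
        assert withex <= base

    def test_model_requires_a_required_feature(self):
        with pytest.raises(ValueError):
            PharmacophoreModel(features=(
                Feature(FeatureType.HBA, (0, 0, 0), 1.0, optional=True),
            ))

    def test_model_json_roundtrip(self, tmp_path, aminopyrimidine_fit):
        _, model = aminopyrimidine_fit
        path = tmp_path / "model.json"
        model.save(path)
        loaded = PharmacophoreModel.load(path)
        assert loaded == model


class TestCapAttachmentPoints:
    def test_key2_caps_to_parseable_core(self):
        frag = Fragment.from_smiles("Nc1ncnc2c1c([At])nn2[*:1]", Role.KEY2)
        capped = cap_attachment_points(frag)
        assert capped.smiles == "Nc1ncnc2[nH]ncc12"

    def test_value_fragment(self):
        frag = Fragment.from_smiles("*C1CCCN(C(=O)C=C)C1", Role.VALUE2)
        assert cap_attachment_points(frag).smiles == "C=CC(=O)N1CCCCC1"
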