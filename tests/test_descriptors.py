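"""Loop-geometry descriptors: probe distances, H-bond flag, rotation, waters."""

import numpy as np
import pandas as pd
import pytest

from neiltriage import descriptors, structio, synthdata
from neiltriage.descriptors import (
    DescriptorNotAvailable,
    LoopDescriptor,
    compute_d242,
    compute_d244,
    compute_descriptors,
    count_shell_waters,
    delta_n_water,
    detect_tautomer_hbond,
    loop_rotation_angle,
    read_descriptor_csv,
    write_descriptor_csv,
)
from neiltriage.structio import Atom, Residue, ResidueView

from conftest import random_rigid_transform


def _base(model):
    return structio.select_residue(model, "B", 5)


class TestD242:
    def test_in242_contact_placed_at_3A(self, toy_models):
        assert compute_d242(toy_models["in242"], "A", _base(toy_models["in242"])) == pytest.approx(3.0, abs=1e-9)

    def test_apo_probe_far_from_base(self, toy_models):
        assert compute_d242(toy_models["apo"], "A", _base(toy_models["apo"])) >= 9.0

    def test_equals_brute_force_min_over_all_pairs(self, toy_models):
        model = toy_models["in242"]
        base = _base(model)
        nz = model.residue("A", 242).atom("NZ").pos
        brute = min(np.linalg.norm(nz - a.pos) for a in base.residue.atoms)
        assert compute_d242(model, "A", base) == pytest.approx(brute, abs=1e-12)

    def test_arg_probe_uses_guanidinium_nitrogens(self, toy_models):
        model = toy_models["in242"].transformed(structio.RigidTransform.identity())
        res = model.residue("A", 242)
        res.name = "ARG"
        nz = res.atom("NZ")
        res.atoms = [a for a in res.atoms if a.name not in ("NZ", "CE")]
        res.atoms.append(Atom("NE", "N", nz.pos + np.array([0.0, 0.4, 0.0])))
        res.atoms.append(Atom("NH1", "N", nz.pos))
        res.atoms.append(Atom("NH2", "N", nz.pos + np.array([0.0, 0.0, 0.7])))
        assert compute_d242(model, "A", _base(model)) == pytest.approx(3.0, abs=1e-9)

    def test_truncated_side_chain_is_not_available(self, toy_models):
        model = toy_models["in242"].transformed(structio.RigidTransform.identity())
        res = model.residue("A", 242)
        res.atoms = [a for a in res.atoms if a.name in ("CA", "CB")]
        with pytest.raises(DescriptorNotAvailable, match="truncated|missing"):
            compute_d242(model, "A", _base(model))

    def test_rigid_invariance(self, toy_models, rng):
        model = toy_models["in242"]
        d0 = compute_d242(model, "A", _base(model))
        for _ in range(5):
            moved = model.transformed(random_rigid_transform(rng))
            assert compute_d242(moved, "A", _base(moved)) == pytest.approx(d0, abs=1e-9)


class TestD244:
    def test_in244_stacking_distance(self, toy_models):
        d, fallback = compute_d244(toy_models["in244"], "A", _base(toy_models["in244"]))
        assert d == pytest.approx(3.6, abs=1e-9)
        assert not fallback

    def test_in242_tyr_swung_out(self, toy_models):
        d, _ = compute_d244(toy_models["in242"], "A", _base(toy_models["in242"]))
        assert d == pytest.approx(8.0, abs=1e-9)

    def test_translation_invariance(self, toy_models):
        model = toy_models["in244"]
        d0, _ = compute_d244(model, "A", _base(model))
        shift = structio.RigidTransform(np.eye(3), np.array([17.0, -4.0, 2.5]))
        moved = model.transformed(shift)
        d1, _ = compute_d244(moved, "A", _base(moved))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_nonaromatic_244_falls_back_flagged(self, toy_models):
        model = toy_models["in244"].transformed(structio.RigidTransform.identity())
        res = model.residue("A", 244)
        res.name = "ALA"
        res.atoms = [a for a in res.atoms if a.name in ("CA", "CB")]
        d, fallback = compute_d244(model, "A", _base(model))
        assert fallback
        assert d > 0


class TestHbond:
    def test_in242_contact_is_hbond(self, toy_models):
        flag, dist = detect_tautomer_hbond(toy_models["in242"], _base(toy_models["in242"]), "A")
        assert flag and dist == pytest.approx(3.0, abs=1e-9)

    def test_apo_no_hbond(self, toy_models):
        flag, dist = detect_tautomer_hbond(toy_models["apo"], _base(toy_models["apo"]), "A")
        assert not flag and dist >= 9.0

    def test_cutoff_is_inclusive(self, toy_models):
        params = synthdata.ToyStructureParams(d242_in=3.5)
        model = synthdata.gen_toy_structure("in242", params=params)
        flag, dist = detect_tautomer_hbond(model, _base(model), "A")
        assert dist == pytest.approx(3.5, abs=1e-9)
        assert flag

    def test_configurable_cutoff(self, toy_models):
        flag, _ = detect_tautomer_hbond(
            toy_models["in242"], _base(toy_models["in242"]), "A", cutoff=2.5
        )
        assert not flag


class TestRotationAngle:
    def test_self_is_zero(self, toy_models):
        m = toy_models["in242"]
        assert loop_rotation_angle(m, m, chain="A") == pytest.approx(0.0, abs=1e-6)

    def test_constructed_40_degrees(self, toy_models):
        ang = loop_rotation_angle(toy_models["apo"], toy_models["in242"], chain="A")
        assert ang == pytest.approx(40.0, abs=1e-6)

    def test_symmetric(self, toy_models):
        a = loop_rotation_angle(toy_models["apo"], toy_models["in242"], chain="A")
        b = loop_rotation_angle(toy_models["in242"], toy_models["apo"], chain="A")
        assert a == pytest.approx(b, abs=1e-6)

    def test_invariant_when_mobile_is_rigidly_moved(self, toy_models, rng):
        # core superposition must undo any rigid motion of one input
        moved = toy_models["apo"].transformed(random_rigid_transform(rng))
        ang = loop_rotation_angle(moved, toy_models["in242"], chain="A")
        assert ang == pytest.approx(40.0, abs=1e-6)

    def test_missing_hinge_is_not_available(self, toy_models):
        model = toy_models["apo"].transformed(structio.RigidTransform.identity())
        model.residues = [r for r in model.residues if not (r.chain == "A" and r.number == 249)]
        with pytest.raises(DescriptorNotAvailable):
            loop_rotation_angle(model, toy_models["in242"], chain="A")


class TestShellWaters:
    def test_constructed_counts(self, toy_models):
        model = toy_models["in242"].transformed(structio.RigidTransform.identity())
        base = _base(model)
        targets = np.array([a.pos for a in base.residue.atoms])
        center = targets.mean(axis=0)
        near = [center + np.array([0.0, 0.0, 3.0 + 0.3 * i]) for i in range(6)]  # 3-4.5 A
        far = [center + np.array([8.4, 0.0, 0.0]) + i for i in range(4)]  # ~7 A from ring edge
        for i, pos in enumerate((*near, *far)):
            w = Residue("W", 900 + i, "HOH", is_water=True)
            w.atoms.append(Atom("O", "O", pos))
            model.waters.append(w)
        assert count_shell_waters(model, base, radius=5.0) == 6

    def test_radius_zero(self, toy_models):
        assert count_shell_waters(toy_models["in242"], _base(toy_models["in242"]), radius=0.0) == 0

    def test_monotone_in_radius(self, toy_models, rng):
        model, _ = synthdata.gen_solvation_shell(
            toy_models["in242"], expected_in_shell=12, seed=7
        )
        base = _base(model)
        counts = [count_shell_waters(model, base, r) for r in (0.0, 2.0, 4.0, 5.0, 8.0, 20.0)]
        assert counts == sorted(counts)

    def test_generator_bookkeeping_oracle(self, toy_models):
        model, k = synthdata.gen_solvation_shell(
            toy_models["in242"], expected_in_shell=12, shell=(2.5, 5.0), seed=42
        )
        assert count_shell_waters(model, _base(model), radius=5.0) == k


class TestDeltaNWater:
    def test_identical_ensembles_zero(self):
        ens = [[3.0, 4.0], [2.8, 6.0], [3.3]]
        assert np.allclose(delta_n_water(ens, ens, [0, 2, 4, 6, 8]), 0.0)

    def test_one_extra_water_in_one_bin(self):
        base = [[4.5], [4.5], [4.5]]
        extra = [[4.5, 3.0], [4.5, 3.0], [4.5, 3.0]]
        diff = delta_n_water(extra, base, [0, 2, 4, 6])
        assert np.allclose(diff, [0.0, 1.0, 0.0])

    def test_poisson_mean_oracle_from_generator(self, toy_models):
        # hydrophilic (lam=10) vs quarantine-prone (lam=6) shells: summed
        # in-shell difference ~ 4 within 3 standard errors
        rng_seeds = range(500)
        base_model = toy_models["in242"]

        def distances(lam, seed):
            model, _ = synthdata.gen_solvation_shell(
                base_model, expected_in_shell=lam, shell=(2.5, 5.0), seed=seed
            )
            base = _base(model)
            targets = np.array([a.pos for a in base.residue.atoms])
            return [
                float(np.linalg.norm(targets - w.atoms[0].pos, axis=1).min())
                for w in model.waters
            ]

        ens_a = [distances(10, 2 * s) for s in rng_seeds]
        ens_q = [distances(6, 2 * s + 1) for s in rng_seeds]
        edges = [0.0, 2.5, 5.0]
        diff = delta_n_water(ens_a, ens_q, edges)
        se = np.sqrt((10 + 6) / 500)  # var of a Poisson-mean difference
        assert abs(diff.sum() - 4.0) < 3 * se

    def test_empty_ensemble_errors(self):
        with pytest.raises(ValueError):
            delta_n_water([], [[1.0]], [0, 5])

    def test_bad_bin_edges(self):
        with pytest.raises(ValueError):
            delta_n_water([[1.0]], [[1.0]], [5, 0])


class TestDescriptorTable:
    def test_compute_descriptors_and_csv_roundtrip(self, toy_models, tmp_path):
        descs = [
            compute_descriptors(m, "A", _base(m), reference=toy_models["in242"], source=s)
            for s, m in toy_models.items()
        ]
        path = tmp_path / "desc.csv"
        write_descriptor_csv(descs, path)
        df = read_descriptor_csv(path)
        assert list(df["source"]) == list(toy_models)
        assert df.loc[df.source == "in242", "d242"].iloc[0] == pytest.approx(3.0, abs=1e-6)
        assert df.loc[df.source == "apo", "rotation_deg"].iloc[0] == pytest.approx(40.0, abs=1e-6)

    def test_not_available_written_as_empty_cell(self, toy_models, tmp_path):
        model = toy_models["in242"].transformed(structio.RigidTransform.identity())
        res = model.residue("A", 242)
        res.atoms = [a for a in res.atoms if a.name in ("CA", "CB")]
        desc = compute_descriptors(model, "A", _base(model))
        assert desc.d242 is None
        assert "d242" in desc.not_available
        path = tmp_path / "na.csv"
        write_descriptor_csv([desc], path)
        raw = path.read_text().splitlines()
        assert raw[1].split(",")[1] == ""  # empty d242 cell

    def test_descriptor_validation(self):
        with pytest.raises(ValueError):
            LoopDescriptor(d242=-1.0)
        with pytest.raises(ValueError):
            LoopDescriptor(rotation_deg=200.0)
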