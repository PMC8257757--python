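"""Generators: determinism, Boltzmann consistency, construction targets."""

import math

import numpy as np
import pandas as pd
import pytest

from neiltriage import descriptors, states, structio, synthdata, thermo
from neiltriage.synthdata import (
    EnsembleSpec,
    KineticsSpec,
    ToyStructureParams,
    gen_conformational_ensemble,
    gen_solvation_shell,
    gen_timecourse_dataset,
    gen_toy_structure,
)


class TestEnsembleGenerator:
    def test_symmetric_two_state_split(self):
        spec = EnsembleSpec(n=10000, free_energies={"in242": 0.0, "in244": 0.0}, seed=1)
        df = gen_conformational_ensemble(spec)
        n242 = (df.true_label == "in242").sum()
        assert abs(n242 - 5000) < 3 * math.sqrt(10000 / 4)

    def test_boltzmann_weight_one_kcal(self):
        spec = EnsembleSpec(n=10000, free_energies={"in242": 1.0, "in244": 0.0}, seed=2)
        df = gen_conformational_ensemble(spec)
        p = thermo.activated_fraction(1.0)
        se = math.sqrt(p * (1 - p) / 10000)
        assert abs((df.true_label == "in242").mean() - p) < 3 * se

    def test_degenerate_zero_covariance(self):
        spec = EnsembleSpec(
            n=50,
            free_energies={"in242": 0.0},
            covariances={"in242": ((0.0, 0.0), (0.0, 0.0))},
            seed=3,
        )
        df = gen_conformational_ensemble(spec)
        assert np.allclose(df[["d242", "d244"]], synthdata.DEFAULT_CENTROIDS["in242"])

    def test_seed_determinism(self):
        spec = EnsembleSpec(n=500, free_energies={"in242": 0.5, "in244": 0.0}, seed=9)
        a = gen_conformational_ensemble(spec)
        b = gen_conformational_ensemble(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_truth_labels_agree_with_classifier_when_separated(self):
        # tight components (sd 0.2) at centroids >= 4 A apart: 6-sigma separation
        spec = EnsembleSpec(
            n=5000,
            free_energies={"apo": 0.0, "in242": 0.0, "in244": 0.0},
            covariances={s: ((0.04, 0.0), (0.0, 0.04)) for s in states.STATE_LABELS},
            seed=4,
        )
        df = gen_conformational_ensemble(spec)
        refs = [states.StateReference(s, c) for s, c in synthdata.DEFAULT_CENTROIDS.items()]
        pred = states.StateClassifier(refs).fit().predict(df[["d242", "d244"]].to_numpy())
        assert (pred == df.true_label.to_numpy()).mean() >= 0.99

    def test_invalid_specs(self):
        with pytest.raises(ValueError):
            gen_conformational_ensemble(EnsembleSpec(n=0, weights={"in242": 1.0}))
        with pytest.raises(ValueError):
            EnsembleSpec(n=10, weights={"in242": 0.4}).resolved_weights()
        bad_cov = EnsembleSpec(
            n=10, free_energies={"in242": 0.0}, covariances={"in242": ((1.0, 2.0), (2.0, 1.0))}
        )
        with pytest.raises(ValueError, match="positive semi-definite"):
            gen_conformational_ensemble(bad_cov)

    def test_end_to_end_dG_recovery(self):
        for dG_true in (-1.5, 0.0, 1.5):
            spec = EnsembleSpec(
                n=10000, free_energies={"in242": dG_true, "in244": 0.0}, seed=77
            )
            df = gen_conformational_ensemble(spec)
            s = states.state_populations(df)
            assert abs(s.dG - dG_true) <= 3 * s.dG_se


class TestKineticsGenerator:
    def _spec(self, noise=0.0, seed=0):
        params = pd.DataFrame(
            [
                {"variant": "K242", "substrate": "DHU", "k_cat": 1.5, "dG_conf": 0.0, "dG_chem": 0.0},
                {"variant": "R242", "substrate": "DHU", "k_cat": 1.5, "dG_conf": 0.6, "dG_chem": 0.4},
            ]
        )
        return KineticsSpec(params=params, noise_sd=noise, replicates=2, seed=seed)

    def test_noiseless_curves_match_closed_form(self):
        data, truth = gen_timecourse_dataset(self._spec())
        for key, info in truth.items():
            grp = data[(data.variant == info["variant"]) & (data.substrate == info["substrate"])]
            grp = grp[grp.replicate == 0]
            expected = info["A"] * (1 - np.exp(-info["k_obs_true"] * grp.time_min.to_numpy()))
            assert np.allclose(grp.fraction_product.to_numpy(), expected, atol=1e-12)

    def test_true_rate_ratio_follows_rate_law(self):
        _, truth = gen_timecourse_dataset(self._spec())
        r = truth["K242:DHU"]["k_obs_true"] / truth["R242:DHU"]["k_obs_true"]
        expected = thermo.activated_fraction(0.0) / thermo.activated_fraction(1.0)
        assert r == pytest.approx(expected, rel=1e-12)

    def test_csv_regeneration_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        gen_timecourse_dataset(self._spec(noise=0.02, seed=5), csv_path=p1)
        gen_timecourse_dataset(self._spec(noise=0.02, seed=5), csv_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_spec_loadable_from_yaml(self, tmp_path):
        import yaml

        cfg = tmp_path / "spec.yaml"
        cfg.write_text(yaml.safe_dump({
            "params": [
                {"variant": "K242", "substrate": "DHU", "k_cat": 1.5,
                 "dG_conf": 0.0, "dG_chem": 0.0},
            ],
            "noise_sd": 0.0,
            "replicates": 1,
            "seed": 4,
        }))
        spec = KineticsSpec.from_file(cfg)
        data, truth = gen_timecourse_dataset(spec)
        assert truth["K242:DHU"]["k_obs_true"] == pytest.approx(0.75)

        ens_cfg = tmp_path / "ens.yaml"
        ens_cfg.write_text(yaml.safe_dump({
            "n": 100, "free_energies": {"in242": 0.0, "in244": 0.0}, "seed": 1,
        }))
        df = gen_conformational_ensemble(EnsembleSpec.from_file(ens_cfg))
        assert len(df) == 100

    def test_truth_sidecar_written(self, tmp_path):
        truth_path = tmp_path / "truth.json"
        gen_timecourse_dataset(self._spec(), truth_path=truth_path)
        import json

        truth = json.loads(truth_path.read_text())
        assert set(truth) == {"K242:DHU", "R242:DHU"}
        assert truth["K242:DHU"]["k_obs_true"] == pytest.approx(0.75)


class TestToyStructures:
    def test_in242_descriptor_targets(self, toy_models):
        model = toy_models["in242"]
        base = structio.select_residue(model, "B", 5)
        assert descriptors.compute_d242(model, "A", base) == pytest.approx(3.0, abs=1e-9)
        flag, _ = descriptors.detect_tautomer_hbond(model, base, "A")
        assert flag

    def test_apo_displacement_and_rotation(self, toy_models):
        model = toy_models["apo"]
        base = structio.select_residue(model, "B", 5)
        assert descriptors.compute_d242(model, "A", base) >= 9.0
        d244, _ = descriptors.compute_d244(model, "A", base)
        assert d244 >= 9.0
        ang = descriptors.loop_rotation_angle(model, toy_models["in242"], chain="A")
        assert ang == pytest.approx(40.0, abs=1e-6)

    def test_custom_targets_honoured(self):
        params = ToyStructureParams(d242_in=2.8, d244_in=3.4, apo_rotation_deg=35.0)
        m242 = gen_toy_structure("in242", params=params)
        base = structio.select_residue(m242, "B", 5)
        assert descriptors.compute_d242(m242, "A", base) == pytest.approx(2.8, abs=1e-9)
        mapo = gen_toy_structure("apo", params=params)
        ang = descriptors.loop_rotation_angle(mapo, gen_toy_structure("in242"), chain="A")
        assert ang == pytest.approx(35.0, abs=1e-6)

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValueError):
            ToyStructureParams(d242_in=9.0, d242_out=3.0)
        with pytest.raises(ValueError, match="infeasible"):
            gen_toy_structure("apo", params=ToyStructureParams(apo_distance=1.0))

    def test_unknown_state_rejected(self):
        with pytest.raises(ValueError, match="state"):
            gen_toy_structure("quarantine")

    def test_written_fixture_reparses_with_same_descriptors(self, tmp_path):
        p = tmp_path / "toy.pdb"
        gen_toy_structure("in244", path=p)
        model = structio.read_structure(p)
        base = structio.select_residue(model, "B", 5)
        d244, _ = descriptors.compute_d244(model, "A", base)
        assert d244 == pytest.approx(3.6, abs=2e-3)  # 3-decimal PDB precision


class TestSolvationShell:
    def test_zero_lambda(self, toy_models):
        model, k = gen_solvation_shell(toy_models["in242"], expected_in_shell=0.0, seed=1)
        assert k == 0
        base = structio.select_residue(model, "B", 5)
        assert descriptors.count_shell_waters(model, base, 5.0) == 0

    def test_poisson_mean_over_500_draws(self, toy_models):
        ks = [
            gen_solvation_shell(toy_models["in242"], expected_in_shell=10, seed=s)[1]
            for s in range(500)
        ]
        # sample mean of Poisson(10) over 500 draws: SE = sqrt(10/500)
        assert abs(np.mean(ks) - 10.0) < 3 * math.sqrt(10 / 500)

    def test_bookkeeping_matches_counter(self, toy_models):
        model, k = gen_solvation_shell(
            toy_models["in242"], expected_in_shell=8, shell=(2.5, 5.0), seed=11
        )
        base = structio.select_residue(model, "B", 5)
        assert descriptors.count_shell_waters(model, base, radius=5.0) == k
        # far-field set sits strictly outside the shell
        assert len(model.waters) == k + 4

    def test_deterministic_file_output(self, toy_models, tmp_path):
        p1, p2 = tmp_path / "s1.pdb", tmp_path / "s2.pdb"
        gen_solvation_shell(toy_models["in242"], 6, seed=3, path=p1)
        gen_solvation_shell(toy_models["in242"], 6, seed=3, path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_shell(self, toy_models):
        with pytest.raises(ValueError):
            gen_solvation_shell(toy_models["in242"], 5, shell=(5.0, 2.0))
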