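import numpy as np
import pandas as pd
import pytest

from recepstruct.features import helix_axis
from recepstruct.regression import ols_fit
from recepstruct.structure import assign_secondary_structure, read_structure, write_structure
from recepstruct.synthetic import (
    ConstructionError,
    DimerSpec,
    FEATURE_NAMES,
    HelixSpec,
    SyntheticFamilySpec,
    count_receptor_pairings,
    enumerate_design_space,
    ideal_helix,
    make_ecd_complex,
    make_tmd_dimer,
    simulate_performance,
)
from recepstruct.synthetic.designs import FamilyDesignSpace
from recepstruct.synthetic.fixtures import generate_demo_dataset


class TestIdealHelix:
    def test_ca_ca_spacing(self, helix_chain):
        cas = helix_chain.coords("CA")
        spacing = np.linalg.norm(np.diff(cas, axis=0), axis=1)
        np.testing.assert_allclose(spacing, 3.8, atol=0.1)

    def test_axis_along_z(self, helix_chain):
        direction, _ = helix_axis(helix_chain)
        angle = np.degrees(np.arccos(abs(float(direction @ [0, 0, 1]))))
        assert angle < 1.0

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            HelixSpec(n_residues=3)

    def test_custom_sequence(self):
        chain = ideal_helix(HelixSpec(n_residues=4, sequence=["GLY", "ALA", "LEU", "MET"]))
        assert [r.name for r in chain.residues] == ["GLY", "ALA", "LEU", "MET"]

    def test_sequence_length_checked(self):
        with pytest.raises(ValueError):
            HelixSpec(n_residues=5, sequence=["GLY"])

    def test_helical_chain_mostly_helix_labels(self):
        from recepstruct.structure.model import Structure

        for n in (15, 20, 30):
            chain = ideal_helix(HelixSpec(n_residues=n))
            ss = assign_secondary_structure(Structure(chains=[chain]))
            labels = ss.chain_labels(chain)
            assert labels.count("H") / n >= 0.7


class TestMakeTmdDimer:
    def test_deterministic(self):
        spec = DimerSpec(axis_separation=9.0, crossing_angle=30.0)
        a = make_tmd_dimer(spec)
        b = make_tmd_dimer(spec)
        np.testing.assert_array_equal(
            np.vstack([c.coords() for c in a.chains]),
            np.vstack([c.coords() for c in b.chains]),
        )

    def test_pdb_round_trip_byte_identical(self, tmp_path):
        spec = DimerSpec(axis_separation=9.0, crossing_angle=30.0)
        p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
        write_structure(make_tmd_dimer(spec), p1)
        write_structure(make_tmd_dimer(spec), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_invalid_separation(self):
        with pytest.raises(ValueError):
            DimerSpec(axis_separation=0.0)

    def test_terminal_gap_override(self):
        spec = DimerSpec(axis_separation=10.0, crossing_angle=20.0, terminal_gap_override=13.0)
        dimer = make_tmd_dimer(spec)
        from recepstruct.features import tmd_terminal_distance

        assert tmd_terminal_distance(dimer) == pytest.approx(13.0, abs=1e-6)

    def test_membrane_frame(self):
        dimer = make_tmd_dimer(DimerSpec())
        direction, _ = helix_axis(dimer.chains[0])
        assert abs(float(direction @ [0, 0, 1])) > 0.999


class TestMakeEcdComplex:
    def test_same_seed_identical(self):
        a = make_ecd_complex(30.0, seed=5)
        b = make_ecd_complex(30.0, seed=5)
        np.testing.assert_array_equal(
            np.vstack([c.coords() for c in a.chains]),
            np.vstack([c.coords() for c in b.chains]),
        )

    def test_different_seed_differs(self):
        a = make_ecd_complex(30.0, seed=5)
        b = make_ecd_complex(30.0, seed=6)
        assert not np.allclose(
            np.vstack([c.coords() for c in a.chains]),
            np.vstack([c.coords() for c in b.chains]),
        )

    def test_infeasible_pose_raises(self):
        with pytest.raises(ConstructionError):
            make_ecd_complex(terminal_distance=5.0, interface_gap=15.0)

    def test_ligand_chain_optional(self):
        assert len(make_ecd_complex(30.0, seed=0).chains) == 2
        with_ligand = make_ecd_complex(30.0, seed=0, with_ligand=True)
        assert len(with_ligand.chains) == 3
        assert with_ligand.chain("L").role == "ligand"

    def test_parses_after_round_trip(self, tmp_path):
        structure = make_ecd_complex(26.5, seed=1)
        path = tmp_path / "ecd.pdb"
        write_structure(structure, path)
        reread = read_structure(path)
        ss = assign_secondary_structure(reread)
        for chain in reread.chains:
            labels = ss.chain_labels(chain)
            assert labels.count("H") / len(labels) >= 0.7


class TestEnumerateDesignSpace:
    def test_vegf_sixteen_pairings(self):
        assert count_receptor_pairings("vegf") == 16

    def test_vegf_thirty_two_combinations(self):
        assert len(enumerate_design_space("vegf")) == 32

    def test_single_levels_give_one_row(self):
        space = FamilyDesignSpace(
            name="tiny",
            ecd_levels=["E"],
            natural_tmds={"E": "T"},
            shared_tmds=[],
            ligand_levels=["L"],
        )
        assert len(enumerate_design_space(space)) == 1

    def test_full_cartesian_option(self):
        # 2 ECD x 3 TMD = 6 variants per role -> 36 pairings x 2 ligands
        assert len(enumerate_design_space("vegf", full_cartesian=True)) == 72

    def test_unknown_family(self):
        with pytest.raises(KeyError):
            enumerate_design_space("notch")

    def test_design_ids_unique(self):
        table = enumerate_design_space("tnf")
        assert table["design_id"].is_unique


class TestSimulatePerformance:
    def _spec(self, **kwargs):
        defaults = dict(
            beta={name: 0.0 for name in FEATURE_NAMES} | {"ecd_distance": -1.0},
            noise_sd=0.3,
            skew="exponential",
            seed=0,
        )
        defaults.update(kwargs)
        return SyntheticFamilySpec(**defaults)

    def test_zero_noise_perfect_fit(self):
        table = simulate_performance(None, self._spec(noise_sd=0.0))
        X = table[["ecd_distance"]]
        y = np.log10(table["os_meptr"].to_numpy())
        fit = ols_fit(X, y)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_null_betas_give_low_r_squared(self):
        low = 0
        n_rep = 40
        for seed in range(n_rep):
            spec = self._spec(beta={name: 0.0 for name in FEATURE_NAMES},
                              noise_sd=1.0, seed=seed)
            table = simulate_performance(None, spec)
            y = np.log10(table["os_meptr"].to_numpy())
            r2_values = [
                ols_fit(table[[name]], y).r_squared for name in FEATURE_NAMES
            ]
            low += all(r2 < 0.2 for r2 in r2_values)
        assert low >= 0.9 * n_rep

    def test_skewed_output_recovers_beta_after_log(self):
        spec = self._spec(noise_sd=0.2, seed=3)
        table = simulate_performance(None, spec)
        X = table[FEATURE_NAMES]
        X_std = (X - X.mean()) / X.std(ddof=1)
        y = np.log10(table["os_meptr"].to_numpy())
        fit = ols_fit(X_std, y)
        n = len(table)
        tolerance = 2 * 0.2 / np.sqrt(n)
        assert fit.coefficients["ecd_distance"] == pytest.approx(-1.0, abs=3 * tolerance)

    def test_deterministic_per_seed(self):
        a = simulate_performance(None, self._spec(seed=9))
        b = simulate_performance(None, self._spec(seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_positive_outputs_when_skewed(self):
        table = simulate_performance(None, self._spec(noise_sd=2.0))
        assert (table["os_meptr"] > 0).all()
        assert (table["fi"] > 0).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            self._spec(noise_sd=-1.0)


class TestDemoDataset:
    def test_generates_parseable_fixture_set(self, tmp_path):
        paths = generate_demo_dataset(tmp_path, seed=0)
        manifest = pd.read_csv(paths["manifest"])
        assert len(manifest) == 32
        first = tmp_path / manifest.loc[0, "structure_file"]
        structure = read_structure(first)
        assert len(structure.chains) == 3  # two receptors + ligand

    def test_byte_identical_across_runs(self, tmp_path):
        generate_demo_dataset(tmp_path / "a", seed=4)
        generate_demo_dataset(tmp_path / "b", seed=4)
        for name in ("manifest.csv", "designs.csv", "structures/ecd_000.pdb",
                     "structures/tmd_031.pdb"):
            assert (tmp_path / "a" / name).read_bytes().replace(
                str(tmp_path / "a").encode(), b""
            ) == (tmp_path / "b" / name).read_bytes().replace(
                str(tmp_path / "b").encode(), b""
            )
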