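import copy

import numpy as np
import pandas as pd
import pytest

from recepstruct.features import (
    ComplexManifestRow,
    ContactParams,
    FeatureConfig,
    FeatureExtractionError,
    FeatureVector,
    TMDFeatures,
    average_ordered_tmd_features,
    build_feature_table,
    ecd_terminal_distance,
    interchain_contacts,
    measure_tmd_dimer,
    read_feature_table,
    read_manifest,
    tetramer_ecd_features,
    write_feature_table,
)
from recepstruct.structure import assign_secondary_structure, write_structure
from recepstruct.structure.model import Structure
from recepstruct.synthetic import (
    DimerSpec,
    HelixSpec,
    ideal_helix,
    make_ecd_complex,
    make_tmd_dimer,
)


class TestFeatureVectorInvariants:
    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(-1.0, 0, 5.0, 0, 0.0, 90.0)

    def test_exit_angle_range_enforced(self):
        with pytest.raises(ValueError):
            FeatureVector(1.0, 0, 5.0, 0, 0.0, 200.0)

    def test_fractional_contacts_allowed(self):
        fv = FeatureVector(1.0, 2.5, 5.0, 7.5, 10.0, 90.0)
        assert fv.ecd_contacts == 2.5


class TestAverageOrderedTmd:
    def test_identical_inputs_unchanged(self):
        features = TMDFeatures(10.0, 12.0, 30.0, 90.0)
        averaged = average_ordered_tmd_features(features, features)
        assert averaged == features

    def test_simple_mean(self):
        a = TMDFeatures(10.0, 4.0, 20.0, 60.0)
        b = TMDFeatures(20.0, 6.0, 40.0, 120.0)
        averaged = average_ordered_tmd_features(a, b)
        assert averaged == TMDFeatures(15.0, 5.0, 30.0, 90.0)

    def test_matches_hand_average_of_two_orderings(self):
        config = FeatureConfig()
        ab = make_tmd_dimer(DimerSpec(
            helix_a=HelixSpec(n_residues=21, chain_id="A"),
            helix_b=HelixSpec(n_residues=18, chain_id="B"),
            axis_separation=8.0, crossing_angle=25.0))
        ba = make_tmd_dimer(DimerSpec(
            helix_a=HelixSpec(n_residues=18, chain_id="A"),
            helix_b=HelixSpec(n_residues=21, chain_id="B"),
            axis_separation=8.0, crossing_angle=25.0))
        f_ab = measure_tmd_dimer(ab, config)
        f_ba = measure_tmd_dimer(ba, config)
        averaged = average_ordered_tmd_features(f_ab, f_ba)
        assert averaged.tmd_distance == pytest.approx((f_ab.tmd_distance + f_ba.tmd_distance) / 2)
        assert averaged.tmd_contacts == pytest.approx((f_ab.tmd_contacts + f_ba.tmd_contacts) / 2)


def _tetramer(shift_far=40.0):
    """Four receptor chains: A1 close to B1, A2 close to B2."""
    chains = []
    serial = 1
    for chain_id, dx, dz in (
        ("E", 0.0, 0.0),  # alpha 1
        ("F", shift_far, 0.0),  # alpha 2
        ("G", 9.0, 0.0),  # beta 1, near alpha 1
        ("H", shift_far + 9.0, 0.0),  # beta 2, near alpha 2
    ):
        chain = ideal_helix(HelixSpec(n_residues=20, chain_id=chain_id), serial_start=serial)
        serial += 100
        for atom in chain.atoms():
            atom.coords = atom.coords + np.array([dx, 0.0, dz])
        chains.append(chain)
    return Structure(chains=chains)


class TestTetramerEcdFeatures:
    def test_matching_equals_brute_force(self):
        structure = _tetramer()
        ss = assign_secondary_structure(structure)
        params = ContactParams()
        _, matching = tetramer_ecd_features(structure, ("E", "F"), ("G", "H"), ss, params)
        # exhaustive: both matchings scored by summed terminal distance
        options = [[("E", "G"), ("F", "H")], [("E", "H"), ("F", "G")]]
        totals = [
            sum(ecd_terminal_distance(structure, a, b, ss) for a, b in m)
            for m in options
        ]
        assert matching == options[int(np.argmin(totals))]
        assert matching == [("E", "G"), ("F", "H")]

    def test_symmetric_tetramer_average_equals_either_pair(self):
        structure = _tetramer()
        ss = assign_secondary_structure(structure)
        params = ContactParams()
        averaged, matching = tetramer_ecd_features(structure, ("E", "F"), ("G", "H"), ss, params)
        pair_distance = ecd_terminal_distance(structure, *matching[0], ss)
        assert averaged.ecd_distance == pytest.approx(pair_distance)


class TestBuildFeatureTable:
    def _write_fixture_set(self, tmp_path, n=4):
        rows = []
        for i in range(n):
            ecd = make_ecd_complex(terminal_distance=20.0 + 5 * i, interface_gap=2.0, seed=i)
            dimer = make_tmd_dimer(DimerSpec(axis_separation=7.0 + i, crossing_angle=10.0 * i))
            ecd_path = tmp_path / f"ecd_{i}.pdb"
            tmd_path = tmp_path / f"tmd_{i}.pdb"
            write_structure(ecd, ecd_path)
            write_structure(dimer, tmd_path)
            rows.append(
                ComplexManifestRow(
                    design_id=f"d{i}",
                    structure_file=str(ecd_path),
                    receptor_chain_a="A",
                    receptor_chain_b="B",
                    ligand_chains=[],
                    complex_kind="dimer",
                    tmd_file_ab=str(tmd_path),
                )
            )
        return rows

    def test_empty_manifest_gives_empty_table(self):
        table = build_feature_table([])
        assert len(table) == 0
        assert "design_id" in table.columns

    def test_matches_row_by_row_oracle(self, tmp_path):
        from recepstruct.structure import read_structure

        rows = self._write_fixture_set(tmp_path)
        config = FeatureConfig()
        table = build_feature_table(rows, config).set_index("design_id")
        for row in rows:
            structure = read_structure(row.structure_file)
            ss = assign_secondary_structure(structure)
            expected_ecd = ecd_terminal_distance(structure, "A", "B", ss)
            expected_contacts = interchain_contacts(structure, "A", "B", config.contact_params).count
            got = table.loc[row.design_id]
            assert got["ecd_distance"] == pytest.approx(expected_ecd, abs=1e-3)
            assert got["ecd_contacts"] == pytest.approx(expected_contacts)

    def test_heterodimer_orderings_averaged(self, tmp_path):
        ab = make_tmd_dimer(DimerSpec(
            helix_a=HelixSpec(n_residues=21, chain_id="A"),
            helix_b=HelixSpec(n_residues=17, chain_id="B"),
            axis_separation=8.0, crossing_angle=20.0))
        ba = make_tmd_dimer(DimerSpec(
            helix_a=HelixSpec(n_residues=17, chain_id="A"),
            helix_b=HelixSpec(n_residues=21, chain_id="B"),
            axis_separation=8.0, crossing_angle=20.0))
        ecd = make_ecd_complex(terminal_distance=25.0, seed=0)
        paths = {}
        for name, structure in (("ab", ab), ("ba", ba), ("ecd", ecd)):
            paths[name] = tmp_path / f"{name}.pdb"
            write_structure(structure, paths[name])
        row = ComplexManifestRow(
            design_id="het", structure_file=str(paths["ecd"]),
            receptor_chain_a="A", receptor_chain_b="B",
            tmd_file_ab=str(paths["ab"]), tmd_file_ba=str(paths["ba"]),
        )
        config = FeatureConfig()
        table = build_feature_table([row], config)
        expected = average_ordered_tmd_features(
            measure_tmd_dimer(ab, config), measure_tmd_dimer(ba, config)
        )
        assert table.loc[0, "tmd_distance"] == pytest.approx(expected.tmd_distance, abs=1e-3)
        assert table.loc[0, "tmd_contacts"] == pytest.approx(expected.tmd_contacts)

    def test_failures_collected_with_design_id(self, tmp_path):
        rows = self._write_fixture_set(tmp_path, n=2)
        rows[1].structure_file = str(tmp_path / "missing.pdb")
        with pytest.raises(FeatureExtractionError) as excinfo:
            build_feature_table(rows)
        assert "d1" in excinfo.value.failures
        assert "d0" not in excinfo.value.failures

    def test_skip_errors_keeps_good_rows(self, tmp_path):
        rows = self._write_fixture_set(tmp_path, n=2)
        rows[1].structure_file = str(tmp_path / "missing.pdb")
        table = build_feature_table(rows, FeatureConfig(skip_errors=True))
        assert list(table["design_id"]) == ["d0"]

    def test_deterministic(self, tmp_path):
        rows = self._write_fixture_set(tmp_path)
        t1 = build_feature_table(rows)
        t2 = build_feature_table(rows)
        pd.testing.assert_frame_equal(t1, t2)


class TestManifestIO:
    def test_round_trip_csv(self, tmp_path):
        manifest_path = tmp_path / "manifest.csv"
        pdb = tmp_path / "s.pdb"
        write_structure(make_ecd_complex(25.0, seed=0), pdb)
        manifest_path.write_text(
            "design_id,structure_file,receptor_chain_a,receptor_chain_b,"
            "ligand_chains,complex_kind,tmd_file_ab,tmd_file_ba\n"
            f"d0,s.pdb,A,B,L,dimer,s.pdb,\n"
        )
        rows = read_manifest(manifest_path)
        assert rows[0].design_id == "d0"
        assert rows[0].ligand_chains == ["L"]
        assert rows[0].structure_file.endswith("s.pdb")

    def test_missing_column_rejected(self, tmp_path):
        manifest_path = tmp_path / "bad.csv"
        manifest_path.write_text("design_id,structure_file\nd0,s.pdb\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_manifest(manifest_path)

    def test_identical_receptor_chains_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ComplexManifestRow(
                design_id="x", structure_file="s.pdb",
                receptor_chain_a="A", receptor_chain_b="A",
            )

    def test_feature_table_round_trip(self, tmp_path):
        table = pd.DataFrame(
            {
                "design_id": ["a"],
                "ecd_distance": [1.0],
                "ecd_contacts": [2.0],
                "tmd_distance": [3.0],
                "tmd_contacts": [4.0],
                "tmd_crossing_angle": [5.0],
                "tmd_exit_angle": [6.0],
            }
        )
        path = tmp_path / "features.csv"
        write_feature_table(table, path)
        pd.testing.assert_frame_equal(read_feature_table(path), table)
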