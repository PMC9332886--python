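"""Descriptor grammar parsing and evaluator correctness."""

import numpy as np
import pytest

from pairqsar.descriptors import (
    DescriptorMatrix,
    avg_molweight,
    compute_matrix,
    count_exact_pairs,
    default_pool,
    evaluate,
    geometric_count,
    make_name,
    parse_descriptor,
    read_matrix,
    sum_charges_within,
    write_matrix,
)
from pairqsar.errors import InvalidDescriptorError, NoGeometryError
from pairqsar.molecule import embed_3d, parse_molecule
from pairqsar.synthetic import oracle_value

MODEL_DESCRIPTORS = [
    "fNringC6B",
    "lipo_ringS_8Bc",
    "famdNnotringO9B",
    "fdonsp3C2B",
    "fringCH3B",
    "fsp3CamdN4B",
    "com_sp2O_4A",
    "avg_molweight",
]


class TestGrammar:
    @pytest.mark.parametrize("name", MODEL_DESCRIPTORS)
    def test_round_trip(self, name):
        assert make_name(parse_descriptor(name)) == name

    @pytest.mark.parametrize("name,family", [
        ("fNringC6B", "exact_pair_count"),
        ("lipo_ringS_8Bc", "charge_sum_within"),
        ("com_sp2O_4A", "geometric_count"),
        ("avg_molweight", "global_property"),
    ])
    def test_families(self, name, family):
        assert parse_descriptor(name).family == family

    @pytest.mark.parametrize("bad", ["totally_unknown", "fXyzzyQ6B", "f0B", "lipo_ringS_0Bc"])
    def test_unknown_names_fail_loudly(self, bad):
        with pytest.raises(InvalidDescriptorError):
            parse_descriptor(bad)


class TestPairCounts:
    def test_absent_center_gives_zero(self):
        g = parse_molecule("C")
        assert count_exact_pairs(g, "N", "ringC", 6) == 0

    def test_amine_to_ring_carbon_at_six_bonds(self):
        g = parse_molecule("NCCCCCC1CCCCC1")
        assert count_exact_pairs(g, "N", "ringC", 6) == 1

    def test_benzene_ring_carbon_to_meta_hydrogens(self):
        g = parse_molecule("c1ccccc1")
        assert count_exact_pairs(g, "ringC", "H", 3) == 12

    def test_invalid_distance(self):
        g = parse_molecule("C")
        with pytest.raises(InvalidDescriptorError):
            count_exact_pairs(g, "N", "ringC", 0)

    def test_matches_bfs_oracle_on_suite(self, toy_suite):
        for smi, g, golden in toy_suite:
            for name, expected in golden.items():
                assert evaluate(g, parse_descriptor(name)) == pytest.approx(
                    expected
                ), f"{name} on {smi}"

    def test_pair_sum_identity_disjoint_flags(self, toy_suite):
        # summing exact counts over every distance recovers |C| x |T|
        # when center and target classes are disjoint
        for smi, g, _ in toy_suite:
            n_c = int(g.flag_mask("N").sum())
            n_t = int(g.flag_mask("H").sum())
            if n_c == 0:
                continue
            diameter = int(g.dist.max())
            total = sum(
                count_exact_pairs(g, "N", "H", n) for n in range(1, diameter + 1)
            )
            assert total == n_c * n_t


class TestChargeSums:
    def test_sulfur_free_molecule_is_zero(self):
        g = parse_molecule("c1ccccc1")
        assert sum_charges_within(g, "ringS", "lipo", 8) == 0.0

    def test_thiophene_equals_oracle(self, toy_by_smiles):
        g, golden = toy_by_smiles["c1ccsc1"]
        assert sum_charges_within(g, "ringS", "lipo", 8) == pytest.approx(
            golden["lipo_ringS_8Bc"]
        )

    def test_contributing_set_grows_with_radius(self, toy_by_smiles):
        # the n=1 contributor set is a subset of the n=8 set: for
        # thiophene only the two alpha carbons lie one bond from S
        g, _ = toy_by_smiles["c1ccsc1"]
        s_idx = next(i for i, a in enumerate(g.atoms) if a.element == "S")
        within1 = {
            i
            for i in range(g.n_atoms)
            if 1 <= g.dist[s_idx, i] <= 1 and "lipophilic" in g.atoms[i].flags
        }
        within8 = {
            i
            for i in range(g.n_atoms)
            if 1 <= g.dist[s_idx, i] <= 8 and "lipophilic" in g.atoms[i].flags
        }
        assert len(within1) == 2
        assert within1 < within8


class TestGeometric:
    def test_no_sp2_oxygen_gives_zero(self):
        g = parse_molecule("CC")
        embed_3d(g, seed=1)
        assert geometric_count(g, "sp2O", 4.0) == 0

    def test_formaldehyde_oxygen_near_com(self):
        g = parse_molecule("C=O")
        embed_3d(g, seed=1)
        assert geometric_count(g, "sp2O", 4.0) == 1

    def test_zero_radius_empty_ball(self):
        g = parse_molecule("C=O")
        embed_3d(g, seed=1)
        assert geometric_count(g, "sp2O", 0.0) == 0

    def test_missing_geometry_raises(self):
        g = parse_molecule("C=O")
        with pytest.raises(NoGeometryError):
            geometric_count(g, "sp2O", 4.0)


class TestGlobal:
    def test_methane(self):
        g = parse_molecule("C")
        assert avg_molweight(g) == pytest.approx(16.043 / 5, abs=2e-3)

    def test_molecular_hydrogen(self):
        g = parse_molecule("[H][H]")
        assert avg_molweight(g) == pytest.approx(1.008, abs=1e-3)

    def test_order_invariant(self):
        assert avg_molweight(parse_molecule("OCC")) == pytest.approx(
            avg_molweight(parse_molecule("CCO"))
        )


class TestMatrix:
    def test_zero_specs(self):
        mols = [parse_molecule("C")]
        m = compute_matrix(mols, [])
        assert m.values.shape == (1, 0)

    def test_duplicate_spec_duplicates_column(self):
        mols = [parse_molecule("OCC"), parse_molecule("CC(N)=O")]
        m = compute_matrix(mols, ["fdonsp3C2B", "fdonsp3C2B"])
        assert np.array_equal(m.values[:, 0], m.values[:, 1])

    def test_matches_single_descriptor_calls(self, toy_suite):
        names = ["fNringC6B", "fdonsp3C2B", "avg_molweight"]
        mols = [g for _, g, _ in toy_suite[:3]]
        m = compute_matrix(mols, names)
        for i, g in enumerate(mols):
            for j, name in enumerate(names):
                assert m.values[i, j] == pytest.approx(
                    evaluate(g, parse_descriptor(name))
                )

    def test_counts_invariant_under_renumbering(self):
        m1 = compute_matrix([parse_molecule("OCC")], ["fdonsp3C2B"])
        m2 = compute_matrix([parse_molecule("C(O)C")], ["fdonsp3C2B"])
        assert np.array_equal(m1.values, m2.values)

    def test_geometric_specs_embed_lazily(self):
        g = parse_molecule("C=O")  # no coordinates yet
        m = compute_matrix([g], ["com_sp2O_4A"])
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == 1

    def test_pool_scale(self):
        pool = default_pool()
        assert 1000 <= len(pool) <= 2500
        names = [s.name for s in pool]
        assert len(set(names)) == len(names)

    def test_tsv_round_trip(self, tmp_path):
        mols = [parse_molecule("OCC"), parse_molecule("CC(N)=O")]
        m = compute_matrix(mols, ["fdonsp3C2B", "avg_molweight"], compound_ids=["a", "b"])
        path = tmp_path / "m.tsv"
        write_matrix(m, path)
        back = read_matrix(path)
        assert back.compound_ids == ["a", "b"]
        assert back.descriptor_names == m.descriptor_names
        assert np.allclose(back.values, m.values)

    def test_oracle_covers_model_descriptors(self, toy_by_smiles):
        # an independent spot check of the oracle itself: the amide
        # nitrogen of N-methylbenzamide sees no non-ring O at 9 bonds
        g, golden = toy_by_smiles["O=C(NC)c1ccccc1"]
        assert golden["famdNnotringO9B"] == 0
        assert oracle_value(g, "fsp3CamdN4B") == golden["fsp3CamdN4B"]
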