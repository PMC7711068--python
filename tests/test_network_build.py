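"""The four network builders and the edge-weight normalisation rule."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from anca import (
    ContractViolation,
    EmptyNetworkError,
    MIN_EDGE_WEIGHT,
    NodeWeightSpec,
    build_aacen,
    build_calpha,
    build_eacen,
    build_nacen,
    normalize_edge_weights,
)
from anca.energy import LABELS_60, EnergyTable
from anca.fixtures import (
    make_nucleic,
    make_peptide,
    make_protein_rna_complex,
    make_toy_energy_table,
    make_two_chain_complex,
)
from anca.structure_io import GRANTHAM_POLARITY
from helpers import annotated, parse_text


def _uniform_table(value):
    return EnergyTable(LABELS_60, np.full((60, 60), float(value)),
                       provenance=f"uniform {value}")


def edge_ids(net):
    return {(e.node_i, e.node_j) for e in net.edges}


def check_network_invariants(net):
    """AM symmetric, zero diagonal, consistent with the edge list."""
    labels, am = net.adjacency()
    assert np.allclose(am, am.T)
    assert np.allclose(np.diag(am), 0.0)
    pos = {l: k for k, l in enumerate(labels)}
    assert len(pos) == net.n
    nz = {(min(i, j), max(i, j)) for i, j in zip(*np.nonzero(am))}
    from_edges = {
        tuple(sorted((pos[e.node_i], pos[e.node_j]))) for e in net.edges
    }
    assert nz == from_edges
    for e in net.edges:
        assert am[pos[e.node_i], pos[e.node_j]] == e.weight


class TestAACEN:
    def test_negative_energy_makes_edge(self):
        model = annotated(make_peptide("helix_peptide", 5))
        net = build_aacen(model, _uniform_table(-1.2))
        assert net.m > 0
        _, am = net.adjacency()
        assert set(np.unique(am)) <= {0.0, 1.0}

    def test_positive_energy_no_edge(self):
        model = annotated(make_peptide("helix_peptide", 5))
        assert build_aacen(model, _uniform_table(0.3)).m == 0

    def test_zero_energy_no_edge_strict_inequality(self):
        model = annotated(make_peptide("helix_peptide", 5))
        assert build_aacen(model, _uniform_table(0.0)).m == 0

    def test_energy_threshold_moves_boundary(self):
        model = annotated(make_peptide("helix_peptide", 5))
        assert build_aacen(model, _uniform_table(0.3), e_thresh=0.5).m > 0

    def test_nucleic_only_structure_is_empty_network(self):
        model = parse_text(make_nucleic("rna_strand", 3))
        with pytest.raises(EmptyNetworkError):
            build_aacen(model, _uniform_table(-1.0))

    def test_requires_secondary_structure(self):
        model = parse_text(make_peptide("helix_peptide", 5))
        with pytest.raises(ContractViolation):
            build_aacen(model, _uniform_table(-1.0))


class TestNACEN:
    def test_edge_set_identical_to_aacen(self, toy_table):
        model = annotated(make_peptide("helix_peptide", 14))
        aacen = build_aacen(model, toy_table)
        nacen = build_nacen(model, toy_table,
                            weight_spec=NodeWeightSpec("polarity"))
        assert edge_ids(aacen) == edge_ids(nacen)

    def test_polarity_weights_attached(self, toy_table):
        model = annotated(make_peptide("helix_peptide", 10))
        net = build_nacen(model, toy_table,
                          weight_spec=NodeWeightSpec("polarity"))
        for node in net.nodes:
            assert node.weight == GRANTHAM_POLARITY[node.label]
            assert net.node_weights[node.node_id] == node.weight

    def test_custom_uniform_weights(self, toy_table, tmp_path):
        model = annotated(make_peptide("helix_peptide", 8))
        path = tmp_path / "w.txt"
        path.write_text("".join(
            f"{r.chain_id} {r.seq_pos} 1.0\n" for r in model.residues()
        ))
        net = build_nacen(
            model, toy_table,
            weight_spec=NodeWeightSpec("custom_file", file_path=str(path)),
        )
        assert set(net.node_weights.values()) == {1.0}


class TestNormalizeEdgeWeights:
    def test_hand_evaluated_example(self):
        assert normalize_edge_weights([-1.0, -2.0, -3.0]) == \
            [MIN_EDGE_WEIGHT, 0.5, 1.0]

    def test_degenerate_range(self):
        assert normalize_edge_weights([-2.0, -2.0]) == \
            [MIN_EDGE_WEIGHT, MIN_EDGE_WEIGHT]

    def test_single_edge_is_the_minimum(self):
        assert normalize_edge_weights([-5.0]) == [MIN_EDGE_WEIGHT]

    def test_rejects_non_negative(self):
        with pytest.raises(ContractViolation):
            normalize_edge_weights([-1.0, 0.0])

    def test_rejects_empty(self):
        with pytest.raises(ContractViolation):
            normalize_edge_weights([])

    @given(st.lists(st.floats(min_value=-50.0, max_value=-1e-3),
                    min_size=2, max_size=30, unique=True))
    def test_extrema_rule(self, energies):
        weights = normalize_edge_weights(energies)
        mags = [abs(e) for e in energies]
        assert weights[mags.index(min(mags))] == MIN_EDGE_WEIGHT
        assert weights[mags.index(max(mags))] == 1.0
        assert all(0.0 <= w <= 1.0 for w in weights)


class TestEACEN:
    def test_three_edge_adjacency_values(self):
        # three collinear CA-only residues: contacts (1,3),(1,4)... build
        # a chain whose realised energies are -1/-2/-3 via a crafted table
        from anca.structure_io import Chain, StructureModel
        from anca.structure_io import Residue as R
        from anca.structure_io import Atom

        def residue(pos, name, xyz):
            r = R("A", pos, "", name, "amino_acid",
                  [Atom("CA", "C", np.asarray(xyz, float))])
            r.ss_state = "coil"
            return r

        chain = Chain("A", [
            residue(1, "ALA", (0, 0, 0)),
            residue(3, "GLY", (5, 0, 0)),
            residue(5, "LEU", (5, 5, 0)),
        ])
        model = StructureModel("toy", [chain])
        idx = {lab: k for k, lab in enumerate(LABELS_60)}
        mat = np.zeros((60, 60))

        def put(a, b, v):
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = v

        put("ALA_C", "GLY_C", -1.0)
        put("GLY_C", "LEU_C", -2.0)
        put("ALA_C", "LEU_C", -3.0)
        table = EnergyTable(LABELS_60, mat, provenance="crafted")
        net = build_eacen(model, table, d_cutoff=8.0)
        assert net.m == 3
        by_energy = {e.energy: e.weight for e in net.edges}
        assert by_energy == {-1.0: MIN_EDGE_WEIGHT, -2.0: 0.5, -3.0: 1.0}
        labels, am = net.adjacency()
        assert np.allclose(am, am.T)
        assert sorted(am[np.triu_indices(3, 1)]) == \
            [MIN_EDGE_WEIGHT, 0.5, 1.0]

    def test_skeleton_equals_aacen(self, toy_table):
        model = annotated(make_two_chain_complex())
        assert edge_ids(build_eacen(model, toy_table)) == \
            edge_ids(build_aacen(model, toy_table))

    def test_weight_extrema_on_fixture(self, negative_table):
        model = annotated(make_peptide("helix_peptide", 12))
        net = build_eacen(model, negative_table)
        weights = [e.weight for e in net.edges]
        energies = [abs(e.energy) for e in net.edges]
        assert weights[int(np.argmin(energies))] == MIN_EDGE_WEIGHT
        assert weights[int(np.argmax(energies))] == 1.0
        assert all(0.0 <= w <= 1.0 for w in weights)

    def test_rejects_positive_threshold(self, toy_table):
        model = annotated(make_peptide("helix_peptide", 6))
        with pytest.raises(ContractViolation):
            build_eacen(model, toy_table, e_thresh=0.5)


class TestCAlpha:
    def test_protein_only_node_count(self):
        model = parse_text(make_peptide("helix_peptide", 9))
        assert build_calpha(model).n == 9

    def test_rna_three_nodes_per_nucleotide(self):
        model = parse_text(make_nucleic("rna_strand", 3))
        net = build_calpha(model)
        assert net.n == 9
        assert sorted({n.node_kind for n in net.nodes}) == \
            ["C2", "C4*", "P"]

    def test_truncated_5prime_phosphate(self):
        model = parse_text(
            make_nucleic("rna_strand", 3, drop_5prime_p=True)
        )
        assert build_calpha(model).n == 8

    def test_strict_distance_threshold(self):
        from anca.structure_io import Atom, Chain, StructureModel
        from anca.structure_io import Residue as R

        def model_with_gap(gap):
            chain = Chain("A", [
                R("A", 1, "", "ALA", "amino_acid",
                  [Atom("CA", "C", np.zeros(3))]),
                R("A", 9, "", "GLY", "amino_acid",
                  [Atom("CA", "C", np.array([gap, 0.0, 0.0]))]),
            ])
            return StructureModel("gap", [chain])

        assert build_calpha(model_with_gap(6.9), 7.0).m == 1
        assert build_calpha(model_with_gap(7.1), 7.0).m == 0
        assert build_calpha(model_with_gap(7.0), 7.0).m == 0

    def test_complex_has_intermolecular_edges(self):
        model = parse_text(make_protein_rna_complex())
        net = build_calpha(model)
        inter = [
            e for e in net.edges
            if net.node(e.node_i).chain_id != net.node(e.node_j).chain_id
        ]
        assert inter and all(e.long_range for e in inter)

    def test_rigid_motion_invariance(self):
        text = make_protein_rna_complex()
        model = parse_text(text)
        moved = parse_text(text)
        # rotate 70° about z then translate
        theta = np.radians(70.0)
        rot = np.array([
            [np.cos(theta), -np.sin(theta), 0],
            [np.sin(theta), np.cos(theta), 0],
            [0, 0, 1],
        ])
        shift = np.array([11.0, -4.0, 23.0])
        for res in moved.residues():
            for atom in res.atoms:
                atom.xyz = rot @ atom.xyz + shift
        assert edge_ids(build_calpha(model)) == \
            edge_ids(build_calpha(moved))


class TestSharedInvariants:
    @pytest.mark.parametrize("seed", range(10))
    def test_builders_share_edge_set_and_satisfy_am_invariants(self, seed):
        length = 6 + (seed % 7)
        model = annotated(make_peptide("helix_peptide", length, seed=seed,
                                       jitter=0.15))
        table = make_toy_energy_table(seed)
        aacen = build_aacen(model, table)
        nacen = build_nacen(model, table,
                            weight_spec=NodeWeightSpec("mass"))
        eacen = build_eacen(model, table)
        assert edge_ids(aacen) == edge_ids(nacen) == edge_ids(eacen)
        for net in (aacen, nacen, eacen, build_calpha(model)):
            check_network_invariants(net)

    @pytest.mark.parametrize("seed", range(10, 20))
    def test_complex_fixtures_satisfy_am_invariants(self, seed):
        model = annotated(make_two_chain_complex(seed=seed, jitter=0.2))
        table = make_toy_energy_table(seed)
        for net in (build_aacen(model, table), build_calpha(model)):
            check_network_invariants(net)
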