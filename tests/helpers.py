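"""Shared test helpers (kept importable from every test module)."""

import io

from anca import AANetwork, Edge, ResidueNode, assign_secondary_structure, \
    parse_structure


def parse_text(pdb_text: str):
    """Parse PDB-format text into a StructureModel."""
    return parse_structure(io.StringIO(pdb_text))


def annotated(pdb_text: str):
    """Parse + assign secondary structure with the dihedral classifier."""
    return assign_secondary_structure(parse_text(pdb_text),
                                      method="dihedral")


def net_from_graph(n_nodes, edges, model_type="CALPHA", weights=None,
                   node_weights=None):
    """Wrap an abstract graph as an AANetwork (nodes A:1..A:n).

    ``weights``: per-edge weights aligned with ``edges``; ``node_weights``:
    list of per-node weights (turns the wrapper into a NACEN).
    """
    nodes = [
        ResidueNode(
            node_id=f"A:{i + 1}", label="ALA", node_kind="amino_acid",
            chain_id="A", seq_pos=i + 1,
            weight=None if node_weights is None else node_weights[i],
        )
        for i in range(n_nodes)
    ]
    edge_objs = [
        Edge(f"A:{a + 1}", f"A:{b + 1}",
             1.0 if weights is None else weights[k], False)
        for k, (a, b) in enumerate(edges)
    ]
    nw = None
    if node_weights is not None:
        model_type = "NACEN"
        nw = {f"A:{i + 1}": node_weights[i] for i in range(n_nodes)}
    return AANetwork(model_type, nodes, edge_objs, node_weights=nw)


def node_index_map(net):
    """node_id -> 0-based index in net node order."""
    return {n.node_id: i for i, n in enumerate(net.nodes)}
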