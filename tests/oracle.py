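"""Independent brute-force graph oracles used only by the tests.

Molecules and SMARTS queries are converted to labeled networkx graphs and
compared by exhaustive subgraph monomorphism / common-edge-subset
enumeration, with no RDKit substructure or MCS machinery involved, so the
oracles stay independent of the code paths they check.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
from networkx.algorithms.isomorphism import GraphMatcher
from rdkit import Chem

UNSPECIFIED = Chem.BondType.UNSPECIFIED


def mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    graph = nx.Graph()
    for atom in mol.GetAtoms():
        graph.add_node(atom.GetIdx(), z=atom.GetAtomicNum())
    for bond in mol.GetBonds():
        graph.add_edge(
            bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order=bond.GetBondType()
        )
    return graph


def _node_match(target_attrs, query_attrs) -> bool:
    return target_attrs["z"] == query_attrs["z"]


def _edge_match(target_attrs, query_attrs) -> bool:
    q = query_attrs["order"]
    t = target_attrs["order"]
    if q == UNSPECIFIED:  # SMARTS default bond: single or aromatic
        return t in (Chem.BondType.SINGLE, Chem.BondType.AROMATIC)
    return t == q


def has_substructure(target: Chem.Mol, query: Chem.Mol) -> bool:
    """Exhaustive subgraph-monomorphism check: does the query pattern
    (a mol parsed from SMARTS or SMILES) occur in the target?"""
    matcher = GraphMatcher(
        mol_to_graph(target),
        mol_to_graph(query),
        node_match=_node_match,
        edge_match=_edge_match,
    )
    return matcher.subgraph_is_monomorphic()


def _exact_edge_match(target_attrs, query_attrs) -> bool:
    return target_attrs["order"] == query_attrs["order"]


def mcs_size(mol_a: Chem.Mol, mol_b: Chem.Mol) -> int:
    """Heavy atoms of the maximum common connected substructure under
    element identity and exact bond-order (aromatic-only-aromatic)
    matching, by enumerating connected edge subsets of the smaller graph.

    Exponential in bond count; intended for molecules of <= ~12 bonds.
    """
    graph_a, graph_b = mol_to_graph(mol_a), mol_to_graph(mol_b)
    if graph_a.number_of_edges() > graph_b.number_of_edges():
        graph_a, graph_b = graph_b, graph_a
    edges = list(graph_a.edges)
    best = 0
    elements_a = {d["z"] for _, d in graph_a.nodes(data=True)}
    elements_b = {d["z"] for _, d in graph_b.nodes(data=True)}
    if elements_a & elements_b:
        best = 1
    for size in range(len(edges), 0, -1):
        if size + 1 <= best:
            break  # a size-k edge set spans at most k+1 atoms
        for subset in combinations(edges, size):
            sub = graph_a.edge_subgraph(subset)
            if sub.number_of_nodes() <= best:
                continue
            if not nx.is_connected(sub):
                continue
            matcher = GraphMatcher(
                graph_b, sub, node_match=_node_match, edge_match=_exact_edge_match
            )
            if matcher.subgraph_is_monomorphic():
                best = sub.number_of_nodes()
    return best


def verify_match(target: Chem.Mol, query: Chem.Mol, matched_atoms) -> bool:
    """Check a recorded atom mapping: query atom i maps to target atom
    matched_atoms[i] with matching element and bonds."""
    if len(matched_atoms) != query.GetNumAtoms():
        return False
    for atom in query.GetAtoms():
        if target.GetAtomWithIdx(matched_atoms[atom.GetIdx()]).GetAtomicNum() != atom.GetAtomicNum():
            return False
    for bond in query.GetBonds():
        i = matched_atoms[bond.GetBeginAtomIdx()]
        j = matched_atoms[bond.GetEndAtomIdx()]
        target_bond = target.GetBondBetweenAtoms(i, j)
        if target_bond is None:
            return False
        if not _edge_match(
            {"order": target_bond.GetBondType()}, {"order": bond.GetBondType()}
        ):
            return False
    return True
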