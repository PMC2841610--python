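import math

import numpy as np
import pytest

from helixpack.contact_labelling import (
    ContactDefinition,
    ContactSet,
    InteractionGraph,
    label_lipid_exposed,
    observed_helix_interactions,
    residue_contacts,
)
from helixpack.io_formats import (
    Atom,
    HelixSpan,
    LipidFractionTable,
    ProteinRecord,
    StructureCoords,
    Topology,
    ValidationError,
)
from helixpack.synthetic_fixtures import BundleSpec, brute_force_contacts, make_bundle

from conftest import random_bundle_spec


class TestLipidLabels:
    def test_strictly_greater_than_threshold(self):
        topo = Topology(helices=(HelixSpan(5, 6, 1),))
        table = LipidFractionTable(fractions={5: 0.51, 6: 0.50})
        labels = label_lipid_exposed(table, topo)
        assert labels == {5: True, 6: False}

    def test_non_tm_residues_excluded(self):
        topo = Topology(helices=(HelixSpan(5, 6, 1),))
        table = LipidFractionTable(fractions={5: 0.9, 6: 0.1, 7: 0.99})
        assert set(label_lipid_exposed(table, topo)) == {5, 6}

    def test_missing_fraction_listed(self):
        topo = Topology(helices=(HelixSpan(5, 7, 1),))
        table = LipidFractionTable(fractions={5: 0.9})
        with pytest.raises(ValidationError, match=r"\[6, 7\]"):
            label_lipid_exposed(table, topo)


def _two_residue_structure(d: float, letters="AA"):
    """Two single-atom-chain residues on different helices, C-beta
    atoms ``d`` Angstrom apart."""
    res = {
        1: (Atom("CA", "C", 0, 0, 0), Atom("CB", "C", 0, 0, 1.5)),
        5: (Atom("CA", "C", d, 0, 0), Atom("CB", "C", d, 0, 1.5)),
    }
    topo = Topology(helices=(HelixSpan(1, 1, 1), HelixSpan(5, 5, 2)))
    seq = letters[0] + "GGG" + letters[1]
    return StructureCoords(residues=res), topo, ProteinRecord(id="t", sequence=seq)


class TestDefinitionOne:
    @pytest.mark.parametrize("d,expect", [(7.9, True), (8.0, True), (8.1, False)])
    def test_cbeta_cutoff_boundary(self, d, expect):
        coords, topo, rec = _two_residue_structure(d)
        cs = residue_contacts(coords, topo, ContactDefinition(kind=1), rec)
        assert ((1, 5) in cs) is expect

    def test_glycine_uses_calpha(self):
        # C-beta atoms 7.9 apart, C-alpha 9.0 apart: a Gly-Ala pair must
        # use Gly's C-alpha and fall outside the cutoff.
        res = {
            1: (Atom("CA", "C", 0, 0, 0), Atom("CB", "C", 1.1, 0, 0)),
            5: (Atom("CA", "C", 9.0, 0, 0), Atom("CB", "C", 9.0, 0, 0)),
        }
        topo = Topology(helices=(HelixSpan(1, 1, 1), HelixSpan(5, 5, 2)))
        gly = ProteinRecord(id="g", sequence="GGGGA")
        ala = ProteinRecord(id="a", sequence="AGGGA")
        coords = StructureCoords(residues=res)
        defn = ContactDefinition(kind=1)
        assert (1, 5) in residue_contacts(coords, topo, defn, ala)  # CB at 7.9
        assert (1, 5) not in residue_contacts(coords, topo, defn, gly)  # CA at 9.0


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind", [1, 2, 3])
    def test_matches_brute_force_on_random_bundles(self, kind):
        rng = np.random.default_rng(42)
        for _ in range(10):
            b = make_bundle(random_bundle_spec(rng))
            defn = ContactDefinition(kind=kind)
            fast = residue_contacts(b.coords, b.topology, defn, b.record)
            slow = brute_force_contacts(b.coords, b.topology, defn, b.record)
            assert fast.pairs == slow.pairs

    def test_rigid_motion_invariance(self, two_helix_bundle):
        b = two_helix_bundle
        defn = ContactDefinition(kind=3)
        before = residue_contacts(b.coords, b.topology, defn, b.record)
        theta = 0.83
        R = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0],
                [math.sin(theta), math.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([13.0, -4.0, 7.5])
        moved = {
            idx: tuple(
                Atom(a.name, a.element, *(R @ a.xyz + shift)) for a in atoms
            )
            for idx, atoms in b.coords.residues.items()
        }
        after = residue_contacts(
            StructureCoords(residues=moved), b.topology, defn, b.record
        )
        assert before.pairs == after.pairs

    def test_vdw_contacts_are_a_subset_of_heavy_atom_contacts(self):
        # with heavy elements (r <= 1.8 A) the van der Waals criterion
        # r1 + r2 + 0.6 <= 4.2 A is always stricter than the 5.5 A
        # heavy-atom cutoff, so definition 2 contacts nest inside
        # definition 3
        rng = np.random.default_rng(9)
        for _ in range(5):
            b = make_bundle(random_bundle_spec(rng))
            d3 = residue_contacts(b.coords, b.topology, ContactDefinition(kind=3), b.record)
            d2 = residue_contacts(b.coords, b.topology, ContactDefinition(kind=2), b.record)
            assert d2.pairs <= d3.pairs


class TestHelixInteractions:
    def test_single_contact_single_edge(self):
        topo = Topology(helices=(HelixSpan(5, 15, 1), HelixSpan(45, 55, 2)))
        cs = ContactSet(pairs=frozenset({(10, 50)}), helix_of={10: 1, 50: 2})
        g = observed_helix_interactions(cs, topo)
        assert g.edges == frozenset({(1, 2)})

    def test_empty_contacts_edgeless(self):
        topo = Topology(
            helices=(HelixSpan(1, 5, 1), HelixSpan(10, 14, 2), HelixSpan(20, 24, 3))
        )
        cs = ContactSet(pairs=frozenset(), helix_of={})
        g = observed_helix_interactions(cs, topo)
        assert g.n == 3 and not g.edges

    def test_many_contacts_one_edge(self):
        topo = Topology(
            helices=(
                HelixSpan(1, 5, 1),
                HelixSpan(10, 60, 2),
                HelixSpan(70, 120, 3),
            )
        )
        helix_of = {p: 2 for p in range(10, 61)}
        helix_of.update({p: 3 for p in range(70, 121)})
        pairs = frozenset((i, i + 60) for i in range(10, 61))
        g = observed_helix_interactions(
            ContactSet(pairs=pairs, helix_of=helix_of), topo
        )
        assert g.edges == frozenset({(2, 3)})


class TestInteractionGraph:
    def test_complement_partitions_pairs(self):
        g = InteractionGraph(n=4, edges=frozenset({(1, 2), (3, 4)}))
        comp = g.complement()
        assert not (g.edges & comp.edges)
        assert len(g.edges) + len(comp.edges) == 6

    def test_invalid_edge_rejected(self):
        with pytest.raises(ValidationError):
            InteractionGraph(n=3, edges=frozenset({(2, 2)}))
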