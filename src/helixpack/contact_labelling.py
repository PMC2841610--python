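"""Ground-truth labels from coordinates and lipid-fraction tables.

Three geometric contact definitions are supported for labelling
inter-helix residue pairs:

1. C-beta/C-beta distance of at most 8 A (C-alpha for glycine);
2. any atom pair closer than the sum of the two van der Waals radii
   plus a 0.6 A margin;
3. any heavy-atom (backbone or side chain, non-hydrogen) pair closer
   than 5.5 A.

Two helices are taken to interact when at least one residue from each
is in contact. Lipid exposure labels come from per-residue fractions of
simulation time spent in lipid contact: exposed iff fraction > 0.5
(strict).

Definition 1 uses "at most" (a maximal distance of 8 A), definitions
2 and 3 use strict "less than"; both conventions are intentional and
fixed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.spatial import cKDTree

from helixpack.io_formats import (
    LipidFractionTable,
    ProteinRecord,
    StructureCoords,
    Topology,
    ValidationError,
)

#: Bondi-style van der Waals radii in Angstrom.
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}


@dataclass(frozen=True)
class ContactDefinition:
    """Geometric rule declaring two residues to be in contact."""

    kind: int
    cbeta_cutoff: float = 8.0
    vdw_margin: float = 0.6
    heavy_cutoff: float = 5.5
    vdw_radii: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VDW_RADII)
    )

    def __post_init__(self) -> None:
        if self.kind not in (1, 2, 3):
            raise ValueError(f"contact definition kind must be 1, 2 or 3, got {self.kind}")
        if min(self.cbeta_cutoff, self.vdw_margin, self.heavy_cutoff) <= 0:
            raise ValueError("contact cutoffs must be strictly positive")

    def radius(self, element: str) -> float:
        return self.vdw_radii.get(element.upper(), 1.70)


@dataclass(frozen=True)
class ContactSet:
    """Inter-helix residue contacts: pairs (i, j), i < j, with the
    helix index of each residue."""

    pairs: frozenset[tuple[int, int]]
    helix_of: Mapping[int, int]

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if i >= j:
                raise ValidationError(f"contact pair ({i}, {j}) not ordered i < j")
            if self.helix_of.get(i) is None or self.helix_of.get(j) is None:
                raise ValidationError(f"contact pair ({i}, {j}) outside TM helices")
            if self.helix_of[i] == self.helix_of[j]:
                raise ValidationError(f"contact pair ({i}, {j}) within one helix")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


@dataclass(frozen=True)
class InteractionGraph:
    """Undirected helix-interaction graph on vertices 1..n."""

    n: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if not (1 <= a < b <= self.n):
                raise ValidationError(f"edge ({a}, {b}) invalid for n={self.n}")

    def has_edge(self, a: int, b: int) -> bool:
        return (min(a, b), max(a, b)) in self.edges

    def neighbours(self, v: int) -> frozenset[int]:
        return frozenset(
            b if a == v else a for a, b in self.edges if v in (a, b)
        )

    def complement(self) -> "InteractionGraph":
        all_pairs = {
            (a, b) for a in range(1, self.n + 1) for b in range(a + 1, self.n + 1)
        }
        return InteractionGraph(n=self.n, edges=frozenset(all_pairs - self.edges))


def label_lipid_exposed(
    fractions: LipidFractionTable,
    topology: Topology,
    threshold: float = 0.5,
) -> dict[int, bool]:
    """Label each TM residue lipid-exposed iff its fraction of
    simulation time in lipid contact is strictly greater than
    ``threshold`` (default 0.5). Residues outside TM helices are
    excluded; a TM residue with no fraction is an error."""
    labels: dict[int, bool] = {}
    missing: list[int] = []
    for pos in topology.tm_residues():
        frac = fractions.get(pos)
        if frac is None:
            missing.append(pos)
        else:
            labels[pos] = frac > threshold
    if missing:
        raise ValidationError(
            f"missing lipid fractions for TM residues: {missing}"
        )
    return labels


def _contact_point(
    coords: StructureCoords, pos: int, residue_letter: str | None
) -> np.ndarray | None:
    """Representative point for definition 1: C-beta, C-alpha for
    glycine, C-alpha fallback when C-beta is absent."""
    use_ca = residue_letter == "G"
    atom = None if use_ca else coords.atom(pos, "CB")
    if atom is None:
        atom = coords.atom(pos, "CA")
        if atom is not None and not use_ca and residue_letter is not None:
            warnings.warn(
                f"residue {pos}: no C-beta atom, falling back to C-alpha",
                stacklevel=2,
            )
    return None if atom is None else atom.xyz


def residue_contacts(
    coords: StructureCoords,
    topology: Topology,
    definition: ContactDefinition,
    record: ProteinRecord | None = None,
) -> ContactSet:
    """All inter-helix residue pairs in contact under ``definition``.

    Only residues inside TM helix spans enter the search; loop and
    re-entrant residues never appear in the output. Neighbour search
    uses a k-d tree over the relevant atoms.
    """
    helix_of = {p: topology.helix_of(p) for p in topology.tm_residues()}
    seq = record.sequence if record is not None else None
    excluded = set()
    if seq is not None:
        excluded = {
            p for p in helix_of if seq[p - 1] not in "ACDEFGHIKLMNPQRSTVWY"
        }
    tm_with_coords = [
        p for p in helix_of if p in coords.residues and p not in excluded
    ]
    if not tm_with_coords:
        raise ValidationError("no TM residues with coordinates")

    pairs: set[tuple[int, int]] = set()
    if definition.kind == 1:
        points, owners = [], []
        for p in tm_with_coords:
            letter = seq[p - 1] if seq is not None else None
            pt = _contact_point(coords, p, letter)
            if pt is not None:
                points.append(pt)
                owners.append(p)
        tree = cKDTree(np.asarray(points))
        for a, b in tree.query_pairs(definition.cbeta_cutoff):  # inclusive cutoff
            i, j = owners[a], owners[b]
            if helix_of[i] != helix_of[j]:
                pairs.add((min(i, j), max(i, j)))
    else:
        points, owners, elements = [], [], []
        for p in tm_with_coords:
            for atom in coords.heavy_atoms(p):
                points.append(atom.xyz)
                owners.append(p)
                elements.append(atom.element.upper())
        pts = np.asarray(points)
        tree = cKDTree(pts)
        if definition.kind == 3:
            reach = definition.heavy_cutoff
        else:
            rmax = max(definition.radius(e) for e in set(elements))
            reach = 2 * rmax + definition.vdw_margin
        for a, b in tree.query_pairs(reach):
            i, j = owners[a], owners[b]
            if helix_of[i] == helix_of[j]:
                continue
            d = float(np.linalg.norm(pts[a] - pts[b]))
            if definition.kind == 3:
                hit = d < definition.heavy_cutoff
            else:
                cut = (
                    definition.radius(elements[a])
                    + definition.radius(elements[b])
                    + definition.vdw_margin
                )
                hit = d < cut
            if hit:
                pairs.add((min(i, j), max(i, j)))
    return ContactSet(pairs=frozenset(pairs), helix_of=helix_of)


def observed_helix_interactions(
    contacts: ContactSet, topology: Topology
) -> InteractionGraph:
    """Helix pairs with at least one residue contact between them."""
    edges = {
        tuple(sorted((contacts.helix_of[i], contacts.helix_of[j])))
        for i, j in contacts.pairs
    }
    return InteractionGraph(n=topology.n, edges=frozenset(edges))
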