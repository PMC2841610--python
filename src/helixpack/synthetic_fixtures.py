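"""Synthetic inputs: idealized helix bundles with known ground truth.

Every input the pipeline consumes can be generated here at desk scale:
ideal alpha-helix bundles (rise 1.5 A per residue, twist 100 deg,
backbone N/CA/C/O plus a C-beta and one extended side-chain
pseudo-atom) arranged on known 2-D centers, with true contacts
computed by a brute-force all-pairs distance oracle; sequence profiles
and lipid-fraction tables carrying a planted, geometry-consistent
lipid-exposure signal; decoy interaction sets; and homology tables.
All outputs are deterministic functions of (spec, seed).

The planted signal emulates what real profiles encode — the helical
periodicity of conserved (core-facing) versus variable hydrophobic
(lipid-facing) positions — but not the full complexity of real
evolutionary profiles: columns here are two template vectors plus
Gaussian noise, so recovering the signal demonstrates that the feature
and classifier machinery works, not that real membrane proteins are
this easy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from helixpack.contact_labelling import (
    ContactDefinition,
    ContactSet,
    InteractionGraph,
)
from helixpack.io_formats import (
    AMINO_ACIDS,
    Atom,
    HelixSpan,
    LipidFractionTable,
    ProteinRecord,
    SequenceProfile,
    StructureCoords,
    Topology,
    ValidationError,
)

RISE_PER_RESIDUE = 1.5   # A along the helix axis
TWIST_PER_RESIDUE = 100.0  # deg
CA_RADIUS = 2.3          # A from the helix axis
CB_RADIUS = 3.3
SIDECHAIN_EXTENSION = 2.5  # pseudo-atom beyond C-beta

HYDROPHOBIC = "ACFILMVW"
POLAR = "DEHKNQRSTY"

#: Signed column template: +1 on hydrophobic, -1 on polar amino acids.
_SIGNAL_TEMPLATE = np.array(
    [1.0 if aa in HYDROPHOBIC else -1.0 for aa in AMINO_ACIDS]
)
SIGNAL_SCALE = 5.0  # profile-score units carried by the planted signal


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an idealized TM helix bundle.

    Helices sit on explicit 2-D centers, or (by default) on a ring
    whose adjacent spacing is ``spacing``; ``ring_order`` assigns
    helices to ring slots (sequence order by default). Odd helices run
    up through the membrane, even helices down.
    """

    n: int = 2
    helix_length: int = 16
    spacing: float = 9.5  # A between adjacent helix axes
    loop_length: int = 4
    centers: tuple[tuple[float, float], ...] | None = None
    ring_order: tuple[int, ...] | None = None
    rotations: tuple[float, ...] | None = None  # initial wheel azimuths, deg
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("bundle needs at least one helix")
        if self.helix_length < 4:
            raise ValidationError("helix length must be at least 4 residues")
        if self.loop_length < 4:
            raise ValidationError("loops must be at least 4 residues")
        if self.ring_order is not None and sorted(self.ring_order) != list(
            range(1, self.n + 1)
        ):
            raise ValidationError("ring_order must permute 1..n")

    def helix_centers(self) -> list[tuple[float, float]]:
        if self.centers is not None:
            if len(self.centers) != self.n:
                raise ValidationError("centers must list one point per helix")
            return [tuple(c) for c in self.centers]
        if self.n == 1:
            return [(0.0, 0.0)]
        if self.n == 2:
            return [(0.0, 0.0), (self.spacing, 0.0)]
        # ring with adjacent spacing
        R = self.spacing / (2.0 * math.sin(math.pi / self.n))
        order = self.ring_order or tuple(range(1, self.n + 1))
        slot_of = {h: s for s, h in enumerate(order)}
        return [
            (
                R * math.cos(2 * math.pi * slot_of[h] / self.n),
                R * math.sin(2 * math.pi * slot_of[h] / self.n),
            )
            for h in range(1, self.n + 1)
        ]

    def true_ring_order(self) -> tuple[int, ...]:
        """Cyclic helix order around the bundle (ground truth)."""
        return self.ring_order or tuple(range(1, self.n + 1))


@dataclass(frozen=True)
class Bundle:
    """A generated bundle with its ground truth."""

    spec: BundleSpec
    record: ProteinRecord
    topology: Topology
    coords: StructureCoords
    contacts: ContactSet
    interactions: InteractionGraph
    definition: ContactDefinition


def _helix_frame(spec: BundleSpec, h: int) -> tuple[float, float, int, float]:
    """(cx, cy, direction, base rotation) for helix h (1-based)."""
    cx, cy = spec.helix_centers()[h - 1]
    direction = 1 if h % 2 == 1 else -1
    if spec.rotations is not None:
        rot = spec.rotations[h - 1]
    else:
        # deterministic but helix-specific starting azimuth
        rot = (h * 77.0) % 360.0
    return cx, cy, direction, rot


def _residue_azimuth(spec: BundleSpec, h: int, t: int) -> float:
    """Wheel azimuth (deg) of local residue t (0-based) of helix h."""
    _, _, _, rot = _helix_frame(spec, h)
    return (rot + TWIST_PER_RESIDUE * t) % 360.0


def _residue_z(spec: BundleSpec, h: int, t: int) -> float:
    _, _, direction, _ = _helix_frame(spec, h)
    top = RISE_PER_RESIDUE * (spec.helix_length - 1)
    return RISE_PER_RESIDUE * t if direction == 1 else top - RISE_PER_RESIDUE * t


def make_bundle(
    spec: BundleSpec,
    definition: ContactDefinition | None = None,
) -> Bundle:
    """Build an idealized bundle and its ground-truth contact labels.

    True contacts come from :func:`brute_force_contacts`, an O(atoms^2)
    oracle independent of the k-d-tree search used by the labelling
    module.
    """
    definition = definition or ContactDefinition(kind=1)
    centers = spec.helix_centers()
    for a in range(spec.n):
        for b in range(a + 1, spec.n):
            d = math.dist(centers[a], centers[b])
            if d < 2 * CA_RADIUS:
                raise ValidationError(
                    f"helices {a + 1} and {b + 1} overlap (axis distance {d:.2f} A)"
                )
    rng = np.random.default_rng(spec.seed)
    spans: list[HelixSpan] = []
    seq_parts: list[str] = []
    pos = 1
    residues: dict[int, tuple[Atom, ...]] = {}
    for h in range(1, spec.n + 1):
        if h > 1:
            loop = "".join(rng.choice(list("GSPN"), size=spec.loop_length))
            seq_parts.append(loop)
            pos += spec.loop_length
        start = pos
        end = pos + spec.helix_length - 1
        spans.append(HelixSpan(start=start, end=end, index=h))
        cx, cy, _, _ = _helix_frame(spec, h)
        letters = []
        for t in range(spec.helix_length):
            k = start + t
            theta = math.radians(_residue_azimuth(spec, h, t))
            z = _residue_z(spec, h, t)
            exposed = _faces_away(spec, h, t)
            pool = HYDROPHOBIC if exposed else POLAR
            letters.append(pool[int(rng.integers(0, len(pool)))])
            ca = (cx + CA_RADIUS * math.cos(theta), cy + CA_RADIUS * math.sin(theta), z)
            cb = (cx + CB_RADIUS * math.cos(theta), cy + CB_RADIUS * math.sin(theta), z)
            ext = CB_RADIUS + SIDECHAIN_EXTENSION
            cg = (cx + ext * math.cos(theta), cy + ext * math.sin(theta), z)
            tn = math.radians(_residue_azimuth(spec, h, t) - 25.0)
            tc = math.radians(_residue_azimuth(spec, h, t) + 25.0)
            residues[k] = (
                Atom("N", "N", cx + 1.5 * math.cos(tn), cy + 1.5 * math.sin(tn), z - 0.5),
                Atom("CA", "C", *ca),
                Atom("C", "C", cx + 1.7 * math.cos(tc), cy + 1.7 * math.sin(tc), z + 0.5),
                Atom("O", "O", cx + 2.0 * math.cos(tc), cy + 2.0 * math.sin(tc), z + 0.7),
                Atom("CB", "C", *cb),
                Atom("CG", "C", *cg),
            )
        seq_parts.append("".join(letters))
        pos = end + 1
    sequence = "".join(seq_parts)
    record = ProteinRecord(id=f"bundle_n{spec.n}_s{spec.seed}", sequence=sequence)
    topology = Topology(helices=tuple(spans))
    coords = StructureCoords(residues=residues)
    contacts = brute_force_contacts(coords, topology, definition, record)
    edges = {
        tuple(sorted((contacts.helix_of[i], contacts.helix_of[j])))
        for i, j in contacts.pairs
    }
    interactions = InteractionGraph(n=spec.n, edges=frozenset(edges))
    return Bundle(
        spec=spec,
        record=record,
        topology=topology,
        coords=coords,
        contacts=contacts,
        interactions=interactions,
        definition=definition,
    )


def _faces_away(spec: BundleSpec, h: int, t: int) -> bool:
    """True iff the residue's wheel azimuth points >= 90 deg away from
    the bundle centroid (the lipid-exposed side)."""
    centers = spec.helix_centers()
    cx, cy = centers[h - 1]
    gx = sum(c[0] for c in centers) / len(centers)
    gy = sum(c[1] for c in centers) / len(centers)
    core = (gx - cx, gy - cy)
    norm = math.hypot(*core)
    if norm < 1e-9:
        return True  # single helix: everything faces lipid
    theta = math.radians(_residue_azimuth(spec, h, t))
    u = (math.cos(theta), math.sin(theta))
    return u[0] * core[0] / norm + u[1] * core[1] / norm <= 0.0


# ---------------------------------------------------------------------------
# Brute-force contact oracle
# ---------------------------------------------------------------------------

def brute_force_contacts(
    coords: StructureCoords,
    topology: Topology,
    definition: ContactDefinition,
    record: ProteinRecord | None = None,
) -> ContactSet:
    """Plain double-loop distance oracle over inter-helix residue pairs.

    Definition 1 compares C-beta points (C-alpha for glycine, or when
    no C-beta exists) with an inclusive 8 A cutoff; definitions 2 and 3
    compare every heavy-atom pair with strict cutoffs. Quadratic and
    simple on purpose: it is the reference the fast k-d-tree search is
    validated against.
    """
    helix_of = {p: topology.helix_of(p) for p in topology.tm_residues()}
    seq = record.sequence if record is not None else None
    tm = [p for p in helix_of if p in coords.residues]
    if seq is not None:
        tm = [p for p in tm if seq[p - 1] in AMINO_ACIDS]
    if not tm:
        raise ValidationError("no TM residues with coordinates")
    pairs: set[tuple[int, int]] = set()
    points: dict[int, np.ndarray | None] = {}
    heavies: dict[int, np.ndarray] = {}
    radii: dict[int, np.ndarray] = {}
    for p in tm:
        if definition.kind == 1:
            name = "CA" if (seq is not None and seq[p - 1] == "G") else "CB"
            atom = coords.atom(p, name) or coords.atom(p, "CA")
            points[p] = None if atom is None else atom.xyz
        else:
            hv = coords.heavy_atoms(p)
            heavies[p] = np.array([a.xyz for a in hv])
            radii[p] = np.array([definition.radius(a.element) for a in hv])
    for ai, i in enumerate(tm):
        for j in tm[ai + 1 :]:
            if helix_of[i] == helix_of[j]:
                continue
            if definition.kind == 1:
                pi, pj = points[i], points[j]
                if pi is None or pj is None:
                    continue
                hit = float(np.linalg.norm(pi - pj)) <= definition.cbeta_cutoff
            else:
                diff = heavies[i][:, None, :] - heavies[j][None, :, :]
                dist = np.sqrt((diff**2).sum(-1))
                if definition.kind == 3:
                    hit = bool((dist < definition.heavy_cutoff).any())
                else:
                    cut = radii[i][:, None] + radii[j][None, :] + definition.vdw_margin
                    hit = bool((dist < cut).any())
            if hit:
                a, b = min(i, j), max(i, j)
                pairs.add((a, b))
    return ContactSet(pairs=frozenset(pairs), helix_of=helix_of)


# ---------------------------------------------------------------------------
# Planted-signal profiles and lipid fractions
# ---------------------------------------------------------------------------

def make_profiles(
    bundle: Bundle,
    signal_strength: float = 4.0,
    seed: int = 0,
) -> tuple[SequenceProfile, LipidFractionTable]:
    """Profile matrix and lipid-fraction table with planted signal.

    Lipid-facing residues (wheel azimuth >= 90 deg from the bundle
    centroid) receive hydrophobic-enriched profile columns and a lipid
    fraction above 0.5; core-facing residues the polar complement and
    a fraction below 0.5. Gaussian column noise has standard deviation
    SIGNAL_SCALE / signal_strength; ``signal_strength = 0`` produces
    pure noise (labels independent of the profile), ``math.inf`` the
    noiseless limit. Deterministic given (bundle, seed).
    """
    if signal_strength < 0:
        raise ValidationError("signal_strength must be >= 0")
    spec = bundle.spec
    L = bundle.record.length
    rng = np.random.default_rng(seed)
    scores = np.zeros((L, 20))
    fractions: dict[int, float] = {}
    for h in bundle.topology.helices:
        for t in range(len(h)):
            k = h.start + t
            exposed = _faces_away(spec, h.index, t)
            e = _exposure_degree(spec, h.index, t)
            fractions[k] = float(np.clip(0.5 + 0.49 * e, 0.0, 1.0))
            if signal_strength > 0:
                sign = 1.0 if exposed else -1.0
                scores[k - 1] = sign * SIGNAL_SCALE * _SIGNAL_TEMPLATE
    if signal_strength == 0:
        noise = rng.normal(0.0, SIGNAL_SCALE, size=(L, 20))
    elif math.isinf(signal_strength):
        noise = np.zeros((L, 20))
    else:
        noise = rng.normal(0.0, SIGNAL_SCALE / signal_strength, size=(L, 20))
    scores = scores + noise
    return SequenceProfile(scores=scores), LipidFractionTable(fractions=fractions)


def _exposure_degree(spec: BundleSpec, h: int, t: int) -> float:
    """Signed exposure in [-1, 1]: positive away from the core."""
    centers = spec.helix_centers()
    cx, cy = centers[h - 1]
    gx = sum(c[0] for c in centers) / len(centers)
    gy = sum(c[1] for c in centers) / len(centers)
    core = (gx - cx, gy - cy)
    norm = math.hypot(*core)
    if norm < 1e-9:
        return 1.0
    theta = math.radians(_residue_azimuth(spec, h, t))
    return -(math.cos(theta) * core[0] + math.sin(theta) * core[1]) / norm


# ---------------------------------------------------------------------------
# Decoy interaction sets
# ---------------------------------------------------------------------------

def make_decoys(
    native: InteractionGraph,
    n_decoys: int,
    seed: int = 0,
) -> list:
    """Distinct decoy interaction graphs, each differing from the
    native in at least one helix pair (1 .. C(n,2) edge flips)."""
    from helixpack.interaction_decoys import ArrangementCandidate

    if n_decoys < 1:
        raise ValidationError("need at least one decoy")
    n = native.n
    all_pairs = [
        (a, b) for a in range(1, n + 1) for b in range(a + 1, n + 1)
    ]
    n_pairs = len(all_pairs)
    available = 2**n_pairs - 1  # every graph except the native itself
    if n_decoys > available:
        raise ValidationError(
            f"only {available} distinct decoy graphs exist for n={n}, "
            f"requested {n_decoys}"
        )
    rng = np.random.default_rng(seed)
    seen: set[frozenset] = {native.edges}
    decoys = []
    while len(decoys) < n_decoys:
        n_flips = int(rng.integers(1, n_pairs + 1))
        flip_idx = rng.choice(n_pairs, size=n_flips, replace=False)
        edges = set(native.edges)
        for fi in sorted(flip_idx):
            pair = all_pairs[fi]
            edges.symmetric_difference_update({pair})
        key = frozenset(edges)
        if key in seen:
            continue
        seen.add(key)
        decoys.append(
            ArrangementCandidate(
                id=f"decoy{len(decoys):03d}",
                graph=InteractionGraph(n=n, edges=key),
                provenance="decoy",
            )
        )
    return decoys
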