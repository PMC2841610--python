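"""Two-dimensional helical packing arrangements.

The helix-interaction graph is embedded in the plane with the
Kamada-Kawai spring model: every vertex pair (i, j) is joined by a
spring of rest length L0 * d_ij and strength K / d_ij**2, where d_ij
is the graph-theoretic shortest-path length, and the total energy

    E = sum_{i<j} k_ij * (||p_i - p_j|| - L0 * d_ij)**2

is minimized by per-vertex Newton sweeps from a regular n-gon start
(the circular initialization avoids poor local minima). Helices that
share the same interactions are interchangeable; every distinct
assignment of such helices to layout slots is enumerated and scored by
the number of same-side loop crossovers: the loop joining
sequence-adjacent helices i and i+1 alternates membrane sides with i,
and two loops on the same side score a crossover when their open
segments properly intersect (exact cross-product orientation tests).
Fewer same-side crossovers ranks higher; ties are broken by the summed
residue contact distance after rotation optimization.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from helixpack.contact_labelling import ContactSet, InteractionGraph
from helixpack.io_formats import Topology, ValidationError


class DisconnectedGraphError(ValidationError):
    """A packing arrangement cannot be generated from a disconnected
    interaction graph."""


@dataclass(frozen=True)
class LayoutParams:
    """Spring-system constants for the force-directed layout."""

    L0: float = 1.0          # ideal edge length, layout units
    K: float = 1.0           # spring-constant scale
    tolerance: float = 1e-6  # max gradient norm at convergence
    max_iterations: int = 1000
    init_radius: float = 1.0
    min_distance_angstrom: float = 10.0  # layout rescale target

    def __post_init__(self) -> None:
        if min(self.L0, self.K, self.tolerance, self.init_radius) <= 0:
            raise ValueError("layout parameters must be positive")


@dataclass(frozen=True)
class Layout2D:
    """Per-helix 2-D positions plus a layout-unit -> Angstrom scale."""

    positions: Mapping[int, tuple[float, float]]
    scale: float = 1.0

    def __post_init__(self) -> None:
        for h, (x, y) in self.positions.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValidationError(f"helix {h}: non-finite layout position")

    @property
    def n(self) -> int:
        return len(self.positions)

    def angstrom(self, h: int) -> tuple[float, float]:
        x, y = self.positions[h]
        return (x * self.scale, y * self.scale)

    def positions_angstrom(self) -> dict[int, tuple[float, float]]:
        return {h: self.angstrom(h) for h in self.positions}


@dataclass(frozen=True)
class Arrangement:
    """One laid-out candidate arrangement of the helices."""

    id: str
    permutation: Mapping[int, int]  # helix -> layout slot
    layout: Layout2D
    crossovers_side0: int
    crossovers_side1: int
    rotations: tuple[int, ...] = ()
    total_contact_distance: float = 0.0

    @property
    def crossovers_total(self) -> int:
        return self.crossovers_side0 + self.crossovers_side1

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "permutation": {str(k): v for k, v in self.permutation.items()},
            "positions_angstrom": {
                str(h): list(self.layout.angstrom(h)) for h in self.layout.positions
            },
            "crossovers": {
                "side0": self.crossovers_side0,
                "side1": self.crossovers_side1,
                "total": self.crossovers_total,
            },
            "rotations_deg": list(self.rotations),
            "total_contact_distance_angstrom": self.total_contact_distance,
        }


def circular_init(n: int, radius: float = 1.0, slots: Mapping[int, int] | None = None) -> Layout2D:
    """Vertices on a regular n-gon: helix k at angle 2*pi*(slot-1)/n,
    slot k by default (helix 1 at angle 0)."""
    if n < 1:
        raise ValidationError(f"need at least one vertex, got n={n}")
    positions = {}
    for k in range(1, n + 1):
        slot = slots[k] if slots is not None else k
        theta = 2.0 * math.pi * (slot - 1) / n
        positions[k] = (radius * math.cos(theta), radius * math.sin(theta))
    return Layout2D(positions=positions)


def _spring_system(
    graph: InteractionGraph, params: LayoutParams
) -> tuple[np.ndarray, np.ndarray]:
    """(rest-length, strength) matrices from shortest-path distances."""
    g = nx.Graph()
    g.add_nodes_from(range(1, graph.n + 1))
    g.add_edges_from(graph.edges)
    if graph.n > 1 and not nx.is_connected(g):
        comps = sorted(tuple(sorted(c)) for c in nx.connected_components(g))
        raise DisconnectedGraphError(
            f"interaction graph is disconnected; components: {comps}"
        )
    spl = dict(nx.all_pairs_shortest_path_length(g))
    n = graph.n
    rest = np.zeros((n, n))
    strength = np.zeros((n, n))
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            if i == j:
                continue
            d = spl[i][j]
            rest[i - 1, j - 1] = params.L0 * d
            strength[i - 1, j - 1] = params.K / d**2
    return rest, strength


def _energy(pos: np.ndarray, rest: np.ndarray, strength: np.ndarray) -> float:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 1.0)
    e = strength * (dist - rest) ** 2
    np.fill_diagonal(e, 0.0)
    return 0.5 * float(e.sum())  # each pair counted once


def _gradient(pos: np.ndarray, rest: np.ndarray, strength: np.ndarray) -> np.ndarray:
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 1.0)
    coef = 2.0 * strength * (dist - rest) / dist
    np.fill_diagonal(coef, 0.0)
    return (coef[:, :, None] * diff).sum(axis=1)


def kamada_kawai(
    graph: InteractionGraph,
    init: Layout2D | None = None,
    params: LayoutParams | None = None,
) -> tuple[Layout2D, float]:
    """Minimize the spring energy; returns (layout, final energy).

    The vertex with the largest gradient norm is relaxed by a damped
    2x2 Newton step (halved until the energy does not increase), so
    the energy is non-increasing across iterations. Raises
    :class:`DisconnectedGraphError` on disconnected graphs.
    """
    params = params or LayoutParams()
    if init is None:
        init = circular_init(graph.n, params.init_radius)
    if set(init.positions) != set(range(1, graph.n + 1)):
        raise ValidationError("initial layout does not cover all helices")
    if graph.n == 1:
        return init, 0.0
    rest, strength = _spring_system(graph, params)
    pos = np.array([init.positions[k] for k in range(1, graph.n + 1)], dtype=float)
    energy = _energy(pos, rest, strength)
    initial_energy = energy
    for _ in range(params.max_iterations):
        grad = _gradient(pos, rest, strength)
        norms = np.linalg.norm(grad, axis=1)
        m = int(np.argmax(norms))
        if norms[m] < params.tolerance:
            break
        # second partials of E w.r.t. vertex m
        diff = pos[m] - pos
        dist = np.sqrt((diff**2).sum(-1))
        dist[m] = 1.0
        k = strength[m].copy()
        k[m] = 0.0
        l = rest[m]
        dx, dy = diff[:, 0], diff[:, 1]
        d3 = dist**3
        exx = np.sum(2 * k * (1 - l * dy**2 / d3))
        eyy = np.sum(2 * k * (1 - l * dx**2 / d3))
        exy = np.sum(2 * k * l * dx * dy / d3)
        gx, gy = grad[m]
        det = exx * eyy - exy**2
        if abs(det) < 1e-12:
            step = -grad[m] / (np.sum(2 * k) + 1e-12)
        else:
            step = np.array(
                [(-gx * eyy + gy * exy) / det, (gx * exy - gy * exx) / det]
            )
        # damp until descent — guarantees the energy-descent invariant
        for _halving in range(60):
            trial = pos.copy()
            trial[m] = pos[m] + step
            trial_energy = _energy(trial, rest, strength)
            if trial_energy <= energy:
                break
            step = step / 2.0
        else:
            break  # cannot descend further from here
        pos, energy = trial, trial_energy
    assert energy <= initial_energy + 1e-12
    layout = Layout2D(
        positions={k: (float(pos[k - 1, 0]), float(pos[k - 1, 1])) for k in init.positions},
        scale=init.scale,
    )
    return layout, energy


def rescale_layout(layout: Layout2D, min_distance_angstrom: float = 10.0) -> Layout2D:
    """Set the layout scale so the closest vertex pair sits at the
    typical helix-axis packing distance (10 A by default)."""
    keys = sorted(layout.positions)
    if len(keys) < 2:
        return replace(layout, scale=1.0)
    pts = np.array([layout.positions[k] for k in keys])
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, np.inf)
    dmin = float(dist.min())
    if dmin == 0:
        raise ValidationError("coincident helix positions; cannot rescale")
    return replace(layout, scale=min_distance_angstrom / dmin)


# ---------------------------------------------------------------------------
# Arrangement enumeration
# ---------------------------------------------------------------------------

MAX_ARRANGEMENTS = 10_000


def _interchangeable_classes(graph: InteractionGraph) -> list[list[int]]:
    """Group helices whose neighbour sets are identical once the pair
    under comparison is removed from each other's sets."""
    parent = {v: v for v in range(1, graph.n + 1)}

    def find(v: int) -> int:
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u in range(1, graph.n + 1):
        for v in range(u + 1, graph.n + 1):
            nu = graph.neighbours(u) - {v}
            nv = graph.neighbours(v) - {u}
            if nu == nv:
                ru, rv = find(u), find(v)
                parent[ru] = rv
    classes: dict[int, list[int]] = {}
    for v in range(1, graph.n + 1):
        classes.setdefault(find(v), []).append(v)
    return [sorted(c) for c in classes.values() if len(c) > 1]


def _is_automorphism(graph: InteractionGraph, perm: Mapping[int, int]) -> bool:
    mapped = {
        tuple(sorted((perm[a], perm[b]))) for a, b in graph.edges
    }
    return mapped == set(graph.edges)


def equivalent_arrangements(
    graph: InteractionGraph, seed: int = 0
) -> list[dict[int, int]]:
    """All distinct helix -> slot assignments arising from helices that
    share the same interactions.

    Returns the identity plus every permutation that exchanges
    interchangeable helices and maps the edge set onto itself; capped
    at 10,000 (seeded sampling beyond, with a warning).
    """
    classes = _interchangeable_classes(graph)
    identity = {v: v for v in range(1, graph.n + 1)}
    if not classes:
        return [identity]
    total = 1
    for c in classes:
        total *= math.factorial(len(c))
    class_perms = []
    if total > MAX_ARRANGEMENTS:
        warnings.warn(
            f"{total} candidate arrangements exceed the cap of "
            f"{MAX_ARRANGEMENTS}; sampling with seed {seed}",
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        seen = set()
        draws = []
        while len(draws) < MAX_ARRANGEMENTS:
            combo = tuple(
                tuple(rng.permutation(c).tolist()) for c in classes
            )
            if combo not in seen:
                seen.add(combo)
                draws.append(combo)
        combos = draws
    else:
        combos = list(
            itertools.product(*[list(itertools.permutations(c)) for c in classes])
        )
    out = []
    seen_perms = set()
    for combo in combos:
        perm = dict(identity)
        for members, image in zip(classes, combo):
            for src, dst in zip(members, image):
                perm[src] = dst
        key = tuple(perm[v] for v in sorted(perm))
        if key in seen_perms:
            continue
        seen_perms.add(key)
        if _is_automorphism(graph, perm):
            out.append(perm)
    # identity first, then lexicographic
    out.sort(key=lambda p: tuple(p[v] for v in sorted(p)))
    if identity in out:
        out.remove(identity)
    return [identity] + out


# ---------------------------------------------------------------------------
# Same-side loop crossovers
# ---------------------------------------------------------------------------

def _orientation(
    a: tuple[Fraction, Fraction],
    b: tuple[Fraction, Fraction],
    c: tuple[Fraction, Fraction],
) -> int:
    """Exact sign of the cross product (b - a) x (c - a)."""
    cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    return (cross > 0) - (cross < 0)


def _properly_intersect(p1, p2, p3, p4) -> bool:
    """True iff open segments p1p2 and p3p4 cross at an interior point.

    Shared endpoints and collinear touching do not count; orientation
    signs are computed in exact rational arithmetic.
    """
    o1 = _orientation(p1, p2, p3)
    o2 = _orientation(p1, p2, p4)
    o3 = _orientation(p3, p4, p1)
    o4 = _orientation(p3, p4, p2)
    return o1 * o2 < 0 and o3 * o4 < 0


def count_same_side_crossovers(layout: Layout2D, n: int | None = None) -> tuple[int, int, int]:
    """Count crossings between connecting loops on each membrane side.

    Loop i joins the positions of sequence-adjacent helices i and i+1
    and lies on side (i mod 2); loops on one side are compared
    pairwise and a crossover is counted when their open segments
    properly intersect. Returns (side0, side1, total).
    """
    n = n if n is not None else layout.n
    if n < 2:
        raise ValidationError("need at least two helices to draw loops")
    pts: dict[int, tuple[Fraction, Fraction]] = {}
    for h in range(1, n + 1):
        x, y = layout.positions[h]
        pts[h] = (Fraction(x), Fraction(y))
    for i in range(1, n):
        if pts[i] == pts[i + 1]:
            raise ValidationError(
                f"helices {i} and {i + 1} coincide; zero-length loop"
            )
    loops = {i: (pts[i], pts[i + 1]) for i in range(1, n)}
    counts = [0, 0]
    for side in (0, 1):
        ids = [i for i in loops if i % 2 == side]
        for a, b in itertools.combinations(ids, 2):
            if _properly_intersect(*loops[a], *loops[b]):
                counts[side] += 1
    return counts[0], counts[1], counts[0] + counts[1]


# ---------------------------------------------------------------------------
# Arrangement selection
# ---------------------------------------------------------------------------

def select_arrangement(
    graph: InteractionGraph,
    topology: Topology | None = None,
    contacts: ContactSet | Sequence[tuple[int, int]] | None = None,
    layout_params: LayoutParams | None = None,
    ga_config=None,
    seed: int = 0,
) -> list[Arrangement]:
    """Lay out, score and rank every equivalent arrangement.

    For each enumerated helix -> slot assignment: run the spring
    relaxation from the permuted n-gon start, rescale to Angstrom,
    count same-side loop crossovers, optimize helix rotations against
    the contact set (when one is supplied), and rank by (crossovers
    ascending, total contact distance ascending, id).
    """
    from helixpack import rotation_optimizer as rot

    layout_params = layout_params or LayoutParams()
    perms = equivalent_arrangements(graph, seed=seed)
    results: list[Arrangement] = []
    contact_pairs = _contact_pairs(contacts)
    for k, perm in enumerate(perms):
        init = circular_init(graph.n, layout_params.init_radius, slots=perm)
        layout, _energy_final = kamada_kawai(graph, init, layout_params)
        if graph.n >= 2:
            layout = rescale_layout(layout, layout_params.min_distance_angstrom)
            side0, side1, _total = count_same_side_crossovers(layout, graph.n)
        else:
            side0 = side1 = 0
        rotations: tuple[int, ...] = tuple([0] * graph.n)
        distance = 0.0
        if contact_pairs and topology is not None:
            config = ga_config or rot.GAConfig(seed=seed + k)
            vec, distance = rot.ga_optimize(
                layout, topology, contact_pairs, config
            )
            rotations = tuple(vec)
        results.append(
            Arrangement(
                id=f"arr{k:04d}",
                permutation=perm,
                layout=layout,
                crossovers_side0=side0,
                crossovers_side1=side1,
                rotations=rotations,
                total_contact_distance=distance,
            )
        )
    results.sort(
        key=lambda a: (a.crossovers_total, a.total_contact_distance, a.id)
    )
    return results


def _contact_pairs(
    contacts: ContactSet | Sequence[tuple[int, int]] | None,
) -> list[tuple[int, int]]:
    if contacts is None:
        return []
    if isinstance(contacts, ContactSet):
        return sorted(contacts.pairs)
    return sorted((min(i, j), max(i, j)) for i, j in contacts)
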