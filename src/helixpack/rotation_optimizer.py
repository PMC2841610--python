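"""Helical-wheel rotation optimization with a genetic algorithm.

Each laid-out helix is drawn as a helical wheel: residue k of a helix
starting at ``start`` sits on a circle of radius r (2.3 A, roughly the
C-beta radial distance) at azimuth

    theta(k) = rotation + 100 deg * (k - start)

— the canonical alpha-helix twist of 3.6 residues per turn. One
integer rotation angle in [0, 359] per helix is then optimized so that
the summed 2-D Euclidean distance over the predicted residue-residue
contact pairs is minimal, which keeps contacting residues from facing
away across the longitudinal helix axis. The optimizer is a seeded
generational genetic algorithm (tournament selection, uniform
crossover, per-gene uniform mutation, elitism), so the best objective
never increases across generations and is never worse than the best
individual of the initial population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from helixpack.io_formats import HelixSpan, Topology, ValidationError
from helixpack.packing_layout import Layout2D

TWIST_DEG = 100.0  # 3.6 residues per alpha-helical turn
WHEEL_RADIUS = 2.3  # A, approximate C-beta radial distance


@dataclass(frozen=True)
class HelixWheel:
    """A helix projected onto a circle in the membrane plane."""

    center: tuple[float, float]
    radius: float
    span: HelixSpan
    twist: float = TWIST_DEG
    direction: float = 1.0  # +1 counter-clockwise; -1 mirrors the wheel

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("wheel radius must be positive")

    def azimuth(self, k: int, rotation: float) -> float:
        if k not in self.span:
            raise ValidationError(
                f"residue {k} outside helix span "
                f"{self.span.start}-{self.span.end}"
            )
        return (rotation + self.direction * self.twist * (k - self.span.start)) % 360.0


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters (all seeded and deterministic)."""

    population: int = 100
    generations: int = 200
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.elitism < self.population:
            raise ValueError("elitism must be in [0, population)")


def residue_xy(wheel: HelixWheel, k: int, rotation: float) -> tuple[float, float]:
    """2-D position of residue k on its helical wheel at the given
    rotation (degrees)."""
    theta = math.radians(wheel.azimuth(k, rotation))
    return (
        wheel.center[0] + wheel.radius * math.cos(theta),
        wheel.center[1] + wheel.radius * math.sin(theta),
    )


def build_wheels(
    layout: Layout2D,
    topology: Topology,
    radius: float = WHEEL_RADIUS,
    twist: float = TWIST_DEG,
) -> dict[int, HelixWheel]:
    """One wheel per helix, centred at the scaled layout position."""
    wheels = {}
    for h in topology.helices:
        if h.index not in layout.positions:
            raise ValidationError(f"helix {h.index} missing from layout")
        wheels[h.index] = HelixWheel(
            center=layout.angstrom(h.index), radius=radius, span=h, twist=twist
        )
    return wheels


def _pair_geometry(
    wheels: dict[int, HelixWheel],
    topology: Topology,
    contacts: Sequence[tuple[int, int]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-contact constants: helix ids, base azimuths and
    wheel centers/radii for both residues of each pair."""
    hi, hj, phase_i, phase_j = [], [], [], []
    ci, cj, ri, rj = [], [], [], []
    for i, j in contacts:
        a = topology.helix_of(i)
        b = topology.helix_of(j)
        if a is None or b is None or a not in wheels or b not in wheels:
            raise ValidationError(
                f"contact ({i}, {j}) references a helix missing from the layout"
            )
        wa, wb = wheels[a], wheels[b]
        hi.append(a - 1)
        hj.append(b - 1)
        phase_i.append(wa.direction * wa.twist * (i - wa.span.start))
        phase_j.append(wb.direction * wb.twist * (j - wb.span.start))
        ci.append(wa.center)
        cj.append(wb.center)
        ri.append(wa.radius)
        rj.append(wb.radius)
    return (
        np.array(hi), np.array(hj),
        np.array(phase_i), np.array(phase_j),
        np.array(ci), np.array(cj),
        np.array(ri)[:, None], np.array(rj)[:, None],
    )


class _Objective:
    """Summed contact distance as a vectorized function of a population
    of rotation vectors (degrees, shape P x n)."""

    def __init__(
        self,
        layout: Layout2D,
        topology: Topology,
        contacts: Sequence[tuple[int, int]],
        radius: float = WHEEL_RADIUS,
        twist: float = TWIST_DEG,
    ) -> None:
        wheels = build_wheels(layout, topology, radius=radius, twist=twist)
        (self.hi, self.hj, self.phase_i, self.phase_j,
         self.ci, self.cj, self.ri, self.rj) = _pair_geometry(
            wheels, topology, contacts
        )
        self.n = topology.n

    def __call__(self, rotations: np.ndarray) -> np.ndarray:
        rot = np.atleast_2d(rotations).astype(float)  # P x n
        ti = np.radians(rot[:, self.hi] + self.phase_i)  # P x m
        tj = np.radians(rot[:, self.hj] + self.phase_j)
        xi = self.ci[:, 0] + self.ri[:, 0] * np.cos(ti)
        yi = self.ci[:, 1] + self.ri[:, 0] * np.sin(ti)
        xj = self.cj[:, 0] + self.rj[:, 0] * np.cos(tj)
        yj = self.cj[:, 1] + self.rj[:, 0] * np.sin(tj)
        return np.sqrt((xi - xj) ** 2 + (yi - yj) ** 2).sum(axis=1)


def contact_distance_sum(
    layout: Layout2D,
    topology: Topology,
    rotations: Sequence[int],
    contacts: Sequence[tuple[int, int]],
    radius: float = WHEEL_RADIUS,
    twist: float = TWIST_DEG,
) -> float:
    """Sum of 2-D distances between the wheel positions of every
    contact pair at the given per-helix rotations (degrees)."""
    if len(rotations) != topology.n:
        raise ValidationError(
            f"expected {topology.n} rotations, got {len(rotations)}"
        )
    if not contacts:
        return 0.0
    obj = _Objective(layout, topology, contacts, radius=radius, twist=twist)
    return float(obj(np.asarray(rotations))[0])


def ga_optimize(
    layout: Layout2D,
    topology: Topology,
    contacts: Sequence[tuple[int, int]],
    config: GAConfig | None = None,
    radius: float = WHEEL_RADIUS,
    twist: float = TWIST_DEG,
) -> tuple[list[int], float]:
    """Minimize the summed contact distance over integer rotations.

    Returns (rotation vector in degrees, objective in Angstrom). The
    result is deterministic for a fixed seed and, through elitism,
    never worse than the best individual of the initial population.
    """
    config = config or GAConfig()
    contacts = list(contacts)
    if not contacts:
        raise ValidationError("no contact pairs; nothing to optimize")
    objective = _Objective(layout, topology, contacts, radius=radius, twist=twist)
    n = topology.n
    rng = np.random.default_rng(config.seed)
    pop = rng.integers(0, 360, size=(config.population, n))
    fitness = objective(pop)
    for _gen in range(config.generations):
        order = np.argsort(fitness, kind="stable")
        elite = pop[order[: config.elitism]]
        # tournament selection
        P = config.population
        draws = rng.integers(0, P, size=(2 * P, config.tournament))
        winners = draws[np.arange(2 * P), np.argmin(fitness[draws], axis=1)]
        parents_a = pop[winners[:P]]
        parents_b = pop[winners[P:]]
        # uniform crossover
        do_cross = rng.random(P) < config.crossover_rate
        mask = rng.random((P, n)) < 0.5
        children = np.where(mask, parents_a, parents_b)
        children[~do_cross] = parents_a[~do_cross]
        # per-gene mutation: redraw uniformly in 0..359
        mut = rng.random((P, n)) < config.mutation_rate
        children[mut] = rng.integers(0, 360, size=int(mut.sum()))
        if config.elitism:
            children[: config.elitism] = elite
        pop = children
        fitness = objective(pop)
    best = int(np.argmin(fitness))
    return [int(g) for g in pop[best]], float(fitness[best])
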