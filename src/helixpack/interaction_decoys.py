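"""Predicted helix interactions and decoy-arrangement discrimination.

Contact-score predictions collapse to a helix-interaction graph (an
edge wherever any inter-helix residue pair scores positive). Candidate
packing arrangements — the native structure, homology models of it,
and decoys — are scored by how many of the C(n,2) helix pairs agree
with the predicted graph, interacting and non-interacting pairs
counting equally, and ranked; the benchmark statistic is how often the
native (or native-model) arrangement ranks first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from helixpack.contact_labelling import InteractionGraph
from helixpack.io_formats import Topology, ValidationError

NATIVE_TAGS = frozenset({"native", "native_model"})


@dataclass(frozen=True)
class ArrangementCandidate:
    """A candidate packing arrangement reduced to its interaction set."""

    id: str
    graph: InteractionGraph
    provenance: str = "decoy"  # native | native_model | decoy | synthetic

    @property
    def is_native(self) -> bool:
        return self.provenance in NATIVE_TAGS


@dataclass(frozen=True)
class DecoyRanking:
    """Candidates sorted by score (desc); ties count for the native."""

    ranking: tuple[tuple[str, int], ...]
    native_first: bool


def write_interaction_graph(graph: InteractionGraph, path) -> None:
    import json
    from pathlib import Path

    payload = {
        "format_version": "1.0",
        "kind": "interaction_graph",
        "n": graph.n,
        "edges": sorted(list(e) for e in graph.edges),
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_interaction_graph(path) -> InteractionGraph:
    import json
    from pathlib import Path

    payload = json.loads(Path(path).read_text())
    return InteractionGraph(
        n=int(payload["n"]),
        edges=frozenset(tuple(sorted(e)) for e in payload["edges"]),
    )


def read_candidates(path) -> list[ArrangementCandidate]:
    """Read candidate arrangements from JSON: a list of objects with
    ``id``, ``provenance``, ``n`` and ``edges``."""
    import json
    from pathlib import Path

    entries = json.loads(Path(path).read_text())
    if isinstance(entries, dict):
        entries = entries["candidates"]
    out = []
    for k, entry in enumerate(entries):
        try:
            out.append(
                ArrangementCandidate(
                    id=str(entry["id"]),
                    graph=InteractionGraph(
                        n=int(entry["n"]),
                        edges=frozenset(
                            tuple(sorted(e)) for e in entry["edges"]
                        ),
                    ),
                    provenance=entry.get("provenance", "decoy"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path}: malformed candidate entry {k + 1}: {exc}"
            ) from None
    return out


def write_candidates(candidates: Sequence[ArrangementCandidate], path) -> None:
    import json
    from pathlib import Path

    payload = [
        {
            "id": c.id,
            "provenance": c.provenance,
            "n": c.graph.n,
            "edges": sorted(list(e) for e in c.graph.edges),
        }
        for c in candidates
    ]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def predicted_interactions(
    pair_scores: Mapping[tuple[int, int], float],
    topology: Topology,
    threshold: float = 0.0,
) -> InteractionGraph:
    """Helix pairs with at least one residue pair scoring above
    ``threshold`` (raw SVM decision values; default 0)."""
    edges = set()
    for (i, j), score in pair_scores.items():
        if score > threshold:
            a = topology.helix_of(i)
            b = topology.helix_of(j)
            if a is None or b is None:
                raise ValidationError(
                    f"scored pair ({i}, {j}) has a residue outside all TM helices"
                )
            edges.add((min(a, b), max(a, b)))
    return InteractionGraph(n=topology.n, edges=frozenset(edges))


def arrangement_score(
    candidate: InteractionGraph, predicted: InteractionGraph
) -> int:
    """Number of helix pairs (of C(n,2)) whose edge presence/absence
    matches between candidate and prediction."""
    if candidate.n != predicted.n:
        raise ValidationError(
            f"vertex count mismatch: candidate {candidate.n} vs "
            f"prediction {predicted.n}"
        )
    n = candidate.n
    score = 0
    for a in range(1, n + 1):
        for b in range(a + 1, n + 1):
            if candidate.has_edge(a, b) == predicted.has_edge(a, b):
                score += 1
    return score


def rank_candidates(
    candidates: Sequence[ArrangementCandidate],
    predicted: InteractionGraph,
    strict_ties: bool = False,
) -> DecoyRanking:
    """Score and sort candidates against the predicted graph.

    ``native_first`` is true when no candidate scores strictly higher
    than the best native-tagged one; with ``strict_ties`` a decoy tying
    the native's score defeats it instead.
    """
    if not candidates:
        raise ValidationError("no candidates to rank")
    scored = [(c, arrangement_score(c.graph, predicted)) for c in candidates]
    scored.sort(key=lambda cs: (-cs[1], cs[0].id))
    native_scores = [s for c, s in scored if c.is_native]
    if not native_scores:
        raise ValidationError("no candidate tagged native or native_model")
    best_native = max(native_scores)
    other_scores = [s for c, s in scored if not c.is_native]
    if strict_ties:
        native_first = all(s < best_native for s in other_scores)
    else:
        native_first = all(s <= best_native for s in other_scores)
    return DecoyRanking(
        ranking=tuple((c.id, s) for c, s in scored),
        native_first=native_first,
    )
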