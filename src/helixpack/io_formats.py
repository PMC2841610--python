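"""Readers and writers for the external formats the pipeline consumes.

FASTA sequences, PSI-BLAST ASCII PSSMs, plain-text/JSON topology files,
PDB coordinates, tab-separated lipid-fraction tables, and JSON/SVG
result output all pass through this module, which converts them into
the validated domain types used everywhere else.

Conventions: residue numbering is 1-based throughout; helix spans are
inclusive; sequences use the 20 canonical one-letter codes, with the
ambiguity codes X/B/Z/U accepted but mapped to zero profile columns
and excluded from contact labelling downstream.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.PDB import PDBParser

FORMAT_VERSION = "1.0"

#: Canonical amino-acid alphabet, alphabetical one-letter order — the
#: fixed column order of every profile matrix.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity/non-canonical codes tolerated in sequences.
NONCANONICAL = "XBZU"


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with identifier; ``length`` is L."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for k, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS and aa not in NONCANONICAL:
                raise ParseError(
                    f"record {self.id!r}: illegal character {aa!r} at residue {k}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class HelixSpan:
    """One TM helix: 1-based inclusive residue span ``start..end``."""

    start: int
    end: int
    index: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"helix {self.index}: start {self.start} < 1")
        if self.start > self.end:
            raise ValidationError(
                f"helix {self.index}: start {self.start} > end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class Topology:
    """Ordered, non-overlapping TM helix spans; ``n`` helices."""

    helices: tuple[HelixSpan, ...]

    def __post_init__(self) -> None:
        spans = tuple(sorted(self.helices))
        spans = tuple(
            HelixSpan(start=s.start, end=s.end, index=i + 1)
            for i, s in enumerate(spans)
        )
        object.__setattr__(self, "helices", spans)
        for a, b in zip(spans, spans[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"helix spans {a.start}-{a.end} and {b.start}-{b.end} overlap"
                )

    @property
    def n(self) -> int:
        return len(self.helices)

    def helix_of(self, pos: int) -> int | None:
        """1-based helix index containing residue ``pos``, or None."""
        for h in self.helices:
            if pos in h:
                return h.index
        return None

    def tm_residues(self) -> list[int]:
        return [p for h in self.helices for p in range(h.start, h.end + 1)]

    def validate_against(self, record: ProteinRecord) -> None:
        last = self.helices[-1]
        if last.end > record.length:
            raise ValidationError(
                f"helix {last.index} span {last.start}-{last.end} exceeds "
                f"sequence length {record.length} of {record.id!r}"
            )


@dataclass(frozen=True)
class SequenceProfile:
    """L x 20 profile matrix, one row per residue, alphabetical columns."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.scores, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 20:
            raise ValidationError(f"profile must be Lx20, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("profile contains non-finite entries")
        object.__setattr__(self, "scores", arr)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    x: float
    y: float
    z: float

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class StructureCoords:
    """Per-residue atom lists, keyed by 1-based residue index."""

    residues: Mapping[int, tuple[Atom, ...]]

    def __post_init__(self) -> None:
        for idx, atoms in self.residues.items():
            for a in atoms:
                if not all(np.isfinite([a.x, a.y, a.z])):
                    raise ValidationError(
                        f"residue {idx} atom {a.name}: non-finite coordinate"
                    )

    def heavy_atoms(self, idx: int) -> tuple[Atom, ...]:
        return tuple(a for a in self.residues.get(idx, ()) if not a.is_hydrogen)

    def atom(self, idx: int, name: str) -> Atom | None:
        for a in self.residues.get(idx, ()):
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class LipidFractionTable:
    """Fraction of simulation time each residue spends in lipid contact."""

    fractions: Mapping[int, float]

    def __post_init__(self) -> None:
        for idx, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(
                    f"residue {idx}: lipid fraction {f} outside [0, 1]"
                )

    def get(self, idx: int) -> float | None:
        return self.fractions.get(idx)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Sequences are whitespace-stripped and uppercased. Duplicate ids,
    empty files and non-amino-acid characters raise :class:`ParseError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_pssm(path: str | Path, expected_length: int | None = None) -> SequenceProfile:
    """Read a PSI-BLAST ASCII PSSM into a :class:`SequenceProfile`.

    The first 20 numeric columns of each residue row (the log-odds
    block of the standard 40-column ASCII dump) are used; header and
    the lambda/K footer are ignored.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            # Residue rows start "<index> <letter> <scores...>"
            if (
                len(parts) < 2
                or not parts[0].isdigit()
                or len(parts[1]) != 1
                or not parts[1].isalpha()
            ):
                continue
            if len(parts) < 22:
                raise ParseError(
                    f"{path}:{lineno}: PSSM row {parts[0]} has fewer than "
                    f"20 score columns"
                )
            try:
                values = [float(v) for v in parts[2:22]]
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric PSSM cell ({exc})"
                ) from None
            rows.append(values)
        if not rows:
            raise ParseError(f"{path}: no PSSM residue rows found")
    profile = SequenceProfile(scores=np.array(rows, dtype=float))
    if expected_length is not None and profile.length != expected_length:
        raise ParseError(
            f"{path}: PSSM has {profile.length} rows, sequence has "
            f"{expected_length} residues"
        )
    return profile


def read_topology(path: str | Path) -> Topology:
    """Read TM helix spans from plain text or JSON.

    Text format: one ``<helix_index> <start>-<end>`` per line; JSON
    format: a list of ``{"index": i, "start": s, "end": e}`` objects
    (or a top-level ``{"helices": [...]}``). Spans are sorted and
    re-indexed by start position.
    """
    text = Path(path).read_text()
    stripped = text.lstrip()
    spans: list[HelixSpan] = []
    if stripped.startswith("{") or stripped.startswith("["):
        data = json.loads(text)
        if isinstance(data, dict):
            data = data["helices"]
        for entry in data:
            spans.append(
                HelixSpan(
                    start=int(entry["start"]),
                    end=int(entry["end"]),
                    index=int(entry.get("index", 0)),
                )
            )
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                idx_str, span_str = line.split(None, 1)
                start_str, end_str = span_str.strip().split("-")
                spans.append(
                    HelixSpan(
                        start=int(start_str), end=int(end_str), index=int(idx_str)
                    )
                )
            except ValidationError:
                raise
            except Exception:
                raise ParseError(
                    f"{path}:{lineno}: expected '<helix> <start>-<end>', got {line!r}"
                ) from None
    if not spans:
        raise ParseError(f"{path}: no helix spans found")
    return Topology(helices=tuple(spans))


def read_structure(
    path: str | Path,
    chain: str,
    sequence: str | None = None,
) -> StructureCoords:
    """Read ATOM coordinates for one chain of a PDB file.

    Altlocs are resolved to the highest-occupancy conformer, residues
    are renumbered sequentially from 1, and hydrogens are kept but
    flagged. If ``sequence`` is given the residue count is checked
    against it.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models(), None)
    if model is None:
        raise ParseError(f"{path}: no ATOM records found")
    if chain not in [c.id for c in model]:
        raise ParseError(f"{path}: chain {chain!r} not present")
    ordered = [
        res for res in model[chain] if not res.id[0].strip()  # skip HETATM
    ]
    # keep the author residue numbers when they are usable as 1-based
    # sequence indices (unique, increasing, positive); otherwise fall
    # back to sequential renumbering
    resseq = [res.id[1] for res in ordered]
    keep_numbers = (
        all(i >= 1 for i in resseq)
        and resseq == sorted(resseq)
        and len(set(resseq)) == len(resseq)
        and all(not res.id[2].strip() for res in ordered)
    )
    residues: dict[int, tuple[Atom, ...]] = {}
    idx = 0
    for res in ordered:
        idx = res.id[1] if keep_numbers else idx + 1
        atoms = []
        for atom in res:
            # Bio.PDB selects the highest-occupancy altloc conformer.
            if atom.is_disordered():
                atom = atom.selected_child
            x, y, z = atom.coord
            atoms.append(
                Atom(
                    name=atom.get_name(),
                    element=(atom.element or "").strip() or atom.get_name()[0],
                    x=float(x),
                    y=float(y),
                    z=float(z),
                )
            )
        residues[idx] = tuple(atoms)
    if not residues:
        raise ParseError(f"{path}: chain {chain!r} has no ATOM records")
    if sequence is not None and idx > len(sequence):
        raise ValidationError(
            f"{path}: chain {chain!r} has {idx} residues but sequence length "
            f"is {len(sequence)}"
        )
    return StructureCoords(residues=residues)


def read_lipid_fractions(path: str | Path) -> LipidFractionTable:
    """Read a tab-separated ``<residue_index>\\t<fraction>`` table."""
    fractions: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                idx_str, frac_str = line.split()
                fractions[int(idx_str)] = float(frac_str)
            except Exception:
                raise ParseError(
                    f"{path}:{lineno}: expected '<residue>\\t<fraction>', got {line!r}"
                ) from None
    return LipidFractionTable(fractions=fractions)


# ---------------------------------------------------------------------------
# Result output
# ---------------------------------------------------------------------------

def write_predictions(
    predictions: Sequence[tuple[int, int, float, bool]],
    path: str | Path,
) -> None:
    """Write contact predictions as versioned, deterministic JSON.

    Each prediction is a ``(res_i, res_j, score, label)`` tuple.
    """
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "contact_predictions",
        "predictions": [
            {"res_i": int(i), "res_j": int(j), "score": float(s), "label": bool(l)}
            for i, j, s, l in predictions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_predictions(path: str | Path) -> list[tuple[int, int, float, bool]]:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "contact_predictions":
        raise ParseError(f"{path}: not a contact-prediction file")
    return [
        (p["res_i"], p["res_j"], p["score"], p["label"])
        for p in payload["predictions"]
    ]


def write_arrangement_json(arrangement_dict: dict, path: str | Path) -> None:
    """Write an arrangement (as produced by ``Arrangement.to_dict``)."""
    payload = {"format_version": FORMAT_VERSION, "kind": "arrangement"}
    payload.update(arrangement_dict)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_arrangement_json(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "arrangement":
        raise ParseError(f"{path}: not an arrangement file")
    return payload


def write_arrangement_svg(
    positions: Mapping[int, tuple[float, float]],
    edges: Iterable[tuple[int, int]],
    path: str | Path,
    radius: float = 2.3,
    annotations: Mapping[int, str] | None = None,
) -> None:
    """Render a packing arrangement as SVG: one circle per helix,
    one line per interaction edge, optional per-helix labels."""
    xs = [p[0] for p in positions.values()]
    ys = [p[1] for p in positions.values()]
    pad = 3 * radius
    x0, x1 = min(xs) - pad, max(xs) + pad
    y0, y1 = min(ys) - pad, max(ys) + pad
    buf = io.StringIO()
    buf.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{x0:.2f} {y0:.2f} {x1 - x0:.2f} {y1 - y0:.2f}">\n'
    )
    for a, b in sorted(edges):
        (ax, ay), (bx, by) = positions[a], positions[b]
        buf.write(
            f'<line x1="{ax:.2f}" y1="{ay:.2f}" x2="{bx:.2f}" y2="{by:.2f}" '
            f'stroke="black" stroke-width="0.2"/>\n'
        )
    for h in sorted(positions):
        x, y = positions[h]
        buf.write(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{radius:.2f}" '
            f'fill="none" stroke="steelblue" stroke-width="0.3"/>\n'
        )
        label = annotations.get(h, str(h)) if annotations else str(h)
        buf.write(
            f'<text x="{x:.2f}" y="{y:.2f}" font-size="{radius:.2f}" '
            f'text-anchor="middle">{label}</text>\n'
        )
    buf.write("</svg>\n")
    Path(path).write_text(buf.getvalue())


def write_topology(topology: Topology, path: str | Path) -> None:
    """Write helix spans in the plain-text dialect of :func:`read_topology`."""
    lines = [f"{h.index} {h.start}-{h.end}" for h in topology.helices]
    Path(path).write_text("\n".join(lines) + "\n")


def write_lipid_fractions(table: LipidFractionTable, path: str | Path) -> None:
    lines = [f"{idx}\t{table.fractions[idx]:.6f}" for idx in sorted(table.fractions)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[k : k + 60] + "\n")


def write_pdb(
    coords: StructureCoords,
    path: str | Path,
    chain: str = "A",
    sequence: str | None = None,
) -> None:
    """Write coordinates as minimal PDB ATOM records (one chain)."""
    three = {
        "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
        "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
        "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
        "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    }
    lines = []
    serial = 1
    for res_idx in sorted(coords.residues):
        letter = sequence[res_idx - 1] if sequence else "A"
        resname = three.get(letter, "UNK")
        for atom in coords.residues[res_idx]:
            name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{resname:>3s} {chain}"
                f"{res_idx:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pssm(profile: SequenceProfile, sequence: str, path: str | Path) -> None:
    """Write a profile in the ASCII PSSM dialect :func:`read_pssm` reads.

    Used by the synthetic generator; round-trips exactly for integer
    profiles and to 4 decimals otherwise.
    """
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(AMINO_ACIDS),
    ]
    for i, row in enumerate(profile.scores):
        aa = sequence[i] if i < len(sequence) else "X"
        cells = " ".join(f"{v:7.4f}" if v != int(v) else f"{int(v):4d}" for v in row)
        extra = " ".join("0" for _ in range(20))  # percentage block placeholder
        lines.append(f"{i + 1:5d} {aa} {cells} {extra} 0.00 0.00")
    lines.append("")
    lines.append("                      K         Lambda")
    lines.append("Standard Ungapped    0.1        0.3")
    Path(path).write_text("\n".join(lines) + "\n")
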