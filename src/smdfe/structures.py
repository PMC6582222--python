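"""XYZ stationary-point structures and interatomic-distance reports.

Stationary points along the adenine→guanine pathway (reactant complexes,
intermediates I1…I6, transition states TS1…TS6) are exchanged as standard
XYZ files: an atom-count line, a comment line, then ``element x y z`` rows
in Å.  Published geometry narratives refer to atoms by label (O21, C6, H23…)
rather than file index, so a label→index sidecar map (CSV with 1-based
indices) translates between the two.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "distance",
    "geometry_report",
    "read_label_map",
]


class XYZParseError(ValueError):
    """Malformed XYZ input; the message carries the offending line number."""


@dataclass
class Structure:
    """A named set of atoms with Cartesian coordinates in Å."""

    name: str
    elements: list[str]
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coordinates disagree on atom count")
        if self.coords.shape[0] < 1:
            raise ValueError("a structure needs at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])


def read_xyz(source) -> Structure:
    """Parse one structure from an XYZ file path, stream or string."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        with open(source) as fh:
            lines = fh.read().splitlines()
    elif isinstance(source, str):
        lines = source.splitlines()
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        raise TypeError(f"cannot read XYZ from {type(source)!r}")
    if not lines:
        raise XYZParseError("line 1: empty XYZ input")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise XYZParseError(f"line 1: expected an atom count, got {lines[0]!r}") from None
    if n < 1:
        raise XYZParseError(f"line 1: atom count must be >= 1, got {n}")
    if len(lines) < n + 2:
        raise XYZParseError(
            f"line {len(lines)}: file ends after {max(len(lines) - 2, 0)} atom rows, "
            f"{n} declared"
        )
    comment = lines[1].strip()
    elements, coords = [], []
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise XYZParseError(f"line {lineno}: expected 'element x y z', got {lines[k + 2]!r}")
        try:
            xyz = [float(v) for v in parts[1:4]]
        except ValueError:
            raise XYZParseError(f"line {lineno}: non-numeric coordinate in {lines[k + 2]!r}") from None
        elements.append(parts[0])
        coords.append(xyz)
    return Structure(name=comment, elements=elements, coords=np.array(coords))


def write_xyz(structure: Structure, target) -> None:
    """Write a structure as XYZ with 6-decimal coordinates."""
    lines = [str(structure.n_atoms), structure.name]
    for el, (x, y, z) in zip(structure.elements, structure.coords):
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    text = "\n".join(lines) + "\n"
    if isinstance(target, (str, Path)):
        Path(target).write_text(text)
    else:
        target.write(text)


def distance(structure: Structure, a: int, b: int) -> float:
    """Euclidean distance (Å) between atoms ``a`` and ``b`` (0-based)."""
    n = structure.n_atoms
    for idx in (a, b):
        if not 0 <= idx < n:
            raise IndexError(f"atom index {idx} outside [0, {n})")
    if a == b:
        raise ValueError(f"distance requires two distinct atoms, got {a} twice")
    d = structure.coords[a] - structure.coords[b]
    return float(np.sqrt(d @ d))


def geometry_report(
    structure: Structure,
    pairs: Sequence[tuple[int, int]],
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """One row per requested atom pair: label, indices, distance (2 decimals).

    Duplicated pairs yield duplicated rows; ``labels`` (index→name) feeds the
    human-readable pair label, defaulting to element+1-based-index.
    """

    def atom_name(i: int) -> str:
        if labels and i in labels:
            return labels[i]
        return f"{structure.elements[i]}{i + 1}"

    rows = []
    for a, b in pairs:
        d = distance(structure, a, b)
        rows.append(
            {
                "label": f"d({atom_name(a)}-{atom_name(b)})",
                "a": a,
                "b": b,
                "distance": round(d, 2),
            }
        )
    return pd.DataFrame(rows, columns=["label", "a", "b", "distance"])


def read_label_map(path) -> dict[str, int]:
    """Read a ``label,index`` CSV (1-based indices) into a label→0-based map."""
    df = pd.read_csv(path)
    missing = [c for c in ("label", "index") if c not in df.columns]
    if missing:
        raise ValueError(f"label map is missing column(s): {', '.join(missing)}")
    return {str(r["label"]): int(r["index"]) - 1 for _, r in df.iterrows()}
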