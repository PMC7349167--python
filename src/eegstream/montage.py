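"""Electrode montages on a square scalp grid.

An EEG cap is described here as a *montage*: an assignment of each electrode
channel to one cell of a ``d x d`` grid that preserves the left/right and
anterior/posterior neighbourhood relations of the physical cap.  Row 0 is the
frontal (Fp) row; columns run left to right.  A single time sample of all
channels placed on this grid is a :class:`SparseFrame` — zero everywhere except
at electrode cells.

Montages are data, not code: the bundled 32-channel DEAP layout ships as a
plain TSV table (one electrode per line: channel index, row, col, optional
name) and any other cap can be supplied in the same format via
:func:`read_montage`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "Placement",
    "ElectrodeMontage",
    "SparseFrame",
    "default_deap_montage",
    "grid_side_of",
    "place_vector",
    "read_montage",
    "write_montage",
]


@dataclass(frozen=True)
class Placement:
    """One electrode: 1-based channel index at a 0-based (row, col) grid cell."""

    channel: int
    row: int
    col: int
    name: Optional[str] = None


@dataclass(frozen=True)
class ElectrodeMontage:
    """Assignment of ``n_electrodes`` channels to distinct cells of a square grid.

    Channel indices are 1-based externally (matching the conventional cap
    numbering); they are converted to 0-based positions only at array
    boundaries.
    """

    placements: tuple[Placement, ...]
    grid_side: int

    def __post_init__(self) -> None:
        if not self.placements:
            raise ValueError("montage must contain at least one electrode")
        if self.grid_side < 1:
            raise ValueError("grid_side must be a positive integer")
        cells = [(p.row, p.col) for p in self.placements]
        if len(set(cells)) != len(cells):
            raise ValueError("two electrodes share a grid cell")
        for p in self.placements:
            if not (0 <= p.row < self.grid_side and 0 <= p.col < self.grid_side):
                raise ValueError(
                    f"channel {p.channel} at ({p.row}, {p.col}) lies outside the "
                    f"{self.grid_side}x{self.grid_side} grid"
                )
        chans = sorted(p.channel for p in self.placements)
        if chans != list(range(1, len(chans) + 1)):
            raise ValueError(
                "channel indices must be exactly 1..n_electrodes with no gaps"
            )

    @property
    def n_electrodes(self) -> int:
        return len(self.placements)

    def by_channel(self) -> tuple[Placement, ...]:
        """Placements sorted by channel index."""
        return tuple(sorted(self.placements, key=lambda p: p.channel))

    def grid_coords(self) -> np.ndarray:
        """(n_electrodes, 2) float array of (row, col) cell coordinates, channel order."""
        return np.array([[p.row, p.col] for p in self.by_channel()], dtype=float)


@dataclass
class SparseFrame:
    """One time sample placed on the montage grid.

    ``values`` is zero wherever ``occupied`` is False; the number of occupied
    cells equals the montage's electrode count.
    """

    values: np.ndarray
    occupied: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if self.values.shape != self.occupied.shape or self.values.ndim != 2:
            raise ValueError("values and occupied must be identical 2-D grids")
        if np.any(self.values[~self.occupied] != 0.0):
            raise ValueError("values must be zero on unoccupied cells")


def _montage_from_rows(
    rows: Iterable[tuple[int, int, int, Optional[str]]],
    grid_side: Optional[int] = None,
) -> ElectrodeMontage:
    placements = tuple(Placement(int(c), int(r), int(k), n) for c, r, k, n in rows)
    if not placements:
        raise ValueError("montage must contain at least one electrode")
    if grid_side is None:
        grid_side = max(max(p.row for p in placements), max(p.col for p in placements)) + 1
    return ElectrodeMontage(placements=placements, grid_side=grid_side)


def default_deap_montage() -> ElectrodeMontage:
    """The 32-channel DEAP cap on a 9x9 grid.

    Only the seven electrode names that are unambiguous for this layout are
    attached (CP1, PO3, Oz, Pz, Fp2, CP2, PO4); other channels are positional
    only.
    """
    ref = importlib.resources.files("eegstream.data") / "deap_9x9.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_montage(path)


def read_montage(path: Union[str, Path]) -> ElectrodeMontage:
    """Read a montage from a TSV table (channel, row, col[, name]); '#' comments."""
    rows: list[tuple[int, int, int, Optional[str]]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed montage line: {line!r}")
        name = parts[3].strip() if len(parts) > 3 and parts[3].strip() else None
        rows.append((int(parts[0]), int(parts[1]), int(parts[2]), name))
    return _montage_from_rows(rows)


def write_montage(montage: ElectrodeMontage, path: Union[str, Path]) -> None:
    """Write a montage as the plain TSV table understood by :func:`read_montage`."""
    lines = ["# columns: channel\trow\tcol\tname (optional)"]
    for p in montage.by_channel():
        lines.append(f"{p.channel}\t{p.row}\t{p.col}" + (f"\t{p.name}" if p.name else ""))
    Path(path).write_text("\n".join(lines) + "\n")


def grid_side_of(montage: ElectrodeMontage) -> int:
    """Grid side d = max(max_row, max_col) + 1 over the placements."""
    if not montage.placements:
        raise ValueError("montage has no placements")
    return max(
        max(p.row for p in montage.placements),
        max(p.col for p in montage.placements),
    ) + 1


def place_vector(v: Sequence[float], montage: ElectrodeMontage) -> SparseFrame:
    """Scatter one time sample of channel values onto the montage grid.

    ``v[i]`` (0-based) is the value of channel ``i+1``; it lands at that
    channel's (row, col) cell.  All other cells are zero and unoccupied.
    """
    v = np.asarray(v, dtype=float).ravel()
    if v.size != montage.n_electrodes:
        raise ValueError(
            f"channel count mismatch: montage expects {montage.n_electrodes} "
            f"values, got {v.size}"
        )
    d = montage.grid_side
    values = np.zeros((d, d))
    occupied = np.zeros((d, d), dtype=bool)
    for p in montage.by_channel():
        values[p.row, p.col] = v[p.channel - 1]
        occupied[p.row, p.col] = True
    return SparseFrame(values=values, occupied=occupied)


def frame_to_vector(frame: SparseFrame, montage: ElectrodeMontage) -> np.ndarray:
    """Read electrode cells back into a channel-ordered vector (inverse of place_vector)."""
    return np.array([frame.values[p.row, p.col] for p in montage.by_channel()])
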