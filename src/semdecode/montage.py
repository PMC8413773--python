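"""Electrode montage: names, 2-D layout positions, and explicit neighbor lists.

Adjacency is data, not computed geometry: a montage file lists each
electrode's neighbors, and searchlight groups are a central electrode plus
its immediate neighbors.  A built-in 32-channel 10–20 layout is provided for
synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = ["Montage", "standard_montage_32", "read_montage_json", "write_montage_json"]


@dataclass(frozen=True)
class Montage:
    names: tuple[str, ...]
    positions: dict  # name -> (x, y)
    neighbors: dict  # name -> tuple of neighbor names

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("electrode names must be unique")
        for e in self.names:
            if e not in self.positions:
                raise ValueError(f"no position for electrode {e}")
            nbrs = self.neighbors.get(e, ())
            if len(nbrs) < 1:
                raise ValueError(f"electrode {e} has no neighbors")
            for n in nbrs:
                if n not in self.names:
                    raise ValueError(f"unknown neighbor {n} of {e}")
                if e not in self.neighbors.get(n, ()):
                    raise ValueError(f"neighbor relation not symmetric: {e} ~ {n}")

    def group(self, electrode: str) -> list[str]:
        """Searchlight group: the central electrode plus its neighbors."""
        if electrode not in self.names:
            raise ValueError(f"unknown electrode {electrode}")
        return [electrode, *self.neighbors[electrode]]

    def validate_covers(self, electrodes) -> None:
        missing = [e for e in electrodes if e not in self.names]
        if missing:
            raise ValueError(f"montage is missing electrodes: {missing}")


# 32-channel 10-20 layout (extended Brain Products style).  x: left(-)/right(+),
# y: front(+)/back(-); unitless layout coordinates for topographic export.
_POSITIONS_32 = {
    "Fp1": (-0.30, 0.90), "Fp2": (0.30, 0.90),
    "F7": (-0.80, 0.55), "F3": (-0.40, 0.55), "Fz": (0.00, 0.55),
    "F4": (0.40, 0.55), "F8": (0.80, 0.55),
    "FC5": (-0.60, 0.28), "FC1": (-0.20, 0.28), "FC2": (0.20, 0.28), "FC6": (0.60, 0.28),
    "T7": (-0.95, 0.00), "C3": (-0.45, 0.00), "Cz": (0.00, 0.00),
    "C4": (0.45, 0.00), "T8": (0.95, 0.00),
    "TP9": (-1.00, -0.30), "CP5": (-0.60, -0.28), "CP1": (-0.20, -0.28),
    "CP2": (0.20, -0.28), "CP6": (0.60, -0.28), "TP10": (1.00, -0.30),
    "P7": (-0.80, -0.55), "P3": (-0.40, -0.55), "Pz": (0.00, -0.55),
    "P4": (0.40, -0.55), "P8": (0.80, -0.55),
    "PO9": (-0.65, -0.80), "O1": (-0.30, -0.85), "Oz": (0.00, -0.90),
    "O2": (0.30, -0.85), "PO10": (0.65, -0.80),
}


def standard_montage_32(neighbor_radius: float = 0.55) -> Montage:
    """The built-in 32-channel layout; electrodes within ``neighbor_radius``
    (layout units) of each other are neighbors."""
    names = tuple(_POSITIONS_32)
    neighbors = {}
    for e in names:
        xe, ye = _POSITIONS_32[e]
        nbrs = []
        for f in names:
            if f == e:
                continue
            xf, yf = _POSITIONS_32[f]
            if (xe - xf) ** 2 + (ye - yf) ** 2 <= neighbor_radius**2:
                nbrs.append(f)
        neighbors[e] = tuple(nbrs)
    return Montage(names=names, positions=dict(_POSITIONS_32), neighbors=neighbors)


def read_montage_json(path) -> Montage:
    with open(path) as fh:
        obj = json.load(fh)
    return Montage(
        names=tuple(obj["names"]),
        positions={k: tuple(v) for k, v in obj["positions"].items()},
        neighbors={k: tuple(v) for k, v in obj["neighbors"].items()},
    )


def write_montage_json(montage: Montage, path) -> None:
    obj = {
        "names": list(montage.names),
        "positions": {k: list(v) for k, v in montage.positions.items()},
        "neighbors": {k: list(v) for k, v in montage.neighbors.items()},
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
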