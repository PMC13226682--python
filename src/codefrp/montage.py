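"""Electrode montage: channel names, schematic 2-D positions, topographies.

The recording montage mirrors a 28-channel 10-20 cap (including A2), four
EOG electrodes around the eyes, and two mastoid electrodes. The left
mastoid (``M1``) is the implicit online reference, so its recorded trace is
identically zero until re-referencing.

2-D positions are an azimuthal-equidistant projection of the standard
10-20 sphere (vertex at the origin, nose up, radius 1 at the lower 10%
ring), frozen here so that adjacency and topography are reproducible
without any external montage file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.spatial import Delaunay

#: 28 scalp channels, in recording order.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC3", "FCz", "FC4", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP3", "CPz", "CP4",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "A2",
)

EOG_CHANNELS: tuple[str, ...] = ("EOG1", "EOG2", "EOG3", "EOG4")
MASTOID_CHANNELS: tuple[str, ...] = ("M1", "M2")

#: Full recorded channel set, in order.
ALL_CHANNELS: tuple[str, ...] = SCALP_CHANNELS + EOG_CHANNELS + MASTOID_CHANNELS

#: Electrodes dropped from the cluster analysis (no effect expected there).
DEFAULT_EXCLUDED: frozenset[str] = frozenset({"T7", "T8", "O1", "O2"})

#: Channels never entering artifact screening (ocular + reference electrodes).
ARTIFACT_EXEMPT: frozenset[str] = frozenset(EOG_CHANNELS) | frozenset(MASTOID_CHANNELS)

#: Schematic 2-D scalp positions (azimuthal-equidistant projection).
POSITIONS_2D: dict[str, tuple[float, float]] = {
    "Fp1": (-0.3475, 0.9907), "Fp2": (0.3485, 0.9905),
    "F7": (-0.9311, 0.5628), "F3": (-0.4582, 0.4844), "Fz": (0.0025, 0.4596),
    "F4": (0.4716, 0.4940), "F8": (0.9303, 0.5657),
    "FC5": (-0.7872, 0.1901), "FC3": (-0.5113, 0.1930), "FCz": (0.0026, 0.1907),
    "FC4": (0.5208, 0.1983), "FC6": (0.7911, 0.1983),
    "T7": (-1.0503, -0.1999), "C3": (-0.5020, -0.0893), "Cz": (0.0025, -0.0581),
    "C4": (0.5146, -0.0836), "T8": (1.0534, -0.1860),
    "CP3": (-0.4494, -0.3324), "CPz": (0.0023, -0.2828), "CP4": (0.4652, -0.3257),
    "P7": (-0.7129, -0.7230), "P3": (-0.3690, -0.5485), "Pz": (0.0020, -0.4942),
    "P4": (0.3827, -0.5400), "P8": (0.7181, -0.7182),
    "O1": (-0.2408, -0.9207), "O2": (0.2447, -0.9198), "A2": (1.3577, -0.3958),
}


def analysis_channels(excluded: frozenset[str] | set[str] = DEFAULT_EXCLUDED) -> list[str]:
    """Scalp channels entering the cluster analysis, in montage order."""
    return [c for c in SCALP_CHANNELS if c not in excluded]


def _gaussian_weights(center: tuple[float, float], sigma: float) -> dict[str, float]:
    cx, cy = center
    w = {}
    for ch, (x, y) in POSITIONS_2D.items():
        w[ch] = float(np.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * sigma**2)))
    peak = max(w.values())
    return {ch: v / peak for ch, v in w.items()}


def frontal_topography(sigma: float = 0.55) -> dict[str, float]:
    """Per-channel weights in [0, 1] peaking at Fz (midline frontal)."""
    return _gaussian_weights(POSITIONS_2D["Fz"], sigma)


def occipital_topography(sigma: float = 0.45) -> dict[str, float]:
    """Per-channel weights peaking between O1 and O2, for the early
    fixation-locked (lambda-like) deflection."""
    return _gaussian_weights((0.0, -0.92), sigma)


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric electrode neighbourhood graph (no self-loops)."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)  # sorted pairs

    def __post_init__(self) -> None:
        nodeset = set(self.nodes)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on {a}")
            if a not in nodeset or b not in nodeset:
                raise ValueError(f"edge ({a},{b}) references unknown electrode")

    def neighbors(self, node: str) -> set[str]:
        return {b if a == node else a for a, b in self.edges if node in (a, b)}

    def has_edge(self, a: str, b: str) -> bool:
        return tuple(sorted((a, b))) in self.edges

    def without(self, excluded: set[str] | frozenset[str]) -> "AdjacencyGraph":
        nodes = tuple(n for n in self.nodes if n not in excluded)
        edges = frozenset(e for e in self.edges if e[0] not in excluded and e[1] not in excluded)
        return AdjacencyGraph(nodes, edges)


def build_adjacency(
    positions: dict[str, tuple[float, float]] | None = None,
    excluded: set[str] | frozenset[str] = DEFAULT_EXCLUDED,
    prune_factor: float = 1.5,
) -> AdjacencyGraph:
    """Derive the electrode adjacency from 2-D positions.

    Delaunay triangulation of the scalp positions, with edges longer than
    ``prune_factor`` times the median edge length removed (those connect
    across the head rim), then removal of ``excluded`` electrodes.
    """
    if positions is None:
        positions = POSITIONS_2D
    names = sorted(positions)
    unknown = set(names) - set(POSITIONS_2D) if positions is not POSITIONS_2D else set()
    if unknown:
        raise ValueError(f"unknown electrodes: {sorted(unknown)}")
    pts = np.array([positions[n] for n in names])
    tri = Delaunay(pts)
    raw: set[tuple[int, int]] = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            raw.add((min(a, b), max(a, b)))
    lengths = {e: float(np.linalg.norm(pts[e[0]] - pts[e[1]])) for e in raw}
    cutoff = prune_factor * float(np.median(list(lengths.values())))
    edges = frozenset(
        tuple(sorted((names[a], names[b])))
        for (a, b), length in lengths.items()
        if length <= cutoff
    )
    return AdjacencyGraph(tuple(names), edges).without(excluded)


def load_default_adjacency(
    excluded: set[str] | frozenset[str] = DEFAULT_EXCLUDED,
) -> AdjacencyGraph:
    """Load the shipped, hand-checked neighbour list and drop excluded nodes."""
    text = resources.files("codefrp.data").joinpath("adjacency_1020.json").read_text()
    payload = json.loads(text)
    nodes = tuple(payload["nodes"])
    edges = frozenset(tuple(sorted(e)) for e in payload["edges"])
    return AdjacencyGraph(nodes, edges).without(excluded)
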