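"""Per-frame persistence of alpha-carbon clouds and cycle tracking.

The growing-balls filtration over one frame's CA point cloud yields finite
intervals in dimension 1 (loops) and 2 (voids), each annotated with the
residues of a representative cycle.  A *cycle identity* — the homology
dimension together with the representative residue set — links intervals
of the same structural feature across frames of one protein and between
the control and case proteins.  Two filters, applied to a matched
control/case pair of tracks, keep only cycles that are observed at least
``min_obs`` times in both proteins and first appear within the first
``first_steps`` frames in both; those are the cycles with enough
observations for a proper posterior and present from the start of the
sampled trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._persistence import persistence
from .ensemble import PointCloud, ResidueKey, residue_sort_key
from .errors import DegenerateInputError


@dataclass(frozen=True)
class PersistenceInterval:
    """One finite homology feature of one frame.

    ``birth`` and ``death`` are filtration values in angstroms (ball
    radius by default); ``representative`` is the residue set of the cycle
    created at birth.
    """

    dimension: int
    birth: float
    death: float
    representative: frozenset[ResidueKey]

    def __post_init__(self) -> None:
        if self.dimension not in (1, 2):
            raise ValueError("dimension must be 1 or 2")
        if not (self.death > self.birth >= 0):
            raise ValueError("need death > birth >= 0")
        if len(self.representative) < self.dimension + 2:
            raise ValueError("representative too small for its dimension")

    @property
    def lifespan(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True)
class CycleIdentity:
    """What makes a cycle 'the same' across frames and across proteins."""

    dimension: int
    residues: frozenset[ResidueKey]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty residue set")

    def sort_key(self):
        return (self.dimension, tuple(sorted(self.residues, key=residue_sort_key)))

    def label(self) -> str:
        res = ";".join(f"{c}:{r}" for c, r in
                       sorted(self.residues, key=residue_sort_key))
        return f"H{self.dimension}[{res}]"


@dataclass
class CycleTrack:
    """Time series of (birth, lifespan) observations for one cycle identity.

    ``frames`` are 1-based frame indices, strictly increasing; row ``i`` of
    ``observations`` is ``(b_t, l_t)`` for ``frames[i]``.
    """

    identity: CycleIdentity
    frames: list[int]
    observations: np.ndarray  # (n_obs, 2): birth, lifespan

    def __post_init__(self) -> None:
        self.observations = np.asarray(self.observations, dtype=float).reshape(-1, 2)
        if len(self.frames) != len(self.observations):
            raise ValueError("frames and observations length mismatch")
        if any(b >= a for a, b in zip(self.frames[1:], self.frames)):
            raise ValueError("frame indices must be strictly increasing")
        if len(self.observations) and (self.observations[:, 1] <= 0).any():
            raise ValueError("lifespans must be positive")

    @property
    def n_obs(self) -> int:
        return len(self.frames)

    @property
    def first_frame(self) -> int:
        return self.frames[0]


def compute_persistence(
    cloud: PointCloud,
    max_dimension: int = 2,
    filtration: str = "alpha",
    scale: str = "radius",
    min_persistence: float = 1e-9,
) -> list[PersistenceInterval]:
    """All finite loop/void intervals of one frame's point cloud.

    ``filtration`` selects the complex ("alpha" is exact for growing balls
    in 3-D and fast; "rips" uses pairwise distances only). ``scale``
    selects the units of birth/death: ball "radius" or "diameter".
    Intervals with lifespan below ``min_persistence`` (round-off from tied
    filtration values) are dropped.
    """
    minimum = 4 if max_dimension == 2 else 3
    if len(cloud) < minimum:
        raise DegenerateInputError(
            f"{len(cloud)} points; need >= {minimum} for dimension {max_dimension}")
    raw = persistence(cloud.coords, max_dimension=max_dimension,
                      filtration=filtration, scale=scale,
                      min_persistence=min_persistence)
    keys = cloud.residue_keys
    return [
        PersistenceInterval(dim, birth, death,
                            frozenset(keys[v] for v in verts))
        for dim, birth, death, verts in raw
    ]


def track_cycles(
    per_frame_intervals: Sequence[Sequence[PersistenceInterval]],
    start_frame: int = 1,
) -> list[CycleTrack]:
    """Group per-frame intervals into tracks by exact cycle identity.

    If one frame contributes several intervals with the same identity, the
    most persistent one (largest lifespan) is kept so that each track has
    at most one observation per frame.
    """
    acc: dict[CycleIdentity, dict[int, PersistenceInterval]] = {}
    for offset, intervals in enumerate(per_frame_intervals):
        t = start_frame + offset
        for iv in intervals:
            ident = CycleIdentity(iv.dimension, iv.representative)
            per_frame = acc.setdefault(ident, {})
            old = per_frame.get(t)
            if old is None or iv.lifespan > old.lifespan:
                per_frame[t] = iv
    tracks = []
    for ident in sorted(acc, key=CycleIdentity.sort_key):
        frames = sorted(acc[ident])
        obs = np.array([[acc[ident][t].birth, acc[ident][t].lifespan]
                        for t in frames])
        tracks.append(CycleTrack(ident, frames, obs))
    return tracks


def match_and_filter(
    control_tracks: Iterable[CycleTrack],
    case_tracks: Iterable[CycleTrack],
    min_obs: int = 5,
    first_steps: int = 5,
) -> list[tuple[CycleTrack, CycleTrack]]:
    """Pair control and case tracks of equal identity and apply the
    observation-count and first-appearance filters to both sides."""
    by_id = {t.identity: t for t in control_tracks}
    pairs = []
    for case in case_tracks:
        control = by_id.get(case.identity)
        if control is None:
            continue
        if control.n_obs < min_obs or case.n_obs < min_obs:
            continue
        if control.first_frame > first_steps or case.first_frame > first_steps:
            continue
        pairs.append((control, case))
    pairs.sort(key=lambda pair: pair[0].identity.sort_key())
    return pairs


def cycle_statistics(
    tracks_by_protein: Mapping[str, Sequence[CycleTrack]],
    detected: Mapping[tuple[str, str], Sequence] | None = None,
) -> dict[str, pd.DataFrame]:
    """Summary tables over one or more proteins' cycle tracks.

    Returns four tables: ``cycles_per_protein`` (count of distinct cycle
    identities per protein), ``residue_participation`` (for each protein,
    how many of its cycles each residue belongs to), ``shared_cycles``
    (protein x protein matrix of identities observed in both), and
    ``detected_variations`` (protein x protein matrix of cycles flagged as
    structurally variable; requires ``detected``, a mapping from protein
    pairs to score results with a ``detected`` attribute).
    """
    proteins = list(tracks_by_protein)
    rows = [{"protein": p, "n_cycles": len(tracks_by_protein[p])} for p in proteins]
    per_protein = pd.DataFrame(rows, columns=["protein", "n_cycles"])

    part_rows = []
    for p in proteins:
        counts: dict[ResidueKey, int] = {}
        for track in tracks_by_protein[p]:
            for key in track.identity.residues:
                counts[key] = counts.get(key, 0) + 1
        for key in sorted(counts, key=residue_sort_key):
            part_rows.append({"protein": p, "chain": key[0], "resid": key[1],
                              "n_cycles": counts[key]})
    participation = pd.DataFrame(
        part_rows, columns=["protein", "chain", "resid", "n_cycles"])

    shared = pd.DataFrame(0, index=proteins, columns=proteins, dtype=int)
    ids = {p: {t.identity for t in tracks_by_protein[p]} for p in proteins}
    for a in proteins:
        for b in proteins:
            shared.loc[a, b] = len(ids[a] & ids[b])

    detections = pd.DataFrame(0, index=proteins, columns=proteins, dtype=int)
    if detected:
        for (a, b), results in detected.items():
            n = sum(1 for r in results if getattr(r, "detected", False))
            if a in proteins and b in proteins:
                detections.loc[a, b] += n
                detections.loc[b, a] += n

    return {
        "cycles_per_protein": per_protein,
        "residue_participation": participation,
        "shared_cycles": shared,
        "detected_variations": detections,
    }


def intervals_to_frame(
    per_frame_intervals: Sequence[Sequence[PersistenceInterval]],
    start_frame: int = 1,
) -> pd.DataFrame:
    """Flatten per-frame intervals into the export table
    (frame, dimension, birth, death, residues)."""
    rows = []
    for offset, intervals in enumerate(per_frame_intervals):
        for iv in intervals:
            residues = ";".join(
                f"{c}:{r}" for c, r in sorted(iv.representative,
                                              key=residue_sort_key))
            rows.append({"frame": start_frame + offset, "dimension": iv.dimension,
                         "birth": iv.birth, "death": iv.death,
                         "residues": residues})
    return pd.DataFrame(rows, columns=["frame", "dimension", "birth",
                                       "death", "residues"])
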