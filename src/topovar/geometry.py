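"""Rigid superposition and RMSD utilities for cycle substructures.

Used to corroborate topological detections in Cartesian terms: extract
the residues of a cycle from every frame, build an average structure by
iterative superposition, and profile per-frame RMSDs of each protein's
conformations against that average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ensemble import ConformationalEnsemble, ResidueKey


@dataclass
class SubStructure:
    """Ordered residue keys with one 3-D coordinate each (angstroms)."""

    residue_keys: tuple[ResidueKey, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.residue_keys = tuple((str(c), str(r)) for c, r in self.residue_keys)
        self.coords = np.asarray(self.coords, dtype=float).reshape(
            len(self.residue_keys), 3)
        if len(self.residue_keys) < 3:
            raise ValueError("need at least 3 points for rigid superposition")


def kabsch_superpose(mobile: SubStructure,
                     reference: SubStructure) -> tuple[SubStructure, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns the transformed copy of ``mobile`` and the minimised RMSD.
    Only proper rotations are allowed (no reflection).
    """
    if mobile.residue_keys != reference.residue_keys:
        raise ValueError("substructures must share the same ordered residue keys")
    X = mobile.coords - mobile.coords.mean(axis=0)
    Y = reference.coords - reference.coords.mean(axis=0)
    H = X.T @ Y
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    moved = X @ R + reference.coords.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference.coords) ** 2, axis=1))))
    return SubStructure(mobile.residue_keys, moved), rmsd


def average_structure(conformations: Sequence[SubStructure],
                      tol: float = 1e-6, max_iter: int = 50) -> SubStructure:
    """Mean conformation under iterative superposition.

    All conformations are superposed onto the running mean (initialised
    from the first conformation) and averaged, repeating until the mean
    moves less than ``tol`` angstroms RMS.
    """
    if not conformations:
        raise ValueError("need at least one conformation")
    keys = conformations[0].residue_keys
    mean = SubStructure(keys, conformations[0].coords.copy())
    for _ in range(max_iter):
        stacked = np.array(
            [kabsch_superpose(c, mean)[0].coords for c in conformations])
        new_coords = stacked.mean(axis=0)
        shift = float(np.sqrt(np.mean((new_coords - mean.coords) ** 2)))
        mean = SubStructure(keys, new_coords)
        if shift < tol:
            break
    return mean


def rmsd_profile(average: SubStructure,
                 ensembles: Mapping[str, Sequence[SubStructure]]
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame RMSDs of each protein's conformations to ``average``.

    Returns the long-form profile (protein, frame, rmsd) and a per-protein
    summary (mean, sd).
    """
    rows = []
    for protein, conformations in ensembles.items():
        for t, conf in enumerate(conformations, start=1):
            _, rmsd = kabsch_superpose(conf, average)
            rows.append({"protein": protein, "frame": t, "rmsd": rmsd})
    profile = pd.DataFrame(rows, columns=["protein", "frame", "rmsd"])
    if profile.empty:
        summary = pd.DataFrame(columns=["protein", "mean_rmsd", "sd_rmsd"])
    else:
        summary = (profile.groupby("protein", sort=False)["rmsd"]
                   .agg(mean_rmsd="mean", sd_rmsd="std")
                   .fillna(0.0).reset_index())
    return profile, summary


def extract_substructures(ensemble: ConformationalEnsemble,
                          residue_keys: Sequence[ResidueKey]
                          ) -> list[SubStructure]:
    """Pull the given residues out of every frame, in the given order."""
    index = {k: i for i, k in enumerate(ensemble.residue_keys)}
    try:
        cols = [index[(str(c), str(r))] for c, r in residue_keys]
    except KeyError as exc:
        raise KeyError(f"residue {exc.args[0]} not in ensemble") from exc
    keys = tuple((str(c), str(r)) for c, r in residue_keys)
    return [SubStructure(keys, ensemble.coords[t, cols, :])
            for t in range(ensemble.n_frames)]
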