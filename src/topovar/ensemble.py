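"""Reading and writing conformational ensembles of alpha-carbon coordinates.

An ensemble is a stack of frames (conformations) of the same molecule, each
frame carrying one point per residue: the alpha carbon (CA).  Two on-disk
representations are supported:

* multi-model PDB (``MODEL``/``ENDMDL`` blocks), read through Biopython;
* a whitespace-delimited table with columns ``frame chain resid resname x y z``.

Residues are addressed by a *residue key* ``(chain_id, resid)`` where
``resid`` is the residue sequence number with any insertion code appended
(e.g. ``"52"`` or ``"52A"``).  Keys sort by chain, then numeric residue
index, then insertion code, and that order is the canonical point order used
by every downstream stage.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, DegenerateInputError, FormatError

ResidueKey = tuple[str, str]

_RESID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


def residue_sort_key(key: ResidueKey) -> tuple[str, int, str]:
    """Sort key: chain, numeric residue index, insertion-code suffix."""
    chain, resid = key
    m = _RESID_RE.match(resid)
    if m is None:
        return (chain, 0, resid)
    return (chain, int(m.group(1)), m.group(2))


@dataclass
class ConformationalEnsemble:
    """Frames x residues CA coordinates with a shared residue table.

    Parameters
    ----------
    residue_keys : sequence of (chain_id, resid)
        One key per residue, identical for every frame.
    residue_names : sequence of str
        Three-letter residue codes aligned with ``residue_keys``.
    coords : ndarray of shape (n_frames, n_residues, 3)
        CA coordinates in angstroms.
    """

    residue_keys: tuple[ResidueKey, ...]
    residue_names: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.residue_keys = tuple((str(c), str(r)) for c, r in self.residue_keys)
        self.residue_names = tuple(str(n) for n in self.residue_names)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_residues, 3)")
        if self.coords.shape[1] != len(self.residue_keys):
            raise ValueError("coords second axis must match number of residue keys")
        if len(self.residue_names) != len(self.residue_keys):
            raise ValueError("residue_names must align with residue_keys")
        if self.coords.shape[0] < 1:
            raise ValueError("an ensemble needs at least one frame")
        if len(set(self.residue_keys)) != len(self.residue_keys):
            raise ConsistencyError("duplicate residue keys in ensemble")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        order = sorted(range(len(self.residue_keys)),
                       key=lambda i: residue_sort_key(self.residue_keys[i]))
        if order != list(range(len(order))):
            self.residue_keys = tuple(self.residue_keys[i] for i in order)
            self.residue_names = tuple(self.residue_names[i] for i in order)
            self.coords = self.coords[:, order, :]

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class ResidueMask:
    """Set of residues to exclude from the topological analysis.

    Stands in for a disorder filter: residues in flexible, poorly structured
    regions contribute spurious short-lived cycles and are removed before
    persistence is computed.
    """

    excluded: frozenset[ResidueKey] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "excluded",
            frozenset((str(c), str(r)) for c, r in self.excluded))


class PointCloud:
    """Labelled 3-D point cloud for one frame, in canonical residue order."""

    __slots__ = ("residue_keys", "coords")

    def __init__(self, residue_keys: Sequence[ResidueKey], coords: np.ndarray):
        keys = [(str(c), str(r)) for c, r in residue_keys]
        coords = np.asarray(coords, dtype=float).reshape(len(keys), 3)
        if len(set(keys)) != len(keys):
            raise ValueError("residue keys in a point cloud must be unique")
        if not np.isfinite(coords).all():
            raise ValueError("point-cloud coordinates must be finite")
        order = sorted(range(len(keys)), key=lambda i: residue_sort_key(keys[i]))
        self.residue_keys: tuple[ResidueKey, ...] = tuple(keys[i] for i in order)
        self.coords: np.ndarray = coords[order]

    def __len__(self) -> int:
        return len(self.residue_keys)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PointCloud({len(self)} points)"


# ---------------------------------------------------------------------------
# Readers


def load_ensemble(path: str | Path, format: str | None = None) -> ConformationalEnsemble:
    """Read a conformational ensemble from disk.

    Parameters
    ----------
    path : str or Path
        Input file.
    format : {"pdb", "xyz", None}
        ``"pdb"`` for multi-model PDB, ``"xyz"`` for the whitespace table.
        ``None`` guesses from the file suffix (``.pdb`` vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "pdb" if path.suffix.lower() in {".pdb", ".ent"} else "xyz"
    if format in {"pdb", "multi-model-PDB"}:
        return _load_pdb(path)
    if format in {"xyz", "xyz-table"}:
        return _load_xyz_table(path)
    raise ValueError(f"unknown ensemble format: {format!r}")


def _load_pdb(path: Path) -> ConformationalEnsemble:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("ensemble", str(path))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise FormatError(f"could not parse PDB file {path}: {exc}") from exc

    frames: list[dict[ResidueKey, tuple[str, np.ndarray]]] = []
    for model in structure:
        frame: dict[ResidueKey, tuple[str, np.ndarray]] = {}
        for chain in model:
            for residue in chain:
                hetflag, resseq, icode = residue.id
                if hetflag.strip():
                    continue
                if "CA" not in residue:
                    continue
                atom = residue["CA"]
                if atom.is_disordered():
                    # take altloc 'A' or blank, deterministically
                    alts = {a.get_altloc(): a for a in atom.disordered_get_list()}
                    atom = alts.get("A") or alts.get(" ") or alts[sorted(alts)[0]]
                resid = f"{resseq}{icode.strip()}"
                frame[(chain.id, resid)] = (residue.get_resname(),
                                            np.asarray(atom.get_coord(), dtype=float))
        frames.append(frame)
    if not frames:
        raise FormatError(f"{path}: no MODEL records or ATOM coordinates found")
    return _assemble(frames, str(path))


def _load_xyz_table(path: Path) -> ConformationalEnsemble:
    try:
        df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                         names=["frame", "chain", "resid", "resname", "x", "y", "z"],
                         dtype={"chain": str, "resid": str, "resname": str})
    except Exception as exc:
        raise FormatError(f"could not parse coordinate table {path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: empty coordinate table")
    if df[["x", "y", "z"]].isna().any().any():
        raise FormatError(f"{path}: non-numeric coordinates in table")
    frames = []
    for _, block in df.groupby("frame", sort=True):
        frame = {}
        for row in block.itertuples(index=False):
            frame[(row.chain, row.resid)] = (
                row.resname, np.array([row.x, row.y, row.z], dtype=float))
        frames.append(frame)
    return _assemble(frames, str(path))


def _assemble(frames: list[dict[ResidueKey, tuple[str, np.ndarray]]],
              source: str) -> ConformationalEnsemble:
    keys = sorted(frames[0], key=residue_sort_key)
    if not keys:
        raise FormatError(f"{source}: first frame contains no CA atoms")
    for t, frame in enumerate(frames):
        if sorted(frame, key=residue_sort_key) != keys:
            missing = set(keys) ^ set(frame)
            raise ConsistencyError(
                f"{source}: frame {t + 1} residue list differs from frame 1 "
                f"(symmetric difference: {sorted(missing)[:5]} ...)")
    names = tuple(frames[0][k][0] for k in keys)
    coords = np.array([[frame[k][1] for k in keys] for frame in frames])
    return ConformationalEnsemble(tuple(keys), names, coords)


def read_mask(path: str | Path) -> ResidueMask:
    """Read a residue-exclusion mask: one ``chain resid`` pair per line,
    ``#`` comments and blank lines ignored."""
    excluded = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'chain resid', got {raw!r}")
        excluded.add((parts[0], parts[1]))
    return ResidueMask(frozenset(excluded))


# ---------------------------------------------------------------------------
# Masking


def apply_mask(ensemble: ConformationalEnsemble,
               mask: ResidueMask | None = None) -> list[PointCloud]:
    """Drop masked residues and return one :class:`PointCloud` per frame.

    Mask entries not present in the ensemble trigger a warning; fewer than
    three surviving residues is a degenerate input (no loop can exist).
    """
    mask = mask or ResidueMask()
    present = set(ensemble.residue_keys)
    stray = mask.excluded - present
    if stray:
        warnings.warn(
            f"mask entries not found in ensemble: {sorted(stray)}", stacklevel=2)
    keep = [i for i, k in enumerate(ensemble.residue_keys) if k not in mask.excluded]
    if len(keep) < 3:
        raise DegenerateInputError(
            f"mask leaves {len(keep)} residues; at least 3 are required")
    kept_keys = [ensemble.residue_keys[i] for i in keep]
    return [PointCloud(kept_keys, ensemble.coords[t, keep, :])
            for t in range(ensemble.n_frames)]


# ---------------------------------------------------------------------------
# Writer (CA-only multi-model PDB)


def write_ensemble_pdb(ensemble: ConformationalEnsemble, path: str | Path) -> None:
    """Write a CA-only multi-model PDB file readable by :func:`load_ensemble`.

    Coordinates are rounded to the PDB fixed-point precision (3 decimals).
    """
    buf = io.StringIO()
    for t in range(ensemble.n_frames):
        buf.write(f"MODEL     {t + 1:4d}\n")
        serial = 1
        for i, (chain, resid) in enumerate(ensemble.residue_keys):
            m = _RESID_RE.match(resid)
            resseq, icode = (int(m.group(1)), m.group(2) or " ") if m else (i + 1, " ")
            x, y, z = ensemble.coords[t, i]
            name = ensemble.residue_names[i][:3].upper()
            buf.write(
                f"ATOM  {serial:5d}  CA  {name:>3s} {chain[:1]}{resseq:4d}{icode}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
            serial += 1
        buf.write("ENDMDL\n")
    buf.write("END\n")
    Path(path).write_text(buf.getvalue())


def write_mask(mask: ResidueMask, path: str | Path) -> None:
    lines = [f"{c} {r}" for c, r in sorted(mask.excluded, key=residue_sort_key)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
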