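"""Synthetic conformational ensembles with known topological ground truth.

Real input to the pipeline is an MD trajectory of a protein; for testing
and calibration this module builds ensembles of labelled 3-D points whose
loops and voids are planted by construction:

* a **ring** of evenly spaced points (a loop, dimension-1 cycle) — with
  the default 8 points and 5 angstrom radius the spacing matches the
  ~3.8 angstrom CA–CA distance of a real backbone loop;
* a **shell** of quasi-uniform points on a sphere (a void, dimension-2
  cycle), placed by the Fibonacci lattice;
* optional **background** points far from every feature, standing in for
  the rest of the chain without creating cycles of their own.

Thermal vibration is emulated as i.i.d. isotropic Gaussian jitter per
frame (default 0.3 angstroms, a typical backbone fluctuation scale in
well-structured regions), matching the i.i.d. assumption of the
downstream Bayesian model.  A control/case pair shares residue labels and
feature layout; the case may have one feature's geometry shifted (radius
and/or center), emulating a mutation-induced intrinsic change against the
backdrop of identical thermal noise.

Each feature occupies its own chain (A, B, ...; background is chain Z),
so ground-truth cycles are identified by their chain's residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .ensemble import ConformationalEnsemble

_FEATURE_KINDS = ("ring", "shell")


@dataclass(frozen=True)
class Feature:
    """One planted topological feature."""

    kind: str                      # "ring" (loop) or "shell" (void)
    n_points: int
    size: float                    # radius in angstroms
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in _FEATURE_KINDS:
            raise ValueError(f"feature kind must be one of {_FEATURE_KINDS}")
        minimum = 4 if self.kind == "ring" else 6
        if self.n_points < minimum:
            raise ValueError(f"{self.kind} needs >= {minimum} points")
        if self.size <= 0:
            raise ValueError("feature size must be positive")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic ensemble.

    Defaults mirror the sampling regime the pipeline expects from MD:
    500 saved frames and sub-angstrom thermal jitter.
    """

    n_frames: int = 500
    noise_sd: float = 0.3
    features: tuple[Feature, ...] = (Feature("ring", 8, 5.0),)
    background_points: int = 10
    seed: int = 0
    clutter: bool = False          # place background uniformly (stress test)

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.background_points < 0:
            raise ValueError("background_points must be >= 0")
        if not self.features:
            raise ValueError("at least one feature is required")
        object.__setattr__(self, "features", tuple(self.features))

    def to_json(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["features"] = [asdict(f) for f in self.features]
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "SyntheticSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        payload["features"] = tuple(
            Feature(**{**f, "center": tuple(f.get("center", (0, 0, 0)))})
            for f in payload.get("features", []))
        return cls(**payload)


# ---------------------------------------------------------------------------
# Ideal geometry


def _ring_points(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    pts[:, 0] = radius * np.cos(angles)
    pts[:, 1] = radius * np.sin(angles)
    return pts + center


def _shell_points(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """Fibonacci sphere: quasi-uniform points on a sphere."""
    i = np.arange(n)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / golden
    r_xy = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = radius * np.column_stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z])
    return pts + center


def _background_points(spec: SyntheticSpec, features_xyz: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    if spec.background_points == 0:
        return np.zeros((0, 3))
    max_size = max(f.size for f in spec.features)
    if spec.clutter:
        lo = features_xyz.min(axis=0) - max_size
        hi = features_xyz.max(axis=0) + max_size
        return rng.uniform(lo, hi, size=(spec.background_points, 3))
    # a straight strand, CA-like spacing, at least 3 x feature size away
    centroid = features_xyz.mean(axis=0)
    extent = np.linalg.norm(features_xyz - centroid, axis=1).max()
    start = centroid + np.array([0.0, 0.0, extent + 3.0 * max_size])
    spacing = np.array([3.8, 0.0, 0.0])
    return start + spacing * np.arange(spec.background_points)[:, None]


def _feature_points(features: Sequence[Feature]) -> np.ndarray:
    blocks = []
    for feat in features:
        center = np.asarray(feat.center, dtype=float)
        blocks.append(_ring_points(feat.n_points, feat.size, center)
                      if feat.kind == "ring"
                      else _shell_points(feat.n_points, feat.size, center))
    return np.vstack(blocks)


def _template(spec: SyntheticSpec, rng: np.random.Generator,
              background: np.ndarray | None = None
              ) -> tuple[np.ndarray, list[tuple[str, str]], list[str]]:
    chains = [chr(ord("A") + i) for i in range(len(spec.features))]
    keys, names = [], []
    for chain, feat in zip(chains, spec.features):
        keys.extend((chain, str(i + 1)) for i in range(feat.n_points))
        names.extend(["ALA"] * feat.n_points)
    features_xyz = _feature_points(spec.features)
    bg = (_background_points(spec, features_xyz, rng)
          if background is None else np.asarray(background, dtype=float))
    keys.extend(("Z", str(i + 1)) for i in range(len(bg)))
    names.extend(["GLY"] * len(bg))
    return np.vstack([features_xyz, bg]) if len(bg) else features_xyz, keys, names


# ---------------------------------------------------------------------------
# Generators


def generate_ensemble(spec: SyntheticSpec,
                      seed: int | np.random.SeedSequence | None = None,
                      background: np.ndarray | None = None
                      ) -> ConformationalEnsemble:
    """Jittered frames of the spec's ideal geometry; reproducible by seed.

    Background placement and thermal noise use separate streams derived
    from ``spec.seed``; ``seed`` overrides the noise stream only (used to
    give each ensemble of a pair its own noise).  ``background`` supplies
    explicit background coordinates instead of placing them from the
    spec's own features — a control/case pair must share background
    positions, or a shifted feature would drag the background with it and
    plant spurious geometry differences.
    """
    ss_place, ss_noise = np.random.SeedSequence(spec.seed).spawn(2)
    template, keys, names = _template(spec, np.random.default_rng(ss_place),
                                      background)
    rng = np.random.default_rng(ss_noise if seed is None else seed)
    noise = rng.normal(0.0, spec.noise_sd,
                       size=(spec.n_frames, len(template), 3))
    coords = template[None, :, :] + noise
    return ConformationalEnsemble(tuple(keys), tuple(names), coords)


def generate_control_case_pair(
    spec: SyntheticSpec,
    shifted_feature: int = 0,
    radius_delta: float = 0.0,
    center_delta: Sequence[float] = (0.0, 0.0, 0.0),
) -> tuple[ConformationalEnsemble, ConformationalEnsemble]:
    """Control ensemble from ``spec`` plus a case ensemble in which one
    feature's radius and/or center is shifted.

    Residue labels, background coordinates and all other features are
    identical; control and case get independent noise streams derived
    from ``spec.seed``, as two separately sampled trajectories would.
    """
    if not 0 <= shifted_feature < len(spec.features):
        raise ValueError("shifted_feature out of range")
    if not np.all(np.isfinite([radius_delta, *center_delta])):
        raise ValueError("shift must be finite")
    feat = spec.features[shifted_feature]
    if feat.size + radius_delta <= 0:
        raise ValueError("shift collapses the feature")
    shifted = Feature(feat.kind, feat.n_points, feat.size + radius_delta,
                      tuple(np.asarray(feat.center) + np.asarray(center_delta)))
    case_features = tuple(shifted if i == shifted_feature else f
                          for i, f in enumerate(spec.features))
    case_spec = SyntheticSpec(n_frames=spec.n_frames, noise_sd=spec.noise_sd,
                              features=case_features,
                              background_points=spec.background_points,
                              seed=spec.seed, clutter=spec.clutter)
    # children 0/1 are the placement/noise streams of generate_ensemble;
    # 2/3 are the pair's independent noise streams
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    background = _background_points(spec, _feature_points(spec.features),
                                    np.random.default_rng(streams[0]))
    control = generate_ensemble(spec, seed=streams[2], background=background)
    case = generate_ensemble(case_spec, seed=streams[3], background=background)
    return control, case
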