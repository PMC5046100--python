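"""Synthetic phantom ROIs and toy decision tables with known ground truth.

Every pipeline stage is testable without clinical CT data by emulating the
three nodule morphologies and the common false-positive structures:

* nodules — solitary (SPN: ball), vascular-adhesion (VAPN: ball with an
  attached vessel-like tube), pleural-adhesion (PAPN: ball clipped by the
  pleural plane);
* distractors — vessel-like tubes, plate-like slabs (bone/pleura), and
  irregular blobs (unions of jittered balls).

Intensity models: constant fill, center-bright radial profile (nodules tend
to be denser at the core), or a linear ramp, over a darker background, with
optional additive Gaussian noise.  Each phantom is a pure function of its
spec and seed, and carries analytic ground truth (volume, diameter,
centroid) for oracle tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .roi import RoiVolume
from .roughset import DecisionTable


@dataclass
class PhantomSpec:
    """Deterministic recipe for one synthetic ROI.

    shape : ball | ellipsoid | tube | plate | ball_tube | clipped_ball | blob
    size : radius (ball-like), semi-axes (ellipsoid), (radius, length) for
        tubes, (thickness, extent) for plates.
    profile : constant | center_bright | ramp.
    contrast : object intensity above background (gray units).
    noise_sigma : additive Gaussian noise sd over the whole volume.
    """

    shape: str = "ball"
    size: Tuple[float, ...] = (8.0,)
    profile: str = "constant"
    contrast: float = 60.0
    background: float = 30.0
    noise_sigma: float = 0.0
    grid: Tuple[int, int, int] = (40, 40, 40)
    seed: int = 0
    label: str = "unknown"
    id: str = "phantom"

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.shape in ("ball", "clipped_ball", "ball_tube", "blob") and self.size[0] < 2:
            raise ValueError("radius must be >= 2")


def _coords(grid: Tuple[int, int, int]):
    z, y, x = np.indices(grid).astype(float)
    center = (np.asarray(grid, dtype=float) - 1) / 2.0
    return z - center[0], y - center[1], x - center[2], center


def _ball_mask(grid, radius, center_offset=(0.0, 0.0, 0.0)):
    dz, dy, dx, _ = _coords(grid)
    dz, dy, dx = dz - center_offset[0], dy - center_offset[1], dx - center_offset[2]
    return dz**2 + dy**2 + dx**2 <= radius**2


def make_roi(spec: PhantomSpec) -> RoiVolume:
    """Render a phantom :class:`RoiVolume` from its spec (deterministic)."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    dz, dy, dx, center = _coords(grid)
    r = spec.size[0]
    truth: dict = {}

    if spec.shape == "ball":
        mask = _ball_mask(grid, r)
        truth = {"true_volume": 4 / 3 * np.pi * r**3, "true_diameter": 2 * r,
                 "true_centroid": tuple(center)}
    elif spec.shape == "ellipsoid":
        a, b, c = spec.size
        mask = (dz / a) ** 2 + (dy / b) ** 2 + (dx / c) ** 2 <= 1.0
        truth = {"true_volume": 4 / 3 * np.pi * a * b * c,
                 "true_diameter": 2 * max(a, b, c), "true_centroid": tuple(center)}
    elif spec.shape == "tube":
        radius, length = spec.size
        mask = (dy**2 + dx**2 <= radius**2) & (np.abs(dz) <= length / 2.0)
        truth = {"true_volume": np.pi * radius**2 * length,
                 "true_diameter": float(np.hypot(length, 2 * radius)),
                 "true_centroid": tuple(center)}
    elif spec.shape == "plate":
        thickness, extent = spec.size
        mask = (np.abs(dz) <= thickness / 2.0) & (np.abs(dy) <= extent / 2.0) \
            & (np.abs(dx) <= extent / 2.0)
        truth = {"true_volume": thickness * extent**2, "true_centroid": tuple(center)}
    elif spec.shape == "clipped_ball":
        # pleural-adhesion morphology: ball cut by the pleural plane
        mask = _ball_mask(grid, r) & (dz <= 0)
        truth = {"true_volume": 2 / 3 * np.pi * r**3, "true_diameter": 2 * r}
    elif spec.shape == "ball_tube":
        # vascular-adhesion morphology: ball with a vessel leaving its surface
        tube_r = spec.size[1] if len(spec.size) > 1 else 2.0
        mask = _ball_mask(grid, r)
        tube = (dy**2 + dz**2 <= tube_r**2) & (dx >= 0)
        mask |= tube
        truth = {"true_volume": None}
    elif spec.shape == "blob":
        # irregular distractor: union of 3-6 jittered balls; the optional
        # second size entry is the jitter spread as a fraction of r (compact
        # blobs with small spread are nearly spherical)
        spread = spec.size[1] if len(spec.size) > 1 else 0.7
        n_lobes = int(rng.integers(3, 7))
        mask = np.zeros(grid, dtype=bool)
        for _ in range(n_lobes):
            off = rng.uniform(-r * spread, r * spread, size=3)
            lobe_r = rng.uniform(0.4 * r, 0.8 * r)
            mask |= _ball_mask(grid, lobe_r, center_offset=tuple(off))
        truth = {"true_volume": None, "n_lobes": n_lobes}
    else:
        raise ValueError(f"unknown phantom shape {spec.shape!r}")

    if not mask.any():
        raise ValueError(f"phantom {spec.shape} with size {spec.size} does not fit grid {grid}")
    if mask.all():
        raise ValueError(f"phantom {spec.shape} with size {spec.size} overflows grid {grid}")

    dist = np.sqrt(dz**2 + dy**2 + dx**2)
    img = np.full(grid, float(spec.background))
    if spec.profile == "constant":
        img[mask] = spec.background + spec.contrast
    elif spec.profile == "center_bright":
        # linear radial decay from full contrast at the center to ~40% at the rim
        r_eff = max(dist[mask].max(), 1.0)
        img[mask] = spec.background + spec.contrast * (1.0 - 0.6 * dist[mask] / r_eff)
    elif spec.profile == "ramp":
        z_idx = np.indices(grid)[0].astype(float)
        img[mask] = spec.background + spec.contrast * z_idx[mask] / max(grid[0] - 1, 1)
    else:
        raise ValueError(f"unknown intensity profile {spec.profile!r}")
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=grid)

    return RoiVolume(intensities=img, mask=mask, label=spec.label, id=spec.id,
                     meta={"spec": spec, **truth})


# ---------------------------------------------------------------------------
# benchmark generation
# ---------------------------------------------------------------------------

#: Difficulty regimes.  "separable" mirrors an easy high-contrast cohort
#: where CV accuracy saturates: distinct morphologies, disjoint contrast
#: ranges, low noise.  "noisy" is deliberately ambiguous: most negatives are
#: compact near-spherical blobs, a fraction of ROIs flips its intensity
#: profile (flat nodules / bright-core vessels), contrast ranges overlap,
#: and pixel noise is heavy, so accuracy drops below saturation while the
#: class signal stays concentrated in a few strong morphology/profile cues
#: (the regime in which feature-level fusion is claimed not to degrade
#: detection).
DIFFICULTY = {
    "separable": {
        "pos_contrast": (70.0, 100.0),
        "neg_contrast": (30.0, 50.0),
        "sigma": 2.0,
        "profile_flip": 0.0,
        "neg_shapes": ("tube", "plate", "blob"),
        "blob_spread": 0.7,
    },
    "noisy": {
        "pos_contrast": (40.0, 70.0),
        "neg_contrast": (30.0, 65.0),
        "sigma": 15.0,
        "profile_flip": 0.10,
        "neg_shapes": ("tube", "plate", "blob", "blob", "blob"),
        "blob_spread": 0.35,
    },
}

_POS_SHAPES = ("ball", "ball_tube", "clipped_ball")
_POS_LABELS = {"ball": "SPN", "ball_tube": "VAPN", "clipped_ball": "PAPN"}


def make_benchmark(
    n_pos: int = 70,
    n_neg: int = 70,
    seed: int = 0,
    difficulty: str = "separable",
) -> list:
    """Balanced labeled ROI benchmark (default 70 nodules + 70 non-nodules).

    Nodules draw from the three morphologies with a center-bright profile;
    non-nodules are vessel-like tubes, plates and irregular blobs with a
    constant fill.  The difficulty regime sets contrast overlap and noise.
    """
    if difficulty not in DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(DIFFICULTY)}")
    params = DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    rois = []
    neg_shapes = params["neg_shapes"]
    for i in range(n_pos):
        shape = _POS_SHAPES[int(rng.integers(len(_POS_SHAPES)))]
        radius = float(rng.uniform(6, 11))
        size = (radius, 2.5) if shape == "ball_tube" else (radius,)
        profile = "constant" if rng.random() < params["profile_flip"] else "center_bright"
        spec = PhantomSpec(
            shape=shape, size=size, profile=profile,
            contrast=float(rng.uniform(*params["pos_contrast"])),
            noise_sigma=params["sigma"], grid=(40, 40, 40),
            seed=int(rng.integers(2**31 - 1)), label=_POS_LABELS[shape],
            id=f"pos{i:03d}",
        )
        rois.append(make_roi(spec))
    for i in range(n_neg):
        shape = neg_shapes[int(rng.integers(len(neg_shapes)))]
        if shape == "tube":
            size = (float(rng.uniform(2, 4)), float(rng.uniform(24, 34)))
        elif shape == "plate":
            size = (float(rng.uniform(2, 4)), float(rng.uniform(18, 30)))
        elif shape == "ellipsoid":
            a = float(rng.uniform(5, 9))
            size = (a, a * float(rng.uniform(1.05, 1.4)), a * float(rng.uniform(1.05, 1.4)))
        else:
            size = (float(rng.uniform(5, 9)), params["blob_spread"])
        profile = "center_bright" if rng.random() < params["profile_flip"] else "constant"
        spec = PhantomSpec(
            shape=shape, size=size, profile=profile,
            contrast=float(rng.uniform(*params["neg_contrast"])),
            noise_sigma=params["sigma"], grid=(40, 40, 40),
            seed=int(rng.integers(2**31 - 1)), label="non-nodule",
            id=f"neg{i:03d}",
        )
        rois.append(make_roi(spec))
    return rois


# ---------------------------------------------------------------------------
# toy decision tables and feature-table fixtures
# ---------------------------------------------------------------------------

def make_toy_decision_table(kind: str = "consistent", seed: int = 0) -> DecisionTable:
    """Small decision systems (<= 12 rows, <= 6 attributes) for oracle tests.

    kind='consistent' : random codes, decision a function of (a1, a2).
    kind='inconsistent' : consistent table plus a conflicting duplicate pair.
    kind='duplicated_attr' : last attribute duplicates the first.
    kind='unique_reduct' : constructed so {a1, a2} is the only reduct
        (decision = a1 XOR a2; a3 constant, a4 = a1 AND a2).
    """
    rng = np.random.default_rng(seed)
    if kind == "unique_reduct":
        rows = np.array([[a, b] for a in (0, 1) for b in (0, 1)] * 2)
        codes = pd.DataFrame(
            {
                "a1": rows[:, 0],
                "a2": rows[:, 1],
                "a3": np.zeros(len(rows), dtype=int),
                "a4": rows[:, 0] & rows[:, 1],
            }
        )
        decision = rows[:, 0] ^ rows[:, 1]
        return DecisionTable(codes=codes, decision=decision)

    n, p = 10, 4
    codes = pd.DataFrame(
        rng.integers(0, 3, size=(n, p)), columns=[f"a{i+1}" for i in range(p)]
    )
    decision = ((codes["a1"] + codes["a2"]) % 2).to_numpy()
    if kind == "consistent":
        pass
    elif kind == "inconsistent":
        codes.iloc[-1] = codes.iloc[-2]
        decision[-1] = 1 - decision[-2]
    elif kind == "duplicated_attr":
        codes[f"a{p}"] = codes["a1"]
    else:
        raise ValueError(f"unknown toy table kind {kind!r}")
    return DecisionTable(codes=codes, decision=decision)


def make_informative_table(
    n_rows: int = 140,
    n_informative: int = 6,
    n_noise: int = 36,
    seed: int = 0,
) -> Tuple[pd.DataFrame, np.ndarray, list]:
    """Continuous feature table with a known indispensable feature subset.

    The informative columns are class-shifted Gaussians (centers -2 / +2,
    sd 0.5); noise columns are standard normal, a third of them duplicating
    other noise columns up to a monotone rescale.  For every informative
    column j one engineered row pair is inserted that is identical in every
    other column but far apart in column j with opposite labels, making j
    indispensable (in the core) under any discretization that separates the
    class modes.

    Returns (features, labels, informative_column_names).
    """
    rng = np.random.default_rng(seed)
    labels = np.zeros(n_rows, dtype=int)
    labels[n_rows // 2 :] = 1
    rng.shuffle(labels)
    cols = {}
    info_names = [f"inf{j}" for j in range(n_informative)]
    for j, name in enumerate(info_names):
        cols[name] = np.where(labels == 1, 2.0, -2.0) + rng.normal(0, 0.5, n_rows)
    n_dup = n_noise // 3
    noise_names = [f"noise{j}" for j in range(n_noise - n_dup)]
    for name in noise_names:
        cols[name] = rng.normal(0, 1, n_rows)
    for j in range(n_dup):
        src = noise_names[j % len(noise_names)]
        cols[f"dup{j}"] = 2.0 * cols[src] + 1.0  # monotone twin
    features = pd.DataFrame(cols)

    # engineered indispensability pairs: rows 2j and 2j+1 agree everywhere
    # except informative column j, where they straddle the class gap
    for j, name in enumerate(info_names):
        u, v = 2 * j, 2 * j + 1
        features.iloc[v] = features.iloc[u]
        features.iloc[u, features.columns.get_loc(name)] = -2.5
        features.iloc[v, features.columns.get_loc(name)] = 2.5
        labels[u], labels[v] = 0, 1
    return features, labels, info_names
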