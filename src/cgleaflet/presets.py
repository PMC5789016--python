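"""Shipped system presets mirroring the two study membranes.

``outer_membrane``: LPS-like upper leaflet over a 90/5/5
POPE/POPG/cardiolipin lower leaflet, with planted anti-correlated order
fields, headgroup voids co-located with cardiolipin clusters, asymmetric
interdigitation (lower tails reach further up than upper tails reach
down) and a 10:1 leaflet mobility asymmetry.

``mixed_phospholipid``: both leaflets 90/5/5 with independent
(orthogonal-mode) order fields, no voids or clusters, symmetric
interdigitation and equal mobilities — the matched control with no
planted interleaflet coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .synthetic import GeneratorConfig

__all__ = [
    "SinusoidalField",
    "outer_membrane_config",
    "mixed_phospholipid_config",
    "preset_config",
    "PRESETS",
]


@dataclass(frozen=True)
class BumpField:
    """P2(x, y) = base + amplitude * sum_i exp(-d_i^2 / (2 width^2)).

    ``d_i`` is the periodic distance to bump center i.  Negative
    amplitude digs order dips (disordered nano-domains); a positive
    amplitude at the same centers plants the anti-correlated response of
    the opposing leaflet.
    """

    base: float
    amplitude: float
    centers: tuple[tuple[float, float], ...]
    width: float
    box_x: float
    box_y: float

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        total = np.zeros(np.broadcast(x, y).shape)
        for cx, cy in self.centers:
            dx = x - cx
            dy = y - cy
            dx -= self.box_x * np.round(dx / self.box_x)
            dy -= self.box_y * np.round(dy / self.box_y)
            total += np.exp(-(dx * dx + dy * dy) / (2.0 * self.width**2))
        return self.base + self.amplitude * total


def _irregular_centers(
    n: int, box_x: float, box_y: float, min_sep: float, seed: int
) -> tuple[tuple[float, float], ...]:
    """Dart-throwing: n centers with a periodic minimum separation."""
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    guard = 0
    while len(centers) < n:
        guard += 1
        if guard > 20000:
            raise RuntimeError("could not place nano-domain centers; lower min_sep")
        x = float(rng.uniform(0.1 * box_x, 0.9 * box_x))
        y = float(rng.uniform(0.1 * box_y, 0.9 * box_y))
        ok = True
        for cx, cy in centers:
            dx = x - cx - box_x * round((x - cx) / box_x)
            dy = y - cy - box_y * round((y - cy) / box_y)
            if dx * dx + dy * dy < min_sep * min_sep:
                ok = False
                break
        if ok:
            centers.append((x, y))
    return tuple(centers)


@dataclass(frozen=True)
class SinusoidalField:
    """P2(x, y) = base + amplitude * sin(2 pi kx x / Lx) * sin(2 pi ky y / Ly).

    A named callable rather than a lambda so configurations that carry it
    stay picklable and printable.
    """

    base: float
    amplitude: float
    box_x: float
    box_y: float
    kx: int = 1
    ky: int = 1

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.base + self.amplitude * np.sin(
            2.0 * math.pi * self.kx * np.asarray(x) / self.box_x
        ) * np.sin(2.0 * math.pi * self.ky * np.asarray(y) / self.box_y)


def outer_membrane_config(
    lipids_per_leaflet: int = 1024,
    n_frames: int = 48,
    seed: int = 0,
    box: tuple[float, float, float] = (23.0, 23.0, 15.0),
    n_water: int = 6000,
) -> GeneratorConfig:
    """Asymmetric LPS / phospholipid outer-membrane preset.

    The planted upper-leaflet order spans roughly 0.20-0.65 (inside the
    0.15-0.70 range reported for LPS phases): disordered nano-domains
    dug into an otherwise ordered field at irregular centers, the way
    headgroup-packing voids actually appear — not a periodic pattern,
    which would hand the toroidal-shift null spurious self-alignments.
    The lower leaflet responds with *raised* order at the same centers
    (planted anti-correlation).  LPS headgroup depletion and 3x
    cardiolipin cluster enrichment sit at the same nano-domain centers.
    The domain layout derives from the seed, so replicate runs sample
    layout variability too.
    """
    lx, ly, _ = box
    centers = _irregular_centers(7, lx, ly, min_sep=5.0, seed=seed + 90001)
    return GeneratorConfig(
        box=box,
        composition_upper={"LPS": 1.0},
        composition_lower={"POPE": 0.90, "POPG": 0.05, "CDL": 0.05},
        lipids_per_leaflet=lipids_per_leaflet,
        order_field_upper=BumpField(0.62, -0.40, centers, 1.4, lx, ly),
        order_field_lower=BumpField(0.35, 0.18, centers, 1.4, lx, ly),
        void_regions=[(c, 1.5) for c in centers],
        void_depletion=0.7,
        void_thinning=0.25,
        cluster_spec={"CDL": [(c, 1.5, 3.0) for c in centers]},
        interdigitation_upper=0.3,
        interdigitation_lower=1.0,
        thickness=4.0,
        mobility_sigma_upper=0.08,
        mobility_sigma_lower=0.8,
        n_frames=n_frames,
        n_water=n_water,
        antifreeze_fraction=0.02,
        seed=seed,
    )


def mixed_phospholipid_config(
    lipids_per_leaflet: int = 1024,
    n_frames: int = 48,
    seed: int = 0,
    box: tuple[float, float, float] = (23.0, 23.0, 15.0),
    n_water: int = 6000,
) -> GeneratorConfig:
    """Symmetric 90/5/5 phospholipid preset with no planted coupling.

    Both leaflets get mild order variation, but on orthogonal Fourier
    modes, so the true field correlation is zero.
    """
    lx, ly, _ = box
    return GeneratorConfig(
        box=box,
        composition_upper={"POPE": 0.90, "POPG": 0.05, "CDL": 0.05},
        composition_lower={"POPE": 0.90, "POPG": 0.05, "CDL": 0.05},
        lipids_per_leaflet=lipids_per_leaflet,
        order_field_upper=SinusoidalField(0.42, 0.10, lx, ly, kx=1, ky=1),
        order_field_lower=SinusoidalField(0.42, 0.10, lx, ly, kx=2, ky=1),
        interdigitation_upper=0.6,
        interdigitation_lower=0.6,
        thickness=4.0,
        mobility_sigma_upper=0.8,
        mobility_sigma_lower=0.8,
        n_frames=n_frames,
        n_water=n_water,
        antifreeze_fraction=0.02,
        seed=seed,
    )


PRESETS = {
    "outer-membrane": outer_membrane_config,
    "mixed-phospholipid": mixed_phospholipid_config,
}


def preset_config(name: str, **kwargs) -> GeneratorConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory(**kwargs)
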