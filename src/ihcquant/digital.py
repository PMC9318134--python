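"""Color-range ("digital count") estimation of stained-area fraction.

This reproduces the seeded color-selection workflow of commercial image
editors: sample the stain color from a stained structure, select every pixel
whose color lies within a fuzziness tolerance of the sampled color(s), and
report selected pixels over total pixels as a percentage.

The selection rule is fully specified here rather than borrowed from any
proprietary tool: distance is per-channel Chebyshev in RGB by default
(Euclidean optional), and falloff is hard (binary) by default with an
optional linear partial-selection mode in which a pixel's weight fades from
1 at distance F/2 to 0 at distance F.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ColorRangeSpec",
    "SelectionMask",
    "sample_stain_color",
    "color_range_select",
    "dc_area_fraction",
]


@dataclass(frozen=True)
class ColorRangeSpec:
    """A saved color-range selection criterion, reusable across images.

    sampled_colors : one or more 8-bit RGB reference triples.
    fuzziness : tolerance in [0, 255]; default 100 (the protocol value used
        throughout this package's study emulation).
    distance_metric : "chebyshev" (max per-channel difference) or "euclidean".
    falloff : "hard" (binary membership at distance <= fuzziness) or "linear"
        (weight 1 below F/2 fading to 0 at F; counts become weight sums).
    """

    sampled_colors: tuple[tuple[int, int, int], ...]
    fuzziness: float = 100.0
    distance_metric: str = "chebyshev"
    falloff: str = "hard"

    def __post_init__(self) -> None:
        colors = tuple(tuple(int(v) for v in c) for c in self.sampled_colors)
        if len(colors) == 0:
            raise ValueError("at least one sampled color is required")
        for c in colors:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise ValueError(f"invalid 8-bit RGB triple {c!r}")
        if not (0 <= self.fuzziness <= 255):
            raise ValueError("fuzziness must be in [0, 255]")
        if self.distance_metric not in ("chebyshev", "euclidean"):
            raise ValueError(f"unknown metric {self.distance_metric!r}")
        if self.falloff not in ("hard", "linear"):
            raise ValueError(f"unknown falloff {self.falloff!r}")
        object.__setattr__(self, "sampled_colors", colors)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sampled_colors": [list(c) for c in self.sampled_colors],
            "fuzziness": self.fuzziness,
            "distance_metric": self.distance_metric,
            "falloff": self.falloff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColorRangeSpec":
        return cls(
            sampled_colors=tuple(tuple(c) for c in d["sampled_colors"]),
            fuzziness=float(d.get("fuzziness", 100.0)),
            distance_metric=d.get("distance_metric", "chebyshev"),
            falloff=d.get("falloff", "hard"),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "ColorRangeSpec":
        path = Path(path)
        raw = path.read_text()
        d = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
        return cls.from_dict(d)


@dataclass(frozen=True)
class SelectionMask:
    """Result of a color-range selection.

    ``weights`` is a float raster in [0, 1] (0/1 under hard falloff);
    ``selected_count`` is its sum and ``total_count`` the pixel count.
    """

    weights: np.ndarray
    selected_count: float
    total_count: int

    def __post_init__(self) -> None:
        if self.selected_count > self.total_count + 1e-9:
            raise ValueError("selected_count cannot exceed total_count")

    @property
    def binary(self) -> np.ndarray:
        return self.weights > 0


def sample_stain_color(
    image: np.ndarray, seed_pixel: tuple[int, int], median3: bool = False
) -> tuple[int, int, int]:
    """Read the reference color at a seed pixel (the eyedropper step).

    With ``median3`` the per-channel median over the 3x3 neighborhood
    (clipped at image borders) is returned instead of the raw pixel, damping
    single-pixel texture jitter. No validation of *what* was sampled is done:
    seeding on background returns the background color.
    """
    h, w = image.shape[:2]
    r, c = int(seed_pixel[0]), int(seed_pixel[1])
    if not (0 <= r < h and 0 <= c < w):
        raise ValueError(f"seed pixel {seed_pixel} outside extent {(h, w)}")
    if not median3:
        return tuple(int(v) for v in image[r, c])
    patch = image[max(r - 1, 0): r + 2, max(c - 1, 0): c + 2].reshape(-1, 3)
    return tuple(int(v) for v in np.median(patch, axis=0))


def _distance_to_nearest(image: np.ndarray, spec: ColorRangeSpec) -> np.ndarray:
    img = image.astype(np.float64)
    d_min = None
    for color in spec.sampled_colors:
        diff = img - np.asarray(color, dtype=np.float64)
        if spec.distance_metric == "chebyshev":
            d = np.abs(diff).max(axis=-1)
        else:
            d = np.sqrt((diff**2).sum(axis=-1))
        d_min = d if d_min is None else np.minimum(d_min, d)
    return d_min


def color_range_select(image: np.ndarray, spec: ColorRangeSpec) -> SelectionMask:
    """Select pixels within the fuzziness tolerance of the nearest sampled color.

    Hard falloff: membership iff distance <= fuzziness. Linear falloff:
    weight = clamp(1 - (d - F/2)/(F/2), 0, 1); at F = 0 this degenerates to
    exact-color membership. Multiple sampled colors combine as the union
    (max weight), which the nearest-color distance realizes directly.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    d = _distance_to_nearest(image, spec)
    f = float(spec.fuzziness)
    if spec.falloff == "hard" or f == 0.0:
        weights = (d <= f).astype(np.float64)
    else:
        half = f / 2.0
        weights = np.clip(1.0 - (d - half) / half, 0.0, 1.0)
    return SelectionMask(
        weights=weights,
        selected_count=float(weights.sum()),
        total_count=int(weights.size),
    )


def dc_area_fraction(image: np.ndarray, spec: ColorRangeSpec) -> float:
    """Digital-count estimate: 100 * selected pixels / total pixels."""
    sel = color_range_select(image, spec)
    return 100.0 * sel.selected_count / sel.total_count
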