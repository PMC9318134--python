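"""Synthetic immunohistochemistry fields and simulated measurement datasets.

Every downstream estimator and statistic in this package is exercised on
images and measurement tables produced here, with exact ground truth. The
image model is deliberately simple: DAB-brown stained blobs (cell clusters)
scattered on a hematoxylin-blue background with nuclei and eosin-pink
patches, at a controlled true stained-area fraction. A paired "NOISE"
regime adds diffuse non-specific brown haze and speckles to the background
only, emulating slides with poor staining quality; the ground-truth mask is
never touched by noise.

Color choices guarantee, by construction, that in the clean ("GOOD") regime
no pixel outside the truth mask lies within Chebyshev distance 100 of the
stain color, so a color-range selection seeded on the stain recovers the
true fraction essentially exactly. This is a design property, not an
accident; see the palette constants below.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "MARKERS",
    "DAB_BROWN",
    "HEMATOXYLIN_BG",
    "NUCLEUS_BLUE",
    "EOSIN_PINK",
    "SyntheticField",
    "FieldGenParams",
    "PairedMeasurementSet",
    "CohortDataset",
    "generate_field",
    "add_background_noise",
    "generate_study_fixtures",
    "generate_paired_differences",
    "generate_cohort",
    "write_fields",
]

#: The seven CD markers assayed in the peri-implantitis / periodontitis design.
MARKERS = ("CD3", "CD4", "CD8", "CD15", "CD20", "CD68", "CD138")

#: DAB chromogen brown used to paint specifically stained tissue.
DAB_BROWN = (120, 66, 18)
#: Pale hematoxylin-tinted background.
HEMATOXYLIN_BG = (205, 205, 230)
#: Darker blue nuclei ellipses.
NUCLEUS_BLUE = (80, 80, 140)
#: Eosin-pink connective-tissue patches.
EOSIN_PINK = (231, 170, 185)


@dataclass(frozen=True)
class SyntheticField:
    """One synthetic 400x-like field with exact ground truth.

    ``true_fraction`` is always exactly ``100 * truth_mask.sum() / truth_mask.size``.
    ``regime`` is ``"GOOD"`` (clean staining) or ``"NOISE"`` (non-specific brown
    background added outside the truth mask).
    """

    image: np.ndarray          # (H, W, 3) uint8
    truth_mask: np.ndarray     # (H, W) bool
    true_fraction: float       # percent in [0, 100]
    regime: str
    field_id: str
    marker: str = "CD3"

    def __post_init__(self) -> None:
        if self.regime not in ("GOOD", "NOISE"):
            raise ValueError(f"regime must be GOOD or NOISE, got {self.regime!r}")


@dataclass(frozen=True)
class FieldGenParams:
    """Parameters of the stained-field generator.

    extent : (height, width) in pixels, each >= 32.
    target_fraction : requested stained-area percent in [0, 100]; the
        generator lands within one pixel of the corresponding pixel count.
    blob_radius_mean / blob_radius_sd : lognormal-ish ellipse semi-axis scale
        in pixels, controlling cell-cluster size.
    stain_color : RGB of the DAB stain painted inside the truth mask.
    color_jitter : per-channel uniform jitter amplitude applied inside blobs
        after the mask is fixed (texture only; Chebyshev distance to
        ``stain_color`` stays <= color_jitter).
    seed : fully determines the output.
    """

    target_fraction: float
    seed: int
    extent: tuple[int, int] = (512, 512)
    blob_radius_mean: float = 9.0
    blob_radius_sd: float = 3.0
    stain_color: tuple[int, int, int] = DAB_BROWN
    background_color: tuple[int, int, int] = HEMATOXYLIN_BG
    nucleus_color: tuple[int, int, int] = NUCLEUS_BLUE
    eosin_color: tuple[int, int, int] = EOSIN_PINK
    color_jitter: int = 10
    field_id: str = "field"
    marker: str = "CD3"

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fraction <= 100.0):
            raise ValueError("target_fraction must be in [0, 100]")
        h, w = self.extent
        if h < 32 or w < 32:
            raise ValueError("extent must be at least 32x32 pixels")
        if not (0 <= self.color_jitter <= 30):
            raise ValueError("color_jitter must be in [0, 30]")


@dataclass(frozen=True)
class PairedMeasurementSet:
    """Paired area-fraction measurements (two methods, observers or timepoints).

    ``value_a``/``value_b`` are percent arrays of equal length with no missing
    pairs; ``n_clipped`` counts simulated values that hit the [0, 100] bounds.
    """

    value_a: np.ndarray
    value_b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    subject_ids: tuple[str, ...] | None = None
    n_clipped: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.value_a, dtype=float)
        b = np.asarray(self.value_b, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("value_a and value_b must be 1-D arrays of equal length")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("missing values are not allowed in a paired set")
        object.__setattr__(self, "value_a", a)
        object.__setattr__(self, "value_b", b)

    def __len__(self) -> int:
        return self.value_a.size

    def to_frame(self) -> pd.DataFrame:
        ids = self.subject_ids or tuple(f"s{i:04d}" for i in range(len(self)))
        return pd.DataFrame(
            {"subject_id": ids, self.label_a: self.value_a, self.label_b: self.value_b}
        )


@dataclass(frozen=True)
class CohortDataset:
    """Long-format per-patient, per-marker, per-field measurements.

    ``data`` columns: patient_id, group (PI/PD), marker, method (MC/DC),
    field_id, value (percent).
    """

    data: pd.DataFrame
    n_pi: int
    n_pd: int
    n_fields: int = 4

    def __post_init__(self) -> None:
        required = {"patient_id", "group", "marker", "method", "field_id", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"cohort data missing columns: {sorted(missing)}")


# ---------------------------------------------------------------------------
# image generation
# ---------------------------------------------------------------------------

def _paint_background(rng: np.random.Generator, params: FieldGenParams) -> np.ndarray:
    h, w = params.extent
    img = np.empty((h, w, 3), dtype=np.int16)
    img[...] = np.asarray(params.background_color, dtype=np.int16)
    # gentle per-pixel tint variation; +-6 keeps every palette color far from brown
    img += rng.integers(-6, 7, size=(h, w, 3), dtype=np.int16)

    # eosin-pink connective patches: a few large soft ellipses
    n_patches = max(1, (h * w) // 40000)
    for _ in range(n_patches):
        rr, cc = draw_ellipse(
            rng.uniform(0, h), rng.uniform(0, w),
            rng.uniform(0.12, 0.3) * h, rng.uniform(0.12, 0.3) * w,
            shape=(h, w), rotation=rng.uniform(0, np.pi),
        )
        img[rr, cc] = np.asarray(params.eosin_color, dtype=np.int16)
        img[rr, cc] += rng.integers(-6, 7, size=(rr.size, 3), dtype=np.int16)

    # hematoxylin nuclei: small dark-blue ellipses
    n_nuclei = max(4, (h * w) // 2500)
    for _ in range(n_nuclei):
        rr, cc = draw_ellipse(
            rng.uniform(0, h), rng.uniform(0, w),
            rng.uniform(2.0, 5.0), rng.uniform(2.0, 5.0),
            shape=(h, w), rotation=rng.uniform(0, np.pi),
        )
        img[rr, cc] = np.asarray(params.nucleus_color, dtype=np.int16)
        img[rr, cc] += rng.integers(-6, 7, size=(rr.size, 3), dtype=np.int16)

    return np.clip(img, 0, 255).astype(np.uint8)


def _build_stain_mask(rng: np.random.Generator, params: FieldGenParams) -> np.ndarray:
    """Place random ellipses until the mask holds exactly the target pixel count.

    The final ellipse is truncated pixel-wise so the achieved count equals the
    rounded target; this keeps ``true_fraction`` within one pixel of the request.
    """
    h, w = params.extent
    total = h * w
    target_px = int(round(params.target_fraction / 100.0 * total))
    mask = np.zeros((h, w), dtype=bool)
    if target_px == 0:
        return mask
    if target_px >= total:
        mask[...] = True
        return mask

    placed = 0
    max_blobs = 200_000
    for _ in range(max_blobs):
        r_a = float(np.clip(rng.normal(params.blob_radius_mean, params.blob_radius_sd), 2.0, None))
        r_b = float(np.clip(rng.normal(params.blob_radius_mean, params.blob_radius_sd), 2.0, None))
        rr, cc = draw_ellipse(
            rng.uniform(0, h), rng.uniform(0, w), r_a, r_b,
            shape=(h, w), rotation=rng.uniform(0, np.pi),
        )
        if rr.size == 0:
            continue
        new = ~mask[rr, cc]
        n_new = int(new.sum())
        if placed + n_new <= target_px:
            mask[rr[new], cc[new]] = True
            placed += n_new
        else:
            need = target_px - placed
            rr_n, cc_n = rr[new][:need], cc[new][:need]
            mask[rr_n, cc_n] = True
            placed = target_px
        if placed >= target_px:
            return mask
    raise RuntimeError(
        f"could not reach target_fraction={params.target_fraction}% with "
        f"blob_radius_mean={params.blob_radius_mean}: placed {placed}/{target_px} "
        f"pixels after {max_blobs} blobs"
    )


def generate_field(params: FieldGenParams) -> SyntheticField:
    """Generate one synthetic GOOD-regime field with exact ground truth.

    The truth mask is painted uniformly in ``params.stain_color`` and then
    textured with per-channel jitter of amplitude ``params.color_jitter``, so
    every stained pixel stays within that Chebyshev distance of the stain
    color. In the GOOD regime no background pixel comes anywhere near the
    brown family (distance > 100 by palette construction).
    """
    rng = np.random.default_rng(params.seed)
    img = _paint_background(rng, params)
    mask = _build_stain_mask(rng, params)

    n_stained = int(mask.sum())
    if n_stained:
        stain = np.asarray(params.stain_color, dtype=np.int16)
        px = np.broadcast_to(stain, (n_stained, 3)).copy()
        if params.color_jitter:
            px += rng.integers(
                -params.color_jitter, params.color_jitter + 1,
                size=(n_stained, 3), dtype=np.int16,
            )
        img[mask] = np.clip(px, 0, 255).astype(np.uint8)

    frac = 100.0 * n_stained / mask.size
    return SyntheticField(
        image=img, truth_mask=mask, true_fraction=frac,
        regime="GOOD", field_id=params.field_id, marker=params.marker,
    )


def add_background_noise(
    field: SyntheticField,
    noise_intensity: float,
    seed: int,
    stain_color: tuple[int, int, int] = DAB_BROWN,
) -> SyntheticField:
    """Degrade a GOOD field with non-specific brown background.

    Two components, both restricted to pixels outside the truth mask:

    * a diffuse haze — a smooth random field blends background pixels toward
      the stain color with strength growing with ``noise_intensity``;
    * brown speckles — small high-opacity blobs whose count scales with
      ``noise_intensity`` and whose colors straddle the fuzziness-100
      selection boundary, so digital counting both overcounts and becomes
      sensitive to the exact reference color.

    The truth mask, the true fraction and every stained pixel are unchanged.
    """
    if field.regime != "GOOD":
        raise ValueError("add_background_noise expects a GOOD-regime field")
    if not (0.0 <= noise_intensity <= 1.0):
        raise ValueError("noise_intensity must be in [0, 1]")

    if noise_intensity == 0.0:
        return dataclasses.replace(field, regime="NOISE")

    rng = np.random.default_rng(seed)
    h, w = field.truth_mask.shape
    img = field.image.astype(np.float64)
    stain = np.asarray(stain_color, dtype=np.float64)

    # diffuse haze over ~45% * intensity of the image
    smooth = gaussian_filter(rng.standard_normal((h, w)), sigma=max(h, w) / 16.0)
    cutoff = np.quantile(smooth, 1.0 - 0.45 * noise_intensity)
    haze = smooth > cutoff
    if haze.any():
        u = smooth[haze] - cutoff
        umax = u.max()
        u = u / umax if umax > 0 else u
        alpha = noise_intensity * (0.25 + 0.75 * u)
        img[haze] += alpha[:, None] * (stain - img[haze])

    # speckles: small near-stain blobs, count proportional to intensity
    n_speckles = int(round(600 * noise_intensity * (h * w) / (512 * 512)))
    for _ in range(n_speckles):
        rr, cc = draw_ellipse(
            rng.uniform(0, h), rng.uniform(0, w),
            rng.uniform(1.0, 3.0), rng.uniform(1.0, 3.0),
            shape=(h, w),
        )
        alpha = rng.uniform(0.50, 0.95)
        img[rr, cc] += alpha * (stain - img[rr, cc])

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    out[field.truth_mask] = field.image[field.truth_mask]  # noise never touches truth
    return dataclasses.replace(field, image=out, regime="NOISE")


def generate_study_fixtures(
    n_good: int,
    n_noise: int,
    seed: int,
    extent: tuple[int, int] = (512, 512),
    fraction_range: tuple[float, float] = (1.0, 30.0),
    noise_intensity: float = 0.5,
) -> list[SyntheticField]:
    """Generate the agreement-study image set: ``n_good`` clean fields plus
    ``n_noise`` noise-regime fields (each a clean field with background haze).

    True fractions are drawn i.i.d. uniform over ``fraction_range`` (default
    1–30%, the sparse occupancy typical of inflammatory-marker staining);
    markers cycle through the seven-CD panel. Fully determined by ``seed``.
    """
    if n_good < 0 or n_noise < 0:
        raise ValueError("n_good and n_noise must be >= 0")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 * (n_good + n_noise))]

    fields: list[SyntheticField] = []
    lo, hi = fraction_range
    for i in range(n_good + n_noise):
        regime_good = i < n_good
        fid = f"G{i:04d}" if regime_good else f"N{i - n_good:04d}"
        params = FieldGenParams(
            target_fraction=float(rng.uniform(lo, hi)),
            seed=child_seeds[2 * i],
            extent=extent,
            field_id=fid,
            marker=MARKERS[i % len(MARKERS)],
        )
        fld = generate_field(params)
        if not regime_good:
            fld = add_background_noise(fld, noise_intensity, seed=child_seeds[2 * i + 1])
        fields.append(fld)
    return fields


def write_fields(fields: Sequence[SyntheticField], outdir: str | Path) -> Path:
    """Write ``<id>_img.png`` / ``<id>_mask.png`` pairs plus ``manifest.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in fields:
        iio.imwrite(outdir / f"{f.field_id}_img.png", f.image)
        iio.imwrite(outdir / f"{f.field_id}_mask.png", (f.truth_mask * 255).astype(np.uint8))
        rows.append(
            {"field_id": f.field_id, "regime": f.regime, "marker": f.marker,
             "true_fraction": f.true_fraction}
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


# ---------------------------------------------------------------------------
# measurement-set and cohort simulation
# ---------------------------------------------------------------------------

def generate_paired_differences(
    n: int,
    bias: float,
    sd: float,
    seed: int,
    base_distribution: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    label_a: str = "A",
    label_b: str = "B",
) -> PairedMeasurementSet:
    """Simulate paired percentages with value_B = value_A + Normal(bias, sd).

    Both columns are clipped to [0, 100]; the number of clipped entries is
    reported on the result. The default base distribution is uniform 1–30%.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    if base_distribution is None:
        a = rng.uniform(1.0, 30.0, size=n)
    else:
        a = np.asarray(base_distribution(rng, n), dtype=float)
    b = a + rng.normal(bias, sd, size=n) if sd > 0 else a + bias
    a_c = np.clip(a, 0.0, 100.0)
    b_c = np.clip(b, 0.0, 100.0)
    n_clipped = int((a != a_c).sum() + (b != b_c).sum())
    return PairedMeasurementSet(
        value_a=a_c, value_b=b_c, label_a=label_a, label_b=label_b, n_clipped=n_clipped
    )


#: Baseline per-marker mean stained-area percent (shared by PI and PD).
DEFAULT_MARKER_BASELINES = {
    "CD3": 8.0, "CD4": 6.0, "CD8": 5.0, "CD15": 3.0,
    "CD20": 4.0, "CD68": 5.0, "CD138": 7.0,
}

#: Default group effects: percent added to PI means for the markers the
#: plasma-cell / macrophage biology elevates in peri-implantitis.
DEFAULT_MARKER_EFFECTS = {"CD68": 6.0, "CD138": 8.0}


def generate_cohort(
    n_per_group: int = 11,
    marker_effects: dict[str, float] | None = None,
    seed: int = 0,
    n_fields: int = 4,
    patient_sd: float = 2.0,
    field_sd: float = 1.5,
    method_sd: float = 0.6,
    baselines: dict[str, float] | None = None,
) -> CohortDataset:
    """Simulate the two-group cohort: PI and PD patients, 7 markers,
    ``n_fields`` fields per patient per marker, measured by both MC and DC.

    Hierarchy: value = marker baseline + group effect (PI only, for markers in
    ``marker_effects``) + patient random effect + field effect + method noise,
    clipped to [0, 100]. ``marker_effects=None`` uses the default CD68/CD138
    elevation; pass ``{}`` for a null cohort with equal group means.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 patients per group")
    if marker_effects is None:
        marker_effects = dict(DEFAULT_MARKER_EFFECTS)
    baselines = dict(DEFAULT_MARKER_BASELINES if baselines is None else baselines)

    rng = np.random.default_rng(seed)
    rows = []
    for g_idx, group in enumerate(("PI", "PD")):
        for p in range(n_per_group):
            pid = f"{group}{p:02d}"
            for marker in MARKERS:
                mu = baselines[marker]
                if group == "PI":
                    mu += marker_effects.get(marker, 0.0)
                patient_eff = rng.normal(0.0, patient_sd)
                for f_idx in range(n_fields):
                    field_true = mu + patient_eff + rng.normal(0.0, field_sd)
                    for method in ("MC", "DC"):
                        v = field_true + rng.normal(0.0, method_sd)
                        rows.append(
                            {"patient_id": pid, "group": group, "marker": marker,
                             "method": method, "field_id": f"f{f_idx}",
                             "value": float(np.clip(v, 0.0, 100.0))}
                        )
    return CohortDataset(
        data=pd.DataFrame(rows), n_pi=n_per_group, n_pd=n_per_group, n_fields=n_fields
    )
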