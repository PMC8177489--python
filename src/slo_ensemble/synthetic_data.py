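"""Synthetic ONH-like SLO images and RNFL thickness tables.

The clinical dataset behind this package (227 en-face SLO images, 122
controls / 105 glaucoma patients, plus per-subject RNFL sector thicknesses)
is not publicly deposited, so this module generates surrogates with the
statistical structure the classifiers rely on:

* images: a bright optic disc with a brighter central cup on a darker
  background, dark vessel polylines radiating from the disc, multiplicative
  speckle and additive Gaussian noise.  The class effect enters only through
  the cup-to-disc ratio (cup enlargement and hence rim thinning in glaucoma)
  and the rim contrast, so a single dial controls separability;
* thickness tables: per-group multivariate-normal draws for the average RNFL
  thickness and the six peripapillary sectors (ts, t, ti, ns, n, ni), with
  group means/SDs defaulting to the published clinical cohort statistics and
  a configurable inter-sector correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .evaluation import CONTROL, GLAUCOMA

RNFL_COLUMNS = ["rnflav", "ts", "t", "ti", "ns", "n", "ni"]

#: Published per-group mean +/- SD of average RNFL thickness and the six
#: sectors (micrometres) for the control and glaucoma cohorts.
RNFL_TABLE_CONTROL = {
    "rnflav": (97.0, 8.0),
    "ts": (136.0, 15.0),
    "t": (70.0, 10.0),
    "ti": (143.0, 18.0),
    "ns": (106.0, 22.0),
    "n": (73.0, 12.0),
    "ni": (109.0, 20.0),
}
RNFL_TABLE_GLAUCOMA = {
    "rnflav": (62.0, 12.0),
    "ts": (78.0, 22.0),
    "t": (50.0, 14.0),
    "ti": (73.0, 29.0),
    "ns": (68.0, 18.0),
    "n": (54.0, 15.0),
    "ni": (70.0, 22.0),
}


@dataclass(frozen=True)
class SyntheticImageConfig:
    """Geometry and noise dials for the image generator.

    ``cup_to_disc_*`` are cup/disc radius ratios; clinically, controls sit
    around 0.3–0.4 and glaucomatous discs around 0.6–0.8.  Setting the two
    ratios equal (and ``rim_contrast_delta`` to 0) is the documented null
    configuration in which the classes are statistically identical.
    """

    image_height: int = 156
    image_width: int = 238
    disc_radius_mean: float = 34.0
    cup_to_disc_control: float = 0.35
    cup_to_disc_glaucoma: float = 0.65
    rim_contrast: float = 0.25
    rim_contrast_delta: float = 0.0  # extra per-class rim dimming for glaucoma
    vessel_count: int = 6
    noise_sd: float = 0.05
    speckle_sd: float = 0.08
    jitter_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_height < 16 or self.image_width < 16:
            raise ValueError("image dimensions too small")
        for name in ("cup_to_disc_control", "cup_to_disc_glaucoma"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must lie strictly inside (0, 1)")
        if self.cup_to_disc_glaucoma < self.cup_to_disc_control:
            raise ValueError(
                "cup_to_disc_glaucoma must be >= cup_to_disc_control "
                "(glaucoma means an enlarged cup); equality is the null setting"
            )
        if self.noise_sd < 0 or self.speckle_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise/jitter SDs must be nonnegative")
        if not 0.0 <= self.rim_contrast <= 1.0:
            raise ValueError("rim_contrast must lie in [0, 1]")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be nonnegative")
        if self.disc_radius_mean <= 2:
            raise ValueError("disc radius too small")


@dataclass(frozen=True)
class RnflPopulationParams:
    """Per-group (mean, SD) for each thickness parameter, in micrometres."""

    control: dict = field(default_factory=lambda: dict(RNFL_TABLE_CONTROL))
    glaucoma: dict = field(default_factory=lambda: dict(RNFL_TABLE_GLAUCOMA))
    n_control: int = 122
    n_glaucoma: int = 105
    inter_sector_correlation: float = 0.6

    def validate(self) -> None:
        if not 0.0 <= self.inter_sector_correlation < 1.0:
            raise ValueError(
                f"inter_sector_correlation={self.inter_sector_correlation} "
                "must lie in [0, 1)"
            )
        if self.n_control < 1 or self.n_glaucoma < 1:
            raise ValueError("group sizes must be positive")
        for group in (self.control, self.glaucoma):
            missing = set(RNFL_COLUMNS) - set(group)
            if missing:
                raise ValueError(f"missing thickness parameters: {sorted(missing)}")
            for name in RNFL_COLUMNS:
                mean, sd = group[name]
                if mean <= 0 or sd < 0:
                    raise ValueError(f"invalid (mean, sd) for {name}: {(mean, sd)}")


def _render_onh(
    rng: np.random.Generator,
    config: SyntheticImageConfig,
    cup_to_disc: float,
    rim_contrast: float,
) -> np.ndarray:
    """Render one image: disc ellipse, brighter cup, vessels, speckle, noise."""
    h, w = config.image_height, config.image_width
    background = 0.30
    cup_boost = 0.25

    cy = h / 2 + rng.normal(0.0, config.jitter_sd)
    cx = w / 2 + rng.normal(0.0, config.jitter_sd)
    # Resample until geometry is valid: cup strictly inside disc, disc inside frame.
    for _ in range(100):
        disc_r = config.disc_radius_mean * (1 + rng.normal(0.0, 0.05))
        cup_r = disc_r * (cup_to_disc + rng.normal(0.0, 0.03))
        if 1.0 <= cup_r < disc_r and disc_r < min(h, w) / 2:
            break
    else:  # pragma: no cover - only under absurd configs
        disc_r = config.disc_radius_mean
        cup_r = disc_r * cup_to_disc
    aspect = 1.0 + rng.normal(0.0, 0.05)  # mild ellipticity

    yy, xx = np.mgrid[0:h, 0:w]
    r2 = ((yy - cy) / aspect) ** 2 + (xx - cx) ** 2
    img = np.full((h, w), background)
    img[r2 <= disc_r**2] = background + rim_contrast
    img[r2 <= cup_r**2] = background + rim_contrast + cup_boost

    # Vessels: dark random-walk polylines radiating from the disc centre.
    for _ in range(config.vessel_count):
        angle = rng.uniform(0, 2 * np.pi)
        y, x = cy, cx
        for _ in range(int(1.2 * max(h, w))):
            y += np.sin(angle)
            x += np.cos(angle)
            angle += rng.normal(0.0, 0.15)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < h and 0 <= ix < w):
                break
            img[max(iy - 1, 0): iy + 1, max(ix - 1, 0): ix + 1] -= 0.18

    if config.speckle_sd > 0:
        img = img * (1.0 + rng.normal(0.0, config.speckle_sd, size=img.shape))
    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_slo_dataset(
    config: SyntheticImageConfig,
    n_control: int,
    n_glaucoma: int,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Generate a labelled image collection.

    Returns ``(images, labels, manifest)`` where ``images`` has shape
    ``(n, height, width)`` with intensities in [0, 1], ``labels`` is an array
    of {"control", "glaucoma"} strings (controls first) and ``manifest``
    records per-image provenance.  Identical (config, seed) yields
    bit-identical output.
    """
    config.validate()
    if n_control < 1 or n_glaucoma < 1:
        raise ValueError("n_control and n_glaucoma must be >= 1")
    rng = np.random.default_rng(config.seed)
    images = np.empty((n_control + n_glaucoma, config.image_height, config.image_width))
    labels = np.array([CONTROL] * n_control + [GLAUCOMA] * n_glaucoma)
    rows = []
    for i, label in enumerate(labels):
        if label == CONTROL:
            cdr, rim = config.cup_to_disc_control, config.rim_contrast
        else:
            cdr = config.cup_to_disc_glaucoma
            rim = max(config.rim_contrast - config.rim_contrast_delta, 0.0)
        images[i] = _render_onh(rng, config, cdr, rim)
        rows.append(
            {
                "index": i,
                "filename": f"slo_{i:04d}_{label}.png",
                "label": label,
                "cup_to_disc": cdr,
                "rim_contrast": rim,
                "seed": config.seed,
            }
        )
    return images, labels, pd.DataFrame(rows)


def write_slo_dataset(
    images: np.ndarray,
    manifest: pd.DataFrame,
    out_dir: str | Path,
    bit_depth: int = 8,
) -> Path:
    """Write images as grayscale PNG plus a manifest CSV; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if bit_depth == 8:
        scale, dtype = 255, np.uint8
    elif bit_depth == 16:
        scale, dtype = 65535, np.uint16
    else:
        raise ValueError("bit_depth must be 8 or 16")
    for _, row in manifest.iterrows():
        arr = (images[int(row["index"])] * scale).round().astype(dtype)
        iio.imwrite(out_dir / row["filename"], arr)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_slo_dataset(manifest_path: str | Path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load a written dataset back into float images in [0, 1]."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    images, labels = [], []
    for _, row in manifest.iterrows():
        arr = iio.imread(manifest_path.parent / row["filename"])
        denom = 65535.0 if arr.dtype == np.uint16 else 255.0
        images.append(arr.astype(float) / denom)
        labels.append(row["label"])
    return np.stack(images), np.array(labels), manifest


def generate_rnfl_table(params: RnflPopulationParams, seed: int) -> pd.DataFrame:
    """Sample a labelled thickness table (columns rnflav,ts,t,ti,ns,n,ni,label).

    Each group is drawn from a multivariate normal whose marginals are the
    configured (mean, SD) pairs and whose off-diagonal correlation equals
    ``inter_sector_correlation``; draws are truncated below at 1 um to keep
    thicknesses physical.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    rho = params.inter_sector_correlation
    p = len(RNFL_COLUMNS)
    corr = np.full((p, p), rho)
    np.fill_diagonal(corr, 1.0)
    frames = []
    for group, n, label in (
        (params.control, params.n_control, CONTROL),
        (params.glaucoma, params.n_glaucoma, GLAUCOMA),
    ):
        means = np.array([group[c][0] for c in RNFL_COLUMNS])
        sds = np.array([group[c][1] for c in RNFL_COLUMNS])
        cov = corr * np.outer(sds, sds)
        # eigh tolerates semidefinite covariances (zero-SD degenerate groups)
        draws = rng.multivariate_normal(means, cov, size=n, method="eigh")
        draws = np.maximum(draws, 1.0)
        df = pd.DataFrame(draws, columns=RNFL_COLUMNS)
        df["label"] = label
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def null_image_config(config: SyntheticImageConfig | None = None) -> SyntheticImageConfig:
    """Variant of ``config`` with identical geometry for both classes.

    Under this configuration no classifier can beat chance in expectation.
    """
    base = asdict(config) if config is not None else asdict(SyntheticImageConfig())
    base["cup_to_disc_glaucoma"] = base["cup_to_disc_control"]
    base["rim_contrast_delta"] = 0.0
    return SyntheticImageConfig(**base)


def high_effect_config(height: int = 64, width: int = 80, seed: int = 0) -> SyntheticImageConfig:
    """Strongly separable study condition: wide cup-to-disc gap, low noise.

    Intended for recovery experiments where near-perfect separation of the
    classes is the expected outcome.
    """
    return SyntheticImageConfig(
        image_height=height,
        image_width=width,
        disc_radius_mean=0.22 * min(height, width),
        cup_to_disc_control=0.30,
        cup_to_disc_glaucoma=0.75,
        rim_contrast=0.35,
        noise_sd=0.02,
        speckle_sd=0.04,
        jitter_sd=1.0,
        seed=seed,
    )


def moderate_effect_config(height: int = 64, width: int = 80, seed: int = 0) -> SyntheticImageConfig:
    """Partially overlapping study condition: narrow cup gap, more noise."""
    return SyntheticImageConfig(
        image_height=height,
        image_width=width,
        disc_radius_mean=0.22 * min(height, width),
        cup_to_disc_control=0.40,
        cup_to_disc_glaucoma=0.52,
        rim_contrast=0.25,
        noise_sd=0.08,
        speckle_sd=0.08,
        jitter_sd=2.0,
        seed=seed,
    )
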