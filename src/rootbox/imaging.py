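"""Image-based root phenotyping.

Turns binarized root-core silhouettes into the four plot-level traits used
throughout the package:

* **FD** — box-counting fractal dimension, a proxy for branching density.
  For 2D silhouettes FD runs from 1 (a single unbranched root) to 2 (a
  space-filling, highly branched system).
* **FA** — fractal abundance, the natural-log intercept ``ln K`` of the
  box-count power law; indicates the extent of soil-space exploration.
* **RA** — root angle, the full apex angle of the root cone in a side view,
  in degrees.
* **SD** — stalk diameter, the mean pixel width of the stem portion of a
  side view.

The box-count model is the power law ``N_L = K * L**(-D)``: tiling the image
with grids of box side ``L`` and counting occupied cells ``N_L`` per scale,
then fitting ``ln N_L = ln K - D ln L`` by ordinary least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BinaryImage",
    "ViewSet",
    "BoxCountCurve",
    "FractalEstimate",
    "ArchitectureEstimate",
    "EmptySilhouetteError",
    "default_ladder",
    "preprocess",
    "box_count",
    "fit_fractal",
    "local_dimensions",
    "measure_stalk_diameter",
    "measure_root_angle",
    "aggregate_sample",
    "filter_outliers",
]

SIDE_VIEW_ANGLES = (0, 90, 180, 270)


class EmptySilhouetteError(ValueError):
    """Raised when an image contains no foreground after thresholding."""


@dataclass(frozen=True)
class BinaryImage:
    """A binarized root silhouette. Foreground (True) = root tissue.

    Origin is top-left, row-major; rows increase downward, matching the
    orientation of a hanging root core photographed from the side.
    """

    mask: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2D boolean array")
        object.__setattr__(self, "mask", m)

    @property
    def height(self) -> int:
        return self.mask.shape[0]

    @property
    def width(self) -> int:
        return self.mask.shape[1]

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())

    def padded_to_pow2(self) -> "BinaryImage":
        """Pad with background so both sides equal the next power of two."""
        side = 1 << (max(self.mask.shape) - 1).bit_length()
        if self.mask.shape == (side, side):
            return self
        out = np.zeros((side, side), dtype=bool)
        out[: self.height, : self.width] = self.mask
        return BinaryImage(out)


@dataclass(frozen=True)
class ViewSet:
    """One root-core sample: four side views (90° apart) plus the underside.

    Side and stalk traits (RA, SD) come from the side views; fractal traits
    (FD, FA) from the single underside view.
    """

    side_views: tuple[BinaryImage, BinaryImage, BinaryImage, BinaryImage]
    underside: BinaryImage

    def __post_init__(self):
        if len(self.side_views) != 4:
            raise ValueError("exactly four side views required (0/90/180/270 deg)")
        shapes = {v.mask.shape for v in self.side_views} | {self.underside.mask.shape}
        if len(shapes) != 1:
            raise ValueError("all views must share one canvas size")


@dataclass(frozen=True)
class BoxCountCurve:
    """Box sizes L (strictly increasing powers of two) and occupied counts N_L."""

    box_sizes: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        L = np.asarray(self.box_sizes, dtype=int)
        N = np.asarray(self.counts, dtype=float)
        if L.ndim != 1 or L.shape != N.shape or L.size == 0:
            raise ValueError("box_sizes and counts must be matching 1D arrays")
        if np.any(np.diff(L) <= 0):
            raise ValueError("box_sizes must be strictly increasing")
        if np.any(N < 1):
            raise ValueError("counts must be >= 1 (curve from a non-empty image)")
        object.__setattr__(self, "box_sizes", L)
        object.__setattr__(self, "counts", N)

    def __len__(self) -> int:
        return int(self.box_sizes.size)


@dataclass(frozen=True)
class FractalEstimate:
    """OLS fit of ln N_L on ln L.

    ``fd`` is minus the slope (the box dimension D); ``fa`` is the intercept
    ``ln K`` (natural log). ``k`` = exp(fa) is the abundance on the raw count
    scale, reported alongside because both scales appear in practice.
    """

    fd: float
    fa: float
    fit_r2: float
    local_dims: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> float:
        return float(math.exp(self.fa))


@dataclass(frozen=True)
class ArchitectureEstimate:
    """Per-view RA/SD values and their mean over valid side views."""

    ra_per_view: tuple[float, ...]
    sd_per_view: tuple[float, ...]

    @property
    def ra(self) -> float:
        vals = [v for v in self.ra_per_view if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def sd(self) -> float:
        vals = [v for v in self.sd_per_view if np.isfinite(v)]
        return float(np.mean(vals)) if vals else float("nan")


def default_ladder(side: int = 512) -> np.ndarray:
    """Powers of two from 1 up to ``side`` (ten sizes for a 512-px canvas)."""
    if side < 1 or side & (side - 1):
        raise ValueError("canvas side must be a power of two")
    return 2 ** np.arange(int(math.log2(side)) + 1)


def preprocess(
    raw_image: np.ndarray,
    threshold: float,
    background_reference: np.ndarray | None = None,
) -> BinaryImage:
    """Convert a raw image to a binary silhouette.

    RGB input is converted to luminance (ITU-R 601 weights); if a background
    reference frame is given it is subtracted first (absolute difference).
    A pixel is foreground iff its value is **strictly greater** than
    ``threshold`` — a pixel exactly at the threshold is background.
    """
    img = np.asarray(raw_image, dtype=float)
    if img.size == 0:
        raise ValueError("empty input image")
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    elif img.ndim != 2:
        raise ValueError("expected a 2D grayscale or 3D RGB image")
    if background_reference is not None:
        ref = np.asarray(background_reference, dtype=float)
        if ref.ndim == 3:
            ref = ref[..., :3] @ np.array([0.299, 0.587, 0.114])
        if ref.shape != img.shape:
            raise ValueError("background reference shape mismatch")
        img = np.abs(img - ref)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = img > threshold
    if not mask.any():
        raise EmptySilhouetteError("empty silhouette: no pixel above threshold")
    return BinaryImage(mask)


def box_count(image: BinaryImage, box_sizes: np.ndarray | None = None) -> BoxCountCurve:
    """Count occupied grid cells per box size.

    The grid is anchored at the image origin (no offset averaging). The image
    is padded with background to the next power of two so every ladder size
    divides the side. ``N_L`` is the number of L×L cells containing at least
    one foreground pixel.
    """
    if image.n_foreground == 0:
        raise EmptySilhouetteError("cannot box-count an empty image")
    padded = image.padded_to_pow2()
    side = padded.height
    sizes = default_ladder(side) if box_sizes is None else np.asarray(box_sizes, dtype=int)
    counts = np.empty(sizes.size, dtype=float)
    for i, L in enumerate(sizes):
        if L < 1 or side % L:
            raise ValueError(f"box size {L} does not divide the canvas side {side}")
        blocks = padded.mask.reshape(side // L, L, side // L, L)
        counts[i] = int(blocks.any(axis=(1, 3)).sum())
    return BoxCountCurve(sizes, counts)


def fit_fractal(curve: BoxCountCurve) -> FractalEstimate:
    """Least-squares fit of ln N_L on ln L: FD = -slope, FA = intercept."""
    if len(curve) < 3:
        raise ValueError("need at least 3 scales to fit the power law")
    x = np.log(curve.box_sizes.astype(float))
    y = np.log(curve.counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return FractalEstimate(
        fd=float(-slope),
        fa=float(intercept),
        fit_r2=float(r2),
        local_dims=local_dimensions(curve),
    )


def local_dimensions(curve: BoxCountCurve) -> np.ndarray:
    """Per-scale slopes of ln N vs ln L between consecutive ladder points.

    For the default ten-size ladder this yields nine local box dimensions;
    a flat profile indicates power-law (self-similar) behavior across scales.
    """
    if len(curve) < 2:
        raise ValueError("need at least 2 scales for local dimensions")
    x = np.log(curve.box_sizes.astype(float))
    y = np.log(curve.counts)
    return -np.diff(y) / np.diff(x)


def _row_widths(mask: np.ndarray) -> np.ndarray:
    """Foreground extent (max col - min col + 1) per row; 0 for empty rows."""
    any_fg = mask.any(axis=1)
    widths = np.zeros(mask.shape[0], dtype=float)
    if any_fg.any():
        idx = np.where(any_fg)[0]
        first = mask[idx].argmax(axis=1)
        last = mask.shape[1] - 1 - mask[idx, ::-1].argmax(axis=1)
        widths[idx] = last - first + 1
    return widths


def _stalk_band(mask: np.ndarray, flare_factor: float, top_frac: float) -> np.ndarray:
    """Row indices of the stalk band: the contiguous top run of foreground rows
    before the width profile first exceeds flare_factor x the median width of
    the top ``top_frac`` of foreground rows."""
    widths = _row_widths(mask)
    fg_rows = np.where(widths > 0)[0]
    if fg_rows.size == 0 or fg_rows[0] >= int(0.10 * mask.shape[0]):
        raise ValueError("no stalk detected: no foreground in the top rows")
    top_n = max(1, int(round(top_frac * fg_rows.size)))
    ref = float(np.median(widths[fg_rows[:top_n]]))
    band = []
    prev = None
    for r in fg_rows:
        if band and r != prev + 1:
            break  # stalk band must be contiguous
        if not band and widths[r] < ref / flare_factor:
            continue  # rounded cap at the very top of the stalk: skip
        # the band ends at the flare of the root cone, or at a narrow waist
        # (e.g. where the silhouette pinches in below the stalk)
        if widths[r] > flare_factor * ref or widths[r] < ref / flare_factor:
            break
        band.append(r)
        prev = r
    if not band:
        raise ValueError("no stalk detected: flare at the first foreground row")
    return np.asarray(band)


def measure_stalk_diameter(
    side_view: BinaryImage, flare_factor: float = 1.5, top_frac: float = 0.05
) -> float:
    """Mean foreground width (px) over the stalk band of a side view.

    The stalk band is the contiguous top run of rows whose width stays below
    ``flare_factor`` times the median width of the top ``top_frac`` of
    foreground rows; the flare below (the root cone) is excluded.
    """
    band = _stalk_band(side_view.mask, flare_factor, top_frac)
    return float(_row_widths(side_view.mask)[band].mean())


def measure_root_angle(
    side_view: BinaryImage,
    flare_factor: float = 1.5,
    top_frac: float = 0.05,
    robust: bool = False,
) -> float:
    """Full apex angle (degrees) of the root cone in a side view.

    Fits left and right envelope lines through the per-row extreme foreground
    columns of the root region (the rows below the stalk band) by least
    squares, and returns the angle between them. With ``robust=True`` the
    5th/95th percentile columns per row are used instead of the strict
    min/max, which resists stray pixels in noisy images.
    """
    mask = side_view.mask
    band = _stalk_band(mask, flare_factor, top_frac)
    root_rows = np.where(mask.any(axis=1))[0]
    root_rows = root_rows[root_rows > band[-1]]
    if root_rows.size < 2:
        raise ValueError("no root cone detected below the stalk band")
    lefts = np.empty(root_rows.size)
    rights = np.empty(root_rows.size)
    for i, r in enumerate(root_rows):
        cols = np.where(mask[r])[0]
        if robust:
            lefts[i], rights[i] = np.percentile(cols, [5, 95])
        else:
            lefts[i], rights[i] = cols[0], cols[-1]
    # The cone expands from the apex down to its widest point and then
    # contracts toward the root tips; only the expanding span carries the
    # cone angle, so each envelope is fitted from the apex to its extreme.
    i_l = int(np.argmin(lefts))
    i_r = int(np.argmax(rights))
    if min(i_l, i_r) < 1:
        raise ValueError("no root cone detected: envelope does not expand")
    # column as a function of row depth; slope in px-per-row
    sl, _ = np.polyfit(root_rows[: i_l + 1].astype(float), lefts[: i_l + 1], 1)
    sr, _ = np.polyfit(root_rows[: i_r + 1].astype(float), rights[: i_r + 1], 1)
    # angle of each envelope from the downward vertical, signed outward
    ang_l = math.degrees(math.atan(-sl))
    ang_r = math.degrees(math.atan(sr))
    ra = ang_l + ang_r
    return float(np.clip(ra, 1e-9, 180.0 - 1e-9))


def phenotype_viewset(
    views: ViewSet,
    box_sizes: np.ndarray | None = None,
    flare_factor: float = 1.5,
    robust_angle: bool = False,
) -> dict:
    """Measure all four traits on one sample.

    RA and SD are averaged over the four side views; FD and FA come from the
    underside view only (side profiles contain the stem, which biases the
    fractal fit). Per-view values are retained for diagnostics.
    """
    ra, sd = [], []
    fd_side = []
    for v in views.side_views:
        try:
            ra.append(measure_root_angle(v, flare_factor=flare_factor, robust=robust_angle))
        except ValueError:
            ra.append(float("nan"))
        try:
            sd.append(measure_stalk_diameter(v, flare_factor=flare_factor))
        except ValueError:
            sd.append(float("nan"))
        try:
            fd_side.append(fit_fractal(box_count(v, box_sizes)).fd)
        except (ValueError, EmptySilhouetteError):
            fd_side.append(float("nan"))
    est = fit_fractal(box_count(views.underside, box_sizes))
    arch = ArchitectureEstimate(ra_per_view=tuple(ra), sd_per_view=tuple(sd))
    return {
        "FD": est.fd,
        "FA": est.fa,
        "K": est.k,
        "RA": arch.ra,
        "SD": arch.sd,
        "fit_r2": est.fit_r2,
        "ra_per_view": arch.ra_per_view,
        "sd_per_view": arch.sd_per_view,
        "fd_per_side_view": tuple(fd_side),
    }


def aggregate_sample(view_results: list[dict]) -> dict:
    """Aggregate per-view trait measurements into one plot-level record.

    ``view_results`` holds one dict per view with keys ``view`` (``side`` or
    ``underside``) and the measured traits. RA/SD are arithmetic means over
    valid side views; FD/FA are taken from the underside entry alone.
    """
    side = [r for r in view_results if r.get("view") == "side"]
    under = [r for r in view_results if r.get("view") == "underside"]
    if not under:
        raise ValueError("an underside view is required for FD/FA")
    out: dict = {}
    for trait in ("RA", "SD"):
        vals = [r[trait] for r in side if np.isfinite(r.get(trait, float("nan")))]
        out[trait] = float(np.mean(vals)) if vals else float("nan")
    out["FD"] = under[0].get("FD", float("nan"))
    out["FA"] = under[0].get("FA", float("nan"))
    out["fit_r2"] = under[0].get("fit_r2", float("nan"))
    out["per_view"] = view_results
    return out


def filter_outliers(
    records,
    plot_cols: tuple[str, ...] = ("sample_id",),
    r2_min: float = 0.95,
    mad_factor: float = 4.0,
    trait_cols: tuple[str, ...] = ("FD", "FA", "RA", "SD"),
):
    """Flag image-processing failures in a per-view phenotype table.

    ``records`` holds one row per view with the plot identified by
    ``plot_cols``. A view is dropped when its fractal fit quality falls below
    ``r2_min`` or when any trait deviates more than ``mad_factor`` median
    absolute deviations from its plot's median for that trait. A plot whose
    views all fail is retained as a single row with traits set to NaN
    (missing, never zero-filled) so the design stays visible downstream.
    Every removal is logged with its reason.
    """
    import pandas as pd

    df = records.copy()
    log: list[str] = []
    keep = np.ones(len(df), dtype=bool)
    pos = {idx: i for i, idx in enumerate(df.index)}
    for key, grp in df.groupby(list(plot_cols), sort=False, dropna=False):
        if "fit_r2" in grp.columns:
            r2 = pd.to_numeric(grp["fit_r2"], errors="coerce")
            for idx in grp.index[r2 < r2_min]:
                log.append(f"plot {key} row {idx}: fit_r2 {r2[idx]:.3f} < {r2_min}")
                keep[pos[idx]] = False
        for col in trait_cols:
            if col not in grp.columns:
                continue
            x = pd.to_numeric(grp[col], errors="coerce")
            med = x.median()
            mad = (x - med).abs().median()
            if not np.isfinite(mad) or mad == 0:
                continue
            bad = (x - med).abs() > mad_factor * mad
            for idx in grp.index[bad]:
                if not keep[pos[idx]]:
                    continue  # already logged
                log.append(
                    f"plot {key} row {idx}: {col}={x[idx]:.4g} deviates >"
                    f" {mad_factor} MAD from plot median {med:.4g}"
                )
                keep[pos[idx]] = False
    out = df.loc[keep]
    # re-insert plots that lost every view, as a single all-missing record
    lost = df.loc[~keep]
    if len(lost):
        surviving = set(map(tuple, out[list(plot_cols)].itertuples(index=False)))
        stubs = []
        for key, grp in lost.groupby(list(plot_cols), sort=False, dropna=False):
            k = key if isinstance(key, tuple) else (key,)
            if k in surviving:
                continue
            stub = grp.iloc[[0]].copy()
            for col in trait_cols:
                if col in stub.columns:
                    stub[col] = np.nan
            stubs.append(stub)
            log.append(f"plot {k}: all views removed; traits set to missing")
        if stubs:
            out = pd.concat([out, *stubs])
    return out, log
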