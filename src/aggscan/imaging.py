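"""Quantitation of punctate protein aggregates in micrograph pairs.

The pipeline mirrors automated aggregate counting in yeast attached to
glass: cells are detected as bright objects in a slightly off-focus DIC
image with a locally adaptive threshold; the GFP channel is split into
*punctate* signal (small bright objects passed by a high-pass spatial
filter, read as protein aggregates) and *diffuse* fluorescence (everything
broader than the puncta scale); and the per-strain statistic is the
percentage of fluorescent cells that contain at least one focus.

The size dichotomy is physical: a detected GFP object counts as a focus
only if its equivalent diameter (2*sqrt(area/pi)) is at or below
``puncta_max_diameter`` (default 2 um); larger objects are classified as
diffuse fluorescence.

A small set of helpers for the human-cell arm is included: maximal
intensity projection of z-stacks, aggregate segmentation and size binning
at a 50 um^2 cutoff, and a Mann-Whitney rank-sum test with exact
enumeration at small sample sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter, uniform_filter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .micrograph import Micrograph

__all__ = [
    "SegmentationParams",
    "CellRecord",
    "FocusObject",
    "StrainPhenotype",
    "AggregateSizeResult",
    "local_adaptive_threshold",
    "highpass_puncta_filter",
    "detect_cells",
    "detect_foci",
    "detect_diffuse",
    "quantify_field",
    "calibrate_thresholds",
    "percent_foci",
    "aggregate_replicates",
    "diffuse_vs_foci_correlation",
    "max_project",
    "segment_aggregates",
    "bin_aggregate_sizes",
    "rank_sum_test",
]


@dataclass
class SegmentationParams:
    """Tunable parameters of the quantitation pipeline.

    All physical scales are in micrometres; window sizes are in pixels.

    puncta_max_diameter
        Objects with equivalent diameter above this are diffuse, not foci.
    highpass_scale
        Gaussian sigma of the smoothing subtracted by the puncta high-pass.
    lowpass_scale
        Gaussian sigma of the smoothing used to score diffuse fluorescence.
    local_window / local_offset_k
        Square window and mean + k*sd offset of the locally adaptive
        threshold used for cell detection in the DIC channel.
    puncta_window / puncta_offset_k
        Same rule applied to the high-passed GFP image for focus
        binarization; ``puncta_offset_k`` is the sensitivity that
        :func:`calibrate_thresholds` sets from a positive control.
    puncta_smooth_px
        Sigma (px) of a light matched smoothing applied to the high-passed
        image before binarization; 0 disables it.
    min_focus_area
        Minimum focus area (um^2); rejects single-pixel noise hits.
    fluor_threshold
        Absolute low-passed GFP intensity above which a pixel counts as
        fluorescent; ``None`` selects an Otsu threshold per image (or a
        calibrated value).
    keep_border_cells
        Cells touching the image border are kept by default; exclusion
        would bias counts in dense synthetic fields.
    """

    puncta_max_diameter: float = 2.0
    highpass_scale: float = 0.8
    lowpass_scale: float = 1.2
    local_window: int = 61
    local_offset_k: float = 1.25
    puncta_window: int = 31
    puncta_offset_k: float = 5.0
    puncta_smooth_px: float = 1.0
    min_cell_area: float = 4.0
    max_cell_area: float = 80.0
    min_focus_area: float = 0.1
    focus_guard_px: int = 2
    fluor_threshold: float | None = None
    keep_border_cells: bool = True

    def __post_init__(self) -> None:
        if self.puncta_max_diameter <= 0:
            raise ValueError("puncta_max_diameter must be > 0")
        if not self.highpass_scale < self.lowpass_scale:
            raise ValueError("highpass_scale must be < lowpass_scale")
        for w in (self.local_window, self.puncta_window):
            if w < 3 or w % 2 == 0:
                raise ValueError(f"window must be odd and >= 3, got {w}")


@dataclass
class FocusObject:
    """One detected punctate focus."""

    centroid: tuple[float, float]
    area_um2: float
    equivalent_diameter_um: float
    pixels: np.ndarray = field(repr=False, default=None)  # (n, 2) global coords


@dataclass
class CellRecord:
    """One detected cell with its mask and (once annotated) fluorescence state."""

    cell_id: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1)
    mask: np.ndarray = field(repr=False, default=None)  # bool, bbox-local
    area_um2: float = 0.0
    centroid: tuple[float, float] = (0.0, 0.0)
    is_fluorescent: bool | None = None
    foci: list[FocusObject] = field(default_factory=list)
    diffuse_mean_intensity: float | None = None

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def contains(self, point: tuple[float, float]) -> bool:
        r, c = int(round(point[0])), int(round(point[1]))
        r0, c0, r1, c1 = self.bbox
        return r0 <= r < r1 and c0 <= c < c1 and bool(self.mask[r - r0, c - c0])


@dataclass
class StrainPhenotype:
    """Counts and the percent-of-fluorescent-cells-with-foci statistic.

    ``percent_foci`` is None (undefined, never 0) when no fluorescent cell
    was observed, and propagates as missing through replicate averaging.
    """

    strain_id: str | None
    n_cells: int
    n_fluorescent: int
    n_with_foci: int
    percent_foci: float | None
    replicates: list[float | None] | None = None
    n_undefined_replicates: int = 0

    def __post_init__(self) -> None:
        if not (self.n_with_foci <= self.n_fluorescent <= self.n_cells):
            raise ValueError("counts must satisfy foci <= fluorescent <= cells")
        if self.n_fluorescent > 0 and self.percent_foci is not None:
            expect = 100.0 * self.n_with_foci / self.n_fluorescent
            if abs(self.percent_foci - expect) > 1e-9 and self.replicates is None:
                raise ValueError("percent_foci inconsistent with counts")


@dataclass
class AggregateSizeResult:
    """Aggregate areas binned at a size cutoff (default 50 um^2)."""

    areas: np.ndarray
    cutoff: float
    fraction_small: float
    u_statistic: float | None = None
    p_value: float | None = None


# ---------------------------------------------------------------------------
# filtering and segmentation primitives
# ---------------------------------------------------------------------------


def local_adaptive_threshold(
    img: Micrograph | np.ndarray, window: int, offset_k: float
) -> np.ndarray:
    """Binarize: foreground iff intensity > local mean + offset_k * local sd.

    Local statistics are computed over a square ``window`` (odd, >= 3 px)
    with reflected padding at the image boundary.  The rule is invariant to
    adding a constant to the whole image.
    """
    pixels = img.pixels if isinstance(img, Micrograph) else np.asarray(img, float)
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if window > min(pixels.shape):
        raise ValueError(
            f"window {window} exceeds image dimensions {pixels.shape}"
        )
    mean = uniform_filter(pixels, size=window, mode="reflect")
    mean_sq = uniform_filter(pixels * pixels, size=window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    # guard against float round-off in the running means: in numerically flat
    # regions a pixel can exceed its own window mean by ~1e-12 of the scale
    tol = 1e-8 * (np.abs(pixels).max() + 1.0)
    return pixels > mean + offset_k * np.sqrt(var) + tol


def highpass_puncta_filter(
    gfp: Micrograph, params: SegmentationParams | None = None
) -> Micrograph:
    """Difference-of-scales high-pass amplifying sub-``highpass_scale`` objects.

    Returns the image minus a Gaussian smoothing at ``highpass_scale``
    (sigma, in um), with negatives clipped to zero.  Constant offsets are
    removed exactly; features much broader than the scale are attenuated
    toward zero while puncta are passed nearly unattenuated.
    """
    params = params or SegmentationParams()
    if params.highpass_scale <= 0:
        raise ValueError("highpass_scale must be > 0")
    sigma_px = gfp.um_to_px(params.highpass_scale)
    smoothed = gaussian_filter(gfp.pixels, sigma_px, mode="reflect")
    return Micrograph(np.clip(gfp.pixels - smoothed, 0.0, None), gfp.pixel_size)


def detect_cells(
    dic: Micrograph, params: SegmentationParams | None = None
) -> list[CellRecord]:
    """Detect cells as bright objects in the off-focus DIC proxy.

    Connected components of the locally adaptively thresholded image whose
    areas fall within [min_cell_area, max_cell_area] um^2.  Returned masks
    are disjoint.  Fluorescence fields are left unset.
    """
    params = params or SegmentationParams()
    binary = local_adaptive_threshold(dic, params.local_window, params.local_offset_k)
    labels = cc_label(binary, connectivity=2)
    cells: list[CellRecord] = []
    h, w = dic.shape
    for prop in regionprops(labels):
        area_um2 = prop.area * dic.pixel_area
        if not (params.min_cell_area <= area_um2 <= params.max_cell_area):
            continue
        r0, c0, r1, c1 = prop.bbox
        if not params.keep_border_cells and (
            r0 == 0 or c0 == 0 or r1 == h or c1 == w
        ):
            continue
        cells.append(
            CellRecord(
                cell_id=len(cells) + 1,
                bbox=(r0, c0, r1, c1),
                mask=prop.image.copy(),
                area_um2=float(area_um2),
                centroid=tuple(prop.centroid),
            )
        )
    return cells


def _cells_label_image(cells: Sequence[CellRecord], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=np.int32)
    for cell in cells:
        r0, c0, r1, c1 = cell.bbox
        out[r0:r1, c0:c1][cell.mask] = cell.cell_id
    return out


def detect_foci(
    gfp: Micrograph,
    cells: list[CellRecord],
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """Annotate cells with punctate foci found in the high-passed GFP image.

    The high-passed image is binarized with the locally adaptive rule at
    sensitivity ``puncta_offset_k``; connected components with equivalent
    diameter above ``puncta_max_diameter`` are classified as diffuse (not
    foci) and dropped, as are sub-``min_focus_area`` specks.  A surviving
    focus is assigned to the cell containing its centroid (the rule that
    settles foci straddling two masks); components outside every cell mask
    are ignored.
    """
    params = params or SegmentationParams()
    hp = highpass_puncta_filter(gfp, params)
    # light matched smoothing before binarization: suppresses single-pixel
    # noise while leaving multi-pixel puncta nearly unattenuated
    hp_px = hp.pixels
    if params.puncta_smooth_px > 0:
        hp_px = gaussian_filter(hp_px, params.puncta_smooth_px, mode="reflect")
    binary = local_adaptive_threshold(hp_px, params.puncta_window, params.puncta_offset_k)
    labels = cc_label(binary, connectivity=2)
    cell_labels = _cells_label_image(cells, gfp.shape)
    by_id = {c.cell_id: c for c in cells}
    for c in cells:
        c.foci = []
    for prop in regionprops(labels):
        area_um2 = prop.area * gfp.pixel_area
        eq_diam_um = 2.0 * np.sqrt(area_um2 / np.pi)
        if eq_diam_um > params.puncta_max_diameter:
            continue  # broader than the puncta rule: diffuse fluorescence
        if area_um2 < params.min_focus_area:
            continue
        r, c = (int(round(x)) for x in prop.centroid)
        if not (0 <= r < gfp.shape[0] and 0 <= c < gfp.shape[1]):
            continue
        owner = int(cell_labels[r, c])
        if owner == 0:
            continue
        by_id[owner].foci.append(
            FocusObject(
                centroid=tuple(prop.centroid),
                area_um2=float(area_um2),
                equivalent_diameter_um=float(eq_diam_um),
                pixels=prop.coords.copy(),
            )
        )
    return cells


def detect_diffuse(
    gfp: Micrograph,
    cells: list[CellRecord],
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """Annotate cells with fluorescence status and foci-excluded diffuse intensity.

    A cell is fluorescent iff the low-passed GFP signal exceeds the
    fluorescence threshold over at least half of its mask, or it contains at
    least one focus.  ``diffuse_mean_intensity`` is the mean *raw* GFP over
    the cell mask minus all focus pixels (each focus is excluded together
    with a ``focus_guard_px`` ring so its tails do not bias the diffuse
    estimate); a cell consisting entirely of focus pixels gets None (flagged
    absent).  Expects foci already detected.
    """
    params = params or SegmentationParams()
    sigma_px = gfp.um_to_px(params.lowpass_scale)
    lowpass = gaussian_filter(gfp.pixels, sigma_px, mode="reflect")
    thr = params.fluor_threshold
    if thr is None:
        thr = float(threshold_otsu(lowpass))
    for cell in cells:
        r0, c0, r1, c1 = cell.bbox
        sub = lowpass[r0:r1, c0:c1]
        frac_above = float((sub[cell.mask] > thr).mean())
        cell.is_fluorescent = frac_above >= 0.5 or len(cell.foci) > 0
        diffuse_mask = cell.mask.copy()
        g = params.focus_guard_px
        for f in cell.foci:
            for dr in range(-g, g + 1):
                for dc in range(-g, g + 1):
                    rr = f.pixels[:, 0] - r0 + dr
                    cc = f.pixels[:, 1] - c0 + dc
                    keep = (rr >= 0) & (rr < r1 - r0) & (cc >= 0) & (cc < c1 - c0)
                    diffuse_mask[rr[keep], cc[keep]] = False
        if diffuse_mask.any():
            raw = gfp.pixels[r0:r1, c0:c1]
            cell.diffuse_mean_intensity = float(raw[diffuse_mask].mean())
        else:
            cell.diffuse_mean_intensity = None
    return cells


def quantify_field(
    dic: Micrograph,
    gfp: Micrograph,
    params: SegmentationParams | None = None,
) -> list[CellRecord]:
    """Run the full per-field pipeline: cells -> foci -> fluorescence."""
    params = params or SegmentationParams()
    cells = detect_cells(dic, params)
    detect_foci(gfp, cells, params)
    detect_diffuse(gfp, cells, params)
    return cells


def calibrate_thresholds(
    dic: Micrograph,
    gfp: Micrograph,
    params: SegmentationParams | None = None,
    quantile: float = 0.10,
    k_grid: np.ndarray | None = None,
    plateau_tolerance: float = 0.05,
) -> SegmentationParams:
    """Set sensitivity thresholds from a positive control (high-aggregating) image.

    ``fluor_threshold`` is set to a fixed quantile (default 10%) of the
    within-cell low-passed GFP intensity of the control: in a control in
    which essentially all cells are fluorescent, that quantile sits below
    the diffuse level but above background.

    ``puncta_offset_k`` is set from the control's focus count as a function
    of sensitivity: sweeping the offset over ``k_grid``, the count first
    falls steeply (noise hits vanish), then sits on a plateau (every real
    focus and nothing else), then decays as real foci are lost.  The
    plateau is the widest stretch of the grid over which successive counts
    change by at most ``plateau_tolerance`` (and is positive); the chosen
    offset is the largest k on that plateau, i.e. the least sensitive
    setting that still recovers the plateau count.  Deterministic given the
    control.
    """
    params = params or SegmentationParams()
    cells = detect_cells(dic, params)
    if not cells:
        raise ValueError("positive control contains no detectable cells")
    sigma_px = gfp.um_to_px(params.lowpass_scale)
    lowpass = gaussian_filter(gfp.pixels, sigma_px, mode="reflect")
    within = np.concatenate(
        [
            lowpass[c.bbox[0] : c.bbox[2], c.bbox[1] : c.bbox[3]][c.mask]
            for c in cells
        ]
    )
    fluor_threshold = float(np.quantile(within, quantile))

    probe = replace(params, fluor_threshold=fluor_threshold)
    check = [cell for cell in detect_diffuse(gfp, detect_foci(gfp, cells, probe), probe)]
    if not any(c.is_fluorescent for c in check):
        raise ValueError("positive control contains no fluorescent cells")

    if k_grid is None:
        k_grid = np.arange(1.0, 8.25, 0.25)
    k_grid = np.sort(np.asarray(k_grid, dtype=float))
    counts = []
    for k in k_grid:
        trial = replace(params, puncta_offset_k=float(k))
        detect_foci(gfp, cells, trial)
        counts.append(sum(len(c.foci) for c in cells))
    counts_arr = np.asarray(counts, dtype=float)

    # steps where the count is stable to within the tolerance
    stable = (
        np.abs(np.diff(counts_arr))
        <= plateau_tolerance * np.maximum.reduce(
            [counts_arr[:-1], counts_arr[1:], np.ones(counts_arr.size - 1)]
        )
    )
    chosen = params.puncta_offset_k  # fallback: no plateau found
    best_len = 0
    i = 0
    while i < stable.size:
        if stable[i]:
            j = i
            while j < stable.size and stable[j]:
                j += 1
            # run covers grid points i .. j (inclusive)
            if np.median(counts_arr[i : j + 1]) > 0 and (j - i) >= best_len:
                best_len = j - i
                chosen = float(k_grid[j])
            i = j
        i += 1
    detect_foci(gfp, cells, replace(params, puncta_offset_k=chosen))  # reset state
    return replace(params, fluor_threshold=fluor_threshold, puncta_offset_k=chosen)


# ---------------------------------------------------------------------------
# per-strain statistics
# ---------------------------------------------------------------------------


def percent_foci(
    cells: Sequence[CellRecord], strain_id: str | None = None
) -> StrainPhenotype:
    """Percentage of fluorescent cells containing at least one focus.

    With zero fluorescent cells the statistic is undefined (None), never 0.
    """
    for c in cells:
        if c.is_fluorescent is None:
            raise ValueError("cells must be annotated (run detect_diffuse first)")
    n_cells = len(cells)
    n_fluor = sum(1 for c in cells if c.is_fluorescent)
    n_foci = sum(1 for c in cells if c.is_fluorescent and len(c.foci) > 0)
    pct = 100.0 * n_foci / n_fluor if n_fluor > 0 else None
    return StrainPhenotype(
        strain_id=strain_id,
        n_cells=n_cells,
        n_fluorescent=n_fluor,
        n_with_foci=n_foci,
        percent_foci=pct,
    )


def aggregate_replicates(
    replicates: Sequence[StrainPhenotype], strain_id: str | None = None
) -> StrainPhenotype:
    """Average replicate (clone) percentages into a strain phenotype.

    The strain value is the unweighted mean of the defined replicate
    percentages; undefined replicates (no fluorescent cells) are excluded
    from the mean and their count reported.
    """
    if not replicates:
        raise ValueError("at least one replicate required")
    values = [r.percent_foci for r in replicates]
    defined = [v for v in values if v is not None]
    mean = float(np.mean(defined)) if defined else None
    return StrainPhenotype(
        strain_id=strain_id or replicates[0].strain_id,
        n_cells=sum(r.n_cells for r in replicates),
        n_fluorescent=sum(r.n_fluorescent for r in replicates),
        n_with_foci=sum(r.n_with_foci for r in replicates),
        percent_foci=mean,
        replicates=values,
        n_undefined_replicates=len(values) - len(defined),
    )


def diffuse_vs_foci_correlation(
    percent: Sequence[float], diffuse: Sequence[float]
) -> float:
    """Pearson correlation between strain percent-foci and mean diffuse intensity.

    A low correlation indicates that expression-level differences between
    strains are not driving the aggregation statistic.
    """
    percent = np.asarray(percent, dtype=float)
    diffuse = np.asarray(diffuse, dtype=float)
    if percent.size != diffuse.size or percent.size < 3:
        raise ValueError("need >= 3 paired strain values")
    if np.ptp(percent) == 0 or np.ptp(diffuse) == 0:
        raise ValueError("zero variance in one of the variables")
    return float(stats.pearsonr(percent, diffuse).statistic)


# ---------------------------------------------------------------------------
# human-cell arm: projection, aggregate sizes, rank-sum test
# ---------------------------------------------------------------------------


def max_project(zstack: Sequence[Micrograph]) -> Micrograph:
    """Maximal intensity projection: per-pixel maximum over the stack."""
    if len(zstack) == 0:
        raise ValueError("empty z-stack")
    shape = zstack[0].shape
    ps = zstack[0].pixel_size
    for plane in zstack[1:]:
        if plane.shape != shape:
            raise ValueError("all planes must have the same shape")
    return Micrograph(np.maximum.reduce([p.pixels for p in zstack]), ps)


def segment_aggregates(
    img: Micrograph, min_area_um2: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Segment bright aggregates by Otsu threshold + connected components.

    Returns (areas in um^2, label map), dropping specks below
    ``min_area_um2``.
    """
    thr = threshold_otsu(img.pixels)
    labels = cc_label(img.pixels > thr, connectivity=2)
    areas = []
    keep_labels = np.zeros_like(labels)
    next_id = 0
    for prop in regionprops(labels):
        area = prop.area * img.pixel_area
        if area < min_area_um2:
            continue
        next_id += 1
        keep_labels[labels == prop.label] = next_id
        areas.append(area)
    return np.asarray(areas, dtype=float), keep_labels


def bin_aggregate_sizes(
    areas: Sequence[float], cutoff: float = 50.0
) -> AggregateSizeResult:
    """Bin aggregate areas into smaller/larger than ``cutoff`` um^2.

    Areas exactly at the cutoff count as "larger".
    """
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("no aggregates to bin")
    fraction_small = float((areas < cutoff).mean())
    return AggregateSizeResult(areas=areas, cutoff=cutoff, fraction_small=fraction_small)


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney rank-sum test with midrank ties.

    Returns (U of sample ``a``, two-sided p).  Small samples (both n <= 8,
    or n1 + n2 <= 12) are handled by exact enumeration of all label
    assignments of the pooled values, with the two-sided p defined as the
    probability of a U at least as far from its null mean as observed; the
    enumeration is valid under ties.  Larger samples use the normal
    approximation with the usual tie correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks
    u_obs = _u_statistic(ranks[:n1], n1)
    mu = n1 * n2 / 2.0

    exact = (n1 <= 8 and n2 <= 8) or (n1 + n2 <= 12)
    if exact:
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        idx = range(n1 + n2)
        for comb in itertools.combinations(idx, n1):
            u = _u_statistic(ranks[list(comb)], n1)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var == 0:
        return u_obs, 1.0
    z = (u_obs - mu) / np.sqrt(var)
    return u_obs, float(2.0 * stats.norm.sf(abs(z)))
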