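"""B-scan preprocessing: Bruch detection, flattening, ILM segmentation.

The raw cross-sectional OCT image is turned into a pit-centred, µm-scaled
ILM profile in four steps:

1. :func:`detect_bruch` — locate the bright deep Bruch-membrane band in
   every A-scan (column).
2. :func:`flatten_bscan` — translate each A-scan vertically by a whole
   number of rows so Bruch sits on a common reference line.
3. :func:`segment_ilm` — trace the first vitreous-to-retina bright
   transition from the top of each flattened A-scan, then enforce
   column-to-column smoothness; an optional override table of
   (column, row) corrections replaces interactive fix-up reproducibly.
4. :func:`to_micrometers` — convert to µm using the pixel scales and a
   lateral correction factor (infant eyes are shorter than the adult eyes
   the scanner's lateral scale assumes, so the true lateral scale depends
   on postmenstrual and gestational age), and re-centre laterally so x = 0
   at a sub-pixel estimate of the deepest point.

:func:`select_foveal_bscan` picks the foveal slice of a volume: the B-scan
with the deepest central point, required to have five well-formed
neighbours on either side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d, median_filter

from .errors import (
    CorrectionLookupError,
    GeometryError,
    InsufficientContextError,
    ParameterError,
    SegmentationError,
)
from .profiles import ILMProfile

__all__ = [
    "BScanImage",
    "SegmentationConfig",
    "CorrectionTable",
    "detect_bruch",
    "flatten_bscan",
    "segment_ilm",
    "select_foveal_bscan",
    "to_micrometers",
]


@dataclass
class BScanImage:
    """A grayscale B-scan with axial/lateral pixel scales in µm/px."""

    data: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    volume_index: Optional[int] = None
    flags: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ParameterError("B-scan data must be a 2-D array")
        if min(self.data.shape) < 16:
            raise ParameterError("B-scan must be at least 16 x 16 pixels")
        if self.axial_um_per_px <= 0 or self.lateral_um_per_px <= 0:
            raise ParameterError("pixel scales must be positive")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]


def _band_subpixel(col, peak: int, k: int = 6) -> float:
    """Sub-pixel centre of a bright band at integer row ``peak``.

    Midpoint of the rising and falling half-maximum crossings: each band
    edge is blurred symmetrically, so the midpoint is unbiased even when
    the backgrounds above and below the band differ (vitreous vs tissue).
    """
    n = len(col)
    pv = col[peak]
    a = col[max(peak - k, 0)]
    b = col[min(peak + k, n - 1)]
    lt = 0.5 * (a + pv)
    rt = 0.5 * (b + pv)
    i = peak
    while i > 0 and col[i - 1] >= lt:
        i -= 1
    if i == 0 or col[i] == col[i - 1]:
        xl = float(i)
    else:
        xl = (i - 1) + (lt - col[i - 1]) / (col[i] - col[i - 1])
    j = peak
    while j < n - 1 and col[j + 1] >= rt:
        j += 1
    if j == n - 1 or col[j] == col[j + 1]:
        xr = float(j)
    else:
        xr = j + (col[j] - rt) / (col[j] - col[j + 1])
    return 0.5 * (xl + xr)


@dataclass
class SegmentationConfig:
    smooth_sigma_px: float = 1.5      # axial pre-smoothing of each A-scan
    band_threshold_frac: float = 0.5  # fraction of (max - vitreous) to call tissue
    max_jump_px: float = 5.0          # column-to-column ILM smoothness bound
    median_window: int = 5
    min_contrast: float = 10.0        # columns with less dynamic range fail
    max_failed_frac: float = 0.5


def detect_bruch(image: BScanImage, config: Optional[SegmentationConfig] = None):
    """Per-column row index of the Bruch membrane (the deepest bright band).

    Returns ``(rows, failed)``: float rows (failed columns filled by linear
    interpolation) and a boolean mask of interpolated columns. Raises
    :class:`SegmentationError` when more than half the columns fail.
    """
    cfg = config or SegmentationConfig()
    sm = gaussian_filter1d(image.data, cfg.smooth_sigma_px, axis=0)
    n_rows, n_cols = sm.shape
    rows = np.full(n_cols, np.nan)
    for c in range(n_cols):
        col = sm[:, c]
        lo, hi = col.min(), col.max()
        if hi - lo < cfg.min_contrast:
            continue
        thresh = lo + 0.75 * (hi - lo)
        bright = np.flatnonzero(col >= thresh)
        if bright.size == 0:
            continue
        # the deepest contiguous bright run is the Bruch band
        breaks = np.flatnonzero(np.diff(bright) > 1)
        start = bright[breaks[-1] + 1] if breaks.size else bright[0]
        run = bright[bright >= start]
        peak = int(run[int(np.argmax(col[run]))])
        rows[c] = _band_subpixel(col, peak)
    failed = ~np.isfinite(rows)
    if failed.mean() > cfg.max_failed_frac:
        raise SegmentationError(
            f"Bruch detection failed on {failed.sum()} of {n_cols} columns"
        )
    if failed.any():
        good = np.flatnonzero(~failed)
        rows[failed] = np.interp(np.flatnonzero(failed), good, rows[good])
    return rows, failed


def flatten_bscan(image: BScanImage, bruch_rows, reference_row: int):
    """Shift each A-scan by an integer row count so Bruch sits at
    ``reference_row``.

    Rows shifted in from outside the frame are padded with the column's
    edge value and the padding is flagged. Returns ``(flattened, shifts)``.
    """
    bruch_rows = np.asarray(bruch_rows, dtype=float)
    if bruch_rows.size != image.n_cols:
        raise ParameterError("bruch_rows length must equal the column count")
    if not 0 <= reference_row < image.n_rows:
        raise ParameterError("reference_row outside the image")
    shifts = np.round(reference_row - bruch_rows).astype(int)
    out = np.empty_like(image.data)
    padded = False
    for c, s in enumerate(shifts):
        col = image.data[:, c]
        if s == 0:
            out[:, c] = col
            continue
        shifted = np.empty_like(col)
        if s > 0:  # move content down; pad top with the vitreous edge value
            shifted[s:] = col[: image.n_rows - s]
            shifted[:s] = col[0]
        else:
            shifted[:s] = col[-s:]
            shifted[s:] = col[-1]
        out[:, c] = shifted
        if abs(s) > 0.25 * image.n_rows:
            padded = True
    flags = list(image.flags)
    if padded:
        flags.append("large_flattening_shift_padding")
    flat = BScanImage(
        data=out,
        axial_um_per_px=image.axial_um_per_px,
        lateral_um_per_px=image.lateral_um_per_px,
        volume_index=image.volume_index,
        flags=flags,
    )
    return flat, shifts


def segment_ilm(
    image: BScanImage,
    reference_row: int,
    config: Optional[SegmentationConfig] = None,
    overrides: Optional[Sequence] = None,
) -> ILMProfile:
    """Trace the ILM on a flattened B-scan and return heights above Bruch
    in *pixel* units (x = column index, h = rows above ``reference_row``).

    The tracer takes the first top-down crossing of a per-column threshold
    (vitreous level plus ``band_threshold_frac`` of the column's dynamic
    range), refines it with a median filter, and enforces a maximum
    column-to-column jump by interpolating across violating columns.
    ``overrides`` is an optional sequence of ``(column, row)`` corrections
    applied after automatic segmentation.
    """
    cfg = config or SegmentationConfig()
    sm = gaussian_filter1d(image.data, cfg.smooth_sigma_px, axis=0)
    n_rows, n_cols = sm.shape
    ilm = np.full(n_cols, np.nan)
    for c in range(n_cols):
        col = sm[:, c]
        vit = np.median(col[: max(3, n_rows // 20)])
        hi = col.max()
        if hi - vit < cfg.min_contrast:
            continue
        thresh = vit + cfg.band_threshold_frac * (hi - vit)
        above = np.flatnonzero(col >= thresh)
        if above.size == 0:
            continue
        # first crossing marks the vitreous/retina transition; centre on the
        # local ILM-band peak just below it (the crossing itself sits half a
        # band width too high)
        # first crossing marks the vitreous/retina transition; the ILM band
        # centre is refined to sub-pixel from its two blurred edges
        r0 = above[0]
        win = col[r0 : min(r0 + 7, n_rows)]
        peak = r0 + int(np.argmax(win))
        ilm[c] = _band_subpixel(col, peak)
    failed = ~np.isfinite(ilm)
    if failed.all() or failed.mean() > cfg.max_failed_frac:
        raise SegmentationError("no vitreous/retina transition found")
    if failed.any():
        good = np.flatnonzero(~failed)
        ilm[failed] = np.interp(np.flatnonzero(failed), good, ilm[good])

    ilm = median_filter(ilm, size=cfg.median_window, mode="nearest")
    # enforce smoothness: replace columns starting a too-large jump
    jumps = np.abs(np.diff(ilm)) > cfg.max_jump_px
    if jumps.any():
        bad = np.zeros(n_cols, dtype=bool)
        bad[1:][jumps] = True
        good = np.flatnonzero(~bad)
        if good.size >= 2:
            ilm[bad] = np.interp(np.flatnonzero(bad), good, ilm[good])

    if overrides:
        for col, row in overrides:
            col = int(col)
            if not 0 <= col < n_cols:
                raise ParameterError(f"override column {col} outside image")
            ilm[col] = float(row)

    h_px = reference_row - ilm
    flags = list(image.flags)
    if failed.any():
        flags.append("ilm_interpolated_columns")
    return ILMProfile(
        x=np.arange(n_cols, dtype=float),
        h=np.maximum(h_px, 0.0),
        metadata={
            "units": "px",
            "reference_row": reference_row,
            "axial_um_per_px": image.axial_um_per_px,
            "lateral_um_per_px": image.lateral_um_per_px,
        },
        quality_flags=flags,
    )


def _min_ilm_height_px(image: BScanImage, config=None) -> float:
    """Depth probe for slice selection: minimum ILM height above Bruch."""
    cfg = config or SegmentationConfig()
    bruch, _ = detect_bruch(image, cfg)
    ref = int(round(np.median(bruch)))
    flat, _ = flatten_bscan(image, bruch, ref)
    prof = segment_ilm(flat, ref, cfg)
    # restrict to the central half: the pit is central by protocol
    n = prof.h.size
    return float(prof.h[n // 4 : 3 * n // 4].min())


def select_foveal_bscan(volume: Sequence[BScanImage], config=None) -> int:
    """Index of the foveal B-scan in a volume.

    The foveal slice has the deepest central point (minimum ILM height
    above Bruch); it must have five analysable slices on either side, and
    ties go to the slice nearest the volume centre.
    """
    n = len(volume)
    if n < 11:
        raise InsufficientContextError("volume must have at least 11 B-scans")
    depths = np.full(n, np.inf)
    for i, img in enumerate(volume):
        try:
            depths[i] = _min_ilm_height_px(img, config)
        except SegmentationError:
            pass  # unanalysable slice: never a candidate, breaks flanking runs
    best = np.min(depths)
    candidates = np.flatnonzero(depths <= best + 1e-9)
    centre = (n - 1) / 2.0
    candidates = sorted(candidates, key=lambda i: (abs(i - centre), i))
    idx = int(candidates[0])
    if idx < 5 or idx > n - 6:
        raise InsufficientContextError(
            f"foveal candidate at slice {idx} lacks 5 flanking B-scans"
        )
    flanks = depths[idx - 5 : idx + 6]
    if not np.all(np.isfinite(flanks)):
        raise InsufficientContextError(
            "an unanalysable B-scan interrupts the 5-slice context window"
        )
    return idx


class CorrectionTable:
    """Lateral-scale correction factors indexed by (PMA, GA) in weeks.

    The scanner's lateral scale assumes an adult axial eye length; infant
    eyes are shorter, so lateral distances must be multiplied by an
    age-dependent factor. The literature conversion values are not bundled
    — load a user-supplied table (CSV with columns ``pma_weeks, ga_weeks,
    factor``) or pass factors directly. Lookups round the requested PMA
    and GA to the nearest whole week; a missing entry raises, it is never
    silently defaulted.
    """

    def __init__(self, entries: dict):
        self._entries = {
            (int(round(p)), int(round(g))): float(f) for (p, g), f in entries.items()
        }
        for k, f in self._entries.items():
            if f <= 0:
                raise ParameterError(f"correction factor for {k} must be > 0")

    @classmethod
    def from_csv(cls, path) -> "CorrectionTable":
        import pandas as pd

        df = pd.read_csv(path)
        for col in ("pma_weeks", "ga_weeks", "factor"):
            if col not in df.columns:
                raise ParameterError(f"correction table missing column {col!r}")
        return cls({(r.pma_weeks, r.ga_weeks): r.factor for r in df.itertuples()})

    def lookup(self, pma_weeks: float, ga_weeks: float) -> float:
        key = (int(round(pma_weeks)), int(round(ga_weeks)))
        if key not in self._entries:
            raise CorrectionLookupError(
                f"no lateral correction entry for PMA={key[0]}, GA={key[1]} weeks"
            )
        return self._entries[key]


def to_micrometers(
    profile: ILMProfile,
    axial_um_per_px: Optional[float] = None,
    lateral_um_per_px: Optional[float] = None,
    lateral_correction: float = 1.0,
) -> ILMProfile:
    """Convert a pixel-unit ILM profile to µm and re-centre at the pit.

    The lateral coordinate is multiplied by ``lateral_um_per_px x
    lateral_correction`` and shifted so x = 0 at the vertex of a local
    quadratic fitted over +-5 samples around the deepest sample (sub-pixel
    pit centring); heights are multiplied by ``axial_um_per_px``.
    """
    ax = axial_um_per_px or profile.metadata.get("axial_um_per_px")
    lat = lateral_um_per_px or profile.metadata.get("lateral_um_per_px")
    if ax is None or lat is None:
        raise ParameterError("axial and lateral pixel scales are required")
    if lateral_correction <= 0:
        raise ParameterError("lateral_correction must be > 0")

    x_um = profile.x * lat * lateral_correction
    h_um = profile.h * ax

    i0 = int(np.argmin(h_um))
    lo, hi = max(0, i0 - 5), min(len(x_um), i0 + 6)
    if hi - lo >= 3:
        coef = np.polyfit(x_um[lo:hi], h_um[lo:hi], 2)
        if coef[0] > 0:
            vertex = -coef[1] / (2.0 * coef[0])
            # only trust the vertex if it stays inside the local window
            if x_um[lo] <= vertex <= x_um[hi - 1]:
                x_um = x_um - vertex
            else:
                x_um = x_um - x_um[i0]
        else:
            x_um = x_um - x_um[i0]
    else:
        x_um = x_um - x_um[i0]

    meta = dict(profile.metadata)
    meta.update({"units": "um", "lateral_correction": lateral_correction})
    return ILMProfile(x=x_um, h=h_um, metadata=meta,
                      quality_flags=list(profile.quality_flags))
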