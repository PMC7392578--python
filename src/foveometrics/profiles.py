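"""The flattened internal-limiting-membrane (ILM) contour.

An :class:`ILMProfile` is the central in-memory object handed between the
image-preprocessing stage and the contour model: lateral positions in µm
(zero at the foveal pit centre, temporal negative, nasal positive by
convention) and heights above the Bruch membrane in µm (so height equals
retinal thickness).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

NASAL = "nasal"
TEMPORAL = "temporal"
SIDES = (NASAL, TEMPORAL)


@dataclass
class ILMProfile:
    """Pit-centred ILM contour in micrometres.

    Parameters
    ----------
    x : ndarray
        Lateral position in µm, strictly increasing; 0 at (or adjacent to)
        the foveal pit centre. Temporal side negative, nasal positive.
    h : ndarray
        Height above the Bruch membrane in µm; non-negative (height above
        Bruch is retinal thickness).
    metadata : dict
        Acquisition metadata (infant id, eye, PMA and GA in weeks, scales).
    quality_flags : list of str
        Non-fatal issues raised during preprocessing (interpolated columns,
        padding, low SNR ...).
    """

    x: np.ndarray
    h: np.ndarray
    metadata: dict = field(default_factory=dict)
    quality_flags: list = field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        if self.x.ndim != 1 or self.h.ndim != 1 or self.x.size != self.h.size:
            raise ParameterError("x and h must be 1-D arrays of equal length")
        if self.x.size < 3:
            raise ParameterError("profile needs at least 3 samples")
        if not np.all(np.diff(self.x) > 0):
            raise ParameterError("x must be strictly increasing")
        if np.any(self.h < 0):
            raise ParameterError("heights above Bruch must be non-negative")

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def spacing(self) -> float:
        """Median lateral sample spacing in µm."""
        return float(np.median(np.diff(self.x)))

    def side_samples(self, side: str):
        """Distance-from-pit / height samples for one side.

        The pit-centre sample (nearest ``x = 0``) is included on both sides
        so each per-side fit is anchored at the pit bottom.
        """
        i0 = int(np.argmin(np.abs(self.x)))
        if side == NASAL:
            sel = self.x >= self.x[i0]
            return np.abs(self.x[sel]), self.h[sel]
        if side == TEMPORAL:
            sel = self.x <= self.x[i0]
            return np.abs(self.x[sel])[::-1], self.h[sel][::-1]
        raise ParameterError(f"side must be one of {SIDES}, got {side!r}")

    def pit_height(self) -> float:
        """Observed height at the sample nearest the pit centre."""
        return float(self.h[int(np.argmin(np.abs(self.x)))])

    def extent(self, side: str) -> float:
        """Maximum distance from the pit centre available on ``side`` (µm)."""
        d, _ = self.side_samples(side)
        return float(d[-1]) if d.size else 0.0

    def mirrored(self) -> "ILMProfile":
        """Left/right mirror image (nasal and temporal swapped)."""
        return ILMProfile(
            x=-self.x[::-1],
            h=self.h[::-1].copy(),
            metadata=dict(self.metadata),
            quality_flags=list(self.quality_flags),
        )
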