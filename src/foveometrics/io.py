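"""Readers and writers for the pipeline's file formats.

Plain-text formats throughout: ILM profiles as two-column CSV (`x_um,
h_um`) with a JSON metadata sidecar, cohort tables as CSV with a
documented column dictionary, DoG fits as JSON, B-scans as multi-page
TIFF. Every reader validates its input and names the offending column /
row / field on failure; every writer/reader pair round-trips exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import validate_cohort
from .dog import DoGFit, DoGFitConfig, DoGSideParams
from .errors import SchemaError
from .profiles import ILMProfile, SIDES

__all__ = [
    "write_profile_csv", "read_profile_csv",
    "write_cohort_csv", "read_cohort_csv",
    "write_fit_json", "read_fit_json",
    "write_bscan_tiff", "read_bscan_tiff",
    "COHORT_COLUMN_DICTIONARY",
]

#: column dictionary written alongside cohort CSVs
COHORT_COLUMN_DICTIONARY = {
    "infant_id": "anonymised infant identifier",
    "eye": "right | left",
    "pma_weeks": "postmenstrual age at imaging (weeks)",
    "ga_weeks": "gestational age at birth (weeks)",
    "bw_g": "birthweight (grams)",
    "rop": "ROP status at this visit: absent | present",
    "sex": "M | F",
    "ethnicity": "Caucasian | non-Caucasian",
    "birth": "single | multiple",
    "poor_quality": "image excluded for poor quality (bool)",
    "cystic": "image excluded for cystoid change (bool)",
    "width_um": "foveal width, rim to rim (um)",
    "depth_um": "foveal depth, mean rim height minus pit floor (um)",
    "area_um2": "pit cross-sectional area below the rim chord (um^2)",
    "cft_um": "central foveal thickness (um)",
    "slope_nasal": "steepest nasal wall slope (um/um)",
    "slope_temporal": "steepest temporal wall slope (um/um)",
    "prt_nasal_um": "nasal parafoveal retinal thickness at 1000 um (um)",
    "prt_temporal_um": "temporal parafoveal retinal thickness at 1000 um (um)",
}


def write_profile_csv(profile: ILMProfile, path) -> None:
    path = Path(path)
    pd.DataFrame({"x_um": profile.x, "h_um": profile.h}).to_csv(
        path, index=False, float_format="%.17g"
    )
    sidecar = {"metadata": profile.metadata, "quality_flags": profile.quality_flags}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, default=str))


def read_profile_csv(path) -> ILMProfile:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("x_um", "h_um"):
        if col not in df.columns:
            raise SchemaError(f"profile CSV missing column {col!r}")
    bad = df.index[~np.isfinite(df["x_um"]) | ~np.isfinite(df["h_um"])]
    if len(bad):
        raise SchemaError(f"profile CSV has a non-finite value at row {bad[0]}")
    meta, flags = {}, []
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        payload = json.loads(sidecar.read_text())
        meta = payload.get("metadata", {})
        flags = payload.get("quality_flags", [])
    return ILMProfile(
        x=df["x_um"].to_numpy(), h=df["h_um"].to_numpy(),
        metadata=meta, quality_flags=flags,
    )


def write_cohort_csv(table: pd.DataFrame, path, with_dictionary: bool = True) -> None:
    validate_cohort(table)
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.17g")
    if with_dictionary:
        path.with_suffix(".columns.json").write_text(
            json.dumps(COHORT_COLUMN_DICTIONARY, indent=2)
        )


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    validate_cohort(table)
    return table


_FIT_SIDE_FIELDS = ("a_pit_um", "sigma_pit_um", "a_para_um", "sigma_para_um")


def write_fit_json(fit: DoGFit, path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=2))


def read_fit_json(path) -> DoGFit:
    payload = json.loads(Path(path).read_text())
    for field in ("baseline_um", "sides"):
        if field not in payload:
            raise SchemaError(f"fit JSON missing field {field!r}")
    sides, rss, n_points = {}, {}, {}
    for s in SIDES:
        if s not in payload["sides"]:
            raise SchemaError(f"fit JSON missing side {s!r}")
        rec = payload["sides"][s]
        for field in _FIT_SIDE_FIELDS:
            if field not in rec:
                raise SchemaError(f"fit JSON side {s!r} missing field {field!r}")
        sides[s] = DoGSideParams(
            a_pit=rec["a_pit_um"], sigma_pit=rec["sigma_pit_um"],
            a_para=rec["a_para_um"], sigma_para=rec["sigma_para_um"],
        )
        rss[s] = rec.get("rss_um", float("nan"))
        n_points[s] = rec.get("n_points", 0)
    cfg = None
    if "config" in payload:
        known = {k: v for k, v in payload["config"].items()
                 if k in DoGFitConfig.__dataclass_fields__}
        for key in ("sigma_bounds", "baseline_bounds"):
            if key in known:
                known[key] = tuple(known[key])
        cfg = DoGFitConfig(**known)
    return DoGFit(
        baseline=payload["baseline_um"], sides=sides, rss=rss,
        converged=payload.get("converged", True), n_points=n_points,
        cost=payload.get("cost", float("nan")),
        degenerate=payload.get("degenerate", False),
        message=payload.get("message", ""), config=cfg,
    )


def write_bscan_tiff(images, path) -> None:
    """Write one or more B-scans as a multi-page float32 TIFF."""
    import tifffile

    from .preprocess import BScanImage

    if isinstance(images, BScanImage):
        images = [images]
    stack = np.stack([img.data.astype(np.float32) for img in images])
    meta = {
        "axial_um_per_px": images[0].axial_um_per_px,
        "lateral_um_per_px": images[0].lateral_um_per_px,
    }
    tifffile.imwrite(path, stack, metadata=meta)


def read_bscan_tiff(path, axial_um_per_px: Optional[float] = None,
                    lateral_um_per_px: Optional[float] = None):
    """Read a (multi-page) TIFF as a list of B-scans.

    Pixel scales are taken from the TIFF metadata when present; explicit
    arguments override.
    """
    import tifffile

    from .preprocess import BScanImage

    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    ax = axial_um_per_px or meta.get("axial_um_per_px")
    lat = lateral_um_per_px or meta.get("lateral_um_per_px")
    if ax is None or lat is None:
        raise SchemaError("TIFF lacks pixel-scale metadata; pass scales explicitly")
    if stack.ndim == 2:
        stack = stack[None]
    return [
        BScanImage(data=stack[i], axial_um_per_px=float(ax),
                   lateral_um_per_px=float(lat), volume_index=i)
        for i in range(stack.shape[0])
    ]
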