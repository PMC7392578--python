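"""Synthetic ILM profiles, OCT B-scans and longitudinal cohorts.

The study scans this package was designed around are not publicly
deposited, so every downstream stage is exercised against simulated data
with known generating truth:

* :func:`gen_ilm_profile` samples the two-sided DoG foveal contour (plus
  optional Gaussian height noise) — the generating analogue of the model
  that :mod:`foveometrics.dog` fits.
* :func:`gen_bscan` renders a grayscale B-scan from a contour using a
  three-band intensity model (dark vitreous, mid-grey retina bounded by a
  bright ILM band and a bright Bruch band) with optional blur and
  multiplicative speckle; the exact per-column ILM and Bruch rows are
  returned as ground truth. Default geometry mirrors the hand-held OCT
  volume protocol: 500 A-scans over 10 mm laterally (20 µm/px) and a 2-mm
  axial window.
* :func:`gen_cohort` simulates a longitudinal preterm cohort imaged at 1–2
  week intervals between 31 and 44 weeks postmenstrual age (PMA), with
  group-specific linear PMA trends for foveal width (decreasing without
  ROP, increasing with ROP), quadratic PMA trends for depth/CFT/slope,
  gestational-age and birthweight effects, per-infant random intercepts
  and residual noise. The generating coefficients are returned so that
  mixed-model recovery can be checked against truth.

Each generator draws from its own named pseudo-random stream derived from
the seed, so adding one generator never perturbs another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .dog import DoGFit, DoGSideParams, dog_eval
from .errors import ConfigurationError, GeometryError, ParameterError
from .profiles import ILMProfile, NASAL, TEMPORAL, SIDES

__all__ = [
    "SideTruth",
    "ProfileTruth",
    "ScanGeometry",
    "BScanTruth",
    "CohortSpec",
    "gen_ilm_profile",
    "gen_bscan",
    "gen_cohort",
    "truth_to_fit",
    "truth_from_metrics",
]

# stream ids keep the generators' random draws independent of each other
_STREAM_PROFILE = 1
_STREAM_BSCAN = 2
_STREAM_COHORT = 3


@dataclass
class SideTruth:
    """Generating DoG parameters for one side of the fovea."""

    pit_amplitude: float = 120.0   # um, > 0 (inverted pit Gaussian)
    pit_sigma: float = 400.0       # um
    para_amplitude: float = 60.0   # um, signed (negative = inverted parafovea)
    para_sigma: float = 1500.0     # um

    def validate(self):
        if self.pit_amplitude <= 0:
            raise ParameterError("pit_amplitude must be > 0")
        if self.pit_sigma <= 0 or self.para_sigma <= 0:
            raise ParameterError("Gaussian sigmas must be > 0")
        if not self.pit_sigma < self.para_sigma:
            raise ParameterError("pit_sigma must be narrower than para_sigma")


@dataclass
class ProfileTruth:
    """Ground truth for one synthetic ILM profile.

    Note that a physically continuous contour needs the same pit-bottom
    height ``baseline + para_amplitude - pit_amplitude`` on both sides;
    asymmetric truths should vary the sigmas and trade amplitude between
    the two Gaussians under that constraint (the fitted model shares its
    baseline and ties both sides to the observed pit bottom, so only
    continuous truths are exactly recoverable).
    """

    baseline_height: float = 200.0  # um above Bruch
    nasal: SideTruth = field(default_factory=SideTruth)
    temporal: SideTruth = field(default_factory=SideTruth)
    noise_sd: float = 0.0           # um
    n_points: int = 500
    lateral_extent: float = 10000.0  # um, full span
    seed: int = 0

    def validate(self):
        self.nasal.validate()
        self.temporal.validate()
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.n_points < 50:
            raise ParameterError("n_points must be >= 50")
        if self.lateral_extent <= 0:
            raise ParameterError("lateral_extent must be > 0")

    def side(self, side: str) -> SideTruth:
        if side == NASAL:
            return self.nasal
        if side == TEMPORAL:
            return self.temporal
        raise ParameterError(f"side must be one of {SIDES}")


def truth_to_fit(truth: ProfileTruth) -> DoGFit:
    """View the generating truth as a DoGFit (for evaluating the noiseless
    contour and for comparing recovered parameters against truth)."""
    sides = {
        s: DoGSideParams(
            a_pit=truth.side(s).pit_amplitude,
            sigma_pit=truth.side(s).pit_sigma,
            a_para=truth.side(s).para_amplitude,
            sigma_para=truth.side(s).para_sigma,
        )
        for s in SIDES
    }
    return DoGFit(
        baseline=truth.baseline_height,
        sides=sides,
        rss={s: 0.0 for s in SIDES},
        converged=True,
        n_points={s: 0 for s in SIDES},
    )


def truth_from_metrics(width_um: float, cft_um: float, depth_um: float = 80.0) -> ProfileTruth:
    """Single-pit generating truth (negligible parafoveal term) whose rim-to-rim
    width and central thickness equal the requested values.

    For a lone pit Gaussian the rim sits at ``sigma_pit * sqrt(3 + sqrt 6)``,
    so ``sigma_pit = width / (2 sqrt(3+sqrt 6))``; the baseline is the pit
    height plus the pit amplitude.
    """
    if width_um <= 0 or cft_um <= 0 or depth_um <= 0:
        raise ParameterError("width, cft and depth must be positive")
    sigma_pit = width_um / (2.0 * np.sqrt(3.0 + np.sqrt(6.0)))
    a_pit = depth_um / (1.0 - np.exp(-0.5 * (3.0 + np.sqrt(6.0))))  # approx: rim ~ baseline
    side = SideTruth(
        pit_amplitude=a_pit,
        pit_sigma=sigma_pit,
        para_amplitude=1e-9,
        para_sigma=max(4.0 * sigma_pit, 2000.0),
    )
    return ProfileTruth(
        baseline_height=cft_um + a_pit,
        nasal=side,
        temporal=SideTruth(**asdict(side)),
    )


def gen_ilm_profile(truth: ProfileTruth, metadata: Optional[dict] = None) -> ILMProfile:
    """Sample the two-sided DoG contour at ``n_points`` evenly spaced lateral
    positions spanning ``lateral_extent``, plus Gaussian height noise.

    Deterministic given ``truth`` (including its seed); with ``noise_sd=0``
    the samples equal the model exactly.
    """
    truth.validate()
    x = np.linspace(-truth.lateral_extent / 2.0, truth.lateral_extent / 2.0, truth.n_points)
    fit = truth_to_fit(truth)
    h = np.where(
        x >= 0,
        dog_eval(fit, NASAL, np.abs(x), order=0),
        dog_eval(fit, TEMPORAL, np.abs(x), order=0),
    )
    if truth.noise_sd > 0:
        rng = np.random.default_rng([truth.seed, _STREAM_PROFILE])
        h = h + rng.normal(0.0, truth.noise_sd, size=h.shape)
    h = np.maximum(h, 0.0)
    meta = {"generator": "gen_ilm_profile", "seed": truth.seed}
    if metadata:
        meta.update(metadata)
    return ILMProfile(x=x, h=h, metadata=meta)


@dataclass
class ScanGeometry:
    """Raster geometry of a rendered B-scan.

    Defaults follow the hand-held OCT protocol: 500 A-scans across 10 mm
    (20 µm/px lateral); the axial window is 2 mm deep. The axial pixel
    count is configurable (512 rows by default, ~3.9 µm/px).
    """

    n_cols: int = 500
    n_rows: int = 512
    lateral_um_per_px: float = 20.0
    axial_depth_um: float = 2000.0
    bruch_row: float = 400.0
    bruch_tilt_px: float = 0.0  # linear Bruch ramp (px) across the image

    @property
    def axial_um_per_px(self) -> float:
        return self.axial_depth_um / self.n_rows

    @property
    def lateral_extent_um(self) -> float:
        return self.n_cols * self.lateral_um_per_px


@dataclass
class BScanTruth:
    """Ground-truth boundary rows (float, per column) of a rendered B-scan."""

    ilm_rows: np.ndarray
    bruch_rows: np.ndarray


# three-band intensity model; the renderer guarantees band boundaries equal
# the returned ground truth, not any particular pixel statistics
_VITREOUS_LEVEL = 25.0
_TISSUE_LEVEL = 110.0
_BAND_LEVEL = 220.0
_BAND_HALFWIDTH_PX = 1.5


def gen_bscan(
    truth: ProfileTruth,
    geometry: Optional[ScanGeometry] = None,
    speckle_sd: float = 0.0,
    blur_sigma_px: float = 1.0,
):
    """Render a grayscale B-scan of the contour in ``truth``.

    Returns ``(image, truth_rows)`` where ``image`` is a
    :class:`~foveometrics.preprocess.BScanImage` and ``truth_rows`` the
    exact per-column ILM/Bruch rows used. ``speckle_sd`` > 0 multiplies
    pixel intensities by log-normal speckle; ``blur_sigma_px`` smooths band
    edges with a Gaussian kernel.
    """
    from scipy.ndimage import gaussian_filter

    from .preprocess import BScanImage

    truth.validate()
    geo = geometry or ScanGeometry()
    cols = np.arange(geo.n_cols)
    x = (cols - (geo.n_cols - 1) / 2.0) * geo.lateral_um_per_px
    fit = truth_to_fit(truth)
    h_um = np.where(
        x >= 0,
        dog_eval(fit, NASAL, np.abs(x), order=0),
        dog_eval(fit, TEMPORAL, np.abs(x), order=0),
    )
    bruch_rows = geo.bruch_row + geo.bruch_tilt_px * cols / max(geo.n_cols - 1, 1)
    ilm_rows = bruch_rows - h_um / geo.axial_um_per_px
    margin = _BAND_HALFWIDTH_PX + 1
    if np.any(ilm_rows < margin) or np.any(bruch_rows > geo.n_rows - margin - 1):
        raise GeometryError("contour leaves the image frame; enlarge geometry")

    rows = np.arange(geo.n_rows)[:, None]
    img = np.full((geo.n_rows, geo.n_cols), _VITREOUS_LEVEL, dtype=float)
    img[(rows > ilm_rows[None, :]) & (rows < bruch_rows[None, :])] = _TISSUE_LEVEL
    img[np.abs(rows - ilm_rows[None, :]) <= _BAND_HALFWIDTH_PX] = _BAND_LEVEL
    img[np.abs(rows - bruch_rows[None, :]) <= _BAND_HALFWIDTH_PX] = _BAND_LEVEL

    if blur_sigma_px > 0:
        img = gaussian_filter(img, blur_sigma_px)
    if speckle_sd > 0:
        rng = np.random.default_rng([truth.seed, _STREAM_BSCAN])
        img = img * rng.lognormal(mean=0.0, sigma=speckle_sd, size=img.shape)

    image = BScanImage(
        data=img,
        axial_um_per_px=geo.axial_um_per_px,
        lateral_um_per_px=geo.lateral_um_per_px,
    )
    return image, BScanTruth(ilm_rows=ilm_rows, bruch_rows=bruch_rows)


@dataclass
class CohortSpec:
    """Generating model of a longitudinal preterm imaging cohort.

    Width follows group-specific linear PMA trends (µm/week, PMA centred
    at 32 weeks) on top of group intercepts at 32 weeks; the default slopes
    and intercepts are the ROP-absent/ROP-present values the width model is
    expected to recover. Depth, CFT and steepest slope carry quadratic PMA
    terms; area, depth, CFT, slope and pRT carry gestational-age (GA) and
    birthweight (BW) effects. Between-infant heterogeneity enters as a
    random intercept; visit-level noise as i.i.d. residuals. The variance
    components are not literature values — they are set to give visible but
    recoverable effects.
    """

    n_infants: int = 80
    pma_range: tuple = (31.0, 44.0)
    visit_interval: tuple = (1, 2)   # weeks, sampled per visit
    prop_rop: float = 0.35
    width_slope_rop_absent: float = -11.18   # um/week
    width_slope_rop_present: float = 24.96   # um/week
    width_intercept_rop_absent: float = 1584.9   # um at 32 wk PMA
    width_intercept_rop_present: float = 1203.6  # um at 32 wk PMA
    ga_range: tuple = (24.0, 31.0)
    bw_range: tuple = (500.0, 1500.0)
    between_infant_sd: float = 150.0  # um, width random intercept
    residual_sd: float = 100.0        # um, width visit-level noise
    # quadratic PMA coefficients (per week^2, PMA centred at 32 wk)
    quad_depth: float = -0.35
    quad_cft: float = 0.30
    quad_slope: float = -2.0e-4
    # GA effects (per week of GA, centred at 28 wk) and BW effects
    # (per 100 g, centred at 1000 g); GA and BW are correlated by
    # construction, mirroring the collinearity of prematurity measures
    ga_effects: dict = field(
        default_factory=lambda: {
            "depth_um": 6.0, "area_um2": 20000.0, "cft_um": -8.0,
            "slope": 4.0e-3, "prt_um": 10.0,
        }
    )
    bw_effects: dict = field(
        default_factory=lambda: {
            "depth_um": 1.5, "area_um2": 6000.0, "cft_um": 0.0,
            "slope": 1.0e-3, "prt_um": 3.0,
        }
    )
    rop_transition_prob: float = 0.0  # per-visit status flip probability
    both_eyes: bool = True
    prob_poor_quality: float = 0.0
    prob_cystic: float = 0.0
    seed: int = 0

    def validate(self):
        lo, hi = self.pma_range
        if not (31.0 <= lo < hi <= 44.0):
            raise ParameterError("pma_range must lie within [31, 44] weeks")
        if not set(self.visit_interval) <= {1, 2}:
            raise ParameterError("visit intervals must be 1 or 2 weeks")
        if not 0.0 <= self.prop_rop <= 1.0:
            raise ParameterError("prop_rop must be a fraction in [0, 1]")
        for name in ("between_infant_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if hi - lo < min(self.visit_interval):
            raise ConfigurationError("pma_range too short for even 2 visits")


# baseline levels at PMA 32 wk / GA 28 wk / BW 1000 g for the non-width metrics
_BASELINES = {
    "depth_um": 80.0,
    "area_um2": 90000.0,
    "cft_um": 200.0,
    "slope": 0.12,
    "prt_um": 320.0,
}
# linear PMA trends (per week from 32) for the non-width metrics
_PMA_LINEAR = {
    "depth_um": 3.0,
    "area_um2": 1500.0,
    "cft_um": -2.0,
    "slope": 3.0e-3,
    "prt_um": 4.0,
}
# visit-level residual SDs for the non-width metrics (fractions of baseline)
_METRIC_NOISE_FRAC = 0.06


def gen_cohort(spec: Optional[CohortSpec] = None):
    """Simulate a longitudinal cohort table.

    Returns ``(table, truth)``: a tidy pandas DataFrame with one row per
    (infant, eye, visit) and a dict echoing every generating coefficient.
    Deterministic given the spec (including its seed).
    """
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng([spec.seed, _STREAM_COHORT])
    lo, hi = spec.pma_range

    rows = []
    for i in range(spec.n_infants):
        infant = f"inf{i:03d}"
        ga = rng.uniform(*spec.ga_range)
        # BW tracks GA (the prematurity measures are collinear) plus noise
        bw = float(np.clip(
            spec.bw_range[0]
            + (ga - spec.ga_range[0])
            / (spec.ga_range[1] - spec.ga_range[0])
            * (spec.bw_range[1] - spec.bw_range[0])
            + rng.normal(0, 120.0),
            *spec.bw_range,
        ))
        rop0 = rng.random() < spec.prop_rop
        sex = "M" if rng.random() < 0.5 else "F"
        ethnicity = "Caucasian" if rng.random() < 0.7 else "non-Caucasian"
        birth = "multiple" if rng.random() < 0.25 else "single"
        b_i = rng.normal(0.0, spec.between_infant_sd)
        b_i_frac = rng.normal(0.0, 0.05)  # shared relative shift, other metrics

        # visit schedule: 1-2 weekly from a jittered start until 44 wk
        pma = lo + rng.uniform(0.0, 1.0)
        pmas = []
        while pma <= hi:
            pmas.append(pma)
            pma += rng.choice(spec.visit_interval)
        if len(pmas) < 2:
            pmas.append(min(hi, pmas[0] + min(spec.visit_interval)))

        eyes = ("right", "left") if spec.both_eyes else ("right",)
        rop = rop0
        for pma in pmas:
            if spec.rop_transition_prob > 0 and rng.random() < spec.rop_transition_prob:
                rop = not rop
            pma = round(pma, 2)  # the recorded PMA drives the generating mean
            t = pma - 32.0
            g = ga - 28.0
            w = (bw - 1000.0) / 100.0
            for eye in eyes:
                if rop:
                    mu_w = spec.width_intercept_rop_present + spec.width_slope_rop_present * t
                else:
                    mu_w = spec.width_intercept_rop_absent + spec.width_slope_rop_absent * t
                width = mu_w + b_i + rng.normal(0.0, spec.residual_sd)

                vals = {}
                for m, base in _BASELINES.items():
                    mu = (
                        base
                        + _PMA_LINEAR[m] * t
                        + {"depth_um": spec.quad_depth,
                           "cft_um": spec.quad_cft,
                           "slope": spec.quad_slope}.get(m, 0.0) * t * t
                        + spec.ga_effects[m] * g
                        + spec.bw_effects[m] * w
                    )
                    mu = mu * (1.0 + b_i_frac)
                    noise = rng.normal(0.0, _METRIC_NOISE_FRAC * abs(base))
                    vals[m] = max(mu + noise, 1e-3)

                rows.append({
                    "infant_id": infant,
                    "eye": eye,
                    "pma_weeks": pma,
                    "ga_weeks": round(ga, 2),
                    "bw_g": round(bw, 1),
                    "rop": "present" if rop else "absent",
                    "sex": sex,
                    "ethnicity": ethnicity,
                    "birth": birth,
                    "poor_quality": bool(rng.random() < spec.prob_poor_quality),
                    "cystic": bool(rng.random() < spec.prob_cystic),
                    "width_um": width,
                    "depth_um": vals["depth_um"],
                    "area_um2": vals["area_um2"],
                    "cft_um": vals["cft_um"],
                    # nasal wall slightly steeper / thicker than temporal
                    "slope_nasal": vals["slope"] * 1.05,
                    "slope_temporal": vals["slope"] * 0.95,
                    "prt_nasal_um": vals["prt_um"] * 1.03,
                    "prt_temporal_um": vals["prt_um"] * 0.97,
                })

    table = pd.DataFrame(rows)
    if table.empty:
        raise ConfigurationError("cohort spec produced no visits")
    truth = {
        "width_slope_rop_absent": spec.width_slope_rop_absent,
        "width_slope_rop_present": spec.width_slope_rop_present,
        "width_intercept_rop_absent": spec.width_intercept_rop_absent,
        "width_intercept_rop_present": spec.width_intercept_rop_present,
        "between_infant_sd": spec.between_infant_sd,
        "residual_sd": spec.residual_sd,
        "quad_pma": {"depth_um": spec.quad_depth, "cft_um": spec.quad_cft,
                     "slope": spec.quad_slope},
        "ga_effects": dict(spec.ga_effects),
        "bw_effects": dict(spec.bw_effects),
        "pma_center": 32.0,
        "seed": spec.seed,
    }
    return table, truth
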