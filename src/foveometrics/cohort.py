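"""Longitudinal cohort statistics for foveal parameters.

The scientific question is whether a foveal parameter's trajectory with
postmenstrual age (PMA) differs between eyes with and without retinopathy
of prematurity (ROP) once the degree of prematurity is adjusted for. Each
parameter is modelled with a linear mixed-effects model:

    y_ij = b0 + b1 PMA* + [b2 PMA*^2] + b3 ROP + b4 ROP x PMA*
             + b5 (GA or BW) + sex + ethnicity + birth + eye [+ side] + u_i + e_ij

where PMA* = PMA - 32 weeks (so the ROP main effect is the 32-week
contrast), ``u_i`` is a random intercept per infant, and GA and BW enter
*separate* models — they are strongly collinear measures of prematurity
and are never used together. Fitting is by REML; inference on fixed
effects uses Wald statistics, and predicted means with 95% confidence
intervals come from linear combinations of the fixed effects.

The module also carries the cohort bookkeeping: exclusion/subgroup
percentage accounting and the 2x2 chi-square test for the inverted-
parafovea frequency contrast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AccountingError,
    CohortValidationError,
    ParameterError,
    UndefinedTestError,
)

__all__ = [
    "PMA_CENTER_WEEKS",
    "round_half_up",
    "validate_cohort",
    "cohort_accounting",
    "chi_square_2x2",
    "FovealTrajectoryModel",
    "TrajectoryResults",
    "fit_mixed_model",
    "rop_interaction_rejection_rate",
]

PMA_CENTER_WEEKS = 32.0

_METRIC_COLUMNS = (
    "width_um", "depth_um", "area_um2", "cft_um",
    "slope_nasal", "slope_temporal", "prt_nasal_um", "prt_temporal_um",
)
_SIDED_RESPONSES = {
    "slope": ("slope_nasal", "slope_temporal"),
    "prt_um": ("prt_nasal_um", "prt_temporal_um"),
}


def round_half_up(x: float) -> int:
    """Round a non-negative percentage to the nearest integer, halves up."""
    if x < 0:
        raise ParameterError("percentages must be non-negative")
    return int(math.floor(x + 0.5))


def validate_cohort(table: pd.DataFrame) -> None:
    """Schema checks for a longitudinal cohort table.

    Raises :class:`CohortValidationError` naming the offending column and
    the first violating row index.
    """
    required = ["infant_id", "eye", "pma_weeks", "ga_weeks", "bw_g", "rop"]
    for col in required:
        if col not in table.columns:
            raise CohortValidationError(f"missing required column {col!r}")

    def _first_bad(mask, col, rule):
        idx = table.index[mask]
        if len(idx):
            raise CohortValidationError(
                f"column {col!r} violates {rule} at row {idx[0]}"
            )

    _first_bad(~table["pma_weeks"].between(31.0, 44.0), "pma_weeks", "PMA in [31, 44] weeks")
    _first_bad(table["ga_weeks"] >= table["pma_weeks"], "ga_weeks", "GA < PMA")
    _first_bad(table["bw_g"] <= 0, "bw_g", "BW > 0")
    _first_bad(~table["rop"].isin(["absent", "present"]), "rop", "rop in {absent, present}")
    _first_bad(~table["eye"].isin(["right", "left"]), "eye", "eye in {right, left}")

    excl = np.zeros(len(table), dtype=bool)
    for flag in ("poor_quality", "cystic"):
        if flag in table.columns:
            excl |= table[flag].astype(bool).to_numpy()
    if excl.any():
        metrics_present = [c for c in _METRIC_COLUMNS if c in table.columns]
        if metrics_present:
            has_val = table.loc[excl, metrics_present].notna().any(axis=1)
            idx = has_val.index[has_val]
            if len(idx):
                raise CohortValidationError(
                    f"excluded row {idx[0]} carries metric values"
                )


# ---------------------------------------------------------------------------
# Cohort accounting
# ---------------------------------------------------------------------------


@dataclass
class CohortCounts:
    recruited: int
    unanalyzable: int
    cystic: int
    analyzed: int
    never_rop: int
    always_rop: int
    mixed_rop: int


def cohort_accounting(counts: CohortCounts) -> pd.DataFrame:
    """Exclusion and ROP-pattern percentages from participant counts.

    Recruitment-level exclusions are expressed over the recruited total,
    ROP-pattern subgroups over the analysed total; percentages are rounded
    half-up to the integer. Additive identities are enforced and an
    :class:`AccountingError` names the violated one.
    """
    c = counts
    for name, v in vars(c).items():
        if v < 0:
            raise AccountingError(f"count {name!r} is negative")
    if c.unanalyzable + c.cystic + c.analyzed != c.recruited:
        raise AccountingError(
            "unanalyzable + cystic + analyzed != recruited "
            f"({c.unanalyzable} + {c.cystic} + {c.analyzed} != {c.recruited})"
        )
    if c.never_rop + c.always_rop + c.mixed_rop != c.analyzed:
        raise AccountingError(
            "never_rop + always_rop + mixed_rop != analyzed "
            f"({c.never_rop} + {c.always_rop} + {c.mixed_rop} != {c.analyzed})"
        )
    rows = [
        ("unanalyzable", c.unanalyzable, c.recruited),
        ("cystic", c.cystic, c.recruited),
        ("analyzed", c.analyzed, c.recruited),
        ("never_rop", c.never_rop, c.analyzed),
        ("always_rop", c.always_rop, c.analyzed),
        ("mixed_rop", c.mixed_rop, c.analyzed),
    ]
    out = []
    for name, num, den in rows:
        if den == 0:
            raise AccountingError(f"zero denominator for {name!r}")
        out.append({
            "group": name,
            "n": num,
            "denominator": den,
            "percent": round_half_up(100.0 * num / den),
        })
    return pd.DataFrame(out)


def chi_square_2x2(table, correction: bool = False):
    """Pearson chi-square (df = 1) on a 2x2 contingency table.

    ``table`` is [[a, b], [c, d]]; Yates continuity correction is off by
    default. A zero row or column margin makes the test undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ParameterError("table must be 2x2 with non-negative counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise UndefinedTestError("a zero margin leaves expected counts undefined")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Trajectory mixed model
# ---------------------------------------------------------------------------


class FovealTrajectoryModel:
    """Linear mixed-effects trajectory model for one foveal parameter.

    Parameters
    ----------
    data : DataFrame
        Visit-level cohort table (wide metric columns); excluded rows
        (``poor_quality`` or ``cystic``) are dropped.
    response : str
        A metric column, or ``"slope"`` / ``"prt_um"`` to analyse the
        nasal/temporal pair jointly with a ``side`` fixed effect.
    adjustment : {"ga", "bw", None}
        Which prematurity measure enters the model (never both).
    quadratic_pma : bool
        Add a PMA-squared fixed effect (depth, CFT and steepest slope show
        curvature in their trajectories).
    extra_factors : bool
        Include sex, ethnicity, birth multiplicity and eye as fixed factors.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str,
        adjustment: Optional[str] = "ga",
        quadratic_pma: bool = False,
        extra_factors: bool = True,
        validate: bool = True,
    ):
        if adjustment not in ("ga", "bw", None):
            raise ParameterError("adjustment must be 'ga', 'bw' or None")
        if validate:
            validate_cohort(data)
        df = data.copy()
        for flag in ("poor_quality", "cystic"):
            if flag in df.columns:
                df = df[~df[flag].astype(bool)]

        self.sided = response in _SIDED_RESPONSES
        if self.sided:
            n_col, t_col = _SIDED_RESPONSES[response]
            keep = [c for c in df.columns if c not in (n_col, t_col)]
            long = pd.concat(
                [
                    df[keep].assign(side="nasal", _y=df[n_col]),
                    df[keep].assign(side="temporal", _y=df[t_col]),
                ],
                ignore_index=True,
            )
            df = long
            ycol = "_y"
        else:
            if response not in df.columns:
                raise ParameterError(f"response column {response!r} not in table")
            ycol = response

        df = df[np.isfinite(df[ycol])]
        n_per_infant = df.groupby("infant_id")["pma_weeks"].nunique()
        if (n_per_infant >= 2).mean() < 0.5:
            raise ParameterError(
                "fewer than half the infants have 2+ visits; trajectories "
                "are not identifiable"
            )
        df["pma_c"] = df["pma_weeks"] - PMA_CENTER_WEEKS
        df["ga_c"] = df["ga_weeks"] - 28.0
        df["bw_c100"] = (df["bw_g"] - 1000.0) / 100.0

        terms = ["pma_c"]
        if quadratic_pma:
            terms.append("I(pma_c ** 2)")
        terms += ["C(rop, Treatment('absent'))",
                  "pma_c:C(rop, Treatment('absent'))"]
        if adjustment == "ga":
            terms.append("ga_c")
        elif adjustment == "bw":
            terms.append("bw_c100")
        if extra_factors:
            for f in ("sex", "ethnicity", "birth", "eye"):
                if f in df.columns and df[f].nunique() > 1:
                    terms.append(f"C({f})")
        if self.sided and df["side"].nunique() > 1:
            terms.append("C(side)")

        self.formula = f"{ycol} ~ " + " + ".join(terms)
        self.data = df
        self.response = response
        self.adjustment = adjustment
        self.quadratic_pma = quadratic_pma

    @classmethod
    def from_dataframe(cls, data, response, **kwargs) -> "FovealTrajectoryModel":
        return cls(data, response, **kwargs)

    def fit(self, reml: bool = True) -> "TrajectoryResults":
        import statsmodels.formula.api as smf

        fallback = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(self.formula, self.data, groups=self.data["infant_id"])
                res = model.fit(reml=reml, method=["lbfgs", "cg"])
                converged = bool(res.converged)
            except Exception:
                # degenerate random structure (e.g. one visit per infant):
                # fall back to ordinary least squares, flagged
                res = smf.ols(self.formula, self.data).fit()
                converged = True
                fallback = "ols"
        return TrajectoryResults(self, res, converged=converged, fallback=fallback)


class TrajectoryResults:
    """Fitted trajectory model: fixed effects, group slopes, predictions."""

    _ROP_TERM = "C(rop, Treatment('absent'))[T.present]"
    _INTER_TERM = "pma_c:C(rop, Treatment('absent'))[T.present]"

    def __init__(self, model: FovealTrajectoryModel, result, converged=True, fallback=None):
        self.model = model
        self.result = result
        self.converged = converged
        self.fallback = fallback
        self._fe_names = list(result.fe_params.index) if hasattr(result, "fe_params") \
            else list(result.params.index)

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params if hasattr(self.result, "fe_params") \
            else self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse[self._fe_names]

    @property
    def pvalues(self) -> pd.Series:
        return self.result.pvalues[self._fe_names]

    def _fe_cov(self) -> pd.DataFrame:
        cov = self.result.cov_params()
        return cov.loc[self._fe_names, self._fe_names]

    @property
    def random_intercept_var(self) -> float:
        if hasattr(self.result, "cov_re"):
            return float(np.asarray(self.result.cov_re)[0, 0])
        return float("nan")

    @property
    def residual_var(self) -> float:
        return float(self.result.scale)

    def fixed_effects(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.fe_params,
            "se": self.bse,
            "p": self.pvalues,
        })

    def slope_by_rop(self) -> dict:
        """Per-group PMA slope (estimate, SE) in response units per week."""
        fe = self.fe_params
        cov = self._fe_cov()
        out = {"absent": {"estimate": float(fe["pma_c"]),
                          "se": float(np.sqrt(cov.loc["pma_c", "pma_c"]))}}
        if self._INTER_TERM in fe.index:
            est = fe["pma_c"] + fe[self._INTER_TERM]
            var = (cov.loc["pma_c", "pma_c"]
                   + cov.loc[self._INTER_TERM, self._INTER_TERM]
                   + 2.0 * cov.loc["pma_c", self._INTER_TERM])
            out["present"] = {"estimate": float(est), "se": float(np.sqrt(var))}
        return out

    def rop_pma_interaction(self) -> dict:
        """Wald test of the ROP x PMA interaction."""
        fe = self.fe_params
        if self._INTER_TERM not in fe.index:
            raise ParameterError("model has no ROP x PMA interaction term")
        return {
            "estimate": float(fe[self._INTER_TERM]),
            "se": float(self.bse[self._INTER_TERM]),
            "p": float(self.pvalues[self._INTER_TERM]),
        }

    def _design_row(self, profile: dict) -> np.ndarray:
        import patsy

        base = {
            "pma_weeks": PMA_CENTER_WEEKS, "ga_weeks": 28.0, "bw_g": 1000.0,
            "rop": "absent",
        }
        for f in ("sex", "ethnicity", "birth", "eye", "side"):
            if f in self.model.data.columns:
                base[f] = self.model.data[f].mode().iloc[0]
        base.update(profile)
        row = pd.DataFrame([base])
        row["pma_c"] = row["pma_weeks"] - PMA_CENTER_WEEKS
        row["ga_c"] = row["ga_weeks"] - 28.0
        row["bw_c100"] = (row["bw_g"] - 1000.0) / 100.0
        design_info = self.result.model.data.design_info
        return np.asarray(patsy.dmatrix(design_info, row))[0]

    def predict_means(self, profiles: Sequence[dict], alpha: float = 0.05) -> pd.DataFrame:
        """Predicted population mean with Wald CI for each covariate profile.

        Profiles are dicts of covariate values (e.g. ``{"pma_weeks": 32,
        "rop": "present", "ga_weeks": 28}``); unspecified covariates are
        filled with reference values. A profile whose PMA lies outside the
        observed range is flagged ``extrapolated``.
        """
        fe = self.fe_params.to_numpy()
        cov = self._fe_cov().to_numpy()
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        pma_lo = self.model.data["pma_weeks"].min()
        pma_hi = self.model.data["pma_weeks"].max()
        rows = []
        for prof in profiles:
            x = self._design_row(prof)
            mean = float(x @ fe)
            q = float(x @ cov @ x)
            se = float(np.sqrt(q)) if q >= 0 else float("nan")
            pma = prof.get("pma_weeks", PMA_CENTER_WEEKS)
            rows.append({
                **prof,
                "mean": mean,
                "se": se,
                "ci_low": mean - z * se,
                "ci_high": mean + z * se,
                "extrapolated": not (pma_lo <= pma <= pma_hi),
            })
        return pd.DataFrame(rows)

    def predicted_ratio(self, profile_num: dict, profile_den: dict) -> int:
        """Ratio of two predicted means, as a half-up-rounded percentage.

        Invariant to any rescaling of the response (µm vs mm).
        """
        pm = self.predict_means([profile_num, profile_den])
        return predicted_mean_ratio(pm["mean"].iloc[0], pm["mean"].iloc[1])

    def summary(self) -> str:
        lines = [
            f"Foveal trajectory model: {self.model.response} "
            f"(adjustment: {self.model.adjustment or 'none'}"
            f"{', quadratic PMA' if self.model.quadratic_pma else ''})",
            f"n_obs = {len(self.model.data)}, "
            f"n_infants = {self.model.data['infant_id'].nunique()}, "
            f"converged = {self.converged}"
            + (f", fallback = {self.fallback}" if self.fallback else ""),
            "",
            self.fixed_effects().to_string(float_format=lambda v: f"{v:10.4g}"),
            "",
            f"random intercept var = {self.random_intercept_var:.4g}, "
            f"residual var = {self.residual_var:.4g}",
        ]
        slopes = self.slope_by_rop()
        for grp, s in slopes.items():
            lines.append(
                f"PMA slope (ROP {grp}): {s['estimate']:+.3f} +- {s['se']:.3f} per week"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response": self.model.response,
            "adjustment": self.model.adjustment,
            "formula": self.model.formula,
            "converged": self.converged,
            "fallback": self.fallback,
            "n_obs": int(len(self.model.data)),
            "n_infants": int(self.model.data["infant_id"].nunique()),
            "fixed_effects": {
                name: {
                    "estimate": float(self.fe_params[name]),
                    "se": float(self.bse[name]),
                    "p": float(self.pvalues[name]),
                }
                for name in self._fe_names
            },
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "slopes_by_rop": self.slope_by_rop(),
        }

    def plot_trajectories(self, pma_grid=None, ax=None):
        """Predicted mean trajectories (with CIs) for ROP absent/present."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        if pma_grid is None:
            pma_grid = np.linspace(
                self.model.data["pma_weeks"].min(),
                self.model.data["pma_weeks"].max(), 40,
            )
        for rop, color in (("absent", "tab:blue"), ("present", "tab:red")):
            pm = self.predict_means(
                [{"pma_weeks": float(p), "rop": rop} for p in pma_grid]
            )
            ax.plot(pma_grid, pm["mean"], color=color, label=f"ROP {rop}")
            ax.fill_between(pma_grid, pm["ci_low"], pm["ci_high"], color=color, alpha=0.2)
        ax.set_xlabel("postmenstrual age (weeks)")
        ax.set_ylabel(self.model.response)
        ax.legend(frameon=False)
        return ax


def predicted_mean_ratio(mean_num: float, mean_den: float) -> int:
    """Two predicted means as a half-up-rounded percentage ratio."""
    if mean_den == 0:
        raise ParameterError("denominator mean is zero")
    return round_half_up(100.0 * mean_num / mean_den)


def fit_mixed_model(
    table: pd.DataFrame,
    response: str,
    adjustment: Optional[str] = "ga",
    quadratic_pma: bool = False,
    **kwargs,
) -> TrajectoryResults:
    """Convenience wrapper: build and fit a :class:`FovealTrajectoryModel`."""
    return FovealTrajectoryModel(
        table, response, adjustment=adjustment, quadratic_pma=quadratic_pma, **kwargs
    ).fit()


def rop_interaction_rejection_rate(
    n_reps: int = 500,
    n_infants: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical size of the ROP x PMA Wald test under a null cohort.

    Cohorts are generated with identical width trajectories in both ROP
    groups (no ROP effect anywhere), single-eye to keep replicates cheap,
    and the interaction p-value collected from a GA-adjusted width model.
    """
    from .synthetic import CohortSpec, gen_cohort

    rejections = 0
    used = 0
    for r in range(n_reps):
        spec = CohortSpec(
            n_infants=n_infants,
            prop_rop=0.5,
            width_slope_rop_present=-11.18,
            width_slope_rop_absent=-11.18,
            width_intercept_rop_present=1584.9,
            width_intercept_rop_absent=1584.9,
            both_eyes=False,
            seed=(seed * 100003 + r) % (2**31 - 1),
        )
        table, _ = gen_cohort(spec)
        try:
            res = FovealTrajectoryModel(
                table, "width_um", adjustment="ga", extra_factors=False,
                validate=False,
            ).fit()
            p = res.rop_pma_interaction()["p"]
        except Exception:
            continue
        used += 1
        if p < alpha:
            rejections += 1
    if used == 0:
        raise ParameterError("no replicate produced a fitted model")
    return rejections / used
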