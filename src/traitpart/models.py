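"""Mixed-model selection and marginal-means contrasts for CWM and FD responses.

For each response (a trait CWM or a functional diversity metric measured per
plot) the candidate set holds the five fixed-effect structures respecting
marginality — intercept, climate, treatment, climate + treatment,
climate x treatment — each with a random intercept for the physical site
(block letter).  Candidates are fitted by maximum likelihood (ML rather than
REML: REML likelihoods are not comparable across different fixed effects) and
compared by AICc,

    AICc = AIC + 2 k (k + 1) / (n - k - 1),

where k counts fixed-effect coefficients plus the random-intercept and
residual variances.  When several candidates sit within two AICc units of the
best, the one with the fewest parameters is chosen.  Pairwise differences
among factor levels are then examined via estimated marginal means (level
means averaged over the other factor with equal weights) with a Tukey
studentized-range adjustment within each contrast family; skewed, strictly
positive responses (leaf-area and seed-mass CWMs by default) are modelled on
the log scale and back-transformed for reporting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy.stats import studentized_range
from statsmodels.regression.mixed_linear_model import MixedLM

from .data_model import ValidationError

#: responses modelled on the log scale (right-skewed, strictly positive)
LOG_RESPONSES = ("CWM_LA", "CWM_seed_mass")

FIXED_STRUCTURES = (
    "1",
    "climate",
    "treatment",
    "climate + treatment",
    "climate * treatment",
)


@dataclass(frozen=True)
class ModelSpec:
    """One candidate: response, fixed-effect structure, transform, random
    intercept on the block letter."""

    response: str
    fixed: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.fixed not in FIXED_STRUCTURES:
            raise ValidationError(f"fixed structure {self.fixed!r} not in candidate set")
        if self.transform not in ("identity", "log"):
            raise ValidationError(f"unknown transform {self.transform!r}")

    @property
    def formula(self) -> str:
        rhs = self.fixed.replace("climate", "C(climate)").replace(
            "treatment", "C(treatment)"
        )
        return f"_y ~ {rhs}"

    @property
    def factors(self) -> tuple[str, ...]:
        out = []
        for f in ("climate", "treatment"):
            if f in self.fixed:
                out.append(f)
        return tuple(out)

    @property
    def has_interaction(self) -> bool:
        return "*" in self.fixed

    def label(self) -> str:
        return f"{self.response} ~ {self.fixed}"


def candidate_set(response: str, log_transform: bool | None = None) -> list[ModelSpec]:
    """The five marginality-respecting candidates for one response.

    ``log_transform=None`` applies the log scale exactly for the responses in
    ``LOG_RESPONSES``.
    """
    if log_transform is None:
        log_transform = response in LOG_RESPONSES
    transform = "log" if log_transform else "identity"
    return [ModelSpec(response, fixed, transform) for fixed in FIXED_STRUCTURES]


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC; infinite when the correction denominator
    n - k - 1 is not positive."""
    if n - k - 1 <= 0:
        return np.inf
    return aic + 2.0 * k * (k + 1.0) / (n - k - 1.0)


@dataclass
class CandidateFit:
    spec: ModelSpec
    k: int
    llf: float
    aic: float
    aicc: float
    converged: bool          # usable fit: finite ML likelihood
    singular: bool           # random-intercept variance at the zero boundary
    result: object = field(repr=False, default=None)
    optimizer_converged: bool = True


@dataclass
class SelectionResult:
    """AICc comparison of the candidate fits plus the chosen model."""

    candidates: list[CandidateFit]
    chosen: CandidateFit

    @property
    def table(self) -> pd.DataFrame:
        rows = []
        best = min(c.aicc for c in self.candidates)
        for c in self.candidates:
            rows.append(
                {
                    "model": c.spec.label(), "fixed": c.spec.fixed,
                    "transform": c.spec.transform, "k": c.k, "loglik": c.llf,
                    "AICc": c.aicc, "dAICc": c.aicc - best,
                    "chosen": c is self.chosen, "singular": c.singular,
                }
            )
        return pd.DataFrame(rows)


def _prepare(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    for col in (spec.response, "climate", "treatment", "block"):
        if col not in data.columns:
            raise ValidationError(f"data lacks column {col!r}")
    df = data.copy()
    y = df[spec.response].astype(float)
    if spec.transform == "log":
        bad = df.index[y <= 0].tolist()
        if bad:
            raise ValidationError(
                f"log transform of {spec.response!r} impossible; "
                f"non-positive values at rows {bad}"
            )
        y = np.log(y)
    df["_y"] = y
    return df


def fit_candidate(spec: ModelSpec, data: pd.DataFrame) -> CandidateFit:
    """ML fit of one candidate; a near-zero random-intercept variance is
    flagged as singular but the model is kept."""
    df = _prepare(data, spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(spec.formula, groups="block", data=df)
        result = model.fit(reml=False)
        if not np.isfinite(result.llf):
            result = model.fit(reml=False, method="lbfgs")
    k_fe = len(result.fe_params)
    k = k_fe + 2  # + random-intercept variance + residual variance
    llf = float(result.llf)
    aic = 2.0 * k - 2.0 * llf
    n = int(result.nobs)
    # a boundary (zero-variance) random intercept is common in small designs:
    # the ML fit is still valid for AICc comparison, so flag it but keep it;
    # the optimizer's own convergence flag routinely reports False there
    singular = float(result.cov_re.iloc[0, 0]) < 1e-6 * max(result.scale, 1e-12)
    return CandidateFit(
        spec=spec, k=k, llf=llf, aic=aic, aicc=aicc(aic, k, n),
        converged=bool(np.isfinite(llf)), singular=singular, result=result,
        optimizer_converged=bool(result.converged),
    )


def select(candidates: list[CandidateFit]) -> CandidateFit:
    """Minimum AICc, except that any model within two units of the best with
    fewer parameters supersedes it (fewest parameters wins; AICc breaks ties)."""
    usable = [c for c in candidates if np.isfinite(c.aicc)]
    if not usable:
        raise ValidationError("no candidate has a finite AICc")
    best = min(c.aicc for c in usable)
    near = [c for c in usable if c.aicc - best < 2.0]
    return min(near, key=lambda c: (c.k, c.aicc))


def fit_and_select(specs: list[ModelSpec], data: pd.DataFrame) -> SelectionResult:
    """Fit every candidate and apply the AICc + fewest-parameters rule.

    Candidates that fail to converge are excluded from selection (but kept,
    flagged, in the comparison table)."""
    fits = []
    for spec in specs:
        n = len(data)
        if n < spec_param_count(spec) + 2:
            raise ValidationError(
                f"{spec.label()}: needs at least k+2={spec_param_count(spec) + 2} "
                f"observations, have {n}"
            )
        try:
            fits.append(fit_candidate(spec, data))
        except (np.linalg.LinAlgError, ValueError) as err:  # non-convergence paths
            fits.append(CandidateFit(spec, spec_param_count(spec), np.nan, np.nan,
                                     np.inf, False, False, None))
            warnings.warn(f"{spec.label()} failed to fit: {err}")
    chosen = select([f for f in fits if f.converged] or fits)
    return SelectionResult(fits, chosen)


def spec_param_count(spec: ModelSpec, n_climates: int = 3, n_treatments: int = 3) -> int:
    k_fe = 1
    if "climate" in spec.fixed:
        k_fe += n_climates - 1
    if "treatment" in spec.fixed:
        k_fe += n_treatments - 1
    if spec.has_interaction:
        k_fe += (n_climates - 1) * (n_treatments - 1)
    return k_fe + 2


# ---------------------------------------------------------------------------
# Estimated marginal means and pairwise contrasts


def _design_rows(result, grid: pd.DataFrame) -> np.ndarray:
    design_info = result.model.data.design_info
    (mat,) = patsy.build_design_matrices([design_info], grid)
    return np.asarray(mat)


def _emm_row(result, grid: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    rows = _design_rows(result, grid[mask])
    return rows.mean(axis=0)


def marginal_means_contrasts(
    fit: CandidateFit, data: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means and Tukey-adjusted pairwise contrasts.

    Marginal means average model predictions over the levels of the other
    factor with equal weights.  Contrast families are (a) all level pairs of
    each factor in the model and, when the interaction is present, (b) level
    pairs of one factor within each level of the other.  Degrees of freedom
    are the residual n - p; for log-scale models back-transformed means and
    ratio estimates are reported alongside.
    """
    spec, result = fit.spec, fit.result
    if result is None:
        raise ValidationError(f"{spec.label()} has no fitted result")
    df_data = _prepare(data, spec)
    climates = sorted(df_data["climate"].unique())
    treatments = sorted(df_data["treatment"].unique())
    grid = pd.DataFrame(
        list(itertools.product(climates, treatments)), columns=["climate", "treatment"]
    )
    fe = result.fe_params.to_numpy()
    fe_names = list(result.fe_params.index)
    cov = np.asarray(result.cov_params().loc[fe_names, fe_names])
    n = int(result.nobs)
    p = len(fe)
    ddf = max(n - p, 1)
    log_scale = spec.transform == "log"

    levels = {"climate": climates, "treatment": treatments}
    emm_rows, contrast_rows = [], []

    def _estimate(L: np.ndarray) -> tuple[float, float]:
        est = float(L @ fe)
        se = float(np.sqrt(L @ cov @ L))
        return est, se

    def _emms_for(factor: str, within: tuple[str, str] | None) -> dict[str, np.ndarray]:
        out = {}
        for lev in levels[factor]:
            mask = (grid[factor] == lev).to_numpy()
            if within is not None:
                mask &= (grid[within[0]] == within[1]).to_numpy()
            out[lev] = _emm_row(result, grid, mask)
        return out

    def _contrast_family(factor: str, rows_by_level: dict[str, np.ndarray],
                         within_desc: str) -> None:
        levs = levels[factor]
        n_lev = len(levs)
        for a, b in itertools.combinations(levs, 2):
            L = rows_by_level[a] - rows_by_level[b]
            est, se = _estimate(L)
            t = est / se if se > 0 else np.nan
            p_adj = float(studentized_range.sf(abs(t) * np.sqrt(2.0), n_lev, ddf)) \
                if np.isfinite(t) else np.nan
            row = {
                "factor": factor, "level_1": a, "level_2": b, "within": within_desc,
                "estimate": est, "se": se, "df": ddf, "t": t, "p_adj": min(p_adj, 1.0),
            }
            if log_scale:
                row["ratio"] = float(np.exp(est))
            contrast_rows.append(row)

    for factor in spec.factors:
        rows_by_level = _emms_for(factor, within=None)
        for lev, L in rows_by_level.items():
            est, se = _estimate(L)
            emm = {"factor": factor, "level": lev, "within": "", "emmean": est,
                   "se": se, "df": ddf}
            if log_scale:
                emm["response"] = float(np.exp(est))
            emm_rows.append(emm)
        _contrast_family(factor, rows_by_level, within_desc="")
    if spec.has_interaction:
        for factor in spec.factors:
            other = "treatment" if factor == "climate" else "climate"
            for other_lev in levels[other]:
                rows_by_level = _emms_for(factor, within=(other, other_lev))
                _contrast_family(factor, rows_by_level,
                                 within_desc=f"{other}={other_lev}")
    return pd.DataFrame(emm_rows), pd.DataFrame(contrast_rows)


def analyse_response(
    response: str,
    data: pd.DataFrame,
    log_transform: bool | None = None,
) -> tuple[SelectionResult, pd.DataFrame, pd.DataFrame]:
    """Candidate set -> AICc selection -> marginal means on the chosen model."""
    specs = candidate_set(response, log_transform)
    sel = fit_and_select(specs, data)
    if sel.chosen.spec.factors:
        emmeans, contrasts = marginal_means_contrasts(sel.chosen, data)
    else:
        emmeans = pd.DataFrame()
        contrasts = pd.DataFrame()
    return sel, emmeans, contrasts
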