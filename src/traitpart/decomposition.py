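"""Decomposition of CWM variation into species turnover, ITV and covariation.

Community trait change between plots mixes two processes: species turnover
(who is there, at what cover) and intraspecific trait variation (ITV; how a
given species' trait differs between plots).  Running the same two-way ANOVA
(climate x treatment, sequential sums of squares) on three response vectors —
specific CWMs (total variation), fixed CWMs (turnover only) and their
difference (ITV) — splits every term's variation:

    SS_cov(term) = SS_specific(term) - SS_fixed(term) - SS_itv(term)

Positive covariation means turnover and ITV pull community trait values the
same way; negative means they oppose each other.  Relative contributions are
expressed as percentages of the specific ANOVA's total sum of squares, the
normalisation under which the contribution table's rows and columns are
simultaneously coherent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .cwm import CWMTable
from .data_model import PlotDesign, ValidationError

TERMS = ("climate", "treatment", "climate:treatment", "residuals")
_FORMULA = "value ~ C(climate, levels=clim_levels) * C(treatment, levels=treat_levels)"


def _design_frame(response: pd.Series, design: PlotDesign) -> pd.DataFrame:
    missing = [p for p in response.index if p not in design.table.index]
    if missing:
        raise ValidationError(f"plots absent from design: {missing}")
    df = design.table.loc[response.index].copy()
    df["value"] = response.to_numpy(dtype=float)
    for factor in ("climate", "treatment"):
        if df[factor].nunique() < 2:
            raise ValidationError(f"factor {factor!r} has a single level")
    return df


def two_way_ss(response: pd.Series, design: PlotDesign) -> pd.Series:
    """Sequential (Type I) sums of squares for climate, treatment, their
    interaction and residuals, in that order, plus the total.

    The response is indexed by plot_id; every plot must carry a value.  With
    one observation per climate x treatment cell the interaction is
    confounded with the residual and an error is raised.
    """
    df = _design_frame(response, design)
    cells = df.groupby(["climate", "treatment"], observed=True).size()
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValidationError(
            f"cells without replication (interaction confounded with residual): {bad}"
        )
    clim_levels = sorted(df["climate"].unique())
    treat_levels = sorted(df["treatment"].unique())
    fit = smf.ols(_FORMULA, data=df).fit()
    tab = anova_lm(fit, typ=1)
    ss = pd.Series(
        {
            "climate": tab["sum_sq"].iloc[0],
            "treatment": tab["sum_sq"].iloc[1],
            "climate:treatment": tab["sum_sq"].iloc[2],
            "residuals": tab["sum_sq"].iloc[3],
        }
    )
    ss["total"] = ss.sum()
    return ss


def _sequential_projectors(df: pd.DataFrame) -> list[np.ndarray]:
    """Orthonormal bases Q for the nested model sequence used in Type I SS."""
    import patsy

    clim_levels = sorted(df["climate"].unique())      # noqa: F841 (patsy eval)
    treat_levels = sorted(df["treatment"].unique())   # noqa: F841
    formulas = [
        "1",
        "C(climate, levels=clim_levels)",
        "C(climate, levels=clim_levels) + C(treatment, levels=treat_levels)",
        _FORMULA.split("~")[1],
    ]
    qs = []
    for f in formulas:
        X = np.asarray(patsy.dmatrix(f, df))
        q, r = np.linalg.qr(X)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        qs.append(q[:, keep])
    return qs


def _ss_from_projectors(y: np.ndarray, qs: list[np.ndarray]) -> np.ndarray:
    """Sequential SS (climate, treatment, interaction, residual) via the
    fitted sums of squares of the nested model sequence."""
    yc = y - y.mean()
    total = float(yc @ yc)
    fitted = [float(np.sum((q.T @ y) ** 2)) - y.size * y.mean() ** 2 for q in qs]
    climate = fitted[1] - fitted[0]
    treatment = fitted[2] - fitted[1]
    interaction = fitted[3] - fitted[2]
    residual = total - fitted[3] + fitted[0]
    return np.array([climate, treatment, interaction, residual])


@dataclass(frozen=True)
class AnovaDecomposition:
    """Per-term turnover/ITV/covariation split for one trait.

    ``table`` is indexed by term (climate, treatment, climate:treatment,
    residuals, total) with the three ANOVAs' sums of squares, the covariation
    term, and relative contributions in percent of the specific ANOVA's total.
    ``p_values`` (permutation mode only) holds per-term one-sided permutation
    p-values for each response.
    """

    trait: str
    table: pd.DataFrame
    p_values: pd.DataFrame | None = None

    @property
    def contributions(self) -> pd.DataFrame:
        """The familiar turnover / ITV / covariation / total percent table."""
        return self.table[["turnover_pct", "itv_pct", "cov_pct", "total_pct"]]


def decompose(
    cwm: CWMTable,
    design: PlotDesign,
    trait: str,
    mode: str = "anova",
    n_permutations: int = 999,
    seed: int = 0,
) -> AnovaDecomposition:
    """Run the three-ANOVA turnover/ITV decomposition for one trait.

    Requires specific, fixed and itv CWMs on a common plot set.  In
    ``permutation`` mode, per-term significance is additionally assessed by
    freely permuting each response across plots and comparing per-term F
    statistics (one-sided, ``n_permutations`` draws, seeded).
    """
    if mode not in ("anova", "permutation"):
        raise ValidationError(f"unknown mode {mode!r}")
    resp = {c: cwm.response(trait, c) for c in ("specific", "fixed", "itv")}
    plot_sets = {c: set(r.index) for c, r in resp.items()}
    common = plot_sets["specific"] & plot_sets["fixed"] & plot_sets["itv"]
    offending = sorted(set.union(*plot_sets.values()) - common)
    if offending:
        raise ValidationError(
            f"trait {trait!r}: plots missing under some convention: {offending}"
        )
    if not common:
        raise ValidationError(f"trait {trait!r}: no plots with all three conventions")
    order = [p for p in design.plot_ids if p in common]

    ss = {c: two_way_ss(resp[c].loc[order], design) for c in resp}
    table = pd.DataFrame(
        {
            "SS_specific": ss["specific"],
            "SS_fixed": ss["fixed"],
            "SS_itv": ss["itv"],
        }
    )
    table["SS_cov"] = table["SS_specific"] - table["SS_fixed"] - table["SS_itv"]
    total_specific = table.loc["total", "SS_specific"]
    if total_specific <= 0:
        # constant specific response: no variation to attribute
        for col, src in (("turnover_pct", "SS_fixed"), ("itv_pct", "SS_itv"),
                         ("cov_pct", "SS_cov"), ("total_pct", "SS_specific")):
            table[col] = 0.0
    else:
        table["turnover_pct"] = table["SS_fixed"] / total_specific * 100.0
        table["itv_pct"] = table["SS_itv"] / total_specific * 100.0
        table["cov_pct"] = table["SS_cov"] / total_specific * 100.0
        table["total_pct"] = table["SS_specific"] / total_specific * 100.0

    p_values = None
    if mode == "permutation":
        p_values = _permutation_pvalues(resp, design, order, n_permutations, seed)
    return AnovaDecomposition(trait, table, p_values)


def _permutation_pvalues(
    resp: dict[str, pd.Series],
    design: PlotDesign,
    order: Sequence[str],
    n_permutations: int,
    seed: int,
) -> pd.DataFrame:
    """One-sided permutation p-values of per-term F statistics, permuting the
    response freely across plots (all three responses share one seed)."""
    df = design.table.loc[order].copy()
    df["value"] = 0.0
    qs = _sequential_projectors(df)
    dfs = np.array([  # term degrees of freedom for the F statistics
        df["climate"].nunique() - 1,
        df["treatment"].nunique() - 1,
        (df["climate"].nunique() - 1) * (df["treatment"].nunique() - 1),
    ])
    n = len(order)
    df_res = n - 1 - dfs.sum()
    out = {}
    for name, series in resp.items():
        rng = np.random.default_rng(seed)
        y = series.loc[order].to_numpy(dtype=float)
        obs_ss = _ss_from_projectors(y, qs)
        def fstats(ss: np.ndarray) -> np.ndarray:
            ms_res = ss[3] / df_res if df_res > 0 else np.nan
            with np.errstate(divide="ignore", invalid="ignore"):
                return (ss[:3] / dfs) / ms_res
        obs_f = fstats(obs_ss)
        exceed = np.zeros(3)
        for _ in range(n_permutations):
            perm = rng.permutation(y)
            exceed += fstats(_ss_from_projectors(perm, qs)) >= obs_f - 1e-12
        pvals = (1.0 + exceed) / (n_permutations + 1.0)
        out[name] = pd.Series(pvals, index=list(TERMS[:3]))
    return pd.DataFrame(out)


def decompose_all(
    cwm: CWMTable,
    design: PlotDesign,
    mode: str = "anova",
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Contribution table (percent of total specific SS) for every trait with
    plot-specific measurements, stacked in long form."""
    rows = []
    for trait in cwm.traits_with_itv():
        dec = decompose(cwm, design, trait, mode=mode,
                        n_permutations=n_permutations, seed=seed)
        for term, row in dec.table.iterrows():
            rows.append(
                {
                    "trait": trait, "term": term,
                    "turnover_pct": row["turnover_pct"],
                    "itv_pct": row["itv_pct"],
                    "cov_pct": row["cov_pct"],
                    "total_pct": row["total_pct"],
                }
            )
    if not rows:
        raise ValidationError("no trait has specific, fixed and itv CWMs")
    return pd.DataFrame(rows)
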