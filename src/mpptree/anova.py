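"""Design-effect analysis: factorial ANOVA on item-level RMSE.

Quantifies how sample size (N), test length (J) and tree node drive recovery
error.  The response is one RMSE value per (node, N, J, item) detail record;
the model is the full three-way between-subjects factorial.  Sums of squares
are Type II (robust to the unbalanced item counts across test lengths), and
effect sizes are partial eta-squared,

    eta_p^2 = SS_effect / (SS_effect + SS_residual).

Pairwise simple effects between nodes use the pooled ANOVA residual variance
and residual degrees of freedom; contrasts are signed first-minus-second so a
lower-RMSE node listed first yields a negative t.  Raw p-values are reported
by default, with optional Bonferroni or Holm adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .core import MppValidationError, NODES

_FACTORS = ("N", "J", "node")
_RESPONSES = {"alpha": "alpha_rmse", "d": "d_rmse", "difficulty": "d_rmse"}


@dataclass
class AnovaResult:
    """Effect table plus residuals of one factorial ANOVA.

    ``effects`` has one row per model term with sum of squares, df, F, p and
    partial eta-squared; ``resid_ss``/``resid_df`` describe the residual.
    """

    effects: pd.DataFrame
    resid_ss: float
    resid_df: int
    response: str

    @property
    def eta_p2(self) -> pd.Series:
        return self.effects.set_index("effect")["eta_p2"]

    def to_csv(self, path) -> None:
        df = self.effects.copy()
        df.loc[len(df)] = {
            "effect": "Residual",
            "ss": self.resid_ss,
            "df": self.resid_df,
            "F": np.nan,
            "p": np.nan,
            "eta_p2": np.nan,
        }
        df.to_csv(path, index=False)


def factorial_anova(detail: pd.DataFrame, response: str = "alpha") -> AnovaResult:
    """Three-way factorial ANOVA of item-level RMSE on N x J x node.

    Factors with a single observed level are dropped from the model with a
    warning entry rather than an error.  Type II sums of squares.
    """
    col = _RESPONSES.get(response, response)
    if col not in detail.columns:
        raise MppValidationError(f"response column {col!r} not in detail records")
    df = detail.copy()
    df["_y"] = df[col].astype(float)

    factors = [f for f in _FACTORS if df[f].nunique() > 1]
    dropped = [f for f in _FACTORS if f not in factors]
    if not factors:
        raise MppValidationError("no factor has more than one level")
    terms = []
    for r in range(1, len(factors) + 1):
        terms += [":".join(f"C({f})" for f in c) for c in combinations(factors, r)]
    formula = "_y ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid > 0 and fit.ssr > 1e-12 * fit.centered_tss:
        table = sm.stats.anova_lm(fit, typ=2)
    else:
        # saturated or zero-residual fit: Type II via sequential SS is exact
        table = sm.stats.anova_lm(fit, typ=1)
    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = int(table.loc["Residual", "df"])
    # clamp numerically-zero sums of squares so eta_p^2 is exactly 0 when an
    # effect explains nothing (OLS leaves ~1e-30 noise on constant responses)
    total_ss = float(((df["_y"] - df["_y"].mean()) ** 2).sum())
    eps = 1e-10 * max(total_ss, float((df["_y"] ** 2).sum()), np.finfo(float).tiny)
    if resid_ss < eps:
        resid_ss = 0.0

    rows = []
    for term in table.index:
        if term == "Residual":
            continue
        ss = float(table.loc[term, "sum_sq"])
        ss = 0.0 if ss < eps else ss
        denom = ss + resid_ss
        rows.append(
            {
                "effect": term.replace("C(", "").replace(")", ""),
                "ss": ss,
                "df": int(table.loc[term, "df"]),
                "F": float(table.loc[term, "F"]),
                "p": float(table.loc[term, "PR(>F)"]),
                "eta_p2": ss / denom if denom > 0 else 0.0,
            }
        )
    for f in dropped:
        rows.append(
            {"effect": f, "ss": np.nan, "df": 0, "F": np.nan, "p": np.nan,
             "eta_p2": np.nan}
        )
    effects = pd.DataFrame(rows)
    return AnovaResult(effects=effects, resid_ss=resid_ss, resid_df=resid_df, response=col)


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if method == "none":
        return p
    from statsmodels.stats.multitest import multipletests

    mapped = {"bonferroni": "bonferroni", "holm": "holm"}[method]
    return multipletests(p, method=mapped)[1]


def pairwise_simple_effects(
    detail: pd.DataFrame,
    response: str = "alpha",
    within: str | None = "J",
    adjust: str = "none",
) -> pd.DataFrame:
    """Pairwise node contrasts on the pooled ANOVA residual df.

    For each level of ``within`` (or overall when ``within`` is None), every
    node pair (in hierarchy order midpoint, agreement, extreme) is compared
    by a t statistic using the full factorial's residual mean square:

        t = (mean_1 - mean_2) / sqrt(MS_resid * (1/n_1 + 1/n_2))

    The first-listed node is earlier in the decision hierarchy, so negative t
    means the earlier node has the smaller RMSE.
    """
    col = _RESPONSES.get(response, response)
    res = factorial_anova(detail, response=response)
    ms = res.resid_ss / res.resid_df if res.resid_df > 0 else 0.0

    groups = [(None, detail)] if within is None else list(detail.groupby(within, sort=True))
    rows = []
    for level, sub in groups:
        for n1, n2 in combinations(NODES, 2):
            g1 = sub.loc[sub["node"] == n1, col]
            g2 = sub.loc[sub["node"] == n2, col]
            if len(g1) == 0 or len(g2) == 0:
                raise MppValidationError(f"empty group for contrast {n1} vs {n2}")
            se = np.sqrt(ms * (1 / len(g1) + 1 / len(g2)))
            diff = g1.mean() - g2.mean()
            t = diff / se if se > 0 else 0.0
            from scipy.stats import t as t_dist

            p = 2 * t_dist.sf(abs(t), res.resid_df) if res.resid_df > 0 else np.nan
            rows.append(
                {
                    "within": level if level is not None else "overall",
                    "contrast": f"{n1}-{n2}",
                    "diff": diff,
                    "t": t,
                    "df": res.resid_df,
                    "p": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = _adjust(out["p"].to_numpy(), adjust)
    return out
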