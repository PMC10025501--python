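"""Recovery metrics: per-item RMSE/bias across replicates and cell summaries.

The unit of analysis is the item: for each (node, N, J, item) the posterior
means from all replicates are scored against that item's generating value,
giving one RMSE and one bias per item.  Cell-level values are means over
items, and the item-level detail records feed the factorial ANOVA.  With the
full design (J in {10, 15, 20}, 4 sample sizes, 3 nodes) this yields
45 x 3 x 4 = 540 item-level observations in 36 cells.

Difficulties are scored on the intercept scale ``d = alpha * b`` by default;
a flag switches to the ``b`` scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ItemParams, MppValidationError, NODES

#: columns of the item-level detail table
DETAIL_COLUMNS = [
    "node", "N", "J", "item",
    "alpha_rmse", "alpha_bias", "d_rmse", "d_bias",
    "alpha_mean", "d_mean", "alpha_true", "d_true",
]


def item_rmse(estimates, truth: float) -> float:
    """Root mean square error of replicate estimates around the true value."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise MppValidationError("item_rmse needs at least one estimate")
    return float(np.sqrt(np.mean((estimates - truth) ** 2)))


def item_bias(estimates, truth: float) -> float:
    """Mean signed error; positive means overestimation."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise MppValidationError("item_bias needs at least one estimate")
    return float(np.mean(estimates - truth))


def detail_records(
    estimates: dict,
    truth: ItemParams,
    N: int,
    J: int,
    scale: str = "d",
) -> pd.DataFrame:
    """Score one design cell's replicate estimates against the truth.

    ``estimates`` maps "alpha" and "d" (or "b") to arrays of shape
    (replicates, 3, J) of posterior means.  Returns one row per node x item
    with RMSE, bias, and mean estimate for both the discrimination and the
    difficulty parameter.
    """
    if scale not in ("d", "b"):
        raise MppValidationError(f"scale must be 'd' or 'b'; got {scale!r}")
    alpha_est = np.asarray(estimates["alpha"], dtype=float)
    diff_est = np.asarray(estimates[scale], dtype=float)
    diff_true = truth.d if scale == "d" else truth.b
    if alpha_est.ndim != 3 or alpha_est.shape[1:] != (3, J):
        raise MppValidationError(
            f"estimates must have shape (replicates, 3, {J}); got {alpha_est.shape}"
        )
    rows = []
    for k, node in enumerate(NODES):
        for i in range(J):
            a = alpha_est[:, k, i]
            d = diff_est[:, k, i]
            rows.append(
                {
                    "node": node,
                    "N": N,
                    "J": J,
                    "item": i + 1,
                    "alpha_rmse": item_rmse(a, truth.alpha[k, i]),
                    "alpha_bias": item_bias(a, truth.alpha[k, i]),
                    "d_rmse": item_rmse(d, diff_true[k, i]),
                    "d_bias": item_bias(d, diff_true[k, i]),
                    "alpha_mean": float(a.mean()),
                    "d_mean": float(d.mean()),
                    "alpha_true": float(truth.alpha[k, i]),
                    "d_true": float(diff_true[k, i]),
                }
            )
    return pd.DataFrame(rows, columns=DETAIL_COLUMNS)


def cell_summary(detail: pd.DataFrame) -> pd.DataFrame:
    """Aggregate item-level detail records into per-(node, N, J) cell rows.

    Cell RMSE/bias are unweighted means over the cell's items.  The mean
    estimate is the grand mean of the items' mean posterior means; its SE is
    the sd over items divided by sqrt(item count), and the 95% CI is the
    normal interval mean +/- 1.96 SE.  A cell needs at least 2 items.
    """
    rows = []
    for (node, N, J), grp in detail.groupby(["node", "N", "J"], sort=False):
        if len(grp) < 2:
            raise MppValidationError(
                f"cell ({node}, N={N}, J={J}) has {len(grp)} item(s); need >= 2 for an SE"
            )
        row = {"node": node, "N": N, "J": J}
        for par in ("alpha", "d"):
            row[f"{par}_rmse"] = grp[f"{par}_rmse"].mean()
            row[f"{par}_bias"] = grp[f"{par}_bias"].mean()
            m = grp[f"{par}_mean"].mean()
            se = grp[f"{par}_mean"].std(ddof=1) / np.sqrt(len(grp))
            row[f"{par}_est_mean"] = m
            row[f"{par}_est_se"] = se
            row[f"{par}_ci_low"] = m - 1.96 * se
            row[f"{par}_ci_high"] = m + 1.96 * se
        rows.append(row)
    out = pd.DataFrame(rows)
    order = ["midpoint", "agreement", "extreme"]
    out["node"] = pd.Categorical(out["node"], categories=order, ordered=True)
    return out.sort_values(["node", "J", "N"]).reset_index(drop=True)


def node_means(detail: pd.DataFrame) -> pd.DataFrame:
    """Mean alpha and difficulty RMSE per node over all detail records."""
    g = detail.groupby("node", sort=False)[["alpha_rmse", "d_rmse"]].mean()
    return g.reindex(list(NODES))
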