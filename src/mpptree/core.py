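"""Core mathematics of the midpoint-primary-process (MPP) IRTree model.

The MPP model describes a 5-point Likert response as the outcome of up to
three sequential binary decisions (nodes):

* **midpoint** (M): respond with the scale midpoint (category 3) or give a
  directed response;
* **agreement** (A): given a directed response, agree (4/5) or disagree (1/2);
* **extreme** (E): given a directed response, pick the endpoint (1/5) or not
  (2/4).

Each node is a two-parameter logistic (2PL) item response model in intercept
form: the probability of "yes" at node *k* is ``sigmoid(alpha_k * theta_k + d_k)``
with item discrimination ``alpha_k > 0``, item intercept ``d_k`` on the
log-odds scale, and person trait ``theta_k``.  Throughout the package the
intercept is tied to the difficulty/location ``b`` by ``d = alpha * b``; both
are stored so either scale can be reported.

A Likert matrix decomposes losslessly into three binary *pseudo-items* per
item.  The agreement and extreme codes are structurally missing whenever the
midpoint was chosen — the tree terminates at the first node — and the
decomposed Bernoulli likelihood over observed codes equals the categorical
likelihood of the original responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

NODES: tuple[str, str, str] = ("midpoint", "agreement", "extreme")
NODE_SUFFIX: tuple[str, str, str] = ("M", "A", "E")

# Table of legal pseudo-item patterns, one row per Likert category 1..5.
# Columns are (midpoint, agreement, extreme); NaN marks a structurally
# missing decision (the tree stopped at the midpoint node).
_PATTERNS = np.array(
    [
        [0.0, 0.0, 1.0],  # 1: disagree, extreme
        [0.0, 0.0, 0.0],  # 2: disagree, not extreme
        [1.0, np.nan, np.nan],  # 3: midpoint — tree terminates
        [0.0, 1.0, 0.0],  # 4: agree, not extreme
        [0.0, 1.0, 1.0],  # 5: agree, extreme
    ]
)


class MppValidationError(ValueError):
    """Raised when data violate the model's structural constraints."""


@dataclass
class ItemParams:
    """Per-node 2PL item parameters for J items.

    Attributes
    ----------
    alpha : ndarray, shape (3, J)
        Discriminations, strictly positive; rows ordered (M, A, E).
    b : ndarray, shape (3, J)
        Difficulties (locations) on the trait scale.

    The intercept ``d = alpha * b`` is derived, never stored independently.
    """

    alpha: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.alpha.shape != self.b.shape or self.alpha.ndim != 2 or self.alpha.shape[0] != 3:
            raise MppValidationError(
                f"alpha/b must both have shape (3, J); got {self.alpha.shape} and {self.b.shape}"
            )
        if not np.all(self.alpha > 0):
            raise MppValidationError("all discriminations must be strictly positive")

    @property
    def d(self) -> np.ndarray:
        """Intercepts on the log-odds scale, ``d = alpha * b``."""
        return self.alpha * self.b

    @property
    def n_items(self) -> int:
        return self.alpha.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, node in enumerate(NODES):
            for i in range(self.n_items):
                rows.append(
                    {
                        "node": node,
                        "item": i + 1,
                        "alpha": self.alpha[k, i],
                        "b": self.b[k, i],
                        "d": self.alpha[k, i] * self.b[k, i],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemParams":
        J = df["item"].max()
        alpha = np.empty((3, J))
        b = np.empty((3, J))
        for k, node in enumerate(NODES):
            sub = df[df["node"] == node].sort_values("item")
            if len(sub) != J:
                raise MppValidationError(f"node {node!r} has {len(sub)} items, expected {J}")
            alpha[k] = sub["alpha"].to_numpy()
            b[k] = sub["b"].to_numpy()
        return cls(alpha=alpha, b=b)


@dataclass
class LatentTraits:
    """Person traits (theta_M, theta_A, theta_E) on the standard-normal scale.

    ``R`` is the 3x3 correlation matrix of the generating trivariate normal.
    """

    theta: np.ndarray
    R: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 3:
            raise MppValidationError(f"theta must have shape (n, 3); got {self.theta.shape}")
        validate_correlation_matrix(self.R)

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]


def validate_correlation_matrix(R: np.ndarray) -> None:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise MppValidationError(f"R must be 3x3; got {R.shape}")
    if not np.allclose(R, R.T):
        raise MppValidationError("R must be symmetric")
    if not np.allclose(np.diag(R), 1.0):
        raise MppValidationError("R must have a unit diagonal")
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() < -1e-10:
        raise MppValidationError(
            f"R is not positive semi-definite (smallest eigenvalue {eigvals.min():.3g})"
        )


@dataclass
class LikertMatrix:
    """Complete persons x items matrix of responses in {1..5}."""

    responses: np.ndarray

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses)
        if self.responses.ndim != 2:
            raise MppValidationError("responses must be 2-D (persons x items)")
        bad = ~np.isin(self.responses, [1, 2, 3, 4, 5])
        if bad.any():
            v, i = np.argwhere(bad)[0]
            raise MppValidationError(
                f"response out of range at person {v}, item {i}: {self.responses[v, i]!r}"
            )
        self.responses = self.responses.astype(np.int64)

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    def to_csv(self, path) -> None:
        cols = [f"item{i + 1}" for i in range(self.n_items)]
        pd.DataFrame(self.responses, columns=cols).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LikertMatrix":
        return cls(pd.read_csv(path).to_numpy())


@dataclass
class PseudoItemMatrix:
    """Binary pseudo-item codes, persons x items x 3 nodes.

    Structural missingness is encoded as NaN: the agreement and extreme codes
    are missing exactly when the midpoint code is 1.  Serialized as "NA" in
    CSV so missingness is never silently coerced to 0/1.
    """

    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 3 or self.codes.shape[2] != 3:
            raise MppValidationError(f"codes must have shape (n, J, 3); got {self.codes.shape}")
        flat = self.codes.reshape(-1, 3)
        legal = np.zeros(flat.shape[0], dtype=bool)
        for pattern in _PATTERNS:
            match = np.ones(flat.shape[0], dtype=bool)
            for c in range(3):
                if np.isnan(pattern[c]):
                    match &= np.isnan(flat[:, c])
                else:
                    match &= flat[:, c] == pattern[c]
            legal |= match
        if not legal.all():
            idx = int(np.argmin(legal))
            v, i = divmod(idx, self.codes.shape[1])
            raise MppValidationError(
                f"illegal pseudo-item pattern {flat[idx]} at person {v}, item {i}"
            )

    @property
    def n_persons(self) -> int:
        return self.codes.shape[0]

    @property
    def n_items(self) -> int:
        return self.codes.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) cells, shape (n, J, 3)."""
        return ~np.isnan(self.codes)

    def to_csv(self, path) -> None:
        n, J, _ = self.codes.shape
        cols = [f"item{i + 1}_{s}" for i in range(J) for s in NODE_SUFFIX]
        flat = self.codes.reshape(n, J * 3)
        df = pd.DataFrame(flat, columns=cols)
        df.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "PseudoItemMatrix":
        df = pd.read_csv(path, na_values=["NA"])
        n = len(df)
        J = df.shape[1] // 3
        return cls(df.to_numpy(dtype=float).reshape(n, J, 3))


def node_probability(alpha, d, theta):
    """Probability of a "yes" at one node: ``sigmoid(alpha * theta + d)``.

    Strictly increasing in ``theta``; ``alpha`` must be positive.  Accepts
    scalars or broadcastable arrays.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise MppValidationError("discrimination alpha must be strictly positive")
    return expit(alpha * np.asarray(theta, dtype=float) + np.asarray(d, dtype=float))


def category_probabilities(alpha, d, theta):
    """Five-category response probabilities for one person x item.

    Parameters are length-3 vectors ordered (midpoint, agreement, extreme).
    Returns ``(P1..P5)`` with

    * ``P3 = p_M``
    * ``P1 = (1-p_M)(1-p_A) p_E``, ``P2 = (1-p_M)(1-p_A)(1-p_E)``
    * ``P4 = (1-p_M) p_A (1-p_E)``, ``P5 = (1-p_M) p_A p_E``

    so the vector sums to one by construction.
    """
    alpha = np.asarray(alpha, dtype=float)
    d = np.asarray(d, dtype=float)
    theta = np.asarray(theta, dtype=float)
    pM, pA, pE = (node_probability(alpha[k], d[k], theta[k]) for k in range(3))
    return np.array(
        [
            (1 - pM) * (1 - pA) * pE,
            (1 - pM) * (1 - pA) * (1 - pE),
            pM,
            (1 - pM) * pA * (1 - pE),
            (1 - pM) * pA * pE,
        ]
    )


def category_probability_array(params: ItemParams, traits: LatentTraits) -> np.ndarray:
    """Vectorized category probabilities, shape (n_persons, n_items, 5)."""
    # p[k] has shape (n, J): node-k yes-probability per person x item
    d = params.d
    p = np.stack(
        [
            expit(params.alpha[k][None, :] * traits.theta[:, k][:, None] + d[k][None, :])
            for k in range(3)
        ]
    )
    pM, pA, pE = p
    out = np.empty(pM.shape + (5,))
    out[..., 0] = (1 - pM) * (1 - pA) * pE
    out[..., 1] = (1 - pM) * (1 - pA) * (1 - pE)
    out[..., 2] = pM
    out[..., 3] = (1 - pM) * pA * (1 - pE)
    out[..., 4] = (1 - pM) * pA * pE
    return out


def decompose(data: LikertMatrix) -> PseudoItemMatrix:
    """Recode a Likert matrix into binary pseudo-items.

    Category mapping (M, A, E): 1 -> (0,0,1); 2 -> (0,0,0); 3 -> (1,NA,NA);
    4 -> (0,1,0); 5 -> (0,1,1).
    """
    return PseudoItemMatrix(_PATTERNS[data.responses - 1])


def recompose(codes: PseudoItemMatrix) -> LikertMatrix:
    """Exact inverse of :func:`decompose`."""
    c = codes.codes
    M = c[..., 0]
    A = c[..., 1]
    E = c[..., 2]
    out = np.where(
        M == 1,
        3,
        np.where(A == 1, np.where(E == 1, 5, 4), np.where(E == 1, 1, 2)),
    )
    return LikertMatrix(out.astype(np.int64))


def bernoulli_loglik_matrix(
    alpha: np.ndarray, d: np.ndarray, theta: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Per-cell Bernoulli log-likelihood for one node, NaN-masked to zero.

    ``alpha``/``d`` have shape (J,), ``theta`` shape (n,), ``y`` shape (n, J)
    with NaN for structurally missing cells.  Uses the log-sigmoid form
    ``y*log_expit(z) + (1-y)*log_expit(-z)`` which is overflow-safe for large
    ``|z|``.
    """
    z = theta[:, None] * alpha[None, :] + d[None, :]
    obs = ~np.isnan(y)
    y0 = np.where(obs, y, 0.0)
    ll = y0 * log_expit(z) + (1.0 - y0) * log_expit(-z)
    return np.where(obs, ll, 0.0)


def mpp_loglik(params: ItemParams, traits: LatentTraits, codes: PseudoItemMatrix) -> float:
    """Log-likelihood of decomposed data: sum of node Bernoulli terms over
    observed cells.  Missing cells contribute zero, so this equals the log of
    the categorical likelihood of the recomposed Likert data."""
    if codes.n_persons != traits.n_persons or codes.n_items != params.n_items:
        raise MppValidationError(
            f"dimension mismatch: codes {codes.codes.shape}, "
            f"traits {traits.theta.shape}, params J={params.n_items}"
        )
    d = params.d
    total = 0.0
    for k in range(3):
        total += bernoulli_loglik_matrix(
            params.alpha[k], d[k], traits.theta[:, k], codes.codes[..., k]
        ).sum()
    return float(total)
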