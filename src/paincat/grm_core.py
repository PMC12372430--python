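"""Samejima graded-response-model probabilities, likelihoods, and information.

All functions use the pure logistic metric (no 1.7 scaling constant), the
convention of mainstream GRM software, so discriminations map directly onto
the usual interpretive bands.

The cumulative ("boundary") probability of responding in category >= k is

    P*_k(theta) = 1 / (1 + exp(-a (theta - b_k)))      k = 1 .. K-1

with P*_0 = 1 and P*_K = 0; category probabilities are adjacent differences
P_k = P*_k - P*_{k+1}.  Fisher information of an item is

    I(theta) = sum_k (dP_k/dtheta)^2 / P_k.

Scalar `Item`-level entry points sit on top of array helpers (`BankArrays`)
that evaluate a whole bank on a theta grid at once; the adaptive engine and
the calibrator use the array path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .item_model import Item, ItemBank

__all__ = [
    "ThetaEstimate",
    "BankArrays",
    "cumulative_prob",
    "category_probs",
    "item_information",
    "test_information",
    "standard_error",
    "log_likelihood",
    "sample_response",
    "expected_score",
    "information_curve",
    "PROB_FLOOR",
    "THETA_GRID",
]

#: floor inside logs; a numerical guard, not a model change
PROB_FLOOR = 1e-10

#: default theta grid for curves and quadrature-style summaries
THETA_GRID = np.arange(-6.0, 6.0 + 1e-9, 0.01)


@dataclass(frozen=True)
class ThetaEstimate:
    """A latent-trait estimate with its standard error and estimator tag."""

    value: float
    se: float
    estimator: str  # "ML" | "EAP" | "MAP" | "WLE"
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("ML", "EAP", "MAP", "WLE"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if not np.isfinite(self.value):
            raise ValueError("theta estimate must be finite")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValueError("standard error must be finite and positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# scalar Item-level API
# ---------------------------------------------------------------------------

def cumulative_prob(item: Item, k: int, theta) -> np.ndarray | float:
    """P*_k(theta): probability of responding in category >= k (k in 1..K-1)."""
    if not (1 <= k <= item.n_categories - 1):
        raise ValueError(
            f"k must be in 1..{item.n_categories - 1} for item {item.id!r}, got {k}"
        )
    theta = np.asarray(theta, dtype=float)
    p = _sigmoid(item.discrimination * (theta - item.thresholds[k - 1]))
    return p if p.ndim else float(p)


def _boundaries(item: Item, theta: np.ndarray) -> np.ndarray:
    """Stacked P*_0..P*_K with the conventional endpoints 1 and 0."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    b = np.asarray(item.thresholds)
    pstar = _sigmoid(item.discrimination * (theta[:, None] - b[None, :]))
    ones = np.ones((theta.size, 1))
    zeros = np.zeros((theta.size, 1))
    return np.concatenate([ones, pstar, zeros], axis=1)


def category_probs(item: Item, theta) -> np.ndarray:
    """Vector of K category probabilities at theta (sums to 1)."""
    scalar = np.ndim(theta) == 0
    ps = _boundaries(item, theta)
    probs = ps[:, :-1] - ps[:, 1:]
    return probs[0] if scalar else probs


def item_information(item: Item, theta) -> np.ndarray | float:
    """GRM Fisher information of one item at theta.

    For a dichotomous item this reduces to ``a^2 P (1 - P)``.
    """
    scalar = np.ndim(theta) == 0
    ps = _boundaries(item, theta)
    a = item.discrimination
    dps = a * ps * (1.0 - ps)  # derivative of each boundary curve
    probs = np.clip(ps[:, :-1] - ps[:, 1:], PROB_FLOOR, None)
    dprobs = dps[:, :-1] - dps[:, 1:]
    info = np.sum(dprobs**2 / probs, axis=1)
    return float(info[0]) if scalar else info


def test_information(bank: ItemBank, theta, subset=None) -> np.ndarray | float:
    """Sum of item informations over ``subset`` (default: the whole bank)."""
    ids = bank.item_ids if subset is None else list(subset)
    unknown = [i for i in ids if i not in bank.item_ids]
    if unknown:
        raise KeyError(f"items not in bank: {unknown}")
    if not ids:
        return 0.0 if np.ndim(theta) == 0 else np.zeros(np.shape(theta))
    total = sum(np.asarray(item_information(bank[i], theta)) for i in ids)
    return float(total) if np.ndim(theta) == 0 else total


def standard_error(information) -> np.ndarray | float:
    """SE(theta) = 1 / sqrt(I(theta)); raises on zero information."""
    info = np.asarray(information, dtype=float)
    if np.any(info <= 0):
        raise ValueError("standard error undefined where information <= 0")
    se = 1.0 / np.sqrt(info)
    return float(se) if se.ndim == 0 else se


def log_likelihood(responses, bank: ItemBank, theta) -> np.ndarray | float:
    """Log-likelihood of one respondent's codes at theta; missing items skipped.

    ``responses`` is a mapping item_id -> code, or a sequence aligned with the
    bank's item order (NaN/None = missing).
    """
    if isinstance(responses, dict):
        pairs = [(iid, responses.get(iid)) for iid in bank.item_ids]
    else:
        if len(responses) != len(bank):
            raise ValueError("response vector length must match bank size")
        pairs = list(zip(bank.item_ids, responses))
    scalar = np.ndim(theta) == 0
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros(theta_arr.size)
    for iid, code in pairs:
        if code is None or (isinstance(code, float) and np.isnan(code)):
            continue
        item = bank[iid]
        c = int(code)
        if not (0 <= c < item.n_categories):
            raise ValueError(f"invalid code {c} for item {iid!r} (K={item.n_categories})")
        probs = category_probs(item, theta_arr)[:, c]
        total += np.log(np.clip(probs, PROB_FLOOR, None))
    return float(total[0]) if scalar else total


def sample_response(item: Item, theta: float, rng: np.random.Generator) -> int:
    """Draw one category code from the item's response distribution at theta."""
    probs = category_probs(item, float(theta))
    u = rng.random()
    return int(np.searchsorted(np.cumsum(probs), u, side="right").clip(0, item.n_categories - 1))


def expected_score(item: Item, theta) -> np.ndarray | float:
    """E[code | theta] = sum_k k P_k(theta); nondecreasing in theta."""
    scalar = np.ndim(theta) == 0
    probs = category_probs(item, np.atleast_1d(theta))
    ks = np.arange(item.n_categories)
    es = probs @ ks
    return float(es[0]) if scalar else es


def information_curve(bank: ItemBank, grid: np.ndarray = THETA_GRID, subset=None):
    """(theta, information, se) arrays for Figure-style precision curves."""
    info = np.asarray(test_information(bank, grid, subset=subset), dtype=float)
    se = np.where(info > 0, 1.0 / np.sqrt(np.clip(info, PROB_FLOOR, None)), np.inf)
    return np.asarray(grid, dtype=float), info, se


# ---------------------------------------------------------------------------
# vectorized bank view
# ---------------------------------------------------------------------------

class BankArrays:
    """Padded-array view of an item bank for vectorized evaluation.

    Thresholds are padded with +inf so padded boundary curves evaluate to 0
    and drop out of the category-probability differences.
    """

    def __init__(self, bank_or_items) -> None:
        items = list(bank_or_items.items if isinstance(bank_or_items, ItemBank) else bank_or_items)
        self.items = items
        self.n_items = len(items)
        self.a = np.array([it.discrimination for it in items])
        self.k = np.array([it.n_categories for it in items])
        self.kmax = int(self.k.max())
        self.b = np.full((self.n_items, self.kmax - 1), np.inf)
        for j, it in enumerate(items):
            self.b[j, : it.n_categories - 1] = it.thresholds

    def boundaries(self, theta: np.ndarray) -> np.ndarray:
        """(Q, J, Kmax+1) boundary probabilities over a theta grid."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        z = self.a[None, :, None] * (theta[:, None, None] - self.b[None, :, :])
        pstar = _sigmoid(np.where(np.isinf(z), np.sign(z) * 700.0, z))
        pstar[np.broadcast_to(np.isinf(self.b)[None, :, :], pstar.shape)] = 0.0
        q = theta.size
        ones = np.ones((q, self.n_items, 1))
        zeros = np.zeros((q, self.n_items, 1))
        return np.concatenate([ones, pstar, zeros], axis=2)

    def category_probs(self, theta: np.ndarray) -> np.ndarray:
        """(Q, J, Kmax) category probabilities (padded categories have prob 0)."""
        ps = self.boundaries(theta)
        return ps[:, :, :-1] - ps[:, :, 1:]

    def log_prob_obs(self, theta: np.ndarray, responses: np.ndarray) -> np.ndarray:
        """(N, Q) log-likelihood matrix for an N x J response array over a grid."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        probs = self.category_probs(theta)  # Q x J x K
        logp = np.log(np.clip(probs, PROB_FLOOR, None))
        resp = np.asarray(responses, dtype=float)
        n = resp.shape[0]
        out = np.zeros((n, theta.size))
        for j in range(self.n_items):
            col = resp[:, j]
            mask = ~np.isnan(col)
            if not mask.any():
                continue
            codes = col[mask].astype(int)
            out[mask] += logp[:, j, :][:, codes].T
        return out

    def information(self, theta: np.ndarray) -> np.ndarray:
        """(Q, J) per-item Fisher information over a theta grid."""
        ps = self.boundaries(theta)
        dps = self.a[None, :, None] * ps * (1.0 - ps)
        probs = np.clip(ps[:, :, :-1] - ps[:, :, 1:], PROB_FLOOR, None)
        dprobs = dps[:, :, :-1] - dps[:, :, 1:]
        valid = np.arange(self.kmax)[None, None, :] < self.k[None, :, None]
        contrib = np.where(valid, dprobs**2 / probs, 0.0)
        return contrib.sum(axis=2)

    def sample(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Draw an N x J response matrix for per-respondent thetas."""
        theta = np.asarray(theta, dtype=float)
        probs = self.category_probs(theta)  # N x J x K
        cum = np.cumsum(probs, axis=2)
        u = rng.random((theta.size, self.n_items, 1))
        codes = (u > cum).sum(axis=2)
        return np.minimum(codes, self.k[None, :] - 1).astype(float)
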