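"""Marginal maximum-likelihood (EM) calibration of graded response models.

The latent scale is identified by the N(0, 1) prior (mean 0, variance 1).
Quadrature is a fixed, evenly spaced grid on [-6, 6] with normal weights, so
fits are deterministic given data and configuration.  The M-step updates each
item by quasi-Newton ascent on (log a, b_1, log-gaps), which keeps a > 0 and
the thresholds strictly increasing by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .grm_core import PROB_FLOOR, BankArrays, ThetaEstimate, _sigmoid
from .item_model import Item, ItemBank, ResponseMatrix

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "fit_grm",
    "parameter_standard_errors",
    "eap_scores",
    "quadrature",
]

logger = logging.getLogger(__name__)

_MIN_GAP = 1e-3  # smallest admissible threshold gap
_MAX_A = 6.0  # slope cap; prevents degenerate near-deterministic items
_ETA_BOUNDS_HEAD = [(np.log(0.05), np.log(_MAX_A)), (-8.0, 8.0)]
_ETA_BOUNDS_GAP = (np.log(_MIN_GAP), np.log(12.0))


@dataclass(frozen=True)
class CalibrationConfig:
    n_quadpoints: int = 61
    theta_range: tuple[float, float] = (-6.0, 6.0)
    tol: float = 1e-4
    max_iter: int = 500
    min_n: int = 150
    warn_n: int = 200
    m_step_maxiter: int = 25


@dataclass
class CalibrationResult:
    bank: ItemBank
    log_likelihood: float
    n_iterations: int
    converged: bool
    quadrature: str
    ll_trace: list[float] = field(default_factory=list)
    collapsed: dict = field(default_factory=dict)
    se_table: dict | None = None


def quadrature(config: CalibrationConfig = CalibrationConfig()):
    """Fixed evenly spaced quadrature nodes with normalized N(0,1) weights."""
    lo, hi = config.theta_range
    nodes = np.linspace(lo, hi, config.n_quadpoints)
    w = norm.pdf(nodes)
    return nodes, w / w.sum()


# ---------------------------------------------------------------------------
# item parametrization: eta = (log a, b1, log(b2-b1), ..., log(b_{K-1}-b_{K-2}))
# ---------------------------------------------------------------------------

def _pack(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(gaps, _MIN_GAP))])


def _unpack(eta: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(eta[0]))
    b = np.empty(eta.size - 1)
    b[0] = eta[1]
    if eta.size > 2:
        b[1:] = eta[1] + np.cumsum(np.exp(eta[2:]))
    return a, b


def _item_objective(eta: np.ndarray, r: np.ndarray, nodes: np.ndarray):
    """Negative expected complete-data log-likelihood for one item + gradient.

    ``r`` is the K x Q table of expected category counts at each node.
    """
    a, b = _unpack(eta)
    kk = r.shape[0]
    pstar = _sigmoid(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
    full = np.vstack([np.ones_like(nodes), pstar, np.zeros_like(nodes)])
    probs = np.clip(full[:-1] - full[1:], PROB_FLOOR, None)  # K x Q
    f = float(np.sum(r * np.log(probs)))

    # d f / d P*_m picks up +r_m/P_m from P_m and -r_{m-1}/P_{m-1}
    ratio = r / probs
    dfdpstar = ratio[1:] - ratio[:-1]  # (K-1, Q)
    s = pstar * (1.0 - pstar)
    dfda = np.sum(dfdpstar * s * (nodes[None, :] - b[:, None]))
    dfdb = np.sum(dfdpstar * s, axis=1) * (-a)  # (K-1,)

    grad = np.empty(eta.size)
    grad[0] = a * dfda
    grad[1] = dfdb.sum()
    if kk > 2:
        gaps = np.exp(eta[2:])
        # b_k depends on gap_m for k >= m (gap index m maps to thresholds m..)
        tail = np.cumsum(dfdb[::-1])[::-1]
        grad[2:] = gaps * tail[1:]
    return -f, -grad


def _start_values(col: np.ndarray, kk: int) -> np.ndarray:
    obs = col[~np.isnan(col)].astype(int)
    counts = np.bincount(obs, minlength=kk).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()  # P(X < k), k = 1..K-1
    cum = np.clip(cum, 0.02, 0.98)
    b = norm.ppf(cum)
    for i in range(1, b.size):
        b[i] = max(b[i], b[i - 1] + _MIN_GAP)
    return _pack(1.0, b)


def _collapse_empty(responses: np.ndarray, item_ids, declared_k) -> tuple[np.ndarray, np.ndarray, dict]:
    """Merge unobserved categories so every fitted item has full support."""
    resp = responses.copy()
    k_out = np.asarray(declared_k, dtype=int).copy()
    collapsed: dict = {}
    for j, iid in enumerate(item_ids):
        col = resp[:, j]
        obs = col[~np.isnan(col)].astype(int)
        if obs.size == 0:
            raise ValueError(f"item {iid!r} has no observed responses")
        counts = np.bincount(obs, minlength=k_out[j])
        if np.all(counts > 0):
            continue
        kept = np.flatnonzero(counts > 0)
        if kept.size < 2:
            raise ValueError(
                f"item {iid!r}: fewer than 2 observed categories; cannot calibrate"
            )
        remap = np.searchsorted(kept, np.arange(k_out[j]))
        remap = np.clip(remap, 0, kept.size - 1)
        mask = ~np.isnan(col)
        col[mask] = remap[col[mask].astype(int)]
        collapsed[iid] = {"observed": kept.tolist(), "new_k": int(kept.size)}
        k_out[j] = kept.size
        logger.warning("item %s: empty categories collapsed to K=%d", iid, kept.size)
    return resp, k_out, collapsed


def fit_grm(
    responses: ResponseMatrix,
    config: CalibrationConfig = CalibrationConfig(),
    construct: str = "",
) -> CalibrationResult:
    """Fit a unidimensional GRM by marginal maximum likelihood (EM).

    Missing responses are ignored in the likelihood (missing-at-random).
    Raises on N below ``config.min_n``; warns below ``config.warn_n``.
    """
    n = responses.n_respondents
    if n < config.min_n:
        raise ValueError(f"N={n} below the minimum of {config.min_n} for calibration")
    if n < config.warn_n:
        warnings.warn(
            f"N={n} is below the recommended 200-300 respondents; "
            "parameter estimates may be unstable",
            stacklevel=2,
        )
    declared_k = [
        int(np.nanmax(responses.responses[:, j])) + 1
        for j in range(responses.n_items)
    ]
    resp, ks, collapsed = _collapse_empty(
        responses.responses, responses.item_ids, declared_k
    )
    nodes, w = quadrature(config)
    j_items = responses.n_items

    etas = [_start_values(resp[:, j], ks[j]) for j in range(j_items)]
    # per-item per-category respondent masks, computed once
    cat_masks = []
    for j in range(j_items):
        col = resp[:, j]
        cat_masks.append([col == k for k in range(ks[j])])

    def current_bank() -> ItemBank:
        items = []
        for j, iid in enumerate(responses.item_ids):
            a, b = _unpack(etas[j])
            items.append(
                Item(
                    id=iid,
                    instrument="",
                    n_categories=int(ks[j]),
                    discrimination=a,
                    thresholds=tuple(b),
                )
            )
        return ItemBank(construct=construct or "fit", items=tuple(items))

    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        arrays = BankArrays(current_bank())
        logl_iq = arrays.log_prob_obs(nodes, resp)  # N x Q
        # stabilized marginal likelihood
        m = logl_iq.max(axis=1, keepdims=True)
        liq = np.exp(logl_iq - m)
        marg = liq @ w
        ll = float(np.sum(np.log(marg) + m[:, 0]))
        ll_trace.append(ll)
        post = liq * w[None, :] / marg[:, None]  # N x Q

        max_change = 0.0
        for j in range(j_items):
            r = np.vstack([post[mask].sum(axis=0) for mask in cat_masks[j]])  # K x Q
            res = minimize(
                _item_objective,
                etas[j],
                args=(r, nodes),
                jac=True,
                method="L-BFGS-B",
                bounds=_ETA_BOUNDS_HEAD + [_ETA_BOUNDS_GAP] * (etas[j].size - 2),
                options={"maxiter": config.m_step_maxiter},
            )
            a_old, b_old = _unpack(etas[j])
            a_new, b_new = _unpack(res.x)
            change = max(abs(a_new - a_old), float(np.max(np.abs(b_new - b_old))))
            max_change = max(max_change, change)
            etas[j] = res.x
        if max_change < config.tol:
            converged = True
            break

    # final log-likelihood at the converged parameters
    arrays = BankArrays(current_bank())
    logl_iq = arrays.log_prob_obs(nodes, resp)
    m = logl_iq.max(axis=1, keepdims=True)
    ll = float(np.sum(np.log((np.exp(logl_iq - m) @ w)) + m[:, 0]))
    ll_trace.append(ll)

    return CalibrationResult(
        bank=current_bank(),
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
        quadrature=(
            f"{config.n_quadpoints} evenly spaced nodes on "
            f"[{config.theta_range[0]}, {config.theta_range[1]}], N(0,1) weights"
        ),
        ll_trace=ll_trace,
        collapsed=collapsed,
    )


# ---------------------------------------------------------------------------
# standard errors (outer product of per-respondent score vectors)
# ---------------------------------------------------------------------------

def _item_logprob_grads(item: Item, nodes: np.ndarray):
    """Gradients of log P_k(theta_q) wrt (a, b_1..b_{K-1}).

    Returns (K, Q) d/da and (K, Q, K-1) d/db arrays.
    """
    a = item.discrimination
    b = np.asarray(item.thresholds)
    kk = item.n_categories
    pstar = _sigmoid(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
    full = np.vstack([np.ones_like(nodes), pstar, np.zeros_like(nodes)])
    probs = np.clip(full[:-1] - full[1:], PROB_FLOOR, None)  # K x Q
    s = pstar * (1.0 - pstar)
    sc = np.vstack([np.zeros_like(nodes), s, np.zeros_like(nodes)])  # pad s_0, s_K
    tb = np.concatenate([[0.0], b, [0.0]])
    # dP_k/da = s_k (theta - b_k) - s_{k+1} (theta - b_{k+1})
    dpda = (
        sc[:-1] * (nodes[None, :] - tb[:-1, None])
        - sc[1:] * (nodes[None, :] - tb[1:, None])
    )
    dlogp_da = dpda / probs
    dlogp_db = np.zeros((kk, nodes.size, kk - 1))
    for m in range(1, kk):  # threshold index m -> b_{m}
        # P_{m-1} gains -(-a s_m) ... dP_{m-1}/db_m = a s_m ; dP_m/db_m = -a s_m
        dlogp_db[m - 1, :, m - 1] += a * s[m - 1] / probs[m - 1]
        dlogp_db[m, :, m - 1] += -a * s[m - 1] / probs[m]
    return dlogp_da, dlogp_db


def parameter_standard_errors(
    result: CalibrationResult,
    responses: ResponseMatrix,
    config: CalibrationConfig = CalibrationConfig(),
) -> dict:
    """Per-parameter SEs from the empirical cross-product (OPG) information.

    Returns ``{item_id: {"a": se_a, "b": [se_b1, ...]}}`` and caches the
    table on ``result.se_table``.
    """
    bank = result.bank
    nodes, w = quadrature(config)
    arrays = BankArrays(bank)
    resp = responses.responses
    logl_iq = arrays.log_prob_obs(nodes, resp)
    m = logl_iq.max(axis=1, keepdims=True)
    liq = np.exp(logl_iq - m)
    post = liq * w[None, :] / (liq @ w)[:, None]  # N x Q posterior weights

    n = resp.shape[0]
    blocks: list[np.ndarray] = []
    sizes: list[int] = []
    for j, item in enumerate(bank.items):
        kk = item.n_categories
        da, db = _item_logprob_grads(item, nodes)
        col = resp[:, j]
        g = np.zeros((n, kk))  # (a, b_1..b_{K-1}) score per respondent
        mask = ~np.isnan(col)
        codes = col[mask].astype(int)
        # score = E_post[ dlog P_{x}(theta) / d eta ]
        g[mask, 0] = np.einsum("iq,iq->i", post[mask], da[codes])
        for p in range(kk - 1):
            g[mask, 1 + p] = np.einsum("iq,iq->i", post[mask], db[codes, :, p])
        blocks.append(g)
        sizes.append(kk)
    scores = np.hstack(blocks)
    info = scores.T @ scores
    diag = np.diag(info)
    if np.any(diag <= 0):
        bad = int(np.argmax(diag <= 0))
        cum = np.cumsum(sizes)
        j_bad = int(np.searchsorted(cum, bad, side="right"))
        raise np.linalg.LinAlgError(
            f"singular information matrix at item {bank.items[j_bad].id!r}"
        )
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular information matrix: {exc}") from exc
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    table: dict = {}
    pos = 0
    for item, size in zip(bank.items, sizes):
        table[item.id] = {"a": float(se[pos]), "b": [float(x) for x in se[pos + 1 : pos + size]]}
        pos += size
    result.se_table = table
    return table


# ---------------------------------------------------------------------------
# person scoring
# ---------------------------------------------------------------------------

def eap_scores(
    responses: ResponseMatrix,
    bank: ItemBank,
    config: CalibrationConfig = CalibrationConfig(),
) -> list[ThetaEstimate]:
    """Expected-a-posteriori theta per respondent (posterior mean and SD).

    Respondents with no answered items get the prior: theta 0, SE 1.
    """
    order = [iid for iid in responses.item_ids if iid in bank.item_ids]
    if not order:
        raise ValueError("no overlap between response columns and bank items")
    sub = bank.subset(order)
    cols = [responses.item_ids.index(i) for i in order]
    resp = responses.responses[:, cols]
    nodes, w = quadrature(config)
    arrays = BankArrays(sub)
    logl = arrays.log_prob_obs(nodes, resp)  # N x Q
    m = logl.max(axis=1, keepdims=True)
    liq = np.exp(logl - m) * w[None, :]
    denom = liq.sum(axis=1)
    mean = (liq @ nodes) / denom
    var = (liq @ nodes**2) / denom - mean**2
    sd = np.sqrt(np.clip(var, 1e-12, None))
    answered = (~np.isnan(resp)).sum(axis=1)
    out = []
    for i in range(resp.shape[0]):
        if answered[i] == 0:
            out.append(ThetaEstimate(0.0, 1.0, "EAP", clamped=False))
        else:
            out.append(ThetaEstimate(float(mean[i]), float(sd[i]), "EAP"))
    return out
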