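"""Pre-calibration item screening.

Covers the unidimensionality check (ML exploratory factor analysis with the
0.30 single-factor loading rule), mixed-type correlation matrices, Yen's Q3
local-dependence diagnostic, differential item functioning (DIF) by Wald
tests on group-specific GRM parameters, discrimination banding, and a seeded
hot-deck imputation surrogate for missing responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2, multivariate_normal, norm, pearsonr

from .calibration import (
    CalibrationConfig,
    _pack,
    _unpack,
    eap_scores,
    fit_grm,
    quadrature,
)
from .grm_core import PROB_FLOOR, BankArrays, expected_score, _sigmoid
from .item_model import Item, ItemBank, ResponseMatrix

__all__ = [
    "FactorSolution",
    "DIFResult",
    "correlation_matrix",
    "efa",
    "loading_filter",
    "q3_local_dependence",
    "dif_wald",
    "classify_discrimination",
    "DISCRIMINATION_BANDS",
    "hotdeck_impute",
]

logger = logging.getLogger(__name__)


@dataclass
class FactorSolution:
    n_factors: int
    loadings: pd.DataFrame  # items x factors
    rotation: str  # "none" | "varimax" | "oblimin"
    extraction: str
    eigenvalues: np.ndarray
    heywood: bool = False
    factor_corr: np.ndarray | None = None


@dataclass(frozen=True)
class DIFResult:
    item_id: str
    wald_statistic: float
    df: int
    p_value: float
    flagged: bool


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def _polychoric_thresholds(codes: np.ndarray) -> np.ndarray:
    """Univariate normal thresholds from marginal category proportions."""
    counts = np.bincount(codes.astype(int))
    cum = np.cumsum(counts)[:-1] / counts.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return norm.ppf(cum)


def _bvn_cdf(x: float, y: float, rho: float) -> float:
    if np.isinf(x) and x > 0:
        x = 37.0
    if np.isinf(y) and y > 0:
        y = 37.0
    if x <= -37.0 or y <= -37.0:
        return 0.0
    return float(
        multivariate_normal.cdf([x, y], mean=[0, 0], cov=[[1, rho], [rho, 1]])
    )


def polychoric(x: np.ndarray, y: np.ndarray) -> float:
    """Two-step maximum-likelihood polychoric correlation of two ordinal codes.

    Thresholds come from the marginals; rho maximizes the bivariate-normal
    quadrant likelihood of the contingency table.
    """
    mask = ~(np.isnan(x) | np.isnan(y))
    xs, ys = x[mask].astype(int), y[mask].astype(int)
    kx, ky = xs.max() + 1, ys.max() + 1
    table = np.zeros((kx, ky))
    np.add.at(table, (xs, ys), 1)
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("empty contingency margin")
    tx = np.concatenate([[-np.inf], _polychoric_thresholds(xs), [np.inf]])
    ty = np.concatenate([[-np.inf], _polychoric_thresholds(ys), [np.inf]])

    def neg_ll(rho: float) -> float:
        ll = 0.0
        for i in range(kx):
            for j in range(ky):
                if table[i, j] == 0:
                    continue
                p = (
                    _bvn_cdf(tx[i + 1], ty[j + 1], rho)
                    - _bvn_cdf(tx[i], ty[j + 1], rho)
                    - _bvn_cdf(tx[i + 1], ty[j], rho)
                    + _bvn_cdf(tx[i], ty[j], rho)
                )
                ll += table[i, j] * np.log(max(p, 1e-12))
        return -ll

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polyserial(x_cont: np.ndarray, y_ord: np.ndarray) -> float:
    """Two-step ML polyserial correlation (continuous x, ordinal y)."""
    mask = ~(np.isnan(x_cont) | np.isnan(y_ord))
    xs = x_cont[mask]
    ys = y_ord[mask].astype(int)
    z = (xs - xs.mean()) / xs.std(ddof=0)
    tau = np.concatenate([[-np.inf], _polychoric_thresholds(ys), [np.inf]])

    def neg_ll(rho: float) -> float:
        denom = np.sqrt(max(1 - rho**2, 1e-10))
        upper = (tau[ys + 1] - rho * z) / denom
        lower = (tau[ys] - rho * z) / denom
        p = norm.cdf(upper) - norm.cdf(lower)
        return -float(np.sum(np.log(np.clip(p, 1e-12, None))))

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def correlation_matrix(
    responses: ResponseMatrix,
    types: dict[str, str] | None = None,
    min_pairwise: int = 10,
) -> pd.DataFrame:
    """Mixed-type correlation matrix over items.

    ``types`` maps item id -> "ordinal" | "continuous" (default ordinal).
    Polychoric is used for ordinal pairs, polyserial for mixed pairs, and
    Pearson for continuous pairs.  Entries whose pair has an empty
    contingency margin or too few complete observations are NaN.
    """
    ids = responses.item_ids
    if len(ids) < 2:
        raise ValueError("need at least 2 items")
    types = types or {}
    kind = [types.get(i, "ordinal") for i in ids]
    j = len(ids)
    out = np.eye(j)
    data = responses.responses
    for p in range(j):
        for q in range(p + 1, j):
            x, y = data[:, p], data[:, q]
            mask = ~(np.isnan(x) | np.isnan(y))
            if mask.sum() < min_pairwise:
                out[p, q] = out[q, p] = np.nan
                continue
            try:
                if kind[p] == "ordinal" and kind[q] == "ordinal":
                    r = polychoric(x, y)
                elif kind[p] == "continuous" and kind[q] == "continuous":
                    r = float(pearsonr(x[mask], y[mask])[0])
                elif kind[p] == "continuous":
                    r = polyserial(x, y)
                else:
                    r = polyserial(y, x)
            except ValueError:
                logger.warning("correlation undefined for pair (%s, %s)", ids[p], ids[q])
                r = np.nan
            out[p, q] = out[q, p] = r
    return pd.DataFrame(out, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------

def _smooth_psd(corr: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= 1e-8:
        return corr, False
    vals = np.clip(vals, 1e-6, None)
    sm = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(sm))
    sm = sm / np.outer(d, d)
    return sm, True


def efa(
    corr: pd.DataFrame | np.ndarray,
    n_factors: int,
    rotation: str = "none",
    nobs: int = 300,
) -> FactorSolution:
    """Maximum-likelihood exploratory factor analysis of a correlation matrix.

    Backed by :mod:`statsmodels` ML factor extraction; rotation is varimax
    (orthogonal) or oblimin (oblique).  Non-PSD inputs are smoothed (logged);
    Heywood cases are flagged on the result, not fatal.
    """
    from statsmodels.multivariate.factor import Factor

    if rotation not in ("none", "varimax", "oblimin"):
        raise ValueError(f"unknown rotation {rotation!r}")
    if isinstance(corr, pd.DataFrame):
        names = list(corr.index)
        mat = corr.to_numpy(dtype=float)
    else:
        mat = np.asarray(corr, dtype=float)
        names = [f"item{i}" for i in range(mat.shape[0])]
    if np.isnan(mat).any():
        raise ValueError("correlation matrix contains undefined entries")
    if n_factors >= mat.shape[0] / 2:
        raise ValueError("n_factors must be < n_items / 2")
    mat, smoothed = _smooth_psd(mat)
    if smoothed:
        logger.warning("correlation matrix smoothed to nearest PSD")
    eigenvalues = np.sort(np.linalg.eigvalsh(mat))[::-1]

    heywood = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fa = Factor(corr=mat, n_factor=n_factors, method="ml", nobs=nobs)
            res = fa.fit()
            loadings = np.asarray(res.loadings)[:, :n_factors]
        except Exception:  # ML can fail on degenerate inputs; fall back to PA
            fa = Factor(corr=mat, n_factor=n_factors, method="pa")
            res = fa.fit()
            loadings = np.asarray(res.loadings)[:, :n_factors]
    communality = np.sum(loadings**2, axis=1)
    if np.any(communality > 1.0 - 1e-8):
        heywood = True

    factor_corr = None
    if rotation != "none" and n_factors > 1:
        from statsmodels.multivariate.factor_rotation import rotate_factors

        if rotation == "varimax":
            loadings, _ = rotate_factors(loadings, "varimax")
            factor_corr = np.eye(n_factors)
        else:
            loadings, t = rotate_factors(loadings, "oblimin", 0, "oblique")
            factor_corr = t.T @ t
    elif rotation == "varimax":
        factor_corr = np.eye(n_factors)

    # sign convention: dominant loading positive per factor
    for f in range(loadings.shape[1]):
        if loadings[np.argmax(np.abs(loadings[:, f])), f] < 0:
            loadings[:, f] = -loadings[:, f]

    return FactorSolution(
        n_factors=n_factors,
        loadings=pd.DataFrame(
            loadings, index=names, columns=[f"F{f + 1}" for f in range(n_factors)]
        ),
        rotation=rotation,
        extraction="ml",
        eigenvalues=eigenvalues,
        heywood=heywood,
        factor_corr=factor_corr,
    )


def loading_filter(
    solution: FactorSolution, threshold: float = 0.30
) -> tuple[list[str], dict[str, str]]:
    """Keep items loading >= threshold on exactly one factor.

    Returns (kept ids, {excluded id: reason}).  Pure function of the loading
    matrix and the threshold.
    """
    kept: list[str] = []
    excluded: dict[str, str] = {}
    lam = solution.loadings
    for iid, row in lam.iterrows():
        above = np.abs(row.to_numpy()) >= threshold
        if above.sum() == 1:
            kept.append(str(iid))
        elif above.sum() == 0:
            excluded[str(iid)] = f"no loading >= {threshold}"
        else:
            excluded[str(iid)] = f"cross-loading on {int(above.sum())} factors"
    return kept, excluded


# ---------------------------------------------------------------------------
# local dependence (Yen's Q3)
# ---------------------------------------------------------------------------

def q3_local_dependence(
    responses: ResponseMatrix,
    bank: ItemBank,
    cutoff: float = 0.2,
    config: CalibrationConfig = CalibrationConfig(),
) -> pd.DataFrame:
    """Yen's Q3 residual correlations between item pairs.

    Residuals are observed minus model-expected scores at each respondent's
    EAP theta.  Under local independence Q3 has a small negative bias of
    about -1/(J-1); a pair is flagged when its Q3 deviates from that
    baseline by more than ``cutoff``.
    """
    order = [iid for iid in responses.item_ids if iid in bank.item_ids]
    sub = bank.subset(order)
    cols = [responses.item_ids.index(i) for i in order]
    data = responses.responses[:, cols]
    thetas = np.array([t.value for t in eap_scores(responses, bank, config)])
    resid = np.full_like(data, np.nan)
    for j, iid in enumerate(order):
        exp = np.asarray(expected_score(sub[iid], thetas))
        resid[:, j] = data[:, j] - exp
    rows = []
    jn = len(order)
    for p in range(jn):
        for q in range(p + 1, jn):
            mask = ~(np.isnan(resid[:, p]) | np.isnan(resid[:, q]))
            rp, rq = resid[mask, p], resid[mask, q]
            if rp.std() < 1e-12 or rq.std() < 1e-12:
                logger.warning("zero residual variance for pair (%s, %s); skipped",
                               order[p], order[q])
                continue
            rows.append((order[p], order[q], float(np.corrcoef(rp, rq)[0, 1])))
    df = pd.DataFrame(rows, columns=["item_1", "item_2", "q3"])
    baseline = -1.0 / (jn - 1) if jn > 1 else 0.0
    df["flagged"] = (df["q3"] - baseline).abs() > cutoff
    df.attrs["baseline"] = baseline
    return df


# ---------------------------------------------------------------------------
# differential item functioning (Wald test)
# ---------------------------------------------------------------------------

def _profile_item_fit(
    resp: np.ndarray,
    j: int,
    anchor: ItemBank,
    ks: np.ndarray,
    config: CalibrationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit one item's (a, b) by marginal ML with every other item anchored.

    Returns the natural parameter vector beta = (a, b_1..b_{K-1}) and its
    covariance from the observed information of the profile likelihood.
    """
    nodes, w = quadrature(config)
    others = [i for i in range(len(anchor)) if i != j]
    arrays_other = BankArrays([anchor.items[i] for i in others])
    la_other = arrays_other.log_prob_obs(nodes, resp[:, others])  # N x Q
    col = resp[:, j]
    obs = ~np.isnan(col)
    codes = np.where(obs, col, 0).astype(int)
    kk = int(ks[j])

    def neg_ll(eta: np.ndarray) -> float:
        a, b = _unpack(eta)
        pstar = _sigmoid(a * (nodes[None, :] - b[:, None]))
        full = np.vstack([np.ones_like(nodes), pstar, np.zeros_like(nodes)])
        logp = np.log(np.clip(full[:-1] - full[1:], PROB_FLOOR, None))  # K x Q
        lj = np.where(obs[:, None], logp[codes], 0.0)  # N x Q
        tot = la_other + lj
        m = tot.max(axis=1, keepdims=True)
        return -float(np.sum(np.log(np.exp(tot - m) @ w) + m[:, 0]))

    item0 = anchor.items[j]
    eta0 = _pack(item0.discrimination, np.asarray(item0.thresholds))
    res = minimize(neg_ll, eta0, method="Nelder-Mead",
                   options={"xatol": 1e-5, "fatol": 1e-7, "maxiter": 2000})
    a_hat, b_hat = _unpack(res.x)
    beta = np.concatenate([[a_hat], b_hat])

    # observed information in the natural parametrization, central differences
    def neg_ll_nat(beta_v: np.ndarray) -> float:
        b = np.sort(beta_v[1:])
        return neg_ll(_pack(max(beta_v[0], 1e-3), b))

    p = beta.size
    h = 1e-4 * np.maximum(np.abs(beta), 1.0)
    hess = np.zeros((p, p))
    f0 = neg_ll_nat(beta)
    for r in range(p):
        for c in range(r, p):
            er = np.zeros(p)
            ec = np.zeros(p)
            er[r] = h[r]
            ec[c] = h[c]
            if r == c:
                val = (neg_ll_nat(beta + er) - 2 * f0 + neg_ll_nat(beta - er)) / h[r] ** 2
            else:
                val = (
                    neg_ll_nat(beta + er + ec)
                    - neg_ll_nat(beta + er - ec)
                    - neg_ll_nat(beta - er + ec)
                    + neg_ll_nat(beta - er - ec)
                ) / (4 * h[r] * h[c])
            hess[r, c] = hess[c, r] = val
    cov = np.linalg.pinv(hess)
    return beta, cov


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, pvals[idx] * n / rank)
        adj[idx] = running
    return adj


def dif_wald(
    responses: ResponseMatrix,
    group: str | np.ndarray = "gender",
    alpha: float = 0.05,
    config: CalibrationConfig | None = None,
    adjust: bool = True,
) -> list[DIFResult]:
    """Wald-test DIF per item with all-other-items anchoring between 2 groups.

    A combined-sample calibration supplies anchor parameters; each item is
    re-fit freely within each group, and W = d' (V_F + V_R)^-1 d with
    d the difference of the group parameter vectors.  P-values are
    Benjamini-Hochberg adjusted across items before flagging at ``alpha``.
    """
    if isinstance(group, str):
        if group not in responses.covariates.columns:
            raise ValueError(f"covariate {group!r} not present")
        gvals = responses.covariates[group].to_numpy()
    else:
        gvals = np.asarray(group)
    levels = pd.unique(gvals[~pd.isna(gvals)])
    if len(levels) != 2:
        raise ValueError(f"DIF requires exactly 2 groups, found {len(levels)}")
    cfg = config or CalibrationConfig(tol=1e-3, min_n=50, warn_n=100)
    masks = [gvals == lv for lv in levels]
    for lv, mask in zip(levels, masks):
        if mask.sum() < 100:
            warnings.warn(f"group {lv!r} has N={int(mask.sum())} < 100", stacklevel=2)

    combined = fit_grm(responses, cfg)
    anchor = combined.bank
    ks = np.array([it.n_categories for it in anchor.items])
    results: list[tuple[str, float, int]] = []
    for j, iid in enumerate(responses.item_ids):
        try:
            b_f, v_f = _profile_item_fit(
                responses.responses[masks[0]], j, anchor, ks, cfg
            )
            b_r, v_r = _profile_item_fit(
                responses.responses[masks[1]], j, anchor, ks, cfg
            )
            d = b_f - b_r
            v = v_f + v_r
            w_stat = float(d @ np.linalg.solve(v, d))
            if not np.isfinite(w_stat) or w_stat < 0:
                raise np.linalg.LinAlgError("non-PD covariance")
        except np.linalg.LinAlgError:
            logger.warning("item %s skipped in DIF (singular covariance)", iid)
            continue
        results.append((iid, w_stat, int(ks[j])))

    pvals = np.array([chi2.sf(w, df) for _, w, df in results])
    padj = _bh_adjust(pvals) if adjust else pvals
    return [
        DIFResult(iid, w, df, float(p), bool(p < alpha))
        for (iid, w, df), p in zip(results, padj)
    ]


# ---------------------------------------------------------------------------
# discrimination banding
# ---------------------------------------------------------------------------

#: conventional slope bands (pure logistic metric)
DISCRIMINATION_BANDS = (
    (0.35, "very_low"),
    (0.65, "low"),
    (1.35, "moderate"),
    (1.70, "high"),
    (np.inf, "very_high"),
)


def classify_discrimination(a: float) -> str:
    """Band a discrimination: very_low < 0.35 <= low < 0.65 <= moderate
    < 1.35 <= high < 1.70 <= very_high."""
    if a < 0:
        raise ValueError("discrimination must be >= 0")
    for upper, name in DISCRIMINATION_BANDS:
        if a < upper:
            return name
    return "very_high"


# ---------------------------------------------------------------------------
# hot-deck imputation surrogate
# ---------------------------------------------------------------------------

def hotdeck_impute(responses: ResponseMatrix, seed: int = 0) -> ResponseMatrix:
    """Fill missing cells from donors in the same total-score decile (seeded).

    Donor pools are respondents with the cell observed whose proportional
    total score falls in the same decile as the recipient's; empty pools fall
    back to the item mode (logged).  Deterministic under ``seed``.
    """
    miss_rate = np.isnan(responses.responses).mean(axis=0)
    if np.any(miss_rate >= 0.30):
        bad = [responses.item_ids[j] for j in np.flatnonzero(miss_rate >= 0.30)]
        raise ValueError(f"per-item missingness >= 30% for {bad}")
    out = responses.copy()
    data = out.responses
    if not np.isnan(data).any():
        return out
    rng = np.random.default_rng(seed)
    # proportional score: mean observed code scaled by item range
    with np.errstate(invalid="ignore"):
        prop = np.nanmean(data / np.maximum(np.nanmax(data, axis=0), 1)[None, :], axis=1)
    prop = np.where(np.isnan(prop), 0.5, prop)
    deciles = np.clip(np.floor(pd.Series(prop).rank(pct=True) * 10).astype(int), 0, 9)
    for j in range(data.shape[1]):
        col = data[:, j]
        missing_rows = np.flatnonzero(np.isnan(col))
        if missing_rows.size == 0:
            continue
        observed = ~np.isnan(col)
        modes = pd.Series(col[observed]).mode()
        mode_val = float(modes.iloc[0])
        for i in missing_rows:
            pool = np.flatnonzero(observed & (deciles == deciles[i]).to_numpy())
            if pool.size == 0:
                logger.warning(
                    "empty donor pool for respondent %s item %s; item mode used",
                    out.respondent_ids[i], out.item_ids[j],
                )
                col[i] = mode_val
            else:
                col[i] = col[rng.choice(pool)]
    return out
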