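"""Adaptive testing engine: item selection, theta estimation, SE stopping.

The session starts from a randomly chosen first item (seeded), selects
subsequent items by maximum Fisher information (MFI) or a posterior-weighted
Kullback-Leibler index, re-estimates theta after every response, and stops
when the standard error of measurement drops to the configured cutoff
(default 0.3) or the bank is exhausted.  The final reporting score is
T = theta * 10 + 50.

In a unidimensional model the determinant/trace/eigenvalue-style selection
rules of multidimensional CAT all reduce to maximizing the single item's
Fisher information, so the engine exposes MFI and KL only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize_scalar

from .grm_core import (
    PROB_FLOOR,
    BankArrays,
    ThetaEstimate,
    cumulative_prob,
    item_information,
    log_likelihood,
)
from .item_model import Item, ItemBank

__all__ = [
    "CatConfig",
    "CatSession",
    "start_session",
    "estimate_theta",
    "select_next_item",
    "step",
    "run_session",
    "t_score",
    "endorsement_table",
]

_EST = ("ML", "EAP", "MAP", "WLE")
_RULES = ("MFI", "KL", "random")

# fine grid for posterior summaries inside the engine
_GRID = np.linspace(-6.0, 6.0, 241)
_LOG_PRIOR = -0.5 * _GRID**2


@dataclass(frozen=True)
class CatConfig:
    se_cutoff: float = 0.3
    estimator: str = "EAP"
    selection_rule: str = "MFI"
    first_item: str = "random"  # "random" | "max_info_at_prior"
    seed: int = 0
    theta_bounds: tuple[float, float] = (-4.0, 4.0)
    max_items: int | None = None

    def __post_init__(self) -> None:
        if self.se_cutoff <= 0:
            raise ValueError("se_cutoff must be > 0")
        if self.estimator not in _EST:
            raise ValueError(f"estimator must be one of {_EST}")
        if self.selection_rule not in _RULES:
            raise ValueError(f"selection_rule must be one of {_RULES}")
        if self.first_item not in ("random", "max_info_at_prior"):
            raise ValueError("first_item must be 'random' or 'max_info_at_prior'")
        if not self.theta_bounds[0] < self.theta_bounds[1]:
            raise ValueError("theta_bounds must be ordered")


@dataclass
class CatSession:
    config: CatConfig
    administered: list[str] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)
    theta_trajectory: list[ThetaEstimate] = field(default_factory=list)
    pending_item: str | None = None
    finished: bool = False
    stop_reason: str | None = None  # "se_reached" | "bank_exhausted" | "max_items"
    t_score: float | None = None
    _rng: np.random.Generator | None = field(default=None, repr=False)

    @property
    def n_administered(self) -> int:
        return len(self.administered)

    def response_map(self) -> dict[str, int]:
        return dict(zip(self.administered, self.responses))


def t_score(theta: float) -> float:
    """Reporting score: theta * 10 + 50."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return theta * 10.0 + 50.0


# ---------------------------------------------------------------------------
# theta estimation
# ---------------------------------------------------------------------------

def _loglik_grid(responses: dict[str, int], bank: ItemBank) -> np.ndarray:
    return np.asarray(log_likelihood(responses, bank, _GRID))


def _observed_se(responses: dict[str, int], bank: ItemBank, theta: float) -> float:
    info = sum(item_information(bank[i], theta) for i in responses)
    return 1.0 / np.sqrt(max(info, PROB_FLOOR))


def estimate_theta(
    responses: dict[str, int],
    bank: ItemBank,
    estimator: str = "EAP",
    theta_bounds: tuple[float, float] = (-4.0, 4.0),
) -> ThetaEstimate:
    """Estimate theta from the responses so far.

    ML maximizes the likelihood within ``theta_bounds`` (clamped + flagged at
    the bounds); MAP is the posterior mode and EAP the posterior mean under a
    N(0,1) prior; WLE maximizes likelihood times the square root of the test
    information (Warm's correction).  SE is the posterior SD for EAP/MAP and
    the observed-information SE for ML/WLE.
    """
    if estimator not in _EST:
        raise ValueError(f"unknown estimator {estimator!r}")
    if not responses:
        if estimator in ("EAP", "MAP"):
            return ThetaEstimate(0.0, 1.0, estimator)
        raise ValueError(f"{estimator} requires at least one response")

    ll = _loglik_grid(responses, bank)
    lo, hi = theta_bounds

    if estimator == "EAP":
        post = ll + _LOG_PRIOR
        post = np.exp(post - post.max())
        post /= post.sum()
        mean = float(post @ _GRID)
        sd = float(np.sqrt(max(post @ _GRID**2 - mean**2, 1e-12)))
        return ThetaEstimate(mean, sd, "EAP")

    def refine(objective, x0: float) -> float:
        res = minimize_scalar(
            lambda t: -objective(t),
            bounds=(max(x0 - 0.5, _GRID[0]), min(x0 + 0.5, _GRID[-1])),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return float(res.x)

    if estimator == "MAP":
        obj_grid = ll + _LOG_PRIOR
        x0 = float(_GRID[np.argmax(obj_grid)])
        mode = refine(
            lambda t: float(log_likelihood(responses, bank, t)) - 0.5 * t**2, x0
        )
        # posterior SD via the grid (same quantity EAP reports)
        post = np.exp(obj_grid - obj_grid.max())
        post /= post.sum()
        mean = float(post @ _GRID)
        sd = float(np.sqrt(max(post @ _GRID**2 - mean**2, 1e-12)))
        return ThetaEstimate(mode, sd, "MAP")

    if estimator == "ML":
        x0 = float(_GRID[np.argmax(ll)])
        mle = refine(lambda t: float(log_likelihood(responses, bank, t)), x0)
        clamped = False
        if mle <= lo or mle >= hi:
            mle = float(np.clip(mle, lo, hi))
            clamped = True
        return ThetaEstimate(
            mle, _observed_se(responses, bank, mle), "ML", clamped=clamped
        )

    # WLE: maximize loglik + 0.5 * log I(theta)
    def wle_obj(t: float) -> float:
        info = sum(item_information(bank[i], t) for i in responses)
        return float(log_likelihood(responses, bank, t)) + 0.5 * np.log(
            max(info, PROB_FLOOR)
        )

    # WLE stays finite without clamping: information decays faster than the
    # likelihood grows, so the maximizer is interior to the grid
    grid_obj = np.array([wle_obj(t) for t in _GRID[::4]])
    x0 = float(_GRID[::4][np.argmax(grid_obj)])
    est = refine(wle_obj, x0)
    return ThetaEstimate(est, _observed_se(responses, bank, est), "WLE")


# ---------------------------------------------------------------------------
# item selection
# ---------------------------------------------------------------------------

def _posterior(responses: dict[str, int], bank: ItemBank) -> np.ndarray:
    ll = _loglik_grid(responses, bank) if responses else np.zeros_like(_GRID)
    post = np.exp(ll + _LOG_PRIOR - (ll + _LOG_PRIOR).max())
    return post / post.sum()


def _kl_index(item: Item, theta_hat: float, posterior: np.ndarray) -> float:
    """Posterior-weighted KL divergence KL(theta_hat || theta) over the grid."""
    from .grm_core import category_probs

    p_hat = np.clip(category_probs(item, float(theta_hat)), PROB_FLOOR, None)
    p_grid = np.clip(category_probs(item, _GRID), PROB_FLOOR, None)  # Q x K
    kl = np.sum(p_hat[None, :] * (np.log(p_hat)[None, :] - np.log(p_grid)), axis=1)
    return float(posterior @ kl)


def select_next_item(
    session: CatSession, bank: ItemBank, rule: str | None = None
) -> str:
    """Choose the next unadministered item; ties break to the lowest index."""
    rule = rule or session.config.selection_rule
    remaining = [
        (j, iid)
        for j, iid in enumerate(bank.item_ids)
        if iid not in session.administered and iid != session.pending_item
    ]
    if not remaining:
        raise LookupError("no unadministered items remain")
    if rule == "random":
        rng = session._rng or np.random.default_rng(session.config.seed)
        return remaining[int(rng.integers(len(remaining)))][1]
    resp = session.response_map()
    theta_hat = (
        session.theta_trajectory[-1].value if session.theta_trajectory else 0.0
    )
    if rule == "MFI":
        crit = [item_information(bank[iid], theta_hat) for _, iid in remaining]
    elif rule == "KL":
        post = _posterior(resp, bank)
        crit = [_kl_index(bank[iid], theta_hat, post) for _, iid in remaining]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    best = int(np.argmax(crit))  # argmax returns the first (lowest-index) max
    return remaining[best][1]


# ---------------------------------------------------------------------------
# session loop
# ---------------------------------------------------------------------------

def start_session(bank: ItemBank, config: CatConfig = CatConfig()) -> CatSession:
    """Open a session with a seeded random (or max-information) first item."""
    if len(bank) == 0:
        raise ValueError("empty item bank")
    rng = np.random.default_rng(config.seed)
    session = CatSession(config=config, _rng=rng)
    if config.first_item == "random":
        session.pending_item = bank.item_ids[int(rng.integers(len(bank)))]
    else:
        infos = [item_information(it, 0.0) for it in bank.items]
        session.pending_item = bank.item_ids[int(np.argmax(infos))]
    return session


def step(session: CatSession, response_code: int, bank: ItemBank) -> CatSession:
    """Record a response to the pending item, re-estimate, and advance."""
    if session.finished:
        raise RuntimeError("session already finished")
    if session.pending_item is None:
        raise RuntimeError("no pending item")
    item = bank[session.pending_item]
    code = int(response_code)
    if not (0 <= code < item.n_categories):
        raise ValueError(
            f"invalid code {code} for item {item.id!r} (K={item.n_categories})"
        )
    session.administered.append(session.pending_item)
    session.responses.append(code)
    session.pending_item = None

    cfg = session.config
    est = estimate_theta(
        session.response_map(), bank, cfg.estimator, cfg.theta_bounds
    )
    session.theta_trajectory.append(est)

    exhausted = len(session.administered) >= len(bank)
    hit_max = cfg.max_items is not None and len(session.administered) >= cfg.max_items
    if est.se <= cfg.se_cutoff:
        session.finished = True
        session.stop_reason = "se_reached"
    elif exhausted:
        session.finished = True
        session.stop_reason = "bank_exhausted"
    elif hit_max:
        session.finished = True
        session.stop_reason = "max_items"
    else:
        session.pending_item = select_next_item(session, bank)
    if session.finished:
        session.t_score = t_score(est.value)
    return session


def run_session(
    bank: ItemBank,
    config: CatConfig,
    responder,
) -> CatSession:
    """Drive a session to completion; ``responder(item) -> code``."""
    session = start_session(bank, config)
    while not session.finished:
        code = responder(bank[session.pending_item])
        step(session, code, bank)
    return session


# ---------------------------------------------------------------------------
# theta-level clinical interpretation
# ---------------------------------------------------------------------------

def endorsement_table(
    bank: ItemBank,
    theta_levels=(-2.0, -1.0, 0.0, 1.0, 2.0),
    top_n: int = 10,
    min_a: float = 0.65,
) -> dict[float, list[dict]]:
    """Most-endorsed pseudo-dichotomous categories per theta level.

    Each polytomous category k becomes the event "respond in category >= k"
    with endorsement probability P*_k(theta).  Items with discrimination
    below ``min_a`` are excluded; per level the ``top_n`` categories are
    returned ranked by endorsement probability (ties to lower item index).
    """
    eligible = [it for it in bank.items if it.discrimination >= min_a]
    if not eligible:
        raise ValueError(f"no items with discrimination >= {min_a}")
    out: dict[float, list[dict]] = {}
    for level in theta_levels:
        if not np.isfinite(level):
            raise ValueError("theta levels must be finite")
        rows = []
        for idx, it in enumerate(eligible):
            for k in range(1, it.n_categories):
                p = float(cumulative_prob(it, k, float(level)))
                rows.append(
                    {
                        "item_id": it.id,
                        "category": k,
                        "probability": p,
                        "_order": idx,
                    }
                )
        rows.sort(key=lambda r: (-r["probability"], r["_order"], r["category"]))
        out[float(level)] = [
            {k: v for k, v in r.items() if k != "_order"} for r in rows[:top_n]
        ]
    return out
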