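"""Adaptive test engine: maximum-information selection, EAP scoring,
fixed-length / SE-threshold stopping with a forced maximum length.

The engine replays a person's complete response vector ("post-hoc"
simulation): at each step the most informative unadministered item at the
current EAP estimate is selected, its recorded response is scored, and the
posterior over the quadrature grid is updated.  Entry level is theta = 0
(the prior mean); the SE check happens after each update, never before the
first item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .evaluation import marginal_reliability
from .models import (
    PROB_FLOOR,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    ThetaGrid,
    category_probs,
    item_information,
)

__all__ = [
    "StoppingRule",
    "PosteriorState",
    "CatResult",
    "CohortRuleResult",
    "prior_state",
    "eap_update",
    "select_next_item",
    "run_cat",
    "batch_eap",
    "simulate_cohort",
]


@dataclass(frozen=True)
class StoppingRule:
    """Fixed-length and/or SE-threshold termination.

    When ``se_threshold`` is set, ``max_items`` caps the test length even if
    the precision target was never reached (default 13).
    """

    fixed_length: int | None = None
    se_threshold: float | None = None
    max_items: int = 13

    def __post_init__(self) -> None:
        if self.fixed_length is None and self.se_threshold is None:
            raise ValueError("need fixed_length and/or se_threshold")
        if self.fixed_length is not None and self.fixed_length < 1:
            raise ValueError("fixed_length must be >= 1")

    @property
    def name(self) -> str:
        if self.se_threshold is None:
            return f"length={self.fixed_length}"
        return f"se<{self.se_threshold}|max={self.max_items}"

    def cap(self, bank_size: int) -> int:
        if self.fixed_length is not None:
            if self.fixed_length > bank_size:
                raise ValueError("fixed_length exceeds bank size")
            return self.fixed_length
        return min(self.max_items, bank_size)


@dataclass
class PosteriorState:
    """Quadrature representation of one person's posterior over theta."""

    grid: ThetaGrid
    log_post: np.ndarray  # unnormalized log posterior at the nodes
    eap: float
    se: float

    def posterior(self) -> np.ndarray:
        p = np.exp(self.log_post - self.log_post.max())
        return p / p.sum()


def _moments(grid: ThetaGrid, log_post: np.ndarray) -> tuple[float, float]:
    p = np.exp(log_post - log_post.max())
    p /= p.sum()
    eap = float(p @ grid.nodes)
    var = float(p @ (grid.nodes - eap) ** 2)
    return eap, float(np.sqrt(max(var, 1e-30)))


def prior_state(grid: ThetaGrid | None = None) -> PosteriorState:
    grid = grid or ThetaGrid.default()
    log_post = np.log(grid.weights)
    eap, se = _moments(grid, log_post)
    return PosteriorState(grid, log_post, eap, se)


def eap_update(
    state: PosteriorState, item: ItemParameters, response: int
) -> PosteriorState:
    """Multiply the posterior by the item's category likelihood."""
    if not 0 <= response < item.n_categories:
        raise ValueError(
            f"response {response} invalid for item {item.item_id} "
            f"with {item.n_categories} categories"
        )
    like = category_probs(item, state.grid.nodes)[:, response]
    log_post = state.log_post + np.log(np.maximum(like, PROB_FLOOR))
    log_post -= log_post.max()  # rescale; never zero out
    eap, se = _moments(state.grid, log_post)
    return PosteriorState(state.grid, log_post, eap, se)


class _BankInfo:
    """Vectorized per-bank information evaluation at a scalar theta."""

    def __init__(self, bank: ItemBank):
        self.bank = bank
        self._grm = bank.model == "GRM" if len(bank) else False
        if self._grm:
            kmax = max(it.n_categories for it in bank)
            self.a = np.array([it.a for it in bank])
            self.b = np.full((len(bank), kmax - 1), np.inf)
            for j, it in enumerate(bank):
                self.b[j, : len(it.b)] = it.b

    def info_at(self, theta: float) -> np.ndarray:
        if not self._grm:
            return np.array([item_information(it, theta) for it in self.bank])
        pstar = expit(self.a[:, None] * (theta - self.b))
        padded = np.concatenate(
            [np.ones((len(self.a), 1)), pstar, np.zeros((len(self.a), 1))], axis=1
        )
        probs = -np.diff(padded, axis=1)
        dstar = self.a[:, None] * padded * (1.0 - padded)
        dprobs = -np.diff(dstar, axis=1)
        return (dprobs**2 / np.maximum(probs, PROB_FLOOR)).sum(axis=1)


def select_next_item(
    state: PosteriorState,
    bank: ItemBank,
    administered: set[str],
    _bank_info: _BankInfo | None = None,
) -> str | None:
    """Unadministered item maximizing information at the current EAP.

    Ties break to the lowest bank index; returns ``None`` when the bank is
    exhausted.
    """
    info = (_bank_info or _BankInfo(bank)).info_at(state.eap)
    best_id, best_info = None, -np.inf
    for j, it in enumerate(bank):
        if it.item_id in administered:
            continue
        if info[j] > best_info:
            best_id, best_info = it.item_id, float(info[j])
    return best_id


@dataclass
class CatResult:
    administered: list[str]
    responses: list[int]
    trajectory: list[tuple[float, float]]  # (eap, se) after each item
    eap: float
    se: float

    @property
    def n_items(self) -> int:
        return len(self.administered)


def run_cat(
    responses_row: np.ndarray,
    bank: ItemBank,
    rule: StoppingRule,
    grid: ThetaGrid | None = None,
    on_missing: str = "error",
    _bank_info: _BankInfo | None = None,
) -> CatResult:
    """Adaptive administration replaying one person's response vector.

    ``responses_row`` aligns with ``bank``; negative/NaN entries are missing.
    ``on_missing='skip'`` removes unanswerable items from selection,
    ``'error'`` aborts.
    """
    row = np.asarray(responses_row, dtype=float)
    if len(row) != len(bank):
        raise ValueError("response row length must equal bank size")
    binfo = _bank_info or _BankInfo(bank)
    missing = {bank[j].item_id for j in range(len(bank)) if np.isnan(row[j]) or row[j] < 0}
    if missing and on_missing == "error":
        raise ValueError(f"missing responses for bank items: {sorted(missing)[:5]}")
    state = prior_state(grid)
    cap = rule.cap(len(bank))
    administered: list[str] = []
    used_responses: list[int] = []
    trajectory: list[tuple[float, float]] = []
    excluded = set(missing)
    while len(administered) < cap:
        nxt = select_next_item(state, bank, excluded, binfo)
        if nxt is None:
            break
        j = bank.item_ids.index(nxt)
        resp = int(row[j])
        state = eap_update(state, bank[j], resp)
        administered.append(nxt)
        used_responses.append(resp)
        excluded.add(nxt)
        trajectory.append((state.eap, state.se))
        if rule.se_threshold is not None and state.se < rule.se_threshold:
            break
    return CatResult(administered, used_responses, trajectory, state.eap, state.se)


def batch_eap(
    responses: ResponseMatrix, bank: ItemBank, grid: ThetaGrid | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """EAP mean and posterior SD for every person on the full pattern."""
    grid = grid or ThetaGrid.default()
    n = responses.n_persons
    logpost = np.tile(np.log(grid.weights), (n, 1))
    for j, item in enumerate(bank):
        probs = category_probs(item, grid.nodes)
        logp = np.log(np.maximum(probs, PROB_FLOOR))
        obs = responses.mask[:, j]
        logpost[obs] += logp[:, responses.data[obs, j]].T
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    eaps = post @ grid.nodes
    var = post @ grid.nodes**2 - eaps**2
    return eaps, np.sqrt(np.maximum(var, 1e-30))


@dataclass
class CohortRuleResult:
    rule: StoppingRule
    eaps: np.ndarray
    ses: np.ndarray
    n_items: np.ndarray
    mean_items: float
    sd_items: float
    mean_se: float
    marginal_reliability: float
    corr_with_full: float


def simulate_cohort(
    responses: ResponseMatrix,
    bank: ItemBank,
    rules: list[StoppingRule],
    grid: ThetaGrid | None = None,
) -> dict[str, CohortRuleResult]:
    """Run the CAT for every person under every stopping rule.

    Per rule: mean/SD of items used, mean SE, marginal reliability, and the
    Pearson correlation of the CAT estimates with the full-bank estimates.
    """
    grid = grid or ThetaGrid.default()
    if not responses.mask.all():
        raise ValueError("cohort simulation requires a complete response matrix")
    binfo = _BankInfo(bank)
    full_eaps, _ = batch_eap(responses, bank, grid)
    out: dict[str, CohortRuleResult] = {}
    for rule in rules:
        eaps = np.empty(responses.n_persons)
        ses = np.empty(responses.n_persons)
        n_items = np.empty(responses.n_persons)
        for i in range(responses.n_persons):
            res = run_cat(responses.data[i], bank, rule, grid, _bank_info=binfo)
            eaps[i], ses[i], n_items[i] = res.eap, res.se, res.n_items
        corr = float(np.corrcoef(eaps, full_eaps)[0, 1])
        out[rule.name] = CohortRuleResult(
            rule=rule,
            eaps=eaps,
            ses=ses,
            n_items=n_items,
            mean_items=float(n_items.mean()),
            sd_items=float(n_items.std(ddof=0)),
            mean_se=float(ses.mean()),
            marginal_reliability=marginal_reliability(eaps, ses),
            corr_with_full=corr,
        )
    return out


def cohort_summary(results: dict[str, CohortRuleResult]):
    """Summary table with one row per stopping rule."""
    import pandas as pd

    return pd.DataFrame(
        {
            "rule": name,
            "mean_items": r.mean_items,
            "sd_items": r.sd_items,
            "mean_se": r.mean_se,
            "marginal_reliability": r.marginal_reliability,
            "corr_with_full": r.corr_with_full,
        }
        for name, r in results.items()
    )
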