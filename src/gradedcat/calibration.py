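"""Marginal-maximum-likelihood (Bock-Aitkin EM) item calibration.

Supports GRM and GPCM with per-item M-steps, and RSM (one location per
item, shared category steps, discrimination fixed at 1) with a joint
M-step.  The latent trait is identified as standard normal; quadrature is
a fixed grid of equally spaced nodes with renormalized N(0,1) weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import (
    PROB_FLOOR,
    ItemBank,
    ItemParameters,
    ResponseMatrix,
    ThetaGrid,
    category_probs,
)

__all__ = ["EMConfig", "FitIndices", "CalibrationResult", "fit_model", "compare_models", "n_free_params"]

_LOG_A_BOUNDS = (np.log(0.05), np.log(15.0))
_B_BOUNDS = (-12.0, 12.0)
_LOG_GAP_BOUNDS = (np.log(1e-3), np.log(12.0))


@dataclass
class EMConfig:
    n_quad: int = 61
    quad_lo: float = -6.0
    quad_hi: float = 6.0
    tol: float = 1e-4
    max_cycles: int = 500
    collapse_unobserved: bool = False

    def grid(self) -> ThetaGrid:
        return ThetaGrid.default(self.n_quad, self.quad_lo, self.quad_hi)


@dataclass(frozen=True)
class FitIndices:
    """-2LL with its AIC/BIC penalizations."""

    neg2ll: float
    n_params: int
    n_persons: int

    @property
    def aic(self) -> float:
        return self.neg2ll + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return self.neg2ll + self.n_params * np.log(self.n_persons)


@dataclass
class CalibrationResult:
    bank: ItemBank
    fit: FitIndices
    converged: bool
    n_cycles: int
    loglik_trajectory: list[float] = field(default_factory=list)
    collapsed_categories: dict = field(default_factory=dict)


def n_free_params(model: str, n_categories: list[int]) -> int:
    """Free parameter count for a bank of items with the given category counts."""
    if model in ("GRM", "GPCM"):
        # one discrimination + (K-1) thresholds/steps per item
        return int(sum(n_categories))
    if model == "RSM":
        ks = set(n_categories)
        if len(ks) != 1:
            raise ValueError("RSM requires a common number of categories")
        k = ks.pop()
        # J locations + (K-1) shared steps - 1 identification constraint
        return len(n_categories) + k - 2
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

def _pack_grm(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.diff(b)
    return np.concatenate([[np.log(a), b[0]], np.log(np.maximum(gaps, 1e-3))])


def _unpack_grm(p: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(p[0]))
    b = p[1] + np.concatenate([[0.0], np.cumsum(np.exp(p[2:]))])
    return a, b


def _grm_prob_table(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    from scipy.special import expit

    pstar = expit(a * (nodes[:, None] - b[None, :]))
    padded = np.concatenate(
        [np.ones((len(nodes), 1)), pstar, np.zeros((len(nodes), 1))], axis=1
    )
    return -np.diff(padded, axis=1)


def _gpcm_prob_table(a: float, deltas: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    k = np.arange(len(deltas) + 1)
    cum = np.concatenate([[0.0], np.cumsum(deltas)])
    z = a * (k[None, :] * nodes[:, None] - cum[None, :])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def _item_prob_table(item: ItemParameters, nodes: np.ndarray) -> np.ndarray:
    if item.model == "GRM":
        return _grm_prob_table(item.a, np.asarray(item.b), nodes)
    if item.model == "GPCM":
        return _gpcm_prob_table(item.a, np.asarray(item.b), nodes)
    return _gpcm_prob_table(item.a, item.location + np.asarray(item.b), nodes)


# ---------------------------------------------------------------------------
# E-step
# ---------------------------------------------------------------------------

def _e_step(
    data: np.ndarray,
    mask: np.ndarray,
    tables: list[np.ndarray],
    grid: ThetaGrid,
) -> tuple[np.ndarray, float]:
    """Posterior weights (N, Q) and the marginal log-likelihood."""
    n, j = data.shape
    q = len(grid)
    logl = np.zeros((n, q))
    for jj in range(j):
        obs = mask[:, jj]
        logp = np.log(np.maximum(tables[jj], PROB_FLOOR))
        logl[obs] += logp[:, data[obs, jj]].T
    logl += np.log(grid.weights)[None, :]
    m = logl.max(axis=1, keepdims=True)
    post = np.exp(logl - m)
    norm = post.sum(axis=1, keepdims=True)
    marginal = float(np.sum(np.log(norm[:, 0])) + np.sum(m[:, 0]))
    return post / norm, marginal


def _expected_counts(
    data: np.ndarray, mask: np.ndarray, post: np.ndarray, j: int, n_cat: int
) -> np.ndarray:
    """r[q, k]: expected number of responses in category k at node q."""
    r = np.zeros((post.shape[1], n_cat))
    obs = mask[:, j]
    col = data[obs, j]
    pobs = post[obs]
    for k in range(n_cat):
        sel = col == k
        if sel.any():
            r[:, k] = pobs[sel].sum(axis=0)
    return r


# ---------------------------------------------------------------------------
# M-steps
# ---------------------------------------------------------------------------

def _m_step_item(
    model: str, p0: np.ndarray, r: np.ndarray, nodes: np.ndarray
) -> np.ndarray:
    n_cat = r.shape[1]
    if model == "GRM":
        bounds = [_LOG_A_BOUNDS, _B_BOUNDS] + [_LOG_GAP_BOUNDS] * (n_cat - 2)

        def nll(p):
            a, b = _unpack_grm(p)
            tab = _grm_prob_table(a, b, nodes)
            return -float(np.sum(r * np.log(np.maximum(tab, PROB_FLOOR))))

    else:  # GPCM
        bounds = [_LOG_A_BOUNDS] + [_B_BOUNDS] * (n_cat - 1)

        def nll(p):
            tab = _gpcm_prob_table(np.exp(p[0]), p[1:], nodes)
            return -float(np.sum(r * np.log(np.maximum(tab, PROB_FLOOR))))

    res = minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
    return res.x if res.fun <= nll(p0) else p0


def _m_step_rsm(
    locs: np.ndarray,
    steps: np.ndarray,
    rs: list[np.ndarray],
    nodes: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    j = len(locs)
    k1 = len(steps)

    def nll(p):
        c, s = p[:j], p[j:]
        total = 0.0
        for jj in range(j):
            tab = _gpcm_prob_table(1.0, c[jj] + s, nodes)
            total -= float(np.sum(rs[jj] * np.log(np.maximum(tab, PROB_FLOOR))))
        return total

    p0 = np.concatenate([locs, steps])
    res = minimize(nll, p0, method="L-BFGS-B")
    p = res.x if res.fun <= nll(p0) else p0
    c, s = p[:j].copy(), p[j:].copy()
    # remove the location/step translation indeterminacy
    shift = s.mean()
    return c + shift, s - shift


# ---------------------------------------------------------------------------
# starting values
# ---------------------------------------------------------------------------

def _start_item(model: str, col: np.ndarray, n_cat: int) -> np.ndarray:
    n = len(col)
    props = np.array(
        [np.clip(np.mean(col >= k), 1 / (n + 2), 1 - 1 / (n + 2)) for k in range(1, n_cat)]
    )
    b = -np.log(props / (1 - props))
    b = np.maximum.accumulate(b) + np.arange(n_cat - 1) * 1e-3
    if model == "GRM":
        return _pack_grm(1.0, b)
    return np.concatenate([[0.0], b])  # log a = 0, steps = thresholds


# ---------------------------------------------------------------------------
# main driver
# ---------------------------------------------------------------------------

def _collapse_categories(
    data: np.ndarray, mask: np.ndarray, n_cats: list[int], collapse: bool
) -> tuple[np.ndarray, list[int], dict]:
    out = data.copy()
    collapsed: dict[int, dict[int, int]] = {}
    new_cats = []
    for j, k in enumerate(n_cats):
        obs = np.unique(data[mask[:, j], j])
        if len(obs) < 2:
            raise ValueError(f"item column {j} has < 2 observed categories")
        if len(obs) == k and obs.max() == k - 1:
            new_cats.append(k)
            continue
        if not collapse:
            raise ValueError(
                f"item column {j} has unobserved categories; set "
                "collapse_unobserved=True to relabel"
            )
        remap = {int(c): i for i, c in enumerate(obs)}
        collapsed[j] = remap
        col = out[:, j]
        out[mask[:, j], j] = np.vectorize(remap.get)(data[mask[:, j], j])
        new_cats.append(len(obs))
    return out, new_cats, collapsed


def fit_model(
    responses: ResponseMatrix,
    model: str = "GRM",
    config: EMConfig | None = None,
    n_categories: list[int] | None = None,
    init_bank: ItemBank | None = None,
) -> CalibrationResult:
    """Calibrate all items of one model family by Bock-Aitkin EM.

    ``n_categories`` overrides the per-item category counts inferred from
    the observed maxima; ``init_bank`` warm-starts the parameters.
    """
    if model not in ("GRM", "GPCM", "RSM"):
        raise ValueError(f"unknown model {model!r}")
    cfg = config or EMConfig()
    grid = cfg.grid()
    nodes = grid.nodes
    data, mask = responses.data, responses.mask
    n, j = data.shape
    if not mask.any(axis=1).all():
        raise ValueError("every person needs at least one observed response")

    inferred = [int(data[mask[:, jj], jj].max()) + 1 for jj in range(j)]
    n_cats = list(n_categories) if n_categories is not None else inferred
    data, n_cats, collapsed = _collapse_categories(data, mask, n_cats, cfg.collapse_unobserved)

    if model == "RSM":
        return _fit_rsm(responses, data, mask, n_cats, grid, cfg, collapsed)

    if init_bank is not None:
        params = []
        for it in init_bank:
            if model == "GRM":
                params.append(_pack_grm(it.a, np.asarray(it.b)))
            else:
                params.append(np.concatenate([[np.log(it.a)], it.b]))
    else:
        params = [
            _start_item(model, data[mask[:, jj], jj], n_cats[jj]) for jj in range(j)
        ]

    def tables_from(params):
        out = []
        for jj in range(j):
            if model == "GRM":
                a, b = _unpack_grm(params[jj])
                out.append(_grm_prob_table(a, b, nodes))
            else:
                out.append(_gpcm_prob_table(np.exp(params[jj][0]), params[jj][1:], nodes))
        return out

    trajectory: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, cfg.max_cycles + 1):
        post, marginal = _e_step(data, mask, tables_from(params), grid)
        trajectory.append(marginal)
        new_params = []
        for jj in range(j):
            r = _expected_counts(data, mask, post, jj, n_cats[jj])
            new_params.append(_m_step_item(model, params[jj], r, nodes))
        delta = max(
            float(np.max(np.abs(np.asarray(pn) - np.asarray(po))))
            for pn, po in zip(new_params, params)
        )
        params = new_params
        if delta < cfg.tol:
            converged = True
            break

    _, marginal = _e_step(data, mask, tables_from(params), grid)
    trajectory.append(marginal)
    if not converged:
        warnings.warn(f"EM did not converge in {cfg.max_cycles} cycles", stacklevel=2)

    items = []
    for jj in range(j):
        iid = responses.item_ids[jj]
        if model == "GRM":
            a, b = _unpack_grm(params[jj])
            items.append(ItemParameters(iid, "GRM", a, tuple(b)))
        else:
            items.append(
                ItemParameters(iid, "GPCM", float(np.exp(params[jj][0])), tuple(params[jj][1:]))
            )
    fit = FitIndices(-2.0 * marginal, n_free_params(model, n_cats), n)
    return CalibrationResult(
        ItemBank(items), fit, converged, cycle, trajectory, collapsed
    )


def _fit_rsm(
    responses: ResponseMatrix,
    data: np.ndarray,
    mask: np.ndarray,
    n_cats: list[int],
    grid: ThetaGrid,
    cfg: EMConfig,
    collapsed: dict,
) -> CalibrationResult:
    if len(set(n_cats)) != 1:
        raise ValueError("RSM requires all items to share one category count")
    n, j = data.shape
    k = n_cats[0]
    nodes = grid.nodes
    locs = np.array([-(data[mask[:, jj], jj].mean() - (k - 1) / 2) for jj in range(j)])
    steps = np.zeros(k - 1)

    trajectory: list[float] = []
    converged = False
    cycle = 0
    for cycle in range(1, cfg.max_cycles + 1):
        tables = [_gpcm_prob_table(1.0, locs[jj] + steps, nodes) for jj in range(j)]
        post, marginal = _e_step(data, mask, tables, grid)
        trajectory.append(marginal)
        rs = [_expected_counts(data, mask, post, jj, k) for jj in range(j)]
        new_locs, new_steps = _m_step_rsm(locs, steps, rs, nodes)
        delta = max(
            float(np.max(np.abs(new_locs - locs))),
            float(np.max(np.abs(new_steps - steps))),
        )
        locs, steps = new_locs, new_steps
        if delta < cfg.tol:
            converged = True
            break

    tables = [_gpcm_prob_table(1.0, locs[jj] + steps, nodes) for jj in range(j)]
    _, marginal = _e_step(data, mask, tables, grid)
    trajectory.append(marginal)
    if not converged:
        warnings.warn(f"EM did not converge in {cfg.max_cycles} cycles", stacklevel=2)

    items = [
        ItemParameters(responses.item_ids[jj], "RSM", 1.0, tuple(steps), float(locs[jj]))
        for jj in range(j)
    ]
    fit = FitIndices(-2.0 * marginal, n_free_params("RSM", n_cats), n)
    return CalibrationResult(ItemBank(items), fit, converged, cycle, trajectory, collapsed)


def compare_models(
    responses: ResponseMatrix,
    models: tuple[str, ...] = ("GRM", "GPCM", "RSM"),
    config: EMConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Fit each candidate model and rank by -2LL / AIC / BIC.

    Non-convergent candidates are excluded from the ranking with a warning.
    Returns the index table (sorted by AIC) and the per-model results.
    """
    results: dict[str, CalibrationResult] = {}
    rows = []
    for model in models:
        try:
            res = fit_model(responses, model=model, config=config)
        except ValueError as exc:
            warnings.warn(f"{model} skipped: {exc}", stacklevel=2)
            continue
        results[model] = res
        if not res.converged:
            warnings.warn(f"{model} did not converge; excluded from ranking", stacklevel=2)
            continue
        rows.append(
            {
                "model": model,
                "neg2ll": res.fit.neg2ll,
                "aic": res.fit.aic,
                "bic": res.fit.bic,
                "n_params": res.fit.n_params,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True) if rows else pd.DataFrame()
    return table, results
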