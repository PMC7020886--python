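"""Item-bank screening: the five-filter construction pipeline.

Filters, in pipeline order: unidimensionality (iterative one-factor
loading cut on the polychoric correlation matrix, plus variance-share and
eigenvalue-ratio checks), calibration, local independence (Yen's Q3),
discrimination, item fit (Orlando-Thissen S-X2 via the summed-score
recursion), and logistic-regression DIF with McFadden pseudo-R2 change
and iterative purification.  The bank is recalibrated after every removal
stage and each stage's survivors are a subset of the previous stage's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2 as chi2_dist
from scipy.stats import multivariate_normal, norm
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .calibration import CalibrationResult, EMConfig, fit_model
from .cat import batch_eap
from .models import (
    PROB_FLOOR,
    ItemBank,
    ResponseMatrix,
    ThetaGrid,
    category_probs,
)

__all__ = [
    "DimensionalityReport",
    "ItemFitResult",
    "DIFResult",
    "ScreeningConfig",
    "ScreeningReport",
    "polychoric_corr",
    "polychoric_matrix",
    "unidimensionality_filter",
    "q3_matrix",
    "discrimination_filter",
    "summed_score_distribution",
    "s_chi2_item_fit",
    "dif_scan",
    "dif_purify",
    "run_screening_pipeline",
]

_TAIL = 8.0  # thresholds clipped to +-8: CDF error < 1e-15


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

def _thresholds(x: np.ndarray) -> np.ndarray:
    """Inverse-normal thresholds from the marginal category proportions."""
    cats, counts = np.unique(x, return_counts=True)
    if len(cats) < 2:
        raise ValueError("degenerate (constant) ordinal vector")
    cum = np.cumsum(counts)[:-1] / len(x)
    return norm.ppf(cum)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    gx = np.clip(np.concatenate([[-_TAIL], tau_x, [_TAIL]]), -_TAIL, _TAIL)
    gy = np.clip(np.concatenate([[-_TAIL], tau_y, [_TAIL]]), -_TAIL, _TAIL)
    xx, yy = np.meshgrid(gx, gy, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
    cdf = np.clip(mvn.cdf(pts).reshape(xx.shape), 0.0, 1.0)
    return np.diff(np.diff(cdf, axis=0), axis=1)


def polychoric_corr(x, y) -> float:
    """Two-step polychoric correlation of two ordinal vectors.

    Thresholds come from the inverse-normal marginals; rho maximizes the
    bivariate-normal cell likelihood of the contingency table.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("vectors must align")
    tau_x, tau_y = _thresholds(x), _thresholds(y)
    cats_x, cats_y = np.unique(x), np.unique(y)
    table = np.zeros((len(cats_x), len(cats_y)))
    for i, cx in enumerate(cats_x):
        for jj, cy in enumerate(cats_y):
            table[i, jj] = np.sum((x == cx) & (y == cy))

    def nll(rho: float) -> float:
        p = np.maximum(_cell_probs(tau_x, tau_y, rho), PROB_FLOOR)
        return -float(np.sum(table * np.log(p)))

    res = minimize_scalar(nll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def polychoric_matrix(responses: ResponseMatrix, item_ids=None) -> pd.DataFrame:
    """Pairwise polychoric correlation matrix (pairwise-complete)."""
    ids = list(item_ids) if item_ids is not None else list(responses.item_ids)
    j = len(ids)
    mat = np.eye(j)
    cols = {}
    for iid in ids:
        cols[iid] = responses.column(iid)
    for p in range(j):
        xp, mp = cols[ids[p]]
        for q in range(p + 1, j):
            xq, mq = cols[ids[q]]
            both = mp & mq
            mat[p, q] = mat[q, p] = polychoric_corr(xp[both], xq[both])
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# unidimensionality
# ---------------------------------------------------------------------------

@dataclass
class DimensionalityReport:
    iterations: list  # (removed_item_ids, min_loading) per refit
    first_factor_variance_pct: float
    eigenvalue_ratio: float
    loadings: dict
    passed: bool


def _first_component_loadings(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh((corr + corr.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    v1 = vecs[:, order[0]]
    if v1.sum() < 0:
        v1 = -v1
    return v1 * np.sqrt(max(vals[0], 0.0)), vals


def unidimensionality_filter(
    responses: ResponseMatrix,
    loading_cutoff: float = 0.40,
    variance_pct_min: float = 20.0,
    eigen_ratio_min: float = 4.0,
    poly: pd.DataFrame | None = None,
) -> tuple[DimensionalityReport, list[str]]:
    """Iterative one-factor loading filter on the polychoric matrix.

    Items with first-component loadings below ``loading_cutoff`` are
    dropped and the loadings refit, until none fall below.  The final
    variance share of the first factor and first/second eigenvalue ratio
    are computed on the retained submatrix.
    """
    if responses.n_items < 3:
        raise ValueError("need at least 3 items")
    if poly is None:
        poly = polychoric_matrix(responses)
    retained = list(poly.index)
    iterations = []
    while True:
        corr = poly.loc[retained, retained].to_numpy()
        loadings, vals = _first_component_loadings(corr)
        min_loading = float(loadings.min())
        below = [iid for iid, ld in zip(retained, loadings) if ld < loading_cutoff]
        iterations.append((below, min_loading))
        if not below:
            break
        retained = [iid for iid in retained if iid not in below]
        if len(retained) < 3:
            raise RuntimeError(
                "unidimensionality filter removed nearly all items "
                f"(left {retained}); aborting"
            )
    pct = 100.0 * float(vals[0]) / len(retained)
    ratio = float(vals[0] / max(vals[1], 1e-12))
    final_loadings = dict(zip(retained, loadings))
    passed = (
        pct >= variance_pct_min
        and ratio >= eigen_ratio_min
        and all(ld >= loading_cutoff for ld in final_loadings.values())
    )
    report = DimensionalityReport(iterations, pct, ratio, final_loadings, passed)
    return report, retained


# ---------------------------------------------------------------------------
# local independence (Q3)
# ---------------------------------------------------------------------------

def q3_matrix(
    responses: ResponseMatrix, bank: ItemBank, grid: ThetaGrid | None = None
) -> pd.DataFrame:
    """Yen's Q3: pairwise correlations of score residuals at the EAP thetas.

    Residual is observed score minus the model-implied expected score at
    each person's EAP estimate; entries with fewer than 3 joint
    observations are NaN.
    """
    grid = grid or ThetaGrid.default()
    sub = responses.subset_items(bank.item_ids)
    eaps, _ = batch_eap(sub, bank, grid)
    resid = np.full((sub.n_persons, len(bank)), np.nan)
    for j, item in enumerate(bank):
        probs = category_probs(item, eaps)
        expected = probs @ np.arange(item.n_categories)
        obs = sub.mask[:, j]
        resid[obs, j] = sub.data[obs, j] - expected[obs]
    frame = pd.DataFrame(resid, columns=bank.item_ids)
    return frame.corr(min_periods=3)


def q3_flagged_pairs(q3: pd.DataFrame, cutoff: float = 0.36) -> list[tuple[str, str, float]]:
    pairs = []
    ids = list(q3.index)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            v = q3.iloc[i, j]
            if np.isfinite(v) and abs(v) > cutoff:
                pairs.append((ids[i], ids[j], float(v)))
    return sorted(pairs, key=lambda t: -abs(t[2]))


# ---------------------------------------------------------------------------
# discrimination
# ---------------------------------------------------------------------------

def discrimination_filter(bank: ItemBank, cutoff: float = 0.7) -> tuple[list[str], list[str]]:
    """Split item ids into (retained, removed) by the discrimination cut."""
    retained = [it.item_id for it in bank if it.a >= cutoff]
    removed = [it.item_id for it in bank if it.a < cutoff]
    return retained, removed


# ---------------------------------------------------------------------------
# item fit (S-X2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ItemFitResult:
    item_id: str
    s_chi2: float
    df: int
    p_value: float


def summed_score_distribution(items, nodes: np.ndarray) -> np.ndarray:
    """Distribution of the summed score at each node, shape (Q, S+1).

    Generalized Lord-Wingersky recursion; at every node the returned
    probabilities sum to 1.
    """
    dist = np.ones((len(nodes), 1))
    for item in items:
        probs = category_probs(item, nodes)
        k = probs.shape[1]
        s_old = dist.shape[1]
        new = np.zeros((len(nodes), s_old + k - 1))
        for c in range(k):
            new[:, c : c + s_old] += probs[:, c][:, None] * dist
        dist = new
    return dist


def _collapse_cells(obs: np.ndarray, exp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge category cells until every expected count >= 1.

    Collapsing proceeds from the extreme categories inward; any remaining
    small interior cell merges with its smaller neighbor.
    """
    o = list(obs)
    e = list(exp)
    while len(e) > 1 and (e[0] < 1.0 or e[-1] < 1.0):
        if e[0] < 1.0:
            o[1] += o[0]
            e[1] += e[0]
            del o[0], e[0]
        elif e[-1] < 1.0:
            o[-2] += o[-1]
            e[-2] += e[-1]
            del o[-1], e[-1]
    while len(e) > 1 and min(e) < 1.0:
        i = int(np.argmin(e))
        j = i - 1 if (i > 0 and (i == len(e) - 1 or e[i - 1] <= e[i + 1])) else i + 1
        lo, hi = min(i, j), max(i, j)
        o[lo] += o[hi]
        e[lo] += e[hi]
        del o[hi], e[hi]
    return np.array(o), np.array(e)


def s_chi2_item_fit(
    responses: ResponseMatrix,
    bank: ItemBank,
    grid: ThetaGrid | None = None,
) -> list[ItemFitResult]:
    """Orlando-Thissen S-X2 for every item of a calibrated bank.

    Persons with incomplete responses on the bank's items are dropped.
    Expected category frequencies conditional on total-score groups come
    from the summed-score recursion integrated over the prior.
    """
    grid = grid or ThetaGrid.default()
    sub = responses.subset_items(bank.item_ids)
    complete = sub.mask.all(axis=1)
    if not complete.all():
        warnings.warn(
            f"S-X2 drops {int((~complete).sum())} incomplete persons", stacklevel=2
        )
    data = sub.data[complete]
    if len(data) == 0:
        raise ValueError("no complete response patterns for S-X2")
    totals = data.sum(axis=1)
    w = grid.weights
    results = []
    for j, item in enumerate(bank):
        rest_items = [it for i, it in enumerate(bank) if i != j]
        s_rest = summed_score_distribution(rest_items, grid.nodes)
        probs_j = category_probs(item, grid.nodes)
        k = item.n_categories
        s_max = s_rest.shape[1] - 1 + k - 1
        # joint[k, s] = integral P_jk(t) * S_rest(s - k | t) dPrior
        joint = np.zeros((k, s_max + 1))
        for c in range(k):
            joint[c, c : c + s_rest.shape[1]] = w @ (probs_j[:, c][:, None] * s_rest)
        denom = joint.sum(axis=0)

        chi2 = 0.0
        df = 0
        rest_totals = totals - data[:, j]
        for s in range(s_max + 1):
            in_group = totals == s
            n_s = int(in_group.sum())
            if n_s == 0 or denom[s] <= 0:
                continue
            lo = max(0, s - (s_rest.shape[1] - 1))
            hi = min(k - 1, s)
            if hi <= lo:
                continue
            cats = np.arange(lo, hi + 1)
            exp_p = joint[cats, s] / denom[s]
            exp_counts = n_s * exp_p
            obs_counts = np.array(
                [np.sum(in_group & (data[:, j] == c)) for c in cats], dtype=float
            )
            o, e = _collapse_cells(obs_counts, exp_counts)
            if len(e) < 2:
                continue
            e = np.maximum(e, PROB_FLOOR)
            chi2 += float(np.sum((o - e) ** 2 / e))
            df += len(e) - 1
        df -= item.n_categories  # a + (K-1) thresholds
        if df < 1:
            warnings.warn(
                f"S-X2 skipped item {item.item_id}: nonpositive df", stacklevel=2
            )
            continue
        results.append(
            ItemFitResult(item.item_id, chi2, df, float(chi2_dist.sf(chi2, df)))
        )
    return results


# ---------------------------------------------------------------------------
# differential item functioning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DIFResult:
    item_id: str
    pseudo_r2_change: float
    flagged: bool
    r2_m1: float = np.nan
    r2_m2: float = np.nan
    r2_m3: float = np.nan
    estimable: bool = True


def _null_loglik(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(np.sum(counts * np.log(p)))


def _ordinal_llf(y: np.ndarray, exog: np.ndarray, start: np.ndarray | None = None):
    model = OrderedModel(y, exog, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(method="bfgs", disp=0, start_params=start, maxiter=200)
    if not np.isfinite(res.llf):
        raise ValueError("non-finite likelihood")
    return res


def dif_scan(
    responses: ResponseMatrix,
    group: np.ndarray,
    theta: np.ndarray,
    threshold: float = 0.02,
    min_group_n: int = 50,
) -> list[DIFResult]:
    """Logistic-regression DIF via McFadden pseudo-R2 change.

    For each item three proportional-odds models of the ordinal response
    are fit -- M1: theta; M2: theta + group; M3: theta + group +
    theta x group -- and the item is flagged when R2(M3) - R2(M1) exceeds
    ``threshold``.  Items with inestimable fits are treated as not-DIF
    with a warning.
    """
    g = np.asarray(group, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n_focal = int(np.sum(g == 1))
    n_ref = int(np.sum(g == 0))
    if min(n_focal, n_ref) < min_group_n:
        raise ValueError(
            f"both groups need >= {min_group_n} persons (got {n_ref}/{n_focal})"
        )
    results = []
    for iid in responses.item_ids:
        x, obs = responses.column(iid)
        y = x[obs]
        th, gg = theta[obs], g[obs]
        ll0 = _null_loglik(y)
        try:
            m1 = _ordinal_llf(y, th[:, None])
            k_thr = len(m1.params) - 1
            s2 = np.concatenate([[m1.params[0], 0.0], m1.params[1:]])
            m2 = _ordinal_llf(y, np.column_stack([th, gg]), start=s2)
            s3 = np.concatenate([[m2.params[0], m2.params[1], 0.0], m2.params[2:]])
            m3 = _ordinal_llf(y, np.column_stack([th, gg, th * gg]), start=s3)
        except Exception as exc:  # separation / optimizer failure
            warnings.warn(f"DIF fit inestimable for {iid}: {exc}", stacklevel=2)
            results.append(DIFResult(iid, 0.0, False, estimable=False))
            continue
        r2 = [1.0 - m.llf / ll0 for m in (m1, m2, m3)]
        change = max(r2[2] - r2[0], 0.0)
        results.append(
            DIFResult(iid, change, change > threshold, r2[0], r2[1], r2[2])
        )
    return results


def dif_purify(
    responses: ResponseMatrix,
    group: np.ndarray,
    bank: ItemBank,
    grid: ThetaGrid | None = None,
    threshold: float = 0.02,
    min_group_n: int = 50,
    max_iter: int = 20,
) -> tuple[list[DIFResult], list[str]]:
    """Iterative DIF purification.

    Theta is re-estimated (EAP, fixed item parameters) from the currently
    retained items each round; the worst flagged item is removed until no
    item is flagged.
    """
    grid = grid or ThetaGrid.default()
    retained = list(bank.item_ids)
    removed: list[str] = []
    results: list[DIFResult] = []
    for _ in range(max_iter):
        sub_bank = bank.subset(retained)
        sub_resp = responses.subset_items(retained)
        theta, _ = batch_eap(sub_resp, sub_bank, grid)
        results = dif_scan(sub_resp, group, theta, threshold, min_group_n)
        flagged = [r for r in results if r.flagged]
        if not flagged:
            break
        worst = max(flagged, key=lambda r: r.pseudo_r2_change)
        removed.append(worst.item_id)
        retained.remove(worst.item_id)
        if not retained:
            raise RuntimeError("DIF purification removed every item")
    return results, removed


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class ScreeningConfig:
    loading_cutoff: float = 0.40
    variance_pct_min: float = 20.0
    eigen_ratio_min: float = 4.0
    q3_cutoff: float = 0.36
    a_cutoff: float = 0.7
    itemfit_alpha: float = 0.01
    dif_threshold: float = 0.02
    min_group_n: int = 50
    model: str = "GRM"
    em: EMConfig = field(default_factory=EMConfig)


@dataclass
class StageResult:
    name: str
    retained: list[str]
    removed: dict  # item_id -> reason


@dataclass
class ScreeningReport:
    stages: list[StageResult]
    dimensionality: DimensionalityReport | None = None
    q3_summary: pd.DataFrame | None = None
    discrimination: pd.DataFrame | None = None
    item_fit: list[ItemFitResult] = field(default_factory=list)
    dif: list[DIFResult] = field(default_factory=list)
    calibration: CalibrationResult | None = None

    @property
    def surviving(self) -> list[str]:
        return self.stages[-1].retained

    def removal_stage(self, item_id: str) -> str | None:
        """Name of the stage at which an item was removed, if any."""
        for stage in self.stages:
            if item_id in stage.removed:
                return stage.name
        return None

    def audit_frame(self) -> pd.DataFrame:
        rows = []
        for stage in self.stages:
            for iid, reason in stage.removed.items():
                rows.append({"item_id": iid, "stage": stage.name, "reason": reason})
        return pd.DataFrame(rows, columns=["item_id", "stage", "reason"])


def _recalibrate(
    responses: ResponseMatrix,
    retained: list[str],
    cfg: ScreeningConfig,
    prev: CalibrationResult | None,
) -> CalibrationResult:
    sub = responses.subset_items(retained)
    init = prev.bank.subset(retained) if prev is not None else None
    if init is not None and len(init) != len(retained):
        init = None
    return fit_model(sub, model=cfg.model, config=cfg.em, init_bank=init)


def run_screening_pipeline(
    responses: ResponseMatrix,
    group: np.ndarray | None = None,
    config: ScreeningConfig | None = None,
) -> ScreeningReport:
    """Run all screening stages in order, recalibrating after each removal.

    Order: unidimensionality -> calibration -> local independence (Q3) ->
    discrimination -> item fit (S-X2) -> DIF (skipped when no group labels
    are supplied).  Aborts if any stage empties the bank.
    """
    cfg = config or ScreeningConfig()
    grid = cfg.em.grid()
    report = ScreeningReport(stages=[])

    # stage 1: unidimensionality
    dim_report, retained = unidimensionality_filter(
        responses, cfg.loading_cutoff, cfg.variance_pct_min, cfg.eigen_ratio_min
    )
    removed = {
        iid: f"loading < {cfg.loading_cutoff}"
        for iteration in dim_report.iterations
        for iid in iteration[0]
    }
    report.dimensionality = dim_report
    report.stages.append(StageResult("unidimensionality", list(retained), removed))

    # stage 2: calibration
    calib = _recalibrate(responses, retained, cfg, None)
    report.stages.append(StageResult("calibration", list(retained), {}))

    # stage 3: local independence
    q3 = q3_matrix(responses.subset_items(retained), calib.bank, grid)
    pairs = q3_flagged_pairs(q3, cfg.q3_cutoff)
    removed = {}
    alive = set(retained)
    for i1, i2, v in pairs:
        if i1 in alive and i2 in alive:
            drop = min((i1, i2), key=lambda iid: calib.bank.by_id(iid).a)
            alive.discard(drop)
            removed[drop] = f"|Q3|={abs(v):.3f} > {cfg.q3_cutoff} (pair {i1},{i2})"
    retained = [iid for iid in retained if iid in alive]
    if not retained:
        raise RuntimeError("local-independence stage removed every item")
    report.q3_summary = q3
    report.stages.append(StageResult("local_independence", list(retained), removed))
    if removed:
        calib = _recalibrate(responses, retained, cfg, calib)

    # stage 4: discrimination
    keep, drop = discrimination_filter(calib.bank, cfg.a_cutoff)
    removed = {iid: f"a={calib.bank.by_id(iid).a:.3f} < {cfg.a_cutoff}" for iid in drop}
    retained = [iid for iid in retained if iid in set(keep)]
    if not retained:
        raise RuntimeError("discrimination stage removed every item")
    report.discrimination = pd.DataFrame(
        {"item_id": calib.bank.item_ids, "a": [it.a for it in calib.bank]}
    )
    report.stages.append(StageResult("discrimination", list(retained), removed))
    if removed:
        calib = _recalibrate(responses, retained, cfg, calib)

    # stage 5: item fit
    fits = s_chi2_item_fit(responses.subset_items(retained), calib.bank, grid)
    removed = {
        r.item_id: f"S-X2 p={r.p_value:.4f} < {cfg.itemfit_alpha}"
        for r in fits
        if r.p_value < cfg.itemfit_alpha
    }
    retained = [iid for iid in retained if iid not in removed]
    if not retained:
        raise RuntimeError("item-fit stage removed every item")
    report.item_fit = fits
    report.stages.append(StageResult("item_fit", list(retained), removed))
    if removed:
        calib = _recalibrate(responses, retained, cfg, calib)

    # stage 6: DIF
    if group is not None:
        dif_results, dif_removed = dif_purify(
            responses.subset_items(retained),
            group,
            calib.bank,
            grid,
            cfg.dif_threshold,
            cfg.min_group_n,
        )
        removed = {iid: f"DIF pseudo-R2 change > {cfg.dif_threshold}" for iid in dif_removed}
        retained = [iid for iid in retained if iid not in removed]
        report.dif = dif_results
        report.stages.append(StageResult("dif", list(retained), removed))
        if removed:
            calib = _recalibrate(responses, retained, cfg, calib)

    report.calibration = calib
    return report
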