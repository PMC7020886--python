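"""Polytomous IRT response models.

Probability, Fisher-information, and likelihood primitives for the three
models used throughout the toolkit:

* **GRM** -- graded response model (ordered boundary logistics),
* **GPCM** -- generalized partial credit model (adjacent-category logits),
* **RSM** -- rating scale model (GPCM with one location per item and a
  category-step vector shared across items).

All functions work in the logistic metric with scaling constant ``D = 1``.
``theta`` may be a scalar or a 1-D array; category-probability functions
return a ``(K,)`` vector for scalar input and a ``(T, K)`` matrix otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "PROB_FLOOR",
    "ItemParameters",
    "ItemBank",
    "ThetaGrid",
    "ResponseMatrix",
    "category_probs",
    "grm_category_probs",
    "gpcm_category_probs",
    "rsm_category_probs",
    "item_information",
    "bank_information",
    "pattern_loglik",
]

#: floor applied to probabilities before logs/divisions (never to the
#: probabilities themselves, which always sum to one).
PROB_FLOOR = 1e-10

_MODELS = ("GRM", "GPCM", "RSM")


@dataclass(frozen=True)
class ItemParameters:
    """Parameters of one polytomous item.

    Parameters
    ----------
    item_id
        Opaque label, unique within a bank.
    model
        One of ``"GRM"``, ``"GPCM"``, ``"RSM"``.
    a
        Discrimination, strictly positive.  Fixed at 1 for RSM items.
    b
        For GRM: strictly increasing thresholds ``b_1 < ... < b_{K-1}``.
        For GPCM: category step parameters (unordered allowed).
        For RSM: the *shared* category steps; the item's own position is
        carried by `location`.
    location
        RSM item location; ``None`` for GRM/GPCM.
    """

    item_id: str
    model: str
    a: float
    b: tuple[float, ...]
    location: float | None = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        object.__setattr__(self, "a", float(self.a))
        if not self.a > 0:
            raise ValueError(f"discrimination must be > 0, got {self.a}")
        if len(self.b) < 1:
            raise ValueError("need at least one threshold/step (K >= 2)")
        if self.model == "GRM":
            diffs = np.diff(self.b)
            if not np.all(diffs > 0):
                raise ValueError(
                    f"GRM thresholds must be strictly increasing, got {self.b}"
                )
        if self.model == "RSM" and self.location is None:
            raise ValueError("RSM item requires a location")

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


class ItemBank:
    """Ordered collection of :class:`ItemParameters` with unique ids."""

    def __init__(self, items: Iterable[ItemParameters], metadata: dict | None = None):
        self.items: list[ItemParameters] = list(items)
        self.metadata: dict = dict(metadata or {})
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        models = {it.model for it in self.items}
        if len(models) > 1:
            raise ValueError(f"bank mixes model families: {sorted(models)}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, i: int) -> ItemParameters:
        return self.items[i]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def model(self) -> str:
        return self.items[0].model

    def by_id(self, item_id: str) -> ItemParameters:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(item_id)

    def subset(self, item_ids: Sequence[str]) -> "ItemBank":
        keep = set(item_ids)
        return ItemBank([it for it in self.items if it.item_id in keep], self.metadata)


@dataclass(frozen=True)
class ThetaGrid:
    """Fixed quadrature grid with (normalized) standard-normal prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", np.asarray(self.nodes, dtype=float))
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        object.__setattr__(self, "weights", w / w.sum())

    @classmethod
    def default(cls, n_nodes: int = 61, lo: float = -6.0, hi: float = 6.0) -> "ThetaGrid":
        nodes = np.linspace(lo, hi, n_nodes)
        return cls(nodes, norm.pdf(nodes))

    def __len__(self) -> int:
        return len(self.nodes)


class ResponseMatrix:
    """Persons x items ordinal responses with a missing-data mask.

    Responses are stored as an ``(N, J)`` int array; ``mask[i, j]`` is True
    where a response was observed.  Categories are 0-based.
    """

    def __init__(
        self,
        data: np.ndarray,
        item_ids: Sequence[str] | None = None,
        person_ids: Sequence | None = None,
        mask: np.ndarray | None = None,
    ):
        arr = np.asarray(data)
        if arr.ndim != 2:
            raise ValueError("response matrix must be 2-D")
        if mask is None:
            if arr.dtype.kind == "f":
                mask = ~np.isnan(arr)
                arr = np.where(mask, arr, 0)
            else:
                mask = arr >= 0
        self.mask = np.asarray(mask, dtype=bool)
        self.data = np.where(self.mask, arr, 0).astype(np.int64)
        if np.any(self.data[self.mask] < 0):
            raise ValueError("observed categories must be >= 0")
        n, j = self.data.shape
        self.item_ids = list(item_ids) if item_ids is not None else [f"item{k+1}" for k in range(j)]
        if len(self.item_ids) != j:
            raise ValueError("item_ids length mismatch")
        self.person_ids = list(person_ids) if person_ids is not None else list(range(n))

    @property
    def n_persons(self) -> int:
        return self.data.shape[0]

    @property
    def n_items(self) -> int:
        return self.data.shape[1]

    def column(self, item_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (values, observed-mask) for one item."""
        j = self.item_ids.index(item_id)
        return self.data[:, j], self.mask[:, j]

    def subset_items(self, item_ids: Sequence[str]) -> "ResponseMatrix":
        idx = [self.item_ids.index(i) for i in item_ids]
        return ResponseMatrix(
            np.where(self.mask[:, idx], self.data[:, idx], -1),
            item_ids=list(item_ids),
            person_ids=self.person_ids,
        )


# ---------------------------------------------------------------------------
# category probabilities
# ---------------------------------------------------------------------------

def _theta_1d(theta) -> tuple[np.ndarray, bool]:
    t = np.atleast_1d(np.asarray(theta, dtype=float))
    return t, np.ndim(theta) == 0


def grm_boundary_probs(item: ItemParameters, theta) -> np.ndarray:
    """Boundary curves ``P*_k(theta) = logistic(a (theta - b_k))``, k=1..K-1."""
    t, _ = _theta_1d(theta)
    b = np.asarray(item.b)
    return expit(item.a * (t[:, None] - b[None, :]))


def grm_category_probs(item: ItemParameters, theta) -> np.ndarray:
    """GRM category probabilities: differences of adjacent boundary curves."""
    if item.model != "GRM":
        raise ValueError(f"item {item.item_id} is not a GRM item")
    t, scalar = _theta_1d(theta)
    pstar = grm_boundary_probs(item, t)
    padded = np.concatenate(
        [np.ones((len(t), 1)), pstar, np.zeros((len(t), 1))], axis=1
    )
    probs = -np.diff(padded, axis=1)
    return probs[0] if scalar else probs


def _gpcm_probs_from_deltas(a: float, deltas: np.ndarray, t: np.ndarray) -> np.ndarray:
    # log-numerator of category k is sum_{h<=k} a (theta - delta_h)
    k = np.arange(len(deltas) + 1)
    cum = np.concatenate([[0.0], np.cumsum(deltas)])
    z = a * (k[None, :] * t[:, None] - cum[None, :])
    z -= z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def gpcm_category_probs(item: ItemParameters, theta) -> np.ndarray:
    """GPCM category probabilities (adjacent-category logits)."""
    if item.model != "GPCM":
        raise ValueError(f"item {item.item_id} is not a GPCM item")
    t, scalar = _theta_1d(theta)
    probs = _gpcm_probs_from_deltas(item.a, np.asarray(item.b), t)
    return probs[0] if scalar else probs


def rsm_category_probs(item: ItemParameters, theta) -> np.ndarray:
    """RSM category probabilities: GPCM with steps ``location + shared steps``."""
    if item.model != "RSM":
        raise ValueError(f"item {item.item_id} is not an RSM item")
    t, scalar = _theta_1d(theta)
    deltas = item.location + np.asarray(item.b)
    probs = _gpcm_probs_from_deltas(item.a, deltas, t)
    return probs[0] if scalar else probs


_PROB_FUNCS = {
    "GRM": grm_category_probs,
    "GPCM": gpcm_category_probs,
    "RSM": rsm_category_probs,
}


def category_probs(item: ItemParameters, theta) -> np.ndarray:
    """Dispatch to the item's model family."""
    return _PROB_FUNCS[item.model](item, theta)


# ---------------------------------------------------------------------------
# information
# ---------------------------------------------------------------------------

def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Fisher information ``I(theta) = sum_k P'_k(theta)^2 / P_k(theta)``.

    GRM uses the analytic boundary-derivative form; GPCM/RSM use the
    equivalent ``a^2 * Var(category | theta)`` identity.
    """
    t, scalar = _theta_1d(theta)
    if item.model == "GRM":
        pstar = grm_boundary_probs(item, t)
        padded = np.concatenate(
            [np.ones((len(t), 1)), pstar, np.zeros((len(t), 1))], axis=1
        )
        probs = -np.diff(padded, axis=1)
        dstar = item.a * padded * (1.0 - padded)  # derivative of each boundary
        dprobs = -np.diff(dstar, axis=1)
        info = (dprobs**2 / np.maximum(probs, PROB_FLOOR)).sum(axis=1)
    else:
        probs = category_probs(item, t)
        k = np.arange(probs.shape[1])
        mean = probs @ k
        var = probs @ (k**2) - mean**2
        info = item.a**2 * var
    return float(info[0]) if scalar else info


def bank_information(bank: ItemBank, theta) -> np.ndarray:
    """Per-item information, shape ``(n_items,)`` for scalar theta."""
    return np.array([item_information(it, theta) for it in bank])


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def pattern_loglik(items: Sequence[ItemParameters], responses, theta) -> float:
    """Log-likelihood of one response pattern at a scalar theta.

    ``responses`` is a sequence aligned with ``items``; missing entries are
    ``None``, ``NaN`` or negative integers and contribute zero.
    """
    total = 0.0
    for item, resp in zip(items, responses, strict=True):
        if resp is None:
            continue
        r = float(resp)
        if np.isnan(r) or r < 0:
            continue
        k = int(r)
        if k != r or k >= item.n_categories:
            raise ValueError(
                f"response {resp!r} out of range for item {item.item_id} "
                f"with {item.n_categories} categories"
            )
        p = category_probs(item, float(theta))[k]
        total += float(np.log(max(p, PROB_FLOOR)))
    return total
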