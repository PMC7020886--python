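"""Synthetic cohorts, banks, criterion scores, and planted item defects.

Everything the toolkit consumes can be generated here: latent traits,
GRM response matrices for any bank, a noisy external criterion on a 0-56
summed-score scale with a high/low dichotomization, and response matrices
with planted defective items for exercising the screening filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import ItemBank, ItemParameters, ResponseMatrix, category_probs

__all__ = [
    "CohortSpec",
    "DefectSpec",
    "reference_bank",
    "simulate_responses",
    "simulate_thetas",
    "synth_bank",
    "plant_defects",
    "simulate_criterion",
]

# 20 calibrated GRM items used as a reference fixture: (a, thresholds).
# Items r1..r10 have 4 response categories, r84..r93 have 5.
_REFERENCE_ROWS: list[tuple[str, float, tuple[float, ...]]] = [
    ("r1", 0.942, (-0.609, 2.211, 4.352)),
    ("r2", 0.902, (-1.761, 0.812, 3.387)),
    ("r3", 1.120, (-0.388, 1.833, 3.388)),
    ("r4", 0.868, (-0.500, 2.318, 4.240)),
    ("r5", 0.851, (-0.421, 2.156, 3.650)),
    ("r6", 0.995, (-1.154, 1.604, 4.030)),
    ("r7", 1.196, (0.226, 2.584, 3.986)),
    ("r8", 1.016, (-0.189, 2.112, 4.123)),
    ("r9", 1.013, (0.612, 3.268, 5.360)),
    ("r10", 1.509, (0.205, 1.928, 3.406)),
    ("r84", 1.048, (-0.612, 1.080, 3.083, 4.671)),
    ("r85", 0.899, (-2.130, -0.216, 1.692, 3.833)),
    ("r86", 1.186, (-0.978, 0.625, 1.978, 3.227)),
    ("r87", 1.024, (-1.086, 0.600, 2.045, 3.271)),
    ("r88", 1.156, (-1.269, 0.398, 1.868, 2.996)),
    ("r89", 1.275, (-0.796, 0.533, 1.880, 3.195)),
    ("r90", 1.513, (-0.276, 0.958, 1.931, 3.051)),
    ("r91", 1.170, (-0.445, 0.884, 2.177, 3.257)),
    ("r92", 1.197, (0.075, 1.578, 2.886, 4.019)),
    ("r93", 0.904, (-0.202, 1.561, 3.049, 4.020)),
]


def reference_bank() -> ItemBank:
    """The packaged 20-item calibrated GRM reference bank (bit-exact)."""
    items = [
        ItemParameters(item_id=iid, model="GRM", a=a, b=b)
        for iid, a, b in _REFERENCE_ROWS
    ]
    return ItemBank(items, metadata={"source": "reference-fixture"})


@dataclass
class CohortSpec:
    """Specification of a simulated respondent cohort."""

    n_persons: int
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    seed: int = 0
    criterion_noise_sd: float = 1.2
    high_cut: float = 28.0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if not self.theta_sd >= 0:
            raise ValueError("theta_sd must be >= 0")


@dataclass
class DefectSpec:
    """Planted item defects for screening-pipeline tests.

    Each field maps item ids to defect settings; the sets of affected
    items must be disjoint.
    """

    noise_items: tuple[str, ...] = ()
    low_a_items: dict = field(default_factory=dict)  # item_id -> a
    dif_items: dict = field(default_factory=dict)  # item_id -> (shift, focal_fraction)
    dependent_pairs: dict = field(default_factory=dict)  # (src, dst) -> copy_prob

    def affected(self) -> list[str]:
        ids = list(self.noise_items) + list(self.low_a_items) + list(self.dif_items)
        for src, dst in self.dependent_pairs:
            ids.append(dst)
        return ids

    def __post_init__(self) -> None:
        ids = self.affected()
        if len(set(ids)) != len(ids):
            raise ValueError("planted defect items must be disjoint")


def simulate_thetas(spec: CohortSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    return rng.normal(spec.theta_mean, spec.theta_sd, size=spec.n_persons)


def _sample_categories(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of a (N, K) probability matrix."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def simulate_responses(
    bank: ItemBank, spec: CohortSpec
) -> tuple[ResponseMatrix, np.ndarray]:
    """Draw thetas ~ Normal and responses from the bank's model, seeded."""
    rng = np.random.default_rng(spec.seed)
    thetas = rng.normal(spec.theta_mean, spec.theta_sd, size=spec.n_persons)
    data = np.empty((spec.n_persons, len(bank)), dtype=np.int64)
    for j, item in enumerate(bank):
        probs = category_probs(item, thetas)
        data[:, j] = _sample_categories(probs, rng)
    return ResponseMatrix(data, item_ids=bank.item_ids), thetas


def synth_bank(
    n_items: int,
    n_categories: int | Sequence[int] = 4,
    a_range: tuple[float, float] = (0.8, 2.8),
    b_range: tuple[float, float] = (-2.5, 4.0),
    seed: int = 0,
    prefix: str = "s",
) -> ItemBank:
    """Random GRM bank: a ~ U(a_range), thresholds sorted draws from U(b_range)."""
    if not a_range[0] > 0:
        raise ValueError("a_range must be positive")
    rng = np.random.default_rng(seed)
    ks = (
        [int(n_categories)] * n_items
        if np.ndim(n_categories) == 0
        else [int(k) for k in n_categories]
    )
    if len(ks) != n_items:
        raise ValueError("n_categories sequence length must equal n_items")
    items = []
    for j, k in enumerate(ks):
        a = rng.uniform(*a_range)
        b = np.sort(rng.uniform(*b_range, size=k - 1))
        # enforce strict ordering with a minimum gap
        b = b + np.arange(k - 1) * 1e-6
        items.append(ItemParameters(f"{prefix}{j+1}", "GRM", a, tuple(b)))
    return ItemBank(items, metadata={"source": "synth"})


def plant_defects(
    responses: ResponseMatrix,
    bank: ItemBank,
    spec: DefectSpec,
    thetas: np.ndarray,
    group: np.ndarray | None = None,
    seed: int = 0,
) -> ResponseMatrix:
    """Return a copy of ``responses`` with the specified defects injected.

    * noise item: responses drawn uniformly over the item's categories,
      independent of theta;
    * low-a item: responses regenerated from the item with discrimination
      replaced by the given value;
    * DIF item: for the focal group (labels from ``group``, or assigned by
      ``focal_fraction``), all thresholds shifted by ``+shift`` and the
      focal responses regenerated;
    * dependent pair ``(src, dst)``: with probability ``copy_prob`` the dst
      response is overwritten by the src response.
    """
    for iid in spec.affected():
        if iid not in responses.item_ids:
            raise ValueError(f"defect on unknown item {iid!r}")
    rng = np.random.default_rng(seed)
    data = responses.data.copy()
    n = responses.n_persons

    for iid in spec.noise_items:
        j = responses.item_ids.index(iid)
        k = bank.by_id(iid).n_categories
        data[:, j] = rng.integers(0, k, size=n)

    for iid, a_new in spec.low_a_items.items():
        j = responses.item_ids.index(iid)
        item = bank.by_id(iid)
        weak = ItemParameters(iid, item.model, a_new, item.b, item.location)
        data[:, j] = _sample_categories(category_probs(weak, thetas), rng)

    for iid, (shift, focal_fraction) in spec.dif_items.items():
        j = responses.item_ids.index(iid)
        item = bank.by_id(iid)
        if group is None:
            focal = rng.random(n) < focal_fraction
        else:
            focal = np.asarray(group, dtype=bool)
        shifted = ItemParameters(
            iid, item.model, item.a, tuple(np.asarray(item.b) + shift), item.location
        )
        probs = category_probs(shifted, thetas[focal])
        data[focal, j] = _sample_categories(probs, rng)

    for (src, dst), copy_prob in spec.dependent_pairs.items():
        js = responses.item_ids.index(src)
        jd = responses.item_ids.index(dst)
        copy = rng.random(n) < copy_prob
        data[copy, jd] = data[copy, js]

    return ResponseMatrix(
        np.where(responses.mask, data, -1),
        item_ids=responses.item_ids,
        person_ids=responses.person_ids,
    )


def simulate_criterion(
    true_thetas: np.ndarray, spec: CohortSpec, slope: float = 9.0
) -> tuple[np.ndarray, np.ndarray]:
    """Noisy external criterion on a 0-56 summed-score scale plus high label.

    ``criterion = 28 + slope * (theta + noise)`` clipped to [0, 56];
    ``label = criterion > high_cut`` (default cut 28).
    """
    if spec.criterion_noise_sd < 0:
        raise ValueError("criterion_noise_sd must be >= 0")
    rng = np.random.default_rng(spec.seed + 1_000_003)
    noise = rng.normal(0.0, spec.criterion_noise_sd, size=len(true_thetas))
    criterion = np.clip(28.0 + slope * (np.asarray(true_thetas) + noise), 0.0, 56.0)
    label = criterion > spec.high_cut
    return criterion, label
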