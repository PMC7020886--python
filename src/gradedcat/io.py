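"""CSV readers/writers for item banks, response matrices, and rule files."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cat import StoppingRule
from .models import ItemBank, ItemParameters, ResponseMatrix

__all__ = [
    "read_bank",
    "write_bank",
    "read_responses",
    "write_responses",
    "read_rules",
]


def write_bank(bank: ItemBank, path) -> None:
    """Bank CSV: item_id, model, n_categories, a, b1..bK (blank unused),
    location (RSM only)."""
    kmax = max(it.n_categories for it in bank) - 1
    rows = []
    for it in bank:
        row = {
            "item_id": it.item_id,
            "model": it.model,
            "n_categories": it.n_categories,
            "a": it.a,
        }
        for k in range(kmax):
            row[f"b{k+1}"] = it.b[k] if k < len(it.b) else ""
        row["location"] = it.location if it.location is not None else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_bank(path) -> ItemBank:
    df = pd.read_csv(path)
    items = []
    bcols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    for _, row in df.iterrows():
        b = [float(row[c]) for c in bcols if pd.notna(row[c]) and row[c] != ""]
        loc = None
        if "location" in df.columns and pd.notna(row.get("location")) and row.get("location") != "":
            loc = float(row["location"])
        items.append(
            ItemParameters(str(row["item_id"]), str(row["model"]), float(row["a"]), tuple(b), loc)
        )
    return ItemBank(items)


def write_responses(responses: ResponseMatrix, path) -> None:
    """Responses CSV: person_id column then one integer column per item;
    missing cells are left blank."""
    vals = responses.data.astype(float)
    vals[~responses.mask] = np.nan
    df = pd.DataFrame(vals, columns=responses.item_ids)
    df.insert(0, "person_id", responses.person_ids)
    df.to_csv(path, index=False, float_format="%.0f")


def read_responses(path, origin: int = 0) -> ResponseMatrix:
    """Read a response CSV.  ``origin=1`` shifts 1-based category codings
    down to the 0-based convention used everywhere in this package."""
    df = pd.read_csv(path)
    person_ids = None
    if "person_id" in df.columns:
        person_ids = df.pop("person_id").tolist()
    vals = df.to_numpy(dtype=float)
    mask = ~np.isnan(vals)
    vals = np.where(mask, vals - origin, np.nan)
    if np.any(vals[mask & ~np.isnan(vals)] < 0):
        raise ValueError("negative categories after origin shift")
    return ResponseMatrix(vals, item_ids=list(df.columns), person_ids=person_ids)


def read_rules(path) -> list[StoppingRule]:
    """Rules YAML: ``fixed_lengths: [...]``, ``se_rules: [{se, max_items}]``,
    ``include_none: true`` (the full-bank rule is added by the caller)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    rules = [StoppingRule(fixed_length=int(n)) for n in raw.get("fixed_lengths", [])]
    for entry in raw.get("se_rules", []):
        rules.append(
            StoppingRule(
                se_threshold=float(entry["se"]),
                max_items=int(entry.get("max_items", 13)),
            )
        )
    if not rules:
        raise ValueError(f"no stopping rules found in {Path(path)}")
    return rules
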