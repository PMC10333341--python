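"""Convert structured-interview PTSD item responses into subscale scores.

Four symptom subscales are scored by summing item responses on a 1-3
scale: re-experiencing (10 items, range 10-30), avoidance (14, 14-42),
hyperarousal (10, 10-30) and negative thoughts (8, 8-24). No items are
reverse-scored and no imputation is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class SubscaleSpec:
    name: str
    n_items: int
    item_min: int = 1
    item_max: int = 3

    @property
    def score_range(self) -> tuple[int, int]:
        return (self.n_items * self.item_min, self.n_items * self.item_max)

    @property
    def prefix(self) -> str:
        return _PREFIXES[self.name]

    @property
    def item_columns(self) -> list[str]:
        return [f"{self.prefix}{i:02d}" for i in range(1, self.n_items + 1)]


_PREFIXES = {
    "re_experiencing": "re",
    "avoidance": "av",
    "hyperarousal": "hy",
    "negative_thoughts": "nt",
}

SUBSCALES: dict[str, SubscaleSpec] = {
    "re_experiencing": SubscaleSpec("re_experiencing", 10),
    "avoidance": SubscaleSpec("avoidance", 14),
    "hyperarousal": SubscaleSpec("hyperarousal", 10),
    "negative_thoughts": SubscaleSpec("negative_thoughts", 8),
}


def score_subscale(items, spec: SubscaleSpec) -> int:
    """Sum item responses for one subscale, validating count and range."""
    items = list(items)
    if len(items) != spec.n_items:
        raise ScoringError(
            f"{spec.name}: expected {spec.n_items} items, got {len(items)}"
        )
    total = 0
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and v != v):
            raise ScoringError(f"{spec.name}: item {i + 1} is missing")
        if isinstance(v, float) and not v.is_integer():
            raise ScoringError(
                f"{spec.name}: item {i + 1} response {v!r} is not an integer"
            )
        v = int(v)
        if not spec.item_min <= v <= spec.item_max:
            raise ScoringError(
                f"{spec.name}: item {i + 1} response {v} outside "
                f"[{spec.item_min}, {spec.item_max}]"
            )
        total += v
    return total


def score_all(items_table: pd.DataFrame) -> pd.DataFrame:
    """Score every subject on all four subscales.

    ``items_table`` needs a ``subject_id`` column plus the item columns of
    the bundled manifest (``re01..re10, av01..av14, hy01..hy10,
    nt01..nt08``). Subjects whose rows fail validation are omitted from the
    output; their error messages are collected in
    ``result.attrs['scoring_errors']`` keyed by subject id.
    """
    if "subject_id" not in items_table.columns:
        raise ScoringError("items table needs a subject_id column")
    for spec in SUBSCALES.values():
        missing = [c for c in spec.item_columns
                   if c not in items_table.columns]
        if missing:
            raise ScoringError(
                f"items table is missing columns {missing} for {spec.name}"
            )
    rows = []
    errors: dict[str, str] = {}
    for _, row in items_table.iterrows():
        sid = row["subject_id"]
        try:
            scores = {
                name: score_subscale(row[spec.item_columns], spec)
                for name, spec in SUBSCALES.items()
            }
        except ScoringError as exc:
            errors[str(sid)] = str(exc)
            continue
        rows.append({"subject_id": sid, **scores})
    out = pd.DataFrame(rows,
                       columns=["subject_id", *SUBSCALES.keys()])
    out.attrs["scoring_errors"] = errors
    if errors:
        logger.warning("scoring failed for %d subject(s): %s",
                       len(errors), sorted(errors))
    if len(out):
        lo = out[list(SUBSCALES)].min().to_dict()
        hi = out[list(SUBSCALES)].max().to_dict()
        logger.info("subscale score ranges: min=%s max=%s", lo, hi)
    return out
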