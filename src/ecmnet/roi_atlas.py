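"""ROI parcellation registry: 111 regions (48+48 cortical, 7+7 subcortical, brainstem).

The bundled registry enumerates the standard cortico-subcortical atlas split
used to index every downstream table: 48 cortical regions per hemisphere,
7 subcortical regions per hemisphere (thalamus, caudate, putamen, pallidum,
hippocampus, amygdala, accumbens), and one midline brainstem region.
Indices are 0-based internally; user-facing reports print 1-based numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

HEMISPHERES = ("left", "right", "midline")
CATEGORIES = ("cortical", "subcortical", "brainstem")

#: required (category, hemisphere) -> count for a full registry
EXPECTED_COUNTS = {
    ("cortical", "left"): 48,
    ("cortical", "right"): 48,
    ("subcortical", "left"): 7,
    ("subcortical", "right"): 7,
    ("brainstem", "midline"): 1,
}
N_ROI = 111

_COLUMNS = ["index", "name", "hemisphere", "abbreviation", "category"]


class RegistryError(ValueError):
    """Raised when a registry file or lookup fails validation."""


@dataclass(frozen=True)
class ROIDef:
    """A single region-of-interest definition."""

    index: int
    name: str
    hemisphere: str
    abbreviation: str
    category: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise RegistryError(
                f"ROI {self.index} ({self.name!r}): unknown hemisphere "
                f"{self.hemisphere!r}, expected one of {HEMISPHERES}"
            )
        if self.category not in CATEGORIES:
            raise RegistryError(
                f"ROI {self.index} ({self.name!r}): unknown category "
                f"{self.category!r}, expected one of {CATEGORIES}"
            )

    @property
    def label(self) -> str:
        """Human-readable label, e.g. ``'right PHG'``."""
        return f"{self.hemisphere} {self.abbreviation}"


class ROIRegistry:
    """Ordered collection of :class:`ROIDef`.

    A *full* registry (``require_full=True``, the default for
    :func:`load_registry`) must contain exactly 111 regions with contiguous
    indices 0..110 and the 48/48/7/7/1 category split. Subsets produced by
    :func:`hub_subset` keep original indices and skip the count checks.
    """

    def __init__(self, rois: Iterable[ROIDef], *, require_full: bool = True):
        self.rois: tuple[ROIDef, ...] = tuple(rois)
        self._by_index = {r.index: r for r in self.rois}
        if len(self._by_index) != len(self.rois):
            dupes = sorted(
                i for i in self._by_index
                if sum(r.index == i for r in self.rois) > 1
            )
            raise RegistryError(f"duplicate ROI indices: {dupes}")
        if require_full:
            self._validate_full()

    def _validate_full(self) -> None:
        n = len(self.rois)
        if n != N_ROI:
            raise RegistryError(f"expected {N_ROI} regions, got {n}")
        indices = [r.index for r in self.rois]
        if indices != list(range(N_ROI)):
            raise RegistryError(
                "ROI indices must be contiguous 0..110 in file order"
            )
        counts: dict[tuple[str, str], int] = {}
        for r in self.rois:
            counts[(r.category, r.hemisphere)] = (
                counts.get((r.category, r.hemisphere), 0) + 1
            )
        if counts != EXPECTED_COUNTS:
            raise RegistryError(
                f"category/hemisphere counts {counts} do not match the "
                f"required split {EXPECTED_COUNTS}"
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self) -> Iterator[ROIDef]:
        return iter(self.rois)

    def __getitem__(self, index: int) -> ROIDef:
        try:
            return self._by_index[index]
        except KeyError:
            raise RegistryError(f"no ROI with index {index}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ROIRegistry):
            return NotImplemented
        return self.rois == other.rois

    # -- lookup -------------------------------------------------------------
    def lookup(self, key: str, hemisphere: str | None = None) -> ROIDef:
        """Find a ROI by abbreviation or full name, optionally by hemisphere.

        Matching is case-insensitive. Raises :class:`RegistryError` when the
        key is unknown or ambiguous without a hemisphere.
        """
        k = key.strip().lower()
        hits = [
            r for r in self.rois
            if (r.abbreviation.lower() == k or r.name.lower() == k)
            and (hemisphere is None or r.hemisphere == hemisphere)
        ]
        if not hits:
            where = f" in hemisphere {hemisphere!r}" if hemisphere else ""
            raise RegistryError(f"no ROI matching {key!r}{where}")
        if len(hits) > 1:
            raise RegistryError(
                f"ambiguous ROI key {key!r}: matches "
                + ", ".join(r.label for r in hits)
                + "; pass a hemisphere"
            )
        return hits[0]

    def resolve(self, identifier) -> ROIDef:
        """Resolve an int index, ``(key, hemisphere)`` pair, or string.

        Strings may be a bare key (``"BST"``) when unique, or
        ``"hemisphere:key"`` (``"right:PHG"``).
        """
        if isinstance(identifier, int):
            return self[identifier]
        if isinstance(identifier, tuple) and len(identifier) == 2:
            return self.lookup(identifier[0], identifier[1])
        if isinstance(identifier, str):
            if ":" in identifier:
                hemi, key = identifier.split(":", 1)
                return self.lookup(key, hemi.strip().lower())
            return self.lookup(identifier)
        raise RegistryError(f"cannot resolve ROI identifier {identifier!r}")

    # -- serialization ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.index, r.name, r.hemisphere, r.abbreviation, r.category)
             for r in self.rois],
            columns=_COLUMNS,
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _registry_from_frame(df: pd.DataFrame, *, require_full: bool,
                         source: str) -> ROIRegistry:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError(f"{source}: missing columns {missing}")
    rois = []
    for pos, row in enumerate(df[_COLUMNS].itertuples(index=False, name=None)):
        try:
            idx, name, hemi, abbr, cat = row
            rois.append(
                ROIDef(
                    index=int(idx),
                    name=str(name),
                    hemisphere=str(hemi),
                    abbreviation=str(abbr),
                    category=str(cat),
                )
            )
        except (TypeError, ValueError, RegistryError) as exc:
            raise RegistryError(f"{source}: row {pos + 2}: {exc}") from exc
    return ROIRegistry(rois, require_full=require_full)


def load_registry(path: str | Path | None = None) -> ROIRegistry:
    """Load and validate a registry TSV; ``None`` loads the bundled default."""
    if path is None:
        with resources.files("ecmnet.data").joinpath("registry.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
        source = "bundled registry"
    else:
        df = pd.read_csv(path, sep="\t")
        source = str(path)
    return _registry_from_frame(df, require_full=True, source=source)


def default_registry() -> ROIRegistry:
    """The bundled 111-region registry."""
    return load_registry(None)


def hub_subset(registry: ROIRegistry, names: Sequence) -> ROIRegistry:
    """Subset a registry by a list of ROI identifiers, preserving indices.

    Duplicate identifiers collapse to a single entry (a warning is logged).
    """
    seen: dict[int, ROIDef] = {}
    for ident in names:
        roi = registry.resolve(ident)
        if roi.index in seen:
            logger.warning("duplicate ROI identifier %r ignored", ident)
            continue
        seen[roi.index] = roi
    return ROIRegistry(seen.values(), require_full=False)
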