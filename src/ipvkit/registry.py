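"""Instrument registry: declares questionnaires, subscales and response scales.

The default registry describes the four flourishing instruments analysed
jointly in this package — the Mental Health Continuum-Short Form (MHC-SF,
14 items in three facets), the PERMA-Profiler (15 items in five facets,
excluding the happiness / health / negative-emotion / loneliness filler
items), the Flourishing Scale (FS, 8 items, unidimensional) and the
Wellbeing Conceptual Framework (WBCF, 10 items in the two-factor
positive-characteristics / positive-functioning solution) — 47 items and
11 sub-pools in total.

The registry validates response matrices (forced-response design: no
missing cells allowed), applies reverse-coding, builds subscale composite
scores, and computes Cronbach's alpha and score intercorrelations.
Sample statistics use the n-1 (unbiased) variance convention throughout.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResponseScale",
    "SubscaleSpec",
    "InstrumentSpec",
    "Registry",
    "SubscaleScores",
    "ReliabilityResult",
    "load_registry",
    "default_registry",
    "validate_responses",
    "score_subscales",
    "cronbach_alpha",
    "correlation_matrix",
    "reliability_table",
]

#: Instruments whose composites are averaged on the raw response scale.
#: WBCF mixes 4-, 5- and 11-point items, so its composites are built from
#: z-scored items instead.
_STANDARDIZE_BY_DEFAULT = frozenset({"WBCF"})

_KNOWN_INSTRUMENTS = ("MHC-SF", "PERMA", "FS", "WBCF")


@dataclass(frozen=True)
class ResponseScale:
    """Closed integer response range of a Likert item."""

    min_code: int
    max_code: int
    anchor_labels: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.min_code >= self.max_code:
            raise ValueError(
                f"invalid response scale [{self.min_code}, {self.max_code}]"
            )

    @property
    def n_categories(self) -> int:
        return self.max_code - self.min_code + 1

    def reverse(self, x):
        """Reverse-code a response: x -> max_code + min_code - x."""
        return self.max_code + self.min_code - x


@dataclass(frozen=True)
class SubscaleSpec:
    """One facet (sub-pool) of an instrument."""

    name: str
    item_ids: tuple[str, ...]
    scales: dict[str, ResponseScale]
    reverse_coded: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def scale_of(self, item_id: str) -> ResponseScale:
        return self.scales[item_id]


@dataclass(frozen=True)
class InstrumentSpec:
    name: str
    subscales: tuple[SubscaleSpec, ...]

    @property
    def n_items(self) -> int:
        return sum(s.n_items for s in self.subscales)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(i for s in self.subscales for i in s.item_ids)


class Registry:
    """An ordered collection of instruments with item lookup helpers."""

    def __init__(self, instruments: list[InstrumentSpec]):
        self.instruments = tuple(instruments)
        self._item_index: dict[str, tuple[str, str]] = {}
        for inst in self.instruments:
            for sub in inst.subscales:
                for iid in sub.item_ids:
                    if iid in self._item_index:
                        raise ValueError(f"duplicate item id {iid!r} in registry")
                    self._item_index[iid] = (inst.name, sub.name)

    @property
    def item_ids(self) -> list[str]:
        return list(self._item_index)

    @property
    def n_items(self) -> int:
        return len(self._item_index)

    @property
    def facet_ids(self) -> list[str]:
        return [s.name for inst in self.instruments for s in inst.subscales]

    @property
    def instrument_names(self) -> list[str]:
        return [inst.name for inst in self.instruments]

    def instrument_of(self, item_id: str) -> str:
        return self._item_index[item_id][0]

    def facet_of(self, item_id: str) -> str:
        return self._item_index[item_id][1]

    def subscale(self, facet: str) -> SubscaleSpec:
        for inst in self.instruments:
            for sub in inst.subscales:
                if sub.name == facet:
                    return sub
        raise KeyError(facet)

    def scale_of(self, item_id: str) -> ResponseScale:
        inst, facet = self._item_index[item_id]
        return self.subscale(facet).scale_of(item_id)

    def reverse_coded_items(self) -> set[str]:
        out: set[str] = set()
        for inst in self.instruments:
            for sub in inst.subscales:
                out |= set(sub.reverse_coded)
        return out

    def items_by_facet(self) -> dict[str, list[str]]:
        return {
            s.name: list(s.item_ids)
            for inst in self.instruments
            for s in inst.subscales
        }

    def items_by_instrument(self) -> dict[str, list[str]]:
        return {inst.name: list(inst.item_ids) for inst in self.instruments}


def _item_id(instrument: str, subscale: str, index: int) -> str:
    # unidimensional instruments (FS) drop the redundant subscale segment
    if subscale == instrument:
        return f"{instrument}-{index}"
    return f"{instrument}-{subscale}-{index}"


def _parse_subscale(instrument: str, name: str, block: dict) -> SubscaleSpec:
    if "items" not in block:
        raise ValueError(f"{instrument}/{name}: missing 'items'")
    items = block["items"]
    if isinstance(items, int):
        item_ids = tuple(_item_id(instrument, name, i) for i in range(1, items + 1))
        index_of = {iid: i for i, iid in enumerate(item_ids, start=1)}
    else:
        item_ids = tuple(str(i) for i in items)
        index_of = {iid: i for i, iid in enumerate(item_ids, start=1)}
    if "range" not in block and "ranges" not in block:
        raise ValueError(f"{instrument}/{name}: items declared without a range")

    default_range = block.get("range")
    overrides = {int(k): tuple(v) for k, v in block.get("ranges", {}).items()}
    scales: dict[str, ResponseScale] = {}
    for iid in item_ids:
        rng = overrides.get(index_of[iid], default_range)
        if rng is None:
            raise ValueError(f"{instrument}/{name}: item {iid} has no range")
        scales[iid] = ResponseScale(int(rng[0]), int(rng[1]))

    reverse = frozenset(
        iid if isinstance(iid, str) else _item_id(instrument, name, iid)
        for iid in block.get("reverse", [])
    )
    unknown = reverse - set(item_ids)
    if unknown:
        raise ValueError(f"{instrument}/{name}: reverse-coded ids {unknown} not in subscale")
    return SubscaleSpec(name=name, item_ids=item_ids, scales=scales, reverse_coded=reverse)


def load_registry(config) -> Registry:
    """Build a :class:`Registry` from a YAML/JSON file path or a mapping.

    The config maps instrument -> subscale -> {items, range, [ranges],
    [reverse]}.  Every item must be declared exactly once with a response
    range; unknown instrument names are rejected.
    """
    if isinstance(config, (str, Path)):
        with open(config, "r", encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise TypeError("registry config must be a mapping or a path to one")

    instruments = []
    for inst_name, subs in config.items():
        if inst_name not in _KNOWN_INSTRUMENTS:
            raise ValueError(
                f"unknown instrument {inst_name!r}; expected one of {_KNOWN_INSTRUMENTS}"
            )
        subscales = tuple(
            _parse_subscale(inst_name, sub_name, block)
            for sub_name, block in subs.items()
        )
        instruments.append(InstrumentSpec(name=inst_name, subscales=subscales))
    return Registry(instruments)


def default_registry() -> Registry:
    """The packaged 4-instrument, 47-item, 11-facet default registry."""
    ref = importlib.resources.files("ipvkit.data") / "registry.yaml"
    return load_registry(yaml.safe_load(ref.read_text(encoding="utf-8")))


def validate_responses(data: pd.DataFrame, registry: Registry) -> pd.DataFrame:
    """Validate a respondent x item matrix and apply reverse-coding.

    Checks that columns exactly match the registry items, that no cell is
    missing (the data model assumes a forced-response design) and that every
    code lies inside its item's response range.  Reverse-coded items are
    recoded as ``max_code + min_code - x``; applying the function twice
    restores the raw codes.
    """
    unknown = set(data.columns) - set(registry.item_ids)
    if unknown:
        raise ValueError(f"unknown response columns: {sorted(unknown)}")
    missing_cols = set(registry.item_ids) - set(data.columns)
    if missing_cols:
        raise ValueError(f"missing response columns: {sorted(missing_cols)}")
    data = data[registry.item_ids]
    if data.isna().any().any():
        bad = data.columns[data.isna().any()].tolist()
        raise ValueError(f"missing cells in columns {bad}")

    out = data.copy()
    for iid in registry.item_ids:
        scale = registry.scale_of(iid)
        col = out[iid]
        if (col < scale.min_code).any() or (col > scale.max_code).any():
            raise ValueError(
                f"item {iid}: responses outside [{scale.min_code}, {scale.max_code}]"
            )
    for iid in registry.reverse_coded_items():
        out[iid] = registry.scale_of(iid).reverse(out[iid])
    return out


@dataclass
class SubscaleScores:
    """Per-respondent subscale composites plus per-subscale summaries."""

    composites: pd.DataFrame  # respondents x subscales
    summary: pd.DataFrame  # subscale -> n_items, M, SD
    standardized: dict[str, bool]  # subscale -> items z-scored before averaging?


def score_subscales(
    data: pd.DataFrame,
    registry: Registry,
    standardize_items: bool | None = None,
) -> SubscaleScores:
    """Compute subscale composites as item means after reverse-coding.

    ``standardize_items=None`` (default) z-scores items only for instruments
    whose items mix response formats (WBCF); True/False forces the choice
    globally.  Standardizing a zero-variance item is an error.
    """
    composites = {}
    standardized = {}
    rows = []
    for inst in registry.instruments:
        std = (
            inst.name in _STANDARDIZE_BY_DEFAULT
            if standardize_items is None
            else standardize_items
        )
        for sub in inst.subscales:
            block = data[list(sub.item_ids)].astype(float)
            if std:
                sd = block.std(ddof=1)
                if (sd == 0).any():
                    bad = sd.index[sd == 0].tolist()
                    raise ValueError(f"zero-variance items {bad}: cannot standardize")
                block = (block - block.mean()) / sd
            comp = block.mean(axis=1)
            composites[sub.name] = comp
            standardized[sub.name] = std
            rows.append(
                {
                    "subscale": sub.name,
                    "instrument": inst.name,
                    "n_items": sub.n_items,
                    "M": comp.mean(),
                    "SD": comp.std(ddof=1),
                }
            )
    comp_df = pd.DataFrame(composites)
    summary = pd.DataFrame(rows).set_index("subscale")
    return SubscaleScores(composites=comp_df, summary=summary, standardized=standardized)


@dataclass(frozen=True)
class ReliabilityResult:
    subscale: str
    alpha: float
    k: int


def cronbach_alpha(items: pd.DataFrame, subscale: str = "") -> ReliabilityResult:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(total)).

    Requires at least two items and three respondents; variances use the
    n-1 denominator.  Alpha is 1 for identical columns and can be negative
    for strongly negatively related items.
    """
    k = items.shape[1]
    if k < 2:
        raise ValueError("cronbach_alpha needs at least 2 items")
    if items.shape[0] < 3:
        raise ValueError("cronbach_alpha needs at least 3 respondents")
    item_vars = items.var(ddof=1)
    total_var = items.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    return ReliabilityResult(subscale=subscale, alpha=float(alpha), k=k)


def correlation_matrix(scores: SubscaleScores | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations among subscale composites (unit diagonal)."""
    comp = scores.composites if isinstance(scores, SubscaleScores) else scores
    if comp.shape[0] < 3:
        raise ValueError("correlation_matrix needs at least 3 respondents")
    sd = comp.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"zero-variance columns {bad}")
    return comp.corr()


def reliability_table(
    data: pd.DataFrame,
    registry: Registry,
    standardize_items: bool | None = None,
) -> pd.DataFrame:
    """Per-subscale descriptives and internal consistency (one row each).

    Columns: instrument, n_items, M, SD, alpha — the layout of a standard
    scale-descriptives table.
    """
    scores = score_subscales(data, registry, standardize_items)
    table = scores.summary.copy()
    alphas = {}
    for inst in registry.instruments:
        for sub in inst.subscales:
            block = data[list(sub.item_ids)].astype(float)
            if scores.standardized[sub.name]:
                block = (block - block.mean()) / block.std(ddof=1)
            alphas[sub.name] = (
                cronbach_alpha(block, sub.name).alpha if sub.n_items >= 2 else np.nan
            )
    table["alpha"] = pd.Series(alphas)
    return table
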