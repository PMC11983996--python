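"""Food-composition handling and FFQ aggregation.

Reads a food-composition table (FCT) and a wide-format FFQ intake matrix
(grams/day per subject and item), and rolls item-level intakes up into the
nine food components of the Mediterranean-diet adherence score, total
energy intake, and the MUFA/SFA fatty-acid ratio.

The MUFA numerator is taken from olive-oil consumption only: olive oil is
the dominant monounsaturated-fat source in Mediterranean populations, so
the score approximates MUFA by the olive-oil contribution. The SFA
denominator sums saturated fat over *all* items, olive oil included.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine food components of the adherence score, in canonical order.
FOOD_COMPONENTS = (
    "cereals",
    "dairy",
    "legumes",
    "fruits_nuts",
    "vegetables",
    "fish",
    "poultry",
    "red_meat",
    "alcohol",
)

#: Items outside every food group (e.g. olive oil, fats, sweets) carry this label.
NO_COMPONENT = "none"

VALID_COMPONENTS = FOOD_COMPONENTS + (NO_COMPONENT,)

#: All ten scored components: the nine food groups plus the fatty-acid ratio.
SCORED_COMPONENTS = FOOD_COMPONENTS + ("mufa_sfa_ratio",)

FCT_COLUMNS = (
    "item_id",
    "name",
    "component",
    "energy_kcal_per_100g",
    "sfa_g_per_100g",
    "mufa_g_per_100g",
    "is_olive_oil",
)


class CompositionError(ValueError):
    """Raised when an FCT or intake file violates its contract."""


@dataclass(frozen=True)
class FoodItem:
    """One FFQ item with its component assignment and nutrient densities."""

    item_id: str
    name: str
    component: str
    energy_kcal_per_100g: float
    sfa_g_per_100g: float
    mufa_g_per_100g: float
    is_olive_oil: bool

    def __post_init__(self) -> None:
        if self.component not in VALID_COMPONENTS:
            raise CompositionError(
                f"item {self.item_id!r}: unknown component label "
                f"{self.component!r}; expected one of {sorted(VALID_COMPONENTS)}"
            )
        for field in ("energy_kcal_per_100g", "sfa_g_per_100g", "mufa_g_per_100g"):
            value = getattr(self, field)
            if not np.isfinite(value) or value < 0:
                raise CompositionError(
                    f"item {self.item_id!r}: {field} must be finite and >= 0, got {value}"
                )


def load_composition_table(path: str | Path) -> dict[str, FoodItem]:
    """Load and validate an FCT CSV, returning items keyed by item id.

    The file must carry the header ``item_id,name,component,
    energy_kcal_per_100g,sfa_g_per_100g,mufa_g_per_100g,is_olive_oil``
    with ``is_olive_oil`` coded 0/1. Unknown component labels, negative
    nutrient densities and duplicate item ids are hard errors.
    """
    df = pd.read_csv(path, dtype={"item_id": str, "name": str, "component": str})
    missing = set(FCT_COLUMNS) - set(df.columns)
    if missing:
        raise CompositionError(f"FCT {path}: missing columns {sorted(missing)}")
    dup = df["item_id"][df["item_id"].duplicated()]
    if not dup.empty:
        raise CompositionError(
            f"FCT {path}: duplicate item_id values {sorted(dup.unique())}"
        )
    items: dict[str, FoodItem] = {}
    for row_no, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            item = FoodItem(
                item_id=rec.item_id,
                name=rec.name,
                component=rec.component,
                energy_kcal_per_100g=float(rec.energy_kcal_per_100g),
                sfa_g_per_100g=float(rec.sfa_g_per_100g),
                mufa_g_per_100g=float(rec.mufa_g_per_100g),
                is_olive_oil=bool(int(rec.is_olive_oil)),
            )
        except CompositionError as exc:
            raise CompositionError(f"FCT {path}, row {row_no}: {exc}") from None
        items[item.item_id] = item
    return items


def items_from_frame(fct: pd.DataFrame) -> dict[str, FoodItem]:
    """Build validated FoodItems from an in-memory FCT table (loader dialect)."""
    items: dict[str, FoodItem] = {}
    for rec in fct.to_dict("records"):
        item = FoodItem(
            item_id=str(rec["item_id"]),
            name=str(rec["name"]),
            component=str(rec["component"]),
            energy_kcal_per_100g=float(rec["energy_kcal_per_100g"]),
            sfa_g_per_100g=float(rec["sfa_g_per_100g"]),
            mufa_g_per_100g=float(rec["mufa_g_per_100g"]),
            is_olive_oil=bool(int(rec["is_olive_oil"])),
        )
        if item.item_id in items:
            raise CompositionError(f"duplicate item_id {item.item_id!r}")
        items[item.item_id] = item
    return items


def load_intake_matrix(
    path: str | Path, items: Mapping[str, FoodItem] | None = None
) -> pd.DataFrame:
    """Load a wide intake CSV (first column subject_id, one column per item).

    Cells are grams/day. Missing cells are a hard error — the FFQ is
    interviewer-administered, so a structurally missing value signals a
    malformed file rather than a true zero.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if df.columns[0] != "subject_id":
        raise CompositionError(f"intake {path}: first column must be subject_id")
    df = df.set_index("subject_id")
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise CompositionError(
            f"intake {path}: missing cells in columns {bad}; missing is not zero"
        )
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values < 0).any():
        raise CompositionError(f"intake {path}: cells must be finite and >= 0")
    if items is not None:
        _check_columns_mapped(df.columns, items)
    return df.astype(float)


def _check_columns_mapped(columns: Iterable[str], items: Mapping[str, FoodItem]) -> None:
    orphans = [c for c in columns if c not in items]
    if orphans:
        raise CompositionError(f"intake columns without an FCT item: {orphans}")


def compute_energy(intake_row: Mapping[str, float], items: Mapping[str, FoodItem]) -> float:
    """Total energy in kcal/day: sum of grams/day x kcal/100 g / 100."""
    return sum(
        grams * items[item_id].energy_kcal_per_100g / 100.0
        for item_id, grams in intake_row.items()
    )


def compute_mufa_sfa_ratio(
    intake_row: Mapping[str, float], items: Mapping[str, FoodItem]
) -> tuple[float, bool]:
    """MUFA/SFA ratio for one subject.

    MUFA sums grams/day x MUFA density over olive-oil items only; SFA sums
    saturated fat over every item. Returns ``(ratio, defined)``; when total
    SFA is zero the ratio is undefined and the subject must be excluded
    from median and score computation.
    """
    if not any(item.is_olive_oil for item in items.values()):
        raise CompositionError("no olive-oil item in the composition table")
    mufa = sum(
        grams * items[i].mufa_g_per_100g / 100.0
        for i, grams in intake_row.items()
        if items[i].is_olive_oil
    )
    sfa = sum(
        grams * items[i].sfa_g_per_100g / 100.0 for i, grams in intake_row.items()
    )
    if sfa <= 0.0:
        return float("nan"), False
    return mufa / sfa, True


def aggregate_components(
    intake: pd.DataFrame, items: Mapping[str, FoodItem]
) -> pd.DataFrame:
    """Aggregate an intake matrix to per-subject component intakes.

    Returns one row per subject with the nine food-component g/day totals,
    ``mufa_sfa_ratio``, ``energy_kcal_per_day`` and a boolean
    ``ratio_defined`` column. Items assigned to no component contribute to
    energy and SFA but to no food group. Subjects with zero total SFA get
    ``ratio_defined = False`` (never a silent NaN downstream).
    """
    _check_columns_mapped(intake.columns, items)
    cols = list(intake.columns)
    grams = intake.to_numpy(dtype=float)

    comp_mask = np.zeros((len(cols), len(FOOD_COMPONENTS)))
    energy_density = np.empty(len(cols))
    sfa_density = np.empty(len(cols))
    mufa_oo_density = np.zeros(len(cols))
    for j, item_id in enumerate(cols):
        item = items[item_id]
        if item.component != NO_COMPONENT:
            comp_mask[j, FOOD_COMPONENTS.index(item.component)] = 1.0
        energy_density[j] = item.energy_kcal_per_100g
        sfa_density[j] = item.sfa_g_per_100g
        if item.is_olive_oil:
            mufa_oo_density[j] = item.mufa_g_per_100g

    out = pd.DataFrame(grams @ comp_mask, index=intake.index, columns=FOOD_COMPONENTS)
    out["energy_kcal_per_day"] = grams @ (energy_density / 100.0)
    sfa = grams @ (sfa_density / 100.0)
    mufa = grams @ (mufa_oo_density / 100.0)
    defined = sfa > 0.0
    ratio = np.full(len(out), np.nan)
    np.divide(mufa, sfa, out=ratio, where=defined)
    out["mufa_sfa_ratio"] = ratio
    out["ratio_defined"] = defined
    n_undef = int((~defined).sum())
    if n_undef:
        logger.warning(
            "%d subject(s) have zero SFA intake; MUFA/SFA ratio undefined, "
            "excluded from median and score computation",
            n_undef,
        )
    return out
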