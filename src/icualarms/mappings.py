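"""Lookup tables turning free-text PDMS entries into leveled categories.

Four mapping families drive the annotation rules:

* **Airway devices (AD)** — free-text device entries map to one of 18
  categories on an invasiveness scale from level 1 ("no AD") to level 9
  (endotracheal tube / tracheal cannula).  Level-0 entries are documentation
  artifacts that are not airway devices and are ignored.  A raw string may
  map to several categories; exactly one mapping per string carries the
  annotation flag that selects the level used for annotation.
* **Respiratory support therapy (RST)** — each ventilation-device /
  ventilation-mode (VD-VM) pair maps to one of 7 RST categories with a total
  severity ordering, level 1 (spontaneous breathing, formally not a therapy)
  to level 7 (controlled ventilation).  Ambiguous VD-VM pairs are
  disambiguated by the documented AD category; a blank AD resolves through a
  default row.  Level 0 exists only as the standby placeholder and never
  appears in the table.
* **Parameter compatibility** — a boolean matrix saying which of the seven
  settable ventilation parameters can be set under each RST level.
* **Medication** — hospital drug identifiers map to active ingredients,
  one of 8 route categories and 2 administration techniques, plus per-PAC
  relevance flags for the two medication intervention types.  Drug products
  combining two or more ingredients ("mixtures") are checked against a
  dedicated mixture mapping.

The tables shipped with the package are representative: schema, category
counts and orderings match the method; users supply their own content for a
real institution.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .data_model import PAC, VentParameter

__all__ = [
    "N_AD_CATEGORIES",
    "N_RST_CATEGORIES",
    "N_ROUTE_CATEGORIES",
    "TECHNIQUES",
    "ROUTE_CATEGORIES",
    "Unmapped",
    "UNMAPPED",
    "MappingTables",
    "MappingValidationError",
    "load_mappings",
    "default_mapping_dir",
    "resolve_ad_level",
    "resolve_rst",
    "is_settable",
    "medication_relevant",
]

N_AD_CATEGORIES = 18
N_RST_CATEGORIES = 7
N_ROUTE_CATEGORIES = 8

TECHNIQUES = ("bolus", "continuous")

ROUTE_CATEGORIES = (
    "intravenous",
    "inhalative",
    "enteral",
    "subcutaneous",
    "intramuscular",
    "transdermal",
    "epidural",
    "intraosseous",
)

#: RST levels allowed to keep their level (and oxygen flow) during standby.
STANDBY_EXEMPT_RST_LEVELS = frozenset({1, 2})


class Unmapped:
    """Sentinel for a lookup that found no mapping.

    An unmapped entry never halts a batch; the rule consuming it simply does
    not fire, and the event is counted in the run log.
    """

    _instance: Optional["Unmapped"] = None

    def __new__(cls) -> "Unmapped":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover
        return "UNMAPPED"

    def __bool__(self) -> bool:
        return False


UNMAPPED = Unmapped()


class MappingValidationError(ValueError):
    """A shipped or user-supplied mapping table violates the method's schema."""


def _relevance_columns() -> list[str]:
    return [f"gi_{p.value}" for p in PAC] + [f"sd_{p.value}" for p in PAC]


@dataclass(frozen=True)
class MappingTables:
    """Validated, immutable bundle of the five mapping tables."""

    ad: pd.DataFrame
    rst: pd.DataFrame
    compatibility: pd.DataFrame  # indexed by rst_level, bool columns per parameter
    medication: pd.DataFrame    # indexed by drug_id
    mixture: pd.DataFrame       # indexed by frozenset-as-sorted-pipe string

    # ---- validation ------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of schema violations (empty list = valid)."""
        problems: list[str] = []
        ad = self.ad
        cats = ad.loc[ad["level"] >= 1, "category"].unique()
        if len(cats) != N_AD_CATEGORIES:
            problems.append(
                f"ad_mapping: expected {N_AD_CATEGORIES} AD categories (level >= 1), found {len(cats)}"
            )
        lv = ad.loc[ad["level"] >= 1].groupby("category")["level"].nunique()
        if (lv > 1).any():
            problems.append("ad_mapping: a category maps to more than one level")
        if not ad["level"].between(0, 9).all():
            problems.append("ad_mapping: levels must lie in 0..9")
        if set(ad.loc[ad["level"] == 1, "category"]) != {"no_ad"}:
            problems.append("ad_mapping: level 1 must be exactly the 'no AD' category")
        if ad.loc[ad["level"] == 9].empty:
            problems.append("ad_mapping: level 9 (endotracheal tube / tracheal cannula) missing")
        flags = ad.groupby("raw_text")["annotation_flag"].sum()
        bad = flags[flags != 1]
        if not bad.empty:
            problems.append(
                "ad_mapping: every raw string needs exactly one annotation-flagged row; "
                f"violated by {sorted(bad.index)[:5]}"
            )

        rst = self.rst
        rcats = rst["rst_category"].unique()
        if len(rcats) != N_RST_CATEGORIES:
            problems.append(
                f"rst_mapping: expected {N_RST_CATEGORIES} RST categories, found {len(rcats)}"
            )
        if not rst["rst_level"].between(1, 7).all():
            problems.append("rst_mapping: levels must lie in 1..7 (0 is reserved for standby)")
        lvl = rst.groupby("rst_category")["rst_level"].nunique()
        if (lvl > 1).any():
            problems.append("rst_mapping: an RST category maps to more than one level")
        dup = rst.duplicated(subset=["vd_text", "vm_text", "ad_category"])
        if dup.any():
            problems.append("rst_mapping: duplicate (VD, VM, AD) rows")

        comp = self.compatibility
        want_cols = [p.value for p in VentParameter]
        if list(comp.columns) != want_cols:
            problems.append(f"compatibility: columns must be {want_cols}")
        if list(comp.index) != list(range(1, 8)):
            problems.append("compatibility: rows must be RST levels 1..7")
        elif comp.loc[1].any():
            problems.append(
                "compatibility: level 1 row must be all-'No' (level 1 is not a therapy)"
            )

        med = self.medication
        routes = set(med["route_category"].unique())
        if routes != set(ROUTE_CATEGORIES):
            problems.append(
                f"medication_mapping: route categories must be exactly the {N_ROUTE_CATEGORIES} "
                f"known categories; got {sorted(routes)}"
            )
        if not med["technique"].isin(TECHNIQUES).all():
            problems.append(f"medication_mapping: technique must be one of {TECHNIQUES}")
        for col in _relevance_columns():
            if col not in med.columns:
                problems.append(f"medication_mapping: missing relevance column {col}")
        if "sd_spo2_low" in med.columns and med["sd_spo2_low"].any():
            problems.append(
                "medication_mapping: stop/decrease relevance must be false for SpO2-low"
            )
        mix = self.mixture
        if "sd_spo2_low" in mix.columns and mix["sd_spo2_low"].any():
            problems.append("mixture_mapping: stop/decrease relevance must be false for SpO2-low")
        for s in mix.index:
            if len(s.split("|")) < 2:
                problems.append(f"mixture_mapping: ingredient set {s!r} has fewer than 2 members")
        return problems

    def assert_valid(self) -> None:
        problems = self.validate()
        if problems:
            raise MappingValidationError("; ".join(problems))


def default_mapping_dir() -> Path:
    """Directory of the mapping tables shipped with the package."""
    return Path(str(importlib.resources.files("icualarms") / "data"))


def load_mappings(directory: Optional[Union[str, Path]] = None, *, validate: bool = True) -> MappingTables:
    """Load the five mapping CSVs from *directory* (default: shipped tables)."""
    d = Path(directory) if directory is not None else default_mapping_dir()
    ad = pd.read_csv(d / "ad_mapping.csv", dtype={"raw_text": str, "category": str})
    ad["level"] = ad["level"].astype(int)
    ad["annotation_flag"] = ad["annotation_flag"].astype(bool)

    rst = pd.read_csv(d / "rst_mapping.csv", keep_default_na=False, dtype=str)
    rst["rst_level"] = rst["rst_level"].astype(int)

    comp = pd.read_csv(d / "compatibility.csv")
    comp = comp.set_index("rst_level")
    comp = comp.apply(lambda col: col.str.strip().str.lower().eq("yes"))

    med = pd.read_csv(d / "medication_mapping.csv", dtype={"drug_id": str}, keep_default_na=False)
    for col in _relevance_columns() + ["is_iv_fluid"]:
        med[col] = med[col].astype(int).astype(bool)
    med = med.set_index("drug_id", drop=False)

    mix = pd.read_csv(d / "mixture_mapping.csv", keep_default_na=False)
    for col in _relevance_columns():
        mix[col] = mix[col].astype(int).astype(bool)
    mix["ingredient_set"] = mix["ingredient_set"].map(
        lambda s: "|".join(sorted(s.split("|")))
    )
    mix = mix.set_index("ingredient_set", drop=False)

    tables = MappingTables(ad=ad, rst=rst, compatibility=comp, medication=med, mixture=mix)
    if validate:
        tables.assert_valid()
    return tables


# ---- resolvers -----------------------------------------------------------


def resolve_ad_level(entry_text: str, mapping: MappingTables) -> Union[int, Unmapped]:
    """Resolve a free-text airway-device entry to its AD level (1-9).

    For strings mapped to several categories, the annotation-flagged row
    decides.  Strings mapped only to level 0 are documentation artifacts,
    reported as :data:`UNMAPPED` (the consuming rule ignores them), as are
    strings absent from the table.
    """
    rows = mapping.ad[mapping.ad["raw_text"] == entry_text]
    if rows.empty:
        return UNMAPPED
    flagged = rows[rows["annotation_flag"]]
    level = int(flagged["level"].iloc[0])
    if level == 0:
        return UNMAPPED
    return level


def resolve_rst(
    vd_text: str,
    vm_text: str,
    ad_category: Optional[str],
    mapping: MappingTables,
) -> Union[tuple[str, int], Unmapped]:
    """Resolve a VD-VM pair (plus optional AD category) to (RST category, level).

    When the pair maps to several RST categories, the documented AD decides;
    with no AD (or no AD-specific row) the blank-AD default row applies.
    """
    rst = mapping.rst
    rows = rst[(rst["vd_text"] == vd_text) & (rst["vm_text"] == vm_text)]
    if rows.empty:
        return UNMAPPED
    if ad_category:
        specific = rows[rows["ad_category"] == ad_category]
        if not specific.empty:
            r = specific.iloc[0]
            return str(r["rst_category"]), int(r["rst_level"])
    default = rows[rows["ad_category"] == ""]
    if default.empty:
        return UNMAPPED
    r = default.iloc[0]
    return str(r["rst_category"]), int(r["rst_level"])


def is_settable(rst_level: int, parameter: VentParameter, mapping: MappingTables) -> bool:
    """Whether *parameter* can be set under *rst_level* per the compatibility table.

    Level 0 (standby placeholder) admits no settable parameter.
    """
    if rst_level == 0:
        return False
    if rst_level not in mapping.compatibility.index:
        raise ValueError(f"RST level must be 0..7, got {rst_level}")
    return bool(mapping.compatibility.at[rst_level, parameter.value])


def _ingredient_key(ingredients: Iterable[str]) -> str:
    return "|".join(sorted(ingredients))


def medication_relevant(
    drug_or_ingredients: Union[str, frozenset, set, tuple, list],
    pac: PAC,
    intervention_type: str,
    mapping: MappingTables,
) -> bool:
    """Whether a drug (by id) or an ingredient set is annotation-relevant for
    the given PAC and intervention type.

    *intervention_type* is ``"give_or_increase"`` or ``"stop_or_decrease"``.
    Single ingredients resolve through the medication mapping, sets of two or
    more through the mixture mapping.  Unknown identifiers are conservatively
    irrelevant (the affected rule does not fire).
    """
    if intervention_type == "give_or_increase":
        col = f"gi_{pac.value}"
    elif intervention_type == "stop_or_decrease":
        col = f"sd_{pac.value}"
    else:
        raise ValueError(f"unknown intervention type {intervention_type!r}")

    if isinstance(drug_or_ingredients, str):
        med = mapping.medication
        if drug_or_ingredients not in med.index:
            return False
        row = med.loc[drug_or_ingredients]
        ingredients = str(row["active_ingredients"]).split("|")
        if len(ingredients) >= 2:
            return medication_relevant(frozenset(ingredients), pac, intervention_type, mapping)
        return bool(row[col])

    key = _ingredient_key(drug_or_ingredients)
    if len(key.split("|")) < 2:
        raise ValueError("ingredient-set lookup requires >= 2 ingredients")
    mix = mapping.mixture
    if key not in mix.index:
        return False
    return bool(mix.at[key, col])
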