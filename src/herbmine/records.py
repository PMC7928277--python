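"""Domain records for a herbal prescription survey corpus.

The survey unit is the *prescription*: a set of standardized medicinal
materials dispensed together. Materials carry taxonomy (kingdom, family,
part used), the traditional thermal *property* (exactly one of
hot/warm/plain/cool/cold), one or more *flavors*, free-text traditional
usage, and curated pharmacology tags (condition tokens such as
``breast_cancer``). Variants produced by processing (red vs. black jujube,
cooked rehmannia, white peony) are distinct materials and carry a variant
suffix in their id.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Mapping

PROPERTIES = ("hot", "warm", "plain", "cool", "cold")
FLAVORS = ("sour", "bitter", "sweet", "pungent", "salty", "plain", "astringent")
KINGDOMS = ("plant", "animal", "fungus")
PARTS = frozenset(
    {
        "radix",
        "rhizoma",
        "semen",
        "fructus",
        "medulla",
        "cortex",
        "ramulus",
        "caulis",
        "sclerotia",
        "arillus",
        "cornu",
        "folium",
        "flos",
        "herba",
        "pericarpium",
        "exocarpium",
        "tuber",
        "bulbus",
        "caulis & radix",
        "whole",
    }
)


class CorpusError(Exception):
    """Base class for corpus validation failures."""


class SchemaError(CorpusError):
    """A required column or field is missing or malformed."""


class VocabularyError(CorpusError):
    """A token falls outside its controlled vocabulary."""


class IntegrityError(CorpusError):
    """Referential or uniqueness constraint violated."""


class StandardizationError(CorpusError):
    """Raw material names could not be mapped to canonical ids."""

    def __init__(self, unmapped: Iterable[str]):
        self.unmapped = sorted(set(unmapped))
        super().__init__(
            "unmappable raw material names: " + ", ".join(repr(n) for n in self.unmapped)
        )


def normalize_name(raw: str) -> str:
    """Fold case, surrounding whitespace, internal whitespace runs, diacritics.

    This is the *normalized* synonym-match policy; nothing fuzzier happens
    silently.
    """
    s = unicodedata.normalize("NFKD", raw)
    s = "".join(c for c in s if not unicodedata.combining(c))
    return re.sub(r"\s+", " ", s.strip()).casefold()


def parse_flavor_property(cell: str) -> tuple[tuple[str, ...], str]:
    """Parse a compound ``"Flavor [and Flavor]; Property"`` registry cell.

    ``"Sweet and pungent; warm"`` -> ``(("sweet", "pungent"), "warm")``.
    The word "plain" is a flavor before the semicolon and a property after
    it; disambiguation is purely positional.
    """
    if ";" not in cell:
        raise SchemaError(f"flavor/property cell {cell!r} lacks a ';' separator")
    flavor_part, _, prop_part = cell.partition(";")
    prop = prop_part.strip().casefold()
    if prop not in PROPERTIES:
        raise VocabularyError(f"unknown property token {prop!r} in cell {cell!r}")
    flavors = tuple(
        tok.strip().casefold()
        for tok in re.split(r"\s+and\s+|,", flavor_part, flags=re.IGNORECASE)
        if tok.strip()
    )
    if not flavors:
        raise SchemaError(f"no flavor tokens in cell {cell!r}")
    for f in flavors:
        if f not in FLAVORS:
            raise VocabularyError(f"unknown flavor token {f!r} in cell {cell!r}")
    if len(set(flavors)) != len(flavors):
        raise IntegrityError(f"duplicate flavor in cell {cell!r}")
    return flavors, prop


@dataclass(frozen=True)
class MaterialRecord:
    """One standardized medicinal material."""

    material_id: str
    scientific_name: str
    local_name: str
    family: str
    kingdom: str
    part_used: str
    tcm_property: str
    tcm_flavors: tuple[str, ...]
    usage_text: str = ""
    pharmacology_tags: frozenset[str] = field(default_factory=frozenset)
    rfc_precomputed: float | None = None

    def __post_init__(self) -> None:
        if self.kingdom not in KINGDOMS:
            raise VocabularyError(
                f"{self.material_id}: unknown kingdom {self.kingdom!r}"
            )
        if self.part_used not in PARTS:
            raise VocabularyError(
                f"{self.material_id}: unknown part {self.part_used!r}"
            )
        if self.tcm_property not in PROPERTIES:
            raise VocabularyError(
                f"{self.material_id}: unknown property {self.tcm_property!r}"
            )
        if not self.tcm_flavors:
            raise IntegrityError(f"{self.material_id}: at least one flavor required")
        if len(set(self.tcm_flavors)) != len(self.tcm_flavors):
            raise IntegrityError(f"{self.material_id}: duplicate flavors")
        for f in self.tcm_flavors:
            if f not in FLAVORS:
                raise VocabularyError(f"{self.material_id}: unknown flavor {f!r}")
        if self.rfc_precomputed is not None and not 0.0 <= self.rfc_precomputed <= 1.0:
            raise IntegrityError(
                f"{self.material_id}: rfc_precomputed {self.rfc_precomputed} outside [0,1]"
            )
        object.__setattr__(self, "pharmacology_tags", frozenset(self.pharmacology_tags))


@dataclass(frozen=True)
class PrescriptionRecord:
    """One prescription as a deduplicated set of canonical material ids."""

    prescription_id: str
    pharmacy_id: str
    materials: frozenset[str]
    region: str | None = None

    def __post_init__(self) -> None:
        if not self.materials:
            raise IntegrityError(
                f"prescription {self.prescription_id}: empty material set"
            )
        object.__setattr__(self, "materials", frozenset(self.materials))


@dataclass
class SurveyCorpus:
    """A validated registry plus prescription transactions."""

    registry: list[MaterialRecord]
    prescriptions: list[PrescriptionRecord]

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_prescriptions(self) -> int:
        return len(self.prescriptions)

    def registry_ids(self) -> set[str]:
        return {m.material_id for m in self.registry}

    def validate(self) -> None:
        ids = [m.material_id for m in self.registry]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate material_id(s) in registry: {dupes}")
        pids = [p.prescription_id for p in self.prescriptions]
        if len(set(pids)) != len(pids):
            dupes = sorted({i for i in pids if pids.count(i) > 1})
            raise IntegrityError(f"duplicate prescription_id(s): {dupes}")
        known = set(ids)
        for p in self.prescriptions:
            missing = p.materials - known
            if missing:
                raise IntegrityError(
                    f"prescription {p.prescription_id} references unknown "
                    f"materials: {sorted(missing)}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyCorpus):
            return NotImplemented
        return (
            self.registry == other.registry
            and self.prescriptions == other.prescriptions
        )


@dataclass
class SynonymTable:
    """Single-valued map from raw names to canonical material ids.

    ``match_policy`` is either ``"exact"`` or ``"normalized"``
    (case/whitespace/diacritic-folded). Fuzzy resolution is opt-in via
    :meth:`resolve` and is always reported in the return value, never
    applied silently.
    """

    entries: Mapping[str, str]
    match_policy: str = "normalized"

    def __post_init__(self) -> None:
        if self.match_policy not in ("exact", "normalized"):
            raise VocabularyError(f"unknown match policy {self.match_policy!r}")
        entries = dict(self.entries)
        if self.match_policy == "normalized":
            folded: dict[str, str] = {}
            for raw, target in entries.items():
                key = normalize_name(raw)
                if key in folded and folded[key] != target:
                    raise IntegrityError(
                        f"synonym {raw!r} maps to both {folded[key]!r} and {target!r} "
                        "after normalization"
                    )
                folded[key] = target
            self._index = folded
        else:
            self._index = entries
        self.entries = entries

    def targets(self) -> set[str]:
        return set(self._index.values())

    def lookup(self, raw: str) -> str | None:
        key = normalize_name(raw) if self.match_policy == "normalized" else raw
        return self._index.get(key)

    def resolve(
        self, raw: str, fuzzy: bool = False, fuzzy_cutoff: float = 0.88
    ) -> tuple[str | None, str]:
        """Resolve a raw name; returns ``(material_id or None, how)``.

        ``how`` is one of ``"exact"``, ``"normalized"``, ``"fuzzy:<matched key>"``
        or ``"unmatched"`` so that callers can report every non-exact match.
        """
        if raw in self.entries:
            return self.entries[raw], "exact"
        hit = self.lookup(raw)
        if hit is not None:
            return hit, "normalized"
        if fuzzy:
            key = normalize_name(raw)
            close = difflib.get_close_matches(key, self._index, n=1, cutoff=fuzzy_cutoff)
            if close:
                return self._index[close[0]], f"fuzzy:{close[0]}"
        return None, "unmatched"
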