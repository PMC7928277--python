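"""Read, validate, and write survey corpora as delimited text files.

Three files make up a corpus on disk (RFC-4180 CSV, UTF-8, header row;
TSV accepted via ``dialect="tsv"``):

* ``registry.csv`` — one row per material; the compound
  ``flavor_and_property`` column uses the ``"Sweet and pungent; warm"``
  convention.
* ``prescriptions.csv`` — long format, one row per (prescription, raw
  material name) mention.
* ``synonyms.csv`` — ``raw_name,material_id`` standardization map.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

from .records import (
    IntegrityError,
    MaterialRecord,
    PrescriptionRecord,
    SchemaError,
    StandardizationError,
    SurveyCorpus,
    SynonymTable,
    parse_flavor_property,
)

REGISTRY_COLUMNS = [
    "material_id",
    "scientific_name",
    "local_name",
    "family",
    "kingdom",
    "part_used",
    "rfc",
    "flavor_and_property",
    "traditional_usage",
    "pharmacology_tags",
]
PRESCRIPTION_COLUMNS = ["prescription_id", "pharmacy_id", "raw_material_name"]
SYNONYM_COLUMNS = ["raw_name", "material_id"]

_SEP = {"csv": ",", "tsv": "\t"}


def _read_table(path: str | Path, dialect: str, required: list[str]) -> pd.DataFrame:
    if dialect not in _SEP:
        raise SchemaError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=_SEP[dialect], dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _format_flavor_property(flavors: tuple[str, ...], prop: str) -> str:
    return f"{' and '.join(f.capitalize() for f in flavors)}; {prop}"


def load_registry(path: str | Path, dialect: str = "csv") -> list[MaterialRecord]:
    """Load and validate a material registry.

    Raises :class:`SchemaError` for missing columns, :class:`VocabularyError`
    (with the offending row) for unknown property/flavor/part/kingdom tokens,
    and :class:`IntegrityError` for duplicate ids.
    """
    df = _read_table(path, dialect, REGISTRY_COLUMNS)
    records: list[MaterialRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            flavors, prop = parse_flavor_property(row.flavor_and_property)
            tags = frozenset(
                t.strip() for t in str(row.pharmacology_tags).split(";") if t.strip()
            )
            rfc = float(row.rfc) if str(row.rfc).strip() else None
            rec = MaterialRecord(
                material_id=row.material_id,
                scientific_name=row.scientific_name,
                local_name=row.local_name,
                family=row.family,
                kingdom=row.kingdom,
                part_used=row.part_used,
                tcm_property=prop,
                tcm_flavors=flavors,
                usage_text=row.traditional_usage,
                pharmacology_tags=tags,
                rfc_precomputed=rfc,
            )
        except (SchemaError, IntegrityError) as exc:
            raise type(exc)(f"{path} row {i}: {exc}") from exc
        except Exception as exc:  # vocabulary errors carry the row number too
            raise type(exc)(f"{path} row {i}: {exc}") from exc
        if rec.material_id in seen:
            raise IntegrityError(f"{path} row {i}: duplicate material_id {rec.material_id!r}")
        seen.add(rec.material_id)
        records.append(rec)
    return records


def load_synonyms(
    path: str | Path, dialect: str = "csv", match_policy: str = "normalized"
) -> SynonymTable:
    df = _read_table(path, dialect, SYNONYM_COLUMNS)
    entries: dict[str, str] = {}
    for row in df.itertuples(index=False):
        if row.raw_name in entries and entries[row.raw_name] != row.material_id:
            raise IntegrityError(
                f"{path}: raw name {row.raw_name!r} mapped to multiple ids"
            )
        entries[row.raw_name] = row.material_id
    return SynonymTable(entries=entries, match_policy=match_policy)


def identity_synonyms(registry: Iterable[MaterialRecord]) -> SynonymTable:
    """A synonym table mapping each canonical id (and names) to itself."""
    entries: dict[str, str] = {}
    for m in registry:
        entries[m.material_id] = m.material_id
        entries.setdefault(m.scientific_name, m.material_id)
        if m.local_name:
            entries.setdefault(m.local_name, m.material_id)
    return SynonymTable(entries=entries)


def load_prescriptions(
    path: str | Path,
    synonyms: SynonymTable,
    registry: list[MaterialRecord],
    dialect: str = "csv",
    fuzzy: bool = False,
) -> SurveyCorpus:
    """Standardize a long-format prescription table into a corpus.

    Raw names pass through the synonym table; repeated mentions of one
    material within a prescription collapse to a single set member.
    Unmappable names raise :class:`StandardizationError` listing every
    offender rather than being dropped.
    """
    known = {m.material_id for m in registry}
    bad_targets = sorted(synonyms.targets() - known)
    if bad_targets:
        raise IntegrityError(
            f"synonym targets absent from registry: {bad_targets}"
        )
    df = _read_table(path, dialect, PRESCRIPTION_COLUMNS)
    unmapped: set[str] = set()
    resolved: list[str] = []
    for raw in df["raw_material_name"]:
        mid, how = synonyms.resolve(raw, fuzzy=fuzzy)
        if mid is None:
            unmapped.add(raw)
        else:
            resolved.append(mid)
    if unmapped:
        raise StandardizationError(unmapped)
    df = df.assign(material_id=resolved)

    has_region = "region" in df.columns
    prescriptions: list[PrescriptionRecord] = []
    for pid, grp in df.groupby("prescription_id", sort=False):
        pharmacies = grp["pharmacy_id"].unique()
        if len(pharmacies) != 1:
            raise IntegrityError(
                f"prescription {pid!r} listed under multiple pharmacies: "
                f"{sorted(pharmacies)}"
            )
        region = grp["region"].iloc[0] if has_region else None
        prescriptions.append(
            PrescriptionRecord(
                prescription_id=str(pid),
                pharmacy_id=str(pharmacies[0]),
                materials=frozenset(grp["material_id"]),
                region=region or None,
            )
        )
    return SurveyCorpus(registry=registry, prescriptions=prescriptions)


def write_corpus(corpus: SurveyCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a corpus as registry/prescriptions/synonyms CSVs.

    Output is byte-stable across runs (fixed column order, sorted material
    mentions, ``\\n`` line terminator) and round-trips losslessly through
    :func:`load_corpus`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg_rows = [
        {
            "material_id": m.material_id,
            "scientific_name": m.scientific_name,
            "local_name": m.local_name,
            "family": m.family,
            "kingdom": m.kingdom,
            "part_used": m.part_used,
            "rfc": "" if m.rfc_precomputed is None else repr(m.rfc_precomputed),
            "flavor_and_property": _format_flavor_property(m.tcm_flavors, m.tcm_property),
            "traditional_usage": m.usage_text,
            "pharmacology_tags": ";".join(sorted(m.pharmacology_tags)),
        }
        for m in corpus.registry
    ]
    presc_rows = [
        {
            "prescription_id": p.prescription_id,
            "pharmacy_id": p.pharmacy_id,
            "region": p.region or "",
            "raw_material_name": mid,
        }
        for p in corpus.prescriptions
        for mid in sorted(p.materials)
    ]
    syn_rows = [
        {"raw_name": m.material_id, "material_id": m.material_id}
        for m in corpus.registry
    ]
    paths = {
        "registry": out / "registry.csv",
        "prescriptions": out / "prescriptions.csv",
        "synonyms": out / "synonyms.csv",
    }
    pd.DataFrame(reg_rows, columns=REGISTRY_COLUMNS).to_csv(
        paths["registry"], index=False, lineterminator="\n"
    )
    pd.DataFrame(
        presc_rows, columns=["prescription_id", "pharmacy_id", "region", "raw_material_name"]
    ).to_csv(paths["prescriptions"], index=False, lineterminator="\n")
    pd.DataFrame(syn_rows, columns=SYNONYM_COLUMNS).to_csv(
        paths["synonyms"], index=False, lineterminator="\n"
    )
    return paths


def load_corpus(in_dir: str | Path, dialect: str = "csv") -> SurveyCorpus:
    """Load a corpus previously written by :func:`write_corpus`."""
    d = Path(in_dir)
    registry = load_registry(d / "registry.csv", dialect)
    synonyms = load_synonyms(d / "synonyms.csv", dialect)
    return load_prescriptions(d / "prescriptions.csv", synonyms, registry, dialect)
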