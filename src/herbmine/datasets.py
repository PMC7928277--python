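"""Packaged fixture data.

``frequent_materials_registry`` is the transcription of the published
table of the 19 frequently used galactagogue materials (RFC >= 0.2 over
90 prescriptions), including taxonomy, part used, flavor/property, and
curated pharmacology tags. ``toy_corpus`` is a 5-prescription corpus over
6 of those materials, small enough to verify every statistic by hand.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .io import load_prescriptions, load_registry, load_synonyms
from .records import MaterialRecord, SurveyCorpus

#: number of prescriptions in the survey the registry was transcribed from
REFERENCE_N_PRESCRIPTIONS = 90


def _data_path(name: str) -> Path:
    return Path(resources.files("herbmine") / "data" / name)


def frequent_materials_registry() -> list[MaterialRecord]:
    """The 19 frequently used materials with precomputed RFC values."""
    return load_registry(_data_path("frequent_materials.csv"))


def toy_corpus() -> SurveyCorpus:
    """Five hand-checkable prescriptions over six registry materials."""
    registry = frequent_materials_registry()
    synonyms = load_synonyms(_data_path("toy_synonyms.csv"))
    return load_prescriptions(
        _data_path("toy_prescriptions.csv"), synonyms, registry
    )


def toy_paths() -> dict[str, Path]:
    """Paths of the packaged toy-corpus CSVs (registry, prescriptions, synonyms)."""
    return {
        "registry": _data_path("frequent_materials.csv"),
        "prescriptions": _data_path("toy_prescriptions.csv"),
        "synonyms": _data_path("toy_synonyms.csv"),
    }
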