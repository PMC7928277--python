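"""Citation statistics and categorical profiles for a survey corpus.

The central statistic is the relative frequency of citation,
``RFC = FC / N``, where FC is the number of prescriptions containing a
material and N the number of prescriptions in the corpus. Materials with
RFC at or above a cutoff (0.2 in the reference analysis) are the
*frequently used* set over which property, flavor, and pharmacology
profiles are computed.

Two counting conventions are exposed explicitly and never chosen
implicitly:

* ``per_material`` — each material counts once per category it carries;
  denominator = number of materials. For single-valued variables the
  proportions sum to 1; for multi-valued variables (flavors, tags) they
  may sum to more than 1.
* ``per_token`` — every mention counts; denominator = total mentions, so
  proportions always sum to 1. Only valid for multi-valued variables.

All internal arithmetic is exact (integer counts, rational proportions);
rounding happens once, at display (half-up).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .records import MaterialRecord, SurveyCorpus

#: registry variables and whether a material carries one value or several
SINGLE_VALUED = {"kingdom": "kingdom", "family": "family",
                 "part_used": "part_used", "tcm_property": "tcm_property"}
MULTI_VALUED = {"tcm_flavors": "tcm_flavors", "pharmacology_tags": "pharmacology_tags"}


class DegenerateCorpusError(ValueError):
    """Raised when a statistic is requested over zero prescriptions."""


class ConventionError(ValueError):
    """Raised when a counting convention does not apply to a variable."""


def round_half_up(x: Fraction | float, digits: int = 0) -> float:
    """Decimal half-up rounding, the single display-rounding rule."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    q = Decimal(1).scaleb(-digits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def _decimal_fraction(cutoff: float) -> Fraction:
    # interpret float thresholds by their shortest decimal form so that
    # e.g. 18/90 passes a 0.2 cutoff inclusively
    return Fraction(str(cutoff))


def compute_rfc(corpus: SurveyCorpus) -> pd.DataFrame:
    """Citation count and RFC for every registry material.

    Returns a DataFrame with columns ``material_id, fc, n, rfc,
    rfc_display``, one row per registry material (zero-citation materials
    retained with rfc = 0), sorted by descending rfc with ties broken on
    material_id. ``rfc`` is the exact quotient fc/n as a float; exactness
    of comparisons is guaranteed by the integer ``fc`` and ``n`` columns.
    """
    n = corpus.n_prescriptions
    if n == 0:
        raise DegenerateCorpusError("corpus has no prescriptions; RFC undefined")
    fc = {m.material_id: 0 for m in corpus.registry}
    for p in corpus.prescriptions:
        for mid in p.materials:
            fc[mid] += 1
    df = pd.DataFrame(
        {
            "material_id": list(fc),
            "fc": list(fc.values()),
            "n": n,
        }
    )
    df["rfc"] = df["fc"] / df["n"]
    df["rfc_display"] = [
        f"{round_half_up(Fraction(f, n), 2):.2f}" for f in df["fc"]
    ]
    df = df.sort_values(
        ["rfc", "material_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def rfc_from_registry(registry: list[MaterialRecord], n: int) -> pd.DataFrame:
    """RFC table from precomputed registry RFC values (for transcribed
    fixtures that carry no prescription-level data).

    fc is back-computed as round(rfc * n); the display value re-rounds to
    the original two-decimal RFC.
    """
    if n <= 0:
        raise DegenerateCorpusError("n must be positive")
    rows = []
    for m in registry:
        if m.rfc_precomputed is None:
            raise ValueError(f"{m.material_id}: no precomputed RFC")
        f = int(round_half_up(m.rfc_precomputed * n))
        rows.append((m.material_id, f, n))
    df = pd.DataFrame(rows, columns=["material_id", "fc", "n"])
    df["rfc"] = df["fc"] / df["n"]
    df["rfc_display"] = [
        f"{round_half_up(Fraction(f, n), 2):.2f}" for f in df["fc"]
    ]
    return df.sort_values(
        ["rfc", "material_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def select_frequent(table: pd.DataFrame, cutoff: float = 0.2) -> pd.DataFrame:
    """Retain rows with RFC >= cutoff (inclusive); order preserved.

    The cutoff is interpreted as a decimal, so the boundary fc/n == cutoff
    is kept exactly regardless of binary float representation.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff {cutoff} outside [0, 1]")
    c = _decimal_fraction(cutoff)
    keep = [Fraction(int(f), int(n)) >= c for f, n in zip(table["fc"], table["n"])]
    return table.loc[keep].reset_index(drop=True)


@dataclass
class ProfileSummary:
    """Category counts and proportions for one registry variable."""

    variable: str
    convention: str
    counts: dict[str, int]
    denominator: int

    @property
    def proportions(self) -> dict[str, Fraction]:
        return {k: Fraction(v, self.denominator) for k, v in self.counts.items()}

    @property
    def percent_display(self) -> dict[str, int]:
        return {
            k: int(round_half_up(Fraction(100 * v, self.denominator)))
            for k, v in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": self.variable,
                "convention": self.convention,
                "category": list(self.counts),
                "count": list(self.counts.values()),
                "denominator": self.denominator,
                "proportion": [v / self.denominator for v in self.counts.values()],
                "percent_display": list(self.percent_display.values()),
            }
        )


def profile_categorical(
    materials: list[MaterialRecord],
    variable: str,
    convention: str = "per_material",
) -> ProfileSummary:
    """Tabulate a registry variable over a material list.

    Categories are ordered by descending count, ties alphabetical.
    """
    if not materials:
        raise ValueError("empty material list")
    if convention not in ("per_material", "per_token"):
        raise ConventionError(f"unknown convention {convention!r}")
    if variable in SINGLE_VALUED:
        if convention == "per_token":
            raise ConventionError(
                f"per_token counting undefined for single-valued variable {variable!r}"
            )
        values = [[getattr(m, SINGLE_VALUED[variable])] for m in materials]
    elif variable in MULTI_VALUED:
        values = [sorted(getattr(m, MULTI_VALUED[variable])) for m in materials]
    else:
        raise ValueError(f"unknown variable {variable!r}")

    counts: dict[str, int] = {}
    total_mentions = 0
    for vals in values:
        for v in vals:
            counts[v] = counts.get(v, 0) + 1
            total_mentions += 1
    denominator = total_mentions if convention == "per_token" else len(materials)
    ordered = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return ProfileSummary(
        variable=variable, convention=convention, counts=ordered, denominator=denominator
    )


def flavor_profile(materials: list[MaterialRecord]) -> ProfileSummary:
    """Flavor profile under the per-token convention (denominator = all
    flavor mentions), the convention that matches radar-chart percentages."""
    return profile_categorical(materials, "tcm_flavors", "per_token")


def property_profile(materials: list[MaterialRecord]) -> ProfileSummary:
    """Thermal-property profile under the per-material convention."""
    return profile_categorical(materials, "tcm_property", "per_material")


def pharmacology_summary(
    materials: list[MaterialRecord], tag: str
) -> tuple[int, Fraction]:
    """Count of materials carrying a pharmacology tag, with the
    per-material proportion. Unknown tags warn and return (0, 0)."""
    if not materials:
        raise ValueError("empty material list")
    count = sum(1 for m in materials if tag in m.pharmacology_tags)
    if count == 0:
        all_tags = set().union(*(m.pharmacology_tags for m in materials))
        if tag not in all_tags:
            warnings.warn(f"pharmacology tag {tag!r} absent from all materials")
    return count, Fraction(count, len(materials))
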