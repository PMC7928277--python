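"""One-command pipeline: corpus -> citation statistics -> pair mining ->
network -> report.

Artifacts written to the output directory:

``rfc_table.csv``, ``profiles.csv``, ``pairs.csv``, ``rules.csv``,
``network.graphml``, ``edges.tsv``, ``report.md``, ``manifest.json``.

CSVs carry full precision plus display columns; every percentage in the
report comes from the same single display-rounding rule as the CSVs. The
manifest records parameters, seed, input digests, and the package
version, and is identical across reruns apart from its timestamp. On any
stage failure the partially written outputs are removed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .indices import (
    compute_rfc,
    pharmacology_summary,
    profile_categorical,
    round_half_up,
    select_frequent,
)
from .io import load_prescriptions, load_registry, load_synonyms
from .mining import (
    association_rules,
    build_network,
    core_ranking,
    count_pairs,
    high_frequency_pairs,
    write_edgelist,
    write_graphml,
)
from .records import SurveyCorpus
from .simulate import GeneratorConfig, generate_corpus

logger = logging.getLogger("herbmine")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


@dataclass
class PipelineConfig:
    """Parameters of one pipeline run."""

    out_dir: Path
    registry_path: Path | None = None
    prescriptions_path: Path | None = None
    synonyms_path: Path | None = None
    generator: GeneratorConfig | None = None
    rfc_cutoff: float = 0.2
    pair_threshold: int = 41
    edge_threshold: int = 18
    min_support: int = 1
    min_confidence: float = 1.0
    strict: bool = True
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.pair_threshold < 0 or self.edge_threshold < 0 or self.min_support < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.rfc_cutoff <= 1.0:
            raise ValueError("rfc_cutoff must lie in [0, 1]")
        has_files = self.registry_path is not None and self.prescriptions_path is not None
        if has_files == (self.generator is not None):
            raise ValueError(
                "provide either registry+prescriptions paths or a generator config"
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_or_generate(config: PipelineConfig) -> tuple[SurveyCorpus, dict[str, str]]:
    if config.generator is not None:
        gen = dataclasses.replace(config.generator, seed=config.seed)
        corpus = generate_corpus(gen)
        digests = {"generator": hashlib.sha256(
            json.dumps(dataclasses.asdict(gen), sort_keys=True, default=list).encode()
        ).hexdigest()}
        return corpus, digests
    registry = load_registry(config.registry_path)
    if config.synonyms_path is not None:
        synonyms = load_synonyms(config.synonyms_path)
    else:
        from .io import identity_synonyms

        synonyms = identity_synonyms(registry)
    corpus = load_prescriptions(config.prescriptions_path, synonyms, registry)
    digests = {
        "registry": _sha256(Path(config.registry_path)),
        "prescriptions": _sha256(Path(config.prescriptions_path)),
    }
    if config.synonyms_path is not None:
        digests["synonyms"] = _sha256(Path(config.synonyms_path))
    return corpus, digests


_PROFILE_PLAN = [
    ("kingdom", "per_material"),
    ("family", "per_material"),
    ("part_used", "per_material"),
    ("tcm_property", "per_material"),
    ("tcm_flavors", "per_token"),
    ("tcm_flavors", "per_material"),
    ("pharmacology_tags", "per_material"),
]


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis; returns the artifact paths."""
    logging.basicConfig(stream=sys.stderr, level=config.log_level.upper())
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "corpus"
        corpus, digests = _load_or_generate(config)
        logger.info("corpus: %d prescriptions, %d registry materials",
                    corpus.n_prescriptions, len(corpus.registry))

        stage = "rfc"
        rfc = compute_rfc(corpus)
        frequent = select_frequent(rfc, config.rfc_cutoff)
        freq_ids = set(frequent["material_id"])
        freq_records = [m for m in corpus.registry if m.material_id in freq_ids]
        logger.info("%d frequent materials at RFC >= %s", len(frequent), config.rfc_cutoff)

        stage = "profiles"
        profiles = []
        for variable, convention in _PROFILE_PLAN:
            try:
                profiles.append(
                    profile_categorical(freq_records, variable, convention).to_frame()
                )
            except ValueError:
                continue  # e.g. no frequent materials carry the variable
        profiles_df = (
            pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame()
        )

        stage = "pairs"
        pairs = count_pairs(corpus)
        hf_pairs = high_frequency_pairs(pairs, config.pair_threshold, config.strict)
        rules = association_rules(pairs, config.min_support, config.min_confidence)

        stage = "network"
        network = build_network(
            pairs, rfc, config.edge_threshold, config.rfc_cutoff, config.strict
        )
        ranking = core_ranking(network)

        stage = "write"
        paths = {
            "rfc_table": out / "rfc_table.csv",
            "profiles": out / "profiles.csv",
            "pairs": out / "pairs.csv",
            "rules": out / "rules.csv",
            "network": out / "network.graphml",
            "edges": out / "edges.tsv",
            "report": out / "report.md",
            "manifest": out / "manifest.json",
        }
        written.extend(paths.values())
        rfc.to_csv(paths["rfc_table"], index=False, lineterminator="\n")
        profiles_df.to_csv(paths["profiles"], index=False, lineterminator="\n")
        pairs.to_csv(paths["pairs"], index=False, lineterminator="\n")
        rules.to_csv(paths["rules"], index=False, lineterminator="\n")
        write_graphml(network, paths["network"])
        write_edgelist(network, paths["edges"])
        paths["report"].write_text(
            _render_report(config, corpus, rfc, frequent, freq_records,
                           hf_pairs, rules, ranking),
            encoding="utf-8",
        )
        manifest = {
            "package": "herbmine",
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "seed": config.seed,
            "parameters": {
                "rfc_cutoff": config.rfc_cutoff,
                "pair_threshold": config.pair_threshold,
                "edge_threshold": config.edge_threshold,
                "min_support": config.min_support,
                "min_confidence": config.min_confidence,
                "strict": config.strict,
            },
            "inputs": digests,
            "outputs": {
                k: _sha256(p) for k, p in paths.items()
                if k != "manifest" and p.exists()
            },
        }
        paths["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return paths
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def _render_report(config, corpus, rfc, frequent, freq_records,
                   hf_pairs, rules, ranking) -> str:
    by_id = {m.material_id: m for m in corpus.registry}
    lines = [
        "# Co-prescription analysis report",
        "",
        f"- prescriptions: {corpus.n_prescriptions}",
        f"- registry materials: {len(corpus.registry)}",
        f"- cited materials: {int((rfc['fc'] > 0).sum())}",
        f"- frequent materials (RFC >= {config.rfc_cutoff}): {len(frequent)}",
        "",
        "## Frequently used materials",
        "",
        "| No | Scientific name/local name | Family | Part used | RFC | Flavor and property |",
        "|---|---|---|---|---|---|",
    ]
    for i, row in enumerate(frequent.itertuples(index=False), start=1):
        m = by_id.get(row.material_id)
        if m is None:
            continue
        name = f"{m.scientific_name}/{m.local_name}" if m.local_name else m.scientific_name
        fl = " and ".join(f.capitalize() for f in m.tcm_flavors)
        lines.append(
            f"| {i} | {name} | {m.family} | {m.part_used} | "
            f"{row.rfc_display} | {fl}; {m.tcm_property} |"
        )

    if freq_records:
        prop = profile_categorical(freq_records, "tcm_property", "per_material")
        flav = profile_categorical(freq_records, "tcm_flavors", "per_token")
        lines += ["", "## Property profile (per material)", ""]
        for cat, pct in prop.percent_display.items():
            lines.append(f"- {cat}: {prop.counts[cat]}/{prop.denominator} ({pct}%)")
        lines += ["", "## Flavor profile (per mention)", ""]
        for cat, pct in flav.percent_display.items():
            lines.append(f"- {cat}: {flav.counts[cat]}/{flav.denominator} ({pct}%)")
        lines += ["", "## Pharmacology tags (per material)", ""]
        tags = sorted({t for m in freq_records for t in m.pharmacology_tags})
        for tag in tags:
            cnt, prop_frac = pharmacology_summary(freq_records, tag)
            pct = int(round_half_up(100 * prop_frac))
            lines.append(f"- {tag}: {cnt}/{len(freq_records)} ({pct}%)")

    lines += ["", f"## High-frequency pairs (support {'>' if config.strict else '>='} "
                  f"{config.pair_threshold}): {len(hf_pairs)}", ""]
    for r in hf_pairs.itertuples(index=False):
        lines.append(f"- {r.material_a} + {r.material_b}: {r.support}")
    lines += ["", f"## Association rules (confidence >= {config.min_confidence}): "
                  f"{len(rules)}", ""]
    for r in rules.head(50).itertuples(index=False):
        lines.append(
            f"- {r.antecedent} -> {r.consequent} "
            f"(support {r.support}, confidence {r.confidence:.2f})"
        )
    lines += ["", "## Core ranking", ""]
    for i, mid in enumerate(ranking, start=1):
        lines.append(f"{i}. {mid}")
    return "\n".join(lines) + "\n"
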