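"""End-to-end orchestration: standardize a name list to a mapping file,
run fragmented-vs-aggregated signal analysis, compute validation
metrics.  The CLI module is a thin shell over these functions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cache import CacheError, CacheSet
from .enrich import enrich, enrichment_summary
from .fixtures import DATA_DIR
from .matcher import (
    DEFAULT_THRESHOLD,
    BatchSummary,
    MatchStatus,
    match_batch,
)
from .preprocess import RuleSet, load_rules
from .signals import ReportRecord, compare_aggregation
from .valmetrics import (
    ConfusionMatrix,
    cohen_kappa,
    metrics,
    recover_matrix,
    round_half_up,
)
from .vocab import Tier, VocabularyError, load_vocabulary

logger = logging.getLogger("mednorm")

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "MAPPING_COLUMNS",
    "run_standardize",
    "run_signals",
    "run_valmetrics",
    "load_reports_csv",
]

MAPPING_COLUMNS = [
    "original_name",
    "preprocessed_name",
    "status",
    "stage",
    "concept_id",
    "standardized_name",
    "score",
    "ingredients",
    "generic_name",
    "atc_codes",
    "drug_classes",
]


class PipelineError(RuntimeError):
    """Operational failure with a process exit code.

    2 = input problem (missing column), 3 = vocabulary load failure,
    4 = cache corruption.
    """

    def __init__(self, message: str, exit_code: int):
        super().__init__(message)
        self.exit_code = exit_code


@dataclass
class PipelineConfig:
    """Run configuration; loadable from a key=value file."""

    vocab_dir: Path = DATA_DIR / "demo_vocab"
    rules_dir: Path = DATA_DIR
    cache_dir: Path | None = None
    threshold: float = DEFAULT_THRESHOLD
    name_column: str = "drug_name"
    backend: str = "local"
    pipeline_version: str = "1"

    def __post_init__(self) -> None:
        self.vocab_dir = Path(self.vocab_dir)
        self.rules_dir = Path(self.rules_dir)
        if self.cache_dir is not None:
            self.cache_dir = Path(self.cache_dir)
        if self.backend != "local":
            raise ValueError(
                f"unsupported backend {self.backend!r}: only the local "
                "vocabulary backend is provided"
            )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Parse a flat key=value config file ('#' comments allowed)."""
        kwargs: dict = {}
        for line in Path(path).read_text("utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip().strip('"')
            if key == "threshold":
                kwargs[key] = float(value)
            elif key in {"vocab_dir", "rules_dir", "cache_dir"}:
                kwargs[key] = Path(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _load_components(config: PipelineConfig):
    rules = load_rules(
        config.rules_dir / "unwanted_terms.txt",
        config.rules_dir / "abbreviations.tsv",
        config.rules_dir / "special_cases.tsv",
    )
    try:
        primary = load_vocabulary(config.vocab_dir, Tier.PRIMARY, rules)
        extended = load_vocabulary(config.vocab_dir, Tier.EXTENDED, rules)
    except VocabularyError as exc:
        raise PipelineError(f"vocabulary load failure: {exc}", 3) from exc
    cache = None
    if config.cache_dir is not None:
        try:
            cache = CacheSet(config.cache_dir, version=config.pipeline_version)
        except CacheError as exc:
            raise PipelineError(f"cache corruption: {exc}", 4) from exc
    return rules, primary, extended, cache


def run_standardize(
    input_csv: str | Path,
    output_csv: str | Path,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Standardize every distinct name in *input_csv* to a mapping file.

    Names are deduplicated before matching (coverage is quoted over
    unique names); each distinct input name yields exactly one mapping
    row.  Matched rows carry the enrichment columns; unmatched rows
    keep their preprocessed form with empty concept fields.  A summary
    JSON (distinct names, matched, match rate, stage breakdown,
    enrichment rates) is written next to the mapping file.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(input_csv, dtype=str, keep_default_na=False)
    if config.name_column not in df.columns:
        raise PipelineError(
            f"input is missing the name column {config.name_column!r}", 2
        )
    rules, primary, extended, cache = _load_components(config)

    seen: set[str] = set()
    names: list[str] = []
    for raw in df[config.name_column]:
        if raw not in seen:
            seen.add(raw)
            names.append(raw)

    try:
        results, summary = match_batch(
            names, primary, extended, cache, rules, config.threshold
        )
    except CacheError as exc:
        raise PipelineError(f"cache corruption: {exc}", 4) from exc

    rows = []
    enriched_records = []
    for res in results:
        row = {
            "original_name": res.raw_name,
            "preprocessed_name": res.normalized,
            "status": res.status.value,
            "stage": res.stage.value,
            "concept_id": res.concept_id or "",
            "standardized_name": res.standardized_name or "",
            "score": "" if res.score is None else f"{res.score:.4f}",
            "ingredients": "",
            "generic_name": "",
            "atc_codes": "",
            "drug_classes": "",
        }
        if res.status is MatchStatus.MATCHED and res.concept_id in primary:
            rec = enrich(primary, res.concept_id)
            enriched_records.append(rec)
            row["ingredients"] = "; ".join(n for _, n in rec.ingredients)
            row["generic_name"] = rec.generic_name
            row["atc_codes"] = "; ".join(code for code, _ in rec.atc_codes)
            row["drug_classes"] = "; ".join(rec.drug_classes)
        rows.append(row)
        logger.debug("mapped %r -> %s/%s", res.raw_name, res.status.value,
                     res.stage.value)

    mapping = pd.DataFrame(rows, columns=MAPPING_COLUMNS)
    output_csv = Path(output_csv)
    output_csv.parent.mkdir(parents=True, exist_ok=True)
    mapping.to_csv(output_csv, index=False)

    ing_rate, atc_rate = enrichment_summary(enriched_records)
    summary_dict = {
        "total_rows": int(len(df)),
        "distinct_names": summary.distinct,
        "matched": summary.matched_distinct,
        "match_rate": summary.match_rate_display,
        "stage_counts": summary.stage_counts,
        "ingredient_rate": "n/a" if ing_rate is None else round(ing_rate, 1),
        "atc_rate": "n/a" if atc_rate is None else round(atc_rate, 1),
    }
    summary_path = output_csv.with_suffix(output_csv.suffix + ".summary.json")
    summary_path.write_text(json.dumps(summary_dict, indent=2), "utf-8")
    logger.info("standardized %d distinct names, match rate %s",
                summary.distinct, summary.match_rate_display)
    return mapping, summary_dict


def load_reports_csv(path: str | Path) -> list[ReportRecord]:
    """Read a long-format report table (report_id, drug, event; repeated
    rows per report allowed, empty cells for missing drugs/events)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("report_id", "drug", "event"):
        if col not in df.columns:
            raise PipelineError(f"reports file missing column {col!r}", 2)
    grouped: dict[str, tuple[set, set]] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        if row.report_id not in grouped:
            grouped[row.report_id] = (set(), set())
            order.append(row.report_id)
        drugs, events = grouped[row.report_id]
        if row.drug:
            drugs.add(row.drug)
        if row.event:
            events.add(row.event)
    return [
        ReportRecord(
            report_id=rid,
            drugs=frozenset(grouped[rid][0]),
            events=frozenset(grouped[rid][1]),
        )
        for rid in order
    ]


def run_signals(
    reports_csv: str | Path,
    variant_map_csv: str | Path,
    event_key: str,
    out_csv: str | Path,
) -> pd.DataFrame:
    """Fragmented-vs-aggregated disproportionality analysis.

    The variant map CSV has columns ``raw`` and ``canonical``.  The
    output holds one row per variant (scope "variant") and one per
    canonical drug after aggregation (scope "aggregated"), with the
    2x2 cells, IC with credibility bounds, ROR with CI and SDR flags.
    """
    reports = load_reports_csv(reports_csv)
    vm = pd.read_csv(variant_map_csv, dtype=str, keep_default_na=False)
    for col in ("raw", "canonical"):
        if col not in vm.columns:
            raise PipelineError(f"variant map missing column {col!r}", 2)
    variant_map = dict(zip(vm["raw"], vm["canonical"]))

    comparison = compare_aggregation(reports, variant_map, event_key)

    def _row(scope: str, key: str, stats, table) -> dict:
        return {
            "scope": scope,
            "drug_key": key,
            "event": event_key,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "ic": round(stats.ic, 4),
            "ic025": round(stats.ic025, 4),
            "ic975": round(stats.ic975, 4),
            "ror": round(stats.ror, 4),
            "ror_low": round(stats.ror_low, 4),
            "ror_high": round(stats.ror_high, 4),
            "sdr_ic": stats.sdr_ic,
            "sdr_ror": stats.sdr_ror,
        }

    rows = [
        _row("variant", key, comparison.per_variant[key],
             comparison.per_variant_tables[key])
        for key in comparison.per_variant
    ] + [
        _row("aggregated", key, comparison.aggregated[key],
             comparison.aggregated_tables[key])
        for key in comparison.aggregated
    ]
    out = pd.DataFrame(rows)
    Path(out_csv).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(out_csv, index=False)
    return out


def run_valmetrics(
    tp: int | None = None,
    fp: int | None = None,
    fn: int | None = None,
    tn: int | None = None,
    recover: dict | None = None,
    kappa_table: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> dict:
    """Validation metrics report from an explicit confusion matrix or,
    in recovery mode, from a validation design plus rounded published
    point estimates (``recover`` keys: n_total, n_pred_pos, n_pred_neg,
    precision, recall, specificity)."""
    if recover is not None:
        cm = recover_matrix(
            n_total=int(recover["n_total"]),
            n_pred_pos=int(recover["n_pred_pos"]),
            n_pred_neg=int(recover["n_pred_neg"]),
            printed={
                "precision": float(recover["precision"]),
                "recall": float(recover["recall"]),
                "specificity": float(recover["specificity"]),
            },
        )
    else:
        if None in (tp, fp, fn, tn):
            raise ValueError("provide tp/fp/fn/tn or a recovery design")
        cm = ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)
    m = metrics(cm)

    def _r(x):
        return None if x is None else round_half_up(x, 4)

    report = {
        "confusion_matrix": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn,
                             "tn": cm.tn},
        "precision": _r(m.precision),
        "precision_ci": [_r(x) for x in m.precision_ci] if m.precision_ci else None,
        "recall": _r(m.recall),
        "recall_ci": [_r(x) for x in m.recall_ci] if m.recall_ci else None,
        "specificity": _r(m.specificity),
        "specificity_ci": (
            [_r(x) for x in m.specificity_ci] if m.specificity_ci else None
        ),
        "balanced_accuracy": _r(m.balanced_accuracy),
        "mcc": _r(m.mcc),
    }
    if kappa_table is not None:
        report["cohen_kappa"] = _r(cohen_kappa(kappa_table))
    return report
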