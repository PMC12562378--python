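"""Cohort QC aggregation, consequence-class composition, and the final
structured report.

Rounding conventions are fixed so reported summaries are reproducible:
mean target coverage to 3 decimals, percentage columns to 2 decimals,
aligned-read means to 1 decimal, class-composition percentages half-up to 1
decimal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import pandas as pd

#: Expected columns of a QC metrics table (one row per sample).
QC_COLUMNS = [
    "sample",
    "mean_coverage",
    "pct_ge_20x",
    "pct_ge_50x",
    "aligned_reads",
    "uniformity",
]

_PERCENT_COLUMNS = {"pct_ge_20x", "pct_ge_50x", "uniformity"}


def read_qc_metrics(source: Union[str, Path]) -> pd.DataFrame:
    """Read a per-sample coverage-metrics TSV (columns as ``QC_COLUMNS``)."""
    df = pd.read_csv(source, sep="\t")
    missing = set(QC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"QC metrics missing column(s): {', '.join(sorted(missing))}")
    bad = df[df["pct_ge_50x"] > df["pct_ge_20x"]]
    if not bad.empty:
        raise ValueError(
            f"pct_ge_50x exceeds pct_ge_20x for sample(s) "
            f"{', '.join(bad['sample'].astype(str))}"
        )
    return df


def summarize_coverage(metrics: pd.DataFrame) -> Dict[str, float]:
    """Cohort (arithmetic) mean of each QC column.

    Coverage means are reported at 3 decimals, percentages at 2, aligned
    reads at 1.  Permutation-invariant over samples; empty input is an error.
    """
    if len(metrics) == 0:
        raise ValueError("cannot summarize an empty QC table")
    out: Dict[str, float] = {}
    for col in QC_COLUMNS[1:]:
        mean = float(metrics[col].mean())
        if col in _PERCENT_COLUMNS:
            out[col] = round(mean, 2)
        elif col == "aligned_reads":
            out[col] = round(mean, 1)
        else:
            out[col] = round(mean, 3)
    return out


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def class_breakdown(counts: Mapping[str, int]) -> Dict[str, float]:
    """Share of each consequence class, as percentages rounded half-up to one
    decimal (so 100/114 -> 87.7).  Zero total is an error."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("class breakdown requires a positive total count")
    if any(c < 0 for c in counts.values()):
        raise ValueError("class counts must be non-negative")
    return {k: _round_half_up(100.0 * v / total, 1) for k, v in counts.items()}


def build_report(
    funnels: Mapping[str, "FunnelResult"],
    model_candidates: Mapping[str, Sequence],
    concordance: Optional["ConcordanceSummary"] = None,
    panel_report: Optional["PanelReport"] = None,
    review_verdicts: Optional[Mapping] = None,
    coverage_summary: Optional[Mapping[str, float]] = None,
) -> Dict:
    """Assemble the per-model funnel, candidate tables (with review verdicts
    attached), twin concordance and panel totals into one JSON-ready dict.

    Ordering is deterministic: models in input order, candidates in natural
    chromosome/position order.  A variant admitted by several models appears
    in each model's table with a cross-reference listing the other models.
    """
    from twinvar.vcf_io import chrom_sort_key  # local import: avoid cycle

    review_verdicts = review_verdicts or {}

    # cross-references for variants shared between models
    membership: Dict[object, List[str]] = {}
    for model, cands in model_candidates.items():
        for c in cands:
            membership.setdefault(c.variant.key, []).append(model)

    report: Dict = {
        "funnels": {
            name: dict(f.stages) for name, f in funnels.items()
        },
        "models": {},
    }
    for model, cands in model_candidates.items():
        rows = []
        for c in sorted(
            cands,
            key=lambda c: (
                chrom_sort_key(c.variant.key.chrom),
                c.variant.key.pos,
                c.variant.key.alt,
            ),
        ):
            key = c.variant.key
            verdict = review_verdicts.get(key)
            other_models = [m for m in membership.get(key, []) if m != model]
            rows.append(
                {
                    "variant": str(key),
                    "gene": c.variant.bundle.gene,
                    "notes": sorted(c.support_notes),
                    "review_verdict": getattr(verdict, "value", verdict),
                    "also_in_models": sorted(other_models),
                }
            )
        report["models"][model] = {"count": len(rows), "candidates": rows}

    if concordance is not None:
        report["twin_concordance"] = {
            "shared": concordance.shared_count,
            "unique_to_affected": concordance.unique_to_affected,
            "unique_to_unaffected": concordance.unique_to_unaffected,
            "percent_shared": _round_half_up(concordance.percent_shared, 1),
        }
    if panel_report is not None:
        report["panel"] = panel_report.totals()
        report["panel"]["discordant_genes"] = sorted(
            g.gene for g in panel_report.per_gene if g.variants and not g.twin_concordant
        )
    if coverage_summary is not None:
        report["coverage_summary"] = dict(coverage_summary)
    return report


def write_report(report: Dict, out_dir: Union[str, Path]) -> None:
    """Write the report bundle: JSON plus TSV mirrors of funnels and models."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")

    lines = ["chain\tstage\tcount"]
    for chain, stages in report.get("funnels", {}).items():
        for stage, count in stages.items():
            lines.append(f"{chain}\t{stage}\t{count}")
    (out / "funnels.tsv").write_text("\n".join(lines) + "\n")

    lines = ["model\tvariant\tgene\tverdict\tnotes\talso_in_models"]
    for model, block in report.get("models", {}).items():
        for row in block["candidates"]:
            lines.append(
                "\t".join(
                    [
                        model,
                        row["variant"],
                        row["gene"] or ".",
                        row["review_verdict"] or ".",
                        ",".join(row["notes"]) or ".",
                        ",".join(row["also_in_models"]) or ".",
                    ]
                )
            )
    (out / "model_candidates.tsv").write_text("\n".join(lines) + "\n")
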