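"""Hotspot flagging, per-sample reports and cohort comparisons.

A :class:`SampleReport` collects one lesion's somatic metrics — mutational
load (filtered SSNVs), TMB, exonic microsatellite indel count, MSI score,
signature exposures, second-hit call and flagged hotspot drivers — each
field taken verbatim from its upstream stage. The cohort report compares
the MMR-deficient and MMR-proficient groups metric by metric with the
pooled two-tailed Student's t test. Group labels are user-declared
metadata (IHC results), never inferred from the data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import group_stats
from .refit import combined_contribution

GROUP_DEFICIENT = "MMR-deficient"
GROUP_PROFICIENT = "MMR-proficient"

MMR_SIGNATURE_PAIR = ("Signature 6", "Signature 15")

#: Metrics compared between groups, in report order.
COHORT_METRICS = ("mutational_load", "tmb", "exonic_ms_indels", "msi_score",
                  "combined_sig6_15")


@dataclass(frozen=True)
class HotspotEntry:
    chrom: str
    pos: int
    ref: str
    alt: str  # "*" matches any alternate allele
    gene: str
    recurrence_count: int

    def matches(self, variant) -> bool:
        return (
            str(variant.chrom) == self.chrom
            and variant.pos == self.pos
            and variant.ref_allele == self.ref
            and (self.alt == "*" or variant.alt_allele == self.alt)
        )


@dataclass
class HotspotTable:
    entries: list

    def __post_init__(self):
        keys = [(e.chrom, e.pos, e.ref, e.alt) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate hotspot entries")
        if any(e.recurrence_count < 1 for e in self.entries):
            raise ValueError("recurrence_count must be >= 1")

    @classmethod
    def from_tsv(cls, path) -> "HotspotTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(
            entries=[
                HotspotEntry(
                    chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
                    gene=r.gene, recurrence_count=int(r.recurrence_count),
                )
                for r in df.itertuples()
            ]
        )


def flag_hotspot_drivers(variants, hotspots: HotspotTable, min_recurrence: int = 3):
    """Moderate/high-impact variants at recurrent hotspot positions.

    Variants without an impact annotation cannot be assessed and are
    tallied, not raised. Returns (flagged variants, n_missing_impact).
    """
    flagged = []
    n_missing = 0
    live = [e for e in hotspots.entries if e.recurrence_count >= min_recurrence]
    for v in variants:
        if v.impact is None:
            n_missing += 1
            continue
        if v.impact not in ("high", "moderate"):
            continue
        if any(e.matches(v) for e in live):
            flagged.append(v)
    return flagged, n_missing


@dataclass
class SampleReport:
    """One lesion's somatic characteristics (a per-sample summary row)."""

    sample_id: str
    group_label: str
    mutational_load: int
    tmb: float
    exonic_ms_indels: int
    msi_score: float
    second_hit: str  # "somatic_mutation", "LOH", "somatic_mutation+LOH" or "none"
    exposures: dict = field(default_factory=dict)
    flagged_drivers: list = field(default_factory=list)

    def __post_init__(self):
        if self.group_label not in (GROUP_DEFICIENT, GROUP_PROFICIENT):
            raise ValueError(f"unknown group label {self.group_label!r}")

    @property
    def combined_sig6_15(self) -> float:
        present = {s: w for s, w in self.exposures.items()}
        total = sum(present.get(s, 0.0) for s in MMR_SIGNATURE_PAIR)
        return 100.0 * total

    def to_json(self, path=None) -> str:
        doc = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(doc)
        return doc

    @classmethod
    def from_json(cls, source) -> "SampleReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


_REQUIRED_STAGES = {
    "mutational_load": "somatic filtering",
    "tmb": "TMB computation",
    "exonic_ms_indels": "microsatellite indel counting",
    "msi_score": "MSI scoring",
    "second_hit": "second-hit classification",
    "exposures": "signature refit",
}


def build_sample_report(sample_id: str, group_label: str, **stage_outputs) -> SampleReport:
    """Assemble a report from completed stage outputs.

    Raises a :class:`ValueError` naming the first missing stage.
    """
    for fld, stage in _REQUIRED_STAGES.items():
        if fld not in stage_outputs or stage_outputs[fld] is None:
            raise ValueError(f"incomplete report: missing {stage} output ({fld!r})")
    second = stage_outputs["second_hit"]
    if isinstance(second, (list, tuple)):
        second = "+".join(second) if second else "none"
    return SampleReport(
        sample_id=sample_id,
        group_label=group_label,
        mutational_load=int(stage_outputs["mutational_load"]),
        tmb=float(stage_outputs["tmb"]),
        exonic_ms_indels=int(stage_outputs["exonic_ms_indels"]),
        msi_score=float(stage_outputs["msi_score"]),
        second_hit=second,
        exposures=dict(stage_outputs["exposures"]),
        flagged_drivers=list(stage_outputs.get("flagged_drivers", [])),
    )


def build_cohort_report(reports, metrics=COHORT_METRICS) -> pd.DataFrame:
    """Group-by-group comparison table over the cohort's metrics.

    For each metric: per-group n/mean/SD plus the pooled two-tailed
    Student's t. Groups with fewer than two samples are skipped with a
    warning column rather than an error.
    """
    rows = []
    for metric in metrics:
        values = {GROUP_DEFICIENT: [], GROUP_PROFICIENT: []}
        for r in reports:
            values[r.group_label].append(getattr(r, metric))
        row = {"metric": metric}
        summaries = {}
        for grp, vals in values.items():
            if vals:
                s = group_stats.summarize(vals)
                summaries[grp] = s
                row[f"{grp}_n"] = s.n
                row[f"{grp}_mean"] = round(s.mean, 1)
                row[f"{grp}_sd"] = round(s.sd, 1) if s.n >= 2 else float("nan")
        if all(g in summaries and summaries[g].n >= 2 for g in values):
            t = group_stats.students_t_test(
                summaries[GROUP_DEFICIENT], summaries[GROUP_PROFICIENT]
            )
            row.update(
                t_statistic=t.t_statistic, df=t.df, p_two_tailed=t.p_two_tailed
            )
        else:
            row["warning"] = "group with n < 2: comparison skipped"
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def cohort_report_tsv(reports, path, metrics=COHORT_METRICS) -> pd.DataFrame:
    df = build_cohort_report(reports, metrics=metrics)
    df.to_csv(path, sep="\t", float_format="%.6g")
    return df
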