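"""Reference cohort handling: CSV I/O, per-site summaries, histogram, percentile.

A cohort is a table of previously scored plans: one row per plan with its
body site, fractionation tag, complexity (mm^-1) and, when known, the
pretreatment-QA outcome.  Summaries group by (site, fractionation) and count
plans above a complexity threshold; "above" is strict (complexity > T), so a
plan exactly at the threshold passes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CohortRecord",
    "GroupStats",
    "CohortSummary",
    "FRACTIONATIONS",
    "SUGGESTED_SITES",
    "load_cohort",
    "save_cohort",
    "cohort_summary",
    "histogram",
    "percentile_of",
    "CohortFormatError",
    "EmptySelectionError",
]

FRACTIONATIONS = ("standard", "SBRT", "unknown")

#: Suggested controlled vocabulary for site labels (free text is accepted).
SUGGESTED_SITES = (
    "head and neck", "brain", "liver", "lung", "prostate", "pelvis",
    "abdomen", "other",
)

_HEADER = ["plan_id", "site", "fractionation", "complexity_mm_inv", "qa_pass"]
_TRUE = {"true", "1", "yes", "pass", "passed"}
_FALSE = {"false", "0", "no", "fail", "failed"}


class CohortFormatError(ValueError):
    """Malformed cohort CSV; message names the offending line."""


class EmptySelectionError(ValueError):
    """No records remain after site filtering."""


@dataclass(frozen=True)
class CohortRecord:
    plan_id: str
    site: str
    fractionation: str  # standard | SBRT | unknown
    complexity: float  # mm^-1, > 0
    qa_pass: bool | None = None  # None = outcome unknown

    def __post_init__(self) -> None:
        if not self.complexity > 0:
            raise ValueError(f"complexity must be > 0, got {self.complexity}")
        if self.fractionation not in FRACTIONATIONS:
            raise ValueError(f"fractionation must be one of {FRACTIONATIONS}")


@dataclass(frozen=True)
class GroupStats:
    """Counts and complexity moments for one (site, fractionation) group.

    ``mean_fail``/``sd_fail`` are ``None`` when undefined: a group with a
    single failing plan reports its mean with no SD; a group with no failing
    plans reports neither (rendered as a dash).
    """

    site: str
    fractionation: str
    n_total: int
    n_fail: int
    n_above: int
    n_fail_above: int
    mean_pass: float | None
    sd_pass: float | None
    mean_fail: float | None
    sd_fail: float | None


@dataclass(frozen=True)
class CohortSummary:
    threshold: float
    overall: GroupStats
    groups: list[GroupStats]


def _parse_qa(text: str, line_no: int) -> bool | None:
    text = text.strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CohortFormatError(f"line {line_no}: unrecognized qa_pass value {text!r}")


def load_cohort(csv_path: str) -> list[CohortRecord]:
    """Read a cohort CSV; raises :class:`CohortFormatError` with line numbers."""
    records: list[CohortRecord] = []
    with open(csv_path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or [f.strip() for f in reader.fieldnames] != _HEADER:
            raise CohortFormatError(
                f"{csv_path}: header must be {','.join(_HEADER)}, "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            line_no = reader.line_num
            try:
                complexity = float(row["complexity_mm_inv"])
            except (TypeError, ValueError):
                raise CohortFormatError(
                    f"line {line_no}: complexity {row.get('complexity_mm_inv')!r} "
                    "is not a number"
                ) from None
            if not complexity > 0 or not math.isfinite(complexity):
                raise CohortFormatError(
                    f"line {line_no}: complexity must be a positive finite "
                    f"number, got {complexity}"
                )
            fx = (row["fractionation"] or "unknown").strip()
            if fx not in FRACTIONATIONS:
                raise CohortFormatError(
                    f"line {line_no}: fractionation {fx!r} not in {FRACTIONATIONS}"
                )
            records.append(
                CohortRecord(
                    plan_id=row["plan_id"].strip(),
                    site=row["site"].strip(),
                    fractionation=fx,
                    complexity=complexity,
                    qa_pass=_parse_qa(row["qa_pass"] or "", line_no),
                )
            )
    return records


def save_cohort(records: list[CohortRecord], csv_path: str) -> None:
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in records:
            qa = "" if r.qa_pass is None else str(r.qa_pass).lower()
            writer.writerow([r.plan_id, r.site, r.fractionation, repr(r.complexity), qa])


def _group_stats(
    site: str, fractionation: str, records: list[CohortRecord], threshold: float
) -> GroupStats:
    above = [r for r in records if r.complexity > threshold]
    failing = [r for r in records if r.qa_pass is False]
    passing = [r for r in records if r.qa_pass is True]

    def moments(rs: list[CohortRecord]) -> tuple[float | None, float | None]:
        if not rs:
            return None, None
        vals = np.array([r.complexity for r in rs])
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1)) if vals.size > 1 else None
        return mean, sd

    mean_pass, sd_pass = moments(passing)
    mean_fail, sd_fail = moments(failing)
    return GroupStats(
        site=site,
        fractionation=fractionation,
        n_total=len(records),
        n_fail=len(failing),
        n_above=len(above),
        n_fail_above=sum(1 for r in failing if r.complexity > threshold),
        mean_pass=mean_pass,
        sd_pass=sd_pass,
        mean_fail=mean_fail,
        sd_fail=sd_fail,
    )


def cohort_summary(records: list[CohortRecord], threshold: float) -> CohortSummary:
    """Per-(site, fractionation) counts and moments at a complexity threshold.

    Unlabeled records count toward totals and above-threshold counts but not
    toward pass/fail statistics.  SDs are sample SDs (ddof=1).
    """
    if not records:
        raise ValueError("cohort is empty")
    keys: list[tuple[str, str]] = []
    by_key: dict[tuple[str, str], list[CohortRecord]] = {}
    for r in records:
        key = (r.site, r.fractionation)
        if key not in by_key:
            by_key[key] = []
            keys.append(key)
        by_key[key].append(r)
    groups = [
        _group_stats(site, fx, by_key[(site, fx)], threshold) for site, fx in keys
    ]
    overall = _group_stats("all", "all", list(records), threshold)
    return CohortSummary(threshold=threshold, overall=overall, groups=groups)


def _filtered(records: list[CohortRecord], site_filter: str) -> list[CohortRecord]:
    if site_filter == "all":
        out = list(records)
    else:
        out = [r for r in records if r.site == site_filter]
    if not out:
        raise EmptySelectionError(f"no records match site filter {site_filter!r}")
    return out


def histogram(
    records: list[CohortRecord], site_filter: str = "all", bin_width: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Complexity histogram with right-open bins [k*w, (k+1)*w) anchored at 0.

    Returns ``(edges, counts)`` with ``len(edges) == len(counts) + 1``;
    counts sum to the number of filtered records.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    vals = np.array([r.complexity for r in _filtered(records, site_filter)])
    idx = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(counts.size + 1) * bin_width
    return edges, counts


def percentile_of(
    m: float, records: list[CohortRecord], site_filter: str = "all"
) -> float:
    """Mid-rank empirical percentile of ``m`` within the filtered cohort."""
    vals = np.array([r.complexity for r in _filtered(records, site_filter)])
    below = np.count_nonzero(vals < m)
    equal = np.count_nonzero(vals == m)
    return 100.0 * (below + 0.5 * equal) / vals.size


def summary_rows(summary: CohortSummary) -> list[dict]:
    """Flatten a summary to rows mirroring the reference-table columns."""
    def row(g: GroupStats) -> dict:
        return {
            "site": g.site,
            "fractionation": g.fractionation,
            "total_plans": g.n_total,
            "failing_plans": g.n_fail,
            "plans_above_threshold": g.n_above,
            "failing_plans_above_threshold": g.n_fail_above,
            "mean_complexity_passing": g.mean_pass,
            "sd_complexity_passing": g.sd_pass,
            "mean_complexity_failing": g.mean_fail,
            "sd_complexity_failing": g.sd_fail,
        }

    return [row(summary.overall)] + [row(g) for g in summary.groups]
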