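"""Likert questionnaire handling: correlation screening and composites.

The modelled survey asks, after each condition, for 1-5 agreement ratings on
items covering willingness to use the decision-support tool and its perceived
impact on work performance.  Items that correlate strongly and positively are
merged into composite indices (arithmetic mean) before the mixed ANOVA; the
screen requires every pairwise Pearson r among a composite's items to be
positive and significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import pearson_r_with_p

logger = logging.getLogger(__name__)

LIKERT_MIN, LIKERT_MAX = 1, 5


@dataclass(frozen=True)
class CompositeSpec:
    """A named ordered list of item ids to merge into one composite index."""

    name: str
    items: tuple[str, ...]
    item_text: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError(f"duplicate items in composite {self.name!r}")


def default_constructs() -> list[CompositeSpec]:
    """Editable default item battery: two acceptability items forming the
    willingness-to-use index and four perceived work-performance items."""
    return [
        CompositeSpec("willingness_to_use", ("wtu_future", "wtu_interface"), {
            "wtu_future": "I would like to use this tool in the future",
            "wtu_interface": "I like the new decision support interface",
        }),
        CompositeSpec("work_performance",
                      ("wp_faster", "wp_accuracy", "wp_performance",
                       "wp_easier"), {
            "wp_faster": "Working with this tool would allow me to solve "
                         "conflicts faster",
            "wp_accuracy": "Working with this tool would increase my "
                           "accuracy in solving conflicts",
            "wp_performance": "Working with this tool would improve my "
                              "performance",
            "wp_easier": "Using this tool would make my work easier",
        }),
    ]


class LikertTable:
    """Long-format 5-point Likert responses.

    One row per subject x condition x item with columns ``subject_id``,
    ``group``, ``condition``, ``item_id``, ``response``.
    """

    COLUMNS = ("subject_id", "group", "condition", "item_id", "response")

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"LikertTable missing columns {missing}")
        frame = frame.loc[:, list(self.COLUMNS)].copy()
        resp = frame["response"]
        if not resp.between(LIKERT_MIN, LIKERT_MAX).all():
            raise ValueError("responses must lie in {1,...,5}")
        dup = frame.duplicated(["subject_id", "condition", "item_id"])
        if dup.any():
            raise ValueError("more than one response per "
                             "subject x condition x item")
        self.frame = frame

    def items(self) -> list[str]:
        return sorted(self.frame["item_id"].unique())

    def wide(self, items: list[str] | None = None) -> pd.DataFrame:
        """Observations (subject x condition rows) by item columns."""
        wide = self.frame.pivot(index=["subject_id", "condition"],
                                columns="item_id", values="response")
        if items is not None:
            wide = wide.loc[:, list(items)]
        return wide

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson r / two-sided p over pooled observations."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flagged: list[str]           # zero-variance items (r undefined)

    @property
    def items(self) -> list[str]:
        return list(self.r.index)


def correlation_matrix(table: LikertTable,
                       items: list[str] | None = None) -> CorrelationMatrix:
    """Pearson correlations between items over all subject x condition
    observations (pooled across conditions); p from the t transform of r
    with n - 2 degrees of freedom."""
    items = items if items is not None else table.items()
    wide = table.wide(items)
    k = len(items)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(wide))
    flagged = [it for it in items if wide[it].std(ddof=1) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[items[i], items[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < 3:
                raise ValueError(
                    f"fewer than 3 complete observations for pair "
                    f"({items[i]!r}, {items[j]!r})")
            if items[i] in flagged or items[j] in flagged:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rij, pij = pearson_r_with_p(pair[items[i]].to_numpy(float),
                                        pair[items[j]].to_numpy(float))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = pd.Index(items, name="item_id")
    return CorrelationMatrix(pd.DataFrame(r, idx, idx),
                             pd.DataFrame(p, idx, idx),
                             pd.DataFrame(n, idx, idx), flagged)


@dataclass
class MergeDecision:
    approved: bool
    report: pd.DataFrame         # one row per item pair: r, p, passes
    alpha: float


def validate_merge(matrix: CorrelationMatrix, spec: CompositeSpec,
                   alpha: float = 0.001) -> MergeDecision:
    """Approve merging ``spec``'s items iff every pairwise r is positive
    with p below ``alpha``.  Rejection is a valid outcome; the report lists
    each pair's r and p either way."""
    missing = [it for it in spec.items if it not in matrix.items]
    if missing:
        raise ValueError(f"items not in correlation matrix: {missing}")
    rows = []
    for i, a in enumerate(spec.items):
        for b in spec.items[i + 1:]:
            r = matrix.r.loc[a, b]
            p = matrix.p.loc[a, b]
            ok = bool(np.isfinite(r) and r > 0 and p < alpha)
            rows.append({"item_a": a, "item_b": b, "r": r, "p": p,
                         "passes": ok})
    report = pd.DataFrame(rows)
    approved = bool(report["passes"].all()) and len(report) > 0
    if not approved:
        bad = report.loc[~report["passes"]]
        logger.info("merge of %r rejected; offending pairs:\n%s",
                    spec.name, bad.to_string(index=False))
    return MergeDecision(approved, report, alpha)


def build_composite(table: LikertTable, spec: CompositeSpec,
                    decision: MergeDecision | None = None,
                    force: bool = False, method: str = "mean") -> pd.DataFrame:
    """Composite value per subject x condition.

    ``method``: ``mean`` (default, unweighted item mean), ``sum``, or
    ``zmean`` (mean of per-item z-scores).  Rows with a missing item
    response are dropped with a warning.
    """
    if decision is not None and not decision.approved and not force:
        raise ValueError(
            f"merge of {spec.name!r} was not approved; pass force=True to "
            "override")
    if decision is not None and not decision.approved and force:
        logger.warning("building composite %r despite failed correlation "
                       "screen (forced override)", spec.name)
    wide = table.wide(list(spec.items))
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        logger.warning("dropping %d observation(s) with missing responses "
                       "for composite %r", int(incomplete.sum()), spec.name)
        wide = wide.loc[~incomplete]
    if method == "mean":
        values = wide.mean(axis=1)
    elif method == "sum":
        values = wide.sum(axis=1)
    elif method == "zmean":
        values = ((wide - wide.mean()) / wide.std(ddof=1)).mean(axis=1)
    else:
        raise ValueError(f"unknown composite method {method!r}")
    out = values.rename(spec.name).reset_index()
    groups = table.frame.drop_duplicates("subject_id")[
        ["subject_id", "group"]]
    out = out.merge(groups, on="subject_id")
    return out[["subject_id", "group", "condition", spec.name]]


def cronbach_alpha(table: LikertTable, spec: CompositeSpec) -> float:
    """Informational internal-consistency diagnostic for a composite."""
    wide = table.wide(list(spec.items)).dropna()
    k = len(spec.items)
    item_vars = wide.var(ddof=1)
    total_var = wide.sum(axis=1).var(ddof=1)
    if total_var == 0:
        return float("nan")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))
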