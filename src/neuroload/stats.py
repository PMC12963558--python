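"""Mixed-design 2x2 repeated-measures ANOVA and Duncan post-hoc test.

The design handled here is fixed: one two-level within-subject factor (the
explainability condition each subject experiences twice) and one two-level
between-subject factor (expertise group), with possibly unequal group sizes.
Sums of squares use the unweighted-cell-means formulation, which coincides
with Type III sums of squares for this design; with two within levels no
sphericity correction applies.

The decomposition, written for subject i in group g with condition values
:math:`y_{i1}, y_{i2}`, subject mean :math:`M_i` and difference
:math:`D_i = y_{i1} - y_{i2}`:

* between stratum (on subject means, times the 2 conditions):
  ``SS_group`` and ``SS_between_resid`` from the one-way decomposition of
  :math:`M_i` by group;
* within stratum (on differences): the condition main effect tests the
  *unweighted* mean of the group difference means
  :math:`(\\bar D_1 + \\bar D_2)/2`, the interaction tests
  :math:`\\bar D_1 - \\bar D_2`, and the within residual is the pooled
  within-group variation of :math:`D_i`.

Two eta-squared conventions are reported for every testable source:
``classical`` (SS over the total of all five SS rows) and ``partial``
(SS over SS plus the residual SS of the source's own stratum).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

WITHIN_SOURCES = ("condition", "interaction", "within_resid")
BETWEEN_SOURCES = ("group", "between_resid")
RESIDUAL_OF = {"condition": "within_resid", "interaction": "within_resid",
               "group": "between_resid"}


def p_from_f(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F distribution."""
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(sps.f.sf(F, df1, df2))


def pearson_r_with_p(x, y) -> tuple[float, float]:
    """Pearson r with the two-sided p from the t transform of r
    (``t = r sqrt((n-2)/(1-r^2))`` on n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def format_p(p: float) -> str:
    """Three-decimal p-value string with '< .001' below a thousandth."""
    if p < 0.001:
        return "< .001"
    return f"{p:.3f}"


@dataclass
class AnovaTable:
    """Five-row mixed 2x2 ANOVA decomposition.

    ``table`` is indexed by source key (``condition``, ``interaction``,
    ``within_resid``, ``group``, ``between_resid``) with columns
    ``SS, df, MS, F, p, eta2_classical, eta2_partial`` (NaN where a column
    does not apply to a residual row).
    """

    table: pd.DataFrame
    n_subjects: int
    group_sizes: dict
    labels: dict = field(default_factory=dict)

    def source(self, key: str) -> pd.Series:
        return self.table.loc[key]

    def formatted(self, within_label: str = "Explainability",
                  between_label: str = "Expertise",
                  eta_convention: str = "partial") -> pd.DataFrame:
        """Publication-style table with labelled sources and formatted p."""
        names = {
            "condition": within_label,
            "interaction": f"{within_label} x {between_label}",
            "within_resid": "Residuals",
            "group": between_label,
            "between_resid": "Residuals",
        }
        rows = []
        for key in (*WITHIN_SOURCES, *BETWEEN_SOURCES):
            r = self.table.loc[key]
            rows.append({
                "Stratum": ("Within-subjects" if key in WITHIN_SOURCES
                            else "Between-subjects"),
                "Source": names[key],
                "Sum of squares": r["SS"],
                "df": int(r["df"]),
                "Mean square": r["MS"],
                "F": r["F"],
                "p": format_p(r["p"]) if np.isfinite(r["p"]) else "",
                "eta2": r[f"eta2_{eta_convention}"],
            })
        return pd.DataFrame(rows)


def _stats_from_ss(ss: dict, df: dict) -> pd.DataFrame:
    """MS, F, p and both eta-squared conventions from the five SS/df rows."""
    rows = {}
    total_ss = sum(ss.values())
    for key in (*WITHIN_SOURCES, *BETWEEN_SOURCES):
        ms = ss[key] / df[key] if df[key] > 0 else np.nan
        rows[key] = {"SS": ss[key], "df": df[key], "MS": ms,
                     "F": np.nan, "p": np.nan,
                     "eta2_classical": np.nan, "eta2_partial": np.nan}
    for key, resid in RESIDUAL_OF.items():
        ms_err = rows[resid]["MS"]
        ms_src = rows[key]["MS"]
        if ms_err == 0 or not np.isfinite(ms_err):
            if ss[key] == 0:
                F, p = 0.0, 1.0
            else:
                F, p = math.inf, 0.0
                logger.warning("zero residual mean square for %s: "
                               "F reported as infinite", key)
        else:
            F = ms_src / ms_err
            p = p_from_f(F, df[key], df[resid])
        rows[key]["F"] = F
        rows[key]["p"] = p
        rows[key]["eta2_classical"] = (ss[key] / total_ss
                                       if total_ss > 0 else 0.0)
        denom = ss[key] + ss[resid]
        rows[key]["eta2_partial"] = ss[key] / denom if denom > 0 else 0.0
    return pd.DataFrame(rows).T[
        ["SS", "df", "MS", "F", "p", "eta2_classical", "eta2_partial"]]


def mixed_anova_2x2(data: pd.DataFrame, dv: str = "value",
                    within: str = "condition", between: str = "group",
                    subject: str = "subject_id") -> AnovaTable:
    """Unweighted-means (Type III-equivalent) mixed 2x2 ANOVA.

    ``data`` is long format: one row per subject x condition, each subject
    in exactly one group, both condition values present for every subject.
    """
    for col in (dv, within, between, subject):
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from data")
    conds = sorted(data[within].unique())
    groups = sorted(data[between].unique())
    if len(conds) != 2 or len(groups) != 2:
        raise ValueError("design must have exactly 2 within levels and "
                         "2 groups")
    wide = data.pivot_table(index=subject, columns=within, values=dv,
                            aggfunc="first")
    if wide.isna().any().any():
        bad = wide.index[wide.isna().any(axis=1)].tolist()
        raise ValueError(f"incomplete within-subject data for {bad}")
    grp = data.drop_duplicates(subject).set_index(subject)[between]
    if data.groupby(subject)[between].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    grp = grp.loc[wide.index]
    sizes = {g: int((grp == g).sum()) for g in groups}
    if min(sizes.values()) < 2:
        raise ValueError("need at least 2 subjects per group")

    values = wide.to_numpy(float)
    M = values.mean(axis=1)                      # subject means
    D = values[:, 0] - values[:, 1]              # condition differences
    n1, n2 = sizes[groups[0]], sizes[groups[1]]
    in_g1 = (grp == groups[0]).to_numpy()

    # between stratum (x2: each subject mean summarises two observations)
    m1, m2 = M[in_g1].mean(), M[~in_g1].mean()
    grand = M.mean()
    ss_group = 2.0 * (n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2)
    ss_bresid = 2.0 * (((M[in_g1] - m1) ** 2).sum()
                       + ((M[~in_g1] - m2) ** 2).sum())

    # within stratum (on differences; /2 converts to the observation metric)
    d1, d2 = D[in_g1].mean(), D[~in_g1].mean()
    inv_n = 1.0 / n1 + 1.0 / n2
    ss_cond = 2.0 * ((d1 + d2) / 2.0) ** 2 / inv_n
    ss_inter = 0.5 * (d1 - d2) ** 2 / inv_n
    ss_wresid = 0.5 * (((D[in_g1] - d1) ** 2).sum()
                       + ((D[~in_g1] - d2) ** 2).sum())

    N = n1 + n2
    ss = {"condition": ss_cond, "interaction": ss_inter,
          "within_resid": ss_wresid, "group": ss_group,
          "between_resid": ss_bresid}
    df = {"condition": 1, "interaction": 1, "within_resid": N - 2,
          "group": 1, "between_resid": N - 2}
    table = _stats_from_ss(ss, df)
    return AnovaTable(table, N, sizes,
                      labels={"within_levels": conds, "groups": groups})


def eta_squared(table: AnovaTable, convention: str = "partial"
                ) -> dict[str, float]:
    """Per-source eta squared under the requested convention."""
    if convention not in ("classical", "partial"):
        raise ValueError("convention must be 'classical' or 'partial'")
    col = f"eta2_{convention}"
    return {key: float(table.table.loc[key, col]) for key in RESIDUAL_OF}


# ---------------------------------------------------------------------------
# Duncan's multiple range test


def q_duncan(span: int, df_error: int, alpha: float = 0.05) -> float:
    """Duncan significant-range quantile: the studentized-range quantile at
    the protection level ``1 - (1 - alpha)^(span - 1)``."""
    if span < 2:
        raise ValueError("span must be >= 2")
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    return float(sps.studentized_range.ppf(1.0 - alpha_p, span, df_error))


@dataclass
class DuncanResult:
    """Stepwise Duncan comparisons of cell means (descending order)."""

    order: list                  # labels sorted by descending mean
    means: np.ndarray            # sorted means
    comparisons: pd.DataFrame    # per pair: diff, span, critical, significant
    alpha: float
    ms_error: float
    df_error: int


def duncan_mrt(cell_means, cell_ns, ms_error: float, df_error: int,
               alpha: float = 0.05, labels=None) -> DuncanResult:
    """Duncan's multiple range test.

    A comparison spanning ``p`` ordered means uses the critical range
    ``q_duncan(p, df_error, alpha) * sqrt(ms_error / n_h)`` with ``n_h``
    the harmonic mean of the two compared cell sizes; the standard
    non-crossing rule suppresses any pair contained in a wider
    non-significant span.
    """
    means = np.asarray(cell_means, dtype=float)
    ns = np.asarray(cell_ns, dtype=float)
    if means.size < 2:
        raise ValueError("need at least 2 means")
    if means.size != ns.size:
        raise ValueError("cell_means and cell_ns must have equal length")
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    labels = list(labels) if labels is not None else \
        [f"cell{i}" for i in range(means.size)]
    order = np.argsort(-means, kind="stable")
    sm = means[order]
    sn = ns[order]
    slab = [labels[i] for i in order]
    k = means.size

    nonsig_spans: list[tuple[int, int]] = []
    rows = []
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            diff = sm[i] - sm[j]
            n_h = 2.0 / (1.0 / sn[i] + 1.0 / sn[j])
            crit = q_duncan(span, df_error, alpha) \
                * math.sqrt(ms_error / n_h)
            blocked = any(a <= i and j <= b for a, b in nonsig_spans)
            significant = (not blocked) and diff > crit
            if not significant:
                nonsig_spans.append((i, j))
            rows.append({"a": slab[i], "b": slab[j], "diff": diff,
                         "span": span, "critical_range": crit,
                         "blocked": blocked, "significant": significant})
    comparisons = pd.DataFrame(rows)
    return DuncanResult(slab, sm, comparisons, alpha, ms_error, df_error)


# ---------------------------------------------------------------------------
# printed-table verification


def load_printed_tables() -> dict:
    """The four published ANOVA tables (SS/df plus printed F, p, eta2),
    shipped as package data."""
    text = resources.files("neuroload").joinpath(
        "data/printed_tables.json").read_text()
    return json.loads(text)


def verify_printed_table(printed: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct MS, F, p and both eta-squared conventions from a printed
    table's SS/df rows and compare with its printed F/p/eta2.

    ``printed`` must carry ``sources``: a mapping of the five source keys to
    ``{"ss": ..., "df": ...}`` plus, for testable sources, printed ``F``,
    ``p`` (number or the string "< .001") and ``eta2``; and
    ``eta_convention``: which convention the printed eta2 column follows.

    Returns the reconstructed table and a comparison report with absolute
    differences.
    """
    src = printed["sources"]
    ss = {k: float(src[k]["ss"]) for k in (*WITHIN_SOURCES, *BETWEEN_SOURCES)}
    df = {k: int(src[k]["df"]) for k in (*WITHIN_SOURCES, *BETWEEN_SOURCES)}
    table = _stats_from_ss(ss, df)
    convention = printed.get("eta_convention", "partial")
    rows = []
    for key in RESIDUAL_OF:
        rec = src[key]
        comp = table.loc[key]
        printed_p = rec.get("p")
        if isinstance(printed_p, str):
            p_ok = comp["p"] < 0.001 if "<" in printed_p else np.nan
            p_diff = np.nan
        else:
            p_ok = None
            p_diff = abs(comp["p"] - printed_p) if printed_p is not None \
                else np.nan
        rows.append({
            "source": key,
            "F_printed": rec.get("F"), "F_computed": comp["F"],
            "F_absdiff": (abs(comp["F"] - rec["F"])
                          if rec.get("F") is not None else np.nan),
            "p_printed": printed_p, "p_computed": comp["p"],
            "p_absdiff": p_diff, "p_below_printed_bound": p_ok,
            "eta2_printed": rec.get("eta2"),
            "eta2_convention": convention,
            "eta2_computed": comp[f"eta2_{convention}"],
            "eta2_absdiff": (abs(comp[f"eta2_{convention}"] - rec["eta2"])
                             if rec.get("eta2") is not None else np.nan),
            "eta2_classical": comp["eta2_classical"],
            "eta2_partial": comp["eta2_partial"],
        })
    return table, pd.DataFrame(rows)


def verify_all_printed_tables(tol_f: float = 5e-4, tol_eta: float = 1e-3
                              ) -> tuple[pd.DataFrame, bool]:
    """Run :func:`verify_printed_table` on every packaged table.

    Agreement is assessed at one unit in the last printed digit (the printed
    sums of squares are themselves rounded to three decimals, so exact
    half-ulp agreement is not attainable for every cell).  Returns the
    concatenated report and an overall pass flag.
    """
    tables = load_printed_tables()
    reports = []
    ok = True
    for name, printed in tables.items():
        _, report = verify_printed_table(printed)
        report.insert(0, "table", name)
        strict_f = printed.get("strict_f_sources", [])
        for _, row in report.iterrows():
            if np.isfinite(row["eta2_absdiff"]):
                tol = max(tol_eta, 0.55 * 10.0 ** -_printed_decimals(
                    row["eta2_printed"]))
                if row["eta2_absdiff"] > tol:
                    ok = False
            if row["source"] in strict_f and np.isfinite(row["F_absdiff"]):
                if row["F_absdiff"] > tol_f:
                    ok = False
            if row["p_below_printed_bound"] is False:
                ok = False
        reports.append(report)
    return pd.concat(reports, ignore_index=True), ok


def _printed_decimals(value) -> int:
    """Number of significant decimals a printed value carries (3 for the
    tables' fixed-point entries; more for scientific-notation entries)."""
    if value is None:
        return 3
    s = f"{value:g}"
    if "e" in s or "E" in s:
        return 12        # scientific notation: compare at fine precision
    if "." in s:
        return len(s.split(".")[1])
    return 0
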