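"""Group statistics and report assembly.

Two tests cover every comparison in this workflow: a two-sided Fisher exact
test for phenotype-by-genotype contingency (valid at any sample size) and a
two-sided Mann-Whitney rank test for continuous readouts with non-Gaussian
distributions and unequal variances.  The two-sided Fisher p-value is the
sum of hypergeometric probabilities of all tables with the observed margins
that are no more probable than the observed table (with a 1 + 1e-7 relative
guard against floating-point ties).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]] with optional row/column labels."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("group 1", "group 2")
    col_labels: tuple[str, str] = ("outcome +", "outcome -")

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table total must be >= 1")

    @property
    def counts(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_sided(table: ContingencyTable2x2 | np.ndarray) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    A zero margin makes the table degenerate (only one table is compatible
    with the margins) and returns p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable2x2) else np.asarray(table, int)
    if counts.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        return 1.0
    _, p = sstats.fisher_exact(counts, alternative="two-sided")
    return float(min(p, 1.0))


#: exact Mann-Whitney enumeration is used up to this combined sample size
MW_EXACT_MAX_N = 16


def mann_whitney_two_sided(x, y) -> dict:
    """Two-sided Mann-Whitney U test with midranks.

    Exact null distribution (enumeration over labelings) when the combined
    sample size is at most ``MW_EXACT_MAX_N`` and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    Returns ``{"U": U of x, "p": p, "method": ...}``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= MW_EXACT_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sstats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return {"U": float(res.statistic), "p": float(res.pvalue), "method": method}


def counts_from_percent(percent: float, n: int) -> int:
    """Reconstruct an integer count from a reported percentage and n.

    Rounds half to even.  Warns when the implied count is more than 0.5 away
    from ``percent * n / 100`` — an internally inconsistent report.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    value = percent * n / 100.0
    count = int(round(value))
    if abs(count - value) > 0.5:
        warnings.warn(
            f"{percent}% of n={n} implies {value:.3f}, not an integer within 0.5",
            stacklevel=2,
        )
    return count


def significance_stars(p: float) -> str:
    """Star label at the conventional strict thresholds; 'ns' at p >= 0.05."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def format_p(p: float) -> str:
    """4 decimals for p >= 1e-4, else scientific with 4 significant digits."""
    if p >= 1e-4:
        return f"{p:.4f}"
    return f"{p:.3e}"


def build_report(
    records=None,
    traces=None,
    tables: list[ContingencyTable2x2] | None = None,
    comparisons: list[dict] | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble a results bundle from any mix of pipeline outputs.

    ``records`` — asymmetry records (timeline fractions, inverted fraction,
    ratio medians); ``traces`` — FRAP traces (per-trace recovery metrics);
    ``tables`` — contingency tables (Fisher tests); ``comparisons`` — dicts
    ``{"name", "x", "y"}`` of samples for Mann-Whitney tests.  Raises when
    every input is empty.
    """
    from .asymmetry import inverted_fraction, timeline_fractions
    from .dynamics import recovery_metrics, sn_series

    if not records and not traces and not tables and not comparisons:
        raise ValueError("nothing to report")
    report: dict = {"config": config or {}}

    if records:
        tf = timeline_fractions(list(records))
        ratios = [r.ratio for r in records if r.ratio is not None and math.isfinite(r.ratio)]
        frac, n_inv, n_elig = inverted_fraction(list(records))
        counts: dict[str, int] = {}
        for r in records:
            counts[r.category] = counts.get(r.category, 0) + 1
        report["asymmetry"] = {
            "n_records": len(records),
            "category_counts": counts,
            "timeline_fractions": tf.to_dict(orient="records"),
            "ratio_median": float(np.median(ratios)) if ratios else None,
            "inverted_fraction": frac if n_elig else None,
            "inverted_n": [n_inv, n_elig],
        }

    if traces:
        trace_rows = []
        for i, tr in enumerate(traces):
            row: dict = {"trace": i, "n_frames": len(tr.times)}
            if tr.bleach_frame is not None and tr.bleach_frame >= 3:
                m = recovery_metrics(sn_series(tr), tr.times, tr.bleach_frame)
                row.update(pre_mean=m["pre_mean"], post_min=m["post_min"],
                           half_time=m["half_time"])
            trace_rows.append(row)
        report["frap"] = {"n_traces": len(traces), "traces": trace_rows}

    if tables:
        fisher_rows = []
        for t in tables:
            p = fisher_exact_two_sided(t)
            fisher_rows.append(
                dict(rows=list(t.row_labels), cols=list(t.col_labels),
                     counts=t.counts.tolist(), p=p, p_display=format_p(p),
                     stars=significance_stars(p), n=int(t.counts.sum()),
                     test="Fisher exact (two-sided)")
            )
        report["fisher_tests"] = fisher_rows

    if comparisons:
        mw_rows = []
        for cmp_ in comparisons:
            x, y = np.asarray(cmp_["x"], float), np.asarray(cmp_["y"], float)
            res = mann_whitney_two_sided(x, y)
            mw_rows.append(
                dict(name=cmp_.get("name", ""), U=res["U"], p=res["p"],
                     p_display=format_p(res["p"]), stars=significance_stars(res["p"]),
                     n=[len(x), len(y)],
                     medians=[float(np.median(x)), float(np.median(y))],
                     test=f"Mann-Whitney (two-sided, {res['method']})")
            )
        report["mann_whitney_tests"] = mw_rows

    return report
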