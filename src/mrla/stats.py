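"""Statistical layer of the study applied to a tidy measurement table.

Continuous variables are summarized as median [interquartile range]; within-
group phase effects use the paired Wilcoxon signed-rank test; between-group
comparisons use Student's t or the exact Mann-Whitney U test. The signed-
rank p-value is exact (tie-aware, via dynamic programming over the signed
midrank distribution) up to n = 25 paired differences and uses the normal
approximation with continuity correction above. No multiple-testing
correction is applied (none is used in the source analysis); this is noted
in the summary metadata.

Also includes the comparative-threshold-cycle (2^dCt) fold change used for
qPCR gene expression normalized to a housekeeping gene.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


# ------------------------------------------------------- exact signed-rank
def _signed_rank_exact_p(d: np.ndarray) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value, ties allowed.

    Midranks are doubled to integers; the null distribution of W+ (sum of
    positive signed ranks) is built by convolution over the 2^n equiprobable
    sign assignments. Two-sided p = min(1, 2*min(P(W+<=w), P(W+>=w))).
    """
    ranks = sps.rankdata(np.abs(d))          # midranks, possibly k.5
    r2 = np.round(2.0 * ranks).astype(int)   # doubled -> integers
    total = int(r2.sum())
    # distribution of doubled W+ over sign assignments
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(np.round(2.0 * float(np.sum(ranks[d > 0]))))
    lo = float(dist[: w2 + 1].sum())
    hi = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lo, hi))


def paired_compare(x, y, exact_max_n: int = 25) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for phase A vs phase B.

    Zero differences are dropped (Wilcoxon's rule); if all differences are
    zero the samples are indistinguishable and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired_compare needs two equal-length 1-D samples")
    if len(x) < 3:
        raise StatsError("paired_compare needs n >= 3 pairs")
    d = x - y
    d = d[d != 0.0]
    if len(d) == 0:
        return 1.0
    if len(d) <= exact_max_n:
        return _signed_rank_exact_p(d)
    res = sps.wilcoxon(d, alternative="two-sided", correction=True,
                       method="approx")
    return float(res.pvalue)


def group_compare(x, y, method: str = "mann-whitney") -> float:
    """Two-sided p for two independent samples: Student's t or Mann-Whitney U.

    Mann-Whitney is exact when min(n) <= 8 and the data are tie-free,
    asymptotic (tie-corrected) otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise StatsError("group_compare needs two 1-D samples with n >= 2")
    if method == "t":
        if np.var(x) == 0.0 and np.var(y) == 0.0:
            raise StatsError("t test undefined for zero-variance input")
        res = sps.ttest_ind(x, y, equal_var=True)
        return float(res.pvalue)
    if method == "mann-whitney":
        pooled = np.concatenate([x, y])
        has_ties = len(np.unique(pooled)) < len(pooled)
        mode = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) \
            else "asymptotic"
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=mode)
        return float(res.pvalue)
    raise StatsError(f"unknown method {method!r} (use 't' or 'mann-whitney')")


def relative_expression(ct_target, ct_reference) -> float:
    """qPCR fold change by the comparative threshold-cycle method:
    2^(Ct_reference - Ct_target)."""
    ct_target = float(ct_target)
    ct_reference = float(ct_reference)
    for name, v in (("ct_target", ct_target), ("ct_reference", ct_reference)):
        if not math.isfinite(v) or v <= 0:
            raise StatsError(f"{name} must be finite and > 0, got {v}")
    return 2.0 ** (ct_reference - ct_target)


# ------------------------------------------------------------- summaries
def format_cell(median: float, q1: float, q3: float,
                significant: bool = False) -> str:
    """Render one summary cell like ``40 [37-42]`` (dagger when significant)."""

    def fmt(v: float) -> str:
        return f"{v:.3g}"

    mark = "†" if significant else ""
    return f"{fmt(median)} [{fmt(q1)}–{fmt(q3)}]{mark}"


_CELL_RE = re.compile(
    r"^\s*(-?[\d.]+)\s*\[\s*(-?[\d.]+)\s*–\s*(-?[\d.]+)\s*\]"
    r"(†?)\s*$")


def parse_cell(cell: str) -> tuple[float, float, float, bool]:
    m = _CELL_RE.match(cell)
    if not m:
        raise StatsError(f"unparsable summary cell: {cell!r}")
    return (float(m.group(1)), float(m.group(2)), float(m.group(3)),
            m.group(4) == "†")


@dataclass
class SummaryTable:
    """Per (group, phase, parameter) summary with baseline comparison flags."""

    data: pd.DataFrame      # columns: group, phase, parameter, n, median,
    #                         q1, q3, p_vs_baseline, significant, tested
    metadata: dict

    def cell(self, group: str, phase: str, parameter: str) -> str:
        d = self.data
        row = d[(d["group"] == group) & (d["phase"] == phase)
                & (d["parameter"] == parameter)]
        if len(row) != 1:
            raise StatsError(f"no cell for ({group}, {phase}, {parameter})")
        r = row.iloc[0]
        return format_cell(r["median"], r["q1"], r["q3"], bool(r["significant"]))

    def to_wide(self) -> pd.DataFrame:
        """One row per parameter, one column per group/phase, cells formatted."""
        d = self.data
        cols = {}
        for (g, ph), _sub in d.groupby(["group", "phase"], sort=False):
            cols[f"{g}/{ph}"] = {
                p: self.cell(g, ph, p)
                for p in d[d["group"] == g]["parameter"].unique()}
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_wide().to_csv(path, index_label="parameter")


def _phase_order(table: pd.DataFrame, group: str) -> list[str]:
    sub = table[table["group"] == group]
    seen: list[str] = []
    for ph in sub["phase"]:
        if ph not in seen:
            seen.append(ph)
    return seen


def summarize(table: pd.DataFrame, alpha: float = 0.05,
              min_n: int = 3) -> SummaryTable:
    """Median [Q1-Q3] per (group, phase, parameter) with paired baseline flags.

    The first phase of each group is its baseline. The paired comparison
    uses only animals measured at both phases; phases with fewer than
    ``min_n`` such pairs are flagged untested.
    """
    required = {"animal_id", "group", "phase", "parameter", "value"}
    missing = required - set(table.columns)
    if missing:
        raise StatsError(f"measurement table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise StatsError("empty measurement table")
    rows = []
    for group in table["group"].unique():
        sub = table[table["group"] == group]
        phases = _phase_order(table, group)
        baseline = phases[0]
        for parameter in sorted(sub["parameter"].unique()):
            psub = sub[sub["parameter"] == parameter]
            base = psub[psub["phase"] == baseline].set_index("animal_id")["value"]
            for phase in phases:
                cell = psub[psub["phase"] == phase].set_index("animal_id")["value"]
                p_val = np.nan
                tested = False
                if phase != baseline:
                    common = base.index.intersection(cell.index)
                    if len(common) >= min_n:
                        p_val = paired_compare(base.loc[common].to_numpy(),
                                               cell.loc[common].to_numpy())
                        tested = True
                rows.append({
                    "group": group, "phase": phase, "parameter": parameter,
                    "n": int(len(cell)),
                    "median": float(cell.median()),
                    "q1": float(cell.quantile(0.25)),
                    "q3": float(cell.quantile(0.75)),
                    "p_vs_baseline": p_val,
                    "significant": bool(tested and p_val < alpha),
                    "tested": tested,
                })
    data = pd.DataFrame(rows)
    meta = {"alpha": alpha, "test": "wilcoxon-signed-rank (paired, exact)",
            "multiple_testing_correction": "none"}
    return SummaryTable(data=data, metadata=meta)
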