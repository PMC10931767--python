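"""Group-level inference on high-activity proportions.

This is the drug-screening readout: each crispant (or treated) group's
fraction of seizure-like flash responses is compared against a reference
group with exact binary-sampling tests — an exact binomial test against
the reference proportion, or Fisher's exact test when expected cell
counts are small.  One-sided alternatives encode the directional
hypotheses: *greater* for crispant-vs-control (seizure enrichment),
*less* for treated-vs-vehicle (drug protection).

Responses (not larvae) are the sampling unit throughout, mirroring how
the screening summaries are tabulated; within-larva correlation of the
five flash responses is therefore ignored (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["TestResult", "binomial_vs_reference", "fisher_exact",
           "compare_high_activity"]

_ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class TestResult:
    comparison: str
    test: str                 # "binomial" | "fisher"
    statistic: float          # observed proportion, or odds ratio for fisher
    p_value: float
    alternative: str
    n_high: int
    n_total: int
    ref_high: int | None = None
    ref_total: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _check_alternative(alternative: str) -> str:
    alt = alternative.replace("_", "-")
    if alt not in _ALTERNATIVES:
        raise ValidationError(f"alternative must be one of {_ALTERNATIVES}")
    return alt


def binomial_vs_reference(n_high: int, n_total: int, p0: float,
                          alternative: str = "greater",
                          comparison: str = "") -> TestResult:
    """Exact binomial test of ``n_high`` successes in ``n_total`` trials
    against a fixed reference proportion ``p0``."""
    alternative = _check_alternative(alternative)
    if not 0 <= n_high <= n_total or n_total <= 0:
        raise ValidationError(f"bad counts {n_high}/{n_total}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"reference proportion must be in (0, 1), got {p0}")
    res = stats.binomtest(int(n_high), int(n_total), p0, alternative=alternative)
    return TestResult(comparison=comparison, test="binomial",
                      statistic=float(n_high) / n_total, p_value=float(res.pvalue),
                      alternative=alternative, n_high=int(n_high), n_total=int(n_total))


def fisher_exact(table, alternative: str = "two-sided",
                 comparison: str = "") -> TestResult:
    """Fisher's exact test on a 2x2 count table
    ``[[high_a, low_a], [high_b, low_b]]``."""
    alternative = _check_alternative(alternative)
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or np.any(table != np.round(table)):
        raise ValidationError("fisher_exact needs a 2x2 table of non-negative integers")
    if table.sum() == 0:
        raise ValidationError("all-zero table")
    table = table.astype(int)
    odds, p = stats.fisher_exact(table, alternative=alternative)
    return TestResult(comparison=comparison, test="fisher",
                      statistic=float(odds), p_value=float(p),
                      alternative=alternative,
                      n_high=int(table[0, 0]), n_total=int(table[0].sum()),
                      ref_high=int(table[1, 0]), ref_total=int(table[1].sum()))


def compare_high_activity(summaries: pd.DataFrame, reference_group: str,
                          alternative: str = "greater",
                          min_expected: float = 5.0) -> pd.DataFrame:
    """Compare every group's high-activity proportion to a reference group.

    Test choice per comparison: Fisher's exact when any expected cell
    count of the 2x2 table is below ``min_expected``, else an exact
    binomial test against the reference proportion (treated as fixed).
    Returns one row per non-reference group with the chosen test logged.
    """
    alternative = _check_alternative(alternative)
    required = {"group_label", "n_responses", "n_high"}
    if not required.issubset(summaries.columns):
        raise ValidationError(f"summaries need columns {sorted(required)}")
    ref = summaries[summaries["group_label"] == reference_group]
    if len(ref) != 1:
        raise ValidationError(f"reference group {reference_group!r} not found "
                              "(or duplicated) in summaries")
    k_r = int(ref["n_high"].iloc[0])
    n_r = int(ref["n_responses"].iloc[0])
    rows = []
    for row in summaries.itertuples(index=False):
        if row.group_label == reference_group:
            continue
        k_g, n_g = int(row.n_high), int(row.n_responses)
        table = np.array([[k_g, n_g - k_g], [k_r, n_r - k_r]], dtype=float)
        n_tot = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n_tot
        name = f"{row.group_label} vs {reference_group}"
        if expected.min() < min_expected or not 0 < k_r < n_r:
            res = fisher_exact(table, alternative=alternative, comparison=name)
        else:
            res = binomial_vs_reference(k_g, n_g, k_r / n_r,
                                        alternative=alternative, comparison=name)
            res = TestResult(**{**res.to_dict(), "ref_high": k_r, "ref_total": n_r})
        d = res.to_dict()
        d["min_expected_cell"] = float(expected.min())
        rows.append(d)
    return pd.DataFrame(rows)
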