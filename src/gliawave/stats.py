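"""Statistical comparisons used on the pipeline outputs.

Chi-square goodness-of-fit (nonuniformity of process distribution across IPL
sublayers), chi-square for independent proportions (age or condition
differences), Wilcoxon signed-rank / rank-sum tests (paired / unpaired
condition contrasts), and Benjamini-Hochberg correction for post hoc test
families.  All tests are two-sided by default.  Small expected counts (< 5)
in chi-square tests warn rather than switching tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n: int
    df: float | None = None
    adjusted_p: float | None = None
    groups: tuple[str, ...] = ()
    effect: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n": self.n,
            "df": self.df,
            "adjusted_p": self.adjusted_p,
            "groups": list(self.groups),
            "effect": self.effect,
        }


def chisq_goodness_of_fit(
    observed_counts: np.ndarray, expected_proportions: np.ndarray | None = None
) -> TestResult:
    """χ² goodness-of-fit of counts against expected proportions (uniform default)."""
    obs = np.asarray(observed_counts, dtype=float)
    if np.any(obs < 0):
        raise ValueError("observed counts must be non-negative")
    if expected_proportions is None:
        expected_proportions = np.full(obs.size, 1.0 / obs.size)
    exp_p = np.asarray(expected_proportions, dtype=float)
    if not np.isclose(exp_p.sum(), 1.0):
        raise ValueError("expected proportions must sum to 1")
    expected = exp_p * obs.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected count; drop empty categories first")
    if np.any(expected < 5):
        warnings.warn("expected count < 5 in chi-square goodness-of-fit", stacklevel=2)
    stat, p = sps.chisquare(obs, expected)
    return TestResult(
        test_name="chisq_goodness_of_fit",
        statistic=float(stat),
        p_value=float(p),
        n=int(obs.sum()),
        df=float(obs.size - 1),
        effect={"observed": obs.tolist(), "expected": expected.tolist()},
    )


def chisq_independent_proportions(count_table: np.ndarray) -> TestResult:
    """Contingency χ² (no continuity correction) on an r×c count table."""
    table = np.asarray(count_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("count_table must be 2-D")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("count table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 5):
        warnings.warn("expected count < 5 in contingency chi-square", stacklevel=2)
    return TestResult(
        test_name="chisq_independent_proportions",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(table.sum()),
        df=float(res.dof),
        effect={"row_proportions": (table / table.sum(axis=1, keepdims=True)).tolist()},
    )


def wilcoxon_tests(
    x: np.ndarray,
    y: np.ndarray,
    paired: bool,
    alternative: str = "two-sided",
    exact_n_max: int = 25,
) -> TestResult:
    """Wilcoxon signed-rank (paired) or rank-sum (unpaired) test.

    The exact null distribution is used for small samples (≤ ``exact_n_max``
    effective pairs/samples), a normal approximation with continuity
    correction otherwise.  Zero paired differences are dropped.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        diffs = x - y
        nz = diffs[diffs != 0]
        if nz.size == 0:
            warnings.warn("all paired differences are zero: degenerate test", stacklevel=2)
            return TestResult(
                test_name="wilcoxon_signed_rank",
                statistic=float("nan"),
                p_value=1.0,
                n=0,
                effect={"median_difference": 0.0, "degenerate": True},
            )
        if nz.size < 3:
            raise ValueError("need at least 3 nonzero paired differences")
        method = "exact" if nz.size <= exact_n_max else "approx"
        res = sps.wilcoxon(
            x, y, zero_method="wilcox", alternative=alternative, method=method, correction=True
        )
        return TestResult(
            test_name="wilcoxon_signed_rank",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            n=int(nz.size),
            effect={"median_difference": float(np.median(diffs))},
        )
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 samples per group")
    method = "exact" if max(x.size, y.size) <= exact_n_max else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult(
        test_name="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(x.size + y.size),
        effect={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
    )


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-invariant)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t_fold_change(fold_changes_a: np.ndarray, fold_changes_b: np.ndarray) -> TestResult:
    """Paired t-test between per-FOV fold-changes of two compartments."""
    a = np.asarray(fold_changes_a, dtype=float)
    b = np.asarray(fold_changes_b, dtype=float)
    res = sps.ttest_rel(a, b)
    return TestResult(
        test_name="paired_t_fold_change",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(a.size),
        df=float(a.size - 1),
        effect={"mean_difference": float(np.mean(a - b))},
    )


def build_report(
    summaries: dict[str, pd.DataFrame],
    tests: list[TestResult] | None = None,
    out_dir: str | Path | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble pipeline summaries and test results into a report bundle.

    ``summaries`` maps a name to a long-format DataFrame (e.g. the response
    summary, latency table, motility summary).  When ``out_dir`` is given,
    writes ``summary_<name>.csv`` per table, ``tests.csv`` and
    ``report.json`` (with the provenance config).  Returns the JSON payload.
    """
    missing = [k for k, v in summaries.items() if v is None]
    if missing:
        raise ValueError(f"missing report inputs: {missing}")
    tests = tests or []
    test_df = pd.DataFrame([t.to_dict() for t in tests])
    payload = {
        "summaries": {k: v.to_dict(orient="records") for k, v in summaries.items()},
        "tests": [t.to_dict() for t in tests],
        "config": config or {},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in summaries.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
        test_df.to_csv(out / "tests.csv", index=False)
        (out / "report.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    return payload
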