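"""Two-stage significance screen over pre/post exercise and weight groups.

Stage 1 (exercise screen): for each feature key and each weight group (L, M,
H) the pre- and post-exercise series are compared pairwise — a paired t-test
when both series pass a Shapiro–Wilk normality gate, otherwise the Wilcoxon
matched-pairs signed-rank test.  A feature is carried forward only when the
pre/post difference is significant in *all three* groups simultaneously.

Stage 2 (group comparison): the post-exercise series of carried-forward
features are compared across L/M/H — one-way ANOVA with Tukey's HSD when all
three series pass the gate, otherwise Kruskal–Wallis with Dunn's multiple
comparisons.  The pairwise outcomes are classified into difference patterns:

* ``I``   — only L vs H differ (superscripts a, ab, b),
* ``II``  — L and M each differ from H but not from each other (a, a, b),
* ``III`` — all three groups differ (a, b, c),
* ``none`` — no pairwise difference; anything else is reported as ``other``.

All decisions use a two-sided alpha of 0.05 by default, with no multiplicity
correction across feature keys (an optional FDR column is emitted for
inspection but never drives selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "shapiro_gate",
    "paired_compare",
    "prepost_screen",
    "group_compare",
    "dunn_posthoc",
    "classify_pattern",
    "ExerciseGroupScreen",
    "build_significance_grid",
]

ALPHA = 0.05
GROUPS = ("L", "M", "H")
PAIRS = (("L", "M"), ("L", "H"), ("M", "H"))


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    test: str
    statistic: float
    p_value: float
    gaussian: tuple[bool, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def shapiro_gate(values, alpha: float = ALPHA) -> bool:
    """Shapiro–Wilk normality gate: True when the series looks Gaussian.

    Degenerate (constant) series are reported as non-Gaussian rather than
    raising, so the pipeline falls back to rank-based tests.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise ValueError("normality gate needs at least 3 observations")
    if np.ptp(values) == 0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bool(sps.shapiro(values).pvalue >= alpha)


def paired_compare(pre, post, gate_alpha: float = ALPHA) -> TestResult:
    """Paired pre/post comparison with a normality-gated test choice.

    Paired t-test when both series pass the Shapiro–Wilk gate, otherwise the
    Wilcoxon matched-pairs signed-rank test (zeros discarded; exact p for
    n <= 25 without ties, else normal approximation with continuity
    correction).  All-zero differences are degenerate and reported as
    maximally non-significant.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 1:
        raise ValueError("pre and post must be paired 1-D series of equal length")
    gauss = (shapiro_gate(pre, gate_alpha), shapiro_gate(post, gate_alpha))
    diffs = post - pre
    if np.all(diffs == 0):
        # no change anywhere: degenerate for either test, non-significant
        return TestResult("wilcoxon", 0.0, 1.0, gauss)
    if all(gauss):
        res = sps.ttest_rel(post, pre)
        return TestResult("paired t", float(res.statistic), float(res.pvalue), gauss)
    n_nonzero = int(np.count_nonzero(diffs))
    method = "exact" if n_nonzero <= 25 else "approx"
    try:
        res = sps.wilcoxon(post, pre, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        res = sps.wilcoxon(post, pre, zero_method="wilcox", correction=True, method="approx")
    return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), gauss)


def dunn_posthoc(samples: dict[str, np.ndarray], p_adjust: str | None = None) -> dict[tuple[str, str], float]:
    """Dunn's multiple-comparisons test on joint ranks, with tie correction.

    For groups i, j the statistic is
    ``z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))`` where
    ``T = sum(t^3 - t) / (12 (N - 1))`` corrects for tied ranks; two-sided
    p-values from the standard normal.  ``p_adjust`` may name any method
    accepted by statsmodels' ``multipletests`` (default: none).
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n = len(samples[g])
        mean_ranks[g] = ranks[start : start + n].mean()
        sizes[g] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = [(a, b) for idx, a in enumerate(names) for b in names[idx + 1 :]]
    pvals = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        pvals.append(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    if p_adjust is not None:
        pvals = list(multipletests(pvals, method=p_adjust)[1])
    return dict(zip(pairs, pvals))


def group_compare(
    series: dict[str, np.ndarray],
    gate_alpha: float = ALPHA,
    dunn_adjust: str | None = None,
) -> tuple[TestResult, dict[tuple[str, str], float]]:
    """Three-group comparison with a normality-gated omnibus and post hoc.

    ANOVA + Tukey HSD when L, M and H all pass the Shapiro–Wilk gate,
    otherwise Kruskal–Wallis + Dunn.  Returns the omnibus result and the
    three pairwise p-values keyed (L,M), (L,H), (M,H).
    """
    missing = [g for g in GROUPS if g not in series]
    if missing:
        raise ValueError(f"group comparison needs all of L, M, H; missing {missing}")
    arrays = {g: np.asarray(series[g], dtype=float) for g in GROUPS}
    if any(a.size < 3 for a in arrays.values()):
        raise ValueError("each group needs at least 3 observations")
    gauss = tuple(shapiro_gate(arrays[g], gate_alpha) for g in GROUPS)
    if all(gauss):
        omni = sps.f_oneway(*(arrays[g] for g in GROUPS))
        result = TestResult("anova", float(omni.statistic), float(omni.pvalue), gauss)
        hsd = sps.tukey_hsd(*(arrays[g] for g in GROUPS))
        order = {g: i for i, g in enumerate(GROUPS)}
        pairwise = {
            (a, b): float(hsd.pvalue[order[a], order[b]]) for a, b in PAIRS
        }
    else:
        if np.ptp(np.concatenate(list(arrays.values()))) == 0:
            # all observations identical: nothing can differ
            return TestResult("kruskal", 0.0, 1.0, gauss), {pair: 1.0 for pair in PAIRS}
        omni = sps.kruskal(*(arrays[g] for g in GROUPS))
        result = TestResult("kruskal", float(omni.statistic), float(omni.pvalue), gauss)
        pairwise = dunn_posthoc(arrays, p_adjust=dunn_adjust)
        pairwise = {pair: pairwise[pair] for pair in PAIRS}
    return result, pairwise


def classify_pattern(pairwise: dict[tuple[str, str], float], alpha: float = ALPHA) -> str:
    """Map the three pairwise post-hoc p-values to a difference pattern."""
    sig_lm = pairwise[("L", "M")] < alpha
    sig_lh = pairwise[("L", "H")] < alpha
    sig_mh = pairwise[("M", "H")] < alpha
    if sig_lm and sig_lh and sig_mh:
        return "III"
    if sig_lh and sig_mh and not sig_lm:
        return "II"
    if sig_lh and not sig_mh and not sig_lm:
        return "I"
    if not (sig_lm or sig_lh or sig_mh):
        return "none"
    return "other"


def _paired_series(table: pd.DataFrame, column: str, group: str):
    """Pre/post series of one feature in one group, paired by (rider, horse)."""
    sub = table[table["group"] == group]
    pre = sub[sub.index.get_level_values("timepoint") == "pre"][column]
    post = sub[sub.index.get_level_values("timepoint") == "post"][column]
    key = lambda s: s.index.droplevel("timepoint")
    pre.index, post.index = key(pre), key(post)
    common = pre.index.intersection(post.index)
    return pre.loc[common].to_numpy(), post.loc[common].to_numpy()


def prepost_screen(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Stage-1 screen: per-group pre/post tests and the carried-forward flag.

    ``table`` is a wide feature table indexed by (rider_id, horse_id,
    timepoint) with a ``group`` column.  Returns one row per feature column
    with per-group p-values, the test used, and ``carried_forward`` true iff
    p < alpha in L, M and H simultaneously.
    """
    if feature_columns is None:
        feature_columns = [c for c in table.columns if c != "group"]
    rows = []
    for col in feature_columns:
        row: dict[str, object] = {"feature": col}
        significant = []
        for group in GROUPS:
            pre, post = _paired_series(table, col, group)
            if pre.size == 0:
                warnings.warn(f"{col}: group {group} has no paired realizations; skipped")
                significant.append(False)
                row[f"p_{group}"] = np.nan
                continue
            res = paired_compare(pre, post)
            row[f"p_{group}"] = res.p_value
            row[f"test_{group}"] = res.test
            significant.append(res.p_value < alpha)
        row["carried_forward"] = all(significant)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("feature")
    # advisory FDR over the worst-case per-feature p; never drives selection
    worst = out[[f"p_{g}" for g in GROUPS]].max(axis=1)
    valid = worst.notna()
    out["fdr_bh"] = np.nan
    if valid.any():
        out.loc[valid, "fdr_bh"] = multipletests(worst[valid], method="fdr_bh")[1]
    return out


class ExerciseGroupScreen(BaseEstimator):
    """Scikit-learn style estimator running the full two-stage screen.

    ``fit`` consumes a wide feature table (rows indexed by rider, horse and
    timepoint; a ``group`` column; feature columns) and exposes:

    ``prepost_``
        stage-1 results, one row per feature.
    ``group_results_``
        stage-2 omnibus and pairwise p-values plus the difference pattern,
        for carried-forward features only.
    ``selection_grid_``
        tidy grid joining both stages for every feature key.
    """

    def __init__(self, alpha: float = ALPHA, gate_alpha: float = ALPHA,
                 dunn_adjust: str | None = None):
        self.alpha = alpha
        self.gate_alpha = gate_alpha
        self.dunn_adjust = dunn_adjust

    def fit(self, table: pd.DataFrame, y=None):
        if "group" not in table.columns:
            raise ValueError("feature table must carry a 'group' column")
        feature_cols = [c for c in table.columns if c != "group"]
        self.prepost_ = prepost_screen(table, feature_cols, self.alpha)
        post = table[table.index.get_level_values("timepoint") == "post"]
        rows = []
        for col in self.prepost_.index[self.prepost_["carried_forward"]]:
            series = {
                g: post.loc[post["group"] == g, col].to_numpy() for g in GROUPS
            }
            omni, pairwise = group_compare(series, self.gate_alpha, self.dunn_adjust)
            rows.append(
                {
                    "feature": col,
                    "omnibus_test": omni.test,
                    "omnibus_p": omni.p_value,
                    "p_LM": pairwise[("L", "M")],
                    "p_LH": pairwise[("L", "H")],
                    "p_MH": pairwise[("M", "H")],
                    "pattern": classify_pattern(pairwise, self.alpha),
                }
            )
        self.group_results_ = (
            pd.DataFrame(rows).set_index("feature")
            if rows
            else pd.DataFrame(
                columns=["omnibus_test", "omnibus_p", "p_LM", "p_LH", "p_MH", "pattern"]
            )
        )
        self.selection_grid_ = build_significance_grid(self.prepost_, self.group_results_)
        return self

    def fit_predict(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).selection_grid_


def build_significance_grid(
    prepost: pd.DataFrame, group_results: pd.DataFrame
) -> pd.DataFrame:
    """Tidy machine-readable twin of the study's significance figures.

    One row per feature key with the per-group pre/post significance flags,
    the carried-forward flag and the difference pattern (``none`` for keys
    never carried forward).
    """
    grid = pd.DataFrame(index=prepost.index)
    for g in GROUPS:
        grid[f"sig_{g}"] = prepost[f"p_{g}"] < ALPHA
    grid["carried_forward"] = prepost["carried_forward"]
    grid["pattern"] = "none"
    if len(group_results):
        grid.loc[group_results.index, "pattern"] = group_results["pattern"]
    return grid


def plot_significance_grid(grid: pd.DataFrame, path) -> None:
    """Heat-grid rendering of the selection grid (crosses = carried forward)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pattern_code = {"none": 0, "I": 1, "II": 2, "III": 3, "other": 4}
    codes = grid["pattern"].map(pattern_code).to_numpy()[None, :]
    fig, ax = plt.subplots(figsize=(max(6, len(grid) / 12), 2.5))
    ax.imshow(codes, aspect="auto", cmap="viridis", vmin=0, vmax=4)
    carried = np.flatnonzero(grid["carried_forward"].to_numpy())
    ax.scatter(carried, np.zeros_like(carried), marker="x", color="white", s=12)
    ax.set_yticks([])
    ax.set_xlabel("feature key")
    ax.set_title("carried-forward (x) and group-difference pattern")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
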