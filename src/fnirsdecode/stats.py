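"""Statistical layer: t-tests, mood correlations, Bonferroni, weight maps.

Three Bonferroni families are fixed by the analysis design:

* ``accuracy`` (m = 120): one-sample t of per-subject balanced accuracies
  against the 50% chance level, 20 feature fractions x 3 comparisons x 2 tasks;
* ``mood`` (m = 64): Spearman correlations between best accuracies and mood,
  2 blocks x 2 time points x 16 mood measures;
* ``ratings`` (m = 12): two-sample t on valence/arousal ratings,
  2 measures x 3 condition comparisons x 2 tasks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decode import LDAModel
from .errors import ValidationError
from .montage import Montage

BONFERRONI_M = {"accuracy": 120, "mood": 64, "ratings": 12}

ALPHA = 0.05


@dataclass
class TestResult:
    family: str
    name: str
    statistic: float
    df: float
    p_raw: float
    p_bonferroni: float
    m_corrections: int
    significant: bool
    extra: dict | None = None


def _bonferroni(p_raw: float, family: str) -> tuple[float, int]:
    m = BONFERRONI_M[family]
    return min(1.0, float(p_raw) * m), m


def _make_result(family, name, stat, df, p_raw, extra=None) -> TestResult:
    p_bonf, m = _bonferroni(p_raw, family)
    return TestResult(family=family, name=name, statistic=float(stat), df=float(df),
                      p_raw=float(p_raw), p_bonferroni=p_bonf, m_corrections=m,
                      significant=p_bonf < ALPHA, extra=extra)


def one_sample_t_vs_chance(accuracies, mu0: float = 50.0,
                           name: str = "accuracy_vs_chance") -> TestResult:
    """Two-sided one-sample t of per-subject accuracies against chance."""
    a = np.asarray(accuracies, dtype=float)
    if len(a) < 2 or not np.isfinite(a).all():
        raise ValidationError("need >= 2 finite accuracies")
    if a.std(ddof=1) == 0.0:
        # degenerate: all values identical
        if a.mean() == mu0:
            return _make_result("accuracy", name, 0.0, len(a) - 1, 1.0)
        return _make_result("accuracy", name, np.inf, len(a) - 1, 0.0)
    t, p = sps.ttest_1samp(a, mu0)
    return _make_result("accuracy", name, t, len(a) - 1, p)


def two_sample_t_ratings(scores_a, scores_b, equal_var: bool = True,
                         name: str = "ratings") -> TestResult:
    """Two-sided two-sample t on per-subject mean ratings (Student by default)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("need >= 2 subjects per group")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        return _make_result("ratings", name, 0.0, len(a) + len(b) - 2, 1.0)
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else np.nan
    return _make_result("ratings", name, t, df, p)


def spearman_mood(best_accuracies, mood_pre: np.ndarray, mood_post: np.ndarray,
                  block: str = "block") -> list[TestResult]:
    """Spearman rho of best accuracies vs each pre item and each post-pre delta.

    ``mood_pre``/``mood_post`` are (n_subjects, 16) arrays aligned with the
    accuracy vector.  Constant inputs yield a flagged result with p = 1.
    """
    acc = np.asarray(best_accuracies, dtype=float)
    pre = np.asarray(mood_pre, dtype=float)
    post = np.asarray(mood_post, dtype=float)
    if acc.ndim != 1 or len(acc) < 3:
        raise ValidationError("need >= 3 paired observations")
    if pre.shape != post.shape or pre.shape[0] != len(acc):
        raise ValidationError("mood arrays must be (n_subjects, n_items) aligned")
    out = []
    for label, mat in (("pre", pre), ("delta", post - pre)):
        for j in range(mat.shape[1]):
            v = mat[:, j]
            if np.all(v == v[0]) or np.all(acc == acc[0]):
                out.append(_make_result("mood", f"{block}_{label}_item{j + 1:02d}",
                                        np.nan, len(acc) - 2, 1.0,
                                        extra={"flagged": "constant input"}))
                continue
            rho, p = sps.spearmanr(acc, v)
            out.append(_make_result("mood", f"{block}_{label}_item{j + 1:02d}",
                                    rho, len(acc) - 2, p))
    return out


def summarize_weights(model: LDAModel, montage: Montage) -> pd.DataFrame:
    """Signed weight per selected (channel, chromophore) with region labels.

    Unselected features simply do not appear; the companion region tally is
    ``table.groupby(["region", "chromophore"]).size()``.
    """
    if model.feature_names is None:
        raise ValidationError("model has no feature names; fit with feature_names=")
    rows = []
    for name, weight in zip(model.feature_names, model.w):
        try:
            channel, chrom = name.rsplit("_", 1)
        except ValueError as exc:
            raise ValidationError(f"unparseable feature name {name!r}") from exc
        rows.append({"channel": channel, "chromophore": chrom,
                     "region": montage.region_of(channel), "weight": float(weight)})
    return pd.DataFrame(rows, columns=["channel", "chromophore", "region", "weight"])


def region_tally(weights: pd.DataFrame) -> pd.DataFrame:
    tally = (weights.groupby(["region", "chromophore"]).size()
             .rename("n_features").reset_index())
    return tally


def accuracy_tests_by_fraction(results_frame: pd.DataFrame) -> pd.DataFrame:
    """One chance-level t-test per (task, comparison, fraction)."""
    rows = []
    group_cols = ["task", "comparison", "subset_fraction"]
    for (task, comp, frac), grp in results_frame.groupby(group_cols):
        accs = grp["balanced_accuracy_pct"].to_numpy()
        tr = one_sample_t_vs_chance(accs, name=f"{task}:{comp}:{frac:.2f}")
        rows.append({"task": task, "comparison": comp, "subset_fraction": frac,
                     "n_subjects": len(accs), "mean_acc": accs.mean(),
                     "sd_acc": accs.std(ddof=1) if len(accs) > 1 else 0.0,
                     "t": tr.statistic, "p_raw": tr.p_raw,
                     "p_bonferroni": tr.p_bonferroni,
                     "significant": tr.significant})
    return pd.DataFrame(rows)


def report(results_frame: pd.DataFrame, tests: pd.DataFrame | None = None,
           weights: pd.DataFrame | None = None,
           out_dir: str | Path | None = None) -> str:
    """Plain-text summary per (task, comparison) plus optional TSV dumps."""
    lines = []
    if results_frame.empty:
        lines.append("No decoding results.")
    else:
        if tests is None:
            tests = accuracy_tests_by_fraction(results_frame)
        for (task, comp), grp in tests.groupby(["task", "comparison"]):
            lines.append(f"== task={task} comparison={comp} ==")
            best = grp.loc[grp["mean_acc"].idxmax()]
            for _, row in grp.sort_values("subset_fraction").iterrows():
                flag = " *" if row["significant"] else ""
                lines.append(
                    f"  {row['subset_fraction']:.2f}: "
                    f"{row['mean_acc']:.2f} ± {row['sd_acc']:.2f}%"
                    f" (p_bonf={row['p_bonferroni']:.3g}){flag}"
                )
            lines.append(
                f"  best fraction {best['subset_fraction']:.2f}: "
                f"{best['mean_acc']:.2f} ± {best['sd_acc']:.2f}%"
                f" (p_bonf={best['p_bonferroni']:.3g},"
                f" significant={bool(best['significant'])})"
            )
    if weights is not None and not weights.empty:
        lines.append("== selected-feature weights ==")
        for _, row in weights.iterrows():
            lines.append(f"  {row['channel']}_{row['chromophore']}"
                         f" [{row['region']}]: {row['weight']:+.4g}")
    text = "\n".join(lines) + "\n"
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "summary.txt").write_text(text)
        results_frame.to_csv(out / "results.tsv", sep="\t", index=False)
        if tests is not None:
            tests.to_csv(out / "accuracy_tests.tsv", sep="\t", index=False)
        if weights is not None:
            weights.to_csv(out / "weights.tsv", sep="\t", index=False)
    return text
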