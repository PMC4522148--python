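"""Per-feature LOH vs no-LOH contrasts for methylation and expression.

Two multi-omic readouts are contrasted between samples with and without
LOH at each feature's locus: methylation array beta values (hypothesis:
promoter hypermethylation co-selected with LOH, i.e. an epigenetic
second hit) and expression values (hypothesis: reduced expression under
copy-number loss, i.e. haploinsufficiency).  The per-feature test is a
two-sided Welch t-test by default but is injectable, so a rank-based
alternative can be swapped in.  Family-wise significance uses the
Bonferroni threshold over the features actually tested (features with
fewer than two samples per arm, or zero variance in an arm, are skipped
and counted).

Beta values are additionally summarised into high (> 0.75),
intermediate and low (< 0.25) methylation categories — both cut-offs
open, so the boundary values are intermediate — and significant features
into fold-change classes (LOH/no-LOH ratio > 1.5 up, < 0.75 down).
Feature-level results are finally stratified by whether their locus is
CNL-enriched or CNN-enriched cohort-wide.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import stats
from .landscape import ThresholdSet, STATE_CNL, STATE_CNN

__all__ = [
    "beta_category",
    "fc_class",
    "feature_contrasts",
    "category_breakdown",
    "locus_class_enrichment",
]


def beta_category(beta: float, thresholds: ThresholdSet = ThresholdSet()) -> str:
    """Categorise one beta value as high / intermediate / low methylation."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta value outside [0, 1]: {beta}")
    if beta > thresholds.methylation_high:
        return "high"
    if beta < thresholds.methylation_low:
        return "low"
    return "intermediate"


def fc_class(fold_change: float, thresholds: ThresholdSet = ThresholdSet()) -> str:
    """Fold-change class of a significant feature: up / down / neither."""
    if not fold_change > 0:
        raise ValueError(f"fold change must be positive, got {fold_change}")
    if fold_change > thresholds.fc_up:
        return "up"
    if fold_change < thresholds.fc_down:
        return "down"
    return "neither"


def feature_contrasts(
    matrix: pd.DataFrame,
    loh: pd.DataFrame,
    feature_locus: pd.Series | None = None,
    profiles: pd.DataFrame | None = None,
    thresholds: ThresholdSet = ThresholdSet(),
    test: Callable = stats.welch_t,
):
    """LOH vs no-LOH contrast for every feature (row) of a matrix.

    ``matrix`` is feature x sample; ``loh`` is a boolean feature x sample
    frame on the same index/columns giving each sample's LOH status at
    the feature's locus.  Optionally attach each feature's locus and the
    cohort locus profile so the contrast carries the locus enrichment
    class.  Returns ``(contrasts, skipped)`` where ``contrasts`` has one
    row per tested feature and ``skipped`` lists untested features with
    a reason.  Significance is Bonferroni over tested features.
    """
    if not matrix.index.equals(loh.index) or not matrix.columns.equals(loh.columns):
        raise ValueError("matrix and loh status must share index and columns")
    values = matrix.to_numpy(dtype=float)
    mask = loh.to_numpy(dtype=bool)
    rows, skipped = [], []
    for i, feat in enumerate(matrix.index):
        a = values[i, mask[i]]
        b = values[i, ~mask[i]]
        try:
            res = test(a, b)
        except stats.DegenerateInputError as err:
            skipped.append({"feature": feat, "reason": str(err)})
            continue
        mean_loh = float(a.mean())
        mean_noloh = float(b.mean())
        fc = mean_loh / mean_noloh if mean_loh > 0 and mean_noloh > 0 else np.nan
        rows.append(
            {
                "feature": feat,
                "n_loh": int(a.size),
                "n_noloh": int(b.size),
                "mean_loh": mean_loh,
                "mean_noloh": mean_noloh,
                "fold_change": fc,
                "statistic": res.statistic,
                "p": res.p_value,
            }
        )
    contrasts = pd.DataFrame(rows)
    skipped_df = pd.DataFrame(skipped, columns=["feature", "reason"])
    if contrasts.empty:
        return contrasts, skipped_df
    cut = stats.bonferroni_threshold(len(contrasts), thresholds.alpha)
    contrasts["significant"] = contrasts["p"] < cut
    diff = contrasts["mean_loh"] - contrasts["mean_noloh"]
    contrasts["direction"] = np.select(
        [diff > 0, diff < 0], ["up_in_loh", "down_in_loh"], default="none"
    )
    contrasts["fc_class"] = [
        fc_class(fc, thresholds) if np.isfinite(fc) else "neither"
        for fc in contrasts["fold_change"]
    ]
    if feature_locus is not None:
        contrasts["locus_id"] = contrasts["feature"].map(feature_locus)
        if profiles is not None:
            cls = profiles.set_index("locus_id")["enrichment_class"]
            contrasts["enrichment_class"] = contrasts["locus_id"].map(cls)
    return contrasts, skipped_df


def category_breakdown(
    matrix: pd.DataFrame,
    loh: pd.DataFrame,
    features: Sequence | None = None,
    thresholds: ThresholdSet = ThresholdSet(),
):
    """Methylation-category proportions in the LOH vs no-LOH arms.

    Pools all (feature, sample) pairs of the chosen feature subset
    (e.g. autosomal or X-linked probes); returns a dict with the two
    proportion triples, the raw counts, and a per-category 2x2
    chi-squared (category membership vs arm).  An empty arm is flagged
    with NaN proportions and no tests.
    """
    if features is not None:
        matrix = matrix.loc[list(features)]
        loh = loh.loc[list(features)]
    values = matrix.to_numpy(dtype=float)
    mask = loh.to_numpy(dtype=bool)
    out: dict = {"counts": {}, "proportions": {}, "tests": {}}
    counts = {}
    for arm, sel in (("loh", mask), ("noloh", ~mask)):
        v = values[sel]
        n = v.size
        hi = int((v > thresholds.methylation_high).sum())
        lo = int((v < thresholds.methylation_low).sum())
        counts[arm] = {"high": hi, "intermediate": n - hi - lo, "low": lo, "n": n}
        out["proportions"][arm] = (
            (hi / n, (n - hi - lo) / n, lo / n) if n else (np.nan, np.nan, np.nan)
        )
    out["counts"] = counts
    if counts["loh"]["n"] and counts["noloh"]["n"]:
        for cat in ("high", "intermediate", "low"):
            a = counts["loh"][cat]
            b = counts["loh"]["n"] - a
            c = counts["noloh"][cat]
            d = counts["noloh"]["n"] - c
            try:
                out["tests"][cat] = stats.chisq_2x2(a, b, c, d)
            except stats.DegenerateInputError:
                out["tests"][cat] = None
    return out


def locus_class_enrichment(contrasts: pd.DataFrame):
    """Share of significant features at CNL- vs CNN-enriched loci.

    ``contrasts`` must carry ``significant`` and ``enrichment_class``
    columns (from :func:`feature_contrasts` with profiles attached).
    Features at "neither"/"insufficient" loci are reported but excluded
    from the 2x2 chi-squared comparing the two enriched classes.
    Returns ``(summary, TestResult-or-None)``.
    """
    rows = []
    counts = {}
    for cls in ("CNL-enriched", "CNN-enriched", "neither", "insufficient"):
        sub = contrasts[contrasts["enrichment_class"] == cls]
        n_sig = int(sub["significant"].sum())
        rows.append(
            {
                "enrichment_class": cls,
                "n_significant": n_sig,
                "n_total": len(sub),
                "fraction": n_sig / len(sub) if len(sub) else np.nan,
            }
        )
        counts[cls] = (n_sig, len(sub))
    summary = pd.DataFrame(rows)
    result = None
    (sig_l, n_l), (sig_n, n_n) = counts["CNL-enriched"], counts["CNN-enriched"]
    if n_l and n_n:
        try:
            result = stats.chisq_2x2(sig_l, n_l - sig_l, sig_n, n_n - sig_n)
        except stats.DegenerateInputError:
            result = None
    return summary, result
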