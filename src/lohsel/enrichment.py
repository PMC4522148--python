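"""Mutation load inside LOH regions, by class and copy-number stratum.

Are somatic mutations over- or under-represented inside LOH?  For a
given mutation class (all, synonymous, other non-synonymous, overtly
deleterious) and stratum (any LOH, CNL-LOH, CNN-LOH), the observed
fraction of mutations falling in the stratum is compared with the
fraction expected if mutations landed uniformly on each sample's gene
territory.  The expectation weights samples by the number of mutations
they contribute (each mutation is one binomial trial whose success
probability is its own sample's stratum territory fraction), and the
test is the exact two-sided binomial on the aggregate count.  The
unweighted per-sample mean territory fraction is reported alongside for
transparency.  Known driver genes (TP53-like outliers) can be excluded
to ask whether the signal survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import stats

__all__ = ["OverlapResult", "mutation_loh_overlap", "enrichment_panel"]

CLASSES = ("all", "synonymous", "non_synonymous_other", "deleterious")
STRATA = ("any", "CNL", "CNN")

_FRAC_COL = {"any": "frac_loh", "CNL": "frac_cnl", "CNN": "frac_cnn"}


@dataclass(frozen=True)
class OverlapResult:
    """One class x stratum mutation-load comparison."""

    mutation_class: str
    stratum: str
    n_mutations: int
    n_in_stratum: int
    observed_fraction: float
    expected_fraction: float
    mean_sample_fraction: float
    p_value: float
    excluded_genes: tuple = ()


def _in_stratum(mutations: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "any":
        return mutations["in_loh"].to_numpy(dtype=bool)
    return (mutations["loh_type"] == stratum).to_numpy()


def mutation_loh_overlap(
    mutations: pd.DataFrame,
    territory: pd.DataFrame,
    mutation_class: str = "all",
    stratum: str = "any",
    excluded_genes: Sequence[str] = (),
) -> OverlapResult:
    """Observed vs expected fraction of mutations inside one LOH stratum.

    ``territory`` is the per-sample table from
    :func:`lohsel.landscape.territory_table`; every mutation's sample
    must appear in it.  Zero mutations of the class yield NaN fractions
    and p-value (flagged, no test).
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}")
    muts = mutations
    if excluded_genes:
        muts = muts[~muts["gene"].isin(set(excluded_genes))]
    if mutation_class != "all":
        muts = muts[muts["class"] == mutation_class]
    n = len(muts)
    frac_col = _FRAC_COL[stratum]
    per_sample = territory.set_index("sample")[frac_col]
    if n == 0:
        return OverlapResult(
            mutation_class, stratum, 0, 0, np.nan, np.nan,
            float(per_sample.mean()), np.nan, tuple(excluded_genes),
        )
    missing = set(muts["sample"]) - set(per_sample.index)
    if missing:
        raise ValueError(f"samples without territory fractions: {sorted(missing)[:5]}")
    k = int(_in_stratum(muts, stratum).sum())
    expected = float(per_sample.reindex(muts["sample"]).mean())  # mutation-weighted
    if 0.0 < expected < 1.0:
        p = stats.binom_two_sided(k, n, expected)
    else:  # degenerate territory: every/no position is in the stratum
        p = 1.0 if k == (n if expected == 1.0 else 0) else 0.0
    return OverlapResult(
        mutation_class, stratum, n, k, k / n, expected,
        float(per_sample.mean()), p, tuple(excluded_genes),
    )


def enrichment_panel(
    mutations: pd.DataFrame,
    territory: pd.DataFrame,
    excluded_genes: Sequence[str] = (),
) -> pd.DataFrame:
    """Full class x stratum x exclusion grid of overlap tests.

    One row per mutation class in {all, synonymous, non_synonymous_other,
    deleterious} x stratum in {any, CNL, CNN} x exclusion toggle (the
    toggle rows appear only when ``excluded_genes`` is non-empty), in a
    fixed, reproducible order.
    """
    exclusions: list[Sequence[str]] = [()]
    if excluded_genes:
        exclusions.append(tuple(excluded_genes))
    rows = []
    for excl in exclusions:
        for klass in CLASSES:
            for stratum in STRATA:
                r = mutation_loh_overlap(mutations, territory, klass, stratum, excl)
                rows.append(
                    {
                        "class": r.mutation_class,
                        "stratum": r.stratum,
                        "n": r.n_mutations,
                        "n_in_stratum": r.n_in_stratum,
                        "observed": r.observed_fraction,
                        "expected": r.expected_fraction,
                        "mean_sample_fraction": r.mean_sample_fraction,
                        "p": r.p_value,
                        "excluded_genes": ",".join(excl),
                    }
                )
    return pd.DataFrame(rows)
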