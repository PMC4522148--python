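"""In-memory five-model analysis of a cohort, for calibration studies.

Runs the full analysis chain (LOH calling, screen, mutation-load
enrichment, methylation and expression contrasts, risk-allele
retention) on a :class:`~lohsel.simulate.SyntheticCohort` without
touching disk, and summarises each model's per-test p-values and its
direction-aware detection verdict.  This is the workhorse for type-I
error calibration (all planted effects off: each model's significant
call rate should sit at or below the nominal level) and for power
studies (strong planted effects: each model should recover the planted
direction).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import contrasts as _contrasts
from . import enrichment as _enrichment
from . import landscape as _landscape
from . import retention as _retention
from . import screen as _screen
from .landscape import ThresholdSet
from .simulate import SyntheticCohort

__all__ = ["analyse_cohort", "model_p_values", "model_significant_rates", "model_detection"]


def analyse_cohort(
    cohort: SyntheticCohort,
    thresholds: ThresholdSet = ThresholdSet(),
    exclude_genes: Sequence[str] = (),
) -> dict:
    """Run every analysis stage on an in-memory cohort.

    Returns a dict with segments, locus profiles, territory fractions,
    screen report, enrichment panel, methylation and expression
    contrast tables (methylation restricted to autosomes carries an
    ``autosome`` flag), and the per-SNP retention report.
    """
    segments = _landscape.call_loh(cohort.acn, thresholds)
    loci = cohort.loci
    profiles = _landscape.locus_profiles(segments, loci, thresholds)
    territory = _landscape.territory_table(segments, loci)

    filtered = _screen.filter_calls(cohort.raw_calls)
    accepted = filtered[filtered["accepted"]].drop(columns=["accepted", "reason"])
    accepted = _screen.annotate_loh(accepted, segments)
    screen_report = (
        _screen.screen_genes(accepted, segments, loci, thresholds)
        if len(accepted)
        else pd.DataFrame(columns=["gene", "recurrence_p", "flags"])
    )
    panel = _enrichment.enrichment_panel(accepted, territory, exclude_genes)

    states, state_samples = _landscape.locus_state_matrix(segments, loci)
    locus_pos = {lid: i for i, lid in enumerate(loci["locus_id"])}

    def _loh_frame(features, feature_locus, columns):
        idx = [locus_pos[feature_locus[f]] for f in features]
        frame = pd.DataFrame(
            (states > 0)[idx], index=features, columns=state_samples
        )
        return frame.reindex(columns=columns, fill_value=False)

    probe_locus = dict(zip(cohort.probe_annotation["probe_id"], cohort.probe_annotation["locus_id"]))
    probe_chrom = dict(zip(cohort.probe_annotation["probe_id"], cohort.probe_annotation["chrom"]))
    meth_loh = _loh_frame(cohort.methylation.index, probe_locus, cohort.methylation.columns)
    meth, _ = _contrasts.feature_contrasts(
        cohort.methylation, meth_loh, pd.Series(probe_locus), profiles, thresholds
    )
    if len(meth):
        meth["chrom"] = meth["feature"].map(probe_chrom)

    gene_locus = {g: g for g in cohort.expression.index}
    expr_loh = _loh_frame(cohort.expression.index, gene_locus, cohort.expression.columns)
    expr, _ = _contrasts.feature_contrasts(
        cohort.expression, expr_loh, pd.Series(gene_locus), profiles, thresholds
    )

    rows = []
    for _, snp_row in cohort.snp_manifest.iterrows():
        calls = cohort.genotypes[cohort.genotypes["snp_id"] == snp_row["snp_id"]]
        table = _retention.tabulate_snp(
            calls["germline_gt"], calls["tumour_gt"], str(snp_row["snp_id"])
        )
        res = _retention.retention_test(table, _retention._snp_from_row(snp_row))
        rows.append(
            {
                "snp_id": table.snp_id,
                "locus": snp_row["locus"],
                "aa": table.aa,
                "bb": table.bb,
                "n_loh": res.n_loh,
                "p": res.p_value,
                "direction": res.direction,
                "pct_loh": res.pct_loh,
            }
        )
    retention_report = pd.DataFrame(rows)

    return {
        "segments": segments,
        "profiles": profiles,
        "territory": territory,
        "mutations": accepted,
        "screen": screen_report,
        "panel": panel,
        "methylation": meth,
        "expression": expr,
        "retention": retention_report,
    }


def model_p_values(results: dict) -> dict[str, np.ndarray]:
    """Per-model arrays of per-test p-values (for calibration rates).

    classic_two_hit: gene recurrence p-values; epigenetic_two_hit:
    autosomal methylation probe contrasts; mutation_load: enrichment
    panel rows; haploinsufficiency: expression gene contrasts;
    risk_retention: per-SNP direction tests.
    """
    meth = results["methylation"]
    auto = meth[meth["chrom"] != "chrX"] if len(meth) else meth
    return {
        "classic_two_hit": results["screen"]["recurrence_p"].to_numpy(dtype=float),
        "epigenetic_two_hit": auto["p"].to_numpy(dtype=float) if len(auto) else np.array([]),
        "mutation_load": results["panel"]["p"].dropna().to_numpy(dtype=float),
        "haploinsufficiency": results["expression"]["p"].to_numpy(dtype=float),
        "risk_retention": results["retention"]["p"].dropna().to_numpy(dtype=float),
    }


def model_significant_rates(results: dict, alpha: float = 0.05) -> dict[str, tuple[int, int]]:
    """(significant calls, tests) per model under its own decision rule.

    The screen and the per-feature contrasts decide at the Bonferroni
    cut (their family-wise rule); the mutation-load panel and the
    retention tests decide at raw alpha.  Under a null simulation each
    rate should sit at or below alpha.
    """
    screen = results["screen"]
    flags = screen["flags"].fillna("") if len(screen) else pd.Series(dtype=str)
    meth = results["methylation"]
    auto = meth[meth["chrom"] != "chrX"] if len(meth) else meth
    expr = results["expression"]
    panel = results["panel"]
    panel = panel[(panel["excluded_genes"] == "") & panel["p"].notna()]
    ret = results["retention"].dropna(subset=["p"])
    return {
        "classic_two_hit": (int(flags.str.contains("recurrence").sum()), len(screen)),
        "epigenetic_two_hit": (int(auto["significant"].sum()) if len(auto) else 0, len(auto)),
        "mutation_load": (int((panel["p"] < alpha).sum()), len(panel)),
        "haploinsufficiency": (int(expr["significant"].sum()) if len(expr) else 0, len(expr)),
        "risk_retention": (int((ret["p"] < alpha).sum()), len(ret)),
    }


def model_detection(results: dict, alpha: float = 0.05) -> dict[str, bool]:
    """Direction-aware detection verdict per model.

    classic_two_hit: some gene carries all three discovery flags.
    epigenetic_two_hit: significant autosomal probes exist and are
    mostly hypermethylated in LOH.  mutation_load: overtly deleterious
    mutations significantly enriched in CNN-LOH.  haploinsufficiency:
    significant expression genes exist and are mostly under-expressed
    in LOH.  risk_retention: some SNP shows significant, risk-oriented
    allele retention.
    """
    screen = results["screen"]
    flags = screen["flags"].fillna("") if len(screen) else pd.Series(dtype=str)
    two_hit = bool(
        len(screen)
        and (
            flags.str.contains("recurrence")
            & flags.str.contains("biallelic")
            & flags.str.contains("deleterious")
        ).any()
    )

    meth = results["methylation"]
    auto = meth[meth["chrom"] != "chrX"] if len(meth) else meth
    sig_m = auto[auto["significant"]] if len(auto) else auto
    epi = bool(len(sig_m)) and (sig_m["direction"] == "up_in_loh").sum() * 2 > len(sig_m)

    panel = results["panel"]
    row = panel[
        (panel["class"] == "deleterious")
        & (panel["stratum"] == "CNN")
        & (panel["excluded_genes"] == "")
    ].iloc[0]
    load = bool(row["n"] > 0 and row["observed"] > row["expected"] and row["p"] < alpha)

    expr = results["expression"]
    sig_e = expr[expr["significant"]] if len(expr) else expr
    haplo = bool(len(sig_e)) and (sig_e["direction"] == "down_in_loh").sum() * 2 > len(sig_e)

    ret = results["retention"]
    risk = bool(((ret["p"] < alpha) & (ret["direction"] == "risk_retained")).any())

    return {
        "classic_two_hit": two_hit,
        "epigenetic_two_hit": epi,
        "mutation_load": load,
        "haploinsufficiency": haplo,
        "risk_retention": risk,
    }
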