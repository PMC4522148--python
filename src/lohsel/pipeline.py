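"""End-to-end orchestration: simulate → call → screen → enrich → contrast → retention.

Each stage reads and writes plain tab-delimited files in a run
directory, so stages can be re-run individually; :func:`run_all` chains
them and finishes with a five-model verdict table and a run manifest of
SHA-256 digests.  A run is fully determined by (config, seed): repeated
runs produce byte-identical outputs, and the manifest intentionally
carries no wall-clock information so that it, too, is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import contrasts as _contrasts
from . import enrichment as _enrichment
from . import landscape as _landscape
from . import retention as _retention
from . import screen as _screen
from . import simulate as _simulate
from ._version import __version__
from .landscape import ThresholdSet

__all__ = [
    "load_config",
    "run_all",
    "stage_simulate",
    "stage_call_loh",
    "stage_screen",
    "stage_enrich",
    "stage_methylation",
    "stage_expression",
    "stage_risk",
]

MODELS = (
    "classic_two_hit",
    "epigenetic_two_hit",
    "mutation_load",
    "haploinsufficiency",
    "risk_retention",
)


def load_config(path=None, seed: int | None = None):
    """Load a YAML run config into (SimConfig, ThresholdSet, excluded genes).

    The file holds three optional sections: ``sim`` (SimConfig fields,
    with ``risk_snps`` as a list of mappings), ``thresholds``
    (ThresholdSet fields) and ``exclude_genes``.  ``seed`` overrides the
    config's ``rng_seed``.
    """
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    sim_kwargs = dict(raw.get("sim") or {})
    if sim_kwargs.get("risk_snps") is not None:
        sim_kwargs["risk_snps"] = tuple(
            _simulate.RiskSNPConfig(**s) for s in sim_kwargs["risk_snps"]
        )
    for key in ("class_mix", "cnl_share_by_chrom", "homdel_loci", "x_inactivation_beta"):
        if sim_kwargs.get(key) is not None:
            sim_kwargs[key] = tuple(sim_kwargs[key])
    if sim_kwargs.get("methylation_baseline") is not None:
        sim_kwargs["methylation_baseline"] = tuple(
            tuple(x) for x in sim_kwargs["methylation_baseline"]
        )
    if sim_kwargs.get("subtype_fractions") is not None:
        sim_kwargs["subtype_fractions"] = tuple(
            (str(a), float(b)) for a, b in sim_kwargs["subtype_fractions"]
        )
    if seed is not None:
        sim_kwargs["rng_seed"] = int(seed)
    sim = _simulate.SimConfig(**sim_kwargs)
    thresholds = ThresholdSet(**(raw.get("thresholds") or {}))
    exclude = tuple(raw.get("exclude_genes") or ())
    return sim, thresholds, exclude


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages


def stage_simulate(sim_config, outdir) -> list[Path]:
    cohort = _simulate.generate_cohort(sim_config)
    return _simulate.write_cohort(cohort, Path(outdir) / "cohort")


def stage_call_loh(outdir, thresholds: ThresholdSet) -> list[Path]:
    outdir = Path(outdir)
    cohort_dir = outdir / "cohort"
    track = _landscape.read_allele_cn(cohort_dir / "allele_cn.tsv")
    loci = _landscape.read_loci_bed(cohort_dir / "loci.bed")
    samples = pd.read_csv(cohort_dir / "samples.tsv", sep="\t", dtype=str)
    segments = _landscape.call_loh(track, thresholds)
    profiles = _landscape.locus_profiles(segments, loci, thresholds)
    subtype_profiles = {}
    for subtype, grp in samples.groupby("subtype"):
        sub_segs = segments[segments["sample"].isin(set(grp["sample"]))]
        if len(sub_segs):
            subtype_profiles[subtype] = _landscape.locus_profiles(sub_segs, loci, thresholds)
    candidates = _landscape.select_candidate_regions(
        profiles, loci, segments, subtype_profiles, thresholds
    )
    territory = _landscape.territory_table(segments, loci)
    paths = []
    for name, writer in (
        ("segments.tsv", lambda p: _landscape.write_segments(segments, p)),
        ("loh_segments.bed", lambda p: _landscape.write_loh_bed(segments, p)),
        ("locus_profiles.tsv", lambda p: profiles.to_csv(p, sep="\t", index=False)),
        ("candidate_regions.tsv", lambda p: candidates.to_csv(p, sep="\t", index=False)),
        ("territory.tsv", lambda p: territory.to_csv(p, sep="\t", index=False)),
    ):
        path = outdir / name
        writer(path)
        paths.append(path)
    return paths


def stage_screen(outdir, thresholds: ThresholdSet) -> list[Path]:
    outdir = Path(outdir)
    raw = _screen.read_maf(outdir / "cohort" / "raw_calls.maf")
    loci = _landscape.read_loci_bed(outdir / "cohort" / "loci.bed")
    segments = _landscape.read_segments(outdir / "segments.tsv")
    filtered = _screen.filter_calls(raw)
    accepted = filtered[filtered["accepted"]].drop(columns=["accepted", "reason"])
    accepted = _screen.annotate_loh(accepted, segments)
    report = _screen.screen_genes(accepted, segments, loci, thresholds)
    rates, rate_test = _screen.wildtype_loh_rates(accepted)
    rates = rates.copy()
    rates["nonsyn_vs_syn_p"] = rate_test.p_value if rate_test is not None else np.nan
    paths = []
    for name, writer in (
        ("mutations.maf", lambda p: _screen.write_maf(accepted, p)),
        ("rejected_calls.tsv", lambda p: filtered[~filtered["accepted"]].to_csv(p, sep="\t", index=False)),
        ("screen_report.tsv", lambda p: report.to_csv(p, sep="\t", index=False)),
        ("wildtype_loh_rates.tsv", lambda p: rates.to_csv(p, sep="\t", index=False)),
    ):
        path = outdir / name
        writer(path)
        paths.append(path)
    return paths


def stage_enrich(outdir, thresholds: ThresholdSet, exclude_genes: Sequence[str] = ()) -> list[Path]:
    outdir = Path(outdir)
    mutations = _screen.read_maf(outdir / "mutations.maf")
    segments = _landscape.read_segments(outdir / "segments.tsv")
    mutations = _screen.annotate_loh(mutations, segments)
    territory = pd.read_csv(outdir / "territory.tsv", sep="\t", dtype={"sample": str})
    panel = _enrichment.enrichment_panel(mutations, territory, exclude_genes)
    path = outdir / "enrichment_report.tsv"
    panel.to_csv(path, sep="\t", index=False)
    return [path]


def _loh_frame(segments, loci, features, feature_locus, samples):
    """Boolean feature x sample LOH-status frame from called segments."""
    states, state_samples = _landscape.locus_state_matrix(segments, loci)
    locus_pos = {lid: i for i, lid in enumerate(loci["locus_id"])}
    loh = pd.DataFrame(False, index=features, columns=samples)
    state_df = pd.DataFrame(states > 0, columns=state_samples)
    for feat in features:
        li = locus_pos[feature_locus[feat]]
        loh.loc[feat, state_samples] = state_df.iloc[li].to_numpy()
    return loh


def stage_methylation(outdir, thresholds: ThresholdSet) -> list[Path]:
    outdir = Path(outdir)
    matrix = pd.read_csv(outdir / "cohort" / "methylation_beta.tsv", sep="\t", index_col=0)
    annot = pd.read_csv(outdir / "cohort" / "probe_annotation.tsv", sep="\t")
    loci = _landscape.read_loci_bed(outdir / "cohort" / "loci.bed")
    segments = _landscape.read_segments(outdir / "segments.tsv")
    profiles = pd.read_csv(outdir / "locus_profiles.tsv", sep="\t")
    feature_locus = dict(zip(annot["probe_id"], annot["locus_id"]))
    loh = _loh_frame(segments, loci, matrix.index, feature_locus, matrix.columns)
    con, skipped = _contrasts.feature_contrasts(
        matrix, loh, pd.Series(feature_locus), profiles, thresholds
    )
    chrom_of = dict(zip(annot["probe_id"], annot["chrom"]))
    if len(con):
        con["chrom"] = con["feature"].map(chrom_of)
    is_x = matrix.index.map(lambda p: chrom_of[p] == "chrX")
    summary_rows = []
    for label, feats in (("autosomes", matrix.index[~is_x]), ("X", matrix.index[is_x])):
        if not len(feats):
            continue
        bd = _contrasts.category_breakdown(matrix, loh, feats, thresholds)
        for arm in ("loh", "noloh"):
            hi, mid, lo = bd["proportions"][arm]
            summary_rows.append(
                {
                    "stratum": label,
                    "arm": arm,
                    "prop_high": hi,
                    "prop_intermediate": mid,
                    "prop_low": lo,
                    "n_pairs": bd["counts"][arm]["n"],
                    "p_high": bd["tests"].get("high").p_value if bd["tests"].get("high") else np.nan,
                    "p_low": bd["tests"].get("low").p_value if bd["tests"].get("low") else np.nan,
                }
            )
    breakdown = pd.DataFrame(summary_rows)
    cls_summary, cls_test = _contrasts.locus_class_enrichment(con) if len(con) else (pd.DataFrame(), None)
    if len(cls_summary):
        cls_summary["chisq_p"] = cls_test.p_value if cls_test is not None else np.nan
    paths = []
    for name, frame in (
        ("methylation_contrasts.tsv", con),
        ("methylation_skipped.tsv", skipped),
        ("methylation_categories.tsv", breakdown),
        ("methylation_locus_class.tsv", cls_summary),
    ):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def stage_expression(outdir, thresholds: ThresholdSet) -> list[Path]:
    outdir = Path(outdir)
    matrix = pd.read_csv(outdir / "cohort" / "expression.tsv", sep="\t", index_col=0)
    loci = _landscape.read_loci_bed(outdir / "cohort" / "loci.bed")
    segments = _landscape.read_segments(outdir / "segments.tsv")
    profiles = pd.read_csv(outdir / "locus_profiles.tsv", sep="\t")
    feature_locus = {g: g for g in matrix.index}
    loh = _loh_frame(segments, loci, matrix.index, feature_locus, matrix.columns)
    con, skipped = _contrasts.feature_contrasts(
        matrix, loh, pd.Series(feature_locus), profiles, thresholds
    )
    cls_summary, cls_test = _contrasts.locus_class_enrichment(con) if len(con) else (pd.DataFrame(), None)
    if len(cls_summary):
        cls_summary["chisq_p"] = cls_test.p_value if cls_test is not None else np.nan
    paths = []
    for name, frame in (
        ("expression_contrasts.tsv", con),
        ("expression_skipped.tsv", skipped),
        ("expression_locus_class.tsv", cls_summary),
    ):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


def stage_risk(outdir, thresholds: ThresholdSet) -> list[Path]:
    outdir = Path(outdir)
    genotypes = _retention.read_genotypes(outdir / "cohort" / "genotypes.tsv")
    manifest = _retention.read_snp_manifest(outdir / "cohort" / "snp_manifest.tsv")
    rows = []
    for _, snp_row in manifest.iterrows():
        calls = genotypes[genotypes["snp_id"] == snp_row["snp_id"]]
        table = _retention.tabulate_snp(
            calls["germline_gt"], calls["tumour_gt"], str(snp_row["snp_id"])
        )
        snp = _retention._snp_from_row(snp_row)
        res = _retention.retention_test(table, snp)
        rows.append(
            {
                "snp_id": table.snp_id,
                "locus": snp.locus,
                "het": table.het,
                "hom": table.hom,
                "aa": table.aa,
                "bb": table.bb,
                "nc": table.nc,
                "n": table.n,
                "p": res.p_value,
                "direction": res.direction,
                "pct_loh": res.pct_loh,
                "n_loh": res.n_loh,
            }
        )
    report = pd.DataFrame(rows)
    consistency = _retention.locus_consistency(report, alpha=thresholds.alpha)
    paths = []
    for name, frame in (
        ("retention_report.tsv", report),
        ("retention_locus_consistency.tsv", consistency),
    ):
        path = outdir / name
        frame.to_csv(path, sep="\t", index=False)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# verdicts and manifest


def model_verdicts(outdir, thresholds: ThresholdSet) -> pd.DataFrame:
    """Summarise each of the five selection models from stage outputs."""
    outdir = Path(outdir)
    alpha = thresholds.alpha
    rows = []

    screen = pd.read_csv(outdir / "screen_report.tsv", sep="\t").fillna({"flags": ""})
    multi = screen[
        screen["flags"].str.contains("recurrence") & screen["flags"].str.contains(",")
    ]
    rows.append(
        {
            "model": "classic_two_hit",
            "supported": bool(len(multi)),
            "detail": f"{len(multi)} gene(s) recurrent plus biallelic/deleterious",
        }
    )

    # the epigenetic model concerns autosomal hypermethylation; the X-like
    # chromosome is the reversed special case (LOH keeps the active copy)
    meth = pd.read_csv(outdir / "methylation_contrasts.tsv", sep="\t")
    auto = meth[meth["chrom"] != "chrX"]
    sig = auto[auto["significant"]]
    up = int((sig["direction"] == "up_in_loh").sum())
    rows.append(
        {
            "model": "epigenetic_two_hit",
            "supported": bool(len(sig)) and up * 2 > len(sig),
            "detail": f"{len(sig)} significant autosomal probe(s), {up} up in LOH",
        }
    )

    panel = pd.read_csv(outdir / "enrichment_report.tsv", sep="\t")
    panel["excluded_genes"] = panel["excluded_genes"].fillna("")
    row = panel[
        (panel["class"] == "deleterious")
        & (panel["stratum"] == "CNN")
        & (panel["excluded_genes"] == "")
    ].iloc[0]
    rows.append(
        {
            "model": "mutation_load",
            "supported": bool(row["observed"] > row["expected"] and row["p"] < alpha),
            "detail": (
                f"deleterious in CNN-LOH {row['observed']:.3f} vs {row['expected']:.3f}"
                f" expected (p={row['p']:.3g})"
            ),
        }
    )

    expr = pd.read_csv(outdir / "expression_contrasts.tsv", sep="\t")
    sig_e = expr[expr["significant"]]
    down = int((sig_e["direction"] == "down_in_loh").sum())
    rows.append(
        {
            "model": "haploinsufficiency",
            "supported": bool(len(sig_e)) and down * 2 > len(sig_e),
            "detail": f"{len(sig_e)} significant gene(s), {down} under-expressed in LOH",
        }
    )

    ret = pd.read_csv(outdir / "retention_report.tsv", sep="\t")
    hits = ret[(ret["p"] < alpha) & (ret["direction"] == "risk_retained")]
    rows.append(
        {
            "model": "risk_retention",
            "supported": bool(len(hits)),
            "detail": f"{len(hits)} SNP(s) with significant risk-allele retention",
        }
    )
    return pd.DataFrame(rows)


def run_all(
    outdir,
    sim_config=None,
    thresholds: ThresholdSet | None = None,
    exclude_genes: Sequence[str] = (),
    config_path=None,
    seed: int | None = None,
) -> dict:
    """Run every stage in dependency order; returns the run manifest."""
    if sim_config is None:
        sim_config, thresholds, cfg_exclude = load_config(config_path, seed)
        exclude_genes = exclude_genes or cfg_exclude
    elif seed is not None:
        sim_config = dataclasses.replace(sim_config, rng_seed=int(seed))
    thresholds = thresholds or ThresholdSet()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = {
        "simulate": stage_simulate(sim_config, outdir),
        "call_loh": stage_call_loh(outdir, thresholds),
        "screen": stage_screen(outdir, thresholds),
        "enrich": stage_enrich(outdir, thresholds, exclude_genes),
        "methylation": stage_methylation(outdir, thresholds),
        "expression": stage_expression(outdir, thresholds),
        "risk": stage_risk(outdir, thresholds),
    }
    verdicts = model_verdicts(outdir, thresholds)
    vpath = outdir / "model_verdicts.tsv"
    verdicts.to_csv(vpath, sep="\t", index=False)
    stages["verdicts"] = [vpath]
    manifest = {
        "tool": "lohsel",
        "version": __version__,
        "seed": sim_config.rng_seed,
        "thresholds": dataclasses.asdict(thresholds),
        "exclude_genes": list(exclude_genes),
        "stages": {
            name: {p.name: _digest(p) for p in paths} for name, paths in stages.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
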