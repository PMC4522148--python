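"""Somatic-variant filtering and the candidate tumour-suppressor screen.

Raw tumour/normal variant calls are accepted as somatic only when the
variant was not called in the matched normal, is supported by fewer than
two reads in the normal, and is seen on both sequencing strands in the
tumour.  Accepted mutations are classified as synonymous, other
non-synonymous (missense, in-frame indel) or overtly deleterious
(nonsense, frameshift, essential splice site), and each (gene, sample)
pair is assessed for biallelic inactivation: mutation plus LOH of the
wild-type allele, homozygous deletion, or two independent mutations.

Three discovery filters mirror a classical two-hit screen: recurrence
beyond the cohort background mutation rate (a Bonferroni-corrected
upper-tail binomial test standing in for a full background-rate model),
a high proportion of biallelically inactivated carriers, and a majority
of overtly deleterious mutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import stats
from .landscape import ThresholdSet

__all__ = [
    "CONSEQUENCES",
    "MAF_CLASSIFICATION",
    "somatic_filter",
    "filter_calls",
    "classify_mutation",
    "annotate_loh",
    "biallelic_status",
    "gene_recurrence_test",
    "screen_genes",
    "wildtype_loh_rates",
    "read_maf",
    "write_maf",
]

CONSEQUENCES = (
    "synonymous",
    "missense",
    "inframe_indel",
    "nonsense",
    "frameshift",
    "essential_splice",
)

_CLASS_OF = {
    "synonymous": "synonymous",
    "missense": "non_synonymous_other",
    "inframe_indel": "non_synonymous_other",
    "nonsense": "deleterious",
    "frameshift": "deleterious",
    "essential_splice": "deleterious",
}

# MAF Variant_Classification <-> internal consequence tags
MAF_CLASSIFICATION = {
    "synonymous": "Silent",
    "missense": "Missense_Mutation",
    "inframe_indel": "In_Frame_Del",
    "nonsense": "Nonsense_Mutation",
    "frameshift": "Frame_Shift_Del",
    "essential_splice": "Splice_Site",
}
_CONSEQUENCE_OF_MAF = {v: k for k, v in MAF_CLASSIFICATION.items()}
_CONSEQUENCE_OF_MAF["In_Frame_Ins"] = "inframe_indel"
_CONSEQUENCE_OF_MAF["Frame_Shift_Ins"] = "frameshift"


def somatic_filter(call) -> tuple[bool, str]:
    """Accept or reject one raw variant call; returns (accepted, reason).

    ``call`` is any mapping with called_in_normal, n_alt_count,
    t_fwd_count and t_rev_count.  Reason codes: ``germline_call``,
    ``normal_support``, ``unidirectional`` or ``pass``.
    """
    if bool(call["called_in_normal"]):
        return False, "germline_call"
    if int(call["n_alt_count"]) >= 2:
        return False, "normal_support"
    if int(call["t_fwd_count"]) < 1 or int(call["t_rev_count"]) < 1:
        return False, "unidirectional"
    return True, "pass"


def filter_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`somatic_filter`; appends accepted/reason columns."""
    out = calls.copy()
    germ = calls["called_in_normal"].astype(bool).to_numpy()
    normal = calls["n_alt_count"].to_numpy() >= 2
    unidir = (calls["t_fwd_count"].to_numpy() < 1) | (calls["t_rev_count"].to_numpy() < 1)
    reason = np.full(len(calls), "pass", dtype=object)
    reason[unidir] = "unidirectional"
    reason[normal & ~germ] = "normal_support"
    reason[germ] = "germline_call"
    out["accepted"] = ~(germ | normal | unidir)
    out["reason"] = reason
    return out


def classify_mutation(consequence: str) -> str:
    """Map a consequence tag to synonymous / non_synonymous_other / deleterious."""
    try:
        return _CLASS_OF[consequence]
    except KeyError:
        raise ValueError(f"unknown consequence tag: {consequence!r}") from None


def annotate_loh(mutations: pd.DataFrame, segments: pd.DataFrame) -> pd.DataFrame:
    """Attach in_loh / loh_type to each mutation from its sample's segments."""
    out = mutations.copy()
    in_loh = np.zeros(len(out), dtype=bool)
    loh_type = np.full(len(out), "none", dtype=object)
    seg_by_sample = {s: g for s, g in segments.groupby("sample", sort=False)}
    for i, mut in enumerate(out.itertuples(index=False)):
        segs = seg_by_sample.get(mut.sample)
        if segs is None:
            continue
        hit = segs[
            (segs["chrom"] == mut.chrom)
            & (segs["start"] <= mut.pos)
            & (mut.pos < segs["end"])
            & segs["loh"]
        ]
        if len(hit):
            in_loh[i] = True
            loh_type[i] = hit.iloc[0]["loh_type"]
    out["in_loh"] = in_loh
    out["loh_type"] = loh_type
    return out


def _gene_mean_total_cn(gene_row, sample_segments: pd.DataFrame) -> float:
    """Overlap-weighted mean total copy number over a gene footprint."""
    segs = sample_segments[sample_segments["chrom"] == gene_row["chrom"]]
    w = 0.0
    acc = 0.0
    for seg in segs.itertuples(index=False):
        ov = min(seg.end, gene_row["end"]) - max(seg.start, gene_row["start"])
        if ov > 0:
            acc += ov * seg.total_cn
            w += ov
    return acc / w if w > 0 else np.nan


def biallelic_status(
    gene: str,
    sample: str,
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    loci: pd.DataFrame,
    thresholds: ThresholdSet = ThresholdSet(),
) -> str:
    """Two-hit status of one (gene, sample) pair.

    Returns one of ``biallelic_mut_loh`` (a mutation inside an LOH
    segment), ``biallelic_homdel`` (gene mean total copy number below
    the homozygous-deletion threshold), ``biallelic_two_mut`` (two or
    more accepted mutations at distinct positions), ``monoallelic`` or
    ``unmutated``.
    """
    muts = mutations[(mutations["gene"] == gene) & (mutations["sample"] == sample)]
    if muts["in_loh"].any():
        return "biallelic_mut_loh"
    gene_rows = loci[loci["locus_id"] == gene]
    if len(gene_rows):
        ssegs = segments[segments["sample"] == sample]
        mean_cn = _gene_mean_total_cn(gene_rows.iloc[0], ssegs)
        if np.isfinite(mean_cn) and mean_cn < thresholds.homozygous_deletion_total_cn_max:
            return "biallelic_homdel"
    if muts["pos"].nunique() >= 2:
        return "biallelic_two_mut"
    return "monoallelic" if len(muts) else "unmutated"


def gene_recurrence_test(count, gene_length, background_rate, n_samples) -> float:
    """Upper-tail exact binomial p for a gene's mutation count.

    The null expectation is background_rate x gene_length x n_samples
    mutations, modelled as Binomial(gene_length x n_samples trials,
    background_rate per-base probability).  A much simpler recurrence
    test than full background-rate modelling frameworks, but monotone in
    the same quantity and easy to verify.
    """
    if background_rate <= 0:
        raise ValueError("background rate must be positive")
    n_trials = int(round(gene_length * n_samples))
    if count == 0:
        return 1.0
    return float(_sps.binom.sf(count - 1, n_trials, background_rate))


def _band(n_biallelic: int, n_mutated: int, thresholds: ThresholdSet) -> str:
    if n_mutated == 2:
        return "two_of_two" if n_biallelic == 2 else "below"
    if n_mutated < 3:
        return "below"
    frac = n_biallelic / n_mutated
    if frac > thresholds.biallelic_high:
        return "gt80"
    if frac >= thresholds.biallelic_mid:
        return "band60_80"
    return "below"


def screen_genes(
    mutations: pd.DataFrame,
    segments: pd.DataFrame,
    loci: pd.DataFrame,
    thresholds: ThresholdSet = ThresholdSet(),
) -> pd.DataFrame:
    """Run the three-filter candidate tumour-suppressor screen.

    ``mutations`` must be accepted calls already annotated with class
    and LOH overlap.  The biallelic band is only computed for genes
    mutated in >= 3 samples (with the exact-2/2 case reported as
    ``two_of_two``); "deleterious majority" requires strictly more than
    half of the gene's inactivating events (mutations plus homozygous
    gene deletions) to be overtly deleterious; the recurrence flag uses
    a Bonferroni cut at ``alpha`` across genes tested.
    """
    if mutations.empty:
        raise ValueError("no accepted mutations in cohort")
    n_samples = segments["sample"].nunique()
    territory_bp = float((loci["end"] - loci["start"]).sum())
    background_rate = len(mutations) / (territory_bp * n_samples)
    gene_len = dict(zip(loci["locus_id"], loci["end"] - loci["start"]))

    rows = []
    genes = sorted(mutations["gene"].unique())
    for gene in genes:
        gmut = mutations[mutations["gene"] == gene]
        carriers = sorted(gmut["sample"].unique())
        statuses = {
            s: biallelic_status(gene, s, mutations, segments, loci, thresholds)
            for s in carriers
        }
        n_biallelic = sum(1 for v in statuses.values() if v.startswith("biallelic"))
        n_homdel = sum(1 for v in statuses.values() if v == "biallelic_homdel")
        band = _band(n_biallelic, len(carriers), thresholds)
        n_del = int((gmut["class"] == "deleterious").sum()) + n_homdel
        n_events = len(gmut) + n_homdel
        p = gene_recurrence_test(
            len(gmut), gene_len.get(gene, int(np.mean(list(gene_len.values())))),
            background_rate, n_samples,
        )
        rows.append(
            {
                "gene": gene,
                "n_mutations": len(gmut),
                "n_mutated_samples": len(carriers),
                "n_biallelic": n_biallelic,
                "biallelic_band": band,
                "deleterious_majority": n_del * 2 > n_events,
                "recurrence_p": p,
            }
        )
    out = pd.DataFrame(rows)
    cut = stats.bonferroni_threshold(len(out), thresholds.alpha)
    flags = []
    for row in out.itertuples(index=False):
        f = []
        if row.recurrence_p < cut:
            f.append("recurrence")
        if row.biallelic_band in ("gt80", "band60_80", "two_of_two"):
            f.append("biallelic")
        if row.deleterious_majority:
            f.append("deleterious")
        flags.append(",".join(f))
    out["flags"] = flags
    return out


def wildtype_loh_rates(mutations: pd.DataFrame):
    """Wild-type-allele LOH rates by mutation class.

    "LOH of the wild-type allele" is operationalised as the mutation
    position falling inside a called LOH segment.  Returns (table,
    TestResult) where the table has one row per class (synonymous,
    non_synonymous_other, deleterious, plus pooled non_synonymous) with
    n_in_loh / n_total / fraction, and the test is the 2x2 chi-squared
    comparing pooled non-synonymous against synonymous.  Empty classes
    are reported with NaN fractions; the test is skipped (None) when
    either pooled class is empty.
    """
    rows = []
    groups = {
        "synonymous": mutations[mutations["class"] == "synonymous"],
        "non_synonymous_other": mutations[mutations["class"] == "non_synonymous_other"],
        "deleterious": mutations[mutations["class"] == "deleterious"],
        "non_synonymous": mutations[mutations["class"] != "synonymous"],
    }
    for name, grp in groups.items():
        n = len(grp)
        k = int(grp["in_loh"].sum())
        rows.append(
            {
                "class": name,
                "n_in_loh": k,
                "n_total": n,
                "fraction": k / n if n else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    syn = groups["synonymous"]
    nsyn = groups["non_synonymous"]
    result = None
    if len(syn) and len(nsyn):
        a = int(nsyn["in_loh"].sum())
        b = len(nsyn) - a
        c = int(syn["in_loh"].sum())
        d = len(syn) - c
        try:
            result = stats.chisq_2x2(a, b, c, d)
        except stats.DegenerateInputError:
            result = None
    return table, result


# ---------------------------------------------------------------------------
# MAF-like on-disk format

_MAF_COLS = {
    "gene": "Hugo_Symbol",
    "sample": "Tumor_Sample_Barcode",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
}
_EXTRA_COLS = ["t_fwd_count", "t_rev_count", "n_alt_count", "called_in_normal"]


def write_maf(mutations: pd.DataFrame, path) -> None:
    """Write a MAF-like table; raw-call read-support columns kept when present."""
    out = mutations.rename(columns=_MAF_COLS).copy()
    out["Variant_Classification"] = mutations["consequence"].map(MAF_CLASSIFICATION)
    cols = list(_MAF_COLS.values()) + ["Variant_Classification"]
    cols += [c for c in _EXTRA_COLS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like table back into the internal mutation dialect."""
    df = pd.read_csv(path, sep="\t", dtype={"Tumor_Sample_Barcode": str, "Chromosome": str})
    inv = {v: k for k, v in _MAF_COLS.items()}
    out = df.rename(columns=inv)
    out["consequence"] = df["Variant_Classification"].map(_CONSEQUENCE_OF_MAF)
    if out["consequence"].isna().any():
        bad = df.loc[out["consequence"].isna(), "Variant_Classification"].unique()
        raise ValueError(f"unknown Variant_Classification values: {list(bad)}")
    out["class"] = out["consequence"].map(_CLASS_OF)
    if "called_in_normal" in out.columns:
        out["called_in_normal"] = out["called_in_normal"].astype(bool)
    return out.drop(columns=["Variant_Classification"])
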