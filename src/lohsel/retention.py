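"""Germline risk-allele retention under LOH at predisposition SNPs.

The modified two-hit hypothesis: LOH could be selected because it
reduces a low-penetrance germline risk allele to homozygosity.  For
each risk SNP (or an LD proxy with r-squared > 0.7 inheriting the lead
SNP's risk-allele orientation), samples heterozygous in the germline
are tabulated by tumour genotype: still heterozygous (het), homozygous
for array allele A or B (aa / bb — allele loss), no-call (nc), with
germline homozygotes uninformative (hom).  Tumour homozygosity is taken
from the genotype calls themselves, not from segment overlap, so it may
include regions of extreme allelic imbalance; callers can cross-check
against called LOH segments separately.

The direction test asks whether loss is allele-biased: a 1-df Pearson
goodness-of-fit of (aa, bb) against an equal split, with direction
``risk_retained`` when the tumour-homozygous class carrying the risk
allele is the larger one.  %LOH is allele-loss cases over all
informative heterozygotes, aa+bb over het+aa+bb.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "RiskSNP",
    "RetentionTable",
    "RetentionResult",
    "tabulate_snp",
    "retention_test",
    "locus_consistency",
    "read_retention_counts",
    "bundled_counts_path",
    "run_counts_table",
    "read_genotypes",
    "read_snp_manifest",
]

GENOTYPES = ("AA", "AB", "BB", "NC")


@dataclass(frozen=True)
class RiskSNP:
    """A predisposition SNP (or LD proxy) with its risk-allele mapping."""

    snp_id: str
    locus: str
    risk_array_allele: str | None  # "A" or "B"; None when unoriented
    risk_is_minor: bool | None = None
    lead_snp: str | None = None
    r2_to_lead: float | None = None

    def __post_init__(self) -> None:
        if self.risk_array_allele not in (None, "A", "B"):
            raise ValueError(f"risk array allele must be A/B/None, got {self.risk_array_allele!r}")


@dataclass(frozen=True)
class RetentionTable:
    """Germline/tumour genotype cross-tabulation at one SNP."""

    snp_id: str
    het: int
    hom: int
    aa: int
    bb: int
    nc: int

    @property
    def n(self) -> int:
        return self.het + self.hom + self.aa + self.bb + self.nc

    @property
    def n_loh(self) -> int:
        return self.aa + self.bb


@dataclass(frozen=True)
class RetentionResult:
    table: RetentionTable
    p_value: float
    direction: str  # risk_retained / risk_lost / none
    pct_loh: float
    n_loh: int


def tabulate_snp(germline, tumour, snp_id: str = "") -> RetentionTable:
    """Cross-tabulate germline vs tumour genotype calls for one SNP.

    ``germline`` and ``tumour`` are equal-length sequences of calls in
    {AA, AB, BB, NC}.  Any no-call in either compartment goes to nc;
    germline homozygotes are uninformative (hom) whatever the tumour
    call; germline heterozygotes split into het (tumour AB) or aa/bb
    (tumour homozygous).
    """
    g = np.asarray(germline, dtype=object)
    t = np.asarray(tumour, dtype=object)
    if g.shape != t.shape:
        raise ValueError("germline and tumour call vectors differ in length")
    bad = set(np.unique(g)) | set(np.unique(t))
    bad -= set(GENOTYPES)
    if bad:
        raise ValueError(f"unknown genotype calls: {sorted(bad)}")
    nc = (g == "NC") | (t == "NC")
    hom = ~nc & ((g == "AA") | (g == "BB"))
    het_g = ~nc & (g == "AB")
    return RetentionTable(
        snp_id=snp_id,
        het=int((het_g & (t == "AB")).sum()),
        hom=int(hom.sum()),
        aa=int((het_g & (t == "AA")).sum()),
        bb=int((het_g & (t == "BB")).sum()),
        nc=int(nc.sum()),
    )


def retention_test(table: RetentionTable, snp: RiskSNP) -> RetentionResult:
    """Allele-loss direction test at one SNP.

    With no allele-loss cases (aa + bb = 0) there is no test: NaN p,
    direction ``none``.  Swapping the A/B labels leaves the p-value
    unchanged and flips the direction.
    """
    n_loh = table.n_loh
    denom = table.het + n_loh
    pct = n_loh / denom if denom else np.nan
    if n_loh == 0:
        return RetentionResult(table, np.nan, "none", pct, 0)
    p = stats.chisq_gof_2(table.aa, table.bb).p_value
    direction = "none"
    if snp.risk_array_allele is not None and table.aa != table.bb:
        retained = table.aa if snp.risk_array_allele == "A" else table.bb
        lost = table.bb if snp.risk_array_allele == "A" else table.aa
        direction = "risk_retained" if retained > lost else "risk_lost"
    return RetentionResult(table, p, direction, pct, n_loh)


def locus_consistency(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-locus concordance of SNP-level retention results.

    ``results`` needs columns locus, snp_id, p, direction.  A locus is
    ``discordant`` when significant SNPs disagree in direction,
    ``concordant`` when two or more agree, ``partially_supported`` with
    exactly one significant SNP, else ``unsupported``.
    """
    rows = []
    for locus, grp in results.groupby("locus", sort=True):
        sig = grp[(grp["p"] < alpha) & (grp["direction"] != "none")]
        dirs = set(sig["direction"])
        if len(dirs) > 1:
            status = "discordant"
        elif len(sig) >= 2:
            status = "concordant"
        elif len(sig) == 1:
            status = "partially_supported"
        else:
            status = "unsupported"
        rows.append(
            {
                "locus": locus,
                "n_snps": len(grp),
                "n_significant": len(sig),
                "directions": ",".join(sorted(dirs)),
                "status": status,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# counts-table input (pre-tabulated het/hom/aa/bb/nc rows)


def bundled_counts_path():
    """Path to the bundled ovarian-cancer GWAS SNP retention counts."""
    return resources.files("lohsel").joinpath("data/ovarian_gwas_snp_loh.tsv")


def read_retention_counts(path) -> pd.DataFrame:
    """Read a pre-tabulated retention counts table, enforcing margins.

    Every row must satisfy het + hom + aa + bb + nc = n; violations
    raise ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str})
    margins = df[["het", "hom", "aa", "bb", "nc"]].sum(axis=1)
    bad = df.loc[margins != df["n"], "snp_id"]
    if len(bad):
        raise ValueError(f"count margins do not reconcile for: {list(bad)}")
    return df


def _snp_from_row(row) -> RiskSNP:
    risk = str(row.get("risk_allele", "") or "")
    allele = None
    minor = None
    if "/" in risk:
        freq_part, allele = risk.split("/", 1)
        minor = freq_part.strip().lower() == "minor"
        allele = allele.strip().upper()
    r2 = row.get("r2")
    return RiskSNP(
        snp_id=str(row["snp_id"]),
        locus=str(row.get("locus", "")),
        risk_array_allele=allele,
        risk_is_minor=minor,
        lead_snp=str(row["lead_snp"]) if "lead_snp" in row else None,
        r2_to_lead=float(r2) if r2 is not None and np.isfinite(r2) else None,
    )


def run_counts_table(counts: pd.DataFrame, alpha: float = 0.05):
    """Run the retention test on every row of a counts table.

    Returns ``(report, consistency)``: a per-SNP report shaped like the
    published retention table (het, hom, aa, bb, nc, n, chi-squared p,
    direction, pct_loh, n_loh) and the per-locus concordance summary.
    """
    rows = []
    for _, row in counts.iterrows():
        table = RetentionTable(
            snp_id=str(row["snp_id"]),
            het=int(row["het"]),
            hom=int(row["hom"]),
            aa=int(row["aa"]),
            bb=int(row["bb"]),
            nc=int(row["nc"]),
        )
        snp = _snp_from_row(row)
        res = retention_test(table, snp)
        rows.append(
            {
                "snp_id": table.snp_id,
                "locus": snp.locus,
                "lead_snp": snp.lead_snp,
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
    consistency = locus_consistency(report, alpha=alpha)
    return report, consistency


# ---------------------------------------------------------------------------
# raw genotype inputs


def read_genotypes(path) -> pd.DataFrame:
    """Tab-delimited snp_id, sample, germline_gt, tumour_gt."""
    return pd.read_csv(path, sep="\t", dtype=str)


def read_snp_manifest(path) -> pd.DataFrame:
    """Tab-delimited snp_id, locus, risk_allele, lead_snp, r2."""
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "lead_snp": str})
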