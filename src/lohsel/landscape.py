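"""LOH calling and typing from allele-specific copy number.

A genomic position is in loss of heterozygosity (LOH) when the minor
("min") allele carries fewer than 0.5 copies in the tumour relative to
the matched normal — regions of allelic imbalance where both alleles are
still present (minor copy number >= 0.5) are explicitly not LOH.  Called
LOH is typed by total copy number: copy-number loss (CNL-LOH, total
below 1.5) versus copy-number-neutral (CNN-LOH, total 1.5 or above,
i.e. the retained allele was duplicated or converted).

Coordinates are 0-based half-open throughout; BED is used on disk for
interval exports.  Probe-level calls are merged into maximal same-state
segments whose boundary sits at the first probe of the next run (the
final run on a chromosome is closed one modal probe-spacing after its
last probe), so on an evenly spaced probe grid segments tile the grid
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "InputError",
    "SEGMENT_COLUMNS",
    "call_loh",
    "classify_loh_type",
    "locus_state_matrix",
    "locus_profiles",
    "select_candidate_regions",
    "sample_territory_fractions",
    "territory_table",
    "read_allele_cn",
    "write_allele_cn",
    "read_segments",
    "write_segments",
    "write_loh_bed",
    "read_loci_bed",
    "write_loci_bed",
]

SEGMENT_COLUMNS = ["sample", "chrom", "start", "end", "total_cn", "minor_cn", "loh", "loh_type"]

# locus-state codes used by locus_state_matrix
STATE_UNCOVERED = -1
STATE_RETAINED = 0
STATE_CNL = 1
STATE_CNN = 2


class InputError(ValueError):
    """Malformed or unsorted input tables."""


@dataclass(frozen=True)
class ThresholdSet:
    """Every numeric cut-off used across the pipeline, in one place.

    loh_min_allele_max
        minor copy number below which a position is LOH (0.5 copies).
    cnl_total_cn_max
        total copy number below which LOH is typed CNL; the boundary
        value itself (1.5, the midpoint between one and two copies) is
        assigned CNN.
    homozygous_deletion_total_cn_max
        total copy number below which a region counts as homozygously
        deleted (0.5 copies).
    locus_enrichment_fraction
        a locus is CNL-enriched (resp. CNN-enriched) when strictly more
        than this share (2/3, ">66 %") of its LOH samples are CNL
        (resp. CNN).
    locus_min_loh_frequency
        loci with LOH in fewer than 20 % of informative samples are
        "insufficient" and excluded from locus-class comparisons.
    candidate_region_frequency
        minimal LOH regions recurrent in more than 35 % of the cohort
        (or of a histological subtype) become candidate regions.
    methylation_high / methylation_low
        beta-value category bounds; both cut-offs are open, so exactly
        0.75 / 0.25 are "intermediate".
    fc_up / fc_down
        fold-change (LOH mean / no-LOH mean) class bounds, 1.5 and 0.75.
    biallelic_high / biallelic_mid
        biallelic-inactivation proportion bands (> 0.80, and 0.60-0.80
        with 0.80 the upper edge of the lower band).
    ld_r2_min
        minimum r-squared for an LD proxy SNP to stand in for a GWAS
        lead SNP.
    alpha
        nominal family-wise significance level.
    """

    loh_min_allele_max: float = 0.5
    cnl_total_cn_max: float = 1.5
    homozygous_deletion_total_cn_max: float = 0.5
    locus_enrichment_fraction: float = 2.0 / 3.0
    locus_min_loh_frequency: float = 0.20
    candidate_region_frequency: float = 0.35
    methylation_high: float = 0.75
    methylation_low: float = 0.25
    fc_up: float = 1.5
    fc_down: float = 0.75
    biallelic_high: float = 0.80
    biallelic_mid: float = 0.60
    ld_r2_min: float = 0.7
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.methylation_low < self.methylation_high < 1.0:
            raise ValueError("need 0 < methylation_low < methylation_high < 1")
        if not self.fc_down < 1.0 < self.fc_up:
            raise ValueError("need fc_down < 1 < fc_up")
        if not self.biallelic_mid < self.biallelic_high:
            raise ValueError("need biallelic_mid < biallelic_high")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def classify_loh_type(segment, thresholds: ThresholdSet = ThresholdSet()) -> str:
    """Type an LOH segment as ``"CNL"`` or ``"CNN"`` by mean total copy number.

    ``segment`` is any mapping with ``loh`` and ``total_cn`` entries
    (a segment-table row).  Calling this on a non-LOH segment is a logic
    error.
    """
    if not bool(segment["loh"]):
        raise ValueError("classify_loh_type called on a non-LOH segment")
    return "CNL" if float(segment["total_cn"]) < thresholds.cnl_total_cn_max else "CNN"


def call_loh(track: pd.DataFrame, thresholds: ThresholdSet = ThresholdSet()) -> pd.DataFrame:
    """Call LOH segments from a per-SNP allele-specific copy-number track.

    ``track`` has columns sample, chrom, pos, major_cn, minor_cn and must
    be position-sorted within each (sample, chromosome).  A position is
    LOH iff minor_cn < 0.5 copies; adjacent same-state positions merge
    into maximal segments.  Returns a segment table with
    :data:`SEGMENT_COLUMNS`, sorted by sample, chrom, start.
    """
    required = {"sample", "chrom", "pos", "major_cn", "minor_cn"}
    missing = required - set(track.columns)
    if missing:
        raise InputError(f"track is missing columns: {sorted(missing)}")
    rows: list[tuple] = []
    for (sample, chrom), grp in track.groupby(["sample", "chrom"], sort=True):
        pos = grp["pos"].to_numpy()
        if pos.size > 1 and (np.diff(pos) <= 0).any():
            raise InputError(f"track not sorted by position for {sample}/{chrom}")
        minor = grp["minor_cn"].to_numpy(dtype=float)
        total = minor + grp["major_cn"].to_numpy(dtype=float)
        is_loh = minor < thresholds.loh_min_allele_max
        gap = int(np.median(np.diff(pos))) if pos.size > 1 else 1
        # run boundaries over the probe grid
        change = np.flatnonzero(np.diff(is_loh.astype(np.int8))) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [pos.size]))
        for lo, hi in zip(starts, ends):
            seg_start = int(pos[lo])
            seg_end = int(pos[hi]) if hi < pos.size else int(pos[-1]) + gap
            seg_total = float(total[lo:hi].mean())
            seg_minor = float(minor[lo:hi].mean())
            loh = bool(is_loh[lo])
            row = {
                "sample": sample,
                "chrom": chrom,
                "start": seg_start,
                "end": seg_end,
                "total_cn": seg_total,
                "minor_cn": seg_minor,
                "loh": loh,
                "loh_type": "none",
            }
            if loh:
                row["loh_type"] = classify_loh_type(row, thresholds)
            rows.append(row)
    out = pd.DataFrame(rows, columns=SEGMENT_COLUMNS)
    return out.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)


def _overlap_lengths(loci: pd.DataFrame, segments: pd.DataFrame):
    """Yield (locus_index, segment_row, overlap_bp) for overlapping pairs.

    Loci must be non-overlapping; both tables use half-open intervals.
    """
    by_chrom: dict = {}
    for chrom, grp in loci.reset_index(drop=True).groupby("chrom", sort=False):
        order = np.argsort(grp["start"].to_numpy())
        idx = grp.index.to_numpy()[order]
        by_chrom[chrom] = (
            grp["start"].to_numpy()[order],
            grp["end"].to_numpy()[order],
            idx,
        )
    for seg in segments.itertuples(index=False):
        entry = by_chrom.get(seg.chrom)
        if entry is None:
            continue
        starts, ends, idx = entry
        lo = int(np.searchsorted(ends, seg.start, side="right"))
        hi = int(np.searchsorted(starts, seg.end, side="left"))
        for j in range(lo, hi):
            ov = min(ends[j], seg.end) - max(starts[j], seg.start)
            if ov > 0:
                yield int(idx[j]), seg, int(ov)


def locus_state_matrix(segments: pd.DataFrame, loci: pd.DataFrame):
    """Per-(locus, sample) LOH state from a cohort segment table.

    Returns ``(states, samples)`` where ``states`` is an int8 array of
    shape (n_loci, n_samples) holding ``STATE_UNCOVERED`` (-1, no
    segment overlaps the locus for that sample), ``STATE_RETAINED`` (0),
    ``STATE_CNL`` (1) or ``STATE_CNN`` (2).  When segments of several
    states overlap one locus the state with the largest overlap wins.
    """
    samples = sorted(segments["sample"].unique())
    s_idx = {s: i for i, s in enumerate(samples)}
    n_loci = len(loci)
    ov = np.zeros((3, n_loci, len(samples)))  # retained / CNL / CNN overlap bp
    code = {"none": 0, "CNL": 1, "CNN": 2}
    for li, seg, bp in _overlap_lengths(loci, segments):
        ov[code[seg.loh_type], li, s_idx[seg.sample]] += bp
    covered = ov.sum(axis=0) > 0
    states = np.where(covered, ov.argmax(axis=0), STATE_UNCOVERED).astype(np.int8)
    return states, samples


def locus_profiles(
    segments: pd.DataFrame,
    loci: pd.DataFrame,
    thresholds: ThresholdSet = ThresholdSet(),
) -> pd.DataFrame:
    """Cohort-wide LOH frequency and CNL/CNN enrichment class per locus.

    ``loh_frequency`` is the share of informative (covered) samples with
    LOH overlapping the locus.  A locus is CNL-enriched when strictly
    more than 2/3 of its LOH samples are CNL, CNN-enriched when strictly
    more than 2/3 are CNN, "insufficient" when LOH frequency is below
    20 % (or no sample is informative), otherwise "neither".
    """
    states, _ = locus_state_matrix(segments, loci)
    informative = (states >= 0).sum(axis=1)
    n_cnl = (states == STATE_CNL).sum(axis=1)
    n_cnn = (states == STATE_CNN).sum(axis=1)
    n_loh = n_cnl + n_cnn
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(informative > 0, n_loh / np.maximum(informative, 1), np.nan)
        cnl_share = np.where(n_loh > 0, n_cnl / np.maximum(n_loh, 1), np.nan)
    classes = []
    f = thresholds.locus_enrichment_fraction
    for i in range(len(loci)):
        if informative[i] == 0 or freq[i] < thresholds.locus_min_loh_frequency:
            classes.append("insufficient")
        elif n_loh[i] > 0 and cnl_share[i] > f:
            classes.append("CNL-enriched")
        elif n_loh[i] > 0 and (1.0 - cnl_share[i]) > f:
            classes.append("CNN-enriched")
        else:
            classes.append("neither")
    return pd.DataFrame(
        {
            "locus_id": loci["locus_id"].to_numpy(),
            "chrom": loci["chrom"].to_numpy(),
            "n_informative": informative,
            "n_loh": n_loh,
            "loh_frequency": freq,
            "cnl_share_of_loh": cnl_share,
            "enrichment_class": classes,
        }
    )


def select_candidate_regions(
    profiles: pd.DataFrame,
    loci: pd.DataFrame,
    segments: pd.DataFrame,
    subtype_profiles: Mapping[str, pd.DataFrame] | None = None,
    thresholds: ThresholdSet = ThresholdSet(),
) -> pd.DataFrame:
    """Select candidate tumour-suppressor loci from recurrent LOH.

    A locus is selected when its overall LOH frequency exceeds 35 %, or
    any histological subtype's frequency exceeds 35 %, or it overlaps a
    recurrent homozygous deletion (total copy number < 0.5 in at least
    two samples).  Returns the overall profiles with ``selected`` and
    ``reason`` columns appended.
    """
    out = profiles.copy()
    fmin = thresholds.candidate_region_frequency
    selected = profiles["loh_frequency"].to_numpy() > fmin
    reason = np.array(["overall_frequency" if s else "" for s in selected], dtype=object)
    if subtype_profiles:
        for name, sp in subtype_profiles.items():
            hit = sp["loh_frequency"].to_numpy() > fmin
            reason[hit & ~selected] = f"subtype_frequency:{name}"
            selected = selected | hit
    # recurrent homozygous deletions
    homdel = segments[segments["total_cn"] < thresholds.homozygous_deletion_total_cn_max]
    if len(homdel):
        carriers: dict[int, set] = {}
        for li, seg, _bp in _overlap_lengths(loci, homdel):
            carriers.setdefault(li, set()).add(seg.sample)
        for li, samp in carriers.items():
            if len(samp) >= 2 and not selected[li]:
                selected[li] = True
                reason[li] = "recurrent_homozygous_deletion"
    out["selected"] = selected
    out["reason"] = reason
    return out


def sample_territory_fractions(segments: pd.DataFrame, loci: pd.DataFrame):
    """Base-pair-weighted (overall, CNL, CNN) LOH fractions of the gene territory.

    ``segments`` holds one sample's segments.  The overall fraction is
    exactly the CNL fraction plus the CNN fraction.
    """
    if loci.empty:
        raise ValueError("gene territory is empty")
    total_bp = float((loci["end"] - loci["start"]).sum())
    bp = {"CNL": 0, "CNN": 0}
    for _li, seg, ov in _overlap_lengths(loci, segments):
        if seg.loh_type in bp:
            bp[seg.loh_type] += ov
    cnl = bp["CNL"] / total_bp
    cnn = bp["CNN"] / total_bp
    return cnl + cnn, cnl, cnn


def territory_table(segments: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Per-sample LOH territory fractions (columns frac_loh, frac_cnl, frac_cnn)."""
    rows = []
    for sample, grp in segments.groupby("sample", sort=True):
        overall, cnl, cnn = sample_territory_fractions(grp, loci)
        rows.append({"sample": sample, "frac_loh": overall, "frac_cnl": cnl, "frac_cnn": cnn})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk formats


def read_allele_cn(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})


def write_allele_cn(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", index=False)


def read_segments(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    df["loh"] = df["loh"].astype(bool)
    return df


def write_segments(segments: pd.DataFrame, path) -> None:
    segments.sort_values(["sample", "chrom", "start"], kind="stable").to_csv(
        path, sep="\t", index=False
    )


def write_loh_bed(segments: pd.DataFrame, path) -> None:
    """Plain BED of LOH intervals, name = sample|loh_type."""
    loh = segments[segments["loh"]].sort_values(["chrom", "start", "sample"], kind="stable")
    bed = pd.DataFrame(
        {
            "chrom": loh["chrom"],
            "start": loh["start"],
            "end": loh["end"],
            "name": loh["sample"].astype(str) + "|" + loh["loh_type"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_loci_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "locus_id"],
        dtype={"chrom": str, "locus_id": str},
    )
    return df


def write_loci_bed(loci: pd.DataFrame, path) -> None:
    loci[["chrom", "start", "end", "locus_id"]].to_csv(path, sep="\t", index=False, header=False)
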