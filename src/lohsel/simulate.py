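"""Synthetic multi-omic tumour cohort with known ground truth.

A toy genome of fixed-size gene bins (default 1000 loci spread over four
autosome-like chromosomes plus one X-like chromosome) carries, per
sample: segmental LOH simulated as a stationary two-state Markov chain
over loci (contiguous runs, geometric segment lengths), typed CNL or
CNN per chromosome-specific shares; a noisy allele-specific copy-number
probe track; raw somatic variant calls (true mutations plus sequencing
artifacts that the somatic filter should remove) with a plantable
excess of overtly deleterious mutations inside CNN-LOH; methylation
beta values from a two-component Beta mixture with a plantable
hypermethylation shift in LOH carriers at a subset of probes (and an
X-inactivation-like pattern where LOH keeps the unmethylated active
copy); expression values with a plantable reduction in CNL-LOH
carriers; and germline/tumour genotypes at risk SNPs with a plantable
bias toward retaining the risk allele under LOH.

Exome-wide LOH territory defaults: 26.8 % CNL-LOH and 8.7 % CNN-LOH of
the gene territory per sample, i.e. 35.5 % LOH overall, with a smooth
per-locus frequency profile so that some loci exceed the 35 % candidate
threshold and others fall below the 20 % informative floor.  All
randomness flows through one seeded generator, in the fixed order:
segments, homozygous deletions, two-hit planting, copy-number noise,
mutations, methylation, expression, genotypes.  The same seed gives
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import screen as _screen

__all__ = [
    "ConfigurationError",
    "RiskSNPConfig",
    "SimConfig",
    "SyntheticCohort",
    "default_config",
    "null_config",
    "strong_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# truth-state codes per (locus, sample)
TRUTH_NONE, TRUTH_CNL, TRUTH_CNN, TRUTH_HOMDEL = 0, 1, 2, 3
TRUTH_TYPE = {TRUTH_NONE: "none", TRUTH_CNL: "CNL", TRUTH_CNN: "CNN", TRUTH_HOMDEL: "CNL"}


class ConfigurationError(ValueError):
    """Infeasible or inconsistent simulation parameters."""


@dataclass(frozen=True)
class RiskSNPConfig:
    """One simulated predisposition SNP.

    ``retention_odds`` is the odds that an LOH event at the SNP retains
    the risk allele rather than the non-risk allele (1 = unbiased).
    """

    snp_id: str
    locus_label: str
    locus_index: int
    risk_allele_freq: float = 0.3
    retention_odds: float = 1.0
    risk_array_allele: str = "A"
    risk_is_minor: bool = True
    lead_snp: str | None = None
    r2: float = 1.0


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of the synthetic cohort.

    Class mix is (synonymous, other non-synonymous, overtly deleterious)
    and must sum to 1.  ``deleterious_cnn_enrichment`` multiplies the
    sampling weight of CNN-LOH loci when placing deleterious mutations.
    Methylation/expression effects apply only in carriers (samples with
    LOH / CNL-LOH at the feature's locus).
    """

    n_samples: int = 100
    n_loci: int = 1000
    n_autosomes: int = 4  # plus one X-like chromosome
    locus_size: int = 10_000
    exome_cnl_fraction: float = 0.268
    exome_cnn_fraction: float = 0.087
    mean_segment_loci: float = 25.0
    locus_weight_amplitude: float = 0.45
    cnl_share_by_chrom: tuple[float, ...] = (0.95, 0.90, 0.85, 0.20, 0.875)
    cn_noise_sd: float = 0.05
    homdel_loci: tuple[int, ...] = (5,)
    n_homdel_samples: int = 3
    mutation_rate: float = 0.01  # per gene bin per sample
    class_mix: tuple[float, float, float] = (0.25, 0.62, 0.13)
    deleterious_cnn_enrichment: float = 1.2
    artifact_rate: float = 0.05
    two_hit_locus: int | None = None
    two_hit_sample_fraction: float = 0.0
    methylated_probe_fraction: float = 0.3
    methylation_baseline: tuple[tuple[float, float], ...] = ((2.0, 8.0), (8.0, 2.0))
    methylation_loh_shift: float = 0.3
    methylation_shift_fraction: float = 0.10
    methylation_shift_scope: str = "autosomes"  # autosomes | cnl_enriched | cnn_enriched
    x_inactivation_beta: tuple[float, float] = (5.0, 5.0)
    x_inactivation_drop: float = 0.3
    expression_mean: float = 8.0
    expression_gene_sd: float = 1.0
    expression_noise_sd: float = 1.0
    expression_cnl_effect: float = -1.0
    risk_snps: tuple[RiskSNPConfig, ...] | None = None
    genotype_no_call_rate: float = 0.03
    subtype_fractions: tuple[tuple[str, float], ...] = (
        ("HGS", 0.52),
        ("END", 0.33),
        ("MUC", 0.08),
        ("CC", 0.07),
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be >= 2")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if not np.isclose(sum(self.class_mix), 1.0):
            raise ConfigurationError("class_mix must sum to 1")
        f = self.exome_cnl_fraction + self.exome_cnn_fraction
        if not 0.0 <= f <= 0.9:
            raise ConfigurationError("exome CNL + CNN fraction must lie in [0, 0.9]")
        for p in (
            self.exome_cnl_fraction,
            self.exome_cnn_fraction,
            self.artifact_rate,
            self.methylation_shift_fraction,
            self.methylated_probe_fraction,
            self.genotype_no_call_rate,
            self.two_hit_sample_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability outside [0, 1]: {p}")
        if self.deleterious_cnn_enrichment < 1.0:
            raise ConfigurationError("deleterious_cnn_enrichment must be >= 1")
        if len(self.cnl_share_by_chrom) != self.n_autosomes + 1:
            raise ConfigurationError("cnl_share_by_chrom needs one entry per chromosome")
        if self.methylation_shift_scope not in ("autosomes", "cnl_enriched", "cnn_enriched"):
            raise ConfigurationError(f"unknown shift scope {self.methylation_shift_scope!r}")

    @property
    def n_chromosomes(self) -> int:
        return self.n_autosomes + 1

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_autosomes)] + ["chrX"]


def _default_risk_snps(config: SimConfig) -> tuple[RiskSNPConfig, ...]:
    """Six SNPs at high-LOH loci: one locus with planted retention bias
    (two linked SNPs, odds 4) and two unbiased loci."""
    per = _loci_per_chrom(config)
    starts = np.concatenate(([0], np.cumsum(per)[:-1]))
    hot = [int(s + per[i] // 4) for i, s in enumerate(starts[: config.n_autosomes])]
    return (
        RiskSNPConfig("snp01", "locA", hot[0], 0.40, 4.0, "A", True, "snp01", 1.0),
        RiskSNPConfig("snp02", "locA", hot[0] + 1, 0.35, 4.0, "B", True, "snp01", 0.9),
        RiskSNPConfig("snp03", "locB", hot[1 % len(hot)], 0.30, 1.0, "A", True, "snp03", 1.0),
        RiskSNPConfig("snp04", "locB", hot[1 % len(hot)] + 1, 0.30, 1.0, "B", False, "snp03", 0.85),
        RiskSNPConfig("snp05", "locC", hot[2 % len(hot)], 0.25, 1.0, "B", True, "snp05", 1.0),
        RiskSNPConfig("snp06", "locC", hot[2 % len(hot)] + 1, 0.20, 1.0, "A", False, "snp05", 0.8),
    )


def default_config(**overrides) -> SimConfig:
    """The standard study conditions."""
    return SimConfig(**overrides)


def null_config(**overrides) -> SimConfig:
    """All planted effects disabled: every model should be at its null."""
    base = dict(
        deleterious_cnn_enrichment=1.0,
        methylation_loh_shift=0.0,
        methylation_shift_fraction=0.0,
        x_inactivation_drop=0.0,
        expression_cnl_effect=0.0,
        two_hit_locus=None,
        two_hit_sample_fraction=0.0,
    )
    base.update(overrides)
    cfg = SimConfig(**base)
    if cfg.risk_snps is None:
        snps = tuple(replace(s, retention_odds=1.0) for s in _default_risk_snps(cfg))
        cfg = replace(cfg, risk_snps=snps)
    return cfg


def strong_config(**overrides) -> SimConfig:
    """Strong planted effects for power / recovery checks."""
    base = dict(
        deleterious_cnn_enrichment=3.0,
        methylation_loh_shift=0.3,
        expression_cnl_effect=-1.0,
        two_hit_locus=2,
        two_hit_sample_fraction=0.3,
    )
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SyntheticCohort:
    """The generated cohort plus its ground truth."""

    config: SimConfig
    samples: pd.DataFrame  # sample, subtype
    loci: pd.DataFrame  # locus_id, chrom, start, end
    acn: pd.DataFrame  # sample, chrom, pos, major_cn, minor_cn
    raw_calls: pd.DataFrame  # MAF-like dialect + read support + is_artifact
    methylation: pd.DataFrame  # probe x sample beta matrix
    probe_annotation: pd.DataFrame  # probe_id, chrom, locus_id
    expression: pd.DataFrame  # gene x sample matrix
    genotypes: pd.DataFrame  # snp_id, sample, germline_gt, tumour_gt
    snp_manifest: pd.DataFrame  # snp_id, locus, risk_allele, lead_snp, r2
    truth_states: np.ndarray  # (n_loci, n_samples) int8 codes

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample"])

    def truth_territory(self) -> pd.DataFrame:
        """Per-sample true (overall, CNL, CNN) LOH territory fractions."""
        cnl = np.isin(self.truth_states, (TRUTH_CNL, TRUTH_HOMDEL)).mean(axis=0)
        cnn = (self.truth_states == TRUTH_CNN).mean(axis=0)
        return pd.DataFrame(
            {
                "sample": self.sample_ids,
                "frac_loh": cnl + cnn,
                "frac_cnl": cnl,
                "frac_cnn": cnn,
            }
        )


def _loci_per_chrom(config: SimConfig) -> np.ndarray:
    n, k = config.n_loci, config.n_chromosomes
    per = np.full(k, n // k, dtype=int)
    per[: n % k] += 1
    return per


def _make_loci(config: SimConfig) -> pd.DataFrame:
    per = _loci_per_chrom(config)
    rows = []
    gid = 0
    for ci, chrom in enumerate(config.chrom_names):
        for j in range(per[ci]):
            rows.append(
                {
                    "locus_id": f"g{gid:04d}",
                    "chrom": chrom,
                    "start": j * config.locus_size,
                    "end": (j + 1) * config.locus_size,
                }
            )
            gid += 1
    return pd.DataFrame(rows)


def _locus_weights(config: SimConfig) -> np.ndarray:
    """Arm-level per-locus LOH frequency multipliers, mean 1 per chromosome.

    Each chromosome is split into two arms, one hot (1 + amplitude) and
    one cold (1 - amplitude), alternating which arm is hot so the toy
    genome carries both recurrent candidate regions and low-LOH
    territory.  Blockwise-constant weights keep the realized mean
    frequency exactly on target (the segment chain is restarted at
    stationarity at every arm boundary).
    """
    per = _loci_per_chrom(config)
    amp = config.locus_weight_amplitude
    parts = []
    for ci, n in enumerate(per):
        half = n // 2
        hot_first = ci % 2 == 0
        w = np.full(n, 1.0 - amp)
        if hot_first:
            w[:half] = 1.0 + amp
        else:
            w[half:] = 1.0 + amp
        # exact mean 1 per chromosome even for odd lengths
        if n:
            w *= n / w.sum()
        parts.append(w)
    return np.concatenate(parts)


def _arm_blocks(config: SimConfig):
    """(chrom_index, lo, hi) half-open locus ranges, one per chromosome arm."""
    per = _loci_per_chrom(config)
    starts = np.concatenate(([0], np.cumsum(per)[:-1]))
    blocks = []
    for ci, (lo, n) in enumerate(zip(starts, per)):
        half = n // 2
        if half:
            blocks.append((ci, int(lo), int(lo + half)))
        blocks.append((ci, int(lo + half), int(lo + n)))
    return blocks


def _simulate_states(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Segmental LOH truth states via a stationary Markov scan over loci.

    Within an arm the chain has constant LOH probability f: it enters
    the arm in a segment with probability f, continues a segment with
    probability 1 - 1/mean_segment_loci, and starts a new one from the
    retained state with the rate that makes f stationary — so the
    expected LOH territory equals the target exactly.
    """
    weights = _locus_weights(config)
    f_total = config.exome_cnl_fraction + config.exome_cnn_fraction
    target = np.clip(f_total * weights, 0.0, 0.95)
    m = config.mean_segment_loci
    cont = 1.0 - 1.0 / m
    states = np.zeros((config.n_loci, config.n_samples), dtype=np.int8)
    blocks = _arm_blocks(config)
    for s in range(config.n_samples):
        for ci, lo, hi in blocks:
            cnl_share = config.cnl_share_by_chrom[ci]
            state = TRUTH_NONE
            for i in range(lo, hi):
                f = target[i]
                if i == lo:
                    start_p = f
                elif state == TRUTH_NONE:
                    start_p = min((f / m) / max(1.0 - f, 1e-9), 1.0)
                else:
                    start_p = None
                if start_p is not None:
                    if rng.random() < start_p:
                        state = TRUTH_CNL if rng.random() < cnl_share else TRUTH_CNN
                elif rng.random() >= cont:
                    state = TRUTH_NONE
                states[i, s] = state
    return states


def _plant_homdel(config: SimConfig, states: np.ndarray, rng: np.random.Generator) -> None:
    for locus in config.homdel_loci:
        if not 0 <= locus < config.n_loci:
            raise ConfigurationError(f"homdel locus {locus} outside the genome")
        n = min(config.n_homdel_samples, config.n_samples)
        carriers = rng.choice(config.n_samples, size=n, replace=False)
        states[locus, carriers] = TRUTH_HOMDEL


def _plant_two_hit(config: SimConfig, states: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if config.two_hit_locus is None or config.two_hit_sample_fraction == 0.0:
        return np.zeros(config.n_samples, dtype=bool)
    if not 0 <= config.two_hit_locus < config.n_loci:
        raise ConfigurationError("two_hit_locus outside the genome")
    carriers = rng.random(config.n_samples) < config.two_hit_sample_fraction
    states[config.two_hit_locus, carriers] = TRUTH_CNN
    return carriers


def _simulate_acn(
    config: SimConfig, loci: pd.DataFrame, states: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """One noisy allele-specific copy-number probe per locus per sample."""
    sd = config.cn_noise_sd
    n_loci, n_samples = states.shape
    major = np.empty_like(states, dtype=float)
    minor = np.empty_like(states, dtype=float)
    noise = rng.normal(0.0, sd, size=(2, n_loci, n_samples))
    major_base = np.select(
        [states == TRUTH_NONE, states == TRUTH_CNL, states == TRUTH_CNN],
        [1.0, 1.0, 2.0],
        default=0.12,
    )
    major = np.maximum(major_base + noise[0], 0.0)
    minor_base = np.where(states == TRUTH_NONE, 1.0, 0.0)
    minor = np.where(
        states == TRUTH_NONE,
        minor_base + noise[1],
        np.abs(noise[1]) * np.where(states == TRUTH_HOMDEL, 0.4, 1.0),
    )
    minor = np.maximum(minor, 0.0)
    swap = minor > major
    major2 = np.where(swap, minor, major)
    minor = np.where(swap, major, minor)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    frames = []
    for j, s in enumerate(samples):
        frames.append(
            pd.DataFrame(
                {
                    "sample": s,
                    "chrom": loci["chrom"].to_numpy(),
                    "pos": loci["start"].to_numpy(),
                    "major_cn": major2[:, j],
                    "minor_cn": minor[:, j],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


_BASES = np.array(list("ACGT"))

_CONSEQ_BY_CLASS = {
    0: (("synonymous",), (1.0,)),
    1: (("missense", "inframe_indel"), (0.9, 0.1)),
    2: (("nonsense", "frameshift", "essential_splice"), (0.5, 0.35, 0.15)),
}


def _simulate_mutations(
    config: SimConfig,
    loci: pd.DataFrame,
    states: np.ndarray,
    two_hit_carriers: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n_loci, n_samples = states.shape
    samples = [f"S{j:03d}" for j in range(n_samples)]
    k = config.deleterious_cnn_enrichment
    rows = []
    chroms = loci["chrom"].to_numpy()
    starts = loci["start"].to_numpy()
    gene_ids = loci["locus_id"].to_numpy()
    size = config.locus_size
    for j, s in enumerate(samples):
        n_mut = rng.poisson(config.mutation_rate * n_loci)
        if n_mut == 0:
            continue
        classes = rng.choice(3, size=n_mut, p=list(config.class_mix))
        cnn_here = states[:, j] == TRUTH_CNN
        w_del = np.where(cnn_here, k, 1.0)
        w_del = w_del / w_del.sum()
        for c in classes:
            gi = int(rng.choice(n_loci, p=w_del)) if c == 2 else int(rng.integers(n_loci))
            pos = int(starts[gi] + rng.integers(size))
            ref, alt = rng.choice(4, size=2, replace=False)
            tags, probs = _CONSEQ_BY_CLASS[int(c)]
            conseq = str(rng.choice(tags, p=probs))
            is_artifact = rng.random() < config.artifact_rate
            t_fwd = 1 + int(rng.poisson(7))
            t_rev = 1 + int(rng.poisson(7))
            n_alt = 0
            in_normal = False
            if is_artifact:
                mode = int(rng.integers(3))
                if mode == 0:
                    in_normal = True
                elif mode == 1:
                    n_alt = 2 + int(rng.poisson(2))
                else:
                    t_rev = 0
            rows.append(
                {
                    "sample": s,
                    "gene": gene_ids[gi],
                    "chrom": chroms[gi],
                    "pos": pos,
                    "ref": _BASES[ref],
                    "alt": _BASES[alt],
                    "consequence": conseq,
                    "t_fwd_count": t_fwd,
                    "t_rev_count": t_rev,
                    "n_alt_count": n_alt,
                    "called_in_normal": in_normal,
                    "is_artifact": is_artifact,
                }
            )
        if config.two_hit_locus is not None and two_hit_carriers[j]:
            gi = config.two_hit_locus
            rows.append(
                {
                    "sample": s,
                    "gene": gene_ids[gi],
                    "chrom": chroms[gi],
                    "pos": int(starts[gi] + rng.integers(size)),
                    "ref": "C",
                    "alt": "T",
                    "consequence": "nonsense",
                    "t_fwd_count": 1 + int(rng.poisson(7)),
                    "t_rev_count": 1 + int(rng.poisson(7)),
                    "n_alt_count": 0,
                    "called_in_normal": False,
                    "is_artifact": False,
                }
            )
    cols = [
        "sample", "gene", "chrom", "pos", "ref", "alt", "consequence",
        "t_fwd_count", "t_rev_count", "n_alt_count", "called_in_normal", "is_artifact",
    ]
    df = pd.DataFrame(rows, columns=cols)
    df["class"] = df["consequence"].map(_screen._CLASS_OF) if len(df) else ""
    return df


def _shift_scope_chroms(config: SimConfig) -> set[int]:
    if config.methylation_shift_scope == "autosomes":
        return set(range(config.n_autosomes))
    picked = set()
    for ci in range(config.n_autosomes):
        share = config.cnl_share_by_chrom[ci]
        if config.methylation_shift_scope == "cnl_enriched" and share > 2.0 / 3.0:
            picked.add(ci)
        if config.methylation_shift_scope == "cnn_enriched" and share < 1.0 / 3.0:
            picked.add(ci)
    if not picked:
        raise ConfigurationError(
            f"no chromosome matches methylation_shift_scope={config.methylation_shift_scope!r}"
        )
    return picked


def _simulate_methylation(
    config: SimConfig, loci: pd.DataFrame, states: np.ndarray, rng: np.random.Generator
):
    n_loci, n_samples = states.shape
    per = _loci_per_chrom(config)
    chrom_idx = np.repeat(np.arange(config.n_chromosomes), per)
    is_x = chrom_idx == config.n_autosomes
    (a_lo, b_lo), (a_hi, b_hi) = config.methylation_baseline
    methylated = rng.random(n_loci) < config.methylated_probe_fraction
    scope = _shift_scope_chroms(config)
    eligible = (~methylated) & (~is_x) & np.isin(chrom_idx, list(scope))
    planted = np.zeros(n_loci, dtype=bool)
    n_plant = int(round(config.methylation_shift_fraction * eligible.sum()))
    if n_plant and config.methylation_loh_shift != 0.0:
        planted[rng.choice(np.flatnonzero(eligible), size=n_plant, replace=False)] = True
    a = np.where(is_x, config.x_inactivation_beta[0], np.where(methylated, a_hi, a_lo))
    b = np.where(is_x, config.x_inactivation_beta[1], np.where(methylated, b_hi, b_lo))
    beta = rng.beta(a[:, None], b[:, None], size=(n_loci, n_samples))
    loh = states > 0
    beta = beta + config.methylation_loh_shift * (planted[:, None] & loh)
    beta = beta - config.x_inactivation_drop * (is_x[:, None] & loh)
    beta = np.clip(beta, 0.001, 0.999)
    samples = [f"S{j:03d}" for j in range(n_samples)]
    probe_ids = ["p_" + g for g in loci["locus_id"]]
    matrix = pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=samples)
    annot = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": loci["chrom"].to_numpy(),
            "locus_id": loci["locus_id"].to_numpy(),
            "planted_shift": planted,
        }
    )
    return matrix, annot


def _simulate_expression(
    config: SimConfig, loci: pd.DataFrame, states: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    n_loci, n_samples = states.shape
    mu = rng.normal(config.expression_mean, config.expression_gene_sd, size=n_loci)
    values = mu[:, None] + rng.normal(0.0, config.expression_noise_sd, size=(n_loci, n_samples))
    cnl = np.isin(states, (TRUTH_CNL, TRUTH_HOMDEL))
    values = values + config.expression_cnl_effect * cnl
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(
        values, index=pd.Index(loci["locus_id"].to_numpy(), name="gene"), columns=samples
    )


def _simulate_genotypes(
    config: SimConfig, snps: tuple[RiskSNPConfig, ...], states: np.ndarray,
    rng: np.random.Generator,
):
    n_samples = states.shape[1]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    rows = []
    for snp in snps:
        if not 0 <= snp.locus_index < config.n_loci:
            raise ConfigurationError(f"risk SNP {snp.snp_id} locus outside the genome")
        q = snp.risk_allele_freq
        p_a = q if snp.risk_array_allele == "A" else 1.0 - q
        g_draw = rng.random(n_samples)
        germ = np.where(
            g_draw < p_a**2, "AA", np.where(g_draw < p_a**2 + 2 * p_a * (1 - p_a), "AB", "BB")
        ).astype(object)
        loh = states[snp.locus_index] > 0
        retain_risk = rng.random(n_samples) < snp.retention_odds / (1.0 + snp.retention_odds)
        tum = germ.copy()
        risk_hom = "AA" if snp.risk_array_allele == "A" else "BB"
        other_hom = "BB" if snp.risk_array_allele == "A" else "AA"
        lost = (germ == "AB") & loh
        tum[lost] = np.where(retain_risk[lost], risk_hom, other_hom)
        nc_g = rng.random(n_samples) < config.genotype_no_call_rate
        nc_t = rng.random(n_samples) < config.genotype_no_call_rate
        germ[nc_g] = "NC"
        tum[nc_t] = "NC"
        for j, s in enumerate(samples):
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "sample": s,
                    "germline_gt": germ[j],
                    "tumour_gt": tum[j],
                }
            )
    genotypes = pd.DataFrame(rows)
    manifest = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in snps],
            "locus": [s.locus_label for s in snps],
            "risk_allele": [
                ("minor/" if s.risk_is_minor else "major/") + s.risk_array_allele for s in snps
            ],
            "lead_snp": [s.lead_snp or s.snp_id for s in snps],
            "r2": [s.r2 for s in snps],
            "locus_index": [s.locus_index for s in snps],
        }
    )
    return genotypes, manifest


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort; deterministic given rng_seed."""
    rng = np.random.default_rng(config.rng_seed)
    loci = _make_loci(config)
    states = _simulate_states(config, rng)
    _plant_homdel(config, states, rng)
    carriers = _plant_two_hit(config, states, rng)
    acn = _simulate_acn(config, loci, states, rng)
    raw_calls = _simulate_mutations(config, loci, states, carriers, rng)
    methylation, probe_annot = _simulate_methylation(config, loci, states, rng)
    expression = _simulate_expression(config, loci, states, rng)
    snps = config.risk_snps if config.risk_snps is not None else _default_risk_snps(config)
    genotypes, manifest = _simulate_genotypes(config, snps, states, rng)
    samples = [f"S{j:03d}" for j in range(config.n_samples)]
    labels, probs = zip(*config.subtype_fractions)
    probs = np.asarray(probs, dtype=float)
    subtype = rng.choice(labels, size=config.n_samples, p=probs / probs.sum())
    sample_df = pd.DataFrame({"sample": samples, "subtype": subtype})
    return SyntheticCohort(
        config=replace(config, risk_snps=tuple(snps)),
        samples=sample_df,
        loci=loci,
        acn=acn,
        raw_calls=raw_calls,
        methylation=methylation,
        probe_annotation=probe_annot,
        expression=expression,
        genotypes=genotypes,
        snp_manifest=manifest,
        truth_states=states,
    )


# ---------------------------------------------------------------------------
# persistence


def _config_to_jsonable(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("risk_snps") is not None:
        d["risk_snps"] = [dict(s) if isinstance(s, dict) else s for s in d["risk_snps"]]
    return d


def _config_from_jsonable(d: dict) -> SimConfig:
    d = dict(d)
    if d.get("risk_snps") is not None:
        d["risk_snps"] = tuple(RiskSNPConfig(**s) for s in d["risk_snps"])
    for key in (
        "homdel_loci", "class_mix", "cnl_share_by_chrom", "x_inactivation_beta",
    ):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    if d.get("methylation_baseline") is not None:
        d["methylation_baseline"] = tuple(tuple(x) for x in d["methylation_baseline"])
    if d.get("subtype_fractions") is not None:
        d["subtype_fractions"] = tuple((str(a), float(b)) for a, b in d["subtype_fractions"])
    return SimConfig(**d)


def write_cohort(cohort: SyntheticCohort, directory) -> list[Path]:
    """Write every on-disk format consumed by the analysis modules.

    Emits sample table, locus BED, allele-specific CN, MAF-like raw
    calls, methylation beta matrix + probe annotation, expression
    matrix, genotypes + SNP manifest, plus ground_truth.json and the
    realized truth-state matrix.  Round-trips losslessly through
    :func:`read_cohort`.
    """
    from .landscape import write_loci_bed  # local import to avoid a cycle

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []

    def _w(name, fn):
        p = directory / name
        fn(p)
        paths.append(p)

    _w("samples.tsv", lambda p: cohort.samples.to_csv(p, sep="\t", index=False))
    _w("loci.bed", lambda p: write_loci_bed(cohort.loci, p))
    _w(
        "allele_cn.tsv",
        lambda p: cohort.acn.sort_values(["sample", "chrom", "pos"], kind="stable").to_csv(
            p, sep="\t", index=False
        ),
    )
    _w("raw_calls.maf", lambda p: _write_raw_maf(cohort.raw_calls, p))
    _w("methylation_beta.tsv", lambda p: cohort.methylation.to_csv(p, sep="\t"))
    _w(
        "probe_annotation.tsv",
        lambda p: cohort.probe_annotation.to_csv(p, sep="\t", index=False),
    )
    _w("expression.tsv", lambda p: cohort.expression.to_csv(p, sep="\t"))
    _w("genotypes.tsv", lambda p: cohort.genotypes.to_csv(p, sep="\t", index=False))
    _w("snp_manifest.tsv", lambda p: cohort.snp_manifest.to_csv(p, sep="\t", index=False))
    _w(
        "truth_states.tsv",
        lambda p: pd.DataFrame(
            cohort.truth_states,
            index=pd.Index(cohort.loci["locus_id"], name="locus_id"),
            columns=cohort.sample_ids,
        ).to_csv(p, sep="\t"),
    )
    realized = cohort.truth_territory()
    truth = {
        "config": _config_to_jsonable(cohort.config),
        "realized_mean_frac_cnl": float(realized["frac_cnl"].mean()),
        "realized_mean_frac_cnn": float(realized["frac_cnn"].mean()),
        "realized_locus_loh_frequency": (cohort.truth_states > 0).mean(axis=1).tolist(),
    }
    _w(
        "ground_truth.json",
        lambda p: p.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n"),
    )
    return paths


def _write_raw_maf(raw_calls: pd.DataFrame, path) -> None:
    out = raw_calls.rename(columns=_screen._MAF_COLS).copy()
    out["Variant_Classification"] = raw_calls["consequence"].map(_screen.MAF_CLASSIFICATION)
    cols = list(_screen._MAF_COLS.values()) + ["Variant_Classification"]
    cols += ["t_fwd_count", "t_rev_count", "n_alt_count", "called_in_normal", "is_artifact"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_cohort(directory) -> SyntheticCohort:
    """Reconstruct a cohort from the files written by :func:`write_cohort`."""
    from .landscape import read_loci_bed

    directory = Path(directory)
    truth = json.loads((directory / "ground_truth.json").read_text())
    config = _config_from_jsonable(truth["config"])
    raw = pd.read_csv(directory / "raw_calls.maf", sep="\t", dtype={"Chromosome": str})
    inv = {v: k for k, v in _screen._MAF_COLS.items()}
    raw = raw.rename(columns=inv)
    raw["consequence"] = raw.pop("Variant_Classification").map(
        {v: k for k, v in _screen.MAF_CLASSIFICATION.items()}
    )
    raw["class"] = raw["consequence"].map(_screen._CLASS_OF)
    raw["called_in_normal"] = raw["called_in_normal"].astype(bool)
    raw["is_artifact"] = raw["is_artifact"].astype(bool)
    states_df = pd.read_csv(directory / "truth_states.tsv", sep="\t", index_col=0)
    return SyntheticCohort(
        config=config,
        samples=pd.read_csv(directory / "samples.tsv", sep="\t", dtype={"sample": str}),
        loci=read_loci_bed(directory / "loci.bed"),
        acn=pd.read_csv(directory / "allele_cn.tsv", sep="\t", dtype={"sample": str, "chrom": str}),
        raw_calls=raw,
        methylation=pd.read_csv(directory / "methylation_beta.tsv", sep="\t", index_col=0),
        probe_annotation=pd.read_csv(directory / "probe_annotation.tsv", sep="\t"),
        expression=pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0),
        genotypes=pd.read_csv(directory / "genotypes.tsv", sep="\t", dtype=str),
        snp_manifest=pd.read_csv(directory / "snp_manifest.tsv", sep="\t"),
        truth_states=states_df.to_numpy(dtype=np.int8),
    )
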