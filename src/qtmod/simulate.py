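"""Synthetic genotype/phenotype generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: biallelic SNPs in Hardy-Weinberg equilibrium at configurable
minor-allele frequencies, optional Markov-copying LD blocks, an
X-flagged chromosome whose heterozygosity encodes genetic sex, raw
structure volumes built from a common ICV-scaling component, per-module
latent factors, planted per-SNP main effects and pairwise interaction
effects on module traits, covariate effects and Gaussian noise. A
companion defect injector plants the failure modes the QC stage must
catch (missingness, duplicated samples, sex flips, Hardy-Weinberg
violations, rare variants).

Every operation is deterministic given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeTable
from .roster import RoiRoster, default_roster, anatomical_assignment

__all__ = [
    "TruthSpec",
    "DefectSpec",
    "simulate_genotypes",
    "simulate_phenotypes",
    "inject_defects",
    "strong_signal_truth",
    "null_truth",
]


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------
def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.1, 0.5),
    n_ld_blocks: int = 0,
    seed: int = 0,
    *,
    ld_block_size: int = 20,
    ld_copy_prob: float = 0.9,
    x_fraction: float = 0.05,
    female_fraction: float = 0.5,
) -> GenotypeMatrix:
    """Draw an additive-coded genotype matrix under HWE.

    Each autosomal SNP is drawn independently as Binomial(2, maf) with
    maf ~ Uniform(maf_range), except inside LD blocks where each
    haplotype allele copies its left neighbour with probability
    ``ld_copy_prob`` (and is redrawn at the block's shared maf
    otherwise), giving geometric r^2 decay along the block. The last
    ``x_fraction`` of SNPs are placed on an X-flagged chromosome: males
    carry one X haplotype (dosage 0/2, zero heterozygosity), females
    two.

    Parameters
    ----------
    n_samples, n_snps
        Matrix dimensions (``n_samples >= 2``, ``n_snps >= 1``).
    maf_range
        Interval in (0, 0.5] the per-SNP minor-allele frequency is
        drawn from.
    n_ld_blocks
        Number of contiguous ``ld_block_size``-SNP blocks with Markov
        LD, placed at the start of the autosome; 0 for fully
        independent SNPs.
    seed
        Seed for the whole draw; identical arguments + seed give a
        bitwise-identical matrix.
    """
    if n_samples < 2 or n_snps < 1:
        raise ValueError("need n_samples >= 2 and n_snps >= 1")
    lo, hi = float(maf_range[0]), float(maf_range[1])
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
    if not (0.0 <= ld_copy_prob < 1.0):
        raise ValueError("ld_copy_prob must be in [0, 1)")
    n_x = int(round(x_fraction * n_snps))
    n_auto = n_snps - n_x
    if n_ld_blocks * ld_block_size > n_auto:
        raise ValueError("LD blocks do not fit in the autosomal SNP count")

    rng = np.random.default_rng(seed)
    sex_is_f = rng.random(n_samples) < female_fraction
    mafs = rng.uniform(lo, hi, size=n_snps)

    block_of = np.full(n_snps, -1, dtype=int)
    for b in range(n_ld_blocks):
        sl = slice(b * ld_block_size, (b + 1) * ld_block_size)
        block_of[sl] = b
        mafs[sl] = mafs[b * ld_block_size]  # shared maf keeps copying HWE-neutral

    h1 = np.empty((n_samples, n_snps), dtype=np.int8)
    h2 = np.empty((n_samples, n_snps), dtype=np.int8)
    for j in range(n_snps):
        fresh1 = (rng.random(n_samples) < mafs[j]).astype(np.int8)
        fresh2 = (rng.random(n_samples) < mafs[j]).astype(np.int8)
        if block_of[j] >= 0 and j > 0 and block_of[j] == block_of[j - 1]:
            keep1 = rng.random(n_samples) < ld_copy_prob
            keep2 = rng.random(n_samples) < ld_copy_prob
            h1[:, j] = np.where(keep1, h1[:, j - 1], fresh1)
            h2[:, j] = np.where(keep2, h2[:, j - 1], fresh2)
        else:
            h1[:, j] = fresh1
            h2[:, j] = fresh2

    dosages = (h1 + h2).astype(float)
    if n_x:
        # males: single X haplotype reported as homozygous diploid calls
        male = ~sex_is_f
        dosages[np.ix_(male, np.arange(n_auto, n_snps))] = (
            2.0 * h1[np.ix_(male, np.arange(n_auto, n_snps))]
        )

    chroms = np.empty(n_snps, dtype=object)
    if n_auto:
        # spread autosomal SNPs over chromosomes 1..22 in contiguous runs
        per = -(-n_auto // 22)
        chroms[:n_auto] = [str(1 + j // per) for j in range(n_auto)]
    chroms[n_auto:] = "X"
    pos = np.empty(n_snps, dtype=int)
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        pos[idx] = 10_000 + 5_000 * np.arange(len(idx))

    variant_meta = pd.DataFrame(
        {
            "snp": [f"snp{j + 1:06d}" for j in range(n_snps)],
            "chrom": chroms,
            "pos": pos,
            "a1": "A",
            "a2": "B",
            "is_x": chroms == "X",
            "ld_block": block_of,
        }
    )
    sample_meta = pd.DataFrame(
        {
            "sample": [f"S{i + 1:04d}" for i in range(n_samples)],
            "reported_sex": np.where(sex_is_f, "F", "M"),
        }
    )
    return GenotypeMatrix(dosages, variant_meta, sample_meta)


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------
@dataclass
class TruthSpec:
    """Generative ground truth for the phenotype simulator.

    Attributes
    ----------
    roster
        Structure roster; its expansion defines the phenotype columns.
    module_assignment_true
        Phenotype id -> module id; drives the latent-factor structure.
    icv_slopes_true
        ICV scaling slope per phenotype (mm^3 of structure per mm^3 of
        ICV); the normalization stage should recover these from NC rows.
    module_factor_sd
        Per-module sd of the dimensionless latent factor; phenotype i
        loads on its module factor with loading = typical volume, so a
        factor sd of 0.03 means ~3% correlated volume fluctuation.
    main_effects
        (snp id, module id, beta) triples; beta is added per copy of the
        minor allele to EACH member phenotype (mm^3 per allele), so the
        module trait moves by ``n_members * beta`` per allele.
    interaction_effects
        (snp1, snp2, module id, beta): beta multiplies the product of
        the two centred dosages, added to each member phenotype.
        Centring keeps interaction betas out of the marginal scan.
    covariate_betas
        module id -> {"age": b, "sex": b, "education": b} in mm^3 per
        unit of the covariate, applied to each member phenotype.
    noise_sd
        Residual sd (mm^3) per phenotype.
    seed
        Seed for covariates, factors and noise.
    """

    roster: RoiRoster = field(default_factory=default_roster)
    module_assignment_true: dict[str, int] = field(default_factory=dict)
    icv_slopes_true: dict[str, float] = field(default_factory=dict)
    module_factor_sd: dict[int, float] = field(default_factory=dict)
    main_effects: list[tuple[str, int, float]] = field(default_factory=list)
    interaction_effects: list[tuple[str, str, int, float]] = field(default_factory=list)
    covariate_betas: dict[int, dict[str, float]] = field(default_factory=dict)
    noise_sd: dict[str, float] = field(default_factory=dict)
    ad_fraction: float = 177.0 / 388.0
    icv_mean: float = 1.5e6
    icv_sd: float = 1.5e5
    seed: int = 0

    def __post_init__(self) -> None:
        phenos = self.roster.expand()
        if not self.module_assignment_true:
            self.module_assignment_true = anatomical_assignment(self.roster)
        if set(self.module_assignment_true) != set(phenos):
            raise ValueError("module_assignment_true must cover the expanded roster")
        typical = self.roster.typical_volumes()
        if not self.icv_slopes_true:
            # proportional head-size scaling: slope = typical volume / mean ICV
            self.icv_slopes_true = {p: typical[p] / self.icv_mean for p in phenos}
        if not self.noise_sd:
            self.noise_sd = {p: 0.01 * typical[p] for p in phenos}
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise_sd must be >= 0")
        mods = set(self.module_assignment_true.values())
        for _, m, _ in self.main_effects:
            if m not in mods:
                raise ValueError(f"main effect references unknown module {m}")
        for _, _, m, _ in self.interaction_effects:
            if m not in mods:
                raise ValueError(f"interaction effect references unknown module {m}")
        if not self.module_factor_sd:
            self.module_factor_sd = {m: 0.03 for m in mods}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roster"] = [asdict(e) for e in self.roster.entries]
        d["main_effects"] = [list(t) for t in self.main_effects]
        d["interaction_effects"] = [list(t) for t in self.interaction_effects]
        return d


def _truncated_normal(rng, mean, sd, size, low=None, high=None):
    x = rng.normal(mean, sd, size=size)
    for _ in range(100):
        bad = np.zeros(size, dtype=bool)
        if low is not None:
            bad |= x < low
        if high is not None:
            bad |= x > high
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(x, low, high) if (low is not None or high is not None) else x


def simulate_phenotypes(
    G: GenotypeMatrix, spec: TruthSpec
) -> tuple[PhenotypeTable, dict]:
    """Build raw volumes + covariates from genotypes under ``spec``.

    The generative model per phenotype i of sample s is

        ROIraw_i(s) = mu_i + eps_i * (ICV_s - icv_mean)
                      + mu_i * F_{m(i)}(s)
                      + sum_main beta * g(s)            [members of m(i)]
                      + sum_int  beta * gc1(s) * gc2(s) [centred dosages]
                      + covariate effects + Normal(0, noise_sd_i)

    where F_m is the module latent factor and eps_i the planted ICV
    slope. Returns the phenotype table and the truth record (the spec
    plus derived bookkeeping) for recovery tests.
    """
    phenos = spec.roster.expand()
    typical = spec.roster.typical_volumes()
    n = G.n_samples
    rng = np.random.default_rng(spec.seed)

    referenced = {s for s, _, _ in spec.main_effects}
    referenced |= {s for s, _, _, _ in spec.interaction_effects}
    referenced |= {s for _, s, _, _ in spec.interaction_effects}
    known = set(G.variant_ids)
    unknown = referenced - known
    if unknown:
        raise ValueError(f"truth spec references SNPs absent from genotypes: {sorted(unknown)[:5]}")

    age = _truncated_normal(rng, 75.5, 6.0, n, low=55.0, high=95.0)
    sex = (G.sample_meta["reported_sex"] == "M").astype(float).to_numpy()
    education = np.round(_truncated_normal(rng, 15.4, 3.0, n, low=6.0, high=20.0), 1)
    icv = _truncated_normal(rng, spec.icv_mean, spec.icv_sd, n, low=1.0)
    is_ad = rng.random(n) < spec.ad_fraction
    diagnosis = np.where(is_ad, "AD", "NC")
    # cognitive scores follow the diagnosis, for Table-1-style summaries
    mmse = np.where(
        is_ad,
        _truncated_normal(rng, 23.3, 2.1, n, low=0.0, high=30.0),
        _truncated_normal(rng, 29.1, 1.0, n, low=0.0, high=30.0),
    ).round(0)
    cdrsb = np.where(
        is_ad,
        _truncated_normal(rng, 4.3, 1.7, n, low=0.5, high=18.0),
        np.abs(rng.normal(0.0, 0.12, n)),
    ).round(1)

    modules = sorted(set(spec.module_assignment_true.values()))
    factors = {
        m: rng.normal(0.0, spec.module_factor_sd.get(m, 0.0), size=n) for m in modules
    }

    def dosage_of(snp: str) -> np.ndarray:
        col = G.dosages[:, G.variant_index([snp])[0]]
        if np.isnan(col).any():
            col = np.where(np.isnan(col), np.nanmean(col), col)
        return col

    # genetic contributions per module (added to each member phenotype)
    genetic = {m: np.zeros(n) for m in modules}
    for snp, m, beta in spec.main_effects:
        genetic[m] += beta * dosage_of(snp)
    for snp1, snp2, m, beta in spec.interaction_effects:
        g1, g2 = dosage_of(snp1), dosage_of(snp2)
        genetic[m] += beta * (g1 - g1.mean()) * (g2 - g2.mean())

    covar = {m: np.zeros(n) for m in modules}
    for m, betas in spec.covariate_betas.items():
        covar[m] = (
            betas.get("age", 0.0) * age
            + betas.get("sex", 0.0) * sex
            + betas.get("education", 0.0) * education
        )

    cols = {}
    for p in phenos:
        m = spec.module_assignment_true[p]
        mu = typical[p]
        vals = (
            mu
            + spec.icv_slopes_true[p] * (icv - spec.icv_mean)
            + mu * factors[m]
            + genetic[m]
            + covar[m]
            + rng.normal(0.0, spec.noise_sd[p], size=n)
        )
        cols[p] = vals

    data = pd.DataFrame(
        {
            "diagnosis": diagnosis,
            "age": np.round(age, 1),
            "sex": sex,
            "education": education,
            "MMSE": mmse,
            "CDRSB": cdrsb,
            "icv": icv,
            **cols,
        },
        index=pd.Index(G.sample_ids, name="sample"),
    )
    truth = {
        "module_assignment_true": dict(spec.module_assignment_true),
        "icv_slopes_true": dict(spec.icv_slopes_true),
        "main_effects": [list(t) for t in spec.main_effects],
        "interaction_effects": [list(t) for t in spec.interaction_effects],
        "icv_mean_generative": spec.icv_mean,
        "seed": spec.seed,
    }
    return PhenotypeTable(data, phenos), truth


# ----------------------------------------------------------------------
# defects
# ----------------------------------------------------------------------
@dataclass
class DefectSpec:
    """Planted QC failures.

    ``hwe_violation_snps`` forces exact genotype counts (n_AA, n_Aa,
    n_aa) summing to the sample count; ``low_maf_snps`` redraws a SNP at
    a forced MAF. Rates are probabilities in [0, 1].
    """

    missing_rate_samples: dict[str, float] = field(default_factory=dict)
    missing_rate_snps: dict[str, float] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    sex_flip_samples: list[str] = field(default_factory=list)
    hwe_violation_snps: list[tuple[str, tuple[int, int, int]]] = field(
        default_factory=list
    )
    low_maf_snps: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for rate in list(self.missing_rate_samples.values()) + list(
            self.missing_rate_snps.values()
        ):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("missingness rates must be in [0, 1]")
        touched = [s for s, _ in self.hwe_violation_snps] + [
            s for s, _ in self.low_maf_snps
        ]
        if len(set(touched)) != len(touched):
            raise ValueError("conflicting defects force the same SNP twice")


def inject_defects(G: GenotypeMatrix, d: DefectSpec, seed: int = 0) -> GenotypeMatrix:
    """Return a defect-laden copy of ``G``; the original is untouched."""
    out = G.copy()
    rng = np.random.default_rng(seed)
    sample_pos = pd.Series(np.arange(out.n_samples), index=out.sample_meta["sample"].to_numpy())

    for snp, counts in d.hwe_violation_snps:
        if sum(counts) != out.n_samples:
            raise ValueError(f"forced counts for {snp} must sum to the sample count")
        j = out.variant_index([snp])[0]
        col = np.repeat([0.0, 1.0, 2.0], counts)
        rng.shuffle(col)
        out.dosages[:, j] = col

    for snp, maf in d.low_maf_snps:
        j = out.variant_index([snp])[0]
        out.dosages[:, j] = rng.binomial(2, maf, size=out.n_samples).astype(float)

    for src, dst in d.duplicate_pairs:
        out.dosages[sample_pos[dst], :] = out.dosages[sample_pos[src], :]

    for sid in d.sex_flip_samples:
        i = sample_pos[sid]
        cur = out.sample_meta.loc[i, "reported_sex"]
        out.sample_meta.loc[i, "reported_sex"] = "F" if cur == "M" else "M"

    for sid, rate in d.missing_rate_samples.items():
        i = sample_pos[sid]
        mask = rng.random(out.n_variants) < rate
        out.dosages[i, mask] = np.nan
    for snp, rate in d.missing_rate_snps.items():
        j = out.variant_index([snp])[0]
        mask = rng.random(out.n_samples) < rate
        out.dosages[mask, j] = np.nan
    return out


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------
def _module_trait_sd(spec_roster: RoiRoster, assignment: dict[str, int],
                     factor_sd: float, noise_frac: float) -> dict[int, float]:
    """Closed-form sd of each module trait under the generative model."""
    typical = spec_roster.typical_volumes()
    out: dict[int, float] = {}
    for m in sorted(set(assignment.values())):
        members = [p for p, mm in assignment.items() if mm == m]
        tot = sum(typical[p] for p in members)
        noise_var = sum((noise_frac * typical[p]) ** 2 for p in members)
        out[m] = float(np.sqrt((tot * factor_sd) ** 2 + noise_var))
    return out


def strong_signal_truth(
    G: GenotypeMatrix,
    seed: int = 0,
    *,
    n_main_per_module: int = 5,
    n_interactions: int = 2,
    partner_degree: int = 3,
    main_es: float = 2.6,
    interaction_es: float = 1.3,
    factor_sd: float = 0.03,
    noise_frac: float = 0.01,
) -> TruthSpec:
    """Truth spec with recoverable planted effects.

    Effect sizes are expressed in units of the BASE module-trait sd
    (latent factor + noise, before any genetic variance): ``main_es``
    is the trait shift per minor allele for the strongest main effect
    (weaker ones grade down by 6% per rank), ``interaction_es`` the
    shift per sd of the centred-dosage product for each interaction
    edge. Each planted partner SNP interacts with ``partner_degree``
    distinct anchors, mirroring the multi-anchor degree structure the
    network selection rewards. Planted effects add variance of their
    own, so realised standardized effects are smaller; the defaults
    keep the weakest planted main comfortably above the genome-wide
    noise floor at n ~ 400-500 samples.
    """
    rng = np.random.default_rng(seed)
    roster = default_roster()
    assignment = anatomical_assignment(roster)
    modules = sorted(set(assignment.values()))
    trait_sd = _module_trait_sd(roster, assignment, factor_sd, noise_frac)
    sizes = {m: sum(1 for v in assignment.values() if v == m) for m in modules}

    # plant on autosomal SNPs outside LD blocks with near-balanced MAF:
    # they comfortably survive the QC filters, and balanced dosages have
    # negligible skewness, so products of pairs sharing a SNP stay nearly
    # uncorrelated and pairwise interaction fits are unbiased
    ok = ~G.variant_meta["is_x"].to_numpy()
    if "ld_block" in G.variant_meta.columns:
        ok &= G.variant_meta["ld_block"].to_numpy() < 0
    ok &= G.maf() >= 0.3
    candidates = np.flatnonzero(ok)
    need = len(modules) * (n_main_per_module + n_interactions) + 5
    if len(candidates) < need:
        raise ValueError("too few eligible SNPs to plant the requested effects")
    picked = rng.choice(candidates, size=need, replace=False)
    picked = list(G.variant_ids.iloc[picked])

    def centred_product_sd(s1: str, s2: str) -> float:
        j1, j2 = G.variant_index([s1, s2])
        g1 = np.nan_to_num(G.dosages[:, j1], nan=np.nanmean(G.dosages[:, j1]))
        g2 = np.nan_to_num(G.dosages[:, j2], nan=np.nanmean(G.dosages[:, j2]))
        return float(((g1 - g1.mean()) * (g2 - g2.mean())).std())

    main_effects: list[tuple[str, int, float]] = []
    interaction_effects: list[tuple[str, str, int, float]] = []
    it = iter(picked)
    for m in modules:
        anchors = []
        for r in range(n_main_per_module):
            snp = next(it)
            anchors.append(snp)
            # graded strengths so recovery can be checked per rank
            beta = main_es * (1.0 - 0.06 * r) * trait_sd[m] / sizes[m]
            main_effects.append((snp, m, beta))
        deg = min(partner_degree, len(anchors))
        for _ in range(n_interactions):
            partner = next(it)
            picked_anchors = rng.choice(anchors, size=deg, replace=False)
            for anchor in picked_anchors:
                sd_prod = max(centred_product_sd(anchor, partner), 0.1)
                beta = interaction_es * trait_sd[m] / (sd_prod * sizes[m])
                interaction_effects.append((anchor, partner, m, beta))

    covariate_betas = {
        m: {"age": -0.15 * trait_sd[m] / sizes[m] / 10.0, "sex": 0.2 * trait_sd[m] / sizes[m], "education": 0.0}
        for m in modules
    }
    typical = roster.typical_volumes()
    return TruthSpec(
        roster=roster,
        module_assignment_true=assignment,
        module_factor_sd={m: factor_sd for m in modules},
        main_effects=main_effects,
        interaction_effects=interaction_effects,
        covariate_betas=covariate_betas,
        noise_sd={p: noise_frac * typical[p] for p in roster.expand()},
        seed=seed,
    )


def null_truth(seed: int = 0, *, factor_sd: float = 0.03, noise_frac: float = 0.01) -> TruthSpec:
    """Truth spec with no genetic effects (type-I calibration runs)."""
    roster = default_roster()
    typical = roster.typical_volumes()
    return TruthSpec(
        roster=roster,
        module_factor_sd={m: factor_sd for m in range(1, 6)},
        noise_sd={p: noise_frac * typical[p] for p in roster.expand()},
        seed=seed,
    )
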