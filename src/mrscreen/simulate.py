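"""Synthetic GWAS summary statistics with known causal ground truth.

The generator emulates the statistical structure of a microbiome-style
exposure GWAS paired with a disease/trait outcome GWAS: standardized
per-SNP effects whose standard errors follow the closed form
1/sqrt(2f(1−f)n), instruments planted to explain a target total variance
R², horizontal pleiotropy in four regimes (none / balanced / directional /
gross outliers), AR(1) LD blocks on pseudo-chromosomes, and the usual
harmonization hazards (palindromic alleles, strand flips, duplicated
records).

Scenario defaults mirror the strongest exposure–outcome pair of the study
conditions this package targets: a 13-instrument bacterial-family exposure
measured in 18,473 individuals explaining 2.61% of variance, a binary
psychiatric outcome GWAS of 46,351, and a causal effect of 0.24 per SD of
exposure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import HarmonizedSet, LDInfo
from .sumstats import CANONICAL_COLUMNS, SummaryStats

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Non-palindromic ordered allele pairs to draw from.
_SAFE_PAIRS = [(a, b) for a in "ACGT" for b in "ACGT"
               if a != b and _COMPLEMENT[a] != b]


@dataclass(frozen=True)
class SimScenario:
    """Generative scenario for one exposure–outcome pair.

    ``instrument_r2_target`` is the total exposure variance explained by
    the instruments, Σ 2f(1−f)γ²; the latent effects are rescaled so the
    realized sum matches it exactly.  ``pleiotropy_mode`` selects the
    regime for the direct instrument–outcome effects α:

    - ``none``: α = 0
    - ``balanced``: α ~ N(0, s²) (zero mean, InSIDE holds)
    - ``directional``: α ~ sign(γ)·N(s, (s/2)²) (nonzero mean along the
      exposure-increasing orientation, biases IVW)
    - ``outliers``: α = 0 except a random ``outlier_fraction`` of
      instruments receiving ±10 outcome-SEs
    where s = ``pleiotropy_scale``.
    """

    n_snps_total: int = 2000
    n_instruments: int = 13
    b_true: float = 0.24
    n_exp: float = 18_473.0
    n_out: float = 46_351.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    instrument_r2_target: float = 0.0261
    pleiotropy_mode: str = "none"
    pleiotropy_scale: float = 0.05
    outlier_fraction: float = 0.1
    ld_block_size: int = 1
    ld_rho: float = 0.0
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    duplicate_fraction: float = 0.0
    from_pool: bool = False
    seed: int | None = 0

    def __post_init__(self) -> None:
        if not 0 < self.instrument_r2_target < 1:
            raise ValueError("instrument_r2_target must lie in (0, 1)")
        if self.n_instruments > self.n_snps_total:
            raise ValueError("n_instruments cannot exceed n_snps_total")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        for name in ("palindromic_fraction", "strand_flip_fraction",
                     "duplicate_fraction", "outlier_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pleiotropy_mode not in ("none", "balanced", "directional",
                                        "outliers"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.ld_block_size < 1 or not 0 <= self.ld_rho < 1:
            raise ValueError("need ld_block_size ≥ 1 and 0 ≤ ld_rho < 1")


def _draw_instrument_effects(k: int, r2_target: float, maf: np.ndarray,
                             rng) -> np.ndarray:
    """Latent effects γ with signed magnitudes, rescaled so the realized
    Σ 2f(1−f)γ² equals ``r2_target`` exactly.

    Magnitudes are drawn from U(0.5, 1.5) before rescaling so no planted
    instrument is vanishingly weak relative to its peers.
    """
    raw = rng.uniform(0.5, 1.5, size=k) * rng.choice([-1.0, 1.0], size=k)
    scale = np.sqrt(r2_target / np.sum(2 * maf * (1 - maf) * raw**2))
    return raw * scale


def _pleiotropy(sc: SimScenario, gamma: np.ndarray, se_out: np.ndarray, rng
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-instrument direct outcome effects α and the planted-outlier mask.

    Directional pleiotropy is planted relative to the instrument's
    orientation (the allele that increases the exposure), i.e. aligned
    with sign(γ); otherwise random effect-allele coding would cancel the
    mean shift and the regime would degenerate to the balanced one.
    """
    k = len(gamma)
    alpha = np.zeros(k)
    outliers = np.zeros(k, dtype=bool)
    if sc.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, sc.pleiotropy_scale, size=k)
    elif sc.pleiotropy_mode == "directional":
        alpha = np.sign(gamma) * rng.normal(
            sc.pleiotropy_scale, sc.pleiotropy_scale / 2, size=k)
    elif sc.pleiotropy_mode == "outliers":
        n_out = max(1, int(round(sc.outlier_fraction * k)))
        idx = rng.choice(k, size=n_out, replace=False)
        outliers[idx] = True
        alpha[idx] = rng.choice([-1.0, 1.0], size=n_out) * 10.0 * se_out[idx]
    return alpha, outliers


def simulate_hset(sc: SimScenario, rng=None) -> tuple[HarmonizedSet, dict]:
    """Instrument-level draw, already harmonized (no allele bookkeeping).

    This is the fast path for estimator benchmarking: it generates only the
    ``n_instruments`` planted instruments and returns them as a
    :class:`HarmonizedSet` plus the ground-truth record.
    """
    rng = np.random.default_rng(sc.seed) if rng is None else rng
    k = sc.n_instruments
    maf = rng.uniform(*sc.maf_range, size=k)
    gamma = _draw_instrument_effects(k, sc.instrument_r2_target, maf, rng)
    het = 2 * maf * (1 - maf)
    se_exp = 1.0 / np.sqrt(het * sc.n_exp)
    se_out = 1.0 / np.sqrt(het * sc.n_out)
    alpha, outliers = _pleiotropy(sc, gamma, se_out, rng)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(sc.b_true * gamma + alpha, se_out)
    ids = np.array([f"rs{i + 1}" for i in range(k)])
    hset = HarmonizedSet(
        snp_ids=ids,
        beta_exp=beta_exp, se_exp=se_exp, eaf_exp=maf,
        beta_out=beta_out, se_out=se_out, eaf_out=maf,
        n_exp=np.full(k, sc.n_exp), n_out=np.full(k, sc.n_out),
    )
    truth = {
        "b_true": sc.b_true, "gamma": gamma, "alpha": alpha,
        "instrument_ids": list(ids), "outlier_ids": list(ids[outliers]),
    }
    return hset, truth


def _ld_blocks(n: int, block: int, rho: float) -> np.ndarray:
    """Block-diagonal r² matrix, AR(1) within blocks: r²(i,j) = ρ^(2|i−j|)."""
    r2 = np.eye(n)
    if block > 1 and rho > 0:
        for start in range(0, n, block):
            stop = min(start + block, n)
            idx = np.arange(start, stop)
            d = np.abs(idx[:, None] - idx[None, :])
            r2[start:stop, start:stop] = rho ** (2.0 * d)
    return r2


def simulate_pair(sc: SimScenario
                  ) -> tuple[SummaryStats, SummaryStats, LDInfo, dict]:
    """Full exposure/outcome summary-statistics pair with LD and hazards.

    Instruments are planted among ``n_snps_total`` SNPs; the remainder are
    null on both traits.  With ``from_pool`` the instruments' observed
    exposure effects are not forced above any significance threshold —
    p-value selection then operates as it would genome-wide (winner's
    curse included); by default the planted latent effects are simply
    strong enough that selection retains essentially all of them.

    SNPs are laid out on one pseudo-chromosome per LD block, 10 kb apart,
    so clumping-window logic is exercised.  Returns (exposure, outcome,
    LD reference, truth record).
    """
    rng = np.random.default_rng(sc.seed)
    n = sc.n_snps_total
    k = sc.n_instruments

    maf = rng.uniform(*sc.maf_range, size=n)
    het = 2 * maf * (1 - maf)
    se_exp = 1.0 / np.sqrt(het * sc.n_exp)
    se_out = 1.0 / np.sqrt(het * sc.n_out)

    inst = np.sort(rng.choice(n, size=k, replace=False))
    gamma_full = np.zeros(n)
    gamma_full[inst] = _draw_instrument_effects(
        k, sc.instrument_r2_target, maf[inst], rng)
    alpha_full = np.zeros(n)
    alpha_k, outliers_k = _pleiotropy(sc, gamma_full[inst], se_out[inst], rng)
    alpha_full[inst] = alpha_k

    beta_exp = rng.normal(gamma_full, se_exp)
    beta_out = rng.normal(sc.b_true * gamma_full + alpha_full, se_out)
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out / se_out))

    ids = np.array([f"rs{i + 1}" for i in range(n)])
    block = sc.ld_block_size
    chrom = (np.arange(n) // block + 1).astype(str)
    pos = (np.arange(n) % block) * 10_000 + 1

    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=n)
    ea = np.array([_SAFE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_SAFE_PAIRS[i][1] for i in pair_idx])
    pal = rng.random(n) < sc.palindromic_fraction
    pal_at = rng.random(n) < 0.5
    ea[pal] = np.where(pal_at[pal], "A", "C")
    oa[pal] = np.where(pal_at[pal], "T", "G")

    # outcome-side allele labels: same strand by default, complemented for
    # a designated fraction (harmonize must recognise and keep these)
    ea_out, oa_out = ea.copy(), oa.copy()
    flip = rng.random(n) < sc.strand_flip_fraction
    comp = np.vectorize(_COMPLEMENT.get)
    if flip.any():
        ea_out[flip] = comp(ea_out[flip])
        oa_out[flip] = comp(oa_out[flip])

    def _frame(beta, se, pv, n_samp, ea_c, oa_c):
        return pd.DataFrame({
            "SNP": ids, "CHR": chrom, "POS": pos, "EA": ea_c, "OA": oa_c,
            "EAF": maf, "BETA": beta, "SE": se, "P": np.clip(pv, 1e-300, 1.0),
            "N": np.full(n, float(n_samp)),
        })

    exp_df = _frame(beta_exp, se_exp, p_exp, sc.n_exp, ea, oa)
    out_df = _frame(beta_out, se_out, p_out, sc.n_out, ea_out, oa_out)

    dup = np.flatnonzero(rng.random(n) < sc.duplicate_fraction)
    if dup.size:
        exp_df = pd.concat([exp_df, exp_df.iloc[dup]], ignore_index=True)
        out_df = pd.concat([out_df, out_df.iloc[dup]], ignore_index=True)

    ld = LDInfo(snp_ids=list(ids), r2=_ld_blocks(n, block, sc.ld_rho))
    truth = {
        "b_true": sc.b_true,
        "instrument_ids": list(ids[inst]),
        "gamma": gamma_full[inst],
        "alpha": alpha_k,
        "outlier_ids": list(ids[inst][outliers_k]),
        "palindromic_ids": list(ids[pal]),
        "flipped_ids": list(ids[flip]),
        "duplicated_ids": list(ids[dup]),
    }
    exposure = SummaryStats("sim_exposure", exp_df, "continuous")
    outcome = SummaryStats("sim_outcome", out_df, "binary")
    return exposure, outcome, ld, truth


def simulate_confounder_table(snp_ids, n_traits: int, planted=(),
                              seed: int | None = 0) -> pd.DataFrame:
    """SNP × trait p-value table with known sub-threshold entries.

    Planted SNPs get one trait with p ~ U(0, 0.05); every other cell is
    p ~ U(0.05, 1), so a nominal 0.05 filter removes exactly the planted
    set.
    """
    snp_ids = list(snp_ids)
    planted = set(planted)
    unknown = planted - set(snp_ids)
    if unknown:
        raise ValueError(f"planted SNPs not in snp_ids: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.05, 1.0, size=(len(snp_ids), n_traits))
    cols = [f"trait_{t + 1}" for t in range(n_traits)]
    df = pd.DataFrame(p, index=pd.Index(snp_ids, name="SNP"), columns=cols)
    for snp in sorted(planted):
        df.loc[snp, cols[rng.integers(n_traits)]] = rng.uniform(0.0, 0.05)
    return df


def simulate_screen_bench(
    features,
    outcome_names,
    planted_effects: dict | None = None,
    base: SimScenario | None = None,
    n_trait_instruments: int = 10,
    trait_r2_target: float = 0.03,
    seed: int | None = 0,
):
    """Multi-feature × multi-outcome bench with disjoint instrument sets.

    ``features`` is a sequence of (feature_id, level) pairs; each feature
    gets its own pseudo-chromosome range so instrument sets never overlap.
    ``planted_effects`` maps (feature_id, outcome_name) to a true causal
    effect; all other pairs are null.

    Each outcome trait additionally carries ``n_trait_instruments`` of its
    own genetic instruments — SNPs with direct trait effects and no effect
    on any feature (the traits are heritable in their own right).  These
    make the bench usable for reverse screening: selecting instruments
    from a trait GWAS finds the trait's own loci, which are null on every
    feature, rather than only feature-mediated loci.

    Returns (exposures, outcomes, ld, truth) where exposures is a list of
    (feature_id, level, SummaryStats) and outcomes a list of SummaryStats.
    """
    planted_effects = dict(planted_effects or {})
    base = base or SimScenario(n_snps_total=60, n_instruments=8,
                               instrument_r2_target=0.03, n_out=50_000.0)
    root = np.random.SeedSequence(seed)
    feat_seeds = root.spawn(len(features))
    trait_seeds = root.spawn(len(outcome_names))

    # per-outcome trait-instrument blocks (meta shared across all tables)
    trait_blocks: dict[str, dict] = {}
    for oj, (oname, oseed) in enumerate(zip(outcome_names, trait_seeds)):
        orng = np.random.default_rng(oseed)
        m = n_trait_instruments
        maf = orng.uniform(*base.maf_range, size=m)
        het = 2 * maf * (1 - maf)
        gamma_t = _draw_instrument_effects(m, trait_r2_target, maf, orng)
        pair_idx = orng.integers(0, len(_SAFE_PAIRS), size=m)
        trait_blocks[oname] = {
            "ids": np.array([f"o{oj}_rs{i + 1}" for i in range(m)]),
            "chrom": np.full(m, str(900_000 + oj)),
            "pos": np.arange(m) * 1_000_000 + 1,
            "maf": maf, "het": het, "gamma": gamma_t,
            "ea": np.array([_SAFE_PAIRS[i][0] for i in pair_idx]),
            "oa": np.array([_SAFE_PAIRS[i][1] for i in pair_idx]),
            "rng": orng,
        }

    exposures = []
    outcome_frames: dict[str, list[pd.DataFrame]] = {o: [] for o in outcome_names}
    ld_ids: list[str] = []
    ld_blocks: list[np.ndarray] = []
    truth: dict = {"planted": planted_effects, "features": {},
                   "trait_instrument_ids": {
                       o: list(b["ids"]) for o, b in trait_blocks.items()}}

    for fi, ((fid, level), fseed) in enumerate(zip(features, feat_seeds)):
        child = fseed.spawn(2 + len(outcome_names))
        sc = replace(base, b_true=0.0, seed=None)
        rng = np.random.default_rng(child[0])
        exp, _, ld, ftruth = _simulate_feature(sc, rng, prefix=f"f{fi}_",
                                               chrom_offset=fi * 1000)
        # trait-instrument SNPs are null on this feature
        null_rng = np.random.default_rng(child[1])
        null_rows = [
            _null_rows_at(tb, sc.n_exp, null_rng) for tb in trait_blocks.values()
        ]
        exp_full = pd.concat([exp] + null_rows, ignore_index=True)
        exposures.append((fid, level, SummaryStats(fid, exp_full, "continuous")))
        ld_ids.extend(ld.snp_ids)
        ld_blocks.append(ld.r2)
        truth["features"][fid] = ftruth

        for oname, oseed in zip(outcome_names, child[2:]):
            b = planted_effects.get((fid, oname), 0.0)
            orng = np.random.default_rng(oseed)
            outcome_frames[oname].append(_outcome_for_feature(sc, ftruth, b, orng))

    # outcome tables: feature loci plus the trait's own instruments
    for oname, tb in trait_blocks.items():
        se_t = 1.0 / np.sqrt(tb["het"] * base.n_out)
        beta_t = tb["rng"].normal(tb["gamma"], se_t)
        p_t = 2.0 * stats.norm.sf(np.abs(beta_t / se_t))
        outcome_frames[oname].append(pd.DataFrame({
            "SNP": tb["ids"], "CHR": tb["chrom"], "POS": tb["pos"],
            "EA": tb["ea"], "OA": tb["oa"], "EAF": tb["maf"],
            "BETA": beta_t, "SE": se_t, "P": np.clip(p_t, 1e-300, 1.0),
            "N": np.full(len(se_t), base.n_out),
        }))
        ld_ids.extend(tb["ids"])
        ld_blocks.append(np.eye(len(tb["ids"])))

    from scipy.linalg import block_diag
    ld = LDInfo(snp_ids=ld_ids, r2=block_diag(*ld_blocks))
    outcomes = [
        SummaryStats(oname,
                     pd.concat(outcome_frames[oname], ignore_index=True),
                     "binary")
        for oname in outcome_names
    ]
    return exposures, outcomes, ld, truth


def _null_rows_at(tb: dict, n_samp: float, rng) -> pd.DataFrame:
    """Null association rows at another trait's instrument SNPs."""
    se = 1.0 / np.sqrt(tb["het"] * n_samp)
    beta = rng.normal(0.0, se)
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return pd.DataFrame({
        "SNP": tb["ids"], "CHR": tb["chrom"], "POS": tb["pos"],
        "EA": tb["ea"], "OA": tb["oa"], "EAF": tb["maf"],
        "BETA": beta, "SE": se, "P": np.clip(p, 1e-300, 1.0),
        "N": np.full(len(se), n_samp),
    })


def _simulate_feature(sc: SimScenario, rng, prefix: str, chrom_offset: int):
    """Exposure-side draw for one feature; returns (exp_df, None, ld, truth)."""
    n, k = sc.n_snps_total, sc.n_instruments
    maf = rng.uniform(*sc.maf_range, size=n)
    het = 2 * maf * (1 - maf)
    se_exp = 1.0 / np.sqrt(het * sc.n_exp)
    inst = np.sort(rng.choice(n, size=k, replace=False))
    gamma = np.zeros(n)
    gamma[inst] = _draw_instrument_effects(k, sc.instrument_r2_target,
                                           maf[inst], rng)
    beta_exp = rng.normal(gamma, se_exp)
    p_exp = 2.0 * stats.norm.sf(np.abs(beta_exp / se_exp))

    ids = np.array([f"{prefix}rs{i + 1}" for i in range(n)])
    block = sc.ld_block_size
    chrom = (np.arange(n) // block + 1 + chrom_offset).astype(str)
    pos = (np.arange(n) % block) * 10_000 + 1
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=n)
    ea = np.array([_SAFE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_SAFE_PAIRS[i][1] for i in pair_idx])

    exp_df = pd.DataFrame({
        "SNP": ids, "CHR": chrom, "POS": pos, "EA": ea, "OA": oa,
        "EAF": maf, "BETA": beta_exp, "SE": se_exp,
        "P": np.clip(p_exp, 1e-300, 1.0), "N": np.full(n, sc.n_exp),
    })
    ld = LDInfo(snp_ids=list(ids), r2=_ld_blocks(n, block, sc.ld_rho))
    ftruth = {"ids": ids, "chrom": chrom, "pos": pos, "maf": maf,
              "het": het, "gamma": gamma, "ea": ea, "oa": oa,
              "instrument_ids": list(ids[inst])}
    return exp_df, None, ld, ftruth


def _outcome_for_feature(sc: SimScenario, ftruth: dict, b: float, rng
                         ) -> pd.DataFrame:
    """Outcome summary rows at one feature's SNPs under causal effect b."""
    het = ftruth["het"]
    se_out = 1.0 / np.sqrt(het * sc.n_out)
    beta_out = rng.normal(b * ftruth["gamma"], se_out)
    p_out = 2.0 * stats.norm.sf(np.abs(beta_out / se_out))
    return pd.DataFrame({
        "SNP": ftruth["ids"], "CHR": ftruth["chrom"], "POS": ftruth["pos"],
        "EA": ftruth["ea"], "OA": ftruth["oa"], "EAF": ftruth["maf"],
        "BETA": beta_out, "SE": se_out, "P": np.clip(p_out, 1e-300, 1.0),
        "N": np.full(len(het), sc.n_out),
    })
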