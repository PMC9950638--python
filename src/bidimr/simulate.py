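"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a cytokine-to-retinopathy MR study:
a quantitative exposure GWAS of ~8,300 individuals, a binary outcome GWAS
given as log-odds with case/control counts (FinnGen-like 2,025/284,826 by
default, with an optional small eight-cohort-like second source), per-SNP
standard errors from the usual 1/sqrt(2*maf*(1-maf)*n) approximation (with
the effective sample size 4/(1/n_case + 1/n_control) for the binary trait),
genome-wide versus relaxed significance tiers made non-trivial by null
filler SNPs, summary-level LD blocks for clumping and proxy logic, and
configurable horizontal pleiotropy and reverse causation.

The generating model per causal SNP j is

    gamma_j ~ Normal(gamma_dist),  alpha_j = 0 w.p. 1-rho else Normal(mu, sd)
    Gamma_j = theta * gamma_j + alpha_j
    beta_exp_j ~ Normal(gamma_j, se_exp_j),  beta_out_j ~ Normal(Gamma_j, se_out_j)

When ``reverse_theta`` is non-zero the causal SNPs are outcome-driven
instead: ``gamma_dist`` parameterises the direct outcome effect delta_j and
the exposure effect is the reverse-transmitted ``reverse_theta * delta_j``,
so Steiger filtering has real signal to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .instruments import LDPanel
from .sumstats import SummaryStatRecord

_NONPALINDROMIC = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                   ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PMIN = 1e-320


@dataclass
class SimulationTruth:
    """Generating parameters of one synthetic exposure-outcome pair."""

    theta: float = 0.0                     # true causal effect (log-odds per SD)
    k_snps: int = 30                       # causal instruments
    gamma_dist: tuple = (0.25, 0.05)       # (mean, sd) of true exposure effects
    gamma_min: float | None = None         # optional lower truncation of gamma
    pleiotropy: tuple = (0.0, 0.0, 0.0)    # (invalid fraction rho, mu_alpha, sd_alpha)
    inside_violation: bool = False         # pleiotropy proportional to strength
    reverse_theta: float = 0.0             # outcome -> exposure effect
    n_exp: int = 8293                      # exposure GWAS sample size
    n_out_case: int = 2025
    n_out_control: int = 284826
    maf_range: tuple = (0.1, 0.5)
    ld_blocks: list = field(default_factory=list)   # [(block size, within r2)]
    seed: int = 0
    n_null: int = 150                      # unassociated filler SNPs
    palindromic_fraction: float = 0.0
    outcome_allele_swap_fraction: float = 0.2
    outcome_missing_fraction: float = 0.0
    n_outlier_snps: int = 0
    outlier_alpha_sd_multiple: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"invalid maf_range {self.maf_range}")
        rho = self.pleiotropy[0]
        if not 0.0 <= rho <= 1.0:
            raise ConfigurationError(f"invalid pleiotropy fraction {rho}")

    @property
    def n_out_effective(self) -> float:
        return 4.0 / (1.0 / self.n_out_case + 1.0 / self.n_out_control)


def _se(maf: np.ndarray, n: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _draw_truth_effects(truth: SimulationTruth, rng: np.random.Generator) -> dict:
    """Per-causal-SNP ground truth and sampling scales."""
    k = truth.k_snps
    maf = rng.uniform(*truth.maf_range, size=k)
    rho, mu_a, sd_a = truth.pleiotropy
    mean_g, sd_g = truth.gamma_dist

    drawn = rng.normal(mean_g, sd_g, size=k)
    if truth.gamma_min is not None:
        drawn = np.maximum(drawn, truth.gamma_min)

    invalid = rng.random(k) < rho
    alpha = np.zeros(k)
    if invalid.any():
        alpha[invalid] = rng.normal(mu_a, sd_a, size=int(invalid.sum()))
        if truth.inside_violation and mean_g != 0:
            alpha[invalid] *= drawn[invalid] / mean_g

    is_outlier = np.zeros(k, dtype=bool)
    if truth.n_outlier_snps > 0:
        idx = np.arange(min(truth.n_outlier_snps, k))
        is_outlier[idx] = True
        signs = np.where(idx % 2 == 0, 1.0, -1.0)
        alpha[idx] += signs * truth.outlier_alpha_sd_multiple * (sd_a if sd_a > 0 else 1.0)

    reverse_driven = np.zeros(k, dtype=bool)
    if truth.reverse_theta != 0.0:
        delta = drawn                      # gamma_dist parameterises delta here
        gamma = truth.reverse_theta * delta
        Gamma = truth.theta * gamma + alpha + delta
        reverse_driven[:] = True
    else:
        gamma = drawn
        Gamma = truth.theta * gamma + alpha

    se_exp = _se(maf, truth.n_exp)
    se_out = _se(maf, truth.n_out_effective)
    return dict(maf=maf, gamma=gamma, alpha=alpha, Gamma=Gamma,
                se_exp=se_exp, se_out=se_out, invalid=invalid,
                is_outlier=is_outlier, reverse_driven=reverse_driven)


def simulate_arrays(truth: SimulationTruth, seed: int | None = None):
    """Fast path for Monte Carlo: observed (beta_exp, se_exp, beta_out, se_out)
    for the causal instruments only, no record objects or LD panel."""
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    t = _draw_truth_effects(truth, rng)
    be = rng.normal(t["gamma"], t["se_exp"])
    bo = rng.normal(t["Gamma"], t["se_out"])
    return be, t["se_exp"], bo, t["se_out"]


@dataclass
class SimulatedPair:
    """One synthetic exposure-outcome dataset with its ground truth."""

    exposure: list
    outcome: list                     # primary source; see ``outcome_sources``
    ld: LDPanel
    truth: SimulationTruth
    snp_truth: pd.DataFrame
    outcome_sources: dict = field(default_factory=dict)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(beta / se)), _PMIN, 1.0)


def _draw_alleles(rng: np.random.Generator, palindromic: bool) -> tuple[str, str]:
    pool = _PALINDROMIC if palindromic else _NONPALINDROMIC
    return pool[rng.integers(len(pool))]


def simulate_pair(truth: SimulationTruth,
                  extra_sources: dict[str, tuple[int, int]] | None = None
                  ) -> SimulatedPair:
    """Generate a full synthetic dataset for one exposure-outcome analysis.

    Returns exposure and outcome summary statistics (records), an LD panel
    covering causal SNPs and their block partners, and a per-SNP truth table.
    ``extra_sources`` maps source names to (n_case, n_control) for additional
    outcome GWAS sharing the same true effects with independent noise.
    All randomness derives from ``truth.seed``.
    """
    rng = np.random.default_rng(truth.seed)
    t = _draw_truth_effects(truth, rng)
    k = truth.k_snps

    rows = []  # snp_id, chrom, pos, gamma, Gamma, maf, flags
    for j in range(k):
        chrom = str((j % 22) + 1)
        pos = 1_000_000 + (j // 22) * 30_000_000
        rows.append(dict(snp_id=f"rs{100000 + j}", chrom=chrom, pos=pos,
                         gamma=t["gamma"][j], Gamma=t["Gamma"][j],
                         alpha=t["alpha"][j], maf=t["maf"][j],
                         is_null=False, is_outlier=bool(t["is_outlier"][j]),
                         reverse_driven=bool(t["reverse_driven"][j]),
                         block_lead=""))

    # summary-level LD blocks: partner SNPs carry attenuated true effects
    ld = LDPanel()
    for b, (size, r2) in enumerate(truth.ld_blocks):
        if b >= k:
            break
        lead = rows[b]
        r = np.sqrt(r2)
        members = [lead["snp_id"]]
        for m in range(size - 1):
            maf = lead["maf"]
            rows.append(dict(snp_id=f"{lead['snp_id']}p{m}", chrom=lead["chrom"],
                             pos=lead["pos"] + 5000 * (m + 1),
                             gamma=r * lead["gamma"], Gamma=r * lead["Gamma"],
                             alpha=0.0, maf=maf, is_null=False, is_outlier=False,
                             reverse_driven=lead["reverse_driven"],
                             block_lead=lead["snp_id"]))
            members.append(rows[-1]["snp_id"])
        for i in range(len(members)):
            for jj in range(i + 1, len(members)):
                ld.add_pair(members[i], members[jj], r2, 1)

    for j in range(truth.n_null):
        chrom = str((j % 22) + 1)
        pos = 2_500_000 + (j // 22) * 7_000_000
        rows.append(dict(snp_id=f"rs{900000 + j}", chrom=chrom, pos=pos,
                         gamma=0.0, Gamma=0.0, alpha=0.0,
                         maf=float(rng.uniform(*truth.maf_range)),
                         is_null=True, is_outlier=False, reverse_driven=False,
                         block_lead=""))

    snp_truth = pd.DataFrame(rows)
    m = len(snp_truth)
    maf = snp_truth["maf"].to_numpy()
    se_exp = _se(maf, truth.n_exp)
    be = rng.normal(snp_truth["gamma"].to_numpy(), se_exp)
    p_exp = _pvals(be, se_exp)

    palindromic = rng.random(m) < truth.palindromic_fraction
    alleles = [_draw_alleles(rng, bool(p)) for p in palindromic]
    eaf_is_minor = rng.random(m) < 0.5
    eaf = np.where(eaf_is_minor, maf, 1.0 - maf)

    exposure = []
    for i, row in enumerate(snp_truth.itertuples(index=False)):
        ea, oa = alleles[i]
        exposure.append(SummaryStatRecord(
            snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos),
            effect_allele=ea, other_allele=oa, beta=float(be[i]),
            se=float(se_exp[i]), pval=float(p_exp[i]), n=truth.n_exp,
            eaf=float(eaf[i]), trait_id="exposure"))
        ld.add_snp(row.snp_id, row.chrom, int(row.pos), ea, oa)

    missing = rng.random(m) < truth.outcome_missing_fraction
    swapped = rng.random(m) < truth.outcome_allele_swap_fraction

    sources = {"a": (truth.n_out_case, truth.n_out_control)}
    if extra_sources:
        sources.update(extra_sources)
    outcome_sources: dict[str, list] = {}
    Gamma = snp_truth["Gamma"].to_numpy()
    for name, (n_case, n_control) in sources.items():
        n_eff = 4.0 / (1.0 / n_case + 1.0 / n_control)
        se_out = _se(maf, n_eff)
        bo = rng.normal(Gamma, se_out)
        p_out = _pvals(bo, se_out)
        recs = []
        for i, row in enumerate(snp_truth.itertuples(index=False)):
            if missing[i]:
                continue
            ea, oa = alleles[i]
            beta, f = float(bo[i]), float(eaf[i])
            if swapped[i]:
                ea, oa, beta, f = oa, ea, -beta, 1.0 - f
            recs.append(SummaryStatRecord(
                snp_id=row.snp_id, chrom=row.chrom, pos=int(row.pos),
                effect_allele=ea, other_allele=oa, beta=beta,
                se=float(se_out[i]), pval=float(p_out[i]),
                n=int(round(n_eff)), eaf=f, trait_id=f"outcome_{name}"))
        outcome_sources[name] = recs

    snp_truth = snp_truth.assign(missing_in_outcome=missing, allele_swapped=swapped)
    return SimulatedPair(exposure=exposure, outcome=outcome_sources["a"],
                         ld=ld, truth=truth, snp_truth=snp_truth,
                         outcome_sources=outcome_sources)


#: preset regimes mirroring the failure modes the sensitivity analyses target
_SCENARIOS: dict[str, dict] = {
    "null": dict(theta=0.0, k_snps=30),
    "causal": dict(theta=0.1, k_snps=50),
    "balanced_pleiotropy": dict(theta=0.1, k_snps=50,
                                pleiotropy=(0.3, 0.0, 0.08)),
    "directional_pleiotropy": dict(theta=0.1, k_snps=150,
                                   gamma_dist=(0.35, 0.18), gamma_min=0.05,
                                   pleiotropy=(0.3, 0.12, 0.02)),
    "outliers": dict(theta=0.1, k_snps=30, pleiotropy=(0.0, 0.0, 0.025),
                     n_outlier_snps=2, outlier_alpha_sd_multiple=10.0),
    "reverse_causation": dict(theta=0.0, reverse_theta=0.5, k_snps=30,
                              gamma_dist=(0.3, 0.05)),
    "weak_instruments": dict(theta=0.1, k_snps=30, gamma_dist=(0.055, 0.01)),
}


def scenario(name: str, seed: int = 0, **overrides) -> SimulationTruth:
    """Preset :class:`SimulationTruth` for a named regime.

    Scenarios: null, causal, balanced_pleiotropy, directional_pleiotropy,
    outliers (two planted SNPs with |alpha| = 10 sd), reverse_causation
    (theta = 0, reverse_theta != 0) and weak_instruments (mean F ~ 5-15).
    """
    if name not in _SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario '{name}'; known: {sorted(_SCENARIOS)}")
    params = dict(_SCENARIOS[name])
    params.update(overrides)
    return SimulationTruth(seed=seed, **params)


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)
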