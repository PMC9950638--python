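"""Orchestration of the full bidirectional MR analysis.

Forward direction: each exposure trait is instrumented (two-tier significance
selection with LD clumping, proxy substitution, harmonization with
palindromic deletion, confounder screening, F-statistic check, Steiger
filtering) against every outcome source, estimated with IVW, MR-Egger,
weighted median and MR-PRESSO, and the per-source IVW estimates are pooled by
meta-analysis.  Reverse direction: the outcome trait of each source is
instrumented against every exposure trait.  Pooled p-values are classified as
strong evidence below the Bonferroni level (0.05 / number of exposures,
0.0012 for 41 traits) and suggestive between that level and 0.05.

Per-pair failures are recorded as flagged rows rather than exceptions so a
large trait batch never dies on one degenerate trait.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .errors import AnalysisError, ConfigurationError
from .estimators import (PressoResult, ivw, mr_egger, mr_presso,
                         weighted_median)
from .instruments import (LDPanel, clump, confounder_filter, find_proxy,
                          mean_f_statistic, select_instruments, steiger_filter)
from .metaanalysis import MetaResult, bonferroni_threshold, meta_combine
from .sumstats import (COMPLEMENT, SummaryStatRecord, harmonize, read_sumstats)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Run configuration; numeric defaults mirror the study design."""

    p_primary: float = 5e-8
    p_fallback: float = 5e-6
    min_snps_for_fallback: int = 3
    tier_mode: str = "fallback"            # fallback | force-primary | force-fallback
    r2_clump: float = 0.001
    window_bp: int = 10_000_000
    proxy_r2: float = 0.80
    palindromic_policy: str = "drop"
    confounder_alpha: float = 0.05
    apply_confounder_reverse: bool = True
    steiger: bool = True
    n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    bonferroni_n: int | None = None        # defaults to the number of exposures
    strong_alpha: float | None = None      # defaults to 0.05 / bonferroni_n
    suggestive_alpha: float = 0.05
    f_stat_method: str = "per_snp"
    # file-mode inputs (CLI)
    exposures: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)
    ld_panel: str | None = None
    ld_meta: str | None = None
    confounders: dict = field(default_factory=dict)
    outdir: str = "results"
    plots: bool = False

    def __post_init__(self) -> None:
        for name in ("p_primary", "p_fallback", "suggestive_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigurationError(f"{name} must lie in (0,1): {v}")
        if self.tier_mode not in ("fallback", "force-primary", "force-fallback"):
            raise ConfigurationError(f"unknown tier_mode: {self.tier_mode}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def classify(meta_pval: float, strong_alpha: float = 0.0012,
             suggestive_alpha: float = 0.05) -> str:
    """Evidence grade for a pooled p-value (strict-less at both cut points)."""
    if meta_pval < strong_alpha:
        return "strong"
    if meta_pval < suggestive_alpha:
        return "suggestive"
    return "none"


@dataclass
class SingleRunResult:
    """One exposure against one outcome source."""

    exposure_id: str
    outcome_id: str
    status: str = "ok"                    # ok | not_estimable | error
    tier: str = "primary"
    estimates: dict = field(default_factory=dict)
    presso: PressoResult | None = None
    steiger: list = field(default_factory=list)
    mean_f: float | None = None
    stage_counts: dict = field(default_factory=dict)
    messages: list = field(default_factory=list)
    hset = None


@dataclass
class EvidenceCall:
    exposure_id: str
    outcome_id: str
    direction: str                        # forward | reverse
    meta: MetaResult | None
    per_source: dict
    classification: str


def _derived_seed(base_seed: int, tag: str) -> int:
    return (base_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2 ** 31)


def _oriented(beta: float, effect_allele: str, allele1: str) -> float | None:
    """Sign of ``beta`` re-expressed for panel ``allele1``; None if foreign."""
    if effect_allele == allele1 or COMPLEMENT.get(effect_allele) == allele1:
        return beta
    return -beta


def _substitute_proxies(instruments, outcome, ld: LDPanel, r2_min: float,
                        messages: list) -> tuple[list, set[str]]:
    """Replace outcome records for instruments missing from the outcome GWAS.

    The proxy's outcome effect is re-expressed for the missing SNP's alleles
    using the panel's phase sign, so downstream harmonization treats it as a
    direct match.  Returns the augmented outcome list and the proxied ids.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    augmented = list(outcome)
    proxied: set[str] = set()
    for rec in instruments:
        if rec.snp_id in out_by_id:
            continue
        hit = find_proxy(rec.snp_id, set(out_by_id), ld, r2_min=r2_min)
        if hit is None:
            continue
        proxy_id, phase = hit
        proxy = out_by_id[proxy_id]
        meta_missing = ld.meta.get(rec.snp_id)
        meta_proxy = ld.meta.get(proxy_id)
        if meta_missing is None or meta_proxy is None:
            messages.append(f"proxy for {rec.snp_id} skipped: no panel alleles")
            continue
        if proxy.is_palindromic:
            messages.append(f"proxy {proxy_id} for {rec.snp_id} is palindromic; skipped")
            continue
        b_exp_side = _oriented(1.0, rec.effect_allele, meta_missing[2])
        b_proxy = _oriented(proxy.beta, proxy.effect_allele, meta_proxy[2])
        if b_exp_side is None or b_proxy is None:
            messages.append(f"proxy for {rec.snp_id} skipped: allele orientation unclear")
            continue
        beta = b_exp_side * phase * b_proxy
        augmented.append(SummaryStatRecord(
            snp_id=rec.snp_id, chrom=rec.chrom, pos=rec.pos,
            effect_allele=rec.effect_allele, other_allele=rec.other_allele,
            beta=beta, se=proxy.se, pval=proxy.pval, n=proxy.n,
            eaf=None, trait_id=proxy.trait_id))
        proxied.add(rec.snp_id)
        messages.append(f"{rec.snp_id} proxied by {proxy_id} (phase {phase:+d})")
    return augmented, proxied


def run_single(exposure, outcome, ld: LDPanel, config: AnalysisConfig,
               confounders=None, seed: int | None = None,
               exposure_id: str | None = None,
               outcome_id: str | None = None) -> SingleRunResult:
    """Full single-pair analysis: selection, QC, harmonization, estimation."""
    exposure_id = exposure_id or (exposure[0].trait_id if exposure else "exposure")
    outcome_id = outcome_id or (outcome[0].trait_id if outcome else "outcome")
    res = SingleRunResult(exposure_id=exposure_id, outcome_id=outcome_id)
    seed = config.seed if seed is None else seed
    counts = res.stage_counts

    try:
        sel = select_instruments(exposure, config.p_primary)
        clumped = clump(sel, ld, config.r2_clump, config.window_bp)
        res.tier = "primary"
        use_fallback = (config.tier_mode == "force-fallback" or
                        (config.tier_mode == "fallback"
                         and len(clumped) < config.min_snps_for_fallback))
        if use_fallback:
            sel = select_instruments(exposure, config.p_fallback)
            clumped = clump(sel, ld, config.r2_clump, config.window_bp)
            res.tier = "fallback"
        counts["selected"] = len(sel)
        counts["clumped"] = len(clumped)
        if not clumped:
            res.status = "not_estimable"
            res.messages.append("no instruments pass the significance tiers")
            return res

        augmented, proxied = _substitute_proxies(
            clumped, outcome, ld, config.proxy_r2, res.messages)
        counts["proxied"] = len(proxied)

        try:
            hset = harmonize(clumped, augmented,
                             palindromic_policy=config.palindromic_policy,
                             exposure_id=exposure_id, outcome_id=outcome_id)
        except AnalysisError as exc:
            res.status = "not_estimable"
            res.messages.append(str(exc))
            return res
        for rec in hset.records:
            rec.is_proxy = rec.snp_id in proxied
        counts["harmonized"] = len(hset)

        if confounders:
            exp_by_id = {r.snp_id: r for r in clumped}
            inst = [exp_by_id[s] for s in hset.snp_ids]
            kept, removed = confounder_filter(inst, confounders,
                                              alpha=config.confounder_alpha)
            if removed:
                hset = hset.subset({r.snp_id for r in kept},
                                   reason="confounder-associated")
                res.messages.extend(
                    f"{s} removed: p={p:.3g} in {t}" for s, t, p in removed)
        counts["post_confounder"] = len(hset)

        if hset.records:
            exp_by_id = {r.snp_id: r for r in clumped}
            res.mean_f = mean_f_statistic(
                [exp_by_id[s] for s in hset.snp_ids], method=config.f_stat_method)
            if res.mean_f <= 10:
                res.messages.append(f"weak instruments: mean F = {res.mean_f:.2f} <= 10")

        if config.steiger and hset.records:
            hset, res.steiger = steiger_filter(hset)
        counts["post_steiger"] = len(hset)

        res.hset = hset
        k = len(hset)
        if k < 1:
            res.status = "not_estimable"
            res.messages.append("no instruments survive QC")
            return res

        res.estimates["ivw"] = ivw(hset, model="auto")
        if k >= 3:
            res.estimates["egger"] = mr_egger(hset)
            res.estimates["weighted_median"] = weighted_median(
                hset, n_boot=config.n_boot, seed=_derived_seed(seed, "wm"))
        if k >= 4:
            res.presso = mr_presso(hset, n_sim=config.n_sim,
                                   seed=_derived_seed(seed, "presso"))
            res.estimates["presso_raw"] = res.presso.raw
            if res.presso.corrected is not None:
                res.estimates["presso_corrected"] = res.presso.corrected
    except AnalysisError as exc:
        res.status = "error"
        res.messages.append(str(exc))
    return res


def _meta_over_sources(runs: dict) -> tuple[MetaResult | None, float | None]:
    """Pool per-source IVW estimates; returns (meta, p-value used for calls)."""
    ests = [r.estimates["ivw"] for r in runs.values()
            if r.status == "ok" and "ivw" in r.estimates]
    if len(ests) >= 2:
        meta = meta_combine(ests, model="auto")
        return meta, meta.pval
    if len(ests) == 1:
        return None, ests[0].pval
    return None, None


def run_bidirectional(exposures: dict, outcome_sources: dict, ld: LDPanel,
                      config: AnalysisConfig, confounders=None
                      ) -> tuple[list[EvidenceCall], dict]:
    """Run both directions over every exposure and outcome source.

    ``exposures`` maps trait id -> records; ``outcome_sources`` maps source
    name -> records of the (shared) outcome trait.  Returns the evidence
    calls plus result tables (DataFrames keyed results_forward,
    results_reverse, meta, instrument_log).
    """
    n_exp = len(exposures)
    bonf_n = config.bonferroni_n or max(n_exp, 1)
    strong = (config.strong_alpha if config.strong_alpha is not None
              else bonferroni_threshold(bonf_n, 0.05))
    if len(outcome_sources) < 2:
        logger.info("single outcome source: meta-analysis will be skipped")

    calls: list[EvidenceCall] = []
    rows, meta_rows, log_rows = [], [], []

    def record(direction, exp_id, out_id, runs):
        meta, pval = _meta_over_sources(runs)
        cls = classify(pval, strong, config.suggestive_alpha) if pval is not None else "none"
        calls.append(EvidenceCall(exp_id, out_id, direction, meta, runs, cls))
        for source, r in runs.items():
            for method, est in sorted(r.estimates.items()):
                rows.append(dict(
                    direction=direction, exposure=exp_id, outcome=out_id,
                    source=source, status=r.status, tier=r.tier, method=method,
                    beta=est.beta, se=est.se, ci_low=est.ci_low,
                    ci_high=est.ci_high, pval=est.pval, n_snp=est.n_snp,
                    intercept=est.intercept, intercept_pval=est.intercept_pval,
                    Q=est.Q, Q_pval=est.Q_pval, I2=est.I2,
                    presso_global_pval=(r.presso.global_pval if r.presso else None),
                    mean_f=r.mean_f))
            if not r.estimates:
                rows.append(dict(direction=direction, exposure=exp_id,
                                 outcome=out_id, source=source, status=r.status,
                                 tier=r.tier, method="", beta=None, se=None,
                                 ci_low=None, ci_high=None, pval=None,
                                 n_snp=0, intercept=None, intercept_pval=None,
                                 Q=None, Q_pval=None, I2=None,
                                 presso_global_pval=None, mean_f=r.mean_f))
            log_rows.append(dict(direction=direction, exposure=exp_id,
                                 outcome=out_id, source=source, tier=r.tier,
                                 status=r.status, **r.stage_counts,
                                 messages="; ".join(r.messages)))
        if meta is not None:
            meta_rows.append(dict(direction=direction, exposure=exp_id,
                                  outcome=out_id, model=meta.model,
                                  beta=meta.pooled_beta, se=meta.pooled_se,
                                  ci_low=meta.ci_low, ci_high=meta.ci_high,
                                  pval=meta.pval, Q=meta.Q, Q_pval=meta.Q_pval,
                                  I2=meta.I2, tau2=meta.tau2,
                                  classification=cls, note=meta.note))

    for exp_id in sorted(exposures):
        runs = {}
        for source in sorted(outcome_sources):
            runs[source] = run_single(
                exposures[exp_id], outcome_sources[source], ld, config,
                confounders=confounders,
                seed=_derived_seed(config.seed, f"fwd:{exp_id}:{source}"),
                exposure_id=exp_id, outcome_id=source)
        record("forward", exp_id, "outcome", runs)

    rev_confounders = confounders if config.apply_confounder_reverse else None
    for exp_id in sorted(exposures):
        runs = {}
        for source in sorted(outcome_sources):
            runs[source] = run_single(
                outcome_sources[source], exposures[exp_id], ld, config,
                confounders=rev_confounders,
                seed=_derived_seed(config.seed, f"rev:{exp_id}:{source}"),
                exposure_id=source, outcome_id=exp_id)
        record("reverse", "outcome", exp_id, runs)

    tables = {
        "results_forward": pd.DataFrame([r for r in rows if r["direction"] == "forward"]),
        "results_reverse": pd.DataFrame([r for r in rows if r["direction"] == "reverse"]),
        "meta": pd.DataFrame(meta_rows),
        "instrument_log": pd.DataFrame(log_rows),
    }
    return calls, tables


def _scatter_plot(call: EvidenceCall, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for source, r in call.per_source.items():
        if r.hset is None or not r.hset.records:
            continue
        be, se_e, bo, se_o = r.hset.arrays()
        ax.errorbar(be, bo, xerr=se_e, yerr=se_o, fmt="o", ms=3, alpha=0.6,
                    label=source)
        if "ivw" in r.estimates:
            slope = r.estimates["ivw"].beta
            ax.axline((0, 0), slope=slope, lw=1)
    ax.set_xlabel(f"SNP effect on {call.exposure_id}")
    ax.set_ylabel(f"SNP effect on {call.outcome_id}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def write_report(calls, tables, outdir, plots: bool = False) -> None:
    """Write result TSVs, a markdown summary and optional scatter plots."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.10g")
    lines = ["# Bidirectional MR summary", ""]
    for direction in ("forward", "reverse"):
        sub = [c for c in calls if c.direction == direction]
        hits = [c for c in sub if c.classification != "none"]
        lines.append(f"## {direction}: {len(hits)} of {len(sub)} pairs with evidence")
        for c in hits:
            p = c.meta.pval if c.meta else "single-source"
            lines.append(f"- {c.exposure_id} -> {c.outcome_id}: "
                         f"{c.classification} (pooled p = {p})")
        lines.append("")
    (outdir / "summary.md").write_text("\n".join(lines))
    if plots:
        for c in calls:
            if c.classification != "none":
                _scatter_plot(c, outdir / f"scatter_{c.direction}_"
                              f"{c.exposure_id}_{c.outcome_id}.png")


def run_from_config(config: AnalysisConfig) -> tuple[list[EvidenceCall], dict]:
    """File-mode entry point: read inputs named in the config, run, write."""
    if not config.exposures or not config.outcomes:
        raise ConfigurationError("config must name exposure and outcome files")
    exposures = {tid: read_sumstats(path, trait_id=tid)
                 for tid, path in config.exposures.items()}
    outcome_sources = {src: read_sumstats(path, trait_id=src)
                       for src, path in config.outcomes.items()}
    ld = (LDPanel.from_tsv(config.ld_panel, config.ld_meta)
          if config.ld_panel else LDPanel())
    confounders = [(tid, read_sumstats(path, trait_id=tid))
                   for tid, path in config.confounders.items()] or None
    calls, tables = run_bidirectional(exposures, outcome_sources, ld, config,
                                      confounders=confounders)
    write_report(calls, tables, config.outdir, plots=config.plots)
    return calls, tables
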