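"""Instrument selection and quality control.

Candidate instruments are the SNPs passing a significance tier (genome-wide
5e-8, or the relaxed 5e-6 tier when too few survive), pruned to approximate
independence by greedy LD clumping (r^2 < 0.001 within 10 Mb), optionally
proxied into the outcome GWAS at r^2 > 0.80, screened against confounder
GWAS at a Bonferroni level, strength-checked by the mean F-statistic
(mean F > 10 is the conventional weak-instrument bar), and direction-checked
by Steiger filtering (a valid instrument must explain more variance in the
exposure than in the outcome).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, InputError
from .sumstats import HarmonizedInstrumentSet

logger = logging.getLogger(__name__)


class LDPanel:
    """Pairwise r^2 and allele-phase sign among SNPs, with positions.

    ``phase_sign(a, b)`` is +1 when b's first-listed allele co-occurs with
    a's first-listed allele on the same haplotype, -1 otherwise.  Pairs not
    stored are treated as unlinked (r^2 = 0); ``r2(s, s)`` is 1.
    """

    def __init__(self) -> None:
        self._pairs: dict[tuple[str, str], tuple[float, int]] = {}
        self.meta: dict[str, tuple[str, int, str, str]] = {}
        self._warned_missing: set[str] = set()

    def add_snp(self, snp_id: str, chrom: str, pos: int,
                allele1: str = "A", allele2: str = "G") -> None:
        self.meta[snp_id] = (str(chrom), int(pos), allele1, allele2)

    def add_pair(self, a: str, b: str, r2: float, phase_sign: int = 1) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise InputError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        if phase_sign not in (1, -1):
            raise InputError(f"phase_sign must be +1/-1, got {phase_sign}")
        self._pairs[(a, b)] = (float(r2), int(phase_sign))
        self._pairs[(b, a)] = (float(r2), int(phase_sign))

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.meta

    def _warn_missing(self, snp_id: str) -> None:
        if snp_id not in self._warned_missing:
            self._warned_missing.add(snp_id)
            logger.warning("SNP %s absent from LD panel; treated as unlinked", snp_id)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        entry = self._pairs.get((a, b))
        return 0.0 if entry is None else entry[0]

    def phase_sign(self, a: str, b: str) -> int:
        if a == b:
            return 1
        entry = self._pairs.get((a, b))
        return 1 if entry is None else entry[1]

    def partners(self, snp_id: str):
        """Iterate (other_snp, r2, phase_sign) over stored pairs of ``snp_id``."""
        for (a, b), (r2, sign) in self._pairs.items():
            if a == snp_id:
                yield b, r2, sign

    @classmethod
    def from_tsv(cls, pairs_path, meta_path=None) -> "LDPanel":
        """Load from long-format TSV (snp_a, snp_b, r2, phase_sign) plus an
        optional SNP metadata TSV (snp_id, chrom, pos, allele1, allele2)."""
        panel = cls()
        pairs = pd.read_csv(pairs_path, sep="\t")
        for row in pairs.itertuples(index=False):
            panel.add_pair(str(row.snp_a), str(row.snp_b), float(row.r2),
                           int(getattr(row, "phase_sign", 1)))
        if meta_path is not None:
            meta = pd.read_csv(meta_path, sep="\t")
            for row in meta.itertuples(index=False):
                panel.add_snp(str(row.snp_id), str(row.chrom), int(row.pos),
                              str(row.allele1), str(row.allele2))
        return panel

    def to_tsv(self, pairs_path, meta_path=None) -> None:
        rows = [(a, b, r2, s) for (a, b), (r2, s) in self._pairs.items() if a < b]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2", "phase_sign"]).to_csv(
            pairs_path, sep="\t", index=False, float_format="%.10g")
        if meta_path is not None:
            rows = [(s, c, p, a1, a2) for s, (c, p, a1, a2) in self.meta.items()]
            pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "allele1", "allele2"]
                         ).to_csv(meta_path, sep="\t", index=False)


@dataclass(slots=True)
class SteigerResult:
    """Directionality test for one instrument.

    ``correct_direction`` is true when the SNP explains at least as much
    variance in the exposure as in the outcome.
    """

    snp_id: str
    r2_exp: float
    r2_out: float
    z: float
    pval: float
    correct_direction: bool


def select_instruments(sumstats, p_threshold: float):
    """Records with p < ``p_threshold``, ascending by p (ties by snp_id)."""
    if not (0.0 < p_threshold <= 1.0):
        raise InputError(f"p_threshold must lie in (0,1]: {p_threshold}")
    hits = [r for r in sumstats if r.pval < p_threshold]
    return sorted(hits, key=lambda r: (r.pval, r.snp_id))


def clump(candidates, ld: LDPanel, r2_max: float = 0.001,
          window_bp: int = 10_000_000):
    """Greedy LD clumping: strongest-association index SNPs, neighbours pruned.

    Repeatedly takes the lowest-p remaining SNP as index and removes remaining
    SNPs on the same chromosome within ``window_bp`` having r^2 > ``r2_max``
    with it.  Ties on p go to the lexicographically smaller snp_id so the
    result is order-independent.  SNPs absent from the panel are treated as
    unlinked (warned), matching the incompleteness of real reference panels.
    """
    order = sorted(candidates, key=lambda r: (r.pval, r.snp_id))
    removed: set[str] = set()
    kept = []
    for i, rec in enumerate(order):
        if rec.snp_id in removed:
            continue
        if ld.meta and rec.snp_id not in ld:
            ld._warn_missing(rec.snp_id)
        kept.append(rec)
        for other in order[i + 1:]:
            if other.snp_id in removed:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.r2(rec.snp_id, other.snp_id) > r2_max:
                removed.add(other.snp_id)
    return kept


def find_proxy(missing_snp: str, outcome_snps, ld: LDPanel,
               r2_min: float = 0.80):
    """Best outcome-present proxy with r^2 strictly above ``r2_min``.

    Returns ``(proxy_snp_id, phase_sign)`` or ``None``; ties on r^2 go to the
    smaller snp_id.
    """
    outcome_snps = set(outcome_snps)
    best = None
    for other, r2, sign in ld.partners(missing_snp):
        if other not in outcome_snps or r2 <= r2_min:
            continue
        if best is None or r2 > best[1] or (r2 == best[1] and other < best[0]):
            best = (other, r2, sign)
    if best is None:
        return None
    return best[0], best[2]


def mean_f_statistic(instruments, method: str = "per_snp") -> float:
    """Instrument-strength summary.

    ``per_snp`` (default): mean over SNPs of (beta/se)^2, the squared z-score
    form that needs no allele frequencies.  ``r2_based``: F = (n-k-1)/k *
    R2/(1-R2) with per-SNP R2 from the summary-level approximation
    F_j/(F_j + n_j - 2).
    """
    instruments = list(instruments)
    if not instruments:
        raise AnalysisError("mean F-statistic undefined for an empty instrument set")
    f_per_snp = np.array([(r.beta / r.se) ** 2 for r in instruments])
    if method == "per_snp":
        return float(f_per_snp.mean())
    if method == "r2_based":
        n = np.array([r.n for r in instruments], dtype=float)
        r2 = f_per_snp / (f_per_snp + n - 2.0)
        total_r2 = min(float(r2.sum()), 0.999999)
        k = len(instruments)
        n_bar = float(n.mean())
        return (n_bar - k - 1.0) / k * total_r2 / (1.0 - total_r2)
    raise InputError(f"unknown F-statistic method: {method}")


def confounder_filter(instruments, confounder_sumstats, alpha: float = 0.05):
    """Bonferroni screen against confounder GWAS.

    The threshold is ``alpha`` divided by the pre-filter instrument count; a
    SNP is removed when its p in ANY confounder trait falls below it.
    Returns ``(kept, removed)`` with removed entries (snp_id, trait_id, pval).
    """
    instruments = list(instruments)
    if not instruments:
        return [], []
    threshold = alpha / len(instruments)
    lookup: dict[str, list[tuple[str, float]]] = {}
    for trait_id, records in confounder_sumstats:
        by_id = {r.snp_id: r.pval for r in records}
        for rec in instruments:
            if rec.snp_id in by_id:
                lookup.setdefault(rec.snp_id, []).append((trait_id, by_id[rec.snp_id]))
            else:
                logger.warning("SNP %s absent from confounder trait %s; kept",
                               rec.snp_id, trait_id)
    kept, removed = [], []
    for rec in instruments:
        hits = [(t, p) for t, p in lookup.get(rec.snp_id, []) if p < threshold]
        if hits:
            trait_id, pval = min(hits, key=lambda tp: tp[1])
            removed.append((rec.snp_id, trait_id, pval))
        else:
            kept.append(rec)
    return kept, removed


def _steiger_r2(beta: float, se: float, n: int) -> float:
    f = (beta / se) ** 2
    return f / (f + n - 2.0)


def steiger_filter(hset: HarmonizedInstrumentSet):
    """Remove instruments explaining more outcome than exposure variance.

    Per SNP the variance explained is approximated from summary data as
    r^2 = F/(F + n - 2) with F the squared z-score; the difference of
    Fisher-transformed correlations gives a two-sided normal p.  A SNP is
    removed iff r2_out > r2_exp (strict, so ties are kept).
    """
    results: list[SteigerResult] = []
    keep_ids = []
    for rec in hset.records:
        if rec.n_exp <= 3 or rec.n_out <= 3:
            raise AnalysisError(
                f"Steiger test needs n > 3 (snp {rec.snp_id}: "
                f"n_exp={rec.n_exp}, n_out={rec.n_out})")
        r2_exp = _steiger_r2(rec.beta_exp, rec.se_exp, rec.n_exp)
        r2_out = _steiger_r2(rec.beta_out, rec.se_out, rec.n_out)
        z = (math.atanh(math.sqrt(r2_exp)) - math.atanh(math.sqrt(r2_out))) / math.sqrt(
            1.0 / (rec.n_exp - 3) + 1.0 / (rec.n_out - 3))
        pval = float(2.0 * stats.norm.sf(abs(z)))
        correct = r2_exp >= r2_out
        results.append(SteigerResult(rec.snp_id, r2_exp, r2_out, z, pval, correct))
        if correct:
            keep_ids.append(rec.snp_id)
    filtered = hset.subset(keep_ids, reason="steiger: wrong direction")
    return filtered, results
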