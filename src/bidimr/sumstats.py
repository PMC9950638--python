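"""GWAS summary-statistics data model, readers/writers and allele harmonization.

Two-sample MR works from per-SNP association records (alleles, beta, SE, p,
allele frequency, sample size) drawn from two independent GWAS.  Before any
estimation the exposure and outcome records for each SNP must be expressed for
the same effect allele: direct matches are kept, swapped allele pairs flip the
sign of the outcome effect, opposite-strand reports are complemented, and
palindromic SNPs (A/T or C/G), whose strand cannot be resolved from the
alleles, are deleted by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, ConfigurationError, InputError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: default header names, overridable via ``column_map``
DEFAULT_COLUMNS = {
    "snp_id": "snp",
    "chrom": "chr",
    "pos": "pos",
    "effect_allele": "ea",
    "other_allele": "oa",
    "eaf": "eaf",
    "beta": "beta",
    "se": "se",
    "pval": "pval",
    "n": "n",
}
_OPTIONAL_FIELDS = {"eaf"}


@dataclass(slots=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``beta`` is the per-effect-allele effect in the trait's units (SD of an
    inverse-normalized biomarker for a quantitative trait, log-odds for a
    binary trait).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float | None = None
    trait_id: str = ""

    @property
    def zscore(self) -> float:
        return self.beta / self.se

    @property
    def is_palindromic(self) -> bool:
        return frozenset((self.effect_allele, self.other_allele)) in PALINDROMIC_PAIRS


@dataclass(slots=True)
class HarmonizedRecord:
    """Exposure/outcome effect pair for one SNP, expressed for one allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    n_exp: int
    n_out: int
    action_taken: str = "kept"
    is_proxy: bool = False
    effect_allele: str = ""
    other_allele: str = ""


@dataclass
class HarmonizedInstrumentSet:
    """All harmonized instruments for one exposure-outcome analysis.

    Every input exposure SNP appears exactly once: in ``records`` or, with a
    reason, in ``dropped``.
    """

    exposure_id: str
    outcome_id: str
    records: list[HarmonizedRecord] = field(default_factory=list)
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise AnalysisError("duplicate snp_ids in harmonized set")

    def __len__(self) -> int:
        return len(self.records)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        be = np.array([r.beta_exp for r in self.records], dtype=float)
        se_e = np.array([r.se_exp for r in self.records], dtype=float)
        bo = np.array([r.beta_out for r in self.records], dtype=float)
        se_o = np.array([r.se_out for r in self.records], dtype=float)
        return be, se_e, bo, se_o

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def subset(self, keep_ids, reason: str = "filtered") -> "HarmonizedInstrumentSet":
        """New set restricted to ``keep_ids``; removed SNPs go to ``dropped``."""
        keep = set(keep_ids)
        records = [r for r in self.records if r.snp_id in keep]
        dropped = list(self.dropped) + [
            (r.snp_id, reason) for r in self.records if r.snp_id not in keep
        ]
        return HarmonizedInstrumentSet(self.exposure_id, self.outcome_id, records, dropped)

    def to_frame(self) -> pd.DataFrame:
        cols = [
            "snp_id", "effect_allele", "other_allele",
            "beta_exp", "se_exp", "pval_exp", "n_exp",
            "beta_out", "se_out", "pval_out", "n_out",
            "action_taken", "is_proxy",
        ]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.records],
                            columns=cols)


def check_pvalue_consistency(rec: SummaryStatRecord, rtol: float = 0.10) -> bool:
    """Whether the reported p agrees with 2*Phi(-|beta/se|) to ``rtol``.

    Only checkable above the double-precision floor; records below it pass.
    """
    if rec.pval <= 1e-300:
        return True
    expected = 2.0 * stats.norm.sf(abs(rec.zscore))
    if expected <= 1e-300:
        return True
    return abs(rec.pval - expected) <= rtol * max(rec.pval, expected)


def _resolve_columns(columns, column_map) -> dict[str, str]:
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for fieldname, header in cmap.items():
        if header.lower() in lower:
            resolved[fieldname] = lower[header.lower()]
        elif fieldname not in _OPTIONAL_FIELDS:
            raise ConfigurationError(
                f"missing mandatory column '{header}' (field '{fieldname}')"
            )
    return resolved


def parse_sumstats(
    df: pd.DataFrame,
    column_map: dict[str, str] | None = None,
    trait_id: str = "",
) -> tuple[list[SummaryStatRecord], list[tuple[int, str]]]:
    """Parse a sumstats DataFrame into records plus (row, reason) rejects.

    Row numbers are 1-based data rows (header not counted).
    """
    resolved = _resolve_columns(df.columns, column_map)
    records: list[SummaryStatRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        d = {f: getattr(row, resolved[f]) for f in resolved}
        try:
            ea = str(d["effect_allele"]).upper().strip()
            oa = str(d["other_allele"]).upper().strip()
            if not (set(ea) <= VALID_ALLELES and set(oa) <= VALID_ALLELES and ea and oa):
                raise ValueError("non-ACGT allele")
            if len(ea) > 1 or len(oa) > 1:
                raise ValueError("indel or multi-allelic site")
            if ea == oa:
                raise ValueError("identical alleles")
            se = float(d["se"])
            if not se > 0:
                raise ValueError("nonpositive SE")
            pval = float(d["pval"])
            if not (0.0 < pval <= 1.0):
                raise ValueError("p-value outside (0,1]")
            eaf = d.get("eaf")
            eaf = None if eaf is None or (isinstance(eaf, float) and math.isnan(eaf)) else float(eaf)
            records.append(SummaryStatRecord(
                snp_id=str(d["snp_id"]),
                chrom=str(d["chrom"]),
                pos=int(d["pos"]),
                effect_allele=ea,
                other_allele=oa,
                beta=float(d["beta"]),
                se=se,
                pval=pval,
                n=int(d["n"]),
                eaf=eaf,
                trait_id=trait_id,
            ))
        except (ValueError, TypeError) as exc:
            rejects.append((i, str(exc)))
    for i, reason in rejects:
        logger.warning("row %d rejected: %s", i, reason)
    return records, rejects


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_id: str = "",
    delimiter: str | None = None,
) -> list[SummaryStatRecord]:
    """Read a headered TSV/CSV (gzip transparently) of GWAS summary statistics."""
    sep = delimiter
    if sep is None:
        sep = "," if str(path).rstrip(".gz").endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty summary-statistics file: {path}") from exc
    if df.empty:
        raise InputError(f"no data rows in summary-statistics file: {path}")
    records, _ = parse_sumstats(df, column_map=column_map, trait_id=trait_id)
    return records


def records_to_frame(records) -> pd.DataFrame:
    cols = ["snp_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n", "trait_id"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_sumstats(records, path, sep: str = "\t") -> None:
    out = records_to_frame(records).rename(columns={
        "snp_id": "snp", "chrom": "chr", "effect_allele": "ea", "other_allele": "oa",
    })
    out.drop(columns=["trait_id"]).to_csv(path, sep=sep, index=False, float_format="%.10g")


def _palindromic_alignment(exp: SummaryStatRecord, out: SummaryStatRecord,
                           base_sign: float) -> tuple[float, str] | None:
    """Resolve a palindromic SNP from allele frequencies, or None if ambiguous.

    Informative when both frequencies are clearly away from 0.5 (outside
    [0.42, 0.58]); concordant frequencies confirm the allele-based alignment,
    discordant ones imply the strands differ and the sign flips.
    """
    if exp.eaf is None or out.eaf is None:
        return None
    out_ea_freq = out.eaf if base_sign > 0 else 1.0 - out.eaf
    lo, hi = 0.42, 0.58
    e_lo, e_hi = exp.eaf < lo, exp.eaf > hi
    o_lo, o_hi = out_ea_freq < lo, out_ea_freq > hi
    if (e_lo and o_lo) or (e_hi and o_hi):
        return base_sign, "kept"
    if (e_lo and o_hi) or (e_hi and o_lo):
        return -base_sign, "strand_flipped_and_sign_flipped"
    return None


def align_alleles(
    exp: SummaryStatRecord,
    out: SummaryStatRecord,
    palindromic_policy: str = "drop",
) -> tuple[HarmonizedRecord | None, str | None]:
    """Express the outcome effect for the exposure's effect allele.

    Returns ``(record, None)`` on success or ``(None, reason)`` when the SNP
    must be dropped.  ``palindromic_policy`` is ``drop`` (default) or
    ``keep_if_eaf_informative``.
    """
    if exp.snp_id != out.snp_id:
        raise AnalysisError(f"snp_id mismatch: {exp.snp_id} vs {out.snp_id}")
    if palindromic_policy not in ("drop", "keep_if_eaf_informative"):
        raise ConfigurationError(f"unknown palindromic policy: {palindromic_policy}")

    e = (exp.effect_allele, exp.other_allele)
    o = (out.effect_allele, out.other_allele)
    oc = (COMPLEMENT[o[0]], COMPLEMENT[o[1]])

    if o == e:
        sign, action = 1.0, "kept"
    elif o == (e[1], e[0]):
        sign, action = -1.0, "sign_flipped"
    elif oc == e:
        sign, action = 1.0, "strand_flipped"
    elif oc == (e[1], e[0]):
        sign, action = -1.0, "strand_flipped_and_sign_flipped"
    else:
        return None, "allele mismatch"

    if exp.is_palindromic:
        if palindromic_policy == "drop":
            return None, "palindromic"
        resolved = _palindromic_alignment(exp, out, sign)
        if resolved is None:
            return None, "palindromic (frequency uninformative)"
        sign, action = resolved

    return HarmonizedRecord(
        snp_id=exp.snp_id,
        beta_exp=exp.beta, se_exp=exp.se, pval_exp=exp.pval,
        beta_out=sign * out.beta, se_out=out.se, pval_out=out.pval,
        n_exp=exp.n, n_out=out.n,
        action_taken=action,
        effect_allele=exp.effect_allele, other_allele=exp.other_allele,
    ), None


def harmonize(
    exposure: list[SummaryStatRecord],
    outcome: list[SummaryStatRecord],
    palindromic_policy: str = "drop",
    exposure_id: str = "exposure",
    outcome_id: str = "outcome",
) -> HarmonizedInstrumentSet:
    """Intersect exposure and outcome records by SNP and align alleles.

    Exposure SNPs missing from the outcome are dropped with reason
    ``missing in outcome`` (proxy substitution is handled upstream by the
    instrument-QC layer).  Raises :class:`AnalysisError` when the two trait
    files share no SNPs at all.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    records: list[HarmonizedRecord] = []
    dropped: list[tuple[str, str]] = []
    n_shared = 0
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            dropped.append((exp.snp_id, "missing in outcome"))
            continue
        n_shared += 1
        rec, reason = align_alleles(exp, out, palindromic_policy)
        if rec is None:
            dropped.append((exp.snp_id, reason))
        else:
            records.append(rec)
    if exposure and n_shared == 0:
        raise AnalysisError("no shared instruments between exposure and outcome")
    if exposure_id == "exposure" and exposure and exposure[0].trait_id:
        exposure_id = exposure[0].trait_id
    if outcome_id == "outcome" and outcome and outcome[0].trait_id:
        outcome_id = outcome[0].trait_id
    return HarmonizedInstrumentSet(exposure_id, outcome_id, records, dropped)


def write_harmonized(hset: HarmonizedInstrumentSet, path, dropped_path=None) -> None:
    """Write the harmonized table plus a ``dropped.tsv`` sidecar."""
    hset.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    if dropped_path is None:
        dropped_path = str(path).rsplit(".", 1)[0] + ".dropped.tsv"
    pd.DataFrame(hset.dropped, columns=["snp_id", "reason"]).to_csv(
        dropped_path, sep="\t", index=False)
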