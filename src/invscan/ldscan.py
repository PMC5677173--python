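"""SNP-inversion linkage disequilibrium scan.

For each diallelic SNP S and inversion I (both treated as binary variables
across inbred lines) disequilibrium is

    D  = freq(major allele & major state) - p_S * p_I
    r2 = D^2 / (p_S (1 - p_S) p_I (1 - p_I))

computed over the N lines non-missing at both the SNP and the karyotype.
Significance uses the 1-df chi-squared transformation chi2 = N * r2
against a per-arm Bonferroni critical value, after the sample-size and
minor-allele-frequency filters (N >= 60, MAF >= 10% for both the SNP and
the inversion state). r2 equals the squared Pearson correlation of the
two 0/1 indicator vectors, and N*r2 equals the standard 2x2 contingency
chi-squared without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Gene, InputError, MISSING, SnpTable


@dataclass
class LdRecord:
    snp_id: str
    n: int
    d: float
    r2: float
    chi2: float
    maf_snp: float
    maf_kary: float
    defined: bool
    passes_filters: bool = False
    significant: bool = False


def _pair_stats(snp: np.ndarray, kary: np.ndarray) -> tuple[int, float, float, float]:
    """(N, D, p_S, p_I) over lines non-missing at both variables.

    ``snp`` holds 0 = major / 1 = minor; ``kary`` holds 0 = standard /
    1 = inverted. Frequencies are of the *major* allele / state among
    the shared N, as the r2 formula expects; D is invariant up to sign
    under relabeling, so r2 does not depend on the convention.
    """
    ok = (snp != MISSING) & (kary != MISSING)
    s, k = snp[ok], kary[ok]
    n = int(ok.sum())
    if n == 0:
        return 0, np.nan, np.nan, np.nan
    p_s = float(np.mean(s == 0))
    p_minor_k = float(np.mean(k == 1))
    p_i = max(p_minor_k, 1 - p_minor_k)  # major-state frequency
    major_state = 1 if p_minor_k > 0.5 else 0
    joint = float(np.mean((s == 0) & (k == major_state)))
    d = joint - p_s * p_i
    return n, d, p_s, p_i


def snp_inversion_ld(snp: np.ndarray, kary: np.ndarray, snp_id: str = "") -> LdRecord:
    """LD record for one SNP against one inversion karyotype vector."""
    snp = np.asarray(snp)
    kary = np.asarray(kary)
    if snp.shape != kary.shape:
        raise InputError("SNP and karyotype vectors must align line-for-line")
    n, d, p_s, p_i = _pair_stats(snp, kary)
    maf_snp = min(p_s, 1 - p_s) if n else np.nan
    maf_kary = min(p_i, 1 - p_i) if n else np.nan
    denom = p_s * (1 - p_s) * p_i * (1 - p_i) if n else 0.0
    if n < 2 or denom == 0.0:
        return LdRecord(snp_id, n, np.nan, np.nan, np.nan, maf_snp, maf_kary, False)
    r2 = d * d / denom
    return LdRecord(snp_id, n, d, r2, n * r2, maf_snp, maf_kary, True)


def bonferroni_critical(n_tests: int, alpha: float = 0.05) -> float:
    """Upper-tail chi-squared(1 df) critical value at alpha / n_tests."""
    if n_tests < 1:
        raise InputError("n_tests must be >= 1")
    a = alpha / n_tests
    if a <= 0 or not np.isfinite(a):
        raise InputError("alpha/n_tests underflows")
    return float(stats.chi2.isf(a, df=1))


def ld_scan_arm(
    snps: SnpTable,
    kary: pd.Series,
    min_n: int = 60,
    min_maf: float = 0.10,
    alpha: float = 0.05,
    bonferroni_universe: str = "all",
) -> pd.DataFrame:
    """Scan every SNP on one arm against one inversion karyotype.

    ``kary`` maps line id to 0/1/:data:`MISSING`. The Bonferroni n is the
    number of diallelic SNPs on the arm — all of them by default, or only
    the filter-passing ones with ``bonferroni_universe="passing"``.
    Returns one row per SNP with N, D, r2, chi2, the filter flags and the
    significance call; ``attrs`` carry ``n_tests`` and ``critical``.
    """
    arms = set(snps.snps["arm"])
    if len(arms) > 1:
        raise InputError(f"ld_scan_arm expects one arm, got {sorted(arms)}")
    kary_vec = kary.reindex(snps.lines).fillna(MISSING).to_numpy(dtype=np.int8)
    records = []
    for j in range(len(snps.snps)):
        rec = snp_inversion_ld(
            snps.calls[:, j], kary_vec, snp_id=snps.snps["snp_id"].iloc[j]
        )
        rec.passes_filters = bool(
            rec.defined
            and rec.n >= min_n
            and rec.maf_snp >= min_maf
            and rec.maf_kary >= min_maf
        )
        records.append(rec)

    # a SNP monomorphic among its N is not diallelic there; it never counts
    diallelic = [r.defined for r in records]
    if bonferroni_universe == "all":
        n_tests = int(np.sum(diallelic))
    elif bonferroni_universe == "passing":
        n_tests = int(np.sum([r.passes_filters for r in records]))
    else:
        raise InputError("bonferroni_universe must be 'all' or 'passing'")
    critical = bonferroni_critical(n_tests, alpha) if n_tests else np.inf
    for rec in records:
        rec.significant = bool(rec.passes_filters and rec.chi2 > critical)

    out = pd.DataFrame([vars(r) for r in records])
    out.insert(1, "arm", snps.snps["arm"].to_numpy())
    out.insert(2, "pos", snps.snps["pos"].to_numpy())
    out.attrs["n_tests"] = n_tests
    out.attrs["critical"] = critical
    out.attrs["alpha"] = alpha
    return out


def genes_in_ld(
    significant_snps: pd.DataFrame,
    genes: list[Gene],
    flank: int = 0,
) -> set[str]:
    """Genes whose annotated region contains >= 1 significant SNP.

    ``significant_snps`` needs ``arm`` and ``pos`` columns (1-based).
    Boundaries are inclusive; an optional symmetric ``flank`` in bp widens
    each gene interval. Overlapping or nested genes are all reported.
    """
    hits: set[str] = set()
    if len(significant_snps) == 0:
        return hits
    by_arm: dict[str, np.ndarray] = {
        arm: np.sort(sub["pos"].to_numpy())
        for arm, sub in significant_snps.groupby("arm")
    }
    for g in genes:
        pos = by_arm.get(g.arm)
        if pos is None:
            continue
        lo, hi = g.start - flank, g.end + flank
        i = np.searchsorted(pos, lo, side="left")
        if i < pos.size and pos[i] <= hi:
            hits.add(g.gene_id)
    return hits
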