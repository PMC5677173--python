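"""Hypergeometric over/underrepresentation tests.

Two applications: inversion-affected loci (IAL) among the genes in LD
with an inversion, and IAL among the targets of transcription factors
that carry significant SNPs. Draws of size n from a universe of N genes
containing K "successes"; the observed overlap x is scored by exact
hypergeometric tails.

Tail conventions: ``p_upper``/``p_lower`` are the inclusive tails
P(X >= x) and P(X <= x) (they share P(X = x), so they sum to >= 1).
``p_gt`` is the exclusive upper tail P(X > x) — the quantity printed by
R's ``phyper(..., lower.tail=FALSE)``, which original reports of this
analysis style tabulate; it is carried alongside for table parity.
The two-tailed decision is made per tail at 0.025 on the inclusive tails.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .core import InputError


@dataclass
class EnrichmentRecord:
    label: str
    N: int
    K: int
    n: int
    x: int
    expected: float
    p_upper: float  # P(X >= x)
    p_lower: float  # P(X <= x)
    p_gt: float  # P(X > x), the R phyper upper tail
    two_tailed_significant: bool
    degenerate: bool = False

    @property
    def expected_display(self) -> int:
        """The expectation rounded to the nearest integer for table display."""
        return int(round(self.expected))


def hypergeom_expectation(N: int, K: int, n: int) -> float:
    """E[X] = n*K/N for the overlap of a size-n draw with a size-K class."""
    if N <= 0:
        raise InputError("universe size N must be positive")
    if K > N or n > N or K < 0 or n < 0:
        raise InputError(f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}")
    return n * K / N


def hypergeom_tail(N: int, K: int, n: int, x: int) -> tuple[float, float]:
    """Exact inclusive tails (P(X >= x), P(X <= x)) of Hypergeom(N, K, n)."""
    if N <= 0 or K > N or n > N or K < 0 or n < 0:
        raise InputError(f"inconsistent hypergeometric parameters N={N}, K={K}, n={n}")
    if x < 0 or x > min(n, K):
        raise InputError(f"x={x} outside [0, min(n, K)={min(n, K)}]")
    h = stats.hypergeom(N, K, n)
    p_upper = float(h.sf(x - 1))  # P(X >= x)
    p_lower = float(h.cdf(x))  # P(X <= x)
    return p_upper, p_lower


def _record(
    label: str, N: int, K: int, n: int, x: int, per_tail_alpha: float = 0.025
) -> EnrichmentRecord:
    p_upper, p_lower = hypergeom_tail(N, K, n, x)
    p_gt = float(stats.hypergeom(N, K, n).sf(x))
    return EnrichmentRecord(
        label=label,
        N=N,
        K=K,
        n=n,
        x=x,
        expected=hypergeom_expectation(N, K, n),
        p_upper=p_upper,
        p_lower=p_lower,
        p_gt=p_gt,
        two_tailed_significant=(p_upper < per_tail_alpha)
        or (p_lower < per_tail_alpha),
        degenerate=(n == 0 or K == 0),
    )


def ial_ld_enrichment(
    universe: set[str],
    ial: set[str],
    in_ld: set[str],
    label: str = "IAL x genes-in-LD",
    per_tail_alpha: float = 0.025,
) -> EnrichmentRecord:
    """Overrepresentation of IAL among genes in LD with the inversion.

    The universe is the set of genes present in both the expression and
    genome annotations; ``ial`` and ``in_ld`` must be subsets of it.
    N = |universe|, K = |in_ld|, n = |ial|, x = |ial & in_ld|.
    """
    for name, s in (("IAL", ial), ("genes-in-LD", in_ld)):
        stray = s - universe
        if stray:
            raise InputError(
                f"{name} contains genes outside the universe: {sorted(stray)[:5]}"
            )
    return _record(
        label, len(universe), len(in_ld), len(ial), len(ial & in_ld), per_tail_alpha
    )


def tf_target_enrichment(
    edges: pd.DataFrame,
    sig_snp_tfs: set[str],
    ial: set[str],
    restrict_to: set[str] | None = None,
    label: str = "IAL x targets-of-sig-SNP-TFs",
    per_tail_alpha: float = 0.025,
) -> EnrichmentRecord:
    """Overrepresentation of IAL among targets of TFs carrying significant SNPs.

    ``edges`` has ``tf`` and ``target`` columns; ``restrict_to`` (when
    given) drops edges whose TF or target is outside the annotated gene
    set. Universe N = distinct targets of the restricted network,
    K = targets that are IAL, n = distinct targets of ``sig_snp_tfs``,
    x = overlap. Because the original table style omits the draw count,
    the record always reports n explicitly.
    """
    if not {"tf", "target"}.issubset(edges.columns):
        raise InputError("edge table needs 'tf' and 'target' columns")
    if restrict_to is not None:
        edges = edges[
            edges["tf"].isin(restrict_to) & edges["target"].isin(restrict_to)
        ]
    if len(edges) == 0:
        raise InputError("TF-target network is empty after restriction")
    targets = set(edges["target"])
    drawn = set(edges.loc[edges["tf"].isin(sig_snp_tfs), "target"])
    K = len(targets & ial)
    return _record(
        label, len(targets), K, len(drawn), len(drawn & ial & targets),
        per_tail_alpha,
    )


def records_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """One TSV-ready row per enrichment record."""
    rows = [
        {
            "label": r.label,
            "N": r.N,
            "K": r.K,
            "n": r.n,
            "x": r.x,
            "E": r.expected,
            "E_display": r.expected_display,
            "p_upper": r.p_upper,
            "p_lower": r.p_lower,
            "p_gt": r.p_gt,
            "two_tailed_significant": r.two_tailed_significant,
            "degenerate": r.degenerate,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
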