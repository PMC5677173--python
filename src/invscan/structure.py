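"""Genomic structure of inversion-affected loci.

Three analyses: classifying each gene's location relative to an inversion
(within the breakpoints, same arm outside, within a 1 Mb flank outside,
or on another arm), reporting genes interrupted by a breakpoint and each
locus's distance to the nearest breakpoint, and a physical-clustering
test that compares the coefficient of variation (CV = SD/mean) of
intergenic gaps in a gene set against a null of equally many genes drawn
uniformly without replacement from the arm.

Verdict naming: a CV above the null CI is reported as "more clustered" —
heterogeneous gaps mean runs of tight genes separated by large voids —
and below as "less clustered"; the mapping is stated in output headers
because the opposite reading ("dispersed") appears in the literature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Gene, InputError, Inversion

WITHIN = "within"
SAME_ARM_OUTSIDE = "same_arm_outside"
WITHIN_FLANK_OUTSIDE = "within_flank_outside"
UNLINKED = "unlinked"


def classify_location(
    gene: Gene, inv: Inversion, flank: int = 1_000_000
) -> str:
    """Primary location class of a gene relative to one inversion.

    ``within`` when the gene interval overlaps [proximal, distal];
    ``unlinked`` on a different arm; ``within_flank_outside`` when on the
    same arm, non-overlapping, and strictly closer than ``flank`` to the
    nearer breakpoint (a subclass of ``same_arm_outside`` for reporting).
    """
    if gene.arm != inv.arm:
        return UNLINKED
    if gene.start <= inv.distal and gene.end >= inv.proximal:
        return WITHIN
    if gene.end < inv.proximal:
        dist = inv.proximal - gene.end
    else:
        dist = gene.start - inv.distal
    return WITHIN_FLANK_OUTSIDE if dist < flank else SAME_ARM_OUTSIDE


def location_table(
    genes: list[Gene],
    inversions: list[Inversion],
    ial_genes: dict[str, set[str]],
    flank: int = 1_000_000,
) -> pd.DataFrame:
    """Counts of IAL per location class and per arm, one row per inversion."""
    by_id = {g.gene_id: g for g in genes}
    arms = sorted({g.arm for g in genes})
    rows = []
    for inv in inversions:
        members = [by_id[g] for g in ial_genes.get(inv.name, set()) if g in by_id]
        classes = {g.gene_id: classify_location(g, inv, flank) for g in members}
        row = {
            "inversion": inv.name,
            "within": sum(c == WITHIN for c in classes.values()),
            "same_arm_outside": sum(
                c in (SAME_ARM_OUTSIDE, WITHIN_FLANK_OUTSIDE)
                for c in classes.values()
            ),
            "within_flank_outside": sum(
                c == WITHIN_FLANK_OUTSIDE for c in classes.values()
            ),
        }
        for arm in arms:
            row[f"n_{arm}"] = sum(g.arm == arm for g in members)
        rows.append(row)
    return pd.DataFrame(rows)


def _distance_to_breakpoint(gene: Gene, bp: int) -> int:
    if gene.start < bp < gene.end:
        return 0
    return min(abs(bp - gene.start), abs(bp - gene.end))


def breakpoint_report(
    genes: list[Gene],
    inversions: list[Inversion],
    ial_genes: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Interrupted genes and per-gene distance to the nearest breakpoint.

    A gene is interrupted iff ``start < breakpoint < end`` for either
    breakpoint of a same-arm inversion (distance 0). When ``ial_genes``
    is given only IAL of each inversion are reported; otherwise all
    same-arm genes are.
    """
    rows = []
    by_id = {g.gene_id: g for g in genes}
    for inv in inversions:
        if ial_genes is not None:
            cand = [by_id[g] for g in ial_genes.get(inv.name, set()) if g in by_id]
        else:
            cand = genes
        for g in cand:
            if g.arm != inv.arm:
                continue
            dists = {
                "proximal": _distance_to_breakpoint(g, inv.proximal),
                "distal": _distance_to_breakpoint(g, inv.distal),
            }
            interrupted = any(
                g.start < bp < g.end for bp in (inv.proximal, inv.distal)
            )
            rows.append(
                {
                    "inversion": inv.name,
                    "gene": g.gene_id,
                    "arm": g.arm,
                    "start": g.start,
                    "end": g.end,
                    "interrupted": interrupted,
                    "dist_proximal": dists["proximal"],
                    "dist_distal": dists["distal"],
                    "dist_nearest": min(dists.values()),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "inversion", "gene", "arm", "start", "end",
            "interrupted", "dist_proximal", "dist_distal", "dist_nearest",
        ],
    )


def intergenic_gaps(
    genes: list[Gene], ids: set[str] | None = None
) -> np.ndarray:
    """Ordered gaps between neighboring genes of one arm.

    Genes are sorted by start; gap_i = max(0, start_{i+1} - end_i - 1),
    so abutting 1-based-inclusive intervals and overlapping genes both
    contribute 0. The flanks to the arm ends are not included.
    """
    subset = [g for g in genes if ids is None or g.gene_id in ids]
    arms = {g.arm for g in subset}
    if len(arms) > 1:
        raise InputError(f"gap computation expects one arm, got {sorted(arms)}")
    if len(subset) < 2:
        raise InputError("need >= 2 genes on the arm to form gaps")
    subset.sort(key=lambda g: (g.start, g.end))
    starts = np.array([g.start for g in subset])
    ends = np.array([g.end for g in subset])
    return np.maximum(0, starts[1:] - ends[:-1] - 1)


def gap_cv(gaps: np.ndarray) -> float:
    """CV of a gap list: sample SD (n-1 denominator) over the mean."""
    gaps = np.asarray(gaps, dtype=float)
    mean = gaps.mean()
    if mean <= 0:
        raise InputError("gap CV undefined: all gaps zero")
    return float(gaps.std(ddof=1) / mean)


@dataclass
class ClusterTestResult:
    arm: str
    label: str
    k: int
    observed_cv: float
    ci_low: float
    ci_high: float
    n_null_samples: int
    verdict: str  # more clustered / less clustered / within CI
    degenerate: bool = False

    def as_row(self) -> dict:
        return {
            "arm": self.arm,
            "label": self.label,
            "k": self.k,
            "observed_cv": self.observed_cv,
            "ci_2.5": self.ci_low,
            "ci_97.5": self.ci_high,
            "n_null_samples": self.n_null_samples,
            "verdict": self.verdict,
            "degenerate": self.degenerate,
        }


def cluster_null(
    arm_genes: list[Gene],
    k: int,
    observed_cv: float,
    n_samples: int = 100_000,
    seed: int = 0,
    label: str = "",
) -> ClusterTestResult:
    """Null CI for the gap CV of k genes drawn uniformly from the arm.

    Each sample draws k gene indices without replacement, computes the
    gap CV, and the CI is the empirical 2.5-97.5% quantile band. An
    observed CV above the band is reported as "more clustered" (gap
    heterogeneity), below as "less clustered". ``k`` equal to the whole
    arm makes every draw identical (degenerate, CI width 0).
    """
    n_genes = len(arm_genes)
    if not 2 <= k <= n_genes:
        raise InputError(f"need 2 <= k <= {n_genes}, got k={k}")
    arm = arm_genes[0].arm
    order = sorted(range(n_genes), key=lambda i: (arm_genes[i].start, arm_genes[i].end))
    starts = np.array([arm_genes[i].start for i in order])
    ends = np.array([arm_genes[i].end for i in order])

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 21]))
    cvs = np.empty(n_samples)
    for b in range(n_samples):
        idx = np.sort(rng.choice(n_genes, size=k, replace=False))
        gaps = np.maximum(0, starts[idx][1:] - ends[idx][:-1] - 1)
        mean = gaps.mean()
        cvs[b] = gaps.std(ddof=1) / mean if mean > 0 else np.nan
    cvs = cvs[np.isfinite(cvs)]
    ci_low, ci_high = np.quantile(cvs, [0.025, 0.975])
    degenerate = k == n_genes
    if observed_cv > ci_high:
        verdict = "more clustered"
    elif observed_cv < ci_low:
        verdict = "less clustered"
    else:
        verdict = "within CI"
    return ClusterTestResult(
        arm=arm,
        label=label,
        k=k,
        observed_cv=observed_cv,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_null_samples=int(cvs.size),
        verdict=verdict,
        degenerate=degenerate,
    )


def clustering_scan(
    genes: list[Gene],
    ial_genes: dict[str, set[str]],
    n_samples: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-arm, per-inversion gap-CV test plus the genome-wide CV."""
    rows = []
    by_arm: dict[str, list[Gene]] = {}
    for g in genes:
        by_arm.setdefault(g.arm, []).append(g)
    for arm, arm_genes in sorted(by_arm.items()):
        genome_cv = gap_cv(intergenic_gaps(arm_genes))
        for inv_name, ial in sorted(ial_genes.items()):
            members = {g.gene_id for g in arm_genes} & ial
            if len(members) < 2:
                continue
            obs = gap_cv(intergenic_gaps(arm_genes, members))
            res = cluster_null(
                arm_genes, len(members), obs,
                n_samples=n_samples, seed=seed, label=inv_name,
            )
            row = res.as_row()
            row["genome_cv"] = genome_cv
            rows.append(row)
    return pd.DataFrame(rows)
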