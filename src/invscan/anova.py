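"""Per-probe nested fixed-effects ANOVA of expression on inversion karyotype.

The model per probe is

    Y_ijkl = mu + Sex_i + InvA_j + InvB_k + Line_(jk)l + eps

with Line coded as lines nested within the joint karyotype combination
(``sum_c (n_c - 1)`` dummies), so inversion contrasts — which are line-level
contrasts — take their sums of squares *sequentially* before Line
(Type-I SS in the order Sex, InvA, InvB, Line). F ratios use the residual
mean square; that denominator is anticonservative for a between-line
factor, which is exactly why significance is assessed by permuting the
line-level karyotype labels rather than by the parametric F distribution.

Multiple testing is handled with Storey q-values on the permutation
P-values; effect sizes are reported as eta-squared per term and Cohen's d
(by default over line means, the units that receive a karyotype).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, InputError, StudyDesign

_ORTH_TOL = 1e-7


def _orth_block(X: np.ndarray, Qall: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the part of ``X`` outside span(Qall)."""
    if X.shape[1] == 0:
        return np.empty((X.shape[0], 0))
    R = X - Qall @ (Qall.T @ X)
    R = R - Qall @ (Qall.T @ R)  # second pass for numerical hygiene
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    return U[:, s > _ORTH_TOL]


@dataclass
class CodedDesign:
    """Sequentially orthogonalized term blocks for one design realization."""

    terms: list[str]  # e.g. ["Sex", "In(2L)t", "In(3R)Mo", "Line"]
    q_blocks: dict[str, np.ndarray]
    df: dict[str, int]
    n: int
    df_resid: int
    dropped: list[str] = field(default_factory=list)
    warnings_: list[str] = field(default_factory=list)

    @property
    def q_model(self) -> np.ndarray:
        return np.concatenate([self.q_blocks[t] for t in self.terms], axis=1)


class AnovaEngine:
    """Precomputed design structure enabling fast refits under permutation.

    Holds the individual-to-line map and the sex column, which never move;
    a permutation round only replaces the line-level karyotype labels and
    rebuilds the inversion and nested-Line blocks.
    """

    def __init__(self, design: StudyDesign, inversions: list[str] | None = None):
        self.design = design
        self.inversions = inversions or design.inversions
        ind = design.individuals
        self.lines = sorted(set(ind["line"]))
        self._line_index = {l: i for i, l in enumerate(self.lines)}
        self.ind_line = np.array([self._line_index[l] for l in ind["line"]])
        self.n = len(ind)
        sexes = set(ind["sex"])
        if len(sexes) < 2:
            raise InputError("design must contain both sexes")
        self.female = (ind["sex"] == "F").to_numpy(dtype=float)
        self.kary_obs = (
            design.karyotypes.loc[self.lines, self.inversions]
            .to_numpy(dtype=float)
        )

    # -- block construction -------------------------------------------------

    def _line_dummies(self, kary: np.ndarray) -> np.ndarray:
        """Nested dummies: per karyotype combination, drop one reference line."""
        combos = [tuple(row) for row in kary]
        cols = []
        for combo in sorted(set(combos)):
            members = [i for i, c in enumerate(combos) if c == combo]
            for line_i in members[1:]:
                cols.append((self.ind_line == line_i).astype(float))
        if not cols:
            return np.empty((self.n, 0))
        return np.column_stack(cols)

    def coded(self, kary: np.ndarray | None = None) -> CodedDesign:
        """Sequential orthonormal blocks for a (possibly permuted) karyotype."""
        if kary is None:
            kary = self.kary_obs
        n = self.n
        dropped, warns = [], []
        blocks: list[tuple[str, np.ndarray]] = [("Sex", self.female[:, None])]
        for j, inv in enumerate(self.inversions):
            col = kary[:, j]
            if np.all(col == col[0]):
                dropped.append(inv)  # empty contrast: df shifts into Line
                continue
            for state in (0, 1):
                if np.sum(col == state) < 2:
                    warns.append(
                        f"{inv}: a karyotype class has <2 lines; "
                        "its F is weakly identified"
                    )
            blocks.append((inv, col[self.ind_line][:, None]))
        blocks.append(("Line", self._line_dummies(kary)))

        Qall = np.full((n, 1), 1.0 / np.sqrt(n))
        q_blocks, df = {}, {}
        for term, X in blocks:
            Qb = _orth_block(X, Qall)
            q_blocks[term] = Qb
            df[term] = Qb.shape[1]
            if Qb.shape[1]:
                Qall = np.concatenate([Qall, Qb], axis=1)
        for name in dropped:  # dropped contrasts keep a 0-df entry
            df[name] = 0
        df_resid = n - Qall.shape[1]
        if df_resid < 1:
            raise InputError(
                "design leaves no residual degrees of freedom "
                "(single line per karyotype combination without replicates?)"
            )
        terms = [t for t, _ in blocks]
        return CodedDesign(
            terms=terms, q_blocks=q_blocks, df=df, n=n,
            df_resid=df_resid, dropped=dropped, warnings_=warns,
        )

    # -- fitting ------------------------------------------------------------

    def block_ss(self, coded: CodedDesign, Y: np.ndarray) -> dict[str, np.ndarray]:
        """Per-term sequential SS for an (n, P) response matrix."""
        out = {}
        for term in coded.terms:
            Qb = coded.q_blocks[term]
            proj = Qb.T @ Y if Qb.shape[1] else np.zeros((0, Y.shape[1]))
            out[term] = np.sum(proj**2, axis=0)
        return out

    def f_stats(
        self, coded: CodedDesign, Y: np.ndarray, ss_total: np.ndarray
    ) -> tuple[dict[str, np.ndarray], np.ndarray]:
        """F per term plus the residual SS, vectorized over probes."""
        ss = self.block_ss(coded, Y)
        ss_resid = ss_total - sum(ss.values())
        ss_resid = np.maximum(ss_resid, 0.0)
        ms_resid = ss_resid / coded.df_resid
        F = {}
        with np.errstate(divide="ignore", invalid="ignore"):
            for term in coded.terms:
                if coded.df[term] == 0:
                    F[term] = np.full(Y.shape[1], np.nan)
                else:
                    F[term] = (ss[term] / coded.df[term]) / ms_resid
        return F, ss_resid


def build_design(
    design: StudyDesign, inversions: list[str] | None = None
) -> CodedDesign:
    """Code the model structure (Sex, inversions, nested Line) for a design."""
    coded = AnovaEngine(design, inversions).coded()
    for w in coded.warnings_:
        warnings.warn(w, stacklevel=2)
    return coded


def fit_probe_anova(y: np.ndarray, design: StudyDesign | AnovaEngine) -> pd.DataFrame:
    """Sequential ANOVA table (df, SS, MS, F, eta2) for one probe."""
    engine = design if isinstance(design, AnovaEngine) else AnovaEngine(design)
    coded = engine.coded()
    y = np.asarray(y, dtype=float)
    if y.shape[0] != engine.n:
        raise InputError(f"response length {y.shape[0]} != {engine.n} individuals")
    Y = y[:, None]
    ss_total = np.sum((y - y.mean()) ** 2)
    ss = {t: v[0] for t, v in engine.block_ss(coded, Y).items()}
    ss_resid = max(ss_total - sum(ss.values()), 0.0)
    rows = []
    ms_resid = ss_resid / coded.df_resid
    for term in coded.terms:
        df_t = coded.df[term]
        ms = ss[term] / df_t if df_t else np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ms / ms_resid if df_t else np.nan
        eta2 = ss[term] / ss_total if ss_total > 0 else np.nan
        rows.append((term, df_t, ss[term], ms, f, eta2))
    rows.append(
        (
            "Residual",
            coded.df_resid,
            ss_resid,
            ms_resid,
            np.nan,
            ss_resid / ss_total if ss_total > 0 else np.nan,
        )
    )
    return pd.DataFrame(
        rows, columns=["term", "df", "SS", "MS", "F", "eta2"]
    ).set_index("term")


# ---------------------------------------------------------------------------
# model selection (add1 / drop1 with AIC, majority rule across probes)


def _aic(n: int, rss: np.ndarray, rank: int) -> np.ndarray:
    """AIC = n*ln(RSS/n) + 2*(p+1): p coefficients plus the variance."""
    with np.errstate(divide="ignore"):
        return n * np.log(rss / n) + 2 * (rank + 1)


def model_selection_scan(
    expr: ExpressionMatrix | pd.DataFrame,
    design: StudyDesign,
    inversions: list[str] | None = None,
) -> dict:
    """Score the main-effects model against single add/drop candidates.

    Candidates: the main-effects model; each pairwise interaction among
    Sex and the inversions added singly; each main effect dropped singly.
    Per probe the lowest AIC wins (ties break toward the model with fewer
    terms); the preferred global model is the per-probe winner majority.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    engine = AnovaEngine(design, inversions)
    Y = values.to_numpy(dtype=float)
    n = engine.n

    kary = engine.kary_obs
    inv_cols = {
        inv: kary[:, j][engine.ind_line][:, None]
        for j, inv in enumerate(engine.inversions)
    }
    base_blocks: list[tuple[str, np.ndarray]] = (
        [("Sex", engine.female[:, None])]
        + [(inv, inv_cols[inv]) for inv in engine.inversions]
        + [("Line", engine._line_dummies(kary))]
    )

    def inter_col(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        return a * b

    candidates: dict[str, list[tuple[str, np.ndarray]]] = {"main": base_blocks}
    pairs = [("Sex", engine.female[:, None])] + [
        (inv, inv_cols[inv]) for inv in engine.inversions
    ]
    for (na, ca), (nb, cb) in itertools.combinations(pairs, 2):
        candidates[f"main+{na}:{nb}"] = base_blocks + [
            (f"{na}:{nb}", inter_col(ca, cb))
        ]
    for name, _ in base_blocks:
        candidates[f"main-{name}"] = [b for b in base_blocks if b[0] != name]

    table = {}
    skipped = []
    for label, blocks in candidates.items():
        Qall = np.full((n, 1), 1.0 / np.sqrt(n))
        for _, X in blocks:
            Qb = _orth_block(X, Qall)
            if Qb.shape[1]:
                Qall = np.concatenate([Qall, Qb], axis=1)
        rank = Qall.shape[1]
        if n - rank < 1:
            skipped.append(label)
            continue
        proj = Qall.T @ Y
        rss = np.maximum(np.sum(Y**2, axis=0) - np.sum(proj**2, axis=0), 1e-300)
        # rank counts all estimated coefficients including the intercept
        table[label] = {
            "aic": _aic(n, rss, rank),
            "rank": rank,
            "n_terms": len(blocks),
        }

    labels = list(table)
    aics = np.stack([table[l]["aic"] for l in labels])  # (C, P)
    n_terms = np.array([table[l]["n_terms"] for l in labels], dtype=float)
    # exact AIC ties break toward the model with fewer terms
    best_idx = np.argmin(aics + 1e-9 * n_terms[:, None], axis=0)
    best = pd.Series([labels[i] for i in best_idx], index=values.columns)
    majority = best.value_counts().idxmax()
    aic_frame = pd.DataFrame(
        {l: table[l]["aic"] for l in labels}, index=values.columns
    )
    return {
        "aic": aic_frame,
        "best_per_probe": best,
        "majority_model": majority,
        "skipped": skipped,
    }


# ---------------------------------------------------------------------------
# permutation P-values


def permutation_scan(
    expr: ExpressionMatrix | pd.DataFrame,
    design: StudyDesign,
    B: int = 10_000,
    seed: int = 0,
    inversions: list[str] | None = None,
    alpha_warn: float | None = 0.05,
    estimator: str = "percentile",
) -> dict:
    """Permutation P-values for each inversion term, shared across probes.

    Each of the ``B`` rounds permutes every inversion's line-level
    karyotype labels independently without replacement (the count of
    inverted lines is preserved and individuals never change lines),
    rebuilds the nested design, refits every probe and records F*.

    ``estimator`` selects how the P-value is formed from the permutation
    count ``cnt = #{F* >= F_obs}``: ``"percentile"`` (default) reports
    cnt/B — the rank of the observed F in the permutation distribution —
    floored at 1/(2B) so P stays in (0, 1] for downstream q-values;
    ``"add_one"`` reports the exactly-valid but conservative
    (1 + cnt)/(B + 1), whose discreteness at small B costs sensitivity.
    """
    if B < 1:
        raise InputError("B must be >= 1")
    if estimator not in ("percentile", "add_one"):
        raise InputError("estimator must be 'percentile' or 'add_one'")
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    engine = AnovaEngine(design, inversions)
    Y = values.to_numpy(dtype=float)
    ss_total = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    constant = ss_total <= 0
    coded_obs = engine.coded()
    F_obs, _ = engine.f_stats(coded_obs, Y, ss_total)

    inv_terms = [t for t in engine.inversions if t not in coded_obs.dropped]
    if alpha_warn is not None and 1.0 / (B + 1) > alpha_warn:
        warnings.warn(
            f"B={B} permutations give a P-value floor of {1/(B+1):.3g} above "
            f"alpha={alpha_warn}", stacklevel=2,
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 11]))
    n_lines = len(engine.lines)
    counts = {inv: np.zeros(Y.shape[1]) for inv in inv_terms}
    for _ in range(B):
        kary = engine.kary_obs.copy()
        for j in range(kary.shape[1]):
            kary[:, j] = kary[rng.permutation(n_lines), j]
        coded_b = engine.coded(kary)
        F_b, _ = engine.f_stats(coded_b, Y, ss_total)
        for inv in inv_terms:
            counts[inv] += F_b[inv] >= F_obs[inv]
    if estimator == "percentile":
        pvals = {
            inv: np.where(
                constant, np.nan, np.maximum(counts[inv] / B, 1.0 / (2.0 * B))
            )
            for inv in inv_terms
        }
    else:
        pvals = {
            inv: np.where(constant, np.nan, (1.0 + counts[inv]) / (B + 1.0))
            for inv in inv_terms
        }
    return {
        "p": pd.DataFrame(pvals, index=values.columns),
        "F_obs": pd.DataFrame(
            {inv: F_obs[inv] for inv in inv_terms}, index=values.columns
        ),
        "constant": pd.Series(constant, index=values.columns),
        "B": B,
        "floor": 1.0 / (B + 1.0),
    }


# ---------------------------------------------------------------------------
# Storey q-values


def storey_pi0(
    p: np.ndarray, lambdas: np.ndarray | None = None
) -> float:
    """pi0-hat: lambda-grid estimates with a cubic smoother taken to 1.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) on the grid
    {0, 0.05, ..., 0.90}; a cubic polynomial fit is evaluated at
    lambda = 1 and clamped into (0, 1] (a non-positive extrapolation
    falls back to 1.0, the conservative BH limit).
    """
    p = np.asarray(p, dtype=float)
    if lambdas is None:
        lambdas = np.arange(0.0, 0.901, 0.05)
    m = p.size
    pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.polyval(coef, 1.0))
    if pi0 <= 0.0:
        return 1.0
    return min(pi0, 1.0)


def storey_qvalues(
    p, lambdas: np.ndarray | None = None, min_m: int = 100
) -> tuple[np.ndarray, float]:
    """Storey q-values: pi0-hat times the BH step-up adjustment.

    With fewer than ``min_m`` P-values the pi0 estimate is unstable and
    the procedure falls back to pi0 = 1 (plain Benjamini-Hochberg).
    """
    p = np.asarray(p, dtype=float)
    ok = np.isfinite(p)
    if np.any((p[ok] <= 0) | (p[ok] > 1)):
        raise InputError("P-values must lie in (0, 1]")
    q = np.full_like(p, np.nan, dtype=float)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return q, 1.0
    if m < min_m:
        pi0 = 1.0
        warnings.warn(
            f"only {m} P-values: pi0 estimation unstable, using pi0=1 (BH)",
            stacklevel=2,
        )
    else:
        pi0 = storey_pi0(pv, lambdas)
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m * pi0 / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]  # enforce monotonicity
    qv = np.empty(m)
    qv[order] = np.minimum(ranked, 1.0)
    q[ok] = qv
    return q, pi0


# ---------------------------------------------------------------------------
# effect sizes


def eta_squared(anova_table: pd.DataFrame) -> pd.Series:
    """Per-term eta^2 = SS_term / SS_total from a fitted ANOVA table."""
    ss_total = anova_table["SS"].sum()
    if ss_total <= 0:
        raise InputError("eta^2 undefined for a constant probe (SS_total = 0)")
    return anova_table["SS"] / ss_total


def cohens_d(values_inverted, values_standard) -> float:
    """Standardized mean difference, SD pooled as the root mean square.

    d = (mean_inv - mean_std) / sqrt((s_inv^2 + s_std^2) / 2), positive
    when the inverted karyotype has the higher expression. Both groups
    need >= 2 observations; if both SDs are zero the value is 0 when the
    means agree and undefined (nan) otherwise.
    """
    x = np.asarray(values_inverted, dtype=float)
    y = np.asarray(values_standard, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("Cohen's d needs >= 2 observations per group")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    denom = np.sqrt((sx**2 + sy**2) / 2.0)
    diff = x.mean() - y.mean()
    if denom == 0.0:
        return 0.0 if diff == 0.0 else float("nan")
    return float(diff / denom)


def expected_overlap(d: float) -> float:
    """Percent overlap of two unit-SD normal densities |d| apart.

    The overlapping coefficient 2*Phi(-|d|/2) expressed as a percentage;
    d = 1 gives ~62% (61.71 before rounding).
    """
    return float(200.0 * stats.norm.cdf(-abs(d) / 2.0))


# ---------------------------------------------------------------------------
# the full scan


def _line_mean_d(
    values: pd.DataFrame, design: StudyDesign, inversion: str
) -> pd.Series:
    """Cohen's d per probe over line means for one inversion."""
    lm = design.line_means(values)
    kary = design.karyotypes[inversion].reindex(lm.index)
    inv_mask = (kary == 1).to_numpy()
    std_mask = (kary == 0).to_numpy()
    X = lm.to_numpy(dtype=float)
    xi, xs = X[inv_mask], X[std_mask]
    if xi.shape[0] < 2 or xs.shape[0] < 2:
        return pd.Series(np.nan, index=values.columns)
    si = xi.std(axis=0, ddof=1)
    ss = xs.std(axis=0, ddof=1)
    denom = np.sqrt((si**2 + ss**2) / 2.0)
    diff = xi.mean(axis=0) - xs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(denom > 0, diff / denom, np.where(diff == 0, 0.0, np.nan))
    return pd.Series(d, index=values.columns)


def anova_scan(
    expr: ExpressionMatrix,
    design: StudyDesign,
    B: int = 10_000,
    seed: int = 0,
    q_threshold: float = 0.05,
    inversions: list[str] | None = None,
    d_unit: str = "line",
    estimator: str = "percentile",
) -> dict:
    """Run the whole per-probe scan and assemble one record per probe.

    Returns a dict with the results frame (df/SS/F/eta2 per term plus
    permutation P, q and Cohen's d per inversion), the IAL sets at
    ``q < q_threshold``, and run metadata. ``d_unit`` selects whether
    Cohen's d is computed over line means (default) or individuals.
    """
    values = expr.values
    engine = AnovaEngine(design, inversions)
    coded = engine.coded()
    Y = values.to_numpy(dtype=float)
    ss_total = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    ss = engine.block_ss(coded, Y)
    ss_resid = np.maximum(ss_total - sum(ss.values()), 0.0)
    F, _ = engine.f_stats(coded, Y, ss_total)

    perm = permutation_scan(
        expr, design, B=B, seed=seed, inversions=inversions, estimator=estimator
    )
    res = pd.DataFrame(index=values.columns)
    res.index.name = "probe"
    with np.errstate(invalid="ignore", divide="ignore"):
        for term in coded.terms:
            res[f"SS_{term}"] = ss[term]
            res[f"F_{term}"] = F[term]
            res[f"eta2_{term}"] = np.where(ss_total > 0, ss[term] / ss_total, np.nan)
        res["SS_Residual"] = ss_resid
        res["eta2_Residual"] = np.where(ss_total > 0, ss_resid / ss_total, np.nan)
    res["constant"] = perm["constant"].to_numpy()

    inv_terms = [t for t in engine.inversions if t not in coded.dropped]
    ial: dict[str, pd.Index] = {}
    for inv in inv_terms:
        p = perm["p"][inv].to_numpy()
        q, pi0 = storey_qvalues(p[np.isfinite(p)])
        qcol = np.full(p.shape, np.nan)
        qcol[np.isfinite(p)] = q
        res[f"p_{inv}"] = p
        res[f"q_{inv}"] = qcol
        if d_unit == "line":
            res[f"d_{inv}"] = _line_mean_d(values, design, inv)
        else:
            km = design.individual_karyotype(inv)
            res[f"d_{inv}"] = [
                cohens_d(Y[km == 1, j], Y[km == 0, j]) for j in range(Y.shape[1])
            ]
        res.attrs[f"pi0_{inv}"] = pi0
        ial[inv] = res.index[(qcol < q_threshold) & np.isfinite(qcol)]

    df_map = {**coded.df, "Residual": coded.df_resid}
    return {
        "results": res,
        "ial": {inv: set(ial[inv]) for inv in inv_terms},
        "df": df_map,
        "dropped_terms": coded.dropped,
        "B": B,
        "seed": seed,
        "q_threshold": q_threshold,
        "n_excluded_constant": int(perm["constant"].sum()),
    }


def call_ial(
    results: pd.DataFrame,
    inversion: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Probes with q < threshold for one inversion, with the sign of d.

    Membership uses a strict inequality; a probe at exactly the threshold
    is excluded.
    """
    q = results[f"q_{inversion}"]
    members = results.index[(q < q_threshold) & q.notna()]
    out = pd.DataFrame(index=members)
    out.index.name = "probe"
    out["q"] = results.loc[members, f"q_{inversion}"]
    dcol = f"d_{inversion}"
    if dcol in results:
        out["d"] = results.loc[members, dcol]
        out["direction"] = np.sign(out["d"]).map({1.0: "up", -1.0: "down", 0.0: "0"})
    return out
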