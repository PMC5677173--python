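"""Ground-truthed synthetic study bundles.

Emulates the structure of an inbred-line expression study crossed with a
genotyped line panel: a small expression panel (default 34 lines x 2 sexes
x 2 replicates = 136 individuals) with two inversion karyotypes segregating
at line level, a larger genotype panel (default 200 lines) whose SNPs are
in distance-decaying LD with the inversion breakpoints, block-correlated
expression modules driven by shared line-level factors, and an optional
trans-acting transcription-factor scenario.

The generative expression model mirrors the analysis model: per individual,

    Y = baseline + sex_effect*1[female] + sum_i d_i*sigma_between*1[inverted_i]
        + line effect (module factor + gene-specific, Var = sigma_line^2)
        + N(0, sigma_resid^2)

where ``sigma_between`` is the between-line SD of line means
(sqrt(sigma_line^2 + sigma_resid^2 / n_reps)), so a planted effect ``d`` is
what the sample Cohen's d estimator over line means targets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ConfigError,
    Gene,
    GroundTruth,
    InputError,
    Inversion,
    MISSING,
    SnpTable,
    StudyDesign,
)

# Default arm lengths and inversion breakpoints follow the D. melanogaster
# release-5 assembly (Mb-scale paracentric inversions on 2L and 3R).
DEFAULT_ARMS: tuple[tuple[str, int], ...] = (
    ("2L", 23_000_000),
    ("2R", 21_100_000),
    ("3L", 24_500_000),
    ("3R", 27_900_000),
    ("X", 22_400_000),
)
DEFAULT_INVERSIONS: tuple[tuple[str, str, int, int], ...] = (
    ("In(2L)t", "2L", 2_225_744, 13_154_180),
    ("In(3R)Mo", "3R", 17_232_639, 24_857_019),
)


@dataclass
class SimulationConfig:
    """Knobs for a synthetic bundle; defaults emulate the study design."""

    n_expr_lines: int = 34
    reps_per_sex: int = 2
    n_inverted: dict[str, int] = field(
        default_factory=lambda: {"In(2L)t": 2, "In(3R)Mo": 7}
    )
    n_both_inverted: int = 1
    n_geno_lines: int = 200
    n_geno_inverted: dict[str, int] = field(
        default_factory=lambda: {"In(2L)t": 19, "In(3R)Mo": 17}
    )
    arms: tuple[tuple[str, int], ...] = DEFAULT_ARMS
    genes_per_arm: int = 100
    gene_length_dist: tuple[float, float] = (3000.0, 1000.0)
    inversions: tuple[tuple[str, str, int, int], ...] = DEFAULT_INVERSIONS
    # planted expression effects: (gene id or gene index, inversion, d)
    planted_effects: list[tuple[object, str, float]] = field(default_factory=list)
    sigma_line: float = 0.3
    sigma_resid: float = 0.3
    sigma_gene_baseline: float = 2.0
    baseline_mean: float = 6.0
    sex_effect: float = 0.5
    n_modules: int = 20
    rho_module: float = 0.5
    # SNP-inversion LD profile: r(delta) = r_max * exp(-delta / ld_lambda)
    r_max: float = 0.9
    ld_lambda: float = 1_000_000.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_snp_maf: float | None = None
    snps_per_arm: int = 200
    # optional fixed SNP positions per arm (replaces the uniform draw there)
    snp_positions: dict[str, tuple[int, ...]] | None = None
    missing_rate: float = 0.02
    # trans-regulator scenario (TF near a breakpoint, targets carry effects)
    n_tfs: int = 5
    tf_out_degree: int = 10
    trans_tf_scenario: bool = False
    trans_inversion: str = "In(3R)Mo"
    trans_d: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        arm_len = dict(self.arms)
        if self.n_expr_lines <= 0 or self.n_geno_lines <= 0:
            raise ConfigError("line counts must be positive")
        if self.reps_per_sex <= 0 or self.genes_per_arm <= 0:
            raise ConfigError("counts must be positive")
        for inv, k in self.n_inverted.items():
            if not 0 <= k < self.n_expr_lines:
                raise ConfigError(
                    f"n_inverted[{inv}]={k} must be in [0, n_expr_lines)"
                )
        for inv, k in self.n_geno_inverted.items():
            if not 0 <= k <= self.n_geno_lines:
                raise ConfigError(f"n_geno_inverted[{inv}]={k} out of range")
        for name, arm, prox, dist in self.inversions:
            if arm not in arm_len:
                raise ConfigError(f"inversion {name} on unknown arm {arm}")
            if not 0 < prox < dist <= arm_len[arm]:
                raise ConfigError(
                    f"inversion {name}: need 0 < proximal < distal <= arm length"
                )
        if not 0.0 <= self.r_max <= 1.0:
            raise ConfigError("r_max must be in [0, 1]")
        if not 0.0 <= self.rho_module < 1.0:
            raise ConfigError("rho_module must be in [0, 1)")
        if self.sigma_resid <= 0:
            raise ConfigError("sigma_resid must be > 0")

    @property
    def inversion_names(self) -> list[str]:
        return [name for name, *_ in self.inversions]

    @property
    def sigma_between(self) -> float:
        n_rep = 2 * self.reps_per_sex
        return float(np.sqrt(self.sigma_line**2 + self.sigma_resid**2 / n_rep))


@dataclass
class Genome:
    genes: list[Gene]
    inversions: list[Inversion]
    probe_map: pd.Series  # probe id -> gene id

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.gene_id, g.arm, g.start, g.end) for g in self.genes],
            columns=["gene", "arm", "start", "end"],
        )


@dataclass
class Bundle:
    """A complete synthetic study: all inputs plus the planted truth."""

    config: SimulationConfig
    design: StudyDesign
    genome: Genome
    snps: SnpTable
    expression: "ExpressionMatrix"
    tf_edges: pd.DataFrame
    truth: GroundTruth


def _rng(cfg_seed: int, seed: int | None, stage: int) -> np.random.Generator:
    s = cfg_seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(s) % (2**31), stage]))


def _assign_karyotypes(
    rng: np.random.Generator,
    lines: list[str],
    counts: dict[str, int],
    n_both: int,
) -> pd.DataFrame:
    """Line-level 0/1 calls; with two inversions, ``n_both`` lines carry both."""
    invs = list(counts)
    kary = pd.DataFrame(0, index=pd.Index(lines, name="line"), columns=invs)
    order = list(rng.permutation(lines))
    if len(invs) == 2:
        a, b = invs
        both = min(n_both, counts[a], counts[b])
        need = counts[a] + counts[b] - both
        if need > len(lines):
            raise ConfigError("inverted-line counts exceed the panel size")
        both_lines = order[:both]
        a_only = order[both : both + counts[a] - both]
        b_only = order[both + counts[a] - both : need]
        kary.loc[both_lines + a_only, a] = 1
        kary.loc[both_lines + b_only, b] = 1
    else:  # disjoint assignment for other inversion counts
        if sum(counts.values()) > len(lines):
            raise ConfigError("inverted-line counts exceed the panel size")
        at = 0
        for inv in invs:
            kary.loc[order[at : at + counts[inv]], inv] = 1
            at += counts[inv]
    return kary


def make_design(cfg: SimulationConfig, seed: int | None = None) -> StudyDesign:
    """Build the expression study design on top of the genotype panel.

    The karyotype table covers the full genotype panel
    (``n_geno_lines`` lines, ``n_geno_inverted`` of them inverted); the
    expression individuals are drawn from a subset of lines chosen so that
    exactly ``n_inverted[i]`` expression lines are inverted for inversion
    ``i`` (with ``n_both_inverted`` lines, default 1, inverted for both, as
    in a design where one line carries both arrangements).
    """
    rng = _rng(cfg.seed, seed, stage=1)
    width = len(str(cfg.n_geno_lines))
    lines = [f"line{str(i + 1).zfill(width)}" for i in range(cfg.n_geno_lines)]
    kary = _assign_karyotypes(rng, lines, cfg.n_geno_inverted, cfg.n_both_inverted)

    invs = list(cfg.n_inverted)
    n_both = min(cfg.n_both_inverted, *(cfg.n_inverted[i] for i in invs)) if len(
        invs
    ) == 2 else 0

    def pick(pool: list[str], k: int, label: str) -> list[str]:
        if len(pool) < k:
            raise ConfigError(
                f"genotype panel has only {len(pool)} {label} lines, need {k}"
            )
        return list(rng.choice(pool, size=k, replace=False))

    chosen: list[str] = []
    if len(invs) == 2:
        a, b = invs
        is_a = kary[a] == 1
        is_b = kary[b] == 1
        chosen += pick(list(kary.index[is_a & is_b]), n_both, "doubly inverted")
        chosen += pick(
            list(kary.index[is_a & ~is_b]), cfg.n_inverted[a] - n_both, f"{a}-only"
        )
        chosen += pick(
            list(kary.index[~is_a & is_b]), cfg.n_inverted[b] - n_both, f"{b}-only"
        )
        n_std = cfg.n_expr_lines - len(chosen)
        chosen += pick(list(kary.index[~is_a & ~is_b]), n_std, "standard")
    else:
        for inv in invs:
            pool = [
                l
                for l in kary.index[kary[inv] == 1]
                if l not in chosen
                and not any(kary.loc[l, o] == 1 for o in invs if o != inv)
            ]
            chosen += pick(pool, cfg.n_inverted[inv], f"{inv}-inverted")
        std_pool = [l for l in kary.index[(kary[invs] == 0).all(axis=1)]]
        chosen += pick(std_pool, cfg.n_expr_lines - len(chosen), "standard")

    chosen = sorted(chosen)
    rows = [
        (f"{line}_{sex}{r + 1}", line, sex)
        for line in chosen
        for sex in ("F", "M")
        for r in range(cfg.reps_per_sex)
    ]
    individuals = pd.DataFrame(rows, columns=["individual", "line", "sex"])
    return StudyDesign(individuals=individuals, karyotypes=kary)


def make_genome(cfg: SimulationConfig, seed: int | None = None) -> Genome:
    """Sample gene intervals per arm plus the inversion definitions.

    Gene lengths are normal-distributed (``gene_length_dist``, floored at
    200 bp); starts are uniform on the arm, then genes are sorted by start.
    The probe map is 1:1 by default (one ``<gene>_at`` probe per gene).
    """
    rng = _rng(cfg.seed, seed, stage=2)
    mean_len, sd_len = cfg.gene_length_dist
    genes: list[Gene] = []
    for arm, arm_len in cfg.arms:
        if mean_len >= arm_len:
            raise ConfigError(f"arm {arm} too short for genes of mean {mean_len}")
        lengths = np.maximum(
            200, rng.normal(mean_len, sd_len, size=cfg.genes_per_arm)
        ).astype(int)
        if np.any(lengths >= arm_len):
            raise ConfigError(f"arm {arm} too short for sampled gene lengths")
        starts = rng.integers(1, arm_len - lengths + 1)
        order = np.argsort(starts, kind="stable")
        for i, j in enumerate(order):
            genes.append(
                Gene(
                    gene_id=f"g{arm}_{i:04d}",
                    arm=arm,
                    start=int(starts[j]),
                    end=int(starts[j] + lengths[j] - 1),
                )
            )
    inversions = [Inversion(*spec) for spec in cfg.inversions]
    probe_map = pd.Series(
        {f"{g.gene_id}_at": g.gene_id for g in genes}, name="gene"
    )
    probe_map.index.name = "probe"
    return Genome(genes=genes, inversions=inversions, probe_map=probe_map)


def max_abs_correlation(p: float, q: float) -> float:
    """Frechet upper bound on |corr| between Bernoulli(p) and Bernoulli(q)."""
    lo, hi = min(p, q), max(p, q)
    if lo <= 0 or hi >= 1:
        return 0.0
    return float(np.sqrt(lo * (1 - hi) / (hi * (1 - lo))))


def _ld_targets(
    positions: np.ndarray, inv: Inversion, cfg: SimulationConfig
) -> np.ndarray:
    delta = np.minimum(
        np.abs(positions - inv.proximal), np.abs(positions - inv.distal)
    )
    return cfg.r_max * np.exp(-delta / cfg.ld_lambda)


def make_genotypes(
    design: StudyDesign,
    genome: Genome,
    cfg: SimulationConfig,
    seed: int | None = None,
) -> tuple[SnpTable, pd.DataFrame]:
    """Simulate per-line SNP calls with breakpoint-decaying inversion LD.

    On an arm carrying inversion ``i`` each SNP's target correlation with
    the karyotype is ``r(delta) = r_max * exp(-delta/lambda)`` where
    ``delta`` is the distance to the nearer breakpoint. The minor allele
    copies the karyotype indicator with probability ``c`` and is otherwise
    an independent Bernoulli draw; with the default (SNP MAF = inversion
    frequency) ``c`` equals the target ``r`` exactly. Setting
    ``ld_snp_maf`` decouples the MAF, subject to the Frechet bound on the
    correlation of two Bernoullis.

    Returns the table plus a per-SNP frame of target ``r`` values.
    """
    rng = _rng(cfg.seed, seed, stage=3)
    lines = design.lines
    n_lines = len(lines)
    inv_by_arm = {inv.arm: inv for inv in genome.inversions}

    trans_positions: dict[str, int] = {}
    if cfg.trans_tf_scenario:
        tf_gene = _choose_trans_tf(genome, cfg)
        trans_positions[tf_gene.arm] = (tf_gene.start + tf_gene.end) // 2

    snp_rows = []
    call_cols = []
    truth_rows = []
    for arm, arm_len in cfg.arms:
        fixed = (cfg.snp_positions or {}).get(arm)
        if fixed is not None:
            positions = np.sort(np.asarray(fixed, dtype=int))
            if positions.size and (positions[0] < 1 or positions[-1] > arm_len):
                raise ConfigError(f"fixed SNP positions outside arm {arm}")
        else:
            positions = np.sort(rng.integers(1, arm_len + 1, size=cfg.snps_per_arm))
        forced = trans_positions.get(arm)
        if forced is not None:
            positions = np.sort(np.append(positions, forced))
        inv = inv_by_arm.get(arm)
        if inv is not None:
            kary = design.karyotypes[inv.name].reindex(lines).to_numpy()
            p_inv = float(kary.mean())
            targets = _ld_targets(positions, inv, cfg)
            if forced is not None:
                targets[np.searchsorted(positions, forced)] = cfg.r_max
            if cfg.ld_snp_maf is not None:
                q = cfg.ld_snp_maf
                bound = max_abs_correlation(p_inv, q)
                if targets.max() > bound + 1e-12:
                    raise ConfigError(
                        f"target r {targets.max():.3f} with SNP MAF {q} and "
                        f"inversion frequency {p_inv:.3f} violates the "
                        f"Frechet correlation bound {bound:.3f}"
                    )
                c = targets * np.sqrt(q * (1 - q) / (p_inv * (1 - p_inv)))
                q_indep = (q - c * p_inv) / np.maximum(1e-12, 1 - c)
            else:
                c = targets
                q_indep = np.full_like(targets, p_inv)
            copy = rng.random((n_lines, len(positions))) < c
            indep = (rng.random((n_lines, len(positions))) < q_indep).astype(np.int8)
            calls = np.where(copy, kary[:, None], indep).astype(np.int8)
            truth_inv = inv.name
        else:
            mafs = rng.uniform(*cfg.maf_range, size=len(positions))
            calls = (rng.random((n_lines, len(positions))) < mafs).astype(np.int8)
            targets = np.zeros(len(positions))
            truth_inv = ""
        for k, pos in enumerate(positions):
            sid = f"snp_{arm}_{pos}_{k}"
            snp_rows.append((sid, arm, int(pos)))
            truth_rows.append((sid, truth_inv, float(targets[k])))
        call_cols.append(calls)

    calls = np.concatenate(call_cols, axis=1)
    if cfg.missing_rate > 0:
        drop = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(drop, np.int8(MISSING), calls)
    snps = pd.DataFrame(snp_rows, columns=["snp_id", "arm", "pos"])
    truth = pd.DataFrame(truth_rows, columns=["snp_id", "inversion", "target_r"])
    return SnpTable(lines=lines, snps=snps, calls=calls), truth


def _choose_trans_tf(genome: Genome, cfg: SimulationConfig) -> Gene:
    inv = next(i for i in genome.inversions if i.name == cfg.trans_inversion)
    arm_genes = [g for g in genome.genes if g.arm == inv.arm]
    if not arm_genes:
        raise ConfigError(f"no genes on arm {inv.arm} for the trans-TF scenario")
    return min(arm_genes, key=lambda g: min(abs(g.start - inv.proximal),
                                            abs(g.end - inv.proximal)))


def resolve_planted(
    genome: Genome, planted: list[tuple[object, str, float]]
) -> pd.DataFrame:
    """Normalize planted-effect specs to (gene id, inversion, d) rows."""
    ids = [g.gene_id for g in genome.genes]
    inv_names = {i.name for i in genome.inversions}
    rows = []
    for gene, inversion, d in planted:
        gid = ids[gene] if isinstance(gene, (int, np.integer)) else str(gene)
        if gid not in set(ids):
            raise InputError(f"planted gene {gid!r} absent from the annotation")
        if inversion not in inv_names:
            raise InputError(f"planted effect names unknown inversion {inversion!r}")
        rows.append((gid, inversion, float(d)))
    return pd.DataFrame(rows, columns=["gene", "inversion", "d"])


def make_expression(
    design: StudyDesign,
    genome: Genome,
    cfg: SimulationConfig,
    seed: int | None = None,
    extra_effects: pd.DataFrame | None = None,
):
    """Simulate the individuals-by-probes matrix and its ground truth."""
    from .core import ExpressionMatrix  # local import to avoid cycle at typing

    rng = _rng(cfg.seed, seed, stage=4)
    ind = design.individuals
    expr_lines = sorted(set(ind["line"]))
    line_idx = {l: i for i, l in enumerate(expr_lines)}
    n_ind, n_lines = len(ind), len(expr_lines)
    gene_ids = [g.gene_id for g in genome.genes]
    n_genes = len(gene_ids)

    modules = pd.Series(
        rng.integers(0, cfg.n_modules, size=n_genes), index=gene_ids, name="module"
    )
    planted = resolve_planted(genome, cfg.planted_effects)
    if extra_effects is not None and len(extra_effects):
        extra = extra_effects.reset_index(drop=True)
        planted = (
            extra if planted.empty
            else pd.concat([planted, extra], ignore_index=True)
        )

    baseline = rng.normal(cfg.baseline_mean, cfg.sigma_gene_baseline, size=n_genes)
    factor = rng.standard_normal((n_lines, cfg.n_modules))
    gene_line = rng.standard_normal((n_lines, n_genes))
    rho = cfg.rho_module
    line_eff = cfg.sigma_line * (
        np.sqrt(rho) * factor[:, modules.to_numpy()]
        + np.sqrt(1 - rho) * gene_line
    )

    shift = np.zeros((n_lines, n_genes))
    gene_col = {g: j for j, g in enumerate(gene_ids)}
    for gid, inversion, d in planted.itertuples(index=False):
        k = design.karyotypes[inversion].reindex(expr_lines).to_numpy(dtype=float)
        shift[:, gene_col[gid]] += d * cfg.sigma_between * k

    il = np.array([line_idx[l] for l in ind["line"]])
    female = (ind["sex"] == "F").to_numpy(dtype=float)
    Y = (
        baseline[None, :]
        + cfg.sex_effect * female[:, None]
        + (line_eff + shift)[il, :]
        + rng.normal(0.0, cfg.sigma_resid, size=(n_ind, n_genes))
    )

    probes = list(genome.probe_map.index)
    gene_to_probe = {g: p for p, g in genome.probe_map.items()}
    values = pd.DataFrame(
        Y, index=pd.Index(ind["individual"], name="individual"),
        columns=[gene_to_probe[g] for g in gene_ids],
    )[probes]
    truth = GroundTruth(effects=planted, modules=modules)
    return ExpressionMatrix(values=values, probe_map=genome.probe_map), truth


def make_tf_network(
    genome: Genome,
    cfg: SimulationConfig,
    seed: int | None = None,
    trans_tf: str | None = None,
) -> pd.DataFrame:
    """Random TF->target edge list with configurable out-degree.

    When ``trans_tf`` is given it is included as a regulator; its targets
    are the genes that carry the planted trans effects in the scenario.
    """
    rng = _rng(cfg.seed, seed, stage=5)
    gene_ids = [g.gene_id for g in genome.genes]
    if cfg.tf_out_degree >= len(gene_ids):
        raise ConfigError("tf_out_degree must be smaller than the gene count")
    if cfg.n_tfs < 1:
        raise ConfigError("need at least one TF")
    tfs = list(rng.choice(gene_ids, size=cfg.n_tfs, replace=False))
    if trans_tf is not None and trans_tf not in tfs:
        tfs[0] = trans_tf
    rows = []
    for tf in tfs:
        pool = [g for g in gene_ids if g != tf]
        targets = rng.choice(pool, size=cfg.tf_out_degree, replace=False)
        rows += [(tf, t) for t in targets]
    return pd.DataFrame(rows, columns=["tf", "target"])


def generate_bundle(cfg: SimulationConfig, seed: int | None = None) -> Bundle:
    """Run every generator stage in order and collect the bundle."""
    design = make_design(cfg, seed)
    genome = make_genome(cfg, seed)
    trans_tf = _choose_trans_tf(genome, cfg).gene_id if cfg.trans_tf_scenario else None
    edges = make_tf_network(genome, cfg, seed, trans_tf=trans_tf)
    extra = None
    if trans_tf is not None:
        targets = edges.loc[edges["tf"] == trans_tf, "target"]
        extra = pd.DataFrame(
            {
                "gene": targets,
                "inversion": cfg.trans_inversion,
                "d": cfg.trans_d,
            }
        )
    expr, truth = make_expression(design, genome, cfg, seed, extra_effects=extra)
    snps, truth_r = make_genotypes(design, genome, cfg, seed)
    truth.snp_target_r = truth_r
    truth.tf_genes = sorted(set(edges["tf"]))
    truth.trans_tf = trans_tf
    return Bundle(
        config=cfg,
        design=design,
        genome=genome,
        snps=snps,
        expression=expr,
        tf_edges=edges,
        truth=truth,
    )


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["arms"] = [list(a) for a in cfg.arms]
    d["inversions"] = [list(i) for i in cfg.inversions]
    d["gene_length_dist"] = list(cfg.gene_length_dist)
    d["maf_range"] = list(cfg.maf_range)
    d["planted_effects"] = [list(p) for p in cfg.planted_effects]
    return d
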