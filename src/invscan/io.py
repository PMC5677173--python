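"""File formats, run manifest and the full-pipeline orchestration.

TSV is the canonical interchange; genotypes are also accepted as a
minimal VCF 4.2 dialect (diploid homozygous calls, inbred lines). BED is
0-based half-open on disk and converted to 1-based inclusive intervals in
memory. ``run_all`` chains the stages (ANOVA scan -> IAL -> LD scan ->
enrichment / genome structure / co-expression) under a single manifest
with per-stage seeds, and every output table carries a provenance header.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    ExpressionMatrix,
    Gene,
    InputError,
    Inversion,
    MISSING,
    SnpTable,
    StudyDesign,
)

log = logging.getLogger("invscan")


def setup_logging(outdir: Path | None = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(outdir / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# writers


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, params: str = "") -> None:
    """TSV with a one-line provenance header comment."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# invscan {__version__} stage={stage} {params}\n")
        df.to_csv(fh, sep="\t", index=True)


def write_design(design: StudyDesign, directory: Path) -> None:
    design.individuals.to_csv(directory / "design.tsv", sep="\t", index=False)
    design.karyotypes.to_csv(directory / "karyotypes.tsv", sep="\t")


def read_design(directory: Path) -> StudyDesign:
    ind = pd.read_csv(directory / "design.tsv", sep="\t", dtype=str)
    kary = pd.read_csv(directory / "karyotypes.tsv", sep="\t", index_col=0)
    return StudyDesign(individuals=ind, karyotypes=kary)


def write_expression(expr: ExpressionMatrix, directory: Path) -> None:
    expr.values.to_csv(directory / "expression.tsv", sep="\t")
    expr.probe_map.rename("gene").to_csv(directory / "probe_map.tsv", sep="\t")


def read_expression(directory: Path) -> ExpressionMatrix:
    values = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    pm = pd.read_csv(directory / "probe_map.tsv", sep="\t", index_col=0)["gene"]
    return ExpressionMatrix(values=values, probe_map=pm)


def write_genes_bed(genes: list[Gene], path: Path) -> None:
    """BED4: 0-based half-open on disk."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.arm}\t{g.start - 1}\t{g.end}\t{g.gene_id}\n")


def read_genes_bed(path: Path) -> list[Gene]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}:{lineno}: BED4 record expected")
            arm, start0, end, name = parts[:4]
            genes.append(Gene(gene_id=name, arm=arm, start=int(start0) + 1,
                              end=int(end)))
    return genes


def write_inversions(inversions: list[Inversion], path: Path) -> None:
    pd.DataFrame(
        [(i.name, i.arm, i.proximal, i.distal) for i in inversions],
        columns=["name", "arm", "proximal", "distal"],
    ).to_csv(path, sep="\t", index=False)


def read_inversions(path: Path) -> list[Inversion]:
    df = pd.read_csv(path, sep="\t")
    return [
        Inversion(r["name"], r["arm"], int(r["proximal"]), int(r["distal"]))
        for _, r in df.iterrows()
    ]


def write_genotypes_vcf(snps: SnpTable, path: Path) -> None:
    """Minimal VCF 4.2: inbred lines as homozygous diploid GT calls."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for arm in dict.fromkeys(snps.snps["arm"]):
            fh.write(f"##contig=<ID={arm}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(snps.lines)
            + "\n"
        )
        code = {0: "0/0", 1: "1/1", MISSING: "./."}
        for j in range(len(snps.snps)):
            row = snps.snps.iloc[j]
            gts = "\t".join(code[int(c)] for c in snps.calls[:, j])
            fh.write(
                f"{row['arm']}\t{row['pos']}\t{row['snp_id']}\tA\tT\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: Path) -> SnpTable:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    lines = list(vcf.samples)
    snp_rows, cols = [], []
    for k, v in enumerate(vcf):
        snp_rows.append((v.ID or f"snp{k}", v.CHROM, v.POS))
        col = np.full(len(lines), MISSING, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a = g[0]
            if a >= 0:
                col[i] = 1 if a > 0 else 0
        cols.append(col)
    if not cols:
        raise InputError(f"{path}: no variant records")
    return SnpTable(
        lines=lines,
        snps=pd.DataFrame(snp_rows, columns=["snp_id", "arm", "pos"]),
        calls=np.column_stack(cols),
    )


def write_genotypes_tsv(snps: SnpTable, path: Path) -> None:
    df = pd.DataFrame(
        snps.calls.T, columns=snps.lines, index=snps.snps["snp_id"]
    )
    out = pd.concat([snps.snps.set_index("snp_id")[["arm", "pos"]], df], axis=1)
    out.to_csv(path, sep="\t")


def read_genotypes_tsv(path: Path) -> SnpTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lines = [c for c in df.columns if c not in ("arm", "pos")]
    return SnpTable(
        lines=lines,
        snps=pd.DataFrame(
            {
                "snp_id": df.index,
                "arm": df["arm"].to_numpy(),
                "pos": df["pos"].to_numpy(),
            }
        ),
        calls=df[lines].to_numpy(dtype=np.int8).T,
    )


def write_bundle(bundle, directory: Path, vcf: bool = True) -> None:
    """Persist a synthetic bundle as the flat-file study inputs."""
    from .synthdata import config_to_dict

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_design(bundle.design, directory)
    write_expression(bundle.expression, directory)
    write_genes_bed(bundle.genome.genes, directory / "genes.bed")
    write_inversions(bundle.genome.inversions, directory / "inversions.tsv")
    if vcf:
        write_genotypes_vcf(bundle.snps, directory / "genotypes.vcf")
    else:
        write_genotypes_tsv(bundle.snps, directory / "genotypes.tsv")
    bundle.tf_edges.to_csv(directory / "tf_edges.tsv", sep="\t", index=False)
    bundle.truth.modules.rename("module").to_csv(
        directory / "modules.tsv", sep="\t", index_label="gene"
    )
    bundle.truth.effects.to_csv(directory / "truth.tsv", sep="\t", index=False)
    if bundle.truth.snp_target_r is not None and len(bundle.truth.snp_target_r):
        bundle.truth.snp_target_r.to_csv(
            directory / "truth_snp_r.tsv", sep="\t", index=False
        )
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(config_to_dict(bundle.config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# manifest and bundle loading


@dataclass
class RunManifest:
    """Everything a full run needs: input paths, parameters, seeds."""

    input_dir: str
    output_dir: str
    genotype_format: str = "vcf"  # or "tsv"
    inversions: list[str] | None = None
    anova_perms: int = 10_000
    q_threshold: float = 0.05
    ld_min_n: int = 60
    ld_min_maf: float = 0.10
    ld_alpha: float = 0.05
    bonferroni_universe: str = "all"
    cluster_samples: int = 100_000
    occupancy_perms: int = 100_000
    flank: int = 1_000_000
    per_tail_alpha: float = 0.025
    seeds: dict[str, int] = field(
        default_factory=lambda: {"anova": 1, "cluster": 2, "occupancy": 3,
                                 "correlation": 4}
    )

    def __post_init__(self) -> None:
        if self.anova_perms < 1:
            raise InputError("anova_perms must be >= 1")
        if self.cluster_samples < 1 or self.occupancy_perms < 1:
            raise InputError("permutation sample counts must be >= 1")
        for stage in ("anova", "cluster", "occupancy", "correlation"):
            if stage not in self.seeds:
                raise InputError(f"manifest is missing a seed for stage {stage!r}")

    @classmethod
    def from_yaml(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path: Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class LoadedBundle:
    design: StudyDesign
    expression: ExpressionMatrix
    snps: SnpTable
    genes: list[Gene]
    inversions: list[Inversion]
    tf_edges: pd.DataFrame | None
    modules: pd.Series | None
    n_dropped_individuals: int = 0


def load_inputs(manifest: RunManifest) -> LoadedBundle:
    """Read and cross-validate the full input bundle.

    Individuals whose line lacks a karyotype call are dropped with a
    logged count (mirroring exclusion of lines with conflicting or
    heterozygous calls upstream of this pipeline); expression individuals
    absent from the design are an error.
    """
    d = Path(manifest.input_dir)
    # reconcile before constructing the validated design object: individuals
    # from lines without karyotype calls are dropped, not fatal
    ind = pd.read_csv(d / "design.tsv", sep="\t", dtype=str)
    kary = pd.read_csv(d / "karyotypes.tsv", sep="\t", index_col=0)
    keep = ind["line"].isin(set(kary.index))
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.warning(
            "dropping %d individuals from lines without karyotype calls",
            n_dropped,
        )
        ind = ind[keep].reset_index(drop=True)
    design = StudyDesign(individuals=ind, karyotypes=kary)
    expr = read_expression(d)
    genes = read_genes_bed(d / "genes.bed")
    inversions = read_inversions(d / "inversions.tsv")
    if manifest.genotype_format == "vcf":
        snps = read_genotypes_vcf(d / "genotypes.vcf")
    else:
        snps = read_genotypes_tsv(d / "genotypes.tsv")
    edges_path = d / "tf_edges.tsv"
    edges = pd.read_csv(edges_path, sep="\t") if edges_path.exists() else None
    modules_path = d / "modules.tsv"
    modules = (
        pd.read_csv(modules_path, sep="\t", index_col=0)["module"]
        if modules_path.exists()
        else None
    )

    missing = set(expr.values.index) - set(design.individuals["individual"])
    if missing:
        log.warning(
            "dropping %d expression individuals absent from the design", len(missing)
        )
        expr = ExpressionMatrix(
            values=expr.values.drop(index=sorted(missing)), probe_map=expr.probe_map
        )
    gene_ids = {g.gene_id for g in genes}
    unmapped = set(expr.probe_map) - gene_ids
    if unmapped:
        log.warning("%d probes map to genes absent from the BED", len(unmapped))
    return LoadedBundle(
        design=design,
        expression=expr,
        snps=snps,
        genes=genes,
        inversions=inversions,
        tf_edges=edges,
        modules=modules,
        n_dropped_individuals=n_dropped,
    )


# ---------------------------------------------------------------------------
# orchestration


def run_all(manifest: RunManifest) -> Path:
    """Execute every stage in dependency order; returns the output dir."""
    from . import anova, coexpr, enrich, ldscan, structure

    outdir = Path(manifest.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir)
    manifest.to_yaml(outdir / "manifest.yaml")
    bundle = load_inputs(manifest)
    inv_names = manifest.inversions or [i.name for i in bundle.inversions]
    inv_defs = {i.name: i for i in bundle.inversions}
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    summary: dict = {"version": __version__, "stages": {}}

    # --- stage 1: per-probe ANOVA + permutation P + q + IAL
    log.info("anova scan: %d probes, B=%d", len(bundle.expression.probes),
             manifest.anova_perms)
    scan = anova.anova_scan(
        bundle.expression,
        bundle.design,
        B=manifest.anova_perms,
        seed=manifest.seeds["anova"],
        q_threshold=manifest.q_threshold,
        inversions=inv_names,
    )
    _write_tsv(scan["results"], outdir / "anova_results.tsv", "anova",
               f"B={manifest.anova_perms} seed={manifest.seeds['anova']} "
               f"q<{manifest.q_threshold}")
    ial_genes: dict[str, set[str]] = {}
    for inv in inv_names:
        tab = anova.call_ial(scan["results"], inv, manifest.q_threshold)
        safe = inv.replace("(", "").replace(")", "").replace("/", "_")
        _write_tsv(tab, outdir / f"ial_{safe}.tsv", "anova",
                   f"inversion={inv} q<{manifest.q_threshold}")
        ial_genes[inv] = bundle.expression.genes_for(tab.index)
    summary["stages"]["anova"] = {
        "B": manifest.anova_perms,
        "seed": manifest.seeds["anova"],
        "n_probes": len(bundle.expression.probes),
        "n_excluded_constant": scan["n_excluded_constant"],
        "dropped_terms": scan["dropped_terms"],
        "n_ial": {inv: len(scan["ial"][inv]) for inv in scan["ial"]},
    }

    # --- stage 2: SNP-inversion LD per arm, genes in LD
    kary_panel = bundle.design.karyotypes
    genes_ld: dict[str, set[str]] = {}
    ld_frames = []
    for inv in inv_names:
        kvec = kary_panel[inv]
        sig_frames = []
        for arm in dict.fromkeys(bundle.snps.snps["arm"]):
            arm_tab = ldscan.ld_scan_arm(
                bundle.snps.on_arm(arm),
                kvec,
                min_n=manifest.ld_min_n,
                min_maf=manifest.ld_min_maf,
                alpha=manifest.ld_alpha,
                bonferroni_universe=manifest.bonferroni_universe,
            )
            arm_tab.insert(0, "inversion", inv)
            ld_frames.append(arm_tab)
            sig_frames.append(arm_tab[arm_tab["significant"]])
        sig = pd.concat(sig_frames, ignore_index=True)
        genes_ld[inv] = ldscan.genes_in_ld(sig, bundle.genes)
    ld_all = pd.concat(ld_frames, ignore_index=True)
    _write_tsv(ld_all, outdir / "ld_records.tsv", "ld",
               f"min_n={manifest.ld_min_n} min_maf={manifest.ld_min_maf}")
    _write_tsv(ld_all[ld_all["significant"]].reset_index(drop=True),
               outdir / "significant_snps.tsv", "ld", "")
    pd.DataFrame(
        [(inv, g) for inv in inv_names for g in sorted(genes_ld[inv])],
        columns=["inversion", "gene"],
    ).to_csv(outdir / "genes_in_ld.tsv", sep="\t", index=False)
    summary["stages"]["ld"] = {
        "n_significant": {
            inv: int(((ld_all["inversion"] == inv) & ld_all["significant"]).sum())
            for inv in inv_names
        },
        "n_genes_in_ld": {inv: len(genes_ld[inv]) for inv in inv_names},
    }

    # --- stage 3: enrichment
    expr_genes = set(bundle.expression.probe_map)
    universe = expr_genes & set(gene_by_id)
    records = []
    for inv in inv_names:
        records.append(
            enrich.ial_ld_enrichment(
                universe,
                ial_genes[inv] & universe,
                genes_ld[inv] & universe,
                label=f"IAL x genes-in-LD [{inv}]",
                per_tail_alpha=manifest.per_tail_alpha,
            )
        )
    if bundle.tf_edges is not None:
        tf_universe = universe & (
            set(bundle.tf_edges["tf"]) | set(bundle.tf_edges["target"])
        )
        tf_gene_objs = [
            gene_by_id[tf] for tf in set(bundle.tf_edges["tf"]) if tf in gene_by_id
        ]
        for inv in inv_names:
            sig_inv = ld_all[(ld_all["inversion"] == inv) & ld_all["significant"]]
            sig_tfs = ldscan.genes_in_ld(sig_inv, tf_gene_objs)
            try:
                records.append(
                    enrich.tf_target_enrichment(
                        bundle.tf_edges,
                        sig_tfs,
                        ial_genes[inv],
                        restrict_to=tf_universe,
                        label=f"IAL x TF-targets [{inv}]",
                        per_tail_alpha=manifest.per_tail_alpha,
                    )
                )
            except InputError as exc:
                log.warning("TF enrichment for %s skipped: %s", inv, exc)
    _write_tsv(enrich.records_frame(records), outdir / "enrichment.tsv",
               "enrich", f"per_tail_alpha={manifest.per_tail_alpha}")

    # --- stage 4: genome structure
    loc = structure.location_table(bundle.genes, bundle.inversions, ial_genes,
                                   flank=manifest.flank)
    _write_tsv(loc, outdir / "locations.tsv", "structure",
               f"flank={manifest.flank}")
    bp = structure.breakpoint_report(bundle.genes, bundle.inversions, ial_genes)
    _write_tsv(bp, outdir / "breakpoints.tsv", "structure", "")
    clust = structure.clustering_scan(
        bundle.genes, ial_genes,
        n_samples=manifest.cluster_samples, seed=manifest.seeds["cluster"],
    )
    _write_tsv(clust, outdir / "clustering.tsv", "structure",
               f"samples={manifest.cluster_samples} "
               f"seed={manifest.seeds['cluster']} "
               "verdict: CV above null CI = 'more clustered'")

    # --- stage 5: co-expression controls
    line_means = bundle.design.line_means(bundle.expression.values)
    corr_rows = []
    occ_rows = []
    for inv in inv_names:
        ial_probes = {
            p for p in bundle.expression.probes
            if bundle.expression.probe_map[p] in ial_genes[inv]
        }
        try:
            cs = coexpr.correlation_summary(
                line_means, ial_probes, seed=manifest.seeds["correlation"]
            )
            corr_rows.append(
                {
                    "inversion": inv,
                    "mean_ial_ial": cs.mean_ial_ial,
                    "mean_ial_other": cs.mean_ial_other,
                    "mean_genome": cs.mean_genome,
                    "n_pairs_ial_ial": cs.n_pairs_ial_ial,
                    "n_pairs_ial_other": cs.n_pairs_ial_other,
                    "n_pairs_genome": cs.n_pairs_genome,
                    "mode": cs.mode,
                }
            )
        except InputError as exc:
            log.warning("correlation summary for %s skipped: %s", inv, exc)
        if bundle.modules is not None and ial_genes[inv]:
            assigned = set(bundle.modules.index)
            members = ial_genes[inv] & assigned
            if members:
                on = coexpr.occupancy_null(
                    bundle.modules, members,
                    n_perm=manifest.occupancy_perms,
                    seed=manifest.seeds["occupancy"],
                )
                occ_rows.append(
                    {
                        "inversion": inv,
                        "observed": on.observed,
                        "ci_2.5": on.ci_low,
                        "ci_97.5": on.ci_high,
                        "n_perm": on.n_perm,
                        "verdict": on.verdict,
                    }
                )
    if corr_rows:
        _write_tsv(pd.DataFrame(corr_rows).set_index("inversion"),
                   outdir / "correlation_summary.tsv", "coexpr",
                   f"seed={manifest.seeds['correlation']}")
    if occ_rows:
        _write_tsv(pd.DataFrame(occ_rows).set_index("inversion"),
                   outdir / "occupancy.tsv", "coexpr",
                   f"perms={manifest.occupancy_perms} "
                   f"seed={manifest.seeds['occupancy']}")

    summary["n_dropped_individuals"] = bundle.n_dropped_individuals
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    log.info("run complete: %s", outdir)
    return outdir
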