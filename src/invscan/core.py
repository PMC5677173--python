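"""Shared domain objects for the inversion-expression scan.

Coordinate convention: gene and inversion intervals are 1-based inclusive
in memory. On-disk BED is 0-based half-open and is converted on read/write
(see :mod:`invscan.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # sentinel for missing genotype / karyotype calls


class ConfigError(ValueError):
    """Raised for inconsistent simulation or run configuration."""


class InputError(ValueError):
    """Raised for malformed or mutually inconsistent input files."""


@dataclass(frozen=True)
class Gene:
    """An annotated gene interval (1-based inclusive, ``start <= end``)."""

    gene_id: str
    arm: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise InputError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Inversion:
    """A named paracentric inversion with proximal < distal breakpoints."""

    name: str
    arm: str
    proximal: int
    distal: int

    def __post_init__(self) -> None:
        if not self.proximal < self.distal:
            raise InputError(
                f"inversion {self.name}: proximal breakpoint must precede distal"
            )


@dataclass
class StudyDesign:
    """Individuals mapped to line and sex, with line-level karyotypes.

    Parameters
    ----------
    individuals
        One row per expression individual with columns
        ``individual`` (unique id), ``line`` and ``sex`` (``"M"``/``"F"``).
    karyotypes
        Line-by-inversion table of 0 (standard) / 1 (inverted) calls,
        indexed by line id, one column per inversion name. Karyotype is a
        property of the line: every individual of a line shares it.
    """

    individuals: pd.DataFrame
    karyotypes: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"individual", "line", "sex"}
        if not req.issubset(self.individuals.columns):
            raise InputError(f"design table needs columns {sorted(req)}")
        if self.individuals["individual"].duplicated().any():
            dup = self.individuals["individual"][
                self.individuals["individual"].duplicated()
            ].iloc[0]
            raise InputError(f"duplicate individual id {dup!r} in design")
        missing = set(self.individuals["line"]) - set(self.karyotypes.index)
        if missing:
            raise InputError(
                f"lines without karyotype calls: {sorted(missing)[:5]} ..."
                if len(missing) > 5
                else f"lines without karyotype calls: {sorted(missing)}"
            )

    @property
    def inversions(self) -> list[str]:
        return list(self.karyotypes.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def lines(self) -> list[str]:
        return list(self.karyotypes.index)

    def individual_karyotype(self, inversion: str) -> np.ndarray:
        """Per-individual 0/1 inversion state, inherited from the line."""
        return (
            self.karyotypes[inversion]
            .reindex(self.individuals["line"])
            .to_numpy(dtype=float)
        )

    def line_means(self, values: pd.DataFrame) -> pd.DataFrame:
        """Average an individuals-by-probes frame within line."""
        joined = values.join(
            self.individuals.set_index("individual")["line"], how="inner"
        )
        return joined.groupby("line").mean()


@dataclass
class ExpressionMatrix:
    """Individuals-by-probes log-scale intensities plus a probe→gene map."""

    values: pd.DataFrame  # index: individual, columns: probe id
    probe_map: pd.Series  # probe id -> gene id

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise InputError("expression matrix contains non-finite values")
        unmapped = set(self.values.columns) - set(self.probe_map.index)
        if unmapped:
            raise InputError(f"probes without gene mapping: {sorted(unmapped)[:5]}")

    @property
    def probes(self) -> list[str]:
        return list(self.values.columns)

    def genes_for(self, probe_ids) -> set[str]:
        return set(self.probe_map.loc[list(probe_ids)])


@dataclass
class SnpTable:
    """Per-line diallelic SNP calls.

    ``calls`` is lines-by-SNPs int8 with 0 = major allele, 1 = minor
    allele, :data:`MISSING` = no call. ``snps`` carries ``snp_id``,
    ``arm`` and 1-based ``pos`` per column of ``calls``.
    """

    lines: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.lines), len(self.snps)):
            raise InputError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.snps)} SNPs"
            )

    def on_arm(self, arm: str) -> "SnpTable":
        mask = (self.snps["arm"] == arm).to_numpy()
        return SnpTable(self.lines, self.snps.loc[mask].reset_index(drop=True),
                        self.calls[:, mask])


@dataclass
class GroundTruth:
    """Planted structure of a synthetic bundle (for validation only)."""

    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene, inversion, d
    modules: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))
    snp_target_r: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: snp_id, inversion, target_r
    tf_genes: list[str] = field(default_factory=list)
    trans_tf: str | None = None
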