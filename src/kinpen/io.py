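"""Readers and writers for the pipeline's on-disk formats.

Formats: VCF (read via cyvcf2, written as plain biallelic-SNP text),
a PLINK-``.raw``-style dosage TSV (first column sample id, header row of
variant ids, cells 0/1/2/NA), PED pedigree text, a square whitespace-
delimited kinship matrix with a sidecar ``.ids`` file (EMMAX-kinf-style
dialect), phenotype/covariate TSV, and the screening/panel/result TSVs.
All ids are treated as opaque strings; no genome-position arithmetic is
performed anywhere in the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import COVARIATE_COLUMNS, GenotypeMatrix, KinshipMatrix, PedigreeSet

logger = logging.getLogger(__name__)

PHENOTYPE_COLUMNS = ("sample_id", "sbp") + COVARIATE_COLUMNS


# ---------------------------------------------------------------------------
# dosage TSV
# ---------------------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(G.dosages, index=G.sample_ids, columns=G.variant_ids)
    df.index.name = "sample_id"
    out = df.map(lambda v: "NA" if np.isnan(v) else f"{int(v)}")
    out.to_csv(path, sep="\t")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    return GenotypeMatrix.from_dosages(
        df.to_numpy(dtype=float),
        [str(s) for s in df.index],
        [str(v) for v in df.columns],
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Dosages re-expanded to unphased GT calls on one synthetic contig.

    The ALT allele is, by construction of the dosage matrix, the minor
    allele, so a round trip through ``read_vcf`` reproduces the dosages.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, vid in enumerate(G.variant_ids):
            calls = "\t".join(
                "./." if np.isnan(d) else _GT[d] for d in G.dosages[:, j]
            )
            fh.write(f"1\t{j + 1}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP records into a minor-allele dosage matrix.

    ALT-allele counts are folded per variant so the stored dosage counts
    the minor allele; missing calls are preserved; records with more than
    one ALT allele are skipped with a count logged.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    n_multi = 0
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        gt = rec.gt_types.astype(float)
        dos = np.where(gt == 3, 2.0, gt)
        dos[gt == 2] = np.nan
        rows.append(dos)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"var{i + 1}")
    if n_multi:
        logger.info("skipped %d non-biallelic VCF records", n_multi)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    D = np.stack(rows, axis=1)
    # fold columns where ALT is the major allele
    with np.errstate(invalid="ignore"):
        p = np.nanmean(D, axis=0) / 2.0
    flip = p > 0.5
    D[:, flip] = 2.0 - D[:, flip]
    return GenotypeMatrix.from_dosages(D, samples, ids)


# ---------------------------------------------------------------------------
# PED
# ---------------------------------------------------------------------------

def write_ped(peds: PedigreeSet, path: str | Path) -> None:
    """Six-column PED text (family, id, father, mother, sex, phenotype=0)."""
    with open(path, "w") as fh:
        for m in peds.members:
            fh.write(
                f"{m.family_id}\t{m.id}\t{m.father or '0'}\t"
                f"{m.mother or '0'}\t{m.sex}\t0\n"
            )


# ---------------------------------------------------------------------------
# kinship matrix text
# ---------------------------------------------------------------------------

def write_kinship(K: KinshipMatrix, path: str | Path) -> None:
    """Square whitespace-delimited matrix; sample ids in a sidecar
    ``<path>.ids`` file, one per line."""
    np.savetxt(path, K.values, fmt="%.10g")
    Path(f"{path}.ids").write_text("\n".join(K.sample_ids) + "\n")


def read_kinship(
    path: str | Path, ids_path: str | Path | None = None
) -> KinshipMatrix:
    vals = np.loadtxt(path)
    ids_path = ids_path or f"{path}.ids"
    if Path(ids_path).exists():
        ids = Path(ids_path).read_text().split()
    else:
        ids = [f"S{i + 1}" for i in range(vals.shape[0])]
        logger.warning("no id sidecar for %s; using positional ids", path)
    return KinshipMatrix(vals, ids)


# ---------------------------------------------------------------------------
# phenotype / covariate table
# ---------------------------------------------------------------------------

def write_phenotypes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str | Path, sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """TSV with sample_id, sbp and the four covariates; extra columns are
    ignored with a log entry. When ``sample_ids`` is given the table is
    aligned to that order and unmatched ids on either side are reported."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file is missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in PHENOTYPE_COLUMNS]
    if extra:
        logger.info("ignoring extra phenotype columns %s", extra)
        df = df.drop(columns=extra)
    for col in PHENOTYPE_COLUMNS[1:]:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r}, "
                f"row {row + 2} of {path}"
            )
        df[col] = vals
    if sample_ids is not None:
        have = set(df["sample_id"])
        unmatched = [s for s in sample_ids if s not in have]
        if unmatched:
            raise ValueError(
                f"{len(unmatched)} genotyped samples missing from phenotype "
                f"file (first: {unmatched[:5]})"
            )
        dropped = have - set(sample_ids)
        if dropped:
            logger.warning(
                "%d phenotype rows have no genotypes and are excluded",
                len(dropped),
            )
        df = df.set_index("sample_id").loc[list(sample_ids)].reset_index()
    return df


# ---------------------------------------------------------------------------
# screening / panel / results
# ---------------------------------------------------------------------------

def write_screening(res, path: str | Path) -> None:
    res.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_panel(panel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tvariant\n")
        for v in panel.cv_ids:
            fh.write(f"CV\t{v}\n")
        for v in panel.rv_ids:
            fh.write(f"RV\t{v}\n")


def read_panel(path: str | Path):
    from .screen import SnpPanel

    df = pd.read_csv(path, sep="\t")
    return SnpPanel(
        cv_ids=df.loc[df["class"] == "CV", "variant"].tolist(),
        rv_ids=df.loc[df["class"] == "RV", "variant"].tolist(),
    )


def write_results(table, out_dir: str | Path) -> None:
    """Long records and the median pivot as TSV in ``out_dir``."""
    out = Path(out_dir)
    table.long.to_csv(out / "results_long.tsv", sep="\t", index=False)
    table.median_pivot().to_csv(out / "median_pmse.tsv", sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end study configuration (YAML-serializable).

    Defaults mirror the emulated study: 20 pedigrees of 21-76 members,
    a CV:RV variant mix, 5% MAF class boundary, 10% missingness exclusion,
    screening panels per class, and the repeated three-way-split scenario
    study.
    """

    out_dir: str = "kinpen_run"
    seed: int = 1
    # simulation
    n_families: int = 20
    family_size_range: tuple[int, int] = (21, 76)
    n_generations: int = 3
    n_cv_variants: int = 1200
    n_rv_variants: int = 1200
    missing_rate: float = 0.0
    n_causal_cv: int = 8
    n_causal_rv: int = 15
    sigma_g2: float = 40.0
    sigma_r2: float = 60.0
    # QC / screening
    max_missing_fraction: float = 0.10
    n_cv_panel: int = 1000
    n_rv_panel: int = 1000
    screen_on_decorrelated: bool = False
    # model
    vc_method: str = "REML"
    # study
    methods: tuple[str, ...] = ("ols", "scad", "lasso", "enet", "ridge", "tlp")
    base_sizes: tuple[int, ...] = (10, 100, 1000)
    added_sizes: tuple[int, ...] = (1, 10, 100, 1000)
    n_replicates: int = 100
    enet_alpha: float = 0.5
    write_vcf: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.methods) - {
            "ols", "scad", "lasso", "enet", "ridge", "tlp"
        }
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    for key in ("family_size_range", "methods", "base_sizes", "added_sizes"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in cfg.__dict__.items()
    }
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
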