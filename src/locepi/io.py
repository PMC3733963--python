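"""Reading and writing PLINK-style text genotypes and phenotype tables.

Genotypes travel as whitespace-delimited ``.ped``/``.map`` pairs with
alleles recoded ``A`` (major) / ``B`` (minor) and ``0 0`` for a missing
genotype, so the per-SNP minor-allele orientation fixed at simulation time
survives a round trip.  Phenotypes and covariates travel as a TSV with a
header (sample_id, trait, sex, age, centre, ...).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .synthetic_data import MISSING, GenotypeDataset

__all__ = ["write_plink_text", "read_plink_text", "write_pheno_tsv", "read_pheno_tsv"]

_ALLELE_PAIRS = {0: "A A", 1: "A B", 2: "B B", MISSING: "0 0"}


class PlinkParseError(ValueError):
    """Raised on a malformed .ped/.map line; names the offending line."""


def write_pheno_tsv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pheno_tsv(path: str) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t")
    if "sample_id" not in pheno.columns:
        raise PlinkParseError(f"{path}: phenotype TSV must have a sample_id column")
    pheno["sample_id"] = pheno["sample_id"].astype(str)
    return pheno


def write_plink_text(
    geno: GenotypeDataset,
    pheno: pd.DataFrame | None,
    directory: str,
    basename: str = "data",
) -> dict[str, str]:
    """Write ``.ped`` + ``.map`` (and ``.pheno.tsv`` if given) under ``directory``.

    ``.map`` columns: chromosome, SNP id, genetic distance (0), position.
    ``.ped`` columns: FID IID PAT MAT SEX PHENO then two alleles per SNP.
    Returns the paths written.  Output is deterministic for a fixed dataset.
    """
    if geno.n_samples == 0 or geno.n_snps == 0:
        raise ValueError("refusing to write an empty dataset")
    os.makedirs(directory, exist_ok=True)
    map_path = os.path.join(directory, basename + ".map")
    ped_path = os.path.join(directory, basename + ".ped")
    with open(map_path, "w") as fh:
        for row in geno.snp_map.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\n")

    sex = {}
    if pheno is not None and "sex" in pheno.columns:
        sex = dict(zip(pheno["sample_id"].astype(str), pheno["sex"]))
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(geno.sample_ids):
            # PLINK sex code: 1=male, 2=female, 0=unknown; our covariate is 0/1
            code = {0: 1, 1: 2}.get(sex.get(sid), 0)
            fields = [sid, sid, "0", "0", str(code), "-9"]
            fields.extend(_ALLELE_PAIRS[int(d)] for d in geno.dosages[i])
            fh.write(" ".join(fields) + "\n")

    out = {"map": map_path, "ped": ped_path}
    if pheno is not None:
        pheno_path = os.path.join(directory, basename + ".pheno.tsv")
        write_pheno_tsv(pheno, pheno_path)
        out["pheno"] = pheno_path
    return out


def _read_map(map_path: str) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            try:
                rows.append((int(parts[0]), parts[1], int(parts[3])))
            except ValueError as exc:
                raise PlinkParseError(f"{map_path}:{ln}: {exc}") from exc
    if not rows:
        raise PlinkParseError(f"{map_path}: no SNPs found")
    return pd.DataFrame(rows, columns=["chrom", "snp", "pos"])[["snp", "chrom", "pos"]]


def read_plink_text(directory: str, basename: str = "data") -> tuple[GenotypeDataset, pd.DataFrame | None]:
    """Read ``.ped``/``.map`` written by :func:`write_plink_text`.

    The A/B allele recoding is interpreted as B = minor, so dosages come
    back as minor-allele counts; the round trip is lossless including
    missing genotypes.  Returns (genotypes, phenotype table or None).
    """
    map_path = os.path.join(directory, basename + ".map")
    ped_path = os.path.join(directory, basename + ".ped")
    snp_map = _read_map(map_path)
    m = len(snp_map)

    sample_ids: list[str] = []
    dosage_rows: list[np.ndarray] = []
    code = {("A", "A"): 0, ("A", "B"): 1, ("B", "A"): 1, ("B", "B"): 2, ("0", "0"): MISSING}
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise PlinkParseError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            sample_ids.append(parts[1])
            row = np.empty(m, dtype=np.int8)
            for k in range(m):
                pair = (parts[6 + 2 * k], parts[7 + 2 * k])
                try:
                    row[k] = code[pair]
                except KeyError:
                    raise PlinkParseError(
                        f"{ped_path}:{ln}: unknown allele pair {pair!r} at SNP {k + 1}"
                    ) from None
            dosage_rows.append(row)
    if not dosage_rows:
        raise PlinkParseError(f"{ped_path}: no samples found")
    geno = GenotypeDataset(
        dosages=np.vstack(dosage_rows), snp_map=snp_map, sample_ids=sample_ids
    )
    pheno_path = os.path.join(directory, basename + ".pheno.tsv")
    pheno = read_pheno_tsv(pheno_path) if os.path.exists(pheno_path) else None
    return geno, pheno
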