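"""Genotype and phenotype containers plus PLINK 1 binary and CSV readers/writers.

Genotype coding convention
--------------------------
Codes count copies of the .bim **allele1** (the A1-dosage convention, PLINK's
default minor-allele column). The sign of every estimated SNP effect depends on
this choice: an effect of +0.5 means each extra copy of A1 raises the trait by
0.5 units. Missing genotypes are stored as -1 inside the integer matrix and
exposed through :attr:`GenotypeMatrix.missing_mask`.

Coordinates are 1-based inclusive throughout (PLINK/GFF convention); BED-style
gene annotation is converted on read (see :func:`read_gene_bed`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

TRAITS = ("tender", "juicy", "flavor", "overall", "mq4")

PHENOTYPE_COLUMNS = (
    "animal_id",
    "tender",
    "juicy",
    "flavor",
    "overall",
    "mq4",
    "cg",
    "days_aged",
    "carcass_weight",
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK v1 SNP-major

# 2-bit PLINK codes -> A1 dosage (00=hom A1, 01=missing, 10=het, 11=hom A2)
_PLINK_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


class PlinkFormatError(ValueError):
    """The .bed magic bytes or storage mode are not PLINK v1 SNP-major."""


class PlinkConsistencyError(ValueError):
    """The .bed payload size disagrees with the .bim/.fam dimensions."""


class PhenotypeSchemaError(ValueError):
    """A required phenotype column is absent."""


@dataclass
class GenotypeMatrix:
    """Animals x SNPs A1-dosage matrix with per-SNP metadata.

    Parameters
    ----------
    codes
        ``(n_animals, n_snps)`` int8 array with entries in {0, 1, 2} and
        ``MISSING`` (-1) for no-calls.
    snp_meta
        DataFrame with columns ``chrom, snp_id, cm, pos, a1, a2`` (``pos`` is
        1-based base pairs).
    animal_ids
        Unique identifiers in .fam order; the reader never reorders animals.
    """

    codes: np.ndarray
    snp_meta: pd.DataFrame
    animal_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D animals x SNPs matrix")
        n, m = self.codes.shape
        if len(self.animal_ids) != n:
            raise PlinkConsistencyError(
                f"{len(self.animal_ids)} animal ids for {n} genotype rows"
            )
        if len(self.snp_meta) != m:
            raise PlinkConsistencyError(
                f"{len(self.snp_meta)} SNP metadata rows for {m} genotype columns"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2} or missing (-1)")
        if len(set(self.animal_ids)) != n:
            raise ValueError("animal ids must be unique")
        if self.snp_meta["snp_id"].duplicated().any():
            raise ValueError("snp ids must be unique")

    @property
    def n_animals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def dosage(self, dtype=np.float64) -> np.ndarray:
        """Codes as floats with missing entries as NaN."""
        out = self.codes.astype(dtype)
        out[self.missing_mask] = np.nan
        return out

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            codes=self.codes[:, keep],
            snp_meta=self.snp_meta.iloc[keep].reset_index(drop=True),
            animal_ids=list(self.animal_ids),
        )

    def subset_animals(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            codes=self.codes[keep, :],
            snp_meta=self.snp_meta,
            animal_ids=[self.animal_ids[i] for i in keep],
        )


@dataclass
class PhenotypeTable:
    """Per-animal trait scores (0-100 sensory scale) and fixed-effect covariates.

    ``data`` holds one row per animal with columns ``animal_id``, the five
    trait scores (``tender, juicy, flavor, overall, mq4``), the contemporary
    group label ``cg``, ``days_aged`` (days) and ``carcass_weight`` (kg).
    Rows with missing trait values are retained; training for a given trait
    drops only the animals missing that trait.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing_cols = [c for c in PHENOTYPE_COLUMNS if c not in self.data.columns]
        if missing_cols:
            raise PhenotypeSchemaError(f"missing required columns: {missing_cols}")
        if self.data["animal_id"].duplicated().any():
            raise ValueError("every animal may appear at most once")
        cg = self.data["cg"].astype(str)
        if (cg.str.len() == 0).any() or self.data["cg"].isna().any():
            raise ValueError("cg must be non-empty for every phenotyped animal")

    @property
    def animal_ids(self) -> list[str]:
        return self.data["animal_id"].astype(str).tolist()

    def trait(self, name: str) -> np.ndarray:
        if name not in TRAITS:
            raise KeyError(f"unknown trait {name!r}; expected one of {TRAITS}")
        return self.data[name].to_numpy(dtype=float)

    def observed(self, trait: str) -> np.ndarray:
        """Boolean mask of animals with a recorded value for `trait`."""
        return np.isfinite(self.trait(trait))


# ---------------------------------------------------------------------------
# PLINK 1 binary
# ---------------------------------------------------------------------------

def read_plink(bed_path, bim_path=None, fam_path=None) -> GenotypeMatrix:
    """Read a PLINK 1 binary fileset into a :class:`GenotypeMatrix`.

    ``bim_path``/``fam_path`` default to the .bed path with swapped suffixes.
    Codes count A1 copies; output animal order equals .fam order.
    """
    bed_path = Path(bed_path)
    bim_path = Path(bim_path) if bim_path else bed_path.with_suffix(".bim")
    fam_path = Path(fam_path) if fam_path else bed_path.with_suffix(".fam")

    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )
    n, m = len(fam), len(bim)

    raw = Path(bed_path).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {raw[:3].hex()}; "
            "expected 6c1b01 (PLINK v1 SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_snp * m:
        raise PlinkConsistencyError(
            f"{bed_path}: payload of {payload.size} bytes does not match "
            f"{m} SNPs x {n} animals ({bytes_per_snp * m} bytes expected)"
        )

    blocks = payload.reshape(m, bytes_per_snp)
    # unpack the four 2-bit genotypes per byte, little-end first
    two_bit = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        two_bit[:, k::4] = (blocks >> (2 * k)) & 0b11
    codes = _PLINK_TO_DOSAGE[two_bit[:, :n]].T  # -> animals x SNPs

    return GenotypeMatrix(codes=codes, snp_meta=bim, animal_ids=fam["iid"].tolist())


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write .bed/.bim/.fam; round-trips bit-exactly with :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = geno.codes.shape

    bim = geno.snp_meta[["chrom", "snp_id", "cm", "pos", "a1", "a2"]]
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.animal_ids,
            "iid": geno.animal_ids,
            "father": "0",
            "mother": "0",
            "sex": "0",
            "pheno": "-9",
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    two_bit = np.empty((m, n), dtype=np.uint8)
    codes_t = geno.codes.T
    two_bit[codes_t == 2] = 0b00
    two_bit[codes_t == 1] = 0b10
    two_bit[codes_t == 0] = 0b11
    two_bit[codes_t == MISSING] = 0b01

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = two_bit
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Phenotype / covariate CSV
# ---------------------------------------------------------------------------

def read_phenotypes(csv_path) -> PhenotypeTable:
    """Read the phenotype/covariate CSV (header required, see PHENOTYPE_COLUMNS)."""
    df = pd.read_csv(csv_path, dtype={"animal_id": str, "cg": str})
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise PhenotypeSchemaError(
            f"{csv_path}: missing required columns {missing}; "
            f"expected header {','.join(PHENOTYPE_COLUMNS)}"
        )
    for col in TRAITS + ("days_aged", "carcass_weight"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return PhenotypeTable(data=df)


def write_phenotypes(table: PhenotypeTable, csv_path) -> None:
    Path(csv_path).parent.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# Gene annotation (BED / GFF3) for nearest-gene reports
# ---------------------------------------------------------------------------

def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into (chrom, start, end, gene).

    Output coordinates are 1-based inclusive; BED's half-open 0-based starts
    are shifted on read. GFF3 rows are filtered to type ``gene`` and the gene
    name is taken from the ``Name=`` or ``ID=`` attribute.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                name = attrs.get("Name", attrs.get("ID", f"{f[0]}:{f[3]}"))
                rows.append((f[0], int(f[3]), int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "gene"],
        dtype={"chrom": str, "gene": str},
    )
    df["start"] = df["start"] + 1  # BED 0-based half-open -> 1-based inclusive
    return df


def write_run_summary(path, **fields) -> None:
    """JSON run summary (seed, config hash, counts...) written by every driver."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, default=str)
        fh.write("\n")
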