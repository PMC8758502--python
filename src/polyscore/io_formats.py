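"""Reading, writing and hygiene of the standard genotype/score exchange formats.

The on-disk dialects are PLINK bed/bim/fam for genotypes (variant-major .bed,
hard calls only), tab-separated GWAS summary statistics, and tab-separated
scoring files modelled on the PGS Catalog column set (``rsID``, ``chr_name``,
``chr_position``, ``effect_allele``, ``other_allele``, ``effect_weight``).
In memory, genotypes are an ``n_samples x n_variants`` float dosage matrix
(``numpy.nan`` marks missing calls) carried next to a per-variant metadata
``pandas.DataFrame``; fractional dosages in [0, 2] are legal because imputed
data is the normal case, but only hard calls can round-trip through .bed.

Genotype hygiene implemented here: mean imputation of missing calls,
duplicate-variant resolution by imputation INFO score, and allele matching of
a scoring file against a genotype panel with strand-ambiguous (A/T, G/C)
variants excluded outright.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariantRecord",
    "GenotypeMatrix",
    "AlleleMatch",
    "FormatError",
    "IntegrityError",
    "read_genotypes",
    "write_genotypes",
    "mean_impute",
    "resolve_duplicates",
    "match_alleles",
    "read_scoring_file",
    "write_scoring_file",
    "read_sumstats",
    "write_sumstats",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Columns every variant-metadata frame carries, in this order.
VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2", "maf", "info", "missing_rate"]


class FormatError(ValueError):
    """A file does not conform to its declared dialect (e.g. bad .bed magic)."""


class IntegrityError(ValueError):
    """Files parse individually but disagree with each other (dimension mismatch)."""


@dataclasses.dataclass
class VariantRecord:
    """One biallelic SNP with its QC metadata.

    ``effect_allele`` is the counted (A1) allele: dosage is the number of
    copies of it.  ``maf`` is the minor allele frequency, ``info`` the
    imputation quality in [0, 1], ``missing_rate`` the fraction of samples
    without a call.
    """

    id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    maf: float = np.nan
    info: float = np.nan
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if np.isfinite(self.maf) and not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.id}: MAF {self.maf} outside [0, 0.5]")
        if np.isfinite(self.info) and not 0.0 <= self.info <= 1.0:
            raise ValueError(f"{self.id}: INFO {self.info} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(f"{self.id}: missing rate {self.missing_rate} outside [0, 1]")


@dataclasses.dataclass
class GenotypeMatrix:
    """Additive dosage matrix plus ordered variant metadata and sample ids.

    ``dosages`` is ``n_samples x n_variants`` float; missing calls are
    ``numpy.nan``.  Column ``j`` counts copies of ``variants.a1[j]``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise IntegrityError(
                f"{m} dosage columns but {len(self.variants)} variant records"
            )
        if len(self.sample_ids) != n:
            raise IntegrityError(
                f"{n} dosage rows but {len(self.sample_ids)} sample ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.variants.copy(),
            [self.sample_ids[i] for i in index],
        )

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {v: j for j, v in enumerate(self.variants["id"])}
        cols = [pos[i] for i in ids]
        return GenotypeMatrix(
            self.dosages[:, cols],
            self.variants.iloc[cols].reset_index(drop=True),
            list(self.sample_ids),
        )


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def read_genotypes(path_prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``.bed/.bim/.fam`` triplet (variant-major .bed).

    Dosage is the count of the .bim A1 allele; the 2-bit codes are
    ``00`` hom-A1 (dosage 2), ``10`` het (1), ``11`` hom-A2 (0), ``01``
    missing (NaN).  A sidecar ``<prefix>.variant_meta.tsv`` with columns
    ``id  maf  info  missing_rate`` is merged in when present, because .bim
    has no QC columns.
    """
    prefix = Path(path_prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if payload.size != bytes_per_variant * m:
        raise IntegrityError(
            f"{prefix}.bed payload is {payload.size} bytes; "
            f"{m} variants x {n} samples needs {bytes_per_variant * m}"
        )
    blocks = payload.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, sample-fastest within each variant block
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts) & 0b11  # m x bytes x 4
    codes = codes.reshape(m, -1)[:, :n]
    decode = np.array([2.0, np.nan, 1.0, 0.0])  # code 0,1,2,3 -> dosage of A1
    dosages = decode[codes].T  # n x m

    variants = bim[["id", "chrom", "pos", "a1", "a2"]].copy()
    meta_path = prefix.parent / (prefix.name + ".variant_meta.tsv")
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"id": str})
        variants = variants.merge(meta, on="id", how="left")
    for col in ("maf", "info", "missing_rate"):
        if col not in variants:
            variants[col] = np.nan
    if "missing_rate" in variants and variants["missing_rate"].isna().all():
        variants["missing_rate"] = np.isnan(dosages).mean(axis=0)
    return GenotypeMatrix(dosages, variants[VARIANT_COLUMNS], list(fam["iid"]))


def write_genotypes(g: GenotypeMatrix, path_prefix: str | Path) -> None:
    """Write ``.bed/.bim/.fam`` plus the QC sidecar TSV.

    Only hard calls round-trip: every non-missing dosage must be exactly
    0, 1 or 2.
    """
    prefix = Path(path_prefix)
    d = g.dosages
    observed = d[~np.isnan(d)]
    if not np.all(np.isin(observed, (0.0, 1.0, 2.0))):
        raise ValueError("bed format carries hard calls only (dosages in {0,1,2})")
    n, m = d.shape
    code = np.full(d.shape, 1, dtype=np.uint8)  # missing
    code[d == 2.0] = 0
    code[d == 1.0] = 2
    code[d == 0.0] = 3
    bytes_per_variant = (n + 3) // 4
    padded = np.full((m, bytes_per_variant * 4), 1, dtype=np.uint8)
    padded[:, :n] = code.T
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    v = g.variants
    bim = pd.DataFrame(
        {"chrom": v["chrom"], "id": v["id"], "cm": 0, "pos": v["pos"],
         "a1": v["a1"], "a2": v["a2"]}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": g.sample_ids, "iid": g.sample_ids, "pat": 0, "mat": 0,
         "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    v[["id", "maf", "info", "missing_rate"]].to_csv(
        prefix.parent / (prefix.name + ".variant_meta.tsv"), sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Genotype hygiene
# ---------------------------------------------------------------------------

def mean_impute(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean of observed dosages.

    Observed cells are untouched, so per-column means are preserved exactly.
    A variant with no observed calls cannot be imputed and raises.
    """
    d = g.dosages.copy()
    missing = np.isnan(d)
    if not missing.any():
        return GenotypeMatrix(d, g.variants.copy(), list(g.sample_ids))
    n_obs = (~missing).sum(axis=0)
    if (n_obs == 0).any():
        bad = g.variants["id"][np.asarray(n_obs == 0)].tolist()
        raise ValueError(f"fully missing variant(s): {bad}")
    col_means = np.nansum(d, axis=0) / n_obs
    d[missing] = np.broadcast_to(col_means, d.shape)[missing]
    return GenotypeMatrix(d, g.variants.copy(), list(g.sample_ids))


def resolve_duplicates(variants: pd.DataFrame) -> pd.DataFrame:
    """Keep, for each duplicated variant id, the record with the highest INFO.

    Ties on INFO keep the first occurrence; input order is otherwise
    preserved.
    """
    if not variants["id"].duplicated().any():
        return variants.reset_index(drop=True)
    v = variants.reset_index(drop=True)
    info = v["info"].to_numpy(dtype=float)
    # stable argmax of INFO within each id group (NaN INFO loses to any number)
    keep_rows = []
    for _, idx in v.groupby("id", sort=False).indices.items():
        grp = np.asarray(idx)
        vals = np.where(np.isnan(info[grp]), -np.inf, info[grp])
        keep_rows.append(grp[int(np.argmax(vals))])
    keep_rows.sort()
    return v.iloc[keep_rows].reset_index(drop=True)


@dataclasses.dataclass
class AlleleMatch:
    """Alignment of a scoring file against a genotype panel.

    ``genotype_index``/``weight`` are parallel arrays over the matched
    variants; ``swapped[i]`` means the model's effect allele is the panel's
    A2, so the weight applies to ``2 - dosage``.  ``counts`` tallies every
    category including exclusions.
    """

    genotype_index: np.ndarray
    weight: np.ndarray
    swapped: np.ndarray
    counts: dict[str, int]
    excluded_ids: list[str]

    def effective_dosages(self, g: GenotypeMatrix) -> np.ndarray:
        """Dosage columns re-oriented so each counts the model's effect allele."""
        d = g.dosages[:, self.genotype_index].copy()
        d[:, self.swapped] = 2.0 - d[:, self.swapped]
        return d


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def match_alleles(model: pd.DataFrame, g: GenotypeMatrix) -> AlleleMatch:
    """Align scoring-file rows to genotype columns by id and allele pair.

    Per variant the outcome is one of: direct match (effect allele = panel
    A1), allele swap (effect allele = panel A2; weight applied to the
    complementary dosage), strand flip (match after complementing both model
    alleles, with or without swap), or exclusion.  All strand-ambiguous
    (A/T, G/C) variants are excluded regardless of apparent match, since
    their strand cannot be resolved from the alleles alone.
    """
    panel = {
        vid: (j, a1, a2)
        for j, (vid, a1, a2) in enumerate(
            zip(g.variants["id"], g.variants["a1"], g.variants["a2"])
        )
    }
    counts = {"direct": 0, "swap": 0, "flip": 0, "flip_swap": 0,
              "ambiguous": 0, "unmatched": 0}
    idx: list[int] = []
    wts: list[float] = []
    swap: list[bool] = []
    excluded: list[str] = []
    for row in model.itertuples(index=False):
        vid, ea, oa, w = row.rsID, row.effect_allele, row.other_allele, row.effect_weight
        if vid not in panel:
            counts["unmatched"] += 1
            excluded.append(vid)
            continue
        j, a1, a2 = panel[vid]
        if _is_ambiguous(ea, oa) or _is_ambiguous(a1, a2):
            counts["ambiguous"] += 1
            excluded.append(vid)
            continue
        fea, foa = _COMPLEMENT.get(ea, "?"), _COMPLEMENT.get(oa, "?")
        if (ea, oa) == (a1, a2):
            category, is_swap = "direct", False
        elif (ea, oa) == (a2, a1):
            category, is_swap = "swap", True
        elif (fea, foa) == (a1, a2):
            category, is_swap = "flip", False
        elif (fea, foa) == (a2, a1):
            category, is_swap = "flip_swap", True
        else:
            counts["unmatched"] += 1
            excluded.append(vid)
            continue
        counts[category] += 1
        idx.append(j)
        wts.append(float(w))
        swap.append(is_swap)
    return AlleleMatch(
        genotype_index=np.asarray(idx, dtype=int),
        weight=np.asarray(wts, dtype=float),
        swapped=np.asarray(swap, dtype=bool),
        counts=counts,
        excluded_ids=excluded,
    )


# ---------------------------------------------------------------------------
# Scoring files and summary statistics (TSV dialects)
# ---------------------------------------------------------------------------

SCORING_COLUMNS = ["rsID", "chr_name", "chr_position", "effect_allele",
                   "other_allele", "effect_weight"]

SUMSTATS_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                    "eaf", "beta", "se", "p", "n", "info"]


def write_scoring_file(rows: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in SCORING_COLUMNS if c not in rows.columns]
    if missing:
        raise FormatError(f"scoring file missing columns: {missing}")
    if not np.all(np.isfinite(rows["effect_weight"].to_numpy(dtype=float))):
        raise ValueError("scoring file weights must be finite")
    # 17 significant digits: float64 weights survive the text round trip exactly
    rows[SCORING_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_scoring_file(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"rsID": str, "chr_name": str},
                     float_precision="round_trip")
    missing = [c for c in SCORING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"scoring file missing columns: {missing}")
    return df[SCORING_COLUMNS]


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id": str, "chrom": str},
                       float_precision="round_trip")
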