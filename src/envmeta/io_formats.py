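"""Genotype, phenotype, annotation and tree I/O plus pre-analysis quality filters.

Genotype calls are alt-allele dosages in {0, 1, 2}; missing calls use a
dedicated sentinel (:data:`MISSING`), never 0, so allele frequencies are
computed on observed calls only.  Coordinates are 1-based inclusive
throughout (VCF/GFF3 convention); distances are in base pairs.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype call inside :class:`GenotypeMatrix.calls`.
MISSING: int = -1

#: Position value for markers without an assigned physical coordinate.
UNPLACED = None


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SnpRecord:
    """A biallelic SNP with its map position.

    ``pos`` is 1-based when placed, or ``None`` for markers without an
    assigned physical coordinate (the array contains a few hundred of
    these; they are excluded from positional analyses via
    :func:`subset_placed`).
    """

    snp_id: str
    chrom: str
    pos: int | None
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"SNP {self.snp_id!r}: empty chromosome label")
        if self.pos is not None and self.pos < 1:
            raise ValueError(f"SNP {self.snp_id!r}: position must be >= 1")

    @property
    def placed(self) -> bool:
        return self.pos is not None


@dataclass
class GenotypeMatrix:
    """SNP x accession matrix of alt-allele dosages.

    ``calls`` has shape ``(n_snps, n_accessions)`` with entries in
    {0, 1, 2, MISSING}.
    """

    accessions: list[str]
    snps: list[SnpRecord]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.snps), len(self.accessions)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.snps)}, {len(self.accessions)})"
            )
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate snp_id in genotype matrix")
        if len(set(self.accessions)) != len(self.accessions):
            raise FormatError("duplicate accession id in genotype matrix")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, missing}")

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def dosage_float(self) -> np.ndarray:
        """Calls as float with missing entries set to NaN."""
        d = self.calls.astype(float)
        d[self.calls == MISSING] = np.nan
        return d

    def missing_rate(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Per-SNP alt-allele frequency on non-missing calls (NaN if none)."""
        d = self.dosage_float()
        n_obs = np.sum(~np.isnan(d), axis=1)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, np.nansum(d, axis=1) / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency min(p, 1-p); NaN when all missing."""
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            accessions=list(self.accessions),
            snps=[self.snps[i] for i in index],
            calls=self.calls[index],
        )

    def take_accessions(self, ids: list[str]) -> "GenotypeMatrix":
        lookup = {a: i for i, a in enumerate(self.accessions)}
        idx = [lookup[a] for a in ids]
        return GenotypeMatrix(
            accessions=list(ids), snps=list(self.snps), calls=self.calls[:, idx]
        )


@dataclass
class PhenotypeTable:
    """Per-accession winter-survival percentages across environments plus a
    censored days-to-flowering trait and free-form metadata.

    ``data`` is indexed by accession id.  Winter-survival columns are
    ``ws_<environment-label>`` with values in [0, 100] (NaN = missing);
    environment labels are opaque codes (e.g. ``AB-14``), never parsed.
    ``dtf`` is days to flowering of unvernalized plants; accessions that
    never flowered carry the censor value with ``dtf_censored=True``.
    """

    data: pd.DataFrame
    environments: list[str] = field(default_factory=list)
    censor_value: int = 154

    def __post_init__(self) -> None:
        for env in self.environments:
            col = f"ws_{env}"
            if col not in self.data.columns:
                raise ValueError(f"missing WS column {col!r}")
            vals = self.data[col]
            bad = vals.dropna()
            if ((bad < 0) | (bad > 100)).any():
                raise FormatError(f"WS values outside [0, 100] in {col!r}")
        if "dtf" in self.data.columns:
            d = self.data["dtf"].dropna()
            if (d < 1).any():
                raise FormatError("DTF values must be >= 1")

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    def ws_matrix(self) -> pd.DataFrame:
        """Accession x environment WS values (NaN = missing)."""
        return self.data[[f"ws_{e}" for e in self.environments]].rename(
            columns=lambda c: c[3:]
        )

    def mean_ws(self) -> pd.Series:
        """Unweighted mean of non-missing environment WS values per accession."""
        return self.ws_matrix().mean(axis=1, skipna=True)


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval, 1-based inclusive, same convention as SnpRecord."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")


# ---------------------------------------------------------------------------
# genotype I/O
# ---------------------------------------------------------------------------

_TABLE_META_COLS = ["snp_id", "chrom", "pos", "alleles"]


def _parse_pos(raw) -> int | None:
    s = str(raw).strip()
    if s.lower() in ("unplaced", "na", "nan", ".", ""):
        return None
    return int(float(s))


def read_genotypes(path, format: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix from a tabular file or a VCF.

    The tabular dialect has SNPs as rows, accessions as columns: a header
    row of accession ids after four metadata columns
    (snp_id, chrom, pos, alleles).  Missing calls are ``NA`` or ``.``.
    VCF input is restricted to biallelic SNP records; anything else is
    skipped with a logged count.
    """
    if format == "table":
        return _read_genotype_table(path)
    if format == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotype_table(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse genotype table {path}: {exc}") from exc
    if list(df.columns[:4]) != _TABLE_META_COLS:
        raise FormatError(
            f"genotype table header must start with {_TABLE_META_COLS}, "
            f"got {list(df.columns[:4])} (line 1)"
        )
    accessions = list(df.columns[4:])
    snps = []
    for _, row in df.iterrows():
        ref, _, alt = str(row["alleles"]).partition("/")
        snps.append(
            SnpRecord(
                snp_id=str(row["snp_id"]),
                chrom=str(row["chrom"]),
                pos=_parse_pos(row["pos"]),
                alleles=(ref, alt or "B"),
            )
        )
    raw = df[accessions].to_numpy(dtype=object)
    calls = np.full(raw.shape, MISSING, dtype=np.int16)
    for code in (0, 1, 2):
        calls[raw == str(code)] = code
    unknown = ~np.isin(raw, [str(c) for c in (0, 1, 2)]) & ~pd.isna(raw)
    unknown &= ~np.isin(raw, ["NA", ".", "nan"])
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise FormatError(
            f"unrecognized genotype call {raw[i, j]!r} for SNP "
            f"{snps[i].snp_id} / accession {accessions[j]}"
        )
    return GenotypeMatrix(accessions=accessions, snps=snps, calls=calls)


def _read_genotype_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    accessions = list(vcf.samples)
    snps, rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        snps.append(
            SnpRecord(
                snp_id=var.ID or f"{var.CHROM}:{var.POS}",
                chrom=var.CHROM,
                pos=var.POS,
                alleles=(var.REF, var.ALT[0]),
            )
        )
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        row = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int16)
        rows.append(row)
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP VCF records", n_skipped)
    calls = np.vstack(rows) if rows else np.empty((0, len(accessions)), np.int16)
    gm = GenotypeMatrix(accessions=accessions, snps=snps, calls=calls)
    gm.n_skipped_records = n_skipped
    return gm


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write the tabular genotype dialect read by :func:`read_genotypes`."""
    meta = pd.DataFrame(
        {
            "snp_id": [s.snp_id for s in gm.snps],
            "chrom": [s.chrom for s in gm.snps],
            "pos": ["unplaced" if s.pos is None else s.pos for s in gm.snps],
            "alleles": ["/".join(s.alleles) for s in gm.snps],
        }
    )
    body = pd.DataFrame(
        np.where(gm.calls == MISSING, "NA", gm.calls.astype(str)),
        columns=gm.accessions,
    )
    pd.concat([meta, body], axis=1).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------


def filter_genotypes(
    gm: GenotypeMatrix, max_missing: float = 0.20, min_maf: float = 0.05
) -> GenotypeMatrix:
    """Drop SNPs with missing-rate > ``max_missing`` or MAF < ``min_maf``.

    MAF is computed on non-missing calls as min(p, 1-p) of the alt-allele
    frequency.  A SNP with every call missing has undefined MAF and is
    always removed.  Accessions are untouched.  Idempotent.
    """
    if not 0 <= max_missing <= 1:
        raise ValueError("max_missing must be in [0, 1]")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    miss = gm.missing_rate()
    maf = gm.maf()
    keep = (miss <= max_missing) & ~np.isnan(maf) & (maf >= min_maf)
    return gm.take_snps(np.flatnonzero(keep))


def subset_placed(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Keep only SNPs with an assigned physical position."""
    keep = [i for i, s in enumerate(gm.snps) if s.placed]
    return gm.take_snps(np.asarray(keep, dtype=int))


# ---------------------------------------------------------------------------
# phenotype I/O
# ---------------------------------------------------------------------------


def read_phenotypes(path, censor_value: int = 154) -> PhenotypeTable:
    """Read a phenotype CSV, one row per accession.

    Environment columns are auto-detected by the ``ws_`` prefix (case
    insensitive); the label is whatever follows the prefix.  Recognised
    optional columns: ``dtf``, ``dtf_censored``, ``row_type`` and any
    further metadata columns, which are kept verbatim.
    """
    df = pd.read_csv(path)
    if "accession" not in df.columns:
        raise FormatError("phenotype CSV must have an 'accession' column")
    df = df.set_index("accession")
    envs = []
    rename = {}
    for col in df.columns:
        m = re.match(r"(?i)^ws_(.+)$", col)
        if m:
            envs.append(m.group(1))
            rename[col] = f"ws_{m.group(1)}"
    df = df.rename(columns=rename)
    if "dtf" in df.columns and "dtf_censored" not in df.columns:
        df["dtf_censored"] = df["dtf"] >= censor_value
    return PhenotypeTable(data=df, environments=envs, censor_value=censor_value)


def write_phenotypes(pt: PhenotypeTable, path) -> None:
    pt.data.to_csv(path, index_label="accession")


# ---------------------------------------------------------------------------
# annotation and trees
# ---------------------------------------------------------------------------


def read_gff3(path, feature_type: str = "gene") -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (1-based inclusive intervals)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneAnnotation] = []
    seen: dict[str, GeneAnnotation] = {}
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        desc = feat.attributes.get("description", feat.attributes.get("Name", [""]))[0]
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        ann = GeneAnnotation(
            gene_id=gene_id,
            chrom=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand or ".",
            description=desc,
        )
        prev = seen.get(gene_id)
        if prev is not None:
            if max(prev.start, ann.start) <= min(prev.end, ann.end):
                raise FormatError(f"overlapping duplicate gene_id {gene_id!r}")
        seen[gene_id] = ann
        genes.append(ann)
    return genes


def write_newick(tree) -> str:
    """Serialize a scikit-bio TreeNode as a Newick string ending in ';'."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if not text.endswith(";"):
        text += ";"
    return text


# ---------------------------------------------------------------------------
# packaged worked-example fixtures
# ---------------------------------------------------------------------------


def _fixture_path(name: str):
    from importlib.resources import files

    return files("envmeta.fixtures").joinpath(name)


def load_top5_table() -> pd.DataFrame:
    """The 44 highest-surviving accessions: clade, row type, DTF, mean WS."""
    with _fixture_path("table1.csv").open() as fh:
        df = pd.read_csv(fh, na_values=["NA", "?"])
    assert len(df) == 44
    return df


def load_locus_call_table() -> pd.DataFrame:
    """KASP-style allele calls at PPD-H1, PPD-H2, VRN-H1 and VRN-H2 for the
    23 re-genotyped high-survival accessions, with WS and DTF."""
    with _fixture_path("table3.csv").open() as fh:
        df = pd.read_csv(fh, na_values=["NA"])
    assert len(df) == 23
    return df
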