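"""Genotype and phenotype input, call-rate QC, and sample alignment.

Supported genotype formats:

* PLINK 1 binary (``.bed`` + ``.bim`` + ``.fam``), v1.0 SNP-major layout
  with magic bytes ``0x6c 0x1b 0x01``.  The two-bit codes are 00 =
  homozygous A1, 01 = missing, 10 = heterozygous, 11 = homozygous A2;
  dosages count the A1 (effect) allele.
* VCF with hard genotypes (GT) or dosages (DS); the effect allele is ALT.
  Multi-allelic records are skipped with a log line.
* Plain dosage CSV with header ``person,snp1,snp2,...``; empty cell =
  missing; the effect allele is whatever the producer encoded (recorded as
  the SNP metadata says nothing).

Positions are 1-based throughout (PLINK/VCF convention).  Quality control
follows the usual call-rate rule: SNPs with genotyping success below the
threshold are dropped first, then individuals are screened on the
surviving SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pedscore._errors import ConfigurationError, DataError, FormatError, ValidationError
from pedscore.pedstruct import Pedigree

__all__ = [
    "GenotypeSource",
    "QCReport",
    "PhenotypeTable",
    "AlignedIndex",
    "read_genotypes",
    "write_dosage_csv",
    "write_plink",
    "qc_filter",
    "align",
    "read_phenotypes",
]

log = logging.getLogger("pedscore.genio")

SNP_COLUMNS = ["snp_id", "chrom", "bp", "allele_effect", "allele_other"]


@dataclass
class GenotypeSource:
    """In-memory genotype matrix with SNP metadata.

    ``dosages`` is individuals × SNPs, values in [0, 2] with NaN for
    missing.  ``snps`` is a DataFrame with columns ``snp_id, chrom, bp,
    allele_effect, allele_other``.  The source is small enough to hold in
    memory at the intended scale; ``iter_batches`` provides SNP-major
    iteration for the scan loop.
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.snps = self.snps.reset_index(drop=True)
        if self.dosages.shape != (len(self.ids), len(self.snps)):
            raise ValidationError("dosage matrix shape does not match ids × snps")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValidationError(f"duplicate SNP id {dup!r}")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0.0) < -1e-9 or \
               np.nanmax(self.dosages, initial=0.0) > 2.0 + 1e-9:
                raise ValidationError("dosages must lie in [0, 2] or be missing")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def iter_batches(self, batch_size: int = 512):
        """Yield (snps slice DataFrame, dosage block individuals × b)."""
        for start in range(0, self.n_snps, batch_size):
            stop = min(start + batch_size, self.n_snps)
            yield self.snps.iloc[start:stop], self.dosages[:, start:stop]

    def subset_individuals(self, positions) -> "GenotypeSource":
        positions = np.asarray(positions, dtype=np.int64)
        return GenotypeSource(self.dosages[positions], self.snps.copy(),
                              [self.ids[i] for i in positions])

    def subset_snps(self, keep_mask) -> "GenotypeSource":
        keep_mask = np.asarray(keep_mask, dtype=bool)
        return GenotypeSource(self.dosages[:, keep_mask],
                              self.snps.loc[keep_mask].copy(), list(self.ids))


@dataclass
class QCReport:
    n_snps_in: int
    n_snps_excluded: int
    n_individuals_in: int
    n_individuals_excluded: int
    snp_call_min: float
    ind_call_min: float

    def __post_init__(self):
        assert 0 <= self.n_snps_excluded <= self.n_snps_in
        assert 0 <= self.n_individuals_excluded <= self.n_individuals_in

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PhenotypeTable:
    """Long-format phenotype/covariate table: one row per (person, visit)."""

    table: pd.DataFrame  # columns: person, visit, then traits/covariates

    def __post_init__(self):
        for col in ("person", "visit"):
            if col not in self.table.columns:
                raise ValidationError(f"phenotype table needs a {col!r} column")
        if self.table.duplicated(["person", "visit"]).any():
            raise ValidationError("duplicate (person, visit) rows in phenotype table")
        self.table = self.table.reset_index(drop=True)
        self.table["person"] = self.table["person"].astype(str)

    @property
    def persons(self) -> list[str]:
        return list(dict.fromkeys(self.table["person"]))

    @property
    def visits(self) -> list:
        return sorted(self.table["visit"].unique())

    def wide(self, column: str) -> pd.DataFrame:
        """Person × visit matrix for one column (NaN where unobserved)."""
        return self.table.pivot(index="person", columns="visit", values=column)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def read_phenotypes(path) -> PhenotypeTable:
    return PhenotypeTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# readers

_BED_MAGIC = b"\x6c\x1b\x01"
# two-bit PLINK codes, indexed by code value: 00→2 (hom A1), 01→missing,
# 10→het, 11→0 (hom A2)
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_genotypes(path, format: str = "dosage_csv",
                   on_bad_record: str = "skip") -> GenotypeSource:
    """Read genotypes; ``format`` is one of plink_bed, vcf, dosage_csv.

    For ``plink_bed`` pass the ``.bed`` path (``.bim``/``.fam`` must sit
    beside it).  ``on_bad_record`` governs VCF records that are not
    biallelic diploid: "skip" (default, logged) or "fail".
    """
    if format == "plink_bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path, on_bad_record)
    if format == "dosage_csv":
        return _read_dosage_csv(path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def _read_plink(bed_path) -> GenotypeSource:
    bed_path = str(bed_path)
    stem = bed_path[:-4] if bed_path.endswith(".bed") else bed_path
    fam = pd.read_csv(stem + ".fam", sep=r"\s+", header=None, dtype=str,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"])
    bim = pd.read_csv(stem + ".bim", sep=r"\s+", header=None, dtype=str,
                      names=["chrom", "snp_id", "cm", "bp", "a1", "a2"])
    n, m = len(fam), len(bim)
    with open(stem + ".bed", "rb") as fh:
        header = fh.read(3)
        if header != _BED_MAGIC:
            raise FormatError(
                f"{stem}.bed: bad magic bytes {header!r} (expected PLINK v1.0 SNP-major)")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise FormatError(f"{stem}.bed: size does not match {n} samples × {m} SNPs")
    raw = raw.reshape(m, bytes_per_snp)
    # unpack two-bit codes, individual order = lowest bits first within a byte
    codes = np.stack([(raw >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _BED_DECODE[codes].T  # individuals × SNPs, A1 counted
    snps = pd.DataFrame({
        "snp_id": bim["snp_id"], "chrom": bim["chrom"],
        "bp": bim["bp"].astype(np.int64),
        "allele_effect": bim["a1"], "allele_other": bim["a2"],
    })
    return GenotypeSource(dosages, snps, list(fam["iid"]))


def _read_vcf(path, on_bad_record: str) -> GenotypeSource:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError("reading VCF requires the cyvcf2 package") from exc
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    has_ds = "DS" in [h.info().get("ID") for h in vcf.header_iter()
                      if h.type == "FORMAT"]
    cols, meta = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            msg = f"skipping multi-allelic record {rec.CHROM}:{rec.POS}"
            if on_bad_record == "fail":
                raise FormatError(msg)
            log.info(msg)
            continue
        ds = rec.format("DS") if has_ds else None
        if ds is not None:
            vec = np.asarray(ds, dtype=float).reshape(-1)
            vec = np.where((vec < 0) | (vec > 2), np.nan, vec)
        else:
            gts = rec.genotype.array()  # columns: allele1, allele2, phased
            if gts.shape[1] - 1 != 2:
                msg = f"non-diploid record {rec.CHROM}:{rec.POS}"
                if on_bad_record == "fail":
                    raise FormatError(msg)
                log.info("skipping %s", msg)
                continue
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan  # -1 encodes '.'
            vec = alleles.sum(axis=1)
        cols.append(vec)
        meta.append((rec.ID or f"{rec.CHROM}:{rec.POS}", rec.CHROM, rec.POS,
                     rec.ALT[0], rec.REF))
    if not meta:
        raise DataError(f"no usable biallelic records in {path}")
    snps = pd.DataFrame(meta, columns=SNP_COLUMNS)
    return GenotypeSource(np.column_stack(cols), snps, ids)


def _read_dosage_csv(path) -> GenotypeSource:
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.columns[0] != "person":
        raise FormatError("dosage CSV must start with a 'person' column")
    ids = list(df["person"].astype(str))
    snp_ids = list(df.columns[1:])
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    snps = pd.DataFrame({
        "snp_id": snp_ids, "chrom": ["0"] * len(snp_ids),
        "bp": np.arange(1, len(snp_ids) + 1, dtype=np.int64),
        "allele_effect": ["NA"] * len(snp_ids), "allele_other": ["NA"] * len(snp_ids),
    })
    return GenotypeSource(dosages, snps, ids)


def write_dosage_csv(g: GenotypeSource, path) -> None:
    """Round-trip-exact dosage CSV (full float repr, empty cell = missing)."""
    df = pd.DataFrame(g.dosages, columns=list(g.snps["snp_id"]))
    df.insert(0, "person", g.ids)
    df.to_csv(path, index=False, float_format="%.17g")


def write_plink(g: GenotypeSource, stem, ped: Pedigree | None = None) -> None:
    """Write hard-call genotypes as PLINK bed/bim/fam (testing/simulation aid).

    Dosages must be integral or missing; fractional dosages cannot be
    represented in .bed.
    """
    d = g.dosages
    frac = ~np.isnan(d) & (np.abs(d - np.round(d)) > 1e-9)
    if frac.any():
        raise ValidationError("write_plink requires hard-call dosages in {0,1,2}")
    fam_rows = []
    by_person = {}
    if ped is not None:
        by_person = {ind.person: ind for ind in ped.individuals}
    for iid in g.ids:
        ind = by_person.get(iid)
        if ind is None:
            fam_rows.append((iid, iid, "0", "0", "0", "-9"))
        else:
            sex = {"male": "1", "female": "2"}.get(ind.sex, "0")
            fam_rows.append((ind.family, iid, ind.father or "0", ind.mother or "0",
                             sex, "-9"))
    with open(f"{stem}.fam", "w") as fh:
        for row in fam_rows:
            fh.write(" ".join(row) + "\n")
    with open(f"{stem}.bim", "w") as fh:
        for _, s in g.snps.iterrows():
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.bp}\t{s.allele_effect}\t{s.allele_other}\n")
    n = g.n_individuals
    bytes_per_snp = (n + 3) // 4
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    with open(f"{stem}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(g.n_snps):
            buf = bytearray(bytes_per_snp)
            for i in range(n):
                v = d[i, j]
                code = 0b01 if np.isnan(v) else code_of[round(v, 0)]
                buf[i // 4] |= code << (2 * (i % 4))
            fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# QC and alignment

def qc_filter(g: GenotypeSource, snp_call_min: float = 0.98,
              ind_call_min: float = 0.98):
    """Call-rate QC: drop SNPs below ``snp_call_min``, then individuals
    below ``ind_call_min`` computed on the surviving SNPs.

    Returns (filtered GenotypeSource, QCReport).
    """
    called = ~np.isnan(g.dosages)
    snp_rate = called.mean(axis=0)
    keep_snps = snp_rate >= snp_call_min
    if not keep_snps.any():
        raise DataError("call-rate QC removed every SNP; nothing left to test")
    g2 = g.subset_snps(keep_snps)
    ind_rate = (~np.isnan(g2.dosages)).mean(axis=1)
    keep_inds = ind_rate >= ind_call_min
    g3 = g2.subset_individuals(np.where(keep_inds)[0])
    report = QCReport(
        n_snps_in=g.n_snps, n_snps_excluded=int((~keep_snps).sum()),
        n_individuals_in=g.n_individuals,
        n_individuals_excluded=int((~keep_inds).sum()),
        snp_call_min=snp_call_min, ind_call_min=ind_call_min)
    log.info("QC excluded %d SNPs and %d individuals (call rate < %g / %g)",
             report.n_snps_excluded, report.n_individuals_excluded,
             snp_call_min, ind_call_min)
    return g3, report


@dataclass
class AlignedIndex:
    """Joint ordering of a pedigree sample across data sources.

    ``ped`` covers every individual (pedigree members plus genotyped or
    phenotyped singletons added as founders of their own one-person
    families).  Relationship matrices are built on all of them;
    ``analysis_ids`` is the subset with genotypes that enters the trait
    vector, and ``analysis_positions`` locates them inside ``ped``.
    """

    ped: Pedigree
    analysis_ids: list[str]
    analysis_positions: np.ndarray  # into ped ordering
    geno_positions: np.ndarray      # into GenotypeSource ordering


def align(ped: Pedigree, g: GenotypeSource,
          ph: PhenotypeTable | None = None) -> AlignedIndex:
    """Build one individual ordering across pedigree, genotypes, phenotypes.

    Pedigree members without genotypes stay in the relationship matrices
    (they still carry information through relatives) but are excluded from
    the trait vector.  Genotyped individuals absent from the pedigree are
    treated as unrelated founders of their own singleton families.
    """
    ids = ped.ids
    dup = pd.Series(ids).duplicated()
    if dup.any():
        raise ValidationError(
            f"person id {ids[int(np.where(dup)[0][0])]!r} appears in more than one "
            "family; ids must be unique across the whole sample to align sources")
    known = set(ids)
    extra = [i for i in g.ids if i not in known]
    full_ped = ped.add_singletons(extra) if extra else ped
    pos_in_ped = {pid: k for k, pid in enumerate(full_ped.ids)}

    analysis = [i for i in g.ids if i in pos_in_ped]
    if ph is not None:
        with_pheno = set(ph.persons)
        analysis = [i for i in analysis if i in with_pheno]
    if not analysis:
        raise DataError("no individuals shared between pedigree/genotypes/phenotypes")
    geno_pos = {pid: k for k, pid in enumerate(g.ids)}
    return AlignedIndex(
        ped=full_ped,
        analysis_ids=analysis,
        analysis_positions=np.array([pos_in_ped[i] for i in analysis], dtype=np.int64),
        geno_positions=np.array([geno_pos[i] for i in analysis], dtype=np.int64),
    )
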