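"""Read, validate and quality-filter SNP genotype data.

Dosages count copies of allele 2 (A2): the ALT allele for VCF input, the
counted allele of a PLINK ``.raw`` export, and the literal cell value for a
TSV matrix.  Genotypes A1A1 / A1A2 / A2A2 therefore code 0 / 1 / 2, and the
frequency ``p`` of allele 2 together with ``q = 1 - p`` drives all centered
codings downstream.

Quality control follows the usual SNP-chip editing rules: loci are kept when
the minor allele frequency exceeds ``maf_min`` and the locus call rate exceeds
``locus_call_min``; individuals are then kept when their call rate over the
retained loci exceeds ``indiv_call_min``.  All thresholds are strict
inequalities.  Missing genotypes are never hard-imputed to a 0/1/2 call: the
centered codings substitute the expected centered coefficient, which is zero
(see :func:`impute_missing_centered`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencies",
    "QCReport",
    "read_genotypes",
    "write_genotypes_tsv",
    "allele_frequencies",
    "qc_filter",
    "impute_missing_centered",
]

logger = logging.getLogger(__name__)

_PLINK_RAW_LEADING = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class GenotypeMatrix:
    """Individuals x loci allele-2 dosage matrix with a missing mask.

    ``dosages`` holds integers in {0, 1, 2} wherever ``missing_mask`` is
    False; masked entries are stored as 0 but carry no information.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    dosages: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(i) for i in self.locus_ids]
        n, m = len(self.individual_ids), len(self.locus_ids)
        if n < 1 or m < 1:
            raise ValueError("genotype matrix needs at least 1 individual and 1 locus")
        if len(set(self.individual_ids)) != n:
            raise ValueError("individual ids are not unique")
        if len(set(self.locus_ids)) != m:
            raise ValueError("locus ids are not unique")
        dos = np.asarray(self.dosages)
        mask = np.asarray(self.missing_mask, dtype=bool)
        if dos.shape != (n, m):
            raise ValueError(f"dosages shape {dos.shape} != ({n}, {m})")
        if mask.shape != (n, m):
            raise ValueError(f"missing_mask shape {mask.shape} != ({n}, {m})")
        observed = dos[~mask]
        if observed.size and not np.isin(observed, (0, 1, 2)).all():
            bad = observed[~np.isin(observed, (0, 1, 2))][0]
            raise ValueError(f"non-missing dosage {bad!r} outside {{0,1,2}}")
        # normalise storage: ints, zeros under the mask
        dos = np.where(mask, 0, dos).astype(np.int8)
        object.__setattr__(self, "dosages", dos)
        object.__setattr__(self, "missing_mask", mask)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "GenotypeMatrix":
        """Return a new matrix restricted to the given row/column selectors."""
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_loci) if cols is None else np.asarray(cols)
        if rows.dtype == bool:
            rows = np.flatnonzero(rows)
        if cols.dtype == bool:
            cols = np.flatnonzero(cols)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in rows],
            [self.locus_ids[j] for j in cols],
            self.dosages[np.ix_(rows, cols)],
            self.missing_mask[np.ix_(rows, cols)],
        )

    def to_frame(self) -> pd.DataFrame:
        """Dosages as a float DataFrame with NaN for missing entries."""
        data = self.dosages.astype(float)
        data[self.missing_mask] = np.nan
        return pd.DataFrame(data, index=self.individual_ids, columns=self.locus_ids)


@dataclass
class AlleleFrequencies:
    """Per-locus frequency of allele 2 (the counted/ALT allele)."""

    locus_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1 or self.p.size != len(self.locus_ids):
            raise ValueError("p must be one value per locus")
        if ((self.p < 0) | (self.p > 1)).any():
            raise ValueError("allele frequencies outside [0, 1]")

    @property
    def q(self) -> np.ndarray:
        """Frequency of allele 1, exactly 1 - p."""
        return 1.0 - self.p

    @property
    def pq(self) -> np.ndarray:
        return self.p * self.q


@dataclass
class QCReport:
    loci_removed_maf: int
    loci_removed_callrate: int
    individuals_removed_callrate: int
    maf_min: float
    locus_call_min: float
    indiv_call_min: float
    n_individuals_in: int
    n_loci_in: int

    @property
    def n_loci_retained(self) -> int:
        return self.n_loci_in - self.loci_removed_maf - self.loci_removed_callrate

    @property
    def n_individuals_retained(self) -> int:
        return self.n_individuals_in - self.individuals_removed_callrate


# ---------------------------------------------------------------------------
# reading / writing


def read_genotypes(path: str | Path, format: str) -> GenotypeMatrix:
    """Read genotypes from ``plink_raw``, ``tsv`` or ``vcf`` input.

    TSV: first column is the individual id, the header row holds locus ids,
    cells are 0/1/2 or NA.  PLINK ``.raw``: whitespace-separated with the
    standard six leading columns, NA missing.  VCF: biallelic SNPs only, read
    from the GT field via cyvcf2; other records are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "plink_raw":
        return _read_plink_raw(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _frame_to_matrix(df: pd.DataFrame, path: Path) -> GenotypeMatrix:
    values = df.to_numpy(dtype=float)
    mask = np.isnan(values)
    dosages = np.where(mask, 0, values)
    if not np.array_equal(dosages, np.round(dosages)):
        raise ValueError(f"{path}: non-integer genotype value present")
    return GenotypeMatrix(
        list(df.index.astype(str)), list(df.columns.astype(str)), dosages.astype(np.int8), mask
    )


def _read_tsv(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    except Exception as exc:  # pandas names the offending line in its message
        raise ValueError(f"failed to parse TSV {path}: {exc}") from exc
    return _frame_to_matrix(df, path)


def _read_plink_raw(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    except Exception as exc:
        raise ValueError(f"failed to parse PLINK .raw {path}: {exc}") from exc
    missing_cols = [c for c in _PLINK_RAW_LEADING if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: not a PLINK .raw file, missing columns {missing_cols}")
    ids = df["IID"].astype(str)
    snp_cols = [c for c in df.columns if c not in _PLINK_RAW_LEADING]
    if not snp_cols:
        raise ValueError(f"{path}: no SNP columns after the six leading fields")
    body = df[snp_cols]
    body.index = ids
    return _frame_to_matrix(body, path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    reader = VCF(str(path))
    ids = [str(s) for s in reader.samples]
    dosage_cols: list[np.ndarray] = []
    mask_cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    n_skipped = 0
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    recode = np.array([0, 1, 0, 2], dtype=np.int8)
    for var in reader:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types)
        dosage_cols.append(recode[gt])
        mask_cols.append(gt == 2)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        locus_ids.append(str(vid))
    reader.close()
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic/non-SNP record(s)", path, n_skipped)
    if not locus_ids:
        raise ValueError(f"{path}: no usable biallelic SNP records")
    return GenotypeMatrix(
        ids, locus_ids, np.column_stack(dosage_cols), np.column_stack(mask_cols)
    )


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the TSV dialect read back by ``read_genotypes(..., "tsv")``."""
    out = g.to_frame().round().astype("Int64")
    out.to_csv(path, sep="\t", index_label="individual_id", na_rep="NA")


# ---------------------------------------------------------------------------
# frequencies and QC


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Observed allele-2 frequency per locus, using non-missing genotypes only."""
    counts = (~g.missing_mask).sum(axis=0)
    if (counts == 0).any():
        bad = g.locus_ids[int(np.argmax(counts == 0))]
        raise ValueError(f"locus {bad!r} has no non-missing genotypes")
    totals = np.where(g.missing_mask, 0, g.dosages).sum(axis=0)
    return AlleleFrequencies(list(g.locus_ids), totals / (2.0 * counts))


def qc_filter(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    locus_call_min: float = 0.95,
    indiv_call_min: float = 0.95,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the marker editing rules and return the filtered matrix.

    Locus filters come first, computed on the input: MAF must exceed
    ``maf_min`` and locus call rate must exceed ``locus_call_min``.
    Individual call rate, computed on the retained loci, must then exceed
    ``indiv_call_min``.  Frequencies should be recomputed on the output.
    """
    n, m = g.n_individuals, g.n_loci
    freqs = allele_frequencies(g)
    maf = np.minimum(freqs.p, freqs.q)
    keep_maf = maf > maf_min
    locus_call = (~g.missing_mask).mean(axis=0)
    keep_call = locus_call > locus_call_min
    keep_locus = keep_maf & keep_call
    loci_removed_maf = int((~keep_maf).sum())
    loci_removed_callrate = int((keep_maf & ~keep_call).sum())
    if not keep_locus.any():
        raise ValueError("QC removed every locus")

    trimmed = g.subset(cols=keep_locus)
    indiv_call = (~trimmed.missing_mask).mean(axis=1)
    keep_indiv = indiv_call > indiv_call_min
    individuals_removed = int((~keep_indiv).sum())
    if not keep_indiv.any():
        raise ValueError("QC removed every individual")

    out = trimmed.subset(rows=keep_indiv)
    report = QCReport(
        loci_removed_maf=loci_removed_maf,
        loci_removed_callrate=loci_removed_callrate,
        individuals_removed_callrate=individuals_removed,
        maf_min=maf_min,
        locus_call_min=locus_call_min,
        indiv_call_min=indiv_call_min,
        n_individuals_in=n,
        n_loci_in=m,
    )
    logger.info(
        "QC: %d/%d loci and %d/%d individuals retained",
        report.n_loci_retained, m, report.n_individuals_retained, n,
    )
    return out, report


def impute_missing_centered(g: GenotypeMatrix, f: AlleleFrequencies) -> dict[str, np.ndarray]:
    """Expected centered genotype coefficients used for missing entries.

    Missing raw dosages are never replaced by a hard 0/1/2 call.  The
    model-facing codings are centered, and the expectation of a centered
    coefficient under the locus allele frequencies is exactly zero for both
    the additive coding (E[x - 2p] = 0) and the centered heterozygosity
    coding (E[h - 2pq] = 0).  The coding builders therefore substitute 0 for
    masked entries; this helper returns those per-locus fill values.
    """
    if list(f.locus_ids) != list(g.locus_ids):
        raise ValueError("allele frequencies computed on different loci")
    zeros = np.zeros(g.n_loci)
    return {"additive": zeros, "dominance": zeros.copy()}
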