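"""Core data containers and file I/O for SNP-regression genomic prediction.

Genotypes are biallelic SNPs coded as allele dosages 0/1/2 (count of the '1'
or ALT allele).  For model fitting each marker column is standardized with its
own allele frequency ``p``::

    b = (dosage - 2 p) / sqrt(2 p (1 - p))

so that, under Hardy-Weinberg proportions, a column has mean 0 and variance 1.
Monomorphic markers (``p`` equal to 0 or 1) have no defined standardization and
are dropped on input; missing dosages are imputed with the column mean ``2 p``.

The on-disk formats are deliberately simple, text-only dialects:

* genotypes: tab-separated matrix, header ``id<TAB>marker...``, one row per
  individual, missing dosage token ``NA``, ``#`` comment lines ignored;
  alternatively a VCF of biallelic SNPs (GT field only);
* phenotypes: 2-column TSV ``id, value``;
* pedigree: 5-column TSV ``id, sire, dam, genotyped, role`` with unknown
  parents coded ``0`` or ``.`` and role in {training, evaluation, none}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKEN = "NA"
UNKNOWN_PARENT_TOKENS = ("0", ".", "")
ROLES = ("training", "evaluation", "none")

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "Pedigree",
    "PedigreeRecord",
    "VarianceSpec",
    "standardize",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "write_effects",
    "read_effects",
]


class GenotypeParseError(ValueError):
    """Malformed genotype file (wrong row length, bad token...)."""


class PedigreeError(ValueError):
    """Invalid pedigree (cycle, self-ancestry, unknown role...)."""


def standardize(dosages: np.ndarray, allele_freq: np.ndarray) -> np.ndarray:
    """Standardize dosage columns: ``(d - 2 p) / sqrt(2 p (1 - p))``.

    Parameters
    ----------
    dosages
        ``(n, M)`` array of allele dosages (may contain imputed, non-integer
        values but no NaN).
    allele_freq
        ``(M,)`` allele frequencies, each strictly inside (0, 1).

    Returns
    -------
    ``(n, M)`` float array of standardized genotypes.
    """
    p = np.asarray(allele_freq, dtype=float)
    if p.ndim != 1 or np.any(p <= 0.0) or np.any(p >= 1.0):
        raise ValueError("allele frequencies must lie strictly in (0, 1); "
                         "filter monomorphic markers first")
    d = np.asarray(dosages, dtype=float)
    return (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


@dataclass
class GenotypeMatrix:
    """Dosage matrix with marker metadata and its standardized design matrix.

    ``dosages`` holds mean-imputed values (so entries may be non-integer where
    the raw file had ``NA``).  ``allele_freq`` is fixed at construction and
    reused verbatim by :meth:`subset`, so training and evaluation individuals
    always share one column scaling.
    """

    dosages: np.ndarray
    marker_ids: list[str]
    allele_freq: np.ndarray
    individual_ids: list[str]
    standardized: np.ndarray = field(repr=False)
    dropped_markers: list[str] = field(default_factory=list)

    @classmethod
    def from_dosages(
        cls,
        dosages: np.ndarray,
        marker_ids: Sequence[str],
        individual_ids: Sequence[str],
    ) -> "GenotypeMatrix":
        """Build from a raw dosage matrix (NaN = missing).

        Allele frequencies are column means / 2 over non-missing entries;
        missing entries are imputed with ``2 p``; monomorphic and all-missing
        columns are dropped (with a logged warning).
        """
        d = np.asarray(dosages, dtype=float)
        if d.ndim != 2:
            raise ValueError("dosage matrix must be 2-dimensional")
        marker_ids = [str(m) for m in marker_ids]
        individual_ids = [str(i) for i in individual_ids]
        if d.shape != (len(individual_ids), len(marker_ids)):
            raise ValueError("dosage matrix shape does not match id lists")
        with np.errstate(invalid="ignore"):
            col_mean = np.nanmean(np.where(np.isnan(d), np.nan, d), axis=0)
        n_obs = np.sum(~np.isnan(d), axis=0)
        p = np.where(n_obs > 0, col_mean / 2.0, np.nan)
        keep = (n_obs > 0) & (p > 0.0) & (p < 1.0)
        dropped = [m for m, k in zip(marker_ids, keep) if not k]
        if dropped:
            logger.warning(
                "dropping %d monomorphic/all-missing marker(s): %s",
                len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
            )
        d = d[:, keep]
        p = p[keep]
        kept_ids = [m for m, k in zip(marker_ids, keep) if k]
        # mean imputation keeps the standardized column mean at 0
        nan_mask = np.isnan(d)
        if nan_mask.any():
            d = np.where(nan_mask, 2.0 * p, d)
        b = standardize(d, p) if d.shape[1] else d.astype(float)
        return cls(
            dosages=d,
            marker_ids=kept_ids,
            allele_freq=p,
            individual_ids=individual_ids,
            standardized=b,
            dropped_markers=dropped,
        )

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def subset(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        """Row subset that keeps the original allele frequencies and scaling."""
        index = {v: i for i, v in enumerate(self.individual_ids)}
        try:
            rows = [index[str(i)] for i in individual_ids]
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix") from None
        return GenotypeMatrix(
            dosages=self.dosages[rows],
            marker_ids=list(self.marker_ids),
            allele_freq=self.allele_freq,
            individual_ids=[str(i) for i in individual_ids],
            standardized=self.standardized[rows],
            dropped_markers=list(self.dropped_markers),
        )


@dataclass
class PhenotypeVector:
    """Trait records ``y`` aligned with individual ids."""

    values: np.ndarray
    individual_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.individual_ids = [str(i) for i in self.individual_ids]
        if self.values.shape != (len(self.individual_ids),):
            raise ValueError("phenotype values and ids must align one-to-one")

    def reindex(self, individual_ids: Sequence[str]) -> "PhenotypeVector":
        index = {v: i for i, v in enumerate(self.individual_ids)}
        rows = [index[str(i)] for i in individual_ids]
        return PhenotypeVector(self.values[rows], list(individual_ids))


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    genotyped: bool
    role: str  # training | evaluation | none


@dataclass
class Pedigree:
    """Topologically sorted pedigree: every parent precedes its offspring."""

    records: list[PedigreeRecord]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.role not in ROLES:
                raise PedigreeError(f"unknown role {rec.role!r} for {rec.id}")
            for parent in (rec.sire, rec.dam):
                if parent is not None and parent not in seen:
                    raise PedigreeError(
                        f"pedigree not sorted: parent {parent!r} of {rec.id!r} "
                        "does not precede it"
                    )
            if rec.id in seen:
                raise PedigreeError(f"duplicate individual {rec.id!r}")
            seen.add(rec.id)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def ids_with_role(self, role: str) -> list[str]:
        return [r.id for r in self.records if r.role == role]

    @property
    def training_ids(self) -> list[str]:
        return self.ids_with_role("training")

    @property
    def evaluation_ids(self) -> list[str]:
        return self.ids_with_role("evaluation")

    @property
    def genotyped_ids(self) -> list[str]:
        return [r.id for r in self.records if r.genotyped]


@dataclass(frozen=True)
class VarianceSpec:
    """Known total genetic variance and residual variance (trait units^2)."""

    genetic_variance: float
    residual_variance: float

    def __post_init__(self) -> None:
        if self.genetic_variance <= 0 or self.residual_variance <= 0:
            raise ValueError("variances must be strictly positive")

    @property
    def heritability(self) -> float:
        return self.genetic_variance / (self.genetic_variance + self.residual_variance)


# ---------------------------------------------------------------------------
# genotype I/O


def _read_matrix_tsv(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    marker_ids: list[str] | None = None
    individual_ids: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if marker_ids is None:
                marker_ids = fields[1:]
                continue
            if len(fields) != len(marker_ids) + 1:
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(marker_ids) + 1} fields, "
                    f"got {len(fields)}"
                )
            individual_ids.append(fields[0])
            row = np.empty(len(marker_ids))
            for j, tok in enumerate(fields[1:]):
                if tok == MISSING_TOKEN:
                    row[j] = np.nan
                else:
                    try:
                        val = float(tok)
                    except ValueError:
                        raise GenotypeParseError(
                            f"{path}:{lineno}: bad dosage token {tok!r}"
                        ) from None
                    if val not in (0.0, 1.0, 2.0):
                        raise GenotypeParseError(
                            f"{path}:{lineno}: dosage must be 0/1/2/NA, got {tok!r}"
                        )
                    row[j] = val
            rows.append(row)
    if marker_ids is None:
        raise GenotypeParseError(f"{path}: empty genotype file")
    dosages = np.vstack(rows) if rows else np.empty((0, len(marker_ids)))
    return dosages, marker_ids, individual_ids


def _read_vcf(path: str) -> tuple[np.ndarray, list[str], list[str]]:
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(path)
    individual_ids = list(vcf.samples)
    marker_ids: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping non-biallelic record %s:%s", var.CHROM, var.POS)
            continue
        col = np.empty(len(individual_ids))
        for j, gt in enumerate(var.genotypes):
            alleles = [a for a in gt[:-1]]  # last entry is the phased flag
            if any(a < 0 for a in alleles):
                col[j] = np.nan
            else:
                col[j] = float(sum(1 for a in alleles if a == 1))
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        cols.append(col)
    dosages = np.column_stack(cols) if cols else np.empty((len(individual_ids), 0))
    return dosages, marker_ids, individual_ids


def read_genotypes(path: str, dialect: str = "matrix-tsv") -> GenotypeMatrix:
    """Read genotypes from ``matrix-tsv`` or ``vcf`` into a GenotypeMatrix.

    Allele frequencies are estimated from all individuals in the file, missing
    dosages mean-imputed, and monomorphic columns dropped (see
    :meth:`GenotypeMatrix.from_dosages`).
    """
    if dialect == "matrix-tsv":
        dosages, marker_ids, individual_ids = _read_matrix_tsv(path)
    elif dialect == "vcf":
        dosages, marker_ids, individual_ids = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype dialect {dialect!r}")
    return GenotypeMatrix.from_dosages(dosages, marker_ids, individual_ids)


def write_genotypes(gm: GenotypeMatrix, path: str) -> None:
    """Write the dosage matrix in the matrix-TSV dialect (bit-exact round trip
    for integer dosages; imputed entries are written back as ``NA`` is not
    recoverable, so they are written with full precision)."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(gm.marker_ids) + "\n")
        for i, ind in enumerate(gm.individual_ids):
            toks = []
            for v in gm.dosages[i]:
                toks.append(str(int(v)) if float(v).is_integer() else repr(float(v)))
            fh.write(ind + "\t" + "\t".join(toks) + "\n")


# ---------------------------------------------------------------------------
# phenotype I/O


def read_phenotypes(path: str) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["id", "value"], dtype={"id": str})
    return PhenotypeVector(df["value"].to_numpy(float), df["id"].tolist())


def write_phenotypes(ph: PhenotypeVector, path: str) -> None:
    with open(path, "w") as fh:
        for ind, v in zip(ph.individual_ids, ph.values):
            fh.write(f"{ind}\t{float(v)!r}\n")


# ---------------------------------------------------------------------------
# pedigree I/O


def _toposort_records(raw: list[PedigreeRecord]) -> list[PedigreeRecord]:
    by_id = {r.id: r for r in raw}
    order = {r.id: i for i, r in enumerate(raw)}
    ts: TopologicalSorter[str] = TopologicalSorter()
    for r in raw:
        parents = [p for p in (r.sire, r.dam) if p is not None and p in by_id]
        ts.add(r.id, *parents)
    try:
        ts.prepare()
    except CycleError as exc:
        raise PedigreeError(f"cyclic parentage: {exc.args[1]}") from None
    out: list[str] = []
    while ts.is_active():
        ready = sorted(ts.get_ready(), key=order.__getitem__)
        out.extend(ready)
        ts.done(*ready)
    if out != [r.id for r in raw]:
        logger.info("pedigree re-sorted so parents precede offspring")
    return [by_id[i] for i in out]


def read_pedigree(path: str) -> Pedigree:
    """Read a 5-column pedigree TSV, re-sorting parents before offspring.

    Unknown parents are coded ``0`` or ``.``.  A parent id that never appears
    as an individual is treated as unknown (founder slot) with a warning.
    """
    raw: list[PedigreeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise PedigreeError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            pid, sire, dam, genotyped, role = fields
            sire = None if sire in UNKNOWN_PARENT_TOKENS else sire
            dam = None if dam in UNKNOWN_PARENT_TOKENS else dam
            if pid in (sire, dam):
                raise PedigreeError(f"{path}:{lineno}: {pid!r} listed as its own parent")
            if role not in ROLES:
                raise PedigreeError(f"{path}:{lineno}: unknown role token {role!r}")
            raw.append(PedigreeRecord(pid, sire, dam, genotyped not in ("0", ""), role))
    known = {r.id for r in raw}
    cleaned = []
    for r in raw:
        sire = r.sire if r.sire in known else None
        dam = r.dam if r.dam in known else None
        if (sire, dam) != (r.sire, r.dam):
            logger.warning("parent of %s not in pedigree; treated as unknown", r.id)
            r = PedigreeRecord(r.id, sire, dam, r.genotyped, r.role)
        cleaned.append(r)
    return Pedigree(_toposort_records(cleaned))


def write_pedigree(ped: Pedigree, path: str) -> None:
    with open(path, "w") as fh:
        for r in ped.records:
            fh.write("\t".join([
                r.id, r.sire or "0", r.dam or "0",
                "1" if r.genotyped else "0", r.role,
            ]) + "\n")


# ---------------------------------------------------------------------------
# estimated-effects I/O


def write_effects(path: str, marker_ids: Sequence[str], g_hat: np.ndarray,
                  prob_big: np.ndarray | None = None) -> None:
    """Write estimated marker effects as TSV (marker_id, g_hat, posterior_prob_big)."""
    g_hat = np.asarray(g_hat, dtype=float)
    if prob_big is None:
        prob_big = np.full(g_hat.shape, np.nan)
    with open(path, "w") as fh:
        fh.write("marker_id\tg_hat\tposterior_prob_big\n")
        for m, g, p in zip(marker_ids, g_hat, prob_big):
            fh.write(f"{m}\t{float(g)!r}\t{float(p)!r}\n")


def read_effects(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str})
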