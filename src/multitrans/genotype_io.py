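"""Genotype and phenotype I/O, filtering, and standardization.

The text dialect is the EMMA/pylmm matrix layout: one row per marker with a
four-column leading block (chromosome, marker id, base-pair position, allele
placeholder) followed by one dosage per individual.  Dosages are additive
allele counts in {0, 1, 2}; missing entries are coded ``NA`` or ``-9``.
PLINK ``.bed/.bim/.fam`` triples are supported in SNP-major layout.

Positions are 1-based inclusive base pairs.  Markers are sorted by
(chromosome, position) on read because the sliding-window sampler assumes
genomic order; chromosomes keep their order of first appearance.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyPanelError, InputError, ParseError, ValidationError

_MISSING_TOKENS = {"NA", "-9", "nan", "NaN"}


def chromosome_blocks(chromosomes: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous [start, stop) runs of equal chromosome label, in order."""
    blocks: list[tuple[int, int]] = []
    start = 0
    for i in range(1, len(chromosomes) + 1):
        if i == len(chromosomes) or chromosomes[i] != chromosomes[start]:
            blocks.append((start, i))
            start = i
    return blocks


@dataclass
class GenotypeMatrix:
    """An n-individuals x m-markers dosage matrix with marker metadata.

    ``dosages`` holds raw allele counts (possibly with NaN for missing) or,
    after :func:`standardize`, real values with each column at mean 0 and
    variance 1 (population variance, denominator n).
    """

    dosages: np.ndarray
    marker_ids: np.ndarray
    chromosomes: np.ndarray
    positions: np.ndarray
    individual_ids: np.ndarray
    standardized: bool = False

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.chromosomes = np.asarray(self.chromosomes, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        n, m = self.dosages.shape
        if n < 2:
            raise ValidationError(f"need at least 2 individuals, got {n}")
        if m < 1:
            raise ValidationError("need at least 1 marker")
        for name, arr, want in (
            ("marker_ids", self.marker_ids, m),
            ("chromosomes", self.chromosomes, m),
            ("positions", self.positions, m),
            ("individual_ids", self.individual_ids, n),
        ):
            if len(arr) != want:
                raise ValidationError(f"{name}: expected {want} entries, got {len(arr)}")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")
        for start, stop in chromosome_blocks(self.chromosomes):
            pos = self.positions[start:stop]
            if np.any(np.diff(pos) <= 0):
                raise ValidationError(
                    f"positions not strictly increasing on chromosome "
                    f"{self.chromosomes[start]!r}"
                )
        if self.standardized:
            if np.isnan(self.dosages).any():
                raise ValidationError("standardized matrix contains missing entries")
            mu = self.dosages.mean(axis=0)
            var = self.dosages.var(axis=0)
            if np.abs(mu).max() > 1e-8 or np.abs(var - 1).max() > 1e-6:
                raise ValidationError("standardized flag set but columns are not N(0,1)-scaled")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)


@dataclass
class PhenotypeVector:
    """One quantitative phenotype value per individual."""

    values: np.ndarray
    individual_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.individual_ids is None:
            self.individual_ids = np.array(
                [f"ind{i:04d}" for i in range(len(self.values))], dtype=object
            )
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if len(self.individual_ids) != len(self.values):
            raise ValidationError("phenotype ids and values differ in length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


def _sort_markers(dosages, marker_ids, chromosomes, positions):
    """Sort columns by (chromosome in order of first appearance, position)."""
    order_of = {}
    for c in chromosomes:
        if c not in order_of:
            order_of[c] = len(order_of)
    codes = np.array([order_of[c] for c in chromosomes])
    idx = np.lexsort((positions, codes))
    return (
        dosages[:, idx],
        np.asarray(marker_ids, dtype=object)[idx],
        np.asarray(chromosomes, dtype=object)[idx],
        np.asarray(positions)[idx],
    )


def read_genotypes(path: str | os.PathLike, format: str = "matrix") -> GenotypeMatrix:
    """Read a raw genotype matrix from ``matrix`` text or ``plink-bed``."""
    if format == "matrix":
        return _read_matrix(path)
    if format == "plink-bed":
        return read_plink(path)
    raise InputError(f"unknown genotype format {format!r}")


def _read_matrix(path) -> GenotypeMatrix:
    if not os.path.exists(path):
        raise InputError(f"genotype file not found: {path}")
    rows, mids, chroms, poss = [], [], [], []
    n = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 5 fields "
                    f"(chrom id pos allele dosages...), got {len(tokens)}"
                )
            chrom, mid, pos_s = tokens[0], tokens[1], tokens[2]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad position {pos_s!r}") from exc
            vals = []
            for tok in tokens[4:]:
                if tok in _MISSING_TOKENS:
                    vals.append(np.nan)
                else:
                    try:
                        vals.append(float(tok))
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: bad dosage {tok!r}"
                        ) from exc
            if n is None:
                n = len(vals)
            elif len(vals) != n:
                raise ParseError(
                    f"{path}: line {lineno}: expected {n} dosages, got {len(vals)}"
                )
            rows.append(vals)
            mids.append(mid)
            chroms.append(chrom)
            poss.append(pos)
    if not rows:
        raise ParseError(f"{path}: no marker rows")
    dosages = np.asarray(rows, dtype=float).T  # rows are markers on disk
    if len(set(mids)) != len(mids):
        dupes = sorted({x for x in mids if mids.count(x) > 1})
        raise ValidationError(f"{path}: duplicate marker ids {dupes[:5]}")
    dosages, mids, chroms, poss = _sort_markers(dosages, mids, chroms, poss)
    ind_ids = [f"ind{i:04d}" for i in range(dosages.shape[0])]
    return GenotypeMatrix(dosages, mids, chroms, poss, ind_ids)


def write_genotypes(g: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the matrix text dialect (one row per marker)."""
    with open(path, "w") as fh:
        for j in range(g.m):
            fields = [str(g.chromosomes[j]), str(g.marker_ids[j]), str(g.positions[j]), "A"]
            for v in g.dosages[:, j]:
                if np.isnan(v):
                    fields.append("NA")
                elif float(v).is_integer():
                    fields.append(str(int(v)))
                else:
                    fields.append(repr(float(v)))
            fh.write(" ".join(fields) + "\n")


# -- PLINK binary ----------------------------------------------------------

_PLINK_MAGIC = b"\x6c\x1b"
# 2-bit codes per sample: 00 hom A1 (dosage 2), 01 missing, 10 het, 11 hom A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(path: str | os.PathLike) -> GenotypeMatrix:
    """Read a PLINK .bed/.bim/.fam triple (SNP-major only).

    ``path`` may be the .bed file or the shared prefix.  Dosages count the
    A1 allele additively.
    """
    prefix = str(path)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    bed, bim, fam = prefix + ".bed", prefix + ".bim", prefix + ".fam"
    for p in (bed, bim, fam):
        if not os.path.exists(p):
            raise InputError(f"PLINK file not found: {p}")
    ind_ids = []
    with open(fam) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 2:
                raise ParseError(f"{fam}: line {lineno}: expected >= 2 fields")
            ind_ids.append(tokens[1])
    mids, chroms, poss = [], [], []
    with open(bim) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 6:
                raise ParseError(f"{bim}: line {lineno}: expected 6 fields")
            chroms.append(tokens[0])
            mids.append(tokens[1])
            try:
                poss.append(int(tokens[3]))
            except ValueError as exc:
                raise ParseError(f"{bim}: line {lineno}: bad position") from exc
    n, m = len(ind_ids), len(mids)
    raw = np.fromfile(bed, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:2]) != _PLINK_MAGIC:
        raise ParseError(f"{bed}: bad magic number, not a PLINK .bed file")
    if raw[2] != 1:
        raise InputError(f"{bed}: only SNP-major .bed layout is supported")
    nbytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != nbytes * m:
        raise ParseError(f"{bed}: size mismatch for {n} individuals x {m} markers")
    codes = body.reshape(m, nbytes)
    shifts = np.arange(4) * 2
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 3  # (m, nbytes, 4)
    dosages = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]].T  # (n, m)
    if len(set(mids)) != m:
        raise ValidationError(f"{bim}: duplicate marker ids")
    dosages, mids, chroms, poss = _sort_markers(dosages, mids, chroms, poss)
    return GenotypeMatrix(dosages, mids, chroms, poss, ind_ids)


def write_plink(g: GenotypeMatrix, prefix: str | os.PathLike) -> None:
    """Write a SNP-major .bed/.bim/.fam triple (raw dosages only)."""
    if g.standardized:
        raise ValidationError("PLINK output requires raw allele-count dosages")
    prefix = str(prefix)
    with open(prefix + ".fam", "w") as fh:
        for iid in g.individual_ids:
            fh.write(f"{iid} {iid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for j in range(g.m):
            fh.write(f"{g.chromosomes[j]} {g.marker_ids[j]} 0 {g.positions[j]} A C\n")
    code_of = {2.0: 0, 1.0: 2, 0.0: 3}
    n = g.n
    nbytes = (n + 3) // 4
    body = np.zeros((g.m, nbytes), dtype=np.uint8)
    for j in range(g.m):
        for i, v in enumerate(g.dosages[:, j]):
            code = 1 if np.isnan(v) else code_of.get(float(v))
            if code is None:
                raise ValidationError(
                    f"marker {g.marker_ids[j]}: dosage {v} is not in {{0,1,2,NA}}"
                )
            body[j, i // 4] |= code << (2 * (i % 4))
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC + b"\x01")
        fh.write(body.tobytes())


# -- Phenotypes ------------------------------------------------------------


def read_phenotype(path: str | os.PathLike, individual_ids=None) -> PhenotypeVector:
    """Read one value per line, or a two-column (id, value) table."""
    if not os.path.exists(path):
        raise InputError(f"phenotype file not found: {path}")
    ids, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                if len(tokens) == 1:
                    vals.append(float(tokens[0]))
                    ids.append(None)
                elif len(tokens) == 2:
                    ids.append(tokens[0])
                    vals.append(float(tokens[1]))
                else:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 1 or 2 fields, got {len(tokens)}"
                    )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: bad value") from exc
    if not vals:
        raise ParseError(f"{path}: empty phenotype file")
    if any(i is not None for i in ids):
        out_ids = np.asarray(ids, dtype=object)
        if individual_ids is not None:
            lookup = dict(zip(ids, vals))
            missing = [i for i in individual_ids if i not in lookup]
            if missing:
                raise ValidationError(f"{path}: no phenotype for individuals {missing[:5]}")
            vals = [lookup[i] for i in individual_ids]
            out_ids = np.asarray(individual_ids, dtype=object)
        return PhenotypeVector(np.asarray(vals), out_ids)
    return PhenotypeVector(np.asarray(vals), individual_ids)


def write_phenotype(y: PhenotypeVector, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iid, v in zip(y.individual_ids, y.values):
            fh.write(f"{iid}\t{float(v)!r}\n")


# -- Filtering and standardization ----------------------------------------


def minor_allele_frequencies(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker MAF from non-missing dosages: min(f, 1-f), f = mean/2."""
    if g.standardized:
        raise ValidationError("MAF is defined on raw allele counts")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        f = np.nanmean(g.dosages, axis=0) / 2.0
    return np.minimum(f, 1.0 - f)


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.05, missing_max: float = 0.10
) -> GenotypeMatrix:
    """Keep markers with MAF >= ``maf_min`` and missing fraction <= ``missing_max``.

    The 5 % MAF / 10 % missingness defaults are the conventional panel QC
    used for mouse and human GWAS panels.
    """
    if g.standardized:
        raise ValidationError("filter_markers expects raw dosages")
    if not 0 <= maf_min <= 0.5:
        raise ValidationError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValidationError("missing_max must be in [0, 1]")
    maf = minor_allele_frequencies(g)
    miss = np.isnan(g.dosages).mean(axis=0)
    keep = (np.nan_to_num(maf, nan=0.0) >= maf_min) & (miss <= missing_max)
    if not keep.any():
        raise EmptyPanelError(
            f"all {g.m} markers removed (maf_min={maf_min}, missing_max={missing_max})"
        )
    return GenotypeMatrix(
        g.dosages[:, keep],
        g.marker_ids[keep],
        g.chromosomes[keep],
        g.positions[keep],
        g.individual_ids,
        standardized=False,
    )


def standardize(g: GenotypeMatrix) -> GenotypeMatrix:
    """Mean-impute missing entries, then scale each column to mean 0, variance 1.

    The variance uses denominator n (population variance), so for two
    standardized columns the Pearson correlation is exactly the inner product
    divided by n.  Idempotent to numerical tolerance.
    """
    X = g.dosages.copy()
    nan_mask = np.isnan(X)
    if nan_mask.any():
        if nan_mask.all(axis=0).any():
            j = int(np.where(nan_mask.all(axis=0))[0][0])
            raise ValidationError(f"marker {g.marker_ids[j]} is entirely missing")
        col_mean = np.nanmean(np.where(nan_mask, np.nan, X), axis=0)
        X[nan_mask] = np.broadcast_to(col_mean, X.shape)[nan_mask]
    mu = X.mean(axis=0)
    Xc = X - mu
    sd = Xc.std(axis=0)  # ddof=0
    zero = sd <= 1e-12
    if zero.any():
        j = int(np.where(zero)[0][0])
        raise ValidationError(
            f"marker {g.marker_ids[j]} has zero variance; filter monomorphic "
            f"markers before standardizing"
        )
    return replace(g, dosages=Xc / sd, standardized=True)
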