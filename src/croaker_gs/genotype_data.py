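"""Genotype matrices: I/O, QC statistics, filtering, imputation, standardization.

Genotypes are coded as counts of the coded allele 'a': 0 for A/A, 1 for A/a,
2 for a/a.  For VCF input the coded allele is the ALT allele; for the
matrix-text format the coding is whatever the file states.  The coded-allele
frequency p_j is therefore not necessarily the minor allele frequency;
MAF = min(p_j, 1 - p_j).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    ConfigurationError,
    GenotypeParseError,
    GenotypeValidationError,
    MonomorphicMarkerError,
)

log = logging.getLogger(__name__)

MARKER_COLUMNS = ["marker_id", "chrom", "pos"]


@dataclass
class GenotypeMatrix:
    """n samples x p markers of integer-coded SNP genotypes with a missing mask.

    ``codes`` is float to admit real-valued mean-dosage imputation downstream;
    raw (un-imputed) entries are in {0, 1, 2} wherever ``missing`` is False.
    """

    sample_ids: list[str]
    markers: pd.DataFrame  # columns marker_id, chrom, pos
    codes: np.ndarray      # (n, p) float
    missing: np.ndarray    # (n, p) bool

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, p = len(self.sample_ids), len(self.markers)
        if self.codes.shape != (n, p) or self.missing.shape != (n, p):
            raise GenotypeValidationError(
                f"codes/missing shape {self.codes.shape}/{self.missing.shape} "
                f"does not match {n} samples x {p} markers"
            )
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError("duplicate sample ids")
        if self.markers["marker_id"].duplicated().any():
            dups = self.markers.loc[self.markers["marker_id"].duplicated(), "marker_id"]
            raise GenotypeValidationError(f"duplicate marker ids: {list(dups[:5])}")
        if (self.markers["pos"] < 0).any():
            raise GenotypeValidationError("negative marker positions")
        obs = self.codes[~self.missing]
        if not np.all(np.isfinite(obs)):
            raise GenotypeValidationError("non-finite genotype codes outside missing mask")
        if obs.size and (obs.min() < 0 or obs.max() > 2):
            raise GenotypeValidationError("genotype codes outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to marker indices/boolean mask ``keep`` (order kept)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            markers=self.markers.iloc[keep].reset_index(drop=True),
            codes=self.codes[:, keep].copy(),
            missing=self.missing[:, keep].copy(),
        )

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in keep],
            markers=self.markers.copy(),
            codes=self.codes[keep].copy(),
            missing=self.missing[keep].copy(),
        )


@dataclass
class MarkerQCStats:
    """Per-marker QC statistics, computed over non-missing calls only."""

    p_coded: np.ndarray       # frequency of coded allele 'a', in [0, 1]
    maf: np.ndarray           # min(p, 1-p)
    missing_rate: np.ndarray
    hwe_p: np.ndarray         # 1-df chi-square HWE test p-value, in (0, 1]
    n_called: np.ndarray
    all_missing: np.ndarray   # markers whose stats are undefined

    def __len__(self) -> int:
        return len(self.p_coded)


@dataclass
class PhenotypeTable:
    """Trait records aligned with a GenotypeMatrix; sex levels are {1, 2}."""

    sample_ids: list[str]
    values: np.ndarray
    sex: np.ndarray
    trait: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        if not (len(self.sample_ids) == len(self.values) == len(self.sex)):
            raise GenotypeValidationError("phenotype table fields have unequal lengths")
        if not set(np.unique(self.sex)) <= {1, 2}:
            raise GenotypeValidationError("sex levels must be within {1, 2}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, self.trait: self.values, "sex": self.sex}
        )


# ---------------------------------------------------------------------------
# I/O

_NA_STRINGS = {"NA", "NaN", "nan", "."}


def _read_matrix_text(path: str, sidecar: str | None) -> GenotypeMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2 or header[0] != "sample_id":
            raise GenotypeParseError(
                f"{path}:1: header must start with 'sample_id' followed by marker ids"
            )
        marker_ids = header[1:]
        sample_ids, rows, mask_rows = [], [], []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(header):
                raise GenotypeParseError(
                    f"{path}:{lineno}: expected {len(header)} columns, found {len(cells)}"
                )
            sample_ids.append(cells[0])
            row = np.empty(len(marker_ids))
            miss = np.zeros(len(marker_ids), dtype=bool)
            for j, cell in enumerate(cells[1:]):
                if cell in _NA_STRINGS:
                    row[j], miss[j] = 0.0, True
                else:
                    try:
                        row[j] = float(cell)
                    except ValueError as exc:
                        raise GenotypeParseError(
                            f"{path}:{lineno}: bad genotype cell {cell!r}"
                        ) from exc
            rows.append(row)
            mask_rows.append(miss)
    if sidecar is not None:
        markers = pd.read_csv(sidecar, sep="\t", dtype={"chrom": str})
        if list(markers.columns) != MARKER_COLUMNS:
            raise GenotypeParseError(
                f"{sidecar}: sidecar columns must be {MARKER_COLUMNS}"
            )
        if list(markers["marker_id"]) != marker_ids:
            raise GenotypeParseError(f"{sidecar}: sidecar marker ids do not match header")
    else:
        markers = pd.DataFrame(
            {"marker_id": marker_ids, "chrom": "0", "pos": np.arange(len(marker_ids))}
        )
    return GenotypeMatrix(sample_ids, markers, np.array(rows), np.array(mask_rows))


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    marker_ids, chroms, poss, cols, masks = [], [], [], [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(var.gt_types)
        code = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=0.0)
        miss = gt == 2
        marker_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        cols.append(code)
        masks.append(miss)
    if n_skipped:
        log.info("read_genotypes: skipped %d non-biallelic/non-SNP records", n_skipped)
    markers = pd.DataFrame({"marker_id": marker_ids, "chrom": chroms, "pos": poss})
    codes = np.column_stack(cols) if cols else np.empty((len(sample_ids), 0))
    missing = np.column_stack(masks) if masks else np.empty((len(sample_ids), 0), bool)
    return GenotypeMatrix(sample_ids, markers, codes, missing)


def read_genotypes(path: str, format: str = "matrix-text",
                   sidecar: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``matrix-text`` format.

    Multi-allelic VCF records are skipped (count logged).  The matrix-text
    format is a tab-separated table: header ``sample_id`` + marker ids, one
    row per sample, cells in {0,1,2,NA}; marker metadata comes from an
    optional sidecar TSV with columns marker_id, chrom, pos.
    """
    if format == "matrix-text":
        return _read_matrix_text(path, sidecar)
    if format == "vcf":
        return _read_vcf(path)
    raise ConfigurationError(f"unknown genotype format {format!r}")


def write_genotypes(g: GenotypeMatrix, path: str, sidecar: str | None = None) -> None:
    """Write matrix-text (and optionally the marker-metadata sidecar).

    Integer-valued codes are written as integers so that a read round-trips
    codes and the missing mask bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(["sample_id", *g.markers["marker_id"]]) + "\n")
        for i, sid in enumerate(g.sample_ids):
            cells = [sid]
            for j in range(g.n_markers):
                if g.missing[i, j]:
                    cells.append("NA")
                else:
                    v = g.codes[i, j]
                    cells.append(str(int(v)) if v == int(v) else repr(float(v)))
            fh.write("\t".join(cells) + "\n")
    if sidecar is not None:
        g.markers.to_csv(sidecar, sep="\t", index=False)


# ---------------------------------------------------------------------------
# QC statistics and filtering


def compute_marker_stats(g: GenotypeMatrix) -> MarkerQCStats:
    """Coded-allele frequency, MAF, missing rate and HWE test per marker.

    p_j = (2 n_aa + n_Aa) / (2 n_called); the HWE p-value is from a 1-df
    chi-square test of observed genotype counts against expectations at p_j.
    Markers with all calls missing are flagged; their statistics are NaN.
    """
    n = g.n_samples
    called = ~g.missing
    n_called = called.sum(axis=0)
    all_missing = n_called == 0
    if all_missing.any():
        log.warning("compute_marker_stats: %d markers have no calls", all_missing.sum())

    codes = np.where(called, g.codes, np.nan)
    n2 = np.nansum(codes == 2, axis=0).astype(float)   # a/a
    n1 = np.nansum(codes == 1, axis=0).astype(float)   # A/a
    n0 = n_called - n1 - n2                            # A/A

    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n_called)
        maf = np.minimum(p, 1 - p)
        missing_rate = g.missing.sum(axis=0) / n
        q = 1 - p
        exp0, exp1, exp2 = n_called * q**2, n_called * 2 * p * q, n_called * p**2
        chi2 = np.zeros(len(p))
        poly = ~all_missing & (p > 0) & (p < 1)
        for obs, exp in ((n0, exp0), (n1, exp1), (n2, exp2)):
            chi2[poly] += (obs[poly] - exp[poly]) ** 2 / exp[poly]
        hwe_p = np.ones(len(p))
        hwe_p[poly] = sps.chi2.sf(chi2[poly], df=1)
    p[all_missing] = np.nan
    maf[all_missing] = np.nan
    hwe_p[all_missing] = np.nan

    return MarkerQCStats(p, maf, missing_rate, hwe_p, n_called, all_missing)


DEFAULT_THRESHOLDS = {"max_missing": 0.20, "min_maf": 0.05, "min_hwe_p": 0.001}


def filter_markers(g: GenotypeMatrix, s: MarkerQCStats,
                   thresholds: dict | None = None) -> GenotypeMatrix:
    """Discard markers failing missing-rate, MAF or HWE thresholds.

    Removal rules (inclusive on the missing bound, as in the study's QC):
    missing_rate >= max_missing, maf < min_maf, hwe_p < min_hwe_p — each
    evaluated on the supplied stats, so per-rule removal counts are
    unambiguous.  Survivor order is preserved.
    """
    th = dict(DEFAULT_THRESHOLDS, **(thresholds or {}))
    for key, val in th.items():
        if not 0 <= val <= 1:
            raise ConfigurationError(f"threshold {key}={val} outside [0, 1]")
    if len(s) != g.n_markers:
        raise GenotypeValidationError("stats not aligned with markers")

    bad_missing = s.missing_rate >= th["max_missing"]
    with np.errstate(invalid="ignore"):
        bad_maf = (s.maf < th["min_maf"]) | np.isnan(s.maf)
        bad_hwe = (s.hwe_p < th["min_hwe_p"]) | np.isnan(s.hwe_p)
    log.info(
        "filter_markers: removed %d by missing>=%.2f, %d by maf<%.2f, %d by hwe_p<%g "
        "(%d unique) of %d",
        bad_missing.sum(), th["max_missing"], bad_maf.sum(), th["min_maf"],
        bad_hwe.sum(), th["min_hwe_p"], (bad_missing | bad_maf | bad_hwe).sum(),
        g.n_markers,
    )
    return g.subset_markers(~(bad_missing | bad_maf | bad_hwe))


def impute_missing(g: GenotypeMatrix, s: MarkerQCStats, mode: str = "mean-dosage",
                   seed: int = 0) -> GenotypeMatrix:
    """Fill missing entries; returns a matrix with an empty missing mask.

    ``mean-dosage`` writes the expected dosage 2 p_j (real-valued);
    ``hwe-sample`` draws 0/1/2 with Hardy-Weinberg probabilities at p_j.
    Non-missing entries are unchanged.
    """
    if mode not in ("mean-dosage", "hwe-sample"):
        raise ConfigurationError(f"unknown imputation mode {mode!r}")
    if np.isnan(s.p_coded[np.any(g.missing, axis=0)]).any():
        raise MonomorphicMarkerError("cannot impute markers with undefined p_j")
    codes = g.codes.copy()
    if g.missing.any():
        rows, cols = np.nonzero(g.missing)
        if mode == "mean-dosage":
            codes[rows, cols] = 2 * s.p_coded[cols]
        else:
            rng = np.random.default_rng(seed)
            codes[rows, cols] = rng.binomial(2, s.p_coded[cols]).astype(float)
    return GenotypeMatrix(
        list(g.sample_ids), g.markers.copy(), codes,
        np.zeros_like(g.missing),
    )


def standardize(g_or_codes, s: MarkerQCStats | None = None,
                freqs: np.ndarray | None = None,
                monomorphic: str = "error") -> np.ndarray:
    """Standardized genotypes X' = (X - 2 p_j) / sqrt(2 p_j (1 - p_j)).

    Frequencies come from ``freqs`` if given, else from the supplied stats.
    Under exact Hardy-Weinberg frequencies each column then has mean 0 and
    variance 1.  ``monomorphic='zero'`` writes an all-zero column for markers
    with p in {0, 1} (useful when standardizing a training split with
    frequencies estimated on that split); the default raises.
    """
    codes = g_or_codes.codes if isinstance(g_or_codes, GenotypeMatrix) else np.asarray(g_or_codes, float)
    if isinstance(g_or_codes, GenotypeMatrix) and g_or_codes.missing.any():
        raise GenotypeValidationError("standardize requires imputed genotypes")
    p = np.asarray(freqs if freqs is not None else s.p_coded, dtype=float)
    if codes.shape[1] != len(p):
        raise GenotypeValidationError("frequency vector not aligned with markers")
    mono = (p <= 0) | (p >= 1)
    if mono.any():
        if monomorphic == "error":
            idx = np.flatnonzero(mono)[:5]
            raise MonomorphicMarkerError(
                f"monomorphic markers at columns {list(idx)}; filter before standardizing"
            )
        p = np.where(mono, 0.5, p)  # placeholder; columns zeroed below
    x = (codes - 2 * p) / np.sqrt(2 * p * (1 - p))
    if mono.any():
        x[:, mono] = 0.0
    return x


def allele_frequencies(codes: np.ndarray) -> np.ndarray:
    """Coded-allele frequencies of an imputed dosage matrix: column mean / 2."""
    return np.asarray(codes, float).mean(axis=0) / 2.0
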