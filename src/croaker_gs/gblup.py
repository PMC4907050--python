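"""Genomic BLUP: the genomic relationship matrix, the mixed-model solver at the
individual level (GBLUP) and the equivalent marker-level ridge solver (RR-BLUP),
plus GEBV prediction for untrained candidates.

The model is y = W b + u + e with u ~ (0, G sigma_u²), e ~ (0, I sigma_e²),
W the fixed design (intercept + sex).  GBLUP uses the shrinkage ratio
lambda = (1 - h²)/h²; RR-BLUP on column-standardized genotypes uses
lambda = p (1 - h²)/h² with p the marker count.  With the standardized-scale
kernel G = X'X'ᵀ/p the two parameterizations give identical GEBV — the pair
of ratios is the unique one with that property.  The classical centered
kernel (X - P)(X - P)ᵀ / (2 Σ p_i(1 - p_i)) is also provided and is the
default; it coincides with the standardized kernel only when all markers
share the same allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .exceptions import (
    ConfigurationError,
    LinearAlgebraError,
    MarkerAlignmentError,
    MonomorphicMarkerError,
)


@dataclass
class GenomicRelationship:
    """A genomic relationship kernel with the scaling information used."""

    G: np.ndarray
    denominator: float
    freqs: np.ndarray
    method: str = "vanraden"

    def __post_init__(self) -> None:
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise LinearAlgebraError("G not symmetric within 1e-10")


@dataclass
class GEBVResult:
    """GBLUP solution: per-sample GEBV and fixed-effect estimates."""

    sample_index: np.ndarray
    gebv: np.ndarray
    mu: float
    sex_effect: float | None
    lam: float
    alpha: np.ndarray    # (G + lam I)^-1 (y - W b), for kernel-route prediction


@dataclass
class MarkerEffects:
    """Per-marker additive effects on the standardized-genotype scale."""

    effects: np.ndarray
    method: str                       # "rr-blup" | "embayesb"
    marker_ids: list[str] | None = None
    mu: float = 0.0
    sex_effect: float | None = None


def build_g_matrix(codes: np.ndarray, p_freqs: np.ndarray | None = None,
                   method: str = "vanraden") -> GenomicRelationship:
    """Genomic relationship matrix from an imputed dosage matrix.

    ``vanraden``: G = (X - P)(X - P)ᵀ / (2 Σ p_i (1 - p_i)), with P the
    vector 2 p_i broadcast over individuals.  ``standardized``:
    G = X' X'ᵀ / p with X' the column-standardized genotypes — the scaling
    under which GBLUP with lambda=(1-h²)/h² equals RR-BLUP exactly.
    Frequencies default to the supplied cohort's own.
    """
    codes = np.atleast_2d(np.asarray(codes, float))
    p = codes.mean(axis=0) / 2.0 if p_freqs is None else np.asarray(p_freqs, float)
    if np.any((p <= 0) | (p >= 1)):
        idx = np.flatnonzero((p <= 0) | (p >= 1))[:5]
        raise MonomorphicMarkerError(
            f"monomorphic markers at columns {list(idx)}; filter before building G"
        )
    centered = codes - 2 * p
    if method == "vanraden":
        denom = float(2 * np.sum(p * (1 - p)))
        G = centered @ centered.T / denom
    elif method == "standardized":
        xs = centered / np.sqrt(2 * p * (1 - p))
        denom = float(codes.shape[1])
        G = xs @ xs.T / denom
    else:
        raise ConfigurationError(f"unknown G-matrix method {method!r}")
    G = (G + G.T) / 2
    return GenomicRelationship(G, denom, p, method)


def _fixed_design(n: int, sex: np.ndarray | None):
    """Intercept + one sex dummy (level 2 vs 1); dummy dropped if single-level."""
    if sex is None:
        return np.ones((n, 1)), False
    sex = np.asarray(sex)
    if len(np.unique(sex)) < 2:
        return np.ones((n, 1)), False
    return np.column_stack([np.ones(n), (sex == 2).astype(float)]), True


def _gls_fit(y: np.ndarray, W: np.ndarray, V: np.ndarray):
    """Solve the GLS fixed effects and return (b, alpha = V^-1 (y - W b))."""
    try:
        cf = sla.cho_factor(V)
    except sla.LinAlgError as exc:
        raise LinearAlgebraError(
            f"mixed-model coefficient matrix not positive definite "
            f"(condition number ~{np.linalg.cond(V):.3g})"
        ) from exc
    ViW = sla.cho_solve(cf, W)
    Viy = sla.cho_solve(cf, y)
    b = np.linalg.solve(W.T @ ViW, W.T @ Viy)
    alpha = Viy - ViW @ b
    return b, alpha


def solve_gblup(y: np.ndarray, sex: np.ndarray | None, G: GenomicRelationship,
                h2: float, ridge: float = 0.0) -> GEBVResult:
    """GEBV for the training samples by the individual-level mixed model.

    Solves the mixed-model equations with kernel inverse shrinkage
    lambda = (1 - h²)/h² through the equivalent variance form
    û = G (G + lambda I)^-1 (y - W b̂), which is defined even when G is
    singular.  ``ridge`` optionally adds a diagonal stabilizer to G first.
    """
    if not 0 < h2 < 1:
        raise ConfigurationError(f"h2={h2} outside (0, 1)")
    y = np.asarray(y, float)
    n = len(y)
    Gm = G.G + ridge * np.eye(n) if ridge else G.G
    if Gm.shape != (n, n):
        raise ConfigurationError("G dimension does not match phenotypes")
    lam = (1 - h2) / h2
    W, has_sex = _fixed_design(n, sex)
    b, alpha = _gls_fit(y, W, Gm + lam * np.eye(n))
    gebv = Gm @ alpha
    return GEBVResult(
        sample_index=np.arange(n), gebv=gebv, mu=float(b[0]),
        sex_effect=float(b[1]) if has_sex else None, lam=lam, alpha=alpha,
    )


def solve_rrblup(y: np.ndarray, sex: np.ndarray | None, x_std: np.ndarray,
                 h2: float, marker_ids: list[str] | None = None) -> MarkerEffects:
    """Marker effects by ridge regression with lambda = p (1 - h²)/h².

    Solved in the dual (n x n) form a = X'ᵀ (X'X'ᵀ + lambda I)^-1 (y - W b̂),
    identical to the primal ridge mixed-model solution and numerically
    aligned with ``solve_gblup`` on the standardized kernel.
    """
    if not 0 < h2 < 1:
        raise ConfigurationError(f"h2={h2} outside (0, 1)")
    y = np.asarray(y, float)
    x_std = np.asarray(x_std, float)
    n, p = x_std.shape
    lam = p * (1 - h2) / h2
    W, has_sex = _fixed_design(n, sex)
    b, alpha = _gls_fit(y, W, x_std @ x_std.T + lam * np.eye(n))
    effects = x_std.T @ alpha
    return MarkerEffects(
        effects=effects, method="rr-blup", marker_ids=marker_ids,
        mu=float(b[0]), sex_effect=float(b[1]) if has_sex else None,
    )


def predict_gebv(effects: MarkerEffects, x_std_candidates: np.ndarray,
                 marker_ids: list[str] | None = None) -> np.ndarray:
    """Candidate GEBV from marker effects: X'_cand · ĝ.

    Candidate genotypes must be standardized with the training cohort's
    frequencies; if both sides carry marker ids they are checked.
    """
    x = np.asarray(x_std_candidates, float)
    if x.shape[1] != len(effects.effects):
        raise MarkerAlignmentError(
            f"candidate marker count {x.shape[1]} != training {len(effects.effects)}"
        )
    if marker_ids is not None and effects.marker_ids is not None:
        bad = [a for a, b in zip(marker_ids, effects.marker_ids) if a != b]
        if bad:
            raise MarkerAlignmentError(f"mismatched marker ids, e.g. {bad[:5]}")
    return x @ effects.effects


def predict_gebv_kernel(g_cross: np.ndarray, fit: GEBVResult) -> np.ndarray:
    """Candidate GEBV through the kernel route: G_cand,train · alpha.

    ``g_cross`` is the candidate-by-training block of the relationship matrix
    built on the same scaling (and training frequencies) as the training G.
    Agrees with the marker route to numerical precision.
    """
    g_cross = np.atleast_2d(np.asarray(g_cross, float))
    if g_cross.shape[1] != len(fit.alpha):
        raise MarkerAlignmentError("cross-kernel block does not match training samples")
    return g_cross @ fit.alpha


def cross_kernel(codes_cand: np.ndarray, codes_train: np.ndarray,
                 G_train: GenomicRelationship) -> np.ndarray:
    """Candidate-by-training kernel block on the training G's scaling."""
    p = G_train.freqs
    cc = np.atleast_2d(np.asarray(codes_cand, float)) - 2 * p
    ct = np.asarray(codes_train, float) - 2 * p
    if G_train.method == "standardized":
        sd = np.sqrt(2 * p * (1 - p))
        cc, ct = cc / sd, ct / sd
    return cc @ ct.T / G_train.denominator
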