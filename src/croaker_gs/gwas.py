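"""Single-marker association scans under the fixed-effect trait model.

Each marker is tested by ordinary least squares of the phenotype on
(intercept, sex, dosage), with a t-test on the dosage coefficient.  Dosages
enter raw (0/1/2 plus imputed reals), so effect sizes keep trait units per
allele copy.  No relatedness correction and no multiple-testing correction
are applied: selection uses raw per-trait p-value thresholds, and
significant markers are expected to cluster in regions of high LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError
from .gblup import MarkerEffects, _fixed_design
from .genotype_data import GenotypeMatrix


@dataclass
class GWASResult:
    """Per-marker OLS scan results; untestable markers carry NaN statistics."""

    table: pd.DataFrame   # marker_id, chrom, pos, beta, se, t, p, testable
    n: int
    df: int


def _chrom_sort_key(chrom: pd.Series):
    """Numeric chromosomes first in numeric order, then other labels lexically."""
    num = pd.to_numeric(chrom, errors="coerce")
    return np.where(np.isnan(num), np.inf, num), chrom.astype(str)


def single_marker_scan(y: np.ndarray, sex: np.ndarray | None,
                       g: GenotypeMatrix) -> GWASResult:
    """OLS scan of y on (intercept, sex, dosage) for every marker.

    Implemented by projecting phenotype and dosages against the fixed
    design once and using the closed-form slope/SE per residualized column;
    identical to per-marker OLS, vectorized over markers.
    """
    y = np.asarray(y, float)
    n = len(y)
    if n <= 3:
        raise ConfigurationError("need more than 3 observations")
    if np.std(y) == 0:
        raise ConfigurationError("constant phenotype: scan undefined")
    if g.missing.any():
        raise ConfigurationError("scan requires imputed genotypes")

    W, _ = _fixed_design(n, sex)
    q = W.shape[1]
    Q, _r = np.linalg.qr(W)
    y_res = y - Q @ (Q.T @ y)
    X_res = g.codes - Q @ (Q.T @ g.codes)

    sxx = np.einsum("ij,ij->j", X_res, X_res)
    testable = sxx > n * 1e-12
    df = n - q - 1

    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(testable, (X_res.T @ y_res) / sxx, np.nan)
        syy = float(y_res @ y_res)
        sse = syy - beta**2 * sxx
        sse = np.clip(sse, 0.0, None)
        s2 = sse / df
        se = np.sqrt(s2 / sxx)
        with np.errstate(invalid="ignore"):
            t = beta / se
        p = 2 * sps.t.sf(np.abs(t), df)
    beta[~testable] = np.nan
    se[~testable] = np.nan
    t[~testable] = np.nan
    p[~testable] = np.nan

    table = g.markers.copy()
    table["beta"], table["se"], table["t"], table["p"] = beta, se, t, p
    table["testable"] = testable
    return GWASResult(table=table, n=n, df=df)


def significant_markers(res: GWASResult, p_threshold: float) -> list[str]:
    """Marker ids with p strictly below the threshold, sorted by (chrom, pos)."""
    if not 0 < p_threshold <= 1:
        raise ConfigurationError(f"p_threshold={p_threshold} outside (0, 1]")
    hits = res.table[res.table["p"] < p_threshold].copy()
    knum, kstr = _chrom_sort_key(hits["chrom"])
    hits["_kn"], hits["_ks"] = knum, kstr
    hits = hits.sort_values(["_kn", "_ks", "pos"], kind="mergesort")
    return list(hits["marker_id"])


def top_effect_markers(effects: MarkerEffects, count: int,
                       markers: pd.DataFrame | None = None) -> list[str]:
    """The ``count`` markers with largest |effect|; ties broken by (chrom, pos)."""
    p = len(effects.effects)
    if count > p:
        raise ConfigurationError(f"count={count} exceeds marker count {p}")
    if effects.marker_ids is not None:
        ids = list(effects.marker_ids)
    elif markers is not None:
        ids = list(markers["marker_id"])
    else:
        ids = [str(j) for j in range(p)]
    df = pd.DataFrame({"marker_id": ids, "absval": np.abs(effects.effects)})
    if markers is not None:
        meta = markers.set_index("marker_id")
        df["chrom"] = meta.loc[df["marker_id"], "chrom"].to_numpy()
        df["pos"] = meta.loc[df["marker_id"], "pos"].to_numpy()
        knum, kstr = _chrom_sort_key(df["chrom"])
        df["_kn"], df["_ks"] = knum, kstr
        df = df.sort_values(["absval", "_kn", "_ks", "pos"],
                            ascending=[False, True, True, True], kind="mergesort")
    else:
        df = df.sort_values("absval", ascending=False, kind="mergesort")
    return list(df["marker_id"].iloc[:count])


def manhattan_frame(markers: pd.DataFrame, values: np.ndarray,
                    value_name: str = "value") -> pd.DataFrame:
    """Chromosome-ordered frame with a cumulative x coordinate for plotting."""
    df = markers.copy()
    df[value_name] = np.asarray(values)
    knum, kstr = _chrom_sort_key(df["chrom"])
    df["_kn"], df["_ks"] = knum, kstr
    df = df.sort_values(["_kn", "_ks", "pos"], kind="mergesort").reset_index(drop=True)
    df["x"] = np.arange(len(df))
    return df.drop(columns=["_kn", "_ks"])


def plot_manhattan(markers: pd.DataFrame, values: np.ndarray, value_name: str,
                   path: str, highlight: list[str] | None = None,
                   title: str = "") -> None:
    """Manhattan-style plot of per-marker values, vertical lines at highlights."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = manhattan_frame(markers, values, value_name)
    fig, ax = plt.subplots(figsize=(10, 3))
    for i, (_, grp) in enumerate(df.groupby("chrom", sort=False)):
        ax.scatter(grp["x"], grp[value_name], s=4,
                   color="steelblue" if i % 2 == 0 else "darkorange")
    if highlight:
        xs = df.loc[df["marker_id"].isin(highlight), "x"]
        for x in xs:
            ax.axvline(x, color="grey", lw=0.5, alpha=0.5, zorder=0)
    ax.set_xlabel("marker (chromosome order)")
    ax.set_ylabel(value_name)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
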