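"""Replicated training-testing cross-validation and method comparison.

The study design is repeated random splits (not k-fold): in each replicate a
training set of the requested size is drawn uniformly at random, the rest is
the test set, and every competing method consumes the identical split.
Predictive ability is the Pearson correlation between test-set GEBV and the
raw observed phenotypes; methods are compared per training size with paired
t-tests across replicates.  Heritability is re-estimated by REML on every
training split and plugged into both predictors.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .embayesb import fit_embayesb, predict_embayesb
from .exceptions import ConfigurationError
from .gblup import build_g_matrix, cross_kernel, predict_gebv_kernel, solve_gblup
from .genotype_data import GenotypeMatrix, PhenotypeTable, allele_frequencies, standardize
from .reml import fit_reml

log = logging.getLogger(__name__)

METHODS = ("gblup", "embayesb")


@dataclass
class CVDesign:
    n_total: int
    n_train: int
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train >= self.n_total:
            raise ConfigurationError("n_train must be smaller than n_total")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates")

    @property
    def n_test(self) -> int:
        return self.n_total - self.n_train


@dataclass
class PairedTest:
    mean_diff: float
    t: float
    df: int
    p: float
    degenerate: bool = False


@dataclass
class CVResult:
    """Per-replicate abilities plus per-method summaries and split fingerprints."""

    table: pd.DataFrame     # columns: n_train, method, replicate, ability[, accuracy]
    summary: pd.DataFrame   # columns: n_train, method, mean, se, n_replicates
    paired_tests: dict      # (n_train, method_a, method_b) -> PairedTest
    split_hashes: dict      # (n_train, replicate) -> sha1 of the split indices


def make_splits(design: CVDesign):
    """Independent uniform train/test partitions per replicate, seeded."""
    rng = np.random.default_rng(design.seed)
    splits = []
    for _ in range(design.n_replicates):
        perm = rng.permutation(design.n_total)
        splits.append((np.sort(perm[: design.n_train]), np.sort(perm[design.n_train:])))
    return splits


def split_hash(train: np.ndarray, test: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.asarray(train, np.int64).tobytes())
    h.update(np.asarray(test, np.int64).tobytes())
    return h.hexdigest()


def predictive_ability(gebv_test: np.ndarray, y_test: np.ndarray) -> float:
    """Pearson correlation r(ĝ, y) between GEBV and observed phenotypes."""
    gebv_test = np.asarray(gebv_test, float)
    y_test = np.asarray(y_test, float)
    if len(gebv_test) != len(y_test) or len(y_test) < 3:
        raise ConfigurationError("need aligned vectors of length >= 3")
    if np.std(gebv_test) == 0 or np.std(y_test) == 0:
        raise ConfigurationError("predictive ability undefined: zero variance")
    return float(np.corrcoef(gebv_test, y_test)[0, 1])


def paired_t_test(abilities_a, abilities_b) -> PairedTest:
    """Classical paired t-test on per-replicate ability differences."""
    a = np.asarray(abilities_a, float)
    b = np.asarray(abilities_b, float)
    if a.shape != b.shape or len(a) < 2:
        raise ConfigurationError("need paired vectors of equal length >= 2")
    d = a - b
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return PairedTest(0.0, 0.0, df, 1.0)
        t = np.inf if d.mean() > 0 else -np.inf
        return PairedTest(float(d.mean()), t, df, 0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(len(d)))
    return PairedTest(float(d.mean()), float(t), df, float(2 * sps.t.sf(abs(t), df)))


def _fit_predict_one(method: str, y_tr, sex_tr, codes_tr, codes_te,
                     h2: float, seed: int) -> np.ndarray:
    """Fit one predictor on the training split and return test GEBV."""
    freqs = allele_frequencies(codes_tr)
    poly = (freqs > 0) & (freqs < 1)
    if method == "gblup":
        G = build_g_matrix(codes_tr[:, poly], freqs[poly])
        fit = solve_gblup(y_tr, sex_tr, G, h2)
        gc = cross_kernel(codes_te[:, poly], codes_tr[:, poly], G)
        return predict_gebv_kernel(gc, fit)
    if method == "embayesb":
        xs_tr = standardize(codes_tr, freqs=freqs, monomorphic="zero")
        xs_te = standardize(codes_te, freqs=freqs, monomorphic="zero")
        model = fit_embayesb(y_tr, sex_tr, xs_tr, h2_init=h2, seed=seed)
        return predict_embayesb(model, xs_te)
    raise ConfigurationError(f"unknown method {method!r}")


def run_cv(genotypes: GenotypeMatrix, phenotypes: PhenotypeTable,
           design: CVDesign, methods=METHODS,
           training_sizes=None, tbv: np.ndarray | None = None,
           adjust_sex: bool = False) -> CVResult:
    """Replicated cross-validation over training sizes and methods.

    For each (training size, replicate): h² is re-estimated by REML on the
    training split, each requested method is fitted on the identical split,
    and the test-set ability (and, when ``tbv`` is given, the true accuracy
    against simulated breeding values) is recorded.  Splits are drawn per
    training-size level and shared across methods within a replicate.
    ``adjust_sex`` correlates GEBV with sex-adjusted phenotypes instead of
    raw observations (off by default, the study's literal definition).
    """
    if genotypes.missing.any():
        raise ConfigurationError("run_cv requires QCed, imputed genotypes")
    if genotypes.sample_ids != phenotypes.sample_ids:
        raise ConfigurationError("genotype and phenotype samples not aligned")
    n = genotypes.n_samples
    sizes = list(training_sizes) if training_sizes is not None else [design.n_train]
    y_all = phenotypes.values
    sex_all = phenotypes.sex

    rows, hashes, tests = [], {}, {}
    for n_train in sizes:
        level = CVDesign(n, n_train, design.n_replicates,
                         seed=design.seed + 1000 * n_train)
        splits = make_splits(level)
        t0 = time.time()
        for rep, (tr, te) in enumerate(splits):
            hashes[(n_train, rep)] = split_hash(tr, te)
            y_tr, sex_tr = y_all[tr], sex_all[tr]
            y_te = y_all[te]
            if adjust_sex:
                from .gblup import _fixed_design
                W, _ = _fixed_design(len(te), sex_all[te])
                b, *_ = np.linalg.lstsq(W, y_te, rcond=None)
                y_te = y_te - W @ b + y_te.mean()
            codes_tr = genotypes.codes[tr]
            codes_te = genotypes.codes[te]
            freqs = allele_frequencies(codes_tr)
            poly = (freqs > 0) & (freqs < 1)
            G_reml = build_g_matrix(codes_tr[:, poly], freqs[poly])
            from .gblup import _fixed_design
            W_tr, _ = _fixed_design(len(tr), sex_tr)
            vc = fit_reml(y_tr, W_tr, G_reml.G)
            h2 = float(np.clip(vc.h2, 0.01, 0.99))
            for method in methods:
                try:
                    gebv_te = _fit_predict_one(method, y_tr, sex_tr, codes_tr,
                                               codes_te, h2, seed=level.seed + rep)
                    ability = predictive_ability(gebv_te, y_te)
                except Exception:   # noqa: BLE001 - record and continue
                    log.exception("run_cv: %s failed at n_train=%d rep=%d",
                                  method, n_train, rep)
                    ability = np.nan
                    gebv_te = None
                row = {"n_train": n_train, "method": method, "replicate": rep,
                       "ability": ability, "h2_train": vc.h2}
                if tbv is not None and gebv_te is not None:
                    from .synthetic_data import true_accuracy
                    row["accuracy"] = true_accuracy(gebv_te, tbv[te])
                rows.append(row)
        log.info("run_cv: n_train=%d done in %.1fs", n_train, time.time() - t0)

    table = pd.DataFrame(rows)
    summ = (table.groupby(["n_train", "method"])["ability"]
            .agg(mean="mean", sd=lambda s: s.std(ddof=1), n_replicates="count")
            .reset_index())
    summ["se"] = summ["sd"] / np.sqrt(summ["n_replicates"])
    summ = summ.drop(columns="sd")

    for n_train in sizes:
        sub = table[table["n_train"] == n_train]
        for i, ma in enumerate(methods):
            for mb in methods[i + 1:]:
                av = sub[sub["method"] == ma].sort_values("replicate")["ability"].to_numpy()
                bv = sub[sub["method"] == mb].sort_values("replicate")["ability"].to_numpy()
                ok = np.isfinite(av) & np.isfinite(bv)
                if ok.sum() < 2:
                    continue
                if ok.sum() < len(av):
                    log.info("paired t: dropped %d incomplete replicates", (~ok).sum())
                tests[(n_train, ma, mb)] = paired_t_test(av[ok], bv[ok])

    return CVResult(table=table, summary=summ, paired_tests=tests, split_hashes=hashes)
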