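"""Imputation accuracy metrics and GBLUP cross-validation.

Accuracy is scored as the squared Pearson correlation between imputed and
true alternate-allele dosages, pooled over all (taxon, site) calls, plus
concordance stratified by allele class — homozygous major / homozygous minor
/ heterozygous, classified from the *true* genotype and the *panel* allele
frequency — and by allele-frequency bin.  Genomic prediction uses the
VanRaden genomic relationship matrix in a single-random-effect mixed model
y = mu + g + e, g ~ N(0, G sigma_g^2), with heritability estimated per
training fold by REML on a grid and held-out phenotypes predicted by BLUP.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_model import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class AlleleClass(enum.IntEnum):
    """Truth-call classes: hom on the major allele, hom on the minor, het.

    A hom call is *major* when its allele has panel frequency >= 0.5
    (frequency exactly 0.5 counts as major by convention).
    """

    HOM_MAJOR = 0
    HOM_MINOR = 1
    HET = 2


CLASS_NAMES = ["hom_major", "hom_minor", "het"]


def _dosage_arrays(imputed, truth) -> tuple[np.ndarray, np.ndarray]:
    a = imputed.calls if isinstance(imputed, GenotypeMatrix) else np.asarray(imputed)
    b = truth.calls if isinstance(truth, GenotypeMatrix) else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def dosage_r2(imputed, truth) -> float:
    """Squared Pearson correlation of dosages pooled over all calls.

    Calls missing in either matrix are excluded.  Sign-blind by construction
    (an imputer predicting 2 - truth scores 1).  Returns NaN (with a warning)
    if either vector has zero variance.
    """
    a, b = _dosage_arrays(imputed, truth)
    mask = (a != MISSING) & (b != MISSING)
    x, y = a[mask].astype(float), b[mask].astype(float)
    if x.size == 0 or x.std() == 0 or y.std() == 0:
        logger.warning("dosage_r2: undefined (empty or zero-variance input)")
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def classify_calls(dosages: np.ndarray, panel_freqs: np.ndarray) -> np.ndarray:
    """Allele class per call from dosage and panel alt frequency (-1 missing)."""
    d = np.asarray(dosages)
    freqs = np.broadcast_to(np.asarray(panel_freqs, dtype=float), d.shape)
    out = np.full(d.shape, -1, dtype=np.int8)
    out[d == 1] = AlleleClass.HET
    hom_ref, hom_alt = d == 0, d == 2
    # a carried allele with frequency exactly 0.5 counts as major
    out[hom_ref & (freqs <= 0.5)] = AlleleClass.HOM_MAJOR
    out[hom_ref & (freqs > 0.5)] = AlleleClass.HOM_MINOR
    out[hom_alt & (freqs >= 0.5)] = AlleleClass.HOM_MAJOR
    out[hom_alt & (freqs < 0.5)] = AlleleClass.HOM_MINOR
    return out


def concordance_by_class(imputed, truth, panel_freqs: np.ndarray) -> pd.DataFrame:
    """Row-normalized 3x3 confusion matrix (true class x imputed class).

    Returns a DataFrame with a MultiIndex-free layout: proportion columns
    named by imputed class plus an ``n`` column of true-class call counts.
    """
    a, b = _dosage_arrays(imputed, truth)
    true_cls = classify_calls(b, panel_freqs)
    imp_cls = classify_calls(a, panel_freqs)
    valid = (true_cls >= 0) & (imp_cls >= 0)
    counts = np.zeros((3, 3), dtype=np.int64)
    for t in range(3):
        sel = valid & (true_cls == t)
        for p in range(3):
            counts[t, p] = int((imp_cls[sel] == p).sum())
    with np.errstate(invalid="ignore"):
        props = counts / counts.sum(axis=1, keepdims=True)
    df = pd.DataFrame(props, index=CLASS_NAMES, columns=CLASS_NAMES)
    df["n"] = counts.sum(axis=1)
    return df


def accuracy_by_frequency(
    imputed,
    truth,
    panel_freqs: np.ndarray,
    bins: Sequence[float] = (0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> pd.DataFrame:
    """Concordance per frequency bin, hom and het truth calls separately.

    Hom calls are binned by the panel frequency of the *true* allele they
    carry (which spans (0, 1]); het calls by the site's minor-allele
    frequency (so bins above 0.5 stay empty for them).  Bin edges are
    treated as (lo, hi] intervals; empty bins report n = 0 and NaN.
    """
    a, b = _dosage_arrays(imputed, truth)
    freqs = np.broadcast_to(np.asarray(panel_freqs, dtype=float), b.shape)
    valid = (a != MISSING) & (b != MISSING)
    concordant = a == b
    rows = []
    edges = np.asarray(bins, dtype=float)
    hom = valid & ((b == 0) | (b == 2))
    hom_freq = np.where(b == 2, freqs, 1.0 - freqs)
    het = valid & (b == 1)
    maf = np.minimum(freqs, 1.0 - freqs)
    for kind, sel, f in (("hom", hom, hom_freq), ("het", het, maf)):
        which = np.digitize(f[sel], edges, right=True) - 1
        conc = concordant[sel]
        for k in range(len(edges) - 1):
            in_bin = which == k
            n = int(in_bin.sum())
            rows.append(
                {
                    "call_type": kind,
                    "bin_lo": edges[k],
                    "bin_hi": edges[k + 1],
                    "concordance": float(conc[in_bin].mean()) if n else float("nan"),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def vanraden_g(dosages: np.ndarray, panel_freqs: np.ndarray) -> np.ndarray:
    """VanRaden (method 1) genomic relationship matrix.

    G = Z Z' / (2 sum p(1-p)) with Z the dosage matrix centered at 2p.
    Monomorphic sites (p in {0, 1}) are excluded; all-monomorphic input is
    an error.  Missing dosages are mean-imputed at 2p (zero contribution).
    """
    M = np.asarray(dosages, dtype=float)
    p = np.asarray(panel_freqs, dtype=float)
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    if M.shape[0] < 2:
        raise ValueError("need >= 2 taxa")
    if not poly.any():
        raise ValueError("no polymorphic sites for the relationship matrix")
    M, p = M[:, poly], p[poly]
    Z = np.where(M >= 0, M, 2 * p[None, :]) - 2 * p[None, :]
    denom = 2.0 * np.sum(p * (1 - p))
    return Z @ Z.T / denom


def _reml_h2_grid(
    d: np.ndarray, yr: np.ndarray, xr: np.ndarray, grid: np.ndarray
) -> float:
    """REML-profile heritability on a grid, after rotation by eig(G).

    d: eigenvalues of G_train; yr, xr: rotated phenotype and intercept.
    """
    n = len(yr)
    best_h2, best_ll = grid[0], -np.inf
    for h2 in grid:
        w = h2 * d + (1 - h2)
        if (w <= 0).any():
            continue
        xw = xr / w
        xx = xw @ xr
        mu = (xw @ yr) / xx
        r = yr - xr * mu
        sp2 = (r / w) @ r / (n - 1)
        ll = -0.5 * (np.log(w).sum() + (n - 1) * np.log(sp2) + np.log(xx))
        if ll > best_ll:
            best_ll, best_h2 = ll, float(h2)
    return best_h2


@dataclass
class CvResult:
    accuracies: np.ndarray  # one per replication (or a single LOO value)
    h2_estimates: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))


def gblup_cv(
    G: np.ndarray,
    phenotypes: np.ndarray,
    folds: int = 10,
    replications: int = 50,
    holdout_mode: str = "kfold",
    seed: int = 0,
) -> CvResult:
    """GBLUP cross-validation with per-fold REML heritability.

    kfold mode: per replication, shuffle taxa into ``folds`` folds, predict
    each held-out fold from the rest, and score the Pearson correlation of
    predicted vs observed phenotype within each held-out fold; the
    replication's accuracy is the mean over its folds.  (Correlating within
    the held-out set, rather than pooling folds, avoids the negative bias
    that fold-specific training means induce in pooled CV correlations.)
    loo mode: one pass of leave-one-out prediction (a single accuracy over
    all held-out predictions, since size-1 folds have no within-fold
    correlation).
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(phenotypes, dtype=float)
    n = len(y)
    if G.shape != (n, n):
        raise ValueError("G and phenotypes are misaligned")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if holdout_mode not in ("kfold", "loo"):
        raise ValueError(f"unknown holdout_mode {holdout_mode!r}")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.01, 0.99, 99)

    def predict(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, float]:
        if len(train) < 2 or len(test) < 1:
            raise ValueError("fold with too few taxa")
        Gtr = G[np.ix_(train, train)]
        d, U = np.linalg.eigh(Gtr)
        ytr = y[train]
        yr, xr = U.T @ ytr, U.T @ np.ones(len(train))
        h2 = _reml_h2_grid(d, yr, xr, grid)
        lam = (1 - h2) / h2
        mu = float(np.mean(ytr))
        alpha = U @ ((U.T @ (ytr - mu)) / (d + lam))
        return mu + G[np.ix_(test, train)] @ alpha, h2

    if holdout_mode == "loo":
        preds = np.zeros(n)
        h2s = np.zeros(n)
        idx = np.arange(n)
        for i in range(n):
            train = idx[idx != i]
            pred, h2s[i] = predict(train, np.array([i]))
            preds[i] = pred[0]
        acc = float(np.corrcoef(preds, y)[0, 1])
        return CvResult(np.array([acc]), h2s)

    accs, h2s = [], []
    for _ in range(replications):
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        fold_of[perm] = np.arange(n) % folds
        fold_accs = []
        for f in range(folds):
            test = np.where(fold_of == f)[0]
            train = np.where(fold_of != f)[0]
            pred, h2 = predict(train, test)
            fold_accs.append(float(np.corrcoef(pred, y[test])[0, 1]))
            h2s.append(h2)
        accs.append(float(np.mean(fold_accs)))
    return CvResult(np.array(accs), np.array(h2s))


def gblup_permutation_null(
    G: np.ndarray,
    phenotypes: np.ndarray,
    n_permutations: int = 15,
    folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of CV accuracy under phenotype permutation.

    Each draw permutes the phenotypes afresh and runs one CV replication, so
    the spread across draws reflects permutation randomness (a single fixed
    permutation can sit several fold-level standard errors from zero purely
    by chance alignment with family structure).
    """
    rng = np.random.default_rng(seed)
    accs = []
    for k in range(n_permutations):
        yp = rng.permutation(np.asarray(phenotypes, dtype=float))
        res = gblup_cv(G, yp, folds=folds, replications=1,
                       seed=int(rng.integers(2**31 - 1)))
        accs.append(res.mean_accuracy)
    return np.array(accs)


def accuracy_report(imputed, truth, panel_freqs: np.ndarray) -> dict:
    """Bundle overall R^2, class concordance and frequency-binned concordance."""
    by_class = concordance_by_class(imputed, truth, panel_freqs)
    by_freq = accuracy_by_frequency(imputed, truth, panel_freqs)
    return {
        "overall_r2": dosage_r2(imputed, truth),
        "concordance_by_class": by_class.to_dict(),
        "accuracy_by_frequency": by_freq.to_dict(orient="records"),
    }
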