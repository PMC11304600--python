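"""Genomic prediction: ridge-regression BLUP, testcross GCA, training window.

The marker model is y = 1*mu + Z u + e with u ~ N(0, I sigma2_m) and
e ~ N(0, I sigma2_e). The single variance ratio lambda = sigma2_e/sigma2_m is
estimated by REML using a spectral trick: one eigendecomposition of the
centred marker Gram matrix Zc'Zc (m x m) yields the non-zero eigenvalues of
the projected kernel, after which the restricted likelihood is a cheap 1-D
function of lambda optimized by Brent search on log(lambda). Working on the
marker side keeps the cost O(m^3) regardless of training-set size, and lets
per-year Gram blocks be cached as the sliding window advances. At the
optimum, effects and intercept solve the exact mixed-model equations
(block-eliminated to the centred ridge system, which is algebraically
identical).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .genome import Population

__all__ = [
    "RRBLUP",
    "MarkerModel",
    "TrainingSet",
    "fit_rrblup",
    "predict_gebv",
    "estimate_gca",
    "update_window",
    "write_effects_table",
]

MarkerModel = "RRBLUP"  # the fitted estimator plays the marker-model role


class RRBLUP(BaseEstimator, RegressorMixin):
    """Ridge-regression BLUP with REML variance components.

    Parameters
    ----------
    lambda_bounds : (low, high) search interval for lambda = sigma2_e/sigma2_m.
    tol : Brent tolerance on log10(lambda).
    grid_points : coarse log-grid evaluations used to bracket the optimum.

    Fitted attributes
    -----------------
    mu_ : intercept (generalized-least-squares solution of the MME).
    u_ : (m,) marker effects.
    center_ : (m,) training-set column means of the dosage matrix
        (2 x allele frequency); predictions center genotypes with these.
    lambda_, sigma2_marker_, sigma2_error_ : variance components.
    n_train_, degenerate_ : training metadata.
    """

    def __init__(self, lambda_bounds=(1e-5, 1e5), tol=1e-8, grid_points=41):
        self.lambda_bounds = lambda_bounds
        self.tol = tol
        self.grid_points = grid_points

    # -- fitting ------------------------------------------------------------

    def fit(self, Z, y):
        Z = np.asarray(Z, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if Z.ndim != 2 or Z.shape[0] != y.size:
            raise ValueError("Z must be (n, m) with one row per response")
        n, m = Z.shape
        if n < 2:
            raise ValueError("need at least 2 training records")
        if m <= n:
            stats = _CrossProducts(
                gram=Z.T @ Z, zt1=Z.sum(axis=0), zty=Z.T @ y,
                y_sum=float(y.sum()), y_ss=float(y @ y), n=n, m=m)
            return self._fit_from_stats(stats)
        return self._fit_nside(Z, y)

    def _degenerate(self, ybar, m):
        # constant response: no signal, prediction collapses to the mean
        self.mu_ = ybar
        self.u_ = np.zeros(m)
        self.lambda_ = np.inf
        self.sigma2_marker_ = 0.0
        self.sigma2_error_ = 1.0
        self.degenerate_ = True
        return self

    def _optimize_lambda(self, d_nz, eta2, ss_rem, n):
        """1-D REML profile on the shared spectral quantities: non-zero
        kernel eigenvalues, squared data projections on their eigvectors,
        and the residual sum of squares in the zero-eigenvalue contrasts."""
        r = d_nz.size

        def neg2_reml_profile(log10_lam):
            lam = 10.0 ** log10_lam
            quad = (eta2 / (d_nz + lam)).sum() + ss_rem / lam
            logdet = np.log(d_nz + lam).sum() + (n - 1 - r) * np.log(lam)
            return (n - 1) * np.log(quad) + logdet

        lo, hi = np.log10(self.lambda_bounds[0]), np.log10(self.lambda_bounds[1])
        grid = np.linspace(lo, hi, self.grid_points)
        vals = [neg2_reml_profile(g) for g in grid]
        i = int(np.argmin(vals))
        blo, bhi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(neg2_reml_profile, bounds=(blo, bhi),
                              method="bounded", options={"xatol": self.tol})
        lam = float(10.0 ** res.x)
        quad = (eta2 / (d_nz + lam)).sum() + ss_rem / lam
        self.lambda_ = lam
        self.sigma2_marker_ = quad / (n - 1)
        self.sigma2_error_ = lam * self.sigma2_marker_
        self.degenerate_ = False
        self._reml_objective = neg2_reml_profile
        return lam

    def _fit_from_stats(self, st: "_CrossProducts"):
        """Marker-side path, O(m^3): eigendecomposition of the centred Gram
        matrix Zc'Zc; cost independent of training-set size."""
        n, m = st.n, st.m
        c = st.zt1 / n
        ybar = st.y_sum / n
        yss_c = max(st.y_ss - n * ybar**2, 0.0)
        self.n_train_ = n
        self.center_ = c
        if yss_c <= 1e-12 * max(1.0, abs(ybar)):
            return self._degenerate(ybar, m)
        gram_c = st.gram - n * np.outer(c, c)
        rhs = st.zty - st.y_sum * c           # Zc' yc
        d, v = eigh(gram_c)
        d = np.maximum(d, 0.0)
        w = v.T @ rhs
        dtol = max(d[-1], 1e-300) * 1e-12
        nz = d > dtol
        if not np.any(nz):
            raise ValueError("no polymorphic markers in the training set")
        eta2 = w[nz] ** 2 / d[nz]
        ss_rem = max(yss_c - eta2.sum(), 0.0)
        lam = self._optimize_lambda(d[nz], eta2, ss_rem, n)
        self.u_ = v @ (w / (d + lam))
        self.mu_ = ybar - float(c @ self.u_)
        return self

    def _fit_nside(self, Z, y):
        """Record-side path, O(n^3 + n^2 m): eigendecomposition of the
        centred kernel Zc Zc'; preferred when markers outnumber records."""
        n, m = Z.shape
        c = Z.mean(axis=0)
        ybar = float(y.mean())
        yc = y - ybar
        yss_c = float(yc @ yc)
        self.n_train_ = n
        self.center_ = c
        if yss_c <= 1e-12 * max(1.0, abs(ybar)):
            return self._degenerate(ybar, m)
        Zc = Z - c
        K = Zc @ Zc.T
        d, u = eigh(K)
        d = np.maximum(d, 0.0)
        dtol = max(d[-1], 1e-300) * 1e-12
        nz = d > dtol
        if not np.any(nz):
            raise ValueError("no polymorphic markers in the training set")
        eta = u[:, nz].T @ yc
        eta2 = eta ** 2
        ss_rem = max(yss_c - eta2.sum(), 0.0)
        lam = self._optimize_lambda(d[nz], eta2, ss_rem, n)
        self.u_ = Zc.T @ (u[:, nz] @ (eta / (d[nz] + lam)))
        self.mu_ = ybar - float(c @ self.u_)
        return self

    # -- prediction ---------------------------------------------------------

    def predict(self, Z):
        Z = np.asarray(Z, dtype=np.float64)
        if Z.ndim != 2 or Z.shape[1] != self.u_.size:
            raise ValueError(
                f"SNP dimension mismatch: model has {self.u_.size} markers, "
                f"got {Z.shape[1] if Z.ndim == 2 else 'non-matrix input'}")
        return self.mu_ + Z @ self.u_


@dataclasses.dataclass
class _CrossProducts:
    """Sufficient statistics of a training set for the marker-side fit."""

    gram: np.ndarray   # Z'Z (m, m)
    zt1: np.ndarray    # Z'1 (m,)
    zty: np.ndarray    # Z'y (m,)
    y_sum: float
    y_ss: float
    n: int
    m: int

    @classmethod
    def from_block(cls, Z, y):
        Z = np.asarray(Z, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        return cls(Z.T @ Z, Z.sum(axis=0), Z.T @ y,
                   float(y.sum()), float(y @ y), Z.shape[0], Z.shape[1])

    def __add__(self, other):
        return _CrossProducts(
            self.gram + other.gram, self.zt1 + other.zt1,
            self.zty + other.zty, self.y_sum + other.y_sum,
            self.y_ss + other.y_ss, self.n + other.n, self.m)


# --------------------------------------------------------------------------
# sliding training window
# --------------------------------------------------------------------------

@dataclasses.dataclass
class _Block:
    year: int
    tag: str
    Z: np.ndarray
    y: np.ndarray
    ids: np.ndarray
    stats: _CrossProducts


class TrainingSet:
    """Genotype/response records retained over a sliding year window.

    Records whose year is <= current_year - window_years are dropped; the
    same individual may contribute separate records from different stages or
    years. Per-block cross-products are cached so refits cost one m x m
    eigendecomposition, not a pass over all genotypes.
    """

    def __init__(self, window_years: int = 4):
        self.window_years = window_years
        self._blocks: list[_Block] = []

    @property
    def n_records(self) -> int:
        return sum(b.Z.shape[0] for b in self._blocks)

    @property
    def years(self) -> list[int]:
        return sorted({b.year for b in self._blocks})

    def records(self) -> pd.DataFrame:
        rows = [pd.DataFrame({"id": b.ids, "year": b.year, "tag": b.tag,
                              "value": b.y}) for b in self._blocks]
        return (pd.concat(rows, ignore_index=True) if rows
                else pd.DataFrame(columns=["id", "year", "tag", "value"]))

    def add(self, Z, y, ids, year: int, tag: str = "") -> None:
        Z = np.asarray(Z, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        ids = np.asarray(ids, dtype=np.int64)
        if self._blocks and Z.shape[1] != self._blocks[0].Z.shape[1]:
            raise ValueError("genotype vectors must all have equal length")
        self._blocks.append(
            _Block(year, tag, Z, y, ids, _CrossProducts.from_block(Z, y)))

    def prune(self, current_year: int) -> None:
        cutoff = current_year - self.window_years
        self._blocks = [b for b in self._blocks if b.year > cutoff]

    def copy(self) -> "TrainingSet":
        new = TrainingSet(self.window_years)
        new._blocks = list(self._blocks)
        return new

    def pooled(self):
        Z = np.concatenate([b.Z for b in self._blocks])
        y = np.concatenate([b.y for b in self._blocks])
        return Z, y

    def stats(self) -> _CrossProducts:
        total = self._blocks[0].stats
        for b in self._blocks[1:]:
            total = total + b.stats
        return total


def update_window(train: TrainingSet, new_records, current_year: int
                  ) -> TrainingSet:
    """Functional window update: union of old and new records, then expiry
    of records older than the window. Idempotent for fixed current_year.

    ``new_records`` is an iterable of (Z, y, ids, year[, tag]) tuples.
    """
    out = train.copy()
    for rec in new_records:
        out.add(*rec)
    out.prune(current_year)
    return out


def fit_rrblup(train: TrainingSet, **kwargs) -> RRBLUP:
    """Fit the marker model on a training window.

    Uses the cached per-block cross-products (marker-side spectral path)
    when markers do not outnumber records; otherwise pools the window and
    works on the record side."""
    if not train._blocks:
        raise ValueError("empty training set")
    n = train.n_records
    m = train._blocks[0].Z.shape[1]
    if n < 2:
        raise ValueError("need at least 2 training records")
    if m <= n:
        return RRBLUP(**kwargs)._fit_from_stats(train.stats())
    Z, y = train.pooled()
    return RRBLUP(**kwargs)._fit_nside(Z, y)


def predict_gebv(model: RRBLUP, pop: Population) -> np.ndarray:
    """Genomic estimated breeding values from SNP dosages."""
    Z = pop.dosage(pop.genome.snp_sites).astype(np.float64)
    return model.predict(Z)


def write_effects_table(model: RRBLUP, genome, path) -> None:
    """Serialize a fitted marker model as a tab-separated effects table
    (snp index, chromosome, map position, effect) under a small header
    carrying the intercept and variance components."""
    chrom = genome.chrom_of_site()[genome.snp_sites]
    pos = genome.site_pos[genome.snp_sites]
    if model.u_.size != genome.snp_sites.size:
        raise ValueError("model marker count does not match the genome's "
                         "SNP set")
    with open(path, "w") as fh:
        fh.write(f"# mu\t{float(model.mu_)!r}\n")
        fh.write(f"# sigma2_marker\t{float(model.sigma2_marker_)!r}\n")
        fh.write(f"# sigma2_error\t{float(model.sigma2_error_)!r}\n")
        fh.write("snp\tchromosome\tposition_morgans\teffect\n")
        for j in range(model.u_.size):
            fh.write(f"{j}\t{chrom[j] + 1}\t{pos[j]:.8f}\t"
                     f"{float(model.u_[j])!r}\n")


# --------------------------------------------------------------------------
# testcross GCA
# --------------------------------------------------------------------------

def estimate_gca(hybrid_phenotypes: pd.DataFrame) -> pd.DataFrame:
    """General combining ability from testcross entry means.

    Fits the two-way main-effects model value ~ mean + parent + tester by
    least squares with sum-to-zero constraints and returns the parent
    effects. In a balanced layout this equals the parent's mean across
    testers minus the grand mean; with a single tester it reduces to the
    testcross mean minus the grand mean.

    ``hybrid_phenotypes`` needs columns parent, tester, value (one entry-mean
    row per hybrid). Parents without hybrids are simply absent.
    """
    df = hybrid_phenotypes
    required = {"parent", "tester", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"hybrid table must have columns {sorted(required)}")
    if not len(df):
        raise ValueError("no hybrid records")
    parents = np.unique(df["parent"].to_numpy())
    testers = np.unique(df["tester"].to_numpy())
    p, t = parents.size, testers.size
    y = df["value"].to_numpy(dtype=float)
    pi = np.searchsorted(parents, df["parent"].to_numpy())
    ti = np.searchsorted(testers, df["tester"].to_numpy())
    cell_counts = np.zeros((p, t), dtype=np.int64)
    np.add.at(cell_counts, (pi, ti), 1)
    balanced = np.all(cell_counts == cell_counts[0, 0])
    if balanced:
        # closed form: parent mean across testers minus grand mean
        sums = np.zeros(p)
        np.add.at(sums, pi, y)
        eff = sums / (t * cell_counts[0, 0]) - y.mean()
    else:
        # effects (sum-to-zero) coding: level k gets e_k - e_last
        X = np.zeros((len(df), 1 + (p - 1) + (t - 1)))
        X[:, 0] = 1.0
        for j in range(p - 1):
            X[:, 1 + j] = (pi == j).astype(float) - (pi == p - 1).astype(float)
        for j in range(t - 1):
            X[:, p + j] = (ti == j).astype(float) - (ti == t - 1).astype(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        eff = np.empty(p)
        eff[: p - 1] = beta[1:p]
        eff[p - 1] = -beta[1:p].sum()
    counts = pd.DataFrame({"parent": df["parent"], "tester": df["tester"]})
    n_testers = counts.groupby("parent")["tester"].nunique()
    n_obs = counts.groupby("parent").size()
    return pd.DataFrame({
        "parent": parents,
        "gca": eff,
        "n_testers": n_testers.loc[parents].to_numpy(),
        "n_obs": n_obs.loc[parents].to_numpy(),
    }).set_index("parent")
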