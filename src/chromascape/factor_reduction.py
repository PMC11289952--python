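"""Dimension reduction of the pattern-statistic table.

The statistic table is first reduced to complete cases (any image whose
pattern is too homogeneous to define contrast statistics produces NaN
and is excluded), then to a low-redundancy column set (greedy Pearson
|r| < threshold scan in registry order). The number of latent factors
is chosen by parallel analysis — observed correlation-matrix
eigenvalues against position-wise median eigenvalues of simulated
standard-normal datasets of the same shape — and an exploratory factor
model is fitted by unweighted least squares (minres) with varimax
rotation, regression-method factor scores, and bootstrap percentile
intervals for the loadings (replicates aligned to the point estimate by
congruence-maximizing signed permutation before taking percentiles).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "FilteredTable",
    "complete_cases",
    "correlation_filter",
    "parallel_analysis",
    "ExploratoryFactorAnalysis",
    "FactorAnalysisResults",
    "varimax",
    "tucker_congruence",
    "align_loadings",
]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


@dataclass
class FilteredTable:
    """A statistic table after row and/or column filtering."""

    table: pd.DataFrame
    dropped_images: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_stats: list[str] = field(default_factory=list)

    @property
    def exclusions_by_distance(self) -> pd.Series:
        if self.dropped_images.empty:
            return pd.Series(dtype=int)
        return self.dropped_images.groupby("distance_cm").size()


_ID_COLS = ("image_id", "species", "distance_cm")


def _stat_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _ID_COLS]


def complete_cases(table: pd.DataFrame) -> FilteredTable:
    """Drop rows containing any NaN or infinite statistic.

    Contrast statistics are undefined for images with fewer than two
    patch classes, so near-uniform backgrounds drop out here; the
    exclusion counts per viewing distance are reported.
    """
    if table.empty:
        raise ValueError("empty statistic table")
    cols = _stat_columns(table)
    vals = table[cols].to_numpy(dtype=np.float64)
    bad = ~np.isfinite(vals).all(axis=1)
    if bad.all():
        raise ValueError(
            "every image produced at least one undefined statistic; "
            "nothing left to analyze"
        )
    dropped = table.loc[bad, [c for c in _ID_COLS if c in table.columns]].copy()
    return FilteredTable(table.loc[~bad].reset_index(drop=True), dropped_images=dropped)


def correlation_filter(table: pd.DataFrame, threshold: float = 0.6) -> FilteredTable:
    """Greedy scan keeping columns pairwise less correlated than the threshold.

    Columns are visited in their (registry) order; a column is kept iff
    its absolute Pearson correlation with every already-kept column is
    below ``threshold``. Zero-variance columns are dropped with a
    warning. The survivor set therefore depends on column order, which
    is fixed by the statistic registry.
    """
    if len(table) < 2:
        raise ValueError("need at least two rows to estimate correlations")
    cols = _stat_columns(table)
    kept: list[str] = []
    dropped: list[str] = []
    x = table[cols].to_numpy(dtype=np.float64)
    sd = x.std(axis=0)
    for j, c in enumerate(cols):
        if sd[j] == 0 or not np.isfinite(sd[j]):
            warnings.warn(f"dropping zero-variance column {c!r}")
            dropped.append(c)
            continue
        ok = True
        for kc in kept:
            r = np.corrcoef(table[c], table[kc])[0, 1]
            if abs(r) >= threshold:
                ok = False
                break
        (kept if ok else dropped).append(c)
    id_cols = [c for c in _ID_COLS if c in table.columns]
    return FilteredTable(table[id_cols + kept].copy(), dropped_stats=dropped)


# ---------------------------------------------------------------------------
# parallel analysis
# ---------------------------------------------------------------------------


def parallel_analysis(
    table: pd.DataFrame, n_sims: int = 10_000, seed: int = 0, batch: int = 200
) -> int:
    """Number of factors by comparison with simulated noise eigenvalues.

    Retains k = the number of leading observed correlation-matrix
    eigenvalues strictly greater than the position-wise median
    eigenvalue over ``n_sims`` iid standard-normal datasets of the same
    shape; counting stops at the first eigenvalue that fails the
    comparison (on pure noise roughly half of all positions beat their
    median by chance, but the leading run is short).
    """
    cols = _stat_columns(table) if any(c in table.columns for c in _ID_COLS) else list(table.columns)
    x = table[cols].to_numpy(dtype=np.float64)
    n, p = x.shape
    if p < 2:
        raise ValueError("need at least two columns")
    obs = np.sort(np.linalg.eigvalsh(np.corrcoef(x, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sim_eigs = np.empty((n_sims, p))
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        z = rng.standard_normal((b, n, p))
        z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
        corr = np.einsum("bni,bnj->bij", z, z) / n
        sim_eigs[done : done + b] = np.sort(np.linalg.eigvalsh(corr), axis=1)[:, ::-1]
        done += b
    med = np.median(sim_eigs, axis=0)
    above = obs > med
    k = 0
    while k < p and above[k]:
        k += 1
    return k


# ---------------------------------------------------------------------------
# factor extraction
# ---------------------------------------------------------------------------


def _uls_loadings(corr: np.ndarray, psi: np.ndarray, k: int) -> np.ndarray:
    """Top-k loadings of the reduced correlation matrix corr - diag(psi)."""
    red = corr - np.diag(psi)
    vals, vecs = np.linalg.eigh(red)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(lam)


def _uls_objective(psi: np.ndarray, corr: np.ndarray, k: int) -> float:
    red = corr - np.diag(psi)
    vals = np.sort(np.linalg.eigvalsh(red))[::-1]
    resid = vals[k:]
    return float(0.5 * np.sum(resid**2))


def _fit_minres(corr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted least squares (minres) factor extraction.

    Minimizes the sum of squared residuals of the off-diagonal
    correlations over the uniquenesses; given uniquenesses, loadings
    are the top-k eigen component of the reduced correlation matrix.
    Heywood cases are clipped at a small positive uniqueness.
    """
    p = corr.shape[0]
    start = 1.0 - 0.5 * np.abs(np.linalg.inv(corr).diagonal() ** -1)
    start = np.clip(start, 0.05, 0.95)
    res = optimize.minimize(
        _uls_objective,
        start,
        args=(corr, k),
        method="L-BFGS-B",
        bounds=[(0.005, 1.0)] * p,
        options={"maxiter": 1000},
    )
    psi = res.x
    if np.any(psi <= 0.005 + 1e-12):
        warnings.warn("Heywood case: uniqueness clipped at 0.005")
    loadings = _uls_loadings(corr, psi, k)
    return loadings, psi


def varimax(
    loadings: np.ndarray, normalize: bool = True, tol: float = 1e-10, max_iter: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    L = np.asarray(loadings, dtype=np.float64).copy()
    p, k = L.shape
    if k < 2:
        return L, np.eye(k)
    comm = None
    if normalize:  # Kaiser normalization
        comm = np.sqrt((L**2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lam = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lam**3 - Lam @ np.diag((Lam**2).sum(axis=0)) / p)
        )
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    Lam = L @ R
    if normalize:
        Lam = Lam * comm[:, None]
    return Lam, R


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> float:
    """Tucker's congruence coefficient between two loading vectors."""
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def align_loadings(
    replicate: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align a replicate loading matrix to a reference.

    Finds the signed column permutation of ``replicate`` maximizing the
    summed absolute Tucker congruence with ``reference`` columns.
    Returns (aligned loadings, permutation, signs).
    """
    k = reference.shape[1]
    best = (-np.inf, None, None)
    cong = np.array(
        [
            [tucker_congruence(replicate[:, i], reference[:, j]) for j in range(k)]
            for i in range(k)
        ]
    )
    for perm in itertools.permutations(range(k)):
        score = sum(abs(cong[perm[j], j]) for j in range(k))
        if score > best[0]:
            best = (score, perm, None)
    perm = np.array(best[1])
    signs = np.sign([cong[perm[j], j] or 1.0 for j in range(k)])
    aligned = replicate[:, perm] * signs
    return aligned, perm, signs


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class ExploratoryFactorAnalysis:
    """Exploratory factor model of a (filtered) statistic table.

    Parameters
    ----------
    data : DataFrame
        Complete-case table; identifier columns (image_id, species,
        distance_cm) are carried through, all other columns are treated
        as variables and standardized internally.
    n_factors : int or None
        Number of factors; if None, chosen by :func:`parallel_analysis`
        at fit time.
    n_sims : int
        Parallel-analysis simulation count (only used if n_factors is
        None).
    """

    def __init__(self, data: pd.DataFrame, n_factors: int | None = None, n_sims: int = 10_000):
        self.data = data.reset_index(drop=True)
        self.columns = _stat_columns(self.data)
        if len(self.columns) < 2:
            raise ValueError("need at least two variables")
        x = self.data[self.columns].to_numpy(dtype=np.float64)
        if not np.isfinite(x).all():
            raise ValueError("data must be complete (run complete_cases first)")
        self.n_factors = n_factors
        self.n_sims = n_sims
        self._x = x

    def fit(
        self, bootstrap_iters: int = 0, seed: int = 0
    ) -> "FactorAnalysisResults":
        x = self._x
        mean, sd = x.mean(axis=0), x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column; run correlation_filter first")
        z = (x - mean) / sd
        corr = np.corrcoef(x, rowvar=False)
        k = self.n_factors
        if k is None:
            k = parallel_analysis(
                pd.DataFrame(x, columns=self.columns), n_sims=self.n_sims, seed=seed
            )
            k = max(k, 1)
        loadings, psi = _fit_minres(corr, k)
        loadings, rotation = varimax(loadings)
        # deterministic orientation and order: sort by explained variance,
        # flip each factor so its largest-|loading| variable loads positive
        ss = (loadings**2).sum(axis=0)
        order = np.argsort(ss)[::-1]
        loadings = loadings[:, order]
        rotation = rotation[:, order]
        for j in range(k):
            i = np.argmax(np.abs(loadings[:, j]))
            if loadings[i, j] < 0:
                loadings[:, j] = -loadings[:, j]
                rotation[:, j] = -rotation[:, j]
        scores = z @ np.linalg.solve(corr, loadings)  # regression (Thurstone)
        var_explained = (loadings**2).sum(axis=0) / len(self.columns)

        ci_low = ci_high = None
        if bootstrap_iters:
            rng = np.random.default_rng(seed)
            boots = np.empty((bootstrap_iters, *loadings.shape))
            n = len(x)
            for b in range(bootstrap_iters):
                idx = rng.integers(0, n, size=n)
                xb = x[idx]
                sdb = xb.std(axis=0)
                if np.any(sdb == 0):
                    boots[b] = np.nan
                    continue
                cb = np.corrcoef(xb, rowvar=False)
                lb, _ = _fit_minres(cb, k)
                lb, _ = varimax(lb)
                boots[b], _, _ = align_loadings(lb, loadings)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                ci_low = np.nanpercentile(boots, 2.5, axis=0)
                ci_high = np.nanpercentile(boots, 97.5, axis=0)

        return FactorAnalysisResults(
            model=self,
            n_factors=k,
            loadings=pd.DataFrame(
                loadings,
                index=self.columns,
                columns=[f"factor{j + 1}" for j in range(k)],
            ),
            uniquenesses=pd.Series(psi, index=self.columns),
            rotation=rotation,
            scores=pd.concat(
                [
                    self.data[[c for c in _ID_COLS if c in self.data.columns]],
                    pd.DataFrame(
                        scores, columns=[f"factor{j + 1}" for j in range(k)]
                    ),
                ],
                axis=1,
            ),
            variance_explained=pd.Series(
                var_explained, index=[f"factor{j + 1}" for j in range(k)]
            ),
            loadings_ci_low=None if ci_low is None else pd.DataFrame(
                ci_low, index=self.columns, columns=[f"factor{j + 1}" for j in range(k)]
            ),
            loadings_ci_high=None if ci_high is None else pd.DataFrame(
                ci_high, index=self.columns, columns=[f"factor{j + 1}" for j in range(k)]
            ),
        )


@dataclass
class FactorAnalysisResults:
    """Fitted factor model: loadings, scores, variance shares, CIs."""

    model: ExploratoryFactorAnalysis
    n_factors: int
    loadings: pd.DataFrame
    uniquenesses: pd.Series
    rotation: np.ndarray
    scores: pd.DataFrame
    variance_explained: pd.Series
    loadings_ci_low: pd.DataFrame | None = None
    loadings_ci_high: pd.DataFrame | None = None

    @property
    def communalities(self) -> pd.Series:
        return (self.loadings**2).sum(axis=1)

    def reconstruction_rmse(self) -> float:
        """RMS residual of off-diagonal correlations under the model."""
        corr = np.corrcoef(self.model._x, rowvar=False)
        L = self.loadings.to_numpy()
        resid = corr - L @ L.T - np.diag(self.uniquenesses.to_numpy())
        off = resid[~np.eye(len(resid), dtype=bool)]
        return float(np.sqrt(np.mean(off**2)))

    def summary(self) -> str:
        lines = [
            "Exploratory factor analysis (minres, varimax)",
            f"  variables: {len(self.loadings)}   observations: {len(self.scores)}",
            f"  factors:   {self.n_factors}",
            "  variance explained: "
            + ", ".join(
                f"{name} {v:.1%}" for name, v in self.variance_explained.items()
            )
            + f"  (total {self.variance_explained.sum():.1%})",
            "",
            self.loadings.round(3).to_string(),
        ]
        return "\n".join(lines)

    def plot_loadings(self, ax=None):
        """Heatmap of the loading matrix (variables x factors)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4 + self.n_factors, 0.3 * len(self.loadings) + 1))
        im = ax.imshow(self.loadings.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
        ax.set_xticks(range(self.n_factors), self.loadings.columns)
        ax.set_yticks(range(len(self.loadings)), self.loadings.index, fontsize=7)
        ax.figure.colorbar(im, ax=ax, label="loading")
        return ax
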