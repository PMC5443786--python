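"""Community ordination and inferential statistics on OTU tables.

Ordination is non-metric MDS on Bray-Curtis dissimilarities with a Shepard
correlation as the goodness-of-fit diagnostic. Differential abundance uses
a per-OTU negative-binomial regression (log link, NB2 variance
mu + alpha*mu^2) with likelihood-ratio tests per factor and a multivariate
statistic formed by summing the per-OTU LRTs; significance comes from a
residual-resampling bootstrap (randomized PIT residuals permuted jointly
across OTUs and inverted through the null model's quantile function),
which preserves the counts' mean-variance relation and the between-OTU
correlation structure under the null.

The NB regression is fitted by iteratively reweighted least squares,
batched across OTUs (and across bootstrap replicates) in numpy; the
dispersion is estimated per OTU by profile maximum likelihood under the
full model and held fixed for reduced-model and bootstrap refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import braycurtis as _scipy_braycurtis
from scipy.special import gammaln
from sklearn.manifold import MDS

logger = logging.getLogger("smdiv")

DEFAULT_PAIRING: dict[str, set[str]] = {
    "ACP": {"Firmicutes"},
    "KS": {"Actinobacteria", "Firmicutes", "Proteobacteria"},
    "met-mal-CoA": {"Actinobacteria", "Firmicutes", "Proteobacteria"},
    "AD": {"Actinobacteria", "Firmicutes", "Proteobacteria"},
}


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) of two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two all-zero vectors")
    return float(_scipy_braycurtis(x, y))


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Sample x sample Bray-Curtis matrix from an OTU x sample table."""
    samples = list(table.columns)
    n = len(samples)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = bray_curtis(table.iloc[:, i], table.iloc[:, j])
    return pd.DataFrame(d, index=samples, columns=samples)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float  # Kruskal stress-1 of the best start
    shepard_r: float


def shepard_correlation(D, coordinates) -> float:
    """Pearson correlation of input dissimilarities vs ordination distances."""
    D = np.asarray(D, dtype=float)
    X = np.asarray(coordinates, dtype=float)
    iu = np.triu_indices(D.shape[0], k=1)
    od = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    return float(np.corrcoef(D[iu], od[iu])[0, 1])


def nmds(
    D,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 300,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1 over several random starts.

    The best-stress embedding over ``n_starts`` isotonic-regression/
    gradient optimizations is returned, with the Shepard correlation of
    that solution; identical seeds give identical results.
    """
    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        Dm = D.values
    else:
        Dm = np.asarray(D, dtype=float)
        labels = list(range(Dm.shape[0]))
    if Dm.shape[0] < 3:
        raise ValueError("NMDS requires at least 3 samples")
    model = MDS(
        n_components=k,
        metric="precomputed",
        metric_mds=False,
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=1e-9,
        normalized_stress=True,
        random_state=seed,
    )
    coords = model.fit_transform(Dm)
    cdf = pd.DataFrame(coords, index=labels, columns=[f"NMDS{i+1}" for i in range(k)])
    return OrdinationResult(cdf, float(model.stress_), shepard_correlation(Dm, coords))


# ---------------------------------------------------------------------------
# Negative-binomial regression, batched across OTUs.
# ---------------------------------------------------------------------------

_ALPHA_MIN, _ALPHA_MAX = 1e-8, 1e4


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB2 log-likelihood summed over samples; Y, mu are n x m, alpha is m."""
    r = 1.0 / np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)
    mu = np.clip(mu, 1e-12, None)
    ll = (
        gammaln(Y + r)
        - gammaln(r)
        - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu))
        + Y * np.log(mu / (r + mu))
    )
    return ll.sum(axis=0)


def _irls_nb(
    X: np.ndarray,
    Y: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Batched IRLS for NB regression with log link and known dispersion.

    X is n x p (shared design), Y is n x m counts, alpha is length-m.
    Returns (beta p x m, loglik m, converged m).
    """
    n, p = X.shape
    m = Y.shape[1]
    beta = np.zeros((p, m))
    # intercept initialised at log mean, assuming column 0 is the intercept
    beta[0] = np.log(np.clip(Y.mean(axis=0), 0.5, None))
    converged = np.zeros(m, dtype=bool)
    ll_old = np.full(m, -np.inf)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha[None, :] * mu)
        Z = eta + (Y - mu) / mu
        A = np.einsum("np,nm,nq->mpq", X, W, X)
        A += 1e-10 * np.eye(p)[None, :, :]
        b = np.einsum("np,nm->mp", X, W * Z)
        try:
            beta_new = np.linalg.solve(A, b[:, :, None])[:, :, 0].T
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(beta_new)):
            beta_new = np.where(np.isfinite(beta_new), beta_new, beta)
        ll = _nb_loglik(Y, np.exp(np.clip(X @ beta_new, -30.0, 30.0)), alpha)
        done = np.abs(ll - ll_old) < tol * (np.abs(ll_old) + 1.0)
        beta = beta_new
        ll_old = ll
        converged |= done
        if done.all():
            break
    eta = np.clip(X @ beta, -30.0, 30.0)
    return beta, _nb_loglik(Y, np.exp(eta), alpha), converged


def _estimate_alpha(X: np.ndarray, Y: np.ndarray, outer: int = 4) -> np.ndarray:
    """Per-OTU ML dispersion by alternating beta-IRLS and scalar profile search."""
    m = Y.shape[1]
    alpha = np.full(m, 0.5)
    for _ in range(outer):
        beta, _, _ = _irls_nb(X, Y, alpha)
        mu = np.exp(np.clip(X @ beta, -30.0, 30.0))
        for j in range(m):
            yj, mj = Y[:, j : j + 1], mu[:, j : j + 1]

            def nll(log_a, yj=yj, mj=mj):
                return -_nb_loglik(yj, mj, np.array([np.exp(log_a)]))[0]

            res = minimize_scalar(
                nll, bounds=(np.log(_ALPHA_MIN), np.log(_ALPHA_MAX)), method="bounded",
                options={"xatol": 1e-3},
            )
            alpha[j] = float(np.exp(res.x))
    return alpha


def _design(metadata: pd.DataFrame, factors: tuple[str, ...]) -> tuple[np.ndarray, dict[str, list[int]]]:
    """Intercept + treatment-coded dummies; returns X and factor->column map."""
    n = len(metadata)
    cols = [np.ones(n)]
    owner: dict[str, list[int]] = {}
    for f in factors:
        levels = sorted(metadata[f].astype(str).unique())
        if len(levels) < 2:
            raise ValueError(f"factor {f!r} has a single level")
        idx = []
        for lev in levels[1:]:
            idx.append(len(cols))
            cols.append((metadata[f].astype(str) == lev).to_numpy(float))
        owner[f] = idx
    return np.column_stack(cols), owner


@dataclass
class DifferentialResult:
    per_otu: pd.DataFrame
    multivariate: dict[str, dict[str, float]]
    fitted: pd.DataFrame = field(default=None, repr=False)
    residuals: pd.DataFrame = field(default=None, repr=False)


def _pit_residuals(Y, mu, alpha, rng) -> np.ndarray:
    """Randomized probability-integral-transform residuals of NB counts."""
    r = 1.0 / np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)
    pnb = r / (r + mu)
    lo = sps.nbinom.cdf(Y - 1, r, pnb)
    hi = sps.nbinom.cdf(Y, r, pnb)
    u = lo + rng.uniform(size=Y.shape) * (hi - lo)
    return np.clip(u, 1e-10, 1.0 - 1e-10)


def fit_differential(
    otu_table: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: tuple[str, ...] = ("site", "stage"),
    n_boot: int = 999,
    seed: int | None = None,
) -> DifferentialResult:
    """Per-OTU NB regression with LRT per factor and bootstrap p-values.

    ``otu_table`` is OTU x sample; ``metadata`` must cover its samples and
    contain the factor columns. For each factor the reduced model drops
    that factor's dummy columns; the per-OTU LRT is 2(ll_full - ll_reduced)
    and the multivariate statistic sums LRTs over converged OTUs. Bootstrap
    p-values are (1 + #{stat* >= stat}) / (n_boot + 1) under joint-row
    permutation of randomized PIT residuals computed under the reduced
    (null) model. Benjamini-Hochberg-adjusted per-OTU p-values are
    reported alongside the raw ones.
    """
    meta = metadata.set_index("sample_id").loc[list(otu_table.columns)].reset_index()
    Y = otu_table.to_numpy(dtype=float).T  # n samples x m OTUs
    if (Y < 0).any() or not np.allclose(Y, np.round(Y)):
        raise ValueError("OTU table must hold non-negative integer counts")
    n, m = Y.shape
    rng = np.random.default_rng(seed)

    X_full, owner = _design(meta, factors)
    alpha = _estimate_alpha(X_full, Y)
    beta_full, ll_full, conv_full = _irls_nb(X_full, Y, alpha)
    mu_full = np.exp(np.clip(X_full @ beta_full, -30.0, 30.0))

    per_otu = pd.DataFrame(index=otu_table.index)
    per_otu["dispersion"] = alpha
    per_otu["converged"] = conv_full
    sat_ll = _nb_loglik(Y, np.clip(Y, 1e-8, None), alpha)
    per_otu["deviance"] = 2.0 * (sat_ll - ll_full)
    multivariate: dict[str, dict[str, float]] = {}

    for f in factors:
        keep = [c for c in range(X_full.shape[1]) if c not in owner[f]]
        X_red = X_full[:, keep]
        beta_red, ll_red, conv_red = _irls_nb(X_red, Y, alpha)
        lrt = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        ok = conv_full & conv_red
        obs_stat = float(lrt[ok].sum())
        per_otu[f"lrt_{f}"] = lrt

        mu_red = np.exp(np.clip(X_red @ beta_red, -30.0, 30.0))
        u = _pit_residuals(Y, mu_red, alpha, rng)
        r = 1.0 / np.clip(alpha, _ALPHA_MIN, _ALPHA_MAX)
        pnb = r / (r + mu_red)

        # build all bootstrap datasets, then one batched fit over B*m columns
        perms = np.stack([rng.permutation(n) for _ in range(n_boot)])
        u_star = u[perms, :]  # B x n x m
        y_star = sps.nbinom.ppf(u_star, r[None, None, :], pnb[None, :, :])
        Yb = y_star.transpose(1, 0, 2).reshape(n, n_boot * m)
        alpha_b = np.tile(alpha, n_boot)
        _, llf_b, convf_b = _irls_nb(X_full, Yb, alpha_b)
        _, llr_b, convr_b = _irls_nb(X_red, Yb, alpha_b)
        lrt_b = np.maximum(2.0 * (llf_b - llr_b), 0.0).reshape(n_boot, m)
        ok_b = (convf_b & convr_b).reshape(n_boot, m)
        stat_b = np.where(ok_b, lrt_b, 0.0)[:, ok].sum(axis=1)

        multivariate[f] = {
            "stat": obs_stat,
            "p": float((1 + (stat_b >= obs_stat).sum()) / (n_boot + 1)),
            "n_otus": int(ok.sum()),
        }
        p_otu = (1 + (lrt_b >= lrt[None, :]).sum(axis=0)) / (n_boot + 1)
        per_otu[f"p_{f}"] = p_otu
        per_otu[f"q_{f}"] = _bh_adjust(p_otu)
        logger.info(
            "fit_differential: factor %s stat %.2f p %.4f (%d OTUs)",
            f, obs_stat, multivariate[f]["p"], int(ok.sum()),
        )

    fitted = pd.DataFrame(mu_full.T, index=otu_table.index, columns=otu_table.columns)
    resid = pd.DataFrame(
        ((Y - mu_full) / np.sqrt(mu_full + alpha[None, :] * mu_full**2)).T,
        index=otu_table.index,
        columns=otu_table.columns,
    )
    return DifferentialResult(per_otu, multivariate, fitted, resid)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def correlate_differential(
    sm_results: DifferentialResult,
    marker_results: DifferentialResult,
    sm_table: pd.DataFrame,
    marker_table: pd.DataFrame,
    marker_taxonomy: pd.DataFrame,
    domain: str,
    pairing_rules: dict[str, set[str]] | None = None,
    p_cutoff: float = 0.05,
    min_genus_abundance: float = 0.01,
) -> pd.DataFrame:
    """Spearman correlations of differentially abundant marker vs SM OTUs.

    Marker (16S) OTUs are restricted to phyla allowed for the SM ``domain``
    by the pairing rules, to genera above ``min_genus_abundance`` mean
    relative abundance, and to OTUs differentially abundant (raw p below
    ``p_cutoff`` for any tested factor) — likewise for SM OTUs. Returns a
    long table (marker_otu, sm_otu, rho, p) with tie-corrected Spearman.
    """
    pairing_rules = pairing_rules if pairing_rules is not None else DEFAULT_PAIRING
    shared = [s for s in marker_table.columns if s in set(sm_table.columns)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")

    def diff_otus(res: DifferentialResult, table: pd.DataFrame) -> list[str]:
        pcols = [c for c in res.per_otu.columns if c.startswith("p_")]
        mask = (res.per_otu[pcols] < p_cutoff).any(axis=1)
        return [o for o in table.index if o in res.per_otu.index[mask]]

    sm_otus = diff_otus(sm_results, sm_table)
    marker_otus = diff_otus(marker_results, marker_table)

    tax = marker_taxonomy.set_index("otu")
    allowed = pairing_rules.get(domain, set())
    marker_otus = [
        o for o in marker_otus
        if o in tax.index and str(tax.loc[o, "phylum"]) in allowed
    ]
    # genus-level >min abundance filter on mean relative abundance
    rel = marker_table[shared] / marker_table[shared].sum(axis=0)
    genus_of = {o: str(tax.loc[o, "genus"]) for o in marker_table.index if o in tax.index}
    genus_ab = rel.groupby(
        pd.Series(genus_of).reindex(marker_table.index)
    ).sum().mean(axis=1)
    good_genera = set(genus_ab.index[genus_ab > min_genus_abundance])
    marker_otus = [o for o in marker_otus if genus_of.get(o) in good_genera]

    rows = []
    for mo in marker_otus:
        for so in sm_otus:
            rho, p = sps.spearmanr(marker_table.loc[mo, shared], sm_table.loc[so, shared])
            rows.append({"marker_otu": mo, "sm_otu": so, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows, columns=["marker_otu", "sm_otu", "rho", "p"])
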