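"""Community-ecology statistics for kelp-forest survey data.

From-first-principles implementations of the statistics used to compare
benthic and fish assemblages between locations and wave exposures: diversity
indices (Margalef d, Shannon H', Pielou J'), the Index of Relative Dominance,
Bray-Curtis dissimilarity, two-way PERMANOVA with Type-III (partial) sums of
squares and permutation of residuals under the reduced model, pairwise
permutation tests, principal coordinates ordination with taxon vector
overlays, Pillai's-trace MANOVA, t-tests, and the chi-square composition test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ln1p_transform",
    "diversity_metrics",
    "DiversityRecord",
    "ird_score",
    "ird_table",
    "bray_curtis",
    "permanova",
    "permanova_2way",
    "pairwise_permanova",
    "pco",
    "PcoResult",
    "vector_overlay",
    "pillai_manova",
    "paired_t",
    "two_sample_t",
    "chi_square_composition",
]


# ---------------------------------------------------------------------------
# transforms and univariate community metrics

def ln1p_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise ln(x+1), the standard variance-stabilizing transform for
    community densities prior to Bray-Curtis analyses."""
    vals = np.asarray(matrix, dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(np.log1p(vals), index=matrix.index, columns=matrix.columns)
    return np.log1p(vals)


@dataclass
class DiversityRecord:
    S: int          # species with non-zero counts
    N: float        # total individuals
    d: float        # Margalef richness (S-1)/ln(N)
    H: float        # Shannon-Wiener diversity, nats
    J: float | None  # Pielou evenness H/ln(S); undefined for S = 1


def diversity_metrics(sample) -> DiversityRecord:
    """Diversity indices for one sample of counts (or densities).

    Natural logarithms throughout: d = (S-1)/ln(N), H = -sum p_i ln p_i,
    J = H/ln(S) (reported as missing when S = 1, since ln S = 0).
    """
    x = np.asarray(sample, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("sample has no positive counts")
    S = int(x.size)
    N = float(x.sum())
    p = x / N
    H = float(-(p * np.log(p)).sum())
    d = 0.0 if S == 1 else float((S - 1) / np.log(N))
    J = None if S == 1 else float(H / np.log(S))
    return DiversityRecord(S=S, N=N, d=d, H=H, J=J)


def ird_score(pct_num: float, pct_freq: float) -> tuple[float, int]:
    """Index of Relative Dominance from percentage inputs.

    IRD = % numerical abundance x % frequency of occurrence (both on the 0-100
    scale, so IRD ranges 0-10000). Returns (exact, rounded-to-nearest-integer).
    """
    ird = float(pct_num) * float(pct_freq)
    return ird, int(np.rint(ird))


def ird_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon dominance table ranked by the Index of Relative Dominance.

    %num is the taxon's share of the summed density across all samples (x100);
    %freq is the share of samples in which the taxon occurs (x100);
    IRD = %num x %freq, reported both unrounded and rounded to the nearest
    integer, sorted descending by IRD. Computed on raw densities (no
    transform).
    """
    if matrix.shape[0] < 1:
        raise ValueError("need at least one sample")
    vals = np.asarray(matrix, dtype=float)
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    total = vals.sum()
    if total == 0:
        raise ValueError("matrix is all zero")
    pct_num = vals.sum(axis=0) / total * 100.0
    pct_freq = (vals > 0).mean(axis=0) * 100.0
    ird = pct_num * pct_freq
    out = pd.DataFrame({
        "pct_num": pct_num,
        "pct_freq": pct_freq,
        "ird": ird,
        "ird_rounded": np.rint(ird).astype(int),
    }, index=matrix.columns)
    return out.sort_values("ird", ascending=False)


# ---------------------------------------------------------------------------
# dissimilarity and ordination

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix:
    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk), in [0, 1].

    A pair of all-zero samples has undefined composition; their distance is
    set to 0 with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if np.any(X < 0):
        raise ValueError("abundances must be non-negative")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    zero = den == 0
    if np.any(zero & ~np.eye(X.shape[0], dtype=bool)):
        warnings.warn("pairs of all-zero samples: distance set to 0 by convention")
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    np.fill_diagonal(D, 0.0)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(D, index=matrix.index, columns=matrix.index)
    return D


def _gower_center(D: np.ndarray) -> np.ndarray:
    """Gower-centered inner-product matrix G = -(1/2) C D^2 C."""
    n = D.shape[0]
    A = -0.5 * D**2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ A @ C


@dataclass
class PcoResult:
    coordinates: np.ndarray        # (n, n_pos) sample scores
    eigenvalues: np.ndarray        # all eigenvalues, sorted descending
    percent_variation: np.ndarray  # eigenvalue / sum(positive) * 100
    has_negative_eigenvalues: bool


def pco(dist) -> PcoResult:
    """Principal coordinates analysis (classical metric scaling).

    Eigen-decomposition of the Gower-centered matrix; coordinates are
    eigenvectors scaled by sqrt of the positive eigenvalues. Negative
    eigenvalues (possible for semimetric input such as Bray-Curtis) are
    retained in the report but excluded from the coordinates; percent
    variation is relative to the sum of positive eigenvalues only.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    G = _gower_center(D)
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals).max())
    pos = evals > tol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    pct = evals / evals[pos].sum() * 100.0
    return PcoResult(coordinates=coords, eigenvalues=evals,
                     percent_variation=pct,
                     has_negative_eigenvalues=bool(np.any(evals < -tol)))


def vector_overlay(pco_result: PcoResult, matrix: pd.DataFrame,
                   threshold: float = 0.5) -> pd.DataFrame:
    """Taxon vectors for ordination plots: Pearson correlations of each taxon
    with PCO axes 1-2; taxa whose max |r| >= threshold (default 0.5) are
    retained; zero-variance taxa are excluded with a warning."""
    coords = pco_result.coordinates
    if coords.shape[1] < 2:
        raise ValueError("need at least 2 positive PCO axes for an overlay")
    if coords.shape[0] != matrix.shape[0]:
        raise ValueError("pco result and matrix are not row-aligned")
    ax1, ax2 = coords[:, 0], coords[:, 1]
    rows = {}
    for taxon in matrix.columns:
        x = np.asarray(matrix[taxon], dtype=float)
        if x.std() == 0:
            warnings.warn(f"taxon {taxon!r} has zero variance: excluded from overlay")
            continue
        r1 = float(np.corrcoef(x, ax1)[0, 1])
        r2 = float(np.corrcoef(x, ax2)[0, 1])
        if max(abs(r1), abs(r2)) >= threshold:
            rows[taxon] = (r1, r2)
    return pd.DataFrame.from_dict(rows, orient="index", columns=["r_axis1", "r_axis2"])


# ---------------------------------------------------------------------------
# PERMANOVA

def _sum_to_zero_design(factors: pd.DataFrame, terms):
    """Sum-to-zero-coded columns for each requested term.

    Returns {term: (n, df) column block}. Interaction columns are elementwise
    products of the main-effect columns.
    """
    def main_cols(name):
        levels = sorted(pd.unique(factors[name]))
        if len(levels) < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
        cols = []
        for lev in levels[:-1]:
            c = np.where(factors[name] == lev, 1.0,
                         np.where(factors[name] == levels[-1], -1.0, 0.0))
            cols.append(c)
        return np.column_stack(cols)

    blocks = {}
    for term in terms:
        parts = term.split(":")
        block = main_cols(parts[0])
        for p in parts[1:]:
            other = main_cols(p)
            block = np.einsum("ni,nj->nij", block, other).reshape(len(factors), -1)
        blocks[term] = block
    return blocks


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(1.0, abs(R).max()))
    if rank < X.shape[1]:
        raise ValueError("design is confounded: a term is not estimable")
    return Q @ Q.T


def permanova(dist, factors: pd.DataFrame, terms=None, n_perm: int = 999,
              seed: int | None = None) -> pd.DataFrame:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    Partitions the Gower-centered matrix with Type-III (partial) sums of
    squares from sum-to-zero-coded design matrices; each term's null
    distribution is built by permutation of residuals under the reduced model
    (Freedman-Lane); p = (b+1)/(n_perm+1) where b counts permuted pseudo-F
    values >= the observed one.

    ``terms`` defaults to all factor columns plus all pairwise interactions.
    """
    if seed is None:
        raise ValueError("a permutation seed is required")
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if n != len(factors):
        raise ValueError("distance matrix and factor table sizes differ")
    if terms is None:
        mains = list(factors.columns)
        terms = mains + [f"{a}:{b}" for i, a in enumerate(mains) for b in mains[i + 1:]]
    blocks = _sum_to_zero_design(factors, terms)
    G = _gower_center(D)
    ss_total = float(np.trace(G))

    intercept = np.ones((n, 1))
    X_full = np.column_stack([intercept] + [blocks[t] for t in terms])
    H_full = _hat(X_full)
    df_terms = {t: blocks[t].shape[1] for t in terms}
    df_resid = n - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ss_resid = ss_total - float(np.trace(H_full @ G))

    rng = np.random.default_rng(seed)
    rows = []
    for term in terms:
        X_red = np.column_stack([intercept] + [blocks[t] for t in terms if t != term])
        H_red = _hat(X_red)
        R_red = np.eye(n) - H_red
        ss_term = float(np.trace(H_full @ G)) - float(np.trace(H_red @ G))
        F_obs = (ss_term / df_terms[term]) / (ss_resid / df_resid)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            M = H_red + R_red[perm]  # Freedman-Lane: permute reduced residuals
            Gp = M @ G @ M.T
            tr_full = float(np.trace(H_full @ Gp))
            ss_t = tr_full - float(np.trace(H_red @ Gp))
            ss_r = float(np.trace(Gp)) - tr_full
            F_p = (ss_t / df_terms[term]) / (ss_r / df_resid)
            # tolerance so that permutations tying the observed statistic
            # (e.g. group-preserving relabelings) count despite round-off
            if F_p >= F_obs - 1e-8 * max(1.0, abs(F_obs)):
                count += 1
        p = (count + 1) / (n_perm + 1)
        rows.append((term, df_terms[term], ss_term / df_terms[term], F_obs, p))
    rows.append(("Residual", df_resid, ss_resid / df_resid, np.nan, np.nan))
    rows.append(("Total", n - 1, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["source", "df", "MS", "pseudo_F", "p_perm"]
                        ).set_index("source")


def permanova_2way(dist, factors: pd.DataFrame, n_perm: int = 999,
                   seed: int | None = None) -> pd.DataFrame:
    """Two-way PERMANOVA with interaction (999 permutations by default),
    e.g. location x exposure on Bray-Curtis of ln(x+1) densities."""
    cols = list(factors.columns)
    if len(cols) != 2:
        raise ValueError("permanova_2way expects exactly two factor columns")
    terms = [cols[0], cols[1], f"{cols[0]}:{cols[1]}"]
    return permanova(dist, factors, terms=terms, n_perm=n_perm, seed=seed)


def pairwise_permanova(dist, factor: pd.Series, stratum: pd.Series | None = None,
                       n_perm: int = 999, seed: int | None = None) -> pd.DataFrame:
    """Pairwise comparisons between factor levels, optionally within each
    level of a stratifying factor; t = sqrt(pseudo-F) of the two-group one-way
    PERMANOVA on the subset, with a permutation p-value."""
    if seed is None:
        raise ValueError("a permutation seed is required")
    D = np.asarray(dist, dtype=float)
    factor = pd.Series(np.asarray(factor), name="g")
    strata = [None] if stratum is None else sorted(pd.unique(stratum))
    rng = np.random.default_rng(seed)
    rows = []
    levels = sorted(pd.unique(factor))
    for s in strata:
        in_stratum = np.ones(len(factor), dtype=bool) if s is None \
            else (np.asarray(stratum) == s)
        for i, a in enumerate(levels):
            for b in levels[i + 1:]:
                sel = in_stratum & factor.isin([a, b]).to_numpy()
                sub_g = factor[sel]
                if (sub_g == a).sum() < 2 or (sub_g == b).sum() < 2:
                    warnings.warn(f"pair ({a}, {b}) in stratum {s!r}: "
                                  "a level has < 2 samples, skipped")
                    continue
                sub_D = D[np.ix_(sel, sel)]
                tab = permanova(sub_D, pd.DataFrame({"g": sub_g.to_numpy()}),
                                terms=["g"], n_perm=n_perm,
                                seed=int(rng.integers(2**31 - 1)))
                F = tab.loc["g", "pseudo_F"]
                rows.append((s, a, b, float(np.sqrt(F)), tab.loc["g", "p_perm"]))
    return pd.DataFrame(rows, columns=["stratum", "level_a", "level_b", "t", "p_perm"])


# ---------------------------------------------------------------------------
# MANOVA and classical tests

def pillai_manova(data, groups) -> tuple[float, float, float]:
    """One-way MANOVA using Pillai's trace (robust to variance heterogeneity).

    Pillai V = sum_i lambda_i / (1 + lambda_i) over the eigenvalues of
    E^{-1} H; the F approximation uses s = min(p, g-1),
    m = (|p - g + 1| - 1)/2, n' = (N - g - p - 1)/2,
    F = [(2n'+s+1)/(2m+s+1)] * V/(s-V) on (s(2m+s+1), s(2n'+s+1)) df.

    Returns (pillai, F_approx, p).
    """
    Y = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2:
        raise ValueError("data must be 2-D (samples x responses)")
    N, p = Y.shape
    levels = np.unique(groups)
    g = len(levels)
    if g < 2:
        raise ValueError("need >= 2 groups")
    if N <= p + g:
        raise ValueError("need n > p + number of groups")
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lev in levels:
        Yg = Y[groups == lev]
        mg = Yg.mean(axis=0)
        H += len(Yg) * np.outer(mg - grand, mg - grand)
        resid = Yg - mg
        E += resid.T @ resid
    try:
        lam = np.linalg.eigvals(np.linalg.solve(E, H))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular error matrix: reduce the response set") from err
    lam = np.real(lam)
    V = float(np.sum(lam / (1.0 + lam)))
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    n_prime = (N - g - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * n_prime + s + 1)
    F = (df2 / df1) * V / (s - V) if s - V > 0 else np.inf
    p_val = float(stats.f.sf(F, df1, df2))
    return V, float(F), p_val


def paired_t(before, after) -> tuple[float, float]:
    """Paired t-test on site-matched differences (after - before),
    two-sided."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("paired samples must have equal lengths")
    if before.size < 3:
        raise ValueError("need n >= 3 pairs")
    d = after - before
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0, 1.0
    t = float(d.mean() / (sd / np.sqrt(d.size)))
    p = float(2.0 * stats.t.sf(abs(t), d.size - 1))
    return t, p


def two_sample_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))
    p = float(2.0 * stats.t.sf(abs(t), na + nb - 2))
    return t, p


def chi_square_composition(table) -> tuple[float, float]:
    """Pearson chi-square test of homogeneity of composition on an r x k
    contingency table ((r-1)(k-1) df, no continuity correction)."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-D")
    row = T.sum(axis=1, keepdims=True)
    col = T.sum(axis=0, keepdims=True)
    total = T.sum()
    if np.any(row == 0) or np.any(col == 0) or total == 0:
        raise ValueError("zero marginal in the contingency table")
    expected = row @ col / total
    X2 = float(((T - expected) ** 2 / expected).sum())
    df = (T.shape[0] - 1) * (T.shape[1] - 1)
    p = float(stats.chi2.sf(X2, df))
    return X2, p
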