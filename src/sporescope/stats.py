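"""Permutation statistics for morphometric tables.

Implements the analysis stack applied to calibrated trait tables with a
nested factor structure (site, host ploidy, individual, replicate):

* Euclidean distance matrices on (optionally z-scored) traits.
* Distance-based permutational multivariate ANOVA (PERMANOVA) with
  sequential (Type-I) sums of squares, pseudo-F, R², and seeded
  permutation p-values.
* Pairwise permutation tests between group levels with Holm-Bonferroni
  family-wise adjustment.
* Principal component analysis by singular value decomposition with a
  deterministic sign convention.
* Fisher linear discriminant analysis with leave-one-out cross-validation,
  reporting the confusion matrix, accuracy, and Cohen's kappa.
* One-way ANOVA with Tukey HSD compact letter display.
* Radial colony growth rate from diameter time series.

PERMANOVA follows the standard construction: with D the distance matrix,
A = -D²/2 is double-centered to G = J A J (J = I - 11'/n); the sum of
squares explained by a model term is tr((H_k - H_{k-1}) G) for the
sequential hat matrices H_k, and the pseudo-F for a term is
(SS_term/df_term) / (SS_residual/df_residual).  The permutation null
permutes the rows/columns of G jointly (free permutation by default,
optionally restricted within strata), and p-values use the
(1 + #{F* >= F}) / (1 + n_perm) estimator so they are never zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .errors import ValidationError


# ---------------------------------------------------------------------------
# distances

def standardize_traits(table: pd.DataFrame, traits: Sequence[str]) -> np.ndarray:
    """z-score trait columns (sample SD, n-1); errors on constant traits."""
    X = table[list(traits)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError("missing values in trait columns")
    sd = X.std(axis=0, ddof=1)
    for name, s in zip(traits, sd):
        if s == 0:
            raise ValidationError(f"trait {name!r} is constant; cannot standardize")
    return (X - X.mean(axis=0)) / sd


def euclidean_distances(
    table: pd.DataFrame, traits: Sequence[str], standardize: bool = True
) -> np.ndarray:
    """Pairwise Euclidean distance matrix on the selected trait columns.

    Traits are z-scored by default because morphometric traits mix units
    (µm and µm²); pass ``standardize=False`` for raw distances.
    """
    if len(table) < 2:
        raise ValidationError("need at least two rows")
    if standardize:
        X = standardize_traits(table, traits)
    else:
        X = table[list(traits)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValidationError("missing values in trait columns")
    return squareform(pdist(X, metric="euclidean"))


# ---------------------------------------------------------------------------
# PERMANOVA

@dataclass
class PermanovaResult:
    """Sequential PERMANOVA table plus the permutation settings used."""

    table: pd.DataFrame  # index: terms + Residual + Total
    n_perm: int
    seed: int

    def __str__(self) -> str:
        return (
            f"PERMANOVA ({self.n_perm} permutations, seed {self.seed})\n"
            + self.table.to_string(float_format=lambda v: f"{v:.4f}")
        )


def _dummy_matrix(labels: pd.Series) -> np.ndarray:
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValidationError(
            f"factor {labels.name!r} has a single level; cannot form a term"
        )
    return pd.get_dummies(pd.Categorical(labels)).to_numpy(dtype=float)


def _term_design(table: pd.DataFrame, term: str) -> np.ndarray:
    """Design columns for a term; ``a:b`` denotes an interaction."""
    if ":" in term:
        parts = term.split(":")
        combo = table[parts[0]].astype(str)
        for p in parts[1:]:
            combo = combo + "\x1f" + table[p].astype(str)
        combo.name = term
        return _dummy_matrix(combo)
    if term not in table.columns:
        raise ValidationError(f"unknown term column {term!r}")
    return _dummy_matrix(table[term])


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal projection onto the column space of X (via thin QR)."""
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    Q = Q[:, keep]
    return Q @ Q.T


def gower_center(dist: np.ndarray) -> np.ndarray:
    """Double-centered inner-product matrix G = J(-D²/2)J."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n):
        raise ValidationError("distance matrix must be square")
    A = -0.5 * dist ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    return J @ A @ J


def permanova(
    dist: np.ndarray,
    table: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Distance-based multivariate ANOVA with sequential (Type-I) SS.

    Terms are fitted in the listed order; each term's SS is the increment
    in explained sum of squares when its design columns are added after
    everything listed before it.  ``strata`` restricts permutations to
    shuffle rows only within the levels of that column.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(table)
    if dist.shape != (n, n):
        raise ValidationError("distance matrix does not match table rows")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if not terms:
        raise ValidationError("no model terms given")

    G = gower_center(dist)
    ss_total = float(np.trace(G))

    ones = np.ones((n, 1))
    designs = [ones]
    hats = [_hat(ones)]
    dfs: list[int] = []
    for term in terms:
        X = _term_design(table, term)
        designs.append(np.hstack([designs[-1], X]))
        H = _hat(designs[-1])
        df = int(round(np.trace(H) - np.trace(hats[-1])))
        if df < 1:
            raise ValidationError(f"term {term!r} adds no degrees of freedom")
        dfs.append(df)
        hats.append(H)
    H_full = hats[-1]
    df_resid = n - int(round(np.trace(H_full)))
    if df_resid < 1:
        raise ValidationError("saturated model: no residual degrees of freedom")
    # projector increments; F for a permuted G needs only elementwise sums
    deltas = [hats[k + 1] - hats[k] for k in range(len(terms))]
    resid_proj = np.eye(n) - H_full

    def term_stats(Gp: np.ndarray) -> tuple[np.ndarray, float]:
        ss = np.array([float(np.sum(d * Gp)) for d in deltas])
        ss_res = float(np.sum(resid_proj * Gp))
        return ss, ss_res

    ss_obs, ss_res_obs = term_stats(G)
    ms_res = ss_res_obs / df_resid
    f_obs = (ss_obs / np.asarray(dfs)) / ms_res

    rng = np.random.default_rng(seed)
    if strata is not None:
        groups = [np.flatnonzero(table[strata].to_numpy() == lvl)
                  for lvl in pd.unique(table[strata])]
    exceed = np.zeros(len(terms), dtype=int)
    idx = np.arange(n)
    for _ in range(n_perm):
        if strata is None:
            p = rng.permutation(n)
        else:
            p = idx.copy()
            for g in groups:
                p[g] = g[rng.permutation(len(g))]
        Gp = G[np.ix_(p, p)]
        ss_p, ss_res_p = term_stats(Gp)
        f_p = (ss_p / np.asarray(dfs)) / (ss_res_p / df_resid)
        # tolerance so permutations tied with the observed F count as >=
        exceed += f_p >= f_obs - 1e-9 * np.abs(f_obs)
    p_perm = (1 + exceed) / (1 + n_perm)

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_obs, f_obs, p_perm):
        rows.append({"df": df, "SS": ss, "R2": ss / ss_total,
                     "pseudo_F": f, "p_perm": p})
    rows.append({"df": df_resid, "SS": ss_res_obs,
                 "R2": ss_res_obs / ss_total, "pseudo_F": np.nan,
                 "p_perm": np.nan})
    rows.append({"df": n - 1, "SS": ss_total, "R2": 1.0,
                 "pseudo_F": np.nan, "p_perm": np.nan})
    out = pd.DataFrame(rows, index=[*terms, "Residual", "Total"])
    return PermanovaResult(table=out, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# pairwise permutation tests + Holm

def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment, returned in input order.

    The k-th smallest p is multiplied by (m - k + 1); a running maximum
    enforces monotonicity and values are capped at 1.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for k, i in enumerate(order):
        running = max(running, p[i] * (m - k))
        adj[i] = min(running, 1.0)
    return adj


@dataclass(frozen=True)
class PairwisePermResult:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_holm: float = np.nan


def pairwise_permutation_tests(
    table: pd.DataFrame,
    traits: Sequence[str],
    grouping: str,
    n_perm: int = 10_000,
    seed: int = 0,
    statistic: str = "centroid",
    standardize: bool = True,
) -> list[PairwisePermResult]:
    """Permutation tests for every unordered pair of group levels.

    The default statistic is the Euclidean distance between multivariate
    group centroids; passing a single trait name tests the absolute
    difference of that trait's group means.  The null is built by permuting
    group labels among the pair's rows; Holm adjustment is applied across
    all pairs.
    """
    levels = [lvl for lvl in pd.unique(table[grouping])]
    if len(levels) < 2:
        raise ValidationError(f"grouping {grouping!r} has fewer than 2 levels")
    if statistic == "centroid":
        X = (standardize_traits(table, traits) if standardize
             else table[list(traits)].to_numpy(dtype=float))
    else:
        if statistic not in table.columns:
            raise ValidationError(f"unknown per-trait statistic {statistic!r}")
        X = table[[statistic]].to_numpy(dtype=float)

    labels = table[grouping].to_numpy()
    rng = np.random.default_rng(seed)
    results: list[PairwisePermResult] = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            ia = np.flatnonzero(labels == a)
            ib = np.flatnonzero(labels == b)
            if len(ia) < 2 or len(ib) < 2:
                warnings.warn(
                    f"pair ({a}, {b}) skipped: a level has fewer than 2 rows",
                    stacklevel=2,
                )
                continue
            sub = X[np.concatenate([ia, ib])]
            na = len(ia)

            def stat(Z: np.ndarray) -> float:
                return float(np.linalg.norm(Z[:na].mean(axis=0) - Z[na:].mean(axis=0)))

            obs = stat(sub)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(len(sub))
                if stat(sub[perm]) >= obs - 1e-9 * abs(obs):
                    exceed += 1
            p_raw = (1 + exceed) / (1 + n_perm)
            results.append(PairwisePermResult(str(a), str(b), obs, p_raw))
    if results:
        adj = holm_adjust([r.p_raw for r in results])
        results = [
            PairwisePermResult(r.group_a, r.group_b, r.statistic, r.p_raw, float(q))
            for r, q in zip(results, adj)
        ]
    return results


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PcaResult:
    scores: np.ndarray       # n x k
    loadings: np.ndarray     # traits x k, orthonormal columns
    variance_fraction: np.ndarray
    cumulative_fraction: np.ndarray
    traits: list[str] = field(default_factory=list)


def pca(
    table: pd.DataFrame, traits: Sequence[str], scale_unit_variance: bool = True
) -> PcaResult:
    """Principal components by SVD of the centered (optionally z-scored) data.

    Sign convention: each loading column is flipped so its
    largest-magnitude element is positive, which makes outputs
    deterministic across platforms.
    """
    if scale_unit_variance:
        X = standardize_traits(table, traits)
    else:
        X = table[list(traits)].to_numpy(dtype=float)
        X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    for j in range(V.shape[1]):
        i_max = int(np.argmax(np.abs(V[:, j])))
        if V[i_max, j] < 0:
            V[:, j] *= -1
            U[:, j] *= -1
    var = s ** 2
    frac = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    return PcaResult(
        scores=U * s,
        loadings=V,
        variance_fraction=frac,
        cumulative_fraction=np.cumsum(frac),
        traits=list(traits),
    )


# ---------------------------------------------------------------------------
# LDA with leave-one-out cross-validation

@dataclass
class LdaCvResult:
    confusion_matrix: pd.DataFrame  # true x predicted counts
    accuracy: float
    kappa: float
    scheme: str = "leave-one-out"


def cohen_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement from a square confusion matrix."""
    confusion = np.asarray(confusion, dtype=float)
    n = confusion.sum()
    if n == 0:
        raise ValidationError("empty confusion matrix")
    po = np.trace(confusion) / n
    pe = float(confusion.sum(axis=1) @ confusion.sum(axis=0)) / n ** 2
    if pe == 1.0:
        return 0.0  # degenerate: a single observed/predicted class
    return float((po - pe) / (1 - pe))


class _FisherLda:
    """Gaussian LDA with pooled within-class covariance and equal priors.

    A small ridge (1e-8 of the mean variance) stabilizes the pooled
    covariance when n is small relative to the number of traits.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_FisherLda":
        self.classes_ = np.array(sorted(set(y), key=str))
        n, p = X.shape
        means, pooled = [], np.zeros((p, p))
        for c in self.classes_:
            Xc = X[y == c]
            means.append(Xc.mean(axis=0))
            pooled += (Xc - Xc.mean(axis=0)).T @ (Xc - Xc.mean(axis=0))
        self.means_ = np.array(means)
        pooled /= max(n - len(self.classes_), 1)
        pooled += self.ridge * np.trace(pooled) / p * np.eye(p)
        self.prec_ = np.linalg.pinv(pooled)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        # equal priors: discriminant d_k(x) = x'S⁻¹µ_k − µ_k'S⁻¹µ_k/2
        M = self.means_ @ self.prec_
        scores = X @ M.T - 0.5 * np.sum(M * self.means_, axis=1)
        return self.classes_[np.argmax(scores, axis=1)]


def lda_loocv(
    table: pd.DataFrame,
    traits: Sequence[str],
    grouping: str,
    standardize: bool = True,
) -> LdaCvResult:
    """Leave-one-out cross-validated LDA classification of group labels."""
    y = table[grouping].astype(str).to_numpy()
    classes = sorted(set(y))
    for c in classes:
        if (y == c).sum() < 2:
            raise ValidationError(f"group {c!r} has a single row; cannot LOOCV")
    X = (standardize_traits(table, traits) if standardize
         else table[list(traits)].to_numpy(dtype=float))
    n = len(y)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = _FisherLda().fit(X[mask], y[mask])
        preds[i] = clf.predict(X[i:i + 1])[0]
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, preds):
        conf.loc[t, p] += 1
    cm = conf.to_numpy()
    return LdaCvResult(
        confusion_matrix=conf,
        accuracy=float(np.trace(cm) / n),
        kappa=cohen_kappa(cm),
    )


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD compact letters

@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    letters: dict[str, str]            # group -> compact letter(s)
    pairwise_p: pd.DataFrame           # symmetric matrix of Tukey p-values
    alpha: float


def _tukey_pairwise_p(
    means: np.ndarray, ns: np.ndarray, ms_within: float, df_within: int
) -> np.ndarray:
    k = len(means)
    P = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            if ms_within == 0:
                p = 0.0 if means[i] != means[j] else 1.0
            else:
                se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(sps.studentized_range.sf(q, k, df_within))
            P[i, j] = P[j, i] = p
    return P


def _compact_letters(names: list[str], means: np.ndarray,
                     sig: np.ndarray) -> dict[str, str]:
    """Greedy compact letter display starting from the largest group mean.

    ``sig[i, j]`` is True when groups i and j differ significantly; two
    groups share a letter iff they are not significantly different.
    """
    order = np.argsort(-means)
    letter_sets: list[set[int]] = []
    for gi in order:
        placed = False
        for members in letter_sets:
            if all(not sig[gi, m] for m in members):
                members.add(gi)
                placed = True
        if not placed:
            letter_sets.append({int(gi)})
    # repair: every non-significant pair must share some letter
    k = len(names)
    for i in range(k):
        for j in range(i + 1, k):
            if sig[i, j] or any({i, j} <= s for s in letter_sets):
                continue
            members = {i, j}
            for gi in order:
                gi = int(gi)
                if gi not in members and all(not sig[gi, m] for m in members):
                    members.add(gi)
            letter_sets.append(members)
    # drop letter groups fully contained in another (redundant letters)
    keep = [s for s in letter_sets
            if not any(s < t for t in letter_sets if s is not t)]
    letters: dict[str, str] = {name: "" for name in names}
    for li, members in enumerate(keep):
        ch = chr(ord("a") + li)
        for m in sorted(members, key=lambda i: -means[i]):
            letters[names[m]] += ch
    return letters


def anova_tukey(
    values: Sequence[float], grouping: Sequence[str], alpha: float = 0.05
) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise tests and letter display.

    Groups sharing no letter differ at the given alpha.  With zero
    within-group variance and unequal means the pairwise p-values sit at
    the 0 floor and every distinct mean gets its own letter.
    """
    v = np.asarray(list(values), dtype=float)
    g = np.asarray([str(x) for x in grouping])
    if v.shape != g.shape:
        raise ValidationError("values and grouping must have equal length")
    names = sorted(set(g))
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    samples = [v[g == name] for name in names]
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    means = np.array([s.mean() for s in samples])
    ns = np.array([len(s) for s in samples])
    n, k = len(v), len(names)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    ss_between = float((ns * (means - v.mean()) ** 2).sum())
    df_w, df_b = n - k, k - 1
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ss_between > 0 else 0.0
        p = 0.0 if ss_between > 0 else 1.0
    else:
        f = (ss_between / df_b) / ms_w
        p = float(sps.f.sf(f, df_b, df_w))
    P = _tukey_pairwise_p(means, ns, ms_w, df_w)
    letters = _compact_letters(names, means, sig=P < alpha)
    pairwise = pd.DataFrame(P, index=names, columns=names)
    return AnovaTukeyResult(
        f_statistic=float(f), p_value=p, letters=letters,
        pairwise_p=pairwise, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# colony growth rate

@dataclass(frozen=True)
class GrowthRateResult:
    gr_mm_per_day: float


def growth_rate(series: Sequence[tuple[float, float]]) -> GrowthRateResult:
    """Radial growth rate: (final - initial diameter) / elapsed days."""
    pts = list(series)
    if len(pts) < 2:
        raise ValidationError("need at least two time points")
    days = np.array([p[0] for p in pts], dtype=float)
    diam = np.array([p[1] for p in pts], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValidationError("days must be strictly increasing")
    if np.any(diam < 0):
        raise ValidationError("diameters must be non-negative")
    gr = (diam[-1] - diam[0]) / (days[-1] - days[0])
    return GrowthRateResult(gr_mm_per_day=float(gr))
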