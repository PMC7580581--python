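"""Distance-based multivariate tests.

Implements sequential (Type I) PERMANOVA on a distance matrix: the total sum
of squared dissimilarities, tr(G) for the Gower-centered matrix G, is
partitioned among ordered model terms through hat matrices of cumulative
design matrices,

    SS_j = tr(H_j G) - tr(H_{j-1} G),     pseudo-F_j = (SS_j/df_j) / (SS_res/df_res),

with significance from free permutation of the samples (rows/columns of G),
using the add-one convention p = (#{F_perm >= F_obs} + 1) / (B + 1).  Nested
factors (family within colony) are encoded as parent:child interaction
columns entered after the parent, so their df is (#children - #parents).

Also provides the betadisper-style homogeneity-of-dispersions test (distance
to group centroid in PCoA space, with the negative-eigenvalue correction),
pairwise PERMANOVAs with Bonferroni correction, and the univariate
compound-count comparisons (t-test / one-way ANOVA).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dissimilarity import DistanceMatrix, gower_center
from .io import FingerprintError, SampleMetadata
from .ordination import pcoa

logger = logging.getLogger("furscent")

DEFAULT_PERMUTATIONS = 99_999

_RANK_TOL = 1e-8


# ---------------------------------------------------------------------------
# model specification

@dataclass(frozen=True)
class Term:
    """One model term: a metadata factor, optionally nested in a parent factor."""

    name: str
    column: str
    nested_in: str | None = None

    def labels(self, metadata: SampleMetadata) -> np.ndarray:
        child = metadata.column(self.column).astype(str)
        if self.nested_in is None:
            return child
        parent = metadata.column(self.nested_in).astype(str)
        return np.char.add(np.char.add(parent, ":"), child)


@dataclass(frozen=True)
class ModelSpec:
    """Ordered PERMANOVA terms plus the permutation settings.

    A nested child term must appear after its parent term.
    """

    terms: tuple[Term, ...]
    permutations: int = DEFAULT_PERMUTATIONS
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        seen: list[str] = []
        for t in self.terms:
            if t.nested_in is not None and t.nested_in not in seen:
                raise FingerprintError(
                    f"nested term {t.name!r} appears before its parent {t.nested_in!r}"
                )
            seen.append(t.column)

    @classmethod
    def from_formula(cls, formula: str, permutations: int = DEFAULT_PERMUTATIONS,
                     seed: int = 0) -> "ModelSpec":
        """Parse e.g. ``"age_class + colony + family_id %in% colony"``."""
        terms = []
        for part in formula.split("+"):
            part = part.strip()
            if not part:
                continue
            if "%in%" in part:
                child, parent = (x.strip() for x in part.split("%in%"))
                terms.append(Term(f"{child} (in {parent})", child, nested_in=parent))
            else:
                terms.append(Term(part, part))
        if not terms:
            raise FingerprintError(f"empty model formula {formula!r}")
        return cls(tuple(terms), permutations=permutations, seed=seed)


# ---------------------------------------------------------------------------
# result containers

@dataclass(frozen=True)
class PermanovaTable:
    """Per-term df, SS, pseudo-F, R-squared and permutation p, plus Residual/Total."""

    table: pd.DataFrame
    permutations: int

    def __getitem__(self, term: str) -> pd.Series:
        row = self.table[self.table["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]

    def r2(self, term: str) -> float:
        return float(self[term]["R2"])


@dataclass(frozen=True)
class DispersionResult:
    distances: np.ndarray          # per-sample distance to its group center
    group_means: pd.Series
    F: float
    df: tuple[int, int]
    p: float
    n_clamped: int
    sample_ids: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PairwiseTable:
    table: pd.DataFrame
    n_pairs: int


# ---------------------------------------------------------------------------
# design-matrix machinery

def _dummies(labels: np.ndarray) -> np.ndarray:
    levels, inv = np.unique(labels, return_inverse=True)
    X = np.zeros((labels.size, levels.size))
    X[np.arange(labels.size), inv] = 1.0
    return X


def _orthonormal_basis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank by SVD threshold)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    if s.size == 0:
        return U[:, :0]
    rank = int((s > _RANK_TOL * s[0] * max(X.shape)).sum())
    return U[:, :rank]


def _hat_matrices(metadata: SampleMetadata, terms: tuple[Term, ...]
                  ) -> tuple[list[np.ndarray], list[int]]:
    """Cumulative-projection hat matrices H_1..H_k and per-term df."""
    n = len(metadata.sample_ids)
    X = np.ones((n, 1))
    prev_rank = 1
    hats, dfs = [], []
    for t in terms:
        X = np.hstack([X, _dummies(t.labels(metadata))])
        Q = _orthonormal_basis(X)
        rank = Q.shape[1]
        df = rank - prev_rank
        if df < 1:
            raise FingerprintError(
                f"term {t.name!r} adds no estimable degrees of freedom "
                "(confounded with preceding terms)"
            )
        hats.append(Q @ Q.T)
        dfs.append(df)
        prev_rank = rank
    return hats, dfs


def _term_ss(G: np.ndarray, hats: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Sequential SS per term and residual SS, from tr(H_j G) differences."""
    tr = np.array([float((H * G).sum()) for H in hats])  # tr(H G), H symmetric
    ss_cum = np.concatenate([[0.0], tr])
    ss_terms = np.diff(ss_cum)
    ss_res = float(np.trace(G)) - tr[-1]
    return ss_terms, ss_res


def permutation_pvalue(observed: float, permuted: np.ndarray) -> float:
    """Add-one permutation p-value; ties count toward the numerator."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise FingerprintError("no permuted statistics supplied")
    return float((np.sum(permuted >= observed) + 1) / (permuted.size + 1))


def permanova(D: DistanceMatrix, metadata: SampleMetadata, model: ModelSpec
              ) -> PermanovaTable:
    """Sequential PERMANOVA of a distance matrix against ordered model terms.

    Metadata must be row-aligned to D.  All terms share one permutation
    stream; on very small n, where fewer distinct permutations exist than
    requested, the null is enumerated exhaustively instead.
    """
    if metadata.sample_ids != D.sample_ids:
        raise FingerprintError("metadata is not row-aligned to the distance matrix")
    n = D.n
    G = gower_center(D)
    hats, dfs = _hat_matrices(metadata, model.terms)
    ss_total = float(np.trace(G))
    ss_terms, ss_res = _term_ss(G, hats)
    df_res = (n - 1) - sum(dfs)
    if df_res < 1:
        raise FingerprintError("model leaves no residual degrees of freedom")
    ms_res = ss_res / df_res
    F_obs = (ss_terms / np.array(dfs)) / ms_res

    pvals = _permutation_null(G, hats, dfs, df_res, F_obs, model.permutations,
                              model.seed, n)

    rows = []
    for t, df, ss, f, p in zip(model.terms, dfs, ss_terms, F_obs, pvals):
        rows.append({"term": t.name, "df": df, "SS": ss, "F": f,
                     "R2": ss / ss_total, "p": p})
    rows.append({"term": "Residual", "df": df_res, "SS": ss_res, "F": np.nan,
                 "R2": ss_res / ss_total, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SS": ss_total, "F": np.nan,
                 "R2": 1.0, "p": np.nan})
    return PermanovaTable(pd.DataFrame(rows), model.permutations)


def _perm_F(G: np.ndarray, perm: np.ndarray, hats, dfs, df_res) -> np.ndarray:
    Gp = G[np.ix_(perm, perm)]
    ss_terms, ss_res = _term_ss(Gp, hats)
    return (ss_terms / np.asarray(dfs)) / (ss_res / df_res)


def _permutation_null(G, hats, dfs, df_res, F_obs, permutations, seed, n):
    if permutations <= 0:
        return [np.nan] * len(dfs)
    n_distinct = math.factorial(n)
    if n_distinct <= permutations:
        # exhaustive enumeration (identity included): p = #{F >= F_obs} / n!
        logger.info("permanova: enumerating all %d permutations exhaustively", n_distinct)
        counts = np.zeros(len(dfs))
        for perm in itertools.permutations(range(n)):
            F = _perm_F(G, np.array(perm), hats, dfs, df_res)
            counts += F >= F_obs - 1e-12
        return list(counts / n_distinct)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(dfs))
    for _ in range(permutations):
        perm = rng.permutation(n)
        F = _perm_F(G, perm, hats, dfs, df_res)
        counts += F >= F_obs
    return list((counts + 1) / (permutations + 1))


def permanova_oneway_oracle(D: DistanceMatrix, groups: np.ndarray) -> tuple[float, float]:
    """Brute-force one-way PERMANOVA F and R-squared via the group-sum identity.

    SS_total = (1/n) sum_{i<j} d_ij^2 ;  SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2.
    Independent of the hat-matrix route; used as a cross-check.
    """
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise FingerprintError("oracle needs at least 2 groups")
    if counts.min() < 1:
        raise FingerprintError("empty group")
    n = D.n
    D2 = D.D ** 2
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lev, n_g in zip(levels, counts):
        idx = np.nonzero(groups == lev)[0]
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / n_g
    ss_between = ss_total - ss_within
    a = levels.size
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    return float(F), float(ss_between / ss_total)


# ---------------------------------------------------------------------------
# homogeneity of multivariate dispersions (betadisper)

def _group_center_distances(real: np.ndarray, imag: np.ndarray, idx: np.ndarray,
                            center: str) -> tuple[np.ndarray, int]:
    """Distances of samples ``idx`` to their group center, PCoA-corrected.

    Squared distance = (squared distance on real axes) - (squared distance on
    imaginary axes); negatives are clamped to 0 and counted.
    """
    Xr, Xi = real[idx], imag[idx]
    if center == "centroid":
        cr, ci = Xr.mean(axis=0), Xi.mean(axis=0)
    elif center == "spatial_median":
        cr, ci = _weiszfeld(Xr), Xi.mean(axis=0)
    else:
        raise FingerprintError(f"unknown center {center!r}")
    d2 = ((Xr - cr) ** 2).sum(axis=1)
    if Xi.size:
        d2 = d2 - ((Xi - ci) ** 2).sum(axis=1)
    n_clamped = int((d2 < 0).sum())
    return np.sqrt(np.clip(d2, 0, None)), n_clamped


def _weiszfeld(X: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    c = X.mean(axis=0)
    for _ in range(max_iter):
        d = np.sqrt(((X - c) ** 2).sum(axis=1))
        if np.any(d < 1e-12):
            return c
        w = 1.0 / d
        c_new = (X * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(c_new - c) < tol:
            return c_new
        c = c_new
    return c


def betadisper(D: DistanceMatrix, groups: np.ndarray, center: str = "centroid",
               p_mode: str = "classical_F", permutations: int = 999,
               seed: int = 0) -> DispersionResult:
    """Test the homogeneity of multivariate group dispersions.

    Samples are embedded by PCoA; each sample's distance to its group center
    (centroid or spatial median) is computed with the negative-eigenvalue
    correction, then those distances are compared across groups by a one-way
    ANOVA F with (k-1, n-k) df.  The p-value comes from the F distribution
    (``classical_F``) or from permuting group labels over the distances
    (``permutation``).
    """
    groups = np.asarray(groups)
    levels, counts = np.unique(groups, return_counts=True)
    if levels.size < 2:
        raise FingerprintError("betadisper needs at least 2 groups")
    if counts.min() < 2:
        lev = levels[counts.argmin()]
        raise FingerprintError(f"group {lev!r} has fewer than 2 samples; "
                               "its dispersion is undefined")
    p = pcoa(D)
    z = np.empty(D.n)
    n_clamped = 0
    for lev in levels:
        idx = np.nonzero(groups == lev)[0]
        z[idx], c = _group_center_distances(p.real_axes, p.imaginary_axes, idx, center)
        n_clamped += c

    k, n = levels.size, D.n
    F = _anova_F(z, groups, levels)
    if p_mode == "classical_F":
        pval = float(stats.f.sf(F, k - 1, n - k)) if F > 0 else 1.0
    elif p_mode == "permutation":
        rng = np.random.default_rng(seed)
        perm_F = np.array([_anova_F(z[rng.permutation(n)], groups, levels)
                           for _ in range(permutations)])
        pval = permutation_pvalue(F, perm_F)
    else:
        raise FingerprintError(f"unknown p_mode {p_mode!r}")
    means = pd.Series({lev: z[groups == lev].mean() for lev in levels})
    return DispersionResult(distances=z, group_means=means, F=float(F),
                            df=(k - 1, n - k), p=pval, n_clamped=n_clamped,
                            sample_ids=list(D.sample_ids))


def _anova_F(z: np.ndarray, groups: np.ndarray, levels: np.ndarray) -> float:
    grand = z.mean()
    ss_b = ss_w = 0.0
    for lev in levels:
        zi = z[groups == lev]
        ss_b += zi.size * (zi.mean() - grand) ** 2
        ss_w += ((zi - zi.mean()) ** 2).sum()
    k, n = levels.size, z.size
    if ss_w == 0:
        return 0.0 if ss_b == 0 else np.inf
    return (ss_b / (k - 1)) / (ss_w / (n - k))


# ---------------------------------------------------------------------------
# pairwise PERMANOVAs with Bonferroni correction

def pairwise_permanova(D: DistanceMatrix, metadata: SampleMetadata,
                       grouping: str | list[str],
                       permutations: int = DEFAULT_PERMUTATIONS,
                       seed: int = 0) -> PairwiseTable:
    """One-way PERMANOVA for every unordered pair of grouping levels.

    ``grouping`` may be a single metadata column or a list of columns, whose
    values are joined with "/" to form a composite factor (e.g. colony x age
    giving the four mother/pup x colony groups).  Raw p-values are Bonferroni
    corrected by the number of pairs actually tested.
    """
    if metadata.sample_ids != D.sample_ids:
        raise FingerprintError("metadata is not row-aligned to the distance matrix")
    cols = [grouping] if isinstance(grouping, str) else list(grouping)
    labels = metadata.column(cols[0]).astype(str)
    for c in cols[1:]:
        labels = np.char.add(np.char.add(labels, "/"), metadata.column(c).astype(str))
    levels = np.unique(labels)
    if levels.size < 2:
        raise FingerprintError("grouping has fewer than 2 levels")

    rng = np.random.default_rng(seed)
    rows = []
    for a, b in itertools.combinations(levels, 2):
        idx = np.nonzero((labels == a) | (labels == b))[0]
        if min((labels[idx] == a).sum(), (labels[idx] == b).sum()) < 2:
            logger.info("pairwise_permanova: skipping %s vs %s (a level has <2 samples)",
                        a, b)
            continue
        sub_D = D.subset(idx)
        sub_meta = SampleMetadata(metadata.table.iloc[idx].assign(_pair_group=labels[idx]))
        model = ModelSpec((Term("group", "_pair_group"),), permutations=permutations,
                          seed=int(rng.integers(2 ** 31)))
        tab = permanova(sub_D, sub_meta, model)
        row = tab["group"]
        rows.append({"group_a": a, "group_b": b, "F": row["F"], "R2": row["R2"],
                     "p": row["p"]})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p"] * m)
    return PairwiseTable(out, n_pairs=m)


# ---------------------------------------------------------------------------
# univariate compound-count comparisons

def compare_counts(counts: np.ndarray, groups: np.ndarray, test: str = "t_test"
                   ) -> tuple[float, float]:
    """Compare per-sample compound counts across groups.

    ``t_test``: Student's two-sample equal-variance t (exactly 2 groups).
    ``anova``: one-way ANOVA F with (k-1, n-k) df.  Classical p-values.
    """
    counts = np.asarray(counts, dtype=float)
    groups = np.asarray(groups)
    levels, ns = np.unique(groups, return_counts=True)
    if ns.min() < 2:
        raise FingerprintError("every group needs at least 2 samples")
    samples = [counts[groups == lev] for lev in levels]
    if test == "t_test":
        if levels.size != 2:
            raise FingerprintError("t_test requires exactly 2 groups")
        t, p = stats.ttest_ind(samples[0], samples[1], equal_var=True)
        return float(t), float(p)
    if test == "anova":
        F, p = stats.f_oneway(*samples)
        return float(F), float(p)
    raise FingerprintError(f"unknown test {test!r}")
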