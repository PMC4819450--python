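"""Perceptual analysis: dissimilarity matrices, non-metric MDS, variance
partition, Williams' test, and repeated-measures ANOVA with the Huynh-Feldt
sphericity correction.

The rating experiment presents all ordered pairs of nine stimuli (a 3 x 3
grid of comodulation x modulation-gain values), each unordered pair ten
times in total; cell means form a symmetric 9 x 9 dissimilarity matrix that
is embedded in 1-3 dimensions by stress-minimizing MDS.  The position of
each stimulus on the dominant dimension is then regressed on candidate
auditory-model statistics to partition its variance, and dependent
correlations between candidate statistics and the perceptual axis are
compared with Williams' test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.manifold import MDS as _SKMDS

__all__ = [
    "DissimilarityMatrix",
    "MDSSolution",
    "VariancePartition",
    "build_dissimilarity",
    "nonmetric_mds",
    "align_dimension",
    "variance_partition",
    "williams_test",
    "rm_anova_hf",
]


@dataclass
class DissimilarityMatrix:
    labels: list[str]
    d: np.ndarray
    n_reps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(self.d < 0):
            raise ValueError("dissimilarities must be non-negative")


@dataclass
class MDSSolution:
    coords: dict[int, np.ndarray]   # k -> (n_stimuli x k), centred at the origin
    stress: dict[int, float]        # k -> stress-1
    method: str = "nonmetric"


@dataclass
class VariancePartition:
    predictor: str
    pct_var: float          # incremental R^2 over the listener-only model, x100
    partial_eta_sq: float   # incremental R^2 / (1 - listener-only R^2)

    def __post_init__(self) -> None:
        if not -1e-9 <= self.pct_var <= 100 + 1e-9:
            raise ValueError("pct_var must lie in [0, 100]")


def build_dissimilarity(ratings: pd.DataFrame) -> DissimilarityMatrix:
    """Mean-rating matrix from a trial table with columns stim_i, stim_j, rating.

    Ratings of (i, j) and (j, i) are pooled; the diagonal comes from
    same-stimulus pairs when present, else 0.  Missing off-diagonal pairs
    raise.
    """
    required = {"stim_i", "stim_j", "rating"}
    if not required.issubset(ratings.columns):
        raise ValueError(f"ratings table needs columns {sorted(required)}")
    labels = sorted(set(ratings["stim_i"]) | set(ratings["stim_j"]))
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    total = np.zeros((n, n))
    count = np.zeros((n, n), dtype=int)
    for si, sj, r in ratings[["stim_i", "stim_j", "rating"]].itertuples(index=False):
        i, j = index[si], index[sj]
        total[i, j] += r
        count[i, j] += 1
        if i != j:
            total[j, i] += r
            count[j, i] += 1
    off_diag_missing = (count == 0) & ~np.eye(n, dtype=bool)
    if off_diag_missing.any():
        missing = [
            (labels[i], labels[j]) for i, j in zip(*np.nonzero(np.triu(off_diag_missing)))
        ]
        raise ValueError(f"unrated stimulus pairs: {missing}")
    with np.errstate(invalid="ignore"):
        d = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    np.fill_diagonal(count, np.diag(count))
    return DissimilarityMatrix(labels=labels, d=d, n_reps=count)


def nonmetric_mds(
    dmat: DissimilarityMatrix,
    dims: tuple[int, ...] = (1, 2, 3),
    rng: np.random.Generator | None = None,
    n_init: int = 16,
    metric: bool = False,
) -> MDSSolution:
    """Best-of-``n_init`` stress-minimizing embedding for each dimensionality.

    Non-metric by default (isotonic-regression disparities, SMACOF
    majorization); stress is Kruskal's stress-1.  Coordinates are centred;
    orientation is arbitrary (solutions are defined up to rotation and
    reflection).
    """
    if np.allclose(dmat.d, dmat.d[0, 0]):
        raise ValueError("degenerate dissimilarity matrix: all entries equal")
    rng = rng or np.random.default_rng()
    coords: dict[int, np.ndarray] = {}
    stress: dict[int, float] = {}
    iu = np.triu_indices(len(dmat.labels), k=1)

    def _run(k: int, init: str, seed: int):
        mds = _SKMDS(
            n_components=k,
            metric_mds=metric,
            metric="precomputed",
            n_init=1,
            init=init,
            max_iter=2000,
            eps=1e-9,
            normalized_stress=not metric,
            random_state=seed,
        )
        xy = mds.fit_transform(dmat.d)
        from scipy.spatial.distance import pdist

        rho = sps.spearmanr(dmat.d[iu], pdist(xy)).statistic
        return xy, float(mds.stress_), float(rho)

    for k in dims:
        if not 1 <= k <= len(dmat.labels) - 1:
            raise ValueError(f"dimensionality {k} out of range")
        # One start from the classical (Torgerson) solution plus random
        # restarts.  Non-metric scaling from random starts can collapse into
        # degenerate cluster solutions with spuriously low stress; restarts
        # whose rank agreement falls clearly below the best seen are dropped.
        runs = [_run(k, "classical_mds", int(rng.integers(2**31)))]
        for _ in range(max(n_init - 1, 0)):
            runs.append(_run(k, "random", int(rng.integers(2**31))))
        best_rho = max(r[2] for r in runs)
        admissible = [r for r in runs if r[2] >= best_rho - 0.02]
        xy, s, _ = min(admissible, key=lambda r: r[1])
        xy = xy - xy.mean(axis=0, keepdims=True)
        # rotate to principal axes: the embedding is defined only up to
        # rotation, and "dimension 1" means the dominant axis of the
        # configuration
        _, _, vt = np.linalg.svd(xy, full_matrices=False)
        coords[k] = xy @ vt.T
        stress[k] = s
    return MDSSolution(coords=coords, stress=stress, method="nonmetric" if not metric else "metric")


def align_dimension(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Sign-align a 1-D coordinate vector to correlate positively with
    ``reference``, then z-score it (the MDS axis orientation and scale are
    arbitrary, so listeners must share a gauge before pooling)."""
    coords = np.asarray(coords, dtype=float).ravel()
    z = (coords - coords.mean()) / coords.std()
    r = np.corrcoef(z, reference)[0, 1]
    return -z if r < 0 else z


def variance_partition(
    coords_dim1: np.ndarray,
    statistic: np.ndarray,
    listeners: np.ndarray,
    name: str = "statistic",
    standardize: bool = True,
) -> VariancePartition:
    """Percent of dimension-1 variance accounted for by one model statistic.

    Fits coordinate ~ listener (fixed factor) and coordinate ~ listener +
    statistic by least squares; the quoted percentage is the incremental R^2
    of the statistic, x100.  Partial eta-squared (increment relative to the
    residual of the listener-only model) is reported alongside.

    With ``standardize`` (default) the statistic is z-scored within each
    listener before pooling: each listener has their own stimulus set, so
    the raw statistic ranges are listener-specific, and a single pooled
    slope is only meaningful on a common gauge (the coordinates themselves
    are already z-scored per listener).
    """
    y = np.asarray(coords_dim1, dtype=float).ravel()
    s = np.asarray(statistic, dtype=float).ravel()
    g = np.asarray(listeners).ravel()
    if not (y.size == s.size == g.size):
        raise ValueError("inputs must have equal lengths")
    if np.std(s) == 0:
        raise ValueError("constant statistic; variance partition undefined")
    if standardize:
        s = s.copy()
        for lev in np.unique(g):
            m = g == lev
            sd = s[m].std()
            if sd == 0:
                raise ValueError(f"constant statistic within listener {lev!r}")
            s[m] = (s[m] - s[m].mean()) / sd
    dummies = pd.get_dummies(pd.Series(g)).to_numpy(dtype=float)
    X0 = dummies
    X1 = np.column_stack([dummies, s])
    if np.linalg.matrix_rank(X1) <= np.linalg.matrix_rank(X0):
        raise ValueError("statistic is collinear with the listener factor")

    def r2(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        return 1.0 - np.sum(resid**2) / tss

    r2_0, r2_1 = r2(X0), r2(X1)
    inc = max(r2_1 - r2_0, 0.0)
    partial = inc / (1.0 - r2_0) if r2_0 < 1.0 else np.nan
    return VariancePartition(predictor=name, pct_var=100.0 * inc, partial_eta_sq=partial)


def williams_test(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Williams' t for the difference of two dependent correlations sharing j.

    Tests H0: rho(j,k) = rho(j,h) given the correlation r(k,h) between the
    two competing variables, on n - 3 degrees of freedom (two-sided p).
    """
    for r in (r_jk, r_jh, r_kh):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    if n <= 3:
        raise ValueError("need n > 3")
    det = 1.0 - r_jk**2 - r_jh**2 - r_kh**2 + 2.0 * r_jk * r_jh * r_kh
    if det < -1e-12:
        raise ValueError("correlation triple is not positive semidefinite")
    det = max(det, 0.0)
    rbar = 0.5 * (r_jk + r_jh)
    denom = 2.0 * det * (n - 1) / (n - 3) + rbar**2 * (1.0 - r_kh) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation triple")
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh) / denom)
    p = 2.0 * sps.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (Helmert, normalized)."""
    m = np.zeros((k - 1, k))
    for i in range(k - 1):
        m[i, : i + 1] = 1.0
        m[i, i + 1] = -(i + 1.0)
        m[i] /= np.linalg.norm(m[i])
    return m


def _hf_epsilon(y: np.ndarray, contrast: np.ndarray) -> tuple[float, float]:
    """Greenhouse-Geisser and Huynh-Feldt epsilon for one within effect.

    ``y`` is subjects x levels (or subjects x cells for an interaction) and
    ``contrast`` the orthonormal contrast matrix of the effect.
    """
    n = y.shape[0]
    d = contrast.shape[0]
    c = y @ contrast.T
    s = np.cov(c, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    gg = np.trace(s) ** 2 / (d * np.sum(s * s))
    hf = (n * d * gg - 2.0) / (d * (n - 1.0) - d**2 * gg)
    return float(gg), float(min(hf, 1.0))


def rm_anova_hf(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    within: tuple[str, str] = ("factor_a", "factor_b"),
) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA with Huynh-Feldt corrected p-values.

    Requires one observation (cell mean) per subject x factorA x factorB
    combination.  Returns one row per effect (A, B, A x B) with the F ratio,
    uncorrected degrees of freedom, the Huynh-Feldt epsilon and the p-value
    from F evaluated at epsilon-scaled degrees of freedom.
    """
    fa, fb = within
    cells = data.pivot_table(index=subject, columns=[fa, fb], values=dv, aggfunc="mean")
    if cells.isna().any().any():
        raise ValueError("design is unbalanced: missing subject x cell combinations")
    counts = data.groupby([subject, fa, fb], observed=True)[dv].count()
    if counts.nunique() != 1:
        raise ValueError("design is unbalanced: unequal cell counts")
    a_levels = cells.columns.get_level_values(0).unique()
    b_levels = cells.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    n = cells.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    y = cells.to_numpy().reshape(n, a, b)

    grand = y.mean()
    subj_m = y.mean(axis=(1, 2))
    a_m = y.mean(axis=(0, 2))
    b_m = y.mean(axis=(0, 1))
    ab_m = y.mean(axis=0)
    as_m = y.mean(axis=2)
    bs_m = y.mean(axis=1)

    ss_a = n * b * np.sum((a_m - grand) ** 2)
    ss_b = n * a * np.sum((b_m - grand) ** 2)
    ss_ab = n * np.sum((ab_m - a_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_as = b * np.sum((as_m - subj_m[:, None] - a_m[None, :] + grand) ** 2)
    ss_bs = a * np.sum((bs_m - subj_m[:, None] - b_m[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_subj = a * b * np.sum((subj_m - grand) ** 2)
    ss_abs = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    ca, cb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    rows = []
    for name, ss_eff, ss_err, df_eff, df_err, ymat, contrast in [
        (fa, ss_a, ss_as, a - 1, (a - 1) * (n - 1), as_m, ca),
        (fb, ss_b, ss_bs, b - 1, (b - 1) * (n - 1), bs_m, cb),
        (f"{fa}*{fb}", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
         y.reshape(n, a * b), np.kron(ca, cb)),
    ]:
        f_stat = (ss_eff / df_eff) / (ss_err / df_err)
        gg, hf = _hf_epsilon(ymat, contrast)
        p = float(sps.f.sf(f_stat, hf * df_eff, hf * df_err))
        rows.append(
            {
                "effect": name, "F": float(f_stat), "df1": df_eff, "df2": df_err,
                "eps_gg": gg, "eps_hf": hf, "p_hf": p,
                "p_uncorrected": float(sps.f.sf(f_stat, df_eff, df_err)),
            }
        )
    return pd.DataFrame(rows)
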