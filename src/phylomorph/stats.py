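"""Morphospace and disparity statistics on aligned shape coordinates.

All statistics operate on flattened Procrustes coordinates (n specimens x
3K variables): PCA of the coordinate covariance as the tangent-space
ordination, linear models with permutation tests by residual randomization
(RRPP), and morphological disparity partitioned into Foote's per-group
partial disparities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AlignedDataset

__all__ = [
    "ShapePCA",
    "AnovaTerm",
    "AnovaResult",
    "DisparityReport",
    "shape_pca",
    "mean_shape",
    "design_matrices",
    "linear_model_anova",
    "procrustes_anova",
    "disparity",
]


@dataclass
class ShapePCA:
    eigenvalues: np.ndarray  # descending, length m (nonzero components retained)
    eigenvectors: np.ndarray  # (p, m), orthonormal columns
    scores: np.ndarray  # (n, m)
    percent_variance: np.ndarray  # (m,), sums to 100
    mean: np.ndarray  # (p,) mean flattened shape

    def project(self, flat_shapes: np.ndarray) -> np.ndarray:
        """Project new flattened shapes (rows) into the PC space."""
        return (np.atleast_2d(flat_shapes) - self.mean) @ self.eigenvectors


@dataclass
class AnovaTerm:
    name: str
    df: int
    ss: float
    ms: float
    f: float
    p_value: float | None = None
    z_score: float | None = None
    perm_distribution: np.ndarray | None = None


@dataclass
class AnovaResult:
    terms: list[AnovaTerm]
    df_residual: int
    ss_residual: float
    ss_total: float
    n_perm: int

    def term(self, name: str) -> AnovaTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass
class DisparityReport:
    overall_md: float
    group_pd: dict[str, float]
    group_pd_percent: dict[str, float]
    group_variance: dict[str, float]
    group_n: dict[str, int] = field(default_factory=dict)


def _flat(aligned) -> np.ndarray:
    if isinstance(aligned, AlignedDataset):
        return aligned.flat()
    arr = np.asarray(aligned, dtype=float)
    if arr.ndim == 3:
        arr = arr.reshape(arr.shape[0], -1)
    return arr


def shape_pca(aligned, n_components: int | None = None) -> ShapePCA:
    """PCA of mean-centered flattened shape coordinates.

    Components with numerically zero variance (rank deficiency from the
    superimposition constraints) are dropped, so ``percent_variance`` sums
    to 100 over the retained components and full-space score distances equal
    inter-shape Procrustes distances.
    """
    x = _flat(aligned)
    n = x.shape[0]
    if n < 3:
        raise ValueError("PCA needs at least 3 specimens")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    scale = max(float(mean @ mean), 1e-300)
    if total <= scale * 1e-24:
        raise ValueError("zero total shape variance: all specimens identical")
    keep = eig > eig[0] * 1e-12
    eig, vt, s = eig[keep], vt[keep], s[keep]
    if n_components is not None:
        eig, vt, s = eig[:n_components], vt[:n_components], s[:n_components]
    scores = xc @ vt.T
    return ShapePCA(
        eigenvalues=eig,
        eigenvectors=vt.T,
        scores=scores,
        percent_variance=100.0 * eig / total,
        mean=mean,
    )


def mean_shape(aligned: AlignedDataset, subset=None) -> np.ndarray:
    """Coordinate-wise arithmetic mean shape of a (subset of a) dataset."""
    shapes = aligned.shapes
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValueError("empty specimen selection")
        shapes = shapes[subset.astype(int) if subset.dtype != bool else subset]
    if shapes.shape[0] == 0:
        raise ValueError("empty specimen selection")
    return shapes.mean(axis=0)


def design_matrices(factors: dict[str, np.ndarray], n: int) -> list[tuple[str, np.ndarray]]:
    """Sequential dummy-coded design blocks, one per factor, after an intercept.

    Each categorical factor contributes treatment-coded columns (first level
    as baseline, levels in sorted order).
    """
    blocks: list[tuple[str, np.ndarray]] = []
    for name, labels in factors.items():
        labels = np.asarray(labels)
        if labels.shape[0] != n:
            raise ValueError(f"factor {name!r} has {labels.shape[0]} entries, expected {n}")
        levels = np.unique(labels)
        if levels.size < 2:
            raise ValueError(f"factor {name!r} has a single level: zero degrees of freedom")
        cols = np.stack([(labels == lv).astype(float) for lv in levels[1:]], axis=1)
        blocks.append((name, cols))
    return blocks


def _fit_rss(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit; returns fitted values and residual sum of squares."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta
    return fitted, float(((y - fitted) ** 2).sum())


def linear_model_anova(
    y: np.ndarray,
    blocks: list[tuple[str, np.ndarray]],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    effect_size_on_log: bool = True,
    intercept: np.ndarray | None = None,
) -> AnovaResult:
    """Multivariate linear-model ANOVA with sequential (Type I) sums of squares
    and significance by residual randomization (RRPP).

    For each term k the reduced model contains the intercept and terms
    1..k-1.  The term SS is the drop in residual SS when the term enters.
    The null distribution of each term's F is built by permuting the
    reduced-model residuals across observations, adding them back to the
    reduced-model fitted values, and refitting; the observed statistic is
    included in the permutation distribution and in the p-value denominator.

    The effect size Z is the standard deviate of the observed statistic
    within its permutation distribution, computed on log F by default (raw F
    when any F is non-positive).
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n = y.shape[0]
    if intercept is None:
        intercept = np.ones((n, 1))

    xs = [intercept]
    for _, cols in blocks:
        xs.append(np.hstack([xs[-1], cols]))

    rss = []
    fits = []
    for x in xs:
        fitted, r = _fit_rss(x, y)
        rss.append(r)
        fits.append(fitted)
    ss_total = rss[0]
    ss_res = rss[-1]
    df_model = [x.shape[1] for x in xs]
    df_res = n - df_model[-1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res

    terms: list[AnovaTerm] = []
    for k, (name, _) in enumerate(blocks):
        df_k = df_model[k + 1] - df_model[k]
        ss_k = rss[k] - rss[k + 1]
        ms_k = ss_k / df_k
        f_k = ms_k / ms_res if ms_res > 0 else np.inf
        terms.append(AnovaTerm(name=name, df=df_k, ss=ss_k, ms=ms_k, f=f_k))

    if n_perm >= 1:
        # hat matrices are fixed across permutations: rss under permuted data
        # reduces to quadratic forms, so each permutation is a matmul
        hats = [x @ np.linalg.pinv(x) for x in xs]
        for k, term in enumerate(terms):
            resid_red = y - fits[k]
            f_perm = np.empty(n_perm + 1)
            f_perm[0] = term.f
            df_k = term.df
            q_red = np.eye(n) - hats[k]
            q_full = np.eye(n) - hats[k + 1]
            q_last = np.eye(n) - hats[-1]
            for j in range(n_perm):
                y_star = fits[k] + resid_red[rng.permutation(n)]
                rss_red = float((q_red @ y_star).ravel() @ (q_red @ y_star).ravel())
                rss_full = float((q_full @ y_star).ravel() @ (q_full @ y_star).ravel())
                rss_last = (
                    rss_full
                    if k + 2 == len(xs)
                    else float((q_last @ y_star).ravel() @ (q_last @ y_star).ravel())
                )
                ms_r = rss_last / df_res
                f_perm[j + 1] = ((rss_red - rss_full) / df_k) / ms_r if ms_r > 0 else np.inf
            term.perm_distribution = f_perm
            term.p_value = float((f_perm >= term.f - 1e-14).sum() / (n_perm + 1))
            if effect_size_on_log and np.all(f_perm > 0):
                stat = np.log(f_perm)
            else:
                stat = f_perm
            sd = stat.std(ddof=1)
            term.z_score = float((stat[0] - stat.mean()) / sd) if sd > 0 else 0.0

    return AnovaResult(
        terms=terms,
        df_residual=df_res,
        ss_residual=ss_res,
        ss_total=ss_total,
        n_perm=n_perm,
    )


def procrustes_anova(
    aligned,
    factors: dict[str, np.ndarray],
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    effect_size_on_log: bool = True,
) -> AnovaResult:
    """Procrustes ANOVA: linear model on flattened shape coordinates with RRPP.

    ``factors`` maps factor name to a per-specimen label array; terms enter
    the model in dict order (sequential SS).  Nested designs such as the
    measurement-error layout (individual as the factor, replicate as
    residual) are expressed by passing the individual labels as a factor.
    """
    y = _flat(aligned)
    blocks = design_matrices(factors, y.shape[0])
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return linear_model_anova(
        y, blocks, n_perm=n_perm, rng=rng, effect_size_on_log=effect_size_on_log
    )


def disparity(
    aligned,
    groups: np.ndarray,
    group_variance_ddof: int = 0,
) -> DisparityReport:
    """Overall morphological disparity and Foote's per-group partial disparity.

    Overall disparity (MD) is the Procrustes variance: summed squared
    distances of specimens to the grand mean divided by N - 1.  A group's
    partial disparity (PD) restricts the sum to its members (same grand-mean
    residuals, same N - 1 denominator), so group PDs sum exactly to MD.  The
    per-group variance instead uses residuals from the group's own mean,
    divided by n_g (``group_variance_ddof=0``, matching Procrustes-variance
    convention) or n_g - 1 (``group_variance_ddof=1``).
    """
    x = _flat(aligned)
    n = x.shape[0]
    if n < 2:
        raise ValueError("disparity undefined for fewer than 2 specimens")
    groups = np.asarray(groups)
    if groups.shape[0] != n:
        raise ValueError("one group label per specimen required")
    grand = x.mean(axis=0)
    sq = ((x - grand) ** 2).sum(axis=1)
    md = float(sq.sum() / (n - 1))
    pd: dict[str, float] = {}
    pct: dict[str, float] = {}
    gv: dict[str, float] = {}
    gn: dict[str, int] = {}
    for g in np.unique(groups):
        m = groups == g
        n_g = int(m.sum())
        pd_g = float(sq[m].sum() / (n - 1))
        pd[str(g)] = pd_g
        pct[str(g)] = 100.0 * pd_g / md if md > 0 else 0.0
        denom = n_g - group_variance_ddof
        gmean = x[m].mean(axis=0)
        gv[str(g)] = float(((x[m] - gmean) ** 2).sum() / denom) if denom > 0 else np.nan
        gn[str(g)] = n_g
    return DisparityReport(
        overall_md=md, group_pd=pd, group_pd_percent=pct, group_variance=gv, group_n=gn
    )
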