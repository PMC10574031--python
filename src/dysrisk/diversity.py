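"""Alpha- and beta-diversity statistics for ASV count tables.

Alpha diversity: Chao1 richness (bias-corrected by default, matching the
vegan estimator), Shannon entropy in nats, and the Simpson complement
1 - sum p_i^2.  Beta diversity: pairwise Jensen-Shannon divergence on
relative-abundance profiles, one-factor PERMANOVA with permutation p-values,
a dispersion-homogeneity (betadisper-style) test, and classical PCoA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import jensenshannon
from statsmodels.stats.multitest import multipletests

from .model import CountTable, ValidationError

UNCLASSIFIED = "Unclassified"


# ---------------------------------------------------------------------------
# alpha diversity

def _as_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.size and not np.issubdtype(c.dtype, np.integer):
        if np.any(np.modf(c.astype(float))[0] != 0):
            raise ValidationError(
                "richness estimators are undefined on non-integer (relative) abundances"
            )
        c = c.astype(np.int64)
    if c.size and (c < 0).any():
        raise ValidationError("negative counts")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 estimated richness from one sample's taxon counts.

    Uses singletons F1 and doubletons F2 to extrapolate unseen taxa:
    bias-corrected (default)  S_obs + F1(F1-1) / (2(F2+1));
    classic                   S_obs + F1^2 / (2 F2), falling back to the
    bias-corrected form when F2 = 0.  An empty (all-zero) sample yields 0.
    """
    c = _as_counts(counts)
    s_obs = int((c > 0).sum())
    if s_obs == 0:
        return 0.0
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if bias_corrected or f2 == 0:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return s_obs + f1 * f1 / (2.0 * f2)


def _proportions(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValidationError("sample has zero total count")
    p = c[c > 0] / total
    return p


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p, in nats."""
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Simpson diversity as the complement 1 - sum p_i^2."""
    p = _proportions(counts)
    return float(1.0 - (p * p).sum())


def alpha_table(table: CountTable, bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample alpha-diversity records (observed, chao1, shannon, simpson)."""
    rows = []
    for sid, row in zip(table.sample_ids, table.counts):
        rows.append({
            "sample_id": sid,
            "observed": int((row > 0).sum()),
            "chao1": chao1(row, bias_corrected=bias_corrected),
            "shannon": shannon(row),
            "simpson": simpson(row),
        })
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# phylum summaries

def phylum_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundance aggregated to phylum.

    Rows sum to 1 over named phyla plus an ``Unclassified`` bucket for taxa
    lacking a phylum-rank lineage.  Columns are ordered by decreasing mean
    abundance (Unclassified last on ties by name).
    """
    from .io import phylum_of

    if not any(t in table.taxonomy for t in table.taxon_ids):
        raise ValidationError("no taxonomy available for any taxon")
    totals = table.counts.sum(axis=1)
    zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValidationError(f"samples with zero total reads: {zero}")

    phyla = []
    for t in table.taxon_ids:
        lin = table.taxonomy.get(t)
        phyla.append((phylum_of(lin) if lin else None) or UNCLASSIFIED)
    df = pd.DataFrame(table.counts, index=table.sample_ids, columns=phyla)
    agg = df.T.groupby(level=0).sum().T
    rel = agg.div(agg.sum(axis=1), axis=0)
    order = rel.mean(axis=0).sort_values(ascending=False, kind="stable").index
    return rel[order]


def fb_ratio(
    phylum_rel: pd.DataFrame,
    groups: pd.Series | None = None,
    *,
    firmicutes: str = "Firmicutes",
    bacteroidetes: str = "Bacteroidetes",
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample Firmicutes/Bacteroidetes ratio and group mean +- SD.

    Samples with zero Bacteroidetes share have an undefined ratio; they are
    flagged (NaN), excluded from the summary, and a warning is emitted.
    """
    for name in (firmicutes, bacteroidetes):
        if name not in phylum_rel.columns:
            raise ValidationError(
                f"phylum {name!r} absent; available: {list(phylum_rel.columns)}"
            )
    denom = phylum_rel[bacteroidetes]
    flagged = denom == 0
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} sample(s) with zero {bacteroidetes}; "
            "ratio undefined, excluded from summary",
            stacklevel=2,
        )
    ratio = phylum_rel[firmicutes] / denom.where(~flagged)
    ratio.name = "fb_ratio"
    if groups is None:
        groups = pd.Series("all", index=ratio.index)
    summary = (
        ratio.groupby(groups.reindex(ratio.index))
        .agg(["mean", "std", "count"])
        .rename(columns={"count": "n"})
    )
    return ratio, summary


# ---------------------------------------------------------------------------
# beta diversity

@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("non-finite distances")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.abs(np.diag(self.d)) > 1e-12):
            raise ValidationError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValidationError("negative distances")
        self.d = np.clip((self.d + self.d.T) / 2.0, 0.0, None)
        np.fill_diagonal(self.d, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


def jsd_matrix(table: CountTable, *, sqrt: bool = False) -> DistanceMatrix:
    """Pairwise Jensen-Shannon divergence between relative-abundance profiles.

    Natural-log JSD:  JSD(P,Q) = 1/2 KL(P||M) + 1/2 KL(Q||M), M = (P+Q)/2,
    bounded by ln 2.  ``sqrt=True`` returns the square-root metric instead.
    """
    counts = np.asarray(table.counts, dtype=float)
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t <= 0]
        raise ValidationError(f"samples with zero total: {bad}")
    p = counts / totals[:, None]
    n = p.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # scipy returns sqrt(JSD) in the requested log base
            root = jensenshannon(p[i], p[j], base=np.e)
            d[i, j] = d[j, i] = root if sqrt else root * root
    return DistanceMatrix(list(table.sample_ids), d)


@dataclass
class PermanovaResult:
    """One-factor PERMANOVA summary."""

    pseudo_f: float
    r2: float
    p_raw: float
    n_permutations: int
    p_adjusted: float | None = None
    n_samples: int = 0
    n_groups: int = 0

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _group_indicator(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    levels, codes = np.unique(groups, return_inverse=True)
    onehot = np.zeros((len(groups), len(levels)))
    onehot[np.arange(len(groups)), codes] = 1.0
    return levels, onehot


def _permanova_f(d2: np.ndarray, onehot: np.ndarray) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared distances and a one-hot group matrix."""
    n = d2.shape[0]
    a = onehot.shape[1]
    sizes = onehot.sum(axis=0)
    ss_total = d2.sum() / (2.0 * n)
    within = np.einsum("ig,ij,jg->g", onehot, d2, onehot) / (2.0 * sizes)
    ss_within = within.sum()
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total
    return float(f), float(r2)


def permanova(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    Partitions the total sum of squared distances (Gower form: SS_total =
    sum_{i<j} d_ij^2 / n, SS_within pooled over groups with group-size
    divisors) and tests the pseudo-F by label permutation with the
    (b+1)/(m+1) estimator.
    """
    groups = np.asarray(list(groups))
    n = dm.d.shape[0]
    if len(groups) != n:
        raise ValidationError("group vector length does not match distance matrix")
    levels, onehot = _group_indicator(groups)
    sizes = onehot.sum(axis=0)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    if (sizes < 2).any():
        small = [str(l) for l, s in zip(levels, sizes) if s < 2]
        raise ValidationError(f"groups of size < 2: {small}")
    d2 = dm.d ** 2
    f_obs, r2 = _permanova_f(d2, onehot)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        f_perm, _ = _permanova_f(d2, onehot[perm])
        if f_perm >= f_obs:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=f_obs, r2=r2, p_raw=p,
        n_permutations=n_permutations, n_samples=n, n_groups=len(levels),
    )


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjustment across a battery of hypotheses."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray            # (n, k)
    eigenvalues: np.ndarray            # all n eigenvalues, descending
    explained: np.ndarray              # fraction of positive-eigenvalue sum, per axis

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)


def pcoa(dm: DistanceMatrix, k: int = 2) -> PcoaResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers -1/2 d^2 and eigendecomposes.  Negative eigenvalues are
    reported in full, never silently dropped; if ``k`` exceeds the number of
    positive eigenvalues the embedding is truncated with a warning.
    """
    d2 = dm.d ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-10, 1e-10 * abs(evals[0]) if n else 0)
    n_pos = int(pos.sum())
    if k > n_pos:
        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        k = n_pos
    coords = evecs[:, :k] * np.sqrt(evals[:k]) if k else np.zeros((n, 0))
    pos_sum = evals[pos].sum()
    explained = (evals[:k] / pos_sum) if pos_sum > 0 else np.zeros(k)
    return PcoaResult(list(dm.sample_ids), coords, evals, explained)


def betadisper_test(
    dm: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int | None = 0,
) -> dict:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Embeds the samples by PCoA (all positive axes), computes each sample's
    Euclidean distance to its group centroid, forms the one-way ANOVA
    F-statistic on those distances, and obtains a permutation p-value by
    relabeling with the (b+1)/(m+1) estimator.
    """
    groups = np.asarray(list(groups))
    n = dm.d.shape[0]
    if len(groups) != n:
        raise ValidationError("group vector length does not match distance matrix")
    levels, onehot = _group_indicator(groups)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    sizes = onehot.sum(axis=0)
    if (sizes < 2).any():
        raise ValidationError("groups of size < 2")

    n_pos = int((np.linalg.eigvalsh(_gower_center(dm.d)) > 1e-10).sum())
    coords = pcoa(dm, k=max(n_pos, 1)).coordinates
    centroids = (onehot.T @ coords) / sizes[:, None]
    codes = onehot.argmax(axis=1)
    z = np.linalg.norm(coords - centroids[codes], axis=1)

    def anova_f(values: np.ndarray, oh: np.ndarray) -> float:
        szs = oh.sum(axis=0)
        means = (oh.T @ values) / szs
        grand = values.mean()
        ss_b = (szs * (means - grand) ** 2).sum()
        resid = values - means[oh.argmax(axis=1)]
        ss_w = (resid ** 2).sum()
        a = oh.shape[1]
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return float((ss_b / (a - 1)) / (ss_w / (len(values) - a)))

    f_obs = anova_f(z, onehot)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if anova_f(z, onehot[perm]) >= f_obs:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return {"f": f_obs, "p": p, "n_permutations": n_permutations,
            "distances_to_centroid": z, "levels": [str(l) for l in levels]}


def _gower_center(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ (d ** 2) @ j
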