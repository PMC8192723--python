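"""Alpha diversity, UniFrac beta diversity, and distance-based permutational
MANOVA, implemented from first principles.

UniFrac
-------
Both variants are computed in a single postorder pass over the rooted tree.
For a branch (the edge above a node) let :math:`P_x` be the total relative
abundance of sample *x*'s leaves beneath it.

* unweighted: a branch is *covered* by a sample iff at least one leaf below
  it is present; the distance is the total length of branches covered by
  exactly one sample divided by the total length covered by at least one.
* weighted (raw): :math:`\\sum_b \\ell_b\\,|P_a(b) - P_b(b)|`; the normalized
  variant divides by :math:`\\sum_b \\ell_b\\,(P_a(b) + P_b(b))`, bounding it
  to [0, 1].

Counts are used unrarefied; weighted UniFrac converts each sample to
relative abundances on the fly.

PERMANOVA
---------
The pseudo-F statistic follows the classical partition of squared
inter-point distances: :math:`SS_{total} = \\frac{1}{N}\\sum_{i<j} d_{ij}^2`,
:math:`SS_{within} = \\sum_g \\frac{1}{n_g}\\sum_{i<j \\in g} d_{ij}^2`, and
significance comes from whole-label permutation with the add-one estimator
:math:`p = (1 + \\#\\{F^\\pi \\ge F\\}) / (1 + n_{perm})`, so p is never
exactly zero and ties count as extreme.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .phylo import PhyloTree, TreeIndex
from .tables_io import AsvCountTable

__all__ = [
    "richness",
    "pielou",
    "DistanceMatrix",
    "unweighted_unifrac",
    "weighted_unifrac",
    "beta_diversity_matrix",
    "alpha_diversity_table",
    "PermanovaResult",
    "permanova",
    "pairwise_permanova",
]


def richness(sample_counts: np.ndarray) -> int:
    """Number of ASVs with nonzero count."""
    return int(np.count_nonzero(np.asarray(sample_counts)))


def pielou(sample_counts: np.ndarray) -> float:
    """Pielou evenness J' = H' / ln(S).

    Undefined (NaN, with a warning) for samples with fewer than two taxa,
    where ln(S) = 0.
    """
    counts = np.asarray(sample_counts, dtype=float)
    counts = counts[counts > 0]
    s = counts.size
    if s < 2:
        warnings.warn("Pielou evenness undefined for richness < 2", stacklevel=2)
        return math.nan
    p = counts / counts.sum()
    shannon = float(-(p * np.log(p)).sum())
    return shannon / math.log(s)


# ---------------------------------------------------------------------------
# UniFrac


def _node_totals(index: TreeIndex, leaf_values: dict[str, float]) -> np.ndarray:
    """Postorder accumulation: per-node sum of leaf values beneath it."""
    totals = np.zeros(index.n_nodes)
    for name, value in leaf_values.items():
        totals[index.leaf_pos[name]] = value
    for node, children in enumerate(index.children):
        for c in children:
            totals[node] += totals[c]
    return totals


def _leaf_values(
    counts: np.ndarray, asv_ids: list[str], index: TreeIndex
) -> dict[str, float]:
    values = {}
    for asv, c in zip(asv_ids, counts):
        if c > 0:
            if asv not in index.leaf_pos:
                raise ValidationError(f"ASV {asv!r} present in sample but not in tree")
            values[asv] = float(c)
    return values


def unweighted_unifrac(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    tree: PhyloTree | TreeIndex,
    asv_ids: list[str],
) -> float:
    index = tree if isinstance(tree, TreeIndex) else tree.index()
    ta = _node_totals(index, _leaf_values(sample_a, asv_ids, index)) > 0
    tb = _node_totals(index, _leaf_values(sample_b, asv_ids, index)) > 0
    union = float(index.lengths[ta | tb].sum())
    if union == 0:
        return 0.0
    unique = float(index.lengths[ta ^ tb].sum())
    return unique / union


def weighted_unifrac(
    sample_a: np.ndarray,
    sample_b: np.ndarray,
    tree: PhyloTree | TreeIndex,
    asv_ids: list[str],
    normalized: bool = True,
) -> float:
    index = tree if isinstance(tree, TreeIndex) else tree.index()
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    ta = _node_totals(index, _leaf_values(a / a.sum(), asv_ids, index))
    tb = _node_totals(index, _leaf_values(b / b.sum(), asv_ids, index))
    raw = float((index.lengths * np.abs(ta - tb)).sum())
    if not normalized:
        return raw
    denom = float((index.lengths * (ta + tb)).sum())
    return raw / denom if denom > 0 else 0.0


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValidationError("distance matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.values = v

    def submatrix(self, sample_ids: list[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())


def beta_diversity_matrix(
    table: AsvCountTable,
    tree: PhyloTree,
    metric: str = "unifrac-w",
    normalized: bool = True,
) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix for a count table."""
    index = tree.index()
    n = len(table.sample_ids)
    totals = []
    present = []
    for i in range(n):
        counts = table.counts[i].astype(float)
        t = _node_totals(index, _leaf_values(counts / counts.sum(), table.asv_ids, index))
        totals.append(t)
        present.append(t > 0)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "unifrac-u":
                union = index.lengths[present[i] | present[j]].sum()
                unique = index.lengths[present[i] ^ present[j]].sum()
                d[i, j] = unique / union if union > 0 else 0.0
            elif metric == "unifrac-w":
                raw = (index.lengths * np.abs(totals[i] - totals[j])).sum()
                if normalized:
                    denom = (index.lengths * (totals[i] + totals[j])).sum()
                    d[i, j] = raw / denom if denom > 0 else 0.0
                else:
                    d[i, j] = raw
            else:
                raise ConfigurationError(f"unknown metric {metric!r}")
            d[j, i] = d[i, j]
    return DistanceMatrix(list(table.sample_ids), d)


def alpha_diversity_table(table: AsvCountTable) -> pd.DataFrame:
    rows = []
    for sid in table.sample_ids:
        counts = table.sample(sid)
        s = richness(counts)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            j = pielou(counts) if s >= 2 else math.nan
        rows.append({"sample_id": sid, "richness": s, "pielou": j})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_perm: float
    df_between: int
    df_within: int
    n_permutations: int
    seed: int | None
    degenerate: bool = False


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Return (pseudo-F, R2) for squared distances ``d2`` and group labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in groups:
        mask = labels == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_between = ss_total - ss_within
    a = len(groups)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_within == 0:
        return math.inf, r2
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    return f, r2


def permanova(
    dist: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with whole-label permutation."""
    labels = np.asarray(groups)
    if labels.shape[0] != len(dist.sample_ids):
        raise ConfigurationError("groups must align with distance matrix samples")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ConfigurationError("need at least two groups")
    if n_permutations < 99:
        raise ConfigurationError("need at least 99 permutations")
    d2 = dist.values**2
    if np.allclose(dist.values, 0):
        return PermanovaResult(
            math.nan, math.nan, math.nan, uniq.size - 1,
            labels.size - uniq.size, n_permutations, seed, degenerate=True,
        )
    f_obs, r2 = _pseudo_f(d2, labels, uniq)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels), uniq)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=f_obs,
        R2=r2,
        p_perm=p,
        df_between=int(uniq.size - 1),
        df_within=int(labels.size - uniq.size),
        n_permutations=n_permutations,
        seed=seed,
    )


def pairwise_permanova(
    dist: DistanceMatrix,
    groups: list[str] | np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """PERMANOVA on every unordered pair of groups, with family-wise p
    adjustment (Bonferroni by default, or Holm)."""
    labels = np.asarray(groups)
    uniq = sorted(set(labels))
    rows = []
    for a, b in itertools.combinations(uniq, 2):
        mask = (labels == a) | (labels == b)
        ids = [s for s, m in zip(dist.sample_ids, mask) if m]
        res = permanova(dist.submatrix(ids), labels[mask], n_permutations, seed)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "pseudo_F": res.pseudo_F,
                "R2": res.R2,
                "p_raw": res.p_perm,
                "degenerate": res.degenerate,
            }
        )
    df = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    method = {"bonferroni": "bonferroni", "holm": "holm"}.get(adjust)
    if method is None:
        raise ConfigurationError(f"unknown adjustment {adjust!r}")
    ok = df["p_raw"].notna()
    adjusted = np.full(len(df), np.nan)
    if ok.any():
        adjusted[ok.to_numpy()] = multipletests(df.loc[ok, "p_raw"], method=method)[1]
    df["p_adjusted"] = adjusted
    return df
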