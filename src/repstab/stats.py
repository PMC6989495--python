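"""Behavioural indices, effect sizes, and cluster-level permutation tests.

The multiple-comparison machinery follows the standard nonparametric recipe
for region x time statistic maps: compute a cell-wise statistic (two-sample
t across groups, or Pearson r against a per-subject covariate), threshold at
an uncorrected two-tailed p, group suprathreshold cells into clusters that
are connected under region adjacency and temporal contiguity (same sign),
score each cluster by its mass (sum of the statistic), and compare the
observed masses against the permutation distribution of the maximum cluster
mass obtained by shuffling group labels (or the covariate).  The corrected
p-value of a cluster is ``(1 + #{null >= observed}) / (n_perm + 1)`` and is
therefore never smaller than ``1 / (n_perm + 1)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats as sstats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "EffectSize",
    "Cluster",
    "ClusterResult",
    "dprime",
    "icv",
    "cohens_d",
    "cohens_d_from_summary",
    "group_compare",
    "correlation_map",
    "cluster_permutation",
    "behavioral_summary",
    "cell_adjacency",
]


# --------------------------------------------------------------------------
# behavioural indices


def dprime(hit_rate: float, fa_rate: float, n_targets: int | None = None,
           n_lures: int | None = None) -> float:
    """Signal-detection sensitivity: z(hit rate) - z(false-alarm rate).

    Extreme rates (0 or 1) are corrected to ``1/(2N)`` / ``1 - 1/(2N)``,
    which requires the corresponding trial count.
    """
    def correct(rate: float, n: int | None, label: str) -> float:
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{label} must lie in [0, 1]")
        if rate in (0.0, 1.0):
            if n is None:
                raise ValueError(f"{label} is extreme ({rate}); trial count needed "
                                 "for the 1/(2N) correction")
            return 1.0 / (2 * n) if rate == 0.0 else 1.0 - 1.0 / (2 * n)
        return rate

    h = correct(hit_rate, n_targets, "hit rate")
    f = correct(fa_rate, n_lures, "false-alarm rate")
    return float(sstats.norm.ppf(h) - sstats.norm.ppf(f))


def icv(rts) -> float:
    """Intra-individual coefficient of variation: sample SD / mean of RTs."""
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2:
        raise ValueError("need at least 2 reaction times")
    mean = rts.mean()
    if mean <= 0:
        raise ValueError("mean RT must be positive")
    return float(rts.std(ddof=1) / mean)


def behavioral_summary(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject recognition indices from a trial table.

    Expects columns subject, condition ('intact'|'rearranged'), outcome
    (1 = response 'old' correct for intact / false alarm for rearranged)
    and optionally rt_ms for hits.
    """
    rows = []
    for subject, grp in trials.groupby("subject", sort=True):
        intact = grp[grp["condition"] == "intact"]
        rearr = grp[grp["condition"] == "rearranged"]
        hit = intact["outcome"].mean() if len(intact) else np.nan
        fa = rearr["outcome"].mean() if len(rearr) else np.nan
        row = {
            "subject": subject,
            "hit_rate": hit,
            "miss_rate": 1.0 - hit if len(intact) else np.nan,
            "fa_rate": fa,
            "cr_rate": 1.0 - fa if len(rearr) else np.nan,
        }
        if len(intact) and len(rearr):
            row["dprime"] = dprime(hit, fa, n_targets=len(intact), n_lures=len(rearr))
        else:
            row["dprime"] = np.nan
        if "rt_ms" in grp.columns:
            hit_rts = intact.loc[intact["outcome"] == 1, "rt_ms"].dropna()
            row["mean_rt_hits_ms"] = hit_rts.mean() if len(hit_rts) else np.nan
            row["icv"] = icv(hit_rts) if len(hit_rts) >= 2 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# effect sizes


@dataclass
class EffectSize:
    d: float
    ci_95: tuple[float, float] | None
    cl: float  # common-language effect size (probability of superiority)


def _pooled_d(m_a, s_a, n_a, m_b, s_b, n_b) -> float:
    sp2 = ((n_a - 1) * s_a ** 2 + (n_b - 1) * s_b ** 2) / (n_a + n_b - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance: d undefined")
    return (m_a - m_b) / np.sqrt(sp2)


def _cl(m_a, s_a, m_b, s_b) -> float:
    return float(sstats.norm.cdf((m_a - m_b) / np.sqrt(s_a ** 2 + s_b ** 2)))


def cohens_d_from_summary(mean_a: float, sd_a: float, n_a: int,
                          mean_b: float, sd_b: float, n_b: int) -> EffectSize:
    """Pooled-SD Cohen's d and common-language effect size from summary stats.

    Positive d means the first group's mean is larger.  No bootstrap CI is
    possible without the raw data.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    d = _pooled_d(mean_a, sd_a, n_a, mean_b, sd_b, n_b)
    return EffectSize(d=float(d), ci_95=None, cl=_cl(mean_a, sd_a, mean_b, sd_b))


def cohens_d(group_a, group_b, n_boot: int = 10_000, seed: int = 0) -> EffectSize:
    """Cohen's d with a percentile-bootstrap 95% CI over subjects.

    Positive d means ``group_a``'s mean is larger.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    d = _pooled_d(a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = a[rng.integers(0, a.size, a.size)]
        rb = b[rng.integers(0, b.size, b.size)]
        sa, sb = ra.std(ddof=1), rb.std(ddof=1)
        if sa == 0 and sb == 0:
            boots[i] = 0.0
        else:
            boots[i] = _pooled_d(ra.mean(), sa, a.size, rb.mean(), sb, b.size)
    ci = tuple(np.percentile(boots, [2.5, 97.5]))
    return EffectSize(d=float(d), ci_95=(float(ci[0]), float(ci[1])),
                      cl=_cl(a.mean(), a.std(ddof=1), b.mean(), b.std(ddof=1)))


def group_compare(values_a, values_b, alpha: float = 0.05,
                  n_tests: int = 1) -> dict:
    """Two-group comparison with normality-dependent test choice.

    Both groups are screened with the Lilliefors-corrected KS test at 0.05;
    Student's t is used when both pass, the Mann-Whitney U test otherwise.
    The p-value is Bonferroni-adjusted (multiplied by ``n_tests``, capped at 1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    normal = all(
        (np.ptp(x) > 0 and lilliefors(x, dist="norm")[1] > 0.05) or np.ptp(x) == 0
        for x in (a, b)
    )
    identical = np.array_equal(np.sort(a), np.sort(b))
    if identical:
        stat, p, test = 0.0, 1.0, "identical"
    elif normal:
        stat, p = sstats.ttest_ind(a, b)
        test = "t"
    else:
        stat, p = sstats.mannwhitneyu(a, b, alternative="two-sided")
        test = "mannwhitney"
    return {"test": test, "stat": float(stat), "p": float(p),
            "p_adjusted": float(min(1.0, p * n_tests)), "alpha": alpha}


# --------------------------------------------------------------------------
# maps and cluster permutation


def correlation_map(maps: np.ndarray, covariate) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Pearson r across subjects and its Fisher z transform.

    ``maps`` is subjects x regions x bins; ``covariate`` one scalar per
    subject.  Zero-variance cells get r = NaN (excluded from clustering).
    """
    maps = np.asarray(maps, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = maps.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects")
    if not np.all(np.isfinite(cov)):
        raise ValueError("covariate must be finite")
    x = maps - maps.mean(axis=0)
    y = cov - cov.mean()
    sx = np.sqrt((x ** 2).sum(axis=0))
    sy = np.sqrt((y ** 2).sum())
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, np.einsum("s,srb->rb", y, x) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12, out=None, where=np.isfinite(r))
    z = np.arctanh(r)
    return r, z


def cell_adjacency(region_adj: np.ndarray, n_bins: int) -> sparse.csr_matrix:
    """Sparse adjacency over flattened (region, bin) cells.

    Two cells are neighbours when they share the region and sit in adjacent
    bins, or share the bin and sit in adjacent regions.
    """
    region_adj = np.asarray(region_adj, dtype=bool)
    n_reg = region_adj.shape[0]
    n_cells = n_reg * n_bins
    rows, cols = [], []
    cell = lambda r, b: r * n_bins + b
    for r in range(n_reg):
        for b in range(n_bins - 1):
            rows.append(cell(r, b)); cols.append(cell(r, b + 1))
    for r1 in range(n_reg):
        for r2 in range(r1 + 1, n_reg):
            if region_adj[r1, r2]:
                for b in range(n_bins):
                    rows.append(cell(r1, b)); cols.append(cell(r2, b))
    rows, cols = np.array(rows), np.array(cols)
    data = np.ones(len(rows), dtype=bool)
    adj = sparse.coo_matrix((data, (rows, cols)), shape=(n_cells, n_cells))
    adj = adj + adj.T
    return adj.tocsr()


@dataclass
class Cluster:
    cells: list[tuple[int, int]]   # (region index, bin index)
    mass: float
    p_corrected: float
    sign: int


@dataclass
class ClusterResult:
    stat_map: np.ndarray           # t or r over regions x bins
    z_map: np.ndarray | None       # Fisher z of r (correlation design only)
    clusters: list[Cluster]
    threshold_p: float
    n_perm: int
    design: str
    max_null: np.ndarray = field(default=None, repr=False)

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_corrected < alpha]


def _tmaps_two_group(maps_flat: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t per cell for many labelings at once.

    ``maps_flat`` is subjects x cells, ``labels`` is labelings x subjects
    (booleans marking group A membership).  Returns labelings x cells.
    """
    n = maps_flat.shape[0]
    n_a = labels.sum(axis=1, keepdims=True).astype(float)
    n_b = n - n_a
    sums = maps_flat.sum(axis=0, keepdims=True)
    sq_sums = (maps_flat ** 2).sum(axis=0, keepdims=True)
    lab = labels.astype(float)
    sum_a = lab @ maps_flat
    sq_a = lab @ (maps_flat ** 2)
    sum_b = sums - sum_a
    sq_b = sq_sums - sq_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sq_a - n_a * mean_a ** 2
    ss_b = sq_b - n_b * mean_b ** 2
    df = n - 2
    sp2 = (ss_a + ss_b) / df
    se = np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / np.where(se > 0, se, 1.0), 0.0)
    return t


def _rmaps_covariate(maps_flat: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """Pearson r per cell for many covariate orderings at once."""
    x = maps_flat - maps_flat.mean(axis=0, keepdims=True)
    sx = np.sqrt((x ** 2).sum(axis=0, keepdims=True))
    c = covs - covs.mean(axis=1, keepdims=True)
    sc = np.sqrt((c ** 2).sum(axis=1, keepdims=True))
    num = c @ x
    denom = sc * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1 + 1e-15, 1 - 1e-15)


def _cluster_masses(stat: np.ndarray, supra: np.ndarray,
                    adj: sparse.csr_matrix, want_members: bool):
    """Connected components of suprathreshold cells, split by sign.

    Returns (masses, members) where members is None unless requested.
    """
    masses, members = [], [] if want_members else None
    for sign in (1, -1):
        mask = supra & ((stat > 0) if sign > 0 else (stat < 0))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            continue
        sub = adj[idx][:, idx]
        n_comp, lab = connected_components(sub, directed=False)
        vals = stat[idx]
        for comp in range(n_comp):
            sel = lab == comp
            masses.append(vals[sel].sum())
            if want_members:
                members.append((sign, idx[sel]))
    return masses, members


def _max_abs_mass(stat: np.ndarray, supra: np.ndarray, adj) -> float:
    masses, _ = _cluster_masses(stat, supra, adj, want_members=False)
    return max((abs(m) for m in masses), default=0.0)


def cluster_permutation(maps, design: str, adjacency: np.ndarray,
                        threshold_p: float = 0.05, n_perm: int = 10_000,
                        seed: int = 0, groups=None, covariate=None,
                        exhaustive: bool = False) -> ClusterResult:
    """Cluster-mass permutation test over subject x region x bin maps.

    Parameters
    ----------
    maps
        subjects x regions x bins array.
    design
        'two_group' (requires ``groups``: per-subject labels, two levels) or
        'correlation' (requires ``covariate``: per-subject scalar).
    adjacency
        Boolean region x region adjacency (symmetric).
    exhaustive
        For the two-group design, enumerate every distinct assignment of
        subjects to groups instead of sampling (feasible for small n); the
        observed labeling is one of the enumerated ones, so corrected
        p-values are exact.
    """
    maps = np.asarray(maps, dtype=float)
    n_sub, n_reg, n_bins = maps.shape
    adjacency = np.asarray(adjacency, dtype=bool)
    if not np.array_equal(adjacency, adjacency.T):
        raise ValueError("region adjacency must be symmetric")
    flat = maps.reshape(n_sub, -1)
    adj = cell_adjacency(adjacency, n_bins)
    rng = np.random.default_rng(seed)

    if design == "two_group":
        groups = np.asarray(groups)
        levels = pd.unique(groups)
        if len(levels) != 2:
            raise ValueError("two_group design needs exactly two group labels")
        is_a = groups == levels[0]
        n_a = int(is_a.sum())
        if n_a < 3 or n_sub - n_a < 3:
            raise ValueError("need >= 3 subjects per group")
        df = n_sub - 2
        t_crit = sstats.t.ppf(1 - threshold_p / 2, df)
        if exhaustive:
            combos = list(itertools.combinations(range(n_sub), n_a))
            labels = np.zeros((len(combos), n_sub), dtype=bool)
            for i, combo in enumerate(combos):
                labels[i, list(combo)] = True
            n_perm_eff = len(combos)
            obs_label = is_a
        else:
            labels = np.empty((n_perm, n_sub), dtype=bool)
            for i in range(n_perm):
                labels[i] = is_a[rng.permutation(n_sub)]
            n_perm_eff = n_perm
            obs_label = is_a
        stat_obs = _tmaps_two_group(flat, obs_label[None, :])[0]
        stats_null = _tmaps_two_group(flat, labels)
        crit = t_crit
    elif design == "correlation":
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != (n_sub,):
            raise ValueError("covariate must have one value per subject")
        df = n_sub - 2
        r_crit = np.sqrt(sstats.t.ppf(1 - threshold_p / 2, df) ** 2 /
                         (sstats.t.ppf(1 - threshold_p / 2, df) ** 2 + df))
        covs = np.empty((n_perm, n_sub))
        for i in range(n_perm):
            covs[i] = covariate[rng.permutation(n_sub)]
        r_obs = _rmaps_covariate(flat, covariate[None, :])[0]
        finite = np.isfinite(r_obs)
        stat_obs = np.where(finite, np.arctanh(r_obs), 0.0)
        stats_null = np.arctanh(_rmaps_covariate(flat, covs))
        crit = np.arctanh(r_crit)
        n_perm_eff = n_perm
    else:
        raise ValueError(f"unknown design {design!r}")

    supra_obs = np.abs(stat_obs) > crit
    masses, members = _cluster_masses(stat_obs, supra_obs, adj, want_members=True)

    max_null = np.empty(n_perm_eff)
    for i in range(n_perm_eff):
        s = stats_null[i]
        max_null[i] = _max_abs_mass(s, np.abs(s) > crit, adj)

    clusters = []
    if masses:
        if design == "two_group" and exhaustive:
            # observed labeling is among the enumerated ones: exact p
            p_of = lambda m: float(np.mean(max_null >= abs(m)))
        else:
            p_of = lambda m: float((1 + np.sum(max_null >= abs(m))) / (n_perm_eff + 1))
        for mass, (sign, idx) in zip(masses, members):
            cells = [(int(c // n_bins), int(c % n_bins)) for c in idx]
            clusters.append(Cluster(cells=cells, mass=float(mass),
                                    p_corrected=p_of(mass), sign=sign))
        clusters.sort(key=lambda c: abs(c.mass), reverse=True)

    stat_map = stat_obs.reshape(n_reg, n_bins)
    if design == "correlation":
        r_map = np.tanh(stat_map)
        return ClusterResult(stat_map=r_map, z_map=stat_map, clusters=clusters,
                             threshold_p=threshold_p, n_perm=n_perm_eff,
                             design=design, max_null=max_null)
    return ClusterResult(stat_map=stat_map, z_map=None, clusters=clusters,
                         threshold_p=threshold_p, n_perm=n_perm_eff,
                         design=design, max_null=max_null)
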