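"""Pair matching, clustering and significance scoring of diffusion pairs.

The screen compares two fitted peak lists (a *reference* and a *test*
condition).  Peaks are matched by chemical shift, each matched pair becomes
a point ``(log10 D_ref, log10 D_test)``, points are clustered by
single-linkage in that plane, and each cluster is scored for a significant
diffusion change via the mean log-ratio

    r = mean(log10 D_ref - log10 D_test)

with a standard error propagated from the per-peak fit uncertainties.
Averaging over the peaks of a cluster is what beats the large uncertainty
of individual DOSY diffusion coefficients.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .dosy import PeakList

__all__ = [
    "DiffusionPair",
    "PairSet",
    "Cluster",
    "ClusterLabel",
    "match_peaks",
    "cluster_pairs",
    "score_cluster",
    "classify_clusters",
]

logger = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: Default chemical-shift matching tolerance (ppm).
DEFAULT_TOL_PPM = 0.02
#: Default single-linkage neighbourhood radius in log10-D units.
DEFAULT_EPS_LOG = 0.05
#: Default FDR level for cluster significance.
DEFAULT_ALPHA = 0.05


class ClusterLabel(str, enum.Enum):
    NO_CHANGE = "no_change"
    SLOWER_IN_TEST = "slower_in_test"
    SLOWER_IN_REF = "slower_in_ref"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class DiffusionPair:
    """One resonance matched across the two conditions."""

    shift_ppm: float
    d_ref: float
    d_test: float
    sigma_ref: float
    sigma_test: float
    ref_peak_id: str
    test_peak_id: str

    def __post_init__(self) -> None:
        if not (self.d_ref > 0 and self.d_test > 0):
            raise ValueError(
                f"pair ({self.ref_peak_id!r}, {self.test_peak_id!r}): "
                "diffusion coefficients must be positive"
            )

    @property
    def log_ratio(self) -> float:
        """log10(D_ref) - log10(D_test); positive = slower in test."""
        return math.log10(self.d_ref) - math.log10(self.d_test)

    @property
    def log_variance(self) -> float:
        """Variance of :attr:`log_ratio` propagated from the fit sigmas."""
        return (self.sigma_ref / (self.d_ref * LN10)) ** 2 + (
            self.sigma_test / (self.d_test * LN10)
        ) ** 2


@dataclass(frozen=True)
class PairSet:
    """Matched pairs plus the peaks left unmatched on either side."""

    pairs: tuple[DiffusionPair, ...]
    unmatched_ref: tuple[str, ...]
    unmatched_test: tuple[str, ...]

    def __post_init__(self) -> None:
        ref_ids = [p.ref_peak_id for p in self.pairs]
        test_ids = [p.test_peak_id for p in self.pairs]
        if len(set(ref_ids)) != len(ref_ids) or len(set(test_ids)) != len(test_ids):
            raise ValueError("a peak appears in more than one pair")

    def __len__(self) -> int:
        return len(self.pairs)

    def points(self) -> np.ndarray:
        """(n, 2) array of (log10 d_ref, log10 d_test) coordinates."""
        if not self.pairs:
            return np.empty((0, 2))
        return np.array(
            [[math.log10(p.d_ref), math.log10(p.d_test)] for p in self.pairs]
        )

    def swapped(self) -> "PairSet":
        """The same pairing with reference and test roles exchanged."""
        return PairSet(
            pairs=tuple(
                DiffusionPair(
                    shift_ppm=p.shift_ppm,
                    d_ref=p.d_test,
                    d_test=p.d_ref,
                    sigma_ref=p.sigma_test,
                    sigma_test=p.sigma_ref,
                    ref_peak_id=p.test_peak_id,
                    test_peak_id=p.ref_peak_id,
                )
                for p in self.pairs
            ),
            unmatched_ref=self.unmatched_test,
            unmatched_test=self.unmatched_ref,
        )


@dataclass(frozen=True)
class Cluster:
    """A cluster of diffusion pairs with its change statistics.

    ``r`` is the mean log10 ratio of the members, ``se_r`` its propagated
    standard error, ``z = r / se_r``, ``p``/``q`` the raw and BH-adjusted
    two-sided significance, and ``label`` the direction call.
    """

    member_indices: tuple[int, ...]
    centroid: tuple[float, float]
    r: float = float("nan")
    se_r: float = float("nan")
    z: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    label: ClusterLabel = ClusterLabel.NO_CHANGE
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.member_indices) == 0:
            raise ValueError("cluster must have at least one member")

    @property
    def n_members(self) -> int:
        return len(self.member_indices)


def _pair_eligible(peak) -> bool:
    return peak.d > 0


def match_peaks(
    ref: PeakList, test: PeakList, tol_ppm: float = DEFAULT_TOL_PPM
) -> PairSet:
    """Greedy globally-nearest chemical-shift matching of two peak lists.

    Repeatedly pairs the unpaired (ref, test) peaks with the smallest
    ``|Δppm| <= tol_ppm``.  Ties break on the smaller of the two shifts,
    then the larger, then the lexicographically smaller peak ids, making
    the result deterministic and symmetric under swapping the lists.
    Peaks flagged with ``d = 0`` are never paired.

    Returns
    -------
    PairSet
        Matched pairs plus unmatched peak ids of both lists.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be positive, got {tol_ppm}")
    ref_peaks = [p for p in ref.peaks if _pair_eligible(p)]
    test_peaks = [p for p in test.peaks if _pair_eligible(p)]
    if not ref_peaks or not test_peaks:
        logger.warning(
            "match_peaks: empty eligible peak list (ref=%d, test=%d); no pairs",
            len(ref_peaks),
            len(test_peaks),
        )
    candidates = []
    for i, rp in enumerate(ref_peaks):
        for j, tp in enumerate(test_peaks):
            dppm = abs(rp.shift_ppm - tp.shift_ppm)
            if dppm <= tol_ppm:
                # symmetric tie-break key: role-agnostic
                key = (
                    dppm,
                    min(rp.shift_ppm, tp.shift_ppm),
                    max(rp.shift_ppm, tp.shift_ppm),
                    min(rp.peak_id, tp.peak_id),
                    max(rp.peak_id, tp.peak_id),
                )
                candidates.append((key, i, j))
    candidates.sort(key=lambda c: c[0])
    used_ref: set[int] = set()
    used_test: set[int] = set()
    pairs: list[DiffusionPair] = []
    for _, i, j in candidates:
        if i in used_ref or j in used_test:
            continue
        used_ref.add(i)
        used_test.add(j)
        rp, tp = ref_peaks[i], test_peaks[j]
        pairs.append(
            DiffusionPair(
                shift_ppm=0.5 * (rp.shift_ppm + tp.shift_ppm),
                d_ref=rp.d,
                d_test=tp.d,
                sigma_ref=rp.sigma_d,
                sigma_test=tp.sigma_d,
                ref_peak_id=rp.peak_id,
                test_peak_id=tp.peak_id,
            )
        )
    pairs.sort(key=lambda p: (p.shift_ppm, p.ref_peak_id))
    unmatched_ref = tuple(
        p.peak_id
        for p in ref.peaks
        if p.peak_id not in {q.ref_peak_id for q in pairs}
    )
    unmatched_test = tuple(
        p.peak_id
        for p in test.peaks
        if p.peak_id not in {q.test_peak_id for q in pairs}
    )
    return PairSet(
        pairs=tuple(pairs), unmatched_ref=unmatched_ref, unmatched_test=unmatched_test
    )


def cluster_pairs(pair_set: PairSet, eps_log: float = DEFAULT_EPS_LOG) -> list[Cluster]:
    """Single-linkage clustering of pairs in the (log10 D_ref, log10 D_test) plane.

    Clusters are the connected components of the graph joining points at
    Euclidean distance <= ``eps_log``; compounds whose diffusion
    coefficients differ by less than the neighbourhood radius merge into
    one cluster and cannot be told apart.  Returned clusters are unscored,
    ordered by smallest member index.
    """
    if eps_log <= 0:
        raise ValueError(f"eps_log must be positive, got {eps_log}")
    n = len(pair_set)
    if n == 0:
        return []
    pts = pair_set.points()
    if n == 1:
        assignments = np.array([1])
    else:
        z = linkage(pts, method="single")
        assignments = fcluster(z, t=eps_log, criterion="distance")
    clusters: list[Cluster] = []
    for cid in np.unique(assignments):
        members = tuple(int(i) for i in np.flatnonzero(assignments == cid))
        centroid = tuple(pts[list(members)].mean(axis=0))
        clusters.append(Cluster(member_indices=members, centroid=centroid))
    clusters.sort(key=lambda c: c.member_indices[0])
    return clusters


def score_cluster(cluster: Cluster, pair_set: PairSet) -> Cluster:
    """Attach the mean log-ratio ``r``, its propagated SE and ``z`` to a cluster.

    ``r = mean_i(log10 d_ref_i - log10 d_test_i)`` over the members;
    the per-member variance is propagated from the two fit sigmas and
    ``se_r = sqrt(sum var_i) / n``.  A zero ``se_r`` with nonzero ``r``
    yields an infinite ``z`` and the cluster is flagged ``"zero_se"``.
    """
    members = [pair_set.pairs[i] for i in cluster.member_indices]
    n = len(members)
    r = sum(p.log_ratio for p in members) / n
    se_r = math.sqrt(sum(p.log_variance for p in members)) / n
    flags = list(cluster.flags)
    if se_r == 0.0:
        z = 0.0 if r == 0.0 else math.copysign(math.inf, r)
        if "zero_se" not in flags:
            flags.append("zero_se")
    else:
        z = r / se_r
    return replace(cluster, r=r, se_r=se_r, z=z, flags=tuple(flags))


def classify_clusters(
    clusters: list[Cluster],
    alpha: float = DEFAULT_ALPHA,
    *,
    pair_set: PairSet | None = None,
    method: str = "normal",
    n_permutations: int = 2000,
    seed: int = 0,
) -> list[Cluster]:
    """Assign significance and direction labels to scored clusters.

    Two-sided p-values come from the standard-normal reference on ``z``
    (``method="normal"``, default) or from a seeded sign-permutation null
    on the member log-ratios (``method="permutation"``, requires
    ``pair_set``).  Benjamini–Hochberg adjustment runs across all clusters
    of the comparison; clusters with ``q <= alpha`` are labelled by the
    sign of ``r`` (positive: slower in the test condition), all others
    ``no_change``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if not clusters:
        return []
    if method == "normal":
        pvals = np.array(
            [2.0 * norm.sf(abs(c.z)) if np.isfinite(c.z) else 0.0 for c in clusters]
        )
        # z exactly 0 (r = 0): never significant
        pvals = np.where([c.z == 0.0 for c in clusters], 1.0, pvals)
    elif method == "permutation":
        if pair_set is None:
            raise ValueError("permutation method requires pair_set")
        pvals = np.array(
            [
                _permutation_pvalue(c, pair_set, n_permutations, seed + k)
                for k, c in enumerate(clusters)
            ]
        )
    else:
        raise ValueError(f"unknown significance method {method!r}")
    _, qvals, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    out: list[Cluster] = []
    for c, p, q in zip(clusters, pvals, qvals):
        if q <= alpha and c.r > 0:
            label = ClusterLabel.SLOWER_IN_TEST
        elif q <= alpha and c.r < 0:
            label = ClusterLabel.SLOWER_IN_REF
        else:
            label = ClusterLabel.NO_CHANGE
        out.append(replace(c, p=float(p), q=float(q), label=label))
    return out


def _permutation_pvalue(
    cluster: Cluster, pair_set: PairSet, n_permutations: int, seed: int
) -> float:
    """Two-sided sign-permutation p-value of the cluster mean log-ratio.

    Under the null of no diffusion change the sign of each member's
    log-ratio is exchangeable; the null distribution is the mean under
    random sign flips.
    """
    ratios = np.array([pair_set.pairs[i].log_ratio for i in cluster.member_indices])
    obs = abs(ratios.mean())
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, len(ratios)))
    null = np.abs((signs * ratios).mean(axis=1))
    return float((1 + np.sum(null >= obs - 1e-15)) / (1 + n_permutations))
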