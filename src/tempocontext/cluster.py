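"""Cluster-based permutation inference for time series and time x feature maps.

Family-wise error is controlled by (1) computing a pointwise statistic
across participants (default: the matched rank-biserial effect size
against zero), (2) thresholding it pointwise against the permutation
ensemble's two-sided 5% band, (3) summing the statistic within contiguous
supra-threshold clusters separately for positive and negative polarities,
and (4) keeping clusters whose summed mass exceeds the 95th percentile of
the maximum-cluster-mass permutation null. The null is built by random
sign flips of whole participants (one-sample; condition-label swaps for a
paired design reduce to sign flips of the differences).

The two-dimensional variant treats the feature axis as circular: maps are
first smoothed along features with a wrap-around uniform kernel (size 4),
and cluster connectivity is 4-neighborhood with wraparound along features
only.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats


@dataclass
class Cluster:
    mask: np.ndarray          # boolean, shape of the statistic map
    mass: float
    polarity: int             # +1 / -1
    significant: bool


@dataclass
class ClusterResult:
    stat: np.ndarray          # observed pointwise statistic
    clusters: list            # all supra-threshold clusters
    threshold_pos: float      # 95th percentile of the positive max-mass null
    threshold_neg: float
    pointwise_lo: np.ndarray
    pointwise_hi: np.ndarray
    n_permutations: int
    seed: object

    @property
    def significant_masks(self):
        return [c.mask for c in self.clusters if c.significant]

    @property
    def any_significant(self):
        return any(c.significant for c in self.clusters)


def _pointwise_stat(X, stat):
    """Statistic across participants at every point. X: (n_subj, ...)."""
    if stat == "mean":
        return X.mean(axis=0)
    if stat == "t":
        se = X.std(axis=0, ddof=1) / np.sqrt(X.shape[0])
        return X.mean(axis=0) / np.maximum(se, 1e-300)
    if stat == "rank_biserial":
        ranks = np.apply_along_axis(stats.rankdata, 0, np.abs(X))
        ranks[X == 0] = 0.0
        total = np.maximum(ranks.sum(axis=0), 1e-300)
        return np.sum(np.sign(X) * ranks, axis=0) / total
    raise ValueError(f"unknown stat {stat!r}")


def _perm_stats(X, stat, signs):
    """Permutation statistics for all sign-flip rows. signs: (n_perm, n_subj)."""
    if stat == "mean":
        return np.tensordot(signs, X, axes=(1, 0)) / X.shape[0]
    if stat == "rank_biserial":
        ranks = np.apply_along_axis(stats.rankdata, 0, np.abs(X))
        ranks[X == 0] = 0.0
        total = np.maximum(ranks.sum(axis=0), 1e-300)
        signed = np.sign(X) * ranks
        return np.tensordot(signs, signed, axes=(1, 0)) / total
    if stat == "t":
        out = np.empty((signs.shape[0],) + X.shape[1:])
        for i, s in enumerate(signs):
            out[i] = _pointwise_stat(X * s.reshape((-1,) + (1,) * (X.ndim - 1)),
                                     "t")
        return out
    raise ValueError(f"unknown stat {stat!r}")


def _clusters_1d(stat, lo, hi):
    """Contiguous supra-threshold runs with their signed masses."""
    out = []
    for pol, sig in ((1, stat > hi), (-1, stat < lo)):
        lab, nlab = ndimage.label(sig)
        for k in range(1, nlab + 1):
            msk = lab == k
            out.append((msk, float(stat[msk].sum()), pol))
    return out


def _clusters_2d_circular(stat, lo, hi):
    """Supra-threshold 2D clusters, 4-connected, circular along axis 1."""
    out = []
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for pol, sig in ((1, stat > hi), (-1, stat < lo)):
        lab, nlab = ndimage.label(sig, structure=structure)
        if nlab == 0:
            continue
        # merge labels adjacent across the feature wrap
        parent = np.arange(nlab + 1)

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        first, last = lab[:, 0], lab[:, -1]
        for a, b in zip(first, last):
            if a and b and a != b:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
        roots = {}
        for k in range(1, nlab + 1):
            roots.setdefault(find(k), []).append(k)
        for members in roots.values():
            msk = np.isin(lab, members)
            out.append((msk, float(stat[msk].sum()), pol))
    return out


def _max_masses(perm_stat, lo, hi, cluster_fn):
    pos = np.zeros(perm_stat.shape[0])
    neg = np.zeros(perm_stat.shape[0])
    for i in range(perm_stat.shape[0]):
        for _, mass, pol in cluster_fn(perm_stat[i], lo, hi):
            if pol > 0:
                pos[i] = max(pos[i], mass)
            else:
                neg[i] = min(neg[i], mass)
    return pos, neg


def _cluster_correct(X, stat, n_perm, alpha, cluster_alpha, random_state,
                     cluster_fn):
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 participants")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable thresholds")
    rng = np.random.default_rng(random_state)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, X.shape[0]))

    obs = _pointwise_stat(X, stat)
    perm = _perm_stats(X, stat, signs)
    lo = np.percentile(perm, 100.0 * alpha / 2.0, axis=0)
    hi = np.percentile(perm, 100.0 * (1.0 - alpha / 2.0), axis=0)

    pos_null, neg_null = _max_masses(perm, lo, hi, cluster_fn)
    # one null of the maximum summed cluster value across both polarities:
    # a single 95th-percentile threshold keeps the two-sided FWER at alpha
    null_abs = np.maximum(pos_null, -neg_null)
    thr = float(np.percentile(null_abs, 100.0 * (1.0 - cluster_alpha)))
    thr_pos, thr_neg = thr, -thr

    clusters = []
    for msk, mass, pol in cluster_fn(obs, lo, hi):
        clusters.append(Cluster(mask=msk, mass=mass, polarity=pol,
                                significant=bool(abs(mass) > thr)))
    return ClusterResult(stat=obs, clusters=clusters, threshold_pos=thr_pos,
                         threshold_neg=thr_neg, pointwise_lo=lo,
                         pointwise_hi=hi, n_permutations=n_perm,
                         seed=random_state)


def cluster_correct_1d(X, stat="rank_biserial", n_perm=5000, alpha=0.05,
                       cluster_alpha=0.05, random_state=0):
    """One-dimensional cluster correction of participant x time inputs.

    ``X`` is (n_participants, n_times), tested against zero (pass
    condition differences for a paired design). Returns a
    :class:`ClusterResult` whose surviving clusters exceed the 95th
    percentile of the maximum-cluster-mass sign-flip null.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be (n_participants, n_times)")
    return _cluster_correct(X, stat, n_perm, alpha, cluster_alpha,
                            random_state, _clusters_1d)


def smooth_circular_feature(maps, kernel_size=4, axis=-1):
    """Uniform moving average with circular wraparound along one axis.

    Each output sample is the mean of ``kernel_size`` neighboring feature
    bins (wrap-around); other axes are untouched, and the map mean is
    preserved exactly.
    """
    maps = np.asarray(maps, dtype=float)
    if kernel_size >= maps.shape[axis]:
        raise ValueError("kernel must be smaller than the feature count")
    return ndimage.uniform_filter1d(maps, size=kernel_size, axis=axis,
                                    mode="wrap")


def cluster_correct_2d_circular(X, stat="rank_biserial", n_perm=5000,
                                alpha=0.05, cluster_alpha=0.05,
                                random_state=0, kernel_size=4):
    """Cluster correction of participant x time x circular-feature maps.

    Maps are smoothed along the (circular) feature axis with a uniform
    kernel before testing; clusters are 4-connected with wraparound along
    features only. Smoothing commutes with the participant-level sign
    flips, so it is applied once to the inputs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must be (n_participants, n_times, n_features)")
    if kernel_size:
        X = smooth_circular_feature(X, kernel_size, axis=-1)
    return _cluster_correct(X, stat, n_perm, alpha, cluster_alpha,
                            random_state, _clusters_2d_circular)
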