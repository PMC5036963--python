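"""Ward hierarchical clustering with surrogate-based selection of the
number of significant clusters.

Neurons are clustered on standardized electrophysiological feature
vectors using Ward's linkage on squared Euclidean distances.  The number
of clusters is chosen by a resampling variant of Thorndike's criterion:
the differences ("gaps") between successive merge heights of the real
dendrogram are compared with those of surrogate data sets obtained by
independently permuting each feature column across neurons, which
destroys any joint cluster structure while preserving every marginal
distribution.  The gap whose size is least probable under the surrogate
null (p < alpha) sets the cut, taken at the midpoint of the two heights
it separates; if no gap beats alpha the result is *zero* significant
clusters -- an explicitly allowed outcome.

Two feature presets mirror the two brain states analyzed: during
slow-wave activity the set is {log ISI p10, CV ISI, CV2 ratio, iLFP
peak median time, slow / spindle / gamma ECoG vector lengths} (7
features; a 6-feature variant without CV ISI is also provided), and
during cortical activation {log ISI p10/p50/p85, rate, CV2 ratio, CV2
mean}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

FEATURE_PRESETS: dict[str, tuple[str, ...]] = {
    # slow-wave activity, 7 parameters (includes CV ISI)
    "swa": (
        "log_isi_p10", "cv_isi", "cv2_ratio", "ilfp_peak_median",
        "ecog_slow_vec", "ecog_spindle_vec", "ecog_gamma_vec",
    ),
    # slow-wave activity, the 6-parameter variant without CV ISI
    "swa6": (
        "log_isi_p10", "cv2_ratio", "ilfp_peak_median",
        "ecog_slow_vec", "ecog_spindle_vec", "ecog_gamma_vec",
    ),
    "activation": (
        "log_isi_p10", "log_isi_p50", "log_isi_p85", "rate",
        "cv2_ratio", "cv2_mean",
    ),
}


@dataclass
class ClusterResult:
    """Outcome of the surrogate-calibrated cluster-number selection."""

    linkage_matrix: np.ndarray  # scipy format, heights on squared scale
    heights: np.ndarray  # nondecreasing merge heights
    gap_k: np.ndarray  # candidate cluster counts for each gap
    gaps: np.ndarray  # height differences, aligned with gap_k
    gap_p: np.ndarray  # surrogate p-value per gap
    threshold: float | None
    n_significant_clusters: int
    labels: np.ndarray  # 1-based cluster labels (all 1s if none significant)

    def dendrogram_nested_lists(self) -> list:
        """Text-serializable nested-list rendering of the merge tree."""
        n = self.linkage_matrix.shape[0] + 1
        nodes: dict[int, object] = {i: i for i in range(n)}
        for m, (a, b, _, _) in enumerate(self.linkage_matrix):
            nodes[n + m] = [nodes[int(a)], nodes[int(b)]]
        return nodes[n + self.linkage_matrix.shape[0] - 1]


def standardize(x: np.ndarray) -> np.ndarray:
    """Column z-scoring; raises on constant columns."""
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant feature column; cannot standardize")
    return (x - x.mean(axis=0)) / sd


def ward_linkage(features: np.ndarray, standardize_cols: bool = True) -> np.ndarray:
    """Ward linkage on (standardized) features, heights on the squared-
    Euclidean scale.

    Ward's objective minimizes the increase in within-cluster sum of
    squares at every merge; reporting heights as squared Euclidean
    merge distances matches that objective (the merge order is
    unaffected by the monotone rescaling).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.all(np.isfinite(x)):
        raise ValueError("features contain missing or non-finite values")
    if standardize_cols:
        x = standardize(x)
    z = linkage(x, method="ward")
    z = z.copy()
    z[:, 2] = z[:, 2] ** 2
    return z


def merge_height_gaps(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Successive differences of merge heights, indexed by the number of
    clusters a cut in that gap would produce.

    With heights h_1 <= ... <= h_{n-1}, cutting between h_{n-k} and
    h_{n-k+1} yields k clusters; the gap for k is h_{n-k+1} - h_{n-k},
    for k = 2 .. n-1.
    """
    h = z[:, 2]
    n = h.size + 1
    ks = np.arange(2, n)
    gaps = np.array([h[n - k] - h[n - k - 1] for k in ks])
    return ks, gaps


def thorndike_resample(
    features: np.ndarray,
    n_surrogates: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
    null: str = "max",
    standardize_cols: bool = True,
    max_k: int | None = None,
) -> ClusterResult:
    """Select the number of significant clusters against a permutation null.

    Parameters
    ----------
    features : (n, d) array
        Feature matrix (rows = neurons).  Identity labels must not be
        among the columns.
    n_surrogates : int
        Number of column-permutation surrogates (>= 100 for stable p).
    null : {"max", "by_rank", "pooled"}
        How real gaps are referred to the surrogate distribution.
        ``"max"`` (default) compares each real gap with the largest gap
        of each surrogate, so the selected p-value is uniform under an
        exchangeable null and the procedure controls its false-positive
        rate.  ``"by_rank"`` compares the gap at each candidate k with
        the surrogate gaps at the same k; ``"pooled"`` pools all
        surrogate gaps.
    max_k : int, optional
        Restrict candidate cluster counts to 2..max_k.

    Returns
    -------
    ClusterResult with p-values per gap, the selected threshold (the
    midpoint of the two merge heights bracketing the winning gap), the
    cluster count (0 if no gap reaches alpha) and row labels.
    """
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for stable p-values")
    x = np.asarray(features, dtype=float)
    rng = np.random.default_rng(seed)
    z = ward_linkage(x, standardize_cols=standardize_cols)
    ks, gaps = merge_height_gaps(z)
    if max_k is not None:
        keep = ks <= max_k
        ks, gaps = ks[keep], gaps[keep]

    exceed = np.zeros(ks.size)
    pooled: list[np.ndarray] = []
    for _ in range(n_surrogates):
        surr = np.empty_like(x)
        for j in range(x.shape[1]):
            surr[:, j] = x[rng.permutation(x.shape[0]), j]
        zs = ward_linkage(surr, standardize_cols=standardize_cols)
        ks_s, gaps_s = merge_height_gaps(zs)
        if max_k is not None:
            gaps_s = gaps_s[ks_s <= max_k]
        if null == "max":
            exceed += gaps_s.max() >= gaps
        elif null == "by_rank":
            exceed += gaps_s >= gaps
        elif null == "pooled":
            pooled.append(gaps_s)
        else:
            raise ValueError(f"unknown null mode {null!r}")
    if null == "pooled":
        allg = np.sort(np.concatenate(pooled))
        exceed = allg.size - np.searchsorted(allg, gaps, side="left")
        p = (exceed + 1) / (allg.size + 1)
    else:
        p = (exceed + 1) / (n_surrogates + 1)

    h = z[:, 2]
    n = h.size + 1
    sig = p < alpha
    if not np.any(sig):
        return ClusterResult(
            linkage_matrix=z, heights=h, gap_k=ks, gaps=gaps, gap_p=p,
            threshold=None, n_significant_clusters=0,
            labels=np.ones(n, dtype=int),
        )
    best_p = p[sig].min()
    candidates = np.flatnonzero(sig & (p == best_p))
    # ties on p broken in favour of the larger gap
    i = candidates[np.argmax(gaps[candidates])]
    k = int(ks[i])
    threshold = 0.5 * (h[n - k - 1] + h[n - k])
    labels = fcluster(z, t=threshold, criterion="distance")
    return ClusterResult(
        linkage_matrix=z, heights=h, gap_k=ks, gaps=gaps, gap_p=p,
        threshold=float(threshold), n_significant_clusters=k, labels=labels,
    )


def cluster_composition(labels: np.ndarray, identities) -> pd.DataFrame:
    """Cluster-by-identity contingency with majority identity per cluster.

    Returns a DataFrame indexed by cluster with identity counts, the
    majority identity and its fraction of the cluster.
    """
    labels = np.asarray(labels)
    identities = np.asarray(identities)
    if labels.size != identities.size:
        raise ValueError("labels and identities must align")
    table = pd.crosstab(pd.Series(labels, name="cluster"),
                        pd.Series(identities, name="identity"))
    majority = table.idxmax(axis=1)
    fraction = table.max(axis=1) / table.sum(axis=1)
    out = table.copy()
    out["majority_identity"] = majority
    out["majority_fraction"] = fraction
    return out


def label_purity(labels: np.ndarray, truth: np.ndarray) -> float:
    """Overall purity: fraction of rows in their cluster's majority class."""
    comp = cluster_composition(labels, truth)
    counts = comp.drop(columns=["majority_identity", "majority_fraction"])
    return float(counts.max(axis=1).sum() / counts.to_numpy().sum())
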