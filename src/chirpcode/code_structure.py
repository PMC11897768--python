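"""Population "visual code" characterisation.

The population of light-responsive units is summarised by sparse principal
components of three chirp segments (step, temporal chirp, contrast chirp;
50 ms PSTH), clustered repeatedly with Gaussian mixture models whose
cluster number is chosen by BIC with a Bayes-factor parsimony rule, turned
into a co-assignment similarity matrix, and partitioned into communities
by weighted-modularity (Louvain) community detection. Condition-wise
community distributions are then compared with a label-permutation test on
total variation distance.

Sparse PCA here enforces an exact cardinality (5 non-zero time bins per
component) via truncated power iteration with projection deflation —
penalised variants do not give an exact bin count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "CodeStructureResult",
    "SEGMENT_WINDOWS",
    "segment_psth_features",
    "sparse_pca",
    "downsample_balanced",
    "consensus_cluster",
    "detect_communities",
    "distribution_shuffle_test",
]

#: analysis windows (s) of the three chirp parts used for population features
SEGMENT_WINDOWS: tuple[tuple[float, float], ...] = (
    (0.5, 4.5),  # step
    (6.5, 15.5),  # temporal chirp
    (17.5, 24.5),  # contrast chirp
)
FEATURE_BIN_S = 0.05

MIN_COMMUNITY_SIZE = 5
BAYES_FACTOR_THRESHOLD = 6.0


@dataclass
class CodeStructureResult:
    spc_loadings: np.ndarray  # components x time-bins (sparse rows)
    spc_scores: np.ndarray  # units x components
    variance_explained: np.ndarray  # per component, fraction of total
    similarity: np.ndarray  # units x units co-assignment fraction
    communities: np.ndarray  # unit -> community id, -1 = unassigned
    community_sizes: dict[int, int] = field(default_factory=dict)
    condition_distributions: dict[str, np.ndarray] = field(default_factory=dict)
    shuffle_p: dict[tuple[str, str], float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# features


def segment_psth_features(
    psth_pop: np.ndarray, bin_s: float = FEATURE_BIN_S, t0: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a units x time population PSTH into the three chirp-segment
    matrices (step, temporal, contrast: 80, 180 and 140 bins at 50 ms)."""
    psth_pop = np.asarray(psth_pop, dtype=float)
    if psth_pop.ndim != 2:
        raise ValueError("psth_pop must be units x time")
    out = []
    for a, b in SEGMENT_WINDOWS:
        i0 = int(round((a - t0) / bin_s))
        i1 = int(round((b - t0) / bin_s))
        if not (0 <= i0 < i1 <= psth_pop.shape[1]):
            raise ValueError(f"segment [{a},{b}) outside the PSTH")
        out.append(psth_pop[:, i0:i1])
    return tuple(out)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# sparse PCA


def _sparse_leading_component(
    x: np.ndarray, cardinality: int, max_iter: int = 200, tol: float = 1e-9
) -> np.ndarray:
    """Leading sparse loading vector with an exact non-zero count.

    Truncated power iteration: multiply by the Gram matrix, keep the
    ``cardinality`` largest-magnitude coordinates, renormalise, repeat.
    """
    gram = x.T @ x
    # deterministic init from the dense leading eigenvector direction
    v = gram.sum(axis=1)
    if not np.any(v):
        v = np.ones(gram.shape[0])
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        u = gram @ v
        if not np.any(u):
            break
        keep = np.argsort(np.abs(u))[-cardinality:]
        u_s = np.zeros_like(u)
        u_s[keep] = u[keep]
        u_s /= np.linalg.norm(u_s)
        if np.linalg.norm(u_s - v) < tol or np.linalg.norm(u_s + v) < tol:
            v = u_s
            break
        v = u_s
    return v


def sparse_pca(
    segments: tuple[np.ndarray, ...],
    sparsity: int = 5,
    min_var: float = 0.01,
    max_components_per_segment: int = 40,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sparse PCs per chirp segment, concatenated over segments.

    Each component has exactly ``sparsity`` non-zero time bins confined to
    one segment; components are extracted per segment by truncated power
    iteration with projection deflation and kept while they explain at
    least ``min_var`` of the total (all-segment) variance.

    Returns ``(loadings, scores, variance_explained)`` with loadings of
    width equal to the summed segment widths and scores = units x
    components projections of the mean-centred data.
    """
    segs = [np.asarray(s, dtype=float) for s in segments]
    n_units = segs[0].shape[0]
    if any(s.shape[0] != n_units for s in segs):
        raise ValueError("inconsistent unit sets across segments")
    if n_units < 2:
        raise ValueError("need at least 2 units")
    centered = [s - s.mean(axis=0, keepdims=True) for s in segs]
    total_var = float(sum(np.sum(c**2) for c in centered))
    if total_var <= 0:
        raise ValueError("population PSTH has no variance")

    widths = [s.shape[1] for s in segs]
    offsets = np.concatenate([[0], np.cumsum(widths)])
    loadings, scores, varexp = [], [], []
    for si, c in enumerate(centered):
        x = c.copy()
        for _ in range(min(max_components_per_segment, x.shape[1] // 1)):
            v = _sparse_leading_component(x, min(sparsity, x.shape[1]))
            proj = x @ v
            ve = float(np.sum(proj**2)) / total_var
            if ve < min_var:
                break
            full = np.zeros(offsets[-1])
            full[offsets[si] : offsets[si + 1]] = v
            loadings.append(full)
            scores.append(c @ v)
            varexp.append(ve)
            x = x - np.outer(proj, v)  # projection deflation
    if not loadings:
        warnings.warn("no sparse component reached the variance floor")
        return (
            np.zeros((0, offsets[-1])),
            np.zeros((n_units, 0)),
            np.zeros(0),
        )
    return np.array(loadings), np.array(scores).T, np.array(varexp)


# ---------------------------------------------------------------------------
# balanced downsampling


def downsample_balanced(
    condition_labels: np.ndarray, seed: int | np.random.SeedSequence = 0
) -> np.ndarray:
    """Indices of a per-condition random subsample matching the smallest
    condition's size (seeded)."""
    labels = np.asarray(condition_labels)
    conds, counts = np.unique(labels, return_counts=True)
    if conds.size < 2:
        raise ValueError("need at least 2 conditions")
    if np.any(counts == 0):
        raise ValueError("empty condition")
    n_min = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in conds:
        idx = np.nonzero(labels == c)[0]
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------
# consensus clustering


def _select_k_bic(bics: dict[int, float], bf_threshold: float) -> int:
    """Pick the cluster number by lowest BIC with a Bayes-factor guard:
    a more complex model replaces a simpler one only when
    exp((BIC_simple - BIC_complex)/2) >= bf_threshold."""
    best = min(bics)
    for k in sorted(bics):
        if k <= best:
            continue
        bf = np.exp(min((bics[best] - bics[k]) / 2.0, 700.0))
        if bf >= bf_threshold:
            best = k
    return best


def consensus_cluster(
    scores: np.ndarray,
    n_repeats: int = 50,
    k_max: int = 20,
    seed: int | np.random.SeedSequence = 0,
    bf_threshold: float = BAYES_FACTOR_THRESHOLD,
    covariance_type: str = "diag",
    reg_covar: float = 1e-4,
    bic_patience: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Repeated GMM clustering into a co-assignment similarity matrix.

    Per repeat, Gaussian mixtures with random initialisation are fitted for
    k = 1..k_max; k is selected by lowest BIC, accepting extra components
    only when the approximate Bayes factor exp(dBIC/2) clears
    ``bf_threshold``. The k-scan stops early once BIC has worsened for
    ``bic_patience`` consecutive k (it is convex in practice).

    Covariances are diagonal by default: with unit counts of a few hundred
    against a few dozen sparse-PC dimensions, full covariances carry more
    parameters than observations and BIC degenerates to k = 1.

    Returns ``(similarity, labels_per_repeat, selected_k)``; similarity is
    the fraction of repeats co-assigning each unit pair.
    """
    x = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("scores must be finite")
    n = x.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    repeat_seeds = root.spawn(n_repeats)

    labels_all = np.zeros((n_repeats, n), dtype=int)
    selected = np.zeros(n_repeats, dtype=int)
    co = np.zeros((n, n))
    for r in range(n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        bics: dict[int, float] = {}
        models: dict[int, GaussianMixture] = {}
        worse_streak = 0
        best_bic = np.inf
        for k in range(1, min(k_max, n) + 1):
            gm = GaussianMixture(
                n_components=k,
                covariance_type=covariance_type,
                init_params="random_from_data",
                n_init=1,
                reg_covar=reg_covar,
                max_iter=200,
                random_state=int(rng.integers(2**31 - 1)),
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gm.fit(x)
            bics[k] = float(gm.bic(x))
            models[k] = gm
            if bics[k] < best_bic:
                best_bic = bics[k]
                worse_streak = 0
            else:
                worse_streak += 1
                if worse_streak >= bic_patience:
                    break
        k_sel = _select_k_bic(bics, bf_threshold)
        selected[r] = k_sel
        lab = models[k_sel].predict(x)
        labels_all[r] = lab
        co += (lab[:, None] == lab[None, :]).astype(float)
    similarity = co / n_repeats
    np.fill_diagonal(similarity, 1.0)
    return similarity, labels_all, selected


# ---------------------------------------------------------------------------
# community detection


def detect_communities(
    similarity: np.ndarray,
    min_size: int = MIN_COMMUNITY_SIZE,
    seed: int = 0,
    n_restarts: int = 20,
) -> np.ndarray:
    """Louvain communities of the similarity-weighted graph.

    The partition with the highest weighted modularity over ``n_restarts``
    seeded runs is kept (consensus by best modularity); communities smaller
    than ``min_size`` are dissolved and their members marked unassigned
    (label -1). Community ids are relabelled 0..k-1 by decreasing size.
    """
    s = np.asarray(similarity, dtype=float)
    n = s.shape[0]
    if s.shape != (n, n):
        raise ValueError("similarity must be square")
    if not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("similarity must be symmetric")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.triu_indices(n, k=1)
    w = s[iu, ju]
    nzi = w > 0
    g.add_weighted_edges_from(zip(iu[nzi].tolist(), ju[nzi].tolist(), w[nzi].tolist()))
    if g.number_of_edges() == 0:
        warnings.warn("all-zero similarity; returning a single community")
        return np.zeros(n, dtype=int)

    best_part, best_q = None, -np.inf
    for r in range(n_restarts):
        part = nx.community.louvain_communities(g, weight="weight", seed=seed + r)
        q = nx.community.modularity(g, part, weight="weight")
        if q > best_q:
            best_part, best_q = part, q

    labels = np.full(n, -1, dtype=int)
    kept = sorted(
        (c for c in best_part if len(c) >= min_size), key=len, reverse=True
    )
    for cid, members in enumerate(kept):
        labels[list(members)] = cid
    return labels


# ---------------------------------------------------------------------------
# between-condition distribution test


def _tv_distance(counts_a: np.ndarray, counts_b: np.ndarray) -> float:
    pa = counts_a / counts_a.sum()
    pb = counts_b / counts_b.sum()
    return 0.5 * float(np.abs(pa - pb).sum())


def distribution_shuffle_test(
    communities: np.ndarray,
    condition_labels: np.ndarray,
    n_shuffles: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> dict[tuple[str, str], float]:
    """Permutation test comparing community membership between conditions.

    Statistic: total variation distance between the conditions' community
    proportion vectors, over assigned units only (community != -1). Null:
    condition labels permuted across units. p = (1 + #{null >= obs}) /
    (n_shuffles + 1), per condition pair.
    """
    comm = np.asarray(communities)
    cond = np.asarray(condition_labels)
    if comm.shape != cond.shape:
        raise ValueError("communities and condition labels must align")
    assigned = comm >= 0
    comm, cond = comm[assigned], cond[assigned]
    conds = np.unique(cond)
    if conds.size < 2:
        raise ValueError("need at least 2 conditions with assigned units")
    comm_ids = np.unique(comm)
    rng = np.random.default_rng(seed)

    out: dict[tuple[str, str], float] = {}
    for i in range(conds.size):
        for j in range(i + 1, conds.size):
            ca, cb = conds[i], conds[j]
            m = (cond == ca) | (cond == cb)
            sub_comm, sub_cond = comm[m], cond[m]
            if not np.any(sub_cond == ca) or not np.any(sub_cond == cb):
                raise ValueError("a condition has zero assigned units")
            k = comm_ids.size
            comm_idx = np.searchsorted(comm_ids, sub_comm)
            is_a = sub_cond == ca
            counts_a = np.bincount(comm_idx[is_a], minlength=k)
            counts_b = np.bincount(comm_idx[~is_a], minlength=k)
            obs = _tv_distance(counts_a, counts_b)
            null = np.empty(n_shuffles)
            for s in range(n_shuffles):
                perm = rng.permutation(is_a)
                na = np.bincount(comm_idx[perm], minlength=k)
                null[s] = _tv_distance(na, counts_a + counts_b - na)
            p = (1.0 + float(np.sum(null >= obs - 1e-12))) / (n_shuffles + 1.0)
            out[(str(ca), str(cb))] = p
    return out
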