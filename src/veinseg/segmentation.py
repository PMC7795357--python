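"""GMM/MRF vein segmentation with global graph-cut optimization.

The fused multi-scale feature image is modeled by one diagonal Gaussian
mixture per label (foreground vein / background tissue).  The Markov
random field energy

    E(gamma) = sum_p R_p(gamma_p) + beta * sum_{(a,b) in N, gamma_a != gamma_b} S_ab

combines a region term — the negative log of the mixture likelihood

    L(p) = sum_k rho_k ( prod_l delta_kl * tau_kl )^(1/N)

(delta the normal normalization, tau the normal exponential, N the
number of fused features) — with a contrast-sensitive smoothness term

    S_ab = d(a,b)^-1 * ( exp(-eta * f(a,b)^2) + c_noise )

whose feature distance f is computed after a locality-preserving
projection (LPP) of the fused features and whose normalization eta is
set from the mean squared neighbor distance.  The binary energy is
submodular and is minimized exactly by an s-t max-flow/min-cut; the
GMMs are refit on the new labeling and the loop repeats until the
foreground/background relative entropy (KL divergence) stabilizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow
from scipy.special import logsumexp

from .config import RunConfig, SegmentationConfig
from .fusion import fuse_orientations
from .gabor import PadRecord, compute_block_grid, extract_roi_and_pad, filter_image

logger = logging.getLogger(__name__)

__all__ = [
    "LabelGMM", "SegGraph", "SegmentationResult", "LPPProjection",
    "init_clusters", "fit_label_gmm", "region_term", "region_energies",
    "lpp_distance", "compute_eta", "smoothness_term", "build_graph",
    "min_cut", "kl_divergence", "segment",
]


@dataclass
class LabelGMM:
    """Diagonal Gaussian mixture describing one label's fused features."""

    weights: np.ndarray     # (K,), non-negative, sums to 1
    means: np.ndarray       # (K, L)
    variances: np.ndarray   # (K, L), floored strictly above 0

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def validate(self) -> "LabelGMM":
        if np.any(self.weights < 0) or not math.isclose(
                float(self.weights.sum()), 1.0, rel_tol=1e-9):
            raise ValueError("mixture weights must be non-negative, sum 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        return self

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Proper mixture log-density (used by the KL estimate)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        diff = x[:, None, :] - self.means[None, :, :]          # (n, K, L)
        comp = -0.5 * (np.log(2 * np.pi * self.variances)[None]
                       + diff * diff / self.variances[None]).sum(axis=-1)
        return logsumexp(comp + np.log(self.weights)[None], axis=1)


@dataclass
class SegGraph:
    """Capacitated s-t graph encoding the binary MRF energy.

    ``source_caps[p]`` (cost of labeling p background) is the capacity of
    the edge from the source/foreground terminal to pixel p;
    ``sink_caps[p]`` (cost of labeling p foreground) is the edge from p
    to the sink/background terminal.  ``pair_a``/``pair_b`` hold the
    flat indices of each undirected neighbor pair with symmetric
    capacity ``pair_caps`` (already scaled by beta).
    """

    shape: tuple[int, int]
    source_caps: np.ndarray
    sink_caps: np.ndarray
    pair_a: np.ndarray
    pair_b: np.ndarray
    pair_caps: np.ndarray
    # per-pixel min(region energies) subtracted from both terminal links so
    # capacities stay non-negative; added back when reporting the energy
    offset: float = 0.0

    def validate(self) -> "SegGraph":
        for name in ("source_caps", "sink_caps", "pair_caps"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise ValueError(f"non-finite capacity in {name} at index {bad}")
            if np.any(arr < 0):
                raise ValueError(f"negative capacity in {name}")
        return self

    def energy(self, labels: np.ndarray) -> float:
        """MRF energy of a labeling under this graph's capacities."""
        lab = np.asarray(labels).ravel().astype(bool)
        unary = float(self.sink_caps.ravel()[lab].sum()
                      + self.source_caps.ravel()[~lab].sum())
        cut = lab[self.pair_a] != lab[self.pair_b]
        return unary + float(self.pair_caps[cut].sum()) + self.offset


@dataclass
class SegmentationResult:
    """Binary vein mask plus the optimization trace."""

    labels: np.ndarray                 # original-frame binary mask
    labels_padded: np.ndarray          # padded-frame binary mask
    energy: float
    energy_trace: list[float]
    kl_trace: list[float]
    converged: bool
    iterations: int
    pad_record: PadRecord | None = None
    config: dict = field(default_factory=dict)


def init_clusters(
    features: np.ndarray, k: int, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means cluster centers and size-proportional weights.

    Minimizes the within-cluster sum of squares; centers are the means
    of the assigned points and the weight of each cluster is its share
    of the points.  Deterministic for a given seed.
    """
    from sklearn.cluster import KMeans

    features = np.atleast_2d(np.asarray(features, dtype=float))
    n = len(features)
    if k <= 0 or k > n:
        raise ValueError(f"cluster count {k} must be in [1, {n}]")
    km = KMeans(n_clusters=k, n_init=4, random_state=int(seed) % (2**31))
    assign = km.fit_predict(features)
    counts = np.bincount(assign, minlength=k).astype(float)
    return km.cluster_centers_, counts / counts.sum()


def fit_label_gmm(
    features: np.ndarray,
    labels: np.ndarray,
    k: int,
    seed: int,
    variance_floor: float = 1e-3,
    kmeans_subsample: int | None = 20000,
) -> tuple[LabelGMM, LabelGMM]:
    """Fit one diagonal GMM per label by k-means partition moments.

    Pixels of each label are clustered with k-means (on a subsample for
    speed when the class is large), every pixel is assigned to its
    nearest center, and per-component per-feature means/variances are
    the assigned pixels' moments with a variance floor.  A class with
    fewer pixels than ``k`` gets a reduced component count.
    """
    features = np.asarray(features, dtype=float).reshape(-1, np.shape(features)[-1])
    labels = np.asarray(labels).ravel().astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be nonempty")
    models = {}
    for value in (1, 0):
        pts = features[labels == bool(value)]
        k_eff = min(k, len(pts))
        if k_eff < k:
            logger.warning("label %d has %d pixels < K=%d; using K=%d",
                           value, len(pts), k, k_eff)
        sub = pts
        if kmeans_subsample and len(pts) > kmeans_subsample:
            rng = np.random.default_rng(seed + value)
            sub = pts[rng.choice(len(pts), kmeans_subsample, replace=False)]
        centers, _ = init_clusters(sub, k_eff, seed + value)
        d2 = ((pts[:, None, :] - centers[None]) ** 2).sum(axis=-1)
        assign = d2.argmin(axis=1)
        means, variances, counts = [], [], []
        for c in range(k_eff):
            sel = pts[assign == c]
            if len(sel) == 0:
                continue
            means.append(sel.mean(axis=0))
            variances.append(np.maximum(sel.var(axis=0), variance_floor))
            counts.append(len(sel))
        counts = np.asarray(counts, dtype=float)
        models[value] = LabelGMM(
            weights=counts / counts.sum(),
            means=np.asarray(means),
            variances=np.asarray(variances),
        ).validate()
    return models[1], models[0]


def region_energies(
    features: np.ndarray, model: LabelGMM, floor: float = 1e-12,
) -> np.ndarray:
    """Vectorized region energies -log L(p) for a batch of feature vectors.

    L(p) = sum_k rho_k (prod_l delta_kl tau_kl)^(1/N) with delta the
    normal normalization constant, tau the exponential term, and N the
    feature count.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    n_feat = model.n_features
    diff = x[:, None, :] - model.means[None]
    log_inner = -0.5 * (np.log(2 * np.pi * model.variances)[None]
                        + diff * diff / model.variances[None]).sum(axis=-1)
    log_l = logsumexp(log_inner / n_feat + np.log(model.weights)[None], axis=1)
    log_l = np.maximum(log_l, math.log(floor))
    return -log_l


def region_term(p: np.ndarray, model: LabelGMM, floor: float = 1e-12) -> float:
    """Region energy of a single feature vector (see :func:`region_energies`)."""
    return float(region_energies(np.atleast_2d(p), model, floor=floor)[0])


class LPPProjection:
    """Locality preserving projection of the fused feature vectors.

    A linear map minimizing sum_ij w_ij ||y_i - y_j||^2 over a k-nearest
    neighbor graph with heat-kernel weights, solved as a generalized
    eigenproblem on a subsample.  ``identity=True`` short-circuits to
    the raw feature space (projection = identity), giving plain
    Euclidean feature distances.
    """

    def __init__(self, n_components: int = 4, n_neighbors: int = 7,
                 subsample: int = 5000, identity: bool = False):
        self.n_components = n_components
        self.n_neighbors = n_neighbors
        self.subsample = subsample
        self.identity = identity
        self.components_: np.ndarray | None = None

    def fit(self, features: np.ndarray, seed: int = 0) -> "LPPProjection":
        x = np.asarray(features, dtype=float).reshape(-1, np.shape(features)[-1])
        n_feat = x.shape[1]
        if self.identity:
            self.components_ = np.eye(n_feat)
            return self
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(seed)
        if len(x) > self.subsample:
            x = x[rng.choice(len(x), self.subsample, replace=False)]
        k = min(self.n_neighbors, len(x) - 1)
        if k < 1:
            self.components_ = np.eye(n_feat)[:, :self.n_components]
            return self
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        dist, idx = nn.kneighbors(x)
        dist, idx = dist[:, 1:], idx[:, 1:]       # drop self-neighbor
        t = float(np.mean(dist ** 2)) or 1.0      # heat-kernel bandwidth
        w = np.exp(-(dist ** 2) / t)
        n = len(x)
        rows = np.repeat(np.arange(n), k)
        adj = csr_matrix((w.ravel(), (rows, idx.ravel())), shape=(n, n))
        adj = adj.maximum(adj.T)                  # symmetrize
        d = np.asarray(adj.sum(axis=1)).ravel()
        # generalized eigenproblem X^T L X a = lam X^T D X a
        xd = x * d[:, None]
        xtdx = x.T @ xd
        xtwx = (adj @ x).T @ x
        xtlx = xtdx - 0.5 * (xtwx + xtwx.T)       # symmetrized X^T (D-W) X
        from scipy.linalg import eigh
        reg = 1e-9 * np.trace(xtdx) / n_feat
        vals, vecs = eigh(xtlx, xtdx + reg * np.eye(n_feat))
        order = np.argsort(vals)
        self.components_ = vecs[:, order[: self.n_components]]
        return self

    def transform(self, features: np.ndarray) -> np.ndarray:
        if self.components_ is None:
            raise RuntimeError("LPP projection has not been fitted")
        shape = np.shape(features)
        flat = np.asarray(features, dtype=float).reshape(-1, shape[-1])
        out = flat @ self.components_
        return out.reshape(shape[:-1] + (out.shape[-1],))


def lpp_distance(projection: LPPProjection, features: np.ndarray,
                 a: tuple[int, int], b: tuple[int, int]) -> float:
    """Euclidean distance between two pixels' LPP-projected features."""
    if projection.components_ is None:
        raise RuntimeError("LPP projection has not been fitted")
    fa = projection.transform(np.asarray(features[a], dtype=float))
    fb = projection.transform(np.asarray(features[b], dtype=float))
    return float(np.linalg.norm(fa - fb))


def _neighbor_shifts(neighborhood: int) -> list[tuple[int, int]]:
    shifts = [(0, 1), (1, 0)]
    if neighborhood == 8:
        shifts += [(1, 1), (1, -1)]
    return shifts


def _neighbor_pairs(shape: tuple[int, int], neighborhood: int):
    """Flat index pairs (a, b) and spatial distances for each neighbor pair."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    pas, pbs, dists = [], [], []
    for dr, dc in _neighbor_shifts(neighborhood):
        src = idx[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        dst = idx[max(0, dr):h + min(0, dr), max(0, dc):w + min(0, dc)]
        pas.append(src.ravel())
        pbs.append(dst.ravel())
        dists.append(np.full(src.size, math.hypot(dr, dc)))
    return np.concatenate(pas), np.concatenate(pbs), np.concatenate(dists)


def compute_eta(
    projected: np.ndarray, neighborhood: int = 8, eta_max: float = 1e6,
) -> float:
    """Feature-contrast normalization eta = (2 * mean-ish squared distance)^-1.

    eta = ( 2 * sum over neighbor pairs of f(m,n)^2 / n_pixels )^-1,
    with f the projected-feature distance.  Degenerate images where all
    neighbor distances vanish fall back to ``eta_max``.
    """
    proj = np.asarray(projected, dtype=float)
    h, w = proj.shape[:2]
    flat = proj.reshape(h * w, -1)
    pa, pb, _ = _neighbor_pairs((h, w), neighborhood)
    sq = ((flat[pa] - flat[pb]) ** 2).sum(axis=-1)
    total = float(sq.sum())
    if total <= 0:
        logger.warning("all neighbor feature distances are zero; "
                       "using eta_max=%g", eta_max)
        return float(eta_max)
    return float(1.0 / (2.0 * total / (h * w)))


def smoothness_term(
    a: tuple[int, int], b: tuple[int, int], projected: np.ndarray,
    eta: float, c_noise: float = math.pi,
) -> float:
    """Boundary penalty between neighboring pixels a and b.

    weight = d(a,b)^-1 * (exp(-eta * f(a,b)^2) + c_noise), with d the
    Euclidean distance between the pixel coordinates and f the
    projected-feature distance.  The additive constant keeps the
    penalty strictly positive (noise robustness).
    """
    if a == b:
        raise ValueError("smoothness term requires two distinct pixels")
    d = math.hypot(a[0] - b[0], a[1] - b[1])
    f2 = float(((np.asarray(projected[a], dtype=float)
                 - np.asarray(projected[b], dtype=float)) ** 2).sum())
    return (math.exp(-eta * f2) + c_noise) / d


def build_graph(
    features: np.ndarray,
    fg: LabelGMM,
    bg: LabelGMM,
    beta: float,
    eta: float,
    projected: np.ndarray | None = None,
    c_noise: float = math.pi,
    neighborhood: int = 8,
    likelihood_floor: float = 1e-12,
    forced_bg: np.ndarray | None = None,
) -> SegGraph:
    """Assemble the s-t graph whose min cut minimizes the MRF energy.

    The source-side terminal capacity of a pixel is its region energy
    under the background model (paid when the pixel is cut to the
    background side) and vice versa; neighbor capacities are
    beta * smoothness weight.  ``forced_bg`` pins pixels (e.g. zero
    padding) to the background by a large foreground cost.
    """
    feats = np.asarray(features, dtype=float)
    h, w = feats.shape[:2]
    flat = feats.reshape(h * w, -1)
    source_caps = region_energies(flat, bg, floor=likelihood_floor)
    sink_caps = region_energies(flat, fg, floor=likelihood_floor)
    if forced_bg is not None:
        # pin padding pixels to the background with a finite cost that no
        # unary gain plus incident pairwise agreement can outweigh
        pin = float(source_caps.max()) + 8 * beta * (1 + c_noise) + 1.0
        sink_caps = sink_caps.copy()
        sink_caps[np.asarray(forced_bg).ravel()] = pin
    proj = flat if projected is None else \
        np.asarray(projected, dtype=float).reshape(h * w, -1)
    pa, pb, dist = _neighbor_pairs((h, w), neighborhood)
    f2 = ((proj[pa] - proj[pb]) ** 2).sum(axis=-1)
    pair_caps = beta * (np.exp(-eta * f2) + c_noise) / dist
    shift = np.minimum(source_caps, sink_caps)
    return SegGraph(
        shape=(h, w),
        source_caps=(source_caps - shift).reshape(h, w),
        sink_caps=(sink_caps - shift).reshape(h, w),
        pair_a=pa, pair_b=pb, pair_caps=pair_caps,
        offset=float(shift.sum()),
    ).validate()


def min_cut(graph: SegGraph) -> np.ndarray:
    """Exact global minimizer of the graph's binary MRF energy.

    Capacities are scaled to int64 (the scale adapts so the total sits
    well inside the integer range while keeping quantization far below
    any realistic energy gap) and the max flow is computed with a
    Dinic-type algorithm; pixels reachable from the source in the
    residual network are labeled foreground.
    """
    h, w = graph.shape
    n = h * w
    source, sink = n, n + 1
    s_caps = graph.source_caps.ravel()
    t_caps = graph.sink_caps.ravel()
    # the solver uses 32-bit arithmetic: scale so that the max flow (bounded
    # by the smaller terminal side) and every single capacity stay inside it
    caps = np.concatenate([
        s_caps, t_caps, graph.pair_caps, graph.pair_caps])
    bound = max(min(float(s_caps.sum()), float(t_caps.sum())),
                float(caps.max(initial=0.0)))
    scale = 0.4 * 2**31 / max(bound, 1e-300)

    rows = np.concatenate([
        np.full(n, source), np.arange(n), graph.pair_a, graph.pair_b])
    cols = np.concatenate([
        np.arange(n), np.full(n, sink), graph.pair_b, graph.pair_a])
    icaps = np.rint(caps * scale).astype(np.int32)
    mat = csr_matrix((icaps, (rows, cols)), shape=(n + 2, n + 2))
    result = maximum_flow(mat, source, sink)
    residual = mat - result.flow
    residual.data = (residual.data > 0).astype(np.int64)
    residual.eliminate_zeros()
    reached, _ = breadth_first_order(residual, source, directed=True,
                                     return_predecessors=True)
    labels = np.zeros(n, dtype=np.uint8)
    reached = reached[reached < n]
    labels[reached] = 1
    return labels.reshape(h, w)


def kl_divergence(p: LabelGMM, q: LabelGMM, n_samples: int = 2000,
                  seed: int = 0) -> float:
    """Monte-Carlo estimate of the relative entropy KL(p || q).

    Draws ``n_samples`` vectors from p and averages log p(x) - log q(x);
    densities are floored to avoid -inf on far-out draws.
    """
    rng = np.random.default_rng(seed)
    comp = rng.choice(p.n_components, size=n_samples, p=p.weights)
    x = (p.means[comp]
         + rng.standard_normal((n_samples, p.n_features))
         * np.sqrt(p.variances[comp]))
    floor = math.log(1e-300)
    logp = np.maximum(p.log_density(x), floor)
    logq = np.maximum(q.log_density(x), floor)
    return float(np.mean(logp - logq))


def _initial_labels(
    image: np.ndarray, features: np.ndarray, valid: np.ndarray,
    method: str, markers: np.ndarray | None,
) -> np.ndarray:
    """Automatic (or marker-driven) foreground/background seeding."""
    from skimage.filters import threshold_otsu

    if method == "markers":
        if markers is None:
            raise ValueError("init_method 'markers' requires a marker mask")
        labels = (np.asarray(markers) > 0).astype(np.uint8)
    elif method == "fused_otsu":
        mid = features.shape[-1] // 2
        channel = features[..., mid].astype(float)
        vals = channel[valid]
        thr = threshold_otsu(vals) if vals.min() < vals.max() else vals.mean()
        labels = (channel <= thr).astype(np.uint8)   # darker-code class
    elif method == "intensity_otsu":
        vals = image[valid]
        thr = threshold_otsu(vals) if vals.min() < vals.max() else vals.mean()
        labels = (image <= thr).astype(np.uint8)     # veins are dark
    else:
        raise ValueError(f"unknown init_method {method!r}")
    labels[~valid] = 0
    if labels[valid].min() == labels[valid].max():
        raise ValueError(
            "degenerate initial labeling (one class empty); adjust the "
            "seeding threshold or supply marker masks")
    return labels


def segment(
    image: np.ndarray,
    config: RunConfig | None = None,
    seed: int | None = None,
    markers: np.ndarray | None = None,
) -> SegmentationResult:
    """End-to-end vein segmentation of a grayscale NIR finger image.

    Pipeline: ROI crop + zero-pad -> block-adaptive Gabor feature stack
    -> LBP orientation fusion -> automatic seeding -> iterated
    {GMM refit, graph build, min cut} until the foreground/background
    KL divergence change falls below tolerance.  Fully deterministic
    for a given seed.
    """
    cfg = (config or RunConfig()).validate()
    seg: SegmentationConfig = cfg.segmentation
    base_seed = cfg.seed if seed is None else int(seed)

    padded, pad_rec = extract_roi_and_pad(image, cfg.gabor.target_size)
    grid = compute_block_grid(padded, cfg.gabor)
    stack = filter_image(padded, grid, cfg.gabor)
    features = fuse_orientations(stack, lsb_first=cfg.fusion.lsb_first)
    features = features.astype(float)

    valid = np.zeros(padded.shape, dtype=bool)
    valid[pad_rec.content_slices] = True
    if markers is not None and markers.shape != padded.shape:
        m = np.zeros(padded.shape, dtype=np.uint8)
        m[pad_rec.content_slices] = np.asarray(markers)[
            pad_rec.crop[0]:pad_rec.crop[1], pad_rec.crop[2]:pad_rec.crop[3]]
        markers = m
    labels = _initial_labels(padded, features, valid,
                             seg.init_method, markers)

    lpp = LPPProjection(
        n_components=seg.lpp_dim, n_neighbors=seg.lpp_neighbors,
        subsample=seg.lpp_subsample, identity=seg.lpp_identity,
    ).fit(features[valid], seed=base_seed % (2**31))
    projected = lpp.transform(features)
    eta = compute_eta(projected, neighborhood=seg.neighborhood,
                      eta_max=seg.eta_max)

    energy_trace: list[float] = []
    kl_trace: list[float] = []
    converged = False
    prev_kl = None
    best_labels = labels
    forced_bg = ~valid
    for it in range(seg.max_iters):
        flat_lab = labels[valid]
        if flat_lab.min() == flat_lab.max():
            logger.warning("labeling collapsed to one class at iteration %d",
                           it)
            break
        fg, bg = fit_label_gmm(
            features[valid], flat_lab, seg.n_components,
            seed=(base_seed + 7919 * it) % (2**31),
            variance_floor=seg.variance_floor,
            kmeans_subsample=seg.kmeans_subsample)
        graph = build_graph(
            features, fg, bg, beta=seg.beta, eta=eta, projected=projected,
            c_noise=seg.c_noise, neighborhood=seg.neighborhood,
            likelihood_floor=seg.likelihood_floor, forced_bg=forced_bg)
        new_labels = min_cut(graph)
        new_labels[forced_bg] = 0
        energy = graph.energy(new_labels)
        if energy_trace and energy > energy_trace[-1]:
            # refitting is not provably monotone; stop at first increase
            logger.info("energy increased at iteration %d; stopping", it)
            break
        energy_trace.append(energy)
        best_labels = new_labels
        kl = max(0.0, kl_divergence(
            fg, bg, n_samples=seg.kl_samples,
            seed=(base_seed + 104729 * it) % (2**31)))
        kl_trace.append(kl)
        labels = new_labels
        if prev_kl is not None and abs(kl - prev_kl) < seg.tol:
            converged = True
            break
        prev_kl = kl

    # map the padded-frame labels back into the original frame
    original = np.zeros(pad_rec.original_shape, dtype=np.uint8)
    r0, r1, c0, c1 = pad_rec.crop
    original[r0:r1, c0:c1] = best_labels[pad_rec.content_slices]
    return SegmentationResult(
        labels=original,
        labels_padded=best_labels,
        energy=energy_trace[-1] if energy_trace else float("nan"),
        energy_trace=energy_trace,
        kl_trace=kl_trace,
        converged=converged,
        iterations=len(energy_trace),
        pad_record=pad_rec,
        config=cfg.to_dict(),
    )
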