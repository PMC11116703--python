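"""Group spatial ICA with two-stage PCA reduction, ICASSO and back-reconstruction.

The decomposition follows the temporal-concatenation group ICA scheme used
for fMRI: each session's (T_s x P) dF/F matrix is compressed in the temporal
domain by PCA to L1 whitened rows, sessions are stacked and reduced again to
K group rows, and spatial FastICA (variables = pixels) unmixes the group
whitened matrix into K spatial maps. Per-session maps and time courses are
recovered by the standard matrix back-reconstruction chain through the
stored reduction models.

Reliability is assessed with ICASSO: FastICA is rerun under bootstrap
resampling (of pixels) and/or random initialization, estimates are clustered
by average-linkage agglomeration on 1 - |corr| dissimilarity, and each
cluster's centrotype (the estimate with maximal total within-cluster
similarity) is taken as the reliable component. Model order is chosen as the
K minimizing the cluster R-index

    I_R(K) = (1/K) * sum_k  d_in(k) / min_{l != k} d_ext(k, l)

with d_in the mean within-cluster dissimilarity (0 for singletons) and
d_ext the mean between-cluster dissimilarity -- compact, well-separated
clusterings give small I_R.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preprocess import DffMovie


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GroupDataset:
    """Sessions sharing an identical mask/pixel order, ready for group ICA."""

    sessions: list[DffMovie]

    def __post_init__(self) -> None:
        if len(self.sessions) < 1:
            raise ValueError("need at least one session")
        m0 = self.sessions[0].mask
        for s in self.sessions[1:]:
            if not np.array_equal(s.mask, m0):
                raise ValueError("sessions must share the same mask")

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def n_pixels(self) -> int:
        return self.sessions[0].n_pixels


@dataclass
class SessionReduction:
    """Per-session temporal-PCA reduction: X_s ~= u @ scaled ~= dewhiten @ whitened.

    ``whitened`` carries the whitening contract (identity covariance over
    pixels); ``scaled`` keeps each retained direction at its natural
    variance, which is what the group stage concatenates so that the
    eigenvalue ordering of the pooled data is preserved.
    """

    u: np.ndarray  # (T_s, L1) temporal eigenvectors
    s: np.ndarray  # (L1,) singular values
    whitened: np.ndarray  # (L1, P); rows satisfy (Y Y^T)/P = I

    @property
    def l1(self) -> int:
        return len(self.s)

    @property
    def scaled(self) -> np.ndarray:
        """(L1, P) PCA projections u^T X_s (variance-preserving)."""
        return (self.s / math.sqrt(self.whitened.shape[1]))[:, None] * self.whitened

    def dewhiten(self) -> np.ndarray:
        """(T_s, L1) matrix D with X_s ~= D @ whitened."""
        return self.u * (self.s / math.sqrt(self.whitened.shape[1]))


@dataclass
class ReductionModel:
    """Both reduction stages of one group fit."""

    sessions: list[SessionReduction]
    group_u: np.ndarray  # (M*L1, K)
    group_s: np.ndarray  # (K,)
    group_white: np.ndarray  # (K, P)
    n_pixels: int

    @property
    def k(self) -> int:
        return len(self.group_s)

    @property
    def l1(self) -> int:
        return self.sessions[0].l1

    def group_whitening(self) -> np.ndarray:
        """(K, M*L1) matrix W with group_white = W @ stacked_session_whitened."""
        return (self.group_u / self.group_s).T * math.sqrt(self.n_pixels)

    def group_dewhitening(self) -> np.ndarray:
        """(M*L1, K) matrix D with stacked ~= D @ group_white."""
        return self.group_u * (self.group_s / math.sqrt(self.n_pixels))


@dataclass
class ComponentSet:
    """Group spatial ICs. ``maps`` are z-scored over masked pixels with the
    peak-|weight| pixel oriented positive; ``raw_maps``/``mixing`` keep the
    algebraic scale with group_white ~= mixing @ raw_maps."""

    maps: np.ndarray  # (K, P) z-scored
    raw_maps: np.ndarray  # (K, P)
    mixing: np.ndarray  # (K, K)
    converged: bool = True
    seed: int | None = None

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class IcassoResult:
    estimates: np.ndarray  # (R*K, P) unit-norm estimate maps
    labels: np.ndarray  # (R*K,) cluster assignment
    centrotype_idx: np.ndarray  # (K,) estimate index per cluster
    stability: np.ndarray  # (K,) cluster quality index in [0, 1]
    r_index: float
    n_runs: int
    seed: int


@dataclass
class BackReconstruction:
    """Per-session maps (K x P) and time courses (K x T_s), ICA scale."""

    session_ids: list[str]
    maps: dict[str, np.ndarray]
    timecourses: dict[str, np.ndarray]


@dataclass
class GicaFit:
    """One complete group decomposition."""

    model: ReductionModel
    components: ComponentSet
    icasso: IcassoResult | None
    back: BackReconstruction
    dataset: GroupDataset = field(repr=False)


# ---------------------------------------------------------------------------
# reduction
# ---------------------------------------------------------------------------

def _economic_svd(x: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-``rank`` SVD of x (T x P) via the Gram matrix on the smaller side."""
    t, p = x.shape
    if p <= t:
        c = (x.T @ x).astype(np.float64)
        w, v = linalg.eigh(c)
        w, v = w[::-1], v[:, ::-1]
        svals = np.sqrt(np.clip(w, 0.0, None))
        good = w > w[0] * 1e-10
        r = min(rank, int(good.sum()))
        if r < rank:
            raise ValueError(f"requested {rank} components but data rank is {r}")
        v = v[:, :rank]
        svals = svals[:rank]
        u = (x @ v) / svals
    else:
        c = (x @ x.T).astype(np.float64)
        w, u = linalg.eigh(c)
        w, u = w[::-1], u[:, ::-1]
        svals = np.sqrt(np.clip(w, 0.0, None))
        good = w > w[0] * 1e-10
        r = min(rank, int(good.sum()))
        if r < rank:
            raise ValueError(f"requested {rank} components but data rank is {r}")
        u = u[:, :rank]
        svals = svals[:rank]
        v = x.T @ (u / svals)
    return u, svals, v


def reduce_session(session: DffMovie, l1: int) -> SessionReduction:
    """Temporal-domain PCA of one session, retaining ``l1`` whitened rows.

    The whitened output Y = sqrt(P) * V^T has (Y Y^T)/P = I by construction.
    """
    t, p = session.data.shape
    if l1 > min(t, p):
        raise ValueError(f"L1={l1} exceeds min(T, P)={min(t, p)}")
    u, s, v = _economic_svd(session.data, l1)
    whitened = math.sqrt(p) * v.T
    return SessionReduction(u=u, s=s, whitened=whitened.astype(np.float64))


def reduce_group(reductions: list[SessionReduction], k: int, n_pixels: int) -> ReductionModel:
    """Second-stage PCA of the temporally stacked session projections.

    The stack concatenates the variance-preserving projections, so group
    eigenvalues reflect pooled energy; the K retained group rows are
    whitened (the usual pre-ICA contract).
    """
    stacked = np.concatenate([r.scaled for r in reductions], axis=0)
    if k > stacked.shape[0]:
        raise ValueError(f"K={k} exceeds stacked reduced dimension {stacked.shape[0]}")
    u2, s2, v2 = _economic_svd(stacked, k)
    group_white = math.sqrt(n_pixels) * v2.T
    return ReductionModel(
        sessions=reductions, group_u=u2, group_s=s2,
        group_white=group_white, n_pixels=n_pixels,
    )


def default_l1(k: int, cap: int | None = None) -> int:
    """First-stage retained dimension: 1.5*K rounded up, optionally capped."""
    l1 = math.ceil(1.5 * k)
    return min(l1, cap) if cap is not None else l1


# ---------------------------------------------------------------------------
# ICA proper
# ---------------------------------------------------------------------------

def _orient_and_zscore(raw_maps: np.ndarray, mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply the sign convention (peak-|weight| pixel positive) and z-score."""
    raw = raw_maps.copy()
    mix = mixing.copy()
    for k in range(raw.shape[0]):
        peak = np.argmax(np.abs(raw[k]))
        if raw[k, peak] < 0:
            raw[k] = -raw[k]
            mix[:, k] = -mix[:, k]
    sd = raw.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (raw - raw.mean(axis=1, keepdims=True)) / sd
    return z, raw, mix


def run_ica(
    group_white: np.ndarray,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
) -> ComponentSet:
    """Spatial FastICA (logcosh, symmetric decorrelation) on whitened rows.

    The input rows are already white, so FastICA runs with ``whiten=False``;
    non-convergence is reported via ``converged`` rather than raised.
    """
    if not np.all(np.isfinite(group_white)):
        raise ValueError("non-finite values in whitened input")
    k = group_white.shape[0]
    ica = FastICA(
        whiten=False, fun="logcosh", max_iter=max_iter, tol=tol,
        random_state=int(np.random.default_rng(seed).integers(2**32 - 1)),
    )
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ica.fit(group_white.T)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    whiten=False, fun="logcosh", max_iter=max_iter, tol=tol,
                    random_state=int(np.random.default_rng(seed).integers(2**32 - 1)),
                )
                ica.fit(group_white.T)
    unmixing = ica.components_  # (K, K): S = unmixing @ group_white
    raw_maps = unmixing @ group_white
    mixing = linalg.pinv(unmixing)
    z, raw, mix = _orient_and_zscore(raw_maps, mixing)
    return ComponentSet(maps=z, raw_maps=raw, mixing=mix, converged=converged, seed=seed)


def _abs_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """|Pearson r| between rows of a and rows of b."""
    az = (a - a.mean(1, keepdims=True))
    bz = (b - b.mean(1, keepdims=True))
    az /= np.maximum(np.linalg.norm(az, axis=1, keepdims=True), 1e-12)
    bz /= np.maximum(np.linalg.norm(bz, axis=1, keepdims=True), 1e-12)
    return np.abs(az @ bz.T)


def _cluster_r_index(dis: np.ndarray, labels: np.ndarray, k: int) -> float:
    d_in = np.zeros(k)
    d_ext = np.full((k, k), np.nan)
    for a in range(k):
        ia = np.flatnonzero(labels == a)
        if len(ia) > 1:
            block = dis[np.ix_(ia, ia)]
            d_in[a] = block[np.triu_indices(len(ia), 1)].mean()
        for b in range(a + 1, k):
            ib = np.flatnonzero(labels == b)
            d_ext[a, b] = d_ext[b, a] = dis[np.ix_(ia, ib)].mean()
    terms = []
    for a in range(k):
        ext = np.nanmin(d_ext[a]) if k > 1 else np.nan
        terms.append(d_in[a] / max(ext, 1e-12) if np.isfinite(ext) else 0.0)
    return float(np.mean(terms))


def _reduce_to_k(stacked: np.ndarray, k: int) -> np.ndarray:
    """Second-stage whitening of ``stacked`` (D x P) down to K rows."""
    u, s, _ = _economic_svd(stacked, k)
    return math.sqrt(stacked.shape[1]) * ((u / s).T @ stacked)


def icasso(
    stacked: np.ndarray,
    k: int,
    n_runs: int = 10,
    mode: str = "both",
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-5,
    group_white: np.ndarray | None = None,
) -> tuple[IcassoResult, ComponentSet]:
    """Stability analysis: rerun FastICA, cluster estimates, take centrotypes.

    ``stacked`` is the pre-reduction matrix (D x P, D >= K): the stacked
    first-stage whitened sessions for a group fit, or a session's whitened
    rows for single-session ICA. ``mode`` selects the perturbation:
    "randinit" (new initialization only), "bootstrap" (resample pixels and
    re-estimate the K-dimensional reduction, fixed init), or "both". Each
    run's unmixing is applied to the full pixel set before clustering; the
    bootstrap therefore perturbs the retained subspace itself, which is what
    exposes unstable model orders. The cluster quality index is the mean
    within-cluster similarity minus the mean similarity to all outside
    estimates, clipped to [0, 1].

    ``group_white`` (K x P), when given, is the full-data whitened matrix
    used to express the centrotype mixing (it must come from the same
    stacked matrix); otherwise it is computed internally.
    """
    if n_runs < 2:
        raise ValueError("ICASSO needs at least 2 runs")
    if mode not in ("randinit", "bootstrap", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if stacked.shape[0] < k:
        raise ValueError(f"stacked dimension {stacked.shape[0]} below K={k}")
    rng = np.random.default_rng(seed)
    p = stacked.shape[1]
    if group_white is None:
        group_white = _reduce_to_k(stacked, k)
    estimates = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for r in range(n_runs):
            init_seed = int(rng.integers(2**32 - 1)) if mode in ("randinit", "both") else 12345
            if mode in ("bootstrap", "both"):
                idx = rng.integers(0, p, size=p)
                boot = stacked[:, idx]
                u, s, _ = _economic_svd(boot, k)
                white_full = math.sqrt(p) * ((u / s).T @ stacked)
                fit_data = white_full[:, idx]
            else:
                white_full = group_white
                fit_data = group_white
            ica = FastICA(
                whiten=False, fun="logcosh", max_iter=max_iter, tol=tol,
                random_state=init_seed,
            )
            ica.fit(fit_data.T)
            est = ica.components_ @ white_full  # estimate maps on the full pixel set
            est /= np.maximum(np.linalg.norm(est, axis=1, keepdims=True), 1e-12)
            estimates.append(est)
    est = np.concatenate(estimates, axis=0)  # (R*K, P)

    sim = _abs_corr(est, est)
    np.fill_diagonal(sim, 1.0)
    dis = 1.0 - sim
    labels = AgglomerativeClustering(
        n_clusters=k, metric="precomputed", linkage="average"
    ).fit_predict(dis)

    centro = np.zeros(k, dtype=int)
    stability = np.zeros(k)
    n_tot = est.shape[0]
    for c in range(k):
        idx = np.flatnonzero(labels == c)
        within = sim[np.ix_(idx, idx)]
        centro[c] = idx[np.argmax(within.sum(axis=1))]
        outside = np.flatnonzero(labels != c)
        s_in = within.mean() if len(idx) > 1 else 1.0
        s_ext = sim[np.ix_(idx, outside)].mean() if len(outside) else 0.0
        stability[c] = float(np.clip(s_in - s_ext, 0.0, 1.0))

    order = np.argsort(-stability)
    centro, stability = centro[order], stability[order]
    r_index = _cluster_r_index(dis, labels, k)
    result = IcassoResult(
        estimates=est, labels=labels, centrotype_idx=centro,
        stability=stability, r_index=r_index, n_runs=n_runs, seed=seed,
    )

    raw_maps = est[centro]
    # mixing via least squares: group_white ~= A @ raw_maps
    a, *_ = linalg.lstsq(raw_maps.T, group_white.T)
    z, raw, mix = _orient_and_zscore(raw_maps, a.T)
    comps = ComponentSet(maps=z, raw_maps=raw, mixing=mix, seed=seed)
    return result, comps


# ---------------------------------------------------------------------------
# order selection and back-reconstruction
# ---------------------------------------------------------------------------

@dataclass
class OrderSelection:
    best_k: int
    candidates: list[int]
    r_index: dict[int, float]


def select_order(
    dataset: GroupDataset,
    candidate_ks: list[int],
    n_runs: int = 10,
    mode: str = "both",
    seed: int = 0,
) -> OrderSelection:
    """Pick the component count minimizing the ICASSO R-index.

    Session reductions are computed once at the largest needed L1 and
    sliced per candidate (PCA bases are nested).
    """
    if not candidate_ks:
        raise ValueError("no candidate orders")
    if len(candidate_ks) == 1:
        warnings.warn("single candidate order; returning it without comparison")
        return OrderSelection(candidate_ks[0], list(candidate_ks), {candidate_ks[0]: np.nan})
    cap = min(min(s.n_frames, s.n_pixels) for s in dataset.sessions)
    l1_max = default_l1(max(candidate_ks), cap=cap)
    full = [reduce_session(s, l1_max) for s in dataset.sessions]
    curve: dict[int, float] = {}
    for k in candidate_ks:
        l1 = default_l1(k, cap=cap)
        sliced = [
            SessionReduction(u=r.u[:, :l1], s=r.s[:l1], whitened=r.whitened[:l1])
            for r in full
        ]
        try:
            model = reduce_group(sliced, k, dataset.n_pixels)
            stacked = np.concatenate([r.scaled for r in sliced], axis=0)
            res, _ = icasso(stacked, k, n_runs=n_runs, mode=mode,
                            seed=seed + 1000 * k, group_white=model.group_white)
        except Exception as exc:  # annotate which candidate failed
            raise RuntimeError(f"ICASSO failed at K={k}: {exc}") from exc
        if not np.isfinite(res.r_index) or res.r_index < 0:
            raise RuntimeError(f"invalid R-index at K={k}: {res.r_index}")
        curve[k] = res.r_index
    best = min(curve, key=curve.get)
    return OrderSelection(best, list(candidate_ks), curve)


def back_reconstruct(model: ReductionModel, components: ComponentSet, dataset: GroupDataset) -> BackReconstruction:
    """GICA back-reconstruction: per-session maps and time courses.

    With session projection blocks G_s = u_s^T X_s, group whitening W and
    dewhitening D over the stacked projections, and group_white = A @ S
    (ICA), the session-specific quantities are

        maps_s = A^{-1} @ W[:, s] @ G_s
        tc_s   = u_s @ D[s, :] @ A

    which collapse to the group maps when a single full-rank session is used.
    """
    k = components.k
    a_inv = linalg.inv(components.mixing)
    w_g = model.group_whitening()  # (K, M*L1)
    d_g = model.group_dewhitening()  # (M*L1, K)
    l1 = model.l1
    maps: dict[str, np.ndarray] = {}
    tcs: dict[str, np.ndarray] = {}
    ids: list[str] = []
    for s_idx, (red, sess) in enumerate(zip(model.sessions, dataset.sessions)):
        sl = slice(s_idx * l1, (s_idx + 1) * l1)
        sid = sess.session_id or f"session{s_idx}"
        ids.append(sid)
        maps[sid] = a_inv @ w_g[:, sl] @ red.scaled
        tcs[sid] = red.u @ d_g[sl, :] @ components.mixing
        tcs[sid] = tcs[sid].T  # (K, T_s)
    return BackReconstruction(session_ids=ids, maps=maps, timecourses=tcs)


def fit_group_ica(
    dataset: GroupDataset,
    k: int,
    l1: int | None = None,
    n_runs: int = 10,
    mode: str = "both",
    seed: int = 0,
) -> GicaFit:
    """Reduce, run ICASSO-stabilized spatial ICA, and back-reconstruct."""
    cap = min(min(s.n_frames, s.n_pixels) for s in dataset.sessions)
    l1 = default_l1(k, cap=cap) if l1 is None else l1
    reductions = [reduce_session(s, l1) for s in dataset.sessions]
    model = reduce_group(reductions, k, dataset.n_pixels)
    if n_runs >= 2:
        stacked = np.concatenate([r.scaled for r in reductions], axis=0)
        ica_res, comps = icasso(stacked, k, n_runs=n_runs, mode=mode, seed=seed,
                                group_white=model.group_white)
    else:
        ica_res, comps = None, run_ica(model.group_white, seed=seed)
    back = back_reconstruct(model, comps, dataset)
    return GicaFit(model=model, components=comps, icasso=ica_res, back=back, dataset=dataset)


def fit_single_session(session: DffMovie, k: int, n_runs: int = 10, seed: int = 0) -> ComponentSet:
    """Single-session ICA with ICASSO centrotypes.

    The session is reduced to the usual L1 headroom first, then to K inside
    the stability analysis, mirroring the group chain on one session.
    """
    cap = min(session.n_frames, session.n_pixels)
    red = reduce_session(session, default_l1(k, cap=cap))
    if n_runs >= 2:
        _, comps = icasso(red.scaled, k, n_runs=n_runs, seed=seed)
    else:
        comps = run_ica(_reduce_to_k(red.scaled, k), seed=seed)
    return comps
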