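"""Synthetic multi-subject, multi-state wide-field calcium movies.

The generator emulates the study design that the analysis pipeline targets:
three subjects, two sessions each, six anesthesia states concatenated per
session (iso 2% ... iso 0.5%, then awake). Each session is a forward model

    F[t, y, x] = f0 * (1 + sum_k map_k[y,x] * tc_k[t]/100 + drift + vessel) + noise

over a set of spatially compact Gaussian sources with known state-dependent
event statistics:

* deep states (iso 2%, 1.75%): a global Poisson "up-state" clock at
  0.1-0.2 Hz; every source joins each global event with a participation
  probability, reproducing near-global bistable dynamics;
* intermediate states (iso 1.5-0.5%): a quasi-periodic oscillatory clock at
  0.2-0.4 Hz with decreasing cross-source coherence as anesthesia lightens;
* awake: independent per-source Poisson transients, except for a designated
  "retrosplenial-like" pair that shares a calibrated fraction of its events.

Events are rendered as single-exponential calcium transients (tau = 0.5 s,
jRCaMP1b-like) with +/-20% amplitude jitter. Two coupling knobs -- the deep
participation probability of the retrosplenial pair and its awake shared
fraction -- are calibrated by bisection so that the phi correlation of the
TRUE binarized time courses hits the design targets (0.8 deep, 0.35 awake),
mirroring the state-dependent co-activation the pipeline must recover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .atlas import SyntheticAtlas, make_atlas
from .states import AWAKE, DEEPEST, STATES, Segment

#: Calcium transient decay constant (s); slow red-shifted indicator regime.
TAU_CALCIUM = 0.5

#: Per-event peak amplitude jitter (uniform fraction of the nominal amplitude).
AMPLITUDE_JITTER = 0.20

#: Per-source onset latency of shared events (s, uniform in [0, this]).
#: Emulates the finite propagation of slow waves across cortex; the
#: retrosplenial pair shares its latency draw (homotopic posterior-medial
#: regions receive the wave nearly synchronously), all other sources draw
#: independently.
ONSET_JITTER_S = 0.10

#: Local sub-threshold transients: every source expresses independent
#: low-amplitude events in every state. They keep each source's raw trace
#: individually identifiable (linearly separable) without contributing to
#: the suprathreshold activation statistics.
SMALL_EVENT_RATE = 12.0  # events/min
SMALL_EVENT_AMP = 0.30  # fraction of the source's nominal amplitude

#: Internal seed for the deterministic coupling calibration (never user-facing).
_CALIBRATION_SEED = 20240501

#: Per-state event mechanics. ``clock`` is the shared-clock rate in events/min
#: (None = no shared clock), ``coherence`` the fraction of each source's events
#: drawn from the shared clock, and participation values give per-source rates
#: as a fraction of the clock rate. Designed so that (a) total crossings rise
#: monotonically from deep to awake, and (b) the retrosplenial share of all
#: crossings falls monotonically (approx. 0.42 -> 0.08).
_STATE_PARAMS: dict[str, dict] = {
    "iso2.0": dict(clock=9.0, mode="poisson", coherence=1.00, g_retro=0.90, g_other=0.415),
    "iso1.75": dict(clock=11.0, mode="poisson", coherence=0.90, g_retro=0.75, g_other=0.48),
    "iso1.5": dict(clock=15.0, mode="periodic", coherence=0.75, g_retro=0.60, g_other=0.57),
    "iso1.0": dict(clock=18.0, mode="periodic", coherence=0.60, g_retro=0.50, g_other=0.71),
    "iso0.5": dict(clock=21.0, mode="periodic", coherence=0.45, g_retro=0.42, g_other=0.93),
    "awake": dict(clock=None, mode="independent", coherence=0.0, rate_retro=6.0, rate_other=23.0),
}

#: Designed phi (binarized co-activation) targets for the retrosplenial pair.
PHI_TARGETS = {"iso2.0": 0.80, "awake": 0.35}


@dataclass
class SourceDesign:
    """Ground-truth source geometry and state-dependent event statistics.

    centers/widths/macro_group/amplitude are per-source; ``state_params``
    follows the table documented at module level after calibration.
    ``retro_pair`` indexes the two retrosplenial-like sources whose
    co-activation carries the designed state dependence.
    """

    centers: np.ndarray  # (S, 2) float, (row, col)
    widths: np.ndarray  # (S,) Gaussian sigma in px
    macro_group: list[str]
    amplitude: np.ndarray  # (S,) peak dF/F0 in %
    state_params: dict[str, dict]
    retro_pair: tuple[int, int]
    awake_shared_fraction: float = 0.5  # calibrated
    phi_targets: dict[str, float] = field(default_factory=lambda: dict(PHI_TARGETS))

    @property
    def n_sources(self) -> int:
        return len(self.centers)

    def rate(self, state: str) -> np.ndarray:
        """Expected per-source event rate (events/min) in ``state``."""
        p = self.state_params[state]
        retro = np.isin(np.arange(self.n_sources), self.retro_pair)
        if p["clock"] is None:
            return np.where(retro, p["rate_retro"], p["rate_other"]).astype(float)
        return p["clock"] * np.where(retro, p["g_retro"], p["g_other"])

    @property
    def state_rate(self) -> dict[str, np.ndarray]:
        """state -> per-source expected event rate (events/min)."""
        return {s: self.rate(s) for s in self.state_params}

    def coupling_matrix(self, state: str) -> np.ndarray:
        """Designed pairwise co-activation probability (symmetric, unit diag).

        For shared-clock states this is the product of coherence^2 and the
        geometric mean of the two participation probabilities; in the awake
        state it is the shared event fraction for the designated pair and 0
        elsewhere.
        """
        p = self.state_params[state]
        n = self.n_sources
        retro = np.isin(np.arange(n), self.retro_pair)
        if p["clock"] is None:
            c = np.zeros((n, n))
            i, j = self.retro_pair
            c[i, j] = c[j, i] = self.awake_shared_fraction
        else:
            g = np.where(retro, p["g_retro"], p["g_other"])
            c = p["coherence"] ** 2 * np.sqrt(np.outer(g, g))
        np.fill_diagonal(c, 1.0)
        return c


@dataclass
class DriftParams:
    """Slow multiplicative baseline drift: sinusoid (< 0.05 Hz) plus linear term."""

    sin_amp: float = 0.01  # fractional
    sin_freq: float = 0.02  # Hz
    linear_amp: float = 0.01  # fractional, end-to-end


@dataclass
class GroundTruth:
    """Everything the downstream recovery tests need to score the pipeline."""

    maps: np.ndarray  # (S, H, W), nonnegative, peak-normalized per source
    timecourses: dict[str, np.ndarray]  # session_id -> (S, T) in % dF/F0
    events: dict[str, list[np.ndarray]]  # session_id -> per-source event frames
    segments: list[Segment]
    design: SourceDesign
    atlas: SyntheticAtlas
    fps: float
    noise_sd: float
    drift: DriftParams
    vessel_map: np.ndarray  # (H, W)
    vessel_timecourses: dict[str, np.ndarray]  # session_id -> (T,)
    shifts: dict[str, tuple[int, int]]  # per-session landmark/pattern shift (rows, cols)
    subject_of: dict[str, str]


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the emulated study conditions."""

    n_subjects: int = 3
    sessions_per_subject: int = 2
    height: int = 64
    width: int = 64
    fps: float = 40.0
    dur_per_state: float = 300.0  # s
    f0: float = 1000.0  # baseline counts
    noise_sd: float = 5.0  # sensor noise counts (0.5% of f0)
    amplitude: float = 8.0  # nominal source peak, % dF/F0
    vessel_amp: float = 0.8  # vessel temporal std, % dF/F0
    drift: DriftParams = field(default_factory=DriftParams)
    landmark_jitter: int = 2  # max per-session integer shift (px)
    subject_scale_jitter: float = 0.10  # per-subject amplitude scaling
    states: tuple[str, ...] = STATES
    calibrate: bool = True


# ---------------------------------------------------------------------------
# source geometry
# ---------------------------------------------------------------------------

def _default_geometry(atlas: SyntheticAtlas) -> tuple[np.ndarray, np.ndarray, list[str]]:
    h, w = atlas.shape
    cx = w // 2
    off = lambda f: f * w  # noqa: E731  (column offset from midline)
    layout = [
        ("Retrosplenial", 0.72, -0.10),
        ("Retrosplenial", 0.72, +0.10),
        ("Somatosensory", 0.50, -0.28),
        ("Somatosensory", 0.50, +0.28),
        ("Somatomotor", 0.22, -0.20),
        ("Somatomotor", 0.22, +0.20),
        ("Visual", 0.82, -0.26),
        ("PosteriorParietal", 0.67, +0.28),
    ]
    centers = np.array([(rf * h, cx + off(cf)) for _, rf, cf in layout])
    widths = np.full(len(layout), 0.055 * min(h, w))
    groups = [g for g, _, _ in layout]
    for (r, c), g in zip(centers, groups):
        got = atlas.group_of(int(round(r)), int(round(c)))
        if got != g:
            raise RuntimeError(f"source center ({r:.0f},{c:.0f}) fell in {got}, wanted {g}")
    return centers, widths, groups


def source_maps(design: SourceDesign, shape: tuple[int, int]) -> np.ndarray:
    """Render per-source Gaussian spatial weights, peak-normalized to 1."""
    h, w = shape
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    maps = np.empty((design.n_sources, h, w), dtype=np.float32)
    for k, ((r0, c0), sig) in enumerate(zip(design.centers, design.widths)):
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        maps[k] = np.exp(-d2 / (2.0 * sig**2))
    return maps


def vessel_map(atlas: SyntheticAtlas) -> np.ndarray:
    """Elongated vessel-like static map: a thin curved streak branching off
    the midline toward posterior-lateral cortex."""
    h, w = atlas.shape
    cx = w // 2
    t = np.linspace(0.0, 1.0, 200)
    rr = (0.30 + 0.45 * t) * h
    cc = cx + (0.02 + 0.22 * t**1.3) * w
    rows = np.arange(h)[:, None, None]
    cols = np.arange(w)[None, :, None]
    d2 = (rows - rr[None, None, :]) ** 2 + (cols - cc[None, None, :]) ** 2
    vm = np.exp(-d2.min(axis=2) / (2.0 * 0.8**2)).astype(np.float32)
    vm[~atlas.mask] = 0.0
    return vm


# ---------------------------------------------------------------------------
# event trains and time courses
# ---------------------------------------------------------------------------

def _poisson_train(rate_per_s: float, n_frames: int, fps: float, rng: np.random.Generator) -> np.ndarray:
    """Frame indices of a Poisson event train."""
    if rate_per_s <= 0:
        return np.empty(0, dtype=np.int64)
    p = rate_per_s / fps
    return np.flatnonzero(rng.random(n_frames) < p)


def _periodic_train(rate_per_s: float, n_frames: int, fps: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-periodic tick train: period 1/rate with +/-15% jitter."""
    if rate_per_s <= 0:
        return np.empty(0, dtype=np.int64)
    period = fps / rate_per_s
    ticks = []
    t = rng.uniform(0, period)
    while t < n_frames:
        ticks.append(int(t))
        t += period * (1.0 + rng.uniform(-0.15, 0.15))
    return np.asarray(ticks, dtype=np.int64)


def _render_kernel(events: np.ndarray, amps: np.ndarray, n_frames: int, fps: float) -> np.ndarray:
    """Convolve an amplitude-weighted event train with the exponential kernel."""
    impulses = np.zeros(n_frames)
    np.add.at(impulses, events, amps)
    alpha = np.exp(-1.0 / (TAU_CALCIUM * fps))
    return signal.lfilter([1.0], [1.0, -alpha], impulses)


def simulate_timecourses(
    design: SourceDesign,
    states: tuple[str, ...],
    fps: float,
    dur_per_state: float,
    seed: int,
    amplitude_scale: float = 1.0,
) -> tuple[np.ndarray, list[np.ndarray], list[Segment]]:
    """Simulate per-source time courses and event trains for one session.

    Returns ``(tc, events, segments)`` with ``tc`` of shape (S, T) in % dF/F0
    and ``events`` a list of per-source event-frame arrays. States must be
    ordered deepest to awake; event counts per source and state have
    expectation rate * duration.
    """
    if not states:
        raise ValueError("empty state list")
    if dur_per_state <= 0:
        raise ValueError("dur_per_state must be positive")
    if fps <= 0:
        raise ValueError("fps must be positive")
    rng = np.random.default_rng(seed)
    n_seg = int(round(dur_per_state * fps))
    n_src = design.n_sources
    total = n_seg * len(states)

    pair = design.retro_pair
    max_lag = max(int(round(ONSET_JITTER_S * fps)), 0)
    per_source_events: list[list[np.ndarray]] = [[] for _ in range(n_src)]
    segments: list[Segment] = []
    for si, state in enumerate(states):
        start = si * n_seg
        segments.append(Segment(state, start, start + n_seg))
        p = design.state_params[state]
        rates = design.rate(state) / 60.0  # events/s
        if p["clock"] is not None:
            clock_rate = p["clock"] / 60.0
            maker = _poisson_train if p["mode"] == "poisson" else _periodic_train
            ticks = maker(clock_rate, n_seg, fps, rng)
            # propagation latency per tick per source; homotopic pair shared
            if max_lag and len(ticks):
                lags = rng.integers(0, max_lag + 1, size=(n_src, len(ticks)))
                lags[pair[1]] = lags[pair[0]]
            else:
                lags = np.zeros((n_src, len(ticks)), dtype=np.int64)
            for k in range(n_src):
                g = rates[k] / clock_rate
                sel = rng.random(len(ticks)) < g * p["coherence"]
                keep = np.minimum(ticks[sel] + lags[k, sel], n_seg - 1)
                indep = _poisson_train(rates[k] * (1.0 - p["coherence"]), n_seg, fps, rng)
                per_source_events[k].append(np.union1d(keep, indep) + start)
        else:
            i, j = pair
            c = design.awake_shared_fraction
            shared_rate = c * min(rates[i], rates[j])
            shared = _poisson_train(shared_rate, n_seg, fps, rng)
            for k in range(n_src):
                own_rate = rates[k] - (shared_rate if k in (i, j) else 0.0)
                own = _poisson_train(max(own_rate, 0.0), n_seg, fps, rng)
                ev = np.union1d(shared, own) if k in (i, j) else own
                per_source_events[k].append(ev + start)

    tc = np.zeros((n_src, total), dtype=np.float64)
    events_out: list[np.ndarray] = []
    for k in range(n_src):
        ev = np.concatenate(per_source_events[k]) if per_source_events[k] else np.empty(0, int)
        ev = np.unique(ev)
        amps = design.amplitude[k] * amplitude_scale * rng.uniform(
            1.0 - AMPLITUDE_JITTER, 1.0 + AMPLITUDE_JITTER, size=len(ev)
        )
        tc[k] = _render_kernel(ev, amps, total, fps)
        # independent local sub-threshold transients, every state
        small = _poisson_train(SMALL_EVENT_RATE / 60.0, total, fps, rng)
        small_amps = SMALL_EVENT_AMP * design.amplitude[k] * amplitude_scale * rng.uniform(
            1.0 - AMPLITUDE_JITTER, 1.0 + AMPLITUDE_JITTER, size=len(small)
        )
        tc[k] += _render_kernel(small, small_amps, total, fps)
        events_out.append(ev)
    return tc, events_out, segments


# ---------------------------------------------------------------------------
# coupling calibration
# ---------------------------------------------------------------------------

def highpass_timecourses(tc: np.ndarray, fps: float, cutoff: float = 0.1) -> np.ndarray:
    """Zero-phase 4th-order Butterworth high-pass, matching the analysis band.

    The pipeline binarizes time courses recovered from 0.1 Hz high-passed
    data, so ground-truth comparisons and the coupling calibration are made
    on traces passed through the same filter.
    """
    sos = signal.butter(4, cutoff, btype="highpass", fs=fps, output="sos")
    return signal.sosfiltfilt(sos, np.atleast_2d(tc), axis=1)


def _binarized_phi(
    tc: np.ndarray,
    segments: list[Segment],
    state: str,
    pair: tuple[int, int],
    fps: float | None = None,
) -> float:
    """Phi correlation of the pair's binarized time courses inside ``state``.

    Thresholds are +/- 3 sigma of each trace during the deepest segment,
    i.e. exactly the rule the analysis pipeline applies; when ``fps`` is
    given the traces are first high-passed into the analysis band.
    """
    if fps is not None:
        tc = highpass_timecourses(tc, fps)
    deep = next(s for s in segments if s.state == DEEPEST)
    seg = next(s for s in segments if s.state == state)
    i, j = pair
    out = []
    for k in (i, j):
        ref = tc[k, deep.start : deep.end]
        mu, sd = ref.mean(), ref.std()
        b = (tc[k] > mu + 3 * sd) | (tc[k] < mu - 3 * sd)
        out.append(b[seg.start : seg.end].astype(float))
    bi, bj = out
    if bi.std() == 0 or bj.std() == 0:
        return 0.0
    return float(np.corrcoef(bi, bj)[0, 1])


def _calibrate(design: SourceDesign, fps: float) -> SourceDesign:
    """Bisect the two coupling knobs against the designed phi targets.

    Uses a fixed internal seed and long (1200 s) calibration segments,
    averaged over six replicates per bisection step, so the result is
    deterministic and estimator noise is well below the design tolerance. Only the deepest-state retro participation and the awake
    shared fraction are adjusted.
    """
    cal_states = (DEEPEST, AWAKE)

    # deep participation of the retro pair
    lo, hi = 0.55, 1.0
    target = design.phi_targets[DEEPEST]
    for _ in range(10):
        mid = 0.5 * (lo + hi)
        d = replace(design, state_params={**design.state_params})
        d.state_params[DEEPEST] = {**d.state_params[DEEPEST], "g_retro": mid}
        phis = []
        for r in range(6):
            tc, _, segs = simulate_timecourses(d, cal_states, fps, 1200.0, _CALIBRATION_SEED + r)
            phis.append(_binarized_phi(tc, segs, DEEPEST, d.retro_pair, fps=fps))
        if float(np.mean(phis)) < target:
            lo = mid
        else:
            hi = mid
    g_deep = 0.5 * (lo + hi)
    design = replace(design, state_params={**design.state_params})
    design.state_params[DEEPEST] = {**design.state_params[DEEPEST], "g_retro": min(g_deep, 1.0)}

    # awake shared fraction
    lo, hi = 0.05, 0.95
    target = design.phi_targets[AWAKE]
    for _ in range(10):
        mid = 0.5 * (lo + hi)
        d = replace(design, awake_shared_fraction=mid)
        phis = []
        for r in range(6):
            tc, _, segs = simulate_timecourses(d, cal_states, fps, 1200.0, _CALIBRATION_SEED + r)
            phis.append(_binarized_phi(tc, segs, AWAKE, d.retro_pair, fps=fps))
        if float(np.mean(phis)) < target:
            lo = mid
        else:
            hi = mid
    return replace(design, awake_shared_fraction=0.5 * (lo + hi))


def default_design(atlas: SyntheticAtlas, fps: float, amplitude: float = 8.0, calibrate: bool = True) -> SourceDesign:
    """The emulated study design: 8 sources over 5 macro areas with the
    state-dependent rate/coherence table and calibrated coupling."""
    centers, widths, groups = _default_geometry(atlas)
    retro = tuple(i for i, g in enumerate(groups) if g == "Retrosplenial")
    design = SourceDesign(
        centers=centers,
        widths=widths,
        macro_group=groups,
        amplitude=np.full(len(groups), amplitude, dtype=float),
        state_params={s: dict(p) for s, p in _STATE_PARAMS.items()},
        retro_pair=(retro[0], retro[1]),
    )
    if calibrate:
        design = _calibrate(design, fps)
    return design


# ---------------------------------------------------------------------------
# movie rendering
# ---------------------------------------------------------------------------

def _integer_shift(img: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape[-2:]
    ys, yd = (slice(0, h - dy), slice(dy, h)) if dy >= 0 else (slice(-dy, h), slice(0, h + dy))
    xs, xd = (slice(0, w - dx), slice(dx, w)) if dx >= 0 else (slice(-dx, w), slice(0, w + dx))
    out[..., yd, xd] = img[..., ys, xs]
    return out


def render_movie(
    maps: np.ndarray,
    tc: np.ndarray,
    f0: float,
    noise_sd: float,
    seed: int,
    drift: DriftParams | None = None,
    vessel: tuple[np.ndarray, np.ndarray] | None = None,
    fps: float = 40.0,
    shift: tuple[int, int] = (0, 0),
    background: float = 0.1,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a fluorescence stack from maps (S,H,W) and time courses (S,T).

    Pixel model: ``f0 * (1 + signal/100 + drift + vessel/100) + N(0, noise_sd)``
    inside the valid region, a dim constant background outside. ``shift``
    translates the whole spatial pattern (and the valid region) by integer
    pixels, emulating a session-specific field-of-view offset that the
    registration stage must undo. Returns ``(frames, valid_mask)``.
    """
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    s, h, w = maps.shape
    if tc.shape[0] != s:
        raise ValueError(f"maps have {s} sources but timecourses {tc.shape[0]}")
    n_frames = tc.shape[1]
    rng = np.random.default_rng(seed)

    if valid is None:
        valid = np.ones((h, w), dtype=bool)
    flat_maps = maps.reshape(s, -1).astype(np.float32)
    sig = (tc.astype(np.float32).T @ flat_maps).reshape(n_frames, h, w)  # % dF/F0

    gain = np.ones(n_frames, dtype=np.float32)
    if drift is not None:
        t = np.arange(n_frames, dtype=np.float32) / fps
        phase = rng.uniform(0, 2 * np.pi)
        gain += drift.sin_amp * np.sin(2 * np.pi * drift.sin_freq * t + phase).astype(np.float32)
        gain += drift.linear_amp * (t / max(t[-1], 1e-9) - 0.5).astype(np.float32)

    if vessel is not None:
        vmap, vtc = vessel
        sig = sig + vtc.astype(np.float32)[:, None, None] * vmap.astype(np.float32)[None]

    if shift != (0, 0):
        dy, dx = shift
        sig = _integer_shift(sig, dy, dx)
        valid = _integer_shift(valid.astype(np.float32), dy, dx) > 0.5
    else:
        valid = valid.copy()

    frames = f0 * gain[:, None, None] * (1.0 + sig / 100.0)
    frames = np.where(valid[None], frames, background * f0).astype(np.float32)
    frames += rng.normal(0.0, noise_sd, size=frames.shape).astype(np.float32)
    np.maximum(frames, 0.0, out=frames)
    return frames, valid


def vessel_timecourse(n_frames: int, fps: float, amp: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited pulsation-like vessel signal (0.5-1.5 Hz), std = amp %."""
    x = rng.standard_normal(n_frames)
    nyq = fps / 2.0
    hi = min(1.5, 0.9 * nyq)
    lo = min(0.5, 0.5 * hi)
    sos = signal.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return (amp / sd * y if sd > 0 else y).astype(np.float32)


# ---------------------------------------------------------------------------
# study-level convenience
# ---------------------------------------------------------------------------

def simulate_study(config: SimulationConfig, seed: int):
    """Simulate the full multi-subject study.

    Returns ``(raw_movies, truth)`` where ``raw_movies`` is a list of
    :class:`wfgica.preprocess.RawMovie` (one per session, states concatenated)
    and ``truth`` the :class:`GroundTruth` used by recovery tests.
    """
    from .preprocess import RawMovie  # local import to avoid a cycle

    ss = np.random.SeedSequence(seed)
    atlas = make_atlas(config.height, config.width, seed=0)
    design = default_design(atlas, config.fps, config.amplitude, calibrate=config.calibrate)
    maps = source_maps(design, atlas.shape)
    vmap = vessel_map(atlas)

    raws: list[RawMovie] = []
    truth_tc: dict[str, np.ndarray] = {}
    truth_ev: dict[str, list[np.ndarray]] = {}
    vessel_tcs: dict[str, np.ndarray] = {}
    shifts: dict[str, tuple[int, int]] = {}
    subject_of: dict[str, str] = {}
    segments_ref: list[Segment] | None = None

    child_seeds = ss.spawn(config.n_subjects)
    for si in range(config.n_subjects):
        subject = f"sub{si + 1}"
        sub_ss = child_seeds[si]
        sub_rng = np.random.default_rng(sub_ss)
        scale = 1.0 + sub_rng.uniform(-1, 1) * config.subject_scale_jitter
        for ri in range(config.sessions_per_subject):
            session = f"{subject}_ses{ri + 1}"
            s_tc, s_ev, s_noise = (int(x.generate_state(1)[0] % (2**31)) for x in sub_ss.spawn(3))
            tc, events, segments = simulate_timecourses(
                design, config.states, config.fps, config.dur_per_state,
                seed=s_tc + ri, amplitude_scale=scale,
            )
            segments_ref = segments
            n_frames = tc.shape[1]
            vtc = vessel_timecourse(n_frames, config.fps, config.vessel_amp,
                                    np.random.default_rng(s_noise + 7 * ri))
            jit = config.landmark_jitter
            shift = tuple(int(v) for v in sub_rng.integers(-jit, jit + 1, size=2)) if jit else (0, 0)
            frames, valid = render_movie(
                maps, tc, config.f0, config.noise_sd, seed=s_noise + ri,
                drift=config.drift, vessel=(vmap, vtc), fps=config.fps,
                shift=shift, valid=atlas.mask,
            )
            raws.append(
                RawMovie(
                    frames=frames,
                    fps=config.fps,
                    bregma=(atlas.bregma[0] + shift[0], atlas.bregma[1] + shift[1]),
                    lambda_=(atlas.lambda_[0] + shift[0], atlas.lambda_[1] + shift[1]),
                    subject_id=subject,
                    session_id=session,
                    segments=segments,
                    valid=valid,
                )
            )
            truth_tc[session] = tc
            truth_ev[session] = events
            vessel_tcs[session] = vtc
            shifts[session] = shift
            subject_of[session] = subject

    truth = GroundTruth(
        maps=maps,
        timecourses=truth_tc,
        events=truth_ev,
        segments=segments_ref or [],
        design=design,
        atlas=atlas,
        fps=config.fps,
        noise_sd=config.noise_sd,
        drift=config.drift,
        vessel_map=vmap,
        vessel_timecourses=vessel_tcs,
        shifts=shifts,
        subject_of=subject_of,
    )
    return raws, truth
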