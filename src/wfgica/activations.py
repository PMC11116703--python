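"""Activation-occurrence statistics of IC time courses across brain states.

The deepest-anesthesia segment (iso 2%) serves as the reference: each IC's
time course is thresholded at its iso-2% mean +/- 3 SD, yielding a per-frame
binary activation vector. The number of suprathreshold frames per state,
N_IC,ST, and its share of all ICs' activations in that state,
N_IC,ST / sum_IC N_IC,ST, quantify how much each component contributes to
the fluorescence signal in each brain state. A bootstrap null -- resampling
threshold-crossing events with replacement, half from the deepest state and
half from the awake state -- gives each IC's expected proportion free of
between-state crossing-count bias; a component is "prominent" in a state
when the lower bound of the across-subject 95% t-CI of its relative
occurrence exceeds that expected proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .states import AWAKE, DEEPEST, Segment, segment_for


@dataclass
class ActivationRecord:
    """Per-session binary activations and occurrence statistics for all ICs."""

    session_id: str
    subject_id: str
    th_pos: np.ndarray  # (K,)
    th_neg: np.ndarray  # (K,)
    binary: np.ndarray  # (K, T) uint8
    segments: list[Segment]
    counts: pd.DataFrame = field(default=None)  # state x ic -> N_IC,ST
    rel_occurrence: pd.DataFrame = field(default=None)  # state x ic, NaN if no crossings

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts, self.rel_occurrence = count_and_proportion(self.binary, self.segments)


@dataclass
class ExpectedNull:
    """Bootstrap expected occurrence proportions per IC."""

    expected: np.ndarray  # (K,) proportions summing to 1
    n_sim: int
    n_per_state: int
    seed: int


def compute_thresholds(
    tc: np.ndarray, segments: list[Segment], n_sd: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Iso-2% mean +/- ``n_sd`` SD thresholds, one pair per IC time course.

    ``tc`` is (K, T); statistics use only the deepest-state segment.
    """
    tc = np.atleast_2d(tc)
    deep = segment_for(segments, DEEPEST)
    ref = tc[:, deep.start : deep.end]
    if ref.shape[1] == 0:
        raise ValueError("empty deepest-state segment")
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant deepest-state reference (sigma = 0)")
    return mu + n_sd * sd, mu - n_sd * sd


def binarize(tc: np.ndarray, th_pos: np.ndarray, th_neg: np.ndarray) -> np.ndarray:
    """1 wherever the time course strictly exceeds either threshold."""
    tc = np.atleast_2d(tc)
    th_pos = np.atleast_1d(th_pos)[:, None]
    th_neg = np.atleast_1d(th_neg)[:, None]
    if np.any(th_pos <= th_neg):
        raise ValueError("th_pos must exceed th_neg")
    return ((tc > th_pos) | (tc < th_neg)).astype(np.uint8)


def count_and_proportion(
    binary: np.ndarray, segments: list[Segment]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-state suprathreshold-frame counts and relative proportions.

    Returns ``(counts, rel)`` DataFrames indexed by state with one column
    per IC. States where no IC crosses are reported as missing (NaN), not 0.
    """
    k = binary.shape[0]
    rows = {}
    for seg in segments:
        rows[seg.state] = binary[:, seg.start : seg.end].sum(axis=1)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=range(k)).astype(float)
    totals = counts.sum(axis=1)
    rel = counts.div(totals.where(totals > 0), axis=0)
    return counts, rel


def make_activation_record(
    session_id: str,
    subject_id: str,
    timecourses: np.ndarray,
    segments: list[Segment],
    n_sd: float = 3.0,
) -> ActivationRecord:
    """Threshold and binarize one session's (K, T) IC time courses."""
    th_pos, th_neg = compute_thresholds(timecourses, segments, n_sd=n_sd)
    binary = binarize(timecourses, th_pos, th_neg)
    return ActivationRecord(
        session_id=session_id, subject_id=subject_id,
        th_pos=th_pos, th_neg=th_neg, binary=binary, segments=segments,
    )


def expected_null(
    records: list[ActivationRecord],
    n_sim: int = 10_000,
    n_per_state: int = 5_000,
    seed: int = 0,
    ic_ids: np.ndarray | None = None,
) -> ExpectedNull:
    """Bootstrap expected occurrence, pooled over the supplied sessions.

    Every suprathreshold frame in the deepest and awake segments is a
    crossing event carrying its IC identity. ``n_per_state`` draws come
    with replacement from the deepest-state pool and ``n_sim - n_per_state``
    from the awake pool; the expected proportion of an IC is its share of
    all draws.
    """
    if not records:
        raise ValueError("no activation records")
    k = records[0].binary.shape[0]
    ids = np.arange(k) if ic_ids is None else np.asarray(ic_ids)
    pools = {DEEPEST: [], AWAKE: []}
    for rec in records:
        for state in (DEEPEST, AWAKE):
            seg = segment_for(rec.segments, state)
            sub = rec.binary[ids][:, seg.start : seg.end]
            ic_of_crossing = np.nonzero(sub)[0]
            pools[state].append(ic_of_crossing)
    deep_pool = np.concatenate(pools[DEEPEST])
    awake_pool = np.concatenate(pools[AWAKE])
    if len(deep_pool) == 0 or len(awake_pool) == 0:
        raise ValueError("empty crossing pool in the deepest or awake state")
    rng = np.random.default_rng(seed)
    draws = np.concatenate([
        rng.choice(deep_pool, size=n_per_state, replace=True),
        rng.choice(awake_pool, size=n_sim - n_per_state, replace=True),
    ])
    expected = np.bincount(draws, minlength=len(ids)) / n_sim
    return ExpectedNull(expected=expected, n_sim=n_sim, n_per_state=n_per_state, seed=seed)


def subject_occurrence(
    records: list[ActivationRecord], state: str, ic_ids: np.ndarray | None = None
) -> pd.DataFrame:
    """Subject x IC relative occurrence for one state (sessions averaged)."""
    rows = []
    for rec in records:
        rel = rec.rel_occurrence.loc[state]
        if ic_ids is not None:
            rel = rel[ic_ids]
        rows.append(pd.Series(rel.values, name=rec.subject_id))
    df = pd.DataFrame(rows)
    return df.groupby(level=0).mean()


def prominent_components(
    subject_props: pd.DataFrame, null: ExpectedNull, alpha: float = 0.05
) -> np.ndarray:
    """ICs whose across-subject CI lower bound exceeds the expected proportion.

    ``subject_props`` is subjects x ICs; the CI is the two-sided t interval
    with N-1 degrees of freedom.
    """
    n = subject_props.shape[0]
    if n < 2:
        raise ValueError("confidence interval undefined for fewer than 2 subjects")
    mean = subject_props.mean(axis=0).values
    sem = subject_props.std(axis=0, ddof=1).values / np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    lower = mean - tcrit * sem
    return np.flatnonzero(lower > null.expected)


def occurrence_by_group(
    labels: list,
    records: list[ActivationRecord],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Macro-group occurrence table.

    For every session and state, relative occurrences are computed over the
    retained ICs only, averaged over the ICs of each macro group, then over
    each subject's sessions. Returns a tidy frame with per-subject values and
    across-subject group mean and 95% t-CI columns merged in.
    """
    retained = [lab.ic_id for lab in labels if lab.retained]
    if not retained:
        raise ValueError("no retained components")
    group_of = {lab.ic_id: lab.macro_group for lab in labels if lab.retained}
    rows = []
    for rec in records:
        counts = rec.counts[retained]
        totals = counts.sum(axis=1)
        rel = counts.div(totals.where(totals > 0), axis=0)
        for state in rel.index:
            for ic in retained:
                rows.append(
                    dict(subject=rec.subject_id, session=rec.session_id,
                         state=state, group=group_of[ic], ic=ic, rel=rel.loc[state, ic])
                )
    tidy = pd.DataFrame(rows)
    per_session = tidy.groupby(["subject", "session", "state", "group"], sort=False)["rel"].mean()
    per_subject = per_session.groupby(["subject", "state", "group"], sort=False).mean().reset_index()

    def ci(g: pd.Series) -> pd.Series:
        n = g.count()
        m = g.mean()
        if n < 2:
            return pd.Series(dict(mean=m, ci_lower=np.nan, ci_upper=np.nan, n=n))
        half = stats.t.ppf(1 - alpha / 2, df=n - 1) * g.std(ddof=1) / np.sqrt(n)
        return pd.Series(dict(mean=m, ci_lower=m - half, ci_upper=m + half, n=n))

    summary = per_subject.groupby(["state", "group"], sort=False)["rel"].apply(ci).unstack()
    return per_subject.merge(summary.reset_index(), on=["state", "group"])
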