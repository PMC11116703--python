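"""Binarized co-occurrence of ICs and its state dependence.

Co-activation between two ICs in a given brain state is the Pearson
correlation of their binary activation vectors restricted to that state's
frames (for binary data this is the phi coefficient). Within-group
coupling is summarized by Fisher z-transforming the within-group pairwise
correlations and averaging; state dependence is tested with a one-factor
repeated-measures ANOVA over the six states followed by paired t-tests on
all state pairs with Holm correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import Segment

#: |r| is clipped here before atanh so coincident binary vectors stay finite.
FISHER_CLIP = 1.0 - 1e-6


@dataclass
class AnovaResult:
    f: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False


def binary_corr(binary_i: np.ndarray, binary_j: np.ndarray) -> float:
    """Phi coefficient (Pearson r of two binary vectors); NaN if either
    vector is constant."""
    bi = np.asarray(binary_i, dtype=float)
    bj = np.asarray(binary_j, dtype=float)
    if bi.std() == 0 or bj.std() == 0:
        return float("nan")
    return float(np.corrcoef(bi, bj)[0, 1])


def state_matrices(binary: np.ndarray, segments: list[Segment]) -> dict[str, np.ndarray]:
    """One K x K phi matrix per state; symmetric with unit diagonal.

    Entries involving a constant vector within the state are NaN.
    """
    out: dict[str, np.ndarray] = {}
    k = binary.shape[0]
    for seg in segments:
        sub = binary[:, seg.start : seg.end].astype(float)
        sd = sub.std(axis=1)
        ok = sd > 0
        mat = np.full((k, k), np.nan)
        if ok.sum() >= 2:
            mat[np.ix_(ok, ok)] = np.corrcoef(sub[ok])
        mat[np.diag_indices(k)] = 1.0
        out[seg.state] = mat
    return out


def fisher_group_mean(matrix: np.ndarray, ic_groups: list[str], group: str) -> float:
    """Mean Fisher z of all within-group IC pairs (NaN if < 2 group ICs).

    Pairs whose phi is undefined are skipped; if all are undefined the
    result is NaN.
    """
    idx = [i for i, g in enumerate(ic_groups) if g == group]
    if len(idx) < 2:
        return float("nan")
    zs = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            r = matrix[idx[a], idx[b]]
            if np.isfinite(r):
                zs.append(np.arctanh(np.clip(r, -FISHER_CLIP, FISHER_CLIP)))
    return float(np.mean(zs)) if zs else float("nan")


def mean_offdiagonal(matrix: np.ndarray) -> float:
    """Mean of the finite off-diagonal entries."""
    k = matrix.shape[0]
    off = matrix[~np.eye(k, dtype=bool)]
    off = off[np.isfinite(off)]
    return float(off.mean()) if off.size else float("nan")


def rm_anova(table: pd.DataFrame | np.ndarray, sphericity_correction: str | None = None) -> AnovaResult:
    """One-factor repeated-measures ANOVA (subjects x states).

    F = MS_state / MS_error with df = (s-1, (s-1)(n-1)). By default no
    sphericity correction is applied (uncorrected degrees of freedom
    convention); ``sphericity_correction="gg"`` rescales both df by the
    Greenhouse-Geisser epsilon when computing p (F is unchanged). Zero
    residual variance is reported as degenerate rather than raised.
    """
    if sphericity_correction not in (None, "gg"):
        raise ValueError("sphericity_correction must be None or 'gg'")
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("table must be subjects x states")
    n, s = x.shape
    if n < 2 or s < 2:
        raise ValueError("need at least 2 subjects and 2 states")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells; drop incomplete subjects first")
    grand = x.mean()
    ss_state = n * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_subj = s * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_state - ss_subj
    df1, df2 = s - 1, (s - 1) * (n - 1)
    ms_state = ss_state / df1
    ms_err = ss_err / df2
    if ms_err <= 1e-300:
        degenerate = True
        f = 0.0 if ms_state <= 1e-300 else float("inf")
        p = 1.0 if ms_state <= 1e-300 else 0.0
        return AnovaResult(f=f, df1=df1, df2=df2, p=p, degenerate=degenerate)
    f = ms_state / ms_err
    if sphericity_correction == "gg":
        c = np.cov(x.T)  # state covariance across subjects
        cc = c - c.mean(0, keepdims=True) - c.mean(1, keepdims=True) + c.mean()
        eps = np.trace(cc) ** 2 / ((s - 1) * np.sum(cc**2))
        eps = float(np.clip(eps, 1.0 / (s - 1), 1.0))
        p = float(stats.f.sf(f, eps * df1, eps * df2))
    else:
        p = float(stats.f.sf(f, df1, df2))
    return AnovaResult(f=float(f), df1=df1, df2=df2, p=p)


def posthoc_holm(table: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests on all state pairs with Holm step-down adjustment.

    ``table`` is subjects x states (columns are state labels). Returns a
    frame with (state_a, state_b, t, df, p_raw, p_holm).
    """
    x = table.to_numpy(dtype=float)
    states = list(table.columns)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects for paired t-tests")
    rows = []
    for a in range(len(states)):
        for b in range(a + 1, len(states)):
            d = x[:, a] - x[:, b]
            if np.allclose(d, d[0]) and np.allclose(d[0], 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(x[:, a], x[:, b])
            rows.append(dict(state_a=states[a], state_b=states[b],
                             t=float(t), df=n - 1, p_raw=float(p)))
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p_raw"].values, method="holm")[1]
    return df


def group_correlation_table(
    matrices_by_session: dict[str, dict[str, np.ndarray]],
    ic_groups: list[str],
    group: str,
    subject_of: dict[str, str],
) -> pd.DataFrame:
    """Subject x state table of mean within-group Fisher z (sessions averaged).

    Values are z-bar; ``np.tanh`` of the table gives the display-scale
    correlation.
    """
    rows = []
    for sid, mats in matrices_by_session.items():
        for state, mat in mats.items():
            rows.append(dict(subject=subject_of[sid], state=state,
                             z=fisher_group_mean(mat, ic_groups, group)))
    tidy = pd.DataFrame(rows)
    return tidy.pivot_table(index="subject", columns="state", values="z", sort=False)
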