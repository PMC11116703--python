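"""End-to-end orchestration: simulate -> preprocess -> group ICA -> annotate
-> activations -> statistics.

`analyze_sessions` is the in-memory core used by tests, the acceptance
script and the CLI alike; `run_pipeline` adds on-disk stage outputs,
per-stage manifests (config hash + seeds) and skip-if-unchanged caching.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .activations import (
    ActivationRecord,
    ExpectedNull,
    expected_null,
    make_activation_record,
    occurrence_by_group,
    prominent_components,
    subject_occurrence,
)
from .annotate import ComponentLabel, flag_artifacts
from .atlas import MACRO_GROUPS, SyntheticAtlas, make_atlas
from .cooccurrence import (
    group_correlation_table,
    posthoc_holm,
    rm_anova,
    state_matrices,
)
from .gica import GicaFit, GroupDataset, fit_group_ica, select_order
from .preprocess import DffMovie, RawMovie, common_mask
from .states import STATES
from .synthetic import SimulationConfig, simulate_study


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    k: int | None = 8
    candidate_ks: list[int] | None = None
    icasso_runs: int = 10
    icasso_mode: str = "both"
    downsample_factor: int = 1
    highpass_cutoff: float = 0.1
    threshold_sd: float = 3.0
    n_sim: int = 10_000
    n_per_state: int = 5_000
    midline_frac_threshold: float = 0.5
    elongation_threshold: float = 4.0
    manual_exclude: tuple[int, ...] = ()
    simulate: dict = field(default_factory=dict)

    _ALLOWED_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}

    def __post_init__(self) -> None:
        if self.k is None and not self.candidate_ks:
            raise ValueError("config must set 'k' or 'candidate_ks'")
        if self.icasso_mode not in ("randinit", "bootstrap", "both"):
            raise ValueError(f"invalid icasso_mode {self.icasso_mode!r}")
        bad = set(self.simulate) - self._ALLOWED_SIM_KEYS
        if bad:
            raise ValueError(f"unknown simulate field(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config field(s): {sorted(bad)}")
        return cls(**raw)

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(**self.simulate)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class StudyResult:
    """Everything the downstream statistics and reports are built from."""

    atlas: SyntheticAtlas
    mask: np.ndarray
    sessions: list[DffMovie]
    fit: GicaFit
    labels: list[ComponentLabel]
    records: list[ActivationRecord]  # retained ICs only, in retained order
    retained_ids: list[int]
    retained_groups: list[str]
    occurrence: pd.DataFrame
    null: ExpectedNull
    prominent: dict[str, np.ndarray]
    matrices: dict[str, dict[str, np.ndarray]]  # session -> state -> K_ret x K_ret
    group_tables: dict[str, pd.DataFrame]  # macro group -> subject x state z-bar
    anova: dict[str, object]
    posthoc: dict[str, pd.DataFrame]
    occurrence_anova: dict[str, object]
    occurrence_posthoc: dict[str, pd.DataFrame]


def preprocess_study(
    raws: list[RawMovie],
    atlas: SyntheticAtlas,
    config: RunConfig,
    free_frames: bool = False,
) -> tuple[list[DffMovie], np.ndarray]:
    """Register all sessions to the atlas landmarks, build the common mask,
    and normalize/filter each session.

    Sessions are processed one at a time; with ``free_frames`` the raw
    frame stacks are released as soon as a session has been normalized,
    which keeps the peak footprint near a single session's working set.
    """
    import dataclasses as _dc

    from .preprocess import compute_dff, downsample, highpass, register

    # first pass: only the warped valid regions (cheap, no frame warping)
    valids = []
    for m in raws:
        probe = _dc.replace(m)
        probe.frames = np.empty((0,) + m.frames.shape[1:], np.float32)
        probe.segments = None
        probe = register(downsample(probe, config.downsample_factor),
                         atlas.bregma, atlas.lambda_)
        if probe.valid is not None:
            valids.append(probe.valid)
    mask = common_mask(valids or [np.ones(atlas.shape, bool)], base=atlas.mask)

    sessions: list[DffMovie] = []
    for m in raws:
        reg = register(downsample(m, config.downsample_factor), atlas.bregma, atlas.lambda_)
        if free_frames:
            m.frames = np.empty((0,) + m.frames.shape[1:], np.float32)
        sessions.append(highpass(compute_dff(reg, mask), cutoff=config.highpass_cutoff))
        del reg
    return sessions, mask


def analyze_sessions(
    sessions: list[DffMovie],
    atlas: SyntheticAtlas,
    mask: np.ndarray,
    config: RunConfig,
    subject_of: dict[str, str] | None = None,
) -> StudyResult:
    """Group ICA + annotation + occurrence and co-occurrence statistics."""
    dataset = GroupDataset(sessions)
    k = config.k
    if k is None:
        sel = select_order(dataset, config.candidate_ks, n_runs=config.icasso_runs,
                           mode=config.icasso_mode, seed=config.seed)
        k = sel.best_k
    fit = fit_group_ica(dataset, k, n_runs=config.icasso_runs,
                        mode=config.icasso_mode, seed=config.seed)

    labels = flag_artifacts(
        fit.components.maps, mask, atlas,
        midline_frac_threshold=config.midline_frac_threshold,
        elongation_threshold=config.elongation_threshold,
        manual_exclude=config.manual_exclude,
    )
    retained = [lab.ic_id for lab in labels if lab.retained]
    retained_groups = [lab.macro_group for lab in labels if lab.retained]
    if not retained:
        raise RuntimeError("every component was flagged as artifact")

    if subject_of is None:
        subject_of = {s.session_id: s.subject_id for s in sessions}

    records = []
    for s in sessions:
        tc = fit.back.timecourses[s.session_id][retained]
        records.append(
            make_activation_record(
                s.session_id, subject_of.get(s.session_id, s.subject_id),
                tc, s.segments, n_sd=config.threshold_sd,
            )
        )

    retained_labels = [
        ComponentLabel(ic_id=i, peak_pixel=lab.peak_pixel, macro_group=lab.macro_group,
                       retained=True)
        for i, lab in enumerate(l for l in labels if l.retained)
    ]
    occurrence = occurrence_by_group(retained_labels, records)
    null = expected_null(records, n_sim=config.n_sim,
                         n_per_state=config.n_per_state, seed=config.seed)
    prominent = {}
    for state in STATES:
        try:
            props = subject_occurrence(records, state)
            prominent[state] = prominent_components(props.fillna(0.0), null)
        except (KeyError, ValueError):
            prominent[state] = np.array([], dtype=int)

    matrices = {rec.session_id: state_matrices(rec.binary, rec.segments) for rec in records}

    group_tables: dict[str, pd.DataFrame] = {}
    anova: dict[str, object] = {}
    posthoc: dict[str, pd.DataFrame] = {}
    for grp in MACRO_GROUPS:
        if grp == "Midline" or retained_groups.count(grp) < 2:
            continue
        table = group_correlation_table(matrices, retained_groups, grp, subject_of)
        table = table.dropna(axis=0, how="any")
        group_tables[grp] = table
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            anova[grp] = rm_anova(table)
            posthoc[grp] = posthoc_holm(table)

    occurrence_anova: dict[str, object] = {}
    occurrence_posthoc: dict[str, pd.DataFrame] = {}
    for grp in sorted(set(retained_groups)):
        table = occurrence.pivot_table(index="subject", columns="state", values="rel",
                                       sort=False).reindex(columns=[s for s in STATES])
        sub = occurrence[occurrence["group"] == grp]
        table = sub.pivot_table(index="subject", columns="state", values="rel", sort=False)
        table = table.reindex(columns=[s for s in STATES if s in table.columns]).dropna(axis=0)
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            occurrence_anova[grp] = rm_anova(table)
            occurrence_posthoc[grp] = posthoc_holm(table)

    return StudyResult(
        atlas=atlas, mask=mask, sessions=sessions, fit=fit, labels=labels,
        records=records, retained_ids=retained, retained_groups=retained_groups,
        occurrence=occurrence, null=null, prominent=prominent, matrices=matrices,
        group_tables=group_tables, anova=anova, posthoc=posthoc,
        occurrence_anova=occurrence_anova, occurrence_posthoc=occurrence_posthoc,
    )


def run_study(config: RunConfig) -> tuple[StudyResult, object]:
    """Simulate the synthetic study and analyze it in memory.

    Returns ``(result, ground_truth)``.
    """
    raws, truth = simulate_study(config.sim_config(), seed=config.seed)
    sessions, mask = preprocess_study(raws, truth.atlas, config, free_frames=True)
    result = analyze_sessions(sessions, truth.atlas, mask, config,
                              subject_of=truth.subject_of)
    return result, truth


# ---------------------------------------------------------------------------
# on-disk pipeline
# ---------------------------------------------------------------------------

def _manifest(stage: str, config: RunConfig, extra: dict | None = None) -> dict:
    return {
        "stage": stage,
        "config_hash": config.digest(),
        "seed": config.seed,
        "wfgica_version": __version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
        **(extra or {}),
    }


def _stage_current(stage_dir: Path, manifest: dict) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    return json.loads(mf.read_text()) == manifest


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Run every stage, writing outputs and manifests under ``outdir``.

    A stage directory whose manifest matches the current config hash is
    left untouched, so re-running with the same config and seeds
    reproduces (and reuses) all outputs.
    """
    from .io import write_atlas, write_components, write_dff, write_raw_movie

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_dir = outdir / "simulate"
    manifest = _manifest("simulate", config)
    raws, truth = simulate_study(config.sim_config(), seed=config.seed)
    if not _stage_current(sim_dir, manifest):
        sim_dir.mkdir(exist_ok=True)
        write_atlas(truth.atlas, sim_dir / "atlas_labels.tif", sim_dir / "atlas_legend.json")
        for m in raws:
            write_raw_movie(m, sim_dir / f"{m.session_id}.tif")
        (sim_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    pre_dir = outdir / "preprocess"
    manifest = _manifest("preprocess", config)
    sessions, mask = preprocess_study(raws, truth.atlas, config)
    if not _stage_current(pre_dir, manifest):
        pre_dir.mkdir(exist_ok=True)
        for s in sessions:
            write_dff(s, pre_dir / f"{s.session_id}.h5")
        (pre_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    result = analyze_sessions(sessions, truth.atlas, mask, config,
                              subject_of=truth.subject_of)

    gica_dir = outdir / "gica"
    gica_dir.mkdir(exist_ok=True)
    write_components(result.fit.components, result.fit.back, gica_dir / "components.h5")
    if result.fit.icasso is not None:
        pd.DataFrame(
            {"cluster": range(result.fit.components.k),
             "stability": result.fit.icasso.stability}
        ).to_csv(gica_dir / "stability.csv", index=False)
    (gica_dir / "manifest.json").write_text(json.dumps(_manifest("gica", config), indent=1))

    ann_dir = outdir / "annotate"
    ann_dir.mkdir(exist_ok=True)
    pd.DataFrame(
        [dict(ic_id=lab.ic_id, peak_row=lab.peak_pixel[0], peak_col=lab.peak_pixel[1],
              group=lab.macro_group, retained=lab.retained, reason=lab.exclusion_reason)
         for lab in result.labels]
    ).to_csv(ann_dir / "labels.csv", index=False)
    (ann_dir / "manifest.json").write_text(json.dumps(_manifest("annotate", config), indent=1))

    act_dir = outdir / "activations"
    act_dir.mkdir(exist_ok=True)
    result.occurrence.to_csv(act_dir / "occurrence.csv", index=False)
    json.dump(
        {"expected": result.null.expected.tolist(), "n_sim": result.null.n_sim,
         "n_per_state": result.null.n_per_state, "seed": result.null.seed,
         "prominent": {k: v.tolist() for k, v in result.prominent.items()}},
        (act_dir / "expected_null.json").open("w"), indent=1,
    )
    (act_dir / "manifest.json").write_text(json.dumps(_manifest("activations", config), indent=1))

    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)
    anova_rows = []
    for grp, res in {**result.anova}.items():
        anova_rows.append(dict(measure="cooccurrence", group=grp, F=res.f,
                               df1=res.df1, df2=res.df2, p=res.p))
        result.posthoc[grp].assign(group=grp).to_csv(
            stats_dir / f"posthoc_cooccurrence_{grp}.csv", index=False)
    for grp, res in result.occurrence_anova.items():
        anova_rows.append(dict(measure="occurrence", group=grp, F=res.f,
                               df1=res.df1, df2=res.df2, p=res.p))
        result.occurrence_posthoc[grp].assign(group=grp).to_csv(
            stats_dir / f"posthoc_occurrence_{grp}.csv", index=False)
    pd.DataFrame(anova_rows).to_csv(stats_dir / "anova.csv", index=False)
    (stats_dir / "manifest.json").write_text(json.dumps(_manifest("stats", config), indent=1))

    (outdir / "manifest.json").write_text(
        json.dumps(_manifest("all", config, {"stages": ["simulate", "preprocess", "gica",
                                                        "annotate", "activations", "stats"]}),
                   indent=1)
    )
    return outdir
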