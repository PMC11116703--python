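"""Readers and writers for the pipeline's on-disk formats.

Raw session movies travel as multi-page TIFF (or an HDF5 ``movie`` dataset)
with a JSON sidecar holding fps, landmarks and state segments; preprocessed
sessions, component sets and back-reconstructions as HDF5; labels, stability
reports and statistics tables as CSV; the atlas as a TIFF label image plus a
JSON legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .atlas import SyntheticAtlas
from .gica import BackReconstruction, ComponentSet
from .preprocess import DffMovie, RawMovie
from .states import Segment


# --- raw movies -------------------------------------------------------------

def write_raw_movie(movie: RawMovie, path: str | Path, fmt: str = "tiff") -> None:
    path = Path(path)
    if fmt == "tiff":
        tifffile.imwrite(path, movie.frames.astype(np.float32))
    elif fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("movie", data=movie.frames, compression="gzip")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    sidecar = {
        "fps": movie.fps,
        "bregma": list(movie.bregma),
        "lambda": list(movie.lambda_),
        "subject_id": movie.subject_id,
        "session_id": movie.session_id,
        "segments": [[s.state, s.start, s.end] for s in (movie.segments or [])],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_raw_movie(path: str | Path) -> RawMovie:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            frames = f["movie"][...]
    else:
        frames = tifffile.imread(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return RawMovie(
        frames=np.asarray(frames, dtype=np.float32),
        fps=meta["fps"],
        bregma=tuple(meta["bregma"]),
        lambda_=tuple(meta["lambda"]),
        subject_id=meta.get("subject_id", ""),
        session_id=meta.get("session_id", ""),
        segments=[Segment(s, a, b) for s, a, b in meta.get("segments", [])],
    )


# --- dF/F movies ------------------------------------------------------------

def write_dff(dff: DffMovie, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=dff.data, compression="gzip")
        f.create_dataset("mask", data=dff.mask)
        f.create_dataset("f0", data=dff.f0)
        f.attrs["fps"] = dff.fps
        f.attrs["subject_id"] = dff.subject_id
        f.attrs["session_id"] = dff.session_id
        seg = np.array([(s.start, s.end) for s in dff.segments], dtype=np.int64)
        f.create_dataset("segments", data=seg)
        f.attrs["segment_states"] = [s.state for s in dff.segments]


def read_dff(path: str | Path) -> DffMovie:
    with h5py.File(path, "r") as f:
        states = [s if isinstance(s, str) else s.decode() for s in f.attrs["segment_states"]]
        seg = [Segment(st, int(a), int(b)) for st, (a, b) in zip(states, f["segments"][...])]
        return DffMovie(
            data=f["data"][...],
            mask=f["mask"][...].astype(bool),
            fps=float(f.attrs["fps"]),
            segments=seg,
            f0=f["f0"][...],
            subject_id=str(f.attrs["subject_id"]),
            session_id=str(f.attrs["session_id"]),
        )


# --- components -------------------------------------------------------------

def write_components(comps: ComponentSet, back: BackReconstruction | None, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=comps.maps)
        f.create_dataset("raw_maps", data=comps.raw_maps)
        f.create_dataset("mixing", data=comps.mixing)
        f.attrs["converged"] = comps.converged
        if back is not None:
            for sid in back.session_ids:
                g = f.create_group(f"sessions/{sid}")
                g.create_dataset("maps", data=back.maps[sid])
                g.create_dataset("timecourses", data=back.timecourses[sid])


def read_components(path: str | Path) -> tuple[ComponentSet, BackReconstruction | None]:
    with h5py.File(path, "r") as f:
        comps = ComponentSet(
            maps=f["maps"][...], raw_maps=f["raw_maps"][...], mixing=f["mixing"][...],
            converged=bool(f.attrs["converged"]),
        )
        back = None
        if "sessions" in f:
            ids = list(f["sessions"].keys())
            back = BackReconstruction(
                session_ids=ids,
                maps={s: f[f"sessions/{s}/maps"][...] for s in ids},
                timecourses={s: f[f"sessions/{s}/timecourses"][...] for s in ids},
            )
    return comps, back


# --- atlas ------------------------------------------------------------------

def write_atlas(atlas: SyntheticAtlas, label_path: str | Path, legend_path: str | Path) -> None:
    tifffile.imwrite(Path(label_path), atlas.labels.astype(np.int32))
    meta = {
        "legend": {str(k): v for k, v in atlas.legend.items()},
        "bregma": list(atlas.bregma),
        "lambda": list(atlas.lambda_),
    }
    Path(legend_path).write_text(json.dumps(meta, indent=1))


def read_atlas(label_path: str | Path, legend_path: str | Path) -> SyntheticAtlas:
    labels = tifffile.imread(Path(label_path))
    meta = json.loads(Path(legend_path).read_text())
    return SyntheticAtlas(
        labels=np.asarray(labels),
        legend={int(k): v for k, v in meta["legend"].items()},
        bregma=tuple(meta["bregma"]),
        lambda_=tuple(meta["lambda"]),
    )
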