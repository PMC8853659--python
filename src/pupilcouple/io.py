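"""HDF5 containers and delimited-text readers.

Dataset layout for one subject::

    /pupil/raw, /pupil/clean        pupil diameter (a.u.), raw contains NaN gaps
    /gaze/x, /gaze/y                gaze coordinates
    /pupil & /gaze attrs: fs
    /neural/data (channels x time), /neural/coords
    /neural attrs: fs
    /meta attrs: ground_truth (JSON), suppression (JSON)

Analysis results are appended under /results/<stage>/... by the pipeline.
"""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .synth import GroundTruth, NeuralSim, PupilSim, SyntheticSubject

__all__ = ["save_subject", "load_subject", "read_pupil_table", "save_results_hdf5"]


def save_subject(path, subject: SyntheticSubject, manifest_path=None) -> None:
    """Write a subject container; the ground-truth manifest also goes to JSON."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("pupil")
        g.create_dataset("raw", data=subject.pupil.pupil_raw)
        g.create_dataset("clean", data=subject.pupil.pupil_clean)
        g.create_dataset("blink_intervals", data=subject.pupil.blink_intervals)
        g.create_dataset("saccade_times", data=subject.pupil.saccade_times)
        g.attrs["fs"] = subject.pupil.fs
        g = fh.create_group("gaze")
        g.create_dataset("x", data=subject.pupil.gaze_x)
        g.create_dataset("y", data=subject.pupil.gaze_y)
        g.attrs["fs"] = subject.pupil.fs
        g = fh.create_group("neural")
        g.create_dataset("data", data=subject.neural.data)
        g.create_dataset("coords", data=subject.neural.coords)
        g.attrs["fs"] = subject.neural.fs
        g.attrs["groups"] = json.dumps(subject.neural.groups)
        g = fh.create_group("meta")
        g.attrs["ground_truth"] = json.dumps(subject.ground_truth.to_dict())
        g.attrs["suppression"] = json.dumps(subject.suppression)
    if manifest_path is not None:
        subject.ground_truth.to_json(manifest_path)


def load_subject(path) -> SyntheticSubject:
    with h5py.File(path, "r") as fh:
        pupil = PupilSim(
            fs=float(fh["pupil"].attrs["fs"]),
            pupil_raw=fh["pupil/raw"][()],
            pupil_clean=fh["pupil/clean"][()],
            gaze_x=fh["gaze/x"][()],
            gaze_y=fh["gaze/y"][()],
            blink_intervals=fh["pupil/blink_intervals"][()].reshape(-1, 2),
            saccade_times=fh["pupil/saccade_times"][()],
        )
        neural = NeuralSim(
            fs=float(fh["neural"].attrs["fs"]),
            data=fh["neural/data"][()],
            coords=fh["neural/coords"][()],
            groups=json.loads(fh["neural"].attrs["groups"]),
        )
        gt = GroundTruth.from_dict(json.loads(fh["meta"].attrs["ground_truth"]))
        sup = json.loads(fh["meta"].attrs["suppression"])
    return SyntheticSubject(ground_truth=gt, pupil=pupil, neural=neural, suppression=sup)


def read_pupil_table(path, fs: float | None = None) -> dict:
    """Read a delimited text table (t, pupil, gaze_x, gaze_y).

    The pupil column may be area or diameter; conversion is the caller's
    choice.  Returns dict with keys t, pupil, gaze_x, gaze_y, fs.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    t = df[cols.get("t", df.columns[0])].to_numpy(float)
    pupil = df[cols.get("pupil", df.columns[1])].to_numpy(float)
    gx = df[cols["gaze_x"]].to_numpy(float) if "gaze_x" in cols else None
    gy = df[cols["gaze_y"]].to_numpy(float) if "gaze_y" in cols else None
    if fs is None:
        dt = np.median(np.diff(t))
        fs = 1.0 / dt
    return {"t": t, "pupil": pupil, "gaze_x": gx, "gaze_y": gy, "fs": float(fs)}


def save_results_hdf5(path, results: dict) -> None:
    """Write a nested dict of arrays/scalars under /results."""

    def write(group, d):
        for key, val in d.items():
            if isinstance(val, dict):
                write(group.create_group(str(key)), val)
            elif val is None:
                continue
            else:
                group.create_dataset(str(key), data=np.asarray(val))

    with h5py.File(path, "a") as fh:
        if "results" in fh:
            del fh["results"]
        write(fh.create_group("results"), results)
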