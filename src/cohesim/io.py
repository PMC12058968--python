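"""Configuration files, trajectory persistence, and run manifests.

Configs are YAML with keys mirroring SimParams plus an ``init`` section;
unknown keys are rejected with their key paths.  Trajectories are stored in
HDF5 (datasets times/pos/images/phi, the full parameter set as attributes)
with an optional extended-XYZ text export for visualization tools.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time

import h5py
import yaml

from .params import SimParams
from .initializers import InitialCondition
from .state import Trajectory

__all__ = [
    "load_config",
    "save_config",
    "write_trajectory",
    "read_trajectory",
    "export_xyz",
    "RunManifest",
]

FORMAT_VERSION = 1

_INIT_KEYS = {"kind", "worm_width", "worm_jitter"}


def load_config(path) -> tuple[SimParams, InitialCondition, dict]:
    """Read a YAML run configuration.

    Returns (SimParams, InitialCondition, analysis options).  Missing keys
    take the model defaults; unknown keys raise with their paths.  An empty
    file yields the default parameter set.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    param_keys = {f.name for f in dataclasses.fields(SimParams)}
    params_d, init_d, analysis = {}, {}, {}
    for key, val in raw.items():
        if key in param_keys:
            params_d[key] = val
        elif key == "init":
            if not isinstance(val, dict):
                raise ValueError("config key 'init' must be a mapping")
            bad = set(val) - _INIT_KEYS
            if bad:
                raise ValueError(f"unknown config keys: {sorted('init.' + b for b in bad)}")
            init_d = val
        elif key == "analysis":
            analysis = dict(val or {})
        else:
            raise ValueError(f"unknown config keys: ['{key}']")
    try:
        params = SimParams(**params_d)
    except ValueError as err:
        raise ValueError(f"invalid config: {err}") from err
    return params, InitialCondition(**init_d), analysis


def save_config(path, params: SimParams, init: InitialCondition | None = None,
                analysis: dict | None = None) -> None:
    doc = params.to_dict()
    if init is not None:
        doc["init"] = {"kind": init.kind, "worm_width": init.worm_width,
                       "worm_jitter": init.worm_jitter}
    if analysis:
        doc["analysis"] = analysis
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


@dataclasses.dataclass
class RunManifest:
    """Provenance of one output file: config hash, seed, version, timestamp."""

    config_hash: str
    seed: int
    code_version: str
    created: str
    outputs: list

    @classmethod
    def for_params(cls, params: SimParams, outputs=()) -> "RunManifest":
        from . import __version__

        blob = json.dumps(params.to_dict(), sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seed=params.seed,
            code_version=__version__,
            created=time.strftime("%Y-%m-%dT%H:%M:%S"),
            outputs=list(outputs),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))


def write_trajectory(path, traj: Trajectory) -> None:
    """Lossless HDF5 dump of a trajectory with its parameters and manifest."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format_version"] = FORMAT_VERSION
        fh.attrs["params"] = json.dumps(traj.params.to_dict())
        fh.attrs["manifest"] = RunManifest.for_params(
            traj.params, [str(path)]).to_json()
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("pos", data=traj.pos)
        fh.create_dataset("images", data=traj.images)
        fh.create_dataset("phi", data=traj.phi)


def read_trajectory(path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    Corrupt or version-mismatched files are rejected explicitly.
    """
    try:
        fh = h5py.File(path, "r")
    except OSError as err:
        raise IOError(f"cannot read trajectory file {path}: {err}") from err
    with fh:
        version = fh.attrs.get("format_version")
        if version != FORMAT_VERSION:
            raise IOError(
                f"trajectory format version {version!r} unsupported "
                f"(expected {FORMAT_VERSION})")
        missing = {"times", "pos", "images", "phi"} - set(fh.keys())
        if missing:
            raise IOError(f"trajectory file missing datasets: {sorted(missing)}")
        params = SimParams.from_dict(json.loads(fh.attrs["params"]))
        return Trajectory(fh["times"][:], fh["pos"][:], fh["images"][:],
                          fh["phi"][:], params)


def export_xyz(path, traj: Trajectory) -> None:
    """Extended-XYZ text export (columns x y z=0 phi), one block per frame."""
    L = traj.params.L
    with open(path, "w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.N}\n")
            fh.write(f'Lattice="{L} 0 0 0 {L} 0 0 0 1" '
                     f'Properties=pos:R:3:phi:R:1 Time={traj.times[k]}\n')
            for x, y, phi in zip(traj.pos[k, :, 0], traj.pos[k, :, 1], traj.phi[k]):
                fh.write(f"{x:.8f} {y:.8f} 0.0 {phi:.8f}\n")
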