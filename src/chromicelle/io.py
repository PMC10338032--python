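"""Trajectory and configuration I/O, run manifests.

Two plain-text trajectory formats:

* extended XYZ — per frame: a bead count line, a comment line with
  ``key=value`` metadata (step, n_chain), then ``type x y z`` rows.
* dump style — per frame: a header line
  ``FRAME step=<s> natoms=<N> n_chain=<nc>`` followed by
  ``id type x y z partner`` rows, where ``partner`` is the dynamically
  bonded bead id or -1.  This is the lossless format (XYZ drops bonds).

Configurations are flat JSON documents; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine.config import SimulationConfig, TYPE_LABELS, TYPE_NAMES
from .engine.state import Trajectory, TrajectoryFrame


class TrajectoryParseError(ValueError):
    def __init__(self, path, line_no, message):
        super().__init__(f"{path}:{line_no}: {message}")
        self.line_no = line_no


def _frames_of(traj) -> list:
    if isinstance(traj, Trajectory):
        return list(traj)
    if isinstance(traj, TrajectoryFrame):
        return [traj]
    return list(traj)


def write_trajectory(traj, path: str | Path, fmt: str = "dump") -> None:
    """Write frames as extended XYZ (``fmt="xyz"``) or dump style."""
    frames = _frames_of(traj)
    if fmt == "xyz":
        text = _to_xyz(frames)
    elif fmt == "dump":
        text = _to_dump(frames)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r}")
    Path(path).write_text(text)


def read_trajectory(path: str | Path, fmt: str | None = None) -> Trajectory:
    """Read a trajectory; the format is sniffed unless given."""
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().split("\n", 1)[0] if text.strip() else ""
    if fmt is None:
        fmt = "dump" if first.startswith("FRAME") else "xyz"
    frames = (
        _from_dump(text, path) if fmt == "dump" else _from_xyz(text, path)
    )
    if not frames:
        raise TrajectoryParseError(path, 1, "no frames in file")
    n_chain = frames[0][3]
    return Trajectory(
        steps=np.array([f[0] for f in frames], dtype=np.int64),
        positions=np.stack([f[1] for f in frames]),
        types=frames[0][2],
        partners=np.stack([f[4] for f in frames]),
        n_chain=n_chain,
    )


def _to_xyz(frames) -> str:
    out = []
    for fr in frames:
        n = len(fr.positions)
        n_chain = int(np.count_nonzero(fr.types != TYPE_NAMES["P"]))
        out.append(f"{n}\n")
        out.append(f"step={fr.step} n_chain={n_chain}\n")
        for t, p in zip(fr.types, fr.positions):
            out.append(
                f"{TYPE_LABELS[int(t)]} {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n"
            )
    return "".join(out)


def _from_xyz(text: str, path) -> list:
    lines = text.splitlines()
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        try:
            n = int(lines[k].strip())
        except ValueError:
            raise TrajectoryParseError(path, k + 1, "expected bead count")
        if k + 2 + n > len(lines):
            raise TrajectoryParseError(path, k + 1, "truncated frame")
        meta = dict(
            kv.split("=", 1) for kv in lines[k + 1].split() if "=" in kv
        )
        step = int(meta.get("step", 0))
        types = np.empty(n, np.int8)
        pos = np.empty((n, 3))
        for i in range(n):
            parts = lines[k + 2 + i].split()
            if len(parts) != 4:
                raise TrajectoryParseError(
                    path, k + 3 + i, f"expected 'type x y z', got {lines[k+2+i]!r}"
                )
            if parts[0] not in TYPE_NAMES:
                raise TrajectoryParseError(
                    path, k + 3 + i, f"unknown bead type {parts[0]!r}"
                )
            types[i] = TYPE_NAMES[parts[0]]
            pos[i] = [float(v) for v in parts[1:]]
        n_chain = int(meta.get("n_chain", np.count_nonzero(types != 2)))
        frames.append(
            (step, pos, types, n_chain, np.full(n, -1, np.int32))
        )
        k += 2 + n
    return frames


def _to_dump(frames) -> str:
    out = []
    for fr in frames:
        n = len(fr.positions)
        n_chain = int(np.count_nonzero(fr.types != TYPE_NAMES["P"]))
        out.append(f"FRAME step={fr.step} natoms={n} n_chain={n_chain}\n")
        for i, (t, p) in enumerate(zip(fr.types, fr.positions)):
            out.append(
                f"{i} {TYPE_LABELS[int(t)]} "
                f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g} {int(fr.partner[i])}\n"
            )
    return "".join(out)


def _from_dump(text: str, path) -> list:
    lines = text.splitlines()
    frames = []
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        if not lines[k].startswith("FRAME"):
            raise TrajectoryParseError(path, k + 1, "expected FRAME header")
        meta = dict(kv.split("=", 1) for kv in lines[k].split()[1:])
        try:
            n = int(meta["natoms"])
            step = int(meta["step"])
            n_chain = int(meta["n_chain"])
        except (KeyError, ValueError):
            raise TrajectoryParseError(path, k + 1, "bad FRAME header")
        if k + 1 + n > len(lines):
            raise TrajectoryParseError(path, k + 1, "truncated frame")
        types = np.empty(n, np.int8)
        pos = np.empty((n, 3))
        partner = np.empty(n, np.int32)
        for i in range(n):
            parts = lines[k + 1 + i].split()
            if len(parts) != 6:
                raise TrajectoryParseError(
                    path, k + 2 + i, "expected 'id type x y z partner'"
                )
            idx = int(parts[0])
            if idx != i:
                raise TrajectoryParseError(path, k + 2 + i, "ids out of order")
            if parts[1] not in TYPE_NAMES:
                raise TrajectoryParseError(
                    path, k + 2 + i, f"unknown bead type {parts[1]!r}"
                )
            types[i] = TYPE_NAMES[parts[1]]
            pos[i] = [float(v) for v in parts[2:5]]
            partner[i] = int(parts[5])
        frames.append((step, pos, types, n_chain, partner))
        k += 1 + n
    return frames


# ---------------------------------------------------------------------------
# configuration files


def save_config(config: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(config.to_dict(), indent=2))


def load_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_dict(json.loads(Path(path).read_text()))


def load_meanfield_config(path: str | Path):
    from .meanfield import MeanFieldParams

    doc = json.loads(Path(path).read_text())
    known = set(MeanFieldParams.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown mean-field config keys: {sorted(unknown)}")
    return MeanFieldParams(**doc)


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Inventory of a run: config snapshot, seed, code version, outputs."""

    config: dict
    seed: int
    start_step: int
    end_step: int
    files: dict = field(default_factory=dict)  # name -> sha256
    code_version: str = ""
    platform: str = ""

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2))


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_file_manifest(out_path: str | Path, **metadata) -> None:
    """Sidecar manifest for a command that writes a single file."""
    from . import __version__

    out_path = Path(out_path)
    doc = {
        "code_version": __version__,
        "platform": platform.platform(),
        "files": {out_path.name: sha256_of(out_path)},
        **metadata,
    }
    Path(str(out_path) + ".manifest.json").write_text(json.dumps(doc, indent=2))


def write_manifest(
    out_dir: str | Path,
    config,
    seed: int,
    start_step: int = 0,
    end_step: int = 0,
) -> RunManifest:
    from . import __version__

    out_dir = Path(out_dir)
    files = {
        p.name: sha256_of(p)
        for p in sorted(out_dir.iterdir())
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config=config.to_dict() if hasattr(config, "to_dict") else dict(config),
        seed=seed,
        start_step=start_step,
        end_step=end_step,
        files=files,
        code_version=__version__,
        platform=platform.platform(),
    )
    manifest.save(out_dir / "manifest.json")
    return manifest
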