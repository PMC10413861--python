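"""Trajectory container and plain-text XYZ input/output."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory", "write_xyz", "read_xyz"]


@dataclass
class Trajectory:
    """Saved frames of a BD run.

    frames : (F, N, 3) positions in Å; frame 0 is the initial conformation
    times_ps : (F,) simulation time of each frame
    labels : per-bead identifiers
    metadata : provenance (seed, tensor kind, intervals, ...)
    """

    frames: np.ndarray
    times_ps: np.ndarray
    labels: list[str] | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]

    def __getitem__(self, idx) -> np.ndarray:
        return self.frames[idx]

    def slice(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(
            frames=self.frames[start:stop],
            times_ps=self.times_ps[start:stop],
            labels=self.labels,
            metadata=dict(self.metadata),
        )

    def save_xyz(self, path) -> None:
        write_xyz(path, self.frames, self.times_ps, self.labels)


def write_xyz(path, frames: np.ndarray, times_ps=None, labels=None) -> None:
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if labels is None:
        labels = [f"B{i}" for i in range(n)]
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            t = times_ps[f] if times_ps is not None else f
            fh.write(f"{n}\n")
            fh.write(f"frame {f} time_ps {t}\n")
            for lab, (x, y, z) in zip(labels, frame):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> Trajectory:
    frames: list[np.ndarray] = []
    times: list[float] = []
    labels: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    pos = 0
    while pos < len(lines) and lines[pos].strip():
        n = int(lines[pos].strip())
        comment = lines[pos + 1].split()
        t = float(comment[comment.index("time_ps") + 1]) if "time_ps" in comment else float(len(frames))
        block = lines[pos + 2 : pos + 2 + n]
        labs = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        if labels is None:
            labels = labs
        frames.append(coords)
        times.append(t)
        pos += 2 + n
    return Trajectory(
        frames=np.asarray(frames), times_ps=np.asarray(times), labels=labels
    )
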