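"""Experiment protocols and observed rate-of-exocytosis datasets.

A :class:`Protocol` specifies one whole-cell patch-clamp experiment: the
pipette filling solution (cAMP in mM, free Ca2+ in uM, ATP in mM), the
extracellular adrenergic stimulus (epinephrine or the beta3-agonist
CL 316243, both in uM), the recording duration in minutes, and an
optional fractional knockdown of the receptor complement.

A :class:`Dataset` couples protocols with sparse observed time courses
(mean +/- SEM of the capacitance rate, fF/s, from n replicate cells).
Datasets are stored as a small CSV dialect with protocols in sidecar
JSON files, one per condition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Protocol",
    "Observation",
    "Dataset",
    "DatasetError",
    "read_dataset",
    "write_dataset",
    "builtin_protocols",
    "get_protocol",
]

CSV_COLUMNS = ["condition_id", "time_min", "mean_fF_per_s", "sem", "n"]


class DatasetError(ValueError):
    """Raised for malformed dataset files or invalid observations."""


@dataclass(frozen=True)
class Protocol:
    """One experimental condition: pipette contents and external stimulus."""

    id: str
    pip: int = 1                 # binary: pipette attached
    pipette_cAMP: float = 0.0    # mM
    pipette_Ca: float = 0.0      # uM, free
    pipette_ATP: float = 0.0     # mM
    EPI: float = 0.0             # uM
    CL: float = 0.0              # uM
    duration: float = 12.0       # minutes
    knockdown_fraction: float = 0.0
    assumed: bool = False        # concentration not stated explicitly in the source

    def __post_init__(self) -> None:
        if self.pip not in (0, 1):
            raise ValueError(f"pip must be 0 or 1, got {self.pip!r}")
        for name in ("pipette_cAMP", "pipette_Ca", "pipette_ATP", "EPI", "CL"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 <= self.knockdown_fraction <= 1.0:
            raise ValueError("knockdown_fraction must lie in [0, 1]")

    @property
    def has_ec_stimulus(self) -> bool:
        return self.EPI > 0 or self.CL > 0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "Protocol":
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "Protocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class Observation:
    """One measured time point of one condition."""

    condition_id: str
    time: float      # minutes
    mean: float      # fF/s
    sem: float       # fF/s
    n: int           # replicate cells

    def __post_init__(self) -> None:
        if self.sem <= 0:
            raise ValueError(f"sem must be strictly positive, got {self.sem!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n!r}")


@dataclass
class Dataset:
    """Observed time courses for a set of conditions.

    ``role`` tags whether the data are used for estimation or held out
    for validation; the cost function only pools estimation datasets.
    """

    protocols: dict[str, Protocol]
    observations: list[Observation] = field(default_factory=list)
    role: str = "estimation"

    def __post_init__(self) -> None:
        if self.role not in ("estimation", "validation"):
            raise DatasetError(f"role must be 'estimation' or 'validation', got {self.role!r}")
        self.validate()

    def validate(self) -> None:
        for obs in self.observations:
            proto = self.protocols.get(obs.condition_id)
            if proto is None:
                raise DatasetError(f"no protocol for condition {obs.condition_id!r}")
            if obs.time > proto.duration:
                raise DatasetError(
                    f"observation at t={obs.time} min exceeds duration "
                    f"{proto.duration} min of condition {obs.condition_id!r}"
                )

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def condition_ids(self) -> list[str]:
        return sorted(self.protocols)

    def sorted_observations(self) -> list[Observation]:
        """Canonical ordering: condition id, then time."""
        return sorted(self.observations, key=lambda o: (o.condition_id, o.time))

    def times_for(self, condition_id: str) -> np.ndarray:
        return np.array(sorted(o.time for o in self.observations
                               if o.condition_id == condition_id))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (o.condition_id, o.time, o.mean, o.sem, o.n)
            for o in self.sorted_observations()
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write ``dataset`` as CSV with per-condition protocol JSON sidecars.

    Protocols go to ``<stem>_protocols/<condition_id>.json`` next to the
    CSV.  Output ordering is bit-stable (condition id, then time).
    """
    path = Path(path)
    # %.17g keeps the round trip exact at float64 precision
    dataset.to_frame().to_csv(path, index=False, float_format="%.17g")
    proto_dir = path.parent / f"{path.stem}_protocols"
    proto_dir.mkdir(parents=True, exist_ok=True)
    for cid in dataset.condition_ids:
        dataset.protocols[cid].to_json(proto_dir / f"{cid}.json")


def read_dataset(
    path: str | Path,
    protocols: str | Path | dict[str, Protocol] | None = None,
    role: str = "estimation",
) -> Dataset:
    """Read a dataset CSV plus its protocols.

    ``protocols`` may be a directory of ``<condition_id>.json`` files or
    an in-memory mapping; by default the ``<stem>_protocols`` directory
    written by :func:`write_dataset` is used.  Malformed rows are
    reported with their line number (header = line 1).
    """
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetError(f"{path}: missing columns {missing}")

    if protocols is None:
        protocols = path.parent / f"{path.stem}_protocols"
    if not isinstance(protocols, dict):
        proto_dir = Path(protocols)
        protocols = {}
        for cid in frame["condition_id"].astype(str).unique():
            proto_path = proto_dir / f"{cid}.json"
            if not proto_path.exists():
                raise DatasetError(f"no protocol JSON for condition {cid!r} in {proto_dir}")
            protocols[cid] = Protocol.from_json(proto_path)

    observations = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header occupies line 1
        try:
            observations.append(
                Observation(
                    condition_id=str(row["condition_id"]),
                    time=float(row["time_min"]),
                    mean=float(row["mean_fF_per_s"]),
                    sem=float(row["sem"]),
                    n=int(row["n"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise DatasetError(f"{path}, line {line}: {exc}") from exc
    return Dataset(protocols=dict(protocols), observations=observations, role=role)


def builtin_protocols() -> list[Protocol]:
    """The library of published experimental conditions.

    All have the pipette attached and a 12-min recording window (extend
    ``duration`` to 30 for long reports).  The control condition's
    pipette cAMP concentration is an assumed default of 0.1 mM and is
    flagged as such.
    """
    return [
        Protocol(id="EPI5_ATP3", EPI=5.0, pipette_ATP=3.0),
        Protocol(id="CL1_ATP3", CL=1.0, pipette_ATP=3.0),
        Protocol(id="CL1_ATP3_Ca1.5", CL=1.0, pipette_ATP=3.0, pipette_Ca=1.5),
        Protocol(id="CTRL_cAMP_ATP", pipette_cAMP=0.1, pipette_ATP=3.0, assumed=True),
    ]


def get_protocol(condition_id: str, duration: float | None = None) -> Protocol:
    """Look up a built-in protocol by id, optionally with a new duration."""
    for proto in builtin_protocols():
        if proto.id == condition_id:
            if duration is not None:
                return Protocol(**{**proto.to_dict(), "duration": duration})
            return proto
    raise KeyError(f"unknown built-in protocol {condition_id!r}")
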