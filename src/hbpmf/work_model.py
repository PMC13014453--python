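"""Domain types for pulling experiments and work-trace file IO.

Units are fixed throughout the package: distances in Å, times in ps, energies
and work in kcal/mol, temperatures in K.  There is no unit-conversion layer.

The native on-disk format is a TSV with one commented header block per
replicate::

    # interaction_id: CRBN_N351-SALL4_S413
    # condition: ternary
    # replicate: 0
    # seed: 12345
    time_ps	target_A	cv_A	work_kcal_mol
    0.0	2.5	2.61	0.0
    ...

A second dialect, ``smd_columns``, accepts whitespace-separated columns named
in the header (``time``, ``target``, ``cv``, ``work``, in any order) to ease
ingestion of steered-MD outputs from other tools.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PullingProtocol",
    "WorkTrace",
    "ReplicateSet",
    "RuptureRecord",
    "read_work_traces",
    "write_work_traces",
    "ValidationError",
    "ParseError",
]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL_MOL_K = 0.0019872041

DIALECTS = ("native_tsv", "smd_columns")


class ValidationError(ValueError):
    """An invariant of a domain type was violated."""


class ParseError(ValueError):
    """A work-trace file could not be parsed; the message names the line."""


@dataclass(frozen=True)
class PullingProtocol:
    """Three-stage steered pulling schedule for one hydrogen bond.

    Stage 1 holds the bond inside a flat-bottom window
    (``restraint_lo``..``restraint_hi``, force constant ``k_restraint``);
    stage 2 moves the harmonic spring centre to ``pull_start``; stage 3 ramps
    the centre linearly from ``pull_start`` to ``pull_end`` at ``pull_rate``.
    Work is accumulated over the ramp stage only.

    ``com_adjustment`` is the outward shift (0 or 0.5 Å) applied when the
    steered coordinate is a centre-of-mass distance.
    """

    temperature: float = 298.0          # K
    restraint_lo: float = 2.5           # Å
    restraint_hi: float = 3.5           # Å
    k_restraint: float = 60.0           # kcal/mol/Å²
    pull_start: float = 2.5             # Å
    pull_end: float = 5.0               # Å
    pull_rate: float = 0.5              # Å/ns
    k_spring: float = 500.0             # kcal/mol/Å²
    hold_duration: float = 0.1          # ns (stage 1)
    approach_duration: float = 0.05     # ns (stage 2)
    timestep: float = 0.05              # ps
    com_adjustment: float = 0.0         # Å

    def __post_init__(self) -> None:
        if not self.pull_end > self.pull_start:
            raise ValidationError("pull_end must exceed pull_start")
        if self.pull_rate <= 0:
            raise ValidationError("pull_rate must be positive")
        if self.k_spring <= 0:
            raise ValidationError("k_spring must be positive")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.timestep <= 0:
            raise ValidationError("timestep must be positive")
        if self.com_adjustment not in (0.0, 0.5):
            raise ValidationError("com_adjustment must be 0 or 0.5 Å")

    @property
    def ramp_span(self) -> float:
        """Distance in Å swept by the ramp, including any COM adjustment."""
        return (self.pull_end + self.com_adjustment) - self.pull_start

    @property
    def ramp_duration(self) -> float:
        """Duration of the ramp stage in ns (span / rate)."""
        return self.ramp_span / self.pull_rate

    @property
    def duration(self) -> float:
        """Total protocol duration in ns."""
        return self.hold_duration + self.approach_duration + self.ramp_duration

    @property
    def kBT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D array")
    return a


@dataclass(frozen=True)
class WorkTrace:
    """One pulling replicate's ramp-stage time series.

    ``target`` is the moving spring centre λ(t), ``cv_value`` the instantaneous
    reaction coordinate, and ``work`` the accumulated external work W(t) with
    W(0) = 0 at the start of the ramp.
    """

    replicate_id: int
    time: np.ndarray        # ps
    target: np.ndarray      # Å
    cv_value: np.ndarray    # Å
    work: np.ndarray        # kcal/mol
    seed: int = 0

    def __post_init__(self) -> None:
        time = _as_array(self.time, "time")
        target = _as_array(self.target, "target")
        cv = _as_array(self.cv_value, "cv_value")
        work = _as_array(self.work, "work")
        n = len(time)
        if not (len(target) == len(cv) == len(work) == n):
            raise ValidationError("trace arrays must have equal length")
        if n < 2:
            raise ValidationError("trace must have at least 2 samples")
        for name, a in (("time", time), ("target", target),
                        ("cv_value", cv), ("work", work)):
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"{name} contains non-finite values")
            object.__setattr__(self, name if name != "cv_value" else "cv_value", a)
        if abs(work[0]) > 1e-9:
            raise ValidationError(f"work[0] must be 0, got {work[0]!r}")
        if np.any(np.diff(target) < -1e-9):
            raise ValidationError("target must be nondecreasing during pulling")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class ReplicateSet:
    """All pulling replicates for one interaction under one condition."""

    interaction_id: str
    condition: str
    traces: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "traces", tuple(self.traces))
        if len(self.traces) == 0:
            raise ValidationError("ReplicateSet requires at least one trace")
        for t in self.traces:
            if not isinstance(t, WorkTrace):
                raise ValidationError("traces must be WorkTrace instances")

    @property
    def n_replicates(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class RuptureRecord:
    """Rupture work of one replicate: the maximum work after the work minimum."""

    replicate_id: int
    rupture_work: float      # kcal/mol
    rupture_distance: float  # Å (cv value at the rupture maximum)
    rupture_time: float      # ps


# ---------------------------------------------------------------------------
# File IO

_NATIVE_COLUMNS = ("time_ps", "target_A", "cv_A", "work_kcal_mol")
_SMD_COLUMN_MAP = {"time": "time", "target": "target", "cv": "cv", "work": "work"}


def write_work_traces(rset: ReplicateSet, path) -> Path:
    """Write a ReplicateSet in the native TSV dialect.

    The inverse of :func:`read_work_traces`; round-trips all numeric fields to
    better than 1e-9 (values are written with 17 significant digits).
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"# interaction_id: {rset.interaction_id}\n")
    buf.write(f"# condition: {rset.condition}\n")
    for trace in rset.traces:
        buf.write(f"# replicate: {trace.replicate_id}\n")
        buf.write(f"# seed: {trace.seed}\n")
        buf.write("\t".join(_NATIVE_COLUMNS) + "\n")
        for row in zip(trace.time, trace.target, trace.cv_value, trace.work):
            buf.write("\t".join(format(v, ".17g") for v in row) + "\n")
    try:
        path.write_text(buf.getvalue(), encoding="utf-8")
    except OSError as exc:
        raise OSError(f"cannot write work traces to {path}: {exc}") from exc
    return path


def _finish_trace(pending: dict, rows: list, line_no: int) -> WorkTrace:
    if not rows:
        raise ParseError(f"line {line_no}: replicate block has no data rows")
    arr = np.asarray(rows, dtype=float)
    try:
        return WorkTrace(
            replicate_id=pending.get("replicate", 0),
            time=arr[:, 0], target=arr[:, 1],
            cv_value=arr[:, 2], work=arr[:, 3],
            seed=pending.get("seed", 0),
        )
    except ValidationError as exc:
        raise ValidationError(
            f"replicate {pending.get('replicate', '?')}: {exc}"
        ) from exc


def read_work_traces(path, dialect: str = "native_tsv") -> ReplicateSet:
    """Read work traces from ``path`` in the given dialect.

    ``native_tsv`` is the package's own format (see module docstring);
    ``smd_columns`` accepts whitespace-separated columns with a header row
    naming ``time``, ``target``, ``cv`` and ``work`` in any order, one
    replicate per ``# replicate`` block (or a single anonymous block).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"{path}: empty work-trace file")

    interaction_id = path.stem
    condition = "unknown"
    traces: list[WorkTrace] = []
    pending: dict = {}
    rows: list = []
    columns: list[int] | None = None
    block_open = False

    def close_block(line_no: int) -> None:
        nonlocal rows, block_open
        if block_open:
            traces.append(_finish_trace(pending, rows, line_no))
            rows = []
            block_open = False

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                key = key.strip().lower()
                value = value.strip()
                if key == "interaction_id":
                    interaction_id = value
                elif key == "condition":
                    condition = value
                elif key == "replicate":
                    close_block(line_no)
                    pending = {"replicate": _parse_int(value, line_no)}
                    block_open = True
                    columns = None
                elif key == "seed":
                    pending["seed"] = _parse_int(value, line_no)
            continue
        fields = line.split("\t") if dialect == "native_tsv" else line.split()
        if _is_header_row(fields):
            columns = _resolve_columns(fields, dialect, line_no)
            if not block_open:
                close_block(line_no)
                pending = {"replicate": len(traces)}
                block_open = True
            continue
        if columns is None:
            if dialect == "native_tsv":
                raise ParseError(f"line {line_no}: data row before column header")
            columns = [0, 1, 2, 3]  # positional fallback: time target cv work
            if not block_open:
                pending = {"replicate": len(traces)}
                block_open = True
        try:
            values = [float(f) for f in fields]
        except ValueError as exc:
            raise ParseError(f"line {line_no}: malformed row {raw!r}") from exc
        if len(values) < len(columns) or max(columns) >= len(values):
            raise ParseError(f"line {line_no}: expected ≥{len(columns)} columns")
        rows.append([values[i] for i in columns])
    close_block(line_no + 1)

    if not traces:
        raise ParseError(f"{path}: no replicate data found")
    return ReplicateSet(interaction_id=interaction_id, condition=condition,
                        traces=traces)


def _parse_int(value: str, line_no: int) -> int:
    try:
        return int(value)
    except ValueError as exc:
        raise ParseError(f"line {line_no}: expected integer, got {value!r}") from exc


def _is_header_row(fields: Sequence[str]) -> bool:
    try:
        float(fields[0])
        return False
    except ValueError:
        return True


def _resolve_columns(fields: Sequence[str], dialect: str, line_no: int) -> list[int]:
    """Map header names to the canonical (time, target, cv, work) order."""
    if dialect == "native_tsv":
        wanted = _NATIVE_COLUMNS
    else:
        wanted = ("time", "target", "cv", "work")
    lowered = [f.strip().lower() for f in fields]
    indices = []
    for name in wanted:
        if name.lower() not in lowered:
            raise ParseError(
                f"line {line_no}: missing column {name!r} in header {fields!r}")
        indices.append(lowered.index(name.lower()))
    return indices
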