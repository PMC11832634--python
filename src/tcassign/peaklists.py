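"""Peak-list, sequence and statistics-table input/output.

Peak lists use the common Sparky text export: whitespace-separated
columns, first column the assignment label, then one chemical-shift
column per dimension (ppm), optionally a trailing height column.
The dimension vocabulary is fixed to the five backbone nuclei
``HN, N, C, CA, CB`` (``C`` is the carbonyl C').
"""

from __future__ import annotations

import logging
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Controlled vocabulary of dimension labels (C denotes the carbonyl C').
DIMENSIONS = ("HN", "N", "C", "CA", "CB")

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


class PeakListError(ValueError):
    """Raised for malformed peak lists, sequences or statistics tables."""


@dataclass(frozen=True)
class AssignmentLabel:
    """Parsed Sparky assignment label, e.g. ``T212N-H`` -> (T, 212, [N, H]).

    Unknown residue type / number are ``None``; atoms are kept verbatim.
    """

    res_type: Optional[str]
    res_num: Optional[int]
    atoms: tuple[str, ...] = ()

    @property
    def is_unknown(self) -> bool:
        return self.res_type is None and self.res_num is None


@dataclass
class Peak:
    """One cross peak: ordered (dimension label, shift/ppm) pairs."""

    positions: tuple[tuple[str, float], ...]
    label: Optional[str] = None
    height: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.positions:
            raise PeakListError("a peak needs at least one dimension")
        dims = [d for d, _ in self.positions]
        if len(set(dims)) != len(dims):
            raise PeakListError(f"duplicate dimension labels in peak: {dims}")
        for d, v in self.positions:
            if d not in DIMENSIONS:
                raise PeakListError(f"unknown dimension label {d!r}")
            if not math.isfinite(v):
                raise PeakListError(f"non-finite shift in dimension {d}")

    @property
    def dims(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.positions)

    def shift(self, dim: str) -> float:
        for d, v in self.positions:
            if d == dim:
                return v
        raise KeyError(dim)

    @property
    def assignment(self) -> AssignmentLabel:
        return parse_assignment_label(self.label) if self.label else AssignmentLabel(None, None)


@dataclass
class PeakList:
    """A peak list from one experiment at one temperature (degC)."""

    peaks: list[Peak]
    experiment: str
    temperature: float
    dims: tuple[str, ...]

    def __post_init__(self) -> None:
        if not math.isfinite(self.temperature):
            raise PeakListError("temperature must be finite")
        self.dims = tuple(self.dims)
        for p in self.peaks:
            if p.dims != self.dims:
                raise PeakListError(
                    f"peak dims {p.dims} differ from list dims {self.dims}"
                )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


_LABEL_GROUP = re.compile(r"^([A-Za-z])(\d+)([A-Za-z0-9']*)$")


def parse_assignment_label(label: str) -> AssignmentLabel:
    """Parse a Sparky assignment label into (residue type, number, atoms).

    Handles ``T212N-H``, ``G45N-HN``, ``?-?`` and mixed forms where atom
    groups after ``-`` inherit the residue of the first group.  Parsing is
    total: anything unparseable yields an all-unknown label plus a warning.
    """
    if label is None:
        return AssignmentLabel(None, None)
    text = label.strip()
    if not text:
        return AssignmentLabel(None, None)
    res_type: Optional[str] = None
    res_num: Optional[int] = None
    atoms: list[str] = []
    parseable = True
    for i, part in enumerate(text.split("-")):
        part = part.strip()
        if part in ("?", ""):
            continue
        m = _LABEL_GROUP.match(part)
        if m:
            rt, rn, atom = m.group(1).upper(), int(m.group(2)), m.group(3)
            if res_type is None:
                res_type, res_num = rt, rn
            elif (rt, rn) != (res_type, res_num):
                # cross-residue labels (rare) keep the first residue
                logger.debug("label %r spans residues; keeping first", label)
            if atom:
                atoms.append(atom.upper())
        elif i > 0 and re.fullmatch(r"[A-Za-z][A-Za-z0-9']*", part):
            atoms.append(part.upper())  # bare atom, inherits residue
        else:
            parseable = False
    if not parseable:
        warnings.warn(f"could not fully parse assignment label {label!r}")
        return AssignmentLabel(None, None)
    return AssignmentLabel(res_type, res_num, tuple(atoms))


def read_sparky_list(
    path: Union[str, Path],
    experiment: str,
    temperature: float,
    dims: Sequence[str],
) -> PeakList:
    """Read a Sparky ``.list`` file.

    The first line is skipped when it is a header (starts with
    ``Assignment`` or ``w1``).  A trailing extra numeric column is read as
    the peak height.
    """
    path = Path(path)
    dims = tuple(dims)
    peaks: list[Peak] = []
    lines = path.read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if lineno == 1 and (line.startswith("Assignment") or line.startswith("w1")):
            continue
        fields = line.split()
        if len(fields) < 1 + len(dims):
            raise PeakListError(
                f"{path}:{lineno}: expected {1 + len(dims)} columns "
                f"(assignment + {len(dims)} shifts), got {len(fields)}"
            )
        label = fields[0]
        try:
            shifts = [float(x) for x in fields[1 : 1 + len(dims)]]
        except ValueError as exc:
            raise PeakListError(f"{path}:{lineno}: bad shift value ({exc})") from exc
        height = None
        if len(fields) > 1 + len(dims):
            try:
                height = float(fields[1 + len(dims)])
            except ValueError:
                height = None
        peaks.append(
            Peak(tuple(zip(dims, shifts)), label=label, height=height)
        )
    if not peaks:
        warnings.warn(f"{path}: empty peak list")
    return PeakList(peaks, experiment=experiment, temperature=temperature, dims=dims)


def write_sparky_list(plist: PeakList, path: Union[str, Path], precision: int = 3) -> None:
    """Write a peak list in the Sparky text dialect read by read_sparky_list."""
    path = Path(path)
    header = "Assignment " + " ".join(f"w{i + 1}" for i in range(len(plist.dims)))
    rows = [header]
    for p in plist.peaks:
        label = p.label if p.label else "?-?"
        shifts = " ".join(f"{v:10.{precision}f}" for _, v in p.positions)
        rows.append(f"{label:>17s} {shifts}")
    path.write_text("\n".join(rows) + "\n")


def read_fasta(path: Union[str, Path]) -> str:
    """Read a single-record FASTA file; returns the sequence, 1-based.

    Position ``i`` of the returned string is residue ``i`` (1-based) in all
    tcassign interfaces.  Lowercase letters are upcased with a warning;
    letters outside the 20-letter alphabet raise an error naming the
    position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise PeakListError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise PeakListError(f"{path}: expected a single record, found {len(records)}")
    seq = str(records[0].seq)
    if seq != seq.upper():
        warnings.warn(f"{path}: lowercase residues upcased")
        seq = seq.upper()
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACIDS:
            raise PeakListError(f"{path}: illegal residue {ch!r} at position {i}")
    return seq


@dataclass
class TypeStatisticsTable:
    """Per-amino-acid-type feature statistics (mean, sd).

    Feature names come from the controlled vocabulary: the five shift
    features ``HN, N, C, CA, CB`` and temperature-coefficient features
    ``TC<k>_<nucleus>`` for interval ``k`` (1 = first temperature interval).
    Missing (type, feature) cells are absent, never zero.
    """

    stats: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)

    def add(self, res_type: str, feature: str, mean: float, sd: float) -> None:
        if sd <= 0:
            raise PeakListError(f"sd must be > 0 for ({res_type}, {feature}), got {sd}")
        key = (res_type, feature)
        if key in self.stats:
            raise PeakListError(f"duplicate statistics cell ({res_type}, {feature})")
        self.stats[key] = (float(mean), float(sd))

    def has(self, res_type: str, feature: str) -> bool:
        return (res_type, feature) in self.stats

    def get(self, res_type: str, feature: str) -> tuple[float, float]:
        return self.stats[(res_type, feature)]

    @property
    def types(self) -> tuple[str, ...]:
        return tuple(sorted({t for t, _ in self.stats}))

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(sorted({f for _, f in self.stats}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"type": t, "feature": f, "mean": m, "sd": s}
            for (t, f), (m, s) in sorted(self.stats.items())
        ]
        return pd.DataFrame(rows, columns=["type", "feature", "mean", "sd"])

    def write_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def read_statistics_table(path: Union[str, Path]) -> TypeStatisticsTable:
    """Read a ``type,feature,mean,sd`` CSV into a TypeStatisticsTable."""
    df = pd.read_csv(path)
    required = {"type", "feature", "mean", "sd"}
    if not required.issubset(df.columns):
        raise PeakListError(
            f"{path}: statistics table needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    table = TypeStatisticsTable()
    for _, row in df.iterrows():
        table.add(str(row["type"]), str(row["feature"]), float(row["mean"]), float(row["sd"]))
    return table


def read_spin_system_table(path: Union[str, Path]):
    """Load a spin-system CSV (see :mod:`tcassign.spinsys` for the schema)."""
    from . import spinsys

    return spinsys.read_spin_systems(path)
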