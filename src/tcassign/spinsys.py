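"""Spin systems: per-residue shift/TC records and their assembly from peak lists.

A spin system collects the backbone shifts (HN, N, C, CA, CB) and
per-interval temperature coefficients belonging to one residue.  Assembly
groups triple-resonance peaks around HN/N root positions: HNCO supplies
C', HN(CO)CA supplies CA, and the CBCA-type experiment supplies the CA/CB
pair (disambiguated against the HN(CO)CA value when available).

Spin-system CSV schema: ``id,res_type,res_num,HN,N,C,CA,CB,TC1_HN,...,
TC2_CB`` with empty cells meaning missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .peaklists import DIMENSIONS, PeakList, PeakListError

NUCLEI = DIMENSIONS

#: Column order of the spin-system CSV.
CSV_COLUMNS = (
    ["id", "res_type", "res_num"]
    + list(NUCLEI)
    + [f"TC{k}_{n}" for k in (1, 2) for n in NUCLEI]
)

#: Default root-matching tolerances (ppm): roots repeat across experiments
#: with small drifts only.
DEFAULT_TOL = {"HN": 0.02, "N": 0.2}

# CA chemical shifts essentially always fall in this window; values below
# it can only be CB.  Heuristic fallback for CA/CB disambiguation, known
# to mis-order Ser/Thr (whose CB > CA) when no HN(CO)CA reference exists.
CA_RANGE = (40.0, 70.0)


class SpinSystemError(ValueError):
    pass


@dataclass
class SpinSystem:
    """Chemical shifts and temperature coefficients of one residue."""

    id: str
    res_type: Optional[str] = None
    res_num: Optional[int] = None
    shifts: dict[str, float] = field(default_factory=dict)
    tcs: dict[str, float] = field(default_factory=dict)
    source: dict[str, str] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.shifts and not self.tcs:
            raise SpinSystemError(f"spin system {self.id} has no features")
        for n in self.shifts:
            if n not in NUCLEI:
                raise SpinSystemError(f"unknown nucleus {n!r} in {self.id}")

    def feature(self, fid: str) -> Optional[float]:
        """Look up a feature by id: a nucleus name or ``TC<k>_<nucleus>``."""
        if fid in NUCLEI:
            return self.shifts.get(fid)
        return self.tcs.get(fid)

    def features_present(self, fids: Iterable[str]) -> tuple[str, ...]:
        return tuple(f for f in fids if self.feature(f) is not None)


@dataclass
class Chain:
    """An ordered run of unassigned spin systems with boundary flags.

    Boundaries say what terminates the chain on each side: ``proline``
    (the neighbouring residue is a proline, invisible in HN-detected
    spectra), ``break`` (signal loss / overlap) or ``terminus``.
    """

    name: str
    systems: list[SpinSystem]
    left_boundary: str = "break"
    right_boundary: str = "break"

    def __post_init__(self) -> None:
        if not self.systems:
            raise SpinSystemError(f"chain {self.name} is empty")
        for b in (self.left_boundary, self.right_boundary):
            if b not in ("proline", "break", "terminus"):
                raise SpinSystemError(f"bad boundary flag {b!r}")

    def __len__(self) -> int:
        return len(self.systems)


def complete_feature_set(s: SpinSystem, features: Sequence[str]) -> bool:
    """True iff every feature id in ``features`` is present in ``s``."""
    return all(s.feature(f) is not None for f in features)


def _root_distance(peak, root_hn: float, root_n: float, tol: Mapping[str, float]):
    dhn = abs(peak.shift("HN") - root_hn)
    dn = abs(peak.shift("N") - root_n)
    if dhn > tol["HN"] or dn > tol["N"]:
        return None
    return (dhn / tol["HN"]) ** 2 + (dn / tol["N"]) ** 2


# which nucleus the third dimension of each experiment type reports
EXPERIMENT_NUCLEUS = {"HNCO": "C", "HNCOCA": "CA", "CBCACONH": "CACB"}


def _experiment_kind(name: str) -> str:
    flat = name.upper().replace("(", "").replace(")", "").replace("-", "").replace("_", "")
    if "CBCA" in flat or "CACB" in flat:
        return "CBCACONH"
    if "HNCOCA" in flat:
        return "HNCOCA"
    if "HNCO" in flat:
        return "HNCO"
    raise SpinSystemError(f"cannot infer experiment type from name {name!r}")


def assemble(
    root_list: PeakList,
    attached: Sequence[PeakList],
    tol: Optional[Mapping[str, float]] = None,
    ca_tol: float = 0.3,
) -> list[SpinSystem]:
    """Group attached-experiment peaks around HN/N roots into spin systems.

    Each root (HN, N) collects the third-dimension shift of attached peaks
    lying within ``tol`` of the root in both HN and N.  The experiment name
    decides where that shift is stored: C from HNCO, CA from HN(CO)CA; the
    CBCA-type experiment contributes two peaks per root, of which the one
    matching the HN(CO)CA CA value within ``ca_tol`` becomes CA and the
    other CB (single-peak roots, e.g. glycines, get CA only; without an
    HN(CO)CA reference a documented range heuristic is used).  Competing
    candidates are recorded in ``conflicts``; the nearest is kept.
    """
    tol = dict(DEFAULT_TOL if tol is None else tol)
    if "HN" not in root_list.dims or "N" not in root_list.dims:
        raise SpinSystemError("root list must have HN and N dimensions")
    for plist in attached:
        if "HN" not in plist.dims or "N" not in plist.dims:
            raise SpinSystemError(f"attached list {plist.experiment} lacks HN or N")

    systems: list[SpinSystem] = []
    for ridx, root in enumerate(root_list.peaks):
        lab = root.assignment
        sid = root.label if root.label and not lab.is_unknown else f"SS{ridx + 1}"
        s = SpinSystem(
            id=sid,
            res_type=lab.res_type,
            res_num=lab.res_num,
            shifts={"HN": root.shift("HN"), "N": root.shift("N")},
            source={"HN": f"{root_list.experiment}[{ridx}]", "N": f"{root_list.experiment}[{ridx}]"},
        )
        hn, n = root.shift("HN"), root.shift("N")

        cbca_hits: list[tuple[float, float, str]] = []
        for plist in attached:
            kind = _experiment_kind(plist.experiment)
            third = [d for d in plist.dims if d not in ("HN", "N")]
            if len(third) != 1:
                raise SpinSystemError(
                    f"{plist.experiment}: expected exactly one carbon dimension"
                )
            dim = third[0]
            hits = []
            for pidx, peak in enumerate(plist.peaks):
                dist = _root_distance(peak, hn, n, tol)
                if dist is not None:
                    hits.append((dist, peak.shift(dim), f"{plist.experiment}[{pidx}]"))
            hits.sort()
            if kind == "CBCACONH":
                cbca_hits.extend(hits)
                continue
            nucleus = EXPERIMENT_NUCLEUS[kind]
            if not hits:
                continue
            if len(hits) > 1:
                s.conflicts.append(
                    f"{nucleus}: {len(hits)} candidates from {plist.experiment}; kept nearest"
                )
            s.shifts[nucleus] = hits[0][1]
            s.source[nucleus] = hits[0][2]

        _assign_cacb(s, cbca_hits, ca_tol)
        systems.append(s)
    return systems


def _assign_cacb(s: SpinSystem, hits: list[tuple[float, float, str]], ca_tol: float) -> None:
    if not hits:
        return
    if len(hits) > 2:
        s.conflicts.append(f"CA/CB: {len(hits)} CBCA candidates; kept nearest two")
        hits = sorted(hits)[:2]
    ca_ref = s.shifts.get("CA")
    if len(hits) == 1:
        # single CBCA peak: glycine-like root, store as CA
        val, src = hits[0][1], hits[0][2]
        if ca_ref is None or abs(val - ca_ref) <= ca_tol:
            if ca_ref is None:
                s.shifts["CA"] = val
                s.source["CA"] = src
        else:
            s.shifts["CB"] = val
            s.source["CB"] = src
        return
    (d1, v1, src1), (d2, v2, src2) = hits
    if ca_ref is not None:
        if abs(v1 - ca_ref) <= abs(v2 - ca_ref):
            ca, cb = (v1, src1), (v2, src2)
        else:
            ca, cb = (v2, src2), (v1, src1)
        if abs(ca[0] - ca_ref) > ca_tol:
            s.conflicts.append(
                f"CA/CB: neither CBCA peak matches HN(CO)CA CA={ca_ref:.2f} within {ca_tol}"
            )
    else:
        in_range = [v for v in (v1, v2) if CA_RANGE[0] <= v <= CA_RANGE[1]]
        if len(in_range) == 0:
            # both in the CB-only range below the CA window
            cb, ca = (max(v1, v2), src1 if v1 >= v2 else src2), None
            s.conflicts.append("CA/CB: no candidate in CA range; stored larger as CB")
            s.shifts["CB"], s.source["CB"] = cb
            return
        hi = (v1, src1) if v1 >= v2 else (v2, src2)
        lo = (v2, src2) if v1 >= v2 else (v1, src1)
        if len(in_range) == 1:
            ca = hi if CA_RANGE[0] <= hi[0] <= CA_RANGE[1] else lo
            cb = lo if ca is hi else hi
        else:
            ca, cb = hi, lo  # heuristic: larger shift in CA range is CA
    if "CA" not in s.shifts:
        s.shifts["CA"], s.source["CA"] = ca
    s.shifts["CB"], s.source["CB"] = cb


def read_spin_systems(path: Union[str, Path]) -> list[SpinSystem]:
    """Read a spin-system CSV; empty cells mean missing values."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("id",) if c not in df.columns]
    if missing:
        raise PeakListError(f"{path}: spin-system CSV lacks column(s) {missing}")
    systems = []
    for _, row in df.iterrows():
        shifts = {
            n: float(row[n]) for n in NUCLEI if n in df.columns and pd.notna(row[n])
        }
        tcs = {
            c: float(row[c])
            for c in df.columns
            if c.startswith("TC") and pd.notna(row[c])
        }
        rt = row.get("res_type")
        rn = row.get("res_num")
        systems.append(
            SpinSystem(
                id=str(row["id"]),
                res_type=str(rt) if pd.notna(rt) else None,
                res_num=int(rn) if pd.notna(rn) else None,
                shifts=shifts,
                tcs=tcs,
            )
        )
    return systems


def write_spin_systems(
    systems: Sequence[SpinSystem], path: Union[str, Path], header_comment: str = ""
) -> None:
    rows = []
    for s in systems:
        row = {"id": s.id, "res_type": s.res_type, "res_num": s.res_num}
        row.update({n: s.shifts.get(n) for n in NUCLEI})
        row.update({c: s.tcs.get(c) for c in CSV_COLUMNS if c.startswith("TC")})
        rows.append(row)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def chains_to_json(chains: Sequence[Chain]) -> list[dict]:
    return [
        {
            "name": c.name,
            "systems": [s.id for s in c.systems],
            "left_boundary": c.left_boundary,
            "right_boundary": c.right_boundary,
        }
        for c in chains
    ]


def chains_from_json(data: Sequence[Mapping], systems: Sequence[SpinSystem]) -> list[Chain]:
    index = {s.id: s for s in systems}
    chains = []
    for entry in data:
        try:
            members = [index[sid] for sid in entry["systems"]]
        except KeyError as exc:
            raise SpinSystemError(f"chain {entry.get('name')}: unknown spin system {exc}")
        chains.append(
            Chain(
                name=entry["name"],
                systems=members,
                left_boundary=entry.get("left_boundary", "break"),
                right_boundary=entry.get("right_boundary", "break"),
            )
        )
    return chains
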