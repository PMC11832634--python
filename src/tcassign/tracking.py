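"""Peak tracking across temperatures and temperature-coefficient computation.

Because chemical-shift-vs-temperature curves are in general not exactly
linear (and coherent deviations can come from referencing), temperature
coefficients are computed per temperature interval rather than as one
global slope: TC over (T_low, T_high) is the finite-difference slope in
ppb/K.  With spectra at 5, 10 and 15 degC this yields the two interval
coefficients TC(5-10) and TC(10-15) per nucleus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .peaklists import Peak, PeakList

#: Default per-dimension matching gates (ppm): typical IDP peak movement
#: over a 5 degC step, with headroom.
DEFAULT_GATES = {"HN": 0.05, "N": 0.5, "C": 0.5, "CA": 0.5, "CB": 0.5}

# Any admissible pair costs at most n_dims (each term <= 1); this is
# safely larger, so maximum cardinality always beats cost.
_FORBIDDEN = 1e6


class TrackingError(ValueError):
    pass


@dataclass
class PeakMatch:
    """One-to-one correspondence between two peak lists.

    ``pairs`` holds (index in A, index in B); indices absent from any pair
    appear in ``unmatched_a`` / ``unmatched_b``.  ``cost`` is the summed
    gate-normalized squared distance over matched pairs.
    """

    pairs: list[tuple[int, int]]
    unmatched_a: list[int]
    unmatched_b: list[int]
    cost: float

    def to_frame(self, a: PeakList, b: PeakList) -> pd.DataFrame:
        rows = []
        for ia, ib in self.pairs:
            rows.append(
                {
                    "index_a": ia,
                    "index_b": ib,
                    "label_a": a.peaks[ia].label,
                    "label_b": b.peaks[ib].label,
                    **{f"{d}_a": a.peaks[ia].shift(d) for d in a.dims},
                    **{f"{d}_b": b.peaks[ib].shift(d) for d in b.dims},
                }
            )
        return pd.DataFrame(rows)


def pair_cost(pa: Peak, pb: Peak, gates: Mapping[str, float]) -> float:
    """Gate-normalized squared distance; inf if any dimension exceeds its gate."""
    total = 0.0
    for d in pa.dims:
        delta = abs(pa.shift(d) - pb.shift(d))
        g = gates[d]
        if delta > g:
            return np.inf
        total += (delta / g) ** 2
    return total


def _label_key(peak: Peak) -> Optional[tuple[str, int]]:
    lab = peak.assignment
    if lab.res_type is not None and lab.res_num is not None:
        return (lab.res_type, lab.res_num)
    return None


def match_peaks(
    a: PeakList,
    b: PeakList,
    gates: Optional[Mapping[str, float]] = None,
    greedy: bool = False,
    use_labels: bool = True,
) -> PeakMatch:
    """Minimum-total-cost one-to-one matching between two peak lists.

    Pairs whose distance exceeds the gate in any dimension are forbidden;
    among matchings of maximum cardinality the total cost (sum over pairs
    of sum_d (delta_d/gate_d)^2) is minimized via the Hungarian algorithm.
    When both peaks carry assignment labels with the same residue, that
    pair is fixed before distance matching (``use_labels``).  ``greedy``
    switches to order-dependent nearest-neighbour matching (faster, not
    optimal).
    """
    if a.dims != b.dims:
        raise TrackingError(f"dimension mismatch: {a.dims} vs {b.dims}")
    gates = dict(DEFAULT_GATES if gates is None else gates)
    for d in a.dims:
        if d not in gates or gates[d] <= 0:
            raise TrackingError(f"gate for dimension {d} must be positive")

    pairs: list[tuple[int, int]] = []
    cost = 0.0
    free_a = list(range(len(a.peaks)))
    free_b = list(range(len(b.peaks)))

    if use_labels:
        by_key = {}
        for ib in free_b:
            key = _label_key(b.peaks[ib])
            if key is not None and key not in by_key:
                by_key[key] = ib
        taken_b: set[int] = set()
        still_free_a = []
        for ia in free_a:
            key = _label_key(a.peaks[ia])
            ib = by_key.get(key) if key is not None else None
            if ib is not None and ib not in taken_b:
                pairs.append((ia, ib))
                taken_b.add(ib)
                c = pair_cost(a.peaks[ia], b.peaks[ib], gates)
                cost += 0.0 if np.isinf(c) else c
            else:
                still_free_a.append(ia)
        free_a = still_free_a
        free_b = [ib for ib in free_b if ib not in taken_b]

    if free_a and free_b:
        cmat = np.array(
            [[pair_cost(a.peaks[ia], b.peaks[ib], gates) for ib in free_b] for ia in free_a]
        )
        if greedy:
            order = np.argsort(cmat, axis=None)
            used_r: set[int] = set()
            used_c: set[int] = set()
            for flat in order:
                r, c = divmod(int(flat), len(free_b))
                if np.isinf(cmat[r, c]):
                    break
                if r in used_r or c in used_c:
                    continue
                pairs.append((free_a[r], free_b[c]))
                cost += cmat[r, c]
                used_r.add(r)
                used_c.add(c)
        else:
            filled = np.where(np.isinf(cmat), _FORBIDDEN, cmat)
            rows, cols = linear_sum_assignment(filled)
            for r, c in zip(rows, cols):
                if np.isinf(cmat[r, c]):
                    continue
                pairs.append((free_a[r], free_b[c]))
                cost += cmat[r, c]

    matched_a = {ia for ia, _ in pairs}
    matched_b = {ib for _, ib in pairs}
    return PeakMatch(
        pairs=sorted(pairs),
        unmatched_a=[i for i in range(len(a.peaks)) if i not in matched_a],
        unmatched_b=[i for i in range(len(b.peaks)) if i not in matched_b],
        cost=float(cost),
    )


@dataclass(frozen=True)
class TemperatureCoefficient:
    """Finite-difference shift slope over one temperature interval, ppb/K.

    Positive values mean the resonance moves downfield as temperature
    increases (degC differences equal kelvin differences).
    """

    nucleus: str
    interval: tuple[float, float]
    value: float

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not hi > lo:
            raise TrackingError(f"interval must have T_high > T_low, got {self.interval}")
        if not np.isfinite(self.value):
            raise TrackingError("TC value must be finite")


def compute_tc(
    shift_low: float, shift_high: float, t_low: float, t_high: float
) -> float:
    """TC = 1000 * (shift_high - shift_low) / (T_high - T_low), in ppb/K."""
    if t_high == t_low:
        raise TrackingError("temperatures must differ")
    return 1000.0 * (shift_high - shift_low) / (t_high - t_low)


def tc_table(systems_by_temperature: Sequence[tuple[float, Mapping[str, "object"]]]) -> pd.DataFrame:
    """Per-residue, per-nucleus TCs for each consecutive temperature interval.

    ``systems_by_temperature`` is a sequence of (temperature, {id: SpinSystem})
    with the same ids linking systems across temperatures.  A shift missing
    at either end of an interval yields a missing TC (never imputed).

    Returns a DataFrame with columns ``id, nucleus, interval, t_low, t_high,
    tc`` where ``interval`` is 1-based over consecutive temperature pairs.
    """
    entries = sorted(systems_by_temperature, key=lambda e: e[0])
    if len(entries) < 2:
        raise TrackingError("need at least two temperatures")
    temps = [t for t, _ in entries]
    if len(set(temps)) != len(temps):
        raise TrackingError("duplicate temperatures")
    ids = sorted({i for _, sys in entries for i in sys})
    rows = []
    for k in range(len(entries) - 1):
        (t_lo, lo_sys), (t_hi, hi_sys) = entries[k], entries[k + 1]
        for sid in ids:
            s_lo = lo_sys.get(sid)
            s_hi = hi_sys.get(sid)
            for nuc in ("HN", "N", "C", "CA", "CB"):
                lo = s_lo.shifts.get(nuc) if s_lo is not None else None
                hi = s_hi.shifts.get(nuc) if s_hi is not None else None
                tc = compute_tc(lo, hi, t_lo, t_hi) if lo is not None and hi is not None else np.nan
                rows.append(
                    {
                        "id": sid,
                        "nucleus": nuc,
                        "interval": k + 1,
                        "t_low": t_lo,
                        "t_high": t_hi,
                        "tc": tc,
                    }
                )
    return pd.DataFrame(rows)


def attach_tcs(base_systems: Mapping[str, "object"], table: pd.DataFrame) -> None:
    """Store TCs from :func:`tc_table` on the base-temperature spin systems.

    TCs land in ``SpinSystem.tcs`` under feature names ``TC<k>_<nucleus>``.
    A TC is attached only when the nucleus has a shift entry in the base
    system (the interval's low-temperature measurement).
    """
    for _, row in table.dropna(subset=["tc"]).iterrows():
        s = base_systems.get(row["id"])
        if s is None:
            continue
        if row["nucleus"] in s.shifts:
            s.tcs[f"TC{int(row['interval'])}_{row['nucleus']}"] = float(row["tc"])
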