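"""Synthetic proteins with known shifts and temperature coefficients.

Every residue type is modelled as a multivariate Gaussian over the five
backbone nuclei: a per-type mean/sd for each chemical shift (ppm) and for
each per-interval temperature coefficient (ppb/K).  A residue's shift at
temperature T follows the piecewise-linear model

    shift(T_k) = shift(T_0) + sum_j TC_j * (T_j - T_{j-1}) / 1000

over consecutive temperature intervals, so interval slopes computed from
the emitted peak lists recover the drawn coefficients exactly when
measurement noise is zero.  Prolines yield no HN-rooted spin system and
glycines have no CB; optional per-nucleus missingness removes shifts (and
hence the dependent TCs) after generation.

The shipped per-type statistics are a synthetic fixture approximating
random-coil values for a disordered protein; they are a modelling choice
of this package, not literature data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .peaklists import AMINO_ACIDS, Peak, PeakList, TypeStatisticsTable
from .spinsys import NUCLEI, Chain, SpinSystem
from .tracking import compute_tc

#: Synthetic per-type base shifts (ppm), loosely random-coil-like.
SHIFT_MEANS: dict[str, dict[str, float]] = {
    "A": {"HN": 8.25, "N": 123.8, "C": 177.8, "CA": 52.5, "CB": 19.1},
    "C": {"HN": 8.32, "N": 118.8, "C": 174.6, "CA": 58.3, "CB": 28.0},
    "D": {"HN": 8.34, "N": 120.4, "C": 176.3, "CA": 54.2, "CB": 41.1},
    "E": {"HN": 8.42, "N": 120.7, "C": 176.6, "CA": 56.6, "CB": 30.0},
    "F": {"HN": 8.30, "N": 120.3, "C": 175.8, "CA": 57.7, "CB": 39.6},
    "G": {"HN": 8.33, "N": 108.8, "C": 174.9, "CA": 45.1},
    "H": {"HN": 8.42, "N": 118.2, "C": 174.1, "CA": 55.0, "CB": 29.0},
    "I": {"HN": 8.00, "N": 120.4, "C": 176.4, "CA": 61.1, "CB": 38.8},
    "K": {"HN": 8.29, "N": 120.4, "C": 176.6, "CA": 56.2, "CB": 33.1},
    "L": {"HN": 8.16, "N": 121.8, "C": 177.6, "CA": 55.1, "CB": 42.4},
    "M": {"HN": 8.28, "N": 119.6, "C": 176.3, "CA": 55.4, "CB": 32.9},
    "N": {"HN": 8.40, "N": 118.7, "C": 175.2, "CA": 53.1, "CB": 38.9},
    "P": {"N": 136.6, "C": 177.3, "CA": 63.3, "CB": 32.1},
    "Q": {"HN": 8.32, "N": 119.8, "C": 176.0, "CA": 55.7, "CB": 29.4},
    "R": {"HN": 8.27, "N": 121.2, "C": 176.3, "CA": 56.0, "CB": 30.9},
    "S": {"HN": 8.31, "N": 116.6, "C": 174.6, "CA": 58.3, "CB": 63.8},
    "T": {"HN": 8.15, "N": 115.5, "C": 174.7, "CA": 61.9, "CB": 69.8},
    "V": {"HN": 8.03, "N": 120.5, "C": 176.1, "CA": 62.2, "CB": 32.9},
    "W": {"HN": 8.25, "N": 121.3, "C": 176.1, "CA": 57.5, "CB": 29.3},
    "Y": {"HN": 8.12, "N": 120.3, "C": 175.9, "CA": 57.9, "CB": 38.8},
}

#: Within-type shift spread (ppm) in a disordered chain.
SHIFT_SDS = {"HN": 0.10, "N": 0.8, "C": 0.4, "CA": 0.4, "CB": 0.4}

#: Within-type TC spread (ppb/K).
TC_SDS = {"HN": 0.5, "N": 0.8, "C": 0.3, "CA": 0.3, "CB": 0.3}

# per-nucleus TC population mean and between-type spread (ppb/K); amide
# protons dominate (solvent exposure), carbons move little
_TC_BASE = {"HN": -7.0, "N": -3.0, "C": -1.0, "CA": -0.5, "CB": -0.5}
_TC_BETWEEN_SD = {"HN": 1.5, "N": 1.5, "C": 0.5, "CA": 0.5, "CB": 0.5}

# fixed stream for the per-type TC means: the default table is a constant
_TC_OFFSET_SEED = 715517


class SyntheticError(ValueError):
    pass


def default_statistics() -> TypeStatisticsTable:
    """The package's default per-type statistics table (synthetic fixture).

    20 types x 5 shift features (no CB for glycine, no HN for proline)
    plus matching TC1/TC2 rows; the two interval coefficients share means
    by default.  Deterministic: repeated calls give identical tables.
    """
    rng = np.random.default_rng(_TC_OFFSET_SEED)
    table = TypeStatisticsTable()
    types = sorted(SHIFT_MEANS)
    offsets = {
        t: {n: rng.normal(0.0, _TC_BETWEEN_SD[n]) for n in NUCLEI} for t in types
    }
    for t in types:
        for n, mean in SHIFT_MEANS[t].items():
            table.add(t, n, mean, SHIFT_SDS[n])
        for n in SHIFT_MEANS[t]:
            tc_mean = _TC_BASE[n] + offsets[t][n]
            table.add(t, f"TC1_{n}", tc_mean, TC_SDS[n])
            table.add(t, f"TC2_{n}", tc_mean, TC_SDS[n])
    return table


def benchmark_statistics(
    pairs: Sequence[tuple[str, str]] = (("E", "Q"), ("F", "Y")),
    tc_separation_sd: float = 3.0,
) -> TypeStatisticsTable:
    """Statistics with shift-degenerate type pairs separable only by TC.

    For each pair (a, b) the shift rows of ``b`` are overwritten with those
    of ``a`` (identical shift distributions) and the TC means are placed
    symmetrically ``tc_separation_sd`` within-type sds apart.  Setting the
    separation to zero makes the pairs fully interchangeable.
    """
    table = default_statistics()
    for a, b in pairs:
        for n in NUCLEI:
            if table.has(a, n):
                mean, sd = table.get(a, n)
                table.stats[(b, n)] = (mean, sd)
            for k in (1, 2):
                f = f"TC{k}_{n}"
                if table.has(a, f) and table.has(b, f):
                    ma, sda = table.get(a, f)
                    mb, _ = table.get(b, f)
                    base = 0.5 * (ma + mb)
                    half = 0.5 * tc_separation_sd * sda
                    table.stats[(a, f)] = (base - half, sda)
                    table.stats[(b, f)] = (base + half, sda)
    return table


def random_sequence(
    rng: np.random.Generator,
    length: int = 239,
    proline_fraction: float = 26 / 239,
    glycine_fraction: float = 28 / 239,
) -> str:
    """Random disordered-protein-like sequence with fixed P/G content.

    Default fractions mimic a proline- and glycine-rich 239-residue
    construct (26 P, 28 G at the default length).  The remaining positions
    carry a near-balanced multiset of the other 18 types (counts differing
    by at most one), shuffled: a benchmark protein in which every
    classifiable type has enough residues to train on.
    """
    n_proline = round(proline_fraction * length)
    n_glycine = round(glycine_fraction * length)
    if n_proline + n_glycine > length:
        raise SyntheticError("more prolines+glycines than residues")
    others = [t for t in AMINO_ACIDS if t not in ("P", "G")]
    n_rest = length - n_proline - n_glycine
    rest = [others[i % len(others)] for i in range(n_rest)]
    seq = ["P"] * n_proline + ["G"] * n_glycine + rest
    perm = rng.permutation(length)
    return "".join(seq[i] for i in perm)


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic protein.

    ``temperatures`` are the acquisition temperatures (degC, strictly
    increasing; the first is the reference at which spin systems are
    reported).  ``noise`` is per-nucleus measurement noise (ppm, sd) added
    independently at each temperature; the default is zero because the
    per-type sds of the statistics table already absorb realistic
    measurement scatter.  ``missingness`` removes a nucleus's shifts (all
    temperatures) with the given probability.  ``distinct_interval_tcs``
    draws TC2 independently of TC1 (otherwise one slope per nucleus).
    """

    sequence: Optional[str] = None
    length: int = 239
    stats: TypeStatisticsTable = field(default_factory=default_statistics)
    temperatures: tuple[float, ...] = (5.0, 10.0, 15.0)
    noise: Mapping[str, float] = field(default_factory=dict)
    missingness: Mapping[str, float] = field(default_factory=dict)
    distinct_interval_tcs: bool = False
    labeled: bool = True

    def __post_init__(self) -> None:
        temps = tuple(self.temperatures)
        if len(temps) < 2 or any(b <= a for a, b in zip(temps, temps[1:])):
            raise SyntheticError("temperatures must be strictly increasing, >= 2")
        self.temperatures = temps
        for rates in (self.missingness,):
            for n, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise SyntheticError(f"missingness rate for {n} outside [0, 1]")
        for n, s in self.noise.items():
            if s < 0:
                raise SyntheticError(f"negative noise sd for {n}")


@dataclass
class SyntheticProtein:
    """Generated data plus the latent truth table."""

    sequence: str
    config: GeneratorConfig
    systems_by_temperature: dict[float, dict[str, SpinSystem]]
    peaklists: dict[tuple[str, float], PeakList]
    truth: pd.DataFrame

    @property
    def base_systems(self) -> dict[str, SpinSystem]:
        """Spin systems at the reference temperature, TC features attached."""
        return self.systems_by_temperature[self.config.temperatures[0]]


def sample_protein(config: GeneratorConfig, seed: int = 0) -> SyntheticProtein:
    """Draw one synthetic protein; fully reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    seq = config.sequence if config.sequence is not None else random_sequence(rng, config.length)
    for i, t in enumerate(seq, start=1):
        if t not in AMINO_ACIDS:
            raise SyntheticError(f"unknown residue letter {t!r} at position {i}")
    temps = config.temperatures
    n_intervals = len(temps) - 1
    stats = config.stats

    systems: dict[float, dict[str, SpinSystem]] = {T: {} for T in temps}
    truth_rows = []
    for i, t in enumerate(seq, start=1):
        if t == "P":
            continue  # no amide proton: invisible in HN-rooted spectra
        sid = f"{t}{i}"
        nuclei = [n for n in NUCLEI if stats.has(t, n)]
        base = {n: rng.normal(*stats.get(t, n)) for n in nuclei}
        tcs: dict[tuple[str, int], float] = {}
        for n in nuclei:
            first = rng.normal(*stats.get(t, f"TC1_{n}")) if stats.has(t, f"TC1_{n}") else 0.0
            tcs[(n, 1)] = first
            for k in range(2, n_intervals + 1):
                if config.distinct_interval_tcs and stats.has(t, f"TC{k}_{n}"):
                    tcs[(n, k)] = rng.normal(*stats.get(t, f"TC{k}_{n}"))
                else:
                    tcs[(n, k)] = first
        missing = {
            n for n in nuclei if rng.random() < config.missingness.get(n, 0.0)
        }
        shifts_at: dict[float, dict[str, float]] = {}
        for j, T in enumerate(temps):
            vals = {}
            for n in nuclei:
                if n in missing:
                    continue
                v = base[n]
                for k in range(1, j + 1):
                    v += tcs[(n, k)] * (temps[k] - temps[k - 1]) / 1000.0
                sd = config.noise.get(n, 0.0)
                if sd > 0:
                    v += rng.normal(0.0, sd)
                vals[n] = v
            shifts_at[T] = vals

        for T in temps:
            if not shifts_at[T]:
                continue
            systems[T][sid] = SpinSystem(
                id=sid, res_type=t, res_num=i, shifts=dict(shifts_at[T])
            )
        # measured per-interval TCs on the reference-temperature system
        ref = systems[temps[0]].get(sid)
        if ref is not None:
            for k in range(1, n_intervals + 1):
                lo_T, hi_T = temps[k - 1], temps[k]
                for n in nuclei:
                    lo = shifts_at[lo_T].get(n)
                    hi = shifts_at[hi_T].get(n)
                    if lo is not None and hi is not None and n in ref.shifts:
                        ref.tcs[f"TC{k}_{n}"] = compute_tc(lo, hi, lo_T, hi_T)

        row = {"res_num": i, "res_type": t}
        row.update({f"{n}_base": base[n] for n in nuclei})
        for (n, k), v in tcs.items():
            row[f"TC{k}_{n}_true"] = v
        truth_rows.append(row)

    peaklists = _emit_peaklists(systems, temps, labeled=config.labeled)
    truth = pd.DataFrame(truth_rows)
    return SyntheticProtein(
        sequence=seq,
        config=config,
        systems_by_temperature=systems,
        peaklists=peaklists,
        truth=truth,
    )


def _emit_peaklists(
    systems: dict[float, dict[str, SpinSystem]],
    temps: Sequence[float],
    labeled: bool,
) -> dict[tuple[str, float], PeakList]:
    """HSQC at every temperature; HNCO / HN(CO)CA / CBCA-type lists too.

    The CBCA-type list holds two rows per root (the CA and the CB peak) in
    a single carbon dimension; by the package's dimension vocabulary that
    column is labeled CA and interpreted by experiment type on assembly.
    """
    out: dict[tuple[str, float], PeakList] = {}
    for T in temps:
        sys_T = systems[T]
        ids = sorted(sys_T, key=lambda s: int(s[1:]))

        def _mk(exp: str, dims: tuple[str, ...], rows) -> None:
            peaks = []
            for sid, vals, atom in rows:
                s = sys_T[sid]
                label = f"{s.res_type}{s.res_num}N-{atom}" if labeled else "?-?"
                peaks.append(Peak(tuple(zip(dims, vals)), label=label))
            out[(exp, T)] = PeakList(peaks, experiment=exp, temperature=T, dims=dims)

        hsqc = [
            (sid, (sys_T[sid].shifts["N"], sys_T[sid].shifts["HN"]), "HN")
            for sid in ids
            if "N" in sys_T[sid].shifts and "HN" in sys_T[sid].shifts
        ]
        _mk("HSQC", ("N", "HN"), hsqc)
        for exp, nuc in (("HNCO", "C"), ("HNCOCA", "CA")):
            rows = [
                (sid, (sys_T[sid].shifts["HN"], sys_T[sid].shifts["N"], sys_T[sid].shifts[nuc]), nuc)
                for sid in ids
                if {"HN", "N", nuc} <= sys_T[sid].shifts.keys()
            ]
            _mk(exp, ("HN", "N", nuc), rows)
        cbca = []
        for sid in ids:
            sh = sys_T[sid].shifts
            if not {"HN", "N"} <= sh.keys():
                continue
            for nuc in ("CA", "CB"):
                if nuc in sh:
                    cbca.append((sid, (sh["HN"], sh["N"], sh[nuc]), nuc))
        _mk("CBCACONH", ("HN", "N", "CA"), cbca)
    return out


@dataclass
class Benchmark:
    """Labeled training systems, anonymized queries, chains and the truth."""

    train: list[SpinSystem]
    queries: list[SpinSystem]
    chains: list[Chain]
    truth: dict[str, tuple[str, int]]  # query id -> (true type, residue number)
    chain_starts: dict[str, int]       # chain name -> true 1-based start


def _anonymize(s: SpinSystem, new_id: str) -> SpinSystem:
    return SpinSystem(
        id=new_id, res_type=None, res_num=None, shifts=dict(s.shifts), tcs=dict(s.tcs)
    )


def _boundary(sequence: str, pos: int) -> str:
    """Boundary flag for the neighbour at 1-based ``pos`` (0 or L+1 allowed)."""
    if pos < 1 or pos > len(sequence):
        return "terminus"
    return "proline" if sequence[pos - 1] == "P" else "break"


def make_benchmark(
    protein: SyntheticProtein,
    train_fraction: float = 0.65,
    seed: int = 0,
    exclude: Sequence[str] = ("G", "P"),
) -> Benchmark:
    """Split residues into a labeled training set and anonymized queries.

    ``train_fraction`` of the eligible residues (those with a spin system
    and a type outside ``exclude``) are kept labeled; the rest become
    unlabeled queries (ids ``U<res_num>``), grouped into chains: maximal
    runs of consecutive query residues, with boundary flags read off the
    true sequence (proline / terminus / break).  The split is stratified
    by residue type — each type contributes ``round(train_fraction * n_t)``
    training systems — so no type is wiped out of the training pool by an
    unlucky draw.
    """
    if not 0.0 < train_fraction < 1.0:
        raise SyntheticError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    base = protein.base_systems
    eligible = [s for s in base.values() if s.res_type not in exclude]
    if len(eligible) < 2:
        raise SyntheticError("too few eligible residues")
    train, query_src = [], []
    for t in sorted({s.res_type for s in eligible}):
        members = sorted(
            (s for s in eligible if s.res_type == t), key=lambda s: s.res_num
        )
        order = rng.permutation(len(members))
        n_t = round(train_fraction * len(members))
        train += [members[i] for i in order[:n_t]]
        query_src += [members[i] for i in order[n_t:]]
    if not train or not query_src:
        raise SyntheticError("degenerate train/query partition")
    train.sort(key=lambda s: s.res_num)
    query_src.sort(key=lambda s: s.res_num)

    queries = []
    truth = {}
    by_pos = {}
    for s in query_src:
        q = _anonymize(s, f"U{s.res_num}")
        queries.append(q)
        truth[q.id] = (s.res_type, s.res_num)
        by_pos[s.res_num] = q

    chains: list[Chain] = []
    chain_starts: dict[str, int] = {}
    run: list[int] = []
    for pos in sorted(by_pos) + [None]:
        if run and (pos is None or pos != run[-1] + 1):
            name = f"chain_{run[0]}_{run[-1]}"
            chains.append(
                Chain(
                    name=name,
                    systems=[by_pos[p] for p in run],
                    left_boundary=_boundary(protein.sequence, run[0] - 1),
                    right_boundary=_boundary(protein.sequence, run[-1] + 1),
                )
            )
            chain_starts[name] = run[0]
            run = []
        if pos is not None:
            run.append(pos)
    return Benchmark(train=train, queries=queries, chains=chains, truth=truth, chain_starts=chain_starts)


def sample_chains(
    protein: SyntheticProtein,
    n: int = 100,
    length_range: tuple[int, int] = (3, 6),
    seed: int = 0,
    exclude: Sequence[str] = ("G", "P"),
) -> tuple[list[Chain], dict[str, int]]:
    """Draw random contiguous windows of eligible residues as unknown chains.

    Windows avoid excluded types entirely (a glycine- or proline-free run,
    as in HN-detected sequential assignment with G/P dropped from the
    classifier).  Returns the chains and their true 1-based start positions.
    """
    rng = np.random.default_rng(seed)
    base = protein.base_systems
    seq = protein.sequence
    lo, hi = length_range
    candidates = {
        ln: [
            start
            for start in range(1, len(seq) - ln + 2)
            if all(
                seq[p - 1] not in exclude and f"{seq[p - 1]}{p}" in base
                for p in range(start, start + ln)
            )
        ]
        for ln in range(lo, hi + 1)
    }
    if all(not v for v in candidates.values()):
        raise SyntheticError("no eligible window in the sequence")
    chains: list[Chain] = []
    starts: dict[str, int] = {}
    for j in range(n):
        while True:
            ln = int(rng.integers(lo, hi + 1))
            if candidates[ln]:
                break
        start = int(candidates[ln][rng.integers(0, len(candidates[ln]))])
        members = [
            _anonymize(base[f"{seq[p - 1]}{p}"], f"c{j}_{p - start}")
            for p in range(start, start + ln)
        ]
        name = f"sample_{j}"
        chains.append(
            Chain(
                name=name,
                systems=members,
                left_boundary=_boundary(seq, start - 1),
                right_boundary=_boundary(seq, start + ln),
            )
        )
        starts[name] = start
    return chains, starts
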