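"""Parameter-space exploration: LHS designs, MI tables, sweeps, Minmax.

Promoter parameters are sampled with Latin hypercube sampling on a
log10 scale over the study ranges (k1, k2, n, Kd, d1; d2 fixed at
0.12/min): each parameter's log-range is divided into ``n_sets``
equiprobable strata containing exactly one draw.  MI is evaluated for
every (parameter set, modulation, cut) combination; ``find_max`` locates
the maximizer MI_M and ``minmax_region`` finds promoters that transmit
well for one modulation while staying near the conditional minimum MI_m
for another (the "Minmax" condition: maximize modulation i, then minimize
modulation j among sets within 90% of MI_M for i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .inputs import Modulation
from .model import D2_DEFAULT, KineticParams, PARAM_NAMES
from .simulate import CUT_LABELS, SimConfig
from .information import DEFAULT_N_BINS, mi_pipeline, mi_pipeline_cuts

__all__ = [
    "TABLE1_RANGES",
    "ParamRanges",
    "LHSDesign",
    "MinmaxRegion",
    "lhs_sample",
    "evaluate_table",
    "sweep_1d",
    "sweep_2d",
    "find_max",
    "minmax_region",
]

#: study sampling intervals (low, high) per free parameter
TABLE1_RANGES = {
    "k1": (0.01, 1.0),
    "k2": (1.0, 100.0),
    "n": (1.0, 10.0),
    "Kd": (10.0, 100.0),
    "d1": (0.01, 1.0),
}

SAMPLED_NAMES = tuple(TABLE1_RANGES)

MI_COLUMNS = ["set_index", *PARAM_NAMES, "modulation", "cut", "mi_bits", "mi_plugin_bits"]


@dataclass(frozen=True)
class ParamRanges:
    """Per-parameter (low, high) sampling bounds; d2 stays fixed."""

    k1: tuple = TABLE1_RANGES["k1"]
    k2: tuple = TABLE1_RANGES["k2"]
    n: tuple = TABLE1_RANGES["n"]
    Kd: tuple = TABLE1_RANGES["Kd"]
    d1: tuple = TABLE1_RANGES["d1"]
    d2: float = D2_DEFAULT

    def __post_init__(self) -> None:
        for name in SAMPLED_NAMES:
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.d2 <= 0:
            raise ValueError("d2 must be > 0")

    def bounds(self) -> tuple:
        lo = np.array([getattr(self, p)[0] for p in SAMPLED_NAMES])
        hi = np.array([getattr(self, p)[1] for p in SAMPLED_NAMES])
        return lo, hi


@dataclass
class LHSDesign:
    """A Latin hypercube design over promoter parameters."""

    n_sets: int
    seed: int
    params: list

    def __iter__(self):
        return iter(self.params)

    def __len__(self) -> int:
        return len(self.params)

    def to_frame(self) -> pd.DataFrame:
        rows = [p.to_dict() for p in self.params]
        frame = pd.DataFrame(rows)
        frame.insert(0, "set_index", np.arange(len(rows)))
        return frame

    def to_csv(self, path) -> None:
        # %.17g keeps the float64 parameter values exact across a roundtrip
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, seed: int = -1) -> "LHSDesign":
        frame = pd.read_csv(path, float_precision="round_trip")
        params = [
            KineticParams.from_dict(row) for row in frame.to_dict("records")
        ]
        return cls(n_sets=len(params), seed=seed, params=params)


@dataclass
class MinmaxRegion:
    """Promoters maximizing MI for mode i while minimizing it for mode j.

    Members satisfy ``MI_i >= 0.9*MI_M`` and ``MI_j <= 1.1*MI_m`` where
    ``MI_m`` is the minimum of ``MI_j`` over the 90%-of-maximum eligible
    sets; the representative is the argmin itself.
    """

    maximized: Modulation
    minimized: Modulation
    cut: str
    MI_M: float
    MI_m: float
    member_indices: list
    representative_index: int
    representative: KineticParams
    max_threshold: float = 0.9
    min_threshold: float = 0.1

    @property
    def label(self) -> str:
        return f"{int(self.maximized)}{int(self.minimized)}"

    def to_json(self) -> str:
        return json.dumps(
            {
                "maximized": int(self.maximized),
                "minimized": int(self.minimized),
                "cut": self.cut,
                "MI_M": self.MI_M,
                "MI_m": self.MI_m,
                "max_threshold": self.max_threshold,
                "min_threshold": self.min_threshold,
                "member_indices": [int(i) for i in self.member_indices],
                "representative_index": int(self.representative_index),
                "representative": self.representative.to_dict(),
            }
        )


def lhs_sample(
    ranges: ParamRanges, n_sets: int, seed: int = 0
) -> LHSDesign:
    """Latin hypercube sample of promoter parameters on a log10 scale.

    Each parameter's log-range is split into ``n_sets`` equiprobable
    strata; one value is drawn uniformly inside each stratum and strata
    are paired across parameters by independent random permutations
    (standard LHS, via :class:`scipy.stats.qmc.LatinHypercube`).
    """
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets!r}")
    sampler = qmc.LatinHypercube(d=len(SAMPLED_NAMES), seed=seed)
    unit = sampler.random(n_sets)
    lo, hi = ranges.bounds()
    log_vals = np.log10(lo) + unit * (np.log10(hi) - np.log10(lo))
    values = 10.0**log_vals
    params = [
        KineticParams(**dict(zip(SAMPLED_NAMES, row)), d2=ranges.d2)
        for row in values
    ]
    return LHSDesign(n_sets=n_sets, seed=seed, params=params)


def evaluate_table(
    design: LHSDesign,
    config: SimConfig,
    modulations: Sequence = tuple(Modulation),
    cuts: Sequence[str] = CUT_LABELS,
    n_inputs: int = 200,
    n_bins: int = DEFAULT_N_BINS,
    store: Optional[str] = None,
) -> pd.DataFrame:
    """MI for every set x modulation x cut of a design (long format).

    Per-set seeds are spawned deterministically from ``config.seed``.
    With ``store`` given, rows are appended to a CSV after each parameter
    set and already-present set indices are skipped on re-run, making
    large evaluations resumable.
    """
    modulations = [Modulation.coerce(m) for m in modulations]
    done: set = set()
    frames = []
    store_path = Path(store) if store is not None else None
    if store_path is not None and store_path.exists():
        prev = pd.read_csv(store_path)
        frames.append(prev)
        done = set(prev["set_index"].astype(int))

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(design))
    for idx, params in enumerate(design):
        if idx in done:
            continue
        rows = []
        for im, mod in enumerate(modulations):
            sub_seed = int(
                children[idx].generate_state(im + 1, dtype=np.uint32)[im]
            )
            ests = mi_pipeline_cuts(
                params,
                mod,
                config.replace(seed=sub_seed),
                n_inputs=n_inputs,
                n_bins=n_bins,
                cuts=cuts,
            )
            for cut, est in ests.items():
                rows.append(
                    {
                        "set_index": idx,
                        **params.to_dict(),
                        "modulation": int(mod),
                        "cut": cut,
                        "mi_bits": est.mi_bits,
                        "mi_plugin_bits": est.mi_plugin_bits,
                    }
                )
        frame = pd.DataFrame(rows, columns=MI_COLUMNS)
        frames.append(frame)
        if store_path is not None:
            header = not store_path.exists()
            frame.to_csv(store_path, mode="a", header=header, index=False)
    if not frames:
        return pd.DataFrame(columns=MI_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    return table.sort_values(["set_index", "modulation", "cut"]).reset_index(
        drop=True
    )


def _column(table: pd.DataFrame, modulation, cut: str) -> pd.DataFrame:
    modulation = Modulation.coerce(modulation)
    if cut not in CUT_LABELS:
        raise ValueError(f"unknown cut label {cut!r}")
    sel = table[(table["modulation"] == int(modulation)) & (table["cut"] == cut)]
    if sel.empty:
        raise ValueError(
            f"table has no rows for modulation {modulation.name}, cut {cut}"
        )
    return sel


def find_max(table: pd.DataFrame, modulation, cut: str):
    """Maximum MI and its parameter set for one (modulation, cut) column."""
    sel = _column(table, modulation, cut)
    row = sel.loc[sel["mi_bits"].idxmax()]
    params = KineticParams.from_dict(row)
    return float(row["mi_bits"]), params, int(row["set_index"])


def minmax_region(
    table: pd.DataFrame,
    maximized,
    minimized,
    cut: str,
    max_threshold: float = 0.9,
    min_threshold: float = 0.1,
) -> MinmaxRegion:
    """Minmax region for the ordered modulation pair (maximized, minimized).

    Eligible sets transmit at least ``max_threshold*MI_M`` for the
    maximized mode; ``MI_m`` is the minimum MI of the minimized mode over
    the eligible sets, and members are the eligible sets within
    ``(1 + min_threshold)*MI_m``.
    """
    i = Modulation.coerce(maximized)
    j = Modulation.coerce(minimized)
    if i == j:
        raise ValueError("maximized and minimized modulations must differ")
    col_i = _column(table, i, cut).set_index("set_index")
    col_j = _column(table, j, cut).set_index("set_index")
    common = col_i.index.intersection(col_j.index)
    if common.empty:
        raise ValueError("no parameter sets present for both modulations")
    mi_i = col_i.loc[common, "mi_bits"]
    mi_j = col_j.loc[common, "mi_bits"]
    mi_max = float(mi_i.max())
    eligible = mi_i[mi_i >= max_threshold * mi_max].index
    mi_m = float(mi_j.loc[eligible].min())
    members = [
        int(s) for s in eligible if mi_j.loc[s] <= (1.0 + min_threshold) * mi_m
    ]
    rep_index = int(mi_j.loc[eligible].idxmin())
    representative = KineticParams.from_dict(col_i.loc[rep_index])
    return MinmaxRegion(
        maximized=i,
        minimized=j,
        cut=cut,
        MI_M=mi_max,
        MI_m=mi_m,
        member_indices=members,
        representative_index=rep_index,
        representative=representative,
        max_threshold=max_threshold,
        min_threshold=min_threshold,
    )


def sweep_1d(
    base: KineticParams,
    name: str,
    grid: Sequence[float],
    modulation,
    cut: str,
    config: SimConfig,
    n_inputs: int = 200,
    n_bins: int = DEFAULT_N_BINS,
    allow_outside: bool = False,
) -> pd.DataFrame:
    """MI along a grid of one parameter, the others held at ``base``."""
    if name not in SAMPLED_NAMES:
        raise ValueError(
            f"unknown sweep parameter {name!r}; choose from {SAMPLED_NAMES}"
        )
    grid = np.asarray(grid, dtype=float)
    lo, hi = TABLE1_RANGES[name]
    if not allow_outside and (grid.min() < lo or grid.max() > hi):
        raise ValueError(
            f"sweep grid for {name} leaves the study range ({lo}, {hi}); "
            "pass allow_outside=True to permit"
        )
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(grid.size)
    rows = []
    for i, value in enumerate(grid):
        params = base.replace(**{name: float(value)})
        sub_seed = int(children[i].generate_state(1, dtype=np.uint32)[0])
        est = mi_pipeline(
            params,
            modulation,
            cut,
            config.replace(seed=sub_seed),
            n_inputs=n_inputs,
            n_bins=n_bins,
        )
        rows.append({"param": name, "value": float(value), "mi_bits": est.mi_bits})
    return pd.DataFrame(rows)


def sweep_2d(
    base: KineticParams,
    names: Sequence[str],
    grids: Sequence[Sequence[float]],
    modulation,
    cut: str,
    config: SimConfig,
    n_inputs: int = 200,
    n_bins: int = DEFAULT_N_BINS,
    allow_outside: bool = False,
) -> pd.DataFrame:
    """MI on the product grid of a parameter pair (long format)."""
    if len(names) != 2 or len(grids) != 2:
        raise ValueError("sweep_2d takes exactly two parameter names and grids")
    name_a, name_b = names
    for name, grid in zip(names, grids):
        if name not in SAMPLED_NAMES:
            raise ValueError(f"unknown sweep parameter {name!r}")
        g = np.asarray(grid, dtype=float)
        lo, hi = TABLE1_RANGES[name]
        if not allow_outside and (g.min() < lo or g.max() > hi):
            raise ValueError(
                f"sweep grid for {name} leaves the study range ({lo}, {hi})"
            )
    if name_a == name_b:
        raise ValueError("sweep_2d needs two distinct parameters")
    grid_a = np.asarray(grids[0], dtype=float)
    grid_b = np.asarray(grids[1], dtype=float)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(grid_a.size * grid_b.size)
    rows = []
    k = 0
    for va in grid_a:
        for vb in grid_b:
            params = base.replace(**{name_a: float(va), name_b: float(vb)})
            sub_seed = int(children[k].generate_state(1, dtype=np.uint32)[0])
            est = mi_pipeline(
                params,
                modulation,
                cut,
                config.replace(seed=sub_seed),
                n_inputs=n_inputs,
                n_bins=n_bins,
            )
            rows.append(
                {
                    name_a: float(va),
                    name_b: float(vb),
                    "mi_bits": est.mi_bits,
                }
            )
            k += 1
    return pd.DataFrame(rows)
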