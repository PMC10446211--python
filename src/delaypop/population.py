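"""Homogeneous/heterogeneous population assembly and delayed population coding.

A *homogeneous* population pools repeated frozen-stimulus trials of one
cell; a *heterogeneous* population pools single trials of distinct
cells, each first aligned to the stimulus by subtracting its response
delay (estimated from the spike-triggered average).  The population
response is the average firing rate of the member trains (Gaussian
kernel, 1.0 ms by default).

Conduction delays are mimicked by shifting *all* spikes of a member by
one Gaussian draw (zero mean, sd ``sigma_delay``) — a rigid shift per
member, so spike-time jitter within a train is untouched.  Increasing
the delay spread low-pass filters the information carried by the
population response; the effect is compared against widening the rate
kernel itself (a proxy for synaptic low-pass filtering) on a
(sigma_delay, sigma_kernel) grid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import RateEstimate, average_rate, response_modulation, sta_delay
from .signal import SampledSignal, SpikeTrain
from .spectral import coherence, lower_bound_mi

__all__ = [
    "Member",
    "PopulationAssembly",
    "DelaySpec",
    "assemble_homogeneous",
    "assemble_heterogeneous",
    "inject_delays",
    "population_response",
    "population_table",
    "mi_vs_size",
    "matched_modulation_compare",
    "delay_kernel_grid",
    "trial_store",
    "alignment_delays",
]


@dataclass(frozen=True)
class Member:
    cell_id: str
    trial_id: str
    alignment_delay: float = 0.0
    injected_delay: float = 0.0


@dataclass
class PopulationAssembly:
    """A set of member trials forming one population response."""

    members: list[Member]
    kernel_sigma: float = 1.0e-3
    kind: str = "heterogeneous"

    def __post_init__(self) -> None:
        cell_ids = [m.cell_id for m in self.members]
        if self.kind == "heterogeneous":
            if len(set(cell_ids)) != len(cell_ids):
                raise ValueError(
                    "heterogeneous populations take at most one trial per cell"
                )
        elif self.kind == "homogeneous":
            if len(set(cell_ids)) > 1:
                raise ValueError("homogeneous populations draw from a single cell")
            trial_ids = [m.trial_id for m in self.members]
            if len(set(trial_ids)) != len(trial_ids):
                raise ValueError("homogeneous populations need distinct trials")
        else:
            raise ValueError("kind must be 'homogeneous' or 'heterogeneous'")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DelaySpec:
    """Gaussian conduction-delay injection: zero mean, sd ``sigma_delay``."""

    sigma_delay: float
    seed: int = 0

    def validate(self) -> None:
        if self.sigma_delay < 0:
            raise ValueError("sigma_delay must be nonnegative")


def assemble_homogeneous(
    trials: Sequence[SpikeTrain],
    size: int,
    n_populations: int = 10,
    seed: int = 0,
    kernel_sigma: float = 1.0e-3,
) -> list[PopulationAssembly]:
    """Unique random combinations of distinct trials of one cell."""
    if size < 1:
        raise ValueError("size must be at least 1")
    if size > len(trials):
        raise ValueError(
            f"population size {size} exceeds the {len(trials)} available trials"
        )
    cell_id = trials[0].cell_id
    rng = np.random.default_rng(seed)
    n = len(trials)
    total = comb(n, size)
    if total <= n_populations:
        combos = list(combinations(range(n), size))
    else:
        seen: set[tuple[int, ...]] = set()
        while len(seen) < n_populations:
            seen.add(tuple(sorted(rng.choice(n, size=size, replace=False))))
        combos = sorted(seen)
    assemblies = []
    for combo in combos[:n_populations]:
        members = [Member(cell_id, trials[i].trial_id) for i in combo]
        assemblies.append(PopulationAssembly(members, kernel_sigma, "homogeneous"))
    return assemblies


def assemble_heterogeneous(
    cells: Mapping[str, Sequence[SpikeTrain]],
    size: int,
    n_populations: int = 50,
    seed: int = 0,
    align: Mapping[str, float] | None = None,
    kernel_sigma: float = 1.0e-3,
) -> list[PopulationAssembly]:
    """Populations of single trials from ``size`` distinct cells.

    ``align`` maps cell ids to response delays (typically the STA
    delays); each member's ``alignment_delay`` is subtracted from its
    spike times when the population response is formed, so that aligned
    responses are synchronous with the stimulus.
    """
    cell_ids = sorted(cells)
    if size < 2:
        raise ValueError("heterogeneous populations start at size 2")
    if size > len(cell_ids):
        raise ValueError(
            f"population size {size} exceeds the {len(cell_ids)} available cells"
        )
    rng = np.random.default_rng(seed)
    assemblies = []
    for _ in range(n_populations):
        chosen = rng.choice(len(cell_ids), size=size, replace=False)
        members = []
        for ci in chosen:
            cid = cell_ids[ci]
            trial = cells[cid][rng.integers(len(cells[cid]))]
            delay = float(align.get(cid, 0.0)) if align else 0.0
            members.append(Member(cid, trial.trial_id, alignment_delay=delay))
        assemblies.append(PopulationAssembly(members, kernel_sigma, "heterogeneous"))
    return assemblies


def inject_delays(assembly: PopulationAssembly, spec: DelaySpec) -> PopulationAssembly:
    """Draw one Gaussian conduction delay per member (rigid per-member shift).

    Draws are clipped at four standard deviations to bound spike loss at
    the trace edges.  ``sigma_delay = 0`` returns the assembly unchanged.
    """
    spec.validate()
    if spec.sigma_delay == 0:
        return assembly
    rng = np.random.default_rng(spec.seed)
    draws = rng.normal(0.0, spec.sigma_delay, size=assembly.size)
    draws = np.clip(draws, -4.0 * spec.sigma_delay, 4.0 * spec.sigma_delay)
    members = [
        replace(m, injected_delay=m.injected_delay + float(d))
        for m, d in zip(assembly.members, draws)
    ]
    return PopulationAssembly(members, assembly.kernel_sigma, assembly.kind)


def trial_store(study) -> dict[tuple[str, str], SpikeTrain]:
    """Index a synthetic study's driven trials by (cell_id, trial_id)."""
    store: dict[tuple[str, str], SpikeTrain] = {}
    for cell in study.cells:
        for tr in cell.driven_trials:
            store[(cell.cell_id, tr.trial_id)] = tr
    return store


def alignment_delays(
    study, stimulus: SampledSignal | None = None, window: float = 0.01
) -> dict[str, float]:
    """Per-cell response delay from the pooled spike-triggered average."""
    stim = stimulus if stimulus is not None else study.stimulus
    return {
        cell.cell_id: sta_delay(cell.driven_trials, stim, window)
        for cell in study.cells
    }


def population_response(
    assembly: PopulationAssembly,
    store: Mapping[tuple[str, str], SpikeTrain],
    kernel_sigma: float | None = None,
    rate_sampling: float = 20000.0,
) -> RateEstimate:
    """Average firing rate of the aligned, delay-injected member trains."""
    sigma = assembly.kernel_sigma if kernel_sigma is None else kernel_sigma
    trains = []
    for m in assembly.members:
        key = (m.cell_id, m.trial_id)
        if key not in store:
            raise KeyError(f"no spike train for cell={m.cell_id} trial={m.trial_id}")
        trains.append(store[key].shifted(m.injected_delay - m.alignment_delay))
    return average_rate(trains, sigma, rate_sampling)


def _population_mi(
    rate: RateEstimate,
    stimulus: SampledSignal,
    band: tuple[float, float],
    nperseg: int,
) -> float:
    coh = coherence(stimulus, [rate.rate], nperseg=nperseg)
    return lower_bound_mi(coh, *band)


def population_table(
    assemblies: Sequence[PopulationAssembly],
    store: Mapping[tuple[str, str], SpikeTrain],
    stimulus: SampledSignal,
    band: tuple[float, float] = (0.0, 300.0),
    nperseg: int = 2**14,
    rate_sampling: float = 20000.0,
) -> pd.DataFrame:
    """Per-population summary: size, response modulation and MI."""
    rows = []
    for idx, asm in enumerate(assemblies):
        rate = population_response(asm, store, rate_sampling=rate_sampling)
        rows.append(
            {
                "population_index": idx,
                "kind": asm.kind,
                "size": asm.size,
                "response_modulation": response_modulation(rate),
                "mi_bits_per_s": _population_mi(rate, stimulus, band, nperseg),
            }
        )
    return pd.DataFrame(rows)


def mi_vs_size(
    assemblies_by_size: Mapping[int, Sequence[PopulationAssembly]],
    store: Mapping[tuple[str, str], SpikeTrain],
    stimulus: SampledSignal,
    band: tuple[float, float] = (0.0, 300.0),
    nperseg: int = 2**14,
    rate_sampling: float = 20000.0,
) -> pd.DataFrame:
    """Per-size MI summary (mean, sd, min, max) over assemblies."""
    rows = []
    for size in sorted(assemblies_by_size):
        mis = [
            _population_mi(
                population_response(a, store, rate_sampling=rate_sampling),
                stimulus, band, nperseg,
            )
            for a in assemblies_by_size[size]
        ]
        mis = np.asarray(mis)
        rows.append(
            {
                "size": size,
                "mean_mi": mis.mean(),
                "sd_mi": mis.std(ddof=0),
                "min_mi": mis.min(),
                "max_mi": mis.max(),
                "n_populations": mis.size,
            }
        )
    return pd.DataFrame(rows)


def matched_modulation_compare(
    hom_table: pd.DataFrame,
    het_table: pd.DataFrame,
    tolerance: float = 0.20,
    sizes: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair homogeneous and heterogeneous populations of similar drive.

    For each homogeneous population, heterogeneous populations of the
    same size whose response modulation lies within ``±tolerance``
    (relative) are paired with it.  Returns the pair table and the
    per-size centers of gravity (mean homogeneous and heterogeneous MI
    over pairs); homogeneous populations without a match are counted in
    the centroid table's ``n_unmatched`` column.
    """
    if sizes is None:
        sizes = sorted(set(hom_table["size"]) & set(het_table["size"]))
    pairs = []
    centroid_rows = []
    for size in sizes:
        hom = hom_table[hom_table["size"] == size]
        het = het_table[het_table["size"] == size]
        unmatched = 0
        for _, h in hom.iterrows():
            lo = h["response_modulation"] * (1.0 - tolerance)
            hi = h["response_modulation"] * (1.0 + tolerance)
            match = het[
                (het["response_modulation"] >= lo)
                & (het["response_modulation"] <= hi)
            ]
            if match.empty:
                unmatched += 1
                continue
            for _, g in match.iterrows():
                pairs.append(
                    {
                        "size": size,
                        "hom_mi": h["mi_bits_per_s"],
                        "het_mi": g["mi_bits_per_s"],
                        "hom_modulation": h["response_modulation"],
                        "het_modulation": g["response_modulation"],
                    }
                )
        size_pairs = [p for p in pairs if p["size"] == size]
        centroid_rows.append(
            {
                "size": size,
                "hom_mi_centroid": np.mean([p["hom_mi"] for p in size_pairs])
                if size_pairs else np.nan,
                "het_mi_centroid": np.mean([p["het_mi"] for p in size_pairs])
                if size_pairs else np.nan,
                "n_pairs": len(size_pairs),
                "n_unmatched": unmatched,
            }
        )
    return pd.DataFrame(pairs), pd.DataFrame(centroid_rows)


def delay_kernel_grid(
    cells: Mapping[str, Sequence[SpikeTrain]],
    stimulus: SampledSignal,
    sigma_delays: Sequence[float],
    sigma_kernels: Sequence[float],
    size: int = 16,
    n_populations: int = 10,
    seed: int = 0,
    align: Mapping[str, float] | None = None,
    band: tuple[float, float] = (0.0, 300.0),
    nperseg: int = 2**14,
    rate_sampling: float = 20000.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MI of heterogeneous populations over a (sigma_delay, sigma_kernel) grid.

    The same ``n_populations`` memberships are reused at every grid
    point (only the injected delays and the rate kernel change), so the
    grid isolates the filtering effects from membership sampling noise.
    ``sigma_kernel`` replaces the rate-estimation kernel width itself,
    acting as the synaptic low-pass proxy.

    Returns ``(mi_matrix, sigma_delays, sigma_kernels)`` with shape
    ``(len(sigma_delays), len(sigma_kernels))``; entries are mean MI
    over the populations.
    """
    sigma_delays = np.asarray(list(sigma_delays), dtype=float)
    sigma_kernels = np.asarray(list(sigma_kernels), dtype=float)
    if sigma_delays.size == 0 or sigma_kernels.size == 0:
        raise ValueError("grids must be nonempty")
    base = assemble_heterogeneous(
        cells, size=size, n_populations=n_populations, seed=seed, align=align
    )
    store = {
        (cid, tr.trial_id): tr for cid, trs in cells.items() for tr in trs
    }
    mi = np.zeros((sigma_delays.size, sigma_kernels.size))
    for i, sd in enumerate(sigma_delays):
        injected = [
            inject_delays(a, DelaySpec(float(sd), seed=hash((seed, i, k)) % (2**31)))
            for k, a in enumerate(base)
        ]
        for j, sk in enumerate(sigma_kernels):
            vals = [
                _population_mi(
                    population_response(a, store, kernel_sigma=float(sk),
                                        rate_sampling=rate_sampling),
                    stimulus, band, nperseg,
                )
                for a in injected
            ]
            mi[i, j] = float(np.mean(vals))
    return mi, sigma_delays, sigma_kernels
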