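"""Post-hoc trajectory analysis: stable flux states, top-flux tables,
cross-feeding edges, flux-coverage fractions.

A community run settles into quasi-steady "flux states" — windows of cycles
over which the per-cycle community exchange-flux vector is nearly constant.
Windows are found by greedy left-to-right expansion: a window is kept while,
for every tracked (organism, metabolite) flux series, the deviation from the
window mean stays below ``tolerance`` relative to the window's own maximum
magnitude (scale-free, since fluxes span many orders of magnitude — vitamin
B12 versus O2). Windows shorter than ``min_length`` cycles are discarded.

The default tolerance (0.25) reflects the demographic noise floor of the
default protocol: with ~70 archaeal lysis events per cycle the community
flux series carry ~10-15% Poisson noise, so a tighter tolerance would never
accept a window on a faithful run. Both tolerance and minimum length are
exposed in the analysis configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .arena import Trajectory

__all__ = [
    "CommunityFluxProfile",
    "CrossFeedingEdge",
    "detect_stable_states",
    "community_profile",
    "top_flux_table",
    "cross_feeding_edges",
    "coverage_fraction",
    "profile_distance",
    "DEFAULT_ALWAYS_INCLUDE",
    "DEFAULT_EXCLUDE",
]

#: metabolites always shown alongside the top fluxes
DEFAULT_ALWAYS_INCLUDE = ("bet_e", "cho_e", "crea_e", "dmsp_e", "b12_e")
#: ubiquitous currency species excluded from ranking and coverage
DEFAULT_EXCLUDE = frozenset({"h2o_e", "h_e"})


@dataclass
class CommunityFluxProfile:
    """Window-averaged community exchange fluxes.

    ``fluxes`` is a tidy frame (organism, metabolite, flux) in community
    mmol/h, export-positive; ``environment`` holds the net environment flux
    per metabolite (positive = the environment absorbs). ``per_cell`` converts
    to fmol/h per cell using the mean population over the window.
    """

    window: tuple[int, int]
    fluxes: pd.DataFrame
    mean_population: dict[str, float] = field(default_factory=dict)

    @property
    def environment(self) -> pd.Series:
        return -self.fluxes.groupby("metabolite")["flux"].sum()

    def per_cell(self) -> pd.DataFrame:
        out = self.fluxes.copy()
        out["flux_fmol_per_h_per_cell"] = [
            row.flux * 1e12 / self.mean_population[row.organism]
            if self.mean_population.get(row.organism) else np.nan
            for row in out.itertuples()]
        return out

    def to_tsv(self) -> str:
        lines = ["organism\tmetabolite\tflux_mmol_per_h"]
        for row in self.fluxes.sort_values(["organism", "metabolite"]).itertuples():
            lines.append(f"{row.organism}\t{row.metabolite}\t{row.flux!r}")
        return "\n".join(lines) + "\n"


@dataclass
class CrossFeedingEdge:
    source: str      # organism id or "environment"
    sink: str        # organism id or "environment"
    metabolite: str
    flux: float      # mmol/h, > 0

    def to_dict(self) -> dict:
        return {"source": self.source, "sink": self.sink,
                "metabolite": self.metabolite, "flux": self.flux}


def _as_matrix(trajectory: Trajectory | pd.DataFrame) -> pd.DataFrame:
    if isinstance(trajectory, Trajectory):
        return trajectory.flux_matrix()
    return trajectory


def detect_stable_states(trajectory: Trajectory | pd.DataFrame,
                         tolerance: float = 0.25,
                         min_length: int = 5) -> list[tuple[int, int]]:
    """Maximal disjoint cycle windows of near-constant community fluxes.

    Returns inclusive ``(start_cycle, end_cycle)`` pairs. Deterministic and
    idempotent; returned windows never overlap.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    matrix = _as_matrix(trajectory)
    if len(matrix) < min_length:
        raise ValueError(f"trajectory has {len(matrix)} cycles, needs >= {min_length}")
    cycles = matrix.index.to_numpy()
    values = matrix.to_numpy(dtype=float)
    n = len(cycles)

    def window_ok(i: int, j: int) -> bool:
        block = values[i:j + 1]
        mean = block.mean(axis=0)
        scale = np.abs(block).max(axis=0)
        scale[scale == 0.0] = 1.0
        return bool((np.abs(block - mean).max(axis=0) / scale < tolerance).all())

    windows: list[tuple[int, int]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and window_ok(i, j + 1):
            j += 1
        if j - i + 1 >= min_length:
            windows.append((int(cycles[i]), int(cycles[j])))
        i = j + 1
    return windows


def community_profile(trajectory: Trajectory,
                      window: tuple[int, int]) -> CommunityFluxProfile:
    """Average the community exchange fluxes over an inclusive cycle window."""
    start, end = window
    if end < start:
        raise ValueError("empty window")
    fx = trajectory.exchange_fluxes
    sel = fx[(fx.cycle >= start) & (fx.cycle <= end)]
    n_cycles = end - start + 1
    # mean over all window cycles: absent rows are zero flux
    mean = (sel.groupby(["organism", "metabolite"])["flux"].sum() / n_cycles)
    fluxes = mean.reset_index()
    pops = trajectory.populations
    psel = pops[(pops.cycle >= start) & (pops.cycle <= end)]
    mean_pop = psel.groupby("organism")["count"].mean().to_dict()
    return CommunityFluxProfile((start, end), fluxes, mean_pop)


def top_flux_table(profile: CommunityFluxProfile, n: int = 15,
                   always_include: Iterable[str] = DEFAULT_ALWAYS_INCLUDE,
                   exclude: Iterable[str] = DEFAULT_EXCLUDE) -> pd.DataFrame:
    """The ``n`` largest-magnitude flux rows plus the always-shown metabolites.

    Water and protons are excluded by default. Rows are ranked by decreasing
    |flux|; ties break lexicographically on (metabolite, organism) so the
    table is stable across runs.
    """
    if profile.fluxes.empty:
        raise ValueError("empty flux profile")
    exclude = set(exclude)
    always = set(always_include)
    df = profile.fluxes[~profile.fluxes.metabolite.isin(exclude)].copy()
    df["magnitude"] = df.flux.abs()
    df = df.sort_values(["magnitude", "metabolite", "organism"],
                        ascending=[False, True, True], kind="mergesort")
    top = df.head(n)
    extra = df[df.metabolite.isin(always) & ~df.index.isin(top.index)]
    out = pd.concat([top, extra]).reset_index(drop=True)
    out["rank"] = range(1, len(out) + 1)
    return out[["rank", "organism", "metabolite", "flux", "magnitude"]]


def cross_feeding_edges(profile: CommunityFluxProfile,
                        threshold: float = 0.0) -> list[CrossFeedingEdge]:
    """Organism-to-organism transfer edges implied by a flux profile.

    An edge (A -> B, m) exists when A's net secretion of m and B's net uptake
    of m both exceed ``threshold``; its flux is min(secretion, uptake). The
    environment supplies or sinks the remainder.
    """
    edges: list[CrossFeedingEdge] = []
    pivot = profile.fluxes.pivot_table(index="metabolite", columns="organism",
                                       values="flux", fill_value=0.0)
    for met, row in pivot.iterrows():
        secretors = {org: v for org, v in row.items() if v > threshold}
        consumers = {org: -v for org, v in row.items() if -v > threshold}
        for src, sec in sorted(secretors.items()):
            for dst, upt in sorted(consumers.items()):
                if src != dst:
                    edges.append(CrossFeedingEdge(src, dst, met, min(sec, upt)))
        total_sec = sum(secretors.values())
        total_upt = sum(consumers.values())
        if total_sec - total_upt > threshold:
            for src, sec in sorted(secretors.items()):
                surplus = sec * (total_sec - total_upt) / total_sec
                if surplus > threshold:
                    edges.append(CrossFeedingEdge(src, "environment", met, surplus))
        elif total_upt - total_sec > threshold:
            for dst, upt in sorted(consumers.items()):
                deficit = upt * (total_upt - total_sec) / total_upt
                if deficit > threshold:
                    edges.append(CrossFeedingEdge("environment", dst, met, deficit))
    return edges


def edges_to_graph_json(edges: Sequence[CrossFeedingEdge]) -> str:
    nodes = sorted({e.source for e in edges} | {e.sink for e in edges})
    return json.dumps({"nodes": nodes,
                       "edges": [e.to_dict() for e in edges]}, indent=1)


def coverage_fraction(profile: CommunityFluxProfile,
                      selected: pd.DataFrame,
                      exclude: Iterable[str] = DEFAULT_EXCLUDE) -> float:
    """Percent of total |flux| carried by the selected rows.

    ``selected`` must be a subset of the profile's rows (e.g. a top-flux
    table). The denominator sums |flux| over all non-excluded rows.
    """
    exclude = set(exclude)
    all_rows = profile.fluxes[~profile.fluxes.metabolite.isin(exclude)]
    denom = all_rows.flux.abs().sum()
    if denom == 0:
        raise ZeroDivisionError("profile carries no flux; coverage undefined")
    keys_all = set(zip(all_rows.organism, all_rows.metabolite))
    keys_sel = set(zip(selected.organism, selected.metabolite))
    if not keys_sel <= keys_all:
        raise ValueError("selected rows are not a subset of the profile")
    mask = [
        (org, met) in keys_sel
        for org, met in zip(all_rows.organism, all_rows.metabolite)]
    return float(100.0 * all_rows.flux.abs()[mask].sum() / denom)


def profile_distance(a: CommunityFluxProfile, b: CommunityFluxProfile,
                     floor_quantile: float = 0.0) -> float:
    """Scale-free L-infinity distance between two flux profiles.

    For every (organism, metabolite) present in either profile the deviation
    |fa - fb| is scaled by max(|fa|, |fb|); rows whose larger magnitude falls
    below ``floor_quantile`` of the combined magnitude distribution are
    ignored as numerical noise. Used for the mirror-state comparison.
    """
    fa = a.fluxes.set_index(["organism", "metabolite"])["flux"]
    fb = b.fluxes.set_index(["organism", "metabolite"])["flux"]
    keys = fa.index.union(fb.index)
    va = fa.reindex(keys, fill_value=0.0).to_numpy()
    vb = fb.reindex(keys, fill_value=0.0).to_numpy()
    scale = np.maximum(np.abs(va), np.abs(vb))
    floor = np.quantile(scale[scale > 0], floor_quantile) if (scale > 0).any() else 0.0
    mask = scale > max(floor, 0.0)
    if not mask.any():
        return 0.0
    return float((np.abs(va - vb)[mask] / scale[mask]).max())
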