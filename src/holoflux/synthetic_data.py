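"""Synthetic inputs for every pipeline stage — no downloads required.

Three generators, all deterministic under a fixed seed:

* a five-analyte UHPLC-style quantification table (betaine, choline,
  creatine, DMSP, taurine) over a handful of specimens with multiplicative
  lognormal noise, entries clipped to the instrument calibration span
  (1-200 ppb);
* two-organism metagenome coverage shares resembling the study samples
  (S29-like 94.6/4.5, S84-like 66.1/32.5), optionally Dirichlet-jittered;
* small random feasible metabolic networks (chain backbone plus random
  shunts) together with their exact FBA optimum computed by exhaustive
  vertex enumeration — the independent oracle used to validate the LP
  solver.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .fba import FBAProblem, UptakeBounds
from .netcore import MetabolicModel, Metabolite, Reaction

__all__ = [
    "SyntheticSpec",
    "generate_metabolite_table",
    "generate_coverage_table",
    "generate_toy_network",
    "enumerate_fba_optimum",
    "CALIBRATION_SPAN_PPB",
]

CALIBRATION_SPAN_PPB = (1.0, 200.0)

_DEFAULT_BASE_PPB = {
    # inside the calibration span, ordered taurine ~ creatine > DMSP >
    # betaine > choline like the study's organic profile
    "taurine": 120.0, "creatine": 110.0, "dmsp": 8.0, "betaine": 2.0,
    "choline": 1.0,
}

_COVERAGE_PROFILES = {
    "S29": {"autotroph": 94.6, "heterotroph": 4.5},
    "S84": {"autotroph": 66.1, "heterotroph": 32.5},
}


@dataclass
class SyntheticSpec:
    rng_seed: int = 0
    n_specimens: int = 5
    base_levels_ppb: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BASE_PPB))
    noise_cv: float = 0.2  # lognormal coefficient of variation
    coverage_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _COVERAGE_PROFILES.items()})

    def validate(self) -> None:
        lo, hi = CALIBRATION_SPAN_PPB
        for analyte, level in self.base_levels_ppb.items():
            if not lo <= level <= hi:
                raise ValueError(
                    f"base level for {analyte} ({level} ppb) outside the "
                    f"calibration span [{lo}, {hi}] ppb")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_specimens < 1:
            raise ValueError("need at least one specimen")


def generate_metabolite_table(spec: SyntheticSpec | None = None) -> pd.DataFrame:
    """Analyte x specimen concentration table in ppb.

    Entries are base * mean-one lognormal noise; anything outside the
    calibration span is clipped, and a ``clipped`` count column is appended
    only when clipping occurred (downstream readers ignore it).
    """
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv ** 2))
    lo, hi = CALIBRATION_SPAN_PPB
    columns = [f"specimen_{i + 1}" for i in range(spec.n_specimens)]
    rows, clipped_counts = {}, {}
    for analyte, base in spec.base_levels_ppb.items():
        noise = np.exp(rng.normal(-sigma ** 2 / 2.0, sigma, spec.n_specimens))
        values = base * noise
        clipped_counts[analyte] = int(((values < lo) | (values > hi)).sum())
        rows[analyte] = np.clip(values, lo, hi)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "analyte"
    if any(clipped_counts.values()):
        table["clipped"] = pd.Series(clipped_counts)
    return table


def generate_coverage_table(spec: SyntheticSpec | None, profile_name: str,
                            jitter_concentration: float | None = None,
                            ) -> pd.DataFrame:
    """Organism abundance shares from a named coverage profile, summing to 1.

    ``jitter_concentration`` draws shares from Dirichlet(k * p); as k -> inf
    the draw converges to the renormalized profile itself (None disables
    jitter entirely).
    """
    spec = spec or SyntheticSpec()
    profiles = spec.coverage_profiles
    if profile_name not in profiles:
        raise KeyError(f"unknown coverage profile {profile_name!r}; "
                       f"available: {sorted(profiles)}")
    raw = profiles[profile_name]
    total = sum(raw.values())
    shares = {org: v / total for org, v in raw.items()}
    if jitter_concentration is not None:
        rng = np.random.default_rng(spec.rng_seed)
        alphas = np.array([shares[o] for o in sorted(shares)]) * jitter_concentration
        draw = rng.dirichlet(alphas)
        shares = dict(zip(sorted(shares), draw.tolist()))
    df = pd.DataFrame({"organism": sorted(shares),
                       "share": [shares[o] for o in sorted(shares)]})
    df.attrs["profile"] = profile_name
    return df


# ---------------------------------------------------------------------------
# Random toy networks with an enumerated optimum (FBA oracle fixtures)
# ---------------------------------------------------------------------------

def generate_toy_network(seed: int, n_internal_mets: int = 4,
                         n_reactions: int = 5,
                         ) -> tuple[MetabolicModel, dict[str, float], float]:
    """A random small feasible model, its uptake bounds, and its true optimum.

    The backbone is a substrate chain (exchange -> transport -> conversions ->
    biomass) guaranteeing feasibility; extra random shunt reactions with
    random yields and bounds create flux degeneracy and alternative routes.
    ``n_reactions`` counts the chain conversions plus shunts (the exchange,
    transport and biomass reactions come on top). The returned optimum is
    computed by exhaustive vertex enumeration, independent of the LP path.
    """
    if n_internal_mets > 5 or n_reactions > 6:
        raise ValueError("toy networks are capped at 5 internal metabolites "
                         "and 6 chain/shunt reactions")
    n_internal_mets = max(2, n_internal_mets)
    rng = np.random.default_rng(seed)
    mets = [Metabolite("A_e", compartment="extracellular")]
    mets += [Metabolite(f"m{i}", compartment="cytosol")
             for i in range(n_internal_mets)]
    reactions = [
        Reaction("EX_A", stoichiometry={"A_e": -1.0},
                 lower_bound=-1000.0, upper_bound=1000.0, kind="exchange"),
        Reaction("T_A", stoichiometry={"A_e": -1.0, "m0": 1.0},
                 lower_bound=0.0, upper_bound=1000.0, kind="transport"),
    ]
    n_chain = n_internal_mets - 1
    for i in range(n_chain):
        yield_coef = float(rng.choice([0.5, 1.0, 2.0]))
        reactions.append(Reaction(
            f"R{i}", stoichiometry={f"m{i}": -1.0, f"m{i + 1}": yield_coef},
            lower_bound=0.0, upper_bound=float(rng.integers(5, 50)),
            kind="internal", evidence="synthetic chain step"))
    n_shunts = max(0, n_reactions - n_chain)
    for s in range(n_shunts):
        i, j = sorted(rng.choice(n_internal_mets, size=2, replace=False))
        reactions.append(Reaction(
            f"S{s}", stoichiometry={f"m{i}": -1.0,
                                    f"m{j}": float(rng.choice([0.5, 1.0, 2.0]))},
            lower_bound=float(rng.choice([0.0, -10.0])),
            upper_bound=float(rng.integers(1, 20)),
            kind="internal", evidence="synthetic shunt"))
    demand = float(rng.choice([0.5, 1.0, 2.0]))
    reactions.append(Reaction(
        "BIOMASS", stoichiometry={f"m{n_internal_mets - 1}": -demand},
        lower_bound=0.0, upper_bound=1000.0, kind="biomass"))
    model = MetabolicModel("toy", mets, reactions, "BIOMASS",
                           biomass_composition={"A_e": 1.0})
    uptake = {"A_e": float(rng.integers(1, 11))}
    optimum = enumerate_fba_optimum(model, uptake)
    return model, uptake, optimum


def enumerate_fba_optimum(model: MetabolicModel, uptake: UptakeBounds,
                          tol: float = 1e-9) -> float:
    """Exact FBA optimum by exhaustive vertex enumeration.

    Enumerates every basic feasible solution of {S v = 0, l <= v <= u} by
    fixing each choice of n - rank(S) variables at a bound and solving for
    the rest; the optimum is the best biomass flux over all vertices. Only
    viable for tiny networks — this is the brute-force oracle, kept entirely
    independent of the LP code path.
    """
    problem = FBAProblem(model)
    S = problem.S.toarray()
    lb, ub = problem.effective_bounds(uptake)
    lb = np.maximum(lb, -1e4)
    ub = np.minimum(ub, 1e4)
    n = problem.n
    rank = np.linalg.matrix_rank(S)
    best = -np.inf
    for free in itertools.combinations(range(n), n - rank):
        basic = [j for j in range(n) if j not in free]
        S_basic = S[:, basic]
        if np.linalg.matrix_rank(S_basic) < rank:
            continue
        for bound_choice in itertools.product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.array(bound_choice) if free else np.zeros(S.shape[0])
            v_basic, residual, *_ = np.linalg.lstsq(S_basic, rhs, rcond=None)
            full = np.zeros(n)
            for j, val in zip(free, bound_choice):
                full[j] = val
            for j, val in zip(basic, v_basic):
                full[j] = val
            if np.abs(S @ full).max() > 1e-6:
                continue
            if (full < lb - tol).any() or (full > ub + tol).any():
                continue
            best = max(best, full[problem.biomass_j])
    if not np.isfinite(best):
        raise RuntimeError("no vertex found; polytope empty or degenerate")
    return float(best)
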