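"""Reaction-network definition and deterministic kinetic simulation.

Networks are lists of reactions with non-negative integer stoichiometries;
the induced ODE system dx/dt = N v(x) is integrated with a stiff-capable
solver.  Supported rate laws:

* ``mass_action``: v = k * prod_i x_i^a_i over the substrate stoichiometry
  (reversible variant: v = kf * prod substrates - kb * prod products);
* ``michaelis_menten``: reversible convenience kinetics,
  v = (vf * prod_s (s/Km_s)^a - vr * prod_p (p/Km_p)^a')
      / (prod_s (1 + s/Km_s)^a + prod_p (1 + p/Km_p)^a' - 1),
  which for a 1:1 reaction S -> P reduces to the textbook reversible
  uni-uni form (vf s/KmS - vr p/KmP) / (1 + s/KmS + p/KmP); vr = 0 gives
  the irreversible hyperbola vf s / (KmS + s).

Enzyme action can be modeled explicitly: a flagged reaction
sum_i a_i S_i -> sum_i a'_i S_i is expanded into the three elementary
mass-action steps binding (substrates + E -> SE, k_on), unbinding
(SE -> substrates + E, k_off) and catalysis (SE -> products + E, k_cat),
whose quasi-steady-state flux is Vmax s / (Km + s) with
Vmax = k_cat * E_tot and Km = (k_off + k_cat) / k_on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .profile_io import ProfileMatrix

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "SteadyStateError",
    "mass_action_rates",
    "michaelis_menten_rates",
    "expand_enzyme_complexes",
    "reversible_to_irreversible",
    "simulate",
    "steady_state",
    "sample_ensemble",
    "conserved_moieties",
    "default_time_grid",
    "fixture_toy_cycle",
    "fixture_tca_mini",
    "read_network",
    "write_network",
]

logger = logging.getLogger(__name__)

#: steady state accepted when ||dx/dt||_inf <= SS_TOL * (1 + ||x||_inf)
SS_TOL = 1e-9


class SteadyStateError(RuntimeError):
    pass


@dataclass
class Reaction:
    name: str
    substrates: dict[str, int]
    products: dict[str, int]
    law: str = "mass_action"
    params: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    enzyme: str | None = None
    inflow: bool = False

    def __post_init__(self):
        for stoich in (self.substrates, self.products):
            for sp, a in stoich.items():
                if not (isinstance(a, (int, np.integer)) and a >= 0):
                    raise ValueError(
                        f"reaction {self.name}: stoichiometry of {sp} must be a "
                        f"non-negative integer, got {a!r}"
                    )
        if not self.substrates and not self.inflow:
            raise ValueError(
                f"reaction {self.name} has no substrates and is not an inflow"
            )
        if self.law == "mass_action":
            if self.reversible:
                for key in ("kf", "kb"):
                    if self.params.get(key, 0) <= 0:
                        raise ValueError(
                            f"reaction {self.name}: reversible mass action needs "
                            f"positive {key}"
                        )
            else:
                if self.params.get("k", 0) <= 0:
                    raise ValueError(
                        f"reaction {self.name}: mass action needs positive k"
                    )
        elif self.law == "michaelis_menten":
            if self.params.get("vf", 0) <= 0:
                raise ValueError(f"reaction {self.name}: needs positive vf")
            if self.params.get("vr", 0) < 0:
                raise ValueError(f"reaction {self.name}: vr must be >= 0")
            for sp in list(self.substrates) + list(self.products):
                if self.params.get(f"km_{sp}", 0) <= 0:
                    raise ValueError(
                        f"reaction {self.name}: needs positive km_{sp}"
                    )
        else:
            raise ValueError(f"reaction {self.name}: unknown law {self.law!r}")


@dataclass
class ReactionNetwork:
    species: list[str]
    reactions: list[Reaction]
    initial_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species names")
        known = set(self.species)
        for rxn in self.reactions:
            for sp in list(rxn.substrates) + list(rxn.products):
                if sp not in known:
                    raise ValueError(
                        f"reaction {rxn.name} references unknown species {sp!r}"
                    )
        for sp, (lo, hi) in self.initial_ranges.items():
            if not (0 < lo <= hi):
                raise ValueError(f"invalid initial range for {sp}: ({lo}, {hi})")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def stoichiometric_matrix(self) -> np.ndarray:
        """Species x reactions matrix N, entries = product - substrate stoichiometry."""
        idx = {sp: i for i, sp in enumerate(self.species)}
        N = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for sp, a in rxn.substrates.items():
                N[idx[sp], j] -= a
            for sp, a in rxn.products.items():
                N[idx[sp], j] += a
        return N

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Rate vector v(x) dispatching on each reaction's law."""
        x = np.asarray(x, dtype=float)
        idx = {sp: i for i, sp in enumerate(self.species)}
        v = np.empty(self.n_reactions)
        for j, rxn in enumerate(self.reactions):
            v[j] = _reaction_rate(rxn, x, idx)
        return v


def _prod_pow(x, idx, stoich) -> float:
    out = 1.0
    for sp, a in stoich.items():
        out *= x[idx[sp]] ** a
    return out


def _reaction_rate(rxn: Reaction, x: np.ndarray, idx: dict[str, int]) -> float:
    if rxn.law == "mass_action":
        fwd = _prod_pow(x, idx, rxn.substrates)
        if rxn.reversible:
            return rxn.params["kf"] * fwd - rxn.params["kb"] * _prod_pow(
                x, idx, rxn.products
            )
        return rxn.params["k"] * fwd
    # reversible convenience (Michaelis-Menten) kinetics
    num_f = rxn.params["vf"]
    den_f = 1.0
    for sp, a in rxn.substrates.items():
        s = x[idx[sp]] / rxn.params[f"km_{sp}"]
        num_f *= s**a
        den_f *= (1.0 + s) ** a
    vr = rxn.params.get("vr", 0.0)
    num_r = vr
    den_r = 1.0
    for sp, a in rxn.products.items():
        p = x[idx[sp]] / rxn.params[f"km_{sp}"]
        num_r *= p**a
        den_r *= (1.0 + p) ** a
    return (num_f - num_r) / (den_f + den_r - 1.0)


def mass_action_rates(net: ReactionNetwork, x) -> np.ndarray:
    """Mass-action rate vector; errors on negative concentrations."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative concentration")
    if any(r.law != "mass_action" for r in net.reactions):
        raise ValueError("network contains non-mass-action reactions")
    return net.rates(x)


def michaelis_menten_rates(net: ReactionNetwork, x) -> np.ndarray:
    """Michaelis-Menten (convenience kinetics) rate vector."""
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("negative concentration")
    if any(r.law != "michaelis_menten" for r in net.reactions):
        raise ValueError("network contains non-Michaelis-Menten reactions")
    return net.rates(x)


# ---------------------------------------------------------------------------
# structural transformations


def expand_enzyme_complexes(
    net: ReactionNetwork,
    k_on: float = 100.0,
    k_off: float = 100.0,
    k_cat: float = 1.0,
    enzyme_range: tuple[float, float] = (0.05, 0.5),
    complex_range: tuple[float, float] = (0.01, 0.1),
) -> ReactionNetwork:
    """Replace every enzyme-flagged reaction by its three elementary steps.

    Binding (substrates + E -> SE), unbinding (SE -> substrates + E) and
    catalysis (SE -> products + E).  Adds the enzyme and complex species;
    collisions with existing species names are an error.
    """
    species = list(net.species)
    ranges = dict(net.initial_ranges)
    reactions: list[Reaction] = []
    for rxn in net.reactions:
        if rxn.enzyme is None:
            reactions.append(rxn)
            continue
        if rxn.law != "mass_action" or rxn.reversible:
            raise ValueError(
                f"reaction {rxn.name}: only irreversible mass-action reactions "
                "can be enzyme-expanded"
            )
        enz = rxn.enzyme
        cplx = f"{enz}_{rxn.name}"
        for new_sp in (enz, cplx):
            if new_sp in species:
                raise ValueError(f"enzyme expansion name collision: {new_sp!r}")
            species.append(new_sp)
        ranges.setdefault(enz, enzyme_range)
        ranges.setdefault(cplx, complex_range)
        p = rxn.params
        reactions.extend(
            [
                Reaction(
                    f"{rxn.name}_bind",
                    {**rxn.substrates, enz: 1},
                    {cplx: 1},
                    params={"k": p.get("k_on", k_on)},
                ),
                Reaction(
                    f"{rxn.name}_unbind",
                    {cplx: 1},
                    {**rxn.substrates, enz: 1},
                    params={"k": p.get("k_off", k_off)},
                ),
                Reaction(
                    f"{rxn.name}_cat",
                    {cplx: 1},
                    {**rxn.products, enz: 1},
                    params={"k": p.get("k_cat", k_cat)},
                ),
            ]
        )
    return ReactionNetwork(species, reactions, ranges)


def reversible_to_irreversible(net: ReactionNetwork) -> ReactionNetwork:
    """Split every reversible mass-action reaction into forward + backward."""
    reactions: list[Reaction] = []
    for rxn in net.reactions:
        if not rxn.reversible:
            reactions.append(rxn)
            continue
        if rxn.law != "mass_action":
            raise ValueError(
                f"reaction {rxn.name}: only mass-action reactions can be split"
            )
        if "kb" not in rxn.params:
            raise ValueError(f"reaction {rxn.name}: missing backward constant kb")
        reactions.append(
            Reaction(
                f"{rxn.name}_f",
                dict(rxn.substrates),
                dict(rxn.products),
                params={"k": rxn.params["kf"]},
                enzyme=rxn.enzyme,
            )
        )
        reactions.append(
            Reaction(
                f"{rxn.name}_b",
                dict(rxn.products),
                dict(rxn.substrates),
                params={"k": rxn.params["kb"]},
                enzyme=rxn.enzyme,
            )
        )
    return ReactionNetwork(list(net.species), reactions, dict(net.initial_ranges))


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    times: np.ndarray
    states: pd.DataFrame  # index = times, columns = species
    diagnostics: dict = field(default_factory=dict)

    def to_profile_matrix(self, floor: float | None = None) -> ProfileMatrix:
        values = self.states.copy()
        if floor is not None:
            values = values.clip(lower=floor)
        values.index = [f"t{t:g}" for t in self.times]
        return ProfileMatrix(values)


def default_time_grid(t_end: float = 1280.0, n_points: int = 21) -> np.ndarray:
    """t = 0 plus log-spaced points spanning [1, t_end] minutes."""
    return np.concatenate([[0.0], np.geomspace(1.0, t_end, n_points - 1)])


def simulate(
    net: ReactionNetwork,
    x0,
    t_grid=None,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate dx/dt = N v(x) and report states at the requested grid."""
    t_grid = default_time_grid() if t_grid is None else np.asarray(t_grid, float)
    if not np.all(np.diff(t_grid) > 0):
        raise ValueError("time grid must be strictly increasing")
    if isinstance(x0, dict):
        x0 = np.array([x0[sp] for sp in net.species], dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if (x0 < 0).any():
        raise ValueError("initial concentrations must be non-negative")
    N = net.stoichiometric_matrix

    def rhs(t, x):
        return N @ net.rates(np.maximum(x, 0.0))

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        x0,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"solver failure: {sol.message}")
    states = sol.y.T
    worst = states.min()
    if worst < -1e-9:
        logger.warning("negative excursion %.3e clipped to 0", worst)
    states = np.maximum(states, 0.0)
    final_ddt = rhs(t_grid[-1], states[-1])
    return Trajectory(
        times=t_grid,
        states=pd.DataFrame(states, index=t_grid, columns=net.species),
        diagnostics={
            "status": sol.status,
            "message": sol.message,
            "final_ddt_inf": float(np.abs(final_ddt).max()),
        },
    )


def steady_state(
    net: ReactionNetwork,
    x0,
    t_end: float = 1280.0,
    tol: float = SS_TOL,
    max_retries: int = 5,
    **solver_options,
) -> np.ndarray:
    """Integrate until ||dx/dt||_inf <= tol * (1 + ||x||_inf), doubling the horizon.

    Raises :class:`SteadyStateError` after ``max_retries`` horizon doublings.
    """
    if isinstance(x0, dict):
        x0 = np.array([x0[sp] for sp in net.species], dtype=float)
    x = np.asarray(x0, dtype=float)
    N = net.stoichiometric_matrix
    horizon = t_end
    for _ in range(max_retries + 1):
        traj = simulate(net, x, t_grid=np.array([0.0, horizon]), **solver_options)
        x = traj.states.iloc[-1].to_numpy()
        ddt = np.abs(N @ net.rates(x)).max()
        if ddt <= tol * (1.0 + np.abs(x).max()):
            return x
        horizon *= 2.0
    raise SteadyStateError(
        f"no steady state within tolerance after {max_retries} retries "
        f"(final ||dx/dt||_inf = {ddt:.3e})"
    )


def sample_ensemble(
    net: ReactionNetwork,
    ranges: dict[str, tuple[float, float]] | None = None,
    n_draws: int = 10,
    seed: int | None = None,
    mode: str = "endpoint",
    t_grid=None,
    t_end: float = 1280.0,
    **solver_options,
):
    """Simulate from random initial conditions drawn uniformly within ranges.

    ``mode="endpoint"`` returns a steady-state :class:`ProfileMatrix`
    (one row per successful draw; draws that never settle are excluded and
    logged); ``mode="timecourse"`` returns a list of :class:`Trajectory`
    sampled on ``t_grid`` (default: 0 plus 20 log-spaced points to 1280 min).
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    ranges = ranges if ranges is not None else net.initial_ranges
    missing = [sp for sp in net.species if sp not in ranges]
    if missing:
        raise ValueError(f"no initial range for species: {missing}")
    rng = np.random.default_rng(seed)
    lo = np.array([ranges[sp][0] for sp in net.species])
    hi = np.array([ranges[sp][1] for sp in net.species])
    draws = lo + (hi - lo) * rng.random((n_draws, net.n_species))

    if mode == "timecourse":
        grid = default_time_grid(t_end) if t_grid is None else np.asarray(t_grid)
        return [
            simulate(net, draws[d], t_grid=grid, **solver_options)
            for d in range(n_draws)
        ]
    if mode != "endpoint":
        raise ValueError(f"unknown ensemble mode {mode!r}")

    rows, kept = [], []
    for d in range(n_draws):
        try:
            rows.append(steady_state(net, draws[d], t_end=t_end, **solver_options))
            kept.append(d)
        except SteadyStateError as exc:
            logger.warning("draw %d excluded: %s", d, exc)
    if not rows:
        raise SteadyStateError("no draw reached a steady state")
    values = pd.DataFrame(
        np.vstack(rows),
        index=[f"draw{d}" for d in kept],
        columns=net.species,
    )
    meta = pd.DataFrame({"draw": kept}, index=values.index)
    return ProfileMatrix(values, meta)


def conserved_moieties(net: ReactionNetwork) -> np.ndarray:
    """Basis of left null vectors of N (conserved linear combinations).

    Computed exactly over the rationals; rows are the basis vectors.
    """
    import sympy

    N = sympy.Matrix(net.stoichiometric_matrix.astype(int))
    basis = N.T.nullspace()
    if not basis:
        return np.zeros((0, net.n_species))
    return np.array([[float(x) for x in vec] for vec in basis])


# ---------------------------------------------------------------------------
# fixtures


def fixture_toy_cycle(k=(1.0, 2.0, 1.5)) -> ReactionNetwork:
    """Closed 4-species cycle: S1 + S2 -(k1)-> S3 -(k2)-> S4 -(k3)-> S1 + S2.

    A mass-conserving single loop: at any positive steady state all three
    rates coincide, so k1*x1*x2 = k2*x3 = k3*x4 and the products x1*x2, x3
    and x4 are mutually proportional across steady states.
    """
    k1, k2, k3 = k
    return ReactionNetwork(
        species=["S1", "S2", "S3", "S4"],
        reactions=[
            Reaction("r1", {"S1": 1, "S2": 1}, {"S3": 1}, params={"k": k1}),
            Reaction("r2", {"S3": 1}, {"S4": 1}, params={"k": k2}),
            Reaction("r3", {"S4": 1}, {"S1": 1, "S2": 1}, params={"k": k3}),
        ],
        initial_ranges={sp: (0.1, 10.0) for sp in ("S1", "S2", "S3", "S4")},
    )


#: metabolites of the mini TCA loop (acetyl-CoA through malate)
TCA_MINI_SPECIES = [
    "accoa",
    "oaa",
    "cit",
    "aco",
    "icit",
    "osuc",
    "akg",
    "succoa",
    "succ",
    "fum",
    "mal",
]

_TCA_CHAIN = [
    ("r1", {"accoa": 1, "oaa": 1}, {"cit": 1}),
    ("r2", {"cit": 1}, {"aco": 1}),
    ("r3", {"aco": 1}, {"icit": 1}),
    ("r4", {"icit": 1}, {"osuc": 1}),
    ("r5", {"osuc": 1}, {"akg": 1}),
    ("r6", {"akg": 1}, {"succoa": 1}),
    ("r7", {"succoa": 1}, {"succ": 1}),
    ("r8", {"succ": 1}, {"fum": 1}),
    ("r9", {"fum": 1}, {"mal": 1}),
    ("r10", {"mal": 1}, {"oaa": 1, "accoa": 1}),
]

_TCA_K = [1.0, 0.8, 1.2, 0.9, 1.1, 0.7, 1.3, 0.6, 1.4, 1.0]


def fixture_tca_mini(kinetics: str = "mass_action") -> ReactionNetwork:
    """Single-loop 11-metabolite, 10-reaction cycle in three kinetic variants.

    The loop runs acetyl-CoA + oxaloacetate -> citrate -> ... -> malate and
    closes with malate -> oxaloacetate + acetyl-CoA, so exactly one reaction
    is bi-substrate.  Variants share the identical metabolite set:

    * ``mass_action``: irreversible mass action with rate constants 0.6-1.4;
    * ``enzyme_complex``: the mass-action loop with every reaction expanded
      into binding / unbinding / catalysis elementary steps (one enzyme per
      reaction, k_on = k_off = 100, k_cat = 1);
    * ``michaelis_menten``: reversible Michaelis-Menten (convenience)
      kinetics, vf as the mass-action constants, vr = 0.3 vf, all Km = 1.
    """
    ranges = {sp: (0.1, 10.0) for sp in TCA_MINI_SPECIES}
    if kinetics == "mass_action":
        reactions = [
            Reaction(name, dict(subs), dict(prods), params={"k": kk})
            for (name, subs, prods), kk in zip(_TCA_CHAIN, _TCA_K)
        ]
        return ReactionNetwork(list(TCA_MINI_SPECIES), reactions, ranges)
    if kinetics == "enzyme_complex":
        reactions = [
            Reaction(
                name, dict(subs), dict(prods), params={"k": kk}, enzyme=f"E_{name}"
            )
            for (name, subs, prods), kk in zip(_TCA_CHAIN, _TCA_K)
        ]
        base = ReactionNetwork(list(TCA_MINI_SPECIES), reactions, ranges)
        return expand_enzyme_complexes(base)
    if kinetics == "michaelis_menten":
        reactions = []
        for (name, subs, prods), kk in zip(_TCA_CHAIN, _TCA_K):
            params = {"vf": kk, "vr": 0.3 * kk}
            for sp in list(subs) + list(prods):
                params[f"km_{sp}"] = 1.0
            reactions.append(
                Reaction(name, dict(subs), dict(prods), "michaelis_menten", params)
            )
        return ReactionNetwork(list(TCA_MINI_SPECIES), reactions, ranges)
    raise ValueError(f"unknown kinetics variant {kinetics!r}")


# ---------------------------------------------------------------------------
# model definition files

_RXN_RE = re.compile(r"^reaction\s+(\w+)\s*:\s*(.+)$")


def _parse_complex(side: str) -> dict[str, int]:
    out: dict[str, int] = {}
    side = side.strip()
    if side in ("", "0"):
        return out
    for term in side.split("+"):
        term = term.strip()
        m = re.match(r"^(\d+)\s+(\S+)$", term)
        if m:
            out[m.group(2)] = out.get(m.group(2), 0) + int(m.group(1))
        else:
            out[term] = out.get(term, 0) + 1
    return out


def read_network(path) -> ReactionNetwork:
    """Parse the structured-text model format.

    Lines (``#`` comments ignored)::

        species: S1 S2 S3 S4
        range S1 0.1 10
        reaction r1: S1 + S2 -> S3 ; law=mass_action ; k=0.5
        reaction r2: A <-> B ; law=mass_action ; kf=1 ; kb=0.5
        reaction r3: A -> B ; law=michaelis_menten ; vf=1 ; vr=0.3 ; km_A=1 ; km_B=1 ; enzyme=E3
    """
    species: list[str] = []
    ranges: dict[str, tuple[float, float]] = {}
    reactions: list[Reaction] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                if line.startswith("species:"):
                    species.extend(line.split(":", 1)[1].split())
                elif line.startswith("range "):
                    _, sp, lo, hi = line.split()
                    ranges[sp] = (float(lo), float(hi))
                elif line.startswith("reaction"):
                    m = _RXN_RE.match(line)
                    if not m:
                        raise ValueError("malformed reaction line")
                    name, rest = m.groups()
                    parts = [p.strip() for p in rest.split(";")]
                    eq = parts[0]
                    reversible = "<->" in eq
                    lhs, rhs = re.split(r"<->|->", eq)
                    opts: dict[str, str] = {}
                    for p in parts[1:]:
                        key, val = p.split("=", 1)
                        opts[key.strip()] = val.strip()
                    law = opts.pop("law", "mass_action")
                    enzyme = opts.pop("enzyme", None)
                    params = {k: float(v) for k, v in opts.items()}
                    reactions.append(
                        Reaction(
                            name,
                            _parse_complex(lhs),
                            _parse_complex(rhs),
                            law,
                            params,
                            reversible=reversible,
                            enzyme=enzyme,
                        )
                    )
                else:
                    raise ValueError(f"unrecognized directive: {line.split()[0]}")
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not species:
        seen: list[str] = []
        for rxn in reactions:
            for sp in list(rxn.substrates) + list(rxn.products):
                if sp not in seen:
                    seen.append(sp)
        species = seen
    return ReactionNetwork(species, reactions, ranges)


def write_network(net: ReactionNetwork, path) -> None:
    def fmt(stoich: dict[str, int]) -> str:
        return " + ".join(
            (f"{a} {sp}" if a != 1 else sp) for sp, a in stoich.items()
        ) or "0"

    with open(path, "w") as fh:
        fh.write("species: " + " ".join(net.species) + "\n")
        for sp, (lo, hi) in net.initial_ranges.items():
            fh.write(f"range {sp} {lo:.17g} {hi:.17g}\n")
        for rxn in net.reactions:
            arrow = "<->" if rxn.reversible else "->"
            line = (
                f"reaction {rxn.name}: {fmt(rxn.substrates)} {arrow} "
                f"{fmt(rxn.products)} ; law={rxn.law}"
            )
            for key, val in rxn.params.items():
                line += f" ; {key}={val:.17g}"
            if rxn.enzyme:
                line += f" ; enzyme={rxn.enzyme}"
            fh.write(line + "\n")
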