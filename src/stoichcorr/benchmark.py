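"""Synthetic profile matrices with planted couplings, and recovery scoring.

Background metabolites are drawn i.i.d. log-normal with unit log-variance
(the multiplicative noise structure mass-action dynamics induces).  A
planted coupling fixes a split (U_p, U_q) with reduced integer weights
(beta, eta) and constructs the designated dependent member of U_q so that
eta . log(x_B) = beta . log(x_A) + eps with Gaussian eps on the log scale,
yielding a stoichiometric correlation of exactly one at zero noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profile_io import ProfileMatrix
from .significance import filter_significant

__all__ = [
    "PlantedCoupling",
    "PlantSpec",
    "generate",
    "score_recovery",
    "default_quadruple_spec",
]


@dataclass(frozen=True)
class PlantedCoupling:
    side_a: tuple[str, ...]
    side_b: tuple[str, ...]
    beta: tuple[int, ...]
    eta: tuple[int, ...]
    noise_sd: float = 0.01

    def __post_init__(self):
        if set(self.side_a) & set(self.side_b):
            raise ValueError("sides must be disjoint")
        if len(self.beta) != len(self.side_a) or len(self.eta) != len(self.side_b):
            raise ValueError("weight length mismatch")
        for w in self.beta + self.eta:
            if not (isinstance(w, int) and w >= 1):
                raise ValueError("weights must be positive integers")
        if len(self.beta) > 1 and math.gcd(*self.beta) != 1:
            raise ValueError("beta must be reduced (coprime)")
        if len(self.eta) > 1 and math.gcd(*self.eta) != 1:
            raise ValueError("eta must be reduced (coprime)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def dependent(self) -> str:
        """The side-B member solved from the coupling relation (the last one)."""
        return self.side_b[-1]


@dataclass
class PlantSpec:
    metabolites: list[str]
    plants: list[PlantedCoupling] = field(default_factory=list)
    n_samples: int = 50
    seed: int | None = None

    def __post_init__(self):
        if len(set(self.metabolites)) != len(self.metabolites):
            raise ValueError("duplicate metabolite names")
        known = set(self.metabolites)
        dependents = []
        for plant in self.plants:
            for m in plant.side_a + plant.side_b:
                if m not in known:
                    raise ValueError(f"planted split references unknown name {m!r}")
            dependents.append(plant.dependent)
        if len(set(dependents)) != len(dependents):
            raise ValueError("each plant needs a distinct dependent metabolite")
        for plant in self.plants:
            for m in plant.side_a + plant.side_b[:-1]:
                if m in dependents:
                    raise ValueError(
                        f"{m!r} is a dependent of one plant but a free member "
                        "of another"
                    )


def generate(spec: PlantSpec, seed: int | None = None):
    """Draw a profile matrix and its ground-truth table.

    Returns ``(ProfileMatrix, truth)`` where ``truth`` has one row per plant
    in the canonical orientation of the emitted column order (sides ordered
    by minimum column index, members ascending within a side).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = list(spec.metabolites)
    col = {m: i for i, m in enumerate(names)}
    n = spec.n_samples
    Z = pd.DataFrame(
        rng.standard_normal((n, len(names))), columns=names
    )  # log-scale values
    for plant in spec.plants:
        target = np.zeros(n)
        for m, w in zip(plant.side_a, plant.beta):
            target += w * Z[m].to_numpy()
        for m, w in zip(plant.side_b[:-1], plant.eta[:-1]):
            target -= w * Z[m].to_numpy()
        eps = rng.normal(0.0, plant.noise_sd, size=n) if plant.noise_sd else 0.0
        Z[plant.dependent] = (target + eps) / plant.eta[-1]

    values = np.exp(Z)
    values.index = [f"s{i}" for i in range(n)]
    matrix = ProfileMatrix(values)

    rows = []
    for plant in spec.plants:
        a = sorted(plant.side_a, key=col.get)
        b = sorted(plant.side_b, key=col.get)
        beta = tuple(w for _, w in sorted(zip(plant.side_a, plant.beta), key=lambda t: col[t[0]]))
        eta = tuple(w for _, w in sorted(zip(plant.side_b, plant.eta), key=lambda t: col[t[0]]))
        if col[b[0]] < col[a[0]]:
            a, b, beta, eta = b, a, eta, beta
        size = len(a) + len(b)
        rows.append(
            {
                "category": ("pair", "triplet", "quadruple")[size - 2],
                "side_A_members": tuple(a),
                "side_B_members": tuple(b),
                "beta": beta,
                "eta": eta,
                "noise_sd": plant.noise_sd,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=[
            "category",
            "side_A_members",
            "side_B_members",
            "beta",
            "eta",
            "noise_sd",
        ],
    )
    return matrix, truth


def score_recovery(
    results, truth: pd.DataFrame, tau: float = 0.95, alpha: float = 0.05
) -> dict:
    """Precision / recall / coefficient accuracy of planted-split recovery.

    A plant is recovered when its canonical split appears among the
    significant records (p_adj <= alpha, r >= tau); its coefficients are
    correct when the reduced weights match the planted ones.  With an empty
    significant set precision is reported as NaN.
    """
    from .profile_io import ResultTable

    records = results.records if isinstance(results, ResultTable) else results
    sig = filter_significant(records, alpha, tau)
    sig_map = {
        (tuple(a), tuple(b)): (tuple(bt), tuple(et))
        for a, b, bt, et in zip(
            sig["side_A_members"], sig["side_B_members"], sig["beta"], sig["eta"]
        )
    }
    planted_keys = {
        (tuple(a), tuple(b)): (tuple(bt), tuple(et))
        for a, b, bt, et in zip(
            truth["side_A_members"],
            truth["side_B_members"],
            truth["beta"],
            truth["eta"],
        )
    }
    recovered = [k for k in planted_keys if k in sig_map]
    correct = [k for k in recovered if sig_map[k] == planted_keys[k]]
    n_planted = len(planted_keys)
    n_sig = len(sig_map)
    return {
        "n_planted": n_planted,
        "n_significant": n_sig,
        "n_recovered": len(recovered),
        "recall": len(recovered) / n_planted if n_planted else float("nan"),
        "precision": len(recovered) / n_sig if n_sig else float("nan"),
        "coefficient_accuracy": (
            len(correct) / len(recovered) if recovered else float("nan")
        ),
    }


def default_quadruple_spec(
    n_samples: int = 50, noise_sd: float = 0.01, seed: int | None = None
) -> PlantSpec:
    """Twelve metabolites, five planted quadruple couplings.

    The dependent member of each planted side B is distinct; free members
    may be shared between plants, as metabolites in real networks are.
    """
    names = [f"M{i:02d}" for i in range(1, 13)]

    def plant(a, b, beta, eta):
        return PlantedCoupling(a, b, beta, eta, noise_sd)

    plants = [
        plant(("M01", "M02"), ("M03", "M08"), (1, 1), (1, 1)),
        plant(("M02", "M03"), ("M04", "M09"), (1, 2), (1, 1)),
        plant(("M04", "M05"), ("M06", "M10"), (2, 1), (1, 2)),
        plant(("M05", "M06"), ("M07", "M11"), (1, 3), (2, 1)),
        plant(("M01", "M07"), ("M02", "M12"), (3, 2), (1, 1)),
    ]
    return PlantSpec(names, plants, n_samples=n_samples, seed=seed)
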