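"""Embedded nuclear data and decay mathematics for Lu-177 and the Ac-225 cascade.

The two radionuclides compared by the pipeline are the pure beta/gamma
emitter lutetium-177 (T1/2 = 6.647 d, decaying to stable Hf-177) and
actinium-225 (T1/2 = 9.92 d), whose cascade emits four alpha particles
before terminating in quasi-stable Bi-209:

    Ac-225 -> Fr-221 -> At-217 -> Bi-213 -> (97.8% Po-213 | 2.2% Tl-209)
           -> Pb-209 -> Bi-209 (stable)

Per-emission data (mean energies and yields) are embedded as versioned
constants taken from a standard evaluated compilation (ICRP-107-like
values).  Beta emissions are represented by their mean energy; the
spectrum endpoint is carried alongside so that transport code can sample
an allowed-shape spectrum when the full energy distribution matters
(e.g. for long-range cross dose).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Emission",
    "NuclideStep",
    "DecayChain",
    "PARTICLE_CLASSES",
    "CHARGED_CLASSES",
    "load_chain",
    "bateman_activities",
    "bateman_atoms",
    "charged_energy_per_decay",
    "equilibrium_decay_weights",
    "equilibrium_time",
    "half_life_s",
]

PARTICLE_CLASSES = frozenset(
    {"alpha", "beta_mean", "conversion_auger_electron", "photon"}
)
#: particle classes that deposit energy locally (charged particles)
CHARGED_CLASSES = frozenset({"alpha", "beta_mean", "conversion_auger_electron"})

DAY = 86400.0
HOUR = 3600.0
MINUTE = 60.0


@dataclass(frozen=True)
class Emission:
    """A single emission line (or lumped emission group) of a nuclide.

    ``mean_energy_mev`` is the mean energy per emission; for beta groups
    ``endpoint_mev`` holds the spectrum endpoint used for spectral
    sampling, and ``mean_energy_mev`` the spectrum mean.
    """

    particle_class: str
    mean_energy_mev: float
    yield_per_decay: float
    endpoint_mev: float | None = None
    daughter_z: int | None = None  # atomic number after beta decay (Fermi factor)

    def __post_init__(self) -> None:
        if self.particle_class not in PARTICLE_CLASSES:
            raise ValueError(f"unknown particle class {self.particle_class!r}")
        if not self.mean_energy_mev > 0:
            raise ValueError("mean_energy_mev must be > 0")
        if not self.yield_per_decay > 0:
            raise ValueError("yield_per_decay must be > 0")


@dataclass(frozen=True)
class NuclideStep:
    """One nuclide in a decay chain.

    ``half_life_s`` is ``math.inf`` for a stable terminus, which must then
    carry no emissions and no daughters.  ``daughters`` lists
    ``(name, branching_fraction)`` pairs summing to 1 for radioactive steps.
    """

    name: str
    half_life_s: float
    emissions: tuple[Emission, ...] = ()
    daughters: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.stable:
            if self.emissions or self.daughters:
                raise ValueError(f"stable step {self.name} must be empty")
        else:
            if not self.half_life_s > 0:
                raise ValueError(f"{self.name}: half_life_s must be > 0")
            total = sum(f for _, f in self.daughters)
            if self.daughters and abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: branching fractions sum to {total}, not 1"
                )

    @property
    def stable(self) -> bool:
        return math.isinf(self.half_life_s)

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / T1/2 in 1/s (0 for a stable step)."""
        return 0.0 if self.stable else math.log(2.0) / self.half_life_s


@dataclass(frozen=True)
class DecayChain:
    """Ordered decay cascade starting at the parent nuclide."""

    steps: tuple[NuclideStep, ...]
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {s.name: i for i, s in enumerate(self.steps)}
        )
        for step in self.steps:
            for name, _ in step.daughters:
                if name not in self._index:
                    raise ValueError(
                        f"daughter {name} of {step.name} not in chain"
                    )

    @property
    def parent(self) -> NuclideStep:
        return self.steps[0]

    def __getitem__(self, name: str) -> NuclideStep:
        return self.steps[self._index[name]]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.steps)

    # --- serialization (JSON dialect) -------------------------------------
    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "name": s.name,
                    "half_life_s": None if s.stable else s.half_life_s,
                    "emissions": [
                        {
                            "class": e.particle_class,
                            "mev": e.mean_energy_mev,
                            "yield": e.yield_per_decay,
                            **(
                                {"endpoint_mev": e.endpoint_mev}
                                if e.endpoint_mev is not None
                                else {}
                            ),
                            **(
                                {"daughter_z": e.daughter_z}
                                if e.daughter_z is not None
                                else {}
                            ),
                        }
                        for e in s.emissions
                    ],
                    "daughters": [[n, f] for n, f in s.daughters],
                }
                for s in self.steps
            ]
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "DecayChain":
        steps = tuple(
            NuclideStep(
                name=s["name"],
                half_life_s=math.inf if s["half_life_s"] is None else s["half_life_s"],
                emissions=tuple(
                    Emission(
                        particle_class=e["class"],
                        mean_energy_mev=e["mev"],
                        yield_per_decay=e["yield"],
                        endpoint_mev=e.get("endpoint_mev"),
                        daughter_z=e.get("daughter_z"),
                    )
                    for e in s["emissions"]
                ),
                daughters=tuple((n, f) for n, f in s["daughters"]),
            )
            for s in data["steps"]
        )
        return cls(steps=steps)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DecayChain":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Embedded chain data
# ---------------------------------------------------------------------------
# Lutetium-177: beta groups (endpoint, mean, yield) for the three main
# branches plus lumped conversion/Auger electrons and the two main photons.
_LU177_STEPS = (
    NuclideStep(
        name="Lu-177",
        half_life_s=6.647 * DAY,
        emissions=(
            Emission("beta_mean", 0.1494, 0.793, endpoint_mev=0.4983, daughter_z=72),
            Emission("beta_mean", 0.1112, 0.090, endpoint_mev=0.3843, daughter_z=72),
            Emission("beta_mean", 0.0476, 0.117, endpoint_mev=0.1761, daughter_z=72),
            # lumped conversion electrons of the 113/208 keV transitions
            Emission("conversion_auger_electron", 0.0936, 0.065),
            Emission("conversion_auger_electron", 0.1946, 0.025),
            # lumped Auger cascade
            Emission("conversion_auger_electron", 0.0066, 0.50),
            Emission("photon", 0.2084, 0.1041),
            Emission("photon", 0.1130, 0.0620),
            Emission("photon", 0.055, 0.040),
        ),
        daughters=(("Hf-177", 1.0),),
    ),
    NuclideStep(name="Hf-177", half_life_s=math.inf),
)

# Actinium-225 cascade.  Alpha lines are branch-weighted mean energies per
# decaying nuclide; Bi-213 branches 97.8% beta (-> Po-213) / 2.2% alpha
# (-> Tl-209), both routes converging on Pb-209.
_AC225_STEPS = (
    NuclideStep(
        name="Ac-225",
        half_life_s=9.92 * DAY,
        emissions=(
            Emission("alpha", 5.79, 1.0),
            Emission("conversion_auger_electron", 0.0160, 1.0),
            Emission("photon", 0.019, 0.30),
        ),
        daughters=(("Fr-221", 1.0),),
    ),
    NuclideStep(
        name="Fr-221",
        half_life_s=4.80 * MINUTE,
        emissions=(
            Emission("alpha", 6.30, 1.0),
            Emission("conversion_auger_electron", 0.0100, 1.0),
            Emission("photon", 0.2183, 0.114),
        ),
        daughters=(("At-217", 1.0),),
    ),
    NuclideStep(
        name="At-217",
        half_life_s=32.3e-3,
        emissions=(Emission("alpha", 7.066, 1.0),),
        daughters=(("Bi-213", 1.0),),
    ),
    NuclideStep(
        name="Bi-213",
        half_life_s=45.6 * MINUTE,
        emissions=(
            Emission("beta_mean", 0.435, 0.978, endpoint_mev=1.423, daughter_z=84),
            Emission("alpha", 5.87, 0.022),
            Emission("conversion_auger_electron", 0.0100, 1.0),
            Emission("photon", 0.4405, 0.261),
        ),
        daughters=(("Po-213", 0.978), ("Tl-209", 0.022)),
    ),
    NuclideStep(
        name="Po-213",
        half_life_s=4.2e-6,
        emissions=(Emission("alpha", 8.376, 1.0),),
        daughters=(("Pb-209", 1.0),),
    ),
    NuclideStep(
        name="Tl-209",
        half_life_s=2.16 * MINUTE,
        emissions=(
            Emission("beta_mean", 0.659, 1.0, endpoint_mev=1.83, daughter_z=82),
            Emission("photon", 1.5670, 0.998),
            Emission("photon", 0.4651, 0.969),
        ),
        daughters=(("Pb-209", 1.0),),
    ),
    NuclideStep(
        name="Pb-209",
        half_life_s=3.28 * HOUR,
        emissions=(Emission("beta_mean", 0.198, 1.0, endpoint_mev=0.644, daughter_z=83),),
        daughters=(("Bi-209", 1.0),),
    ),
    # Bi-209 (T1/2 ~ 2e19 y) treated as the stable terminus
    NuclideStep(name="Bi-209", half_life_s=math.inf),
)

_CHAINS = {
    "Lu-177": DecayChain(steps=_LU177_STEPS),
    "Ac-225": DecayChain(steps=_AC225_STEPS),
}

#: physical half-lives of the parent radiolabels, seconds
PARENT_HALF_LIFE_S = {"Lu-177": 6.647 * DAY, "Ac-225": 9.92 * DAY}


class UnsupportedNuclideError(ValueError):
    """Raised when a decay chain is requested for an unknown parent."""


def load_chain(parent: str) -> DecayChain:
    """Return the embedded decay chain starting at ``parent``.

    Supported parents: ``"Lu-177"`` and ``"Ac-225"``.
    """
    try:
        return _CHAINS[parent]
    except KeyError:
        raise UnsupportedNuclideError(
            f"no embedded decay chain for {parent!r}; "
            f"supported parents: {sorted(_CHAINS)}"
        ) from None


def half_life_s(parent: str) -> float:
    """Physical half-life of the parent radiolabel in seconds."""
    try:
        return PARENT_HALF_LIFE_S[parent]
    except KeyError:
        raise UnsupportedNuclideError(f"unknown parent {parent!r}") from None


# ---------------------------------------------------------------------------
# Bateman solution with branching
# ---------------------------------------------------------------------------
def _paths(chain: DecayChain) -> dict[str, list[tuple[list[float], float]]]:
    """All decay paths parent->nuclide.

    Returns, per nuclide name, a list of ``(lambdas_along_path, branch_prob)``
    where ``lambdas_along_path`` includes the target nuclide's own decay
    constant as last element and ``branch_prob`` is the product of branching
    fractions along the path.
    """
    out: dict[str, list[tuple[list[float], float]]] = {}

    def walk(name: str, lambdas: list[float], prob: float) -> None:
        step = chain[name]
        lam = step.decay_constant
        path = lambdas + [lam]
        out.setdefault(name, []).append((path, prob))
        for dname, frac in step.daughters:
            walk(dname, path, prob * frac)

    walk(chain.parent.name, [], 1.0)
    return out


def _bateman_path_atoms(lambdas: np.ndarray, t: np.ndarray, n1_0: float) -> np.ndarray:
    """Atom count of the last member of a linear subchain (classic Bateman).

    ``lambdas`` are the decay constants along the path (branching fractions
    handled by the caller); values must be pairwise distinct.
    """
    lams = np.asarray(lambdas, dtype=float)
    n = lams.size
    if n == 1:
        return n1_0 * np.exp(-lams[0] * t)
    prefac = n1_0 * np.prod(lams[:-1])
    total = np.zeros_like(t, dtype=float)
    for j in range(n):
        denom = np.prod(np.delete(lams, j) - lams[j])
        total = total + np.exp(-lams[j] * t) / denom
    return prefac * total


def bateman_atoms(
    chain: DecayChain, t: float | np.ndarray, parent_atoms_0: float
) -> dict[str, np.ndarray | float]:
    """Atom counts of every chain member at time(s) ``t`` (s), closed form.

    Only the parent is present at t = 0.  Branching is handled by summing
    classic Bateman terms over all decay paths reaching each nuclide.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    paths = _paths(chain)
    out: dict[str, np.ndarray | float] = {}
    scalar = np.isscalar(t) or np.ndim(t) == 0
    for name in chain.names:
        total = np.zeros_like(t_arr)
        for lambdas, prob in paths[name]:
            total = total + prob * _bateman_path_atoms(
                np.asarray(lambdas), t_arr, parent_atoms_0
            )
        total = np.clip(total, 0.0, None)  # guard tiny negative round-off
        if name != chain.parent.name:
            total[t_arr == 0.0] = 0.0  # exact initial condition
        out[name] = float(total[0]) if scalar else total
    return out


def bateman_activities(
    chain: DecayChain, t: float | np.ndarray, parent_activity_0: float
) -> dict[str, np.ndarray | float]:
    """Activities (Bq) of every chain member at time(s) ``t`` in seconds.

    Closed-form Bateman solution with branching; only the parent is present
    at t = 0 with activity ``parent_activity_0``.
    """
    if parent_activity_0 < 0:
        raise ValueError("parent_activity_0 must be >= 0")
    lam_parent = chain.parent.decay_constant
    n0 = parent_activity_0 / lam_parent if lam_parent > 0 else 0.0
    atoms = bateman_atoms(chain, t, n0)
    return {
        name: chain[name].decay_constant * atoms[name] for name in chain.names
    }


def equilibrium_time(
    chain: DecayChain, daughter: str, level: float = 0.98
) -> float:
    """Time (s) for a direct daughter's activity to reach ``level`` of its
    equilibrium ratio to the parent.

    For a short-lived daughter d of a long-lived parent p the
    activity ratio grows as ``1 - exp(-(lambda_d - lambda_p) t)`` toward the
    transient-equilibrium value, so the crossing time is
    ``-ln(1 - level) / (lambda_d - lambda_p)``.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lam_p = chain.parent.decay_constant
    lam_d = chain[daughter].decay_constant
    if lam_d <= lam_p:
        raise ValueError("daughter must be shorter-lived than the parent")
    return -math.log(1.0 - level) / (lam_d - lam_p)


# ---------------------------------------------------------------------------
# Energy bookkeeping
# ---------------------------------------------------------------------------
def equilibrium_decay_weights(chain: DecayChain) -> dict[str, float]:
    """Decays of each chain member per parent decay at equilibrium.

    The weight of a nuclide is the total branching probability of reaching
    it from the parent (stable terminus included, with weight = probability
    of ever being produced).
    """
    paths = _paths(chain)
    return {name: sum(p for _, p in paths[name]) for name in chain.names}


def charged_energy_per_decay(
    chain: DecayChain, classes: Iterable[str] = CHARGED_CLASSES
) -> float:
    """Branching-weighted emitted energy (MeV) per parent decay at chain
    equilibrium, summed over the requested particle classes."""
    classes = set(classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    unknown = classes - PARTICLE_CLASSES
    if unknown:
        raise ValueError(f"unknown particle classes {sorted(unknown)}")
    weights = equilibrium_decay_weights(chain)
    total = 0.0
    for step in chain.steps:
        w = weights[step.name]
        for em in step.emissions:
            if em.particle_class in classes:
                total += w * em.yield_per_decay * em.mean_energy_mev
    return total


def alpha_transition_count(chain: DecayChain) -> float:
    """Branch-weighted number of alpha-emitting transitions per parent decay."""
    weights = equilibrium_decay_weights(chain)
    return sum(
        weights[s.name] * em.yield_per_decay
        for s in chain.steps
        for em in s.emissions
        if em.particle_class == "alpha"
    )
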