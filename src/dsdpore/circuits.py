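"""Mass-action kinetics of toehold-mediated strand-displacement (DSD) circuits.

This module models the two circuit architectures read out by the nanopore
pipeline:

* a **catalytic seesaw gate** — an input strand displaces a gate-bound,
  3'-biotinylated output strand (Input + Gate <-> Intermediate + Output); a
  fuel strand then displaces the input from the intermediate, recycling it
  (Fuel + Intermediate <-> Waste + Input), so one input molecule can release
  many outputs;
* a bank of **competitive miRNA probes** (let-7 style) — each miRNA input
  irreversibly displaces a barcoded output strand from its cognate probe,
  with optional off-diagonal crosstalk rates.

Concentrations are in micromolar (uM), time in seconds.  Bimolecular rate
constants are per-uM-per-second (1e5 M^-1 s^-1 == 0.1 uM^-1 s^-1, the typical
toehold-mediated displacement scale used as default).  Integration is done
with a stiff-capable adaptive solver (``scipy.integrate.solve_ivp``, LSODA).

Species may carry a *strand composition* (how many copies of each named
ssDNA strand they contain); every reaction must conserve strands, and the
resulting linear conservation laws are checkable on any trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Species",
    "Reaction",
    "CircuitSystem",
    "KineticsTrajectory",
    "SimulationError",
    "build_seesaw",
    "build_let7_system",
    "simulate",
    "load_circuit",
    "dump_circuit",
]

#: default bimolecular displacement rate, uM^-1 s^-1 (1e5 M^-1 s^-1)
DEFAULT_BIMOLECULAR_RATE = 0.1
#: default reverse/forward ratio for seesaw displacement steps.  Toehold
#: asymmetry biases displacement forward; a symmetric choice would cap the
#: catalytic displacement fraction well below 1 at the standard 0.5/2/0.2 uM
#: operating point, contrary to the near-complete turnover seesaw circuits
#: are designed for.
DEFAULT_REVERSIBILITY = 0.01

ROLES = {
    "input",
    "gate_complex",
    "output",
    "fuel",
    "intermediate",
    "waste",
    "probe",
    "helper",
    "reporter",
}


class SimulationError(RuntimeError):
    """Raised when the ODE integrator fails to meet tolerance."""


@dataclass(frozen=True)
class Species:
    """One molecular species of a DSD network.

    ``strands`` maps ssDNA strand identifiers to their copy number within
    the species (e.g. a gate complex contains one bottom strand and one
    output strand).  It is optional but enables strand-conservation checks.
    """

    name: str
    role: str
    initial_concentration: float  # uM
    strands: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown species role {self.role!r} for {self.name!r}")
        if not np.isfinite(self.initial_concentration) or self.initial_concentration < 0:
            raise ValueError(
                f"initial_concentration of species {self.name!r} must be >= 0, "
                f"got {self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """An elementary (uni- or bimolecular) mass-action reaction."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float  # s^-1 (unimolecular) or uM^-1 s^-1 (bimolecular)
    reversible: bool = False
    reverse_rate_constant: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= len(self.reactants) <= 2:
            raise ValueError("reactions must have 1 or 2 reactants")
        if not self.products:
            raise ValueError("reactions must have at least one product")
        if self.rate_constant < 0:
            raise ValueError(f"rate_constant must be >= 0, got {self.rate_constant}")
        if self.reverse_rate_constant < 0:
            raise ValueError(
                f"reverse_rate_constant must be >= 0, got {self.reverse_rate_constant}"
            )
        if self.reversible and not 1 <= len(self.products) <= 2:
            raise ValueError("reversible reactions need 1 or 2 products")


@dataclass
class CircuitSystem:
    """A named set of species plus the reactions connecting them."""

    species: dict[str, Species]
    reactions: list[Reaction]
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        names = set(self.species)
        if len(names) != len(self.species):
            raise ValueError("species names must be unique")
        for rxn in self.reactions:
            for s in (*rxn.reactants, *rxn.products):
                if s not in names:
                    raise ValueError(f"reaction references undeclared species {s!r}")
            self._check_strand_balance(rxn)

    def _check_strand_balance(self, rxn: Reaction) -> None:
        comps = [self.species[s].strands for s in (*rxn.reactants, *rxn.products)]
        if any(c is None for c in comps):
            return  # composition unknown; balance not checkable
        lhs: dict[str, int] = {}
        rhs: dict[str, int] = {}
        for s in rxn.reactants:
            for k, v in self.species[s].strands.items():  # type: ignore[union-attr]
                lhs[k] = lhs.get(k, 0) + v
        for s in rxn.products:
            for k, v in self.species[s].strands.items():  # type: ignore[union-attr]
                rhs[k] = rhs.get(k, 0) + v
        if lhs != rhs:
            raise ValueError(
                f"reaction {rxn.reactants} -> {rxn.products} does not conserve strands: "
                f"{lhs} != {rhs}"
            )

    @property
    def species_names(self) -> list[str]:
        return list(self.species)

    def initial_state(self) -> np.ndarray:
        return np.array([sp.initial_concentration for sp in self.species.values()])

    def strand_matrix(self) -> tuple[list[str], np.ndarray] | None:
        """Conservation matrix S (strands x species), or None if unannotated."""
        if any(sp.strands is None for sp in self.species.values()):
            return None
        strands = sorted({k for sp in self.species.values() for k in sp.strands})  # type: ignore[union-attr]
        mat = np.zeros((len(strands), len(self.species)))
        for j, sp in enumerate(self.species.values()):
            for k, v in sp.strands.items():  # type: ignore[union-attr]
                mat[strands.index(k), j] = v
        return strands, mat


@dataclass
class KineticsTrajectory:
    """Solution of a circuit simulation on a fixed output grid."""

    times: np.ndarray  # seconds, strictly increasing
    concentrations: pd.DataFrame  # one column per species, uM
    label: str = ""

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must align")

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[name].to_numpy()

    def to_tidy_csv(self, path) -> None:
        tidy = self.concentrations.copy()
        tidy.insert(0, "time_s", self.times)
        tidy = tidy.melt(id_vars="time_s", var_name="species", value_name="concentration_uM")
        tidy.to_csv(path, index=False)

    def conservation_error(self, system: CircuitSystem) -> float:
        """Max relative drift of any strand-conservation law over the run."""
        sm = system.strand_matrix()
        if sm is None:
            raise ValueError("system has no strand annotations")
        _, mat = sm
        totals = mat @ self.concentrations.to_numpy().T  # (strands, times)
        ref = totals[:, :1]
        scale = np.where(np.abs(ref) > 0, np.abs(ref), 1.0)
        return float(np.max(np.abs(totals - ref) / scale))


# ---------------------------------------------------------------------------
# Builders


def _require_nonneg(value: float, name: str) -> float:
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a non-negative finite number, got {value}")
    return float(value)


def build_seesaw(
    gate_conc: float,
    input_conc: float,
    fuel_conc: float,
    rates: Mapping[str, float] | None = None,
    leak_rate: float = 0.0,
    reporter_conc: float = 0.0,
    label: str = "seesaw",
) -> CircuitSystem:
    """Build the catalytic seesaw circuit.

    Reactions (all concentrations uM):

    1. ``input + gate <-> intermediate + output``  (toehold displacement)
    2. ``fuel + intermediate <-> waste + input``   (fuel exchange, recycles input)
    3. optional ``gate + reporter -> gate_reporter + quencher`` at ``leak_rate``
       — blunt-end stacking of the gate on a fluorophore/quencher reporter,
       which produces a spurious *fluorescent* signal but releases no free
       barcoded output (a direct nanopore readout is leak-free here).

    ``rates`` keys: ``k_displace``, ``k_displace_rev``, ``k_fuel``,
    ``k_fuel_rev`` (uM^-1 s^-1).  Defaults: forward 0.1, reverse 0.01x forward.
    """
    gate_conc = _require_nonneg(gate_conc, "gate_conc")
    input_conc = _require_nonneg(input_conc, "input_conc")
    fuel_conc = _require_nonneg(fuel_conc, "fuel_conc")
    reporter_conc = _require_nonneg(reporter_conc, "reporter_conc")
    leak_rate = _require_nonneg(leak_rate, "leak_rate")

    r = dict(rates or {})
    kd = _require_nonneg(r.pop("k_displace", DEFAULT_BIMOLECULAR_RATE), "k_displace")
    kdr = _require_nonneg(
        r.pop("k_displace_rev", kd * DEFAULT_REVERSIBILITY), "k_displace_rev"
    )
    kf = _require_nonneg(r.pop("k_fuel", DEFAULT_BIMOLECULAR_RATE), "k_fuel")
    kfr = _require_nonneg(r.pop("k_fuel_rev", kf * DEFAULT_REVERSIBILITY), "k_fuel_rev")
    if r:
        raise ValueError(f"unknown rate keys: {sorted(r)}")

    species = {
        "input": Species("input", "input", input_conc, {"in": 1}),
        "gate": Species("gate", "gate_complex", gate_conc, {"bottom": 1, "out": 1}),
        "output": Species("output", "output", 0.0, {"out": 1}),
        "intermediate": Species(
            "intermediate", "intermediate", 0.0, {"bottom": 1, "in": 1}
        ),
        "fuel": Species("fuel", "fuel", fuel_conc, {"fuel": 1}),
        "waste": Species("waste", "waste", 0.0, {"bottom": 1, "fuel": 1}),
        "reporter": Species(
            "reporter", "reporter", reporter_conc, {"rep_f": 1, "rep_q": 1}
        ),
    }
    reactions = [
        Reaction(("input", "gate"), ("intermediate", "output"), kd, True, kdr),
        Reaction(("fuel", "intermediate"), ("waste", "input"), kf, True, kfr),
    ]
    if leak_rate > 0:
        species["gate_reporter"] = Species(
            "gate_reporter", "waste", 0.0, {"bottom": 1, "out": 1, "rep_f": 1}
        )
        species["quencher"] = Species("quencher", "waste", 0.0, {"rep_q": 1})
        reactions.append(
            Reaction(("gate", "reporter"), ("gate_reporter", "quencher"), leak_rate)
        )
    return CircuitSystem(species, reactions, label=label)


def build_let7_system(
    probe_concs: Mapping[str, float],
    input_concs: Mapping[str, float],
    rate_matrix: np.ndarray,
    label: str = "let7",
) -> CircuitSystem:
    """Competitive SNV probe bank: one irreversible displacement per nonzero
    rate-matrix entry.

    ``rate_matrix[i, j]`` is the displacement rate (uM^-1 s^-1) of input *i*
    acting on probe *j*; off-diagonal entries encode crosstalk (e.g. a let-7e
    input slowly triggering the let-7a probe).  No fuel reactions: the probes
    are single-turnover by design.
    """
    inputs = list(input_concs)
    probes = list(probe_concs)
    rate_matrix = np.asarray(rate_matrix, dtype=float)
    if rate_matrix.shape != (len(inputs), len(probes)):
        raise ValueError(
            f"rate_matrix shape {rate_matrix.shape} does not match "
            f"({len(inputs)} inputs x {len(probes)} probes)"
        )
    if np.any(rate_matrix < 0):
        raise ValueError("rate_matrix entries must be >= 0")

    species: dict[str, Species] = {}
    for name in inputs:
        species[f"input_{name}"] = Species(
            f"input_{name}", "input", _require_nonneg(input_concs[name], name), {f"mi_{name}": 1}
        )
    for name in probes:
        species[f"probe_{name}"] = Species(
            f"probe_{name}",
            "probe",
            _require_nonneg(probe_concs[name], name),
            {f"bottom_{name}": 1, f"out_{name}": 1},
        )
        species[f"output_{name}"] = Species(
            f"output_{name}", "output", 0.0, {f"out_{name}": 1}
        )
    reactions = []
    for i, inp in enumerate(inputs):
        for j, prb in enumerate(probes):
            k = rate_matrix[i, j]
            if k == 0:
                continue
            duplex = f"duplex_{inp}_{prb}"
            species[duplex] = Species(
                duplex, "waste", 0.0, {f"bottom_{prb}": 1, f"mi_{inp}": 1}
            )
            reactions.append(
                Reaction(
                    (f"input_{inp}", f"probe_{prb}"),
                    (duplex, f"output_{prb}"),
                    float(k),
                )
            )
    return CircuitSystem(species, reactions, label=label)


# ---------------------------------------------------------------------------
# Simulation


def _rate_terms(system: CircuitSystem) -> list[tuple[tuple[int, ...], np.ndarray, float]]:
    """Flatten reactions into (reactant indices, stoichiometry vector, k)."""
    idx = {name: i for i, name in enumerate(system.species)}
    n = len(idx)
    terms = []
    for rxn in system.reactions:
        stoich = np.zeros(n)
        for s in rxn.reactants:
            stoich[idx[s]] -= 1
        for s in rxn.products:
            stoich[idx[s]] += 1
        terms.append((tuple(idx[s] for s in rxn.reactants), stoich, rxn.rate_constant))
        if rxn.reversible:
            terms.append(
                (tuple(idx[s] for s in rxn.products), -stoich, rxn.reverse_rate_constant)
            )
    return terms


def simulate(
    system: CircuitSystem,
    duration: float,
    step: float = 10.0,
    rtol: float = 1e-10,
    atol: float = 1e-13,
) -> KineticsTrajectory:
    """Integrate the mass-action ODEs of ``system`` on a fixed output grid.

    Raises :class:`SimulationError` if the solver fails; small negative
    excursions within integrator tolerance (|c| < 1e-9 uM) are zeroed, larger
    ones are treated as failure rather than silently clipped.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if step <= 0 or step > duration:
        raise ValueError(f"step must be in (0, duration], got {step}")

    terms = _rate_terms(system)
    y0 = system.initial_state()

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        yc = np.maximum(y, 0.0)  # guard mass-action law against tiny negatives
        for reactants, stoich, k in terms:
            if k == 0.0:
                continue
            flux = k
            for i in reactants:
                flux *= yc[i]
            dy += flux * stoich
        return dy

    t_eval = np.arange(0.0, duration + 0.5 * step, step)
    t_eval[-1] = min(t_eval[-1], duration)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        y0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"integrator failed: {sol.message}")
    y = sol.y
    if np.any(y < -1e-9):
        raise SimulationError(
            f"integrator produced negative concentration {y.min():.3e} uM"
        )
    y = np.clip(y, 0.0, None)
    frame = pd.DataFrame(y.T, columns=system.species_names)
    return KineticsTrajectory(sol.t, frame, label=system.label)


# ---------------------------------------------------------------------------
# Structured-config I/O (JSON or YAML)


def dump_circuit(system: CircuitSystem, path) -> None:
    doc = {
        "label": system.label,
        "species": [
            {
                "name": sp.name,
                "role": sp.role,
                "initial_concentration_uM": sp.initial_concentration,
                "strands": dict(sp.strands) if sp.strands else None,
            }
            for sp in system.species.values()
        ],
        "reactions": [
            {
                "reactants": list(r.reactants),
                "products": list(r.products),
                "rate_constant": r.rate_constant,
                "reversible": r.reversible,
                "reverse_rate_constant": r.reverse_rate_constant,
            }
            for r in system.reactions
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_circuit(path) -> CircuitSystem:
    text = open(path).read()
    if str(path).endswith((".yml", ".yaml")):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    species = {
        s["name"]: Species(
            s["name"],
            s["role"],
            s["initial_concentration_uM"],
            s.get("strands"),
        )
        for s in doc["species"]
    }
    reactions = [
        Reaction(
            tuple(r["reactants"]),
            tuple(r["products"]),
            r["rate_constant"],
            r.get("reversible", False),
            r.get("reverse_rate_constant", 0.0),
        )
        for r in doc["reactions"]
    ]
    return CircuitSystem(species, reactions, label=doc.get("label", ""))
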