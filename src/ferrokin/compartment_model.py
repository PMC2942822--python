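"""Whole-body linear tracer compartment model.

The mouse body is represented as 16 kinetically homogeneous iron pools
exchanging tracer at first-order (fractional clearance) rates, plus an
EXTERNAL sink collecting body losses.  Plasma (together with the
extravascular fluid, modelled as one pool) is the central compartment of a
mammillary layout: 13 plasma-to-organ edges, 10 organ-to-plasma reflux
edges, 3 body-exit edges and 3 irreversible erythron-chain edges
(bone marrow -> red blood cells -> spleen), 29 named rate constants in all.

Tracer content is expressed in percent of the injected dose and time in
days throughout.  The governing equations are linear with constant
coefficients, so trajectories are obtained from the matrix exponential
(exact up to floating point) rather than by numerical integration.
"""

from __future__ import annotations

import enum
import json
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "EXTERNAL",
    "BODY_COMPARTMENTS",
    "Diet",
    "Edge",
    "Topology",
    "RateConstants",
    "DietParameterSet",
    "TracerTrajectory",
    "InvalidParameterError",
    "build_topology",
    "rate_matrix",
    "simulate",
    "total_plasma_clearance",
    "load_table1",
    "diet_parameters",
    "topology_to_json",
    "to_sbml",
]

EXTERNAL = "EXTERNAL"

#: The 16 body compartments; plasma is the central (injection) compartment.
BODY_COMPARTMENTS: tuple[str, ...] = (
    "plasma",
    "bone_marrow",
    "rbc",
    "spleen",
    "liver",
    "kidney",
    "duodenum",
    "intestine",
    "stomach",
    "integument",
    "fat",
    "muscle",
    "lungs",
    "brain",
    "heart",
    "testes",
)

# (param_name, source, target) in canonical (parameter-table) order.
_EDGES: tuple[tuple[str, str, str], ...] = (
    ("kp_bon", "plasma", "bone_marrow"),
    ("kp_kid", "plasma", "kidney"),
    ("kp_int", "plasma", "intestine"),
    ("kp_liv", "plasma", "liver"),
    ("kp_sto", "plasma", "stomach"),
    ("kp_intg", "plasma", "integument"),
    ("kp_fat", "plasma", "fat"),
    ("kp_mus", "plasma", "muscle"),
    ("kp_lun", "plasma", "lungs"),
    ("kp_duo", "plasma", "duodenum"),
    ("kp_bra", "plasma", "brain"),
    ("kp_hea", "plasma", "heart"),
    ("kp_tes", "plasma", "testes"),
    ("kkid_p", "kidney", "plasma"),
    ("kliv_p", "liver", "plasma"),
    ("ksto_out", "stomach", EXTERNAL),
    ("kfat_p", "fat", "plasma"),
    ("kmus_p", "muscle", "plasma"),
    ("klun_p", "lungs", "plasma"),
    ("kbra_p", "brain", "plasma"),
    ("khea_p", "heart", "plasma"),
    ("ktes_p", "testes", "plasma"),
    ("kspl_p", "spleen", "plasma"),
    ("kintg_out", "integument", EXTERNAL),
    ("kint_out", "intestine", EXTERNAL),
    ("kduo_p", "duodenum", "plasma"),
    ("kbon_rbc", "bone_marrow", "rbc"),
    ("kbon_spl", "bone_marrow", "spleen"),
    ("krbc_spl", "rbc", "spleen"),
)

#: Names of the 13 plasma-to-organ clearance constants, in table order.
PLASMA_EXIT_PARAMS: tuple[str, ...] = tuple(p for p, s, _ in _EDGES if s == "plasma")


class Diet(str, enum.Enum):
    """Dietary iron states of the study."""

    DEFICIENT = "deficient"
    ADEQUATE = "adequate"
    LOADED = "loaded"

    @classmethod
    def coerce(cls, value: "Diet | str") -> "Diet":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(f"unknown diet {value!r}; expected one of "
                             f"{[d.value for d in cls]}") from None


class InvalidParameterError(ValueError):
    """A rate constant is missing, negative or non-finite."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    param: str


@dataclass(frozen=True)
class Topology:
    """Directed compartment graph: 16 body compartments + EXTERNAL sink."""

    compartments: tuple[str, ...]
    edges: tuple[Edge, ...]
    central: str = "plasma"
    cold_influx_sites: tuple[str, ...] = ("duodenum",)

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(e.param for e in self.edges)

    @property
    def plasma_exit_params(self) -> tuple[str, ...]:
        return tuple(e.param for e in self.edges if e.source == self.central)

    def index(self, compartment: str) -> int:
        return self.compartments.index(compartment)

    def exit_params(self, compartment: str) -> tuple[str, ...]:
        """All edges leaving ``compartment`` (including EXTERNAL exits)."""
        return tuple(e.param for e in self.edges if e.source == compartment)

    def influx_params(self, compartment: str) -> tuple[str, ...]:
        return tuple(e.param for e in self.edges if e.target == compartment)


@dataclass(frozen=True)
class RateConstants:
    """Named fractional clearance constants (1/day), the parameter vector."""

    values: Mapping[str, float]

    def __post_init__(self):
        clean = {}
        for name, v in dict(self.values).items():
            v = float(v)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(
                    f"rate {name!r} must be finite and >= 0, got {v}")
            clean[name] = v
        object.__setattr__(self, "values", clean)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def __iter__(self):
        return iter(self.values)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.values[p] for p in order], dtype=float)
        except KeyError as exc:
            raise InvalidParameterError(f"missing rate constant {exc}") from None

    def replace(self, **updates: float) -> "RateConstants":
        merged = {**self.values, **updates}
        return RateConstants(merged)

    @classmethod
    def from_array(cls, order: Sequence[str], values: Iterable[float]) -> "RateConstants":
        return cls(dict(zip(order, values, strict=True)))


@dataclass(frozen=True)
class DietParameterSet:
    """Best-fit rates with Monte-Carlo scatter bounds for one diet.

    ``anomalies`` lists parameters whose printed upper limit exceeds the
    best fit by more than tenfold (two such rows exist for the loaded
    diet); they are stored verbatim, not corrected.
    """

    diet: Diet
    best_fit: RateConstants
    lower: RateConstants
    upper: RateConstants
    anomalies: tuple[str, ...] = field(default=())

    def __post_init__(self):
        for p in self.best_fit:
            lo, hi, best = self.lower[p], self.upper[p], self.best_fit[p]
            if not (lo <= best <= hi):
                raise InvalidParameterError(
                    f"{self.diet.value}/{p}: best fit {best} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class TracerTrajectory:
    """Simulated tracer content per compartment over time (% of dose).

    ``external_loss`` is the cumulative share of the dose exported through
    the EXTERNAL sink, computed by whole-body balance.
    """

    times: np.ndarray
    compartments: tuple[str, ...]
    content: np.ndarray  # shape (n_times, n_compartments)
    external_loss: np.ndarray

    def __getitem__(self, compartment: str) -> np.ndarray:
        return self.content[:, self.compartments.index(compartment)]

    def total(self) -> np.ndarray:
        return self.content.sum(axis=1) + self.external_loss

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.content, columns=list(self.compartments))
        df.insert(0, "time_days", self.times)
        df["external_loss"] = self.external_loss
        return df

    def at(self, time: float, compartment: str) -> float:
        idx = np.flatnonzero(np.isclose(self.times, time))
        if idx.size == 0:
            raise KeyError(f"time {time} not on the trajectory grid")
        return float(self.content[idx[0], self.compartments.index(compartment)])


def build_topology() -> Topology:
    """Return the canonical 16+1-node, 29-edge compartment graph.

    Deterministic; spleen is fed only through the erythron chain (there is
    no direct plasma->spleen edge), and exactly stomach, integument and
    intestine lose tracer to EXTERNAL.
    """
    return Topology(
        compartments=BODY_COMPARTMENTS,
        edges=tuple(Edge(s, t, p) for p, s, t in _EDGES),
    )


def rate_matrix(topology: Topology, rates: RateConstants) -> np.ndarray:
    """Coefficient matrix A of dx/dt = A x over the body compartments.

    Off-diagonal A[i, j] is the rate of flow j -> i; the diagonal collects
    the negative total exit rate of each compartment, EXTERNAL included,
    so each column sums to minus that compartment's body-loss rate.
    """
    k = rates.as_array(topology.param_names)  # validates completeness
    n = len(topology.compartments)
    A = np.zeros((n, n))
    for edge, rate in zip(topology.edges, k):
        j = topology.index(edge.source)
        A[j, j] -= rate
        if edge.target != EXTERNAL:
            A[topology.index(edge.target), j] += rate
    return A


def _propagate(A: np.ndarray, x0: np.ndarray, times: np.ndarray) -> np.ndarray:
    """exp(A t) x0 on a time grid, by eigendecomposition when well
    conditioned, otherwise by incremental matrix exponentials."""
    try:
        w, V = np.linalg.eig(A)
        # a defective A (repeated eigenvalues, e.g. many zero rates) can
        # slip past a bare condition check; verify the reconstruction too
        recon_err = np.abs((V * w) @ np.linalg.inv(V) - A).max()
        scale = max(np.abs(A).max(), 1.0)
        if np.linalg.cond(V) < 1e8 and recon_err < 1e-10 * scale:
            c = np.linalg.solve(V, x0.astype(complex))
            X = np.real((np.exp(np.outer(times, w)) * c) @ V.T)
            X[times == 0] = x0
            return X
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        pass
    X = np.empty((len(times), len(x0)))
    x = x0.astype(float)
    prev = 0.0
    for i, t in enumerate(times):
        if t != prev:
            x = expm(A * (t - prev)) @ x
            prev = t
        X[i] = x
    return X


def simulate(
    topology: Topology,
    rates: RateConstants,
    times: Sequence[float],
    initial: Mapping[str, float] | None = None,
) -> TracerTrajectory:
    """Solve the linear tracer system on the requested time grid.

    By default 100% of the dose starts in plasma and every other
    compartment at zero.  ``external_loss`` is obtained by balance against
    the (conserved) initial total.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be ascending")

    x0 = np.zeros(len(topology.compartments))
    if initial is None:
        x0[topology.index(topology.central)] = 100.0
    else:
        for organ, amount in initial.items():
            x0[topology.index(organ)] = float(amount)

    A = rate_matrix(topology, rates)
    X = _propagate(A, x0, t)
    # clip solver noise, not genuine negativity
    X[(X < 0) & (X > -1e-9)] = 0.0
    loss = x0.sum() - X.sum(axis=1)
    return TracerTrajectory(times=t, compartments=topology.compartments,
                            content=X, external_loss=loss)


def total_plasma_clearance(rates: RateConstants) -> float:
    """Sum of the 13 plasma-to-organ clearance constants (1/day)."""
    return float(sum(rates[p] for p in PLASMA_EXIT_PARAMS))


# ---------------------------------------------------------------------------
# bundled parameter tables


def load_table1() -> pd.DataFrame:
    """The packaged parameter table (diet, param, best_fit, lower, upper)."""
    with resources.files("ferrokin").joinpath("data/table1.csv").open() as fh:
        return pd.read_csv(fh)


def diet_parameters(diet: Diet | str) -> DietParameterSet:
    """Bundled best-fit/lower/upper rate constants for one diet."""
    diet = Diet.coerce(diet)
    tab = load_table1()
    sub = tab[tab["diet"] == diet.value].set_index("param")
    if len(sub) != len(_EDGES):
        raise InvalidParameterError(
            f"parameter table for {diet.value} has {len(sub)} rows, expected {len(_EDGES)}")
    best = RateConstants(sub["best_fit"].to_dict())
    lower = RateConstants(sub["lower"].to_dict())
    upper = RateConstants(sub["upper"].to_dict())
    # flag rows whose printed upper limit is implausibly far above the best
    # fit (more than 20-fold); two such rows exist in the loaded column
    anomalies = tuple(
        p for p in best
        if best[p] > 0 and upper[p] / best[p] > 20.0
    )
    return DietParameterSet(diet=diet, best_fit=best, lower=lower,
                            upper=upper, anomalies=anomalies)


# ---------------------------------------------------------------------------
# serialization


def topology_to_json(topology: Topology, rates: RateConstants | None = None) -> str:
    doc = {
        "compartments": list(topology.compartments) + [EXTERNAL],
        "central": topology.central,
        "cold_influx_sites": list(topology.cold_influx_sites),
        "edges": [
            {"source": e.source, "target": e.target, "param": e.param}
            for e in topology.edges
        ],
    }
    if rates is not None:
        doc["params"] = dict(rates.values)
    return json.dumps(doc, indent=2, sort_keys=True)


def topology_from_json(text: str) -> tuple[Topology, RateConstants | None]:
    doc = json.loads(text)
    comps = tuple(c for c in doc["compartments"] if c != EXTERNAL)
    edges = tuple(Edge(e["source"], e["target"], e["param"]) for e in doc["edges"])
    topo = Topology(compartments=comps, edges=edges,
                    central=doc.get("central", "plasma"),
                    cold_influx_sites=tuple(doc.get("cold_influx_sites", ("duodenum",))))
    rates = RateConstants(doc["params"]) if "params" in doc else None
    return topo, rates


_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def to_sbml(topology: Topology, rates: RateConstants,
            model_id: str = "ferrokinetic_model") -> str:
    """Serialize the linear model to SBML Level 3 (write-only export).

    One species per body compartment, one irreversible first-order
    reaction per edge; EXTERNAL is a boundary species.
    """
    ET.register_namespace("", _SBML_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", level="3", version="2")
    model = ET.SubElement(sbml, f"{{{_SBML_NS}}}model",
                          id=model_id, timeUnits="time")
    comps = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    ET.SubElement(comps, f"{{{_SBML_NS}}}compartment", id="body",
                  constant="true", spatialDimensions="3", size="1")
    species = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for organ in topology.compartments:
        ET.SubElement(
            species, f"{{{_SBML_NS}}}species", id=organ, compartment="body",
            initialAmount="100" if organ == topology.central else "0",
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false")
    ET.SubElement(
        species, f"{{{_SBML_NS}}}species", id=EXTERNAL, compartment="body",
        initialAmount="0", hasOnlySubstanceUnits="true",
        boundaryCondition="true", constant="false")
    params = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    for name in topology.param_names:
        ET.SubElement(params, f"{{{_SBML_NS}}}parameter", id=name,
                      value=repr(rates[name]), constant="true")
    reactions = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for edge in topology.edges:
        rxn = ET.SubElement(reactions, f"{{{_SBML_NS}}}reaction",
                            id=f"flux_{edge.param}", reversible="false")
        reac = ET.SubElement(rxn, f"{{{_SBML_NS}}}listOfReactants")
        ET.SubElement(reac, f"{{{_SBML_NS}}}speciesReference",
                      species=edge.source, stoichiometry="1", constant="true")
        prod = ET.SubElement(rxn, f"{{{_SBML_NS}}}listOfProducts")
        ET.SubElement(prod, f"{{{_SBML_NS}}}speciesReference",
                      species=edge.target, stoichiometry="1", constant="true")
        law = ET.SubElement(rxn, f"{{{_SBML_NS}}}kineticLaw")
        math_el = ET.SubElement(law, f"{{{_MATHML_NS}}}math")
        apply_el = ET.SubElement(math_el, f"{{{_MATHML_NS}}}apply")
        ET.SubElement(apply_el, f"{{{_MATHML_NS}}}times")
        ci_k = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
        ci_k.text = f" {edge.param} "
        ci_x = ET.SubElement(apply_el, f"{{{_MATHML_NS}}}ci")
        ci_x.text = f" {edge.source} "
    ET.indent(sbml)
    return ET.tostring(sbml, encoding="unicode", xml_declaration=True)
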