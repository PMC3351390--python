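"""Declarative observed-variable path models and their covariance algebra.

A :class:`PathModel` is a causal hypothesis over a fixed set of observed,
standardized variables: directed edges carry path coefficients, bidirectional
edges carry covariances (between error terms when both endpoints are
endogenous), and equality groups tie several directed edges to a single free
parameter.  The model zoo encodes the twelve candidate structural-equation
models linking body mass (``mb``), basal and maximum metabolic rate (``BMR``,
``MMR``), body temperature (``T_b``) and intrinsic population growth rate
(``R_max``) that formalize the thermoregulatory (higher-body-temperature and
thermogenic-capacity variants) and parental-care hypotheses for the origin of
endothermy.

The implied covariance of a model at a parameter vector is the standard
observed-variable reduced form

    Sigma(theta) = (I - B)^-1 Psi (I - B)^-T

where ``B[t, s]`` holds the coefficient of the directed edge ``s -> t`` and
``Psi`` holds exogenous variances (fixed at 1 for standardized analysis),
endogenous error variances, and bidirectional-edge covariances.  Covariances
among variables not connected by any edge are fixed at zero, so an unconnected
variable (e.g. ``T_b`` in the thermogenic-capacity models) still contributes
its sample correlations to model misfit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "VARIABLES",
    "ZOO_IDS",
    "DirectedEdge",
    "BidirectedEdge",
    "Parameter",
    "PathModel",
    "SpecificationError",
    "build_model",
    "model_zoo",
    "implied_covariance",
    "count_df",
    "standardizing_error_variances",
    "model_to_dict",
    "model_from_dict",
]

#: Canonical variable order used for every matrix layout.
VARIABLES = ("mb", "BMR", "MMR", "T_b", "R_max")

#: Roman-numeral identifiers of the twelve candidate models.
ZOO_IDS = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")


class SpecificationError(ValueError):
    """A path model violates a structural constraint (unknown variable,
    duplicate edge, self-loop, malformed equality group...)."""


@dataclass(frozen=True)
class DirectedEdge:
    """A causal path ``source -> target`` with a unique label."""

    source: str
    target: str
    label: str


@dataclass(frozen=True)
class BidirectedEdge:
    """An unanalyzed covariance between two variables (their error terms
    when endogenous), drawn as a double-headed arrow."""

    var_a: str
    var_b: str
    label: str


@dataclass(frozen=True)
class Parameter:
    """One free parameter of a model.

    kind is ``"path"`` (directed-edge coefficient, possibly shared by an
    equality group), ``"cov"`` (bidirectional-edge covariance) or ``"var"``
    (error or free exogenous variance).  ``members`` lists the edge labels
    (path/cov) or the single variable (var) the parameter maps onto.
    """

    name: str
    kind: str
    members: tuple[str, ...]


def _group_name(labels: Iterable[str]) -> str:
    """Name an equality group by the longest common prefix of its member
    labels (stripped of trailing separators), so the reciprocal pair
    ``{"b3a", "b3b"}`` is reported as the single coefficient ``b3``."""
    labels = sorted(labels)
    prefix = labels[0]
    for lab in labels[1:]:
        while not lab.startswith(prefix):
            prefix = prefix[:-1]
    prefix = prefix.rstrip("_-")
    return prefix if prefix else "=".join(labels)


@dataclass(frozen=True)
class PathModel:
    """A validated observed-variable path model.

    Instances are created through :func:`build_model` (or :func:`model_zoo`),
    which performs all structural validation and fills in defaults.
    """

    variables: tuple[str, ...]
    directed_edges: tuple[DirectedEdge, ...]
    bidirectional_edges: tuple[BidirectedEdge, ...]
    equality_groups: tuple[frozenset[str], ...]
    fixed_unit_variance: frozenset[str]
    model_id: str | None = None

    # ------------------------------------------------------------------
    @property
    def endogenous(self) -> tuple[str, ...]:
        """Variables with at least one incoming directed edge, in canonical
        order."""
        targets = {e.target for e in self.directed_edges}
        return tuple(v for v in self.variables if v in targets)

    @property
    def exogenous(self) -> tuple[str, ...]:
        endo = set(self.endogenous)
        return tuple(v for v in self.variables if v not in endo)

    @property
    def is_recursive(self) -> bool:
        """True when the directed part is a DAG (no feedback loops)."""
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from((e.source, e.target) for e in self.directed_edges)
        return nx.is_directed_acyclic_graph(g)

    @property
    def free_parameters(self) -> tuple[Parameter, ...]:
        """Free parameters in a fixed, reproducible order: path coefficients
        (one per equality group, in first-edge order), covariances, then
        variances of every variable not fixed at unit variance."""
        label_to_group: dict[str, frozenset[str]] = {}
        for grp in self.equality_groups:
            for lab in grp:
                label_to_group[lab] = grp
        params: list[Parameter] = []
        seen: set[frozenset[str]] = set()
        for edge in self.directed_edges:
            grp = label_to_group.get(edge.label, frozenset([edge.label]))
            if grp in seen:
                continue
            seen.add(grp)
            name = _group_name(grp) if len(grp) > 1 else edge.label
            params.append(Parameter(name, "path", tuple(sorted(grp))))
        for edge in self.bidirectional_edges:
            params.append(Parameter(edge.label, "cov", (edge.label,)))
        for v in self.variables:
            if v not in self.fixed_unit_variance:
                params.append(Parameter(f"v_{v}", "var", (v,)))
        return tuple(params)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.free_parameters)

    def parameter_of_label(self, label: str) -> str:
        """Map a directed/bidirectional edge label to its parameter name."""
        for p in self.free_parameters:
            if p.kind in ("path", "cov") and label in p.members:
                return p.name
        raise KeyError(label)

    # ------------------------------------------------------------------
    def parents(self, v: str) -> tuple[str, ...]:
        return tuple(e.source for e in self.directed_edges if e.target == v)

    def structural_matrices(
        self, theta: Mapping[str, float]
    ) -> tuple[np.ndarray, np.ndarray]:
        """Assemble (B, Psi) at a parameter vector.

        ``theta`` maps every free-parameter name to a value; error variances
        are keyed ``v_<variable>``.
        """
        p = len(self.variables)
        idx = {v: i for i, v in enumerate(self.variables)}
        B = np.zeros((p, p))
        for edge in self.directed_edges:
            B[idx[edge.target], idx[edge.source]] = theta[
                self.parameter_of_label(edge.label)
            ]
        Psi = np.zeros((p, p))
        for v in self.variables:
            if v in self.fixed_unit_variance:
                Psi[idx[v], idx[v]] = 1.0
            else:
                Psi[idx[v], idx[v]] = theta[f"v_{v}"]
        for edge in self.bidirectional_edges:
            val = theta[self.parameter_of_label(edge.label)]
            i, j = idx[edge.var_a], idx[edge.var_b]
            Psi[i, j] = Psi[j, i] = val
        return B, Psi


# ----------------------------------------------------------------------
def build_model(
    variables: Sequence[str],
    directed_edges: Iterable[tuple[str, str, str]] = (),
    bidirectional_edges: Iterable[tuple[str, str, str]] = (),
    equality_groups: Iterable[Iterable[str]] = (),
    fixed_unit_variance: Iterable[str] | None = None,
    model_id: str | None = None,
) -> PathModel:
    """Validate and construct a :class:`PathModel`.

    Parameters
    ----------
    variables
        Ordered variable names; every edge endpoint must appear here.
    directed_edges
        ``(source, target, label)`` triples; labels must be unique across all
        edges and no ``(source, target)`` pair may repeat.
    bidirectional_edges
        ``(var_a, var_b, label)`` triples representing free covariances.
    equality_groups
        Iterables of directed-edge labels constrained to share one parameter
        value (e.g. a reciprocal pair).
    fixed_unit_variance
        Variables whose variance is fixed at 1.  Defaults to all exogenous
        variables (the standardized-analysis convention); endogenous variables
        may never appear here.
    """
    variables = tuple(variables)
    if len(set(variables)) != len(variables):
        raise SpecificationError("duplicate variable names")
    declared = set(variables)

    d_edges: list[DirectedEdge] = []
    labels: set[str] = set()
    pairs: set[tuple[str, str]] = set()
    for s, t, lab in directed_edges:
        if s not in declared or t not in declared:
            raise SpecificationError(f"edge {lab}: undeclared variable in ({s}, {t})")
        if s == t:
            raise SpecificationError(f"edge {lab}: self-loop on {s}")
        if lab in labels:
            raise SpecificationError(f"duplicate edge label {lab!r}")
        if (s, t) in pairs:
            raise SpecificationError(f"duplicate directed edge {s} -> {t}")
        labels.add(lab)
        pairs.add((s, t))
        d_edges.append(DirectedEdge(s, t, lab))

    b_edges: list[BidirectedEdge] = []
    upairs: set[frozenset[str]] = set()
    for a, b, lab in bidirectional_edges:
        if a not in declared or b not in declared:
            raise SpecificationError(f"edge {lab}: undeclared variable in ({a}, {b})")
        if a == b:
            raise SpecificationError(f"edge {lab}: self-loop on {a}")
        if lab in labels:
            raise SpecificationError(f"duplicate edge label {lab!r}")
        key = frozenset((a, b))
        if key in upairs:
            raise SpecificationError(f"duplicate bidirectional edge {a} <-> {b}")
        labels.add(lab)
        upairs.add(key)
        b_edges.append(BidirectedEdge(a, b, lab))

    directed_labels = {e.label for e in d_edges}
    groups: list[frozenset[str]] = []
    grouped: set[str] = set()
    for grp in equality_groups:
        grp = frozenset(grp)
        if len(grp) < 2:
            raise SpecificationError("equality group needs at least two labels")
        missing = grp - directed_labels
        if missing:
            raise SpecificationError(
                f"equality group references unknown directed-edge labels {sorted(missing)}"
            )
        if grp & grouped:
            raise SpecificationError("equality groups overlap")
        grouped |= grp
        groups.append(grp)

    endogenous = {e.target for e in d_edges}
    bidir_endpoints = {v for e in b_edges for v in (e.var_a, e.var_b)}
    if fixed_unit_variance is None:
        # A bidirectional-edge endpoint keeps a free variance even when it has
        # no incoming directed edge (it is a dependent variable of the model's
        # structural equations, its variance is not a fixed standardization).
        fixed = frozenset(declared - endogenous - bidir_endpoints)
    else:
        fixed = frozenset(fixed_unit_variance)
        if fixed - declared:
            raise SpecificationError("fixed_unit_variance references unknown variables")
        if fixed & endogenous:
            raise SpecificationError(
                "endogenous variables cannot have fixed unit variance"
            )

    return PathModel(
        variables=variables,
        directed_edges=tuple(d_edges),
        bidirectional_edges=tuple(b_edges),
        equality_groups=tuple(groups),
        fixed_unit_variance=fixed,
        model_id=model_id,
    )


# ----------------------------------------------------------------------
# The model zoo.  Directed-edge labels map onto fixed variable pairs:
#   b1: mb -> MMR      b2: mb -> BMR      b4: MMR -> R_max
#   b6: T_b -> R_max   b7: mb -> R_max    b8: BMR -> T_b
# b3 links BMR and MMR (default: equality-constrained reciprocal pair);
# b5 is always the BMR <-> R_max covariance (double-headed arrow).
_DIRECTED_SLOTS = {
    "b1": ("mb", "MMR"),
    "b2": ("mb", "BMR"),
    "b4": ("MMR", "R_max"),
    "b6": ("T_b", "R_max"),
    "b7": ("mb", "R_max"),
    "b8": ("BMR", "T_b"),
}

_ZOO: dict[str, tuple[str, ...]] = {
    "I": ("b1", "b2", "b3", "b6", "b7"),
    "II": ("b1", "b2", "b3", "b6"),
    "III": ("b1", "b2", "b3", "b6", "b7", "b8"),
    "IV": ("b1", "b2", "b3", "b6", "b8"),
    "V": ("b1", "b2", "b3", "b4", "b7"),
    "VI": ("b1", "b2", "b3", "b4"),
    "VII": ("b1", "b2", "b3", "b5", "b7"),
    "VIII": ("b1", "b2", "b3", "b5"),
    "IX": ("b1", "b2", "b3", "b4", "b5", "b6", "b7"),
    "X": ("b1", "b2", "b4", "b5", "b6"),
    "XI": ("b1", "b2", "b4", "b5", "b6", "b7"),
    "XII": ("b1", "b2", "b3", "b4", "b5", "b6"),
}


def model_zoo(model_id: str, b3: str = "reciprocal") -> PathModel:
    """Return one of the twelve candidate endothermy path models.

    Every model uses the full variable set ``(mb, BMR, MMR, T_b, R_max)``;
    variables not touched by any edge stay in the analyzed matrix with their
    covariances fixed at zero.

    Parameters
    ----------
    model_id
        Roman numeral ``"I"`` ... ``"XII"``.
    b3
        ``"reciprocal"`` (default) models the BMR-MMR link as an
        equality-constrained pair of directed edges (the literal structural
        equations); ``"covariance"`` models it as a free BMR<->MMR covariance.
        Both carry one free parameter, so degrees of freedom are identical.
    """
    if model_id not in _ZOO:
        raise KeyError(
            f"unknown model id {model_id!r}; expected one of {', '.join(ZOO_IDS)}"
        )
    if b3 not in ("reciprocal", "covariance"):
        raise ValueError("b3 must be 'reciprocal' or 'covariance'")
    slots = _ZOO[model_id]
    directed = [(_DIRECTED_SLOTS[s] + (s,)) for s in slots if s in _DIRECTED_SLOTS]
    bidirectional = []
    equality = []
    if "b3" in slots:
        if b3 == "reciprocal":
            directed.append(("MMR", "BMR", "b3a"))
            directed.append(("BMR", "MMR", "b3b"))
            equality.append(("b3a", "b3b"))
        else:
            bidirectional.append(("BMR", "MMR", "b3"))
    if "b5" in slots:
        bidirectional.append(("BMR", "R_max", "b5"))
    return build_model(
        VARIABLES,
        directed_edges=directed,
        bidirectional_edges=bidirectional,
        equality_groups=equality,
        model_id=model_id,
    )


# ----------------------------------------------------------------------
def implied_covariance(model: PathModel, theta: Mapping[str, float]) -> np.ndarray:
    """Model-implied covariance ``Sigma(theta) = (I-B)^-1 Psi (I-B)^-T``.

    Raises :class:`numpy.linalg.LinAlgError` when ``I - B`` is singular at
    ``theta`` (a feedback loop with product of coefficients equal to 1).
    """
    B, Psi = model.structural_matrices(theta)
    p = len(model.variables)
    IB = np.eye(p) - B
    if abs(np.linalg.det(IB)) < 1e-12:
        raise np.linalg.LinAlgError(
            f"singular (I - B) at theta={dict(theta)!r}"
        )
    A = np.linalg.inv(IB)
    Sigma = A @ Psi @ A.T
    return (Sigma + Sigma.T) / 2.0


def count_df(model: PathModel) -> int:
    """Model degrees of freedom: distinct covariance moments minus free
    parameters, ``p(p+1)/2 - t``."""
    p = len(model.variables)
    return p * (p + 1) // 2 - len(model.free_parameters)


def standardizing_error_variances(
    model: PathModel, theta_struct: Mapping[str, float]
) -> dict[str, float]:
    """Solve for the error variances that give every variable unit implied
    variance, given structural (path and covariance) parameter values.

    Returns a dict of ``v_<variable>`` entries.  Raises ``ValueError`` when no
    positive solution exists — e.g. a standardized single-predictor
    coefficient larger than 1 in magnitude leaves no room for an error
    variance.
    """
    free_vars = [v for v in model.variables if v not in model.fixed_unit_variance]
    theta = dict(theta_struct)
    for v in free_vars:
        theta[f"v_{v}"] = 0.0
    B, Psi0 = model.structural_matrices(theta)
    p = len(model.variables)
    idx = {v: i for i, v in enumerate(model.variables)}
    A = np.linalg.inv(np.eye(p) - B)
    base = np.diag(A @ Psi0 @ A.T)  # contribution of fixed variances + covariances
    rows = [idx[v] for v in free_vars]
    M = np.array([[A[i, idx[e]] ** 2 for e in free_vars] for i in rows])
    rhs = np.array([1.0 - base[i] for i in rows])
    sol = np.linalg.solve(M, rhs)
    if np.any(sol <= 0):
        bad = {v: s for v, s in zip(free_vars, sol) if s <= 0}
        raise ValueError(
            "no positive error variances standardize this model at these "
            f"coefficients (offending variables: {bad}); the implied "
            "covariance would not be positive definite"
        )
    return {f"v_{v}": float(s) for v, s in zip(free_vars, sol)}


# ----------------------------------------------------------------------
def model_to_dict(model: PathModel) -> dict:
    """Serialize to the JSON dialect ``{variables, edges, equality, ...}``."""
    edges = [
        {"from": e.source, "to": e.target, "label": e.label, "type": "directed"}
        for e in model.directed_edges
    ] + [
        {"from": e.var_a, "to": e.var_b, "label": e.label, "type": "bidirectional"}
        for e in model.bidirectional_edges
    ]
    return {
        "variables": list(model.variables),
        "edges": edges,
        "equality": [sorted(g) for g in model.equality_groups],
        "fixed_unit_variance": sorted(model.fixed_unit_variance),
        "model_id": model.model_id,
    }


def model_from_dict(d: Mapping) -> PathModel:
    directed = [
        (e["from"], e["to"], e["label"])
        for e in d["edges"]
        if e["type"] == "directed"
    ]
    bidirectional = [
        (e["from"], e["to"], e["label"])
        for e in d["edges"]
        if e["type"] == "bidirectional"
    ]
    return build_model(
        d["variables"],
        directed_edges=directed,
        bidirectional_edges=bidirectional,
        equality_groups=d.get("equality", ()),
        fixed_unit_variance=d.get("fixed_unit_variance"),
        model_id=d.get("model_id"),
    )


def model_to_json(model: PathModel, indent: int = 2) -> str:
    return json.dumps(model_to_dict(model), indent=indent)


def model_from_json(text: str) -> PathModel:
    return model_from_dict(json.loads(text))
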