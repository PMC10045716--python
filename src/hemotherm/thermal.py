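"""Layered tissue thermal RC network per body segment.

Each segment is a one-dimensional chain of tissue layers (head/torso: core,
bone, muscle, fat, skin; limbs and hand: bone, muscle, fat, skin).  A layer
contributes two serial resistance–capacitance elements (the epidermis is a
third serial element on the skin layer); a perfused layer's nodes are tied
to the arterial blood temperature T_b through the perfusion thermal
resistance R_Eq = 1/(ωρc), and the outermost node exchanges with the ambient
temperature T_a through the environment resistance REL = 1/h_t, with a large
parallel isolation-loss resistance Re.

Temperatures are in °C.  The steady state is an exact linear solve (the
capacitors are open); transients use unconditionally stable implicit Euler
steps.  All element values are areal (cm²·°C/W, J/cm²·°C) and converted to
absolute units with the segment's surface area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

from . import parameters
from .parameters import EnvironmentSpec, LayerThermalProps

BLOOD = "blood"
AMBIENT = "ambient"

#: layer stacks, innermost → outermost (dermis+epidermis form the skin layer)
LAYER_ORDER = {
    "head": ("core", "bone", "muscle", "fat", "dermis", "epidermis"),
    "torso": ("core", "bone", "muscle", "fat", "dermis", "epidermis"),
    "upper_limbs": ("bone", "muscle", "fat", "dermis", "epidermis"),
    "lower_limbs": ("bone", "muscle", "fat", "dermis", "epidermis"),
    "hand": ("bone", "muscle", "fat", "dermis", "epidermis"),
}
#: perfusion-table layer feeding each thermal layer (bone unperfused)
_PERFUSION_KEY = {"core": "core", "muscle": "muscle", "fat": "fat", "dermis": "skin"}


@dataclass
class SegmentSpec:
    """Geometry, properties and environment of one body segment."""

    name: str
    layers: list[LayerThermalProps]          # innermost → outermost
    area_cm2: float
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)
    thickness_scale: float = 1.0             # subject-specific multiplier on all layers

    def __post_init__(self) -> None:
        if self.area_cm2 <= 0:
            raise ValueError("segment area must be positive")
        if self.thickness_scale <= 0:
            raise ValueError("thickness scale must be positive")


@dataclass
class ThermalNode:
    name: str
    C: float                                  # J/°C, absolute
    sources: list[tuple[str, float]] = field(default_factory=list)  # (kind, R °C/W)


@dataclass
class ThermalEdge:
    i: int
    j: int
    r: float                                  # °C/W, absolute


@dataclass
class ThermalNetwork:
    """Node/edge graph with blood and ambient source attachments."""

    nodes: list[ThermalNode]
    edges: list[ThermalEdge]
    segment: str = ""
    skin_node: int = -1                       # outermost tissue node

    def node_index(self, name: str) -> int:
        for i, n in enumerate(self.nodes):
            if n.name == name:
                return i
        raise KeyError(f"unknown node {name!r}")

    def system(self, T_b: float, T_a: float) -> tuple[np.ndarray, np.ndarray]:
        """Conductance matrix G and source vector b of the resistive balance G·T = b."""
        n = len(self.nodes)
        G = np.zeros((n, n))
        b = np.zeros(n)
        for e in self.edges:
            g = 1.0 / e.r
            G[e.i, e.i] += g
            G[e.j, e.j] += g
            G[e.i, e.j] -= g
            G[e.j, e.i] -= g
        src = {BLOOD: T_b, AMBIENT: T_a}
        for i, node in enumerate(self.nodes):
            for kind, r in node.sources:
                if math.isinf(r):
                    continue
                G[i, i] += 1.0 / r
                b[i] += src[kind] / r
        return G, b

    def capacitances(self) -> np.ndarray:
        return np.array([n.C for n in self.nodes])

    def to_dict(self) -> dict:
        """JSON-serialisable dump for inspection and oracle testing."""
        return {
            "segment": self.segment,
            "skin_node": self.skin_node,
            "nodes": [{"name": n.name, "C_J_per_C": n.C,
                       "sources": [{"kind": k, "R_C_per_W": r} for k, r in n.sources]}
                      for n in self.nodes],
            "edges": [{"i": e.i, "j": e.j, "r_C_per_W": e.r} for e in self.edges],
        }


@dataclass
class TemperatureField:
    """Solved node temperatures of one segment network."""

    network: ThermalNetwork
    T: np.ndarray                              # °C per node

    @property
    def skin(self) -> float:
        return float(self.T[self.network.skin_node])

    @property
    def core(self) -> float:
        return float(self.T[0])


def default_segment_spec(name: str, environment: EnvironmentSpec | None = None,
                         thickness_scale: float = 1.0) -> SegmentSpec:
    """Segment built from the packaged property tables.

    Head, torso and limb layers carry the printed element values verbatim
    (they are the authoritative numbers for the default geometry).  The hand
    has no printed thermal rows: its elements are computed from r = l/λ and
    C = cρl using upper-limb layer properties and the hand's own layer
    thicknesses.
    """
    thermal = parameters.load_thermal_table()
    perf = parameters.load_perfusion_table()
    if name not in LAYER_ORDER:
        raise KeyError(f"unknown segment {name!r}")
    layers = []
    for layer in LAYER_ORDER[name]:
        if name == "hand":
            ref = thermal[("upper_limbs", layer)]
            if layer == "epidermis":
                props = ref  # verbatim epidermis element, common to all segments
            else:
                key = _PERFUSION_KEY.get(layer, layer)
                l_cm = perf.segment("hand").set_index("layer")["l_cm"][key]
                r, C = parameters.layer_elements(ref.lambda_, ref.rho, ref.c, float(l_cm))
                props = LayerThermalProps(name=layer, lambda_=ref.lambda_, rho=ref.rho,
                                          c=ref.c, l_cm=float(l_cm), r_elem=r, C_elem=C)
        else:
            props = thermal[(name, layer)]
        layers.append(props)
    env = environment if environment is not None else EnvironmentSpec()
    return SegmentSpec(name=name, layers=layers, area_cm2=perf.area(name),
                       environment=env, thickness_scale=thickness_scale)


def build_segment_network(spec: SegmentSpec, omega: dict[str, float],
                          rho_b: float = parameters.units.BLOOD_DENSITY,
                          c_b: float = parameters.units.BLOOD_SPECIFIC_HEAT) -> ThermalNetwork:
    """Assemble the RC graph of one segment.

    ``omega`` maps thermal layer name (core/muscle/fat/dermis) to its blood
    flow in mL/s; absent or zero entries leave that layer's blood branch
    open.  Each regular layer contributes two nodes; each node carries half
    the layer's blood-source conductance and the element resistance sits on
    the node's outward side, so the outermost element resistance is in
    series with the environment attachment.
    """
    if spec.environment is None:
        raise ValueError("segment spec is missing an environment")
    for v in omega.values():
        if v < 0:
            raise ValueError("layer perfusion must be non-negative")
    A = spec.area_cm2
    s = spec.thickness_scale
    nodes: list[ThermalNode] = []
    edges: list[ThermalEdge] = []
    prev = -1
    for props in spec.layers:
        n_elem = 1 if props.name == "epidermis" else 2
        w = omega.get(props.name, 0.0)
        for k in range(n_elem):
            C_abs = props.C_elem * s * A          # J/°C
            node = ThermalNode(name=f"{props.name}_{k + 1}", C=C_abs)
            if w > 0:
                r_src = n_elem * parameters.perfusion_source_resistance(w, rho_b, c_b)
                node.sources.append((BLOOD, r_src))
            nodes.append(node)
            idx = len(nodes) - 1
            if prev >= 0:
                # inward element resistance of the previous element
                edges.append(ThermalEdge(prev, idx, r_prev))
            r_prev = props.r_elem * s / A          # °C/W, outward side of this element
            prev = idx
    env = spec.environment
    rel_abs = env.REL_cm2 / A
    re_abs = env.Re_cm2 / A
    r_env = r_prev + rel_abs * re_abs / (rel_abs + re_abs)
    nodes[prev].sources.append((AMBIENT, r_env))
    net = ThermalNetwork(nodes=nodes, edges=edges, segment=spec.name, skin_node=prev)
    _check_connected(net)
    return net


def _check_connected(net: ThermalNetwork) -> None:
    n = len(net.nodes)
    reach = [bool(node.sources) for node in net.nodes]
    adj: list[list[int]] = [[] for _ in range(n)]
    for e in net.edges:
        adj[e.i].append(e.j)
        adj[e.j].append(e.i)
    stack = [i for i in range(n) if reach[i]]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if not reach[j]:
                reach[j] = True
                stack.append(j)
    for i, ok in enumerate(reach):
        if not ok:
            raise ValueError(f"node {net.nodes[i].name!r} is isolated from every source")


def steady_state(net: ThermalNetwork, T_b: float, T_a: float) -> TemperatureField:
    """Exact steady-state solve of the resistive balance (capacitors open).

    At every node Σ_edges (T_n − T_k)/r + Σ_sources (T_src − T_k)/R = 0.
    """
    if not (math.isfinite(T_b) and math.isfinite(T_a)):
        raise ValueError("source temperatures must be finite")
    G, b = net.system(T_b, T_a)
    try:
        T = np.linalg.solve(G, b)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"singular thermal network for segment {net.segment!r}") from err
    return TemperatureField(network=net, T=T)


def transient(net: ThermalNetwork, T0: np.ndarray, T_b: float, T_a: float,
              duration: float, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Implicit-Euler integration of C_k dT_k/dt = Σ inflows.

    Returns (times, fields) with fields of shape (n_times, n_nodes); the
    scheme is unconditionally stable and relaxes to the steady_state
    solution for long horizons.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    G, b = net.system(T_b, T_a)
    C = net.capacitances()
    n_steps = max(1, int(round(duration / dt)))
    A = np.diag(C / dt) + G
    lu_piv = np.linalg.inv(A)  # small dense systems; reuse across steps
    T = np.array(T0, dtype=float)
    if T.shape != C.shape:
        raise ValueError("initial field has wrong length")
    out = np.empty((n_steps + 1, C.size))
    out[0] = T
    for k in range(n_steps):
        T = lu_piv @ (C / dt * T + b)
        out[k + 1] = T
    times = np.arange(n_steps + 1) * dt
    return times, out


def skin_temperature(field: TemperatureField, segment: str | None = None) -> float:
    """Outermost (epidermis-side) node temperature of the segment, °C."""
    if segment is not None and field.network.segment != segment:
        raise KeyError(f"field belongs to segment {field.network.segment!r}, "
                       f"not {segment!r}")
    return field.skin


def slowest_time_constant(net: ThermalNetwork) -> float:
    """Largest RC time constant (s), from the generalised eigenproblem G·v = λ·C·v."""
    G, _ = net.system(0.0, 0.0)
    C = net.capacitances()
    lam = np.linalg.eigvalsh(np.diag(1.0 / np.sqrt(C)) @ G @ np.diag(1.0 / np.sqrt(C)))
    lam = lam[lam > 1e-15]
    return float(1.0 / lam.min())
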