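"""Network geometry of the two-system (core/matrix) thalamocortical model.

The model is a one-dimensional strip.  Each of three cortical layers
(L3/4, L5, L6) holds pyramidal cells (PY) and interneurons (IN); the
thalamus holds relay (TC) and reticular (RE) cells split into two systems
that never connect to each other inside the thalamus:

* **core**: focal loop -- core TC cells excite L3/4 (PY and IN), and L6 PY
  cells project back to core TC and RE cells;
* **matrix**: diffuse loop -- matrix TC cells excite the distal dendrites of
  L5 PY cells (and L5 IN), and L5 PY cells project back to matrix TC/RE.

Fanout is geometric: populations of different sizes are mapped onto a
common axis by normalizing index by population size, and a projection with
radius ``r`` (in source-index units) reaches every target whose scaled
position lies within ``r`` source spacings of the source's position,
truncated at the strip edges (no wraparound).  At the default 1000 PY per
layer vs 200 TC per system this gives the familiar 5:1 index scaling.

Synaptic strengths are specified as the *total* conductance a target
receives from a given (source type, receptor) connection; the per-synapse
weight is that total divided by the number of inputs the target actually
receives ("input normalization").  Broadening a projection therefore makes
each of its synapses proportionally weaker -- the mechanism behind the weak
diffuse matrix vs strong focal core contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "ConnectionRule",
    "NetworkSpec",
    "Network",
    "fanout_targets",
    "normalize_weight",
    "baseline_rules",
    "build_network",
    "CORTICAL_LAYERS",
    "THALAMIC_SYSTEMS",
]

CORTICAL_LAYERS = ("L34", "L5", "L6")
THALAMIC_SYSTEMS = ("core", "matrix")
RECEPTORS = ("AMPA", "NMDA", "GABA_A", "GABA_B")

#: populations whose thalamic system must stay isolated from the other
_CORE_THAL = {"TC_core", "RE_core"}
_MATRIX_THAL = {"TC_matrix", "RE_matrix"}


@dataclass(frozen=True)
class Population:
    name: str
    size: int

    @property
    def cell_class(self) -> str:
        return self.name.split("_")[0]


@dataclass(frozen=True)
class ConnectionRule:
    """One projection: source population -> target population via a receptor."""

    source: str
    target: str
    receptor: str
    radius: float            # fanout radius in source-index units
    g_total: float           # total conductance per target (uS)
    normalize: bool = True
    depressing: bool = False
    minis: bool = False
    e_syn: float | None = None  # reversal override (defaults by receptor/target)

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be non-negative")
        if self.g_total < 0:
            raise ValueError("g_total must be non-negative")
        if self.receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {self.receptor!r}")


# Total conductances (uS) of each connection type in the baseline model.
DEFAULT_CONDUCTANCES: dict[str, float] = {
    "py_py_ampa": 0.6,
    "py_py_nmda": 0.06,
    "py_in_ampa": 0.2,
    "py_in_nmda": 0.08,
    "in_py_gabaa": 0.15,
    "inter_py_py_ampa": 0.3,   # between-layer PY->PY; half the within-layer value
    "inter_py_py_nmda": 0.03,  # half of within-layer NMDA (see NetworkSpec)
    "py_tc_ampa": 0.05,
    "py_re_ampa": 0.15,
    "tc_py_ampa": 0.15,
    "tc_in_ampa": 0.1,
    "re_re_gabaa": 0.1,
    "re_tc_gabaa": 0.06,
    "re_tc_gabab": 0.0025,
    "tc_re_ampa": 0.06,
}


@dataclass(frozen=True)
class NetworkSpec:
    """Sizes, radii and strengths defining one network realization.

    Radii follow the source-index-unit convention: thalamocortical radii are
    in thalamic units, corticothalamic radii in cortical units, matching the
    quadruple (core TC->L3/4, L6->core TC, matrix TC->L5, L5->matrix TC) =
    (10, 2, 100, 20) of the baseline model (fanout ratio 10).

    ``n_in_per_layer`` defaults to 200 interneurons in each of the three
    layers; a 400-total variant (200 in two populations) is not expressible
    with three layers, so the per-layer count is simply configurable.

    ``interlaminar_nmda_printed`` switches the between-layer NMDA total to
    0.75 uS; the default 0.03 uS keeps the interlaminar strengths at half
    their within-layer values, consistent with how the interlaminar sweep is
    parameterized (100% = half the intralaminar strength).
    """

    n_py_per_layer: int = 1000
    n_in_per_layer: int = 200
    n_tc_per_system: int = 200
    n_re_per_system: int = 200
    radius_tc_core: float = 10.0
    radius_ct_core: float = 2.0
    radius_tc_matrix: float = 100.0
    radius_ct_matrix: float = 20.0
    radius_py_py: float = 5.0
    radius_py_in: float = 1.0
    radius_in_py: float = 5.0
    radius_thal: float = 5.0
    interlaminar_up: float = 1.0    # L3/4 -> L5 strength, 1.0 = baseline (half intralaminar)
    interlaminar_down: float = 1.0  # L5 -> L3/4 strength
    interlaminar_nmda_printed: bool = False
    normalize: bool = True
    conductances: dict = field(default_factory=lambda: dict(DEFAULT_CONDUCTANCES))

    @property
    def fanout_ratio(self) -> float:
        return self.radius_tc_matrix / self.radius_tc_core

    def with_fanout_ratio(self, ratio: float) -> "NetworkSpec":
        """Scale the matrix radii to ``ratio`` times the (fixed) core radii."""
        return replace(
            self,
            radius_tc_matrix=self.radius_tc_core * ratio,
            radius_ct_matrix=self.radius_ct_core * ratio,
        )

    def scaled(self, factor: float) -> "NetworkSpec":
        """Desk-scale variant: divide population sizes and the printed
        thalamocortical radii by ``factor``.

        The intracortical radii are kept in absolute units: spindle
        initiation depends on the absolute number of locally summing inputs,
        which proportional scaling would destroy in small networks.  The
        intrathalamic radius scales with the network but is floored at 2
        cells so the TC-RE loop keeps a minimal local neighborhood; without
        the scaling, thalamic spindles span the whole strip in small
        networks and the core/matrix locality contrast disappears.

        The corticothalamic radii are also kept absolute: they set how many
        cortical inputs a thalamic cell integrates (5 for the focal core,
        41 for the diffuse matrix), i.e. the amount of local cortical
        synchrony needed to ignite a spindle.  Scaling them down would give
        every TC cell a single full-weight input (initiation by lone
        spikes) and erase the core/matrix recruitment-threshold contrast.
        """
        return replace(
            self,
            n_py_per_layer=max(int(round(self.n_py_per_layer / factor)), 1),
            n_in_per_layer=max(int(round(self.n_in_per_layer / factor)), 1),
            n_tc_per_system=max(int(round(self.n_tc_per_system / factor)), 1),
            n_re_per_system=max(int(round(self.n_re_per_system / factor)), 1),
            radius_tc_core=self.radius_tc_core / factor,
            radius_tc_matrix=self.radius_tc_matrix / factor,
            radius_thal=max(self.radius_thal / factor, 2.0),
        )

    def populations(self) -> list[Population]:
        pops = []
        for layer in CORTICAL_LAYERS:
            pops.append(Population(f"PY_{layer}", self.n_py_per_layer))
        for layer in CORTICAL_LAYERS:
            pops.append(Population(f"IN_{layer}", self.n_in_per_layer))
        for system in THALAMIC_SYSTEMS:
            pops.append(Population(f"TC_{system}", self.n_tc_per_system))
        for system in THALAMIC_SYSTEMS:
            pops.append(Population(f"RE_{system}", self.n_re_per_system))
        return pops


def fanout_targets(
    source_index: int,
    radius: float,
    source_size: int,
    target_size: int,
    exclude_self: bool = False,
) -> np.ndarray:
    """Indices of all targets within ``radius`` source units of the source.

    Both populations are mapped to a common axis (position = index / size);
    target ``j`` is reached iff ``|j/Nt - i/Ns| <= radius/Ns``, i.e.
    ``|j*Ns - i*Nt| <= radius*Nt``.  Ranges are truncated at the strip
    edges.  The returned array may be empty when the radius is below the
    scaling quantum (``Ns/Nt`` target spacings); receiving-side coverage
    should be audited via :meth:`Network.input_counts`.
    """
    if not 0 <= source_index < source_size:
        raise ValueError(f"source index {source_index} outside [0, {source_size})")
    eps = 1e-9
    lo = math.ceil((source_index - radius) * target_size / source_size - eps)
    hi = math.floor((source_index + radius) * target_size / source_size + eps)
    lo, hi = max(lo, 0), min(hi, target_size - 1)
    if hi < lo:
        return np.empty(0, dtype=np.int64)
    out = np.arange(lo, hi + 1, dtype=np.int64)
    if exclude_self:
        out = out[out != source_index]
    return out


def normalize_weight(g_total: float, n_inputs: int) -> float:
    """Per-synapse conductance: total strength split across actual inputs."""
    if n_inputs < 1:
        raise ValueError("target receives no inputs; per-synapse weight undefined")
    return g_total / n_inputs


def _gaba_a_reversal(target: str) -> float:
    # TC cells: -85 mV (the deeper chloride reversal of the thalamic relay
    # literature; required for post-inhibitory rebound given the adopted
    # kinetics -- see docs/methods.md), RE and cortical targets: -70 mV
    return -85.0 if target.startswith("TC") else -70.0


def _default_reversal(rule: ConnectionRule) -> float:
    if rule.e_syn is not None:
        return rule.e_syn
    if rule.receptor in ("AMPA", "NMDA"):
        return 0.0
    if rule.receptor == "GABA_A":
        return _gaba_a_reversal(rule.target)
    return -95.0  # GABA_B


def baseline_rules(spec: NetworkSpec) -> list[ConnectionRule]:
    """The full wiring diagram of the baseline two-system model."""
    g = spec.conductances
    rules: list[ConnectionRule] = []
    norm = spec.normalize

    for layer in CORTICAL_LAYERS:
        py, inh = f"PY_{layer}", f"IN_{layer}"
        rules += [
            ConnectionRule(py, py, "AMPA", spec.radius_py_py, g["py_py_ampa"],
                           norm, depressing=True, minis=True),
            ConnectionRule(py, py, "NMDA", spec.radius_py_py, g["py_py_nmda"],
                           norm, depressing=True),
            ConnectionRule(py, inh, "AMPA", spec.radius_py_in, g["py_in_ampa"],
                           norm, minis=True),
            ConnectionRule(py, inh, "NMDA", spec.radius_py_in, g["py_in_nmda"], norm),
            ConnectionRule(inh, py, "GABA_A", spec.radius_in_py, g["in_py_gabaa"],
                           norm, minis=True),
        ]

    # interlaminar excitation (L3/4 <-> L5); totals are half the intralaminar
    # values at the 100% setting, scaled by the sweep multipliers
    nmda_inter = 0.75 if spec.interlaminar_nmda_printed else g["inter_py_py_nmda"]
    for src, dst, scale in (
        ("PY_L34", "PY_L5", spec.interlaminar_up),
        ("PY_L5", "PY_L34", spec.interlaminar_down),
    ):
        rules += [
            ConnectionRule(src, dst, "AMPA", spec.radius_py_py,
                           g["inter_py_py_ampa"] * scale, norm,
                           depressing=True, minis=True),
            ConnectionRule(src, dst, "NMDA", spec.radius_py_py,
                           nmda_inter * scale, norm, depressing=True),
        ]

    # core loop: TC_core -> L3/4, L6 -> core thalamus
    rules += [
        ConnectionRule("TC_core", "PY_L34", "AMPA", spec.radius_tc_core,
                       g["tc_py_ampa"], norm),
        ConnectionRule("TC_core", "IN_L34", "AMPA", spec.radius_tc_core,
                       g["tc_in_ampa"], norm),
        ConnectionRule("PY_L6", "TC_core", "AMPA", spec.radius_ct_core,
                       g["py_tc_ampa"], norm),
        ConnectionRule("PY_L6", "RE_core", "AMPA", spec.radius_ct_core,
                       g["py_re_ampa"], norm),
    ]
    # matrix loop: TC_matrix -> L5 apical dendrites, L5 -> matrix thalamus
    rules += [
        ConnectionRule("TC_matrix", "PY_L5", "AMPA", spec.radius_tc_matrix,
                       g["tc_py_ampa"], norm),
        ConnectionRule("TC_matrix", "IN_L5", "AMPA", spec.radius_tc_matrix,
                       g["tc_in_ampa"], norm),
        ConnectionRule("PY_L5", "TC_matrix", "AMPA", spec.radius_ct_matrix,
                       g["py_tc_ampa"], norm),
        ConnectionRule("PY_L5", "RE_matrix", "AMPA", spec.radius_ct_matrix,
                       g["py_re_ampa"], norm),
    ]

    # intrathalamic loops, strictly within each system
    for system in THALAMIC_SYSTEMS:
        tc, re = f"TC_{system}", f"RE_{system}"
        rules += [
            ConnectionRule(tc, re, "AMPA", spec.radius_thal, g["tc_re_ampa"], norm),
            ConnectionRule(re, tc, "GABA_A", spec.radius_thal, g["re_tc_gabaa"], norm),
            ConnectionRule(re, tc, "GABA_B", spec.radius_thal, g["re_tc_gabab"], norm),
            ConnectionRule(re, re, "GABA_A", spec.radius_thal, g["re_re_gabaa"], norm),
        ]
    return rules


class Network:
    """Realized connectivity: populations plus flat edge arrays.

    Edge arrays (all length ``n_edges``): ``pre_pop``/``post_pop`` (indices
    into :attr:`populations`), ``pre_idx``/``post_idx`` (within-population
    indices), ``receptor`` (index into ``RECEPTORS``), ``weight`` (uS,
    normalized if the rule requests it), ``e_syn`` (mV), ``depressing``,
    ``minis`` and ``rule_index``.
    """

    def __init__(self, populations: list[Population], rules: list[ConnectionRule]):
        self.populations = list(populations)
        self.rules = list(rules)
        self._pop_index = {p.name: i for i, p in enumerate(self.populations)}
        self._build()

    # -- construction -----------------------------------------------------
    def _build(self) -> None:
        for rule in self.rules:
            if (rule.source in _CORE_THAL and rule.target in _MATRIX_THAL) or (
                rule.source in _MATRIX_THAL and rule.target in _CORE_THAL
            ):
                raise ValueError(
                    f"cross-system thalamic connection {rule.source}->{rule.target} "
                    "is not allowed: core and matrix thalamus are independent"
                )
            if rule.source not in self._pop_index or rule.target not in self._pop_index:
                raise ValueError(f"rule references unknown population: {rule}")

        pre_pop, pre_idx, post_pop, post_idx = [], [], [], []
        receptor, weight, e_syn, depressing, minis, rule_index = [], [], [], [], [], []
        for ri, rule in enumerate(self.rules):
            ns = self.size(rule.source)
            nt = self.size(rule.target)
            same = rule.source == rule.target
            pairs_pre, pairs_post = [], []
            for i in range(ns):
                tgts = fanout_targets(i, rule.radius, ns, nt, exclude_self=same)
                pairs_pre.append(np.full(len(tgts), i, dtype=np.int64))
                pairs_post.append(tgts)
            pre = np.concatenate(pairs_pre) if pairs_pre else np.empty(0, np.int64)
            post = np.concatenate(pairs_post) if pairs_post else np.empty(0, np.int64)
            counts = np.bincount(post, minlength=nt)
            if rule.normalize:
                w = rule.g_total / np.maximum(counts[post], 1)
            else:
                w = np.full(len(post), rule.g_total)
            rev = _default_reversal(rule)
            pre_pop.append(np.full(len(pre), self._pop_index[rule.source], np.int16))
            post_pop.append(np.full(len(pre), self._pop_index[rule.target], np.int16))
            pre_idx.append(pre)
            post_idx.append(post)
            receptor.append(np.full(len(pre), RECEPTORS.index(rule.receptor), np.int8))
            weight.append(np.asarray(w, float))
            e_syn.append(np.full(len(pre), rev))
            depressing.append(np.full(len(pre), rule.depressing, bool))
            minis.append(np.full(len(pre), rule.minis, bool))
            rule_index.append(np.full(len(pre), ri, np.int32))

        self.pre_pop = np.concatenate(pre_pop)
        self.post_pop = np.concatenate(post_pop)
        self.pre_idx = np.concatenate(pre_idx)
        self.post_idx = np.concatenate(post_idx)
        self.receptor = np.concatenate(receptor)
        self.weight = np.concatenate(weight)
        self.e_syn = np.concatenate(e_syn)
        self.depressing = np.concatenate(depressing)
        self.minis = np.concatenate(minis)
        self.rule_index = np.concatenate(rule_index)

    # -- queries ----------------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.pre_idx)

    def size(self, population: str) -> int:
        return self.populations[self._pop_index[population]].size

    def pop_index(self, population: str) -> int:
        return self._pop_index[population]

    def edges_for_rule(self, rule_index: int) -> np.ndarray:
        return np.flatnonzero(self.rule_index == rule_index)

    def input_counts(self, rule_index: int) -> np.ndarray:
        """Inputs per target cell for one rule (length = target size)."""
        rule = self.rules[rule_index]
        sel = self.edges_for_rule(rule_index)
        return np.bincount(self.post_idx[sel], minlength=self.size(rule.target))

    def to_dataframe(self) -> pd.DataFrame:
        """Edge list as a table (one row per synapse)."""
        names = [p.name for p in self.populations]
        return pd.DataFrame(
            {
                "source_pop": [names[i] for i in self.pre_pop],
                "source_idx": self.pre_idx,
                "target_pop": [names[i] for i in self.post_pop],
                "target_idx": self.post_idx,
                "receptor": [RECEPTORS[i] for i in self.receptor],
                "weight": self.weight,
                "e_syn": self.e_syn,
                "depressing": self.depressing,
                "minis": self.minis,
                "rule": self.rule_index,
            }
        )


def build_network(spec: NetworkSpec, rules: list[ConnectionRule] | None = None) -> Network:
    """Realize the connectivity for ``spec``.

    Deterministic: the edge set is a pure function of the spec (and rules).
    """
    if rules is None:
        rules = baseline_rules(spec)
    return Network(spec.populations(), rules)
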