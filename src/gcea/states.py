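"""Health-state graphs for the three cancer natural-history models.

Each cancer is described by a directed graph of exhaustive, mutually
exclusive health states (healthy, infection, precancer, preclinical and
clinical cancer stages, immunity, death).  Edges are typed by the kind of
transition they represent (onset, progression, regression, diagnosis,
mortality, clearance, waning immunity); transition *rates* never live on the
graph — they are supplied separately as a :class:`~gcea.engine.RateSchedule`
so the same structure serves every region and the null scenario alike.

Structural conventions:

* death is the single absorbing state; every non-dead state carries a
  mortality edge (its rate may be zero);
* diagnosis edges connect a preclinical stage to the clinical state of the
  same stage only;
* regression toward health is only possible from pre-cancerous states
  (HPV infection, CIN, polyps) — never from preclinical or clinical cancer;
* clinical stage IV doubles as the terminal phase for disability-weight
  purposes (no separate terminal state exists).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

CANCERS = ("cervical", "breast", "colorectal")

CATEGORIES = (
    "healthy",
    "infection",
    "precancer",
    "preclinical_cancer",
    "clinical_cancer",
    "immune",
    "dead",
)

EDGE_KINDS = (
    "onset",
    "progression",
    "regression",
    "diagnosis",
    "mortality",
    "clearance",
    "waning_immunity",
)

#: invasive stage ladder, in progression order
STAGES = ("CIS", "I", "II", "III", "IV")

#: categories whose states must carry a stage/subtype label
_LABELLED = {"infection", "precancer", "preclinical_cancer", "clinical_cancer"}

HPV_GROUPS = ("HPV_16_18", "HPV_high_risk", "HPV_low_risk")


@dataclass(frozen=True)
class HealthState:
    """One exhaustive-and-mutually-exclusive state of a Markov model."""

    name: str
    cancer: str  # one of CANCERS or "shared"
    category: str
    stage_label: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        has = self.stage_label is not None
        if has != (self.category in _LABELLED):
            raise ValueError(
                f"state {self.name!r}: stage_label must be present iff the "
                f"category is one of {sorted(_LABELLED)}"
            )


@dataclass
class StateGraph:
    """Typed directed graph of health states for one cancer."""

    cancer: str
    states: list[HealthState] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)

    # -- lookup helpers -------------------------------------------------
    def state(self, name: str) -> HealthState:
        for s in self.states:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def state_names(self) -> list[str]:
        return [s.name for s in self.states]

    @property
    def dead_state(self) -> str:
        for s in self.states:
            if s.category == "dead":
                return s.name
        raise ValueError("graph has no dead state")

    def states_of(self, *categories: str) -> list[HealthState]:
        return [s for s in self.states if s.category in categories]

    def edges_of(self, kind: str) -> list[tuple[str, str]]:
        return [(u, v) for (u, v, k) in self.edges if k == kind]

    def out_edges(self, name: str) -> list[tuple[str, str, str]]:
        return [e for e in self.edges if e[0] == name]

    # -- graph views ----------------------------------------------------
    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(cancer=self.cancer)
        for s in self.states:
            g.add_node(s.name, category=s.category, stage_label=s.stage_label)
        for u, v, k in self.edges:
            g.add_edge(u, v, kind=k)
        return g

    def to_dict(self) -> dict:
        """Plain-data serialization (round-trips through YAML/JSON)."""
        return {
            "cancer": self.cancer,
            "states": [
                {
                    "name": s.name,
                    "cancer": s.cancer,
                    "category": s.category,
                    "stage_label": s.stage_label,
                }
                for s in self.states
            ],
            "edges": [list(e) for e in self.edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StateGraph":
        return cls(
            cancer=d["cancer"],
            states=[HealthState(**s) for s in d["states"]],
            edges=[tuple(e) for e in d["edges"]],
        )

    def to_dot(self) -> str:
        """GraphViz DOT text for visual inspection."""
        lines = [f'digraph "{self.cancer}" {{', "  rankdir=LR;"]
        for s in self.states:
            shape = {"dead": "octagon", "clinical_cancer": "box"}.get(
                s.category, "ellipse"
            )
            lines.append(f'  "{s.name}" [shape={shape}];')
        for u, v, k in self.edges:
            lines.append(f'  "{u}" -> "{v}" [label="{k}"];')
        lines.append("}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# constructors
# ---------------------------------------------------------------------------


def _cancer_stage_block(cancer: str) -> tuple[list[HealthState], list[tuple]]:
    """Preclinical/clinical stage ladder shared by all three cancers.

    Returns the ten stage states plus progression, diagnosis and mortality
    edges.  Clinical stages also progress (treatment modifies those rates);
    clinical IV is the terminal phase.
    """
    states: list[HealthState] = []
    edges: list[tuple] = []
    for phase, cat in (("pre", "preclinical_cancer"), ("clin", "clinical_cancer")):
        for i, stage in enumerate(STAGES):
            states.append(HealthState(f"{phase}_{stage}", cancer, cat, stage))
            if i > 0:
                edges.append(
                    (f"{phase}_{STAGES[i - 1]}", f"{phase}_{stage}", "progression")
                )
    for stage in STAGES:
        edges.append((f"pre_{stage}", f"clin_{stage}", "diagnosis"))
    for s in states:
        edges.append((s.name, "dead", "mortality"))
    return states, edges


def build_cervical_graph() -> StateGraph:
    """Female cervical model: dynamic HPV infection, CIN, invasive stages.

    Women acquire one of three HPV subtype groups (16/18, other high-risk,
    low-risk) through sexual contact; infection can clear into a short-term
    immune state that wanes back to healthy, or progress through CIN1 and
    CIN2-3 into preclinical carcinoma in situ and onward to stage IV.  CIN
    regresses to the infected state (naturally or on screen-and-treat);
    invasive disease never regresses.
    """
    c = "cervical"
    states = [HealthState("healthy", c, "healthy")]
    edges: list[tuple] = []
    for g in HPV_GROUPS:
        states.append(HealthState(g.lower(), c, "infection", g))
        edges.append(("healthy", g.lower(), "onset"))
        edges.append((g.lower(), "immune", "clearance"))
    states.append(HealthState("cin1", c, "precancer", "CIN1"))
    states.append(HealthState("cin2_3", c, "precancer", "CIN2-3"))
    # oncogenic groups progress to CIN; the low-risk group rarely does but the
    # edge exists (its rate may be ~0)
    for g in HPV_GROUPS:
        edges.append((g.lower(), "cin1", "progression"))
    edges.append(("cin1", "cin2_3", "progression"))
    edges.append(("cin2_3", "pre_CIS", "progression"))
    # CIN regression: one grade down, and back to the infected state
    edges.append(("cin2_3", "cin1", "regression"))
    edges.append(("cin1", "hpv_16_18", "regression"))
    edges.append(("cin1", "hpv_high_risk", "regression"))
    stage_states, stage_edges = _cancer_stage_block(c)
    states += stage_states
    states.append(HealthState("immune", c, "immune"))
    states.append(HealthState("dead", c, "dead"))
    edges += stage_edges
    edges.append(("immune", "healthy", "waning_immunity"))
    for name in ("healthy", "immune", "cin1", "cin2_3") + tuple(
        g.lower() for g in HPV_GROUPS
    ):
        edges.append((name, "dead", "mortality"))
    return StateGraph(c, states, edges)


def build_male_hpv_graph() -> StateGraph:
    """Male companion model: HPV infection, clearance and immunity only.

    Men contribute to heterosexual HPV transmission but never develop the
    modelled cancers, so the graph has no precancer or cancer states.
    """
    c = "cervical"
    states = [HealthState("healthy", c, "healthy")]
    edges: list[tuple] = []
    for g in HPV_GROUPS:
        states.append(HealthState(g.lower(), c, "infection", g))
        edges.append(("healthy", g.lower(), "onset"))
        edges.append((g.lower(), "immune", "clearance"))
    states.append(HealthState("immune", c, "immune"))
    states.append(HealthState("dead", c, "dead"))
    edges.append(("immune", "healthy", "waning_immunity"))
    for s in states:
        if s.category != "dead":
            edges.append((s.name, "dead", "mortality"))
    return StateGraph(c, states, edges)


def build_breast_graph() -> StateGraph:
    """Breast model: disease initiates directly as carcinoma in situ.

    healthy → preclinical CIS → I → II → III → IV, with per-stage diagnosis
    edges into the clinical ladder.  There are no precancer states and no
    regression of any kind.
    """
    c = "breast"
    states = [HealthState("healthy", c, "healthy")]
    edges: list[tuple] = [("healthy", "pre_CIS", "onset")]
    stage_states, stage_edges = _cancer_stage_block(c)
    states += stage_states
    states.append(HealthState("dead", c, "dead"))
    edges += stage_edges
    edges.append(("healthy", "dead", "mortality"))
    return StateGraph(c, states, edges)


def build_colorectal_graph(route_split: tuple[float, float] = (0.77, 0.23)) -> StateGraph:
    """Colorectal model with two onset routes.

    Most disease (default 77%) arises through an adenoma pathway with three
    polyp size classes (≤5 mm, 6–9 mm, ≥10 mm) before carcinoma in situ; the
    remainder (23%) initiates de novo as CIS.  ``route_split`` records the
    onset-mass split as graph metadata consumed by the rate generator.
    """
    if len(route_split) != 2 or abs(sum(route_split) - 1.0) > 1e-9:
        raise ValueError("route_split must be two fractions summing to 1")
    c = "colorectal"
    states = [HealthState("healthy", c, "healthy")]
    polyps = ("polyp_small", "polyp_medium", "polyp_large")
    for p in polyps:
        states.append(HealthState(p, c, "precancer", p))
    edges: list[tuple] = [
        ("healthy", "polyp_small", "onset"),  # adenoma route
        ("healthy", "pre_CIS", "onset"),  # de-novo route
        ("polyp_small", "polyp_medium", "progression"),
        ("polyp_medium", "polyp_large", "progression"),
        ("polyp_large", "pre_CIS", "progression"),
        ("polyp_small", "healthy", "regression"),
        ("polyp_medium", "healthy", "regression"),
    ]
    stage_states, stage_edges = _cancer_stage_block(c)
    states += stage_states
    states.append(HealthState("dead", c, "dead"))
    edges += stage_edges
    edges.append(("healthy", "dead", "mortality"))
    for p in polyps:
        edges.append((p, "dead", "mortality"))
    g = StateGraph(c, states, edges)
    g.route_split = route_split  # type: ignore[attr-defined]
    return g


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_graph(graph: StateGraph) -> list[str]:
    """Check every structural invariant; returns human-readable violations.

    An empty list means the graph is valid.  Violations are returned rather
    than raised so test fixtures can assert on injected defects.
    """
    v: list[str] = []
    names = set(graph.state_names)
    if len(names) != len(graph.states):
        v.append("duplicate state names")
    dead = [s.name for s in graph.states if s.category == "dead"]
    if len(dead) != 1:
        v.append(f"graph must have exactly one dead state, found {len(dead)}")
        return v
    dead_name = dead[0]

    for u, w, k in graph.edges:
        if u not in names or w not in names:
            v.append(f"edge ({u} -> {w}) references unknown state")
            continue
        if k not in EDGE_KINDS:
            v.append(f"edge ({u} -> {w}) has unknown kind {k!r}")
        if u == dead_name and w != dead_name:
            v.append(f"dead state has out-edge ({u} -> {w}, {k}): dead is absorbing")
        su, sw = graph.state(u), graph.state(w)
        if k == "diagnosis":
            if not (
                su.category == "preclinical_cancer"
                and sw.category == "clinical_cancer"
                and su.stage_label == sw.stage_label
            ):
                v.append(
                    f"diagnosis edge ({u} -> {w}) must connect preclinical to "
                    "clinical cancer of the same stage"
                )
        if k == "regression" and su.category in (
            "preclinical_cancer",
            "clinical_cancer",
        ):
            v.append(
                f"regression edge ({u} -> {w}) originates from cancer state {u}"
            )
        if k == "progression" and su.stage_label in STAGES and sw.stage_label in STAGES:
            if STAGES.index(sw.stage_label) != STAGES.index(su.stage_label) + 1:
                v.append(
                    f"progression edge ({u} -> {w}) skips stages "
                    f"({su.stage_label} -> {sw.stage_label})"
                )

    for s in graph.states:
        if s.category == "dead":
            continue
        if not any(
            u == s.name and k == "mortality" and w == dead_name
            for (u, w, k) in graph.edges
        ):
            v.append(f"state {s.name} has no mortality edge")

    # reachability checks on the directed structure
    g = graph.to_networkx()
    for s in graph.states:
        if s.name != dead_name and not nx.has_path(g, s.name, dead_name):
            v.append(f"dead not reachable from {s.name}")
    if "clin_IV" in names and "healthy" in names:
        if not nx.has_path(g, "healthy", "clin_IV"):
            v.append("clinical stage IV not reachable from healthy")
    return v
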