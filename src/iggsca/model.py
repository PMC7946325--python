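"""Model specification for composite-based structural models.

A model is built from *components* — weighted sums (composites) of observed
variables such as SNPs of a gene or the two hemisphere thickness values of a
brain region of interest (ROI) — together with directed *paths* between
components and optional component *interactions* (e.g. gene-by-environment
products).  Three pattern matrices encode the specification:

* ``W`` (P×J): weights defining each component score as ``gamma = W z``;
* ``C`` (J×P): loadings regressing each observed variable on its own
  component;
* ``B`` (P×P): path coefficients among components, ``gamma = B gamma + zeta``.

Entries of these matrices are either *free* (estimated), fixed at 0, or fixed
at 1 (single-indicator components).  Interaction components carry no weights
or loadings of their own: their score is the rescaled elementwise product of
the two parent scores, and their weight rows are determined by the parents'
weights (shared-weight rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ComponentDef",
    "InteractionDef",
    "ModelSpec",
    "ParameterSet",
    "ModelSpecError",
    "build_model",
    "pattern_matrices",
    "load_model_config",
    "parse_model_config",
]


class ModelSpecError(ValueError):
    """Raised when a model specification is structurally invalid."""


@dataclass(frozen=True)
class ComponentDef:
    """A component and the observed variables (indicators) that form it.

    ``kind`` is derived: a component with exactly one indicator is a
    ``single_indicator`` component whose weight and loading are fixed at 1;
    otherwise it is a ``composite``.
    """

    name: str
    indicators: tuple[str, ...]

    def __init__(self, name: str, indicators: Sequence[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "indicators", tuple(str(i) for i in indicators))

    @property
    def kind(self) -> str:
        return "single_indicator" if len(self.indicators) == 1 else "composite"

    @property
    def is_single(self) -> bool:
        return len(self.indicators) == 1


@dataclass(frozen=True)
class InteractionDef:
    """A product interaction between two previously declared components."""

    first: str
    second: str

    @property
    def name(self) -> str:
        return f"{self.first} x {self.second}"


def _check_name(name: str) -> None:
    if not name:
        raise ModelSpecError("empty component name")
    if "->" in name or " x " in name:
        raise ModelSpecError(
            f"component name {name!r} may not contain '->' or ' x ' "
            "(reserved for path/interaction syntax)"
        )


@dataclass(frozen=True)
class ModelSpec:
    """Validated specification: components, interactions and free paths.

    Component order is the declared order with interactions appended last;
    every matrix produced from the spec is indexed in that order.
    """

    components: tuple[ComponentDef, ...]
    interactions: tuple[InteractionDef, ...]
    paths: tuple[tuple[str, str], ...]
    # derived, filled in __post_init__
    names: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self):
        comp_names = [c.name for c in self.components]
        for n in comp_names:
            _check_name(n)
        if len(set(comp_names)) != len(comp_names):
            dup = sorted({n for n in comp_names if comp_names.count(n) > 1})
            raise ModelSpecError(f"duplicate component name(s): {dup}")
        seen: dict[str, str] = {}
        for c in self.components:
            if not c.indicators:
                raise ModelSpecError(f"component {c.name!r} has an empty indicator list")
            for ind in c.indicators:
                if ind in seen:
                    raise ModelSpecError(
                        f"indicator {ind!r} assigned to both {seen[ind]!r} and {c.name!r}"
                    )
                seen[ind] = c.name
        comp_set = set(comp_names)
        inter_names = []
        for it in self.interactions:
            for parent in (it.first, it.second):
                if parent not in comp_set:
                    raise ModelSpecError(
                        f"interaction {it.name!r} refers to unknown component {parent!r}"
                    )
            if it.name in comp_set or it.name in inter_names:
                raise ModelSpecError(f"duplicate name {it.name!r}")
            inter_names.append(it.name)
        all_names = comp_names + inter_names
        all_set = set(all_names)
        inter_set = set(inter_names)
        for src, tgt in self.paths:
            if src not in all_set:
                raise ModelSpecError(f"path source {src!r} is not a declared component")
            if tgt not in all_set:
                raise ModelSpecError(f"path target {tgt!r} is not a declared component")
            if tgt in inter_set:
                raise ModelSpecError(
                    f"path {src!r} -> {tgt!r} targets an interaction; interactions "
                    "may only appear as path sources"
                )
            if src == tgt:
                raise ModelSpecError(f"self-loop path on {src!r}")
        if len(set(self.paths)) != len(self.paths):
            raise ModelSpecError("duplicate path declared")
        object.__setattr__(self, "names", tuple(all_names))
        # cached derived structure (spec objects are immutable)
        object.__setattr__(self, "_ix", {n: i for i, n in enumerate(all_names)})
        object.__setattr__(
            self, "_observed", tuple(i for c in self.components for i in c.indicators)
        )
        object.__setattr__(self, "_comp_map", {c.name: c for c in self.components})
        targets = {t for _, t in self.paths}
        object.__setattr__(
            self, "_dependent", tuple(n for n in all_names if n in targets)
        )
        preds: dict[str, list] = {}
        for s, t in self.paths:
            preds.setdefault(t, []).append(s)
        object.__setattr__(self, "_preds", {t: tuple(v) for t, v in preds.items()})
        object.__setattr__(self, "_path_set", frozenset(self.paths))

    # -- derived structure ----------------------------------------------

    @property
    def P(self) -> int:
        """Total component count, interactions included."""
        return len(self.components) + len(self.interactions)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def observed(self) -> tuple[str, ...]:
        """All indicator names in declared component order."""
        return self._observed

    @property
    def J(self) -> int:
        return len(self._observed)

    def index(self, name: str) -> int:
        return self._ix[name]

    def component(self, name: str) -> ComponentDef:
        return self._comp_map[name]

    def dependent(self) -> tuple[str, ...]:
        """Components that receive at least one free path."""
        return self._dependent

    def predictors_of(self, target: str) -> tuple[str, ...]:
        return self._preds.get(target, ())

    def has_path(self, src: str, tgt: str) -> bool:
        return (src, tgt) in self._path_set


def build_model(
    components: Iterable[ComponentDef | tuple | Mapping],
    interactions: Iterable[InteractionDef | tuple] = (),
    paths: Iterable[tuple[str, str]] = (),
) -> ModelSpec:
    """Assemble and validate a :class:`ModelSpec`.

    Accepts ``ComponentDef`` objects, ``(name, indicators)`` tuples, or
    mappings with ``name``/``indicators`` keys; interactions as
    ``InteractionDef`` or ``(first, second)`` tuples.
    """
    comps = []
    for c in components:
        if isinstance(c, ComponentDef):
            comps.append(c)
        elif isinstance(c, Mapping):
            comps.append(ComponentDef(c["name"], c["indicators"]))
        else:
            name, inds = c
            comps.append(ComponentDef(name, inds))
    inters = [
        it if isinstance(it, InteractionDef) else InteractionDef(*it)
        for it in interactions
    ]
    return ModelSpec(tuple(comps), tuple(inters), tuple((str(s), str(t)) for s, t in paths))


@dataclass
class ParameterSet:
    """The W, C, B matrices with their free-entry masks.

    Entries outside the free masks are fixed: 0 everywhere except weight and
    loading entries of single-indicator components, which are fixed at 1.
    ``interaction_scales`` holds, per interaction (in spec order), the factor
    that rescales the raw product of parent scores to unit variance; it is a
    derived quantity, refreshed whenever weights change.
    """

    spec: ModelSpec
    columns: tuple[str, ...]
    W: np.ndarray  # (P, J)
    C: np.ndarray  # (J, P)
    B: np.ndarray  # (P, P)
    w_free: np.ndarray  # bool (P, J)
    c_free: np.ndarray  # bool (J, P)
    b_free: np.ndarray  # bool (P, P)
    interaction_scales: np.ndarray  # (n_interactions,)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            self.spec,
            self.columns,
            self.W.copy(),
            self.C.copy(),
            self.B.copy(),
            self.w_free,
            self.c_free,
            self.b_free,
            self.interaction_scales.copy(),
        )

    # -- free-parameter bookkeeping (used by bootstrap / recovery) -------

    def free_labels(self) -> list[tuple[str, str, str]]:
        """Labels ``(block, component, indicator-or-target)`` of free entries.

        Order: weights row-major, then loadings, then paths — the order used
        by :meth:`free_values`.
        """
        spec = self.spec
        labels: list[tuple[str, str, str]] = []
        for p, j in zip(*np.nonzero(self.w_free)):
            labels.append(("weight", spec.names[p], self.columns[j]))
        for j, p in zip(*np.nonzero(self.c_free)):
            labels.append(("loading", spec.names[p], self.columns[j]))
        for t, s in zip(*np.nonzero(self.b_free)):
            labels.append(("path", spec.names[s], spec.names[t]))
        return labels

    def free_values(self) -> np.ndarray:
        return np.concatenate(
            [self.W[self.w_free], self.C.T[self.c_free.T], self.B[self.b_free]]
        )

    def set_free_values(self, values: np.ndarray) -> None:
        nw = int(self.w_free.sum())
        nc = int(self.c_free.sum())
        self.W[self.w_free] = values[:nw]
        CT = self.C.T
        CT[self.c_free.T] = values[nw : nw + nc]
        self.C = CT.T
        self.B[self.b_free] = values[nw + nc :]

    @property
    def V(self) -> np.ndarray:
        """Stacked [I; W] of the combined model."""
        return np.vstack([np.eye(len(self.columns)), self.W])

    @property
    def A(self) -> np.ndarray:
        """Stacked [C; B] of the combined model."""
        return np.vstack([self.C, self.B])


def pattern_matrices(spec: ModelSpec, columns: Sequence[str] | None = None) -> ParameterSet:
    """Build the free/fixed masks of W, C, B for ``spec`` (values zeroed).

    ``columns`` fixes the observed-variable order (defaults to the spec's
    declared indicator order).  Single-indicator weights/loadings are set to
    their fixed value 1; all free entries start at 0.
    """
    if columns is None:
        columns = spec.observed
    columns = tuple(columns)
    missing = set(spec.observed) - set(columns)
    if missing:
        raise ModelSpecError(f"columns missing declared indicators: {sorted(missing)}")
    extra = set(columns) - set(spec.observed)
    if extra:
        raise ModelSpecError(f"columns not assigned to any component: {sorted(extra)}")
    col_ix = {c: j for j, c in enumerate(columns)}
    P, J = spec.P, len(columns)
    W = np.zeros((P, J))
    C = np.zeros((J, P))
    B = np.zeros((P, P))
    w_free = np.zeros((P, J), dtype=bool)
    c_free = np.zeros((J, P), dtype=bool)
    for p, comp in enumerate(spec.components):
        js = [col_ix[i] for i in comp.indicators]
        if comp.is_single:
            W[p, js[0]] = 1.0
            C[js[0], p] = 1.0
        else:
            w_free[p, js] = True
            c_free[js, p] = True
    b_free = np.zeros((P, P), dtype=bool)
    for src, tgt in spec.paths:
        b_free[spec.index(tgt), spec.index(src)] = True
    scales = np.ones(len(spec.interactions))
    return ParameterSet(spec, columns, W, C, B, w_free, c_free, b_free, scales)


# ---------------------------------------------------------------------------
# plain-text model configuration
# ---------------------------------------------------------------------------

def parse_model_config(text: str) -> ModelSpec:
    """Parse a YAML model configuration into a :class:`ModelSpec`.

    Schema::

        components:
          - name: FKBP5
            indicators: [rs9296158, rs3800373]
          - name: PTE
            indicators: [pte]
        interactions:
          - PTE x FKBP5          # "first x second"
        paths:
          - FKBP5 -> roi_1       # "source -> target"
          - PTE x FKBP5 -> roi_1
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "components" not in doc:
        raise ModelSpecError("model config must be a mapping with a 'components' list")
    comps = []
    for entry in doc["components"]:
        if not isinstance(entry, Mapping) or "name" not in entry or "indicators" not in entry:
            raise ModelSpecError(f"bad component entry: {entry!r}")
        comps.append(ComponentDef(entry["name"], entry["indicators"]))
    inters = []
    for s in doc.get("interactions") or []:
        parts = str(s).split(" x ")
        if len(parts) != 2:
            raise ModelSpecError(f"bad interaction {s!r}; expected 'A x B'")
        inters.append(InteractionDef(parts[0].strip(), parts[1].strip()))
    paths = []
    for s in doc.get("paths") or []:
        parts = str(s).split("->")
        if len(parts) != 2:
            raise ModelSpecError(f"bad path {s!r}; expected 'source -> target'")
        paths.append((parts[0].strip(), parts[1].strip()))
    return build_model(comps, inters, paths)


def load_model_config(path) -> ModelSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_model_config(fh.read())


def model_config_text(spec: ModelSpec) -> str:
    """Serialize a spec back to the configuration format (round-trippable)."""
    doc = {
        "components": [
            {"name": c.name, "indicators": list(c.indicators)} for c in spec.components
        ],
        "interactions": [it.name for it in spec.interactions],
        "paths": [f"{s} -> {t}" for s, t in spec.paths],
    }
    return yaml.safe_dump(doc, sort_keys=False)
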