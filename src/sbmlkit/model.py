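"""In-memory document model for SBML Level 3 core.

Elements mirror the Level 3 core constructs: a :class:`Document` wraps a
:class:`Model`, which owns ordered lists of compartments, species,
parameters, reactions, rules, initial assignments, events, function
definitions and unit definitions.  Element order is preserved from the
input, and SIds link everything together.

Level 3 has no attribute defaults for ``constant``, ``reversible``,
``boundaryCondition`` and ``hasOnlySubstanceUnits``; when the reader meets
an element with such an attribute missing it records the attribute name in
the element's ``missing_attrs`` list (parsing stays lenient) and the
validator reports it as E1006.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from .errors import SbmlFormatError, SIdLookupError
from .mathml import Lambda, MathNode

SID_PATTERN = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")

#: SBML base-unit enumeration.
BASE_UNIT_KINDS = frozenset(
    {
        "second", "metre", "mole", "litre", "gram", "kilogram", "katal",
        "dimensionless", "item", "volt", "ampere", "kelvin", "candela",
        "hertz", "joule", "watt", "newton", "pascal", "coulomb", "siemens",
        "weber", "tesla", "henry", "ohm", "farad", "gray", "sievert",
        "becquerel", "lumen", "lux", "steradian", "radian", "avogadro",
    }
)

#: Controlled biology/model qualifier names for CV terms.
CV_QUALIFIERS = frozenset(
    {
        # biology qualifiers
        "is", "hasPart", "isPartOf", "isVersionOf", "hasVersion",
        "isHomologTo", "isDescribedBy", "isEncodedBy", "encodes",
        "occursIn", "hasProperty", "isPropertyOf", "hasTaxon",
        # model qualifiers
        "isDerivedFrom", "isInstanceOf", "hasInstance",
    }
)


def is_valid_sid(sid: str) -> bool:
    return bool(SID_PATTERN.match(sid or ""))


def check_sid(sid: str) -> str:
    if not is_valid_sid(sid):
        raise SbmlFormatError(f"invalid SId {sid!r}")
    return sid


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


@dataclass
class CVTerm:
    qualifier: str
    resources: tuple[str, ...]


@dataclass
class Annotation:
    metaid: Optional[str] = None
    sbo_term: Optional[int] = None
    cv_terms: list[CVTerm] = field(default_factory=list)
    notes: Optional[str] = None  # serialized XHTML content of <notes>
    raw: list[bytes] = field(default_factory=list)  # preserved annotation XML

    def is_empty(self) -> bool:
        return (
            self.sbo_term is None
            and not self.cv_terms
            and self.notes is None
            and not self.raw
        )


def attach_cv_term(element, qualifier: str, resources) -> None:
    """Append a controlled-vocabulary term to an element's annotation.

    Idempotent: a term with the same qualifier and resource set is not
    duplicated.  Unknown qualifier names and empty resource lists are
    rejected.
    """
    if qualifier not in CV_QUALIFIERS:
        raise ValueError(f"unknown CV qualifier {qualifier!r}")
    resources = tuple(resources)
    if not resources or any(not r for r in resources):
        raise ValueError("CV term needs a non-empty list of non-empty URIs")
    ann = element.annotations
    for term in ann.cv_terms:
        if term.qualifier == qualifier and set(term.resources) == set(resources):
            return
    ann.cv_terms.append(CVTerm(qualifier, resources))


# ---------------------------------------------------------------------------
# Core elements
# ---------------------------------------------------------------------------


@dataclass
class Compartment:
    id: str
    size: Optional[float] = None
    spatial_dimensions: Optional[float] = None
    constant: bool = True
    units: Optional[str] = None
    name: Optional[str] = None
    annotations: Annotation = field(default_factory=Annotation)
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class Species:
    id: str
    compartment: str = ""
    initial_amount: Optional[float] = None
    initial_concentration: Optional[float] = None
    has_only_substance_units: bool = False
    boundary_condition: bool = False
    constant: bool = False
    substance_units: Optional[str] = None
    name: Optional[str] = None
    chemical_formula: Optional[str] = None  # fbc extension attribute
    charge: Optional[int] = None  # fbc extension attribute
    annotations: Annotation = field(default_factory=Annotation)
    missing_attrs: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.initial_amount is not None and self.initial_concentration is not None:
            raise SbmlFormatError(
                f"species {self.id!r}: initialAmount and initialConcentration "
                "are mutually exclusive"
            )


@dataclass
class Parameter:
    id: str
    value: Optional[float] = None
    constant: bool = True
    units: Optional[str] = None
    name: Optional[str] = None
    annotations: Annotation = field(default_factory=Annotation)
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class LocalParameter:
    id: str
    value: Optional[float] = None
    units: Optional[str] = None


@dataclass
class SpeciesReference:
    species: str
    stoichiometry: float = 1.0
    constant: bool = True
    id: Optional[str] = None
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class KineticLaw:
    math: Optional[MathNode] = None
    local_parameters: list[LocalParameter] = field(default_factory=list)


@dataclass
class Reaction:
    id: str
    reversible: bool = False
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_law: Optional[KineticLaw] = None
    name: Optional[str] = None
    # fbc extension attributes
    lower_flux_bound: Optional[str] = None
    upper_flux_bound: Optional[str] = None
    gene_association: Optional["object"] = None  # fbc.GPA
    annotations: Annotation = field(default_factory=Annotation)
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class Rule:
    kind: str  # "assignment" | "rate"
    variable: str
    math: MathNode

    def __post_init__(self):
        if self.kind not in ("assignment", "rate"):
            raise SbmlFormatError(f"unknown rule kind {self.kind!r}")


@dataclass
class InitialAssignment:
    symbol: str
    math: MathNode


@dataclass
class Trigger:
    math: MathNode
    initial_value: bool = True
    persistent: bool = True
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class EventAssignment:
    variable: str
    math: MathNode


@dataclass
class Event:
    trigger: Trigger
    id: Optional[str] = None
    delay: Optional[MathNode] = None
    use_values_from_trigger_time: bool = True
    assignments: list[EventAssignment] = field(default_factory=list)
    annotations: Annotation = field(default_factory=Annotation)
    missing_attrs: list[str] = field(default_factory=list)


@dataclass
class FunctionDefinition:
    id: str
    math: Lambda
    name: Optional[str] = None


@dataclass
class Unit:
    kind: str
    exponent: float = 1.0
    scale: int = 0
    multiplier: float = 1.0

    def __post_init__(self):
        if self.kind not in BASE_UNIT_KINDS:
            raise SbmlFormatError(f"unknown base unit kind {self.kind!r}")


@dataclass
class UnitDefinition:
    id: str
    units: list[Unit] = field(default_factory=list)
    name: Optional[str] = None


@dataclass
class PackageDecl:
    prefix: str
    namespace_uri: str
    required: bool

    def __post_init__(self):
        if not self.namespace_uri:
            raise SbmlFormatError("package declaration with empty namespace URI")


# ---------------------------------------------------------------------------
# Model & Document
# ---------------------------------------------------------------------------

Element = Union[
    Compartment, Species, Parameter, Reaction, Event, LocalParameter,
    SpeciesReference, FunctionDefinition, UnitDefinition,
]


@dataclass
class Model:
    id: Optional[str] = None
    name: Optional[str] = None
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    initial_assignments: list[InitialAssignment] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    function_definitions: list[FunctionDefinition] = field(default_factory=list)
    unit_definitions: list[UnitDefinition] = field(default_factory=list)
    substance_units: Optional[str] = None
    time_units: Optional[str] = None
    extent_units: Optional[str] = None
    volume_units: Optional[str] = None
    annotations: Annotation = field(default_factory=Annotation)
    fbc: Optional["object"] = None  # fbc.FbcExtension
    qual: Optional["object"] = None  # qual.QualModel
    #: (path, description) pairs for constructs read but not interpreted
    #: (algebraic rules, delay/rateOf csymbols, qual consumption inputs ...)
    unsupported_constructs: list[tuple[str, str]] = field(default_factory=list)

    # -- SId namespace ---------------------------------------------------

    def sid_elements(self) -> Iterator[tuple[str, object]]:
        """Yield (sid, element) for every model-namespace SId, in order."""
        for c in self.compartments:
            yield c.id, c
        for s in self.species:
            yield s.id, s
        for p in self.parameters:
            yield p.id, p
        for r in self.reactions:
            yield r.id, r
            for ref in list(r.reactants) + list(r.products):
                if ref.id:
                    yield ref.id, ref
        for e in self.events:
            if e.id:
                yield e.id, e
        for f in self.function_definitions:
            yield f.id, f
        q = self.qual
        if q is not None:
            for qs in q.species:
                yield qs.id, qs
            for tr in q.transitions:
                if tr.id:
                    yield tr.id, tr
        x = self.fbc
        if x is not None:
            for gp in x.gene_products:
                yield gp.id, gp
            for obj in x.objectives:
                yield obj.id, obj

    def element_by_sid(self, sid: str, scope: Optional[str] = None):
        """Resolve an SId; a reaction ``scope`` lets its local parameters
        shadow model-level ids."""
        if scope is not None:
            for r in self.reactions:
                if r.id == scope:
                    if r.kinetic_law is not None:
                        for lp in r.kinetic_law.local_parameters:
                            if lp.id == sid:
                                return lp
                    break
        for known, element in self.sid_elements():
            if known == sid:
                return element
        raise SIdLookupError(sid)

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise SIdLookupError(sid)

    def compartment_by_id(self, sid: str) -> Compartment:
        for c in self.compartments:
            if c.id == sid:
                return c
        raise SIdLookupError(sid)

    def parameter_by_id(self, sid: str) -> Parameter:
        for p in self.parameters:
            if p.id == sid:
                return p
        raise SIdLookupError(sid)

    def unit_definition_by_id(self, sid: str) -> Optional[UnitDefinition]:
        for u in self.unit_definitions:
            if u.id == sid:
                return u
        return None

    # -- construction helpers -------------------------------------------

    def _check_new_sid(self, sid: str) -> None:
        check_sid(sid)
        for known, _ in self.sid_elements():
            if known == sid:
                raise SbmlFormatError(f"duplicate SId {sid!r}")

    def add_compartment(self, id: str, **kw) -> Compartment:
        self._check_new_sid(id)
        c = Compartment(id=id, **kw)
        self.compartments.append(c)
        return c

    def add_species(self, id: str, compartment: str, **kw) -> Species:
        self._check_new_sid(id)
        s = Species(id=id, compartment=compartment, **kw)
        self.species.append(s)
        return s

    def add_parameter(self, id: str, **kw) -> Parameter:
        self._check_new_sid(id)
        p = Parameter(id=id, **kw)
        self.parameters.append(p)
        return p

    def add_reaction(self, id: str, **kw) -> Reaction:
        self._check_new_sid(id)
        r = Reaction(id=id, **kw)
        self.reactions.append(r)
        return r


def element_by_sid(model: Model, sid: str, scope: Optional[str] = None):
    """Module-level alias for :meth:`Model.element_by_sid`."""
    return model.element_by_sid(sid, scope=scope)


@dataclass
class Document:
    level: int = 3
    version: int = 2
    model: Optional[Model] = None
    declared_packages: list[PackageDecl] = field(default_factory=list)
    unknown_elements: list[bytes] = field(default_factory=list)
    #: diagnostics raised while reading (lenient-parse findings)
    read_diagnostics: list = field(default_factory=list)

    def __post_init__(self):
        if self.level != 3:
            raise SbmlFormatError(f"only SBML Level 3 is supported, got {self.level}")
        prefixes = [p.prefix for p in self.declared_packages]
        if len(prefixes) != len(set(prefixes)):
            raise SbmlFormatError("duplicate package prefixes declared")
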