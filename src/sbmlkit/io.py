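"""Read and write SBML Level 3 XML.

The reader is lenient: structural problems (missing required attributes,
unsupported math constructs, algebraic rules) are recorded on the document
and surface later through the validator, so that a best-effort document
model is always available.  The one hard policy is the ``required``
attribute of package declarations: a document declaring an *unknown*
package with ``required="true"`` cannot be interpreted and is rejected,
unless ``permissive=True`` downgrades this to a diagnostic with the package
content preserved opaquely.

The writer emits a canonical form — attributes sorted lexicographically,
two-space indentation, ListOf containers never self-closed — so that
``write(read(write(doc)))`` is byte-identical to ``write(doc)``.  Raw
preserved annotation fragments are re-emitted byte-identically.
"""

from __future__ import annotations

import copy
from typing import Optional

from lxml import etree

from . import fbc as fbc_mod
from . import qual as qual_mod
from .errors import SbmlFormatError, SbmlParseError, UnsupportedPackageError
from .mathml import (
    MATHML_NS,
    Lambda,
    MathNode,
    UnsupportedMathError,
    format_number,
    mathml_lines,
    parse_mathml_element,
)
from .model import (
    Annotation,
    Compartment,
    CVTerm,
    Document,
    Event,
    EventAssignment,
    FunctionDefinition,
    InitialAssignment,
    KineticLaw,
    LocalParameter,
    Model,
    PackageDecl,
    Parameter,
    Reaction,
    Rule,
    Species,
    SpeciesReference,
    Trigger,
    Unit,
    UnitDefinition,
)

CORE_NS_V1 = "http://www.sbml.org/sbml/level3/version1/core"
CORE_NS_V2 = "http://www.sbml.org/sbml/level3/version2/core"
CORE_NAMESPACES = (CORE_NS_V1, CORE_NS_V2)

FBC_NS = fbc_mod.FBC_V2_NS
QUAL_NS = qual_mod.QUAL_V1_NS

#: packages this toolkit can interpret, with their canonical prefixes and
#: the `required` value the writer emits (their content does not change the
#: core-math interpretation of other constructs).
KNOWN_PACKAGES = {FBC_NS: "fbc", QUAL_NS: "qual"}
PACKAGE_REQUIRED_DEFAULT = {FBC_NS: False, QUAL_NS: False}

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

_MODEL_QUALIFIERS = {"isDerivedFrom", "isInstanceOf", "hasInstance"}


def _fragment_bytes(el) -> bytes:
    """Serialize a subtree without the whitespace tail that follows it."""
    clone = copy.deepcopy(el)
    clone.tail = None
    return etree.tostring(clone)


class ReadDiagnostic:
    """Lenient-parse finding attached to ``Document.read_diagnostics``."""

    def __init__(self, path: str, message: str):
        self.path = path
        self.message = message

    def __repr__(self):
        return f"ReadDiagnostic({self.path!r}, {self.message!r})"


# ===========================================================================
# Reading
# ===========================================================================


def read_sbml(source: bytes | str, permissive: bool = False) -> Document:
    """Parse SBML Level 3 XML into a :class:`~sbmlkit.model.Document`."""
    if isinstance(source, str):
        source = source.encode("utf-8")
    try:
        root = etree.fromstring(source)
    except etree.XMLSyntaxError as exc:
        raise SbmlParseError(f"malformed XML: {exc}") from exc
    qname = etree.QName(root)
    if qname.localname != "sbml" or qname.namespace not in CORE_NAMESPACES:
        raise SbmlFormatError(
            f"root element is <{qname.localname}> in namespace "
            f"{qname.namespace!r}, not an SBML Level 3 core <sbml> element"
        )
    core_ns = qname.namespace
    level = int(root.get("level", "3"))
    version = int(root.get("version", "1" if core_ns == CORE_NS_V1 else "2"))

    doc = Document(level=level, version=version)
    _read_package_decls(root, doc, permissive)

    for child in root:
        if not isinstance(child.tag, str):
            continue
        cq = etree.QName(child)
        if cq.namespace == core_ns and cq.localname == "model":
            doc.model = _read_model(child, core_ns, doc)
        else:
            doc.unknown_elements.append(_fragment_bytes(child))
    return doc


def _read_package_decls(root, doc: Document, permissive: bool) -> None:
    for prefix, uri in (root.nsmap or {}).items():
        if uri in CORE_NAMESPACES or uri == MATHML_NS:
            continue
        required_attr = root.get(f"{{{uri}}}required")
        is_sbml_pkg = uri.startswith("http://www.sbml.org/sbml/level3/")
        if required_attr is None and not is_sbml_pkg:
            continue  # unrelated namespace declaration (e.g. XHTML)
        if required_attr is None:
            doc.read_diagnostics.append(
                ReadDiagnostic(
                    "sbml",
                    f"package namespace {uri!r} declared without a required "
                    "attribute; assuming required=\"false\"",
                )
            )
            required = False
        else:
            required = required_attr == "true"
        decl_prefix = prefix or KNOWN_PACKAGES.get(uri, "pkg")
        doc.declared_packages.append(PackageDecl(decl_prefix, uri, required))
        if uri in KNOWN_PACKAGES:
            expected = PACKAGE_REQUIRED_DEFAULT[uri]
            if required_attr is not None and required != expected:
                doc.read_diagnostics.append(
                    ReadDiagnostic(
                        "sbml",
                        f"package {KNOWN_PACKAGES[uri]!r} declared with "
                        f"required=\"{required_attr}\"; this toolkit treats "
                        f"it as {str(expected).lower()}",
                    )
                )
        elif required:
            if not permissive:
                raise UnsupportedPackageError(decl_prefix, uri)
            doc.read_diagnostics.append(
                ReadDiagnostic(
                    "sbml",
                    f"unsupported package {decl_prefix!r} ({uri}) is declared "
                    "required; content preserved opaquely",
                )
            )


def declared_packages(doc: Document) -> list[PackageDecl]:
    """One entry per xmlns-declared package namespace on the root."""
    return list(doc.declared_packages)


# -- attribute helpers ------------------------------------------------------


def _get_bool(el, name: str, default: bool, missing: list[str]) -> bool:
    v = el.get(name)
    if v is None:
        missing.append(name)
        return default
    return v == "true"


def _opt_bool(el, name: str, default: bool) -> bool:
    v = el.get(name)
    return default if v is None else v == "true"


def _opt_float(el, name: str) -> Optional[float]:
    v = el.get(name)
    return None if v is None else float(v)


def _opt_int(el, name: str) -> Optional[int]:
    v = el.get(name)
    return None if v is None else int(v)


def _children(el, ns: str, localname: str):
    return [c for c in el if isinstance(c.tag, str)
            and etree.QName(c).namespace == ns
            and etree.QName(c).localname == localname]


def _child(el, ns: str, localname: str):
    found = _children(el, ns, localname)
    return found[0] if found else None


def _list_of(el, ns: str, container: str, item: str):
    lo = _child(el, ns, container)
    return _children(lo, ns, item) if lo is not None else []


def _read_math(el, model: Model, path: str) -> Optional[MathNode]:
    math_el = _child(el, MATHML_NS, "math")
    if math_el is None:
        return None
    inner = [c for c in math_el if isinstance(c.tag, str)]
    if len(inner) != 1:
        model.unsupported_constructs.append(
            (path, "math container without exactly one expression")
        )
        return None
    try:
        return parse_mathml_element(inner[0])
    except UnsupportedMathError as exc:
        model.unsupported_constructs.append((path, str(exc)))
        return None


def _read_annotation(el) -> Annotation:
    ann = Annotation()
    ann.metaid = el.get("metaid")
    sbo = el.get("sboTerm")
    if sbo is not None and sbo.startswith("SBO:"):
        ann.sbo_term = int(sbo[4:])
    notes_el = None
    for c in el:
        if isinstance(c.tag, str) and etree.QName(c).localname == "notes":
            notes_el = c
            break
    if notes_el is not None:
        parts = [etree.tostring(c, encoding="unicode") for c in notes_el]
        ann.notes = "".join(parts).strip() or None
    ann_el = None
    for c in el:
        if isinstance(c.tag, str) and etree.QName(c).localname == "annotation":
            ann_el = c
            break
    if ann_el is not None:
        for c in ann_el:
            if not isinstance(c.tag, str):
                continue
            if etree.QName(c).namespace == RDF_NS:
                terms = _parse_cv_rdf(c)
                if terms is not None:
                    ann.cv_terms.extend(terms)
                    continue
            ann.raw.append(_fragment_bytes(c))
    return ann


def _parse_cv_rdf(rdf_el) -> Optional[list[CVTerm]]:
    """Recognize the standard CV-term RDF pattern; None means 'not it'."""
    terms: list[CVTerm] = []
    descriptions = _children(rdf_el, RDF_NS, "Description")
    if not descriptions:
        return None
    for desc in descriptions:
        for qual_el in desc:
            if not isinstance(qual_el.tag, str):
                continue
            q = etree.QName(qual_el)
            if q.namespace not in (BQBIOL_NS, BQMODEL_NS):
                return None
            bag = _child(qual_el, RDF_NS, "Bag")
            if bag is None:
                return None
            resources = [
                li.get(f"{{{RDF_NS}}}resource")
                for li in _children(bag, RDF_NS, "li")
            ]
            if any(r is None for r in resources):
                return None
            terms.append(CVTerm(q.localname, tuple(resources)))
    return terms


# -- model ------------------------------------------------------------------


def _read_model(el, ns: str, doc: Document) -> Model:
    m = Model(
        id=el.get("id"),
        name=el.get("name"),
        substance_units=el.get("substanceUnits"),
        time_units=el.get("timeUnits"),
        extent_units=el.get("extentUnits"),
        volume_units=el.get("volumeUnits"),
        annotations=_read_annotation(el),
    )
    for fd_el in _list_of(el, ns, "listOfFunctionDefinitions", "functionDefinition"):
        math = _read_math(fd_el, m, f"functionDefinition[{fd_el.get('id')}]")
        if isinstance(math, Lambda):
            m.function_definitions.append(
                FunctionDefinition(id=fd_el.get("id", ""), math=math,
                                   name=fd_el.get("name"))
            )
        else:
            m.unsupported_constructs.append(
                (f"functionDefinition[{fd_el.get('id')}]",
                 "function definition body must be a lambda")
            )
    for ud_el in _list_of(el, ns, "listOfUnitDefinitions", "unitDefinition"):
        units = [
            Unit(
                kind=u.get("kind", "dimensionless"),
                exponent=float(u.get("exponent", "1")),
                scale=int(u.get("scale", "0")),
                multiplier=float(u.get("multiplier", "1")),
            )
            for u in _list_of(ud_el, ns, "listOfUnits", "unit")
        ]
        m.unit_definitions.append(
            UnitDefinition(id=ud_el.get("id", ""), units=units,
                           name=ud_el.get("name"))
        )
    for c_el in _list_of(el, ns, "listOfCompartments", "compartment"):
        missing: list[str] = []
        m.compartments.append(
            Compartment(
                id=c_el.get("id", ""),
                size=_opt_float(c_el, "size"),
                spatial_dimensions=_opt_float(c_el, "spatialDimensions"),
                constant=_get_bool(c_el, "constant", True, missing),
                units=c_el.get("units"),
                name=c_el.get("name"),
                annotations=_read_annotation(c_el),
                missing_attrs=missing,
            )
        )
    for s_el in _list_of(el, ns, "listOfSpecies", "species"):
        missing = []
        amount = _opt_float(s_el, "initialAmount")
        conc = _opt_float(s_el, "initialConcentration")
        if amount is not None and conc is not None:
            doc.read_diagnostics.append(
                ReadDiagnostic(
                    f"species[{s_el.get('id')}]",
                    "both initialAmount and initialConcentration set; "
                    "keeping initialAmount",
                )
            )
            conc = None
        charge = s_el.get(f"{{{FBC_NS}}}charge")
        m.species.append(
            Species(
                id=s_el.get("id", ""),
                compartment=s_el.get("compartment", ""),
                initial_amount=amount,
                initial_concentration=conc,
                has_only_substance_units=_get_bool(
                    s_el, "hasOnlySubstanceUnits", False, missing),
                boundary_condition=_get_bool(
                    s_el, "boundaryCondition", False, missing),
                constant=_get_bool(s_el, "constant", False, missing),
                substance_units=s_el.get("substanceUnits"),
                name=s_el.get("name"),
                chemical_formula=s_el.get(f"{{{FBC_NS}}}chemicalFormula"),
                charge=int(charge) if charge is not None else None,
                annotations=_read_annotation(s_el),
                missing_attrs=missing,
            )
        )
    for p_el in _list_of(el, ns, "listOfParameters", "parameter"):
        missing = []
        m.parameters.append(
            Parameter(
                id=p_el.get("id", ""),
                value=_opt_float(p_el, "value"),
                constant=_get_bool(p_el, "constant", True, missing),
                units=p_el.get("units"),
                name=p_el.get("name"),
                annotations=_read_annotation(p_el),
                missing_attrs=missing,
            )
        )
    for ia_el in _list_of(el, ns, "listOfInitialAssignments", "initialAssignment"):
        math = _read_math(ia_el, m, f"initialAssignment[{ia_el.get('symbol')}]")
        if math is not None:
            m.initial_assignments.append(
                InitialAssignment(symbol=ia_el.get("symbol", ""), math=math)
            )
    _read_rules(el, ns, m)
    _read_reactions(el, ns, m)
    _read_events(el, ns, m)
    _read_fbc(el, m)
    _read_qual(el, m)
    return m


def _read_rules(el, ns: str, m: Model) -> None:
    lo = _child(el, ns, "listOfRules")
    if lo is None:
        return
    for r_el in lo:
        if not isinstance(r_el.tag, str):
            continue
        localname = etree.QName(r_el).localname
        if localname == "algebraicRule":
            m.unsupported_constructs.append(
                ("listOfRules", "algebraic rules are not supported")
            )
            continue
        kind = {"assignmentRule": "assignment", "rateRule": "rate"}.get(localname)
        if kind is None:
            continue
        variable = r_el.get("variable", "")
        math = _read_math(r_el, m, f"{localname}[{variable}]")
        if math is not None:
            m.rules.append(Rule(kind=kind, variable=variable, math=math))


def _read_reactions(el, ns: str, m: Model) -> None:
    for r_el in _list_of(el, ns, "listOfReactions", "reaction"):
        missing: list[str] = []
        rid = r_el.get("id", "")
        reaction = Reaction(
            id=rid,
            reversible=_get_bool(r_el, "reversible", False, missing),
            name=r_el.get("name"),
            lower_flux_bound=r_el.get(f"{{{FBC_NS}}}lowerFluxBound"),
            upper_flux_bound=r_el.get(f"{{{FBC_NS}}}upperFluxBound"),
            annotations=_read_annotation(r_el),
            missing_attrs=missing,
        )
        for side, attr in (("listOfReactants", "reactants"),
                           ("listOfProducts", "products")):
            for ref_el in _list_of(r_el, ns, side, "speciesReference"):
                ref_missing: list[str] = []
                getattr(reaction, attr).append(
                    SpeciesReference(
                        species=ref_el.get("species", ""),
                        stoichiometry=float(ref_el.get("stoichiometry", "1")),
                        constant=_get_bool(ref_el, "constant", True, ref_missing),
                        id=ref_el.get("id"),
                        missing_attrs=ref_missing,
                    )
                )
        for mod_el in _list_of(r_el, ns, "listOfModifiers",
                               "modifierSpeciesReference"):
            reaction.modifiers.append(mod_el.get("species", ""))
        kl_el = _child(r_el, ns, "kineticLaw")
        if kl_el is not None:
            kl = KineticLaw(math=_read_math(kl_el, m, f"reaction[{rid}]/kineticLaw"))
            for lp_el in _list_of(kl_el, ns, "listOfLocalParameters",
                                  "localParameter"):
                kl.local_parameters.append(
                    LocalParameter(
                        id=lp_el.get("id", ""),
                        value=_opt_float(lp_el, "value"),
                        units=lp_el.get("units"),
                    )
                )
            reaction.kinetic_law = kl
        gpa_el = _child(r_el, FBC_NS, "geneProductAssociation")
        if gpa_el is not None:
            inner = [c for c in gpa_el if isinstance(c.tag, str)]
            if len(inner) == 1:
                reaction.gene_association = _read_gpa(inner[0])
        m.reactions.append(reaction)


def _read_gpa(el) -> fbc_mod.GPA:
    q = etree.QName(el)
    if q.localname == "geneProductRef":
        return fbc_mod.gpa_ref(el.get(f"{{{FBC_NS}}}geneProduct", ""))
    children = [_read_gpa(c) for c in el if isinstance(c.tag, str)]
    if q.localname == "and":
        return fbc_mod.GPA(and_=children)
    if q.localname == "or":
        return fbc_mod.GPA(or_=children)
    raise SbmlFormatError(f"unexpected element <{q.localname}> in GPA")


def _read_events(el, ns: str, m: Model) -> None:
    for e_el in _list_of(el, ns, "listOfEvents", "event"):
        missing: list[str] = []
        eid = e_el.get("id")
        trig_el = _child(e_el, ns, "trigger")
        if trig_el is None:
            m.unsupported_constructs.append(
                (f"event[{eid}]", "event without a trigger")
            )
            continue
        trig_missing: list[str] = []
        trig_math = _read_math(trig_el, m, f"event[{eid}]/trigger")
        if trig_math is None:
            continue
        trigger = Trigger(
            math=trig_math,
            initial_value=_get_bool(trig_el, "initialValue", True, trig_missing),
            persistent=_get_bool(trig_el, "persistent", True, trig_missing),
            missing_attrs=trig_missing,
        )
        delay_el = _child(e_el, ns, "delay")
        delay = (
            _read_math(delay_el, m, f"event[{eid}]/delay")
            if delay_el is not None else None
        )
        ev = Event(
            trigger=trigger,
            id=eid,
            delay=delay,
            use_values_from_trigger_time=_get_bool(
                e_el, "useValuesFromTriggerTime", True, missing),
            annotations=_read_annotation(e_el),
            missing_attrs=missing,
        )
        for ea_el in _list_of(e_el, ns, "listOfEventAssignments",
                              "eventAssignment"):
            math = _read_math(ea_el, m, f"event[{eid}]/eventAssignment")
            if math is not None:
                ev.assignments.append(
                    EventAssignment(variable=ea_el.get("variable", ""), math=math)
                )
        m.events.append(ev)


def _read_fbc(el, m: Model) -> None:
    lo_obj = _child(el, FBC_NS, "listOfObjectives")
    lo_gp = _child(el, FBC_NS, "listOfGeneProducts")
    has_fbc_attrs = any(
        r.lower_flux_bound or r.upper_flux_bound for r in m.reactions
    )
    if lo_obj is None and lo_gp is None and not has_fbc_attrs:
        return
    ext = fbc_mod.FbcExtension(
        strict=el.get(f"{{{FBC_NS}}}strict", "true") == "true"
    )
    if lo_obj is not None:
        ext.active_objective = lo_obj.get(f"{{{FBC_NS}}}activeObjective")
        for o_el in _children(lo_obj, FBC_NS, "objective"):
            obj = fbc_mod.Objective(
                id=o_el.get(f"{{{FBC_NS}}}id", ""),
                type=o_el.get(f"{{{FBC_NS}}}type", "maximize"),
            )
            for fo_el in _list_of(o_el, FBC_NS, "listOfFluxObjectives",
                                  "fluxObjective"):
                obj.terms.append(
                    (
                        fo_el.get(f"{{{FBC_NS}}}reaction", ""),
                        float(fo_el.get(f"{{{FBC_NS}}}coefficient", "1")),
                    )
                )
            ext.objectives.append(obj)
    if lo_gp is not None:
        for gp_el in _children(lo_gp, FBC_NS, "geneProduct"):
            ext.gene_products.append(
                fbc_mod.GeneProduct(
                    id=gp_el.get(f"{{{FBC_NS}}}id", ""),
                    label=gp_el.get(f"{{{FBC_NS}}}label", ""),
                )
            )
    m.fbc = ext


def _read_qual(el, m: Model) -> None:
    lo_qs = _child(el, QUAL_NS, "listOfQualitativeSpecies")
    lo_tr = _child(el, QUAL_NS, "listOfTransitions")
    if lo_qs is None and lo_tr is None:
        return
    qm = qual_mod.QualModel()
    if lo_qs is not None:
        for qs_el in _children(lo_qs, QUAL_NS, "qualitativeSpecies"):
            missing: list[str] = []
            constant_attr = qs_el.get(f"{{{QUAL_NS}}}constant")
            if constant_attr is None:
                missing.append("constant")
            qm.species.append(
                qual_mod.QualSpecies(
                    id=qs_el.get(f"{{{QUAL_NS}}}id", ""),
                    compartment=qs_el.get(f"{{{QUAL_NS}}}compartment"),
                    max_level=int(qs_el.get(f"{{{QUAL_NS}}}maxLevel", "1")),
                    initial_level=(
                        int(qs_el.get(f"{{{QUAL_NS}}}initialLevel"))
                        if qs_el.get(f"{{{QUAL_NS}}}initialLevel") is not None
                        else None
                    ),
                    constant=constant_attr == "true",
                    missing_attrs=missing,
                )
            )
    if lo_tr is not None:
        for tr_el in _children(lo_tr, QUAL_NS, "transition"):
            tr = qual_mod.QualTransition(id=tr_el.get(f"{{{QUAL_NS}}}id"))
            for in_el in _list_of(tr_el, QUAL_NS, "listOfInputs", "input"):
                effect = in_el.get(f"{{{QUAL_NS}}}transitionEffect", "none")
                if effect == "consumption":
                    m.unsupported_constructs.append(
                        (
                            f"transition[{tr.id}]/input",
                            "transitionEffect=\"consumption\" on qual inputs "
                            "is not supported",
                        )
                    )
                thr = in_el.get(f"{{{QUAL_NS}}}thresholdLevel")
                tr.inputs.append(
                    qual_mod.QualInput(
                        qual_species=in_el.get(
                            f"{{{QUAL_NS}}}qualitativeSpecies", ""),
                        sign=in_el.get(f"{{{QUAL_NS}}}sign", "unknown"),
                        threshold=int(thr) if thr is not None else None,
                        transition_effect=effect,
                    )
                )
            for out_el in _list_of(tr_el, QUAL_NS, "listOfOutputs", "output"):
                tr.outputs.append(
                    qual_mod.QualOutput(
                        qual_species=out_el.get(
                            f"{{{QUAL_NS}}}qualitativeSpecies", ""),
                        transition_effect=out_el.get(
                            f"{{{QUAL_NS}}}transitionEffect", "assignmentLevel"),
                    )
                )
            lo_ft = _child(tr_el, QUAL_NS, "listOfFunctionTerms")
            if lo_ft is not None:
                for ft_el in _children(lo_ft, QUAL_NS, "functionTerm"):
                    math = _read_math(
                        ft_el, m, f"transition[{tr.id}]/functionTerm")
                    if math is not None:
                        tr.function_terms.append(
                            qual_mod.FunctionTerm(
                                result_level=int(
                                    ft_el.get(f"{{{QUAL_NS}}}resultLevel", "0")),
                                math=math,
                            )
                        )
                dt_el = _child(lo_ft, QUAL_NS, "defaultTerm")
                if dt_el is not None:
                    tr.default_term = qual_mod.DefaultTerm(
                        result_level=int(
                            dt_el.get(f"{{{QUAL_NS}}}resultLevel", "0"))
                    )
            qm.transitions.append(tr)
    m.qual = qm


# ===========================================================================
# Writing
# ===========================================================================


def _esc(v: str) -> str:
    return (
        str(v)
        .replace("&", "&amp;")
        .replace("<", "&lt;")
        .replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _fmt_attrs(attrs: dict[str, object]) -> str:
    parts = []
    for k in sorted(attrs):
        v = attrs[k]
        if v is None:
            continue
        if isinstance(v, bool):
            v = "true" if v else "false"
        elif isinstance(v, float):
            v = format_number(v)
        parts.append(f' {k}="{_esc(v)}"')
    return "".join(parts)


class _Writer:
    def __init__(self, doc: Document, version: int):
        self.doc = doc
        self.version = version
        self.lines: list[str] = []
        self.packages = self._collect_packages()

    def _collect_packages(self) -> list[PackageDecl]:
        decls: dict[str, PackageDecl] = {}
        for p in self.doc.declared_packages:
            decls[p.namespace_uri] = p
        m = self.doc.model
        if m is not None:
            uses_fbc = (
                m.fbc is not None
                or any(s.chemical_formula is not None or s.charge is not None
                       for s in m.species)
                or any(r.lower_flux_bound or r.upper_flux_bound
                       or r.gene_association is not None
                       for r in m.reactions)
            )
            if uses_fbc and FBC_NS not in decls:
                decls[FBC_NS] = PackageDecl("fbc", FBC_NS, False)
            if m.qual is not None and QUAL_NS not in decls:
                decls[QUAL_NS] = PackageDecl("qual", QUAL_NS, False)
        return sorted(decls.values(), key=lambda d: d.prefix)

    def emit(self, line: str, indent: int) -> None:
        self.lines.append("  " * indent + line)

    def element(self, tag: str, attrs: dict, indent: int,
                body=None, annotations: Annotation | None = None,
                element_id: str | None = None) -> None:
        """Emit one element; ``body`` is a callable writing children."""
        if annotations is not None:
            attrs = dict(attrs)
            if annotations.sbo_term is not None:
                attrs["sboTerm"] = f"SBO:{annotations.sbo_term:07d}"
            if annotations.metaid is not None or annotations.cv_terms:
                attrs["metaid"] = annotations.metaid or f"meta_{element_id}"
        rendered = _fmt_attrs(attrs)
        has_ann = annotations is not None and not annotations.is_empty()
        if body is None and not has_ann:
            if tag.startswith("listOf"):
                self.emit(f"<{tag}{rendered}>", indent)
                self.emit(f"</{tag}>", indent)
            else:
                self.emit(f"<{tag}{rendered}/>", indent)
            return
        self.emit(f"<{tag}{rendered}>", indent)
        if has_ann:
            self._write_annotation(annotations, indent + 1,
                                   attrs.get("metaid"))
        if body is not None:
            body(indent + 1)
        self.emit(f"</{tag}>", indent)

    def _write_annotation(self, ann: Annotation, indent: int,
                          metaid: str | None) -> None:
        if ann.notes is not None:
            self.emit("<notes>", indent)
            for ln in ann.notes.splitlines():
                self.emit(ln, indent + 1)
            self.emit("</notes>", indent)
        if ann.cv_terms or ann.raw:
            self.emit("<annotation>", indent)
            if ann.cv_terms:
                self._write_cv_terms(ann.cv_terms, indent + 1, metaid or "meta")
            for fragment in ann.raw:
                for ln in fragment.decode("utf-8").splitlines():
                    self.emit(ln, indent + 1)
            self.emit("</annotation>", indent)

    def _write_cv_terms(self, terms: list[CVTerm], indent: int,
                        metaid: str) -> None:
        self.emit(
            f'<rdf:RDF xmlns:bqbiol="{BQBIOL_NS}" xmlns:bqmodel="{BQMODEL_NS}" '
            f'xmlns:rdf="{RDF_NS}">',
            indent,
        )
        self.emit(f'<rdf:Description rdf:about="#{metaid}">', indent + 1)
        for term in terms:
            prefix = "bqmodel" if term.qualifier in _MODEL_QUALIFIERS else "bqbiol"
            self.emit(f"<{prefix}:{term.qualifier}>", indent + 2)
            self.emit("<rdf:Bag>", indent + 3)
            for res in term.resources:
                self.emit(f'<rdf:li rdf:resource="{_esc(res)}"/>', indent + 4)
            self.emit("</rdf:Bag>", indent + 3)
            self.emit(f"</{prefix}:{term.qualifier}>", indent + 2)
        self.emit("</rdf:Description>", indent + 1)
        self.emit("</rdf:RDF>", indent)

    def write_math(self, math: MathNode, indent: int) -> None:
        self.emit(f'<math xmlns="{MATHML_NS}">', indent)
        self.lines.extend(
            "  " * (indent + 1) + ln for ln in mathml_lines(math))
        self.emit("</math>", indent)

    # -- document --------------------------------------------------------

    def write(self) -> bytes:
        core_ns = CORE_NS_V1 if self.version == 1 else CORE_NS_V2
        attrs: dict[str, object] = {
            "level": "3",
            "version": str(self.version),
            "xmlns": core_ns,
        }
        for decl in self.packages:
            attrs[f"xmlns:{decl.prefix}"] = decl.namespace_uri
            attrs[f"{decl.prefix}:required"] = decl.required
        self.emit('<?xml version="1.0" encoding="UTF-8"?>', 0)
        m = self.doc.model
        if m is None:
            raise SbmlFormatError("cannot write a document without a model")
        self.emit(f"<sbml{_fmt_attrs(attrs)}>", 0)
        self._write_model(m, 1)
        for fragment in self.doc.unknown_elements:
            for ln in fragment.decode("utf-8").splitlines():
                self.emit(ln, 1)
        self.emit("</sbml>", 0)
        return ("\n".join(self.lines) + "\n").encode("utf-8")

    def _write_model(self, m: Model, indent: int) -> None:
        attrs = {
            "id": m.id,
            "name": m.name,
            "substanceUnits": m.substance_units,
            "timeUnits": m.time_units,
            "extentUnits": m.extent_units,
            "volumeUnits": m.volume_units,
        }
        has_fbc = m.fbc is not None
        if has_fbc:
            attrs["fbc:strict"] = m.fbc.strict

        def body(ind: int) -> None:
            self._write_function_definitions(m, ind)
            self._write_unit_definitions(m, ind)
            self._write_compartments(m, ind)
            self._write_species(m, ind)
            self._write_parameters(m, ind)
            self._write_initial_assignments(m, ind)
            self._write_rules(m, ind)
            self._write_reactions(m, ind)
            self._write_events(m, ind)
            if m.fbc is not None:
                self._write_fbc(m, ind)
            if m.qual is not None:
                self._write_qual(m, ind)

        needs_body = any(
            [m.function_definitions, m.unit_definitions, m.compartments,
             m.species, m.parameters, m.initial_assignments, m.rules,
             m.reactions, m.events, m.fbc is not None, m.qual is not None]
        )
        self.element("model", attrs, indent,
                     body=body if needs_body else None,
                     annotations=m.annotations, element_id=m.id or "model")

    def _write_function_definitions(self, m: Model, ind: int) -> None:
        if not m.function_definitions:
            return
        self.emit("<listOfFunctionDefinitions>", ind)
        for fd in m.function_definitions:
            self.element(
                "functionDefinition", {"id": fd.id, "name": fd.name}, ind + 1,
                body=lambda i, fd=fd: self.write_math(fd.math, i),
            )
        self.emit("</listOfFunctionDefinitions>", ind)

    def _write_unit_definitions(self, m: Model, ind: int) -> None:
        if not m.unit_definitions:
            return
        self.emit("<listOfUnitDefinitions>", ind)
        for ud in m.unit_definitions:
            def body(i, ud=ud):
                self.emit("<listOfUnits>", i)
                for u in ud.units:
                    self.element(
                        "unit",
                        {"exponent": u.exponent, "kind": u.kind,
                         "multiplier": u.multiplier, "scale": str(u.scale)},
                        i + 1,
                    )
                self.emit("</listOfUnits>", i)
            self.element("unitDefinition", {"id": ud.id, "name": ud.name},
                         ind + 1, body=body)
        self.emit("</listOfUnitDefinitions>", ind)

    def _write_compartments(self, m: Model, ind: int) -> None:
        if not m.compartments:
            return
        self.emit("<listOfCompartments>", ind)
        for c in m.compartments:
            self.element(
                "compartment",
                {"constant": c.constant, "id": c.id, "name": c.name,
                 "size": c.size, "spatialDimensions": c.spatial_dimensions,
                 "units": c.units},
                ind + 1, annotations=c.annotations, element_id=c.id,
            )
        self.emit("</listOfCompartments>", ind)

    def _write_species(self, m: Model, ind: int) -> None:
        if not m.species:
            return
        self.emit("<listOfSpecies>", ind)
        for s in m.species:
            attrs = {
                "boundaryCondition": s.boundary_condition,
                "compartment": s.compartment,
                "constant": s.constant,
                "hasOnlySubstanceUnits": s.has_only_substance_units,
                "id": s.id,
                "initialAmount": s.initial_amount,
                "initialConcentration": s.initial_concentration,
                "name": s.name,
                "substanceUnits": s.substance_units,
            }
            if s.chemical_formula is not None:
                attrs["fbc:chemicalFormula"] = s.chemical_formula
            if s.charge is not None:
                attrs["fbc:charge"] = str(s.charge)
            self.element("species", attrs, ind + 1,
                         annotations=s.annotations, element_id=s.id)
        self.emit("</listOfSpecies>", ind)

    def _write_parameters(self, m: Model, ind: int) -> None:
        if not m.parameters:
            return
        self.emit("<listOfParameters>", ind)
        for p in m.parameters:
            self.element(
                "parameter",
                {"constant": p.constant, "id": p.id, "name": p.name,
                 "units": p.units, "value": p.value},
                ind + 1, annotations=p.annotations, element_id=p.id,
            )
        self.emit("</listOfParameters>", ind)

    def _write_initial_assignments(self, m: Model, ind: int) -> None:
        if not m.initial_assignments:
            return
        self.emit("<listOfInitialAssignments>", ind)
        for ia in m.initial_assignments:
            self.element(
                "initialAssignment", {"symbol": ia.symbol}, ind + 1,
                body=lambda i, ia=ia: self.write_math(ia.math, i),
            )
        self.emit("</listOfInitialAssignments>", ind)

    def _write_rules(self, m: Model, ind: int) -> None:
        if not m.rules:
            return
        self.emit("<listOfRules>", ind)
        for r in m.rules:
            tag = "assignmentRule" if r.kind == "assignment" else "rateRule"
            self.element(
                tag, {"variable": r.variable}, ind + 1,
                body=lambda i, r=r: self.write_math(r.math, i),
            )
        self.emit("</listOfRules>", ind)

    def _write_reactions(self, m: Model, ind: int) -> None:
        if not m.reactions:
            return
        self.emit("<listOfReactions>", ind)
        for r in m.reactions:
            attrs: dict[str, object] = {
                "id": r.id, "name": r.name, "reversible": r.reversible,
            }
            if r.lower_flux_bound is not None:
                attrs["fbc:lowerFluxBound"] = r.lower_flux_bound
            if r.upper_flux_bound is not None:
                attrs["fbc:upperFluxBound"] = r.upper_flux_bound

            def body(i, r=r):
                for tag, refs in (("listOfReactants", r.reactants),
                                  ("listOfProducts", r.products)):
                    if refs:
                        self.emit(f"<{tag}>", i)
                        for ref in refs:
                            self.element(
                                "speciesReference",
                                {"constant": ref.constant, "id": ref.id,
                                 "species": ref.species,
                                 "stoichiometry": ref.stoichiometry},
                                i + 1,
                            )
                        self.emit(f"</{tag}>", i)
                if r.modifiers:
                    self.emit("<listOfModifiers>", i)
                    for mod in r.modifiers:
                        self.element("modifierSpeciesReference",
                                     {"species": mod}, i + 1)
                    self.emit("</listOfModifiers>", i)
                if r.gene_association is not None:
                    self.emit("<fbc:geneProductAssociation>", i)
                    self._write_gpa(r.gene_association, i + 1)
                    self.emit("</fbc:geneProductAssociation>", i)
                if r.kinetic_law is not None:
                    def kl_body(j, kl=r.kinetic_law):
                        if kl.math is not None:
                            self.write_math(kl.math, j)
                        if kl.local_parameters:
                            self.emit("<listOfLocalParameters>", j)
                            for lp in kl.local_parameters:
                                self.element(
                                    "localParameter",
                                    {"id": lp.id, "units": lp.units,
                                     "value": lp.value},
                                    j + 1,
                                )
                            self.emit("</listOfLocalParameters>", j)
                    self.element("kineticLaw", {}, i, body=kl_body)

            has_body = (r.reactants or r.products or r.modifiers
                        or r.kinetic_law is not None
                        or r.gene_association is not None)
            self.element("reaction", attrs, ind + 1,
                         body=body if has_body else None,
                         annotations=r.annotations, element_id=r.id)
        self.emit("</listOfReactions>", ind)

    def _write_gpa(self, gpa: fbc_mod.GPA, ind: int) -> None:
        if gpa.ref is not None:
            self.emit(f'<fbc:geneProductRef fbc:geneProduct="{gpa.ref}"/>', ind)
            return
        tag = "fbc:and" if gpa.and_ is not None else "fbc:or"
        self.emit(f"<{tag}>", ind)
        for child in gpa.and_ or gpa.or_:
            self._write_gpa(child, ind + 1)
        self.emit(f"</{tag}>", ind)

    def _write_events(self, m: Model, ind: int) -> None:
        if not m.events:
            return
        self.emit("<listOfEvents>", ind)
        for e in m.events:
            def body(i, e=e):
                self.element(
                    "trigger",
                    {"initialValue": e.trigger.initial_value,
                     "persistent": e.trigger.persistent},
                    i,
                    body=lambda j, t=e.trigger: self.write_math(t.math, j),
                )
                if e.delay is not None:
                    self.element("delay", {}, i,
                                 body=lambda j, d=e.delay: self.write_math(d, j))
                if e.assignments:
                    self.emit("<listOfEventAssignments>", i)
                    for ea in e.assignments:
                        self.element(
                            "eventAssignment", {"variable": ea.variable},
                            i + 1,
                            body=lambda j, ea=ea: self.write_math(ea.math, j),
                        )
                    self.emit("</listOfEventAssignments>", i)
            self.element(
                "event",
                {"id": e.id,
                 "useValuesFromTriggerTime": e.use_values_from_trigger_time},
                ind + 1, body=body, annotations=e.annotations,
                element_id=e.id or "event",
            )
        self.emit("</listOfEvents>", ind)

    def _write_fbc(self, m: Model, ind: int) -> None:
        ext: fbc_mod.FbcExtension = m.fbc
        if ext.objectives:
            attrs = {"fbc:activeObjective": ext.active_objective}
            self.emit(f"<fbc:listOfObjectives{_fmt_attrs(attrs)}>", ind)
            for obj in ext.objectives:
                self.emit(
                    f'<fbc:objective fbc:id="{obj.id}" fbc:type="{obj.type}">',
                    ind + 1,
                )
                self.emit("<fbc:listOfFluxObjectives>", ind + 2)
                for rid, coeff in obj.terms:
                    self.emit(
                        f'<fbc:fluxObjective fbc:coefficient="'
                        f'{format_number(coeff)}" fbc:reaction="{rid}"/>',
                        ind + 3,
                    )
                self.emit("</fbc:listOfFluxObjectives>", ind + 2)
                self.emit("</fbc:objective>", ind + 1)
            self.emit("</fbc:listOfObjectives>", ind)
        if ext.gene_products:
            self.emit("<fbc:listOfGeneProducts>", ind)
            for gp in ext.gene_products:
                self.emit(
                    f'<fbc:geneProduct fbc:id="{gp.id}" '
                    f'fbc:label="{_esc(gp.label)}"/>',
                    ind + 1,
                )
            self.emit("</fbc:listOfGeneProducts>", ind)

    def _write_qual(self, m: Model, ind: int) -> None:
        qm: qual_mod.QualModel = m.qual
        if qm.species:
            self.emit("<qual:listOfQualitativeSpecies>", ind)
            for qs in qm.species:
                attrs = {
                    "qual:compartment": qs.compartment,
                    "qual:constant": qs.constant,
                    "qual:id": qs.id,
                    "qual:initialLevel": (
                        str(qs.initial_level)
                        if qs.initial_level is not None else None
                    ),
                    "qual:maxLevel": str(qs.max_level),
                }
                self.element("qual:qualitativeSpecies", attrs, ind + 1)
            self.emit("</qual:listOfQualitativeSpecies>", ind)
        if qm.transitions:
            self.emit("<qual:listOfTransitions>", ind)
            for tr in qm.transitions:
                self.emit(
                    f"<qual:transition{_fmt_attrs({'qual:id': tr.id})}>",
                    ind + 1,
                )
                if tr.inputs:
                    self.emit("<qual:listOfInputs>", ind + 2)
                    for inp in tr.inputs:
                        attrs = {
                            "qual:qualitativeSpecies": inp.qual_species,
                            "qual:sign": inp.sign,
                            "qual:thresholdLevel": (
                                str(inp.threshold)
                                if inp.threshold is not None else None
                            ),
                            "qual:transitionEffect": inp.transition_effect,
                        }
                        self.element("qual:input", attrs, ind + 3)
                    self.emit("</qual:listOfInputs>", ind + 2)
                if tr.outputs:
                    self.emit("<qual:listOfOutputs>", ind + 2)
                    for out in tr.outputs:
                        self.element(
                            "qual:output",
                            {"qual:qualitativeSpecies": out.qual_species,
                             "qual:transitionEffect": out.transition_effect},
                            ind + 3,
                        )
                    self.emit("</qual:listOfOutputs>", ind + 2)
                self.emit("<qual:listOfFunctionTerms>", ind + 2)
                for ft in tr.function_terms:
                    self.element(
                        "qual:functionTerm",
                        {"qual:resultLevel": str(ft.result_level)},
                        ind + 3,
                        body=lambda j, ft=ft: self.write_math(ft.math, j),
                    )
                if tr.default_term is not None:
                    self.element(
                        "qual:defaultTerm",
                        {"qual:resultLevel": str(tr.default_term.result_level)},
                        ind + 3,
                    )
                self.emit("</qual:listOfFunctionTerms>", ind + 2)
                self.emit("</qual:transition>", ind + 1)
            self.emit("</qual:listOfTransitions>", ind)


def write_sbml(doc: Document, version: int = 2) -> bytes:
    """Serialize a document to canonical SBML Level 3 XML (UTF-8 bytes).

    ``version`` selects the core namespace (2 by default, 1 on request).
    """
    if version not in (1, 2):
        raise ValueError("SBML Level 3 version must be 1 or 2")
    return _Writer(doc, version).write()
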