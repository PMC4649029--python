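"""SBML Level 2/3 reader producing :class:`~invjac.models.KineticModel`.

Kinetic models (e.g. from the BioModels database) are parsed from SBML with
their kinetic laws compiled from content MathML into sympy expressions.
Species with ``boundaryCondition="true"`` or ``constant="true"`` are held at
their initial concentration and treated as fixed parameters rather than
dynamic state, following the SBML convention for constant metabolites.

Supported constructs: compartments (rates are divided by the species'
compartment size), global and local parameters, function definitions
(inlined), assignment rules for parameters (substituted, iterated to a
fixed point), reversibility flags and modifier lists.  Events, algebraic
and rate rules, delays, and time-dependent csymbols are rejected loudly —
a model that cannot be represented exactly is not approximated.
"""

from __future__ import annotations

import logging

import numpy as np
import sympy as sp
from lxml import etree

from .models import KineticModel

logger = logging.getLogger("invjac")

__all__ = ["read_sbml_model", "SBMLError"]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SBMLError(ValueError):
    """The SBML file is missing something or uses an unsupported construct."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _bool_attr(el, name: str, default: bool) -> bool:
    v = el.get(name)
    if v is None:
        return default
    return v.lower() == "true"


# ---------------------------------------------------------------------------
# content MathML -> sympy
# ---------------------------------------------------------------------------

_BINARY = {
    "divide": lambda a, b: a / b,
    "power": lambda a, b: a**b,
    "minus": lambda a, b: a - b,
}
_NARY = {
    "plus": lambda args: sp.Add(*args) if args else sp.Integer(0),
    "times": lambda args: sp.Mul(*args) if args else sp.Integer(1),
}
_UNARY = {
    "exp": sp.exp,
    "ln": sp.log,
    "abs": sp.Abs,
    "floor": sp.floor,
    "ceiling": sp.ceiling,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "tanh": sp.tanh,
}
_RELATIONAL = {
    "lt": sp.Lt, "leq": sp.Le, "gt": sp.Gt, "geq": sp.Ge, "eq": sp.Eq, "neq": sp.Ne,
}


def _parse_cn(el) -> sp.Expr:
    ctype = el.get("type", "real")
    parts = [el.text or ""]
    sep_tail = None
    for child in el:
        if _local(child.tag) == "sep":
            sep_tail = child.tail or ""
    if ctype in ("real", "integer", ""):
        return sp.Float(float(parts[0].strip())) if ctype == "real" else sp.Integer(int(parts[0].strip()))
    if ctype == "e-notation":
        mant = float(parts[0].strip())
        expo = int(float(sep_tail.strip()))
        return sp.Float(mant * 10.0**expo)
    if ctype == "rational":
        return sp.Rational(int(parts[0].strip()), int(float(sep_tail.strip())))
    raise SBMLError(f"unsupported cn type {ctype!r}")


def _parse_math(el, funcdefs: dict) -> sp.Expr:
    """Recursively convert one content-MathML element to sympy."""
    tag = _local(el.tag)
    if tag == "math":
        children = [c for c in el if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLError("math element must contain exactly one expression")
        return _parse_math(children[0], funcdefs)
    if tag == "ci":
        return sp.Symbol(el.text.strip())
    if tag == "cn":
        return _parse_cn(el)
    if tag == "csymbol":
        raise SBMLError(
            f"unsupported csymbol {el.get('definitionURL', '')!r} (time/delay)"
        )
    if tag == "pi":
        return sp.pi
    if tag == "exponentiale":
        return sp.E
    if tag == "true":
        return sp.true
    if tag == "false":
        return sp.false
    if tag == "notanumber":
        raise SBMLError("NaN literal in kinetic law")
    if tag == "piecewise":
        pieces = []
        otherwise = sp.Integer(0)
        for child in el:
            ctag = _local(child.tag)
            sub = [c for c in child if isinstance(c.tag, str)]
            if ctag == "piece":
                val, cond = (_parse_math(s, funcdefs) for s in sub)
                pieces.append((val, cond))
            elif ctag == "otherwise":
                otherwise = _parse_math(sub[0], funcdefs)
        return sp.Piecewise(*pieces, (otherwise, True))
    if tag == "apply":
        children = [c for c in el if isinstance(c.tag, str)]
        op = children[0]
        op_tag = _local(op.tag)
        args = [_parse_math(c, funcdefs) for c in children[1:]]
        if op_tag == "ci":  # user function definition application
            fname = op.text.strip()
            if fname not in funcdefs:
                raise SBMLError(f"call to undefined function {fname!r}")
            params, body = funcdefs[fname]
            if len(args) != len(params):
                raise SBMLError(f"function {fname!r} arity mismatch")
            return body.xreplace(dict(zip(params, args)))
        if op_tag in _NARY:
            return _NARY[op_tag](args)
        if op_tag == "minus":
            if len(args) == 1:
                return -args[0]
            return _BINARY["minus"](*args)
        if op_tag in _BINARY:
            if len(args) != 2:
                raise SBMLError(f"{op_tag} expects 2 arguments")
            return _BINARY[op_tag](args[0], args[1])
        if op_tag in _UNARY:
            if len(args) != 1:
                raise SBMLError(f"{op_tag} expects 1 argument")
            return _UNARY[op_tag](args[0])
        if op_tag == "root":
            degree = sp.Integer(2)
            for c in children[1:]:
                if _local(c.tag) == "degree":
                    degree = _parse_math([x for x in c if isinstance(x.tag, str)][0], funcdefs)
            return args[-1] ** (sp.Integer(1) / degree)
        if op_tag == "log":
            base = sp.Integer(10)
            vals = []
            for c in children[1:]:
                if _local(c.tag) == "logbase":
                    base = _parse_math([x for x in c if isinstance(x.tag, str)][0], funcdefs)
                else:
                    vals.append(_parse_math(c, funcdefs))
            return sp.log(vals[-1], base)
        if op_tag in _RELATIONAL:
            return _RELATIONAL[op_tag](args[0], args[1])
        if op_tag == "and":
            return sp.And(*args)
        if op_tag == "or":
            return sp.Or(*args)
        if op_tag == "not":
            return sp.Not(args[0])
        raise SBMLError(f"unsupported MathML operator {op_tag!r}")
    if tag in ("degree", "logbase", "sep"):
        raise SBMLError(f"misplaced MathML element {tag!r}")
    raise SBMLError(f"unsupported MathML element {tag!r}")


def _find(el, name: str):
    for child in el:
        if isinstance(child.tag, str) and _local(child.tag) == name:
            return child
    return None


def _iter(el, name: str):
    container = _find(el, name) if name.startswith("listOf") else el
    if container is None:
        return []
    return [c for c in container if isinstance(c.tag, str)]


def read_sbml_model(path: str) -> KineticModel:
    """Parse an SBML file into a :class:`KineticModel`.

    Boundary/constant species are excluded from the dynamic state and their
    initial concentrations substituted into the rate laws as fixed numbers;
    the remaining species define the state vector in document order.
    dS_i/dt contributions are each reaction's kinetic law divided by the
    species' compartment size (SBML kinetic laws are in substance/time).
    """
    tree = etree.parse(path)
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLError(f"{path}: not an SBML document")
    model_el = _find(root, "model")
    if model_el is None:
        raise SBMLError(f"{path}: no <model> element")
    model_id = model_el.get("id") or model_el.get("name") or "sbml_model"

    # constants: compartments, parameters, boundary species
    fixed: dict[str, float] = {}
    compartments: dict[str, float] = {}
    for comp in _iter(model_el, "listOfCompartments"):
        size = comp.get("size") or comp.get("volume") or "1"
        compartments[comp.get("id")] = float(size)
        fixed[comp.get("id")] = float(size)

    funcdefs: dict[str, tuple[list[sp.Symbol], sp.Expr]] = {}
    for fd in _iter(model_el, "listOfFunctionDefinitions"):
        math = _find(fd, "math")
        lam = [c for c in math if isinstance(c.tag, str)][0]
        if _local(lam.tag) != "lambda":
            raise SBMLError("function definition without lambda")
        bvars: list[sp.Symbol] = []
        body = None
        for c in lam:
            if not isinstance(c.tag, str):
                continue
            if _local(c.tag) == "bvar":
                ci = [x for x in c if isinstance(x.tag, str)][0]
                bvars.append(sp.Symbol(ci.text.strip()))
            else:
                body = _parse_math(c, funcdefs)
        if body is None:
            raise SBMLError("function definition without body")
        funcdefs[fd.get("id")] = (bvars, body)

    for par in _iter(model_el, "listOfParameters"):
        if par.get("value") is not None:
            fixed[par.get("id")] = float(par.get("value"))

    species_order: list[str] = []
    boundary: list[str] = []
    initial: dict[str, float] = {}
    species_comp: dict[str, str] = {}
    for s in _iter(model_el, "listOfSpecies"):
        sid = s.get("id")
        comp = s.get("compartment")
        species_comp[sid] = comp
        if s.get("initialConcentration") is not None:
            conc = float(s.get("initialConcentration"))
        elif s.get("initialAmount") is not None:
            conc = float(s.get("initialAmount")) / compartments.get(comp, 1.0)
        else:
            conc = 0.0
        initial[sid] = conc
        if _bool_attr(s, "boundaryCondition", False) or _bool_attr(s, "constant", False):
            boundary.append(sid)
            fixed[sid] = conc
        else:
            species_order.append(sid)
    if not species_order:
        raise SBMLError(f"{path}: no dynamic species")

    # assignment rules: substitute to fixed point; rate/algebraic rules rejected
    assignments: dict[sp.Symbol, sp.Expr] = {}
    for rule in _iter(model_el, "listOfRules"):
        rtag = _local(rule.tag)
        if rtag == "assignmentRule":
            var = rule.get("variable")
            if var in species_order:
                raise SBMLError(
                    f"assignment rule targets dynamic species {var!r}; unsupported"
                )
            assignments[sp.Symbol(var)] = _parse_math(_find(rule, "math"), funcdefs)
        elif rtag in ("rateRule", "algebraicRule"):
            raise SBMLError(f"unsupported rule type {rtag}")

    fixed_subs = {sp.Symbol(k): sp.Float(v) for k, v in fixed.items()}

    def resolve(expr: sp.Expr, local_subs: dict) -> sp.Expr:
        prev = None
        for _ in range(20):
            if expr == prev:
                break
            prev = expr
            expr = expr.xreplace(assignments).xreplace(local_subs).xreplace(fixed_subs)
        return expr

    species_syms = {s: sp.Symbol(s) for s in species_order}
    n = len(species_order)
    sp_index = {s: i for i, s in enumerate(species_order)}

    cols: list[np.ndarray] = []
    laws: list[sp.Expr] = []
    reversibility: list[bool] = []
    modifiers: list[list[str]] = []
    for rxn in _iter(model_el, "listOfReactions"):
        rid = rxn.get("id") or "?"
        kl = _find(rxn, "kineticLaw")
        if kl is None or _find(kl, "math") is None:
            raise SBMLError(f"reaction {rid!r} has no kinetic law")
        local_subs = {}
        for plist in ("listOfParameters", "listOfLocalParameters"):
            for par in _iter(kl, plist):
                if par.get("value") is not None:
                    local_subs[sp.Symbol(par.get("id"))] = sp.Float(float(par.get("value")))
        try:
            expr = _parse_math(_find(kl, "math"), funcdefs)
        except SBMLError as exc:
            raise SBMLError(f"reaction {rid!r}: {exc}") from exc
        expr = resolve(expr, local_subs)
        leftover = {str(s) for s in expr.free_symbols} - set(species_order)
        if leftover:
            raise SBMLError(
                f"reaction {rid!r}: unresolved symbols {sorted(leftover)}"
            )
        col = np.zeros(n)
        mods: set[str] = set()
        for ref in _iter(rxn, "listOfReactants"):
            sid = ref.get("species")
            stoich = float(ref.get("stoichiometry") or 1)
            if sid in sp_index:
                col[sp_index[sid]] -= stoich / compartments.get(species_comp[sid], 1.0)
        for ref in _iter(rxn, "listOfProducts"):
            sid = ref.get("species")
            stoich = float(ref.get("stoichiometry") or 1)
            if sid in sp_index:
                col[sp_index[sid]] += stoich / compartments.get(species_comp[sid], 1.0)
        for ref in _iter(rxn, "listOfModifiers"):
            sid = ref.get("species")
            if sid in sp_index:
                mods.add(sid)
        # dynamic species that appear in the rate law but not as reactant /
        # product of this reaction act as modifiers for the sparsity pattern
        participants = {
            ref.get("species")
            for lname in ("listOfReactants", "listOfProducts")
            for ref in _iter(rxn, lname)
        }
        for s in expr.free_symbols:
            name = str(s)
            if name in sp_index and name not in participants:
                mods.add(name)
        cols.append(col)
        laws.append(expr)
        reversibility.append(_bool_attr(rxn, "reversible", True))
        modifiers.append(sorted(mods))

    if not laws:
        raise SBMLError(f"{path}: model has no reactions")

    model = KineticModel(
        species_ids=species_order,
        stoichiometry=np.column_stack(cols),
        rate_laws=laws,
        parameters={k: float(v) for k, v in fixed.items()},
        reversibility=reversibility,
        modifiers=modifiers,
        initial_state=np.array([initial[s] for s in species_order]),
        model_id=model_id,
    )
    logger.info(
        "read SBML model %s: %d dynamic species, %d excluded boundary/constant, "
        "%d reactions", model_id, n, len(boundary), len(laws),
    )
    # sanity: rate laws must evaluate finitely at the initial state
    _ = model.rates(model.initial_state)
    return model
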