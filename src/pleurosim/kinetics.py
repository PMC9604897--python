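"""Automatic kinetic rate-law assignment from reaction structure.

Every reaction receives a symbolic rate law derived purely from its
reactants and modifier roles, the way an SBML "squeezer" generates
kinetics from SBO-annotated structure:

* **gma** (generalized mass action, the default)::

      v = k * prod_i [R_i]^s_i * prod_j [E_j]
            * prod_a ([A_a] / (K_A,a + [A_a]))
            * prod_b (K_I,b / (K_I,b + [I_b]))

  where R are reactants with stoichiometries s, E catalysts, A activators
  and I inhibitors.  A source reaction (no reactants) reduces to
  ``v = k * modifier factors``.

* **mm** (Michaelis-Menten) for single-substrate catalysed conversions::

      v = V_max * [E] * [S] / (K_m + [S]) * (activator/inhibitor factors)

Activation and inhibition enter as saturating hyperbolic factors, so a
law evaluates to a finite non-negative rate for any non-negative amounts
and positive constants: the activator factor rises from 0 to 1, the
inhibitor factor falls from 1 toward 0 (and equals 1/2 at [I] = K_I).
All constants default to 1.0 in arbitrary units; the source network
publishes no fitted values, so the defaults make the qualitative
dose-response claims the testable surface.

Parameter naming: ``k_<rid>``, ``Vmax_<rid>``, ``Km_<rid>``,
``KA_<rid>_<species>``, ``KI_<rid>_<species>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Optional

import sympy as sp

from .core import Model, ModifierMode, Reaction, require_valid

Form = Literal["gma", "mm"]


@dataclass(frozen=True)
class RateLaw:
    reaction_id: str
    form: Form
    expression: sp.Expr
    parameters: dict[str, float]

    def evaluate(self, amounts: Mapping[str, float]) -> float:
        """Numeric rate at the given species amounts (parameters bound)."""
        subs = {sp.Symbol(k): v for k, v in self.parameters.items()}
        subs.update({sp.Symbol(k): v for k, v in amounts.items()})
        val = self.expression.xreplace(subs)
        return float(val)

    @property
    def symbols(self) -> set[str]:
        return {s.name for s in self.expression.free_symbols}


def _modifier_factors(
    reaction: Reaction, params: dict[str, float], defaults: Mapping[str, float]
) -> sp.Expr:
    expr: sp.Expr = sp.Integer(1)
    for m in reaction.modifiers:
        s = sp.Symbol(m.species)
        if m.mode is ModifierMode.catalyst:
            expr *= s
        elif m.mode is ModifierMode.activator:
            ka = f"KA_{reaction.id}_{m.species}"
            params[ka] = float(defaults.get(ka, defaults.get("K_A", 1.0)))
            expr *= s / (sp.Symbol(ka) + s)
        elif m.mode is ModifierMode.inhibitor:
            ki = f"KI_{reaction.id}_{m.species}"
            params[ki] = float(defaults.get(ki, defaults.get("K_I", 1.0)))
            expr *= sp.Symbol(ki) / (sp.Symbol(ki) + s)
    return expr


def assign_rate_law(
    reaction: Reaction,
    form: Form = "gma",
    defaults: Optional[Mapping[str, float]] = None,
) -> RateLaw:
    """Build the symbolic rate law for one reaction.

    ``defaults`` overrides parameter values by exact name (for example
    ``{"k_re6": 2.0}``) or by family (``"k"``, ``"K_I"``, ``"K_A"``,
    ``"V_max"``, ``"K_m"``); anything unspecified is 1.0.

    Raises ``ValueError`` when the mm form is requested for a reaction
    that does not have exactly one reactant and at least one catalyst.
    """
    defaults = dict(defaults or {})
    params: dict[str, float] = {}

    catalysts = [m for m in reaction.modifiers if m.mode is ModifierMode.catalyst]

    if form == "mm":
        if len(reaction.reactants) != 1 or not catalysts:
            raise ValueError(
                f"{reaction.id}: Michaelis-Menten form needs exactly one reactant "
                f"and at least one catalyst"
            )
        vmax = f"Vmax_{reaction.id}"
        km = f"Km_{reaction.id}"
        params[vmax] = float(defaults.get(vmax, defaults.get("V_max", 1.0)))
        params[km] = float(defaults.get(km, defaults.get("K_m", 1.0)))
        s_id, _ = reaction.reactants[0]
        s = sp.Symbol(s_id)
        enzyme: sp.Expr = sp.Integer(1)
        for c in catalysts:
            enzyme *= sp.Symbol(c.species)
        expr = sp.Symbol(vmax) * enzyme * s / (sp.Symbol(km) + s)
        # activator / inhibitor factors still apply; catalysts already used
        non_cat = Reaction(
            reaction.id, reaction.name, reaction.reactants, reaction.products,
            tuple(m for m in reaction.modifiers if m.mode is not ModifierMode.catalyst),
        )
        expr *= _modifier_factors(non_cat, params, defaults)
        return RateLaw(reaction.id, "mm", expr, params)

    if form != "gma":
        raise ValueError(f"unknown rate-law form {form!r}")

    kname = f"k_{reaction.id}"
    params[kname] = float(defaults.get(kname, defaults.get("k", 1.0)))
    expr = sp.Symbol(kname)
    for sid, stoich in reaction.reactants:
        expr *= sp.Symbol(sid) ** stoich
    expr *= _modifier_factors(reaction, params, defaults)
    return RateLaw(reaction.id, "gma", expr, params)


def assign_all(
    model: Model,
    policy: Literal["gma", "mm_enzymes"] = "gma",
    defaults: Optional[Mapping[str, float]] = None,
) -> dict[str, RateLaw]:
    """Assign a rate law to every reaction of a model (total mapping).

    ``policy="gma"`` uses generalized mass action everywhere;
    ``policy="mm_enzymes"`` upgrades single-substrate catalysed
    conversions to Michaelis-Menten and leaves the rest as gma.
    """
    require_valid(model)
    laws: dict[str, RateLaw] = {}
    for r in model.reactions:
        form: Form = "gma"
        if policy == "mm_enzymes":
            has_cat = any(m.mode is ModifierMode.catalyst for m in r.modifiers)
            if len(r.reactants) == 1 and has_cat:
                form = "mm"
        elif policy != "gma":
            raise ValueError(f"unknown policy {policy!r}")
        laws[r.id] = assign_rate_law(r, form=form, defaults=defaults)
    return laws


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def _to_content_mathml(expr: sp.Expr) -> str:
    """Content MathML for the small operator set rate laws use.

    Handles products, sums, powers, rational functions, symbols and
    numbers — the closed set generated kinetics are built from.  Symbol
    names are emitted verbatim in ``<ci>`` elements (no sub/superscript
    interpretation of underscores).
    """
    from xml.sax.saxutils import escape

    def conv(e: sp.Expr) -> str:
        if isinstance(e, sp.Symbol):
            return f"<ci>{escape(e.name)}</ci>"
        if isinstance(e, sp.Integer):
            return f"<cn>{int(e)}</cn>"
        if isinstance(e, (sp.Float, sp.Rational)):
            if isinstance(e, sp.Rational) and not isinstance(e, sp.Integer):
                return f"<apply><divide/><cn>{e.p}</cn><cn>{e.q}</cn></apply>"
            return f"<cn>{float(e)!r}</cn>"
        if isinstance(e, sp.Pow):
            base, exp = e.args
            if exp == -1:
                return f"<apply><divide/><cn>1</cn>{conv(base)}</apply>"
            if exp.is_Integer and exp < -1:
                return (f"<apply><divide/><cn>1</cn>"
                        f"<apply><power/>{conv(base)}<cn>{int(-exp)}</cn></apply></apply>")
            return f"<apply><power/>{conv(base)}{conv(exp)}</apply>"
        if isinstance(e, sp.Mul):
            num, den = e.as_numer_denom()
            if den != 1:
                return f"<apply><divide/>{conv(num)}{conv(den)}</apply>"
            return "<apply><times/>" + "".join(conv(a) for a in e.args) + "</apply>"
        if isinstance(e, sp.Add):
            return "<apply><plus/>" + "".join(conv(a) for a in e.args) + "</apply>"
        raise ValueError(f"cannot render {type(e).__name__} as content MathML")

    return conv(expr)


def render_expression(law: RateLaw, dialect: Literal["text", "mathml"] = "text") -> str:
    """Render a rate law as unambiguous infix text or SBML-embeddable MathML."""
    if dialect == "text":
        return sp.sstr(law.expression, order="lex")
    if dialect == "mathml":
        body = _to_content_mathml(law.expression)
        return f'<math xmlns="{_MATHML_NS}">{body}</math>'
    raise ValueError(f"unknown dialect {dialect!r}")


def parse_content_mathml(document: str) -> sp.Expr:
    """Parse the content-MathML subset emitted by :func:`render_expression`.

    Supports apply/times/plus/minus/divide/power with ci symbols and cn
    numbers — the closed operator set of generated rate laws.
    """
    from lxml import etree

    root = etree.fromstring(document.encode())

    def strip(tag: str) -> str:
        return tag.rsplit("}", 1)[-1]

    def conv(node) -> sp.Expr:
        tag = strip(node.tag)
        if tag == "math":
            children = [c for c in node if isinstance(c.tag, str)]
            if len(children) != 1:
                raise ValueError("math element must wrap a single expression")
            return conv(children[0])
        if tag == "ci":
            return sp.Symbol(node.text.strip())
        if tag == "cn":
            text = node.text.strip()
            return sp.Integer(int(text)) if "." not in text and "e" not in text.lower() else sp.Float(text)
        if tag == "apply":
            children = [c for c in node if isinstance(c.tag, str)]
            op = strip(children[0].tag)
            args = [conv(c) for c in children[1:]]
            if op == "times":
                return sp.Mul(*args)
            if op == "plus":
                return sp.Add(*args)
            if op == "minus":
                if len(args) == 1:
                    return -args[0]
                return args[0] - sp.Add(*args[1:])
            if op == "divide":
                return args[0] / args[1]
            if op == "power":
                return args[0] ** args[1]
            raise ValueError(f"unsupported MathML operator {op!r}")
        raise ValueError(f"unsupported MathML element {tag!r}")

    return conv(root)
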