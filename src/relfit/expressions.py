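"""Parsing of model expressions.

Model right-hand sides, initial states and output functions are written in a
minimal arithmetic grammar: identifiers (state and parameter names, optionally
``t`` for time), numeric literals, ``+ - * / ^`` and parentheses.  ``^``
denotes exponentiation.  Function calls are rejected: the grammar is small on
purpose so that a model file is unambiguous and symbolically differentiable.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import sympy
from sympy.parsing.sympy_parser import (
    convert_xor,
    parse_expr,
    standard_transformations,
)

from .exceptions import ConfigurationError

_TRANSFORMS = standard_transformations + (convert_xor,)


def make_symbols(names: Iterable[str]) -> dict[str, sympy.Symbol]:
    """Map each identifier to a (positive-unassumed) real sympy symbol."""
    out: dict[str, sympy.Symbol] = {}
    for name in names:
        if not str(name).isidentifier():
            raise ConfigurationError(f"invalid identifier: {name!r}")
        out[str(name)] = sympy.Symbol(str(name), real=True)
    return out


def parse_expression(text: str, symbols: Mapping[str, sympy.Symbol]) -> sympy.Expr:
    """Parse ``text`` into a sympy expression over the declared symbols.

    Raises ConfigurationError on syntax errors, undeclared identifiers or
    anything outside the arithmetic grammar (function calls, relational
    operators, ...).
    """
    try:
        expr = parse_expr(
            str(text),
            local_dict=dict(symbols),
            transformations=_TRANSFORMS,
            evaluate=True,
        )
    except (SyntaxError, TypeError, sympy.SympifyError) as exc:
        raise ConfigurationError(f"cannot parse expression {text!r}: {exc}") from exc
    allowed = set(symbols.values())
    extra = expr.free_symbols - allowed
    if extra:
        names = ", ".join(sorted(str(s) for s in extra))
        raise ConfigurationError(
            f"expression {text!r} uses undeclared identifier(s): {names}"
        )
    if expr.atoms(sympy.Function):
        raise ConfigurationError(
            f"expression {text!r} uses function calls, which the model grammar forbids"
        )
    return expr
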