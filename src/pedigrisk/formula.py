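"""Wilkinson-Rogers-style model formulas for CIF regression.

Grammar::

    CIF ~ 1 [+ term]*
    term := name[:name ...] | const(name[:name ...]) | cluster(name)

``1`` is the baseline CIF; a colon is an interaction between covariates
(two- and higher-order, as in full-factorial designs); ``const()`` marks a term whose coefficient is constant over
time (semi-parametric); ``cluster()`` names the grouping variable for
cluster-robust variance.  ``const`` and ``cluster`` cannot be nested.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Term", "ModelFormula", "parse_formula", "factorial_design"]

_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_NAME_RE = re.compile(_NAME)


@dataclass(frozen=True)
class Term:
    """One covariate term: product of its components; time-varying unless
    marked constant."""

    components: tuple[str, ...]
    constant: bool = False

    @property
    def name(self) -> str:
        base = ":".join(self.components)
        return f"const({base})" if self.constant else base

    def values(self, covariates: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(covariates))
        for c in self.components:
            if c not in covariates.columns:
                raise KeyError(f"covariate {c!r} not found in sample")
            out = out * pd.to_numeric(covariates[c]).to_numpy(dtype=float)
        return out


@dataclass
class ModelFormula:
    """Parsed CIF regression formula."""

    response: str = "CIF"
    terms: tuple[Term, ...] = ()
    cluster: str | None = None
    link: str = "proportional"

    @property
    def varying_terms(self) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if not t.constant)

    @property
    def constant_terms(self) -> tuple[Term, ...]:
        return tuple(t for t in self.terms if t.constant)

    def unparse(self) -> str:
        parts = ["1"] + [t.name for t in self.terms]
        if self.cluster:
            parts.append(f"cluster({self.cluster})")
        return f"{self.response} ~ " + " + ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.unparse()


class FormulaError(ValueError):
    """Parse error with the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _parse_components(body: str, offset: int) -> tuple[str, ...]:
    parts = [p.strip() for p in body.split(":")]
    if not parts or any(not p for p in parts):
        raise FormulaError("malformed interaction term", offset)
    for p in parts:
        if not _NAME_RE.fullmatch(p):
            raise FormulaError(f"invalid covariate name {p!r}", offset)
        if p in ("const", "cluster"):
            raise FormulaError("const() and cluster() cannot be nested", offset)
    return tuple(parts)


def parse_formula(text: str, link: str = "proportional") -> ModelFormula:
    """Parse ``"CIF ~ 1 + A + A:B + const(C) + cluster(g)"``.

    Unknown syntax raises :class:`FormulaError` carrying the character
    position; duplicate terms are errors.  The baseline ``1`` must be
    present.
    """
    if link not in ("proportional", "additive"):
        raise ValueError("link must be 'proportional' or 'additive'")
    if "~" not in text:
        raise FormulaError("formula must contain '~'", 0)
    lhs, rhs = text.split("~", 1)
    response = lhs.strip()
    if not response:
        raise FormulaError("missing response", 0)
    terms: list[Term] = []
    cluster: str | None = None
    saw_baseline = False
    pos = len(lhs) + 1
    for chunk in rhs.split("+"):
        tok = chunk.strip()
        start = pos + chunk.index(tok) if tok else pos
        pos += len(chunk) + 1
        if not tok:
            raise FormulaError("empty term", start)
        if tok == "1":
            if saw_baseline:
                raise FormulaError("duplicate baseline term '1'", start)
            saw_baseline = True
            continue
        m = re.fullmatch(r"(const|cluster)\s*\(\s*([^()]*)\s*\)", tok)
        if m:
            kind, body = m.group(1), m.group(2)
            if kind == "cluster":
                if cluster is not None:
                    raise FormulaError("duplicate cluster() term", start)
                if not _NAME_RE.fullmatch(body.strip()):
                    raise FormulaError(f"invalid cluster variable {body!r}", start)
                cluster = body.strip()
                continue
            term = Term(_parse_components(body, start), constant=True)
        elif re.fullmatch(rf"{_NAME}(:{_NAME})*", tok):
            term = Term(_parse_components(tok, start))
        else:
            raise FormulaError(f"unknown syntax {tok!r}", start)
        if any(t.components == term.components for t in terms):
            raise FormulaError(f"duplicate term {term.name!r}", start)
        terms.append(term)
    if not saw_baseline:
        raise FormulaError("formula must include the baseline term '1'", len(lhs) + 1)
    return ModelFormula(response=response, terms=tuple(terms),
                        cluster=cluster, link=link)


def factorial_design(
    factors: list[str],
    max_order: int | None = None,
    *,
    sample=None,
    response: str = "CIF",
    link: str = "proportional",
    constant: bool = False,
) -> ModelFormula:
    """Full-factorial formula: all main effects and interactions up to
    ``max_order`` (default: all orders).

    Each factor must be binary-codeable; if ``sample`` is given its
    covariate columns are checked for two-level coding.
    """
    if max_order is None:
        max_order = len(factors)
    if sample is not None:
        for f in factors:
            vals = np.unique(pd.to_numeric(sample.covariates[f]).to_numpy())
            if vals.size > 2 or not np.all(np.isin(vals, (0.0, 1.0))):
                raise ValueError(f"factor {f!r} is not binary (0/1) coded")
    terms = [
        Term(combo, constant=constant)
        for order in range(1, max_order + 1)
        for combo in itertools.combinations(factors, order)
    ]
    return ModelFormula(response=response, terms=tuple(terms), link=link)
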