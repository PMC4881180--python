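"""Model-term grammar shared by the generator, the regression core and selection.

A *term* is either a single (possibly transformed) predictor or a product of
two such atoms (a space-time interaction).  Terms are written and parsed in a
small canonical string form so that model specifications, generator truth
coefficients and coefficient-table rows all speak the same language::

    temperature
    log(aqm_no2)
    sqrt(traffic_nearest_road)
    square(year)                  (also accepted: year^2)
    spline(wind_speed, 3)
    road_major_len_100 * season   (interaction: elementwise product)

Transforms are applied to the raw predictor column; ``log`` and ``sqrt``
enforce their domains and report the offending variable and row indices.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "TermSpec",
    "TransformDomainError",
    "parse_term",
    "build_design_matrix",
    "natural_spline_basis",
]

TRANSFORMS = ("identity", "log", "sqrt", "square", "spline")


class TransformDomainError(ValueError):
    """A transform was applied outside its domain (e.g. log of a non-positive value)."""


@dataclass(frozen=True)
class Atom:
    """One predictor with an optional transform."""

    var: str
    transform: str = "identity"
    df: int = 3  # spline degrees of freedom; ignored otherwise

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; known: {TRANSFORMS}"
            )

    @property
    def label(self) -> str:
        if self.transform == "identity":
            return self.var
        if self.transform == "spline":
            return f"spline({self.var}, {self.df})"
        return f"{self.transform}({self.var})"

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform == "identity":
            return x
        if self.transform == "log":
            bad = np.flatnonzero(~(x > 0))
            if bad.size:
                raise TransformDomainError(
                    f"log({self.var}) requires strictly positive values; "
                    f"offending rows: {bad[:10].tolist()}"
                )
            return np.log(x)
        if self.transform == "sqrt":
            bad = np.flatnonzero(x < 0)
            if bad.size:
                raise TransformDomainError(
                    f"sqrt({self.var}) requires non-negative values; "
                    f"offending rows: {bad[:10].tolist()}"
                )
            return np.sqrt(x)
        if self.transform == "square":
            return x * x
        raise ValueError("spline atoms expand to multiple columns; use expand()")


@dataclass(frozen=True)
class TermSpec:
    """A model term: a transformed predictor, optionally interacted with a partner.

    Interaction columns are the elementwise product of the two transformed
    atoms.  Spline atoms cannot take part in interactions.
    """

    primary: Atom
    partner: Atom | None = field(default=None)

    def __post_init__(self) -> None:
        if self.partner is not None and "spline" in (
            self.primary.transform,
            self.partner.transform,
        ):
            raise ValueError("spline terms cannot be interacted")

    @property
    def label(self) -> str:
        if self.partner is None:
            return self.primary.label
        return f"{self.primary.label} * {self.partner.label}"

    @property
    def is_interaction(self) -> bool:
        return self.partner is not None

    @property
    def variables(self) -> tuple[str, ...]:
        if self.partner is None:
            return (self.primary.var,)
        return (self.primary.var, self.partner.var)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


_ATOM_RE = re.compile(
    r"^(?:(?P<fn>log|sqrt|square)\s*\(\s*(?P<v1>[\w.]+)\s*\)"
    r"|spline\s*\(\s*(?P<v2>[\w.]+)\s*,\s*(?P<df>\d+)\s*\)"
    r"|\(\s*(?P<v3>[\w.]+)\s*\)\s*\^\s*2"
    r"|(?P<v4>[\w.]+)\s*\^\s*2"
    r"|(?P<v5>[\w.]+))$"
)


def _parse_atom(text: str) -> Atom:
    m = _ATOM_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse term atom {text!r}")
    if m.group("fn"):
        return Atom(m.group("v1"), m.group("fn"))
    if m.group("v2"):
        return Atom(m.group("v2"), "spline", int(m.group("df")))
    if m.group("v3"):
        return Atom(m.group("v3"), "square")
    if m.group("v4"):
        return Atom(m.group("v4"), "square")
    return Atom(m.group("v5"))


def parse_term(text: str) -> TermSpec:
    """Parse the canonical string form of a model term."""
    parts = text.split("*")
    if len(parts) == 1:
        return TermSpec(_parse_atom(parts[0]))
    if len(parts) == 2:
        return TermSpec(_parse_atom(parts[0]), _parse_atom(parts[1]))
    raise ValueError(f"cannot parse term {text!r}: more than one '*'")


def natural_spline_basis(x: np.ndarray, df: int = 3) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns and quantile-placed knots.

    Used for linearity diagnostics during model selection only; final models
    never carry spline terms.  The basis is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if df < 2:
        raise ValueError("natural spline needs df >= 2")
    # df columns need df+1 knots (including boundaries)
    probs = np.linspace(0, 1, df + 1)
    knots = np.quantile(x, probs)
    knots = np.unique(knots)
    if knots.size < 3:  # degenerate predictor: fall back to a linear column
        out = np.empty((x.size, df))
        out[:, 0] = x
        out[:, 1:] = 0.0
        return out
    bound_lo, bound_hi = knots[0], knots[-1]
    inner = knots[1:-1]

    def d(k: float) -> np.ndarray:
        num = np.clip(x - k, 0, None) ** 3 - np.clip(x - bound_hi, 0, None) ** 3
        return num / (bound_hi - k)

    cols = [x]
    for k in inner:
        cols.append(d(k) - d(bound_lo))
    basis = np.column_stack(cols)
    if basis.shape[1] < df:  # pad if unique knots collapsed
        pad = np.zeros((x.size, df - basis.shape[1]))
        basis = np.hstack([basis, pad])
    return basis[:, :df]


def _atom_columns(atom: Atom, data: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    if atom.var not in data.columns:
        raise KeyError(f"predictor {atom.var!r} not found in data")
    raw = data[atom.var].to_numpy(dtype=float)
    if atom.transform == "spline":
        basis = natural_spline_basis(raw, atom.df)
        names = [f"{atom.label}[{i}]" for i in range(basis.shape[1])]
        return basis, names
    return atom.apply(raw)[:, None], [atom.label]


def build_design_matrix(
    terms: list[TermSpec], data: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Build the no-intercept design matrix: one column per term (spline terms
    expand to their basis columns), interactions as products of the transformed
    partners."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    for term in terms:
        cols, labels = _atom_columns(term.primary, data)
        if term.partner is not None:
            pcols, _ = _atom_columns(term.partner, data)
            cols = cols * pcols
            labels = [term.label]
        blocks.append(cols)
        names.extend(labels)
    if not blocks:
        raise ValueError("no terms given")
    return np.hstack(blocks), names
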