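"""Iterative thematic-group supervised stepwise variable selection.

Candidate predictors are organised in thematic groups (land use, traffic,
roads, topography, dispersion NO2, AQM NO2, meteorology, population), each
with an a-priori base variable.  Starting from the base model (one term per
group), the procedure iterates:

* **forward/swap** within each group: candidate buffers and transforms are
  tried against the current model; a change is accepted when it improves the
  model R^2 by at least one percentage point *and* does not worsen the
  ten-fold cross-validated R^2;
* **backward**: a term whose removal costs less than one percentage point of
  both model and CV R^2 is dropped (the fewer-variables rule);
* when alternatives differ by less than one percentage point of R^2 the
  tie-break order is: fewer variables, then buffer radii similar to those
  already in the model, then the most linear dependency (an identity-
  transform variant losing < 1 point vs its best transform), then no
  transformation.

After the main effects converge, products of one spatial and one temporal
model term are tested as space-time interactions under the same acceptance
rule.  Every step is logged with the rule invoked, so the trace is auditable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regression import fit_terms
from .temporal import TEMPORAL_VARIABLES
from .terms import TermSpec, parse_term
from .validation import kfold_cv
from .regression import manual_r2

__all__ = [
    "ThematicGroup",
    "SelectionStep",
    "SelectionTrace",
    "base_model",
    "select",
    "default_groups",
]

_TEMPORAL_VARS = set(TEMPORAL_VARIABLES) | {"season", "year"}
_BUFFER_RE = re.compile(r"_(\d+)$")


@dataclass
class ThematicGroup:
    """A named group of candidate predictor terms with an a-priori base."""

    name: str
    candidates: list[str]  # canonical term strings
    base: str

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError(f"group {self.name!r} has no candidates")
        if self.base not in self.candidates:
            raise ValueError(
                f"group {self.name!r}: base {self.base!r} not among candidates"
            )


@dataclass
class SelectionStep:
    action: str  # add | swap | remove | interaction | converged
    term: str
    model_r2: float
    cv_r2: float
    accepted: bool
    rule: str


@dataclass
class SelectionTrace:
    steps: list[SelectionStep] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def log(self, **kw) -> None:
        self.steps.append(SelectionStep(**kw))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.steps])


def default_groups(region_kind: str = "rural") -> list[ThematicGroup]:
    """Thematic candidate groups over the canonical predictor names."""
    groups = [
        ThematicGroup(
            "land use",
            ["lu_highdens_100", "lu_highdens_200", "lu_highdens_300",
             "lu_lowdens_200", "lu_industrial_300"],
            "lu_highdens_200",
        ),
        ThematicGroup(
            "traffic",
            ["vehicles_50", "vehicles_100", "sqrt(vehicles_100)",
             "sqrt(traffic_nearest_road)", "traffic_nearest_road"],
            "sqrt(traffic_nearest_road)" if region_kind == "rural"
            else "sqrt(vehicles_100)",
        ),
        ThematicGroup(
            "roads",
            ["road_major_len_50", "road_major_len_100", "road_major_len_300",
             "road_major_len_500", "road_major_len_1000",
             "log(inv_dist_major_road)"],
            "road_major_len_100",
        ),
        ThematicGroup("topography", ["altitude"], "altitude"),
        ThematicGroup("dispersion NO2", ["log(dispersion_no2)", "dispersion_no2"],
                      "log(dispersion_no2)"),
        ThematicGroup("AQM NO2", ["log(aqm_no2)", "aqm_no2"], "log(aqm_no2)"),
        ThematicGroup(
            "meteorology",
            ["temperature", "boundary_layer_height",
             "square(boundary_layer_height)", "wind_speed", "season", "year"],
            "temperature",
        ),
        ThematicGroup("population", ["pop_100", "pop_300", "pop_500"], "pop_100"),
    ]
    if region_kind == "urban":
        groups = [g for g in groups if g.name != "topography"]
    return groups


def base_model(groups: list[ThematicGroup]) -> list[TermSpec]:
    """The a-priori base model: one term per thematic group."""
    return [parse_term(g.base) for g in groups]


def _buffer_radius(term: TermSpec) -> int | None:
    m = _BUFFER_RE.search(term.primary.var)
    return int(m.group(1)) if m else None


def _is_temporal(term: TermSpec) -> bool:
    return all(v in _TEMPORAL_VARS for v in term.variables)


def _tiebreak_score(
    term: TermSpec, model: list[TermSpec], linear_ok: dict[str, bool]
) -> tuple:
    """Smaller is preferred: similar buffer radius, linear dependency,
    untransformed."""
    radii = {_buffer_radius(t) for t in model if _buffer_radius(t) is not None}
    r = _buffer_radius(term)
    similar = 0 if (r is None or r in radii) else 1
    linear = 0 if linear_ok.get(term.label, True) else 1
    untransformed = 0 if term.primary.transform == "identity" else 1
    return (similar, linear, untransformed)


class _Evaluator:
    """Caches model/CV R^2 per candidate term list."""

    def __init__(self, data: pd.DataFrame, y: np.ndarray, k: int, seed: int):
        self.data = data
        self.y = np.asarray(y, float)
        self.k = k
        self.seed = seed
        self._cache: dict[tuple[str, ...], tuple[float, float]] = {}

    def r2(self, terms: list[TermSpec]) -> tuple[float, float]:
        key = tuple(sorted(t.label for t in terms))
        if key not in self._cache:
            try:
                fit = fit_terms(terms, self.data, self.y)
                preds = kfold_cv(terms, self.data, self.y, self.k, self.seed)
                cv = manual_r2(self.y, preds)
                self._cache[key] = (fit.r2, cv)
            except np.linalg.LinAlgError:
                self._cache[key] = (-np.inf, -np.inf)
        return self._cache[key]


def _linearity_ok(ev: _Evaluator, term: TermSpec, model: list[TermSpec],
                  tol: float) -> bool:
    """A transformed candidate counts as 'linear' when its identity variant
    loses less than ``tol`` R^2 against it in the current model context."""
    if term.primary.transform == "identity" or term.is_interaction:
        return True
    ident = TermSpec(type(term.primary)(term.primary.var))
    others = [t for t in model if t.label != term.label]
    r2_t, _ = ev.r2(others + [term])
    r2_i, _ = ev.r2(others + [ident])
    return (r2_t - r2_i) < tol


def select(
    groups: list[ThematicGroup],
    data: pd.DataFrame,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    r2_tol: float = 0.01,
    max_iter: int = 20,
    test_interactions: bool = True,
) -> tuple[list[TermSpec], SelectionTrace]:
    """Run the iterative thematic stepwise selection.

    Returns the selected term list and the full decision trace.  Re-running
    with the same seed reproduces the identical trace (the seed only fixes
    the cross-validation folds).
    """
    ev = _Evaluator(data, y, k, seed)
    model = base_model(groups)
    trace = SelectionTrace()
    cur_r2, cur_cv = ev.r2(model)

    for it in range(max_iter):
        trace.iterations = it + 1
        changed = False

        # forward / swap within each thematic group
        for g in groups:
            in_group = [t for t in model if t.label in g.candidates]
            for cand_str in g.candidates:
                cand = parse_term(cand_str)
                if any(t.label == cand.label for t in model):
                    continue
                # addition
                add_r2, add_cv = ev.r2(model + [cand])
                if add_r2 - cur_r2 >= r2_tol and add_cv > cur_cv:
                    model = model + [cand]
                    cur_r2, cur_cv = add_r2, add_cv
                    changed = True
                    trace.log(action="add", term=cand.label, model_r2=cur_r2,
                              cv_r2=cur_cv, accepted=True,
                              rule="delta R2 >= 1pp, CV improved")
                    continue
                trace.log(action="add", term=cand.label, model_r2=add_r2,
                          cv_r2=add_cv, accepted=False,
                          rule="fewer variables (delta R2 < 1pp)"
                          if add_r2 - cur_r2 < r2_tol else "CV not improved")
                # swap against the group's current representative
                for old in in_group:
                    swapped = [t for t in model if t.label != old.label] + [cand]
                    sw_r2, sw_cv = ev.r2(swapped)
                    if sw_r2 - cur_r2 >= r2_tol and sw_cv > cur_cv:
                        rule = "swap: delta R2 >= 1pp, CV improved"
                    elif abs(sw_r2 - cur_r2) < r2_tol and sw_cv >= cur_cv - r2_tol:
                        lin = {
                            cand.label: _linearity_ok(ev, cand, swapped, r2_tol),
                            old.label: _linearity_ok(ev, old, model, r2_tol),
                        }
                        if _tiebreak_score(cand, model, lin) < _tiebreak_score(
                            old, model, lin
                        ):
                            rule = "swap: tie-break (buffer/linearity/transform)"
                        else:
                            trace.log(action="swap", term=f"{old.label}->{cand.label}",
                                      model_r2=sw_r2, cv_r2=sw_cv, accepted=False,
                                      rule="tie-break keeps incumbent")
                            continue
                    else:
                        trace.log(action="swap", term=f"{old.label}->{cand.label}",
                                  model_r2=sw_r2, cv_r2=sw_cv, accepted=False,
                                  rule="no R2/CV improvement")
                        continue
                    model = swapped
                    cur_r2, cur_cv = sw_r2, sw_cv
                    changed = True
                    in_group = [t for t in model if t.label in g.candidates]
                    trace.log(action="swap", term=f"{old.label}->{cand.label}",
                              model_r2=cur_r2, cv_r2=cur_cv, accepted=True, rule=rule)
                    break

        # backward elimination: drop terms that cost < 1pp
        for term in list(model):
            if len(model) <= 2:
                break
            reduced = [t for t in model if t.label != term.label]
            red_r2, red_cv = ev.r2(reduced)
            if cur_r2 - red_r2 < r2_tol and cur_cv - red_cv < r2_tol:
                model = reduced
                cur_r2, cur_cv = red_r2, red_cv
                changed = True
                trace.log(action="remove", term=term.label, model_r2=cur_r2,
                          cv_r2=cur_cv, accepted=True,
                          rule="fewer variables (removal costs < 1pp)")
            else:
                trace.log(action="remove", term=term.label, model_r2=red_r2,
                          cv_r2=red_cv, accepted=False,
                          rule="removal costs >= 1pp")

        if not changed:
            trace.converged = True
            break

    # space-time interactions over the converged main effects: greedily add
    # the best-improving product until none clears the threshold
    if test_interactions:
        spatial = [t for t in model if not t.is_interaction and not _is_temporal(t)]
        temporal = [t for t in model if not t.is_interaction and _is_temporal(t)]
        candidates = [TermSpec(s.primary, t.primary) for s in spatial for t in temporal]
        while True:
            scored = []
            for inter in candidates:
                if any(m.label == inter.label for m in model):
                    continue
                int_r2, int_cv = ev.r2(model + [inter])
                scored.append((int_r2, int_cv, inter))
            if not scored:
                break
            best_r2, best_cv, best = max(scored, key=lambda t: t[0])
            ok = best_r2 - cur_r2 >= r2_tol and best_cv > cur_cv
            for int_r2, int_cv, inter in scored:
                if inter.label != best.label:
                    trace.log(action="interaction", term=inter.label,
                              model_r2=int_r2, cv_r2=int_cv, accepted=False,
                              rule="not the best candidate"
                              if ok else "no improvement")
            trace.log(action="interaction", term=best.label, model_r2=best_r2,
                      cv_r2=best_cv, accepted=ok,
                      rule="delta R2 >= 1pp, CV improved" if ok
                      else "no improvement")
            if not ok:
                break
            model = model + [best]
            cur_r2, cur_cv = best_r2, best_cv

    if not trace.converged:
        trace.log(action="converged", term="", model_r2=cur_r2, cv_r2=cur_cv,
                  accepted=False, rule=f"iteration cap {max_iter} reached")
    return model, trace
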