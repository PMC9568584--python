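"""Cumulative postnatal adversity score from binary component rules.

Each component is a named cut-off rule over one phenotype column (or an
OR over several sub-rules, e.g. maternal mental health firing when any of
several questionnaire scores crosses its cut-off).  A fired component
contributes one point; the total score is the sum over components.
Cut-off values live in editable YAML rule sets, with presets mirroring
two birth-cohort designs (a 10-component and a 7-component score).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

_COMPARATORS = {
    "greater": lambda v, t: v > t,
    "greater_equal": lambda v, t: v >= t,
    "less": lambda v, t: v < t,
    "less_equal": lambda v, t: v <= t,
    "equals": lambda v, t: v == t,
    "is_true": lambda v, t: bool(v),
}


@dataclass
class SubRule:
    """One cut-off over one column: fires when column <comparison> threshold."""

    column: str
    comparison: str
    threshold: float | str | None = None

    def __post_init__(self) -> None:
        if self.comparison not in _COMPARATORS:
            raise ValueError(
                f"unknown comparison {self.comparison!r}; "
                f"valid: {sorted(_COMPARATORS)}"
            )


@dataclass
class ComponentRule:
    """A scored component: one point when any sub-rule fires."""

    name: str
    rules: list[SubRule]


@dataclass
class AdversityRuleSet:
    components: list[ComponentRule] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names")

    @property
    def n_components(self) -> int:
        return len(self.components)

    def columns(self) -> list[str]:
        return sorted({r.column for c in self.components for r in c.rules})


def load_ruleset(source: str | Path | dict) -> AdversityRuleSet:
    """Load a rule set from a YAML file, a preset name (``"mavan"`` or
    ``"gusto"``), or an already-parsed dict."""
    if isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists() and not path.suffix:
            ref = resources.files("eprskit").joinpath(f"presets/{source}.yaml")
            raw = yaml.safe_load(ref.read_text())
        else:
            raw = yaml.safe_load(path.read_text())
    components = []
    for comp in raw["components"]:
        subs = [SubRule(column=r["column"], comparison=r["comparison"],
                        threshold=r.get("threshold")) for r in comp["rules"]]
        components.append(ComponentRule(name=comp["name"], rules=subs))
    return AdversityRuleSet(components=components)


def score_component(row: pd.Series, rule: ComponentRule) -> float:
    """0/1 indicator for one subject and one component; NaN when every
    informative sub-rule value is missing.

    With several sub-rules (an OR), any firing sub-rule yields 1 even if
    other sub-rule values are missing; the indicator is missing only when
    no observed value fires and at least one value is unobserved.
    """
    fired = False
    any_missing = False
    for sub in rule.rules:
        if sub.column not in row.index:
            raise KeyError(f"component {rule.name!r} needs column {sub.column!r}")
        value = row[sub.column]
        if pd.isna(value):
            any_missing = True
            continue
        try:
            if _COMPARATORS[sub.comparison](value, sub.threshold):
                fired = True
        except TypeError as exc:
            raise TypeError(
                f"component {rule.name!r}: cannot compare {value!r} "
                f"({sub.comparison} {sub.threshold!r})"
            ) from exc
    if fired:
        return 1.0
    return np.nan if any_missing else 0.0


def compute_adversity_score(
    components: pd.DataFrame,
    rules: AdversityRuleSet,
    min_nonmissing: int | None = None,
) -> pd.DataFrame:
    """Per-subject cumulative adversity score.

    ``components`` must contain a ``subject`` column plus every column the
    rule set references.  Missing component indicators contribute 0 to the
    sum but are tracked; a subject with fewer than ``min_nonmissing``
    observed components (default: all of them) gets a missing total.

    Returns ``subject, adversity`` plus one 0/1/NaN indicator column per
    component.
    """
    if min_nonmissing is None:
        min_nonmissing = rules.n_components
    missing_cols = [c for c in rules.columns() if c not in components.columns]
    if missing_cols:
        raise KeyError(f"component table missing columns: {missing_cols}")
    out = pd.DataFrame({"subject": components["subject"]})
    indicators = np.empty((len(components), rules.n_components))
    for k, comp in enumerate(rules.components):
        indicators[:, k] = components.apply(lambda r: score_component(r, comp), axis=1)
        out[f"ind_{comp.name}"] = indicators[:, k]
    n_obs = np.sum(~np.isnan(indicators), axis=1)
    total = np.nansum(indicators, axis=1)
    total[n_obs < min_nonmissing] = np.nan
    out["adversity"] = total
    return out
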