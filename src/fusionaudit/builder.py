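"""Construction of fusion-validity model variants from a study configuration.

A fusion-validity audit of a multi-item scale compares four covariance-structure
models built from one study description:

* **scale-only** — the arithmetic scale scores (error-free observed variables)
  cause the downstream variables; no items in the model.
* **item-only** — the items (with fixed measurement-error variances) replace the
  scales and carry a chosen set of direct item -> downstream effects.
* **basic fusion** — items plus composite-scale latents; the composite is an
  exact weighted sum of the item true scores (zero disturbance, fixed scoring
  weights) and *only* the composites may affect downstream variables.  Its
  chi-square test is the core fusion-validity check.
* **expanded scale-and-item** — the basic fusion model plus specific
  scale-bypassing item -> downstream effects.

Every observed variable is represented by a true-score latent with a fixed unit
loading; its measurement-error variance is fixed at the assigned percent of the
observed variance, so the collinearity between a composite and its items lives
entirely at the latent level and never in the modeled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sem_core import Fixed, Free, SemModelSpec, SemSpecError

__all__ = [
    "VariableSummary",
    "ScaleDefinition",
    "FusionStudySpec",
    "ConfigError",
    "ts",
    "apply_error_spec",
    "build_composite",
    "build_scale_only",
    "build_item_only",
    "build_fusion",
    "compute_scale_scores",
    "candidate_item_effects",
    "augment_covariance_with_scores",
]


class ConfigError(ValueError):
    """Invalid study configuration."""


def ts(name: str) -> str:
    """Name of the true-score latent behind observed variable ``name``."""
    return f"ts_{name}"


@dataclass(frozen=True)
class VariableSummary:
    """An observed variable: name, mean (metadata), variance, and the percent
    of that variance assigned to measurement error."""

    name: str
    mean: float
    variance: float
    error_percent: float

    def __post_init__(self):
        if self.variance <= 0:
            raise ConfigError(f"{self.name}: variance must be strictly positive")
        if not (0 <= self.error_percent < 100):
            raise ConfigError(f"{self.name}: error_percent must lie in [0, 100)")

    @property
    def error_variance(self) -> float:
        """Fixed measurement-error variance = (error_percent/100) * variance."""
        return (self.error_percent / 100.0) * self.variance


@dataclass(frozen=True)
class ScaleDefinition:
    """A named scale with fixed item scoring weights (never estimated)."""

    scale_name: str
    item_weights: tuple[tuple[str, float], ...]
    constant: float = 0.0  # additive scoring constant; shifts means only

    def __post_init__(self):
        if isinstance(self.item_weights, dict):
            object.__setattr__(self, "item_weights", tuple(self.item_weights.items()))
        if not any(w != 0 for _, w in self.item_weights):
            raise ConfigError(f"scale {self.scale_name!r} has no nonzero weight")
        names = [i for i, _ in self.item_weights]
        if len(set(names)) != len(names):
            raise ConfigError(f"scale {self.scale_name!r} repeats an item")

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(i for i, _ in self.item_weights)

    def weight(self, item: str) -> float:
        return dict(self.item_weights)[item]


@dataclass(frozen=True)
class FusionStudySpec:
    """Full study description: variables, scales, downstream/control structure,
    and any scale-bypassing item effects."""

    variables: tuple[VariableSummary, ...]
    scales: tuple[ScaleDefinition, ...]
    downstream: tuple[str, ...]
    controls: tuple[str, ...]
    structural_paths: tuple[tuple[str, str], ...]  # (cause, effect) incl. controls
    scale_effects: tuple[tuple[str, str], ...] | None = None  # None = all pairs
    direct_item_effects: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "scales", tuple(self.scales))
        object.__setattr__(self, "downstream", tuple(self.downstream))
        object.__setattr__(self, "controls", tuple(self.controls))
        object.__setattr__(self, "structural_paths",
                           tuple((c, e) for c, e in self.structural_paths))
        object.__setattr__(self, "direct_item_effects",
                           tuple((c, e) for c, e in self.direct_item_effects))
        if self.scale_effects is None:
            object.__setattr__(self, "scale_effects", tuple(
                (s.scale_name, d) for s in self.scales for d in self.downstream))
        else:
            object.__setattr__(self, "scale_effects",
                               tuple((s, d) for s, d in self.scale_effects))
        roster = {v.name for v in self.variables}
        if len(roster) != len(self.variables):
            raise ConfigError("duplicate variable names in roster")
        items = set(self.items)
        down, ctrl = set(self.downstream), set(self.controls)
        if items & down or items & ctrl or down & ctrl:
            raise ConfigError("items, downstream and control sets must be disjoint")
        for group, label in ((down, "downstream"), (ctrl, "control")):
            missing = group - roster
            if missing:
                raise ConfigError(f"{label} variables not in roster: {sorted(missing)}")
        for s in self.scales:
            missing = set(s.items) - roster
            if missing:
                raise ConfigError(
                    f"scale {s.scale_name!r} references unknown items: {sorted(missing)}")
        scale_names = [s.scale_name for s in self.scales]
        if len(set(scale_names)) != len(scale_names):
            raise ConfigError("duplicate scale names")
        for c, e in self.structural_paths:
            if c not in down | ctrl or e not in down:
                raise ConfigError(f"structural path ({c}, {e}) must run from a "
                                  "downstream/control variable to a downstream variable")
        for s, d in self.scale_effects:
            if s not in scale_names or d not in down:
                raise ConfigError(f"scale effect ({s}, {d}) references unknown names")
        for i, d in self.direct_item_effects:
            if i not in items or d not in down:
                raise ConfigError(f"direct item effect ({i}, {d}) references unknown names")
        if len(set(self.direct_item_effects)) != len(self.direct_item_effects):
            raise ConfigError("duplicate direct item effects")
        # acyclicity among downstream variables
        try:
            SemModelSpec(observed_names=(), latent_names=tuple(down | ctrl),
                         loadings=(),
                         paths=tuple((c, e, Fixed(0.0)) for c, e in self.structural_paths))
        except SemSpecError as exc:
            raise ConfigError(str(exc)) from exc

    @property
    def items(self) -> tuple[str, ...]:
        """Items of all scales, in roster order."""
        in_scale = {i for s in self.scales for i in s.items}
        return tuple(v.name for v in self.variables if v.name in in_scale)

    def summary(self, name: str) -> VariableSummary:
        for v in self.variables:
            if v.name == name:
                return v
        raise ConfigError(f"unknown variable {name!r}")

    def replace_effects(self, direct_item_effects) -> "FusionStudySpec":
        return FusionStudySpec(
            variables=self.variables, scales=self.scales,
            downstream=self.downstream, controls=self.controls,
            structural_paths=self.structural_paths,
            scale_effects=self.scale_effects,
            direct_item_effects=tuple(direct_item_effects))


# ---------------------------------------------------------------------------
# Measurement layer
# ---------------------------------------------------------------------------


def apply_error_spec(summaries):
    """Measurement layer for a list of :class:`VariableSummary`.

    Each observed variable gets one true-score latent with a fixed unit
    loading and an error variance fixed at (error_percent/100) * variance.
    Returns ``(loadings, theta_entries)``; true-score (co)variances are added
    by the structure builders since their free/fixed status depends on the
    variable's causal role.
    """
    loadings, theta = [], []
    for v in summaries:
        loadings.append((v.name, ts(v.name), Fixed(1.0)))
        theta.append((v.name, v.name, Fixed(v.error_variance)))
    return tuple(loadings), tuple(theta)


def build_composite(scale: ScaleDefinition, roster: set[str] | None = None):
    """Latent-layer entries for an exact weighted-composite scale.

    The composite latent receives fixed paths (the scoring weights) from each
    item's true-score latent and has disturbance variance fixed at zero, so its
    model value is exactly the weighted sum a researcher computes.  Returns
    ``(paths, psi_entries)``.
    """
    if roster is not None:
        missing = set(scale.items) - roster
        if missing:
            raise ConfigError(
                f"scale {scale.scale_name!r} items not in roster: {sorted(missing)}")
    paths = tuple((ts(i), scale.scale_name, Fixed(w)) for i, w in scale.item_weights)
    psi = ((scale.scale_name, scale.scale_name, Fixed(0.0)),)
    return paths, psi


def _free_cov_block(names):
    """Free variances and free covariances among true-score latents."""
    entries = []
    for i, a in enumerate(names):
        entries.append((ts(a), ts(a), Free(f"var_{a}")))
        for b in names[i + 1:]:
            entries.append((ts(a), ts(b), Free(f"cov_{a}_{b}")))
    return entries


def _structure(study: FusionStudySpec):
    """Shared downstream structure: disturbances plus configured paths."""
    psi = [(ts(d), ts(d), Free(f"dist_{d}")) for d in study.downstream]
    paths = [(ts(c), ts(e), Free(f"b_{c}_{e}")) for c, e in study.structural_paths]
    return paths, psi


def build_scale_only(study: FusionStudySpec) -> SemModelSpec:
    """Scale-only model: arithmetic scale scores as observed causes.

    The scale-score variables (0%-error entries of the roster) plus controls
    and downstream variables; every configured scale -> downstream effect is
    free; no items appear.
    """
    if not study.scales:
        raise ConfigError("scale-only model requires at least one scale")
    roster = {v.name for v in study.variables}
    score_names = []
    for s in study.scales:
        if s.scale_name not in roster:
            raise ConfigError(
                f"scale-score variable {s.scale_name!r} missing from the data roster")
        score_names.append(s.scale_name)
    observed = tuple(score_names) + study.controls + study.downstream
    summaries = [study.summary(n) for n in observed]
    loadings, theta = apply_error_spec(summaries)
    exo = list(score_names) + list(study.controls)
    psi = _free_cov_block(exo)
    paths, psi_d = _structure(study)
    paths = [(ts(s), ts(d), Free(f"g_{s}_{d}")) for s, d in study.scale_effects] + paths
    return SemModelSpec(
        observed_names=observed,
        latent_names=tuple(ts(n) for n in observed),
        loadings=loadings, paths=tuple(paths),
        psi=tuple(psi) + tuple(psi_d), theta=theta)


def build_item_only(study: FusionStudySpec, effects=None) -> SemModelSpec:
    """Item-only model: items replace the scales as causes.

    ``effects`` is the list of (item, downstream) direct effects to free
    (default: the study's ``direct_item_effects``).  Item true scores covary
    freely with each other and the controls, so no factor structure — and no
    particular number of common causes — is imposed on the items.
    """
    if effects is None:
        effects = study.direct_item_effects
    effects = tuple((i, d) for i, d in effects)
    if len(set(effects)) != len(effects):
        raise ConfigError("duplicate entries in the item-effect list")
    items = study.items
    for i, d in effects:
        if i not in items or d not in study.downstream:
            raise ConfigError(f"effect ({i}, {d}) references unknown item/downstream")
    observed = items + study.controls + study.downstream
    summaries = [study.summary(n) for n in observed]
    loadings, theta = apply_error_spec(summaries)
    psi = _free_cov_block(list(items) + list(study.controls))
    paths, psi_d = _structure(study)
    paths = [(ts(i), ts(d), Free(f"e_{i}_{d}")) for i, d in effects] + paths
    return SemModelSpec(
        observed_names=observed,
        latent_names=tuple(ts(n) for n in observed),
        loadings=loadings, paths=tuple(paths),
        psi=tuple(psi) + tuple(psi_d), theta=theta)


def build_fusion(study: FusionStudySpec, direct_item_effects=None) -> SemModelSpec:
    """Scale-and-item fusion model.

    Items, exact composite-scale latents, scale -> downstream effects, plus any
    scale-bypassing direct item effects (``None`` uses the study's list; an
    empty list gives the basic fusion validity model).
    """
    if not study.scales:
        raise ConfigError("fusion model requires at least one scale")
    if not study.downstream:
        raise ConfigError("fusion model requires at least one downstream variable")
    if direct_item_effects is None:
        direct_item_effects = study.direct_item_effects
    direct_item_effects = tuple((i, d) for i, d in direct_item_effects)
    items = study.items
    observed = items + study.controls + study.downstream
    roster = set(items)
    for s in study.scales:
        if s.scale_name in observed:
            raise ConfigError(
                f"scale latent {s.scale_name!r} collides with an observed variable")
    summaries = [study.summary(n) for n in observed]
    loadings, theta = apply_error_spec(summaries)
    psi = _free_cov_block(list(items) + list(study.controls))
    comp_paths, comp_psi = [], []
    for s in study.scales:
        pa, ps = build_composite(s, roster)
        comp_paths += list(pa)
        comp_psi += list(ps)
    fixed_comp = {(c, e) for c, e, _ in comp_paths}
    for i, d in direct_item_effects:
        if i not in items or d not in study.downstream:
            raise ConfigError(f"direct effect ({i}, {d}) references unknown names")
        if (ts(i), ts(d)) in fixed_comp or (ts(i), d) in fixed_comp:
            raise ConfigError(f"direct effect ({i}, {d}) duplicates a composite path")
    paths, psi_d = _structure(study)
    paths = ([(s_, ts(d), Free(f"g_{s_}_{d}")) for s_, d in study.scale_effects]
             + [(ts(i), ts(d), Free(f"e_{i}_{d}")) for i, d in direct_item_effects]
             + paths)
    latents = tuple(ts(n) for n in observed) + tuple(s.scale_name for s in study.scales)
    return SemModelSpec(
        observed_names=observed, latent_names=latents,
        loadings=loadings,
        paths=tuple(comp_paths) + tuple(paths),
        psi=tuple(psi) + tuple(comp_psi) + tuple(psi_d),
        theta=theta)


# ---------------------------------------------------------------------------
# Data-side helpers
# ---------------------------------------------------------------------------


def compute_scale_scores(item_values, scale: ScaleDefinition) -> np.ndarray:
    """Arithmetic scale scores: weighted item sum plus the scoring constant.

    ``item_values`` is a mapping (or pandas DataFrame) of item name -> values
    per respondent.  Missing responses propagate to missing scores.
    """
    cols = [np.asarray(item_values[i], float) for i in scale.items]
    arr = np.column_stack(cols)
    w = np.array([w for _, w in scale.item_weights])
    return arr @ w + scale.constant


def candidate_item_effects(study: FusionStudySpec, exclude=()):
    """All (item, downstream) pairs, minus ``exclude`` — the scale-bypassing
    candidate space (8 items x 4 downstream = 32 in a two-scale, eight-item, four-outcome study)."""
    exclude = set(tuple(e) for e in exclude)
    return tuple((i, d) for i in study.items for d in study.downstream
                 if (i, d) not in exclude)


def augment_covariance_with_scores(S, names, scales):
    """Append arithmetic scale-score rows/columns to a covariance matrix.

    For score = w' items: Cov(score, x) = w' Cov(items, x) and
    Var(score) = w' S_items w — the quadratic-form identity of score
    calculation, applied on the data side.  Returns ``(S_aug, names_aug)``.
    """
    out = np.asarray(S, float)
    out_names = list(names)
    for s in scales:
        if s.scale_name in out_names:
            continue
        w = np.zeros(out.shape[0])
        for i, wi in s.item_weights:
            if i not in out_names:
                raise ConfigError(f"item {i!r} not present in the covariance matrix")
            w[out_names.index(i)] = wi
        cross = out @ w
        var = float(w @ out @ w)
        out = np.block([[out, cross[:, None]], [cross[None, :], np.array([[var]])]])
        out_names = out_names + [s.scale_name]
    return out, out_names
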