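"""End-to-end fusion-validity audit.

Follows the development sequence of the method: fit the basic fusion model,
let the data demand scale-bypassing effects through a forward search, fit the
expanded scale-and-item model, then the scale-only and item-only companions
(the item-only search starts from the effects the expanded model required),
and close with the triplicate effect table and the verdict.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from .builder import (FusionStudySpec, VariableSummary,
                      augment_covariance_with_scores, build_fusion,
                      build_item_only, build_scale_only,
                      candidate_item_effects, ts)
from .diagnostics import (MI_THRESHOLD, AuditReport, effect_table,
                          forward_search, fusion_verdict)
from .io import subset_covariance
from .sem_core import fit_ml

__all__ = ["run_audit", "audit_log_lines"]


def _strip_ts(pair):
    return tuple(x.removeprefix("ts_") for x in pair)


def run_audit(S, names, n, study: FusionStudySpec, *,
              mi_threshold: float = MI_THRESHOLD, alpha: float = 0.05,
              max_steps: int | None = None) -> AuditReport:
    """Fit all four model variants and assemble the audit report.

    ``S`` is the sample covariance over ``names`` (sample size ``n``).  If the
    arithmetic scale-score variables are not among ``names`` they are appended
    from the item block and the scoring weights, which is exactly how a
    researcher would compute them from raw data.
    """
    S = np.asarray(S, float)
    names = list(names)
    have_scores = all(s.scale_name in names for s in study.scales)
    if not have_scores:
        S, names = augment_covariance_with_scores(S, names, study.scales)

    fits: dict = {}

    basic_spec = build_fusion(study, study.direct_item_effects)
    S_f = subset_covariance(S, names, basic_spec.observed_names)
    fits["basic_fusion"] = fit_ml(basic_spec, S_f, n)

    candidates = [(ts(i), ts(d))
                  for i, d in candidate_item_effects(study, study.direct_item_effects)]
    _, trail = forward_search(basic_spec, S_f, n, candidates,
                              mi_threshold=mi_threshold, alpha=alpha,
                              max_steps=max_steps)
    selected = tuple(_strip_ts(step.freed) for step in trail)
    all_effects = tuple(study.direct_item_effects) + selected
    expanded_spec = build_fusion(study, all_effects)
    fits["expanded"] = fit_ml(expanded_spec, S_f, n)

    # the scale-score variables are 0%-error observed variables; if the study
    # roster does not list them, register them with their data-side variance
    roster = {v.name for v in study.variables}
    extra = tuple(
        VariableSummary(s.scale_name, 0.0, float(S[names.index(s.scale_name),
                                                   names.index(s.scale_name)]), 0.0)
        for s in study.scales if s.scale_name not in roster)
    study_scores = study if not extra else FusionStudySpec(
        variables=study.variables + extra, scales=study.scales,
        downstream=study.downstream, controls=study.controls,
        structural_paths=study.structural_paths,
        scale_effects=study.scale_effects,
        direct_item_effects=study.direct_item_effects)
    scale_spec = build_scale_only(study_scores)
    S_s = subset_covariance(S, names, scale_spec.observed_names)
    fits["scale_only"] = fit_ml(scale_spec, S_s, n)

    item_spec = build_item_only(study, all_effects)
    S_i = subset_covariance(S, names, item_spec.observed_names)
    fits["item_only"] = fit_ml(item_spec, S_i, n)
    io_candidates = [(ts(i), ts(d))
                     for i, d in candidate_item_effects(study, all_effects)]
    _, io_trail = forward_search(item_spec, S_i, n, io_candidates,
                                 mi_threshold=mi_threshold, alpha=alpha,
                                 max_steps=max_steps)
    if io_trail:
        io_effects = all_effects + tuple(_strip_ts(s.freed) for s in io_trail)
        fits["item_only"] = fit_ml(build_item_only(study, io_effects), S_i, n)

    values, bands = effect_table(fits, study)
    report = AuditReport(study=study, fits=fits,
                         effect_values=values, effect_bands=bands,
                         selected_effects=selected,
                         search_trail=tuple(trail),
                         item_only_trail=tuple(io_trail))
    report.verdict = fusion_verdict(report, alpha=alpha)
    return report


def audit_log_lines(report: AuditReport, *, S=None, config_text: str | None = None,
                    seed=None) -> list[str]:
    """Machine (JSON-lines) trace of an audit: input digests and per-model fit
    statistics — enough to replay the run exactly."""
    lines = []
    meta = {"record": "inputs", "seed": seed}
    if S is not None:
        meta["cov_sha256"] = hashlib.sha256(
            np.ascontiguousarray(np.asarray(S, float)).tobytes()).hexdigest()
    if config_text is not None:
        meta["config_sha256"] = hashlib.sha256(config_text.encode()).hexdigest()
    lines.append(json.dumps(meta, sort_keys=True))
    for key in ("basic_fusion", "expanded", "scale_only", "item_only"):
        fit = report.fits[key]
        lines.append(json.dumps({
            "record": "fit", "model": key,
            "chi_square": round(fit.chi_square, 6), "df": fit.df,
            "p_value": round(fit.p_value, 6), "n": fit.n,
            "converged": fit.converged, "admissible": fit.admissible,
        }, sort_keys=True))
    for step in report.search_trail:
        lines.append(json.dumps({
            "record": "search_step", "freed": list(step.freed),
            "mod_index": round(step.mod_index, 4),
            "delta_chi2": round(step.delta_chi2, 4),
            "chi_square": round(step.chi_square, 4), "df": step.df,
            "p_value": round(step.p_value, 6)}, sort_keys=True))
    lines.append(json.dumps({"record": "verdict", **report.verdict}, sort_keys=True))
    return lines
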