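"""Model comparison and data-prompted search machinery.

Univariate Lagrange-multiplier (modification-index) statistics drive a forward
search for scale-bypassing effects; nested models are compared by chi-square
differences; the three informative model variants are laid out in a triplicate
standardized-effect table; and the audit closes with a machine-readable
fusion-validity verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .builder import FusionStudySpec, ts
from .sem_core import (FitResult, Free, SemInputError, SemModelSpec,
                       chisq_pvalue, fit_ml, standard_errors, _fit_internals)

__all__ = [
    "ModIndexEntry",
    "SearchStep",
    "AuditReport",
    "modification_indices",
    "forward_search",
    "chisq_difference",
    "effect_table",
    "render_effect_table",
    "fusion_verdict",
    "MI_THRESHOLD",
]

# chi-square(1) critical value at alpha = .01: candidates below this are not
# considered data-demanded.
MI_THRESHOLD = 6.64
SEARCH_ALPHA = 0.05


@dataclass(frozen=True)
class ModIndexEntry:
    """Expected chi-square drop (and parameter change) from freeing one
    fixed-at-zero structural path."""

    candidate: tuple[str, str]
    mod_index: float
    epc: float
    ok: bool = True
    reason: str = ""


def modification_indices(fit: FitResult, candidates) -> list[ModIndexEntry]:
    """Univariate score (Lagrange-multiplier) statistics for latent paths.

    For each candidate (cause, effect) latent path currently absent/fixed at
    zero, MI = (n-1) * g^2 / (2 h) where g is the gradient of the ML
    discrepancy with respect to the candidate and h its expected-information
    curvature partialled on the free parameters; EPC = -g / h.
    """
    cm, x = _fit_internals(fit)
    free_paths = {(c, e) for c, e, st in fit.spec.paths if isinstance(st, Free)}
    f, g, sigma, sigma_inv, A, C, psi = cm.gradient(x, fit.S)
    if sigma_inv is None:
        raise SemInputError("fitted model has a non-PD implied covariance")
    G = sigma_inv - sigma_inv @ fit.S @ sigma_inv
    stack_free = cm.delta_stack(A, C, psi)
    R = C @ psi @ A.T  # m x p
    Mfree = np.einsum("ab,kbc->kac", sigma_inv, stack_free)
    D_ff = np.einsum("jab,kba->jk", Mfree, Mfree)
    try:
        D_ff_inv = sla.inv(D_ff) if cm.q else np.zeros((0, 0))
    except sla.LinAlgError:
        D_ff_inv = sla.pinv(D_ff)
    out = []
    for cand in candidates:
        c, e = cand
        if c not in cm.lat_index or e not in cm.lat_index:
            out.append(ModIndexEntry((c, e), 0.0, 0.0, ok=False,
                                     reason="unknown latent name"))
            continue
        if (c, e) in free_paths:
            out.append(ModIndexEntry((c, e), 0.0, 0.0, ok=False,
                                     reason="candidate already free"))
            continue
        ic, ie = cm.lat_index[c], cm.lat_index[e]
        delta = np.outer(A[:, ie], R[ic]) + np.outer(R[ic], A[:, ie])
        g_c = float(np.sum(G * delta))
        Mc = sigma_inv @ delta
        d_cc = float(np.sum(Mc * Mc.T))
        d_cf = np.einsum("ab,kba->k", Mc, Mfree)
        h = d_cc - float(d_cf @ D_ff_inv @ d_cf) if cm.q else d_cc
        if h <= 1e-12:
            out.append(ModIndexEntry((c, e), 0.0, 0.0, ok=False,
                                     reason="candidate not identified given the model"))
            continue
        mi = (fit.n - 1) * g_c * g_c / (2.0 * h)
        out.append(ModIndexEntry((c, e), float(max(mi, 0.0)), float(-g_c / h)))
    return out


@dataclass(frozen=True)
class SearchStep:
    freed: tuple[str, str]
    mod_index: float
    delta_chi2: float
    chi_square: float
    df: int
    p_value: float


def _add_free_path(spec: SemModelSpec, cause: str, effect: str,
                   name: str | None = None) -> SemModelSpec:
    name = name or f"mi_{cause}_{effect}"
    return SemModelSpec(
        observed_names=spec.observed_names, latent_names=spec.latent_names,
        loadings=spec.loadings,
        paths=spec.paths + ((cause, effect, Free(name)),),
        psi=spec.psi, theta=spec.theta)


def forward_search(base: SemModelSpec, S, n, candidates, *,
                   mi_threshold: float = MI_THRESHOLD,
                   alpha: float = SEARCH_ALPHA,
                   max_steps: int | None = None,
                   stop_on_fit: bool = True):
    """Iteratively free the largest-MI candidate path and refit.

    Stops when the model p-value reaches ``alpha`` (if ``stop_on_fit``), when
    no remaining candidate's MI exceeds ``mi_threshold``, or after
    ``max_steps`` additions.  Ties between equal MIs break lexicographically by
    the candidate order given, so the trail is deterministic.  Returns
    ``(expanded_spec, trail)``; a non-convergent refit truncates the trail with
    a diagnostic step recorded in ``trail``.
    """
    candidates = [tuple(c) for c in candidates]
    if max_steps is None:
        max_steps = len(candidates)
    spec = base
    fit = fit_ml(spec, S, n)
    trail: list[SearchStep] = []
    remaining = list(candidates)
    for _ in range(max_steps):
        if stop_on_fit and fit.p_value >= alpha:
            break
        if not remaining:
            break
        entries = modification_indices(fit, remaining)
        usable = [en for en in entries if en.ok]
        if not usable:
            break
        best = max(usable, key=lambda en: (en.mod_index, -remaining.index(en.candidate)))
        if best.mod_index <= mi_threshold:
            break
        new_spec = _add_free_path(spec, *best.candidate)
        new_fit = fit_ml(new_spec, S, n)
        step = SearchStep(best.candidate, best.mod_index,
                          fit.chi_square - new_fit.chi_square,
                          new_fit.chi_square, new_fit.df, new_fit.p_value)
        trail.append(step)
        if not new_fit.converged:
            break
        spec, fit = new_spec, new_fit
        remaining.remove(best.candidate)
    return spec, trail


def chisq_difference(nested: FitResult, fuller: FitResult):
    """Likelihood-ratio difference test for nested covariance-structure fits."""
    nested_free = set(nested.spec.free_names)
    fuller_free = set(fuller.spec.free_names)
    if nested.n != fuller.n:
        raise SemInputError("nested comparison requires the same sample size N")
    if nested.S is not None and fuller.S is not None and \
            not np.allclose(nested.S, fuller.S, atol=1e-10):
        raise SemInputError("nested comparison requires the same sample covariance")
    same = nested_free == fuller_free
    if not same and not nested_free < fuller_free:
        raise SemInputError("models are not nested (free-parameter sets do not nest)")
    delta_df = nested.df - fuller.df
    delta = nested.chi_square - fuller.chi_square
    if delta < -1e-6 * max(1.0, fuller.chi_square):
        raise SemInputError(
            f"fuller model fits worse (delta chi2 = {delta:.3g}); check convergence")
    delta = max(delta, 0.0)
    p = 1.0 if delta_df == 0 else chisq_pvalue(delta, delta_df)
    return delta, delta_df, p


# ---------------------------------------------------------------------------
# Triplicate effect table
# ---------------------------------------------------------------------------

VARIANT_LABELS = (("scale_only", "Scales"), ("item_only", "Items"),
                  ("expanded", "Scales + Items"))


def _std_direct(fit: FitResult, cause: str, effect: str):
    """Standardized direct effect for observed/scale-level names, or None."""
    for key in ((ts(cause), ts(effect)), (cause, ts(effect)),
                (ts(cause), effect), (cause, effect)):
        if key in fit.standardized:
            return fit.standardized[key], key
    return None, None


def _band_for(fit: FitResult, bands: dict, key):
    for c, e, st in fit.spec.paths:
        if (c, e) == key and isinstance(st, Free):
            return bands.get(st.name, 0)
    return 0


def effect_table(fits: dict, study: FusionStudySpec):
    """Triplicate standardized-direct-effect table across model variants.

    Rows are causes (scales, items, controls, upstream work variables) with a
    sub-row per variant; columns are the downstream variables.  Cells are blank
    (NaN) when the causal variable, or the particular path, is not part of that
    model.  Returns ``(values, bands)`` DataFrames sharing a (cause, variant)
    MultiIndex; bands are 3 / 2 / 0 for |estimate| above 3 or 2 standard
    errors.
    """
    for key in ("scale_only", "item_only", "expanded"):
        if key not in fits:
            raise SemInputError(f"effect_table requires a {key!r} fit")
    causes = ([s.scale_name for s in study.scales] + list(study.items)
              + list(study.controls) + [d for d in study.downstream])
    effects = list(study.downstream)
    band_cache = {}
    for key, _ in VARIANT_LABELS:
        try:
            band_cache[key] = standard_errors(fits[key])[1]
        except Exception:
            band_cache[key] = {}
    index = pd.MultiIndex.from_tuples(
        [(c, lab) for c in causes for _, lab in VARIANT_LABELS],
        names=["cause", "model"])
    values = pd.DataFrame(np.nan, index=index, columns=effects)
    bands = pd.DataFrame(0, index=index, columns=effects)
    for c in causes:
        for key, lab in VARIANT_LABELS:
            fit = fits[key]
            for d in effects:
                if c == d:
                    continue
                v, pkey = _std_direct(fit, c, d)
                if v is None:
                    continue
                values.loc[(c, lab), d] = v
                bands.loc[(c, lab), d] = _band_for(fit, band_cache[key], pkey)
    return values, bands


def render_effect_table(values: pd.DataFrame, bands: pd.DataFrame,
                        decimals: int = 2) -> str:
    """Plain-text rendering: 2-dp effects with a/b marks for the 3/2-SE bands."""
    out = values.copy().astype(object)
    for idx in values.index:
        for col in values.columns:
            v = values.loc[idx, col]
            if pd.isna(v):
                out.loc[idx, col] = "--"
            else:
                mark = {3: "a", 2: "b"}.get(int(bands.loc[idx, col]), "")
                out.loc[idx, col] = f"{v:.{decimals}f}{mark}"
    return out.to_string()


# ---------------------------------------------------------------------------
# Verdict
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    """Four-model fusion-validity comparison."""

    study: FusionStudySpec
    fits: dict
    effect_values: pd.DataFrame
    effect_bands: pd.DataFrame
    selected_effects: tuple[tuple[str, str], ...]
    search_trail: tuple[SearchStep, ...]
    item_only_trail: tuple[SearchStep, ...] = ()
    verdict: dict = field(default_factory=dict)


def _expected_sign(study: FusionStudySpec, scale_fit: FitResult,
                   item: str, down: str) -> float:
    """Sign the scales claim for an item's effect: sum over scales of
    (scoring weight) x (scale-only standardized scale effect)."""
    total = 0.0
    for s in study.scales:
        if item in s.items:
            v, _ = _std_direct(scale_fit, s.scale_name, down)
            if v is not None:
                total += s.weight(item) * v
    return float(np.sign(total))


def fusion_verdict(report: AuditReport, *, alpha: float = 0.05) -> dict:
    """Machine-readable fusion-validity verdict.

    * basic-fusion pass/fail by its chi-square p-value;
    * the scale-bypassing effects the data demanded;
    * a per-item profile from the item-only model (none / partial / full /
      sign_reversal relative to the sign the scales claim);
    * scale-effect attenuation between the scale-only and expanded models.
    """
    fits = report.fits
    for key in ("scale_only", "item_only", "basic_fusion", "expanded"):
        if key not in fits:
            raise SemInputError(f"verdict requires a {key!r} fit")
    study = report.study
    basic = fits["basic_fusion"]
    verdict: dict = {
        "basic_fusion": {
            "chi_square": round(basic.chi_square, 6),
            "df": basic.df,
            "p_value": basic.p_value,
            "pass": bool(basic.p_value >= alpha),
        },
        "bypass_effects": [list(e) for e in report.selected_effects],
    }
    item_fit = fits["item_only"]
    item_effects = {}
    for c, e, st in item_fit.spec.paths:
        if isinstance(st, Free) and st.name.startswith("e_"):
            item_effects.setdefault(c, []).append(e)
    profiles = {}
    n_down = len(study.downstream)
    for item in study.items:
        present = item_effects.get(ts(item), [])
        reversal = False
        for d in study.downstream:
            if ts(d) in present:
                v, _ = _std_direct(item_fit, item, d)
                expect = _expected_sign(study, fits["scale_only"], item, d)
                if v is not None and expect != 0 and np.sign(v) != expect:
                    reversal = True
        if reversal:
            profiles[item] = "sign_reversal"
        elif len(present) == 0:
            profiles[item] = "none"
        elif len(present) == n_down:
            profiles[item] = "full"
        else:
            profiles[item] = "partial"
    verdict["item_profiles"] = profiles
    attenuation = {}
    for s, d in study.scale_effects:
        v0, _ = _std_direct(fits["scale_only"], s, d)
        v1, _ = _std_direct(fits["expanded"], s, d)
        if v0 is not None and v1 is not None:
            attenuation[f"{s}->{d}"] = {
                "scale_only": float(v0), "expanded": float(v1),
                "ratio": float(v1 / v0) if abs(v0) > 1e-12 else float("nan"),
            }
    verdict["scale_attenuation"] = attenuation
    return verdict
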