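"""Synthetic scenarios: population covariances and finite-sample draws under
valid-fusion and invalid-fusion generating models, plus recovery/power
harnesses.

A scenario is a study layout plus a full assignment of true parameter values
to the generating fusion model.  In the *valid* scenario every item reaches
the downstream variables only through the weighted composite(s); an *invalid*
scenario adds direct item -> downstream paths of stated standardized size.
Generated data are multivariate normal (the ML discrepancy's own assumption);
sample covariances come from exact Wishart draws by default, or from averaging
n Gaussian observations.  A master seed expands to per-replicate seeds through
``numpy.random.SeedSequence.spawn`` — one integer reproduces every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .builder import (FusionStudySpec, ScaleDefinition, VariableSummary,
                      build_fusion, ts)
from .sem_core import SemInputError, fit_ml, implied_covariance
from .diagnostics import forward_search

__all__ = [
    "GeneratingScenario",
    "ScenarioError",
    "population_sigma",
    "sample_cov",
    "recovery_experiment",
    "compact_scenario",
    "care_aide_scenario",
]


class ScenarioError(ValueError):
    """A generating scenario that cannot produce a PD population covariance."""


@dataclass(frozen=True)
class GeneratingScenario:
    """A study layout with true parameter values for the generating model."""

    study: FusionStudySpec
    true_values: dict
    direct_effects_truth: tuple[tuple[str, str, float], ...] = ()

    @property
    def valid(self) -> bool:
        """Valid fusion scenario iff no true scale-bypassing effects exist."""
        return len(self.direct_effects_truth) == 0

    @property
    def generating_spec(self):
        pairs = tuple((i, d) for i, d, _ in self.direct_effects_truth)
        return build_fusion(self.study, pairs)


def population_sigma(scenario: GeneratingScenario) -> np.ndarray:
    """Exact implied covariance of the generating model; PD verified."""
    sigma = implied_covariance(scenario.generating_spec, scenario.true_values)
    w = np.linalg.eigvalsh(sigma)
    if w[0] <= 0:
        raise ScenarioError(
            f"population covariance not positive definite (min eigenvalue {w[0]:.3e})")
    return sigma


def sample_cov(sigma_pop: np.ndarray, n: int, seed, *, method: str = "wishart"):
    """Sample covariance of n multivariate-normal observations.

    ``method='wishart'`` draws the covariance exactly from its sampling
    distribution W_p(n-1, Sigma/(n-1)); ``method='mvn'`` averages n explicit
    Gaussian draws.  A seed is required: no silent randomness.
    """
    sigma_pop = np.asarray(sigma_pop, float)
    p = sigma_pop.shape[0]
    if n <= p:
        raise SemInputError("n must exceed the matrix dimension for a PD draw")
    rng = np.random.default_rng(seed)
    if method == "wishart":
        return stats.wishart.rvs(df=n - 1, scale=sigma_pop / (n - 1), random_state=rng)
    if method == "mvn":
        x = rng.multivariate_normal(np.zeros(p), sigma_pop, size=n, method="cholesky")
        return np.cov(x, rowvar=False, ddof=1)
    raise ValueError(f"unknown sampling method {method!r}")


def recovery_experiment(scenario: GeneratingScenario, n: int, reps: int, seed, *,
                        alpha: float = 0.05, do_search: bool = False,
                        search_candidates=None) -> dict:
    """Monte-Carlo recovery/power study under one generating scenario.

    Per replicate: a sample covariance is drawn, the *correctly specified*
    model is fitted (bias/RMSE of every free parameter), the *basic* fusion
    model is tested at level ``alpha``, and (optionally) the forward search is
    run from the basic model to see which bypassing effects it selects.
    Non-convergent replicates are counted and reported, never hidden.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    sigma = population_sigma(scenario)
    gen_spec = scenario.generating_spec
    basic_spec = build_fusion(scenario.study, ())
    truth_pairs = {(i, d) for i, d, _ in scenario.direct_effects_truth}
    if search_candidates is None:
        search_candidates = [(ts(i), ts(d)) for i in scenario.study.items
                             for d in scenario.study.downstream]
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    seeds = root.spawn(reps)
    names = list(gen_spec.free_names)
    truth = np.array([scenario.true_values[nm] for nm in names])
    ests = np.full((reps, len(names)), np.nan)
    rejected = np.zeros(reps, bool)
    exact_select = np.zeros(reps, bool)
    reject_and_correct = np.zeros(reps, bool)
    nonconv = 0
    same_model = gen_spec.free_names == basic_spec.free_names
    for r, ss in enumerate(seeds):
        S = sample_cov(sigma, n, ss)
        fit_true = fit_ml(gen_spec, S, n)
        if not fit_true.converged:
            nonconv += 1
        else:
            ests[r] = [fit_true.estimates[nm] for nm in names]
        fit_basic = fit_true if same_model else fit_ml(basic_spec, S, n)
        rejected[r] = fit_basic.p_value < alpha
        if do_search:
            _, trail = forward_search(basic_spec, S, n, search_candidates,
                                      alpha=alpha)
            picked = {(st.freed[0].removeprefix("ts_"),
                       st.freed[1].removeprefix("ts_")) for st in trail}
            exact_select[r] = picked == truth_pairs
            reject_and_correct[r] = rejected[r] and truth_pairs <= picked
    ok = ~np.isnan(ests[:, 0]) if len(names) else np.ones(reps, bool)
    bias = np.nanmean(ests, axis=0) - truth
    rmse = np.sqrt(np.nanmean((ests - truth[None, :]) ** 2, axis=0))
    table = pd.DataFrame({"true": truth, "bias": bias, "rmse": rmse}, index=names)
    out = {
        "parameters": table,
        "rejection_rate": float(np.mean(rejected)),
        "n_nonconverged": int(nonconv),
        "reps": reps,
        "n": n,
    }
    if do_search:
        out["exact_selection_rate"] = float(np.mean(exact_select))
        out["reject_and_correct_rate"] = float(np.mean(reject_and_correct))
    return out


# ---------------------------------------------------------------------------
# Scenario construction
# ---------------------------------------------------------------------------


def _true_variance(v: VariableSummary) -> float:
    return (1.0 - v.error_percent / 100.0) * v.variance


def _assemble_true_values(study: FusionStudySpec, exo_corr: dict,
                          std_effects: dict,
                          direct_effects: tuple[tuple[str, str, float], ...]):
    """Translate standardized settings into generating-model parameter values.

    ``exo_corr[(a, b)]`` are correlations among exogenous true scores;
    ``std_effects[(cause, effect)]`` standardized structural coefficients.
    Downstream disturbances are solved so every observed variance matches the
    roster exactly.  Returns the ``true_values`` dict for the generating
    fusion model (direct effects included).
    """
    exo = list(study.items) + list(study.controls)
    tau = {v.name: _true_variance(v) for v in study.variables}
    values: dict[str, float] = {}
    # exogenous latent covariance block
    k = len(exo)
    V = np.zeros((k, k))
    lat_names = [ts(x) for x in exo]
    for i, a in enumerate(exo):
        V[i, i] = tau[a]
        values[f"var_{a}"] = tau[a]
        for j in range(i + 1, k):
            b = exo[j]
            r = exo_corr.get((a, b), exo_corr.get((b, a), 0.0))
            V[i, j] = V[j, i] = r * np.sqrt(tau[a] * tau[b])
            values[f"cov_{a}_{b}"] = V[i, j]
    # extend with composite scales
    for s in study.scales:
        w = np.zeros(len(lat_names))
        for i_, wi in s.item_weights:
            w[lat_names.index(ts(i_))] = wi
        col = V @ w
        var = float(w @ V @ w)
        V = np.block([[V, col[:, None]], [col[None, :], np.array([[var]])]])
        lat_names.append(s.scale_name)
    # downstream, in declared (causal) order
    direct = {(i, d): m for i, d, m in direct_effects}
    sd = {nm: float(np.sqrt(V[lat_names.index(nm), lat_names.index(nm)]))
          for nm in lat_names}
    for d in study.downstream:
        sd_d = float(np.sqrt(tau[d]))
        causes, coefs = [], []
        for s, dd in study.scale_effects:
            if dd == d:
                beta = std_effects.get((s, d), 0.0)
                b = beta * sd_d / sd[s]
                values[f"g_{s}_{d}"] = b
                causes.append(s)
                coefs.append(b)
        for (i, dd), mag in direct.items():
            if dd == d:
                b = mag * sd_d / sd[ts(i)]
                values[f"e_{i}_{d}"] = b
                causes.append(ts(i))
                coefs.append(b)
        for c, dd in study.structural_paths:
            if dd == d:
                beta = std_effects.get((c, d), 0.0)
                b = beta * sd_d / sd[ts(c)]
                values[f"b_{c}_{d}"] = b
                causes.append(ts(c))
                coefs.append(b)
        bvec = np.array(coefs)
        idx = [lat_names.index(c) for c in causes]
        explained = float(bvec @ V[np.ix_(idx, idx)] @ bvec)
        psi_d = tau[d] - explained
        if psi_d <= 0:
            raise ScenarioError(
                f"downstream variable {d!r}: explained variance {explained:.3g} "
                f"exceeds its true-score variance {tau[d]:.3g}")
        values[f"dist_{d}"] = psi_d
        cov_row = V[:, idx] @ bvec  # cov(ts_d, x) = sum_c b_c cov(c, x)
        V = np.block([[V, cov_row[:, None]],
                      [cov_row[None, :], np.array([[tau[d]]])]])
        lat_names.append(ts(d))
        sd[ts(d)] = sd_d
    return values


def _scenario(study, exo_corr, std_effects, direct_effects):
    values = _assemble_true_values(study, exo_corr, std_effects,
                                   tuple(direct_effects))
    return GeneratingScenario(study=study, true_values=values,
                              direct_effects_truth=tuple(direct_effects))


def compact_scenario(direct_effects=()) -> GeneratingScenario:
    """Small one-scale layout for simulation studies.

    Four items feeding one composite, two downstream variables in a chain, two
    controls; effect sizes in the weak-but-significant band (|beta| 0.1-0.3).
    ``direct_effects`` is a list of (item, downstream, standardized magnitude)
    true scale-bypassing effects; empty means the valid-fusion scenario.
    """
    variables = (
        VariableSummary("a1", 50.0, 49.0, 5),
        VariableSummary("a2", 48.0, 64.0, 5),
        VariableSummary("a3", 52.0, 36.0, 5),
        VariableSummary("a4", 49.0, 56.25, 5),
        VariableSummary("c1", 3.1, 1.6, 5),
        VariableSummary("c2", 4.0, 0.5, 4),
        VariableSummary("d1", 2.9, 4.0, 2),
        VariableSummary("d2", 5.3, 1.5, 4),
    )
    study = FusionStudySpec(
        variables=variables,
        scales=(ScaleDefinition("comp", (("a1", 0.4), ("a2", 0.3),
                                         ("a3", 0.2), ("a4", 0.1))),),
        downstream=("d1", "d2"),
        controls=("c1", "c2"),
        structural_paths=(("d1", "d2"), ("c1", "d1"), ("c2", "d2")),
    )
    items = ("a1", "a2", "a3", "a4")
    exo_corr = {}
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            exo_corr[(a, b)] = 0.40
    exo_corr[("c1", "c2")] = 0.05
    for a in items:
        exo_corr[(a, "c1")] = 0.05
        exo_corr[(a, "c2")] = 0.05
    std_effects = {
        ("comp", "d1"): -0.20, ("comp", "d2"): 0.20,
        ("d1", "d2"): -0.25, ("c1", "d1"): -0.15, ("c2", "d2"): 0.10,
    }
    return _scenario(study, exo_corr, std_effects, direct_effects)


# Observed means/variances/error percents on the scale of a care-aide
# work-life survey (overall health rating, activity/work limitation, pain,
# energy, social/emotional limitation items; staffing, support, demographic
# and disruptive-action controls; tiredness, rushing, burnout and
# looking-forward work-life outcomes).
_CARE_AIDE_VARIABLES = (
    ("RH", 50.04, 49.84, 5), ("PLA", 48.06, 52.66, 5), ("PLW", 48.33, 52.64, 5),
    ("BP", 49.05, 75.93, 5), ("EN", 55.15, 57.09, 5), ("PELS", 48.56, 60.14, 5),
    ("BE", 50.37, 60.92, 5), ("PELW", 47.76, 36.02, 5),
    ("physical", 49.10, 65.09, 0), ("mental", 51.86, 72.94, 0),
    ("EnoughStaff", 3.12, 1.63, 5), ("Supportive", 4.03, 0.56, 4),
    ("Sex", 1.90, 0.09, 3), ("Age", 6.59, 5.14, 4), ("ESL", 1.65, 0.23, 20),
    ("DRAN", 2.87, 1.71, 5), ("DRAS", 0.38, 0.45, 5),
    ("TiredAM", 2.89, 4.27, 2), ("Rushed", 3.00, 7.65, 7),
    ("Burntout", 2.40, 4.04, 4), ("LookForward", 5.33, 1.47, 4),
)

_PHYS_ITEMS = ("RH", "PLA", "PLW", "BP")
_MENT_ITEMS = ("PELS", "BE", "PELW")

# Synthetic stand-in scoring weights (the real instrument's weights are
# license-restricted); both scales draw on all eight items, one scale
# dominated by the physical items, the other by the emotional ones.
_SYNTH_PHYS_W = (("RH", 0.30), ("PLA", 0.25), ("PLW", 0.25), ("BP", 0.20),
                 ("EN", 0.10), ("PELS", 0.05), ("BE", 0.02), ("PELW", 0.02))
_SYNTH_MENT_W = (("RH", 0.05), ("PLA", 0.02), ("PLW", 0.02), ("BP", 0.05),
                 ("EN", 0.20), ("PELS", 0.25), ("BE", 0.30), ("PELW", 0.25))

CARE_AIDE_CONTROL_PATHS = (
    ("EnoughStaff", "TiredAM"), ("EnoughStaff", "Rushed"), ("EnoughStaff", "Burntout"),
    ("Supportive", "Rushed"), ("Supportive", "Burntout"),
    ("DRAN", "TiredAM"), ("DRAN", "Rushed"), ("DRAN", "Burntout"),
    ("DRAN", "LookForward"),
    ("DRAS", "Rushed"), ("DRAS", "LookForward"),
    ("Sex", "TiredAM"), ("Sex", "Burntout"),
    ("Age", "TiredAM"), ("Age", "Burntout"),
    ("ESL", "Rushed"), ("ESL", "LookForward"),
)

CARE_AIDE_WORK_PATHS = (
    ("TiredAM", "Rushed"), ("TiredAM", "Burntout"), ("TiredAM", "LookForward"),
    ("Rushed", "Burntout"), ("Rushed", "LookForward"),
    ("Burntout", "LookForward"),
)


def care_aide_study_spec(direct_item_effects=()) -> FusionStudySpec:
    """Two-scale care-aide work-life study layout: eight
    items, two composite scales built from all eight (synthetic weights), four
    chained work-life downstream variables and seven controls with seventeen
    control paths.  The layout gives the canonical degrees of freedom: 11
    (scale-only), 35 (basic fusion), and 32 candidate item effects."""
    variables = tuple(VariableSummary(*row) for row in _CARE_AIDE_VARIABLES)
    return FusionStudySpec(
        variables=variables,
        scales=(ScaleDefinition("physical", _SYNTH_PHYS_W),
                ScaleDefinition("mental", _SYNTH_MENT_W)),
        downstream=("TiredAM", "Rushed", "Burntout", "LookForward"),
        controls=("EnoughStaff", "Supportive", "Sex", "Age", "ESL",
                  "DRAN", "DRAS"),
        structural_paths=CARE_AIDE_WORK_PATHS + CARE_AIDE_CONTROL_PATHS,
        direct_item_effects=tuple(direct_item_effects),
    )


def care_aide_scenario(direct_effects=()) -> GeneratingScenario:
    """Generating scenario for a care-aide work-life survey: realistic
    observed variances, weak-but-significant standardized effects (0.05-0.25),
    block-structured item correlations."""
    study = care_aide_study_spec()
    items = study.items
    exo_corr = {}
    for i, a in enumerate(items):
        for b in items[i + 1:]:
            if a in _PHYS_ITEMS and b in _PHYS_ITEMS:
                r = 0.45
            elif a in _MENT_ITEMS and b in _MENT_ITEMS:
                r = 0.45
            elif "EN" in (a, b):
                r = 0.40
            else:
                r = 0.30
            exo_corr[(a, b)] = r
    ctrls = study.controls
    for i, a in enumerate(ctrls):
        for b in ctrls[i + 1:]:
            exo_corr[(a, b)] = 0.05
    for a in items:
        for b in ctrls:
            exo_corr[(a, b)] = -0.05 if b in ("DRAN", "DRAS") else 0.05
    std_effects = {
        ("physical", "TiredAM"): -0.15, ("physical", "Rushed"): -0.10,
        ("physical", "Burntout"): -0.10, ("physical", "LookForward"): 0.10,
        ("mental", "TiredAM"): -0.15, ("mental", "Rushed"): -0.10,
        ("mental", "Burntout"): -0.20, ("mental", "LookForward"): 0.15,
        ("TiredAM", "Rushed"): 0.20, ("TiredAM", "Burntout"): 0.20,
        ("TiredAM", "LookForward"): -0.10,
        ("Rushed", "Burntout"): 0.20, ("Rushed", "LookForward"): -0.10,
        ("Burntout", "LookForward"): -0.20,
        ("EnoughStaff", "TiredAM"): -0.10, ("EnoughStaff", "Rushed"): -0.15,
        ("EnoughStaff", "Burntout"): -0.15,
        ("Supportive", "Rushed"): -0.10, ("Supportive", "Burntout"): -0.15,
        ("DRAN", "TiredAM"): 0.10, ("DRAN", "Rushed"): 0.15,
        ("DRAN", "Burntout"): 0.15, ("DRAN", "LookForward"): -0.10,
        ("DRAS", "Rushed"): 0.10, ("DRAS", "LookForward"): 0.05,
        ("Sex", "TiredAM"): 0.05, ("Sex", "Burntout"): 0.05,
        ("Age", "TiredAM"): 0.05, ("Age", "Burntout"): -0.05,
        ("ESL", "Rushed"): -0.05, ("ESL", "LookForward"): 0.05,
    }
    return _scenario(study, exo_corr, std_effects, direct_effects)
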