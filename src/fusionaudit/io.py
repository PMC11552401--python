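"""Readers and writers: covariance-matrix files and YAML study configurations.

Covariance files are plain text.  Comment lines start with ``#``; the first
data line is ``n: <sample size>``, the second the whitespace- (or comma-)
separated variable names, followed by the matrix in one of two dialects:

* ``square`` — p full rows of p entries;
* ``lower`` — lower triangle with diagonal, row i holding i+1 entries.

The study configuration is YAML with keys ``variables`` (name, mean,
variance or sd, error_percent), ``scales`` (name, weights, optional
constant), ``downstream``, ``controls``, ``structural_paths``,
``scale_effects`` (``all`` or a pair list) and ``direct_item_effects``.
Canonical re-serialization is byte-stable, so configs can be hashed for
replay.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .builder import ConfigError, FusionStudySpec, ScaleDefinition, VariableSummary

__all__ = [
    "CovarianceFile",
    "CovarianceFormatError",
    "read_covariance",
    "write_covariance",
    "read_study_config",
    "write_study_config",
    "study_config_text",
    "subset_covariance",
]

SYMMETRY_TOL = 1e-10


class CovarianceFormatError(ValueError):
    """Malformed covariance file; ``code`` distinguishes the failure mode."""

    def __init__(self, message: str, code: str):
        super().__init__(message)
        self.code = code


@dataclass(frozen=True)
class CovarianceFile:
    """A named sample covariance matrix with its sample size."""

    variable_names: tuple[str, ...]
    matrix: np.ndarray
    n: int
    dialect: str = "square"

    def __post_init__(self):
        p = len(self.variable_names)
        if len(set(self.variable_names)) != p:
            raise CovarianceFormatError("duplicate variable names", "duplicate-names")
        m = np.asarray(self.matrix, float)
        if m.shape != (p, p):
            raise CovarianceFormatError(
                f"matrix shape {m.shape} does not match {p} names", "shape")
        if np.max(np.abs(m - m.T)) > SYMMETRY_TOL * max(1.0, np.max(np.abs(m))):
            raise CovarianceFormatError("matrix asymmetric beyond tolerance",
                                        "asymmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))
        w = np.linalg.eigvalsh(self.matrix)
        if w[0] <= 0:
            raise CovarianceFormatError(
                f"matrix not positive definite (min eigenvalue {w[0]:.6e})",
                "not-positive-definite")


def _tokenize(line: str):
    return line.replace(",", " ").split()


def read_covariance(path, dialect: str | None = None) -> CovarianceFile:
    """Read a covariance file, sniffing the dialect when not declared."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    data = [ln for ln in lines if ln and not ln.startswith("#")]
    if not data or not data[0].replace(" ", "").lower().startswith("n:"):
        raise CovarianceFormatError("first data line must be 'n: <sample size>'",
                                    "missing-n")
    n = int(data[0].split(":", 1)[1])
    names = tuple(_tokenize(data[1]))
    p = len(names)
    rows = [[float(t) for t in _tokenize(ln)] for ln in data[2:]]
    if len(rows) != p:
        raise CovarianceFormatError(
            f"expected {p} matrix rows, found {len(rows)}", "row-count")
    if dialect is None:
        if all(len(r) == p for r in rows):
            dialect = "square"
        elif all(len(r) == i + 1 for i, r in enumerate(rows)):
            dialect = "lower"
        else:
            raise CovarianceFormatError("cannot sniff dialect from row lengths",
                                        "dialect")
    mat = np.zeros((p, p))
    if dialect == "square":
        for i, r in enumerate(rows):
            if len(r) != p:
                raise CovarianceFormatError(
                    f"square row {i} has {len(r)} entries, expected {p}", "row-length")
            mat[i] = r
    elif dialect == "lower":
        for i, r in enumerate(rows):
            if len(r) != i + 1:
                raise CovarianceFormatError(
                    f"lower-triangle row {i} has {len(r)} entries, expected {i + 1}",
                    "row-length")
            mat[i, :i + 1] = r
            mat[:i + 1, i] = r
    else:
        raise CovarianceFormatError(f"unknown dialect {dialect!r}", "dialect")
    return CovarianceFile(names, mat, n, dialect)


def write_covariance(path, cov: CovarianceFile, dialect: str | None = None) -> None:
    """Write a covariance file (full float precision, round-trip stable)."""
    dialect = dialect or cov.dialect
    buf = _io.StringIO()
    buf.write(f"n: {cov.n}\n")
    buf.write(" ".join(cov.variable_names) + "\n")
    p = len(cov.variable_names)
    for i in range(p):
        stop = p if dialect == "square" else i + 1
        buf.write(" ".join(repr(float(v)) for v in cov.matrix[i, :stop]) + "\n")
    Path(path).write_text(buf.getvalue())


def subset_covariance(cov_or_matrix, names, wanted):
    """Reorder/subset a covariance matrix to the ``wanted`` variables."""
    S = np.asarray(cov_or_matrix, float)
    names = list(names)
    missing = [w for w in wanted if w not in names]
    if missing:
        raise CovarianceFormatError(
            f"variables missing from the covariance matrix: {missing}", "missing-var")
    idx = [names.index(w) for w in wanted]
    return S[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# Study configuration
# ---------------------------------------------------------------------------


def _as_variable(entry: dict) -> VariableSummary:
    if "variance" in entry:
        var = float(entry["variance"])
    elif "sd" in entry:
        var = float(entry["sd"]) ** 2
    else:
        raise ConfigError(f"variable {entry.get('name')!r} needs 'variance' or 'sd'")
    return VariableSummary(name=str(entry["name"]),
                           mean=float(entry.get("mean", 0.0)),
                           variance=var,
                           error_percent=float(entry.get("error_percent", 0.0)))


def read_study_config(path) -> FusionStudySpec:
    """Load and validate a YAML study configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    return study_spec_from_mapping(raw)


def study_spec_from_mapping(raw: dict) -> FusionStudySpec:
    try:
        variables = tuple(_as_variable(v) for v in raw["variables"])
        scales = tuple(
            ScaleDefinition(scale_name=str(s["name"]),
                            item_weights=tuple((str(k), float(w))
                                               for k, w in s["weights"].items()),
                            constant=float(s.get("constant", 0.0)))
            for s in raw.get("scales", ()))
        se = raw.get("scale_effects", "all")
        scale_effects = None if se in ("all", None) else tuple(
            (str(a), str(b)) for a, b in se)
        return FusionStudySpec(
            variables=variables,
            scales=scales,
            downstream=tuple(str(d) for d in raw["downstream"]),
            controls=tuple(str(c) for c in raw.get("controls", ())),
            structural_paths=tuple((str(a), str(b))
                                   for a, b in raw.get("structural_paths", ())),
            scale_effects=scale_effects,
            direct_item_effects=tuple(
                (str(a), str(b)) for a, b in raw.get("direct_item_effects", ())),
        )
    except KeyError as exc:
        raise ConfigError(f"study config missing required key: {exc}") from exc


def study_config_text(study: FusionStudySpec) -> str:
    """Canonical YAML serialization (byte-stable across round trips)."""
    doc = {
        "variables": [
            {"name": v.name, "mean": float(v.mean), "variance": float(v.variance),
             "error_percent": float(v.error_percent)}
            for v in study.variables],
        "scales": [
            {"name": s.scale_name,
             "weights": {i: float(w) for i, w in s.item_weights},
             "constant": float(s.constant)}
            for s in study.scales],
        "downstream": list(study.downstream),
        "controls": list(study.controls),
        "structural_paths": [list(p) for p in study.structural_paths],
        "scale_effects": [list(p) for p in study.scale_effects],
        "direct_item_effects": [list(p) for p in study.direct_item_effects],
    }
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=None)


def write_study_config(path, study: FusionStudySpec) -> None:
    Path(path).write_text(study_config_text(study))
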