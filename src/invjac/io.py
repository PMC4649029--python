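"""Labeled matrix I/O, run configuration, and manifests.

Matrices (covariance, fluctuation, Jacobian, stoichiometry, pattern) travel
as comma-separated text with a header row and a first column of species
ids; '.' decimal, scientific notation accepted.  Files written and re-read
round-trip to full double precision.  A run configuration is a single YAML
file validated before any compute.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("invjac")

__all__ = [
    "read_matrix",
    "write_matrix",
    "export_linear_system",
    "RunConfig",
    "load_config",
    "write_manifest",
]


def write_matrix(path: str | Path, M: np.ndarray, labels: list[str]) -> None:
    """Write a labeled square/rectangular matrix as CSV (full precision)."""
    M = np.asarray(M)
    df = pd.DataFrame(M, index=labels[: M.shape[0]], columns=labels[: M.shape[1]] if M.shape[1] == len(labels) else [f"c{j}" for j in range(M.shape[1])])
    df.to_csv(path, float_format=lambda v: repr(float(v)))


def read_matrix(
    path: str | Path, labels: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a labeled CSV matrix; reorder rows/columns to ``labels`` if given.

    A label set differing from the model's raises with the symmetric
    difference; a mere reordering is canonicalized (and logged).
    """
    try:
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse numeric matrix: {exc}") from exc
    if not all(np.issubdtype(dt, np.number) for dt in df.dtypes):
        badcol = [c for c, dt in df.dtypes.items() if not np.issubdtype(dt, np.number)]
        for c in badcol:
            badrow = df[~df[c].apply(lambda v: _is_number(v))].index.tolist()
            raise ValueError(
                f"{path}: non-numeric cell at row {badrow[:1]}, column {c!r}"
            )
    file_labels = [str(x) for x in df.index]
    if labels is not None:
        diff = set(file_labels) ^ set(labels)
        if diff:
            raise ValueError(
                f"{path}: labels do not match the active model; "
                f"symmetric difference = {sorted(diff)}"
            )
        if file_labels != list(labels):
            logger.info("%s: reordering rows/columns to model species order", path)
            df = df.loc[labels]
            if set(df.columns) == set(labels):
                df = df[labels]
        file_labels = list(labels)
    return df.to_numpy(dtype=float), file_labels


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def export_linear_system(sys, prefix: str | Path) -> list[Path]:
    """Write A and b as delimited text plus a JSON index-map sidecar.

    Produces ``<prefix>_A.csv`` (n^2 x p coefficient matrix), ``<prefix>_b.csv``
    (right-hand side) and ``<prefix>_map.json`` (column -> Jacobian position,
    row -> equation position, condition number), for comparison against
    external solvers.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    a_path = prefix.with_name(prefix.name + "_A.csv")
    b_path = prefix.with_name(prefix.name + "_b.csv")
    map_path = prefix.with_name(prefix.name + "_map.json")
    np.savetxt(a_path, sys.A, delimiter=",", fmt="%.17g")
    np.savetxt(b_path, sys.b, delimiter=",", fmt="%.17g")
    map_path.write_text(json.dumps({
        "index_map": [list(ij) for ij in sys.index_map],
        "row_map": [list(ik) for ik in sys.row_map],
        "kappa_A": None if not np.isfinite(sys.kappa_A) else sys.kappa_A,
        "kappa_A_finite": None if not np.isfinite(sys.kappa_A_finite) else sys.kappa_A_finite,
    }, indent=2))
    return [a_path, b_path, map_path]


@dataclass
class RunConfig:
    """Validated configuration of a benchmark run."""

    model_sbml: str | None = None
    synthetic_n: int = 8
    synthetic_density: float = 0.3
    N: int = 2000
    dt: float | None = None
    burn_in: float | None = None
    rho: float = 0.05
    cov_fractions: list[float] = field(default_factory=lambda: [1.0, 0.5, 0.1, 0.02])
    sigma_levels: list[float] = field(default_factory=lambda: [0.01, 0.1, 1.0])
    repeats: int = 100
    methods: list[str] = field(default_factory=lambda: ["OLS", "TSVD", "TTLS", "TIKH"])
    truncation_threshold: float = 1e-8
    lambda_method: str = "cv"
    cv_folds: int = 5
    seed: int = 0
    output_dir: str = "invjac_out"

    def validate(self) -> None:
        errs = []
        if self.model_sbml is not None and not Path(self.model_sbml).exists():
            errs.append(f"model_sbml: file not found: {self.model_sbml}")
        if self.model_sbml is None and self.synthetic_n < 2:
            errs.append("synthetic_n must be >= 2")
        if not isinstance(self.seed, int):
            errs.append("seed must be an integer")
        if self.N < 2:
            errs.append("N must be >= 2")
        if not self.cov_fractions or not all(0 < f <= 1 for f in self.cov_fractions):
            errs.append("cov_fractions must be a non-empty list within (0, 1]")
        if not self.sigma_levels or any(s < 0 for s in self.sigma_levels):
            errs.append("sigma_levels must be non-empty and non-negative")
        if self.repeats < 1:
            errs.append("repeats must be >= 1")
        bad = [m for m in self.methods if m.upper() not in ("OLS", "TSVD", "TTLS", "TIKH")]
        if bad:
            errs.append(f"unknown methods: {bad}")
        if errs:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errs))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def write_manifest(out_dir: str | Path, config: dict, seed: int) -> Path:
    """JSON manifest (config echo, seed, versions) making runs reproducible."""
    import invjac

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "invjac": invjac.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
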